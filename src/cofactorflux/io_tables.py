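"""TSV/YAML interchange for tables used across the toolchain."""

from __future__ import annotations

from typing import Dict, List, Sequence

import pandas as pd

from .cofactor_augmentation import CofactorRequirement
from .biomass_cofactors import BindingRule
from .lp_engine import FluxRange, FluxSolution

__all__ = [
    "read_cofactor_table",
    "write_cofactor_table",
    "read_essentiality_reference",
    "read_binding_rules",
    "write_flux_solution",
    "write_flux_ranges",
]


def read_cofactor_table(path: str) -> List[CofactorRequirement]:
    """Columns: reaction_id, cofactor_species, coefficient[, mode]."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"reaction_id", "cofactor_species", "coefficient"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"cofactor table {path!r} lacks columns {sorted(missing)}")
    table = []
    for row in frame.itertuples(index=False):
        table.append(
            CofactorRequirement(
                reaction_id=str(row.reaction_id),
                cofactor_species_id=str(row.cofactor_species),
                coefficient=float(row.coefficient),
                mode=str(getattr(row, "mode", "free_to_spent")),
            )
        )
    return table


def write_cofactor_table(table: Sequence[CofactorRequirement], path: str) -> None:
    pd.DataFrame(
        {
            "reaction_id": [r.reaction_id for r in table],
            "cofactor_species": [r.cofactor_species_id for r in table],
            "coefficient": [r.coefficient for r in table],
            "mode": [r.mode for r in table],
        }
    ).to_csv(path, sep="\t", index=False)


def read_essentiality_reference(path: str) -> Dict[str, str]:
    """Columns: gene, essential (yes/no)."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    if not {"gene", "essential"} <= set(frame.columns):
        raise ValueError(
            f"essentiality reference {path!r} needs columns 'gene' and 'essential'"
        )
    return {str(r.gene): str(r.essential) for r in frame.itertuples(index=False)}


def read_binding_rules(path: str) -> List[BindingRule]:
    """Columns: entity, amino_acid, ratio. Multi-residue rules repeat the
    entity with one row per amino acid."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    if not {"entity", "amino_acid", "ratio"} <= set(frame.columns):
        raise ValueError(
            f"binding rules {path!r} need columns entity/amino_acid/ratio"
        )
    grouped: Dict[str, List] = {}
    for row in frame.itertuples(index=False):
        grouped.setdefault(str(row.entity), []).append(
            (str(row.amino_acid), int(row.ratio))
        )
    return [
        BindingRule(entity, tuple(a for a, _ in pairs), tuple(r for _, r in pairs))
        for entity, pairs in grouped.items()
    ]


def write_flux_solution(solution: FluxSolution, path: str) -> None:
    pd.DataFrame(
        {
            "reaction_id": list(solution.fluxes),
            "flux": list(solution.fluxes.values()),
        }
    ).to_csv(path, sep="\t", index=False)


def write_flux_ranges(ranges: FluxRange, path: str) -> None:
    pd.DataFrame(
        {
            "reaction_id": list(ranges.ranges),
            "minimum": [lo for lo, _ in ranges.ranges.values()],
            "maximum": [hi for _, hi in ranges.ranges.values()],
        }
    ).to_csv(path, sep="\t", index=False)
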
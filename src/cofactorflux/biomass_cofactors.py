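"""Biomass coefficients for iron entities from amino-acid binding rules.

Each iron entity (cluster, haem variant, mononuclear iron site) binds a
known number of residues of specific amino acids. Given the biomass
stoichiometric coefficients of those amino acids and the proteome
fraction of proteins bearing each entity, a per-entity biomass
coefficient is derived and injected into the biomass reaction, so iron
enters biomass through its entities rather than as a free ion (which
would let the iron flux be syphoned straight to biomass).

The default derivation is ``c_e = p_e * (sum of c_a) / r_total`` and is
isolated behind a strategy hook so an alternative weighting can replace
it without touching callers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Sequence, Tuple, Union

from .model_core import MetabolicModel

__all__ = [
    "BindingRule",
    "BiomassCofactorInput",
    "biomass_cofactor_coefficients",
    "inject_biomass_terms",
    "DEFAULT_BINDING_RULES",
]


@dataclass(frozen=True)
class BindingRule:
    """Residues of one or two amino acids binding a single iron entity."""

    entity: str
    amino_acids: Tuple[str, ...]
    residues_per_entity: Tuple[int, ...]

    def __init__(
        self,
        entity: str,
        amino_acids: Union[str, Sequence[str]],
        residues_per_entity: Union[int, Sequence[int]],
    ):
        aas = (amino_acids,) if isinstance(amino_acids, str) else tuple(amino_acids)
        res = (
            (residues_per_entity,)
            if isinstance(residues_per_entity, int)
            else tuple(residues_per_entity)
        )
        if len(aas) != len(res):
            raise ValueError("amino_acids and residues_per_entity lengths differ")
        if any(r < 1 for r in res):
            raise ValueError("residues_per_entity entries must be >= 1")
        object.__setattr__(self, "entity", entity)
        object.__setattr__(self, "amino_acids", aas)
        object.__setattr__(self, "residues_per_entity", res)

    @property
    def total_residues(self) -> int:
        return sum(self.residues_per_entity)


#: Binding ratios per iron entity (residues binding one entity).
DEFAULT_BINDING_RULES: List[BindingRule] = [
    BindingRule("4Fe-4S", "cysteine", 2),
    BindingRule("4Fe-4S (biotin synthase)", "arginine", 2),
    BindingRule("2Fe-2S (Rieske)", ("histidine", "cysteine"), (2, 2)),
    BindingRule("2Fe-2S (non-Rieske)", "cysteine", 4),
    BindingRule("haem b", "cysteine", 1),
    BindingRule("haem c", "cysteine", 2),
    BindingRule("Fe(III)-mono", "cysteine", 4),
]


@dataclass
class BiomassCofactorInput:
    """Inputs for the coefficient derivation.

    ``entity_proteome_fraction`` is the fraction of the proteome
    attributable to proteins bearing each entity. Whether this should
    be a residue-count, protein-copy or mass fraction is a property of
    the upstream proteomics extraction, not of this computation; the
    value is used as given.
    """

    aa_biomass_coefficients: Dict[str, float]  # mmol/gDW
    entity_proteome_fraction: Dict[str, float]  # in [0, 1]
    binding_rules: List[BindingRule] = field(
        default_factory=lambda: list(DEFAULT_BINDING_RULES)
    )

    def __post_init__(self) -> None:
        for aa, c in self.aa_biomass_coefficients.items():
            if c < 0:
                raise ValueError(f"negative biomass coefficient for {aa!r}")
        for entity, p in self.entity_proteome_fraction.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"proteome fraction for {entity!r} must lie in [0, 1], got {p}"
                )


Strategy = Callable[[float, int, float], float]


def _ratio_weighted(total_aa_coefficient: float, total_residues: int, fraction: float) -> float:
    return fraction * total_aa_coefficient / total_residues


def biomass_cofactor_coefficients(
    inputs: BiomassCofactorInput, strategy: Strategy = _ratio_weighted
) -> Dict[str, float]:
    """Per-entity biomass coefficients (mmol/gDW).

    Only entities with a proteome fraction are computed; every amino
    acid referenced by the corresponding binding rule must have a
    biomass coefficient.
    """
    coefficients: Dict[str, float] = {}
    rules = {rule.entity: rule for rule in inputs.binding_rules}
    for entity, fraction in inputs.entity_proteome_fraction.items():
        if entity not in rules:
            raise KeyError(f"no binding rule for entity {entity!r}")
        rule = rules[entity]
        total = 0.0
        for aa in rule.amino_acids:
            if aa not in inputs.aa_biomass_coefficients:
                raise KeyError(
                    f"amino acid {aa!r} (required by entity {entity!r}) has no "
                    "biomass coefficient"
                )
            total += inputs.aa_biomass_coefficients[aa]
        coefficients[entity] = strategy(total, rule.total_residues, fraction)
    return coefficients


def inject_biomass_terms(
    model: MetabolicModel, coefficients: Dict[str, float]
) -> MetabolicModel:
    """Make the biomass reaction consume each entity at its coefficient."""
    out = model.copy()
    biomass = out.objective_reaction
    for entity, coeff in coefficients.items():
        if coeff == 0.0:
            continue
        if not out.has_species(entity):
            raise KeyError(f"entity species {entity!r} absent from model")
        biomass.stoichiometry[entity] = (
            biomass.stoichiometry.get(entity, 0.0) - coeff
        )
    return out
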
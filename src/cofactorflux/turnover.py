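"""Cofactor-recruiting enzyme turnover.

The total turnover is the coefficient-weighted sum of absolute fluxes
over all cofactor-augmented reactions, in mmol·gDW⁻¹·h⁻¹. In
free-to-spent mode this equals the total flux into the spent-cofactor
pools, which provides an internal consistency check. A coefficient
sweep locates the largest coefficient magnitude that does not impair
growth, and FVA at the growth optimum brackets the turnover between
its theoretical minimum and maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .cofactor_augmentation import (
    CofactorRequirement,
    augment_model,
    drain_reaction_id,
)
from .lp_engine import FluxSolution, flux_variability, optimize_growth
from .model_core import MetabolicModel

__all__ = [
    "TurnoverResult",
    "SweepCurve",
    "sweep_coefficient",
    "total_turnover",
    "turnover_range_gap",
]


@dataclass
class TurnoverResult:
    total: float
    per_reaction: Dict[str, float]
    minimum: float
    maximum: float
    coefficient_magnitude: float
    spent_pool_total: Optional[float] = None

    def __post_init__(self) -> None:
        if self.total < -1e-12:
            raise ValueError("turnover total must be non-negative")


@dataclass
class SweepCurve:
    points: List[Tuple[float, float]]  # (coefficient magnitude, growth flux)
    baseline_growth: float
    knee: Optional[float]
    delta: float = 0.01

    @property
    def magnitudes(self) -> List[float]:
        return [m for m, _ in self.points]

    @property
    def growths(self) -> List[float]:
        return [g for _, g in self.points]


def _scaled_table(
    table: Sequence[CofactorRequirement], magnitude: float
) -> List[CofactorRequirement]:
    """Rescale all coefficients so the largest equals *magnitude*.

    Per-row relative weights are preserved: an enzyme recruiting two
    clusters keeps recruiting twice as much as a one-cluster enzyme.
    """
    max_coeff = max(req.coefficient for req in table)
    if max_coeff <= 0:
        raise ValueError("requirement table has no positive coefficient")
    return [
        CofactorRequirement(
            reaction_id=req.reaction_id,
            cofactor_species_id=req.cofactor_species_id,
            coefficient=req.coefficient / max_coeff * magnitude,
            mode=req.mode,
        )
        for req in table
    ]


def sweep_coefficient(
    model: MetabolicModel,
    table: Sequence[CofactorRequirement],
    magnitudes: Sequence[float],
    delta: float = 0.01,
) -> SweepCurve:
    """Growth as a function of the global cofactor coefficient magnitude.

    *model* is the unaugmented network; each grid point augments it
    with the table rescaled to that magnitude and re-optimises growth.
    The knee is the largest magnitude whose growth stays within
    ``delta`` of the unaugmented baseline.
    """
    if not table:
        raise ValueError("requirement table is empty")
    mags = list(magnitudes)
    if any(m < 0 for m in mags):
        raise ValueError("magnitudes must be non-negative")
    if mags != sorted(mags):
        raise ValueError("magnitudes must be sorted ascending")
    baseline = optimize_growth(model, selection_rule="solver_default")
    if not baseline.optimal:
        raise RuntimeError(f"unaugmented model FBA is {baseline.status}")
    points: List[Tuple[float, float]] = []
    for magnitude in mags:
        if magnitude == 0.0:
            points.append((0.0, baseline.objective_value))
            continue
        augmented = augment_model(model, _scaled_table(table, magnitude))
        sol = optimize_growth(augmented, selection_rule="solver_default")
        growth = sol.objective_value if sol.optimal else 0.0
        points.append((magnitude, growth))
    floor = (1.0 - delta) * baseline.objective_value
    admissible = [m for m, g in points if g >= floor]
    knee = max(admissible) if admissible else None
    return SweepCurve(
        points=points,
        baseline_growth=baseline.objective_value,
        knee=knee,
        delta=delta,
    )


def total_turnover(
    model: MetabolicModel,
    table: Sequence[CofactorRequirement],
    solution: Optional[FluxSolution] = None,
    compute_range: bool = True,
) -> TurnoverResult:
    """Coefficient-weighted total flux through the augmented reactions.

    Reversible augmented reactions contribute |v|: the cofactor is
    recruited regardless of direction. The FVA-based minimum/maximum
    take, per reaction, the smallest/largest |v| admissible at 100% of
    the growth optimum, so ``minimum <= total <= maximum``.

    In free-to-spent mode the summed drain fluxes of the spent pools
    are reported alongside (``spent_pool_total``); mass balance forces
    them to agree with the coefficient-weighted sum.
    """
    if not table:
        raise ValueError("requirement table is empty")
    missing = [req.reaction_id for req in table if not model.has_reaction(req.reaction_id)]
    if missing:
        raise ValueError(
            f"requirement table references reactions absent from model: {missing}"
        )
    if solution is None:
        solution = optimize_growth(model)
    if not solution.optimal:
        raise RuntimeError(f"flux solution is {solution.status}; turnover undefined")

    per_reaction: Dict[str, float] = {}
    for req in table:
        v = solution.fluxes[req.reaction_id]
        per_reaction[req.reaction_id] = (
            per_reaction.get(req.reaction_id, 0.0) + req.coefficient * abs(v)
        )
    total = sum(per_reaction.values())

    spent_total: Optional[float] = None
    drain_ids = {
        drain_reaction_id(req.cofactor_species_id)
        for req in table
        if req.mode == "free_to_spent"
    }
    if drain_ids and all(model.has_reaction(d) for d in drain_ids):
        spent_total = sum(solution.fluxes[d] for d in drain_ids)

    minimum = maximum = total
    if compute_range:
        aug_ids = sorted({req.reaction_id for req in table})
        fva = flux_variability(model, fraction_of_optimum=1.0, reactions=aug_ids)
        coeff_of: Dict[str, float] = {}
        for req in table:
            coeff_of[req.reaction_id] = coeff_of.get(req.reaction_id, 0.0) + req.coefficient
        minimum = 0.0
        maximum = 0.0
        for rid in aug_ids:
            lo, hi = fva[rid]
            smallest_abs = 0.0 if lo <= 0.0 <= hi else min(abs(lo), abs(hi))
            largest_abs = max(abs(lo), abs(hi))
            minimum += coeff_of[rid] * smallest_abs
            maximum += coeff_of[rid] * largest_abs
        # guard against solver noise inverting the bracket
        minimum = min(minimum, total)
        maximum = max(maximum, total)

    return TurnoverResult(
        total=total,
        per_reaction=per_reaction,
        minimum=minimum,
        maximum=maximum,
        coefficient_magnitude=max(req.coefficient for req in table),
        spent_pool_total=spent_total,
    )


def turnover_range_gap(
    result: TurnoverResult,
) -> Tuple[Optional[float], Optional[float]]:
    """Relative gaps (total-min)/min and (max-total)/total.

    With a zero minimum the first gap is undefined and reported None.
    """
    gap_to_min: Optional[float]
    if result.minimum > 0:
        gap_to_min = (result.total - result.minimum) / result.minimum
    else:
        gap_to_min = None
    gap_to_max = (
        (result.maximum - result.total) / result.total if result.total > 0 else None
    )
    return gap_to_min, gap_to_max
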
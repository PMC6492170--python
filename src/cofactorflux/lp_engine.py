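"""Steady-state flux optimisation.

FBA growth maximisation and flux variability analysis on top of
scipy's HiGHS linear-programming backend, plus a deterministic
minimal-total-flux (parsimonious) selection rule so that flux vectors
are reproducible across solvers and reaction orderings, and a
precision guard for very small stoichiometric coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model_core import MetabolicModel

__all__ = [
    "FluxSolution",
    "FluxRange",
    "PrecisionReport",
    "optimize_growth",
    "flux_variability",
    "precision_guard",
    "rescale_cofactor_units",
    "DEFAULT_FEASIBILITY_TOL",
]

#: Default solver feasibility/optimality tolerance. Sits at least two
#: orders of magnitude below the smallest admissible stoichiometric
#: coefficient once ``precision_guard`` has been satisfied.
DEFAULT_FEASIBILITY_TOL = 1e-9

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


@dataclass
class FluxSolution:
    fluxes: Dict[str, float]
    objective_value: float
    status: str
    selection_rule: str = "solver_default"

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


@dataclass
class FluxRange:
    ranges: Dict[str, Tuple[float, float]]
    fraction_of_optimum: float = 1.0

    def __getitem__(self, reaction_id: str) -> Tuple[float, float]:
        return self.ranges[reaction_id]

    def __iter__(self):
        return iter(self.ranges)

    def items(self):
        return self.ranges.items()


def _lp_arrays(model: MetabolicModel):
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    rids = model.reaction_ids()
    obj = np.zeros(len(rids))
    if model.objective is not None:
        obj[rids.index(model.objective)] = 1.0
    return S, lb, ub, rids, obj


def _solve(c, A_eq, b_eq, bounds, A_ub=None, b_ub=None):
    return linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )


def _min_total_flux_vector(S, lb, ub, obj, optimum, tol):
    """Second stage: minimise sum |v| at (numerically) fixed optimum."""
    n = S.shape[1]
    # v = p - q with p, q >= 0; sign-fixed reactions keep their bounds on
    # the active half so forced fluxes (positive lower bounds) survive
    p_bounds = []
    q_bounds = []
    for lo, hi in zip(lb, ub):
        if lo >= 0.0:
            p_bounds.append((lo, hi))
            q_bounds.append((0.0, 0.0))
        elif hi <= 0.0:
            p_bounds.append((0.0, 0.0))
            q_bounds.append((-hi, -lo))
        else:
            p_bounds.append((0.0, hi))
            q_bounds.append((0.0, -lo))
    bounds = p_bounds + q_bounds
    A_eq = sparse.hstack([S, -S]).tocsr()
    b_eq = np.zeros(S.shape[0])
    # keep objective at optimum (tiny relaxation guards against round-off)
    relax = tol * max(1.0, abs(optimum))
    A_ub = sparse.csr_matrix(np.concatenate([-obj, obj])[None, :])
    b_ub = np.array([-(optimum - relax)])
    c = np.ones(2 * n)
    res = _solve(c, A_eq, b_eq, bounds, A_ub=A_ub, b_ub=b_ub)
    if res.status != 0:
        return None
    v = res.x[:n] - res.x[n:]
    return v


def optimize_growth(
    model: MetabolicModel,
    selection_rule: str = "min_total_flux",
    tol: float = DEFAULT_FEASIBILITY_TOL,
) -> FluxSolution:
    """Maximise the model objective subject to S·v = 0 and flux bounds.

    With ``selection_rule="min_total_flux"`` a second LP minimises the
    total absolute flux at the fixed optimal objective, which removes
    LP degeneracy from the returned vector. ``"solver_default"``
    returns the first-stage vertex as reported by HiGHS.
    """
    if selection_rule not in ("min_total_flux", "solver_default"):
        raise ValueError(f"unknown selection rule {selection_rule!r}")
    model.objective_reaction  # raises with instructions if unset
    S, lb, ub, rids, obj = _lp_arrays(model)
    res = _solve(-obj, S.tocsr(), np.zeros(S.shape[0]), list(zip(lb, ub)))
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxSolution({}, math.nan, status, selection_rule)
    optimum = float(obj @ res.x)
    v = res.x
    if selection_rule == "min_total_flux":
        v2 = _min_total_flux_vector(S, lb, ub, obj, optimum, tol)
        if v2 is not None:
            v = v2
    return FluxSolution(
        fluxes=dict(zip(rids, (float(x) for x in v))),
        objective_value=optimum,
        status="optimal",
        selection_rule=selection_rule,
    )


def flux_variability(
    model: MetabolicModel,
    fraction_of_optimum: float = 1.0,
    reactions: Optional[Iterable[str]] = None,
    tol: float = DEFAULT_FEASIBILITY_TOL,
) -> FluxRange:
    """Per-reaction flux minima/maxima at a fraction of the optimum."""
    if not 0 < fraction_of_optimum <= 1:
        raise ValueError("fraction_of_optimum must lie in (0, 1]")
    base = optimize_growth(model, selection_rule="solver_default", tol=tol)
    if not base.optimal:
        raise RuntimeError(f"base FBA problem is {base.status}; FVA impossible")
    S, lb, ub, rids, obj = _lp_arrays(model)
    S = S.tocsr()
    b_eq = np.zeros(S.shape[0])
    bounds = list(zip(lb, ub))
    target = fraction_of_optimum * base.objective_value
    relax = tol * max(1.0, abs(target))
    A_ub = sparse.csr_matrix(-obj[None, :])
    b_ub = np.array([-(target - relax)])
    wanted = list(reactions) if reactions is not None else rids
    index = {r: i for i, r in enumerate(rids)}
    ranges: Dict[str, Tuple[float, float]] = {}
    n = len(rids)
    for rid in wanted:
        j = index[rid]
        c = np.zeros(n)
        c[j] = 1.0
        lo = _solve(c, S, b_eq, bounds, A_ub=A_ub, b_ub=b_ub)
        hi = _solve(-c, S, b_eq, bounds, A_ub=A_ub, b_ub=b_ub)
        if lo.status != 0 or hi.status != 0:
            raise RuntimeError(f"FVA subproblem for {rid!r} failed")
        vmin, vmax = float(lo.x[j]), float(hi.x[j])
        if vmin > vmax:  # numerical ordering noise on degenerate ranges
            vmin, vmax = vmax, vmin
        ranges[rid] = (vmin, vmax)
    return FluxRange(ranges=ranges, fraction_of_optimum=fraction_of_optimum)


# ---------------------------------------------------------------------------
# precision guard
# ---------------------------------------------------------------------------

@dataclass
class PrecisionReport:
    """Outcome of the solver-precision audit.

    The pass criterion requires every stoichiometric coefficient to be
    at least two orders of magnitude above the solver feasibility
    tolerance; otherwise a unit rescaling of the offending cofactor
    species is suggested.
    """

    min_abs_coefficient: float
    min_abs_coefficient_location: str
    min_abs_bound: float
    solver_feasibility_tol: float
    passed: bool
    suggested_rescale_k: int = 0
    message: str = ""
    offending: list = field(default_factory=list)


def precision_guard(
    model: MetabolicModel, solver_feasibility_tol: float = DEFAULT_FEASIBILITY_TOL
) -> PrecisionReport:
    """Audit coefficient magnitudes against the 100x-tolerance rule."""
    min_coeff = math.inf
    location = ""
    offending = []
    # small relative slack so k-fold power-of-ten rescales land exactly on
    # the floor instead of a few ulp below it
    floor = 100.0 * solver_feasibility_tol * (1.0 - 1e-9)
    for rxn in model.reactions:
        entries = dict(rxn.stoichiometry)
        for sid, x in rxn.literal_cofactors().items():
            entries.setdefault(sid, x)
        for sid, coeff in entries.items():
            a = abs(coeff)
            if a == 0.0:
                continue
            if a < min_coeff:
                min_coeff = a
                location = f"{rxn.id}/{sid}"
            if a < floor:
                offending.append((rxn.id, sid, coeff))
    min_bound = math.inf
    for rxn in model.reactions:
        for b in (rxn.lower_bound, rxn.upper_bound):
            if b != 0 and abs(b) < min_bound:
                min_bound = abs(b)
    passed = min_coeff >= floor
    k = 0
    if not passed:
        k = math.ceil(math.log10(floor / min_coeff))
    message = (
        "all stoichiometric coefficients sit >= 100x above the solver "
        "feasibility tolerance"
        if passed
        else (
            f"smallest coefficient {min_coeff:.3e} at {location} is below "
            f"100 x tolerance = {floor:.3e}; rescale the affected cofactor "
            f"species units by 10^{k} (rescale_cofactor_units with k >= {k}) "
            "or tighten the solver tolerance"
        )
    )
    return PrecisionReport(
        min_abs_coefficient=min_coeff,
        min_abs_coefficient_location=location,
        min_abs_bound=min_bound,
        solver_feasibility_tol=solver_feasibility_tol,
        passed=passed,
        suggested_rescale_k=k,
        message=message,
        offending=offending,
    )


def rescale_cofactor_units(
    model: MetabolicModel, species_ids: Iterable[str], k: int
) -> MetabolicModel:
    """Express the given cofactor species in 10^-k smaller units.

    Stoichiometric coefficients of the species are multiplied by 10^k
    everywhere; pure cofactor exchange/drain reactions keep unit
    stoichiometry and have their bounds scaled by 10^k instead (their
    flux is now reported in the new units). Fluxes of all
    real-metabolite reactions are invariant under this change.
    """
    target = set(species_ids)
    factor = 10.0 ** k
    out = model.copy()
    for rxn in out.reactions:
        involved = set(rxn.stoichiometry) | set(rxn.literal_cofactors())
        if involved and involved <= target:
            # pure cofactor mover: rescale its flux units via the bounds
            rxn.lower_bound *= factor
            rxn.upper_bound *= factor
            continue
        for sid in list(rxn.stoichiometry):
            if sid in target:
                rxn.stoichiometry[sid] *= factor
        for sid, x in rxn.literal_cofactors().items():
            if sid in target:
                rxn.annotations[f"cofactor:{sid}"] = repr(x * factor)
    return out
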
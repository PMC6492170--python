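"""Environmental and genetic perturbations and flux-rewiring analysis.

Reduction-of-function mimics hemizygosity by capping the bounds of a
gene's reactions at a fraction of their wild-type flux in the wild-type
direction; exchange scaling mimics medium composition changes; flux
change classification compares two solutions reaction by reaction and
labels each as unchanged, scaled-as-expected, changed above a relative
threshold, or rewired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

from .essentiality import delete_gene
from .lp_engine import FluxSolution, optimize_growth
from .model_core import MetabolicModel

__all__ = [
    "ReductionOfFunction",
    "FluxChangeClassification",
    "reduce_function",
    "scale_exchange",
    "classify_flux_changes",
    "threshold_sensitivity",
    "qualitative_benchmark",
    "LABELS",
]

#: Classification labels. ``below_threshold`` covers relative changes
#: larger than the noise tolerance but not above the reporting
#: threshold; it exists so the labels partition the compared set.
LABELS = (
    "inactive_both",
    "unchanged",
    "scaled_as_expected",
    "below_threshold",
    "changed_above_threshold",
    "rewired",
)

DEFAULT_FLUX_TOLERANCE = 1e-6
DEFAULT_CHANGE_THRESHOLD = 0.25
DEFAULT_QUALITATIVE_TOLERANCE = 0.01


@dataclass
class ReductionOfFunction:
    """Record of one reduction-of-function perturbation."""

    gene: str
    fraction: float
    affected_reactions: List[str] = field(default_factory=list)
    wild_type_fluxes: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction < 1.0:
            raise ValueError(
                f"reduction fraction must lie strictly in (0, 1), got {self.fraction}"
            )


@dataclass
class FluxChangeClassification:
    labels: Dict[str, str]
    threshold: float
    tolerance: float
    expected_scale: Optional[float] = None

    @property
    def counts(self) -> Dict[str, int]:
        out = {label: 0 for label in LABELS}
        for label in self.labels.values():
            out[label] += 1
        return out

    def reactions_with(self, label: str) -> List[str]:
        return sorted(r for r, l in self.labels.items() if l == label)


def reduce_function(
    model: MetabolicModel,
    gene: str,
    fraction: float,
    wild_type_solution: FluxSolution,
    flux_tolerance: float = DEFAULT_FLUX_TOLERANCE,
) -> MetabolicModel:
    """Cap the gene's reactions at *fraction* of their wild-type flux.

    Both bounds are capped in the wild-type flux direction (the
    opposite direction is closed), so the perturbed reaction cannot
    compensate by reversing. Nutrient-uptake exchanges are not eligible
    targets; gene-associated reactions never are exchanges in practice,
    and any that are get rejected.
    """
    record = ReductionOfFunction(gene=gene, fraction=fraction)  # validates fraction
    if gene not in model.genes:
        raise KeyError(f"gene {gene!r} not in model {model.id!r}")
    out = model.copy()
    touched = 0
    for rxn in out.reactions:
        if rxn.gpr is None or gene not in rxn.gpr.genes():
            continue
        if rxn.is_exchange:
            raise ValueError(
                f"reduction of function must not touch nutrient-uptake exchange "
                f"{rxn.id!r}"
            )
        wt = wild_type_solution.fluxes.get(rxn.id, 0.0)
        record.affected_reactions.append(rxn.id)
        record.wild_type_fluxes[rxn.id] = wt
        if abs(wt) <= flux_tolerance:
            continue
        if wt > 0:
            rxn.lower_bound = 0.0
            rxn.upper_bound = fraction * wt
        else:
            rxn.lower_bound = fraction * wt
            rxn.upper_bound = 0.0
        touched += 1
    if not record.affected_reactions:
        raise KeyError(f"gene {gene!r} catalyses no reactions in model {model.id!r}")
    if touched == 0:
        warnings.warn(
            f"all reactions of gene {gene!r} carry zero wild-type flux; "
            "model returned unchanged",
            stacklevel=2,
        )
    out.annotations[f"reduced:{gene}"] = repr(fraction)
    return out


def scale_exchange(
    model: MetabolicModel, species_id: str, factor: float
) -> MetabolicModel:
    """Multiply the bound magnitudes of the species' exchange reactions."""
    if factor < 0:
        raise ValueError("scale factor must be >= 0")
    out = model.copy()
    hits = 0
    for rxn in out.reactions:
        if rxn.is_exchange and species_id in rxn.stoichiometry:
            rxn.lower_bound *= factor
            rxn.upper_bound *= factor
            hits += 1
    if hits == 0:
        raise KeyError(f"no exchange reaction found for species {species_id!r}")
    return out


def classify_flux_changes(
    ref: FluxSolution,
    new: FluxSolution,
    threshold: float = DEFAULT_CHANGE_THRESHOLD,
    tolerance: float = DEFAULT_FLUX_TOLERANCE,
    expected_scale: Optional[float] = None,
) -> FluxChangeClassification:
    """Label each shared reaction by how its flux changed.

    Relative change is ``|v_new - v_ref| / max(|v_ref|, tolerance)``;
    the tolerance also serves as the zero-flux floor. Zero<->nonzero
    transitions and sign flips are ``rewired``; with *expected_scale*
    given, any change that is neither unchanged nor the expected scaling
    is ``rewired`` as well.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    shared = sorted(set(ref.fluxes) & set(new.fluxes))
    if not shared:
        raise ValueError("flux solutions share no reaction ids")
    labels: Dict[str, str] = {}
    for rid in shared:
        v_ref = ref.fluxes[rid]
        v_new = new.fluxes[rid]
        ref_zero = abs(v_ref) <= tolerance
        new_zero = abs(v_new) <= tolerance
        if ref_zero and new_zero:
            labels[rid] = "inactive_both"
            continue
        if ref_zero != new_zero or v_ref * v_new < 0:
            labels[rid] = "rewired"
            continue
        rel = abs(v_new - v_ref) / max(abs(v_ref), tolerance)
        if rel <= tolerance:
            labels[rid] = "unchanged"
            continue
        if expected_scale is not None:
            scale = v_new / v_ref
            if abs(scale - expected_scale) <= max(tolerance, 1e-9):
                labels[rid] = "scaled_as_expected"
            else:
                labels[rid] = "rewired"
            continue
        labels[rid] = "changed_above_threshold" if rel > threshold else "below_threshold"
    return FluxChangeClassification(
        labels=labels,
        threshold=threshold,
        tolerance=tolerance,
        expected_scale=expected_scale,
    )


def threshold_sensitivity(
    ref: FluxSolution,
    new: FluxSolution,
    thresholds: Sequence[float],
    tolerance: float = DEFAULT_FLUX_TOLERANCE,
) -> Dict[float, Dict[str, int]]:
    """Classification counts across a sweep of change thresholds."""
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    return {
        th: classify_flux_changes(ref, new, threshold=th, tolerance=tolerance).counts
        for th in thresholds
    }


def _apply_perturbation(
    model: MetabolicModel,
    perturbation: Dict,
    control_solution: FluxSolution,
) -> MetabolicModel:
    kind = perturbation.get("type")
    if kind == "scale_exchange":
        return scale_exchange(
            model, perturbation["species"], float(perturbation["factor"])
        )
    if kind == "delete_gene":
        return delete_gene(model, perturbation["gene"])
    if kind == "reduce_function":
        return reduce_function(
            model,
            perturbation["gene"],
            float(perturbation["fraction"]),
            control_solution,
        )
    if kind == "set_bounds":
        out = model.copy()
        rxn = out.get_reaction(perturbation["reaction"])
        rxn.lower_bound = float(perturbation["lower_bound"])
        rxn.upper_bound = float(perturbation["upper_bound"])
        return out
    raise ValueError(f"unknown perturbation type {kind!r}")


def qualitative_benchmark(
    model: MetabolicModel,
    scenario: Sequence[Dict],
    reporters: Iterable[str],
    tolerance: float = DEFAULT_QUALITATIVE_TOLERANCE,
) -> Dict[str, str]:
    """Direction of reporter flux changes under a perturbation scenario.

    *scenario* is a list of perturbation dicts (``type`` plus
    arguments, see :func:`_apply_perturbation`) applied in order to a
    copy of the model. Reporter fluxes are compared by magnitude
    against the unperturbed control: within *tolerance* relative is
    ``same``, otherwise ``up`` or ``down``.
    """
    reporters = list(reporters)
    missing = [r for r in reporters if not model.has_reaction(r)]
    if missing:
        raise KeyError(f"reporter reactions missing from model: {missing}")
    control = optimize_growth(model)
    if not control.optimal:
        raise RuntimeError(f"control FBA is {control.status}")
    perturbed_model = model
    for perturbation in scenario:
        perturbed_model = _apply_perturbation(perturbed_model, perturbation, control)
    perturbed = optimize_growth(perturbed_model)
    out: Dict[str, str] = {}
    for rid in reporters:
        before = abs(control.fluxes[rid])
        after = abs(perturbed.fluxes[rid]) if perturbed.optimal else 0.0
        denom = max(before, DEFAULT_FLUX_TOLERANCE)
        if abs(after - before) / denom <= tolerance:
            out[rid] = "same"
        else:
            out[rid] = "up" if after > before else "down"
    return out
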
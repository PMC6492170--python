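"""In-silico single-gene deletions and predictive-power evaluation.

A gene deletion closes every reaction whose GPR evaluates false with
that gene removed (OR keeps isoenzyme-backed reactions alive, AND kills
complexes). Predictions are scored against reference viability labels
in a confusion matrix whose positive class is "viable".
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, List, Optional, Tuple

from .lp_engine import optimize_growth
from .model_core import MetabolicModel

__all__ = [
    "ConfusionMatrix",
    "EssentialityCall",
    "ConfusionMetrics",
    "delete_gene",
    "evaluate_essentiality",
    "confusion_metrics",
    "round_half_up",
]

VIABLE = "viable"
INVIABLE = "inviable"
UNKNOWN = "unknown"

#: Deletion strains growing below this fraction of wild type are called
#: inviable. Conventional choice; configurable everywhere it is used.
DEFAULT_VIABILITY_THRESHOLD = 0.01


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with positive class = viable (predicted and observed)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class EssentialityCall:
    gene: str
    predicted: str
    observed: str
    growth_ratio: float


def round_half_up(value: float) -> int:
    """Round to integer with ties away from zero (.5 rounds up)."""
    return int(Decimal(repr(value)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMetrics:
    """Percentages; a metric with a zero denominator is None (undefined)."""

    ppv: Optional[float]
    npv: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    predictive_success: Optional[float]

    def rounded(self) -> Dict[str, Optional[int]]:
        return {
            name: (None if value is None else round_half_up(value))
            for name, value in (
                ("ppv", self.ppv),
                ("npv", self.npv),
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity),
                ("predictive_success", self.predictive_success),
            )
        }


def confusion_metrics(cm: ConfusionMatrix) -> ConfusionMetrics:
    """PPV, NPV, sensitivity, specificity and predictive success in %."""

    def ratio(num: int, den: int) -> Optional[float]:
        return None if den == 0 else 100.0 * num / den

    return ConfusionMetrics(
        ppv=ratio(cm.tp, cm.tp + cm.fp),
        npv=ratio(cm.tn, cm.tn + cm.fn),
        sensitivity=ratio(cm.tp, cm.tp + cm.fn),
        specificity=ratio(cm.tn, cm.tn + cm.fp),
        predictive_success=ratio(cm.tp + cm.tn, cm.n_genes),
    )


def delete_gene(model: MetabolicModel, gene: str) -> MetabolicModel:
    """Close every reaction whose GPR fails without *gene*."""
    if gene not in model.genes:
        raise KeyError(f"gene {gene!r} not in model {model.id!r}")
    out = model.copy()
    for rxn in out.reactions:
        if rxn.gpr is not None and not rxn.gpr.evaluate({gene}):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out


def _deletion_growth_ratio(
    model: MetabolicModel, gene: str, wild_type_objective: float
) -> float:
    sol = optimize_growth(delete_gene(model, gene), selection_rule="solver_default")
    if not sol.optimal:
        return 0.0
    return max(0.0, sol.objective_value) / wild_type_objective


def evaluate_essentiality(
    model: MetabolicModel,
    reference: Dict[str, str],
    threshold: float = DEFAULT_VIABILITY_THRESHOLD,
) -> Tuple[List[EssentialityCall], ConfusionMatrix]:
    """One deletion FBA per referenced gene, scored against observations.

    *reference* maps gene ids to ``viable``/``inviable`` (``yes``/``no``
    essentiality shorthand is accepted: yes = essential = inviable).
    Genes with unknown observations are excluded from the matrix but
    still reported in the calls.
    """
    if not 0 < threshold < 1:
        raise ValueError("viability threshold must lie strictly in (0, 1)")
    wild_type = optimize_growth(model, selection_rule="solver_default")
    if not wild_type.optimal or wild_type.objective_value <= 0:
        raise RuntimeError(
            f"wild-type FBA is {wild_type.status} with objective "
            f"{wild_type.objective_value}; cannot evaluate essentiality"
        )
    normalise = {
        "viable": VIABLE,
        "inviable": INVIABLE,
        "no": VIABLE,
        "yes": INVIABLE,
        "unknown": UNKNOWN,
    }
    calls: List[EssentialityCall] = []
    tp = tn = fp = fn = 0
    for gene in sorted(reference):
        observed = normalise.get(str(reference[gene]).strip().lower())
        if observed is None:
            raise ValueError(
                f"unrecognised essentiality label {reference[gene]!r} for {gene!r}"
            )
        if gene not in model.genes:
            calls.append(EssentialityCall(gene, UNKNOWN, observed, 1.0))
            continue
        ratio = _deletion_growth_ratio(model, gene, wild_type.objective_value)
        predicted = INVIABLE if ratio < threshold else VIABLE
        calls.append(EssentialityCall(gene, predicted, observed, ratio))
        if observed == UNKNOWN:
            continue
        if predicted == VIABLE and observed == VIABLE:
            tp += 1
        elif predicted == INVIABLE and observed == INVIABLE:
            tn += 1
        elif predicted == VIABLE and observed == INVIABLE:
            fp += 1
        else:
            fn += 1
    return calls, ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)
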
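"""Structural queries: dead-end detection and model diffing."""

from __future__ import annotations

from typing import Dict, List, Tuple

from .model import MetabolicModel, ModelDiff, Reaction

__all__ = ["find_dead_ends", "diff_models"]


def _producible_consumable(model: MetabolicModel) -> Dict[str, Tuple[bool, bool]]:
    status: Dict[str, Tuple[bool, bool]] = {s.id: (False, False) for s in model.species}
    for rxn in model.reactions:
        fwd = rxn.upper_bound > 0
        rev = rxn.lower_bound < 0
        for sid, coeff in rxn.stoichiometry.items():
            if coeff == 0:
                continue
            produced, consumed = status[sid]
            if coeff > 0:
                produced = produced or fwd
                consumed = consumed or rev
            else:
                consumed = consumed or fwd
                produced = produced or rev
            status[sid] = (produced, consumed)
    return status


def find_dead_ends(model: MetabolicModel, include_pseudo: bool = True) -> List[str]:
    """Species never produced or never consumed by any admissible flux.

    A reversible reaction counts as both producer and consumer of each
    participant; exchange reactions count like any other reaction.
    Pseudo-metabolites are included by default since the new dead ends
    reported for the extended model include such species.
    """
    status = _producible_consumable(model)
    dead = []
    for sp in model.species:
        if not include_pseudo and sp.is_pseudo:
            continue
        produced, consumed = status[sp.id]
        if not (produced and consumed):
            dead.append(sp.id)
    return sorted(dead)


def _stoich_key(rxn: Reaction) -> Tuple[Tuple[str, float], ...]:
    return tuple(sorted((s, round(c, 12)) for s, c in rxn.stoichiometry.items() if c))


def _reactions_equal(a: Reaction, b: Reaction, tol: float = 1e-12) -> bool:
    keys = set(a.stoichiometry) | set(b.stoichiometry)
    for k in keys:
        if abs(a.stoichiometry.get(k, 0.0) - b.stoichiometry.get(k, 0.0)) > tol:
            return False
    if abs(a.lower_bound - b.lower_bound) > tol:
        return False
    if abs(a.upper_bound - b.upper_bound) > tol:
        return False
    return a.gpr_string == b.gpr_string


def diff_models(
    base: MetabolicModel,
    extended: MetabolicModel,
    match_by_stoichiometry: bool = False,
) -> ModelDiff:
    """Compare two models, matching reactions primarily by id.

    With ``match_by_stoichiometry`` a reaction absent by id from one side
    may still be matched to a reaction with identical canonicalised
    stoichiometry on the other (an id-rename fallback).
    """
    base_ids = set(base.reaction_ids())
    ext_ids = set(extended.reaction_ids())

    matched = sorted(base_ids & ext_ids)
    added = sorted(ext_ids - base_ids)
    removed = sorted(base_ids - ext_ids)

    if match_by_stoichiometry and added and removed:
        removed_by_key = {}
        for rid in removed:
            removed_by_key.setdefault(_stoich_key(base.get_reaction(rid)), []).append(rid)
        still_added = []
        renamed_pairs = []
        for rid in added:
            key = _stoich_key(extended.get_reaction(rid))
            if removed_by_key.get(key):
                old = removed_by_key[key].pop(0)
                renamed_pairs.append((old, rid))
            else:
                still_added.append(rid)
        renamed_old = {old for old, _ in renamed_pairs}
        removed = sorted(set(removed) - renamed_old)
        added = still_added
        matched = sorted(set(matched) | {new for _, new in renamed_pairs})

    modified = [
        rid
        for rid in matched
        if base.has_reaction(rid)
        and extended.has_reaction(rid)
        and not _reactions_equal(base.get_reaction(rid), extended.get_reaction(rid))
    ]

    base_species = set(base.species_ids())
    added_species = sorted(s for s in extended.species_ids() if s not in base_species)

    return ModelDiff(
        added_species=added_species,
        added_reactions=added,
        removed_reactions=removed,
        modified_reactions=modified,
        matched_reactions=matched,
    )
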
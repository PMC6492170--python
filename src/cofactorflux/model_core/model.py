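"""Core stoichiometric data model.

A :class:`MetabolicModel` holds species, reactions (net stoichiometry,
flux bounds in mmol·gDW⁻¹·h⁻¹, GPR rules) and a growth objective.
Pseudo-metabolites (signalling/scaffold species that carry no mass)
are first-class species tagged with SBO:0000409.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Set

import numpy as np
from scipy import sparse

from .gpr import GPR, parse_gpr

__all__ = [
    "SpeciesCategory",
    "Species",
    "Reaction",
    "MetabolicModel",
    "ModelDiff",
    "SBO_PSEUDO_METABOLITE",
    "DEFAULT_INF_BOUND",
]

#: SBO term marking interaction-outcome pseudo-metabolites.
SBO_PSEUDO_METABOLITE = "SBO:0000409"

#: Conventional stand-in for an unbounded flux.
DEFAULT_INF_BOUND = 1000.0


class SpeciesCategory(str, Enum):
    METABOLITE = "metabolite"
    ENZYME_SPECIES = "enzyme_species"
    PSEUDO_METABOLITE = "pseudo_metabolite"


@dataclass
class Species:
    id: str
    name: str = ""
    compartment: str = "c"
    category: SpeciesCategory = SpeciesCategory.METABOLITE
    annotations: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if isinstance(self.category, str) and not isinstance(
            self.category, SpeciesCategory
        ):
            self.category = SpeciesCategory(self.category)
        if self.category is SpeciesCategory.PSEUDO_METABOLITE:
            self.annotations.setdefault("sbo", SBO_PSEUDO_METABOLITE)

    @property
    def sbo_term(self) -> Optional[str]:
        return self.annotations.get("sbo")

    @property
    def is_pseudo(self) -> bool:
        return self.category is SpeciesCategory.PSEUDO_METABOLITE


@dataclass
class Reaction:
    """Net stoichiometry: substrates negative, products positive.

    Cofactors represented literally on both sides (net zero entry) are
    recorded in ``annotations["cofactor:<species>"]`` so the requirement
    is not silently lost.
    """

    id: str
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_INF_BOUND
    gpr: Optional[GPR] = None
    is_exchange: bool = False
    membrane_spanning: bool = False
    name: str = ""
    annotations: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if isinstance(self.gpr, str):
            self.gpr = parse_gpr(self.gpr)
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def genes(self) -> Set[str]:
        return self.gpr.genes() if self.gpr is not None else set()

    @property
    def gpr_string(self) -> str:
        return self.gpr.to_string() if self.gpr is not None else ""

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def literal_cofactors(self) -> Dict[str, float]:
        """Both-sides cofactor entries recorded in annotations."""
        out = {}
        for key, value in self.annotations.items():
            if key.startswith("cofactor:"):
                out[key.split(":", 1)[1]] = float(value)
        return out


@dataclass
class ModelDiff:
    added_species: List[str] = field(default_factory=list)
    added_reactions: List[str] = field(default_factory=list)
    removed_reactions: List[str] = field(default_factory=list)
    modified_reactions: List[str] = field(default_factory=list)
    matched_reactions: List[str] = field(default_factory=list)

    @property
    def n_added_species(self) -> int:
        return len(self.added_species)

    @property
    def n_added_reactions(self) -> int:
        return len(self.added_reactions)

    @property
    def n_removed_reactions(self) -> int:
        return len(self.removed_reactions)

    @property
    def n_modified_reactions(self) -> int:
        return len(self.modified_reactions)

    def __post_init__(self) -> None:
        overlap = set(self.matched_reactions) & set(self.added_reactions)
        if overlap:
            raise ValueError(f"reactions both matched and added: {sorted(overlap)}")


class MetabolicModel:
    """A stoichiometric network with an optimisation objective."""

    def __init__(
        self,
        model_id: str = "model",
        compartments: Optional[Iterable[str]] = None,
        objective: Optional[str] = None,
        default_growth_rate: float = 0.1,
    ):
        self.id = model_id
        self.compartments: List[str] = list(compartments or [])
        self.species: List[Species] = []
        self.reactions: List[Reaction] = []
        self.objective: Optional[str] = objective
        self.default_growth_rate = default_growth_rate
        self.annotations: Dict[str, str] = {}
        self._species_index: Dict[str, Species] = {}
        self._reaction_index: Dict[str, Reaction] = {}

    # -- construction -------------------------------------------------

    def add_compartment(self, cid: str) -> None:
        if cid not in self.compartments:
            self.compartments.append(cid)

    def add_species(self, species: Species) -> Species:
        if species.id in self._species_index:
            raise ValueError(f"duplicate species id {species.id!r}")
        if species.compartment not in self.compartments:
            raise ValueError(
                f"species {species.id!r} placed in undeclared compartment "
                f"{species.compartment!r}"
            )
        self.species.append(species)
        self._species_index[species.id] = species
        return species

    def add_reaction(self, reaction: Reaction) -> Reaction:
        if reaction.id in self._reaction_index:
            raise ValueError(f"duplicate reaction id {reaction.id!r}")
        missing = [s for s in reaction.stoichiometry if s not in self._species_index]
        if missing:
            raise ValueError(
                f"reaction {reaction.id!r} references unknown species {missing}"
            )
        if not reaction.stoichiometry and not reaction.is_exchange:
            raise ValueError(
                f"reaction {reaction.id!r} has empty stoichiometry and is not a "
                "declared exchange sink"
            )
        self.reactions.append(reaction)
        self._reaction_index[reaction.id] = reaction
        return reaction

    def remove_reaction(self, reaction_id: str) -> None:
        rxn = self.get_reaction(reaction_id)
        self.reactions.remove(rxn)
        del self._reaction_index[reaction_id]

    # -- lookup -------------------------------------------------------

    def get_species(self, sid: str) -> Species:
        try:
            return self._species_index[sid]
        except KeyError:
            raise KeyError(f"no species {sid!r} in model {self.id!r}") from None

    def get_reaction(self, rid: str) -> Reaction:
        try:
            return self._reaction_index[rid]
        except KeyError:
            raise KeyError(f"no reaction {rid!r} in model {self.id!r}") from None

    def has_species(self, sid: str) -> bool:
        return sid in self._species_index

    def has_reaction(self, rid: str) -> bool:
        return rid in self._reaction_index

    @property
    def genes(self) -> Set[str]:
        out: Set[str] = set()
        for rxn in self.reactions:
            out |= rxn.genes
        return out

    @property
    def objective_reaction(self) -> Reaction:
        if self.objective is None:
            raise ValueError(
                f"model {self.id!r} has no objective reaction set; assign "
                "model.objective to a growth/biomass reaction id"
            )
        return self.get_reaction(self.objective)

    # -- numerics -----------------------------------------------------

    def species_ids(self) -> List[str]:
        return [s.id for s in self.species]

    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        """Species-by-reactions matrix of net coefficients."""
        row_of = {s.id: i for i, s in enumerate(self.species)}
        rows, cols, vals = [], [], []
        for j, rxn in enumerate(self.reactions):
            for sid, coeff in rxn.stoichiometry.items():
                if coeff != 0.0:
                    rows.append(row_of[sid])
                    cols.append(j)
                    vals.append(float(coeff))
        return sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.species), len(self.reactions))
        )

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    # -- integrity ----------------------------------------------------

    def validate(self) -> None:
        """Raise on any violated structural invariant."""
        seen = set()
        for sp in self.species:
            if sp.id in seen:
                raise ValueError(f"duplicate species id {sp.id!r}")
            seen.add(sp.id)
            if sp.compartment not in self.compartments:
                raise ValueError(
                    f"species {sp.id!r} in undeclared compartment {sp.compartment!r}"
                )
            if sp.is_pseudo and sp.sbo_term != SBO_PSEUDO_METABOLITE:
                raise ValueError(
                    f"pseudo-metabolite {sp.id!r} must carry {SBO_PSEUDO_METABOLITE}"
                )
        seen = set()
        for rxn in self.reactions:
            if rxn.id in seen:
                raise ValueError(f"duplicate reaction id {rxn.id!r}")
            seen.add(rxn.id)
            if rxn.lower_bound > rxn.upper_bound:
                raise ValueError(f"reaction {rxn.id!r} has inverted bounds")
            for sid in rxn.stoichiometry:
                if sid not in self._species_index:
                    raise ValueError(
                        f"reaction {rxn.id!r} references unknown species {sid!r}"
                    )
        if self.objective is not None and self.objective not in self._reaction_index:
            raise ValueError(f"objective reaction {self.objective!r} not in model")

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<MetabolicModel {self.id!r}: {len(self.species)} species, "
            f"{len(self.reactions)} reactions, {len(self.genes)} genes>"
        )
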
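"""Non-consumed cofactor injection and pseudo-metabolite circuits.

A cofactor enters a catalysed reaction as a substrate and leaves as a
catalytically unreactive product. Two encodings are provided:

``literal_both_sides``
    The cofactor appears with coefficient x on both sides. The net
    stoichiometric entry is zero, so this form can never make cofactor
    availability binding in an LP; the requirement is recorded in the
    reaction annotations so it is not silently lost.

``free_to_spent`` (default)
    The cofactor is split into a free pool (consumed, x per catalytic
    event) and an auto-created spent pool (produced, x per event) that
    is closed by a drain reaction. Availability of the free pool then
    binds the LP, and total flux into the spent pools gives the
    cofactor turnover a concrete, measurable meaning.

The module also builds the scaffold cycle used for cluster biogenesis
(empty scaffold ES <-> sulphonylated scaffold SS, a conserved moiety),
the availability/depletion signalling circuit (PS/AS relays around a
shared signal precursor), haem-gene coupling of low-affinity uptake,
and threshold-derived flux bounds for high/low-affinity transport.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .model_core import (
    DEFAULT_INF_BOUND,
    MetabolicModel,
    Reaction,
    Species,
    SpeciesCategory,
    gpr_and,
    parse_gpr,
)

__all__ = [
    "CofactorRequirement",
    "PseudoMetaboliteCircuit",
    "AffinityThreshold",
    "ScaffoldRoute",
    "ClusterSpec",
    "ScaffoldConfig",
    "RegulonConfig",
    "augment_reaction",
    "augment_model",
    "build_scaffold_cycle",
    "build_regulon_circuit",
    "couple_haem_to_low_affinity",
    "threshold_to_bound",
    "spent_species_id",
    "drain_reaction_id",
]

MODE_LITERAL = "literal_both_sides"
MODE_FREE_TO_SPENT = "free_to_spent"


@dataclass(frozen=True)
class CofactorRequirement:
    """One (reaction, cofactor) augmentation record with coefficient x."""

    reaction_id: str
    cofactor_species_id: str
    coefficient: float
    mode: str = MODE_FREE_TO_SPENT

    def __post_init__(self) -> None:
        if self.coefficient < 0:
            raise ValueError(
                f"cofactor coefficient must be >= 0, got {self.coefficient} "
                f"for {self.reaction_id}/{self.cofactor_species_id}"
            )
        if self.mode not in (MODE_LITERAL, MODE_FREE_TO_SPENT):
            raise ValueError(f"unknown augmentation mode {self.mode!r}")


@dataclass
class PseudoMetaboliteCircuit:
    """Declaration of a coupled, unbounded pseudo-metabolite circuit."""

    circuit_id: str
    members: List[str]
    coupled_reactions: List[Tuple[str, str]]  # (reaction id, producer|consumer|relay)
    unbounded: bool = True

    def validate(self, model: MetabolicModel) -> None:
        roles: Dict[str, set] = {m: set() for m in self.members}
        for rid, _role in self.coupled_reactions:
            rxn = model.get_reaction(rid)
            for sid, coeff in rxn.stoichiometry.items():
                if sid in roles and coeff != 0:
                    roles[sid].add("producer" if coeff > 0 else "consumer")
                    if rxn.reversible:
                        roles[sid].update({"producer", "consumer"})
        missing = {
            m: sorted({"producer", "consumer"} - r) for m, r in roles.items()
            if r != {"producer", "consumer"}
        }
        if missing:
            raise ValueError(
                f"circuit {self.circuit_id!r}: members without both producing and "
                f"consuming couplings (accumulation risk): {missing}"
            )


@dataclass
class AffinityThreshold:
    """Concentration threshold converted to a flux bound.

    Default thresholds follow the uptake switching concentrations:
    1 uM for iron and 20 uM for copper.
    """

    ion: str
    threshold_concentration: float  # uM
    conversion_factor: float  # mmol/gDW/h per uM

    def __post_init__(self) -> None:
        if self.ion not in ("iron", "copper"):
            raise ValueError(f"ion must be 'iron' or 'copper', got {self.ion!r}")

    @property
    def derived_flux_bound(self) -> float:
        return threshold_to_bound(self)


def threshold_to_bound(th: AffinityThreshold) -> float:
    """Flux bound = threshold concentration x conversion factor."""
    if th.threshold_concentration <= 0:
        raise ValueError("threshold concentration must be positive")
    if th.conversion_factor <= 0:
        raise ValueError("conversion factor must be positive")
    return th.threshold_concentration * th.conversion_factor


# ---------------------------------------------------------------------------
# reaction / model augmentation
# ---------------------------------------------------------------------------

def spent_species_id(cofactor_species_id: str) -> str:
    return f"{cofactor_species_id}__spent"


def drain_reaction_id(cofactor_species_id: str) -> str:
    return f"DM_{spent_species_id(cofactor_species_id)}"


def _ensure_spent_pool(model: MetabolicModel, cofactor_id: str) -> str:
    """Create the spent companion species and its drain if absent."""
    free = model.get_species(cofactor_id)
    spent_id = spent_species_id(cofactor_id)
    if not model.has_species(spent_id):
        model.add_species(
            Species(
                id=spent_id,
                name=f"{free.name or free.id} (spent pool)",
                compartment=free.compartment,
                category=free.category,
                annotations={"spent_pool_of": cofactor_id},
            )
        )
    drain_id = drain_reaction_id(cofactor_id)
    if not model.has_reaction(drain_id):
        model.add_reaction(
            Reaction(
                id=drain_id,
                name=f"spent-pool drain for {cofactor_id}",
                stoichiometry={spent_id: -1.0},
                lower_bound=0.0,
                upper_bound=DEFAULT_INF_BOUND,
                is_exchange=True,
                annotations={"drain_for": cofactor_id},
            )
        )
    return spent_id


def augment_reaction(model: MetabolicModel, req: CofactorRequirement) -> Reaction:
    """Apply one cofactor requirement to its reaction, in place on *model*."""
    rxn = model.get_reaction(req.reaction_id)
    if not model.has_species(req.cofactor_species_id):
        raise KeyError(
            f"cofactor species {req.cofactor_species_id!r} not in model"
        )
    rxn.annotations[f"cofactor_requirement:{req.cofactor_species_id}"] = repr(
        req.coefficient
    )
    if req.coefficient == 0.0:
        return rxn
    if req.mode == MODE_LITERAL:
        # net-zero entry; keep the x on record so it round-trips
        rxn.annotations[f"cofactor:{req.cofactor_species_id}"] = repr(req.coefficient)
        rxn.stoichiometry.setdefault(req.cofactor_species_id, 0.0)
    else:
        spent_id = _ensure_spent_pool(model, req.cofactor_species_id)
        rxn.stoichiometry[req.cofactor_species_id] = (
            rxn.stoichiometry.get(req.cofactor_species_id, 0.0) - req.coefficient
        )
        rxn.stoichiometry[spent_id] = (
            rxn.stoichiometry.get(spent_id, 0.0) + req.coefficient
        )
    return rxn


def augment_model(
    model: MetabolicModel, table: Sequence[CofactorRequirement]
) -> MetabolicModel:
    """Apply a whole requirement table, returning a new model.

    The table is recorded in the model annotations so downstream
    turnover computations can recover it.
    """
    seen = set()
    duplicates = []
    for req in table:
        key = (req.reaction_id, req.cofactor_species_id)
        if key in seen:
            duplicates.append(key)
        seen.add(key)
    if duplicates:
        raise ValueError(
            f"duplicate (reaction, cofactor) rows in requirement table: {duplicates}"
        )
    out = model.copy()
    for req in table:
        augment_reaction(out, req)
    if table:
        out.annotations["cofactor_table"] = ";".join(
            f"{r.reaction_id},{r.cofactor_species_id},{r.coefficient!r},{r.mode}"
            for r in table
        )
    return out


def requirement_table_from_annotations(model: MetabolicModel) -> List[CofactorRequirement]:
    """Recover the requirement table recorded by :func:`augment_model`."""
    raw = model.annotations.get("cofactor_table", "")
    table = []
    for chunk in filter(None, raw.split(";")):
        rid, sid, coeff, mode = chunk.split(",")
        table.append(CofactorRequirement(rid, sid, float(coeff), mode))
    return table


# ---------------------------------------------------------------------------
# scaffold cycle (cluster biogenesis)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaffoldRoute:
    """One maturation route for a cluster product (distinct GPR)."""

    suffix: str = ""
    gpr: str = ""


@dataclass
class ClusterSpec:
    product_species_id: str
    iron_stoichiometry: float = 4.0
    routes: List[ScaffoldRoute] = field(default_factory=lambda: [ScaffoldRoute()])


@dataclass
class ScaffoldConfig:
    sulphur_donor: str = "cys_m"
    iron_species: str = "fe_m"
    compartment: str = "m"
    es_id: str = "ES_m"
    ss_id: str = "SS_m"
    clusters: List[ClusterSpec] = field(default_factory=list)
    load_gpr: str = ""
    upper_bound: float = DEFAULT_INF_BOUND


def scaffold_load_id(cluster: str) -> str:
    return f"SCAFFOLD_LOAD_{cluster}"


def scaffold_release_id(cluster: str, suffix: str = "") -> str:
    rid = f"SCAFFOLD_RELEASE_{cluster}"
    return f"{rid}_{suffix}" if suffix else rid


def build_scaffold_cycle(
    model: MetabolicModel, config: ScaffoldConfig
) -> MetabolicModel:
    """Add the ES/SS scaffold cycle and cluster maturation reactions.

    Per cluster type: (i) ES + donor -> SS and (ii) SS + iron -> cluster
    + ES. The indicator vector on {ES, SS} is a left null vector of all
    added columns, so the scaffold total is a conserved moiety and at
    steady state the flux through (i) equals the flux through (ii).
    """
    out = model.copy()
    if not out.has_species(config.sulphur_donor):
        raise KeyError(
            f"sulphur donor species {config.sulphur_donor!r} not in model"
        )
    if not out.has_species(config.iron_species):
        raise KeyError(f"iron species {config.iron_species!r} not in model")
    for sid, name in ((config.es_id, "empty scaffold"), (config.ss_id, "sulphonylated scaffold")):
        if not out.has_species(sid):
            out.add_species(
                Species(
                    id=sid,
                    name=name,
                    compartment=config.compartment,
                    category=SpeciesCategory.PSEUDO_METABOLITE,
                )
            )
    coupled: List[Tuple[str, str]] = []
    members = [config.es_id, config.ss_id]
    for cluster in config.clusters:
        if not out.has_species(cluster.product_species_id):
            raise KeyError(
                f"cluster product species {cluster.product_species_id!r} not in model"
            )
        load_id = scaffold_load_id(cluster.product_species_id)
        out.add_reaction(
            Reaction(
                id=load_id,
                name=f"scaffold sulphuration for {cluster.product_species_id}",
                stoichiometry={
                    config.es_id: -1.0,
                    config.sulphur_donor: -1.0,
                    config.ss_id: 1.0,
                },
                lower_bound=0.0,
                upper_bound=config.upper_bound,
                gpr=parse_gpr(config.load_gpr),
                annotations={"circuit": "scaffold"},
            )
        )
        coupled.append((load_id, "producer"))
        for route in cluster.routes:
            release_id = scaffold_release_id(cluster.product_species_id, route.suffix)
            out.add_reaction(
                Reaction(
                    id=release_id,
                    name=f"cluster release for {cluster.product_species_id}",
                    stoichiometry={
                        config.ss_id: -1.0,
                        config.iron_species: -cluster.iron_stoichiometry,
                        cluster.product_species_id: 1.0,
                        config.es_id: 1.0,
                    },
                    lower_bound=0.0,
                    upper_bound=config.upper_bound,
                    gpr=parse_gpr(route.gpr),
                    annotations={"circuit": "scaffold", "scaffold_release": "true"},
                )
            )
            coupled.append((release_id, "consumer"))
    circuit = PseudoMetaboliteCircuit(
        circuit_id="scaffold", members=members, coupled_reactions=coupled
    )
    circuit.validate(out)
    out.annotations["scaffold_es"] = config.es_id
    out.annotations["scaffold_ss"] = config.ss_id
    return out


# ---------------------------------------------------------------------------
# availability/depletion signalling circuit
# ---------------------------------------------------------------------------

@dataclass
class RegulonConfig:
    """Wiring of the PS (availability) / AS (depletion) signal circuit.

    The cluster-release reactions consume one PS per event and emit
    ``signal_yield`` units of a signal precursor. The precursor is
    relayed to the cell envelope where mutually competing branch
    reactions convert it into either PS (returned to the biogenesis
    compartment) or AS (required as a co-substrate by high-affinity
    uptake); surplus precursor leaves through an unbounded drain. All
    relays are mass- and energy-neutral and unbounded.
    """

    high_affinity_uptake_reactions: List[str] = field(default_factory=list)
    ps_mito_id: str = "PS_m"
    ps_env_id: str = "PS_e"
    as_env_id: str = "AS_e"
    signal_mito_id: str = "SG_m"
    signal_env_id: str = "SG_e"
    mito_compartment: str = "m"
    env_compartment: str = "e"
    as_coefficient: float = 1e-3
    signal_yield: float = 2.0
    return_gpr: str = ""  # karyopherin analog carrying PS back inward
    upper_bound: float = DEFAULT_INF_BOUND


def build_regulon_circuit(
    model: MetabolicModel, config: RegulonConfig
) -> MetabolicModel:
    out = model.copy()
    release_ids = [
        r.id
        for r in out.reactions
        if r.annotations.get("scaffold_release") == "true"
    ]
    if not release_ids:
        raise ValueError(
            "no scaffold cycle present: build_scaffold_cycle must run before "
            "build_regulon_circuit"
        )
    missing = [
        rid for rid in config.high_affinity_uptake_reactions if not out.has_reaction(rid)
    ]
    if missing:
        raise KeyError(f"high-affinity uptake reactions not found: {missing}")
    if not config.high_affinity_uptake_reactions:
        raise ValueError("config names no high-affinity uptake reactions")

    pseudo = [
        (config.ps_mito_id, "iron availability signal", config.mito_compartment),
        (config.ps_env_id, "iron availability signal", config.env_compartment),
        (config.as_env_id, "iron depletion signal", config.env_compartment),
        (config.signal_mito_id, "signal precursor", config.mito_compartment),
        (config.signal_env_id, "signal precursor", config.env_compartment),
    ]
    for sid, name, comp in pseudo:
        if not out.has_species(sid):
            out.add_species(
                Species(
                    id=sid,
                    name=name,
                    compartment=comp,
                    category=SpeciesCategory.PSEUDO_METABOLITE,
                )
            )

    for rid in release_ids:
        rxn = out.get_reaction(rid)
        rxn.stoichiometry[config.ps_mito_id] = (
            rxn.stoichiometry.get(config.ps_mito_id, 0.0) - 1.0
        )
        rxn.stoichiometry[config.signal_mito_id] = (
            rxn.stoichiometry.get(config.signal_mito_id, 0.0) + config.signal_yield
        )

    ub = config.upper_bound
    relays = [
        Reaction(
            id="SIG_RELAY_OUT",
            name="signal precursor relay to envelope",
            stoichiometry={config.signal_mito_id: -1.0, config.signal_env_id: 1.0},
            upper_bound=ub,
            annotations={"circuit": "regulon"},
        ),
        Reaction(
            id="SIG_BRANCH_PS",
            name="availability branch",
            stoichiometry={config.signal_env_id: -1.0, config.ps_env_id: 1.0},
            upper_bound=ub,
            annotations={"circuit": "regulon"},
        ),
        Reaction(
            id="SIG_BRANCH_AS",
            name="depletion branch",
            stoichiometry={config.signal_env_id: -1.0, config.as_env_id: 1.0},
            upper_bound=ub,
            annotations={"circuit": "regulon"},
        ),
        Reaction(
            id="SIG_PS_RETURN",
            name="availability signal return",
            stoichiometry={config.ps_env_id: -1.0, config.ps_mito_id: 1.0},
            upper_bound=ub,
            gpr=parse_gpr(config.return_gpr),
            annotations={"circuit": "regulon"},
        ),
        Reaction(
            id="DM_SIG",
            name="signal precursor drain",
            stoichiometry={config.signal_env_id: -1.0},
            upper_bound=ub,
            is_exchange=True,
            annotations={"circuit": "regulon"},
        ),
    ]
    for rxn in relays:
        out.add_reaction(rxn)

    for rid in config.high_affinity_uptake_reactions:
        rxn = out.get_reaction(rid)
        rxn.stoichiometry[config.as_env_id] = (
            rxn.stoichiometry.get(config.as_env_id, 0.0) - config.as_coefficient
        )

    circuit = PseudoMetaboliteCircuit(
        circuit_id="regulon",
        members=[
            config.ps_mito_id,
            config.ps_env_id,
            config.as_env_id,
            config.signal_mito_id,
            config.signal_env_id,
        ],
        coupled_reactions=[(r.id, "relay") for r in relays]
        + [(rid, "consumer") for rid in release_ids]
        + [(rid, "consumer") for rid in config.high_affinity_uptake_reactions],
    )
    circuit.validate(out)
    return out


def couple_haem_to_low_affinity(
    model: MetabolicModel,
    haem_gene_ids: Iterable[str],
    uptake_reaction_id: str,
) -> MetabolicModel:
    """AND the haem biosynthesis genes onto the low-affinity uptake GPR.

    Deleting any listed haem gene then disables low-affinity uptake.
    """
    genes = list(haem_gene_ids)
    out = model.copy()
    rxn = out.get_reaction(uptake_reaction_id)
    if not genes:
        return out
    rxn.gpr = gpr_and(rxn.gpr, *genes)
    return out
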
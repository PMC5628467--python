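"""Packaged MFO fragments and a planted-label random fragment generator.

The packaged fragments reconstruct the transmembrane-transporter segment of
the Molecular Function Ontology that motivates the whole toolkit, each scoped
to one illustration: the single carbohydrate transporter with full structure
(``fig1_2``), minimal two-term examples of operand specialization (``fig3``)
and mode addition (``fig4``), the ten-term transporter segment with the
grouping artifact GO:0022891 (``fig5``), the receptor-activity family used for
specialization-style profiling (``receptor``), and a two-child electron
carrier demo (``electron_carrier``). They ship in ``fuelkit/data`` as
OBO + sidecar pairs, which double as format documentation; the builders here
are the source of truth and the packaged files are their verbatim emission.

:func:`generate_random` builds fragments whose links are constructed by
*instantiating* the pattern definitions (strict operand refinement, mode
addition, strict mode refinement, or no edit), recording the planted facet of
every link — an oracle the classifier must recover exactly.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from importlib import resources

from .model import (
    Facet,
    FunctionConcept,
    GoalAchievement,
    Mode,
    OntologyFragment,
    ParticipantCategory,
    Situation,
    SubsumptionLink,
    TermId,
)
from .obo_io import load_sidecar, parse_obo, assemble_fragment

__all__ = [
    "PlantedFragment",
    "fig1_2_fragment",
    "fig3_fragment",
    "fig4_fragment",
    "fig5_fragment",
    "receptor_fragment",
    "electron_carrier_fragment",
    "generate_random",
    "FIXTURE_NAMES",
    "fixture_fragment",
    "load_packaged",
]

# situation templates shared by the transporter fixtures (phrasing of the
# transport definitions, with the transported substance lifted into a slot)
_T_IN = "{operand} is on one side of the membrane"
_T_OUT = "{operand} is on the other side of the membrane"


def _sit(template: str, operand: TermId) -> Situation:
    return Situation.make(template, operand=operand)


def _cat(local: str, label: str, *parents: str) -> ParticipantCategory:
    return ParticipantCategory(
        id=TermId(f"FX:{local}"),
        label=label,
        parents=frozenset(TermId(f"FX:{p}") for p in parents),
    )


def _fx(local: str) -> TermId:
    return TermId(f"FX:{local}")


def _transport_ga(operand: TermId, mode: TermId | None = None, **kw) -> GoalAchievement:
    return GoalAchievement(
        input=_sit(_T_IN, operand), output=_sit(_T_OUT, operand), operand=operand, mode=mode, **kw
    )


def fig1_2_fragment() -> OntologyFragment:
    """GO:0015144 with its full FueL structure (compact/extended showcase).

    One function, its goal achievement realized by the process GO:0034219,
    operand CHEBI:16646 *carbohydrate*, and the bearer entity *putative
    glucose uptake protein*.
    """
    carb = TermId("CHEBI:16646")
    fn = FunctionConcept(
        id=TermId("GO:0015144"),
        name="carbohydrate transmembrane transporter activity",
        definition=(
            "Catalysis of the transfer of carbohydrate from one side of the "
            "membrane to the other."
        ),
        synonyms=("sugar transporter",),
        ga=_transport_ga(carb, process=TermId("GO:0034219")),
        bearer="putative glucose uptake protein",
    )
    return OntologyFragment(
        functions={fn.id: fn},
        participant_taxonomy={carb: ParticipantCategory(carb, "carbohydrate")},
        processes={TermId("GO:0034219"): "carbohydrate transmembrane transport"},
        extra_relationships={
            fn.id: (("transports_or_maintains_localization_of", carb),)
        },
    )


def fig3_fragment() -> OntologyFragment:
    """Operand specialization in isolation: cation under ion."""
    ion, cation = _cat("ion", "ion"), _cat("cation", "cation", "ion")
    parent = FunctionConcept(
        id=TermId("GO:0015075"),
        name="ion transmembrane transporter activity",
        ga=_transport_ga(ion.id),
    )
    child = FunctionConcept(
        id=TermId("GO:0008324"),
        name="cation transmembrane transporter activity",
        ga=_transport_ga(cation.id),
    )
    return OntologyFragment(
        functions={parent.id: parent, child.id: child},
        links=[SubsumptionLink(child.id, parent.id)],
        participant_taxonomy={ion.id: ion, cation.id: cation},
    )


_ACTIVE_MODE_DESC = (
    "the transporter binding the solute undergoes a series of conformational changes"
)
_SECONDARY_MODE_DESC = (
    "the transporter binds the solute and undergoes a series of conformational "
    "changes driven by chemiosmotic energy sources, including uniport, symport or antiport"
)


def fig4_fragment() -> OntologyFragment:
    """Mode addition in isolation: both functions share the operand *substance*."""
    substance = _cat("substance", "a substance")
    active = Mode(_fx("active-transport-mode"), _ACTIVE_MODE_DESC)
    parent = FunctionConcept(
        id=TermId("GO:0022857"),
        name="transmembrane transporter activity",
        ga=_transport_ga(substance.id),
    )
    child = FunctionConcept(
        id=TermId("GO:0022804"),
        name="active transmembrane transporter activity",
        ga=_transport_ga(substance.id, mode=active.id),
    )
    return OntologyFragment(
        functions={parent.id: parent, child.id: child},
        links=[SubsumptionLink(child.id, parent.id)],
        participant_taxonomy={substance.id: substance},
        mode_taxonomy={active.id: active},
    )


def fig5_fragment() -> OntologyFragment:
    """The ten-term transporter segment containing the grouping artifact.

    GO:0022804's operand follows the reading under which it equals
    GO:0022891's ("a specific substance or group of substances"), so its link
    to GO:0022857 carries both mode addition and operand specialization.
    GO:0005402 (cation:sugar symporter) binds *cation* as operand and the
    symport mode, sitting under both GO:0008324 and GO:0015291 — the
    questionable member of the grouping term's down-set.
    """
    cats = [
        _cat("substance", "a substance"),
        _cat("specific-substance", "a specific substance or group of substances", "substance"),
        _cat("ion", "ion", "specific-substance"),
        _cat("cation", "cation", "ion"),
        _cat("carbohydrate", "carbohydrate", "specific-substance"),
        _cat("sugar", "sugar", "carbohydrate"),
        _cat("vitamin", "vitamin", "specific-substance"),
        _cat("drug", "drug", "specific-substance"),
        _cat("solute", "solute", "specific-substance"),
        _cat("transporter-protein", "transporter protein"),
    ]
    modes = [
        Mode(_fx("active-transport-mode"), _ACTIVE_MODE_DESC),
        Mode(
            _fx("secondary-active-transport-mode"),
            _SECONDARY_MODE_DESC,
            specializes=_fx("active-transport-mode"),
        ),
        Mode(
            _fx("symport-mode"),
            "the transporter co-transports the solute together with a coupled "
            "ion in the same direction",
            specializes=_fx("secondary-active-transport-mode"),
        ),
    ]

    spec = _fx("specific-substance")
    defs = [
        # id, name, operand, mode, parents, extras
        ("GO:0022857", "transmembrane transporter activity", _fx("substance"), None, []),
        (
            "GO:0022891",
            "substrate-specific transmembrane transporter activity",
            spec,
            None,
            ["GO:0022857"],
        ),
        (
            "GO:0022804",
            "active transmembrane transporter activity",
            spec,
            _fx("active-transport-mode"),
            ["GO:0022857"],
        ),
        (
            "GO:0015291",
            "secondary active transmembrane transporter activity",
            spec,
            _fx("secondary-active-transport-mode"),
            ["GO:0022804"],
        ),
        ("GO:0015075", "ion transmembrane transporter activity", _fx("ion"), None, ["GO:0022891"]),
        (
            "GO:0008324",
            "cation transmembrane transporter activity",
            _fx("cation"),
            None,
            ["GO:0015075"],
        ),
        (
            "GO:0015144",
            "carbohydrate transmembrane transporter activity",
            _fx("carbohydrate"),
            None,
            ["GO:0022891"],
        ),
        (
            "GO:0005402",
            "cation:sugar symporter activity",
            _fx("cation"),
            _fx("symport-mode"),
            ["GO:0008324", "GO:0015291"],
        ),
        (
            "GO:0090482",
            "vitamin transmembrane transporter activity",
            _fx("vitamin"),
            None,
            ["GO:0022857"],
        ),
        (
            "GO:0015238",
            "drug transmembrane transporter activity",
            _fx("drug"),
            None,
            ["GO:0022857"],
        ),
    ]

    functions: dict[TermId, FunctionConcept] = {}
    links: list[SubsumptionLink] = []
    for gid, name, operand, mode, parents in defs:
        tid = TermId(gid)
        extra = {}
        if gid == "GO:0015144":
            extra = dict(
                definition=(
                    "Catalysis of the transfer of carbohydrate from one side of "
                    "the membrane to the other."
                ),
                synonyms=("sugar transporter",),
            )
        ga = _transport_ga(operand, mode=mode)
        if gid == "GO:0015144":
            ga = replace(ga, process=TermId("GO:0034219"))
        if gid == "GO:0005402":
            ga = replace(ga, doer=_fx("transporter-protein"))
        functions[tid] = FunctionConcept(id=tid, name=name, ga=ga, **extra)
        links.extend(SubsumptionLink(tid, TermId(p)) for p in parents)

    return OntologyFragment(
        functions=functions,
        links=links,
        participant_taxonomy={c.id: c for c in cats},
        mode_taxonomy={m.id: m for m in modes},
        processes={TermId("GO:0034219"): "carbohydrate transmembrane transport"},
    )


_R_IN = "{operand} is available to the receptor"
_R_OUT = "binding of {operand} is transduced into a cellular response"


def receptor_fragment() -> OntologyFragment:
    """GO:0004872 *receptor activity* and its seven direct subclasses.

    Four of the subclasses carry fixture-local ids (the ontology ids are not
    fixed by the source material). Every child operand sits strictly below the
    parent's generic ligand-or-signal category, so every child link is an
    operand specialization; only cargo receptor activity additionally adds a
    mode (cargo delivery by endocytosis).
    """
    cats = [
        _cat("ligand", "ligand or signal"),
        _cat("apolipoprotein", "apolipoprotein", "ligand"),
        _cat("cargo", "cargo macromolecule", "ligand"),
        _cat("laminin", "laminin", "ligand"),
        _cat("molecular-pattern", "molecular pattern", "ligand"),
        _cat("signal", "signal", "ligand"),
        _cat(
            "extracellular-or-intracellular-signal",
            "extracellular or intracellular signal",
            "signal",
        ),
        _cat("virus", "virus particle", "ligand"),
    ]
    cargo_mode = Mode(
        _fx("cargo-uptake-mode"),
        "binds a cargo macromolecule and delivers it for internalization by endocytosis",
    )

    def rga(operand: TermId, mode: TermId | None = None) -> GoalAchievement:
        return GoalAchievement(
            input=_sit(_R_IN, operand),
            output=_sit(_R_OUT, operand),
            operand=operand,
            mode=mode,
        )

    parent = FunctionConcept(
        id=TermId("GO:0004872"), name="receptor activity", ga=rga(_fx("ligand"))
    )
    children = [
        FunctionConcept(
            id=_fx("0000001"),
            name="apolipoprotein receptor activity",
            ga=rga(_fx("apolipoprotein")),
        ),
        FunctionConcept(
            id=_fx("0000002"),
            name="cargo receptor activity",
            ga=rga(_fx("cargo"), mode=cargo_mode.id),
        ),
        FunctionConcept(
            id=TermId("GO:0005055"), name="laminin receptor activity", ga=rga(_fx("laminin"))
        ),
        FunctionConcept(
            id=_fx("0000003"),
            name="pattern recognition receptor activity",
            ga=rga(_fx("molecular-pattern")),
        ),
        FunctionConcept(
            id=TermId("GO:0038023"), name="signaling receptor activity", ga=rga(_fx("signal"))
        ),
        FunctionConcept(
            id=TermId("GO:0099600"),
            name="transmembrane receptor activity",
            ga=rga(_fx("extracellular-or-intracellular-signal")),
        ),
        FunctionConcept(
            id=_fx("0000004"), name="virus receptor activity", ga=rga(_fx("virus"))
        ),
    ]
    return OntologyFragment(
        functions={f.id: f for f in [parent, *children]},
        links=[SubsumptionLink(c.id, parent.id) for c in children],
        participant_taxonomy={c.id: c for c in cats},
        mode_taxonomy={cargo_mode.id: cargo_mode},
    )


def electron_carrier_fragment() -> OntologyFragment:
    """GO:0009055 with two of its mode-distinguished children (rendering demo).

    Deliberately partial — the full family is larger — so it serves diagram
    demonstrations, not quantitative checks.
    """
    electron = _cat("electron", "electron")
    modes = [
        Mode(
            _fx("cco-mode"),
            "transfers electrons within the cytochrome c oxidase complex",
        ),
        Mode(
            _fx("cyclic-mode"),
            "transfers electrons within the cyclic electron transport pathway "
            "of photosynthesis",
        ),
    ]
    t_in = "{operand} is held by the donor"
    t_out = "{operand} is held by the acceptor"

    def ega(mode: TermId | None = None) -> GoalAchievement:
        return GoalAchievement(
            input=_sit(t_in, electron.id),
            output=_sit(t_out, electron.id),
            operand=electron.id,
            mode=mode,
        )

    parent = FunctionConcept(
        id=TermId("GO:0009055"), name="electron carrier activity", ga=ega()
    )
    c1 = FunctionConcept(
        id=TermId("GO:0045154"),
        name=(
            "electron transporter, transferring electrons within cytochrome c "
            "oxidase complex activity"
        ),
        ga=ega(_fx("cco-mode")),
    )
    c2 = FunctionConcept(
        id=TermId("GO:0045156"),
        name=(
            "electron transporter, transferring electrons within the cyclic "
            "electron transport pathway of photosynthesis activity"
        ),
        ga=ega(_fx("cyclic-mode")),
    )
    return OntologyFragment(
        functions={f.id: f for f in [parent, c1, c2]},
        links=[SubsumptionLink(c1.id, parent.id), SubsumptionLink(c2.id, parent.id)],
        participant_taxonomy={electron.id: electron},
        mode_taxonomy={m.id: m for m in modes},
    )


FIXTURE_NAMES = ("fig1", "fig3", "fig4", "fig5", "receptor", "electron")

_BUILDERS = {
    "fig1": fig1_2_fragment,
    "fig3": fig3_fragment,
    "fig4": fig4_fragment,
    "fig5": fig5_fragment,
    "receptor": receptor_fragment,
    "electron": electron_carrier_fragment,
}


def fixture_fragment(name: str) -> OntologyFragment:
    try:
        return _BUILDERS[name]()
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}") from None


def load_packaged(name: str) -> OntologyFragment:
    """Load a fixture from its packaged OBO + sidecar pair (via obo_io)."""
    if name not in _BUILDERS:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    data = resources.files("fuelkit") / "data"
    stanzas = parse_obo((data / f"{name}.obo").read_text(encoding="utf-8"))
    sidecar = load_sidecar((data / f"{name}.sidecar.yaml").read_text(encoding="utf-8"))
    return assemble_fragment(stanzas, sidecar)


# ---------------------------------------------------------------------------
# Random planted fragments


@dataclass(frozen=True)
class PlantedFragment:
    """A random fragment together with the facet planted on each link."""

    fragment: OntologyFragment
    planted: dict[tuple[TermId, TermId], frozenset[Facet]] = field(default_factory=dict)
    seed: int = 0


def generate_random(
    seed: int, n_functions: int, taxonomy_depth: int = 3
) -> PlantedFragment:
    """Build a random valid fragment with known (planted) link facets.

    A binary participant tree of ``taxonomy_depth`` levels and a small mode
    tree are generated first. The root function binds the taxonomy root as
    operand and has no mode; every further function derives its goal
    achievement from a randomly chosen existing function by one or two
    definition-instantiating edits — strict operand refinement (plants
    operand-spec), adding a mode to a mode-less ancestor (mode-added), strict
    mode refinement (mode-spec) — or no edit at all (plain). Deterministic
    given ``seed``.
    """
    if n_functions < 1:
        raise ValueError("n_functions must be >= 1")
    if taxonomy_depth < 1:
        raise ValueError("taxonomy_depth must be >= 1")
    rng = random.Random(seed)

    # participant tree, binary, taxonomy_depth levels below the root
    cats: dict[TermId, ParticipantCategory] = {}
    cat_children: dict[TermId, list[TermId]] = {}
    root_cat = _fx("c0")
    cats[root_cat] = ParticipantCategory(root_cat, "category 0")
    frontier = [root_cat]
    counter = 1
    for _ in range(taxonomy_depth):
        nxt = []
        for parent in frontier:
            for _ in range(2):
                cid = _fx(f"c{counter}")
                cats[cid] = ParticipantCategory(cid, f"category {counter}", frozenset({parent}))
                cat_children.setdefault(parent, []).append(cid)
                nxt.append(cid)
                counter += 1
        frontier = nxt

    # mode tree: root plus two levels of two children each
    modes: dict[TermId, Mode] = {}
    mode_children: dict[TermId, list[TermId]] = {}
    mroot = _fx("m0")
    modes[mroot] = Mode(mroot, "mode 0")
    mfrontier = [mroot]
    mcounter = 1
    for _ in range(2):
        nxt = []
        for parent in mfrontier:
            for _ in range(2):
                mid = _fx(f"m{mcounter}")
                modes[mid] = Mode(mid, f"mode {mcounter}", specializes=parent)
                mode_children.setdefault(parent, []).append(mid)
                nxt.append(mid)
                mcounter += 1
        mfrontier = nxt

    t_in = "{operand} is in the initial configuration"
    t_out = "{operand} is in the goal configuration"

    def make_ga(operand: TermId, mode: TermId | None, process: TermId | None) -> GoalAchievement:
        return GoalAchievement(
            input=Situation.make(t_in, operand=operand),
            output=Situation.make(t_out, operand=operand),
            operand=operand,
            mode=mode,
            process=process,
        )

    functions: dict[TermId, FunctionConcept] = {}
    links: list[SubsumptionLink] = []
    planted: dict[tuple[TermId, TermId], frozenset[Facet]] = {}
    processes: dict[TermId, str] = {}

    def new_function(i: int, operand: TermId, mode: TermId | None) -> FunctionConcept:
        process = None
        if rng.random() < 0.5:
            process = TermId(f"FX:p{i}")
            processes[process] = f"random process {i}"
        fc = FunctionConcept(
            id=_fx(f"f{i:04d}"),
            name=f"random function {i}",
            ga=make_ga(operand, mode, process),
        )
        functions[fc.id] = fc
        return fc

    new_function(0, root_cat, None)

    for i in range(1, n_functions):
        parent = functions[rng.choice(sorted(functions))]
        pga = parent.ga
        assert pga is not None
        operand, mode = pga.operand, pga.mode

        applicable = []
        if operand in cat_children:
            applicable.append(Facet.OPERAND_SPEC)
        if mode is None:
            applicable.append(Facet.MODE_ADDED)
        elif mode in mode_children:
            applicable.append(Facet.MODE_SPEC)

        edits: set[Facet] = set()
        if applicable and rng.random() < 0.85:
            edits.add(rng.choice(applicable))
            # sometimes combine the operand edit with the (single) mode edit
            others = [e for e in applicable if e not in edits]
            if others and rng.random() < 0.3:
                edits.add(rng.choice(others))

        if Facet.OPERAND_SPEC in edits:
            operand = rng.choice(cat_children[operand])
        if Facet.MODE_ADDED in edits:
            mode = rng.choice(sorted(modes))
        if Facet.MODE_SPEC in edits:
            mode = rng.choice(mode_children[mode])

        child = new_function(i, operand, mode)
        links.append(SubsumptionLink(child.id, parent.id))
        planted[(child.id, parent.id)] = frozenset(edits) if edits else frozenset({Facet.PLAIN})

    fragment = OntologyFragment(
        functions=functions,
        links=links,
        participant_taxonomy=cats,
        mode_taxonomy=modes,
        processes=processes,
    )
    return PlantedFragment(fragment=fragment, planted=planted, seed=seed)
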
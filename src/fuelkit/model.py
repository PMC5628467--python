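"""Core domain types for FueL function models.

FueL (Function Modeling Language) describes a molecular function through its
*goal achievement*: a teleological transition from an input situation to an
output situation, optionally constrained by a *mode* of realization and
involving *participants* — an operand (the entity acted on) and a doer (the
acting entity). Function terms, their declared ``is_a`` links, and the small
participant/mode taxonomies referenced by their goal achievements are bundled
into an :class:`OntologyFragment`.

Validation is centralized in :func:`validate_fragment`; the dataclasses
themselves stay permissive so that partially built or deliberately broken
fragments can be represented and reported on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Optional

import networkx as nx

__all__ = [
    "TermId",
    "ParticipantCategory",
    "Situation",
    "Mode",
    "GoalAchievement",
    "FunctionConcept",
    "Facet",
    "SubsumptionLink",
    "OntologyFragment",
    "Violation",
    "ValidationReport",
    "validate_fragment",
]

_CURIE_RE = re.compile(r"^([A-Za-z][A-Za-z0-9._-]*):(\S+)$")


class TermId(str):
    """A CURIE-style term identifier, ``PREFIX:LOCAL``.

    The prefix is normalized to upper case on construction; the local part is
    kept verbatim (GO local ids are numeric, but fixture-local categories use
    readable lower-case locals under the ``FX:`` prefix). Being a ``str``
    subclass, ids sort and hash like plain strings, which keeps every report
    deterministically ordered.
    """

    __slots__ = ()

    def __new__(cls, value: str) -> "TermId":
        m = _CURIE_RE.match(value)
        if m is None:
            raise ValueError(f"not a PREFIX:LOCAL term id: {value!r}")
        prefix, local = m.groups()
        return super().__new__(cls, f"{prefix.upper()}:{local}")

    @property
    def prefix(self) -> str:
        return self.partition(":")[0]

    @property
    def local(self) -> str:
        return self.partition(":")[2]


@dataclass(frozen=True)
class ParticipantCategory:
    """A category of potential goal-achievement participants.

    Houses operand and doer categories (e.g. *ion*, *cation*, *carbohydrate*);
    ``parents`` point into the fragment's participant taxonomy.
    """

    id: TermId
    label: str
    parents: frozenset[TermId] = frozenset()


_SLOT_RE = re.compile(r"\{([A-Za-z_][A-Za-z0-9_]*)\}")
_WS_RE = re.compile(r"\s+")


@dataclass(frozen=True)
class Situation:
    """A situation category given as a template with participant slots.

    Example: template ``"{operand} is on one side of the membrane"`` with the
    ``operand`` slot bound to the *carbohydrate* category. Structural
    comparison of situations is only defined between identical templates
    (after whitespace normalization); it then reduces to comparing the bound
    participant categories slot by slot.
    """

    template: str
    bindings: tuple[tuple[str, TermId], ...] = ()

    @staticmethod
    def make(template: str, **bindings: TermId) -> "Situation":
        return Situation(template, tuple(sorted(bindings.items())))

    def slots(self) -> frozenset[str]:
        return frozenset(_SLOT_RE.findall(self.template))

    def binding_map(self) -> dict[str, TermId]:
        return dict(self.bindings)

    @property
    def normalized_template(self) -> str:
        return _WS_RE.sub(" ", self.template).strip()

    def render(self, labels: dict[TermId, str]) -> str:
        """Fill the template with participant labels (falls back to the id)."""
        b = self.binding_map()
        return _SLOT_RE.sub(
            lambda m: labels.get(b.get(m.group(1), ""), str(b.get(m.group(1), m.group(0)))),
            self.template,
        )


@dataclass(frozen=True)
class Mode:
    """A mode of goal achievement: *how* the transition is realized.

    A mode constrains the manner of realization while leaving the input and
    output situations untouched (e.g. "driven by chemiosmotic energy
    sources"). ``specializes`` points to a more general mode, forming the
    fragment's mode taxonomy.
    """

    id: TermId
    description: str
    specializes: Optional[TermId] = None


@dataclass(frozen=True)
class GoalAchievement:
    """A teleological transition from an input to an output situation.

    ``process`` links the goal achievement to the GO biological-process term
    that realizes it (the ontology's ``part_of`` target); its absence marks a
    function with no corresponding process in the ontology.
    """

    input: Situation
    output: Situation
    mode: Optional[TermId] = None
    operand: Optional[TermId] = None
    doer: Optional[TermId] = None
    process: Optional[TermId] = None


@dataclass(frozen=True)
class FunctionConcept:
    """A GO-style molecular function term, optionally carrying FueL structure.

    A concept whose ``ga`` is absent is *unannotated*: it can sit in the
    hierarchy but cannot take part in structural subsumption or pattern
    classification. ``bearer`` names the entity playing the function role
    (the «plays» association of the extended notation), when known.
    """

    id: TermId
    name: str
    definition: str = ""
    synonyms: tuple[str, ...] = ()
    ga: Optional[GoalAchievement] = None
    bearer: Optional[str] = None


class Facet(str, Enum):
    """Classification of a declared is_a link between two functions."""

    PLAIN = "plain"
    OPERAND_SPEC = "operand-spec"
    MODE_ADDED = "mode-added"
    MODE_SPEC = "mode-spec"
    OUTPUT_SPEC = "output-spec"
    UNSUPPORTED = "unsupported"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class SubsumptionLink:
    """A declared is_a edge (child is_a parent) plus its classified facets."""

    child: TermId
    parent: TermId
    facets: frozenset[Facet] = frozenset()

    def with_facets(self, facets: Iterable[Facet]) -> "SubsumptionLink":
        return replace(self, facets=frozenset(facets))


@dataclass
class OntologyFragment:
    """A self-contained fragment: functions, links and supporting taxonomies.

    ``processes`` maps biological-process term ids to their names (empty
    string when unknown); ``externals`` lists raw cross-ontology ids declared
    as legal reference targets without a taxonomy entry of their own.
    """

    functions: dict[TermId, FunctionConcept] = field(default_factory=dict)
    links: list[SubsumptionLink] = field(default_factory=list)
    participant_taxonomy: dict[TermId, ParticipantCategory] = field(default_factory=dict)
    mode_taxonomy: dict[TermId, Mode] = field(default_factory=dict)
    processes: dict[TermId, str] = field(default_factory=dict)
    externals: frozenset[TermId] = frozenset()
    # relationships other than is_a/part_of, kept verbatim but never interpreted
    extra_relationships: dict[TermId, tuple[tuple[str, TermId], ...]] = field(
        default_factory=dict
    )

    # -- convenience accessors -------------------------------------------------

    def sorted_functions(self) -> list[FunctionConcept]:
        return [self.functions[i] for i in sorted(self.functions)]

    def sorted_links(self) -> list[SubsumptionLink]:
        return sorted(self.links, key=lambda l: (l.child, l.parent))

    def parents_of(self, term: TermId) -> list[TermId]:
        return sorted({l.parent for l in self.links if l.child == term})

    def children_of(self, term: TermId) -> list[TermId]:
        return sorted({l.child for l in self.links if l.parent == term})

    def child_links_of(self, term: TermId) -> list[SubsumptionLink]:
        return sorted(
            (l for l in self.links if l.parent == term), key=lambda l: (l.child, l.parent)
        )

    def isa_graph(self) -> "nx.DiGraph":
        """The child→parent is_a digraph over function terms."""
        g = nx.DiGraph()
        g.add_nodes_from(self.functions)
        g.add_edges_from((l.child, l.parent) for l in self.links)
        return g

    def participant_label(self, term: TermId) -> str:
        cat = self.participant_taxonomy.get(term)
        return cat.label if cat is not None else str(term)

    def copy(self) -> "OntologyFragment":
        return OntologyFragment(
            functions=dict(self.functions),
            links=list(self.links),
            participant_taxonomy=dict(self.participant_taxonomy),
            mode_taxonomy=dict(self.mode_taxonomy),
            processes=dict(self.processes),
            externals=self.externals,
            extra_relationships=dict(self.extra_relationships),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OntologyFragment):
            return NotImplemented
        return (
            self.functions == other.functions
            and sorted(self.links, key=lambda l: (l.child, l.parent)) == sorted(other.links, key=lambda l: (l.child, l.parent))
            and self.participant_taxonomy == other.participant_taxonomy
            and self.mode_taxonomy == other.mode_taxonomy
            and self.processes == other.processes
            and self.externals == other.externals
            and self.extra_relationships == other.extra_relationships
        )


@dataclass(frozen=True)
class Violation:
    kind: str
    offending_id: str
    message: str


ValidationReport = list[Violation]


def _resolves(fragment: OntologyFragment, term: TermId, *maps: dict) -> bool:
    return any(term in m for m in maps) or term in fragment.externals


def _taxonomy_cycle_violations(
    name: str, edges: Iterator[tuple[TermId, TermId]], nodes: Iterable[TermId]
) -> list[Violation]:
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    out = []
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        members = sorted({str(u) for u, _ in cycle})
        out.append(
            Violation(
                kind=f"{name}-cycle",
                offending_id=members[0],
                message=f"cycle in {name} relation involving: {', '.join(members)}",
            )
        )
    return out


def validate_fragment(fragment: OntologyFragment) -> ValidationReport:
    """Check every fragment invariant; violations are data, never exceptions.

    Returns the (possibly empty) list of violations sorted by (kind, id).
    The fragment is never mutated, and the check is idempotent.
    """
    v: list[Violation] = []
    fns = fragment.functions
    ptax = fragment.participant_taxonomy
    mtax = fragment.mode_taxonomy

    # function map keys vs ids
    for tid, fc in fns.items():
        if fc.id != tid:
            v.append(Violation("id-mismatch", str(tid), f"function keyed {tid} has id {fc.id}"))

    # participant taxonomy: parents resolve, acyclic
    for cat in ptax.values():
        for p in cat.parents:
            if p not in ptax:
                v.append(
                    Violation(
                        "dangling-participant-parent",
                        str(cat.id),
                        f"participant {cat.id} has unresolved parent {p}",
                    )
                )
    v += _taxonomy_cycle_violations(
        "participant",
        ((c.id, p) for c in ptax.values() for p in c.parents if p in ptax),
        ptax,
    )

    # mode taxonomy: specializes resolves, acyclic
    for mode in mtax.values():
        if mode.specializes is not None and mode.specializes not in mtax:
            v.append(
                Violation(
                    "dangling-mode-parent",
                    str(mode.id),
                    f"mode {mode.id} specializes unresolved {mode.specializes}",
                )
            )
    v += _taxonomy_cycle_violations(
        "mode",
        (
            (m.id, m.specializes)
            for m in mtax.values()
            if m.specializes is not None and m.specializes in mtax
        ),
        mtax,
    )

    # per-function goal achievement invariants
    for fc in fns.values():
        ga = fc.ga
        if ga is None:
            continue
        for which, sit in (("input", ga.input), ("output", ga.output)):
            slots = sit.slots()
            bound = set(sit.binding_map())
            for s in sorted(slots - bound):
                v.append(
                    Violation(
                        "unbound-slot",
                        str(fc.id),
                        f"{which} template slot {{{s}}} of {fc.id} has no binding",
                    )
                )
            for s in sorted(bound - slots):
                v.append(
                    Violation(
                        "dangling-binding",
                        str(fc.id),
                        f"{which} binding {s!r} of {fc.id} matches no template slot",
                    )
                )
            if "operand" in slots and ga.operand is None:
                v.append(
                    Violation(
                        "missing-operand",
                        str(fc.id),
                        f"{which} template of {fc.id} uses {{operand}} but the "
                        "goal achievement declares no operand",
                    )
                )
            for s, t in sit.bindings:
                if not _resolves(fragment, t, ptax):
                    v.append(
                        Violation(
                            "dangling-ref",
                            str(fc.id),
                            f"{which} binding {s}={t} of {fc.id} resolves nowhere",
                        )
                    )
        for label, ref, taxo in (
            ("operand", ga.operand, ptax),
            ("doer", ga.doer, ptax),
            ("mode", ga.mode, mtax),
        ):
            if ref is not None and not _resolves(fragment, ref, taxo):
                v.append(
                    Violation(
                        "dangling-ref",
                        str(fc.id),
                        f"{label} {ref} of {fc.id} resolves nowhere",
                    )
                )
        if ga.process is not None and not _resolves(fragment, ga.process, fragment.processes):
            v.append(
                Violation(
                    "dangling-ref",
                    str(fc.id),
                    f"process {ga.process} of {fc.id} resolves nowhere",
                )
            )

    # links: endpoints resolve, no self links, DAG
    for link in fragment.links:
        if link.child == link.parent:
            v.append(
                Violation("self-link", str(link.child), f"link {link.child} is_a itself")
            )
            continue
        for end in (link.child, link.parent):
            if end not in fns:
                v.append(
                    Violation(
                        "dangling-link",
                        str(end),
                        f"link {link.child} is_a {link.parent}: {end} is not a function",
                    )
                )
        if Facet.UNSUPPORTED in link.facets and len(link.facets) > 1:
            v.append(
                Violation(
                    "facet-conflict",
                    str(link.child),
                    f"link {link.child} is_a {link.parent}: 'unsupported' must be a singleton facet",
                )
            )
        if Facet.MODE_ADDED in link.facets and Facet.MODE_SPEC in link.facets:
            v.append(
                Violation(
                    "facet-conflict",
                    str(link.child),
                    f"link {link.child} is_a {link.parent}: mode-added and mode-spec cannot co-occur",
                )
            )
    g = nx.DiGraph()
    g.add_nodes_from(fns)
    g.add_edges_from(
        (l.child, l.parent)
        for l in fragment.links
        if l.child != l.parent and l.child in fns and l.parent in fns
    )
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        members = sorted({str(u) for u, _ in cycle})
        v.append(
            Violation(
                "isa-cycle",
                members[0],
                f"is_a cycle involving: {', '.join(members)}",
            )
        )

    return sorted(v, key=lambda x: (x.kind, x.offending_id, x.message))
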
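"""Diagram export: FueL's compact and extended notations.

FueL is a UML profile: model elements carry stereotypes rendered in guillemets
(«Function», «has-input», «operand-spec», ...). The profile splits its
stereotypes into two groups — 15 for representing functions and function
structure, 8 for function decomposition, subsumption and dependencies — and
:func:`default_registry` ships that catalogue. Seven stereotype names are
fixed by the pattern and notation definitions themselves; the remainder of
the catalogue is an explicit reconstruction from the profile's concepts and
is user-replaceable.

Two text backends are provided: PlantUML class-diagram syntax (primary, since
it renders guillemet stereotypes natively) and Graphviz DOT. The *compact*
notation shows one classifier per function with its goal achievement folded
into attributes; the *extended* notation explodes each function into its goal
achievement, situations, mode and participant categories with stereotyped
associations. All output is deterministic byte-for-byte.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .model import Facet, OntologyFragment, Situation, TermId

__all__ = [
    "Stereotype",
    "StereotypeRegistry",
    "RegistryError",
    "UnknownStereotypeError",
    "default_registry",
    "render_compact",
    "render_extended",
    "render_dot",
]

STRUCTURE = "structure"
RELATION = "relation"


class RegistryError(ValueError):
    """The registry breaks the 15-structure/8-relation profile invariant."""


class UnknownStereotypeError(ValueError):
    """A renderer was asked to emit a stereotype absent from the registry."""


@dataclass(frozen=True)
class Stereotype:
    name: str
    category: str  # structure | relation
    applies_to: str  # node | edge

    def guillemets(self) -> str:
        return f"«{self.name}»"


@dataclass(frozen=True)
class StereotypeRegistry:
    entries: tuple[Stereotype, ...]

    # the seven stereotype names fixed by the profile's published fragment
    REQUIRED = frozenset(
        {
            "Function",
            "has-goal-achievement",
            "has-input",
            "has-output",
            "operand-spec",
            "mode-added",
            "mode-spec",
        }
    )

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise RegistryError("stereotype names must be unique")
        n_struct = sum(1 for e in self.entries if e.category == STRUCTURE)
        n_rel = sum(1 for e in self.entries if e.category == RELATION)
        if (n_struct, n_rel) != (15, 8):
            raise RegistryError(
                f"profile declares 15 structure + 8 relation stereotypes, got "
                f"{n_struct} + {n_rel}"
            )
        missing = self.REQUIRED - set(names)
        if missing:
            raise RegistryError(f"registry lacks required stereotypes: {sorted(missing)}")

    def __contains__(self, name: str) -> bool:
        return any(e.name == name for e in self.entries)

    def get(self, name: str) -> Stereotype:
        for e in self.entries:
            if e.name == name:
                return e
        raise UnknownStereotypeError(f"stereotype not in registry: {name}")

    def count(self, category: str) -> int:
        return sum(1 for e in self.entries if e.category == category)


def default_registry() -> StereotypeRegistry:
    """The built-in FueL profile: 15 structure + 8 relation stereotypes.

    Structure covers functions and function structure (classifier stereotypes
    plus the structural has-* associations and the bearer's «plays»); relation
    covers subsumption patterns, decomposition and dependencies.
    """
    s, r = STRUCTURE, RELATION
    return StereotypeRegistry(
        entries=(
            # function structure — classifiers
            Stereotype("Function", s, "node"),
            Stereotype("GoalAchievement", s, "node"),
            Stereotype("InputSituation", s, "node"),
            Stereotype("OutputSituation", s, "node"),
            Stereotype("Mode", s, "node"),
            Stereotype("Operand", s, "node"),
            Stereotype("Doer", s, "node"),
            Stereotype("Bearer", s, "node"),
            # function structure — associations
            Stereotype("has-goal-achievement", s, "edge"),
            Stereotype("has-input", s, "edge"),
            Stereotype("has-output", s, "edge"),
            Stereotype("has-operand", s, "edge"),
            Stereotype("has-doer", s, "edge"),
            Stereotype("has-mode", s, "edge"),
            Stereotype("plays", s, "edge"),
            # subsumption patterns
            Stereotype("operand-spec", r, "edge"),
            Stereotype("mode-added", r, "edge"),
            Stereotype("mode-spec", r, "edge"),
            Stereotype("output-spec", r, "edge"),
            # decomposition and dependencies (reconstructed placeholders)
            Stereotype("subfunction-of", r, "edge"),
            Stereotype("depends-on", r, "edge"),
            Stereotype("requires", r, "edge"),
            Stereotype("triggers", r, "edge"),
        )
    )


_FACET_STEREOTYPE = {
    Facet.OPERAND_SPEC: "operand-spec",
    Facet.MODE_ADDED: "mode-added",
    Facet.MODE_SPEC: "mode-spec",
    Facet.OUTPUT_SPEC: "output-spec",
}

_ALIAS_RE = re.compile(r"[^A-Za-z0-9]")


def _alias(term: TermId | str, suffix: str = "") -> str:
    return _ALIAS_RE.sub("_", str(term)) + suffix


def _check(registry: StereotypeRegistry, name: str) -> str:
    """Guillemet-render a stereotype, failing fast if it is not registered."""
    return registry.get(name).guillemets()


def _facet_labels(
    facets: Iterable[Facet], registry: StereotypeRegistry
) -> list[str]:
    out = []
    for facet in sorted(f.value for f in facets):
        f = Facet(facet)
        if f in _FACET_STEREOTYPE:
            out.append(_check(registry, _FACET_STEREOTYPE[f]))
        elif f is Facet.UNSUPPORTED:
            out.append("(unsupported)")
        else:  # plain: an unstereotyped generalization
            pass
    return out


def _labels(fragment: OntologyFragment) -> dict[TermId, str]:
    return {c.id: c.label for c in fragment.participant_taxonomy.values()}


def _ga_name(fragment: OntologyFragment, fc) -> str:
    if fc.ga is not None and fc.ga.process is not None:
        name = fragment.processes.get(fc.ga.process, "")
        if name:
            return name
        return str(fc.ga.process)
    return f"{fc.name} goal achievement"


def render_compact(
    fragment: OntologyFragment, registry: Optional[StereotypeRegistry] = None
) -> str:
    """Compact notation as PlantUML: one «Function» classifier per term.

    Goal achievement, input, output, operand, mode and doer appear as
    attribute lines (absent fields are omitted); declared links become
    generalizations labeled with their facet stereotypes.
    """
    registry = registry or default_registry()
    labels = _labels(fragment)
    lines = ["@startuml", "skinparam classAttributeIconSize 0"]
    for fc in fragment.sorted_functions():
        stereo = _check(registry, "Function")
        lines.append(f'class "{fc.name or fc.id}" as {_alias(fc.id)} <<Function>> {{')
        if fc.ga is not None:
            ga = fc.ga
            lines.append(f"  goal_achievement = {_ga_name(fragment, fc)}")
            lines.append(f"  input = {ga.input.render(labels)}")
            lines.append(f"  output = {ga.output.render(labels)}")
            if ga.operand is not None:
                lines.append(f"  operand = {fragment.participant_label(ga.operand)}")
            if ga.mode is not None:
                mode = fragment.mode_taxonomy.get(ga.mode)
                lines.append(
                    f"  mode = {mode.description if mode and mode.description else ga.mode}"
                )
            if ga.doer is not None:
                lines.append(f"  doer = {fragment.participant_label(ga.doer)}")
        lines.append("}")
        del stereo  # registry check is the point; PlantUML takes <<Function>> above
    for link in fragment.sorted_links():
        label = " ".join(_facet_labels(link.facets, registry))
        edge = f"{_alias(link.parent)} <|-- {_alias(link.child)}"
        lines.append(f"{edge} : {label}" if label else edge)
    lines.append("@enduml")
    return "\n".join(lines) + "\n"


def render_extended(
    fragment: OntologyFragment, registry: Optional[StereotypeRegistry] = None
) -> str:
    """Extended notation as PlantUML: function structure as separate nodes.

    Each function links to its goal achievement («has-goal-achievement»),
    which links to input/output situations («has-input»/«has-output»), its
    operand/doer categories, and its mode; a bearer entity attaches with
    «plays». Participant categories shared between functions are rendered
    once.
    """
    registry = registry or default_registry()
    labels = _labels(fragment)
    lines = ["@startuml", "skinparam classAttributeIconSize 0"]
    emitted_categories: set[TermId] = set()
    emitted_modes: set[TermId] = set()
    edges: list[str] = []

    def category_node(cid: TermId, stereotype: str) -> str:
        a = _alias(cid, "_cat")
        if cid not in emitted_categories:
            _check(registry, stereotype)
            lines.append(
                f'class "{fragment.participant_label(cid)}" as {a} <<{stereotype}>>'
            )
            emitted_categories.add(cid)
        return a

    for fc in fragment.sorted_functions():
        _check(registry, "Function")
        fa = _alias(fc.id)
        lines.append(f'class "{fc.name or fc.id}" as {fa} <<Function>>')
        if fc.ga is None:
            continue
        ga = fc.ga
        ga_alias = _alias(fc.id, "_ga")
        _check(registry, "GoalAchievement")
        lines.append(f'class "{_ga_name(fragment, fc)}" as {ga_alias} <<GoalAchievement>>')
        edges.append(f'{fa} --> {ga_alias} : {_check(registry, "has-goal-achievement")}')
        for which, sit, stereo in (
            ("in", ga.input, "InputSituation"),
            ("out", ga.output, "OutputSituation"),
        ):
            sa = _alias(fc.id, f"_{which}")
            _check(registry, stereo)
            lines.append(f'class "{sit.render(labels)}" as {sa} <<{stereo}>>')
            edges.append(
                f'{ga_alias} --> {sa} : '
                f'{_check(registry, "has-input" if which == "in" else "has-output")}'
            )
        if ga.operand is not None:
            oa = category_node(ga.operand, "Operand")
            edges.append(f'{ga_alias} --> {oa} : {_check(registry, "has-operand")}')
        if ga.doer is not None:
            da = category_node(ga.doer, "Doer")
            edges.append(f'{ga_alias} --> {da} : {_check(registry, "has-doer")}')
        if ga.mode is not None:
            ma = _alias(ga.mode, "_mode")
            if ga.mode not in emitted_modes:
                mode = fragment.mode_taxonomy.get(ga.mode)
                desc = mode.description if mode and mode.description else str(ga.mode)
                _check(registry, "Mode")
                lines.append(f'class "{desc}" as {ma} <<Mode>>')
                emitted_modes.add(ga.mode)
            edges.append(f'{ga_alias} --> {ma} : {_check(registry, "has-mode")}')
        if fc.bearer:
            ba = _alias(fc.id, "_bearer")
            _check(registry, "Bearer")
            lines.append(f'class "{fc.bearer}" as {ba} <<Bearer>>')
            edges.append(f'{ba} --> {fa} : {_check(registry, "plays")}')
    for link in fragment.sorted_links():
        label = " ".join(_facet_labels(link.facets, registry))
        edge = f"{_alias(link.parent)} <|-- {_alias(link.child)}"
        edges.append(f"{edge} : {label}" if label else edge)
    lines.extend(edges)
    lines.append("@enduml")
    return "\n".join(lines) + "\n"


def _dot_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def _record_escape(text: str) -> str:
    """Escape user text for use inside a DOT record label field."""
    out = text.replace("\\", "\\\\").replace('"', '\\"')
    for ch in "{}|<>":
        out = out.replace(ch, "\\" + ch)
    return out


def render_dot(
    fragment: OntologyFragment, registry: Optional[StereotypeRegistry] = None
) -> str:
    """Compact notation as Graphviz DOT.

    Generalization edges point child→parent with an empty arrowhead (UML
    style); facet stereotypes become edge labels.
    """
    registry = registry or default_registry()
    labels = _labels(fragment)
    lines = [
        "digraph fuel {",
        "  rankdir=BT;",
        '  node [shape=record, fontname="Helvetica"];',
        '  edge [arrowhead=empty, fontname="Helvetica"];',
    ]
    for fc in fragment.sorted_functions():
        stereo = _check(registry, "Function")
        parts = [_record_escape(stereo) + "\\n" + _record_escape(fc.name or fc.id)]
        if fc.ga is not None:
            ga = fc.ga
            attrs = [
                f"goal_achievement = {_ga_name(fragment, fc)}",
                f"input = {ga.input.render(labels)}",
                f"output = {ga.output.render(labels)}",
            ]
            if ga.operand is not None:
                attrs.append(f"operand = {fragment.participant_label(ga.operand)}")
            if ga.mode is not None:
                mode = fragment.mode_taxonomy.get(ga.mode)
                attrs.append(
                    f"mode = {mode.description if mode and mode.description else ga.mode}"
                )
            if ga.doer is not None:
                attrs.append(f"doer = {fragment.participant_label(ga.doer)}")
            parts.append("\\l".join(_record_escape(a) for a in attrs) + "\\l")
        label = "{" + "|".join(parts) + "}"
        lines.append(f'  "{_dot_escape(str(fc.id))}" [label="{label}"];')
    for link in fragment.sorted_links():
        label = ", ".join(_facet_labels(link.facets, registry))
        attr = f' [label="{_dot_escape(label)}"]' if label else ""
        lines.append(
            f'  "{_dot_escape(str(link.child))}" -> "{_dot_escape(str(link.parent))}"{attr};'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"
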
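"""OBO flat-file I/O plus the YAML sidecar carrying FueL structure.

The OBO 1.2 flat file carries what the ontology itself records: term stanzas
with id, name, definition, synonyms, ``is_a`` parents and ``relationship``
lines. FueL structure (goal achievements, operands, modes, the participant and
mode taxonomies) has no OBO serialization, so it travels in a YAML *sidecar*
keyed by term id; :func:`assemble_fragment` merges the two into an
:class:`~fuelkit.model.OntologyFragment`.

Only ``is_a`` and ``part_of`` are interpreted — ``part_of`` on a function term
names the process realizing its goal achievement. Every other relationship is
preserved verbatim for round-tripping.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Optional, Union

import yaml

from .model import (
    FunctionConcept,
    GoalAchievement,
    Mode,
    OntologyFragment,
    ParticipantCategory,
    Situation,
    SubsumptionLink,
    TermId,
    validate_fragment,
)

__all__ = [
    "OboStanza",
    "OboParseError",
    "SidecarError",
    "AssemblyError",
    "Sidecar",
    "parse_obo",
    "write_obo",
    "load_sidecar",
    "write_sidecar",
    "assemble_fragment",
    "fragment_to_stanzas",
    "load_fragment",
]

logger = logging.getLogger(__name__)

_KNOWN_TAGS = {"id", "name", "def", "synonym", "is_a", "relationship", "is_obsolete"}


class OboParseError(ValueError):
    """Malformed OBO input; the message names the offending line number."""


class SidecarError(ValueError):
    """Schema violation or unresolved reference in a sidecar file."""


class AssemblyError(ValueError):
    """The merged fragment failed validation; violations are in the message."""


@dataclass(frozen=True)
class OboStanza:
    """One ``[Term]`` stanza, fields in OBO tag order."""

    id: TermId
    name: str = ""
    definition: str = ""
    synonyms: tuple[str, ...] = ()
    is_a: tuple[TermId, ...] = ()
    relationships: tuple[tuple[str, TermId], ...] = ()


def _strip_comment(value: str) -> str:
    # an unescaped "!" starts a trailing comment
    out = []
    prev = ""
    for ch in value:
        if ch == "!" and prev != "\\":
            break
        out.append(ch)
        prev = ch
    return "".join(out).strip()


_DEF_RE = re.compile(r'"((?:[^"\\]|\\.)*)"')


def _unquote_def(value: str, lineno: int) -> str:
    m = _DEF_RE.search(value)
    if m is None:
        raise OboParseError(f"line {lineno}: def tag lacks a quoted string: {value!r}")
    return m.group(1).replace('\\"', '"').replace("\\\\", "\\")


def _quote_def(text: str) -> str:
    return '"' + text.replace("\\", "\\\\").replace('"', '\\"') + '" []'


def parse_obo(source: Union[str, IO[str]]) -> list[OboStanza]:
    """Parse OBO 1.2 text into a list of ``[Term]`` stanzas, in file order.

    The header and non-``[Term]`` stanzas are skipped; unknown tags and
    obsolete terms are skipped with a logged warning. A ``[Term]`` stanza
    without an ``id`` raises :class:`OboParseError` naming the line.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = source
    stanzas: list[OboStanza] = []

    cur: Optional[dict] = None
    cur_start = 0
    in_term = False

    def flush() -> None:
        nonlocal cur
        if cur is None:
            return
        if cur.get("obsolete"):
            logger.warning("skipping obsolete term %s", cur.get("id", "<no id>"))
            cur = None
            return
        if "id" not in cur:
            raise OboParseError(f"line {cur_start}: [Term] stanza without an id tag")
        stanzas.append(
            OboStanza(
                id=cur["id"],
                name=cur.get("name", ""),
                definition=cur.get("def", ""),
                synonyms=tuple(cur.get("synonyms", [])),
                is_a=tuple(cur.get("is_a", [])),
                relationships=tuple(cur.get("relationships", [])),
            )
        )
        cur = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("["):
            flush()
            in_term = line == "[Term]"
            if in_term:
                cur = {}
                cur_start = lineno
            elif line not in ("[Term]",):
                logger.warning("line %d: skipping stanza %s", lineno, line)
            continue
        if not in_term or cur is None:
            continue  # header or foreign stanza content
        tag, sep, value = line.partition(":")
        if not sep:
            logger.warning("line %d: ignoring malformed line %r", lineno, line)
            continue
        tag = tag.strip()
        value = value.strip()
        if tag not in _KNOWN_TAGS:
            logger.warning("line %d: ignoring tag %r", lineno, tag)
            continue
        if tag == "id":
            try:
                cur["id"] = TermId(_strip_comment(value))
            except ValueError as e:
                raise OboParseError(f"line {lineno}: {e}") from None
        elif tag == "name":
            cur["name"] = _strip_comment(value)
        elif tag == "def":
            cur["def"] = _unquote_def(value, lineno)
        elif tag == "synonym":
            cur.setdefault("synonyms", []).append(value)
        elif tag == "is_a":
            cur.setdefault("is_a", []).append(TermId(_strip_comment(value)))
        elif tag == "relationship":
            body = _strip_comment(value)
            parts = body.split(None, 1)
            if len(parts) != 2:
                raise OboParseError(
                    f"line {lineno}: relationship needs a relation and a target: {value!r}"
                )
            rel, target = parts
            cur.setdefault("relationships", []).append((rel, TermId(target)))
        elif tag == "is_obsolete":
            cur["obsolete"] = value.lower().startswith("true")
    flush()
    return stanzas


def write_obo(stanzas: Iterable[OboStanza]) -> str:
    """Serialize stanzas as OBO 1.2 text; ``parse_obo`` round-trips it exactly.

    Tags are emitted in fixed order (id, name, def, synonym*, is_a*,
    relationship*), stanzas in input order.
    """
    out = io.StringIO()
    out.write("format-version: 1.2\n")
    for st in stanzas:
        out.write("\n[Term]\n")
        out.write(f"id: {st.id}\n")
        if st.name:
            out.write(f"name: {st.name}\n")
        if st.definition:
            out.write(f"def: {_quote_def(st.definition)}\n")
        for syn in st.synonyms:
            out.write(f"synonym: {syn}\n")
        for parent in st.is_a:
            out.write(f"is_a: {parent}\n")
        for rel, target in st.relationships:
            out.write(f"relationship: {rel} {target}\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Sidecar


@dataclass(frozen=True)
class Sidecar:
    """Parsed sidecar content, before merging with the OBO stanzas."""

    annotations: dict[TermId, GoalAchievement] = field(default_factory=dict)
    participant_taxonomy: dict[TermId, ParticipantCategory] = field(default_factory=dict)
    mode_taxonomy: dict[TermId, Mode] = field(default_factory=dict)
    externals: frozenset[TermId] = frozenset()
    bearers: dict[TermId, str] = field(default_factory=dict)


class _StrictLoader(yaml.SafeLoader):
    """SafeLoader that rejects duplicate mapping keys (duplicate annotations)."""


def _strict_map(loader: _StrictLoader, node: yaml.MappingNode):
    seen = set()
    for key_node, _ in node.value:
        key = loader.construct_object(key_node, deep=True)
        if key in seen:
            raise SidecarError(f"duplicate entry for {key!r}")
        seen.add(key)
    return loader.construct_mapping(node, deep=True)


_StrictLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _strict_map
)


def _situation_from(raw: dict, owner: str, which: str) -> Situation:
    if not isinstance(raw, dict) or "template" not in raw:
        raise SidecarError(f"{owner}: {which} must be a mapping with a 'template' key")
    bindings = raw.get("bindings", {}) or {}
    if not isinstance(bindings, dict):
        raise SidecarError(f"{owner}: {which} bindings must be a mapping")
    return Situation(
        template=str(raw["template"]),
        bindings=tuple(sorted((str(k), TermId(str(v))) for k, v in bindings.items())),
    )


def load_sidecar(source: Union[str, IO[str]]) -> Sidecar:
    """Load a YAML sidecar (a JSON-compatible subset is equally accepted).

    Top-level keys: ``functions``, ``participants``, ``modes``, ``externals``.
    Every category/mode reference must resolve in the sidecar's own taxonomies
    or be declared under ``externals``; duplicate annotations for one term are
    rejected.
    """
    text = source.read() if hasattr(source, "read") else source
    try:
        doc = yaml.load(text, Loader=_StrictLoader) or {}
    except yaml.YAMLError as e:
        raise SidecarError(f"invalid YAML: {e}") from None
    if not isinstance(doc, dict):
        raise SidecarError("sidecar root must be a mapping")
    unknown = set(doc) - {"functions", "participants", "modes", "externals"}
    for key in sorted(unknown):
        logger.warning("ignoring unknown sidecar key %r", key)

    externals = frozenset(TermId(str(x)) for x in (doc.get("externals") or []))

    participants: dict[TermId, ParticipantCategory] = {}
    for pid, spec in (doc.get("participants") or {}).items():
        tid = TermId(str(pid))
        spec = spec or {}
        participants[tid] = ParticipantCategory(
            id=tid,
            label=str(spec.get("label", tid.local)),
            parents=frozenset(TermId(str(p)) for p in (spec.get("parents") or [])),
        )

    modes: dict[TermId, Mode] = {}
    for mid, spec in (doc.get("modes") or {}).items():
        tid = TermId(str(mid))
        spec = spec or {}
        sp = spec.get("specializes")
        modes[tid] = Mode(
            id=tid,
            description=str(spec.get("description", "")),
            specializes=TermId(str(sp)) if sp is not None else None,
        )

    def check_ref(owner: str, kind: str, ref: Optional[TermId], taxonomy: dict) -> None:
        if ref is None:
            return
        if ref not in taxonomy and ref not in externals:
            raise SidecarError(f"{owner}: unresolved {kind} reference {ref}")

    for cat in participants.values():
        for p in cat.parents:
            check_ref(str(cat.id), "participant parent", p, participants)
    for mode in modes.values():
        check_ref(str(mode.id), "mode parent", mode.specializes, modes)

    annotations: dict[TermId, GoalAchievement] = {}
    bearers: dict[TermId, str] = {}
    for fid, spec in (doc.get("functions") or {}).items():
        tid = TermId(str(fid))
        if tid in annotations:
            raise SidecarError(f"duplicate annotation for {tid}")
        spec = spec or {}
        if "input" not in spec or "output" not in spec:
            raise SidecarError(f"{tid}: annotation needs 'input' and 'output' situations")
        ga = GoalAchievement(
            input=_situation_from(spec["input"], str(tid), "input"),
            output=_situation_from(spec["output"], str(tid), "output"),
            operand=TermId(str(spec["operand"])) if spec.get("operand") else None,
            doer=TermId(str(spec["doer"])) if spec.get("doer") else None,
            mode=TermId(str(spec["mode"])) if spec.get("mode") else None,
            process=TermId(str(spec["process"])) if spec.get("process") else None,
        )
        check_ref(str(tid), "operand", ga.operand, participants)
        check_ref(str(tid), "doer", ga.doer, participants)
        check_ref(str(tid), "mode", ga.mode, modes)
        for which, sit in (("input", ga.input), ("output", ga.output)):
            for slot, ref in sit.bindings:
                check_ref(f"{tid}/{which}", f"binding {slot}", ref, participants)
        annotations[tid] = ga
        if spec.get("bearer"):
            bearers[tid] = str(spec["bearer"])

    return Sidecar(annotations, participants, modes, externals, bearers)


def write_sidecar(fragment: OntologyFragment) -> str:
    """Serialize a fragment's FueL structure to deterministic sidecar YAML."""
    doc: dict = {}
    functions: dict = {}
    for fc in fragment.sorted_functions():
        if fc.ga is None:
            continue
        ga = fc.ga
        entry: dict = {
            "input": {
                "template": ga.input.template,
                "bindings": {k: str(v) for k, v in ga.input.bindings},
            },
            "output": {
                "template": ga.output.template,
                "bindings": {k: str(v) for k, v in ga.output.bindings},
            },
        }
        for key, val in (
            ("operand", ga.operand),
            ("doer", ga.doer),
            ("mode", ga.mode),
            ("process", ga.process),
        ):
            if val is not None:
                entry[key] = str(val)
        if fc.bearer:
            entry["bearer"] = fc.bearer
        functions[str(fc.id)] = entry
    doc["functions"] = functions
    doc["participants"] = {
        str(c.id): {"label": c.label, "parents": sorted(str(p) for p in c.parents)}
        for c in (fragment.participant_taxonomy[i] for i in sorted(fragment.participant_taxonomy))
    }
    doc["modes"] = {
        str(m.id): (
            {"description": m.description}
            | ({"specializes": str(m.specializes)} if m.specializes else {})
        )
        for m in (fragment.mode_taxonomy[i] for i in sorted(fragment.mode_taxonomy))
    }
    doc["externals"] = sorted(str(x) for x in fragment.externals)
    return yaml.safe_dump(doc, sort_keys=True, allow_unicode=True, default_flow_style=False)


# ---------------------------------------------------------------------------
# Assembly


def assemble_fragment(
    stanzas: Iterable[OboStanza], sidecar: Optional[Sidecar] = None
) -> OntologyFragment:
    """Merge OBO stanzas with a sidecar into a validated fragment.

    ``is_a`` pairs become unclassified links; a ``part_of`` target fills the
    goal achievement's process slot unless the sidecar already set it (the
    sidecar wins, with a logged warning). Stanzas whose id is only ever named
    as a process — a ``part_of`` target or a sidecar ``process`` value, never
    annotated or linked as a function — become process entries rather than
    function concepts. A fragment that fails validation aborts assembly.
    """
    sidecar = sidecar or Sidecar()
    stanzas = list(stanzas)
    stanza_ids = {st.id for st in stanzas}

    process_ids: set[TermId] = set()
    for st in stanzas:
        process_ids.update(t for rel, t in st.relationships if rel == "part_of")
    process_ids.update(
        ga.process for ga in sidecar.annotations.values() if ga.process is not None
    )
    function_ids: set[TermId] = set()
    for st in stanzas:
        if st.id in sidecar.annotations or st.is_a or st.id not in process_ids:
            function_ids.add(st.id)
        function_ids.update(p for p in st.is_a)
    process_ids -= function_ids

    functions: dict[TermId, FunctionConcept] = {}
    links: list[SubsumptionLink] = []
    processes: dict[TermId, str] = {}
    extra: dict[TermId, tuple[tuple[str, TermId], ...]] = {}

    for st in stanzas:
        if st.id in process_ids:
            processes[st.id] = st.name
            continue
        ga = sidecar.annotations.get(st.id)
        part_of = [t for rel, t in st.relationships if rel == "part_of"]
        if ga is not None and part_of:
            if ga.process is None:
                ga = replace(ga, process=part_of[0])
            elif ga.process != part_of[0]:
                logger.warning(
                    "%s: sidecar process %s overrides OBO part_of %s",
                    st.id,
                    ga.process,
                    part_of[0],
                )
        functions[st.id] = FunctionConcept(
            id=st.id,
            name=st.name,
            definition=st.definition,
            synonyms=st.synonyms,
            ga=ga,
            bearer=sidecar.bearers.get(st.id),
        )
        links.extend(SubsumptionLink(child=st.id, parent=p) for p in st.is_a)
        other = tuple((rel, t) for rel, t in st.relationships if rel != "part_of")
        if other:
            extra[st.id] = other

    for pid in sorted(process_ids):
        processes.setdefault(pid, "")
    # processes referenced only from the sidecar, with no stanza of their own
    for ga in sidecar.annotations.values():
        if ga.process is not None and ga.process not in functions:
            processes.setdefault(ga.process, "")

    fragment = OntologyFragment(
        functions=functions,
        links=links,
        participant_taxonomy=dict(sidecar.participant_taxonomy),
        mode_taxonomy=dict(sidecar.mode_taxonomy),
        processes=processes,
        externals=sidecar.externals,
        extra_relationships=extra,
    )
    report = validate_fragment(fragment)
    if report:
        lines = "; ".join(f"{x.kind}[{x.offending_id}]: {x.message}" for x in report)
        raise AssemblyError(f"assembled fragment is invalid: {lines}")
    return fragment


def fragment_to_stanzas(fragment: OntologyFragment) -> list[OboStanza]:
    """Regenerate OBO stanzas: functions (sorted by id), then process terms."""
    stanzas: list[OboStanza] = []
    for fc in fragment.sorted_functions():
        rels: list[tuple[str, TermId]] = []
        if fc.ga is not None and fc.ga.process is not None:
            rels.append(("part_of", fc.ga.process))
        rels.extend(fragment.extra_relationships.get(fc.id, ()))
        stanzas.append(
            OboStanza(
                id=fc.id,
                name=fc.name,
                definition=fc.definition,
                synonyms=fc.synonyms,
                is_a=tuple(fragment.parents_of(fc.id)),
                relationships=tuple(rels),
            )
        )
    for pid in sorted(fragment.processes):
        stanzas.append(OboStanza(id=pid, name=fragment.processes[pid]))
    return stanzas


def load_fragment(obo_path, sidecar_path=None) -> OntologyFragment:
    """Convenience wrapper: read files and assemble."""
    with open(obo_path, encoding="utf-8") as fh:
        stanzas = parse_obo(fh)
    sidecar = None
    if sidecar_path is not None:
        with open(sidecar_path, encoding="utf-8") as fh:
            sidecar = load_sidecar(fh)
    return assemble_fragment(stanzas, sidecar)
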
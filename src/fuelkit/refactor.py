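"""Pattern-driven refactoring analysis of a classified fragment.

The classifier's facets make certain taxonomy smells mechanically visible. The
chief one is the *grouping artifact*: a term introduced purely to collect all
children that differ only in their operands, duplicating its own parent's
function specification. Such terms can be dropped, with their children rewired
to the parent, without changing what the hierarchy says. The analyzer also
proposes *reattachments* (functions structurally subsumed by a group term but
not declared under it), lists functions whose goal achievement lacks a
realizing process, and profiles a term's specialization style (mode-dominant
vs operand-dominant).

All operations report; none silently edits — the decision stays with the
ontology's curators. :func:`apply_drop` performs one explicitly requested edit
and guarantees the subsumption closure over the surviving terms is unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx

from .model import Facet, OntologyFragment, SubsumptionLink, TermId
from .patterns import ClassifyOptions, classify_link
from .subsumption import UnannotatedError, function_subsumes

__all__ = [
    "NotClassifiedError",
    "GroupingCandidate",
    "ChangeLog",
    "RefactorReport",
    "find_grouping_artifacts",
    "apply_drop",
    "find_reattachment_candidates",
    "find_missing_goal_achievements",
    "TermProfile",
    "profile_term",
    "build_report",
    "report_to_tsv",
    "report_to_json",
]


class NotClassifiedError(ValueError):
    """An analysis that needs facets was run on an unclassified fragment."""


def _require_classified(fragment: OntologyFragment) -> None:
    for link in fragment.links:
        child = fragment.functions.get(link.child)
        parent = fragment.functions.get(link.parent)
        if child is None or parent is None:
            continue
        if child.ga is not None and parent.ga is not None and not link.facets:
            raise NotClassifiedError(
                f"link {link.child} is_a {link.parent} has no facets; "
                "run classify_fragment first"
            )


@dataclass(frozen=True)
class GroupingCandidate:
    term: TermId
    parents: tuple[TermId, ...]
    evidence: tuple[tuple[TermId, frozenset[Facet]], ...]  # per-child facet sets


def find_grouping_artifacts(fragment: OntologyFragment) -> list[GroupingCandidate]:
    """Terms that merely group their operand-distinguished children.

    A term ``g`` qualifies iff (i) it has at least two children and every
    child link carries facets within {operand-spec}; (ii) some parent link of
    ``g`` carries facets within {operand-spec, plain}; and (iii) rewiring is
    sound: that parent structurally subsumes every child of ``g``.
    """
    _require_classified(fragment)
    out: list[GroupingCandidate] = []
    for term in sorted(fragment.functions):
        child_links = fragment.child_links_of(term)
        if len(child_links) < 2:
            continue
        if not all(l.facets and l.facets <= {Facet.OPERAND_SPEC} for l in child_links):
            continue
        good_parents = []
        for plink in (l for l in fragment.sorted_links() if l.child == term):
            if not (plink.facets and plink.facets <= {Facet.OPERAND_SPEC, Facet.PLAIN}):
                continue
            parent = fragment.functions[plink.parent]
            try:
                if all(
                    function_subsumes(
                        parent,
                        fragment.functions[cl.child],
                        fragment.participant_taxonomy,
                        fragment.mode_taxonomy,
                    )
                    for cl in child_links
                ):
                    good_parents.append(plink.parent)
            except UnannotatedError:
                continue
        if good_parents:
            out.append(
                GroupingCandidate(
                    term=term,
                    parents=tuple(sorted(good_parents)),
                    evidence=tuple((l.child, l.facets) for l in child_links),
                )
            )
    return out


@dataclass(frozen=True)
class ChangeLog:
    removed_term: TermId
    removed_links: tuple[SubsumptionLink, ...]
    added_links: tuple[SubsumptionLink, ...]


def apply_drop(
    fragment: OntologyFragment,
    term: TermId,
    options: ClassifyOptions = ClassifyOptions(),
) -> tuple[OntologyFragment, ChangeLog]:
    """Drop a term, rewiring its children to its parents.

    A child→parent link is added only where the remaining graph offers no
    path already, so a transitively reduced link set stays reduced. The
    transitive is_a closure over the surviving terms equals the original
    closure restricted to them. New links are classified when both endpoints
    are annotated.
    """
    if term not in fragment.functions:
        raise KeyError(f"no such term: {term}")
    parents = fragment.parents_of(term)
    if not parents:
        raise ValueError(f"cannot drop root term {term} (it has no parents)")
    children = fragment.children_of(term)

    removed = tuple(
        l for l in fragment.sorted_links() if term in (l.child, l.parent)
    )
    surviving = [l for l in fragment.links if term not in (l.child, l.parent)]

    g = nx.DiGraph()
    g.add_nodes_from(t for t in fragment.functions if t != term)
    g.add_edges_from((l.child, l.parent) for l in surviving)

    added: list[SubsumptionLink] = []
    for child in children:
        for parent in parents:
            if nx.has_path(g, child, parent):
                continue
            cf = fragment.functions[child]
            pf = fragment.functions[parent]
            facets: frozenset[Facet] = frozenset()
            if cf.ga is not None and pf.ga is not None:
                facets = classify_link(
                    cf, pf, fragment.participant_taxonomy, fragment.mode_taxonomy, options
                )
            link = SubsumptionLink(child=child, parent=parent, facets=facets)
            added.append(link)
            g.add_edge(child, parent)

    out = fragment.copy()
    out.functions = {k: v for k, v in fragment.functions.items() if k != term}
    out.links = surviving + added
    out.extra_relationships = {
        k: v for k, v in fragment.extra_relationships.items() if k != term
    }
    return out, ChangeLog(term, removed, tuple(added))


def find_reattachment_candidates(
    fragment: OntologyFragment, group_term: TermId
) -> list[tuple[TermId, TermId]]:
    """Functions the group term structurally subsumes but does not yet collect.

    Proposes every annotated function (other than the group term, and not one
    of its ancestors) that the group term subsumes while no declared is_a path
    leads from it to the group term.
    """
    group = fragment.functions.get(group_term)
    if group is None:
        raise KeyError(f"no such term: {group_term}")
    if group.ga is None:
        raise UnannotatedError(f"group term {group_term} carries no goal achievement")
    g = fragment.isa_graph()
    ancestors = nx.descendants(g, group_term)  # child→parent edges: up-set
    out: list[tuple[TermId, TermId]] = []
    for fid in sorted(fragment.functions):
        if fid == group_term or fid in ancestors:
            continue
        fc = fragment.functions[fid]
        if fc.ga is None:
            continue
        if nx.has_path(g, fid, group_term):
            continue
        if function_subsumes(
            group, fc, fragment.participant_taxonomy, fragment.mode_taxonomy
        ):
            out.append((fid, group_term))
    return out


def find_missing_goal_achievements(
    fragment: OntologyFragment,
) -> tuple[list[TermId], list[TermId]]:
    """Functions with no realizing process, and functions with no structure at all.

    Returns ``(no_process, unannotated)``, both sorted: the first lists
    annotated functions whose goal achievement names no process term, the
    second lists functions without any goal achievement.
    """
    no_process: list[TermId] = []
    unannotated: list[TermId] = []
    for fid in sorted(fragment.functions):
        fc = fragment.functions[fid]
        if fc.ga is None:
            unannotated.append(fid)
        elif fc.ga.process is None:
            no_process.append(fid)
    return no_process, unannotated


@dataclass(frozen=True)
class TermProfile:
    """Specialization style of a term over its direct child links."""

    term: TermId
    counts: dict[str, int]
    n_links: int
    style: str  # mode-dominant | operand-dominant | mixed | undetermined


def profile_term(
    fragment: OntologyFragment,
    term: TermId,
    majority: float = 0.5,
    max_offstyle: int = 1,
) -> TermProfile:
    """Tally facets across a term's direct child links and label the style.

    A term is *mode-dominant* when more than ``majority`` of its classified
    child links carry a mode facet (mode-added or mode-spec) and at most
    ``max_offstyle`` of them are operand-spec-only; *operand-dominant*
    symmetrically; otherwise *mixed*. A link with several facets feeds every
    matching counter. No classified child links → *undetermined*.
    """
    if term not in fragment.functions:
        raise KeyError(f"no such term: {term}")
    child_links = [l for l in fragment.child_links_of(term) if l.facets]
    counts = {f.value: 0 for f in Facet}
    for link in child_links:
        for facet in link.facets:
            counts[facet.value] += 1
    n = len(child_links)
    if n == 0:
        return TermProfile(term, counts, 0, "undetermined")

    mode_facets = {Facet.MODE_ADDED, Facet.MODE_SPEC}
    n_mode = sum(1 for l in child_links if l.facets & mode_facets)
    n_operand = sum(1 for l in child_links if Facet.OPERAND_SPEC in l.facets)
    n_mode_only = sum(
        1 for l in child_links if l.facets & mode_facets and Facet.OPERAND_SPEC not in l.facets
    )
    n_operand_only = sum(
        1 for l in child_links if Facet.OPERAND_SPEC in l.facets and not l.facets & mode_facets
    )
    if n_mode > majority * n and n_operand_only <= max_offstyle:
        style = "mode-dominant"
    elif n_operand > majority * n and n_mode_only <= max_offstyle:
        style = "operand-dominant"
    else:
        style = "mixed"
    return TermProfile(term, counts, n, style)


# ---------------------------------------------------------------------------
# Report container + serialization


@dataclass
class RefactorReport:
    grouping_candidates: list[GroupingCandidate] = field(default_factory=list)
    reattachments: list[tuple[TermId, TermId]] = field(default_factory=list)
    missing_ga: tuple[list[TermId], list[TermId]] = field(default_factory=lambda: ([], []))
    notes: list[str] = field(default_factory=list)


def build_report(fragment: OntologyFragment) -> RefactorReport:
    """Full analysis: grouping artifacts, their reattachments, missing processes.

    For each grouping candidate, descendants that add or specialize a mode the
    candidate lacks are flagged in ``notes`` — their membership under a purely
    operand-grouping term is questionable rather than wrong.
    """
    candidates = find_grouping_artifacts(fragment)
    reattachments: list[tuple[TermId, TermId]] = []
    notes: list[str] = []
    g = fragment.isa_graph()
    for cand in candidates:
        reattachments.extend(find_reattachment_candidates(fragment, cand.term))
        cand_fc = fragment.functions[cand.term]
        for desc in sorted(nx.ancestors(g, cand.term)):  # down-set under child→parent
            fc = fragment.functions[desc]
            if (
                fc.ga is not None
                and fc.ga.mode is not None
                and cand_fc.ga is not None
                and cand_fc.ga.mode is None
            ):
                notes.append(
                    f"{desc} sits under grouping candidate {cand.term} but adds or "
                    "specializes a mode; whether it is a pure member may be questioned"
                )
    no_process, unannotated = find_missing_goal_achievements(fragment)
    return RefactorReport(
        grouping_candidates=candidates,
        reattachments=sorted(set(reattachments)),
        missing_ga=(no_process, unannotated),
        notes=notes,
    )


def _facets_str(facets: frozenset[Facet]) -> str:
    return ",".join(sorted(f.value for f in facets))


def report_to_tsv(report: RefactorReport) -> str:
    """Flat TSV: one row per finding (columns: kind, term, parents, child, facets, proposal, reason)."""
    rows = [["kind", "term", "parents", "child", "facets", "proposal", "reason"]]
    for cand in report.grouping_candidates:
        for child, facets in cand.evidence:
            rows.append(
                [
                    "grouping-artifact",
                    str(cand.term),
                    ",".join(cand.parents),
                    str(child),
                    _facets_str(facets),
                    f"drop {cand.term}",
                    "children differ only in their operands",
                ]
            )
    for fn, group in report.reattachments:
        rows.append(
            [
                "reattachment",
                str(group),
                "",
                str(fn),
                "",
                f"add {fn} is_a {group}",
                "structurally subsumed but not declared",
            ]
        )
    no_process, unannotated = report.missing_ga
    for fn in no_process:
        rows.append(
            ["missing-process", str(fn), "", "", "", "", "goal achievement names no process"]
        )
    for fn in unannotated:
        rows.append(["unannotated", str(fn), "", "", "", "", "no goal achievement"])
    for note in report.notes:
        rows.append(["note", "", "", "", "", "", note])
    return "\n".join("\t".join(r) for r in rows) + "\n"


def report_to_json(report: RefactorReport) -> str:
    no_process, unannotated = report.missing_ga
    doc = {
        "grouping_candidates": [
            {
                "term": str(c.term),
                "parents": [str(p) for p in c.parents],
                "evidence": [
                    {"child": str(ch), "facets": sorted(f.value for f in fs)}
                    for ch, fs in c.evidence
                ],
            }
            for c in report.grouping_candidates
        ],
        "reattachments": [
            {"proposal": f"add {fn} is_a {group}", "child": str(fn), "term": str(group)}
            for fn, group in report.reattachments
        ],
        "missing_ga": {
            "no_process": [str(x) for x in no_process],
            "unannotated": [str(x) for x in unannotated],
        },
        "notes": list(report.notes),
    }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"
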
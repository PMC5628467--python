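"""Structural (intensional) subsumption over FueL concept structure.

Rather than comparing instance sets, subsumption here is decided by comparing
the *structure* of two concepts: a function subsumes another iff its goal
achievement does, and a goal achievement subsumes another iff the input and
output situations subsume slot-wise, the operand constraint is at least as
general, and the mode constraint is at least as general. An absent operand or
mode on the general side acts as the universal (unconstrained) restriction; an
absent one on the specific side, facing a present one on the general side,
breaks subsumption (the specific would be *less* constrained).

Doers are deliberately outside the subsumption criterion: they describe who
acts, typically alongside a mode, and ground no specialization pattern. They
are still reported informationally by :func:`audit_links`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .model import (
    FunctionConcept,
    GoalAchievement,
    Mode,
    OntologyFragment,
    ParticipantCategory,
    Situation,
    SubsumptionLink,
    TermId,
)

__all__ = [
    "UnresolvedTermError",
    "UnannotatedError",
    "category_subsumes",
    "situation_subsumes",
    "mode_specializes",
    "ga_subsumes",
    "function_subsumes",
    "LinkAudit",
    "audit_links",
]


class UnresolvedTermError(KeyError):
    """A term id does not resolve in the taxonomy it was looked up in."""


class UnannotatedError(ValueError):
    """A structural comparison was requested on a function without FueL structure."""


def category_subsumes(
    ancestor: TermId,
    descendant: TermId,
    taxonomy: Mapping[TermId, ParticipantCategory],
) -> bool:
    """Reflexive-transitive reachability in the participant taxonomy.

    True iff ``ancestor`` is reachable from ``descendant`` along zero or more
    parent edges (so every category subsumes itself).
    """
    for t in (ancestor, descendant):
        if t not in taxonomy:
            raise UnresolvedTermError(f"participant category not in taxonomy: {t}")
    if ancestor == descendant:
        return True
    seen: set[TermId] = set()
    stack = [descendant]
    while stack:
        cur = stack.pop()
        if cur in seen:
            continue
        seen.add(cur)
        for p in taxonomy[cur].parents:
            if p == ancestor:
                return True
            if p in taxonomy:
                stack.append(p)
    return False


def situation_subsumes(
    general: Situation,
    specific: Situation,
    taxonomy: Mapping[TermId, ParticipantCategory],
) -> bool:
    """Slot-wise structural subsumption between template-identical situations.

    Situations over different templates are incomparable (False); identical
    templates compare binding-by-binding through :func:`category_subsumes`.
    Bindings to ids outside the taxonomy (raw cross-ontology ids) subsume only
    themselves.
    """
    if general.normalized_template != specific.normalized_template:
        return False
    gb, sb = general.binding_map(), specific.binding_map()
    if set(gb) != set(sb):
        return False
    for slot, gcat in gb.items():
        scat = sb[slot]
        if gcat == scat:
            continue
        if gcat not in taxonomy or scat not in taxonomy:
            return False
        if not category_subsumes(gcat, scat, taxonomy):
            return False
    return True


def mode_specializes(
    child_mode: TermId,
    parent_mode: TermId,
    mode_taxonomy: Mapping[TermId, Mode],
) -> bool:
    """Reflexive-transitive closure of the mode ``specializes`` relation."""
    for t in (child_mode, parent_mode):
        if t not in mode_taxonomy:
            raise UnresolvedTermError(f"mode not in taxonomy: {t}")
    cur: Optional[TermId] = child_mode
    seen: set[TermId] = set()
    while cur is not None and cur not in seen:
        if cur == parent_mode:
            return True
        seen.add(cur)
        mode = mode_taxonomy.get(cur)
        cur = mode.specializes if mode is not None else None
    return False


def ga_subsumes(
    general: GoalAchievement,
    specific: GoalAchievement,
    participant_taxonomy: Mapping[TermId, ParticipantCategory],
    mode_taxonomy: Mapping[TermId, Mode],
) -> bool:
    """Structural subsumption between goal achievements.

    All four conditions must hold: (i) the general input situation subsumes
    the specific one; (ii) likewise for outputs; (iii) the general operand is
    absent, or both operands are present and the general one subsumes the
    specific one; (iv) the general mode is absent, or both modes are present
    and the specific mode specializes the general one.
    """
    if not situation_subsumes(general.input, specific.input, participant_taxonomy):
        return False
    if not situation_subsumes(general.output, specific.output, participant_taxonomy):
        return False
    if general.operand is not None:
        if specific.operand is None:
            return False
        if general.operand != specific.operand:
            if (
                general.operand not in participant_taxonomy
                or specific.operand not in participant_taxonomy
            ):
                return False
            if not category_subsumes(general.operand, specific.operand, participant_taxonomy):
                return False
    if general.mode is not None:
        if specific.mode is None:
            return False
        if not mode_specializes(specific.mode, general.mode, mode_taxonomy):
            return False
    return True


def function_subsumes(
    general: FunctionConcept,
    specific: FunctionConcept,
    participant_taxonomy: Mapping[TermId, ParticipantCategory],
    mode_taxonomy: Mapping[TermId, Mode],
) -> bool:
    """A function subsumes another iff its goal achievement subsumes the other's."""
    if general.ga is None or specific.ga is None:
        missing = general.id if general.ga is None else specific.id
        raise UnannotatedError(f"function {missing} carries no goal achievement")
    return ga_subsumes(general.ga, specific.ga, participant_taxonomy, mode_taxonomy)


@dataclass(frozen=True)
class LinkAudit:
    """Structural support status of one declared is_a link.

    ``supported`` is None ("unknown") when either endpoint is unannotated.
    ``doer_note`` informationally flags doer combinations the subsumption
    criterion ignores (specific lacking a doer the general declares).
    """

    link: SubsumptionLink
    supported: Optional[bool]
    doer_note: Optional[str] = None


def audit_links(fragment: OntologyFragment) -> list[LinkAudit]:
    """Report, per declared link, whether the hierarchy is structurally supported.

    Sorted by (child, parent). Links with an unannotated endpoint are reported
    with ``supported=None`` rather than being judged.
    """
    out: list[LinkAudit] = []
    for link in fragment.sorted_links():
        child = fragment.functions[link.child]
        parent = fragment.functions[link.parent]
        if child.ga is None or parent.ga is None:
            out.append(LinkAudit(link, None))
            continue
        ok = function_subsumes(
            parent, child, fragment.participant_taxonomy, fragment.mode_taxonomy
        )
        note = None
        if parent.ga.doer is not None and child.ga.doer is None:
            note = f"parent {link.parent} declares doer {parent.ga.doer}; child has none"
        out.append(LinkAudit(link, ok, note))
    return out
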
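"""Classification of declared is_a links into subsumption-pattern facets.

Three patterns recur behind the flat is_a relation of the Molecular Function
Ontology, and each gets a stereotype facet on the link:

* ``operand-spec`` — the child's operand is *strictly* below the parent's in
  the participant taxonomy (cation under ion), or the parent is operand-free
  while the child names one;
* ``mode-added`` — the child declares a mode of realization where the parent
  declares none;
* ``mode-spec`` — both declare modes and the child's strictly specializes the
  parent's.

Facets require proper specialization; a link whose two goal achievements are
structurally equal is ``plain``. A link whose declared direction is not backed
by structural subsumption at all is ``unsupported``. The experimental
``output-spec`` facet (specialization purely through a narrower output
situation, as in activator/inhibitor families) is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .model import Facet, FunctionConcept, OntologyFragment, TermId
from .subsumption import (
    UnannotatedError,
    category_subsumes,
    function_subsumes,
    mode_specializes,
    situation_subsumes,
)

__all__ = ["ClassifyOptions", "ClassificationResult", "classify_link", "classify_fragment"]


@dataclass(frozen=True)
class ClassifyOptions:
    enable_output_spec: bool = False


@dataclass(frozen=True)
class ClassificationResult:
    fragment: OntologyFragment
    warnings: tuple[str, ...] = ()


def classify_link(
    child: FunctionConcept,
    parent: FunctionConcept,
    participant_taxonomy,
    mode_taxonomy,
    options: ClassifyOptions = ClassifyOptions(),
) -> frozenset[Facet]:
    """Facet set for one declared child is_a parent link.

    Both functions must carry goal achievements; the declared direction is
    first checked against structural subsumption (parent subsumes child) and
    yields the singleton ``{unsupported}`` when it fails.
    """
    if child.ga is None or parent.ga is None:
        missing = child.id if child.ga is None else parent.id
        raise UnannotatedError(f"function {missing} carries no goal achievement")
    if not function_subsumes(parent, child, participant_taxonomy, mode_taxonomy):
        return frozenset({Facet.UNSUPPORTED})

    cga, pga = child.ga, parent.ga
    facets: set[Facet] = set()

    # operand specialization (parent-absent/child-present folds in here)
    if cga.operand is not None:
        if pga.operand is None:
            facets.add(Facet.OPERAND_SPEC)
        elif cga.operand != pga.operand and category_subsumes(
            pga.operand, cga.operand, participant_taxonomy
        ):
            facets.add(Facet.OPERAND_SPEC)

    # mode addition / specialization (mutually exclusive by construction)
    if cga.mode is not None:
        if pga.mode is None:
            facets.add(Facet.MODE_ADDED)
        elif cga.mode != pga.mode and mode_specializes(cga.mode, pga.mode, mode_taxonomy):
            facets.add(Facet.MODE_SPEC)

    if options.enable_output_spec and not facets:
        strictly_narrower_output = (
            cga.output != pga.output
            and situation_subsumes(pga.output, cga.output, participant_taxonomy)
            and not situation_subsumes(cga.output, pga.output, participant_taxonomy)
        )
        if strictly_narrower_output:
            facets.add(Facet.OUTPUT_SPEC)

    if not facets:
        facets.add(Facet.PLAIN)
    return frozenset(facets)


def classify_fragment(
    fragment: OntologyFragment, options: ClassifyOptions = ClassifyOptions()
) -> ClassificationResult:
    """Classify every link of the fragment; the input is not mutated.

    Links with an unannotated endpoint keep an empty facet set and produce a
    warning each instead of being judged unsupported.
    """
    new_links = []
    warnings: list[str] = []
    for link in fragment.sorted_links():
        child = fragment.functions[link.child]
        parent = fragment.functions[link.parent]
        if child.ga is None or parent.ga is None:
            missing = sorted(f.id for f in (child, parent) if f.ga is None)
            warnings.append(
                f"link {link.child} is_a {link.parent} left unclassified: "
                f"no goal achievement on {', '.join(missing)}"
            )
            new_links.append(link.with_facets(()))
            continue
        facets = classify_link(
            child, parent, fragment.participant_taxonomy, fragment.mode_taxonomy, options
        )
        new_links.append(link.with_facets(facets))
    out = fragment.copy()
    out.links = new_links
    return ClassificationResult(out, tuple(warnings))
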
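"""Refactoring analysis: grouping artifacts, drop-and-rewire, reattachment, profiling."""

import json

import networkx as nx
import pytest

from fuelkit.fixtures import (
    electron_carrier_fragment,
    fig3_fragment,
    generate_random,
)
from fuelkit.model import Facet, TermId
from fuelkit.patterns import classify_fragment
from fuelkit.refactor import (
    NotClassifiedError,
    apply_drop,
    build_report,
    find_grouping_artifacts,
    find_missing_goal_achievements,
    find_reattachment_candidates,
    profile_term,
    report_to_json,
    report_to_tsv,
)
from fuelkit.subsumption import UnannotatedError, function_subsumes

from conftest import reachability


def brute_grouping_candidates(frag):
    """Direct evaluation of the three grouping-artifact conditions."""
    out = []
    for term in sorted(frag.functions):
        child_links = frag.child_links_of(term)
        if len(child_links) < 2:
            continue
        if not all(l.facets and l.facets <= {Facet.OPERAND_SPEC} for l in child_links):
            continue
        ok_parents = []
        for plink in frag.sorted_links():
            if plink.child != term:
                continue
            if not (plink.facets and plink.facets <= {Facet.OPERAND_SPEC, Facet.PLAIN}):
                continue
            parent = frag.functions[plink.parent]
            if parent.ga is None:
                continue
            if all(
                frag.functions[cl.child].ga is not None
                and function_subsumes(
                    parent,
                    frag.functions[cl.child],
                    frag.participant_taxonomy,
                    frag.mode_taxonomy,
                )
                for cl in child_links
            ):
                ok_parents.append(plink.parent)
        if ok_parents:
            out.append(term)
    return out


class TestGroupingArtifacts:
    def test_fig5_candidate_is_the_grouping_term(self, fig5_classified):
        cands = find_grouping_artifacts(fig5_classified)
        assert [c.term for c in cands] == ["GO:0022891"]
        (cand,) = cands
        assert cand.parents == ("GO:0022857",)
        assert {str(c) for c, _ in cand.evidence} == {"GO:0015075", "GO:0015144"}

    def test_two_term_fragment_has_none(self):
        frag = classify_fragment(fig3_fragment()).fragment
        assert find_grouping_artifacts(frag) == []

    def test_unclassified_fragment_rejected(self, fig5):
        with pytest.raises(NotClassifiedError):
            find_grouping_artifacts(fig5)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_on_random_fragments(self, seed):
        frag = classify_fragment(generate_random(seed, 14).fragment).fragment
        got = [c.term for c in find_grouping_artifacts(frag)]
        assert got == brute_grouping_candidates(frag)


class TestApplyDrop:
    def test_fig5_drop_reproduces_rewiring(self, fig5_classified):
        new, log = apply_drop(fig5_classified, TermId("GO:0022891"))
        assert TermId("GO:0022891") not in new.functions
        added = {(str(l.child), str(l.parent)): {f.value for f in l.facets} for l in log.added_links}
        assert added == {
            ("GO:0015075", "GO:0022857"): {"operand-spec"},
            ("GO:0015144", "GO:0022857"): {"operand-spec"},
        }
        removed = {(str(l.child), str(l.parent)) for l in log.removed_links}
        assert removed == {
            ("GO:0022891", "GO:0022857"),
            ("GO:0015075", "GO:0022891"),
            ("GO:0015144", "GO:0022891"),
        }

    def test_closure_preserved_on_fixture(self, fig5_classified):
        before = reachability(fig5_classified)
        new, _ = apply_drop(fig5_classified, TermId("GO:0022891"))
        after = reachability(new)
        dropped = {TermId("GO:0022891")}
        for term, anc in after.items():
            assert anc == before[term] - dropped

    def test_drop_leaf_removes_only_its_links(self, fig5_classified):
        new, log = apply_drop(fig5_classified, TermId("GO:0005402"))
        assert log.added_links == ()
        assert len(new.links) == len(fig5_classified.links) - 2

    def test_drop_root_rejected(self, fig5_classified):
        with pytest.raises(ValueError, match="root"):
            apply_drop(fig5_classified, TermId("GO:0022857"))

    def test_no_redundant_links_added(self, fig5_classified):
        """Rewiring keeps a transitively reduced link set reduced."""
        new, _ = apply_drop(fig5_classified, TermId("GO:0022891"))
        g = new.isa_graph()
        for link in new.links:
            g.remove_edge(link.child, link.parent)
            assert not nx.has_path(g, link.child, link.parent)
            g.add_edge(link.child, link.parent)

    @pytest.mark.parametrize("seed", range(30))
    def test_closure_restriction_on_random_fragments(self, seed):
        import random

        frag = classify_fragment(generate_random(seed, 12).fragment).fragment
        rng = random.Random(seed)
        droppable = [t for t in sorted(frag.functions) if frag.parents_of(t)]
        if not droppable:
            return
        term = rng.choice(droppable)
        before = reachability(frag)
        new, _ = apply_drop(frag, term)
        after = reachability(new)
        for t, anc in after.items():
            assert anc == before[t] - {term}

    def test_dropped_term_not_recreated_as_candidate(self, fig5_classified):
        new, _ = apply_drop(fig5_classified, TermId("GO:0022891"))
        cands = {c.term for c in find_grouping_artifacts(new)}
        assert TermId("GO:0022891") not in cands
        former_children = {TermId("GO:0015075"), TermId("GO:0015144")}
        assert not (cands & former_children)


class TestReattachment:
    def test_fig5_proposals_include_vitamin_and_drug_transporters(self, fig5_classified):
        props = find_reattachment_candidates(fig5_classified, TermId("GO:0022891"))
        proposed = {str(f) for f, _ in props}
        assert {"GO:0090482", "GO:0015238"} <= proposed
        # already-declared descendants and ancestors never proposed
        assert "GO:0015075" not in proposed
        assert "GO:0022857" not in proposed

    def test_universal_group_with_everything_below_proposes_nothing(self):
        frag = classify_fragment(fig3_fragment()).fragment
        assert find_reattachment_candidates(frag, TermId("GO:0015075")) == []

    def test_unannotated_group_rejected(self, fig3):
        from dataclasses import replace

        ion = fig3.functions[TermId("GO:0015075")]
        fig3.functions[ion.id] = replace(ion, ga=None)
        with pytest.raises(UnannotatedError):
            find_reattachment_candidates(fig3, ion.id)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_scan(self, seed):
        frag = classify_fragment(generate_random(seed, 12).fragment).fragment
        g = frag.isa_graph()
        group = sorted(frag.functions)[0]  # the generator root is always annotated
        got = find_reattachment_candidates(frag, group)
        expected = []
        for fid in sorted(frag.functions):
            if fid == group or fid in nx.descendants(g, group):
                continue
            if nx.has_path(g, fid, group):
                continue
            if function_subsumes(
                frag.functions[group],
                frag.functions[fid],
                frag.participant_taxonomy,
                frag.mode_taxonomy,
            ):
                expected.append((fid, group))
        assert got == expected


class TestMissingGoalAchievements:
    def test_function_with_process_not_listed(self, fig1):
        no_process, unannotated = find_missing_goal_achievements(fig1)
        assert TermId("GO:0015144") not in no_process
        assert unannotated == []

    def test_function_without_process_listed(self, fig3):
        no_process, unannotated = find_missing_goal_achievements(fig3)
        assert no_process == ["GO:0008324", "GO:0015075"]
        assert unannotated == []

    def test_empty_fragment_both_lists_empty(self):
        from fuelkit.model import OntologyFragment

        assert find_missing_goal_achievements(OntologyFragment()) == ([], [])


class TestProfileTerm:
    def test_receptor_activity_operand_dominant(self, receptor_classified):
        profile = profile_term(receptor_classified, TermId("GO:0004872"))
        assert profile.style == "operand-dominant"
        assert profile.counts["operand-spec"] == 7
        assert profile.n_links == 7

    def test_electron_carrier_mode_dominant(self):
        frag = classify_fragment(electron_carrier_fragment()).fragment
        profile = profile_term(frag, TermId("GO:0009055"))
        assert profile.style == "mode-dominant"
        assert profile.counts["mode-added"] == 2

    def test_childless_term_undetermined(self, receptor_classified):
        profile = profile_term(receptor_classified, TermId("GO:0005055"))
        assert profile.style == "undetermined"
        assert profile.n_links == 0

    def test_counts_equal_planted_tallies_on_star_graph(self):
        pf = generate_random(3, 8, taxonomy_depth=4)
        frag = classify_fragment(pf.fragment).fragment
        root = TermId("FX:f0000")
        profile = profile_term(frag, root)
        planted_counts = {}
        for (child, parent), facets in pf.planted.items():
            if parent != root:
                continue
            for f in facets:
                planted_counts[f.value] = planted_counts.get(f.value, 0) + 1
        assert {k: v for k, v in profile.counts.items() if v} == planted_counts


class TestReportSerialization:
    def test_tsv_and_json_round_out_the_findings(self, fig5_classified):
        report = build_report(fig5_classified)
        tsv = report_to_tsv(report)
        assert tsv.splitlines()[0] == "kind\tterm\tparents\tchild\tfacets\tproposal\treason"
        assert "grouping-artifact\tGO:0022891" in tsv
        doc = json.loads(report_to_json(report))
        assert [c["term"] for c in doc["grouping_candidates"]] == ["GO:0022891"]
        proposals = {r["child"] for r in doc["reattachments"]}
        assert {"GO:0090482", "GO:0015238"} <= proposals

    def test_questionable_member_noted(self, fig5_classified):
        report = build_report(fig5_classified)
        assert any("GO:0005402" in note for note in report.notes)

    def test_report_stable_under_link_reordering(self, fig5):
        a = build_report(classify_fragment(fig5).fragment)
        shuffled = fig5.copy()
        shuffled.links = list(reversed(shuffled.links))
        b = build_report(classify_fragment(shuffled).fragment)
        assert report_to_json(a) == report_to_json(b)
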
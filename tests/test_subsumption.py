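"""Structural subsumption semantics, checked against brute-force oracles."""

import random
from dataclasses import replace

import pytest

from fuelkit.fixtures import fig3_fragment, fig5_fragment, generate_random
from fuelkit.model import Mode, ParticipantCategory, Situation, TermId
from fuelkit.subsumption import (
    UnannotatedError,
    UnresolvedTermError,
    audit_links,
    category_subsumes,
    function_subsumes,
    ga_subsumes,
    mode_specializes,
    situation_subsumes,
)


def brute_reachable(start, goal, parents_of):
    """Exhaustive path enumeration: is goal reachable via parent edges?"""
    if start == goal:
        return True
    paths = [[start]]
    while paths:
        path = paths.pop()
        for p in parents_of(path[-1]):
            if p == goal:
                return True
            if p not in path:
                paths.append(path + [p])
    return False


def random_participant_dag(rng, n):
    """Random DAG taxonomy: each node picks parents among earlier nodes."""
    cats = {}
    ids = [TermId(f"FX:n{i}") for i in range(n)]
    for i, tid in enumerate(ids):
        k = rng.randint(0, min(2, i))
        parents = frozenset(rng.sample(ids[:i], k)) if k else frozenset()
        cats[tid] = ParticipantCategory(tid, f"n{i}", parents)
    return cats


class TestCategorySubsumes:
    def test_ion_subsumes_cation(self, fig3):
        taxo = fig3.participant_taxonomy
        assert category_subsumes(TermId("FX:ion"), TermId("FX:cation"), taxo)
        assert not category_subsumes(TermId("FX:cation"), TermId("FX:ion"), taxo)

    def test_reflexive(self, fig3):
        taxo = fig3.participant_taxonomy
        for tid in taxo:
            assert category_subsumes(tid, tid, taxo)

    def test_unresolved_id_raises(self, fig3):
        with pytest.raises(UnresolvedTermError):
            category_subsumes(TermId("FX:ghost"), TermId("FX:ion"), fig3.participant_taxonomy)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_path_enumeration_on_random_dags(self, seed):
        rng = random.Random(seed)
        taxo = random_participant_dag(rng, 12)
        ids = sorted(taxo)
        for anc in ids:
            for desc in ids:
                expected = brute_reachable(desc, anc, lambda t: taxo[t].parents)
                assert category_subsumes(anc, desc, taxo) == expected


class TestSituationSubsumes:
    TAXO = {
        TermId("FX:ion"): ParticipantCategory(TermId("FX:ion"), "ion"),
        TermId("FX:cation"): ParticipantCategory(
            TermId("FX:cation"), "cation", frozenset({TermId("FX:ion")})
        ),
    }

    def test_binding_refinement_subsumes(self):
        t = "{operand} is on one side of the membrane"
        gen = Situation.make(t, operand=TermId("FX:ion"))
        spec = Situation.make(t, operand=TermId("FX:cation"))
        assert situation_subsumes(gen, spec, self.TAXO)
        assert not situation_subsumes(spec, gen, self.TAXO)

    def test_identical_situations_subsume(self):
        s = Situation.make("{operand} here", operand=TermId("FX:ion"))
        assert situation_subsumes(s, s, self.TAXO)

    def test_different_templates_incomparable(self):
        a = Situation.make("{operand} here", operand=TermId("FX:ion"))
        b = Situation.make("{operand} there", operand=TermId("FX:ion"))
        assert not situation_subsumes(a, b, self.TAXO)

    def test_whitespace_differences_ignored(self):
        a = Situation.make("{operand}   here", operand=TermId("FX:ion"))
        b = Situation.make("{operand} here", operand=TermId("FX:cation"))
        assert situation_subsumes(a, b, self.TAXO)


class TestModeSpecializes:
    def test_fig5_mode_chain(self, fig5):
        taxo = fig5.mode_taxonomy
        assert mode_specializes(
            TermId("FX:secondary-active-transport-mode"),
            TermId("FX:active-transport-mode"),
            taxo,
        )
        assert mode_specializes(
            TermId("FX:symport-mode"), TermId("FX:active-transport-mode"), taxo
        )
        assert not mode_specializes(
            TermId("FX:active-transport-mode"),
            TermId("FX:symport-mode"),
            taxo,
        )

    def test_reflexive(self, fig5):
        for m in fig5.mode_taxonomy:
            assert mode_specializes(m, m, fig5.mode_taxonomy)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_path_enumeration_on_random_trees(self, seed):
        rng = random.Random(seed)
        ids = [TermId(f"FX:m{i}") for i in range(10)]
        taxo = {}
        for i, tid in enumerate(ids):
            parent = rng.choice(ids[:i]) if i else None
            taxo[tid] = Mode(tid, f"m{i}", specializes=parent)
        parents_of = lambda t: [taxo[t].specializes] if taxo[t].specializes else []
        for a in ids:
            for b in ids:
                assert mode_specializes(a, b, taxo) == brute_reachable(a, b, parents_of)


class TestGaAndFunctionSubsumes:
    def test_modeless_general_subsumes_moded_specific(self, fig4):
        parent = fig4.functions[TermId("GO:0022857")]
        child = fig4.functions[TermId("GO:0022804")]
        assert function_subsumes(parent, child, fig4.participant_taxonomy, fig4.mode_taxonomy)
        # reversed: general has a mode the specific lacks
        assert not function_subsumes(
            child, parent, fig4.participant_taxonomy, fig4.mode_taxonomy
        )

    def test_reflexive_on_every_annotated_function(self, fig5):
        for fc in fig5.functions.values():
            assert function_subsumes(
                fc, fc, fig5.participant_taxonomy, fig5.mode_taxonomy
            )

    def test_fig3_direction(self, fig3):
        ion = fig3.functions[TermId("GO:0015075")]
        cation = fig3.functions[TermId("GO:0008324")]
        assert function_subsumes(ion, cation, fig3.participant_taxonomy, fig3.mode_taxonomy)
        assert not function_subsumes(
            cation, ion, fig3.participant_taxonomy, fig3.mode_taxonomy
        )

    def test_general_operand_present_specific_absent_fails(self, fig3):
        ion = fig3.functions[TermId("GO:0015075")]
        stripped = replace(
            ion,
            ga=replace(
                ion.ga,
                operand=None,
                input=Situation("the operand is on one side of the membrane"),
                output=Situation("the operand is on the other side of the membrane"),
            ),
        )
        assert not ga_subsumes(
            ion.ga, stripped.ga, fig3.participant_taxonomy, fig3.mode_taxonomy
        )

    def test_unannotated_raises(self, fig3):
        ion = fig3.functions[TermId("GO:0015075")]
        bare = replace(ion, ga=None)
        with pytest.raises(UnannotatedError):
            function_subsumes(ion, bare, fig3.participant_taxonomy, fig3.mode_taxonomy)

    def test_mode_removal_monotone(self):
        """Dropping the general side's mode never turns subsumption false."""
        for seed in range(20):
            pf = generate_random(seed, 10)
            frag = pf.fragment
            fns = sorted(frag.functions)
            for a in fns:
                for b in fns:
                    ga, gb = frag.functions[a].ga, frag.functions[b].ga
                    if ga_subsumes(
                        ga, gb, frag.participant_taxonomy, frag.mode_taxonomy
                    ):
                        assert ga_subsumes(
                            replace(ga, mode=None),
                            gb,
                            frag.participant_taxonomy,
                            frag.mode_taxonomy,
                        )

    @pytest.mark.parametrize("seed", range(10))
    def test_declared_ancestry_implies_subsumption_on_planted(self, seed):
        """Generator edits only ever specialize, so is_a reachability must imply subsumption."""
        import networkx as nx

        pf = generate_random(seed, 20)
        frag = pf.fragment
        g = frag.isa_graph()
        for desc in frag.functions:
            for anc in nx.descendants(g, desc):
                assert function_subsumes(
                    frag.functions[anc],
                    frag.functions[desc],
                    frag.participant_taxonomy,
                    frag.mode_taxonomy,
                )

    @pytest.mark.parametrize("seed", range(5))
    def test_transitive_on_random_fragments(self, seed):
        pf = generate_random(seed, 12)
        frag = pf.fragment
        fns = sorted(frag.functions)
        sub = {
            (a, b): function_subsumes(
                frag.functions[a],
                frag.functions[b],
                frag.participant_taxonomy,
                frag.mode_taxonomy,
            )
            for a in fns
            for b in fns
        }
        for a in fns:
            for b in fns:
                for c in fns:
                    if sub[(a, b)] and sub[(b, c)]:
                        assert sub[(a, c)]


class TestAuditLinks:
    def test_all_fixture_links_supported(self, any_fixture):
        audits = audit_links(any_fixture)
        assert all(a.supported is not False for a in audits)
        annotated = [a for a in audits if a.supported is not None]
        assert all(a.supported for a in annotated)

    def test_unannotated_endpoint_reported_unknown(self, fig3):
        ion = fig3.functions[TermId("GO:0015075")]
        fig3.functions[ion.id] = replace(ion, ga=None)
        (audit,) = audit_links(fig3)
        assert audit.supported is None

    def test_operand_outside_parent_operand_unsupported(self, fig3):
        cation = fig3.functions[TermId("GO:0008324")]
        ion = fig3.functions[TermId("GO:0015075")]
        # reverse the declared direction: ion is_a cation is structurally wrong
        fig3.links = [type(fig3.links[0])(ion.id, cation.id)]
        (audit,) = audit_links(fig3)
        assert audit.supported is False

    def test_sorted_by_child_parent(self, fig5):
        audits = audit_links(fig5)
        keys = [(a.link.child, a.link.parent) for a in audits]
        assert keys == sorted(keys)
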
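"""Orthologous-insertion testing, event clustering and tree dating."""

import pytest

from helpers import mutate_frac, rand_nt, random_ultrametric_newick
from hervtrace.discovery import ErvElement, GenomicInterval
from hervtrace.transmission import (FlankedElement, OrthologPair,
                                    TransmissionEvent, build_event_graph,
                                    map_event_to_tree, ortholog_pair_test,
                                    screen_ortholog_pairs, summarize_events)
from hervtrace.trees import SpeciesTreeError, TimedSpeciesTree


def make_flanked(element_seq, up, down, species, eid="e", cls="HERVHF"):
    element = ErvElement(
        element_id=f"{species}_{eid}", species=species,
        interval=GenomicInterval("c", 10, 10 + len(element_seq), "+"),
        ltrs=None, genes=[], classification=cls, is_full_length=True)
    return FlankedElement(element=element, element_seq=element_seq,
                          upstream_flank=up, downstream_flank=down)


class TestOrthologPairTest:
    def test_exact_copy_in_another_species_is_accepted(self, rng):
        el, up, down = rand_nt(rng, 3000), rand_nt(rng, 2000), rand_nt(rng, 2000)
        a = make_flanked(el, up, down, "Homo_sapiens")
        b = make_flanked(el, up, down, "Pan_troglodytes")
        pair = ortholog_pair_test(a, b)
        assert pair.condition_flags == (True, True, True)
        assert pair.accepted

    def test_unrelated_flanks_fail_conditions_two_and_three(self, rng):
        el = rand_nt(rng, 3000)
        a = make_flanked(el, rand_nt(rng, 2000), rand_nt(rng, 2000),
                         "Homo_sapiens")
        b = make_flanked(el, rand_nt(rng, 2000), rand_nt(rng, 2000),
                         "Pan_troglodytes")
        pair = ortholog_pair_test(a, b)
        assert pair.condition_flags == (True, False, False)
        assert not pair.accepted

    def test_moderate_divergence_accepted_deep_divergence_rejected(self, rng):
        el, up, down = rand_nt(rng, 3000), rand_nt(rng, 2000), rand_nt(rng, 2000)
        a = make_flanked(el, up, down, "Homo_sapiens")
        near = make_flanked(mutate_frac(el, 0.06, rng),
                            mutate_frac(up, 0.04, rng),
                            mutate_frac(down, 0.04, rng), "Pan_troglodytes")
        assert ortholog_pair_test(a, near).accepted
        far = make_flanked(mutate_frac(el, 0.06, rng),
                           mutate_frac(up, 0.12, rng),
                           mutate_frac(down, 0.12, rng), "Pan_troglodytes")
        pair = ortholog_pair_test(a, far)
        assert not pair.condition_flags[1]
        assert not pair.accepted

    def test_result_is_symmetric(self, rng):
        for frac in (0.02, 0.08, 0.12):
            el, up, down = (rand_nt(rng, 2500), rand_nt(rng, 2000),
                            rand_nt(rng, 2000))
            a = make_flanked(el, up, down, "Homo_sapiens")
            b = make_flanked(mutate_frac(el, frac, rng),
                             mutate_frac(up, frac, rng),
                             mutate_frac(down, frac, rng), "Pan_troglodytes")
            ab = ortholog_pair_test(a, b)
            ba = ortholog_pair_test(b, a)
            assert ab.condition_flags == ba.condition_flags
            assert ab.accepted == ba.accepted

    def test_missing_flank_fails_condition_three_without_raising(self, rng):
        el, up, down = rand_nt(rng, 3000), rand_nt(rng, 2000), rand_nt(rng, 2000)
        a = make_flanked(el, up, down, "Homo_sapiens")
        b = make_flanked(el, "", down, "Pan_troglodytes")  # contig edge
        pair = ortholog_pair_test(a, b)
        assert not pair.condition_flags[2]

    def test_same_species_pair_rejected(self, rng):
        el = rand_nt(rng, 3000)
        a = make_flanked(el, rand_nt(rng, 2000), rand_nt(rng, 2000),
                         "Homo_sapiens", eid="e1")
        b = make_flanked(el, rand_nt(rng, 2000), rand_nt(rng, 2000),
                         "Homo_sapiens", eid="e2")
        with pytest.raises(ValueError, match="same-species"):
            ortholog_pair_test(a, b)


def accepted_pair(a, b, sa, sb):
    return OrthologPair(element_a=a, element_b=b, species_a=sa, species_b=sb,
                        condition_flags=(True, True, True))


class TestEventGraph:
    def test_transitive_pairs_form_one_event(self):
        pairs = [accepted_pair("A", "B", "s1", "s2"),
                 accepted_pair("B", "C", "s2", "s3")]
        events = build_event_graph(pairs, {"A": "HERVHF", "B": "HERVHF",
                                           "C": "HERVHF"})
        assert len(events) == 1
        assert set(events[0].members) == {"A", "B", "C"}
        assert events[0].species_set == frozenset({"s1", "s2", "s3"})

    def test_no_pairs_no_events(self):
        assert build_event_graph([]) == []

    def test_seventeen_species_component_is_one_event(self):
        species = [f"sp{i:02d}" for i in range(17)]
        pairs = [accepted_pair(f"E{i}", f"E{i + 1}", species[i], species[i + 1])
                 for i in range(16)]
        events = build_event_graph(pairs, {f"E{i}": "HERVHF"
                                           for i in range(17)})
        assert len(events) == 1
        assert len(events[0].species_set) == 17

    def test_rejected_pairs_are_ignored(self):
        pairs = [OrthologPair("A", "B", "s1", "s2", (True, False, True))]
        assert build_event_graph(pairs) == []


class TestTreeMapping:
    def test_homo_gorilla_event_dates_to_9_1(self):
        tree = TimedSpeciesTree.default_fixture()
        ev = TransmissionEvent("e", ("a", "b"),
                               ("Homo_sapiens", "Gorilla_gorilla_gorilla"),
                               frozenset({"Homo_sapiens",
                                          "Gorilla_gorilla_gorilla"}),
                               ("HERVHF", "HERVHF"))
        map_event_to_tree(ev, tree)
        assert ev.age_mya == pytest.approx(9.1)

    def test_root_spanning_set_dates_to_root(self):
        tree = TimedSpeciesTree.default_fixture()
        ev = TransmissionEvent("e", ("a", "b"),
                               ("Homo_sapiens", "Macaca_mulatta"),
                               frozenset({"Homo_sapiens", "Macaca_mulatta"}),
                               ("HERVK", "HERVK"))
        map_event_to_tree(ev, tree)
        assert ev.age_mya == pytest.approx(tree.root_age)

    def test_unknown_species_error_names_it(self):
        tree = TimedSpeciesTree.default_fixture()
        ev = TransmissionEvent("e", ("a", "b"), ("Homo_sapiens", "Mus_musculus"),
                               frozenset({"Homo_sapiens", "Mus_musculus"}),
                               ("HERVK", "HERVK"))
        with pytest.raises(SpeciesTreeError, match="Mus_musculus"):
            map_event_to_tree(ev, tree)

    def test_mrca_age_is_max_pairwise_divergence(self, rng):
        """On random ultrametric trees the MRCA age of any subset equals the
        deepest pairwise split in that subset (brute-force over pairs)."""
        for _ in range(5):
            tree = TimedSpeciesTree.from_newick(
                random_ultrametric_newick(rng, 8))
            leaves = tree.leaves
            for _ in range(6):
                subset = list(rng.choice(leaves, size=3, replace=False))
                _node, age = tree.mrca(subset)
                brute = max(tree.pairwise_divergence(a, b)
                            for i, a in enumerate(subset)
                            for b in subset[i + 1:])
                assert age == pytest.approx(brute)

    def test_adding_outside_species_never_decreases_age(self, rng):
        tree = TimedSpeciesTree.default_fixture()
        leaves = tree.leaves
        for _ in range(10):
            k = int(rng.integers(2, 5))
            subset = list(rng.choice(leaves, size=k, replace=False))
            _n, age = tree.mrca(subset)
            outside = [sp for sp in leaves if sp not in subset]
            if not outside:
                continue
            _n2, age2 = tree.mrca(subset + [outside[0]])
            assert age2 >= age


class TestSummaries:
    def _event(self, n, node, age):
        ev = TransmissionEvent(f"VT{n}", ("a", "b"),
                               ("Homo_sapiens", "Pan_troglodytes"),
                               frozenset({"Homo_sapiens", "Pan_troglodytes"}),
                               ("HERVHF", "HERVHF"))
        ev.mrca_node, ev.age_mya = node, age
        return ev

    def test_two_events_at_one_node_count_two(self):
        tree = TimedSpeciesTree.default_fixture()
        events = [self._event(1, "node0", 6.7), self._event(2, "node0", 6.7)]
        per_node, per_species = summarize_events(events, tree)
        assert int(per_node.set_index("node").loc["node0", "n_events"]) == 2
        assert per_species["n_elements"].sum() == 4

    def test_zero_events_keep_full_node_list(self):
        tree = TimedSpeciesTree.default_fixture()
        per_node, per_species = summarize_events([], tree)
        assert set(per_node["node"]) == {n for n, _ in tree.internal_nodes()}
        assert (per_node["n_events"] == 0).all()
        assert per_species.empty


class TestCohortRecovery:
    def test_planted_insertions_recovered_at_correct_nodes(self, small_cohort):
        """Every multi-species planted insertion becomes one event at its
        planting node; no single-species events appear."""
        cohort = small_cohort
        tree = cohort.config.resolve_tree()
        flanked = []
        for ins in cohort.truth.insertions:
            for sp, (contig, start, end) in sorted(ins.species_coords.items()):
                e = ErvElement(
                    element_id=cohort.truth.element_name(ins, sp), species=sp,
                    interval=GenomicInterval(contig, start, end, ins.strand),
                    ltrs=None, genes=[], classification=ins.classification,
                    is_full_length=True)
                flanked.append(
                    FlankedElement.from_element(e, cohort.genomes[sp]))
        pairs = screen_ortholog_pairs(flanked)
        events = build_event_graph(
            pairs, {fe.element_id: fe.element.classification
                    for fe in flanked})
        for ev in events:
            map_event_to_tree(ev, tree)
        multi = [t for t in cohort.truth.insertions
                 if len(t.species_coords) >= 2]
        assert len(events) == len(multi)
        by_species_set = {ev.species_set: ev for ev in events}
        for t in multi:
            ev = by_species_set[t.species_set]
            expected_node, _ = tree.mrca(t.species_coords)
            assert ev.mrca_node == expected_node
        assert all(len(ev.species_set) >= 2 for ev in events)

    def test_pan_loss_yields_homo_gorilla_event_at_9_1(self, small_cohort):
        """The insertion lost in Pan dates to the Homo/Gorilla split."""
        cohort = small_cohort
        lost = [t for t in cohort.truth.insertions if t.lost_in]
        assert lost and lost[0].species_set == frozenset(
            {"Homo_sapiens", "Gorilla_gorilla_gorilla"})
        tree = cohort.config.resolve_tree()
        _node, age = tree.mrca(lost[0].species_set)
        assert age == pytest.approx(9.1)
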
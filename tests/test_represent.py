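"""Greedy simplitigs, unitig compaction, and maximality checking."""

import pytest

from simplitig import (
    ExtensionPolicy,
    Representation,
    build_kmer_set,
    compute_simplitigs,
    compute_unitigs,
    encode_kmer,
    is_maximal,
    verify,
)

THREE_BRANCH = ["ACG", "CGA", "CGT"]  # ACG branches into CGA and CGT
THREE_CYCLE = ["ACG", "CGA", "GAC"]  # a 3-node cycle


def kset(kmers, model="uni"):
    k = len(kmers[0])
    return build_kmer_set(kmers, k, model)


class TestSimplitigs:
    def test_branching_example(self):
        rep = compute_simplitigs(kset(THREE_BRANCH))
        assert rep.sequences == ["ACGA", "CGT"]
        assert rep.ns == 2 and rep.cl == 7

    def test_single_chain(self):
        rep = compute_simplitigs(build_kmer_set(["ACGTT"], 3, "uni"))
        assert rep.sequences == ["ACGTT"]

    def test_cycle_covered_by_one_path(self):
        rep = compute_simplitigs(kset(THREE_CYCLE))
        assert rep.sequences == ["ACGAC"]
        assert rep.cl == len(kset(THREE_CYCLE)) + 2 * rep.ns  # CL = n + (k-1)NS

    def test_empty_set_yields_empty_representation(self):
        empty = build_kmer_set([], 3, "uni")
        assert compute_simplitigs(empty).sequences == []
        assert compute_unitigs(empty).sequences == []

    def test_bi_mode_collapses_strands(self):
        ks = build_kmer_set(["ACGT"], 3, "bi")
        rep = compute_simplitigs(ks)
        assert verify(rep, ks).passed
        assert rep.cl == 3  # one canonical 3-mer spelled once

    @pytest.mark.parametrize("order", ["unitig-starts", "sorted-code"])
    def test_deterministic_seed_orders(self, order):
        ks = build_kmer_set(["ACGTTGCAGGTAACGTAGCT"], 4, "bi")
        a = compute_simplitigs(ks, ExtensionPolicy(seed_order=order))
        b = compute_simplitigs(ks, ExtensionPolicy(seed_order=order))
        assert a.sequences == b.sequences

    def test_random_seed_order_reproducible_per_seed(self):
        ks = build_kmer_set(["ACGTTGCAGGTAACGTAGCT"], 4, "uni")
        pol = ExtensionPolicy(seed_order="random", seed=5)
        a = compute_simplitigs(ks, pol)
        b = compute_simplitigs(ks, pol)
        assert a.sequences == b.sequences
        assert verify(a, ks).passed

    def test_random_seed_order_requires_seed(self):
        with pytest.raises(ValueError):
            ExtensionPolicy(seed_order="random")

    def test_nucleotide_order_must_be_permutation(self):
        with pytest.raises(ValueError):
            ExtensionPolicy(nucleotide_order="AACG")


class TestUnitigs:
    def test_branching_node_prevents_compaction(self):
        rep = compute_unitigs(kset(THREE_BRANCH))
        assert sorted(rep.sequences) == ["ACG", "CGA", "CGT"]
        assert rep.ns == 3 and rep.cl == 9

    def test_chain_equals_simplitig(self):
        ks = build_kmer_set(["ACGTT"], 3, "uni")
        assert compute_unitigs(ks).sequences == ["ACGTT"]

    def test_isolated_cycle_broken_at_smallest_code(self):
        rep = compute_unitigs(kset(THREE_CYCLE))
        assert rep.sequences == ["ACGAC"]  # break point = min code node ACG

    def test_bi_unitigs_conserve_kmers(self):
        ks = build_kmer_set(["ACGTTGCAGGTAACGTAGCTTCCAG"], 5, "bi")
        rep = compute_unitigs(ks)
        assert verify(rep, ks).passed


class TestMaximality:
    def test_greedy_output_is_maximal(self):
        ks = kset(THREE_BRANCH)
        rep = compute_simplitigs(ks)
        assert is_maximal(rep, ks).is_maximal

    def test_mergeable_singletons_are_not_maximal(self):
        ks = kset(THREE_BRANCH)
        rep = Representation(
            kind="simplitigs", k=3, model="uni", sequences=["ACG", "CGA", "CGT"]
        )
        report = is_maximal(rep, ks)
        assert not report.is_maximal
        assert any("merges" in v for v in report.violations)

    def test_single_chain_is_maximal(self):
        ks = build_kmer_set(["ACGTT"], 3, "uni")
        rep = Representation(
            kind="simplitigs", k=3, model="uni", sequences=["ACGTT"]
        )
        assert is_maximal(rep, ks).is_maximal

    def test_rejects_non_conserving_representation(self):
        ks = kset(THREE_BRANCH)
        rep = Representation(
            kind="simplitigs", k=3, model="uni", sequences=["ACG"]
        )
        with pytest.raises(ValueError):
            is_maximal(rep, ks)

    def test_bi_merge_through_reverse_complement_detected(self):
        # CCA's successor TGG... in rc orientation: CAA -> AAC etc.
        ks = build_kmer_set(["AACCA"], 3, "bi")  # kmers AAC, ACC, CCA
        rep = Representation(
            kind="simplitigs", k=3, model="bi", sequences=["AACC", "TGG"]
        )  # TGG == rc(CCA) should merge onto AACC
        report = is_maximal(rep, ks)
        assert not report.is_maximal


class TestRandomSuiteProperties:
    def test_conservation_and_bounds(self, small_random_suite):
        from simplitig import stats_of

        for inst in small_random_suite:
            for rep in (inst.simplitigs, inst.unitigs):
                assert verify(rep, inst.kmer_set).passed
                st = stats_of(rep, inst.kmer_set)
                assert st.eq1_residual == 0
                assert st.ns_bounds_ok and st.cl_bounds_ok

    def test_unitig_refinement_in_uni_mode(self, small_random_suite):
        for inst in small_random_suite:
            if inst.kmer_set.model.value != "uni":
                continue
            k = inst.kmer_set.k
            assert inst.simplitigs.ns <= inst.unitigs.ns
            assert inst.simplitigs.cl <= inst.unitigs.cl
            position = {}
            for si, s in enumerate(inst.simplitigs.sequences):
                for j in range(len(s) - k + 1):
                    position[encode_kmer(s[j : j + k])] = (si, j)
            for u in inst.unitigs.sequences:
                si, j = position[encode_kmer(u[:k])]
                assert inst.simplitigs.sequences[si][j : j + len(u)] == u

    def test_uni_mode_outputs_are_maximal(self, small_random_suite):
        for inst in small_random_suite:
            if inst.kmer_set.model.value == "uni":
                assert is_maximal(inst.simplitigs, inst.kmer_set).is_maximal

    def test_default_policy_is_deterministic(self, small_random_suite):
        for inst in small_random_suite[:5]:
            again = compute_simplitigs(inst.kmer_set)
            assert again.sequences == inst.simplitigs.sequences
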
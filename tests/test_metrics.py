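"""NS/CL accounting, the CL = n + (k-1)NS identity, and storage rates."""

import math

import pytest

from simplitig import (
    Representation,
    bits_per_kmer,
    build_kmer_set,
    compressed_bits_per_kmer,
    compute_simplitigs,
    compute_unitigs,
    random_genome,
    reduction_ratios,
    stats_of,
)
from simplitig.metrics import stats_table, write_stats


def rep(sequences, k=3, model="uni", kind="simplitigs"):
    return Representation(kind=kind, k=k, model=model, sequences=sequences)


THREE = build_kmer_set(["ACG", "CGA", "CGT"], 3, "uni")


class TestStats:
    def test_worked_example(self):
        st = stats_of(rep(["ACGA", "CGT"]), THREE)
        assert (st.ns, st.cl, st.n_kmers) == (2, 7, 3)
        assert st.eq1_residual == 7 - (3 + 2 * 2) == 0
        assert st.ns_bounds_ok and st.cl_bounds_ok

    def test_single_chain(self):
        ks = build_kmer_set(["ACGTT"], 3, "uni")
        st = stats_of(rep(["ACGTT"]), ks)
        assert (st.ns, st.cl, st.eq1_residual) == (1, 5, 0)

    def test_maximal_fragmentation_hits_upper_bounds(self):
        # pairwise non-overlapping k-mers kept as singletons: NS=m, CL=k*m
        kmers = ["AAT", "CCG", "GGA", "TTC"]
        ks = build_kmer_set(kmers, 3, "uni")
        st = stats_of(rep(kmers), ks)
        m = len(kmers)
        assert (st.ns, st.cl) == (m, 3 * m)
        assert st.eq1_residual == 0
        assert st.ns_bounds_ok and st.cl_bounds_ok

    def test_mismatched_k_or_model_rejected(self):
        with pytest.raises(ValueError):
            stats_of(rep(["ACGA"], k=4), THREE)
        with pytest.raises(ValueError):
            stats_of(rep(["ACGA"], model="bi"), THREE)


class TestReductionRatios:
    def test_branching_example(self):
        u = stats_of(rep(["ACG", "CGA", "CGT"], kind="unitigs"), THREE)
        s = stats_of(rep(["ACGA", "CGT"]), THREE)
        ns_ratio, cl_ratio = reduction_ratios(u, s)
        assert ns_ratio == pytest.approx(1.5)
        assert cl_ratio == pytest.approx(9 / 7)

    def test_identity(self):
        s = stats_of(rep(["ACGA", "CGT"]), THREE)
        assert reduction_ratios(s, s) == (1.0, 1.0)

    def test_extreme_fragmentation_closed_form(self):
        k, m = 3, 4
        kmers = ["AAT", "CCG", "GGA", "TTC"]
        ks = build_kmer_set(kmers, k, "uni")
        frag = stats_of(rep(kmers, kind="unitigs"), ks)
        # against a hypothetical single path of the same k-mer count
        from simplitig import RepresentationStats

        single = RepresentationStats(
            kind="simplitigs", k=k, model="uni", ns=1, cl=k + m - 1,
            n_kmers=m, eq1_residual=0, ns_bounds_ok=True, cl_bounds_ok=True,
        )
        ns_ratio, cl_ratio = reduction_ratios(frag, single)
        assert ns_ratio == m
        assert cl_ratio == pytest.approx(k * m / (k + m - 1))

    def test_empty_denominator_rejected(self):
        from simplitig import RepresentationStats

        s = stats_of(rep(["ACGA", "CGT"]), THREE)
        empty = RepresentationStats(
            kind="simplitigs", k=3, model="uni", ns=0, cl=0, n_kmers=0,
            eq1_residual=0, ns_bounds_ok=True, cl_bounds_ok=True,
        )
        with pytest.raises(ValueError):
            reduction_ratios(s, empty)


class TestBitsPerKmer:
    def test_worked_example(self):
        assert bits_per_kmer(7, 3) == pytest.approx(56 / 3)

    def test_payload_rate_approaches_8_for_one_long_chain(self):
        # CL = n + (k-1) for a single sequence
        for n in (10, 100, 10_000):
            k = 11
            rate = bits_per_kmer(n + (k - 1), n)
            assert rate == pytest.approx(8 * (1 + (k - 1) / n))
        assert rate < 8.01

    def test_zero_kmers_rejected(self):
        with pytest.raises(ValueError):
            bits_per_kmer(10, 0)
        with pytest.raises(ValueError):
            compressed_bits_per_kmer(b"ACGT", 0)

    def test_compression_is_deterministic_and_finite(self):
        genome = random_genome(20_000, 3)
        ks = build_kmer_set([genome], 31, "uni")
        payload = "".join(compute_simplitigs(ks).sequences).encode()
        a = compressed_bits_per_kmer(payload, len(ks))
        b = compressed_bits_per_kmer(payload, len(ks))
        assert a == b
        assert 0 < a < bits_per_kmer(len(payload), len(ks))
        assert math.isfinite(a)

    def test_unknown_compressor_rejected(self):
        with pytest.raises(ValueError):
            compressed_bits_per_kmer(b"ACGT", 1, compressor="zip")


def test_merging_two_sequences_drops_ns_by_1_and_cl_by_k_minus_1():
    # one compaction step: glue across a (k-1)-overlap
    k = 3
    ks = build_kmer_set(["ACGA"], k, "uni")
    split = rep(["ACG", "CGA"])
    merged = rep(["ACGA"])
    s0, s1 = stats_of(split, ks), stats_of(merged, ks)
    assert s1.ns == s0.ns - 1
    assert s1.cl == s0.cl - (k - 1)


def test_stats_serialization_roundtrip(tmp_path):
    rows = [stats_of(rep(["ACGA", "CGT"]), THREE)]
    df = stats_table(rows)
    assert list(df["ns"]) == [2] and list(df["cl"]) == [7]
    tsv = tmp_path / "stats.tsv"
    jsn = tmp_path / "stats.json"
    write_stats(rows, str(tsv))
    write_stats(rows, str(jsn))
    assert "eq1_residual" in tsv.read_text()
    assert '"ns": 2' in jsn.read_text()
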
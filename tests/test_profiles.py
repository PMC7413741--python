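from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from conftest import make_record
from patseq.io_model import GeneSet
from patseq.profiles import (
    PATHistogram,
    decile_bins,
    histogram,
    per_gene_medians,
    rank_correlation,
    set_averages,
    smooth,
    to_profile,
    tpm,
    welch_ttest,
)


def records_with_lengths(lengths, gene_id="G1", condition=""):
    return [
        make_record(read_id=f"r{i}", gene_id=gene_id, pat_length=length, condition=condition)
        for i, length in enumerate(lengths)
    ]


class TestHistogram:
    def test_simple_counts(self):
        h = histogram(records_with_lengths([5, 5, 7]))
        assert h.counts[4] == 2 and h.counts[6] == 1
        assert h.n_reads == 3

    def test_empty_subset(self):
        h = histogram(records_with_lengths([5, 5]), subset={"OTHER"})
        assert h.n_reads == 0

    def test_overflow_truncated_into_top_bin(self):
        h = histogram(records_with_lengths([400]), l_max=350)
        assert h.counts[349] == 1
        assert h.n_overflow == 1

    def test_geneset_subset(self):
        records = records_with_lengths([5], gene_id="G1") + records_with_lengths(
            [9], gene_id="G2"
        )
        h = histogram(records, subset=GeneSet("s", frozenset({"G2"})))
        assert h.n_reads == 1 and h.counts[8] == 1

    def test_invariant_enforced(self):
        with pytest.raises(ValueError):
            PATHistogram(counts=np.zeros(350), condition="", n_reads=5, l_max=350)


class TestToProfile:
    def test_two_lengths(self):
        p = to_profile(histogram(records_with_lengths([10, 20])))
        assert p.fraction[9] == p.fraction[19] == 0.5
        assert p.cumulative[9] == 0.5 and p.cumulative[19] == 1.0

    def test_single_length(self):
        p = to_profile(histogram(records_with_lengths([42])))
        assert p.fraction[41] == 1.0

    def test_uniform_cdf_midpoint(self):
        p = to_profile(histogram(records_with_lengths(list(range(1, 101)))))
        assert p.cumulative[49] == pytest.approx(0.5)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            to_profile(histogram([]))

    def test_normalization_and_monotone(self):
        rng = np.random.default_rng(0)
        lengths = rng.integers(1, 351, size=500).tolist()
        p = to_profile(histogram(records_with_lengths(lengths)))
        assert p.fraction.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(p.cumulative) >= 0)
        assert p.cumulative[-1] == pytest.approx(1.0, abs=1e-9)


class TestSmooth:
    def test_constant_unchanged(self):
        f = np.full(100, 0.01)
        assert np.allclose(smooth(f, 5), f)

    def test_delta_spreads_over_window(self):
        f = np.zeros(350)
        f[99] = 1.0  # length 100
        s = smooth(f, 5)
        assert np.allclose(s[94:105], 1 / 11)
        assert s[93] == 0 and s[105] == 0

    def test_half_window_zero_is_identity(self):
        f = np.random.default_rng(1).random(50)
        assert np.array_equal(smooth(f, 0), f)

    def test_mass_preserved_and_nonnegative(self):
        rng = np.random.default_rng(2)
        f = rng.random(350)
        f /= f.sum()
        s = smooth(f, 5)
        assert s.sum() == pytest.approx(f.sum(), abs=1e-6)
        assert (s >= 0).all()


class TestPerGeneMedians:
    def test_min_reads_exclusion(self):
        records = records_with_lengths(range(20, 29), gene_id="G9")  # 9 reads
        assert per_gene_medians(records, min_reads=10) == []

    def test_odd_median(self):
        out = per_gene_medians(records_with_lengths(range(1, 12)))
        assert out[0].median_pat == 6

    def test_even_median_mean_of_central_pair(self):
        out = per_gene_medians(records_with_lengths(range(10, 101, 10)))
        assert out[0].median_pat == 55

    def test_simulated_recovery(self):
        rng = np.random.default_rng(3)
        hits = 0
        n_genes = 60
        for g in range(n_genes):
            true_median = int(rng.integers(40, 200))
            # sd chosen so the median's sampling sd (~1.25*sd/sqrt(50)) fits the +/-2 nt target
            lengths = np.clip(rng.normal(true_median, 5, size=50).round().astype(int), 1, None)
            out = per_gene_medians(records_with_lengths(lengths.tolist(), gene_id=f"G{g}"))
            if abs(out[0].median_pat - true_median) <= 2:
                hits += 1
        assert hits >= 0.95 * n_genes


class TestSetAverages:
    def test_single_set_mean(self):
        records = records_with_lengths([50, 60, 70])
        out = set_averages(records, [GeneSet("s", frozenset({"G1"}))])
        assert out[0].mean_pat == 60
        assert out[0].n_reads == 3

    def test_disjoint_sets_independent(self):
        records = records_with_lengths([10, 20], gene_id="G1") + records_with_lengths(
            [100, 200], gene_id="G2"
        )
        out = set_averages(
            records,
            [GeneSet("a", frozenset({"G1"})), GeneSet("b", frozenset({"G2"}))],
        )
        assert out[0].mean_pat == 15 and out[1].mean_pat == 150

    def test_empty_set_flagged(self):
        out = set_averages(records_with_lengths([50]), [GeneSet("s", frozenset({"GX"}))])
        assert out[0].n_reads == 0
        assert np.isnan(out[0].mean_pat)

    def test_sampling_property(self):
        rng = np.random.default_rng(4)
        lengths = np.clip(rng.normal(80, 20, size=1000).round().astype(int), 1, None)
        out = set_averages(
            records_with_lengths(lengths.tolist()), [GeneSet("s", frozenset({"G1"}))]
        )
        assert abs(out[0].mean_pat - 80) <= 3 * out[0].sem_pat + 0.5  # 0.5 for rounding


class TestDecileBins:
    def test_100_records(self):
        bins = decile_bins(records_with_lengths(list(range(1, 101))))
        assert [len(b) for b in bins] == [10] * 10
        assert bins[0][0].pat_length == 100  # longest first

    def test_101_records_sizes(self):
        bins = decile_bins(records_with_lengths(list(range(1, 102))))
        assert sorted(len(b) for b in bins) == [10] * 9 + [11]
        assert len(bins[0]) == 11

    def test_ties_stable_order(self):
        records = records_with_lengths([7] * 20)
        bins = decile_bins(records)
        flattened = [r.read_id for b in bins for r in b]
        assert flattened == [r.read_id for r in records]

    def test_exact_partition(self):
        rng = np.random.default_rng(5)
        records = records_with_lengths(rng.integers(1, 300, size=97).tolist())
        bins = decile_bins(records)
        assert sorted(r.read_id for b in bins for r in b) == sorted(
            r.read_id for r in records
        )
        # descending across bin boundaries
        mins = [min(r.pat_length for r in b) for b in bins]
        maxs = [max(r.pat_length for r in b) for b in bins]
        assert all(mins[i] >= maxs[i + 1] for i in range(9))

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            decile_bins(records_with_lengths([1] * 9))


class TestWelch:
    def test_identical_samples(self):
        res = welch_ttest([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.t == 0
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        res = welch_ttest([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert res.t == pytest.approx(-1.0, abs=1e-12)
        assert res.df == pytest.approx(8.0, abs=1e-12)

    def test_p_matches_t_distribution(self):
        res = welch_ttest([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert res.p == pytest.approx(2 * stats.t.sf(1.0, 8), abs=1e-10)

    def test_agrees_with_scipy_reference(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            x = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), size=rng.integers(5, 40))
            y = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), size=rng.integers(5, 40))
            mine = welch_ttest(x, y)
            ref = stats.ttest_ind(x, y, equal_var=False)
            assert mine.t == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.df == pytest.approx(ref.df, abs=1e-10)
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            welch_ttest([1], [1, 2])
        with pytest.raises(ValueError):
            welch_ttest([1, 1, 1], [1, 1, 1])


class TestTPM:
    def test_two_gene_closed_form(self):
        out = tpm({"a": 10, "b": 10}, {"a": 1000, "b": 2000})
        assert out["a"] == pytest.approx(2e6 / 3, rel=1e-9)
        assert out["b"] == pytest.approx(1e6 / 3, rel=1e-9)

    def test_single_transcript(self):
        assert tpm({"a": 7}, {"a": 500})["a"] == pytest.approx(1e6)

    def test_scale_invariance(self):
        counts = {"a": 3, "b": 11, "c": 5}
        lengths = {"a": 900, "b": 1500, "c": 2100}
        base = tpm(counts, lengths)
        doubled = tpm({k: 2 * v for k, v in counts.items()}, lengths)
        for k in counts:
            assert doubled[k] == pytest.approx(base[k], rel=1e-12)

    def test_sums_to_million(self):
        rng = np.random.default_rng(7)
        counts = {f"t{i}": int(c) for i, c in enumerate(rng.integers(0, 500, size=200))}
        lengths = {f"t{i}": float(l) for i, l in enumerate(rng.integers(200, 5000, size=200))}
        out = tpm(counts, lengths)
        assert sum(out.values()) == pytest.approx(1e6, abs=1e-6)

    def test_all_zero_counts(self):
        with pytest.raises(ValueError):
            tpm({"a": 0, "b": 0}, {"a": 100, "b": 100})


class TestRankCorrelation:
    def test_perfect_monotone(self):
        a = np.array([1.0, 2, 3, 4, 5])
        res = rank_correlation(a, 2 * a)
        assert res.spearman_rho == pytest.approx(1.0)

    def test_reverse_ranks(self):
        a = np.array([1.0, 2, 3, 4, 5])
        res = rank_correlation(a, a[::-1])
        assert res.spearman_rho == pytest.approx(-1.0)

    def test_null_permutation(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(1, 100, size=1000)
        b = rng.permutation(a)
        res = rank_correlation(a, b)
        assert abs(res.spearman_rho) < 0.1

    def test_constant_vector_error(self):
        with pytest.raises(ValueError):
            rank_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
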
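"""Statistical core: sampling theory, ratios, parasite flags, GOF/QQ,
TMM, NB exact test, BH."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from parascreen.containers import PeptideMultiset, ReplicateMatrix
from parascreen.simulate import simulate_replicate_matrix
from parascreen.stats import (
    _exact_tail,
    bh_adjust,
    classify_p10_p1r,
    nb_exact_test,
    normalize_abundance,
    pearson_gof,
    qq_slope,
    ratio_table,
    sampling_theory,
    tmm_factors,
    volcano,
)


class TestSamplingTheory:
    def test_lambda_for_deep_run_of_uniform_library(self):
        st = sampling_theory(4_000_000, 1e9)
        assert st.lambda_ == pytest.approx(0.004)

    def test_conditional_copy_two_probability(self):
        st = sampling_theory(4_000_000, 1e9)
        # lambda/2 to first order; the run prints 0.002 at 1 s.f.
        assert st.conditional_copy_probability(2) == pytest.approx(0.002, abs=5e-5)

    def test_at_most_one_sequence_above_copy_three(self):
        st = sampling_theory(4_000_000, 1e9)
        expected = st.expected_sequences_above(3)
        assert expected == pytest.approx(1e9 * sps.poisson.sf(3, 0.004), rel=1e-9)
        assert expected <= 1.0

    def test_zero_diversity_rejected(self):
        with pytest.raises(ValueError):
            sampling_theory(100, 0)


class TestNormalizeAbundance:
    @pytest.mark.parametrize(
        "count,total,expected",
        [(5548, 4_000_000, 0.0014), (60_099, 5_000_000, 0.012)],
    )
    def test_worked_examples(self, count, total, expected):
        ms = PeptideMultiset(
            {"GKPMPPM": count, "XFILLER": total - count}, label="lib"
        )
        ab = normalize_abundance(ms)["GKPMPPM"]
        assert ab == pytest.approx(expected, rel=0.05)

    def test_sums_to_one_single_entry(self):
        ms = PeptideMultiset({"AAAAAAA": 7}, label="one")
        assert normalize_abundance(ms) == {"AAAAAAA": 1.0}


class TestRatioTable:
    def make(self, naive, amp, tn, ta):
        n = PeptideMultiset(naive, total_reads=tn, label="n")
        a = PeptideMultiset(amp, total_reads=ta, label="a")
        return ratio_table(n, a)

    def test_tenfold_enrichment(self):
        t = self.make({"AAAAAAA": 20}, {"AAAAAAA": 200}, 1000, 1000)
        assert t.loc["AAAAAAA", "normalized_ratio"] == pytest.approx(10.0)

    def test_equal_abundance_ratio_one(self):
        t = self.make({"AAAAAAA": 20}, {"AAAAAAA": 40}, 1000, 2000)
        assert t.loc["AAAAAAA", "normalized_ratio"] == pytest.approx(1.0)

    def test_pseudo_count_only_on_zero(self):
        t = self.make({"CCCCCCC": 10}, {"AAAAAAA": 8, "CCCCCCC": 10}, 1000, 1000)
        # absent from naive: (8 + 0.5) / 0.5 = 17
        assert t.loc["AAAAAAA", "normalized_ratio"] == pytest.approx(17.0)
        assert t.loc["AAAAAAA", "naive_count"] == 0
        # nonzero pair untouched by the pseudo-count
        assert t.loc["CCCCCCC", "normalized_ratio"] == pytest.approx(1.0)


class TestClassify:
    @pytest.mark.parametrize(
        "naive,ratio,p10,p1r",
        [(20, 10.0, True, True),
         (10, 10.0, False, False),   # strict n > 10
         (500, 1.2, True, False),
         (11, 3.0, True, False)],    # strict ratio > 3
    )
    def test_strict_predicates(self, naive, ratio, p10, p1r):
        table = pd.DataFrame(
            {"naive_count": [naive], "normalized_ratio": [ratio]},
            index=["AAAAAAA"],
        )
        out = classify_p10_p1r(table)
        assert bool(out["P10"].iloc[0]) is p10
        assert bool(out["P1R"].iloc[0]) is p1r


def _null_pair(rng, n_seq=2000, m=8, k=5, lo=1.0, hi=2.5, phi=1.0):
    mu = 10 ** rng.uniform(lo, hi, size=n_seq)
    if phi == 1.0:
        nc = rng.poisson(mu[:, None], size=(n_seq, m))
        ac = rng.poisson(mu[:, None], size=(n_seq, k))
    else:
        r = mu / (phi - 1)
        nc = rng.negative_binomial(r[:, None], 1 / phi, size=(n_seq, m))
        ac = rng.negative_binomial(r[:, None], 1 / phi, size=(n_seq, k))
    seqs = [f"s{i}" for i in range(n_seq)]
    naive = ReplicateMatrix(seqs, nc, nc.sum(axis=0), ["naive"] * m)
    amp = ReplicateMatrix(seqs, ac, ac.sum(axis=0), ["amplified"] * k)
    return naive, amp


class TestVolcano:
    def test_flat_sequence_not_flagged(self, rng):
        naive, amp = _null_pair(rng, n_seq=50)
        # identical scaled counts -> f == 1, never significant
        seqs = ["flat"]
        n = ReplicateMatrix(seqs, np.full((1, 5), 10), np.full(5, 1e6))
        a = ReplicateMatrix(seqs, np.full((1, 5), 10), np.full(5, 1e6))
        out = volcano(n, a)
        assert out.loc["flat", "f"] == pytest.approx(1.0)
        assert not out.loc["flat", "PBR"]

    def test_zero_naive_with_consistent_amp_is_significant(self):
        seqs = ["hit"]
        n = ReplicateMatrix(seqs, np.zeros((1, 8), int), np.full(8, 1e6))
        a = ReplicateMatrix(
            seqs, np.array([[10, 12, 8, 11, 9]]), np.full(5, 1e6)
        )
        out = volcano(n, a)
        assert out.loc["hit", "f"] > 1
        assert out.loc["hit", "p"] < 0.05
        assert out.loc["hit", "PBR"]

    def test_null_type_one_error_near_alpha(self, rng):
        naive, amp = _null_pair(rng)
        out = volcano(naive, amp, alpha=0.05)
        assert out["PBR"].mean() == pytest.approx(0.05, abs=0.02)

    def test_requires_two_replicates(self):
        one = ReplicateMatrix(["a"], np.array([[5]]), np.array([100.0]))
        with pytest.raises(ValueError):
            volcano(one, one)


class TestPearsonGOF:
    def test_zero_statistic_for_constant_counts(self):
        m = ReplicateMatrix(["a"], np.array([[10, 10, 10, 10, 10]]),
                            np.full(5, 100.0))
        x, s = pearson_gof(m)
        assert x.iloc[0] == 0.0
        assert np.allclose(s, 1.0)

    def test_hand_computed_statistic(self):
        # deviations (2,-2,0,1,-1)^2 / 10 summed = 1.0
        m = ReplicateMatrix(["a"], np.array([[8, 12, 10, 9, 11]]),
                            np.full(5, 10.0))
        x, _ = pearson_gof(m)
        assert x.iloc[0] == pytest.approx(1.0)

    def test_poisson_matrix_mean_near_df(self, rng):
        rm = simulate_replicate_matrix(5000, 20, 200, 1.0, k=5, seed=31)
        x, _ = pearson_gof(rm)
        assert x.mean() == pytest.approx(4.0, abs=0.2)

    def test_all_zero_matrix_rejected(self):
        m = ReplicateMatrix(["a"], np.zeros((1, 3), int), np.zeros(3))
        with pytest.raises(ValueError):
            pearson_gof(m)


class TestQQSlope:
    def test_chi2_sample_slope_one(self, rng):
        x = rng.chisquare(4, size=20_000)
        assert qq_slope(x, df=4) == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("scale", [1.25, 1.5])
    def test_scaled_chi2_recovers_scale(self, rng, scale):
        x = scale * rng.chisquare(4, size=20_000)
        assert qq_slope(x, df=4) == pytest.approx(scale, abs=0.05)

    def test_scale_equivariance(self, rng):
        x = rng.chisquare(4, size=5000)
        assert qq_slope(3.3 * x, df=4) == pytest.approx(3.3 * qq_slope(x, df=4),
                                                        rel=1e-9)

    def test_needs_enough_statistics(self):
        with pytest.raises(ValueError):
            qq_slope(np.ones(10), df=4)


class TestTMM:
    def test_identical_replicates_unit_factors(self):
        y = np.array([[10, 10], [30, 30], [5, 5]])
        rm = ReplicateMatrix(["a", "b", "c"], y, y.sum(axis=0))
        assert np.allclose(tmm_factors(rm), 1.0)

    def test_pure_depth_difference_unit_factors(self):
        # frozen edgeR::calcNormFactors output: (1, 1)
        y = np.array([[10, 20], [30, 60], [5, 10], [100, 200], [7, 14]])
        rm = ReplicateMatrix([f"g{i}" for i in range(5)], y, y.sum(axis=0))
        assert np.allclose(tmm_factors(rm), [1.0, 1.0], atol=1e-9)

    def test_matches_edger_on_composition_bias(self):
        # frozen edgeR::calcNormFactors (TMM) output for this matrix
        y = np.array(
            [[100, 200, 30], [50, 100, 10], [80, 160, 20], [120, 240, 40],
             [40, 80, 500], [60, 120, 15], [90, 180, 25], [70, 140, 18]]
        )
        rm = ReplicateMatrix([f"g{i}" for i in range(8)], y, y.sum(axis=0))
        expected = [1.5652825834, 1.5652825834, 0.4081450128]
        assert np.allclose(tmm_factors(rm), expected, rtol=1e-6)

    def test_corrects_spiked_composition_bias(self, rng):
        base = rng.integers(50, 500, size=400)
        y = np.column_stack([base, base.copy()])
        spiked = rng.choice(400, size=20, replace=False)
        y[spiked, 1] *= 100
        rm = ReplicateMatrix([f"g{i}" for i in range(400)], y, y.sum(axis=0))
        f = tmm_factors(rm)
        # effective sizes N_j * f_j should equalize the unspiked majority
        eff = y.sum(axis=0) * f
        unspiked = np.setdiff1d(np.arange(400), spiked)
        ratio = (y[unspiked, 1] / eff[1]) / (y[unspiked, 0] / eff[0])
        assert np.median(ratio) == pytest.approx(1.0, abs=0.05)


class TestNBExactTest:
    def test_identical_groups_p_one(self):
        y = np.array([[20, 21, 19, 20, 20]])
        n = ReplicateMatrix(["a"], y, np.full(5, 1000.0))
        a = ReplicateMatrix(["a"], y.copy(), np.full(5, 1000.0))
        out = nb_exact_test(n, a)
        assert out.loc["a", "p"] == 1.0

    @pytest.mark.parametrize("s1,s2,n1,n2", [(10, 25, 3, 3), (5, 30, 4, 2),
                                             (0, 12, 8, 5)])
    def test_poisson_limit_matches_binomial_oracle(self, s1, s2, n1, n2):
        """As dispersion -> 0 the conditional NB split becomes binomial."""
        p_nb = _exact_tail(s1, s2, n1, n2, 1e-10)
        total = s1 + s2
        share = n2 / (n1 + n2)
        if s2 <= total * share:
            p_bin = 1.0
        else:
            p_bin = float(sps.binom.sf(s2 - 1, total, share))
        assert p_nb == pytest.approx(p_bin, abs=1e-6)

    def test_null_type_one_error_calibrated(self, rng):
        naive, amp = _null_pair(rng, phi=1.5)
        out = nb_exact_test(naive, amp)
        assert (out["p"] < 0.05).mean() == pytest.approx(0.05, abs=0.02)

    def test_enriched_spikes_detected_with_bh(self, rng):
        naive, amp = _null_pair(rng, n_seq=500, phi=1.5)
        counts = amp.counts.copy()
        counts[:10] *= 8  # strong enrichment spikes
        amp = ReplicateMatrix(amp.sequences, counts, counts.sum(axis=0),
                              amp.roles)
        out = nb_exact_test(naive, amp)
        spiked = out.loc[[f"s{i}" for i in range(10)]]
        assert (spiked["q"] < 0.05).all()

    def test_tagwise_mode_runs(self, rng):
        naive, amp = _null_pair(rng, n_seq=200, phi=1.5)
        out = nb_exact_test(naive, amp, dispersion="tagwise")
        assert ((out["p"] >= 0) & (out["p"] <= 1)).all()


class TestBH:
    def test_hand_computed_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_all_ones_stay_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_q_at_least_p_and_monotone(self, rng):
        p = rng.uniform(size=100)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
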
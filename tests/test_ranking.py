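"""Welch t statistic, channel ranking, and the KS normality diagnostic."""

import numpy as np
import pytest
from scipy import stats

from gammase import ks_normality, rank_channels, welch_t
from gammase.errors import DegenerateSamplesError, GroupingError, SizeError

from conftest import make_features


class TestWelchT:
    def test_identical_groups(self):
        r = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0 and r.p == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # means 2 and 5, variances 1 and 1: t = -3 / sqrt(2/3)
        r = welch_t([1, 2, 3], [4, 5, 6])
        assert r.t == pytest.approx(-3 / np.sqrt(2 / 3), rel=1e-12)
        ref = stats.ttest_ind([1, 2, 3], [4, 5, 6], equal_var=False)
        assert r.df == pytest.approx(ref.df, rel=1e-12)
        assert r.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_equal_sizes_and_variances_reduce_to_pooled_t(self, rng):
        x = rng.standard_normal(20)
        y = x[::-1] + 0.7  # same variance, shifted mean
        r = welch_t(x, y)
        pooled = stats.ttest_ind(x, y, equal_var=True)
        assert r.t == pytest.approx(pooled.statistic, rel=1e-12)

    def test_matches_reference_on_random_cases(self, rng):
        for _ in range(100):
            n1, n2 = rng.integers(2, 40, size=2)
            x = rng.standard_normal(n1) * rng.uniform(0.5, 3)
            y = rng.standard_normal(n2) * rng.uniform(0.5, 3) + rng.normal()
            r = welch_t(x, y)
            ref = stats.ttest_ind(x, y, equal_var=False)
            assert r.t == pytest.approx(ref.statistic, rel=1e-9)
            assert r.df == pytest.approx(ref.df, rel=1e-9)
            assert r.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_antisymmetry_exact(self, rng):
        x, y = rng.standard_normal(12), rng.standard_normal(15)
        assert welch_t(x, y).t == -welch_t(y, x).t

    def test_location_and_scale_equivariance(self, rng):
        x, y = rng.standard_normal(12), rng.standard_normal(15)
        base = welch_t(x, y).t
        assert welch_t(x + 5.0, y + 5.0).t == pytest.approx(base, rel=1e-12)
        assert welch_t(x * -2.5, y * -2.5).t == pytest.approx(-base, rel=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateSamplesError):
            welch_t([1.0, 1.0], [2.0, 2.0])
        with pytest.raises(SizeError):
            welch_t([1.0], [1.0, 2.0])


class TestRankChannels:
    @staticmethod
    def random_features(gen, n_per_group=30, n_channels=10, shift=None):
        values = gen.standard_normal((2 * n_per_group, n_channels)) * 0.05 + 0.5
        if shift is not None:
            values[:n_per_group] += shift
        labels = ["alcoholic"] * n_per_group + ["control"] * n_per_group
        return make_features(np.clip(values, 0, 1), labels)

    def test_order_contract(self, rng):
        fm = self.random_features(np.random.default_rng(0))
        rr = rank_channels(fm, alpha=0.05)
        assert sorted(rr.order.tolist()) == list(range(10))
        ts = np.asarray([abs(r.t) for r in rr.per_channel])
        sig_block = [c for c in rr.order if rr.significant[c]]
        non_block = [c for c in rr.order if not rr.significant[c]]
        assert rr.order.tolist() == sig_block + non_block
        for block in (sig_block, non_block):
            assert np.all(np.diff(ts[block]) <= 1e-15)

    def test_sign_matches_mean_difference(self):
        fm = self.random_features(np.random.default_rng(1))
        for r in rank_channels(fm).per_channel:
            assert np.sign(r.t) == np.sign(r.mean1 - r.mean2)

    def test_invariant_to_epoch_order(self):
        gen = np.random.default_rng(2)
        fm = self.random_features(gen)
        perm = gen.permutation(fm.n_epochs)
        fm_p = make_features(fm.values[perm], fm.labels[perm])
        assert np.array_equal(rank_channels(fm).order, rank_channels(fm_p).order)

    def test_planted_channel_ranks_first(self):
        """A single channel with a mean gap far beyond the noise must take
        the top slot (the gap here is ~13 channel-level standard errors)."""
        gen = np.random.default_rng(11)
        shift = np.zeros(10)
        shift[6] = 0.05
        fm = self.random_features(gen, n_per_group=200, shift=shift)
        rr = rank_channels(fm)
        assert rr.order[0] == 6
        assert rr.significant[6]

    def test_null_significant_fraction_near_alpha(self):
        """All channels exchangeable: the p < 0.05 gate should fire at the
        nominal rate (99% binomial band over 500 replicates)."""
        gen = np.random.default_rng(17)
        n_sig, n_tot = 0, 0
        for _ in range(500):
            fm = self.random_features(gen, n_per_group=20, n_channels=8)
            n_sig += int(rank_channels(fm).significant.sum())
            n_tot += 8
        lo = stats.binom.ppf(0.005, n_tot, 0.05) / n_tot
        hi = stats.binom.ppf(0.995, n_tot, 0.05) / n_tot
        assert lo <= n_sig / n_tot <= hi

    def test_mean_gap_ordering_mode(self):
        fm = self.random_features(np.random.default_rng(4), n_per_group=50)
        rr = rank_channels(fm, order_by="mean_gap")
        gaps = np.asarray([abs(r.mean1 - r.mean2) for r in rr.per_channel])
        sig_block = [c for c in rr.order if rr.significant[c]]
        assert np.all(np.diff(gaps[sig_block]) <= 1e-15)

    def test_single_group_rejected(self):
        fm = make_features(np.random.default_rng(0).uniform(0, 1, (6, 3)),
                           ["control"] * 6)
        with pytest.raises(GroupingError):
            rank_channels(fm)

    def test_rank_table_columns(self):
        fm = self.random_features(np.random.default_rng(5), n_channels=4)
        table = rank_channels(fm).to_table(["F8", "O2", "T7", "AF8"])
        assert list(table["rank"]) == [1, 2, 3, 4]
        assert set(table["channel"]) == {1, 2, 3, 4}  # reported 1-based
        assert {"t", "p", "electrode", "significant"} <= set(table.columns)


class TestKsNormality:
    def test_normal_sample_fits(self):
        gen = np.random.default_rng(8)
        stat, _ = ks_normality(gen.standard_normal(1000))
        assert stat < 0.05

    def test_uniform_sample_fits_worse(self):
        gen = np.random.default_rng(8)
        stat_n, _ = ks_normality(gen.standard_normal(1000))
        u = gen.uniform(size=1000)
        stat_u, _ = ks_normality((u - u.mean()) / u.std(ddof=1))
        assert stat_u > stat_n

    def test_small_and_constant_samples_rejected(self):
        with pytest.raises(SizeError):
            ks_normality([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(DegenerateSamplesError):
            ks_normality([2.0] * 10)
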
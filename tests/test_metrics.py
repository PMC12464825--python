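"""De-partitioning and cross-condition metrics."""

import numpy as np
import pytest
from scipy import stats

from ladkit.domains import DomainSet, LAD, ILAD
from ladkit.metrics import (
    bimodality_assess, departition_slope, differential_track,
    domain_overlap, domain_score_compare, track_correlation,
)

from conftest import track_from_array

BS = 20_000


class TestDifferentialTrack:
    def test_identical_gives_zeros(self):
        t = track_from_array([0.5, 1.0, -2.0])
        np.testing.assert_allclose(differential_track(t, t).values(), 0.0)

    def test_unit_shift_gives_ones(self):
        t = track_from_array([0.5, 1.0, -2.0])
        shifted = t.map(lambda v: v + 1.0)
        np.testing.assert_allclose(differential_track(shifted, t).values(), 1.0)

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=100), rng.normal(size=100)
        out = differential_track(track_from_array(a), track_from_array(b)).values()
        np.testing.assert_allclose(out, a - b)

    def test_zscore_inputs_option(self):
        rng = np.random.default_rng(1)
        a = rng.normal(3.0, 2.0, 200)
        b = rng.normal(-1.0, 0.5, 200)
        out = differential_track(
            track_from_array(a), track_from_array(b), zscored=False).values()
        za = (a - a.mean()) / a.std(ddof=0)
        zb = (b - b.mean()) / b.std(ddof=0)
        np.testing.assert_allclose(out, za - zb, atol=1e-12)


class TestDepartitionSlope:
    def test_no_change_slope_zero(self):
        t = track_from_array([1.0, -1.0, 0.5, 2.0])
        diff = differential_track(t, t)
        res = departition_slope(t, diff)
        assert res.slope == 0.0 and res.r == 0.0 and res.p == 1.0

    def test_half_contrast_exact_slope(self):
        control = track_from_array([2.0, -2.0, 1.0, -1.0, 0.5, 3.0])
        perturbed = control.map(lambda v: 0.5 * v)
        res = departition_slope(control, differential_track(perturbed, control))
        assert res.slope == pytest.approx(-0.5, abs=1e-12)
        assert res.r == pytest.approx(-1.0, abs=1e-12)

    def test_noisy_shrinkage_recovered(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 10_000)
        k = 0.3
        y = (1 - k) * x + rng.normal(0, 0.3, 10_000)
        res = departition_slope(
            track_from_array(x), track_from_array(y - x))
        assert res.slope == pytest.approx(-0.3, abs=0.02)

    def test_slope_identity_with_perturbed_regression(self):
        # slope(control, perturbed - control) == slope(control, perturbed) - 1
        rng = np.random.default_rng(3)
        x = rng.normal(size=500)
        y = 0.4 * x + rng.normal(0, 0.2, 500)
        res_diff = departition_slope(track_from_array(x), track_from_array(y - x))
        direct = stats.linregress(x, y)
        assert res_diff.slope == pytest.approx(direct.slope - 1.0, abs=1e-12)

    def test_constant_control_error(self):
        with pytest.raises(ValueError, match="variance"):
            departition_slope(track_from_array([1.0, 1.0, 1.0]),
                              track_from_array([0.0, 1.0, 2.0]))


class TestBimodality:
    def test_separated_mixture_bimodal(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(-2, 0.5, 5000), rng.normal(2, 0.5, 5000)])
        res = bimodality_assess(track_from_array(x))
        assert res["verdict"] == "bimodal"
        # closed form: sqrt(2)*|mu1-mu2|/sqrt(s1^2+s2^2) = sqrt(2)*4/sqrt(0.5) = 8.0
        assert res["ashman_D"] == pytest.approx(8.0, rel=0.10)

    def test_single_gaussian_unimodal(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 10_000)
        assert bimodality_assess(track_from_array(x))["verdict"] == "unimodal"

    def test_equal_means_unimodal(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(0, 1, 2000), rng.normal(0, 1, 2000)])
        res = bimodality_assess(track_from_array(x))
        assert res["verdict"] == "unimodal"
        assert res["ashman_D"] < 2.0

    def test_affine_invariance_of_verdict(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(-2, 0.5, 3000), rng.normal(2, 0.5, 3000)])
        r1 = bimodality_assess(track_from_array(x))
        r2 = bimodality_assess(track_from_array(5.0 * x - 3.0))
        assert r1["verdict"] == r2["verdict"] == "bimodal"
        assert r1["ashman_D"] == pytest.approx(r2["ashman_D"], rel=0.05)

    def test_too_few_bins_error(self):
        with pytest.raises(ValueError, match="100"):
            bimodality_assess(track_from_array(np.random.default_rng(0).normal(size=50)))


class TestDomainScoreCompare:
    def make_domains(self, n_per_state=20, bins_per_domain=5):
        intervals, pos = [], 0
        for i in range(2 * n_per_state):
            state = LAD if i % 2 == 0 else ILAD
            end = pos + bins_per_domain * BS
            intervals.append(("chr1", pos, end, state))
            pos = end
        return DomainSet.from_intervals(intervals), pos // BS

    def test_separated_scores_tiny_p(self):
        rng = np.random.default_rng(8)
        domains, n_bins = self.make_domains(50)
        labels = domains.state_per_bin(
            track_from_array(np.zeros(n_bins)).grid)["chr1"]
        vals = np.where(labels == 1, 5.0, 0.0) + rng.normal(0, 1, n_bins)
        res = domain_score_compare(track_from_array(vals), domains)
        assert res["p"] < 1e-10

    def test_welch_statistic_matches_textbook_formula(self):
        domains, n_bins = self.make_domains(3, bins_per_domain=1)
        vals = np.array([1.2, 0.1, 3.4, -0.5, 2.2, 0.8])
        res = domain_score_compare(track_from_array(vals), domains, test="welch")
        a, b = vals[::2], vals[1::2]   # LAD, iLAD single-bin scores
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t_oracle = (a.mean() - b.mean()) / np.sqrt(va + vb)
        assert res["statistic"] == pytest.approx(t_oracle, abs=1e-12)
        df_oracle = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        p_oracle = 2 * stats.t.sf(abs(t_oracle), df_oracle)
        assert res["p"] == pytest.approx(p_oracle, abs=1e-12)

    def test_trimming_only_affects_plot_lists(self):
        rng = np.random.default_rng(9)
        domains, n_bins = self.make_domains(150, bins_per_domain=1)
        vals = rng.normal(0, 1, n_bins)
        vals[0] = 50.0  # gross outlier in a LAD
        res = domain_score_compare(track_from_array(vals), domains,
                                   trim_pct=0.5)
        assert 50.0 in res["lad_scores"]
        assert 50.0 not in res["lad_scores_trimmed"]
        # the test itself is computed on the untrimmed lists
        t_full, _ = stats.ttest_ind(res["lad_scores"], res["ilad_scores"],
                                    equal_var=False)
        assert res["statistic"] == pytest.approx(t_full)

    def test_wilcoxon_variant_runs(self):
        rng = np.random.default_rng(10)
        domains, n_bins = self.make_domains(20)
        vals = rng.normal(0, 1, n_bins)
        res = domain_score_compare(track_from_array(vals), domains,
                                   test="wilcoxon")
        u_oracle, p_oracle = stats.mannwhitneyu(
            res["lad_scores"], res["ilad_scores"], alternative="two-sided")
        assert res["statistic"] == pytest.approx(u_oracle)
        assert res["p"] == pytest.approx(p_oracle)

    def test_single_domain_state_error(self):
        domains = DomainSet.from_intervals([
            ("chr1", 0, 5 * BS, LAD), ("chr1", 5 * BS, 10 * BS, ILAD)])
        with pytest.raises(ValueError, match="2 scored domains"):
            domain_score_compare(track_from_array(np.arange(10.0)), domains)


class TestDomainOverlap:
    GENOME = {"chr1": 100 * BS}

    def sets(self, a_bins, b_bins):
        import pandas as pd

        def df(bins):
            return pd.DataFrame([
                {"chrom": "chr1", "start": b * BS, "end": (b + 1) * BS}
                for b in bins
            ], columns=["chrom", "start", "end"])
        return df(a_bins), df(b_bins)

    def test_self_overlap(self):
        a, _ = self.sets(range(10), [])
        res = domain_overlap(a, a, BS, self.GENOME)
        assert res.overlap_mb == pytest.approx(10 * BS / 1e6)
        assert res.odds_ratio == np.inf

    def test_disjoint_zero(self):
        a, b = self.sets(range(10), range(50, 60))
        res = domain_overlap(a, b, BS, self.GENOME)
        assert res.overlap_mb == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(11)
        a, b = self.sets(rng.choice(100, 30, replace=False),
                         rng.choice(100, 40, replace=False))
        r1 = domain_overlap(a, b, BS, self.GENOME)
        r2 = domain_overlap(b, a, BS, self.GENOME)
        assert r1.overlap_mb == r2.overlap_mb
        assert r1.fisher_p == pytest.approx(r2.fisher_p)

    def test_fisher_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(12)
        for trial in range(5):
            a, b = self.sets(rng.choice(100, rng.integers(5, 40), replace=False),
                             rng.choice(100, rng.integers(5, 40), replace=False))
            res = domain_overlap(a, b, BS, self.GENOME)
            # brute-force two-sided Fisher: sum probabilities of all tables
            # with the same margins that are as or less probable
            t = res.table
            row1, col1, n = t[0].sum(), t[:, 0].sum(), t.sum()
            k_obs = t[0, 0]
            kmin = max(0, row1 + col1 - n)
            kmax = min(row1, col1)
            probs = {k: stats.hypergeom.pmf(k, n, row1, col1)
                     for k in range(kmin, kmax + 1)}
            p_oracle = sum(v for v in probs.values()
                           if v <= probs[k_obs] * (1 + 1e-9))
            assert res.fisher_p == pytest.approx(p_oracle, rel=1e-7)

    def test_empty_set_flagged(self):
        a, b = self.sets(range(10), [])
        res = domain_overlap(a, b, BS, self.GENOME)
        assert res.fisher_skipped and res.overlap_mb == 0.0


class TestTrackCorrelation:
    def test_perfect_correlation(self):
        rng = np.random.default_rng(13)
        a = track_from_array(rng.normal(size=100))
        assert track_correlation(a, a)["r"] == pytest.approx(1.0)
        neg = a.map(lambda v: -v)
        assert track_correlation(a, neg)["r"] == pytest.approx(-1.0)

    def test_mask_oracle(self):
        rng = np.random.default_rng(14)
        x, y = rng.normal(size=1000), rng.normal(size=1000)
        mask = rng.random(1000) > 0.3   # drop ~30% of bins
        res = track_correlation(track_from_array(x), track_from_array(y),
                                mask=mask)
        r_oracle, p_oracle = stats.pearsonr(x[mask], y[mask])
        assert res["r"] == pytest.approx(r_oracle, abs=1e-12)
        assert res["p"] == pytest.approx(p_oracle, rel=1e-9)
        assert res["n"] == mask.sum()

    def test_too_few_bins_error(self):
        with pytest.raises(ValueError, match="3"):
            track_correlation(track_from_array([1.0, 2.0]),
                              track_from_array([1.0, 2.0]))
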
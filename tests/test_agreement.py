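"""Wilcoxon, Bland–Altman, ICC, splines, stratification, heterogeneity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plaquekit.agreement import (
    DegenerateDataError,
    IccModelSpec,
    IccResult,
    bland_altman,
    compare_adjusted_icc,
    icc_band,
    icc_heterogeneity,
    icc_mixed,
    rcs_basis,
    rcs_knots,
    stratify,
    wilcoxon_paired,
)
from plaquekit.synthetic import two_way_table


class TestWilcoxon:
    def test_all_positive_shift_matches_exact_tail(self):
        # y > x everywhere with distinct gaps: all ranks carry the same
        # sign, so the exact two-sided p is 2 / 2^n
        x = np.arange(20, dtype=float)
        y = x + np.linspace(1.0, 2.0, 20)
        assert wilcoxon_paired(x, y) == pytest.approx(2.0 / 2**20)

    def test_null_p_values_are_uniform(self, rng):
        # symmetric noise about x: p approximately U(0,1) across
        # simulations (the signed-rank statistic is discrete, so check
        # moments and the rejection rate rather than an exact KS)
        ps = np.array(
            [
                wilcoxon_paired(
                    (x := rng.normal(0, 1, 30)), x + rng.normal(0, 1, 30)
                )
                for _ in range(1000)
            ]
        )
        assert abs(ps.mean() - 0.5) < 0.03
        assert 0.03 <= (ps < 0.05).mean() <= 0.07

    def test_identical_vectors_are_degenerate(self):
        x = np.arange(10, dtype=float)
        with pytest.raises(DegenerateDataError):
            wilcoxon_paired(x, x.copy())

    def test_too_few_nonzero_differences(self):
        x = np.zeros(10)
        y = np.zeros(10)
        y[:3] = 1.0
        with pytest.raises(ValueError, match="at least 5"):
            wilcoxon_paired(x, y)


def pinball_loss(d, tau, q):
    return float(np.sum(np.where(d >= q, tau * (d - q), (1 - tau) * (q - d))))


def pinball_min_loss(d, tau):
    """Minimum pinball loss over a dense grid (independent oracle); the
    minimiser can be an interval, so the loss is the comparable quantity."""
    grid = np.linspace(d.min(), d.max(), 20001)
    return min(pinball_loss(d, tau, g) for g in grid)


class TestBlandAltman:
    def test_zero_variance(self):
        assert bland_altman([2.0, 2.0, 2.0]) == pytest.approx((2.0, 2.0, 2.0))

    def test_unit_sd_example(self):
        bias, lo, hi = bland_altman([-1.0, 0.0, 1.0])
        assert (bias, lo, hi) == pytest.approx((0.0, -1.96, 1.96))

    def test_nonparametric_matches_pinball_oracle(self, rng):
        d = rng.gamma(2, 1.5, 400) - 2.0
        bias, lo, hi = bland_altman(d, "nonparametric")
        for tau, q in ((0.5, bias), (0.025, lo), (0.975, hi)):
            loss = pinball_loss(d, tau, q)
            best = pinball_min_loss(d, tau)
            assert loss <= best * (1 + 1e-6) + 1e-9

    def test_nonparametric_standard_normal_limits(self, rng):
        d = rng.normal(0, 1, 10000)
        bias, lo, hi = bland_altman(d, "nonparametric")
        assert bias == pytest.approx(0.0, abs=0.05)
        assert lo == pytest.approx(-1.96, abs=0.1)
        assert hi == pytest.approx(1.96, abs=0.1)

    def test_insufficient_data(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0])


def anova_icc_a2(mat):
    """Textbook two-way ANOVA ICC(A,k) oracle, written from the mean
    squares directly."""
    n, k = mat.shape
    grand = mat.mean()
    msr = k * ((mat.mean(1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((mat.mean(0) - grand) ** 2).sum() / (k - 1)
    mse = ((mat - mat.mean(1)[:, None] - mat.mean(0)[None, :] + grand) ** 2).sum() / (
        (n - 1) * (k - 1)
    )
    return (msr - mse) / (msr + (msc - mse) / n)


class TestIcc:
    def test_perfect_agreement_is_one(self):
        df = two_way_table(40, 2.0, 0.0, 0.0, 3)
        df["value"] = df.groupby("subject")["value"].transform("mean")
        r = icc_mixed(df, n_boot=0)
        assert r.icc == pytest.approx(1.0)

    def test_mixedlm_matches_anova_closed_form(self):
        # the REML mixed model and the ANOVA mean-squares formula must
        # coincide on balanced data
        df = two_way_table(60, 1.5, 0.6, 1.0, 11)
        r = icc_mixed(df, n_boot=0, fitter="mixedlm")
        mat = df.pivot(index="subject", columns="modality", values="value").to_numpy()
        assert r.icc == pytest.approx(anova_icc_a2(mat), abs=1e-4)
        assert r.method == "mixedlm-reml"

    def test_parameter_recovery_at_500_subjects(self):
        # sigma_s^2=3, sigma_m^2=0.5, sigma_e^2=1 -> ICC(A,2) = 0.8
        df = two_way_table(500, np.sqrt(3), np.sqrt(0.5), 1.0, 2024)
        r = icc_mixed(df, n_boot=500, seed=5)
        assert r.icc == pytest.approx(0.8, abs=0.05)
        assert r.ci[0] < r.icc < r.ci[1]

    def test_monotone_in_error_variance(self):
        iccs = []
        for sigma_e in (0.5, 1.0, 2.0, 4.0):
            df = two_way_table(400, np.sqrt(3), np.sqrt(0.5), sigma_e, 99)
            iccs.append(icc_mixed(df, n_boot=0).icc)
        assert all(a > b for a, b in zip(iccs, iccs[1:]))

    def test_patient_cluster_bootstrap(self):
        df = two_way_table(60, 1.5, 0.3, 1.0, 8)
        df["patient"] = [f"P{i % 12}" for i in range(len(df))]
        r = icc_mixed(df, IccModelSpec(cluster="patient"), n_boot=200, seed=3)
        assert r.ci[0] <= r.icc <= r.ci[1]

    def test_adjusted_mixedlm_and_residual_anova_agree(self, rng):
        n = 150
        subj = [f"S{i}" for i in range(n)]
        ca = rng.gamma(2, 1.5, n)
        base = 0.8 * ca + rng.normal(0, 1.2, n)
        vals = np.column_stack([base + rng.normal(0, 0.7, n),
                                base + 0.3 + rng.normal(0, 0.7, n)])
        df = pd.DataFrame({
            "subject": np.repeat(subj, 2),
            "modality": np.tile(["NIRS_IVUS", "CTA"], n),
            "value": vals.ravel(),
            "ca": np.repeat(ca, 2),
        })
        spec = IccModelSpec(covariate="ca", n_knots=3)
        r_lm = icc_mixed(df, spec, n_boot=0, fitter="mixedlm")
        r_ra = icc_mixed(df, spec, n_boot=0, fitter="residual-anova")
        assert r_lm.icc == pytest.approx(r_ra.icc, abs=0.05)
        # adjustment removes the covariate-driven between-target variance
        r_un = icc_mixed(df, n_boot=0)
        assert r_lm.icc < r_un.icc

    def test_requires_two_subjects(self):
        df = two_way_table(1, 1, 0.1, 1, 0)
        with pytest.raises(ValueError):
            icc_mixed(df, n_boot=0)


class TestRcs:
    def test_k_minus_one_columns(self, rng):
        x = rng.normal(0, 1, 200)
        assert rcs_basis(x, 3).shape == (200, 2)
        assert rcs_basis(x, 5).shape == (200, 4)

    def test_truncated_power_formula_via_sympy(self):
        import sympy as sp

        xs = sp.symbols("x")
        knots = np.array([-1.0, 0.2, 1.5])
        t1, t2, t3 = knots
        plus = lambda v: sp.Piecewise((v**3, v > 0), (0, True))
        expr = (
            plus(xs - t1)
            - plus(xs - t2) * (t3 - t1) / (t3 - t2)
            + plus(xs - t3) * (t2 - t1) / (t3 - t2)
        )
        pts = np.array([-2.0, -1.0, 0.0, 0.2, 1.0, 1.5, 3.0])
        want = [float(expr.subs(xs, p)) for p in pts]
        got = rcs_basis(pts, knots=knots)[:, 1]
        assert got == pytest.approx(want)

    def test_continuous_second_derivative_at_knots(self, rng):
        x = rng.normal(0, 1, 500)
        knots = rcs_knots(x, 5)
        h = 1e-4
        for t in knots:
            pts = np.array([t - 2 * h, t - h, t, t + h, t + 2 * h])
            cols = rcs_basis(pts, knots=knots)
            for j in range(cols.shape[1]):
                d2_left = (cols[0, j] - 2 * cols[1, j] + cols[2, j]) / h**2
                d2_right = (cols[2, j] - 2 * cols[3, j] + cols[4, j]) / h**2
                assert d2_left == pytest.approx(d2_right, abs=1e-2)

    def test_linear_tails(self):
        knots = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        left = np.array([-10.0, -9.0, -8.0])
        right = np.array([8.0, 9.0, 10.0])
        for pts in (left, right):
            cols = rcs_basis(pts, knots=knots)
            for j in range(cols.shape[1]):
                d2 = cols[0, j] - 2 * cols[1, j] + cols[2, j]
                assert d2 == pytest.approx(0.0, abs=1e-8)

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError):
            rcs_knots([1.0, 1.0, 2.0], 3)


class TestCompareAndBands:
    def _res(self, icc, lo, hi):
        return IccResult(icc, (lo, hi), 1, 0, 1, 10, 20, "anova-reml", 0, 0)

    def test_disjoint_is_significant(self):
        assert compare_adjusted_icc(self._res(0.35, 0.2, 0.5), self._res(0.7, 0.6, 0.8))

    def test_overlap_is_not(self):
        assert not compare_adjusted_icc(
            self._res(0.35, 0.2, 0.5), self._res(0.55, 0.4, 0.7)
        )

    def test_identical_cis_are_not(self):
        a = self._res(0.35, 0.2, 0.5)
        assert not compare_adjusted_icc(a, a)

    @pytest.mark.parametrize(
        "icc,band",
        [(0.49, "poor"), (0.50, "moderate"), (0.74, "moderate"), (0.75, "good"),
         (0.90, "good"), (0.91, "excellent")],
    )
    def test_interpretation_band_boundaries(self, icc, band):
        assert icc_band(icc) == band


class TestStratify:
    def test_nine_distinct_values_balanced_terciles(self):
        labels = stratify([5, 1, 9, 3, 7, 2, 8, 4, 6], "terciles")
        assert sorted(np.bincount(labels)) == [3, 3, 3]

    def test_all_equal_collapse_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            labels = stratify([2.0] * 10, "terciles")
        assert set(labels) == {0}

    def test_decile_sizes_within_one(self, rng):
        v = rng.uniform(0, 1, 1000)
        labels = stratify(v, "deciles")
        counts = np.bincount(labels)
        assert counts.size == 10
        assert counts.min() >= 99 and counts.max() <= 101

    def test_tie_at_cutpoint_goes_to_lower_group(self):
        v = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        labels = stratify(v, "terciles")
        cut = np.quantile(v, 1 / 3, method="inverted_cdf")
        assert all(labels[i] == 0 for i in range(6) if v[i] == cut)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            stratify([1.0, 2.0], "terciles")


class TestHeterogeneity:
    def test_identical_strata_give_q_zero_p_one(self):
        strata = [(0.5, (0.4, 0.6))] * 3
        het = icc_heterogeneity(strata)
        assert het.q == pytest.approx(0.0, abs=1e-12)
        assert het.p_value == pytest.approx(1.0)

    def test_two_strata_equal_z_test(self):
        s1, s2 = (0.3, (0.24, 0.36)), (0.55, (0.48, 0.62))
        het = icc_heterogeneity([s1, s2])
        z = np.arctanh
        z1, z2 = z(0.3), z(0.55)
        se1 = (z(0.36) - z(0.24)) / (2 * 1.959963984540054)
        se2 = (z(0.62) - z(0.48)) / (2 * 1.959963984540054)
        stat = (z1 - z2) / np.hypot(se1, se2)
        p = 2 * stats.norm.sf(abs(stat))
        assert het.p_value == pytest.approx(p, rel=1e-10)

    def test_narrow_frame_level_cis_yield_small_p(self):
        # tercile ICCs with tight CIs, echoing a cross-sectional lipid
        # burden pattern: heterogeneity should be clearly significant
        strata = [(0.27, (0.24, 0.29)), (0.36, (0.32, 0.39)), (0.20, (0.15, 0.25))]
        het = icc_heterogeneity(strata)
        assert het.p_value < 0.001

    def test_zero_width_ci_rejected(self):
        with pytest.raises(ValueError, match="zero-width"):
            icc_heterogeneity([(0.3, (0.3, 0.3)), (0.5, (0.4, 0.6))])
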
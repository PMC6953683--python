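import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clinepop.pstfst import (
    bootstrap_variance,
    decompose_variance,
    default_ch2_grid,
    pst_fst_curve,
    pst_value,
    reml_oneway,
)


# ---------------------------------------------------------------------------
# independent REML oracle: coarse grid + golden-section on the same criterion
# ---------------------------------------------------------------------------

def reml_criterion(lam, y, groups):
    """Profiled negative REML criterion, written independently from scratch."""
    import pandas as pd

    df = pd.DataFrame({"y": y, "g": groups})
    out = 0.0
    n_j, ybar_j, ssw = [], [], 0.0
    for _, sub in df.groupby("g"):
        n_j.append(len(sub))
        ybar_j.append(sub["y"].mean())
        ssw += ((sub["y"] - sub["y"].mean()) ** 2).sum()
    n_j, ybar_j = np.array(n_j, float), np.array(ybar_j)
    d = 1.0 + lam * n_j
    w = n_j / d
    mu = (w * ybar_j).sum() / w.sum()
    q = ssw + (n_j * (ybar_j - mu) ** 2 / d).sum()
    return np.log(d).sum() + np.log(w.sum()) + (len(y) - 1) * np.log(q), q, mu


def reml_oracle(y, groups):
    """Grid search + golden-section refinement of the REML criterion."""
    grid = np.concatenate([[0.0], np.logspace(-8, 6, 3000)])
    vals = [reml_criterion(l, y, groups)[0] for l in grid]
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    phi = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    for _ in range(200):
        c1 = b - phi * (b - a)
        c2 = a + phi * (b - a)
        if reml_criterion(c1, y, groups)[0] < reml_criterion(c2, y, groups)[0]:
            b = c2
        else:
            a = c1
    lam = (a + b) / 2
    _, q, _ = reml_criterion(lam, y, groups)
    s2w = q / (len(y) - 1)
    return lam * s2w, s2w


class TestRemlOracle:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_grid_golden_section(self, seed):
        rng = np.random.default_rng(seed)
        n_pops = int(rng.integers(3, 6))
        n = int(rng.integers(4, 11))
        groups = np.repeat(np.arange(n_pops), n)
        y = rng.normal(0, 1.0, size=groups.size) + np.repeat(
            rng.normal(0, 1.2, n_pops), n
        )
        s2b, s2w, _ = reml_oneway(y, groups)
        ob, ow = reml_oracle(y, groups)
        assert s2w == pytest.approx(ow, rel=1e-6, abs=1e-9)
        assert s2b == pytest.approx(ob, rel=1e-6, abs=1e-6)

    def test_balanced_case_equals_anova(self):
        """For balanced data with MSB > MSW, REML equals the ANOVA estimators."""
        rng = np.random.default_rng(10)
        n_pops, n = 8, 12
        groups = np.repeat(np.arange(n_pops), n)
        y = np.repeat(rng.normal(0, 2.0, n_pops), n) + rng.normal(0, 1.0, groups.size)
        s2b, s2w, _ = reml_oneway(y, groups)
        g_means = y.reshape(n_pops, n).mean(axis=1)
        msb = n * g_means.var(ddof=1)
        msw = y.reshape(n_pops, n).var(axis=1, ddof=1).mean()
        assert s2w == pytest.approx(msw, rel=1e-6)
        assert s2b == pytest.approx((msb - msw) / n, rel=1e-6)

    def test_cross_check_against_mixedlm(self):
        """statsmodels MixedLM (independent implementation) agrees."""
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        sizes = [4, 9, 6, 12, 7]
        groups = np.repeat(np.arange(len(sizes)), sizes)
        y = rng.normal(0, 1.0, groups.size) + np.repeat(
            rng.normal(0, 1.5, len(sizes)), sizes
        )
        s2b, s2w, _ = reml_oneway(y, groups)
        md = sm.MixedLM(y, np.ones((groups.size, 1)), groups=groups).fit(reml=True)
        assert s2w == pytest.approx(float(md.scale), rel=1e-4)
        assert s2b == pytest.approx(float(np.asarray(md.cov_re)[0, 0]), rel=1e-3, abs=1e-6)

    def test_degenerate_all_identical(self):
        d = decompose_variance(np.zeros(12), np.repeat([0, 1, 2], 4))
        assert d.sigma2_B == 0.0
        assert d.sigma2_W < 1e-12
        assert d.degenerate

    def test_two_group_zero_within(self):
        """No within-group variance: sigma2_W collapses, sigma2_B stays large."""
        y = np.array([0.0] * 4 + [10.0] * 4)
        groups = np.repeat([0, 1], 4)
        s2b, s2w, mu = reml_oneway(y, groups)
        assert s2w < 1e-4
        assert s2b > 1.0
        assert mu == pytest.approx(5.0, abs=1e-6)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(12)
        est = []
        for _ in range(20):
            groups = np.repeat(np.arange(30), 30)
            y = np.repeat(rng.normal(0, 1.0, 30), 30) + rng.normal(
                0, np.sqrt(2.0), groups.size
            )
            s2b, s2w, _ = reml_oneway(y, groups)
            est.append((s2b, s2w))
        est = np.array(est)
        assert abs(est[:, 0].mean() - 1.0) < 0.25
        assert abs(est[:, 1].mean() - 2.0) < 0.25


class TestBootstrap:
    def test_seed_determinism(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, 60) + np.repeat(rng.normal(0, 1, 6), 10)
        d1 = decompose_variance(y, np.repeat(np.arange(6), 10))
        d2 = decompose_variance(y, np.repeat(np.arange(6), 10))
        b1 = bootstrap_variance(d1, n_boot=50, seed=3)
        b2 = bootstrap_variance(d2, n_boot=50, seed=3)
        np.testing.assert_array_equal(b1, b2)

    def test_zero_between_variance_boundary(self):
        rng = np.random.default_rng(2)
        y = rng.normal(0, 1, 200)  # no group structure at all
        d = decompose_variance(y, np.repeat(np.arange(10), 20))
        draws = bootstrap_variance(d, n_boot=100, seed=0)
        if d.sigma2_B == 0.0:
            assert np.percentile(draws[:, 0], 50) < 0.05
            assert d.ci_B[0] == pytest.approx(0.0, abs=1e-6)

    def test_ci_bounds_ordered_and_contain_typical_estimate(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, 90) + np.repeat(rng.normal(0, 2, 9), 10)
        d = decompose_variance(y, np.repeat(np.arange(9), 10))
        bootstrap_variance(d, n_boot=200, seed=1)
        assert d.ci_B[0] <= d.ci_B[1]
        assert d.ci_W[0] <= d.sigma2_W <= d.ci_W[1]


class TestPstValue:
    def test_algebraic_identities(self):
        assert pst_value(2.0, 1.0, 1.0) == pytest.approx(0.5)
        assert pst_value(5.0, 3.0, 0.0) == 0.0
        assert pst_value(0.01, 0.003, 1.0) == pytest.approx(0.625)

    def test_both_variances_zero_undefined(self):
        assert np.isnan(pst_value(0.0, 0.0, 1.0))

    @given(
        st.floats(0.01, 100.0),
        st.floats(0.01, 100.0),
        st.floats(0.01, 2.0),
        st.floats(1.01, 3.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotonicities(self, s2b, s2w, ch2, mult):
        base = pst_value(s2b, s2w, ch2)
        assert pst_value(s2b, s2w, ch2 * mult) > base  # increasing in ch2
        assert pst_value(s2b * mult, s2w, ch2) > base  # increasing in s2b
        assert pst_value(s2b, s2w * mult, ch2) < base  # decreasing in s2w
        assert 0.0 <= base < 1.0

    @given(st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance(self, k):
        assert pst_value(2.0 * k**2, 1.0 * k**2, 0.7) == pytest.approx(
            pst_value(2.0, 1.0, 0.7)
        )


class TestPstCurve:
    def test_grid_default_matches_count_and_range(self):
        g = default_ch2_grid()
        assert len(g) == 100
        assert g[0] == pytest.approx(0.02)
        assert g[-1] == pytest.approx(2.0)

    def test_strong_divergence_small_critical(self):
        rng = np.random.default_rng(4)
        groups = np.repeat(np.arange(9), 15)
        y = np.repeat(rng.normal(0, np.sqrt(20.0), 9), 15) + rng.normal(
            0, 1.0, groups.size
        )
        curve = pst_fst_curve(y, groups, fst_ref=0.015, n_boot=300, seed=0)
        assert curve.critical <= 0.2
        assert np.all(np.diff(curve.pst) >= 0)  # nondecreasing along grid
        assert np.all(curve.pst_low <= curve.pst + 1e-12)
        assert np.all(curve.pst <= curve.pst_high + 1e-12)

    def test_zero_between_variance_flat_curve(self):
        rng = np.random.default_rng(5)
        groups = np.repeat(np.arange(9), 15)
        y = rng.normal(0, 1.0, groups.size)
        curve = pst_fst_curve(y, groups, fst_ref=0.015, n_boot=100, seed=0)
        if curve.decomposition.sigma2_B == 0.0:
            assert np.allclose(curve.pst, 0.0)
            assert np.isinf(curve.critical)

    def test_trait_rescaling_leaves_curve_unchanged(self):
        rng = np.random.default_rng(6)
        groups = np.repeat(np.arange(9), 12)
        y = np.repeat(rng.normal(0, 1.0, 9), 12) + rng.normal(0, 0.5, groups.size)
        c1 = pst_fst_curve(y, groups, fst_ref=0.02, n_boot=150, seed=7)
        c2 = pst_fst_curve(y * 3.7, groups, fst_ref=0.02, n_boot=150, seed=7)
        np.testing.assert_allclose(c1.pst, c2.pst, atol=1e-10)
        np.testing.assert_allclose(c1.pst_low, c2.pst_low, atol=1e-10)
        assert c1.critical == c2.critical
        d1, d2 = c1.decomposition, c2.decomposition
        assert d2.sigma2_B == pytest.approx(d1.sigma2_B * 3.7**2, rel=1e-6)
        assert d2.sigma2_W == pytest.approx(d1.sigma2_W * 3.7**2, rel=1e-6)

    def test_endpoint_ci_variant_available(self):
        rng = np.random.default_rng(8)
        groups = np.repeat(np.arange(6), 10)
        y = np.repeat(rng.normal(0, 1.0, 6), 10) + rng.normal(0, 0.5, groups.size)
        curve = pst_fst_curve(
            y, groups, fst_ref=0.02, n_boot=100, seed=0, ci_method="endpoints"
        )
        assert np.all(curve.pst_low <= curve.pst + 1e-12)

    def test_bad_fst_ref_rejected(self):
        with pytest.raises(ValueError):
            pst_fst_curve(np.zeros(10), np.repeat([0, 1], 5), fst_ref=1.5)
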
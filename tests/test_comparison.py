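import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from braintrends.bootstrap import BootstrapResult
from braintrends.comparison import (
    ComparisonError,
    compare_regions,
    kappa,
    laterality_summary,
    welch_t,
    welch_t_from_draws,
)
from braintrends.regions import RegionWeights


class TestWelchT:
    @pytest.mark.parametrize(
        "m1, s1, m2, s2, expected_round",
        [
            # printed summary moments from study-vs-reference slope tables,
            # n = 1000 bootstrap realizations per side
            (0.41, 0.29, -0.37, 0.18, 72),
            (0.93, 0.32, -0.31, 0.13, 114),
            (0.55, 0.32, -0.11, 0.20, 55),
            (0.74, 0.32, -0.24, 0.13, 90),
            (-0.61, 0.16, -0.05, 0.12, -89),
        ],
    )
    def test_reported_t_statistics(self, m1, s1, m2, s2, expected_round):
        t, df, p = welch_t(m1, s1, 1000, m2, s2, 1000)
        assert round(float(t)) == expected_round
        assert p < 0.001

    def test_equal_means_give_zero(self):
        t, _, p = welch_t(1.0, 0.5, 100, 1.0, 0.7, 100)
        assert t == 0.0 and p == pytest.approx(1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        m1=st.floats(-5, 5), m2=st.floats(-5, 5),
        s1=st.floats(0.01, 3), s2=st.floats(0.01, 3),
        n1=st.integers(2, 5000), n2=st.integers(2, 5000),
    )
    def test_antisymmetry_and_df_bounds(self, m1, m2, s1, s2, n1, n2):
        t, df, p = welch_t(m1, s1, n1, m2, s2, n2)
        t2, df2, p2 = welch_t(m2, s2, n2, m1, s1, n1)
        assert t == pytest.approx(-t2, rel=1e-12, abs=1e-12)
        assert df == pytest.approx(df2)
        assert p == pytest.approx(p2)
        assert min(n1, n2) - 1 <= df + 1e-9
        assert df <= n1 + n2 - 2 + 1e-9

    def test_agrees_with_scipy_from_stats(self):
        t, df, p = welch_t(0.3, 0.2, 40, 0.1, 0.5, 60)
        res = stats.ttest_ind_from_stats(0.3, 0.2, 40, 0.1, 0.5, 60, equal_var=False)
        assert t == pytest.approx(res.statistic, abs=1e-12)
        assert p == pytest.approx(res.pvalue, abs=1e-12)

    def test_draws_level_agreement(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0.2, 1, 300), rng.normal(-0.1, 2, 400)
        td, dfd, pd_ = welch_t_from_draws(x, y)
        t, df, p = welch_t(x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y))
        assert t == pytest.approx(td, abs=1e-9)
        assert df == pytest.approx(dfd, abs=1e-6)
        assert p == pytest.approx(pd_, abs=1e-9)

    def test_degenerate_variances_rejected(self):
        with pytest.raises(ComparisonError):
            welch_t(1.0, 0.0, 10, 2.0, 0.0, 10)


def _boot(mu_s, sd_s, mu_r, sd_r, B=1000, seed=0, names=None):
    """BootstrapResult whose draws realize the requested moments exactly."""
    rng = np.random.default_rng(seed)
    R = len(mu_s)
    zs = rng.normal(size=(B, R))
    zs = (zs - zs.mean(0)) / zs.std(0, ddof=1)
    zr = rng.normal(size=(B, R))
    zr = (zr - zr.mean(0)) / zr.std(0, ddof=1)
    names = names or tuple(f"r{i}" for i in range(R))
    return BootstrapResult(
        group="study", reference="ref", region_names=tuple(names),
        B=B, m_sub=100, seed=seed,
        betas_study=np.asarray(mu_s) + zs * np.asarray(sd_s),
        betas_reference=np.asarray(mu_r) + zr * np.asarray(sd_r),
    )


class TestCompareRegions:
    def test_identical_distributions_all_zero(self):
        res = _boot([0.1, -0.2], [0.2, 0.2], [0.1, -0.2], [0.2, 0.2])
        comp = compare_regions(res)
        assert (comp["m"] == 0).all()

    def test_shifted_study_all_plus_one(self):
        res = _boot([-1.1, -1.2], [0.01, 0.01], [-0.1, -0.2], [0.01, 0.01])
        comp = compare_regions(res)
        assert (comp["m"] == 1).all()
        assert (comp["p"] < 0.05 / 148).all()

    def test_reported_comparison_row(self):
        """A study slope of -0.61 (sd 0.16) against -0.05 (sd 0.12) over
        1000 realizations is strongly significant with m = +1."""
        res = _boot([-0.61], [0.16], [-0.05], [0.12])
        comp = compare_regions(res)
        assert round(float(comp.loc[0, "t"])) == -89
        assert comp.loc[0, "m"] == 1

    def test_uses_b_as_sample_size(self):
        res = _boot([0.41], [0.29], [-0.37], [0.18], B=1000)
        comp = compare_regions(res)
        t, df, _ = welch_t(0.41, 0.29, 1000, -0.37, 0.18, 1000)
        assert comp.loc[0, "t"] == pytest.approx(t, abs=1e-9)
        assert comp.loc[0, "df"] == pytest.approx(df, rel=1e-6)


class TestKappa:
    def _weights(self, registry, values=None):
        v = np.full(148, 1 / 148) if values is None else values
        return RegionWeights(pd.Series(v, index=registry.names))

    def _comparisons(self, registry, m):
        return pd.DataFrame({"region": registry.names, "m": m})

    def test_all_plus_one_saturates(self, registry):
        ks = kappa(self._comparisons(registry, np.ones(148, dtype=int)),
                   self._weights(registry))
        assert ks.kappa == pytest.approx(100.0)
        assert ks.frac_faster_study == pytest.approx(1.0)

    def test_all_zero(self, registry):
        ks = kappa(self._comparisons(registry, np.zeros(148, dtype=int)),
                   self._weights(registry))
        assert ks.kappa == 0.0
        assert ks.frac_no_difference == pytest.approx(1.0)

    def test_directional_fraction_example(self, registry):
        """m = +1 on 82% of cortical weight and -1 on 12% gives kappa 70."""
        m = np.zeros(148, dtype=int)
        m[:100] = 1
        m[100:120] = -1
        w = np.empty(148)
        w[:100] = 0.82 / 100
        w[100:120] = 0.12 / 20
        w[120:] = 0.06 / 28
        ks = kappa(self._comparisons(registry, m), self._weights(registry, w))
        assert ks.kappa == pytest.approx(70.0, abs=1e-9)
        assert ks.frac_faster_study == pytest.approx(0.82)
        assert ks.frac_faster_reference == pytest.approx(0.12)

    def test_fraction_identity_and_bounds(self, registry):
        rng = np.random.default_rng(0)
        for _ in range(50):
            m = rng.integers(-1, 2, size=148)
            w = rng.dirichlet(np.ones(148))
            ks = kappa(self._comparisons(registry, m), self._weights(registry, w))
            assert -100.0 <= ks.kappa <= 100.0
            assert ks.kappa == pytest.approx(
                100.0 * (ks.frac_faster_study - ks.frac_faster_reference), abs=1e-9
            )
            total = ks.frac_faster_study + ks.frac_faster_reference + ks.frac_no_difference
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_brute_force_oracle(self, registry):
        """kappa equals an explicit per-region loop on random inputs."""
        rng = np.random.default_rng(99)
        for _ in range(200):
            m = rng.integers(-1, 2, size=148)
            w = rng.dirichlet(np.ones(148))
            ks = kappa(self._comparisons(registry, m), self._weights(registry, w))
            brute = 0.0
            for mi, wi in zip(m, w):
                brute += 100.0 * mi * wi
            assert ks.kappa == pytest.approx(brute, abs=1e-9)

    def test_per_hemisphere_variants(self, registry):
        m = np.ones(148, dtype=int)
        ks = kappa(self._comparisons(registry, m), self._weights(registry), registry)
        # all +1: renormalized hemispheric kappa is 100, raw halves sum to 100
        assert ks.per_hemisphere["left"]["renormalized"] == pytest.approx(100.0)
        raw_sum = ks.per_hemisphere["left"]["raw"] + ks.per_hemisphere["right"]["raw"]
        assert raw_sum == pytest.approx(ks.kappa)

    def test_bad_weights_rejected(self, registry):
        comp = self._comparisons(registry, np.zeros(148, dtype=int)).iloc[:10].copy()
        w = self._weights(registry)
        comp.loc[0, "region"] = "not_a_region"
        with pytest.raises(ComparisonError, match="not_a_region"):
            kappa(comp, w)


class TestLaterality:
    def test_mirror_symmetric_slopes_have_equal_counts(self, registry):
        betas = np.concatenate([np.linspace(-1, 1, 74)] * 2)
        tr = pd.DataFrame({"region": registry.names, "beta": betas})
        out = laterality_summary(tr, registry)
        assert out["left"]["n_negative"] == out["right"]["n_negative"]
        assert out["left"]["n_positive"] == out["right"]["n_positive"]

    def test_constructed_left_count(self, registry):
        """A fixture with 55 of 74 negative left structures reports 55."""
        betas = np.zeros(148)
        left_names = registry.hemisphere_names("left")
        betas[:55] = -1.0  # first 55 left structures negative
        betas[74:] = 1.0  # right hemisphere all positive
        tr = pd.DataFrame({"region": registry.names, "beta": betas})
        out = laterality_summary(tr, registry)
        assert out["left"]["n_negative"] == 55
        assert out["right"]["n_negative"] == 0
        assert out["right"]["n_positive"] == 74
        assert len(left_names) == 74

    def test_all_negative_on_left_only(self, registry):
        betas = np.concatenate([np.full(74, -1.0), np.full(74, 1.0)])
        tr = pd.DataFrame({"region": registry.names, "beta": betas})
        out = laterality_summary(tr, registry)
        assert out["left"]["n_negative"] == 74
        assert out["right"]["n_negative"] == 0
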
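import numpy as np
import pandas as pd
import pytest

from braintrends.normalization import anchor_by_group
from braintrends.synthetic import (
    ConfigError,
    SynthConfig,
    generate_cohort,
    generate_mediation_dataset,
    generate_validation_pairs,
)
from braintrends.trends import fit_region_trends

TINY = {("study_A", "M"): 60, ("reference", "M"): 80}


class TestGenerateCohort:
    def test_deterministic_given_seed(self, registry):
        cfg = SynthConfig(seed=11, n_per_group=TINY)
        a = generate_cohort(cfg, registry)
        b = generate_cohort(cfg, registry)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_different_seed_differs(self, registry):
        a = generate_cohort(SynthConfig(seed=11, n_per_group=TINY), registry)
        b = generate_cohort(SynthConfig(seed=12, n_per_group=TINY), registry)
        assert not np.allclose(a["icv"], b["icv"])

    def test_zero_slope_zero_noise_gives_flat_trends(self, registry):
        slopes = {("study_A", "M"): np.zeros(148), ("reference", "M"): np.zeros(148)}
        cfg = SynthConfig(seed=5, n_per_group=TINY, noise_sd=0.0, true_slopes=slopes)
        cohort = generate_cohort(cfg, registry)
        anchored = anchor_by_group(cohort, registry)
        tr = fit_region_trends(anchored[("study_A", "M")])
        np.testing.assert_allclose(tr["beta"], 0.0, atol=1e-9)
        np.testing.assert_allclose(
            anchored[("study_A", "M")].vpp.to_numpy(), 100.0, atol=1e-8
        )

    def test_ages_within_range_and_volumes_valid(self, small_cohort, small_config):
        lo, hi = small_config.age_range
        assert small_cohort["age"].between(lo, hi).all()
        assert (small_cohort["icv"] > 0).all()
        vol_cols = [c for c in small_cohort.columns if c.startswith(("lh_", "rh_"))]
        assert (small_cohort[vol_cols] >= 0).all().all()
        assert small_cohort["subject_id"].is_unique

    def test_age_marginals_uniform(self, small_cohort, small_config):
        """Empirical age mean within 3 standard errors of the uniform mean."""
        lo, hi = small_config.age_range
        ages = small_cohort.loc[small_cohort["population"] == "reference", "age"]
        mean_expected = (lo + hi) / 2
        se = (hi - lo) / np.sqrt(12 * len(ages))
        assert abs(ages.mean() - mean_expected) < 3 * se

    def test_truncnorm_ages_match_moments(self, registry):
        cfg = SynthConfig(
            seed=2, n_per_group={("reference", "M"): 2000},
            age_distribution="truncnorm",
        )
        ages = generate_cohort(cfg, registry)["age"]
        assert ages.between(*cfg.age_range).all()
        assert ages.mean() == pytest.approx(61.6, abs=1.0)  # truncation pulls above 60.2

    def test_slope_recovery_in_fitted_trends(self, small_cohort, small_config, registry):
        """Fitted per-region slopes track the generative ones closely."""
        anchored = anchor_by_group(small_cohort, registry)
        tr = fit_region_trends(anchored[("reference", "M")]).set_index("region")
        truth = dict(zip(registry.names, small_config.slopes(registry)[("reference", "M")]))
        err = np.array([tr.loc[n, "beta"] - truth[n] for n in registry.names])
        assert np.abs(err).mean() < 0.05  # noise 5%, n=400

    def test_invalid_config_rejected(self, registry):
        with pytest.raises(ConfigError):
            generate_cohort(SynthConfig(age_range=(80, 50), n_per_group=TINY), registry)
        with pytest.raises(ConfigError):
            generate_cohort(SynthConfig(noise_sd=-1, n_per_group=TINY), registry)
        with pytest.raises(ConfigError):
            SynthConfig(region_shares=np.ones(148), n_per_group=TINY).validate(registry)


class TestValidationPairs:
    def test_zero_offset_gives_identical_modalities(self, registry):
        cfg = SynthConfig(seed=3, modality_offset=(0.0, 0.0), n_per_group=TINY)
        pairs = generate_validation_pairs(cfg, 5, registry)
        np.testing.assert_allclose(pairs["v_ct"], pairs["v_mri"], rtol=1e-12)

    def test_deterministic_and_well_formed(self, registry):
        cfg = SynthConfig(seed=4, n_per_group=TINY)
        a = generate_validation_pairs(cfg, 13, registry)
        b = generate_validation_pairs(cfg, 13, registry)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == 13 * 148
        assert not a.duplicated(subset=["subject_id", "region"]).any()
        assert (a[["v_ct", "v_mri"]] > 0).all().all()

    def test_uniform_offset_shifts_every_region(self, registry):
        cfg = SynthConfig(seed=4, modality_offset=(0.025, 0.0), n_per_group=TINY)
        pairs = generate_validation_pairs(cfg, 13, registry)
        ratio = pairs["v_ct"] / pairs["v_mri"]
        np.testing.assert_allclose(ratio, 1.025, rtol=1e-12)

    def test_requires_subjects(self, registry):
        with pytest.raises(ConfigError):
            generate_validation_pairs(SynthConfig(n_per_group=TINY), 0, registry)


class TestMediationDataset:
    def test_generative_moments(self):
        df = generate_mediation_dataset(5000, seed=9)
        # mediator ~ 0.5 * age + N(0,1): regression slope near 0.5
        slope = np.polyfit(df["age"], df["mediator"], 1)[0]
        assert slope == pytest.approx(0.5, abs=0.05)

    def test_deterministic(self):
        a = generate_mediation_dataset(50, seed=1)
        b = generate_mediation_dataset(50, seed=1)
        pd.testing.assert_frame_equal(a, b)
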
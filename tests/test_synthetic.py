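"""Determinism, validity and statistical calibration of the generators."""
import math

import numpy as np
import pytest

from zebrascreen.imaging import dice, tumor_area
from zebrascreen.qpcr import fit_standard_curve, standards_from_table
from zebrascreen.synthetic import (
    CohortSimParams,
    ImageSimParams,
    QpcrSimParams,
    SITE_PRESETS,
    simulate_cohort,
    simulate_image,
    simulate_mask_pair,
    simulate_qpcr,
)


class TestCohortGenerator:
    def test_same_seed_gives_identical_cohorts(self):
        a, truth_a = simulate_cohort(CohortSimParams(), seed=7)
        b, truth_b = simulate_cohort(CohortSimParams(), seed=7)
        assert a == b
        assert truth_a.equals(truth_b)

    def test_different_seeds_differ(self):
        a, _ = simulate_cohort(CohortSimParams(), seed=1)
        b, _ = simulate_cohort(CohortSimParams(), seed=2)
        assert a != b

    def test_generated_cohorts_pass_validation(self):
        for seed in range(5):
            cohort, _ = simulate_cohort(
                CohortSimParams(daily_mortality=0.3, final_dpi=5), seed=seed
            )
            cohort.validate()  # raises on any invariant violation

    def test_degenerate_parameters_give_boundary_engraftment(self):
        params = CohortSimParams(
            growth_factor=1.0,
            growth_log_sd=0.0,
            noise_sd=0.0,
            daily_mortality=0.0,
            misinjection_fraction=0.0,
        )
        cohort, _ = simulate_cohort(params, seed=0)
        for rec in cohort.records:
            assert rec.ta_by_dpi[params.final_dpi] == rec.ta_by_dpi[1]

    def test_mean_rtg_matches_closed_form(self):
        # three days at g = 1.4/day: expected RTG = 100*(1.4^3 - 1) = 174.4%
        params = CohortSimParams(
            n_per_group=500,
            n_replicates=1,
            groups=("vehicle",),
            growth_factor=1.4,
            growth_log_sd=0.0,
            noise_sd=0.10,
            daily_mortality=0.0,
            misinjection_fraction=0.0,
            final_dpi=4,
        )
        cohort, _ = simulate_cohort(params, seed=0)
        rtgs = [
            100 * (r.ta_by_dpi[4] - r.ta_by_dpi[1]) / r.ta_by_dpi[1]
            for r in cohort.records
        ]
        assert np.mean(rtgs) == pytest.approx(174.4, rel=0.05)

    def test_baseline_moments_match_design(self):
        params = CohortSimParams(
            n_per_group=1000,
            n_replicates=1,
            groups=("vehicle",),
            misinjection_fraction=0.0,
            daily_mortality=0.0,
        )
        cohort, _ = simulate_cohort(params, seed=4)
        logs = np.log([r.ta_by_dpi[1] for r in cohort.records])
        n = len(logs)
        se_mean = params.baseline_log_sd / math.sqrt(n)
        se_sd = params.baseline_log_sd / math.sqrt(2 * n)
        assert abs(logs.mean() - params.baseline_log_mean) < 3 * se_mean
        assert abs(logs.std(ddof=1) - params.baseline_log_sd) < 3 * se_sd

    def test_truth_table_matches_cohort(self):
        cohort, truth = simulate_cohort(CohortSimParams(), seed=9)
        assert len(truth) == len(cohort)
        assert set(truth.columns) >= {
            "embryo_id",
            "misinjected",
            "daily_growth_factor",
            "death_dpi",
        }
        dead = truth[truth["death_dpi"].notna()]
        by_id = {r.embryo_id: r for r in cohort.records}
        for row in dead.itertuples():
            assert not by_id[row.embryo_id].is_alive(cohort.final_dpi)

    def test_site_presets_construct(self):
        for site in SITE_PRESETS:
            params = CohortSimParams.for_site(site)
            assert params.site == site
        with pytest.raises(ValueError):
            CohortSimParams.for_site("fin")

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(CohortSimParams(daily_mortality=1.5))
        with pytest.raises(ValueError):
            simulate_cohort(CohortSimParams(growth_factor=-1))
        with pytest.raises(ValueError):
            simulate_cohort(CohortSimParams(misinjection_factor=1.0))


class TestQpcrGenerator:
    def test_zero_noise_recovers_truth_exactly(self):
        params = QpcrSimParams(noise_sd=0.0)
        curve = fit_standard_curve(
            standards_from_table(simulate_qpcr(params, seed=0))
        )
        assert curve.slope == pytest.approx(params.slope, rel=1e-12)
        assert curve.intercept == pytest.approx(params.intercept, rel=1e-12)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_layout_matches_design(self):
        df = simulate_qpcr(QpcrSimParams(replicates=3), seed=0)
        standards = df[df["role"] == "standard"]
        assert sorted(standards["known_cells"].unique()) == [
            500.0, 2000.0, 8000.0, 32000.0, 128000.0,
        ]
        assert (standards.groupby("sample_id").size() == 3).all()
        neg = df[df["role"] == "negative"]
        assert len(neg) == 1
        assert neg["known_cells"].iloc[0] == 0.0 and neg["ct"].isna().all()

    def test_determinism(self):
        a = simulate_qpcr(QpcrSimParams(), seed=3)
        b = simulate_qpcr(QpcrSimParams(), seed=3)
        assert a.equals(b)

    def test_slope_recovery_across_seeds(self):
        params = QpcrSimParams(noise_sd=0.2, replicates=3)
        ok = 0
        for seed in range(100):
            curve = fit_standard_curve(
                standards_from_table(simulate_qpcr(params, seed=seed))
            )
            ok += abs(curve.slope - params.slope) / abs(params.slope) <= 0.05
        assert ok >= 95


class TestImageGenerator:
    def test_noise_free_blob_area_is_exact(self):
        params = ImageSimParams(background_noise_sd=0.0, blob_noise_sd=0.0)
        sample = simulate_image(params, seed=0)
        assert tumor_area(sample.image, params.threshold) == sample.true_area

    def test_noisy_background_contributes_nothing(self):
        params = ImageSimParams(background_noise_sd=800.0, blob_noise_sd=2000.0)
        sample = simulate_image(params, seed=5)
        assert tumor_area(sample.image, params.threshold) == sample.true_area

    def test_determinism(self):
        a = simulate_image(ImageSimParams(), seed=2)
        b = simulate_image(ImageSimParams(), seed=2)
        assert np.array_equal(a.image, b.image) and a.true_area == b.true_area

    def test_blob_must_fit_in_frame(self):
        with pytest.raises(ValueError, match="fit"):
            simulate_image(ImageSimParams(shape=(32, 32), blob_radius=20))

    def test_background_must_sit_below_threshold(self):
        with pytest.raises(ValueError):
            simulate_image(ImageSimParams(background=8000.0))


class TestMaskPairGenerator:
    def test_target_one_gives_identical_masks(self):
        a, b = simulate_mask_pair((64, 128), 1.0, seed=0)
        assert np.array_equal(a, b) and a.any()

    def test_target_zero_gives_disjoint_masks(self):
        a, b = simulate_mask_pair((64, 128), 0.0, seed=0)
        assert not (a & b).any() and a.any() and b.any()

    @pytest.mark.parametrize("target", [0.2, 0.4, 0.60, 0.81, 0.95])
    def test_targets_reached_within_tolerance(self, target):
        a, b = simulate_mask_pair((128, 256), target, seed=1)
        assert dice(a, b) == pytest.approx(target, abs=0.02)

    def test_determinism(self):
        a1, b1 = simulate_mask_pair((64, 128), 0.7, seed=4)
        a2, b2 = simulate_mask_pair((64, 128), 0.7, seed=4)
        assert np.array_equal(a1, a2) and np.array_equal(b1, b2)

    def test_unreachable_target_errors(self):
        with pytest.raises(ValueError):
            simulate_mask_pair((20, 26), 0.0, seed=0, radius=8)
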
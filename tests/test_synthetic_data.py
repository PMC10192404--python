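"""Ground-truth cohort generator: determinism, calibration, recovery."""

import numpy as np
import pytest

from picturesort.adult_reference_measures import score_adult_survey
from picturesort.diet_scoring import score_cohort
from picturesort.psychosocial_scoring import cronbach_alpha, default_scales
from picturesort.synthetic_data import (
    DEFAULT_LIKERT_THRESHOLDS,
    SyntheticConfig,
    SyntheticConfigError,
    analytic_alpha,
    calibrate_latent_correlation,
    discretized_correlation,
    generate_cohort,
    one_factor_likert,
)
from picturesort.validity import pearson_with_p


class TestAnalyticAlpha:
    @pytest.mark.parametrize(
        "k,rbar,expected",
        [(3, 0.5, 0.75), (4, 0.0, 0.0), (2, 1.0 / 3.0, 0.5)],
    )
    def test_closed_form(self, k, rbar, expected):
        assert analytic_alpha(k, rbar) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(SyntheticConfigError):
            analytic_alpha(1, 0.5)
        with pytest.raises(SyntheticConfigError):
            analytic_alpha(3, 1.0)


class TestConfig:
    def test_errors_name_offending_field(self):
        with pytest.raises(SyntheticConfigError, match="latent_sd"):
            SyntheticConfig(latent_sd=-1)
        with pytest.raises(SyntheticConfigError, match="target_interitem_r"):
            SyntheticConfig(target_interitem_r=1.0)
        with pytest.raises(SyntheticConfigError, match="rho_index_reference"):
            SyntheticConfig(rho_index_reference=1.5)


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        cfg = SyntheticConfig(n_children=25, n_adults=18, seed=7)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        for name in ("responses", "likert", "adult_survey", "retest"):
            assert getattr(a, name).to_csv() == getattr(b, name).to_csv()

    def test_different_seed_differs(self):
        a = generate_cohort(SyntheticConfig(seed=1))
        b = generate_cohort(SyntheticConfig(seed=2))
        assert not a.responses.equals(b.responses)


class TestCohortStructure:
    def test_labels_valid_for_dialect(self, cohort, dialects):
        for role, d in dialects.items():
            sub = cohort.responses[cohort.responses.role == role]
            assert set(sub.response) <= set(d.categories)

    def test_children_never_see_alcohol_cards(self, cohort, registry):
        alcohol = {it.item_id for it in registry if it.is_alcohol}
        child = cohort.responses[cohort.responses.role == "child"]
        assert not (set(child.item_id) & alcohol)

    def test_completion_counts_match_study_design(self, cohort):
        resp = cohort.responses
        for role, nb, nf in (("child", 25, 18), ("adult", 18, 12)):
            sub = resp[resp.role == role]
            assert sub[sub.timepoint == "baseline"].subject_id.nunique() == nb
            assert sub[sub.timepoint == "followup"].subject_id.nunique() == nf

    def test_every_category_at_least_5pct_at_defaults(self):
        c = generate_cohort(
            SyntheticConfig(n_children=2000, n_adults=2000, seed=2)
        )
        for role, k in (("child", 4), ("adult", 5)):
            freq = (
                c.responses[c.responses.role == role]
                .response.value_counts(normalize=True)
            )
            assert len(freq) == k
            assert (freq >= 0.05).all()

    def test_likert_values_in_range(self, cohort):
        assert cohort.likert.response.between(1, 4).all()

    def test_noise_free_retest_reproduces_baseline(self):
        c = generate_cohort(
            SyntheticConfig(seed=7, sigma_within=0.0,
                            completion_children=1.0, completion_adults=1.0)
        )
        piv = c.responses.pivot_table(
            index=["subject_id", "item_id"], columns="timepoint",
            values="response", aggfunc="first",
        )
        assert (piv["baseline"] == piv["followup"]).all()
        ix = score_cohort(c.responses)
        wide = ix.pivot_table(index="subject_id", columns="timepoint",
                              values="modified_ahei_total")
        assert np.allclose(wide["baseline"], wide["followup"])


class TestCalibration:
    def test_discretized_correlation_monotone(self):
        r1 = discretized_correlation(0.3, DEFAULT_LIKERT_THRESHOLDS)
        r2 = discretized_correlation(0.6, DEFAULT_LIKERT_THRESHOLDS)
        assert 0 < r1 < r2 < 0.6  # attenuation

    def test_calibration_inverts_attenuation(self):
        for target in (0.2, 0.3, 0.5):
            rho = calibrate_latent_correlation(
                target, DEFAULT_LIKERT_THRESHOLDS
            )
            assert rho > target  # latent must exceed observed
            assert discretized_correlation(
                rho, DEFAULT_LIKERT_THRESHOLDS
            ) == pytest.approx(target, abs=1e-4)

    def test_observed_interitem_r_matches_target_empirically(self):
        rng = np.random.default_rng(41)
        m = one_factor_likert(100000, 2, 0.3, rng)
        r = np.corrcoef(m[:, 0], m[:, 1])[0, 1]
        assert r == pytest.approx(0.3, abs=0.01)


class TestParameterRecovery:
    def test_alpha_recovered_through_full_scoring_path(self):
        """Scored discretized Likert tables reproduce the analytic alpha."""
        c = generate_cohort(SyntheticConfig(n_children=1000, n_adults=0,
                                            seed=9))
        base = c.likert[c.likert.timepoint == "baseline"]
        wide = base.pivot_table(index="subject_id", columns="item_id",
                                values="response", aggfunc="first")
        for scale_id in ("se_fv_5", "se_fv_8", "tendency_fv"):
            sd = default_scales()[scale_id]
            alpha = cronbach_alpha(wide[list(sd.item_ids)].to_numpy(float))
            assert alpha == pytest.approx(
                c.ground_truth["analytic_alphas"][scale_id], abs=0.05
            )

    def test_rho_recovered_from_reference_measures(self):
        """FFQ and obesogenic references carry the programmed +/- rho with
        latent diet quality."""
        c = generate_cohort(
            SyntheticConfig(n_children=0, n_adults=10000, seed=5,
                            completion_adults=1.0)
        )
        ref = score_adult_survey(c.adult_survey)
        ref = ref[ref.timepoint == "baseline"].set_index("subject_id")
        q = (
            c.retest[c.retest.timepoint == "baseline"]
            .set_index("subject_id")["diet_quality"]
        )
        ref = ref.loc[q.index]
        rho = c.ground_truth["rho_index_reference"]
        assert pearson_with_p(ref["ffq_fv"], q).r == pytest.approx(
            rho, abs=0.05
        )
        assert pearson_with_p(ref["obesogenic_index"], q).r == pytest.approx(
            -rho, abs=0.05
        )

    def test_sigma_within_recovered_from_retest(self):
        from picturesort.reliability import bland_altman

        c = generate_cohort(
            SyntheticConfig(n_children=5000, n_adults=0, seed=3,
                            completion_children=1.0)
        )
        rt = c.retest.pivot(index="subject_id", columns="timepoint",
                            values="diet_quality")
        res = bland_altman(rt["baseline"], rt["followup"])
        assert res.sd_diff / np.sqrt(2) == pytest.approx(
            c.ground_truth["sigma_within"], rel=0.05
        )

    def test_ratio_index_degrades_less_under_reporting_bias(self):
        """The healthy-to-total ratio is designed to dampen per-subject
        over/under-reporting: its correlation with latent diet quality
        degrades less than raw frequency totals when the reporting-bias
        SD grows."""

        def corr_with_latent(bias_sd):
            c = generate_cohort(
                SyntheticConfig(n_children=3000, n_adults=0, seed=11,
                                reporting_bias_sd=bias_sd,
                                completion_children=1.0)
            )
            ix = score_cohort(c.responses)
            ixb = ix[ix.timepoint == "baseline"].set_index("subject_id")
            gt = (
                c.ground_truth["subjects"]
                .set_index("subject_id")["latent"]
                .loc[ixb.index]
            )
            return {
                col: pearson_with_p(ixb[col], gt).r
                for col in ("ratio_healthy_total", "healthy_freq",
                            "total_freq")
            }

        low, high = corr_with_latent(0.1), corr_with_latent(1.5)
        deg_ratio = low["ratio_healthy_total"] - high["ratio_healthy_total"]
        deg_healthy = low["healthy_freq"] - high["healthy_freq"]
        deg_total = low["total_freq"] - high["total_freq"]
        assert deg_ratio < deg_healthy
        assert deg_ratio < deg_total

    def test_write_emits_consumable_files(self, tmp_path):
        c = generate_cohort(SyntheticConfig(seed=7))
        paths = c.write(tmp_path)
        from picturesort.food_registry import load_response_table

        frame, report = load_response_table(paths["responses"])
        assert report.ok and len(frame) == len(c.responses)
        assert paths["ground_truth"].exists()
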
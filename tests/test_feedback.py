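"""Feedback components: BAC model, spend, suppression, bands, rendering."""

import pytest
from hypothesis import given, settings, strategies as st

from esbi.errors import ConfigError, ValidationError
from esbi.feedback import (
    BacParams,
    age_group,
    audit_band,
    build_feedback,
    compare_to_guideline_and_norm,
    default_feedback_config,
    estimate_monthly_spend,
    estimate_peak_bac,
    ldq_band,
    render_feedback,
)
from esbi.instruments import EpisodeReport, score_record


class TestPeakBac:
    def test_zero_drinks_is_zero_regardless(self):
        assert estimate_peak_bac(EpisodeReport(0.0, 5.0, 80.0), "male") == 0.0
        assert estimate_peak_bac(EpisodeReport(0.0, 0.0, 1.0), "female") == 0.0

    def test_widmark_closed_form_hand_value(self):
        # 10 drinks x 10 g / (80 kg x 0.68 x 10) - 0.015/h x 4 h
        bac = estimate_peak_bac(EpisodeReport(10.0, 4.0, 80.0), "male")
        assert bac == pytest.approx(100 / 544 - 0.06, abs=1e-12)

    def test_long_duration_clamps_to_exact_zero(self):
        assert estimate_peak_bac(EpisodeReport(1.0, 24.0, 80.0), "male") == 0.0

    @pytest.mark.parametrize(
        "episode",
        [EpisodeReport(5.0, 2.0, 0.0), EpisodeReport(5.0, 0.0, 80.0), EpisodeReport(-1.0, 2.0, 80.0)],
    )
    def test_invalid_inputs_rejected(self, episode):
        with pytest.raises(ValidationError):
            estimate_peak_bac(episode, "male")

    @settings(derandomize=True, max_examples=200)
    @given(
        drinks=st.floats(0.5, 30),
        hours=st.floats(0.5, 24),
        weight=st.floats(45, 150),
        gender=st.sampled_from(["male", "female"]),
    )
    def test_monotone_in_drinks_weight_duration_and_nonnegative(self, drinks, hours, weight, gender):
        bac = estimate_peak_bac(EpisodeReport(drinks, hours, weight), gender)
        assert bac >= 0.0
        assert estimate_peak_bac(EpisodeReport(drinks + 1, hours, weight), gender) >= bac
        assert estimate_peak_bac(EpisodeReport(drinks, hours + 1, weight), gender) <= bac
        assert estimate_peak_bac(EpisodeReport(drinks, hours, weight + 5), gender) <= bac

    def test_female_ratio_gives_higher_bac(self):
        ep = EpisodeReport(6.0, 2.0, 70.0)
        assert estimate_peak_bac(ep, "female") > estimate_peak_bac(ep, "male")


class TestMonthlySpend:
    def test_never_drinking_spends_nothing(self):
        assert estimate_monthly_spend(0, 3, 5.0) == 0.0

    def test_documented_midpoint_arithmetic(self):
        cfg = default_feedback_config()
        spend = estimate_monthly_spend(2, 1, 5.0)
        assert spend == cfg.frequency_days_per_month[2] * cfg.typical_drinks_midpoint[1] * 5.0

    @settings(derandomize=True, max_examples=50)
    @given(f=st.integers(0, 4), t=st.integers(0, 4), price=st.floats(0.5, 50))
    def test_linear_in_price_and_zero_iff_never(self, f, t, price):
        spend = estimate_monthly_spend(f, t, price)
        assert estimate_monthly_spend(f, t, 2 * price) == pytest.approx(2 * spend)
        assert (spend == 0) == (f == 0)

    def test_unmapped_band_is_config_error(self):
        with pytest.raises(ConfigError):
            estimate_monthly_spend(9, 0, 5.0)


class TestSuppression:
    @pytest.mark.parametrize(
        "own,guideline,status",
        [(2, 4, "suppressed"), (4, 4, "shown"), (9, 4, "shown"), (3.99, 4, "suppressed")],
    )
    def test_strictly_below_guideline_suppresses(self, own, guideline, status):
        assert compare_to_guideline_and_norm(own, guideline, 5).status == status

    def test_rule_holds_over_exhaustive_grid(self):
        for own10 in range(0, 121):  # 0 to 12 drinks in 0.1 steps
            for guideline in (2, 4, 14):
                cmp = compare_to_guideline_and_norm(own10 / 10, guideline, 6.0)
                assert (cmp.status == "suppressed") == (own10 / 10 < guideline)

    def test_values_preserved_in_output(self):
        cmp = compare_to_guideline_and_norm(9, 4, 5)
        assert (cmp.own, cmp.guideline, cmp.norm) == (9, 4, 5)


class TestBands:
    def test_audit_bands_partition_0_to_40(self):
        labels = [audit_band(s).label for s in range(41)]
        assert labels[0] == labels[7] != labels[8]
        assert labels[15] != labels[16] and labels[19] != labels[20]
        assert labels[40] == "possible dependence"

    def test_ldq_bands_partition_0_to_30(self):
        # every score maps to exactly one band; boundaries at 0/1, 10/11, 20/21
        labels = [ldq_band(s).label for s in range(31)]
        assert labels[0] == "no dependence"
        assert labels[1] == labels[10] != labels[11]
        assert labels[20] != labels[21] and labels[30] == "high dependence"

    def test_out_of_domain_score_rejected(self):
        with pytest.raises(ValidationError):
            audit_band(41)


class TestBundleAndRendering:
    def test_heavy_drinker_bundle_is_internally_consistent(self, drinker_record):
        scores = score_record(drinker_record)
        bundle = build_feedback(drinker_record, scores)
        cfg = default_feedback_config()
        # recompute each component independently of build_feedback
        assert bundle.audit_score == scores.audit_total
        assert bundle.audit_band == audit_band(scores.audit_total, cfg)
        assert bundle.peak_bac == estimate_peak_bac(drinker_record.episode, "male", cfg.bac)
        assert bundle.monthly_spend == estimate_monthly_spend(
            drinker_record.audit_items[0], drinker_record.audit_items[1], cfg.price_per_drink, cfg
        )
        assert bundle.ldq_band == ldq_band(scores.ldq_total, cfg)
        # own typical occasion (item 2 index 2 -> 5.5 drinks) exceeds the limit
        assert bundle.episodic_comparison.status == "shown"

    def test_low_drinker_suppresses_both_comparisons(self, drinker_record):
        drinker_record.audit_items = (1, 0, 0, 0, 0, 0, 0, 0, 0, 0)
        bundle = build_feedback(drinker_record, score_record(drinker_record))
        assert bundle.episodic_comparison.status == "suppressed"
        assert bundle.weekly_comparison.status == "suppressed"

    def test_all_zero_audit_zero_episode_floor_case(self, drinker_record):
        drinker_record.audit_items = (0,) * 10
        drinker_record.ldq_items = (0,) * 10
        drinker_record.episode = EpisodeReport(0.0, 1.0, 80.0)
        bundle = build_feedback(drinker_record, score_record(drinker_record))
        assert bundle.peak_bac == 0.0 and bundle.monthly_spend == 0.0
        assert bundle.audit_band.lo == 0 and bundle.ldq_band.label == "no dependence"

    def test_missing_norm_cell_is_config_error(self, drinker_record):
        import dataclasses

        cfg = default_feedback_config()
        broken = dataclasses.replace(cfg, norms={k: v for k, v in cfg.norms.items() if k != ("male", "35-54")})
        with pytest.raises(ConfigError, match="male"):
            build_feedback(drinker_record, score_record(drinker_record), broken)

    @pytest.mark.parametrize("fmt", ["text", "html"])
    def test_rendering_is_deterministic_and_faithful(self, drinker_record, fmt):
        bundle = build_feedback(drinker_record, score_record(drinker_record))
        doc1 = render_feedback(bundle, fmt)
        doc2 = render_feedback(bundle, fmt)
        assert doc1 == doc2  # byte-identical
        assert bundle.audit_band.message in doc1  # message verbatim from config
        for page in default_feedback_config().info_pages:
            assert page.title in doc1

    def test_suppressed_norm_absent_from_rendering(self, drinker_record):
        drinker_record.audit_items = (1, 0, 0, 0, 0, 0, 0, 0, 0, 0)
        bundle = build_feedback(drinker_record, score_record(drinker_record))
        doc = render_feedback(bundle, "text")
        assert "Average for people your age" not in doc

    def test_unknown_format_rejected(self, drinker_record):
        bundle = build_feedback(drinker_record, score_record(drinker_record))
        with pytest.raises(ValidationError):
            render_feedback(bundle, "pdf")


def test_age_groups_cover_adult_range():
    assert age_group(18) == "18-34" and age_group(34) == "18-34"
    assert age_group(35) == "35-54" and age_group(54) == "35-54"
    assert age_group(55) == "55+" and age_group(90) == "55+"
    with pytest.raises(ValidationError):
        age_group(17)
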
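"""Feasibility summaries: published-flow counts, conservation, quantiles."""

import numpy as np
import pytest

from esbi.errors import ValidationError
from esbi.feasibility import (
    FlowEventRecord,
    acceptability_table,
    completion_rate,
    median_iqr,
    pct,
    proportion_endorsing,
    recruitment_summary,
    retention_rate,
    round_half_up,
    summarize,
    validate_flow_records,
)
from esbi.screening import ScreeningCategory


class TestRecruitmentSummary:
    def test_published_flow_counts_reproduce_printed_percentages(self, fixture_records):
        s = recruitment_summary(fixture_records)
        assert s["approached"] == 172
        assert s["consented"] == {"count": 108, "denominator": 172, "pct": 62.8}
        assert s["refused"]["pct"] == 36.0
        assert s["ineligible_at_approach"]["pct"] == 1.2
        assert s["ineligible_after_consent"]["pct"] == 1.9
        assert s["eligible_consenting"] == 106
        mix = s["screening"]
        assert mix["noncompleted"] == {"count": 7, "denominator": 106, "pct": 6.6}
        assert mix["nondrinker_12m"]["pct"] == 14.2
        assert mix["negative"]["pct"] == 40.6
        assert mix["hazardous_harmful"]["pct"] == 31.1
        assert mix["possible_dependence"]["pct"] == 7.5
        assert s["unhealthy_use"] == {"count": 41, "denominator": 106, "pct": 38.7}

    def test_single_completer_is_100_percent_everywhere(self):
        rec = FlowEventRecord(
            participant_id="solo",
            consented=True,
            completed_esbi=True,
            category=ScreeningCategory.HAZARDOUS_HARMFUL,
            invited_followup=True,
            completed_followup=True,
        )
        s = recruitment_summary([rec])
        assert s["consented"]["pct"] == 100.0
        assert s["screening"]["hazardous_harmful"]["pct"] == 100.0
        assert completion_rate([rec])["completed"]["pct"] == 100.0
        assert retention_rate([rec])["pct"] == 100

    def test_empty_input_defines_no_percentages(self):
        s = recruitment_summary([])
        assert s["approached"] == 0
        assert s["consented"]["pct"] is None
        assert s["unhealthy_use"]["pct"] is None

    def test_invalid_records_rejected_naming_offenders(self):
        bad = FlowEventRecord(participant_id="bad1", consented=False, completed_esbi=True)
        with pytest.raises(ValidationError, match="bad1"):
            recruitment_summary([bad])

    def test_flow_conservation_on_fixture(self, fixture_records):
        s = recruitment_summary(fixture_records)
        assert (
            s["consented"]["count"] + s["refused"]["count"] + s["ineligible_at_approach"]["count"]
            == s["approached"]
        )
        assert s["consented"]["count"] - s["ineligible_after_consent"]["count"] == s["eligible_consenting"]
        assert sum(d["count"] for d in s["screening"].values()) == s["eligible_consenting"]


class TestCompletionAndRetention:
    def test_published_completion_and_reason_split(self, fixture_records):
        c = completion_rate(fixture_records)
        assert c["completed"] == {"count": 99, "denominator": 106, "pct": 93.4}
        assert c["reasons"]["technical"] == {"count": 3, "denominator": 7, "pct": 43}
        assert c["reasons"]["called_for_appointment"] == {"count": 4, "denominator": 7, "pct": 57}

    def test_all_completers_no_reason_table(self):
        recs = [
            FlowEventRecord(participant_id=f"c{i}", consented=True, completed_esbi=True,
                            category=ScreeningCategory.NEGATIVE)
            for i in range(5)
        ]
        c = completion_rate(recs)
        assert c["completed"]["pct"] == 100.0 and c["reasons"] == {}

    def test_randomized_records_match_recount_oracle(self, small_cohort):
        _, flow = small_cohort
        c = completion_rate(flow)
        eligible = [r for r in flow if r.consented and r.eligible]
        done = sum(r.completed_esbi for r in eligible)
        assert c["completed"]["count"] == done
        assert c["completed"]["denominator"] == len(eligible)
        assert c["completed"]["pct"] == round_half_up(100 * done / len(eligible), 1)

    def test_published_retention_overall_and_subgroup(self, fixture_records):
        assert retention_rate(fixture_records)["pct"] == 75
        sub = retention_rate(
            fixture_records, lambda r: r.category is ScreeningCategory.HAZARDOUS_HARMFUL
        )
        assert sub == {"count": 22, "denominator": 30, "pct": 73, "undefined": False}

    def test_empty_subgroup_is_undefined_not_zero(self, fixture_records):
        out = retention_rate(fixture_records, lambda r: r.category is ScreeningCategory.NONDRINKER_12M)
        assert out["undefined"] is True and out["pct"] is None


class TestAcceptability:
    def test_useful_feedback_column_matches_published_crosstab(self, fixture_records):
        df = acceptability_table(fixture_records)
        useful = df[df["question"] == "feedback_useful"]
        assert list(useful["hazardous_harmful_n"]) == [6, 11, 10, 5]
        assert list(useful["negative_n"]) == [11, 7, 13, 12]
        assert list(useful["all_drinkers_n"]) == [21, 20, 25, 17]
        assert df.attrs["column_totals"]["hazardous_harmful"] == 33
        # published column percentages out of n=33
        assert list(useful["hazardous_harmful_pct"]) == [18, 33, 30, 15]

    def test_abstract_82_percent_very_quite_somewhat(self, fixture_records):
        out = proportion_endorsing(
            fixture_records, "feedback_useful", [0, 1, 2], ScreeningCategory.HAZARDOUS_HARMFUL
        )
        assert out == {"count": 27, "denominator": 33, "pct": 82}

    def test_single_record_is_a_100_percent_cell(self):
        rec = FlowEventRecord(
            participant_id="one",
            consented=True,
            completed_esbi=True,
            category=ScreeningCategory.NEGATIVE,
            acceptability={"feedback_useful": 2, "appeal": 1},
        )
        df = acceptability_table([rec])
        cell = df[(df["question"] == "feedback_useful") & (df["option"] == "Somewhat useful")]
        assert cell["negative_pct"].iloc[0] == 100

    def test_crosstab_marginals_equal_category_counts(self, small_cohort):
        _, flow = small_cohort
        df = acceptability_table(flow)
        totals = df.attrs["column_totals"]
        for cat in ("negative", "hazardous_harmful", "possible_dependence"):
            recount = sum(
                1 for r in flow if r.completed_esbi and r.category is not None and r.category.value == cat
            )
            assert totals[cat] == recount
        assert totals["all_drinkers"] == sum(
            totals[c] for c in ("negative", "hazardous_harmful", "possible_dependence")
        )


class TestMedianIqr:
    def test_degenerate_and_odd_lists(self):
        assert median_iqr([5]) == (5, 5, 5)
        assert median_iqr([1, 2, 3, 4, 5])[0] == 3

    def test_matches_sort_and_interpolate_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            vals = rng.integers(0, 40, size=rng.integers(2, 30)).astype(float)
            med, q25, q75 = median_iqr(vals)

            def oracle(q):
                # linear interpolation between order statistics
                s = np.sort(vals)
                h = (len(s) - 1) * q
                lo = int(np.floor(h))
                hi = min(lo + 1, len(s) - 1)
                return s[lo] + (h - lo) * (s[hi] - s[lo])

            assert med == pytest.approx(oracle(0.5))
            assert q25 == pytest.approx(oracle(0.25))
            assert q75 == pytest.approx(oracle(0.75))

    def test_empty_list_is_an_error(self):
        with pytest.raises(ValidationError):
            median_iqr([])


class TestRounding:
    @pytest.mark.parametrize(
        "x,d,expected",
        [(62.7906, 1, 62.8), (14.1509, 1, 14.2), (0.5, 0, 1.0), (2.5, 0, 3.0), (81.81, 0, 82.0)],
    )
    def test_half_up(self, x, d, expected):
        assert round_half_up(x, d) == expected

    def test_every_summary_percentage_recomputes_from_its_counts(self, fixture_records):
        s = summarize(fixture_records)

        def check(d, decimals):
            if d["pct"] is None:
                assert d["denominator"] == 0
            else:
                assert d["pct"] == pct(d["count"], d["denominator"], decimals).pct

        rec = s.recruitment
        for key in ("consented", "refused", "ineligible_at_approach", "ineligible_after_consent", "unhealthy_use"):
            check(rec[key], 1)
        for d in rec["screening"].values():
            check(d, 1)
        check(s.completion["completed"], 1)
        for d in s.completion["reasons"].values():
            check(d, 0)
        for d in (s.retention_overall, s.retention_hazardous_harmful):
            assert d["pct"] == pct(d["count"], d["denominator"], 0).pct


def test_summary_tables_render(fixture_records):
    from esbi.feasibility import format_summary_tables

    text = format_summary_tables(summarize(fixture_records))
    assert "62.8%" in text and "93.4%" in text and "Acceptability" in text
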
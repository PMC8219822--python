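"""Annual tables, decade averages, medians, and the reporting breakdown."""

import numpy as np
import pytest
from scipy.special import logit

from thermorep import (
    GeneratorConfig,
    StudyRecord,
    TrendCoefficients,
    annual_summary,
    attach_reporting,
    decade_averages,
    generate_study_dataset,
    load_packaged_tables,
    sample_size_medians,
    women_inclusion_breakdown,
)
from thermorep.data_model import NO, YES
from thermorep.descriptives import AnnualSummary, summaries_to_frame


def _rec(year, w, m, sid="s"):
    return StudyRecord(sid, year, n_women=w, n_men=m) if w == 0 else StudyRecord(
        sid, year, n_women=w, n_men=m, orientation_reported=NO, phase_reported=NO
    )


class TestPackagedTables:
    def test_decade_totals(self):
        tables = load_packaged_tables()
        assert sum(s.articles_total for s in tables) == 1407
        assert sum(s.participants_total for s in tables) == 28_030

    def test_category_sums_and_percentage_rows(self):
        for s in load_packaged_tables():
            pct = s.article_percentages()
            assert sum(pct.values()) == pytest.approx(100, abs=0.2)
            assert all(0 <= v <= 100 for v in pct.values())

    def test_printed_percentage_spot_checks(self):
        tables = {s.year: s for s in load_packaged_tables()}
        assert tables[2019].article_percentages()["articles_women_only"] == 8.5
        assert tables[2010].participant_percentages()["participants_both_women"] == 12.1

    def test_decade_averages_match_printed_row(self):
        avg = decade_averages(load_packaged_tables())
        assert avg.loc["articles_women_only", "mean"] == pytest.approx(7.4)
        assert avg.loc["articles_men_only", "mean"] == pytest.approx(97.9)
        assert avg.loc["articles_women_only", "sd"] == pytest.approx(3.3, abs=0.05)
        assert avg.loc["articles_men_only", "sd"] == pytest.approx(18.6, abs=0.05)


class TestAnnualSummary:
    def test_categories_partition_records(self, default_corpus):
        summaries = annual_summary(default_corpus)
        frame = summaries_to_frame(summaries)
        assert frame["articles_total"].sum() == len(default_corpus)
        assert (
            frame["articles_women_only"] + frame["articles_men_only"] + frame["articles_both"]
        ).equals(frame["articles_total"])
        assert frame["participants_total"].sum() == sum(r.total for r in default_corpus)

    def test_empty_record_set_yields_all_zero_rows(self):
        summaries = annual_summary([])
        assert len(summaries) == 10
        assert all(s.articles_total == 0 and s.participants_total == 0 for s in summaries)

    def test_constructed_year(self):
        recs = [_rec(2010, 0, 10), _rec(2010, 5, 0), _rec(2010, 3, 7)]
        s = annual_summary(recs)[0]
        assert (s.articles_men_only, s.articles_women_only, s.articles_both) == (1, 1, 1)
        assert s.participants_total == 25
        assert s.participants_both_women == 3 and s.participants_both_men == 7

    def test_inconsistent_totals_rejected(self):
        with pytest.raises(ValueError):
            AnnualSummary(year=2010, articles_total=5, articles_men_only=1)


class TestDecadeAverages:
    def test_constant_series(self):
        summaries = [
            AnnualSummary(year=y, articles_total=5, articles_men_only=5)
            for y in range(2010, 2020)
        ]
        avg = decade_averages(summaries)
        assert avg.loc["articles_total", "mean"] == 5.0
        assert avg.loc["articles_total", "sd"] == 0.0

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            decade_averages([])

    def test_ddof_zero_gives_population_sd(self):
        tables = load_packaged_tables()
        pop = decade_averages(tables, ddof=0).loc["articles_women_only", "sd"]
        samp = decade_averages(tables, ddof=1).loc["articles_women_only", "sd"]
        assert pop < samp


class TestSampleSizeMedians:
    def test_odd_and_even_length_medians(self):
        odd = [_rec(2010, 0, n, sid=f"o{n}") for n in (8, 10, 12)]
        assert sample_size_medians(odd)["men_only"]["median"] == 10
        even = [_rec(2011, 0, n, sid=f"e{n}") for n in (6, 10)]
        assert sample_size_medians(even)["men_only"]["median"] == 8.0

    def test_empty_categories_absent_not_zero(self):
        out = sample_size_medians([_rec(2010, 0, 9)])
        assert "men_only" in out and "women_only" not in out and "mixed_women" not in out

    def test_generated_men_only_median_matches_size_model(self):
        cfg = GeneratorConfig(seed=123)
        rng = np.random.default_rng(0)
        sizes = cfg.men_only_sizes.sample(rng, 500)
        recs = [_rec(2010, 0, int(n), sid=f"m{i}") for i, n in enumerate(sizes)]
        med = sample_size_medians(recs)["men_only"]["median"]
        assert abs(med - 10) <= 1

    def test_mixed_studies_feed_two_distributions(self):
        recs = [_rec(2012, 4, 9, "a"), _rec(2012, 6, 11, "b")]
        out = sample_size_medians(recs)
        assert out["mixed_women"]["median"] == 5.0
        assert out["mixed_men"]["median"] == 10.0
        assert out["mixed_women"]["q1"] <= out["mixed_women"]["median"] <= out["mixed_women"]["q3"]


class TestWomenInclusionBreakdown:
    def test_constructed_seventy_percent_not_reporting(self):
        recs = [
            StudyRecord(f"r{i}", 2012, n_women=4, n_men=4,
                        orientation_reported=NO, phase_reported=NO)
            for i in range(7)
        ] + [
            StudyRecord(f"y{i}", 2012, n_women=4, n_men=4, orientation_reported=YES,
                        orientation_counts={"natural-menstruating": 4}, phase_reported=NO)
            for i in range(3)
        ]
        out = women_inclusion_breakdown(recs)
        assert out["pct_not_reporting_orientation"] == 70.0
        assert out["orientation_category_pct"] == {"natural-menstruating": 100.0}

    def test_no_women_errors(self):
        with pytest.raises(ValueError):
            women_inclusion_breakdown([_rec(2010, 0, 8)])

    def test_reporting_rate_within_binomial_bounds_of_generator(self):
        # 400 eligible articles at constant reporting probability 0.28:
        # observed non-reporting within the 99% binomial band of 72%
        base = [_rec(2010 + i % 10, 5, 5, sid=f"s{i}") for i in range(400)]
        recs = attach_reporting(base, TrendCoefficients(g0=float(logit(0.28)), g1=0.0), seed=9)
        out = women_inclusion_breakdown(recs)
        half_width = 2.576 * np.sqrt(0.28 * 0.72 / 400) * 100
        assert abs(out["pct_not_reporting_orientation"] - 72.0) <= half_width


def test_default_corpus_has_published_table_shape(default_corpus):
    """Men-only is the largest article category every year and the overall
    female participant share falls in the 10–35% band."""
    summaries = annual_summary(default_corpus)
    for s in summaries:
        assert s.articles_men_only > s.articles_women_only
        assert s.articles_men_only > s.articles_both
    women = sum(s.participants_women_only + s.participants_both_women for s in summaries)
    total = sum(s.participants_total for s in summaries)
    assert 0.10 < women / total < 0.35
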
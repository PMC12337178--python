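import numpy as np
import pandas as pd
import pytest

from dispro.datasets import published_profile_cohort
from dispro.descriptives import compute_tto, summarize_cohort, summary_to_frame
from dispro.synth import GeneratorConfig, generate_tables


@pytest.fixture(scope="module")
def profile():
    demo, outc, ps = published_profile_cohort()
    return summarize_cohort(demo, outc), compute_tto(demo, ps)


class TestDenominatorRules:
    def test_sex_shares_use_known_denominator(self, profile):
        summary, _ = profile
        sex = summary.blocks["sex"].set_index("category")
        assert summary.denominators["sex"] == 356
        assert sex.loc["Male", "pct"] == pytest.approx(56.18, abs=0.005)
        assert sex.loc["Female", "pct"] == pytest.approx(43.82, abs=0.005)

    def test_death_share_of_serious(self, profile):
        summary, _ = profile
        codes = summary.serious_code_counts.set_index("category")
        assert codes.loc["Death", "n"] == 220
        assert codes.loc["Death", "pct"] == pytest.approx(34.70, abs=0.005)

    def test_blocks_sum_to_hundred(self, profile):
        summary, _ = profile
        for name, frame in summary.blocks.items():
            if len(frame) and frame["n"].sum() > 0:
                assert frame["pct"].sum() == pytest.approx(100.0, abs=0.05), name

    def test_known_plus_missing_equals_cohort(self, profile):
        summary, _ = profile
        for name in ("sex", "age", "country", "reporter", "year"):
            assert summary.denominators[name] <= summary.n_total

    def test_all_missing_block_has_zero_denominator(self):
        demo = pd.DataFrame({"primaryid": ["1", "2"], "sex": ["", ""],
                             "age_years": [np.nan, np.nan]})
        s = summarize_cohort(demo, pd.DataFrame(columns=["primaryid", "outc_cod"]))
        assert s.denominators["sex"] == 0
        assert s.blocks["sex"].empty or s.blocks["sex"]["n"].sum() == 0

    def test_empty_cohort(self):
        s = summarize_cohort(pd.DataFrame(columns=["primaryid", "sex"]),
                             pd.DataFrame(columns=["primaryid", "outc_cod"]))
        assert s.n_total == 0 and not s.blocks

    def test_serious_precedence_one_category_per_report(self):
        demo = pd.DataFrame({"primaryid": ["1", "2", "3"]})
        outc = pd.DataFrame({"primaryid": ["1", "1", "2", "3"],
                             "outc_cod": ["HO", "DE", "LT", "OT"]})
        s = summarize_cohort(demo, outc)
        brk = s.blocks["serious_breakdown"].set_index("category")["n"]
        assert brk["Death"] == 1            # DE outranks HO on report 1
        assert brk["Hospitalization"] == 0
        assert brk["Life-threatening"] == 1
        assert s.blocks["outcomes"].set_index("category").loc["Serious", "n"] == 3

    def test_flattened_frame_carries_denominators(self, profile):
        summary, _ = profile
        flat = summary_to_frame(summary)
        assert set(["block", "category", "n", "pct",
                    "block_denominator"]) <= set(flat.columns)
        assert (flat.loc[flat.block == "sex", "block_denominator"] == 356).all()


class TestTimeToOnset:
    def test_simple_arithmetic(self):
        demo = pd.DataFrame({"primaryid": ["1"], "event_dt": ["20220128"]})
        ps = pd.DataFrame({"primaryid": ["1"], "start_dt": ["20220101"]})
        t = compute_tto(demo, ps)
        assert t.n_evaluable == 1 and t.median_days == 27
        assert t.bins.set_index("bin").loc["0-30 d", "n"] == 1

    def test_negative_interval_excluded_with_reason(self):
        demo = pd.DataFrame({"primaryid": ["1"], "event_dt": ["20220101"]})
        ps = pd.DataFrame({"primaryid": ["1"], "start_dt": ["20220401"]})
        t = compute_tto(demo, ps)
        assert t.n_evaluable == 0 and t.excluded["negative"] == 1

    def test_partial_dates_excluded_with_reason(self):
        demo = pd.DataFrame({"primaryid": ["1", "2"],
                             "event_dt": ["202201", "20220115"]})
        ps = pd.DataFrame({"primaryid": ["1", "2"],
                           "start_dt": ["20220101", "2022"]})
        t = compute_tto(demo, ps)
        assert t.n_evaluable == 0
        assert t.excluded["event_date_partial"] == 1
        assert t.excluded["therapy_start_unusable"] == 1

    def test_day_zero_included_in_first_bin(self):
        demo = pd.DataFrame({"primaryid": ["1"], "event_dt": ["20220101"]})
        ps = pd.DataFrame({"primaryid": ["1"], "start_dt": ["20220101"]})
        t = compute_tto(demo, ps)
        assert t.n_evaluable == 1
        assert t.bins.set_index("bin").loc["0-30 d", "n"] == 1

    def test_bin_boundary_convention(self):
        # day 30 falls in the first bin, day 31 in the second
        demo = pd.DataFrame({"primaryid": ["1", "2"],
                             "event_dt": ["20220131", "20220201"]})
        ps = pd.DataFrame({"primaryid": ["1", "2"],
                           "start_dt": ["20220101", "20220101"]})
        t = compute_tto(demo, ps).bins.set_index("bin")
        assert t.loc["0-30 d", "n"] == 1 and t.loc["31-90 d", "n"] == 1

    def test_earliest_start_of_multiple_rows_wins(self):
        demo = pd.DataFrame({"primaryid": ["1"], "event_dt": ["20220301"]})
        ps = pd.DataFrame({"primaryid": ["1", "1"],
                           "start_dt": ["20220201", "20220101"]})
        t = compute_tto(demo, ps)
        assert t.median_days == 59

    def test_bins_partition_evaluable(self, profile):
        _, onset = profile
        assert onset.bins["n"].sum() == onset.n_evaluable
        assert onset.iqr_lo <= onset.median_days <= onset.iqr_hi

    def test_matches_generator_ground_truth(self):
        cfg = GeneratorConfig(n_reports=8000, missing_tto_rate=0.3, seed=17)
        frames, truth = generate_tables(cfg)
        demo = frames["DEMO"][["primaryid", "event_dt"]]
        ther = frames["THER"].rename(columns={"dsg_drug_seq": "drug_seq"})
        t = compute_tto(demo, ther[["primaryid", "start_dt"]])
        gt = truth.reports.loc[truth.reports.tto_evaluable, "onset_days"]
        assert t.n_evaluable == len(gt)
        assert t.median_days == pytest.approx(float(np.median(gt)))
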
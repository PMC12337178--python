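import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

from dispro.synth import (GeneratorConfig, background_pair_probs,
                          generate_package, generate_tables,
                          sample_time_to_onset, target_pair_probs)



class TestConfigValidation:
    def test_bad_rates_rejected(self):
        with pytest.raises(ValidationError):
            GeneratorConfig(n_reports=10, duplicate_rate=1.0)
        with pytest.raises(ValidationError):
            GeneratorConfig(n_reports=0)
        with pytest.raises(ValidationError):
            GeneratorConfig(n_reports=10, quarters=["2022-Q1"])

    def test_nonpositive_planted_ratio_rejected(self):
        with pytest.raises(ValidationError):
            GeneratorConfig(n_reports=10, planted_signals=[("Diarrhoea", 0.0)])

    def test_planted_pt_must_exist_in_vocabulary(self):
        cfg = GeneratorConfig(n_reports=10,
                              planted_signals=[("NotATerm", 2.0)])
        with pytest.raises(ValueError, match="vocabulary"):
            generate_tables(cfg)


class TestBookkeeping:
    def test_no_duplication_means_distinct_caseids(self):
        cfg = GeneratorConfig(n_reports=1000, duplicate_rate=0, deleted_rate=0,
                              seed=5)
        frames, truth = generate_tables(cfg)
        demo = frames["DEMO"]
        assert demo["caseid"].nunique() == 1000
        assert len(demo) == 1000
        assert truth.n_duplicate_rows == 0 and not truth.deleted_caseids

    def test_duplicate_rate_bookkeeping_identity(self):
        cfg = GeneratorConfig(n_reports=2000, duplicate_rate=0.1, seed=5)
        frames, truth = generate_tables(cfg)
        demo = frames["DEMO"]
        n_pairs = len(demo[["caseid", "primaryid"]].drop_duplicates())
        assert n_pairs - demo["caseid"].nunique() == truth.n_duplicate_rows
        assert truth.n_duplicate_rows == round(0.1 * 2000)

    def test_quarters_partition_the_report_set(self):
        cfg = GeneratorConfig(n_reports=1500, seed=9)
        frames, truth = generate_tables(cfg)
        demo = frames["DEMO"]
        per_quarter = demo.groupby("quarter")["caseid"].apply(set)
        all_ids = set().union(*per_quarter)
        assert all_ids == set(truth.reports["caseid"])
        assert sum(len(s) for s in per_quarter) == len(demo["caseid"].unique())

    def test_ground_truth_covers_every_report_once(self):
        cfg = GeneratorConfig(n_reports=800, duplicate_rate=0.05,
                              deleted_rate=0.02, seed=3)
        frames, truth = generate_tables(cfg)
        assert truth.reports["caseid"].is_unique
        assert set(truth.reports["caseid"]) == set(frames["DEMO"]["caseid"])
        assert truth.deleted_caseids <= set(truth.reports["caseid"])

    def test_deleted_only_when_rate_positive(self):
        cfg = GeneratorConfig(n_reports=500, deleted_rate=0.0, seed=3)
        frames, truth = generate_tables(cfg)
        assert len(frames["DELETED"]) == 0


class TestDeterminism:
    def test_identical_config_gives_byte_identical_files(self, tmp_path):
        cfg = GeneratorConfig(n_reports=400, duplicate_rate=0.1,
                              deleted_rate=0.05, seed=11)
        d1, _ = generate_package(cfg, tmp_path / "a")
        d2, _ = generate_package(cfg, tmp_path / "b")
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*.txt"))
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*.txt"))
        assert files1 == files2 and files1
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()

    def test_different_seed_changes_output(self, tmp_path):
        a, _ = generate_package(GeneratorConfig(n_reports=200, seed=1),
                                tmp_path / "a")
        b, _ = generate_package(GeneratorConfig(n_reports=200, seed=2),
                                tmp_path / "b")
        assert (a / "2022q1" / "DEMO.txt").read_bytes() != \
            (b / "2022q1" / "DEMO.txt").read_bytes()


class TestPlantedSignals:
    def test_relative_reporting_ratio_recovered(self):
        """Planted Diarrhoea at ratio 4: the empirical (a/(a+b))/(c/(c+d))
        computed on the raw generated pairs lands within +-15%."""
        cfg = GeneratorConfig(n_reports=50_000,
                              planted_signals=[("Diarrhoea", 4.0)], seed=21)
        frames, truth = generate_tables(cfg)
        reac = frames["REAC"]
        target_cases = set(
            truth.reports.loc[truth.reports.is_target_ps, "caseid"])
        is_t = reac["caseid"].isin(target_cases)
        a = int(((reac["pt"] == "Diarrhoea") & is_t).sum())
        b = int(is_t.sum()) - a
        c = int(((reac["pt"] == "Diarrhoea") & ~is_t).sum())
        d = int((~is_t).sum()) - c
        rr = (a / (a + b)) / (c / (c + d))
        assert rr == pytest.approx(4.0, rel=0.15)

    def test_target_probabilities_encode_exact_ratio(self, vocab):
        cfg = GeneratorConfig(n_reports=10,
                              planted_signals=[("Epistaxis", 4.0)])
        q0 = background_pair_probs(cfg, vocab)
        qt = target_pair_probs(cfg, vocab)
        assert qt["Epistaxis"] == pytest.approx(4.0 * q0["Epistaxis"])
        assert qt.sum() == pytest.approx(q0.sum())

    def test_unattainable_ratio_rejected(self, vocab):
        cfg = GeneratorConfig(n_reports=10,
                              planted_signals=[("Diarrhoea", 50.0)])
        with pytest.raises(ValueError, match="rarer PT|attainable"):
            target_pair_probs(cfg, vocab)


class TestTimeToOnset:
    def test_sample_median_close_to_configured(self):
        cfg = GeneratorConfig(n_reports=10, onset_median_days=27.0, seed=4)
        days = sample_time_to_onset(cfg, 10_000,
                                    rng=np.random.default_rng(4))
        assert (days >= 0).all()
        assert np.median(days) == pytest.approx(27.0, rel=0.10)

    def test_all_missing_when_rate_is_one(self):
        from dispro.descriptives import compute_tto
        cfg = GeneratorConfig(n_reports=500, missing_tto_rate=1.0, seed=6)
        frames, truth = generate_tables(cfg)
        assert not truth.reports["tto_evaluable"].any()
        # no report yields a computable onset downstream either
        t = compute_tto(frames["DEMO"][["primaryid", "event_dt"]],
                        frames["THER"][["primaryid", "start_dt"]])
        assert t.n_evaluable == 0

    def test_evaluable_fraction_tracks_published_regime(self):
        """missing rate 0.7577 emulates 470-of-1940 computable onsets."""
        cfg = GeneratorConfig(n_reports=20_000, seed=8)
        _, truth = generate_tables(cfg)
        frac = truth.reports["tto_evaluable"].mean()
        assert frac == pytest.approx(1 - 0.7577, abs=0.01)
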
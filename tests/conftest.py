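import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from dispro.io import tables_from_frames
from dispro.pipeline import PipelineConfig, analyze
from dispro.synth import GeneratorConfig, generate_package, generate_tables
from dispro.vocabulary import Vocabulary

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def vocab() -> Vocabulary:
    return Vocabulary.bundled()


@pytest.fixture(scope="session")
def small_world(tmp_path_factory):
    """A written-to-disk synthetic package small enough for fast I/O tests."""
    # plant a high-frequency PT so even a ~60-report cohort shows the signal
    cfg = GeneratorConfig(n_reports=2000, planted_signals=[("Diarrhoea", 4.0)],
                          duplicate_rate=0.1, deleted_rate=0.02, seed=123)
    out = tmp_path_factory.mktemp("pkg")
    path, truth = generate_package(cfg, out)
    return cfg, path, truth


#: planted relative-reporting ratios exercised by the recovery study
PLANTED = [("Gout", 1.0), ("Night sweats", 2.0), ("Epistaxis", 4.0)]


def run_replicate(seed: int, n_reports: int = 50_000) -> pd.DataFrame:
    """One synthetic-package replicate through the full pipeline; returns the
    PT-level signal rows for the three planted terms."""
    cfg = GeneratorConfig(n_reports=n_reports, planted_signals=PLANTED, seed=seed)
    frames, truth = generate_tables(cfg)
    res = analyze(tables_from_frames(frames), PipelineConfig(input_dir=".", seed=seed))
    assert res.cohort_ids == truth.canonical_cohort
    pt = res.signals["pt"].set_index("stratum")
    rows = []
    for name, lam in PLANTED:
        if name in pt.index:
            r = pt.loc[name]
            rows.append({"seed": seed, "pt": name, "lambda": lam, "n": r.n,
                         "ror": r.ror, "lo": r.ror95_lo, "hi": r.ror95_hi,
                         "flag_all": bool(r.flag_all)})
        else:  # term never drawn in this replicate (possible for rare PTs)
            rows.append({"seed": seed, "pt": name, "lambda": lam, "n": 0,
                         "ror": np.nan, "lo": np.nan, "hi": np.nan,
                         "flag_all": False})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def replicate_study() -> pd.DataFrame:
    """100 seeded replicates of the planted-signal recovery study."""
    return pd.concat([run_replicate(1000 + i) for i in range(100)],
                     ignore_index=True)
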
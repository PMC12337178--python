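"""Synthetic FAERS-dialect data with known ground truth.

Emulates the quarterly spontaneous-report world a disproportionality
pipeline faces: "$"-delimited DEMO/DRUG/REAC/OUTC/RPSR/THER/INDI tables per
quarter, a deleted-cases list, duplicate CASEIDs re-emitted under higher
PRIMARYIDs, partial dates, heavy missingness in demographics, and a
Zipf-tailed event vocabulary.  Drug–event dependencies of configurable
strength are planted for the target drug: a planted PT with relative
reporting ratio lambda is given exactly lambda times its background
event probability among target-drug reports (the remaining probability
mass is rescaled over the other PTs), so the realised relative reporting
ratio estimates lambda directly.

Every generated record is covered exactly once by the returned
:class:`GroundTruth`, which downstream stages are tested against.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .vocabulary import Vocabulary

_QUARTER_RE = re.compile(r"^(\d{4})Q([1-4])$")

DEFAULT_QUARTERS = ["2022Q1", "2022Q2", "2022Q3", "2022Q4",
                    "2023Q1", "2023Q2", "2023Q3", "2023Q4",
                    "2024Q1", "2024Q2"]

#: reporting-year weights emulating the observed report flow after a
#: first-quarter market introduction (ramp-up, peak, partial final year)
DEFAULT_YEAR_WEIGHTS = {2022: 0.1933, 2023: 0.5531, 2024: 0.2536}

#: within serious reports: death, life-threatening, disability,
#: hospitalisation, other — one category per report
SERIOUS_CATEGORY_SHARES = {"DE": 0.3470, "LT": 0.0032, "DS": 0.0,
                           "HO": 0.5284, "OT": 0.1214}


class GeneratorConfig(BaseModel):
    """All knobs of the synthetic FAERS world.

    Default rates mirror the demographic-missingness and seriousness regime
    of a real post-marketing cohort for a recently approved orphan drug:
    ~82% missing age/sex, ~33% serious reports, ~24% of reports with a
    computable time-to-onset, US-dominated reporting by consumers.
    """

    n_reports: int = Field(ge=1)
    quarters: list[str] = Field(default_factory=lambda: list(DEFAULT_QUARTERS))
    target_drug_names: list[str] = Field(
        default_factory=lambda: ["pacritinib", "Vonjo"])
    background_drugs: int = Field(default=500, ge=1)
    planted_signals: list[tuple[str, float]] = Field(default_factory=list)
    target_share: float = Field(default=0.04, gt=0, lt=1)
    ps_share: float = Field(default=0.9, ge=0, le=1)
    target_concomitant_rate: float = Field(default=0.01, ge=0, lt=1)
    duplicate_rate: float = Field(default=0.0, ge=0, lt=1)
    deleted_rate: float = Field(default=0.0, ge=0, lt=1)
    missing_sex_rate: float = Field(default=0.8165, ge=0, le=1)
    missing_age_rate: float = Field(default=0.8258, ge=0, le=1)
    missing_tto_rate: float = Field(default=0.7577, ge=0, le=1)
    partial_date_rate: float = Field(default=0.3, ge=0, lt=1)
    negative_tto_share: float = Field(default=0.05, ge=0, lt=1)
    serious_rate: float = Field(default=0.3268, ge=0, le=1)
    onset_median_days: float = Field(default=27.0, gt=0)
    onset_sigma: float = Field(default=1.5, gt=0)
    reactions_extra_mean: float = Field(default=1.3, ge=0)
    zipf_s: float = Field(default=0.7, gt=0)
    drug_heterogeneity_sigma: float = Field(default=0.8, ge=0)
    year_weights: dict[int, float] = Field(
        default_factory=lambda: dict(DEFAULT_YEAR_WEIGHTS))
    seed: int = 0

    @field_validator("quarters")
    @classmethod
    def _quarters_valid(cls, v: list[str]) -> list[str]:
        if not v:
            raise ValueError("at least one quarter is required")
        for q in v:
            if not _QUARTER_RE.match(q):
                raise ValueError(f"bad quarter label {q!r}; expected e.g. 2022Q1")
        return v

    @field_validator("target_drug_names")
    @classmethod
    def _names_nonempty(cls, v: list[str]) -> list[str]:
        if not v:
            raise ValueError("at least one target drug name is required")
        return v

    @model_validator(mode="after")
    def _signals_valid(self) -> "GeneratorConfig":
        for pt, lam in self.planted_signals:
            if lam <= 0:
                raise ValueError(f"planted ratio for {pt!r} must be > 0")
        return self


@dataclass
class GroundTruth:
    """What the generator actually did, one row per canonical report."""

    reports: pd.DataFrame
    """Columns: caseid, primaryid (canonical, max version), quarter,
    is_target_ps, is_duplicated, is_deleted, tto_evaluable, onset_days,
    start_date, event_date."""

    lambda_true: dict[str, float]
    n_duplicate_rows: int
    deleted_caseids: set[str]

    @property
    def canonical_cohort(self) -> set[str]:
        """Primaryids the pipeline should retain as the target-drug cohort."""
        keep = self.reports[self.reports.is_target_ps & ~self.reports.is_deleted]
        return set(keep.primaryid.astype(str))


# ---------------------------------------------------------------------------
# pieces
# ---------------------------------------------------------------------------

def _quarter_bounds(label: str) -> tuple[np.datetime64, int]:
    year, q = map(int, _QUARTER_RE.match(label).groups())
    start = np.datetime64(f"{year}-{(q - 1) * 3 + 1:02d}-01")
    end = (np.datetime64(f"{year + 1}-01-01") if q == 4
           else np.datetime64(f"{year}-{q * 3 + 1:02d}-01"))
    return start, int((end - start) / np.timedelta64(1, "D"))


def _quarter_weights(config: GeneratorConfig) -> np.ndarray:
    years = [int(_QUARTER_RE.match(q).group(1)) for q in config.quarters]
    per_year: dict[int, int] = {}
    for y in years:
        per_year[y] = per_year.get(y, 0) + 1
    w = np.array([config.year_weights.get(y, 0.0) / per_year[y] for y in years])
    if w.sum() <= 0:
        w = np.ones(len(years))
    return w / w.sum()


def background_event_probs(config: GeneratorConfig, vocabulary: Vocabulary,
                           ) -> pd.Series:
    """Zipf-law relative frequencies over the vocabulary PTs (rank = listed
    order, so the clinically common terms listed first are the frequent ones)."""
    pts = vocabulary.pts
    ranks = np.arange(1, len(pts) + 1, dtype=float)
    p = ranks ** -config.zipf_s
    return pd.Series(p / p.sum(), index=pts)


def background_pair_probs(config: GeneratorConfig, vocabulary: Vocabulary,
                          ) -> pd.Series:
    """Per-report inclusion probability q_j of each PT for background drugs;
    sum of q equals the mean number of (report, PT) pairs per report."""
    p0 = background_event_probs(config, vocabulary)
    m = 1.0 + config.reactions_extra_mean
    q = m * p0
    if q.max() >= 0.95:
        raise ValueError("background event distribution too concentrated; "
                         "lower zipf_s or reactions_extra_mean")
    return q


def target_pair_probs(config: GeneratorConfig, vocabulary: Vocabulary,
                      ) -> pd.Series:
    """Inclusion probabilities for target-drug reports with planted signals.

    A planted PT gets exactly lambda times its background inclusion
    probability; the remaining PTs are rescaled so the expected pairs per
    report is unchanged.  The realised relative reporting ratio
    (a/(a+b)) / (c/(c+d)) of a planted PT is therefore lambda.
    """
    q0 = background_pair_probs(config, vocabulary)
    for pt, _ in config.planted_signals:
        if pt not in q0.index:
            raise ValueError(f"planted PT {pt!r} not in the event vocabulary")
    planted = {pt: lam for pt, lam in config.planted_signals}
    for pt, lam in planted.items():
        if lam * q0[pt] >= 0.97:
            raise ValueError(
                f"planted ratio {lam} for {pt!r} exceeds the attainable "
                "per-report probability; plant a rarer PT or lower lambda")
    total = q0.sum()
    planted_mass = sum(lam * q0[pt] for pt, lam in planted.items())
    base_mass = sum(q0[pt] for pt in planted)
    scale = (total - planted_mass) / (total - base_mass)
    if scale <= 0:
        raise ValueError("planted signals absorb the whole reaction budget")
    q = q0 * scale
    for pt, lam in planted.items():
        q[pt] = lam * q0[pt]
    return q


def sample_time_to_onset(config: GeneratorConfig, n: int,
                         rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Draw nonnegative integer onset days from the configured log-normal.

    The distribution is a stand-in calibrated only by its median
    (``onset_median_days``) and spread (``onset_sigma`` on the log scale).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    draws = rng.lognormal(mean=np.log(config.onset_median_days),
                          sigma=config.onset_sigma, size=n)
    return np.rint(draws).astype(int)


def _date_str(dates: np.ndarray) -> np.ndarray:
    """np.datetime64[D] -> YYYYMMDD strings."""
    s = np.datetime_as_string(dates, unit="D")
    return np.char.replace(s, "-", "")


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def generate_tables(config: GeneratorConfig,
                    vocabulary: Optional[Vocabulary] = None,
                    ) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Generate one multi-quarter package fully in memory.

    Returns ``(tables, ground_truth)`` where ``tables`` holds the seven
    section frames (string-typed, FAERS column names) plus the deleted-case
    list under key ``"DELETED"``.
    """
    vocab = vocabulary or Vocabulary.bundled()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    caseid = np.arange(20_000_000, 20_000_000 + n)
    primaryid = caseid * 10 + 1  # caseversion 1
    quarter_idx = rng.choice(len(config.quarters), size=n,
                             p=_quarter_weights(config))

    is_target = rng.random(n) < config.target_share
    n_t = int(is_target.sum())

    # ---- reactions: one increment per (report, PT) pair -----------------
    # Each report lists PT j independently with probability q_j (distinct
    # PTs by construction), so pair counts are exactly Bernoulli-binomial
    # and planted relative reporting ratios are realised without the
    # shrinkage a draw-then-deduplicate scheme would introduce.
    pts_arr = np.array(vocab.pts)
    q_bg = background_pair_probs(config, vocab).to_numpy()
    q_tg = target_pair_probs(config, vocab).to_numpy()
    # per-drug event-profile tilts (mean-1 log-normal): real databases show
    # across-drug heterogeneity in reporting profiles, which is what the
    # empirical-Bayes shrinkage prior exists to capture
    bg_suspect_pick = rng.integers(0, config.background_drugs, size=n)
    sig = config.drug_heterogeneity_sigma
    tilt = rng.lognormal(-sig**2 / 2, sig,
                         size=(config.background_drugs, len(pts_arr)))
    pair_mask = np.empty((n, len(pts_arr)), dtype=bool)
    t_idx, b_idx = np.flatnonzero(is_target), np.flatnonzero(~is_target)
    pair_mask[t_idx] = rng.random((len(t_idx), len(pts_arr))) < q_tg
    q_b = np.minimum(q_bg[None, :] * tilt[bg_suspect_pick[b_idx]], 0.95)
    pair_mask[b_idx] = rng.random((len(b_idx), len(pts_arr))) < q_b
    # every report must carry at least one reaction
    empty = np.flatnonzero(~pair_mask.any(axis=1))
    if len(empty):
        p0 = q_bg / q_bg.sum()
        forced = rng.choice(len(pts_arr), size=len(empty), p=p0)
        pair_mask[empty, forced] = True
    rep_i, pt_i = np.nonzero(pair_mask)
    reac = pd.DataFrame({"rep": rep_i, "pt": pts_arr[pt_i]})

    # ---- demographics ----------------------------------------------------
    sex = np.where(rng.random(n) < 0.5618, "M", "F")
    sex = np.where(rng.random(n) < config.missing_sex_rate, "", sex)
    age_years = np.clip(np.rint(rng.normal(70, 9, size=n)), 18, 99).astype(int)
    age_known = rng.random(n) >= config.missing_age_rate
    age_in_months = rng.random(n) < 0.05  # a few reports use MON units
    age_val = np.where(age_in_months, age_years * 12, age_years).astype(str)
    age_val = np.where(age_known, age_val, "")
    age_cod = np.where(age_known, np.where(age_in_months, "MON", "YR"), "")

    country_u = rng.random(n)
    country = np.where(country_u < 0.9907, "US",
                       np.where(country_u < 0.9928, "PL", "GB"))
    occp_u = rng.random(n)
    occp = np.where(occp_u < 0.0077, "",
                    np.where(occp_u < 0.0077 + 0.8478 * 0.9923, "CN", "MD"))

    # ---- outcomes --------------------------------------------------------
    serious = rng.random(n) < config.serious_rate
    cats = list(SERIOUS_CATEGORY_SHARES)
    cat_p = np.array(list(SERIOUS_CATEGORY_SHARES.values()))
    cat_p = cat_p / cat_p.sum()
    outc_cat = rng.choice(cats, size=n, p=cat_p)

    # ---- dates and time-to-onset ----------------------------------------
    q_start = np.array([_quarter_bounds(q)[0] for q in config.quarters])
    q_days = np.array([_quarter_bounds(q)[1] for q in config.quarters])
    fda_dt = (q_start[quarter_idx]
              + (rng.random(n) * q_days[quarter_idx]).astype(int))
    delay = rng.integers(0, 90, size=n)
    event_dt = fda_dt - delay
    onset = sample_time_to_onset(config, n, rng)
    start_dt = event_dt - onset

    evaluable = rng.random(n) >= config.missing_tto_rate
    # non-evaluable reports: truncated event date, negative interval, or
    # blank therapy start
    u = rng.random(n)
    trunc_month = ~evaluable & (u < config.partial_date_rate / 2)
    trunc_year = ~evaluable & (u >= config.partial_date_rate / 2) \
        & (u < config.partial_date_rate)
    negative = ~evaluable & (u >= config.partial_date_rate) \
        & (u < config.partial_date_rate + config.negative_tto_share)
    blank_start = ~evaluable & ~(trunc_month | trunc_year | negative)
    start_dt = np.where(negative, event_dt + 1 + rng.integers(1, 60, size=n),
                        start_dt)

    event_str = _date_str(event_dt.astype("datetime64[D]"))
    start_str = _date_str(start_dt.astype("datetime64[D]"))
    fda_str = _date_str(fda_dt.astype("datetime64[D]"))
    event_str = event_str.astype(object)
    event_str[trunc_month] = [s[:6] for s in event_str[trunc_month]]
    event_str[trunc_year] = [s[:4] for s in event_str[trunc_year]]
    start_str = np.where(blank_start, "", start_str)

    # ---- drug rows -------------------------------------------------------
    target_variants = []
    for name in config.target_drug_names:
        target_variants += [name, name.upper(), f"{name.upper()} 200MG",
                            f"{name} capsule"]
    # single-token names survive dose/form stripping in the name normaliser
    bg_names = np.array([f"COMPARATOR-{i:04d}"
                         for i in range(config.background_drugs)])

    role_target = np.where(rng.random(n) < config.ps_share, "1", "2")
    target_name_pick = rng.integers(0, len(target_variants), size=n)
    n_concom = rng.integers(0, 3, size=n)
    concom_target = (~is_target) & (rng.random(n) < config.target_concomitant_rate)

    variants_arr = np.array(target_variants)
    all_rep = np.arange(n)
    # suspect row (seq 1) for every report
    sus_name = np.where(is_target, variants_arr[target_name_pick],
                        bg_names[bg_suspect_pick])
    sus_role = np.where(is_target, role_target, "1")
    # concomitant background drugs (seq 2..)
    rep_c = np.repeat(all_rep, n_concom)
    seq_c = (np.arange(len(rep_c))
             - np.repeat(np.cumsum(n_concom) - n_concom, n_concom)) + 2
    name_c = bg_names[rng.integers(0, config.background_drugs, size=len(rep_c))]
    # the target drug sometimes appears as a concomitant on background reports
    rep_t = np.flatnonzero(concom_target)
    seq_t = n_concom[rep_t] + 2
    drug_frame = pd.DataFrame({
        "rep": np.concatenate([all_rep, rep_c, rep_t]),
        "drug_seq": np.concatenate([np.ones(n, int), seq_c, seq_t]).astype(str),
        "role_cod": np.concatenate([sus_role, np.full(len(rep_c), "2"),
                                    np.full(len(rep_t), "2")]),
        "drugname": np.concatenate([sus_name, name_c,
                                    variants_arr[target_name_pick[rep_t]]]),
    }).sort_values(["rep", "drug_seq"], kind="mergesort").reset_index(drop=True)
    ther_frame = pd.DataFrame({
        "rep": all_rep, "dsg_drug_seq": np.ones(n, int).astype(str),
        "start_dt": start_str,
    })
    indi_frame = pd.DataFrame({
        "rep": all_rep, "indi_drug_seq": np.ones(n, int).astype(str),
        "indi_pt": np.where(is_target, "Myelofibrosis",
                            "Product used for unknown indication"),
    })

    # a report only belongs to the PS cohort when the *target* row has role 1
    is_target_ps = is_target & (role_target == "1")

    # ---- duplicates and deletions ---------------------------------------
    n_dup = int(round(config.duplicate_rate * n))
    dup_idx = rng.choice(n, size=n_dup, replace=False) if n_dup else np.array([], int)
    n_del = int(round(config.deleted_rate * n))
    del_idx = rng.choice(n, size=n_del, replace=False) if n_del else np.array([], int)
    deleted_caseids = {str(caseid[i]) for i in del_idx}

    # ---- assemble section frames ----------------------------------------
    quarters_arr = np.array(config.quarters)

    def emit(rep_idx: np.ndarray, version: int) -> dict[str, pd.DataFrame]:
        member = np.zeros(n, dtype=bool)
        member[rep_idx] = True
        pid_all = (caseid * 10 + version).astype(str)
        cid_all = caseid.astype(str)
        q_all = quarters_arr[quarter_idx]
        demo = pd.DataFrame({
            "primaryid": pid_all[rep_idx], "caseid": cid_all[rep_idx],
            "caseversion": np.full(len(rep_idx), str(version)),
            "event_dt": event_str[rep_idx], "fda_dt": fda_str[rep_idx],
            "age": age_val[rep_idx], "age_cod": age_cod[rep_idx],
            "sex": sex[rep_idx], "occp_cod": occp[rep_idx],
            "reporter_country": country[rep_idx],
            "occr_country": country[rep_idx],
            "quarter": q_all[rep_idx],
        })

        def expand(frame: pd.DataFrame) -> pd.DataFrame:
            rep = frame["rep"].to_numpy()
            sel = member[rep]
            out = frame.loc[sel].drop(columns="rep").copy()
            out.insert(0, "primaryid", pid_all[rep[sel]])
            out.insert(1, "caseid", cid_all[rep[sel]])
            out["quarter"] = q_all[rep[sel]]
            return out.reset_index(drop=True)

        ser_idx = rep_idx[serious[rep_idx]]
        outc = pd.DataFrame({
            "primaryid": pid_all[ser_idx], "caseid": cid_all[ser_idx],
            "outc_cod": outc_cat[ser_idx], "quarter": q_all[ser_idx],
        })
        rpsr = pd.DataFrame({
            "primaryid": pid_all[rep_idx], "caseid": cid_all[rep_idx],
            "rpsr_cod": np.where(occp[rep_idx] == "CN", "CSM", "HP"),
            "quarter": q_all[rep_idx],
        })
        return {"DEMO": demo, "DRUG": expand(drug_frame),
                "REAC": expand(reac), "OUTC": outc,
                "THER": expand(ther_frame), "RPSR": rpsr,
                "INDI": expand(indi_frame)}

    base = emit(np.arange(n), 1)
    tables = base
    if n_dup:
        dup = emit(np.sort(dup_idx), 2)
        tables = {k: pd.concat([base[k], dup[k]], ignore_index=True)
                  for k in base}
    for k in tables:
        tables[k] = tables[k].sort_values(
            ["quarter", "primaryid"], kind="mergesort").reset_index(drop=True)
    tables["DELETED"] = pd.DataFrame({"caseid": sorted(deleted_caseids)})

    is_dup = np.zeros(n, dtype=bool)
    is_dup[dup_idx] = True
    is_del = np.zeros(n, dtype=bool)
    is_del[del_idx] = True
    canonical_pid = caseid * 10 + np.where(is_dup, 2, 1)
    truth = GroundTruth(
        reports=pd.DataFrame({
            "caseid": caseid.astype(str),
            "primaryid": canonical_pid.astype(str),
            "quarter": [config.quarters[q] for q in quarter_idx],
            "is_target_ps": is_target_ps,
            "is_duplicated": is_dup,
            "is_deleted": is_del,
            "tto_evaluable": evaluable,
            "onset_days": np.where(evaluable, onset, -1),
            "start_date": start_dt.astype("datetime64[D]"),
            "event_date": event_dt.astype("datetime64[D]"),
        }),
        lambda_true=dict(config.planted_signals),
        n_duplicate_rows=n_dup,
        deleted_caseids=deleted_caseids,
    )
    return tables, truth


def generate_package(config: GeneratorConfig, out_dir: str | Path,
                     vocabulary: Optional[Vocabulary] = None,
                     ) -> tuple[Path, GroundTruth]:
    """Write a synthetic package to disk: one directory per quarter holding
    the seven "$"-delimited section files, plus DELETED.txt at the root.

    Identical config + seed produce a byte-identical file set.
    """
    tables, truth = generate_tables(config, vocabulary)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for quarter in config.quarters:
        qdir = out_dir / quarter.lower()
        qdir.mkdir(exist_ok=True)
        for section in ("DEMO", "DRUG", "REAC", "OUTC", "RPSR", "THER", "INDI"):
            frame = tables[section]
            part = frame[frame.quarter == quarter].drop(columns="quarter")
            part.to_csv(qdir / f"{section}.txt", sep="$", index=False,
                        lineterminator="\n")
    (out_dir / "DELETED.txt").write_text(
        "".join(f"{c}\n" for c in tables["DELETED"]["caseid"]))
    return out_dir, truth
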
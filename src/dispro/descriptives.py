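"""Descriptive cohort profile and time-to-onset analysis.

Spontaneous-report demographics are mostly missing, so every categorical
block is summarised over its *known* (non-missing) denominator and the
denominator itself is reported as a share of the cohort — the layout of a
typical pharmacovigilance "Table 1".  Seriousness is derived from outcome
codes: a report is serious iff it carries at least one outcome code, and
within serious reports one category per report is assigned with precedence
death > life-threatening > disability > hospitalisation > other.

Time-to-onset (TTO) is the day difference between the adverse-event date
and the earliest therapy start of a primary-suspect drug row.  Pairs where
either date is missing, lacks day precision, or yields a negative
difference are excluded and counted by reason.  Same-day onsets count as
0 days and fall into the first bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: outcome-code precedence; CA (congenital anomaly) and RI (required
#: intervention) fold into "other" alongside OT
OUTCOME_PRECEDENCE = ["DE", "LT", "DS", "HO", "OT", "CA", "RI"]
OUTCOME_LABELS = {"DE": "Death", "LT": "Life-threatening", "DS": "Disability",
                  "HO": "Hospitalization", "OT": "Other serious outcome",
                  "CA": "Other serious outcome", "RI": "Other serious outcome"}

#: onset bins in days: first month, 1-3 months, 3-12 months, beyond a year
TTO_BINS = [(0, 30), (30, 90), (90, 365), (365, np.inf)]
TTO_BIN_LABELS = ["0-30 d", "31-90 d", "91-365 d", "> 365 d"]


@dataclass
class DescriptiveSummary:
    """Per-block category counts with explicit known-denominators."""

    n_total: int
    blocks: dict[str, pd.DataFrame] = field(default_factory=dict)
    """block name -> frame with columns (category, n, pct)."""
    denominators: dict[str, int] = field(default_factory=dict)
    age_median: Optional[float] = None
    age_iqr: Optional[tuple[float, float]] = None
    serious_code_counts: Optional[pd.DataFrame] = None
    """Per-outcome-code counts over the serious denominator.  Codes overlap
    (one report may carry several), so these percentages can sum past 100 —
    this is the counting convention of published safety profiles, kept
    alongside the non-overlapping precedence block."""

    def pct_known(self, block: str) -> float:
        """The known denominator of a block as % of the cohort."""
        if self.n_total == 0:
            return float("nan")
        return 100.0 * self.denominators[block] / self.n_total


@dataclass
class OnsetSummary:
    n_input: int
    n_evaluable: int
    median_days: float
    iqr_lo: float
    iqr_hi: float
    bins: pd.DataFrame
    """columns (bin, n, pct) over the evaluable reports."""
    excluded: dict[str, int] = field(default_factory=dict)


def _block(series: pd.Series, order: Optional[list[str]] = None) -> pd.DataFrame:
    known = series.dropna()
    counts = known.value_counts()
    if order is not None:
        counts = counts.reindex(order).fillna(0).astype(int)
    denom = int(counts.sum())
    pct = 100.0 * counts / denom if denom else counts * float("nan")
    return pd.DataFrame({"category": counts.index, "n": counts.to_numpy(),
                         "pct": pct.to_numpy()}).reset_index(drop=True)


def summarize_cohort(demo: pd.DataFrame, outc: pd.DataFrame) -> DescriptiveSummary:
    """Build the descriptive profile of a deduplicated cohort.

    ``demo`` needs columns ``primaryid``, ``sex``, ``age_years``,
    ``occr_country``, ``occp_cod`` (or ``reporter_type``), ``report_year``;
    ``outc`` needs ``primaryid`` and ``outc_cod``.
    """
    n_total = len(demo)
    summary = DescriptiveSummary(n_total=n_total)
    if n_total == 0:
        return summary

    def col(name: str) -> pd.Series:
        if name in demo.columns:
            return demo[name]
        return pd.Series(pd.NA, index=demo.index, dtype=object)

    sex = col("sex").replace("", pd.NA)
    sex = sex.where(sex.isin(["F", "M"]))
    summary.blocks["sex"] = _block(sex.map({"F": "Female", "M": "Male"}))
    summary.denominators["sex"] = int(sex.notna().sum())

    age = pd.to_numeric(col("age_years"), errors="coerce")
    groups = pd.cut(age, bins=[-np.inf, 18, 65, np.inf], right=False,
                    labels=["< 18", "18-65", "> 65"])
    # pd.cut with right=False puts 65 in "> 65"; the conventional grouping
    # keeps 65 inclusive in the middle band
    groups = groups.astype(object).where(~(age == 65), "18-65")
    summary.blocks["age"] = _block(pd.Series(groups), order=["< 18", "18-65", "> 65"])
    summary.denominators["age"] = int(age.notna().sum())
    if age.notna().any():
        summary.age_median = float(age.median())
        summary.age_iqr = (float(age.quantile(0.25)), float(age.quantile(0.75)))

    country = col("occr_country").replace("", pd.NA)
    summary.blocks["country"] = _block(country)
    summary.denominators["country"] = int(country.notna().sum())

    if "reporter_type" in demo.columns:
        rep = demo["reporter_type"].replace({"unknown": pd.NA})
    else:
        from .io import OCCP_TO_REPORTER
        rep = col("occp_cod").replace("", pd.NA).map(OCCP_TO_REPORTER)
    summary.blocks["reporter"] = _block(rep)
    summary.denominators["reporter"] = int(rep.notna().sum())

    year = pd.to_numeric(col("report_year"), errors="coerce").astype("Int64")
    summary.blocks["year"] = _block(year.astype(object).astype("string"))
    summary.denominators["year"] = int(year.notna().sum())

    # seriousness: serious iff >= 1 outcome code; one category per report
    ids = demo["primaryid"].astype(str)
    if len(outc):
        codes = outc[["primaryid", "outc_cod"]].copy()
        codes["primaryid"] = codes["primaryid"].astype(str)
        codes = codes[codes["primaryid"].isin(set(ids))]
        rank = {c: i for i, c in enumerate(OUTCOME_PRECEDENCE)}
        codes["rank"] = codes["outc_cod"].map(rank)
        codes = codes.dropna(subset=["rank"])
        best = codes.sort_values("rank").drop_duplicates("primaryid")
        serious_ids = set(best["primaryid"])
    else:
        codes = pd.DataFrame(columns=["primaryid", "outc_cod"])
        best = codes
        serious_ids = set()
    n_serious = len(serious_ids)
    summary.blocks["outcomes"] = pd.DataFrame({
        "category": ["Non-serious", "Serious"],
        "n": [n_total - n_serious, n_serious],
        "pct": [100.0 * (n_total - n_serious) / n_total,
                100.0 * n_serious / n_total],
    })
    summary.denominators["outcomes"] = n_total
    labels = best["outc_cod"].map(OUTCOME_LABELS) if len(best) else pd.Series(dtype=str)
    order = ["Death", "Disability", "Life-threatening", "Hospitalization",
             "Other serious outcome"]
    summary.blocks["serious_breakdown"] = _block(labels, order=order)
    summary.denominators["serious_breakdown"] = n_serious
    if len(codes):
        per_code = (codes.assign(label=codes["outc_cod"].map(OUTCOME_LABELS))
                    .drop_duplicates(["primaryid", "label"])["label"]
                    .value_counts().reindex(order).fillna(0).astype(int))
        summary.serious_code_counts = pd.DataFrame({
            "category": per_code.index, "n": per_code.to_numpy(),
            "pct": 100.0 * per_code.to_numpy() / n_serious if n_serious
            else float("nan"),
        }).reset_index(drop=True)
    return summary


# ---------------------------------------------------------------------------
# time to onset
# ---------------------------------------------------------------------------

def _parse_day_precision(tokens: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Parse YYYYMMDD tokens; returns (datetime series, reason series).

    Reasons: '' (ok), 'missing', 'partial' (4/6-digit), 'invalid'.
    """
    s = tokens.astype("string").str.strip()
    reason = pd.Series("", index=s.index, dtype=object)
    missing = s.isna() | (s == "")
    reason[missing] = "missing"
    digits = s.str.fullmatch(r"\d+").fillna(False)
    reason[~missing & ~digits] = "invalid"
    partial = ~missing & digits & s.str.len().isin([4, 6])
    reason[partial] = "partial"
    full = ~missing & digits & (s.str.len() == 8)
    reason[~missing & digits & ~partial & ~full] = "invalid"
    parsed = pd.to_datetime(s.where(full), format="%Y%m%d", errors="coerce")
    reason[full & parsed.isna()] = "invalid"  # e.g. month 13
    return parsed, reason


def compute_tto(demo: pd.DataFrame, ps_mentions: pd.DataFrame) -> OnsetSummary:
    """Time-to-onset summary over a deduplicated cohort.

    ``ps_mentions`` holds the primary-suspect target-drug rows with their
    therapy start (columns ``primaryid``, ``start_dt``); ``demo`` supplies
    ``event_dt`` per report.  TTO = event date minus the earliest
    day-precision therapy start of the report.
    """
    ids = demo["primaryid"].astype(str)
    event, ev_reason = _parse_day_precision(
        demo.get("event_dt", pd.Series("", index=demo.index)))

    ment = ps_mentions.copy()
    ment["primaryid"] = ment["primaryid"].astype(str)
    start, st_reason = _parse_day_precision(
        ment.get("start_dt", pd.Series("", index=ment.index)))
    ment["_start"] = start
    earliest = ment.dropna(subset=["_start"]).groupby("primaryid")["_start"].min()

    start_per_report = ids.map(earliest)
    excluded: dict[str, int] = {}
    ok_event = ev_reason == ""
    for r in ("missing", "partial", "invalid"):
        k = int(((ev_reason == r)).sum())
        if k:
            excluded[f"event_date_{r}"] = k
    no_start = ok_event & start_per_report.isna()
    excluded["therapy_start_unusable"] = int(no_start.sum())

    usable = ok_event & start_per_report.notna()
    days = (event[usable] - start_per_report[usable]).dt.days
    negative = days < 0
    if int(negative.sum()):
        excluded["negative"] = int(negative.sum())
    days = days[~negative].astype(float)

    n_eval = len(days)
    if n_eval:
        med = float(np.percentile(days, 50))
        q1, q3 = (float(np.percentile(days, q)) for q in (25, 75))
    else:
        med = q1 = q3 = float("nan")
    rows = []
    for (lo, hi), label in zip(TTO_BINS, TTO_BIN_LABELS):
        if lo == 0:
            n_bin = int(((days >= 0) & (days <= hi)).sum())  # day 0 included
        else:
            n_bin = int(((days > lo) & (days <= hi)).sum())
        rows.append({"bin": label, "n": n_bin,
                     "pct": 100.0 * n_bin / n_eval if n_eval else float("nan")})
    return OnsetSummary(n_input=len(demo), n_evaluable=n_eval,
                        median_days=med, iqr_lo=q1, iqr_hi=q3,
                        bins=pd.DataFrame(rows), excluded=excluded)


def summary_to_frame(summary: DescriptiveSummary) -> pd.DataFrame:
    """Flatten a DescriptiveSummary into one tidy frame for writing."""
    parts = []
    for block, frame in summary.blocks.items():
        f = frame.copy()
        f.insert(0, "block", block)
        f["block_denominator"] = summary.denominators.get(block, 0)
        parts.append(f)
    if not parts:
        return pd.DataFrame(columns=["block", "category", "n", "pct",
                                     "block_denominator"])
    return pd.concat(parts, ignore_index=True)
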
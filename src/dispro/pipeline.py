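"""End-to-end pipeline: package -> dedup -> cohort -> signals -> reports.

Mirrors the standard pharmacovigilance study flow: load the quarterly
package, deduplicate cases and drop deleted ones, select the cohort whose
primary-suspect drug matches the target name rule, map reaction terms to
PT/SOC, screen every stratum with the four disproportionality measures,
and write descriptive, signal and time-to-onset tables plus a run manifest
whose record counts form the study funnel.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .cohort import (DrugMatchRule, build_cohort, match_drug_name,
                     normalize_drug_name)
from .descriptives import (DescriptiveSummary, OnsetSummary, compute_tto,
                           summarize_cohort, summary_to_frame)
from .io import (attach_therapy_start, normalize_age_years, read_package,
                 write_analysis_tables)
from .stats import SignalCriteria, build_tables, compute_signals, mgps_fit_prior
from .vocabulary import Vocabulary


class PipelineConfig(BaseModel):
    """Everything a run needs; every statistical variant is user-visible."""

    input_dir: str
    output_dir: str = "dispro_out"
    drug_names: list[str] = Field(default_factory=lambda: ["pacritinib", "Vonjo"])
    match_threshold: float = 0.1
    substring_match: bool = True
    vocabulary_path: Optional[str] = None
    label_pt_file: Optional[str] = None
    bcpnn_variant: str = "gamma"
    yates: bool = True
    continuity: float = 0.0
    criteria: SignalCriteria = Field(default_factory=SignalCriteria)
    seed: int = 0

    model_config = {"arbitrary_types_allowed": True}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "criteria" in raw and isinstance(raw["criteria"], dict):
            raw["criteria"] = SignalCriteria(**raw["criteria"])
        return cls(**raw)


@dataclass
class RunManifest:
    """Stage-by-stage record counts (the study funnel) plus provenance."""

    config: dict
    counts: dict[str, int]
    version: str
    seed: int
    started: str
    finished: str

    def validate_funnel(self) -> None:
        funnel = [self.counts[k] for k in
                  ("reports_loaded", "after_dedup", "after_deleted_removed",
                   "ps_cohort")]
        if any(b > a for a, b in zip(funnel, funnel[1:])):
            raise ValueError(f"funnel counts increased: {funnel}")

    def to_yaml(self) -> str:
        return yaml.safe_dump({
            "config": self.config, "counts": self.counts,
            "version": self.version, "seed": self.seed,
            "started": self.started, "finished": self.finished,
        }, sort_keys=False)


@dataclass
class PipelineResult:
    signals: dict[str, pd.DataFrame]
    descriptives: DescriptiveSummary
    onset: OnsetSummary
    manifest: RunManifest
    cohort_ids: set[str]


def _event_pairs(reac: pd.DataFrame, vocab: Vocabulary) -> pd.DataFrame:
    """Unique (primaryid, pt, soc) pairs after vocabulary normalisation."""
    pairs = reac[["primaryid", "pt"]].dropna().copy()
    pairs["primaryid"] = pairs["primaryid"].astype(str)
    mapped = vocab.map_series(pairs.pop("pt"))
    pairs["pt"] = mapped["pt"]
    pairs["soc"] = mapped["soc"]
    return pairs.drop_duplicates(["primaryid", "pt"])


def _database_cells(drug: pd.DataFrame, pairs: pd.DataFrame) -> pd.DataFrame:
    """(n, E) for every drug x PT cell of the loaded package (all drugs),
    the database-wide basis of the MGPS prior."""
    d = drug[["primaryid", "drugname"]].dropna().copy()
    d["primaryid"] = d["primaryid"].astype(str)
    d["drug"] = d["drugname"].map(normalize_drug_name)
    trip = d.merge(pairs[["primaryid", "pt"]], on="primaryid")
    trip = trip.drop_duplicates(["primaryid", "drug", "pt"])
    mat = pd.crosstab(trip["drug"], trip["pt"])
    n_i = mat.sum(axis=1).to_numpy()[:, None]
    n_j = mat.sum(axis=0).to_numpy()[None, :]
    total = mat.to_numpy().sum()
    e = n_i * n_j / total
    out = pd.DataFrame({"a": mat.to_numpy().ravel(), "E": e.ravel()})
    return out[out.E > 0]


def analyze(tables, config: PipelineConfig) -> PipelineResult:
    """Run the analysis flow on already-loaded tables (no file output).

    ``tables`` is a :class:`dispro.io.FaersTables`, from :func:`read_package`
    or built in memory from the synthetic generator's frames.
    """
    started = _dt.datetime.now(_dt.timezone.utc).isoformat()
    vocab = (Vocabulary.from_file(config.vocabulary_path)
             if config.vocabulary_path else Vocabulary.bundled())
    rule = DrugMatchRule(names=config.drug_names,
                         threshold=config.match_threshold,
                         substring_match=config.substring_match)

    demo = tables.demo
    if "age_years" not in demo.columns and "age" in demo.columns:
        demo["age_years"] = normalize_age_years(demo["age"], demo["age_cod"])
    deduped, cohort_ids, audit = build_cohort(
        demo, tables.drug, tables.deleted_caseids, rule)
    kept_ids = set(deduped["primaryid"].astype(str))

    pairs = _event_pairs(tables.reac, vocab)
    pairs = pairs[pairs["primaryid"].isin(kept_ids)]
    cohort_pairs = pairs[pairs["primaryid"].isin(cohort_ids)]
    background_pairs = pairs[~pairs["primaryid"].isin(cohort_ids)]

    drug_kept = tables.drug[tables.drug["primaryid"].astype(str).isin(kept_ids)]
    prior = mgps_fit_prior(_database_cells(drug_kept, pairs))

    signals: dict[str, pd.DataFrame] = {}
    for level in ("pt", "soc"):
        tab = build_tables(cohort_pairs, background_pairs, level=level)
        signals[level] = compute_signals(
            tab, prior=prior, criteria=config.criteria,
            bcpnn_variant=config.bcpnn_variant, yates=config.yates,
            continuity=config.continuity)

    if config.label_pt_file:
        listed = {line.strip().casefold()
                  for line in Path(config.label_pt_file).read_text().splitlines()
                  if line.strip()}
        flagged = signals["pt"][signals["pt"].flag_all]
        on_label = flagged["stratum"].str.casefold().isin(listed)
        signals["pt_label_listed"] = flagged[on_label].reset_index(drop=True)
        signals["pt_novel"] = flagged[~on_label].reset_index(drop=True)

    cohort_demo = deduped[deduped["primaryid"].astype(str).isin(cohort_ids)]
    desc = summarize_cohort(cohort_demo, tables.outc)

    drug_ps = drug_kept[drug_kept["primaryid"].astype(str).isin(cohort_ids)]
    drug_ps = drug_ps[(drug_ps["role_cod"].astype(str).str.strip() == "1")]
    is_target = drug_ps["drugname"].astype(str).map(
        lambda s: match_drug_name(s, rule))
    ps_mentions = attach_therapy_start(drug_ps[is_target], tables.ther)
    onset = compute_tto(cohort_demo, ps_mentions)

    finished = _dt.datetime.now(_dt.timezone.utc).isoformat()
    manifest = RunManifest(
        config=config.model_dump(mode="json"),
        counts={
            "reports_loaded": audit.n_rows,
            "after_dedup": audit.n_rows - audit.n_duplicates_removed,
            "after_deleted_removed": audit.n_retained,
            "ps_cohort": len(cohort_ids),
            "skipped_rows": sum(tables.skipped_rows.values()),
        },
        version=__version__, seed=config.seed,
        started=started, finished=finished,
    )
    manifest.validate_funnel()
    return PipelineResult(signals=signals, descriptives=desc, onset=onset,
                          manifest=manifest, cohort_ids=cohort_ids)


def write_results(result: PipelineResult, config: PipelineConfig) -> Path:
    """Write all output tables and the manifest under ``config.output_dir``."""
    desc, onset, signals = result.descriptives, result.onset, result.signals
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_analysis_tables(signals, out_dir)
    summary_to_frame(desc).to_csv(out_dir / "descriptives.tsv", sep="\t",
                                  index=False, float_format="%.2f")
    onset_meta = onset.bins.copy()
    onset_meta.to_csv(out_dir / "onset_bins.tsv", sep="\t", index=False,
                      float_format="%.2f")
    (out_dir / "onset_summary.yaml").write_text(yaml.safe_dump({
        "n_input": onset.n_input, "n_evaluable": onset.n_evaluable,
        "median_days": None if onset.median_days != onset.median_days
        else float(onset.median_days),
        "iqr": [float(onset.iqr_lo), float(onset.iqr_hi)]
        if onset.n_evaluable else None,
        "excluded": onset.excluded,
        "bin_boundaries_days": "[0,30], (30,90], (90,365], (365,inf)",
    }, sort_keys=False))
    (out_dir / "manifest.yaml").write_text(result.manifest.to_yaml())
    return out_dir


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full flow on a package directory and write all outputs.

    Outputs under ``config.output_dir``: ``signals_pt.tsv``,
    ``signals_soc.tsv`` (and a label-listed/novel split of flagged PTs when
    a label list is supplied), ``descriptives.tsv``, ``onset_bins.tsv``,
    ``onset_summary.yaml`` and ``manifest.yaml``.  Raises before writing
    anything on invalid input, so failures leave no partial results.
    """
    tables = read_package(config.input_dir)
    result = analyze(tables, config)
    write_results(result, config)
    return result
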
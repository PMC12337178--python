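"""Reading and writing FAERS-style quarterly ASCII packages.

A quarterly package is a directory tree holding one "$"-delimited text table
per section (DEMO, DRUG, REAC, OUTC, RPSR, THER, INDI; first line is the
header) plus a deleted-cases list (one CASEID per line).  Field names follow
the FAERS ASCII data dictionary (``primaryid``, ``caseid``, ``role_cod``,
``pt``, ``outc_cod``, ``start_dt``, ``event_dt``, ...) so the same reader
ingests real quarters without remapping.

Dates are FAERS partial dates: digit strings of length 8 (YYYYMMDD),
6 (YYYYMM) or 4 (YYYY).  Anything else is treated as missing and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field, field_validator

logger = logging.getLogger(__name__)

SECTIONS = ("DEMO", "DRUG", "REAC", "OUTC", "RPSR", "THER", "INDI")
MANDATORY_SECTIONS = ("DEMO", "DRUG", "REAC")
DELETED_FILENAME = "DELETED.txt"

OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})

#: FAERS age-unit code -> factor converting the stored value to years
AGE_UNIT_TO_YEARS = {"YR": 1.0, "DEC": 10.0, "MON": 1 / 12, "WK": 1 / 52, "DY": 1 / 365}

#: occupation code -> reporter type used in descriptive tables
OCCP_TO_REPORTER = {
    "MD": "health professional",
    "PH": "health professional",
    "HP": "health professional",
    "RN": "health professional",
    "CN": "consumer",
    "OT": "other",
    "LW": "other",
}


class MissingSectionError(FileNotFoundError):
    """A mandatory FAERS section file is absent from the package."""


# ---------------------------------------------------------------------------
# partial dates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartialDate:
    """A FAERS date known to year, month or day precision."""

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None:
            if self.month is None:
                raise ValueError("day precision requires a month")
            if not 1 <= self.day <= 31:
                raise ValueError(f"day out of range: {self.day}")

    @property
    def precision(self) -> Literal["year", "month", "day"]:
        if self.day is not None:
            return "day"
        if self.month is not None:
            return "month"
        return "year"


def parse_partial_date(token: object) -> Optional[PartialDate]:
    """Parse a FAERS date token; non-conforming tokens yield ``None``.

    Length 8 -> day precision, 6 -> month, 4 -> year; anything else
    (including separators, blanks, non-digits) is missing.
    """
    if token is None or (isinstance(token, float) and pd.isna(token)):
        return None
    s = str(token).strip()
    if s.endswith(".0"):  # numeric round-trip through pandas
        s = s[:-2]
    if not s.isdigit():
        return None
    try:
        if len(s) == 8:
            return PartialDate(int(s[:4]), int(s[4:6]), int(s[6:8]))
        if len(s) == 6:
            return PartialDate(int(s[:4]), int(s[4:6]))
        if len(s) == 4:
            return PartialDate(int(s))
    except ValueError:
        return None
    return None


# ---------------------------------------------------------------------------
# typed record models (row-level views over the tables)
# ---------------------------------------------------------------------------

class SafetyReport(BaseModel):
    """One demographic row: a case as received by the agency."""

    primaryid: str
    caseid: str
    sex: Literal["F", "M", "unknown"] = "unknown"
    age_years: Optional[float] = None
    country: Optional[str] = None
    reporter_type: Literal["health professional", "consumer", "other", "unknown"] = "unknown"
    event_date: Optional[PartialDate] = None
    fda_receipt_date: Optional[PartialDate] = None
    report_year: Optional[int] = None

    model_config = {"arbitrary_types_allowed": True}

    @field_validator("age_years")
    @classmethod
    def _age_plausible(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and not 0 <= v < 150:
            raise ValueError(f"implausible age in years: {v}")
        return v


class DrugMention(BaseModel):
    primaryid: str
    drug_seq: int
    name_raw: str
    role_code: Literal[1, 2, 3]
    therapy_start: Optional[PartialDate] = None

    model_config = {"arbitrary_types_allowed": True}


class ReactionMention(BaseModel):
    primaryid: str
    pt_raw: str = Field(min_length=1)

    @field_validator("pt_raw")
    @classmethod
    def _nonblank(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("blank reaction term")
        return v.strip()


class OutcomeMention(BaseModel):
    primaryid: str
    outcome_code: Literal["DE", "LT", "HO", "DS", "CA", "RI", "OT"]


# ---------------------------------------------------------------------------
# package reader
# ---------------------------------------------------------------------------

@dataclass
class FaersTables:
    """The parsed contents of one or more FAERS quarterly packages."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    rpsr: pd.DataFrame
    indi: pd.DataFrame
    deleted_caseids: set[str] = field(default_factory=set)
    #: per-section counts of rows that could not be parsed (wrong field count)
    skipped_rows: dict[str, int] = field(default_factory=dict)
    #: per-section total data rows seen in the files
    total_rows: dict[str, int] = field(default_factory=dict)

    def table(self, section: str) -> pd.DataFrame:
        return getattr(self, section.lower())


def _read_dollar_file(path: Path, section: str) -> tuple[pd.DataFrame, int, int]:
    """Read one "$"-delimited table; quarantine rows with a wrong field count.

    Returns ``(frame, n_rows_seen, n_rows_skipped)``.
    """
    with open(path, encoding="utf-8", errors="replace") as fh:
        lines = fh.read().splitlines()
    if not lines:
        return pd.DataFrame(), 0, 0
    header = lines[0].split("$")
    ncol = len(header)
    rows: list[list[str]] = []
    skipped = 0
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("$")
        if len(fields) != ncol:
            skipped += 1
            logger.warning("%s:%d quarantined (%d fields, expected %d)",
                           path.name, lineno, len(fields), ncol)
            continue
        rows.append(fields)
    frame = pd.DataFrame(rows, columns=header, dtype=str)
    frame = frame.replace("", pd.NA)
    return frame, len(rows) + skipped, skipped


def _find_section_files(directory: Path, section: str) -> list[Path]:
    # accept DEMO.txt in quarter subdirectories or DEMO22Q1.txt style names
    pattern = f"{section}*.txt"
    hits = sorted(directory.rglob(pattern)) + sorted(directory.rglob(pattern.lower()))
    return [h for h in hits if h.is_file()]


def normalize_age_years(age: pd.Series, age_cod: pd.Series) -> pd.Series:
    """Convert FAERS (age, age_cod) pairs to years; unknown units -> missing."""
    value = pd.to_numeric(age, errors="coerce")
    factor = age_cod.fillna("YR").str.strip().str.upper().map(AGE_UNIT_TO_YEARS)
    years = value * factor
    return years.where((years >= 0) & (years < 150))


def read_package(directory: str | Path) -> FaersTables:
    """Load every section of a FAERS package directory tree.

    Malformed rows are logged and counted per section (never silently
    dropped); a missing mandatory section raises :class:`MissingSectionError`.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise MissingSectionError(f"not a directory: {directory}")
    frames: dict[str, pd.DataFrame] = {}
    skipped: dict[str, int] = {}
    totals: dict[str, int] = {}
    for section in SECTIONS:
        files = _find_section_files(directory, section)
        if not files:
            if section in MANDATORY_SECTIONS:
                raise MissingSectionError(
                    f"mandatory section {section} not found under {directory}")
            frames[section] = pd.DataFrame()
            skipped[section] = 0
            totals[section] = 0
            continue
        parts, n_seen, n_skip = [], 0, 0
        for f in files:
            frame, seen, skip = _read_dollar_file(f, section)
            parts.append(frame)
            n_seen += seen
            n_skip += skip
        frames[section] = pd.concat(parts, ignore_index=True)
        skipped[section] = n_skip
        totals[section] = n_seen

    deleted: set[str] = set()
    for f in sorted(directory.rglob(DELETED_FILENAME)):
        deleted.update(x.strip() for x in f.read_text().splitlines() if x.strip())

    demo = frames["DEMO"]
    if not demo.empty:
        if "age" in demo.columns:
            demo["age_years"] = normalize_age_years(
                demo["age"], demo.get("age_cod", pd.Series(index=demo.index, dtype=str)))
        if "fda_dt" in demo.columns:
            demo["report_year"] = demo["fda_dt"].str.slice(0, 4).pipe(
                pd.to_numeric, errors="coerce").astype("Int64")

    tables = FaersTables(
        demo=demo, drug=frames["DRUG"], reac=frames["REAC"], outc=frames["OUTC"],
        ther=frames["THER"], rpsr=frames["RPSR"], indi=frames["INDI"],
        deleted_caseids=deleted, skipped_rows=skipped, total_rows=totals,
    )
    return tables


def tables_from_frames(frames: dict[str, pd.DataFrame]) -> FaersTables:
    """Build a :class:`FaersTables` from in-memory section frames (the
    synthetic generator's output), applying the same normalisation as the
    file reader: blank -> missing, age in years, report year from fda_dt."""
    def clean(name: str) -> pd.DataFrame:
        frame = frames.get(name, pd.DataFrame())
        if frame.empty:
            return pd.DataFrame()
        frame = frame.drop(columns=[c for c in ("quarter",) if c in frame.columns])
        return frame.astype(str).replace({"": pd.NA, "<NA>": pd.NA})

    demo = clean("DEMO")
    if not demo.empty:
        if "age" in demo.columns:
            demo["age_years"] = normalize_age_years(
                demo["age"], demo.get("age_cod", pd.Series(index=demo.index, dtype=str)))
        if "fda_dt" in demo.columns:
            demo["report_year"] = demo["fda_dt"].str.slice(0, 4).pipe(
                pd.to_numeric, errors="coerce").astype("Int64")
    deleted = frames.get("DELETED", pd.DataFrame())
    deleted_ids = (set(deleted["caseid"].astype(str)) if len(deleted) else set())
    return FaersTables(
        demo=demo, drug=clean("DRUG"), reac=clean("REAC"), outc=clean("OUTC"),
        ther=clean("THER"), rpsr=clean("RPSR"), indi=clean("INDI"),
        deleted_caseids=deleted_ids,
    )


def attach_therapy_start(drug: pd.DataFrame, ther: pd.DataFrame) -> pd.DataFrame:
    """Join THER start dates onto drug mentions via (primaryid, drug_seq)."""
    if ther.empty or "start_dt" not in ther.columns:
        out = drug.copy()
        out["start_dt"] = pd.NA
        return out
    key = ther.rename(columns={"dsg_drug_seq": "drug_seq"})
    key = key[["primaryid", "drug_seq", "start_dt"]].drop_duplicates(
        subset=["primaryid", "drug_seq"])
    return drug.merge(key, on=["primaryid", "drug_seq"], how="left")


def demo_to_reports(demo: pd.DataFrame) -> list[SafetyReport]:
    """Materialise DEMO rows as validated :class:`SafetyReport` records."""
    def val(d, key):
        v = d.get(key)
        return None if v is None or pd.isna(v) else v

    reports = []
    for row in demo.itertuples(index=False):
        d = row._asdict()
        sex = val(d, "sex")
        occp = val(d, "occp_cod")
        age = val(d, "age_years")
        year = val(d, "report_year")
        reports.append(SafetyReport(
            primaryid=str(d["primaryid"]),
            caseid=str(d["caseid"]),
            sex=sex if sex in ("F", "M") else "unknown",
            age_years=None if age is None else float(age),
            country=val(d, "occr_country"),
            reporter_type=OCCP_TO_REPORTER.get(occp, "unknown")
            if occp is not None else "unknown",
            event_date=parse_partial_date(val(d, "event_dt")),
            fda_receipt_date=parse_partial_date(val(d, "fda_dt")),
            report_year=None if year is None else int(year),
        ))
    return reports


# ---------------------------------------------------------------------------
# analysis-table writer
# ---------------------------------------------------------------------------

#: column order of the signal tables written for each stratification level
ANALYSIS_COLUMNS = [
    "stratum", "n", "ror", "ror95_lo", "ror95_hi", "prr", "chi2",
    "ic", "ic025", "ebgm", "ebgm05",
    "flag_ror", "flag_prr", "flag_bcpnn", "flag_mgps", "flag_all",
]

_STAT_COLUMNS = ["ror", "ror95_lo", "ror95_hi", "prr", "chi2",
                 "ic", "ic025", "ebgm", "ebgm05"]


def write_analysis_tables(results: dict[str, pd.DataFrame], directory: str | Path,
                          decimals: int = 2) -> list[Path]:
    """Write one TSV per stratification level (e.g. ``pt``, ``soc``).

    ``results`` maps a level name to a frame carrying at least the
    :data:`ANALYSIS_COLUMNS`; statistics are rounded to ``decimals`` as in
    published signal tables.  An empty frame yields a header-only file.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for level, frame in results.items():
        out = frame.copy()
        for col in ANALYSIS_COLUMNS:
            if col not in out.columns:
                out[col] = pd.NA
        out = out[ANALYSIS_COLUMNS]
        out[_STAT_COLUMNS] = out[_STAT_COLUMNS].astype(float).round(decimals)
        path = directory / f"signals_{level}.tsv"
        out.to_csv(path, sep="\t", index=False)
        written.append(path)
    return written


def read_analysis_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
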
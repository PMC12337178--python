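"""Case deduplication and primary-suspect cohort selection.

Spontaneous-report databases re-emit the same case (CASEID) across quarters
under new version identifiers (PRIMARYID).  Following the FDA convention the
pipeline keeps, per CASEID, only the row with the largest PRIMARYID, then
drops every CASEID named in the quarterly deleted-cases list.  The target
cohort is then the set of reports in which a drug matching the target name
rule carries role code 1 ("primary suspect") on that same drug row —
concomitant (2) or interacting (3) mentions never qualify a report.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import pandas as pd

ROLE_PRIMARY_SUSPECT = "1"

#: dose/form tokens stripped from the tail of raw drug strings
_FORM_TOKENS = {
    "mg", "mcg", "g", "ml", "tablet", "tablets", "capsule", "capsules",
    "tab", "cap", "oral", "solution", "injection", "cream", "unknown",
}
_TRAIL_DOSE = re.compile(r"^\d+(\.\d+)?(mg|mcg|g|ml)?$")
_WS = re.compile(r"\s+")
_PAREN = re.compile(r"[()\[\]]")


@dataclass(frozen=True)
class DedupPolicy:
    """Keep max-PRIMARYID per CASEID, then remove deleted CASEIDs."""

    deleted_caseids: frozenset[str] = frozenset()


@dataclass
class DrugMatchRule:
    """Fuzzy name matcher for the target drug (generic + brand names).

    A raw string matches when, after normalisation (case-fold, trim,
    collapse whitespace, strip trailing dose/form tokens), any target name
    occurs as a substring, or the normalised Levenshtein distance to a
    target name is at most ``threshold``.
    """

    names: list[str]
    threshold: float = 0.1
    substring_match: bool = True

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError("at least one target drug name is required")
        if not 0 <= self.threshold <= 1:
            raise ValueError("threshold must lie in [0, 1]")
        self._targets = [normalize_drug_name(n) for n in self.names]


def normalize_drug_name(name: str) -> str:
    """Case-fold, collapse whitespace and strip trailing dose/form tokens."""
    s = _PAREN.sub(" ", str(name)).casefold().strip()
    s = _WS.sub(" ", s)
    tokens = s.split(" ")
    while tokens and (tokens[-1] in _FORM_TOKENS or _TRAIL_DOSE.match(tokens[-1])):
        tokens.pop()
    return " ".join(tokens)


def match_drug_name(name_raw: str, rule: DrugMatchRule) -> bool:
    """True iff the raw drug string matches the target name rule."""
    s = normalize_drug_name(name_raw)
    if not s:
        return False
    for target in rule._targets:
        if rule.substring_match and target in s:
            return True
        dist = edlib.align(s, target, task="distance")["editDistance"]
        if dist / max(len(s), len(target)) <= rule.threshold:
            return True
    return False


def _primaryid_sort_key(ids: pd.Series) -> pd.Series:
    """Numeric comparison when every id parses as an integer, else
    lexicographic on zero-padded strings."""
    numeric = pd.to_numeric(ids, errors="coerce")
    if numeric.notna().all():
        return numeric
    width = ids.str.len().max()
    return ids.str.zfill(int(width))


@dataclass
class DedupAudit:
    """Counts removed per rule, mirroring a study-flowchart funnel."""

    n_rows: int = 0
    n_duplicates_removed: int = 0
    n_deleted_removed: int = 0
    n_retained: int = 0
    extra: dict[str, int] = field(default_factory=dict)


def deduplicate(demo: pd.DataFrame, deleted_caseids: set[str] | frozenset[str] = frozenset(),
                ) -> tuple[pd.DataFrame, DedupAudit]:
    """One row per CASEID (largest PRIMARYID wins), deleted cases removed.

    Idempotent and independent of input row order.
    """
    audit = DedupAudit(n_rows=len(demo))
    if demo.empty:
        return demo.copy(), audit
    frame = demo.copy()
    frame["_key"] = _primaryid_sort_key(frame["primaryid"].astype(str))
    frame = frame.sort_values(["caseid", "_key"], kind="mergesort")
    kept = frame.drop_duplicates(subset="caseid", keep="last").drop(columns="_key")
    audit.n_duplicates_removed = len(frame) - len(kept)
    if deleted_caseids:
        mask = kept["caseid"].astype(str).isin(set(deleted_caseids))
        audit.n_deleted_removed = int(mask.sum())
        kept = kept[~mask]
    kept = kept.sort_index()
    audit.n_retained = len(kept)
    return kept.reset_index(drop=True), audit


def select_primary_suspect(drug_mentions: pd.DataFrame, rule: DrugMatchRule,
                           ) -> set[str]:
    """Primaryids whose report has >= 1 mention that BOTH matches the target
    name rule AND carries role code 1 on that same row."""
    if drug_mentions.empty:
        return set()
    names = drug_mentions["drugname"].astype(str)
    matched = pd.Series(
        [match_drug_name(n, rule) for n in names.unique()], index=names.unique())
    is_target = names.map(matched)
    is_ps = drug_mentions["role_cod"].astype(str).str.strip() == ROLE_PRIMARY_SUSPECT
    hits = drug_mentions.loc[is_target & is_ps, "primaryid"].astype(str)
    return set(hits)


def build_cohort(demo: pd.DataFrame, drug: pd.DataFrame,
                 deleted_caseids: set[str] | frozenset[str],
                 rule: DrugMatchRule,
                 ) -> tuple[pd.DataFrame, set[str], DedupAudit]:
    """Deduplicate first (matching the study-flow order), then select the
    primary-suspect cohort.  Returns (deduplicated demo, cohort ids, audit)."""
    deduped, audit = deduplicate(demo, deleted_caseids)
    keep_ids = set(deduped["primaryid"].astype(str))
    mentions = drug[drug["primaryid"].astype(str).isin(keep_ids)]
    cohort = select_primary_suspect(mentions, rule)
    audit.extra["n_ps_matched"] = len(cohort)
    return deduped, cohort, audit
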
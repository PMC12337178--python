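"""MedDRA-style vocabulary: map raw reaction strings to PT and SOC levels.

MedDRA itself is licensed and cannot be redistributed, so the package ships a
small synthetic mock vocabulary (``data/mock_meddra.tsv``) that covers the
preferred terms (PTs) and system organ classes (SOCs) exercised by the test
suite and the synthetic-report generator.  A user-supplied MedDRA export in
the same two-level format (columns ``llt_or_pt``, ``pt``, ``soc``) can be
loaded instead; lookup resolves lowest-level-term (LLT) synonyms to their PT
and each PT to a single primary SOC, mirroring how published signal tables
report each PT under exactly one SOC.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

UNMAPPED_SOC = "Unmapped"

_WS = re.compile(r"\s+")


def _norm_key(term: str) -> str:
    return _WS.sub(" ", term.strip()).casefold()


@dataclass
class Vocabulary:
    """Case-insensitive LLT/PT -> PT -> SOC lookup table.

    Attributes
    ----------
    pt_to_soc_map : canonical PT -> primary SOC
    term_to_pt : normalized LLT-or-PT string -> canonical PT
    unmapped_count : number of lookups that failed since construction
    """

    pt_to_soc_map: dict[str, str]
    term_to_pt: dict[str, str]
    unmapped_count: int = 0
    unmapped_terms: set[str] = field(default_factory=set)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Vocabulary":
        required = {"llt_or_pt", "pt", "soc"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"vocabulary table lacks columns: {sorted(missing)}")
        pt_to_soc: dict[str, str] = {}
        term_to_pt: dict[str, str] = {}
        for row in frame.itertuples(index=False):
            pt = str(row.pt).strip()
            soc = str(row.soc).strip()
            prev = pt_to_soc.setdefault(pt, soc)
            if prev != soc:
                raise ValueError(f"PT {pt!r} mapped to two SOCs: {prev!r}, {soc!r}")
            term_to_pt[_norm_key(str(row.llt_or_pt))] = pt
            term_to_pt.setdefault(_norm_key(pt), pt)
        return cls(pt_to_soc_map=pt_to_soc, term_to_pt=term_to_pt)

    @classmethod
    def from_file(cls, path: str | Path, sep: str = "\t") -> "Vocabulary":
        return cls.from_frame(pd.read_csv(path, sep=sep, dtype=str))

    @classmethod
    def bundled(cls) -> "Vocabulary":
        """The mock vocabulary shipped with the package."""
        ref = resources.files("dispro.data") / "mock_meddra.tsv"
        with resources.as_file(ref) as path:
            return cls.from_file(path)

    # -- lookups ---------------------------------------------------------

    @property
    def pts(self) -> list[str]:
        return list(self.pt_to_soc_map)

    @property
    def socs(self) -> list[str]:
        return sorted(set(self.pt_to_soc_map.values()))

    def normalize_pt(self, pt_raw: str) -> tuple[str, bool]:
        """Resolve a raw reaction string to its canonical PT.

        Returns ``(canonical_pt, mapped)``.  Unmapped terms come back
        verbatim (trimmed) with ``mapped=False`` and are counted.
        """
        key = _norm_key(pt_raw)
        hit = self.term_to_pt.get(key)
        if hit is not None:
            return hit, True
        self.unmapped_count += 1
        self.unmapped_terms.add(pt_raw.strip())
        return pt_raw.strip(), False

    def pt_to_soc(self, pt: str) -> str:
        """Primary SOC for a canonical PT; unknown PTs fall into 'Unmapped'."""
        return self.pt_to_soc_map.get(pt, UNMAPPED_SOC)

    def map_series(self, pt_raw: pd.Series) -> pd.DataFrame:
        """Vectorised mapping of raw reaction strings.

        Returns a frame with columns ``pt`` (canonical), ``soc`` and
        ``mapped`` aligned to the input index.
        """
        keys = pt_raw.fillna("").map(_norm_key)
        pt = keys.map(self.term_to_pt)
        mapped = pt.notna()
        pt = pt.where(mapped, pt_raw.str.strip())
        soc = pt.map(self.pt_to_soc_map).fillna(UNMAPPED_SOC)
        n_unmapped = int((~mapped).sum())
        self.unmapped_count += n_unmapped
        if n_unmapped:
            self.unmapped_terms.update(pt_raw[~mapped].str.strip())
        return pd.DataFrame({"pt": pt, "soc": soc, "mapped": mapped})


def normalize_pt(pt_raw: str, vocabulary: Vocabulary) -> tuple[str, bool]:
    return vocabulary.normalize_pt(pt_raw)


def pt_to_soc(pt: str, vocabulary: Vocabulary) -> str:
    return vocabulary.pt_to_soc(pt)
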
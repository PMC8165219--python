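"""Affinity table parsing, normalization, level mapping and deduplication.

IEDB-style binding tables mix quantitative IC50 measurements (nM) with
qualitative binding calls.  Both are brought onto a common footing: IC50
values are normalized to ``b = clamp(1 - log_50000(x), 0, 1)`` and mapped to
the five-tier binding-level scale, qualitative calls keep their level and
receive a representative ``b`` from the level's IC50 threshold.  Repeated
measurements of the same (allele, peptide) pair are consolidated by majority
vote over levels; pairs without a unique majority level are dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Normalization base: 50 uM, the conventional ceiling for reportable IC50.
IC50_BASE = 50000.0

MIN_PEPTIDE_LENGTH = 8
MAX_PEPTIDE_LENGTH = 15

#: Level bands, half-open toward the stronger-binding side:
#: 5 = (0, 100], 4 = (100, 500], 3 = (500, 1000], 2 = (1000, 5000],
#: 1 = (5000, inf).  Upper IC50 bound of each band, strongest first.
_LEVEL_UPPER_BOUNDS = ((5, 100.0), (4, 500.0), (3, 1000.0), (2, 5000.0))

#: Representative IC50 threshold per qualitative level, used to impute a
#: normalized affinity for qualitative-only records.  For a positive level
#: the band's upper IC50 bound is the guaranteed bound on b; the negative
#: level shares the 5000 nM threshold.
LEVEL_THRESHOLD_NM = {5: 100.0, 4: 500.0, 3: 1000.0, 2: 5000.0, 1: 5000.0}


class InvalidMeasurementError(ValueError):
    """Raised for non-positive IC50 values or malformed records."""


class MeasurementKind(str, Enum):
    QUANTITATIVE = "quantitative"
    QUALITATIVE = "qualitative"


@dataclass(frozen=True)
class MeasurementEntry:
    """One raw binding record: quantitative IC50 (nM) or qualitative level."""

    allele: str
    peptide: str
    kind: MeasurementKind
    ic50: float | None = None
    level: int | None = None

    def __post_init__(self):
        if self.kind == MeasurementKind.QUANTITATIVE:
            if self.ic50 is None or self.level is not None:
                raise InvalidMeasurementError(
                    "quantitative entry must carry ic50 and no level"
                )
            if not (0.0 < self.ic50 <= 1e7):
                raise InvalidMeasurementError(f"ic50 out of range: {self.ic50}")
        else:
            if self.level is None or self.ic50 is not None:
                raise InvalidMeasurementError(
                    "qualitative entry must carry level and no ic50"
                )
            if self.level not in (1, 2, 3, 4, 5):
                raise InvalidMeasurementError(f"level out of range: {self.level}")


@dataclass(frozen=True)
class NormalizedEntry:
    """Consolidated record with normalized affinity b in [0, 1] and level."""

    allele: str
    peptide: str
    b: float
    level: int
    kind: MeasurementKind


#: Sentinel returned by :func:`consolidate_duplicates` for conflicting groups.
REMOVED = object()


def normalize_affinity(x):
    """Map IC50 in nM to a normalized affinity ``clamp(1 - log_50000 x, 0, 1)``.

    Monotone non-increasing in ``x``: stronger binders (small IC50) score
    near 1, non-binders near 0.  Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise InvalidMeasurementError("IC50 must be positive")
    b = np.clip(1.0 - np.log(x) / math.log(IC50_BASE), 0.0, 1.0)
    return float(b) if b.ndim == 0 else b


def denormalize_affinity(b):
    """Inverse of :func:`normalize_affinity` on (0, 1): ``x = 50000**(1-b)``."""
    b = np.asarray(b, dtype=float)
    x = IC50_BASE ** (1.0 - b)
    return float(x) if x.ndim == 0 else x


def affinity_to_level(x: float) -> int:
    """Map IC50 (nM) to the 5-tier binding level.

    Boundary values belong to the stronger-binding level (half-open bands),
    e.g. 100 nM -> level 5, 500 nM -> level 4.
    """
    if x <= 0:
        raise InvalidMeasurementError("IC50 must be positive")
    for level, upper in _LEVEL_UPPER_BOUNDS:
        if x <= upper:
            return level
    return 1


def level_threshold_b(level: int) -> float:
    """Normalized affinity imputed for a qualitative record at ``level``."""
    return normalize_affinity(LEVEL_THRESHOLD_NM[level])


def entry_level(entry: MeasurementEntry) -> int:
    if entry.kind == MeasurementKind.QUANTITATIVE:
        return affinity_to_level(entry.ic50)
    return entry.level


def _normalize_single(entry: MeasurementEntry) -> NormalizedEntry:
    if entry.kind == MeasurementKind.QUANTITATIVE:
        return NormalizedEntry(
            allele=entry.allele,
            peptide=entry.peptide,
            b=normalize_affinity(entry.ic50),
            level=affinity_to_level(entry.ic50),
            kind=MeasurementKind.QUANTITATIVE,
        )
    return NormalizedEntry(
        allele=entry.allele,
        peptide=entry.peptide,
        b=level_threshold_b(entry.level),
        level=entry.level,
        kind=MeasurementKind.QUALITATIVE,
    )


def consolidate_duplicates(entries: Sequence[MeasurementEntry]):
    """Resolve repeated measurements of one (allele, peptide) pair.

    Every entry is mapped to a binding level; a unique plurality level wins.
    The consolidated ``b`` is the normalized mean IC50 of the winning level's
    quantitative members, or the level-threshold ``b`` if the winners are all
    qualitative.  Without a unique plurality the group is conflicting and
    :data:`REMOVED` is returned.
    """
    if not entries:
        raise InvalidMeasurementError("empty measurement group")
    alleles = {e.allele for e in entries}
    peptides = {e.peptide for e in entries}
    if len(alleles) != 1 or len(peptides) != 1:
        raise InvalidMeasurementError("group must share allele and peptide")
    if len(entries) == 1:
        return _normalize_single(entries[0])

    levels = [entry_level(e) for e in entries]
    counts: dict[int, int] = {}
    for lv in levels:
        counts[lv] = counts.get(lv, 0) + 1
    top = max(counts.values())
    winners = [lv for lv, c in counts.items() if c == top]
    if len(winners) != 1:
        return REMOVED
    major = winners[0]

    xs = [
        e.ic50
        for e, lv in zip(entries, levels)
        if lv == major and e.kind == MeasurementKind.QUANTITATIVE
    ]
    allele, peptide = entries[0].allele, entries[0].peptide
    if xs:
        return NormalizedEntry(
            allele=allele,
            peptide=peptide,
            b=normalize_affinity(float(np.mean(xs))),
            level=major,
            kind=MeasurementKind.QUANTITATIVE,
        )
    return NormalizedEntry(
        allele=allele,
        peptide=peptide,
        b=level_threshold_b(major),
        level=major,
        kind=MeasurementKind.QUALITATIVE,
    )


def is_valid_peptide(peptide: str) -> bool:
    return (
        MIN_PEPTIDE_LENGTH <= len(peptide) <= MAX_PEPTIDE_LENGTH
        and set(peptide) <= _AA_SET
    )


def _parse_row(row) -> MeasurementEntry | None:
    peptide = str(row["peptide"]).strip().upper()
    if not is_valid_peptide(peptide):
        logger.warning("dropping invalid peptide %r", peptide)
        return None
    kind = MeasurementKind(str(row["measurement_kind"]).strip().lower())
    value = float(row["measurement_value"])
    if kind == MeasurementKind.QUANTITATIVE:
        return MeasurementEntry(row["allele"], peptide, kind, ic50=value)
    return MeasurementEntry(row["allele"], peptide, kind, level=int(value))


def entries_from_frame(frame: pd.DataFrame) -> list[MeasurementEntry]:
    """Parse a raw table (columns allele/peptide/measurement_kind/
    measurement_value) into entries, dropping malformed peptides."""
    out = []
    for _, row in frame.iterrows():
        entry = _parse_row(row)
        if entry is not None:
            out.append(entry)
    return out


def consolidate_entries(
    entries: Iterable[MeasurementEntry],
) -> tuple[list[NormalizedEntry], list[tuple[str, str]]]:
    """Group entries by (allele, peptide) and consolidate each group.

    Returns the consolidated entries and the list of removed conflicting
    (allele, peptide) pairs.  Output order follows first appearance.
    """
    groups: dict[tuple[str, str], list[MeasurementEntry]] = {}
    order: list[tuple[str, str]] = []
    for e in entries:
        key = (e.allele, e.peptide)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(e)
    kept, removed = [], []
    for key in order:
        result = consolidate_duplicates(groups[key])
        if result is REMOVED:
            removed.append(key)
        else:
            kept.append(result)
    return kept, removed


def normalized_to_frame(entries: Sequence[NormalizedEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "allele": [e.allele for e in entries],
            "peptide": [e.peptide for e in entries],
            "measurement_kind": [e.kind.value for e in entries],
            "b": [e.b for e in entries],
            "level": [e.level for e in entries],
        }
    )


def normalized_from_frame(frame: pd.DataFrame) -> list[NormalizedEntry]:
    return [
        NormalizedEntry(
            allele=row["allele"],
            peptide=row["peptide"],
            b=float(row["b"]),
            level=int(row["level"]),
            kind=MeasurementKind(row["measurement_kind"]),
        )
        for _, row in frame.iterrows()
    ]


def _sniff_sep(path) -> str:
    with open(path) as fh:
        head = fh.readline()
    return "\t" if "\t" in head else ","


def read_affinity_table(path) -> pd.DataFrame:
    """Read a TSV/CSV affinity table with the canonical header columns."""
    frame = pd.read_csv(path, sep=_sniff_sep(path))
    required = {"allele", "peptide", "measurement_kind", "measurement_value"}
    missing = required - set(frame.columns)
    if missing:
        raise InvalidMeasurementError(f"missing columns: {sorted(missing)}")
    return frame


def preprocess_table(
    frame: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full preprocessing: parse, normalize, consolidate.

    Returns (consolidated table with b and level columns, removed-pairs log).
    """
    entries = entries_from_frame(frame)
    kept, removed = consolidate_entries(entries)
    removed_frame = pd.DataFrame(removed, columns=["allele", "peptide"])
    return normalized_to_frame(kept), removed_frame
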
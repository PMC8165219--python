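"""Synthetic per-allele affinity tables with planted ground truth.

The generator emulates the data regime of IEDB-style binding tables: a mix
of quantitative IC50 and qualitative level records over peptides of length
8-15, with injected conflicting duplicates.  Affinity comes from a planted
position-specific scoring profile whose signal lives only at anchor
positions (by default position 2 and the terminal residue, the classic
class-I anchor pattern); a model that recovers the anchors from data
demonstrably learns the planted motif.

Profile frame: a 20 x 15 matrix.  Residue j of an n-mer reads column j,
except the terminal residue which always reads column 15 — so the second
and last positions of every peptide are anchors regardless of length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import (
    AMINO_ACIDS,
    IC50_BASE,
    MeasurementEntry,
    MeasurementKind,
    affinity_to_level,
    denormalize_affinity,
    normalize_affinity,
)

#: Length distribution: all of 8-15 represented, 9-11 most frequent (the
#: empirical mode of class-I binding data).
DEFAULT_LENGTH_WEIGHTS = {
    8: 0.10, 9: 0.30, 10: 0.20, 11: 0.15, 12: 0.09, 13: 0.07, 14: 0.05, 15: 0.04,
}

TERMINAL_COLUMN = 14  # 0-based column read by the terminal residue
ANCHOR_COLUMNS = (1, TERMINAL_COLUMN)  # position 2 and the terminal slot

#: Normalized affinity of the 500 nM positive threshold.
B_500 = normalize_affinity(500.0)


@dataclass
class SyntheticAllele:
    """Planted allele: anchor-only scoring profile plus noise/mix rates."""

    name: str = "SYN-A*01:01"
    profile: np.ndarray | None = None  # (20, 15); built from seed if None
    anchor_columns: tuple[int, ...] = ANCHOR_COLUMNS
    noise_sd: float = 0.05
    qualitative_fraction: float = 0.2
    conflict_rate: float = 0.05
    length_weights: dict = field(default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS))

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for rate in (self.qualitative_fraction, self.conflict_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates must be in [0, 1]")
        for col in self.anchor_columns:
            if not (0 <= col < 15):
                raise ValueError("anchor columns must be within the 15 frame")

    def ensure_profile(self, rng: np.random.Generator) -> np.ndarray:
        if self.profile is None:
            profile = np.zeros((20, 15))
            for col in self.anchor_columns:
                profile[:, col] = rng.normal(0.0, 1.0, 20)
            self.profile = profile
        return self.profile

    def profile_columns_for_length(self, n: int) -> np.ndarray:
        """0-based profile column read by each residue of an n-mer."""
        cols = np.arange(n)
        cols[-1] = TERMINAL_COLUMN
        return cols

    def profile_for_length(self, n: int) -> np.ndarray:
        """The planted 20 x n ground-truth matrix seen by n-mers."""
        return self.profile[:, self.profile_columns_for_length(n)]

    def score_peptide(self, peptide: str) -> float:
        cols = self.profile_columns_for_length(len(peptide))
        idx = [AMINO_ACIDS.index(a) for a in peptide]
        return float(self.profile[idx, cols].sum())


def _sample_peptides(rng, n, length_weights):
    lengths = np.array(sorted(length_weights))
    probs = np.array([length_weights[l] for l in lengths], dtype=float)
    probs /= probs.sum()
    peptides = set()
    aas = np.array(list(AMINO_ACIDS))
    while len(peptides) < n:
        length = int(rng.choice(lengths, p=probs))
        peptides.add("".join(rng.choice(aas, size=length)))
    return sorted(peptides)  # deterministic order given the sample


def generate_dataset(allele: SyntheticAllele, n_peptides: int, seed: int):
    """Emit raw measurement entries plus the ground-truth table.

    True normalized affinity: the profile score is affinely squashed so
    that ~30% of peptides fall below 500 nM, then Gaussian noise of sd
    ``noise_sd`` is added on the normalized scale and the result clamped
    to [0, 1].  IC50 values are emitted through the exact inverse of the
    normalization, so re-normalizing recovers b* wherever unclamped.
    A ``conflict_rate`` fraction of peptides gains a duplicated entry at a
    shifted level, producing an unresolvable two-way vote.

    Returns (entries, truth frame, allele) — the allele carries the
    realized profile.
    """
    if n_peptides < 1:
        raise ValueError("need at least one peptide")
    rng = np.random.default_rng(seed)
    allele.ensure_profile(rng)
    peptides = _sample_peptides(rng, n_peptides, allele.length_weights)
    raw = np.array([allele.score_peptide(p) for p in peptides])
    # affine calibration: 70th percentile -> the 500 nM threshold
    thr = np.quantile(raw, 0.70)
    spread = np.std(raw)
    if spread == 0:
        spread = 1.0
    b_clean = B_500 + (raw - thr) / (4.0 * spread)
    b_true = np.clip(
        b_clean + rng.normal(0.0, allele.noise_sd, len(peptides)), 0.0, 1.0
    )
    # keep b* strictly inside (0, 1) so the IC50 round trip is exact
    b_true = np.clip(b_true, 1e-6, 1.0 - 1e-6)
    ic50 = denormalize_affinity(b_true)
    levels = np.array([affinity_to_level(x) for x in ic50])

    n = len(peptides)
    qualitative = np.zeros(n, dtype=bool)
    n_qual = int(round(allele.qualitative_fraction * n))
    if n_qual:
        qualitative[rng.choice(n, size=n_qual, replace=False)] = True
    conflicted = np.zeros(n, dtype=bool)
    n_conf = int(round(allele.conflict_rate * n))
    if n_conf:
        conflicted[rng.choice(n, size=n_conf, replace=False)] = True

    entries = []
    for i, pep in enumerate(peptides):
        if qualitative[i]:
            entries.append(
                MeasurementEntry(
                    allele.name, pep, MeasurementKind.QUALITATIVE,
                    level=int(levels[i]),
                )
            )
        else:
            entries.append(
                MeasurementEntry(
                    allele.name, pep, MeasurementKind.QUANTITATIVE,
                    ic50=float(ic50[i]),
                )
            )
        if conflicted[i]:
            other = int(levels[i]) + (1 if levels[i] < 5 else -1)
            entries.append(
                MeasurementEntry(
                    allele.name, pep, MeasurementKind.QUALITATIVE, level=other
                )
            )
    truth = pd.DataFrame(
        {
            "peptide": peptides,
            "b_true": b_true,
            "ic50": ic50,
            "level": levels,
            "qualitative": qualitative,
            "conflicted": conflicted,
        }
    )
    return entries, truth, allele


def entries_to_frame(entries) -> pd.DataFrame:
    """Raw entries in the canonical table dialect."""
    return pd.DataFrame(
        {
            "allele": [e.allele for e in entries],
            "peptide": [e.peptide for e in entries],
            "measurement_kind": [e.kind.value for e in entries],
            "measurement_value": [
                e.ic50 if e.kind == MeasurementKind.QUANTITATIVE else e.level
                for e in entries
            ],
        }
    )


def generate_ranked_fixture(n_pos: int, n_neg: int, seed: int):
    """Random scores with known positive/negative affinities, for metric
    property tests."""
    from .metrics import RankedPredictions

    rng = np.random.default_rng(seed)
    b_pos = rng.uniform(B_500 + 1e-6, 1.0, n_pos)
    b_neg = rng.uniform(0.0, B_500 - 1e-6, n_neg)
    b = np.concatenate([b_pos, b_neg])
    scores = rng.normal(0.0, 1.0, n_pos + n_neg)
    levels = np.array([affinity_to_level(denormalize_affinity(v)) for v in b])
    return RankedPredictions(scores=scores, b=b, levels=levels)


def anchor_recovery_dataset(n_peptides: int = 2000, seed: int = 0,
                            noise_sd: float = 0.05):
    """The clean anchor-recovery study conditions: quantitative-only
    entries, no conflicts, anchors at position 2 and the terminus."""
    allele = SyntheticAllele(
        noise_sd=noise_sd, qualitative_fraction=0.0, conflict_rate=0.0
    )
    return generate_dataset(allele, n_peptides, seed)
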
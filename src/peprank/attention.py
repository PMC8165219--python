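"""Attention-weight extraction and motif analysis.

With kernel size 1 the attention weights are per-residue, and summing them
by (amino acid, position) over a peptide set yields a position x amino-acid
matrix SMM_l — the learned analogue of a stabilized-matrix-method (SMM)
scoring matrix.  SMM scores are energies (smaller = preferred) while SMM_l
entries grow with attended frequency, so a well-recovered motif shows a
strongly *negative* Pearson correlation between the two.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .encoding import AA_INDEX, AMINO_ACIDS, PADDED_LENGTH, padded_position_map
from .models import ModelState, attention_weights

logger = logging.getLogger(__name__)


class MotifError(ValueError):
    pass


def collect_attention(peptides, state: ModelState) -> list[np.ndarray]:
    """Evaluation-mode attention profile (one weight per k-mer) per
    peptide; each profile sums to 1."""
    return attention_weights(state, list(peptides))


def smm_like_matrix(profiles, peptides, frame: str = "raw") -> np.ndarray:
    """Accumulate per-residue attention into a 20 x L matrix.

    ``SMM_l[a, j] = sum_p 1(residue a at position j of p) * w_j(p)``.
    Requires kernel size 1 (profile length == peptide length).  With
    ``frame='raw'`` all peptides must share one length L; ``frame='padded'``
    maps positions into the 15-slot middle-padded frame so mixed lengths
    can be pooled.
    """
    peptides = list(peptides)
    profiles = [np.asarray(w, dtype=float) for w in profiles]
    if not peptides:
        raise MotifError("no peptides")
    if len(profiles) != len(peptides):
        raise MotifError("profiles and peptides must align")
    for pep, w in zip(peptides, profiles):
        if len(w) != len(pep):
            raise MotifError(
                "profile length must equal peptide length (kernel size 1)"
            )
    if frame == "raw":
        lengths = {len(p) for p in peptides}
        if len(lengths) != 1:
            raise MotifError("raw frame needs a single peptide length")
        L = lengths.pop()
        out = np.zeros((20, L))
        for pep, w in zip(peptides, profiles):
            for j, a in enumerate(pep):
                out[AA_INDEX[a], j] += w[j]
        return out
    if frame == "padded":
        out = np.zeros((20, PADDED_LENGTH))
        for pep, w in zip(peptides, profiles):
            cols = padded_position_map(pep)
            for j, a in enumerate(pep):
                out[AA_INDEX[a], cols[j]] += w[j]
        return out
    raise MotifError(f"unknown frame {frame!r}")


def motif_correlation(smm_l, external_smm, columns=None) -> float:
    """Pearson correlation between the flattened matrices (optionally a
    column subset, e.g. anchor positions only)."""
    smm_l = np.asarray(smm_l, dtype=float)
    external_smm = np.asarray(external_smm, dtype=float)
    if columns is not None:
        smm_l = smm_l[:, columns]
        external_smm = external_smm[:, columns]
    if smm_l.shape != external_smm.shape:
        raise MotifError("matrices must share shape after column selection")
    a = smm_l.ravel()
    e = external_smm.ravel()
    if np.std(a) == 0 or np.std(e) == 0:
        raise MotifError("zero variance: correlation undefined")
    return float(stats.pearsonr(a, e)[0])


def matrix_to_frame(matrix: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        matrix,
        index=list(AMINO_ACIDS),
        columns=[f"pos{j+1}" for j in range(matrix.shape[1])],
    )


def read_matrix_tsv(path) -> np.ndarray:
    """20 x L matrix from TSV with amino-acid row index."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame = frame.reindex(list(AMINO_ACIDS))
    if frame.isna().any().any():
        raise MotifError("matrix must cover the 20 canonical amino acids")
    return frame.to_numpy(dtype=float)
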
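"""Residue encodings, dual-end position embeddings and peptide feature
matrices.

A peptide ``p = [a_1, ..., a_n]`` (8 <= n <= 15) is represented column-wise:
column j concatenates the residue encoding ``e_j`` (BLOSUM62 row, one-hot,
and/or a learned 20-dim table, in declared order) with two learned position
vectors — one indexed by the offset from one end (``c_table[j]``), one by
the offset from the opposite end (``n_table[n+1-j]``) — so that models see
both absolute and end-anchored position information across variable
lengths.

For global kernels, peptides are middle-padded to length 15 in the
MHCflurry convention (first/last four residues fixed, pads in the centre)
and encoded without position vectors; pad slots are all-zero columns.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

from .preprocessing import (
    AMINO_ACIDS,
    MAX_PEPTIDE_LENGTH,
    MIN_PEPTIDE_LENGTH,
)

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
PAD_CHAR = "X"
PADDED_LENGTH = 15

VALID_COMPONENTS = ("blosum", "onehot", "deep")


class EncodingError(ValueError):
    pass


def _load_blosum62() -> np.ndarray:
    """20x20 BLOSUM62 over the canonical alphabet, raw integer scores."""
    text = (
        importlib.resources.files("peprank.data")
        .joinpath("blosum62.txt")
        .read_text()
    )
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split()
    rows = {}
    for ln in lines[1:]:
        parts = ln.split()
        rows[parts[0]] = {h: float(v) for h, v in zip(header, parts[1:])}
    mat = np.zeros((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            mat[i, j] = rows[a][b]
    return mat


BLOSUM62 = _load_blosum62()
ONEHOT = np.eye(20)


@dataclass(frozen=True)
class EncodingScheme:
    """Ordered combination of residue encodings; total dim is 20 each."""

    components: tuple[str, ...] = ("blosum",)

    def __post_init__(self):
        if not self.components:
            raise EncodingError("scheme needs at least one component")
        for c in self.components:
            if c not in VALID_COMPONENTS:
                raise EncodingError(f"unknown encoding component {c!r}")
        if len(set(self.components)) != len(self.components):
            raise EncodingError("duplicate encoding component")

    @property
    def d_e(self) -> int:
        return 20 * len(self.components)

    @property
    def uses_deep(self) -> bool:
        return "deep" in self.components

    @classmethod
    def parse(cls, spec) -> "EncodingScheme":
        """Accept 'blosum+onehot+deep' strings, iterables, or schemes."""
        if isinstance(spec, EncodingScheme):
            return spec
        if isinstance(spec, str):
            parts = tuple(s.strip().lower() for s in spec.split("+"))
        else:
            parts = tuple(str(s).strip().lower() for s in spec)
        return cls(parts)


@dataclass
class PositionEmbeddingTable:
    """Two learnable 15-row tables of dual-end position vectors."""

    c_table: np.ndarray  # (15, d_o), row j-1 = offset j from one end
    n_table: np.ndarray  # (15, d_o), row j-1 = offset j from the other end

    def __post_init__(self):
        if self.c_table.shape != self.n_table.shape:
            raise EncodingError("position tables must share shape")
        if self.c_table.shape[0] != MAX_PEPTIDE_LENGTH:
            raise EncodingError("position tables must have 15 rows")

    @property
    def d_o(self) -> int:
        return self.c_table.shape[1]

    @classmethod
    def random(cls, d_o: int, rng: np.random.Generator, scale: float = 0.1):
        return cls(
            c_table=rng.normal(0.0, scale, (MAX_PEPTIDE_LENGTH, d_o)),
            n_table=rng.normal(0.0, scale, (MAX_PEPTIDE_LENGTH, d_o)),
        )


def peptide_indices(peptide: str) -> np.ndarray:
    try:
        return np.array([AA_INDEX[a] for a in peptide], dtype=np.intp)
    except KeyError as exc:
        raise EncodingError(f"unknown residue {exc.args[0]!r}") from None


def _check_length(peptide: str):
    if not (MIN_PEPTIDE_LENGTH <= len(peptide) <= MAX_PEPTIDE_LENGTH):
        raise EncodingError(
            f"peptide length {len(peptide)} outside "
            f"[{MIN_PEPTIDE_LENGTH}, {MAX_PEPTIDE_LENGTH}]"
        )


def fixed_encoding_matrix(scheme: EncodingScheme) -> np.ndarray:
    """Stacked non-learnable encoding rows, (d_fixed, 20) column-per-residue.

    Deep components are excluded; they live in the model state.
    """
    blocks = []
    for c in scheme.components:
        if c == "blosum":
            blocks.append(BLOSUM62.T)
        elif c == "onehot":
            blocks.append(ONEHOT.T)
    if not blocks:
        return np.zeros((0, 20))
    return np.vstack(blocks)


def encode_residue(
    a: str, scheme: EncodingScheme, deep_table: np.ndarray | None = None
) -> np.ndarray:
    """Encoding vector of one residue, components concatenated in order."""
    if a not in AA_INDEX:
        raise EncodingError(f"unknown residue {a!r}")
    i = AA_INDEX[a]
    parts = []
    for c in scheme.components:
        if c == "blosum":
            parts.append(BLOSUM62[i])
        elif c == "onehot":
            parts.append(ONEHOT[i])
        else:
            if deep_table is None:
                raise EncodingError("deep component requires a deep table")
            parts.append(deep_table[i])
    return np.concatenate(parts)


def encode_peptide(
    peptide: str, scheme: EncodingScheme, deep_table: np.ndarray | None = None
) -> np.ndarray:
    """Residue-encoding block, shape (d_e, n), in component order."""
    idx = peptide_indices(peptide)
    parts = []
    for c in scheme.components:
        if c == "blosum":
            parts.append(BLOSUM62[idx].T)
        elif c == "onehot":
            parts.append(ONEHOT[idx].T)
        else:
            if deep_table is None:
                raise EncodingError("deep component requires a deep table")
            parts.append(deep_table[idx].T)
    return np.vstack(parts)


def build_feature_matrix(
    peptide: str,
    scheme: EncodingScheme,
    positions: PositionEmbeddingTable | None,
    deep_table: np.ndarray | None = None,
) -> np.ndarray:
    """Feature matrix F, shape (d_e + 2*d_o, n); column j = [e_j; o_j; o_-j].

    With ``positions=None`` (ablation) the position block is omitted and the
    shape is (d_e, n).
    """
    _check_length(peptide)
    enc = encode_peptide(peptide, scheme, deep_table)
    if positions is None:
        return enc
    n = len(peptide)
    pc = positions.c_table[:n].T  # o_j, offset from the first end
    pn = positions.n_table[:n][::-1].T  # o_-j, offset n+1-j from the other
    return np.vstack([enc, pc, pn])


def pad_middle(peptide: str) -> str:
    """Middle-pad to 15 characters with 'X', MHCflurry style.

    The first and last four residues keep their terminal positions; the
    middle n-8 residues sit in the central block with floor-split pads on
    the left and the remainder on the right.
    """
    _check_length(peptide)
    n = len(peptide)
    middle = peptide[4 : n - 4]
    n_pad = 7 - len(middle)
    left = n_pad // 2
    right = n_pad - left
    return (
        peptide[:4]
        + PAD_CHAR * left
        + middle
        + PAD_CHAR * right
        + peptide[n - 4 :]
    )


def build_global_feature_matrix(
    peptide: str, scheme: EncodingScheme, deep_table: np.ndarray | None = None
) -> np.ndarray:
    """Padded global-input matrix F_G, shape (d_e, 15), zero pad columns."""
    padded = pad_middle(peptide)
    out = np.zeros((scheme.d_e, PADDED_LENGTH))
    for j, a in enumerate(padded):
        if a != PAD_CHAR:
            out[:, j] = encode_residue(a, scheme, deep_table)
    return out


def padded_position_map(peptide: str) -> np.ndarray:
    """For residue j (0-based) of ``peptide``, its column in the padded
    15-slot frame."""
    padded = pad_middle(peptide)
    return np.array([j for j, a in enumerate(padded) if a != PAD_CHAR], dtype=np.intp)


def read_fasta_peptides(path) -> list[str]:
    """Peptide list from a FASTA file (sequences uppercased)."""
    from Bio import SeqIO

    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
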
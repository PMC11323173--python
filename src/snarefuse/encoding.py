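"""Numeric representations of protein sequences.

Covers integer residue codes, the substitution-matrix pseudo-PSSM (a
self-contained stand-in for PSI-BLAST profiles), PSSM normalization to
[0, 1], the M x 40 augmented profile, the 400-D residue-by-column
composition vector, and hashed n-gram ("bag of subwords") embedding inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio.Align import substitution_matrices

from .sequence_io import (
    ALPHABET,
    CANONICAL_ORDER,
    MASK,
    PSSMatrix,
    ProteinSequence,
    RESIDUE_INDEX,
)


@dataclass
class EncodedSequence:
    """Integer residue codes (A=0 .. V=19, X=20) for one sequence."""

    codes: np.ndarray
    sequence_id: str = ""

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 1 or self.codes.size < 1:
            raise ValueError("codes must be a non-empty 1-D integer array")
        if self.codes.min() < 0 or self.codes.max() > 20:
            raise ValueError("residue codes must lie in [0, 20]")

    @property
    def m(self) -> int:
        return self.codes.size


def encode_residues(seq: ProteinSequence) -> EncodedSequence:
    """Map a canonicalized sequence to integer codes in canonical order."""
    try:
        codes = np.fromiter(
            (RESIDUE_INDEX[ch] for ch in seq.residues), dtype=np.int64
        )
    except KeyError as exc:  # unreachable after canonicalization
        raise ValueError(f"character outside alphabet: {exc.args[0]!r}") from exc
    return EncodedSequence(codes=codes, sequence_id=seq.id)


def blosum62_table() -> np.ndarray:
    """21 x 20 substitution table: BLOSUM62 rows over canonical targets.

    Row index = residue code (the X row, code 20, is all zeros so masked
    positions carry no profile signal).
    """
    blosum = substitution_matrices.load("BLOSUM62")
    table = np.zeros((21, 20), dtype=float)
    for a, aa in enumerate(CANONICAL_ORDER):
        for b, bb in enumerate(CANONICAL_ORDER):
            table[a, b] = blosum[aa, bb]
    return table


def compute_pseudo_pssm(
    seq: ProteinSequence, substitution_table: Optional[np.ndarray] = None
) -> PSSMatrix:
    """Profile stand-in: row i = substitution-table row of residue i.

    Defaults to BLOSUM62.  The result has the same M x 20 shape and
    log-odds character as a PSI-BLAST PSSM, but carries no evolutionary
    information beyond the residue identity.
    """
    if substitution_table is None:
        substitution_table = blosum62_table()
    substitution_table = np.asarray(substitution_table, dtype=float)
    if substitution_table.shape != (21, 20):
        raise ValueError("substitution_table must be 21 x 20")
    codes = encode_residues(seq).codes
    return PSSMatrix(sequence_id=seq.id, scores=substitution_table[codes])


def normalize_pssm(pssm: PSSMatrix, mode: str = "logistic") -> PSSMatrix:
    """Squash PSSM scores into [0, 1].

    ``logistic``      x -> 1 / (1 + exp(-x))   (elementwise, bounded).
    ``length_scaled`` x -> x / M, then min-max rescale of the whole matrix
                      to [0, 1]; a constant matrix maps to all 0.5.
    """
    x = pssm.scores
    if mode == "logistic":
        out = 1.0 / (1.0 + np.exp(-x))
    elif mode == "length_scaled":
        scaled = x / pssm.m
        lo, hi = scaled.min(), scaled.max()
        if hi == lo:
            out = np.full_like(scaled, 0.5)
        else:
            out = (scaled - lo) / (hi - lo)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return PSSMatrix(sequence_id=pssm.sequence_id, scores=out)


@dataclass
class AugmentedPSSM:
    """M x 40 profile: original PSSM beside its row-reversed copy."""

    combined: np.ndarray
    sequence_id: str = ""

    def __post_init__(self) -> None:
        self.combined = np.asarray(self.combined, dtype=float)
        if self.combined.ndim != 2 or self.combined.shape[1] != 40:
            raise ValueError("combined matrix must have exactly 40 columns")

    @property
    def left(self) -> np.ndarray:
        return self.combined[:, :20]

    @property
    def right(self) -> np.ndarray:
        return self.combined[:, 20:]


def augment_pssm(pssm: PSSMatrix) -> AugmentedPSSM:
    """P_com = [A | A'], where A' is A with row order reversed.

    The reversed block gives every position a view of the profile of the
    mirrored position, a deterministic augmentation of the sequence
    profile; applying the reversal to the right block recovers A.
    """
    a = pssm.scores
    return AugmentedPSSM(
        combined=np.concatenate([a, a[::-1]], axis=1),
        sequence_id=pssm.sequence_id,
    )


def pssm_to_400(seq: EncodedSequence, pssm: PSSMatrix) -> np.ndarray:
    """Length-normalized 400-D composition vector.

    Entry (a, b) = (1/M) * sum over positions i with code a of pssm[i, b];
    masked positions (code 20) contribute nothing.  With a [0, 1] PSSM all
    entries stay in [0, 1].  Flattened row-major: index = 20 * a + b.
    """
    if pssm.m != seq.m:
        raise ValueError(
            f"sequence length {seq.m} != PSSM rows {pssm.m} "
            f"for {seq.sequence_id!r}"
        )
    vec = np.zeros((20, 20), dtype=float)
    keep = seq.codes < 20
    np.add.at(vec, seq.codes[keep], pssm.scores[keep])
    return (vec / seq.m).reshape(400)


# ---------------------------------------------------------------------------
# Hashed n-gram embedding inputs (bag-of-subwords, fastText-style)
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingConfig:
    """Hashed character n-gram embedding configuration.

    The embedding table itself is learnable (trained jointly with the
    model); n-grams are bucketed by a fixed seed-independent hash so two
    runs always agree on which row an n-gram uses.
    """

    ngram_orders: frozenset = frozenset({1, 2, 3})
    embedding_dim: int = 64
    hash_buckets: int = 1024
    seed: int = 0

    def __post_init__(self) -> None:
        self.ngram_orders = frozenset(int(n) for n in self.ngram_orders)
        if 1 not in self.ngram_orders:
            raise ValueError("ngram_orders must contain 1 (unigrams)")
        if min(self.ngram_orders) < 1:
            raise ValueError("n-gram orders must be positive")
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")
        if self.hash_buckets < 1:
            raise ValueError("hash_buckets must be positive")


_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3


def ngram_hash(gram: str, buckets: int) -> int:
    """Deterministic FNV-1a (64-bit) hash of an n-gram string, mod buckets."""
    h = _FNV_OFFSET
    for byte in gram.encode("utf-8"):
        h ^= byte
        h = (h * _FNV_PRIME) & 0xFFFFFFFFFFFFFFFF
    return h % buckets


def ngram_ids(residues: str, config: EmbeddingConfig) -> np.ndarray:
    """Per-position table row ids: the unigram at i plus every higher-order
    n-gram ending at i.

    Returns an M x G int array (G = number of orders), with -1 where an
    n-gram does not fit (position too close to the start).
    """
    orders = sorted(config.ngram_orders)
    m = len(residues)
    ids = np.full((m, len(orders)), -1, dtype=np.int64)
    for i in range(m):
        for j, n in enumerate(orders):
            if i + 1 >= n:
                ids[i, j] = ngram_hash(residues[i - n + 1 : i + 1],
                                       config.hash_buckets)
    return ids


def init_embedding_table(config: EmbeddingConfig) -> np.ndarray:
    """Gaussian-initialized hash_buckets x embedding_dim table (seeded)."""
    rng = np.random.default_rng(config.seed)
    scale = 1.0 / np.sqrt(config.embedding_dim)
    return rng.normal(0.0, scale, size=(config.hash_buckets,
                                        config.embedding_dim))


def embed_ngrams(
    seq: EncodedSequence | ProteinSequence,
    config: EmbeddingConfig,
    table: np.ndarray,
) -> np.ndarray:
    """Mean of table rows for all n-grams ending at each position (M x dim)."""
    if isinstance(seq, ProteinSequence):
        residues = seq.residues
    else:
        residues = "".join(ALPHABET[c] for c in seq.codes)
    table = np.asarray(table, dtype=float)
    if table.shape[0] != config.hash_buckets:
        raise ValueError("embedding table row count != hash_buckets")
    ids = ngram_ids(residues, config)
    valid = ids >= 0
    rows = table[np.where(valid, ids, 0)]          # M x G x dim
    rows = rows * valid[:, :, None]
    return rows.sum(axis=1) / valid.sum(axis=1, keepdims=True)


def export_feature_table(
    ids: list[str], vectors: np.ndarray, path
) -> None:
    """Write a TSV: one row per sequence, id + feature values."""
    vectors = np.asarray(vectors)
    with open(path, "w") as fh:
        ncol = vectors.shape[1]
        fh.write("id\t" + "\t".join(f"f{i}" for i in range(ncol)) + "\n")
        for sid, row in zip(ids, vectors):
            fh.write(sid + "\t" + "\t".join(f"{v:.8g}" for v in row) + "\n")
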
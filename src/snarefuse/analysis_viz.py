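"""Descriptive analyses: per-class amino-acid frequency profiles,
alignment-free k-mer similarity, and 2-D t-SNE projection of learned
features."""

from __future__ import annotations

from collections import Counter
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .sequence_io import CANONICAL_ORDER, MASK, ProteinSequence


class AnalysisError(ValueError):
    """Raised for ill-posed analysis requests."""


def aa_frequency_profile(
    records: Sequence[ProteinSequence],
) -> dict[int, np.ndarray]:
    """Pooled relative residue frequencies per class (X excluded).

    Returns {label: 20-vector in canonical order summing to 1}.
    """
    counts = {0: np.zeros(20), 1: np.zeros(20)}
    seen = {0: False, 1: False}
    index = {aa: i for i, aa in enumerate(CANONICAL_ORDER)}
    for rec in records:
        if rec.label is None:
            raise AnalysisError(f"record {rec.id!r} has no label")
        seen[rec.label] = True
        for ch, n in Counter(rec.residues).items():
            if ch != MASK:
                counts[rec.label][index[ch]] += n
    out = {}
    for lab in (0, 1):
        if not seen[lab]:
            raise AnalysisError(f"no sequences for class {lab}")
        total = counts[lab].sum()
        if total == 0:
            raise AnalysisError(f"class {lab} has no countable residues")
        out[lab] = counts[lab] / total
    return out


def _kmer_counts(residues: str, k: int) -> Counter:
    return Counter(residues[i:i + k] for i in range(len(residues) - k + 1))


def pairwise_similarity(a: ProteinSequence, b: ProteinSequence,
                        k: int = 3) -> float:
    """Cosine similarity of k-mer count vectors (alignment-free).

    1.0 for identical sequences, 0.0 for disjoint k-mer sets.
    """
    if len(a) < k or len(b) < k:
        raise AnalysisError(f"both sequences must be at least {k} residues")
    ca, cb = _kmer_counts(a.residues, k), _kmer_counts(b.residues, k)
    dot = sum(ca[g] * cb[g] for g in ca.keys() & cb.keys())
    na = np.sqrt(sum(v * v for v in ca.values()))
    nb = np.sqrt(sum(v * v for v in cb.values()))
    return float(dot / (na * nb))


def similarity_matrix(records: Sequence[ProteinSequence],
                      k: int = 3) -> np.ndarray:
    """Symmetric all-pairs k-mer cosine similarity."""
    n = len(records)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = pairwise_similarity(records[i],
                                                        records[j], k)
    return sim


def project_features(features: np.ndarray, method: str = "tsne",
                     seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    """2-D t-SNE embedding of n feature vectors (perplexity clipped to
    (n - 1) / 3); deterministic given the seed."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] < 5:
        raise AnalysisError("need at least 5 feature vectors to project")
    if method != "tsne":
        raise AnalysisError(f"unknown projection method {method!r}")
    n = features.shape[0]
    perplexity = min(perplexity, (n - 1) / 3)
    tsne = TSNE(n_components=2, perplexity=perplexity, init="pca",
                random_state=int(seed) % (2 ** 31))
    return tsne.fit_transform(features)


def projection_table(ids: Sequence[str], coords: np.ndarray,
                     labels: Optional[Sequence[int]] = None) -> pd.DataFrame:
    """Tidy (id, x, y, label) table for plotting / TSV export."""
    coords = np.asarray(coords)
    df = pd.DataFrame({"id": list(ids), "x": coords[:, 0], "y": coords[:, 1]})
    if labels is not None:
        df["label"] = list(labels)
    return df


def plot_projection(df: pd.DataFrame, path) -> None:
    """Scatter the 2-D projection, colored by class if labels exist."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    if "label" in df.columns:
        for lab, marker, name in ((0, "o", "non-SNARE"), (1, "^", "SNARE")):
            sub = df[df["label"] == lab]
            ax.scatter(sub["x"], sub["y"], s=12, marker=marker, label=name,
                       alpha=0.7)
        ax.legend()
    else:
        ax.scatter(df["x"], df["y"], s=12, alpha=0.7)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
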
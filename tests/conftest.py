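"""Shared fixtures: programmatic FASTA / PSSM fixtures and tiny datasets."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import snarefuse as sf
from snarefuse.encoding import EmbeddingConfig
from snarefuse.fusion_model import (
    BiLSTMConfig,
    ConvBranchConfig,
    ModelConfig,
    RBFLayerConfig,
)
from snarefuse.sequence_io import CANONICAL_ORDER

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


def make_pssm_text(matrix: np.ndarray, residues: str,
                   layout: str = "classic") -> str:
    """Render an M x 20 integer matrix as PSI-BLAST ASCII PSSM text.

    ``classic`` = 40 numeric columns (log-odds + percentages) plus the
    two trailing statistics; ``short`` = only the 20 log-odds columns.
    """
    matrix = np.asarray(matrix)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + "  ".join(CANONICAL_ORDER) + "   "
        + "  ".join(CANONICAL_ORDER),
    ]
    rng = np.random.default_rng(0)
    for i, row in enumerate(matrix, 1):
        fields = [f"{i:5d} {residues[i - 1]}"]
        fields += [f"{int(v):4d}" for v in row]
        if layout == "classic":
            fields += [f"{int(v):4d}" for v in rng.integers(0, 100, 20)]
            fields += ["  0.36", "  0.12"]
        lines.append(" ".join(fields))
    lines += ["", "                      K         Lambda", ""]
    return "\n".join(lines) + "\n"


@pytest.fixture
def pssm_file(tmp_path):
    def _make(matrix, residues, layout="classic", name="seq.pssm"):
        path = tmp_path / name
        path.write_text(make_pssm_text(matrix, residues, layout))
        return path

    return _make


@pytest.fixture
def tiny_model_config():
    """Smallest config that still exercises every layer."""
    return ModelConfig(
        embedding=EmbeddingConfig(embedding_dim=6, hash_buckets=32),
        conv=ConvBranchConfig(num_filters=4, kernel_sizes=(3,),
                              dropout_rate=0.0, embedding_dim=6),
        rbf=RBFLayerConfig(num_centers=3),
        bilstm=BiLSTMConfig(hidden_size=4),
    )


@pytest.fixture
def toy_dataset():
    """20 short, easily separable sequences (exact motif, uniform bg)."""
    cfg = sf.GeneratorConfig(n_positive=10, n_negative=10,
                             length_range=(25, 35), seed=7)
    records, truth = sf.generate_dataset(cfg, sf.MotifSpec(mutation_rate=0.0))
    return records, truth


@pytest.fixture(scope="session")
def easy_benchmark():
    """Small separable benchmark shared by training-behaviour tests."""
    cfg = sf.GeneratorConfig(n_positive=40, n_negative=40,
                             length_range=(40, 60), seed=5)
    records, truth = sf.generate_dataset(cfg,
                                         sf.MotifSpec(mutation_rate=0.05))
    return records, truth
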
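"""Synthetic SNARE-like benchmark generator.

Positives are background sequences with one degenerate planted motif — a
16-residue coiled-coil-like heptad pattern with a central glutamine
anchor, echoing the Q-SNARE zero-layer — at a uniformly chosen interior
position; negatives are background only.  Background residue
frequencies, motif mutation rate, lengths, and class sizes are all
configurable, and the full dataset is a pure function of (config, motif,
seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .sequence_io import CANONICAL_ORDER, ProteinSequence, write_fasta

#: Default planted consensus: hydrophobic heptad-like 16-mer with a
#: central Q anchor (positions follow an LxxLLxQL-style repeat).
DEFAULT_CONSENSUS = "LVKLLEQLSVLLDKLL"

#: Swiss-Prot-style natural amino-acid frequencies (canonical order
#: A R N D C Q E G H I L K M F P S T W Y V), renormalized to sum to 1.
NATURAL_AA_FREQS = np.array([
    0.0826, 0.0553, 0.0406, 0.0546, 0.0137, 0.0393, 0.0674, 0.0708,
    0.0227, 0.0593, 0.0965, 0.0582, 0.0241, 0.0386, 0.0474, 0.0660,
    0.0535, 0.0110, 0.0292, 0.0686,
])
NATURAL_AA_FREQS = NATURAL_AA_FREQS / NATURAL_AA_FREQS.sum()

#: Interior margin: plants never start in the first/last 2 residues.
_EDGE_MARGIN = 2


class GeneratorError(ValueError):
    """Invalid generator configuration."""


@dataclass
class MotifSpec:
    """Degenerate planted motif: consensus + per-position mutation rate."""

    consensus: str = DEFAULT_CONSENSUS
    mutation_rate: float = 0.1
    placement: str = "uniform_interior"

    def __post_init__(self) -> None:
        self.consensus = self.consensus.upper()
        if len(self.consensus) < 4:
            raise GeneratorError("consensus must be at least 4 residues")
        if any(ch not in CANONICAL_ORDER for ch in self.consensus):
            raise GeneratorError("consensus must use the 20-letter alphabet")
        if not (0.0 <= self.mutation_rate < 1.0):
            raise GeneratorError("mutation_rate must lie in [0, 1)")
        if self.placement != "uniform_interior":
            raise GeneratorError("only uniform_interior placement is supported")


@dataclass
class GeneratorConfig:
    """Two-class dataset layout: sizes, lengths, background composition."""

    n_positive: int = 300
    n_negative: int = 300
    length_range: tuple = (80, 120)
    background_freqs: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positive < 1 or self.n_negative < 1:
            raise GeneratorError("n_positive and n_negative must be positive")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise GeneratorError("length_range must satisfy 1 <= min <= max")
        self.length_range = (int(lo), int(hi))
        if self.background_freqs is None:
            self.background_freqs = np.full(20, 0.05)
        self.background_freqs = np.asarray(self.background_freqs, dtype=float)
        if self.background_freqs.shape != (20,) or \
                np.any(self.background_freqs < 0):
            raise GeneratorError("background_freqs must be 20 nonnegative reals")
        if abs(self.background_freqs.sum() - 1.0) > 1e-9:
            raise GeneratorError("background_freqs must sum to 1")

    def to_dict(self) -> dict:
        return {
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "length_range": list(self.length_range),
            "background_freqs": self.background_freqs.tolist(),
            "seed": self.seed,
        }


def sample_background(length: int, freqs: np.ndarray,
                      rng: np.random.Generator) -> str:
    """i.i.d. residues from the background distribution."""
    if length < 1:
        raise GeneratorError("length must be >= 1")
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (20,) or np.any(freqs < 0) or \
            abs(freqs.sum() - 1.0) > 1e-9:
        raise GeneratorError("freqs must be 20 nonnegative reals summing to 1")
    codes = rng.choice(20, size=length, p=freqs)
    return "".join(CANONICAL_ORDER[c] for c in codes)


def plant_motif(background: str, motif: MotifSpec,
                rng: np.random.Generator) -> tuple[str, int]:
    """Overwrite a mutated copy of the consensus at an interior start.

    Each consensus position independently mutates to a uniformly chosen
    *different* residue with probability ``mutation_rate``.  Returns the
    new sequence and the 0-based start.  The start is uniform over
    interior positions (excluding the first/last 2 residues where room
    permits).
    """
    L, w = len(background), len(motif.consensus)
    if L < w:
        raise GeneratorError("background shorter than the motif")
    lo = min(_EDGE_MARGIN, L - w)
    hi = max(lo, L - w - _EDGE_MARGIN)
    start = int(rng.integers(lo, hi + 1))
    instance = []
    for ch in motif.consensus:
        if rng.random() < motif.mutation_rate:
            alt = CANONICAL_ORDER.replace(ch, "")
            instance.append(alt[rng.integers(len(alt))])
        else:
            instance.append(ch)
    seq = background[:start] + "".join(instance) + background[start + w:]
    return seq, start


def generate_dataset(
    config: GeneratorConfig, motif: Optional[MotifSpec] = None
) -> tuple[list[ProteinSequence], pd.DataFrame]:
    """Labeled records plus a truth table (id, label, motif_start).

    Positives are ids ``pos_i`` with label 1 and a recorded motif start;
    negatives are ``neg_i`` with label 0 and start -1.  Deterministic per
    seed.
    """
    motif = motif or MotifSpec()
    lo, hi = config.length_range
    if lo < len(motif.consensus):
        raise GeneratorError("min length must cover the motif")
    rng = np.random.default_rng(config.seed)
    records: list[ProteinSequence] = []
    truth_rows = []
    for i in range(config.n_positive):
        length = int(rng.integers(lo, hi + 1))
        seq, start = plant_motif(
            sample_background(length, config.background_freqs, rng),
            motif, rng)
        rec_id = f"pos_{i}"
        records.append(ProteinSequence(rec_id, seq, 1))
        truth_rows.append({"id": rec_id, "label": 1, "motif_start": start})
    for i in range(config.n_negative):
        length = int(rng.integers(lo, hi + 1))
        seq = sample_background(length, config.background_freqs, rng)
        rec_id = f"neg_{i}"
        records.append(ProteinSequence(rec_id, seq, 0))
        truth_rows.append({"id": rec_id, "label": 0, "motif_start": -1})
    return records, pd.DataFrame(truth_rows)


def write_dataset(records, truth: pd.DataFrame, out_dir,
                  config: Optional[GeneratorConfig] = None,
                  motif: Optional[MotifSpec] = None) -> dict:
    """Write data.fasta + truth.tsv (+ config echo) into a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / "data.fasta"
    write_fasta(records, fasta)
    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    paths = {"fasta": str(fasta), "truth": str(truth_path)}
    if config is not None:
        echo = {"generator": config.to_dict()}
        if motif is not None:
            echo["motif"] = {
                "consensus": motif.consensus,
                "mutation_rate": motif.mutation_rate,
                "placement": motif.placement,
            }
        cfg_path = out_dir / "generator_config.json"
        with open(cfg_path, "w") as fh:
            json.dump(echo, fh, indent=2)
        paths["config"] = str(cfg_path)
    return paths
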
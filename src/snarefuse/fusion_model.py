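"""The hybrid CNN + RBF + Bi-LSTM feature-fusion classifier.

The full pipeline is ``BiLSTM(CNN+RBF(Embedding(Encoding(seq))))``: each
residue position gets a hashed n-gram embedding concatenated with its
normalized augmented profile row (M x 40), a bank of 1-D convolutions
extracts per-position features, an RBF layer measures kernel similarity
to learnable centers in CNN-feature space, the two blocks are fused by
concatenation, and a bidirectional LSTM with a softmax head produces the
SNARE / non-SNARE decision.  Ablation baselines (plain CNN, LSTM,
CNN+RNN, CNN+Bi-LSTM) share the same encoding front-end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans

from . import _nn
from ._nn import (
    Adam,
    ConvBank,
    Dense,
    LSTM,
    NgramEmbedding,
    RBFLayer,
    SimpleRNN,
    relu,
    reverse_indices,
    softmax,
)
from .encoding import (
    EmbeddingConfig,
    augment_pssm,
    compute_pseudo_pssm,
    encode_residues,
    ngram_ids,
    normalize_pssm,
)
from .sequence_io import ProteinSequence, PSSMatrix


class ConfigurationError(ValueError):
    """Invalid model / layer configuration."""


class StateError(RuntimeError):
    """Checkpoint or parameter state inconsistent with the request."""


# ---------------------------------------------------------------------------
# Configurations
# ---------------------------------------------------------------------------

@dataclass
class ConvBranchConfig:
    """Convolutional feature-extraction branch.

    Parallel 1-D convolutions (one per kernel size), each with
    ``num_filters`` filters, ReLU, and dropout active only in training.
    """

    num_filters: int = 64
    kernel_sizes: tuple = (3, 5, 7)
    dropout_rate: float = 0.3
    embedding_dim: int = 64

    def __post_init__(self) -> None:
        self.kernel_sizes = tuple(int(k) for k in self.kernel_sizes)
        if any(k < 1 or k % 2 == 0 for k in self.kernel_sizes):
            raise ConfigurationError("kernel sizes must be odd and positive")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigurationError("dropout_rate must lie in [0, 1)")
        if self.num_filters < 1 or self.embedding_dim < 1:
            raise ConfigurationError("filter count / embedding dim must be >= 1")


@dataclass
class RBFLayerConfig:
    """Radial-basis-function layer: k centers + a kernel of the distance.

    gamma is the Gaussian width (phi(s) = exp(-gamma s^2)); sigma the
    quadratic-kernel width (p(r) = 1 - r^2/sigma).  ``centers`` may be
    preset; otherwise they come from k-means over CNN features.
    """

    num_centers: int = 32
    kernel: str = "gaussian"
    gamma: float = 1.0
    sigma: Optional[float] = None
    centers: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.kernel not in ("gaussian", "quadratic"):
            raise ConfigurationError(f"unknown RBF kernel {self.kernel!r}")
        if self.num_centers < 1:
            raise ConfigurationError("num_centers must be >= 1")
        if self.gamma <= 0:
            raise ConfigurationError("gamma must be positive")
        if self.sigma is not None and self.sigma <= 0:
            raise ConfigurationError("sigma must be positive")


@dataclass
class BiLSTMConfig:
    """Bidirectional LSTM classifier head configuration."""

    hidden_size: int = 64

    def __post_init__(self) -> None:
        if self.hidden_size < 1:
            raise ConfigurationError("hidden_size must be >= 1")


@dataclass
class ModelConfig:
    """Everything that determines the forward function besides the weights."""

    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    conv: ConvBranchConfig = field(default_factory=ConvBranchConfig)
    rbf: RBFLayerConfig = field(default_factory=RBFLayerConfig)
    bilstm: BiLSTMConfig = field(default_factory=BiLSTMConfig)
    use_pssm_features: bool = True
    pssm_normalization: str = "logistic"
    pooling: str = "mean"             # or "final"
    rbf_input: str = "per_position"   # or "pooled"
    max_length: int = 1000

    def __post_init__(self) -> None:
        if self.pooling not in ("final", "mean"):
            raise ConfigurationError("pooling must be 'final' or 'mean'")
        if self.rbf_input not in ("per_position", "pooled"):
            raise ConfigurationError(
                "rbf_input must be 'per_position' or 'pooled'")
        if self.max_length < 1:
            raise ConfigurationError("max_length must be >= 1")

    @classmethod
    def desk_scale(cls) -> "ModelConfig":
        """Compact profile for laptop-scale experiments and benchmarks."""
        return cls(
            embedding=EmbeddingConfig(embedding_dim=32, hash_buckets=512),
            conv=ConvBranchConfig(num_filters=32, kernel_sizes=(3, 5),
                                  dropout_rate=0.2, embedding_dim=32),
            rbf=RBFLayerConfig(num_centers=16),
            bilstm=BiLSTMConfig(hidden_size=32),
        )

    def to_dict(self) -> dict:
        d = {
            "embedding": {
                "ngram_orders": sorted(self.embedding.ngram_orders),
                "embedding_dim": self.embedding.embedding_dim,
                "hash_buckets": self.embedding.hash_buckets,
                "seed": self.embedding.seed,
            },
            "conv": {
                "num_filters": self.conv.num_filters,
                "kernel_sizes": list(self.conv.kernel_sizes),
                "dropout_rate": self.conv.dropout_rate,
                "embedding_dim": self.conv.embedding_dim,
            },
            "rbf": {
                "num_centers": self.rbf.num_centers,
                "kernel": self.rbf.kernel,
                "gamma": self.rbf.gamma,
                "sigma": self.rbf.sigma,
            },
            "bilstm": {"hidden_size": self.bilstm.hidden_size},
            "use_pssm_features": self.use_pssm_features,
            "pssm_normalization": self.pssm_normalization,
            "pooling": self.pooling,
            "rbf_input": self.rbf_input,
            "max_length": self.max_length,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(
            embedding=EmbeddingConfig(
                ngram_orders=frozenset(d["embedding"]["ngram_orders"]),
                embedding_dim=d["embedding"]["embedding_dim"],
                hash_buckets=d["embedding"]["hash_buckets"],
                seed=d["embedding"]["seed"],
            ),
            conv=ConvBranchConfig(**d["conv"]),
            rbf=RBFLayerConfig(**d["rbf"]),
            bilstm=BiLSTMConfig(**d["bilstm"]),
            use_pssm_features=d["use_pssm_features"],
            pssm_normalization=d["pssm_normalization"],
            pooling=d["pooling"],
            rbf_input=d["rbf_input"],
            max_length=d["max_length"],
        )


# ---------------------------------------------------------------------------
# Functional building blocks (single-sequence, library surface)
# ---------------------------------------------------------------------------

def rbf_gaussian(s, gamma: float):
    """Gaussian radial basis kernel: phi(s) = exp(-gamma * s^2)."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("distance s must be nonnegative")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    out = np.exp(-gamma * s ** 2)
    return float(out) if out.ndim == 0 else out


def rbf_quadratic(r, sigma: float):
    """Linear-quadratic kernel: p(r) = 1 - r^2 / sigma (not clipped)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance r must be nonnegative")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    out = 1.0 - r ** 2 / sigma
    return float(out) if out.ndim == 0 else out


def init_rbf_centers(features: np.ndarray, k: int, seed: int) -> np.ndarray:
    """k-means centers (k-means++ seeding, <=100 iterations, tol 1e-4)."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        raise ValueError("features must be an n x d array")
    if features.shape[0] < k:
        raise ConfigurationError(
            f"need at least k={k} feature vectors, got {features.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=100,
                tol=1e-4, random_state=int(seed) % (2 ** 31))
    km.fit(features)
    return km.cluster_centers_.astype(float)


def rbf_forward(x: np.ndarray, config: RBFLayerConfig) -> np.ndarray:
    """Kernel activations of ||x - mu_j|| for each center j."""
    x = np.asarray(x, dtype=float)
    if config.centers is None:
        raise ConfigurationError("RBFLayerConfig.centers not set")
    centers = np.asarray(config.centers, dtype=float)
    if x.shape[-1] != centers.shape[-1]:
        raise ValueError(
            f"input dim {x.shape[-1]} != center dim {centers.shape[-1]}")
    d = np.sqrt(np.maximum(((x[..., None, :] - centers) ** 2).sum(-1), 0.0))
    if config.kernel == "gaussian":
        return rbf_gaussian(d, config.gamma)
    sigma = config.sigma if config.sigma is not None else 1.0
    return rbf_quadratic(d, sigma)


def cnn_forward(embedded: np.ndarray, bank: ConvBank,
                training_mode: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Run the convolution bank on one sequence of M position vectors."""
    embedded = np.asarray(embedded, dtype=float)
    if embedded.ndim != 2:
        raise ValueError("embedded must be M x D")
    x = embedded[None]
    mask = np.ones((1, embedded.shape[0]))
    return bank.forward(x, mask, training_mode, rng)[0]


def fuse_features(cnn: np.ndarray, rbf: np.ndarray) -> np.ndarray:
    """Per-position concatenation [cnn_i ; rbf_i] -> F_com."""
    cnn = np.asarray(cnn, dtype=float)
    rbf = np.asarray(rbf, dtype=float)
    if cnn.shape[0] != rbf.shape[0]:
        raise ValueError(
            f"position counts differ: {cnn.shape[0]} vs {rbf.shape[0]}")
    return np.concatenate([cnn, rbf], axis=-1)


def bilstm_forward(fused: np.ndarray, forward_cell: LSTM,
                   backward_cell: LSTM, head: Dense) -> dict:
    """Bidirectional pass over one fused sequence (T x D).

    Returns per-step hidden states ``H`` (T x 2H, forward state beside the
    position-aligned backward state), per-step output distributions
    ``O`` (softmax(W_o H_t + b_o)), the pooled state
    [h_T^(f); h_1^(b)], sequence-level ``logits`` and ``probabilities``.
    """
    fused = np.asarray(fused, dtype=float)
    if fused.ndim != 2 or fused.shape[0] < 1:
        raise ValueError("fused must be a non-empty T x D array")
    t = fused.shape[0]
    mask = np.ones((1, t))
    hs_f, hf = forward_cell.forward(fused[None], mask)
    hs_b, hb = backward_cell.forward(fused[None, ::-1], mask)
    h_aligned_b = hs_b[0][::-1]
    h_seq = np.concatenate([hs_f[0], h_aligned_b], axis=-1)
    pooled = np.concatenate([hf[0], hb[0]])
    logits = head.forward(pooled[None])[0]
    return {
        "H": h_seq,
        "O": softmax(head.forward(h_seq), axis=-1),
        "pooled": pooled,
        "logits": logits,
        "probabilities": softmax(logits),
    }


# ---------------------------------------------------------------------------
# Input preparation
# ---------------------------------------------------------------------------

@dataclass
class PreparedSequence:
    """Model-ready view of one sequence."""

    id: str
    ids: np.ndarray                 # M x G n-gram table indices (-1 = absent)
    profile: Optional[np.ndarray]   # M x 40 normalized augmented profile
    length: int
    label: Optional[int]


def prepare_sequence(record: ProteinSequence, config: ModelConfig,
                     pssm: Optional[PSSMatrix] = None) -> PreparedSequence:
    """Encode one record: n-gram ids plus the normalized augmented profile.

    When no externally computed PSSM is supplied the BLOSUM62 pseudo-PSSM
    stands in.  Sequences longer than ``max_length`` are truncated
    centrally (equal trim from both ends).
    """
    residues = record.residues
    if len(residues) > config.max_length:
        excess = len(residues) - config.max_length
        start = excess // 2
        residues = residues[start:start + config.max_length]
        record = ProteinSequence(record.id, residues, record.label)
        pssm = None  # external profile no longer aligns after truncation
    ids = ngram_ids(record.residues, config.embedding)
    profile = None
    if config.use_pssm_features:
        if pssm is None:
            pssm = compute_pseudo_pssm(record)
        elif pssm.m != len(record.residues):
            raise ValueError(
                f"PSSM rows ({pssm.m}) != sequence length "
                f"({len(record.residues)}) for {record.id!r}")
        norm = normalize_pssm(pssm, config.pssm_normalization)
        profile = augment_pssm(norm).combined
    return PreparedSequence(
        id=record.id, ids=ids, profile=profile,
        length=len(record.residues), label=record.label,
    )


def prepare_dataset(records: Sequence[ProteinSequence], config: ModelConfig,
                    pssms: Optional[dict] = None) -> list[PreparedSequence]:
    pssms = pssms or {}
    return [prepare_sequence(r, config, pssms.get(r.id)) for r in records]


def collate(batch: Sequence[PreparedSequence]):
    """Pad a batch to its longest sequence.

    Returns (ids, profiles or None, mask, lengths); ids padded with -1,
    profiles with zeros.
    """
    b = len(batch)
    m = max(p.length for p in batch)
    g = batch[0].ids.shape[1]
    ids = np.full((b, m, g), -1, dtype=np.int64)
    mask = np.zeros((b, m))
    lengths = np.array([p.length for p in batch], dtype=np.int64)
    profiles = None
    if batch[0].profile is not None:
        profiles = np.zeros((b, m, 40))
    for i, p in enumerate(batch):
        ids[i, :p.length] = p.ids
        mask[i, :p.length] = 1.0
        if profiles is not None:
            profiles[i, :p.length] = p.profile
    return ids, profiles, mask, lengths


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------

MODEL_KINDS = ("cnn", "lstm", "cnn_rnn", "cnn_bilstm", "hybrid")


class FusionModel:
    """One of the five architecture variants, with shared encoding front-end.

    ``hybrid`` is the full feature-fusion model; the others are the
    ablation baselines (no RBF layer, and/or a different recurrent unit).
    """

    def __init__(self, kind: str = "hybrid",
                 config: Optional[ModelConfig] = None, seed: int = 0):
        if kind not in MODEL_KINDS:
            raise ConfigurationError(
                f"unknown model kind {kind!r}; choose from {MODEL_KINDS}")
        self.kind = kind
        self.config = config or ModelConfig()
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)

        cfg = self.config
        self.embedding = NgramEmbedding(cfg.embedding.hash_buckets,
                                        cfg.embedding.embedding_dim, rng)
        din = cfg.embedding.embedding_dim + (40 if cfg.use_pssm_features else 0)
        self.input_dim = din

        self.conv: Optional[ConvBank] = None
        self.rbf: Optional[RBFLayer] = None
        self.lstm_f: Optional[LSTM] = None
        self.lstm_b: Optional[LSTM] = None
        self.rnn: Optional[SimpleRNN] = None

        if kind in ("cnn", "cnn_rnn", "cnn_bilstm", "hybrid"):
            self.conv = ConvBank(din, cfg.conv.num_filters,
                                 cfg.conv.kernel_sizes,
                                 cfg.conv.dropout_rate, rng)
            feat_dim = self.conv.out_dim
        else:
            feat_dim = din
        self.feature_dim = feat_dim

        if kind == "hybrid":
            self.rbf = RBFLayer(feat_dim, cfg.rbf.num_centers, cfg.rbf.kernel)
            # until k-means init, spread centers randomly in feature space
            self.rbf.params["centers"] = rng.normal(
                0.0, 1.0, size=(cfg.rbf.num_centers, feat_dim))
            if cfg.rbf.kernel == "gaussian":
                self.rbf.params["log_width"] = np.array(
                    [np.log(cfg.rbf.gamma)])
            elif cfg.rbf.sigma is not None:
                self.rbf.params["log_width"] = np.array(
                    [np.log(cfg.rbf.sigma)])
            self.rbf.zero_grads()
            rec_in = feat_dim + cfg.rbf.num_centers
        else:
            rec_in = feat_dim

        h = cfg.bilstm.hidden_size
        if kind in ("hybrid", "cnn_bilstm"):
            self.lstm_f = LSTM(rec_in, h, rng)
            self.lstm_b = LSTM(rec_in, h, rng)
            head_in = 2 * h
        elif kind == "lstm":
            self.lstm_f = LSTM(rec_in, h, rng)
            head_in = h
        elif kind == "cnn_rnn":
            self.rnn = SimpleRNN(rec_in, h, rng)
            head_in = h
        else:  # cnn: masked mean pool straight to the head
            head_in = feat_dim
        self.head = Dense(head_in, 2, rng)

        self.layers: list[_nn.Layer] = [
            lay for lay in (self.embedding, self.conv, self.rbf,
                            self.lstm_f, self.lstm_b, self.rnn, self.head)
            if lay is not None
        ]
        self.centers_initialized = kind != "hybrid"

    # -- forward / backward -------------------------------------------------

    def _front_end(self, ids, profiles, mask, training, rng):
        emb = self.embedding.forward(ids)
        if profiles is not None:
            x0 = np.concatenate([emb, profiles], axis=-1)
        else:
            x0 = emb
        x0 = x0 * mask[:, :, None]
        self._had_profiles = profiles is not None
        if self.conv is not None:
            feats = self.conv.forward(x0, mask, training, rng)
        else:
            feats = x0
        return feats

    def _front_end_backward(self, dfeats, mask):
        if self.conv is not None:
            dx0 = self.conv.backward(dfeats)
        else:
            dx0 = dfeats
        dx0 = dx0 * mask[:, :, None]
        demb = dx0[:, :, :self.config.embedding.embedding_dim] \
            if self._had_profiles else dx0
        self.embedding.backward(demb)

    def forward_batch(self, ids, profiles, mask, lengths,
                      training: bool = False,
                      rng: Optional[np.random.Generator] = None) -> np.ndarray:
        """Logits (B x 2) for a collated batch."""
        feats = self._front_end(ids, profiles, mask, training, rng)
        b, m, _ = feats.shape
        lengths = np.asarray(lengths)
        cache: dict = {"mask": mask, "lengths": lengths, "m": m}

        if self.kind == "hybrid":
            if self.config.rbf_input == "per_position":
                acts = self.rbf.forward(feats, mask)
            else:
                pooledf = (feats * mask[:, :, None]).sum(1) / lengths[:, None]
                acts1 = self.rbf.forward(pooledf[:, None, :],
                                         np.ones((b, 1)))
                acts = np.broadcast_to(acts1, (b, m, acts1.shape[-1])).copy()
                acts *= mask[:, :, None]
            rec_in = np.concatenate([feats, acts], axis=-1)
        else:
            rec_in = feats

        if self.kind in ("hybrid", "cnn_bilstm"):
            rev = reverse_indices(lengths, m)
            rows = np.arange(b)[:, None]
            hs_f, hf = self.lstm_f.forward(rec_in, mask)
            hs_b, hb = self.lstm_b.forward(rec_in[rows, rev], mask)
            if self.config.pooling == "final":
                pooled = np.concatenate([hf, hb], axis=-1)
            else:
                h_seq = np.concatenate([hs_f, hs_b[rows, rev]], axis=-1)
                pooled = (h_seq * mask[:, :, None]).sum(1) / lengths[:, None]
            cache["rev"] = rev
        elif self.kind == "lstm":
            hs_f, hf = self.lstm_f.forward(rec_in, mask)
            pooled = hf if self.config.pooling == "final" else \
                (hs_f * mask[:, :, None]).sum(1) / lengths[:, None]
        elif self.kind == "cnn_rnn":
            hs_r, hr = self.rnn.forward(rec_in, mask)
            pooled = hr if self.config.pooling == "final" else \
                (hs_r * mask[:, :, None]).sum(1) / lengths[:, None]
        else:  # cnn
            pooled = (rec_in * mask[:, :, None]).sum(1) / lengths[:, None]

        self._cache = cache
        return self.head.forward(pooled)

    def backward_batch(self, dlogits: np.ndarray) -> None:
        cache = self._cache
        mask, lengths, m = cache["mask"], cache["lengths"], cache["m"]
        b = mask.shape[0]
        dpooled = self.head.backward(dlogits)
        h = self.config.bilstm.hidden_size

        if self.kind in ("hybrid", "cnn_bilstm"):
            rev = cache["rev"]
            rows = np.arange(b)[:, None]
            if self.config.pooling == "final":
                drec = self.lstm_f.backward(None, dpooled[:, :h])
                drec_rev = self.lstm_b.backward(None, dpooled[:, h:])
            else:
                dh_seq = dpooled[:, None, :] * (mask / lengths[:, None])[..., None]
                dhs_b = np.zeros((b, m, h))
                dhs_b[rows, rev] = dh_seq[:, :, h:]
                drec = self.lstm_f.backward(dh_seq[:, :, :h],
                                            np.zeros((b, h)))
                drec_rev = self.lstm_b.backward(dhs_b, np.zeros((b, h)))
            dback = np.zeros_like(drec_rev)
            dback[rows, rev] = drec_rev
            drec = drec + dback
        elif self.kind == "lstm":
            if self.config.pooling == "final":
                drec = self.lstm_f.backward(None, dpooled)
            else:
                dhs = dpooled[:, None, :] * (mask / lengths[:, None])[..., None]
                drec = self.lstm_f.backward(dhs, np.zeros((b, h)))
        elif self.kind == "cnn_rnn":
            if self.config.pooling == "final":
                drec = self.rnn.backward(None, dpooled)
            else:
                dhs = dpooled[:, None, :] * (mask / lengths[:, None])[..., None]
                drec = self.rnn.backward(dhs, np.zeros((b, h)))
        else:  # cnn mean pool
            drec = dpooled[:, None, :] * (mask / lengths[:, None])[..., None]

        if self.kind == "hybrid":
            fdim = self.feature_dim
            dfeats = drec[:, :, :fdim]
            dacts = drec[:, :, fdim:]
            if self.config.rbf_input == "per_position":
                dfeats = dfeats + self.rbf.backward(dacts)
            else:
                dacts1 = (dacts * mask[:, :, None]).sum(1, keepdims=True)
                dpooledf = self.rbf.backward(dacts1)[:, 0, :]
                dfeats = dfeats + dpooledf[:, None, :] * (
                    mask / lengths[:, None])[..., None]
        else:
            dfeats = drec

        self._front_end_backward(dfeats, mask)

    # -- inference ----------------------------------------------------------

    def predict_proba(self, records: Sequence[ProteinSequence],
                      pssms: Optional[dict] = None,
                      batch_size: int = 64) -> np.ndarray:
        """Deterministic class-1 probabilities, one per input record."""
        prepared = prepare_dataset(records, self.config, pssms)
        probs = np.empty(len(prepared))
        for start in range(0, len(prepared), batch_size):
            chunk = prepared[start:start + batch_size]
            ids, profiles, mask, lengths = collate(chunk)
            logits = self.forward_batch(ids, profiles, mask, lengths,
                                        training=False)
            probs[start:start + len(chunk)] = softmax(logits, axis=-1)[:, 1]
        return probs

    def predict_labels(self, records, threshold: float = 0.5,
                       pssms: Optional[dict] = None) -> np.ndarray:
        probs = self.predict_proba(records, pssms)
        return (probs >= threshold).astype(int)

    # -- parameter access ---------------------------------------------------

    def named_params(self) -> dict[str, np.ndarray]:
        names = {"embedding": self.embedding, "conv": self.conv,
                 "rbf": self.rbf, "lstm_f": self.lstm_f,
                 "lstm_b": self.lstm_b, "rnn": self.rnn, "head": self.head}
        out = {}
        for prefix, lay in names.items():
            if lay is None:
                continue
            for key, val in lay.params.items():
                out[f"{prefix}.{key}"] = val
        return out

    def set_params(self, flat: dict[str, np.ndarray]) -> None:
        current = self.named_params()
        if set(flat) != set(current):
            raise StateError(
                "checkpoint parameter names do not match this architecture")
        names = {"embedding": self.embedding, "conv": self.conv,
                 "rbf": self.rbf, "lstm_f": self.lstm_f,
                 "lstm_b": self.lstm_b, "rnn": self.rnn, "head": self.head}
        for full, val in flat.items():
            prefix, key = full.split(".", 1)
            lay = names[prefix]
            if lay.params[key].shape != val.shape:
                raise StateError(
                    f"parameter {full} shape {val.shape} != expected "
                    f"{lay.params[key].shape}")
            lay.params[key] = np.asarray(val, dtype=float).copy()
        for lay in self.layers:
            lay.zero_grads()


def predict(seq: ProteinSequence, model: FusionModel,
            threshold: float = 0.5) -> tuple[int, float]:
    """Classify one sequence: (label, class-1 probability).

    Label is 1 iff probability >= threshold (ties go to the SNARE class).
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    prob = float(model.predict_proba([seq])[0])
    return (1 if prob >= threshold else 0), prob


def build_baseline(kind: str, config: Optional[ModelConfig] = None,
                   seed: int = 0) -> FusionModel:
    """Construct one of the comparison architectures (same front-end)."""
    return FusionModel(kind=kind, config=config, seed=seed)
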
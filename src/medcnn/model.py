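"""The MEDCNN classifier: dual-conv branches, CBAM-style attention, tensor fusion.

Architecture (per fitted window length L):

* one convolutional branch per selected encoding (BPF 4xL, NCP 3xL,
  DPCP 6xL — or a single trunk on the stacked 13xL input), each
  ``conv -> relu -> conv -> relu -> attention -> global average pool ->
  linear projection`` yielding a branch embedding ``Z_k`` of length d_k;
* attention multiplies the feature map by per-channel weights (pooled
  descriptors through a bottleneck MLP) and then per-position weights
  (channel-wise average/max maps through a 1-D convolution), both
  sigmoid-gated in (0, 1);
* the branch embeddings, each augmented with a constant 1, are fused by
  an outer product into a (d_1+1)x(d_2+1)x(d_3+1) tensor whose fibers at
  the appended-one indices reproduce the unimodal embeddings exactly;
* the flattened fusion tensor feeds two fully connected layers ending in
  a single sigmoid logit, trained with binary cross-entropy (mean negative
  log-likelihood) by Adam with early stopping on validation loss.

The network runs on the package's numpy reverse-mode autodiff backend
(:mod:`medcnn._autodiff`); training is CPU-only and deterministic for a
fixed seed up to platform floating-point behavior.

The public surface is the scikit-learn style estimator
:class:`MedcnnClassifier`; :func:`build_model`, :func:`train` and
:func:`predict` are thin functional wrappers over it.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from ._autodiff import Parameter, Tensor, conv1d_same
from .encoders import DinucPropertyTable, batch_encode, load_property_table
from .sequence_io import LabeledDataset

__all__ = [
    "ModelConfig",
    "FusionTensor",
    "TrainingState",
    "PredictionResult",
    "MedcnnClassifier",
    "build_model",
    "train",
    "predict",
    "fuse_tensors",
    "bce_loss",
    "attention_weights",
]

#: Epsilon used to clamp probabilities inside the cross-entropy loss.
LOSS_EPS = 1e-7


@dataclass
class ModelConfig:
    """Every architecture/training hyperparameter, with the seed.

    Defaults are the package's pinned choices; all are overridable and are
    recorded in every checkpoint.
    """

    encodings: tuple[str, ...] = ("bpf", "ncp", "dpcp")
    conv_channels: tuple[int, int] = (32, 64)
    kernel_size: int = 5
    attention: bool = True
    attention_reduction: int = 8
    spatial_kernel_size: int = 7
    embed_dim: int = 16
    fc_width: int = 128
    dropout: float = 0.3
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    validation_fraction: float = 0.1
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if len(self.conv_channels) != 2:
            raise ValueError("exactly two convolutional layers per branch")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.embed_dim <= 0 or any(c <= 0 for c in self.conv_channels):
            raise ValueError("all dimensions must be positive")

    def to_kwargs(self) -> dict:
        kw = asdict(self)
        kw["random_state"] = kw.pop("seed")
        return kw


@dataclass(frozen=True)
class FusionTensor:
    """Outer product of the 1-augmented branch embeddings."""

    values: np.ndarray
    component_dims: tuple[int, ...]


@dataclass
class TrainingState:
    """Loss trajectories and the best-validation checkpoint bookkeeping."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int | None = None
    seed: int = 0

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


@dataclass(frozen=True)
class PredictionResult:
    """Per-record positive-class probability and thresholded hard label."""

    id: str
    probability: float
    label: int


# ---------------------------------------------------------------------------
# functional pieces
# ---------------------------------------------------------------------------

def fuse_tensors(z1, z2, z3) -> FusionTensor:
    """Fuse three branch embeddings by the augmented outer product.

    Each vector gets a constant 1 appended, then
    ``Z[a, b, c] = z1~[a] * z2~[b] * z3~[c]`` — the 3-D cube of all
    cross-terms, whose corner fibers preserve the original vectors.
    """
    vecs = []
    for z in (z1, z2, z3):
        z = np.asarray(z, dtype=np.float64).ravel()
        if z.size == 0:
            raise ValueError("empty branch embedding")
        vecs.append(np.concatenate([z, [1.0]]))
    values = np.einsum("a,b,c->abc", *vecs)
    return FusionTensor(values, tuple(v.size - 1 for v in vecs))


def bce_loss(probs, labels, eps: float = LOSS_EPS) -> float:
    """Mean binary cross-entropy of predicted probabilities.

    Probabilities are clamped to ``[eps, 1 - eps]`` before the logs.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if probs.shape != labels.shape:
        raise ValueError("probs and labels must have equal length")
    p = np.clip(probs, eps, 1.0 - eps)
    return float(-np.mean(labels * np.log(p) + (1.0 - labels) * np.log(1.0 - p)))


def _conv1d(x: Tensor, W: Parameter, b: Parameter, L: int) -> Tensor:
    """'same' 1-D convolution. x: (B, Cin, L); W: (Cin, Cout, k); b: (Cout,)."""
    return conv1d_same(x, W, b)


def _channel_attention(x: Tensor, W1, b1, W2, b2) -> tuple[Tensor, Tensor]:
    """Channel weights from pooled descriptors through a shared bottleneck."""
    s_avg = x.mean(axis=2)  # (B, C)
    s_max = x.max(axis=2)
    h = ((s_avg @ W1) + b1).relu() @ W2 + b2
    hm = ((s_max @ W1) + b1).relu() @ W2 + b2
    a = (h + hm).sigmoid()  # (B, C)
    B, C = a.shape
    return a, x * a.reshape(B, C, 1)


def _spatial_attention(x: Tensor, Wa, Wm, b, L: int) -> tuple[Tensor, Tensor]:
    """Per-position weights from channel-wise average/max maps."""
    m_avg = x.mean(axis=1, keepdims=True)  # (B, 1, L)
    m_max = x.max(axis=1, keepdims=True)
    s = (_conv1d(m_avg, Wa, b, L) + _conv1d(m_max, Wm, Tensor(np.zeros(1)), L)
         ).sigmoid()  # (B, 1, L)
    return s, x * s


def attention_weights(feature_map: np.ndarray, params: dict
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply one attention block to a raw feature map, exposing its weights.

    ``feature_map`` is channels x positions (a batch axis is added
    internally); ``params`` holds numpy arrays ``ca_W1, ca_b1, ca_W2,
    ca_b2, sa_Wa, sa_Wm, sa_b``. Returns the channel-weight vector, the
    position-weight vector and the doubly reweighted map.
    """
    fm = np.asarray(feature_map, dtype=np.float64)
    squeeze = fm.ndim == 2
    if squeeze:
        fm = fm[None]
    x = Tensor(fm)
    L = fm.shape[2]
    a, x1 = _channel_attention(x, Tensor(params["ca_W1"]), Tensor(params["ca_b1"]),
                               Tensor(params["ca_W2"]), Tensor(params["ca_b2"]))
    s, x2 = _spatial_attention(x1, Tensor(params["sa_Wa"]), Tensor(params["sa_Wm"]),
                               Tensor(params["sa_b"]), L)
    cw, sw, out = a.data, s.data[:, 0, :], x2.data
    if squeeze:
        cw, sw, out = cw[0], sw[0], out[0]
    return cw, sw, out


class _Adam:
    """Adam with bias correction over a named parameter dict."""

    def __init__(self, params: dict[str, Parameter], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class MedcnnClassifier(ClassifierMixin, BaseEstimator):
    """Multi-dimensional-encoding CNN for methylation window classification.

    Parameters mirror :class:`ModelConfig`; ``encodings`` selects the
    branches: the default three-branch form fuses BPF/NCP/DPCP embeddings
    by the augmented outer product, a single entry (e.g. ``("bpf",)``)
    trains one branch whose embedding feeds the fully connected head
    directly, and ``("multi",)`` is the single-trunk variant on the
    stacked 13-channel input.

    ``X`` is a sequence of equal-length DNA window strings (or a
    :class:`~medcnn.sequence_io.LabeledDataset`); ``y`` is 0/1.
    """

    def __init__(self, encodings=("bpf", "ncp", "dpcp"),
                 conv_channels=(32, 64), kernel_size=5, attention=True,
                 attention_reduction=8, spatial_kernel_size=7, embed_dim=16,
                 fc_width=128, dropout=0.3, optimizer="adam",
                 learning_rate=1e-3, batch_size=64, max_epochs=100,
                 patience=10, validation_fraction=0.1, threshold=0.5,
                 property_table=None, random_state=0, verbose=0):
        self.encodings = encodings
        self.conv_channels = conv_channels
        self.kernel_size = kernel_size
        self.attention = attention
        self.attention_reduction = attention_reduction
        self.spatial_kernel_size = spatial_kernel_size
        self.embed_dim = embed_dim
        self.fc_width = fc_width
        self.dropout = dropout
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.threshold = threshold
        self.property_table = property_table
        self.random_state = random_state
        self.verbose = verbose

    # -- configuration ----------------------------------------------------
    @classmethod
    def from_config(cls, config: ModelConfig, **overrides) -> "MedcnnClassifier":
        kw = config.to_kwargs()
        kw.update(overrides)
        return cls(**kw)

    def _table(self) -> DinucPropertyTable:
        if self.property_table is None:
            if not hasattr(self, "_cached_table"):
                self._cached_table = load_property_table()
            return self._cached_table
        return self.property_table

    def _branch_inputs(self, sequences) -> list[np.ndarray]:
        from .sequence_io import SequenceRecord

        ds = LabeledDataset(
            [SequenceRecord(f"r{i}", s, label=0) for i, s in enumerate(sequences)]
        )
        table = self._table()
        needs_table = any(e in ("dpcp", "multi") for e in self.encodings)
        return [
            batch_encode(ds, enc, table if needs_table else None)[0]
            for enc in self.encodings
        ]

    # -- network ----------------------------------------------------------
    def _init_network(self, L: int, branch_channels: list[int]) -> dict:
        if L < self.kernel_size:
            raise ValueError(
                f"window length {L} is smaller than kernel_size "
                f"{self.kernel_size}"
            )
        rng = np.random.default_rng(self.random_state)
        params: dict[str, Parameter] = {}

        def he(shape, fan_in):
            return Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape))

        c1, c2 = self.conv_channels
        k = self.kernel_size
        ks = self.spatial_kernel_size
        for bi, cin in enumerate(branch_channels):
            p = f"b{bi}_"
            params[p + "conv1_W"] = he((cin, c1, k), cin * k)
            params[p + "conv1_b"] = Parameter(np.zeros(c1))
            params[p + "conv2_W"] = he((c1, c2, k), c1 * k)
            params[p + "conv2_b"] = Parameter(np.zeros(c2))
            if self.attention:
                hidden = max(1, c2 // self.attention_reduction)
                params[p + "ca_W1"] = he((c2, hidden), c2)
                params[p + "ca_b1"] = Parameter(np.zeros(hidden))
                params[p + "ca_W2"] = he((hidden, c2), hidden)
                params[p + "ca_b2"] = Parameter(np.zeros(c2))
                params[p + "sa_Wa"] = he((1, 1, ks), ks)
                params[p + "sa_Wm"] = he((1, 1, ks), ks)
                params[p + "sa_b"] = Parameter(np.zeros(1))
            params[p + "proj_W"] = he((c2, self.embed_dim), c2)
            params[p + "proj_b"] = Parameter(np.zeros(self.embed_dim))

        n_branches = len(branch_channels)
        if n_branches == 3:
            fusion_dim = (self.embed_dim + 1) ** 3
        elif n_branches == 1:
            fusion_dim = self.embed_dim
        else:
            fusion_dim = int(np.prod([self.embed_dim + 1] * n_branches))
        params["fc1_W"] = he((fusion_dim, self.fc_width), fusion_dim)
        params["fc1_b"] = Parameter(np.zeros(self.fc_width))
        params["fc2_W"] = he((self.fc_width, 1), self.fc_width)
        params["fc2_b"] = Parameter(np.zeros(1))
        return params

    def _branch_forward(self, x: Tensor, bi: int, L: int,
                        collect: dict | None = None) -> Tensor:
        p = self.params_
        pre = f"b{bi}_"
        h = _conv1d(x, p[pre + "conv1_W"], p[pre + "conv1_b"], L).relu()
        h = _conv1d(h, p[pre + "conv2_W"], p[pre + "conv2_b"], L).relu()
        if self.attention:
            a, h = _channel_attention(h, p[pre + "ca_W1"], p[pre + "ca_b1"],
                                      p[pre + "ca_W2"], p[pre + "ca_b2"])
            s, h = _spatial_attention(h, p[pre + "sa_Wa"], p[pre + "sa_Wm"],
                                      p[pre + "sa_b"], L)
            if collect is not None:
                collect[f"branch{bi}_channel"] = a.data
                collect[f"branch{bi}_spatial"] = s.data[:, 0, :]
        pooled = h.mean(axis=2)  # (B, C2)
        return pooled @ p[pre + "proj_W"] + p[pre + "proj_b"]

    def _forward(self, branch_arrays: list[np.ndarray], training: bool,
                 rng: np.random.Generator | None = None,
                 collect: dict | None = None) -> Tensor:
        L = branch_arrays[0].shape[2]
        zs = [
            self._branch_forward(Tensor(arr), bi, L, collect)
            for bi, arr in enumerate(branch_arrays)
        ]
        B = branch_arrays[0].shape[0]
        if len(zs) == 1:
            flat = zs[0]
        else:
            aug = [z.append_one() for z in zs]
            d = [a.shape[1] for a in aug]
            fused = aug[0].reshape(B, d[0], 1, 1) \
                * aug[1].reshape(B, 1, d[1], 1) \
                * aug[2].reshape(B, 1, 1, d[2])
            flat = fused.reshape(B, int(np.prod(d)))
        h = (flat @ self.params_["fc1_W"] + self.params_["fc1_b"]).relu()
        if training and self.dropout > 0:
            mask = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
            h = h * Tensor(mask)
        logit = h @ self.params_["fc2_W"] + self.params_["fc2_b"]
        return logit.reshape(B)

    # -- fit / predict ----------------------------------------------------
    @staticmethod
    def _coerce_X_y(X, y):
        if isinstance(X, LabeledDataset):
            seqs = X.sequences
            if y is None:
                y = X.labels
        else:
            seqs = [str(s) for s in X]
        if y is None:
            raise ValueError("y is required unless X is a LabeledDataset")
        y = np.asarray(y, dtype=int)
        if len(seqs) != len(y):
            raise ValueError("X and y length mismatch")
        return seqs, y

    def fit(self, X, y=None, validation_data=None):
        """Train by minibatch Adam on binary cross-entropy with early stopping.

        ``validation_data`` is an optional ``(X_val, y_val)`` pair; by
        default a stratified ``validation_fraction`` slice is carved from
        the training data for early stopping.
        """
        seqs, y = self._coerce_X_y(X, y)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        if isinstance(self.encodings, str):
            raise ValueError("encodings must be a sequence of encoding names")
        if len(self.encodings) not in (1, 3):
            raise ValueError("encodings must select one branch or three")

        L = len(seqs[0])
        if any(len(s) != L for s in seqs):
            raise ValueError("all training sequences must share one length")
        self.L_ = L
        self.classes_ = np.array([0, 1])

        rng = np.random.default_rng(self.random_state)

        if validation_data is not None:
            val_seqs, val_y = self._coerce_X_y(*validation_data)
            train_seqs, train_y = seqs, y
        else:
            idx_pos = np.flatnonzero(y == 1)
            idx_neg = np.flatnonzero(y == 0)
            val_idx = []
            for idx in (idx_pos, idx_neg):
                perm = rng.permutation(idx)
                n_val = int(round(len(idx) * self.validation_fraction))
                val_idx.extend(perm[:n_val])
            val_mask = np.zeros(len(seqs), dtype=bool)
            val_mask[val_idx] = True
            train_seqs = [s for s, m in zip(seqs, val_mask) if not m]
            train_y = y[~val_mask]
            val_seqs = [s for s, m in zip(seqs, val_mask) if m]
            val_y = y[val_mask]

        Xtr = self._branch_inputs(train_seqs)
        Xval = self._branch_inputs(val_seqs) if len(val_seqs) else None
        branch_channels = [a.shape[1] for a in Xtr]
        self.params_ = self._init_network(L, branch_channels)
        self.history_ = TrainingState(seed=self.random_state)
        opt = _Adam(self.params_, self.learning_rate)

        ytr = train_y.astype(np.float64)
        n = len(train_seqs)
        best_val = np.inf
        best_params = {k: p.data.copy() for k, p in self.params_.items()}
        best_epoch = None
        since_best = 0

        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                batch = order[start : start + self.batch_size]
                arrays = [a[batch] for a in Xtr]
                yb = ytr[batch]
                logits = self._forward(arrays, training=True, rng=rng)
                # BCE from logits: softplus(z) - y*z, numerically stable
                loss = (logits.softplus() - logits * Tensor(yb)).mean()
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"training diverged (non-finite loss) at epoch {epoch}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(batch)
            epoch_loss /= n
            self.history_.train_loss.append(epoch_loss)

            if Xval is not None:
                val_probs = self._predict_arrays(Xval)
                vl = bce_loss(val_probs, val_y)
                va = float(np.mean((val_probs >= self.threshold) == (val_y == 1)))
                self.history_.val_loss.append(vl)
                self.history_.val_acc.append(va)
                if self.verbose:
                    print(f"epoch {epoch}: train {epoch_loss:.4f} "
                          f"val {vl:.4f} acc {va:.3f}")
                if vl < best_val:
                    best_val = vl
                    best_params = {k: p.data.copy()
                                   for k, p in self.params_.items()}
                    best_epoch = epoch
                    since_best = 0
                else:
                    since_best += 1
                    if since_best > self.patience:
                        break

        if Xval is not None and best_epoch is not None:
            for k, p in self.params_.items():
                p.data = best_params[k]
        self.history_.best_epoch = best_epoch
        return self

    def _predict_arrays(self, branch_arrays: list[np.ndarray]) -> np.ndarray:
        n = branch_arrays[0].shape[0]
        out = np.empty(n)
        step = max(self.batch_size, 1)
        for start in range(0, n, step):
            chunk = [a[start : start + step] for a in branch_arrays]
            logits = self._forward(chunk, training=False)
            out[start : start + step] = 1.0 / (1.0 + np.exp(-logits.data))
        return out

    def _check_fitted_and_encode(self, X) -> tuple[list[str], list[np.ndarray]]:
        if not hasattr(self, "params_"):
            raise ValueError("estimator is not fitted")
        seqs = X.sequences if isinstance(X, LabeledDataset) else [str(s) for s in X]
        bad = next((s for s in seqs if len(s) != self.L_), None)
        if bad is not None:
            raise ValueError(
                f"sequence length {len(bad)} does not match fitted length "
                f"{self.L_}"
            )
        return seqs, self._branch_inputs(seqs)

    def predict_proba(self, X) -> np.ndarray:
        """Class probabilities, shape (n, 2), column 1 = methylated."""
        _, arrays = self._check_fitted_and_encode(X)
        p = self._predict_arrays(arrays)
        return np.column_stack([1.0 - p, p])

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)[:, 1]
        return (p >= self.threshold).astype(int)

    def predict_records(self, X, threshold: float | None = None
                        ) -> list[PredictionResult]:
        """Per-record results preserving input order and identifiers."""
        if threshold is None:
            threshold = self.threshold
        if isinstance(X, LabeledDataset):
            ids = [r.id for r in X.records]
        else:
            ids = [f"r{i}" for i in range(len(X))]
        p = self.predict_proba(X)[:, 1]
        return [
            PredictionResult(i, float(pi), int(pi >= threshold))
            for i, pi in zip(ids, p)
        ]

    def attention_maps(self, X) -> dict[str, np.ndarray]:
        """Channel/position attention weights per branch for every input."""
        if not self.attention:
            raise ValueError("attention is disabled in this model")
        _, arrays = self._check_fitted_and_encode(X)
        collect: dict[str, np.ndarray] = {}
        self._forward(arrays, training=False, collect=collect)
        return collect

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint parameters, full config, property-table hash and L."""
        if not hasattr(self, "params_"):
            raise ValueError("cannot save an unfitted estimator")
        table = self._table()
        table_hash = hashlib.sha256(
            table.normalized.to_csv().encode()
        ).hexdigest()
        meta = {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.get_params().items()
                       if k != "property_table"},
            "L": int(self.L_),
            "property_table_sha256": table_hash,
        }
        arrays = {f"param::{k}": p.data for k, p in self.params_.items()}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path, property_table=None) -> "MedcnnClassifier":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            params = {
                k[len("param::"):]: Parameter(data[k].copy())
                for k in data.files if k.startswith("param::")
            }
        config = meta["config"]
        config["encodings"] = tuple(config["encodings"])
        config["conv_channels"] = tuple(config["conv_channels"])
        est = cls(property_table=property_table, **config)
        est.params_ = params
        est.L_ = meta["L"]
        est.classes_ = np.array([0, 1])
        est.history_ = TrainingState(seed=config.get("random_state", 0))
        table_hash = hashlib.sha256(
            est._table().normalized.to_csv().encode()
        ).hexdigest()
        if table_hash != meta["property_table_sha256"]:
            warnings.warn(
                "property table hash differs from the checkpointed one",
                stacklevel=2,
            )
        return est


# ---------------------------------------------------------------------------
# spec-shaped functional wrappers
# ---------------------------------------------------------------------------

def build_model(config: ModelConfig, L: int) -> MedcnnClassifier:
    """Instantiate an estimator with seeded initial parameters for length L."""
    est = MedcnnClassifier.from_config(config)
    channels = {"bpf": 4, "ncp": 3, "dpcp": 6, "multi": 13}
    branch_channels = [channels[e] for e in est.encodings]
    est.params_ = est._init_network(L, branch_channels)
    est.L_ = L
    est.classes_ = np.array([0, 1])
    est.history_ = TrainingState(seed=est.random_state)
    return est


def train(model: MedcnnClassifier, train_ds: LabeledDataset,
          val_ds: LabeledDataset, config: ModelConfig | None = None,
          table: DinucPropertyTable | None = None) -> TrainingState:
    """Fit on an explicit train/validation dataset pair."""
    if config is not None:
        model.set_params(**{k: v for k, v in config.to_kwargs().items()
                            if k != "property_table"})
    if table is not None:
        model.set_params(property_table=table)
    model.fit(train_ds, validation_data=(val_ds, None) if len(val_ds) else None)
    return model.history_


def predict(model: MedcnnClassifier, records,
            table: DinucPropertyTable | None = None,
            threshold: float = 0.5) -> list[PredictionResult]:
    """Per-record probabilities/labels (order preserved)."""
    if table is not None:
        model.set_params(property_table=table)
    return model.predict_records(records, threshold=threshold)
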
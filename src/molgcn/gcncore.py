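"""Graph-convolutional classifiers: layers, model objects, training, CV.

Three layer types act on a node-feature matrix ``X`` (one molecule, ``N``
nodes):

* graph convolution   ``X <- sigma( sum_t  Atilde^(t) X W_t )``  — one weight
  matrix per bond type ``t``, with the degree-normalized adjacency
  ``Atilde^(t)`` mixing information between bonded atoms;
* graph dense         ``X <- X W``  — node-wise linear map, no mixing;
* graph gather        ``x_j <- sum_i X_ij``  — permutation-invariant readout
  collapsing the graph to a single vector.

After the gather, ordinary dense layers produce two logits per task; each
task head is an independent two-class softmax trained with cross-entropy
masked over observed labels (a missing label contributes zero loss and zero
gradient).  Multi-modal models concatenate encoded modality vectors (e.g. a
tokenized protein sequence passed through an embedding, a 1-D convolution
and a masked global max-pool) with the gathered graph vector at the fusion
point.

The user-facing surface follows the model/results idiom:
:class:`GraphConvModel` is constructed from a :class:`ModelSpec` and a
:class:`~molgcn.chemio.GraphDataset`; ``fit()`` returns :class:`GCNResults`
carrying the fitted parameters, the loss history, prediction methods and a
``summary()`` table.  The module-level ``build_model`` / ``train`` /
``predict`` functions expose the same machinery functionally.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import logsumexp
from scipy.stats import rankdata

from . import graphrep
from ._autograd import Tensor, concat
from .chemio import GraphDataset, make_cv_folds
from .errors import CompatibilityError, SpecError, TrainingError

ARCHIVE_VERSION = 1

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
PAD_TOKEN = 0
UNKNOWN_TOKEN = len(AA_ALPHABET) + 1  # 21
SEQ_VOCAB_SIZE = len(AA_ALPHABET) + 2


# ---------------------------------------------------------------------------
# specs


@dataclass
class LayerSpec:
    kind: str  # graph_conv | graph_dense | graph_gather | dense
    out_dim: int | None = None
    activation: str = "identity"  # relu | identity | softmax | sigmoid
    batch_norm: bool = False

    _KINDS = ("graph_conv", "graph_dense", "graph_gather", "dense")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise SpecError(f"unknown layer kind {self.kind!r}")
        if self.kind != "graph_gather" and self.out_dim is None:
            raise SpecError(f"{self.kind} layer needs out_dim")


@dataclass
class ModelSpec:
    """Declarative layer stack plus task/head/modality configuration.

    The layer order must be: zero or more graph_* layers, exactly one
    graph_gather, then dense layers ending in the classification head
    (``out_dim == 2 * n_tasks``, softmax activation interpreted per task).
    """

    layers: list[LayerSpec]
    n_tasks: int = 1
    head: str = "softmax_per_task"
    modality_encoders: dict[str, dict] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        kinds = [l.kind for l in self.layers]
        if kinds.count("graph_gather") != 1:
            raise SpecError("spec must contain exactly one graph_gather layer")
        gi = kinds.index("graph_gather")
        if any(k == "dense" for k in kinds[:gi]):
            raise SpecError("dense layers must come after graph_gather")
        if any(k.startswith("graph") for k in kinds[gi + 1 :]):
            raise SpecError("graph_* layers must come before graph_gather")
        if self.n_tasks < 1:
            raise SpecError("n_tasks must be >= 1")
        if kinds[-1] != "dense" or self.layers[-1].out_dim != 2 * self.n_tasks:
            raise SpecError("final layer must be dense with out_dim == 2 * n_tasks")

    def to_dict(self) -> dict:
        return {
            "layers": [asdict(l) for l in self.layers],
            "n_tasks": self.n_tasks,
            "head": self.head,
            "modality_encoders": self.modality_encoders,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            layers=[LayerSpec(**l) for l in d["layers"]],
            n_tasks=d["n_tasks"],
            head=d["head"],
            modality_encoders=d.get("modality_encoders", {}),
            seed=d.get("seed", 0),
        )


def default_model_spec(
    n_tasks: int = 1,
    n_conv_layers: int = 1,
    n_dense_layers: int = 0,
    conv_dim: int = 32,
    graph_dense_dim: int = 32,
    dense_dim: int = 32,
    modality_encoders: dict[str, dict] | None = None,
    seed: int = 0,
) -> ModelSpec:
    """The default architecture: GraphConv (+BN, ReLU) -> graph dense (ReLU)
    -> gather -> optional dense hidden layers -> softmax head."""
    layers = [
        LayerSpec("graph_conv", conv_dim, "relu", batch_norm=True)
        for _ in range(n_conv_layers)
    ]
    layers.append(LayerSpec("graph_dense", graph_dense_dim, "relu"))
    layers.append(LayerSpec("graph_gather"))
    layers += [LayerSpec("dense", dense_dim, "relu") for _ in range(n_dense_layers)]
    layers.append(LayerSpec("dense", 2 * n_tasks, "softmax"))
    return ModelSpec(
        layers=layers,
        n_tasks=n_tasks,
        modality_encoders=modality_encoders or {},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# sequences


@dataclass
class SequenceRecord:
    """Integer-token amino-acid sequence, padded to ``max_len``."""

    tokens: np.ndarray
    max_len: int

    def __post_init__(self):
        self.tokens = np.asarray(self.tokens, dtype=int)
        if self.tokens.shape != (self.max_len,):
            raise ValueError("tokens must have length max_len")
        if self.tokens.min() < 0 or self.tokens.max() >= SEQ_VOCAB_SIZE:
            raise ValueError("token outside vocabulary")


def tokenize_sequence(seq: str, max_len: int) -> SequenceRecord:
    """Map an amino-acid string to padded integer tokens (unknowns to a spare slot)."""
    toks = np.full(max_len, PAD_TOKEN, dtype=int)
    for i, ch in enumerate(seq[:max_len].upper()):
        toks[i] = AA_ALPHABET.index(ch) + 1 if ch in AA_ALPHABET else UNKNOWN_TOKEN
    return SequenceRecord(tokens=toks, max_len=max_len)


def default_sequence_encoder(max_len: int = 50, embed_dim: int = 8,
                             conv_channels: int = 16, kernel: int = 3,
                             out_dim: int = 16) -> dict:
    return {
        "kind": "sequence",
        "max_len": max_len,
        "embed_dim": embed_dim,
        "conv_channels": conv_channels,
        "kernel": kernel,
        "out_dim": out_dim,
        "vocab_size": SEQ_VOCAB_SIZE,
    }


# ---------------------------------------------------------------------------
# activations and primitive forwards


def _activate(x: Tensor, name: str) -> Tensor:
    if name in ("identity", "softmax"):  # softmax applied by the head
        return x
    if name == "relu":
        return x.relu()
    if name == "sigmoid":
        return x.sigmoid()
    raise SpecError(f"unknown activation {name!r}")


def graph_conv_forward(X, norm_adjacency: dict, weights: dict, activation: str = "identity"):
    """Single-graph graph convolution: ``sigma( sum_t Atilde^(t) X W_t )``."""
    x = X if isinstance(X, Tensor) else Tensor(X)
    acc = None
    for t, a in norm_adjacency.items():
        w = weights[t] if isinstance(weights[t], Tensor) else Tensor(weights[t])
        term = Tensor(a) @ x @ w
        acc = term if acc is None else acc + term
    return _activate(acc, activation)


def graph_dense_forward(X, W):
    """Node-wise linear map ``X W`` (no mixing across nodes)."""
    x = X if isinstance(X, Tensor) else Tensor(X)
    w = W if isinstance(W, Tensor) else Tensor(W)
    return x @ w


def graph_gather(X, node_mask=None):
    """Sum node feature vectors into one graph-level vector."""
    x = X if isinstance(X, Tensor) else Tensor(X)
    if node_mask is not None:
        x = x * Tensor(np.asarray(node_mask)[..., None])
    return x.sum(axis=-2)


# ---------------------------------------------------------------------------
# parameter initialization


def _init_params(spec: ModelSpec, n_features: int,
                 bond_types: tuple[str, ...]) -> tuple[dict, dict]:
    rng = np.random.default_rng(spec.seed)
    params: dict[str, np.ndarray] = {}
    bn_stats: dict[str, np.ndarray] = {}
    dim = n_features
    gathered_dim = None
    for li, layer in enumerate(spec.layers):
        if layer.kind == "graph_conv":
            for t in bond_types:
                params[f"L{li}_W_{t}"] = rng.normal(0, np.sqrt(2.0 / dim), (dim, layer.out_dim))
            if layer.batch_norm:
                params[f"L{li}_bn_gamma"] = np.ones(layer.out_dim)
                params[f"L{li}_bn_beta"] = np.zeros(layer.out_dim)
                bn_stats[f"L{li}_mean"] = np.zeros(layer.out_dim)
                bn_stats[f"L{li}_var"] = np.ones(layer.out_dim)
            dim = layer.out_dim
        elif layer.kind == "graph_dense":
            params[f"L{li}_W"] = rng.normal(0, np.sqrt(2.0 / dim), (dim, layer.out_dim))
            dim = layer.out_dim
        elif layer.kind == "graph_gather":
            gathered_dim = dim
            for name, enc in sorted(spec.modality_encoders.items()):
                if enc["kind"] == "sequence":
                    e, c, k, o = enc["embed_dim"], enc["conv_channels"], enc["kernel"], enc["out_dim"]
                    params[f"M{name}_emb"] = rng.normal(0, 1.0, (enc["vocab_size"], e))
                    for ki in range(k):
                        params[f"M{name}_K{ki}"] = rng.normal(0, np.sqrt(2.0 / (e * k)), (e, c))
                    params[f"M{name}_convb"] = np.zeros(c)
                    params[f"M{name}_W"] = rng.normal(0, np.sqrt(2.0 / c), (c, o))
                    params[f"M{name}_b"] = np.zeros(o)
                    dim += o
                elif enc["kind"] == "vector":
                    dim += enc["dim"]  # pass-through, no parameters
                else:
                    raise SpecError(f"unknown modality encoder kind {enc['kind']!r}")
        elif layer.kind == "dense":
            params[f"L{li}_W"] = rng.normal(0, np.sqrt(1.0 / dim), (dim, layer.out_dim))
            params[f"L{li}_b"] = np.zeros(layer.out_dim)
            dim = layer.out_dim
    return params, bn_stats


# ---------------------------------------------------------------------------
# forward pass


def _encode_modality(name: str, enc: dict, values: np.ndarray, params: dict) -> Tensor:
    """Encode one modality batch; sequence encodings max-pool over real tokens only."""
    if enc["kind"] == "vector":
        return Tensor(np.asarray(values, dtype=np.float64))
    tokens = np.asarray(values, dtype=int)  # (B, L)
    b, L = tokens.shape
    k = enc["kernel"]
    emb = params[f"M{name}_emb"]
    y = None
    for ki in range(k):
        off = ki - k // 2
        shifted = np.full_like(tokens, PAD_TOKEN)
        if off < 0:
            shifted[:, -off:] = tokens[:, :off]
        elif off > 0:
            shifted[:, :-off] = tokens[:, off:]
        else:
            shifted = tokens
        e = emb.take_rows(shifted.ravel()).reshape(b, L, enc["embed_dim"])
        term = e @ params[f"M{name}_K{ki}"]
        y = term if y is None else y + term
    y = (y + params[f"M{name}_convb"]).relu()
    seq_mask = (tokens != PAD_TOKEN).astype(np.float64)[..., None]  # (B, L, 1)
    # masked max-pool with a zero sentinel: pad positions contribute nothing,
    # and an all-pad sequence pools to the zero vector
    z = y * Tensor(seq_mask) + Tensor((seq_mask - 1.0) * 1e9)
    z = concat([z, Tensor(np.zeros((b, 1, enc["conv_channels"])))], axis=1)
    pooled = z.max(axis=1)
    return (pooled @ params[f"M{name}_W"] + params[f"M{name}_b"]).relu()


def encode_sequence(record: SequenceRecord, encoder_spec: dict,
                    params: dict | None = None, seed: int = 0) -> np.ndarray:
    """Encode one tokenized sequence to its fixed-length vector.

    When ``params`` is omitted a fresh seeded parameter set is drawn, so the
    map is deterministic given (record, encoder_spec, seed).
    """
    if params is None:
        rng = np.random.default_rng(seed)
        e, c, k, o = (encoder_spec["embed_dim"], encoder_spec["conv_channels"],
                      encoder_spec["kernel"], encoder_spec["out_dim"])
        params = {"M_seq_emb": Tensor(rng.normal(0, 1.0, (encoder_spec["vocab_size"], e)))}
        for ki in range(k):
            params[f"M_seq_K{ki}"] = Tensor(rng.normal(0, np.sqrt(2.0 / (e * k)), (e, c)))
        params["M_seq_convb"] = Tensor(np.zeros(c))
        params["M_seq_W"] = Tensor(rng.normal(0, np.sqrt(2.0 / c), (c, o)))
        params["M_seq_b"] = Tensor(np.zeros(o))
    out = _encode_modality("_seq", encoder_spec, record.tokens[None, :], params)
    return out.data[0]


def _forward(
    spec: ModelSpec,
    params: dict,  # name -> Tensor
    bn_stats: dict,  # name -> ndarray (running stats, mutated when update_bn)
    adjacency: np.ndarray,  # (B, |T|, N, N)
    bond_types: tuple[str, ...],
    features,  # (B, N, D) ndarray or Tensor
    node_mask: np.ndarray,  # (B, N)
    modalities: dict[str, np.ndarray] | None = None,
    training: bool = False,
    dropout_rate: float = 0.0,
    dropout_rng: np.random.Generator | None = None,
    update_bn: bool = False,
) -> Tensor:
    """Run the full network; returns per-task logits of shape (B, n_tasks, 2)."""
    x = features if isinstance(features, Tensor) else Tensor(features)
    mask3 = node_mask[..., None]  # (B, N, 1)
    h: Tensor | None = None

    def dropout(t: Tensor) -> Tensor:
        if training and dropout_rate > 0.0:
            keep = (dropout_rng.random(t.shape) >= dropout_rate).astype(np.float64)
            return t * Tensor(keep / (1.0 - dropout_rate))
        return t

    for li, layer in enumerate(spec.layers):
        if layer.kind == "graph_conv":
            acc = None
            for ti, t in enumerate(bond_types):
                term = Tensor(adjacency[:, ti]) @ x @ params[f"L{li}_W_{t}"]
                acc = term if acc is None else acc + term
            if layer.batch_norm:
                acc = _batch_norm(acc, node_mask, params[f"L{li}_bn_gamma"],
                                  params[f"L{li}_bn_beta"], bn_stats, f"L{li}",
                                  training=training, update=update_bn)
            x = _activate(acc, layer.activation) * Tensor(mask3)
        elif layer.kind == "graph_dense":
            x = _activate(x @ params[f"L{li}_W"], layer.activation)
            x = dropout(x) * Tensor(mask3)
        elif layer.kind == "graph_gather":
            h = x.sum(axis=1)  # padded rows are already zero
            pieces = [h]
            for name, enc in sorted(spec.modality_encoders.items()):
                if modalities is None or name not in modalities:
                    raise CompatibilityError(f"modality {name!r} required but not supplied")
                pieces.append(_encode_modality(name, enc, modalities[name], params))
            if len(pieces) > 1:
                h = concat(pieces, axis=-1)
        else:  # dense
            h = _activate(h @ params[f"L{li}_W"] + params[f"L{li}_b"], layer.activation)
            if li != len(spec.layers) - 1:
                h = dropout(h)
    return h.reshape(-1, spec.n_tasks, 2)


def _batch_norm(x: Tensor, node_mask: np.ndarray, gamma: Tensor, beta: Tensor,
                bn_stats: dict, prefix: str, training: bool, update: bool,
                eps: float = 1e-5, momentum: float = 0.9) -> Tensor:
    """Per-channel BN with statistics pooled over real (unmasked) nodes."""
    m3 = Tensor(node_mask[..., None])
    count = float(node_mask.sum())
    if training:
        mean = (x * m3).sum(axis=0).sum(axis=0) / count
        var = (((x - mean) * m3) ** 2).sum(axis=0).sum(axis=0) / count
        if update:
            bn_stats[f"{prefix}_mean"] = (momentum * bn_stats[f"{prefix}_mean"]
                                          + (1 - momentum) * mean.data)
            bn_stats[f"{prefix}_var"] = (momentum * bn_stats[f"{prefix}_var"]
                                         + (1 - momentum) * var.data)
        xhat = (x - mean) / (var + eps).sqrt()
    else:
        mean = Tensor(bn_stats[f"{prefix}_mean"])
        var = Tensor(bn_stats[f"{prefix}_var"])
        xhat = (x - mean) / (var + eps).sqrt()
    return gamma * xhat + beta


# ---------------------------------------------------------------------------
# trained model state


class TrainedModel:
    """Layer stack + fitted parameters + featurization config.

    Serializable to a single ``.npz`` archive (JSON spec + parameter arrays,
    versioned header) and restorable losslessly.
    """

    def __init__(self, spec: ModelSpec, params: dict[str, np.ndarray],
                 bn_stats: dict[str, np.ndarray],
                 feature_config: graphrep.FeatureConfig,
                 bond_types: tuple[str, ...] = graphrep.DEFAULT_BOND_TYPES,
                 history: list[float] | None = None):
        self.spec = spec
        self.params = params
        self.bn_stats = bn_stats
        self.feature_config = feature_config
        self.bond_types = tuple(bond_types)
        self.history = list(history or [])

    @property
    def n_features(self) -> int:
        return self.feature_config.n_features

    def copy(self) -> "TrainedModel":
        return TrainedModel(
            spec=self.spec,
            params={k: v.copy() for k, v in self.params.items()},
            bn_stats={k: v.copy() for k, v in self.bn_stats.items()},
            feature_config=self.feature_config,
            bond_types=self.bond_types,
            history=list(self.history),
        )

    def _param_tensors(self, requires_grad: bool) -> dict[str, Tensor]:
        return {k: Tensor(v, requires_grad=requires_grad) for k, v in self.params.items()}

    def logits(self, batch: graphrep.GraphBatch,
               modalities: dict[str, np.ndarray] | None = None,
               features: Tensor | None = None) -> Tensor:
        """Inference-mode forward; ``features`` may override the batch's matrix
        with a differentiable tensor (used by integrated gradients)."""
        return _forward(
            self.spec, self._param_tensors(False), self.bn_stats,
            batch.adjacency, self.bond_types,
            features if features is not None else batch.features,
            batch.node_mask, modalities=modalities, training=False,
        )

    def save(self, path: str) -> None:
        meta = {
            "version": ARCHIVE_VERSION,
            "spec": self.spec.to_dict(),
            "feature_config": self.feature_config.to_dict(),
            "bond_types": list(self.bond_types),
            "history": self.history,
        }
        arrays = {f"param/{k}": v for k, v in self.params.items()}
        arrays.update({f"bn/{k}": v for k, v in self.bn_stats.items()})
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            if meta.get("version") != ARCHIVE_VERSION:
                raise CompatibilityError(f"unsupported model archive version in {path}")
            params = {k[6:]: z[k].copy() for k in z.files if k.startswith("param/")}
            bn = {k[3:]: z[k].copy() for k in z.files if k.startswith("bn/")}
        return cls(
            spec=ModelSpec.from_dict(meta["spec"]),
            params=params,
            bn_stats=bn,
            feature_config=graphrep.FeatureConfig.from_dict(meta["feature_config"]),
            bond_types=tuple(meta["bond_types"]),
            history=meta["history"],
        )


def build_model(spec: ModelSpec,
                feature_config: graphrep.FeatureConfig | None = None,
                bond_types: tuple[str, ...] = graphrep.DEFAULT_BOND_TYPES) -> TrainedModel:
    """Initialize a model's parameters from the spec's seed."""
    cfg = feature_config or graphrep.FeatureConfig()
    params, bn_stats = _init_params(spec, cfg.n_features, bond_types)
    return TrainedModel(spec=spec, params=params, bn_stats=bn_stats,
                        feature_config=cfg, bond_types=bond_types)


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate < 0:
            raise TrainingError("config values must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise TrainingError("dropout_rate must lie in [0, 1)")


def dataset_batch(data: GraphDataset, max_nodes: int | str = "auto") -> graphrep.GraphBatch:
    """Normalize and pad every graph in a dataset into one dense batch."""
    normed = [graphrep.normalize_adjacency(g) for g in data.graphs]
    return graphrep.pad_and_batch(normed, max_nodes=max_nodes)


def masked_cross_entropy(logits: Tensor, labels: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean two-class cross-entropy over observed (compound, task) entries."""
    onehot = np.zeros(logits.shape)
    lab = labels.astype(int)
    b_idx, t_idx = np.meshgrid(np.arange(lab.shape[0]), np.arange(lab.shape[1]), indexing="ij")
    onehot[b_idx, t_idx, lab] = 1.0
    lse = logits.logsumexp(axis=2)  # (B, T)
    true_logit = (logits * Tensor(onehot)).sum(axis=2)
    ce = (lse - true_logit) * Tensor(mask)
    denom = max(float(mask.sum()), 1.0)
    return ce.sum() / denom


class _Adam:
    def __init__(self, keys, lr: float, b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: 0.0 for k in keys}
        self.v = {k: 0.0 for k in keys}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(model: TrainedModel, data: GraphDataset, config: TrainConfig | None = None) -> TrainedModel:
    """Fit by Adam on the masked cross-entropy; returns a new TrainedModel.

    The random trajectory (shuffling, dropout) is fully determined by
    ``config.seed``; parameter initialization by ``model.spec.seed``.
    """
    config = config or TrainConfig()
    if float(data.label_mask.sum()) == 0:
        raise TrainingError("dataset has no observed labels")
    if data.feature_config.n_features != model.n_features:
        raise CompatibilityError("dataset feature_config does not match model")
    model = model.copy()
    batch = dataset_batch(data)
    rng = np.random.default_rng(config.seed)
    opt = _Adam(model.params.keys(), config.learning_rate)
    n = len(data)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            if float(data.label_mask[idx].sum()) == 0:
                continue  # nothing observed in this minibatch
            tensors = model._param_tensors(True)
            logits = _forward(
                model.spec, tensors, model.bn_stats,
                batch.adjacency[idx], model.bond_types,
                batch.features[idx], batch.node_mask[idx],
                modalities={k: v[idx] for k, v in data.modalities.items()} or None,
                training=True, dropout_rate=config.dropout_rate, dropout_rng=rng,
                update_bn=True,
            )
            loss = masked_cross_entropy(logits, data.labels[idx], data.label_mask[idx])
            loss.backward()
            grads = {k: t.grad for k, t in tensors.items() if t.grad is not None}
            if config.learning_rate > 0:
                opt.step(model.params, grads)
            losses.append(float(loss.data))
        model.history.append(float(np.mean(losses)) if losses else float("nan"))
    return model


def predict(model: TrainedModel, data: GraphDataset) -> np.ndarray:
    """Per-task P(active) in [0, 1], shape (n_compounds, n_tasks)."""
    if data.feature_config.n_features != model.n_features:
        raise CompatibilityError("dataset feature_config does not match model")
    batch = dataset_batch(data)
    logits = model.logits(batch, modalities=data.modalities or None).data
    return np.exp(logits[..., 1] - logsumexp(logits, axis=2))


# ---------------------------------------------------------------------------
# evaluation


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """P(score_pos > score_neg) + 0.5 P(tie), via the Mann-Whitney statistic."""
    labels = np.asarray(labels)
    pos, neg = int((labels == 1).sum()), int((labels == 0).sum())
    if pos == 0 or neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - pos * (pos + 1) / 2) / (pos * neg))


def evaluate_auc(scores: np.ndarray, labels: np.ndarray,
                 mask: np.ndarray | None = None) -> np.ndarray:
    """Per-task ROC-AUC over observed entries; NaN flags a single-class task."""
    scores, labels = np.asarray(scores), np.asarray(labels)
    if scores.ndim == 1:
        scores, labels = scores[:, None], labels[:, None]
        if mask is not None:
            mask = np.asarray(mask)[:, None]
    if mask is None:
        mask = np.ones_like(labels, dtype=float)
    out = np.empty(scores.shape[1])
    for t in range(scores.shape[1]):
        obs = mask[:, t] == 1
        out[t] = roc_auc(scores[obs, t], labels[obs, t])
    return out


def run_cross_validation(spec: ModelSpec, data: GraphDataset, k: int,
                         config: TrainConfig | None = None, seed: int = 0) -> dict:
    """k-fold CV: train on k-1 folds, score the held-out fold; report per-fold
    and mean/sd per-task ROC-AUC.  Seeded end-to-end (fold assignment, per-fold
    training trajectories)."""
    config = config or TrainConfig()
    if data.fold_assignment is None:
        data = make_cv_folds(data, k, seed)
    folds = data.fold_assignment
    per_fold_auc = []
    fold_sizes = []
    for f in range(k):
        test_idx = np.where(folds == f)[0]
        train_idx = np.where(folds != f)[0]
        fold_sizes.append(int(test_idx.size))
        model = build_model(spec, data.feature_config, data.bond_types)
        fold_cfg = TrainConfig(**{**asdict(config), "seed": (seed * 1009 + f) % (2**31)})
        fitted = train(model, data.subset(train_idx), fold_cfg)
        scores = predict(fitted, data.subset(test_idx))
        per_fold_auc.append(evaluate_auc(scores, data.labels[test_idx], data.label_mask[test_idx]))
    per_fold = np.asarray(per_fold_auc)  # (k, n_tasks)
    report = {"k": k, "seed": seed, "fold_sizes": fold_sizes, "tasks": {}}
    for t, name in enumerate(data.tasks):
        vals = per_fold[:, t]
        ok = vals[~np.isnan(vals)]
        report["tasks"][name] = {
            "fold_aucs": [None if np.isnan(v) else float(v) for v in vals],
            "mean_auc": float(ok.mean()) if ok.size else None,
            "sd_auc": float(ok.std(ddof=1)) if ok.size > 1 else None,
        }
    means = [v["mean_auc"] for v in report["tasks"].values() if v["mean_auc"] is not None]
    report["mean_auc"] = float(np.mean(means)) if means else None
    return report


# ---------------------------------------------------------------------------
# model / results surface


class GraphConvModel:
    """A graph-convolutional classifier bound to a dataset.

    Parameters
    ----------
    spec : ModelSpec
        Declarative layer stack; ``default_model_spec()`` gives the standard
        conv -> graph dense -> gather -> softmax stack.
    data : GraphDataset
        Featurized training compounds with masked task labels.
    """

    def __init__(self, spec: ModelSpec, data: GraphDataset):
        if spec.n_tasks != data.n_tasks:
            raise SpecError(f"spec has {spec.n_tasks} tasks, dataset has {data.n_tasks}")
        self.spec = spec
        self.data = data

    @classmethod
    def from_dataset(cls, data: GraphDataset, **spec_kwargs) -> "GraphConvModel":
        return cls(default_model_spec(n_tasks=data.n_tasks, **spec_kwargs), data)

    def fit(self, epochs: int = 50, batch_size: int = 32, learning_rate: float = 1e-3,
            dropout_rate: float = 0.0, seed: int = 0) -> "GCNResults":
        config = TrainConfig(epochs=epochs, batch_size=batch_size,
                             learning_rate=learning_rate, dropout_rate=dropout_rate,
                             seed=seed)
        fitted = train(build_model(self.spec, self.data.feature_config, self.data.bond_types),
                       self.data, config)
        return GCNResults(self, fitted, config)


class GCNResults:
    """Fitted parameters, training history and prediction/summary methods."""

    def __init__(self, model: GraphConvModel, trained: TrainedModel, config: TrainConfig):
        self.model = model
        self.trained = trained
        self.config = config

    @property
    def history(self) -> list[float]:
        return self.trained.history

    @property
    def params(self) -> dict[str, np.ndarray]:
        return self.trained.params

    def predict(self, data: GraphDataset | None = None) -> np.ndarray:
        return predict(self.trained, data if data is not None else self.model.data)

    def training_auc(self) -> np.ndarray:
        d = self.model.data
        return evaluate_auc(self.predict(d), d.labels, d.label_mask)

    def save(self, path: str) -> None:
        self.trained.save(path)

    def summary(self) -> str:
        d = self.model.data
        buf = io.StringIO()
        print("Graph Convolutional Classifier Results", file=buf)
        print("=" * 54, file=buf)
        print(f"{'No. compounds:':<26}{len(d)}", file=buf)
        print(f"{'No. tasks:':<26}{d.n_tasks}", file=buf)
        print(f"{'Bond types:':<26}{', '.join(d.bond_types)}", file=buf)
        print(f"{'Atom features:':<26}{d.feature_config.n_features}", file=buf)
        n_par = sum(v.size for v in self.trained.params.values())
        print(f"{'No. parameters:':<26}{n_par}", file=buf)
        print(f"{'Epochs:':<26}{self.config.epochs}", file=buf)
        if self.history:
            print(f"{'Loss (first -> final):':<26}{self.history[0]:.4f} -> {self.history[-1]:.4f}",
                  file=buf)
        print("-" * 54, file=buf)
        print(f"{'layer':<14}{'out_dim':>8}{'activation':>12}{'batch_norm':>12}", file=buf)
        for l in self.trained.spec.layers:
            print(f"{l.kind:<14}{str(l.out_dim or '-'):>8}{l.activation:>12}"
                  f"{str(l.batch_norm):>12}", file=buf)
        print("-" * 54, file=buf)
        aucs = self.training_auc()
        for t, name in enumerate(d.tasks):
            val = "undefined (single class)" if np.isnan(aucs[t]) else f"{aucs[t]:.3f}"
            print(f"{'train ROC-AUC ' + name + ':':<26}{val}", file=buf)
        return buf.getvalue()
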
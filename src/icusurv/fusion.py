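"""Multimodal DeepSurv-style risk network.

The network estimates the Cox log-relative-hazard ``psi(x)`` with a small
multilayer perceptron over fused multimodal features:

* each enabled modality (severity factors, finding labels, pooled report
  embedding, GCN text features, image embedding) passes through its own
  fully-connected head;
* the hidden vectors of all non-saps modalities — which share an output
  width — are fused by elementwise averaging ("early average fusion");
* the averaged block is concatenated with the saps-head output (averaged
  block first, saps block second — the order is fixed so serialized weights
  are portable);
* a nonlinear risk head (one ReLU hidden layer with dropout by default) maps
  the fused vector to the scalar risk score.

Training minimises the negative Cox partial likelihood computed within each
mini-batch (risk sets restricted to the batch, standard DeepSurv practice)
with the Adam optimizer, early-stopping on the validation partial likelihood
and restoring the best-epoch weights.  Every batch is constructed to contain
at least one event so its partial likelihood is defined.

The implementation is plain numpy with hand-written backpropagation: all
default sizes (15/14/768/1024-dim inputs, 32-dim heads) train in seconds on
one CPU, and seeded end-to-end reproducibility is simple to guarantee.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .cox import (
    BaselineSurvival,
    SurvivalCurve,
    cox_partial_log_likelihood,
    cox_partial_loglik_gradient,
    survival_function,
)
from .encoders import GCNParams, encode_saps_factors, encode_text, pool_token_embeddings
from .synthetic import Cohort, SubjectRecord

__all__ = [
    "MODALITIES",
    "DEFAULT_HEAD_DIMS",
    "FusionConfig",
    "TrainedRiskModel",
    "fuse_features",
    "encode_modalities",
    "train_model",
    "train_on_arrays",
    "risk_forward",
    "risk_forward_batch",
    "predict_survival",
]

MODALITIES = ("saps", "labels", "transformer_text", "gcn_text", "image")

DEFAULT_HEAD_DIMS: dict[str, tuple[int, int]] = {
    "saps": (15, 15),
    "labels": (14, 14),
    "transformer_text": (768, 32),
    "gcn_text": (28, 32),
    "image": (1024, 32),
}


@dataclass(frozen=True)
class FusionConfig:
    """Architecture and training settings for the fused risk network."""

    enabled_modalities: tuple[str, ...] = ("saps",)
    head_dims: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_HEAD_DIMS)
    )
    risk_hidden_layers: tuple[int, ...] | None = None  # None -> one layer of fused width
    dropout: float = 0.5
    learning_rate: float = 1e-3
    weight_decay: float = 1e-3  # L2 penalty on weight matrices (not biases);
    # experiments with high-dimensional heads typically share a stronger value
    batch_size: int = 72
    max_epochs: int = 250
    early_stop_patience: int = 10
    saps_activation: bool = False  # linear saps head; nonlinearity lives in the risk head
    seed: int = 0

    def __post_init__(self):
        if not self.enabled_modalities:
            raise ValueError("at least one modality must be enabled")
        for m in self.enabled_modalities:
            if m not in MODALITIES:
                raise ValueError(f"unknown modality {m!r}; expected one of {MODALITIES}")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        avg = self.averaged_modalities
        if avg:
            outs = {self.head_dims[m][1] for m in avg}
            if len(outs) > 1:
                raise ValueError(
                    "modalities joining the elementwise average must share an "
                    f"output width; got {dict((m, self.head_dims[m][1]) for m in avg)}"
                )

    @property
    def averaged_modalities(self) -> tuple[str, ...]:
        return tuple(m for m in self.enabled_modalities if m != "saps")

    @property
    def fused_dim(self) -> int:
        d = 0
        if self.averaged_modalities:
            d += self.head_dims[self.averaged_modalities[0]][1]
        if "saps" in self.enabled_modalities:
            d += self.head_dims["saps"][1]
        return d

    @property
    def hidden_layers(self) -> tuple[int, ...]:
        if self.risk_hidden_layers is None:
            return (self.fused_dim,)
        return tuple(self.risk_hidden_layers)


def fuse_features(
    saps: np.ndarray | None, hidden_by_modality: Mapping[str, np.ndarray]
) -> np.ndarray:
    """Elementwise-average the modality hidden vectors, then append saps.

    ``saps`` may be the raw 15-vector or the saps-head output; ``None`` omits
    the block.  With a single non-saps modality the average is that vector;
    with none, the result is the saps block alone.
    """
    blocks = []
    if hidden_by_modality:
        vecs = [np.asarray(v, dtype=float) for v in hidden_by_modality.values()]
        lengths = {v.shape[-1] for v in vecs}
        if len(lengths) > 1:
            raise ValueError(f"averaged vectors must share a length, got {lengths}")
        blocks.append(np.mean(vecs, axis=0))
    if saps is not None:
        blocks.append(np.asarray(saps, dtype=float))
    if not blocks:
        raise ValueError("nothing to fuse")
    return np.concatenate(blocks, axis=-1)


# ---------------------------------------------------------------------------
# parameters


def _glorot(rng, shape):
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def _init_params(config: FusionConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    params: dict[str, np.ndarray] = {}
    for m in config.enabled_modalities:
        d_in, d_out = config.head_dims[m]
        params[f"head_{m}_W"] = _glorot(rng, (d_in, d_out))
        params[f"head_{m}_b"] = np.zeros(d_out)
    d_prev = config.fused_dim
    for l, width in enumerate(config.hidden_layers):
        params[f"risk_{l}_W"] = _glorot(rng, (d_prev, width))
        params[f"risk_{l}_b"] = np.zeros(width)
        d_prev = width
    params["out_W"] = _glorot(rng, (d_prev, 1))
    params["out_b"] = np.zeros(1)
    return params


@dataclass
class TrainedRiskModel:
    """Weights + config + training history of a fused risk network.

    ``training_history`` rows are (epoch, train_loss, val_loss);
    ``best_epoch`` indexes the row with the lowest validation loss.  GCN
    encoder context (frozen params and normalised adjacency) travels with the
    model when the gcn_text modality is enabled.
    """

    parameters: dict[str, np.ndarray]
    config: FusionConfig
    training_history: list[tuple[int, float, float]]
    best_epoch: int
    gcn_params: GCNParams | None = None
    a_hat: np.ndarray | None = None


# ---------------------------------------------------------------------------
# forward / backward


def _forward(params, config, features, *, dropout_rng=None):
    """Batch forward pass; returns (psi, cache for backprop).

    ``features`` maps modality -> (n, d_in) matrix.  Dropout is active only
    when ``dropout_rng`` is given (training mode).
    """
    cache: dict = {"heads": {}}
    avg_terms = []
    for m in config.averaged_modalities:
        X = features[m]
        A = X @ params[f"head_{m}_W"] + params[f"head_{m}_b"]
        H = np.maximum(A, 0.0)
        cache["heads"][m] = (X, A)
        avg_terms.append(H)
    blocks = []
    if avg_terms:
        blocks.append(np.mean(avg_terms, axis=0))
    if "saps" in config.enabled_modalities:
        X = features["saps"]
        A = X @ params["head_saps_W"] + params["head_saps_b"]
        H = np.maximum(A, 0.0) if config.saps_activation else A
        cache["heads"]["saps"] = (X, A)
        blocks.append(H)
    Z = np.concatenate(blocks, axis=1)
    cache["fused"] = Z
    cache["layers"] = []
    p = config.dropout
    for l in range(len(config.hidden_layers)):
        P = Z @ params[f"risk_{l}_W"] + params[f"risk_{l}_b"]
        R = np.maximum(P, 0.0)
        if dropout_rng is not None and p > 0:
            mask = (dropout_rng.uniform(size=R.shape) >= p) / (1 - p)
            D = R * mask
        else:
            mask = None
            D = R
        cache["layers"].append((Z, P, mask))
        Z = D
    psi = (Z @ params["out_W"] + params["out_b"]).ravel()
    cache["last"] = Z
    return psi, cache


def _backward(params, config, cache, dpsi):
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    g = dpsi[:, None] * params["out_W"].T  # (n, d_last)
    grads["out_W"] = cache["last"].T @ dpsi[:, None]
    grads["out_b"] = np.array([dpsi.sum()])
    p = config.dropout
    for l in reversed(range(len(config.hidden_layers))):
        Z_in, P, mask = cache["layers"][l]
        if mask is not None:
            g = g * mask
        g = g * (P > 0)
        grads[f"risk_{l}_W"] = Z_in.T @ g
        grads[f"risk_{l}_b"] = g.sum(axis=0)
        g = g @ params[f"risk_{l}_W"].T
    # split fused gradient into the averaged block and the saps block
    offset = 0
    avg = config.averaged_modalities
    if avg:
        d_avg = config.head_dims[avg[0]][1]
        g_avg = g[:, :d_avg] / len(avg)
        offset = d_avg
        for m in avg:
            X, A = cache["heads"][m]
            gm = g_avg * (A > 0)
            grads[f"head_{m}_W"] = X.T @ gm
            grads[f"head_{m}_b"] = gm.sum(axis=0)
    if "saps" in config.enabled_modalities:
        g_s = g[:, offset:]
        X, A = cache["heads"]["saps"]
        gs = g_s * (A > 0) if config.saps_activation else g_s
        grads["head_saps_W"] = X.T @ gs
        grads["head_saps_b"] = gs.sum(axis=0)
    return grads


def _neg_pll_and_grad(psi, times, events):
    """Batch loss (negative partial log-likelihood per event) and d/d psi."""
    n_events = int(np.sum(events))
    ll = cox_partial_log_likelihood(psi, times, events)
    g = cox_partial_loglik_gradient(psi, times, events)
    return -ll / n_events, -g / n_events


# ---------------------------------------------------------------------------
# encoding cohorts into modality matrices


def encode_modalities(
    cohort_or_records,
    modalities: tuple[str, ...],
    *,
    gcn_params: GCNParams | None = None,
    a_hat: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Stack per-record feature vectors into modality matrices."""
    records = list(cohort_or_records)
    out: dict[str, np.ndarray] = {}
    for m in modalities:
        if m == "saps":
            out[m] = np.stack([encode_saps_factors(r) for r in records])
        elif m == "labels":
            out[m] = np.stack([np.asarray(r.labels, dtype=float) for r in records])
        elif m == "transformer_text":
            out[m] = np.stack([pool_token_embeddings(r.token_embeddings) for r in records])
        elif m == "gcn_text":
            out[m] = np.stack(
                [encode_text(r, "gcn", gcn_params=gcn_params, a_hat=a_hat) for r in records]
            )
        elif m == "image":
            for r in records:
                if r.image_embedding is None:
                    raise ValueError(f"record {r.subject_id} has no image embedding")
            out[m] = np.stack([np.asarray(r.image_embedding, dtype=float) for r in records])
        else:
            raise ValueError(f"unknown modality {m!r}")
    return out


# ---------------------------------------------------------------------------
# training


def _event_balanced_batches(events, batch_size, rng):
    """Batch index lists with events dealt round-robin, so every batch that is
    used for a loss evaluation contains at least one event."""
    n = len(events)
    n_batches = max(1, int(np.ceil(n / batch_size)))
    ev_idx = np.flatnonzero(events)
    cen_idx = np.flatnonzero(~np.asarray(events, dtype=bool))
    rng.shuffle(ev_idx)
    rng.shuffle(cen_idx)
    batches = [[] for _ in range(n_batches)]
    for i, idx in enumerate(ev_idx):
        batches[i % n_batches].append(idx)
    for i, idx in enumerate(cen_idx):
        batches[i % n_batches].append(idx)
    batches = [np.array(b) for b in batches if len(b) >= 2 and events[b].sum() > 0]
    return batches


class _Adam:
    def __init__(self, params, lr):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads, beta1=0.9, beta2=0.999, eps=1e-8):
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = beta1 * self.m[k] + (1 - beta1) * g
            self.v[k] = beta2 * self.v[k] + (1 - beta2) * g * g
            mhat = self.m[k] / (1 - beta1**self.t)
            vhat = self.v[k] / (1 - beta2**self.t)
            params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + eps)


def train_on_arrays(
    features: dict[str, np.ndarray],
    times: np.ndarray,
    events: np.ndarray,
    val_features: dict[str, np.ndarray],
    val_times: np.ndarray,
    val_events: np.ndarray,
    config: FusionConfig,
    *,
    gcn_params: GCNParams | None = None,
    a_hat: np.ndarray | None = None,
) -> TrainedRiskModel:
    """Train the fused risk network on pre-encoded modality matrices."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    val_times = np.asarray(val_times, dtype=float)
    val_events = np.asarray(val_events).astype(bool)
    if events.sum() == 0:
        raise ValueError("training set has no events")

    init_rng = np.random.default_rng([config.seed, 11])
    batch_rng = np.random.default_rng([config.seed, 12])
    drop_rng = np.random.default_rng([config.seed, 13])

    params = _init_params(config, init_rng)
    model = TrainedRiskModel(
        parameters=params,
        config=config,
        training_history=[],
        best_epoch=0,
        gcn_params=gcn_params,
        a_hat=a_hat,
    )
    if config.max_epochs == 0:
        return model

    opt = _Adam(params, config.learning_rate)
    best_val = np.inf
    best_params = copy.deepcopy(params)
    best_epoch = 0
    patience_left = config.early_stop_patience
    history: list[tuple[int, float, float]] = []

    for epoch in range(1, config.max_epochs + 1):
        batches = _event_balanced_batches(events, config.batch_size, batch_rng)
        epoch_losses = []
        for idx in batches:
            fb = {m: X[idx] for m, X in features.items()}
            psi, cache = _forward(params, config, fb, dropout_rng=drop_rng)
            loss, dpsi = _neg_pll_and_grad(psi, times[idx], events[idx])
            grads = _backward(params, config, cache, dpsi)
            if config.weight_decay > 0:
                for k in grads:
                    if k.endswith("_W"):
                        grads[k] = grads[k] + config.weight_decay * params[k]
            opt.step(params, grads)
            epoch_losses.append(loss)
        train_loss = float(np.mean(epoch_losses))
        val_psi, _ = _forward(params, config, val_features)
        if val_events.sum() > 0:
            val_loss = -cox_partial_log_likelihood(val_psi, val_times, val_events) / int(
                val_events.sum()
            )
        else:
            val_loss = np.nan
        history.append((epoch, train_loss, float(val_loss)))
        if np.isfinite(val_loss) and val_loss < best_val - 1e-9:
            best_val = val_loss
            best_params = copy.deepcopy(params)
            best_epoch = epoch
            patience_left = config.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break

    model.parameters = best_params
    model.training_history = history
    model.best_epoch = best_epoch
    return model


def train_model(
    cohort_train: Cohort | list[SubjectRecord],
    cohort_val: Cohort | list[SubjectRecord],
    config: FusionConfig,
    *,
    gcn_params: GCNParams | None = None,
    a_hat: np.ndarray | None = None,
) -> TrainedRiskModel:
    """Encode both cohorts and train; see :func:`train_on_arrays`."""
    mods = config.enabled_modalities
    f_train = encode_modalities(cohort_train, mods, gcn_params=gcn_params, a_hat=a_hat)
    f_val = encode_modalities(cohort_val, mods, gcn_params=gcn_params, a_hat=a_hat)

    def _outcomes(c):
        recs = list(c)
        return (
            np.array([r.outcome.observed_time for r in recs]),
            np.array([r.outcome.event for r in recs]),
        )

    t_tr, e_tr = _outcomes(cohort_train)
    t_va, e_va = _outcomes(cohort_val)
    return train_on_arrays(
        f_train, t_tr, e_tr, f_val, t_va, e_va, config, gcn_params=gcn_params, a_hat=a_hat
    )


# ---------------------------------------------------------------------------
# inference


def risk_forward_batch(model: TrainedRiskModel, features: dict[str, np.ndarray]) -> np.ndarray:
    """Risk scores for pre-encoded features (evaluation mode, dropout off)."""
    psi, _ = _forward(model.parameters, model.config, features)
    return psi


def risk_forward(model: TrainedRiskModel, record: SubjectRecord) -> float:
    """Deterministic risk score psi(x) for one subject."""
    feats = encode_modalities(
        [record],
        model.config.enabled_modalities,
        gcn_params=model.gcn_params,
        a_hat=model.a_hat,
    )
    return float(risk_forward_batch(model, feats)[0])


def save_model(model: TrainedRiskModel, path) -> None:
    """Single-file checkpoint: weights + config JSON (+ GCN context)."""
    import dataclasses
    import json

    payload = {f"param_{k}": v for k, v in model.parameters.items()}
    cfg = dataclasses.asdict(model.config)
    cfg["head_dims"] = {k: list(v) for k, v in cfg["head_dims"].items()}
    meta = {
        "config": cfg,
        "best_epoch": model.best_epoch,
        "training_history": model.training_history,
    }
    payload["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    if model.gcn_params is not None:
        for name in ("conv_weights", "W0", "b0", "W1", "b1"):
            payload[f"gcn_{name}"] = getattr(model.gcn_params, name)
        payload["a_hat"] = model.a_hat
    np.savez(path, **payload)


def load_model(path) -> TrainedRiskModel:
    """Inverse of :func:`save_model`."""
    import json

    archive = np.load(path)
    meta = json.loads(bytes(archive["meta_json"]).decode())
    cfg = meta["config"]
    cfg["enabled_modalities"] = tuple(cfg["enabled_modalities"])
    cfg["head_dims"] = {k: tuple(v) for k, v in cfg["head_dims"].items()}
    if cfg.get("risk_hidden_layers") is not None:
        cfg["risk_hidden_layers"] = tuple(cfg["risk_hidden_layers"])
    config = FusionConfig(**cfg)
    params = {
        k[len("param_") :]: archive[k] for k in archive.files if k.startswith("param_")
    }
    gcn_params, a_hat = None, None
    if "gcn_W0" in archive.files:
        gcn_params = GCNParams(
            conv_weights=archive["gcn_conv_weights"],
            W0=archive["gcn_W0"],
            b0=archive["gcn_b0"],
            W1=archive["gcn_W1"],
            b1=archive["gcn_b1"],
        )
        a_hat = archive["a_hat"]
    return TrainedRiskModel(
        parameters=params,
        config=config,
        training_history=[tuple(h) for h in meta["training_history"]],
        best_epoch=int(meta["best_epoch"]),
        gcn_params=gcn_params,
        a_hat=a_hat,
    )


def predict_survival(
    model: TrainedRiskModel, baseline: BaselineSurvival, record: SubjectRecord
) -> SurvivalCurve:
    """Survival curve S(t | x) = S0(t) ** exp(psi(x)) for one subject."""
    return survival_function(baseline, risk_forward(model, record))
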
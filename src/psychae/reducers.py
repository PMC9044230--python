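"""Dimension reducers under a common encode/reconstruct contract.

Five variants share a 3-unit latent space by default:

``pca``
    Principal component analysis: project onto the top-k eigenvectors of
    the training correlation matrix and back-project.
``simple_ae``
    Single-hidden-layer linear autoencoder (15 -> 3 -> 15), trained with
    plain minibatch SGD.
``tied_ae``
    Same shape, but the decoder weight is constrained to the transpose of
    the encoder weight throughout training.
``deep_ae``
    Stacked encoder 15 -> 11 -> 6 -> 6 -> 3 with a mirrored decoder;
    saturating (tanh) hidden layers, linear bottleneck and output.
``independent_ae``
    15 -> 3 -> 15 with two extra penalties: the summed absolute
    off-diagonal entries of the latent covariance (decorrelated features)
    and squared deviations of the encoder/decoder weight Grams from the
    identity (orthogonality).

All variants operate on z-scored data (training statistics only) so that
reconstruction errors are comparable across algorithms.  Training is a
small self-contained float64 backprop engine seeded from the config, so
repeated fits are bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "VARIANTS",
    "ReducerConfig",
    "Standardizer",
    "FittedReducer",
    "TrainingError",
    "ConstructAssignment",
    "standardize_fit",
    "standardize_apply",
    "fit_pca",
    "fit_autoencoder",
    "fit_reducer",
    "encode",
    "reconstruct",
    "assign_items",
    "assign_from_weights",
]

VARIANTS = ("pca", "simple_ae", "tied_ae", "deep_ae", "independent_ae")


class TrainingError(RuntimeError):
    """Raised when optimization produces a non-finite loss."""


@dataclass(frozen=True)
class ReducerConfig:
    """Hyperparameters for one reducer fit.

    ``learning_rate=None`` resolves to the per-variant default: 1e-2 for
    the SGD-trained simple variant, 1e-3 for the Adam-trained ones.
    """

    variant: str = "pca"
    bottleneck: int = 3
    epochs: int = 500
    batch_size: int = 32
    learning_rate: float | None = None
    penalty_covariance: float = 0.1
    penalty_orthogonality: float = 0.1
    seed: int = 0
    patience: int = 50
    min_delta: float = 1e-6

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        if self.bottleneck < 1:
            raise ValueError("bottleneck must be >= 1")
        if self.penalty_covariance < 0 or self.penalty_orthogonality < 0:
            raise ValueError("penalty weights must be non-negative")

    @property
    def resolved_learning_rate(self) -> float:
        if self.learning_rate is not None:
            return self.learning_rate
        return 1e-2 if self.variant == "simple_ae" else 1e-3


# ---------------------------------------------------------------------------
# standardization


@dataclass(frozen=True)
class Standardizer:
    mean: np.ndarray
    sd: np.ndarray

    def transform(self, data: np.ndarray) -> np.ndarray:
        data = np.asarray(data, dtype=float)
        if data.shape[1] != self.mean.size:
            raise ValueError(
                f"expected {self.mean.size} columns, got {data.shape[1]}"
            )
        return (data - self.mean) / self.sd


def standardize_fit(train: np.ndarray) -> Standardizer:
    """Column z-scoring parameters from the training partition only."""
    train = np.asarray(train, dtype=float)
    if train.ndim != 2 or train.shape[0] < 2:
        raise ValueError("training data must have at least 2 rows")
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero-variance column(s): {zero.tolist()}")
    return Standardizer(mean, sd)


def standardize_apply(scaler: Standardizer, data: np.ndarray) -> np.ndarray:
    return scaler.transform(data)


# ---------------------------------------------------------------------------
# fitted model container


@dataclass
class FittedReducer:
    """A fitted reducer exposing encode/reconstruct on the standardized scale."""

    variant: str
    config: ReducerConfig
    # AE variants: alternating weight/bias per layer; activations per layer.
    weights: list[np.ndarray] = field(default_factory=list)
    biases: list[np.ndarray] = field(default_factory=list)
    activations: list[str] = field(default_factory=list)
    n_encoder_layers: int = 0
    tied: bool = False
    # PCA: orthonormal components (k x m) and training mean (zero after z-scoring).
    components: np.ndarray | None = None
    pca_mean: np.ndarray | None = None
    loss_history: list[float] = field(default_factory=list)

    # -- layer math ---------------------------------------------------------

    def _effective_weights(self) -> list[np.ndarray]:
        if not self.tied:
            return self.weights
        w = self.weights[0]
        return [w, w.T]

    def _forward(self, data: np.ndarray, upto: int | None = None) -> np.ndarray:
        a = data
        ws = self._effective_weights()
        stop = len(ws) if upto is None else upto
        for layer in range(stop):
            z = a @ ws[layer] + self.biases[layer]
            a = np.tanh(z) if self.activations[layer] == "tanh" else z
        return a

    def encode(self, data: np.ndarray) -> np.ndarray:
        data = self._check(data)
        if self.variant == "pca":
            return (data - self.pca_mean) @ self.components.T
        return self._forward(data, upto=self.n_encoder_layers)

    def reconstruct(self, data: np.ndarray) -> np.ndarray:
        data = self._check(data)
        if self.variant == "pca":
            return self.encode(data) @ self.components + self.pca_mean
        return self._forward(data)

    def _check(self, data: np.ndarray) -> np.ndarray:
        data = np.asarray(data, dtype=float)
        n_in = (
            self.components.shape[1]
            if self.variant == "pca"
            else self.weights[0].shape[0]
        )
        if data.ndim != 2 or data.shape[1] != n_in:
            raise ValueError(
                f"expected an (n, {n_in}) matrix, got shape {data.shape}"
            )
        return data

    def item_weights(self) -> np.ndarray:
        """Per-item absolute bottleneck weights (items x bottleneck).

        For the deep variant this is the product of the encoder layer
        weight matrices, i.e. the linearized item-to-bottleneck map.
        """
        if self.variant == "pca":
            w = self.components.T
        else:
            ws = self._effective_weights()[: self.n_encoder_layers]
            w = ws[0]
            for nxt in ws[1:]:
                w = w @ nxt
        return np.abs(w)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        out = {
            "variant": self.variant,
            "bottleneck": self.config.bottleneck,
            "seed": self.config.seed,
            "activations": list(self.activations),
            "n_encoder_layers": self.n_encoder_layers,
            "tied": self.tied,
            "loss_history": [float(v) for v in self.loss_history],
        }
        if self.variant == "pca":
            out["components"] = self.components.tolist()
            out["pca_mean"] = self.pca_mean.tolist()
        else:
            out["layers"] = [
                {"shape": list(w.shape), "w": w.ravel().tolist(), "b": b.tolist()}
                for w, b in zip(self.weights, self.biases)
            ]
        return out

    @classmethod
    def from_dict(cls, payload: dict) -> "FittedReducer":
        config = ReducerConfig(
            variant=payload["variant"],
            bottleneck=payload["bottleneck"],
            seed=payload.get("seed", 0),
        )
        model = cls(
            variant=payload["variant"],
            config=config,
            activations=list(payload.get("activations", [])),
            n_encoder_layers=payload.get("n_encoder_layers", 0),
            tied=payload.get("tied", False),
            loss_history=list(payload.get("loss_history", [])),
        )
        if payload["variant"] == "pca":
            model.components = np.asarray(payload["components"], dtype=float)
            model.pca_mean = np.asarray(payload["pca_mean"], dtype=float)
        else:
            for layer in payload["layers"]:
                shape = tuple(layer["shape"])
                model.weights.append(
                    np.asarray(layer["w"], dtype=float).reshape(shape)
                )
                model.biases.append(np.asarray(layer["b"], dtype=float))
        return model


def encode(model: FittedReducer, data: np.ndarray) -> np.ndarray:
    return model.encode(data)


def reconstruct(model: FittedReducer, data: np.ndarray) -> np.ndarray:
    return model.reconstruct(data)


# ---------------------------------------------------------------------------
# PCA


def fit_pca(train: np.ndarray, k: int = 3) -> FittedReducer:
    """PCA reducer with ``k`` components on (already standardized) data."""
    train = np.asarray(train, dtype=float)
    if k < 1 or k > train.shape[1]:
        raise ValueError(f"k must be in [1, {train.shape[1]}], got {k}")
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(train)
    model = FittedReducer(variant="pca", config=ReducerConfig("pca", bottleneck=k))
    model.components = pca.components_.copy()
    model.pca_mean = pca.mean_.copy()
    return model


# ---------------------------------------------------------------------------
# autoencoders


def _architecture(config: ReducerConfig, n_items: int):
    k = config.bottleneck
    if config.variant == "simple_ae":
        dims = [n_items, k, n_items]
        acts = ["linear", "linear"]
        n_enc = 1
    elif config.variant == "tied_ae":
        dims = [n_items, k, n_items]
        acts = ["linear", "linear"]
        n_enc = 1
    elif config.variant == "deep_ae":
        dims = [n_items, 11, 6, 6, k, 6, 6, 11, n_items]
        acts = ["tanh", "tanh", "tanh", "linear", "tanh", "tanh", "tanh", "linear"]
        n_enc = 4
    elif config.variant == "independent_ae":
        dims = [n_items, k, n_items]
        acts = ["tanh", "linear"]
        n_enc = 1
    else:
        raise ValueError(f"{config.variant!r} is not an autoencoder variant")
    return dims, acts, n_enc


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _SGD:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        for p, g in zip(params, grads):
            p -= self.lr * g


def _forward_cache(model: FittedReducer, batch: np.ndarray):
    activations = [batch]
    ws = model._effective_weights()
    for layer, w in enumerate(ws):
        z = activations[-1] @ w + model.biases[layer]
        a = np.tanh(z) if model.activations[layer] == "tanh" else z
        activations.append(a)
    return activations


def _objective(model: FittedReducer, data: np.ndarray, config: ReducerConfig) -> float:
    acts = _forward_cache(model, data)
    recon = float(np.mean((acts[-1] - data) ** 2))
    total = recon
    if config.variant == "independent_ae":
        h = acts[model.n_encoder_layers]
        hc = h - h.mean(axis=0)
        cov = hc.T @ hc / max(h.shape[0] - 1, 1)
        off = cov - np.diag(np.diag(cov))
        total += config.penalty_covariance * float(np.abs(off).sum())
        we, wd = model.weights[0], model.weights[1]
        total += config.penalty_orthogonality * (
            float(np.sum((we.T @ we - np.eye(we.shape[1])) ** 2))
            + float(np.sum((wd @ wd.T - np.eye(wd.shape[0])) ** 2))
        )
    return total


def _backward(model: FittedReducer, batch: np.ndarray, config: ReducerConfig):
    """Gradients of the (penalized) mean-squared reconstruction objective."""
    acts = _forward_cache(model, batch)
    ws = model._effective_weights()
    n_layers = len(ws)
    m = batch.shape[0]
    grad_w = [np.zeros_like(w) for w in ws]
    grad_b = [np.zeros_like(b) for b in model.biases]

    # output error: d mean((out - x)^2) / d out
    delta = 2.0 * (acts[-1] - batch) / acts[-1].size

    # latent-covariance penalty injects gradient at the bottleneck activation
    cov_grad = None
    if config.variant == "independent_ae" and config.penalty_covariance > 0:
        h = acts[model.n_encoder_layers]
        hc = h - h.mean(axis=0)
        denom = max(m - 1, 1)
        cov = hc.T @ hc / denom
        sign = np.sign(cov)
        np.fill_diagonal(sign, 0.0)
        cov_grad = config.penalty_covariance * 2.0 * (hc @ sign) / denom

    for layer in range(n_layers - 1, -1, -1):
        if model.activations[layer] == "tanh":
            delta = delta * (1.0 - acts[layer + 1] ** 2)
        grad_w[layer] = acts[layer].T @ delta
        grad_b[layer] = delta.sum(axis=0)
        if layer > 0:
            delta = delta @ ws[layer].T
            if cov_grad is not None and layer == model.n_encoder_layers:
                # penalty acts on h = acts[n_enc]; the next loop iteration
                # applies the bottleneck activation derivative
                delta = delta + cov_grad

    if config.variant == "independent_ae" and config.penalty_orthogonality > 0:
        we, wd = model.weights[0], model.weights[1]
        grad_w[0] += (
            config.penalty_orthogonality
            * 4.0
            * we
            @ (we.T @ we - np.eye(we.shape[1]))
        )
        grad_w[1] += (
            config.penalty_orthogonality
            * 4.0
            * (wd @ wd.T - np.eye(wd.shape[0]))
            @ wd
        )

    if model.tied:
        return [grad_w[0] + grad_w[1].T], grad_b
    return grad_w, grad_b


def fit_autoencoder(train: np.ndarray, config: ReducerConfig) -> FittedReducer:
    """Train one autoencoder variant on (already standardized) data.

    Minibatch gradient descent (SGD for ``simple_ae``, Adam otherwise)
    on the mean-squared reconstruction loss plus any variant penalties,
    with early stopping once the full-sample objective plateaus.  The
    training log records the full-sample objective at the end of every
    epoch.
    """
    train = np.asarray(train, dtype=float)
    if config.variant == "pca":
        raise ValueError("use fit_pca for the pca variant")
    n, n_items = train.shape
    if config.bottleneck >= n_items:
        raise ValueError(
            f"bottleneck {config.bottleneck} must be < {n_items} input variables"
        )
    dims, acts, n_enc = _architecture(config, n_items)
    rng = np.random.default_rng(config.seed)

    model = FittedReducer(
        variant=config.variant,
        config=config,
        activations=acts,
        n_encoder_layers=n_enc,
        tied=config.variant == "tied_ae",
    )
    n_layers = len(dims) - 1
    for layer in range(n_layers):
        if model.tied and layer == 1:
            continue
        limit = 1.0 / np.sqrt(dims[layer])
        model.weights.append(
            rng.uniform(-limit, limit, size=(dims[layer], dims[layer + 1]))
        )
    model.biases = [np.zeros(dims[layer + 1]) for layer in range(n_layers)]

    params = model.weights + model.biases
    lr = config.resolved_learning_rate
    opt_cls = _SGD if config.variant == "simple_ae" else _Adam
    opt = opt_cls(params, lr)

    best = np.inf
    stall = 0
    batch = max(1, min(config.batch_size, n))
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        with np.errstate(over="ignore", invalid="ignore"):
            for start in range(0, n, batch):
                rows = train[order[start : start + batch]]
                grad_w, grad_b = _backward(model, rows, config)
                opt.step(params, grad_w + grad_b)
            loss = _objective(model, train, config)
        if not np.isfinite(loss):
            raise TrainingError(
                f"non-finite loss at epoch {epoch} (variant={config.variant}, "
                f"learning_rate={lr})"
            )
        model.loss_history.append(loss)
        if loss < best - config.min_delta:
            best = loss
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    return model


def fit_reducer(train: np.ndarray, config: ReducerConfig) -> FittedReducer:
    """Dispatch to ``fit_pca`` or ``fit_autoencoder`` by variant."""
    if config.variant == "pca":
        return fit_pca(train, config.bottleneck)
    return fit_autoencoder(train, config)


# ---------------------------------------------------------------------------
# item-to-construct assignment


@dataclass(frozen=True)
class ConstructAssignment:
    """Per-item construct labels (1-based) and absolute bottleneck weights."""

    construct: np.ndarray  # (items,) int, values in 1..k
    weights: np.ndarray  # (items, k) absolute weights


def assign_from_weights(weights: np.ndarray) -> ConstructAssignment:
    """Assign each item to the construct with the largest absolute weight.

    Ties are broken toward the lowest construct index, with a warning.
    """
    w = np.abs(np.asarray(weights, dtype=float))
    if w.ndim != 2:
        raise ValueError("weights must be a 2-D (items x constructs) array")
    construct = w.argmax(axis=1)
    n_max = (w == w.max(axis=1, keepdims=True)).sum(axis=1)
    if np.any(n_max > 1):
        warnings.warn(
            f"tied maximum weights for item(s) "
            f"{np.flatnonzero(n_max > 1).tolist()}; assigned to the lowest "
            "construct index",
            stacklevel=2,
        )
    return ConstructAssignment(construct + 1, w)


def assign_items(model: FittedReducer) -> ConstructAssignment:
    """Max-|weight| item classification from a fitted reducer."""
    return assign_from_weights(model.item_weights())
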
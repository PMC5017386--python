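"""One-vs-all ensemble of small feed-forward networks.

Nine binary networks, one per gesture, each trained to separate its gesture
from the other eight (targets 1 vs 0) by minimizing binary cross-entropy with
scaled conjugate gradient on the full training batch.  Hidden layers use
tanh; the single output unit is a logistic sigmoid.  At prediction time the
gesture whose network responds most strongly wins; ties break toward the
lower routine ordinal.

Features are z-scored with statistics fitted on the training set only; the
standardizer travels with the ensemble so held-out data is transformed
identically (no leakage).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import GestureLabel, N_GESTURES, ROUTINE_ORDER
from .features import FeatureMatrix
from .scg import scg_minimize

__all__ = [
    "TrainConfig",
    "NetworkParams",
    "Standardizer",
    "OvaEnsemble",
    "train_ensemble",
    "predict_frames",
    "save_ensemble",
    "load_ensemble",
]


@dataclass(frozen=True)
class TrainConfig:
    """Network topology and SCG settings.

    Defaults are the empirically optimal configuration for this task: one
    hidden layer of 25 tanh units.  ``train_frame_stride`` trains on every
    k-th frame — at 50 Hz, neighbouring frames share most of their analysis
    window, so a stride of 4 discards almost no information while cutting
    the training cost fourfold; prediction always uses every frame.
    ``scg_ftol`` stops training once the mean cross-entropy stops improving
    (plateau over 10 accepted steps); set to 0 to always run max_iter.
    """

    hidden_nodes: int = 25
    hidden_layers: int = 1
    max_iter: int = 300
    grad_tol: float = 1e-6
    seed: int = 0
    scg_sigma: float = 1e-4
    scg_lambda0: float = 1e-6
    scg_ftol: float = 1e-5
    train_frame_stride: int = 4

    def __post_init__(self):
        if min(self.hidden_nodes, self.hidden_layers, self.max_iter) < 1:
            raise ValueError("hidden_nodes, hidden_layers and max_iter must be >= 1")
        if self.grad_tol <= 0 or self.scg_sigma <= 0 or self.scg_lambda0 <= 0:
            raise ValueError("tolerances must be positive")
        if self.train_frame_stride < 1:
            raise ValueError("train_frame_stride must be >= 1")

    def layer_sizes(self, n_features: int) -> list[int]:
        return [n_features] + [self.hidden_nodes] * self.hidden_layers + [1]


@dataclass
class NetworkParams:
    """Weights/biases of one binary network; tanh hidden, sigmoid output."""

    layer_sizes: list[int]
    weights: list[np.ndarray]  # W[l] has shape (fan_in, fan_out)
    biases: list[np.ndarray]

    def validate(self) -> None:
        sizes = self.layer_sizes
        assert len(self.weights) == len(self.biases) == len(sizes) - 1
        for l, (W, b) in enumerate(zip(self.weights, self.biases)):
            assert W.shape == (sizes[l], sizes[l + 1]) and b.shape == (sizes[l + 1],)
            if not (np.all(np.isfinite(W)) and np.all(np.isfinite(b))):
                raise ValueError("non-finite network parameters")


@dataclass
class Standardizer:
    """Per-feature z-scoring statistics; zero-variance features get std 1 so
    they standardize to a constant 0 instead of dividing by zero."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std = np.where(std > 0, std, 1.0)
        return cls(mean=mean, std=std)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.std


@dataclass
class OvaEnsemble:
    """The nine binary networks keyed by gesture, plus the shared feature
    standardizer and the training configuration that produced them."""

    networks: dict[GestureLabel, NetworkParams]
    standardizer: Standardizer
    train_config: TrainConfig

    def __post_init__(self):
        if set(self.networks) != set(ROUTINE_ORDER):
            raise ValueError("ensemble must contain exactly one network per gesture")


# ---------------------------------------------------------------------------
# parameter packing and the cross-entropy objective


def _init_params(sizes: list[int], rng: np.random.Generator) -> np.ndarray:
    """Uniform init in +-1/sqrt(fan_in), flattened."""
    chunks = []
    for l in range(len(sizes) - 1):
        bound = 1.0 / np.sqrt(sizes[l])
        chunks.append(rng.uniform(-bound, bound, size=sizes[l] * sizes[l + 1]))
        chunks.append(np.zeros(sizes[l + 1]))
    return np.concatenate(chunks)


def _unpack(theta: np.ndarray, sizes: list[int]) -> tuple[list[np.ndarray], list[np.ndarray]]:
    Ws, bs, o = [], [], 0
    for l in range(len(sizes) - 1):
        n_in, n_out = sizes[l], sizes[l + 1]
        Ws.append(theta[o : o + n_in * n_out].reshape(n_in, n_out))
        o += n_in * n_out
        bs.append(theta[o : o + n_out])
        o += n_out
    return Ws, bs


def _forward(X: np.ndarray, Ws, bs) -> tuple[np.ndarray, list[np.ndarray]]:
    """Return output logits (n,) and the hidden activations per layer."""
    hidden = []
    A = X
    for W, b in zip(Ws[:-1], bs[:-1]):
        A = np.tanh(A @ W + b)
        hidden.append(A)
    z = A @ Ws[-1] + bs[-1]
    return z[:, 0], hidden


def _bce_from_logits(z: np.ndarray, y: np.ndarray) -> float:
    # mean softplus(z) - y*z, computed stably
    return float(np.mean(np.logaddexp(0.0, z) - y * z))


def _make_objective(X: np.ndarray, y: np.ndarray, sizes: list[int]):
    n = X.shape[0]

    def fun_grad(theta: np.ndarray):
        Ws, bs = _unpack(theta, sizes)
        z, hidden = _forward(X, Ws, bs)
        f = _bce_from_logits(z, y)
        # backprop
        delta = (1.0 / (1.0 + np.exp(-z)) - y)[:, None] / n  # (n,1)
        gWs = [None] * len(Ws)
        gbs = [None] * len(bs)
        acts = [X] + hidden
        for l in range(len(Ws) - 1, -1, -1):
            gWs[l] = acts[l].T @ delta
            gbs[l] = delta.sum(axis=0)
            if l > 0:
                delta = (delta @ Ws[l].T) * (1.0 - hidden[l - 1] ** 2)
        g = np.concatenate([np.concatenate([w.ravel(), b]) for w, b in zip(gWs, gbs)])
        return f, g

    return fun_grad


# ---------------------------------------------------------------------------
# training and prediction


def train_ensemble(features: FeatureMatrix, cfg: TrainConfig) -> OvaEnsemble:
    """Fit the standardizer and the nine one-vs-all networks.

    Each network g minimizes binary cross-entropy on targets
    1{frame label == g} via SCG; weight initialization is seeded per gesture,
    so training is deterministic for a fixed config.
    """
    ords = features.label_ordinals()
    if np.unique(ords).size < 2:
        raise ValueError("training data must contain at least 2 gesture classes")

    std = Standardizer.fit(features.X)
    Xs = std.transform(features.X)[:: cfg.train_frame_stride]
    ys = ords[:: cfg.train_frame_stride]

    sizes = cfg.layer_sizes(features.dim)
    networks: dict[GestureLabel, NetworkParams] = {}
    for g in ROUTINE_ORDER:
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), g.ordinal]))
        theta0 = _init_params(sizes, rng)
        y = (ys == g.ordinal).astype(float)
        res = scg_minimize(
            _make_objective(Xs, y, sizes),
            theta0,
            max_iter=cfg.max_iter,
            grad_tol=cfg.grad_tol,
            sigma=cfg.scg_sigma,
            lambda0=cfg.scg_lambda0,
            ftol=cfg.scg_ftol,
        )
        Ws, bs = _unpack(res.x, sizes)
        net = NetworkParams(layer_sizes=sizes, weights=Ws, biases=bs)
        net.validate()
        networks[g] = net

    return OvaEnsemble(networks=networks, standardizer=std, train_config=cfg)


def predict_frames(
    ensemble: OvaEnsemble, features: FeatureMatrix
) -> tuple[list[GestureLabel], np.ndarray]:
    """Per-frame scores (sigmoid response of each network) and the winning
    labels (argmax, ties to the lowest ordinal)."""
    D = ensemble.networks[ROUTINE_ORDER[0]].layer_sizes[0]
    if features.dim != D:
        raise ValueError(f"feature dimension {features.dim} != ensemble dimension {D}")
    Xs = ensemble.standardizer.transform(features.X)
    scores = np.empty((features.n_frames, N_GESTURES))
    for g in ROUTINE_ORDER:
        net = ensemble.networks[g]
        z, _ = _forward(Xs, net.weights, net.biases)
        scores[:, g.ordinal] = 1.0 / (1.0 + np.exp(-z))
    winners = np.argmax(scores, axis=1)  # np.argmax takes the first (lowest) max
    labels = [GestureLabel.from_ordinal(i) for i in winners]
    return labels, scores


# ---------------------------------------------------------------------------
# persistence (JSON: layer sizes, flattened weights, standardizer stats)


def save_ensemble(ensemble: OvaEnsemble, path: Path) -> Path:
    doc = {
        "train_config": ensemble.train_config.__dict__,
        "standardizer": {
            "mean": ensemble.standardizer.mean.tolist(),
            "std": ensemble.standardizer.std.tolist(),
        },
        "networks": {
            g.name: {
                "layer_sizes": net.layer_sizes,
                "weights": [w.ravel().tolist() for w in net.weights],
                "biases": [b.tolist() for b in net.biases],
            }
            for g, net in ensemble.networks.items()
        },
    }
    path = Path(path)
    path.write_text(json.dumps(doc))
    return path


def load_ensemble(path: Path) -> OvaEnsemble:
    doc = json.loads(Path(path).read_text())
    std = Standardizer(
        mean=np.asarray(doc["standardizer"]["mean"]),
        std=np.asarray(doc["standardizer"]["std"]),
    )
    networks = {}
    for name, nd in doc["networks"].items():
        sizes = list(nd["layer_sizes"])
        Ws = [
            np.asarray(w).reshape(sizes[l], sizes[l + 1])
            for l, w in enumerate(nd["weights"])
        ]
        bs = [np.asarray(b) for b in nd["biases"]]
        networks[GestureLabel.from_code(name)] = NetworkParams(
            layer_sizes=sizes, weights=Ws, biases=bs
        )
    return OvaEnsemble(
        networks=networks,
        standardizer=std,
        train_config=TrainConfig(**doc["train_config"]),
    )
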
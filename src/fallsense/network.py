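"""Backpropagation classifier: an 8-20-1 multilayer perceptron.

Architecture is fixed by the feature vector: 8 inputs, 20 hidden units with
tansig activation (tansig(u) = 2 / (1 + e^{-2u}) - 1 = tanh(u)) and a single
relu output unit.  Training minimizes the half sum of squared errors

    ERR = (EY - Tg)' (EY - Tg) / 2

over {0, 1}-coded targets, by Levenberg-Marquardt (default) or plain batch
steepest descent; both drive the same objective and both are deterministic
given the initialization seed.  Weights and thresholds initialize uniformly
in [-0.5, 0.5].

Classification thresholds the relu output at 0.5 (configurable); outputs at
the threshold count as falls.  Optional min-max scaling of the inputs to
[0, 1] is fitted on training data only — the raw features mix binary flags
with durations up to 120 s, so scaling materially conditions the problem.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

N_INPUT = 8
N_HIDDEN = 20
N_OUTPUT = 1
N_PARAMS = N_HIDDEN * N_INPUT + N_HIDDEN + N_OUTPUT * N_HIDDEN + N_OUTPUT


@dataclass
class NetworkParams:
    """Weights and thresholds of the 8-20-1 network."""

    w1: np.ndarray  # (20, 8)
    b1: np.ndarray  # (20,)
    w2: np.ndarray  # (1, 20)
    b2: np.ndarray  # (1,)

    def __post_init__(self):
        self.w1 = np.asarray(self.w1, dtype=np.float64).reshape(N_HIDDEN, N_INPUT)
        self.b1 = np.asarray(self.b1, dtype=np.float64).reshape(N_HIDDEN)
        self.w2 = np.asarray(self.w2, dtype=np.float64).reshape(N_OUTPUT, N_HIDDEN)
        self.b2 = np.asarray(self.b2, dtype=np.float64).reshape(N_OUTPUT)
        for a in (self.w1, self.b1, self.w2, self.b2):
            if not np.all(np.isfinite(a)):
                raise ValueError("network parameters must be finite")

    def copy(self) -> "NetworkParams":
        return NetworkParams(self.w1.copy(), self.b1.copy(),
                             self.w2.copy(), self.b2.copy())


@dataclass
class TrainConfig:
    algorithm: str = "levenberg-marquardt"  # or "steepest-descent"
    target_mse: float = 1e-3
    max_epochs: int = 1000
    learning_rate: float = 0.001    # steepest-descent step size (summed gradient)
    damping: float = 1e-3           # initial LM damping lambda
    seed: int = 0
    input_scaling: str = "minmax"   # none | minmax | zscore
    restarts: int = 5               # seeded re-initializations if a fit stalls

    def __post_init__(self):
        if self.target_mse <= 0:
            raise ValueError("target_mse must be positive")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be nonnegative")
        if self.algorithm not in ("levenberg-marquardt", "steepest-descent"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.input_scaling not in ("none", "minmax", "zscore"):
            raise ValueError(f"unknown input_scaling {self.input_scaling!r}")


@dataclass
class TrainedClassifier:
    params: NetworkParams
    config: TrainConfig
    final_error: float              # training MSE at stop
    decision_threshold: float = 0.5
    scale_offset: np.ndarray | None = None
    scale_factor: np.ndarray | None = None

    def scale(self, x: np.ndarray) -> np.ndarray:
        if self.scale_offset is None:
            return x
        return (x - self.scale_offset) * self.scale_factor


def init_params(rng: np.random.Generator) -> NetworkParams:
    u = lambda *shape: rng.uniform(-0.5, 0.5, size=shape)
    return NetworkParams(u(N_HIDDEN, N_INPUT), u(N_HIDDEN),
                         u(N_OUTPUT, N_HIDDEN), u(N_OUTPUT))


def pack(params: NetworkParams) -> np.ndarray:
    return np.concatenate([params.w1.ravel(), params.b1,
                           params.w2.ravel(), params.b2])


def unpack(theta: np.ndarray) -> NetworkParams:
    i = 0
    w1 = theta[i:i + N_HIDDEN * N_INPUT].reshape(N_HIDDEN, N_INPUT); i += w1.size
    b1 = theta[i:i + N_HIDDEN]; i += N_HIDDEN
    w2 = theta[i:i + N_OUTPUT * N_HIDDEN].reshape(N_OUTPUT, N_HIDDEN); i += w2.size
    b2 = theta[i:i + N_OUTPUT]
    return NetworkParams(w1, b1, w2, b2)


def _forward_parts(x: np.ndarray, params: NetworkParams):
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    z = np.tanh(x @ params.w1.T + params.b1)          # (n, 20)
    a2 = z @ params.w2.T + params.b2                  # (n, 1)
    y = np.maximum(a2, 0.0)
    return x, z, a2, y[:, 0]


def forward(x: np.ndarray, params: NetworkParams) -> float | np.ndarray:
    """Network output for one feature vector (scalar) or a batch (array)."""
    xa = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(xa)):
        raise ValueError("input features must be finite")
    single = xa.ndim == 1
    _, _, _, y = _forward_parts(xa, params)
    return float(y[0]) if single else y


def err_value(params: NetworkParams, x: np.ndarray, t: np.ndarray) -> float:
    """ERR = half sum of squared output errors over the batch."""
    _, _, _, y = _forward_parts(x, params)
    r = y - np.asarray(t, dtype=np.float64)
    return 0.5 * float(r @ r)


def _jacobian(params: NetworkParams, x: np.ndarray) -> np.ndarray:
    """d output / d theta per sample, shape (n, N_PARAMS)."""
    x, z, a2, _ = _forward_parts(x, params)
    n = x.shape[0]
    drelu = (a2[:, 0] > 0).astype(np.float64)          # (n,)
    dz = (1.0 - z * z)                                 # (n, 20) tanh'
    # hidden pre-activation sensitivities: drelu * w2_j * dz_j
    s = drelu[:, None] * params.w2[0][None, :] * dz    # (n, 20)
    J = np.empty((n, N_PARAMS))
    J[:, :N_HIDDEN * N_INPUT] = (s[:, :, None] * x[:, None, :]).reshape(n, -1)
    i = N_HIDDEN * N_INPUT
    J[:, i:i + N_HIDDEN] = s
    i += N_HIDDEN
    J[:, i:i + N_HIDDEN] = drelu[:, None] * z
    i += N_HIDDEN
    J[:, i] = drelu
    return J


def err_gradient(params: NetworkParams, x: np.ndarray,
                 t: np.ndarray) -> np.ndarray:
    """Backpropagation gradient of ERR with respect to the packed parameters."""
    _, _, _, y = _forward_parts(x, params)
    r = y - np.asarray(t, dtype=np.float64)
    return _jacobian(params, x).T @ r


def train(features: np.ndarray, targets: np.ndarray,
          config: TrainConfig | None = None) -> TrainedClassifier:
    """Fit the 8-20-1 network to {0, 1}-coded targets.

    Refuses single-class data (nothing to separate).  With
    ``max_epochs == 0`` the seeded initialization is returned untouched.
    Stops when the training MSE reaches ``target_mse`` or after
    ``max_epochs`` epochs; Levenberg-Marquardt only accepts steps that
    decrease ERR, so ERR is non-increasing across accepted iterations.
    """
    config = config or TrainConfig()
    x = np.asarray(features, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64).ravel()
    if x.ndim != 2 or x.shape[1] != N_INPUT:
        raise ValueError(f"features must be (n, {N_INPUT})")
    if x.shape[0] != t.shape[0]:
        raise ValueError("features and targets are misaligned")
    classes = np.unique(t)
    if classes.size < 2:
        raise ValueError(
            f"training data contains a single class ({classes.tolist()}); "
            "at least one sample per class is required"
        )

    offset = factor = None
    if config.input_scaling == "minmax":
        lo, hi = x.min(axis=0), x.max(axis=0)
        rng_ = np.where(hi > lo, hi - lo, 1.0)
        offset, factor = lo, 1.0 / rng_
    elif config.input_scaling == "zscore":
        mu, sd = x.mean(axis=0), x.std(axis=0)
        offset, factor = mu, 1.0 / np.where(sd > 0, sd, 1.0)
    if offset is not None:
        x = (x - offset) * factor

    rng = np.random.default_rng(config.seed)
    n = x.shape[0]

    if config.max_epochs == 0:
        params = init_params(rng)
        mse = 2.0 * err_value(params, x, t) / n
        return TrainedClassifier(params, config, mse,
                                 scale_offset=offset, scale_factor=factor)

    # the relu output has a flat region (all pre-activations negative) where
    # the gradient vanishes and a fit can stall; restart from the next
    # seeded initialization and keep the best run
    best_theta = None
    best_err = np.inf
    for _restart in range(max(1, config.restarts)):
        p0 = init_params(rng)
        # calibrate the output bias so the mean pre-activation starts at the
        # target mean (0.5): the hidden tanh layer can saturate to nearly
        # sample-independent outputs, and an uncalibrated start then lands in
        # the relu's dead region with even odds
        _, z0, _, _ = _forward_parts(x, p0)
        p0.b2 = p0.b2 - float((z0 @ p0.w2.T + p0.b2).mean()) + 0.5
        theta = pack(p0)
        if config.algorithm == "steepest-descent":
            for _ in range(config.max_epochs):
                p = unpack(theta)
                if 2.0 * err_value(p, x, t) / n <= config.target_mse:
                    break
                theta = theta - config.learning_rate * err_gradient(p, x, t)
            err = err_value(unpack(theta), x, t)
        else:
            lam = config.damping
            err = err_value(unpack(theta), x, t)
            for _ in range(config.max_epochs):
                if 2.0 * err / n <= config.target_mse:
                    break
                p = unpack(theta)
                J = _jacobian(p, x)
                if not J.any():
                    break  # dead relu everywhere: this start is hopeless
                _, _, _, y = _forward_parts(x, p)
                r = y - t
                g = J.T @ r
                jtj = J.T @ J
                improved = False
                for _try in range(50):
                    try:
                        delta = np.linalg.solve(jtj + lam * np.eye(N_PARAMS), -g)
                    except np.linalg.LinAlgError:
                        lam *= 10.0
                        continue
                    cand = theta + delta
                    cand_err = err_value(unpack(cand), x, t)
                    if cand_err < err:
                        theta, err = cand, cand_err
                        lam = max(lam / 10.0, 1e-12)
                        improved = True
                        break
                    lam *= 10.0
                    if lam > 1e12:
                        break
                if not improved:
                    break
        if err < best_err:
            best_theta, best_err = theta, err
        if 2.0 * best_err / n <= config.target_mse:
            break

    params = unpack(best_theta)
    mse = 2.0 * best_err / n
    return TrainedClassifier(params, config, mse,
                             scale_offset=offset, scale_factor=factor)


def classify(x: np.ndarray, clf: TrainedClassifier):
    """'fall' iff the network output is at or above the decision threshold."""
    xa = np.asarray(x, dtype=np.float64)
    single = xa.ndim == 1
    y = forward(clf.scale(np.atleast_2d(xa)), clf.params)
    out = np.where(y >= clf.decision_threshold, "fall", "non_fall")
    return str(out[0]) if single else out


def save_model(clf: TrainedClassifier, path: str | Path) -> Path:
    """Persist a trained model as flat JSON (weights, thresholds, config)."""
    path = Path(path)
    doc = {
        "architecture": [N_INPUT, N_HIDDEN, N_OUTPUT],
        "w1": clf.params.w1.tolist(),
        "b1": clf.params.b1.tolist(),
        "w2": clf.params.w2.tolist(),
        "b2": clf.params.b2.tolist(),
        "config": asdict(clf.config),
        "final_error": clf.final_error,
        "decision_threshold": clf.decision_threshold,
        "scale_offset": None if clf.scale_offset is None else clf.scale_offset.tolist(),
        "scale_factor": None if clf.scale_factor is None else clf.scale_factor.tolist(),
    }
    path.write_text(json.dumps(doc, indent=1), encoding="utf-8")
    return path


def load_model(path: str | Path) -> TrainedClassifier:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("architecture") != [N_INPUT, N_HIDDEN, N_OUTPUT]:
        warnings.warn("model file reports an unexpected architecture")
    return TrainedClassifier(
        params=NetworkParams(np.array(doc["w1"]), np.array(doc["b1"]),
                             np.array(doc["w2"]), np.array(doc["b2"])),
        config=TrainConfig(**doc["config"]),
        final_error=doc["final_error"],
        decision_threshold=doc["decision_threshold"],
        scale_offset=None if doc["scale_offset"] is None else np.array(doc["scale_offset"]),
        scale_factor=None if doc["scale_factor"] is None else np.array(doc["scale_factor"]),
    )
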
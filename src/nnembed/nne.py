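"""The NNE autoencoder: a symmetric, linearly tapered multilayer perceptron.

Each node's row of outgoing connections is one training sample, so a
network of ``n`` neurons contributes ``n`` binary vectors of length ``n``.
The encoder narrows linearly from the input width to the middle layer over
``depth`` weight layers, and the decoder mirrors it; the whole architecture
is therefore fixed by two integers, *Depth* and *Middle Size*.  Hidden
layers use ReLU, the output layer a sigmoid, and training minimises binary
cross-entropy with the Adam optimiser (Keras-default hyperparameters:
learning rate 1e-3, beta1 0.9, beta2 0.999, epsilon 1e-7) with early
stopping once the monitored loss has not improved for ``patience``
consecutive epochs.

The implementation is plain NumPy: the model is small (a few hundred
units), and a closed implementation makes training bit-for-bit
reproducible for a given seed, which the reproducibility contracts of this
package rely on.

The compressed *features* are the middle-layer activations: with Middle
Size 13 on 100-node networks, 13 vectors of 100 components per network.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    ConfigurationError,
    DimensionError,
    StatisticsError,
    TrainingDivergenceError,
    UndefinedValueError,
)
from .netio import DirectedBinaryNetwork, make_folds

logger = logging.getLogger(__name__)

__all__ = [
    "NNEArchitecture",
    "TrainingConfig",
    "NNEModel",
    "FeatureMatrix",
    "build_layer_sizes",
    "train",
    "bce_loss",
    "reconstruct",
    "accuracy",
    "error_rate",
    "tp_accuracy",
    "extract_features",
    "grid_survey",
    "summarize_survey",
    "compare_middle_sizes",
    "DEFAULT_DEPTHS",
    "DEFAULT_MIDDLE_SIZES",
]

#: Grid surveyed in the architecture sweep: depths 3..11, middle sizes 1..29 odd.
DEFAULT_DEPTHS = tuple(range(3, 12))
DEFAULT_MIDDLE_SIZES = tuple(range(1, 30, 2))

_EPS = 1e-7  # probability clipping floor for the cross-entropy


def build_layer_sizes(input_size: int, depth: int, middle_size: int) -> list[int]:
    """Unit counts of the symmetric taper.

    Encoder step ``d`` (0..depth) has
    ``round(input_size + (middle_size - input_size) * d / depth)`` units
    (round half to even); the decoder mirrors the encoder without
    duplicating the middle.  ``(100, 3, 13)`` gives
    ``[100, 71, 42, 13, 42, 71, 100]``.
    """
    if depth < 1:
        raise ConfigurationError(f"depth must be >= 1, got {depth}")
    if not 1 <= middle_size <= input_size:
        raise ConfigurationError(
            f"middle_size must be in 1..input_size, got {middle_size} vs {input_size}"
        )
    enc = [
        int(np.rint(input_size + (middle_size - input_size) * d / depth))
        for d in range(depth + 1)
    ]
    return enc + enc[-2::-1]


@dataclass(frozen=True)
class NNEArchitecture:
    """Symmetric tapered autoencoder shape: fixed by depth and middle size."""

    input_size: int
    depth: int
    middle_size: int

    @property
    def layer_sizes(self) -> list[int]:
        return build_layer_sizes(self.input_size, self.depth, self.middle_size)


@dataclass
class TrainingConfig:
    """Optimisation settings (defaults follow the study conditions)."""

    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-7
    patience: int = 50
    max_epochs: int = 2000
    batch_size: int = 32
    binarization_threshold: float = 0.5
    monitor: str = "validation"  # or "training"
    seed: int = 0

    def __post_init__(self):
        if self.patience < 1:
            raise ConfigurationError("patience must be >= 1")
        if not 0 < self.binarization_threshold < 1:
            raise ConfigurationError("binarization_threshold must be in (0,1)")
        if self.monitor not in ("validation", "training"):
            raise ConfigurationError(f"unknown monitor {self.monitor!r}")


@dataclass
class NNEModel:
    """A trained autoencoder: architecture, weights and training history."""

    architecture: NNEArchitecture
    weights: list[tuple[np.ndarray, np.ndarray]]
    history: pd.DataFrame
    config: TrainingConfig
    stopped_epoch: int = 0

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Output probabilities for input rows ``x`` (2-D array)."""
        h = np.asarray(x, dtype=float)
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(self.weights):
            z = h @ w + b
            h = _sigmoid(z) if i == last else np.maximum(z, 0.0)
        return h

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Middle-layer (ReLU) activations for input rows ``x``."""
        h = np.asarray(x, dtype=float)
        for w, b in self.weights[: self.architecture.depth]:
            h = np.maximum(h @ w + b, 0.0)
        return h


@dataclass
class FeatureMatrix:
    """Compressed per-node features: column j = feature j across nodes."""

    values: np.ndarray  # n_nodes x middle_size
    node_ids: list[str]
    provenance: str = ""

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"feature_{j + 1}" for j in range(self.n_features)]
        return pd.DataFrame(self.values, index=self.node_ids, columns=cols)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(y: np.ndarray, p: np.ndarray, eps: float = _EPS) -> float:
    """Mean binary cross-entropy ``-(1/N) sum[y log p + (1-y) log(1-p)]``.

    Probabilities are clipped to ``[eps, 1-eps]`` before the logs.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise DimensionError(f"shape mismatch: y {y.shape} vs p {p.shape}")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _init_weights(sizes: Sequence[int], rng: np.random.Generator):
    weights = []
    for fan_in, fan_out in itertools.pairwise(sizes):
        limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
        w = rng.uniform(-limit, limit, size=(fan_in, fan_out))
        b = np.zeros(fan_out)
        weights.append((w, b))
    return weights


def _stack_rows(nets: Sequence[DirectedBinaryNetwork], input_size: int) -> np.ndarray:
    for net in nets:
        if net.n_nodes != input_size:
            raise DimensionError(
                f"network {net.name!r} has {net.n_nodes} nodes, expected {input_size}"
            )
    return np.vstack([n.adjacency for n in nets]).astype(float)


def train(
    train_nets: Sequence[DirectedBinaryNetwork],
    val_nets: Sequence[DirectedBinaryNetwork],
    arch: NNEArchitecture,
    config: TrainingConfig | None = None,
) -> NNEModel:
    """Fit the autoencoder on pooled node rows with early stopping.

    All rows of all training networks form one sample pool.  After every
    epoch the full training and validation losses are recorded; when the
    monitored loss (validation by default) has not improved for
    ``patience`` consecutive epochs, training stops and the best-epoch
    weights are restored.  Fully deterministic for a given seed.
    """
    config = config or TrainingConfig()
    if len(val_nets) == 0:
        raise ConfigurationError("validation set must be nonempty")
    x_train = _stack_rows(train_nets, arch.input_size)
    x_val = _stack_rows(val_nets, arch.input_size)

    rng = np.random.default_rng(config.seed)
    weights = _init_weights(arch.layer_sizes, rng)
    m_state = [(np.zeros_like(w), np.zeros_like(b)) for w, b in weights]
    v_state = [(np.zeros_like(w), np.zeros_like(b)) for w, b in weights]
    adam_t = 0

    def adam_step(grads):
        nonlocal adam_t
        adam_t += 1
        b1, b2, lr, eps = config.beta1, config.beta2, config.learning_rate, config.epsilon
        corr1 = 1.0 - b1**adam_t
        corr2 = 1.0 - b2**adam_t
        for i, ((gw, gb), (w, b)) in enumerate(zip(grads, weights)):
            mw, mb = m_state[i]
            vw, vb = v_state[i]
            mw = b1 * mw + (1 - b1) * gw
            mb = b1 * mb + (1 - b1) * gb
            vw = b2 * vw + (1 - b2) * gw**2
            vb = b2 * vb + (1 - b2) * gb**2
            m_state[i] = (mw, mb)
            v_state[i] = (vw, vb)
            w -= lr * (mw / corr1) / (np.sqrt(vw / corr2) + eps)
            b -= lr * (mb / corr1) / (np.sqrt(vb / corr2) + eps)

    def backprop(xb):
        acts = [xb]
        h = xb
        last = len(weights) - 1
        for i, (w, b) in enumerate(weights):
            z = h @ w + b
            h = _sigmoid(z) if i == last else np.maximum(z, 0.0)
            acts.append(h)
        # BCE + sigmoid output: delta = (p - y) / batch_size
        delta = (acts[-1] - xb) / xb.shape[0]
        grads = [None] * len(weights)
        for i in range(last, -1, -1):
            grads[i] = (acts[i].T @ delta, delta.sum(axis=0))
            if i > 0:
                delta = (delta @ weights[i][0].T) * (acts[i] > 0)
        return grads

    history: dict[str, list] = {
        "epoch": [], "train_loss": [], "train_accuracy": [],
        "val_loss": [], "val_accuracy": [],
    }
    thr = config.binarization_threshold
    best = np.inf
    best_weights = [(w.copy(), b.copy()) for w, b in weights]
    wait = 0
    stopped = config.max_epochs
    model = NNEModel(arch, weights, pd.DataFrame(), config)

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(x_train.shape[0])
        for start in range(0, len(order), config.batch_size):
            xb = x_train[order[start : start + config.batch_size]]
            adam_step(backprop(xb))

        p_train = model.forward(x_train)
        p_val = model.forward(x_val)
        tl = bce_loss(x_train, p_train)
        vl = bce_loss(x_val, p_val)
        history["epoch"].append(epoch)
        history["train_loss"].append(tl)
        history["train_accuracy"].append(float(((p_train >= thr) == x_train).mean()))
        history["val_loss"].append(vl)
        history["val_accuracy"].append(float(((p_val >= thr) == x_val).mean()))
        if not (np.isfinite(tl) and np.isfinite(vl)):
            raise TrainingDivergenceError(
                f"non-finite loss at epoch {epoch}", history=pd.DataFrame(history)
            )
        monitored = vl if config.monitor == "validation" else tl
        if monitored < best:
            best = monitored
            best_weights = [(w.copy(), b.copy()) for w, b in weights]
            wait = 0
        else:
            wait += 1
            if wait >= config.patience:
                stopped = epoch
                break

    model.weights = best_weights
    model.history = pd.DataFrame(history)
    model.stopped_epoch = stopped
    logger.info(
        "training stopped at epoch %d (best %s loss %.4f)",
        stopped, config.monitor, best,
    )
    return model


def reconstruct(
    model: NNEModel, net: DirectedBinaryNetwork
) -> tuple[DirectedBinaryNetwork, np.ndarray]:
    """Pass a network through the autoencoder and binarise the output.

    Returns the thresholded reconstruction (``p >= threshold`` maps to 1;
    the boundary value itself counts as 1; diagonal forced to 0) together
    with the raw probability matrix.
    """
    if net.n_nodes != model.architecture.input_size:
        raise DimensionError(
            f"network has {net.n_nodes} nodes, model expects "
            f"{model.architecture.input_size}"
        )
    p = model.forward(net.adjacency.astype(float))
    binary = (p >= model.config.binarization_threshold).astype(np.int8)
    np.fill_diagonal(binary, 0)
    recon = DirectedBinaryNetwork(binary, list(net.node_ids), None, f"{net.name}_recon")
    return recon, p


def _offdiag_mask(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


def accuracy(recon: np.ndarray, orig: np.ndarray) -> float:
    """Fraction of matching off-diagonal entries (self-cells excluded)."""
    recon = np.asarray(recon)
    orig = np.asarray(orig)
    if recon.shape != orig.shape:
        raise DimensionError(f"shape mismatch: {recon.shape} vs {orig.shape}")
    mask = _offdiag_mask(recon.shape[0])
    return float((recon[mask] == orig[mask]).mean())


def error_rate(recon: np.ndarray, orig: np.ndarray) -> float:
    """``1 - accuracy``."""
    return 1.0 - accuracy(recon, orig)


def tp_accuracy(recon: np.ndarray, orig: np.ndarray) -> float:
    """Recall of original edges in percent: ``100 * TP / (TP + FN)``."""
    recon = np.asarray(recon)
    orig = np.asarray(orig)
    if recon.shape != orig.shape:
        raise DimensionError(f"shape mismatch: {recon.shape} vs {orig.shape}")
    mask = _offdiag_mask(recon.shape[0])
    pos = orig[mask] == 1
    if not pos.any():
        raise UndefinedValueError("TP accuracy undefined: network has no edges")
    return float(100.0 * (recon[mask][pos] == 1).mean())


def extract_features(model: NNEModel, net: DirectedBinaryNetwork) -> FeatureMatrix:
    """Middle-layer activations per node: an ``n_nodes x middle_size`` matrix."""
    if net.n_nodes != model.architecture.input_size:
        raise DimensionError(
            f"network has {net.n_nodes} nodes, model expects "
            f"{model.architecture.input_size}"
        )
    values = model.encode(net.adjacency.astype(float))
    prov = (
        f"depth={model.architecture.depth},middle={model.architecture.middle_size},"
        f"net={net.name}"
    )
    return FeatureMatrix(values, list(net.node_ids), prov)


def grid_survey(
    nets: Sequence[DirectedBinaryNetwork],
    depths: Sequence[int] = DEFAULT_DEPTHS,
    middle_sizes: Sequence[int] = DEFAULT_MIDDLE_SIZES,
    config: TrainingConfig | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated sweep over (Depth, Middle Size).

    For every grid cell and fold, a model is trained on the pure-training
    networks, early-stopped on the validation networks, and evaluated on
    the test networks.  Returns a long-format table (depth, middle_size,
    fold, loss, accuracy); a failed cell is recorded as NaN with the error
    message, not raised.
    """
    if not depths or not middle_sizes:
        raise ConfigurationError("depth and middle-size grids must be nonempty")
    config = config or TrainingConfig()
    folds = make_folds(nets, n_folds=n_folds, seed=seed)
    input_size = nets[0].n_nodes
    rows = []
    for depth in depths:
        for mid in middle_sizes:
            arch = NNEArchitecture(input_size, depth, mid)
            for f in range(n_folds):
                tr, va, te = folds.split(f)
                try:
                    model = train(
                        [nets[i] for i in tr],
                        [nets[i] for i in va],
                        arch,
                        replace(config, seed=config.seed + f),
                    )
                    x_test = _stack_rows([nets[i] for i in te], input_size)
                    p = model.forward(x_test)
                    loss = bce_loss(x_test, p)
                    accs = [
                        accuracy(reconstruct(model, nets[i])[0].adjacency,
                                 nets[i].adjacency)
                        for i in te
                    ]
                    rows.append((depth, mid, f, loss, float(np.mean(accs)), ""))
                except Exception as exc:  # recorded, not fatal
                    logger.warning("cell (%d,%d) fold %d failed: %s", depth, mid, f, exc)
                    rows.append((depth, mid, f, np.nan, np.nan, str(exc)))
    return pd.DataFrame(
        rows, columns=["depth", "middle_size", "fold", "loss", "accuracy", "error"]
    )


def summarize_survey(survey: pd.DataFrame) -> pd.DataFrame:
    """Per-cell mean and standard deviation over folds."""
    return (
        survey.groupby(["depth", "middle_size"])[["loss", "accuracy"]]
        .agg(["mean", "std"])
        .reset_index()
    )


_FLAG_LEVELS = ((0.01, "***"), (0.05, "**"), (0.1, "*"))


def compare_middle_sizes(
    accuracies: Mapping[int, Sequence[float]],
    reference: int = 1,
    correction: str = "benjamini-hochberg",
) -> pd.DataFrame:
    """Welch's t-test of each middle size against the reference size.

    Per-network accuracies for each middle size are compared with the
    reference group by a two-sample t-test with unequal variances, and the
    p-values corrected across comparisons (Bonferroni or
    Benjamini-Hochberg).  Significance flags mirror the */**/*** notation
    at thresholds 0.1 / 0.05 / 0.01.
    """
    from statsmodels.stats.multitest import multipletests

    if reference not in accuracies:
        raise ConfigurationError(f"reference middle size {reference} not in data")
    ref = np.asarray(accuracies[reference], dtype=float)
    others = [m for m in accuracies if m != reference]
    for m in [reference, *others]:
        if len(accuracies[m]) < 2:
            raise StatisticsError(f"middle size {m}: need >= 2 observations")
    raw = []
    for m in others:
        grp = np.asarray(accuracies[m], dtype=float)
        if np.var(grp) == 0 and np.var(ref) == 0 and np.mean(grp) == np.mean(ref):
            raw.append(1.0)  # identical degenerate groups
        else:
            raw.append(float(stats.ttest_ind(grp, ref, equal_var=False).pvalue))
    method = {"bonferroni": "bonferroni", "benjamini-hochberg": "fdr_bh"}.get(correction)
    if method is None:
        raise ConfigurationError(f"unknown correction {correction!r}")
    corrected = multipletests(raw, method=method)[1] if raw else np.array([])

    def flag(p: float) -> str:
        for level, stars in _FLAG_LEVELS:
            if p < level:
                return stars
        return "n.s."

    return pd.DataFrame(
        {
            "middle_size": others,
            "p_raw": raw,
            "p_corrected": corrected,
            "significance": [flag(p) for p in corrected],
        }
    ).sort_values("middle_size", ignore_index=True)
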
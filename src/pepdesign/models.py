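"""Potency regression models.

The central model is a two-headed multi-task convolutional network that
maps a one-hot encoded aligned peptide (30 positions x 21 channels) to
log10-molar EC50 at GCGR and GLP-1R. Robustness against initialization
noise comes from a committee (ensemble) of M independently seeded copies
whose prediction is the member average; the member spread estimates model
uncertainty.

Also provided: the baseline registry (ridge, SVR, Gaussian-process,
random-forest, single-task network variants) and a nearest-neighbour
regressor scored by BLOSUM62 global alignment.

Reference architecture: conv(256, k3, valid, L2 0.01 on kernel, ReLU)
-> batch-norm -> max-pool/2 -> dropout 0.5 -> conv(512, k3, valid,
L2 0.01 kernel+bias, ReLU) -> batch-norm -> max-pool/2 -> dropout 0.5
-> conv(128, k3, same, L2 kernel+bias) -> max-pool/2 -> flatten
-> dense 256 ReLU -> dense 64 ReLU -> two linear single-unit heads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from . import seqdata
from ._network import (
    Adam,
    BatchNorm,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    MaxPool1D,
    Network,
    fit_network,
    weighted_mse,
)

# ---------------------------------------------------------------------------
# Model specification


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters of the convolutional multi-task regressor."""

    conv_filters: tuple[int, ...] = (256, 512, 128)
    kernel: int = 3
    conv_padding: tuple[str, ...] = ("valid", "valid", "same")
    conv_relu: tuple[bool, ...] = (True, True, False)
    l2_kernel: tuple[float, ...] = (0.01, 0.01, 0.01)
    l2_bias: tuple[float, ...] = (0.0, 0.01, 0.01)
    batchnorm: tuple[bool, ...] = (True, True, False)
    dropout: tuple[float, ...] = (0.5, 0.5, 0.0)
    pool: int = 2
    dense: tuple[int, ...] = (256, 64)
    heads: int = 2
    alpha: tuple[float, ...] = (0.5, 0.5)
    learning_rate: float = 1e-3
    batch_size: int = 25
    max_epochs: int = 1500
    patience: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.conv_filters)
        for name in ("conv_padding", "conv_relu", "l2_kernel", "l2_bias",
                     "batchnorm", "dropout"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have one entry per conv layer")
        if self.heads != len(self.alpha):
            raise ValueError("alpha must have one weight per head")
        if any(a < 0 for a in self.alpha):
            raise ValueError("task-loss weights must be non-negative")
        if self.kernel < 1 or any(f < 1 for f in self.conv_filters) or \
                any(d < 1 for d in self.dense):
            raise ValueError("all layer widths must be positive")

    @classmethod
    def reference(cls, **overrides) -> "ModelSpec":
        """The printed reference configuration (120-example regime:
        batch 25, up to 1500 epochs, patience 100)."""
        return cls(**overrides)

    @classmethod
    def cv_regime(cls, **overrides) -> "ModelSpec":
        """The 105-example cross-validation regime: batch 20 (five
        parameter updates per epoch), patience 75."""
        return cls(batch_size=20, patience=75, **overrides)

    @classmethod
    def reduced(cls, **overrides) -> "ModelSpec":
        """A down-scaled configuration for fast experimentation and tests:
        same topology, fewer filters and epochs."""
        defaults = dict(
            conv_filters=(16, 32, 16), dense=(32, 16),
            batch_size=16, max_epochs=800, patience=100,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def single_task(self, task: int) -> "ModelSpec":
        return replace(self, heads=1, alpha=(1.0,))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        for key, val in d.items():
            if isinstance(val, list):
                d[key] = tuple(val)
        return cls(**d)


def build_multitask_model(spec: ModelSpec) -> Network:
    """Assemble the untrained network for ``spec``.

    The architecture is deterministic given the spec; initial weights are
    drawn from a generator seeded by ``spec.seed``."""
    rng = np.random.default_rng([int(spec.seed), 0])
    layers = []
    in_ch = len(seqdata.ALPHABET)
    length = seqdata.WIDTH
    for i, filters in enumerate(spec.conv_filters):
        layers.append(Conv1D(
            in_ch, filters, kernel=spec.kernel, padding=spec.conv_padding[i],
            relu=spec.conv_relu[i], l2_kernel=spec.l2_kernel[i],
            l2_bias=spec.l2_bias[i], rng=rng,
        ))
        if spec.conv_padding[i] == "valid":
            length = length - spec.kernel + 1
        if spec.batchnorm[i]:
            layers.append(BatchNorm(filters))
        layers.append(MaxPool1D(spec.pool))
        length //= spec.pool
        if spec.dropout[i] > 0:
            layers.append(Dropout(spec.dropout[i]))
        in_ch = filters
    layers.append(Flatten())
    dim = length * in_ch
    for width in spec.dense:
        layers.append(Dense(dim, width, relu=True, rng=rng))
        dim = width
    # The output heads: one linear single-unit layer per task, realised as
    # a single linear map with one column per head.
    layers.append(Dense(dim, spec.heads, relu=False, rng=rng))
    return Network(layers)


def multitask_loss(y_true, y_pred, alpha: Sequence[float] = (0.5, 0.5)) -> float:
    """Weighted average of per-task mean-squared errors,
    L_total = sum_i alpha_i * mse_i."""
    return weighted_mse(y_true, y_pred, alpha)


# ---------------------------------------------------------------------------
# Training


@dataclass
class TrainedModel:
    spec: ModelSpec
    net: Network
    history: dict
    stopped_epoch: int

    def predict(self, inputs) -> np.ndarray:
        X = as_conv_input(inputs)
        return self.net.forward(X, training=False)


def as_conv_input(inputs) -> np.ndarray:
    """Coerce peptides / flattened features / conv-shaped arrays to
    (n, W, 21)."""
    if isinstance(inputs, np.ndarray):
        if inputs.ndim == 3:
            return inputs
        if inputs.ndim == 2:
            return inputs.reshape(
                inputs.shape[0], seqdata.WIDTH, len(seqdata.ALPHABET))
        raise ValueError(f"cannot interpret array of ndim {inputs.ndim}")
    return seqdata.encode_batch(list(inputs))


def train(net: Network, X, Y, X_val, Y_val, spec: ModelSpec) -> TrainedModel:
    """Train ``net`` with Adam and validation-loss early stopping
    (best-validation weights restored)."""
    X, X_val = as_conv_input(X), as_conv_input(X_val)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    Y_val = np.atleast_2d(np.asarray(Y_val, dtype=float))
    if X.shape[0] == 0 or X_val.shape[0] == 0:
        raise ValueError("training and validation sets must be non-empty")
    # Start the output heads at the per-task target means: log10-molar
    # potencies sit around -8 to -12, and with Adam's unit-sized steps a
    # zero-initialised bias would otherwise eat thousands of epochs just
    # drifting onto the target scale.
    net.layers[-1].params["b"][:] = Y.mean(axis=0)
    rng = np.random.default_rng([int(spec.seed), 1])
    history, stopped = fit_network(
        net, X, Y, X_val, Y_val, alpha=spec.alpha,
        batch_size=spec.batch_size, max_epochs=spec.max_epochs,
        patience=spec.patience, lr=spec.learning_rate, rng=rng,
    )
    return TrainedModel(spec, net, history, stopped)


def train_model(spec: ModelSpec, X, Y, X_val, Y_val) -> TrainedModel:
    return train(build_multitask_model(spec), X, Y, X_val, Y_val, spec)


@dataclass
class EnsembleModel:
    """Committee of M independently seeded trained copies; the prediction
    is the arithmetic mean of the member predictions."""

    members: list[TrainedModel]

    @property
    def M(self) -> int:
        return len(self.members)

    def member_predictions(self, inputs) -> np.ndarray:
        X = as_conv_input(inputs)
        return np.stack([m.predict(X) for m in self.members])  # (M, n, k)

    def predict(self, inputs) -> np.ndarray:
        return self.member_predictions(inputs).mean(axis=0)

    def predict_with_spread(self, inputs) -> tuple[np.ndarray, np.ndarray]:
        preds = self.member_predictions(inputs)
        return preds.mean(axis=0), preds.std(axis=0)


def train_ensemble(spec: ModelSpec, X, Y, X_val, Y_val, M: int = 12) -> EnsembleModel:
    """Train M copies differing only in their random seed."""
    if M < 1:
        raise ValueError("ensemble must have at least one member")
    members = []
    for i in range(M):
        member_spec = replace(spec, seed=int(spec.seed) + i)
        members.append(train_model(member_spec, X, Y, X_val, Y_val))
    return EnsembleModel(members)


def ensemble_predict(ensemble: EnsembleModel, peptides) -> tuple[np.ndarray, np.ndarray]:
    """Per-peptide mean prediction and per-task member standard deviation."""
    if ensemble.M == 0:
        raise ValueError("empty ensemble")
    return ensemble.predict_with_spread(peptides)


# ---------------------------------------------------------------------------
# Checkpointing


def save_ensemble(ensemble: EnsembleModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "ensemble.json").write_text(json.dumps(
        {"M": ensemble.M,
         "specs": [asdict(m.spec) for m in ensemble.members],
         "stopped_epochs": [m.stopped_epoch for m in ensemble.members]},
        indent=2))
    for i, member in enumerate(ensemble.members):
        np.savez(directory / f"member_{i}.npz", **member.net.get_state())
        pd.DataFrame(member.history).to_csv(
            directory / f"history_{i}.csv", index_label="epoch")


def load_ensemble(directory: str | Path) -> EnsembleModel:
    directory = Path(directory)
    meta = json.loads((directory / "ensemble.json").read_text())
    members = []
    for i in range(meta["M"]):
        d = meta["specs"][i]
        spec = ModelSpec(**{k: tuple(v) if isinstance(v, list) else v
                            for k, v in d.items()})
        net = build_multitask_model(spec)
        with np.load(directory / f"member_{i}.npz") as state:
            net.set_state({k: state[k] for k in state.files})
        history = pd.read_csv(directory / f"history_{i}.csv").to_dict("list")
        members.append(TrainedModel(spec, net, history,
                                    meta["stopped_epochs"][i]))
    return EnsembleModel(members)


# ---------------------------------------------------------------------------
# BLOSUM62 global alignment and the nearest-neighbour baseline

_BLOSUM62 = None


def blosum62():
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return _BLOSUM62


def needleman_wunsch_score(
    a: str,
    b: str,
    matrix=None,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> float:
    """Optimal global alignment score under affine gap penalties (Gotoh).

    A gap of length g costs ``gap_open + (g - 1) * gap_extend``; end gaps
    are penalized. Inputs are ungapped amino-acid strings.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if seqdata.GAP in a or seqdata.GAP in b:
        raise ValueError("inputs must be ungapped; strip gaps first")
    mat = matrix if matrix is not None else blosum62()
    n, m = len(a), len(b)
    NEG = -1e30
    # M: a_i aligned to b_j; Ix: a_i aligned to a gap; Iy: b_j to a gap.
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Iy[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        srow = np.array([mat[a[i - 1], b[j]] for j in range(m)])
        for j in range(1, m + 1):
            best_prev = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            M[i, j] = best_prev + srow[j - 1]
            Ix[i, j] = max(M[i - 1, j] + gap_open, Ix[i - 1, j] + gap_extend)
            Iy[i, j] = max(M[i, j - 1] + gap_open, Iy[i, j - 1] + gap_extend)
    return float(max(M[n, m], Ix[n, m], Iy[n, m]))


def nearest_neighbour_predict(
    train_sequences: Sequence[str],
    train_labels: np.ndarray,
    query: str,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> np.ndarray:
    """Labels of the best-scoring training sequence(s); exact score ties
    are averaged per task."""
    if len(train_sequences) == 0:
        raise ValueError("empty training set")
    train_labels = np.atleast_2d(np.asarray(train_labels, dtype=float))
    scores = np.array([
        needleman_wunsch_score(seqdata.strip_gaps(s), seqdata.strip_gaps(query),
                               gap_open=gap_open, gap_extend=gap_extend)
        for s in train_sequences
    ])
    best = scores.max()
    ties = np.isclose(scores, best)
    return train_labels[ties].mean(axis=0)


# ---------------------------------------------------------------------------
# Baseline registry

BASELINE_NAMES = (
    "ridge", "svr", "gpr", "random_forest",
    "nn_single_task", "nn_multi_task", "nn_multi_task_ensemble",
    "nearest_neighbour",
)


class _SklearnPerTask:
    """Fits one scikit-learn regressor per receptor on flattened one-hot
    features; ignores the validation split (no early stopping)."""

    def __init__(self, factory):
        self._factory = factory
        self._models = None

    def fit(self, X, Y, X_val=None, Y_val=None):
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        self._models = []
        for k in range(Y.shape[1]):
            model = self._factory()
            model.fit(X, Y[:, k])
            self._models.append(model)
        return self

    def predict(self, X):
        return np.column_stack([m.predict(X) for m in self._models])


class _SklearnMultiOutput:
    def __init__(self, factory):
        self._factory = factory
        self._model = None

    def fit(self, X, Y, X_val=None, Y_val=None):
        self._model = self._factory()
        self._model.fit(X, np.atleast_2d(np.asarray(Y, dtype=float)))
        return self

    def predict(self, X):
        return self._model.predict(X)


class _NeuralRegressor:
    """Single- or multi-task convolutional network behind the uniform
    fit/predict interface. If no validation split is supplied, a seeded
    10% split is carved from the training data for early stopping."""

    def __init__(self, spec: ModelSpec, single_task: bool = False,
                 ensemble_size: int = 1):
        self.spec = spec
        self.single_task = single_task
        self.ensemble_size = ensemble_size
        self._models = None

    def _split(self, X, Y):
        rng = np.random.default_rng([int(self.spec.seed), 2])
        n = X.shape[0]
        n_val = max(1, n // 10)
        perm = rng.permutation(n)
        val, tr = perm[:n_val], perm[n_val:]
        return X[tr], Y[tr], X[val], Y[val]

    def fit(self, X, Y, X_val=None, Y_val=None):
        X = as_conv_input(X)
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if X_val is None:
            X, Y, X_val, Y_val = self._split(X, Y)
        else:
            X_val = as_conv_input(X_val)
            Y_val = np.atleast_2d(np.asarray(Y_val, dtype=float))
        self._models = []
        if self.single_task:
            for k in range(Y.shape[1]):
                spec = replace(self.spec.single_task(k),
                               seed=int(self.spec.seed) + 97 * k)
                self._models.append(
                    train_model(spec, X, Y[:, [k]], X_val, Y_val[:, [k]]))
        else:
            for i in range(self.ensemble_size):
                spec = replace(self.spec, seed=int(self.spec.seed) + i)
                self._models.append(train_model(spec, X, Y, X_val, Y_val))
        return self

    def predict(self, X):
        X = as_conv_input(X)
        if self.single_task:
            return np.column_stack(
                [m.predict(X)[:, 0] for m in self._models])
        return np.mean([m.predict(X) for m in self._models], axis=0)


class _NearestNeighbourRegressor:
    """BLOSUM62 global-alignment nearest neighbour; equidistant ties are
    averaged."""

    def __init__(self, gap_open=-10.0, gap_extend=-0.5):
        self.gap_open, self.gap_extend = gap_open, gap_extend
        self._sequences = None
        self._labels = None

    def fit(self, X, Y, X_val=None, Y_val=None):
        self._sequences = [seqdata.features_to_sequence(row) for row in
                           np.asarray(X).reshape(len(X), -1)]
        self._labels = np.atleast_2d(np.asarray(Y, dtype=float))
        return self

    def predict(self, X):
        queries = [seqdata.features_to_sequence(row) for row in
                   np.asarray(X).reshape(len(X), -1)]
        return np.vstack([
            nearest_neighbour_predict(
                self._sequences, self._labels, q,
                gap_open=self.gap_open, gap_extend=self.gap_extend)
            for q in queries
        ])


def baseline_registry(name: str, spec: ModelSpec | None = None,
                      seed: int = 0, ensemble_size: int = 12):
    """Instantiate a registered regressor with the uniform
    fit(features, two targets) / predict interface.

    ``spec`` configures the network-family entries (default: the reduced
    configuration, suitable for repeated cross-validation)."""
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.linear_model import Ridge
    from sklearn.svm import SVR

    if name not in BASELINE_NAMES:
        raise KeyError(
            f"unknown model {name!r}; choose one of {', '.join(BASELINE_NAMES)}")
    nn_spec = spec if spec is not None else ModelSpec.reduced(seed=seed)
    if name == "ridge":
        return _SklearnMultiOutput(Ridge)
    if name == "svr":
        return _SklearnPerTask(SVR)
    if name == "gpr":
        return _SklearnPerTask(
            lambda: GaussianProcessRegressor(normalize_y=True,
                                             random_state=seed))
    if name == "random_forest":
        return _SklearnMultiOutput(
            lambda: RandomForestRegressor(random_state=seed))
    if name == "nn_single_task":
        return _NeuralRegressor(nn_spec, single_task=True)
    if name == "nn_multi_task":
        return _NeuralRegressor(nn_spec)
    if name == "nn_multi_task_ensemble":
        return _NeuralRegressor(nn_spec, ensemble_size=ensemble_size)
    return _NearestNeighbourRegressor()
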
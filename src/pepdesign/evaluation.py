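"""Model evaluation: regression metrics, the repeated sixfold
cross-validation protocol, adversarial shuffle controls and
significance testing.

The cross-validation scheme follows the study protocol literally: per
repeat, a seeded permutation yields six disjoint 10-sequence test sets;
for each fold a further 10 sequences form the validation split and the
remaining 105 are used for training, so ten repeats produce
60 x 10 = 600 held-out squared errors per model and receptor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import seqdata
from .seqdata import Dataset, AlignedPeptide, PotencyRecord

# ---------------------------------------------------------------------------
# Metrics


def rmse(y, y_hat) -> float:
    """Root-mean-square error sqrt(mean((y - y_hat)^2))."""
    y, y_hat = np.asarray(y, float), np.asarray(y_hat, float)
    if y.shape != y_hat.shape or y.size == 0:
        raise ValueError("inputs must be non-empty and of equal shape")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def mae(y, y_hat) -> float:
    """Mean absolute error."""
    y, y_hat = np.asarray(y, float), np.asarray(y_hat, float)
    if y.shape != y_hat.shape or y.size == 0:
        raise ValueError("inputs must be non-empty and of equal shape")
    return float(np.mean(np.abs(y - y_hat)))


def r_squared(y, y_hat) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    y, y_hat = np.asarray(y, float), np.asarray(y_hat, float)
    if y.shape != y_hat.shape or y.size < 2:
        raise ValueError("need at least two paired observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: constant true values")
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / ss_tot


# ---------------------------------------------------------------------------
# Cross-validation scheme


@dataclass(frozen=True)
class CVFold:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray


@dataclass(frozen=True)
class CVScheme:
    n: int
    repeats: tuple[tuple[CVFold, ...], ...]
    seeds: tuple[int, ...]

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)

    @property
    def n_folds(self) -> int:
        return len(self.repeats[0])


def make_cv_scheme(
    n: int = 125,
    seeds: list[int] | None = None,
    n_repeats: int = 10,
    n_folds: int = 6,
    test_size: int | None = None,
    val_size: int | None = None,
) -> CVScheme:
    """Build the repeated sixfold scheme.

    For the 125-sequence dataset the fold sizes are 105/10/10. For other
    dataset sizes the test and validation sizes scale proportionally
    (rounded, at least 1) unless given explicitly.
    """
    if seeds is None:
        seeds = list(range(n_repeats))
    if test_size is None:
        test_size = max(1, round(n * 10 / 125))
    if val_size is None:
        val_size = test_size
    if n_folds * test_size + val_size >= n:
        raise ValueError(
            f"dataset of size {n} too small for {n_folds} folds of "
            f"test={test_size}, val={val_size}")
    repeats = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        folds = []
        for k in range(n_folds):
            test = np.sort(perm[k * test_size:(k + 1) * test_size])
            rest = np.setdiff1d(np.arange(n), test)
            val = np.sort(rng.choice(rest, size=val_size, replace=False))
            train = np.setdiff1d(rest, val)
            folds.append(CVFold(train=train, val=val, test=test))
        repeats.append(tuple(folds))
    return CVScheme(n=n, repeats=tuple(repeats), seeds=tuple(seeds))


def _assert_no_leak(fold: CVFold) -> None:
    if np.intersect1d(fold.train, fold.test).size or \
            np.intersect1d(fold.train, fold.val).size or \
            np.intersect1d(fold.val, fold.test).size:
        raise AssertionError("cross-validation split leaks between subsets")


def run_cv(
    model_factories: dict,
    dataset: Dataset,
    scheme: CVScheme,
    use_validation: set[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every model through the scheme.

    ``model_factories`` maps a model name to a zero-argument callable
    returning a fresh fit/predict regressor. Models named in
    ``use_validation`` (default: the nn_* family) receive the fold's
    validation split for early stopping; all others train on the 105
    training sequences only.

    Returns (errors, summary): ``errors`` holds one squared error per
    (model, receptor, repeat, fold, test sequence); ``summary`` reports
    per model and receptor the mean +/- sd of repeat-level RMSE across
    repeats.
    """
    if use_validation is None:
        use_validation = {name for name in model_factories if name.startswith("nn_")}
    X = seqdata.onehot_features(dataset.peptides)
    Y = dataset.labels()
    rows = []
    for name, factory in model_factories.items():
        for rep_idx, folds in enumerate(scheme.repeats):
            for fold_idx, fold in enumerate(folds):
                _assert_no_leak(fold)
                try:
                    model = factory()
                    if name in use_validation:
                        model.fit(X[fold.train], Y[fold.train],
                                  X_val=X[fold.val], Y_val=Y[fold.val])
                    else:
                        model.fit(X[fold.train], Y[fold.train])
                    pred = np.atleast_2d(model.predict(X[fold.test]))
                except Exception as exc:  # noqa: BLE001 - surfaced, run continues
                    warnings.warn(
                        f"model {name!r} failed on repeat {rep_idx} fold "
                        f"{fold_idx}: {exc}")
                    continue
                sq = (pred - Y[fold.test]) ** 2
                for j, receptor in enumerate(seqdata.RECEPTORS):
                    for t, i in enumerate(fold.test):
                        rows.append((name, receptor, rep_idx, fold_idx,
                                     int(i), float(sq[t, j])))
    errors = pd.DataFrame(
        rows, columns=["model", "receptor", "repeat", "fold", "index",
                       "squared_error"])
    summaries = []
    for (name, receptor), grp in errors.groupby(["model", "receptor"]):
        per_repeat = grp.groupby("repeat")["squared_error"].mean() ** 0.5
        summaries.append((name, receptor, float(per_repeat.mean()),
                          float(per_repeat.std(ddof=1)) if len(per_repeat) > 1
                          else float("nan")))
    summary = pd.DataFrame(
        summaries, columns=["model", "receptor", "rmse_mean", "rmse_sd"])
    return errors, summary


# ---------------------------------------------------------------------------
# Adversarial controls


def adversarial_controls(dataset: Dataset, mode: str, seed: int = 0) -> Dataset:
    """Return a shuffled copy of the dataset.

    mode="shuffle_sequences": permute the residues within each sequence
    (gap positions stay put, so the alignment frame is preserved).
    mode="shuffle_targets": permute the measured label pairs (with their
    censoring flags) across examples.
    """
    rng = np.random.default_rng(seed)
    if mode == "shuffle_sequences":
        peptides = []
        for p in dataset.peptides:
            residues = [s for s in p.residues if s != seqdata.GAP]
            rng.shuffle(residues)
            it = iter(residues)
            shuffled = "".join(
                next(it) if s != seqdata.GAP else seqdata.GAP
                for s in p.residues)
            peptides.append(AlignedPeptide(p.id, shuffled))
        return Dataset(peptides, list(dataset.records))
    if mode == "shuffle_targets":
        perm = rng.permutation(len(dataset))
        records = [
            PotencyRecord(dataset.peptides[i].id,
                          dataset.records[j].log_ec50,
                          dataset.records[j].censored)
            for i, j in enumerate(perm)
        ]
        return Dataset(list(dataset.peptides), records)
    raise ValueError(
        f"mode must be 'shuffle_sequences' or 'shuffle_targets', got {mode!r}")


# ---------------------------------------------------------------------------
# Model comparison


def compare_models(errors_a, errors_b) -> tuple[float, float]:
    """Welch's two-sided t-test on two squared-error populations.

    Returns (statistic, p-value); equal variances are not assumed."""
    a = np.asarray(errors_a, float)
    b = np.asarray(errors_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two error samples per model")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
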
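"""The multi-task network, its training loop and ensemble, the global
aligner and the baseline registry."""

import numpy as np
import pytest

from pepdesign import models, seqdata
from pepdesign._network import (
    BatchNorm, Conv1D, Dense, Flatten, MaxPool1D, Network, weighted_mse,
)
from pepdesign.models import (
    ModelSpec,
    baseline_registry,
    build_multitask_model,
    ensemble_predict,
    multitask_loss,
    needleman_wunsch_score,
    nearest_neighbour_predict,
    train_ensemble,
    train_model,
)

# ---------------------------------------------------------------------------
# Architecture


def test_default_spec_builds_two_headed_model_with_expected_shapes():
    net = build_multitask_model(ModelSpec())
    x = seqdata.encode_batch(
        [seqdata.HUMAN_GLP1] * 5).astype(float)
    out = net.forward(x, training=False)
    assert out.shape == (5, 2)
    assert np.isfinite(out).all()


def test_architecture_is_deterministic_across_seeds():
    a = build_multitask_model(ModelSpec(seed=1))
    b = build_multitask_model(ModelSpec(seed=2))
    assert a.n_parameters() == b.n_parameters()
    # same seed gives identical initial weights
    c = build_multitask_model(ModelSpec(seed=1))
    for (_, _, pa), (_, _, pc) in zip(a.parameters(), c.parameters()):
        assert np.array_equal(pa, pc)


def test_spec_validation():
    with pytest.raises(ValueError, match="alpha"):
        ModelSpec(heads=1)
    with pytest.raises(ValueError, match="non-negative"):
        ModelSpec(alpha=(0.5, -0.5))
    with pytest.raises(ValueError, match="per conv layer"):
        ModelSpec(dropout=(0.5,))


def test_spec_json_roundtrip():
    spec = ModelSpec.reduced(seed=42)
    assert ModelSpec.from_json(spec.to_json()) == spec


# ---------------------------------------------------------------------------
# Loss


def test_multitask_loss_closed_forms():
    y = np.zeros((4, 2))
    assert multitask_loss(y, y) == 0.0
    # per-task mse 2 and 4, equal weights -> 3
    y_hat = np.column_stack([np.full(4, np.sqrt(2.0)), np.full(4, 2.0)])
    assert multitask_loss(y, y_hat, alpha=(0.5, 0.5)) == pytest.approx(3.0)
    # degenerate weights reduce to single-task mse
    assert multitask_loss(y, y_hat, alpha=(1.0, 0.0)) == pytest.approx(2.0)
    with pytest.raises(ValueError, match="shape"):
        multitask_loss(np.zeros((3, 2)), np.zeros((4, 2)))


def test_equal_weights_equal_half_the_summed_task_mse(rng):
    y = rng.normal(size=(20, 2))
    y_hat = rng.normal(size=(20, 2))
    mse = ((y - y_hat) ** 2).mean(axis=0)
    assert multitask_loss(y, y_hat) == pytest.approx(0.5 * mse.sum())


# ---------------------------------------------------------------------------
# Gradients (numeric check of the backprop through every layer type)


def test_backprop_matches_numeric_gradients():
    rng = np.random.default_rng(3)
    net = Network([
        Conv1D(21, 3, padding="valid", relu=True, l2_kernel=0.01, rng=rng),
        BatchNorm(3),
        MaxPool1D(2),
        Conv1D(3, 2, padding="same", relu=False, l2_kernel=0.01,
               l2_bias=0.01, rng=rng),
        Flatten(),
        Dense(28, 2, relu=False, rng=rng),
    ])
    x = rng.normal(size=(6, 30, 21))
    y = rng.normal(size=(6, 2))
    alpha = np.array([0.5, 0.5])

    def loss():
        pred = net.forward(x, training=True)
        return weighted_mse(y, pred, alpha) + net.reg_loss()

    pred = net.forward(x, training=True)
    net.backward(2.0 * alpha * (pred - y) / x.shape[0])
    eps = 1e-6
    checked = 0
    for layer in net.layers:
        for name, p in layer.params.items():
            flat = p.ravel()
            for k in rng.choice(flat.size, size=min(4, flat.size),
                                replace=False):
                orig = flat[k]
                flat[k] = orig + eps
                up = loss()
                flat[k] = orig - eps
                down = loss()
                flat[k] = orig
                numeric = (up - down) / (2 * eps)
                analytic = layer.grads[name].ravel()[k]
                assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-7)
                checked += 1
    assert checked >= 20


# ---------------------------------------------------------------------------
# Training behaviour


def _linear_problem(n=60, seed=0):
    """Noiseless additive landscape: y is linear in the one-hot encoding."""
    rng = np.random.default_rng(seed)
    seqs = ["".join(rng.choice(list(seqdata.AMINO_ACIDS), 30))
            for _ in range(n)]
    X = seqdata.encode_batch(seqs)
    w = rng.normal(scale=0.2, size=(30, 21, 2))
    Y = np.einsum("nwa,wak->nk", X, w) - 10.0
    return X, Y


def test_training_reduces_loss_on_noiseless_linear_landscape(tiny_spec):
    X, Y = _linear_problem()
    model = train_model(tiny_spec, X[:50], Y[:50], X[50:], Y[50:])
    hist = model.history["train_loss"]
    assert hist[-1] < hist[0]
    assert model.stopped_epoch <= tiny_spec.max_epochs


def test_patience_zero_stops_at_first_non_improving_epoch(tiny_spec):
    from dataclasses import replace
    X, Y = _linear_problem(30)
    spec = replace(tiny_spec, patience=0, max_epochs=200)
    model = train_model(spec, X[:25], Y[:25], X[25:], Y[25:])
    val = model.history["val_loss"]
    # every epoch before the last improved on the best so far
    best = np.inf
    for v in val[:-1]:
        assert v < best
        best = v


def test_same_seed_gives_identical_training_histories(tiny_spec):
    X, Y = _linear_problem(40)
    m1 = train_model(tiny_spec, X[:30], Y[:30], X[30:], Y[30:])
    m2 = train_model(tiny_spec, X[:30], Y[:30], X[30:], Y[30:])
    assert m1.history == m2.history
    assert m1.stopped_epoch == m2.stopped_epoch


def test_empty_sets_rejected(tiny_spec):
    X, Y = _linear_problem(10)
    with pytest.raises(ValueError, match="non-empty"):
        train_model(tiny_spec, X[:0], Y[:0], X, Y)


# ---------------------------------------------------------------------------
# Ensemble


def test_ensemble_mean_and_spread(tiny_ensemble, dataset):
    peptides = dataset.peptides[:7]
    mean, spread = ensemble_predict(tiny_ensemble, peptides)
    assert mean.shape == spread.shape == (7, 2)
    # mean equals the brute-force average of individually queried members
    member_preds = np.stack([m.predict(peptides)
                             for m in tiny_ensemble.members])
    assert np.allclose(mean, member_preds.mean(axis=0))
    assert np.allclose(spread, member_preds.std(axis=0))


def test_constant_members_have_zero_spread(tiny_ensemble, dataset):
    class Const:
        def predict(self, X):
            X = models.as_conv_input(X)
            return np.full((X.shape[0], 2), -9.5)

    ens = models.EnsembleModel(members=[Const(), Const(), Const()])
    mean, spread = ens.predict_with_spread(dataset.peptides[:3])
    assert np.allclose(mean, -9.5) and np.allclose(spread, 0.0)


def test_ensemble_mse_never_exceeds_mean_member_mse(tiny_ensemble, dataset):
    # Jensen: the mse of the averaged prediction is at most the average mse
    X = seqdata.encode_batch(dataset.peptides[110:])
    Y = dataset.labels()[110:]
    member_preds = np.stack([m.predict(X) for m in tiny_ensemble.members])
    ens_mse = ((member_preds.mean(axis=0) - Y) ** 2).mean()
    mean_mse = ((member_preds - Y) ** 2).mean(axis=(1, 2)).mean()
    assert ens_mse <= mean_mse + 1e-12


def test_checkpoint_roundtrip(tmp_path, tiny_ensemble, dataset):
    models.save_ensemble(tiny_ensemble, tmp_path / "ckpt")
    loaded = models.load_ensemble(tmp_path / "ckpt")
    X = seqdata.encode_batch(dataset.peptides[:5])
    assert np.allclose(loaded.predict(X), tiny_ensemble.predict(X))


# ---------------------------------------------------------------------------
# Global alignment


def _brute_force_global(a, b, mat, gap_open, gap_extend):
    """Exhaustive enumeration of all global alignments (affine gaps)."""
    best = [-np.inf]

    def rec(i, j, last, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + mat[a[i], b[j]])
        if i < len(a):
            rec(i + 1, j, "X",
                score + (gap_extend if last == "X" else gap_open))
        if j < len(b):
            rec(i, j + 1, "Y",
                score + (gap_extend if last == "Y" else gap_open))

    rec(0, 0, None, 0.0)
    return best[0]


def test_alignment_score_matches_brute_force_on_short_pairs(rng):
    mat = models.blosum62()
    for _ in range(12):
        a = "".join(rng.choice(list(seqdata.AMINO_ACIDS),
                               rng.integers(1, 6)))
        b = "".join(rng.choice(list(seqdata.AMINO_ACIDS),
                               rng.integers(1, 6)))
        expected = _brute_force_global(a, b, mat, -10.0, -0.5)
        assert needleman_wunsch_score(a, b) == pytest.approx(expected)


def test_alignment_self_score_and_symmetry(rng):
    mat = models.blosum62()
    s = seqdata.HUMAN_GLP1
    assert needleman_wunsch_score(s, s) == sum(mat[c, c] for c in s)
    a, b = seqdata.HUMAN_GLUCAGON, seqdata.HUMAN_GLP1
    assert needleman_wunsch_score(a, b) == needleman_wunsch_score(b, a)
    with pytest.raises(ValueError, match="non-empty"):
        needleman_wunsch_score("", "AA")


def test_alignment_agrees_with_biopython_aligner(rng):
    from Bio import Align
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = models.blosum62()
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    for _ in range(10):
        a = "".join(rng.choice(list(seqdata.AMINO_ACIDS), rng.integers(5, 20)))
        b = "".join(rng.choice(list(seqdata.AMINO_ACIDS), rng.integers(5, 20)))
        assert needleman_wunsch_score(a, b) == pytest.approx(aligner.score(a, b))


# ---------------------------------------------------------------------------
# Nearest neighbour


def test_nearest_neighbour_exact_match_and_tie_averaging():
    train = ["AAAAA", "WWWWW"]
    labels = np.array([[-10.0, -9.0], [-12.0, -11.0]])
    assert np.allclose(
        nearest_neighbour_predict(train, labels, "AAAAA"), [-10.0, -9.0])
    # two equidistant neighbours (same substitution, different position)
    # average per task
    ties = ["CAAAA", "AAAAC"]
    tie_labels = np.array([[-10.0, -9.0], [-12.0, -11.0]])
    brute = np.array([
        models.needleman_wunsch_score(t, "AAAAA") for t in ties])
    assert brute[0] == brute[1]
    pred = nearest_neighbour_predict(ties, tie_labels, "AAAAA")
    assert np.allclose(pred, [-11.0, -10.0])


def test_nearest_neighbour_matches_exhaustive_scan(rng, dataset):
    train = [seqdata.strip_gaps(s) for s in dataset.sequences[:20]]
    labels = dataset.labels()[:20]
    query = seqdata.strip_gaps(dataset.sequences[30])
    scores = np.array([models.needleman_wunsch_score(t, query)
                       for t in train])
    expected = labels[np.isclose(scores, scores.max())].mean(axis=0)
    assert np.allclose(
        nearest_neighbour_predict(train, labels, query), expected)


# ---------------------------------------------------------------------------
# Baseline registry


def test_registry_rejects_unknown_names():
    with pytest.raises(KeyError, match="ridge"):
        baseline_registry("linear")


def test_registry_returns_fresh_objects():
    assert baseline_registry("ridge") is not baseline_registry("ridge")


@pytest.mark.parametrize("name", ["ridge", "svr", "random_forest",
                                  "nearest_neighbour"])
def test_registry_models_conform_to_interface(name, dataset):
    X = seqdata.onehot_features(dataset.peptides[:40])
    Y = dataset.labels()[:40]
    model = baseline_registry(name, seed=0)
    pred = model.fit(X, Y).predict(X[:9])
    assert pred.shape == (9, 2)
    assert np.isfinite(pred).all()


def test_registry_network_models_conform(tiny_spec, dataset):
    X = seqdata.onehot_features(dataset.peptides[:40])
    Y = dataset.labels()[:40]
    for name in ("nn_single_task", "nn_multi_task", "nn_multi_task_ensemble"):
        model = baseline_registry(name, spec=tiny_spec, ensemble_size=2)
        pred = model.fit(X, Y).predict(X[:5])
        assert pred.shape == (5, 2)


def test_ridge_recovers_linear_labels():
    X, Y = _linear_problem(80)
    Xf = X.reshape(80, -1)
    model = baseline_registry("ridge").fit(Xf, Y)
    train_rmse = np.sqrt(((model.predict(Xf) - Y) ** 2).mean())
    assert train_rmse < 0.1
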
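"""Alignment-column statistics and sequence-set PCA.

Position-specific scoring matrices (PSSM), per-column Shannon entropy,
Kullback-Leibler divergence between column distributions and mutual
information between paired columns, all with base-21 logarithms so that a
uniform distribution over the 21-symbol alphabet (20 amino acids + gap)
has entropy 1. PCA projects one-hot encoded sequence sets into the plane
of the first two principal components of the training-set covariance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import seqdata
from .seqdata import ALPHABET, SYMBOL_INDEX, WIDTH, AlignedPeptide

_N_SYMBOLS = len(ALPHABET)
_LOG_BASE = np.log(_N_SYMBOLS)


def _log21(x: np.ndarray) -> np.ndarray:
    return np.log(x) / _LOG_BASE


@dataclass(frozen=True)
class PSSM:
    """Column-wise symbol probabilities of an aligned sequence set."""

    probabilities: np.ndarray  # (21, W)
    pseudocount: float
    n_sequences: int

    def __post_init__(self) -> None:
        p = self.probabilities
        if p.ndim != 2 or p.shape[0] != _N_SYMBOLS:
            raise ValueError("PSSM must be 21 x W")
        if (p < 0).any() or not np.allclose(p.sum(axis=0), 1.0):
            raise ValueError("PSSM columns must be probability distributions")

    @property
    def width(self) -> int:
        return self.probabilities.shape[1]


def _sequences(peptides: Sequence[AlignedPeptide | str]) -> list[str]:
    seqs = [p.residues if isinstance(p, AlignedPeptide) else p
            for p in peptides]
    if not seqs:
        raise ValueError("empty sequence set")
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValueError("sequences differ in width")
    return seqs


def build_pssm(peptides: Sequence[AlignedPeptide | str],
               pseudocount: float = 0.0) -> PSSM:
    """Column-wise symbol frequencies with an additive pseudocount per
    symbol (default 0; use a positive value for KL/MI so no column
    probability is exactly zero)."""
    seqs = _sequences(peptides)
    width = len(seqs[0])
    counts = np.full((_N_SYMBOLS, width), float(pseudocount))
    for s in seqs:
        for b, sym in enumerate(s):
            counts[SYMBOL_INDEX[sym], b] += 1.0
    return PSSM(counts / counts.sum(axis=0), pseudocount, len(seqs))


def column_entropy(pssm: PSSM) -> np.ndarray:
    """Per-position Shannon entropy, base 21: 0 for a conserved column,
    1 for a uniform one. 0*log(0) is taken as 0."""
    p = pssm.probabilities
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * _log21(p), 0.0)
    return -terms.sum(axis=0)


def kl_divergence(s: PSSM | np.ndarray, t: PSSM | np.ndarray) -> np.ndarray:
    """Per-position relative entropy KL(s || t), base 21.

    Zero iff the column distributions match exactly. ``t`` must be
    strictly positive wherever ``s`` is (guarantee this via a
    pseudocount), else an error is raised."""
    ps = s.probabilities if isinstance(s, PSSM) else np.atleast_2d(
        np.asarray(s, float).T).reshape(_N_SYMBOLS, -1)
    pt = t.probabilities if isinstance(t, PSSM) else np.atleast_2d(
        np.asarray(t, float).T).reshape(_N_SYMBOLS, -1)
    if ps.shape != pt.shape:
        raise ValueError("distributions must have matching shape")
    if np.any((ps > 0) & (pt == 0)):
        raise ValueError(
            "KL undefined: t has zero mass where s is positive; "
            "rebuild the PSSMs with a pseudocount")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(ps > 0, ps * _log21(ps / np.where(pt > 0, pt, 1.0)),
                         0.0)
    kl = terms.sum(axis=0)
    return kl if kl.size > 1 else float(kl[0])


def mutual_information(col_a: Sequence[str], col_b: Sequence[str],
                       pseudocount: float = 0.0) -> float:
    """Mutual information between two paired alignment columns, base 21.

    ``col_a`` and ``col_b`` are the symbols observed at two positions in
    the same (ordered) sequence set. Equals KL(joint || product of
    marginals); with pseudocount 0, MI(A; A) equals the entropy of A.
    The pseudocount is spread over the 21x21 joint cells so the marginals
    gain ``pseudocount`` per symbol."""
    if len(col_a) != len(col_b):
        raise ValueError("columns must pair the same sequences")
    if len(col_a) == 0:
        raise ValueError("empty columns")
    joint = np.full((_N_SYMBOLS, _N_SYMBOLS),
                    float(pseudocount) / _N_SYMBOLS)
    for x, y in zip(col_a, col_b):
        joint[SYMBOL_INDEX[x], SYMBOL_INDEX[y]] += 1.0
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(joint > 0, joint * _log21(
            joint / np.where(pa * pb > 0, pa * pb, 1.0)), 0.0)
    return float(terms.sum())


def pssm_column(peptides: Sequence[AlignedPeptide | str], position: int) -> list[str]:
    """Extract the symbols at a 0-based alignment position."""
    return [s[position] for s in _sequences(peptides)]


# ---------------------------------------------------------------------------
# PCA of one-hot encoded sequence sets


@dataclass(frozen=True)
class PCAProjection:
    """Principal components of a one-hot encoded training set.

    External sets are projected using the stored training mean, so e.g.
    wild-type single-mutant clouds land in the training-set space."""

    components: np.ndarray  # (k, 630), orthonormal rows
    explained_variance: np.ndarray  # (k,), non-increasing
    mean: np.ndarray  # (630,)


def pca_fit(peptides_or_X, n_components: int | None = None) -> PCAProjection:
    """Eigendecomposition of the covariance of mean-centred flattened
    one-hot encodings (via SVD). Component signs are fixed by making each
    component's largest-magnitude loading positive."""
    if isinstance(peptides_or_X, np.ndarray):
        X = np.asarray(peptides_or_X, float)
    else:
        X = seqdata.onehot_features(list(peptides_or_X)).astype(float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two sequences")
    mean = X.mean(axis=0)
    Xc = X - mean
    if not np.any(Xc):
        raise ValueError("degenerate set: all sequences identical")
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2 / (n - 1)
    k = n_components if n_components is not None else len(var)
    components = vt[:k]
    signs = np.sign(components[
        np.arange(components.shape[0]),
        np.abs(components).argmax(axis=1)])
    components = components * signs[:, None]
    return PCAProjection(components=components,
                         explained_variance=var[:k], mean=mean)


def pca_project(projection: PCAProjection, peptides_or_X,
                n_components: int = 2) -> np.ndarray:
    """Coordinates of sequences in the fitted component space (first two
    components by default)."""
    if isinstance(peptides_or_X, np.ndarray):
        X = np.asarray(peptides_or_X, float)
    else:
        X = seqdata.onehot_features(list(peptides_or_X)).astype(float)
    comps = projection.components[:n_components]
    return (X - projection.mean) @ comps.T
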
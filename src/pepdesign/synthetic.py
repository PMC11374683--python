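"""Synthetic two-receptor potency landscapes and study-shaped datasets.

The generator produces a ground-truth landscape over the 30-wide aligned
peptide frame — additive per-position substitution effects plus sparse
pairwise epistasis, independently for each receptor but with a shared
fraction of terms to make the two tasks correlated — and samples labelled
training sets shaped like the study data: 125 unique variants carrying
2-20 mutations from the nearer of the two natural references, labels with
Gaussian assay noise, censoring at the inactive ceiling (log10 EC50 = -8)
and configurable activity-region occupancies (defaults: 11.2% dual, 3.2%
GCGR-selective, 25.6% GLP-1R-selective, rest inactive).

The landscape is anchored at human glucagon (a potent GCGR-selective
peptide); a "chimera axis" of engineered weights along the GLP-1 residues
makes human GLP-1 a potent GLP-1R-selective peptide, and a handful of
dual-enabling substitutions (GLP-1R-boosting, GCGR-neutral — emulating the
C-terminal chimera substitutions seen in real dual agonists) make the dual
region reachable. This is a statistical stand-in for the assay data, not a
model of glucagon biochemistry.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import seqdata
from .seqdata import (
    ActivityRegion,
    AlignedPeptide,
    Dataset,
    PotencyRecord,
    classify_activity_region,
)

DEFAULT_REGION_TARGETS = {
    ActivityRegion.DUAL: 0.112,
    ActivityRegion.GCGR_SELECTIVE: 0.032,
    ActivityRegion.GLP1R_SELECTIVE: 0.256,
    ActivityRegion.INACTIVE: 0.600,
}

# Ground-truth potencies assigned to the two anchors (log10 molar):
# glucagon is potent at GCGR and moderate at GLP-1R; GLP-1 is potent at
# GLP-1R and unmeasurably weak at GCGR.
_GCG_BASE = (-11.94, -8.70)
_GLP1_RAW = (-7.50, -11.87)


@dataclass
class LandscapeSpec:
    """Parameters of a synthetic ground-truth potency landscape."""

    reference_gcg: str
    reference_glp1: str
    base: tuple[float, float]  # truth of the glucagon anchor
    weights: np.ndarray  # (2, W, 21) additive effects; 0 at the anchor residues
    epistasis: list  # (receptor, i, j, sym_a, sym_b, value)
    noise_sd: float = 0.3
    ceiling: float = seqdata.DEFAULT_CEILING
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps({
            "reference_gcg": self.reference_gcg,
            "reference_glp1": self.reference_glp1,
            "base": list(self.base),
            "weights": self.weights.tolist(),
            "epistasis": [list(e) for e in self.epistasis],
            "noise_sd": self.noise_sd,
            "ceiling": self.ceiling,
            "seed": self.seed,
        })

    @classmethod
    def from_json(cls, text: str) -> "LandscapeSpec":
        d = json.loads(text)
        return cls(
            reference_gcg=d["reference_gcg"],
            reference_glp1=d["reference_glp1"],
            base=tuple(d["base"]),
            weights=np.asarray(d["weights"], float),
            epistasis=[tuple(e) for e in d["epistasis"]],
            noise_sd=d["noise_sd"], ceiling=d["ceiling"], seed=d["seed"],
        )


def make_landscape_spec(
    seed: int = 0,
    share_fraction: float = 0.6,
    beneficial_fraction: tuple[float, float] = (0.08, 0.15),
    n_dual_enablers: int = 12,
    n_epistatic: int = 30,
    noise_sd: float = 0.3,
    ceiling: float = seqdata.DEFAULT_CEILING,
) -> LandscapeSpec:
    """Draw a randomized landscape with the structural features above.

    ``share_fraction`` of the per-(position, symbol) effects are identical
    across receptors (correlated tasks); the remainder are independent.
    Most substitutions are deleterious; ``beneficial_fraction`` of cells
    per receptor improve potency.
    """
    rng = np.random.default_rng(seed)
    W, A = seqdata.WIDTH, len(seqdata.ALPHABET)
    ref_g = seqdata.HUMAN_GLUCAGON + seqdata.GAP * (W - len(seqdata.HUMAN_GLUCAGON))
    ref_l = seqdata.HUMAN_GLP1

    def draw(p_beneficial: float, size) -> np.ndarray:
        ben = rng.random(size) < p_beneficial
        vals = np.where(ben, rng.uniform(-0.8, -0.1, size),
                        rng.uniform(0.1, 1.2, size))
        return vals

    w = np.zeros((2, W, A))
    w[0] = draw(beneficial_fraction[0], (W, A))
    shared = rng.random((W, A)) < share_fraction
    w[1] = np.where(shared, w[0], draw(beneficial_fraction[1], (W, A)))

    # Anchor: the glucagon residues carry zero effect by construction.
    for pos, sym in enumerate(ref_g):
        w[:, pos, seqdata.SYMBOL_INDEX[sym]] = 0.0

    # Chimera axis: the GLP-1 residues at positions where the references
    # differ are tuned so the GLP-1 anchor lands at its target potencies.
    diff = [pos for pos in range(W) if ref_l[pos] != ref_g[pos]]
    per_pos_g = (_GLP1_RAW[0] - _GCG_BASE[0]) / len(diff)
    per_pos_l = (_GLP1_RAW[1] - _GCG_BASE[1]) / len(diff)
    for pos in diff:
        idx = seqdata.SYMBOL_INDEX[ref_l[pos]]
        w[0, pos, idx] = per_pos_g
        w[1, pos, idx] = per_pos_l

    # Dual enablers: rare substitutions that strongly boost GLP-1R potency
    # while leaving GCGR essentially untouched.
    non_gap = [pos for pos in range(W) if ref_g[pos] != seqdata.GAP]
    placed = 0
    while placed < n_dual_enablers:
        pos = int(rng.choice(non_gap))
        sym = int(rng.integers(0, 20))
        if seqdata.ALPHABET[sym] in (ref_g[pos], ref_l[pos]):
            continue
        w[0, pos, sym] = rng.uniform(-0.3, 0.0)
        w[1, pos, sym] = rng.uniform(-3.2, -2.0)
        placed += 1

    epistasis = []
    for _ in range(n_epistatic):
        r = int(rng.integers(0, 2))
        i, j = sorted(rng.choice(W, size=2, replace=False).tolist())
        a = int(rng.integers(0, 20))
        b = int(rng.integers(0, 20))
        epistasis.append((r, int(i), int(j), a, b,
                          float(rng.uniform(-0.4, 0.8))))
    return LandscapeSpec(
        reference_gcg=ref_g, reference_glp1=ref_l, base=_GCG_BASE,
        weights=w, epistasis=epistasis, noise_sd=noise_sd, ceiling=ceiling,
        seed=seed)


class Landscape:
    """Deterministic ground-truth oracle: sequence -> true potency pair."""

    def __init__(self, spec: LandscapeSpec):
        self.spec = spec

    def raw(self, sequences) -> np.ndarray:
        """Unclipped truth: base + additive + epistatic terms."""
        seqs = [s.residues if isinstance(s, AlignedPeptide) else s
                for s in sequences]
        w = self.spec.weights
        out = np.tile(np.asarray(self.spec.base, float), (len(seqs), 1))
        for n, seq in enumerate(seqs):
            idx = [seqdata.SYMBOL_INDEX[sym] for sym in seq]
            for r in range(2):
                out[n, r] += w[r, np.arange(len(seq)), idx].sum()
            for (r, i, j, a, b, value) in self.spec.epistasis:
                if idx[i] == a and idx[j] == b:
                    out[n, r] += value
        return out

    def truth(self, sequences) -> np.ndarray:
        """True potency pair, clipped at the inactive ceiling."""
        return np.minimum(self.raw(sequences), self.spec.ceiling)

    # Oracle duck-types a trained model for the design loop and tests.
    def predict(self, sequences) -> np.ndarray:
        return self.truth(sequences)

    def observe(self, sequences, rng: np.random.Generator
                ) -> tuple[np.ndarray, np.ndarray]:
        """Noisy, censored labels: truth + N(0, sd), censored at ceiling."""
        raw = self.raw(sequences)
        noisy = raw + rng.normal(0.0, self.spec.noise_sd, size=raw.shape)
        censored = noisy >= self.spec.ceiling
        return np.minimum(noisy, self.spec.ceiling), censored


def make_landscape(spec: LandscapeSpec) -> Landscape:
    return Landscape(spec)


def sample_training_set(
    landscape: Landscape,
    n: int = 125,
    mutation_range: tuple[int, int] = (2, 20),
    region_targets: dict | None = None,
    seed: int = 0,
    rejection_budget: int | None = None,
    threshold: float = seqdata.DEFAULT_THRESHOLD,
) -> tuple[Dataset, dict]:
    """Sample a labelled study-shaped dataset from the landscape.

    Variants carry a uniform 2-20 substitutions from one of the two
    reference anchors; observed labels add Gaussian noise and are censored
    at the ceiling. Sampling is stratified toward the configured
    activity-region occupancies; if a region quota cannot be filled within
    the rejection budget the remainder is filled with unconstrained draws
    and a warning reports the achieved fractions.

    Returns (dataset, achieved region fractions).
    """
    spec = landscape.spec
    rng = np.random.default_rng(seed)
    if region_targets is None:
        region_targets = DEFAULT_REGION_TARGETS
    if rejection_budget is None:
        rejection_budget = 400 * n
    quotas = {r: int(round(n * f)) for r, f in region_targets.items()}
    # Rounding can leave the quotas short or over; adjust on INACTIVE.
    quotas[ActivityRegion.INACTIVE] += n - sum(quotas.values())
    refs = (spec.reference_gcg, spec.reference_glp1)
    lo, hi = mutation_range

    def propose() -> str:
        ref = refs[int(rng.integers(0, 2))]
        non_gap = [p for p in range(len(ref)) if ref[p] != seqdata.GAP]
        m = int(rng.integers(lo, hi + 1))
        positions = rng.choice(non_gap, size=min(m, len(non_gap)),
                               replace=False)
        residues = list(ref)
        for pos in positions:
            choices = [a for a in seqdata.AMINO_ACIDS if a != ref[pos]]
            residues[pos] = choices[int(rng.integers(0, len(choices)))]
        return "".join(residues)

    accepted: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    counts = {r: 0 for r in quotas}
    attempts = 0
    while len(accepted) < n and attempts < rejection_budget:
        attempts += 1
        seq = propose()
        if seq in accepted:
            continue
        label, censored = landscape.observe([seq], rng)
        region = classify_activity_region(tuple(label[0]), threshold)
        if counts[region] >= quotas[region]:
            continue
        accepted[seq] = (label[0], censored[0])
        counts[region] += 1
    if len(accepted) < n:
        warnings.warn(
            "region quotas unreachable within the rejection budget; "
            f"achieved counts {counts}; filling {n - len(accepted)} "
            "remaining slots without stratification")
        while len(accepted) < n:
            seq = propose()
            if seq in accepted:
                continue
            label, censored = landscape.observe([seq], rng)
            region = classify_activity_region(tuple(label[0]), threshold)
            accepted[seq] = (label[0], censored[0])
            counts[region] += 1

    # Shuffle acceptance order so record order carries no region signal.
    items = list(accepted.items())
    rng.shuffle(items)
    peptides, records = [], []
    for i, (seq, (label, censored)) in enumerate(items, start=1):
        pid = f"T{i:03d}"
        peptides.append(AlignedPeptide(pid, seq))
        records.append(PotencyRecord(
            pid, (float(label[0]), float(label[1])),
            (bool(censored[0]), bool(censored[1]))))
    achieved = {r: counts[r] / n for r in counts}
    return Dataset(peptides, records), achieved


def write_dataset(dataset: Dataset, directory: str | Path,
                  landscape_spec: LandscapeSpec | None = None) -> None:
    """Emit the FASTA + potency-table pair consumed by the data loaders,
    plus the landscape spec as JSON for exact regeneration."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    seqdata.write_fasta(dataset.peptides, directory / "sequences.fasta")
    seqdata.write_potency_table(dataset, directory / "potency.tsv")
    if landscape_spec is not None:
        (directory / "landscape.json").write_text(landscape_spec.to_json())
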
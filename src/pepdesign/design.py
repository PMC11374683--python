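"""Model-guided directed evolution.

Starting from training sequences whose measured activity matches a target
profile, each generation enumerates all single-substitution variants of
the current parents, removes duplicates and training-set overlaps, scores
the model-predicted potency pair against the objective, keeps the top k
candidates and carries the most diverse of them forward. Three generations
are run by default, so every candidate stays within three substitutions of
a measured training sequence — the model's trust region.

Activity profiles (log10 molar EC50):
  DUAL            both receptors < -11.5 (EC50 ratio ~ 1)
  GCGR_SELECTIVE  GCGR < -11 and GLP-1R > -9 (ratio ~ 100)
  GLP1R_SELECTIVE GLP-1R < -11.5 and GCGR > -9 (ratio ~ 100)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from . import seqdata
from .seqdata import (
    ActivityRegion,
    AlignedPeptide,
    Dataset,
    classify_activity_region,
    enumerate_single_mutants,
    hamming_distance,
)

# Scores of candidates violating a profile inequality are pushed to the
# back of any ranking that includes them.
INFEASIBLE_PENALTY = 1e6


class Profile(Enum):
    DUAL = "dual"
    GCGR_SELECTIVE = "gcgr_selective"
    GLP1R_SELECTIVE = "glp1r_selective"

    @property
    def region(self) -> ActivityRegion:
        return ActivityRegion(self.value)


@dataclass(frozen=True)
class DesignObjective:
    """An activity profile with its threshold inequalities and ranking rule.

    ``potent_threshold`` bounds the on-target log10 EC50 from above;
    ``inactive_threshold`` bounds the anti-target from below (selective
    profiles only). Lower scores are better.
    """

    profile: Profile
    potent_threshold: float
    inactive_threshold: float | None = None

    @classmethod
    def dual(cls) -> "DesignObjective":
        return cls(Profile.DUAL, potent_threshold=-11.5)

    @classmethod
    def gcgr_selective(cls) -> "DesignObjective":
        return cls(Profile.GCGR_SELECTIVE, potent_threshold=-11.0,
                   inactive_threshold=-9.0)

    @classmethod
    def glp1r_selective(cls) -> "DesignObjective":
        return cls(Profile.GLP1R_SELECTIVE, potent_threshold=-11.5,
                   inactive_threshold=-9.0)

    @classmethod
    def for_profile(cls, profile: Profile | str) -> "DesignObjective":
        profile = Profile(profile) if isinstance(profile, str) else profile
        return {
            Profile.DUAL: cls.dual,
            Profile.GCGR_SELECTIVE: cls.gcgr_selective,
            Profile.GLP1R_SELECTIVE: cls.glp1r_selective,
        }[profile]()

    def score(self, pred: tuple[float, float]) -> tuple[float, float, bool]:
        """Return (primary score, tie-break score, feasible).

        DUAL: primary = max of the two predicted log EC50s (both must be
        potent; minimizing the worse one drives the EC50 ratio toward 1),
        tie-break = the other. Selective: primary = on-target prediction;
        infeasible candidates are penalized to the back of the ranking.
        """
        g, l = float(pred[0]), float(pred[1])
        if self.profile is Profile.DUAL:
            feasible = g < self.potent_threshold and l < self.potent_threshold
            primary, secondary = max(g, l), min(g, l)
        elif self.profile is Profile.GCGR_SELECTIVE:
            feasible = g < self.potent_threshold and l > self.inactive_threshold
            primary, secondary = g, -l
        else:
            feasible = l < self.potent_threshold and g > self.inactive_threshold
            primary, secondary = l, -g
        if not feasible:
            primary += INFEASIBLE_PENALTY
        return primary, secondary, feasible


def objective_score(pred, objective: DesignObjective) -> tuple[float, bool]:
    """Scalar objective score (lower is better) and feasibility flag."""
    primary, _, feasible = objective.score(pred)
    return primary, feasible


@dataclass
class Candidate:
    peptide: AlignedPeptide
    prediction: tuple[float, float]
    score: float
    secondary: float
    feasible: bool
    parent_id: str
    distance_to_seed: int

    @property
    def sort_key(self):
        return (self.score, self.secondary, self.peptide.residues)


@dataclass
class GenerationRecord:
    """Bookkeeping for one generation of the design loop."""

    generation: int
    parent_ids: list[str]
    candidates: list[Candidate]
    top_k: list[Candidate]
    next_parents: list[AlignedPeptide]
    used_feasibility_fallback: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (c.peptide.id, c.peptide.residues, c.prediction[0], c.prediction[1],
             c.score, c.feasible, c.parent_id, c.distance_to_seed)
            for c in self.top_k
        ]
        return pd.DataFrame(rows, columns=[
            "id", "sequence", "pred_gcgr", "pred_glp1r", "score", "feasible",
            "parent", "distance_to_seed"])


def seed_sequences(dataset: Dataset, objective: DesignObjective,
                   threshold: float = seqdata.DEFAULT_THRESHOLD,
                   fallback_k: int = 5) -> list[AlignedPeptide]:
    """Training sequences whose measured activity region matches the
    objective profile; falls back to the nearest-by-rank training
    sequences (with a warning) when the region is empty."""
    seeds, seen = [], set()
    for p, r in zip(dataset.peptides, dataset.records):
        if classify_activity_region(r, threshold) is objective.profile.region \
                and p.residues not in seen:
            seeds.append(p)
            seen.add(p.residues)
    if seeds:
        return seeds
    ranked = sorted(
        zip(dataset.peptides, dataset.records),
        key=lambda pr: objective.score(pr[1].log_ec50)[:2])
    seeds = []
    for p, _ in ranked:
        if p.residues not in seen:
            seeds.append(p)
            seen.add(p.residues)
        if len(seeds) == fallback_k:
            break
    if not seeds:
        raise ValueError(
            "no seed sequences available; supply seeds manually")
    warnings.warn(
        f"no training sequence matches profile {objective.profile.value}; "
        f"using the {len(seeds)} nearest-by-rank sequences as seeds")
    return seeds


def select_top_k(candidates: list[Candidate], k: int = 50) -> list[Candidate]:
    """The k best feasible candidates by score (ties broken by the
    secondary score, then lexicographic sequence order). If fewer than k
    are feasible, all feasible candidates are returned with a warning."""
    feasible = sorted((c for c in candidates if c.feasible),
                      key=lambda c: c.sort_key)
    if len(feasible) < k:
        warnings.warn(
            f"only {len(feasible)} feasible candidates for k={k}")
        return feasible
    return feasible[:k]


def select_diverse(ranked: list[Candidate], m: int) -> list[Candidate]:
    """Greedy max-min Hamming selection of m sequences, seeded with the
    top-ranked candidate; distance ties fall back to rank order."""
    if m > len(ranked):
        raise ValueError(f"cannot select {m} from {len(ranked)} candidates")
    if m == len(ranked):
        return list(ranked)
    chosen = [ranked[0]]
    remaining = list(ranked[1:])
    while len(chosen) < m:
        best_idx, best_dist = 0, -1
        for i, cand in enumerate(remaining):
            d = min(hamming_distance(cand.peptide, c.peptide, mode="full")
                    for c in chosen)
            if d > best_dist:
                best_idx, best_dist = i, d
        chosen.append(remaining.pop(best_idx))
    return chosen


def _min_seed_distance(peptide: AlignedPeptide,
                       seeds: list[AlignedPeptide]) -> int:
    return min(hamming_distance(peptide, s, mode="full") for s in seeds)


def run_directed_evolution(
    model,
    dataset: Dataset,
    objective: DesignObjective,
    generations: int = 3,
    k: int = 50,
    diversity_sizes: tuple[int, ...] = (10, 5),
    fill_gaps: bool = False,
    seeds: list[AlignedPeptide] | None = None,
) -> list[GenerationRecord]:
    """Run the three-generation model-guided directed-evolution loop.

    ``model`` is anything with ``predict(peptides) -> (n, 2)`` log10-molar
    predictions (the trained ensemble, a baseline, or a ground-truth
    oracle in tests). Returns one record per generation, with the seeds as
    generation 0. When a generation yields no feasible candidate, the loop
    falls back to ranking all candidates by penalized score so progress
    continues (recorded on the GenerationRecord).
    """
    if seeds is None:
        seeds = seed_sequences(dataset, objective)
    training_sequences = set(dataset.sequences)
    records: list[GenerationRecord] = [GenerationRecord(
        generation=0, parent_ids=[], candidates=[], top_k=[],
        next_parents=list(seeds))]
    parents = list(seeds)
    for g in range(1, generations + 1):
        pool: dict[str, AlignedPeptide] = {}
        parent_of: dict[str, str] = {}
        for parent in parents:
            for mut in enumerate_single_mutants(parent, fill_gaps=fill_gaps):
                if mut.residues in training_sequences:
                    continue
                if mut.residues not in pool:
                    pool[mut.residues] = mut
                    parent_of[mut.residues] = parent.id
        if not pool:
            warnings.warn(f"generation {g}: empty candidate pool, stopping")
            break
        peptides = list(pool.values())
        preds = np.asarray(model.predict(peptides), dtype=float)
        candidates = []
        for pep, pred in zip(peptides, preds):
            primary, secondary, feasible = objective.score(pred)
            candidates.append(Candidate(
                peptide=pep, prediction=(float(pred[0]), float(pred[1])),
                score=primary, secondary=secondary, feasible=feasible,
                parent_id=parent_of[pep.residues],
                distance_to_seed=_min_seed_distance(pep, seeds)))
        top = select_top_k(candidates, k=k)
        fallback = False
        if not top:
            fallback = True
            top = sorted(candidates, key=lambda c: c.sort_key)[:k]
            warnings.warn(
                f"generation {g}: no feasible candidate; ranking by "
                "penalized score to continue")
        for cand in top:
            if cand.distance_to_seed > g:
                raise AssertionError(
                    "mutation budget violated: candidate "
                    f"{cand.peptide.id} is {cand.distance_to_seed} "
                    f"substitutions from the seeds in generation {g}")
        if g <= len(diversity_sizes) and g < generations:
            m = min(diversity_sizes[g - 1], len(top))
        else:
            m = 0
        next_parents = [c.peptide for c in select_diverse(top, m)] if m else []
        records.append(GenerationRecord(
            generation=g, parent_ids=[p.id for p in parents],
            candidates=candidates, top_k=top, next_parents=next_parents,
            used_feasibility_fallback=fallback))
        if g < generations and not next_parents:
            warnings.warn(f"generation {g}: no parents to continue with")
            break
        parents = next_parents
    return records


def final_candidate_pool(records: list[GenerationRecord]) -> list[Candidate]:
    """The design output: the first and last generations' top-k pools
    (the "100 model-optimized sequences" when both are full)."""
    gens = [r for r in records if r.generation > 0]
    if not gens:
        return []
    pool = list(gens[0].top_k)
    if len(gens) > 1:
        pool += gens[-1].top_k
    return pool
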
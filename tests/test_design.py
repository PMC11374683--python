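"""Objective scoring, candidate selection and the directed-evolution loop."""

import warnings
from itertools import combinations

import numpy as np
import pytest

from pepdesign import design, seqdata, synthetic
from pepdesign.design import (
    Candidate,
    DesignObjective,
    Profile,
    final_candidate_pool,
    objective_score,
    run_directed_evolution,
    seed_sequences,
    select_diverse,
    select_top_k,
)
from pepdesign.seqdata import ActivityRegion, AlignedPeptide, classify_activity_region


# ---------------------------------------------------------------------------
# Objectives


@pytest.mark.parametrize("objective,pred,feasible", [
    (DesignObjective.dual(), (-12.0, -12.0), True),
    (DesignObjective.dual(), (-12.0, -11.0), False),  # second bound violated
    (DesignObjective.gcgr_selective(), (-12.0, -8.0), True),
    (DesignObjective.gcgr_selective(), (-12.0, -10.0), False),
    (DesignObjective.glp1r_selective(), (-8.0, -12.0), True),
])
def test_objective_feasibility(objective, pred, feasible):
    _, flag = objective_score(pred, objective)
    assert flag is feasible


def test_dual_score_is_the_worse_of_the_pair():
    obj = DesignObjective.dual()
    score, feasible = objective_score((-12.0, -12.0), obj)
    assert feasible and score == -12.0
    # the worse receptor dominates, driving the EC50 ratio toward 1
    assert objective_score((-13.0, -11.6), obj)[0] == -11.6


def test_infeasible_candidates_rank_behind_all_feasible_ones():
    obj = DesignObjective.gcgr_selective()
    feasible_score, _ = objective_score((-11.1, -8.5), obj)
    infeasible_score, _ = objective_score((-14.0, -10.0), obj)
    assert feasible_score < infeasible_score


# ---------------------------------------------------------------------------
# Seeds


def test_seed_sequences_match_objective_region(dataset):
    seeds = seed_sequences(dataset, DesignObjective.dual())
    by_id = {p.id: r for p, r in zip(dataset.peptides, dataset.records)}
    assert seeds
    for p in seeds:
        assert classify_activity_region(by_id[p.id]) is ActivityRegion.DUAL
    assert len({p.id for p in seeds}) == len(seeds)


def test_seed_fallback_warns_when_region_is_empty(dataset):
    # impossible profile: nothing in the dataset satisfies it at -20
    objective = DesignObjective(Profile.DUAL, potent_threshold=-20.0)
    sub = dataset.subset(range(20))
    with pytest.warns(UserWarning, match="nearest-by-rank"):
        seeds = seed_sequences(sub, objective, threshold=-20.0)
    assert len(seeds) == 5


# ---------------------------------------------------------------------------
# Selection


def _seq(i: int) -> str:
    """Distinct valid residue strings indexed by i."""
    aa = seqdata.AMINO_ACIDS
    return (aa[i % 20] + aa[(i // 20) % 20]).ljust(30, "A")


def _candidate(seq, score, feasible=True, secondary=0.0):
    return Candidate(
        peptide=AlignedPeptide(seq.rstrip("-") or "pep", seq.ljust(30, "-")[:30]),
        prediction=(score, score), score=score, secondary=secondary,
        feasible=feasible, parent_id="p", distance_to_seed=1)


def test_select_top_k_orders_and_warns():
    cands = [_candidate(_seq(i), score=-10.0 - 0.01 * i)
             for i in range(100)]
    top = select_top_k(cands, k=50)
    assert len(top) == 50
    scores = [c.score for c in top]
    assert scores == sorted(scores)
    assert top[0].score == min(c.score for c in cands)

    few = [_candidate(_seq(i), -12.0, feasible=(i < 5)) for i in range(60)]
    with pytest.warns(UserWarning, match="only 5 feasible"):
        top = select_top_k(few, k=50)
    assert len(top) == 5


def test_select_top_k_breaks_ties_lexicographically():
    cands = [_candidate(s, -12.0) for s in ("CAAA", "AAAA", "DAAA")]
    top = select_top_k(cands, k=2)
    residues = [c.peptide.residues for c in top]
    assert residues == sorted(residues)


def test_select_diverse_boundaries_and_greedy_maxmin():
    same = [_candidate("AAAA", -12.0) for _ in range(6)]
    assert select_diverse(same, 3) == same[:3]
    mixed = [_candidate(s, -12.0 + 0.1 * i)
             for i, s in enumerate(["AAAA", "AAAC", "WWWW", "AACC"])]
    assert select_diverse(mixed, 4) == mixed
    # greedy max-min with m=2 equals the exhaustive best pair that
    # includes the top-ranked candidate
    chosen = select_diverse(mixed, 2)
    def dist(x, y):
        return seqdata.hamming_distance(x.peptide, y.peptide, mode="full")
    best = max((c for c in mixed[1:]), key=lambda c: dist(mixed[0], c))
    assert chosen == [mixed[0], best]
    with pytest.raises(ValueError):
        select_diverse(mixed, 9)


# ---------------------------------------------------------------------------
# The loop


def _unconstrained_gcgr_objective():
    """Everything feasible; score = predicted GCGR potency (additive in
    the sequence for an additive landscape)."""
    return DesignObjective(Profile.GCGR_SELECTIVE, potent_threshold=1e9,
                           inactive_threshold=-1e9)


def _additive_landscape(seed=4):
    return synthetic.make_landscape(
        synthetic.make_landscape_spec(seed=seed, n_epistatic=0))


def _seed_only_dataset(landscape):
    ref = AlignedPeptide("seed", landscape.spec.reference_gcg)
    truth = landscape.truth([ref])[0]
    rec = seqdata.PotencyRecord("seed", (float(truth[0]), float(truth[1])))
    return seqdata.Dataset([ref], [rec]), ref


def test_zero_generations_returns_seeds(dataset, landscape):
    records = run_directed_evolution(
        landscape, dataset, DesignObjective.dual(), generations=0)
    assert len(records) == 1
    assert records[0].generation == 0
    assert records[0].next_parents  # the seeds


def test_loop_respects_mutation_budget_and_excludes_training(dataset, landscape):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records = run_directed_evolution(
            landscape, dataset, DesignObjective.dual(), generations=3)
    training = set(dataset.sequences)
    seeds = records[0].next_parents
    for record in records[1:]:
        for cand in record.top_k:
            assert cand.peptide.residues not in training
            d = min(seqdata.hamming_distance(cand.peptide, s, mode="full")
                    for s in seeds)
            assert d <= record.generation


def test_loop_is_deterministic(dataset, landscape):
    def run():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return run_directed_evolution(
                landscape, dataset, DesignObjective.dual(), generations=2)
    a, b = run(), run()
    for ra, rb in zip(a, b):
        assert [c.peptide.residues for c in ra.top_k] == \
            [c.peptide.residues for c in rb.top_k]


def test_best_score_is_monotone_with_a_fixed_scoring_model(dataset, landscape):
    objective = _unconstrained_gcgr_objective()
    records = run_directed_evolution(
        landscape, dataset, objective, generations=3)
    best = [min(c.score for c in r.top_k) for r in records[1:]]
    assert all(b1 >= b2 for b1, b2 in zip(best, best[1:]))


def test_loop_reaches_exhaustive_three_step_optimum_on_additive_oracle():
    landscape = _additive_landscape()
    ds, ref = _seed_only_dataset(landscape)
    objective = _unconstrained_gcgr_objective()
    records = run_directed_evolution(
        landscape, ds, objective, generations=3, seeds=[ref])
    best = min(c.score for c in records[-1].top_k)

    # Exhaustive: with a purely additive landscape the best 3-step variant
    # combines the three positions with the largest single-substitution
    # gains (the reference residues carry zero weight by construction).
    w = landscape.spec.weights[0]
    gains = []
    for pos, sym in enumerate(ref.residues):
        if sym == seqdata.GAP:
            continue
        best_delta = min(
            w[pos, seqdata.SYMBOL_INDEX[a]]
            for a in seqdata.AMINO_ACIDS if a != sym)
        gains.append(best_delta)
    base = landscape.truth([ref])[0][0]
    optimum = base + sum(sorted(gains)[:3])
    assert best == pytest.approx(optimum, abs=1e-9)


def test_final_pool_combines_first_and_last_generations(dataset, landscape):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records = run_directed_evolution(
            landscape, dataset, DesignObjective.dual(), generations=3)
    pool = final_candidate_pool(records)
    gen1 = {c.peptide.residues for c in records[1].top_k}
    gen3 = {c.peptide.residues for c in records[3].top_k}
    assert {c.peptide.residues for c in pool} == gen1 | gen3
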
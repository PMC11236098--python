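"""The bi-objective Pareto pruning search and its building blocks."""

from collections import Counter
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scpruner import (
    LabelVector,
    Population,
    PruneConfig,
    ScoredMask,
    dominates,
    evaluate,
    local_search,
    mutate,
    prune,
    update_population,
    weakly_dominates,
)
from scpruner.ensemble import PathPredictionMatrix
from scpruner.exceptions import ConfigError

from conftest import random_preds


def oracle_consensus(preds, bits):
    """Per-cell mode with the documented tie-break, tallied by hand."""
    sel = [p for p in range(preds.n_paths) if bits[p]]
    out = []
    for i in range(preds.n_cells):
        votes = Counter(preds.labels[p, i] for p in sel)
        top = max(votes.values())
        tied = [lab for lab, v in votes.items() if v == top]
        if len(tied) > 1:
            psum = {lab: sum(preds.probs[p, i, preds.categories.index(lab)]
                             for p in sel) for lab in tied}
            best = max(psum.values())
            tied = sorted(lab for lab in tied if psum[lab] == best)
        else:
            tied = sorted(tied)
        out.append(tied[0])
    return np.asarray(out, dtype=object)


def oracle_objectives(preds, y, bits):
    if sum(bits) == 0:
        return preds.n_cells + 1, 0
    cons = oracle_consensus(preds, bits)
    return int(np.sum(cons != y.labels)), int(sum(bits))


def scored(f1, f2, l=6):
    """A ScoredMask carrying given objectives (bits consistent with f2)."""
    bits = tuple(1 if i < f2 else 0 for i in range(l))
    return ScoredMask(bits, f1, f2)


class TestEvaluate:
    def test_singleton_mask_scores_path_error(self):
        preds = random_preds(4, 30, ["a", "b"], seed=0)
        y = LabelVector(preds.labels[2].copy(), ["a", "b"])
        sm = evaluate(np.array([0, 0, 1, 0]), preds, y)
        assert (sm.f1, sm.f2) == (0, 1)

    def test_majority_correct_paths_give_zero_error(self):
        labels = np.asarray([["a"] * 10, ["a"] * 10, ["b"] * 10], dtype=object)
        probs = np.zeros((3, 10, 2))
        probs[:2, :, 0] = 1.0
        probs[2, :, 1] = 1.0
        preds = PathPredictionMatrix(labels, probs, ["a", "b"])
        y = LabelVector(np.asarray(["a"] * 10, dtype=object), ["a", "b"])
        assert evaluate(np.ones(3), preds, y).f1 == 0

    def test_matches_hand_tally_on_random_fixture(self):
        preds = random_preds(6, 40, ["a", "b", "c"], seed=3)
        rng = np.random.default_rng(4)
        y = LabelVector(rng.choice(["a", "b", "c"], 40), ["a", "b", "c"])
        for trial in range(20):
            bits = rng.integers(0, 2, 6)
            sm = evaluate(bits, preds, y)
            assert (sm.f1, sm.f2) == oracle_objectives(preds, y, bits)

    def test_empty_mask_sentinel(self):
        preds = random_preds(3, 15, ["a", "b"], seed=1)
        y = LabelVector(preds.labels[0].copy(), ["a", "b"])
        sm = evaluate(np.zeros(3), preds, y)
        assert (sm.f1, sm.f2) == (16, 0)


class TestDomination:
    @pytest.mark.parametrize("a,b,weak,strict", [
        ((5, 2), (5, 2), True, False),   # reflexive / irreflexive
        ((5, 2), (6, 3), True, True),
        ((4, 1), (6, 3), True, True),
        ((5, 3), (6, 2), False, False),  # incomparable pair
        ((6, 2), (5, 3), False, False),
        ((5, 2), (5, 3), True, False),   # f1 tie blocks strict domination
    ])
    def test_examples(self, a, b, weak, strict):
        sa, sb = scored(*a), scored(*b)
        assert weakly_dominates(sa, sb) is weak
        assert dominates(sa, sb) is strict

    @settings(max_examples=200, derandomize=True)
    @given(st.tuples(st.integers(0, 9), st.integers(0, 6)),
           st.tuples(st.integers(0, 9), st.integers(0, 6)),
           st.tuples(st.integers(0, 9), st.integers(0, 6)))
    def test_order_properties(self, a, b, c):
        sa, sb, sc = scored(*a), scored(*b), scored(*c)
        assert weakly_dominates(sa, sa)
        if weakly_dominates(sa, sb) and weakly_dominates(sb, sc):
            assert weakly_dominates(sa, sc)
        if dominates(sa, sb):
            assert weakly_dominates(sa, sb)


class TestMutate:
    def test_q1_flips_every_bit(self):
        rng = np.random.default_rng(0)
        out = mutate(np.array([0, 1, 0]), 1, rng)
        np.testing.assert_array_equal(out, [1, 0, 1])

    def test_same_seed_same_output(self):
        a = mutate(np.zeros(20, dtype=np.uint8), 20, np.random.default_rng(9))
        b = mutate(np.zeros(20, dtype=np.uint8), 20, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_invalid_q(self):
        with pytest.raises(ConfigError):
            mutate(np.zeros(3, dtype=np.uint8), 0, np.random.default_rng(0))


class TestPopulation:
    def test_insert_into_empty(self):
        pop = update_population(Population(), scored(5, 2))
        assert [(m.f1, m.f2) for m in pop.members] == [(5, 2)]

    def test_dominating_candidate_replaces(self):
        pop = Population([scored(6, 3)])
        update_population(pop, scored(5, 2))
        assert [(m.f1, m.f2) for m in pop.members] == [(5, 2)]

    def test_matches_brute_force_front(self):
        rng = np.random.default_rng(12)
        history = []
        pop = Population()
        for _ in range(200):
            f2 = int(rng.integers(0, 7))
            f1 = int(rng.integers(0, 30))
            cand = scored(f1, f2)
            history.append((f1, f2))
            update_population(pop, cand)
            # antichain invariant after every update
            for a, b in product(pop.members, repeat=2):
                if a is not b:
                    assert not weakly_dominates(a, b)
        pairs = set(history)
        front = {p for p in pairs
                 if not any(q != p and q[0] <= p[0] and q[1] <= p[1] for q in pairs)}
        assert {(m.f1, m.f2) for m in pop.members} == front


class TestLocalSearch:
    def test_single_path_explores_one_neighbor(self):
        preds = random_preds(1, 10, ["a", "b"], seed=0)
        y = LabelVector(preds.labels[0].copy(), ["a", "b"])
        center = evaluate(np.zeros(1), preds, y)
        pop = Population()
        local_search(center, preds, y, pop)
        # the only Hamming-1 neighbor is the singleton mask with zero error
        assert {(m.f1, m.f2) for m in pop.members} == {(0, 1)}

    def test_population_front_consistent_with_enumeration(self):
        preds = random_preds(4, 25, ["a", "b", "c"], seed=6)
        rng = np.random.default_rng(7)
        y = LabelVector(rng.choice(["a", "b", "c"], 25), ["a", "b", "c"])
        all_scores = [evaluate(np.asarray(bits), preds, y)
                      for bits in product([0, 1], repeat=4)]
        true_front = {(s.f1, s.f2) for s in all_scores
                      if not any(weakly_dominates(t, s) and (t.f1, t.f2) != (s.f1, s.f2)
                                 for t in all_scores)}
        center = min(all_scores, key=lambda s: (s.f1, s.f2))
        pop = Population()
        pop.add(center)
        local_search(center, preds, y, pop)
        # every archive member must sit on the true Pareto front
        assert {(m.f1, m.f2) for m in pop.members} <= true_front


class TestPrune:
    def test_finds_perfect_singleton(self):
        preds = random_preds(5, 30, ["a", "b"], seed=2)
        y = LabelVector(preds.labels[3].copy(), ["a", "b"])
        best, pop, trace = prune(preds, y, PruneConfig(max_iter=40, seed=0))
        assert (best.f1, best.f2) == (0, 1)
        assert best.bits[3] == 1

    def test_trace_best_f1_non_increasing(self):
        preds = random_preds(6, 40, ["a", "b", "c"], seed=5)
        rng = np.random.default_rng(6)
        y = LabelVector(rng.choice(["a", "b", "c"], 40), ["a", "b", "c"])
        _, _, trace = prune(preds, y, PruneConfig(max_iter=60, seed=1))
        f1s = [row[1] for row in trace]
        assert all(a >= b for a, b in zip(f1s, f1s[1:]))

    def test_bit_reproducible(self):
        preds = random_preds(6, 40, ["a", "b"], seed=8)
        rng = np.random.default_rng(9)
        y = LabelVector(rng.choice(["a", "b"], 40), ["a", "b"])
        r1 = prune(preds, y, PruneConfig(max_iter=50, seed=13))
        r2 = prune(preds, y, PruneConfig(max_iter=50, seed=13))
        assert r1[0] == r2[0]
        assert r1[2] == r2[2]

    def test_invalid_max_iter(self):
        with pytest.raises(ConfigError):
            PruneConfig(max_iter=0)
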
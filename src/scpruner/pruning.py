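"""Bi-objective Pareto pruning of the path lattice.

A sub-network is a binary mask over the l paths.  Two objectives are
minimized jointly: f1, the number of reference cells the masked ensemble's
consensus vote misclassifies, and f2, the number of retained paths.  The
search alternates a global bit-flip mutation step over a weak-domination
archive (the population, an antichain in objective space) with a greedy
Hamming-1 local search around each mutant, and finally returns the archive
member with the lowest consensus error, preferring smaller sub-networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, ValidationError
from .ensemble import PathPredictionMatrix
from .matrix import LabelVector


@dataclass(frozen=True)
class ScoredMask:
    """A mask with its objective pair (f1 = consensus errors, f2 = #paths)."""

    bits: tuple[int, ...]
    f1: int
    f2: int

    def bits_array(self) -> np.ndarray:
        return np.asarray(self.bits, dtype=np.uint8)


@dataclass
class PruneConfig:
    """q: mutation denominator (default l); d: local radius; max_iter; seed."""

    q: int | None = None
    d: int = 1
    max_iter: int = 1800
    seed: int = 0

    def __post_init__(self) -> None:
        if self.q is not None and self.q < 1:
            raise ConfigError("q must be >= 1")
        if self.d != 1:
            raise ConfigError("only a Hamming-1 local radius is supported")
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")


class ConsensusEvaluator:
    """Vectorized consensus vote and objective evaluation for one dataset.

    Ties in the per-cell vote are broken by the highest summed probability
    among the tied labels, then by the lexicographically smallest label.
    """

    def __init__(self, preds: PathPredictionMatrix, y: LabelVector | None = None):
        self.categories = list(preds.categories)
        k = len(self.categories)
        codes = preds.codes()  # (l, n)
        self.l, self.n = codes.shape
        # one-hot vote tensor (l, k, n) and probability tensor (l, k, n)
        onehot = np.zeros((self.l, k, self.n))
        rows = np.arange(self.n)
        for p in range(self.l):
            onehot[p, codes[p], rows] = 1.0
        self._onehot = onehot
        self._probsT = np.ascontiguousarray(np.transpose(preds.probs, (0, 2, 1)))
        self._probs = preds.probs
        # lexicographic rank order of categories
        self._lexorder = np.argsort(np.asarray(self.categories, dtype=object))
        self._ycodes = None
        if y is not None:
            lut = {c: i for i, c in enumerate(self.categories)}
            try:
                self._ycodes = np.fromiter((lut[v] for v in y.labels),
                                           dtype=np.int64, count=len(y.labels))
            except KeyError as exc:
                raise ValidationError(f"reference label {exc} unseen by paths") from exc
            if len(y.labels) != self.n:
                raise ValidationError("labels and predictions are misaligned")

    def consensus_codes(self, bits: np.ndarray) -> np.ndarray:
        """Per-cell consensus label codes under the given mask (nonempty)."""
        w = np.asarray(bits, dtype=np.float64)
        votes = np.tensordot(w, self._onehot, axes=1)       # (k, n)
        probsum = np.tensordot(w, self._probsT, axes=1)     # (k, n)
        tied = votes == votes.max(axis=0)
        p = np.where(tied, probsum, -np.inf)
        tied &= p == p.max(axis=0)
        # first tied label in lexicographic category order
        in_lex = tied[self._lexorder]
        return self._lexorder[np.argmax(in_lex, axis=0)]

    def consensus(self, bits: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Consensus labels and mean probability assigned to them."""
        sel = np.flatnonzero(np.asarray(bits))
        if sel.size == 0:
            raise ConfigError("empty sub-network mask")
        winner = self.consensus_codes(bits)
        conf = self._probs[sel][:, np.arange(self.n), winner].mean(axis=0)
        labels = np.asarray(self.categories, dtype=object)[winner]
        return labels, conf

    def evaluate(self, bits: np.ndarray) -> ScoredMask:
        """Objective pair; the empty mask scores the sentinel f1 = n + 1."""
        if self._ycodes is None:
            raise ValidationError("evaluator built without reference labels")
        bits = np.asarray(bits, dtype=np.uint8)
        if bits.shape != (self.l,):
            raise ValidationError(f"mask length {bits.shape} != {self.l}")
        f2 = int(bits.sum())
        if f2 == 0:
            return ScoredMask(tuple(int(b) for b in bits), self.n + 1, 0)
        winner = self.consensus_codes(bits)
        f1 = int(np.count_nonzero(winner != self._ycodes))
        return ScoredMask(tuple(int(b) for b in bits), f1, f2)


def evaluate(mask: np.ndarray, preds: PathPredictionMatrix,
             y: LabelVector) -> ScoredMask:
    """One-shot objective evaluation of a mask."""
    return ConsensusEvaluator(preds, y).evaluate(mask)


def weakly_dominates(a: ScoredMask, b: ScoredMask) -> bool:
    return a.f1 <= b.f1 and a.f2 <= b.f2


def dominates(a: ScoredMask, b: ScoredMask) -> bool:
    return a.f1 < b.f1 and a.f2 < b.f2


@dataclass
class Population:
    """Archive of mutually non-weakly-dominating masks (an antichain)."""

    members: list[ScoredMask] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)

    def add(self, cand: ScoredMask) -> bool:
        """Offer a candidate; returns True if it entered the archive.

        A candidate weakly dominated by an existing member is discarded;
        otherwise it is inserted and every member it weakly dominates is
        removed, restoring the antichain.
        """
        for m in self.members:
            if weakly_dominates(m, cand):
                return False
        self.members = [m for m in self.members if not weakly_dominates(cand, m)]
        self.members.append(cand)
        return True

    def best(self) -> ScoredMask:
        """Lowest f1; ties to lower f2 then the lexicographically smallest mask."""
        return min(self.members, key=lambda m: (m.f1, m.f2, m.bits))


def update_population(pop: Population, cand: ScoredMask) -> Population:
    pop.add(cand)
    return pop


def mutate(bits: np.ndarray, q: int, rng: np.random.Generator) -> np.ndarray:
    """Flip every bit independently with probability 1/q."""
    if q < 1:
        raise ConfigError("q must be >= 1")
    bits = np.asarray(bits, dtype=np.uint8)
    flips = rng.random(bits.shape[0]) < 1.0 / q
    return bits ^ flips.astype(np.uint8)


def local_search(center: ScoredMask, preds: PathPredictionMatrix,
                 y: LabelVector, pop: Population,
                 _evaluate=None) -> Population:
    """Greedy Hamming-1 walk from ``center``; each step flips a fresh index.

    At each step the unexplored single-bit flips of the current point are
    evaluated; the best (minimal f1, then f2, then lowest flipped index)
    becomes the new center and its index is retired.  The walk ends when no
    unexplored flip remains (at most l steps) and every visited point is
    offered to the population.
    """
    ev = _evaluate or ConsensusEvaluator(preds, y).evaluate
    l = len(center.bits)
    L = center
    explored: set[int] = set()
    visited: list[ScoredMask] = []
    while len(explored) < l:
        best = None
        for i in range(l):
            if i in explored:
                continue
            nb = list(L.bits)
            nb[i] = 1 - nb[i]
            sm = ev(np.asarray(nb, dtype=np.uint8))
            key = (sm.f1, sm.f2, i)
            if best is None or key < best[0]:
                best = (key, sm, i)
        _, sm, i = best
        visited.append(sm)
        explored.add(i)
        L = sm
    for sm in visited:
        pop.add(sm)
    return pop


def prune(preds: PathPredictionMatrix, y: LabelVector,
          cfg: PruneConfig | None = None) -> tuple[ScoredMask, Population, list]:
    """Run the full pruning search; returns (best mask, archive, trace).

    The trace holds one (iteration, best_f1, best_f2, population_size) row
    per global iteration; its best_f1 column is non-increasing because the
    archive never discards its incumbent best.
    """
    cfg = cfg or PruneConfig()
    l = preds.n_paths
    q = cfg.q if cfg.q is not None else l
    rng = np.random.default_rng(cfg.seed)
    base = ConsensusEvaluator(preds, y)
    cache: dict[tuple, ScoredMask] = {}

    def ev(bits: np.ndarray) -> ScoredMask:
        key = tuple(int(b) for b in bits)
        hit = cache.get(key)
        if hit is None:
            hit = base.evaluate(np.asarray(key, dtype=np.uint8))
            cache[key] = hit
        return hit

    pop = Population()
    pop.add(ev(rng.integers(0, 2, size=l, dtype=np.uint8)))
    trace: list[tuple[int, int, int, int]] = []
    for it in range(cfg.max_iter):
        parent = pop.members[int(rng.integers(len(pop)))]
        child_bits = mutate(parent.bits_array(), q, rng)
        child = ev(child_bits)
        pop.add(child)
        local_search(child, preds, y, pop, _evaluate=ev)
        best = pop.best()
        trace.append((it, best.f1, best.f2, len(pop)))
    return pop.best(), pop, trace
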
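"""Wrapper feature-subset selection by scatter search.

Candidate subsets of the 61 descriptors are scored by the cross-validated
accuracy of the same PUK-SVM used for final classification (a wrapper, not
a filter). Scatter search maintains a small reference set split between
the highest-scoring subsets (quality half) and subsets maximally distant
from them in Hamming distance over indicator vectors (diversity half);
parent pairs are recombined, children improved by a single-feature
add/remove hill climb, and the refset updated elitistically until it
stalls or the generation budget is spent.

Every score is memoized by subset, and the whole search is a deterministic
function of (dataset, config seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .datasets import LabeledDataset
from .errors import EmptySubset, StratificationError
from .evaluation import cross_validate
from .svm import KernelParams, SVMConfig


@dataclass(frozen=True)
class SubsetCandidate:
    """A scored feature subset (names kept sorted for determinism)."""

    features: tuple[str, ...]
    score: float
    evaluations: int = 0

    def __post_init__(self) -> None:
        if not self.features:
            raise EmptySubset("candidate subset is empty")


@dataclass
class ScatterSearchConfig:
    """Search budget and shape.

    refset_size ``b`` splits evenly into b/2 quality + b/2 diversity
    members; the initial population holds ``4*b`` random subsets; the
    improvement operator is a first-improvement single-feature add/remove
    hill climb capped at ``improve_cap`` evaluated neighbours.
    """

    refset_size: int = 10
    initial_population: int | None = None   # defaults to 4 * refset_size
    max_generations: int = 20
    cv_folds: int = 5
    improve_cap: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.refset_size < 4 or self.refset_size % 2:
            raise ValueError("refset_size must be even and >= 4")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.initial_population is None:
            self.initial_population = 4 * self.refset_size


def evaluate_subset(dataset: LabeledDataset, subset: Sequence[str],
                    folds: int = 5, seed: int = 0,
                    config: SVMConfig = SVMConfig(),
                    kernel: KernelParams = KernelParams()) -> float:
    """Mean stratified k-fold accuracy (in [0, 1]) of the wrapped SVM."""
    subset = sorted(subset)
    if not subset:
        raise EmptySubset("cannot evaluate an empty subset")
    report = cross_validate(dataset, k=folds, seed=seed, subset=subset,
                            config=config, kernel=kernel)
    return report.accuracy / 100.0


def _hamming(a: frozenset, b: frozenset) -> int:
    return len(a ^ b)


class _Scorer:
    """Memoized wrapper-CV scorer."""

    def __init__(self, dataset, folds, seed, config, kernel):
        self.dataset = dataset
        self.folds = folds
        self.seed = seed
        self.config = config
        self.kernel = kernel
        self.cache: dict[frozenset, float] = {}
        self.evaluations = 0

    def __call__(self, subset: frozenset) -> float:
        if subset not in self.cache:
            self.cache[subset] = evaluate_subset(
                self.dataset, sorted(subset), folds=self.folds,
                seed=self.seed, config=self.config, kernel=self.kernel)
            self.evaluations += 1
        return self.cache[subset]


def _improve(subset: frozenset, names: list[str], scorer: _Scorer,
             rng: np.random.Generator, cap: int) -> frozenset:
    """First-improvement add/remove hill climb, neighbour order seeded."""
    current = subset
    best = scorer(current)
    budget = cap
    improved = True
    while improved and budget > 0:
        improved = False
        moves = list(names)
        rng.shuffle(moves)
        for name in moves:
            if budget <= 0:
                break
            cand = (current - {name}) if name in current else (current | {name})
            if not cand:
                continue
            budget -= 1
            s = scorer(cand)
            if s > best + 1e-12:
                current, best = cand, s
                improved = True
                break
    return current


def _prefer(a: tuple[float, frozenset], b: tuple[float, frozenset]) -> bool:
    """True when a beats b: higher score, then fewer features, then
    lexicographically earlier sorted names."""
    (sa, fa), (sb, fb) = a, b
    if sa != sb:
        return sa > sb
    if len(fa) != len(fb):
        return len(fa) < len(fb)
    return sorted(fa) < sorted(fb)


def _update_refset(scored: dict[frozenset, float], b: int
                   ) -> tuple[list[frozenset], list[frozenset]]:
    """Split b members into a quality half (top scores, ties toward
    smaller subsets) and a diversity half (greedy max-min Hamming
    distance to the members already chosen)."""
    b1 = b // 2
    ordered = sorted(scored, key=lambda s: (-scored[s], len(s), sorted(s)))
    quality = ordered[:b1]
    chosen = list(quality)
    pool = [s for s in ordered[b1:]]
    diversity: list[frozenset] = []
    while pool and len(diversity) < b - b1:
        best = max(pool, key=lambda s: (min(_hamming(s, c) for c in chosen),
                                        scored[s], sorted(s)))
        diversity.append(best)
        chosen.append(best)
        pool.remove(best)
    return quality, diversity


@dataclass
class SearchTrace:
    """Per-generation log: best score and the refset halves."""

    generations: list[dict] = field(default_factory=list)

    def record(self, gen: int, best_score: float,
               quality: list[frozenset], diversity: list[frozenset]) -> None:
        self.generations.append({
            "generation": gen,
            "best_score": best_score,
            "quality": [tuple(sorted(s)) for s in quality],
            "diversity": [tuple(sorted(s)) for s in diversity],
        })


def scatter_search(dataset: LabeledDataset,
                   config: ScatterSearchConfig = ScatterSearchConfig(),
                   svm_config: SVMConfig = SVMConfig(),
                   kernel: KernelParams = KernelParams(),
                   feature_names: Sequence[str] | None = None,
                   return_trace: bool = False):
    """Best feature subset found by scatter search over the wrapper score.

    Ties break toward fewer features, then lexicographic name order. With
    ``return_trace=True`` also returns the :class:`SearchTrace` of
    per-generation refsets.
    """
    names = list(feature_names) if feature_names is not None else list(dataset.X.columns)
    if not names:
        raise EmptySubset("no features to search over")
    rng = np.random.default_rng(config.seed)
    scorer = _Scorer(dataset, config.cv_folds, config.seed, svm_config, kernel)
    trace = SearchTrace()

    # diverse initial population: random subsets of varying density
    population: set[frozenset] = set()
    while len(population) < config.initial_population:
        density = rng.uniform(0.1, 0.6)
        mask = rng.random(len(names)) < density
        if not mask.any():
            continue
        population.add(frozenset(n for n, m in zip(names, mask) if m))
    population = {_improve(s, names, scorer, rng, config.improve_cap // 3)
                  for s in population}

    scored = {s: scorer(s) for s in population}
    quality, diversity = _update_refset(scored, config.refset_size)
    refset = quality + diversity
    best_score, best_subset = scored[refset[0]], refset[0]
    for s in refset[1:]:
        if _prefer((scored[s], s), (best_score, best_subset)):
            best_score, best_subset = scored[s], s
    trace.record(0, best_score, quality, diversity)

    for gen in range(1, config.max_generations + 1):
        children: set[frozenset] = set()
        for a, b in combinations(refset, 2):
            both = frozenset(a & b)
            either = list((a | b) - both)
            keep = [n for n in either if rng.random() < 0.5]
            child = both | frozenset(keep)
            if child:
                children.add(child)
        children = {_improve(c, names, scorer, rng, config.improve_cap)
                    for c in children}
        for c in children:
            scored[c] = scorer(c)
        new_quality, new_diversity = _update_refset(scored, config.refset_size)
        new_refset = new_quality + new_diversity
        for s in new_refset:
            if _prefer((scored[s], s), (best_score, best_subset)):
                best_score, best_subset = scored[s], s
        trace.record(gen, best_score, new_quality, new_diversity)
        if set(new_refset) == set(refset):
            break
        refset = new_refset
        quality, diversity = new_quality, new_diversity

    candidate = SubsetCandidate(tuple(sorted(best_subset)), best_score,
                                evaluations=scorer.evaluations)
    if return_trace:
        return candidate, trace
    return candidate
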
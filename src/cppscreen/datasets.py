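"""Training-set construction under five class-imbalance strategies.

With 111 known positives and only 34 experimentally confirmed negatives,
the class ratio itself is a design choice. The five strategies:

``UNBALANCED``
    all 111 positives + all 34 negatives (145 rows).
``RANDOM_NEG``
    111 positives + 111 random peptides from a 0th-order Markov model,
    assumed non-penetrating.
``BIOLOGICAL_NEG``
    111 positives + 111 peptides drawn without replacement from a
    biological peptide pool, assumed non-penetrating.
``OVERSAMPLE_NEG``
    111 positives + 111 draws with replacement from the 34 known
    negatives (222 rows).
``SUBSAMPLE_POS``
    ten datasets, each 34 positives drawn with replacement + the 34 known
    negatives (68 rows each).

Rows are positives-then-negatives, then shuffled once under the dataset
seed; the shuffle belongs to the dataset so downstream folds are
deterministic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptors import FEATURE_NAMES, feature_table
from .errors import DegenerateLabels, MissingGenerator, PoolTooSmall
from .generator import ResidueFrequencyModel, sample_peptides
from .peptides import Label, Peptide, PeptideCollection


class Strategy(enum.Enum):
    UNBALANCED = "unbalanced"
    RANDOM_NEG = "random_neg"
    BIOLOGICAL_NEG = "biological_neg"
    OVERSAMPLE_NEG = "oversample_neg"
    SUBSAMPLE_POS = "subsample_pos"


@dataclass
class LabeledDataset:
    """A featurized training set: X (61 columns), y in {+1, -1}, provenance.

    ``y`` uses +1 for CPP. ``provenance`` maps each row to the id of the
    source peptide it was drawn from (repeats allowed for with-replacement
    strategies).
    """

    X: pd.DataFrame
    y: np.ndarray
    strategy: Strategy
    seed: int
    provenance: list[str] = field(default_factory=list)
    peptides: list[Peptide] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise ValueError("X and y lengths differ")
        self.y = np.asarray(self.y, dtype=int)
        if not set(np.unique(self.y)) <= {-1, 1}:
            raise ValueError("labels must be +1/-1")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def n_positive(self) -> int:
        return int((self.y == 1).sum())

    @property
    def n_negative(self) -> int:
        return int((self.y == -1).sum())


def _assemble(pos: list[Peptide], neg: list[Peptide], strategy: Strategy,
              seed: int, rng: np.random.Generator) -> LabeledDataset:
    peps = pos + neg
    y = np.array([1] * len(pos) + [-1] * len(neg))
    order = rng.permutation(len(peps))
    peps = [peps[i] for i in order]
    y = y[order]
    provenance = [p.id for p in peps]
    rows = [Peptide(f"row_{i:04d}", p.sequence, p.label, p.source)
            for i, p in enumerate(peps)]
    X = feature_table(rows)
    X.index = pd.Index([p.id for p in peps], name="source_id")
    if len(set(y)) < 2:
        raise DegenerateLabels("dataset must contain both classes")
    return LabeledDataset(X=X, y=y, strategy=strategy, seed=seed,
                          provenance=provenance, peptides=peps)


def build_dataset(strategy: Strategy | str,
                  positives: PeptideCollection,
                  negatives: PeptideCollection,
                  pool_or_model: PeptideCollection | ResidueFrequencyModel | None = None,
                  seed: int = 0,
                  n_subsample_datasets: int = 10,
                  ) -> LabeledDataset | list[LabeledDataset]:
    """Build a featurized training set under one of the five strategies.

    Returns a single :class:`LabeledDataset`, or a list of ten for
    ``SUBSAMPLE_POS``. All sampling and the final row shuffle derive from
    ``seed`` (SUBSAMPLE_POS dataset *i* uses ``seed + i``).
    """
    strategy = Strategy(strategy)
    pos = [p for p in positives]
    neg = [p for p in negatives]
    rng = np.random.default_rng(seed)

    if strategy is Strategy.UNBALANCED:
        return _assemble(pos, neg, strategy, seed, rng)

    if strategy is Strategy.RANDOM_NEG:
        if not isinstance(pool_or_model, ResidueFrequencyModel):
            raise MissingGenerator("RANDOM_NEG needs a ResidueFrequencyModel")
        sampled = sample_peptides(pool_or_model, len(pos), rng,
                                  prefix="randneg", label=Label.NON_CPP)
        return _assemble(pos, list(sampled), strategy, seed, rng)

    if strategy is Strategy.BIOLOGICAL_NEG:
        if not isinstance(pool_or_model, PeptideCollection):
            raise MissingGenerator("BIOLOGICAL_NEG needs a peptide pool")
        if len(pool_or_model) < len(pos):
            raise PoolTooSmall(
                f"pool of {len(pool_or_model)} < {len(pos)} positives")
        idx = rng.choice(len(pool_or_model), size=len(pos), replace=False)
        drawn = [pool_or_model[int(i)] for i in idx]
        drawn = [Peptide(p.id, p.sequence, Label.NON_CPP, p.source) for p in drawn]
        return _assemble(pos, drawn, strategy, seed, rng)

    if strategy is Strategy.OVERSAMPLE_NEG:
        idx = rng.integers(0, len(neg), size=len(pos))
        drawn = [neg[int(i)] for i in idx]
        return _assemble(pos, drawn, strategy, seed, rng)

    # SUBSAMPLE_POS: ten balanced 34+34 datasets
    out = []
    for k in range(n_subsample_datasets):
        sub_rng = np.random.default_rng(seed + k)
        idx = sub_rng.integers(0, len(pos), size=len(neg))
        drawn = [pos[int(i)] for i in idx]
        out.append(_assemble(drawn, neg, strategy, seed + k, sub_rng))
    return out


def synthetic_biological_pool(model: ResidueFrequencyModel, n: int = 200,
                              seed: int = 20110714) -> PeptideCollection:
    """Deterministic synthetic stand-in for a biological peptide pool.

    The original pool of proteome-derived 12-26-mers is not redistributable,
    so tests and examples use peptides sampled from the background
    frequency model under a fixed seed; any real FASTA pool can be passed
    to :func:`build_dataset` instead.
    """
    pool = sample_peptides(model, n, seed, prefix="pool", label=Label.NON_CPP)
    return PeptideCollection(list(pool), name="synthetic_pool")
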
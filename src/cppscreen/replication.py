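"""End-to-end drivers for the dataset-construction comparison.

Each function rebuilds a training set from the packaged fixtures under one
of the imbalance strategies, runs scatter-search wrapper feature selection
with the PUK-SVM (defaults omega=1, sigma=1, C=1), and reports stratified
10-fold cross-validated accuracy, averaged over several resampling seeds.
These are the headline quantities of the screening method: how each way
of balancing the 111-positive / 34-negative data affects accuracy.

The scatter-search budget used here is deliberately compact (refset 6, a
few generations, 3-fold inner CV, capped hill climbs): the wrapper score
surface for these 61 descriptors is dominated by a handful of charge and
hydrogen-bonding features that a small search finds reliably, and the
final reported accuracies always come from a fresh 10-fold CV at full
precision, never from the inner wrapper score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import Strategy, build_dataset
from .evaluation import cross_validate, evaluate_on
from .feature_selection import ScatterSearchConfig, scatter_search
from .generator import default_frequency_model
from .peptides import load_bundled
from .svm import train_svm


@dataclass(frozen=True)
class ReplicationConfig:
    """Search budgets for the wrapper step inside the replication runs.

    The 222-row balanced datasets use a compact budget (3-fold inner CV,
    capped hill climbs); the 68-row subsampled datasets are cheap enough
    to search with a 5-fold inner wrapper and a deeper climb, which the
    small-sample selection step needs to be effective.
    """

    refset_size: int = 6
    max_generations: int = 3
    inner_folds: int = 3
    improve_cap: int = 15
    small_max_generations: int = 4
    small_inner_folds: int = 5
    small_improve_cap: int = 25
    n_seeds: int = 5


def _sub_seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds below 2**31 derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def _select_features(dataset, seed: int, cfg: ReplicationConfig,
                     small: bool = False):
    if small:
        search_cfg = ScatterSearchConfig(
            refset_size=cfg.refset_size,
            max_generations=cfg.small_max_generations,
            cv_folds=cfg.small_inner_folds,
            improve_cap=cfg.small_improve_cap, seed=seed)
    else:
        search_cfg = ScatterSearchConfig(
            refset_size=cfg.refset_size, max_generations=cfg.max_generations,
            cv_folds=cfg.inner_folds, improve_cap=cfg.improve_cap, seed=seed)
    return list(scatter_search(dataset, search_cfg).features)


def oversampled_negatives_cv_accuracy(seed: int,
                                      cfg: ReplicationConfig = ReplicationConfig(),
                                      ) -> tuple[float, float]:
    """Approach 4: oversample the 34 known negatives to 111.

    Returns ``(mean 10-fold CV accuracy, mean accuracy of the same models
    re-evaluated on the original unbalanced 145-peptide set)``, each
    averaged over ``cfg.n_seeds`` resampling seeds.
    """
    pos = load_bundled("cpp111")
    neg = load_bundled("noncpp34")
    cv_accs, test_accs = [], []
    for s in _sub_seeds(seed, cfg.n_seeds):
        ds = build_dataset(Strategy.OVERSAMPLE_NEG, pos, neg, seed=s)
        subset = _select_features(ds, s, cfg)
        cv_accs.append(cross_validate(ds, k=10, seed=s, subset=subset).accuracy)
        model = train_svm(ds, subset=subset)
        unbalanced = build_dataset(Strategy.UNBALANCED, pos, neg, seed=s)
        test_accs.append(evaluate_on(model, unbalanced).accuracy)
    return float(np.mean(cv_accs)), float(np.mean(test_accs))


def subsampled_positives_mean_cv_accuracy(seed: int,
                                          cfg: ReplicationConfig = ReplicationConfig(),
                                          ) -> float:
    """Approach 5: mean 10-fold CV accuracy over the ten 34+34 datasets."""
    pos = load_bundled("cpp111")
    neg = load_bundled("noncpp34")
    datasets = build_dataset(Strategy.SUBSAMPLE_POS, pos, neg,
                             seed=seed % (2 ** 31))
    accs = []
    for ds in datasets:
        subset = _select_features(ds, ds.seed, cfg, small=True)
        accs.append(cross_validate(ds, k=10, seed=ds.seed, subset=subset).accuracy)
    return float(np.mean(accs))


def random_negatives_cv_accuracy(seed: int,
                                 cfg: ReplicationConfig = ReplicationConfig(),
                                 ) -> float:
    """Approach 2: known CPPs vs generated random peptides, mean 10-fold
    CV accuracy over ``cfg.n_seeds`` generator seeds."""
    pos = load_bundled("cpp111")
    neg = load_bundled("noncpp34")
    freq_model = default_frequency_model()
    accs = []
    for s in _sub_seeds(seed, cfg.n_seeds):
        ds = build_dataset(Strategy.RANDOM_NEG, pos, neg, freq_model, seed=s)
        subset = _select_features(ds, s, cfg)
        accs.append(cross_validate(ds, k=10, seed=s, subset=subset).accuracy)
    return float(np.mean(accs))
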
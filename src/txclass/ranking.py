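"""Random-forest importance ranking of genes.

Many independently seeded forests are grown on the same training data and
their per-gene importances averaged into a single ranking; the top-C
prefix of that ranking feeds the gradient-boosted classifier. Importance
is mean decrease in impurity by default (the forest's embedded measure),
with permutation importance available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance


@dataclass
class RfConfig:
    """Forest ensemble configuration.

    Defaults follow the reference protocol: 1000 trees per forest, sqrt(f)
    candidate features per split, 100 independently seeded repetitions.
    Desk-scale runs shrink ``n_trees`` / ``n_repetitions`` via the config.
    """
    n_trees: int = 1000
    features_per_split: str | int | float = "sqrt"
    n_repetitions: int = 100
    importance_mode: str = "impurity"
    base_seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1 or self.n_repetitions < 1:
            raise ValueError("n_trees and n_repetitions must be >= 1")
        if self.importance_mode not in ("impurity", "permutation"):
            raise ValueError("importance_mode must be impurity or permutation")


@dataclass
class RankedFeatures:
    """Gene ordering by non-increasing mean importance.

    Ties are broken by lexicographic gene id (deterministic); ``source``
    is a fingerprint of the training data the ranking came from.
    """
    gene_ids: list
    mean_importance: pd.Series
    source: str = ""

    def __len__(self):
        return len(self.gene_ids)


def rf_importance(X_train: np.ndarray, y_train: np.ndarray, config: RfConfig,
                  rep_seed: int) -> np.ndarray:
    """Importance vector over genes from one seeded forest fit.

    ``X_train`` is samples x genes, training portion only — the caller
    guarantees no validation samples are present.
    """
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training labels contain a single class")
    rf = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.features_per_split,
        random_state=int(rep_seed) % (2**31),
        n_jobs=1,
    )
    rf.fit(X_train, y_train)
    if config.importance_mode == "impurity":
        return rf.feature_importances_
    res = permutation_importance(rf, X_train, y_train, n_repeats=5,
                                 random_state=int(rep_seed) % (2**31), n_jobs=1)
    return res.importances_mean


def average_rank(importances, gene_ids, source: str = "") -> RankedFeatures:
    """Average B aligned importance vectors and sort descending.

    Ties broken by gene id, ascending lexicographic.
    """
    mats = [np.asarray(v, dtype=float) for v in importances]
    if not mats:
        raise ValueError("no importance vectors")
    f = len(gene_ids)
    if any(v.shape != (f,) for v in mats):
        raise ValueError("importance vectors misaligned with gene ids")
    mean = np.mean(mats, axis=0)
    ids = np.asarray(gene_ids)
    order = np.lexsort((ids, -mean))
    ordered = ids[order]
    return RankedFeatures(
        gene_ids=list(ordered),
        mean_importance=pd.Series(mean[order], index=ordered,
                                  name="mean_importance"),
        source=source,
    )


def top_c(ranked: RankedFeatures, C: int) -> list:
    """First C gene ids of the ranking, order preserved."""
    if not 1 <= C <= len(ranked):
        raise ValueError(f"C={C} outside 1..{len(ranked)}")
    return ranked.gene_ids[:C]


def rank_features(X_train, y_train, gene_ids, config: RfConfig,
                  source: str = "") -> RankedFeatures:
    """Full ranking: B seeded forests (seed = base_seed + repetition index),
    importances averaged, sorted with the documented tie-break."""
    vecs = [rf_importance(X_train, y_train, config, config.base_seed + b)
            for b in range(config.n_repetitions)]
    return average_rank(vecs, gene_ids, source=source)
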
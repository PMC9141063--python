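"""Nested cross-validated feature selection and gradient-boosted classification.

The outer loop is repeated stratified k-fold cross-validation. Inside each
training fold, genes are ranked by averaged random-forest importance
(computed from the training samples only — validation samples never touch
the ranking), and for each candidate feature-set size C a gradient-boosted
tree classifier is trained on the top-C genes and scored on the held-out
fold. Pooling validation predictions per repetition gives one AUC-vs-C
curve per repetition; the pointwise median and its mean absolute deviation
summarize the curves and the grid argmax of the median defines C*, the
operating feature-set size.

A univariate baseline (`de_baseline`) trains the same boosted classifier
on differentially expressed genes from a single stratified 90/10 split,
for comparison with the nested multivariate selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, KFold, train_test_split
from xgboost import XGBClassifier

from . import evaluate
from ._seeds import derive_seed
from .ranking import RfConfig, RankedFeatures, average_rank, rank_features, top_c
from .stability import selection_frequency


class LeakageError(RuntimeError):
    """Validation samples contaminated the ranking or training stage."""


DEFAULT_BOOST_PARAMS = {
    "n_estimators": 100,
    "max_depth": 6,
    "learning_rate": 0.3,
}


def default_c_grid(f: int) -> list:
    """Geometric grid {5, 10, 20, ..., 640} clipped to f, plus f itself."""
    base = [5, 10, 20, 40, 80, 160, 320, 640]
    grid = [c for c in base if c < f]
    grid.append(f)
    return grid


@dataclass
class CvConfig:
    """Outer cross-validation configuration.

    Reference protocol: k=10 stratified folds, R=20 repetitions. C_grid
    defaults to a geometric sweep up to the full gene count.
    """
    k_folds: int = 10
    n_repetitions: int = 20
    stratified: bool = True
    C_grid: list | None = None
    boost_params: dict = field(default_factory=lambda: dict(DEFAULT_BOOST_PARAMS))
    seed: int = 0

    def __post_init__(self):
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.C_grid is not None:
            g = list(self.C_grid)
            if any(b <= a for a, b in zip(g, g[1:])):
                raise ValueError("C_grid must be strictly increasing")


@dataclass
class AucCurve:
    """Per-repetition AUC as a function of C with median/MAD aggregate."""

    grid: np.ndarray                # C values
    per_rep: pd.DataFrame           # repetitions x C
    median: pd.Series               # median AUC per C
    mad: pd.Series                  # mean absolute deviation about the median
    c_star: int                     # grid argmax of the median (smallest on ties)

    def interpolate(self, C):
        """Linear interpolation of the median curve between grid points."""
        return np.interp(C, self.grid, self.median.to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"C": self.grid,
                             "median_auc": self.median.to_numpy(),
                             "mad_auc": self.mad.to_numpy()})

    def to_json(self, path) -> None:
        obj = {"grid": [int(c) for c in self.grid],
               "median_auc": list(map(float, self.median)),
               "mad_auc": list(map(float, self.mad)),
               "c_star": int(self.c_star),
               "per_rep": self.per_rep.to_numpy().tolist()}
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.median.to_numpy()
        d = self.mad.to_numpy()
        ax.plot(self.grid, m, "k-", label="median AUC")
        ax.plot(self.grid, m + d, "r--", lw=0.8, label="median ± MAD")
        ax.plot(self.grid, m - d, "r--", lw=0.8)
        ax.axvline(self.c_star, color="b", lw=0.8,
                   label=f"C* = {self.c_star}")
        ax.set_xscale("log")
        ax.set_xlabel("number of input features C")
        ax.set_ylabel("AUC")
        ax.legend()
        return ax


def make_folds(labels, k: int, seed: int, stratified: bool = True) -> np.ndarray:
    """Fold assignment (0..k-1 per sample); stratified folds keep per-fold
    class proportions within one sample of the global ratio."""
    y = np.asarray(labels, dtype=int)
    if stratified:
        counts = np.bincount(y, minlength=2)
        if counts.min() < k:
            raise ValueError(f"smallest class ({counts.min()}) < k ({k})")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    fold = np.empty(len(y), dtype=int)
    for i, (_, val_idx) in enumerate(splitter.split(np.zeros(len(y)), y)):
        fold[val_idx] = i
    return fold


def _fit_boost(X_train, y_train, params: dict, seed: int) -> XGBClassifier:
    clf = XGBClassifier(objective="binary:logistic", eval_metric="logloss",
                        tree_method="hist", n_jobs=1, verbosity=0,
                        random_state=int(seed) % (2**31), **params)
    clf.fit(X_train, y_train)
    return clf


def run_fold(X, y, train_idx, val_idx, C_grid, rf_config: RfConfig,
             boost_params: dict, seed: int, gene_ids):
    """Rank on the training portion, then classify the validation portion
    for every C.

    Returns ``(records, ranking)`` where records is a list of dicts (one
    per validation sample per C) and ranking the fold's RankedFeatures.
    Raises LeakageError if the index sets overlap.
    """
    train_idx = np.asarray(train_idx)
    val_idx = np.asarray(val_idx)
    if np.intersect1d(train_idx, val_idx).size:
        raise LeakageError("train and validation folds overlap")
    rf_cfg = RfConfig(n_trees=rf_config.n_trees,
                      features_per_split=rf_config.features_per_split,
                      n_repetitions=rf_config.n_repetitions,
                      importance_mode=rf_config.importance_mode,
                      base_seed=derive_seed(seed, "rf"))
    ranking = rank_features(X[train_idx], y[train_idx], gene_ids, rf_cfg,
                            source=f"train_hash={hash(train_idx.tobytes())}")
    gene_pos = {g: j for j, g in enumerate(gene_ids)}
    records = []
    for C in C_grid:
        top = top_c(ranking, C)
        cols = np.array([gene_pos[g] for g in top])
        clf = _fit_boost(X[np.ix_(train_idx, cols)], y[train_idx],
                         boost_params, derive_seed(seed, "boost", C))
        prob = clf.predict_proba(X[np.ix_(val_idx, cols)])[:, 1]
        for i, pr in zip(val_idx, prob):
            records.append({"sample_index": int(i), "C": int(C),
                            "probability": float(pr)})
    return records, ranking


def aggregate_curve(records: pd.DataFrame, C_grid) -> AucCurve:
    """Pool validation predictions per repetition, compute AUC(C) per
    repetition, and summarize by pointwise median and mean absolute
    deviation; C* is the grid argmax of the median (smallest C on ties)."""
    grid = np.asarray(list(C_grid), dtype=int)
    reps = sorted(records["repetition"].unique())
    rows = np.empty((len(reps), len(grid)))
    for ri, r in enumerate(reps):
        rrec = records[records["repetition"] == r]
        for ci, C in enumerate(grid):
            cell = rrec[rrec["C"] == C]
            if cell.empty:
                raise ValueError(f"missing predictions for repetition {r}, "
                                 f"C={C}")
            rows[ri, ci] = evaluate.roc_auc(cell["label"].to_numpy(),
                                            cell["probability"].to_numpy())
    per_rep = pd.DataFrame(rows, index=reps, columns=grid)
    median = per_rep.median(axis=0)
    mad = (per_rep - median).abs().mean(axis=0)
    c_star = int(grid[int(np.argmax(median.to_numpy()))])
    return AucCurve(grid=grid, per_rep=per_rep, median=median, mad=mad,
                    c_star=c_star)


class NestedCVClassifier:
    """Case/control classifier with nested feature selection.

    Parameters
    ----------
    expr : ExpressionMatrix-style DataFrame (genes x samples), already
        preprocessed (variance stabilized, batch and covariates removed).
    metadata : sample table with a ``label`` column (case / control).
    rf_config : forest ranking configuration (inner selection engine).
    cv_config : outer cross-validation configuration.
    """

    def __init__(self, expr: pd.DataFrame, metadata: pd.DataFrame,
                 rf_config: RfConfig | None = None,
                 cv_config: CvConfig | None = None):
        if list(expr.columns) != list(metadata.index):
            metadata = metadata.loc[expr.columns]
        self.expr = expr
        self.metadata = metadata
        self.rf_config = rf_config or RfConfig()
        self.cv_config = cv_config or CvConfig()
        self.gene_ids = list(expr.index)
        self.sample_ids = list(expr.columns)
        self.y = (metadata["label"] == "case").to_numpy(dtype=int)
        if self.y.sum() in (0, len(self.y)):
            raise ValueError("both classes required")
        self.C_grid = (list(self.cv_config.C_grid)
                       if self.cv_config.C_grid is not None
                       else default_c_grid(len(self.gene_ids)))
        if self.C_grid[-1] > len(self.gene_ids):
            raise ValueError("C_grid exceeds the number of genes")

    def fit(self, seed: int | None = None) -> "NestedCVResults":
        """Run the full nested scheme; returns a NestedCVResults."""
        seed = self.cv_config.seed if seed is None else seed
        X = self.expr.to_numpy(dtype=float).T     # samples x genes
        rec_rows = []
        rep_importances = np.zeros((len(self.gene_ids),
                                    self.cv_config.n_repetitions))
        for r in range(self.cv_config.n_repetitions):
            fold = make_folds(self.y, self.cv_config.k_folds,
                              derive_seed(seed, "folds", r),
                              self.cv_config.stratified)
            fold_imps = []
            for f in range(self.cv_config.k_folds):
                val_idx = np.flatnonzero(fold == f)
                train_idx = np.flatnonzero(fold != f)
                records, ranking = run_fold(
                    X, self.y, train_idx, val_idx, self.C_grid,
                    self.rf_config, self.cv_config.boost_params,
                    derive_seed(seed, "fold", r, f), self.gene_ids)
                fold_imps.append(
                    ranking.mean_importance.reindex(self.gene_ids).to_numpy())
                for row in records:
                    row.update({"repetition": r, "fold": f})
                    rec_rows.append(row)
            rep_importances[:, r] = np.mean(fold_imps, axis=0)
        records = pd.DataFrame(rec_rows)
        records["sample_id"] = [self.sample_ids[i]
                                for i in records["sample_index"]]
        records["label"] = self.y[records["sample_index"].to_numpy()]
        records = records[["sample_id", "repetition", "fold", "C",
                           "probability", "label"]]
        self._check_coverage(records)
        return NestedCVResults(
            model=self, records=records,
            rep_importances=pd.DataFrame(rep_importances, index=self.gene_ids),
            C_grid=self.C_grid, seed=seed)

    def _check_coverage(self, records: pd.DataFrame) -> None:
        per = records.groupby(["repetition", "C"])["sample_id"].agg(
            ["count", "nunique"])
        n = len(self.sample_ids)
        if not ((per["count"] == n) & (per["nunique"] == n)).all():
            raise LeakageError("each sample must be predicted exactly once "
                               "per (repetition, C)")


@dataclass
class NestedCVResults:
    """Fitted nested-CV run: prediction records, AUC curve, rankings."""

    model: NestedCVClassifier
    records: pd.DataFrame
    rep_importances: pd.DataFrame   # genes x repetitions (fold-averaged)
    C_grid: list
    seed: int
    _curve: AucCurve | None = None

    @property
    def auc_curve(self) -> AucCurve:
        if self._curve is None:
            self._curve = aggregate_curve(self.records, self.C_grid)
        return self._curve

    @property
    def c_star(self) -> int:
        return self.auc_curve.c_star

    def rep_rankings(self) -> list:
        """One RankedFeatures per repetition (fold-averaged importances)."""
        genes = list(self.rep_importances.index)
        return [average_rank([self.rep_importances[r].to_numpy()], genes,
                             source=f"repetition={r}")
                for r in self.rep_importances.columns]

    def top_sets(self, C: int | None = None) -> list:
        C = self.c_star if C is None else C
        return [top_c(rk, C) for rk in self.rep_rankings()]

    def selection_frequency(self, C: int | None = None) -> pd.DataFrame:
        C = self.c_star if C is None else C
        rankings = self.rep_rankings()
        return selection_frequency(
            [top_c(rk, C) for rk in rankings],
            importances=[rk.mean_importance for rk in rankings])

    def metric_report(self, C: int | None = None,
                      threshold: float = 0.5) -> pd.DataFrame:
        """Mean and standard deviation over repetitions of AUC plus the
        threshold metrics, at feature-set size C (default C*)."""
        C = self.c_star if C is None else C
        rows = []
        for r, rrec in self.records[self.records["C"] == C].groupby("repetition"):
            y = rrec["label"].to_numpy()
            p = rrec["probability"].to_numpy()
            _, metrics = evaluate.confusion_metrics(y, p, threshold)
            metrics["auc"] = evaluate.roc_auc(y, p)
            rows.append(metrics)
        frame = pd.DataFrame(rows)
        cols = ["auc", "accuracy", "sensitivity", "specificity",
                "balanced_accuracy", "f1"]
        return pd.DataFrame({"mean": frame[cols].mean(),
                             "sd": frame[cols].std(ddof=1)})

    def endophenotype_report(self, C: int | None = None) -> pd.DataFrame:
        C = self.c_star if C is None else C
        return evaluate.endophenotype_report(self.records,
                                             self.model.metadata, C)

    def summary(self) -> str:
        curve = self.auc_curve
        rep = self.metric_report()
        cfg = self.model.cv_config
        lines = [
            "Nested cross-validated classification",
            "=" * 45,
            f"samples: {len(self.model.sample_ids)} "
            f"({int(self.model.y.sum())} cases / "
            f"{int((1 - self.model.y).sum())} controls), "
            f"genes: {len(self.model.gene_ids)}",
            f"outer CV: {cfg.k_folds}-fold x {cfg.n_repetitions} repetitions"
            f"{' (stratified)' if cfg.stratified else ''}",
            f"C grid: {[int(c) for c in curve.grid]}",
            f"C* = {curve.c_star}  "
            f"(median AUC {100 * curve.median[curve.c_star]:.1f}% "
            f"± {100 * curve.mad[curve.c_star]:.1f} MAD)",
            "",
            "metrics at C* (mean ± sd over repetitions, % scale):",
        ]
        for name, row in rep.iterrows():
            lines.append(f"  {name:<18s} {100 * row['mean']:5.1f} "
                         f"± {100 * (row['sd'] if np.isfinite(row['sd']) else 0):.1f}")
        return "\n".join(lines)


def de_baseline(expr: pd.DataFrame, metadata: pd.DataFrame,
                counts: pd.DataFrame | None = None,
                gene_set=None, alpha: float = 0.05,
                boost_params: dict | None = None, split_seed: int = 0,
                test_fraction: float = 0.10, leakage_safe: bool = True):
    """Gradient-boosted classification on DE genes with one stratified
    90/10 split; returns the test AUC.

    With ``gene_set=None``, DE genes are computed with the NB Wald screen —
    on the training portion of the split only when ``leakage_safe`` (the
    default), or on the full data when not (the literal, optimistic
    variant). Providing ``gene_set`` skips the DE step (e.g. to use a known
    truth set). Raises if the gene set comes out empty.
    """
    if list(expr.columns) != list(metadata.index):
        metadata = metadata.loc[expr.columns]
    y = (metadata["label"] == "case").to_numpy(dtype=int)
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=y, random_state=split_seed)
    if gene_set is None:
        from .diffexp import NegativeBinomialDE

        if counts is None:
            raise ValueError("counts required to derive the DE gene set")
        sub = train_idx if leakage_safe else idx
        cols = metadata.index[sub]
        de = NegativeBinomialDE(counts.loc[:, cols],
                                metadata.loc[cols]).fit()
        gene_set = de.de_gene_set(alpha)
    gene_set = [g for g in expr.index if g in set(gene_set)]
    if not gene_set:
        raise ValueError("empty DE gene set")
    X = expr.loc[gene_set].to_numpy(dtype=float).T
    clf = _fit_boost(X[train_idx], y[train_idx],
                     boost_params or dict(DEFAULT_BOOST_PARAMS),
                     derive_seed(split_seed, "de-baseline"))
    prob = clf.predict_proba(X[test_idx])[:, 1]
    return evaluate.roc_auc(y[test_idx], prob)
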
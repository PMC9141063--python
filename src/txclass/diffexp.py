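"""Per-gene negative-binomial Wald test — the univariate baseline.

Each gene is fitted with an NB generalized linear model (log link, library
size factors as offsets, dispersion fixed at the fitted mean-variance
trend) against a design of technical covariates plus the disease label,
and the label coefficient is tested with a two-sided Wald test. P-values
are Benjamini–Hochberg adjusted. Relative to DESeq2 this is deliberately
simplified: trend dispersions without per-gene empirical-Bayes shrinkage,
no fold-change shrinkage and no outlier handling — the role of this module
is a univariate feature-selection baseline, not DESeq2 parity.

The sign convention: a positive log2 fold change means higher expression
in cases than in controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import estimate_size_factors, fit_dispersion_trend

_LN2 = np.log(2.0)


@dataclass
class DesignSpec:
    """Ordered design: covariates first, disease label last.

    ``covariates`` may contain "rin" (standardized), "site" (categorical,
    treatment coding) and "sex" (indicator). The label column is always the
    final one so the Wald test targets a fixed coefficient position.
    """
    covariates: tuple = ("rin", "site", "sex")

    def build(self, metadata: pd.DataFrame):
        cols = [np.ones(len(metadata))]
        names = ["intercept"]
        for cov in self.covariates:
            if cov == "rin":
                r = metadata["rin"].to_numpy(dtype=float)
                sd = r.std()
                cols.append((r - r.mean()) / (sd if sd > 0 else 1.0))
                names.append("rin")
            elif cov == "site":
                levels = sorted(metadata["site"].unique())
                for lev in levels[1:]:
                    cols.append((metadata["site"] == lev).to_numpy(dtype=float))
                    names.append(f"site[{lev}]")
            elif cov == "sex":
                cols.append((metadata["sex"] == "M").to_numpy(dtype=float))
                names.append("sex[M]")
            else:
                v = metadata[cov]
                if v.dtype == object:
                    levels = sorted(v.unique())
                    for lev in levels[1:]:
                        cols.append((v == lev).to_numpy(dtype=float))
                        names.append(f"{cov}[{lev}]")
                else:
                    cols.append(v.to_numpy(dtype=float))
                    names.append(cov)
        cols.append((metadata["label"] == "case").to_numpy(dtype=float))
        names.append("label")
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        return X, names


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment.

    NaN entries (tests not performed) are excluded from m and returned NaN.
    """
    p = np.asarray(p_values, dtype=float)
    if np.nanmin(p, initial=0.0) < 0 or np.nanmax(p, initial=0.0) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    q = p[ok]
    m = q.size
    if m == 0:
        return out
    order = np.argsort(q, kind="mergesort")
    ranked = q[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def _irls_nb(Y, X, offset, alpha, tol=1e-8, max_iter=100):
    """Vectorized IRLS for NB GLMs with log link and fixed dispersion.

    Fits all G genes simultaneously against the shared design X (n x p)
    with per-sample offsets (log size factors) and per-gene dispersion
    alpha. Returns (beta [G x p], se [G x p], converged [G]).
    """
    G, n = Y.shape
    p = X.shape[1]
    beta = np.zeros((G, p))
    # init from the intercept: mean of offset-corrected counts
    with np.errstate(divide="ignore"):
        beta[:, 0] = np.log(np.maximum((Y / np.exp(offset)).mean(axis=1), 1e-8))
    converged = np.zeros(G, dtype=bool)
    active = np.arange(G)
    alpha = np.asarray(alpha, dtype=float)

    for _ in range(max_iter):
        b = beta[active]
        eta = np.clip(b @ X.T + offset, -30.0, 30.0)   # G' x n
        mu = np.exp(eta)
        W = mu / (1.0 + alpha[active, None] * mu)
        z = (eta - offset) + (Y[active] - mu) / mu
        XtWX = np.einsum("np,gn,nq->gpq", X, W, X, optimize=True)
        XtWz = np.einsum("np,gn,gn->gp", X, W, z, optimize=True)
        try:
            new = np.linalg.solve(XtWX + 1e-10 * np.eye(p),
                                  XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            break
        delta = np.max(np.abs(new - b), axis=1)
        beta[active] = new
        done = delta < tol
        converged[active[done]] = True
        active = active[~done]
        if active.size == 0:
            break

    eta = np.clip(beta @ X.T + offset, -30.0, 30.0)
    mu = np.exp(eta)
    W = mu / (1.0 + alpha[:, None] * mu)
    XtWX = np.einsum("np,gn,nq->gpq", X, W, X, optimize=True)
    try:
        cov = np.linalg.inv(XtWX + 1e-10 * np.eye(p))
        se = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0))
    except np.linalg.LinAlgError:
        se = np.full((G, p), np.nan)
    bad = ~np.all(np.isfinite(beta), axis=1) | ~np.all(np.isfinite(se), axis=1)
    converged &= ~bad
    return beta, se, converged


class NegativeBinomialDE:
    """Per-gene NB Wald differential-expression model.

    Parameters
    ----------
    counts : raw counts (genes x samples), prior to independent filtering,
        batch correction and variance stabilization.
    metadata : sample table with label, and the design covariates.
    size_factors : optional precomputed size factors (median-of-ratios
        estimated from ``counts`` when omitted).
    dispersion_trend : optional fitted trend (fitted from ``counts`` when
        omitted).
    design : DesignSpec; label is always the tested, final coefficient.
    """

    def __init__(self, counts, metadata, size_factors=None,
                 dispersion_trend=None, design: DesignSpec | None = None):
        if list(counts.columns) != list(metadata.index):
            metadata = metadata.loc[counts.columns]
        self.counts = counts
        self.metadata = metadata
        self.design = design or DesignSpec()
        self.size_factors = (size_factors if size_factors is not None
                             else estimate_size_factors(counts))
        self.dispersion_trend = (dispersion_trend if dispersion_trend is not None
                                 else fit_dispersion_trend(counts, self.size_factors))

    def fit(self, tol: float = 1e-8, max_iter: int = 100) -> "DEResults":
        X, names = self.design.build(self.metadata)
        Y = self.counts.to_numpy(dtype=float)
        s = self.size_factors.loc[self.counts.columns].to_numpy(dtype=float)
        offset = np.log(s)
        mean_norm = (Y / s).mean(axis=1)
        alpha = np.maximum(self.dispersion_trend(np.maximum(mean_norm, 1e-8)),
                           1e-8)
        beta, se, converged = _irls_nb(Y, X, offset, alpha, tol=tol,
                                       max_iter=max_iter)
        j = len(names) - 1
        lfc = beta[:, j] / _LN2
        lfc_se = se[:, j] / _LN2
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta[:, j] / se[:, j]
        pval = 2.0 * stats.norm.sf(np.abs(z))
        pval[~converged] = np.nan
        n_fail = int((~converged).sum())
        if n_fail:
            warnings.warn(f"{n_fail} gene(s) failed to converge; excluded "
                          "from multiple-testing correction")
        table = pd.DataFrame({
            "lfc": lfc, "lfc_se": lfc_se, "p_value": pval,
            "adj_p": bh_adjust(pval), "mean_norm_count": mean_norm,
            "converged": converged,
        }, index=self.counts.index)
        return DEResults(table, coef_names=names, model=self)


@dataclass
class DEResults:
    """Result of a per-gene NB Wald screen."""

    table: pd.DataFrame
    coef_names: list = field(default_factory=list)
    model: NegativeBinomialDE | None = None

    def de_genes(self, alpha: float = 0.05):
        """Genes with adjusted p strictly below ``alpha``, split by the sign
        of the fold change; returns ``(up, down)`` id sets."""
        t = self.table
        sig = t["adj_p"] < alpha
        up = set(t.index[sig & (t["lfc"] > 0)])
        down = set(t.index[sig & (t["lfc"] < 0)])
        return up, down

    def de_gene_set(self, alpha: float = 0.05) -> set:
        up, down = self.de_genes(alpha)
        return up | down

    def sorted_table(self) -> pd.DataFrame:
        return self.table.sort_values("adj_p", kind="mergesort")

    def summary(self, alpha: float = 0.05) -> str:
        up, down = self.de_genes(alpha)
        n = len(self.table)
        lines = [
            "Negative-binomial Wald differential expression",
            "=" * 47,
            f"genes tested          {int(self.table['converged'].sum()):>8d} / {n}",
            f"significant (adj p<{alpha:g})  {len(up) + len(down):>6d}",
            f"  up-regulated        {len(up):>8d}",
            f"  down-regulated      {len(down):>8d}",
        ]
        top = self.sorted_table().head(5)
        lines.append("top genes by adjusted p:")
        for g, r in top.iterrows():
            lines.append(f"  {g:<12s} lfc={r['lfc']:+.3f}±{r['lfc_se']:.3f} "
                         f"adj_p={r['adj_p']:.3g}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.sorted_table().to_csv(path, sep="\t")
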
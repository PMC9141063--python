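"""Count preprocessing: filtering, normalization, VST, batch/covariate removal.

The cascade turns a raw gene x sample count matrix into the classifier-ready
expression matrix, in a fixed order:

  biotype filter -> blacklist -> low-expression filter -> size factors ->
  independent filtering -> variance stabilizing transform ->
  small-site exclusion -> control-anchored site-batch removal ->
  sex/RIN covariate removal

All filters before batch correction use label-independent statistics only.
The site batch effect is estimated on control samples alone (sum-to-zero
site coding, per-gene least squares) and subtracted from cases and controls
alike — the control-anchored removal that motivates excluding sites with
fewer than two controls.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# gene-level filters


def filter_biotypes(counts: pd.DataFrame, annotation: pd.DataFrame,
                    allowed=("protein_coding", "lincRNA")) -> pd.DataFrame:
    """Keep genes whose annotated biotype is in ``allowed``; order preserved."""
    missing = counts.index.difference(annotation.index)
    if len(missing):
        raise KeyError(f"genes missing from annotation: {list(missing[:5])}"
                       + ("..." if len(missing) > 5 else ""))
    keep = annotation.loc[counts.index, "biotype"].isin(set(allowed))
    return counts.loc[keep.to_numpy()]


def drop_blacklist(counts: pd.DataFrame, blacklist) -> pd.DataFrame:
    """Remove blacklisted gene ids; absent ids are ignored with a warning."""
    blacklist = set(blacklist)
    absent = blacklist - set(counts.index)
    if absent:
        log.warning("%d blacklisted ids not in matrix", len(absent))
    keep = ~counts.index.isin(blacklist)
    out = counts.loc[keep]
    if out.shape[0] == 0:
        log.warning("blacklist removed every gene")
    return out


def filter_low_expression(counts: pd.DataFrame, min_count: int = 5,
                          min_fraction: float = 0.10) -> pd.DataFrame:
    """Keep genes with more than ``min_count`` counts (strict) in at least
    ``min_fraction`` of samples."""
    n = counts.shape[1]
    need = int(np.ceil(min_fraction * n))
    keep = (counts.to_numpy() > min_count).sum(axis=1) >= need
    return counts.loc[keep]


# ---------------------------------------------------------------------------
# normalization


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Reference genes are those with strictly positive geometric mean across
    samples (i.e. nonzero in every sample).
    """
    x = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        loggeo = np.log(x).mean(axis=1)
    ref = np.isfinite(loggeo)
    if not ref.any():
        raise PipelineError("no gene has all counts > 0; cannot estimate "
                            "size factors")
    ratios = x[ref] / np.exp(loggeo[ref])[:, None]
    s = np.median(ratios, axis=0)
    if np.any(s <= 0):
        raise PipelineError("non-positive size factor")
    s = s / np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=counts.columns, name="size_factor")


def independent_filter(counts: pd.DataFrame, size_factors: pd.Series,
                       mean_quantile: float = 0.4) -> pd.DataFrame:
    """Drop genes whose mean normalized count falls below the given quantile
    of that statistic across genes. Ties at the cutoff are retained. The
    statistic never sees the class labels, so the filter is label-independent
    by construction."""
    if not 0.0 <= mean_quantile < 1.0:
        raise ValueError("mean_quantile must be in [0, 1)")
    if mean_quantile == 0.0:
        return counts
    stat = (counts / size_factors).mean(axis=1)
    cut = np.quantile(stat.to_numpy(), mean_quantile)
    return counts.loc[(stat >= cut).to_numpy()]


# ---------------------------------------------------------------------------
# dispersion trend + VST


@dataclass
class DispersionTrend:
    """Parametric NB dispersion trend alpha(mu) = a1 / mu + a0."""
    a0: float
    a1: float

    def __call__(self, mu):
        return self.a1 / np.maximum(np.asarray(mu, dtype=float), 1e-8) + self.a0


def fit_dispersion_trend(counts: pd.DataFrame, size_factors: pd.Series,
                         min_mean: float = 5.0) -> DispersionTrend:
    """Fit the trend by robust regression of per-gene method-of-moments
    dispersions on 1/mean.

    The per-gene estimate is ``max(0, (var - mean) / mean^2)`` on normalized
    counts; genes with mean below ``min_mean`` are excluded from the fit.
    Negative fitted coefficients are clipped at zero (with a warning), which
    downstream triggers the log2 fallback transform if a0 hits zero.
    """
    norm = (counts / size_factors).to_numpy(dtype=float)
    m = norm.mean(axis=1)
    v = norm.var(axis=1, ddof=1)
    use = m > min_mean
    if use.sum() < 10:
        raise PipelineError("too few genes to fit a dispersion trend")
    disp = np.maximum(0.0, (v[use] - m[use]) / m[use] ** 2)
    X = sm.add_constant(1.0 / m[use])
    fit = sm.RLM(disp, X, M=sm.robust.norms.HuberT()).fit()
    a0, a1 = float(fit.params[0]), float(fit.params[1])
    if a0 < 0 or a1 < 0:
        warnings.warn("negative fitted dispersion trend coefficient; clipped")
        a0, a1 = max(a0, 0.0), max(a1, 0.0)
    return DispersionTrend(a0=a0, a1=a1)


def vst(counts: pd.DataFrame, size_factors: pd.Series,
        dispersion_trend: DispersionTrend) -> pd.DataFrame:
    """Closed-form variance stabilizing transform for the NB trend.

    For normalized counts n and trend alpha(mu) = a1/mu + a0,

        v(n) = log2( (1 + a1 + 2 a0 n + 2 sqrt(a0 n (1 + a1 + a0 n)))
                     / (4 a0) )

    which is monotone in n and approaches log2(n) + const for large n.
    Falls back to log2(n + 1) when a0 <= 0 (no shot-noise-free asymptote).
    """
    norm = counts / size_factors
    a0, a1 = dispersion_trend.a0, dispersion_trend.a1
    if a0 <= 0:
        warnings.warn("dispersion trend a0 <= 0; falling back to log2(n+1)")
        out = np.log2(norm + 1.0)
        out.attrs["transform_tag"] = "log2(norm+1)"
        return out
    n = norm.to_numpy(dtype=float)
    val = np.log2((1.0 + a1 + 2.0 * a0 * n
                   + 2.0 * np.sqrt(a0 * n * (1.0 + a1 + a0 * n)))
                  / (4.0 * a0))
    out = pd.DataFrame(val, index=counts.index, columns=counts.columns)
    out.attrs["transform_tag"] = "vst"
    return out


# ---------------------------------------------------------------------------
# sample-level correction


def exclude_small_sites(counts: pd.DataFrame, metadata: pd.DataFrame,
                        min_controls: int = 2):
    """Drop every sample from sites with fewer than ``min_controls`` control
    samples (their batch effect cannot be anchored on controls).

    Returns ``(counts, metadata, removed_per_site)``.
    """
    ctrl = metadata["label"] == "control"
    ctrl_per_site = metadata.loc[ctrl, "site"].value_counts()
    n_ctrl = metadata["site"].map(ctrl_per_site).fillna(0)
    bad_sites = sorted(set(metadata.loc[(n_ctrl < min_controls).to_numpy(), "site"]))
    removed = {s: int((metadata["site"] == s).sum()) for s in bad_sites}
    keep = ~metadata["site"].isin(bad_sites)
    if not keep.any():
        raise PipelineError("small-site exclusion removed every sample")
    for s, k in removed.items():
        log.info("excluding site %s (%d samples, <%d controls)", s, k, min_controls)
    return counts.loc[:, keep.to_numpy()], metadata.loc[keep], removed


def remove_site_batch(expr: pd.DataFrame, metadata: pd.DataFrame,
                      cross_fit: bool = True):
    """Estimate per-gene site offsets on control samples and subtract them
    from all samples.

    Site is sum-to-zero coded so the per-site offset is identified relative
    to the mean control level. Because the estimation uses the class labels
    (controls only), naively subtracting each site's control mean centers
    the controls exactly while cases keep the estimation noise — a
    systematic case/control variance asymmetry that a multivariate
    classifier can aggregate across genes into spurious discrimination.
    With ``cross_fit`` (the default) each control sample is therefore
    corrected with the leave-one-out offset estimated from the *other*
    controls of its site, which equalizes the residual noise between
    classes while leaving the estimator unchanged for cases. With
    ``cross_fit=False`` the literal correction is applied and per-site
    control means agree exactly after correction.

    Returns ``(corrected, offsets)`` with ``offsets`` a gene x site frame
    (full-fit estimates).
    """
    site = metadata["site"]
    ctrl = (metadata["label"] == "control").to_numpy()
    ctrl_per_site = site[ctrl].value_counts()
    zero = [s for s in site.unique() if ctrl_per_site.get(s, 0) == 0]
    if zero:
        raise PipelineError(
            f"sites {zero} have no controls; run exclude_small_sites first")
    levels = sorted(site.unique())
    Y = expr.to_numpy(dtype=float)
    # saturated controls-only fit: fitted per-site control level is the
    # per-site control mean; sum-to-zero intercept is their site average
    site_means = np.column_stack([
        Y[:, ctrl & (site == lev).to_numpy()].mean(axis=1) for lev in levels])
    grand = site_means.mean(axis=1, keepdims=True)
    off = site_means - grand                 # genes x k
    offsets = pd.DataFrame(off, index=expr.index, columns=levels)
    site_idx = np.array([levels.index(s) for s in site])
    corrected = Y - off[:, site_idx]
    if cross_fit:
        for j, lev in enumerate(levels):
            in_site_ctrl = ctrl & (site == lev).to_numpy()
            n_s = int(in_site_ctrl.sum())
            if n_s < 2:
                continue
            cols = np.flatnonzero(in_site_ctrl)
            m_s = site_means[:, j][:, None]
            loo = (n_s * m_s - Y[:, cols]) / (n_s - 1)
            # scale the leave-one-out residual so control and case
            # residual variances match exactly: a control's LOO residual
            # has variance sigma^2 * n/(n-1), a case's sigma^2 * (n+1)/n
            lam = np.sqrt(n_s * n_s - 1.0) / n_s
            corrected[:, cols] = grand + lam * (Y[:, cols] - loo)
    out = pd.DataFrame(corrected, index=expr.index, columns=expr.columns)
    out.attrs["transform_tag"] = expr.attrs.get("transform_tag", "") + "+site-removed"
    return out, offsets


def remove_covariates(expr: pd.DataFrame, metadata: pd.DataFrame,
                      covariates=("sex", "rin")) -> pd.DataFrame:
    """Residualize each gene on the given covariates (least squares on all
    samples; the disease label is not in the model).

    Categorical covariates are indicator-coded; constant covariates are
    skipped with a warning. The intercept is retained so only covariate
    structure, not overall level, is removed.
    """
    cols, names = [], []
    for cov in covariates:
        v = metadata[cov]
        if v.dtype == object or str(v.dtype) == "category":
            levels = sorted(v.unique())
            if len(levels) < 2:
                warnings.warn(f"covariate {cov} is constant; skipped")
                continue
            for lev in levels[1:]:
                cols.append((v == lev).to_numpy(dtype=float))
                names.append(f"{cov}[{lev}]")
        else:
            arr = v.to_numpy(dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"covariate {cov} has non-finite values")
            if np.ptp(arr) == 0:
                warnings.warn(f"covariate {cov} is constant; skipped")
                continue
            cols.append(arr - arr.mean())
            names.append(cov)
    if not cols:
        return expr
    C = np.column_stack(cols)
    X = np.column_stack([np.ones(len(metadata)), C])
    Y = expr.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    fitted_cov = C @ beta[1:]                # samples x genes
    out = pd.DataFrame(Y - fitted_cov.T, index=expr.index, columns=expr.columns)
    out.attrs["transform_tag"] = (expr.attrs.get("transform_tag", "")
                                  + "+" + "".join(c[0] for c in covariates)
                                  + "-removed")
    return out


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class PreprocessConfig:
    allowed_biotypes: tuple = ("protein_coding", "lincRNA")
    min_count: int = 5
    min_fraction: float = 0.10
    mean_quantile: float = 0.4
    min_controls: int = 2
    cross_fit_batch: bool = True
    covariates: tuple = ("sex", "rin")


def run_preprocess(counts: pd.DataFrame, metadata: pd.DataFrame,
                   annotation: pd.DataFrame, blacklist=(),
                   config: PreprocessConfig | None = None):
    """Run the full cascade; returns ``(expr, meta, report)``.

    ``report`` records per-stage gene/sample counts, the size factors, the
    fitted dispersion trend and the excluded sites, so a run can be audited
    stage by stage.
    """
    cfg = config or PreprocessConfig()
    report: dict = {"stages": []}

    def stage(name, c):
        report["stages"].append(
            {"stage": name, "n_genes": int(c.shape[0]), "n_samples": int(c.shape[1])})
        log.info("%s: %d genes x %d samples", name, *c.shape)

    stage("input", counts)
    counts = filter_biotypes(counts, annotation, cfg.allowed_biotypes)
    stage("biotype_filter", counts)
    counts = drop_blacklist(counts, blacklist)
    stage("blacklist", counts)
    counts = filter_low_expression(counts, cfg.min_count, cfg.min_fraction)
    stage("low_expression_filter", counts)
    size_factors = estimate_size_factors(counts)
    counts = independent_filter(counts, size_factors, cfg.mean_quantile)
    stage("independent_filter", counts)
    trend = fit_dispersion_trend(counts, size_factors)
    expr = vst(counts, size_factors, trend)
    stage("vst", expr)
    expr, metadata, removed = exclude_small_sites(expr, metadata, cfg.min_controls)
    stage("site_exclusion", expr)
    expr, offsets = remove_site_batch(expr, metadata,
                                      cross_fit=cfg.cross_fit_batch)
    stage("site_batch_removal", expr)
    expr = remove_covariates(expr, metadata, cfg.covariates)
    stage("covariate_removal", expr)

    report.update({
        "size_factors": size_factors.to_dict(),
        "dispersion_trend": {"a0": trend.a0, "a1": trend.a1},
        "excluded_sites": removed,
        "transform_tag": expr.attrs.get("transform_tag", ""),
    })
    return expr, metadata, report
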
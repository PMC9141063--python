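"""Synthetic multi-site case/control RNA-seq cohort generator.

Generates gene-level negative-binomial count matrices with known ground
truth — planted differentially expressed genes, per-site batch offsets,
sex and RIN covariate effects, and library-size factors — together with a
clinical-style metadata table (disease label, site, sex, RIN, age, and
endophenotype fields) and a gene annotation table with biotypes. Every
downstream stage of the pipeline (filtering, normalization, batch removal,
differential expression, nested feature selection) can therefore be tested
against a known truth without any external data.

The count model is

    log2 mu_gi = b_g + log2(s_i) + d_{site(i)} + beta_sex * male_i
                 + beta_rin * (rin_i - 8) + lfc_g * label_i

with counts drawn as NB(mean mu_gi, dispersion alpha_g), variance
mu + alpha * mu^2, and alpha_g following the trend a1 / mu + a0 evaluated
at the gene's baseline mean (the DESeq2 mean-variance convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is structurally impossible."""


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults describe a desk-scale cohort with the 2:1 case:control
    imbalance, multi-site structure with some control-deficient sites, a
    small planted set of informative genes with modest fold changes, and
    NB counts whose dispersion follows the trend ``alpha(mu) = a1/mu + a0``.
    """

    n_cases: int = 200
    n_controls: int = 100
    n_genes: int = 2000
    n_sites: int = 10
    n_informative: int = 50
    lfc_range: tuple[float, float] = (0.1, 0.4)
    batch_sd: float = 0.15
    beta_sex: float = 0.2
    beta_rin: float = 0.05
    libsize_log_sd: float = 0.5
    dispersion_a0: float = 0.2
    dispersion_a1: float = 1.5
    baseline_mean_log_range: tuple[float, float] = (3.0, 9.0)
    frac_zero_informative_sites: float = 0.15
    frac_protein_coding: float = 0.70
    frac_lincrna: float = 0.20
    age_linked_signal: bool = False
    gene_specific_batch: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ConfigurationError("need at least 2 sites")
        if self.n_informative > self.n_genes:
            raise ConfigurationError("n_informative exceeds n_genes")
        if self.n_informative < 0 or self.n_genes < 1:
            raise ConfigurationError("gene counts must be non-negative")
        if self.lfc_range[0] > self.lfc_range[1] or self.lfc_range[0] < 0:
            raise ConfigurationError("lfc_range must satisfy 0 <= min <= max")
        if self.dispersion_a0 < 0 or self.dispersion_a1 < 0:
            raise ConfigurationError("dispersion trend parameters must be >= 0")
        if self.n_sites > self.n_cases + self.n_controls:
            raise ConfigurationError("more sites than samples")
        if not 0.0 <= self.frac_zero_informative_sites < 1.0:
            raise ConfigurationError("frac_zero_informative_sites in [0, 1)")
        if self.frac_protein_coding + self.frac_lincrna > 1.0:
            raise ConfigurationError("biotype fractions exceed 1")

    @classmethod
    def ppmi_scale(cls, n_genes: int = 2000, **kw) -> "SimConfig":
        """Cohort with the published study's sample structure.

        390 cases, 189 controls, 25 clinical sites with a fraction lacking
        enough controls for batch estimation.
        """
        return cls(n_cases=390, n_controls=189, n_sites=25,
                   frac_zero_informative_sites=0.16, n_genes=n_genes, **kw)


@dataclass
class TruthSet:
    """Ground truth behind a simulated cohort."""

    informative_gene_ids: set[str]
    true_lfc: pd.Series            # gene -> signed log2 fold change (0 for null genes)
    site_offsets: pd.Series | pd.DataFrame  # site (or site x gene) log2 offsets
    true_size_factors: pd.Series   # sample -> positive factor

    def to_json(self, path) -> None:
        obj = {
            "informative_gene_ids": sorted(self.informative_gene_ids),
            "true_lfc": self.true_lfc.to_dict(),
            "site_offsets": (self.site_offsets.to_dict()
                             if isinstance(self.site_offsets, pd.Series)
                             else {c: self.site_offsets[c].to_dict()
                                   for c in self.site_offsets.columns}),
            "true_size_factors": self.true_size_factors.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def _allocate(total: int, weights: np.ndarray, minimum: int) -> np.ndarray:
    """Integer allocation of ``total`` over groups, proportional to
    ``weights`` with a per-group minimum (largest-remainder rounding)."""
    k = len(weights)
    if total < minimum * k:
        raise ConfigurationError(
            f"cannot allocate {total} items over {k} groups (min {minimum})")
    base = np.full(k, minimum)
    rest = total - minimum * k
    ideal = rest * weights / weights.sum()
    counts = np.floor(ideal).astype(int)
    short = rest - counts.sum()
    order = np.argsort(-(ideal - counts), kind="stable")
    counts[order[:short]] += 1
    return base + counts


def assign_sites(labels: np.ndarray, n_sites: int,
                 frac_deficient_sites: float, seed: int) -> np.ndarray:
    """Assign each sample a site, with some sites control-deficient.

    A fraction of sites (``frac_deficient_sites``) receive fewer than two
    control samples (zero or one), emulating clinical sites where the site
    batch effect cannot be estimated from controls; all other sites are
    guaranteed at least two controls. Within the remaining sites, cases and
    controls are allocated proportionally to site size, so site membership
    carries (essentially) no information about the label — sites recruit
    both groups at the cohort ratio.

    Parameters
    ----------
    labels : array of 0/1, 1 = case.
    """
    labels = np.asarray(labels)
    if n_sites < 2:
        raise ConfigurationError("need at least 2 sites")
    rng = np.random.default_rng(seed)
    n = len(labels)
    n_cases = int((labels == 1).sum())
    n_controls = n - n_cases
    n_deficient = max(1, round(frac_deficient_sites * n_sites)) \
        if frac_deficient_sites > 0 else 0
    n_normal = n_sites - n_deficient
    if n_normal < 1:
        raise ConfigurationError("every site control-deficient")
    if n_cases < n_sites:
        raise ConfigurationError("fewer cases than sites")

    sites = np.array([f"site{k:02d}" for k in range(n_sites)])
    normal, deficient = sites[:n_normal], sites[n_normal:]
    # site size weights: moderately uneven, like real multi-site recruitment
    w = rng.dirichlet(np.full(n_sites, 5.0))
    w_norm, w_def = w[:n_normal], w[n_normal:]

    # deficient sites: a handful of cases each, zero or one control
    def_ctrl = (rng.random(n_deficient) < 0.5).astype(int) if n_deficient else \
        np.zeros(0, int)
    if def_ctrl.sum() > max(n_controls - 2 * n_normal, 0):
        def_ctrl[:] = 0
    def_cases = _allocate(min(n_cases - n_normal,
                              max(n_deficient, int(round(w_def.sum() * n_cases)))),
                          w_def, 1) if n_deficient else np.zeros(0, int)

    ctrl_rest = n_controls - int(def_ctrl.sum())
    case_rest = n_cases - int(def_cases.sum())
    if ctrl_rest < 2 * n_normal:
        raise ConfigurationError(
            f"{n_controls} controls cannot give {n_normal} sites >=2 controls each")
    norm_ctrl = _allocate(ctrl_rest, w_norm, 2)
    norm_cases = _allocate(case_rest, w_norm, 1)

    out = np.empty(n, dtype=object)
    ctrl_idx = rng.permutation(np.flatnonzero(labels == 0))
    case_idx = rng.permutation(np.flatnonzero(labels == 1))
    pos = 0
    for s, k in zip(normal, norm_ctrl):
        out[ctrl_idx[pos:pos + k]] = s
        pos += k
    for s, k in zip(deficient, def_ctrl):
        out[ctrl_idx[pos:pos + k]] = s
        pos += k
    pos = 0
    for s, k in zip(normal, norm_cases):
        out[case_idx[pos:pos + k]] = s
        pos += k
    for s, k in zip(deficient, def_cases):
        out[case_idx[pos:pos + k]] = s
        pos += k
    return out


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def generate_cohort(config: SimConfig):
    """Simulate a cohort; returns ``(counts, metadata, annotation, truth)``.

    counts : DataFrame (genes x samples, integer)
    metadata : DataFrame indexed by sample id with columns label, site, sex,
        rin, age, age_class, moca_class, rbd, motor_class, smell_class
    annotation : DataFrame indexed by gene id with columns symbol, biotype
    truth : TruthSet
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cases + cfg.n_controls
    sample_ids = [f"S{i:04d}" for i in range(n)]
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]

    label = np.zeros(n, dtype=int)
    label[rng.choice(n, size=cfg.n_cases, replace=False)] = 1

    site = assign_sites(label, cfg.n_sites, cfg.frac_zero_informative_sites,
                        seed=int(rng.integers(2**31)))

    # clinical covariates: Gender ~64% male in both groups, age ~62+-10 (PD)
    # and 61+-11 (HC), RIN ~ N(8, 1.7) truncated to [1, 10]
    male = rng.random(n) < 0.64
    rin = _truncnorm(rng, 8.0, 1.7, 1.0, 10.0, n)
    age = np.where(label == 1, rng.normal(62, 10, n), rng.normal(61, 11, n))
    age = np.clip(age, 30, 90)

    # endophenotype fields from case/control marginal frequencies,
    # independent of expression
    p_moca = np.where(label == 1, 0.33, 0.005)
    moca_class = np.where(rng.random(n) < p_moca, "CI", "normal")
    rbd = np.where(rng.random(n) < np.where(label == 1, 0.37, 0.20), "yes", "no")
    motor = np.where(rng.random(n) < np.where(label == 1, 0.70, 0.13), "TD", "PIGD")
    smell = np.where(rng.random(n) < np.where(label == 1, 0.35, 0.85),
                     "normosmia", "hyposmia")

    metadata = pd.DataFrame({
        "label": np.where(label == 1, "case", "control"),
        "site": site,
        "sex": np.where(male, "M", "F"),
        "rin": rin,
        "age": age,
        "age_class": np.where(age >= 56, ">=56", "<56"),
        "moca_class": moca_class,
        "rbd": rbd,
        "motor_class": motor,
        "smell_class": smell,
    }, index=pd.Index(sample_ids, name="sample_id"))

    # gene-level truth
    lo, hi = cfg.baseline_mean_log_range
    baseline = rng.uniform(lo, hi, cfg.n_genes)
    true_lfc = np.zeros(cfg.n_genes)
    info_idx = rng.choice(cfg.n_genes, size=cfg.n_informative, replace=False)
    signs = rng.choice([-1.0, 1.0], size=cfg.n_informative)
    true_lfc[info_idx] = signs * rng.uniform(*cfg.lfc_range, cfg.n_informative)

    site_levels = sorted(set(site))
    if cfg.gene_specific_batch:
        offsets = pd.DataFrame(
            rng.normal(0, cfg.batch_sd, (cfg.n_genes, len(site_levels))),
            index=gene_ids, columns=site_levels)
        batch = offsets[site].to_numpy()
    else:
        offsets = pd.Series(rng.normal(0, cfg.batch_sd, len(site_levels)),
                            index=site_levels)
        batch = offsets[site].to_numpy()[None, :]

    sf = 2.0 ** rng.normal(0, cfg.libsize_log_sd, n)

    effect = true_lfc[:, None] * label[None, :]
    if cfg.age_linked_signal:
        # late-onset cases carry a stronger version of the planted signal
        scale = np.where(age >= 56, 1.4, 0.5)
        effect = effect * scale[None, :]

    log2_mu = (baseline[:, None] + np.log2(sf)[None, :] + batch
               + cfg.beta_sex * male[None, :]
               + cfg.beta_rin * (rin - 8.0)[None, :]
               + effect)
    mu = 2.0 ** np.clip(log2_mu, -20, 30)

    alpha = cfg.dispersion_a1 / (2.0 ** baseline) + cfg.dispersion_a0
    counts = _nb_draw(rng, mu, alpha[:, None])

    counts = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                          columns=sample_ids)

    # biotypes: planted genes are protein coding so they survive the biotype
    # filter; the rest drawn from (protein_coding, lincRNA, other) marginals
    other = 1.0 - cfg.frac_protein_coding - cfg.frac_lincrna
    biotype = rng.choice(
        ["protein_coding", "lincRNA", "rRNA", "pseudogene"],
        size=cfg.n_genes,
        p=[cfg.frac_protein_coding, cfg.frac_lincrna, other / 2, other / 2])
    biotype[info_idx] = "protein_coding"
    annotation = pd.DataFrame(
        {"symbol": [g.replace("G", "SYM") for g in gene_ids],
         "biotype": biotype},
        index=pd.Index(gene_ids, name="gene_id"))

    truth = TruthSet(
        informative_gene_ids={gene_ids[i] for i in info_idx},
        true_lfc=pd.Series(true_lfc, index=gene_ids),
        site_offsets=offsets,
        true_size_factors=pd.Series(sf, index=sample_ids),
    )
    return counts, metadata, annotation, truth


def _nb_draw(rng, mu, alpha):
    """NB(mu, alpha) with Var = mu + alpha*mu^2 via the gamma-Poisson mixture.

    alpha == 0 degenerates to Poisson(mu).
    """
    mu = np.asarray(mu, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    safe = np.where(alpha > 0, alpha, 1.0)
    lam = np.where(alpha > 0, rng.gamma(1.0 / safe, safe * mu), mu)
    return rng.poisson(lam).astype(np.int64)


def config_to_dict(cfg: SimConfig) -> dict:
    return asdict(cfg)
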
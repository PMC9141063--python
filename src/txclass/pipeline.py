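"""End-to-end pipeline orchestration.

Runs simulate/load -> preprocess -> differential expression -> nested CV ->
stability -> evaluation as one reproducible unit. A single master seed
fans out deterministically to every stage; the run directory receives the
preprocessing report, DE table, AUC curve, selection-frequency table,
metric and endophenotype reports, and a manifest with the config echo,
derived seeds, stage durations and input checksums.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as tio
from ._seeds import derive_seed
from .diffexp import NegativeBinomialDE
from .nested_cv import CvConfig, NestedCVClassifier, de_baseline
from .preprocess import PreprocessConfig, run_preprocess
from .ranking import RfConfig
from .simulate import SimConfig, generate_cohort
from .stability import annotate_with_de, frequent_genes, selection_histogram

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full pipeline configuration.

    Either ``counts``/``metadata``/``annotation`` paths are given, or
    ``simulate`` is set and a synthetic cohort is generated in-run.
    """
    outdir: str = "run"
    counts: str | None = None
    metadata: str | None = None
    annotation: str | None = None
    blacklist: str | None = None
    simulate: dict | None = None
    preprocess: dict = field(default_factory=dict)
    rf: dict = field(default_factory=dict)
    cv: dict = field(default_factory=dict)
    alpha: float = 0.05
    stability_threshold: float = 0.70
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate_paths(self) -> None:
        if self.simulate is None:
            for name in ("counts", "metadata", "annotation"):
                p = getattr(self, name)
                if p is None:
                    raise FileNotFoundError(f"input '{name}' not configured "
                                            "and simulation not requested")
                if not Path(p).exists():
                    raise FileNotFoundError(f"missing input: {p}")
        if self.blacklist and not Path(self.blacklist).exists():
            raise FileNotFoundError(f"missing input: {self.blacklist}")


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory."""
    config.validate_paths()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {k: v for k, v in vars(config).items()},
                      "seeds": {}, "durations_s": {}, "checksums": {}}
    t0 = time.time()

    def tick(stage):
        manifest["durations_s"][stage] = round(time.time() - t0, 3)

    try:
        if config.simulate is not None:
            sim_seed = derive_seed(config.seed, "simulate")
            manifest["seeds"]["simulate"] = sim_seed
            sim_cfg = SimConfig(**{**config.simulate, "seed": sim_seed})
            counts, metadata, annotation, truth = generate_cohort(sim_cfg)
            tio.write_counts_tsv(counts, out / "counts.tsv")
            metadata.to_csv(out / "metadata.tsv", sep="\t")
            annotation.to_csv(out / "annotation.tsv", sep="\t")
            truth.to_json(out / "truth.json")
        else:
            counts = tio.read_counts_tsv(config.counts)
            metadata = tio.read_metadata(config.metadata)
            annotation = tio.read_annotation(config.annotation)
            for name in ("counts", "metadata", "annotation", "blacklist"):
                p = getattr(config, name)
                if p:
                    manifest["checksums"][name] = _checksum(p)
        blacklist = (tio.read_blacklist(config.blacklist)
                     if config.blacklist else set())
        tick("inputs")
    except Exception as e:
        raise RuntimeError(f"stage 'inputs' failed: {e}") from e

    try:
        expr, meta, report = run_preprocess(
            counts, metadata, annotation, blacklist,
            PreprocessConfig(**config.preprocess))
        expr.to_csv(out / "expression.tsv", sep="\t")
        tio.write_json(report, out / "preprocess_report.json")
        tick("preprocess")
    except Exception as e:
        raise RuntimeError(f"stage 'preprocess' failed: {e}") from e

    try:
        raw_sub = counts.loc[:, meta.index]
        de = NegativeBinomialDE(raw_sub, meta).fit()
        de.to_tsv(out / "de_table.tsv")
        tick("diffexp")
    except Exception as e:
        raise RuntimeError(f"stage 'diffexp' failed: {e}") from e

    try:
        cv_seed = derive_seed(config.seed, "nested_cv")
        manifest["seeds"]["nested_cv"] = cv_seed
        model = NestedCVClassifier(expr, meta, RfConfig(**config.rf),
                                   CvConfig(**config.cv))
        result = model.fit(seed=cv_seed)
        result.records.to_csv(out / "prediction_records.tsv", sep="\t",
                              index=False)
        curve = result.auc_curve
        curve.to_json(out / "auc_curve.json")
        curve.to_frame().to_csv(out / "auc_curve.tsv", sep="\t", index=False)
        tick("nested_cv")
    except Exception as e:
        raise RuntimeError(f"stage 'nested_cv' failed: {e}") from e

    try:
        result.rep_importances.to_csv(out / "rep_importances.tsv", sep="\t")
        freq = result.selection_frequency()
        freq = annotate_with_de(freq, de.table, config.alpha)
        freq.to_csv(out / "selection_frequency.tsv", sep="\t")
        selection_histogram(freq).to_csv(out / "selection_histogram.tsv",
                                         sep="\t")
        pd.Series(frequent_genes(freq, config.stability_threshold),
                  name="gene_id").to_csv(out / "frequent_genes.tsv",
                                         sep="\t", index=False)
        tick("stability")
    except Exception as e:
        raise RuntimeError(f"stage 'stability' failed: {e}") from e

    try:
        result.metric_report().to_csv(out / "metrics.tsv", sep="\t")
        result.endophenotype_report().to_csv(out / "endophenotypes.tsv",
                                             sep="\t", index=False)
        base_seed = derive_seed(config.seed, "de_baseline")
        manifest["seeds"]["de_baseline"] = base_seed
        try:
            auc = de_baseline(expr, meta, counts=raw_sub,
                              alpha=config.alpha, split_seed=base_seed)
            manifest["de_baseline_auc"] = float(auc)
        except ValueError as e:
            manifest["de_baseline_auc"] = None
            log.warning("DE baseline skipped: %s", e)
        (out / "summary.txt").write_text(result.summary() + "\n")
        tick("evaluate")
    except Exception as e:
        raise RuntimeError(f"stage 'evaluate' failed: {e}") from e

    manifest["c_star"] = int(curve.c_star)
    manifest["median_auc_at_c_star"] = float(curve.median[curve.c_star])
    tio.write_json(manifest, out / "manifest.json")
    return out
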
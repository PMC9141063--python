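"""Selection-frequency analysis of repeatedly selected genes.

Across R repetitions of the cross-validated feature selection, each
repetition contributes one top-C gene set. Counting how often each gene
appears measures the stability of the signature; genes selected in at
least 70% of repetitions form the reported frequent-gene list.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def selection_frequency(top_sets, R: int | None = None,
                        importances=None) -> pd.DataFrame:
    """Tally gene membership over R top-C sets.

    Parameters
    ----------
    top_sets : sequence of R gene-id collections, each of the same size C.
    importances : optional sequence of R mappings/Series gene -> importance,
        used to report each gene's mean importance in the repetitions where
        it was selected.

    Returns a frame indexed by gene id with columns ``times_selected``,
    ``frequency`` and ``mean_importance_when_selected``, sorted by
    (frequency desc, mean importance desc, gene id asc). Only genes selected
    at least once appear.
    """
    top_sets = [list(s) for s in top_sets]
    if R is None:
        R = len(top_sets)
    if len(top_sets) != R:
        raise ValueError(f"expected {R} sets, got {len(top_sets)}")
    if not top_sets:
        raise ValueError("no selection sets given")
    C = len(top_sets[0])
    for i, s in enumerate(top_sets):
        if len(s) != C or len(set(s)) != C:
            raise ValueError(f"set {i} does not contain exactly C={C} "
                             "distinct genes")
    counts: dict = {}
    imp_sum: dict = {}
    for rep, s in enumerate(top_sets):
        imp = importances[rep] if importances is not None else None
        for g in s:
            counts[g] = counts.get(g, 0) + 1
            if imp is not None:
                imp_sum[g] = imp_sum.get(g, 0.0) + float(imp[g])
    genes = sorted(counts)
    times = np.array([counts[g] for g in genes])
    mean_imp = np.array([imp_sum.get(g, np.nan) / counts[g] for g in genes]) \
        if importances is not None else np.full(len(genes), np.nan)
    table = pd.DataFrame({
        "times_selected": times,
        "frequency": times / R,
        "mean_importance_when_selected": mean_imp,
    }, index=pd.Index(genes, name="gene_id"))
    table = table.sort_values(
        ["frequency", "mean_importance_when_selected", "gene_id"],
        ascending=[False, False, True], kind="mergesort",
        na_position="last")
    return table


def frequent_genes(table: pd.DataFrame, threshold: float = 0.70) -> list:
    """Genes selected in at least ``threshold`` of repetitions (inclusive),
    in table order."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    return list(table.index[table["frequency"] >= threshold])


def selection_histogram(table: pd.DataFrame) -> pd.Series:
    """Number of genes by times-selected (the stability histogram)."""
    return table["times_selected"].value_counts().sort_index()


def annotate_with_de(table: pd.DataFrame, de_table: pd.DataFrame,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Join DE direction onto the frequency table.

    Adds ``lfc``, ``adj_p`` and a ``de_direction`` column ("up", "down" or
    "ns"); genes selected by the classifier but not differentially
    expressed are thereby flagged.
    """
    out = table.join(de_table[["lfc", "adj_p"]], how="left")
    sig = out["adj_p"] < alpha
    out["de_direction"] = np.where(sig & (out["lfc"] > 0), "up",
                                   np.where(sig & (out["lfc"] < 0), "down",
                                            "ns"))
    return out


def plot_selection_histogram(table: pd.DataFrame, ax=None):
    """Bar plot of the stability histogram (genes by times selected)."""
    import matplotlib.pyplot as plt

    hist = selection_histogram(table)
    if ax is None:
        _, ax = plt.subplots()
    ax.bar(hist.index, hist.to_numpy())
    ax.set_xlabel("times selected")
    ax.set_ylabel("number of genes")
    return ax
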
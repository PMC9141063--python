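"""Reading and writing the pipeline's on-disk formats.

Counts travel as TSV (genes x samples, first column gene id) or
MatrixMarket (.mtx plus row/column id files); metadata, annotation and all
result tables as TSV; ground truth and reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(np.int64)


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def read_counts_mtx(mtx_path, gene_path, sample_path) -> pd.DataFrame:
    mat = spio.mmread(mtx_path)
    genes = Path(gene_path).read_text().split()
    samples = Path(sample_path).read_text().split()
    if sparse.issparse(mat):
        mat = mat.toarray()
    return pd.DataFrame(np.asarray(mat, dtype=np.int64),
                        index=pd.Index(genes, name="gene_id"),
                        columns=samples)


def write_counts_mtx(counts: pd.DataFrame, mtx_path, gene_path,
                     sample_path) -> None:
    spio.mmwrite(str(mtx_path), sparse.csr_matrix(counts.to_numpy()))
    Path(gene_path).write_text("\n".join(counts.index) + "\n")
    Path(sample_path).write_text("\n".join(counts.columns) + "\n")


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_blacklist(path) -> set:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_jsonify)


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
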
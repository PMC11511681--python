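"""Readers and writers for the plain-text formats used across the package.

Count matrices travel as MatrixMarket (.mtx, features x cells, 10x-style)
with TSV sidecars for feature and cell ids, or as dense TSV.  Videos are
multi-page TIFF.  Ground-truth records are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .expression import ExpressionMatrix


def write_mtx(m: ExpressionMatrix, prefix) -> None:
    """Write ``<prefix>.mtx`` (features x cells) plus ``<prefix>.features.tsv``,
    ``<prefix>.cells.tsv`` and ``<prefix>.metadata.tsv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(prefix) + ".mtx", sparse.csr_matrix(m.values.T))
    pd.Series(m.feature_ids).to_csv(str(prefix) + ".features.tsv",
                                    sep="\t", index=False, header=False)
    pd.Series(m.cell_ids).to_csv(str(prefix) + ".cells.tsv",
                                 sep="\t", index=False, header=False)
    m.cell_metadata.to_csv(str(prefix) + ".metadata.tsv", sep="\t")


def read_mtx(prefix, layer: str = "counts") -> ExpressionMatrix:
    prefix = Path(prefix)
    vals = spio.mmread(str(prefix) + ".mtx").toarray().T
    features = pd.read_csv(str(prefix) + ".features.tsv", sep="\t",
                           header=None)[0].to_numpy()
    cells = pd.read_csv(str(prefix) + ".cells.tsv", sep="\t",
                        header=None)[0].to_numpy()
    meta_path = Path(str(prefix) + ".metadata.tsv")
    meta = pd.read_csv(meta_path, sep="\t", index_col=0) if meta_path.exists() else None
    if layer == "counts":
        vals = np.rint(vals).astype(np.int64)
    return ExpressionMatrix(vals, cells, features, layer=layer, cell_metadata=meta)


def write_tsv(m: ExpressionMatrix, path) -> None:
    """Dense cells x features TSV with metadata written alongside."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(m.values, index=m.cell_ids, columns=m.feature_ids).to_csv(
        path, sep="\t")
    m.cell_metadata.to_csv(path.with_suffix(".metadata.tsv"), sep="\t")


def read_tsv(path, layer: str = "counts") -> ExpressionMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_path = path.with_suffix(".metadata.tsv")
    meta = pd.read_csv(meta_path, sep="\t", index_col=0) if meta_path.exists() else None
    vals = df.to_numpy()
    if layer == "counts":
        vals = np.rint(vals).astype(np.int64)
    return ExpressionMatrix(vals, df.index.to_numpy(), df.columns.to_numpy(),
                            layer=layer, cell_metadata=meta)


def write_video(frames: np.ndarray, path) -> None:
    """Multi-page TIFF, one page per frame (float32)."""
    import tifffile

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(frames, dtype=np.float32))


def read_video(path) -> np.ndarray:
    import tifffile

    return np.asarray(tifffile.imread(path), dtype=np.float64)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_truth(truth: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(truth, fh, cls=_NumpyEncoder, indent=1)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
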
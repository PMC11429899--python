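"""Matrix Market + TSV count I/O (CellRanger-style triplet layout)."""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["write_counts", "read_counts"]


def write_counts(adata: ad.AnnData, path) -> None:
    """Write ``matrix.mtx`` (genes x nuclei), ``genes.tsv`` and
    ``barcodes.tsv`` (with the obs metadata columns) into a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    X = adata.X
    X = sp.csr_matrix(X) if not sp.issparse(X) else X
    scipy.io.mmwrite(str(path / "matrix.mtx"), X.T.astype(np.int64).tocoo())
    pd.Series(adata.var_names).to_csv(path / "genes.tsv", sep="\t",
                                      index=False, header=False)
    bc = adata.obs.copy()
    bc.insert(0, "barcode", adata.obs_names)
    bc.to_csv(path / "barcodes.tsv", sep="\t", index=False)


def read_counts(path) -> ad.AnnData:
    """Read a directory written by :func:`write_counts`; lossless for
    integer counts and metadata.  Dimension mismatches raise."""
    path = Path(path)
    X = scipy.io.mmread(str(path / "matrix.mtx")).tocsr().astype(np.int64)
    genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0] \
        if (path / "genes.tsv").stat().st_size else pd.Series([], dtype=str)
    bc = pd.read_csv(path / "barcodes.tsv", sep="\t")
    if X.shape[0] != len(genes):
        raise ValueError(f"matrix has {X.shape[0]} genes but genes.tsv "
                         f"lists {len(genes)}")
    if X.shape[1] != len(bc):
        raise ValueError(f"matrix has {X.shape[1]} nuclei but barcodes.tsv "
                         f"lists {len(bc)}")
    obs = bc.set_index("barcode")
    obs.index = obs.index.astype(str)
    obs.index.name = None
    for col in ("sample", "age", "genotype"):
        if col in obs:
            obs[col] = pd.Categorical(obs[col])
    return ad.AnnData(X=X.T.tocsr(), obs=obs,
                      var=pd.DataFrame(index=genes.astype(str)))
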
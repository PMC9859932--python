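"""Expression-matrix container, readers/writers, normalization and QC.

Matrices are stored cells × genes internally.  Two on-disk layouts are
supported: a dense TSV (genes in rows, cells in columns — the common
export convention) and a Matrix Market triplet with ``genes.tsv`` /
``barcodes.tsv`` sidecar files (the 10x convention).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = ["ExpressionMatrix", "read_matrix", "write_matrix", "normalize", "qc_mito"]


@dataclass
class ExpressionMatrix:
    """Cells × genes expression values with optional per-cell labels.

    ``values`` is a DataFrame indexed by cell id with gene symbols as
    columns.  ``class_labels`` (cell class / cell type) and ``group_labels``
    (subclass / batch, used to keep groups intact in cross-validation) are
    Series aligned to the cell index.
    """

    values: pd.DataFrame
    class_labels: pd.Series | None = None
    group_labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.shape[0] < 1:
            raise ValueError("expression matrix needs at least one cell")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate gene symbols: {dups}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        for name in ("class_labels", "group_labels"):
            lab = getattr(self, name)
            if lab is not None:
                lab = pd.Series(lab).reindex(self.values.index)
                if lab.isna().any():
                    raise ValueError(f"{name} missing for some cells")
                setattr(self, name, lab)

    # ---- views ---------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def genes(self) -> list:
        return list(self.values.columns)

    @property
    def cell_ids(self) -> list:
        return list(self.values.index)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.columns]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return replace(self, values=self.values[list(genes)])

    def subset_cells(self, cell_ids) -> "ExpressionMatrix":
        sub = self.values.loc[list(cell_ids)]
        return ExpressionMatrix(
            sub,
            None if self.class_labels is None else self.class_labels.loc[sub.index],
            None if self.group_labels is None else self.group_labels.loc[sub.index],
        )

    def cells_of_class(self, class_id) -> "ExpressionMatrix":
        if self.class_labels is None:
            raise ValueError("matrix has no class labels")
        keep = self.class_labels.index[self.class_labels == class_id]
        if len(keep) == 0:
            raise KeyError(f"no cells labeled {class_id!r}")
        return self.subset_cells(keep)

    # ---- interop -------------------------------------------------------
    def to_anndata(self):
        import anndata

        obs = pd.DataFrame(index=self.values.index)
        if self.class_labels is not None:
            obs["cell_class"] = self.class_labels
        if self.group_labels is not None:
            obs["group"] = self.group_labels
        return anndata.AnnData(X=self.values.to_numpy(), obs=obs,
                               var=pd.DataFrame(index=self.values.columns))

    @classmethod
    def from_anndata(cls, adata) -> "ExpressionMatrix":
        x = adata.X
        if scipy.sparse.issparse(x):
            x = x.toarray()
        values = pd.DataFrame(np.asarray(x), index=adata.obs_names,
                              columns=adata.var_names)
        cls_lab = adata.obs["cell_class"] if "cell_class" in adata.obs else None
        grp_lab = adata.obs["group"] if "group" in adata.obs else None
        return cls(values, cls_lab, grp_lab)


def _dedupe_genes(symbols) -> list:
    seen: dict = {}
    out = []
    for s in symbols:
        if s in seen:
            seen[s] += 1
            new = f"{s}.{seen[s]}"
            logger.warning("duplicate gene symbol %s renamed to %s", s, new)
            out.append(new)
        else:
            seen[s] = 0
            out.append(s)
    return out


def read_matrix(path, format: str = "dense_tsv") -> ExpressionMatrix:
    """Read an expression matrix from disk.

    ``dense_tsv``: genes × cells TSV with gene symbols in the first column
    and cell ids in the header (transposed on load).  ``mtx``: a directory
    with ``matrix.mtx`` (genes × cells triplet), ``genes.tsv`` and
    ``barcodes.tsv``.
    """
    path = Path(path)
    if format == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.size == 0:
            raise ValueError(f"{path}: empty matrix")
        bad = df.apply(lambda col: pd.to_numeric(col, errors="coerce")).isna()
        if bad.any().any():
            row = int(np.argmax(bad.to_numpy().any(axis=1)))
            raise ValueError(f"{path}: non-numeric entry at data line {row + 1}")
        df.index = _dedupe_genes(df.index)
        return ExpressionMatrix(df.T.astype(float))
    if format == "mtx":
        mat = scipy.io.mmread(path / "matrix.mtx")
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None).iloc[:, -1]
        barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None).iloc[:, 0]
        mat = scipy.sparse.coo_matrix(mat)
        if mat.shape != (len(genes), len(barcodes)):
            raise ValueError(
                f"{path}: matrix is {mat.shape} but sidecars declare "
                f"{len(genes)} genes x {len(barcodes)} barcodes"
            )
        values = pd.DataFrame(
            mat.toarray().T, index=list(barcodes), columns=_dedupe_genes(genes)
        )
        if values.size == 0:
            raise ValueError(f"{path}: empty matrix")
        return ExpressionMatrix(values.astype(float))
    raise ValueError(f"unknown format {format!r}")


def write_matrix(m: ExpressionMatrix, path, format: str = "dense_tsv") -> None:
    path = Path(path)
    if format == "dense_tsv":
        m.values.T.to_csv(path, sep="\t")
    elif format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        sparse = scipy.sparse.coo_matrix(m.values.to_numpy().T)
        scipy.io.mmwrite(path / "matrix.mtx", sparse)
        pd.Series(m.genes).to_csv(path / "genes.tsv", sep="\t",
                                  header=False, index=False)
        pd.Series(m.cell_ids).to_csv(path / "barcodes.tsv", sep="\t",
                                     header=False, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def normalize(m: ExpressionMatrix, mode: str = "rpm_log2") -> ExpressionMatrix:
    """Reads-per-million scaling followed by a log transform.

    ``rpm_log2`` (reference convention) applies log2(RPM + 1); ``rpm_ln``
    (query convention) applies ln(RPM + 1); ``none`` returns the input.
    """
    if mode == "none":
        return m
    if mode not in ("rpm_log2", "rpm_ln"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    x = m.values.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("normalization expects non-negative raw counts")
    totals = x.sum(axis=1)
    zero = totals == 0
    if zero.any():
        cells = [m.cell_ids[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"cells with zero total counts: {cells}")
    rpm = x / totals[:, None] * 1e6
    out = np.log2(rpm + 1.0) if mode == "rpm_log2" else np.log1p(rpm)
    return replace(m, values=pd.DataFrame(out, index=m.values.index,
                                          columns=m.values.columns))


def qc_mito(m: ExpressionMatrix, mito_prefix: str = "MT-",
            ceiling: float = 0.10) -> ExpressionMatrix:
    """Drop cells whose mitochondrial-count fraction exceeds *ceiling*."""
    mito = [g for g in m.genes if str(g).startswith(mito_prefix)]
    if not mito:
        warnings.warn(f"no genes match mitochondrial prefix {mito_prefix!r}; "
                      "QC is a no-op")
        return m
    x = m.values.to_numpy(dtype=float)
    totals = x.sum(axis=1)
    frac = np.zeros_like(totals)
    nonzero = totals > 0
    frac[nonzero] = m.values[mito].to_numpy().sum(axis=1)[nonzero] / totals[nonzero]
    keep = frac <= ceiling
    logger.info("mito QC dropped %d / %d cells", int((~keep).sum()), m.n_cells)
    if keep.all():
        return m
    if not keep.any():
        raise ValueError("mito QC would drop every cell")
    return m.subset_cells([cid for cid, k in zip(m.cell_ids, keep) if k])
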
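"""Expression-table input/output and pre-network transcript filtering.

Expression values are TPM (transcripts per million), genes in rows and
samples in columns. Each sample carries a condition label (e.g. a carbon
source) and a replicate index; the low-expression filter is applied per
condition so that transcripts expressed under only one condition survive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "write_expression",
    "filter_low_expression",
    "drop_constant_genes",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples TPM table plus per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
        Entries must be finite and non-negative.
    sample_meta
        DataFrame indexed by sample id with columns ``condition`` and
        ``replicate``; every sample in ``values`` must have a row.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene id(s): {dup}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample id(s): {dup}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = [
                c for c in v.columns
                if not np.issubdtype(v[c].dtype, np.number)
            ]
            raise ValueError(f"non-numeric values in column(s): {bad}")
        if not np.isfinite(arr).all():
            genes = v.index[~np.isfinite(arr).all(axis=1)].tolist()
            raise ValueError(f"non-finite values in gene(s): {genes}")
        if (arr < 0).any():
            genes = v.index[(arr < 0).any(axis=1)].tolist()
            raise ValueError(f"negative TPM values in gene(s): {genes}")
        missing = set(v.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def conditions(self) -> dict[str, list[str]]:
        """Map condition label -> ordered sample ids in that condition."""
        out: dict[str, list[str]] = {}
        for s in self.sample_ids:
            out.setdefault(str(self.sample_meta.loc[s, "condition"]), []).append(s)
        return out

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.sample_meta)

    def log2_transform(self) -> "ExpressionMatrix":
        """Return log2(TPM + 1)-transformed copy."""
        return ExpressionMatrix(np.log2(self.values + 1.0), self.sample_meta)


def read_expression(expression_path, metadata_path) -> ExpressionMatrix:
    """Read an expression table and sample metadata from TSV/CSV.

    The expression file has gene ids in the first column and a header row
    of sample ids; the metadata file has columns sample, condition,
    replicate. The delimiter is auto-detected.
    """
    values = pd.read_csv(expression_path, sep=None, engine="python", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    values.index.name = None
    values.columns.name = None
    for col in values.columns:
        if not np.issubdtype(values[col].dtype, np.number):
            bad = values.index[pd.to_numeric(values[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric cell(s) in sample column {col!r}, "
                f"gene row(s) {bad.tolist()[:5]}"
            )
    meta = pd.read_csv(metadata_path, sep=None, engine="python")
    required = {"sample", "condition", "replicate"}
    if not required.issubset(meta.columns):
        raise ValueError(
            f"metadata must have columns {sorted(required)}, got {list(meta.columns)}"
        )
    meta = meta.set_index(meta["sample"].astype(str))[["condition", "replicate"]]
    return ExpressionMatrix(values, meta)


def write_expression(m: ExpressionMatrix, expression_path, metadata_path) -> None:
    """Write the matrix and metadata as TSV in the dialect read_expression reads."""
    m.values.rename_axis("gene").to_csv(expression_path, sep="\t")
    meta = m.sample_meta.rename_axis("sample").reset_index()
    meta.to_csv(metadata_path, sep="\t", index=False)


def filter_low_expression(
    m: ExpressionMatrix,
    max_zero_fraction: float = 0.5,
    per_condition: bool = True,
) -> tuple[ExpressionMatrix, list[str]]:
    """Remove transcripts that are zero in most replicates.

    A gene is removed iff its fraction of zero-TPM samples exceeds
    ``max_zero_fraction`` in *every* condition (``per_condition=True``,
    the default) or across all samples pooled (``per_condition=False``).
    Surviving genes keep their input order. Returns the filtered matrix
    and the list of removed gene ids.
    """
    if not 0.0 <= max_zero_fraction <= 1.0:
        raise ValueError(f"max_zero_fraction must be in [0, 1], got {max_zero_fraction}")
    if m.n_genes == 0:
        raise ValueError("cannot filter an empty expression matrix")
    zero = m.values.to_numpy() == 0.0
    if per_condition:
        remove = np.ones(m.n_genes, dtype=bool)
        col_index = {s: j for j, s in enumerate(m.sample_ids)}
        for samples in m.conditions().values():
            cols = [col_index[s] for s in samples]
            frac = zero[:, cols].mean(axis=1)
            remove &= frac > max_zero_fraction
    else:
        remove = zero.mean(axis=1) > max_zero_fraction
    removed = [g for g, r in zip(m.gene_ids, remove) if r]
    kept = [g for g, r in zip(m.gene_ids, remove) if not r]
    return m.subset_genes(kept), removed


def drop_constant_genes(m: ExpressionMatrix) -> tuple[ExpressionMatrix, list[str]]:
    """Remove zero-variance genes (Pearson correlation is undefined for them)."""
    var = m.values.to_numpy().var(axis=1)
    removed = [g for g, v in zip(m.gene_ids, var) if v == 0.0]
    if removed:
        warnings.warn(
            f"dropping {len(removed)} constant gene(s): {removed[:5]}"
            + ("..." if len(removed) > 5 else ""),
            stacklevel=2,
        )
    kept = [g for g, v in zip(m.gene_ids, var) if v != 0.0]
    return m.subset_genes(kept), removed
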
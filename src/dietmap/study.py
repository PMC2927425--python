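"""Core data container for a multi-tissue expression study.

An :class:`ExpressionStudy` bundles a log2 expression matrix (genes x
samples) with per-sample metadata (tissue, diet group, replicate) and
per-gene genomic annotation (chromosome, position).  It is the root input
of every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionStudy"]

#: canonical chromosome order used for genome-ordered exports: autosomes
#: 1..19 (mouse karyotype) followed by X.
CHROMOSOME_ORDER: tuple[str, ...] = tuple(str(i) for i in range(1, 20)) + ("X",)


@dataclass
class ExpressionStudy:
    """Log2 expression matrix plus sample metadata and gene annotation.

    Parameters
    ----------
    expression:
        DataFrame of log2 expression values, genes as rows (index =
        gene ids), samples as columns (sample ids).
    samples:
        DataFrame indexed by sample id with columns ``tissue``, ``group``
        and ``replicate``.  Every expression column must be present.
    genes:
        Optional DataFrame indexed by gene id with columns ``chromosome``
        and ``position_bp``.  Only required for genome-ordered exports.
    """

    expression: pd.DataFrame
    samples: pd.DataFrame
    genes: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.expression.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if self.expression.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        if not np.isfinite(self.expression.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")
        missing = set(self.expression.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        for col in ("tissue", "group", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")
        # keep metadata aligned to, and restricted to, the matrix columns
        self.samples = self.samples.loc[list(self.expression.columns)]

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.expression.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.expression.columns

    @property
    def tissues(self) -> list[str]:
        """Tissue labels in first-appearance order."""
        return list(dict.fromkeys(self.samples["tissue"]))

    @property
    def groups(self) -> list[str]:
        """Diet group labels in first-appearance order."""
        return list(dict.fromkeys(self.samples["group"]))

    def samples_where(self, tissue: str | None = None, group: str | None = None) -> list[str]:
        """Sample ids matching a tissue and/or group."""
        mask = pd.Series(True, index=self.samples.index)
        if tissue is not None:
            mask &= self.samples["tissue"] == tissue
        if group is not None:
            mask &= self.samples["group"] == group
        return list(self.samples.index[mask])

    def subset_genes(self, gene_ids) -> "ExpressionStudy":
        """Study restricted to the given genes (order preserved)."""
        genes = None
        if self.genes is not None:
            genes = self.genes.loc[self.genes.index.intersection(gene_ids)]
        return ExpressionStudy(self.expression.loc[list(gene_ids)], self.samples.copy(), genes)

    def with_expression(self, matrix: pd.DataFrame) -> "ExpressionStudy":
        """Same metadata, new matrix (e.g. after normalization)."""
        return ExpressionStudy(matrix, self.samples.copy(), self.genes)
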
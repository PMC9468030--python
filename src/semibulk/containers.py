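"""Shared in-memory containers for count and composition data.

The pipeline moves three kinds of tables between stages: UMI count matrices
(genes x units), cell-type composition matrices (units x cell types, rows on
the simplex), and small per-unit tables.  They are kept as thin dataclasses
over numpy arrays with explicit id lists so that every stage's contract
(dimension consistency, non-negativity, row normalisation) is checked at
construction time rather than rediscovered downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Gene-id prefixes treated as mitochondrial when no explicit mask is given.
MITO_PREFIXES = ("mt-", "MT-")


def _as_str_list(ids) -> list[str]:
    return [str(i) for i in ids]


@dataclass
class CountMatrix:
    """A genes x units matrix of non-negative integer UMI counts.

    Parameters
    ----------
    gene_ids, unit_ids:
        Row and column identifiers.
    counts:
        ``(n_genes, n_units)`` array of non-negative integers.
    mito_gene_mask:
        Optional boolean array flagging mitochondrial genes.  When absent,
        genes whose id starts with one of :data:`MITO_PREFIXES` are used.
    """

    gene_ids: list[str]
    unit_ids: list[str]
    counts: np.ndarray
    mito_gene_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_ids = _as_str_list(self.gene_ids)
        self.unit_ids = _as_str_list(self.unit_ids)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x units array")
        if self.counts.shape != (len(self.gene_ids), len(self.unit_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.unit_ids)} units"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                raise ValueError("counts must be integral")
            self.counts = rounded.astype(np.int64)
        if self.mito_gene_mask is not None:
            self.mito_gene_mask = np.asarray(self.mito_gene_mask, dtype=bool)
            if self.mito_gene_mask.shape != (len(self.gene_ids),):
                raise ValueError("mito_gene_mask length must equal gene count")

    # -- derived per-unit quantities -------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def mito_mask(self, prefixes: tuple[str, ...] = MITO_PREFIXES) -> np.ndarray:
        """Boolean mitochondrial-gene mask (explicit mask or id-prefix match)."""
        if self.mito_gene_mask is not None:
            return self.mito_gene_mask
        return np.array(
            [g.startswith(prefixes) for g in self.gene_ids], dtype=bool
        )

    def umis_per_unit(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def expressed_genes_per_unit(self) -> np.ndarray:
        """Number of genes with count > 0 in each unit."""
        return (self.counts > 0).sum(axis=0)

    def mito_fraction_per_unit(
        self, prefixes: tuple[str, ...] = MITO_PREFIXES
    ) -> np.ndarray:
        """Mitochondrial UMI fraction per unit; 0 for empty units."""
        mask = self.mito_mask(prefixes)
        totals = self.umis_per_unit().astype(float)
        mito = self.counts[mask].sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito / totals, 0.0)
        return frac

    # -- subsetting ------------------------------------------------------

    def subset_units(self, keep: np.ndarray) -> "CountMatrix":
        """Return a new matrix restricted to units selected by ``keep``
        (boolean mask or integer index array)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return CountMatrix(
            gene_ids=self.gene_ids,
            unit_ids=[self.unit_ids[i] for i in idx],
            counts=self.counts[:, idx],
            mito_gene_mask=self.mito_gene_mask,
        )

    def subset_genes(self, gene_ids: list[str]) -> "CountMatrix":
        """Restrict to the given genes, in the given order."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        idx = np.array([pos[g] for g in gene_ids], dtype=int)
        mask = None
        if self.mito_gene_mask is not None:
            mask = self.mito_gene_mask[idx]
        return CountMatrix(
            gene_ids=list(gene_ids),
            unit_ids=self.unit_ids,
            counts=self.counts[idx, :],
            mito_gene_mask=mask,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.gene_ids, columns=self.unit_ids
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, mito_gene_mask: np.ndarray | None = None
    ) -> "CountMatrix":
        return cls(
            gene_ids=list(df.index),
            unit_ids=list(df.columns),
            counts=df.to_numpy(),
            mito_gene_mask=mito_gene_mask,
        )


@dataclass
class CompositionMatrix:
    """Units x cell-types fractions; each row is a point on the simplex."""

    unit_ids: list[str]
    cell_types: list[str]
    fractions: np.ndarray
    #: optional per-unit relative L2 misfit from deconvolution
    residuals: np.ndarray | None = field(default=None, compare=False)

    ROW_SUM_TOL = 1e-6

    def __post_init__(self) -> None:
        self.unit_ids = _as_str_list(self.unit_ids)
        self.cell_types = _as_str_list(self.cell_types)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (len(self.unit_ids), len(self.cell_types)):
            raise ValueError(
                f"fractions shape {self.fractions.shape} does not match "
                f"{len(self.unit_ids)} units x {len(self.cell_types)} types"
            )
        if np.any(self.fractions < -1e-12):
            raise ValueError("fractions must be non-negative")
        self.fractions = np.clip(self.fractions, 0.0, None)
        rs = self.fractions.sum(axis=1)
        if np.any(np.abs(rs - 1.0) > self.ROW_SUM_TOL):
            bad = int(np.argmax(np.abs(rs - 1.0)))
            raise ValueError(
                f"row sums must be 1 within {self.ROW_SUM_TOL}; unit "
                f"{self.unit_ids[bad]} sums to {rs[bad]:.8f}"
            )

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def column(self, cell_type: str) -> np.ndarray:
        try:
            j = self.cell_types.index(cell_type)
        except ValueError:
            raise KeyError(
                f"unknown cell type {cell_type!r}; have {self.cell_types}"
            ) from None
        return self.fractions[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.fractions, index=self.unit_ids, columns=self.cell_types
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CompositionMatrix":
        return cls(
            unit_ids=list(df.index),
            cell_types=list(df.columns),
            fractions=df.to_numpy(dtype=float),
        )

    def restrict_types(self, cell_types: list[str]) -> "CompositionMatrix":
        """Project onto a subset of cell types and renormalise rows.

        Raises if a row loses all of its mass under the projection.
        """
        df = self.to_frame()[list(cell_types)]
        sums = df.sum(axis=1)
        if (sums <= 0).any():
            bad = sums.index[sums <= 0][0]
            raise ValueError(f"unit {bad} has zero mass on {cell_types}")
        return CompositionMatrix(
            unit_ids=self.unit_ids,
            cell_types=list(cell_types),
            fractions=(df.div(sums, axis=0)).to_numpy(),
        )
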
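"""Cell-type signature matrices from labelled reference single-cell data.

A signature matrix holds, for a set of marker genes, the mean normalised
expression of each cell type in a reference single-cell dataset.  It is the
fixed design matrix against which mixed samples are deconvolved.  Marker
selection is a transparent fold-change ranking: for each type, genes are
ranked by (type mean) / (maximum other-type mean) and the top genes with
fold >= ``min_fold`` are retained; the signature is restricted to the union
of markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .qc import normalize_units

__all__ = ["SignatureMatrix", "build_signature", "pseudo_bulk"]

#: reference units are rescaled to this total before averaging so cluster
#: depth differences do not bias the profiles
REFERENCE_SCALE = 10_000.0


@dataclass
class SignatureMatrix:
    """Marker-gene x cell-type mean expression profiles."""

    gene_ids: list[str]
    cell_types: list[str]
    profiles: np.ndarray
    marker_map: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.shape != (len(self.gene_ids), len(self.cell_types)):
            raise ValueError("profiles shape mismatch")
        if np.any(self.profiles < 0):
            raise ValueError("profiles must be non-negative")
        if np.any(self.profiles.sum(axis=0) == 0):
            raise ValueError("signature contains an all-zero cell-type column")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.profiles, index=self.gene_ids, columns=self.cell_types
        )

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(
            path, sep="\t", index_label="gene_id", float_format="%.10g"
        )
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            gene_ids=list(df.index),
            cell_types=list(df.columns),
            profiles=df.to_numpy(dtype=float),
        )


def _labels_series(labels, unit_ids: list[str]) -> pd.Series:
    s = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
    missing = [u for u in unit_ids if u not in s.index]
    if missing:
        raise ValueError(f"units without a cell-type label: {missing[:5]}")
    return s.loc[unit_ids].astype(str)


def type_means(
    ref_counts: CountMatrix, labels, scale: float = REFERENCE_SCALE
) -> pd.DataFrame:
    """Mean unit-normalised expression per cell type (genes x types)."""
    s = _labels_series(labels, ref_counts.unit_ids)
    norm = normalize_units(ref_counts, scale=scale)
    return norm.T.groupby(s).mean().T.sort_index(axis=1)


def build_signature(
    ref_counts: CountMatrix,
    labels,
    markers_per_type: int = 50,
    min_fold: float = 2.0,
    scale: float = REFERENCE_SCALE,
) -> SignatureMatrix:
    """Build a signature matrix from labelled reference counts.

    Parameters
    ----------
    ref_counts:
        Reference single-cell (or pseudo-cell) UMI counts.
    labels:
        Mapping or Series ``unit_id -> cell_type``; every unit must be
        labelled, at least two types, each with at least three units.
    markers_per_type:
        Number of markers requested per type; fewer are kept when fewer
        genes meet ``min_fold``.
    min_fold:
        Minimum (type mean) / (max other-type mean) ratio for a marker.

    Raises
    ------
    ValueError
        If a type has no gene meeting ``min_fold`` (naming the type), or
        the labelling preconditions fail.
    """
    s = _labels_series(labels, ref_counts.unit_ids)
    sizes = s.value_counts()
    if len(sizes) < 2:
        raise ValueError("need at least two cell types")
    small = sizes[sizes < 3]
    if len(small):
        raise ValueError(
            f"cell types with fewer than 3 units: {sorted(small.index)}"
        )
    means = type_means(ref_counts, s, scale=scale)
    cell_types = list(means.columns)
    m = means.to_numpy()

    marker_map: dict[str, list[str]] = {}
    for j, t in enumerate(cell_types):
        own = m[:, j]
        others = np.delete(m, j, axis=1).max(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = np.where(
                others > 0, own / others, np.where(own > 0, np.inf, 0.0)
            )
        ok = np.flatnonzero(fold >= min_fold)
        if len(ok) == 0:
            raise ValueError(
                f"cell type {t!r} has no gene with fold change >= {min_fold}"
            )
        # rank by fold, then mean expression; gene order breaks ties
        order = ok[np.lexsort((-own[ok], -fold[ok]))]
        chosen = order[:markers_per_type]
        marker_map[t] = [means.index[g] for g in sorted(chosen)]

    marker_union = sorted({g for gs in marker_map.values() for g in gs})
    sig = means.loc[marker_union]
    return SignatureMatrix(
        gene_ids=marker_union,
        cell_types=cell_types,
        profiles=sig.to_numpy(),
        marker_map=marker_map,
    )


def pseudo_bulk(
    ref_counts: CountMatrix,
    labels,
    composition,
    depth: int = 5000,
    seed: int = 0,
    scale: float = REFERENCE_SCALE,
) -> pd.Series:
    """Draw a synthetic mixed-unit expression vector with known composition.

    The gene-probability vector is the composition-weighted mixture of the
    normalised type means; the return is one multinomial draw at ``depth``,
    indexed by gene.  ``composition`` is a mapping ``cell_type -> fraction``
    or a sequence aligned with the sorted type order; it must sum to 1.
    """
    means = type_means(ref_counts, labels, scale=scale)
    cell_types = list(means.columns)
    if isinstance(composition, dict):
        comp = np.array([composition.get(t, 0.0) for t in cell_types])
    else:
        comp = np.asarray(composition, dtype=float)
        if comp.shape != (len(cell_types),):
            raise ValueError(
                f"composition must have one entry per type ({len(cell_types)})"
            )
    if np.any(comp < 0):
        raise ValueError("composition fractions must be non-negative")
    if abs(comp.sum() - 1.0) > 1e-6:
        raise ValueError("composition must sum to 1")
    p = means.to_numpy() @ comp
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    return pd.Series(
        rng.multinomial(int(depth), p), index=means.index, name="pseudo_bulk"
    )
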
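"""Cross-platform comparison of composition datasets.

Semibulk fragments and spatial-transcriptomics spots both measure small
neighbourhoods of tissue, so their deconvolved compositions should occupy
the same region of composition space wherever both platforms sample the
same anatomy.  The comparison pools units from both platforms, clusters
them hierarchically on their composition rows, and asks what fraction of
semibulk units land in clusters that also contain at least one spot (the
"mixing fraction").  A platform-private niche — anatomy one platform
captures and the other does not — shows up as an unmixed cluster and a
depressed mixing fraction.  Per-unit expression similarity across platforms
is measured as Pearson correlation of log-normalised shared genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import pearsonr

from .containers import CompositionMatrix

__all__ = [
    "LabeledCompositionSet",
    "ClusteringResult",
    "combine_platforms",
    "joint_cluster",
    "mixing_fraction",
    "cluster_membership_table",
    "expression_correlation",
]

PLATFORM_SEMIBULK = "semibulk"
PLATFORM_SPOT = "spot"

_LINKAGES = ("complete", "average", "ward")
_METRICS = ("euclidean", "correlation")


@dataclass
class LabeledCompositionSet:
    """Pooled compositions carrying a per-unit platform label."""

    composition: CompositionMatrix
    platform: np.ndarray

    def __post_init__(self) -> None:
        self.platform = np.asarray(self.platform, dtype=object)
        if self.platform.shape != (self.composition.n_units,):
            raise ValueError("one platform label per unit required")
        bad = set(self.platform) - {PLATFORM_SEMIBULK, PLATFORM_SPOT}
        if bad:
            raise ValueError(f"unknown platform labels: {sorted(bad)}")


@dataclass
class ClusteringResult:
    """Cluster ids 1..k per unit from agglomerative clustering."""

    unit_ids: list[str]
    cluster: np.ndarray
    linkage_method: str
    metric: str
    k: int


def combine_platforms(
    semibulk: CompositionMatrix, spots: CompositionMatrix
) -> LabeledCompositionSet:
    """Pool two composition matrices on their shared cell types.

    The cell-type intersection is taken in the semibulk matrix's column
    order and both row sets are renormalised onto it; unit ids are prefixed
    with the platform so the pooled index is unique.
    """
    shared = [t for t in semibulk.cell_types if t in set(spots.cell_types)]
    if not shared:
        raise ValueError("the two composition matrices share no cell types")
    sb = semibulk.restrict_types(shared)
    st = spots.restrict_types(shared)
    pooled = CompositionMatrix(
        unit_ids=[f"sb:{u}" for u in sb.unit_ids]
        + [f"st:{u}" for u in st.unit_ids],
        cell_types=shared,
        fractions=np.vstack([sb.fractions, st.fractions]),
    )
    labels = np.array(
        [PLATFORM_SEMIBULK] * sb.n_units + [PLATFORM_SPOT] * st.n_units,
        dtype=object,
    )
    return LabeledCompositionSet(composition=pooled, platform=labels)


def joint_cluster(
    s: LabeledCompositionSet,
    k: int = 3,
    metric: str = "euclidean",
    linkage_method: str = "complete",
) -> ClusteringResult:
    """Agglomerative clustering of pooled composition rows, cut at k.

    Defaults mirror the R heatmap-clustering conventions this analysis is
    usually run with: Euclidean distance, complete linkage, three clusters.
    Ward linkage requires the Euclidean metric.
    """
    n = s.composition.n_units
    if k < 1 or k > n:
        raise ValueError(f"k={k} not feasible for {n} units")
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    if linkage_method not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    if linkage_method == "ward" and metric != "euclidean":
        raise ValueError("ward linkage requires the euclidean metric")
    z = linkage(s.composition.fractions, method=linkage_method, metric=metric)
    assignment = fcluster(z, t=k, criterion="maxclust")
    return ClusteringResult(
        unit_ids=s.composition.unit_ids,
        cluster=np.asarray(assignment, dtype=int),
        linkage_method=linkage_method,
        metric=metric,
        k=int(assignment.max()),
    )


def mixing_fraction(c: ClusteringResult, labels) -> float:
    """Fraction of semibulk units in clusters containing at least one spot."""
    labels = np.asarray(labels, dtype=object)
    if labels.shape != c.cluster.shape:
        raise ValueError("one platform label per clustered unit required")
    sb = labels == PLATFORM_SEMIBULK
    st = labels == PLATFORM_SPOT
    if not sb.any() or not st.any():
        raise ValueError("both platforms must be present")
    mixed_clusters = set(c.cluster[st])
    return float(np.isin(c.cluster[sb], list(mixed_clusters)).mean())


def cluster_membership_table(c: ClusteringResult, labels) -> pd.DataFrame:
    """k x 2 table of platform counts per cluster."""
    labels = np.asarray(labels, dtype=object)
    if labels.shape != c.cluster.shape:
        raise ValueError("one platform label per clustered unit required")
    df = pd.DataFrame({"cluster": c.cluster, "platform": labels})
    table = (
        df.groupby(["cluster", "platform"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=[PLATFORM_SEMIBULK, PLATFORM_SPOT], fill_value=0)
    )
    table.columns.name = None
    return table


def expression_correlation(
    a, b, scale: float = 10_000.0
) -> float:
    """Pearson correlation of two units' log-normalised expression.

    ``a`` and ``b`` are gene-indexed Series (aligned on their shared genes)
    or equal-length arrays.  Each vector is scaled to ``scale`` total over
    the shared genes, genes expressed in neither unit are dropped, and the
    correlation is computed on log1p values.  Fewer than 3 informative genes
    or a zero-variance vector is an error.
    """
    if isinstance(a, pd.Series) and isinstance(b, pd.Series):
        shared = a.index.intersection(b.index)
        a = a.loc[shared].to_numpy(dtype=float)
        b = b.loc[shared].to_numpy(dtype=float)
    else:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("expression vectors must be 1-D and aligned")
    keep = (a > 0) | (b > 0)
    a, b = a[keep], b[keep]
    if len(a) < 3:
        raise ValueError("need at least 3 shared expressed genes")
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("an all-zero expression vector has no correlation")
    la = np.log1p(a * (scale / a.sum()))
    lb = np.log1p(b * (scale / b.sum()))
    if la.std() == 0 or lb.std() == 0:
        raise ValueError("zero-variance expression; correlation undefined")
    return float(pearsonr(la, lb).statistic)
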
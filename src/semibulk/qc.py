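"""Per-unit quality control and normalisation of UMI count matrices.

Units (semibulks, spots, or reference cells) are kept when they express at
least ``min_genes`` genes (count > 0) and their mitochondrial UMI fraction
does not exceed ``max_mito``.  Sample-appropriate gene floors differ —
deeply sequenced tissue tolerates a 1000-gene floor while shallow clinical
material may warrant 200 or 500 — so the floor is a parameter with named
profiles rather than a constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MITO_PREFIXES, CountMatrix

__all__ = ["QcThresholds", "filter_units", "qc_summary", "normalize_units"]

#: per-sample threshold profiles: deeply sequenced mouse tissue vs. the two
#: shallower clinical profiles
QC_PROFILES = {
    "mouse_kidney": dict(min_genes=1000, max_mito=0.25),
    "clinical_a": dict(min_genes=200, max_mito=0.25),
    "clinical_b": dict(min_genes=500, max_mito=0.25),
}

REASON_LOW_GENES = "low_genes"
REASON_HIGH_MITO = "high_mito"


@dataclass(frozen=True)
class QcThresholds:
    """Unit-retention thresholds.

    ``min_genes``: minimum number of expressed genes (count > 0) a unit must
    reach to be kept ("less than min_genes" is discarded).
    ``max_mito``: maximum tolerated mitochondrial UMI fraction (strictly
    above is discarded).
    """

    min_genes: int = 1000
    max_mito: float = 0.25
    mito_prefixes: tuple[str, ...] = MITO_PREFIXES

    def __post_init__(self) -> None:
        if self.min_genes < 0:
            raise ValueError("min_genes must be non-negative")
        if not (0.0 <= self.max_mito <= 1.0):
            raise ValueError("max_mito must be in [0, 1]")

    @classmethod
    def profile(cls, name: str) -> "QcThresholds":
        try:
            return cls(**QC_PROFILES[name])
        except KeyError:
            raise KeyError(
                f"unknown QC profile {name!r}; have {sorted(QC_PROFILES)}"
            ) from None


def filter_units(
    m: CountMatrix, t: QcThresholds = QcThresholds()
) -> tuple[CountMatrix, pd.DataFrame]:
    """Drop units failing the gene floor or the mitochondrial ceiling.

    Returns the filtered matrix and a discard report with one row per
    removed unit and its first failing rule (the gene floor is checked
    before the mitochondrial ceiling, so each discarded unit has exactly
    one reason).
    """
    expressed = m.expressed_genes_per_unit()
    mito_frac = m.mito_fraction_per_unit(t.mito_prefixes)
    low_genes = expressed < t.min_genes
    high_mito = mito_frac > t.max_mito
    keep = ~low_genes & ~high_mito

    reasons = []
    for i, unit in enumerate(m.unit_ids):
        if low_genes[i]:
            reasons.append((unit, REASON_LOW_GENES, int(expressed[i]), mito_frac[i]))
        elif high_mito[i]:
            reasons.append((unit, REASON_HIGH_MITO, int(expressed[i]), mito_frac[i]))
    report = pd.DataFrame(
        reasons, columns=["unit_id", "reason", "expressed_genes", "mito_fraction"]
    )
    if not keep.any():
        warnings.warn("all units were discarded by QC")
    return m.subset_units(keep), report


def qc_summary(m: CountMatrix) -> dict:
    """Dataset-level QC metrics.

    Medians use the conventional even-length rule (mean of the two central
    values).  The mitochondrial percentage is over all UMIs in the matrix.
    """
    umis = m.umis_per_unit()
    genes = m.expressed_genes_per_unit()
    total = int(umis.sum())
    mito_total = int(m.counts[m.mito_mask()].sum())
    return {
        "n_units": m.n_units,
        "n_genes": m.n_genes,
        "total_umis": total,
        "mean_umis_per_unit": float(umis.mean()) if m.n_units else 0.0,
        "median_umis_per_unit": float(np.median(umis)) if m.n_units else 0.0,
        "median_genes_per_unit": float(np.median(genes)) if m.n_units else 0.0,
        "pct_mito_umis": 100.0 * mito_total / total if total else 0.0,
    }


def normalize_units(
    m: CountMatrix, scale: float = 10_000.0, log_transform: bool = False
) -> pd.DataFrame:
    """Scale each unit to ``scale`` total counts, optionally log1p.

    Returns a float genes x units DataFrame.  An all-zero unit cannot be
    scaled and raises, naming the unit.
    """
    totals = m.umis_per_unit().astype(float)
    zero = np.flatnonzero(totals == 0)
    if len(zero):
        raise ValueError(
            f"unit {m.unit_ids[zero[0]]} has zero counts and cannot be "
            "normalized; filter first"
        )
    x = m.counts * (scale / totals)[None, :]
    if log_transform:
        x = np.log1p(x)
    return pd.DataFrame(x, index=m.gene_ids, columns=m.unit_ids)
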
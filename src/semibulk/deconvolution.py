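"""Composition estimation: express a mixed unit as a weighted sum of
cell-type signatures.

UMI counts mix linearly: a unit containing fractions f_t of each cell type
has expected expression Σ_t f_t · s_t, with s_t the type's signature
profile.  Each unit is therefore solved as a nonnegative least-squares
problem against the signature columns and the coefficients are renormalised
to the simplex.  Expression and signature are both scaled to a common total
before the solve (linear mixing holds on the linear scale, so no log
transform is applied).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .containers import CompositionMatrix, CountMatrix
from .signatures import SignatureMatrix

__all__ = [
    "UnitDeconvolution",
    "deconvolve_unit",
    "deconvolve_matrix",
    "presence_threshold",
    "presence_overlap",
]

SOLVE_SCALE = 10_000.0

#: presence cut used when reporting which units "contain" a cell type
DEFAULT_PRESENCE_FRACTION = 0.03


@dataclass
class UnitDeconvolution:
    """One unit's estimated composition and fit quality.

    ``residual`` is the relative L2 misfit ||S w - x|| / ||x|| of the
    unnormalised NNLS solution.  ``uniform_fallback`` marks the pathological
    all-zero solution, which is reported as a uniform composition.
    """

    fractions: np.ndarray
    residual: float
    uniform_fallback: bool = False


def _scale_to(v: np.ndarray, total: float) -> np.ndarray:
    s = v.sum()
    if s <= 0:
        raise ValueError("cannot scale an all-zero vector")
    return v * (total / s)


def deconvolve_unit(
    expression, sig: SignatureMatrix, scale: float = SOLVE_SCALE
) -> UnitDeconvolution:
    """Estimate one unit's cell-type fractions.

    ``expression`` must already be restricted to (and aligned with) the
    signature genes; a pandas Series indexed by gene id is aligned
    automatically.  Raises if the overlap with the signature is all zero.
    """
    if isinstance(expression, pd.Series):
        expression = expression.reindex(sig.gene_ids, fill_value=0).to_numpy()
    x = np.asarray(expression, dtype=float)
    if x.shape != (sig.n_genes,):
        raise ValueError(
            f"expression has {x.shape} entries; signature expects {sig.n_genes}"
        )
    if np.any(x < 0):
        raise ValueError("expression must be non-negative")
    if x.sum() == 0:
        raise ValueError("expression has no counts on the signature genes")
    b = _scale_to(x, scale)
    a = sig.profiles / sig.profiles.sum(axis=0, keepdims=True) * scale
    w, rnorm = nnls(a, b)
    if w.sum() == 0:
        k = len(sig.cell_types)
        return UnitDeconvolution(
            fractions=np.full(k, 1.0 / k), residual=1.0, uniform_fallback=True
        )
    return UnitDeconvolution(
        fractions=w / w.sum(),
        residual=float(rnorm / np.linalg.norm(b)),
        uniform_fallback=False,
    )


def deconvolve_matrix(
    m: CountMatrix, sig: SignatureMatrix, scale: float = SOLVE_SCALE
) -> CompositionMatrix:
    """Row-wise deconvolution of a whole count matrix.

    The matrix is restricted to the signature genes (missing signature genes
    count as zero).  Deterministic given inputs; unit-level failures are
    re-raised with the unit id attached.  Per-unit residuals ride along on
    the returned composition matrix.
    """
    present = [g for g in sig.gene_ids if g in set(m.gene_ids)]
    if not present:
        raise ValueError("count matrix shares no genes with the signature")
    sub = m.subset_genes(present).to_frame()
    expr = sub.reindex(sig.gene_ids, fill_value=0)
    fractions = np.zeros((m.n_units, len(sig.cell_types)))
    residuals = np.zeros(m.n_units)
    for i, unit in enumerate(m.unit_ids):
        try:
            r = deconvolve_unit(expr.iloc[:, i].to_numpy(), sig, scale=scale)
        except ValueError as e:
            raise ValueError(f"unit {unit}: {e}") from e
        fractions[i] = r.fractions
        residuals[i] = r.residual
    return CompositionMatrix(
        unit_ids=m.unit_ids,
        cell_types=list(sig.cell_types),
        fractions=fractions,
        residuals=residuals,
    )


def presence_threshold(
    c: CompositionMatrix,
    cell_type: str,
    min_fraction: float = DEFAULT_PRESENCE_FRACTION,
) -> list[str]:
    """Units whose fraction of ``cell_type`` strictly exceeds the cut."""
    col = c.column(cell_type)
    return [u for u, f in zip(c.unit_ids, col) if f > min_fraction]


def presence_overlap(
    c: CompositionMatrix,
    type_a: str,
    type_b: str,
    min_fraction: float = DEFAULT_PRESENCE_FRACTION,
) -> dict:
    """Co-presence summary: of the units containing ``type_a`` above the
    cut, how many also contain ``type_b``?

    Returns counts and the percentage (rounded to the nearest integer, the
    convention for quoting such overlaps).
    """
    a_units = presence_threshold(c, type_a, min_fraction)
    b_units = set(presence_threshold(c, type_b, min_fraction))
    both = [u for u in a_units if u in b_units]
    pct = round(100.0 * len(both) / len(a_units)) if a_units else 0.0
    return {
        "n_with_a": len(a_units),
        "n_with_both": len(both),
        "percentage": pct,
    }
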
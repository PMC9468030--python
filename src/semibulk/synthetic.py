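"""Synthetic data generators for every pipeline input.

The real experiment produces UMI count matrices whose columns are semibulks:
small tissue fragments of on the order of a hundred cells, each a mixture of
cell types drawn from the local anatomy.  The generators here emulate those
inputs from explicit, seeded distributions so that every downstream stage
can be tested against known ground truth:

* a reference expression catalog with planted marker genes,
* semibulk counts as depth-limited multinomial draws from composition-
  weighted mixtures of reference profiles, with Dirichlet compositions and
  optional planted colocalization between chosen cell-type pairs,
* Poisson droplet-occupancy tables at a given loading rate λ,
* two-species barnyard mixtures with a known multiplet rate.

All generators are deterministic given (arguments, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .barnyard import BarnyardTable
from .containers import CompositionMatrix, CountMatrix
from .encapsulation import OccupancyTable

__all__ = [
    "ReferenceProfile",
    "ColocalizationSpec",
    "SyntheticSemibulkSet",
    "simulate_reference",
    "simulate_compositions",
    "simulate_semibulks",
    "simulate_occupancy",
    "simulate_barnyard",
    "simulate_reference_cells",
]

#: factor by which pair fractions are multiplied when a colocalization event
#: is planted in a unit
DEFAULT_BOOST = 3.0

#: minimum own-type / other-type expression-fraction ratio guaranteed for
#: planted marker genes
MARKER_MIN_FOLD = 5.0


@dataclass
class ReferenceProfile:
    """Per-type relative expression profiles with planted markers.

    ``expression_fractions`` is genes x cell-types; every column sums to 1.
    ``marker_map`` records which genes were planted as markers of each type
    (ground truth for signature-recovery tests).
    """

    gene_ids: list[str]
    cell_types: list[str]
    expression_fractions: np.ndarray
    mito_gene_mask: np.ndarray
    marker_map: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.expression_fractions = np.asarray(
            self.expression_fractions, dtype=float
        )
        shape = (len(self.gene_ids), len(self.cell_types))
        if self.expression_fractions.shape != shape:
            raise ValueError("expression_fractions shape mismatch")
        if np.any(self.expression_fractions < 0):
            raise ValueError("expression fractions must be non-negative")
        colsums = self.expression_fractions.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-9):
            raise ValueError("each column must sum to 1 within 1e-9")
        self.mito_gene_mask = np.asarray(self.mito_gene_mask, dtype=bool)
        if self.mito_gene_mask.shape != (len(self.gene_ids),):
            raise ValueError("mito_gene_mask length must equal gene count")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class ColocalizationSpec:
    """Planted positive association between cell-type pairs.

    Each entry of ``pairs`` is ``(type_a, type_b, strength)`` with strength
    in [0, 1]: the per-unit probability that the pair receives a shared
    co-abundance boost.  In a boosted unit one exponential mass
    ``z ~ Exp(mean = (boost - 1) * E[fraction])`` is added to BOTH
    fractions before the row is renormalised, so in expectation each
    boosted fraction is multiplied by ``boost``.  Because the added mass is
    shared, the two fractions rise and fall together within boosted units —
    which is what makes the planted pair a positive presence association
    under median dichotomisation at any strength.  ``baseline_alpha`` is
    the symmetric Dirichlet concentration of the baseline composition
    (scalar, or one value per type).
    """

    pairs: tuple = ()
    baseline_alpha: float | tuple = 1.0
    boost: float = DEFAULT_BOOST

    def __post_init__(self) -> None:
        for a, b, s in self.pairs:
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"association strength {s} not in [0, 1]")
            if a == b:
                raise ValueError("a colocalization pair needs two distinct types")
        if self.boost <= 0:
            raise ValueError("boost must be positive")

    def validate_types(self, cell_types: list[str]) -> None:
        known = set(cell_types)
        for a, b, _ in self.pairs:
            for t in (a, b):
                if t not in known:
                    raise KeyError(
                        f"colocalization names unknown cell type {t!r}; "
                        f"reference has {sorted(known)}"
                    )

    def alpha_vector(self, n_types: int) -> np.ndarray:
        alpha = np.asarray(self.baseline_alpha, dtype=float)
        if alpha.ndim == 0:
            alpha = np.full(n_types, float(alpha))
        if alpha.shape != (n_types,):
            raise ValueError("baseline_alpha must be scalar or one per type")
        if np.any(alpha <= 0):
            raise ValueError("Dirichlet concentrations must be positive")
        return alpha


@dataclass
class SyntheticSemibulkSet:
    """Simulated semibulk counts together with their generating truth."""

    counts: CountMatrix
    true_compositions: CompositionMatrix
    depth_per_unit: np.ndarray
    seed: int
    #: per planted pair (a, b): boolean array marking units where the boost
    #: was applied (ground truth for co-occurrence power tests)
    boosted_units: dict[tuple[str, str], np.ndarray] = field(
        default_factory=dict
    )


def _gene_ids(n_genes: int, mito_mask: np.ndarray) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [
        ("mt-g" if mito_mask[i] else "g") + str(i).zfill(width)
        for i in range(n_genes)
    ]


def simulate_reference(
    n_genes: int,
    cell_types: list[str] | int,
    markers_per_type: int = 10,
    mito_fraction: float = 0.05,
    seed: int = 0,
    marker_fold_range: tuple[float, float] = (6.0, 12.0),
) -> ReferenceProfile:
    """Generate a reference profile with planted marker genes.

    Non-marker genes share one baseline expression level across all types;
    each type additionally gets ``markers_per_type`` private marker genes
    whose expression fraction in the own type is at least
    :data:`MARKER_MIN_FOLD` times the fraction in any other type.  Marker
    block masses are equalised across types so the guarantee survives
    column normalisation exactly.

    ``mito_fraction`` of genes are flagged mitochondrial and named with an
    ``mt-`` prefix so the default QC prefix rule recognises them.
    """
    if isinstance(cell_types, int):
        cell_types = [f"type{i}" for i in range(cell_types)]
    n_types = len(cell_types)
    if n_types < 1:
        raise ValueError("need at least one cell type")
    if markers_per_type < 1:
        raise ValueError("markers_per_type must be >= 1")
    n_markers = n_types * markers_per_type
    if n_genes < n_markers:
        raise ValueError(
            f"{n_genes} genes cannot host {n_types} x {markers_per_type} "
            "marker genes"
        )
    if not (0.0 <= mito_fraction < 1.0):
        raise ValueError("mito_fraction must be in [0, 1)")
    lo, hi = marker_fold_range
    if lo < MARKER_MIN_FOLD:
        raise ValueError(
            f"marker folds below {MARKER_MIN_FOLD} would break the marker "
            "guarantee"
        )

    rng = np.random.default_rng(seed)
    baseline = rng.gamma(shape=0.6, scale=1.0, size=n_genes) + 1e-3
    marker_genes = rng.choice(n_genes, size=n_markers, replace=False)
    # markers are, by definition, robustly expressed in their own type:
    # their baselines are drawn bounded away from zero so planted markers
    # stay detectable at realistic sequencing depths
    baseline[marker_genes] = rng.gamma(2.0, 1.0, size=n_markers) + 0.05
    folds = rng.uniform(lo, hi, size=n_markers)

    # equalise the extra marker mass (fold-1)*baseline per type so all
    # column sums match and fraction fold-changes equal the raw folds
    blocks = marker_genes.reshape(n_types, markers_per_type)
    fold_blocks = folds.reshape(n_types, markers_per_type)
    extra = (fold_blocks - 1.0) * baseline[blocks]
    target = extra.sum(axis=1).mean()
    for t in range(n_types):
        baseline[blocks[t]] *= target / extra[t].sum()

    x = np.tile(baseline[:, None], (1, n_types))
    for t in range(n_types):
        x[blocks[t], t] = fold_blocks[t] * baseline[blocks[t]]
    fractions = x / x.sum(axis=0, keepdims=True)

    # mitochondrial flags: prefer non-marker genes
    n_mito = int(round(mito_fraction * n_genes))
    mito_mask = np.zeros(n_genes, dtype=bool)
    non_marker = np.setdiff1d(np.arange(n_genes), marker_genes)
    pool = non_marker if len(non_marker) >= n_mito else np.arange(n_genes)
    if n_mito > 0:
        mito_mask[rng.choice(pool, size=n_mito, replace=False)] = True

    gene_ids = _gene_ids(n_genes, mito_mask)
    marker_map = {
        cell_types[t]: [gene_ids[g] for g in sorted(blocks[t])]
        for t in range(n_types)
    }
    return ReferenceProfile(
        gene_ids=gene_ids,
        cell_types=list(cell_types),
        expression_fractions=fractions,
        mito_gene_mask=mito_mask,
        marker_map=marker_map,
    )


def simulate_compositions(
    cell_types: list[str],
    n_units: int,
    coloc: ColocalizationSpec | None = None,
    seed: int = 0,
) -> tuple[CompositionMatrix, dict[tuple[str, str], np.ndarray]]:
    """Draw per-unit compositions with optional planted colocalization.

    Baseline compositions are Dirichlet(``baseline_alpha``); for each
    planted pair (A, B, s), with probability s a shared exponential
    co-abundance mass (mean ``(boost - 1)`` times the pair's expected
    baseline fraction) is added to the unit's A and B fractions, after
    which the row is renormalised.  Returns the compositions and, per
    pair, the boolean boost indicator.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    coloc = coloc or ColocalizationSpec()
    coloc.validate_types(list(cell_types))
    n_types = len(cell_types)
    rng = np.random.default_rng(seed)
    alpha = coloc.alpha_vector(n_types)
    comp = rng.dirichlet(alpha, size=n_units)
    boosted: dict[tuple[str, str], np.ndarray] = {}
    for a, b, s in coloc.pairs:
        ia, ib = cell_types.index(a), cell_types.index(b)
        hit = rng.random(n_units) < s
        mean_pair = (alpha[ia] + alpha[ib]) / (2.0 * alpha.sum())
        z = rng.exponential((coloc.boost - 1.0) * mean_pair, size=n_units)
        comp[hit, ia] += z[hit]
        comp[hit, ib] += z[hit]
        boosted[(a, b)] = hit
    comp /= comp.sum(axis=1, keepdims=True)
    unit_ids = [f"unit{str(i).zfill(max(4, len(str(n_units))))}" for i in range(n_units)]
    return (
        CompositionMatrix(
            unit_ids=unit_ids, cell_types=list(cell_types), fractions=comp
        ),
        boosted,
    )


def simulate_archetype_compositions(
    cell_types: list[str],
    n_units: int,
    archetype_alphas,
    weights=None,
    seed: int = 0,
    unit_prefix: str = "unit",
) -> CompositionMatrix:
    """Draw compositions from a mixture of Dirichlet archetypes.

    Each archetype is a Dirichlet concentration vector (typically peaked on
    one or two types, emulating an anatomical niche); every unit picks an
    archetype by ``weights`` and draws its composition from it.  Used to
    model platforms that sample the same — or deliberately different —
    sets of niches.
    """
    alphas = [np.asarray(a, dtype=float) for a in archetype_alphas]
    for a in alphas:
        if a.shape != (len(cell_types),) or np.any(a <= 0):
            raise ValueError(
                "each archetype needs one positive concentration per type"
            )
    if weights is None:
        weights = np.full(len(alphas), 1.0 / len(alphas))
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(alphas),) or np.any(weights < 0):
        raise ValueError("weights must be non-negative, one per archetype")
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    which = rng.choice(len(alphas), size=n_units, p=weights)
    fractions = np.vstack([rng.dirichlet(alphas[w]) for w in which])
    width = max(4, len(str(n_units)))
    return CompositionMatrix(
        unit_ids=[f"{unit_prefix}{str(i).zfill(width)}" for i in range(n_units)],
        cell_types=list(cell_types),
        fractions=fractions,
    )


def _resolve_depths(depth, n_units: int, rng: np.random.Generator) -> np.ndarray:
    """Accept a constant depth, a (low, high) uniform range, or explicit
    per-unit depths."""
    if np.isscalar(depth):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        return np.full(n_units, int(depth), dtype=np.int64)
    depth = np.asarray(depth)
    if depth.shape == (2,):
        lo, hi = int(depth[0]), int(depth[1])
        if lo < 1 or hi < lo:
            raise ValueError("depth range must satisfy 1 <= low <= high")
        return rng.integers(lo, hi + 1, size=n_units, dtype=np.int64)
    if depth.shape == (n_units,):
        if np.any(depth < 1):
            raise ValueError("all depths must be >= 1")
        return depth.astype(np.int64)
    raise ValueError("depth must be a scalar, a (low, high) pair, or per-unit")


def simulate_semibulks(
    ref: ReferenceProfile,
    n_units: int,
    depth=5000,
    coloc: ColocalizationSpec | None = None,
    seed: int = 0,
    dirichlet_multinomial_phi: float = 0.0,
) -> SyntheticSemibulkSet:
    """Simulate semibulk UMI counts from composition-weighted mixtures.

    Each unit's gene-probability vector is the reference columns mixed by
    its composition; counts are one multinomial draw at the unit's depth.
    ``dirichlet_multinomial_phi`` > 0 switches to Dirichlet-multinomial
    counts with alpha = mixture / phi (overdispersion grows with phi).
    """
    rng = np.random.default_rng(seed)
    comp, boosted = simulate_compositions(
        ref.cell_types, n_units, coloc=coloc, seed=rng.integers(2**31)
    )
    depths = _resolve_depths(depth, n_units, rng)
    counts = np.zeros((ref.n_genes, n_units), dtype=np.int64)
    mix_all = ref.expression_fractions @ comp.fractions.T  # genes x units
    for u in range(n_units):
        p = mix_all[:, u]
        if dirichlet_multinomial_phi > 0:
            alpha = np.clip(p / dirichlet_multinomial_phi, 1e-12, None)
            p = rng.dirichlet(alpha)
        counts[:, u] = rng.multinomial(depths[u], p / p.sum())
    cm = CountMatrix(
        gene_ids=ref.gene_ids,
        unit_ids=comp.unit_ids,
        counts=counts,
        mito_gene_mask=ref.mito_gene_mask,
    )
    return SyntheticSemibulkSet(
        counts=cm,
        true_compositions=comp,
        depth_per_unit=depths,
        seed=seed,
        boosted_units=boosted,
    )


def simulate_occupancy(
    lambda_value: float, n_droplets: int, kmax: int = 3, seed: int = 0
) -> OccupancyTable:
    """Draw per-droplet object counts from Poisson(λ), binning counts above
    ``kmax`` into the top category."""
    if lambda_value < 0:
        raise ValueError("lambda must be non-negative")
    if n_droplets < 1:
        raise ValueError("n_droplets must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.poisson(lambda_value, size=n_droplets)
    binned = np.minimum(draws, kmax)
    counts = np.bincount(binned, minlength=kmax + 1)
    return OccupancyTable(np.arange(kmax + 1), counts)


def simulate_barnyard(
    n_units: int,
    multiplet_rate: float,
    depth: int = 5000,
    purity: float = 0.99,
    seed: int = 0,
) -> BarnyardTable:
    """Simulate a two-species mixture with a known multiplet rate.

    Each unit is a multiplet with probability ``multiplet_rate``, otherwise
    a genome-A or genome-B singlet with equal probability.  Singlets draw
    ``depth`` UMIs with own-genome probability ``purity`` (the remainder
    models ambient cross-contamination); multiplets draw with probability
    0.5 per genome, the 1:1 mixing expectation.  Truth labels are stored on
    the returned table.
    """
    if not (0.0 <= multiplet_rate <= 1.0):
        raise ValueError("multiplet_rate must be in [0, 1]")
    if not (0.5 < purity <= 1.0):
        raise ValueError("purity must be in (0.5, 1]")
    if depth < 1 or n_units < 1:
        raise ValueError("depth and n_units must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random(n_units)
    truth = np.where(
        u < multiplet_rate, "multiplet", np.where(rng.random(n_units) < 0.5, "A", "B")
    ).astype(object)
    p_a = np.select(
        [truth == "multiplet", truth == "A"], [0.5, purity], default=1.0 - purity
    )
    umi_a = rng.binomial(depth, p_a)
    umi_b = depth - umi_a
    unit_ids = [f"bc{str(i).zfill(max(4, len(str(n_units))))}" for i in range(n_units)]
    return BarnyardTable(
        unit_ids=unit_ids, umi_a=umi_a, umi_b=umi_b, truth=truth
    )


def simulate_reference_cells(
    ref: ReferenceProfile,
    cells_per_type: int = 30,
    depth=2000,
    seed: int = 0,
) -> tuple[CountMatrix, pd.Series]:
    """Simulate labelled single cells from a reference profile.

    Each cell of type t is one multinomial draw from column t at the given
    depth (scalar, range pair, or per-cell).  Returns the cell-level count
    matrix and a ``unit_id -> cell_type`` label Series — the inputs the
    signature-building stage expects.
    """
    if cells_per_type < 1:
        raise ValueError("cells_per_type must be >= 1")
    rng = np.random.default_rng(seed)
    n_cells = cells_per_type * len(ref.cell_types)
    depths = _resolve_depths(depth, n_cells, rng)
    counts = np.zeros((ref.n_genes, n_cells), dtype=np.int64)
    labels = []
    for j, t in enumerate(ref.cell_types):
        p = ref.expression_fractions[:, j]
        for c in range(cells_per_type):
            i = j * cells_per_type + c
            counts[:, i] = rng.multinomial(depths[i], p)
            labels.append(t)
    cell_ids = [f"cell{str(i).zfill(max(4, len(str(n_cells))))}" for i in range(n_cells)]
    cm = CountMatrix(
        gene_ids=ref.gene_ids,
        unit_ids=cell_ids,
        counts=counts,
        mito_gene_mask=ref.mito_gene_mask,
    )
    return cm, pd.Series(labels, index=cell_ids, name="cell_type")
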
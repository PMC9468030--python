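import numpy as np
import pytest

import semibulk as sb

KIDNEY_TYPES = ["podocyte", "mesangium", "tubule", "immune"]


@pytest.fixture(scope="session")
def ref4() -> sb.ReferenceProfile:
    """A 300-gene, 4-type reference with 12 planted markers per type."""
    return sb.simulate_reference(
        300, KIDNEY_TYPES, markers_per_type=12, mito_fraction=0.05, seed=11
    )


@pytest.fixture(scope="session")
def ref_cells(ref4):
    """Labelled synthetic single cells drawn from the reference."""
    return sb.simulate_reference_cells(
        ref4, cells_per_type=30, depth=2000, seed=13
    )


@pytest.fixture(scope="session")
def signature4(ref_cells) -> sb.SignatureMatrix:
    cells, labels = ref_cells
    return sb.build_signature(cells, labels, markers_per_type=20, min_fold=2.0)


def build_qc_fixture(n_units=100, n_low_genes=20, n_high_mito=10, min_genes=50):
    """A count matrix with known QC failures.

    ``n_low_genes`` units express fewer than ``min_genes`` genes,
    ``n_high_mito`` further units exceed 25% mitochondrial UMIs, and the
    rest are clean; the three groups are disjoint by construction.
    Returns (matrix, low_gene_unit_ids, high_mito_unit_ids).
    """
    rng = np.random.default_rng(42)
    n_genes = 200
    gene_ids = [f"mt-g{i:03d}" if i < 10 else f"g{i:03d}" for i in range(n_genes)]
    counts = np.zeros((n_genes, n_units), dtype=np.int64)
    unit_ids = [f"u{i:03d}" for i in range(n_units)]
    low, mito = [], []
    for i in range(n_units):
        if i < n_low_genes:  # too few expressed genes
            genes = rng.choice(np.arange(10, n_genes), min_genes - 20, replace=False)
            counts[genes, i] = rng.integers(1, 20, size=len(genes))
            low.append(unit_ids[i])
        elif i < n_low_genes + n_high_mito:  # mito-heavy but gene-rich
            genes = rng.choice(np.arange(10, n_genes), min_genes + 40, replace=False)
            counts[genes, i] = rng.integers(1, 10, size=len(genes))
            counts[:10, i] = counts[:, i].sum()  # mito ≈ 50% of UMIs
            mito.append(unit_ids[i])
        else:  # clean
            genes = rng.choice(np.arange(10, n_genes), min_genes + 40, replace=False)
            counts[genes, i] = rng.integers(1, 20, size=len(genes))
    m = sb.CountMatrix(gene_ids=gene_ids, unit_ids=unit_ids, counts=counts)
    return m, low, mito


def count_matrix_from_columns(columns: dict[str, np.ndarray], gene_ids=None):
    """Build a CountMatrix from explicit per-unit count vectors."""
    units = list(columns)
    counts = np.column_stack([columns[u] for u in units])
    n_genes = counts.shape[0]
    if gene_ids is None:
        gene_ids = [f"g{i:03d}" for i in range(n_genes)]
    return sb.CountMatrix(gene_ids=gene_ids, unit_ids=units, counts=counts)
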
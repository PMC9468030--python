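"""Reading and writing count and composition matrices.

Two on-disk dialects are supported for UMI counts, mirroring what droplet
pipelines emit:

* a Matrix-Market triplet file ``matrix.mtx`` with ``genes.tsv`` and
  ``barcodes.tsv`` sidecars (one id per line) in a directory, and
* a dense TSV with genes as rows and a header row of unit ids.

Composition matrices travel as dense TSV (units x cell types with header),
which is also the import format for externally produced deconvolution
output.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import CompositionMatrix, CountMatrix

#: float format used for all numeric TSV output; fixed so reruns are
#: byte-identical.
FLOAT_FORMAT = "%.10g"


# ---------------------------------------------------------------------------
# counts: Matrix-Market directory dialect
# ---------------------------------------------------------------------------

def write_counts_mtx(m: CountMatrix, outdir: str | Path) -> Path:
    """Write ``matrix.mtx`` + ``genes.tsv`` / ``barcodes.tsv`` sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.coo_matrix(m.counts))
    (outdir / "genes.tsv").write_text("\n".join(m.gene_ids) + "\n")
    (outdir / "barcodes.tsv").write_text("\n".join(m.unit_ids) + "\n")
    return outdir


def read_counts_mtx(indir: str | Path) -> CountMatrix:
    indir = Path(indir)
    mat = spio.mmread(indir / "matrix.mtx")
    counts = np.asarray(sparse.coo_matrix(mat).todense())
    genes = (indir / "genes.tsv").read_text().splitlines()
    # tolerate the common two-column genes.tsv (id<TAB>symbol)
    genes = [g.split("\t")[0] for g in genes if g]
    barcodes = [b for b in (indir / "barcodes.tsv").read_text().splitlines() if b]
    return CountMatrix(gene_ids=genes, unit_ids=barcodes, counts=counts)


# ---------------------------------------------------------------------------
# counts: dense TSV dialect
# ---------------------------------------------------------------------------

def write_counts_tsv(m: CountMatrix, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    m.to_frame().to_csv(path, sep="\t", index_label="gene_id")
    return path


def read_counts_tsv(path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix.from_frame(df)


def read_counts(path: str | Path) -> CountMatrix:
    """Dispatch on path: a directory (or ``.mtx`` file inside one) is read as
    the Matrix-Market dialect, anything else as dense TSV."""
    path = Path(path)
    if path.is_dir():
        return read_counts_mtx(path)
    if path.suffix == ".mtx":
        return read_counts_mtx(path.parent)
    return read_counts_tsv(path)


# ---------------------------------------------------------------------------
# compositions
# ---------------------------------------------------------------------------

def write_composition_tsv(c: CompositionMatrix, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    c.to_frame().to_csv(
        path, sep="\t", index_label="unit_id", float_format=FLOAT_FORMAT
    )
    return path


def read_composition_tsv(path: str | Path) -> CompositionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CompositionMatrix.from_frame(df)
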
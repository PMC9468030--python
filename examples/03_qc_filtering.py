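"""Quality-control filtering of a semibulk count matrix.

Simulates semibulks over a range of depths, filters units on expressed
genes and mitochondrial fraction, and prints the summary statistics a QC
report would table (unit counts, median UMIs/genes, mito percentage).
"""

import semibulk as sb

ref = sb.simulate_reference(
    n_genes=400, cell_types=4, markers_per_type=15, mito_fraction=0.05, seed=5
)
sbset = sb.simulate_semibulks(ref, n_units=300, depth=(300, 6000), seed=6)

thresholds = sb.QcThresholds(min_genes=200, max_mito=0.25)
kept, discards = sb.filter_units(sbset.counts, thresholds)

print(f"units before/after QC: {sbset.counts.n_units} -> {kept.n_units}")
print("discard reasons:", discards["reason"].value_counts().to_dict())
summary = sb.qc_summary(kept)
for key in ("median_umis_per_unit", "median_genes_per_unit", "pct_mito_umis"):
    print(f"{key}: {summary[key]:.1f}")
# Shallow units fail the gene floor; the mito ceiling would catch
# stressed/lysed material in real data.
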
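"""Generators: planted structure, conservation laws, seed determinism."""

import numpy as np
import pytest

import semibulk as sb
from semibulk.synthetic import (
    MARKER_MIN_FOLD,
    simulate_archetype_compositions,
)


class TestSimulateReference:
    def test_shapes_and_planted_counts(self):
        ref = sb.simulate_reference(
            200, 4, markers_per_type=10, mito_fraction=0.05, seed=1
        )
        assert ref.expression_fractions.shape == (200, 4)
        assert sum(len(v) for v in ref.marker_map.values()) == 40
        assert ref.mito_gene_mask.sum() == 10
        assert all(g.startswith("mt-") for g, m in
                   zip(ref.gene_ids, ref.mito_gene_mask) if m)

    def test_marker_folds_by_direct_scan(self):
        # brute-force check of the planted-marker guarantee
        ref = sb.simulate_reference(150, 3, markers_per_type=8, seed=7)
        f = ref.expression_fractions
        assert np.allclose(f.sum(axis=0), 1.0, atol=1e-9)
        assert np.all(f >= 0)
        for t, genes in ref.marker_map.items():
            j = ref.cell_types.index(t)
            for g in genes:
                i = ref.gene_ids.index(g)
                others = np.delete(f[i], j)
                assert f[i, j] >= MARKER_MIN_FOLD * others.max()

    def test_all_genes_markers_boundary(self):
        ref = sb.simulate_reference(40, 4, markers_per_type=10, seed=2)
        assert sum(len(v) for v in ref.marker_map.values()) == 40
        assert np.allclose(ref.expression_fractions.sum(axis=0), 1.0, atol=1e-9)

    def test_infeasible_marker_allocation(self):
        with pytest.raises(ValueError, match="marker"):
            sb.simulate_reference(39, 4, markers_per_type=10, seed=1)

    def test_seed_determinism(self):
        a = sb.simulate_reference(100, 3, markers_per_type=5, seed=9)
        b = sb.simulate_reference(100, 3, markers_per_type=5, seed=9)
        assert np.array_equal(a.expression_fractions, b.expression_fractions)
        assert a.marker_map == b.marker_map


class TestSimulateSemibulks:
    def test_depth_conservation_and_truth_rows(self, ref4):
        out = sb.simulate_semibulks(ref4, 40, depth=3000, seed=3)
        assert np.array_equal(
            out.counts.counts.sum(axis=0), out.depth_per_unit
        )
        assert np.allclose(out.true_compositions.fractions.sum(axis=1), 1.0)

    def test_degenerate_single_type_mixture(self, ref4):
        # composition forced onto one type: counts are a draw from that
        # column alone, so the expected count of gene g is depth * f[g]
        spec = sb.ColocalizationSpec(baseline_alpha=(100.0, 1e-4, 1e-4, 1e-4))
        out = sb.simulate_semibulks(ref4, 200, depth=2000, coloc=spec, seed=4)
        observed = out.counts.counts.sum(axis=1) / out.counts.counts.sum()
        assert np.corrcoef(observed, ref4.expression_fractions[:, 0])[0, 1] > 0.99

    def test_strength_zero_leaves_presence_independent(self, ref4):
        spec = sb.ColocalizationSpec(
            pairs=((ref4.cell_types[0], ref4.cell_types[1], 0.0),)
        )
        comp, boosted = sb.simulate_compositions(
            ref4.cell_types, 10_000, coloc=spec, seed=5
        )
        assert not boosted[(ref4.cell_types[0], ref4.cell_types[1])].any()
        pres = sb.dichotomize(comp)
        a = pres.column(ref4.cell_types[2]).astype(float)
        b = pres.column(ref4.cell_types[3]).astype(float)
        # Dirichlet rows carry a small negative cross-type correlation;
        # presence correlation must sit near it, far from the planted regime
        r = np.corrcoef(a, b)[0, 1]
        assert -0.35 < r < 0.05

    def test_unknown_type_in_coloc(self, ref4):
        spec = sb.ColocalizationSpec(pairs=(("podocyte", "stroma", 0.5),))
        with pytest.raises(KeyError, match="stroma"):
            sb.simulate_semibulks(ref4, 10, depth=100, coloc=spec, seed=1)

    def test_depth_range_and_determinism(self, ref4):
        a = sb.simulate_semibulks(ref4, 25, depth=(1000, 4000), seed=6)
        b = sb.simulate_semibulks(ref4, 25, depth=(1000, 4000), seed=6)
        assert np.array_equal(a.counts.counts, b.counts.counts)
        assert a.depth_per_unit.min() >= 1000
        assert a.depth_per_unit.max() <= 4000

    def test_overdispersion_inflates_variance(self, ref4):
        tight = sb.simulate_semibulks(ref4, 150, depth=3000, seed=8)
        wide = sb.simulate_semibulks(
            ref4, 150, depth=3000, seed=8, dirichlet_multinomial_phi=0.05
        )
        # per-gene across-unit variance grows under Dirichlet-multinomial
        assert wide.counts.counts.var(axis=1).mean() > (
            tight.counts.counts.var(axis=1).mean()
        )


class TestSimulateOccupancy:
    def test_lambda_zero_all_empty(self):
        table = sb.simulate_occupancy(0.0, 100, seed=1)
        assert table.droplet_counts[0] == 100
        assert table.droplet_counts[1:].sum() == 0

    def test_empty_fraction_matches_closed_form(self):
        n = 100_000
        table = sb.simulate_occupancy(0.66, n, seed=2)
        p0 = np.exp(-0.66)
        se = np.sqrt(p0 * (1 - p0) / n)
        assert abs(table.droplet_counts[0] / n - p0) < 3 * se

    @pytest.mark.parametrize("lam,n", [(0.03, 500), (0.66, 1000), (5.0, 200)])
    def test_total_conservation(self, lam, n):
        assert sb.simulate_occupancy(lam, n, seed=3).n_droplets == n

    def test_binning_above_kmax(self):
        table = sb.simulate_occupancy(5.0, 1000, kmax=2, seed=4)
        assert len(table.droplet_counts) == 3
        assert table.n_droplets == 1000


class TestSimulateBarnyard:
    def test_zero_rate_has_no_multiplets(self):
        table = sb.simulate_barnyard(500, 0.0, depth=1000, seed=1)
        assert not (table.truth == "multiplet").any()

    def test_pure_singlets_have_no_cross_counts(self):
        table = sb.simulate_barnyard(300, 0.0, depth=1000, purity=1.0, seed=2)
        is_a = table.truth == "A"
        assert (table.umi_b[is_a] == 0).all()
        assert (table.umi_a[~is_a] == 0).all()

    def test_depth_conservation(self):
        table = sb.simulate_barnyard(100, 0.1, depth=777, seed=3)
        assert ((table.umi_a + table.umi_b) == 777).all()

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            sb.simulate_barnyard(10, 1.5, depth=100, seed=1)
        with pytest.raises(ValueError):
            sb.simulate_barnyard(10, 0.1, depth=100, purity=0.4, seed=1)


class TestArchetypeCompositions:
    def test_rows_on_simplex_and_determinism(self):
        arch = [[20, 1, 1], [1, 20, 1]]
        a = simulate_archetype_compositions(list("XYZ"), 50, arch, seed=1)
        b = simulate_archetype_compositions(list("XYZ"), 50, arch, seed=1)
        assert np.array_equal(a.fractions, b.fractions)
        assert np.allclose(a.fractions.sum(axis=1), 1.0)

    def test_archetypes_dominate_their_type(self):
        arch = [[50, 1, 1]]
        c = simulate_archetype_compositions(list("XYZ"), 200, arch, seed=2)
        assert (c.column("X") > 0.5).mean() > 0.95
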
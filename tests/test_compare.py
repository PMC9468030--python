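"""Joint clustering, platform mixing, and cross-platform correlation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import semibulk as sb
from semibulk.compare import PLATFORM_SEMIBULK, PLATFORM_SPOT
from semibulk.synthetic import simulate_archetype_compositions

TYPES = list("ABCD")
SHARED_ARCHETYPES = [[20, 1, 1, 1], [1, 20, 1, 1], [1, 1, 20, 1]]


def pooled_sets(seed, sb_arch=SHARED_ARCHETYPES, st_arch=SHARED_ARCHETYPES, n=200):
    c_sb = simulate_archetype_compositions(TYPES, n, sb_arch, seed=seed)
    c_st = simulate_archetype_compositions(TYPES, n, st_arch, seed=10_000 + seed)
    return sb.combine_platforms(c_sb, c_st)


class TestJointCluster:
    def test_planted_archetypes_recovered_exactly(self):
        rng = np.random.default_rng(0)
        n = 60
        which = rng.integers(0, 2, size=2 * n)
        frac = np.vstack(
            [rng.dirichlet(SHARED_ARCHETYPES[w]) for w in which]
        )
        comp = sb.CompositionMatrix(
            unit_ids=[f"u{i}" for i in range(2 * n)],
            cell_types=TYPES,
            fractions=frac,
        )
        pooled = sb.combine_platforms(
            comp, simulate_archetype_compositions(TYPES, 5, SHARED_ARCHETYPES[:1], seed=1)
        )
        result = sb.joint_cluster(pooled, k=2, linkage_method="ward")
        # restrict ARI to the constructed units (the 5 spots are fillers)
        ari = adjusted_rand_score(which, result.cluster[: 2 * n])
        assert ari == 1.0

    def test_k_equal_n_gives_singletons(self):
        pooled = pooled_sets(3, n=10)
        result = sb.joint_cluster(pooled, k=20)
        assert len(set(result.cluster)) == 20

    def test_duplicate_rows_co_cluster(self):
        frac = np.array([[0.7, 0.1, 0.1, 0.1]] * 3 + [[0.1, 0.1, 0.1, 0.7]] * 3)
        comp = sb.CompositionMatrix(
            unit_ids=[f"u{i}" for i in range(6)], cell_types=TYPES, fractions=frac
        )
        pooled = sb.LabeledCompositionSet(
            composition=comp,
            platform=np.array([PLATFORM_SEMIBULK] * 3 + [PLATFORM_SPOT] * 3, dtype=object),
        )
        for k in (2, 3):
            result = sb.joint_cluster(pooled, k=k)
            assert len(set(result.cluster[:3])) == 1
            assert len(set(result.cluster[3:])) == 1

    def test_unit_order_invariance_up_to_relabeling(self):
        pooled = pooled_sets(5, n=50)
        result = sb.joint_cluster(pooled, k=3)
        rng = np.random.default_rng(2)
        perm = rng.permutation(pooled.composition.n_units)
        shuffled = sb.LabeledCompositionSet(
            composition=sb.CompositionMatrix(
                unit_ids=[pooled.composition.unit_ids[i] for i in perm],
                cell_types=pooled.composition.cell_types,
                fractions=pooled.composition.fractions[perm],
            ),
            platform=pooled.platform[perm],
        )
        result2 = sb.joint_cluster(shuffled, k=3)
        assert adjusted_rand_score(result.cluster[perm], result2.cluster) == 1.0

    def test_parameter_validation(self):
        pooled = pooled_sets(1, n=5)
        with pytest.raises(ValueError, match="k="):
            sb.joint_cluster(pooled, k=100)
        with pytest.raises(ValueError, match="metric"):
            sb.joint_cluster(pooled, k=2, metric="cosine")
        with pytest.raises(ValueError, match="ward"):
            sb.joint_cluster(pooled, k=2, metric="correlation", linkage_method="ward")


class TestMixingFraction:
    def test_identical_distributions_mix(self):
        # both platforms sample the same three niches: across 20 seeds the
        # semibulk units virtually always share clusters with spots
        mixes = [
            sb.mixing_fraction(
                sb.joint_cluster(pooled_sets(s), k=3), pooled_sets(s).platform
            )
            for s in range(20)
        ]
        assert min(mixes) >= 0.95

    def test_platform_private_niche_depresses_mixing(self):
        # spots never sample the third niche: its cluster is semibulk-only
        for s in range(20):
            pooled = pooled_sets(s, st_arch=SHARED_ARCHETYPES[:2])
            mix = sb.mixing_fraction(sb.joint_cluster(pooled, k=3), pooled.platform)
            assert mix < 0.95

    def test_k_one_is_always_fully_mixed(self):
        pooled = pooled_sets(7, n=30)
        assert sb.mixing_fraction(sb.joint_cluster(pooled, k=1), pooled.platform) == 1.0

    def test_single_platform_is_an_error(self):
        pooled = pooled_sets(1, n=10)
        labels = np.array([PLATFORM_SEMIBULK] * 20, dtype=object)
        with pytest.raises(ValueError, match="both platforms"):
            sb.mixing_fraction(sb.joint_cluster(pooled, k=2), labels)


class TestMembershipTable:
    def test_total_conservation(self):
        pooled = pooled_sets(9)
        result = sb.joint_cluster(pooled, k=3)
        table = sb.cluster_membership_table(result, pooled.platform)
        assert table.to_numpy().sum() == pooled.composition.n_units

    def test_private_niche_cluster_is_one_platform(self):
        pooled = pooled_sets(4, st_arch=SHARED_ARCHETYPES[:2])
        result = sb.joint_cluster(pooled, k=3)
        table = sb.cluster_membership_table(result, pooled.platform)
        assert (table[PLATFORM_SPOT] == 0).any()


class TestExpressionCorrelation:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        v = rng.integers(0, 100, size=50).astype(float)
        assert sb.expression_correlation(v, v) == pytest.approx(1.0)

    def test_symmetry_and_scale_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 100, size=80).astype(float)
        b = rng.integers(0, 100, size=80).astype(float)
        r1 = sb.expression_correlation(a, b)
        assert sb.expression_correlation(b, a) == pytest.approx(r1)
        assert sb.expression_correlation(a * 12, b) == pytest.approx(r1)

    def test_series_align_on_shared_genes(self):
        a = pd.Series([5.0, 3.0, 2.0, 9.0], index=list("wxyz"))
        b = pd.Series([4.0, 2.0, 1.0, 7.0], index=list("xyzq"))
        r = sb.expression_correlation(a, b)
        assert -1 <= r <= 1

    def test_same_composition_correlates_higher_than_disjoint(self, ref_cells):
        cells, labels = ref_cells
        same = []
        cross = []
        for seed in range(20):
            a = sb.pseudo_bulk(cells, labels, [0.5, 0.5, 0, 0], 10_000, seed=seed)
            b = sb.pseudo_bulk(cells, labels, [0.5, 0.5, 0, 0], 10_000, seed=500 + seed)
            c = sb.pseudo_bulk(cells, labels, [0, 0, 0.5, 0.5], 10_000, seed=900 + seed)
            same.append(sb.expression_correlation(a, b))
            cross.append(sb.expression_correlation(a, c))
        assert min(same) > 0.9
        assert np.mean(cross) < np.mean(same)
        assert all(s > c for s, c in zip(same, cross))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="3 shared"):
            sb.expression_correlation(np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="variance|zero"):
            sb.expression_correlation(
                np.array([0.0, 0.0, 0.0]), np.array([1.0, 2.0, 3.0])
            )
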
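import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import braycurtis as scipy_bc
from scipy.spatial.distance import squareform

from planctostrat import (
    DistanceMatrix,
    alpha_table,
    bray_curtis,
    bray_curtis_matrix,
    make_community,
    observed,
    rarefaction_curve,
    shannon,
    single_linkage,
)
from planctostrat.diversity import rarefaction_resampled
from planctostrat.synthetic_data import CommunityConfig

from conftest import random_distance_matrix


# ---------------------------------------------------------------------------
# Brute-force single-linkage oracle: O(n^3) agglomeration over index sets
# ---------------------------------------------------------------------------

def oracle_single_linkage_heights(d):
    n = d.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            dist = min(d[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or dist < best[0]:
                best = (dist, a, b)
        dist, a, b = best
        heights.append(dist)
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return heights


class TestShannon:
    @pytest.mark.parametrize("counts,expected", [
        ((5, 5, 5, 5), 2.0),
        ((10, 0, 0), 0.0),
        ((1, 2, 3), 1.4591),
    ])
    def test_known_values_bits(self, counts, expected):
        assert shannon(counts) == pytest.approx(expected, abs=1e-4)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            shannon([0, 0, 0])

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.integers(0, 1000), min_size=2, max_size=20).filter(
            lambda c: sum(c) > 0
        ),
        st.integers(2, 50),
    )
    def test_invariant_under_rescaling(self, counts, k):
        scaled = [k * c for c in counts]
        assert shannon(scaled) == pytest.approx(shannon(counts), abs=1e-9)

    def test_bounded_by_log2_richness(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c = rng.integers(0, 50, size=12)
            if c.sum() == 0:
                continue
            assert shannon(c) <= np.log2(max(observed(c), 1)) + 1e-9

    def test_matches_skbio(self):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        c = np.array([4, 0, 9, 1, 7])
        assert shannon(c) == pytest.approx(
            float(skbio_alpha.shannon(c, base=2)), abs=1e-12
        )


class TestObserved:
    @pytest.mark.parametrize("counts,expected", [
        ((0, 0, 0), 0), ((1, 0, 7), 2), ((3,), 1),
    ])
    def test_counts_positive_entries(self, counts, expected):
        assert observed(counts) == expected

    def test_deep_multinomial_approaches_pool_size(self):
        rng = np.random.default_rng(1)
        probs = rng.dirichlet(np.ones(50))
        draw = rng.multinomial(10 ** 6, probs)
        assert observed(draw) == 50


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        assert bray_curtis([3, 4, 5], [3, 4, 5]) == 0.0
        assert bray_curtis([5, 0, 0], [0, 2, 3]) == 1.0

    def test_closed_form_example(self):
        assert bray_curtis((6, 4, 0), (2, 4, 4)) == pytest.approx(0.4, abs=1e-12)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            bray_curtis([0, 0], [1, 2])

    def test_symmetry_and_scipy_agreement(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            u = rng.integers(0, 40, size=15)
            v = rng.integers(0, 40, size=15)
            if u.sum() == 0 or v.sum() == 0:
                continue
            assert bray_curtis(u, v) == pytest.approx(bray_curtis(v, u))
            assert bray_curtis(u, v) == pytest.approx(
                float(scipy_bc(u, v)), abs=1e-12
            )


class TestSingleLinkage:
    def test_hand_agglomeration(self):
        dm = DistanceMatrix(
            ids=["A", "B", "C"],
            d=np.array([[0, 1, 5], [1, 0, 3], [5, 3, 0]], dtype=float),
        )
        tree = single_linkage(dm)
        assert tree.heights == [1.0, 3.0]
        a, b, h, new = tree.merges[0]
        assert {a, b} == {0, 1} and new == 3

    def test_all_equal_distances_tie_rule(self):
        n = 4
        d = np.ones((n, n)) - np.eye(n)
        dm = DistanceMatrix(ids=["s1", "s2", "s3", "s4"], d=d)
        tree = single_linkage(dm)
        assert tree.heights == [1.0, 1.0, 1.0]
        # lexicographic tie rule: first merge joins the two smallest ids
        assert {tree.merges[0][0], tree.merges[0][1]} == {0, 1}

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle_on_random_8x8(self, seed):
        rng = np.random.default_rng(seed)
        dm = random_distance_matrix(rng, 8)
        tree = single_linkage(dm)
        assert tree.heights == pytest.approx(
            oracle_single_linkage_heights(dm.d)
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_heights(self, seed):
        rng = np.random.default_rng(100 + seed)
        dm = random_distance_matrix(rng, 9)
        tree = single_linkage(dm)
        z = linkage(squareform(dm.d), method="single")
        assert tree.heights == pytest.approx(list(z[:, 2]))

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            dm = random_distance_matrix(rng, 7)
            h = single_linkage(dm).heights
            assert all(b >= a - 1e-12 for a, b in zip(h, h[1:]))

    def test_single_sample_rejected(self):
        dm = DistanceMatrix(ids=["only"], d=np.zeros((1, 1)))
        with pytest.raises(ValueError, match="at least 2"):
            single_linkage(dm)


class TestRarefaction:
    def test_closed_form_two_taxa(self):
        (depth, richness), = rarefaction_curve([5, 5], [2])
        assert depth == 2
        assert richness == pytest.approx(1.5556, abs=1e-4)

    def test_depth_equal_to_total_gives_observed(self):
        counts = [7, 1, 12, 3]
        (_, richness), = rarefaction_curve(counts, [sum(counts)])
        assert richness == pytest.approx(4.0, abs=1e-9)

    def test_depth_one_gives_one(self):
        (_, richness), = rarefaction_curve([9, 2, 4], [1])
        assert richness == pytest.approx(1.0, abs=1e-12)

    def test_depth_beyond_total_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            rarefaction_curve([2, 2], [5])

    def test_monotone_in_depth(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 30, size=25)
        counts[0] = 5
        depths = list(range(1, int(counts.sum()), 7))
        curve = rarefaction_curve(counts, depths)
        vals = [v for _, v in curve]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_monte_carlo_parity(self):
        counts = [40, 25, 10, 5, 1]
        analytic = dict(rarefaction_curve(counts, [10, 40]))
        resampled = dict(
            rarefaction_resampled(counts, [10, 40], n_iter=400, seed=5)
        )
        for d in (10, 40):
            assert resampled[d] == pytest.approx(analytic[d], abs=0.15)


class TestPipelineAlpha:
    def test_deep_layers_have_higher_observed_richness(self, community):
        """Pools (10,10,40,40) must show the depth gradient in observed ASVs."""
        from planctostrat import filter_phylum

        table, taxonomy, _ = community
        target, _ = filter_phylum(table, taxonomy, "Planctomycetota")
        alpha = alpha_table(target)
        by_layer = alpha.groupby("layer")["observed_asvs"].mean()
        deep = (by_layer["below_dcm"] + by_layer["mesopelagic"]) / 2
        shallow = (by_layer["surface"] + by_layer["dcm"]) / 2
        assert deep > shallow

    def test_zero_read_sample_dropped_from_beta_with_warning(self, caplog):
        import logging

        from planctostrat import AsvTable

        table = AsvTable(
            sample_ids=["s1", "s2", "s3"],
            asv_ids=["a", "b"],
            counts=np.array([[5, 5], [0, 0], [1, 9]]),
            layer_of={"s1": "surface", "s2": "dcm", "s3": "mesopelagic"},
        )
        with caplog.at_level(logging.WARNING):
            dm = bray_curtis_matrix(table)
        assert dm.ids == ["s1", "s3"]
        assert "s2" in caplog.text
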
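"""Region query: TD-weighted aggregation of layered labels over a mask."""

import numpy as np
import pytest

import regionconnect as rc
from regionconnect.connectome import EdgeCountField

E = rc.Edge


@pytest.fixture(scope="module")
def phantom_query(canonical_phantom, canonical_field):
    labels, _, truth = canonical_phantom
    field, _ = canonical_field
    ml = rc.build_multilayer_labels(field, n_layers=60)
    td = rc.track_density_map(field)
    lookup = rc.NodeLookup({i: f"node_{i:02d}" for i in range(1, 5)})
    return labels, truth, field, ml, td, lookup


def mask_from(voxels, shape, affine):
    data = np.zeros(shape, dtype=np.int8)
    for v in voxels:
        data[tuple(v)] = 1
    return rc.VolumeGrid(data, affine)


def tiny_two_voxel_setup():
    """Voxel A {S12=3, S13=1} (TD 4), voxel B {S12=2, S23=4} (TD 6)."""
    field = EdgeCountField(
        shape=(3, 1, 1), affine=np.eye(4),
        counts={(0, 0, 0): {E(1, 2): 3, E(1, 3): 1},
                (2, 0, 0): {E(1, 2): 2, E(2, 3): 4}},
    )
    lookup = rc.NodeLookup({1: "one", 2: "two", 3: "three"})
    return field, lookup


class TestRegionconnect:
    def test_two_voxel_region_probabilities_and_ranking(self):
        field, lookup = tiny_two_voxel_setup()
        ml = rc.build_multilayer_labels(field, n_layers=10)
        td = rc.track_density_map(field)
        mask = mask_from([(0, 0, 0), (2, 0, 0)], (3, 1, 1), np.eye(4))
        result = rc.regionconnect(mask, ml, td, lookup)
        got = [(e.edge, e.probability) for e in result.entries]
        assert [e for e, _ in got] == [E(1, 2), E(2, 3), E(1, 3)]
        assert got[0][1] == pytest.approx(5 / 10, abs=1e-6)
        assert got[1][1] == pytest.approx(4 / 10, abs=1e-6)
        assert got[2][1] == pytest.approx(1 / 10, abs=1e-6)
        assert result.region_voxel_count == 2
        assert result.region_td_sum == pytest.approx(10)

    def test_single_voxel_mask_returns_that_voxels_confidences(self, phantom_query):
        labels, _, field, ml, td, lookup = phantom_query
        vox = next(iter(field.counts))
        mask = mask_from([vox], labels.shape, labels.affine)
        result = rc.regionconnect(mask, ml, td, lookup)
        expected = dict(ml.voxel_layers(vox))
        assert len(result.entries) == len(expected)
        for entry in result.entries:
            assert entry.probability == pytest.approx(expected[entry.edge], abs=1e-6)

    def test_names_come_from_the_lookup(self):
        field, lookup = tiny_two_voxel_setup()
        ml = rc.build_multilayer_labels(field, n_layers=10)
        td = rc.track_density_map(field)
        mask = mask_from([(0, 0, 0)], (3, 1, 1), np.eye(4))
        result = rc.regionconnect(mask, ml, td, lookup)
        assert (result.entries[0].name_i, result.entries[0].name_j) == ("one", "two")

    def test_crossing_region_ranks_the_thirty_streamline_edge_first(self, phantom_query):
        labels, truth, _, ml, td, lookup = phantom_query
        mask = mask_from(truth.crossing_voxels, labels.shape, labels.affine)
        result = rc.regionconnect(mask, ml, td, lookup)
        assert result.entries[0].edge == E(1, 2)
        assert result.entries[1].edge == E(3, 4)
        assert result.entries[0].probability == pytest.approx(0.75, abs=0.1)

    def test_probabilities_sum_to_one_when_untruncated(self, phantom_query):
        labels, truth, _, ml, td, lookup = phantom_query
        mask = mask_from(truth.crossing_voxels, labels.shape, labels.affine)
        result = rc.regionconnect(mask, ml, td, lookup)
        assert sum(e.probability for e in result.entries) == pytest.approx(1.0, abs=1e-6)

    def test_empty_mask_and_zero_td_region_are_errors(self, phantom_query):
        labels, _, field, ml, td, lookup = phantom_query
        with pytest.raises(ValueError, match="empty"):
            rc.regionconnect(mask_from([], labels.shape, labels.affine), ml, td, lookup)
        untraversed = [v for v in np.ndindex(*labels.shape)
                       if v not in field.counts][:4]
        with pytest.raises(ValueError, match="no traversed"):
            rc.regionconnect(mask_from(untraversed, labels.shape, labels.affine),
                             ml, td, lookup)

    def test_grid_mismatch_is_a_hard_error(self, phantom_query):
        labels, truth, _, ml, td, lookup = phantom_query
        shifted = np.array(labels.affine)
        shifted[0, 3] += 2.0
        mask = mask_from(truth.crossing_voxels, labels.shape, shifted)
        with pytest.raises(Exception, match="resample"):
            rc.regionconnect(mask, ml, td, lookup)


class TestOracleEquivalence:
    def test_direct_route_matches_layered_route_on_random_masks(self, phantom_query):
        labels, _, field, ml, td, lookup = phantom_query
        rng = np.random.default_rng(42)
        traversed = list(field.counts)
        for _ in range(50):
            k = rng.integers(1, len(traversed) + 1)
            chosen = [traversed[i] for i in rng.choice(len(traversed), size=k, replace=False)]
            mask = mask_from(chosen, labels.shape, labels.affine)
            a = rc.regionconnect(mask, ml, td, lookup)
            b = rc.regionconnect_direct(mask, field, lookup)
            assert [e.edge for e in a.entries] == [e.edge for e in b.entries]
            for ea, eb in zip(a.entries, b.entries):
                assert ea.probability == pytest.approx(eb.probability, abs=1e-6)

    def test_whole_field_mask_is_proportional_to_total_edge_counts(self, phantom_query):
        labels, _, field, _, _, lookup = phantom_query
        mask = mask_from(list(field.counts), labels.shape, labels.affine)
        result = rc.regionconnect_direct(mask, field, lookup)
        totals = {}
        td_total = 0
        for per_voxel in field.counts.values():
            for e, s in per_voxel.items():
                totals[e] = totals.get(e, 0) + s
                td_total += s
        for entry in result.entries:
            assert entry.probability == pytest.approx(totals[entry.edge] / td_total)

    def test_disjoint_clusters_equal_the_combined_mask(self, phantom_query):
        labels, truth, field, _, _, lookup = phantom_query
        cluster_a = sorted(truth.crossing_voxels)[:3]
        far = [v for v in field.counts if v not in truth.crossing_voxels][:3]
        combined = mask_from(cluster_a + far, labels.shape, labels.affine)
        result = rc.regionconnect_direct(combined, field, lookup)
        # recompute by summing S over the union straight from the field
        sums, denom = {}, 0
        for v in cluster_a + far:
            for e, s in field.counts.get(v, {}).items():
                sums[e] = sums.get(e, 0) + s
                denom += s
        for entry in result.entries:
            assert entry.probability == pytest.approx(sums[entry.edge] / denom)


class TestInvariants:
    def test_scale_invariance_of_probabilities(self, phantom_query):
        labels, truth, field, _, _, lookup = phantom_query
        scaled = EdgeCountField(
            shape=field.shape, affine=field.affine,
            counts={v: {e: 7 * s for e, s in per.items()} for v, per in field.counts.items()},
        )
        mask = mask_from(truth.crossing_voxels, labels.shape, labels.affine)
        a = rc.regionconnect_direct(mask, field, lookup)
        b = rc.regionconnect_direct(mask, scaled, lookup)
        for ea, eb in zip(a.entries, b.entries):
            assert ea.edge == eb.edge
            assert ea.probability == pytest.approx(eb.probability, abs=1e-12)

    def test_td_mass_monotone_under_mask_growth(self, phantom_query):
        labels, _, field, ml, td, lookup = phantom_query
        voxels = sorted(field.counts)
        small = mask_from(voxels[:5], labels.shape, labels.affine)
        large = mask_from(voxels[:20], labels.shape, labels.affine)
        assert (rc.regionconnect(large, ml, td, lookup).region_td_sum
                >= rc.regionconnect(small, ml, td, lookup).region_td_sum)

    def test_truncation_never_inflates_surviving_probabilities(self, phantom_query):
        """With a shared full-TD denominator, dropping layers can only lose mass."""
        labels, truth, field, _, td, lookup = phantom_query
        mask = mask_from(truth.crossing_voxels, labels.shape, labels.affine)
        full = rc.regionconnect(mask, rc.build_multilayer_labels(field, 60), td, lookup)
        truncated = rc.regionconnect(mask, rc.build_multilayer_labels(field, 1), td, lookup)
        full_p = {e.edge: e.probability for e in full.entries}
        for entry in truncated.entries:
            assert entry.probability <= full_p[entry.edge] + 1e-9
        assert sum(e.probability for e in truncated.entries) <= 1.0 + 1e-6

    def test_result_ordering_is_strict_and_tie_broken(self):
        field = EdgeCountField(
            shape=(1, 1, 1), affine=np.eye(4),
            counts={(0, 0, 0): {E(1, 3): 2, E(1, 2): 2, E(2, 3): 1}},
        )
        lookup = rc.NodeLookup({1: "a", 2: "b", 3: "c"})
        mask = mask_from([(0, 0, 0)], (1, 1, 1), np.eye(4))
        result = rc.regionconnect_direct(mask, field, lookup)
        assert [e.edge for e in result.entries] == [E(1, 2), E(1, 3), E(2, 3)]

    def test_top_n_truncates_for_display_only(self, phantom_query):
        labels, truth, field, ml, td, lookup = phantom_query
        mask = mask_from(truth.crossing_voxels, labels.shape, labels.affine)
        result = rc.regionconnect(mask, ml, td, lookup)
        top1 = result.top(1)
        assert len(top1.entries) == 1
        assert top1.entries[0].edge == result.entries[0].edge
        assert top1.region_td_sum == result.region_td_sum
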
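"""Aggregation (partition meet), label propagation, fragmentation reporting."""

import warnings

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from ailp import (
    Parcellation,
    aggregate,
    ailp,
    fragmentation_report,
    generate_toy_lattice,
    label_propagation,
)
from ailp.consensus import _neighborhood_vote
from conftest import comembership, random_partition


def part(labels, provenance="truth"):
    return Parcellation(labels=np.asarray(labels), provenance=provenance)


class TestAggregate:
    def test_idempotence_up_to_relabeling(self):
        p = part([3, 3, 1, 1, 7])
        out = aggregate(p, p)
        assert adjusted_rand_score(out.labels, p.labels) == 1.0

    def test_worked_example_of_ordered_pairs(self):
        # pairs (a,x),(a,y),(b,y),(b,y) -> three aROIs {1},{2},{3,4}
        out = aggregate(part([0, 0, 1, 1]), part([0, 1, 1, 1]))
        assert np.array_equal(out.labels, [0, 1, 2, 2])

    def test_meet_refines_both_inputs(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(5, 60))
            p1, p2 = random_partition(n, rng), random_partition(n, rng)
            out = aggregate(p1, p2)
            assert out.n_rois >= max(p1.n_rois, p2.n_rois)

    def test_comembership_is_elementwise_and(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            n = int(rng.integers(5, 100))
            p1, p2 = random_partition(n, rng), random_partition(n, rng)
            out = aggregate(p1, p2)
            expected = comembership(p1.labels) & comembership(p2.labels)
            assert np.array_equal(comembership(out.labels), expected)

    def test_mismatched_voxel_sets_are_an_error(self):
        with pytest.raises(ValueError, match="same voxel set"):
            aggregate(part([0, 1]), part([0, 1, 2]))

    def test_provenance_is_aroi(self):
        assert aggregate(part([0, 1]), part([0, 0])).provenance == "aROI"


class TestNeighborhoodVote:
    """The per-voxel reassignment rule, in its three canonical situations."""

    def test_three_to_one_majority_wins(self):
        rng = np.random.default_rng(0)
        votes = np.array([1, 1, 1, 2])  # three orange, one blue
        assert _neighborhood_vote(votes, rng) == 1

    def test_five_vote_plurality_keeps_the_label(self):
        rng = np.random.default_rng(0)
        votes = np.array([2, 2, 2, 2, 2, 1, 3])  # five blue, one orange, one green
        assert _neighborhood_vote(votes, rng) == 2

    def test_exact_tie_is_broken_uniformly_at_random(self):
        votes = np.array([4, 5])  # one yellow, one blue
        outcomes = {
            _neighborhood_vote(votes, np.random.default_rng(s)) for s in range(50)
        }
        assert outcomes == {4, 5}

    def test_tie_break_is_seed_reproducible(self):
        votes = np.array([4, 5])
        a = _neighborhood_vote(votes, np.random.default_rng(99))
        b = _neighborhood_vote(votes, np.random.default_rng(99))
        assert a == b


class TestLabelPropagation:
    def test_surrounded_voxel_joins_the_majority_cluster(self):
        # center has neighbors orange x3 + blue x1; LP flips it to orange
        labels = np.array([[1, 1, 1], [1, 2, 2], [1, 1, 1]])
        lattice, init = generate_toy_lattice(labels)
        out = label_propagation(lattice, init, seed=0, densify=False)
        center = 4  # (1,1) in row-major order
        assert out.labels[center] == 1

    def test_stable_initialization_is_returned_unchanged(self):
        labels = np.array([[0, 0, 1, 1], [0, 0, 1, 1]])
        lattice, init = generate_toy_lattice(labels)
        out = label_propagation(lattice, init, seed=3, densify=False)
        assert np.array_equal(out.labels, init.labels)

    def test_output_labels_are_a_subset_of_init_labels(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(10, 20, size=(5, 5, 2))
        lattice, init = generate_toy_lattice(labels)
        out = label_propagation(lattice, init, seed=1, densify=False)
        assert set(out.labels) <= set(init.labels)

    def test_checkerboard_stabilizes_within_the_sweep_budget(self):
        labels = np.indices((4, 4)).sum(axis=0) % 2
        lattice, init = generate_toy_lattice(labels.astype(int))
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # the max_sweeps guard must not fire
            out = label_propagation(lattice, init, seed=2)
        assert out.n_voxels == 16

    def test_fixed_seed_gives_bit_identical_output(self):
        rng = np.random.default_rng(11)
        labels = rng.integers(0, 6, size=(6, 6, 2))
        lattice, init = generate_toy_lattice(labels)
        a = label_propagation(lattice, init, seed=42)
        b = label_propagation(lattice, init, seed=42)
        assert np.array_equal(a.labels, b.labels)

    def test_degree_zero_voxels_keep_their_init_label(self):
        from ailp import LatticeGraph

        g = LatticeGraph(coords=np.zeros((3, 3)), edges=np.array([[0, 1]]))
        out = label_propagation(g, part([5, 5, 9]), seed=0, densify=False)
        assert out.labels[2] == 9

    def test_mismatched_init_is_an_error(self):
        lattice, _ = generate_toy_lattice(np.zeros((2, 2), dtype=int))
        with pytest.raises(ValueError, match="total"):
            label_propagation(lattice, part([0, 1]), seed=0)


class TestAilp:
    def test_identical_stable_inputs_pass_through(self):
        labels = np.array([[0, 0, 1, 1], [0, 0, 1, 1]])
        lattice, p = generate_toy_lattice(labels)
        out = ailp(lattice, p, p, seed=0)
        assert adjusted_rand_score(out.labels, p.labels) == 1.0
        assert out.provenance == "lpROI"

    def test_shifted_blocks_fragment_then_heal(self):
        """Two block parcellations offset by one column on a 10x10 sheet:
        the meet has more ROIs than either input, LP has no more than the
        meet."""
        cols = np.tile(np.arange(10), (10, 1))
        p1 = (cols // 3).astype(int)
        p2 = (np.clip(cols + 1, 0, 9) // 3).astype(int)
        lattice, part1 = generate_toy_lattice(p1)
        _, part2 = generate_toy_lattice(p2)
        agg = aggregate(part1, part2)
        assert agg.n_rois > max(part1.n_rois, part2.n_rois)
        out = ailp(lattice, part1, part2, seed=4)
        assert out.n_rois <= agg.n_rois

    def test_small_roi_fraction_drops_after_propagation(self, standard_pipeline):
        frag = standard_pipeline["fragmentation"]
        assert frag["lproi"].frac_lt5 < frag["aroi"].frac_lt5


class TestFragmentationReport:
    def test_uniform_modules(self):
        rep = fragmentation_report(part(np.repeat(np.arange(10), 10)))
        assert rep.n_rois == 10
        assert rep.size_mean == 10
        assert rep.size_sd == 0
        assert rep.size_median == 10
        assert rep.frac_lt5 == 0

    def test_mixed_sizes_by_inspection(self):
        sizes = [1, 2, 3, 10]
        labels = np.repeat(np.arange(4), sizes)
        rep = fragmentation_report(part(labels))
        assert rep.n_rois == 4
        assert rep.frac_lt5 == 0.75
        assert rep.frac_lt10 == 0.75
        assert rep.size_median == 2.5

    def test_single_module(self):
        rep = fragmentation_report(part(np.zeros(7, dtype=int)))
        assert rep.n_rois == 1
        assert rep.frac_lt5 == 0.0
        assert fragmentation_report(part(np.zeros(3, dtype=int))).frac_lt5 == 1.0
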
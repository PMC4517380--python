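"""Lattice construction and multitaper coherence weighting."""

import numpy as np
import pytest

from ailp import (
    CoherenceSpectrum,
    VolumeGrid,
    band_weight,
    binarize_mask,
    build_lattice,
    multitaper_msc,
    weight_lattice,
)
from conftest import lattice_oracle


class TestBinarizeMask:
    def test_saturated_volume_is_all_true(self):
        assert binarize_mask(np.ones((2, 2, 2))).all()

    def test_threshold_is_strict(self):
        vol = np.full((2, 2, 2), 0.5)
        vol[0, 0, 0] = 0.6
        mask = binarize_mask(vol)
        assert mask.sum() == 1  # exactly-0.5 voxels excluded

    def test_counts_by_inspection(self):
        vol = np.array([0.2, 0.4, 0.6, 0.8]).reshape(4, 1, 1)
        assert binarize_mask(vol).sum() == 2

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError, match="empty mask"):
            binarize_mask(np.zeros((2, 2, 2)))

    def test_nonfinite_values_rejected(self):
        vol = np.ones((2, 2, 2))
        vol[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            binarize_mask(vol)


def _grid(mask, meta):
    return VolumeGrid(mask=np.asarray(mask, bool), meta_region=np.asarray(meta))


class TestBuildLattice:
    def test_minimal_two_voxel_lattice(self):
        g = _grid(np.ones((2, 1, 1)), np.ones((2, 1, 1), dtype=int))
        lat = build_lattice(g)
        assert (lat.n, lat.m) == (2, 1)

    def test_full_cube_has_twelve_face_adjacencies(self):
        g = _grid(np.ones((2, 2, 2)), np.ones((2, 2, 2), dtype=int))
        lat = build_lattice(g)
        assert (lat.n, lat.m) == (8, 12)

    def test_meta_region_boundary_blocks_the_edge(self):
        meta = np.array([1, 2]).reshape(2, 1, 1)
        lat = build_lattice(_grid(np.ones((2, 1, 1)), meta))
        assert (lat.n, lat.m) == (2, 0)

    def test_degree_never_exceeds_six(self):
        rng = np.random.default_rng(0)
        mask = rng.random((4, 4, 4)) < 0.7
        mask[0, 0, 0] = True
        meta = np.where(mask, 1, 0)
        lat = build_lattice(_grid(mask, meta))
        deg = np.zeros(lat.n)
        np.add.at(deg, lat.edges.ravel(), 1)
        assert deg.max() <= 6

    def test_agrees_with_allpairs_bruteforce_on_random_grids(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            dims = tuple(rng.integers(2, 5, size=3))
            mask = rng.random(dims) < 0.6
            mask.flat[0] = True
            meta = np.where(mask, rng.integers(1, 4, size=dims), 0)
            lat = build_lattice(_grid(mask, meta))
            coords, edges = lattice_oracle(mask, meta)
            assert np.array_equal(lat.coords, coords)
            assert [tuple(e) for e in lat.edges] == edges

    def test_components_never_span_meta_regions(self):
        import networkx as nx

        rng = np.random.default_rng(9)
        mask = rng.random((5, 5, 3)) < 0.8
        mask.flat[0] = True
        meta = np.where(mask, rng.integers(1, 4, size=mask.shape), 0)
        lat = build_lattice(_grid(mask, meta))
        g = nx.Graph()
        g.add_nodes_from(range(lat.n))
        g.add_edges_from(map(tuple, lat.edges))
        for comp in nx.connected_components(g):
            assert len({lat.meta_region[i] for i in comp}) == 1


class TestMultitaperMsc:
    def test_self_coherence_is_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=256)
        spec = multitaper_msc(x, x, sampling_interval_s=2.0)
        assert np.allclose(spec.msc, 1.0, atol=1e-9)

    def test_independent_noise_has_low_band_coherence(self):
        rng = np.random.default_rng(12345)
        x, y = rng.normal(size=(2, 4096))
        spec = multitaper_msc(x, y, sampling_interval_s=2.0)
        mean_band = band_weight(spec, 0.005, 0.12)
        # bias-limited floor for 7 tapers; frozen regression value ~0.13
        assert mean_band < 0.2

    def test_pure_delay_leaves_coherence_at_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=512)
        spec = multitaper_msc(x[:-1], x[1:], sampling_interval_s=2.0)
        # phase shifts do not reduce magnitude coherence
        assert band_weight(spec, 0.005, 0.12) > 0.98

    def test_zero_variance_input_is_an_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            multitaper_msc(np.ones(64), np.arange(64.0), sampling_interval_s=2.0)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            multitaper_msc(np.arange(8.0), np.arange(8.0), sampling_interval_s=2.0)


class TestBandWeight:
    @pytest.mark.parametrize("level", [0.0, 0.5, 1.0])
    def test_constant_msc_integrates_to_its_level(self, level):
        f = np.linspace(0.0, 0.25, 100)
        spec = CoherenceSpectrum(frequencies=f, msc=np.full(100, level))
        assert band_weight(spec) == pytest.approx(level)

    def test_unnormalized_area_scales_with_band_width(self):
        f = np.linspace(0.0, 0.25, 101)
        spec = CoherenceSpectrum(frequencies=f, msc=np.ones(101))
        raw = band_weight(spec, 0.005, 0.12, normalize=False)
        assert raw == pytest.approx(0.115, abs=0.005)

    def test_sparse_band_is_an_error(self):
        spec = CoherenceSpectrum(
            frequencies=np.array([0.0, 0.1, 0.2]), msc=np.ones(3)
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            band_weight(spec, 0.11, 0.19)

    def test_band_beyond_nyquist_is_an_error(self):
        spec = CoherenceSpectrum(
            frequencies=np.linspace(0, 0.1, 50), msc=np.ones(50)
        )
        with pytest.raises(ValueError, match="Nyquist"):
            band_weight(spec, 0.005, 0.2)


class TestWeightLattice:
    def test_identical_series_weight_near_one(self):
        g = _grid(np.ones((2, 1, 1)), np.ones((2, 1, 1), dtype=int))
        lat = build_lattice(g)
        rng = np.random.default_rng(2)
        series = rng.normal(size=145)
        bold = np.broadcast_to(series, (2, 1, 1, 145)).copy()
        w = weight_lattice(lat, bold, 2.0)
        assert w.weights[0] == pytest.approx(1.0, abs=1e-9)

    def test_weights_invariant_to_global_scaling(self):
        g = _grid(np.ones((2, 2, 1)), np.ones((2, 2, 1), dtype=int))
        lat = build_lattice(g)
        rng = np.random.default_rng(3)
        bold = rng.normal(size=(2, 2, 1, 145))
        w1 = weight_lattice(lat, bold, 2.0)
        w2 = weight_lattice(lat, bold * 7.5, 2.0)
        assert np.allclose(w1.weights, w2.weights)

    def test_flat_voxel_is_reported_by_coordinate(self):
        g = _grid(np.ones((2, 1, 1)), np.ones((2, 1, 1), dtype=int))
        lat = build_lattice(g)
        bold = np.random.default_rng(0).normal(size=(2, 1, 1, 64))
        bold[1, 0, 0] = 5.0
        with pytest.raises(ValueError, match=r"\(1, 0, 0\)"):
            weight_lattice(lat, bold, 2.0)

    def test_weights_bounded_in_unit_interval(self, standard_phantom):
        ds = standard_phantom
        lat = build_lattice(ds.grid)
        w = weight_lattice(lat, ds.bold_t1, ds.spec.sampling_interval_s)
        assert w.weights.min() >= 0.0 and w.weights.max() <= 1.0
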
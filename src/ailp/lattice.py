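"""Anatomically constrained voxel lattice graphs weighted by band-limited coherence.

The voxelwise brain network is a 6-connectivity lattice over in-mask voxels,
with edges forbidden across meta-region (coarse anatomical territory)
boundaries.  Each retained edge is weighted by the area under the multitaper
magnitude-squared-coherence (MSC) spectrum of its two voxel time series over a
low-frequency band (default 0.005-0.12 Hz, the canonical resting-state band).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import dpss

#: Low-frequency band of interest for resting-state BOLD coherence, in Hz.
DEFAULT_BAND = (0.005, 0.12)
#: Multitaper time-half-bandwidth product (standard practice).
DEFAULT_NW = 4.0
#: Number of Slepian tapers; 2*NW - 1 keeps only well-concentrated tapers.
DEFAULT_N_TAPERS = 7

__all__ = [
    "VolumeGrid",
    "LatticeGraph",
    "CoherenceSpectrum",
    "binarize_mask",
    "build_lattice",
    "multitaper_msc",
    "band_weight",
    "weight_lattice",
    "DEFAULT_BAND",
    "DEFAULT_NW",
    "DEFAULT_N_TAPERS",
]


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D voxel raster carrying mask membership and a meta-region ID per voxel.

    Parameters
    ----------
    mask : (nx, ny, nz) bool array
        True for voxels inside the analysis (gray-matter) mask.
    meta_region : (nx, ny, nz) int array
        Positive meta-region ID inside the mask, 0 outside.  Lattice edges
        never cross meta-region boundaries.
    """

    mask: np.ndarray
    meta_region: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        meta = np.asarray(self.meta_region)
        if mask.ndim != 3 or meta.shape != mask.shape:
            raise ValueError("mask and meta_region must be 3D arrays of equal shape")
        if not np.issubdtype(meta.dtype, np.integer):
            raise ValueError("meta_region must be an integer volume")
        if not np.array_equal(meta > 0, mask):
            raise ValueError("meta_region must be positive exactly on in-mask voxels")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "meta_region", meta)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def voxel_coords(self) -> np.ndarray:
        """In-mask voxel coordinates, (n, 3), in lexicographic (x, y, z) order."""
        return np.argwhere(self.mask)


@dataclass
class LatticeGraph:
    """Voxel-node graph: coordinates, undirected edge list, optional edge weights.

    ``build_lattice`` guarantees face-adjacency, within-mask and within-meta-
    region edges, and degree <= 6.  Hand-built instances (e.g. for label-
    propagation fixtures) may use arbitrary small graphs.
    """

    coords: np.ndarray  # (n, 3) int voxel coordinates
    edges: np.ndarray  # (m, 2) int indices into coords, i < j, lexicographic
    weights: np.ndarray | None = None  # (m,) nonnegative, aligned with edges
    meta_region: np.ndarray | None = field(default=None)  # (n,) per-voxel region id

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.intp).reshape(-1, 3)
        self.edges = np.asarray(self.edges, dtype=np.intp).reshape(-1, 2)
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (len(self.edges),):
                raise ValueError("weights must align with edges")
            if np.any(self.weights < 0):
                raise ValueError("edge weights must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.coords)

    @property
    def m(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        """Weighted degree k_i (unit weights if the graph is unweighted)."""
        w = self.weights if self.weights is not None else np.ones(self.m)
        k = np.zeros(self.n)
        np.add.at(k, self.edges[:, 0], w)
        np.add.at(k, self.edges[:, 1], w)
        return k

    def adjacency(self) -> list[np.ndarray]:
        """Neighbor index arrays per node (unweighted 6-neighborhoods)."""
        nbrs: list[list[int]] = [[] for _ in range(self.n)]
        for i, j in self.edges:
            nbrs[i].append(int(j))
            nbrs[j].append(int(i))
        return [np.asarray(a, dtype=np.intp) for a in nbrs]


@dataclass(frozen=True)
class CoherenceSpectrum:
    """MSC estimate per frequency; msc values lie in [0, 1]."""

    frequencies: np.ndarray
    msc: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        c = np.asarray(self.msc, dtype=float)
        if f.shape != c.shape or f.ndim != 1:
            raise ValueError("frequencies and msc must be 1D of equal length")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "msc", c)


def binarize_mask(probability_volume: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarize a probability volume with a strict ``value > threshold`` rule.

    Raises if no voxel survives, since an empty mask yields an empty graph
    downstream.
    """
    vol = np.asarray(probability_volume, dtype=float)
    if not np.all(np.isfinite(vol)):
        raise ValueError("probability volume contains non-finite values")
    mask = vol > threshold
    if not mask.any():
        raise ValueError(f"no voxel exceeds threshold {threshold}: empty mask")
    return mask


def build_lattice(grid: VolumeGrid) -> LatticeGraph:
    """Build the 6-connectivity lattice over in-mask voxels of one grid.

    Edges join face-adjacent voxel pairs that are both in-mask and share a
    meta-region ID; node and edge order are lexicographic, so the result is
    deterministic.  Isolated in-mask voxels are retained as degree-0 nodes.
    """
    coords = grid.voxel_coords()
    index_vol = np.full(grid.dims, -1, dtype=np.intp)
    index_vol[tuple(coords.T)] = np.arange(len(coords))

    pairs = []
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        a = index_vol[tuple(lo)]
        b = index_vol[tuple(hi)]
        ra = grid.meta_region[tuple(lo)]
        rb = grid.meta_region[tuple(hi)]
        ok = (a >= 0) & (b >= 0) & (ra == rb)
        pairs.append(np.stack([a[ok], b[ok]], axis=1))
    edges = np.concatenate(pairs, axis=0) if pairs else np.empty((0, 2), dtype=np.intp)
    edges = np.sort(edges, axis=1)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    meta = grid.meta_region[tuple(coords.T)]
    return LatticeGraph(coords=coords, edges=edges[order], meta_region=meta)


def _tapered_ffts(series: np.ndarray, nw: float, n_tapers: int) -> np.ndarray:
    """Slepian-tapered one-sided FFTs, shape (n_series, n_tapers, n_freq)."""
    series = np.atleast_2d(np.asarray(series, dtype=float))
    n_t = series.shape[-1]
    tapers = dpss(n_t, nw, Kmax=n_tapers)  # (K, T), unit-energy
    return rfft(series[:, None, :] * tapers[None, :, :], axis=-1)


def multitaper_msc(
    x: np.ndarray,
    y: np.ndarray,
    sampling_interval_s: float,
    half_bandwidth_product: float = DEFAULT_NW,
    n_tapers: int = DEFAULT_N_TAPERS,
) -> CoherenceSpectrum:
    """Multitaper magnitude-squared coherence between two equal-length series.

    Cross- and auto-spectra are averaged over Slepian tapers and combined as
    ``MSC = |S_xy|^2 / (S_xx * S_yy)`` per frequency; by the Cauchy-Schwarz
    inequality the estimate lies in [0, 1] (clipped for float safety).

    Raises
    ------
    ValueError
        If the series differ in length, are shorter than 16 samples, contain
        non-finite values, or either has zero variance (coherence undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    if len(x) < 16:
        raise ValueError("series too short for spectral estimation (need >= 16)")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("series contain non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance series: coherence undefined")

    fx, fy = _tapered_ffts(np.stack([x, y]), half_bandwidth_product, n_tapers)
    sxx = np.mean(np.abs(fx) ** 2, axis=0)
    syy = np.mean(np.abs(fy) ** 2, axis=0)
    sxy = np.mean(fx * np.conj(fy), axis=0)
    msc = np.clip(np.abs(sxy) ** 2 / (sxx * syy), 0.0, 1.0)
    freqs = rfftfreq(len(x), d=sampling_interval_s)
    return CoherenceSpectrum(frequencies=freqs, msc=msc)


def band_weight(
    spectrum: CoherenceSpectrum,
    f_lo: float = DEFAULT_BAND[0],
    f_hi: float = DEFAULT_BAND[1],
    normalize: bool = True,
) -> float:
    """Area under the MSC spectrum over [f_lo, f_hi] (trapezoidal).

    With ``normalize=True`` (default) the integral is divided by the width of
    the integrated frequency span so the weight lies in [0, 1]; the raw area
    is available with ``normalize=False``.  Normalization rescales all edge
    weights by one common constant, which leaves the modularity-optimal
    partition unchanged.
    """
    if not f_lo < f_hi:
        raise ValueError("need f_lo < f_hi")
    f = spectrum.frequencies
    if f_hi > f[-1] + 1e-12:
        raise ValueError("f_hi exceeds the Nyquist frequency of the spectrum")
    sel = (f >= f_lo) & (f <= f_hi)
    if sel.sum() < 2:
        raise ValueError("band contains fewer than 2 frequency samples")
    fb = f[sel]
    area = float(np.trapezoid(spectrum.msc[sel], fb))
    if normalize:
        area /= fb[-1] - fb[0]
    return area


def weight_lattice(
    lattice: LatticeGraph,
    bold: np.ndarray,
    sampling_interval_s: float,
    band: tuple[float, float] = DEFAULT_BAND,
    half_bandwidth_product: float = DEFAULT_NW,
    n_tapers: int = DEFAULT_N_TAPERS,
    normalize: bool = True,
    chunk: int = 20_000,
) -> LatticeGraph:
    """Attach the band-limited MSC weight to every edge of a lattice.

    The tapered FFT of every voxel series is computed once; per-edge cross-
    spectra are then formed by vectorized products, in chunks to bound memory.

    Raises
    ------
    ValueError
        If any in-graph voxel has a zero-variance series, identifying the
        offending voxel coordinate.
    """
    bold = np.asarray(bold, dtype=float)
    if bold.ndim != 4:
        raise ValueError("bold must be a 4D (x, y, z, t) array")
    series = bold[tuple(lattice.coords.T)]  # (n, T)
    flat = np.ptp(series, axis=1) == 0
    if flat.any():
        bad = lattice.coords[np.argmax(flat)]
        raise ValueError(f"zero-variance series at voxel {tuple(int(c) for c in bad)}")

    ft = _tapered_ffts(series, half_bandwidth_product, n_tapers)  # (n, K, F)
    freqs = rfftfreq(series.shape[1], d=sampling_interval_s)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if sel.sum() < 2:
        raise ValueError("band contains fewer than 2 frequency samples")
    auto = np.mean(np.abs(ft) ** 2, axis=1)  # (n, F)
    fb = freqs[sel]
    span = fb[-1] - fb[0]

    weights = np.empty(lattice.m)
    for start in range(0, lattice.m, chunk):
        e = lattice.edges[start : start + chunk]
        sxy = np.mean(ft[e[:, 0]] * np.conj(ft[e[:, 1]]), axis=1)
        msc = np.clip(np.abs(sxy) ** 2 / (auto[e[:, 0]] * auto[e[:, 1]]), 0.0, 1.0)
        area = np.trapezoid(msc[:, sel], fb, axis=1)
        weights[start : start + chunk] = area / span if normalize else area
    return LatticeGraph(
        coords=lattice.coords,
        edges=lattice.edges,
        weights=weights,
        meta_region=lattice.meta_region,
    )
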
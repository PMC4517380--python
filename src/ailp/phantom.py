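"""Synthetic 4D phantoms with known block community structure.

No public resting-state dataset accompanies the method, so every pipeline
stage is exercised on phantoms: masked 4D volumes in which spatially
contiguous blocks of voxels share a band-limited source signal (a sum of
sinusoids confined to the analysis band) plus independent Gaussian noise, at
two "time points" whose block boundaries are partially perturbed.  The
ground-truth block labels at each time point come along, so recovery can be
scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.fft import rfftfreq

from .lattice import DEFAULT_BAND, LatticeGraph, VolumeGrid, build_lattice
from .parcellation import Parcellation

__all__ = [
    "PhantomSpec",
    "PhantomDataset",
    "generate_phantom",
    "generate_toy_lattice",
    "is_contiguous",
]

#: 6-connectivity structuring element for flood fills
_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)

#: number of sinusoids summed per block source
N_SINUSOIDS = 3


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a two-timepoint block phantom.

    Defaults mirror a standard resting-state acquisition: 145 retained
    volumes at TR = 2 s, signals confined to 0.005-0.12 Hz.
    ``perturbation_fraction`` is the fraction of block-boundary voxels
    reassigned to an adjacent block at the second time point.
    """

    grid_dims: tuple[int, int, int] = (12, 12, 4)
    n_meta_regions: int = 2
    blocks_per_region: int = 2
    n_volumes: int = 145
    sampling_interval_s: float = 2.0
    signal_band_hz: tuple[float, float] = DEFAULT_BAND
    noise_sd: float = 0.5
    perturbation_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_dims) != 3 or any(d < 2 for d in self.grid_dims):
            raise ValueError("grid_dims must be three integers, all >= 2")
        if self.n_meta_regions < 1 or self.blocks_per_region < 1:
            raise ValueError("need at least one meta-region and one block")
        if self.n_volumes < 16:
            raise ValueError("n_volumes must be >= 16 for spectral estimation")
        if self.sampling_interval_s <= 0:
            raise ValueError("sampling_interval_s must be positive")
        lo, hi = self.signal_band_hz
        nyquist = 0.5 / self.sampling_interval_s
        if not 0 <= lo < hi:
            raise ValueError("signal band must satisfy 0 <= lo < hi")
        if hi >= nyquist:
            raise ValueError(f"band upper edge must be below Nyquist = {nyquist} Hz")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 <= self.perturbation_fraction <= 1.0:
            raise ValueError("perturbation_fraction must lie in [0, 1]")
        if self.n_meta_regions > self.grid_dims[0]:
            raise ValueError("more meta-regions than x-planes: cannot tile slabs")
        if self.blocks_per_region > self.grid_dims[1]:
            raise ValueError(
                "blocks_per_region exceeds what contiguous tiling of a "
                "meta-region allows (more blocks than y-planes)"
            )


@dataclass
class PhantomDataset:
    """Generated phantom: two 4D series, mask, atlas, ground-truth labels."""

    bold_t1: np.ndarray
    bold_t2: np.ndarray
    mask: np.ndarray
    atlas: np.ndarray
    truth_t1: Parcellation
    truth_t2: Parcellation
    spec: PhantomSpec = field(repr=False, default=None)

    @property
    def grid(self) -> VolumeGrid:
        return VolumeGrid(mask=self.mask, meta_region=self.atlas)


def is_contiguous(block_mask: np.ndarray) -> bool:
    """True when the voxels of ``block_mask`` form one 6-connected component."""
    if not block_mask.any():
        return False
    _, n = ndimage.label(block_mask, structure=_FACE_STRUCTURE)
    return n == 1


def _tile_blocks(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Atlas (meta-region slabs along x) and block labels (sub-slabs along y)."""
    nx, ny, nz = spec.grid_dims
    atlas = np.zeros(spec.grid_dims, dtype=np.int64)
    blocks = np.zeros(spec.grid_dims, dtype=np.int64)
    x_slabs = np.array_split(np.arange(nx), spec.n_meta_regions)
    block_id = 0
    for meta_id, xs in enumerate(x_slabs, start=1):
        atlas[xs] = meta_id
        for ys in np.array_split(np.arange(ny), spec.blocks_per_region):
            blocks[np.ix_(xs, ys, np.arange(nz))] = block_id
            block_id += 1
    return atlas, blocks


def _perturb_boundaries(
    blocks: np.ndarray,
    atlas: np.ndarray,
    fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Reassign a fraction of block-boundary voxels to an adjacent block.

    Only moves that keep both donor and recipient blocks 6-connected are
    accepted, so every ground-truth block stays contiguous at both time
    points.  Meta-region boundaries are never crossed.
    """
    out = blocks.copy()
    shifts = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]

    def neighbor_blocks(pos: tuple[int, int, int]) -> list[int]:
        cands = []
        for dx, dy, dz in shifts:
            q = (pos[0] + dx, pos[1] + dy, pos[2] + dz)
            if all(0 <= q[a] < out.shape[a] for a in range(3)):
                if atlas[q] == atlas[pos] and out[q] != out[pos]:
                    cands.append(int(out[q]))
        return cands

    boundary = [tuple(p) for p in np.argwhere(out >= 0) if neighbor_blocks(tuple(p))]
    n_target = int(round(fraction * len(boundary)))
    if n_target == 0:
        return out
    order = rng.permutation(len(boundary))
    n_moved = 0
    for idx in order:
        if n_moved >= n_target:
            break
        pos = boundary[idx]
        cands = neighbor_blocks(pos)
        if not cands:
            continue
        donor = int(out[pos])
        recipient = int(rng.choice(np.unique(cands)))
        out[pos] = recipient
        if is_contiguous(out == donor) and is_contiguous(out == recipient):
            n_moved += 1
        else:
            out[pos] = donor  # reject moves that break contiguity
    return out


def _block_sources(
    spec: PhantomSpec, n_blocks: int, rng: np.random.Generator
) -> np.ndarray:
    """One band-confined source signal per block, shape (n_blocks, T).

    Each source is a sum of ``N_SINUSOIDS`` unit-amplitude sinusoids with
    uniform random phases.  Frequencies are drawn uniformly among the discrete
    Fourier bin frequencies lying at least two Rayleigh widths inside the
    band, sampled without replacement across *all* blocks, so (a) the signals
    carry no power outside the band at the acquired length and (b) distinct
    blocks have orthogonal sources.
    """
    freqs = rfftfreq(spec.n_volumes, d=spec.sampling_interval_s)
    margin = 2.0 / (spec.n_volumes * spec.sampling_interval_s)
    lo, hi = spec.signal_band_hz
    pool = np.flatnonzero((freqs >= lo + margin) & (freqs <= hi - margin))
    need = N_SINUSOIDS * n_blocks
    if len(pool) < need:
        raise ValueError(
            f"band supports only {len(pool)} usable frequency bins at "
            f"n_volumes={spec.n_volumes}; {need} needed for {n_blocks} blocks"
        )
    bins = rng.choice(pool, size=need, replace=False).reshape(n_blocks, N_SINUSOIDS)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=bins.shape)
    t = np.arange(spec.n_volumes) * spec.sampling_interval_s
    # (n_blocks, K, T) -> sum over K
    return np.sin(
        2.0 * np.pi * freqs[bins][:, :, None] * t[None, None, :]
        + phases[:, :, None]
    ).sum(axis=1)


def _render_bold(
    spec: PhantomSpec,
    blocks: np.ndarray,
    sources: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    bold = sources[blocks]  # (x, y, z, T) via label indexing
    if spec.noise_sd > 0:
        bold = bold + rng.normal(0.0, spec.noise_sd, size=bold.shape)
    return bold


def generate_phantom(spec: PhantomSpec) -> PhantomDataset:
    """Generate a two-timepoint block phantom; bit-identical given the seed.

    The mask covers the whole grid; meta-regions are axis-aligned x-slabs,
    each tiled into contiguous y-slab blocks.  Time point 2 re-assigns
    ``perturbation_fraction`` of the block-boundary voxels to an adjacent
    block (contiguity-preserving) and regenerates all signals.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_perturb, rng_src1, rng_src2, rng_noise1, rng_noise2 = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )
    atlas, blocks_t1 = _tile_blocks(spec)
    blocks_t2 = _perturb_boundaries(
        blocks_t1, atlas, spec.perturbation_fraction, rng_perturb
    )
    n_blocks = spec.n_meta_regions * spec.blocks_per_region
    src_t1 = _block_sources(spec, n_blocks, rng_src1)
    src_t2 = _block_sources(spec, n_blocks, rng_src2)
    mask = np.ones(spec.grid_dims, dtype=bool)
    return PhantomDataset(
        bold_t1=_render_bold(spec, blocks_t1, src_t1, rng_noise1),
        bold_t2=_render_bold(spec, blocks_t2, src_t2, rng_noise2),
        mask=mask,
        atlas=atlas,
        truth_t1=Parcellation(labels=blocks_t1[mask], provenance="truth"),
        truth_t2=Parcellation(labels=blocks_t2[mask], provenance="truth"),
        spec=spec,
    )


def generate_toy_lattice(labels: np.ndarray) -> tuple[LatticeGraph, Parcellation]:
    """Lattice + labeling from an explicit small 2D/3D label array.

    Every cell is in-mask and in one meta-region, so the lattice is the plain
    face-adjacency grid; handy for hand-checkable label-propagation fixtures.
    """
    arr = np.asarray(labels)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3:
        raise ValueError("labels must be a 2D or 3D integer array")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("labels must be integers")
    grid = VolumeGrid(
        mask=np.ones(arr.shape, dtype=bool),
        meta_region=np.ones(arr.shape, dtype=np.int64),
    )
    lattice = build_lattice(grid)
    part = Parcellation(labels=arr[grid.mask], provenance="truth")
    return lattice, part
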
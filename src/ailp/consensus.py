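"""Consensus ROIs across time points: aggregation + label propagation (AILP).

Two per-timepoint parcellations are first aggregated into their partition
meet: each voxel gets the ordered pair (Time-1 label, Time-2 label) and voxels
share an aggregate ROI (aROI) exactly when their pairs match.  The meet
refines both inputs, so it fragments ROIs wherever the two parcellations
disagree.  Label propagation (LP) then reconstitutes the fragments: voxels are
visited in random order and each adopts the label occurring most frequently
among its 6-lattice neighbors, with ties broken uniformly at random, until
every voxel already holds one of its neighborhood's maximal-frequency labels.
Initializing LP with the aggregate rather than with singletons is what makes
the procedure a consensus method (aggregate-initialized label propagation).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .lattice import LatticeGraph
from .parcellation import Parcellation

__all__ = [
    "AggregateLabel",
    "FragmentationReport",
    "aggregate",
    "label_propagation",
    "ailp",
    "fragmentation_report",
]

logger = logging.getLogger(__name__)

#: default cap on LP sweeps; LP converges in a handful of sweeps in practice
DEFAULT_MAX_SWEEPS = 100


@dataclass(frozen=True)
class AggregateLabel:
    """Ordered (Time-1 label, Time-2 label) pairs per voxel."""

    pairs: np.ndarray  # (n, 2) int

    def __post_init__(self) -> None:
        p = np.asarray(self.pairs)
        if p.ndim != 2 or p.shape[1] != 2:
            raise ValueError("pairs must be an (n, 2) array")
        object.__setattr__(self, "pairs", p)


@dataclass(frozen=True)
class FragmentationReport:
    """Per-stage ROI size summary (voxel counts per module)."""

    n_rois: int
    size_mean: float
    size_sd: float
    size_median: float
    frac_lt5: float
    frac_lt10: float

    def __post_init__(self) -> None:
        if self.n_rois < 1:
            raise ValueError("need at least one ROI")
        if self.frac_lt5 > self.frac_lt10 + 1e-12:
            raise ValueError("frac_lt5 cannot exceed frac_lt10")


def aggregate(p1: Parcellation, p2: Parcellation) -> Parcellation:
    """Partition meet of two parcellations over the same voxel set.

    Voxels are co-assigned in the output iff they are co-assigned in *both*
    inputs.  Output labels are dense integers numbered in first-occurrence
    order, so the result is deterministic.

    Raises
    ------
    ValueError
        If the two parcellations cover different numbers of voxels.
    """
    if p1.n_voxels != p2.n_voxels:
        raise ValueError("parcellations must be total over the same voxel set")
    pairs = np.stack([p1.labels.astype(np.int64), p2.labels.astype(np.int64)], axis=1)
    # encode the ordered pair injectively, then renumber by first occurrence
    span = int(pairs[:, 1].max()) - int(pairs[:, 1].min()) + 1
    codes = (pairs[:, 0] - pairs[:, 0].min()) * span + (pairs[:, 1] - pairs[:, 1].min())
    return Parcellation(labels=codes, provenance="aROI").densify()


def _neighborhood_vote(
    neighbor_labels: np.ndarray, rng: np.random.Generator
) -> int:
    """Label occurring with the highest frequency among the neighbors.

    Ties are broken uniformly at random.  The focal voxel's own label does
    not vote.
    """
    labs, counts = np.unique(neighbor_labels, return_counts=True)
    best = labs[counts == counts.max()]
    if len(best) == 1:
        return int(best[0])
    return int(rng.choice(best))


def _is_stable(
    labels: np.ndarray, adjacency: list[np.ndarray]
) -> bool:
    """True when every voxel's label is among the maximal-frequency labels of
    its neighborhood (ties count as satisfied); degree-0 voxels always are."""
    for i, nbrs in enumerate(adjacency):
        if len(nbrs) == 0:
            continue
        labs, counts = np.unique(labels[nbrs], return_counts=True)
        top = counts.max()
        pos = np.searchsorted(labs, labels[i])
        if pos >= len(labs) or labs[pos] != labels[i] or counts[pos] != top:
            return False
    return True


def label_propagation(
    lattice: LatticeGraph,
    init: Parcellation,
    seed: int,
    max_sweeps: int = DEFAULT_MAX_SWEEPS,
    densify: bool = True,
) -> Parcellation:
    """Asynchronous label propagation on the (unweighted) lattice.

    Each sweep visits all voxels in a fresh random order; a voxel adopts the
    most frequent label among its neighbors immediately, so later voxels in
    the same sweep see a mixture of updated and not-yet-updated labels.
    Neighbor voting is by count only — coherence weights play no role here.
    The algorithm stops when the current labeling is stable in the sense of
    ``_is_stable``; the stability check runs before each sweep, so an
    already-stable initialization is returned unchanged after one
    verification pass.

    Degree-0 voxels keep their initial label.  Output labels are a subset of
    the initial labels (LP never invents labels) and, with ``densify=True``,
    are renumbered to consecutive integers in first-occurrence order
    (``densify=False`` preserves the surviving initial labels verbatim).  A
    fixed seed makes the visit order and tie-breaks, hence the output, fully
    reproducible.
    """
    if init.n_voxels != lattice.n:
        raise ValueError("init partition must be total over the lattice's voxels")
    rng = np.random.default_rng(seed)
    adjacency = lattice.adjacency()
    labels = init.labels.astype(np.int64).copy()

    converged = False
    for sweep in range(max_sweeps):
        if _is_stable(labels, adjacency):
            converged = True
            break
        order = rng.permutation(lattice.n)
        n_changed = 0
        for i in order:
            nbrs = adjacency[i]
            if len(nbrs) == 0:
                continue
            new = _neighborhood_vote(labels[nbrs], rng)
            if new != labels[i]:
                labels[i] = new
                n_changed += 1
        logger.debug("LP sweep %d: %d voxels changed label", sweep + 1, n_changed)
    else:
        converged = _is_stable(labels, adjacency)
    if not converged:
        warnings.warn(
            f"label propagation hit max_sweeps={max_sweeps} without stabilizing",
            RuntimeWarning,
        )
    out = Parcellation(labels=labels, provenance="lpROI")
    return out.densify() if densify else out


def ailp(
    lattice: LatticeGraph,
    p1: Parcellation,
    p2: Parcellation,
    seed: int,
    max_sweeps: int = DEFAULT_MAX_SWEEPS,
) -> Parcellation:
    """Aggregate-initialized label propagation: LP seeded with the meet of two
    per-timepoint parcellations."""
    return label_propagation(lattice, aggregate(p1, p2), seed, max_sweeps=max_sweeps)


def fragmentation_report(part: Parcellation) -> FragmentationReport:
    """Summarize per-module voxel counts (sd is the sample sd, n-1)."""
    sizes = part.sizes()
    sd = float(np.std(sizes, ddof=1)) if len(sizes) > 1 else 0.0
    return FragmentationReport(
        n_rois=len(sizes),
        size_mean=float(np.mean(sizes)),
        size_sd=sd,
        size_median=float(np.median(sizes)),
        frac_lt5=float(np.mean(sizes < 5)),
        frac_lt10=float(np.mean(sizes < 10)),
    )
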
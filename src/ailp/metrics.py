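"""ROI-level correlation networks and global graph metrics of plasticity.

The consensus ROIs' mean BOLD series are correlated pairwise (Pearson);
Benjamini-Hochberg FDR at level alpha decides which correlations become
weighted links.  Four global metrics summarize each time point's network:
link count, total strength (sum of surviving weights), mean binary clustering
coefficient, and mean binary shortest-path length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import shortest_path
from statsmodels.stats.multitest import multipletests

from .parcellation import Parcellation

__all__ = [
    "RoiNetwork",
    "PathLengthResult",
    "roi_mean_series",
    "correlation_network",
    "count_links",
    "total_strength",
    "mean_clustering",
    "mean_path_length",
]


@dataclass(frozen=True)
class RoiNetwork:
    """FDR-thresholded pairwise-correlation network over ROIs.

    ``weight`` holds the signed Pearson r on surviving pairs and 0 elsewhere;
    the binary adjacency is simply ``weight != 0``.
    """

    roi_ids: np.ndarray
    weight: np.ndarray  # (k, k) symmetric, zero diagonal

    def __post_init__(self) -> None:
        w = np.asarray(self.weight, dtype=float)
        ids = np.asarray(self.roi_ids)
        if w.ndim != 2 or w.shape[0] != w.shape[1] or len(ids) != w.shape[0]:
            raise ValueError("weight must be square and aligned with roi_ids")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("weight matrix must have a zero diagonal")
        object.__setattr__(self, "weight", w)
        object.__setattr__(self, "roi_ids", ids)

    @property
    def binary(self) -> np.ndarray:
        return self.weight != 0

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)


class PathLengthResult(NamedTuple):
    """Mean binary path length; ``disconnected`` flags excluded infinite pairs."""

    value: float
    disconnected: bool


def roi_mean_series(bold: np.ndarray, part: Parcellation, mask: np.ndarray) -> tuple[
    np.ndarray, np.ndarray
]:
    """Mean BOLD series per ROI.

    Returns ``(roi_ids, series)`` with ``series`` of shape (n_rois, T); row r
    is the unweighted mean over voxels labeled ``roi_ids[r]``.  ``part`` must
    be total over the in-mask voxels of ``bold`` (lexicographic order, the
    same convention as the lattice).
    """
    bold = np.asarray(bold, dtype=float)
    voxel_series = bold[np.asarray(mask, dtype=bool)]  # (n, T)
    if part.n_voxels != len(voxel_series):
        raise ValueError("partition must be total over the masked voxels")
    roi_ids, inverse = np.unique(part.labels, return_inverse=True)
    out = np.zeros((len(roi_ids), bold.shape[-1]))
    np.add.at(out, inverse, voxel_series)
    counts = np.bincount(inverse, minlength=len(roi_ids)).astype(float)
    return roi_ids, out / counts[:, None]


def correlation_network(
    ts: np.ndarray,
    alpha: float = 0.05,
    roi_ids: np.ndarray | None = None,
    positive_only: bool = False,
) -> RoiNetwork:
    """Pairwise-Pearson network with Benjamini-Hochberg FDR thresholding.

    All n(n-1)/2 pairwise Pearson correlations are tested two-sided using the
    t approximation with T-2 degrees of freedom; BH at level ``alpha``
    controls the FDR over the full set of tests.  Surviving pairs keep their
    signed r as edge weight (``positive_only=True`` drops negative survivors).
    Constant ROI series are excluded from testing with a warning, since their
    correlations are undefined.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("ts must be (n_rois, n_timepoints)")
    k, t = ts.shape
    if k < 2 or t < 3:
        raise ValueError("need >= 2 ROIs and >= 3 time samples")
    if roi_ids is None:
        roi_ids = np.arange(k)

    constant = np.ptp(ts, axis=1) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant ROI series excluded from the "
            "correlation network (r undefined)"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(ts)
    iu, ju = np.triu_indices(k, 1)
    valid = ~(constant[iu] | constant[ju])
    rv = np.clip(r[iu[valid], ju[valid]], -1.0, 1.0)

    weight = np.zeros((k, k))
    if valid.any():
        # two-sided p via the exact t distribution, df = T - 2
        with np.errstate(divide="ignore"):
            tstat = rv * np.sqrt((t - 2) / np.maximum(1.0 - rv**2, 1e-300))
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df=t - 2)
        reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        if positive_only:
            reject &= rv > 0
        ii, jj = iu[valid][reject], ju[valid][reject]
        weight[ii, jj] = rv[reject]
        weight[jj, ii] = rv[reject]
    return RoiNetwork(roi_ids=np.asarray(roi_ids), weight=weight)


def count_links(net: RoiNetwork) -> int:
    """Number of surviving unordered ROI pairs."""
    return int(np.count_nonzero(np.triu(net.binary, 1)))


def total_strength(net: RoiNetwork) -> float:
    """Sum of surviving (signed) link weights."""
    return float(np.triu(net.weight, 1).sum())


def mean_clustering(net: RoiNetwork) -> float:
    """Mean binary clustering coefficient.

    C_i = 2 * (links among neighbors of i) / (k_i * (k_i - 1)), averaged over
    all nodes; nodes of degree < 2 contribute C_i = 0 (the formula is 0/0
    there — documented convention).
    """
    a = net.binary.astype(float)
    deg = a.sum(axis=1)
    # (A^3)_ii counts closed walks of length 3 = 2 * triangles through i
    tri2 = np.diag(a @ a @ a)  # 2 * links among neighbors, per node
    denom = deg * (deg - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, tri2 / denom, 0.0)
    return float(np.mean(c))


def mean_path_length(net: RoiNetwork) -> PathLengthResult:
    """Mean binary shortest-path length over reachable ordered pairs.

    Distances are BFS hop counts on the binary graph.  Unreachable pairs are
    excluded from both numerator and denominator; if any exist the
    ``disconnected`` flag is set.

    Raises
    ------
    ValueError
        If no finite off-diagonal pair exists (edgeless network).
    """
    a = sparse.csr_matrix(net.binary.astype(np.int8))
    d = shortest_path(a, method="D", directed=False, unweighted=True)
    off = ~np.eye(net.n_rois, dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        raise ValueError("no connected ROI pair: path length undefined")
    return PathLengthResult(
        value=float(d[finite].mean()),
        disconnected=bool((~np.isfinite(d) & off).any()),
    )
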
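"""Run-to-run stability of label-propagated ROIs.

Label propagation has two stochastic ingredients (visit order, tie-breaks),
so repeated runs on the same data can differ.  Two summaries quantify how
much: (1) a size-weighted Sørensen overlap between best-matching ROIs of each
run pair, and (2) the probability that a within-meta-region voxel pair is
consistently co-assigned (or consistently separated) across runs, i.e. the
fraction of runs agreeing with the modal outcome.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .lattice import VolumeGrid
from .parcellation import Parcellation

__all__ = ["ReliabilityReport", "sorensen", "run_consistency"]

#: default cap on sampled voxel pairs per consistency estimate
DEFAULT_MAX_PAIRS = 1_000_000


@dataclass(frozen=True)
class ReliabilityReport:
    """Stability summaries over repeated runs (both proportions in [0, 1])."""

    weighted_sorensen: float
    voxel_pair_consistency: float
    n_runs: int
    n_run_pairs: int

    def __post_init__(self) -> None:
        for v in (self.weighted_sorensen, self.voxel_pair_consistency):
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError("reliability proportions must lie in [0, 1]")
        if self.n_run_pairs != self.n_runs * (self.n_runs - 1) // 2:
            raise ValueError("n_run_pairs must equal C(n_runs, 2)")


def sorensen(x: Iterable, y: Iterable) -> float:
    """Sørensen overlap of two voxel sets: 2|X∩Y| / (|X| + |Y|).

    Symmetric, bounded in [0, 1], and 1 exactly when the sets are equal.

    Raises
    ------
    ValueError
        If either set is empty (the index is undefined).
    """
    xs, ys = set(x), set(y)
    if not xs or not ys:
        raise ValueError("Sørensen index undefined for empty sets")
    return 2.0 * len(xs & ys) / (len(xs) + len(ys))


def _pairwise_weighted_sorensen(
    a: np.ndarray, b: np.ndarray, region: np.ndarray
) -> tuple[float, float]:
    """Size-weighted best-match Sørensen between two labelings, one run pair.

    Within each meta-region, every ROI of each run is matched to the ROI of
    the other run with which it shares the most voxels; its Sørensen score is
    weighted by its own size.  Scores from both directions are pooled, which
    keeps the measure symmetric in the two runs.  Returns (weighted sum,
    total weight).
    """
    score_sum = 0.0
    weight_sum = 0.0
    for reg in np.unique(region):
        sel = region == reg
        ar, br = a[sel], b[sel]
        a_ids, a_inv = np.unique(ar, return_inverse=True)
        b_ids, b_inv = np.unique(br, return_inverse=True)
        overlap = np.zeros((len(a_ids), len(b_ids)), dtype=np.int64)
        np.add.at(overlap, (a_inv, b_inv), 1)
        a_sizes = overlap.sum(axis=1)
        b_sizes = overlap.sum(axis=0)
        # direction A -> B
        best_b = overlap.argmax(axis=1)
        s_ab = 2.0 * overlap[np.arange(len(a_ids)), best_b] / (
            a_sizes + b_sizes[best_b]
        )
        # direction B -> A
        best_a = overlap.argmax(axis=0)
        s_ba = 2.0 * overlap[best_a, np.arange(len(b_ids))] / (
            a_sizes[best_a] + b_sizes
        )
        score_sum += float(np.dot(s_ab, a_sizes) + np.dot(s_ba, b_sizes))
        weight_sum += float(a_sizes.sum() + b_sizes.sum())
    return score_sum, weight_sum


def _sample_region_pairs(
    region: np.ndarray,
    max_pairs: int | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Within-meta-region voxel index pairs, exhaustive or subsampled.

    The budget is split over meta-regions in proportion to their pair counts;
    sampling is with replacement (the estimate is an average, so duplicates
    are harmless).
    """
    idx_i: list[np.ndarray] = []
    idx_j: list[np.ndarray] = []
    regions = np.unique(region)
    counts = np.array(
        [np.count_nonzero(region == r) for r in regions], dtype=np.int64
    )
    pair_counts = counts * (counts - 1) // 2
    total = int(pair_counts.sum())
    if total == 0:
        raise ValueError("no within-region voxel pair exists")
    exhaustive = max_pairs is None or total <= max_pairs
    for reg, cnt, n_pairs in zip(regions, counts, pair_counts):
        if n_pairs == 0:
            continue
        members = np.flatnonzero(region == reg)
        if exhaustive:
            iu, ju = np.triu_indices(cnt, 1)
            idx_i.append(members[iu])
            idx_j.append(members[ju])
        else:
            take = int(round(max_pairs * n_pairs / total))
            if take == 0:
                continue
            ii = rng.integers(0, cnt, size=take)
            jj = rng.integers(0, cnt - 1, size=take)
            jj = np.where(jj >= ii, jj + 1, jj)  # distinct indices
            idx_i.append(members[ii])
            idx_j.append(members[jj])
    return np.concatenate(idx_i), np.concatenate(idx_j)


def run_consistency(
    runs: Sequence[Parcellation],
    grid: VolumeGrid,
    max_pairs: int | None = DEFAULT_MAX_PAIRS,
    seed: int = 0,
) -> ReliabilityReport:
    """Stability of repeated runs of the same labeling procedure.

    ``runs`` must all be total on the same mask.  The weighted Sørensen score
    is averaged over all unordered run pairs; voxel-pair consistency is the
    mean (over within-meta-region voxel pairs, subsampled to ``max_pairs``
    with the given seed, or exhaustive when ``max_pairs=None``) fraction of
    runs agreeing with the modal co-assignment outcome for that pair.
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 runs")
    n_vox = grid.n_voxels
    labels = np.stack([r.labels for r in runs])  # (R, n)
    if labels.shape[1] != n_vox:
        raise ValueError("runs must be total over the grid's mask")
    region = grid.meta_region[grid.mask]
    rng = np.random.default_rng(seed)
    n_runs = len(runs)

    score_sum = 0.0
    weight_sum = 0.0
    for a, b in combinations(range(n_runs), 2):
        s, w = _pairwise_weighted_sorensen(labels[a], labels[b], region)
        score_sum += s
        weight_sum += w
    weighted_sorensen = score_sum / weight_sum

    ii, jj = _sample_region_pairs(region, max_pairs, rng)
    same = labels[:, ii] == labels[:, jj]  # (R, n_pairs)
    n_same = same.sum(axis=0)
    agree = np.maximum(n_same, n_runs - n_same) / n_runs
    return ReliabilityReport(
        weighted_sorensen=float(weighted_sorensen),
        voxel_pair_consistency=float(agree.mean()),
        n_runs=n_runs,
        n_run_pairs=n_runs * (n_runs - 1) // 2,
    )
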
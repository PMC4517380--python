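"""Shared fixtures: phantoms, hand-built graphs, and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from ailp import (
    LatticeGraph,
    Parcellation,
    PhantomSpec,
    generate_phantom,
    run_pipeline_arrays,
)

# seeds used throughout the suite; fixed once, never revisited
LOUVAIN_SEED = 11
LP_SEED = 13


@pytest.fixture(scope="session")
def standard_spec() -> PhantomSpec:
    """The standard perturbed phantom: 12x12x4 grid, 2 meta-regions of 2
    blocks each, 145 volumes at TR 2 s, moderate noise, 30% boundary
    perturbation."""
    return PhantomSpec(seed=7)


@pytest.fixture(scope="session")
def standard_phantom(standard_spec):
    return generate_phantom(standard_spec)


@pytest.fixture(scope="session")
def standard_pipeline(standard_phantom):
    """Full pipeline output on the standard perturbed phantom."""
    ds = standard_phantom
    return run_pipeline_arrays(
        ds.bold_t1,
        ds.bold_t2,
        ds.mask,
        ds.atlas,
        louvain_seed=LOUVAIN_SEED,
        lp_seed=LP_SEED,
    )


def two_block_spec(noise_sd: float) -> PhantomSpec:
    """Recovery phantom: one meta-region tiled into two 2x2x2 cube blocks.

    Cube blocks are compact enough that the modularity optimum coincides
    with the ground-truth blocks, making recovery well-posed.
    """
    return PhantomSpec(
        grid_dims=(2, 4, 2),
        n_meta_regions=1,
        blocks_per_region=2,
        noise_sd=noise_sd,
        perturbation_fraction=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def noiseless_two_block_phantom():
    return generate_phantom(two_block_spec(0.0))


def two_triangles() -> LatticeGraph:
    """Two disjoint unweighted triangles (nodes 0-2 and 3-5)."""
    coords = np.array([[i, 0, 0] for i in range(6)])
    edges = np.array([[0, 1], [0, 2], [1, 2], [3, 4], [3, 5], [4, 5]])
    return LatticeGraph(coords=coords, edges=edges)


@pytest.fixture(name="two_triangles_graph")
def two_triangles_fixture() -> LatticeGraph:
    return two_triangles()


def random_weighted_graph(
    n_max: int, rng: np.random.Generator, p_edge: float = 0.4
) -> LatticeGraph:
    """Random weighted graph on <= n_max nodes (at least one edge)."""
    while True:
        n = int(rng.integers(3, n_max + 1))
        iu, ju = np.triu_indices(n, 1)
        keep = rng.random(len(iu)) < p_edge
        if keep.sum() == 0:
            continue
        edges = np.stack([iu[keep], ju[keep]], axis=1)
        weights = rng.uniform(0.1, 2.0, size=len(edges))
        coords = np.stack([np.arange(n), np.zeros(n), np.zeros(n)], axis=1)
        return LatticeGraph(coords=coords, edges=edges, weights=weights)


def random_partition(n: int, rng: np.random.Generator, k_max: int = 6) -> Parcellation:
    k = int(rng.integers(1, k_max + 1))
    return Parcellation(labels=rng.integers(0, k, size=n), provenance="truth")


# ---------------------------------------------------------------- oracles


def modularity_oracle(graph: LatticeGraph, part: Parcellation) -> float:
    """Literal O(n^2) double loop over the Q equation's adjacency matrix."""
    n = graph.n
    a = np.zeros((n, n))
    w = graph.weights if graph.weights is not None else np.ones(graph.m)
    for (i, j), wij in zip(graph.edges, w):
        a[i, j] = a[j, i] = wij
    k = a.sum(axis=1)
    m = a.sum() / 2.0
    q = 0.0
    for i in range(n):
        for j in range(n):
            if part.labels[i] == part.labels[j]:
                q += a[i, j] - k[i] * k[j] / (2.0 * m)
    return q / (2.0 * m)


def lattice_oracle(mask: np.ndarray, meta: np.ndarray):
    """All-pairs brute force over voxels: face-adjacent, in-mask, same region."""
    coords = [tuple(c) for c in np.argwhere(mask)]
    index = {c: i for i, c in enumerate(coords)}
    edges = set()
    for a in coords:
        for b in coords:
            if a >= b:
                continue
            diff = [abs(x - y) for x, y in zip(a, b)]
            if sorted(diff) == [0, 0, 1] and meta[a] == meta[b]:
                edges.add((index[a], index[b]))
    return np.array(coords), sorted(edges)


def clustering_oracle(binary: np.ndarray) -> float:
    """Per-node triangle enumeration; degree-<2 nodes contribute 0."""
    n = len(binary)
    cs = []
    for i in range(n):
        nbrs = np.flatnonzero(binary[i])
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        links = sum(
            binary[u, v] for ai, u in enumerate(nbrs) for v in nbrs[ai + 1 :]
        )
        cs.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(cs))


def path_length_oracle(binary: np.ndarray) -> tuple[float, bool]:
    """Floyd-Warshall on hop counts; unreachable pairs excluded."""
    n = len(binary)
    inf = float("inf")
    d = np.where(binary, 1.0, inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    return float(d[finite].mean()), bool((~np.isfinite(d) & off).any())


def comembership(labels: np.ndarray) -> np.ndarray:
    return labels[:, None] == labels[None, :]
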
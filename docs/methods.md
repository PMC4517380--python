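# Methods

## Overview

`ailp` derives a single, consensus set of voxel-level regions of interest
(ROIs) from two acquisitions of 4D BOLD fMRI data, so that network change
between the time points (plasticity) can be measured over a common
parcellation while keeping voxel-level signal intact. The pipeline has four
stages:

1. **Voxel lattice.** Every in-mask voxel is a node; edges join face-adjacent
   (6-connectivity) voxel pairs that share a meta-region ID in the supplied
   atlas volume. Edges never cross meta-region boundaries, which makes the
   optimization separable by anatomical territory and keeps ROIs inside
   known anatomy. Each edge is weighted by the normalized area under the
   multitaper magnitude-squared-coherence (MSC) spectrum of its two voxel
   series over the low-frequency band 0.005–0.12 Hz.
2. **Per-timepoint parcellation.** Weighted modularity

   Q = (1/2m) Σ_ij (A_ij − k_i k_j / 2m) δ(C_i, C_j)

   is maximized by the greedy two-phase Louvain algorithm, separately per
   time point, giving iROIs.
3. **Consensus (AILP).** The two iROI maps are aggregated into their
   partition meet (voxels co-assigned iff co-assigned at *both* time points;
   equivalently, grouped by the ordered label pair (m_i, n_i)), which
   fragments disagreeing regions into aROIs. Label propagation (LP) then
   heals the fragments: voxels are visited in random order and each adopts
   the most frequent label among its 6 lattice neighbors, ties broken
   uniformly at random, until every voxel already holds a maximal-frequency
   label of its neighborhood. The result is the lpROI map.
4. **Plasticity metrics.** Mean lpROI series are correlated pairwise per
   time point; Benjamini–Hochberg FDR at α = 0.05 selects the links. Four
   global metrics summarize each network: link count, total strength (sum of
   signed surviving correlations), mean binary clustering coefficient, and
   mean binary shortest-path length.

## Assumptions

- Preprocessing (slice timing, realignment, normalization, smoothing, motion
  scrubbing) happens upstream; the package consumes analysis-ready 4D
  volumes, a gray-matter mask (probability or binary), and an integer atlas.
- The mask and atlas are shared by both time points, so the voxel sets being
  compared are identical.
- Functional association is adequately captured by linear coherence in the
  low-frequency band; no hemodynamic deconvolution is attempted.
- The meta-region atlas is user-supplied configuration (TSV lookup + integer
  volume); no specific atlas is hard-coded.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| mask threshold | 0.5, strict `>` | probability | boundary voxels at exactly 0.5 are excluded; inclusivity is a documented convention |
| coherence band | 0.005–0.12 | Hz | canonical resting-state band |
| band weight | normalized by band width | – | puts weights in [0, 1]; a pure rescaling, so the modularity optimum is unchanged; `normalize=False` gives the raw area |
| multitaper NW | 4 | – | standard time-half-bandwidth product |
| tapers | 7 | – | 2·NW − 1 well-concentrated Slepian tapers |
| Louvain resolution | 1.0 | – | plain modularity |
| LP max sweeps | 100 | sweeps | safety guard; LP converges in a handful of sweeps on all fixtures, and hitting the cap raises a loud warning |
| FDR α | 0.05 | – | two-sided Pearson p-values, t approximation with T−2 df, BH over all n(n−1)/2 tests |
| reliability pair budget | 10⁶ | voxel pairs | caps the O(p²) voxel-pair consistency scan; exact mode via `max_pairs=None` |

Seeds for Louvain and LP are independent so each stage's stochasticity can
be probed separately; every stochastic routine takes an explicit seed and is
bit-reproducible given it.

## Numerical and design choices

- **Lattice**: 0-based (x, y, z) indexing, face adjacency only (no
  diagonals). Isolated in-mask voxels stay as degree-0 nodes and become
  singleton ROIs; they keep their initial label through LP.
- **Modularity** is authored directly from the Q equation (zero diagonal,
  weighted degrees, total weight m) and cross-checked in the tests against a
  brute-force double loop and an independent library implementation.
  Louvain itself is delegated to networkx's seeded implementation.
- **LP update order** is asynchronous: within a sweep, already-visited
  voxels contribute their new labels, the rest their previous ones. This
  matches the per-voxel update rule and avoids the two-coloring oscillation
  synchronous LP is prone to. The stopping check runs before each sweep and
  counts ties as satisfied: a voxel whose label is tied for maximal
  neighborhood frequency does not force another sweep. The focal voxel's own
  label does not vote. Voting is unweighted — coherence weights matter only
  in the modularity stage. No small-ROI filter is applied afterwards; the
  fragmentation report (ROI count, size mean/sd/median, fractions below 5
  and 10 voxels) quantifies what LP healed.
- **Labels** are densified to consecutive integers in first-occurrence order
  after aggregation and after LP, for stable file output.
- **Correlation network**: surviving edges keep their signed r
  (`positive_only` excludes negative ones); link counting and the binary
  metrics ignore sign. Constant ROI series are excluded with a warning.
  Nodes of degree < 2 contribute a clustering coefficient of 0 (the formula
  is 0/0 there). Path length averages over reachable ordered pairs only and
  flags disconnectedness; an edgeless network raises instead of returning a
  number. No autocorrelation correction is applied to the Pearson p-values —
  with serially correlated BOLD data the nominal FDR level is approximate
  (see Limitations).
- **Reliability**: the ROI-matching rule for the weighted Sørensen score is
  best-overlap matching evaluated from both runs' sides (each ROI of each
  run is paired with the maximal-overlap ROI of the other run, scores
  weighted by ROI size and pooled). One-to-one matching was rejected because
  it scores a perfectly reproduced region split differently in two runs as
  zero for the unmatched half, punishing benign relabelings. Voxel-pair
  consistency reads "consistent assignment" as agreement with the modal
  outcome across runs.

## The phantom generator

Phantoms emulate masked 4D volumes with planted community structure: the
grid is tiled into axis-aligned meta-region slabs, each slab into contiguous
blocks; all voxels of a block share one source signal (a sum of three
unit-amplitude sinusoids with random phases) plus iid Gaussian noise. At the
second time point a chosen fraction of block-boundary voxels is re-assigned
to an adjacent block — only moves that keep both donor and recipient blocks
6-connected are accepted — and all signals are regenerated.

Source frequencies are drawn uniformly among the discrete Fourier bin
frequencies lying at least two Rayleigh widths (2/(T·TR)) inside the band,
sampled without replacement across blocks per time point. Drawing on the bin
grid keeps the signal power exactly band-confined at the acquired length
(off-bin sinusoids leak a few percent of their power through the rectangular
periodogram at T = 145) and makes distinct blocks' sources exactly
orthogonal.

Two standing configurations are used throughout the tests and the
acceptance script, chosen once:

- **Standard perturbed phantom**: 12×12×4 grid (576 voxels), 2 meta-regions
  × 2 blocks, 145 volumes at TR 2 s, noise sd 0.5 against unit-amplitude
  sinusoid sources, 30% boundary perturbation. This is the fixture for
  fragmentation behavior, reliability, and the graph metrics.
- **Recovery phantom**: 2×4×2 grid, one meta-region, two 2×2×2 cube blocks,
  no perturbation. Recovery is scored by adjusted Rand index of the lpROIs
  against the planted blocks.

The recovery phantom's block size is deliberate. Plain (resolution 1.0)
modularity splits large homogeneous lattice blocks: for a uniformly weighted
block, separating two halves raises Q whenever the cut between them carries
less than roughly a quarter of the block's internal weight, which holds for
any block much larger than a 2×2×2 cube (and for thin slab-shaped blocks of
any size). Recovery of the planted partition is therefore only a well-posed
question when the blocks are compact and commensurate with modularity's
intrinsic scale; with cube blocks the modularity optimum coincides with the
ground truth and the pipeline attains ARI = 1 noiseless and ≥ 0.8 at noise
sd 0.5. On the standard phantom, whose blocks are ~144 voxels, Louvain
legitimately subdivides each block (~9 iROIs for 4 planted blocks); the
pipeline's consensus machinery is exercised on exactly this fragmentation,
but planted-block ARI is not a meaningful score there.

What the phantoms do **not** emulate: scanner physics, head motion,
physiological noise, hemodynamic response convolution, spatial smoothness of
real BOLD noise, or 1/f spectra. Passing tests demonstrate algorithmic
correctness and stability under the planted-structure model, not performance
on clinical data.

## Problem sizes

The test suite and the acceptance script run the full pipeline on the
576-voxel standard phantom (≈1,400 edges, 145 volumes) and the 16-voxel
recovery phantom, with 10 repeated LP runs for the reliability report; the
whole suite completes in seconds on one CPU. These sizes were chosen so
every quantity is recomputed from scratch at run time while the phantoms
remain large enough to show the fragmentation-and-healing behavior
(aggregation roughly triples the ROI count, LP then removes all or nearly
all sub-5-voxel fragments).

## Known limitations

- Louvain is greedy; different seeds can return different near-optimal
  partitions. Single-run with a fixed seed is the contract; the reliability
  module quantifies the LP stage's stochasticity but not Louvain's.
- The FDR stage inherits the usual caveat that BOLD autocorrelation inflates
  the effective false-positive rate of the t-approximated Pearson test.
- Aggregation is defined for exactly two time points (the meet generalizes,
  but more than two inputs are untested and unsupported).
- Group-level inference over subjects is out of scope; the package computes
  per-dataset networks and metrics only.
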
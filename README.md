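# ailp

Consensus voxelwise brain parcellation across time points by
**aggregate-initialized label propagation**, with graph-theoretic metrics of
network plasticity.

## The problem

Studying how a functional brain network changes between two scanning
sessions (learning, maturation, clinical recovery) requires regions of
interest that are *the same* at both time points — otherwise the networks
are not comparable — yet *data-driven* at the voxel level, so that real
functional boundaries are not averaged away by a fixed anatomical atlas or
biased by investigator-chosen seeds. Parcellating each session separately
solves the second problem and recreates the first: two independent voxelwise
parcellations of the same brain never line up exactly.

`ailp` resolves the dilemma in three steps, for researchers analyzing
longitudinal resting-state BOLD fMRI:

1. **Per-session parcellation.** Each in-mask voxel is a node of a
   6-connectivity lattice, restricted to anatomically defined meta-regions;
   edges are weighted by the area under the multitaper magnitude-squared
   coherence spectrum of the two voxel series over 0.005–0.12 Hz. Weighted
   modularity

   *Q* = (1/2*m*) Σ<sub>ij</sub> (*A*<sub>ij</sub> − *k*<sub>i</sub>*k*<sub>j</sub>/2*m*) δ(*C*<sub>i</sub>, *C*<sub>j</sub>)

   is maximized with the Louvain algorithm, giving per-session iROIs.
2. **Aggregation.** The two iROI maps are intersected (the partition meet):
   each voxel gets the ordered label pair (*m*<sub>i</sub>, *n*<sub>i</sub>)
   and equal pairs define aROIs. The meet is the coarsest common refinement
   of both inputs — it fragments wherever the sessions disagree, producing
   many tiny regions.
3. **Label propagation.** Initialized with the aROIs, each voxel iteratively
   adopts the most frequent label among its 6 lattice neighbors (ties broken
   uniformly at random) until every voxel already holds a maximal-frequency
   neighborhood label. The fragments are reabsorbed into spatially coherent
   consensus lpROIs, over which plasticity is finally measured: per-session
   Pearson correlation networks over mean lpROI series, thresholded by
   Benjamini–Hochberg FDR, summarized by link count, total strength, mean
   clustering coefficient and mean binary path length.

Because no public dataset accompanies the method, the package ships a
first-class phantom generator: masked 4D volumes with planted contiguous
blocks sharing band-limited signals at two time points with partially
perturbed block boundaries, so every stage is testable against known ground
truth. See `docs/methods.md` for the full model description, parameter
rationale, and limitations.

## Worked example

```python
import ailp

spec = ailp.PhantomSpec(seed=7)  # 12x12x4 grid, 2 meta-regions x 2 blocks
ds = ailp.generate_phantom(spec)
res = ailp.run_pipeline_arrays(
    ds.bold_t1, ds.bold_t2, ds.mask, ds.atlas, louvain_seed=11, lp_seed=13
)
frag = res["fragmentation"]
print(f"iROIs: {res['iroi_t1'].n_rois} (t1), {res['iroi_t2'].n_rois} (t2)")
print(f"aROIs after aggregation: {res['aroi'].n_rois} "
      f"({100*frag['aroi'].frac_lt5:.1f}% below 5 voxels)")
print(f"lpROIs after label propagation: {res['lproi'].n_rois} "
      f"({100*frag['lproi'].frac_lt5:.1f}% below 5 voxels)")
for tp in ("t1", "t2"):
    m = res["metrics"][tp]
    print(f"{tp}: links={m['n_links']} strength={m['total_strength']:.2f} "
          f"clustering={m['mean_clustering']:.3f} path={m['mean_path_length']:.3f}")
```

prints

```
iROIs: 8 (t1), 8 (t2)
aROIs after aggregation: 20 (10.0% below 5 voxels)
lpROIs after label propagation: 15 (0.0% below 5 voxels)
t1: links=21 strength=20.88 clustering=1.000 path=1.000
t2: links=25 strength=21.81 clustering=0.811 path=1.694
```

Reading the numbers: the two sessions parcellate into 8 regions each, but
not the same 8 — intersecting them fragments the map into 20 aROIs, a tenth
of them tiny slivers of fewer than 5 voxels. Label propagation reabsorbs
every sliver, leaving 15 consensus lpROIs over which the two sessions'
networks are directly comparable; here the second time point shows more
links and higher strength but lower clustering and longer paths — the kind
of topological change the consensus ROIs exist to expose.

## Command line

The same stages are available as subcommands operating on NIfTI volumes:

```sh
ailp simulate   --out phantom/ --seed 7
ailp parcellate --bold phantom/bold_t1.nii --mask phantom/mask.nii \
                --atlas phantom/atlas.nii --out iroi_t1.nii --seed 11
ailp aggregate  --labels-t1 iroi_t1.nii --labels-t2 iroi_t2.nii \
                --mask phantom/mask.nii --out aroi.nii
ailp propagate  --labels aroi.nii --mask phantom/mask.nii \
                --atlas phantom/atlas.nii --out lproi.nii --seed 13
ailp network    --labels lproi.nii --bold phantom/bold_t1.nii \
                --mask phantom/mask.nii --out metrics_t1.json
ailp run        --config config.json     # full pipeline + hashed manifest
```

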
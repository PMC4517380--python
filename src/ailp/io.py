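"""NIfTI and tabular I/O for volumes, label maps, edge lists and lookup tables."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .lattice import LatticeGraph, VolumeGrid
from .parcellation import Parcellation
from .phantom import PhantomDataset

__all__ = [
    "load_volume",
    "save_volume",
    "save_labels",
    "load_labels",
    "load_meta_table",
    "write_edge_list",
    "write_voxel_table",
    "save_phantom",
]

_IDENTITY = np.eye(4)


def load_volume(path: str | Path) -> np.ndarray:
    """Load a NIfTI volume as a plain array (3D or 4D)."""
    return np.asarray(nib.load(str(path)).get_fdata())


def save_volume(
    data: np.ndarray, path: str | Path, affine: np.ndarray | None = None
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data), _IDENTITY if affine is None else affine)
    nib.save(img, str(path))
    return path


def save_labels(
    part: Parcellation,
    mask: np.ndarray,
    path: str | Path,
    affine: np.ndarray | None = None,
    background: int = -1,
) -> Path:
    """Write a parcellation as an integer NIfTI label map."""
    return save_volume(
        part.to_volume(mask, background=background).astype(np.int32), path, affine
    )


def load_labels(
    path: str | Path, mask: np.ndarray, provenance: str = "truth"
) -> Parcellation:
    vol = np.asarray(nib.load(str(path)).dataobj)  # keep integer dtype
    return Parcellation.from_volume(vol, mask, provenance=provenance)


def load_meta_table(path: str | Path) -> pd.DataFrame:
    """Meta-region lookup TSV with columns meta_id, name, source_atlas_ids."""
    df = pd.read_csv(path, sep="\t")
    required = {"meta_id", "name"}
    if not required.issubset(df.columns):
        raise ValueError(f"meta-region table needs columns {sorted(required)}")
    return df


def write_edge_list(lattice: LatticeGraph, path: str | Path) -> Path:
    """Weighted lattice as a TSV edge list (voxel indices + weight)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    w = lattice.weights if lattice.weights is not None else np.ones(lattice.m)
    pd.DataFrame(
        {"voxel_i": lattice.edges[:, 0], "voxel_j": lattice.edges[:, 1], "weight": w}
    ).to_csv(path, sep="\t", index=False)
    return path


def write_voxel_table(lattice: LatticeGraph, path: str | Path) -> Path:
    """Voxel index table: node index -> (x, y, z) and meta-region ID."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(lattice.coords, columns=["x", "y", "z"])
    df.insert(0, "voxel", np.arange(lattice.n))
    if lattice.meta_region is not None:
        df["meta_region"] = lattice.meta_region
    df.to_csv(path, sep="\t", index=False)
    return path


def save_phantom(dataset: PhantomDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a phantom as NIfTI volumes plus a JSON sidecar of its spec."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "bold_t1": save_volume(dataset.bold_t1, out / "bold_t1.nii"),
        "bold_t2": save_volume(dataset.bold_t2, out / "bold_t2.nii"),
        "mask": save_volume(dataset.mask.astype(np.uint8), out / "mask.nii"),
        "atlas": save_volume(dataset.atlas.astype(np.int32), out / "atlas.nii"),
        "truth_t1": save_labels(dataset.truth_t1, dataset.mask, out / "truth_t1.nii"),
        "truth_t2": save_labels(dataset.truth_t2, dataset.mask, out / "truth_t2.nii"),
    }
    spec = dataset.spec
    sidecar = out / "phantom.json"
    sidecar.write_text(
        json.dumps(
            {
                "grid_dims": list(spec.grid_dims),
                "n_meta_regions": spec.n_meta_regions,
                "blocks_per_region": spec.blocks_per_region,
                "n_volumes": spec.n_volumes,
                "sampling_interval_s": spec.sampling_interval_s,
                "signal_band_hz": list(spec.signal_band_hz),
                "noise_sd": spec.noise_sd,
                "perturbation_fraction": spec.perturbation_fraction,
                "seed": spec.seed,
            },
            indent=2,
        )
    )
    paths["sidecar"] = sidecar
    return paths
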
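"""End-to-end pipeline: mask -> lattice -> coherence weights -> per-timepoint
Louvain -> aggregation -> label propagation -> per-timepoint ROI networks.

Configuration is a validated JSON document (schema available via
``PipelineConfig.model_json_schema()``); every run writes all intermediates
plus a manifest with content hashes and the seeds used, so reruns can be
compared byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import io as ailp_io
from .consensus import DEFAULT_MAX_SWEEPS, aggregate, ailp, fragmentation_report
from .lattice import (
    DEFAULT_BAND,
    DEFAULT_N_TAPERS,
    DEFAULT_NW,
    VolumeGrid,
    binarize_mask,
    build_lattice,
    weight_lattice,
)
from .metrics import (
    RoiNetwork,
    correlation_network,
    count_links,
    mean_clustering,
    mean_path_length,
    roi_mean_series,
    total_strength,
)
from .parcellation import Parcellation, louvain_partition, modularity_score

__all__ = ["PipelineConfig", "run_pipeline", "run_pipeline_arrays"]

logger = logging.getLogger(__name__)


class MultitaperParams(BaseModel):
    half_bandwidth_product: float = Field(DEFAULT_NW, gt=0)
    n_tapers: int = Field(DEFAULT_N_TAPERS, ge=1)


class LouvainParams(BaseModel):
    seed: int = 0
    resolution: float = Field(1.0, gt=0)


class LpParams(BaseModel):
    seed: int = 0
    max_sweeps: int = Field(DEFAULT_MAX_SWEEPS, ge=1)


class NetworkParams(BaseModel):
    alpha: float = Field(0.05, gt=0, lt=1)
    positive_only: bool = False


class PipelineConfig(BaseModel):
    """Validated configuration of a full two-timepoint run."""

    bold_t1: Path
    bold_t2: Path
    mask: Path
    atlas: Path
    output_dir: Path
    mask_threshold: float = 0.5
    sampling_interval_s: float = Field(2.0, gt=0)
    band: tuple[float, float] = DEFAULT_BAND
    multitaper: MultitaperParams = MultitaperParams()
    louvain: LouvainParams = LouvainParams()
    lp: LpParams = LpParams()
    network: NetworkParams = NetworkParams()

    @field_validator("band")
    @classmethod
    def _band_ordered(cls, v: tuple[float, float]) -> tuple[float, float]:
        if not 0 <= v[0] < v[1]:
            raise ValueError("band must satisfy 0 <= f_lo < f_hi")
        return v

    def validate_inputs(self) -> None:
        for name in ("bold_t1", "bold_t2", "mask", "atlas"):
            p = getattr(self, name)
            if not Path(p).is_file():
                raise FileNotFoundError(f"{name} input not found: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _network_report(net: RoiNetwork) -> dict:
    try:
        path = mean_path_length(net)
        path_value, disconnected = path.value, path.disconnected
    except ValueError:  # edgeless network: no finite pair
        path_value, disconnected = None, True
    return {
        "n_rois": net.n_rois,
        "n_links": count_links(net),
        "total_strength": total_strength(net),
        "mean_clustering": mean_clustering(net),
        "mean_path_length": path_value,
        "disconnected": disconnected,
    }


def run_pipeline_arrays(
    bold_t1: np.ndarray,
    bold_t2: np.ndarray,
    mask: np.ndarray,
    atlas: np.ndarray,
    sampling_interval_s: float = 2.0,
    band: tuple[float, float] = DEFAULT_BAND,
    half_bandwidth_product: float = DEFAULT_NW,
    n_tapers: int = DEFAULT_N_TAPERS,
    louvain_seed: int = 0,
    resolution: float = 1.0,
    lp_seed: int = 0,
    max_sweeps: int = DEFAULT_MAX_SWEEPS,
    alpha: float = 0.05,
    positive_only: bool = False,
) -> dict:
    """In-memory pipeline over already-loaded arrays.

    Returns a dict with the grid, the weighted lattices, the three ROI stages
    (iROI x2, aROI implicit in lpROI provenance, lpROI), fragmentation
    reports, and per-timepoint ROI networks with their global metrics.
    """
    mask = np.asarray(mask, dtype=bool)
    atlas = np.where(mask, np.asarray(atlas), 0).astype(np.int64)
    grid = VolumeGrid(mask=mask, meta_region=atlas)
    lattice = build_lattice(grid)
    logger.info("lattice: %d voxels, %d edges", lattice.n, lattice.m)

    stages: dict = {"grid": grid, "lattice": lattice}
    iroi = {}
    for tp, bold in (("t1", bold_t1), ("t2", bold_t2)):
        t0 = time.perf_counter()
        weighted = weight_lattice(
            lattice,
            bold,
            sampling_interval_s,
            band=band,
            half_bandwidth_product=half_bandwidth_product,
            n_tapers=n_tapers,
        )
        part = louvain_partition(weighted, seed=louvain_seed, resolution=resolution)
        logger.info(
            "%s: %d iROIs, Q=%.4f (%.1fs)",
            tp,
            part.n_rois,
            modularity_score(weighted, part),
            time.perf_counter() - t0,
        )
        stages[f"weighted_{tp}"] = weighted
        iroi[tp] = part
    stages["iroi_t1"], stages["iroi_t2"] = iroi["t1"], iroi["t2"]

    aroi = aggregate(iroi["t1"], iroi["t2"])
    lproi = ailp(lattice, iroi["t1"], iroi["t2"], seed=lp_seed, max_sweeps=max_sweeps)
    stages["aroi"] = aroi
    stages["lproi"] = lproi
    stages["fragmentation"] = {
        "iroi_t1": fragmentation_report(iroi["t1"]),
        "iroi_t2": fragmentation_report(iroi["t2"]),
        "aroi": fragmentation_report(aroi),
        "lproi": fragmentation_report(lproi),
    }

    networks = {}
    for tp, bold in (("t1", bold_t1), ("t2", bold_t2)):
        roi_ids, ts = roi_mean_series(bold, lproi, mask)
        networks[tp] = correlation_network(
            ts, alpha=alpha, roi_ids=roi_ids, positive_only=positive_only
        )
    stages["network_t1"], stages["network_t2"] = networks["t1"], networks["t2"]
    stages["metrics"] = {tp: _network_report(networks[tp]) for tp in ("t1", "t2")}
    return stages


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline from files per a validated config.

    Writes all intermediates (label maps, edge lists, adjacency matrices,
    reports, a resolved-config copy) under ``config.output_dir`` and returns
    a manifest mapping artifact names to paths and content hashes.
    """
    config.validate_inputs()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.model_dump_json(indent=2))

    bold_t1 = ailp_io.load_volume(config.bold_t1)
    bold_t2 = ailp_io.load_volume(config.bold_t2)
    mask_vol = ailp_io.load_volume(config.mask)
    atlas = np.rint(ailp_io.load_volume(config.atlas)).astype(np.int64)
    for name, b in (("bold_t1", bold_t1), ("bold_t2", bold_t2)):
        if b.ndim != 4 or b.shape[:3] != mask_vol.shape:
            raise ValueError(f"{name} grid does not match the mask volume")
    if atlas.shape != mask_vol.shape:
        raise ValueError("atlas grid does not match the mask volume")
    mask = (
        mask_vol.astype(bool)
        if mask_vol.dtype == bool or set(np.unique(mask_vol)) <= {0.0, 1.0}
        else binarize_mask(mask_vol, config.mask_threshold)
    )
    mask &= atlas > 0  # voxels without a meta-region cannot enter the graph

    stages = run_pipeline_arrays(
        bold_t1,
        bold_t2,
        mask,
        atlas,
        sampling_interval_s=config.sampling_interval_s,
        band=config.band,
        half_bandwidth_product=config.multitaper.half_bandwidth_product,
        n_tapers=config.multitaper.n_tapers,
        louvain_seed=config.louvain.seed,
        resolution=config.louvain.resolution,
        lp_seed=config.lp.seed,
        max_sweeps=config.lp.max_sweeps,
        alpha=config.network.alpha,
        positive_only=config.network.positive_only,
    )

    artifacts: dict[str, Path] = {"config": out / "config.json"}
    for name in ("iroi_t1", "iroi_t2", "aroi", "lproi"):
        part: Parcellation = stages[name]
        artifacts[name] = ailp_io.save_labels(part, mask, out / f"{name}.nii")
    for tp in ("t1", "t2"):
        artifacts[f"edges_{tp}"] = ailp_io.write_edge_list(
            stages[f"weighted_{tp}"], out / f"edges_{tp}.tsv"
        )
        net: RoiNetwork = stages[f"network_{tp}"]
        adj = pd.DataFrame(net.weight, index=net.roi_ids, columns=net.roi_ids)
        adj_path = out / f"adjacency_{tp}.tsv"
        adj.to_csv(adj_path, sep="\t")
        artifacts[f"adjacency_{tp}"] = adj_path
    artifacts["voxels"] = ailp_io.write_voxel_table(
        stages["lattice"], out / "voxels.tsv"
    )

    frag_rows = [
        {"stage": name, **vars(rep)} for name, rep in stages["fragmentation"].items()
    ]
    frag_path = out / "fragmentation.tsv"
    pd.DataFrame(frag_rows).to_csv(frag_path, sep="\t", index=False)
    artifacts["fragmentation"] = frag_path

    metrics_path = out / "metrics.json"
    metrics_path.write_text(json.dumps(stages["metrics"], indent=2))
    artifacts["metrics"] = metrics_path

    manifest = {
        "seeds": {"louvain": config.louvain.seed, "lp": config.lp.seed},
        "artifacts": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in artifacts.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
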
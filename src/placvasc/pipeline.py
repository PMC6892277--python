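"""End-to-end runs over the three analysis tracks, driven by a YAML config.

Every run writes its tabular outputs as CSV plus a provenance record
(config hash, seed, package version) sufficient to reproduce them
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .density import (
    block_density,
    chunk_grid_labels,
    density_map_chunked,
    radial_profile,
)
from .errors import ConfigError, DataError
from .geometry import compute_distance_map, normalise_block_location
from .histology import analyse_micrograph, apply_inclusion_rule, summarise_block
from .segmentation import ThresholdPair, find_thresholds, segment
from .skeleton import exclude_large_vessels, measure_radius, skeletonise, skeleton_table
from .stackio import ChunkGrid, read_stack
from .stats import density_location_report


@dataclass
class RunConfig:
    """Run parameters; defaults are the reference analysis settings."""

    out_dir: str = "results"
    stack_dir: str | None = None
    placenta_id: str = "placenta"
    cord_point: tuple[float, float] | None = None  # (y, x) pixels
    voxel_size_um: float = 116.5
    block_voxel_size_um: float = 13.5
    thresholds_auto: bool = True
    thresholds_tissue: float | None = None
    thresholds_microfil: float | None = None
    chunk_grid: tuple[int, int] = (10, 10)
    halo: int = 7
    radius_threshold_vox: float = 6.0
    particle_area_um2: tuple[float, float] = (60.0, 1_000_000.0)
    particle_circularity: tuple[float, float] = (0.20, 1.00)
    fill_cutoffs_um2: tuple[float, float] = (10_000.0, 200.0)
    min_fill_pct: float = 75.0
    blocks_csv: str | None = None
    manifest_csv: str | None = None
    blocks_density_csv: str | None = None
    histology_blocks_csv: str | None = None
    seed: int = 0
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in raw.items() if k in known}
        kwargs["extra"] = {k: v for k, v in raw.items() if k not in known}
        cfg = cls(**kwargs)
        for key in ("cord_point", "chunk_grid", "particle_area_um2",
                    "particle_circularity", "fill_cutoffs_um2"):
            val = getattr(cfg, key)
            if isinstance(val, list):
                setattr(cfg, key, tuple(val))
        return cfg

    def resolve_thresholds(self, volume) -> ThresholdPair:
        if self.thresholds_auto:
            return find_thresholds(volume)
        if self.thresholds_tissue is None or self.thresholds_microfil is None:
            raise ConfigError("manual thresholds requested but not provided")
        return ThresholdPair(self.thresholds_tissue, self.thresholds_microfil)


def _write_provenance(cfg: RunConfig, out_dir: Path, subcommand: str) -> None:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    record = {
        "subcommand": subcommand,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "config": asdict(cfg),
        "seed": cfg.seed,
        "placvasc_version": __version__,
    }
    (out_dir / f"provenance_{subcommand}.json").write_text(
        json.dumps(record, indent=2, sort_keys=True, default=str)
    )


def run_whole(cfg: RunConfig) -> dict:
    """Whole-placenta track: stack -> masks -> skeleton -> filtered vessels
    -> density map (chunk regions) and 100-bin radial profile."""
    if cfg.stack_dir is None:
        raise ConfigError("stack_dir missing from config")
    if cfg.cord_point is None:
        raise ConfigError("cord_point missing from config")
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    volume = read_stack(cfg.stack_dir, voxel_size_um=cfg.voxel_size_um)
    thresholds = cfg.resolve_thresholds(volume)
    tissue, vessel = segment(volume, thresholds)
    if not tissue.any():
        raise DataError("no tissue found above threshold")

    mask2d = tissue.any(axis=0)
    geometry = compute_distance_map(mask2d, cfg.cord_point)

    skel = skeletonise(vessel)
    skel = measure_radius(skel, vessel, volume.voxel_size_um)
    filtered = exclude_large_vessels(vessel, skel, cfg.radius_threshold_vox)

    labels = chunk_grid_labels(mask2d.shape, ChunkGrid(*cfg.chunk_grid))
    dens, counts = density_map_chunked(
        filtered, tissue, labels, grid=ChunkGrid(*cfg.chunk_grid)
    )
    profile = radial_profile(filtered, tissue, geometry, cfg.placenta_id)

    profile.to_frame().to_csv(out_dir / "profile.csv", index=False)
    skeleton_table(skel).to_csv(out_dir / "skeleton.csv", index=False)
    pd.DataFrame(
        {"region": np.arange(len(dens)), "density_pct": dens, "n_voxels": counts}
    ).to_csv(out_dir / "density_map.csv", index=False)
    _write_provenance(cfg, out_dir, "whole")
    return {
        "thresholds": thresholds,
        "profile": profile,
        "density_map": dens,
        "n_skeleton_voxels": len(skel),
    }


def run_block(cfg: RunConfig) -> pd.DataFrame:
    """Block track: per-block stacks + measured distances -> density table."""
    if cfg.blocks_csv is None:
        raise ConfigError("blocks_csv missing from config")
    blocks = pd.read_csv(cfg.blocks_csv)
    if blocks.empty:
        raise DataError("blocks manifest is empty")
    required = {"placenta_id", "block_id", "stack_dir", "d_block_mm", "d_edge_mm"}
    if not required.issubset(blocks.columns):
        raise DataError(f"blocks manifest must have columns {sorted(required)}")
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in blocks.itertuples(index=False):
        volume = read_stack(rec.stack_dir, voxel_size_um=cfg.block_voxel_size_um)
        thresholds = cfg.resolve_thresholds(volume)
        loc = normalise_block_location(rec.d_block_mm, rec.d_edge_mm)
        bd = block_density(
            volume, thresholds, str(rec.placenta_id), str(rec.block_id), loc
        )
        rows.append(asdict(bd))
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "blocks_density.csv", index=False)
    _write_provenance(cfg, out_dir, "block")
    return table


def run_histology(cfg: RunConfig) -> pd.DataFrame:
    """Histology track: micrograph manifest -> particle and block tables."""
    import tifffile

    if cfg.manifest_csv is None:
        raise ConfigError("manifest_csv missing from config")
    manifest = pd.read_csv(cfg.manifest_csv)
    if manifest.empty:
        raise DataError("histology manifest is empty")
    required = {"placenta_id", "block_id", "image", "position", "um_per_px"}
    if not required.issubset(manifest.columns):
        raise DataError(f"histology manifest must have columns {sorted(required)}")
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    particle_rows = []
    block_rows = []
    for (pid, bid), grp in manifest.groupby(["placenta_id", "block_id"]):
        tables, villous, basal = [], [], []
        for rec in grp.itertuples(index=False):
            image = tifffile.imread(rec.image)
            parts, villous_area = analyse_micrograph(
                image,
                rec.um_per_px,
                area_range_um2=cfg.particle_area_um2,
                circ_range=cfg.particle_circularity,
            )
            parts.insert(0, "placenta_id", pid)
            parts.insert(1, "block_id", bid)
            particle_rows.append(parts)
            tables.append(parts)
            villous.append(villous_area)
            basal.append(str(rec.position).lower() == "basal")
        bh = summarise_block(
            str(pid), str(bid), tables, villous, basal, cfg.min_fill_pct
        )
        block_rows.append(asdict(bh))

    particles = pd.concat(particle_rows, ignore_index=True)
    blocks = pd.DataFrame(block_rows)
    particles.to_csv(out_dir / "particles.csv", index=False)
    blocks.to_csv(out_dir / "histology_blocks.csv", index=False)
    _write_provenance(cfg, out_dir, "histology")
    return blocks


def run_stats(cfg: RunConfig) -> dict:
    """Statistics track over the block-density and/or histology tables."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {}
    if cfg.blocks_density_csv:
        blocks = pd.read_csv(cfg.blocks_density_csv)
        report["block_imaging"] = density_location_report(blocks)
    if cfg.histology_blocks_csv:
        hist = pd.read_csv(cfg.histology_blocks_csv)
        included = apply_inclusion_rule(hist, cfg.min_fill_pct)
        report["histology"] = {
            "n_blocks": int(len(hist)),
            "n_included": int(len(included)),
            "n_excluded": int(len(hist) - len(included)),
        }
        if "normalised_location" in hist.columns and len(included) >= 3:
            report["histology"].update(
                density_location_report(
                    included.rename(columns={"density_pct": "density_pct"})
                )
            )
    if not report:
        raise ConfigError("stats needs blocks_density_csv or histology_blocks_csv")
    (out_dir / "stats_report.json").write_text(json.dumps(report, indent=2))
    _write_provenance(cfg, out_dir, "stats")
    return report
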
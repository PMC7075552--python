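"""Synthetic landscapes, presence points and fixtures for the pipeline.

Generates inputs with the statistical structure of the Oklahoma study
system: a contiguous "timberland" region occupying part of a rectangular
grid (anchored at the south-east corner, as the state's forests sit in
its south-east), and ~76 presence points spatially clumped inside that
region.  Points come from a cluster process — cluster centres uniform
over masked cells, members scattered isotropically around them — because
the observed occurrences are clumped and clustering exercises the
simulator's local-neighbourhood logic.

Everything is reproducible from (seed, config); ``write_fixtures`` emits
byte-stable files plus a checksum manifest.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .landscape import (
    GridSpec,
    PresencePointSet,
    write_ascii_grid,
    write_points_csv,
)

__all__ = [
    "SyntheticConfig",
    "generate_timberland_mask",
    "generate_presence_points",
    "write_fixtures",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Settings for the synthetic study system.

    Defaults: 120x120 grid of 500 m cells (a 60x60 km domain), 40% of it
    timberland, 76 presence points in 8 clusters with 1 km scatter.
    """

    seed: int = 0
    n_rows: int = 120
    n_cols: int = 120
    cell_size_m: float = 500.0
    mask_fraction: float = 0.4
    n_points: int = 76
    n_clusters: int = 8
    cluster_sd_m: float = 1000.0

    def __post_init__(self) -> None:
        if not 0.0 < self.mask_fraction <= 1.0:
            raise ValueError("mask_fraction must lie in (0, 1]")
        if self.n_points < 0:
            raise ValueError("n_points must be non-negative")
        if self.cluster_sd_m < 0:
            raise ValueError("cluster_sd_m must be non-negative")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(
            n_rows=self.n_rows, n_cols=self.n_cols, cell_size_m=self.cell_size_m
        )


def generate_timberland_mask(cfg: SyntheticConfig) -> np.ndarray:
    """Contiguous binary timberland mask anchored at the south-east corner.

    Exactly round(mask_fraction x n_cells) cells, filled row-major from
    the grid's last cell backwards: full southern rows plus a partial row
    whose east end touches the block below, so the region is 4-connected.
    Deterministic (the seed only drives point placement).
    """
    n_total = cfg.n_rows * cfg.n_cols
    k = int(round(cfg.mask_fraction * n_total))
    k = max(1, k)
    flat = np.zeros(n_total, dtype=np.uint8)
    flat[n_total - k :] = 1
    return flat.reshape(cfg.n_rows, cfg.n_cols)


def generate_presence_points(
    cfg: SyntheticConfig, mask: np.ndarray
) -> PresencePointSet:
    """Clumped presence points inside the masked region.

    Cluster centres are drawn uniformly over masked cell centroids; each
    point is its centre plus isotropic Gaussian scatter (sd
    ``cluster_sd_m``), redrawn until it lands on a masked cell.
    """
    mask = np.asarray(mask, dtype=bool)
    masked_rows, masked_cols = np.nonzero(mask)
    if masked_rows.size == 0:
        raise ValueError("cannot place presence points: mask is empty")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    spec = cfg.grid
    picks = rng.integers(0, masked_rows.size, size=cfg.n_clusters)
    centers = np.array(
        [spec.cell_centroid(int(masked_rows[i]), int(masked_cols[i])) for i in picks]
    )
    assignment = rng.integers(0, cfg.n_clusters, size=cfg.n_points)
    pts = np.empty((cfg.n_points, 2), dtype=float)
    for i, ci in enumerate(assignment):
        while True:
            xy = centers[ci] + rng.normal(0.0, cfg.cluster_sd_m, size=2)
            rc = spec.point_to_cell(*xy)
            if rc is not None and mask[rc]:
                pts[i] = xy
                break
    return PresencePointSet(points=pts)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


_CONFIG_TEMPLATE = """\
seed: {seed}
kernel:
  constraints:
    - [30.0, 0.90]
    - [1610.0, 0.0005]
grid:
  n_rows: {n_rows}
  n_cols: {n_cols}
  cell_size_m: {cell_size_m}
simulation:
  years: 5
  iterations: 6000
  p_floor: 1.0e-6
scenarios:
  band_a: [0.01, 0.25]
  band_b: [0.25, 1.0]
  scenario_a_includes_b: false
  scenario_c_fraction: 0.1
  report_years: [1, 3, 5]
economics:
  use_default_base: true
sensitivity:
  fractions: ["1/2", "2/3", "3/4"]
synthetic:
  mask_fraction: {mask_fraction}
  n_points: {n_points}
  n_clusters: {n_clusters}
  cluster_sd_m: {cluster_sd_m}
"""


def write_fixtures(out_dir: str | Path, cfg: SyntheticConfig | None = None) -> list[Path]:
    """Emit points CSV, mask grid and a ready-to-run config, plus a manifest.

    Files are byte-stable for a given (seed, config); the manifest lists
    the seed and a sha256 checksum per file.
    """
    cfg = cfg or SyntheticConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mask = generate_timberland_mask(cfg)
    points = generate_presence_points(cfg, mask)

    paths = []
    mask_path = out / "timberland_mask.asc"
    write_ascii_grid(mask_path, mask, cfg.grid, fmt="%d")
    paths.append(mask_path)
    pts_path = out / "presence_points.csv"
    write_points_csv(pts_path, points)
    paths.append(pts_path)
    cfg_path = out / "config.yaml"
    cfg_path.write_text(
        _CONFIG_TEMPLATE.format(
            seed=cfg.seed,
            n_rows=cfg.n_rows,
            n_cols=cfg.n_cols,
            cell_size_m=cfg.cell_size_m,
            mask_fraction=cfg.mask_fraction,
            n_points=cfg.n_points,
            n_clusters=cfg.n_clusters,
            cluster_sd_m=cfg.cluster_sd_m,
        )
    )
    paths.append(cfg_path)

    manifest = out / "MANIFEST.txt"
    lines = [f"seed: {cfg.seed}"]
    lines += [f"{p.name}  sha256:{_sha256(p)}" for p in paths]
    manifest.write_text("\n".join(lines) + "\n")
    paths.append(manifest)
    return paths
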
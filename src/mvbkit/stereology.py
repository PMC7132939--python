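"""Unbiased counting-frame density estimation and Cavalieri point counting.

The counting frame is the 3D "unbiased brick": three inclusion faces meet at
one corner (by convention the low corner) and the opposite three faces are
exclusion planes. An object is counted iff its unique counting point — the
centroid — lies on the inclusion side of every plane: inside the half-open
box [lo, hi). A centroid exactly on an exclusion plane is not counted, one
exactly on an inclusion face is; this gives every object equal counting
probability under translation of the frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import Box3D
from .synthetic import VoxelStack


@dataclass(frozen=True)
class CountingFrame:
    """Unbiased 3D counting frame (brick).

    Inclusion faces are those adjacent to the low corner of ``box``;
    the high faces are exclusion planes.
    """

    box: Box3D

    @classmethod
    def cube(cls, volume_um3: float, origin=(0.0, 0.0, 0.0)) -> "CountingFrame":
        return cls(Box3D.cube(volume_um3, origin))

    @property
    def volume(self) -> float:
        return self.box.volume


def count_in_frame(
    catalog: pd.DataFrame | np.ndarray,
    frame: CountingFrame,
    window: Box3D | None = None,
) -> int:
    """Count objects whose centroid falls inside the brick.

    ``window``, when given, is the parent stack window; the frame must lie
    inside it.
    """
    if window is not None:
        lo_ok = np.all(np.asarray(frame.box.lo) >= np.asarray(window.lo))
        hi_ok = np.all(np.asarray(frame.box.hi) <= np.asarray(window.hi))
        if not (lo_ok and hi_ok):
            raise ValueError("counting frame must lie inside the stack window")
    if isinstance(catalog, pd.DataFrame):
        pts = catalog[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    else:
        pts = np.atleast_2d(np.asarray(catalog, dtype=float))
    if pts.size == 0:
        return 0
    return int(np.count_nonzero(frame.box.contains(pts)))


@dataclass
class DensityResult:
    """Per-stack densities with layer and grand aggregation."""

    per_stack: pd.DataFrame           # stack_id, layer, count, frame_volume_um3, density
    per_layer: pd.DataFrame           # layer, mean, sem, n_stacks
    grand_mean: float
    grand_sem: float
    aggregation: str                  # "layer_mean" or "pooled_stacks"


def estimate_density(
    catalog: pd.DataFrame,
    frames: dict[int, CountingFrame] | CountingFrame,
    aggregation: str = "layer_mean",
) -> DensityResult:
    """Density = count / frame volume per stack, then aggregate.

    Default aggregation is the unweighted mean of layer means ("mean density
    across layers"); ``aggregation="pooled_stacks"`` instead averages all
    stacks with equal weight.
    """
    stack_ids = sorted(catalog["stack_id"].unique()) if len(catalog) else []
    rows = []
    for sid in stack_ids:
        sub = catalog[catalog["stack_id"] == sid]
        frame = frames[sid] if isinstance(frames, dict) else frames
        if frame.volume <= 0:
            raise ValueError("frame volume must be positive")
        n = count_in_frame(sub, frame)
        layer = sub["layer"].iloc[0] if len(sub) else ""
        rows.append(
            {
                "stack_id": sid,
                "layer": layer,
                "count": n,
                "frame_volume_um3": frame.volume,
                "density": n / frame.volume,
            }
        )
    per_stack = pd.DataFrame(
        rows, columns=["stack_id", "layer", "count", "frame_volume_um3", "density"]
    )
    per_layer = aggregate_by_layer(per_stack)

    if aggregation == "layer_mean":
        vals = per_layer["mean"].to_numpy(dtype=float)
    elif aggregation == "pooled_stacks":
        vals = per_stack["density"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    grand_mean = float(np.mean(vals)) if vals.size else float("nan")
    grand_sem = (
        float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
    )
    return DensityResult(per_stack, per_layer, grand_mean, grand_sem, aggregation)


def aggregate_by_layer(per_stack: pd.DataFrame, value: str = "density") -> pd.DataFrame:
    """Layer mean ± sem of a per-stack quantity (stacks weighted equally)."""
    if not len(per_stack):
        return pd.DataFrame(columns=["layer", "mean", "sem", "n_stacks"])
    g = per_stack.groupby("layer", sort=True)[value]
    out = pd.DataFrame(
        {
            "layer": g.mean().index,
            "mean": g.mean().to_numpy(),
            "sem": g.sem().to_numpy(),
            "n_stacks": g.count().to_numpy(),
        }
    ).reset_index(drop=True)
    return out


@dataclass(frozen=True)
class CavalieriGrid:
    """Systematic point grid for Cavalieri volume-fraction estimation.

    ``spacing_nm`` is the XY grid constant (each point carries spacing² of
    associated area); sampling uses every ``section_step``-th section.
    """

    spacing_nm: float = 632.0
    section_step: int = 40

    def __post_init__(self) -> None:
        if self.spacing_nm <= 0:
            raise ValueError("grid spacing must be positive")
        if self.section_step < 1:
            raise ValueError("section step must be >= 1")

    @property
    def associated_area_nm2(self) -> float:
        return self.spacing_nm**2


def cavalieri_volume_fraction(
    stack: VoxelStack,
    grid: CavalieriGrid,
    target_labels: set[int] | list[int],
    use_compartments: bool = False,
    seed: int | None = None,
) -> float:
    """Point-counted volume fraction of a label set.

    Grid points are laid at ``spacing_nm`` in XY on every
    ``section_step``-th section; the fraction is (points hitting the target
    labels) / (points hitting the reference area — here, all grid points
    inside the raster). The grid origin is fixed at half a spacing by
    default, or uniform-random within one grid cell when ``seed`` is given.
    """
    raster = stack.compartments if use_compartments else stack.labels
    if use_compartments and raster is None:
        raise ValueError("stack has no compartment raster")
    geom = stack.geometry
    nz, ny, nx = stack.labels.shape
    vx, vy, vz = geom.voxel_size_nm
    if grid.spacing_nm < min(vx, vy):
        raise ValueError("grid spacing must be at least the voxel size")

    if seed is None:
        ox = oy = grid.spacing_nm / 2.0
        oz = 0
    else:
        rng = np.random.default_rng(seed)
        ox, oy = rng.uniform(0.0, grid.spacing_nm, size=2)
        oz = int(rng.integers(0, grid.section_step))

    xs_nm = np.arange(ox, nx * vx, grid.spacing_nm)
    ys_nm = np.arange(oy, ny * vy, grid.spacing_nm)
    z_idx = np.arange(oz, nz, grid.section_step)
    if xs_nm.size == 0 or ys_nm.size == 0 or z_idx.size == 0:
        raise ValueError("grid produced zero sample points")

    ix = np.minimum((xs_nm / vx).astype(int), nx - 1)
    iy = np.minimum((ys_nm / vy).astype(int), ny - 1)
    sampled = raster[np.ix_(z_idx, iy, ix)]

    targets = np.asarray(sorted(set(int(t) for t in target_labels)))
    hits = np.isin(sampled, targets).sum()
    total = sampled.size
    return float(hits) / float(total)
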
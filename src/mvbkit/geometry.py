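"""Axis-aligned 3D windows and voxel-grid geometry.

All physical coordinates are in micrometres (μm); voxel sizes are given in
nanometres (nm) because that is how FIB-SEM resolutions are reported
(single-digit nm in XY, tens of nm in Z).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NM_PER_UM = 1000.0


class InvalidSpecificationError(ValueError):
    """A spec object violates its invariants."""


class OutOfBoundsError(ValueError):
    """An object does not fit inside the stack it is rendered into."""


@dataclass(frozen=True)
class Box3D:
    """Axis-aligned box window, coordinates in μm."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def __post_init__(self) -> None:
        lo = np.asarray(self.lo, dtype=float)
        hi = np.asarray(self.hi, dtype=float)
        if lo.shape != (3,) or hi.shape != (3,):
            raise InvalidSpecificationError("Box3D corners must be 3-vectors")
        if not np.all(hi > lo):
            raise InvalidSpecificationError(
                f"degenerate window: lo={self.lo}, hi={self.hi}"
            )
        object.__setattr__(self, "lo", tuple(float(v) for v in lo))
        object.__setattr__(self, "hi", tuple(float(v) for v in hi))

    @classmethod
    def cube(cls, volume_um3: float, origin: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> "Box3D":
        side = float(volume_um3) ** (1.0 / 3.0)
        o = np.asarray(origin, dtype=float)
        return cls(tuple(o), tuple(o + side))

    @property
    def sides(self) -> np.ndarray:
        return np.asarray(self.hi) - np.asarray(self.lo)

    @property
    def volume(self) -> float:
        return float(np.prod(self.sides))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: point in the half-open box [lo, hi)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        return np.all((p >= lo) & (p < hi), axis=1)

    def expand(self, margin: float) -> "Box3D":
        lo = np.asarray(self.lo) - margin
        hi = np.asarray(self.hi) + margin
        return Box3D(tuple(lo), tuple(hi))

    def boundary_distance(self, points: np.ndarray) -> np.ndarray:
        """Distance from each point to the nearest face of the box."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        d_lo = p - np.asarray(self.lo)
        d_hi = np.asarray(self.hi) - p
        return np.minimum(d_lo, d_hi).min(axis=1)


@dataclass(frozen=True)
class StackGeometry:
    """Voxel grid of a FIB-SEM stack.

    shape is (nx, ny, nz) voxels; voxel_size_nm is (vx, vy, vz) in nm per
    voxel — independently settable because section thickness (Z) is much
    coarser than the imaging resolution in XY. Label arrays are stored in
    (nz, ny, nx) page order, matching multi-page TIFF.
    """

    shape: tuple[int, int, int]
    voxel_size_nm: tuple[float, float, float] = (20.0, 20.0, 20.0)
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise InvalidSpecificationError(f"bad stack shape {self.shape}")
        if any(v <= 0 for v in self.voxel_size_nm):
            raise InvalidSpecificationError(
                f"voxel sizes must be positive, got {self.voxel_size_nm}"
            )
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(
            self, "voxel_size_nm", tuple(float(v) for v in self.voxel_size_nm)
        )
        object.__setattr__(
            self, "origin_um", tuple(float(v) for v in self.origin_um)
        )

    @property
    def voxel_size_um(self) -> np.ndarray:
        return np.asarray(self.voxel_size_nm) / NM_PER_UM

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))

    @property
    def extent_um(self) -> np.ndarray:
        return np.asarray(self.shape) * self.voxel_size_um

    @property
    def window(self) -> Box3D:
        o = np.asarray(self.origin_um)
        return Box3D(tuple(o), tuple(o + self.extent_um))

    def index_to_um(self, idx_xyz: np.ndarray) -> np.ndarray:
        """Physical position (μm) of voxel centers given 0-based (x, y, z) indices."""
        idx = np.atleast_2d(np.asarray(idx_xyz, dtype=float))
        return np.asarray(self.origin_um) + (idx + 0.5) * self.voxel_size_um

    def um_to_index(self, pos_um: np.ndarray) -> np.ndarray:
        """Voxel (x, y, z) indices containing physical positions (μm)."""
        p = np.atleast_2d(np.asarray(pos_um, dtype=float))
        idx = np.floor((p - np.asarray(self.origin_um)) / self.voxel_size_um)
        return idx.astype(np.int64)

    def empty_labels(self) -> np.ndarray:
        nx, ny, nz = self.shape
        return np.zeros((nz, ny, nx), dtype=np.int32)
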
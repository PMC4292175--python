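"""Shared containers, geometry conventions and file I/O.

Conventions used throughout the package:

* Volumes are 3D numpy arrays indexed ``grid[ix, iy, iz]`` with an isotropic
  physical voxel size in nanometres.
* The physical origin sits at the corner of the first voxel, so voxel ``i``
  is centred at ``(i + 0.5) * voxel_size`` along each axis.
* Rotations are proper (det = +1) and are exchanged on disk as intrinsic
  ZYZ Euler angles in degrees.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class ParameterError(ValueError):
    """A numeric parameter is outside its valid domain."""


class GeometryError(ValueError):
    """Shapes, voxel sizes or coordinates are inconsistent."""


class PlacementError(RuntimeError):
    """Hard-sphere rejection sampling failed to place a particle."""


class ResolutionError(ValueError):
    """A requested feature is not resolvable at the given voxel size."""


class EmptyStackError(ValueError):
    """No subvolumes survived extraction."""


class CardinalityError(ValueError):
    """Too few points for the requested operation."""


class NoPeriodicityError(RuntimeError):
    """A profile shows no usable periodic signal."""


# ---------------------------------------------------------------------------
# Density volumes
# ---------------------------------------------------------------------------

@dataclass
class DensityVolume:
    """A 3D scalar field with isotropic voxel size.

    Parameters
    ----------
    grid
        3D float array indexed ``[ix, iy, iz]``.
    voxel_size
        Edge length of a voxel in nm (identical on all axes).
    origin
        Physical offset (nm) of the corner of voxel (0, 0, 0).
    """

    grid: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 3:
            raise GeometryError(f"grid must be 3D, got {self.grid.ndim}D")
        if not np.all(np.isfinite(self.grid)):
            raise GeometryError("grid contains non-finite values")
        self.voxel_size = float(self.voxel_size)
        if self.voxel_size <= 0:
            raise ParameterError("voxel_size must be > 0")
        self.origin = np.asarray(self.origin, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def extent(self) -> np.ndarray:
        """Physical box dimensions in nm."""
        return np.asarray(self.grid.shape) * self.voxel_size

    def index_to_position(self, idx: np.ndarray) -> np.ndarray:
        """Voxel index -> physical coordinate of that voxel's centre (nm)."""
        return (np.asarray(idx, dtype=float) + 0.5) * self.voxel_size + self.origin

    def position_to_index(self, pos: np.ndarray) -> np.ndarray:
        """Physical coordinate (nm) -> nearest voxel index."""
        idx = np.round((np.asarray(pos, dtype=float) - self.origin)
                       / self.voxel_size - 0.5)
        return idx.astype(int)

    # -- MRC I/O (MRC2014, mode 2 float32) ---------------------------------

    def save_mrc(self, path: str | Path) -> None:
        write_mrc(path, self)

    @classmethod
    def load_mrc(cls, path: str | Path) -> "DensityVolume":
        return read_mrc(path)


_MRC_HEADER_SIZE = 1024


def write_mrc(path: str | Path, volume: DensityVolume) -> None:
    """Write a volume as an MRC2014 mode-2 file.

    The voxel size is recorded in the header cell dimensions (Angstrom),
    following the usual cella / mx convention.
    """
    nx, ny, nz = volume.grid.shape
    vx_ang = volume.voxel_size * 10.0  # nm -> Angstrom
    data = np.ascontiguousarray(
        np.transpose(volume.grid, (2, 1, 0)).astype("<f4"))  # x fastest
    header = bytearray(_MRC_HEADER_SIZE)
    struct.pack_into("<10i", header, 0,
                     nx, ny, nz,        # dimensions
                     2,                 # mode 2 = float32
                     0, 0, 0,          # nxstart/nystart/nzstart
                     nx, ny, nz)       # sampling grid mx/my/mz
    struct.pack_into("<6f", header, 40,
                     nx * vx_ang, ny * vx_ang, nz * vx_ang,  # cella
                     90.0, 90.0, 90.0)                       # cellb
    struct.pack_into("<3i", header, 64, 1, 2, 3)             # mapc/mapr/maps
    struct.pack_into("<3f", header, 76,
                     float(volume.grid.min()), float(volume.grid.max()),
                     float(volume.grid.mean()))
    struct.pack_into("<2i", header, 88, 1, 0)                # ispg, nsymbt
    struct.pack_into("<3f", header, 196, *(volume.origin * 10.0))
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])        # little-endian
    struct.pack_into("<f", header, 216, float(volume.grid.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())


def read_mrc(path: str | Path) -> DensityVolume:
    """Read an MRC2014 mode-2 file written by :func:`write_mrc`."""
    with open(path, "rb") as fh:
        header = fh.read(_MRC_HEADER_SIZE)
        nx, ny, nz, mode = struct.unpack_from("<4i", header, 0)
        if mode != 2:
            raise GeometryError(f"unsupported MRC mode {mode} (only mode 2)")
        mx = struct.unpack_from("<i", header, 28)[0]
        cella_x = struct.unpack_from("<f", header, 40)[0]
        origin = np.array(struct.unpack_from("<3f", header, 196)) / 10.0
        voxel_size = (cella_x / mx) / 10.0 if mx > 0 else 1.0
        raw = np.frombuffer(fh.read(nx * ny * nz * 4), dtype="<f4")
    grid = np.transpose(raw.reshape(nz, ny, nx), (2, 1, 0)).astype(np.float64)
    return DensityVolume(grid, voxel_size, origin)


def bin_volume(volume: DensityVolume, factor: int) -> DensityVolume:
    """Block-average binning by an integer factor (trailing voxels cropped).

    Standard practice for coarse alignment stages: doubles the voxel
    size per factor of 2 while keeping physical coordinates.
    """
    if factor < 1 or int(factor) != factor:
        raise ParameterError("factor must be a positive integer")
    if factor == 1:
        return volume
    n = [s - s % factor for s in volume.grid.shape]
    g = volume.grid[:n[0], :n[1], :n[2]]
    g = g.reshape(n[0] // factor, factor, n[1] // factor, factor,
                  n[2] // factor, factor).mean(axis=(1, 3, 5))
    return DensityVolume(g, volume.voxel_size * factor, volume.origin)


# ---------------------------------------------------------------------------
# Tilt geometry / rigid transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TiltGeometry:
    """Single-axis tilt scheme: half-range and increment in degrees."""

    tilt_increment: float = 2.0
    tilt_range: float = 60.0

    def __post_init__(self) -> None:
        if not (0 < self.tilt_increment <= self.tilt_range):
            raise ParameterError(
                "require 0 < tilt_increment <= tilt_range, got "
                f"{self.tilt_increment}, {self.tilt_range}")


@dataclass
class RigidTransform:
    """Proper rotation plus translation (nm), applied as ``R x + t``."""

    rotation: Rotation
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float)
        mat = self.rotation.as_matrix()
        if abs(np.linalg.det(mat) - 1.0) > 1e-9:
            raise ParameterError("rotation must be proper (det +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(Rotation.identity(), np.zeros(3))

    @classmethod
    def from_euler_zyz(cls, angles_deg: Sequence[float],
                       translation: Sequence[float] = (0.0, 0.0, 0.0)
                       ) -> "RigidTransform":
        return cls(Rotation.from_euler("ZYZ", angles_deg, degrees=True),
                   np.asarray(translation, float))

    def as_euler_zyz(self) -> np.ndarray:
        import warnings
        with warnings.catch_warnings():
            # gimbal-locked angles are still a valid representation
            warnings.filterwarnings("ignore", message="Gimbal lock")
            return self.rotation.as_euler("ZYZ", degrees=True)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.rotation.apply(np.atleast_2d(points)) + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation * other.rotation,
            self.rotation.apply(other.translation) + self.translation)

    def inverse(self) -> "RigidTransform":
        inv = self.rotation.inv()
        return RigidTransform(inv, -inv.apply(self.translation))


def euler_grid(step_deg: float) -> Rotation:
    """Deduplicated intrinsic-ZYZ Euler grid covering SO(3) at ``step_deg``.

    Duplicates arising from the gimbal degeneracy at beta = 0 / 180 are
    removed by canonicalised-quaternion rounding; the identity is always
    included. Ordering is lexicographic in (z1, y, z2), which fixes the
    tie-break for grid searches.
    """
    if step_deg <= 0:
        raise ParameterError("angular step must be > 0")
    z1 = np.arange(0.0, 360.0, step_deg)
    y = np.arange(0.0, 180.0 + 1e-9, step_deg)
    z2 = np.arange(0.0, 360.0, step_deg)
    angles = np.array(np.meshgrid(z1, y, z2, indexing="ij")).reshape(3, -1).T
    rots = Rotation.from_euler("ZYZ", angles, degrees=True)
    quat = rots.as_quat()
    # canonicalise sign, round to merge numerically equal rotations
    sign = np.where(quat[:, 3:4] < 0, -1.0, 1.0)
    sign[quat[:, 3] == 0] = np.where(quat[quat[:, 3] == 0, 0:1] < 0, -1, 1)
    key = np.round(quat * sign, 6)
    _, keep = np.unique(key, axis=0, return_index=True)
    return rots[np.sort(keep)]


# ---------------------------------------------------------------------------
# Particle tables
# ---------------------------------------------------------------------------

@dataclass
class ParticleSet:
    """Particle positions (nm) with optional scores and orientations."""

    positions: np.ndarray
    scores: np.ndarray | None = None
    orientations: Rotation | None = None
    source_volume: str = ""

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        if self.positions.shape[1] != 3:
            raise GeometryError("positions must be (N, 3)")
        if self.scores is not None:
            self.scores = np.asarray(self.scores, float)
            if self.scores.shape[0] != len(self):
                raise GeometryError("scores length mismatch")
            if np.any(self.scores > 1 + 1e-6) or np.any(self.scores < -1 - 1e-6):
                raise ParameterError("scores must lie in [-1, 1]")

    def __len__(self) -> int:
        return self.positions.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = {"x_nm": self.positions[:, 0],
                "y_nm": self.positions[:, 1],
                "z_nm": self.positions[:, 2]}
        if self.orientations is not None:
            import warnings
            with warnings.catch_warnings():
                warnings.filterwarnings("ignore", message="Gimbal lock")
                eul = self.orientations.as_euler("ZYZ", degrees=True)
            cols["rot_z1"], cols["rot_y"], cols["rot_z2"] = eul.T
        if self.scores is not None:
            cols["score"] = self.scores
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ParticleSet":
        df = pd.read_csv(path)
        positions = df[["x_nm", "y_nm", "z_nm"]].to_numpy()
        orientations = None
        if {"rot_z1", "rot_y", "rot_z2"}.issubset(df.columns):
            orientations = Rotation.from_euler(
                "ZYZ", df[["rot_z1", "rot_y", "rot_z2"]].to_numpy(),
                degrees=True)
        scores = df["score"].to_numpy() if "score" in df.columns else None
        return cls(positions, scores=scores, orientations=orientations,
                   source_volume=str(path))


# ---------------------------------------------------------------------------
# Soft-sphere rendering primitive (shared by generator and template)
# ---------------------------------------------------------------------------

def soft_sphere_profile(r: np.ndarray, radius: float,
                        edge_width: float) -> np.ndarray:
    """Radial profile of a cosine-tapered solid sphere.

    The half-cosine edge of width ``edge_width`` (normally one voxel)
    straddles the nominal radius: 1 inside ``radius - edge_width/2``,
    0 outside ``radius + edge_width/2``, so the integrated density
    matches the analytic sphere volume to second order in the taper
    width.
    """
    r = np.asarray(r, float)
    lo = radius - edge_width / 2.0
    hi = radius + edge_width / 2.0
    out = np.zeros_like(r)
    out[r <= lo] = 1.0
    band = (r > lo) & (r < hi)
    out[band] = 0.5 * (1.0 + np.cos(np.pi * (r[band] - lo) / edge_width))
    return out
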
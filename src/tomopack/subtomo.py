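"""Subvolume extraction, symmetry-free iterative averaging, and FSC.

Boxes are cut from the *unfiltered* volume around detected particle
positions (the low-pass is only for matching), aligned to the evolving
average by an exhaustive coarse-to-fine Euler grid search with a
Fourier-correlation shift search, and averaged without imposing any
point-group symmetry. Resolution is estimated by Fourier shell
correlation at the 0.5 threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .core import (DensityVolume, EmptyStackError, GeometryError,
                   ParameterError, ParticleSet, RigidTransform, euler_grid,
                   soft_sphere_profile)

logger = logging.getLogger(__name__)

#: Default cubic box edge (nm) for neighborhood-preserving subvolumes.
DEFAULT_BOX_EDGE = 45.6
#: Coarse-to-fine Euler grid schedule (degrees per iteration).
DEFAULT_ANGULAR_SCHEDULE = (30.0, 30.0, 15.0, 7.5)


@dataclass
class SubvolumeStack:
    """Identically shaped cubic boxes cut around particles."""

    boxes: np.ndarray              # (N, n, n, n)
    voxel_size: float
    box_edge: float
    particle_ids: np.ndarray       # indices into the source ParticleSet

    def __post_init__(self) -> None:
        self.boxes = np.asarray(self.boxes, float)
        if self.boxes.ndim != 4:
            raise GeometryError("boxes must be a (N, n, n, n) array")
        self.particle_ids = np.asarray(self.particle_ids, int)

    def __len__(self) -> int:
        return self.boxes.shape[0]


@dataclass
class FSCCurve:
    """Fourier shell correlation per shell of width one Fourier voxel."""

    frequencies: np.ndarray        # 1/nm, strictly increasing
    correlations: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, float)
        self.correlations = np.asarray(self.correlations, float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise GeometryError("frequencies must be strictly increasing")


@dataclass(frozen=True)
class ResolutionEstimate:
    resolution_nm: float
    crossed: bool                  # False -> curve never fell below threshold


def extract_subvolumes(volume: DensityVolume, particles: ParticleSet,
                       box_edge: float = DEFAULT_BOX_EDGE) -> SubvolumeStack:
    """Cut cubic boxes centred on particle positions (nearest voxel).

    Particles whose box would cross the volume boundary are dropped with
    a logged count; an empty surviving set raises
    :class:`EmptyStackError`.
    """
    n = int(round(box_edge / volume.voxel_size))
    if n < 2:
        raise ParameterError("box_edge smaller than two voxels")
    half_lo = n // 2
    boxes, kept = [], []
    for i, pos in enumerate(particles.positions):
        c = volume.position_to_index(pos - volume.origin)
        lo = c - half_lo
        hi = lo + n
        if np.any(lo < 0) or np.any(hi > np.asarray(volume.grid.shape)):
            continue
        boxes.append(volume.grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]])
        kept.append(i)
    dropped = len(particles) - len(kept)
    if dropped:
        logger.info("extract_subvolumes: dropped %d/%d boundary particle(s)",
                    dropped, len(particles))
    if not boxes:
        raise EmptyStackError("no particle admits a full box")
    return SubvolumeStack(np.stack(boxes), volume.voxel_size,
                          n * volume.voxel_size, np.asarray(kept))


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def _soft_mask(shape: tuple[int, ...]) -> np.ndarray:
    """Soft spherical mask filling the box (two-voxel cosine edge)."""
    centre = (np.asarray(shape) - 1) / 2.0
    ax = [np.arange(s) - c for s, c in zip(shape, centre)]
    r = np.sqrt(ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
                + ax[2][None, None, :] ** 2)
    return soft_sphere_profile(r, min(shape) / 2.0, 2.0)


def _rotate_grid_about_centre(grid: np.ndarray, rot: Rotation) -> np.ndarray:
    """Sample grid at rotated coordinates: out(y) = grid(R y), centre-fixed."""
    mat = rot.as_matrix()
    centre = (np.asarray(grid.shape) - 1) / 2.0
    offset = centre - mat @ centre
    return ndimage.affine_transform(grid, mat, offset=offset, order=1,
                                    mode="constant", cval=0.0)


def _shift_ball_indices(shape: tuple[int, ...], max_shift_vox: float
                        ) -> np.ndarray:
    """Integer shift vectors |u| <= max_shift (for FFT correlation peaks)."""
    s = int(np.floor(max_shift_vox))
    off = np.arange(-s, s + 1)
    ox, oy, oz = np.meshgrid(off, off, off, indexing="ij")
    keep = ox ** 2 + oy ** 2 + oz ** 2 <= max_shift_vox ** 2
    return np.stack([ox[keep], oy[keep], oz[keep]], axis=1)


class _GridAligner:
    """Exhaustive rotation-grid aligner against a fixed reference.

    For rotation R and shift t the aligned box is
    ``box(R^-1 (x - t))``. The score at (R, t) equals the correlation
    of ``ref(R y)`` with the box at shift ``u = R^-1 t``, so each grid
    rotation is applied once to the *reference* and reused for every
    box; the best integer shift within ``max_shift`` is read off the
    FFT cross-correlation. Scores are normalized by the masked,
    mean-subtracted norms of both boxes (evaluated at zero shift).
    """

    def __init__(self, reference: np.ndarray, angular_step: float,
                 max_shift_vox: float):
        if angular_step <= 0:
            raise ParameterError("angular step must be > 0")
        self.rotations = euler_grid(angular_step)
        self.mask = _soft_mask(reference.shape)
        self.msum = self.mask.sum()
        self.shifts = _shift_ball_indices(reference.shape, max_shift_vox)
        self.shape = reference.shape
        self._ref_fts, self._ref_norms = [], []
        for rot in self.rotations:
            ref_r = _rotate_grid_about_centre(reference, rot)
            ref_m = self._premask(ref_r)
            self._ref_fts.append(np.fft.rfftn(ref_m))
            self._ref_norms.append(np.linalg.norm(ref_m))

    def _premask(self, grid: np.ndarray) -> np.ndarray:
        mean = (grid * self.mask).sum() / self.msum
        return (grid - mean) * self.mask

    def align(self, box: np.ndarray) -> tuple[Rotation, np.ndarray, float]:
        """Best (rotation, shift in voxels, score) for one box."""
        box_m = self._premask(box)
        box_norm = np.linalg.norm(box_m)
        if box_norm == 0:
            return Rotation.identity(), np.zeros(3), 0.0
        box_ft = np.fft.rfftn(box_m)
        best = (-np.inf, 0, np.zeros(3))
        sh = self.shifts
        for gi, (ref_ft, ref_norm) in enumerate(
                zip(self._ref_fts, self._ref_norms)):
            if ref_norm == 0:
                continue
            cc = np.fft.irfftn(ref_ft * np.conj(box_ft), s=self.shape,
                               axes=(0, 1, 2))
            vals = cc[sh[:, 0] % self.shape[0], sh[:, 1] % self.shape[1],
                      sh[:, 2] % self.shape[2]] / (ref_norm * box_norm)
            k = int(np.argmax(vals))
            if vals[k] > best[0]:
                best = (float(vals[k]), gi, sh[k].astype(float))
        score, gi, u = best
        rot = self.rotations[gi]
        shift = rot.apply(u)          # t = R u, in voxels
        return rot, shift, score


def align_pair(moving: DensityVolume, reference: DensityVolume,
               angular_step: float = 15.0, max_shift: float = 5.0
               ) -> tuple[RigidTransform, float]:
    """Align one box to a reference by exhaustive ZYZ grid search.

    Returns the transform such that applying it to ``moving``
    (``moving(R^-1 (x - t))``) best matches ``reference``, with the
    constrained-correlation score under a soft spherical mask. Ties on
    the rotation grid break to the first rotation in lexicographic
    Euler order.
    """
    if moving.grid.shape != reference.grid.shape:
        raise GeometryError("align_pair requires equal shapes")
    aligner = _GridAligner(reference.grid, angular_step,
                           max_shift / reference.voxel_size)
    rot, shift_vox, score = aligner.align(moving.grid)
    return (RigidTransform(rot, shift_vox * reference.voxel_size), score)


def apply_transform(box: np.ndarray, transform: RigidTransform,
                    voxel_size: float) -> np.ndarray:
    """Resample a box under a rigid transform about its centre (trilinear)."""
    mat = transform.rotation.as_matrix()
    centre = (np.asarray(box.shape) - 1) / 2.0
    t_vox = transform.translation / voxel_size
    inv = mat.T
    offset = centre - inv @ (centre + t_vox)
    return ndimage.affine_transform(box, inv, offset=offset, order=1,
                                    mode="constant", cval=0.0)


def iterative_average(stack: SubvolumeStack,
                      angular_schedule=DEFAULT_ANGULAR_SCHEDULE,
                      max_shift: float = 5.0, seed: int = 0
                      ) -> tuple[DensityVolume, list[RigidTransform],
                                 np.ndarray]:
    """Iteratively align all boxes to the evolving average (no symmetry).

    Iteration 0 uses the unaligned mean as reference; each subsequent
    pass aligns every box on the scheduled Euler grid and re-averages
    with the transforms applied. Returns the final average, the final
    per-particle transforms (exactly those applied to build the
    average), and the mean alignment score per iteration. A drop in
    mean score logs a warning rather than raising.
    """
    if len(stack) == 0:
        raise EmptyStackError("empty stack")
    vx = stack.voxel_size
    reference = stack.boxes.mean(axis=0)
    transforms = [RigidTransform.identity() for _ in range(len(stack))]
    mean_scores = []
    for step in angular_schedule:
        aligner = _GridAligner(reference, step, max_shift / vx)
        aligned = np.empty_like(stack.boxes)
        scores = np.empty(len(stack))
        for i, box in enumerate(stack.boxes):
            rot, shift_vox, score = aligner.align(box)
            transforms[i] = RigidTransform(rot, shift_vox * vx)
            aligned[i] = apply_transform(box, transforms[i], vx)
            scores[i] = score
        reference = aligned.mean(axis=0)
        mean_scores.append(scores.mean())
        if len(mean_scores) > 1 and (mean_scores[-1]
                                     < mean_scores[-2] - 1e-6):
            logger.warning("iterative_average: mean score dropped "
                           "%.4f -> %.4f", mean_scores[-2], mean_scores[-1])
    return (DensityVolume(reference, vx), transforms,
            np.asarray(mean_scores))


# ---------------------------------------------------------------------------
# Fourier shell correlation
# ---------------------------------------------------------------------------

def fourier_shell_correlation(map_a: DensityVolume,
                              map_b: DensityVolume) -> FSCCurve:
    """FSC over concentric shells of width one Fourier voxel.

    Symmetric in its arguments; shells run from the first non-DC shell
    to Nyquist.
    """
    if map_a.grid.shape != map_b.grid.shape:
        raise GeometryError("FSC requires equal shapes")
    if abs(map_a.voxel_size - map_b.voxel_size) > 1e-9:
        raise GeometryError("FSC requires equal voxel sizes")
    shape = map_a.grid.shape
    fa = np.fft.fftn(map_a.grid)
    fb = np.fft.fftn(map_b.grid)
    k = [np.fft.fftfreq(n) * n for n in shape]
    r = np.sqrt(k[0][:, None, None] ** 2 + k[1][None, :, None] ** 2
                + k[2][None, None, :] ** 2)
    shell = np.round(r).astype(int)
    nmax = min(shape) // 2
    num = np.zeros(nmax + 1)
    pa = np.zeros(nmax + 1)
    pb = np.zeros(nmax + 1)
    flat = shell.ravel()
    sel = flat <= nmax
    np.add.at(num, flat[sel], np.real(fa.ravel()[sel]
                                      * np.conj(fb.ravel()[sel])))
    np.add.at(pa, flat[sel], np.abs(fa.ravel()[sel]) ** 2)
    np.add.at(pb, flat[sel], np.abs(fb.ravel()[sel]) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fsc = num / np.sqrt(pa * pb)
    fsc = np.nan_to_num(fsc[1:], nan=0.0)          # drop DC shell
    freqs = np.arange(1, nmax + 1) / (min(shape) * map_a.voxel_size)
    return FSCCurve(freqs, fsc, map_a.voxel_size)


def resolution_at(curve: FSCCurve, threshold: float = 0.5
                  ) -> ResolutionEstimate:
    """Resolution (nm) at the first crossing below ``threshold``.

    The crossing is located by linear interpolation in frequency; a
    shell sitting exactly at the threshold counts as the crossing (tie
    rule). If the curve never falls to the threshold, the Nyquist
    spacing is returned with ``crossed=False``.
    """
    if len(curve.correlations) == 0:
        raise ParameterError("empty FSC curve")
    c = curve.correlations
    f = curve.frequencies
    below = np.nonzero(c <= threshold)[0]
    if below.size == 0:
        return ResolutionEstimate(2.0 * curve.voxel_size, False)
    i = int(below[0])
    if i == 0 or c[i] == threshold:
        return ResolutionEstimate(1.0 / f[i], True)
    frac = (c[i - 1] - threshold) / (c[i - 1] - c[i])
    f_cross = f[i - 1] + frac * (f[i] - f[i - 1])
    return ResolutionEstimate(1.0 / f_cross, True)
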
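"""Particle localization by spherical-template matching.

A rotation-free search: because the template is a sphere, a single
locally normalized cross-correlation pass localizes every particle. The
volume is first low-pass filtered to the resolution the tilt sampling
supports for a particle of given diameter (Crowther criterion), then
correlation peaks are exhaustively extracted under a hard-sphere
exclusion radius.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

from .core import (DensityVolume, GeometryError, ParameterError, ParticleSet,
                   ResolutionError, TiltGeometry, soft_sphere_profile)
from .latticegen import missing_wedge_mask

#: Template diameter (nm) used for RuBisCO localization.
DEFAULT_TEMPLATE_DIAMETER = 13.68
#: Particle diameter (nm) defining the Crowther low-pass cutoff.
DEFAULT_CROWTHER_DIAMETER = 12.0


def make_spherical_template(diameter: float, voxel_size: float
                            ) -> DensityVolume:
    """Centred soft-edged sphere in a cubic box, values in [0, 1].

    The box edge is at least ``diameter + 2`` voxels and odd, so the
    sphere centre coincides with the centre voxel. The edge taper is
    the same one-voxel cosine used by the scene renderer.
    """
    if voxel_size <= 0:
        raise ParameterError("voxel_size must be > 0")
    if diameter < 2 * voxel_size:
        raise ResolutionError("diameter must be >= 2 voxels")
    n = int(np.ceil(diameter / voxel_size)) + 3
    if n % 2 == 0:
        n += 1
    centre = (n / 2.0) * voxel_size
    ax = (np.arange(n) + 0.5) * voxel_size - centre
    r = np.sqrt(ax[:, None, None] ** 2 + ax[None, :, None] ** 2
                + ax[None, None, :] ** 2)
    grid = soft_sphere_profile(r, diameter / 2.0, voxel_size)
    return DensityVolume(grid, voxel_size)


def crowther_cutoff(particle_diameter: float, tilt: TiltGeometry,
                    voxel_size: float | None = None) -> float:
    """Resolution (nm) attainable for a particle under the tilt sampling.

    Uses N = 180 / tilt_increment projections over a half-turn and
    d = pi * D / N. If ``voxel_size`` is given, the cutoff is clamped to
    be no finer than the Nyquist spacing ``2 * voxel_size`` (the nominal
    2-degree cutoff is sub-pixel at typical tomogram voxel sizes).
    """
    if particle_diameter <= 0:
        raise ParameterError("particle_diameter must be > 0")
    n_proj = 180.0 / tilt.tilt_increment
    d_res = np.pi * particle_diameter / n_proj
    if voxel_size is not None:
        d_res = max(d_res, 2.0 * voxel_size)
    return float(d_res)


def lowpass(volume: DensityVolume, cutoff_resolution: float) -> DensityVolume:
    """Fourier low-pass with a raised-cosine edge of 3 Fourier voxels.

    Amplitudes beyond spatial frequency ``1 / cutoff_resolution`` roll
    off through a half-cosine; DC is untouched so the mean is preserved.
    """
    if cutoff_resolution < 2.0 * volume.voxel_size - 1e-9:
        raise ParameterError("cutoff finer than the Nyquist spacing")
    shape = volume.grid.shape
    freqs = [np.fft.fftfreq(n, d=volume.voxel_size) for n in shape[:2]]
    freqs.append(np.fft.rfftfreq(shape[2], d=volume.voxel_size))
    fmag = np.sqrt(freqs[0][:, None, None] ** 2 + freqs[1][None, :, None] ** 2
                   + freqs[2][None, None, :] ** 2)
    fc = 1.0 / cutoff_resolution
    width = 3.0 / (max(shape) * volume.voxel_size)   # 3 Fourier voxels
    filt = np.ones_like(fmag)
    band = (fmag > fc) & (fmag < fc + width)
    filt[fmag >= fc + width] = 0.0
    filt[band] = 0.5 * (1.0 + np.cos(np.pi * (fmag[band] - fc) / width))
    ft = np.fft.rfftn(volume.grid) * filt
    grid = np.fft.irfftn(ft, s=shape, axes=(0, 1, 2))
    return DensityVolume(grid, volume.voxel_size, volume.origin)


def _correlate_same(volume: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """corr[p] = sum_q volume[p + q] * kernel[q], kernel centred (odd)."""
    return fftconvolve(volume, kernel[::-1, ::-1, ::-1], mode="same")


def match_template(volume: DensityVolume, template: DensityVolume,
                   tilt: TiltGeometry | None = None) -> DensityVolume:
    """Locally normalized cross-correlation map of a spherical template.

    At each position the template is correlated with the volume patch
    under a binary spherical mask, normalizing by the patch mean and
    standard deviation under that mask, so scores are comparable across
    an uneven background. No rotational search is performed. Positions
    whose mask overlaps the volume boundary are set to -1; where the
    local variance vanishes the score is defined as 0. If a tilt
    geometry is supplied, its missing wedge is imposed on the template
    so the reference matches wedge-distorted data.
    """
    if abs(volume.voxel_size - template.voxel_size) > 1e-9:
        raise GeometryError("voxel size mismatch between volume and template")
    if any(t > v for t, v in zip(template.grid.shape, volume.grid.shape)):
        raise GeometryError("template larger than volume")

    tgrid = template.grid
    if tilt is not None:
        ft = np.fft.fftn(tgrid)
        ft *= missing_wedge_mask(tgrid.shape, tilt)
        tgrid = np.real(np.fft.ifftn(ft))

    n = tgrid.shape[0]
    centre = (np.asarray(tgrid.shape) - 1) / 2.0
    ax = [np.arange(s) - c for s, c in zip(tgrid.shape, centre)]
    r = np.sqrt(ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
                + ax[2][None, None, :] ** 2)
    mask = (r <= n / 2.0).astype(float)
    m = mask.sum()

    t_mean = (tgrid * mask).sum() / m
    t0 = (tgrid - t_mean) * mask
    t_norm = np.sqrt((t0 ** 2).sum())
    if t_norm == 0:
        raise ParameterError("template is constant under its mask")

    v = volume.grid
    num = _correlate_same(v, t0)
    s1 = _correlate_same(v, mask)
    s2 = _correlate_same(v * v, mask)
    var = np.maximum(s2 - s1 * s1 / m, 0.0)
    denom = np.sqrt(var) * t_norm

    floor = 1e-12 * max(float(var.max()), 1e-30)
    ncc = np.zeros_like(v)
    good = var > floor
    ncc[good] = num[good] / denom[good]
    ncc = np.clip(ncc, -1.0, 1.0)

    half = [s // 2 for s in tgrid.shape]
    for axis, h in enumerate(half):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(0, h)
        sl_hi[axis] = slice(v.shape[axis] - h, None)
        ncc[tuple(sl_lo)] = -1.0
        ncc[tuple(sl_hi)] = -1.0
    return DensityVolume(ncc, volume.voxel_size, volume.origin)


def extract_peaks(corr: DensityVolume, exclusion_radius: float,
                  max_peaks: int | None = None,
                  min_score: float = 0.0) -> ParticleSet:
    """Greedy exhaustive peak extraction under a hard exclusion radius.

    Repeatedly takes the global maximum of the correlation map, records
    its position and score, and silences a sphere of ``exclusion_radius``
    around it, stopping when ``max_peaks`` is reached or the next maximum
    falls below ``min_score``. Positions are voxel centres in nm, sorted
    by descending score. An empty result is valid.
    """
    if exclusion_radius <= 0:
        raise ParameterError("exclusion_radius must be > 0")
    work = corr.grid.copy()
    vx = corr.voxel_size
    rvox = int(np.ceil(exclusion_radius / vx))
    off = np.arange(-rvox, rvox + 1)
    ox, oy, oz = np.meshgrid(off, off, off, indexing="ij")
    ball = (ox ** 2 + oy ** 2 + oz ** 2) * vx ** 2 <= exclusion_radius ** 2
    ball_off = np.stack([ox[ball], oy[ball], oz[ball]], axis=1)

    positions, scores = [], []
    shape = np.asarray(work.shape)
    limit = max_peaks if max_peaks is not None else work.size
    while len(positions) < limit:
        flat = int(np.argmax(work))
        idx = np.asarray(np.unravel_index(flat, work.shape))
        score = work[tuple(idx)]
        if score < min_score:
            break
        positions.append(corr.index_to_position(idx))
        scores.append(float(score))
        pts = idx + ball_off
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        p = pts[ok]
        work[p[:, 0], p[:, 1], p[:, 2]] = -np.inf
    if not positions:
        return ParticleSet(np.empty((0, 3)), scores=np.empty(0),
                           source_volume="")
    return ParticleSet(np.asarray(positions), scores=np.asarray(scores))
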
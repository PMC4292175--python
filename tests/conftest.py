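"""Shared fixtures and independent oracle implementations.

The oracle functions here are deliberately naive (direct sums,
exhaustive enumeration) so they stay independent of the FFT / vectorised
code paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import ndimage

import tomopack as tp


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def asymmetric_volume():
    """A smooth density with no rotational or mirror symmetry."""
    grid = np.zeros((16, 16, 16))
    grid[4, 6, 8] = 3.0
    grid[9, 7, 7] = 2.0
    grid[7, 11, 6] = 1.5
    grid[6, 8, 10] = 1.0
    grid = ndimage.gaussian_filter(grid, 1.2)
    return tp.DensityVolume(grid, 1.0)


@pytest.fixture()
def hcp_scene():
    spec = tp.LatticeSpec(tp.LatticeModel.HCP, 15.05)
    return tp.generate_lattice_points(spec, (100.0, 100.0, 100.0))


def interior_positions(scene, margin):
    pos = scene.positions
    keep = np.all((pos > margin) & (pos < scene.extent - margin), axis=1)
    return pos[keep]


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def direct_masked_ncc(volume: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Sliding-window locally normalized correlation by direct summation.

    Boundary positions (mask outside the volume) are set to -1; zero
    local variance gives 0, mirroring the fast path's contract.
    """
    n = template.shape[0]
    centre = (np.asarray(template.shape) - 1) / 2.0
    ax = [np.arange(s) - c for s, c in zip(template.shape, centre)]
    r = np.sqrt(ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
                + ax[2][None, None, :] ** 2)
    mask = r <= n / 2.0
    m = mask.sum()
    t_mean = template[mask].mean()
    t0 = np.where(mask, template - t_mean, 0.0)
    t_norm = np.sqrt((t0 ** 2).sum())
    half = n // 2
    out = np.full(volume.shape, -1.0)
    for i in range(half, volume.shape[0] - half):
        for j in range(half, volume.shape[1] - half):
            for k in range(half, volume.shape[2] - half):
                patch = volume[i - half:i - half + n, j - half:j - half + n,
                               k - half:k - half + n]
                pv = patch[mask]
                var = ((pv - pv.mean()) ** 2).sum()
                if var <= 1e-12 * max(pv.max() ** 2, 1e-30) * m:
                    out[i, j, k] = 0.0
                else:
                    out[i, j, k] = float(
                        (patch * t0).sum() / np.sqrt(var) / t_norm)
    return out


def exhaustive_kmeans_objective(points: np.ndarray, k: int) -> float:
    """Globally optimal k-means objective by enumerating all assignments."""
    best = np.inf
    npts = len(points)
    for assign in itertools.product(range(k), repeat=npts):
        assign = np.asarray(assign)
        if len(set(assign)) < k:
            continue
        obj = 0.0
        for c in range(k):
            cluster = points[assign == c]
            obj += ((cluster - cluster.mean(axis=0)) ** 2).sum()
        best = min(best, obj)
    return best


def distance_census(positions: np.ndarray, centre_point: np.ndarray,
                    tol: float = 1e-6) -> dict:
    """Sorted distance classes (rounded) from one point to all others."""
    d = np.linalg.norm(positions - centre_point, axis=1)
    d = np.sort(d[d > tol])
    classes: dict[float, int] = {}
    for v in map(float, d):
        matched = next((c for c in classes if abs(c - v) < tol * 10), None)
        if matched is None:
            classes[v] = 1
        else:
            classes[matched] += 1
    return classes
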
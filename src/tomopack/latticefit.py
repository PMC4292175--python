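"""Hard-sphere lattice fitting by rotationally registered RMSD.

The cluster centers live in the subtomogram average's frame, which
bears no relation to ideal lattice axes, so every candidate model is
first rotationally registered to the data: a coarse Euler grid of
starts, each refined by iterative closest-correspondence (re-assign
each data point to its nearest model point, re-solve the optimal
rotation by SVD on the correspondences, repeat to convergence). The
sphere diameter is scanned per model and the model with the smallest
minimal RMSD wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .core import CardinalityError, ParameterError, euler_grid
from .latticegen import LatticeModel, LatticeSpec, ideal_unit_cell, \
    _lattice_points_near

#: Diameter scan defaults (nm): coarse grid and refinement pass.
DEFAULT_SCAN = dict(d_min=10.0, d_max=20.0, step=0.05, refine_step=0.01)
#: Coarse rotation-grid spacing (degrees) for registration starts.
DEFAULT_GRID_STEP = 15.0
_WARM_STARTS = 24      # rotations carried between neighboring scan diameters
_MAX_ICP_ITER = 60


@dataclass(frozen=True)
class RegistrationResult:
    rmsd: float
    rotation: Rotation
    mirrored: bool = False


@dataclass
class ScanResult:
    """RMSD-vs-diameter curve for one lattice model."""

    model: LatticeModel
    diameters: np.ndarray
    rmsds: np.ndarray
    best_diameter: float
    best_rmsd: float
    best_rotation: Rotation
    at_boundary: bool


@dataclass
class FitResult:
    """Outcome of model selection over HCP / CCP / BCC."""

    model: LatticeModel
    diameter: float
    rmsd: float
    rotation: Rotation
    curves: dict = field(default_factory=dict)      # model -> ScanResult
    at_boundary: bool = False
    ambiguous_with: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

def _batched_icp(data: np.ndarray, model: np.ndarray,
                 rotations: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Refine a batch of start rotations by closest-correspondence ICP.

    ``rotations`` is (G, 3, 3), data (N, 3), model (M, 3). Each step
    assigns every data point to its nearest rotated model point (model
    points reusable) and re-solves the rotation on the correspondences
    by SVD, projecting onto det = +1. Returns (rmsd per start, final
    rotation matrices).
    """
    R = rotations.copy()
    prev_assign = None
    for _ in range(_MAX_ICP_ITER):
        rm = np.einsum("gij,mj->gmi", R, model)             # (G, M, 3)
        diff = data[None, :, None, :] - rm[:, None, :, :]   # (G, N, M, 3)
        d2 = np.einsum("gnmi,gnmi->gnm", diff, diff)
        assign = np.argmin(d2, axis=2)                      # (G, N)
        if prev_assign is not None and np.array_equal(assign, prev_assign):
            break
        prev_assign = assign
        msel = model[assign]                                # (G, N, 3)
        H = np.einsum("gni,gnj->gij", data[None].repeat(len(R), 0), msel)
        U, _, Vt = np.linalg.svd(H)
        det = np.linalg.det(U @ Vt)
        D = np.repeat(np.eye(3)[None], len(R), axis=0)
        D[:, 2, 2] = det
        R = U @ D @ Vt
    rm = np.einsum("gij,mj->gmi", R, model)
    diff = data[None, :, None, :] - rm[:, None, :, :]
    d2 = np.einsum("gnmi,gnmi->gnm", diff, diff)
    rmsd = np.sqrt(d2.min(axis=2).mean(axis=1))
    return rmsd, R


def registered_rmsd(centers: np.ndarray, model_points: np.ndarray,
                    grid_step: float = DEFAULT_GRID_STEP,
                    include_mirror: bool = True,
                    starts: np.ndarray | None = None
                    ) -> RegistrationResult:
    """Best rotation about the origin minimizing nearest-correspondence RMSD.

    Correspondences run data -> nearest model point (model points may be
    reused). Only proper rotations are searched; the enantiomorph is
    handled by also registering the z-mirrored model set and reporting
    the better of the two (``mirrored`` flag). ``starts`` replaces the
    default coarse grid with explicit (G, 3, 3) start rotations.
    """
    centers = np.atleast_2d(np.asarray(centers, float))
    model_points = np.atleast_2d(np.asarray(model_points, float))
    if len(centers) == 0 or len(model_points) == 0:
        raise CardinalityError("both point sets must be non-empty")
    if starts is None:
        starts = euler_grid(grid_step).as_matrix()
    best: RegistrationResult | None = None
    variants = [(model_points, False)]
    if include_mirror:
        variants.append((model_points * np.array([1.0, 1.0, -1.0]), True))
    for pts, mirrored in variants:
        rmsds, mats = _batched_icp(centers, pts, starts)
        g = int(np.argmin(rmsds))
        cand = RegistrationResult(float(rmsds[g]),
                                  Rotation.from_matrix(mats[g]), mirrored)
        if best is None or cand.rmsd < best.rmsd:
            best = cand
    return best


# ---------------------------------------------------------------------------
# Diameter scan and model selection
# ---------------------------------------------------------------------------

def model_neighborhood(model: LatticeModel, diameter: float,
                       query_radius: float | None = None) -> np.ndarray:
    """Ideal model point set at a given diameter.

    Default: the unit-cell neighborhood (origin + contact shell),
    matching cluster-center fitting. With ``query_radius``, all lattice
    points within that radius are returned instead, for fitting clouds
    that retain second-shell points.
    """
    spec = LatticeSpec(model, diameter)
    if query_radius is None:
        return ideal_unit_cell(spec)
    return _lattice_points_near(spec, query_radius)


def _rmsd_for_diameter(centers: np.ndarray, model: LatticeModel, d: float,
                       query_radius: float | None,
                       starts: np.ndarray | None) -> RegistrationResult:
    pts = model_neighborhood(model, d, query_radius)
    return registered_rmsd(centers, pts, starts=starts)


def scan_diameter(centers: np.ndarray, model: LatticeModel,
                  d_min: float = DEFAULT_SCAN["d_min"],
                  d_max: float = DEFAULT_SCAN["d_max"],
                  step: float = DEFAULT_SCAN["step"],
                  refine_step: float | None = DEFAULT_SCAN["refine_step"],
                  query_radius: float | None = None,
                  grid_step: float = DEFAULT_GRID_STEP) -> ScanResult:
    """RMSD curve over sphere diameters with a refinement pass.

    The full rotation grid is searched at the first diameter; subsequent
    diameters warm-start from the best rotations found so far (the
    registration optimum moves continuously with the scale). After the
    coarse scan, a ``refine_step`` pass brackets the coarse arg-min one
    coarse step to either side. An arg-min at the scan boundary is
    flagged, not silently reported.
    """
    if not (d_min < d_max):
        raise ParameterError("require d_min < d_max")
    if step <= 0:
        raise ParameterError("step must be > 0")
    centers = np.atleast_2d(np.asarray(centers, float))
    diameters = np.arange(d_min, d_max + step / 2, step)

    full_grid = euler_grid(grid_step).as_matrix()
    warm: np.ndarray | None = None
    rmsds = np.empty(len(diameters))
    rotations = []
    for i, d in enumerate(diameters):
        starts = full_grid if warm is None else warm
        res = _rmsd_for_diameter(centers, model, d, query_radius, starts)
        rmsds[i] = res.rmsd
        rotations.append(res)
        if warm is None:
            # carry the K most promising refined rotations forward
            pts = model_neighborhood(model, d, query_radius)
            all_r, all_m = _batched_icp(centers, pts, full_grid)
            order = np.argsort(all_r)[:_WARM_STARTS]
            warm = all_m[order]
        else:
            warm = np.concatenate([res.rotation.as_matrix()[None], warm])[
                :_WARM_STARTS + 1]

    i_best = int(np.argmin(rmsds))
    best_d = float(diameters[i_best])
    best = rotations[i_best]

    if refine_step is not None and refine_step < step:
        lo = max(d_min, best_d - step)
        hi = min(d_max, best_d + step)
        fine = np.arange(lo, hi + refine_step / 2, refine_step)
        for d in fine:
            res = _rmsd_for_diameter(centers, model, float(d), query_radius,
                                     warm)
            if res.rmsd < best.rmsd:
                best, best_d = res, float(d)

    at_boundary = bool(abs(best_d - d_min) < step / 2
                       or abs(best_d - d_max) < step / 2)
    return ScanResult(model, diameters, rmsds, best_d, best.rmsd,
                      best.rotation, at_boundary)


def select_model(centers: np.ndarray,
                 models=(LatticeModel.HCP, LatticeModel.CCP,
                         LatticeModel.BCC),
                 **scan_kwargs) -> FitResult:
    """Scan every candidate model and return the best hard-sphere fit.

    Per-model RMSD curves are retained for reporting. Models whose
    minimal RMSDs tie within 1e-9 are reported as ambiguous (all tied
    models listed in ``ambiguous_with``).
    """
    curves = {m: scan_diameter(centers, m, **scan_kwargs) for m in models}
    winner = min(curves.values(), key=lambda r: r.best_rmsd)
    ties = [r.model for r in curves.values()
            if r.model is not winner.model
            and abs(r.best_rmsd - winner.best_rmsd) < 1e-9]
    return FitResult(model=winner.model, diameter=winner.best_diameter,
                     rmsd=winner.best_rmsd, rotation=winner.best_rotation,
                     curves=curves, at_boundary=winner.at_boundary,
                     ambiguous_with=ties)
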
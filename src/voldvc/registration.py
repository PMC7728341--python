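"""Rigid-body pre-registration between repeated scans.

Before correlation, the residual rigid motion between the two scans is
estimated by minimising the intensity Euclidean distance — the square root
of the summed squared voxel intensity differences — over three translations
and three rotations, and the recovered transform is applied to the target
volume by trilinear interpolation. Removing rigid motion first matters
because any uncorrected offset shows up downstream as spurious displacement
(and, through its spatial gradient, spurious strain).

Optimisation is a derivative-free Nelder-Mead simplex over the six
parameters, preceded by a coarse integer-voxel grid search over translations
(+-4 voxels, step 2) to avoid local minima; integer-voxel shifts are applied
exactly (array slicing, no interpolation). Rotations are intrinsic,
x-then-y-then-z, about the physical volume centre by default — only the
composed map matters, so any fixed documented convention suffices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .volume_io import Mask, Volume, check_compatible

__all__ = [
    "RigidTransform",
    "RegistrationResult",
    "euclidean_distance",
    "apply_transform",
    "register_rigid",
]

ROTATION_CONVENTION = "intrinsic x-y-z about center, degrees"


@dataclass(frozen=True)
class RigidTransform:
    """Map x -> R(x - c) + c + t (translations in mm, rotations in degrees)."""

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def is_identity(self) -> bool:
        return not (any(self.translation) or any(self.rotation))

    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler("XYZ", self.rotation, degrees=True).as_matrix()

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        return (np.asarray(pts, dtype=np.float64) - c) @ self.rotation_matrix().T + c + t

    def inverse_points(self, pts: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        return (np.asarray(pts, dtype=np.float64) - c - t) @ self.rotation_matrix() + c

    def inverse(self) -> "RigidTransform":
        R = self.rotation_matrix()
        rot_inv = Rotation.from_matrix(R.T).as_euler("XYZ", degrees=True)
        t_inv = -R.T @ np.asarray(self.translation)
        return RigidTransform(tuple(t_inv), tuple(rot_inv), self.center)

    def as_dict(self) -> dict:
        return {
            "translation_mm": list(self.translation),
            "rotation_deg": list(self.rotation),
            "center_mm": list(self.center),
            "convention": ROTATION_CONVENTION,
        }


@dataclass
class RegistrationResult:
    """Outcome of :func:`register_rigid`: the transform plus diagnostics."""

    transform: RigidTransform
    initial_distance: float
    final_distance: float
    n_evaluations: int
    converged: bool
    trace: np.ndarray  # best-so-far objective after each evaluation


def euclidean_distance(a: Volume, b: Volume, mask: Mask | None = None) -> float:
    """sqrt(sum over (in-mask) voxels of (a - b)^2); 0 iff identical there."""
    check_compatible(a, b, mask)
    da = np.asarray(a.data, dtype=np.float64)
    db = np.asarray(b.data, dtype=np.float64)
    diff = da - db
    if mask is not None:
        diff = diff[mask.data]
    return float(np.sqrt(np.sum(diff * diff)))


def _integer_shift(data: np.ndarray, shift: tuple[int, int, int]) -> np.ndarray:
    """Exact shifted copy out[i] = in[i - s], zero-filled outside."""
    out = np.zeros_like(data, dtype=np.float64)
    src = []
    dst = []
    for n, s in zip(data.shape, shift):
        dst.append(slice(max(0, s), n + min(0, s)))
        src.append(slice(max(0, -s), n + min(0, -s)))
    out[tuple(dst)] = data[tuple(src)]
    return out


def apply_transform(
    volume: Volume,
    transform: RigidTransform,
    order: int = 1,
    return_valid: bool = False,
):
    """Resample ``volume`` under the rigid map.

    Output voxel x takes the value of the input at the pulled-back coordinate
    T^{-1}(x), sampled with trilinear interpolation (``order`` configurable).
    Out-of-field voxels are set to 0 (and flagged when ``return_valid``).
    The identity transform and exact integer-voxel translations bypass
    interpolation entirely.
    """
    data = np.asarray(volume.data, dtype=np.float64)
    if transform.is_identity:
        out = Volume(data.copy(), volume.voxel_size, volume.origin)
        if return_valid:
            return out, np.ones(volume.shape, dtype=bool)
        return out
    vs = volume.voxel_size
    t_vox = np.asarray(transform.translation) / vs
    if not any(transform.rotation) and np.allclose(t_vox, np.round(t_vox), atol=1e-12):
        s = tuple(int(v) for v in np.round(t_vox))
        out = Volume(_integer_shift(data, s), vs, volume.origin)
        if return_valid:
            valid = _integer_shift(np.ones(volume.shape), s) > 0.5
            return out, valid
        return out
    pts = volume.grid_points()
    src = transform.inverse_points(pts.reshape(-1, 3))
    idx = (src - np.asarray(volume.origin)) / vs
    sampled = map_coordinates(
        data, idx.T, order=order, mode="constant", cval=0.0
    ).reshape(volume.shape)
    out = Volume(sampled, vs, volume.origin)
    if return_valid:
        lim = np.asarray(volume.shape, dtype=np.float64) - 1.0
        valid = ((idx >= 0.0) & (idx <= lim)).all(axis=1).reshape(volume.shape)
        return out, valid
    return out


def register_rigid(
    reference: Volume,
    target: Volume,
    mask: Mask | None = None,
    presearch: bool = True,
    presearch_range_vox: int = 4,
    presearch_step_vox: int = 2,
    max_iter: int = 500,
    ftol: float = 1e-6,
    xatol: float = 1e-3,
) -> RegistrationResult:
    """Estimate the rigid transform aligning ``target`` onto ``reference``.

    Minimises ``euclidean_distance(reference, apply_transform(target, T), mask)``.
    The returned final distance never exceeds the initial (identity) distance.
    Non-convergence within the iteration budget warns and returns the best
    transform found so far, flagged via ``converged=False``.
    """
    check_compatible(reference, target, mask)
    vs = reference.voxel_size
    center = tuple((np.asarray(reference.shape) - 1) / 2.0 * vs)
    trace: list[float] = []
    ref_data = np.asarray(reference.data, dtype=np.float64)
    roi = mask.data if mask is not None else np.ones(reference.shape, dtype=bool)
    n_roi = float(roi.sum())

    def objective(p: np.ndarray) -> float:
        # p = (tx, ty, tz) voxels, (rx, ry, rz) degrees. Out-of-field voxels
        # are excluded and the summed square rescaled to the full ROI count,
        # otherwise the zero fill would swamp the intensity term whenever the
        # background level is nonzero.
        tr = RigidTransform(tuple(np.asarray(p[:3]) * vs), tuple(p[3:6]), center)
        moved, valid = apply_transform(target, tr, return_valid=True)
        sel = roi & valid
        n = int(sel.sum())
        if n == 0:
            return float("inf")
        diff = ref_data[sel] - moved.data[sel]
        d = float(np.sqrt(np.sum(diff * diff) * (n_roi / n)))
        trace.append(min(d, trace[-1]) if trace else d)
        return d

    x0 = np.zeros(6)
    d0 = objective(x0)
    best_x, best_d = x0.copy(), d0

    if presearch and d0 > 0:
        r, s = presearch_range_vox, presearch_step_vox
        ticks = np.arange(-r, r + 1, s)
        for sx in ticks:
            for sy in ticks:
                for sz in ticks:
                    if sx == sy == sz == 0:
                        continue
                    p = np.array([sx, sy, sz, 0.0, 0.0, 0.0])
                    d = objective(p)
                    if d < best_d:
                        best_d, best_x = d, p.copy()

    converged = True
    if best_d > 0:
        init_simplex = np.tile(best_x, (7, 1))
        steps = [1.0, 1.0, 1.0, 1.0, 1.0, 1.0]  # 1 voxel / 1 degree
        for i in range(6):
            init_simplex[i + 1, i] += steps[i]
        res = minimize(
            objective,
            best_x,
            method="Nelder-Mead",
            options={
                "maxiter": max_iter,
                "fatol": ftol * max(d0, 1.0),
                "xatol": xatol,
                "initial_simplex": init_simplex,
                "adaptive": False,
            },
        )
        if res.fun <= best_d:
            best_d, best_x = float(res.fun), np.asarray(res.x)
        if not res.success:
            converged = False
            warnings.warn(
                "Rigid registration did not converge within the iteration "
                "budget; returning best transform found",
                stacklevel=2,
            )

    transform = RigidTransform(
        tuple(np.asarray(best_x[:3]) * vs), tuple(best_x[3:6]), center
    )
    return RegistrationResult(
        transform=transform,
        initial_distance=d0,
        final_distance=best_d,
        n_evaluations=len(trace),
        converged=converged,
        trace=np.asarray(trace),
    )
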
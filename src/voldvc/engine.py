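"""Subset-based displacement search: DC, FFT and FFT+DC correlation engines.

The measurement volume is tiled with cubic N-voxel subsets (50 % overlap by
default); each active subset — one whose window holds at least the minimal
fraction of valid (in-mask) voxels, MFVP — yields one displacement vector.

Three search strategies are provided:

* **DC** (direct correlation): the normalised correlation coefficient
  C_norm is evaluated at every integer shift inside a search cube and the
  peak is refined to sub-voxel precision. C_norm is the cosine of the angle
  between the mean-subtracted reference and shifted windows, so it is
  invariant to affine intensity changes between scans.
* **FFT**: the windows are mean-subtracted and circularly cross-correlated
  through the Fourier transform, giving the full correlation map for every
  possible shift within the window at once; the circular peak is unwrapped
  to [-N/2, N/2) per axis. Cheap for large shifts.
* **FFT+DC**: the FFT peak serves as an integer predictor; the deformed
  window is re-extracted there and a small DC search (+-refine_range)
  around it provides the refined sub-voxel vector.

Sub-voxel refinement is a three-point Gaussian fit per axis on the 3x3x3
correlation neighbourhood of the integer peak — the standard PIV/DVC
estimator. When the integer-peak C_norm is numerically 1 the windows are
exactly aligned (Cauchy-Schwarz equality) and the fractional part is 0 by
definition; this makes the zero-strain fixed point exact.

A coarse-to-fine multi-pass scheme (predictor-corrector, adapted from
particle image velocimetry) is available: each pass's field, interpolated
onto the next grid, pre-shifts the deformed windows of the following pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .volume_io import Mask, Volume, check_compatible

__all__ = [
    "SubsetStatus",
    "SubsetGrid",
    "CorrelationMap",
    "DisplacementField",
    "MultipassSchedule",
    "DvcSettings",
    "build_subset_grid",
    "cnorm",
    "subvoxel_peak",
    "dc_correlation_map",
    "dc_displacement",
    "fft_displacement",
    "fftdc_displacement",
    "run_multipass",
    "compute_displacement",
]

logger = logging.getLogger(__name__)

_PERFECT_MATCH = 1.0 - 1e-9


class SubsetStatus(IntEnum):
    OK = 0
    LOW_CORRELATION = 1
    OUT_OF_RANGE = 2
    INACTIVE = 3


class ConstantWindowError(ValueError):
    """Correlation is undefined on an intensity-constant window."""


@dataclass
class SubsetGrid:
    """Lattice of cubic interrogation windows over a masked volume.

    Window ``(ix, iy, iz)`` covers the half-open index cube
    ``[starts[a][i], starts[a][i] + subset_size)`` per axis; a window is
    *active* iff its in-mask voxel fraction reaches ``mfvp`` (inclusive).
    """

    subset_size: int
    overlap: float
    mfvp: float
    stride: int
    starts: tuple[np.ndarray, np.ndarray, np.ndarray]
    valid_fraction: np.ndarray  # (gx, gy, gz)
    active: np.ndarray  # (gx, gy, gz) bool
    mask: np.ndarray  # (nx, ny, nz) bool
    volume_shape: tuple[int, int, int]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(len(s) for s in self.starts)

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    def centers(self) -> np.ndarray:
        """Window centres in voxel coordinates, shape (gx, gy, gz, 3)."""
        half = (self.subset_size - 1) / 2.0
        gx, gy, gz = self.grid_shape
        out = np.empty((gx, gy, gz, 3))
        out[..., 0] = (self.starts[0] + half)[:, None, None]
        out[..., 1] = (self.starts[1] + half)[None, :, None]
        out[..., 2] = (self.starts[2] + half)[None, None, :]
        return out

    def window_start(self, idx) -> np.ndarray:
        return np.array(
            [self.starts[0][idx[0]], self.starts[1][idx[1]], self.starts[2][idx[2]]],
            dtype=np.int64,
        )

    def window_valid(self, idx) -> np.ndarray | None:
        """Boolean in-mask pattern of a window, or None if fully valid."""
        if self.valid_fraction[tuple(idx)] >= 1.0 - 1e-12:
            return None
        s = self.window_start(idx)
        N = self.subset_size
        return self.mask[s[0] : s[0] + N, s[1] : s[1] + N, s[2] : s[2] + N]


@dataclass
class CorrelationMap:
    """C_norm over an integer search lattice around a predictor shift."""

    offsets: np.ndarray  # 1-D relative shifts, -r .. r
    values: np.ndarray  # (2r+1, 2r+1, 2r+1); NaN where the shift was invalid
    predictor: np.ndarray  # (3,) integer shift the lattice is centred on
    peak_rel: np.ndarray | None  # (3,) relative integer peak, None if all invalid
    peak_value: float

    @property
    def peak_total(self) -> np.ndarray | None:
        if self.peak_rel is None:
            return None
        return self.predictor + self.peak_rel

    def peak_on_boundary(self) -> bool:
        if self.peak_rel is None:
            return True
        r = (len(self.offsets) - 1) // 2
        return bool(np.max(np.abs(self.peak_rel)) == r)

    def neighborhood(self) -> np.ndarray | None:
        """3x3x3 values around the peak; None if the peak touches the border."""
        if self.peak_rel is None or self.peak_on_boundary():
            return None
        r = (len(self.offsets) - 1) // 2
        i, j, k = (np.asarray(self.peak_rel) + r).astype(int)
        return self.values[i - 1 : i + 2, j - 1 : j + 2, k - 1 : k + 2]


@dataclass
class DisplacementField:
    """Per-subset displacement vectors on a SubsetGrid.

    ``u_vox = u_int + u_frac`` (voxels); micrometre values are exactly
    ``u_vox * voxel_size_mm * 1000``.
    """

    grid: SubsetGrid
    u_int: np.ndarray  # (gx, gy, gz, 3) int64
    u_frac: np.ndarray  # (gx, gy, gz, 3) float64
    cnorm: np.ndarray  # (gx, gy, gz)
    status: np.ndarray  # (gx, gy, gz) int8
    voxel_size: float

    @property
    def u_vox(self) -> np.ndarray:
        return self.u_int + self.u_frac

    @property
    def u_um(self) -> np.ndarray:
        return self.u_vox * self.voxel_size * 1000.0

    @property
    def ok(self) -> np.ndarray:
        return self.status == SubsetStatus.OK

    def to_dataframe(self) -> pd.DataFrame:
        gx, gy, gz = self.grid.grid_shape
        ii, jj, kk = np.meshgrid(range(gx), range(gy), range(gz), indexing="ij")
        centers = self.grid.centers().reshape(-1, 3)
        u = self.u_vox.reshape(-1, 3)
        um = self.u_um.reshape(-1, 3)
        return pd.DataFrame(
            {
                "ix": ii.ravel(),
                "iy": jj.ravel(),
                "iz": kk.ravel(),
                "center_x": centers[:, 0],
                "center_y": centers[:, 1],
                "center_z": centers[:, 2],
                "Vx": u[:, 0],
                "Vy": u[:, 1],
                "Vz": u[:, 2],
                "Vx_um": um[:, 0],
                "Vy_um": um[:, 1],
                "Vz_um": um[:, 2],
                "cnorm": self.cnorm.ravel(),
                "status": [SubsetStatus(s).name.lower() for s in self.status.ravel()],
            }
        )


@dataclass(frozen=True)
class MultipassSchedule:
    """Coarse-to-fine subset sizes with repeated correlations per size."""

    sizes: tuple[int, ...] = (64, 56, 48, 40)
    iterations_per_size: int = 3

    def __post_init__(self):
        sizes = tuple(int(s) for s in self.sizes)
        if any(b >= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError(f"Multipass sizes must be strictly decreasing: {sizes}")
        if min(sizes) < 8:
            raise ValueError("Subset sizes below 8 voxels are not supported")
        if self.iterations_per_size < 1:
            raise ValueError("iterations_per_size must be >= 1")
        object.__setattr__(self, "sizes", sizes)


@dataclass
class DvcSettings:
    """One DVC run configuration (defaults mirror the standard protocol)."""

    approach: str = "fft_dc"  # dc | fft | fft_dc
    subset_size: int = 40
    overlap: float = 0.5
    mfvp: float = 0.5
    search_range: int | None = None  # DC; default subset_size // 4
    refine_range: int = 2  # FFT+DC refinement half-width
    cnorm_threshold: float = 0.5
    multipass: MultipassSchedule | None = None
    register: bool = True
    strain_spacing: str = "stride"  # "stride" (actual span) | "subset" (2 x subset length)

    def to_dict(self) -> dict:
        d = {
            "approach": self.approach,
            "subset_size": self.subset_size,
            "overlap": self.overlap,
            "mfvp": self.mfvp,
            "search_range": self.search_range,
            "refine_range": self.refine_range,
            "cnorm_threshold": self.cnorm_threshold,
            "register": self.register,
            "strain_spacing": self.strain_spacing,
            "multipass": None,
        }
        if self.multipass is not None:
            d["multipass"] = {
                "sizes": list(self.multipass.sizes),
                "iterations_per_size": self.multipass.iterations_per_size,
            }
        return d


# ---------------------------------------------------------------------------
# grid construction
# ---------------------------------------------------------------------------


def _box_sums(x: np.ndarray, n: int) -> np.ndarray:
    """Sums over every n^3 window of x (integral-image cumsum trick)."""
    c = x.astype(np.float64).cumsum(0).cumsum(1).cumsum(2)
    c = np.pad(c, ((1, 0), (1, 0), (1, 0)))
    return (
        c[n:, n:, n:]
        - c[:-n, n:, n:]
        - c[n:, :-n, n:]
        - c[n:, n:, :-n]
        + c[:-n, :-n, n:]
        + c[:-n, n:, :-n]
        + c[n:, :-n, :-n]
        - c[:-n, :-n, :-n]
    )


def build_subset_grid(
    mask: Mask, subset_size: int, overlap: float = 0.5, mfvp: float = 0.5
) -> SubsetGrid:
    """Tile the mask bounding box with subset windows and flag active ones.

    The stride is ``round(N * (1 - overlap))``; windows are clamped to lie
    fully inside the volume. The MFVP comparison is inclusive (a window with
    exactly the threshold fraction of in-mask voxels is active).
    """
    N = int(subset_size)
    shape = mask.shape
    if N > min(shape):
        raise ValueError(f"subset_size {N} exceeds smallest volume dimension {min(shape)}")
    if not 0.0 <= overlap <= 0.75:
        raise ValueError(f"overlap must lie in [0, 0.75], got {overlap}")
    if not 0.0 <= mfvp <= 1.0:
        raise ValueError(f"mfvp must lie in [0, 1], got {mfvp}")
    stride = max(1, round(N * (1.0 - overlap)))
    nz = np.argwhere(mask.data)
    bb_min, bb_max = nz.min(axis=0), nz.max(axis=0)
    starts = []
    for ax in range(3):
        first = min(int(bb_min[ax]), shape[ax] - N)
        last = min(int(bb_max[ax]) + 1 - N, shape[ax] - N)
        if last < first:
            starts.append(np.array([first], dtype=np.int64))
        else:
            starts.append(np.arange(first, last + 1, stride, dtype=np.int64))
    counts = _box_sums(mask.data, N)
    frac = counts[np.ix_(*starts)] / float(N**3)
    active = frac >= mfvp - 1e-12
    if not active.any():
        raise ValueError("mask too small for subset size: no active subsets")
    return SubsetGrid(
        subset_size=N,
        overlap=float(overlap),
        mfvp=float(mfvp),
        stride=stride,
        starts=tuple(starts),
        valid_fraction=frac,
        active=active,
        mask=mask.data,
        volume_shape=shape,
    )


# ---------------------------------------------------------------------------
# correlation primitives
# ---------------------------------------------------------------------------


def cnorm(
    a_window: np.ndarray, b_window: np.ndarray, valid: np.ndarray | None = None
) -> float:
    """Normalised correlation coefficient of two equal-shape windows.

    ``sum(A* B*) / sqrt(sum(A*^2) sum(B*^2))`` with A*, B* mean-subtracted
    over the valid voxels. Masked voxels are excluded from every sum and the
    voxel count replaces N^3 in the means. Invariant (up to roundoff) under
    b -> alpha b + beta with alpha > 0.
    """
    a = np.asarray(a_window, dtype=np.float64)
    b = np.asarray(b_window, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"Window shapes differ: {a.shape} vs {b.shape}")
    if valid is not None:
        v = np.asarray(valid, dtype=bool)
        a = a[v]
        b = b[v]
    else:
        a = a.ravel()
        b = b.ravel()
    if a.size < 2:
        raise ValueError("cnorm needs at least 2 valid voxels")
    astar = a - a.mean()
    bstar = b - b.mean()
    da = float(astar @ astar)
    db = float(bstar @ bstar)
    if da == 0.0 or db == 0.0:
        raise ConstantWindowError("correlation undefined on a constant window")
    return float(astar @ bstar) / np.sqrt(da * db)


def subvoxel_peak(map3: np.ndarray) -> np.ndarray:
    """Fractional peak offset from a 3x3x3 correlation neighbourhood.

    Per axis a three-point Gaussian fit through (c-, c0, c+):
    ``delta = (ln c- - ln c+) / (2 ln c- - 4 ln c0 + 2 ln c+)``, applied to
    positive-shifted values; a parabolic fit is the fallback when the values
    cannot be made positive, and any non-finite intermediate or |delta| >= 1
    falls back to 0. Flat neighbourhoods return (0, 0, 0).
    """
    m = np.asarray(map3, dtype=np.float64)
    if m.shape != (3, 3, 3):
        raise ValueError(f"Expected a 3x3x3 neighbourhood, got {m.shape}")
    c0 = m[1, 1, 1]
    if not np.isfinite(c0):
        return np.zeros(3)
    if c0 < np.nanmax(m) - 1e-12:
        raise ValueError("Centre of the neighbourhood is not the maximum")
    out = np.zeros(3)
    for ax, (cm, cp) in enumerate(
        [(m[0, 1, 1], m[2, 1, 1]), (m[1, 0, 1], m[1, 2, 1]), (m[1, 1, 0], m[1, 1, 2])]
    ):
        # an axis whose neighbours fell outside the valid search lattice
        # contributes no sub-voxel refinement
        if np.isfinite(cm) and np.isfinite(cp):
            out[ax] = _fit_1d_peak(cm, c0, cp)
    return out


def _fit_1d_peak(cm: float, c0: float, cp: float) -> float:
    if cm == c0 == cp:
        return 0.0
    vals = np.array([cm, c0, cp], dtype=np.float64)
    lo = vals.min()
    if lo <= 0.0:
        span = vals.max() - lo
        vals = vals - lo + (1e-6 * span if span > 0 else 1.0)
    if (vals <= 0.0).any():
        return _parabolic_1d(cm, c0, cp)
    lm, l0, lp = np.log(vals)
    den = 2.0 * lm - 4.0 * l0 + 2.0 * lp
    if not np.isfinite(den) or den == 0.0:
        return _parabolic_1d(cm, c0, cp)
    delta = (lm - lp) / den
    if not np.isfinite(delta) or abs(delta) >= 1.0:
        return _parabolic_1d(cm, c0, cp)
    return float(delta)


def _parabolic_1d(cm: float, c0: float, cp: float) -> float:
    den = 2.0 * (cm - 2.0 * c0 + cp)
    if den == 0.0 or not np.isfinite(den):
        return 0.0
    delta = (cm - cp) / den
    if not np.isfinite(delta) or abs(delta) >= 1.0:
        return 0.0
    return float(delta)


def _tie_break_peak(values: np.ndarray, offsets: np.ndarray, predictor: np.ndarray):
    """Peak of a correlation lattice with deterministic tie-breaking.

    ``offsets`` holds one (3,) shift per flattened entry of ``values``. Ties
    at the maximum resolve to the smallest Euclidean norm of the *total*
    shift (offset + predictor), then lexicographically. Returns
    ``(rel_peak (3,), value)`` or ``(None, nan)`` when every entry is invalid.
    """
    flat = np.asarray(values, dtype=np.float64).reshape(-1)
    offs = np.asarray(offsets, dtype=np.int64).reshape(-1, 3)
    if not np.isfinite(flat).any():
        return None, float("nan")
    peak_val = np.nanmax(flat)
    cand = np.flatnonzero(flat == peak_val)
    if len(cand) == 1:
        return offs[cand[0]].copy(), float(peak_val)
    totals = offs[cand] + np.asarray(predictor, dtype=np.int64)
    norms = (totals**2).sum(axis=1)
    order = np.lexsort((totals[:, 2], totals[:, 1], totals[:, 0], norms))
    return offs[cand[order[0]]].copy(), float(peak_val)


def _window(data: np.ndarray, start, N: int) -> np.ndarray:
    s = np.asarray(start)
    return data[s[0] : s[0] + N, s[1] : s[1] + N, s[2] : s[2] + N]


def dc_correlation_map(
    reference: np.ndarray,
    deformed: np.ndarray,
    start,
    subset_size: int,
    search_range: int,
    predictor=(0, 0, 0),
    valid: np.ndarray | None = None,
) -> CorrelationMap:
    """C_norm at every integer shift in predictor + [-r, r]^3 for one subset.

    Shifts whose deformed window would read outside the volume are skipped
    (NaN). Raises :class:`ConstantWindowError` if the reference window is
    constant over its valid voxels.
    """
    ref = np.asarray(reference, dtype=np.float64)
    dfm = np.asarray(deformed, dtype=np.float64)
    N = int(subset_size)
    r = int(search_range)
    start = np.asarray(start, dtype=np.int64)
    pred = np.asarray(predictor, dtype=np.int64)
    offsets = np.arange(-r, r + 1, dtype=np.int64)

    a = _window(ref, start, N)
    if valid is not None:
        vidx = np.flatnonzero(np.asarray(valid, dtype=bool).ravel())
        av = a.reshape(-1)[vidx]
    else:
        vidx = None
        av = a.ravel()
    astar = av - av.mean()
    da = float(astar @ astar)
    if da == 0.0:
        raise ConstantWindowError("constant reference window")

    shape = np.asarray(dfm.shape)
    lo = start + pred - r
    hi = start + pred + N + r
    values = np.full((2 * r + 1,) * 3, np.nan)

    if vidx is None and (lo >= 0).all() and (hi <= shape).all():
        region = dfm[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        region = region - region.mean()  # reduces cancellation; C_norm unchanged
        win = sliding_window_view(region, (N, N, N))
        a3 = astar.reshape(N, N, N)
        sab = np.tensordot(win, a3, axes=3)
        s1 = _box_sums(region, N)
        s2 = _box_sums(region * region, N)
        n = float(N**3)
        sa = float(astar.sum())
        num = sab - (s1 / n) * sa
        db = s2 - s1 * s1 / n
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(db > 0.0, num / np.sqrt(da * db), np.nan)
    else:
        for ii, dx in enumerate(offsets):
            for jj, dy in enumerate(offsets):
                for kk, dz in enumerate(offsets):
                    o = start + pred + np.array([dx, dy, dz])
                    if (o < 0).any() or (o + N > shape).any():
                        continue
                    b = _window(dfm, o, N)
                    bv = b.reshape(-1)[vidx] if vidx is not None else b.ravel()
                    bstar = bv - bv.mean()
                    db = float(bstar @ bstar)
                    if db <= 0.0:
                        continue
                    values[ii, jj, kk] = float(astar @ bstar) / np.sqrt(da * db)

    off3 = np.stack(np.meshgrid(offsets, offsets, offsets, indexing="ij"), axis=-1)
    rel, peak_val = _tie_break_peak(values, off3, pred)
    return CorrelationMap(
        offsets=offsets, values=values, predictor=pred, peak_rel=rel, peak_value=peak_val
    )


# ---------------------------------------------------------------------------
# displacement drivers
# ---------------------------------------------------------------------------


def _empty_field(grid: SubsetGrid, voxel_size: float) -> DisplacementField:
    g = grid.grid_shape
    return DisplacementField(
        grid=grid,
        u_int=np.zeros(g + (3,), dtype=np.int64),
        u_frac=np.zeros(g + (3,)),
        cnorm=np.full(g, np.nan),
        status=np.full(g, SubsetStatus.INACTIVE, dtype=np.int8),
        voxel_size=float(voxel_size),
    )


def _predictor_at(predictor, idx) -> np.ndarray:
    if predictor is None:
        return np.zeros(3, dtype=np.int64)
    return np.asarray(predictor[tuple(idx)], dtype=np.int64)


def _finalize_dc_peak(field, idx, cmap: CorrelationMap, threshold: float) -> None:
    """Record a DC-style peak (integer + sub-voxel + status) into the field."""
    if cmap.peak_rel is None:
        field.status[idx] = SubsetStatus.INACTIVE
        return
    field.u_int[idx] = cmap.peak_total
    field.cnorm[idx] = cmap.peak_value
    if cmap.peak_on_boundary():
        field.status[idx] = SubsetStatus.OUT_OF_RANGE
        return
    if cmap.peak_value < _PERFECT_MATCH:
        hood = cmap.neighborhood()
        if hood is not None:
            field.u_frac[idx] = subvoxel_peak(hood)
    field.status[idx] = (
        SubsetStatus.OK if cmap.peak_value >= threshold else SubsetStatus.LOW_CORRELATION
    )


def dc_displacement(
    reference: Volume,
    deformed: Volume,
    grid: SubsetGrid,
    search_range: int | None = None,
    predictor: np.ndarray | None = None,
    cnorm_threshold: float = 0.5,
) -> DisplacementField:
    """Direct-correlation search over an integer shift cube per subset."""
    check_compatible(reference, deformed)
    r = int(search_range) if search_range is not None else max(1, grid.subset_size // 4)
    if r < 1:
        raise ValueError("search_range must be >= 1")
    field = _empty_field(grid, reference.voxel_size)
    ref = np.asarray(reference.data, dtype=np.float64)
    dfm = np.asarray(deformed.data, dtype=np.float64)
    for idx in np.ndindex(grid.grid_shape):
        if not grid.active[idx]:
            continue
        pred = _predictor_at(predictor, idx)
        try:
            cmap = dc_correlation_map(
                ref, dfm, grid.window_start(idx), grid.subset_size, r, pred,
                grid.window_valid(idx),
            )
        except ConstantWindowError:
            field.status[idx] = SubsetStatus.LOW_CORRELATION
            continue
        _finalize_dc_peak(field, idx, cmap, cnorm_threshold)
    return field


def _wrap_shift(p: np.ndarray, N: int) -> np.ndarray:
    """Unwrap a circular peak index in [0, N) to a shift in [-N/2, N/2)."""
    p = np.asarray(p, dtype=np.int64)
    return np.where(p >= (N + 1) // 2, p - N, p)


def _fft_subset(ref, dfm, start, N, pred, valid):
    """Circular FFT cross-correlation of one subset.

    Returns ``(c, d, norm2_a, norm2_b)`` — the circular correlation map, the
    unwrapped integer peak shift (3,), and the squared norms of the
    mean-subtracted windows — or None when the predictor-shifted window
    leaves the volume.
    """
    shape = np.asarray(dfm.shape)
    bstart = start + pred
    if (bstart < 0).any() or (bstart + N > shape).any():
        return None
    a = _window(ref, start, N)
    b = _window(dfm, bstart, N)
    if valid is not None:
        v = np.asarray(valid, dtype=bool)
        astar = np.where(v, a - a[v].mean(), 0.0)
        bstar = np.where(v, b - b[v].mean(), 0.0)
    else:
        astar = a - a.mean()
        bstar = b - b.mean()
    if not astar.any() or not bstar.any():
        raise ConstantWindowError("constant window in FFT correlation")
    c = np.fft.irfftn(
        np.conj(np.fft.rfftn(astar)) * np.fft.rfftn(bstar),
        s=(N, N, N), axes=(0, 1, 2),
    )
    # every circular shift is a candidate; unwrap indices to signed shifts
    grid_idx = np.indices((N, N, N)).reshape(3, -1).T
    shifts = _wrap_shift(grid_idx, N)
    d, _ = _tie_break_peak(c, shifts, pred)
    return c, d, float((astar * astar).sum()), float((bstar * bstar).sum())


def fft_displacement(
    reference: Volume,
    deformed: Volume,
    grid: SubsetGrid,
    predictor: np.ndarray | None = None,
    cnorm_threshold: float = 0.5,
) -> DisplacementField:
    """FFT cross-correlation per subset with circular-peak unwrapping."""
    check_compatible(reference, deformed)
    field = _empty_field(grid, reference.voxel_size)
    ref = np.asarray(reference.data, dtype=np.float64)
    dfm = np.asarray(deformed.data, dtype=np.float64)
    N = grid.subset_size
    for idx in np.ndindex(grid.grid_shape):
        if not grid.active[idx]:
            continue
        pred = _predictor_at(predictor, idx)
        start = grid.window_start(idx)
        valid = grid.window_valid(idx)
        try:
            out = _fft_subset(ref, dfm, start, N, pred, valid)
        except ConstantWindowError:
            field.status[idx] = SubsetStatus.LOW_CORRELATION
            continue
        if out is None:
            field.status[idx] = SubsetStatus.OUT_OF_RANGE
            field.u_int[idx] = pred
            continue
        c, d, norm2_a, norm2_b = out
        total = pred + d
        field.u_int[idx] = total
        # true C_norm at the unwrapped integer shift (falls back to the
        # normalised circular value when the shifted window leaves the volume)
        cval = _cnorm_at_shift(ref, dfm, start, N, total, valid)
        if cval is None:
            peak_idx = tuple(int(v) for v in np.mod(d, N))
            denom = max(np.sqrt(norm2_a * norm2_b), 1e-300)
            cval = float(np.clip(c[peak_idx] / denom, -1.0, 1.0))
        field.cnorm[idx] = cval
        if cval < _PERFECT_MATCH:
            hood = _wrap_neighborhood(c, np.mod(d, N), N)
            field.u_frac[idx] = subvoxel_peak(hood)
        field.status[idx] = (
            SubsetStatus.OK if cval >= cnorm_threshold else SubsetStatus.LOW_CORRELATION
        )
    return field


def _cnorm_at_shift(ref, dfm, start, N, total_shift, valid):
    o = np.asarray(start) + np.asarray(total_shift)
    shape = np.asarray(dfm.shape)
    if (o < 0).any() or (o + N > shape).any():
        return None
    try:
        return cnorm(_window(ref, start, N), _window(dfm, o, N), valid)
    except (ConstantWindowError, ValueError):
        return None


def _wrap_neighborhood(c: np.ndarray, peak_idx, N: int) -> np.ndarray:
    sel = [np.array([(int(p) - 1) % N, int(p), (int(p) + 1) % N]) for p in peak_idx]
    return c[np.ix_(sel[0], sel[1], sel[2])]


def fftdc_displacement(
    reference: Volume,
    deformed: Volume,
    grid: SubsetGrid,
    refine_range: int = 2,
    predictor: np.ndarray | None = None,
    cnorm_threshold: float = 0.5,
) -> DisplacementField:
    """FFT prediction of large displacements refined by a local DC search."""
    check_compatible(reference, deformed)
    if refine_range < 1:
        raise ValueError("refine_range must be >= 1")
    field = _empty_field(grid, reference.voxel_size)
    ref = np.asarray(reference.data, dtype=np.float64)
    dfm = np.asarray(deformed.data, dtype=np.float64)
    N = grid.subset_size
    for idx in np.ndindex(grid.grid_shape):
        if not grid.active[idx]:
            continue
        pred = _predictor_at(predictor, idx)
        start = grid.window_start(idx)
        valid = grid.window_valid(idx)
        try:
            out = _fft_subset(ref, dfm, start, N, pred, valid)
        except ConstantWindowError:
            field.status[idx] = SubsetStatus.LOW_CORRELATION
            continue
        if out is None:
            field.status[idx] = SubsetStatus.OUT_OF_RANGE
            field.u_int[idx] = pred
            continue
        d = out[1]
        p2 = pred + d
        try:
            cmap = dc_correlation_map(ref, dfm, start, N, refine_range, p2, valid)
        except ConstantWindowError:
            field.status[idx] = SubsetStatus.LOW_CORRELATION
            continue
        _finalize_dc_peak(field, idx, cmap, cnorm_threshold)
    return field


# ---------------------------------------------------------------------------
# multi-pass
# ---------------------------------------------------------------------------


def _interp_predictor(prev: DisplacementField, grid: SubsetGrid) -> np.ndarray:
    """Trilinear interpolation of the previous field onto a new grid (voxels).

    Outside the previous grid's hull, nearest-neighbour extrapolation is
    used (and logged). Vectors from non-ok subsets are treated as zero.
    """
    from scipy.interpolate import RegularGridInterpolator

    u = prev.u_vox.copy()
    u[~prev.ok] = 0.0
    pgrid = prev.grid
    half = (pgrid.subset_size - 1) / 2.0
    axes = [s.astype(np.float64) + half for s in pgrid.starts]
    new_centers = grid.centers().reshape(-1, 3)
    if min(len(ax) for ax in axes) < 2:
        from scipy.spatial import cKDTree

        pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        _, nn = cKDTree(pts).query(new_centers)
        vals = u.reshape(-1, 3)[nn]
    else:
        lin = RegularGridInterpolator(
            axes, u, method="linear", bounds_error=False, fill_value=np.nan
        )
        vals = lin(new_centers)
        bad = ~np.isfinite(vals).all(axis=1)
        if bad.any():
            logger.debug(
                "multipass predictor: %d/%d centres outside previous hull, "
                "using nearest-neighbour extrapolation",
                int(bad.sum()),
                len(new_centers),
            )
            near = RegularGridInterpolator(
                axes, u, method="nearest", bounds_error=False, fill_value=None
            )
            vals[bad] = near(new_centers[bad])
    return np.rint(vals).astype(np.int64).reshape(grid.grid_shape + (3,))


def run_multipass(
    reference: Volume,
    deformed: Volume,
    mask: Mask,
    schedule: MultipassSchedule | None = None,
    approach: str = "fft_dc",
    overlap: float = 0.5,
    mfvp: float = 0.5,
    search_range: int | None = None,
    refine_range: int = 2,
    cnorm_threshold: float = 0.5,
) -> tuple[DisplacementField, dict]:
    """Coarse-to-fine predictor-corrector correlation.

    At each subset size the previous field (interpolated onto the new grid
    and rounded to integer voxels) pre-shifts the deformed windows;
    ``iterations_per_size`` correlations run at each size with updated
    predictors. Returns the field on the final (smallest) grid plus an info
    dict listing every executed pass.
    """
    schedule = schedule or MultipassSchedule()
    check_compatible(reference, deformed, mask)
    prev: DisplacementField | None = None
    passes: list[dict] = []
    for size in schedule.sizes:
        grid = build_subset_grid(mask, size, overlap, mfvp)
        for it in range(schedule.iterations_per_size):
            pred = None if prev is None else _interp_predictor(prev, grid)
            field = _dispatch(
                approach, reference, deformed, grid,
                search_range=search_range,
                refine_range=refine_range,
                predictor=pred,
                cnorm_threshold=cnorm_threshold,
            )
            passes.append(
                {"subset_size": size, "iteration": it + 1, "n_active": grid.n_active}
            )
            logger.info("multipass: size %d iteration %d done", size, it + 1)
            prev = field
    return prev, {"passes": passes, "n_passes": len(passes)}


def _dispatch(approach, reference, deformed, grid, search_range, refine_range,
              predictor, cnorm_threshold):
    if approach == "dc":
        return dc_displacement(
            reference, deformed, grid, search_range, predictor, cnorm_threshold
        )
    if approach == "fft":
        return fft_displacement(reference, deformed, grid, predictor, cnorm_threshold)
    if approach in ("fft_dc", "fft+dc"):
        return fftdc_displacement(
            reference, deformed, grid, refine_range, predictor, cnorm_threshold
        )
    raise ValueError(f"Unknown approach {approach!r}; use dc, fft or fft_dc")


def compute_displacement(
    reference: Volume,
    deformed: Volume,
    mask: Mask,
    settings: DvcSettings,
) -> tuple[DisplacementField, SubsetGrid]:
    """Run the configured approach (single-pass or multipass) over a mask."""
    if settings.multipass is not None:
        field, _ = run_multipass(
            reference, deformed, mask,
            schedule=settings.multipass,
            approach=settings.approach,
            overlap=settings.overlap,
            mfvp=settings.mfvp,
            search_range=settings.search_range,
            refine_range=settings.refine_range,
            cnorm_threshold=settings.cnorm_threshold,
        )
        return field, field.grid
    grid = build_subset_grid(mask, settings.subset_size, settings.overlap, settings.mfvp)
    field = _dispatch(
        settings.approach, reference, deformed, grid,
        search_range=settings.search_range,
        refine_range=settings.refine_range,
        predictor=None,
        cnorm_threshold=settings.cnorm_threshold,
    )
    return field, grid
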
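"""Zero-strain-test uncertainty metrics.

Two repeated scans of an unloaded object should show zero displacement and
zero strain; whatever a DVC pipeline measures instead *is* its error. This
module quantifies that error:

* random displacement error — per-axis standard deviation of the measured
  displacement components (um);
* MAER, the mean absolute error in strain: the average over measurement
  points of the six-component mean absolute strain (accuracy, ue);
* SDER, the standard deviation of the same per-point quantity about MAER
  (precision, ue) — population SD (1/N), as the definition prints it;
* per-component accuracy/precision — mean and sample SD of |eps_c| for each
  of the six components separately;
* power-law fits of an error metric against subset size (log-log least
  squares, matching trendline-style fits).

Only status-ok vectors and valid strain points enter any statistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .engine import DisplacementField, DvcSettings, compute_displacement
from .registration import apply_transform, register_rigid
from .strain import COMPONENT_NAMES, StrainField, compute_strain
from .volume_io import Mask, Volume, check_compatible

__all__ = [
    "ErrorReport",
    "PowerLawFit",
    "report_from_results",
    "random_displacement_error",
    "maer",
    "sder",
    "component_accuracy_precision",
    "fit_power_law",
    "zero_strain_report",
]


@dataclass
class ErrorReport:
    """Zero-strain uncertainty summary for one (approach, subset size) run."""

    random_displacement_error_um: tuple[float, float, float]
    maer_ue: float
    sder_ue: float
    component_accuracy_ue: tuple[float, ...]  # per xx, yy, zz, xy, xz, yz
    component_precision_ue: tuple[float, ...]
    mean_cnorm: float
    n_subsets: int  # valid strain points entering MAER/SDER
    n_vectors: int  # status-ok displacement vectors
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "random_displacement_error_um": {
                "x": self.random_displacement_error_um[0],
                "y": self.random_displacement_error_um[1],
                "z": self.random_displacement_error_um[2],
            },
            "maer_ue": self.maer_ue,
            "sder_ue": self.sder_ue,
            "component_accuracy_ue": dict(
                zip(COMPONENT_NAMES, self.component_accuracy_ue)
            ),
            "component_precision_ue": dict(
                zip(COMPONENT_NAMES, self.component_precision_ue)
            ),
            "mean_cnorm": self.mean_cnorm,
            "n_subsets": self.n_subsets,
            "n_vectors": self.n_vectors,
            "settings": self.settings,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


@dataclass
class PowerLawFit:
    """value = coefficient * SS ** exponent, SS = subset size in voxels."""

    coefficient: float
    exponent: float
    r_squared: float
    metric: str = ""

    def predict(self, subset_size) -> np.ndarray:
        return self.coefficient * np.asarray(subset_size, dtype=np.float64) ** (
            self.exponent
        )


def random_displacement_error(field: DisplacementField) -> np.ndarray:
    """Per-axis sample SD (ddof=1) of ok-subset displacement components, um."""
    ok = field.ok
    if int(ok.sum()) < 2:
        raise ValueError("Need at least 2 ok subsets for a displacement SD")
    return np.std(field.u_um[ok], axis=0, ddof=1)


def _per_point_mean_abs(strain: StrainField) -> np.ndarray:
    if strain.n_valid < 1:
        raise ValueError("No valid strain points")
    return np.abs(strain.valid_components()).mean(axis=1)


def maer(strain: StrainField) -> float:
    """Mean over valid points of the six-component mean absolute strain (ue)."""
    return float(_per_point_mean_abs(strain).mean())


def sder(strain: StrainField, population: bool = True) -> float:
    """SD of the per-point mean absolute strain about MAER (ue).

    Population SD (1/N) by default, per the printed definition; set
    ``population=False`` for the sample (1/(N-1)) convention.
    """
    vals = _per_point_mean_abs(strain)
    if vals.size == 1:
        return 0.0
    return float(np.std(vals, ddof=0 if population else 1))


def component_accuracy_precision(
    strain: StrainField, ddof: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Per-component (mean |eps_c|, SD |eps_c|) over valid points, ue."""
    if strain.n_valid < 2:
        raise ValueError("Need at least 2 valid strain points")
    a = np.abs(strain.valid_components())
    return a.mean(axis=0), a.std(axis=0, ddof=ddof)


def fit_power_law(subset_sizes, values, metric: str = "") -> PowerLawFit:
    """Least-squares line on (log SS, log value); R^2 on the log scale.

    A constant response is reported as exponent 0 with R^2 = 1 (the
    zero-variance-response convention). Non-positive values are rejected.
    """
    ss = np.asarray(subset_sizes, dtype=np.float64)
    v = np.asarray(values, dtype=np.float64)
    if ss.size < 3 or ss.size != v.size:
        raise ValueError("Need >= 3 (subset size, value) pairs")
    if (v <= 0).any() or (ss <= 0).any():
        raise ValueError("Power-law fit requires strictly positive values")
    x, y = np.log(ss), np.log(v)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0.0:
        return PowerLawFit(float(np.exp(y.mean())), 0.0, 1.0, metric)
    r2 = 1.0 - float(np.sum(resid**2)) / sstot
    return PowerLawFit(float(np.exp(intercept)), float(slope), float(r2), metric)


def registration_safe_mask(
    mask: Mask, valid: np.ndarray, settings: DvcSettings
) -> Mask:
    """Restrict the ROI to trustworthy voxels after rigid resampling.

    Voxels resampled from outside the field of view are zero-filled; the
    validity mask is additionally eroded by the correlation search margin so
    that every shifted window read stays on genuine data.
    """
    from scipy.ndimage import binary_erosion

    if settings.approach == "dc":
        margin = settings.search_range or max(1, settings.subset_size // 4)
    elif settings.approach in ("fft_dc", "fft+dc"):
        margin = settings.refine_range
    else:
        margin = 0
    v = valid
    if margin > 0 and not valid.all():
        v = binary_erosion(valid, iterations=int(margin))
    data = mask.data & v
    if not data.any():
        raise ValueError(
            "No ROI voxels left after excluding out-of-field resampled voxels"
        )
    return Mask(data.astype(np.uint8))


def zero_strain_report(
    reference: Volume,
    repeat: Volume,
    mask: Mask,
    settings: DvcSettings | None = None,
) -> ErrorReport:
    """Full zero-strain pipeline: rigid correction -> DVC -> strain -> metrics.

    Deterministic given its inputs and settings. Registration can be skipped
    (``settings.register = False``) for pairs known to be pre-aligned, e.g.
    synthetic phantoms generated without an inter-scan offset.
    """
    settings = settings or DvcSettings()
    check_compatible(reference, repeat, mask)
    corrected = repeat
    if settings.register:
        reg = register_rigid(reference, repeat, mask)
        corrected, valid = apply_transform(
            repeat, reg.transform, return_valid=True
        )
        mask = registration_safe_mask(mask, valid, settings)
    field, grid = compute_displacement(reference, corrected, mask, settings)
    strain = compute_strain(field, grid, spacing=settings.strain_spacing)
    return report_from_results(field, strain, settings)


def report_from_results(
    field: DisplacementField, strain, settings: DvcSettings
) -> ErrorReport:
    """Assemble an ErrorReport from an already-computed field and strain."""
    ok = field.ok
    n_ok = int(ok.sum())
    rde = (
        tuple(random_displacement_error(field))
        if n_ok >= 2
        else (float("nan"),) * 3
    )
    mean_cnorm = float(np.mean(field.cnorm[ok])) if n_ok else float("nan")
    if strain.n_valid >= 1:
        m = maer(strain)
        s = sder(strain)
    else:
        m = s = float("nan")
    if strain.n_valid >= 2:
        acc, prec = component_accuracy_precision(strain)
    else:
        acc = prec = np.full(6, np.nan)
    return ErrorReport(
        random_displacement_error_um=tuple(float(v) for v in rde),
        maer_ue=m,
        sder_ue=s,
        component_accuracy_ue=tuple(float(v) for v in acc),
        component_precision_ue=tuple(float(v) for v in prec),
        mean_cnorm=mean_cnorm,
        n_subsets=strain.n_valid,
        n_vectors=n_ok,
        settings=settings.to_dict(),
    )
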
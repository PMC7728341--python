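"""Small-strain tensors from a displacement grid by centred finite differences.

Each interior grid point gets the symmetric tensor
``eps_ij = (dVi/dj + dVj/di) / 2`` with the derivatives taken between the +1
and -1 grid neighbours. The physical span between those neighbours is
``2 x stride x voxel_size``; by default that actual span is the denominator.
With non-overlapping subsets the stride equals the subset length, recovering
the textbook "2 x subset length" convention, which remains available as
``spacing="subset"`` for strict compatibility — but with 50 % overlap the
two differ by a factor of two and only the actual span is dimensionally
consistent.

Boundary grid points get no strain (invalid) rather than one-sided
differences: edge strains are known to be unreliable, and a vector whose
status is not ok propagates invalidity to every strain point that would
difference it.

Components are stored as (eps_xx, eps_yy, eps_zz, eps_xy, eps_xz, eps_yz)
in microstrain (ue, 1e-6 mm/mm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import DisplacementField, SubsetGrid

__all__ = ["StrainField", "compute_strain", "COMPONENT_NAMES"]

COMPONENT_NAMES = ("exx", "eyy", "ezz", "exy", "exz", "eyz")


@dataclass
class StrainField:
    """Six-component small-strain tensors (ue) on a subset grid."""

    components: np.ndarray  # (gx, gy, gz, 6) microstrain
    valid: np.ndarray  # (gx, gy, gz) bool
    grid: SubsetGrid
    voxel_size: float

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def valid_components(self) -> np.ndarray:
        """(n_valid, 6) strain rows at valid grid points."""
        return self.components[self.valid]

    def to_dataframe(self) -> pd.DataFrame:
        gx, gy, gz = self.grid.grid_shape
        ii, jj, kk = np.meshgrid(range(gx), range(gy), range(gz), indexing="ij")
        centers = self.grid.centers().reshape(-1, 3)
        comp = self.components.reshape(-1, 6)
        df = pd.DataFrame(
            {
                "ix": ii.ravel(),
                "iy": jj.ravel(),
                "iz": kk.ravel(),
                "center_x": centers[:, 0],
                "center_y": centers[:, 1],
                "center_z": centers[:, 2],
            }
        )
        for c, name in enumerate(COMPONENT_NAMES):
            df[name + "_ue"] = comp[:, c]
        df["valid"] = self.valid.ravel()
        return df


def compute_strain(
    field: DisplacementField,
    grid: SubsetGrid | None = None,
    voxel_size: float | None = None,
    spacing: str = "stride",
) -> StrainField:
    """Centred-finite-difference strain from a displacement field.

    Parameters
    ----------
    field : DisplacementField
        Vectors on a regular subset grid.
    grid, voxel_size : optional
        Default to the field's own grid and voxel size.
    spacing : {"stride", "subset"}
        Denominator convention: the actual neighbour span (2 x stride, the
        default) or the literal 2 x subset length.
    """
    grid = grid or field.grid
    voxel_size = voxel_size if voxel_size is not None else field.voxel_size
    if spacing == "stride":
        span_vox = 2.0 * grid.stride
    elif spacing == "subset":
        span_vox = 2.0 * grid.subset_size
    else:
        raise ValueError(f"spacing must be 'stride' or 'subset', got {spacing!r}")

    gshape = grid.grid_shape
    u = field.u_vox  # voxels; dividing by a voxel span keeps this dimensionless
    ok = field.ok
    comp = np.zeros(gshape + (6,))
    valid = np.zeros(gshape, dtype=bool)

    if min(gshape) < 3:
        short = [ax for ax in range(3) if gshape[ax] < 3]
        warnings.warn(
            f"Grid too small along axes {short} for centred differences; "
            "no valid strain points along them",
            stacklevel=2,
        )
        return StrainField(comp, valid, grid, float(voxel_size))

    interior = (slice(1, -1),) * 3
    # dV[i]/d j on the interior, in strain units (voxel/voxel)
    G = np.zeros(tuple(s - 2 for s in gshape) + (3, 3))
    for j in range(3):
        plus = [slice(1, -1)] * 3
        minus = [slice(1, -1)] * 3
        plus[j] = slice(2, None)
        minus[j] = slice(None, -2)
        G[..., :, j] = (u[tuple(plus)] - u[tuple(minus)]) / span_vox
    eps = 0.5 * (G + np.swapaxes(G, -1, -2)) * 1e6
    comp[interior + (0,)] = eps[..., 0, 0]
    comp[interior + (1,)] = eps[..., 1, 1]
    comp[interior + (2,)] = eps[..., 2, 2]
    comp[interior + (3,)] = eps[..., 0, 1]
    comp[interior + (4,)] = eps[..., 0, 2]
    comp[interior + (5,)] = eps[..., 1, 2]

    # valid iff the point and all six difference neighbours carry ok vectors
    v = ok[interior].copy()
    for j in range(3):
        plus = [slice(1, -1)] * 3
        minus = [slice(1, -1)] * 3
        plus[j] = slice(2, None)
        minus[j] = slice(None, -2)
        v &= ok[tuple(plus)] & ok[tuple(minus)]
    valid[interior] = v
    comp[~valid] = 0.0
    return StrainField(comp, valid, grid, float(voxel_size))
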
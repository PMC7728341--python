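"""Independent brute-force oracles for the correlation arithmetic.

These are deliberately literal translations of the normalised correlation
definition — explicit Python loops over window voxels and shifts — kept
independent of the vectorised implementation they check.
"""

import math

import numpy as np


def cnorm_loops(a_window, b_window, valid=None):
    """C_norm by literal triple loops: mean-subtract, multiply, accumulate."""
    a = np.asarray(a_window, dtype=float)
    b = np.asarray(b_window, dtype=float)
    nx, ny, nz = a.shape
    if valid is None:
        valid = np.ones(a.shape, dtype=bool)
    n = 0
    sa = sb = 0.0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if valid[i, j, k]:
                    n += 1
                    sa += a[i, j, k]
                    sb += b[i, j, k]
    amean, bmean = sa / n, sb / n
    num = da = db = 0.0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if valid[i, j, k]:
                    astar = a[i, j, k] - amean
                    bstar = b[i, j, k] - bmean
                    num += astar * bstar
                    da += astar * astar
                    db += bstar * bstar
    return num / math.sqrt(da * db)


def dc_map_loops(reference, deformed, start, subset_size, search_range):
    """Correlation values at every shift of a cubic search lattice.

    Seven nested loops in total (three shift axes via the outer product,
    three window axes inside cnorm_loops, plus the accumulation); shifts
    whose window leaves the volume are NaN.
    """
    ref = np.asarray(reference, dtype=float)
    dfm = np.asarray(deformed, dtype=float)
    N = subset_size
    r = search_range
    x0, y0, z0 = start
    a = ref[x0 : x0 + N, y0 : y0 + N, z0 : z0 + N]
    values = np.full((2 * r + 1,) * 3, np.nan)
    for ii, dx in enumerate(range(-r, r + 1)):
        for jj, dy in enumerate(range(-r, r + 1)):
            for kk, dz in enumerate(range(-r, r + 1)):
                ox, oy, oz = x0 + dx, y0 + dy, z0 + dz
                if ox < 0 or oy < 0 or oz < 0:
                    continue
                if (
                    ox + N > dfm.shape[0]
                    or oy + N > dfm.shape[1]
                    or oz + N > dfm.shape[2]
                ):
                    continue
                b = dfm[ox : ox + N, oy : oy + N, oz : oz + N]
                values[ii, jj, kk] = cnorm_loops(a, b)
    return values
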
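"""Per-quadrat topography, the habitat table, and its PCA reduction.

Topographic variables follow forest-dynamics-plot (CTFS) conventions:
quadrat elevation is the mean of the four subplot corner elevations; slope is
the mean dip angle of the four planes through corner triples, computed from
exact 3-D triangle normals; convexity is the focal elevation minus the mean
of the eight surrounding quadrats, with an edge rule based on the quadrat's
own centre point.

The PCA z-scores every variable (sample SD), eigendecomposes the correlation
structure via SVD, and orients each component so its largest-magnitude
loading is positive, which makes repeated runs bit-identical.  Canopy
openness stays out of the PCA and enters the survival model on its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable

import numpy as np
import pandas as pd

from .config import SOIL_VARIABLES, TOPO_VARIABLES
from .errors import InvalidArgumentError


# ---------------------------------------------------------------------------
# topography
# ---------------------------------------------------------------------------

def quadrat_elevation(corner_elevs) -> float:
    """Mean of the four corner elevations (m)."""
    e = np.asarray(corner_elevs, dtype=float)
    if e.shape != (4,) or not np.isfinite(e).all():
        raise InvalidArgumentError("quadrat_elevation needs exactly 4 finite corner elevations")
    return float(e.mean())


def quadrat_slope(corner_elevs, side_m: float) -> float:
    """Mean dip angle (degrees) of the four corner-triple planes.

    Corners are ordered SW, SE, NW, NE on a square of side ``side_m``.  For
    each of the four triples of corners the plane through the three 3-D
    points is constructed and its angle from the horizontal taken from the
    exact triangle normal; the quadrat slope is the mean of the four angles.
    """
    e = np.asarray(corner_elevs, dtype=float)
    if e.shape != (4,) or not np.isfinite(e).all():
        raise InvalidArgumentError("quadrat_slope needs exactly 4 finite corner elevations")
    if side_m <= 0:
        raise InvalidArgumentError("side_m must be > 0")
    xy = np.array([[0.0, 0.0], [side_m, 0.0], [0.0, side_m], [side_m, side_m]])
    pts = np.column_stack([xy, e])
    angles = []
    for tri in combinations(range(4), 3):
        p0, p1, p2 = pts[list(tri)]
        n = np.cross(p1 - p0, p2 - p0)
        cos_dip = abs(n[2]) / np.linalg.norm(n)
        angles.append(np.degrees(np.arccos(np.clip(cos_dip, -1.0, 1.0))))
    return float(np.mean(angles))


def quadrat_convexity(
    corner_grid: np.ndarray,
    dem: Callable[[float, float], float] | None = None,
    side_m: float = 20.0,
) -> np.ndarray:
    """Convexity (m) for every quadrat of a rectangular subplot grid.

    ``corner_grid`` holds elevations at subplot corners, shape
    ``(n_rows+1, n_cols+1)`` with row 0 at the south.  Interior quadrats:
    own mean elevation minus the mean of the eight surrounding quadrats.
    Edge/corner quadrats: elevation at the quadrat centre minus the mean of
    the quadrat's own four corners.  With corner data only, the centre is the
    corner mean, so edge convexity is identically zero; passing a ``dem``
    callback ``f(x, y) -> m`` substitutes a true centre sample.
    """
    g = np.asarray(corner_grid, dtype=float)
    if g.ndim != 2 or min(g.shape) < 2:
        raise InvalidArgumentError("corner grid must be 2-D with at least 2 corners per side")
    # mean corner elevation per quadrat
    elev = (g[:-1, :-1] + g[:-1, 1:] + g[1:, :-1] + g[1:, 1:]) / 4.0
    ny, nx = elev.shape
    out = np.zeros_like(elev)
    for r in range(ny):
        for c in range(nx):
            if 0 < r < ny - 1 and 0 < c < nx - 1:
                nb = elev[r - 1 : r + 2, c - 1 : c + 2].copy()
                nb[1, 1] = np.nan
                out[r, c] = elev[r, c] - np.nanmean(nb)
            else:
                if dem is None:
                    center = elev[r, c]  # corner mean stands in for the centre sample
                else:
                    center = dem((c + 0.5) * side_m, (r + 0.5) * side_m)
                out[r, c] = center - elev[r, c]
    return out


def topography_table(
    corner_grid: np.ndarray,
    side_m: float = 20.0,
    dem: Callable[[float, float], float] | None = None,
) -> pd.DataFrame:
    """Elevation, slope and convexity per quadrat, indexed by ``rXXcYY`` id."""
    from .dataio import quadrat_id

    g = np.asarray(corner_grid, dtype=float)
    conv = quadrat_convexity(g, dem=dem, side_m=side_m)
    ny, nx = conv.shape
    rows = []
    for r in range(ny):
        for c in range(nx):
            corners = [g[r, c], g[r, c + 1], g[r + 1, c], g[r + 1, c + 1]]
            rows.append(
                {
                    "quadrat_id": quadrat_id(r, c),
                    "elevation_m": quadrat_elevation(corners),
                    "slope_deg": quadrat_slope(corners, side_m),
                    "convexity_m": conv[r, c],
                }
            )
    return pd.DataFrame(rows).set_index("quadrat_id")


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    loadings: pd.DataFrame          # variable x component
    variance_explained: np.ndarray  # fraction per returned component
    scores: pd.DataFrame            # quadrat x component
    all_eigenvalues: np.ndarray

    @property
    def components(self) -> list[str]:
        return list(self.loadings.columns)


def habitat_pca(table: pd.DataFrame, n_components: int = 3) -> PcaResult:
    """PCA of the z-scored habitat table (correlation-matrix PCA).

    Rows are quadrats, columns are topography + soil variables.  Missing
    values and constant columns are errors (no imputation).  Component signs
    follow the largest-|loading|-positive rule so output is deterministic.
    """
    if table.isna().any().any():
        col = table.columns[table.isna().any()][0]
        raise InvalidArgumentError(f"habitat table has missing values in column {col!r}")
    if n_components < 1 or n_components > table.shape[1]:
        raise InvalidArgumentError(
            f"n_components must be in 1..{table.shape[1]}, got {n_components}"
        )
    X = table.to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    constant = sd < 1e-12
    if constant.any():
        name = table.columns[np.flatnonzero(constant)[0]]
        raise InvalidArgumentError(f"habitat variable {name!r} is constant; cannot standardize")
    Z = (X - mean) / sd
    # SVD of the standardized data gives the eigenstructure of the
    # correlation matrix: eigenvalues = s^2 / (n - 1).
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    eigvals = s**2 / (X.shape[0] - 1)
    total = eigvals.sum()
    load = vt.T[:, :n_components]
    # orient: largest-|loading| entry positive
    for k in range(load.shape[1]):
        j = np.argmax(np.abs(load[:, k]))
        if load[j, k] < 0:
            load[:, k] = -load[:, k]
    comp_names = [f"pca{k + 1}" for k in range(n_components)]
    loadings = pd.DataFrame(load, index=table.columns, columns=comp_names)
    scores = pd.DataFrame(Z @ load, index=table.index, columns=comp_names)
    return PcaResult(
        loadings=loadings,
        variance_explained=eigvals[:n_components] / total,
        scores=scores,
        all_eigenvalues=eigvals,
    )


def assemble_habitat(
    topo: pd.DataFrame,
    soil: pd.DataFrame,
    canopy: pd.Series,
    quadrats: list[str] | None = None,
    n_components: int = 3,
) -> tuple[pd.DataFrame, PcaResult]:
    """Join topography + soil, run the PCA on *quadrats*, attach canopy.

    Returns ``(habitat_df, pca)`` where ``habitat_df`` has canopy openness and
    the PCA scores per quadrat.  The PCA is fit on exactly the requested
    quadrat subset (the seasonal analysis recomputes it per season because the
    set of quadrats holding live seedlings may differ).
    """
    table = topo[TOPO_VARIABLES].join(soil[SOIL_VARIABLES], how="inner")
    if quadrats is not None:
        missing = sorted(set(quadrats) - set(table.index))
        if missing:
            raise InvalidArgumentError(f"quadrats missing from habitat variables: {missing}")
        table = table.loc[sorted(set(quadrats))]
    pca = habitat_pca(table, n_components=n_components)
    out = pca.scores.copy()
    out.insert(0, "canopy", canopy.reindex(out.index))
    if out["canopy"].isna().any():
        missing = sorted(out.index[out["canopy"].isna()])
        raise InvalidArgumentError(f"quadrats missing canopy openness: {missing}")
    return out, pca
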
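"""Fixed-kernel utilization distributions with least-squares
cross-validated bandwidth and percent-volume isopleth areas.

Locations are projected into a local Lambert azimuthal equal-area plane
(km) about their centroid, so cell counts translate directly into km².
The estimator is the classic fixed (single-bandwidth) bivariate
Gaussian kernel of home-range analysis: coordinates are standardized by
their marginal SDs, one scalar bandwidth ``h`` is chosen on the
standardized points by minimizing the least-squares cross-validation
score

    CV(h) = ∫ f̂_h² − (2/n) Σ_i f̂_h,−i(x_i),

and the per-axis bandwidths ``h·σx, h·σy`` are used on the original
scale.  Isopleths are percent-volume contours: the smallest set of
grid cells containing a given fraction of the UD mass.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist

from .track_io import EARTH_RADIUS_KM


class DegenerateInputError(ValueError):
    """Too few or zero-variance points for bandwidth estimation."""


class ResolutionError(ValueError):
    """Grid cell size is too coarse for the bandwidth."""


@dataclasses.dataclass
class PlanarPoints:
    """Points in a local azimuthal equal-area plane (km), with the
    geographic centre used for the projection."""

    xy: np.ndarray                 # (n, 2) km
    center: tuple[float, float]    # (lat0, lon0) degrees

    @property
    def n(self) -> int:
        return len(self.xy)


def project_local(lats, lons) -> PlanarPoints:
    """Lambert azimuthal equal-area projection about the data centroid.

    Areas are preserved exactly on the sphere, so polygon/cell areas in
    the plane are km² on the ground to first order.
    """
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    if lats.size == 0:
        raise ValueError("need at least one point")
    lat0, lon0 = float(np.mean(lats)), float(np.mean(lons))
    xy = _laea_forward(lats, lons, lat0, lon0)
    return PlanarPoints(xy=xy, center=(lat0, lon0))


def _laea_forward(lats, lons, lat0, lon0) -> np.ndarray:
    p, p0 = np.radians(lats), math.radians(lat0)
    dl = np.radians(lons) - math.radians(lon0)
    denom = 1.0 + math.sin(p0) * np.sin(p) + math.cos(p0) * np.cos(p) * np.cos(dl)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.sqrt(np.where(denom > 0, 2.0 / denom, np.inf))
    x = EARTH_RADIUS_KM * k * np.cos(p) * np.sin(dl)
    y = EARTH_RADIUS_KM * k * (math.cos(p0) * np.sin(p)
                               - math.sin(p0) * np.cos(p) * np.cos(dl))
    return np.column_stack([x, y])


def _laea_inverse(xy: np.ndarray, lat0: float, lon0: float) -> np.ndarray:
    """Inverse projection; returns (lat, lon) columns in degrees."""
    x = np.asarray(xy)[:, 0] / EARTH_RADIUS_KM
    y = np.asarray(xy)[:, 1] / EARTH_RADIUS_KM
    rho = np.hypot(x, y)
    c = 2.0 * np.arcsin(np.clip(rho / 2.0, -1.0, 1.0))
    p0 = math.radians(lat0)
    with np.errstate(invalid="ignore", divide="ignore"):
        lat = np.where(rho == 0, p0, np.arcsin(
            np.clip(np.cos(c) * math.sin(p0)
                    + np.where(rho == 0, 0, y * np.sin(c) * math.cos(p0) / np.where(rho == 0, 1, rho)),
                    -1.0, 1.0)))
        lon = math.radians(lon0) + np.arctan2(
            x * np.sin(c),
            rho * math.cos(p0) * np.cos(c) - y * math.sin(p0) * np.sin(c))
    lon = np.where(rho == 0, math.radians(lon0), lon)
    return np.degrees(np.column_stack([lat, lon]))


# --------------------------------------------------------------------------
# LSCV bandwidth
# --------------------------------------------------------------------------

@dataclasses.dataclass
class LSCVResult:
    """Bandwidths from least-squares cross-validation.

    ``h`` is the geometric-mean bandwidth in km; ``hx``/``hy`` are the
    per-axis bandwidths after back-transforming the standardization.
    ``converged`` is False when the CV score was monotone over the
    bracket and the reference bandwidth was returned instead.
    """

    h: float
    hx: float
    hy: float
    h_std: float
    h_ref_std: float
    cv_min: float
    converged: bool

    def __float__(self) -> float:  # pragma: no cover
        return self.h


def lscv_score(z: np.ndarray, h: float,
               d2: np.ndarray | None = None) -> float:
    """Closed-form LSCV score for an isotropic bivariate Gaussian KDE
    at bandwidth ``h`` on (standardized) points ``z``.

    Uses the identities
    ``∫f̂² = (n + 2 Σ_{i<j} e^{−d²/4h²}) / (4π h² n²)`` and
    ``(2/n) Σ_i f̂_{−i}(x_i) = 2 Σ_{i<j} e^{−d²/2h²}·2 / (2π h² n (n−1))``.
    """
    n = len(z)
    if d2 is None:
        d2 = pdist(z, metric="sqeuclidean")
    s4 = float(np.sum(np.exp(-d2 / (4.0 * h * h))))
    s2 = float(np.sum(np.exp(-d2 / (2.0 * h * h))))
    int_f2 = (n + 2.0 * s4) / (4.0 * math.pi * h * h * n * n)
    loo = (2.0 * s2 * 2.0) / (2.0 * math.pi * h * h * n * (n - 1))
    return int_f2 - loo


def lscv_bandwidth(pts: PlanarPoints, n_candidates: int = 50,
                   bracket: tuple[float, float] = (0.1, 2.0)) -> LSCVResult:
    """Least-squares cross-validated bandwidth for a fixed Gaussian
    kernel.

    The score is evaluated on ``n_candidates`` log-spaced candidates in
    ``bracket`` (as multiples of the bivariate-normal reference
    bandwidth ``h_ref = n^(−1/6)`` on standardized coordinates) and the
    best candidate is refined by bounded golden-section search.  If the
    score is monotone over the bracket, ``h_ref`` is returned with
    ``converged=False`` and a warning.
    """
    xy = np.asarray(pts.xy, dtype=float)
    n = len(xy)
    if n < 5:
        raise DegenerateInputError(f"need >= 5 points, got {n}")
    sx, sy = xy.std(axis=0, ddof=1)
    if sx == 0.0 or sy == 0.0:
        raise DegenerateInputError("zero marginal variance")
    z = xy / np.array([sx, sy])
    d2 = pdist(z, metric="sqeuclidean")

    h_ref = n ** (-1.0 / 6.0)
    hs = np.geomspace(bracket[0] * h_ref, bracket[1] * h_ref, n_candidates)
    scores = np.array([lscv_score(z, h, d2) for h in hs])
    k = int(np.argmin(scores))
    if k == 0 or k == len(hs) - 1:
        warnings.warn("LSCV score monotone over bracket; "
                      "falling back to the reference bandwidth")
        h_std, cv, converged = h_ref, float(lscv_score(z, h_ref, d2)), False
    else:
        res = minimize_scalar(lambda h: lscv_score(z, h, d2),
                              bounds=(hs[k - 1], hs[k + 1]), method="bounded",
                              options={"xatol": 1e-4 * h_ref})
        h_std, cv, converged = float(res.x), float(res.fun), True

    hx, hy = h_std * sx, h_std * sy
    return LSCVResult(h=float(math.sqrt(hx * hy)), hx=float(hx), hy=float(hy),
                      h_std=h_std, h_ref_std=h_ref, cv_min=cv,
                      converged=converged)


# --------------------------------------------------------------------------
# kernel UD and isopleths
# --------------------------------------------------------------------------

@dataclasses.dataclass
class UDGrid:
    """A gridded utilization distribution (density per km², cell
    centres at ``x0 + i·cell_km``)."""

    x0: float
    y0: float
    cell_km: float
    density: np.ndarray            # (ny, nx), integrates to 1
    center: tuple[float, float] | None = None

    @property
    def mass(self) -> float:
        return float(self.density.sum() * self.cell_km ** 2)


def kernel_ud(pts: PlanarPoints, h, cell_km: float | None = None,
              margin_factor: float = 3.0) -> UDGrid:
    """Equal-weight Gaussian-mixture UD on a regular grid.

    ``h`` may be a scalar (isotropic), an ``(hx, hy)`` pair or an
    :class:`LSCVResult`.  The grid covers the points plus a
    ``margin_factor``·h margin; default cell size is h/4.  The density
    is normalized to integrate to exactly 1.
    """
    if isinstance(h, LSCVResult):
        hx, hy = h.hx, h.hy
    elif np.isscalar(h):
        hx = hy = float(h)
    else:
        hx, hy = (float(v) for v in h)
    if hx <= 0 or hy <= 0:
        raise ValueError("bandwidth must be positive")
    if cell_km is None:
        cell_km = math.sqrt(hx * hy) / 4.0
    if cell_km >= math.sqrt(hx * hy):
        raise ResolutionError(f"cell_km={cell_km} too coarse for h")

    xy = np.asarray(pts.xy, dtype=float)
    x0 = xy[:, 0].min() - margin_factor * hx
    x1 = xy[:, 0].max() + margin_factor * hx
    y0 = xy[:, 1].min() - margin_factor * hy
    y1 = xy[:, 1].max() + margin_factor * hy
    xs = np.arange(x0, x1 + cell_km, cell_km)
    ys = np.arange(y0, y1 + cell_km, cell_km)

    dens = np.zeros((len(ys), len(xs)))
    # accumulate the mixture in point chunks to bound memory
    chunk = max(1, 20_000_000 // (len(xs) + len(ys)))
    for i in range(0, len(xy), chunk):
        px = xy[i:i + chunk, 0][:, None]
        py = xy[i:i + chunk, 1][:, None]
        gx = np.exp(-0.5 * ((xs[None, :] - px) / hx) ** 2)
        gy = np.exp(-0.5 * ((ys[None, :] - py) / hy) ** 2)
        dens += gy.T @ gx
    dens /= (2.0 * math.pi * hx * hy * len(xy))
    total = dens.sum() * cell_km ** 2
    if total <= 0:
        raise ValueError("empty density grid")
    dens /= total
    return UDGrid(x0=float(xs[0]), y0=float(ys[0]), cell_km=float(cell_km),
                  density=dens, center=pts.center)


@dataclasses.dataclass(frozen=True)
class IsoplethResult:
    """Area of the smallest region holding ``level`` of the UD mass."""

    level: float
    area_km2: float
    threshold: float       # density cutoff of the included cells


def isopleth_area(ud: UDGrid, level: float) -> IsoplethResult:
    """Percent-volume contour area: cells are ranked by density and the
    smallest prefix whose cumulative mass reaches ``level`` is counted."""
    if not 0.0 < level <= 1.0:
        raise ValueError(f"level {level} out of (0, 1]")
    flat = np.sort(ud.density.ravel())[::-1]
    mass = np.cumsum(flat) * ud.cell_km ** 2
    k = int(np.searchsorted(mass, level * ud.mass)) + 1
    k = min(k, int(np.count_nonzero(flat)))
    return IsoplethResult(level=float(level),
                          area_km2=float(k * ud.cell_km ** 2),
                          threshold=float(flat[k - 1]))


def isopleth_mask(ud: UDGrid, level: float) -> np.ndarray:
    """Boolean grid of the cells inside the ``level`` isopleth."""
    thr = isopleth_area(ud, level).threshold
    return ud.density >= thr


def isopleth_geojson(ud: UDGrid, levels) -> dict:
    """Isopleth cell outlines as a GeoJSON FeatureCollection (cells are
    unioned into polygons and unprojected back to lat/lon)."""
    import shapely
    from shapely.geometry import box, mapping
    if ud.center is None:
        raise ValueError("UD grid carries no geographic centre")
    feats = []
    half = ud.cell_km / 2.0
    for level in levels:
        mask = isopleth_mask(ud, level)
        ys, xs = np.nonzero(mask)
        cells = [box(ud.x0 + x * ud.cell_km - half, ud.y0 + y * ud.cell_km - half,
                     ud.x0 + x * ud.cell_km + half, ud.y0 + y * ud.cell_km + half)
                 for y, x in zip(ys, xs)]
        union = shapely.unary_union(cells)
        polys = getattr(union, "geoms", [union])
        coords = []
        for poly in polys:
            ring = np.asarray(poly.exterior.coords)
            ll = _laea_inverse(ring, *ud.center)
            coords.append([[[round(float(lon), 6), round(float(lat), 6)]
                            for lat, lon in ll]])
        feats.append({
            "type": "Feature",
            "properties": {"level": level,
                           "area_km2": isopleth_area(ud, level).area_km2},
            "geometry": {"type": "MultiPolygon", "coordinates": coords},
        })
    return {"type": "FeatureCollection", "features": feats}
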
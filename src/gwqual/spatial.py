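"""Spatial interpolation of point observations to a regular grid.

Reduced-fidelity surface mapping: a local planar projection of lon/lat,
the Matheron empirical semivariogram, weighted-least-squares fits of
spherical/exponential models, ordinary kriging (Lagrange-multiplier
system, weights summing to 1), and inverse-distance weighting as the
simple fallback interpolator.

Distances are computed on a local equirectangular plane (kilometres,
authalic Earth radius, cos-latitude scaling at the data midpoint), which
is accurate to well under a percent over a district-scale survey box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "VariogramModel",
    "GridSurface",
    "project_local",
    "make_grid",
    "empirical_variogram",
    "fit_variogram",
    "krige",
    "idw",
]

_EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class VariogramModel:
    """Bounded semivariogram: γ(0)=nugget, γ(∞)→sill; range in distance units."""

    model: str  # "spherical" | "exponential"
    nugget: float
    sill: float
    range_: float

    def __post_init__(self) -> None:
        if self.model not in ("spherical", "exponential"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.nugget < 0:
            raise ValueError("nugget must be nonnegative")
        if self.sill <= self.nugget:
            raise ValueError("sill must exceed nugget")
        if self.range_ <= 0:
            raise ValueError("range must be positive")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, float)
        c = self.sill - self.nugget
        if self.model == "spherical":
            hr = np.clip(h / self.range_, 0.0, 1.0)
            gamma = c * (1.5 * hr - 0.5 * hr**3)
            gamma = np.where(h >= self.range_, c, gamma)
        else:
            gamma = c * (1.0 - np.exp(-3.0 * h / self.range_))
        return np.where(h > 0, self.nugget + gamma, 0.0)


@dataclass
class GridSurface:
    x: np.ndarray  # 1-D cell-centre coordinates
    y: np.ndarray
    values: np.ndarray  # (len(y), len(x))
    variance: np.ndarray | None = None  # kriging variance, same shape
    crs_note: str = "local equirectangular plane, km"

    def to_table(self):
        """Long-form (x, y, value) records for CSV export."""
        import pandas as pd

        xx, yy = np.meshgrid(self.x, self.y)
        out = {"x": xx.ravel(), "y": yy.ravel(), "value": self.values.ravel()}
        if self.variance is not None:
            out["variance"] = self.variance.ravel()
        return pd.DataFrame(out)


def project_local(lon: np.ndarray, lat: np.ndarray,
                  origin: tuple[float, float] | None = None) -> np.ndarray:
    """Project lon/lat (degrees) onto a local km plane around ``origin``
    (defaults to the data midpoint). Returns an (n, 2) array."""
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    if origin is None:
        origin = (float(lon.mean()), float(lat.mean()))
    lon0, lat0 = origin
    kx = _EARTH_RADIUS_KM * np.cos(np.radians(lat0)) * np.pi / 180.0
    ky = _EARTH_RADIUS_KM * np.pi / 180.0
    return np.column_stack([(lon - lon0) * kx, (lat - lat0) * ky])


def make_grid(points: np.ndarray, cell_size: float, pad: float = 0.0
              ) -> tuple[np.ndarray, np.ndarray]:
    """Cell-centre axes covering the bounding box of ``points`` (+``pad``)."""
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    x0, y0 = points.min(axis=0) - pad
    x1, y1 = points.max(axis=0) + pad
    nx = max(2, int(np.ceil((x1 - x0) / cell_size)) + 1)
    ny = max(2, int(np.ceil((y1 - y0) / cell_size)) + 1)
    return x0 + np.arange(nx) * cell_size, y0 + np.arange(ny) * cell_size


def _pairwise_dist(a: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    b = a if b is None else b
    return np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))


def empirical_variogram(points: np.ndarray, values: np.ndarray,
                        n_lags: int = 12, max_lag: float | None = None):
    """Matheron estimator γ(h) = mean(Δz²)/2 per distance bin.

    Returns a DataFrame with lag-bin centres, semivariance, and pair counts.
    """
    import pandas as pd

    points = np.asarray(points, float)
    values = np.asarray(values, float)
    if len(points) < 2:
        raise ValueError(f"need at least 2 points, got {len(points)}")
    d = _pairwise_dist(points)
    iu = np.triu_indices(len(points), k=1)
    h = d[iu]
    if np.all(h == 0):
        raise ValueError("all points are coincident")
    sq = (values[:, None] - values[None, :])[iu] ** 2
    hmax = max_lag if max_lag is not None else h.max() / 2.0
    edges = np.linspace(0.0, hmax, n_lags + 1)
    idx = np.digitize(h, edges) - 1
    rows = []
    for k in range(n_lags):
        mask = idx == k
        if not mask.any():
            continue
        rows.append({"lag": float(h[mask].mean()),
                     "semivariance": float(sq[mask].mean() / 2.0),
                     "n_pairs": int(mask.sum())})
    return pd.DataFrame(rows)


def fit_variogram(lag_table, model: str = "spherical") -> VariogramModel:
    """Weighted least squares (weights = pair counts) fit of a bounded model."""
    lags = lag_table["lag"].to_numpy(float)
    gam = lag_table["semivariance"].to_numpy(float)
    w = np.sqrt(lag_table["n_pairs"].to_numpy(float))
    sill0 = max(gam.max(), 1e-12)
    range0 = max(lags.max() / 2.0, 1e-6)

    def resid(theta):
        nug, psill, rng = theta
        m = VariogramModel(model, nug, nug + max(psill, 1e-12), max(rng, 1e-9))
        return w * (m(lags) - gam)

    res = optimize.least_squares(
        resid, x0=[0.0, sill0, range0],
        bounds=([0.0, 1e-12, 1e-9], [sill0 * 2 + 1e-9, np.inf, np.inf]))
    nug, psill, rng = res.x
    return VariogramModel(model, float(nug), float(nug + psill), float(rng))


def _dedupe(points: np.ndarray, values: np.ndarray):
    """Average values at duplicated locations (exact-coordinate ties)."""
    uniq, inv = np.unique(points, axis=0, return_inverse=True)
    if len(uniq) == len(points):
        return points, values
    agg = np.zeros(len(uniq))
    counts = np.zeros(len(uniq))
    np.add.at(agg, inv, values)
    np.add.at(counts, inv, 1.0)
    return uniq, agg / counts


def krige(points: np.ndarray, values: np.ndarray, model: VariogramModel,
          grid: tuple[np.ndarray, np.ndarray]) -> GridSurface:
    """Ordinary kriging over a grid.

    Solves the (n+1) system with a Lagrange multiplier at every node, so
    weights sum to 1; with a zero nugget the predictor interpolates the
    data exactly. Duplicate points are averaged first; a singular system
    after deduplication raises.
    """
    points = np.asarray(points, float)
    values = np.asarray(values, float)
    if len(points) < 3:
        raise ValueError("need at least 3 points")
    points, values = _dedupe(points, values)
    n = len(points)
    gx, gy = grid
    a = np.zeros((n + 1, n + 1))
    a[:n, :n] = model(_pairwise_dist(points))
    a[n, :n] = 1.0
    a[:n, n] = 1.0
    try:
        a_inv = np.linalg.inv(a)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular kriging matrix after deduplication") from exc

    xx, yy = np.meshgrid(gx, gy)
    nodes = np.column_stack([xx.ravel(), yy.ravel()])
    g0 = model(_pairwise_dist(nodes, points))  # (m, n)
    rhs = np.hstack([g0, np.ones((len(nodes), 1))])
    sol = rhs @ a_inv.T  # (m, n+1): weights + multiplier
    weights, mu = sol[:, :n], sol[:, n]
    pred = weights @ values
    var = np.maximum((weights * g0).sum(axis=1) + mu, 0.0)
    return GridSurface(gx, gy, pred.reshape(len(gy), len(gx)),
                       var.reshape(len(gy), len(gx)))


def kriging_weights(points: np.ndarray, values: np.ndarray,
                    model: VariogramModel, node: np.ndarray) -> np.ndarray:
    """Ordinary-kriging weight vector at a single node (diagnostic)."""
    points = np.asarray(points, float)
    n = len(points)
    a = np.zeros((n + 1, n + 1))
    a[:n, :n] = model(_pairwise_dist(points))
    a[n, :n] = 1.0
    a[:n, n] = 1.0
    b = np.append(model(np.sqrt(((points - node) ** 2).sum(1))), 1.0)
    return np.linalg.solve(a, b)[:n]


def idw(points: np.ndarray, values: np.ndarray, grid: tuple[np.ndarray, np.ndarray],
        power: float = 2.0) -> GridSurface:
    """Inverse-distance weighting; exact at data locations."""
    if power <= 0:
        raise ValueError("power must be positive")
    points = np.asarray(points, float)
    values = np.asarray(values, float)
    points, values = _dedupe(points, values)
    gx, gy = grid
    xx, yy = np.meshgrid(gx, gy)
    nodes = np.column_stack([xx.ravel(), yy.ravel()])
    d = _pairwise_dist(nodes, points)
    pred = np.empty(len(nodes))
    exact = d.min(axis=1) == 0
    pred[exact] = values[d[exact].argmin(axis=1)]
    w = 1.0 / d[~exact] ** power
    pred[~exact] = (w * values).sum(axis=1) / w.sum(axis=1)
    return GridSurface(gx, gy, pred.reshape(len(gy), len(gx)), None)
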
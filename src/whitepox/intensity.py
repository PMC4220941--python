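"""Kernel-smoothed intensity surfaces of the colony point pattern.

Two surfaces describe the study site: the colony density (unweighted point
pattern of tagged colonies) and the disease-reoccurrence intensity, where each
colony is weighted by the number of survey occasions on which it showed
disease.  The estimator is an isotropic Gaussian kernel sum with Diggle-style
edge correction — each point's kernel is renormalised by the kernel mass that
falls inside the rectangular window at that point — so the surface integrates
to the total (weighted) point count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = ["IntensitySurface", "kernel_intensity", "silverman_bandwidth", "reoccurrence_weights"]


@dataclass
class IntensitySurface:
    """Gridded intensity: expected (weighted) points per unit area."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    values: np.ndarray  # (ny, nx)
    bandwidth: float
    weights_label: str = "unweighted"

    def integral(self) -> float:
        """Integral of the surface over the window (trapezoidal)."""
        return float(np.trapezoid(np.trapezoid(self.values, self.grid_x, axis=1), self.grid_y))

    def to_dataframe(self):
        import pandas as pd

        xx, yy = np.meshgrid(self.grid_x, self.grid_y)
        return pd.DataFrame(
            {"x": xx.ravel(), "y": yy.ravel(), "intensity": self.values.ravel()}
        )


def silverman_bandwidth(points: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth, averaged over the two axes."""
    n = points.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points for an automatic bandwidth")
    sd = points.std(axis=0, ddof=1)
    return float(np.mean(sd) * (4.0 / (3.0 * n)) ** 0.2)


def reoccurrence_weights(presence: np.ndarray, annualize: bool = False) -> np.ndarray:
    """Per-colony disease-reoccurrence weights for the intensity map.

    The number of survey occasions at which each colony showed disease over
    the study; with ``annualize=True``, the number of calendar years (12
    occasion blocks) in which it showed disease at least once.
    """
    presence = np.nan_to_num(np.asarray(presence, dtype=float), nan=0.0)
    if not annualize:
        return presence.sum(axis=1)
    n, T = presence.shape
    blocks = np.array_split(np.arange(T), max(1, int(np.ceil(T / 12))))
    return np.sum(
        [(presence[:, b].sum(axis=1) > 0).astype(float) for b in blocks], axis=0
    )


def kernel_intensity(
    points: np.ndarray,
    window: tuple[float, float, float, float],
    bandwidth: float | None = None,
    weights: np.ndarray | None = None,
    grid_shape: tuple[int, int] = (128, 128),
    weights_label: str | None = None,
) -> IntensitySurface:
    """Gaussian kernel intensity estimate of a planar point pattern.

    Parameters
    ----------
    points:
        (n, 2) planar coordinates (metres), inside the window.
    window:
        (xmin, xmax, ymin, ymax) rectangle.
    bandwidth:
        Gaussian kernel sd in metres; Silverman's rule when omitted.
    weights:
        Optional non-negative per-point weights (disease-reoccurrence counts
        for the disease panel); default all ones.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        raise ValueError("empty point set")
    if points.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    xmin, xmax, ymin, ymax = map(float, window)
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("degenerate window")
    if np.any(points[:, 0] < xmin) or np.any(points[:, 0] > xmax):
        raise ValueError("points fall outside the window (easting)")
    if np.any(points[:, 1] < ymin) or np.any(points[:, 1] > ymax):
        raise ValueError("points fall outside the window (northing)")
    if bandwidth is None:
        bandwidth = silverman_bandwidth(points)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    n = points.shape[0]
    if weights is None:
        w = np.ones(n)
        label = weights_label or "unweighted"
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValueError("weights must align with points")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        label = weights_label or "disease_reoccurrence"

    ny, nx = grid_shape
    gx = np.linspace(xmin, xmax, nx)
    gy = np.linspace(ymin, ymax, ny)

    # Diggle edge correction: kernel mass inside the window at each data point
    h = bandwidth
    mass_x = norm.cdf((xmax - points[:, 0]) / h) - norm.cdf((xmin - points[:, 0]) / h)
    mass_y = norm.cdf((ymax - points[:, 1]) / h) - norm.cdf((ymin - points[:, 1]) / h)
    edge = mass_x * mass_y

    # separable Gaussian kernels: (n, nx) and (n, ny)
    kx = norm.pdf((gx[None, :] - points[:, 0][:, None]) / h) / h
    ky = norm.pdf((gy[None, :] - points[:, 1][:, None]) / h) / h
    values = np.einsum("i,iy,ix->yx", w / edge, ky, kx)

    return IntensitySurface(
        grid_x=gx, grid_y=gy, values=values, bandwidth=float(h), weights_label=label
    )
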
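"""Per-group kernel-density overlays on a shared embedding grid."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde


@dataclass
class DensityMap:
    group: str
    xs: np.ndarray              # grid x centres
    ys: np.ndarray              # grid y centres
    density: np.ndarray         # ys x xs, integrates to 1
    bandwidth: float

    def integral(self) -> float:
        dx = self.xs[1] - self.xs[0]
        dy = self.ys[1] - self.ys[0]
        return float(self.density.sum() * dx * dy)


def _isotropic_kde(pts: np.ndarray, XY: np.ndarray, bw: float) -> np.ndarray:
    d2 = ((XY[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return np.exp(-d2 / (2 * bw * bw)).sum(1) / (2 * np.pi * bw * bw * len(pts))


def density_overlay(
    embedding,
    group_labels,
    bandwidth: float | str = "auto",
    grid: int = 100,
    margin: float = 0.05,
) -> dict[str, DensityMap]:
    """Gaussian KDE per group on a shared grid covering all points plus a
    margin; every map is renormalized to integrate to exactly 1 on the
    grid.  Groups with singular covariance (e.g. coincident points) fall
    back to an isotropic kernel with a floored bandwidth."""
    coords = np.asarray(getattr(embedding, "coords", embedding), float)
    labels = np.asarray(group_labels)
    if coords.shape[0] != labels.shape[0]:
        raise ValueError("labels do not match embedding")
    for g in np.unique(labels):
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 points")

    lo = coords.min(0)
    hi = coords.max(0)
    span = np.maximum(hi - lo, 1e-9)
    lo = lo - margin * span
    hi = hi + margin * span
    xs = np.linspace(lo[0], hi[0], grid)
    ys = np.linspace(lo[1], hi[1], grid)
    XX, YY = np.meshgrid(xs, ys)
    XY = np.column_stack([XX.ravel(), YY.ravel()])
    dx, dy = xs[1] - xs[0], ys[1] - ys[0]

    out = {}
    scale = float(span.mean())
    for g in np.unique(labels):
        pts = coords[labels == g]
        bw_used: float
        try:
            if isinstance(bandwidth, str):
                kde = gaussian_kde(pts.T)
            else:
                kde = gaussian_kde(pts.T, bw_method=bandwidth / max(pts.std(), 1e-12))
            dens = kde(XY.T)
            bw_used = float(kde.factor * pts.std())
        except np.linalg.LinAlgError:
            bw_used = max(
                bandwidth if isinstance(bandwidth, (int, float)) else 0.0,
                1e-3 * scale)
            warnings.warn(
                f"group {g!r}: singular covariance, isotropic bandwidth floor "
                f"{bw_used:.3g} applied", stacklevel=2)
            dens = _isotropic_kde(pts, XY, bw_used)
        dens = dens.reshape(grid, grid)
        total = dens.sum() * dx * dy
        if total <= 0:
            raise ValueError(f"degenerate density for group {g!r}")
        out[str(g)] = DensityMap(str(g), xs, ys, dens / total, bw_used)
    return out
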
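"""Weighted kernel-density mode finding shared by the sample-level estimators."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde


@dataclass
class Mode:
    location: float
    mass: float  # integral of the density over the mode's basin


def density_modes(values: np.ndarray,
                  weights: np.ndarray | None = None,
                  min_mass_ratio: float = 0.2,
                  grid_size: int = 2048) -> list[Mode]:
    """Local maxima of a Gaussian KDE (Silverman bandwidth), with basin mass.

    Each mode's mass is the integral of the density between the
    surrounding local minima. Modes with mass below ``min_mass_ratio``
    times the dominant mode's mass are dropped as noise. Returned in
    increasing order of location.

    Degenerate inputs (fewer than two distinct values) collapse to a
    single mode at the weighted mean with mass 1.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("density_modes requires at least one value")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
    if values.size < 2 or np.ptp(values) < 1e-12:
        return [Mode(float(np.average(values, weights=weights)), 1.0)]
    kde = gaussian_kde(values, bw_method="silverman", weights=weights)
    bw = float(np.sqrt(kde.covariance[0, 0]))
    xs = np.linspace(values.min() - 3 * bw, values.max() + 3 * bw, grid_size)
    dens = kde(xs)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.flatnonzero(interior) + 1
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(dens))])
    # basin boundaries: minima between consecutive peaks
    bounds = [0]
    for a, b in zip(peaks[:-1], peaks[1:]):
        bounds.append(a + int(np.argmin(dens[a:b + 1])))
    bounds.append(len(xs) - 1)
    modes = []
    for i, p in enumerate(peaks):
        lo, hi = bounds[i], bounds[i + 1]
        mass = float(np.trapezoid(dens[lo:hi + 1], xs[lo:hi + 1]))
        modes.append(Mode(float(xs[p]), mass))
    top = max(m.mass for m in modes)
    modes = [m for m in modes if m.mass >= min_mass_ratio * top]
    return sorted(modes, key=lambda m: m.location)
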
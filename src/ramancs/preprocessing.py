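"""Standard Raman spectral preprocessing chain.

Order of the default chain: iterative polynomial fluorescence-baseline
removal, median-based despiking, Savitzky-Golay smoothing, and
max-normalization — applied independently per pixel spectrum.

Baseline removal uses the clipped-refit scheme: fit a polynomial, pull
every point above the fit down onto it, refit, and iterate, so the fit
slides under the Raman peaks and converges to the smooth fluorescence
background. Despiking is threshold-gated: a channel is replaced by the
running median only when its deviation from that median exceeds
``k * MAD`` (k = 8), so genuine narrow Raman peaks pass through
untouched while single-channel cosmic-ray spikes are removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import savgol_filter

from .io import HyperspectralCube

__all__ = [
    "PreprocessConfig",
    "remove_baseline",
    "despike",
    "smooth",
    "normalize_max",
    "preprocess_cube",
]

STEP_NAMES = ("baseline", "despike", "smooth", "normalize")


@dataclass
class PreprocessConfig:
    poly_order: int = 3
    baseline_iters: int = 20
    median_window: int = 5
    despike_k: float = 8.0
    sg_window: int = 9
    sg_order: int = 3
    steps: tuple = STEP_NAMES

    def __post_init__(self) -> None:
        for window in (self.median_window, self.sg_window):
            if window < 3 or window % 2 == 0:
                raise ValueError("filter windows must be odd and >= 3")
        if self.sg_order >= self.sg_window:
            raise ValueError("sg_order must be < sg_window")
        if self.poly_order < 1:
            raise ValueError("poly_order must be >= 1")
        if not self.steps:
            raise ValueError("steps must be a nonempty ordered subset")
        for step in self.steps:
            if step not in STEP_NAMES:
                raise ValueError(f"unknown step {step!r}")


def _fit_baseline_matrix(Y: np.ndarray, poly_order: int, iters: int) -> np.ndarray:
    """Clipped-refit polynomial baseline for each row of ``Y`` (n, L)."""
    n, L = Y.shape
    x = np.linspace(-1.0, 1.0, L)
    V = np.polynomial.polynomial.polyvander(x, poly_order)  # (L, deg+1)
    # precompute the hat operation via lstsq each iteration (columns = spectra)
    work = Y.T.copy()  # (L, n)
    fit = work
    for _ in range(max(1, iters)):
        coef, *_ = np.linalg.lstsq(V, work, rcond=None)
        fit = V @ coef
        work = np.minimum(work, fit)
    return fit.T  # (n, L)


def remove_baseline(spectrum, poly_order: int = 3, baseline_iters: int = 20):
    """Subtract an iteratively re-fitted polynomial background.

    Each iteration points above the current fit are replaced by the fit
    before refitting, making the fit insensitive to peaks. Output may
    contain small negatives. A degree representable exactly by the
    polynomial (e.g. a pure cubic with ``poly_order >= 3``) is removed
    to round-off.
    """
    y = np.asarray(spectrum, dtype=float)
    if poly_order < 0:
        raise ValueError("poly_order must be >= 0")
    if y.size < poly_order + 2:
        raise ValueError("spectrum too short for the requested polynomial order")
    baseline = _fit_baseline_matrix(y[None, :], poly_order, baseline_iters)[0]
    return y - baseline


def _despike_matrix(Y: np.ndarray, median_window: int, k: float) -> np.ndarray:
    med = median_filter(Y, size=(1, median_window), mode="nearest")
    dev = Y - med
    # robust per-spectrum noise scale from first differences; the MAD of
    # the median residual itself is depressed (the center point often
    # *is* the window median) and would flag ordinary noise excursions
    diff = np.diff(Y, axis=1)
    scale = (
        np.median(np.abs(diff - np.median(diff, axis=1, keepdims=True)),
                  axis=1, keepdims=True)
        * 1.4826 / np.sqrt(2.0)
    )
    # floor keeps a perfectly flat spectrum from flagging round-off as spikes
    floor = 1e-12 * np.maximum(1.0, np.abs(Y).max(axis=1, keepdims=True))
    spikes = np.abs(dev) > np.maximum(k * scale, floor)
    return np.where(spikes, med, Y)


def despike(spectrum, median_window: int = 5, k: float = 8.0):
    """Replace channels deviating from the running median by more than
    ``k * MAD`` with the median; all other channels pass through exactly."""
    y = np.asarray(spectrum, dtype=float)
    if median_window < 3 or median_window % 2 == 0:
        raise ValueError("median_window must be odd and >= 3")
    if median_window >= y.size:
        raise ValueError("median_window must be smaller than the spectrum")
    return _despike_matrix(y[None, :], median_window, k)[0]


def smooth(spectrum, sg_window: int = 9, sg_order: int = 3):
    """Savitzky-Golay smoothing; edges handled by a polynomial fit on the
    truncated end windows. Polynomials of degree <= ``sg_order`` pass
    through unchanged (within round-off)."""
    y = np.asarray(spectrum, dtype=float)
    if sg_window < 3 or sg_window % 2 == 0:
        raise ValueError("sg_window must be odd and >= 3")
    if sg_order >= sg_window:
        raise ValueError("sg_order must be < sg_window")
    if sg_window > y.size:
        raise ValueError("sg_window must not exceed the spectrum length")
    return savgol_filter(y, sg_window, sg_order, mode="interp")


def normalize_max(spectrum):
    """Scale so the maximum equals exactly 1; rejects non-positive maxima."""
    y = np.asarray(spectrum, dtype=float)
    peak = y.max()
    if peak <= 0:
        raise ValueError("normalize_max requires a positive maximum")
    return y / peak


def preprocess_cube(
    cube: HyperspectralCube, config: PreprocessConfig | None = None
) -> HyperspectralCube:
    """Apply the configured steps, in order, independently per spectrum.

    The applied configuration is recorded in the cube metadata. Any
    per-spectrum failure is reported with the pixel coordinates.
    """
    config = config or PreprocessConfig()
    Y = cube.intensities.copy()
    for step in config.steps:
        if step == "baseline":
            Y = Y - _fit_baseline_matrix(Y, config.poly_order, config.baseline_iters)
        elif step == "despike":
            if config.median_window >= Y.shape[1]:
                raise ValueError("median_window must be smaller than the spectrum")
            Y = _despike_matrix(Y, config.median_window, config.despike_k)
        elif step == "smooth":
            if config.sg_window > Y.shape[1]:
                raise ValueError("sg_window must not exceed the spectrum length")
            Y = savgol_filter(Y, config.sg_window, config.sg_order,
                              axis=1, mode="interp")
        elif step == "normalize":
            peaks = Y.max(axis=1)
            bad = np.flatnonzero(peaks <= 0)
            if bad.size:
                r, c = divmod(int(bad[0]), cube.grid[1])
                raise ValueError(
                    f"normalize failed at pixel (row={r}, col={c}): "
                    "non-positive maximum"
                )
            Y = Y / peaks[:, None]
    return cube.with_intensities(
        Y, cube.observed,
        preprocess_steps=list(config.steps),
        preprocess_poly_order=config.poly_order,
        preprocess_sg=[config.sg_window, config.sg_order],
        preprocess_median_window=config.median_window,
    )
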
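"""Random spectral under-sampling: build and apply observation masks.

Sparsity level ``s`` is the fraction of (pixel, wavenumber) entries
discarded. The default scheme keeps an exact count of
``round((1 - s) * L)`` channels per spectrum, chosen uniformly without
replacement and independently across pixels, so the acquisition-time
saving is exactly ``1 / (1 - s)``; an entrywise Bernoulli scheme is
also available.
"""

from __future__ import annotations

import numpy as np

from .io import HyperspectralCube, ObservationMask

__all__ = ["make_random_mask", "apply_mask", "sparsify_cube"]

SCHEMES = ("per_spectrum_exact", "global_bernoulli")


def make_random_mask(
    n_pixels: int,
    n_channels: int,
    sparsity: float,
    seed: int = 0,
    scheme: str = "per_spectrum_exact",
) -> ObservationMask:
    """Seeded random observation mask over (pixel, wavenumber)."""
    if not (0.0 <= sparsity < 1.0):
        raise ValueError("sparsity must be in [0, 1)")
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    rng = np.random.default_rng(seed)
    if scheme == "per_spectrum_exact":
        n_obs = int(round((1.0 - sparsity) * n_channels))
        if n_obs == 0:
            raise ValueError(
                "requested sparsity leaves zero observed channels per spectrum"
            )
        # rank a fresh uniform draw per row: first n_obs order statistics are
        # a uniform sample of channels without replacement
        order = np.argsort(rng.random((n_pixels, n_channels)), axis=1)
        observed = np.zeros((n_pixels, n_channels), dtype=bool)
        np.put_along_axis(observed, order[:, :n_obs], True, axis=1)
    else:
        observed = rng.random((n_pixels, n_channels)) < (1.0 - sparsity)
    return ObservationMask(observed, requested_sparsity=float(sparsity),
                           seed=seed, scheme=scheme)


def apply_mask(cube: HyperspectralCube, mask: ObservationMask) -> HyperspectralCube:
    """Discard masked entries: observed values are kept bit-identical,
    missing entries are zeroed and flagged. The input cube is untouched."""
    if mask.shape != cube.intensities.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match cube {cube.intensities.shape}"
        )
    observed = mask.observed.copy()
    if cube.observed is not None:
        observed &= cube.observed
    intensities = np.where(observed, cube.intensities, 0.0)
    return cube.with_intensities(
        intensities, observed, requested_sparsity=mask.requested_sparsity
    )


def sparsify_cube(
    cube: HyperspectralCube,
    sparsity: float,
    seed: int = 0,
    scheme: str = "per_spectrum_exact",
):
    """Convenience: draw a mask for the cube and apply it."""
    mask = make_random_mask(cube.n_pixels, len(cube.axis), sparsity, seed, scheme)
    return apply_mask(cube, mask), mask
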
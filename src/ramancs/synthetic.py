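"""Seeded synthetic Raman datasets with known ground truth.

Every generator here produces data with the statistical structure the
evaluation pipeline assumes: a small number of pure-component spectra
(endmembers) mixed per pixel, optional smooth fluorescence baseline,
additive and shot-like noise, and single-channel cosmic-ray spikes.
With baseline and noise switched off, the pixels-by-wavenumbers matrix
has numerical rank equal to the number of distinct per-class spectra —
the low-rank premise that makes matrix completion work.

Three scene families mirror common use cases:

* two-component water/protein mixtures over a 60–80 % hydration range
  (concentration regression),
* a cell scene (background / cytoplasm / drug) in which the drug
  occupies ~3 % of pixels and carries a distinctive 1168 cm^-1 peak
  (rare-component detection),
* a layered three-class tissue scene with a large smooth fluorescence
  background and shot noise (clustering under low SNR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import HyperspectralCube, WavenumberAxis

__all__ = [
    "WavenumberAxis",
    "Endmember",
    "SceneSpec",
    "ConcentrationDataset",
    "default_axis",
    "make_endmember_spectrum",
    "make_mixture_series",
    "make_cell_scene",
    "make_tissue_scene",
    "add_spikes",
    "WATER",
    "PROTEIN",
    "CELL_BACKGROUND",
    "CYTOPLASM",
    "DRUG",
    "TISSUE_BACKGROUND",
    "GRAY_MATTER",
    "WHITE_MATTER",
    "DRUG_PEAK_CM1",
]

MIN_AXIS_LENGTH = 16
DRUG_PEAK_CM1 = 1168.0


def default_axis(n_channels: int = 300) -> WavenumberAxis:
    """Fingerprint-region axis, 600–1800 cm^-1."""
    return WavenumberAxis(np.linspace(600.0, 1800.0, n_channels))


@dataclass(frozen=True)
class Endmember:
    """Pure-component spectrum as a sum of peaks.

    ``peaks`` is a list of ``(center_cm1, fwhm_cm1, amplitude)``;
    ``profile`` selects the lineshape (lorentzian is the natural Raman
    lineshape, gaussian is available).
    """

    name: str
    peaks: tuple = ()
    profile: str = "lorentzian"

    def __post_init__(self) -> None:
        if len(self.peaks) == 0:
            raise ValueError(f"endmember {self.name!r} needs at least one peak")
        if self.profile not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown peak profile {self.profile!r}")
        for center, fwhm, amp in self.peaks:
            if fwhm <= 0:
                raise ValueError("peak widths must be > 0")
            if amp < 0:
                raise ValueError("peak amplitudes must be >= 0")
        object.__setattr__(self, "peaks", tuple(tuple(map(float, p)) for p in self.peaks))


def make_endmember_spectrum(endmember: Endmember, axis: WavenumberAxis) -> np.ndarray:
    """Evaluate an endmember's peaks on the axis; deterministic, nonnegative."""
    x = axis.values
    for center, _fwhm, _amp in endmember.peaks:
        if not axis.covers(center):
            raise ValueError(
                f"peak center {center} cm^-1 outside axis "
                f"[{axis.lo}, {axis.hi}] for endmember {endmember.name!r}"
            )
    spectrum = np.zeros_like(x)
    for center, fwhm, amp in endmember.peaks:
        if endmember.profile == "lorentzian":
            half = fwhm / 2.0
            spectrum += amp * half**2 / ((x - center) ** 2 + half**2)
        else:
            spectrum += amp * np.exp(-4.0 * np.log(2.0) * (x - center) ** 2 / fwhm**2)
    return spectrum


# Library endmembers. These are stand-in pure-component spectra with peak
# positions borrowed from typical biological band assignments (phenylalanine
# 1003, CH2 1440-1450, amide I ~1660, lipid 1064/1298, OH bend ~1640); no
# numeric match to any measured sample is intended.
# broad OH-bend water band: gaussian profile (light tails), so the
# inter-peak floor stays near zero and baseline fitting leaves it alone
WATER = Endmember("water", peaks=((1640.0, 100.0, 1.0), (760.0, 80.0, 0.25)),
                  profile="gaussian")
PROTEIN = Endmember(
    "protein",
    peaks=(
        (1003.0, 20.0, 1.0),
        (1245.0, 40.0, 0.45),
        (1450.0, 30.0, 0.7),
        (1660.0, 35.0, 0.8),
        (850.0, 25.0, 0.3),
    ),
)
CELL_BACKGROUND = Endmember(
    "background", peaks=((800.0, 400.0, 0.10), (1500.0, 500.0, 0.06))
)
CYTOPLASM = Endmember(
    "cytoplasm",
    peaks=(
        (1003.0, 20.0, 0.9),
        (1304.0, 30.0, 0.5),
        (1450.0, 30.0, 0.85),
        (1660.0, 35.0, 0.7),
    ),
)
# The probe signature is deliberately trace-level: a nanoparticle reservoir
# inside a cell adds a clear marker peak but nowhere near the dominant
# cytoplasm bands, so detection leans entirely on the 1168 cm^-1 channel.
DRUG = Endmember(
    "drug",
    peaks=(
        (DRUG_PEAK_CM1, 12.0, 0.35),
        (1290.0, 22.0, 0.10),
        (1600.0, 25.0, 0.12),
    ),
)
TISSUE_BACKGROUND = Endmember(
    "background", peaks=((900.0, 500.0, 0.12), (1600.0, 450.0, 0.08))
)
GRAY_MATTER = Endmember(
    "gray_matter",
    peaks=(
        (1003.0, 20.0, 0.7),
        (1440.0, 30.0, 0.8),
        (1660.0, 35.0, 0.9),
        (1240.0, 45.0, 0.4),
    ),
)
WHITE_MATTER = Endmember(
    "white_matter",
    peaks=(
        (1064.0, 20.0, 0.9),
        (1298.0, 22.0, 0.85),
        (1440.0, 30.0, 1.0),
        (1660.0, 35.0, 0.6),
        (700.0, 25.0, 0.35),
    ),
)


@dataclass
class SceneSpec:
    """Parameters of a synthetic imaging scene.

    ``baseline_amplitude`` scales a per-pixel smooth fluorescence curve
    (cubic polynomial with random nonnegative coefficients);
    ``noise_sd`` is the additive gaussian noise scale; ``shot_noise``
    adds a signal-proportional term with sd ``noise_sd * sqrt(signal)``;
    ``spike_rate`` is the per-pixel probability of a single-channel
    cosmic-ray spike.
    """

    grid: tuple[int, int] = (32, 36)
    baseline_amplitude: float = 0.0
    noise_sd: float = 0.0
    shot_noise: bool = False
    spike_rate: float = 0.0
    seed: int = 0
    n_channels: int = 300

    def __post_init__(self) -> None:
        rows, cols = self.grid
        self.grid = (int(rows), int(cols))
        if rows < 1 or cols < 1:
            raise ValueError("grid must have at least one pixel")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.spike_rate <= 1.0):
            raise ValueError("spike_rate must be in [0, 1]")
        if self.baseline_amplitude < 0:
            raise ValueError("baseline_amplitude must be >= 0")

    def to_config(self) -> str:
        """Flat key = value text serialization."""
        lines = [
            f"rows = {self.grid[0]}",
            f"cols = {self.grid[1]}",
            f"baseline_amplitude = {self.baseline_amplitude!r}",
            f"noise_sd = {self.noise_sd!r}",
            f"shot_noise = {int(self.shot_noise)}",
            f"spike_rate = {self.spike_rate!r}",
            f"seed = {self.seed}",
            f"n_channels = {self.n_channels}",
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "SceneSpec":
        kv = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
        return cls(
            grid=(int(kv["rows"]), int(kv["cols"])),
            baseline_amplitude=float(kv["baseline_amplitude"]),
            noise_sd=float(kv["noise_sd"]),
            shot_noise=bool(int(kv["shot_noise"])),
            spike_rate=float(kv["spike_rate"]),
            seed=int(kv["seed"]),
            n_channels=int(kv["n_channels"]),
        )


@dataclass
class ConcentrationDataset:
    """Replicate spectra grouped by known water fraction (% by weight)."""

    concentrations: np.ndarray  # distinct fractions, sorted ascending
    y: np.ndarray  # per-spectrum true fraction, length n
    spectra: np.ndarray  # (n, L)
    axis: WavenumberAxis
    truth_endmembers: tuple[Endmember, Endmember] = (WATER, PROTEIN)

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.shape != (self.y.size, len(self.axis)):
            raise ValueError("spectra must be (n_spectra, axis length)")
        if np.unique(self.concentrations).size < 2:
            raise ValueError("need >= 2 distinct concentrations")
        counts = [np.sum(self.y == c) for c in self.concentrations]
        if min(counts) < 2:
            raise ValueError("need >= 2 replicates per concentration")

    def group(self, concentration: float) -> np.ndarray:
        return self.spectra[self.y == concentration]

    def with_spectra(self, spectra: np.ndarray) -> "ConcentrationDataset":
        return ConcentrationDataset(
            self.concentrations, self.y, spectra, self.axis, self.truth_endmembers
        )


def _check_axis(axis: WavenumberAxis) -> WavenumberAxis:
    if len(axis) < MIN_AXIS_LENGTH:
        raise ValueError(f"synthetic axis must have >= {MIN_AXIS_LENGTH} channels")
    return axis


def _baseline_curves(rng: np.random.Generator, n: int, L: int, amplitude: float):
    """Per-pixel smooth fluorescence: cubic in scaled position, coefficients
    drawn uniform-positive so the curve stays nonnegative and is exactly
    removable by a polynomial baseline fit of degree >= 3."""
    if amplitude == 0.0:
        return np.zeros((n, L))
    x = np.linspace(0.0, 1.0, L)
    coeffs = rng.uniform(0.2, 1.0, size=(n, 4))
    powers = np.vstack([np.ones_like(x), x, x**2, x**3])  # (4, L)
    curves = coeffs @ powers
    return amplitude * curves / 2.4  # mean coefficient sum ~2.4 -> mean level ~amplitude


def _apply_noise(rng, clean: np.ndarray, noise_sd: float, shot: bool) -> np.ndarray:
    noisy = clean.copy()
    if noise_sd > 0:
        noisy = noisy + rng.normal(0.0, noise_sd, size=clean.shape)
        if shot:
            sd = noise_sd * np.sqrt(np.clip(clean, 0.0, None))
            noisy = noisy + rng.normal(0.0, 1.0, size=clean.shape) * sd
    return noisy


def make_mixture_series(
    fractions=None,
    n_replicates: int = 10,
    axis: WavenumberAxis | None = None,
    endmembers: tuple[Endmember, Endmember] = (WATER, PROTEIN),
    noise_sd: float = 0.01,
    baseline_amplitude: float = 0.05,
    seed: int = 0,
) -> ConcentrationDataset:
    """Two-component concentration series.

    Each spectrum is ``f/100 * water + (1 - f/100) * solute`` plus a
    smooth baseline and noise; replicates at one fraction differ only by
    their noise/baseline realization. The default sweep covers the
    60–80 % water-fraction range in 2 % steps.
    """
    if fractions is None:
        fractions = np.arange(60.0, 81.0, 2.0)
    fractions = np.sort(np.asarray(fractions, dtype=float))
    if np.any((fractions <= 0) | (fractions >= 100)):
        raise ValueError("fractions must lie in (0, 100) % by weight")
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates per concentration")
    axis = _check_axis(axis or default_axis())
    water, solute = endmembers
    w = make_endmember_spectrum(water, axis)
    s = make_endmember_spectrum(solute, axis)

    rng = np.random.default_rng(seed)
    n = fractions.size * n_replicates
    y = np.repeat(fractions, n_replicates)
    clean = (y[:, None] / 100.0) * w[None, :] + (1.0 - y[:, None] / 100.0) * s[None, :]
    spectra = clean + _baseline_curves(rng, n, len(axis), baseline_amplitude)
    spectra = _apply_noise(rng, spectra, noise_sd, shot=False)
    return ConcentrationDataset(fractions, y, spectra, axis, (water, solute))


def _grow_blobs(
    rng: np.random.Generator,
    allowed: np.ndarray,
    n_pixels: int,
    n_blobs: int,
) -> np.ndarray:
    """Grow ``n_pixels`` contiguous pixels (4-connected blobs) inside the
    boolean ``allowed`` region."""
    rows, cols = allowed.shape
    chosen = np.zeros_like(allowed, dtype=bool)
    allowed_idx = np.argwhere(allowed)
    seeds = allowed_idx[rng.choice(len(allowed_idx), size=min(n_blobs, n_pixels),
                                   replace=False)]
    frontier: list[tuple[int, int]] = []
    for r, c in seeds:
        if chosen.sum() >= n_pixels:
            break
        if not chosen[r, c]:
            chosen[r, c] = True
            frontier.append((r, c))
    while chosen.sum() < n_pixels:
        if not frontier:  # regrow from a fresh allowed pixel
            remaining = np.argwhere(allowed & ~chosen)
            r, c = remaining[rng.integers(len(remaining))]
            chosen[r, c] = True
            frontier.append((int(r), int(c)))
            continue
        i = rng.integers(len(frontier))
        r, c = frontier[i]
        neighbors = [
            (r + dr, c + dc)
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
            if 0 <= r + dr < rows and 0 <= c + dc < cols
            and allowed[r + dr, c + dc] and not chosen[r + dr, c + dc]
        ]
        if not neighbors:
            frontier.pop(i)
            continue
        nr, nc = neighbors[rng.integers(len(neighbors))]
        chosen[nr, nc] = True
        frontier.append((nr, nc))
    return chosen


def _scene_cube(
    spec: SceneSpec,
    class_map: np.ndarray,
    class_spectra: np.ndarray,
    rng: np.random.Generator,
    scene: str,
) -> HyperspectralCube:
    axis = _check_axis(default_axis(spec.n_channels))
    n = spec.grid[0] * spec.grid[1]
    labels = class_map.reshape(n)
    clean = class_spectra[labels]
    clean = clean + _baseline_curves(rng, n, len(axis), spec.baseline_amplitude)
    noisy = _apply_noise(rng, clean, spec.noise_sd, spec.shot_noise)
    cube = HyperspectralCube(
        axis, spec.grid, noisy, meta={"scene": scene, "seed": spec.seed}
    )
    if spec.spike_rate > 0:
        cube = add_spikes(cube, spec.spike_rate, amplitude=10.0, seed=spec.seed + 1)
    return cube


def make_cell_scene(
    spec: SceneSpec | None = None,
    rare_fraction: float = 3.0,
    drug_peak_center: float = DRUG_PEAK_CM1,
    endmembers: dict | None = None,
):
    """Cell scene: background / cytoplasm / drug, drug rare and blobby.

    The drug class occupies ``rare_fraction`` percent of all pixels
    (rounded to pixel count, floored at 1), grown as a few contiguous
    blobs strictly inside the cytoplasm ellipse. The drug spectrum is
    cytoplasm plus the drug endmember, whose distinctive peak sits at
    ``drug_peak_center`` (1168 cm^-1 by default) and appears in no other
    class. Returns ``(cube, label_map)`` with labels
    0 = background, 1 = cytoplasm, 2 = drug.
    """
    spec = spec or SceneSpec(grid=(32, 36), noise_sd=0.04,
                             baseline_amplitude=0.05, seed=0)
    if not (0.0 < rare_fraction <= 20.0):
        raise ValueError("rare_fraction must be in (0, 20] percent")
    ems = endmembers or {
        "background": CELL_BACKGROUND,
        "cytoplasm": CYTOPLASM,
        "drug": DRUG,
    }
    drug_em = ems["drug"]
    if not any(abs(c - drug_peak_center) < 1.0 for c, _, _ in drug_em.peaks):
        raise ValueError(f"drug endmember must have a peak at {drug_peak_center} cm^-1")
    for name in ("background", "cytoplasm"):
        if any(abs(c - drug_peak_center) < 1.0 for c, _, _ in ems[name].peaks):
            raise ValueError(f"{name} endmember must not share the drug peak")

    rows, cols = spec.grid
    rng = np.random.default_rng(spec.seed)
    r = (np.arange(rows)[:, None] - (rows - 1) / 2.0) / (rows / 2.0)
    c = (np.arange(cols)[None, :] - (cols - 1) / 2.0) / (cols / 2.0)
    cell = (r**2 / 0.72 + c**2 / 0.72) <= 1.0  # centered ellipse ~ cell body
    class_map = np.where(cell, 1, 0)

    n_total = rows * cols
    n_drug = max(1, round(rare_fraction / 100.0 * n_total))
    if n_drug > cell.sum():
        raise ValueError("rare_fraction exceeds the cytoplasm area")
    # keep blobs off the cell rim so they sit inside the cytoplasm
    interior = (r**2 / 0.5 + c**2 / 0.5) <= 1.0
    allowed = interior if interior.sum() >= n_drug else cell
    drug = _grow_blobs(rng, allowed, n_drug, n_blobs=max(1, n_drug // 12))
    class_map[drug] = 2

    axis = _check_axis(default_axis(spec.n_channels))
    bg = make_endmember_spectrum(ems["background"], axis)
    cyto = make_endmember_spectrum(ems["cytoplasm"], axis)
    drug_spec = 0.6 * cyto + make_endmember_spectrum(drug_em, axis)
    class_spectra = np.vstack([bg, cyto, drug_spec])
    cube = _scene_cube(spec, class_map, class_spectra, rng, scene="cell")
    return cube, class_map


def _layered_map(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    """Three layered bands with wavy boundaries (background / gray / white)."""
    c = np.arange(cols)
    phase1, phase2 = rng.uniform(0, 2 * np.pi, size=2)
    b1 = rows * (0.30 + 0.06 * np.sin(2 * np.pi * c / cols + phase1))
    b2 = rows * (0.62 + 0.06 * np.sin(2 * np.pi * c / cols * 1.7 + phase2))
    rr = np.arange(rows)[:, None]
    class_map = np.zeros((rows, cols), dtype=int)
    class_map[(rr >= b1[None, :])] = 1
    class_map[(rr >= b2[None, :])] = 2
    return class_map


def make_tissue_scene(spec: SceneSpec | None = None, endmembers: dict | None = None):
    """Layered three-class tissue scene (background / gray / white matter).

    Defaults emulate a raw tissue acquisition: a large smooth
    fluorescence baseline (amplitude ~20x the Raman peak scale, typical
    of visible-excitation tissue autofluorescence) plus shot-like noise. The full-size study geometry is 65 x 145 pixels; a
    scaled-down 16 x 36 grid is used throughout the test suite. Returns
    ``(cube, label_map)`` with labels 0 = background, 1 = gray matter,
    2 = white matter.
    """
    spec = spec or SceneSpec(
        grid=(65, 145), baseline_amplitude=20.0, noise_sd=0.05,
        shot_noise=True, seed=0
    )
    ems = endmembers or {
        "background": TISSUE_BACKGROUND,
        "gray": GRAY_MATTER,
        "white": WHITE_MATTER,
    }
    if len(ems) < 3:
        raise ValueError("tissue scene needs 3 classes")
    rows, cols = spec.grid
    rng = np.random.default_rng(spec.seed)
    class_map = _layered_map(rng, rows, cols)
    axis = _check_axis(default_axis(spec.n_channels))
    class_spectra = np.vstack(
        [make_endmember_spectrum(ems[k], axis) for k in ("background", "gray", "white")]
    )
    cube = _scene_cube(spec, class_map, class_spectra, rng, scene="tissue")
    return cube, class_map


def tissue_test_spec(seed: int = 0, **overrides) -> SceneSpec:
    """Scaled-down tissue scene defaults used by tests and sweeps."""
    base = dict(grid=(16, 36), baseline_amplitude=20.0, noise_sd=0.05,
                shot_noise=True, seed=seed)
    base.update(overrides)
    return SceneSpec(**base)


def add_spikes(
    cube: HyperspectralCube, spike_rate: float, amplitude: float, seed: int = 0
) -> HyperspectralCube:
    """Add single-channel positive cosmic-ray spikes.

    Each pixel independently receives one spike with probability
    ``spike_rate`` at a uniformly random channel; the spike adds
    ``amplitude`` to that channel only.
    """
    if amplitude <= 0:
        raise ValueError("spike amplitude must be > 0")
    if not (0.0 <= spike_rate <= 1.0):
        raise ValueError("spike_rate must be in [0, 1]")
    if spike_rate == 0.0:
        return cube
    rng = np.random.default_rng(seed)
    intensities = cube.intensities.copy()
    hit = rng.random(cube.n_pixels) < spike_rate
    channels = rng.integers(0, len(cube.axis), size=cube.n_pixels)
    intensities[hit, channels[hit]] += amplitude
    return cube.with_intensities(intensities, cube.observed,
                                 spikes=int(hit.sum()))
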
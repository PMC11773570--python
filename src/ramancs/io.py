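"""Portable containers and readers/writers for hyperspectral Raman data.

The in-memory convention everywhere in :mod:`ramancs` is rows = pixels
(or spectra), columns = wavenumbers, with pixels linearized row-major
over the spatial grid. On disk a cube or observation mask is one
self-describing HDF5 file (schema ``/axis``, ``/intensities``,
``/observed``, grid and metadata as root attributes); flat spectra
tables are delimited text with the wavenumber axis in the first column
and one spectrum per subsequent column.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

SCHEMA_VERSION = "1"
PIXEL_ORDER = "row-major"

__all__ = [
    "WavenumberAxis",
    "HyperspectralCube",
    "ObservationMask",
    "read_spectra_table",
    "write_spectra_table",
    "read_cube",
    "write_cube",
    "read_mask",
    "write_mask",
]


@dataclass(frozen=True, eq=False)
class WavenumberAxis:
    """Shared spectral axis in cm^-1, strictly increasing."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("wavenumber axis must be 1-D with at least 2 points")
        if not np.all(np.isfinite(values)):
            raise ValueError("wavenumber axis must be finite")
        if not np.all(np.diff(values) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return np.array_equal(self.values, other.values)

    def __hash__(self) -> int:  # frozen dataclass with eq=False keeps identity hash
        return id(self)

    @property
    def lo(self) -> float:
        return float(self.values[0])

    @property
    def hi(self) -> float:
        return float(self.values[-1])

    def covers(self, wavenumber: float) -> bool:
        return self.lo <= wavenumber <= self.hi

    def nearest_index(self, wavenumber: float) -> int:
        """Index of the channel closest to ``wavenumber`` (must be in range)."""
        if not self.covers(wavenumber):
            raise ValueError(
                f"wavenumber {wavenumber} outside axis range [{self.lo}, {self.hi}]"
            )
        return int(np.argmin(np.abs(self.values - wavenumber)))


@dataclass
class HyperspectralCube:
    """Spatial grid of spectra on a shared wavenumber axis.

    ``intensities`` has shape (rows*cols, L); missing entries (after
    sparsification) are zeroed and flagged ``False`` in ``observed``.
    ``observed is None`` means fully observed.
    """

    axis: WavenumberAxis
    grid: tuple[int, int]
    intensities: np.ndarray
    observed: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rows, cols = self.grid
        self.grid = (int(rows), int(cols))
        if rows < 1 or cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (rows * cols, len(self.axis)):
            raise ValueError(
                f"intensities shape {self.intensities.shape} does not match "
                f"grid {self.grid} x axis length {len(self.axis)}"
            )
        if self.observed is not None:
            self.observed = np.asarray(self.observed, dtype=bool)
            if self.observed.shape != self.intensities.shape:
                raise ValueError("observed flags must match intensities shape")
            check = self.intensities[self.observed]
        else:
            check = self.intensities
        if not np.all(np.isfinite(check)):
            raise ValueError("observed intensities must be finite")

    @property
    def n_pixels(self) -> int:
        return self.grid[0] * self.grid[1]

    def image(self, channel: int) -> np.ndarray:
        """Spatial (rows, cols) image of one wavenumber channel."""
        return self.intensities[:, channel].reshape(self.grid)

    def with_intensities(
        self, intensities: np.ndarray, observed: np.ndarray | None = None, **meta
    ) -> "HyperspectralCube":
        merged = dict(self.meta)
        merged.update(meta)
        return HyperspectralCube(self.axis, self.grid, intensities, observed, merged)

    def copy(self) -> "HyperspectralCube":
        return HyperspectralCube(
            self.axis,
            self.grid,
            self.intensities.copy(),
            None if self.observed is None else self.observed.copy(),
            dict(self.meta),
        )


@dataclass
class ObservationMask:
    """Boolean observed/missing pattern over (pixel, wavenumber)."""

    observed: np.ndarray
    requested_sparsity: float = 0.0
    seed: int = 0
    scheme: str = "per_spectrum_exact"

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.observed.ndim != 2:
            raise ValueError("observation mask must be 2-D (pixels x wavenumbers)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.observed.shape

    @property
    def sparsity(self) -> float:
        """Realized fraction of missing entries, exactly."""
        return 1.0 - self.observed.sum() / self.observed.size


# ---------------------------------------------------------------------------
# delimited spectra tables


def _detect_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_spectra_table(path, delimiter: str | None = None):
    """Read a delimited spectra table.

    Layout: first column wavenumber, one column per spectrum, optional
    single header row with spectrum labels. Returns
    ``(axis, spectra, labels)`` with ``spectra`` of shape
    (n_spectra, L) — one row per spectrum, even for a single column.
    A descending wavenumber column is reversed (with a warning) so the
    axis convention stays strictly increasing.
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty spectra table")
    if delimiter is None:
        delimiter = _detect_delimiter(lines[0])

    first = [c.strip() for c in lines[0].split(delimiter)]
    try:
        float(first[0])
        header = None
        data_lines = lines
    except ValueError:
        header = first
        data_lines = lines[1:]
    if not data_lines:
        raise ValueError(f"{path}: no data rows")

    width = len(data_lines[0].split(delimiter))
    if width < 2:
        raise ValueError(f"{path}: need a wavenumber column plus >= 1 spectrum column")
    rows = []
    for i, ln in enumerate(data_lines):
        cells = [c.strip() for c in ln.split(delimiter)]
        if len(cells) != width:
            raise ValueError(
                f"{path}: ragged row {i}: expected {width} cells, got {len(cells)}"
            )
        row = []
        for j, cell in enumerate(cells):
            try:
                row.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell at row {i}, column {j}: {cell!r}"
                ) from None
        rows.append(row)
    table = np.asarray(rows, dtype=float)
    wn = table[:, 0]
    spectra = table[:, 1:].T  # (n_spectra, L)
    if wn.size > 1 and np.all(np.diff(wn) < 0):
        warnings.warn(
            f"{path}: descending wavenumber axis; reversing", stacklevel=2
        )
        wn = wn[::-1]
        spectra = spectra[:, ::-1]
    axis = WavenumberAxis(wn)
    if header is not None:
        labels = [h for h in header[1:]]
    else:
        labels = [f"spectrum_{k}" for k in range(spectra.shape[0])]
    return axis, np.ascontiguousarray(spectra), labels


def write_spectra_table(path, axis: WavenumberAxis, spectra, labels=None,
                        delimiter: str = ","):
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    if spectra.shape[1] != len(axis):
        raise ValueError("spectra width does not match axis length")
    if labels is None:
        labels = [f"spectrum_{k}" for k in range(spectra.shape[0])]
    if len(labels) != spectra.shape[0]:
        raise ValueError("one label per spectrum required")
    with open(path, "w") as fh:
        fh.write(delimiter.join(["wavenumber_cm1", *map(str, labels)]) + "\n")
        for i, w in enumerate(axis.values):
            cells = [repr(float(w))] + [repr(float(v)) for v in spectra[:, i]]
            fh.write(delimiter.join(cells) + "\n")


# ---------------------------------------------------------------------------
# HDF5 cube / mask containers


def _check_schema(fh: h5py.File, path, kind: str) -> None:
    version = fh.attrs.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"{path}: container schema version {version!r} unsupported; "
            f"expected {SCHEMA_VERSION!r}"
        )
    found = fh.attrs.get("kind")
    if found != kind:
        raise ValueError(f"{path}: expected a {kind} container, found {found!r}")


def write_cube(path, cube: HyperspectralCube) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        fh.attrs["kind"] = "cube"
        fh.attrs["rows"], fh.attrs["cols"] = cube.grid
        fh.attrs["pixel_order"] = PIXEL_ORDER
        fh.attrs["meta"] = json.dumps(cube.meta, sort_keys=True)
        fh.create_dataset("axis", data=cube.axis.values)
        fh.create_dataset("intensities", data=cube.intensities)
        if cube.observed is not None:
            fh.create_dataset("observed", data=cube.observed.astype(np.uint8))


def read_cube(path) -> HyperspectralCube:
    with h5py.File(path, "r") as fh:
        _check_schema(fh, path, "cube")
        axis = WavenumberAxis(fh["axis"][()])
        grid = (int(fh.attrs["rows"]), int(fh.attrs["cols"]))
        intensities = fh["intensities"][()]
        observed = fh["observed"][()].astype(bool) if "observed" in fh else None
        meta = json.loads(fh.attrs["meta"])
    return HyperspectralCube(axis, grid, intensities, observed, meta)


def write_mask(path, mask: ObservationMask) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        fh.attrs["kind"] = "mask"
        fh.attrs["requested_sparsity"] = float(mask.requested_sparsity)
        fh.attrs["seed"] = int(mask.seed)
        fh.attrs["scheme"] = mask.scheme
        fh.create_dataset("observed", data=mask.observed.astype(np.uint8))


def read_mask(path, cube: HyperspectralCube | None = None) -> ObservationMask:
    """Load a mask; if ``cube`` is given, reject on shape mismatch."""
    with h5py.File(path, "r") as fh:
        _check_schema(fh, path, "mask")
        mask = ObservationMask(
            fh["observed"][()].astype(bool),
            requested_sparsity=float(fh.attrs["requested_sparsity"]),
            seed=int(fh.attrs["seed"]),
            scheme=str(fh.attrs["scheme"]),
        )
    if cube is not None and mask.shape != cube.intensities.shape:
        raise ValueError(
            f"{path}: mask shape {mask.shape} does not match cube "
            f"{cube.intensities.shape}"
        )
    return mask
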
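"""Sparsity-sweep orchestration for the three evaluation studies.

Each study runs the same skeleton per (sparsity level, seed): draw a
random spectral mask, recover the missing entries by nuclear-norm
completion, preprocess, then score the downstream task —

* ``concentration``: leave-one-concentration-out PLS regression
  (R^2, max per-level CV, LoQ) on a two-component mixture series;
* ``cell``: k = 2 segmentation of cell vs background plus
  peak-intensity drug detection (overall and drug-class accuracy);
* ``tissue``: PCA (10 scores) + k = 3 clustering, run either
  ``raw_first`` (mask the raw spectra, complete, then preprocess) or
  ``processed_first`` (preprocess, then mask and complete), with the
  PCA-loading matching prefix against the unsparsified reference.

At sparsity 0 completion is bypassed entirely, giving the exact
baseline of each sweep. All randomness is seeded; re-running an
identical spec reproduces the records bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .chemometrics import locoo_validate
from .completion import CompletionConfig, complete_cube, fista_complete
from .imaging import (align_labels, compare_pc_loadings, detect_drug_pixels,
                      kmeans, pca_fit, segmentation_accuracy)
from .io import HyperspectralCube
from .preprocessing import PreprocessConfig, preprocess_cube
from .sparsity import make_random_mask, sparsify_cube
from .synthetic import (DRUG_PEAK_CM1, SceneSpec, make_cell_scene,
                        make_mixture_series, make_tissue_scene,
                        tissue_test_spec)

__all__ = [
    "SweepSpec",
    "SweepResult",
    "run_concentration_study",
    "run_cell_study",
    "run_tissue_study",
    "run_study",
    "write_report",
    "load_report",
]

REPORT_SCHEMA_VERSION = "1"
STUDIES = ("concentration", "cell", "tissue")
ORDERINGS = ("raw_first", "processed_first")

# default sparsity grids mirroring the three studies' operating points
DEFAULT_LEVELS = {
    "concentration": (0.0, 0.5, 0.9),
    "cell": (0.0, 0.2, 0.7, 0.95),
    "tissue": (0.0, 0.1, 0.5, 0.9, 0.95, 0.99),
}


@dataclass
class SweepSpec:
    study: str
    sparsity_levels: tuple = ()
    seeds: tuple = (0,)
    ordering: str | None = None  # tissue only
    scheme: str = "per_spectrum_exact"
    # Sweeps score the reconstruction engine's low-rank estimate at every
    # entry (no clamping of observed values): downstream consumers of a
    # compressive acquisition see the completed matrix, and the raw-vs-
    # processed ordering effect lives in what that estimate keeps or drops.
    completion: CompletionConfig = field(
        default_factory=lambda: CompletionConfig(max_iter=300,
                                                 clamp_observed=False)
    )
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    pls_components: int = 2
    pca_components: int = 10
    cv_threshold: float = 2.0
    kmeans_n_init: int = 10
    scene: SceneSpec | None = None          # cell / tissue template; seed overridden
    dataset_kwargs: dict = field(default_factory=dict)  # concentration generator

    def __post_init__(self) -> None:
        if self.study not in STUDIES:
            raise ValueError(f"study must be one of {STUDIES}")
        if not self.sparsity_levels:
            self.sparsity_levels = DEFAULT_LEVELS[self.study]
        self.sparsity_levels = tuple(float(s) for s in self.sparsity_levels)
        self.seeds = tuple(int(s) for s in self.seeds)
        if not self.seeds:
            raise ValueError("need at least one seed")
        if self.ordering is not None:
            if self.study != "tissue":
                raise ValueError("ordering applies to the tissue study only")
            if self.ordering not in ORDERINGS:
                raise ValueError(f"ordering must be one of {ORDERINGS}")
        if self.study == "tissue" and self.ordering is None:
            self.ordering = "processed_first"


@dataclass
class SweepResult:
    records: list  # dicts: study, ordering, sparsity, seed, metric, value, ...
    provenance: dict = field(default_factory=dict)

    def frame(self):
        import pandas as pd

        return pd.DataFrame(self.records)

    def median(self, metric: str, sparsity: float, ordering: str | None = None):
        """Median of one metric over seeds at one sparsity level.
        ``None`` metric values (e.g. an unattained LoQ) count as +inf."""
        vals = [
            (np.inf if r["value"] is None else r["value"])
            for r in self.records
            if r["metric"] == metric
            and r["sparsity"] == sparsity
            and (ordering is None or r.get("ordering") == ordering)
        ]
        if not vals:
            raise KeyError(f"no records for {metric} at sparsity {sparsity}")
        return float(np.median(vals))


def _mask_seed(seed: int, level_index: int) -> int:
    return (seed * 1009 + 7 * level_index + 1) % (2**31 - 1)


def _provenance(spec: SweepSpec) -> dict:
    return {
        "package": "ramancs",
        "version": __version__,
        "study": spec.study,
        "ordering": spec.ordering,
        "sparsity_levels": list(spec.sparsity_levels),
        "seeds": list(spec.seeds),
        "scheme": spec.scheme,
        "completion": dataclasses.asdict(spec.completion),
        "preprocess": dataclasses.asdict(spec.preprocess),
        "pls_components": spec.pls_components,
        "pca_components": spec.pca_components,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }


def run_concentration_study(spec: SweepSpec) -> SweepResult:
    """Mask -> complete -> preprocess -> leave-one-concentration-out PLS."""
    if spec.study != "concentration":
        raise ValueError("spec.study must be 'concentration'")
    records = []
    for seed in spec.seeds:
        dataset = make_mixture_series(seed=seed, **spec.dataset_kwargs)
        n, L = dataset.spectra.shape
        for li, level in enumerate(spec.sparsity_levels):
            if level == 0.0:
                spectra, realized = dataset.spectra, 0.0
            else:
                mask = make_random_mask(n, L, level, _mask_seed(seed, li),
                                        spec.scheme)
                sparse = np.where(mask.observed, dataset.spectra, 0.0)
                result = fista_complete(sparse, mask.observed, spec.completion)
                spectra = result.X_hat.copy()
                if spec.completion.clamp_observed:
                    spectra[mask.observed] = dataset.spectra[mask.observed]
                realized = mask.sparsity
            cube = HyperspectralCube(dataset.axis, (n, 1), spectra)
            processed = preprocess_cube(cube, spec.preprocess)
            report = locoo_validate(
                dataset.with_spectra(processed.intensities),
                n_components=spec.pls_components,
                sparsity_level=level,
                seed=seed,
                cv_threshold=spec.cv_threshold,
            )
            base = dict(study="concentration", sparsity=level, seed=seed,
                        realized_sparsity=realized)
            records.append({**base, "metric": "r2", "value": report.r2})
            records.append({**base, "metric": "max_cv_percent",
                            "value": report.max_cv_percent})
            records.append({**base, "metric": "loq", "value": report.loq})
    return SweepResult(records, _provenance(spec))


def _recover(cube, level, seed, li, spec: SweepSpec):
    """Sparsify + complete one cube; bypass completion at level 0."""
    if level == 0.0:
        return cube, 0.0
    sparse, mask = sparsify_cube(cube, level, _mask_seed(seed, li), spec.scheme)
    recovered, _ = complete_cube(sparse, mask, spec.completion)
    return recovered, mask.sparsity


def run_cell_study(spec: SweepSpec) -> SweepResult:
    """Mask -> complete -> preprocess -> k=2 cell mask + drug detection."""
    if spec.study != "cell":
        raise ValueError("spec.study must be 'cell'")
    records = []
    scene_template = spec.scene or SceneSpec(
        grid=(32, 36), noise_sd=0.04, baseline_amplitude=0.05
    )
    for seed in spec.seeds:
        scene = dataclasses.replace(scene_template, seed=seed)
        cube, truth = make_cell_scene(scene)
        cell_truth = (truth > 0).astype(int).reshape(-1)
        drug_truth = (truth == 2).astype(int).reshape(-1)
        # drug detection thresholds absolute peak intensities, so it runs on
        # the shape-preserving stage of the chain (before per-spectrum
        # max-normalization, which would blow up the near-empty background
        # spectra); clustering uses the full chain
        shape_steps = tuple(s for s in spec.preprocess.steps if s != "normalize")
        shape_config = dataclasses.replace(spec.preprocess, steps=shape_steps)
        for li, level in enumerate(spec.sparsity_levels):
            recovered, realized = _recover(cube, level, seed, li, spec)
            processed = preprocess_cube(recovered, spec.preprocess)
            cm = kmeans(processed.intensities, 2, seed=seed,
                        n_init=spec.kmeans_n_init)
            aligned = align_labels(cm, cell_truth)
            cell_acc = segmentation_accuracy(aligned, cell_truth)
            shaped = preprocess_cube(recovered, shape_config)
            detected = detect_drug_pixels(shaped, DRUG_PEAK_CM1)
            drug_acc = segmentation_accuracy(
                detected.astype(int).reshape(-1), drug_truth, class_of_interest=1
            )
            base = dict(study="cell", sparsity=level, seed=seed,
                        realized_sparsity=realized)
            records.append({**base, "metric": "cell_accuracy_percent",
                            "value": cell_acc})
            records.append({**base, "metric": "drug_accuracy_percent",
                            "value": drug_acc})
    return SweepResult(records, _provenance(spec))


def run_tissue_study(spec: SweepSpec) -> SweepResult:
    """PCA(10) + k=3 clustering under the chosen sparsification ordering.

    ``raw_first``: mask the raw cube -> complete -> preprocess;
    ``processed_first``: preprocess -> mask -> complete. Both then run
    PCA and k-means, align labels, and score accuracy; the PC-loading
    matching prefix is measured against the level-0 reference PCA.
    """
    if spec.study != "tissue":
        raise ValueError("spec.study must be 'tissue'")
    records = []
    scene_template = spec.scene or tissue_test_spec()
    for seed in spec.seeds:
        scene = dataclasses.replace(scene_template, seed=seed)
        cube, truth = make_tissue_scene(scene)
        flat_truth = truth.reshape(-1)
        processed0 = preprocess_cube(cube, spec.preprocess)
        pca_ref = pca_fit(processed0.intensities, spec.pca_components)
        for li, level in enumerate(spec.sparsity_levels):
            if level == 0.0:
                X, realized = processed0.intensities, 0.0
                pca = pca_ref
            elif spec.ordering == "raw_first":
                recovered, realized = _recover(cube, level, seed, li, spec)
                X = preprocess_cube(recovered, spec.preprocess).intensities
                pca = pca_fit(X, spec.pca_components)
            else:
                recovered, realized = _recover(processed0, level, seed, li, spec)
                X = recovered.intensities
                pca = pca_fit(X, spec.pca_components)
            cm = kmeans(pca.scores, 3, seed=seed, n_init=spec.kmeans_n_init)
            aligned = align_labels(cm, flat_truth)
            acc = segmentation_accuracy(aligned, flat_truth)
            prefix, _, _ = compare_pc_loadings(pca_ref, pca)
            base = dict(study="tissue", ordering=spec.ordering, sparsity=level,
                        seed=seed, realized_sparsity=realized)
            records.append({**base, "metric": "accuracy_percent", "value": acc})
            records.append({**base, "metric": "pc_matching_prefix",
                            "value": prefix})
    return SweepResult(records, _provenance(spec))


_RUNNERS = {
    "concentration": run_concentration_study,
    "cell": run_cell_study,
    "tissue": run_tissue_study,
}


def run_study(spec: SweepSpec) -> SweepResult:
    return _RUNNERS[spec.study](spec)


def write_report(result: SweepResult, path) -> None:
    """Write a sweep result as line-oriented JSON (header + one record
    per line) plus a human-readable summary table next to it."""
    path = Path(path)
    with open(path, "w") as fh:
        header = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "kind": "sweep_result",
            "provenance": result.provenance,
        }
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for record in result.records:
            fh.write(json.dumps(record, sort_keys=True) + "\n")
    frame = result.frame()
    summary = frame.pivot_table(
        index=[c for c in ("ordering", "sparsity") if c in frame.columns],
        columns="metric",
        values="value",
        aggfunc="median",
    )
    path.with_suffix(path.suffix + ".summary.txt").write_text(
        summary.to_string() + "\n"
    )


def load_report(path) -> SweepResult:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty report")
    header = json.loads(lines[0])
    version = header.get("schema_version")
    if version != REPORT_SCHEMA_VERSION:
        raise ValueError(
            f"{path}: report schema version {version!r} unsupported; "
            f"expected {REPORT_SCHEMA_VERSION!r}"
        )
    records = [json.loads(ln) for ln in lines[1:]]
    return SweepResult(records, header.get("provenance", {}))
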
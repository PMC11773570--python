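"""Segmentation and dimensionality-reduction endpoints for
hyperspectral images: PCA, k-means clustering, peak-intensity drug
detection, cluster-label alignment, and pixel accuracies.

k-means labels are arbitrary, so before any accuracy is computed the
predicted labels are permuted to maximize agreement with the ground
truth (exhaustive search for k <= 8 with lexicographic tie-break,
assignment solver above). "Overall" accuracy is the fraction of pixels
whose aligned label matches the truth; class accuracy is recall on the
truth pixels of that class, so a present class that is never predicted
scores exactly 0 %.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from skimage.filters import threshold_otsu
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .io import HyperspectralCube

__all__ = [
    "PCAResult",
    "ClusterMap",
    "pca_fit",
    "kmeans",
    "detect_drug_pixels",
    "align_labels",
    "segmentation_accuracy",
    "compare_pc_loadings",
]


@dataclass
class PCAResult:
    mean: np.ndarray
    components: np.ndarray            # (n_components, L), orthonormal rows
    scores: np.ndarray                # (n, n_components)
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def pca_fit(X, n_components: int = 10) -> PCAResult:
    """Principal components of mean-centered ``X`` (rows = pixels).

    Sign convention: each loading's largest-magnitude element is made
    positive, so loadings are reproducible across runs and libraries.
    """
    X = np.asarray(X, dtype=float)
    if not (1 <= n_components <= min(X.shape)):
        raise ValueError(
            f"n_components must be in [1, {min(X.shape)}] for shape {X.shape}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    components = pca.components_.copy()
    flip = np.sign(
        components[np.arange(n_components),
                   np.argmax(np.abs(components), axis=1)]
    )
    flip[flip == 0] = 1.0
    components *= flip[:, None]
    scores = scores * flip[None, :]
    return PCAResult(
        mean=pca.mean_.copy(),
        components=components,
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


@dataclass
class ClusterMap:
    labels: np.ndarray   # flat, one label in [0, k) per point
    k: int
    inertia: float
    seed: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int).reshape(-1)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.k):
            raise ValueError("labels must lie in [0, k)")

    def image(self, grid: tuple[int, int]) -> np.ndarray:
        return self.labels.reshape(grid)


def kmeans(points, k: int, seed: int = 0, n_init: int = 10) -> ClusterMap:
    """Lloyd's k-means from ``n_init`` random initializations; the
    lowest-inertia run wins. Every point gets a label in [0, k)."""
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    if k <= 0:
        raise ValueError("k must be >= 1")
    if np.unique(points, axis=0).shape[0] < k:
        raise ValueError("k exceeds the number of distinct points")
    km = KMeans(
        n_clusters=k, init="random", n_init=n_init,
        algorithm="lloyd", random_state=seed,
    ).fit(points)
    return ClusterMap(labels=km.labels_, k=k, inertia=float(km.inertia_), seed=seed)


def detect_drug_pixels(
    cube: HyperspectralCube,
    peak_wavenumber: float = 1168.0,
    rule: str = "mean_plus_ksd",
    threshold: float | None = None,
    k_sd: float = 3.0,
) -> np.ndarray:
    """Flag pixels whose intensity at the channel nearest
    ``peak_wavenumber`` exceeds a threshold.

    Rules: ``mean_plus_ksd`` (default, mean + ``k_sd`` standard
    deviations — an outlier rule suited to a rare class that cannot
    dominate the intensity histogram), ``otsu`` (bimodal split of the
    channel intensities), ``fixed`` (explicit ``threshold``). Returns a
    boolean (rows, cols) map.
    """
    channel = cube.axis.nearest_index(peak_wavenumber)  # rejects out-of-range
    values = cube.intensities[:, channel]
    if rule == "otsu":
        thr = float(threshold_otsu(values))
    elif rule == "fixed":
        if threshold is None:
            raise ValueError("fixed rule needs an explicit threshold")
        thr = float(threshold)
    elif rule == "mean_plus_ksd":
        thr = float(values.mean() + k_sd * values.std())
    else:
        raise ValueError(f"unknown detection rule {rule!r}")
    return (values > thr).reshape(cube.grid)


def _labels_of(x) -> np.ndarray:
    if isinstance(x, ClusterMap):
        return x.labels
    return np.asarray(x, dtype=int).reshape(-1)


def align_labels(predicted, truth):
    """Permute predicted cluster labels to maximize pixel agreement with
    the truth map. Exhaustive search over permutations for k <= 8 (ties
    broken by the lexicographically smallest permutation); Hungarian
    assignment above. Returns a relabeled :class:`ClusterMap`."""
    pred = _labels_of(predicted)
    true = _labels_of(truth)
    if pred.shape != true.shape:
        raise ValueError("predicted and truth label maps differ in size")
    pred_vals = np.unique(pred)
    true_vals = np.unique(np.concatenate([true, pred_vals]))
    k = len(true_vals)
    # agreement counts C[i, j] = pixels with predicted value i and truth value j
    C = np.zeros((len(pred_vals), k), dtype=int)
    for i, pv in enumerate(pred_vals):
        sel = pred == pv
        for j, tv in enumerate(true_vals):
            C[i, j] = int(np.sum(true[sel] == tv))
    if k <= 8:
        best_perm, best_score = None, -1
        for perm in itertools.permutations(range(k), len(pred_vals)):
            score = sum(C[i, perm[i]] for i in range(len(pred_vals)))
            if score > best_score:
                best_perm, best_score = perm, score
        mapping = {pv: true_vals[best_perm[i]] for i, pv in enumerate(pred_vals)}
    else:
        rows, cols = linear_sum_assignment(-C)
        mapping = {pred_vals[i]: true_vals[j] for i, j in zip(rows, cols)}
    relabeled = np.array([mapping[v] for v in pred])
    source = predicted if isinstance(predicted, ClusterMap) else None
    return ClusterMap(
        labels=relabeled,
        k=int(max(true_vals.max(), relabeled.max())) + 1,
        inertia=source.inertia if source else float("nan"),
        seed=source.seed if source else 0,
    )


def segmentation_accuracy(predicted, truth, class_of_interest=None) -> float:
    """Percent agreement between aligned labels and truth.

    ``class_of_interest=None``: fraction of all pixels correctly
    labeled. Otherwise: recall on the truth pixels of that class (an
    empty detection of a present class scores 0)."""
    pred = _labels_of(predicted)
    true = _labels_of(truth)
    if pred.shape != true.shape:
        raise ValueError("label maps differ in size")
    if class_of_interest is None:
        return 100.0 * float(np.mean(pred == true))
    sel = true == class_of_interest
    if not sel.any():
        raise ValueError(f"class {class_of_interest} absent from truth")
    return 100.0 * float(np.mean(pred[sel] == class_of_interest))


def compare_pc_loadings(
    a: PCAResult, b: PCAResult, similarity_threshold: float = 0.95
):
    """Per-component |cosine similarity| of two loading sets.

    Returns ``(prefix_length, similarities, flags)`` where
    ``prefix_length`` is the number of leading components whose
    similarity clears the threshold — the depth to which the second
    decomposition preserves the first's structure.
    """
    if a.components.shape[1] != b.components.shape[1]:
        raise ValueError("loading sets live on different wavenumber axes")
    n = min(a.n_components, b.n_components)
    sims = np.empty(n)
    for i in range(n):
        u, v = a.components[i], b.components[i]
        sims[i] = abs(float(u @ v)) / (np.linalg.norm(u) * np.linalg.norm(v))
    flags = sims >= similarity_threshold
    prefix = int(np.argmin(flags)) if not flags.all() else n
    return prefix, sims, flags
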
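"""Figure-support utilities: kernel-PCA ordering for stacked histograms,
hierarchical heatmap ordering, and the UMAP niche atlas.

These are pure functions of (matrix, parameters, seed); they emit orders and
coordinates, not rendered figures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.decomposition import KernelPCA

ATLAS_N_NEIGHBORS = 100
ATLAS_MIN_DIST = 8.0
ATLAS_SPREAD = 8.0


@dataclass
class AtlasLayout:
    coordinates: np.ndarray  # (n, 2)
    n_neighbors: int
    min_dist: float
    spread: float
    seed: int


def _kpca_scores(matrix: np.ndarray) -> np.ndarray:
    """First kernel principal component with a Gaussian kernel.

    Length scale ell = 1/d (d = feature count), in the convention
    k(x, y) = exp(-||x - y||^2 / (2 ell^2)), i.e. gamma = d^2 / 2.
    """
    d = matrix.shape[1]
    gamma = d**2 / 2.0
    kpca = KernelPCA(n_components=1, kernel="rbf", gamma=gamma)
    return kpca.fit_transform(matrix)[:, 0]


def kpca_order(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row and column orders by the first kernel-PC score.

    The global sign of a principal component is arbitrary; it is fixed by the
    score skewness (a content-based rule, so the sorted output is invariant
    to shuffling the input rows), falling back to the smaller original index
    when the scores are perfectly symmetric.
    """
    x = np.asarray(matrix, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("matrix contains non-finite values")

    def _order(m: np.ndarray) -> np.ndarray:
        if m.shape[0] == 1:
            return np.array([0])
        scores = _kpca_scores(m)
        skew = ((scores - scores.mean()) ** 3).sum()
        if abs(skew) > 1e-12:
            if skew < 0:
                scores = -scores
            return np.argsort(scores, kind="stable")
        fwd = np.argsort(scores, kind="stable")
        rev = np.argsort(-scores, kind="stable")
        return fwd if fwd[0] <= rev[0] else rev

    return _order(x), _order(x.T)


def heatmap_order(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row/column leaf orders from Euclidean single-linkage on z-scored logs."""
    x = np.log1p(np.asarray(matrix, dtype=float))
    mean, std = x.mean(axis=0), x.std(axis=0)
    std[std == 0] = 1.0
    z = (x - mean) / std

    def _order(m: np.ndarray) -> np.ndarray:
        if m.shape[0] == 1:
            return np.array([0])
        return leaves_list(linkage(m, method="single", metric="euclidean"))

    return _order(z), _order(z.T)


def umap_atlas(
    abundance_matrix: np.ndarray,
    n_neighbors: int = ATLAS_N_NEIGHBORS,
    min_dist: float = ATLAS_MIN_DIST,
    spread: float = ATLAS_SPREAD,
    seed: int = 0,
) -> AtlasLayout:
    """2-D UMAP embedding of per-spot niche abundance patterns.

    The wide min_dist/spread defaults scatter spots so per-spot composition
    glyphs do not overlap in the rendered atlas. n_neighbors is clipped (with
    a warning) when fewer rows are available.
    """
    import umap

    x = np.asarray(abundance_matrix, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("abundance matrix contains non-finite values")
    if x.shape[0] <= n_neighbors:
        warnings.warn(
            f"n_neighbors={n_neighbors} clipped to n_rows-1={x.shape[0] - 1}", stacklevel=2
        )
        n_neighbors = max(x.shape[0] - 1, 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            spread=spread,
            random_state=seed,
        )
        coords = reducer.fit_transform(x)
    return AtlasLayout(
        coordinates=np.asarray(coords, dtype=float),
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        spread=spread,
        seed=seed,
    )
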
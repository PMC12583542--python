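"""Cell-niche detection: neighborhood composition vectors, prototype
clustering, assignment, abundances, niche profiles and the dominance-entropy
permutation test.

A cell's *neighborhood feature* is the 12-vector of marker-positive cell
counts within 34 µm (inclusive; each neighbor contributes to every marker it
carries, and the index cell counts itself), log1p-transformed to saturate
large counts and normalized by the local mass so it expresses the relative
marker composition of the neighborhood. Mini-batch k-means++ over these
vectors defines k prototypical neighborhoods ("niches"); each cell is
assigned to its nearest prototype. Niche discovery is intended to be run per
subtype (LUAD and LUSC separately) — the two subtypes are distinct entities
and pooling them would blur subtype-specific spatial biology; matched pairs
are recovered post hoc (see :mod:`cellniche.matching`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import entropy, permutation_test
from sklearn.cluster import MiniBatchKMeans

from .markers import MARKERS, N_MARKERS

DEFAULT_RADIUS_UM = 34.0
DEFAULT_K = 10
DEFAULT_MINIBATCH = 8000

#: A niche is "hot" when at least this fraction of its cells are
#: lymphocyte-lineage (T, B or NK, including activated/exhausted/regulatory
#: states). Macrophage-dominated niches therefore classify cold.
HOT_LYMPHOCYTE_FRACTION = 0.25

LYMPHOCYTE_LINEAGES = frozenset({"T", "B", "NK"})


@dataclass
class NicheModel:
    """Fitted niche prototypes in transformed 12-marker composition space."""

    centroids: np.ndarray  # (k, 12)
    radius_um: float = DEFAULT_RADIUS_UM
    minibatch_size: int = DEFAULT_MINIBATCH
    seed: int = 0
    include_self: bool = True
    marker_order: tuple[str, ...] = MARKERS
    inertia: float = float("nan")

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def to_json(self, path: str | Path) -> None:
        payload = dict(
            centroids=self.centroids.tolist(),
            radius_um=self.radius_um,
            minibatch_size=self.minibatch_size,
            seed=self.seed,
            include_self=self.include_self,
            marker_order=list(self.marker_order),
            inertia=self.inertia,
        )
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "NicheModel":
        d = json.loads(Path(path).read_text())
        return cls(
            centroids=np.asarray(d["centroids"], dtype=float),
            radius_um=d["radius_um"],
            minibatch_size=d["minibatch_size"],
            seed=d["seed"],
            include_self=d["include_self"],
            marker_order=tuple(d["marker_order"]),
            inertia=d.get("inertia", float("nan")),
        )


@dataclass
class NicheProfile:
    """Per-niche phenotype distribution, marker proportions and hot/cold call."""

    niche_id: int
    phenotype_distribution: pd.Series  # sums to 1
    marker_proportions: np.ndarray  # (12,) marker-positive cell fractions
    lymphocyte_fraction: float
    hot_cold: str  # 'hot' | 'cold'
    n_cells: int
    label: str = ""


def neighborhood_features(
    cells: pd.DataFrame,
    radius_um: float = DEFAULT_RADIUS_UM,
    include_self: bool = True,
) -> np.ndarray:
    """Transformed neighborhood composition vector for every cell of one spot.

    Counts marker-positive neighbors within Euclidean distance <= radius
    (KD-tree), applies log1p elementwise, and divides by the vector sum.
    Zero-mass neighborhoods map to the zero vector.
    """
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        raise ValueError("non-finite cell coordinates")
    markers = cells[list(MARKERS)].to_numpy(dtype=float)
    n = len(cells)
    if n == 0:
        return np.empty((0, N_MARKERS))
    tree = cKDTree(xy)
    counts = np.zeros((n, N_MARKERS))
    if include_self:
        counts += markers
    pairs = tree.query_pairs(r=radius_um, output_type="ndarray")
    if len(pairs):
        np.add.at(counts, pairs[:, 0], markers[pairs[:, 1]])
        np.add.at(counts, pairs[:, 1], markers[pairs[:, 0]])
    feats = np.log1p(counts)
    mass = feats.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        feats = np.where(mass > 0, feats / np.where(mass == 0, 1.0, mass), 0.0)
    return feats


def neighborhood_features_by_spot(
    cells: pd.DataFrame,
    radius_um: float = DEFAULT_RADIUS_UM,
    include_self: bool = True,
) -> np.ndarray:
    """Neighborhood features computed spot by spot (spots are separate tissues)."""
    feats = np.zeros((len(cells), N_MARKERS))
    for idx in cells.groupby("spot_id", sort=False).indices.values():
        feats[idx] = neighborhood_features(cells.iloc[idx], radius_um, include_self)
    return feats


def fit_niche_model(
    feature_vectors: np.ndarray,
    k: int = DEFAULT_K,
    minibatch_size: int = DEFAULT_MINIBATCH,
    seed: int = 0,
    radius_um: float = DEFAULT_RADIUS_UM,
    include_self: bool = True,
    n_restarts: int = 3,
) -> NicheModel:
    """Mini-batch k-means++ clustering of neighborhood vectors.

    Runs ``n_restarts`` seeded initializations and keeps the lowest-inertia
    fit, so results are deterministic given ``seed``.
    """
    X = np.asarray(feature_vectors, dtype=float)
    if len(np.unique(X, axis=0)) < k:
        raise ValueError(f"need at least k={k} distinct feature vectors")
    best: MiniBatchKMeans | None = None
    for r in range(n_restarts):
        km = MiniBatchKMeans(
            n_clusters=k,
            init="k-means++",
            batch_size=minibatch_size,
            random_state=seed + r,
            n_init=1,
        ).fit(X)
        if best is None or km.inertia_ < best.inertia_:
            best = km
    assert best is not None
    return NicheModel(
        centroids=best.cluster_centers_.copy(),
        radius_um=radius_um,
        minibatch_size=minibatch_size,
        seed=seed,
        include_self=include_self,
        inertia=float(best.inertia_),
    )


def assign_niches(feature_vectors: np.ndarray, model: NicheModel) -> np.ndarray:
    """Nearest-centroid assignment (Euclidean); ties break to the lowest id.

    Niche ids are 1-based to match the reporting convention.
    """
    X = np.asarray(feature_vectors, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.centroids.shape[1]:
        raise ValueError("feature dimension does not match model centroids")
    d2 = ((X[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2) if len(X) < 100_000 else None
    if d2 is None:
        # chunked to bound memory on multi-million-cell inputs
        out = np.empty(len(X), dtype=int)
        for start in range(0, len(X), 100_000):
            chunk = X[start : start + 100_000]
            dd = ((chunk[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
            out[start : start + 100_000] = np.argmin(dd, axis=1)
        return out + 1
    return np.argmin(d2, axis=1) + 1


def spot_niche_abundance(
    cells: pd.DataFrame, k: int, niche_col: str = "niche_id"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-spot niche counts and proportions over 1..k.

    Returns (counts, proportions) indexed by spot_id with one column per
    niche. Empty spots cannot occur here (groupby of assigned cells); spots
    with zero cells must be flagged upstream.
    """
    if niche_col not in cells.columns:
        raise ValueError(f"cells lack a {niche_col!r} column")
    counts = (
        cells.groupby(["spot_id", niche_col]).size().unstack(fill_value=0)
        .reindex(columns=range(1, k + 1), fill_value=0)
    )
    counts.columns = [f"niche_{j}" for j in range(1, k + 1)]
    totals = counts.sum(axis=1)
    proportions = counts.div(totals, axis=0)
    return counts, proportions


def niche_phenotype_profiles(
    cells: pd.DataFrame,
    gating_lineage: dict[str, str],
    grain: str = "medium",
    hot_threshold: float = HOT_LYMPHOCYTE_FRACTION,
    niche_col: str = "niche_id",
) -> dict[int, NicheProfile]:
    """Phenotype distribution and hot/cold call per niche.

    ``gating_lineage`` maps phenotype class -> lineage; a niche is hot when
    its T+B+NK cell fraction is at least ``hot_threshold``. Empty niches are
    omitted (flagged by absence).
    """
    col = f"phenotype_{grain}"
    for c in (col, niche_col):
        if c not in cells.columns:
            raise ValueError(f"cells lack a {c!r} column")
    profiles: dict[int, NicheProfile] = {}
    marker_mat = cells[list(MARKERS)].to_numpy(dtype=float)
    for niche_id, group in cells.groupby(niche_col):
        dist = group[col].value_counts(normalize=True).sort_index()
        lineages = group[col].map(
            lambda ph: gating_lineage.get(ph, "other")
        )
        lymph = float(lineages.isin(LYMPHOCYTE_LINEAGES).mean())
        idx = cells.index.get_indexer(group.index)
        marker_pos = marker_mat[idx]
        denom = max(marker_pos.sum(), 1.0)
        profiles[int(niche_id)] = NicheProfile(
            niche_id=int(niche_id),
            phenotype_distribution=dist,
            marker_proportions=marker_pos.sum(axis=0) / denom,
            lymphocyte_fraction=lymph,
            hot_cold="hot" if lymph >= hot_threshold else "cold",
            n_cells=len(group),
        )
    return profiles


def dominance_entropy_test(
    proportions_a: np.ndarray,
    proportions_b: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation test on niche-dominance entropy between two spot groups.

    Statistic: difference in mean Shannon entropy (nats) of per-spot niche
    proportion vectors. Low entropy = a single dominant niche; high entropy =
    mixed niches. Two-sided p over random group-label shuffles; permuting
    group labels of spots is equivalent to permuting their precomputed
    entropies, which is what runs here. Returns (statistic, p-value).
    """
    a = np.atleast_2d(np.asarray(proportions_a, dtype=float))
    b = np.atleast_2d(np.asarray(proportions_b, dtype=float))
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ent_a = entropy(a, axis=1)
    ent_b = entropy(b, axis=1)
    if np.array_equal(a, b):
        return 0.0, 1.0

    def statistic(x, y, axis):
        return np.mean(x, axis=axis) - np.mean(y, axis=axis)

    res = permutation_test(
        (ent_a, ent_b),
        statistic,
        permutation_type="independent",
        vectorized=True,
        n_resamples=n_perm,
        alternative="two-sided",
        rng=np.random.default_rng(seed),
    )
    return float(res.statistic), float(res.pvalue)
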
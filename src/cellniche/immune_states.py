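"""Spot-level immune states: hierarchical clustering of density profiles,
TME-type assignment, and group-composition tests.

Tumor spots are clustered on their (log1p, column z-scored) phenotype density
profiles with Euclidean single-linkage agglomerative clustering. Cluster mean
profiles support a 2x2 tumor-microenvironment (TME) typing on PD-L1+
carcinoma-cell density and lymphocyte (TIL) density:

==========  =========  ====
PD-L1       TIL        type
==========  =========  ====
high        high       1
low         low        2  ("cold")
high        low        3
low         high       4
==========  =========  ====
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import chi2_contingency


@dataclass
class ImmuneStateResult:
    labels: np.ndarray  # per-spot cluster id, contiguous 1..k
    linkage_matrix: np.ndarray
    cluster_profiles: pd.DataFrame  # per-cluster mean of the raw input densities
    tme_types: dict[int, int | str] | None = None


def _zscore_log(matrix: np.ndarray) -> np.ndarray:
    x = np.log1p(matrix)
    mean = x.mean(axis=0)
    std = x.std(axis=0, ddof=0)
    std[std == 0] = 1.0
    return (x - mean) / std


def cluster_immune_states(density_matrix: pd.DataFrame | np.ndarray, k: int) -> ImmuneStateResult:
    """Cut the single-linkage dendrogram of z-scored log densities at k clusters."""
    if isinstance(density_matrix, pd.DataFrame):
        values = density_matrix.to_numpy(dtype=float)
        columns = list(density_matrix.columns)
    else:
        values = np.asarray(density_matrix, dtype=float)
        columns = [f"f{i}" for i in range(values.shape[1])]
    if not np.isfinite(values).all():
        raise ValueError("density matrix contains non-finite values")
    if k < 1 or k > values.shape[0]:
        raise ValueError(f"k must be in [1, n_rows={values.shape[0]}]")
    if values.shape[0] == 1:
        labels = np.array([1])
        Z = np.empty((0, 4))
    else:
        Z = linkage(_zscore_log(values), method="single", metric="euclidean")
        labels = fcluster(Z, t=k, criterion="maxclust")
    # relabel to contiguous 1..k in order of first appearance
    remap: dict[int, int] = {}
    for lab in labels:
        remap.setdefault(int(lab), len(remap) + 1)
    labels = np.array([remap[int(lab)] for lab in labels])
    profiles = (
        pd.DataFrame(values, columns=columns)
        .groupby(labels).mean()
        .rename_axis("cluster")
    )
    return ImmuneStateResult(labels=labels, linkage_matrix=Z, cluster_profiles=profiles)


def classify_tme_type(
    cluster_profile: dict[str, float] | pd.Series,
    thresholds: dict[str, float],
) -> int:
    """2x2 TME rule on immunosuppressive-carcinoma-cell and lymphocyte density.

    ``cluster_profile`` must provide 'immunosuppressive carcinoma cell' and
    'lymphocyte' densities (counts/mm^2); ``thresholds`` the corresponding
    cutoffs under keys 'pdl1_pos_density' and 'til_density'. Densities at or
    above the cutoff count as high.
    """
    for key in ("immunosuppressive carcinoma cell", "lymphocyte"):
        if key not in cluster_profile:
            raise KeyError(f"cluster profile is missing {key!r}")
    for key in ("pdl1_pos_density", "til_density"):
        if key not in thresholds:
            raise KeyError(f"thresholds missing {key!r}")
    pdl1_high = cluster_profile["immunosuppressive carcinoma cell"] >= thresholds["pdl1_pos_density"]
    til_high = cluster_profile["lymphocyte"] >= thresholds["til_density"]
    if pdl1_high and til_high:
        return 1
    if not pdl1_high and not til_high:
        return 2
    if pdl1_high:
        return 3
    return 4


def group_composition_test(counts_a: np.ndarray, counts_b: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared on the 2 x k contingency table of category counts."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("count vectors must be 1-D with matching categories")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be nonnegative")
    table = np.vstack([a, b])
    if table.sum() == 0:
        raise ValueError("all-zero contingency table")
    # drop empty categories: they contribute nothing and break expected counts
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    stat, p, _, _ = chi2_contingency(table, correction=False)
    return float(stat), float(p)
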
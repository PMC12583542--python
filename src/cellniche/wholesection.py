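"""Whole-section validation: virtual-core tiling, section-level risk, and
TMA concordance / risk heterogeneity.

Whole tumor sections are scored by sliding 1.5 mm virtual cores (the TMA
core geometry) over the tumor area on a regular grid, computing each kept
core's niche composition and spot-level risk, and taking the maximum core
risk as the section risk — the same hot-spot rule used for TMA patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import pearsonr

from .markers import TUMOR_COMPARTMENTS
from .niches import NicheModel, assign_niches, neighborhood_features
from .survival import RiskModel

DEFAULT_CORE_DIAMETER_UM = 1500.0
#: Half-diameter stride: adjacent cores overlap, so the tumor area is
#: exhaustively covered wherever cell density suffices.
DEFAULT_STRIDE_UM = 750.0
#: Minimum tumor-compartment cells for a core to count (proxy for the
#: 0.7 mm^2 aligned-area floor, since no raster areas exist here).
DEFAULT_MIN_CELLS = 100


@dataclass
class VirtualCore:
    center_x_um: float
    center_y_um: float
    diameter_um: float
    cell_index: np.ndarray  # positional indices into the section cell table
    tumor_cell_count: int


def tile_virtual_cores(
    cells: pd.DataFrame,
    diameter_um: float = DEFAULT_CORE_DIAMETER_UM,
    stride_um: float = DEFAULT_STRIDE_UM,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> list[VirtualCore]:
    """Place circular virtual cores on a regular grid over the tumor area.

    Grid centers span the bounding box of tumor-compartment cells with the
    given stride; a core is kept when it contains at least ``min_cells``
    tumor cells. Membership is Euclidean distance <= diameter/2.
    """
    if stride_um <= 0:
        raise ValueError("stride must be positive")
    if diameter_um <= 0:
        raise ValueError("core diameter must be positive")
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    tumor_mask = cells["compartment"].isin(TUMOR_COMPARTMENTS).to_numpy()
    if not tumor_mask.any():
        return []
    radius = diameter_um / 2.0
    txy = xy[tumor_mask]
    x0, y0 = txy.min(axis=0)
    x1, y1 = txy.max(axis=0)
    xs = np.arange(x0, x1 + stride_um, stride_um)
    ys = np.arange(y0, y1 + stride_um, stride_um)
    tree = cKDTree(xy)
    cores: list[VirtualCore] = []
    for cx in xs:
        for cy in ys:
            members = np.asarray(tree.query_ball_point([cx, cy], r=radius), dtype=int)
            n_tumor = int(tumor_mask[members].sum()) if len(members) else 0
            if n_tumor >= min_cells:
                cores.append(
                    VirtualCore(float(cx), float(cy), diameter_um, np.sort(members), n_tumor)
                )
    return cores


def core_risk(
    cells: pd.DataFrame,
    core: VirtualCore,
    niche_model: NicheModel,
    risk_model: RiskModel,
    extra_features: dict[str, float] | None = None,
) -> float:
    """Spot-level risk of one virtual core from its niche composition.

    Neighborhood features are computed within the core's own cells (the core
    is treated as a self-contained tissue spot, exactly like a TMA spot).
    ``extra_features`` supplies non-niche covariates (e.g. the patient's
    UICC8 stage) expected by the risk model.
    """
    sub = cells.iloc[core.cell_index]
    feats = neighborhood_features(sub, niche_model.radius_um, niche_model.include_self)
    niche_ids = assign_niches(feats, niche_model)
    counts = np.bincount(niche_ids, minlength=niche_model.k + 1)[1:]
    proportions = counts / counts.sum()
    row = {f"niche_{j + 1}": proportions[j] for j in range(niche_model.k)}
    row.update(extra_features or {})
    frame = pd.DataFrame([row])
    return float(risk_model.predict_spot_risk(frame).iloc[0])


def section_risk(
    cells: pd.DataFrame,
    cores: list[VirtualCore],
    niche_model: NicheModel,
    risk_model: RiskModel,
    extra_features: dict[str, float] | None = None,
) -> tuple[float, np.ndarray]:
    """Section-level risk = max over virtual-core risks (hot-spot rule)."""
    if not cores:
        raise ValueError("no kept virtual cores")
    risks = np.array([core_risk(cells, c, niche_model, risk_model, extra_features) for c in cores])
    return float(risks.max()), risks


def concordance_and_heterogeneity(
    tma_risks: np.ndarray | None = None,
    section_risks: np.ndarray | None = None,
    spot_risks: pd.DataFrame | None = None,
) -> dict[str, float]:
    """Paired TMA/section concordance and intra- vs inter-tumoral variance.

    With paired ``tma_risks``/``section_risks``: Pearson r (two-sided p) and
    the fraction of identical tertile risk-group labels. With ``spot_risks``
    (columns patient_id, risk): one-way variance decomposition of spot risks
    into within-patient and between-patient components
    (total = within + between, exact).
    """
    out: dict[str, float] = {}
    if tma_risks is not None and section_risks is not None:
        a = np.asarray(tma_risks, dtype=float)
        b = np.asarray(section_risks, dtype=float)
        if len(a) != len(b):
            raise ValueError("paired risk vectors must have equal length")
        if len(a) < 3:
            raise ValueError("need at least 3 pairs for correlation")
        if np.std(a) == 0 or np.std(b) == 0:
            out["pearson_r"] = float("nan")
            out["pearson_p"] = float("nan")
        else:
            r, p = pearsonr(a, b)
            out["pearson_r"] = float(r)
            out["pearson_p"] = float(p)
        from .survival import stratify_tertiles

        ga = stratify_tertiles(pd.Series(a)).to_numpy()
        gb = stratify_tertiles(pd.Series(b)).to_numpy()
        out["risk_group_agreement"] = float((ga == gb).mean())
    if spot_risks is not None:
        risks = spot_risks["risk"].to_numpy(dtype=float)
        patients = spot_risks["patient_id"].to_numpy()
        grand = risks.mean()
        within = 0.0
        between = 0.0
        for pid in np.unique(patients):
            r = risks[patients == pid]
            within += ((r - r.mean()) ** 2).sum()
            between += len(r) * (r.mean() - grand) ** 2
        n = len(risks)
        out["total_variance"] = float(((risks - grand) ** 2).sum() / n)
        out["within_patient_variance"] = float(within / n)
        out["between_patient_variance"] = float(between / n)
    return out
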
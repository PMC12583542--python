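"""Cell phenotyping: 12-marker vectors + tissue context -> phenotype hierarchy.

A :class:`GatingTable` is an ordered list of first-match rules. Each rule
tests required markers, forbidden markers and (optionally) the tissue
compartment, and emits a fine-grained phenotype, its medium-grained parent,
a lineage and a set of state modifiers.

The default table is a reconstruction from standard immunophenotyping
conventions for this panel, engineered around:

* lineage precedence CK (compartment-gated) > CD3 > CD20 > CD56 > CD163/CD68;
  marker conflicts resolve to the dominant lineage rather than inventing
  combination phenotypes of unknown biological meaning;
* CK+ cells are carcinoma only outside the healthy compartment; in healthy
  tissue they are normal epithelium (pneumocytes etc. share CK);
* lymphocyte states: GrB+ = activated, PD-1+ without GrB = exhausted,
  FoxP3+ T cells = regulatory;
* PD-L1 marks cells as immunosuppressive independent of lineage;
* TAM1 = CD68+CD163-, TAM2 = CD163+.

This yields exactly 43 fine and 23 medium classes. The table is an editable
artifact (CSV round-trip) so a published supplementary definition can be
substituted verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .markers import COMPARTMENTS, MARKERS, TUMOR_COMPARTMENTS

LINEAGES = ("carcinoma", "T", "B", "NK", "macrophage", "other")
MODIFIERS = ("activated", "exhausted", "immunosuppressive", "regulatory")


@dataclass(frozen=True)
class GatingRule:
    required: frozenset[str]
    forbidden: frozenset[str]
    compartments: frozenset[str] | None  # None = any compartment
    fine: str
    medium: str
    lineage: str
    modifiers: frozenset[str] = field(default_factory=frozenset)


@dataclass
class GatingTable:
    """Ordered, first-match phenotype rules with a terminal catch-all."""

    rules: list[GatingRule]

    def __post_init__(self) -> None:
        self.validate()

    @property
    def fine_classes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.rules:
            seen.setdefault(r.fine)
        return list(seen)

    @property
    def medium_classes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.rules:
            seen.setdefault(r.medium)
        return list(seen)

    @property
    def fine_to_medium(self) -> dict[str, str]:
        return {r.fine: r.medium for r in self.rules}

    @property
    def fine_to_lineage(self) -> dict[str, str]:
        return {r.fine: r.lineage for r in self.rules}

    def validate(self) -> None:
        for r in self.rules:
            unknown = (r.required | r.forbidden) - set(MARKERS)
            if unknown:
                raise ValueError(f"rule {r.fine!r}: unknown marker(s) {sorted(unknown)}")
            if r.lineage not in LINEAGES:
                raise ValueError(f"rule {r.fine!r}: unknown lineage {r.lineage!r}")
            if not r.modifiers <= set(MODIFIERS):
                raise ValueError(f"rule {r.fine!r}: unknown modifier(s)")
        # hierarchy consistency: a fine class maps to exactly one medium/lineage
        seen: dict[str, tuple[str, str]] = {}
        for r in self.rules:
            prev = seen.setdefault(r.fine, (r.medium, r.lineage))
            if prev != (r.medium, r.lineage):
                raise ValueError(f"fine class {r.fine!r} has inconsistent medium/lineage")
        # totality: every marker combination x compartment must match some rule
        combos = np.array(list(product([0, 1], repeat=len(MARKERS))), dtype=np.int8)
        grid = pd.DataFrame(np.tile(combos, (len(COMPARTMENTS), 1)), columns=list(MARKERS))
        grid["compartment"] = np.repeat(COMPARTMENTS, len(combos))
        fine = _apply_rules(grid, self.rules)
        if (fine == "").any():
            row = grid.loc[fine == ""].iloc[0]
            pos = [m for m in MARKERS if row[m]]
            raise ValueError(
                f"gating table is not total: no rule for markers {pos} "
                f"in compartment {row['compartment']!r}"
            )

    def to_csv(self, path: str | Path) -> None:
        rows = [
            dict(
                required=" ".join(sorted(r.required)),
                forbidden=" ".join(sorted(r.forbidden)),
                compartments=" ".join(sorted(r.compartments)) if r.compartments else "",
                fine=r.fine,
                medium=r.medium,
                lineage=r.lineage,
                modifiers=" ".join(sorted(r.modifiers)),
            )
            for r in self.rules
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GatingTable":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        rules = [
            GatingRule(
                required=frozenset(str(row["required"]).split()),
                forbidden=frozenset(str(row["forbidden"]).split()),
                compartments=frozenset(str(row["compartments"]).split()) or None,
                fine=row["fine"],
                medium=row["medium"],
                lineage=row["lineage"],
                modifiers=frozenset(str(row["modifiers"]).split()),
            )
            for _, row in df.iterrows()
        ]
        return cls(rules)


def _apply_rules(cells: pd.DataFrame, rules: list[GatingRule]) -> pd.Series:
    fine = pd.Series("", index=cells.index, dtype=object)
    unassigned = np.ones(len(cells), dtype=bool)
    markers = {m: cells[m].to_numpy(dtype=bool) for m in MARKERS}
    compartment = cells["compartment"].to_numpy()
    for rule in rules:
        if not unassigned.any():
            break
        mask = unassigned.copy()
        for m in rule.required:
            mask &= markers[m]
        for m in rule.forbidden:
            mask &= ~markers[m]
        if rule.compartments is not None:
            mask &= np.isin(compartment, list(rule.compartments))
        fine.iloc[np.flatnonzero(mask)] = rule.fine
        unassigned &= ~mask
    return fine


def _lymphocyte_state_rules(
    required: frozenset[str],
    forbidden: frozenset[str],
    base: str,
    lineage: str,
    extra_mods: frozenset[str] = frozenset(),
) -> list[GatingRule]:
    """Six-rule block: {activated, exhausted, base} x optional PD-L1 variant."""
    r = []
    for state, state_req, state_forb, mods in [
        ("activated", {"GRB"}, set(), {"activated"}),
        ("exhausted", {"PD1"}, {"GRB"}, {"exhausted"}),
        ("", set(), set(), set()),
    ]:
        medium = f"{state} {base}".strip()
        for pdl1 in (True, False):
            fine = f"immunosuppressive {medium}" if pdl1 else medium
            r.append(
                GatingRule(
                    required=frozenset(required | state_req | ({"PDL1"} if pdl1 else set())),
                    forbidden=frozenset(forbidden | state_forb),
                    compartments=None,
                    fine=fine,
                    medium=medium,
                    lineage=lineage,
                    modifiers=frozenset(
                        extra_mods | mods | ({"immunosuppressive"} if pdl1 else set())
                    ),
                )
            )
    return r


def default_gating_table() -> GatingTable:
    tumor_like = frozenset(set(COMPARTMENTS) - {"healthy"})
    healthy = frozenset({"healthy"})
    R: list[GatingRule] = []

    # epithelium: compartment decides carcinoma vs normal epithelium
    R += [
        GatingRule(frozenset({"CK", "PDL1"}), frozenset(), healthy,
                   "immunosuppressive normal epithelial cell", "normal epithelial cell",
                   "other", frozenset({"immunosuppressive"})),
        GatingRule(frozenset({"CK"}), frozenset(), healthy,
                   "normal epithelial cell", "normal epithelial cell", "other"),
        GatingRule(frozenset({"CK", "PDL1"}), frozenset(), tumor_like,
                   "immunosuppressive carcinoma cell", "immunosuppressive carcinoma cell",
                   "carcinoma", frozenset({"immunosuppressive"})),
        GatingRule(frozenset({"CK"}), frozenset(), tumor_like,
                   "carcinoma cell", "carcinoma cell", "carcinoma"),
    ]

    # regulatory T cells take precedence over CD4/CD8 subsets
    R += [
        GatingRule(frozenset({"CD3", "FOXP3", "GRB"}), frozenset(), None,
                   "activated regulatory T cell", "regulatory T cell", "T",
                   frozenset({"regulatory", "activated"})),
        GatingRule(frozenset({"CD3", "FOXP3", "PDL1"}), frozenset(), None,
                   "immunosuppressive regulatory T cell", "regulatory T cell", "T",
                   frozenset({"regulatory", "immunosuppressive"})),
        GatingRule(frozenset({"CD3", "FOXP3"}), frozenset(), None,
                   "regulatory T cell", "regulatory T cell", "T", frozenset({"regulatory"})),
    ]
    # CD4+CD8+ and CD4-CD8- fall through to the generic T-cell block
    R += _lymphocyte_state_rules(frozenset({"CD3", "CD8"}), frozenset({"CD4"}),
                                 "cytotoxic T cell", "T")
    R += _lymphocyte_state_rules(frozenset({"CD3", "CD4"}), frozenset({"CD8"}),
                                 "T helper cell", "T")
    R += [
        GatingRule(frozenset({"CD3", "PDL1"}), frozenset(), None,
                   "immunosuppressive T cell", "T cell", "T",
                   frozenset({"immunosuppressive"})),
        GatingRule(frozenset({"CD3"}), frozenset(), None, "T cell", "T cell", "T"),
    ]

    R += _lymphocyte_state_rules(frozenset({"CD20"}), frozenset(), "B cell", "B")
    R += _lymphocyte_state_rules(frozenset({"CD56"}), frozenset(), "NK cell", "NK")

    # macrophages: CD163 dominates (TAM2), CD68-only is TAM1
    R += [
        GatingRule(frozenset({"CD163", "PDL1"}), frozenset(), None,
                   "immunosuppressive TAM2", "TAM2", "macrophage",
                   frozenset({"immunosuppressive"})),
        GatingRule(frozenset({"CD163"}), frozenset(), None, "TAM2", "TAM2", "macrophage"),
        GatingRule(frozenset({"CD68", "PDL1"}), frozenset({"CD163"}), None,
                   "immunosuppressive TAM1", "TAM1", "macrophage",
                   frozenset({"immunosuppressive"})),
        GatingRule(frozenset({"CD68"}), frozenset({"CD163"}), None,
                   "TAM1", "TAM1", "macrophage"),
    ]

    # lineage-negative cells with state markers only
    R += [
        GatingRule(frozenset({"GRB", "PDL1"}), frozenset(), None,
                   "immunosuppressive cytotoxic lymphocyte", "cytotoxic lymphocyte",
                   "other", frozenset({"activated", "immunosuppressive"})),
        GatingRule(frozenset({"GRB"}), frozenset(), None,
                   "cytotoxic lymphocyte", "cytotoxic lymphocyte", "other",
                   frozenset({"activated"})),
        GatingRule(frozenset({"PD1", "PDL1"}), frozenset(), None,
                   "immunosuppressive exhausted lymphocyte", "exhausted lymphocyte",
                   "other", frozenset({"exhausted", "immunosuppressive"})),
        GatingRule(frozenset({"PD1"}), frozenset(), None,
                   "exhausted lymphocyte", "exhausted lymphocyte", "other",
                   frozenset({"exhausted"})),
        GatingRule(frozenset({"PDL1"}), frozenset(), None,
                   "immunosuppressive cell", "immunosuppressive cell", "other",
                   frozenset({"immunosuppressive"})),
        GatingRule(frozenset(), frozenset(), None, "other cell", "other cell", "other"),
    ]
    return GatingTable(R)


def assign_phenotypes(cells: pd.DataFrame, gating: GatingTable | None = None) -> pd.DataFrame:
    """Return a copy of ``cells`` with phenotype_fine / phenotype_medium columns."""
    if gating is None:
        gating = default_gating_table()
    cells = cells.copy()
    fine = _apply_rules(cells, gating.rules)
    cells["phenotype_fine"] = fine
    cells["phenotype_medium"] = fine.map(gating.fine_to_medium)
    return cells


def compute_densities(
    cells: pd.DataFrame,
    spots: pd.DataFrame,
    grain: str = "marker",
    region: str = "tumor",
    log_transform: bool = False,
    gating: GatingTable | None = None,
) -> pd.DataFrame:
    """Per-spot cell densities (counts / mm^2), optionally log1p-transformed.

    ``grain='marker'`` counts marker-positive cells (a cell contributes to
    every marker it carries); ``'fine'``/``'medium'`` count phenotype classes
    (requires assigned phenotypes, or a gating table to assign them here).
    ``region='tumor'`` restricts cells to carcinoma+stroma compartments and
    divides by tumor_area_mm2; ``'total'`` uses all non-excluded cells over
    aligned_area_mm2. Only QC-passing spots are evaluated.
    """
    if grain not in ("marker", "fine", "medium"):
        raise ValueError("grain must be 'marker', 'fine' or 'medium'")
    if region not in ("tumor", "total"):
        raise ValueError("region must be 'tumor' or 'total'")
    spots = spots.loc[spots["qc_pass"].astype(bool)]
    area_col = "tumor_area_mm2" if region == "tumor" else "aligned_area_mm2"

    cells = cells.loc[cells["spot_id"].isin(spots["spot_id"])]
    cells = cells.loc[cells["compartment"] != "excluded"]
    if region == "tumor":
        cells = cells.loc[cells["compartment"].isin(TUMOR_COMPARTMENTS)]

    if grain == "marker":
        counts = cells.groupby("spot_id")[list(MARKERS)].sum()
        columns = list(MARKERS)
    else:
        col = f"phenotype_{grain}"
        if col not in cells.columns:
            cells = assign_phenotypes(cells, gating)
        table = gating or default_gating_table()
        columns = table.fine_classes if grain == "fine" else table.medium_classes
        counts = (
            cells.groupby(["spot_id", col]).size().unstack(fill_value=0)
            .reindex(columns=columns, fill_value=0)
        )
    counts = counts.reindex(spots["spot_id"], fill_value=0).astype(float)
    areas = spots.set_index("spot_id")[area_col].reindex(counts.index)

    zero_area = areas.to_numpy() <= 0
    has_cells = counts.sum(axis=1).to_numpy() > 0
    if (zero_area & has_cells).any():
        bad = counts.index[zero_area & has_cells][0]
        raise ValueError(f"spot {bad!r}: zero {region} area but nonzero cell count")
    dens = counts.div(areas.replace(0.0, np.nan), axis=0).fillna(0.0)
    if log_transform:
        dens = np.log1p(dens)
    dens.columns.name = None
    return dens[columns]
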
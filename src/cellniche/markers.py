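"""Canonical 12-marker panel.

The multiplex immunofluorescence panel covers epithelium (CK), T-cell lineage
and subsets (CD3, CD4, CD8, FOXP3), B cells (CD20), NK cells (CD56),
macrophages (CD68, CD163), and activation / checkpoint state (PD1, PDL1, GRB).
The order below is fixed and used everywhere a 12-vector appears: marker
columns in cell tables, neighborhood composition vectors, niche centroids and
radar-profile exports.
"""

from __future__ import annotations

MARKERS: tuple[str, ...] = (
    "CK",
    "CD3",
    "CD4",
    "CD8",
    "CD20",
    "CD56",
    "CD68",
    "CD163",
    "FOXP3",
    "PD1",
    "PDL1",
    "GRB",
)

N_MARKERS: int = len(MARKERS)

MARKER_INDEX: dict[str, int] = {m: i for i, m in enumerate(MARKERS)}

#: Tissue compartments a cell can fall in (from tissue segmentation).
COMPARTMENTS: tuple[str, ...] = ("carcinoma", "stroma", "necrosis", "healthy", "excluded")

#: Compartments that count as tumor region for density denominators.
TUMOR_COMPARTMENTS: frozenset[str] = frozenset({"carcinoma", "stroma"})
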
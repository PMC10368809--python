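"""Marker panels, phenotype rule tables and compartment codes.

Two 5-plex panels are stained on serial 4 µm sections of the same tissue
block, each counterstained with DAPI.  Panel 1 carries the lymphoid /
granulocyte markers, panel 2 the cytotoxic / myeloid / stemness markers.
Because the panels live on different physical sections, cells can never be
matched across panels; every per-cell quantity is panel-local.
"""

from __future__ import annotations

PANEL1 = "panel1"
PANEL2 = "panel2"
PANELS = (PANEL1, PANEL2)

#: Channel order of the marker pages of each panel TIFF (page 0 is DAPI).
PANEL_MARKERS: dict[str, list[str]] = {
    PANEL1: ["FOXP3", "CD38", "CD4", "CD20", "CD66b"],
    PANEL2: ["CD8", "CD68", "PD-L1", "CD163", "CD133"],
}

#: Fluorescence-strength bins defined by the per-marker threshold Z:
#: intensity < Z -> neg, [Z, 2Z) -> low, [2Z, 3Z) -> med, >= 3Z -> high.
FS_LEVELS = ("neg", "low", "med", "high")

# Compartment raster codes: tumour nest (intratumoural), tumour stroma,
# and non-tissue (glass / artefact; cells there are excluded downstream).
NON_TISSUE = 0
TUMOUR_NEST = 1
TUMOUR_STROMA = 2
COMPARTMENT_NAMES = {NON_TISSUE: "excluded", TUMOUR_NEST: "TN", TUMOUR_STROMA: "TS"}
COMPARTMENTS = ("TN", "TS")

#: Ordered phenotype rule tables: first rule whose markers are all
#: non-negative wins; no match -> "other".  PD-L1 is recorded as an
#: independent flag, never as an exclusive phenotype.
PHENOTYPE_RULES: dict[str, list[tuple[str, frozenset[str]]]] = {
    PANEL1: [
        ("Treg", frozenset({"CD4", "FOXP3"})),
        ("CD4 T", frozenset({"CD4"})),
        ("activated T", frozenset({"CD38"})),
        ("B", frozenset({"CD20"})),
        ("neutrophil", frozenset({"CD66b"})),
    ],
    PANEL2: [
        ("M2 macrophage", frozenset({"CD68", "CD163"})),
        ("macrophage", frozenset({"CD68"})),
        ("CD8 T", frozenset({"CD8"})),
        ("CSC", frozenset({"CD133"})),
    ],
}

OTHER = "other"
PDL1_FLAG = "PD-L1+"

#: Inverse map used by the synthetic generator: which markers a phenotype
#: expresses.  "other" expresses none.
POSITIVE_MARKERS: dict[str, frozenset[str]] = {
    name: markers for rules in PHENOTYPE_RULES.values() for name, markers in rules
}
POSITIVE_MARKERS[OTHER] = frozenset()

#: Panel of each exclusive phenotype.
PHENOTYPE_PANEL: dict[str, str] = {
    name: panel for panel, rules in PHENOTYPE_RULES.items() for name, _ in rules
}
PHENOTYPE_PANEL[PDL1_FLAG] = PANEL2

#: Five spatial cell classes per panel (the pair schema is built on these).
#: On panel 2 the PD-L1+ class overlays the exclusive phenotypes, so a cell
#: may belong to two classes there.
SPATIAL_CLASSES: dict[str, list[str]] = {
    PANEL1: ["Treg", "CD4 T", "activated T", "B", "neutrophil"],
    PANEL2: ["CD8 T", "macrophage", "M2 macrophage", "CSC", PDL1_FLAG],
}

#: The 11 phenotypes of the default cell-content schema (x 2 compartments
#: x 3 metrics = 66 content features).
CONTENT_PHENOTYPES: list[str] = [
    "Treg", "CD4 T", "activated T", "B", "neutrophil",
    "CD8 T", "macrophage", "M2 macrophage", "CSC", PDL1_FLAG, OTHER,
]

#: Marker whose H-score summarises each phenotype's staining intensity.
#: "other" is marker-negative by definition and carries no H-score.
PRIMARY_MARKER: dict[str, str] = {
    "Treg": "FOXP3",
    "CD4 T": "CD4",
    "activated T": "CD38",
    "B": "CD20",
    "neutrophil": "CD66b",
    "CD8 T": "CD8",
    "macrophage": "CD68",
    "M2 macrophage": "CD163",
    "CSC": "CD133",
    PDL1_FLAG: "PD-L1",
}
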
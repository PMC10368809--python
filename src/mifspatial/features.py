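"""Cell-content (composition) features and the patient feature table.

Composition is the percentage of cells of a phenotype among all cells in
sight within a compartment (tumour nest or stroma); density normalises the
count by compartment area in mm²; the per-phenotype H-score summarises the
staining intensity of the phenotype's defining marker.  The default content
schema is 11 phenotypes x 2 compartments x 3 metrics = 66 columns, joined
with the 30 spatial features and the clinical table into one row per
patient.  Missing values are empty CSV fields, never zero-imputed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .panels import (
    COMPARTMENTS,
    CONTENT_PHENOTYPES,
    OTHER,
    PANEL1,
    PDL1_FLAG,
    PHENOTYPE_PANEL,
    PRIMARY_MARKER,
    TUMOUR_NEST,
    TUMOUR_STROMA,
)
from .quantify import h_score_from_levels

__all__ = [
    "composition",
    "density",
    "compartment_area_mm2",
    "ratio_features",
    "content_feature_schema",
    "patient_content_features",
    "assemble_feature_table",
]


def _in_compartment(cells: pd.DataFrame, compartment: str) -> pd.DataFrame:
    if compartment not in COMPARTMENTS:
        raise ValueError(f"unknown compartment {compartment!r}")
    return cells[cells["compartment"] == compartment]


def composition(cells: pd.DataFrame, compartment: str) -> dict[str, float]:
    """Percentage of each exclusive phenotype among the compartment's cells.

    Computed per panel (the denominator is the panel's cells in the
    compartment, i.e. cells in sight on that section); the PD-L1+ flag class
    is reported against the panel-2 denominator.  An empty compartment
    yields an empty dict with a warning.
    """
    sub = _in_compartment(cells, compartment)
    if sub.empty:
        warnings.warn(f"no cells in compartment {compartment}", stacklevel=2)
        return {}
    out: dict[str, float] = {}
    panel_totals = sub.groupby("panel").size()
    for pheno in CONTENT_PHENOTYPES:
        if pheno == OTHER:
            panel = PANEL1
            count = ((sub["phenotype"] == OTHER) & (sub["panel"] == panel)).sum()
        elif pheno == PDL1_FLAG:
            panel = PHENOTYPE_PANEL[pheno]
            count = sub.loc[sub["panel"] == panel, "pdl1_pos"].eq(True).sum() \
                if "pdl1_pos" in sub.columns else 0
        else:
            panel = PHENOTYPE_PANEL[pheno]
            count = (sub["phenotype"] == pheno).sum()
        total = panel_totals.get(panel, 0)
        out[pheno] = 100.0 * float(count) / float(total) if total else float("nan")
    return out


def compartment_area_mm2(
    compartment_mask: np.ndarray, compartment: str, pixel_size_um: float
) -> float:
    code = {"TN": TUMOUR_NEST, "TS": TUMOUR_STROMA}.get(compartment)
    if code is None:
        raise ValueError(f"unknown compartment {compartment!r}")
    area_px = int((np.asarray(compartment_mask) == code).sum())
    return area_px * pixel_size_um**2 * 1e-6


def density(count: int, area_mm2: float) -> float:
    """Cells per mm² of compartment area."""
    if area_mm2 <= 0:
        raise ValueError(f"compartment area must be positive, got {area_mm2}")
    if count < 0:
        raise ValueError("count must be >= 0")
    return count / area_mm2


def ratio_features(
    comp: dict[str, float], pairs: list[tuple[str, str]]
) -> dict[str, float | None]:
    """Named percentage ratios, e.g. Treg / CD4 T; zero denominator -> missing."""
    out: dict[str, float | None] = {}
    for num, den in pairs:
        for name in (num, den):
            if name not in comp:
                raise ValueError(f"unknown phenotype {name!r}")
        d = comp[den]
        out[f"ratio_{num}/{den}"] = None if (d == 0 or np.isnan(d)) else comp[num] / d
    return out


def content_feature_schema(
    phenotypes: list[str] | None = None,
) -> list[str]:
    """Column names of the content schema (default 11 x 2 x 3 = 66)."""
    phenotypes = phenotypes or CONTENT_PHENOTYPES
    cols = []
    for pheno in phenotypes:
        for comp in COMPARTMENTS:
            cols += [f"pct_{pheno}_{comp}", f"density_{pheno}_{comp}", f"hscore_{pheno}_{comp}"]
    return cols


def patient_content_features(
    cells: pd.DataFrame,
    compartment_mask: np.ndarray,
    pixel_size_um: float,
    phenotypes: list[str] | None = None,
) -> dict[str, float]:
    """The 66 content features of one patient's sections.

    Percentages and counts pool the patient's sections; density divides the
    pooled count by the summed compartment area of the sections (the mask is
    shared across a patient's serial sections, scaled by section count);
    the H-score uses the phenotype's primary-marker FS levels over the
    phenotype's cells in the compartment.  Undefined cells stay NaN.
    """
    phenotypes = phenotypes or CONTENT_PHENOTYPES
    n_sections = cells["section_id"].nunique() if not cells.empty else 1
    out: dict[str, float] = {}
    for comp in COMPARTMENTS:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pct = composition(cells, comp)
        area = compartment_area_mm2(compartment_mask, comp, pixel_size_um) * n_sections
        sub = _in_compartment(cells, comp)
        for pheno in phenotypes:
            out[f"pct_{pheno}_{comp}"] = pct.get(pheno, float("nan"))
            if pheno == PDL1_FLAG:
                members = sub[sub["pdl1_pos"].eq(True)] if "pdl1_pos" in sub.columns else sub.iloc[0:0]
            elif pheno == OTHER:
                members = sub[(sub["phenotype"] == OTHER) & (sub["panel"] == PANEL1)]
            else:
                members = sub[sub["phenotype"] == pheno]
            out[f"density_{pheno}_{comp}"] = (
                density(len(members), area) if area > 0 else float("nan")
            )
            marker = PRIMARY_MARKER.get(pheno)
            col = f"fs_{marker}" if marker else None
            if col and not members.empty and col in members.columns:
                out[f"hscore_{pheno}_{comp}"] = h_score_from_levels(members[col].dropna())
            else:
                out[f"hscore_{pheno}_{comp}"] = float("nan")
    return out


def assemble_feature_table(
    content: pd.DataFrame,
    spatial: pd.DataFrame | None,
    clinical: pd.DataFrame,
    patient_col: str = "patient_id",
) -> pd.DataFrame:
    """One row per patient: clinical columns + 66 content + 30 spatial.

    Patient ids must align between content and clinical; a patient with no
    spatial row is kept with missing spatial cells.  Mismatching ids raise,
    listing the offenders.
    """
    c_ids = set(content[patient_col])
    k_ids = set(clinical[patient_col])
    if c_ids != k_ids:
        raise ValueError(
            "patient ids differ between content and clinical tables: "
            f"content-only {sorted(c_ids - k_ids)}, clinical-only {sorted(k_ids - c_ids)}"
        )
    table = clinical.merge(content, on=patient_col, how="left", validate="1:1")
    if spatial is not None and not spatial.empty:
        extra = set(spatial[patient_col]) - k_ids
        if extra:
            raise ValueError(f"spatial table has unknown patient ids {sorted(extra)}")
        table = table.merge(spatial, on=patient_col, how="left", validate="1:1")
    return table
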
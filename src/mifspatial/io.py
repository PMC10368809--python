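"""Reading and writing scene rasters and tables.

Scenes are stored as per-panel multi-page TIFFs (page 0 = DAPI, pages 1-5 =
the panel's markers in panel order), a nucleus label TIFF and a compartment
label TIFF per panel/section, plus `clinical.csv` and `truth_cells.csv`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .panels import PANEL_MARKERS
from .synth import CohortResult, GroundTruth

__all__ = [
    "write_scene",
    "read_panel_stack",
    "read_label_tiff",
    "write_label_tiff",
    "truth_cells_frame",
    "write_cohort",
]


def write_label_tiff(path, labels: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(labels).astype(np.int32))


def read_label_tiff(path) -> np.ndarray:
    return tifffile.imread(str(path))


def read_panel_stack(path) -> np.ndarray:
    """A (6, H, W) panel stack (page 0 DAPI)."""
    return tifffile.imread(str(path))


def truth_cells_frame(truth: GroundTruth, section_id: str = "s1") -> pd.DataFrame:
    """Ground-truth cells as a flat table (one row per cell and panel)."""
    rows = []
    for panel, pt in truth.panels.items():
        for cid, (x, y) in pt.centroids.items():
            row = {
                "section_id": section_id,
                "panel": panel,
                "cell_id": cid,
                "x_px": x,
                "y_px": y,
                "phenotype": pt.phenotype_of[cid],
                "pdl1_pos": cid in pt.pdl1_pos,
            }
            for marker in PANEL_MARKERS[panel]:
                row[f"fs_{marker}"] = pt.marker_truth[cid][marker]
                row[f"intensity_{marker}"] = pt.marker_intensity[cid][marker]
            rows.append(row)
    return pd.DataFrame(rows)


def write_scene(
    out_dir, channels: dict[str, np.ndarray], truth: GroundTruth, section_id: str = "s1"
) -> None:
    """One section pair: panel stacks, label/compartment TIFFs, truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for panel, stack in channels.items():
        tifffile.imwrite(str(out / f"{section_id}_{panel}.tif"), stack)
        write_label_tiff(out / f"{section_id}_{panel}_nuclei.tif",
                         truth.panels[panel].nucleus_labels)
    write_label_tiff(out / f"{section_id}_compartments.tif", truth.compartment_mask)
    truth_cells_frame(truth, section_id).to_csv(out / f"{section_id}_truth_cells.csv", index=False)
    (out / f"{section_id}_meta.json").write_text(json.dumps({
        "pixel_size_um": truth.pixel_size_um,
        "z_thresholds": truth.z_thresholds,
    }, indent=2))


def write_cohort(out_dir, cohort: CohortResult) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pat in cohort.patients:
        pdir = out / pat.patient_id
        for s, (channels, truth) in enumerate(pat.sections, start=1):
            write_scene(pdir, channels, truth, section_id=f"s{s}")
    cohort.clinical.to_csv(out / "clinical.csv", index=False)
    cohort.true_features.to_csv(out / "truth_features.csv", index=False)
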
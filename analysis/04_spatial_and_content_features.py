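"""Spatial and composition features for the quantified demo scene.

Builds the per-patient feature set from scratch/cells_demo.csv: the 30
within-panel Delaunay pair-distance features and the 66 content features
(11 phenotypes x TN/TS x percentage/density/H-score), assembled into one
patient row.  Run 03_quantify_cells.py first (it writes scratch/cells_demo.csv).
"""

from pathlib import Path

import pandas as pd

from mifspatial.features import (
    assemble_feature_table,
    content_feature_schema,
    patient_content_features,
    ratio_features,
    composition,
)
from mifspatial.spatial import spatial_feature_table
from mifspatial.synth import SceneSpec, generate_scene

cells = pd.read_csv("scratch/cells_demo.csv")

# the demo scene's compartment mask is regenerated from the same seed
spec = SceneSpec(n_cells=500, seed=7, blur_sd=0.0, noise_sd=0.0)
_, truth = generate_scene(spec)

spatial = spatial_feature_table(cells)
content = pd.DataFrame([{
    "patient_id": "P0001",
    **patient_content_features(cells, truth.compartment_mask, spec.pixel_size_um),
}])
clinical = pd.DataFrame([{"patient_id": "P0001"}])
table = assemble_feature_table(content, spatial, clinical)
Path("results").mkdir(exist_ok=True)
table.to_csv("results/feature_table_demo.csv", index=False)

n_spatial = spatial.shape[1] - 1
n_content = len(content_feature_schema())
defined = int(table.drop(columns="patient_id").notna().sum(axis=1).iloc[0])
print(f"feature table: {n_content} content + {n_spatial} spatial columns "
      f"({defined} defined for this patient)")
treg_ratio = ratio_features(composition(cells, "TS"), [("Treg", "CD4 T")])
print(f"intrastromal Treg/CD4 T ratio: {treg_ratio['ratio_Treg/CD4 T']:.3f}")
print("-> results/feature_table_demo.csv")
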
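import numpy as np
import pandas as pd
import pytest

from mifspatial.synth import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """A small noiseless rendered scene with its spec and ground truth."""
    spec = SceneSpec(
        n_cells=120, width_px=512, height_px=384, seed=11,
        blur_sd=0.0, noise_sd=0.0,
    )
    channels, truth = generate_scene(spec)
    return spec, channels, truth


@pytest.fixture(scope="session")
def table1_clinical():
    """Patient-level reconstruction of the published cohort's summary counts.

    553 patients: histology 269/92/22 (LUAD/LUSC/other) in stage IA-IIA and
    113/39/18 in IIB-IIIB; 126 of 383 early-stage and 114 of 170
    mid-to-late-stage patients relapsed.
    """
    rows = []
    histology = {
        "IA-IIA": [("LUAD", 269), ("LUSC", 92), ("other", 22)],
        "IIB-IIIB": [("LUAD", 113), ("LUSC", 39), ("other", 18)],
    }
    relapse = {"IA-IIA": 126, "IIB-IIIB": 114}
    for stage, counts in histology.items():
        flat = [h for h, n in counts for _ in range(n)]
        n_rel = relapse[stage]
        for i, h in enumerate(flat):
            rows.append({
                "stage_group": stage,
                "histology": h,
                "relapse": int(i < n_rel),
            })
    df = pd.DataFrame(rows)
    assert len(df) == 553
    return df


def disk_mask(shape, cy, cx, r):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
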
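"""Per-cell marker quantification.

Turns channel rasters plus nucleus coordinates into per-cell marker calls:
fluorescent-field extraction, intersection of fluorescent fields with
(dilated) nuclei, Z/2Z/3Z fluorescence-strength binning, H-scores,
phenotype calling and compartment assignment.

The central convention is the per-marker positive threshold ``Z``: a cell
whose mean marker intensity is below Z is negative, ``[Z, 2Z)`` is low,
``[2Z, 3Z)`` is median and ``>= 3Z`` is high fluorescence strength (FS).
Boundary values belong to the upper bin.  The H-score summarises a marker
over a cell population as ``%low x 1 + %med x 2 + %high x 3`` on a 0-100
percent scale, hence ranges over [0, 300].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.segmentation import expand_labels

from .panels import (
    COMPARTMENT_NAMES,
    FS_LEVELS,
    OTHER,
    PANEL_MARKERS,
    PHENOTYPE_RULES,
    PANEL2,
)

__all__ = [
    "FluorescenceField",
    "extract_fluorescence",
    "intersect_cf_ccn",
    "assign_fs_level",
    "h_score",
    "h_score_from_levels",
    "call_phenotype",
    "assign_compartment",
    "quantify_scene",
]


@dataclass
class FluorescenceField:
    """Pixels of one marker channel judged to carry real signal."""

    marker: str
    mask: np.ndarray  # boolean raster, same shape as the channel

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def extract_fluorescence(
    channel: np.ndarray, background_quantile: float = 0.95, marker: str = ""
) -> FluorescenceField:
    """Pixels strictly above the channel's background-quantile intensity.

    ``background_quantile = 0`` degenerately selects every pixel (warned);
    a constant channel yields an empty field with a warning.
    """
    if not 0.0 <= background_quantile < 1.0:
        raise ValueError(f"background_quantile must be in [0, 1), got {background_quantile}")
    channel = np.asarray(channel)
    if background_quantile == 0.0:
        warnings.warn("background_quantile 0 selects every pixel", stacklevel=2)
        return FluorescenceField(marker, np.ones(channel.shape, dtype=bool))
    cutoff = np.quantile(channel, background_quantile)
    mask = channel > cutoff
    if not mask.any():
        warnings.warn(
            f"channel {marker!r} has no pixel above its {background_quantile:g} "
            "quantile (constant channel?); empty fluorescence field",
            stacklevel=2,
        )
    return FluorescenceField(marker, mask)


def intersect_cf_ccn(
    channel: np.ndarray,
    fluorescence: FluorescenceField,
    nuclei: np.ndarray,
    dilation_px: int = 2,
) -> dict[int, float]:
    """Attribute fluorescent pixels to cells and average their intensity.

    A fluorescent pixel belongs to cell ``k`` iff it falls inside nucleus k
    dilated by ``dilation_px`` (dilated nuclei never overlap: each pixel goes
    to its nearest nucleus).  Fluorescent pixels outside every dilated
    nucleus are discarded as non-specific signal.  Returns the mean channel
    intensity over attributed pixels per cell id, 0.0 for cells with none.
    """
    channel = np.asarray(channel)
    nuclei = np.asarray(nuclei)
    if channel.shape != nuclei.shape or channel.shape != fluorescence.mask.shape:
        raise ValueError("channel, fluorescence field and nucleus mask shapes differ")
    if dilation_px < 0:
        raise ValueError("dilation_px must be >= 0")
    ids = np.unique(nuclei)
    ids = ids[ids > 0]
    grown = expand_labels(nuclei, distance=dilation_px) if dilation_px else nuclei
    attributed = grown * fluorescence.mask
    sums = np.bincount(
        attributed.ravel(), weights=channel.ravel(), minlength=int(ids.max()) + 1 if ids.size else 1
    )
    counts = np.bincount(attributed.ravel(), minlength=sums.size)
    out: dict[int, float] = {}
    for k in ids:
        out[int(k)] = float(sums[k] / counts[k]) if counts[k] else 0.0
    return out


def assign_fs_level(intensity: float, z: float) -> str:
    """Bin a mean intensity into neg/low/med/high by the Z, 2Z, 3Z thresholds."""
    if z <= 0:
        raise ValueError(f"threshold Z must be positive, got {z}")
    if intensity < 0:
        raise ValueError(f"negative intensity {intensity}")
    if intensity < z:
        return "neg"
    if intensity < 2 * z:
        return "low"
    if intensity < 3 * z:
        return "med"
    return "high"


def h_score(frac_low: float, frac_med: float, frac_high: float) -> float:
    """H-score = %low x 1 + %med x 2 + %high x 3, fractions on a 0-100 scale."""
    for f in (frac_low, frac_med, frac_high):
        if f < 0:
            raise ValueError("percentages must be non-negative")
    total = frac_low + frac_med + frac_high
    if total > 100 + 1e-9:
        raise ValueError(f"positive-cell percentages sum to {total} > 100")
    return frac_low * 1 + frac_med * 2 + frac_high * 3


def h_score_from_levels(levels) -> float:
    """H-score of a collection of per-cell FS levels."""
    levels = list(levels)
    if not levels:
        raise ValueError("no cells")
    unknown = set(levels) - set(FS_LEVELS)
    if unknown:
        raise ValueError(f"unknown FS levels {sorted(unknown)}")
    n = len(levels)
    pct = {lv: 100.0 * sum(x == lv for x in levels) / n for lv in FS_LEVELS}
    return h_score(pct["low"], pct["med"], pct["high"])


def call_phenotype(
    fs: dict[str, str],
    rules: list[tuple[str, frozenset[str]]] | None = None,
    panel: str | None = None,
) -> str:
    """First matching rule of the ordered rule table wins; no match -> "other".

    A rule matches when every one of its markers is non-negative in ``fs``.
    Either an explicit rule table or a panel name (using the default table)
    must be given; every marker a rule references must be present in ``fs``.
    """
    if rules is None:
        if panel is None:
            raise ValueError("either rules or panel must be given")
        rules = PHENOTYPE_RULES[panel]
    for name, markers in rules:
        missing = markers - fs.keys()
        if missing:
            raise ValueError(f"markers {sorted(missing)} missing from FS map")
        if all(fs[m] != "neg" for m in markers):
            return name
    return OTHER


def assign_compartment(centroid_xy: tuple[float, float], compartment_mask: np.ndarray) -> str:
    """Compartment label ("TN"/"TS"/"excluded") of the mask pixel under a centroid."""
    x, y = centroid_xy
    r, c = int(round(y)), int(round(x))
    h, w = compartment_mask.shape
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"centroid ({x}, {y}) outside the {w}x{h} raster")
    return COMPARTMENT_NAMES[int(compartment_mask[r, c])]


@dataclass
class QuantifyConfig:
    """Knobs of the per-cell quantification path."""

    background_quantile: float = 0.95
    dilation_px: int = 2
    #: per-marker positive thresholds Z; markers absent here fall back to
    #: Otsu on the per-cell mean-intensity distribution.
    thresholds: dict[str, float] = field(default_factory=dict)


def _otsu_threshold(values: np.ndarray) -> float:
    from skimage.filters import threshold_otsu

    v = values[values > 0]
    if v.size < 2 or np.ptp(v) == 0:
        return float(values.max() + 1.0)  # nothing separable: everything negative
    return float(threshold_otsu(v))


def quantify_scene(
    channels: dict[str, np.ndarray],
    nuclei: dict[str, np.ndarray],
    compartment_mask: np.ndarray,
    pixel_size_um: float,
    config: QuantifyConfig | None = None,
    section_id: str = "s1",
) -> pd.DataFrame:
    """Full per-cell quantification of one scene (both panels).

    ``channels[panel]`` is the (6, H, W) stack (page 0 DAPI), ``nuclei[panel]``
    the nucleus label raster of that panel's section.  Returns one row per
    cell with centroid, compartment, per-marker mean intensity and FS level,
    the phenotype call and (panel 2) the PD-L1 flag.
    """
    config = config or QuantifyConfig()
    rows = []
    for panel, stack in channels.items():
        markers = PANEL_MARKERS[panel]
        labels = np.asarray(nuclei[panel])
        ids = np.unique(labels)
        ids = ids[ids > 0]
        if ids.size == 0:
            continue
        # centroids from the label raster
        idx = np.flatnonzero(labels.ravel())
        lab = labels.ravel()[idx]
        rr, cc = np.unravel_index(idx, labels.shape)
        order = np.argsort(lab, kind="stable")
        lab, rr, cc = lab[order], rr[order], cc[order]
        counts = np.bincount(lab, minlength=int(ids.max()) + 1)
        cy = np.bincount(lab, weights=rr, minlength=counts.size)
        cx = np.bincount(lab, weights=cc, minlength=counts.size)

        intensity: dict[str, dict[int, float]] = {}
        for page, marker in enumerate(markers, start=1):
            channel = stack[page]
            fld = extract_fluorescence(channel, config.background_quantile, marker)
            intensity[marker] = intersect_cf_ccn(channel, fld, labels, config.dilation_px)

        z: dict[str, float] = {}
        for marker in markers:
            if marker in config.thresholds:
                z[marker] = config.thresholds[marker]
            else:
                z[marker] = _otsu_threshold(np.array([intensity[marker][int(k)] for k in ids]))

        for k in ids:
            k = int(k)
            x, y = cx[k] / counts[k], cy[k] / counts[k]
            fs = {m: assign_fs_level(intensity[m][k], z[m]) for m in markers}
            row = {
                "cell_id": k,
                "section_id": section_id,
                "panel": panel,
                "x_px": x,
                "y_px": y,
                "x_um": x * pixel_size_um,
                "y_um": y * pixel_size_um,
                "compartment": assign_compartment((x, y), compartment_mask),
                "phenotype": call_phenotype(fs, panel=panel),
            }
            for m in markers:
                row[f"intensity_{m}"] = intensity[m][k]
                row[f"fs_{m}"] = fs[m]
            if panel == PANEL2:
                row["pdl1_pos"] = fs["PD-L1"] != "neg"
            rows.append(row)
    return pd.DataFrame(rows)
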
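"""Delaunay spatial graph and the 30 within-panel pairwise distance features.

Cell nuclei of one section/panel are connected by Delaunay triangulation;
the connection length between two cells is their Euclidean distance in µm.
For two 5-class panels the schema of pairwise features is, per panel, the
C(5,2) = 10 distinct-class pairs plus the 5 same-class pairs, i.e. 30
features per patient.  Panels are never mixed: the two panels sit on
different physical serial sections, so cross-panel cell pairs do not exist.
When a patient has more than one section, features are averaged over the
sections where they are defined.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

from .panels import PDL1_FLAG, SPATIAL_CLASSES

__all__ = [
    "SpatialGraph",
    "build_delaunay",
    "pair_distance",
    "pair_key",
    "enumerate_pair_schema",
    "section_feature_vector",
    "patient_spatial_features",
    "spatial_feature_table",
    "brute_force_delaunay_edges",
]


@dataclass
class SpatialGraph:
    """Delaunay graph of one section's cells (positions in px, lengths in µm)."""

    points_px: np.ndarray                     # (n, 2) x, y
    classes: list[frozenset[str]]             # class memberships per node
    edges: list[tuple[int, int]]              # unordered index pairs, i < j
    lengths_um: np.ndarray                    # per edge
    class_universe: frozenset[str] = field(default_factory=frozenset)

    @property
    def n_nodes(self) -> int:
        return self.points_px.shape[0]


def build_delaunay(
    points_px: np.ndarray,
    classes: list[frozenset[str]] | list[set[str]] | list[str],
    pixel_size_um: float = 1.0,
    class_universe=None,
) -> SpatialGraph:
    """Delaunay triangulation of cell centroids.

    ``classes`` gives each cell's spatial class memberships (a bare string is
    treated as a singleton set).  Duplicate centroids are deduplicated with a
    warning (class sets merged); fewer than 3 distinct points, or all
    collinear, yield a degenerate edgeless graph with a warning.
    """
    pts = np.asarray(points_px, dtype=float).reshape(-1, 2)
    cls = [frozenset((c,)) if isinstance(c, str) else frozenset(c) for c in classes]
    if len(cls) != pts.shape[0]:
        raise ValueError("one class set per point required")
    uniq, inverse = np.unique(pts, axis=0, return_inverse=True)
    if uniq.shape[0] < pts.shape[0]:
        warnings.warn(
            f"{pts.shape[0] - uniq.shape[0]} duplicate centroids deduplicated",
            stacklevel=2,
        )
        merged: list[set[str]] = [set() for _ in range(uniq.shape[0])]
        for i, j in enumerate(inverse):
            merged[j] |= cls[i]
        pts = uniq
        cls = [frozenset(m) for m in merged]
    universe = frozenset(class_universe) if class_universe is not None else frozenset().union(*cls) if cls else frozenset()

    edges: list[tuple[int, int]] = []
    if pts.shape[0] >= 3:
        try:
            tri = Delaunay(pts)
            es = set()
            for simplex in tri.simplices:
                for a in range(3):
                    i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
                    es.add((min(i, j), max(i, j)))
            edges = sorted(es)
        except QhullError:
            warnings.warn("degenerate point set (collinear?): no Delaunay edges", stacklevel=2)
    else:
        warnings.warn("fewer than 3 points: no Delaunay edges", stacklevel=2)
    if edges:
        d = pts[[i for i, _ in edges]] - pts[[j for _, j in edges]]
        lengths = np.hypot(d[:, 0], d[:, 1]) * pixel_size_um
    else:
        lengths = np.empty(0)
    return SpatialGraph(points_px=pts, classes=cls, edges=edges,
                        lengths_um=lengths, class_universe=universe)


def brute_force_delaunay_edges(points: np.ndarray) -> set[tuple[int, int]]:
    """Delaunay edges by the empty-circumcircle definition (small point sets).

    An edge {i, j} is Delaunay iff some circle through i and j contains no
    other point; checked by scanning circumcircles of every triple plus the
    diametral circle of the pair.  Independent oracle for ``build_delaunay``
    on point sets in general position (<= 8 points).
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if n > 8:
        raise ValueError("oracle limited to <= 8 points")

    def circumcircle(a, b, c):
        ax, ay = a
        bx, by = b
        cx, cy = c
        d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        if abs(d) < 1e-12:
            return None
        ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
              + (cx**2 + cy**2) * (ay - by)) / d
        uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
              + (cx**2 + cy**2) * (bx - ax)) / d
        r = math.hypot(ax - ux, ay - uy)
        return (ux, uy), r

    def empty(center, r, exclude):
        eps = 1e-9 * max(r, 1.0)
        for k in range(n):
            if k in exclude:
                continue
            if math.hypot(pts[k, 0] - center[0], pts[k, 1] - center[1]) < r - eps:
                return False
        return True

    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            mid = ((pts[i, 0] + pts[j, 0]) / 2, (pts[i, 1] + pts[j, 1]) / 2)
            r = math.hypot(pts[i, 0] - pts[j, 0], pts[i, 1] - pts[j, 1]) / 2
            if empty(mid, r, {i, j}):
                edges.add((i, j))
                continue
            for k in range(n):
                if k in (i, j):
                    continue
                cc = circumcircle(pts[i], pts[j], pts[k])
                if cc and empty(cc[0], cc[1], {i, j, k}):
                    edges.add((i, j))
                    break
    return edges


def pair_distance(g: SpatialGraph, a: str, b: str, aggregate: str = "mean") -> float | None:
    """Mean (or median) length of Delaunay edges joining classes ``a`` and ``b``.

    For ``a == b`` both endpoints must carry the class.  Returns None when no
    qualifying edge exists; unknown class names raise.
    """
    for name in (a, b):
        if g.class_universe and name not in g.class_universe:
            raise ValueError(f"unknown phenotype/class {name!r}")
    vals = []
    for (i, j), length in zip(g.edges, g.lengths_um):
        ci, cj = g.classes[i], g.classes[j]
        if (a in ci and b in cj) or (b in ci and a in cj):
            vals.append(length)
    if not vals:
        return None
    if aggregate == "mean":
        return float(np.mean(vals))
    if aggregate == "median":
        return float(np.median(vals))
    raise ValueError(f"unknown aggregate {aggregate!r}")


def pair_key(panel: str, a: str, b: str) -> str:
    a, b = sorted((a, b))
    return f"{panel}:{a}--{b}"


def enumerate_pair_schema(panel_classes: dict[str, list[str]] | None = None) -> list[str]:
    """Canonical ordered pair keys: panel 1 pairs then panel 2, alphabetical.

    Two 5-class panels give 2 x (C(5,2) + 5) = 30 keys.  Other panel sizes
    are allowed; the generalised count 2 x (C(k,2) + k) is recomputed.
    """
    panel_classes = panel_classes or SPATIAL_CLASSES
    keys: list[str] = []
    for panel in sorted(panel_classes):
        names = sorted(panel_classes[panel])
        for i, a in enumerate(names):
            for b in names[i:]:
                keys.append(pair_key(panel, a, b))
    return keys


def section_feature_vector(
    graphs: dict[str, SpatialGraph],
    panel_classes: dict[str, list[str]] | None = None,
    aggregate: str = "mean",
) -> dict[str, float | None]:
    """The spatial feature vector of one section pair (both panels)."""
    panel_classes = panel_classes or SPATIAL_CLASSES
    out: dict[str, float | None] = {}
    for panel in sorted(panel_classes):
        names = sorted(panel_classes[panel])
        g = graphs.get(panel)
        for i, a in enumerate(names):
            for b in names[i:]:
                out[pair_key(panel, a, b)] = (
                    pair_distance(g, a, b, aggregate) if g is not None else None
                )
    return out


def patient_spatial_features(
    sections: list[dict[str, float | None]],
) -> dict[str, float | None]:
    """Average per-key over sections where the feature is defined."""
    if not sections:
        raise ValueError("at least one section is required")
    keys = sections[0].keys()
    out: dict[str, float | None] = {}
    for k in keys:
        vals = [s[k] for s in sections if s.get(k) is not None]
        out[k] = float(np.mean(vals)) if vals else None
    return out


def _cell_classes(row: pd.Series) -> frozenset[str]:
    cls = {row["phenotype"]}
    if bool(row.get("pdl1_pos", False)):
        cls.add(PDL1_FLAG)
    return frozenset(cls)


def spatial_feature_table(
    cells: pd.DataFrame,
    pixel_size_um: float | None = None,
    aggregate: str = "mean",
    patient_col: str = "patient_id",
) -> pd.DataFrame:
    """Patient x 30 spatial feature table from a per-cell table.

    ``cells`` must carry patient/section/panel ids, centroids and phenotype
    calls (the output of the quantification step).  Distances use ``x_um`` /
    ``y_um`` when present, else centroids in px scaled by ``pixel_size_um``.
    """
    rows = []
    for pid, pat in cells.groupby(patient_col, sort=True):
        per_section = []
        for _, sec in pat.groupby("section_id", sort=True):
            graphs = {}
            for panel, sub in sec.groupby("panel", sort=True):
                if "x_um" in sub.columns:
                    pts = sub[["x_um", "y_um"]].to_numpy()
                    scale = 1.0
                else:
                    pts = sub[["x_px", "y_px"]].to_numpy()
                    scale = pixel_size_um or 1.0
                cls = [_cell_classes(r) for _, r in sub.iterrows()]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    graphs[panel] = build_delaunay(
                        pts, cls, scale, class_universe=SPATIAL_CLASSES[panel]
                    )
            per_section.append(section_feature_vector(graphs, aggregate=aggregate))
        feats = patient_spatial_features(per_section)
        rows.append({patient_col: pid, **{k: (np.nan if v is None else v) for k, v in feats.items()}})
    cols = [patient_col] + enumerate_pair_schema()
    df = pd.DataFrame(rows)
    n_expected = len(enumerate_pair_schema())
    if len(df.columns) - 1 != n_expected:
        warnings.warn(f"emitted {len(df.columns) - 1} spatial features (schema expects {n_expected})")
    return df[cols]
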
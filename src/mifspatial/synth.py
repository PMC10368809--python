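"""Synthetic mIF scenes, cohorts and expression tables.

The generator emulates the data a two-panel multiplex-immunofluorescence
study produces: per patient, serial 4 µm sections stained with two 5-plex
panels plus DAPI, a tumour-nest / stroma compartment geometry shared by the
two sections, phenotype-dependent lognormal marker intensities, pairwise
spatial attraction/repulsion between phenotypes, stage-dependent
composition shifts and survival outcomes from a Weibull
proportional-hazards model.  Everything is deterministic under the seed.

Cell positions follow a hard-core Gibbs point process: positions are
initialised by dart throwing with a hard-core radius of one mean nucleus
diameter, then relaxed by Metropolis birth-death sweeps under a pairwise
potential ``U = -sum s_AB (1 - d/R)`` over interacting phenotype pairs
within range ``R`` (``s_AB > 0`` attracts, ``< 0`` repels).  Nuclei are
star-convex polygons (8 radial rays, radii jittered ±30%) rasterised
without overlap.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as draw_polygon

from .panels import (
    COMPARTMENT_NAMES,
    CONTENT_PHENOTYPES,
    NON_TISSUE,
    OTHER,
    PANEL_MARKERS,
    PANELS,
    PDL1_FLAG,
    PHENOTYPE_PANEL,
    POSITIVE_MARKERS,
    TUMOUR_NEST,
    TUMOUR_STROMA,
)
from .quantify import assign_fs_level

__all__ = [
    "MarkerIntensityModel",
    "SceneSpec",
    "PanelTruth",
    "GroundTruth",
    "PackingError",
    "generate_scene",
    "StageGroup",
    "SurvivalModel",
    "CohortSpec",
    "CohortResult",
    "generate_cohort",
    "generate_expression",
    "simulate_survival",
    "true_content_features",
]


class PackingError(RuntimeError):
    """Raised when the requested cell density cannot be packed."""


@dataclass
class MarkerIntensityModel:
    """Lognormal intensity model of one marker.

    Positive cells draw ``exp(N(mu_pos, sigma))``, negative cells
    ``exp(N(mu_neg, sigma))``; the truth FS level is the Z/2Z/3Z bin the
    draw lands in, so downstream binning can recover it exactly on
    noiseless scenes.
    """

    mu_pos: float = math.log(3.0)
    mu_neg: float = math.log(0.2)
    sigma: float = 0.4
    z: float = 1.0  # the generator's positive threshold for this marker


def _default_mixture() -> dict[str, dict[str, float]]:
    return {
        "panel1": {
            OTHER: 0.50, "CD4 T": 0.14, "Treg": 0.05,
            "activated T": 0.08, "B": 0.08, "neutrophil": 0.15,
        },
        "panel2": {
            OTHER: 0.50, "CD8 T": 0.15, "macrophage": 0.12,
            "M2 macrophage": 0.08, "CSC": 0.15,
        },
    }


@dataclass
class SceneSpec:
    """Parameters of one synthetic two-panel scene."""

    width_px: int = 1024
    height_px: int = 768
    pixel_size_um: float = 0.5
    n_cells: int = 500
    n_nests: int = 3
    nest_radius_px: tuple[float, float] = (60.0, 140.0)
    phenotype_mixture: dict[str, dict[str, float]] = field(default_factory=_default_mixture)
    #: (phenotypeA, phenotypeB, strength) attraction (>0) / repulsion (<0)
    interaction: list[tuple[str, str, float]] = field(default_factory=list)
    interaction_range_um: float = 30.0
    intensity_model: dict[str, MarkerIntensityModel] = field(default_factory=dict)
    noise_sd: float = 0.02
    blur_sd: float = 0.8
    nucleus_radius_px: float = 5.0
    radius_jitter: float = 0.3
    n_rays: int = 8
    n_sweeps: int = 50
    pdl1_positive_rate: float = 0.15
    #: when False, skip nucleus rasterisation and channel rendering and
    #: return point-level truth only (for cohort-scale feature studies)
    render: bool = True
    seed: int = 0

    @classmethod
    def full_resolution(cls, **kw) -> "SceneSpec":
        """Scene at the scanner's full-slide resolution (4028 x 3012 px)."""
        kw.setdefault("width_px", 4028)
        kw.setdefault("height_px", 3012)
        kw.setdefault("n_cells", 8000)
        return cls(**kw)

    def marker_model(self, marker: str) -> MarkerIntensityModel:
        return self.intensity_model.get(marker, MarkerIntensityModel())

    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("scene dimensions must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for panel in PANELS:
            mix = self.phenotype_mixture.get(panel, {})
            total = sum(mix.values())
            if mix and abs(total - 1.0) > 1e-9:
                raise ValueError(f"{panel} phenotype fractions sum to {total}, not 1")
            for pheno in mix:
                if pheno != OTHER and PHENOTYPE_PANEL.get(pheno) != panel:
                    raise ValueError(f"phenotype {pheno!r} does not belong to {panel}")
        for a, b, _ in self.interaction:
            for p in (a, b):
                if p != OTHER and p not in PHENOTYPE_PANEL:
                    raise ValueError(f"unknown phenotype {p!r} in interaction")
        max_r = self.nucleus_radius_px * (1 + self.radius_jitter)
        if self.n_cells * math.pi * max_r**2 >= self.width_px * self.height_px:
            raise ValueError("n_cells x max nucleus area exceeds the scene area")


@dataclass
class PanelTruth:
    """Ground truth of one panel's section."""

    nucleus_labels: np.ndarray
    centroids: dict[int, tuple[float, float]]  # id -> (x, y) px
    phenotype_of: dict[int, str]
    marker_truth: dict[int, dict[str, str]]  # id -> marker -> FS level
    marker_intensity: dict[int, dict[str, float]]
    pdl1_pos: set[int] = field(default_factory=set)


@dataclass
class GroundTruth:
    """Shared compartment geometry plus per-panel cell-level truth."""

    compartment_mask: np.ndarray
    panels: dict[str, PanelTruth]
    z_thresholds: dict[str, float]
    pixel_size_um: float


# ---------------------------------------------------------------------------
# geometry

def _compartment_mask(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height_px, spec.width_px
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    tissue = ((xx - cx) / (0.48 * w)) ** 2 + ((yy - cy) / (0.48 * h)) ** 2 <= 1.0
    mask = np.full((h, w), NON_TISSUE, dtype=np.uint8)
    mask[tissue] = TUMOUR_STROMA
    r_lo, r_hi = spec.nest_radius_px
    for _ in range(spec.n_nests):
        r = rng.uniform(r_lo, r_hi)
        ny = rng.uniform(cy - 0.35 * h, cy + 0.35 * h)
        nx = rng.uniform(cx - 0.35 * w, cx + 0.35 * w)
        nest = (xx - nx) ** 2 + (yy - ny) ** 2 <= r**2
        mask[nest & tissue] = TUMOUR_NEST
    return mask


class _Bins:
    """Uniform-grid neighbour index for 2-D points."""

    def __init__(self, size: float):
        self.size = size
        self.map: dict[tuple[int, int], set[int]] = defaultdict(set)

    def _key(self, p) -> tuple[int, int]:
        return (int(p[0] // self.size), int(p[1] // self.size))

    def add(self, i: int, p) -> None:
        self.map[self._key(p)].add(i)

    def remove(self, i: int, p) -> None:
        self.map[self._key(p)].discard(i)

    def near(self, p):
        kx, ky = self._key(p)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                yield from self.map.get((kx + dx, ky + dy), ())


def _sample_positions(
    spec: SceneSpec, tissue_px: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Hard-core dart throwing over the tissue region."""
    n = spec.n_cells
    hard = 2.0 * spec.nucleus_radius_px  # mean nucleus diameter
    bins = _Bins(max(hard, 1.0))
    pos = np.empty((n, 2))
    placed = 0
    attempts = 0
    max_attempts = 200 * max(n, 1)
    while placed < n:
        if attempts >= max_attempts:
            dens = n / (tissue_px.shape[0] or 1)
            raise PackingError(
                f"could not pack {n} cells with hard-core {hard:.1f} px "
                f"({dens:.4f} cells per tissue pixel) after {max_attempts} attempts"
            )
        attempts += 1
        k = rng.integers(tissue_px.shape[0])
        p = tissue_px[k] + rng.random(2)  # (x, y) with sub-pixel jitter
        ok = all(
            (p[0] - pos[j, 0]) ** 2 + (p[1] - pos[j, 1]) ** 2 >= hard**2
            for j in bins.near(p)
        )
        if ok:
            pos[placed] = p
            bins.add(placed, p)
            placed += 1
    return pos


def _metropolis(
    pos: np.ndarray,
    phenos: np.ndarray,
    spec: SceneSpec,
    tissue_px: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fixed-iteration Metropolis birth-death relaxation of the Gibbs process."""
    strengths: dict[frozenset, float] = {}
    for a, b, s in spec.interaction:
        if s != 0.0:
            strengths[frozenset((a, b))] = s
    if not strengths:
        return pos
    hard = 2.0 * spec.nucleus_radius_px
    rng_px = spec.interaction_range_um / spec.pixel_size_um
    bins = _Bins(max(hard, rng_px))
    n = pos.shape[0]
    for i in range(n):
        bins.add(i, pos[i])

    def local_energy(i: int, p) -> float:
        u = 0.0
        pi = phenos[i]
        for j in bins.near(p):
            if j == i:
                continue
            d2 = (p[0] - pos[j, 0]) ** 2 + (p[1] - pos[j, 1]) ** 2
            if d2 < hard**2:
                return math.inf
            s = strengths.get(frozenset((pi, phenos[j])))
            if s is not None and d2 < rng_px**2:
                u -= s * (1.0 - math.sqrt(d2) / rng_px)
        return u

    for _ in range(spec.n_sweeps):
        for i in rng.permutation(n):
            k = rng.integers(tissue_px.shape[0])
            cand = tissue_px[k] + rng.random(2)
            du = local_energy(i, cand) - local_energy(i, pos[i])
            if du <= 0 or rng.random() < math.exp(-du):
                bins.remove(i, pos[i])
                pos[i] = cand
                bins.add(i, pos[i])
    return pos


def _rasterise_nuclei(
    pos: np.ndarray, spec: SceneSpec, rng: np.random.Generator
) -> np.ndarray:
    h, w = spec.height_px, spec.width_px
    labels = np.zeros((h, w), dtype=np.int32)
    n_rays = spec.n_rays
    base = 2.0 * math.pi * np.arange(n_rays) / n_rays
    for i in range(pos.shape[0]):
        cx, cy = pos[i]
        ang = base + rng.uniform(0, 2 * math.pi / n_rays)
        rad = spec.nucleus_radius_px * (
            1.0 + rng.uniform(-spec.radius_jitter, spec.radius_jitter, n_rays)
        )
        rr, cc = draw_polygon(cy + rad * np.sin(ang), cx + rad * np.cos(ang), (h, w))
        free = labels[rr, cc] == 0
        labels[rr[free], cc[free]] = i + 1
        r0, c0 = int(round(cy)), int(round(cx))
        if 0 <= r0 < h and 0 <= c0 < w and labels[r0, c0] == 0:
            labels[r0, c0] = i + 1
    return labels


def _panel_truth(
    spec: SceneSpec, panel: str, tissue_px: np.ndarray, rng: np.random.Generator
) -> PanelTruth:
    mix = spec.phenotype_mixture[panel]
    names = sorted(mix)  # stable draw order
    pos = _sample_positions(spec, tissue_px, rng)
    phenos = np.array(names, dtype=object)[
        rng.choice(len(names), size=spec.n_cells, p=[mix[k] for k in names])
    ] if spec.n_cells else np.empty(0, dtype=object)
    panel_inter = [
        (a, b, s) for a, b, s in spec.interaction
        if PHENOTYPE_PANEL.get(a, panel if a == OTHER else None) == panel
        and PHENOTYPE_PANEL.get(b, panel if b == OTHER else None) == panel
    ]
    pos = _metropolis(pos, phenos, replace(spec, interaction=panel_inter), tissue_px, rng)
    if spec.render:
        labels = _rasterise_nuclei(pos, spec, rng)
    else:
        labels = np.zeros((spec.height_px, spec.width_px), dtype=np.int32)

    pdl1 = set()
    if panel == "panel2" and spec.n_cells:
        flags = rng.random(spec.n_cells) < spec.pdl1_positive_rate
        pdl1 = {i + 1 for i in range(spec.n_cells) if flags[i]}

    marker_truth: dict[int, dict[str, str]] = {}
    marker_intensity: dict[int, dict[str, float]] = {}
    for i in range(spec.n_cells):
        cid = i + 1
        pheno = phenos[i]
        positive = set(POSITIVE_MARKERS[pheno])
        if cid in pdl1:
            positive.add("PD-L1")
        truth_i: dict[str, str] = {}
        inten_i: dict[str, float] = {}
        for marker in PANEL_MARKERS[panel]:
            m = spec.marker_model(marker)
            mu = m.mu_pos if marker in positive else m.mu_neg
            value = float(np.exp(rng.normal(mu, m.sigma)))
            inten_i[marker] = value
            truth_i[marker] = assign_fs_level(value, m.z)
        marker_truth[cid] = truth_i
        marker_intensity[cid] = inten_i

    return PanelTruth(
        nucleus_labels=labels,
        centroids={i + 1: (float(pos[i, 0]), float(pos[i, 1])) for i in range(spec.n_cells)},
        phenotype_of={i + 1: str(phenos[i]) for i in range(spec.n_cells)},
        marker_truth=marker_truth,
        marker_intensity=marker_intensity,
        pdl1_pos=pdl1,
    )


def _render_panel(
    spec: SceneSpec, panel: str, truth: PanelTruth, rng: np.random.Generator
) -> np.ndarray:
    h, w = spec.height_px, spec.width_px
    markers = PANEL_MARKERS[panel]
    stack = np.zeros((1 + len(markers), h, w), dtype=np.float32)
    labels = truth.nucleus_labels
    n = len(truth.centroids)
    if n:
        dapi_amp = 100.0 * rng.uniform(0.8, 1.2, n + 1)
        stack[0] = np.where(labels > 0, dapi_amp[np.minimum(labels, n)], 0.0)
        for page, marker in enumerate(markers, start=1):
            lut = np.zeros(n + 1, dtype=np.float32)
            for cid, inten in truth.marker_intensity.items():
                lut[cid] = inten[marker]
            stack[page] = lut[labels]
    if spec.blur_sd > 0:
        for page in range(stack.shape[0]):
            stack[page] = gaussian_filter(stack[page], spec.blur_sd)
    if spec.noise_sd > 0:
        stack += rng.normal(0.0, spec.noise_sd, stack.shape).astype(np.float32)
        np.clip(stack, 0.0, None, out=stack)
    return stack


def generate_scene(spec: SceneSpec) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """One two-panel scene: serial sections sharing compartment geometry.

    Returns ``(channels, truth)`` where ``channels[panel]`` is a
    ``(6, H, W)`` float stack (page 0 DAPI, pages 1-5 the panel's markers)
    and ``truth`` carries the nucleus labels, phenotypes, marker FS levels
    and the compartment mask.  The two panels resample cell positions
    independently: serial sections are different physical slices.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    mask = _compartment_mask(spec, rng)
    ys, xs = np.nonzero(mask != NON_TISSUE)
    tissue_px = np.column_stack([xs, ys]).astype(float)

    panels: dict[str, PanelTruth] = {}
    channels: dict[str, np.ndarray] = {}
    for panel in PANELS:
        truth = _panel_truth(spec, panel, tissue_px, rng)
        panels[panel] = truth
        if spec.render:
            channels[panel] = _render_panel(spec, panel, truth, rng)
        else:
            channels[panel] = np.empty((1 + len(PANEL_MARKERS[panel]), 0, 0), dtype=np.float32)

    z = {m: spec.marker_model(m).z for p in PANELS for m in PANEL_MARKERS[p]}
    return channels, GroundTruth(
        compartment_mask=mask, panels=panels, z_thresholds=z,
        pixel_size_um=spec.pixel_size_um,
    )


def true_content_features(truth: GroundTruth) -> dict[str, float]:
    """True composition percentages ``pct_<phenotype>_<TN|TS>`` of a scene.

    Denominators are the panel's cells in the compartment; the PD-L1+ class
    counts flagged panel-2 cells.  ``other`` is pooled per panel and keyed by
    its own panel (panel 1); compartments with no cells yield NaN.
    """
    out: dict[str, float] = {}
    counts: dict[tuple[str, str], float] = defaultdict(float)
    totals: dict[tuple[str, str], float] = defaultdict(float)
    for panel, pt in truth.panels.items():
        for cid, pheno in pt.phenotype_of.items():
            x, y = pt.centroids[cid]
            comp = COMPARTMENT_NAMES[int(truth.compartment_mask[int(y), int(x)])]
            if comp == "excluded":
                continue
            totals[(panel, comp)] += 1
            counts[(pheno if pheno != OTHER else f"{OTHER}:{panel}", comp)] += 1
            if cid in pt.pdl1_pos:
                counts[(PDL1_FLAG, comp)] += 1
    for pheno in CONTENT_PHENOTYPES:
        panel = PHENOTYPE_PANEL.get(pheno, "panel1")
        key = f"{OTHER}:panel1" if pheno == OTHER else pheno
        for comp in ("TN", "TS"):
            tot = totals[(panel, comp)]
            out[f"pct_{pheno}_{comp}"] = 100.0 * counts[(key, comp)] / tot if tot else float("nan")
    return out


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class StageGroup:
    """Prevalence and composition shift of one stage group."""

    prevalence: float
    #: additive shifts to the phenotype mixture, renormalised after applying
    mixture_shift: dict[str, dict[str, float]] = field(default_factory=dict)


def _default_stage_model() -> dict[str, StageGroup]:
    # Mid-to-late disease: stromal neutrophils and CD133+ CSCs recede,
    # CD163+ M2 macrophages expand.
    return {
        "IA-IIA": StageGroup(prevalence=0.693),
        "IIB-IIIB": StageGroup(
            prevalence=0.307,
            mixture_shift={
                "panel1": {"neutrophil": -0.06, OTHER: +0.06},
                "panel2": {"M2 macrophage": +0.05, "CSC": -0.05},
            },
        ),
    }


@dataclass
class SurvivalModel:
    """Weibull proportional-hazards model for event times (days)."""

    baseline_shape: float = 1.2
    baseline_scale_days: float = 1500.0
    #: coefficient per feature/covariate name (e.g. "pct_neutrophil_TS", "age")
    beta: dict[str, float] = field(default_factory=dict)

    def baseline_survival(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.exp(-((t / self.baseline_scale_days) ** self.baseline_shape))


@dataclass
class CohortSpec:
    """Parameters of a synthetic patient cohort."""

    n_patients: int = 50
    sections_per_patient: int = 1
    scene: SceneSpec = field(default_factory=SceneSpec)
    stage_model: dict[str, StageGroup] = field(default_factory=_default_stage_model)
    survival_model: SurvivalModel = field(default_factory=SurvivalModel)
    censoring_rate: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.sections_per_patient < 1:
            raise ValueError("sections_per_patient must be >= 1")
        total = sum(g.prevalence for g in self.stage_model.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"stage prevalences sum to {total}, not 1")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValueError("censoring_rate must be in [0, 1]")


@dataclass
class PatientScenes:
    patient_id: str
    stage_group: str
    sections: list[tuple[dict[str, np.ndarray], GroundTruth]]


@dataclass
class CohortResult:
    patients: list[PatientScenes]
    clinical: pd.DataFrame       # one row per patient incl. time/event
    true_features: pd.DataFrame  # realised composition features per patient


def _shifted_mixture(
    base: dict[str, dict[str, float]], shift: dict[str, dict[str, float]]
) -> dict[str, dict[str, float]]:
    out = {}
    for panel, mix in base.items():
        m = dict(mix)
        for pheno, delta in shift.get(panel, {}).items():
            m[pheno] = m.get(pheno, 0.0) + delta
        clipped = {k: max(v, 0.0) for k, v in m.items()}
        total = sum(clipped.values())
        out[panel] = {k: v / total for k, v in clipped.items()}
    return out


def simulate_survival(
    lp: np.ndarray,
    model: SurvivalModel,
    censoring_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Weibull PH event times under linear predictor ``lp``, with censoring.

    Censoring mixes an administrative horizon with uniform random censoring
    ``C ~ U(0, u)``; ``u`` is solved so the expected censored fraction equals
    ``censoring_rate`` for the realised event-time sample.
    """
    lp = np.asarray(lp, dtype=float)
    n = lp.shape[0]
    u = rng.random(n)
    t = model.baseline_scale_days * (-np.log(u) / np.exp(lp)) ** (1.0 / model.baseline_shape)
    t = np.maximum(t, 1e-6)
    if censoring_rate <= 0.0:
        return t, np.ones(n, dtype=int)
    if censoring_rate >= 1.0:
        return rng.uniform(0.0, t), np.zeros(n, dtype=int)

    from scipy.optimize import brentq

    def censored_frac(uu: float) -> float:
        return float(np.mean(np.minimum(t / uu, 1.0)))

    lo, hi = 1e-9, float(t.max()) * 1e4
    target = censoring_rate
    if censored_frac(hi) > target:   # heavy tail: essentially uncensorable below target
        umax = hi
    else:
        umax = brentq(lambda uu: censored_frac(uu) - target, lo, hi)
    c = rng.uniform(0.0, umax, n)
    event = (t <= c).astype(int)
    time = np.minimum(t, c)
    return np.maximum(time, 1e-6), event


def generate_cohort(spec: CohortSpec) -> CohortResult:
    """Scenes plus a clinical table for a synthetic cohort.

    Each patient receives ``sections_per_patient`` two-panel scene pairs with
    a stage-shifted phenotype mixture, covariates (sex, age, T stage, VPI,
    VTE), and a survival time and event drawn from the Weibull
    proportional-hazards model on the patient's realised feature values.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    groups = sorted(spec.stage_model)
    prev = np.array([spec.stage_model[g].prevalence for g in groups])

    patients: list[PatientScenes] = []
    clin_rows = []
    feat_rows = []
    for i in range(spec.n_patients):
        pid = f"P{i + 1:04d}"
        stage = groups[int(rng.choice(len(groups), p=prev))]
        mixture = _shifted_mixture(
            spec.scene.phenotype_mixture, spec.stage_model[stage].mixture_shift
        )
        sections = []
        feats_per_section = []
        for s in range(spec.sections_per_patient):
            sc = replace(
                spec.scene,
                phenotype_mixture=mixture,
                seed=int(rng.integers(2**31)),
            )
            channels, truth = generate_scene(sc)
            sections.append((channels, truth))
            feats_per_section.append(true_content_features(truth))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN sections
            feats = {
                k: float(np.nanmean([f[k] for f in feats_per_section]))
                for k in feats_per_section[0]
            }
        covs = {
            "sex": int(rng.random() < 0.585),  # 1 = male
            "age": float(np.clip(rng.normal(62.0, 9.0), 30, 88)),
            "t_stage": int(rng.choice([1, 2, 3, 4], p=[0.35, 0.40, 0.18, 0.07])),
            "vpi": int(rng.choice([0, 1, 2], p=[0.38, 0.55, 0.07])),
            "vte": int(rng.random() < (0.30 if stage == groups[0] else 0.55)),
        }
        patients.append(PatientScenes(pid, stage, sections))
        feat_rows.append({"patient_id": pid, **feats})
        clin_rows.append({"patient_id": pid, "stage_group": stage, **covs, **feats})

    clinical = pd.DataFrame(clin_rows)
    beta = spec.survival_model.beta
    missing = [k for k in beta if k not in clinical.columns]
    if missing:
        raise ValueError(
            f"survival_model.beta references features not produced by the cohort: {missing}"
        )
    if spec.n_patients:
        lp = np.zeros(spec.n_patients)
        for name, b in beta.items():
            x = clinical[name].to_numpy(dtype=float)
            x = np.where(np.isnan(x), np.nanmean(x) if np.isfinite(np.nanmean(x)) else 0.0, x)
            lp += b * x
        time, event = simulate_survival(lp, spec.survival_model, spec.censoring_rate, rng)
        clinical["time_days"] = time
        clinical["event"] = event
    else:
        clinical["time_days"] = pd.Series(dtype=float)
        clinical["event"] = pd.Series(dtype=int)

    drop = [c for c in clinical.columns if c.startswith("pct_")]
    return CohortResult(
        patients=patients,
        clinical=clinical.drop(columns=drop),
        true_features=pd.DataFrame(feat_rows),
    )


# ---------------------------------------------------------------------------
# expression fixture

def generate_expression(n: int, score_effect: float, seed: int) -> pd.DataFrame:
    """Expression table for the six risk-score genes with linked survival.

    Per-sample lognormal expression (log-scale mean 1.0, sd 0.25) for CTSZ,
    PLAUR, NME2, NPM1, EIF3E and PPIA; the hazard is log-linear in the true
    six-gene score with coefficient ``score_effect``.  Columns: sample_id,
    the six genes, time_days, event and true_score.
    """
    if n < 2:
        raise ValueError(f"need at least 2 samples, got {n}")
    from .ndegs import NDEGS_COEFFICIENTS, ndegs_score

    rng = np.random.default_rng(seed)
    genes = list(NDEGS_COEFFICIENTS)
    expr = pd.DataFrame(
        np.exp(rng.normal(1.0, 0.25, size=(n, len(genes)))), columns=genes
    )
    score = ndegs_score(expr)
    lp = score_effect * (score.to_numpy() - float(score.mean()))
    model = SurvivalModel(baseline_shape=1.2, baseline_scale_days=2000.0)
    time, event = simulate_survival(lp, model, censoring_rate=0.3, rng=rng)
    out = expr.copy()
    out.insert(0, "sample_id", [f"S{i + 1:04d}" for i in range(n)])
    out["time_days"] = time
    out["event"] = event
    out["true_score"] = score.to_numpy()
    return out
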
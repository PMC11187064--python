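"""Synthetic patches and cohorts with exactly known ground truth.

Image side: patches of non-overlapping elliptical "nuclei" with per-class
CIELAB fill colors, rasterized with a hard pixel-center-inside rule (no
anti-aliasing) so that area/solidity oracles are exact, on a white H&E-like
background.  Every ellipse has closed-form feature values
(:func:`analytic_truth`), so the extraction pipeline can be tested against
analytic truth rather than against itself.

Cohort side: slide-level nuHIF tables with planted statistical structure —
per-group mean shifts, a linear aneuploidy–feature relationship, a
proportional-hazards survival signal tied to one feature (exponential
baseline, independent uniform censoring), and an expression matrix with a
planted block of rank-correlated genes (Gaussian copula) plus a gene-set
collection containing the planted set.  Every generator is a pure function
of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtri
from skimage import color as skcolor
from skimage.morphology import dilation, disk, erosion

from . import schema
from .schema import nuhif_name

__all__ = [
    "EllipseSpec",
    "SyntheticPatch",
    "CohortSimParams",
    "PlacementError",
    "sample_ellipses",
    "rasterize",
    "render_rgb",
    "analytic_truth",
    "make_patch",
    "simulate_cohort",
    "perturb_labels",
]

#: Default per-class nucleus fill colors (CIELAB), loosely hematoxylin-like:
#: darker/bluer for lymphocytes, lighter for fibroblasts.
DEFAULT_CLASS_COLORS: dict[str, tuple[float, float, float]] = {
    "CANCER": (45.0, 25.0, -35.0),
    "FIBROBLAST": (55.0, 15.0, -25.0),
    "LYMPHOCYTE": (35.0, 30.0, -45.0),
    "MACROPHAGE": (60.0, 10.0, -20.0),
    "PLASMA": (50.0, 20.0, -30.0),
}

#: Near-white background typical of H&E glass.
DEFAULT_BACKGROUND_LAB = (95.0, 0.0, 0.0)

#: Median physical pixel size of the emulated slide scans (µm/px).
DEFAULT_MPP = 0.25


class PlacementError(RuntimeError):
    """Rejection sampling could not place the requested number of ellipses."""


@dataclass(frozen=True)
class EllipseSpec:
    """Ground-truth nucleus: an ellipse with known geometry and fill color."""

    id: int
    center: tuple[float, float]  # (row, col), pixels
    a: float  # semi-major, px
    b: float  # semi-minor, px
    angle: float  # radians CCW from the row axis
    cell_class: str
    fill_lab: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.id <= 0:
            raise ValueError("instance id must be a positive integer")
        if not (self.a >= self.b > 0):
            raise ValueError("require a >= b > 0")
        L, A, B = self.fill_lab
        if not (0 <= L <= 100 and -128 <= A <= 127 and -128 <= B <= 127):
            raise ValueError("fill_lab outside CIELAB gamut bounds")


@dataclass
class SyntheticPatch:
    """A rendered patch bundled with its ground truth."""

    rgb: np.ndarray
    labels: np.ndarray
    mpp: float
    specs: list[EllipseSpec]
    truth_features: pd.DataFrame


def _inside(spec: EllipseSpec, rr: np.ndarray, cc: np.ndarray) -> np.ndarray:
    """Strict pixel-center-inside-ellipse test."""
    dr = rr - spec.center[0]
    dc = cc - spec.center[1]
    x = dr * np.cos(spec.angle) + dc * np.sin(spec.angle)
    y = -dr * np.sin(spec.angle) + dc * np.cos(spec.angle)
    return (x / spec.a) ** 2 + (y / spec.b) ** 2 < 1.0


def _footprint(spec: EllipseSpec, canvas: tuple[int, int]) -> np.ndarray:
    rr, cc = np.mgrid[0 : canvas[0], 0 : canvas[1]]
    return _inside(spec, rr, cc)


def sample_ellipses(
    n: int,
    size_dist: tuple[float, float] = (14.0, 2.5),
    class_mix: Mapping[str, float] | None = None,
    canvas: tuple[int, int] = (512, 512),
    seed: int = 0,
    *,
    min_semiaxis: float = 10.0,
    class_colors: Mapping[str, tuple[float, float, float]] | None = None,
    max_attempts: int = 200,
) -> list[EllipseSpec]:
    """Place up to ``n`` non-overlapping ellipses by rejection sampling.

    Semi-axes are drawn from N(mean, sd) truncated below at
    ``min_semiaxis``; of the two draws the larger becomes the semi-major
    axis.  Rasterized footprints plus a 1-px margin must be pairwise
    disjoint and lie fully inside the canvas.  Deterministic given ``seed``.

    Raises
    ------
    PlacementError
        If fewer than ``n`` ellipses fit within ``max_attempts`` tries per
        ellipse.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    mean, sd = size_dist
    if mean <= 0:
        raise ValueError("size mean must be positive")
    if class_mix is None:
        class_mix = {"CANCER": 0.5, "FIBROBLAST": 0.3, "LYMPHOCYTE": 0.2}
    classes = list(class_mix)
    probs = np.array([class_mix[c] for c in classes], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("class_mix probabilities must sum to 1")
    colors = dict(DEFAULT_CLASS_COLORS)
    if class_colors:
        colors.update(class_colors)

    rng = np.random.default_rng(seed)
    H, W = canvas
    occupied = np.zeros((H, W), dtype=bool)
    specs: list[EllipseSpec] = []
    margin = disk(1)
    for k in range(1, n + 1):
        for _ in range(max_attempts):
            draws = np.maximum(rng.normal(mean, sd, size=2), min_semiaxis)
            a, b = float(draws.max()), float(draws.min())
            angle = float(rng.uniform(0, np.pi))
            # extent bound: the ellipse lies within a disk of radius a
            pad = a + 2.0
            if 2 * pad >= min(H, W):
                continue
            center = (
                float(rng.uniform(pad, H - pad)),
                float(rng.uniform(pad, W - pad)),
            )
            cls = classes[int(rng.choice(len(classes), p=probs))]
            cand = EllipseSpec(
                id=k, center=center, a=a, b=b, angle=angle,
                cell_class=cls, fill_lab=colors.get(cls, (50.0, 20.0, -30.0)),
            )
            fp = _footprint(cand, canvas)
            if not fp.any():
                continue
            fp_margin = dilation(fp, margin)
            if not (occupied & fp_margin).any():
                occupied |= fp_margin
                specs.append(cand)
                break
        else:
            raise PlacementError(
                f"could only place {len(specs)} of {n} ellipses on a "
                f"{H}x{W} canvas after {max_attempts} attempts each; "
                "reduce n or the nucleus size"
            )
    return specs


def rasterize(
    specs: Sequence[EllipseSpec], canvas: tuple[int, int]
) -> np.ndarray:
    """Hard binary rasterization: pixel (r, c) gets label k iff its center
    lies strictly inside ellipse k; background 0.

    Raises if two specs claim the same pixel (the generator's
    non-overlap contract is violated).
    """
    H, W = canvas
    labels = np.zeros((H, W), dtype=np.uint16)
    rr, cc = np.mgrid[0:H, 0:W]
    for spec in specs:
        m = _inside(spec, rr, cc)
        if (labels[m] != 0).any():
            raise ValueError(
                f"ellipse {spec.id} overlaps a previously rasterized instance"
            )
        labels[m] = spec.id
    return labels


def lab_to_rgb8(lab: tuple[float, float, float]) -> np.ndarray:
    """CIELAB triple to an 8-bit sRGB pixel (rounded, clipped)."""
    rgb = skcolor.lab2rgb(np.asarray(lab, dtype=float).reshape(1, 1, 3))
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8).reshape(3)


def render_rgb(
    labels: np.ndarray,
    specs: Sequence[EllipseSpec],
    background_lab: tuple[float, float, float] = DEFAULT_BACKGROUND_LAB,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Flat-fill rendering: instance pixels take the spec's fill color
    (LAB→sRGB), background the background color, plus optional i.i.d.
    per-channel Gaussian noise, clipped to [0, 255]."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    H, W = labels.shape
    img = np.empty((H, W, 3), dtype=float)
    img[:] = lab_to_rgb8(background_lab)
    for spec in specs:
        img[labels == spec.id] = lab_to_rgb8(spec.fill_lab)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _ramanujan_perimeter(a: float, b: float) -> float:
    """Ramanujan's second approximation to the ellipse perimeter."""
    h = ((a - b) / (a + b)) ** 2
    return np.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + np.sqrt(4.0 - 3.0 * h)))


def analytic_truth(spec: EllipseSpec, mpp: float) -> dict[str, float]:
    """Closed-form feature values of an ellipse (noise-free reference).

    Shape: area = πab·mpp², axis lengths 2a/2b·mpp, Ramanujan perimeter,
    eccentricity sqrt(1 − (b/a)²), circularity 4π·area/perimeter²,
    solidity 1 (ellipses are convex).  Color means follow from the
    8-bit-quantized rendering of ``fill_lab``; color SDs are 0.
    """
    if mpp <= 0:
        raise ValueError("mpp must be positive")
    area = np.pi * spec.a * spec.b * mpp**2
    perim = _ramanujan_perimeter(spec.a, spec.b) * mpp
    rgb = lab_to_rgb8(spec.fill_lab).reshape(1, 1, 3)
    gray = float(rgb.astype(float).reshape(3) @ np.array([0.299, 0.587, 0.114]))
    sat = float(skcolor.rgb2hsv(rgb)[0, 0, 1])
    lab_rt = skcolor.rgb2lab(rgb)[0, 0]
    return {
        "area": float(area),
        "perimeter": float(perim),
        "major_axis_length": 2.0 * spec.a * mpp,
        "minor_axis_length": 2.0 * spec.b * mpp,
        "eccentricity": float(np.sqrt(1.0 - (spec.b / spec.a) ** 2)),
        "circularity": float(4.0 * np.pi * area / perim**2),
        "solidity": 1.0,
        "gray_mean": gray,
        "gray_sd": 0.0,
        "sat_mean": sat,
        "sat_sd": 0.0,
        "lab_a_mean": float(lab_rt[1]),
        "lab_a_sd": 0.0,
        "lab_b_mean": float(lab_rt[2]),
        "lab_b_sd": 0.0,
    }


def make_patch(
    n_nuclei: int = 50,
    canvas: tuple[int, int] = (512, 512),
    mpp: float = DEFAULT_MPP,
    noise_sd: float = 0.0,
    seed: int = 0,
    **sample_kwargs,
) -> SyntheticPatch:
    """Sample, rasterize, and render one patch with its analytic truth."""
    specs = sample_ellipses(n_nuclei, canvas=canvas, seed=seed, **sample_kwargs)
    labels = rasterize(specs, canvas)
    rgb = render_rgb(labels, specs, noise_sd=noise_sd, seed=seed + 1)
    truth = pd.DataFrame(
        [{"nucleus_id": s.id, "cell_class": s.cell_class,
          **analytic_truth(s, mpp)} for s in specs]
    )
    return SyntheticPatch(rgb=rgb, labels=labels, mpp=mpp, specs=specs,
                          truth_features=truth)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortSimParams:
    """Parameters of the planted-structure cohort generator.

    Defaults encode the study conditions used throughout the test suite:
    three cancer-type groups, 30 nuHIFs per cell class for three classes,
    unit feature noise, exponential survival with ~20% uniform censoring,
    and a 100-gene planted expression block at Spearman magnitude 0.4 out
    of 5,000 genes.
    """

    n_slides_per_group: int = 400
    group_labels: tuple[str, ...] = ("BRCA", "LUAD", "PRAD")
    #: group -> {nuHIF column -> mean shift in SD units}
    effect_sizes: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    classes: tuple[str, ...] = ("CANCER", "FIBROBLAST", "LYMPHOCYTE")
    noise_sd: float = 1.0
    aneuploidy_feature: str = nuhif_name("STD", "CANCER", "area")
    aneuploidy_beta: float = 0.0
    wgd_beta: float = 0.0
    survival_feature: str = nuhif_name("MEAN", "FIBROBLAST", "area")
    survival_beta: float = 0.0
    baseline_hazard: float = 0.01  # events per month
    censoring_rate: float = 0.2
    #: subtype labels assigned uniformly; shifts planted via subtype_effects
    subtype_labels: tuple[str, ...] = ("LUMA", "LUMB", "BASAL")
    subtype_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    n_genes: int = 5000
    n_planted_genes: int = 100
    planted_gene_rho: float = 0.4
    n_decoy_sets: int = 20
    decoy_set_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slides_per_group <= 0:
            raise ValueError("n_slides_per_group must be positive")
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring_rate must be in [0, 1)")
        if abs(self.planted_gene_rho) > 1:
            raise ValueError("|planted_gene_rho| must be <= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.n_genes < self.n_planted_genes:
            raise ValueError("n_planted_genes cannot exceed n_genes")


def _uniform_censor_bound(lam: float, target_rate: float) -> float:
    """Upper bound b of U(0, b) censoring achieving the target censoring
    fraction against Exp(lam) event times: P(C < T) = (1 − e^{−λb})/(λb)."""
    f = lambda b: (1.0 - np.exp(-lam * b)) / (lam * b) - target_rate
    return brentq(f, 1e-9 / lam, 1e9 / lam)


def simulate_cohort(
    params: CohortSimParams,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]]]:
    """Simulate (cohort table, expression matrix, gene-set collection).

    Returns
    -------
    cohort : DataFrame
        One row per slide: ``slide_id``, ``cancer_type``,
        ``molecular_subtype``, ``aneuploidy_score``, ``hrd_score``,
        ``wgd_count``, ``age``, ``stage``, ``surv_time`` (months),
        ``surv_event``, plus 30 nuHIF columns per cell class.
    expression : DataFrame
        Samples × genes, index matching ``slide_id``.  The first
        ``n_planted_genes`` genes share a Gaussian-copula rank correlation
        of magnitude ``planted_gene_rho`` with the designated survival
        feature; the rest are independent.
    gene_sets : dict
        ``{"PLANTED_SET": [...], "DECOY_SET_01": [...], ...}``.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n_total = p.n_slides_per_group * len(p.group_labels)
    nuhif_cols = schema.nuhif_columns(p.classes)

    groups = np.repeat(list(p.group_labels), p.n_slides_per_group)
    X = rng.normal(0.0, p.noise_sd, size=(n_total, len(nuhif_cols)))
    cohort = pd.DataFrame(X, columns=nuhif_cols)
    for g, shifts in p.effect_sizes.items():
        sel = groups == g
        for col, shift in shifts.items():
            cohort.loc[sel, col] += shift * p.noise_sd

    subtypes = rng.choice(list(p.subtype_labels), size=n_total)
    for st, shifts in p.subtype_effects.items():
        sel = subtypes == st
        for col, shift in shifts.items():
            cohort.loc[sel, col] += shift * p.noise_sd

    def resolve(col: str) -> str:
        # designated features fall back to the first simulated class when
        # their class is outside the chosen vocabulary
        if col in cohort.columns:
            return col
        stat, _, feat = schema.parse_nuhif_name(col)
        return schema.nuhif_name(stat, p.classes[0], feat)

    def z(col: str) -> np.ndarray:
        v = cohort[resolve(col)].to_numpy()
        return (v - v.mean()) / v.std(ddof=0)

    z_aneu = z(p.aneuploidy_feature)
    aneuploidy = 12.0 + 5.0 * (p.aneuploidy_beta * z_aneu + rng.normal(size=n_total))
    hrd = 20.0 + 8.0 * (p.aneuploidy_beta * z_aneu + rng.normal(size=n_total))
    # WGD probability increases in the same atypia feature
    p_wgd = 1.0 / (1.0 + np.exp(-(p.wgd_beta * z_aneu - 0.5)))
    has_wgd = rng.random(n_total) < p_wgd
    second = rng.random(n_total) < 0.15
    wgd_count = np.where(has_wgd, np.where(second, 2, 1), 0)

    z_surv = z(p.survival_feature)
    hazard = p.baseline_hazard * np.exp(p.survival_beta * z_surv)
    t_event = rng.exponential(1.0 / hazard)
    if p.censoring_rate > 0:
        b = _uniform_censor_bound(p.baseline_hazard, p.censoring_rate)
        t_cens = rng.uniform(0.0, b, size=n_total)
        surv_time = np.minimum(t_event, t_cens)
        surv_event = (t_event <= t_cens).astype(int)
    else:
        surv_time = t_event
        surv_event = np.ones(n_total, dtype=int)

    cohort.insert(0, "slide_id", [f"SLIDE_{i:04d}" for i in range(n_total)])
    cohort["cancer_type"] = groups
    cohort["molecular_subtype"] = subtypes
    cohort["aneuploidy_score"] = np.maximum(0, np.rint(aneuploidy)).astype(int)
    cohort["hrd_score"] = np.maximum(0.0, hrd)
    cohort["wgd_count"] = wgd_count
    cohort["age"] = np.clip(np.rint(rng.normal(60, 11, n_total)), 25, 95).astype(int)
    cohort["stage"] = rng.choice([1, 2, 3, 4], size=n_total, p=[0.2, 0.45, 0.25, 0.1])
    cohort["surv_time"] = np.maximum(surv_time, 1e-3)
    cohort["surv_event"] = surv_event

    # Expression: Gaussian copula on the survival feature's ranks.  The
    # Pearson correlation of latent normals that yields a target Spearman
    # rho_s is r = 2 sin(pi * rho_s / 6).
    ranks = cohort[resolve(p.survival_feature)].rank(method="average").to_numpy()
    z_lat = ndtri((ranks - 0.5) / n_total)
    r_lat = 2.0 * np.sin(np.pi * p.planted_gene_rho / 6.0)
    genes = [f"GENE_{i:05d}" for i in range(p.n_genes)]
    E = rng.normal(size=(n_total, p.n_genes))
    E[:, : p.n_planted_genes] = (
        r_lat * z_lat[:, None]
        + np.sqrt(1.0 - r_lat**2) * E[:, : p.n_planted_genes]
    )
    expression = pd.DataFrame(E, columns=genes, index=cohort["slide_id"].to_numpy())
    expression.index.name = "slide_id"

    gene_sets: dict[str, list[str]] = {"PLANTED_SET": genes[: p.n_planted_genes]}
    for j in range(p.n_decoy_sets):
        members = rng.choice(genes, size=min(p.decoy_set_size, p.n_genes),
                             replace=False)
        gene_sets[f"DECOY_SET_{j + 1:02d}"] = sorted(members.tolist())
    return cohort, expression, gene_sets


# ---------------------------------------------------------------------------
# Label-map perturbations (test harness for segmentation metrics)
# ---------------------------------------------------------------------------

PERTURB_MODES = ("erode", "dilate", "drop_fraction", "merge_pairs", "split")


def perturb_labels(
    labels: np.ndarray, mode: str, magnitude: float, seed: int = 0
) -> np.ndarray:
    """Degrade an instance map with a documented, monotone effect direction
    on Dice/AJI.

    Modes
    -----
    erode / dilate
        Per-instance morphological erosion (instances may vanish) or
        dilation into unclaimed background, by a disk of radius
        ``magnitude`` (int).
    drop_fraction
        Remove a seeded random ``magnitude`` ∈ [0, 1] fraction of instances.
    merge_pairs
        Merge ``magnitude`` (int) seeded random pairs of distinct instances
        into single labels.
    split
        Split a seeded random ``magnitude`` ∈ [0, 1] fraction of instances
        into two labels along the minor axis through the centroid.
    """
    if mode not in PERTURB_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {PERTURB_MODES}")
    out = labels.copy()
    if magnitude == 0:
        return out
    rng = np.random.default_rng(seed)
    ids = np.unique(labels)
    ids = ids[ids > 0]

    if mode == "erode":
        selem = disk(int(magnitude))
        result = np.zeros_like(labels)
        for i in ids:
            m = erosion(labels == i, selem)
            result[m] = i
        return result
    if mode == "dilate":
        selem = disk(int(magnitude))
        claimed = labels != 0
        result = labels.copy()
        for i in ids:
            grow = dilation(labels == i, selem) & ~claimed
            result[grow] = i
            claimed |= grow
        return result
    if mode == "drop_fraction":
        if not (0 <= magnitude <= 1):
            raise ValueError("drop_fraction magnitude must be in [0, 1]")
        n_drop = int(round(magnitude * len(ids)))
        drop = rng.choice(ids, size=n_drop, replace=False)
        out[np.isin(out, drop)] = 0
        return out
    if mode == "merge_pairs":
        n_pairs = int(magnitude)
        if 2 * n_pairs > len(ids):
            raise ValueError("not enough instances to merge that many pairs")
        chosen = rng.choice(ids, size=2 * n_pairs, replace=False)
        for keep, absorb in zip(chosen[::2], chosen[1::2]):
            out[out == absorb] = keep
        return out
    # split
    if not (0 <= magnitude <= 1):
        raise ValueError("split magnitude must be in [0, 1]")
    n_split = int(round(magnitude * len(ids)))
    chosen = rng.choice(ids, size=n_split, replace=False)
    next_id = int(labels.max()) + 1
    for i in chosen:
        rr, cc = np.nonzero(out == i)
        coords = np.column_stack([rr, cc]).astype(float)
        centered = coords - coords.mean(axis=0)
        cov = np.cov(centered.T)
        eigval, eigvec = np.linalg.eigh(cov)
        major_dir = eigvec[:, np.argmax(eigval)]
        half = centered @ major_dir >= 0
        out[rr[half], cc[half]] = next_id
        next_id += 1
    return out
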
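"""Seeded synthetic TMA cohorts with known ground truth.

No public image cohort accompanies the analysis this package implements, so
every downstream stage is exercised on synthetic tissue-microarray cores that
reproduce the *statistical* structure the analysis assumes:

* a circular tissue core containing irregular tumour nests embedded in
  stroma (thresholded low-frequency Gaussian fields, so the tumour/stroma
  interface is ragged like real nests);
* immune cells as Poisson point processes with separate intensities per
  compartment, rendered as anti-aliased haematoxylin discs, with DAB discs
  added for marker-positive cells, mixed by Beer-Lambert optics;
* cohorts whose cases are planned as hot / cold / excluded immune phenotypes
  via class-conditional log-normal densities, with a correlated lymphocyte
  marker pair (CD3-CD8, Spearman rho ~ 0.9 in the source cohort), a PD-L1
  CPS-high status enriched in hot cases, an FGFR3 mutation that attenuates
  cytotoxic/B-cell densities, and exponential survival with a protective
  proportional-hazards effect of perforin-high status.

Everything is driven by a single cohort seed; identical (spec, seed) pairs
give bit-identical images and tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from . import stainsep
from .stainsep import StainVectorSet
from .tissueclass import BACKGROUND, STROMA, TUMOUR, Annotation, CompartmentMask

__all__ = [
    "CoreSpec",
    "CohortSpec",
    "GroundTruth",
    "CohortCase",
    "generate_mask",
    "sample_cells",
    "render_marker_image",
    "generate_core",
    "draw_cohort_plan",
    "generate_cohort",
    "annotations_from_mask",
]

COMPARTMENT_NAMES = {TUMOUR: "tumour", STROMA: "stroma"}


@dataclass(frozen=True)
class CoreSpec:
    """Geometry and staining parameters of one synthetic TMA core.

    Densities are cells/mm^2 of *marker-positive* cells per compartment;
    ``negative_cell_density`` adds counterstain-only nuclei (tumour cells,
    fibroblasts) that carry no DAB. The haematoxylin background wash differs
    between tumour nests and stroma, which is the texture cue the pixel
    classifier learns.
    """

    core_diameter_um: float = 1000.0
    pixel_size_um: float = 2.0
    tumour_fraction: float = 0.4
    nest_count: int = 4
    marker_densities: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"CD3": (500.0, 400.0)}
    )
    negative_cell_density: tuple[float, float] = (900.0, 350.0)
    cell_radius_um: tuple[float, float] = (3.5, 0.4)
    hema_amplitude: tuple[float, float] = (0.55, 0.08)
    dab_amplitude: tuple[float, float] = (0.65, 0.10)
    tumour_wash_od: float = 0.30
    stroma_wash_od: float = 0.10
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.core_diameter_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("core diameter and pixel size must be positive")
        if not 0 < self.tumour_fraction < 1:
            raise ValueError("tumour_fraction must be in (0, 1)")
        if self.nest_count < 1:
            raise ValueError("nest_count must be >= 1")
        for marker, (td, sd) in self.marker_densities.items():
            if td < 0 or sd < 0:
                raise ValueError(f"negative density for marker {marker}")


@dataclass(frozen=True)
class GroundTruth:
    """True cell table plus the true compartment mask of one core."""

    cells: pd.DataFrame  # x_um, y_um, marker, positive, compartment
    mask: CompartmentMask


@dataclass(frozen=True)
class CohortCase:
    case_id: str
    spec: CoreSpec
    images: dict[str, np.ndarray]  # marker -> RGB uint8
    truth: GroundTruth


def generate_mask(spec: CoreSpec, rng: np.random.Generator) -> CompartmentMask:
    """Circular tissue disk with tumour nests from a thresholded random field."""
    radius_px = spec.core_diameter_um / 2 / spec.pixel_size_um
    n = int(np.ceil(2 * radius_px)) + 4
    yy, xx = np.mgrid[0:n, 0:n]
    cy = cx = n / 2
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2

    # low-frequency field; smoothing scale set so ~nest_count blobs fit the core
    sigma = radius_px / np.sqrt(spec.nest_count) / 1.6
    noise = ndi.gaussian_filter(rng.standard_normal((n, n)), sigma=sigma)
    inside = noise[disk]
    cut = np.quantile(inside, 1.0 - spec.tumour_fraction)
    labels = np.where(disk, np.where(noise > cut, TUMOUR, STROMA), BACKGROUND)
    # degenerate fields (tiny cores) could wipe out one class; re-cut if so
    if not (labels == TUMOUR).any() or not (labels == STROMA).any():
        order = np.argsort(inside)
        k = int(round((1.0 - spec.tumour_fraction) * len(inside)))
        k = min(max(k, 1), len(inside) - 1)
        flat = np.zeros(len(inside), dtype=np.uint8)
        flat[order[k:]] = TUMOUR
        flat[order[:k]] = STROMA
        labels = np.zeros((n, n), dtype=np.uint8)
        labels[disk] = flat
    return CompartmentMask(labels=labels.astype(np.uint8), pixel_size_um=spec.pixel_size_um)


def _scatter_in_compartment(
    mask: CompartmentMask, label: int, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform random (x_um, y_um) positions on pixels of one compartment."""
    flat = np.flatnonzero(mask.labels == label)
    if count == 0 or flat.size == 0:
        return np.empty((0, 2))
    picks = rng.choice(flat, size=count, replace=True)
    rows, cols = np.unravel_index(picks, mask.labels.shape)
    jitter = rng.random((count, 2))
    x = (cols + jitter[:, 0]) * mask.pixel_size_um
    y = (rows + jitter[:, 1]) * mask.pixel_size_um
    return np.stack([x, y], axis=1)


def sample_cells(spec: CoreSpec, mask: CompartmentMask, rng: np.random.Generator) -> pd.DataFrame:
    """Poisson cell counts per compartment for every marker, plus negatives.

    Counts are Poisson(density x compartment area); each marker stains a
    separate serial-slide image of the same geometry, so draws are
    independent between markers.
    """
    areas = {TUMOUR: mask.tumour_area_mm2, STROMA: mask.stroma_area_mm2}
    frames = []
    for marker, (t_density, s_density) in spec.marker_densities.items():
        densities = {TUMOUR: t_density, STROMA: s_density}
        for label in (TUMOUR, STROMA):
            n_pos = rng.poisson(densities[label] * areas[label])
            pos_xy = _scatter_in_compartment(mask, label, n_pos, rng)
            neg_rate = spec.negative_cell_density[0 if label == TUMOUR else 1]
            n_neg = rng.poisson(neg_rate * areas[label])
            neg_xy = _scatter_in_compartment(mask, label, n_neg, rng)
            for xy, positive in ((pos_xy, True), (neg_xy, False)):
                if len(xy):
                    frames.append(
                        pd.DataFrame(
                            {
                                "x_um": xy[:, 0],
                                "y_um": xy[:, 1],
                                "marker": marker,
                                "positive": positive,
                                "compartment": COMPARTMENT_NAMES[label],
                            }
                        )
                    )
    if not frames:
        return pd.DataFrame(columns=["x_um", "y_um", "marker", "positive", "compartment"])
    cells = pd.concat(frames, ignore_index=True)
    return cells.sort_values(["marker", "y_um", "x_um"], kind="mergesort").reset_index(drop=True)


def _add_discs(
    canvas: np.ndarray,
    xy_um: np.ndarray,
    radii_um: np.ndarray,
    amplitudes: np.ndarray,
    pixel_size: float,
) -> None:
    """Accumulate anti-aliased discs (linear edge coverage) onto an OD canvas."""
    h, w = canvas.shape
    for (x, y), r, amp in zip(xy_um / pixel_size, radii_um / pixel_size, amplitudes):
        r = max(r, 0.6)
        x0, x1 = int(np.floor(x - r - 1)), int(np.ceil(x + r + 1)) + 1
        y0, y1 = int(np.floor(y - r - 1)), int(np.ceil(y + r + 1)) + 1
        x0, x1 = max(x0, 0), min(x1, w)
        y0, y1 = max(y0, 0), min(y1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dist = np.hypot(xx + 0.5 - x, yy + 0.5 - y)
        canvas[y0:y1, x0:x1] += amp * np.clip(r + 0.5 - dist, 0.0, 1.0)


def render_marker_image(
    spec: CoreSpec,
    mask: CompartmentMask,
    cells: pd.DataFrame,
    rng: np.random.Generator,
    stains: StainVectorSet | None = None,
) -> np.ndarray:
    """Beer-Lambert rendering of one marker's stained core as RGB uint8.

    All cells get a haematoxylin disc on top of the compartment-specific
    haematoxylin wash; positive cells additionally get a DAB disc. Gaussian
    OD noise is added after stain mixing.
    """
    stains = stains or StainVectorSet.hdab_default()
    h_conc = np.zeros(mask.labels.shape, dtype=float)
    h_conc[mask.labels == TUMOUR] = spec.tumour_wash_od
    h_conc[mask.labels == STROMA] = spec.stroma_wash_od
    dab_conc = np.zeros_like(h_conc)

    n = len(cells)
    if n:
        xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
        radii = np.maximum(rng.normal(*spec.cell_radius_um, size=n), 0.5)
        h_amp = np.maximum(rng.normal(*spec.hema_amplitude, size=n), 0.05)
        _add_discs(h_conc, xy, radii, h_amp, spec.pixel_size_um)
        pos = cells["positive"].to_numpy(dtype=bool)
        if pos.any():
            d_amp = np.maximum(rng.normal(*spec.dab_amplitude, size=int(pos.sum())), 0.05)
            _add_discs(dab_conc, xy[pos], radii[pos], d_amp, spec.pixel_size_um)

    amplitudes = np.stack([h_conc, dab_conc, np.zeros_like(h_conc)], axis=-1)
    od = stainsep.render_stains(amplitudes, stains)
    od = np.maximum(od + rng.normal(0.0, spec.noise_sd, size=od.shape), 0.0)
    rgb = stainsep.od_to_rgb(od, stains.background)
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def generate_core(
    spec: CoreSpec, seed: int | None = None, stains: StainVectorSet | None = None
) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Generate one core: per-marker RGB images plus ground truth.

    Each marker yields its own stained image of the shared tumour/stroma
    geometry (serial-slide TMA practice). Identical (spec, seed) pairs are
    bit-identical.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    mask = generate_mask(spec, rng)
    cells = sample_cells(spec, mask, rng)
    images = {}
    for marker in spec.marker_densities:
        sub = cells[cells["marker"] == marker].reset_index(drop=True)
        images[marker] = render_marker_image(spec, mask, sub, rng, stains=stains)
    return images, GroundTruth(cells=cells, mask=mask)


def annotations_from_mask(
    mask: CompartmentMask,
    rng: np.random.Generator,
    n_per_class: int = 4,
    box_px: int = 12,
) -> list[Annotation]:
    """Square training annotations sampled fully inside each compartment.

    Emulates a pathologist outlining representative tumour and stroma areas;
    boxes are drawn where an eroded compartment guarantees purity.
    """
    annotations = []
    half = box_px // 2
    for label in (TUMOUR, STROMA):
        eroded = ndi.binary_erosion(mask.labels == label, iterations=half + 1)
        flat = np.flatnonzero(eroded)
        if flat.size == 0:
            raise ValueError(f"compartment {COMPARTMENT_NAMES[label]} too thin to annotate")
        picks = rng.choice(flat, size=min(n_per_class, flat.size), replace=False)
        rows, cols = np.unravel_index(picks, mask.labels.shape)
        for r, c in zip(rows, cols):
            poly = np.array(
                [
                    [c - half, r - half],
                    [c + half, r - half],
                    [c + half, r + half],
                    [c - half, r + half],
                ],
                dtype=float,
            )
            annotations.append(Annotation(polygon=poly, label=label))
    return annotations


# ---------------------------------------------------------------------------
# cohort level


@dataclass(frozen=True)
class CohortSpec:
    """Statistical plan of a synthetic cohort.

    Class-conditional medians are (tumour, stroma) cells/mm^2 of a log-normal
    with log-sd ``log_sigma``; the hot class concentrates cells in tumour
    nests, excluded in stroma, cold in neither. ``pdl1_model`` is
    (baseline P(CPS>=10 | not hot), odds ratio for hot); ``fgfr3_model``
    multiplies the affected markers' densities by ``effect`` in mutant cases;
    survival is exponential with a proportional hazard for perforin-high.
    """

    n_cases: int = 114
    phenotype_mix: Mapping[str, float] = field(
        default_factory=lambda: {"hot": 1 / 3, "cold": 1 / 3, "excluded": 1 / 3}
    )
    markers: Sequence[str] = ("CD3", "CD8", "perforin")
    correlated_pair: tuple[str, str] = ("CD3", "CD8")
    marker_corr: float = 0.9
    class_medians: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "hot": (700.0, 350.0),
            "excluded": (50.0, 700.0),
            "cold": (50.0, 70.0),
        }
    )
    log_sigma: float = 0.3
    pdl1_baseline: float = 0.10
    pdl1_odds_ratio: float = 6.0
    fgfr3_prevalence: float = 0.10
    fgfr3_effect: float = 0.4
    fgfr3_markers: Sequence[str] = ("CD8", "perforin", "CD79A")
    baseline_hazard: float = 0.02
    perforin_hr: float = 0.4
    censoring_rate: float = 0.3
    max_follow_months: float = 120.0
    mix_fraction: float = 0.40
    tumour_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        total = float(sum(self.phenotype_mix.values()))
        if abs(total - 1.0) > 1e-9 or any(p < 0 for p in self.phenotype_mix.values()):
            raise ValueError("phenotype_mix must be non-negative and sum to 1")
        if not -1.0 <= self.marker_corr <= 1.0:
            raise ValueError("marker_corr must be in [-1, 1]")
        if self.baseline_hazard <= 0 or self.perforin_hr <= 0:
            raise ValueError("hazards must be positive")
        if not 0.0 <= self.pdl1_baseline <= 1.0 or self.pdl1_odds_ratio <= 0:
            raise ValueError("invalid pdl1 model")


def draw_cohort_plan(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the per-case statistical plan without rendering any image.

    Returns ``(plan, clinical)``: ``plan`` has one row per (case, marker)
    with true tumour/stroma/overall densities and the planned phenotype;
    ``clinical`` is the cohort table (subtype, age, sex, stage, FGFR3 status,
    CPS status, overall survival and event flag).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cases
    classes = list(spec.phenotype_mix)
    probs = np.array([spec.phenotype_mix[c] for c in classes])
    phenotype = rng.choice(classes, size=n, p=probs)
    case_ids = [f"case_{i:03d}" for i in range(n)]

    fgfr3 = rng.random(n) < spec.fgfr3_prevalence
    # log-normal multipliers; the correlated pair shares a Gaussian copula
    z: dict[str, np.ndarray] = {}
    pair = [m for m in spec.correlated_pair if m in spec.markers]
    if len(pair) == 2:
        cov = np.array([[1.0, spec.marker_corr], [spec.marker_corr, 1.0]])
        chol = np.linalg.cholesky(cov)
        for comp_idx in range(2):  # tumour, stroma draws
            draws = rng.standard_normal((n, 2)) @ chol.T
            for j, m in enumerate(pair):
                z[f"{m}_{comp_idx}"] = draws[:, j]
    for m in spec.markers:
        for comp_idx in range(2):
            z.setdefault(f"{m}_{comp_idx}", rng.standard_normal(n))

    med_t = np.array([spec.class_medians[c][0] for c in phenotype])
    med_s = np.array([spec.class_medians[c][1] for c in phenotype])
    plan_rows = []
    tf = spec.tumour_fraction
    for m in spec.markers:
        atten = np.where(fgfr3 & (m in spec.fgfr3_markers), spec.fgfr3_effect, 1.0)
        t_density = med_t * np.exp(spec.log_sigma * z[f"{m}_0"]) * atten
        s_density = med_s * np.exp(spec.log_sigma * z[f"{m}_1"]) * atten
        overall = tf * t_density + (1 - tf) * s_density
        plan_rows.append(
            pd.DataFrame(
                {
                    "case_id": case_ids,
                    "marker": m,
                    "phenotype": phenotype,
                    "tumour_density": t_density,
                    "stroma_density": s_density,
                    "overall_density": overall,
                }
            )
        )
    plan = pd.concat(plan_rows, ignore_index=True)

    # PD-L1 CPS-high status: logistic in hot membership
    base_odds = spec.pdl1_baseline / max(1.0 - spec.pdl1_baseline, 1e-12)
    odds = base_odds * np.where(phenotype == "hot", spec.pdl1_odds_ratio, 1.0)
    p_cps = odds / (1.0 + odds)
    cps_high = rng.random(n) < p_cps

    # survival with protective perforin effect (cohort-median split on truth)
    if "perforin" in spec.markers:
        perf = plan.loc[plan["marker"] == "perforin", "overall_density"].to_numpy()
    else:
        perf = plan.loc[plan["marker"] == spec.markers[0], "overall_density"].to_numpy()
    perforin_high = perf > np.median(perf)
    hazard = spec.baseline_hazard * np.where(perforin_high, spec.perforin_hr, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = np.where(
        rng.random(n) < spec.censoring_rate,
        rng.uniform(0.0, spec.max_follow_months, size=n),
        spec.max_follow_months,
    )
    os_months = np.minimum(event_time, censor_time)
    event = event_time <= censor_time

    clinical = pd.DataFrame(
        {
            "case_id": case_ids,
            "subtype": np.where(rng.random(n) < spec.mix_fraction, "mix", "pure"),
            "age": np.clip(rng.normal(68, 10, size=n).round(), 35, 95).astype(int),
            "sex": rng.choice(["male", "female"], size=n),
            "stage": rng.choice(["pT1", "pT2", "pT3", "pT4"], size=n, p=[0.07, 0.08, 0.6, 0.25]),
            "nodal": rng.choice(["pN0", "pN+"], size=n, p=[0.75, 0.25]),
            "grade": rng.choice(["G1-G2", "G3-G4"], size=n, p=[0.3, 0.7]),
            "planned_phenotype": phenotype,
            "fgfr3_mutated": fgfr3,
            "cps_high": cps_high,
            "perforin_high_true": perforin_high,
            "os_months": os_months,
            "event": event,
        }
    )
    return plan, clinical


def generate_cohort(
    spec: CohortSpec,
    core_template: CoreSpec | None = None,
    render: bool = True,
) -> tuple[list[CohortCase], pd.DataFrame]:
    """Generate a full cohort of cores with ground truth and a clinical table.

    ``core_template`` provides the geometry/staining parameters; each case's
    marker densities come from the cohort plan. With ``render=False`` the
    per-marker images are omitted (masks and cell tables only), which is much
    faster for statistics-level experiments.
    """
    template = core_template or CoreSpec()
    plan, clinical = draw_cohort_plan(spec)
    seeds = np.random.SeedSequence(spec.seed).generate_state(spec.n_cases) % (2**31)
    cases = []
    for i, case_id in enumerate(clinical["case_id"]):
        case_plan = plan[plan["case_id"] == case_id]
        densities = {
            row.marker: (row.tumour_density, row.stroma_density)
            for row in case_plan.itertuples()
        }
        case_spec = CoreSpec(
            core_diameter_um=template.core_diameter_um,
            pixel_size_um=template.pixel_size_um,
            tumour_fraction=spec.tumour_fraction,
            nest_count=template.nest_count,
            marker_densities=densities,
            negative_cell_density=template.negative_cell_density,
            cell_radius_um=template.cell_radius_um,
            hema_amplitude=template.hema_amplitude,
            dab_amplitude=template.dab_amplitude,
            tumour_wash_od=template.tumour_wash_od,
            stroma_wash_od=template.stroma_wash_od,
            noise_sd=template.noise_sd,
            seed=int(seeds[i]),
        )
        rng = np.random.default_rng(int(seeds[i]))
        mask = generate_mask(case_spec, rng)
        cells = sample_cells(case_spec, mask, rng)
        images = {}
        if render:
            for marker in densities:
                sub = cells[cells["marker"] == marker].reset_index(drop=True)
                images[marker] = render_marker_image(case_spec, mask, sub, rng)
        cases.append(CohortCase(case_id=case_id, spec=case_spec, images=images,
                                truth=GroundTruth(cells=cells, mask=mask)))
    return cases, clinical
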
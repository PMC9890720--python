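"""From detections and compartment masks to tumour-immune topography.

Converts per-core cell detections into per-case compartment densities
(cells/mm^2), derives cohort-level density cutoffs (median-based), calls the
hot / cold / excluded tumour-immune phenotype per marker or marker
combination, dichotomizes densities at the cohort median, maps densities to
semiquantitative TILs scores (0 / + / ++ / +++), and computes the PD-L1
combined positive score (CPS).

Phenotype decision rule (densities d_t in tumour, d_s in stroma, cutoff c):

* ``hot``       if d_t >= c              (immune cells inside tumour nests)
* ``excluded``  elif d_s >= c            (immune cells held in the stroma)
* ``cold``      otherwise                (low density in both compartments)

Dichotomization uses strict ``>`` for "high" so a case sitting exactly on
the median lands in the low group (low rows are labelled "<= cutoff").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tissueclass import STROMA, TUMOUR, CompartmentMask

__all__ = [
    "DensityRecord",
    "CPSResult",
    "UnusableCaseError",
    "MissingThresholdError",
    "assign_cells",
    "compute_density",
    "cohort_median_threshold",
    "call_phenotype",
    "combine_markers",
    "dichotomize",
    "compute_cps",
    "semiquant_bins",
    "phenotype_table",
]

PHENOTYPES = ("hot", "cold", "excluded")
SEMIQUANT_LEVELS = ("0", "+", "++", "+++")
DEFAULT_SEMIQUANT_EDGES = (10.0, 100.0, 500.0)


class UnusableCaseError(ValueError):
    """Raised when a case lacks a usable tumour or stroma compartment."""


class MissingThresholdError(ValueError):
    """Raised when no usable record exists to derive a marker cutoff."""


@dataclass(frozen=True)
class DensityRecord:
    """Per-case, per-marker cell counts, areas and densities."""

    case_id: str
    marker: str
    tumour_count: int
    stroma_count: int
    tumour_area_mm2: float
    stroma_area_mm2: float

    @property
    def tumour_density(self) -> float:
        return self.tumour_count / self.tumour_area_mm2 if self.tumour_area_mm2 > 0 else np.nan

    @property
    def stroma_density(self) -> float:
        return self.stroma_count / self.stroma_area_mm2 if self.stroma_area_mm2 > 0 else np.nan

    @property
    def overall_density(self) -> float:
        total_area = self.tumour_area_mm2 + self.stroma_area_mm2
        if total_area <= 0:
            return np.nan
        return (self.tumour_count + self.stroma_count) / total_area

    def as_row(self) -> dict:
        return {
            "case_id": self.case_id,
            "marker": self.marker,
            "tumour_count": self.tumour_count,
            "stroma_count": self.stroma_count,
            "tumour_area_mm2": self.tumour_area_mm2,
            "stroma_area_mm2": self.stroma_area_mm2,
            "tumour_density": self.tumour_density,
            "stroma_density": self.stroma_density,
            "overall_density": self.overall_density,
        }


def assign_cells(detections: pd.DataFrame, mask: CompartmentMask) -> pd.DataFrame:
    """Label each detection with the compartment at its centroid pixel.

    Centroids on background (or outside the frame, which triggers a warning)
    become ``unassigned`` and are excluded from both compartment counts.
    """
    out = detections.copy()
    if not len(out):
        out["compartment"] = pd.Series(dtype=object)
        return out
    px = mask.pixel_size_um
    cols = np.floor(out["x_um"].to_numpy(dtype=float) / px).astype(int)
    rows = np.floor(out["y_um"].to_numpy(dtype=float) / px).astype(int)
    h, w = mask.labels.shape
    in_frame = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    if not in_frame.all():
        warnings.warn(
            f"{int((~in_frame).sum())} detection centroid(s) outside the mask frame",
            stacklevel=2,
        )
    labels = np.zeros(len(out), dtype=np.uint8)
    labels[in_frame] = mask.labels[rows[in_frame], cols[in_frame]]
    out["compartment"] = np.select(
        [labels == TUMOUR, labels == STROMA], ["tumour", "stroma"], default="unassigned"
    )
    return out


def compute_density(
    assigned: pd.DataFrame,
    mask: CompartmentMask,
    case_id: str,
    marker: str,
    positive_only: bool = True,
) -> DensityRecord:
    """Compartment densities of (positive) detections for one case/marker.

    Cores whose classified tumour or stroma area is zero are unusable for
    topography (they cannot support a phenotype call) and raise
    :class:`UnusableCaseError`, mirroring the exclusion of degraded cores.
    """
    if mask.tumour_area_mm2 <= 0 or mask.stroma_area_mm2 <= 0:
        raise UnusableCaseError(f"case {case_id}: zero tumour or stroma area")
    cells = assigned
    if positive_only and "positive" in cells.columns:
        cells = cells[cells["positive"].astype(bool)]
    return DensityRecord(
        case_id=case_id,
        marker=marker,
        tumour_count=int((cells["compartment"] == "tumour").sum()),
        stroma_count=int((cells["compartment"] == "stroma").sum()),
        tumour_area_mm2=mask.tumour_area_mm2,
        stroma_area_mm2=mask.stroma_area_mm2,
    )


def cohort_median_threshold(
    records: pd.DataFrame, derivation: str = "cohort_median_overall"
) -> pd.DataFrame:
    """Per-marker density cutoff as a cohort median.

    ``cohort_median_overall`` (default): median over cases of the per-case
    overall density. ``pooled_compartment_median``: median of the pooled
    tumour and stroma densities (each case contributes both compartments).
    Even n uses the mean of the middle pair.
    """
    if derivation not in ("cohort_median_overall", "pooled_compartment_median"):
        raise ValueError(f"unknown derivation {derivation!r}")
    rows = []
    for marker, grp in records.groupby("marker", sort=True):
        if derivation == "cohort_median_overall":
            values = grp["overall_density"].to_numpy(dtype=float)
        else:
            values = np.concatenate(
                [grp["tumour_density"].to_numpy(dtype=float),
                 grp["stroma_density"].to_numpy(dtype=float)]
            )
        values = values[np.isfinite(values)]
        if values.size == 0:
            raise MissingThresholdError(f"no usable densities for marker {marker}")
        rows.append({"marker": marker, "cutoff": float(np.median(values)),
                     "derivation": derivation})
    return pd.DataFrame(rows)


def call_phenotype(tumour_density: float, stroma_density: float, cutoff: float) -> str:
    """Hot / cold / excluded call for one case and marker."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not (np.isfinite(tumour_density) and np.isfinite(stroma_density)):
        raise UnusableCaseError("missing compartment density; no phenotype call")
    if tumour_density >= cutoff:
        return "hot"
    if stroma_density >= cutoff:
        return "excluded"
    return "cold"


def combine_markers(
    densities: Mapping[str, tuple[float, float]],
    cutoffs: Mapping[str, float],
    rule: str = "and",
) -> str:
    """Phenotype call over a marker combination (e.g. CD3/CD8 T-cells).

    Under the default ``and`` rule a compartment counts as high only when
    every constituent marker is high there; ``or`` needs any marker high;
    ``mean`` averages cutoff-normalized densities. The combined high flags
    then feed the usual decision order (hot, else excluded, else cold).
    """
    if not densities:
        raise ValueError("no markers in combination")
    flags_t, flags_s, ratios_t, ratios_s = [], [], [], []
    for marker, (d_t, d_s) in densities.items():
        c = cutoffs[marker]
        if c <= 0:
            raise ValueError(f"cutoff for {marker} must be positive")
        if not (np.isfinite(d_t) and np.isfinite(d_s)):
            raise UnusableCaseError(f"marker {marker} unusable; no combined call")
        flags_t.append(d_t >= c)
        flags_s.append(d_s >= c)
        ratios_t.append(d_t / c)
        ratios_s.append(d_s / c)
    if rule == "and":
        high_t, high_s = all(flags_t), all(flags_s)
    elif rule == "or":
        high_t, high_s = any(flags_t), any(flags_s)
    elif rule == "mean":
        high_t = float(np.mean(ratios_t)) >= 1.0
        high_s = float(np.mean(ratios_s)) >= 1.0
    else:
        raise ValueError(f"unknown combination rule {rule!r}")
    if high_t:
        return "hot"
    if high_s:
        return "excluded"
    return "cold"


def dichotomize(overall_density: float, cutoff: float) -> str:
    """Low/high split at the cohort median; ties go to ``low`` (<= cutoff)."""
    return "high" if overall_density > cutoff else "low"


@dataclass(frozen=True)
class CPSResult:
    """PD-L1 combined positive score for one case."""

    case_id: str
    n_positive: int
    n_viable_tumour_cells: int
    cps: float
    high: bool


def compute_cps(
    n_positive: int, n_viable_tumour_cells: int, cutoff: float = 10.0, case_id: str = ""
) -> CPSResult:
    """CPS = 100 x (PD-L1+ tumour cells, lymphocytes, macrophages) / viable
    tumour cells, capped at 100; ``high`` when CPS >= cutoff (default 10)."""
    if n_viable_tumour_cells <= 0:
        raise UnusableCaseError("CPS undefined: no viable tumour cells")
    if n_positive < 0:
        raise ValueError("negative positive-cell count")
    cps = min(100.0, 100.0 * n_positive / n_viable_tumour_cells)
    return CPSResult(
        case_id=case_id,
        n_positive=int(n_positive),
        n_viable_tumour_cells=int(n_viable_tumour_cells),
        cps=cps,
        high=cps >= cutoff,
    )


def semiquant_bins(
    density: float, bin_edges: Sequence[float] = DEFAULT_SEMIQUANT_EDGES
) -> str:
    """Semiquantitative TILs score from a density (cells/mm^2).

    Edges (e1, e2, e3) map [0, e1) -> "0", [e1, e2) -> "+", [e2, e3) -> "++",
    [e3, inf) -> "+++"; zero density is always "0".
    """
    edges = tuple(bin_edges)
    if len(edges) != 3 or not (edges[0] < edges[1] < edges[2]):
        raise ValueError("bin_edges must be 3 strictly increasing values")
    if density < 0 or not np.isfinite(density):
        raise ValueError("density must be finite and non-negative")
    return SEMIQUANT_LEVELS[int(np.searchsorted(edges, density, side="right"))]


def phenotype_table(
    density_table: pd.DataFrame,
    thresholds: pd.DataFrame,
    combos: Mapping[str, Sequence[str]] | None = None,
    rule: str = "and",
) -> pd.DataFrame:
    """Per-case phenotype calls for every marker and marker combination.

    ``density_table`` needs columns case_id, marker, tumour_density,
    stroma_density; ``thresholds`` comes from
    :func:`cohort_median_threshold`. ``combos`` maps a combination name
    (e.g. ``"CD3/CD8"``) to its constituent markers.
    """
    cutoffs = dict(zip(thresholds["marker"], thresholds["cutoff"]))
    rows = []
    for (case_id, marker), grp in density_table.groupby(["case_id", "marker"], sort=True):
        rec = grp.iloc[0]
        try:
            call = call_phenotype(rec["tumour_density"], rec["stroma_density"], cutoffs[marker])
        except UnusableCaseError:
            continue
        rows.append({"case_id": case_id, "marker": marker, "phenotype": call})
    if combos:
        wide = density_table.set_index(["case_id", "marker"])
        for case_id in density_table["case_id"].unique():
            for name, members in combos.items():
                try:
                    dens = {
                        m: (
                            float(wide.loc[(case_id, m), "tumour_density"]),
                            float(wide.loc[(case_id, m), "stroma_density"]),
                        )
                        for m in members
                    }
                    call = combine_markers(dens, cutoffs, rule=rule)
                except (KeyError, UnusableCaseError):
                    continue
                rows.append({"case_id": case_id, "marker": name, "phenotype": call})
    return pd.DataFrame(rows, columns=["case_id", "marker", "phenotype"])
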
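"""Positive-cell detection on deconvolved H-DAB optical-density channels.

Mirrors the classical brightfield IHC workflow: detect every nucleus on a
smoothed, background-subtracted detection channel (the H + DAB OD sum, so
strongly DAB-positive cells with weak counterstain are not missed), then flag
marker-positive cells by their mean DAB optical density. Densities per mm^2
follow from these counts and compartment areas downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.morphology import closing, disk, remove_small_holes, remove_small_objects
from skimage.segmentation import watershed

__all__ = [
    "DetectionParams",
    "TissueMask",
    "EmptyTissueError",
    "simple_tissue_detection",
    "detect_cells",
    "classify_positive",
    "DETECTION_COLUMNS",
]

DETECTION_COLUMNS = [
    "x_um",
    "y_um",
    "area_um2",
    "mean_h_od",
    "mean_dab_od",
    "max_dab_od",
    "positive",
    "compartment",
]


class EmptyTissueError(ValueError):
    """Raised when tissue detection finds no tissue (unusable core)."""


@dataclass(frozen=True)
class DetectionParams:
    """Cell-detection parameters for one staining type.

    Values are physical (microns, OD) so the same parameter file applies
    across magnifications. Defaults suit lymphocyte-sized nuclei; per-marker
    overrides live in the pipeline config, since the optimal settings vary
    with the staining type.
    """

    smoothing_sigma_um: float = 1.5
    background_radius_um: float = 8.0
    detection_threshold_od: float = 0.1
    min_area_um2: float = 10.0
    max_area_um2: float = 400.0
    dab_positive_threshold_od: float = 0.2
    watershed_split: bool = True
    split_min_distance_um: float = 3.0

    def __post_init__(self) -> None:
        if not (0 < self.min_area_um2 < self.max_area_um2):
            raise ValueError("need 0 < min_area < max_area")
        if min(self.smoothing_sigma_um, self.background_radius_um,
               self.detection_threshold_od, self.dab_positive_threshold_od) <= 0:
            raise ValueError("sigma, radius and thresholds must be positive")


@dataclass(frozen=True)
class TissueMask:
    """Binary tissue flag per pixel with its physical pixel size."""

    mask: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def area_mm2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size_um**2 / 1e6


def simple_tissue_detection(
    od: np.ndarray,
    pixel_size_um: float,
    od_threshold: float = 0.1,
    min_hole_area_um2: float = 2500.0,
    min_object_area_um2: float = 400.0,
) -> TissueMask:
    """Threshold total OD to a tissue mask, then clean it morphologically.

    ``od`` is the *channel* OD image (before stain separation): tissue is
    wherever any stain absorbs. Raises :class:`EmptyTissueError` when
    nothing survives, mirroring unusable TMA cores that drop out of
    downstream analyses.
    """
    total = np.asarray(od, dtype=float).sum(axis=-1)
    mask = total > od_threshold
    if mask.any():
        px_area = pixel_size_um**2
        mask = closing(mask, disk(2))
        mask = remove_small_holes(mask, max_size=max(1, int(min_hole_area_um2 / px_area)))
        mask = remove_small_objects(mask, max_size=max(1, int(min_object_area_um2 / px_area)))
    if not mask.any():
        raise EmptyTissueError("no tissue detected on this core")
    return TissueMask(mask=mask, pixel_size_um=pixel_size_um)


def _background_subtract(channel: np.ndarray, radius_px: int) -> np.ndarray:
    # rolling-ball style background: grey opening with a disk footprint
    background = ndi.grey_opening(channel, footprint=disk(max(1, radius_px)))
    return channel - background


def detect_cells(
    stain_od: np.ndarray,
    params: DetectionParams,
    tissue: TissueMask,
) -> pd.DataFrame:
    """Detect cells on deconvolved stain channels (H, DAB, residual).

    Pipeline: Gaussian smooth the H+DAB sum, subtract a rolling-ball
    background, threshold, label connected components, optionally split
    touching nuclei by a distance-transform watershed, filter by area and
    tissue membership. Returns one row per detection with centroids in
    microns, sorted by (y, x) for determinism.
    """
    px = tissue.pixel_size_um
    stain_od = np.asarray(stain_od, dtype=float)
    h_channel = stain_od[..., 0]
    dab_channel = stain_od[..., 1]
    detection = h_channel + dab_channel

    smoothed = ndi.gaussian_filter(detection, sigma=params.smoothing_sigma_um / px)
    signal = _background_subtract(smoothed, int(round(params.background_radius_um / px)))
    binary = signal > params.detection_threshold_od

    if params.watershed_split and binary.any():
        # smoothing the distance transform suppresses spurious plateau peaks
        # in fused nuclei clumps before seed extraction
        distance = ndi.gaussian_filter(
            ndi.distance_transform_edt(binary), sigma=max(1.0 / px, 0.5)
        )
        min_dist = max(1, int(round(params.split_min_distance_um / px)))
        peaks = peak_local_max(distance, min_distance=min_dist, labels=binary,
                               exclude_border=False)
        markers = np.zeros_like(binary, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = watershed(-distance, markers=markers, mask=binary)
    else:
        labels, _ = ndi.label(binary)

    # regionprops-free accumulation keeps this stage cheap on large cores
    rows = []
    px_area = px**2
    n_labels = int(labels.max())
    if n_labels:
        idx = np.arange(1, n_labels + 1)
        areas_px = ndi.sum_labels(np.ones_like(labels, dtype=np.uint8), labels, idx)
        cy, cx = np.array(ndi.center_of_mass(np.ones_like(labels, dtype=np.uint8),
                                             labels, idx)).T
        # stain means are measured over the eroded region (the nucleus
        # proper): the segmentation skirt from smoothing would otherwise
        # dilute the per-cell DAB signal
        core = np.where(ndi.binary_erosion(labels > 0), labels, 0)
        core_areas = ndi.sum_labels(np.ones_like(labels, dtype=np.uint8), core, idx)
        measure = core
        vanished = idx[core_areas == 0]  # tiny cells: fall back to full region
        if vanished.size:
            measure = np.where(np.isin(labels, vanished), labels, core)
        mean_h = ndi.mean(h_channel, measure, idx)
        mean_dab = ndi.mean(dab_channel, measure, idx)
        max_dab = ndi.maximum(dab_channel, measure, idx)
        areas = areas_px * px_area
        keep = (areas >= params.min_area_um2) & (areas <= params.max_area_um2)
        ys = np.clip(np.round(cy).astype(int), 0, tissue.mask.shape[0] - 1)
        xs = np.clip(np.round(cx).astype(int), 0, tissue.mask.shape[1] - 1)
        keep &= tissue.mask[ys, xs]
        for i in np.flatnonzero(keep):
            rows.append((cx[i] * px, cy[i] * px, areas[i], mean_h[i],
                         mean_dab[i], max_dab[i]))

    out = pd.DataFrame(rows, columns=["x_um", "y_um", "area_um2", "mean_h_od",
                                      "mean_dab_od", "max_dab_od"])
    out = out.sort_values(["y_um", "x_um"], kind="mergesort").reset_index(drop=True)
    out["positive"] = False
    out["compartment"] = "unassigned"
    return classify_positive(out, params)


def classify_positive(detections: pd.DataFrame, params: DetectionParams) -> pd.DataFrame:
    """Flag detections whose mean DAB OD exceeds the positivity threshold."""
    out = detections.copy()
    out["positive"] = out["mean_dab_od"].to_numpy() > params.dab_positive_threshold_od
    return out
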
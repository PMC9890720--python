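"""Beer-Lambert colour deconvolution for haematoxylin + DAB brightfield images.

Brightfield stains absorb light multiplicatively, so they mix *additively* in
optical-density space: ``OD_c = -log10(I_c / I0_c)`` per channel c, and the OD
of a pixel is a non-negative combination of per-stain unit "stain vectors".
Deconvolution inverts that 3x3 mixing system per pixel, recovering per-stain
OD amplitudes (haematoxylin counterstain, DAB chromogen, and a residual axis).

The default H-DAB vectors are the widely used published pair for this stain
combination; :func:`estimate_stain_vectors` re-estimates them per image from
the extreme directions of the OD point cloud (robust-percentile variant of
the standard SVD approach), falling back to the defaults on blank images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StainVectorSet",
    "StainEstimationWarning",
    "DegenerateStainsError",
    "rgb_to_od",
    "od_to_rgb",
    "deconvolve",
    "render_stains",
    "estimate_stain_vectors",
    "DEFAULT_HEMATOXYLIN",
    "DEFAULT_DAB",
]

# Published H-DAB absorption directions in OD(R, G, B) space.
DEFAULT_HEMATOXYLIN = (0.650, 0.704, 0.286)
DEFAULT_DAB = (0.269, 0.568, 0.778)

_EPS = 1e-8  # guards log10(0) for saturated black pixels
_MAX_CONDITION = 1e8


class DegenerateStainsError(ValueError):
    """Raised when the stain matrix is singular or near-singular."""


class StainEstimationWarning(UserWarning):
    """Emitted when per-image stain estimation falls back to defaults."""


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length stain vector")
    return v / n


@dataclass(frozen=True)
class StainVectorSet:
    """Three unit stain vectors (rows) plus per-channel background intensity.

    ``matrix`` rows are (haematoxylin, DAB, residual) in OD(R,G,B) space; a
    pixel's OD is ``amplitudes @ matrix``.
    """

    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.array([255.0, 255.0, 255.0]))
    names: tuple[str, ...] = ("hematoxylin", "dab", "residual")

    def __post_init__(self) -> None:
        m = np.array([_unit(row) for row in np.asarray(self.matrix, dtype=float)])
        if m.shape != (3, 3):
            raise ValueError("stain matrix must be 3x3")
        if np.linalg.cond(m) > _MAX_CONDITION:
            raise DegenerateStainsError("stain vectors are linearly dependent")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (3,) or np.any(bg <= 0):
            raise ValueError("background intensity must be 3 positive values")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background", bg)

    @classmethod
    def from_pair(
        cls,
        hematoxylin=DEFAULT_HEMATOXYLIN,
        dab=DEFAULT_DAB,
        background=(255.0, 255.0, 255.0),
    ) -> "StainVectorSet":
        """Build a set from H and DAB vectors; residual is their cross product."""
        h, d = _unit(hematoxylin), _unit(dab)
        res = np.cross(h, d)
        if np.linalg.norm(res) < 1e-6:
            raise DegenerateStainsError("H and DAB vectors are parallel")
        return cls(matrix=np.stack([h, d, _unit(res)]), background=background)

    @classmethod
    def hdab_default(cls, background=(255.0, 255.0, 255.0)) -> "StainVectorSet":
        return cls.from_pair(background=background)


def rgb_to_od(image: np.ndarray, background=(255.0, 255.0, 255.0)) -> np.ndarray:
    """Convert RGB intensities to optical density per channel.

    ``OD_c = -log10((I_c + eps) / I0_c)``, clamped at 0 so over-bright pixels
    (brighter than the background estimate) do not go negative.
    """
    bg = np.asarray(background, dtype=float)
    if np.any(bg <= 0):
        raise ValueError("background intensity I0 must be positive")
    img = np.asarray(image, dtype=float)
    od = -np.log10((img + _EPS) / bg)
    return np.maximum(od, 0.0)


def od_to_rgb(od: np.ndarray, background=(255.0, 255.0, 255.0)) -> np.ndarray:
    """Inverse Beer-Lambert transform: OD back to float RGB intensities."""
    bg = np.asarray(background, dtype=float)
    return bg * np.power(10.0, -np.asarray(od, dtype=float)) - _EPS


def render_stains(amplitudes: np.ndarray, stains: StainVectorSet) -> np.ndarray:
    """Forward-mix per-stain OD amplitudes (..., 3) into channel OD (..., 3)."""
    return np.asarray(amplitudes, dtype=float) @ stains.matrix


def deconvolve(od: np.ndarray, stains: StainVectorSet) -> np.ndarray:
    """Separate channel OD into per-stain amplitudes (H, DAB, residual).

    Solves the 3x3 linear system per pixel and clamps negative amplitudes to
    zero (noise can push pure-stain pixels slightly outside the cone).
    """
    m = stains.matrix
    if np.linalg.cond(m) > _MAX_CONDITION:
        raise DegenerateStainsError("stain matrix is singular")
    amplitudes = np.asarray(od, dtype=float) @ np.linalg.inv(m)
    return np.maximum(amplitudes, 0.0)


def estimate_stain_vectors(
    od: np.ndarray,
    od_floor: float = 0.15,
    percentiles: tuple[float, float] = (1.0, 99.0),
    min_pixels: int = 200,
    background=(255.0, 255.0, 255.0),
) -> tuple[StainVectorSet, bool]:
    """Estimate H and DAB vectors from an OD image.

    Tissue pixels (total OD above ``od_floor``) are projected onto the
    principal plane of the OD point cloud; the robust extreme directions at
    the given angle percentiles are taken as the two stain vectors. Returns
    ``(vectors, estimated)`` where ``estimated`` is False when too few tissue
    pixels were found and the published H-DAB defaults were used instead.
    """
    pixels = np.asarray(od, dtype=float).reshape(-1, 3)
    tissue = pixels[pixels.sum(axis=1) > od_floor]
    if tissue.shape[0] < min_pixels:
        warnings.warn(
            "too few stained pixels for stain estimation; using default H-DAB vectors",
            StainEstimationWarning,
            stacklevel=2,
        )
        return StainVectorSet.hdab_default(background=background), False

    # principal plane of the OD cloud (no centring: stains radiate from 0)
    _, _, vt = np.linalg.svd(tissue, full_matrices=False)
    plane = vt[:2]
    # orient basis so projections are mostly positive
    plane = plane * np.sign(plane @ tissue.mean(axis=0))[:, None]
    proj = tissue @ plane.T
    angles = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(angles, percentiles)
    v1 = np.array([np.cos(lo), np.sin(lo)]) @ plane
    v2 = np.array([np.cos(hi), np.sin(hi)]) @ plane
    v1, v2 = _unit(np.abs(v1)), _unit(np.abs(v2))

    # label the vector closer to the published haematoxylin direction as H
    h_ref = _unit(DEFAULT_HEMATOXYLIN)
    if float(v1 @ h_ref) >= float(v2 @ h_ref):
        h, d = v1, v2
    else:
        h, d = v2, v1
    return StainVectorSet.from_pair(h, d, background=background), True
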
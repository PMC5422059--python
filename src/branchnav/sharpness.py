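"""ROI sharpness indexes and frame down-selection.

Three edge-energy indexes are computed on the red channel of each frame,
inside three circular regions of interest (diameter 100 px) placed on the
central horizontal band of the image:

* Sobel index — sum over ROI pixels of sqrt(Sx^2 + Sy^2) with the standard
  3x3 horizontal/vertical kernels;
* Laplacian index — sum of |L| with the 3x3 4-neighbor Laplacian kernel;
* Canny index — sum of the {0, 255} edge map, hysteresis limits set to one
  and three standard deviations of the full red channel.

A frame is accepted when ANY ROI's index for the chosen operator is
strictly above that operator's threshold.  Defocused and motion-blurred
frames score low on all three; the default thresholds separate frames
acquired below 5 cm/s from faster (blurred) ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import correlate
from skimage.feature import canny as _canny

__all__ = [
    "RoiSpec",
    "SharpnessReport",
    "SharpnessThresholds",
    "FrameSelection",
    "default_rois",
    "red_channel",
    "sobel_index",
    "laplacian_index",
    "canny_index",
    "compute_indexes",
    "accept_frame",
    "select_frames",
]

SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
SOBEL_Y = SOBEL_X.T
LAPLACIAN = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)

OPERATORS = ("sobel", "laplacian", "canny")


@dataclass(frozen=True)
class RoiSpec:
    """Three circular ROIs on the central band: (x, y) centers + diameter."""

    centers: tuple
    diameter: int = 100

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("ROI diameter must be positive")


@dataclass(frozen=True)
class SharpnessThresholds:
    """Acceptance boundaries per operator (dimensionless index units)."""

    sobel: float = 1_100_000.0
    laplacian: float = 54_000.0
    canny: float = 290_000.0

    def __post_init__(self) -> None:
        if min(self.sobel, self.laplacian, self.canny) <= 0:
            raise ValueError("thresholds must be positive")

    def for_operator(self, operator: str) -> float:
        if operator not in OPERATORS:
            raise ValueError(f"unknown operator {operator!r}; expected one of {OPERATORS}")
        return getattr(self, operator)


@dataclass
class SharpnessReport:
    """Per-frame index values (one per ROI per operator) and the decision."""

    frame_id: int
    idx_sobel: tuple
    idx_laplacian: tuple
    idx_canny: tuple
    accepted: bool
    operator_used: str

    def indexes(self, operator: str) -> tuple:
        if operator not in OPERATORS:
            raise ValueError(f"unknown operator {operator!r}")
        return getattr(self, f"idx_{operator}")


@dataclass
class FrameSelection:
    """Outcome of frame down-selection for one trimmed video."""

    selected: list
    reports: list
    reacquire: bool
    qc_frames: tuple


def default_rois(width: int, height: int, diameter: int = 100) -> RoiSpec:
    """Three ROIs at 1/4, 1/2, 3/4 of the width on the central row."""
    if width < 2 * diameter or height < 2 * diameter:
        raise ValueError(
            f"image {width}x{height} too small for three {diameter}-px ROIs; "
            f"need at least {2 * diameter} px per side"
        )
    y = height // 2
    centers = ((width // 4, y), (width // 2, y), (3 * width // 4, y))
    return RoiSpec(centers=centers, diameter=diameter)


def red_channel(frame: np.ndarray) -> np.ndarray:
    """Red channel of an RGB frame as float; grayscale passes through."""
    arr = np.asarray(frame)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr.astype(float)


def _roi_mask(shape: tuple, center: tuple, diameter: int) -> np.ndarray:
    h, w = shape
    cx, cy = center
    r = diameter / 2.0
    if cx - r < 0 or cy - r < 0 or cx + r > w or cy + r > h:
        raise ValueError(f"ROI at {center} (d={diameter}) extends outside the {w}x{h} image")
    yy, xx = np.ogrid[:h, :w]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2


def sobel_index(image: np.ndarray, center: tuple, diameter: int = 100) -> float:
    """Sum of the Sobel gradient magnitude over one circular ROI.

    3x3 kernels in both directions, replicate padding at the borders.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("sobel_index expects a single-channel image")
    mask = _roi_mask(img.shape, center, diameter)
    sx = correlate(img, SOBEL_X, mode="nearest")
    sy = correlate(img, SOBEL_Y, mode="nearest")
    return float(np.hypot(sx, sy)[mask].sum())


def laplacian_index(image: np.ndarray, center: tuple, diameter: int = 100) -> float:
    """Sum of |Laplacian| (3x3 kernel, replicate padding) over one ROI."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("laplacian_index expects a single-channel image")
    mask = _roi_mask(img.shape, center, diameter)
    lap = correlate(img, LAPLACIAN, mode="nearest")
    return float(np.abs(lap)[mask].sum())


def canny_index(image: np.ndarray, center: tuple, diameter: int = 100) -> float:
    """Sum of the {0,255} Canny edge map over one ROI.

    Hysteresis limits are sigma and 3*sigma, where sigma is the standard
    deviation of the FULL image (self-adjusting to scene illumination).
    A constant image has sigma 0 and scores 0.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("canny_index expects a single-channel image")
    mask = _roi_mask(img.shape, center, diameter)
    sigma_img = float(img.std())
    if sigma_img == 0.0:
        return 0.0
    edges = _canny(img, low_threshold=sigma_img, high_threshold=3.0 * sigma_img)
    return float(255.0 * edges[mask].sum())


_INDEX_FN = {"sobel": sobel_index, "laplacian": laplacian_index, "canny": canny_index}


def compute_indexes(
    frame: np.ndarray,
    rois: Optional[RoiSpec] = None,
    operators: Sequence[str] = OPERATORS,
) -> dict:
    """All requested indexes on the red channel: {operator: (roi1, roi2, roi3)}.

    Gradient images are computed once per frame and shared across ROIs.
    """
    img = red_channel(frame)
    h, w = img.shape
    rois = rois or default_rois(w, h)
    out: dict[str, tuple] = {}
    precomputed: dict[str, np.ndarray] = {}
    for op in operators:
        if op not in OPERATORS:
            raise ValueError(f"unknown operator {op!r}")
        if op == "sobel":
            sx = correlate(img, SOBEL_X, mode="nearest")
            sy = correlate(img, SOBEL_Y, mode="nearest")
            precomputed[op] = np.hypot(sx, sy)
        elif op == "laplacian":
            precomputed[op] = np.abs(correlate(img, LAPLACIAN, mode="nearest"))
        else:
            sigma_img = float(img.std())
            if sigma_img == 0.0:
                precomputed[op] = np.zeros_like(img)
            else:
                precomputed[op] = 255.0 * _canny(
                    img, low_threshold=sigma_img, high_threshold=3.0 * sigma_img
                )
    for op in operators:
        vals = []
        for center in rois.centers:
            mask = _roi_mask(img.shape, center, rois.diameter)
            vals.append(float(precomputed[op][mask].sum()))
        out[op] = tuple(vals)
    return out


def accept_frame(
    roi_indexes: Sequence[float],
    thresholds: SharpnessThresholds = SharpnessThresholds(),
    operator: str = "laplacian",
) -> bool:
    """Accept iff ANY ROI index is strictly above the operator's threshold."""
    thr = thresholds.for_operator(operator)
    return bool(any(v > thr for v in roi_indexes))


def _load(frame) -> np.ndarray:
    if isinstance(frame, np.ndarray):
        return frame
    import imageio.v3 as iio

    return iio.imread(frame)


def select_frames(
    source: FrameSource,
    frame_range: Optional[tuple[int, int]] = None,
    thresholds: SharpnessThresholds = SharpnessThresholds(),
    operator: str = "laplacian",
    retention: float = 0.2,
    rois: Optional[RoiSpec] = None,
) -> FrameSelection:
    """Quality-check and down-select the trimmed frames of one scan.

    The beginning, middle and end frames of the trimmed range are scored
    first; if all three fail the sharpness test the whole video is flagged
    for re-acquisition.  Otherwise the accepted QC-range frames are
    uniformly subsampled to the retention fraction (default 20 %, the share
    needed by downstream fruit-detection), rounding the count to nearest.
    """
    if not 0 < retention <= 1:
        raise ValueError("retention must lie in (0, 1]")
    f0, f1 = frame_range if frame_range is not None else (0, len(source))
    f0, f1 = max(0, f0), min(len(source), f1)
    if f1 <= f0:
        raise ValueError("empty frame range")
    qc = (f0, f0 + (f1 - f0) // 2, f1 - 1)
    qc = tuple(dict.fromkeys(qc))  # dedupe for tiny ranges, keep order

    reports = []
    any_sharp = False
    for fid in qc:
        idx = compute_indexes(_load(source.frames[fid]), rois)
        ok = accept_frame(idx[operator], thresholds, operator)
        any_sharp = any_sharp or ok
        reports.append(
            SharpnessReport(
                frame_id=fid,
                idx_sobel=idx["sobel"],
                idx_laplacian=idx["laplacian"],
                idx_canny=idx["canny"],
                accepted=ok,
                operator_used=operator,
            )
        )
    if not any_sharp:
        return FrameSelection(selected=[], reports=reports, reacquire=True, qc_frames=qc)

    n_total = f1 - f0
    n_keep = max(1, int(round(retention * n_total)))
    picks = f0 + np.round(np.linspace(0, n_total - 1, n_keep)).astype(int)
    return FrameSelection(
        selected=sorted(set(picks.tolist())),
        reports=reports,
        reacquire=False,
        qc_frames=qc,
    )
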
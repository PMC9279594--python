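"""Fluorescence quantification: per-cell relative telomere length and CTCF.

Relative telomere length (RTL) is measured on background-subtracted
quantitative-FISH images: telomeric spots inside a per-cell region of
interest are segmented by thresholding and 8-connected labelling, and the
cell's RTL is the sum over spots of mean spot intensity times spot area, in
arbitrary units. Corrected total cell fluorescence (CTCF) quantifies diffuse
staining (e.g. a mitochondrial dye) as the integrated density over the cell
ROI minus the cell area times the mean intensity of user-drawn background
ROIs.

ROIs use 0-based, row-major pixel coordinates; rectangles and run-length
masks are half-open, polygons follow the usual point-in-polygon rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage import draw as skdraw
from skimage import measure as skmeasure

from .stats import MultipleRangeResult, multiple_range_bonferroni

__all__ = [
    "RoiSpec",
    "SpotMeasure",
    "CellRTL",
    "subtract_background",
    "detect_spots",
    "compute_rtl",
    "compute_ctcf",
    "compare_rtl_groups",
]


@dataclass(frozen=True)
class RoiSpec:
    """A region of interest for one cell, as rectangle, polygon or run-length mask.

    Exactly one of ``rect`` ((r0, c0, r1, c1), half-open), ``polygon``
    (vertex list [[r, c], ...]) or ``runs`` ([[row, c0, c1], ...], half-open)
    must be given.
    """

    cell_id: str
    rect: tuple[int, int, int, int] | None = None
    polygon: tuple[tuple[float, float], ...] | None = None
    runs: tuple[tuple[int, int, int], ...] | None = None

    def __post_init__(self) -> None:
        given = sum(x is not None for x in (self.rect, self.polygon, self.runs))
        if given != 1:
            raise ValueError("RoiSpec needs exactly one of rect, polygon or runs")
        if self.rect is not None:
            object.__setattr__(self, "rect", tuple(int(v) for v in self.rect))
            r0, c0, r1, c1 = self.rect
            if r1 <= r0 or c1 <= c0:
                raise ValueError(f"degenerate rectangle {self.rect}")
        if self.polygon is not None:
            object.__setattr__(
                self, "polygon", tuple((float(r), float(c)) for r, c in self.polygon)
            )
            if len(self.polygon) < 3:
                raise ValueError("polygon needs at least 3 vertices")
        if self.runs is not None:
            object.__setattr__(
                self, "runs", tuple((int(r), int(a), int(b)) for r, a, b in self.runs)
            )

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean pixel mask of this ROI on an image of the given shape."""
        h, w = shape
        out = np.zeros(shape, dtype=bool)
        if self.rect is not None:
            r0, c0, r1, c1 = self.rect
            if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
                raise ValueError(f"rectangle {self.rect} exceeds image bounds {shape}")
            out[r0:r1, c0:c1] = True
        elif self.polygon is not None:
            out = skdraw.polygon2mask(shape, np.asarray(self.polygon))
        else:
            for r, a, b in self.runs:
                if r < 0 or r >= h or a < 0 or b > w or b <= a:
                    raise ValueError(f"run ({r}, {a}, {b}) exceeds image bounds {shape}")
                out[r, a:b] = True
        if not out.any():
            raise ValueError(f"ROI {self.cell_id!r} covers no pixels on shape {shape}")
        return out

    def to_dict(self) -> dict:
        d: dict = {"cell_id": self.cell_id}
        if self.rect is not None:
            d["rect"] = list(self.rect)
        if self.polygon is not None:
            d["polygon"] = [list(v) for v in self.polygon]
        if self.runs is not None:
            d["runs"] = [list(v) for v in self.runs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RoiSpec":
        return cls(
            cell_id=str(d["cell_id"]),
            rect=tuple(d["rect"]) if "rect" in d else None,
            polygon=tuple(map(tuple, d["polygon"])) if "polygon" in d else None,
            runs=tuple(map(tuple, d["runs"])) if "runs" in d else None,
        )


@dataclass(frozen=True)
class SpotMeasure:
    """One segmented telomeric signal: area and (background-subtracted) mean intensity."""

    spot_id: int
    cell_id: str
    area: int
    mean_intensity: float

    @property
    def integrated(self) -> float:
        return self.mean_intensity * self.area


@dataclass(frozen=True)
class CellRTL:
    cell_id: str
    rtl: float
    n_spots: int


def subtract_background(
    signal_image: np.ndarray,
    background: float | np.ndarray,
    exclude_rois: Sequence[RoiSpec] = (),
) -> np.ndarray:
    """Subtract a background estimate from a signal image, clipping at zero.

    ``background`` is either a scalar level or a matched reference-channel
    image, in which case the estimate is the median of reference pixels
    outside the given (e.g. nuclear) ROIs.
    """
    img = np.asarray(signal_image, dtype=float)
    if np.ndim(background) == 0:
        est = float(background)
    else:
        ref = np.asarray(background, dtype=float)
        if ref.shape != img.shape:
            raise ValueError(f"shape mismatch: signal {img.shape} vs reference {ref.shape}")
        outside = np.ones(ref.shape, dtype=bool)
        for roi in exclude_rois:
            outside &= ~roi.mask(ref.shape)
        if not outside.any():
            raise ValueError("ROIs cover the whole reference image; no background pixels left")
        est = float(np.median(ref[outside]))
    return np.clip(img - est, 0.0, None)


def detect_spots(
    image: np.ndarray,
    roi: RoiSpec,
    threshold: float | None = None,
    min_area: int = 2,
) -> list[SpotMeasure]:
    """Segment telomeric spots inside a cell ROI.

    Pixels strictly above ``threshold`` within the ROI are grouped into
    8-connected components; components of at least ``min_area`` pixels are
    reported with their area and mean intensity. When ``threshold`` is None
    it defaults to mean + 3 SD of the ROI pixels, a robust cut for sparse
    bright spots on a dim nucleus.
    """
    img = np.asarray(image, dtype=float)
    mask = roi.mask(img.shape)
    pixels = img[mask]
    if threshold is None:
        threshold = float(pixels.mean() + 3.0 * pixels.std())
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    fg = (img > threshold) & mask
    labels = skmeasure.label(fg, connectivity=2)
    spots: list[SpotMeasure] = []
    for region in skmeasure.regionprops(labels, intensity_image=img):
        if region.area < min_area:
            continue
        spots.append(
            SpotMeasure(
                spot_id=len(spots),
                cell_id=roi.cell_id,
                area=int(region.area),
                mean_intensity=float(region.intensity_mean),
            )
        )
    return spots


def compute_rtl(spots: Sequence[SpotMeasure], cell_id: str) -> CellRTL:
    """Per-cell relative telomere length: sum of mean intensity x area over spots."""
    wrong = [s.cell_id for s in spots if s.cell_id != cell_id]
    if wrong:
        raise ValueError(f"spots from other cells present: {sorted(set(wrong))}")
    rtl = float(sum(s.integrated for s in spots))
    return CellRTL(cell_id=cell_id, rtl=rtl, n_spots=len(spots))


def compute_ctcf(
    image: np.ndarray,
    cell_roi: RoiSpec,
    background_rois: Sequence[RoiSpec],
) -> float:
    """Corrected total cell fluorescence.

    CTCF = integrated density over the cell ROI minus (cell area x mean of
    the pooled background-ROI pixels). Negative values are reported as-is.
    """
    img = np.asarray(image, dtype=float)
    cell_mask = cell_roi.mask(img.shape)
    if not background_rois:
        raise ValueError("at least one background ROI is required")
    bg_mask = np.zeros(img.shape, dtype=bool)
    for roi in background_rois:
        m = roi.mask(img.shape)
        if (m & cell_mask).any():
            raise ValueError(f"background ROI {roi.cell_id!r} overlaps the cell ROI")
        bg_mask |= m
    integrated = float(img[cell_mask].sum())
    area = int(cell_mask.sum())
    bg_mean = float(img[bg_mask].mean())
    return integrated - area * bg_mean


def compare_rtl_groups(
    rtl_by_condition: Sequence[Sequence[float]], alpha: float = 0.05
) -> MultipleRangeResult:
    """Bonferroni multiple-range comparison of per-cell RTL values across conditions."""
    groups = [list(g) for g in rtl_by_condition]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 conditions with >= 2 cells each")
    return multiple_range_bonferroni(groups, alpha=alpha)
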
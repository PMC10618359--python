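"""From raw photograph to a square, tightly cropped object image.

The pipeline mirrors how single dried mushrooms are photographed on a white
balance card: grayscale conversion, adaptive (OOA-Otsu) binarization, external
contour extraction, largest-contour filtering (cap-texture fragments and
residue speckles are discarded), minimum outer rectangle, adjustment to a
minimum outer *square* so later resizing cannot distort the object's aspect
ratio, and finally a crop of the original color image.

Coordinates are 0-based (row, col); boxes are half-open:
[x0, x0+width) × [y0, y0+height) in column/row pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .thresholding import OOAConfig, ThresholdResult, apply_threshold, ooa_otsu_threshold

__all__ = [
    "Contour",
    "BoundingBox",
    "SquareROI",
    "to_grayscale",
    "extract_contours",
    "select_main_contour",
    "square_roi",
    "crop",
    "segment_mushroom",
]

#: ITU-R BT.601 luma weights — the dominant grayscale convention in imaging toolkits.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned minimum outer rectangle; ``x0``/``y0`` is the top-left corner."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("box must be at least 1×1")


@dataclass(frozen=True)
class SquareROI:
    """Adjusted minimum outer square; ``clipped`` marks a side reduced to fit."""

    x0: int
    y0: int
    side: int
    clipped: bool = False


@dataclass(frozen=True)
class Contour:
    """External boundary of one 8-connected foreground component.

    ``points`` is the ordered (row, col) boundary polygon; ``area`` its
    shoelace area in px²; ``bbox`` the pixel bounding box of the component
    the boundary encloses.
    """

    points: np.ndarray
    area: float
    bbox: BoundingBox
    is_external: bool = True

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise ValueError("a contour needs at least 3 points")
        if self.area < 0:
            raise ValueError("contour area must be >= 0")


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """BT.601 luma: round(0.299·R + 0.587·G + 0.114·B), clipped to [0, 255]."""
    arr = np.asarray(rgb)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 image, got shape {arr.shape}")
    gray = np.rint(arr.astype(np.float64) @ _LUMA)
    return np.clip(gray, 0, 255).astype(np.uint8)


def _shoelace(points: np.ndarray) -> float:
    r, c = points[:, 0], points[:, 1]
    return 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))


def extract_contours(mask: np.ndarray) -> list[Contour]:
    """External boundaries of the 8-connected foreground components.

    Hole (nested) contours are not returned; the texture fragments inside the
    cap are irrelevant to localization.  Returns an empty list for an empty
    mask.
    """
    mask = np.asarray(mask).astype(bool)
    labels = measure.label(mask, connectivity=2)
    contours: list[Contour] = []
    for region in measure.regionprops(labels):
        r0, c0, r1, c1 = region.bbox
        comp = np.pad(labels[r0:r1, c0:c1] == region.label, 1)
        # the longest 0.5-level curve of the padded component is its outer boundary
        curves = measure.find_contours(comp.astype(float), 0.5)
        outer = max(curves, key=len)
        points = outer + np.array([r0 - 1, c0 - 1])
        bbox = BoundingBox(x0=c0, y0=r0, width=c1 - c0, height=r1 - r0)
        contours.append(Contour(points=points, area=_shoelace(points), bbox=bbox))
    return contours


def select_main_contour(contours: list[Contour]) -> Contour:
    """The contour of maximum area; speckle residues around the object lose."""
    if not contours:
        raise ValueError("no foreground found")
    return max(contours, key=lambda c: c.area)


def square_roi(box: BoundingBox, image_shape: tuple[int, int]) -> SquareROI:
    """Adjust a bounding box to the minimum outer square that fits the image.

    The square has side max(width, height), centered on the box center
    (corner = floor(center − side/2)).  If it crosses an image edge it is
    shifted inward; if the side exceeds the smaller image dimension it is
    reduced to that dimension and flagged ``clipped``.
    """
    h, w = image_shape[:2]
    side = max(box.width, box.height)
    clipped = False
    if side > min(h, w):
        side = min(h, w)
        clipped = True
    cx = box.x0 + box.width / 2.0
    cy = box.y0 + box.height / 2.0
    x0 = int(np.floor(cx - side / 2.0))
    y0 = int(np.floor(cy - side / 2.0))
    x0 = min(max(x0, 0), w - side)
    y0 = min(max(y0, 0), h - side)
    return SquareROI(x0=x0, y0=y0, side=side, clipped=clipped)


def crop(image: np.ndarray, roi: SquareROI) -> np.ndarray:
    """Pixel-identical side×side crop of ``image`` at ``roi``."""
    arr = np.asarray(image)
    h, w = arr.shape[:2]
    if roi.x0 < 0 or roi.y0 < 0 or roi.x0 + roi.side > w or roi.y0 + roi.side > h:
        raise ValueError(f"ROI {roi} out of bounds for image {h}×{w}")
    return arr[roi.y0 : roi.y0 + roi.side, roi.x0 : roi.x0 + roi.side].copy()


def segment_mushroom(
    rgb: np.ndarray,
    config: OOAConfig | None = None,
    margin: int = 0,
) -> tuple[np.ndarray, SquareROI, ThresholdResult]:
    """Locate and crop the object from a color photograph.

    Composition of grayscale → OOA-Otsu threshold → dark-foreground mask →
    external contours → largest contour → minimum outer rectangle (optionally
    enlarged by ``margin`` px on every side) → minimum outer square → crop of
    the ORIGINAL color image.  Deterministic given the threshold seed.

    Returns
    -------
    (crop, roi, threshold_result)

    Raises
    ------
    ValueError
        "no foreground found" when the binarized mask is empty (e.g. a blank
        background image).
    """
    arr = np.asarray(rgb)
    gray = to_grayscale(arr)
    tres = ooa_otsu_threshold(gray, config)
    if tres.degenerate:
        raise ValueError("no foreground found")
    mask = apply_threshold(gray, tres.threshold)
    contours = extract_contours(mask)
    main = select_main_contour(contours)
    box = main.bbox
    if margin:
        h, w = gray.shape
        x0 = max(box.x0 - margin, 0)
        y0 = max(box.y0 - margin, 0)
        x1 = min(box.x0 + box.width + margin, w)
        y1 = min(box.y0 + box.height + margin, h)
        box = BoundingBox(x0=x0, y0=y0, width=x1 - x0, height=y1 - y0)
    roi = square_roi(box, gray.shape)
    return crop(arr, roi), roi, tres
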
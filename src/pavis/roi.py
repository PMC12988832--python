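"""Constrained brightest-pixel ROI placement.

The target ROI (default 3 mm lateral x 0.6 mm axial) starts centered on
the brightest photoacoustic pixel inside a search region (typically the
intersection of the ureter and signal masks).  If the initial ROI is not
entirely contained in the ureter mask, it is iteratively moved one pixel
at a time through eight directional offsets — evaluated in the fixed order
left, right, proximal (shallower), distal (deeper), then the four
diagonals — accepting the first admissible move that strictly increases
the number of ROI pixels inside the mask, until the ROI is fully
contained.  Admissibility requires the ROI to stay within the image, keep
the brightest pixel inside, and intersect the ureter mask.  The matched
background ROI shares the target's rows (same depth) and sits at a fixed
lateral margin from the right image edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import ImageGrid

__all__ = [
    "ROI",
    "RoiPlacementError",
    "find_brightest_pixel",
    "place_target_roi",
    "place_background_roi",
    "roi_size_px",
]

DEFAULT_ROI_LATERAL_MM = 3.0
DEFAULT_ROI_AXIAL_MM = 0.6
BACKGROUND_MARGIN_MM = 0.54

# candidate offsets as (drow, dcol): left, right, proximal, distal,
# left-proximal, left-distal, right-proximal, right-distal
_OFFSETS = ((0, -1), (0, 1), (-1, 0), (1, 0), (-1, -1), (1, -1), (-1, 1), (1, 1))


class RoiPlacementError(ValueError):
    """No admissible ROI position exists (or the search stalled)."""


@dataclass(frozen=True)
class ROI:
    """Rectangular pixel region; rows ``row0..row0+height_px-1``."""

    row0: int
    col0: int
    height_px: int
    width_px: int
    role: str = "target"

    @property
    def rows(self) -> slice:
        return slice(self.row0, self.row0 + self.height_px)

    @property
    def cols(self) -> slice:
        return slice(self.col0, self.col0 + self.width_px)

    def contains(self, row: int, col: int) -> bool:
        return (
            self.row0 <= row < self.row0 + self.height_px
            and self.col0 <= col < self.col0 + self.width_px
        )

    def within(self, shape: tuple[int, int]) -> bool:
        return (
            self.row0 >= 0
            and self.col0 >= 0
            and self.row0 + self.height_px <= shape[0]
            and self.col0 + self.width_px <= shape[1]
        )

    def extract(self, image: np.ndarray) -> np.ndarray:
        if not self.within(image.shape):
            raise ValueError("ROI extends beyond image bounds")
        return image[self.rows, self.cols]


def roi_size_px(
    grid: ImageGrid,
    lateral_mm: float = DEFAULT_ROI_LATERAL_MM,
    axial_mm: float = DEFAULT_ROI_AXIAL_MM,
) -> tuple[int, int]:
    """(height_px, width_px) of a physical ROI on ``grid``, rounded to
    whole pixels (minimum 1)."""
    dz, dx = grid.pixel_size_mm
    h = max(1, round(axial_mm / dz))
    w = max(1, round(lateral_mm / dx))
    return h, w


def find_brightest_pixel(
    envelope: np.ndarray, search_mask: np.ndarray
) -> tuple[int, int]:
    """Argmax of the envelope restricted to ``search_mask``; ties broken
    by smallest row, then smallest column."""
    envelope = np.asarray(envelope, dtype=float)
    search_mask = np.asarray(search_mask, dtype=bool)
    if envelope.shape != search_mask.shape:
        raise ValueError("envelope and mask shapes differ")
    if not search_mask.any():
        raise RoiPlacementError("no valid search region: empty mask")
    masked = np.where(search_mask, envelope, -np.inf)
    # np.argmax on the flattened array returns the first (row-major)
    # maximum, which is exactly smallest-row-then-smallest-column
    idx = int(np.argmax(masked))
    return np.unravel_index(idx, envelope.shape)  # type: ignore[return-value]


def _centered(bright: tuple[int, int], h: int, w: int) -> tuple[int, int]:
    # even sizes put the extra pixel toward larger index
    return bright[0] - (h - 1) // 2, bright[1] - (w - 1) // 2


def _feasible_positions_exist(
    mask_cumsum: np.ndarray, bright: tuple[int, int], h: int, w: int,
    shape: tuple[int, int],
) -> bool:
    """Exhaustive check: does any in-bounds ROI containing the brightest
    pixel lie entirely inside the mask?  Uses a summed-area table."""
    br, bc = bright
    for r0 in range(max(0, br - h + 1), min(br, shape[0] - h) + 1):
        for c0 in range(max(0, bc - w + 1), min(bc, shape[1] - w) + 1):
            if _rect_sum(mask_cumsum, r0, c0, h, w) == h * w:
                return True
    return False


def _rect_sum(cumsum: np.ndarray, r0: int, c0: int, h: int, w: int) -> int:
    """Sum of a mask rectangle from a zero-padded 2-D cumulative sum."""
    return int(
        cumsum[r0 + h, c0 + w] - cumsum[r0, c0 + w] - cumsum[r0 + h, c0] + cumsum[r0, c0]
    )


def place_target_roi(
    ureter_mask: np.ndarray,
    brightest: tuple[int, int],
    roi_height_px: int,
    roi_width_px: int,
    max_iter: int = 10000,
) -> ROI:
    """Place the target ROI by the greedy eight-direction walk.

    Starts centered on ``brightest``; while not fully contained in
    ``ureter_mask``, moves to the first one-pixel offset (fixed order:
    left, right, proximal, distal, left-proximal, left-distal,
    right-proximal, right-distal) that is admissible — in bounds, keeps
    the brightest pixel inside, intersects the mask — and strictly
    increases the in-mask pixel count.  Raises :class:`RoiPlacementError`
    when no fully contained position containing the brightest pixel exists
    or the walk stalls.
    """
    mask = np.asarray(ureter_mask, dtype=bool)
    shape = mask.shape
    br, bc = brightest
    if not (0 <= br < shape[0] and 0 <= bc < shape[1]) or not mask[br, bc]:
        raise RoiPlacementError("brightest pixel is not inside the ureter mask")
    h, w = roi_height_px, roi_width_px
    if h < 1 or w < 1:
        raise ValueError("ROI size must be at least 1x1 pixels")

    cum = np.zeros((shape[0] + 1, shape[1] + 1), dtype=np.int64)
    cum[1:, 1:] = np.cumsum(np.cumsum(mask, axis=0), axis=1)

    if not _feasible_positions_exist(cum, brightest, h, w, shape):
        raise RoiPlacementError(
            "no valid ROI: no position containing the brightest pixel "
            "fits entirely inside the ureter mask"
        )

    r0, c0 = _centered(brightest, h, w)
    # initial position may hang off the image; clamp into bounds while
    # keeping the brightest pixel inside the ROI
    r0 = min(max(r0, 0, br - h + 1), shape[0] - h, br)
    c0 = min(max(c0, 0, bc - w + 1), shape[1] - w, bc)

    def in_mask(r: int, c: int) -> int:
        return _rect_sum(cum, r, c, h, w)

    current = in_mask(r0, c0)
    visited = {(r0, c0)}
    for _ in range(max_iter):
        if current == h * w:
            return ROI(row0=r0, col0=c0, height_px=h, width_px=w, role="target")
        moved = False
        for dr, dc in _OFFSETS:
            nr, nc = r0 + dr, c0 + dc
            cand = ROI(nr, nc, h, w)
            if not cand.within(shape):
                continue
            if not cand.contains(br, bc):
                continue
            score = in_mask(nr, nc)
            if score == 0:
                continue
            if score > current:
                r0, c0, current = nr, nc, score
                if (r0, c0) in visited:
                    raise RoiPlacementError("no valid ROI: search revisited a position")
                visited.add((r0, c0))
                moved = True
                break
        if not moved:
            raise RoiPlacementError("no valid ROI: no admissible improving move")
    raise RoiPlacementError("no valid ROI: iteration limit reached")


def place_background_roi(
    target: ROI,
    image_shape: tuple[int, int],
    pitch_mm: float = 0.09,
    margin_mm: float = BACKGROUND_MARGIN_MM,
) -> ROI:
    """Background ROI of identical size at the same depth (rows) as the
    target, with its right edge ``margin_mm`` from the right image edge."""
    margin_px = round(margin_mm / pitch_mm)
    col0 = image_shape[1] - margin_px - target.width_px
    if col0 < 0:
        raise ValueError("image too narrow for background ROI plus margin")
    bg = ROI(
        row0=target.row0,
        col0=col0,
        height_px=target.height_px,
        width_px=target.width_px,
        role="background",
    )
    if not bg.within(image_shape):
        raise ValueError("background ROI does not fit in the image")
    return bg
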
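"""Segmentation-driven frame retention and stationary-duplicate exclusion.

A frame is retained when its segmented photoacoustic signal region overlaps
the segmented ureter lumen by at least ``min_overlap_px`` pixels (default
one pixel), indicating effective light delivery to the ureter within the
imaging plane.  Consecutive near-identical frames — high signal-mask IoU
combined with near-perfect envelope correlation inside the mask union —
are flagged as stationary duplicates and excluded from analysis sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import ImageGrid

__all__ = ["MaskPair", "retain_frame", "flag_stationary_duplicates"]


@dataclass
class MaskPair:
    """Coregistered binary masks on the image grid: ureter lumen (from
    B-mode) and photoacoustic signal region."""

    ureter_mask: np.ndarray
    signal_mask: np.ndarray
    grid: ImageGrid | None = None
    frame_id: str = "frame"

    def __post_init__(self) -> None:
        u = np.asarray(self.ureter_mask)
        s = np.asarray(self.signal_mask)
        if u.shape != s.shape:
            raise ValueError(
                f"mask shapes differ: ureter {u.shape} vs signal {s.shape}"
            )
        for name, m in (("ureter", u), ("signal", s)):
            vals = np.unique(m)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"{name} mask is not binary")
        self.ureter_mask = u.astype(bool)
        self.signal_mask = s.astype(bool)


def retain_frame(masks: MaskPair, min_overlap_px: int = 1) -> tuple[bool, int]:
    """Return ``(retained, overlap_px)`` for one frame.

    Retained iff the pixelwise intersection of the ureter and signal masks
    has at least ``min_overlap_px`` pixels.
    """
    if min_overlap_px < 1:
        raise ValueError("min_overlap_px must be >= 1")
    overlap = int(np.count_nonzero(masks.ureter_mask & masks.signal_mask))
    return overlap >= min_overlap_px, overlap


def flag_stationary_duplicates(
    masks: list[MaskPair],
    envelopes: list[np.ndarray],
    iou_threshold: float = 0.95,
    corr_threshold: float = 0.99,
    manual_exclusions: set[str] | None = None,
) -> list[bool]:
    """Flag frames that are stationary copies of the previous kept frame.

    A frame is flagged when its signal mask's intersection-over-union with
    the previous unflagged frame's signal mask exceeds ``iou_threshold``
    AND the Pearson correlation of the two envelope images inside the mask
    union exceeds ``corr_threshold``.  Frames listed in
    ``manual_exclusions`` (by frame_id) are always flagged.

    Flagging is idempotent: re-running on the surviving frames flags
    nothing new, because comparisons are always against the previous
    *unflagged* frame.
    """
    if len(masks) != len(envelopes):
        raise ValueError("masks and envelopes must have equal length")
    if len(masks) == 0:
        return []
    shape = masks[0].signal_mask.shape
    for m, e in zip(masks, envelopes):
        if m.signal_mask.shape != shape or np.asarray(e).shape != shape:
            raise ValueError("all frames must share a common grid")
    manual_exclusions = manual_exclusions or set()

    flags = [False] * len(masks)
    prev = None  # index of previous unflagged frame
    for i, (m, env) in enumerate(zip(masks, envelopes)):
        if m.frame_id in manual_exclusions:
            flags[i] = True
            continue
        if prev is not None:
            a = masks[prev].signal_mask
            b = m.signal_mask
            union = a | b
            n_union = np.count_nonzero(union)
            if n_union > 0:
                iou = np.count_nonzero(a & b) / n_union
                if iou > iou_threshold:
                    ea = np.asarray(envelopes[prev], dtype=float)[union]
                    eb = np.asarray(env, dtype=float)[union]
                    if ea.size >= 2 and ea.std() > 0 and eb.std() > 0:
                        corr = float(np.corrcoef(ea, eb)[0, 1])
                    else:
                        # constant patches: identical means stationary
                        corr = 1.0 if np.allclose(ea, eb) else 0.0
                    if corr > corr_threshold:
                        flags[i] = True
                        continue
        prev = i
    return flags
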
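"""ROI-based image quality metrics: contrast, SNR, and gCNR.

All three are computed on normalized envelope amplitudes (pre-log, in
[0, 1]) sampled from a target and a background ROI:

* contrast = 20 log10(mu_t / mu_b), in dB;
* SNR = mu_t / sigma_b (sample standard deviation, n-1 denominator);
* gCNR = 1 - sum_k min(h_t(x_k), h_b(x_k)) over N shared equal-width
  probability-mass histogram bins spanning [0, 1] (default N = 256).

gCNR is bounded in [0, 1] and invariant to any invertible remapping of
the amplitude scale applied jointly to both ROIs (with correspondingly
remapped bins), which makes it insensitive to dynamic-range choices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MetricRecord",
    "contrast_db",
    "snr",
    "gcnr",
    "compute_frame_metrics",
    "N_BINS_DEFAULT",
]

N_BINS_DEFAULT = 256


@dataclass(frozen=True)
class MetricRecord:
    """Image-quality metrics of one retained frame."""

    contrast_db: float
    snr: float
    gcnr: float
    frame_id: str = "frame"
    time_point_min: float = 0.0


def _validate(samples: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError(f"{name} sample set is empty")
    if not np.isfinite(x).all():
        raise ValueError(f"{name} samples contain non-finite values")
    return x


def contrast_db(target, background) -> float:
    """20 log10 of the mean-amplitude ratio between target and background."""
    t = _validate(target, "target")
    b = _validate(background, "background")
    mu_b = b.mean()
    if mu_b <= 0:
        raise ValueError("degenerate background: mean amplitude is not positive")
    return float(20.0 * np.log10(t.mean() / mu_b))


def snr(target, background) -> float:
    """Target mean over background sample standard deviation (ddof=1)."""
    t = _validate(target, "target")
    b = _validate(background, "background")
    if b.size < 2:
        raise ValueError("background needs at least 2 samples for a standard deviation")
    sigma_b = b.std(ddof=1)
    if sigma_b == 0:
        raise ValueError("degenerate background: zero standard deviation")
    return float(t.mean() / sigma_b)


def gcnr(target, background, n_bins: int = N_BINS_DEFAULT) -> float:
    """Generalized contrast-to-noise ratio.

    Probability-mass histograms of both sample sets are built over
    ``n_bins`` shared equal-width bins spanning [0, 1] (amplitude 1.0
    falls in the last bin); the result is one minus their overlap.
    """
    t = _validate(target, "target")
    b = _validate(background, "background")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if t.min() < 0 or t.max() > 1 or b.min() < 0 or b.max() > 1:
        raise ValueError("samples must lie in [0, 1] (normalized envelope)")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    ht = np.histogram(t, bins=edges)[0] / t.size
    hb = np.histogram(b, bins=edges)[0] / b.size
    return float(1.0 - np.minimum(ht, hb).sum())


def compute_frame_metrics(
    image,
    target_roi,
    background_roi,
    n_bins: int = N_BINS_DEFAULT,
) -> MetricRecord:
    """Extract normalized-envelope samples from both ROIs of a
    :class:`~pavis.beamform.BeamformedImage` and compute all three metrics."""
    env = image.envelope
    try:
        t = target_roi.extract(env).ravel()
        b = background_roi.extract(env).ravel()
        return MetricRecord(
            contrast_db=contrast_db(t, b),
            snr=snr(t, b),
            gcnr=gcnr(t, b, n_bins=n_bins),
            frame_id=image.frame_id,
            time_point_min=image.time_point_min,
        )
    except ValueError as exc:
        raise ValueError(f"frame {image.frame_id!r}: {exc}") from exc
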
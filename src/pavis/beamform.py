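"""Delay-and-sum image formation for photoacoustic channel data.

Reconstruction is receive-only: a photoacoustic source emits at t = 0, so
the delay from pixel (x, z) to element e is the one-way time of flight
``sqrt(z^2 + (x - x_e)^2) / c``.  Channel samples are linearly
interpolated at the delayed times and summed across the full aperture with
uniform apodization.  The summed RF image is envelope-detected via the
analytic-signal magnitude along depth, normalized to the brightest pixel,
and log-compressed (20 log10) for display within a stated dynamic range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .acquisition import AcquisitionParams, ChannelFrame, ImageGrid

__all__ = [
    "BeamformedImage",
    "das_beamform",
    "envelope_detect",
    "normalize_log_compress",
    "bandpass_filter",
    "beamform_frame",
]


@dataclass
class BeamformedImage:
    """Reconstructed image triplet on a pixel grid.

    ``envelope`` is normalized to the brightest pixel (max 1 for any
    non-all-zero input); ``bmode_db`` is 20*log10(envelope) clipped at
    ``-dynamic_range_db``.
    """

    rf: np.ndarray
    envelope: np.ndarray
    bmode_db: np.ndarray
    grid: ImageGrid
    dynamic_range_db: float
    time_point_min: float = 0.0
    frame_id: str = "frame"


def das_beamform(
    frame: ChannelFrame,
    grid: ImageGrid | None = None,
    apodization: np.ndarray | None = None,
    f_number: float | None = None,
) -> np.ndarray:
    """Delay-and-sum the channel data of ``frame`` onto ``grid``.

    Parameters
    ----------
    frame : ChannelFrame
        Raw RF channel data with acquisition parameters.
    grid : ImageGrid, optional
        Reconstruction grid; defaults to the natural grid (one column per
        element, axial spacing c/fs).
    apodization : ndarray of shape (n_elements,), optional
        Receive weights; default uniform (all ones).
    f_number : float, optional
        If given, element e contributes to pixel (x, z) only when
        ``|x - x_e| <= z / (2 * f_number)``; default no gating.

    Returns
    -------
    ndarray
        Summed RF image of shape ``grid.shape``. Samples delayed outside
        the recorded window contribute zero.
    """
    params = frame.params
    grid = grid or ImageGrid.from_params(params)
    xe = params.element_positions_mm
    if apodization is None:
        apodization = np.ones(params.n_elements)
    apodization = np.asarray(apodization, dtype=float)
    if apodization.shape != (params.n_elements,):
        raise ValueError("apodization must have one weight per element")

    c_mm_s = params.speed_of_sound_m_s * 1e3
    fs = params.sampling_frequency_hz
    z = grid.axial_mm[:, None]  # (nz, 1)
    x = grid.lateral_mm[None, :]  # (1, nx)
    n_samp = frame.data.shape[0]

    rf = np.zeros(grid.shape)
    for e in range(params.n_elements):
        if apodization[e] == 0.0:
            continue
        dx = x - xe[e]
        idx = np.sqrt(z**2 + dx**2) / c_mm_s * fs  # fractional sample index
        i0 = np.floor(idx).astype(np.int64)
        w = idx - i0
        valid = (i0 >= 0) & (i0 < n_samp - 1)
        i0c = np.clip(i0, 0, n_samp - 2)
        line = frame.data[:, e]
        contrib = np.where(valid, (1.0 - w) * line[i0c] + w * line[i0c + 1], 0.0)
        if f_number is not None:
            contrib = np.where(np.abs(dx) <= z / (2.0 * f_number), contrib, 0.0)
        rf += apodization[e] * contrib
    return rf


def envelope_detect(rf: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal along the axial (first) axis."""
    rf = np.asarray(rf, dtype=float)
    if not np.isfinite(rf).all():
        raise ValueError("rf image contains non-finite values")
    return np.abs(hilbert(rf, axis=0))


def normalize_log_compress(
    envelope: np.ndarray, dynamic_range_db: float = 30.0
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize an envelope to its brightest pixel and log-compress.

    Returns ``(normalized_envelope, bmode_db)`` where ``bmode_db`` is
    ``20 log10`` of the normalized envelope, clipped at
    ``-dynamic_range_db``.  Raises on an all-zero envelope.
    """
    envelope = np.asarray(envelope, dtype=float)
    if (envelope < 0).any():
        raise ValueError("envelope must be non-negative")
    if dynamic_range_db <= 0:
        raise ValueError("dynamic range must be positive")
    peak = envelope.max()
    if peak == 0:
        raise ValueError("all-zero envelope: empty frame")
    norm = envelope / peak
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(norm)
    return norm, np.maximum(db, -dynamic_range_db)


def bandpass_filter(frame: ChannelFrame, order: int = 4) -> ChannelFrame:
    """Zero-phase Butterworth bandpass of each channel line over the
    transducer band.  Optional preprocessing; off by default in the
    pipeline."""
    p = frame.params
    sos = butter(
        order,
        [p.bandwidth_hz[0], p.bandwidth_hz[1]],
        btype="bandpass",
        fs=p.sampling_frequency_hz,
        output="sos",
    )
    data = sosfiltfilt(sos, frame.data, axis=0)
    return ChannelFrame(
        data=data, params=p, time_point_min=frame.time_point_min, frame_id=frame.frame_id
    )


def beamform_frame(
    frame: ChannelFrame,
    dynamic_range_db: float = 30.0,
    grid: ImageGrid | None = None,
    bandpass: bool = False,
    **das_kwargs,
) -> BeamformedImage:
    """Full image-formation chain: (optional bandpass) -> DAS -> envelope
    -> normalize -> log compress."""
    if bandpass:
        frame = bandpass_filter(frame)
    grid = grid or ImageGrid.from_params(frame.params)
    rf = das_beamform(frame, grid, **das_kwargs)
    env = envelope_detect(rf)
    norm, db = normalize_log_compress(env, dynamic_range_db)
    return BeamformedImage(
        rf=rf,
        envelope=norm,
        bmode_db=db,
        grid=grid,
        dynamic_range_db=dynamic_range_db,
        time_point_min=frame.time_point_min,
        frame_id=frame.frame_id,
    )
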
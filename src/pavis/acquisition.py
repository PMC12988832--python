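"""Acquisition geometry shared by the simulator and the beamformer.

A linear-array photoacoustic acquisition is described by the transducer
constants (element count, pitch, bandwidth, sampling rate, assumed speed
of sound) plus the per-channel sample count.  The image grid derived from
those constants places one lateral column per element and one axial row
per RF sample (one-way spacing ``c / fs``), which is the natural pixel
grid of the recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionParams", "ImageGrid", "ChannelFrame"]


@dataclass(frozen=True)
class AcquisitionParams:
    """Transducer and sampling constants of a linear-array acquisition.

    Defaults describe a 256-element array with 0.09 mm pitch, 21.33 MHz
    center frequency, 15--29 MHz bandwidth, sampled at 96 MHz with an
    assumed speed of sound of 1538.5 m/s.
    """

    n_elements: int = 256
    pitch_mm: float = 0.09
    aperture_width_mm: float = 23.0
    center_frequency_hz: float = 21.33e6
    sampling_frequency_hz: float = 96e6
    speed_of_sound_m_s: float = 1538.5
    bandwidth_hz: tuple[float, float] = (15e6, 29e6)
    n_samples: int = 1280  # covers ~20.5 mm one-way depth at 96 MHz

    def __post_init__(self) -> None:
        if self.n_elements < 1:
            raise ValueError("n_elements must be positive")
        if self.pitch_mm <= 0 or self.sampling_frequency_hz <= 0:
            raise ValueError("pitch and sampling frequency must be positive")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if abs(self.n_elements * self.pitch_mm - self.aperture_width_mm) > 0.5:
            raise ValueError(
                "n_elements * pitch must match aperture width within 0.5 mm"
            )
        if self.sampling_frequency_hz <= 2 * self.bandwidth_hz[1]:
            raise ValueError("sampling frequency must exceed twice the upper band edge")

    @property
    def element_positions_mm(self) -> np.ndarray:
        """Lateral element centers, symmetric about 0 mm."""
        e = np.arange(self.n_elements)
        return (e - (self.n_elements - 1) / 2.0) * self.pitch_mm

    @property
    def axial_spacing_mm(self) -> float:
        """One-way axial sample spacing c / fs, in mm."""
        return self.speed_of_sound_m_s / self.sampling_frequency_hz * 1e3

    @property
    def max_depth_mm(self) -> float:
        return (self.n_samples - 1) * self.axial_spacing_mm

    @property
    def wavelength_mm(self) -> float:
        return self.speed_of_sound_m_s / self.center_frequency_hz * 1e3


@dataclass(frozen=True)
class ImageGrid:
    """Pixel grid of the beamformed image.

    Lateral positions coincide with the element centers (one column per
    element); axial positions are ``z_j = j * c / fs``.
    """

    lateral_mm: np.ndarray
    axial_mm: np.ndarray

    @classmethod
    def from_params(cls, params: AcquisitionParams) -> "ImageGrid":
        z = np.arange(params.n_samples) * params.axial_spacing_mm
        return cls(lateral_mm=params.element_positions_mm, axial_mm=z)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.axial_mm.size, self.lateral_mm.size)

    @property
    def pixel_size_mm(self) -> tuple[float, float]:
        """(axial, lateral) pixel dimensions in mm."""
        dz = float(self.axial_mm[1] - self.axial_mm[0]) if self.axial_mm.size > 1 else 0.0
        dx = float(self.lateral_mm[1] - self.lateral_mm[0]) if self.lateral_mm.size > 1 else 0.0
        return (dz, dx)


@dataclass
class ChannelFrame:
    """One frame of raw photoacoustic RF channel data.

    ``data`` is (n_samples, n_elements); each column is the RF line
    recorded by one element.
    """

    data: np.ndarray
    params: AcquisitionParams
    time_point_min: float = 0.0
    frame_id: str = "frame"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("channel data must be 2-D (n_samples, n_elements)")
        if self.data.shape[1] != self.params.n_elements:
            raise ValueError(
                f"channel data has {self.data.shape[1]} columns, "
                f"expected {self.params.n_elements} elements"
            )
        if self.data.shape[0] != self.params.n_samples:
            raise ValueError(
                f"channel data has {self.data.shape[0]} rows, "
                f"expected params.n_samples = {self.params.n_samples}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("channel data contains non-finite samples")
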
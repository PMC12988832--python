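"""Synthetic linear-array photoacoustic acquisitions of a tube-shaped absorber.

The forward model is deliberately minimal: lossless single scattering from
omnidirectional point sources with 1/r geometric spreading, received by
ideal point elements — the simplest physics for which delay-and-sum
beamforming is a consistent approximate inverse.  A scene places point
absorbers inside (and optionally lining) a simulated ureter lumen; each
element's RF line is the superposition of amplitude-weighted, time-shifted
copies of a Gaussian-windowed sinusoid at the transducer center frequency,
plus additive white Gaussian channel noise.

The module also draws grouped image-quality metric samples with a
controllable distribution per time point, so the downstream rank statistics
can be exercised without any acquisition at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.draw import ellipse as _draw_ellipse

from .acquisition import AcquisitionParams, ChannelFrame, ImageGrid

__all__ = [
    "PhantomScene",
    "GroupSpec",
    "make_phantom",
    "simulate_channel_data",
    "make_truth_masks",
    "sample_metric_groups",
    "gaussian_pulse",
    "pulse_sigma_s",
]

#: clamp on 1/r spreading so near-field absorbers keep finite amplitude
R_MIN_MM = 1.0


@dataclass(frozen=True)
class PhantomScene:
    """Point-absorber scene standing in for a methylene-blue-filled ureter.

    ``absorbers`` rows are (lateral mm, depth mm, amplitude a.u.).
    ``lumen_region`` is ``(cx_mm, cz_mm, half_width_mm, half_depth_mm,
    shape)`` with shape ``"ellipse"`` or ``"rect"``; ``None`` means no
    lumen (background-only scene).
    """

    absorbers: np.ndarray
    lumen_region: tuple[float, float, float, float, str] | None = None
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        arr = np.atleast_2d(np.asarray(self.absorbers, dtype=float))
        if arr.size == 0:
            arr = np.empty((0, 3))
        if arr.shape[1] != 3:
            raise ValueError("absorbers must be rows of (lateral, depth, amplitude)")
        object.__setattr__(self, "absorbers", arr)
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if arr.shape[0] and (arr[:, 1] <= 0).any():
            raise ValueError("absorber depths must be > 0")


@dataclass(frozen=True)
class GroupSpec:
    """Per-time-point sampling distributions for one image-quality metric.

    Each group is ``(label_min, n_samples, family, location, scale)``.
    ``location`` is the distribution median; supported families are
    ``"normal"`` (mean=median=location, sd=scale), ``"lognormal"``
    (underlying normal mu=log(location), sigma=scale) and ``"uniform"``
    (location +/- scale).
    """

    groups: tuple[tuple[float, int, str, float, float], ...]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("GroupSpec needs at least one group")
        for label, n, family, loc, scale in self.groups:
            if n < 3:
                raise ValueError(f"group {label}: n_samples must be >= 3")
            if scale < 0:
                raise ValueError(f"group {label}: scale must be >= 0")
            if family not in ("normal", "lognormal", "uniform"):
                raise ValueError(f"group {label}: unknown family {family!r}")
            if family == "lognormal" and loc <= 0:
                raise ValueError(f"group {label}: lognormal median must be > 0")


def _inside_lumen(xz: np.ndarray, region) -> np.ndarray:
    cx, cz, hw, hd, shape = region
    if shape == "ellipse":
        return ((xz[:, 0] - cx) / hw) ** 2 + ((xz[:, 1] - cz) / hd) ** 2 <= 1.0
    return (np.abs(xz[:, 0] - cx) <= hw) & (np.abs(xz[:, 1] - cz) <= hd)


def make_phantom(
    config: dict,
    params: AcquisitionParams | None = None,
) -> PhantomScene:
    """Build a deterministic :class:`PhantomScene` from a config dict.

    Config keys (all optional unless noted):

    - ``absorbers``: explicit list of ``[lateral_mm, depth_mm, amplitude]``
    - ``lumen``: ``{center: [x, z], half_widths: [hw, hd], shape,
      n_absorbers, amplitude}`` — draws ``n_absorbers`` uniformly inside
      the lumen region
    - ``adventitia``: ``{n_absorbers, amplitude, thickness_mm}`` — absorbers
      on a thin band lining the lumen boundary
    - ``noise_sigma``, ``seed``

    The same (config, seed) pair always yields the identical scene.
    """
    params = params or AcquisitionParams()
    seed = int(config.get("seed", 0))
    rng = np.random.default_rng(seed)
    absorbers: list[list[float]] = [list(map(float, a)) for a in config.get("absorbers", [])]

    lumen_region = None
    lumen_cfg = config.get("lumen")
    if lumen_cfg is not None:
        cx, cz = (float(v) for v in lumen_cfg["center"])
        hw, hd = (float(v) for v in lumen_cfg["half_widths"])
        shape = lumen_cfg.get("shape", "ellipse")
        if shape not in ("ellipse", "rect"):
            raise ValueError(f"unknown lumen shape {shape!r}")
        lumen_region = (cx, cz, hw, hd, shape)
        n_lum = int(lumen_cfg.get("n_absorbers", 0))
        amp = float(lumen_cfg.get("amplitude", 1.0))
        # rejection-sample uniformly inside the region
        count = 0
        while count < n_lum:
            x = rng.uniform(cx - hw, cx + hw)
            z = rng.uniform(cz - hd, cz + hd)
            if _inside_lumen(np.array([[x, z]]), lumen_region)[0]:
                absorbers.append([x, z, amp])
                count += 1

        adv = config.get("adventitia")
        if adv is not None:
            n_adv = int(adv.get("n_absorbers", 0))
            a_amp = float(adv.get("amplitude", 1.0))
            thick = float(adv.get("thickness_mm", 0.1))
            theta = rng.uniform(0, 2 * math.pi, n_adv)
            r = 1.0 + rng.uniform(0, thick / max(hw, hd), n_adv)
            for t, rr in zip(theta, r):
                absorbers.append([cx + hw * rr * math.cos(t), cz + hd * rr * math.sin(t), a_amp])

    arr = np.array(absorbers, dtype=float) if absorbers else np.empty((0, 3))
    if arr.shape[0] == 0:
        raise ValueError("phantom config produced no absorbers")

    half_ap = params.aperture_width_mm / 2.0
    if (np.abs(arr[:, 0]) > 1.5 * half_ap).any():
        raise ValueError("absorber lateral position outside aperture extent +/- 50%")
    if (arr[:, 1] <= 0).any():
        raise ValueError("absorber depth must be > 0")
    if (arr[:, 1] > params.max_depth_mm).any():
        raise ValueError("absorber deeper than the reconstruction depth range")

    return PhantomScene(
        absorbers=arr,
        lumen_region=lumen_region,
        noise_sigma=float(config.get("noise_sigma", 0.0)),
        seed=seed,
    )


def pulse_sigma_s(params: AcquisitionParams) -> float:
    """Gaussian envelope sigma (seconds) whose -6 dB amplitude spectral
    half-width matches half the stated transducer bandwidth."""
    half_band = (params.bandwidth_hz[1] - params.bandwidth_hz[0]) / 2.0
    # |P(f)| ~ exp(-2 pi^2 sigma^2 (f - f0)^2); -6 dB at delta f = half_band
    return math.sqrt(math.log(10 ** (6 / 20)) / (2 * math.pi**2 * half_band**2))


def gaussian_pulse(t: np.ndarray, params: AcquisitionParams) -> np.ndarray:
    """Received pulse: Gaussian-windowed sinusoid at the center frequency.

    Truncated to |t| <= 6 sigma so far-field samples are exactly zero
    (keeps superposition exactly linear in absorber amplitude).
    """
    sigma = pulse_sigma_s(params)
    p = np.sin(2 * math.pi * params.center_frequency_hz * t) * np.exp(
        -(t**2) / (2 * sigma**2)
    )
    return np.where(np.abs(t) <= 6 * sigma, p, 0.0)


def simulate_channel_data(
    scene: PhantomScene,
    params: AcquisitionParams | None = None,
    time_point_min: float = 0.0,
    frame_id: str = "frame",
) -> ChannelFrame:
    """Forward-simulate one frame of raw channel data from a scene.

    Element ``e`` records ``sum_k a_k / max(r_ek, 1 mm) * p(t - r_ek / c)``
    over absorbers ``k`` (one-way, receive-only propagation: photoacoustic
    sources emit at t = 0), plus N(0, noise_sigma) white noise.

    Raises ``ValueError`` if any absorber's time of flight to any element
    falls outside the sampled window.
    """
    params = params or AcquisitionParams()
    fs = params.sampling_frequency_hz
    c_mm_s = params.speed_of_sound_m_s * 1e3
    t = np.arange(params.n_samples) / fs

    data = np.zeros((params.n_samples, params.n_elements))
    if scene.absorbers.shape[0]:
        xe = params.element_positions_mm  # (n_el,)
        ax, az, amp = scene.absorbers.T
        # distances (n_abs, n_el), mm
        r = np.sqrt((ax[:, None] - xe[None, :]) ** 2 + az[:, None] ** 2)
        tof = r / c_mm_s
        if tof.max() > t[-1]:
            raise ValueError(
                "time of flight exceeds the sampled window; increase n_samples"
            )
        w = amp[:, None] / np.maximum(r, R_MIN_MM)
        for k in range(r.shape[0]):
            data += w[k][None, :] * gaussian_pulse(t[:, None] - tof[k][None, :], params)

    if scene.noise_sigma > 0:
        rng = np.random.default_rng(scene.seed)
        data += rng.normal(0.0, scene.noise_sigma, size=data.shape)

    return ChannelFrame(data=data, params=params, time_point_min=time_point_min, frame_id=frame_id)


def _resolution_cell_px(grid: ImageGrid, params: AcquisitionParams) -> tuple[int, int]:
    lam = params.wavelength_mm
    dz, dx = grid.pixel_size_mm
    return (max(1, round(lam / dz)), max(1, round(lam / dx)))


def make_truth_masks(
    scene: PhantomScene,
    grid: ImageGrid,
    params: AcquisitionParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth (lumen_mask, signal_mask) boolean images on ``grid``.

    The lumen mask rasterizes the scene's lumen region; the signal mask is
    the absorber footprint dilated by one resolution cell (one wavelength,
    converted separately to axial and lateral pixels).
    """
    params = params or AcquisitionParams()
    nz, nx = grid.shape
    dz, dx = grid.pixel_size_mm

    lumen = np.zeros((nz, nx), dtype=bool)
    if scene.lumen_region is not None:
        cx, cz, hw, hd, shape = scene.lumen_region
        ci = (cz - grid.axial_mm[0]) / dz
        cj = (cx - grid.lateral_mm[0]) / dx
        if shape == "ellipse":
            rr, cc = _draw_ellipse(ci, cj, hd / dz, hw / dx, shape=(nz, nx))
            lumen[rr, cc] = True
        else:
            r0 = max(0, round(ci - hd / dz))
            r1 = min(nz, round(ci + hd / dz) + 1)
            c0 = max(0, round(cj - hw / dx))
            c1 = min(nx, round(cj + hw / dx) + 1)
            lumen[r0:r1, c0:c1] = True

    signal = np.zeros((nz, nx), dtype=bool)
    for x, z, _ in scene.absorbers:
        i = round((z - grid.axial_mm[0]) / dz)
        j = round((x - grid.lateral_mm[0]) / dx)
        if 0 <= i < nz and 0 <= j < nx:
            signal[i, j] = True
    rz, rx = _resolution_cell_px(grid, params)
    fp = np.ones((2 * rz + 1, 2 * rx + 1), dtype=bool)
    signal = binary_dilation(signal, structure=fp)
    return lumen, signal


DEFAULT_METRIC_GROUPS = GroupSpec(
    groups=(
        # (time-point min, n, family, median, scale) — contrast-like dB values
        (10.0, 28, "normal", 3.46, 1.5),
        (20.0, 43, "normal", 11.43, 2.0),
        (30.0, 39, "normal", 9.0, 2.0),
        (60.0, 64, "normal", 5.0, 1.5),
        (70.0, 48, "normal", 3.5, 1.5),
        (80.0, 65, "normal", 6.0, 1.5),
    )
)


def sample_metric_groups(spec: GroupSpec, seed: int) -> dict[float, np.ndarray]:
    """Draw per-group metric samples; reproducible for a given seed."""
    rng = np.random.default_rng(seed)
    out: dict[float, np.ndarray] = {}
    for label, n, family, loc, scale in spec.groups:
        if family == "normal":
            x = rng.normal(loc, scale, n)
        elif family == "lognormal":
            x = rng.lognormal(math.log(loc), scale, n)
        else:
            x = rng.uniform(loc - scale, loc + scale, n)
        out[label] = x
    return out
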
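"""File formats: HDF5 channel frames, TIFF/PNG images, CSV/JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import tifffile

from .acquisition import AcquisitionParams, ChannelFrame, ImageGrid

__all__ = [
    "write_frame_h5",
    "read_frame_h5",
    "write_image_tiff",
    "read_image_tiff",
    "write_mask_png",
    "read_mask_png",
]

# HDF5 attribute name <-> AcquisitionParams field
_PARAM_ATTRS = {
    "Transducer aperture width": ("aperture_width_mm", float),
    "Number of receive elements": ("n_elements", int),
    "Pitch": ("pitch_mm", float),
    "Center frequency": ("center_frequency_hz", float),
    "Sampling frequency": ("sampling_frequency_hz", float),
    "Speed of sound": ("speed_of_sound_m_s", float),
}


def write_frame_h5(frame: ChannelFrame, path: str | Path) -> None:
    """Write one channel-data frame to HDF5.

    Dataset ``channel_data`` is (n_samples, n_elements) float; acquisition
    constants are stored as attributes of the ``params`` group.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("channel_data", data=frame.data.astype(np.float64))
        g = f.create_group("params")
        p = frame.params
        for attr, (fieldname, _) in _PARAM_ATTRS.items():
            g.attrs[attr] = getattr(p, fieldname)
        g.attrs["Bandwidth low"] = p.bandwidth_hz[0]
        g.attrs["Bandwidth high"] = p.bandwidth_hz[1]
        f.attrs["time_point_min"] = frame.time_point_min
        f.attrs["frame_id"] = frame.frame_id


def read_frame_h5(path: str | Path) -> ChannelFrame:
    with h5py.File(path, "r") as f:
        data = f["channel_data"][()]
        g = f["params"]
        kwargs = {
            fieldname: typ(g.attrs[attr])
            for attr, (fieldname, typ) in _PARAM_ATTRS.items()
        }
        kwargs["bandwidth_hz"] = (
            float(g.attrs.get("Bandwidth low", 15e6)),
            float(g.attrs.get("Bandwidth high", 29e6)),
        )
        kwargs["n_samples"] = data.shape[0]
        params = AcquisitionParams(**kwargs)
        return ChannelFrame(
            data=data,
            params=params,
            time_point_min=float(f.attrs.get("time_point_min", 0.0)),
            frame_id=str(f.attrs.get("frame_id", Path(path).stem)),
        )


def write_image_tiff(image: np.ndarray, path: str | Path, grid: ImageGrid | None = None) -> None:
    """32-bit float TIFF plus a JSON sidecar with grid metadata."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    if grid is not None:
        sidecar = {
            "lateral_mm": grid.lateral_mm.tolist(),
            "axial_mm": grid.axial_mm.tolist(),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_image_tiff(path: str | Path) -> tuple[np.ndarray, ImageGrid | None]:
    path = Path(path)
    img = tifffile.imread(path).astype(float)
    grid = None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        grid = ImageGrid(
            lateral_mm=np.asarray(meta["lateral_mm"]),
            axial_mm=np.asarray(meta["axial_mm"]),
        )
    return img, grid


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Single-channel PNG, 0 = background, 255 = mask."""
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask_png(path: str | Path) -> np.ndarray:
    img = np.asarray(iio.imread(Path(path)))
    if img.ndim == 3:
        img = img[..., 0]
    return img > 127
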
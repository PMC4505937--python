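"""Multi-channel core images and OME-TIFF I/O.

A :class:`CoreImage` holds one TMA core as a small stack of aligned 2-D
intensity rasters keyed by channel name.  The four canonical channels are

- ``dapi``        — nuclear counterstain,
- ``epithelium``  — CK18/CK19/PSA epithelial cocktail (orange channel),
- ``relb``        — RelB, alternative NF-κB pathway (A488),
- ``p65``         — p65/RelA, classical NF-κB pathway (Cy5).

Intensities are arbitrary units in [0, 1] stored as float; files are written as
16-bit OME-TIFF with channel names in the OME metadata and rescaled back to
float on read.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

CANONICAL_CHANNELS = ("dapi", "epithelium", "relb", "p65")

_UINT16_MAX = 65535


@dataclass
class CoreImage:
    """One TMA core: aligned channel rasters plus identifying metadata.

    Parameters
    ----------
    channels
        Mapping from channel name to a 2-D float array of non-negative
        intensities.  All rasters must share the same shape.
    core_id, patient_id
        Free-form identifiers.
    tissue_type
        ``"tumor"`` or ``"normal_adjacent"``.
    """

    channels: dict[str, np.ndarray]
    core_id: str = "core"
    patient_id: str = "patient"
    tissue_type: str = "tumor"
    pixel_size_um: float = 0.3225

    def __post_init__(self) -> None:
        shapes = {ch: np.asarray(a).shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel rasters differ in shape: {shapes}")
        for ch, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2:
                raise ValueError(f"channel {ch!r} is not 2-D")
            if np.any(arr < 0):
                raise ValueError(f"channel {ch!r} has negative intensities")
            self.channels[ch] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def content_digest(self) -> str:
        """SHA-256 over channel names and pixel data.

        Used for run manifests: OME-TIFF files embed a fresh UUID on every
        write, so byte-level file hashes are not reproducible while the imaging
        content is.
        """
        h = hashlib.sha256()
        for ch in sorted(self.channels):
            h.update(ch.encode())
            h.update(np.ascontiguousarray(self.channels[ch]).tobytes())
        return h.hexdigest()


def write_core_tiff(path: str | Path, core: CoreImage) -> Path:
    """Write a core as a 16-bit multi-channel OME-TIFF (axes CYX)."""
    path = Path(path)
    names = list(core.channels)
    stack = np.stack(
        [
            np.clip(np.round(core.channels[ch] * _UINT16_MAX), 0, _UINT16_MAX)
            for ch in names
        ]
    ).astype(np.uint16)
    tifffile.imwrite(
        path,
        stack,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "CYX",
            "Channel": {"Name": names},
        },
    )
    return path


def _channel_names_from_ome(tf: tifffile.TiffFile, n: int) -> list[str]:
    try:
        meta = tifffile.xml2dict(tf.ome_metadata)
        ch = meta["OME"]["Image"]["Pixels"]["Channel"]
        if isinstance(ch, dict):
            ch = [ch]
        names = [c.get("Name", f"channel{i}") for i, c in enumerate(ch)]
        if len(names) == n:
            return names
    except Exception:
        pass
    # fall back to canonical order for 4-channel stacks
    if n == len(CANONICAL_CHANNELS):
        return list(CANONICAL_CHANNELS)
    return [f"channel{i}" for i in range(n)]


def read_core_tiff(
    path: str | Path,
    core_id: str | None = None,
    patient_id: str = "patient",
    tissue_type: str = "tumor",
) -> CoreImage:
    """Read a multi-channel core TIFF written by :func:`write_core_tiff`.

    Integer data are rescaled to float [0, 1]; float data are taken as-is.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.series[0].asarray()
        if data.ndim == 2:
            data = data[None]
        names = _channel_names_from_ome(tf, data.shape[0])
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max)
        data = data.astype(float) / scale
    else:
        data = data.astype(float)
    return CoreImage(
        channels={name: plane for name, plane in zip(names, data)},
        core_id=core_id if core_id is not None else path.stem,
        patient_id=patient_id,
        tissue_type=tissue_type,
    )
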
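"""NIfTI and TCK file I/O.

Thin wrappers over :mod:`nibabel` that return the package's container types
and fail loudly (with the offending filename) on malformed inputs.
Streamline coordinates are kept in world (scanner/RAS) millimetres, the TCK
native frame, so no resampling happens on read or write.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .images import Image3D, Image4D
from .tractmap import StreamlineSet

__all__ = [
    "FormatError",
    "read_image",
    "write_image",
    "read_tck",
    "write_tck",
    "write_json",
    "read_json",
]


class FormatError(ValueError):
    """An input file could not be parsed in its declared format."""


def read_image(path: str | Path) -> Image3D | Image4D:
    """Read a NIfTI-1 volume, returning Image3D or Image4D by dimensionality."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read NIfTI image {path}: {exc}") from exc
    if not isinstance(img, (nib.Nifti1Image, nib.Nifti2Image)):
        raise FormatError(f"{path} is not a NIfTI image (got {type(img).__name__})")
    data = np.asanyarray(img.dataobj)
    if data.ndim == 3:
        return Image3D.from_nifti(img)
    if data.ndim == 4:
        return Image4D.from_nifti(img)
    raise FormatError(f"{path}: unsupported dimensionality {data.ndim}")


def write_image(img: Image3D | Image4D, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img.to_nifti(), str(path))
    return path


def read_tck(path: str | Path) -> StreamlineSet:
    """Read an MRtrix TCK file into a StreamlineSet (world mm coordinates)."""
    path = Path(path)
    try:
        tfile = nib.streamlines.load(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read TCK file {path}: {exc}") from exc
    if not isinstance(tfile, nib.streamlines.TckFile):
        raise FormatError(f"{path} is not a TCK file (got {type(tfile).__name__})")
    streamlines = [np.asarray(s, dtype=np.float32) for s in tfile.streamlines]
    for i, s in enumerate(streamlines):
        if not np.all(np.isfinite(s)):
            raise FormatError(f"{path}: streamline {i} contains non-finite points")
    return StreamlineSet(streamlines)


def write_tck(ss: StreamlineSet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tractogram = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in ss.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    nib.streamlines.save(tractogram, str(path))
    return path


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.floating):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
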
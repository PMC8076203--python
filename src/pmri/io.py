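"""File formats: HDF5 k-space container, mask JSON, PNG/NIfTI image export.

The k-space container is a plain HDF5 layout (datasets ``/kspace/real``,
``/kspace/imag`` of shape ``[coils, ny, nx]`` and ``/sampled`` ``[ny]``
uint8, plus provenance attributes) rather than ISMRMRD: the scope here is
line-based Cartesian data only and round trips must be lossless and fast.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
from PIL import Image

from .sampling import SamplingMask
from .simulate import KSpace

__all__ = [
    "FORMAT_VERSION",
    "write_kspace",
    "read_kspace",
    "write_mask",
    "read_mask",
    "export_image",
    "write_weights",
]

FORMAT_VERSION = "1"


def write_kspace(kspace: KSpace, path: str | Path) -> None:
    """Write a :class:`~pmri.simulate.KSpace` to an HDF5 container."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("kspace")
        grp.create_dataset("real", data=kspace.data.real)
        grp.create_dataset("imag", data=kspace.data.imag)
        f.create_dataset("sampled", data=kspace.sampled.astype(np.uint8))
        f.attrs["format_version"] = FORMAT_VERSION
        for key, val in kspace.meta.items():
            if isinstance(val, (str, int, float, bool, np.number)):
                f.attrs[key] = val


def read_kspace(path: str | Path) -> KSpace:
    """Read a k-space container; raises on missing datasets or bad version."""
    with h5py.File(path, "r") as f:
        for name in ("kspace/real", "kspace/imag", "sampled"):
            if name not in f:
                raise KeyError(f"missing dataset {name!r} in {path}")
        version = f.attrs.get("format_version")
        if version != FORMAT_VERSION:
            raise ValueError(
                f"unsupported k-space container version {version!r}"
            )
        data = f["kspace/real"][()] + 1j * f["kspace/imag"][()]
        sampled = f["sampled"][()].astype(bool)
        meta = {
            k: v for k, v in f.attrs.items() if k != "format_version"
        }
    return KSpace(data, sampled, meta)


def write_mask(mask: SamplingMask, path: str | Path) -> None:
    Path(path).write_text(json.dumps(mask.to_json_dict(), indent=2))


def read_mask(path: str | Path) -> SamplingMask:
    return SamplingMask.from_json_dict(json.loads(Path(path).read_text()))


def write_weights(weights, path: str | Path) -> None:
    """Export a fitted WeightSet to HDF5 (`/weights/orf{R}/offset{r}`)."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("weights")
        grp.attrs["model_order"] = weights.model_order
        grp.attrs["block_offsets"] = list(weights.geometry.block_offsets)
        grp.attrs["col_offsets"] = list(weights.geometry.col_offsets)
        for (orf, offset), w in weights.entries.items():
            ds = grp.create_dataset(f"orf{orf}/offset{offset}", data=w)
            ds.attrs["residual"] = weights.residuals.get((orf, offset), np.nan)
            ds.attrs["rank"] = weights.ranks.get((orf, offset), -1)


def export_image(image: np.ndarray, path: str | Path, format: str) -> None:
    """Save a real 2-D image as 8-bit PNG (max-normalized) or NIfTI (raw
    float32, identity affine)."""
    image = np.asarray(image)
    if image.ndim != 2 or np.iscomplexobj(image):
        raise ValueError("export_image expects a real 2-D array")
    if format == "png":
        peak = image.max()
        scaled = image / peak if peak > 0 else image
        Image.fromarray(
            (np.clip(scaled, 0, 1) * 255).astype(np.uint8)
        ).save(path)
    elif format == "nifti":
        nib.save(
            nib.Nifti1Image(image.astype(np.float32), affine=np.eye(4)),
            str(path),
        )
    else:
        raise ValueError(f"unknown image format: {format!r}")
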
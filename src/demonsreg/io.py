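"""Reading and writing images, displacement fields, traces and manifests.

Supported image containers: PNG and TIFF (8/16-bit integer or float, via
imageio) and NIfTI-1 (.nii / .nii.gz, via nibabel; pixel spacing is taken
from the header). Images are always loaded as float64; the method is defined
on scalar images, so RGB inputs are rejected with instructions to convert.

Displacement fields are written either as a multi-component NIfTI (last
axis = component, row-displacement first) or, for any other extension, as a
flat little-endian float64 binary plus a JSON sidecar header recording
shape, spacing and the convention string ``pull/pixel-units/0-based``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as _dcfield, asdict
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from . import __version__
from .exceptions import FormatError
from .image import DisplacementField, Image

__all__ = [
    "read_image",
    "write_image",
    "read_field",
    "write_field",
    "write_trace_csv",
    "RunManifest",
]

FIELD_CONVENTION = "pull/pixel-units/0-based"

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_RASTER_SUFFIXES = (".png", ".tif", ".tiff")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_image(path, declared_format: str | None = None) -> Image:
    """Load a greyscale image as float64 with spacing metadata."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = declared_format or ("nifti" if _is_nifti(path) else "raster")
    if fmt == "nifti":
        img = nib.load(str(path))
        data = np.squeeze(np.asarray(img.get_fdata(), dtype=np.float64))
        zooms = img.header.get_zooms()[: data.ndim]
        return Image(data, spacing=tuple(float(z) for z in zooms))
    if path.suffix.lower() not in _RASTER_SUFFIXES:
        raise FormatError(f"unsupported image format: {path}")
    try:
        data = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if data.ndim == 3:
        raise FormatError(
            f"{path} is multi-channel (shape {data.shape}); registration is "
            "defined on scalar greyscale images — convert to single-channel first"
        )
    return Image(np.asarray(data, dtype=np.float64))


def write_image(image: Image, path) -> None:
    """Write an image; container chosen by extension.

    PNG output is quantized to 16-bit (the container has no float type);
    TIFF and NIfTI store float values losslessly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        affine = np.diag(list(image.spacing) + [1.0] * (4 - image.ndim))
        nib.save(nib.Nifti1Image(image.data.astype(np.float64), affine), str(path))
        return
    suffix = path.suffix.lower()
    if suffix == ".png":
        data = np.clip(np.rint(image.data), 0, 65535).astype(np.uint16)
        iio.imwrite(path, data)
    elif suffix in (".tif", ".tiff"):
        iio.imwrite(path, image.data.astype(np.float32))
    else:
        raise FormatError(f"unsupported output format: {path}")


def write_field(field: DisplacementField, path) -> None:
    """Persist a displacement field; see module docstring for layouts."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        # last axis = vector component, row displacement first
        arr = np.moveaxis(field.vectors, 0, -1).astype(np.float64)
        img = nib.Nifti1Image(arr, np.eye(4))
        img.header["descrip"] = FIELD_CONVENTION.encode()
        nib.save(img, str(path))
        return
    header = {
        "shape": list(field.spatial_shape),
        "components": field.ndim,
        "dtype": "<f8",
        "order": "component-first,C",
        "convention": FIELD_CONVENTION,
    }
    path.write_bytes(field.vectors.astype("<f8").tobytes())
    Path(str(path) + ".json").write_text(json.dumps(header, indent=2))


def read_field(path) -> DisplacementField:
    path = Path(path)
    if _is_nifti(path):
        arr = np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64)
        return DisplacementField(np.moveaxis(arr, -1, 0))
    header_path = Path(str(path) + ".json")
    if not header_path.exists():
        raise FormatError(f"missing sidecar header {header_path}")
    header = json.loads(header_path.read_text())
    vectors = np.frombuffer(path.read_bytes(), dtype=header["dtype"]).reshape(
        header["components"], *header["shape"]
    )
    return DisplacementField(vectors.copy())


def write_trace_csv(traces: list, path) -> None:
    """Energy traces as CSV with columns level,iteration,energy."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["level,iteration,energy"]
    for level, trace in enumerate(traces):
        for it, e in enumerate(trace, start=1):
            lines.append(f"{level},{it},{e!r}")
    path.write_text("\n".join(lines) + "\n")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record serialized next to the outputs of a CLI run."""

    command: str
    config: dict
    inputs: dict = _dcfield(default_factory=dict)   # name -> {path, sha256}
    outputs: list = _dcfield(default_factory=list)  # paths written
    iterations_per_level: list = _dcfield(default_factory=list)
    metrics: dict = _dcfield(default_factory=dict)
    success: bool = False
    version: str = __version__

    def add_input(self, name: str, path) -> None:
        self.inputs[name] = {"path": str(path), "sha256": sha256_of(path)}

    def write(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")
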
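"""Volumes, region maps and multi-b-value series, with NIfTI/Analyze/raw I/O.

The canonical in-memory model is a 3D integer grid ``g`` on a finite lattice
``R`` of ``X x Y x Z`` unit voxels, with gray values in ``{0..Q-1}`` (default
``Q = 256``).  Arrays are indexed ``[x, y, z]`` with 0-based indices and ``x``
fastest-varying; every reader converts into this order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Volume",
    "RegionMap",
    "DWISeries",
    "DEFAULT_B_VALUES",
    "read_volume",
    "write_volume",
    "read_region_map",
    "write_region_map",
    "load_series",
]

#: Acquisition protocol diffusion weightings (s/mm^2).
DEFAULT_B_VALUES = (0, 50, 100, 200, 300, 400, 500, 600, 700, 800, 900, 1000)

_SUPPORTED_FORMATS = ("nifti", "analyze", "raw")


class VolumeFormatError(ValueError):
    """Raised for unreadable files or unsupported/non-3D content."""


@dataclass
class Volume:
    """A 3D grayscale image on the voxel lattice.

    Parameters
    ----------
    data
        Integer grid of gray levels, shape ``(X, Y, Z)``.
    spacing
        Voxel size ``(sx, sy, sz)`` in mm, strictly positive.
    q_levels
        Number of gray levels ``Q``; values lie in ``{0..Q-1}``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    q_levels: int = 256

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"volume data must be 3D, got {self.data.ndim}D"
            )
        if not np.issubdtype(self.data.dtype, np.integer):
            self.data = quantize(self.data, self.q_levels)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if self.data.size and (self.data.min() < 0 or self.data.max() >= self.q_levels):
            raise ValueError("gray levels outside {0..Q-1}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        sx, sy, sz = self.spacing
        return sx * sy * sz


@dataclass
class RegionMap:
    """Binary kidney(1)/background(0) label field over the same lattice."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise VolumeFormatError("region map must be 3D")
        uniq = np.unique(self.labels)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"region map labels must be binary, got {uniq}")
        self.labels = self.labels.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)  # type: ignore[return-value]


@dataclass
class DWISeries:
    """One subject's multi-b-value acquisition: one volume per b-value."""

    b_values: tuple[float, ...]
    volumes: list[Volume]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.b_values = tuple(float(b) for b in self.b_values)
        if len(self.b_values) != len(self.volumes):
            raise ValueError("one volume per b-value required")
        if any(b < 0 for b in self.b_values):
            raise ValueError("b-values must be non-negative")
        if any(b2 <= b1 for b1, b2 in zip(self.b_values, self.b_values[1:])):
            raise ValueError("b-values must be strictly increasing")
        dims0 = self.volumes[0].dims
        sp0 = self.volumes[0].spacing
        for b, v in zip(self.b_values, self.volumes):
            if v.dims != dims0 or v.spacing != sp0:
                raise ValueError(
                    f"volume at b={b} has dims {v.dims}/spacing {v.spacing}, "
                    f"expected {dims0}/{sp0}"
                )

    def volume(self, b: float) -> Volume:
        """The volume acquired at weighting ``b``."""
        try:
            return self.volumes[self.b_values.index(float(b))]
        except ValueError:
            raise KeyError(f"no volume at b={b} in series {self.subject_id!r}")


def quantize(data: np.ndarray, q_levels: int = 256) -> np.ndarray:
    """Linearly map a real-valued array onto the gray-level set {0..Q-1}.

    A constant array maps to zero.  Integer arrays already inside the range
    are passed through unchanged.
    """
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        if data.size == 0 or (data.min() >= 0 and data.max() < q_levels):
            return data.astype(np.int32)
        data = data.astype(np.float64)
    lo, hi = float(data.min()), float(data.max())
    if hi <= lo:
        return np.zeros(data.shape, dtype=np.int32)
    scaled = (data - lo) / (hi - lo) * (q_levels - 1)
    return np.rint(scaled).astype(np.int32)


def _nibabel_spacing(header) -> tuple[float, float, float]:
    zooms = header.get_zooms()[:3]
    if len(zooms) < 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        return (1.0, 1.0, 1.0)
    return tuple(float(z) for z in zooms)


def _detect_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".hdr", ".img")):
        return "analyze"
    if name.endswith(".npy"):
        return "raw"
    raise VolumeFormatError(f"cannot infer volume format from {path.name!r}")


def read_volume(path: str | Path, format: str | None = None,
                q_levels: int = 256) -> Volume:
    """Read a 3D volume; values are rescaled/clipped into {0..Q-1}.

    ``format`` is one of ``nifti``, ``analyze``, ``raw`` (``.npy`` array plus a
    JSON sidecar holding spacing); inferred from the extension when omitted.
    Spacing is taken from the header when present, else (1, 1, 1) mm.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _detect_format(path)
    if fmt not in _SUPPORTED_FORMATS:
        raise VolumeFormatError(f"unsupported format {fmt!r}")
    if fmt == "raw":
        data = np.load(path)
        sidecar = path.with_suffix(".json")
        spacing = (1.0, 1.0, 1.0)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            spacing = tuple(meta.get("spacing", spacing))
            q_levels = int(meta.get("q_levels", q_levels))
    else:
        import nibabel as nib

        try:
            img = nib.load(str(path))
        except Exception as exc:  # nibabel raises several types
            raise VolumeFormatError(f"cannot read {path}: {exc}") from exc
        data = np.asanyarray(img.dataobj)
        spacing = _nibabel_spacing(img.header)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise VolumeFormatError(f"{path} does not contain a 3D volume")
    return Volume(quantize(data, q_levels), spacing=spacing, q_levels=q_levels)


def write_volume(v: Volume, path: str | Path, format: str | None = None) -> None:
    """Write a volume so that :func:`read_volume` round-trips it exactly."""
    path = Path(path)
    fmt = format or _detect_format(path)
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        if fmt == "raw":
            np.save(path, v.data.astype(np.int32))
            path.with_suffix(".json").write_text(
                json.dumps({"spacing": list(v.spacing), "q_levels": v.q_levels})
            )
            return
        import nibabel as nib

        affine = np.diag(list(v.spacing) + [1.0])
        if fmt == "nifti":
            img = nib.Nifti1Image(v.data.astype(np.int16), affine)
        elif fmt == "analyze":
            img = nib.AnalyzeImage(v.data.astype(np.int16), affine)
        else:
            raise VolumeFormatError(f"unsupported format {fmt!r}")
        img.header.set_zooms(v.spacing)
        nib.save(img, str(path))
    except (OSError, VolumeFormatError):
        raise
    except Exception as exc:
        raise OSError(f"failed writing volume to {path}: {exc}") from exc


def read_region_map(path: str | Path, format: str | None = None) -> RegionMap:
    """Read a binary region map stored in any supported volume format."""
    v = read_volume(path, format=format, q_levels=256)
    labels = (v.data > 0).astype(np.uint8)
    return RegionMap(labels, spacing=v.spacing)


def write_region_map(m: RegionMap, path: str | Path,
                     format: str | None = None) -> None:
    write_volume(Volume(m.labels.astype(np.int32), spacing=m.spacing),
                 path, format=format)


def load_series(manifest: dict | str | Path, base_dir: str | Path | None = None,
                ) -> DWISeries:
    """Assemble a :class:`DWISeries` from a manifest.

    The manifest maps b-values to file paths::

        {"subject_id": "s01", "scans": {"0": "s01_b0.nii", "500": ...}}

    or is a path to a YAML/JSON file with that structure.  b-values are sorted
    ascending; duplicate b-values and inconsistent dims are rejected.
    """
    if isinstance(manifest, (str, Path)):
        p = Path(manifest)
        text = p.read_text()
        if p.suffix.lower() in (".yaml", ".yml"):
            import yaml

            manifest = yaml.safe_load(text)
        else:
            manifest = json.loads(text)
        if base_dir is None:
            base_dir = p.parent
    base = Path(base_dir) if base_dir is not None else Path(".")
    scans = manifest["scans"]
    b_raw = [float(b) for b in scans]
    if len(set(b_raw)) != len(b_raw):
        raise ValueError("duplicate b-value entries in manifest")
    order = sorted(scans, key=lambda k: float(k))
    volumes = [read_volume(base / scans[k]) for k in order]
    return DWISeries(
        b_values=tuple(float(k) for k in order),
        volumes=volumes,
        subject_id=str(manifest.get("subject_id", "")),
    )
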
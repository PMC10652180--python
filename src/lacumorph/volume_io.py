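"""Volume and table I/O with explicit physical metadata.

Volumes are 3D grayscale grids with an isotropic voxel size in micrometers.
Axis order is fixed as (z, y, x): TIFF page k maps to z index k.  Supported
formats are multipage TIFF (8/16-bit, with a JSON sidecar carrying the voxel
size) and MHD/RAW (voxel size from the header).  A missing voxel size is an
error, never a silent default — every downstream shape metric depends on it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
import tifffile

__all__ = [
    "ImageVolume",
    "CompartmentMask",
    "read_volume",
    "write_volume",
    "write_tables",
    "read_table",
    "MissingMetadataError",
]

COMPARTMENTS = ("cortical", "trabecular")


class MissingMetadataError(ValueError):
    """Raised when a volume has no voxel size and none was supplied."""


@dataclass
class ImageVolume:
    """A 3D grayscale image with isotropic voxel size.

    Attributes
    ----------
    voxels : (nz, ny, nx) float or integer array, arbitrary attenuation units.
    voxel_size_um : isotropic voxel edge length in micrometers.
    provenance : free text (file path or generator description).
    """

    voxels: np.ndarray
    voxel_size_um: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("voxels must be a 3D grid with all dimensions >= 1")
        if not np.isscalar(self.voxel_size_um) or not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be a positive scalar")
        self.voxel_size_um = float(self.voxel_size_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class CompartmentMask:
    """Binary grid marking mineralized bone of one compartment."""

    voxels: np.ndarray
    compartment: str
    voxel_size_um: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3D")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"compartment must be one of {COMPARTMENTS}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(vol: ImageVolume, path: str | Path, dtype: str = "uint16") -> Path:
    """Write a volume as a multipage TIFF (+JSON sidecar) or MHD/RAW pair.

    Format is chosen by suffix: ``.tif``/``.tiff`` or ``.mhd``.  TIFF data
    is clipped and rounded into the target integer dtype; page k holds z
    slice k.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        info = np.iinfo(np.dtype(dtype))
        data = np.clip(np.rint(vol.voxels), info.min, info.max).astype(dtype)
        tifffile.imwrite(path, data, photometric="minisblack")
        _sidecar_path(path).write_text(
            json.dumps(
                {"voxel_size_um": vol.voxel_size_um, "provenance": vol.provenance},
                indent=2,
            )
        )
    elif suffix == ".mhd":
        img = sitk.GetImageFromArray(np.ascontiguousarray(vol.voxels.astype(np.float32)))
        img.SetSpacing((vol.voxel_size_um,) * 3)
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported volume format: {suffix!r} (use .tif or .mhd)")
    return path


def read_volume(path: str | Path, voxel_size_um: float | None = None) -> ImageVolume:
    """Read a multipage TIFF stack or MHD/RAW volume.

    The voxel size comes from the JSON sidecar (TIFF) or header (MHD) and
    can be overridden by the argument.  Anisotropic spacing in an MHD
    header is rejected — every shape metric here assumes isotropy.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"expected a 3D TIFF stack, got shape {data.shape}")
        vs = voxel_size_um
        sidecar = _sidecar_path(path)
        if vs is None and sidecar.exists():
            vs = json.loads(sidecar.read_text()).get("voxel_size_um")
        if vs is None:
            raise MissingMetadataError(
                f"no voxel size for {path}: supply voxel_size_um or a JSON sidecar"
            )
        return ImageVolume(data, float(vs), provenance=str(path))
    if suffix == ".mhd":
        img = sitk.ReadImage(str(path))
        spacing = img.GetSpacing()
        if voxel_size_um is not None:
            vs = float(voxel_size_um)
        else:
            if max(spacing) - min(spacing) > 1e-9 * max(spacing):
                raise ValueError(
                    f"anisotropic voxels {spacing} are unsupported; "
                    "resample to isotropic first"
                )
            vs = float(spacing[0])
        return ImageVolume(sitk.GetArrayFromImage(img), vs, provenance=str(path))
    raise ValueError(f"unsupported volume format: {suffix!r}")


# Stable column orders for the CSV outputs.
LACUNA_COLUMNS = [
    "lacuna_id", "sample_id", "compartment", "label",
    "centroid_z_um", "centroid_y_um", "centroid_x_um",
    "volume_um3", "surface_area_um2", "sphericity", "oblateness",
    "semi_axis_a_um", "semi_axis_b_um", "semi_axis_c_um",
    "surface_distance_um", "region", "sa_method", "degenerate",
]

SAMPLE_COLUMNS = [
    "sample_id", "compartment", "bvtv_pct", "ct_th_mm", "ct_po_pct",
    "lc_n", "lc_n_bv_mm3",
    "lc_v_um3", "lc_sr", "lc_o",
    "lc_n_peripheral", "lc_n_central",
    "lc_v_peripheral_um3", "lc_v_central_um3",
    "lc_sr_peripheral", "lc_sr_central",
]


def write_tables(
    lacunae: pd.DataFrame,
    samples: pd.DataFrame,
    out_dir: str | Path,
    cohort: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write per-lacuna, per-sample and (optionally) cohort CSV files.

    Empty inputs are an error: writing an empty table would silently
    propagate an upstream failure.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if lacunae is None or len(lacunae) == 0:
        raise ValueError("no lacuna records to write")
    if samples is None or len(samples) == 0:
        raise ValueError("no sample summaries to write")
    paths = {}
    lac = lacunae.reindex(columns=[c for c in LACUNA_COLUMNS if c in lacunae.columns]
                          + [c for c in lacunae.columns if c not in LACUNA_COLUMNS])
    paths["lacunae"] = out_dir / "lacunae.csv"
    lac.to_csv(paths["lacunae"], index=False)
    samp = samples.reindex(columns=[c for c in SAMPLE_COLUMNS if c in samples.columns]
                           + [c for c in samples.columns if c not in SAMPLE_COLUMNS])
    paths["samples"] = out_dir / "samples.csv"
    samp.to_csv(paths["samples"], index=False)
    if cohort is not None:
        if len(cohort) == 0:
            raise ValueError("cohort table is empty")
        paths["cohort"] = out_dir / "cohort.csv"
        cohort.to_csv(paths["cohort"], index=False)
    return paths


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
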
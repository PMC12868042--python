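"""Core volume containers, standard-format I/O and in-plane resampling.

Axis convention throughout the package: arrays are indexed ``(slice, row, col)``
with 0-based indices; an axial slice is ``vol.data[k]``. ``spacing_mm`` follows
the same order. CT intensities are Hounsfield units; after preprocessing they
live in the fixed range [-1000, +1047] HU. MRI intensities are arbitrary units
with a per-volume range.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk

__all__ = [
    "Modality",
    "Volume",
    "LabelVolume",
    "TissueTable",
    "DoseGrid",
    "read_volume",
    "write_volume",
    "read_label_volume",
    "resample_inplane",
    "CT_RANGE",
]

#: Fixed CT intensity range (HU) used for clipping and [-1, +1] normalization.
CT_RANGE = (-1000.0, 1047.0)

_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


class Modality(str, enum.Enum):
    CT = "CT"
    MRI = "MRI"
    DOSE = "DOSE"
    GENERIC = "GENERIC"


class FormatError(ValueError):
    """Raised when a file cannot be read as a supported volume format."""


@dataclasses.dataclass
class Volume:
    """A 3D scalar grid with physical spacing and an intensity-range record.

    Parameters
    ----------
    data
        3D float array ordered (slice, row, col).
    spacing_mm
        Voxel spacing in mm, same axis order as ``data``.
    modality
        One of CT / MRI / DOSE / GENERIC.
    intensity_range
        The physical (lo, hi) range used when normalizing to [-1, +1].
        For CT this is the fixed clip range; for MRI the per-volume min/max.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    modality: Modality = Modality.GENERIC
    intensity_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing_mm}")
        self.modality = Modality(self.modality)
        if self.intensity_range is not None:
            lo, hi = self.intensity_range
            if not lo < hi:
                raise ValueError(f"intensity_range must satisfy lo < hi, got {self.intensity_range}")
            self.intensity_range = (float(lo), float(hi))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, **overrides) -> "Volume":
        kw = dict(
            spacing_mm=self.spacing_mm,
            modality=self.modality,
            intensity_range=self.intensity_range,
        )
        kw.update(overrides)
        return Volume(data, **kw)


@dataclasses.dataclass
class LabelVolume:
    """Integer organ label map; 0 is background. Same geometry contract as Volume."""

    labels: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.allclose(labels, np.round(labels)):
                raise ValueError("label volume must hold integers")
            labels = np.round(labels).astype(np.int32)
        if labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.labels = labels.astype(np.int32, copy=False)
        if self.labels.ndim != 3:
            raise ValueError(f"label volume must be 3D, got shape {self.labels.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def present_labels(self) -> np.ndarray:
        return np.unique(self.labels)

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


class TissueTable:
    """Per-label tissue lookup: linear attenuation μ at 120 keV and MRI intensity.

    Backed by a DataFrame with columns ``label, name, mu_120kev, mri_intensity``.
    Label 0 is air (μ = 0). ``mu_water`` (1/cm at 120 keV) is carried so CT
    numbers can be derived from μ.
    """

    COLUMNS = ("label", "name", "mu_120kev", "mri_intensity")

    def __init__(self, rows: pd.DataFrame, mu_water: float = 0.1615):
        df = pd.DataFrame(rows).copy()
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"tissue table missing columns: {sorted(missing)}")
        df["label"] = df["label"].astype(int)
        if df["label"].duplicated().any():
            raise ValueError("tissue table labels must be unique")
        if (df["mu_120kev"] < 0).any():
            raise ValueError("mu_120kev must be >= 0")
        if 0 in set(df["label"]) and df.loc[df["label"] == 0, "mu_120kev"].iloc[0] != 0:
            raise ValueError("label 0 must map to air (mu = 0)")
        if mu_water <= 0:
            raise ValueError("mu_water must be > 0")
        self.df = df[list(self.COLUMNS)].reset_index(drop=True)
        self.mu_water = float(mu_water)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def labels(self) -> np.ndarray:
        return self.df["label"].to_numpy()

    def mu(self, label: int) -> float:
        row = self.df[self.df["label"] == label]
        if row.empty:
            raise KeyError(f"label {label} not in tissue table")
        return float(row["mu_120kev"].iloc[0])

    def mri_intensity(self, label: int) -> float:
        row = self.df[self.df["label"] == label]
        if row.empty:
            raise KeyError(f"label {label} not in tissue table")
        return float(row["mri_intensity"].iloc[0])

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# mu_water={self.mu_water}\n")
            self.df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TissueTable":
        path = Path(path)
        mu_water = 0.1615
        with open(path) as fh:
            first = fh.readline()
        skip = 0
        if first.startswith("#"):
            skip = 1
            if "mu_water=" in first:
                mu_water = float(first.split("mu_water=")[1].strip())
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=sep, skiprows=skip)
        return cls(df, mu_water=mu_water)


def DoseGrid(data: np.ndarray, spacing_mm) -> Volume:
    """A dose grid is a Volume with DOSE modality; values are Gy [RBE], >= 0."""
    data = np.asarray(data, dtype=np.float32)
    if (data < 0).any():
        raise ValueError("dose values must be non-negative")
    return Volume(data, spacing_mm, modality=Modality.DOSE)


# ---------------------------------------------------------------------------
# File I/O (NIfTI-1 and MetaImage via SimpleITK)
# ---------------------------------------------------------------------------

def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise FormatError(
            f"unsupported volume format for {path}; expected one of {_SUPPORTED_SUFFIXES}"
        )


def read_volume(path: str | Path, modality: Modality | str = Modality.GENERIC) -> Volume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) file.

    Spacing is taken from the file header (never assumed); axis order is
    normalized to (slice, row, col).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    _check_suffix(path)
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # noqa: BLE001 - sitk raises RuntimeError
        raise FormatError(f"could not read volume {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise FormatError(f"{path}: expected a 3D volume, got {img.GetDimension()}D")
    arr = sitk.GetArrayFromImage(img)  # already (slice, row, col)
    sx, sy, sz = img.GetSpacing()  # sitk order: (col, row, slice)
    spacing = (float(sz), float(sy), float(sx))
    if any(s <= 0 for s in spacing):
        raise FormatError(f"{path}: header has non-positive spacing {spacing}")
    return Volume(arr.astype(np.float32), spacing, modality=modality)


def write_volume(vol: Volume | LabelVolume, path: str | Path) -> None:
    """Write a volume; integer grids round-trip exactly, floats within float32."""
    path = Path(path)
    _check_suffix(path)
    if not path.parent.exists():
        raise IOError(f"directory does not exist: {path.parent}")
    if isinstance(vol, LabelVolume):
        arr, spacing = vol.labels.astype(np.int32), vol.spacing_mm
    else:
        arr, spacing = vol.data.astype(np.float32), vol.spacing_mm
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing((spacing[2], spacing[1], spacing[0]))
    try:
        sitk.WriteImage(img, str(path))
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"could not write volume {path}: {exc}") from exc


def read_label_volume(path: str | Path) -> LabelVolume:
    vol = read_volume(path)
    return LabelVolume(np.round(vol.data).astype(np.int32), vol.spacing_mm)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else int(np.ceil(x - 0.5))


def resample_inplane(vol: Volume | LabelVolume, new_spacing_rc: tuple[float, float]):
    """Resample the in-plane (row, col) axes to a new spacing; slices untouched.

    The output grid size is ``round(old_size * old_spacing / new_spacing)`` per
    in-plane axis (round half away from zero), so a 370-pixel plane at 1 mm
    resampled to 1.0625 mm becomes 348 pixels. Scalar volumes use bilinear
    interpolation; label volumes nearest-neighbour.
    """
    sr, sc = (float(s) for s in new_spacing_rc)
    if sr <= 0 or sc <= 0:
        raise ValueError(f"new spacing must be positive, got {new_spacing_rc}")

    is_labels = isinstance(vol, LabelVolume)
    arr = vol.labels if is_labels else vol.data
    _, old_r, old_c = arr.shape
    _, old_sr, old_sc = vol.spacing_mm
    new_r = _round_half_away(old_r * old_sr / sr)
    new_c = _round_half_away(old_c * old_sc / sc)

    if (new_r, new_c) == (old_r, old_c):
        out = arr.copy()
    else:
        from skimage.transform import resize

        order = 0 if is_labels else 1
        out = resize(
            arr.astype(np.float32),
            (arr.shape[0], new_r, new_c),
            order=order,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )

    new_spacing = (vol.spacing_mm[0], sr, sc)
    if is_labels:
        return LabelVolume(out.astype(np.int32), new_spacing)
    return vol.with_data(out.astype(np.float32), spacing_mm=new_spacing)
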
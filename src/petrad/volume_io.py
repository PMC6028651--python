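"""Volume and mask I/O, SUV conversion, and VOI extraction.

Volumes are 3D scalar grids of standardized uptake values (SUV, body-weight
normalized, g/mL) stored as NIfTI; masks are binary grids on the same voxel
lattice selecting the primary-tumor volume of interest (VOI). Voxel indices
are 0-based; all geometry is in millimetres from the volume origin. The
injected dose passed to :func:`compute_suv` is assumed already decay-corrected
to scan time.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "SUVVolume",
    "VOIMask",
    "VOI",
    "PatientRecord",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "compute_suv",
    "extract_voi",
]

#: column order of the clinical CSV table
CLINICAL_CSV_COLUMNS = [
    "id",
    "location",
    "t_stage",
    "n_stage",
    "m_stage",
    "bed_gy",
    "chemo_cycles",
    "age",
    "gender",
    "label",
    "lc_time",
    "lc_event",
    "pfs_time",
    "pfs_event",
]


@dataclasses.dataclass(frozen=True)
class SUVVolume:
    """3D grid of SUV values with voxel spacing and origin in mm."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError(f"expected 3D volume, got {values.ndim}D")
        if min(values.shape) < 1:
            raise ValueError("volume must have at least one voxel per axis")
        if not np.all(np.isfinite(values)):
            raise ValueError("volume contains non-finite voxels")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclasses.dataclass(frozen=True)
class VOIMask:
    """Binary 3D mask on the same lattice as its companion volume."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"expected 3D mask, got {values.ndim}D")
        uniq = np.unique(values)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask must be strictly binary (0/1)")
        values = values.astype(bool)
        if not values.any():
            raise ValueError("mask has no foreground voxel")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


@dataclasses.dataclass(frozen=True)
class VOI:
    """A volume/mask pair cropped to the tight bounding box of the mask."""

    suv: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]

    @property
    def masked_values(self) -> np.ndarray:
        """1D array of the SUV values of the foreground voxels."""
        return self.suv[self.mask]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclasses.dataclass
class PatientRecord:
    """Clinical covariates, outcome label and follow-up of one patient.

    ``label`` is 1 for local progression (positive class). ``lc_time`` /
    ``pfs_time`` are months; event indicators are 1 when the endpoint was
    observed. Local progression implies an observed local-control event.
    """

    id: str
    location: int  # 0=cervical, 1=upper, 2=middle, 3=lower thoracic
    t_stage: int
    n_stage: int
    m_stage: int
    bed_gy: float  # biological equivalent dose, Gy
    chemo_cycles: int
    age: float
    gender: int  # 0=male, 1=female
    label: int
    lc_time: float
    lc_event: int
    pfs_time: float
    pfs_event: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0/1, got {self.label}")
        if self.lc_time < 0 or self.pfs_time < 0:
            raise ValueError("follow-up times must be >= 0")
        if self.label == 1 and self.lc_event != 1:
            raise ValueError("local progression implies an observed LC event")

    @property
    def clinical_features(self) -> dict[str, float]:
        """The 8 clinical covariates as an ordered name -> value map."""
        return {
            "location": float(self.location),
            "t_stage": float(self.t_stage),
            "n_stage": float(self.n_stage),
            "m_stage": float(self.m_stage),
            "bed_gy": float(self.bed_gy),
            "chemo_cycles": float(self.chemo_cycles),
            "age": float(self.age),
            "gender": float(self.gender),
        }


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def read_volume(path) -> SUVVolume:
    """Read a 3D NIfTI volume; spacing and origin come from the header."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume in {path}, got {data.ndim}D")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"non-finite voxels in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    return SUVVolume(values=data.astype(np.float64), spacing=spacing, origin=origin)


def write_volume(volume: SUVVolume, path) -> None:
    img = nib.Nifti1Image(volume.values, _affine(volume.spacing, volume.origin))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_mask(path) -> VOIMask:
    """Read a binary 3D NIfTI mask (stored as unsigned 8-bit)."""
    vol = read_volume(path)
    return VOIMask(values=vol.values, spacing=vol.spacing, origin=vol.origin)


def write_mask(mask: VOIMask, path) -> None:
    img = nib.Nifti1Image(
        mask.values.astype(np.uint8), _affine(mask.spacing, mask.origin)
    )
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def compute_suv(
    activity,
    body_weight: float,
    injected_dose: float,
    spacing=(1.0, 1.0, 1.0),
    origin=(0.0, 0.0, 0.0),
) -> SUVVolume:
    """Convert an activity-concentration grid to body-weight SUV.

    Parameters
    ----------
    activity : 3D array, kBq/mL
    body_weight : kg
    injected_dose : MBq, decay-corrected to scan time.

    With tissue density 1 g/mL, MBq/kg equals kBq/g, so
    ``SUV = activity[kBq/mL] * body_weight[kg] / injected_dose[MBq]``
    and a uniform activity of ``dose/weight`` maps to SUV 1 everywhere.
    """
    if body_weight <= 0:
        raise ValueError(f"body weight must be positive, got {body_weight}")
    if injected_dose <= 0:
        raise ValueError(f"injected dose must be positive, got {injected_dose}")
    activity = np.asarray(activity, dtype=np.float64)
    return SUVVolume(
        values=activity * (body_weight / injected_dose),
        spacing=spacing,
        origin=origin,
    )


def extract_voi(volume: SUVVolume, mask: VOIMask) -> VOI:
    """Crop a volume and mask to the tight bounding box of the mask.

    Foreground voxel values are preserved exactly; spacing is carried over.
    """
    if volume.shape != mask.shape:
        raise ValueError(
            f"volume shape {volume.shape} does not match mask shape {mask.shape}"
        )
    m = mask.values
    slices = tuple(
        slice(int(idx.min()), int(idx.max()) + 1) for idx in np.nonzero(m)
    )
    return VOI(
        suv=volume.values[slices].copy(),
        mask=m[slices].copy(),
        spacing=volume.spacing,
    )
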
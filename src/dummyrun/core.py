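"""Volumetric core: grids, masks, prescriptions, isodose extraction, EQD2, NIfTI I/O.

Everything downstream (consensus, agreement, dosimetry) operates on these
types. All analysis requires *exactly* compatible geometries — there is no
implicit resampling; :func:`resample_nearest` is provided for callers that
need to bring a mismatched volume onto an analysis grid explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "GridGeometry",
    "DoseGrid",
    "BinaryMask",
    "FractionationScheme",
    "PlanRecord",
    "StructureSet",
    "STATION_NAMES",
    "NODAL_STATIONS",
    "mask_volume_cc",
    "extract_isodose_mask",
    "convert_to_eqd2",
    "read_volume",
    "write_volume",
    "resample_nearest",
]

#: Fixed structure vocabulary: nodal stations, target, organs at risk.
NODAL_STATIONS = ("ALN_I", "ALN_II", "ALN_III", "SCN", "IMN")
STATION_NAMES = NODAL_STATIONS + ("BREAST", "LUNG_IPSI", "HEART")

#: Tolerance (mm) for spacing/origin agreement after an I/O round trip.
GEOMETRY_IO_TOL = 1e-6


@dataclass(frozen=True)
class GridGeometry:
    """Regular 3D voxel grid: shape (voxels), spacing and origin (mm).

    Two geometries are *compatible* iff shape, spacing and origin agree
    exactly; compare with ``==``. Use :meth:`approx_equal` only to absorb
    floating-point jitter introduced by file headers.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths (mm), got {self.spacing}")
        if len(self.origin) != 3:
            raise ValueError("origin must have 3 coordinates")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def approx_equal(self, other: "GridGeometry", tol: float = GEOMETRY_IO_TOL) -> bool:
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical coordinates (mm) of voxel centers."""
        return tuple(
            self.origin[ax] + self.spacing[ax] * np.arange(self.shape[ax])
            for ax in range(3)
        )


def _require_compatible(a: GridGeometry, b: GridGeometry, what: str) -> None:
    if a != b:
        raise ValueError(f"incompatible geometries for {what}: {a} vs {b}")


@dataclass
class DoseGrid:
    """Absorbed dose (Gy), one finite non-negative value per voxel."""

    geometry: GridGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"dose array shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )
        if not np.issubdtype(self.values.dtype, np.floating):
            self.values = self.values.astype(np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")


@dataclass
class BinaryMask:
    """Boolean voxel mask on a :class:`GridGeometry` (structure or isodose region)."""

    geometry: GridGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"mask array shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )
        if self.values.dtype != bool:
            uniq = np.unique(self.values)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be boolean or 0/1")
            self.values = self.values.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.values))


@dataclass(frozen=True)
class FractionationScheme:
    """Prescription: total dose (Gy) delivered in ``n_fractions`` equal fractions."""

    total_dose: float
    n_fractions: int

    def __post_init__(self) -> None:
        if self.total_dose <= 0:
            raise ValueError("total_dose must be positive")
        if int(self.n_fractions) != self.n_fractions or self.n_fractions < 1:
            raise ValueError("n_fractions must be a positive integer")
        object.__setattr__(self, "total_dose", float(self.total_dose))
        object.__setattr__(self, "n_fractions", int(self.n_fractions))

    @property
    def dose_per_fraction(self) -> float:
        return self.total_dose / self.n_fractions


@dataclass
class PlanRecord:
    """One institution's plan for one case and arm."""

    institution_id: str
    case_id: str  # "A" or "S"
    arm: str  # "WBI" or "WBI_RNI"
    dose: DoseGrid
    scheme: FractionationScheme
    includes_imn: bool = False  # meaningful only for WBI_RNI


@dataclass
class StructureSet:
    """Named structure masks (stations + organs) sharing one geometry."""

    masks: dict[str, BinaryMask] = field(default_factory=dict)

    def __post_init__(self) -> None:
        geoms = {m.geometry for m in self.masks.values()}
        if len(geoms) > 1:
            raise ValueError("all masks in a StructureSet must share one geometry")
        unknown = set(self.masks) - set(STATION_NAMES)
        if unknown:
            raise ValueError(f"unknown structure names: {sorted(unknown)}")

    @property
    def geometry(self) -> GridGeometry:
        if not self.masks:
            raise ValueError("empty StructureSet has no geometry")
        return next(iter(self.masks.values())).geometry

    def __getitem__(self, name: str) -> BinaryMask:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def items(self):
        return self.masks.items()


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def mask_volume_cc(mask: BinaryMask) -> float:
    """Volume of the mask in cubic centimeters (true voxels x voxel volume)."""
    return mask.n_voxels * mask.geometry.voxel_volume_mm3 / 1000.0


def extract_isodose_mask(
    dose: DoseGrid,
    scheme: FractionationScheme,
    level_fraction: float = 0.9,
) -> BinaryMask:
    """Voxels receiving at least ``level_fraction`` of the prescription dose.

    The threshold is inclusive (>=): a voxel exactly at 90% of the
    prescription belongs to the 90% isodose region.
    """
    if not 0 < level_fraction <= 1.5:
        raise ValueError("level_fraction must be in (0, 1.5]")
    threshold = level_fraction * scheme.total_dose
    return BinaryMask(dose.geometry, dose.values >= threshold)


def convert_to_eqd2(
    dose: DoseGrid,
    scheme: FractionationScheme,
    alpha_beta: float = 3.0,
) -> DoseGrid:
    """Equivalent dose in 2 Gy fractions under the linear-quadratic model.

    Per voxel, with total dose D delivered in n equal fractions of
    d = D/n: EQD2 = D * (d + alpha/beta) / (2 + alpha/beta). The per-voxel
    fraction dose uses the plan's single fraction count, so V_x thresholds
    remain well defined in EQD2 space. Identity when d = 2 Gy.
    """
    if alpha_beta <= 0:
        raise ValueError("alpha_beta must be positive")
    d = dose.values / scheme.n_fractions
    eqd2 = dose.values * (d + alpha_beta) / (2.0 + alpha_beta)
    return DoseGrid(dose.geometry, eqd2.astype(dose.values.dtype, copy=False))


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine(geometry: GridGeometry) -> np.ndarray:
    aff = np.diag(list(geometry.spacing) + [1.0])
    aff[:3, 3] = geometry.origin
    return aff


def write_volume(obj: DoseGrid | BinaryMask, path: str | Path) -> Path:
    """Serialize to NIfTI: masks as uint8 0/1, doses as float32 Gy."""
    path = Path(path)
    if isinstance(obj, BinaryMask):
        data = obj.values.astype(np.uint8)
    elif isinstance(obj, DoseGrid):
        data = obj.values.astype(np.float32)
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    img = nib.Nifti1Image(data, _affine(obj.geometry))
    img.header.set_zooms(obj.geometry.spacing)
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path, kind: str = "auto") -> DoseGrid | BinaryMask:
    """Load a 3D NIfTI volume as a :class:`DoseGrid` or :class:`BinaryMask`.

    ``kind`` is "auto" (integer data holding only 0/1 becomes a mask),
    "dose" or "mask". Non-3D files, unreadable headers and NaN values are
    rejected.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise IOError(f"cannot read NIfTI header from {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D")
    if np.issubdtype(data.dtype, np.floating) and np.isnan(data).any():
        raise ValueError(f"{path}: volume contains NaN values")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    geom = GridGeometry(data.shape, zooms, origin)
    if kind not in ("auto", "dose", "mask"):
        raise ValueError(f"unknown kind {kind!r}")
    is_int = np.issubdtype(data.dtype, np.integer) or data.dtype == bool
    looks_binary = bool(np.all(np.isin(np.unique(data), (0, 1))))
    if kind == "mask" or (kind == "auto" and is_int and looks_binary):
        if not looks_binary:
            raise ValueError(f"{path}: values outside {{0,1}} cannot form a mask")
        return BinaryMask(geom, data.astype(bool))
    return DoseGrid(geom, np.asarray(data, dtype=np.float64))


def resample_nearest(
    obj: DoseGrid | BinaryMask, target: GridGeometry
) -> DoseGrid | BinaryMask:
    """Explicit nearest-neighbor resampling onto ``target``.

    Voxel centers of ``target`` are mapped to the nearest source voxel;
    coordinates outside the source grid clamp to its edge. This is the only
    sanctioned way to mix geometries — analysis functions never resample.
    """
    src = obj.geometry
    idx = []
    for ax in range(3):
        coords = target.origin[ax] + target.spacing[ax] * np.arange(target.shape[ax])
        i = np.rint((coords - src.origin[ax]) / src.spacing[ax]).astype(int)
        idx.append(np.clip(i, 0, src.shape[ax] - 1))
    grid = np.ix_(*idx)
    out = obj.values[grid]
    if isinstance(obj, BinaryMask):
        return BinaryMask(target, out)
    return DoseGrid(target, out)


# ---------------------------------------------------------------------------
# JSON helpers for structure sets
# ---------------------------------------------------------------------------

def write_structure_set(structures: StructureSet, directory: str | Path) -> dict[str, str]:
    """Write each mask as NIfTI under ``directory``; return name -> filename map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mapping: dict[str, str] = {}
    for name, mask in sorted(structures.items()):
        fn = f"{name}.nii.gz"
        write_volume(mask, directory / fn)
        mapping[name] = fn
    return mapping


def read_structure_set(directory: str | Path, mapping: Mapping[str, str]) -> StructureSet:
    directory = Path(directory)
    masks = {}
    for name, fn in mapping.items():
        vol = read_volume(directory / fn, kind="mask")
        masks[name] = vol
    return StructureSet(masks)
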
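"""Core data model: voxel grids, structure sets, plans, and NIfTI/manifest I/O.

Conventions
-----------
* Grid arrays are indexed ``(slice, row, col)``; the slice index increases
  superior -> inferior, rows anterior -> posterior, columns left -> right.
* Doses are stored as fractions of the prescription dose (1.0 = 70 Gy);
  RMSE-style errors elsewhere in the package are 100x these fractions.
* Structure masks are 0/1 float grids so that priority scaling is a plain
  multiplication.
* Grids are persisted as NIfTI-1 with voxel spacing in the header zooms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import nibabel as nib
import numpy as np

from .errors import GridParseError, ValidationError

#: canonical in-plane shape of clinical grids
INPLANE_SHAPE = (128, 128)

STRUCTURE_NAMES = ("ptv", "bladder", "rectum", "body")


@dataclass
class VoxelGrid:
    """A 3-D scalar field with physical voxel spacing.

    Parameters
    ----------
    values
        Array of shape ``(n_slices, n_rows, n_cols)``.
    spacing
        ``(slice_mm, row_mm, col_mm)`` — strictly positive, millimetres.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValidationError(f"grid must be 3-D, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 positive floats, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_slices(self) -> int:
        return self.values.shape[0]

    def diagonal_mm(self) -> float:
        """Physical length of the grid diagonal (used as the distance cap)."""
        return math.sqrt(sum((n * s) ** 2 for n, s in zip(self.shape, self.spacing)))

    def same_lattice(self, other: "VoxelGrid", tol: float = 1e-9) -> bool:
        return self.shape == other.shape and all(
            abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing)
        )

    def copy_with(self, values: np.ndarray) -> "VoxelGrid":
        return VoxelGrid(values=np.asarray(values, dtype=np.float64), spacing=self.spacing)


@dataclass
class StructureSet:
    """Binary masks for PTV, bladder, rectum and body on one shared lattice."""

    masks: Mapping[str, VoxelGrid]

    def __post_init__(self) -> None:
        missing = [n for n in STRUCTURE_NAMES if n not in self.masks]
        if missing:
            raise ValidationError(f"structure set missing masks: {missing}")
        ref = self.masks["body"]
        for name, grid in self.masks.items():
            if not grid.same_lattice(ref):
                raise ValidationError(f"mask '{name}' not on the shared lattice")
            vals = grid.values
            if not np.all((vals == 0) | (vals == 1)):
                raise ValidationError(f"mask '{name}' is not binary")
        body = ref.values.astype(bool)
        for name in ("ptv", "bladder", "rectum"):
            inside = self.masks[name].values.astype(bool)
            if np.any(inside & ~body):
                raise ValidationError(f"mask '{name}' has voxels outside the body")
        if not self.masks["ptv"].values.any():
            raise ValidationError("PTV mask is empty")

    def __getitem__(self, name: str) -> VoxelGrid:
        return self.masks[name]

    @property
    def grid(self) -> VoxelGrid:
        return self.masks["body"]

    def bool_mask(self, name: str) -> np.ndarray:
        return self.masks[name].values.astype(bool)


@dataclass(frozen=True)
class PriorityVector:
    """Optimization priorities on (PTV homogeneity, bladder D25%, rectum D25%)."""

    w_hi: float
    w_bladder: float
    w_rectum: float

    def __post_init__(self) -> None:
        comps = self.as_array()
        if np.any(comps < 0):
            raise ValidationError(f"priorities must be nonnegative, got {tuple(comps)}")
        if not np.any(comps > 0):
            raise ValidationError("at least one priority must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.w_hi, self.w_bladder, self.w_rectum], dtype=np.float64)


#: dose values are fractions of prescription; anything above this is a data error
DOSE_MAX_FRACTION = 1.5


@dataclass
class PlanRecord:
    """One patient-plan: structures + priorities + optional reference dose."""

    structures: StructureSet
    priorities: PriorityVector
    reference_dose: Optional[VoxelGrid] = None
    patient_id: str = ""
    plan_id: str = ""

    def __post_init__(self) -> None:
        if self.reference_dose is not None:
            if not self.reference_dose.same_lattice(self.structures.grid):
                raise ValidationError("reference dose not on the structure lattice")
            vals = self.reference_dose.values
            if vals.min() < 0 or vals.max() > DOSE_MAX_FRACTION:
                raise ValidationError(
                    "reference dose outside [0, %.1f] of prescription" % DOSE_MAX_FRACTION
                )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def write_grid(grid: VoxelGrid, path) -> None:
    """Write a grid to ``path`` in NIfTI-1 format, spacing in the header."""
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"directory does not exist: {path.parent}")
    affine = np.diag([grid.spacing[0], grid.spacing[1], grid.spacing[2], 1.0])
    img = nib.Nifti1Image(grid.values.astype(np.float32), affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def read_grid(path, require_inplane: Optional[tuple[int, int]] = INPLANE_SHAPE) -> VoxelGrid:
    """Read a NIfTI-1 grid.

    By default the in-plane shape must be 128x128 (the model's working
    resolution); pass ``require_inplane=None`` to accept any shape (used for
    down-scaled phantoms).
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        values = np.asanyarray(img.dataobj, dtype=np.float64)
        zooms = img.header.get_zooms()[:3]
    except Exception as exc:  # nibabel raises a zoo of types for bad bytes
        if isinstance(exc, (ValidationError,)):
            raise
        raise GridParseError(f"could not parse {path} as NIfTI-1: {exc}") from exc
    if values.ndim != 3:
        raise ValidationError(f"{path}: expected 3-D volume, got shape {values.shape}")
    if require_inplane is not None and tuple(values.shape[1:]) != tuple(require_inplane):
        raise ValidationError(
            f"{path}: in-plane shape {values.shape[1:]} != required {require_inplane}"
        )
    return VoxelGrid(values=values, spacing=tuple(float(z) for z in zooms))


# ---------------------------------------------------------------------------
# Cohort manifest
# ---------------------------------------------------------------------------

def _as_mask(grid: VoxelGrid) -> VoxelGrid:
    # tolerate float32 round-off from disk
    vals = np.round(grid.values)
    if not np.all((vals == 0) | (vals == 1)):
        raise ValidationError("grid is not a 0/1 mask")
    return grid.copy_with(vals)


def load_plan(patient_entry: Mapping, plan_entry: Mapping, base_dir,
              require_inplane: Optional[tuple[int, int]] = None) -> PlanRecord:
    """Build a validated :class:`PlanRecord` from manifest records.

    ``patient_entry`` carries ``patient_id`` and ``masks`` (name -> relative
    path); ``plan_entry`` carries ``plan_id``, ``priorities`` and optionally
    ``dose``. Paths are resolved against ``base_dir``.
    """
    base_dir = Path(base_dir)
    mask_paths = patient_entry.get("masks", {})
    if "ptv" not in mask_paths:
        raise ValidationError("manifest patient entry has no PTV mask")
    masks = {}
    for name in STRUCTURE_NAMES:
        if name not in mask_paths:
            raise ValidationError(f"manifest patient entry has no '{name}' mask")
        masks[name] = _as_mask(read_grid(base_dir / mask_paths[name], require_inplane))
    structures = StructureSet(masks=masks)
    pri = [float(p) for p in plan_entry["priorities"]]
    if len(pri) != 3:
        raise ValidationError(f"priorities must have 3 components, got {len(pri)}")
    priorities = PriorityVector(*pri)
    dose = None
    if plan_entry.get("dose"):
        dose = read_grid(base_dir / plan_entry["dose"], require_inplane)
    return PlanRecord(
        structures=structures,
        priorities=priorities,
        reference_dose=dose,
        patient_id=str(patient_entry.get("patient_id", "")),
        plan_id=str(plan_entry.get("plan_id", "")),
    )


def load_manifest(manifest_path, require_inplane: Optional[tuple[int, int]] = None
                  ) -> list[PlanRecord]:
    """Load every plan of a cohort manifest (JSON) into memory.

    Structure sets are shared between the plans of one patient.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base_dir = manifest_path.parent
    plans: list[PlanRecord] = []
    for patient in manifest["patients"]:
        shared: Optional[StructureSet] = None
        for plan in patient["plans"]:
            rec = load_plan(patient, plan, base_dir, require_inplane)
            if shared is None:
                shared = rec.structures
            else:
                rec.structures = shared
            plans.append(rec)
    return plans


def group_by_patient(plans: list[PlanRecord]) -> dict[str, list[PlanRecord]]:
    """Group a flat plan list by patient id, preserving order."""
    out: dict[str, list[PlanRecord]] = {}
    for p in plans:
        out.setdefault(p.patient_id, []).append(p)
    return out
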
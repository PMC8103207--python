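"""Analytic dose initialization from PTV distance maps.

The initialization assumes an isotropic inverse decay of dose with distance
from the planning target volume, which suits VMAT arcs wrapping (nearly) 360
degrees around the patient:

    D_init(v) = 1 / (1 + a1 * s1(v)**a2 + c * s2(v)**a3)

where ``s1`` is the in-plane distance (mm/10) from the voxel to the nearest
PTV voxel within the voxel's own slice, and ``s2`` is the along-axis distance
(mm/10) to the nearest slice in which the PTV occupies the voxel's (row, col).
Distances are divided by 10 before exponentiation so that the power terms stay
numerically tame (10 mm -> 1.0). Where a distance is undefined (a slice with
no PTV, or a (row, col) column the PTV never meets) it is capped at the grid
diagonal, which drives the initialization toward 0 far from the target.

All four constants a1, a2, a3, c are fitted jointly to reference doses by
minimizing the masked RMSE, using the same Adam optimizer as network training,
on log-parameters to keep them positive. Fitting happens before any network
training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .grids import PlanRecord, StructureSet, VoxelGrid

#: distances are expressed in units of this many millimetres before the
#: power terms are evaluated
DISTANCE_SCALE_MM = 10.0


@dataclass
class DistanceMaps:
    """In-plane and along-axis distances (mm) from each voxel to the PTV."""

    d_inplane: VoxelGrid
    d_axial: VoxelGrid
    cap_mm: float


@dataclass
class InitParams:
    """Fitted constants of the initialization formula; all strictly positive."""

    a1: float
    a2: float
    a3: float
    c: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
            raise ValidationError(f"init params must be positive finite, got {vals}")

    def as_array(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.a3, self.c], dtype=np.float64)

    @classmethod
    def from_array(cls, arr) -> "InitParams":
        a1, a2, a3, c = (float(x) for x in arr)
        return cls(a1=a1, a2=a2, a3=a3, c=c)


def compute_distance_maps(structures: StructureSet) -> DistanceMaps:
    """Distance maps to the PTV, capped at the grid diagonal where undefined.

    ``d_inplane``: per slice, Euclidean distance (mm) to the nearest PTV voxel
    in that slice; slices without PTV get the cap.
    ``d_axial``: per (row, col), distance (mm) along the slice axis to the
    nearest slice whose PTV covers that (row, col); columns the PTV never
    meets get the cap.
    """
    ptv = structures.bool_mask("ptv")
    if not ptv.any():
        raise ValidationError("PTV mask is empty")
    grid = structures.grid
    slice_mm, row_mm, col_mm = grid.spacing
    cap = grid.diagonal_mm()

    d_in = np.full(ptv.shape, cap, dtype=np.float64)
    for s in range(ptv.shape[0]):
        sl = ptv[s]
        if sl.any():
            # EDT of the complement = distance to the nearest PTV voxel
            d_in[s] = ndimage.distance_transform_edt(~sl, sampling=(row_mm, col_mm))

    # 1-D chamfer scan along the slice axis (exact in one dimension)
    d_ax = np.full(ptv.shape, np.inf, dtype=np.float64)
    d_ax[ptv] = 0.0
    for s in range(1, ptv.shape[0]):
        np.minimum(d_ax[s], d_ax[s - 1] + slice_mm, out=d_ax[s])
    for s in range(ptv.shape[0] - 2, -1, -1):
        np.minimum(d_ax[s], d_ax[s + 1] + slice_mm, out=d_ax[s])
    d_ax[~np.isfinite(d_ax)] = cap

    return DistanceMaps(
        d_inplane=grid.copy_with(d_in),
        d_axial=grid.copy_with(d_ax),
        cap_mm=cap,
    )


def init_dose(dmaps: DistanceMaps, params: InitParams) -> VoxelGrid:
    """Evaluate the initialization formula; output values lie in (0, 1]."""
    s1 = dmaps.d_inplane.values / DISTANCE_SCALE_MM
    s2 = dmaps.d_axial.values / DISTANCE_SCALE_MM
    di = 1.0 / (1.0 + params.a1 * s1 ** params.a2 + params.c * s2 ** params.a3)
    return dmaps.d_inplane.copy_with(di)


@dataclass
class FitOptions:
    """Options for the initialization fit (full-batch Adam on log-params)."""

    iterations: int = 800
    learning_rate: float = 0.05
    initial_guess: tuple[float, float, float, float] = (1.0, 2.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise ValidationError("iterations must be >= 0")
        if self.learning_rate <= 0:
            raise ValidationError("learning rate must be > 0")


def fit_init_params(training_plans: list[PlanRecord], mask_fn=None,
                    opts: FitOptions | None = None) -> tuple[InitParams, float]:
    """Fit (a1, a2, a3, c) to the reference doses of ``training_plans``.

    Minimizes the RMSE between the initialized dose and the reference dose
    over all masked voxels of all plans jointly. ``mask_fn`` maps a plan to a
    binary loss mask (defaults to the training loss mask: in-body voxels on
    structure-bearing slices). Returns the fitted parameters and the achieved
    RMSE in % of prescription.
    """
    from .training import loss_mask  # local import to avoid a cycle

    if opts is None:
        opts = FitOptions()
    if mask_fn is None:
        mask_fn = loss_mask
    if not training_plans:
        raise ValidationError("no training plans supplied")

    s1_parts, s2_parts, ref_parts = [], [], []
    dmaps_cache: dict[int, DistanceMaps] = {}
    for plan in training_plans:
        if plan.reference_dose is None:
            raise ValidationError(f"plan {plan.plan_id!r} has no reference dose")
        key = id(plan.structures)
        if key not in dmaps_cache:
            dmaps_cache[key] = compute_distance_maps(plan.structures)
        dmaps = dmaps_cache[key]
        m = mask_fn(plan).values.astype(bool)
        if not m.any():
            continue
        s1_parts.append(dmaps.d_inplane.values[m] / DISTANCE_SCALE_MM)
        s2_parts.append(dmaps.d_axial.values[m] / DISTANCE_SCALE_MM)
        ref_parts.append(plan.reference_dose.values[m])
    if not s1_parts:
        raise ValidationError("all loss masks are empty")
    s1 = np.concatenate(s1_parts)
    s2 = np.concatenate(s2_parts)
    ref = np.concatenate(ref_parts)
    n = s1.size
    # log(s) terms, with s=0 contributing nothing to the a2/a3 gradients
    with np.errstate(divide="ignore"):
        log_s1 = np.where(s1 > 0, np.log(np.maximum(s1, 1e-300)), 0.0)
        log_s2 = np.where(s2 > 0, np.log(np.maximum(s2, 1e-300)), 0.0)

    theta = np.log(np.asarray(opts.initial_guess, dtype=np.float64))

    def loss_and_grad(theta):
        a1, a2, a3, c = np.exp(theta)
        p1 = s1 ** a2
        p2 = s2 ** a3
        di = 1.0 / (1.0 + a1 * p1 + c * p2)
        err = di - ref
        rmse = np.sqrt(np.mean(err ** 2))
        # d rmse / d di
        g_di = err / (n * max(rmse, 1e-12))
        common = -g_di * di * di
        g_a1 = np.sum(common * p1)
        g_a2 = np.sum(common * a1 * p1 * log_s1)
        g_a3 = np.sum(common * c * p2 * log_s2)
        g_c = np.sum(common * p2)
        grad = np.array([g_a1, g_a2, g_a3, g_c])
        return rmse, grad * np.exp(theta)  # chain rule through exp

    from .optim import AdamState

    adam = AdamState([theta], learning_rate=opts.learning_rate)
    rmse = loss_and_grad(theta)[0]
    for _ in range(opts.iterations):
        rmse, grad = loss_and_grad(theta)
        adam.step([grad])
    rmse = loss_and_grad(theta)[0]
    params = InitParams.from_array(np.exp(theta))
    return params, 100.0 * float(rmse)
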
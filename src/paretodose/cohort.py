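"""Synthetic pelvic cohort with surrogate treatment-planning-system doses.

A real clinical cohort (CT-based contours plus doses optimized by a
commercial planning system) is not shippable, so this module generates
pelvic phantoms carrying the statistical structure the prediction model
assumes:

* anatomy — an elliptical body per slice; an ellipsoidal PTV near the grid
  centre; an ellipsoidal bladder anterior-superior to the PTV; a rectal tube
  posterior to the PTV — with per-patient jitter of centres and radii;
* 25 plans per patient on a deterministic 5x5 grid of convex combinations of
  three bounding priority vectors;
* a surrogate dose per plan with monotone priority -> objective trade-offs:

      dose = base * sparing * heterogeneity + noise,   then D95% normalization

  ``base`` is the analytic initialization evaluated with known "true"
  parameters, so the network's learning target (the residual) is small but
  structured. ``sparing`` lowers dose near a prioritized organ:
  1 - sum_o s_o * (w_o / (1 + w_o)) * exp(-d_o / tau) over o in {bladder,
  rectum}, with d_o the in-plane distance to the organ; it is applied only
  outside the PTV so target coverage (and hence the D95% normalization
  factor) does not depend on organ priorities, which makes each organ's D25%
  strictly non-increasing in its own priority. ``heterogeneity`` perturbs
  the PTV dose by a smooth zero-mean field whose amplitude shrinks as the
  homogeneity priority grows, giving a monotone HI trade-off. ``noise`` is
  uniform-kernel-smoothed white noise, renormalized to unit variance before
  scaling by sigma.

The saturating priority response w/(1+w) (rather than a share w/sum(w)) keeps
every organ's trade-off monotone in its *own* priority regardless of the
other priorities.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .dose_init import InitParams, compute_distance_maps, init_dose
from .errors import ValidationError
from .features import smooth2d
from .grids import (PriorityVector, StructureSet, VoxelGrid, load_manifest,
                    write_grid)
from .pareto import normalize_to_d95


@dataclass
class PhantomConfig:
    """Geometry, surrogate-dose physics and randomization of one cohort."""

    n_patients: int = 1
    n_slices: int = 40
    n_rows: int = 128
    n_cols: int = 128
    spacing: tuple[float, float, float] = (3.0, 2.0, 2.0)
    #: anatomy jitter: centre offsets (mm) and relative radius jitter
    centre_jitter_mm: float = 4.0
    radius_jitter: float = 0.10
    #: baseline radii as fractions of the grid's physical half-extent
    ptv_radius_frac: tuple[float, float, float] = (0.22, 0.14, 0.14)
    bladder_radius_frac: tuple[float, float, float] = (0.28, 0.18, 0.20)
    rectum_radius_frac: tuple[float, float] = (0.07, 0.07)  # in-plane tube
    body_frac: tuple[float, float] = (0.92, 0.95)
    #: surrogate-dose parameters
    true_init: InitParams = field(default_factory=lambda: InitParams(1.5, 2.0, 0.8, 0.6))
    s_bladder: float = 0.25
    s_rectum: float = 0.25
    sparing_tau_mm: float = 15.0
    #: anterior-posterior dose asymmetry outside the PTV; emulates the
    #: anisotropy of real arc doses that an isotropic distance model misses
    anisotropy: float = 0.20
    anisotropy_range_mm: float = 40.0
    heterogeneity: float = 0.05
    noise_sigma: float = 0.02
    noise_kernel: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if self.n_slices < 4 or self.n_rows < 8 or self.n_cols < 8:
            raise ValidationError("grid too small for a phantom")
        for s in (self.s_bladder, self.s_rectum):
            if not 0.0 <= s <= 0.5:
                raise ValidationError("sparing strengths must be in [0, 0.5]")
        if self.noise_sigma < 0:
            raise ValidationError("noise sigma must be >= 0")
        if min(self.ptv_radius_frac + self.bladder_radius_frac
               + self.rectum_radius_frac) <= 0:
            raise ValidationError("radii must be positive")


@dataclass
class PriorityGridSpec:
    """Bounding priority vectors + the number of convex-combination plans."""

    bounding: tuple[PriorityVector, PriorityVector, PriorityVector] = (
        PriorityVector(10.0, 1.0, 1.0),
        PriorityVector(1.0, 10.0, 1.0),
        PriorityVector(1.0, 1.0, 10.0),
    )
    n_plans: int = 25

    def __post_init__(self) -> None:
        if self.n_plans < 3:
            raise ValidationError("n_plans must be >= 3")
        arrs = [tuple(b.as_array()) for b in self.bounding]
        if len(set(arrs)) != 3:
            raise ValidationError("bounding priority vectors must be distinct")


def priority_grid(spec: PriorityGridSpec) -> list[PriorityVector]:
    """The deterministic convex-combination grid of priority vectors.

    With n_plans = m^2 the parameters run over (alpha, beta) in
    {0, 1/(m-1), ..., 1}^2 (alpha outer, row-major) and

        p = alpha * P1 + (1 - alpha) * (beta * P2 + (1 - beta) * P3)

    Duplicates produced at alpha = 1 are retained so the grid stays matched
    to the (alpha, beta) triangulation plane.
    """
    side = int(round(math.sqrt(spec.n_plans)))
    if side * side != spec.n_plans:
        raise ValidationError("n_plans must be a perfect square for the grid scheme")
    p1, p2, p3 = (b.as_array() for b in spec.bounding)
    ticks = np.linspace(0.0, 1.0, side)
    out = []
    for alpha in ticks:
        for beta in ticks:
            p = alpha * p1 + (1.0 - alpha) * (beta * p2 + (1.0 - beta) * p3)
            out.append(PriorityVector(*p))
    return out


# ---------------------------------------------------------------------------
# Anatomy
# ---------------------------------------------------------------------------

def _ellipsoid(shape, spacing, centre_mm, radii_mm) -> np.ndarray:
    coords = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    zz = (coords[0] - centre_mm[0]) / radii_mm[0]
    yy = (coords[1] - centre_mm[1]) / radii_mm[1]
    xx = (coords[2] - centre_mm[2]) / radii_mm[2]
    return (zz[:, None, None] ** 2 + yy[None, :, None] ** 2
            + xx[None, None, :] ** 2) <= 1.0


def generate_anatomy(config: PhantomConfig, patient_index: int) -> StructureSet:
    """One jittered pelvic phantom; deterministic in (config.seed, index)."""
    rng = np.random.default_rng([config.seed, patient_index])
    shape = (config.n_slices, config.n_rows, config.n_cols)
    spacing = config.spacing
    extent = np.array([n * s for n, s in zip(shape, spacing)])  # mm
    half = extent / 2.0

    def jitter_centre():
        return rng.uniform(-config.centre_jitter_mm, config.centre_jitter_mm, 3)

    def jitter_radii(base, sp=spacing):
        r = np.asarray(base) * (1.0 + rng.uniform(-config.radius_jitter,
                                                  config.radius_jitter,
                                                  len(base)))
        # floor at just over one voxel pitch so every structure catches at
        # least one voxel centre even on coarse grids
        return np.maximum(r, 1.05 * np.asarray(sp[-len(base):]))

    # body: large ellipse per slice, spanning all slices
    body_r = np.array([10 * extent[0],  # effectively a cylinder along z
                       config.body_frac[0] * half[1],
                       config.body_frac[1] * half[2]])
    body = _ellipsoid(shape, spacing, half, body_r)

    ptv_r = jitter_radii([f * h for f, h in zip(config.ptv_radius_frac, half)])
    if np.any(2 * ptv_r > extent):
        raise ValidationError("PTV radius too large for the grid")
    # clamp the jittered centre so the target always fits inside the grid
    ptv_c = np.clip(half + jitter_centre(), ptv_r, extent - ptv_r)
    ptv = _ellipsoid(shape, spacing, ptv_c, ptv_r)

    # bladder: anterior (smaller row) and superior (smaller slice) of the PTV
    bl_r = jitter_radii([f * h for f, h in zip(config.bladder_radius_frac, half)])
    bl_c = ptv_c + np.array([-(ptv_r[0] + bl_r[0]) * 0.85,
                             -(ptv_r[1] + bl_r[1]) * 0.85, 0.0]) + jitter_centre() * 0.5
    bladder = _ellipsoid(shape, spacing, bl_c, bl_r)

    # rectum: posterior tube along the slice axis
    re_r = jitter_radii([f * h for f, h in
                         zip(config.rectum_radius_frac, half[1:])])
    re_c = ptv_c[1:] + np.array([(ptv_r[1] + re_r[0]) * 1.1, 0.0]) \
        + jitter_centre()[1:] * 0.5
    coords_r = (np.arange(shape[1]) + 0.5) * spacing[1]
    coords_c = (np.arange(shape[2]) + 0.5) * spacing[2]
    tube2d = (((coords_r - re_c[0]) / re_r[0]) ** 2)[:, None] \
        + (((coords_c - re_c[1]) / re_r[1]) ** 2)[None, :] <= 1.0
    lo = int(shape[0] * 0.15)
    hi = int(shape[0] * 0.9)
    rectum = np.zeros(shape, dtype=bool)
    rectum[lo:hi] = tube2d

    ptv &= body
    bladder &= body & ~ptv
    rectum &= body & ~ptv & ~bladder
    if not ptv.any():
        raise ValidationError("generated PTV is empty")

    def mk(m):
        return VoxelGrid(values=m.astype(np.float64), spacing=spacing)

    return StructureSet(masks={"ptv": mk(ptv), "bladder": mk(bladder),
                               "rectum": mk(rectum), "body": mk(body)})


# ---------------------------------------------------------------------------
# Surrogate dose
# ---------------------------------------------------------------------------

def _inplane_organ_distance(mask: np.ndarray, spacing, cap: float) -> np.ndarray:
    out = np.full(mask.shape, cap, dtype=np.float64)
    for s in range(mask.shape[0]):
        if mask[s].any():
            out[s] = ndimage.distance_transform_edt(
                ~mask[s], sampling=(spacing[1], spacing[2]))
    return out


def _smooth_field(shape, rng, kernel: int) -> np.ndarray:
    """Zero-mean, unit-variance spatially smooth random field."""
    white = rng.standard_normal(shape)
    out = np.empty_like(white)
    for s in range(shape[0]):
        out[s] = smooth2d(white[s], kernel)
    out -= out.mean()
    sd = out.std()
    return out / sd if sd > 0 else out


def simulate_tps_dose(structures: StructureSet, priorities: PriorityVector,
                      config: PhantomConfig, rng_seed: int) -> VoxelGrid:
    """Surrogate planning-system dose for one plan, D95%-normalized.

    The random fields (PTV heterogeneity pattern and noise) are derived from
    ``rng_seed`` alone, so all plans of one patient share them and the
    priority -> objective trade-offs are exactly monotone when sigma = 0.
    """
    grid = structures.grid
    ptv = structures.bool_mask("ptv")
    cap = grid.diagonal_mm()

    dmaps = compute_distance_maps(structures)
    dose = init_dose(dmaps, config.true_init).values.copy()

    # anisotropic (anterior/posterior) component outside the PTV: real arc
    # doses are not radially symmetric around the target, and this is the
    # part of the surrogate that the isotropic initialization cannot fit
    if config.anisotropy > 0:
        com = np.argwhere(ptv).mean(axis=0)  # (slice, row, col) in voxels
        rr = ((np.arange(dose.shape[1]) + 0.5) - (com[1] + 0.5)) * grid.spacing[1]
        cc = ((np.arange(dose.shape[2]) + 0.5) - (com[2] + 0.5)) * grid.spacing[2]
        radius = np.hypot(rr[:, None], cc[None, :])
        cos_theta = -rr[:, None] / np.maximum(radius, 1e-9)  # +1 anterior
        aniso = config.anisotropy * cos_theta[None, :, :] \
            * np.exp(-dmaps.d_inplane.values / config.anisotropy_range_mm)
        aniso[ptv] = 0.0
        dose = np.clip(dose + aniso, 0.0, None)

    # organ sparing (outside the PTV only)
    w = priorities.as_array()
    sparing = np.ones_like(dose)
    for organ, strength, w_o in (("bladder", config.s_bladder, w[1]),
                                 ("rectum", config.s_rectum, w[2])):
        if strength == 0 or w_o == 0:
            continue
        d_o = _inplane_organ_distance(structures.bool_mask(organ),
                                      grid.spacing, cap)
        sparing -= strength * (w_o / (1.0 + w_o)) \
            * np.exp(-d_o / config.sparing_tau_mm)
    sparing = np.clip(sparing, 0.0, None)
    sparing[ptv] = 1.0
    dose *= sparing

    # PTV heterogeneity, shrinking with the homogeneity priority
    if config.heterogeneity > 0:
        g = _smooth_field(dose.shape, np.random.default_rng([rng_seed, 0]),
                          config.noise_kernel)
        het = 1.0 + config.heterogeneity * (1.0 / (1.0 + w[0])) * g
        dose[ptv] *= het[ptv]

    if config.noise_sigma > 0:
        noise = _smooth_field(dose.shape, np.random.default_rng([rng_seed, 1]),
                              config.noise_kernel)
        dose += config.noise_sigma * noise

    np.clip(dose, 0.0, None, out=dose)
    return normalize_to_d95(grid.copy_with(dose), structures["ptv"])


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: PhantomConfig, spec: PriorityGridSpec, out_dir,
                    priorities_override: Optional[Sequence[PriorityVector]] = None
                    ) -> Path:
    """Write a full cohort (masks, doses, manifest JSON); returns the manifest
    path. ``priorities_override`` replaces the grid scheme with an explicit
    plan list (used for small training cohorts)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plan_priorities = (list(priorities_override) if priorities_override
                       else priority_grid(spec))
    manifest = {"spacing": list(config.spacing),
                "shape": [config.n_slices, config.n_rows, config.n_cols],
                "patients": []}
    for pi in range(config.n_patients):
        pid = f"patient{pi:03d}"
        pdir = out_dir / pid
        pdir.mkdir(exist_ok=True)
        structures = generate_anatomy(config, pi)
        mask_paths = {}
        for name in ("ptv", "bladder", "rectum", "body"):
            rel = f"{pid}/{name}.nii.gz"
            write_grid(structures[name], out_dir / rel)
            mask_paths[name] = rel
        entry = {"patient_id": pid, "masks": mask_paths, "plans": []}
        patient_seed = int(np.random.default_rng(
            [config.seed, 1000 + pi]).integers(0, 2 ** 31 - 1))
        for qi, pri in enumerate(plan_priorities):
            dose = simulate_tps_dose(structures, pri, config, patient_seed)
            rel = f"{pid}/dose{qi:03d}.nii.gz"
            write_grid(dose, out_dir / rel)
            entry["plans"].append({"plan_id": f"{pid}-plan{qi:03d}",
                                   "priorities": [float(x) for x in pri.as_array()],
                                   "dose": rel})
        manifest["patients"].append(entry)
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest_path


def generate_cohort_in_memory(config: PhantomConfig,
                              priorities: Sequence[PriorityVector]):
    """Like :func:`generate_cohort` but returns PlanRecords without touching
    disk (the workhorse for tests and desk-scale experiments)."""
    from .grids import PlanRecord

    plans = []
    for pi in range(config.n_patients):
        structures = generate_anatomy(config, pi)
        patient_seed = int(np.random.default_rng(
            [config.seed, 1000 + pi]).integers(0, 2 ** 31 - 1))
        for qi, pri in enumerate(priorities):
            dose = simulate_tps_dose(structures, pri, config, patient_seed)
            plans.append(PlanRecord(structures=structures, priorities=pri,
                                    reference_dose=dose,
                                    patient_id=f"patient{pi:03d}",
                                    plan_id=f"patient{pi:03d}-plan{qi:03d}"))
    return plans
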
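"""DVH metrics, D95% normalization, Pareto-surface construction and the four
surface-distance metrics (matched RMSE, Hausdorff, APD, ANPD).

Objective space is 3-D: (PTV homogeneity index HI = D2% - D98%, bladder D25%,
rectum D25%), all in % of prescription. A patient's Pareto surface is the set
of objective vectors of its 25 plans, sampled on a 5x5 grid of convex
combinations of three bounding priority vectors; the surface is triangulated
in that 2-D (alpha, beta) parameter plane (objective-space triangulation of a
curved surface can flip simplices) and the triangles are carried to objective
space.

Dx% convention: structure doses sorted descending, element ceil(x/100 * N)
(1-based), no interpolation — the minimum dose of the hottest x% of volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegenerateDirectionError, ValidationError
from .grids import PriorityVector, StructureSet, VoxelGrid


# ---------------------------------------------------------------------------
# DVH metrics and normalization
# ---------------------------------------------------------------------------

def dvh_dose_at_volume(dose: VoxelGrid, mask: VoxelGrid, x: float) -> float:
    """Dx%: minimum dose (% of prescription) of the hottest x% of the mask."""
    if not 0 < x <= 100:
        raise ValidationError("x must be in (0, 100]")
    m = mask.values.astype(bool)
    if not m.any():
        raise ValidationError("empty structure mask")
    vals = np.sort(dose.values[m])[::-1]
    idx = math.ceil(x / 100.0 * vals.size)  # 1-based rank
    return 100.0 * float(vals[idx - 1])


def normalize_to_d95(dose: VoxelGrid, ptv: VoxelGrid) -> VoxelGrid:
    """Scale a dose so that PTV D95% equals exactly 100% of prescription."""
    d95 = dvh_dose_at_volume(dose, ptv, 95.0) / 100.0
    if d95 <= 0:
        raise ValidationError("PTV D95% is zero; cannot normalize")
    return dose.copy_with(dose.values / d95)


@dataclass(frozen=True)
class ParetoPoint:
    """One plan's objectives, in % of prescription."""

    hi: float
    bladder_d25: float
    rectum_d25: float

    def as_array(self) -> np.ndarray:
        return np.array([self.hi, self.bladder_d25, self.rectum_d25])


def compute_objectives(dose: VoxelGrid, structures: StructureSet) -> ParetoPoint:
    """(HI, bladder D25%, rectum D25%) of one dose map."""
    ptv = structures["ptv"]
    hi = dvh_dose_at_volume(dose, ptv, 2.0) - dvh_dose_at_volume(dose, ptv, 98.0)
    return ParetoPoint(
        hi=hi,
        bladder_d25=dvh_dose_at_volume(dose, structures["bladder"], 25.0),
        rectum_d25=dvh_dose_at_volume(dose, structures["rectum"], 25.0),
    )


# ---------------------------------------------------------------------------
# Surface construction
# ---------------------------------------------------------------------------

@dataclass
class ParetoSurface:
    """Sampled Pareto surface: objective-space vertices + a simplicial complex.

    ``params`` holds each vertex's (alpha, beta) coordinates in the convex-
    combination parameter plane used for triangulation.
    """

    vertices: np.ndarray          # (n, 3) objective space
    simplices: np.ndarray         # (m, 3) vertex indices
    params: np.ndarray            # (n, 2) triangulation-plane coordinates
    priorities: list[PriorityVector]
    plan_ids: list[str]

    def __post_init__(self) -> None:
        if self.simplices.size and (self.simplices.min() < 0
                                    or self.simplices.max() >= len(self.vertices)):
            raise ValidationError("simplex indices out of range")


def grid_param_coords(n_points: int) -> np.ndarray:
    """(alpha, beta) coordinates of the deterministic convex-combination grid,
    row-major with alpha as the outer loop (matching the priority grid)."""
    side = int(round(math.sqrt(n_points)))
    if side * side != n_points or side < 2:
        raise ValidationError(f"{n_points} points do not form a square grid")
    ticks = np.linspace(0.0, 1.0, side)
    a, b = np.meshgrid(ticks, ticks, indexing="ij")
    return np.column_stack([a.ravel(), b.ravel()])


def build_surface(points: Sequence[tuple[PriorityVector, ParetoPoint]],
                  param_coords: Optional[np.ndarray] = None,
                  plan_ids: Optional[Sequence[str]] = None) -> ParetoSurface:
    """Triangulate sampled plans into a Pareto surface.

    ``param_coords`` are the 2-D parameter-plane coordinates of the samples;
    if omitted they are inferred from the square-grid sampling scheme (so a
    5x5 grid yields 25 vertices and 2*(5-1)^2 = 32 triangles; exactly 3
    points yield a single triangle).
    """
    n = len(points)
    if n < 3:
        raise ValidationError("need at least 3 sampled plans")
    vertices = np.array([p.as_array() for _, p in points], dtype=np.float64)
    priorities = [pri for pri, _ in points]
    if plan_ids is None:
        plan_ids = [str(i) for i in range(n)]
    if param_coords is None:
        if n == 3:
            param_coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
            simplices = np.array([[0, 1, 2]])
            return ParetoSurface(vertices, simplices, param_coords,
                                 priorities, list(plan_ids))
        param_coords = grid_param_coords(n)
    else:
        param_coords = np.asarray(param_coords, dtype=np.float64)
        if param_coords.shape != (n, 2):
            raise ValidationError("param_coords must have shape (n, 2)")
    uniq = {tuple(np.round(c, 12)) for c in param_coords}
    if len(uniq) != n:
        raise ValidationError("duplicated parameter coordinates")
    side = int(round(math.sqrt(n)))
    if side * side != n:
        raise ValidationError("non-square sample count needs explicit simplices")
    # structured triangulation of the (alpha, beta) grid: 2 triangles per cell
    tris = []
    for i in range(side - 1):
        for j in range(side - 1):
            v00 = i * side + j
            v01 = v00 + 1
            v10 = v00 + side
            v11 = v10 + 1
            tris.append([v00, v01, v11])
            tris.append([v00, v11, v10])
    return ParetoSurface(vertices, np.array(tris), param_coords, priorities,
                         list(plan_ids))


# ---------------------------------------------------------------------------
# Surface distance metrics
# ---------------------------------------------------------------------------

def pareto_rmse(matched: Sequence[tuple[np.ndarray, np.ndarray]]) -> float:
    """RMSE over matched objective-space pairs; per-pair errors accumulate the
    three objective components through the 3-D Euclidean distance."""
    if len(matched) == 0:
        raise ValidationError("no matched pairs")
    sq = [float(np.sum((np.asarray(x) - np.asarray(y)) ** 2)) for x, y in matched]
    return float(np.sqrt(np.mean(sq)))


def hausdorff(A: np.ndarray, B: np.ndarray) -> float:
    """Hausdorff distance between two finite vertex sets."""
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    B = np.atleast_2d(np.asarray(B, dtype=np.float64))
    if A.size == 0 or B.size == 0:
        raise ValidationError("empty point set")
    d = cdist(A, B)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def apd(matched: Sequence[tuple[np.ndarray, np.ndarray]],
        zero_tol: float = 1e-12) -> float:
    """Average projected distance of matched pairs.

    Displacements x_i - y_i are projected onto the direction of the mean
    displacement and averaged. If the mean displacement is ~zero the formula
    is undefined — unless every displacement is itself ~zero (surface
    self-comparison), which returns 0 by convention.
    """
    if len(matched) == 0:
        raise ValidationError("no matched pairs")
    disp = np.array([np.asarray(x, dtype=np.float64) - np.asarray(y, dtype=np.float64)
                     for x, y in matched])
    mean = disp.mean(axis=0)
    norm = float(np.linalg.norm(mean))
    if norm < zero_tol:
        if float(np.abs(disp).max(initial=0.0)) < zero_tol:
            return 0.0
        raise DegenerateDirectionError(
            "mean displacement ~0 with nonzero displacements; APD undefined")
    return float(np.mean(disp @ (mean / norm)))


def _point_segment_dist2(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-30:
        d = p - a
        return np.einsum("ij,ij->i", d, d)
    t = np.clip((p - a) @ ab / denom, 0.0, 1.0)
    d = p - (a + t[:, None] * ab)
    return np.einsum("ij,ij->i", d, d)


def _point_triangle_dist2(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Squared distance from each point (n, 3) to one triangle (3, 3)."""
    a, b, c = tri
    ab = b - a
    ac = c - a
    n = np.cross(ab, ac)
    n2 = float(n @ n)
    edge = np.minimum(_point_segment_dist2(p, a, b),
                      np.minimum(_point_segment_dist2(p, b, c),
                                 _point_segment_dist2(p, c, a)))
    if n2 < 1e-30:  # degenerate triangle: fall back to edges
        return edge
    ap = p - a
    # barycentric coordinates of the in-plane projection
    d00 = float(ab @ ab)
    d01 = float(ab @ ac)
    d11 = float(ac @ ac)
    d20 = ap @ ab
    d21 = ap @ ac
    denom = d00 * d11 - d01 * d01
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    inside = (v >= 0) & (w >= 0) & (v + w <= 1)
    dist_n = (ap @ n) ** 2 / n2
    return np.where(inside, dist_n, edge)


def point_to_complex_distance(points: np.ndarray, surface: ParetoSurface
                              ) -> np.ndarray:
    """Exact minimum distance from each point to a surface's triangles."""
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    best = np.full(len(points), np.inf)
    for tri_idx in surface.simplices:
        tri = surface.vertices[tri_idx]
        np.minimum(best, _point_triangle_dist2(points, tri), out=best)
    return np.sqrt(best)


def supersample_surface(surface: ParetoSurface, density: int = 105) -> np.ndarray:
    """Barycentric supersampling: >= ``density`` points per triangle.

    Subdivision level L yields (L+1)(L+2)/2 points per triangle; the default
    density of 105 corresponds to L = 13.
    """
    if density < 1:
        raise ValidationError("density must be >= 1")
    level = 0
    while (level + 1) * (level + 2) // 2 < density:
        level += 1
    ij = [(i, j) for i in range(level + 1) for j in range(level + 1 - i)]
    bary = np.array([
        (i / level, j / level, (level - i - j) / level) if level else (1.0, 0.0, 0.0)
        for i, j in ij])
    samples = []
    for tri_idx in surface.simplices:
        tri = surface.vertices[tri_idx]
        samples.append(bary @ tri)
    return np.vstack(samples)


def anpd(surfA: ParetoSurface, surfB: ParetoSurface, density: int = 105) -> float:
    """Average nearest-point distance between two simplicial surfaces.

    Each surface is supersampled on a barycentric grid; each sample's exact
    minimum distance to the *other* surface's complex (point-to-triangle) is
    averaged per direction, then the two directed means are averaged.
    """
    if len(surfA.simplices) == 0 or len(surfB.simplices) == 0:
        raise ValidationError("surfaces must have at least one simplex")
    pa = supersample_surface(surfA, density)
    pb = supersample_surface(surfB, density)
    a_to_b = float(point_to_complex_distance(pa, surfB).mean())
    b_to_a = float(point_to_complex_distance(pb, surfA).mean())
    return 0.5 * (a_to_b + b_to_a)


def surface_to_json(surface: ParetoSurface) -> dict:
    """JSON-serializable surface: vertices, simplices, parameters, plan ids."""
    return {
        "plan_ids": list(surface.plan_ids),
        "vertices": [list(map(float, v)) for v in surface.vertices],
        "simplices": [list(map(int, s)) for s in surface.simplices],
        "params": [list(map(float, p)) for p in surface.params],
        "priorities": [list(map(float, p.as_array()))
                       for p in surface.priorities],
    }


def surface_to_csv(surface: ParetoSurface, path) -> None:
    """One CSV row per vertex: plan_id, hi, bladder_d25, rectum_d25."""
    import pandas as pd

    pd.DataFrame({
        "plan_id": surface.plan_ids,
        "hi": surface.vertices[:, 0],
        "bladder_d25": surface.vertices[:, 1],
        "rectum_d25": surface.vertices[:, 2],
    }).to_csv(path, index=False)


def surface_metrics(pred: ParetoSurface, ref: ParetoSurface,
                    density: int = 105) -> dict[str, float]:
    """All four metrics between matched predicted and reference surfaces."""
    if len(pred.vertices) != len(ref.vertices):
        raise ValidationError("matched surfaces need equal vertex counts")
    pairs = list(zip(pred.vertices, ref.vertices))
    return {
        "rmse": pareto_rmse(pairs),
        "hausdorff": hausdorff(pred.vertices, ref.vertices),
        "apd": apd(pairs),
        "anpd": anpd(pred, ref, density=density),
    }
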
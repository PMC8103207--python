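"""Priority scaling, uniform smoothing, atrous patch extraction and per-voxel
feature assembly.

Feature layout (length 975 for the default three atrous rates):

    [rate 1 | PTV(81) bladder(81) rectum(81) dose(81)]
    [rate 3 | PTV(81) bladder(81) rectum(81) dose(81)]
    [rate 10| PTV(81) bladder(81) rectum(81) dose(81)]
    [w_hi, w_bladder, w_rectum]

Patches are 9x9, transverse (2-D, within the voxel's slice), sampled at
offsets {-4r..+4r} around the voxel in row-major order; samples outside the
slice are zero. Before extraction at rate r > 1 every channel (structure maps
*and* the dose map) is smoothed with a uniform r x r kernel so each atrous
sample summarizes the voxels the dilation skips. Smoothing uses zero padding;
for an even kernel the anchor sits at the top-left of the central 2x2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .grids import PriorityVector, StructureSet, VoxelGrid

PATCH_SIDE = 9
PATCH_LEN = PATCH_SIDE * PATCH_SIDE  # 81
CHANNELS = ("ptv", "bladder", "rectum", "dose")
N_PRIORITIES = 3


@dataclass(frozen=True)
class AtrousSpec:
    """One patch set: dilation rate and the matching smoothing kernel size."""

    rate: int
    smoothing_kernel: int
    patch_side: int = PATCH_SIDE

    def __post_init__(self) -> None:
        if self.rate < 1:
            raise ValidationError("atrous rate must be >= 1")
        if self.smoothing_kernel < 1:
            raise ValidationError("smoothing kernel must be >= 1")
        if self.patch_side % 2 != 1:
            raise ValidationError("patch side must be odd")


DEFAULT_SPECS: tuple[AtrousSpec, ...] = (
    AtrousSpec(rate=1, smoothing_kernel=1),
    AtrousSpec(rate=3, smoothing_kernel=3),
    AtrousSpec(rate=10, smoothing_kernel=10),
)


def n_features(specs=DEFAULT_SPECS) -> int:
    return len(CHANNELS) * len(specs) * PATCH_LEN + N_PRIORITIES


def dose_column_slice(rate_index: int, specs=DEFAULT_SPECS) -> slice:
    """Columns of the dose channel for one atrous set in the feature matrix."""
    base = rate_index * len(CHANNELS) * PATCH_LEN + 3 * PATCH_LEN
    return slice(base, base + PATCH_LEN)


# ---------------------------------------------------------------------------
# Priority scaling
# ---------------------------------------------------------------------------

def scale_masks(structures: StructureSet, priorities: PriorityVector
                ) -> tuple[VoxelGrid, VoxelGrid, VoxelGrid]:
    """PTV, bladder and rectum masks multiplied by their priorities."""
    w = priorities.as_array()
    return (
        structures["ptv"].copy_with(structures["ptv"].values * w[0]),
        structures["bladder"].copy_with(structures["bladder"].values * w[1]),
        structures["rectum"].copy_with(structures["rectum"].values * w[2]),
    )


# ---------------------------------------------------------------------------
# Uniform smoothing
# ---------------------------------------------------------------------------

def _window_extents(k: int) -> tuple[int, int]:
    # offsets [-a, +b]; for odd k a == b, for even k the anchor is the
    # top-left of the central 2x2 (a = k/2 - 1, b = k/2)
    return (k - 1) // 2, k // 2


def smooth2d(arr: np.ndarray, k: int, transpose: bool = False) -> np.ndarray:
    """2-D uniform k x k smoothing of one slice with zero padding.

    ``transpose=True`` applies the adjoint operator (the window extents are
    mirrored), which backpropagation uses.
    """
    if k == 1:
        return arr.copy()
    a, b = _window_extents(k)
    if transpose:
        a, b = b, a
    r, c = arr.shape
    integ = np.zeros((r + 1, c + 1), dtype=np.float64)
    np.cumsum(arr, axis=0, out=integ[1:, 1:])
    np.cumsum(integ[1:, 1:], axis=1, out=integ[1:, 1:])
    i = np.arange(r)[:, None]
    j = np.arange(c)[None, :]
    r1 = np.clip(i - a, 0, r)
    r2 = np.clip(i + b + 1, 0, r)
    c1 = np.clip(j - a, 0, c)
    c2 = np.clip(j + b + 1, 0, c)
    out = (integ[r2, c2] - integ[r1, c2] - integ[r2, c1] + integ[r1, c1])
    return out / float(k * k)


def smooth_uniform(grid: VoxelGrid, k: int) -> VoxelGrid:
    """Per-slice uniform k x k smoothing of a grid (k = 1 is the identity)."""
    if k < 1:
        raise ValidationError("kernel size must be >= 1")
    if k > 128:
        raise ValidationError("kernel size must be <= 128")
    out = np.empty_like(grid.values)
    for s in range(grid.n_slices):
        out[s] = smooth2d(grid.values[s], k)
    return grid.copy_with(out)


# ---------------------------------------------------------------------------
# Atrous patch extraction
# ---------------------------------------------------------------------------

def _offsets(spec: AtrousSpec) -> np.ndarray:
    half = spec.patch_side // 2
    return spec.rate * np.arange(-half, half + 1)


def extract_patch(grid: VoxelGrid, voxel: tuple[int, int, int], spec: AtrousSpec
                  ) -> np.ndarray:
    """81-element atrous patch of one voxel's slice, row-major, zero-padded.

    Smoothing is *not* applied here; the caller smooths the grid first.
    """
    s, row, col = voxel
    vals = grid.values
    if not (0 <= s < vals.shape[0] and 0 <= row < vals.shape[1] and 0 <= col < vals.shape[2]):
        raise ValidationError(f"voxel {voxel} outside grid of shape {vals.shape}")
    sl = vals[s]
    offs = _offsets(spec)
    out = np.zeros(spec.patch_side * spec.patch_side, dtype=np.float64)
    idx = 0
    for dr in offs:
        rr = row + dr
        for dc in offs:
            cc = col + dc
            if 0 <= rr < sl.shape[0] and 0 <= cc < sl.shape[1]:
                out[idx] = sl[rr, cc]
            idx += 1
    return out


def patch_matrix(slice2d: np.ndarray, spec: AtrousSpec) -> np.ndarray:
    """Patches of *all* voxels of a slice: array of shape (R*C, 81).

    Row-major over voxels and over patch offsets, matching
    :func:`extract_patch` at each voxel.
    """
    r, c = slice2d.shape
    half = spec.patch_side // 2
    pad = half * spec.rate
    padded = np.zeros((r + 2 * pad, c + 2 * pad), dtype=slice2d.dtype)
    padded[pad:pad + r, pad:pad + c] = slice2d
    out = np.empty((r * c, spec.patch_side * spec.patch_side), dtype=slice2d.dtype)
    offs = _offsets(spec)
    k = 0
    for dr in offs:
        for dc in offs:
            out[:, k] = padded[pad + dr:pad + dr + r, pad + dc:pad + dc + c].ravel()
            k += 1
    return out


def scatter_patch_matrix(dpatch: np.ndarray, shape: tuple[int, int],
                         spec: AtrousSpec) -> np.ndarray:
    """Adjoint of :func:`patch_matrix`: scatter patch-gradients back to a slice."""
    r, c = shape
    half = spec.patch_side // 2
    pad = half * spec.rate
    padded = np.zeros((r + 2 * pad, c + 2 * pad), dtype=np.float64)
    offs = _offsets(spec)
    k = 0
    for dr in offs:
        for dc in offs:
            padded[pad + dr:pad + dr + r, pad + dc:pad + dc + c] += \
                dpatch[:, k].reshape(r, c)
            k += 1
    return padded[pad:pad + r, pad:pad + c]


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

def assemble_features(scaled_masks, dose: VoxelGrid, priorities: PriorityVector,
                      voxel: tuple[int, int, int], specs=DEFAULT_SPECS) -> np.ndarray:
    """Full feature vector of one voxel (see the module docstring for layout)."""
    channels = list(scaled_masks) + [dose]
    shape = dose.shape
    for g in channels:
        if g.shape != shape:
            raise ValidationError("feature channels must share one shape")
    pieces = []
    for spec in specs:
        for grid in channels:
            smoothed = smooth_uniform(grid, spec.smoothing_kernel) \
                if spec.smoothing_kernel > 1 else grid
            pieces.append(extract_patch(smoothed, voxel, spec))
    pieces.append(priorities.as_array())
    return np.concatenate(pieces)


def structure_feature_blocks(structures: StructureSet, slice_index: int,
                             specs=DEFAULT_SPECS, dtype=np.float64) -> np.ndarray:
    """Patch blocks of the *unscaled* structure channels of one slice.

    Returns an array of shape ``(n_specs, 3, R*C, 81)``; multiplying block
    ``[:, ch]`` by the channel's priority gives the scaled-mask features, so
    one set of blocks serves every plan of a patient.
    """
    out = None
    for si, spec in enumerate(specs):
        for ci, name in enumerate(("ptv", "bladder", "rectum")):
            sl = structures[name].values[slice_index].astype(dtype)
            if spec.smoothing_kernel > 1:
                sl = smooth2d(sl, spec.smoothing_kernel).astype(dtype)
            block = patch_matrix(sl, spec)
            if out is None:
                out = np.empty((len(specs), 3) + block.shape, dtype=dtype)
            out[si, ci] = block
    return out


def slice_feature_matrix(struct_blocks: np.ndarray, dose_slice: np.ndarray,
                         priorities: PriorityVector, specs=DEFAULT_SPECS,
                         dtype=np.float64, out: np.ndarray | None = None) -> np.ndarray:
    """Feature matrix (R*C, n_features) of one slice.

    ``struct_blocks`` comes from :func:`structure_feature_blocks`;
    ``dose_slice`` is the current 2-D dose of the slice (re-extracted every
    residual block).
    """
    n_vox = struct_blocks.shape[2]
    nf = len(CHANNELS) * len(specs) * PATCH_LEN + N_PRIORITIES
    if out is None:
        out = np.empty((n_vox, nf), dtype=dtype)
    w = priorities.as_array().astype(dtype)
    col = 0
    for si, spec in enumerate(specs):
        for ci in range(3):
            np.multiply(struct_blocks[si, ci], w[ci], out=out[:, col:col + PATCH_LEN])
            col += PATCH_LEN
        d = dose_slice.astype(dtype, copy=False)
        if spec.smoothing_kernel > 1:
            d = smooth2d(d, spec.smoothing_kernel).astype(dtype)
        out[:, col:col + PATCH_LEN] = patch_matrix(d, spec)
        col += PATCH_LEN
    out[:, col:col + N_PRIORITIES] = w
    return out


def update_dose_columns(X: np.ndarray, dose_slice: np.ndarray,
                        specs=DEFAULT_SPECS, dtype=np.float64) -> None:
    """Rewrite only the dose-channel columns of a feature matrix in place
    (the structure columns are constant across residual blocks)."""
    for si, spec in enumerate(specs):
        d = dose_slice.astype(dtype, copy=False)
        if spec.smoothing_kernel > 1:
            d = smooth2d(d, spec.smoothing_kernel).astype(dtype)
        X[:, dose_column_slice(si, specs)] = patch_matrix(d, spec)
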
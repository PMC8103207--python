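"""Voxel-wise residual network that sequentially refines the initialized dose.

The network is a stack of (by default six) residual blocks. Each block is a
small fully connected net applied independently at every voxel: two hidden
layers of 100 leaky-ReLU units followed by a single output with a scaled
softsign activation, so each block contributes a dose shift bounded by
+-0.3 of prescription. The block input is the voxel's feature vector
(atrous patches of the priority-scaled structure maps and of the *current*
dose map, plus the raw priority triplet); because every block changes the
dose map, the dose-channel patches are re-extracted after each update while
the structure-channel patches are computed once per slice.

Everything here is plain numpy; gradients for training are computed by the
hand-written reverse pass in :func:`backward_slice`, which mirrors
:func:`forward_slice` exactly (patch gather -> scatter-add, smoothing -> its
adjoint).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dose_init import InitParams, compute_distance_maps, init_dose
from .errors import ValidationError
from .features import (DEFAULT_SPECS, AtrousSpec, dose_column_slice, n_features,
                       patch_matrix, scatter_patch_matrix, slice_feature_matrix,
                       smooth2d, structure_feature_blocks, update_dose_columns)
from .grids import PlanRecord, PriorityVector, VoxelGrid

SOFTSIGN_SCALE = 0.3
LRELU_SLOPE = 0.2
DEFAULT_WIDTHS = (100, 100)
DEFAULT_N_BLOCKS = 6


def lrelu(x):
    """Leaky ReLU: x for x > 0, else 0.2 x."""
    x = np.asarray(x)
    return np.maximum(x, LRELU_SLOPE * x)


def scaled_softsign(x):
    """0.3 * x / (1 + |x|); range (-0.3, 0.3)."""
    x = np.asarray(x)
    return SOFTSIGN_SCALE * x / (1.0 + np.abs(x))


def _lrelu_grad_from_output(h):
    # h > 0 iff the pre-activation was > 0 (the map is sign-preserving)
    return np.where(h > 0, 1.0, LRELU_SLOPE).astype(h.dtype)


def _softsign_grad(z):
    d = 1.0 + np.abs(z)
    return (SOFTSIGN_SCALE / (d * d)).astype(z.dtype)


@dataclass
class BlockParams:
    """Weights of one residual block (three fully connected layers)."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    W3: np.ndarray
    b3: np.ndarray

    def arrays(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2, self.W3, self.b3]

    def astype(self, dtype) -> "BlockParams":
        return BlockParams(*[a.astype(dtype) for a in self.arrays()])


@dataclass
class ModelParams:
    """Full model: fitted initialization constants + the residual blocks."""

    blocks: list[BlockParams]
    init_params: Optional[InitParams] = None
    specs: Sequence[AtrousSpec] = DEFAULT_SPECS
    feature_version: str = "atrous-1-3-10/ptv-bladder-rectum-dose/v1"

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def arrays(self) -> list[np.ndarray]:
        return [a for b in self.blocks for a in b.arrays()]


def init_model_glorot(seed: int, n_feat: Optional[int] = None,
                      widths: Sequence[int] = DEFAULT_WIDTHS,
                      n_blocks: int = DEFAULT_N_BLOCKS,
                      specs: Sequence[AtrousSpec] = DEFAULT_SPECS) -> ModelParams:
    """Glorot-uniform weights (U(+-sqrt(6/(fan_in+fan_out)))), zero biases."""
    if n_feat is None:
        n_feat = n_features(specs)
    rng = np.random.default_rng(seed)
    dims = [n_feat, *widths, 1]
    blocks = []
    for _ in range(n_blocks):
        mats, biases = [], []
        for fi, fo in zip(dims[:-1], dims[1:]):
            bound = np.sqrt(6.0 / (fi + fo))
            mats.append(rng.uniform(-bound, bound, size=(fi, fo)))
            biases.append(np.zeros(fo))
        blocks.append(BlockParams(mats[0], biases[0], mats[1], biases[1],
                                  mats[2], biases[2]))
    return ModelParams(blocks=blocks, specs=tuple(specs))


def block_forward(feats: np.ndarray, params: BlockParams) -> np.ndarray:
    """Dose shift(s) of one block for feature vector(s); |shift| < 0.3."""
    feats = np.asarray(feats)
    single = feats.ndim == 1
    X = feats[None, :] if single else feats
    if X.shape[1] != params.W1.shape[0]:
        raise ValidationError(
            f"feature length {X.shape[1]} != W1 rows {params.W1.shape[0]}")
    h1 = lrelu(X @ params.W1 + params.b1)
    h2 = lrelu(h1 @ params.W2 + params.b2)
    z = h2 @ params.W3 + params.b3
    shift = scaled_softsign(z[:, 0])
    return shift[0] if single else shift


# ---------------------------------------------------------------------------
# Slice-level forward / backward (the unit of batched training)
# ---------------------------------------------------------------------------

def forward_slice(struct_blocks: np.ndarray, d0_slice: np.ndarray,
                  priorities: PriorityVector, blocks: Sequence[BlockParams],
                  specs=DEFAULT_SPECS, dtype=np.float64, keep_cache: bool = False):
    """Run all residual blocks over every voxel of one slice.

    Returns the final dose slice and (optionally) the cache used by
    :func:`backward_slice`: the shared feature matrix (structure columns are
    constant across blocks) plus per-block dose columns and activations.
    """
    d = d0_slice.astype(dtype)
    shape = d.shape
    cache = []
    X = slice_feature_matrix(struct_blocks, d, priorities, specs=specs,
                             dtype=dtype)
    dose_cols = [dose_column_slice(si, specs) for si in range(len(specs))]
    for bi, bp in enumerate(blocks):
        if bi > 0:
            update_dose_columns(X, d, specs=specs, dtype=dtype)
        h1 = lrelu(X @ bp.W1 + bp.b1)
        h2 = lrelu(h1 @ bp.W2 + bp.b2)
        z = (h2 @ bp.W3 + bp.b3)[:, 0]
        d = d + scaled_softsign(z).reshape(shape)
        if keep_cache:
            cache.append(([X[:, c].copy() for c in dose_cols], h1, h2, z))
    return d, (X, cache)


def backward_slice(g_final: np.ndarray, fwd_cache, blocks: Sequence[BlockParams],
                   grads: list[np.ndarray], specs=DEFAULT_SPECS) -> np.ndarray:
    """Reverse pass of :func:`forward_slice` for one slice.

    ``g_final`` is dL/d(final dose slice); parameter gradients are
    accumulated into ``grads`` (same layout as ``ModelParams.arrays()``).
    Returns dL/d(initial dose slice), which training does not use but the
    gradient tests do.
    """
    X, cache = fwd_cache
    shape = g_final.shape
    dose_cols = [dose_column_slice(si, specs) for si in range(len(specs))]
    g = g_final.astype(X.dtype)
    for b in range(len(blocks) - 1, -1, -1):
        bp = blocks[b]
        block_dose_cols, h1, h2, z = cache[b]
        for c, vals in zip(dose_cols, block_dose_cols):
            X[:, c] = vals
        gb = grads[6 * b:6 * b + 6]
        dz = g.ravel() * _softsign_grad(z)
        gb[5] += dz.sum()                     # b3
        gb[4][:, 0] += h2.T @ dz              # W3
        dh2 = np.outer(dz, bp.W3[:, 0])
        dpre2 = dh2 * _lrelu_grad_from_output(h2)
        gb[3] += dpre2.sum(axis=0)            # b2
        gb[2] += h1.T @ dpre2                 # W2
        dh1 = dpre2 @ bp.W2.T
        dpre1 = dh1 * _lrelu_grad_from_output(h1)
        gb[1] += dpre1.sum(axis=0)            # b1
        gb[0] += X.T @ dpre1                  # W1
        dX = dpre1 @ bp.W1.T
        # route dose-channel gradients back through gather (+ smoothing)
        for si, spec in enumerate(specs):
            dP = dX[:, dose_column_slice(si, specs)]
            g_sl = scatter_patch_matrix(dP.astype(np.float64), shape, spec)
            if spec.smoothing_kernel > 1:
                g_sl = smooth2d(g_sl, spec.smoothing_kernel, transpose=True)
            g = g + g_sl.astype(g.dtype)
    return g


# ---------------------------------------------------------------------------
# Whole-plan prediction
# ---------------------------------------------------------------------------

def model_forward(plan: PlanRecord, model: ModelParams, clip: bool = True,
                  dtype=np.float64) -> VoxelGrid:
    """Predict the dose map of one plan: initialization + six residual updates.

    The returned grid is clipped to [0, 1.5] of prescription for reporting
    (training operates on the unclipped values).
    """
    if model.init_params is None:
        raise ValidationError("model has no fitted initialization parameters")
    dmaps = compute_distance_maps(plan.structures)
    d0 = init_dose(dmaps, model.init_params)
    out = np.empty_like(d0.values)
    for s in range(d0.n_slices):
        sb = structure_feature_blocks(plan.structures, s, specs=model.specs,
                                      dtype=dtype)
        d_final, _ = forward_slice(sb, d0.values[s], plan.priorities,
                                   model.blocks, specs=model.specs, dtype=dtype)
        out[s] = d_final
    if clip:
        np.clip(out, 0.0, 1.5, out=out)
    return d0.copy_with(out)


# ---------------------------------------------------------------------------
# Checkpoint I/O
# ---------------------------------------------------------------------------

def save_model(path, model: ModelParams) -> None:
    """Store a model checkpoint (npz: weights + shape/feature metadata)."""
    meta = {
        "feature_version": model.feature_version,
        "n_blocks": model.n_blocks,
        "specs": [(s.rate, s.smoothing_kernel, s.patch_side) for s in model.specs],
        "init_params": None if model.init_params is None else
                       list(model.init_params.as_array()),
    }
    payload = {"meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    for i, blk in enumerate(model.blocks):
        for name, arr in zip(("W1", "b1", "W2", "b2", "W3", "b3"), blk.arrays()):
            payload[f"block{i}_{name}"] = arr
    np.savez(path, **payload)


def load_model(path) -> ModelParams:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        blocks = []
        for i in range(meta["n_blocks"]):
            blocks.append(BlockParams(*[
                data[f"block{i}_{name}"] for name in ("W1", "b1", "W2", "b2", "W3", "b3")
            ]))
    init = None if meta["init_params"] is None else \
        InitParams.from_array(meta["init_params"])
    specs = tuple(AtrousSpec(rate=r, smoothing_kernel=k, patch_side=p)
                  for r, k, p in meta["specs"])
    return ModelParams(blocks=blocks, init_params=init, specs=specs,
                       feature_version=meta["feature_version"])
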
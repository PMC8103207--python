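"""Masked-RMSE loss, diagonal batch sampling, Adam training, and the two
cross-validation protocols.

The training loss is the RMSE between predicted and reference dose maps,
restricted to voxels inside the body contour on slices containing at least
one critical structure (PTV, bladder or rectum). Gradients are estimated on
batches of whole slices sampled "diagonally": the batch slots cycle through
the patients in a seeded order while each slot's slice index advances one
slice per iteration from a staggered starting depth, so concurrent batch
slices sit at different levels within different patients and each batch
approximates the cohort-wide loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dose_init import FitOptions, InitParams, compute_distance_maps, init_dose, \
    fit_init_params
from .errors import ValidationError
from .features import DEFAULT_SPECS, structure_feature_blocks
from .grids import PlanRecord, VoxelGrid, group_by_patient
from .network import ModelParams, backward_slice, forward_slice, \
    init_model_glorot, model_forward
from .optim import AdamState


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults follow the model's protocol)."""

    iterations: int = 2000
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    #: slices per batch; None -> median slice count of the cohort
    batch_slices: Optional[int] = None
    seed: int = 0
    dtype: str = "float32"
    widths: tuple[int, ...] = (100, 100)
    n_blocks: int = 6
    specs: tuple = DEFAULT_SPECS
    fit_opts: FitOptions = field(default_factory=FitOptions)

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise ValidationError("iterations must be >= 0")
        if self.learning_rate <= 0:
            raise ValidationError("learning rate must be > 0")


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def loss_mask(plan: PlanRecord) -> VoxelGrid:
    """Voxels inside the body on slices containing >= 1 critical structure."""
    body = plan.structures.bool_mask("body")
    struct_any = (plan.structures.bool_mask("ptv")
                  | plan.structures.bool_mask("bladder")
                  | plan.structures.bool_mask("rectum"))
    keep_slice = struct_any.any(axis=(1, 2))
    mask = body & keep_slice[:, None, None]
    return plan.structures.grid.copy_with(mask.astype(np.float64))


def masked_rmse(pred: VoxelGrid, ref: VoxelGrid, mask: VoxelGrid) -> float:
    """100 * sqrt(mean over masked voxels of (pred - ref)^2)."""
    if pred.shape != ref.shape or pred.shape != mask.shape:
        raise ValidationError("masked_rmse: shapes do not match")
    m = mask.values.astype(bool)
    if not m.any():
        raise ValidationError("masked_rmse: empty mask")
    diff = pred.values[m] - ref.values[m]
    return 100.0 * float(np.sqrt(np.mean(diff ** 2)))


# ---------------------------------------------------------------------------
# Diagonal batch sampling
# ---------------------------------------------------------------------------

def diagonal_batches(cohort: Sequence[PlanRecord], cfg: TrainConfig,
                     iteration: int) -> list[tuple[PlanRecord, int]]:
    """The (plan, slice) pairs of one batch; deterministic in (seed, iteration).

    Batch slot ``j`` visits patient ``perm[(j + iteration * B) mod P]`` and
    contributes slice ``(floor(j * S / B) + iteration) mod S``, so slots sit
    at staggered depths and each patient's slices are swept cyclically. The
    plan of a multi-plan patient rotates with ``(iteration + j) mod n_plans``.
    """
    if not cohort:
        raise ValidationError("empty cohort")
    by_patient = group_by_patient(list(cohort))
    pids = list(by_patient)
    n_pat = len(pids)
    slice_counts = [by_patient[p][0].structures.grid.n_slices for p in pids]
    batch = cfg.batch_slices or int(np.median(slice_counts))
    if batch > sum(slice_counts):
        raise ValidationError("batch_slices exceeds the total slice count")
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n_pat)
    out = []
    for j in range(batch):
        pi = perm[(j + iteration * batch) % n_pat]
        plans = by_patient[pids[pi]]
        n_slices = slice_counts[pi]
        offset = (j * n_slices) // batch
        s = (offset + iteration) % n_slices
        plan = plans[(iteration + j) % len(plans)]
        out.append((plan, s))
    return out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class _CohortCache:
    """Per-patient distance maps / init doses and per-slice structure blocks."""

    def __init__(self, cohort, init_params: InitParams, cfg: TrainConfig):
        self.cfg = cfg
        self.dtype = np.dtype(cfg.dtype)
        self.init_params = init_params
        self._d0: dict[int, np.ndarray] = {}
        self._mask: dict[int, np.ndarray] = {}
        self._blocks: dict[tuple[int, int], np.ndarray] = {}
        self._plans = cohort

    def d0(self, plan: PlanRecord) -> np.ndarray:
        key = id(plan.structures)
        if key not in self._d0:
            dmaps = compute_distance_maps(plan.structures)
            self._d0[key] = init_dose(dmaps, self.init_params).values
        return self._d0[key]

    def mask(self, plan: PlanRecord) -> np.ndarray:
        key = id(plan.structures)
        if key not in self._mask:
            self._mask[key] = loss_mask(plan).values.astype(bool)
        return self._mask[key]

    def struct_blocks(self, plan: PlanRecord, s: int) -> np.ndarray:
        key = (id(plan.structures), s)
        if key not in self._blocks:
            self._blocks[key] = structure_feature_blocks(
                plan.structures, s, specs=self.cfg.specs, dtype=self.dtype)
        return self._blocks[key]


def train(cohort: Sequence[PlanRecord], cfg: TrainConfig,
          init_params: InitParams) -> tuple[ModelParams, list[float]]:
    """Train the residual network with Adam on diagonal slice batches.

    ``init_params`` must have been fitted beforehand (the initialization is
    trained before the network). Returns the trained model and the batch-RMSE
    trace (% of prescription, one entry per iteration; NaN if a batch hit no
    masked voxel).
    """
    for plan in cohort:
        if plan.reference_dose is None:
            raise ValidationError(f"plan {plan.plan_id!r} has no reference dose")
    dtype = np.dtype(cfg.dtype)
    model = init_model_glorot(cfg.seed, widths=cfg.widths, n_blocks=cfg.n_blocks,
                              specs=cfg.specs)
    model.blocks = [b.astype(dtype) for b in model.blocks]
    model.init_params = init_params
    if cfg.iterations == 0:
        return model, []
    cache = _CohortCache(cohort, init_params, cfg)
    params = model.arrays()
    adam = AdamState(params, learning_rate=cfg.learning_rate, beta1=cfg.beta1,
                     beta2=cfg.beta2, eps=cfg.eps)
    trace: list[float] = []
    for it in range(cfg.iterations):
        batch = diagonal_batches(cohort, cfg, it)
        stored = []
        total_sq, total_n = 0.0, 0
        for plan, s in batch:
            msl = cache.mask(plan)[s]
            if not msl.any():
                continue
            sb = cache.struct_blocks(plan, s)
            d_final, fwd_cache = forward_slice(
                sb, cache.d0(plan)[s], plan.priorities, model.blocks,
                specs=cfg.specs, dtype=dtype, keep_cache=True)
            err = (d_final - plan.reference_dose.values[s].astype(dtype)) * msl
            total_sq += float(np.sum(err.astype(np.float64) ** 2))
            total_n += int(msl.sum())
            stored.append((err, fwd_cache))
        if total_n == 0:
            trace.append(float("nan"))
            continue
        rmse = np.sqrt(total_sq / total_n)
        trace.append(100.0 * rmse)
        grads = [np.zeros_like(p) for p in params]
        scale = 1.0 / (total_n * max(rmse, 1e-12))
        for err, fwd_cache in stored:
            backward_slice((err * scale).astype(dtype), fwd_cache, model.blocks,
                           grads, specs=cfg.specs)
        adam.step(grads)
    return model, trace


def evaluate_rmse(plans: Sequence[PlanRecord], model: ModelParams) -> list[float]:
    """Masked dose-map RMSE (% of prescription) of each plan's prediction."""
    out = []
    for plan in plans:
        pred = model_forward(plan, model, clip=False)
        out.append(masked_rmse(pred, plan.reference_dose, loss_mask(plan)))
    return out


def init_only_rmse(plans: Sequence[PlanRecord], init_params: InitParams) -> list[float]:
    """Masked RMSE of the bare initialization (no network) per plan."""
    out = []
    dmaps_cache: dict[int, VoxelGrid] = {}
    for plan in plans:
        key = id(plan.structures)
        if key not in dmaps_cache:
            dmaps_cache[key] = init_dose(compute_distance_maps(plan.structures),
                                         init_params)
        out.append(masked_rmse(dmaps_cache[key], plan.reference_dose,
                               loss_mask(plan)))
    return out


# ---------------------------------------------------------------------------
# Cross-validation protocols
# ---------------------------------------------------------------------------

@dataclass
class CvReport:
    """Per-fold and aggregate train/test masked-RMSE statistics."""

    rows: list[dict]
    scheme: str

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def aggregate(self) -> dict:
        df = self.to_dataframe()
        out = {"scheme": self.scheme, "n_validations": len(df)}
        for col in ("train_rmse", "test_rmse"):
            vals = df[col].astype(float)
            out[f"{col}_mean"] = float(vals.mean())
            out[f"{col}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        return out

    def test_counts(self) -> dict[str, int]:
        """How many times each patient appeared in a test set."""
        counts: dict[str, int] = {}
        for row in self.rows:
            for pid in row["test_patients"].split(";"):
                counts[pid] = counts.get(pid, 0) + 1
        return counts


def _fit_and_score(train_plans, test_plans, cfg: TrainConfig) -> tuple[float, float]:
    params, _ = fit_init_params(train_plans, opts=cfg.fit_opts)
    model, _ = train(train_plans, cfg, params)
    tr = float(np.mean(evaluate_rmse(train_plans, model)))
    te = float(np.mean(evaluate_rmse(test_plans, model)))
    return tr, te


def crossval_repeated_kfold(cohort: Sequence[PlanRecord], k: int = 10,
                            repetitions: int = 1,
                            cfg: TrainConfig | None = None) -> CvReport:
    """k-fold cross-validation over patients, repeated with fresh shuffles.

    Every patient lands in a test fold exactly once per repetition and in
    training exactly k-1 times.
    """
    cfg = cfg or TrainConfig()
    by_patient = group_by_patient(list(cohort))
    pids = list(by_patient)
    if k < 2 or k > len(pids):
        raise ValidationError(f"k={k} invalid for {len(pids)} patients")
    rows = []
    for rep in range(repetitions):
        rng = np.random.default_rng([cfg.seed, rep])
        order = [pids[i] for i in rng.permutation(len(pids))]
        folds = [list(f) for f in np.array_split(order, k)]
        for fi, fold in enumerate(folds):
            test_p = set(fold)
            train_plans = [p for pid in pids if pid not in test_p
                           for p in by_patient[pid]]
            test_plans = [p for pid in fold for p in by_patient[pid]]
            tr, te = _fit_and_score(train_plans, test_plans, cfg)
            rows.append({"repetition": rep, "fold": fi, "train_rmse": tr,
                         "test_rmse": te,
                         "train_patients": ";".join(pid for pid in pids
                                                    if pid not in test_p),
                         "test_patients": ";".join(fold)})
    return CvReport(rows=rows, scheme=f"repeated-{k}fold-x{repetitions}")


def rotation_fold_indices(train_subsets: int, n_subsets: int = 10
                          ) -> list[tuple[list[int], list[int]]]:
    """Cyclic train/test subset indices of the rotating-ratio scheme.

    Validation ``j`` trains on subsets ``j .. j+train_subsets-1`` (cyclic) and
    tests on the remainder; e.g. with 8 training subsets validation 0 trains
    on subsets 0-7 and tests on 8 and 9, validation 1 trains on 1-8 and tests
    on 9 and 0, and so on.
    """
    if not 1 <= train_subsets <= n_subsets - 1:
        raise ValidationError("train_subsets must be in 1..n_subsets-1")
    out = []
    for j in range(n_subsets):
        tr = [(j + i) % n_subsets for i in range(train_subsets)]
        te = [i for i in ((j + train_subsets + m) % n_subsets
                          for m in range(n_subsets - train_subsets))]
        out.append((tr, te))
    return out


def crossval_ratio_rotation(cohort: Sequence[PlanRecord], train_subsets: int,
                            cfg: TrainConfig | None = None,
                            n_subsets: int = 10) -> CvReport:
    """Rotating-subset cross-validation at a chosen train:test ratio.

    Patients are grouped (seeded shuffle) into ``n_subsets`` nearly equal
    subsets; each of the ``n_subsets`` validations trains on a cyclic window
    of ``train_subsets`` subsets and tests on the rest, so every subset
    appears in exactly ``train_subsets`` training sets and
    ``n_subsets - train_subsets`` test sets.
    """
    cfg = cfg or TrainConfig()
    by_patient = group_by_patient(list(cohort))
    pids = list(by_patient)
    if len(pids) < n_subsets:
        raise ValidationError(f"need >= {n_subsets} patients, got {len(pids)}")
    rng = np.random.default_rng(cfg.seed)
    order = [pids[i] for i in rng.permutation(len(pids))]
    subsets = [list(s) for s in np.array_split(order, n_subsets)]
    rows = []
    for j, (tr_idx, te_idx) in enumerate(rotation_fold_indices(train_subsets,
                                                               n_subsets)):
        train_pids = [pid for i in tr_idx for pid in subsets[i]]
        test_pids = [pid for i in te_idx for pid in subsets[i]]
        train_plans = [p for pid in train_pids for p in by_patient[pid]]
        test_plans = [p for pid in test_pids for p in by_patient[pid]]
        tr, te = _fit_and_score(train_plans, test_plans, cfg)
        rows.append({"repetition": 0, "fold": j, "train_rmse": tr,
                     "test_rmse": te,
                     "train_subsets": ";".join(map(str, tr_idx)),
                     "test_subsets": ";".join(map(str, te_idx)),
                     "train_patients": ";".join(train_pids),
                     "test_patients": ";".join(test_pids)})
    return CvReport(rows=rows, scheme=f"rotation-{train_subsets}of{n_subsets}")
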
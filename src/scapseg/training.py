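"""Loss, metrics, cross-validation splitting, the training loop, and
DSC-gated ensembling.

Training minimizes the negative logarithmic dice loss

    F = -log10( 2|p.y| / (|p| + |y|) )

between the predicted probability map ``p`` and the binary ground truth
``y`` with an Adam optimizer (beta1 0.9, beta2 0.999, eps 1e-8), batch
size 1.  A validation epoch (mean validation DSC on predictions binarized
at 0.5) runs every ``validate_every`` training steps (default 90); the
best-DSC weights are checkpointed and training stops early after
``patience`` (default 30) validation epochs without an improvement of more
than 1e-4, or at ``max_iterations`` (default 100,000).

Subjects are split into k consecutive folds without shuffling; each fold
serves once as the validation set.  After training, all model records with
validation DSC strictly above 0.70 are combined into an ensemble whose
prediction is the unweighted voxel-wise mean of the member probability
maps (each member reconstructed to the full-resolution grid first: 2D
members by slice-wise stacking on their own view axis, 3D members by
predicting the two interleaved halves and re-interleaving).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .imaging import GridMismatchError, Mask, ProbMap, Volume, binarize
from .preprocessing import (NormalizationSpec, interleave_merge,
                            interleave_split, normalize)
from .vnet import VNet, VIEW_AXES, predict, predict_slices

__all__ = [
    "dice_coefficient",
    "neg_log_dice_loss",
    "FoldSplit",
    "kfold_split",
    "TrainConfig",
    "TrainedModelRecord",
    "train",
    "TrainingError",
    "EnsembleSpec",
    "EmptyEnsembleError",
    "build_ensemble",
    "full_volume_predict",
    "ensemble_predict",
]

_LN10 = math.log(10.0)


class TrainingError(RuntimeError):
    """Raised when optimization diverges (non-finite loss)."""


class EmptyEnsembleError(ValueError):
    """Raised when no trained model passes the ensembling DSC gate."""


def _as_array(x) -> np.ndarray:
    if isinstance(x, (Volume, Mask, ProbMap)):
        return x.data
    return np.asarray(x)


def dice_coefficient(p, y) -> float:
    """Dice similarity 2|p.y| / (|p| + |y|); both-empty returns 1.0.

    ``p`` may be a binary mask or a soft probability map; ``y`` is the
    reference mask.  Accepts grid objects or bare arrays of equal shape.
    """
    pa, ya = _as_array(p).astype(np.float64), _as_array(y).astype(np.float64)
    if pa.shape != ya.shape:
        raise GridMismatchError(f"shape mismatch: {pa.shape} vs {ya.shape}")
    denom = pa.sum() + ya.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (pa * ya).sum() / denom)


def neg_log_dice_loss(p, y, smooth: float = 1e-5) -> float:
    """F = -log10 of the (smoothed) dice; >= 0, and 0 iff dice = 1.

    ``smooth`` is added to numerator and denominator so the logarithm stays
    finite when prediction and reference barely overlap.
    """
    if smooth < 0:
        raise ValueError("smooth must be >= 0")
    pa, ya = _as_array(p).astype(np.float64), _as_array(y).astype(np.float64)
    if pa.shape != ya.shape:
        raise GridMismatchError(f"shape mismatch: {pa.shape} vs {ya.shape}")
    num = 2.0 * (pa * ya).sum() + smooth
    den = pa.sum() + ya.sum() + smooth
    if den == 0 or num <= 0:
        raise ValueError(
            "dice undefined: empty prediction and reference with smooth = 0"
        )
    return float(-math.log10(num / den))


def _loss_and_grad(p: np.ndarray, y: np.ndarray, smooth: float):
    """Loss value and its gradient w.r.t. the probability map."""
    y = y.astype(p.dtype)
    num = 2.0 * float((p * y).sum()) + smooth
    den = float(p.sum() + y.sum()) + smooth
    loss = -math.log10(num / den)
    grad = -(2.0 * y * den - num) / (num * den * _LN10)
    return loss, grad.astype(p.dtype)


# ---------------------------------------------------------------------------
# cross-validation


@dataclass(frozen=True)
class FoldSplit:
    """Consecutive, non-overlapping folds covering all subjects in order."""

    k: int
    subject_ids: tuple
    boundaries: tuple  # k+1 cut points into subject_ids

    @property
    def folds(self) -> list[tuple[list, list]]:
        """Per fold, the (train_ids, val_ids) pair."""
        out = []
        for i in range(self.k):
            lo, hi = self.boundaries[i], self.boundaries[i + 1]
            val = list(self.subject_ids[lo:hi])
            train = list(self.subject_ids[:lo]) + list(self.subject_ids[hi:])
            out.append((train, val))
        return out

    @property
    def assignments(self) -> dict:
        """Map subject id -> validation fold index."""
        out = {}
        for i in range(self.k):
            lo, hi = self.boundaries[i], self.boundaries[i + 1]
            for sid in self.subject_ids[lo:hi]:
                out[sid] = i
        return out

    def val_ids(self, fold: int) -> list:
        return self.folds[fold][1]

    def train_ids(self, fold: int) -> list:
        return self.folds[fold][0]


def kfold_split(subject_ids: Sequence, k: int) -> FoldSplit:
    """Split subjects into k consecutive folds without shuffling.

    Fold sizes are ``n // k`` or ``n // k + 1`` with the larger folds
    first, so sizes differ by at most one.
    """
    ids = tuple(subject_ids)
    n = len(ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"cannot split {n} subjects into {k} folds")
    base, extra = divmod(n, k)
    boundaries = [0]
    for i in range(k):
        boundaries.append(boundaries[-1] + base + (1 if i < extra else 0))
    return FoldSplit(k=k, subject_ids=ids, boundaries=tuple(boundaries))


# ---------------------------------------------------------------------------
# the training loop


@dataclass
class TrainConfig:
    """Training-loop parameters (defaults follow the reference protocol)."""

    max_iterations: int = 100_000
    validate_every: int = 90
    patience: int = 30
    min_improvement: float = 1e-4
    learning_rate: float | None = None  # None: use the model's configured rate
    smooth: float = 1e-5
    binarize_threshold: float = 0.5
    stop_dsc: float | None = None
    seed: int = 0
    train_norm: NormalizationSpec | None = None

    def __post_init__(self):
        if min(self.max_iterations, self.validate_every, self.patience) < 1:
            raise ValueError("all loop counts must be positive")


@dataclass
class TrainedModelRecord:
    """A trained model with its best validation DSC."""

    model_id: str
    model: VNet
    val_dsc: float
    dims: int = 3
    view: str | None = None
    n_iterations: int = 0
    history: list = field(default_factory=list)


class Adam:
    """Adam with the standard internal parameters (0.9, 0.999, 1e-8)."""

    def __init__(self, beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params, lr: float):
        """Update each (name, weight, grad) triple in place."""
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for name, w, g in params:
            m = self.m.setdefault(name, np.zeros_like(w, dtype=np.float64))
            v = self.v.setdefault(name, np.zeros_like(w, dtype=np.float64))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g.astype(np.float64) ** 2
            w -= (lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)).astype(
                w.dtype
            )


def _validation_dsc(model: VNet, val_pairs, view, threshold) -> float:
    scores = []
    for v, m in val_pairs:
        if model.config.dims == 3:
            pm = predict(model, v)
        else:
            pm = predict_slices(model, v, view=view)
        scores.append(dice_coefficient(binarize(pm, threshold), m))
    return float(np.mean(scores))


def train(
    model: VNet,
    train_pairs: Sequence[tuple[Volume, Mask]],
    val_pairs: Sequence[tuple[Volume, Mask]],
    cfg: TrainConfig,
    model_id: str = "model",
    view: str = "axial",
    val_metric: Callable[[VNet], float] | None = None,
) -> TrainedModelRecord:
    """Train one model with Adam on the negative-log-dice loss.

    ``train_pairs``/``val_pairs`` hold raw (Volume, Mask) pairs; training
    inputs are re-normalized with the training scheme (fresh random divisor)
    at every iteration, validation inputs once with the validation scheme.
    For a 2D model the volumes are decomposed into slices along the view
    axis and iterated slice by slice; validation is still volume-level
    (slice-wise prediction stacked back).

    ``val_metric`` optionally replaces the validation-DSC computation (used
    to exercise the early-stopping rule in isolation).
    """
    if not train_pairs or not val_pairs:
        raise ValueError("train and validation sets must be non-empty")
    dims = model.config.dims
    rng = np.random.default_rng(cfg.seed)
    lr = cfg.learning_rate or model.config.learning_rate
    norm = cfg.train_norm or NormalizationSpec(
        mode="train3d" if dims == 3 else "train2d"
    )
    val_norm = NormalizationSpec(mode="validation")
    val_ready = [(normalize(v, val_norm), m) for v, m in val_pairs]

    # enumerate training examples: whole volumes (3D) or slices (2D)
    if dims == 3:
        examples = [(i, None) for i in range(len(train_pairs))]
    else:
        axis = VIEW_AXES[view]
        examples = [
            (i, k)
            for i, (v, _) in enumerate(train_pairs)
            for k in range(v.shape[axis])
        ]

    optimizer = Adam()
    best_dsc = -np.inf
    best_state = model.state_dict()
    epochs_since_improvement = 0
    history = []
    it = 0
    mult = 2 ** model.config.n_levels

    def _example(idx):
        i, k = examples[idx]
        v, m = train_pairs[i]
        x = normalize(v, norm, rng).data
        y = m.data
        if k is not None:
            axis = VIEW_AXES[view]
            x = np.take(x, k, axis=axis)
            y = np.take(y, k, axis=axis)
        pads = [(0, (-n) % mult) for n in x.shape]
        if any(p[1] for p in pads):
            x = np.pad(x, pads, mode="reflect")
            y = np.pad(y, pads, mode="reflect")
        return x, y

    stop = False
    while it < cfg.max_iterations and not stop:
        x, y = _example(it % len(examples))
        p = model.forward(x, train=True, rng=rng)
        loss, grad = _loss_and_grad(p, y, cfg.smooth)
        if not math.isfinite(loss):
            raise TrainingError(f"non-finite loss at iteration {it}")
        model.zero_grad()
        model.backward(grad)
        optimizer.step(model.parameters(), lr)
        it += 1
        if it % cfg.validate_every == 0:
            if val_metric is not None:
                dsc = float(val_metric(model))
            else:
                dsc = _validation_dsc(
                    model, val_ready, view, cfg.binarize_threshold
                )
            history.append({"iteration": it, "loss": loss, "val_dsc": dsc})
            if dsc > best_dsc + cfg.min_improvement:
                best_dsc = dsc
                best_state = model.state_dict()
                epochs_since_improvement = 0
            else:
                epochs_since_improvement += 1
            if epochs_since_improvement >= cfg.patience:
                stop = True
            if cfg.stop_dsc is not None and best_dsc >= cfg.stop_dsc:
                stop = True
    model.load_state_dict(best_state)
    return TrainedModelRecord(
        model_id=model_id,
        model=model,
        val_dsc=float(best_dsc),
        dims=dims,
        view=None if dims == 3 else view,
        n_iterations=it,
        history=history,
    )


# ---------------------------------------------------------------------------
# ensembling


@dataclass(frozen=True)
class EnsembleSpec:
    """Models admitted by the DSC gate plus the fusion rule."""

    members: tuple
    dsc_threshold: float = 0.70
    fusion: str = "mean"  # or "vote"
    excluded: tuple = ()

    def __post_init__(self):
        if self.fusion not in ("mean", "vote"):
            raise ValueError("fusion must be 'mean' or 'vote'")


def build_ensemble(
    records: Sequence[TrainedModelRecord],
    threshold: float = 0.70,
    fusion: str = "mean",
) -> EnsembleSpec:
    """Admit every record with validation DSC strictly above ``threshold``.

    Excluded model ids are kept on the spec for reporting.  Raises
    :class:`EmptyEnsembleError` if nothing passes the gate.
    """
    if not records:
        raise ValueError("no trained model records supplied")
    members = tuple(r for r in records if r.val_dsc > threshold)
    excluded = tuple(r.model_id for r in records if r.val_dsc <= threshold)
    if not members:
        raise EmptyEnsembleError(
            f"no model exceeded the DSC threshold {threshold}"
        )
    return EnsembleSpec(members=members, dsc_threshold=threshold,
                        fusion=fusion, excluded=excluded)


def full_volume_predict(record: TrainedModelRecord, v: Volume) -> ProbMap:
    """Reconstruct one member's full-resolution probability map.

    3D members predict the two interleaved slice halves and the results are
    re-interleaved; 2D members predict slice-wise along their own view axis
    and the maps are stacked.  ``v`` must already carry validation-scheme
    normalization.
    """
    if record.dims == 3:
        a, b = interleave_split(v)
        return interleave_merge(predict(record.model, a),
                                predict(record.model, b))
    return predict_slices(record.model, v, view=record.view or "axial")


def ensemble_predict(e: EnsembleSpec, v: Volume) -> ProbMap:
    """Voxel-wise mean (or majority vote) of the member probability maps."""
    maps = [full_volume_predict(r, v) for r in e.members]
    shapes = {m.shape for m in maps}
    if len(shapes) != 1:
        raise GridMismatchError(
            f"member outputs disagree in shape after reconstruction: {shapes}"
        )
    stack = np.stack([m.data for m in maps])
    if e.fusion == "vote":
        votes = (stack >= 0.5).mean(axis=0)
        return ProbMap(votes.astype(np.float32), v.spacing)
    return ProbMap(stack.mean(axis=0), v.spacing)
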
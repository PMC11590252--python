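"""The five training objectives: CE, FL, DL, CE_DL and FL_DL.

All losses operate on a per-voxel probability volume ``p`` (K = 3
channels: helix, sheet, background — background deliberately *last*)
and a matching one-hot label volume ``y``, and are **sums** over voxels,

    CE(y, p)  = - Σ_j Σ_k  y_jk log p_jk
    FL(y, p)  = - Σ_j (1 - p_t,j)^γ log p_t,j          (p_t = prob of true class)
    D(y, p)   = 2 Σ_{k ∈ {helix, sheet}}  (Σ_j y_jk p_jk) / (Σ_j y_jk + Σ_j p_jk)
    DL(y, p)  = 2 - D(y, p)
    CE_DL     = CE + DL
    FL_DL     = FL + DL

With γ = 0, FL reduces exactly to CE.  The Dice coefficient sums the
per-class overlap ratio over the two foreground classes only, so D ∈
[0, 2] and DL ∈ [0, 2] for a single map; losses are therefore computed
per map and averaged over a batch (batch size is 1 in practice because
input volumes vary in size).

An optional boolean ``region`` mask restricts every sum to the center
box, mirroring training where the loss ignores the spatial padding.
Probabilities are clamped at ``epsilon`` inside logarithms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .volumes import LabelMap

#: channel layout: foreground classes first, background last
CH_HELIX, CH_SHEET, CH_BACKGROUND = 0, 1, 2
FOREGROUND_CHANNELS = (CH_HELIX, CH_SHEET)
N_CLASSES = 3

#: LabelMap class id -> channel index
_CLASS_TO_CHANNEL = {0: CH_BACKGROUND, 1: CH_HELIX, 2: CH_SHEET}
#: channel index -> LabelMap class id
CHANNEL_TO_CLASS = {CH_HELIX: 1, CH_SHEET: 2, CH_BACKGROUND: 0}

LOSS_NAMES = ("CE", "FL", "DL", "CE_DL", "FL_DL")


@dataclass
class ProbabilityMap:
    """Per-voxel class probabilities, channels-first ``(3, nx, ny, nz)``."""

    probs: np.ndarray
    spacing: float = 1.0
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=np.float64)
        if p.ndim != 4 or p.shape[0] != N_CLASSES:
            raise ValueError("probability volume must have shape (3, nx, ny, nz)")
        if p.min() < -1e-6 or np.abs(p.sum(axis=0) - 1.0).max() > 1e-5:
            raise ValueError("channel vectors must be non-negative and sum to 1")
        self.probs = p


@dataclass
class OneHotLabels:
    """One-hot label volume matching :class:`ProbabilityMap` layout."""

    onehot: np.ndarray

    def __post_init__(self):
        y = np.asarray(self.onehot, dtype=np.float64)
        if y.ndim != 4 or y.shape[0] != N_CLASSES:
            raise ValueError("one-hot volume must have shape (3, nx, ny, nz)")
        s = y.sum(axis=0)
        if not (np.isin(y, (0.0, 1.0)).all() and np.all(s == 1.0)):
            raise ValueError("exactly one 1 per voxel required")
        self.onehot = y


@dataclass
class LossConfig:
    """Loss selection and numerical settings.

    gamma is only consulted by FL and FL_DL; ``region`` is an optional
    boolean spatial mask (True = voxel participates); ``dice_smooth``
    defaults to 0 so the Dice term stays the exact ratio form (a class
    term with zero denominator contributes 0).
    """

    name: str = "FL_DL"
    gamma: float = 1.0
    epsilon: float = 1e-7
    region: Optional[np.ndarray] = None
    #: "sum" matches the Σ definitions exactly; "mean" divides the CE/FL
    #: term by the voxel count (the Dice term is a bounded ratio and is
    #: never reduced).  Training uses "mean" so that in the combined
    #: losses the Dice term keeps comparable magnitude to CE/FL instead
    #: of being drowned by a sum over ~10^4 voxels.
    reduction: str = "sum"
    dice_smooth: float = 0.0

    def __post_init__(self):
        if self.name not in LOSS_NAMES:
            raise ValueError(f"unknown loss {self.name!r}; expected one of {LOSS_NAMES}")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not (0.0 < self.epsilon < 1e-3):
            raise ValueError("epsilon must be in (0, 1e-3)")
        if self.reduction not in ("sum", "mean"):
            raise ValueError("reduction must be 'sum' or 'mean'")


def onehot_from_labels(labels: LabelMap | np.ndarray) -> OneHotLabels:
    """Convert a class-id label grid to channels-first one-hot."""
    arr = labels.classes if isinstance(labels, LabelMap) else np.asarray(labels)
    y = np.zeros((N_CLASSES,) + arr.shape, dtype=np.float64)
    for cls, ch in _CLASS_TO_CHANNEL.items():
        y[ch][arr == cls] = 1.0
    return OneHotLabels(y)


def _unwrap(y, p) -> Tuple[np.ndarray, np.ndarray]:
    ya = y.onehot if isinstance(y, OneHotLabels) else np.asarray(y, dtype=np.float64)
    pa = p.probs if isinstance(p, ProbabilityMap) else np.asarray(p, dtype=np.float64)
    if ya.shape != pa.shape:
        raise ValueError(f"shape mismatch: labels {ya.shape} vs probabilities {pa.shape}")
    return ya, pa


def _region_mask(config: LossConfig, spatial_shape) -> np.ndarray:
    if config.region is None:
        return np.ones(spatial_shape, dtype=bool)
    mask = np.asarray(config.region, dtype=bool)
    if mask.shape != spatial_shape:
        raise ValueError("region mask shape does not match the volume")
    return mask


def _reduce(total: float, n_voxels: int, config: LossConfig) -> float:
    if config.reduction == "mean" and n_voxels > 0:
        return total / n_voxels
    return total


# ---------------------------------------------------------------------------
# Loss values
# ---------------------------------------------------------------------------

def cross_entropy(y, p, config: LossConfig = LossConfig("CE")) -> float:
    """Multiclass cross-entropy, summed over (masked) voxels."""
    ya, pa = _unwrap(y, p)
    mask = _region_mask(config, ya.shape[1:])
    pt = np.clip((ya * pa).sum(axis=0)[mask], config.epsilon, None)
    return _reduce(float(-np.log(pt).sum()), int(mask.sum()), config)


def focal_loss(y, p, config: LossConfig = LossConfig("FL", gamma=1.0)) -> float:
    """Focal loss: CE with each voxel scaled by ``(1 - p_t)^γ``."""
    if config.gamma < 0:
        raise ValueError("gamma must be >= 0")
    ya, pa = _unwrap(y, p)
    mask = _region_mask(config, ya.shape[1:])
    pt = (ya * pa).sum(axis=0)[mask]
    ptc = np.clip(pt, config.epsilon, None)
    mod = np.power(1.0 - pt, config.gamma) if config.gamma > 0 else 1.0
    return _reduce(float(-(mod * np.log(ptc)).sum()), int(mask.sum()), config)


def dice_coefficient(y, p, config: LossConfig = LossConfig("DL")) -> float:
    """Dice coefficient over the two foreground classes, in [0, 2].

    Each class contributes ``intersection / (truth mass + predicted
    mass)``; a class with zero denominator (no truth and no predicted
    probability mass in the region) contributes 0.
    """
    ya, pa = _unwrap(y, p)
    mask = _region_mask(config, ya.shape[1:])
    total = 0.0
    s = config.dice_smooth
    for ch in FOREGROUND_CHANNELS:
        num = float((ya[ch][mask] * pa[ch][mask]).sum())
        den = float(ya[ch][mask].sum() + pa[ch][mask].sum())
        if den + s > 0:
            total += (num + s) / (den + s)
    return 2.0 * total


def dice_loss(y, p, config: LossConfig = LossConfig("DL")) -> float:
    """``2 - D``; 0 for a perfect foreground prediction, 2 in the worst case."""
    return 2.0 - dice_coefficient(y, p, config)


def combined_loss(y, p, config: LossConfig) -> float:
    """CE_DL = CE + DL or FL_DL = FL + DL, with identical masks and clamps."""
    if config.name == "CE_DL":
        return cross_entropy(y, p, config) + dice_loss(y, p, config)
    if config.name == "FL_DL":
        return focal_loss(y, p, config) + dice_loss(y, p, config)
    raise ValueError(f"combined_loss expects CE_DL or FL_DL, got {config.name!r}")


def loss_value(y, p, config: LossConfig) -> float:
    """Dispatch on ``config.name``."""
    if config.name == "CE":
        return cross_entropy(y, p, config)
    if config.name == "FL":
        return focal_loss(y, p, config)
    if config.name == "DL":
        return dice_loss(y, p, config)
    return combined_loss(y, p, config)


# ---------------------------------------------------------------------------
# Gradients (w.r.t. probabilities and w.r.t. pre-softmax logits)
# ---------------------------------------------------------------------------

def _grad_probs(ya, pa, config: LossConfig) -> np.ndarray:
    """dL/dp, same shape as p, zero outside the region mask."""
    mask = _region_mask(config, ya.shape[1:])
    g = np.zeros_like(pa)
    eps = config.epsilon
    name = config.name

    if name in ("CE", "FL", "CE_DL", "FL_DL"):
        pt = (ya * pa).sum(axis=0)
        ptc = np.clip(pt, eps, None)
        live = pt > eps  # clamped voxels have zero analytic gradient
        if name in ("CE", "CE_DL") or config.gamma == 0:
            dpt = np.where(live, -1.0 / ptc, 0.0)
        else:
            gam = config.gamma
            one_m = np.clip(1.0 - pt, 0.0, None)
            # d/dpt [-(1-pt)^γ log(clip(pt))]; the log term is constant
            # below the clamp but the modulating factor never is
            dpt = gam * np.power(one_m, gam - 1.0, where=one_m > 0,
                                 out=np.zeros_like(one_m)) * np.log(ptc)
            dpt -= np.where(live, np.power(one_m, gam) / ptc, 0.0)
        g_pt = ya * (dpt * mask)[None]
        if config.reduction == "mean":
            n = int(mask.sum())
            if n > 0:
                g_pt = g_pt / n
        g += g_pt

    if name in ("DL", "CE_DL", "FL_DL"):
        s = config.dice_smooth
        for ch in FOREGROUND_CHANNELS:
            num = float((ya[ch] * pa[ch] * mask).sum())
            den = float((ya[ch] * mask).sum() + (pa[ch] * mask).sum())
            if den + s > 0:
                # d(DL)/dp = -d(D)/dp
                dd = 2.0 * (ya[ch] * (den + s) - (num + s)) / (den + s) ** 2
                g[ch] -= dd * mask
    return g


def softmax(logits: np.ndarray, axis: int = 0) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def loss_and_logit_grad(y, logits: np.ndarray, config: LossConfig):
    """Loss value and analytic gradient w.r.t. pre-softmax logits.

    Returns ``(value, dL/dz)`` with ``p = softmax(z)`` along channel 0.
    Used by the training loop; verified against central finite
    differences in the test suite.
    """
    ya, _ = _unwrap(y, np.zeros_like(np.asarray(logits, dtype=np.float64)))
    pa = softmax(np.asarray(logits, dtype=np.float64))
    value = loss_value(ya, pa, config)
    g = _grad_probs(ya, pa, config)
    # softmax Jacobian: dz_k = p_k (g_k - Σ_m g_m p_m)
    dz = pa * (g - (g * pa).sum(axis=0, keepdims=True))
    return value, dz
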
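"""Training loop, hyperparameter grid search and dataset splitting.

Training follows the protocol used for medium-resolution secondary
structure segmenters: batch size 1 (volumes vary in size), the loss
evaluated only on center-box voxels (the spatial padding has no
supervision signal), model selection by the mean of the per-class
validation F1 scores (macro over cases, then over the helix/sheet
pair), and a hyperparameter grid over learning rates
{1e-3, 1e-4, 1e-5} and — for the focal losses — γ ∈ {1, 2, 5, 8}.
The optimizer is Adam with default betas.  Everything is a pure
function of (dataset seed, training seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .evaluation import f1_from_counts, voxel_confusion
from .losses import LossConfig, loss_and_logit_grad, onehot_from_labels
from .model import ModelConfig, UNet3D, build_model, normalize_input, segment
from .structures import HELIX, SHEET
from .volumes import center_box_mask

logger = logging.getLogger(__name__)

DEFAULT_LEARNING_RATES = (1e-3, 1e-4, 1e-5)
DEFAULT_GAMMA_GRID = (1, 2, 5, 8)


@dataclass
class TrainConfig:
    """Hyperparameters of one training run (and the grids around it)."""

    loss: LossConfig = field(default_factory=lambda: LossConfig("FL_DL", gamma=1.0, reduction="mean"))
    learning_rate: float = 1e-3
    epochs: int = 30
    seed: int = 0
    batch_size: int = 1  # variable-size volumes force singleton batches
    learning_rates: Tuple[float, ...] = DEFAULT_LEARNING_RATES
    gamma_grid: Tuple[float, ...] = DEFAULT_GAMMA_GRID

    def __post_init__(self):
        if self.batch_size != 1:
            raise ValueError("batch_size must be 1 (inputs vary in size)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not self.learning_rates or (
            self.loss.name in ("FL", "FL_DL") and not self.gamma_grid
        ):
            raise ValueError("hyperparameter grids must be non-empty")


@dataclass
class TrainRecord:
    """Learning curves and the hyperparameters of one run."""

    loss_name: str
    gamma: Optional[float]
    learning_rate: float
    train_loss: List[float] = field(default_factory=list)
    val_f1_helix: List[float] = field(default_factory=list)
    val_f1_sheet: List[float] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def val_f1_mean(self) -> List[float]:
        return [
            (h + s) / 2.0 for h, s in zip(self.val_f1_helix, self.val_f1_sheet)
        ]

    def best_val_f1(self) -> float:
        means = self.val_f1_mean
        return means[self.best_epoch] if means and self.best_epoch >= 0 else float("nan")

    def curves_tsv(self, path) -> None:
        """Write per-epoch learning curves as a TSV file."""
        lines = ["epoch\ttrain_loss\tval_f1_helix\tval_f1_sheet\tval_f1_mean"]
        means = self.val_f1_mean
        for e, loss in enumerate(self.train_loss):
            lines.append(
                f"{e}\t{loss:.6g}\t{self.val_f1_helix[e]:.6g}"
                f"\t{self.val_f1_sheet[e]:.6g}\t{means[e]:.6g}"
            )
        from pathlib import Path as _P
        _P(path).write_text("\n".join(lines) + "\n")

    def to_dict(self) -> dict:
        return {
            "loss": self.loss_name,
            "gamma": self.gamma,
            "learning_rate": self.learning_rate,
            "train_loss": self.train_loss,
            "val_f1_helix": self.val_f1_helix,
            "val_f1_sheet": self.val_f1_sheet,
            "val_f1_mean": self.val_f1_mean,
            "best_epoch": self.best_epoch,
        }


def _case_f1(model: UNet3D, case) -> Tuple[float, float]:
    """Voxel-level helix/sheet F1 of one case on its center box.

    Undefined scores (class absent from truth and prediction) count as
    1.0 for selection purposes: the model was right about the absence.
    """
    pred = segment(model, case.density, case.box)
    cc = voxel_confusion(case.labels, pred, case.box)
    out = []
    for cls in (HELIX, SHEET):
        f1 = f1_from_counts(cc.for_class(cls))[2]
        out.append(1.0 if np.isnan(f1) else f1)
    return out[0], out[1]


def validation_f1(model: UNet3D, cases: Sequence) -> Tuple[float, float]:
    """Macro (case-averaged) helix and sheet voxel F1."""
    scores = np.array([_case_f1(model, c) for c in cases])
    return float(scores[:, 0].mean()), float(scores[:, 1].mean())


def train(
    train_cases: Sequence,
    val_cases: Sequence,
    config: TrainConfig,
    model_config: Optional[ModelConfig] = None,
) -> Tuple[UNet3D, TrainRecord]:
    """Train a model under one loss/learning-rate setting.

    The loss is evaluated on center-box voxels only; padding voxels
    contribute neither to the loss value nor to any gradient.  The
    returned model carries the parameters of the best validation epoch
    (falling back to the last epoch when there is no validation set).
    """
    if not train_cases:
        raise ValueError("empty training set")
    mc = model_config or ModelConfig()
    mc = replace(mc, seed=config.seed)
    model = build_model(mc)
    opt = nn.Adam(model.layers(), lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]).generate_state(1)[0])

    record = TrainRecord(
        loss_name=config.loss.name,
        gamma=config.loss.gamma if config.loss.name in ("FL", "FL_DL") else None,
        learning_rate=config.learning_rate,
    )
    best_f1 = -np.inf
    best_params = None

    prepared = []
    for case in train_cases:
        prepared.append((
            normalize_input(case.density.values)[None],
            onehot_from_labels(case.labels).onehot,
            center_box_mask(case.box),
        ))

    for epoch in range(config.epochs):
        order = rng.permutation(len(prepared))
        epoch_loss = 0.0
        for idx in order:
            x, y, mask = prepared[idx]
            logits = model.forward(x)
            cfg = replace(config.loss, region=mask)
            value, dz = loss_and_logit_grad(y, logits, cfg)
            model.zero_grads()
            model.backward(dz.astype(np.float32))
            opt.step()
            epoch_loss += value
        record.train_loss.append(epoch_loss / len(prepared))

        if val_cases:
            f1h, f1s = validation_f1(model, val_cases)
        else:
            f1h = f1s = float("nan")
        record.val_f1_helix.append(f1h)
        record.val_f1_sheet.append(f1s)
        mean_f1 = (f1h + f1s) / 2.0
        if not val_cases or np.isnan(mean_f1):
            mean_f1 = float(epoch)  # no validation: keep the last epoch
        if mean_f1 > best_f1:
            best_f1 = mean_f1
            best_params = [
                {k: v.copy() for k, v in layer.params.items()}
                for layer in model.layers()
            ]
            record.best_epoch = epoch

    if best_params is not None:
        for layer, params in zip(model.layers(), best_params):
            layer.params.update(params)
    return model, record


def grid_search(
    train_cases: Sequence,
    val_cases: Sequence,
    base_config: TrainConfig,
    model_config: Optional[ModelConfig] = None,
) -> Tuple[TrainConfig, UNet3D, List[TrainRecord]]:
    """Train every grid cell; select the best mean validation F1.

    For CE/DL/CE_DL the grid is over learning rates only; for FL/FL_DL
    it is the product with the γ grid.  Ties are broken toward the
    lower learning rate, then the lower γ.
    """
    gammas: Sequence[Optional[float]]
    if base_config.loss.name in ("FL", "FL_DL"):
        gammas = list(base_config.gamma_grid)
    else:
        gammas = [None]

    records: List[TrainRecord] = []
    results = []
    for lr in base_config.learning_rates:
        for gamma in gammas:
            loss_cfg = base_config.loss if gamma is None else replace(
                base_config.loss, gamma=float(gamma)
            )
            cfg = replace(base_config, loss=loss_cfg, learning_rate=lr)
            model, rec = train(train_cases, val_cases, cfg, model_config)
            records.append(rec)
            results.append((rec.best_val_f1(), lr, gamma, cfg, model))
            logger.info(
                "grid cell %s lr=%g gamma=%s -> val F1 %.4f",
                base_config.loss.name, lr, gamma, rec.best_val_f1(),
            )

    # argmax with documented tie-break: lower lr, then lower gamma
    def key(item):
        f1, lr, gamma, _, _ = item
        g = gamma if gamma is not None else 0.0
        return (-(f1 if not np.isnan(f1) else -np.inf), lr, g)

    best = sorted(results, key=key)[0]
    return best[3], best[4], records


def split_dataset(
    cases: Sequence,
    fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    stratum_key=None,
):
    """Seeded (train, validation, test) split, optionally stratified.

    ``stratum_key(case)`` groups cases (e.g. by composition band); each
    stratum is split independently so the three sets share its
    distribution.  Strata smaller than 3 trigger a warning and a plain
    non-stratified split.  The result is disjoint and exhaustive.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    cases = list(cases)
    rng = np.random.default_rng(seed)

    groups: Dict[str, List] = {}
    if stratum_key is not None:
        for c in cases:
            groups.setdefault(str(stratum_key(c)), []).append(c)
        if any(len(g) < 3 for g in groups.values()):
            logger.warning("a stratum has fewer than 3 cases; splitting unstratified")
            groups = {"all": cases}
    else:
        groups = {"all": cases}

    splits: Tuple[List, List, List] = ([], [], [])
    for name in sorted(groups):
        group = groups[name]
        order = rng.permutation(len(group))
        n = len(group)
        counts = np.floor(np.asarray(fractions) * n).astype(int)
        frac_part = np.asarray(fractions) * n - counts
        for i in np.argsort(-frac_part):
            if counts.sum() >= n:
                break
            counts[i] += 1
        start = 0
        for part, cnt in zip(splits, counts):
            part.extend(group[i] for i in order[start:start + cnt])
            start += cnt
    return splits
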
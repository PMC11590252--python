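"""Voxel- and residue-level F1 evaluation of segmentations.

Per-class scores are one-vs-rest over the two foreground classes
(helix, sheet) and are always computed on the center box — the region
left after removing the crop padding, where the network has a full
receptive field.  Residue-level predictions are obtained by plurality
vote among the predicted voxel labels within 3 Å of each residue's Cα.
Test-set aggregates are weighted averages with each case weighted by
its voxel (or residue) count for the class in question, so a case with
no sheet content contributes nothing to the sheet average.

F1 is computed directly from counts as ``2 TP / (2 TP + FP + FN)`` and
is NA (NaN) when that denominator is zero, i.e. when the class occurs
in neither truth nor prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .structures import (
    BACKGROUND, DEFAULT_RADIUS, HELIX, SHEET, ChainStructure, residues_in_box,
)
from .volumes import BoxSpec, LabelMap, center_box

FOREGROUND_CLASSES = (HELIX, SHEET)


@dataclass
class ClassCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0


@dataclass
class ConfusionCounts:
    """One-vs-rest counts for the two foreground classes."""

    helix: ClassCounts = field(default_factory=ClassCounts)
    sheet: ClassCounts = field(default_factory=ClassCounts)

    def for_class(self, cls: int) -> ClassCounts:
        return self.helix if cls == HELIX else self.sheet


def _counts_from_arrays(truth: np.ndarray, pred: np.ndarray) -> ConfusionCounts:
    cc = ConfusionCounts()
    for cls in FOREGROUND_CLASSES:
        t = truth == cls
        p = pred == cls
        c = cc.for_class(cls)
        c.tp = int(np.sum(t & p))
        c.fp = int(np.sum(~t & p))
        c.fn = int(np.sum(t & ~p))
    return cc


def voxel_confusion(
    truth: LabelMap, pred: LabelMap, box: Optional[BoxSpec] = None
) -> ConfusionCounts:
    """Per-class voxel counts over the center box of a cropped pair.

    *truth* and *pred* must share the grid.  When *box* is given both
    volumes are reduced to the center box first (*pred* may already be
    center-box sized, in which case it is used as is).
    """
    t, p = truth, pred
    if box is not None:
        if t.shape == box.shape:
            t = center_box(t, box)
        if p.shape == box.shape:
            p = center_box(p, box)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch: truth {t.shape} vs prediction {p.shape}")
    return _counts_from_arrays(t.classes, p.classes)


def residue_vote(
    pred_labels: LabelMap, structure: ChainStructure, radius: float = DEFAULT_RADIUS
) -> np.ndarray:
    """Predicted class per residue by plurality vote of nearby voxels.

    Counts predicted voxel labels whose centers lie within ``radius`` Å
    of the residue's Cα; ties for the plurality and empty spheres give
    background.
    """
    n = len(structure.residues)
    out = np.zeros(n, dtype=np.int64)
    if n == 0:
        return out
    shape = pred_labels.shape
    origin = np.asarray(pred_labels.origin)
    s = pred_labels.spacing
    rad_vox = int(math.ceil(radius / s))
    for i, res in enumerate(structure.residues):
        c = (res.ca_xyz - origin) / s
        sl, axes = [], []
        for ax in range(3):
            a0 = max(0, int(math.floor(c[ax])) - rad_vox)
            a1 = min(shape[ax], int(math.ceil(c[ax])) + rad_vox + 1)
            if a0 >= a1:
                sl = None
                break
            sl.append(slice(a0, a1))
            axes.append((np.arange(a0, a1) - c[ax]) * s)
        if sl is None:
            continue
        d2 = (axes[0][:, None, None] ** 2 + axes[1][None, :, None] ** 2
              + axes[2][None, None, :] ** 2)
        inside = d2 <= radius ** 2 + 1e-9
        votes = pred_labels.classes[tuple(sl)][inside]
        if votes.size == 0:
            continue
        counts = np.bincount(votes, minlength=3)
        best = counts.max()
        winners = np.flatnonzero(counts == best)
        out[i] = int(winners[0]) if winners.size == 1 else BACKGROUND
    return out


def residue_confusion(
    truth_classes: Sequence[int], pred_classes: Sequence[int]
) -> ConfusionCounts:
    """One-vs-rest residue counts; inputs must be equal-length vectors."""
    t = np.asarray(truth_classes)
    p = np.asarray(pred_classes)
    if t.shape != p.shape:
        raise ValueError("truth and prediction vectors differ in length")
    return _counts_from_arrays(t, p)


def f1_from_counts(c: ClassCounts) -> Tuple[float, float, float]:
    """(precision, recall, F1); NaN where the defining denominator is 0."""
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else float("nan")
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else float("nan")
    denom = 2 * c.tp + c.fp + c.fn
    f1 = 2 * c.tp / denom if denom > 0 else float("nan")
    return precision, recall, f1


def weighted_average(
    per_case_f1: Sequence[float], weights: Sequence[float]
) -> float:
    """Σ w_i F1_i / Σ w_i over cases with defined F1 and positive weight.

    NaN when no case qualifies (e.g. all weights zero).  Invariant under
    uniform weight scaling; reduces to the plain mean for equal weights.
    """
    f = np.asarray(per_case_f1, dtype=float)
    w = np.asarray(weights, dtype=float)
    if f.shape != w.shape:
        raise ValueError("scores and weights differ in length")
    if (w < 0).any():
        raise ValueError("weights must be >= 0")
    ok = ~np.isnan(f) & (w > 0)
    if not ok.any():
        return float("nan")
    return float(np.sum(f[ok] * w[ok]) / np.sum(w[ok]))


@dataclass
class EvaluationReport:
    """Per-case table plus voxel-count-weighted aggregate scores."""

    table: pd.DataFrame
    weighted: Dict[str, float]

    def to_tsv(self, path) -> None:
        df = self.table.copy()
        agg = {"case": "weighted_average"}
        agg.update({k: v for k, v in self.weighted.items() if k in df.columns})
        df = pd.concat([df, pd.DataFrame([agg])], ignore_index=True)
        df.to_csv(path, sep="\t", index=False, float_format="%.4f", na_rep="NA")


def evaluate_testset(predictor: Callable, cases: Iterable) -> EvaluationReport:
    """Evaluate a predictor over test cases at voxel and residue level.

    *predictor* maps a case to a center-box :class:`LabelMap` (e.g.
    ``lambda case: segment(model, case.density, case.box)``); a truth
    oracle can be passed for pipeline self-checks.  Each case must carry
    ``density``, ``labels``, ``structure`` and ``box`` attributes.
    """
    rows = []
    for case in cases:
        pred_cb = predictor(case)
        truth_cb = center_box(case.labels, case.box)
        vox = _counts_from_arrays(truth_cb.classes, pred_cb.classes)

        res_sub = residues_in_box(case.structure, case.box, case.density)
        res_truth = res_sub.classes_array()
        res_pred = residue_vote(pred_cb, res_sub)
        res = residue_confusion(res_truth, res_pred)

        row = {"case": case.id}
        for name, cls in (("helix", HELIX), ("sheet", SHEET)):
            row[f"voxels_{name}"] = int(np.sum(truth_cb.classes == cls))
            row[f"residues_{name}"] = int(np.sum(res_truth == cls))
            row[f"voxel_f1_{name}"] = f1_from_counts(vox.for_class(cls))[2]
            row[f"residue_f1_{name}"] = f1_from_counts(res.for_class(cls))[2]
        row["voxels_background"] = int(np.sum(truth_cb.classes == BACKGROUND))
        rows.append(row)

    table = pd.DataFrame(rows)
    weighted = {}
    for name in ("helix", "sheet"):
        weighted[f"voxel_f1_{name}"] = weighted_average(
            table[f"voxel_f1_{name}"], table[f"voxels_{name}"]
        )
        weighted[f"residue_f1_{name}"] = weighted_average(
            table[f"residue_f1_{name}"], table[f"residues_{name}"]
        )
    weighted["voxel_f1_mean"] = float(
        np.nanmean([weighted["voxel_f1_helix"], weighted["voxel_f1_sheet"]])
    )
    return EvaluationReport(table, weighted)
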
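"""Voxel-wise concordance between thresholded tractography and a
reference segmentation: confusion counts, ROC and Dice-similarity
curves, optimal-threshold selection, and false-negative dilation
profiles, per region of interest and averaged across raters.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GridMismatchError, UndefinedRateError
from .tractography import ConnectivityMap, threshold_map


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    roi_id: str = ""
    threshold: float = np.nan

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(
    pred_mask: np.ndarray,
    ref_mask: np.ndarray,
    roi_mask: np.ndarray,
    roi_id: str = "",
    threshold: float = np.nan,
) -> ConfusionCounts:
    """Four-way tally restricted to the voxels of ``roi_mask``."""
    if not (pred_mask.shape == ref_mask.shape == roi_mask.shape):
        raise ValueError("pred, ref and roi masks must share a shape")
    if not roi_mask.any():
        raise ValueError("roi_mask is empty")
    p = pred_mask[roi_mask].astype(bool)
    r = ref_mask[roi_mask].astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & r)),
        fp=int(np.count_nonzero(p & ~r)),
        tn=int(np.count_nonzero(~p & ~r)),
        fn=int(np.count_nonzero(~p & r)),
        roi_id=roi_id,
        threshold=threshold,
    )


def tpr_fpr(c: ConfusionCounts) -> tuple[float, float]:
    """Sensitivity ``TP/(TP+FN)`` and fall-out ``FP/(FP+TN)``."""
    if c.tp + c.fn == 0:
        raise UndefinedRateError("TPR undefined: no reference-positive voxels in ROI")
    if c.fp + c.tn == 0:
        raise UndefinedRateError("FPR undefined: no reference-negative voxels in ROI")
    return c.tp / (c.tp + c.fn), c.fp / (c.fp + c.tn)


def dice_si(pred_mask: np.ndarray, ref_mask: np.ndarray) -> float:
    """Dice similarity ``2|A∩B| / (|A|+|B|)``; 0 when both masks are empty."""
    if pred_mask.shape != ref_mask.shape:
        raise ValueError("masks must share a shape")
    p = pred_mask.astype(bool)
    r = ref_mask.astype(bool)
    denom = int(p.sum()) + int(r.sum())
    if denom == 0:
        return 0.0
    return 2.0 * int(np.count_nonzero(p & r)) / denom


@dataclass
class OverlapReport:
    """Per-(roi, threshold) confusion rows plus per-roi summaries.

    ``rows`` columns: roi, threshold, TP, FP, TN, FN, TPR, FPR, SI.
    ``summary`` maps roi -> {auc, optimal_threshold, max_si}.
    ``dilation`` maps roi -> DataFrame(margin_mm, covered_fraction).
    """

    rows: pd.DataFrame
    summary: dict = dc_field(default_factory=dict)
    dilation: dict = dc_field(default_factory=dict)


def _auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    """Trapezoidal area under the ROC points.

    Anchored at (0, 0) (threshold above the map maximum) and (1, 1)
    (every voxel included, i.e. thresholding below zero), so the value
    is comparable across ROIs even when the sweep covers only part of
    the FPR range.
    """
    f = np.concatenate([[0.0], np.asarray(fpr, dtype=float), [1.0]])
    t = np.concatenate([[0.0], np.asarray(tpr, dtype=float), [1.0]])
    order = np.lexsort((t, f))
    return float(np.trapezoid(t[order], f[order]))


def roc_and_si_curves(
    cmap: ConnectivityMap,
    ref_mask: np.ndarray,
    roi_masks: dict[str, np.ndarray],
    thresholds: np.ndarray,
) -> OverlapReport:
    """Sweep connectivity thresholds and tabulate concordance per ROI.

    For each threshold the map is binarized, confusion counts are taken
    within each ROI, and TPR/FPR/SI recorded.  Per ROI the report also
    carries the trapezoidal AUC and the optimal threshold (the smallest
    threshold attaining the maximal SI).
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be sorted ascending")
    records = []
    for t in thresholds:
        pred = threshold_map(cmap, t)
        for roi_id, roi in roi_masks.items():
            c = confusion_counts(pred, ref_mask, roi, roi_id=roi_id, threshold=t)
            tpr, fpr = tpr_fpr(c)
            si = dice_si(pred & roi, ref_mask & roi)
            records.append(
                dict(roi=roi_id, threshold=t, TP=c.tp, FP=c.fp, TN=c.tn, FN=c.fn,
                     TPR=tpr, FPR=fpr, SI=si)
            )
    rows = pd.DataFrame.from_records(records)
    summary = {}
    for roi_id in roi_masks:
        sub = rows[rows["roi"] == roi_id]
        max_si = float(sub["SI"].max())
        best = sub[sub["SI"] == max_si]["threshold"].min()  # ties -> smaller threshold
        summary[roi_id] = {
            "auc": _auc(sub["FPR"].to_numpy(), sub["TPR"].to_numpy()),
            "optimal_threshold": float(best),
            "max_si": max_si,
        }
    return OverlapReport(rows=rows, summary=summary)


def fn_dilation_profile(
    pred_mask: np.ndarray,
    ref_mask: np.ndarray,
    roi_mask: np.ndarray,
    voxel_size_mm: float,
    max_margin_mm: float,
) -> pd.DataFrame:
    """Fraction of reference voxels covered as the prediction grows.

    The prediction mask is dilated one voxel at a time with a
    6-connected (face) structuring element; at step ``k`` the covered
    fraction of ``ref ∩ roi`` is reported at margin ``k * voxel_size``.
    An empty prediction yields an all-zero profile (dilation from
    nothing produces nothing) and is flagged in the ``empty_pred``
    attribute of the returned frame.
    """
    if not (pred_mask.shape == ref_mask.shape == roi_mask.shape):
        raise ValueError("masks must share a shape")
    ref = ref_mask.astype(bool) & roi_mask.astype(bool)
    n_ref = int(ref.sum())
    if n_ref == 0:
        raise ValueError("no reference voxels inside the ROI")
    structure = ndimage.generate_binary_structure(pred_mask.ndim, 1)
    n_steps = int(np.floor(max_margin_mm / voxel_size_mm + 1e-9))
    cur = pred_mask.astype(bool)
    empty = not cur.any()
    margins, fractions = [], []
    for k in range(n_steps + 1):
        margins.append(k * voxel_size_mm)
        if empty:
            fractions.append(0.0)
        else:
            fractions.append(int(np.count_nonzero(cur & ref)) / n_ref)
        if k < n_steps and not empty:
            cur = ndimage.binary_dilation(cur, structure=structure)
    out = pd.DataFrame({"margin_mm": margins, "covered_fraction": fractions})
    out.attrs["empty_pred"] = empty
    return out


def average_reports(reports: list[OverlapReport]) -> OverlapReport:
    """Arithmetic mean of rates (and AUC) across raters; counts summed.

    All reports must share the same (roi, threshold) grid.
    """
    if not reports:
        raise GridMismatchError("no reports to average")
    base = reports[0].rows[["roi", "threshold"]]
    for r in reports[1:]:
        other = r.rows[["roi", "threshold"]]
        if len(other) != len(base) or not (
            (other["roi"].to_numpy() == base["roi"].to_numpy()).all()
            and np.allclose(other["threshold"].to_numpy(), base["threshold"].to_numpy())
        ):
            raise GridMismatchError("reports do not share a (roi, threshold) grid")

    rows = base.copy()
    for col in ("TP", "FP", "TN", "FN"):
        rows[col] = sum(r.rows[col].to_numpy() for r in reports)
    for col in ("TPR", "FPR", "SI"):
        rows[col] = np.mean([r.rows[col].to_numpy() for r in reports], axis=0)

    summary = {}
    for roi_id in reports[0].summary:
        summary[roi_id] = {
            "auc": float(np.mean([r.summary[roi_id]["auc"] for r in reports])),
            "optimal_threshold": float(np.mean(
                [r.summary[roi_id]["optimal_threshold"] for r in reports])),
            "max_si": float(np.mean([r.summary[roi_id]["max_si"] for r in reports])),
        }
    dilation = {}
    common = set.intersection(*[set(r.dilation) for r in reports]) if reports else set()
    for roi_id in common:
        frames = [r.dilation[roi_id] for r in reports]
        m0 = frames[0]["margin_mm"].to_numpy()
        if not all(np.allclose(f["margin_mm"].to_numpy(), m0) for f in frames):
            raise GridMismatchError("dilation profiles do not share a margin grid")
        dilation[roi_id] = pd.DataFrame({
            "margin_mm": m0,
            "covered_fraction": np.mean(
                [f["covered_fraction"].to_numpy() for f in frames], axis=0),
        })
    return OverlapReport(rows=rows, summary=summary, dilation=dilation)


def default_thresholds(n: int = 100, upper: float = 0.0035) -> np.ndarray:
    """Evenly spaced connectivity thresholds over [0, 0.35%]."""
    return np.linspace(0.0, upper, n)
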
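"""Pixel-wise segmentation metrics and diagnostic overlays.

Sensitivity, specificity and accuracy follow the usual confusion-count
definitions over vessel (positive) vs background (negative) pixels:

    Se = tp / (tp + fn)     Sp = tn / (tn + fp)     Acc = (tp + tn) / total

AUC is the area under the pixel-wise ROC curve obtained by sweeping every
distinct probability threshold (trapezoidal rule), computed here via
scikit-learn over pooled pixels.  By default metrics cover all image pixels;
an optional evaluation region (e.g. the circular field of view) restricts
them, since conventions differ across the retinal literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "OverlayStyle",
    "confusion",
    "se_sp_acc",
    "roc_auc",
    "render_overlay",
    "evaluate_dataset",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("negative count")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricsReport:
    Se: float
    Sp: float
    Acc: float
    AUC: float | None = None


@dataclass(frozen=True)
class OverlayStyle:
    tp_color: tuple[int, int, int] = (0, 0, 255)    # blue
    fp_color: tuple[int, int, int] = (0, 255, 0)    # green
    fn_color: tuple[int, int, int] = (0, 0, 0)      # black
    # fn is sometimes drawn red instead; colors are configurable for that.

    def __post_init__(self) -> None:
        if len({self.tp_color, self.fp_color, self.fn_color}) != 3:
            raise ValueError("overlay colors must be distinct")


def _check_binary(mask: np.ndarray, name: str) -> np.ndarray:
    mask = np.asarray(mask)
    if not np.isin(np.unique(mask), (0, 1)).all():
        raise ValueError(f"{name} is not binary {{0,1}}")
    return mask.astype(bool)


def confusion(
    pred_mask: np.ndarray,
    gt_mask: np.ndarray,
    eval_region: np.ndarray | None = None,
) -> ConfusionCounts:
    """Pixel confusion counts of a predicted vs ground-truth vessel mask."""
    pred = _check_binary(pred_mask, "prediction")
    gt = _check_binary(gt_mask, "ground truth")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {gt.shape}")
    if eval_region is None:
        region = np.ones_like(gt, dtype=bool)
    else:
        region = _check_binary(eval_region, "eval region")
        if region.shape != gt.shape:
            raise ValueError("eval region shape mismatch")
    p, g = pred[region], gt[region]
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    return ConfusionCounts(tp, fp, tn, fn)


def se_sp_acc(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Sensitivity, specificity, accuracy; NaN where a denominator is zero."""
    se = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else float("nan")
    sp = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else float("nan")
    acc = (counts.tp + counts.tn) / counts.total if counts.total else float("nan")
    return se, sp, acc


def roc_auc(
    vessel_prob_map: np.ndarray,
    gt_mask: np.ndarray,
    eval_region: np.ndarray | None = None,
) -> float:
    """Area under the pixel-wise ROC curve (all distinct thresholds)."""
    p = np.asarray(vessel_prob_map, dtype=np.float64)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    gt = _check_binary(gt_mask, "ground truth")
    if p.shape != gt.shape:
        raise ValueError("shape mismatch")
    if eval_region is not None:
        region = _check_binary(eval_region, "eval region")
        p, gt = p[region], gt[region]
    else:
        p, gt = p.ravel(), gt.ravel()
    if gt.all() or not gt.any():
        raise ValueError("AUC undefined: ground truth has a single class")
    return float(roc_auc_score(gt.astype(int), p))


def render_overlay(
    image: np.ndarray,
    pred_mask: np.ndarray,
    gt_mask: np.ndarray,
    style: OverlayStyle | None = None,
) -> np.ndarray:
    """Paint tp/fp/fn pixels over a dimmed grayscale of the input.

    True negatives keep the dimmed background, which is mapped into the
    mid-gray range [32, 159] so no background pixel can collide with the
    saturated (or pure-black) error colors — recounting painted pixels
    reproduces the confusion counts exactly.
    """
    style = style or OverlayStyle()
    pred = _check_binary(pred_mask, "prediction")
    gt = _check_binary(gt_mask, "ground truth")
    img = np.asarray(image)
    if img.shape[:2] != gt.shape or pred.shape != gt.shape:
        raise ValueError("inputs not aligned")
    gray = img.mean(axis=2) if img.ndim == 3 else img.astype(np.float64)
    base = (gray / 2 + 32).clip(32, 159).astype(np.uint8)
    out = np.repeat(base[:, :, None], 3, axis=2)
    out[pred & gt] = style.tp_color
    out[pred & ~gt] = style.fp_color
    out[~pred & gt] = style.fn_color
    return out


def evaluate_dataset(model, pairs, eval_regions=None, with_auc: bool = True):
    """Per-image metrics plus a pooled-pixel aggregate.

    ``model`` needs ``predict(image_batch)`` and ``forward`` (class-
    probability maps); ``pairs`` is a SamplePair list.  Returns a list of
    row dicts, one per image and a final ``"pooled"`` row whose counts are
    summed over all pixels (so its Acc is the count-weighted mean).
    """
    if not pairs:
        raise ValueError("empty evaluation set")
    rows = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    probs_all, gt_all = [], []
    for i, pair in enumerate(pairs):
        x = pair.image.astype(np.float32).transpose(2, 0, 1)[None] / 255.0
        pmap = model.forward(x, training=False)[0]
        pred = (pmap[1] > pmap[0]).astype(np.uint8)
        region = None if eval_regions is None else eval_regions[i]
        counts = confusion(pred, pair.mask, region)
        pooled = pooled + counts
        se, sp, acc = se_sp_acc(counts)
        row = {"image": i, "tp": counts.tp, "fp": counts.fp, "tn": counts.tn,
               "fn": counts.fn, "Se": se, "Sp": sp, "Acc": acc}
        if with_auc:
            vp = pmap[1]
            if region is not None:
                reg = _check_binary(region, "eval region")
                probs_all.append(vp[reg])
                gt_all.append(pair.mask[reg])
            else:
                probs_all.append(vp.ravel())
                gt_all.append(pair.mask.ravel())
            try:
                row["AUC"] = roc_auc(vp, pair.mask, region)
            except ValueError:
                row["AUC"] = float("nan")
        rows.append(row)
    se, sp, acc = se_sp_acc(pooled)
    agg = {"image": "pooled", "tp": pooled.tp, "fp": pooled.fp, "tn": pooled.tn,
           "fn": pooled.fn, "Se": se, "Sp": sp, "Acc": acc}
    if with_auc:
        p = np.concatenate(probs_all)
        g = np.concatenate(gt_all)
        agg["AUC"] = float(roc_auc_score(g.astype(int), p)) if 0 < g.sum() < g.size else float("nan")
    rows.append(agg)
    return rows


def report_tsv(rows) -> str:
    """Serialize evaluate_dataset rows as TSV."""
    cols = list(rows[0].keys())
    lines = ["\t".join(cols)]
    for r in rows:
        lines.append("\t".join(str(r[c]) for c in cols))
    return "\n".join(lines) + "\n"
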
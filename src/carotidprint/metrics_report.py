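"""Classification metrics and cross-validation reporting.

Per class (one-vs-rest): TP, TN, FP, FN and the derived proportions
SEN = TP/(TP+FN), SPE = TN/(TN+FP), PRE = TP/(TP+FP),
F1 = 2*PRE*SEN/(PRE+SEN), ACC = (TP+TN)/(TP+TN+FP+FN).  The headline
"overall accuracy" of a run is the multiclass trace/total, the only
single-number reading when one value is reported per experiment; the
one-vs-rest ACC is computed and reported alongside per class.  Undefined
0/0 ratios are surfaced as NaN, never silently zeroed.  Across repeated
CV runs, metrics aggregate as mean +- sample standard deviation,
formatted as percentages like ``(96.38±2.32)%``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

METRIC_NAMES = ("SEN", "SPE", "PRE", "F1", "ACC")


@dataclass
class ClassMetrics:
    """Counts and metrics from one confusion matrix."""

    classes: list
    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    sen: np.ndarray
    spe: np.ndarray
    pre: np.ndarray
    f1: np.ndarray
    acc_ovr: np.ndarray        # per-class one-vs-rest accuracy
    acc_trace: float           # multiclass trace/total accuracy

    def metric(self, name: str) -> np.ndarray:
        return {"SEN": self.sen, "SPE": self.spe, "PRE": self.pre,
                "F1": self.f1, "ACC": self.acc_ovr}[name]


def _safe_div(num, den):
    num = np.asarray(num, dtype=np.float64)
    den = np.asarray(den, dtype=np.float64)
    out = np.full(num.shape, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def confusion_to_metrics(cm, classes=None) -> ClassMetrics:
    """One-vs-rest reduction of a square confusion matrix (rows = truth)."""
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(cm < 0) or not np.issubdtype(cm.dtype, np.number):
        raise ValueError("confusion matrix must hold non-negative counts")
    n = cm.shape[0]
    classes = list(classes) if classes is not None else list(range(n))
    total = cm.sum()
    tp = np.diag(cm).astype(np.float64)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = total - tp - fn - fp
    sen = _safe_div(tp, tp + fn)
    spe = _safe_div(tn, tn + fp)
    pre = _safe_div(tp, tp + fp)
    f1 = _safe_div(2.0 * pre * sen, pre + sen)
    acc_ovr = _safe_div(tp + tn, tp + tn + fp + fn)
    acc_trace = float(tp.sum() / total) if total > 0 else float("nan")
    return ClassMetrics(classes, tp, tn, fp, fn, sen, spe, pre, f1,
                        acc_ovr, acc_trace)


def aggregate_runs(runs: list[ClassMetrics]) -> dict:
    """Mean and sample standard deviation over CV runs, in percent.

    Returns ``{"classes": [...], "per_class": {metric: (mean[%], sd[%])
    arrays}, "overall_acc": (mean, sd)}``; NaN metrics (undefined 0/0
    in a run) propagate into the aggregates.
    """
    if len(runs) < 2:
        raise ValueError("need at least two runs to aggregate")
    classes = runs[0].classes
    if any(r.classes != classes for r in runs):
        raise ValueError("runs cover different class sets")
    per_class = {}
    for name in METRIC_NAMES:
        vals = np.stack([r.metric(name) for r in runs]) * 100.0
        per_class[name] = (vals.mean(axis=0), vals.std(axis=0, ddof=1))
    overall = np.array([r.acc_trace for r in runs]) * 100.0
    return {"classes": classes, "per_class": per_class,
            "overall_acc": (float(overall.mean()),
                            float(overall.std(ddof=1)))}


def format_pm(mean: float, sd: float) -> str:
    """Percentage with two decimals, e.g. ``(96.38±2.32)%``."""
    return f"({mean:.2f}±{sd:.2f})%"


def summary_table(agg: dict, side: str | None = None) -> pd.DataFrame:
    """Per-class SEN/SPE/PRE/F1 table of formatted mean±sd strings."""
    rows = []
    for i, cls in enumerate(agg["classes"]):
        label = f"{cls}-{side}" if side else str(cls)
        row = {"class": label}
        for name in ("SEN", "SPE", "PRE", "F1"):
            mean, sd = agg["per_class"][name]
            row[name] = format_pm(mean[i], sd[i])
        rows.append(row)
    return pd.DataFrame(rows)


def normalize_confusion(cms: list[np.ndarray]) -> np.ndarray:
    """Row-normalized mean confusion matrix across runs.

    Rows that sum to zero (a class never present in any test fold) come
    back as NaN rows, flagged rather than silently zeroed.
    """
    mean = np.mean([np.asarray(c, dtype=np.float64) for c in cms], axis=0)
    sums = mean.sum(axis=1, keepdims=True)
    out = np.full_like(mean, np.nan)
    ok = sums[:, 0] > 0
    out[ok] = mean[ok] / sums[ok]
    return out


def save_confusion_heatmap(norm_cm: np.ndarray, classes, path) -> None:
    """Render the mean normalized confusion matrix as a PNG heatmap."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.4))
    im = ax.imshow(norm_cm, vmin=0.0, vmax=1.0, cmap="viridis")
    ax.set_xticks(range(len(classes)), classes)
    ax.set_yticks(range(len(classes)), classes)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(len(classes)):
        for j in range(len(classes)):
            if np.isfinite(norm_cm[i, j]):
                ax.text(j, i, f"{norm_cm[i, j]:.2f}", ha="center",
                        va="center", fontsize=7,
                        color="white" if norm_cm[i, j] < 0.5 else "black")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
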
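"""Metrics, ROC analysis, plot data and report bundles for CV results.

Sensitivity and specificity are one-vs-rest per class (the other classes
pooled); "overall accuracy" is the correct fraction, "balanced accuracy" the
mean of average sensitivity and average specificity — both are reported
because published figures of this kind are consistent with either reading.
AUC is the concordance probability (ties count 1/2), computed from ranks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .classify import CVResult
from .core import InvariantError

LEVELS = ("spectrum", "sample")


def _level_frame(cv: CVResult, level: str) -> pd.DataFrame:
    if level == "spectrum":
        return cv.spectrum_df
    if level == "sample":
        return cv.sample_df
    raise InvariantError(f"unknown level {level!r}; expected one of {LEVELS}")


@dataclass
class ConfusionMatrix:
    classes: list[str]
    counts: np.ndarray   # (C, C) true x predicted
    level: str

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.classes),) * 2:
            raise InvariantError("counts must be square over the class list")
        if (self.counts < 0).any():
            raise InvariantError("counts must be non-negative")

    def normalized(self) -> np.ndarray:
        """Row-normalized percentages (rows with no entries stay NaN)."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.counts / totals

    def to_frame(self, normalized: bool = False) -> pd.DataFrame:
        data = self.normalized() if normalized else self.counts
        return pd.DataFrame(data, index=self.classes, columns=self.classes)


def confusion(cv: CVResult, level: str = "sample") -> ConfusionMatrix:
    """Confusion matrix of per-spectrum or majority-vote predictions."""
    df = _level_frame(cv, level)
    if len(df) == 0:
        raise InvariantError("CV result is empty")
    classes = cv.classes
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(df["true"], df["predicted"]):
        counts[idx[str(t)], idx[str(p)]] += 1
    return ConfusionMatrix(list(classes), counts, level)


@dataclass
class MetricsReport:
    classes: list[str]
    sensitivity: dict[str, float | None]   # None when a class has no truth rows
    specificity: dict[str, float | None]
    average_sensitivity: float
    average_specificity: float
    overall_accuracy: float
    balanced_accuracy: float
    level: str


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest sensitivity/specificity per class plus both accuracies."""
    if len(cm.classes) < 2:
        raise InvariantError("metrics need at least 2 classes")
    counts = cm.counts.astype(float)
    total = counts.sum()
    sens: dict[str, float | None] = {}
    spec: dict[str, float | None] = {}
    for i, c in enumerate(cm.classes):
        tp = counts[i, i]
        fn = counts[i].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn == 0:
            warnings.warn(
                f"class '{c}' has no true instances; sensitivity undefined",
                RuntimeWarning,
            )
            sens[c] = None
        else:
            sens[c] = tp / (tp + fn)
        spec[c] = tn / (tn + fp) if tn + fp > 0 else None
    def _avg(d):
        vals = [v for v in d.values() if v is not None]
        return float(np.mean(vals)) if vals else float("nan")
    avg_sens = _avg(sens)
    avg_spec = _avg(spec)
    return MetricsReport(
        classes=list(cm.classes),
        sensitivity=sens,
        specificity=spec,
        average_sensitivity=avg_sens,
        average_specificity=avg_spec,
        overall_accuracy=float(np.trace(counts) / total) if total else float("nan"),
        balanced_accuracy=(avg_sens + avg_spec) / 2.0,
        level=cm.level,
    )


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def auc_score(is_positive: np.ndarray, scores: np.ndarray) -> float:
    """Concordance-probability AUC (ties count 1/2), via the rank formula."""
    is_positive = np.asarray(is_positive, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise InvariantError("scores must be finite")
    n_pos = int(is_positive.sum())
    n_neg = is_positive.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise InvariantError("AUC needs both positive and negative scores")
    ranks = rankdata(scores)
    return float(
        (ranks[is_positive].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    positive_class: str
    level: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def roc(
    cv: CVResult,
    positive_class: str,
    level: str = "spectrum",
    score: str = "posterior",
) -> ROCResult:
    """ROC over pooled held-out scores.

    At the spectrum level the score is the positive-class posterior (or the
    first LD score, ``score="ld"``); at the sample level it is the
    positive-class vote fraction.
    """
    if len(cv.classes) != 2:
        raise InvariantError(
            "ROC is defined for 2-class results; use one_vs_rest_roc for "
            "multiclass"
        )
    positive_class = str(positive_class)
    if positive_class not in cv.classes:
        raise InvariantError(f"unknown positive class {positive_class!r}")
    df = _level_frame(cv, level)
    truth = df["true"].to_numpy() == positive_class
    if level == "sample":
        values = df[f"frac_{positive_class}"].to_numpy(float)
    elif score == "posterior":
        values = df[f"posterior_{positive_class}"].to_numpy(float)
    elif score == "ld":
        values = df["ld1"].to_numpy(float)
        # orient the LD axis so the positive class scores higher
        if values[truth].mean() < values[~truth].mean():
            values = -values
    else:
        raise InvariantError(f"unknown score kind {score!r}")
    fpr, tpr, thresholds = _sk_roc_curve(truth, values)
    return ROCResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=auc_score(truth, values),
        positive_class=positive_class,
        level=level,
    )


def one_vs_rest_roc(cv: CVResult, positive_class: str,
                    level: str = "spectrum") -> ROCResult:
    """Convenience one-vs-rest ROC for multiclass results (posterior score)."""
    positive_class = str(positive_class)
    df = _level_frame(cv, level)
    truth = df["true"].to_numpy() == positive_class
    col = (f"frac_{positive_class}" if level == "sample"
           else f"posterior_{positive_class}")
    values = df[col].to_numpy(float)
    fpr, tpr, thresholds = _sk_roc_curve(truth, values)
    return ROCResult(thresholds, tpr, fpr, auc_score(truth, values),
                     positive_class, level)


# ---------------------------------------------------------------------------
# Plot data
# ---------------------------------------------------------------------------

def ld_scatter(cv: CVResult, max_axes: int = 3) -> pd.DataFrame:
    """First <= 3 LD scores per spectrum with group labels."""
    df = cv.spectrum_df
    ld_cols = [c for c in df.columns if c.startswith("ld")][:max_axes]
    if not ld_cols:
        raise InvariantError("CV result carries no discriminant scores")
    return df[["sample_id", "true"] + ld_cols].copy()


def ld_histograms(cv: CVResult, bins: int = 40) -> dict[str, pd.DataFrame]:
    """Per-group histogram of the first LD score (2-class separation view)."""
    df = cv.spectrum_df
    if "ld1" not in df.columns:
        raise InvariantError("CV result carries no discriminant scores")
    lo, hi = df["ld1"].min(), df["ld1"].max()
    edges = np.linspace(lo, hi if hi > lo else lo + 1.0, bins + 1)
    out = {}
    for group, sub in df.groupby("true"):
        counts, _ = np.histogram(sub["ld1"].to_numpy(float), bins=edges)
        out[str(group)] = pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
        )
    return out


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

def run_report(cv: CVResult, outdir, figures: bool = True) -> dict:
    """Write metrics JSON, confusion CSVs (both levels), ROC data, LD plot
    data and figures; deterministic given the same CVResult."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload: dict = {"config": cv.config, "classes": cv.classes, "metrics": {}}
    for level in LEVELS:
        cm = confusion(cv, level)
        rep = metrics(cm)
        payload["metrics"][level] = {
            "sensitivity": rep.sensitivity,
            "specificity": rep.specificity,
            "average_sensitivity": rep.average_sensitivity,
            "average_specificity": rep.average_specificity,
            "overall_accuracy": rep.overall_accuracy,
            "balanced_accuracy": rep.balanced_accuracy,
        }
        cm.to_frame().to_csv(outdir / f"confusion_{level}.csv")
        cm.to_frame(normalized=True).to_csv(
            outdir / f"confusion_{level}_percent.csv"
        )
    if len(cv.classes) == 2:
        positive = cv.classes[-1]
        for level in LEVELS:
            r = roc(cv, positive, level=level)
            r.to_frame().to_csv(outdir / f"roc_{level}.csv", index=False)
            payload["metrics"][level]["auc"] = r.auc
            payload["metrics"][level]["roc_positive_class"] = positive
    scatter = ld_scatter(cv)
    scatter.to_csv(outdir / "ld_scatter.csv", index=False)
    (outdir / "metrics.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )
    if figures:
        _render_figures(cv, outdir)
    return payload


def _render_figures(cv: CVResult, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cm = confusion(cv, "sample")
    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(cm.normalized(), cmap="Blues", vmin=0, vmax=100)
    ax.set_xticks(range(len(cm.classes)), cm.classes, rotation=45, ha="right")
    ax.set_yticks(range(len(cm.classes)), cm.classes)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.colorbar(im, ax=ax, label="% of true class")
    fig.tight_layout()
    fig.savefig(outdir / "confusion_sample.png", dpi=120)
    plt.close(fig)

    scatter = ld_scatter(cv)
    ld_cols = [c for c in scatter.columns if c.startswith("ld")]
    if len(ld_cols) >= 2:
        fig, ax = plt.subplots(figsize=(4.5, 4))
        for group, sub in scatter.groupby("true"):
            ax.scatter(sub[ld_cols[0]], sub[ld_cols[1]], s=4, alpha=0.5,
                       label=str(group))
        ax.set_xlabel("LD1")
        ax.set_ylabel("LD2")
        ax.legend(markerscale=3, fontsize=7)
        fig.tight_layout()
        fig.savefig(outdir / "ld_scatter.png", dpi=120)
        plt.close(fig)
    if len(cv.classes) == 2:
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        for group, hist in ld_histograms(cv).items():
            centers = (hist["bin_left"] + hist["bin_right"]) / 2
            ax.step(centers, hist["count"], where="mid", label=group)
        ax.set_xlabel("LD1 score")
        ax.set_ylabel("spectra")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(outdir / "ld_histogram.png", dpi=120)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(4, 4))
        for level, style in (("spectrum", "-"), ("sample", "--")):
            r = roc(cv, cv.classes[-1], level=level)
            ax.plot(r.fpr, r.tpr, style, label=f"{level} (AUC {r.auc:.2f})")
        ax.plot([0, 1], [0, 1], ":", color="gray")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(outdir / "roc.png", dpi=120)
        plt.close(fig)
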
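"""Stratified splitting and per-stage evaluation of stage classifiers.

The protocol: hold out 30% of each severity stage for testing (70% train),
so every stage is represented on both sides regardless of class imbalance.
Each stage is then scored as a one-vs-rest binary problem on the fused
multiclass predictions — sensitivity (TPR), specificity (TNR), precision
(PPV), miss rate (FNR), fall-out (FPR), F-score, trapezoidal ROC AUC and
binary "class accuracy" (tp+tn)/N — and the report carries the unweighted
average of each column over the four stages.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import STAGES, STAGE_NAMES, DatasetManifest

logger = logging.getLogger(__name__)


class UndefinedMetricError(ValueError):
    """A requested rate has an empty denominator (no positives/negatives)."""


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/test split: per-stage fraction, seeded, optional
    subsampling of every stage down to the minimum class count first."""

    train_fraction: float = 0.7
    seed: int = 17
    balanced: bool = False

    def __post_init__(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie strictly between 0 and 1")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def train_count(n: int, train_fraction: float) -> int:
    """Per-stage training count: round-half-up of fraction*n, reduced by one
    if that would leave a stage (n >= 2) absent from the test set."""
    k = _round_half_up(train_fraction * n)
    if k == n and n >= 2:
        logger.warning("split: reducing train count %d -> %d so the stage "
                       "appears in the test set", k, k - 1)
        k -= 1
    return k


def split_indices(stages, spec: SplitSpec = SplitSpec()) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays (train, test) of a stratified split of the label vector.

    Within each stage the assignment is a seeded permutation; with
    ``balanced=True`` every stage is first subsampled (seeded) to the
    smallest per-stage count, mirroring a balanced-database experiment.
    """
    y = np.asarray(stages, dtype=int)
    rng = np.random.default_rng(spec.seed)
    present = [s for s in STAGES if np.any(y == s)]
    if not present:
        raise ValueError("no entries to split")
    floor_count = min(int(np.sum(y == s)) for s in present)
    train_idx, test_idx = [], []
    for s in present:
        idx = np.flatnonzero(y == s)
        idx = idx[rng.permutation(idx.size)]
        if spec.balanced:
            idx = idx[:floor_count]
        k = train_count(idx.size, spec.train_fraction)
        train_idx.extend(idx[:k])
        test_idx.extend(idx[k:])
    return np.sort(np.array(train_idx, dtype=int)), np.sort(np.array(test_idx, dtype=int))


def stratified_split(
    manifest: DatasetManifest, spec: SplitSpec = SplitSpec()
) -> tuple[DatasetManifest, DatasetManifest]:
    """Split a manifest into (train, test) manifests per :func:`split_indices`."""
    tr, te = split_indices(manifest.stages, spec)
    return (
        manifest.subset(tr, name=f"{manifest.name}-train"),
        manifest.subset(te, name=f"{manifest.name}-test"),
    )


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts of one one-vs-rest stage problem."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.positives + self.negatives


def confusion_from_predictions(y_true, y_pred, stage: int) -> ConfusionCounts:
    """One-vs-rest confusion counts of a multiclass prediction for `stage`."""
    t = np.asarray(y_true, dtype=int) == stage
    p = np.asarray(y_pred, dtype=int) == stage
    return ConfusionCounts(
        tp=int(np.sum(t & p)), fn=int(np.sum(t & ~p)),
        tn=int(np.sum(~t & ~p)), fp=int(np.sum(~t & p)),
    )


def binary_metrics(counts: ConfusionCounts, stage: int | None = None) -> dict[str, float]:
    """Derived rates of one one-vs-rest confusion table.

    TPR=tp/(tp+fn), FNR=fn/(tp+fn), TNR=tn/(tn+fp), FPR=fp/(tn+fp),
    PPV=tp/(tp+fp) (0 when nothing was predicted positive, flagged),
    F=2*PPV*TPR/(PPV+TPR) (0 when both vanish), and binary class accuracy
    (tp+tn)/N.  Raises if either class is empty.
    """
    label = f" for stage {stage}" if stage is not None else ""
    if counts.positives == 0:
        raise UndefinedMetricError(f"no positive examples{label}: TPR undefined")
    if counts.negatives == 0:
        raise UndefinedMetricError(f"no negative examples{label}: TNR undefined")
    tpr = counts.tp / counts.positives
    tnr = counts.tn / counts.negatives
    if counts.tp + counts.fp > 0:
        ppv = counts.tp / (counts.tp + counts.fp)
    else:
        logger.warning("binary_metrics%s: nothing predicted positive, PPV := 0", label)
        ppv = 0.0
    f_score = 2 * ppv * tpr / (ppv + tpr) if (ppv + tpr) > 0 else 0.0
    return {
        "TPR": tpr, "FNR": 1.0 - tpr, "TNR": tnr, "FPR": 1.0 - tnr,
        "PPV": ppv, "F_score": f_score,
        "class_accuracy": (counts.tp + counts.tn) / counts.total,
    }


def roc_curve(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """ROC points (FPR, TPR) at every distinct score threshold.

    Thresholds sweep the distinct scores in decreasing order ("predict
    positive at or above the threshold"); the endpoints (0,0) and (1,1)
    are always included.  Both coordinate sequences are non-decreasing.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC needs both classes present")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    tps = np.cumsum(y == 1)
    fps = np.cumsum(y == 0)
    # keep only the last index of each tied-score run
    last = np.r_[np.flatnonzero(np.diff(s) != 0), s.size - 1]
    fpr = np.r_[0.0, fps[last] / n_neg]
    tpr = np.r_[0.0, tps[last] / n_pos]
    return fpr, tpr


def auc(fpr, tpr) -> float:
    """Trapezoidal area under an ROC curve (equals the Mann-Whitney
    probability of correct ranking, counting ties one half)."""
    return float(np.trapezoid(np.asarray(tpr, float), np.asarray(fpr, float)))


def roc_auc(scores, labels) -> float:
    return auc(*roc_curve(scores, labels))


class MetricsReport:
    """Per-stage one-vs-rest metrics of a fused multiclass classifier.

    Wraps a DataFrame with one row per stage plus an ``Average`` row of
    unweighted column means over the stages that appear in the test set.
    """

    COLUMNS = ["n_test", "TPR", "FNR", "TNR", "PPV", "FPR",
               "F_score", "AUC", "class_accuracy"]

    def __init__(self, table: pd.DataFrame,
                 confusions: dict[int, ConfusionCounts] | None = None,
                 rocs: dict[int, tuple[np.ndarray, np.ndarray]] | None = None):
        self.table = table
        self.confusions = confusions or {}
        self.rocs = rocs or {}

    @property
    def average(self) -> pd.Series:
        return self.table.loc["Average"]

    def summary(self, digits: int = 3) -> str:
        t = self.table.copy()
        num = [c for c in t.columns if c != "n_test"]
        lines = [
            "One-vs-rest test metrics per cellulite stage",
            "=" * 78,
            t.to_string(float_format=lambda x: f"{x:.{digits}f}"),
            "=" * 78,
            "class accuracy = (tp+tn)/N of the stage's binary problem; "
            "Average is the unweighted mean over stages.",
        ]
        del num
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = {
            str(idx): {c: (int(row[c]) if c == "n_test" else float(row[c]))
                       for c in self.table.columns}
            for idx, row in self.table.iterrows()
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def evaluate_predictions(y_true, y_pred, scores=None) -> MetricsReport:
    """Build a :class:`MetricsReport` from fused predictions.

    `scores` is the optional (n, 4) matrix of per-stage probability scores;
    when given, per-stage ROC/AUC is computed from each stage's column
    against the one-vs-rest labels.  Stages absent from the test set are
    excluded from the table and the averages, with a warning.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty test set")
    rows, confusions, rocs = {}, {}, {}
    for s in STAGES:
        n_s = int(np.sum(y_true == s))
        if n_s == 0:
            logger.warning("stage %d absent from the test set; row undefined, "
                           "excluded from averages", s)
            continue
        counts = confusion_from_predictions(y_true, y_pred, s)
        row = binary_metrics(counts, stage=s)
        row["n_test"] = n_s
        if scores is not None:
            fpr, tpr = roc_curve(np.asarray(scores)[:, s], (y_true == s).astype(int))
            rocs[s] = (fpr, tpr)
            row["AUC"] = auc(fpr, tpr)
        else:
            row["AUC"] = np.nan
        confusions[s] = counts
        rows[f"Stage {s} ({STAGE_NAMES[s]})"] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table = table[MetricsReport.COLUMNS]
    avg = table.mean(axis=0)
    avg["n_test"] = table["n_test"].sum()
    table.loc["Average"] = avg
    table["n_test"] = table["n_test"].astype(int)
    return MetricsReport(table, confusions, rocs)
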
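"""End-to-end helpers chaining the pipeline stages.

These wrap the module-level building blocks (preprocess -> features ->
classify -> evaluate) for the common workflows: preprocessing a whole
manifest, fitting one extractor/classifier combination on a stratified
split, and sweeping the full benchmark grid.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import FAMILIES, OvRStageResults, train_ovr
from .evaluate import MetricsReport, SplitSpec, split_indices
from .features import EXTRACTORS, HOGConfig, build_extractor, feature_matrix
from .io import DatasetManifest, read_image, resolve_manifest_paths
from .preprocess import PreprocessConfig, ROIImage, extract_roi

logger = logging.getLogger(__name__)


def preprocess_images(raws, config: PreprocessConfig = PreprocessConfig()) -> list[ROIImage]:
    """Run ROI extraction over a list of thermograms (raises on failure)."""
    return [extract_roi(raw, config) for raw in raws]


def load_roi_dataset(
    manifest: DatasetManifest, root=None,
    config: PreprocessConfig = PreprocessConfig(),
    preprocessed: bool = False,
) -> tuple[list[ROIImage], np.ndarray]:
    """Read every manifest image and return (ROI images, stage labels).

    With ``preprocessed=True`` the images are assumed to already be ROI
    crops and are only normalised to [0, 1] grayscale.
    """
    if root is not None:
        manifest = resolve_manifest_paths(manifest, root)
    rois, stages = [], []
    for path, stage in manifest:
        raw = read_image(path)
        if preprocessed:
            from .preprocess import to_grayscale

            roi = ROIImage(pixels=to_grayscale(raw.pixels),
                           source_id=raw.source_id, stage=stage)
        else:
            roi = extract_roi(raw, config)
            roi.stage = stage
        rois.append(roi)
        stages.append(stage)
    return rois, np.asarray(stages, dtype=int)


def split_features(
    rois, stages, method: str,
    split: SplitSpec = SplitSpec(),
    hog_config: HOGConfig = HOGConfig(),
    pca_k: int = 40,
):
    """Stratified split followed by leakage-free feature extraction.

    Fitted extractors (PCA, EucDist) see only the training partition.
    Returns (X_train, y_train, X_test, y_test).
    """
    stages = np.asarray(stages, dtype=int)
    tr, te = split_indices(stages, split)
    train_rois = [rois[i] for i in tr]
    test_rois = [rois[i] for i in te]
    extractor = build_extractor(
        method, train_images=train_rois, train_stages=stages[tr],
        hog_config=hog_config, pca_k=pca_k,
    )
    X_tr = feature_matrix(train_rois, extractor)
    X_te = feature_matrix(test_rois, extractor)
    return X_tr, stages[tr], X_te, stages[te]


def run_experiment(
    rois, stages, method: str = "hog", family: str = "ann",
    split: SplitSpec = SplitSpec(), hog_config: HOGConfig = HOGConfig(),
    seed: int = 17, class_weight: str | None = None, **family_params,
) -> tuple[OvRStageResults, MetricsReport]:
    """Fit one extractor/classifier combination and evaluate it."""
    X_tr, y_tr, X_te, y_te = split_features(
        rois, stages, method, split=split, hog_config=hog_config
    )
    results = train_ovr(X_tr, y_tr, family=family, seed=seed,
                        class_weight=class_weight, feature_method=method,
                        **family_params)
    return results, results.evaluate(X_te, y_te)


def benchmark_grid(
    rois, stages,
    methods=EXTRACTORS, families=FAMILIES,
    split: SplitSpec = SplitSpec(), hog_config: HOGConfig = HOGConfig(),
    seed: int = 17, class_weight: str | None = None,
) -> pd.DataFrame:
    """Sweep every extractor x classifier combination on one fixed split.

    Returns one row per combination with the report's Average-row metrics.
    Features are extracted once per method and shared across families.
    """
    rows = []
    for method in methods:
        X_tr, y_tr, X_te, y_te = split_features(
            rois, stages, method, split=split, hog_config=hog_config
        )
        for family in families:
            results = train_ovr(X_tr, y_tr, family=family, seed=seed,
                                class_weight=class_weight, feature_method=method)
            report = results.evaluate(X_te, y_te)
            avg = report.average
            row = {"feature_method": method, "family": family,
                   "n_train": len(y_tr), "n_test": len(y_te)}
            row.update({c: float(avg[c]) for c in report.table.columns
                        if c != "n_test"})
            rows.append(row)
            logger.info("benchmark %s+%s: avg class accuracy %.3f",
                        method, family, row["class_accuracy"])
    return pd.DataFrame(rows)


def write_roc_points(report: MetricsReport, out_dir) -> list[Path]:
    """Dump each stage's ROC points to ``roc_stage<k>.csv`` under out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for s, (fpr, tpr) in report.rocs.items():
        p = out_dir / f"roc_stage{s}.csv"
        pd.DataFrame({"FPR": fpr, "TPR": tpr}).to_csv(p, index=False)
        paths.append(p)
    return paths


def plot_roc(report: MetricsReport, path) -> None:
    """Plot all stages' ROC curves on one axis (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for s, (fpr, tpr) in sorted(report.rocs.items()):
        auc_s = report.table.iloc[list(report.rocs).index(s)]["AUC"]
        ax.plot(fpr, tpr, label=f"stage {s} (AUC {auc_s:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
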
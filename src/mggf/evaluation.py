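"""Metrics, ROC/AUC, the 24-order fusion sweep and the leave-one-panel-out
sensitivity analysis.

The positive class everywhere is hypoalbuminemia. "Overall" metrics pool
the test predictions of the per-stratum models (pneumonia and
non-pneumonia), mirroring how the study reports a single accuracy for
models trained on the two groups.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .fusion import MggfConfig, fit_mggf, predict_mggf, rank_panels_by_mi
from .panels import PANEL_ORDER, PanelSpec


class EvaluationError(ValueError):
    pass


@dataclass
class MetricsReport:
    n: int
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    recall: float | None        # None when no positives in y_true
    specificity: float | None   # None when no negatives in y_true
    stratum: str = ""
    model_id: str = ""


def compute_metrics(y_true, y_pred, stratum: str = "",
                    model_id: str = "") -> MetricsReport:
    """Confusion counts, accuracy, recall and specificity."""
    yt = np.asarray(y_true, int).ravel()
    yp = np.asarray(y_pred, int).ravel()
    if len(yt) != len(yp):
        raise EvaluationError("length mismatch")
    if len(yt) == 0:
        raise EvaluationError("empty input")
    tp = int(((yt == 1) & (yp == 1)).sum())
    fp = int(((yt == 0) & (yp == 1)).sum())
    tn = int(((yt == 0) & (yp == 0)).sum())
    fn = int(((yt == 1) & (yp == 0)).sum())
    recall = tp / (tp + fn) if tp + fn else None
    spec = tn / (tn + fp) if tn + fp else None
    return MetricsReport(n=len(yt), tp=tp, fp=fp, tn=tn, fn=fn,
                         accuracy=(tp + tn) / len(yt), recall=recall,
                         specificity=spec, stratum=stratum,
                         model_id=model_id)


def roc_points(y_true, scores) -> tuple[pd.DataFrame, float]:
    """ROC curve by threshold sweep over unique scores; trapezoid AUC.

    The AUC equals the pairwise-concordance (rank) statistic with ties
    counted one half.
    """
    yt = np.asarray(y_true, int).ravel()
    s = np.asarray(scores, float).ravel()
    if len(np.unique(yt)) < 2:
        raise EvaluationError("ROC requires both classes present")
    fpr, tpr, thresholds = _sk_roc_curve(yt, s)
    auc = float(np.trapezoid(tpr, fpr))
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr,
                           "threshold": thresholds})
    return points, auc


def order_sweep(train: pd.DataFrame, test: pd.DataFrame,
                panel_spec: PanelSpec | None = None,
                config: MggfConfig | None = None
                ) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Test accuracy of the gradual fusion under all 24 panel orders.

    The mutual-information ranking is bypassed and each permutation of the
    four panels is imposed as the fusion order. Returns the 24-row result
    frame and the order MI would have chosen on the training table.
    """
    panel_spec = panel_spec or PanelSpec.default()
    config = config or MggfConfig()
    mi_order = tuple(rank_panels_by_mi(train, panel_spec, config.n_bins))
    y_test = test["hypoalbuminemia"].to_numpy(int)
    rows = []
    for perm in itertools.permutations(PANEL_ORDER):
        model = fit_mggf(train, panel_spec, config, panel_order=list(perm))
        _, pred = predict_mggf(model, test)
        rows.append({"order": ">".join(perm),
                     "accuracy": compute_metrics(y_test, pred).accuracy,
                     "is_mi_order": perm == mi_order})
    return pd.DataFrame(rows), mi_order


def _stratum_frames(table: pd.DataFrame, stratum: str) -> pd.DataFrame:
    flag = 1 if stratum == "PWH" else 0
    return table[table["pneumonia"] == flag]


#: sensitivity-analysis strata: the pneumonia and non-pneumonia tasks
SENSITIVITY_STRATA = ("PWH", "NPWH")


def sensitivity_analysis(train: pd.DataFrame, test: pd.DataFrame,
                         panel_spec: PanelSpec | None = None,
                         config: MggfConfig | None = None) -> pd.DataFrame:
    """Leave-one-panel-out ablation of the gradual-fusion model.

    For each pneumonia stratum (PWH = pneumonia task, NPWH =
    non-pneumonia task) the full four-panel model and each three-panel
    reduced model (mutual information re-ranked among the remaining
    panels) are fitted on the stratum's training rows and evaluated on its
    test rows. ``acc_drop`` is full-model accuracy minus reduced-model
    accuracy; a negative value (removal helped) is preserved and flagged.
    """
    panel_spec = panel_spec or PanelSpec.default()
    config = config or MggfConfig()
    rows = []
    for stratum in SENSITIVITY_STRATA:
        tr = _stratum_frames(train, stratum)
        te = _stratum_frames(test, stratum)
        y_te = te["hypoalbuminemia"].to_numpy(int)
        full = fit_mggf(tr, panel_spec, config)
        _, pred = predict_mggf(full, te)
        full_m = compute_metrics(y_te, pred, stratum=stratum,
                                 model_id="full")
        rows.append({"stratum": stratum, "removed_panel": None,
                     "accuracy": full_m.accuracy, "recall": full_m.recall,
                     "specificity": full_m.specificity,
                     "acc_drop": 0.0, "removal_helped": False})
        for removed in PANEL_ORDER:
            remaining = tuple(p for p in PANEL_ORDER if p != removed)
            order = rank_panels_by_mi(tr, panel_spec, config.n_bins,
                                      panels=remaining)
            reduced = fit_mggf(tr, panel_spec, config, panel_order=order)
            _, pred = predict_mggf(reduced, te)
            m = compute_metrics(y_te, pred, stratum=stratum,
                                model_id=f"minus-{removed}")
            drop = full_m.accuracy - m.accuracy
            rows.append({"stratum": stratum, "removed_panel": removed,
                         "accuracy": m.accuracy, "recall": m.recall,
                         "specificity": m.specificity,
                         "acc_drop": drop, "removal_helped": drop < 0})
    return pd.DataFrame(rows)


def max_drop_panel(report: pd.DataFrame, stratum: str) -> str:
    """The panel whose removal caused the largest accuracy reduction."""
    sub = report[(report["stratum"] == stratum)
                 & report["removed_panel"].notna()]
    if sub.empty:
        raise EvaluationError(f"no ablation rows for stratum {stratum!r}")
    return str(sub.loc[sub["acc_drop"].idxmax(), "removed_panel"])
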
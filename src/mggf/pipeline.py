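"""End-to-end study pipeline: simulate, augment, describe, train, evaluate.

``run_study`` reproduces the full synthetic study in one call and writes
every artifact to a run directory:

* ``cohort.csv`` / ``augmented.csv`` — the simulated and enhanced tables
* ``stats/`` — t-test/SMD tables, panel logistic weights, Pearson matrix
  and the Mantel test, all as tidy tables
* ``models/`` — the fitted gradual-fusion model per stratum, as JSON
* ``metrics/`` — accuracy/recall/specificity per model and stratum,
  pooled "overall" rows, and ROC point tables with AUC
* ``sweep.csv`` — test accuracy of all 24 panel orders per stratum
* ``sensitivity.csv`` — the leave-one-panel-out ablation grid
* ``config.yaml`` and ``run.log``

Reruns with the same configuration are byte-identical for all CSVs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .augment import augment, standardize
from .baselines import BaselineSpec, fit_baseline, split_train_test
from .cohort import generate_cohort, write_cohort
from .config import RunConfig
from .evaluation import (compute_metrics, max_drop_panel, order_sweep,
                         roc_points, sensitivity_analysis)
from .fusion import fit_mggf, predict_mggf
from .panels import PANEL_ORDER, PanelSpec
from .stats import (STRATA, diff_table, feature_distance_matrix,
                    label_distance_matrix, logistic_panel_weights,
                    mantel_test, pearson_matrix, select_stratum)

log = logging.getLogger("mggf")

#: the comparison-model kinds of the baseline suite
BASELINE_KINDS = ("svm-linear", "svm-rbf", "decision-tree")

_MODEL_STRATA = ("pneumonia", "non-pneumonia")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


@_stage("stats")
def _run_stats(cohort: pd.DataFrame, panel_spec: PanelSpec,
               cfg: RunConfig, out: Path) -> None:
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    for stratum in STRATA:
        diff_table(cohort, panel_spec, stratum).to_csv(
            stats_dir / f"diff_{stratum}.csv", index=False)
        w = logistic_panel_weights(cohort, stratum, panel_spec,
                                   C=cfg.baseline_C)
        pd.DataFrame({
            "panel": list(w.panel_weights),
            "avg_weight": list(w.panel_weights.values()),
        }).to_csv(stats_dir / f"weights_{stratum}.csv", index=False)
    pearson_matrix(cohort, panel_spec.features()).to_csv(
        stats_dir / "pearson.csv")
    da = feature_distance_matrix(cohort, panel_spec.features())
    db = label_distance_matrix(cohort["hypoalbuminemia"].to_numpy(int))
    r, p = mantel_test(da, db, n_perm=cfg.mantel_permutations,
                       seed=cfg.split_seed)
    (stats_dir / "mantel.json").write_text(
        json.dumps({"r": r, "p": p,
                    "n_perm": cfg.mantel_permutations}, indent=2))


def _evaluate_models(train: pd.DataFrame, test: pd.DataFrame,
                     panel_spec: PanelSpec, cfg: RunConfig,
                     out: Path) -> pd.DataFrame:
    metrics_dir = out / "metrics"
    metrics_dir.mkdir(exist_ok=True)
    models_dir = out / "models"
    models_dir.mkdir(exist_ok=True)

    records = []
    pooled: dict[str, dict[str, list]] = {}

    def note(model_id, stratum, y, pred, scores=None):
        m = compute_metrics(y, pred, stratum=stratum, model_id=model_id)
        rec = vars(m).copy()
        if scores is not None and len(np.unique(y)) == 2:
            points, auc = roc_points(y, scores)
            rec["auc"] = auc
            safe = model_id.replace("/", "-")
            points.to_csv(metrics_dir / f"roc_{safe}_{stratum}.csv",
                          index=False)
        records.append(rec)
        slot = pooled.setdefault(model_id, {"y": [], "pred": []})
        slot["y"].append(np.asarray(y))
        slot["pred"].append(np.asarray(pred))

    for stratum in _MODEL_STRATA:
        tr, te = select_stratum(train, stratum), select_stratum(test, stratum)
        y_te = te["hypoalbuminemia"].to_numpy(int)

        model = fit_mggf(tr, panel_spec, cfg.mggf)
        model.to_json(models_dir / f"mggf_{stratum}.json")
        scores, pred = predict_mggf(model, te)
        note("mggf", stratum, y_te, pred, scores)

        for kind in BASELINE_KINDS:
            for panel in list(PANEL_ORDER) + ["all"]:
                spec = BaselineSpec(kind=kind, panel=panel,
                                    C=cfg.baseline_C,
                                    max_depth=cfg.baseline_max_depth,
                                    seed=cfg.mggf.seed)
                b = fit_baseline(tr, spec, panel_spec)
                model_id = (f"ef-{kind}" if panel == "all"
                            else f"{kind}/{panel}")
                note(model_id, stratum, y_te, b.predict(te),
                     b.decision_scores(te))

    for model_id, slot in pooled.items():
        y = np.concatenate(slot["y"])
        pred = np.concatenate(slot["pred"])
        m = compute_metrics(y, pred, stratum="overall", model_id=model_id)
        records.append(vars(m).copy())

    frame = pd.DataFrame(records)
    frame.to_csv(metrics_dir / "metrics.csv", index=False)
    return frame


def run_study(config: RunConfig, out_dir) -> Path:
    """Run the whole synthetic study and return the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        config.to_yaml(out / "config.yaml")
        panel_spec = PanelSpec.default()

        cohort = _stage("simulate")(generate_cohort)(config.cohort,
                                                     panel_spec)
        write_cohort(cohort, out / "cohort.csv")

        std, _ = standardize(cohort, panel_spec)
        augmented = _stage("augment")(augment)(std, config.augment,
                                               panel_spec)
        write_cohort(augmented, out / "augmented.csv")

        _run_stats(cohort, panel_spec, config, out)

        train, test = _stage("split")(split_train_test)(
            augmented, config.split_ratio, config.split_seed,
            by_source=config.split_by_source)

        _stage("evaluate")(_evaluate_models)(train, test, panel_spec,
                                             config, out)

        sweep_frames = []
        for stratum in _MODEL_STRATA:
            frame, mi_order = _stage("sweep")(order_sweep)(
                select_stratum(train, stratum),
                select_stratum(test, stratum), panel_spec, config.mggf)
            frame.insert(0, "stratum", stratum)
            sweep_frames.append(frame)
            log.info("MI order (%s): %s", stratum, ">".join(mi_order))
        pd.concat(sweep_frames, ignore_index=True).to_csv(
            out / "sweep.csv", index=False)

        sens = _stage("sensitivity")(sensitivity_analysis)(
            train, test, panel_spec, config.mggf)
        sens.to_csv(out / "sensitivity.csv", index=False)
        for stratum in ("PWH", "NPWH"):
            log.info("max accuracy drop (%s): %s", stratum,
                     max_drop_panel(sens, stratum))
        return out
    finally:
        log.removeHandler(handler)
        handler.close()
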
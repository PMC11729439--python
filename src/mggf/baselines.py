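"""Classical comparison models and the train/test split.

Single-panel baselines (linear SVM, RBF SVM, Gini decision tree capped at
depth 4) train on one examination panel only; early-fusion (EF) variants
concatenate all 19 features into one model. Every baseline exposes the
same score/label predict contract as the gradual-fusion model so the
evaluation module is model-agnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .panels import PanelSpec

#: early-fusion aliases map onto a base kind with panel scope "all"
_EF_PREFIX = "early-fusion-"
BASE_KINDS = ("svm-linear", "svm-rbf", "decision-tree", "logistic")


class BaselineError(ValueError):
    pass


@dataclass
class BaselineSpec:
    kind: str = "svm-rbf"
    panel: str = "all"        # a panel name or "all"
    C: float = 1.0
    max_depth: int = 4
    seed: int = 0

    def resolve(self) -> tuple[str, str]:
        kind, panel = self.kind, self.panel
        if kind.startswith(_EF_PREFIX):
            kind, panel = kind[len(_EF_PREFIX):], "all"
        if kind == "tree":
            kind = "decision-tree"
        if kind not in BASE_KINDS:
            raise BaselineError(f"unknown baseline kind {self.kind!r}")
        if kind == "decision-tree" and self.max_depth > 4:
            raise BaselineError("decision-tree max depth must be <= 4")
        return kind, panel


@dataclass
class BaselineModel:
    spec: BaselineSpec
    features: list[str]
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    estimator: object

    def _matrix(self, table: pd.DataFrame) -> np.ndarray:
        for f in self.features:
            if f not in table.columns:
                raise BaselineError(f"missing feature column {f!r}")
        X = table[self.features].to_numpy(float)
        return (X - self.scaler_mean) / self.scaler_sd

    def decision_scores(self, table: pd.DataFrame) -> np.ndarray:
        """Continuous score increasing with the positive class."""
        X = self._matrix(table)
        if hasattr(self.estimator, "decision_function"):
            return np.asarray(self.estimator.decision_function(X), float)
        return np.asarray(self.estimator.predict_proba(X)[:, 1], float)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.estimator.predict(self._matrix(table)), int)


def fit_baseline(train: pd.DataFrame, spec: BaselineSpec,
                 panel_spec: PanelSpec | None = None) -> BaselineModel:
    """Fit one comparison classifier on the hypoalbuminemia label."""
    panel_spec = panel_spec or PanelSpec.default()
    kind, panel = spec.resolve()
    features = (panel_spec.features() if panel == "all"
                else list(panel_spec.panels[panel]))
    y = train["hypoalbuminemia"].to_numpy(int)
    if len(np.unique(y)) < 2:
        raise BaselineError("training labels contain a single class")
    X = train[features].to_numpy(float)
    mean, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xs = (X - mean) / sd
    if kind == "svm-linear":
        est = SVC(kernel="linear", C=spec.C, random_state=spec.seed)
    elif kind == "svm-rbf":
        est = SVC(kernel="rbf", C=spec.C, gamma="scale",
                  random_state=spec.seed)
    elif kind == "decision-tree":
        est = DecisionTreeClassifier(criterion="gini",
                                     max_depth=spec.max_depth,
                                     random_state=spec.seed)
    else:  # logistic — sanity baseline, not part of the comparison suite
        est = LogisticRegression(C=spec.C, max_iter=5000)
    est.fit(Xs, y)
    return BaselineModel(spec=spec, features=features, scaler_mean=mean,
                         scaler_sd=sd, estimator=est)


def split_train_test(table: pd.DataFrame, ratio: float = 0.2,
                     seed: int = 0, stratify: bool = True,
                     by_source: bool = False
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint train/test partition, test fraction ``ratio``.

    Stratified on the (pneumonia, hypoalbuminemia) subgroup; if any
    subgroup is too small to stratify, falls back to hypoalbuminemia-only
    stratification with a warning.

    With ``by_source=True`` (strict mode for augmented tables) the split
    is made over source patients, and every noisy copy follows its source
    row, so no patient contributes to both sides. Sizes then match the
    ratio only approximately, at source-patient granularity.
    """
    if not 0 < ratio < 1:
        raise BaselineError(f"ratio must be in (0, 1), got {ratio}")
    if by_source:
        key = "source_id" if "source_id" in table.columns else "patient_id"
        sources = table.drop_duplicates(key)
        tr_src, te_src = split_train_test(sources, ratio, seed, stratify)
        te_ids = set(te_src[key])
        mask = table[key].isin(te_ids)
        return (table[~mask].reset_index(drop=True),
                table[mask].reset_index(drop=True))
    strat = None
    if stratify:
        combo = (table["pneumonia"].astype(str) + "/"
                 + table["hypoalbuminemia"].astype(str))
        if combo.value_counts().min() >= 2:
            strat = combo
        else:
            warnings.warn("a (pneumonia, hypoalbuminemia) subgroup is too "
                          "small to stratify; stratifying on "
                          "hypoalbuminemia only", RuntimeWarning,
                          stacklevel=2)
            strat = table["hypoalbuminemia"]
    train, test = train_test_split(table, test_size=ratio,
                                   random_state=seed, stratify=strat)
    return (train.reset_index(drop=True), test.reset_index(drop=True))
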
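"""JSON-serializable regression submodels for the gradual-fusion steps.

Every step of the fusion pipeline fits a regressor so that residuals
compose additively: ordinary least squares (the linear candidate), a
depth-limited regression tree, or an RBF support-vector regressor. Fits go
through scikit-learn; the fitted parameters are extracted into plain
dictionaries so a model document round-trips through JSON, and prediction
is re-evaluated from those arrays.
"""

from __future__ import annotations

import numpy as np
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

SUBMODEL_KINDS = ("linear", "tree", "svr-rbf")


def fit_submodel(kind: str, X: np.ndarray, y: np.ndarray,
                 seed: int = 0, max_depth: int = 4) -> dict:
    """Fit one submodel and return its JSON-serializable parameter dict."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if kind == "linear":
        A = np.column_stack([X, np.ones(len(X))])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        return {"kind": "linear",
                "coef": beta[:-1].tolist(),
                "intercept": float(beta[-1])}
    if kind == "tree":
        tree = DecisionTreeRegressor(max_depth=max_depth, random_state=seed)
        tree.fit(X, y)
        t = tree.tree_
        return {"kind": "tree",
                "children_left": t.children_left.tolist(),
                "children_right": t.children_right.tolist(),
                "feature": t.feature.tolist(),
                "threshold": t.threshold.tolist(),
                "value": t.value.reshape(-1).tolist()}
    if kind == "svr-rbf":
        svr = SVR(kernel="rbf")  # gamma='scale', C=1.0
        svr.fit(X, y)
        return {"kind": "svr-rbf",
                "support_vectors": svr.support_vectors_.tolist(),
                "dual_coef": svr.dual_coef_.reshape(-1).tolist(),
                "intercept": float(svr.intercept_[0]),
                "gamma": float(svr._gamma)}
    raise ValueError(f"unknown submodel kind {kind!r}; "
                     f"expected one of {SUBMODEL_KINDS}")


def predict_submodel(params: dict, X: np.ndarray) -> np.ndarray:
    """Evaluate a fitted submodel from its parameter dict."""
    X = np.asarray(X, float)
    kind = params["kind"]
    if kind == "linear":
        return X @ np.asarray(params["coef"]) + params["intercept"]
    if kind == "tree":
        left = np.asarray(params["children_left"])
        right = np.asarray(params["children_right"])
        feat = np.asarray(params["feature"])
        thr = np.asarray(params["threshold"])
        value = np.asarray(params["value"])
        out = np.empty(len(X))
        for i, row in enumerate(X):
            node = 0
            while left[node] != -1:  # -1 marks a leaf
                node = left[node] if row[feat[node]] <= thr[node] \
                    else right[node]
            out[i] = value[node]
        return out
    if kind == "svr-rbf":
        # an empty support set (all targets within epsilon) loses its 2-D
        # shape through JSON; restore it so prediction is the intercept
        sv = np.asarray(params["support_vectors"], float).reshape(
            -1, X.shape[1])
        dual = np.asarray(params["dual_coef"])
        gamma = params["gamma"]
        sq = ((X[:, None, :] - sv[None, :, :]) ** 2).sum(axis=-1)
        return np.exp(-gamma * sq) @ dual + params["intercept"]
    raise ValueError(f"unknown submodel kind {kind!r}")
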
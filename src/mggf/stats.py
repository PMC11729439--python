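"""Group-difference statistics for the hypoalbuminemia cohort.

Implements the descriptive comparison suite run before modelling:
pooled-variance Student t-tests with standardized mean differences
(Cohen's d, hypoalbuminemia minus non-hypoalbuminemia), panel-averaged
logistic-regression weights, a Pearson correlation matrix, and a Mantel
permutation test between a feature-distance matrix and a label-distance
matrix.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression

from .panels import PANEL_ORDER, PanelSpec

STRATA = ("pneumonia", "non-pneumonia", "all")


class StatsError(ValueError):
    pass


def select_stratum(table: pd.DataFrame, stratum: str) -> pd.DataFrame:
    """Rows of one pneumonia stratum ('pneumonia', 'non-pneumonia' or 'all')."""
    if stratum == "all":
        return table
    if stratum == "pneumonia":
        return table[table["pneumonia"] == 1]
    if stratum == "non-pneumonia":
        return table[table["pneumonia"] == 0]
    raise StatsError(f"unknown stratum {stratum!r}")


def significance_band(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class DiffResult:
    feature: str
    stratum: str
    smd: float
    t_stat: float
    p_value: float
    band: str


def ttest_by_label(table: pd.DataFrame, feature: str,
                   stratum: str = "all", welch: bool = False) -> DiffResult:
    """Two-sided t-test of a feature between hypo- and non-hypoalbuminemia.

    SMD is Cohen's d with pooled sd, signed hypo minus non-hypo. The
    pooled-variance Student test is the default; Welch is available via
    ``welch=True``.
    """
    sub = select_stratum(table, stratum)
    x1 = sub.loc[sub["hypoalbuminemia"] == 1, feature].to_numpy(float)
    x0 = sub.loc[sub["hypoalbuminemia"] == 0, feature].to_numpy(float)
    if len(x1) < 2 or len(x0) < 2:
        raise StatsError(
            f"insufficient data for {feature!r} in stratum {stratum!r}: "
            f"group sizes {len(x1)}/{len(x0)}")
    t, p = sps.ttest_ind(x1, x0, equal_var=not welch)
    n1, n0 = len(x1), len(x0)
    pooled_var = (((n1 - 1) * x1.var(ddof=1) + (n0 - 1) * x0.var(ddof=1))
                  / (n1 + n0 - 2))
    if pooled_var == 0:
        smd = 0.0
    else:
        smd = (x1.mean() - x0.mean()) / np.sqrt(pooled_var)
    return DiffResult(feature=feature, stratum=stratum, smd=float(smd),
                      t_stat=float(t), p_value=float(p),
                      band=significance_band(float(p)))


def diff_table(table: pd.DataFrame, panel_spec: PanelSpec,
               stratum: str = "all") -> pd.DataFrame:
    """Tidy frame of :func:`ttest_by_label` over every panel feature."""
    rows = [ttest_by_label(table, f, stratum) for f in panel_spec.features()]
    return pd.DataFrame([vars(r) for r in rows])


@dataclass
class WeightResult:
    stratum: str
    feature_weights: dict[str, float]   # |standardized logistic coefficient|
    panel_weights: dict[str, float]     # mean of member |coefficients|
    separation_warning: bool


def logistic_panel_weights(table: pd.DataFrame, stratum: str,
                           panel_spec: PanelSpec | None = None,
                           C: float = 1.0) -> WeightResult:
    """Panel importance from a single multivariable logistic regression.

    Features are standardized within the stratum, the hypoalbuminemia label
    is regressed on all of them with a weak L2 ridge (strength ``1/C``),
    and each panel's weight is the mean absolute coefficient of its member
    features. A separation warning is raised when the regularized fit
    classifies the training stratum perfectly.
    """
    panel_spec = panel_spec or PanelSpec.default()
    sub = select_stratum(table, stratum)
    y = sub["hypoalbuminemia"].to_numpy(int)
    if len(np.unique(y)) < 2:
        raise StatsError(f"both labels required in stratum {stratum!r}")
    X = sub[panel_spec.features()].to_numpy(float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    model = LogisticRegression(C=C, solver="lbfgs", max_iter=5000)
    model.fit(X, y)
    coefs = np.abs(model.coef_.ravel())
    feature_weights = dict(zip(panel_spec.features(), map(float, coefs)))
    panel_weights = {
        name: float(np.mean([feature_weights[f]
                             for f in panel_spec.panels[name]]))
        for name in PANEL_ORDER}
    separated = bool((model.predict(X) == y).all())
    return WeightResult(stratum=stratum, feature_weights=feature_weights,
                        panel_weights=panel_weights,
                        separation_warning=separated)


def pearson_matrix(table: pd.DataFrame, features: list[str]) -> pd.DataFrame:
    """Pearson correlations between features; zero-variance entries are NaN."""
    if len(table) < 3:
        raise StatsError("pearson_matrix requires at least 3 rows")
    sub = table[features]
    degenerate = [f for f in features if sub[f].std(ddof=0) == 0]
    if degenerate:
        warnings.warn(f"zero-variance features, correlations undefined (NaN): "
                      f"{degenerate}", RuntimeWarning, stacklevel=2)
    return sub.corr(method="pearson")


def _check_distance_matrix(d: np.ndarray, name: str) -> np.ndarray:
    d = np.asarray(d, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise StatsError(f"{name} is not square")
    if not np.allclose(d, d.T):
        raise StatsError(f"{name} is not symmetric")
    if not np.allclose(np.diag(d), 0):
        raise StatsError(f"{name} has a nonzero diagonal")
    return d


def mantel_test(dist_a: np.ndarray, dist_b: np.ndarray,
                n_perm: int = 999, seed: int = 0,
                exhaustive: bool = False) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    The statistic is the Pearson correlation of the strict upper triangles.
    The one-sided (greater) p-value is computed over row/column
    permutations of ``dist_b``: either ``n_perm`` random permutations with
    the observed statistic included in the null set, giving
    ``p = (1 + #{r_perm >= r_obs}) / (n_perm + 1)``, or, with
    ``exhaustive=True``, all n! permutations (identity included), giving
    ``p = #{r_perm >= r_obs} / n!``.
    """
    a = _check_distance_matrix(dist_a, "dist_a")
    b = _check_distance_matrix(dist_b, "dist_b")
    if a.shape != b.shape:
        raise StatsError(f"size mismatch: {a.shape} vs {b.shape}")
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)

    def corr(m: np.ndarray) -> float:
        return float(np.corrcoef(a[iu], m[iu])[0, 1])

    r_obs = corr(b)
    if exhaustive:
        perms = itertools.permutations(range(n))
        count = total = 0
        for perm in perms:
            p_idx = np.array(perm)
            r = corr(b[np.ix_(p_idx, p_idx)])
            count += r >= r_obs - 1e-12
            total += 1
        return r_obs, count / total

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p_idx = rng.permutation(n)
        count += corr(b[np.ix_(p_idx, p_idx)]) >= r_obs - 1e-12
    return r_obs, (1 + count) / (n_perm + 1)


def label_distance_matrix(labels: np.ndarray) -> np.ndarray:
    """Pairwise 0/1 mismatch distance for a binary label vector."""
    y = np.asarray(labels).reshape(-1, 1)
    return (y != y.T).astype(float)


def feature_distance_matrix(table: pd.DataFrame,
                            features: list[str]) -> np.ndarray:
    """Euclidean distances on standardized features."""
    X = table[features].to_numpy(float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    diff = X[:, None, :] - X[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))
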
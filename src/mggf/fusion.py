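"""The gradual-fusion classifier (MGGF).

The model consumes the four examination panels one at a time. Panels are
ordered by the average mutual information between their (discretized)
member features and the hypoalbuminemia label. The first step fits a
regressor of the first panel's features to the 0/1 label; each later step
fits a regressor of the next panel's features to the residual left by the
cumulative score so far, and adds its prediction to that score, scaled by
a squared-error line-search multiplier so the training fit never degrades. Which
regressor a step uses — linear least squares or a nonlinear candidate —
is decided by the average grey relational grade (Deng's coefficient with
distinguishing coefficient rho) between the step's target sequence and
the panel's features: a high grade indicates the target tracks the
features closely enough for a linear fit. The final classification
thresholds the 4-step cumulative score at 0.5.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panels import PANEL_ORDER, PanelSpec
from .submodels import fit_submodel, predict_submodel


class FusionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Mutual information

@dataclass
class MiEstimate:
    feature: str
    mi: float       # bits
    n_bins: int     # bins actually used after merging duplicate edges


def _bin_feature(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency discretization; tied values share a bin."""
    edges = np.unique(np.quantile(x, np.arange(1, n_bins) / n_bins))
    return np.searchsorted(edges, x, side="left")


def mutual_information(feature: np.ndarray, label: np.ndarray,
                       n_bins: int = 10, name: str = "") -> MiEstimate:
    """Plug-in mutual information (bits) between a binned feature and a
    binary label.

    The feature is discretized into ``n_bins`` equal-frequency bins and
    MI = sum over observed cells of p(b,y) log2[p(b,y)/(p(b)p(y))].
    A constant feature yields MI = 0 with a warning.
    """
    x = np.asarray(feature, float)
    y = np.asarray(label)
    if len(x) != len(y):
        raise FusionError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < n_bins:
        raise FusionError(f"need at least n_bins={n_bins} samples, "
                          f"got {len(x)}")
    if not np.isin(y, (0, 1)).all():
        raise FusionError("label must be binary 0/1")
    if np.ptp(x) == 0:
        warnings.warn(f"constant feature {name!r}: MI set to 0",
                      RuntimeWarning, stacklevel=2)
        return MiEstimate(feature=name, mi=0.0, n_bins=1)
    bins = _bin_feature(x, n_bins)
    joint = pd.crosstab(bins, y).to_numpy(float)
    joint /= joint.sum()
    pb = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    mi = float((joint[mask] * np.log2(joint[mask]
                                      / (pb @ py)[mask])).sum())
    return MiEstimate(feature=name, mi=max(mi, 0.0),
                      n_bins=joint.shape[0])


def effective_n_bins(n: int, n_bins: int) -> int:
    """Shrink the bin count to floor(sqrt(n)) on small samples (n < 100)."""
    return min(n_bins, int(np.sqrt(n))) if n < 100 else n_bins


def rank_panels_by_mi(table: pd.DataFrame, panel_spec: PanelSpec,
                      n_bins: int = 10,
                      panels: tuple[str, ...] | None = None) -> list[str]:
    """Panels sorted by descending mean member-feature MI with the label.

    Ties break by the canonical panel order VS, NTproBNP, BRE, URE.
    ``panels`` restricts the ranking to a subset (used by the
    leave-one-panel-out analysis).
    """
    panels = panels or PANEL_ORDER
    y = table["hypoalbuminemia"].to_numpy(int)
    nb = effective_n_bins(len(table), n_bins)
    means = {}
    for name in panels:
        ests = [mutual_information(table[f].to_numpy(float), y, nb, name=f)
                for f in panel_spec.panels[name]]
        means[name] = float(np.mean([e.mi for e in ests]))
    return sorted(panels, key=lambda p: (-means[p], PANEL_ORDER.index(p)))


# ---------------------------------------------------------------------------
# Grey relational analysis

@dataclass
class GrcResult:
    reference: str
    comparison: str
    rho: float
    coefficients: np.ndarray
    grade: float


def _minmax(x: np.ndarray) -> np.ndarray:
    rng = np.ptp(x)
    if rng == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.min()) / rng


def grey_relational(reference: np.ndarray, comparison: np.ndarray,
                    rho: float = 0.5, ref_name: str = "reference",
                    cmp_name: str = "comparison") -> GrcResult:
    """Deng's grey relational coefficient between two sequences.

    Both sequences are min-max normalized to [0,1] (each by its own
    range). With pointwise deviations D(k) = |x0(k) - xi(k)| and Dmin/Dmax
    taken over all k, coefficient(k) = (Dmin + rho*Dmax) / (D(k) +
    rho*Dmax); the grade is their mean. Identical sequences give all
    coefficients 1.
    """
    if not 0 < rho <= 1:
        raise FusionError(f"rho must be in (0, 1], got {rho}")
    x0 = np.asarray(reference, float)
    xi = np.asarray(comparison, float)
    if x0.shape != xi.shape:
        raise FusionError("sequence length mismatch")
    d = np.abs(_minmax(x0) - _minmax(xi))
    dmin, dmax = d.min(), d.max()
    if dmax == 0:
        coef = np.ones_like(d)
    else:
        coef = (dmin + rho * dmax) / (d + rho * dmax)
    return GrcResult(reference=ref_name, comparison=cmp_name, rho=rho,
                     coefficients=coef, grade=float(coef.mean()))


def select_submodel(residual: np.ndarray, panel_features: pd.DataFrame,
                    rho: float = 0.5, tau: float = 0.75,
                    nonlinear: str = "tree") -> tuple[str, float]:
    """Pick a step's regressor from the grey relational grade.

    The mean grade between the target sequence (reference) and each
    feature column decides the candidate: grade >= tau selects the linear
    least-squares submodel, otherwise the nonlinear candidate. Returns
    (submodel kind, mean grade).
    """
    if panel_features.shape[1] == 0:
        raise FusionError("empty panel")
    grades = [grey_relational(residual, panel_features[c].to_numpy(float),
                              rho, cmp_name=c).grade
              for c in panel_features.columns]
    grade = float(np.mean(grades))
    return ("linear" if grade >= tau else nonlinear), grade


# ---------------------------------------------------------------------------
# Model fitting

@dataclass
class MggfConfig:
    n_bins: int = 10
    rho: float = 0.5
    tau: float = 0.75
    threshold: float = 0.5
    nonlinear: str = "svr-rbf"  # nonlinear candidate: "svr-rbf" or "tree"
    max_depth: int = 4        # regression-tree depth cap
    seed: int = 0


@dataclass
class MggfStep:
    panel: str
    features: list[str]
    kind: str
    grade: float
    params: dict
    gamma: float = 1.0  # line-search multiplier on the step's contribution


@dataclass
class MggfModel:
    panel_order: list[str]
    steps: list[MggfStep]
    scaler_mean: dict[str, float]
    scaler_sd: dict[str, float]
    threshold: float
    config: dict
    train_scores: np.ndarray | None = field(default=None, repr=False)

    def to_json(self, path=None) -> str:
        doc = {
            "panel_order": self.panel_order,
            "steps": [{"panel": s.panel, "features": s.features,
                       "kind": s.kind, "grade": s.grade,
                       "gamma": s.gamma, "params": s.params}
                      for s in self.steps],
            "scaler_mean": self.scaler_mean,
            "scaler_sd": self.scaler_sd,
            "threshold": self.threshold,
            "config": self.config,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "MggfModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        steps = [MggfStep(panel=s["panel"], features=s["features"],
                          kind=s["kind"], grade=s["grade"],
                          gamma=s.get("gamma", 1.0),
                          params=s["params"]) for s in doc["steps"]]
        return cls(panel_order=doc["panel_order"], steps=steps,
                   scaler_mean=doc["scaler_mean"],
                   scaler_sd=doc["scaler_sd"],
                   threshold=doc["threshold"], config=doc["config"])


def _scale(table: pd.DataFrame, features: list[str],
           mean: dict, sd: dict) -> pd.DataFrame:
    out = pd.DataFrame(index=table.index)
    for f in features:
        if f not in table.columns:
            raise FusionError(f"missing feature column {f!r}")
        out[f] = (table[f].to_numpy(float) - mean[f]) / sd[f]
    return out


def fit_mggf(train: pd.DataFrame, panel_spec: PanelSpec | None = None,
             config: MggfConfig | None = None,
             panel_order: list[str] | None = None) -> MggfModel:
    """Fit the gradual-fusion model.

    Panels are ranked by mean mutual information with the label on the
    training table (or an explicit ``panel_order`` is imposed, as in the
    order sweep). The cumulative score starts at 0, so step k's target is
    the residual y - s_{k-1}; step 1 therefore regresses on the label
    itself. Each step's regressor kind is chosen by the grey relational
    grade of its target against the panel's features. Features are
    z-scored on the training table and the scaler is stored in the model.
    """
    panel_spec = panel_spec or PanelSpec.default()
    config = config or MggfConfig()
    y = train["hypoalbuminemia"].to_numpy(int)
    if len(np.unique(y)) < 2:
        raise FusionError("training labels contain a single class")

    if panel_order is not None:
        if (len(set(panel_order)) != len(panel_order)
                or not set(panel_order) <= set(PANEL_ORDER)):
            raise FusionError(f"invalid panel order {panel_order}")
        order = list(panel_order)
    else:
        order = rank_panels_by_mi(train, panel_spec, config.n_bins)

    feats = [f for p in order for f in panel_spec.panels[p]]
    mean = {f: float(train[f].mean()) for f in feats}
    sd = {f: float(train[f].std(ddof=0)) for f in feats}
    for f, s in sd.items():
        if s == 0:
            sd[f] = 1.0  # constant feature carries no signal; leave centered
    X = _scale(train, feats, mean, sd)

    score = np.zeros(len(train), float)
    steps = []
    for panel in order:
        cols = list(panel_spec.panels[panel])
        target = y - score
        kind, grade = select_submodel(target, X[cols], config.rho,
                                      config.tau, config.nonlinear)
        params = fit_submodel(kind, X[cols].to_numpy(), target,
                              seed=config.seed, max_depth=config.max_depth)
        pred = predict_submodel(params, X[cols].to_numpy())
        # line-search multiplier (stagewise additive modelling): optimal
        # for squared error along the step's prediction, so the training
        # SSE never increases; equals 1 exactly for least-squares and
        # regression-tree steps
        denom = float(pred @ pred)
        gamma = float(target @ pred) / denom if denom > 0 else 0.0
        score = score + gamma * pred
        steps.append(MggfStep(panel=panel, features=cols, kind=kind,
                              grade=grade, params=params, gamma=gamma))

    return MggfModel(panel_order=order, steps=steps, scaler_mean=mean,
                     scaler_sd=sd, threshold=config.threshold,
                     config=vars(config).copy(), train_scores=score)


def predict_mggf(model: MggfModel,
                 table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative fusion score and thresholded 0/1 label for each row."""
    feats = [f for s in model.steps for f in s.features]
    X = _scale(table, feats, model.scaler_mean, model.scaler_sd)
    score = np.zeros(len(table), float)
    for step in model.steps:
        score = score + step.gamma * predict_submodel(
            step.params, X[step.features].to_numpy())
    return score, (score >= model.threshold).astype(int)
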
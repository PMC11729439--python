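"""Copy-and-noise data enhancement for the small admission cohort.

The recipe: standardize the feature columns, duplicate every patient a
fixed number of times with additive Gaussian noise on the standardized
features, then subsample each diagnostic subgroup without replacement to
target counts. With the study's cohort (21/15/21/61) and two noisy copies,
the hypoalbuminemia strata are kept in full (63 PHP, 45 NPHP -> 108
hypoalbuminemia rows) and the non-hypoalbuminemia strata are subsampled to
55 PNHP and 53 NPNHP, balancing the classes at 108 apiece.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import SUBGROUPS, subgroup_of
from .panels import PanelSpec


class AugmentError(ValueError):
    """Invalid augmentation request."""


#: Default per-subgroup counts after subsampling (the balanced-class design).
DEFAULT_TARGET_COUNTS: dict[str, int] = {
    "PHP": 63, "NPHP": 45, "PNHP": 55, "NPNHP": 53,
}


@dataclass
class ScalerParams:
    """Per-feature mean and (population, ddof=0) standard deviation."""

    mean: dict[str, float]
    sd: dict[str, float]


@dataclass
class AugmentSpec:
    n_copies: int = 2
    noise_sd: float = 0.1  # on standardized (unit-variance) features
    target_counts: dict[str, int] | None = field(
        default_factory=lambda: dict(DEFAULT_TARGET_COUNTS))
    seed: int = 0

    def validate(self) -> None:
        if self.n_copies < 0:
            raise AugmentError(f"n_copies must be >= 0, got {self.n_copies}")
        if self.noise_sd < 0:
            raise AugmentError(f"noise_sd must be >= 0, got {self.noise_sd}")


def standardize(table: pd.DataFrame,
                panel_spec: PanelSpec | None = None
                ) -> tuple[pd.DataFrame, ScalerParams]:
    """Z-score the feature columns (population sd, ddof=0).

    Returns the transformed table and the scaler parameters needed to
    invert the transform. Raises on a zero-variance feature, naming it.
    """
    panel_spec = panel_spec or PanelSpec.default()
    if len(table) < 2:
        raise AugmentError("standardize requires at least 2 rows")
    out = table.copy()
    mean, sd = {}, {}
    for feat in panel_spec.features():
        m = float(out[feat].mean())
        s = float(out[feat].std(ddof=0))
        if s == 0:
            raise AugmentError(f"zero-variance feature {feat!r}")
        out[feat] = (out[feat] - m) / s
        mean[feat], sd[feat] = m, s
    return out, ScalerParams(mean=mean, sd=sd)


def inverse_standardize(table: pd.DataFrame,
                        params: ScalerParams) -> pd.DataFrame:
    out = table.copy()
    for feat, m in params.mean.items():
        out[feat] = out[feat] * params.sd[feat] + m
    return out


def augment(table: pd.DataFrame, spec: AugmentSpec,
            panel_spec: PanelSpec | None = None) -> pd.DataFrame:
    """Originals plus noisy copies, optionally subsampled per subgroup.

    Copies inherit all label and demographic columns from their source row;
    Gaussian noise with sd ``spec.noise_sd`` is added to the feature columns
    only. Provenance is recorded in ``source_id`` (the source patient_id;
    equal to ``patient_id`` for originals) and ``copy_idx`` (0 for
    originals). Deterministic given ``spec.seed``.
    """
    panel_spec = panel_spec or PanelSpec.default()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    feats = panel_spec.features()

    base = table.copy()
    base["source_id"] = base["patient_id"]
    base["copy_idx"] = 0
    pool = [base]
    next_id = int(table["patient_id"].max()) + 1 if len(table) else 0
    for k in range(1, spec.n_copies + 1):
        copy = table.copy()
        copy["source_id"] = copy["patient_id"]
        copy["copy_idx"] = k
        copy["patient_id"] = np.arange(next_id, next_id + len(copy))
        next_id += len(copy)
        noise = rng.normal(0.0, spec.noise_sd, size=(len(copy), len(feats)))
        copy[feats] = copy[feats].to_numpy() + noise
        pool.append(copy)
    pooled = pd.concat(pool, ignore_index=True)

    if spec.target_counts is None:
        return pooled

    groups = subgroup_of(pooled)
    kept = []
    for name in SUBGROUPS:
        idx = pooled.index[groups == name].to_numpy()
        target = spec.target_counts.get(name, len(idx))
        if target > len(idx):
            raise AugmentError(
                f"target count {target} for subgroup {name} exceeds "
                f"available pool of {len(idx)}")
        if target < len(idx):
            idx = np.sort(rng.choice(idx, size=target, replace=False))
        kept.append(pooled.loc[idx])
    return pd.concat(kept, ignore_index=True)
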
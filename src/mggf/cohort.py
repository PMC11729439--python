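"""Synthetic patient-cohort generation and cohort CSV I/O.

The generator emulates a geriatric admission cohort split into four
diagnostic subgroups crossing pneumonia with hypoalbuminemia:

* PHP   — pneumonia with hypoalbuminemia
* NPHP  — non-pneumonia with hypoalbuminemia
* PNHP  — pneumonia, non-hypoalbuminemia
* NPNHP — neither pneumonia nor hypoalbuminemia

Hypoalbuminemia is defined as serum albumin below 30 g/L; the albumin
column is drawn from stratum-specific truncated normals so the label is
consistent with the threshold by construction. Effects are placed
pneumonia-conditionally: blood-routine (BRE) features are shifted only in
the PHP stratum and urine-routine (URE) features only in the NPHP stratum,
so each pneumonia stratum carries a different discriminative panel.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .panels import PanelSpec

#: Albumin threshold (g/L) below which hypoalbuminemia is diagnosed.
ALBUMIN_THRESHOLD = 30.0

SUBGROUPS = ("PHP", "NPHP", "PNHP", "NPNHP")

#: (pneumonia, hypoalbuminemia) coding of each subgroup.
SUBGROUP_LABELS = {
    "PHP": (1, 1), "NPHP": (0, 1), "PNHP": (1, 0), "NPNHP": (0, 0),
}

LABEL_COLUMNS = ("pneumonia", "hypoalbuminemia")
META_COLUMNS = ("patient_id", "pneumonia", "hypoalbuminemia",
                "albumin", "age", "sex")


class CohortParameterError(ValueError):
    """Invalid cohort-generation parameters."""


class CohortFormatError(ValueError):
    """A cohort CSV violates the table contract."""


def load_reference_baselines() -> dict[str, tuple[float, float]]:
    """Per-feature (mean, sd) in the healthy stratum, from the shipped config."""
    ref = importlib.resources.files("mggf").joinpath("reference_ranges.yaml")
    raw = yaml.safe_load(ref.read_text())
    return {name: (float(v["mean"]), float(v["sd"])) for name, v in raw.items()}


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions: subgroup sizes 21/15/21/61
    (118 patients), standardized effect sizes of 1.2 baseline-sd units on
    the discriminative panel of each pneumonia stratum, mean age
    78.37 +/- 8.57 years and 63/118 female.
    """

    n_php: int = 21
    n_nphp: int = 15
    n_pnhp: int = 21
    n_npnhp: int = 61
    effect_size_bre: float = 1.2
    effect_size_ure: float = 1.2
    albumin_hypo: tuple[float, float] = (26.0, 2.5)    # mean, sd g/L, < 30
    albumin_normal: tuple[float, float] = (38.0, 4.0)  # mean, sd g/L, >= 30
    age_mean: float = 78.37
    age_sd: float = 8.57
    age_range: tuple[float, float] = (60.0, 100.0)
    p_female: float = 63.0 / 118.0
    feature_baselines: dict[str, tuple[float, float]] | None = None
    seed: int = 0

    def counts(self) -> dict[str, int]:
        return {"PHP": self.n_php, "NPHP": self.n_nphp,
                "PNHP": self.n_pnhp, "NPNHP": self.n_npnhp}

    def validate(self, panel_spec: PanelSpec) -> dict[str, tuple[float, float]]:
        for name, n in self.counts().items():
            if n < 0:
                raise CohortParameterError(f"negative count for {name}: {n}")
        if not np.isfinite([self.effect_size_bre, self.effect_size_ure]).all():
            raise CohortParameterError("effect sizes must be finite")
        baselines = self.feature_baselines or load_reference_baselines()
        for feat in panel_spec.features():
            if feat not in baselines:
                raise CohortParameterError(f"no baseline for feature {feat!r}")
            _, sd = baselines[feat]
            if not sd > 0:
                raise CohortParameterError(f"non-positive sd for {feat!r}: {sd}")
        for label, (_, sd) in (("albumin_hypo", self.albumin_hypo),
                               ("albumin_normal", self.albumin_normal)):
            if not sd > 0:
                raise CohortParameterError(f"non-positive sd in {label}")
        return baselines


def _truncated_normal(rng, mean, sd, low, high, size):
    a, b = (low - mean) / sd, (high - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(spec: CohortSpec,
                    panel_spec: PanelSpec | None = None) -> pd.DataFrame:
    """Draw a synthetic patient table.

    Returns a DataFrame with columns ``patient_id, pneumonia,
    hypoalbuminemia, albumin, age, sex`` followed by the 19 panel features
    in canonical order. Deterministic given ``spec.seed``.
    """
    panel_spec = panel_spec or PanelSpec.default()
    baselines = spec.validate(panel_spec)
    rng = np.random.default_rng(spec.seed)

    frames = []
    next_id = 0
    for group in SUBGROUPS:
        n = spec.counts()[group]
        pneu, hypo = SUBGROUP_LABELS[group]
        alb_mean, alb_sd = spec.albumin_hypo if hypo else spec.albumin_normal
        lo, hi = ((10.0, ALBUMIN_THRESHOLD) if hypo
                  else (ALBUMIN_THRESHOLD, 55.0))
        row = {
            "patient_id": np.arange(next_id, next_id + n),
            "pneumonia": np.full(n, pneu, dtype=int),
            "hypoalbuminemia": np.full(n, hypo, dtype=int),
            "albumin": _truncated_normal(rng, alb_mean, alb_sd, lo, hi, n),
            "age": _truncated_normal(rng, spec.age_mean, spec.age_sd,
                                     *spec.age_range, size=n),
            "sex": (rng.random(n) < spec.p_female).astype(int),  # 1 = female
        }
        next_id += n
        for feat in panel_spec.features():
            mean, sd = baselines[feat]
            shift = 0.0
            panel = panel_spec.panel_of(feat)
            if panel == "BRE" and group == "PHP":
                shift = spec.effect_size_bre * sd
            elif panel == "URE" and group == "NPHP":
                shift = spec.effect_size_ure * sd
            row[feat] = rng.normal(mean + shift, sd, size=n)
        frames.append(pd.DataFrame(row))

    table = pd.concat(frames, ignore_index=True)
    return table[list(META_COLUMNS) + panel_spec.features()]


def subgroup_of(table: pd.DataFrame) -> pd.Series:
    """Map each row to its diagnostic subgroup name."""
    inv = {v: k for k, v in SUBGROUP_LABELS.items()}
    return pd.Series(
        [inv[(int(p), int(h))]
         for p, h in zip(table["pneumonia"], table["hypoalbuminemia"])],
        index=table.index, name="subgroup")


def validate_table(table: pd.DataFrame, panel_spec: PanelSpec,
                   require_albumin_consistency: bool = True) -> None:
    """Check the cohort-table contract, raising :class:`CohortFormatError`."""
    if table.empty:
        raise CohortFormatError("cohort table is empty")
    for col in LABEL_COLUMNS:
        if col not in table.columns:
            raise CohortFormatError(f"missing label column {col!r}")
        if table[col].isna().any():
            raise CohortFormatError(f"missing values in label column {col!r}")
        bad = ~table[col].isin((0, 1))
        if bad.any():
            raise CohortFormatError(
                f"non-binary value in label column {col!r} "
                f"at row {int(table.index[bad][0])}")
    for feat in panel_spec.features():
        if feat not in table.columns:
            raise CohortFormatError(f"missing feature column {feat!r}")
        if not pd.api.types.is_numeric_dtype(table[feat]):
            raise CohortFormatError(f"non-numeric feature column {feat!r}")
    if require_albumin_consistency and "albumin" in table.columns:
        expected = (table["albumin"] < ALBUMIN_THRESHOLD).astype(int)
        mismatch = expected != table["hypoalbuminemia"].astype(int)
        if mismatch.any():
            row = int(table.index[mismatch][0])
            raise CohortFormatError(
                "hypoalbuminemia label inconsistent with albumin "
                f"< {ALBUMIN_THRESHOLD} g/L at row {row} "
                f"(albumin={table.loc[row, 'albumin']}, "
                f"label={table.loc[row, 'hypoalbuminemia']})")


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort table to CSV (UTF-8, header row, full precision)."""
    table.to_csv(path, index=False)


def read_cohort(path, panel_spec: PanelSpec | None = None) -> pd.DataFrame:
    """Read and validate a cohort CSV."""
    panel_spec = panel_spec or PanelSpec.default()
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise CohortFormatError(f"empty cohort file: {path}") from exc
    validate_table(table, panel_spec)
    return table
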
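"""Examination-panel metadata.

The four admission examination panels used throughout the package:
vital signs (VS), NT-proBNP, blood routine examination (BRE) and urine
routine examination (URE). Every feature belongs to exactly one panel,
and the panels are the units of fusion, ranking and ablation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

#: Canonical panel order, used for deterministic tie-breaking.
PANEL_ORDER: tuple[str, ...] = ("VS", "NTproBNP", "BRE", "URE")

_DEFAULT_PANELS: dict[str, tuple[str, ...]] = {
    "VS": ("RR", "SBP"),
    "NTproBNP": ("NT-proBNP",),
    "BRE": ("PLT", "RBC", "WBC", "RDW-CV", "RDW-SD",
            "MCHC", "MCH", "MCV", "HCT", "HB"),
    "URE": ("USG", "UPh", "UWBC", "URBC", "EQRWC", "EQWBC"),
}


class PanelSpecError(ValueError):
    """Invalid panel specification."""


@dataclass(frozen=True)
class PanelSpec:
    """Ordered grouping of feature names into the four examination panels.

    Parameters
    ----------
    panels
        Mapping from panel name to a tuple of feature (column) names.
        Panel names must be exactly ``VS, NTproBNP, BRE, URE`` and feature
        names must be unique across panels.
    """

    panels: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_PANELS))

    def __post_init__(self) -> None:
        if set(self.panels) != set(PANEL_ORDER):
            raise PanelSpecError(
                f"panel names must be exactly {PANEL_ORDER}, "
                f"got {tuple(self.panels)}")
        feats = self.features()
        if len(feats) != len(set(feats)):
            raise PanelSpecError("feature names must be unique across panels")

    def features(self) -> list[str]:
        """All feature names, in canonical panel order."""
        return [f for name in PANEL_ORDER for f in self.panels[name]]

    def panel_of(self, feature: str) -> str:
        for name, feats in self.panels.items():
            if feature in feats:
                return name
        raise KeyError(feature)

    @classmethod
    def default(cls) -> "PanelSpec":
        """The 19-feature specification of the four admission panels."""
        return cls()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: list(v) for k, v in self.panels.items()}, fh,
                           sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PanelSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls({k: tuple(v) for k, v in raw.items()})
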
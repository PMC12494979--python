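"""Marker panel definitions.

Three nested feature sets drive every feature-subset analysis:

* ``minimal`` — protein and phospho-protein targets that directly control
  cell-cycle checkpoints and progression (cyclins, licensing factors,
  proliferation markers, mitotic phospho-marks).
* ``core`` — minimal plus direct measurements of DNA content and replication
  (DNA intercalator channel, IdU incorporation).
* ``complete`` — core plus chromatin state, cell-size proxies, and broader
  cell-cycle regulators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError

PANEL_LEVELS = ("minimal", "core", "complete")

#: Default marker -> panel category. The union is the 17-feature diversity pool.
DEFAULT_PANEL_CATEGORIES: dict[str, str] = {
    "Ki67": "minimal",
    "pRbS780": "minimal",
    "pH3_s10": "minimal",
    "CDT1": "minimal",
    "Geminin": "minimal",
    "PLK1": "minimal",
    "CyclinB1": "minimal",
    "CyclinE": "minimal",
    "PCNA": "minimal",
    "SLBP": "minimal",
    "IdU": "core",
    "DNA": "core",
    "WGA": "complete",
    "HH3": "complete",
    "EZH2": "complete",
    "CTCF": "complete",
    "MLL1": "complete",
}


@dataclass
class PanelDefinition:
    """Marker -> category map with cumulative panel lookup."""

    categories: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_PANEL_CATEGORIES)
    )

    def __post_init__(self) -> None:
        bad = {m: c for m, c in self.categories.items() if c not in PANEL_LEVELS}
        if bad:
            raise ConfigurationError(f"unknown panel categories: {bad}")

    def markers(self, panel: str = "complete") -> list[str]:
        """Markers in the cumulative panel (minimal < core < complete)."""
        if panel not in PANEL_LEVELS:
            raise ConfigurationError(f"unknown panel {panel!r}")
        keep = PANEL_LEVELS[: PANEL_LEVELS.index(panel) + 1]
        return [m for m, c in self.categories.items() if c in keep]

    def exclusive_markers(self, panel: str) -> list[str]:
        """Markers introduced at exactly this panel level."""
        if panel not in PANEL_LEVELS:
            raise ConfigurationError(f"unknown panel {panel!r}")
        return [m for m, c in self.categories.items() if c == panel]

    @classmethod
    def from_table(cls, path) -> "PanelDefinition":
        """Load a delimited table with columns ``marker`` and ``category``."""
        df = pd.read_csv(path, sep=None, engine="python")
        if not {"marker", "category"} <= set(df.columns):
            raise ConfigurationError(
                "panel table needs 'marker' and 'category' columns"
            )
        return cls(dict(zip(df["marker"].astype(str), df["category"].astype(str))))


DEFAULT_PANEL = PanelDefinition()

#: The 17 markers used for the diversity analysis, in panel order.
DIVERSITY_FEATURES: tuple[str, ...] = tuple(DEFAULT_PANEL_CATEGORIES)
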
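"""Cell x channel expression container.

The :class:`ExpressionMatrix` is the substrate every stage operates on: a dense
``cells x channels`` array of ion-count intensities plus aligned per-cell
metadata. Intensities start on the raw (nonnegative count) scale and move
through a one-way chain of scale states: ``raw -> asinh -> normalized``. The
transforms applied along the way (asinh cofactor, per-channel percentile
divisors) are recorded in ``transform_info`` so that raw-scale gate positions
can be mapped onto the analysis scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, StateError

#: Cell-cycle phases, in progression order.
PHASES = ("G0G1", "S", "G2", "M")

_SCALE_ORDER = {"raw": 0, "asinh": 1, "normalized": 2}


@dataclass
class ExpressionMatrix:
    """Cells x channels intensity matrix with aligned per-cell metadata.

    Parameters
    ----------
    values
        ``(n_cells, n_channels)`` float array. Must be nonnegative while
        ``scale_state == "raw"``.
    channel_names
        Unique channel (marker) names, one per column.
    cell_meta
        Per-cell metadata table (sample, batch, treatment, cell line, ...).
        Row count must equal the number of cells.
    scale_state
        One of ``{"raw", "asinh", "normalized"}``.
    transform_info
        Bookkeeping for applied transforms: ``cofactor`` after the asinh step,
        ``divisors`` (per-channel percentile values) after normalization, and
        ``scaled`` once features have been z-scored for statistics.
    """

    values: np.ndarray
    channel_names: list[str]
    cell_meta: pd.DataFrame
    scale_state: str = "raw"
    transform_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ParameterError("values must be a 2-D cells x channels array")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.values.shape[1]:
            raise ParameterError(
                f"{len(self.channel_names)} channel names for "
                f"{self.values.shape[1]} columns"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ParameterError("channel names must be unique")
        if self.scale_state not in _SCALE_ORDER:
            raise ParameterError(f"unknown scale state {self.scale_state!r}")
        if not isinstance(self.cell_meta, pd.DataFrame):
            self.cell_meta = pd.DataFrame(self.cell_meta)
        if len(self.cell_meta) != self.values.shape[0]:
            raise ParameterError(
                f"cell_meta has {len(self.cell_meta)} rows for "
                f"{self.values.shape[0]} cells"
            )
        if self.scale_state == "raw" and self.values.size and self.values.min() < 0:
            raise ParameterError("raw intensities must be nonnegative")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in matrix") from None

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a 1-D array (a view where possible)."""
        return self.values[:, self.channel_index(name)]

    def require_channels(self, names: Sequence[str]) -> list[int]:
        missing = [n for n in names if n not in self.channel_names]
        if missing:
            raise KeyError(f"channels missing from matrix: {missing}")
        return [self.channel_names.index(n) for n in names]

    def require_state(self, state: str, op: str) -> None:
        if self.scale_state != state:
            raise StateError(
                f"{op} requires scale_state={state!r}, got {self.scale_state!r}"
            )

    # -- derived views -----------------------------------------------------

    def copy(self) -> "ExpressionMatrix":
        return replace(
            self,
            values=self.values.copy(),
            channel_names=list(self.channel_names),
            cell_meta=self.cell_meta.copy(),
            transform_info=dict(self.transform_info),
        )

    def with_values(self, values: np.ndarray, scale_state: str | None = None,
                    **info_updates) -> "ExpressionMatrix":
        """New matrix sharing metadata, with replaced values/state.

        Scale state may only move forward along raw -> asinh -> normalized.
        """
        new_state = scale_state or self.scale_state
        if _SCALE_ORDER[new_state] < _SCALE_ORDER[self.scale_state]:
            raise StateError(
                f"scale state cannot move backwards "
                f"({self.scale_state!r} -> {new_state!r})"
            )
        info = dict(self.transform_info)
        info.update(info_updates)
        return ExpressionMatrix(
            values=values,
            channel_names=list(self.channel_names),
            cell_meta=self.cell_meta,
            scale_state=new_state,
            transform_info=info,
        )

    def select_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        return ExpressionMatrix(
            values=self.values[mask],
            channel_names=list(self.channel_names),
            cell_meta=self.cell_meta.loc[np.asarray(mask)].reset_index(drop=True)
            if mask.dtype == bool
            else self.cell_meta.iloc[mask].reset_index(drop=True),
            scale_state=self.scale_state,
            transform_info=dict(self.transform_info),
        )

    def subset_channels(self, names: Sequence[str]) -> np.ndarray:
        """Column block for the named channels (cells x len(names))."""
        idx = self.require_channels(names)
        return self.values[:, idx]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.channel_names)


def concat_matrices(mats: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    """Stack matrices with identical channels and scale state."""
    if not mats:
        raise ParameterError("nothing to concatenate")
    first = mats[0]
    for m in mats[1:]:
        if m.channel_names != first.channel_names:
            raise ParameterError("channel sets differ between matrices")
        if m.scale_state != first.scale_state:
            raise StateError("scale states differ between matrices")
    return ExpressionMatrix(
        values=np.vstack([m.values for m in mats]),
        channel_names=list(first.channel_names),
        cell_meta=pd.concat([m.cell_meta for m in mats], ignore_index=True),
        scale_state=first.scale_state,
        transform_info=dict(first.transform_info),
    )
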
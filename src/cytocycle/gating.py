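"""Programmatic cell-cycle phase gating.

Reproduces the classical cytometry gating logic: IdU incorporation marks
S-phase, pH3(S10) marks mitosis, and high CyclinB1 marks G2; everything else
is G0G1. Precedence is M > S > G2 > G0G1 — mitotic cells do not incorporate
IdU on mitotic timescales, and CyclinB1 peaks in M, so the pH3 gate must
dominate the CyclinB1 gate.

An optional G0-like sub-gate (Ki67-low AND pRb(S780)-low within G0G1)
separates quiescent-like cells; it is disabled by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import argrelextrema
from scipy.stats import gaussian_kde

from .errors import ParameterError
from .matrix import ExpressionMatrix
from .preprocess import raw_to_normalized

#: Default channel names for the three gating markers.
GATING_CHANNELS = {"idu": "IdU", "ph3": "pH3_s10", "cyclinb1": "CyclinB1"}


@dataclass
class G0Rules:
    """Ki67-low AND pRb(S780)-low cutoffs defining the G0-like sub-gate."""

    ki67_max: float
    prb_max: float
    ki67_channel: str = "Ki67"
    prb_channel: str = "pRbS780"


@dataclass
class GateThresholds:
    """Gate positions on the scale of the matrix they are applied to."""

    idu_pos: float
    ph3_pos: float
    cyclinb1_high: float
    dna_window: Optional[tuple[float, float]] = None
    g0_rules: Optional[G0Rules] = None
    derivation_method: str = "manual"
    channels: dict[str, str] = field(default_factory=lambda: dict(GATING_CHANNELS))

    def __post_init__(self) -> None:
        for name in ("idu_pos", "ph3_pos", "cyclinb1_high"):
            if not np.isfinite(getattr(self, name)):
                raise ParameterError(f"{name} must be finite")
        if self.dna_window is not None and self.dna_window[0] > self.dna_window[1]:
            raise ParameterError("dna_window bounds must be ordered")


def valley_threshold(x: np.ndarray, fallback_q: float = 0.95,
                     grid_size: int = 512) -> float:
    """Minimum-density point between the two largest modes of a KDE.

    Falls back to the ``fallback_q`` quantile (with a warning) when the
    density estimate is unimodal.
    """
    x = np.asarray(x, dtype=float)
    kde = gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), grid_size)
    dens = kde(grid)
    peaks = argrelextrema(dens, np.greater)[0]
    if len(peaks) < 2:
        warnings.warn(
            "channel looks unimodal under KDE; falling back to quantile "
            f"threshold q={fallback_q}",
            stacklevel=2,
        )
        return float(np.quantile(x, fallback_q))
    top_two = peaks[np.argsort(dens[peaks])[-2:]]
    lo, hi = np.sort(top_two)
    valley = lo + int(np.argmin(dens[lo : hi + 1]))
    return float(grid[valley])


def derive_thresholds(m: ExpressionMatrix, method: str = "quantile",
                      params: Optional[dict] = None) -> GateThresholds:
    """Derive gate thresholds from the data.

    ``manual`` passes ``params`` values straight through; ``quantile`` uses
    per-channel quantiles (``params`` maps gate -> q); ``valley`` places each
    gate at the KDE valley between the two largest modes.
    """
    params = dict(params or {})
    channels = params.pop("channels", dict(GATING_CHANNELS))
    m.require_channels(list(channels.values()))
    gates = {}
    if method == "manual":
        for gate in ("idu_pos", "ph3_pos", "cyclinb1_high"):
            if gate not in params:
                raise ParameterError(f"manual method requires {gate!r}")
            gates[gate] = float(params[gate])
    elif method == "quantile":
        qs = {"idu_pos": 0.95, "ph3_pos": 0.99, "cyclinb1_high": 0.90}
        qs.update(params)
        for gate, chan_key in (("idu_pos", "idu"), ("ph3_pos", "ph3"),
                               ("cyclinb1_high", "cyclinb1")):
            gates[gate] = float(np.quantile(m.channel(channels[chan_key]), qs[gate]))
    elif method == "valley":
        for gate, chan_key in (("idu_pos", "idu"), ("ph3_pos", "ph3"),
                               ("cyclinb1_high", "cyclinb1")):
            gates[gate] = valley_threshold(m.channel(channels[chan_key]))
    else:
        raise ParameterError(f"unknown threshold method {method!r}")
    return GateThresholds(derivation_method=method, channels=channels, **gates)


def thresholds_from_raw(m: ExpressionMatrix, raw_gates: dict[str, float],
                        **kwargs) -> GateThresholds:
    """Map raw-scale gate positions onto a normalized matrix's scale."""
    channels = kwargs.pop("channels", dict(GATING_CHANNELS))
    return GateThresholds(
        idu_pos=raw_to_normalized(m, channels["idu"], raw_gates["idu_pos"]),
        ph3_pos=raw_to_normalized(m, channels["ph3"], raw_gates["ph3_pos"]),
        cyclinb1_high=raw_to_normalized(
            m, channels["cyclinb1"], raw_gates["cyclinb1_high"]
        ),
        derivation_method="manual",
        channels=channels,
        **kwargs,
    )


def assign_phases(m: ExpressionMatrix, t: GateThresholds,
                  g0like: bool = False) -> np.ndarray:
    """Assign each cell exactly one phase label.

    Precedence: pH3 >= ph3_pos -> M; else IdU >= idu_pos -> S; else
    CyclinB1 >= cyclinb1_high -> G2; else G0G1. With ``g0like=True`` (and
    ``t.g0_rules`` set), G0G1 cells that are Ki67-low AND pRb-low are
    sub-labeled ``G0like``.
    """
    idu = m.channel(t.channels["idu"])
    ph3 = m.channel(t.channels["ph3"])
    cyb = m.channel(t.channels["cyclinb1"])

    labels = np.full(m.n_cells, "G0G1", dtype=object)
    labels[cyb >= t.cyclinb1_high] = "G2"
    labels[idu >= t.idu_pos] = "S"
    labels[ph3 >= t.ph3_pos] = "M"

    if g0like:
        if t.g0_rules is None:
            raise ParameterError("g0like labeling requires g0_rules")
        r = t.g0_rules
        quiescent = (
            (labels == "G0G1")
            & (m.channel(r.ki67_channel) <= r.ki67_max)
            & (m.channel(r.prb_channel) <= r.prb_max)
        )
        labels[quiescent] = "G0like"
    return labels
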
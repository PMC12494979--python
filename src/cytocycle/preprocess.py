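"""Fixed CyTOF preprocessing chain.

Order of operations on raw ion counts:

1. :func:`anchor_batch_adjust` — multiplicative per-channel batch correction
   from a shared anchor sample, on the raw scale (an ion-count correction
   commutes with asinh only approximately, so factors are derived and applied
   before transformation).
2. :func:`asinh_transform` — ``asinh(x / cofactor)`` with cofactor 5.
3. :func:`cleanup_filter` — threshold removal of debris/doublets (DNA window)
   and pre-apoptotic cells (cPARP high), on the asinh scale.
4. :func:`percentile_normalize` — divide each channel by its 99.9th
   percentile (linear-interpolation definition); optional censoring at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import ParameterError
from .matrix import ExpressionMatrix


@dataclass
class PreprocessParams:
    cofactor: float = 5.0
    percentile_q: float = 99.9
    clip_at_one: bool = False
    #: channel -> (min, max) on the asinh scale; None bound = unbounded.
    cleanup_thresholds: dict[str, tuple[Optional[float], Optional[float]]] = field(
        default_factory=dict
    )
    reference_batch: Optional[str] = None

    def __post_init__(self) -> None:
        if self.cofactor <= 0:
            raise ParameterError("cofactor must be > 0")
        if not 0 < self.percentile_q <= 100:
            raise ParameterError("percentile_q must be in (0, 100]")


def asinh_transform(m: ExpressionMatrix, cofactor: float = 5.0) -> ExpressionMatrix:
    """asinh(x / cofactor); strictly monotone, order-preserving per channel."""
    m.require_state("raw", "asinh_transform")
    if cofactor <= 0:
        raise ParameterError("cofactor must be > 0")
    return m.with_values(
        np.arcsinh(m.values / cofactor), scale_state="asinh", cofactor=cofactor
    )


def percentile_normalize(m: ExpressionMatrix, q: float = 99.9,
                         clip: bool = False) -> ExpressionMatrix:
    """Divide each channel by its q-th percentile; optionally censor at 1."""
    m.require_state("asinh", "percentile_normalize")
    if not 0 < q <= 100:
        raise ParameterError("q must be in (0, 100]")
    divisors = np.percentile(m.values, q, axis=0)
    zero = np.flatnonzero(divisors <= 0)
    if zero.size:
        names = [m.channel_names[i] for i in zero]
        raise ParameterError(
            f"channel(s) with nonpositive {q}th percentile: {names}"
        )
    values = m.values / divisors
    if clip:
        values = np.minimum(values, 1.0)
    return m.with_values(
        values,
        scale_state="normalized",
        divisors=dict(zip(m.channel_names, divisors.tolist())),
        percentile_q=q,
        clipped=clip,
    )


def raw_to_normalized(m: ExpressionMatrix, channel: str, raw_value: float) -> float:
    """Map a raw-scale threshold onto a normalized matrix's scale using its
    recorded cofactor and channel divisor (both transforms are monotone)."""
    m.require_state("normalized", "raw_to_normalized")
    info = m.transform_info
    if "cofactor" not in info or "divisors" not in info:
        raise ParameterError("matrix lacks recorded transform parameters")
    return float(np.arcsinh(raw_value / info["cofactor"]) / info["divisors"][channel])


def anchor_batch_adjust(m: ExpressionMatrix, anchor_mask: np.ndarray,
                        batch: np.ndarray, reference: str) -> ExpressionMatrix:
    """Multiplicative per-channel batch correction from anchor samples.

    For channel c and batch b, ``f(c, b) = median(anchor, reference, c) /
    median(anchor, b, c)``; every cell of batch b is multiplied by f(c, b).
    The reference batch is untouched. A zero anchor median leaves the channel
    unadjusted with a warning.
    """
    m.require_state("raw", "anchor_batch_adjust")
    anchor_mask = np.asarray(anchor_mask, dtype=bool)
    batch = np.asarray(batch)
    if len(anchor_mask) != m.n_cells or len(batch) != m.n_cells:
        raise ParameterError("anchor_mask/batch must have one entry per cell")
    batches = pd.unique(batch)
    if reference not in batches:
        raise ParameterError(f"reference batch {reference!r} not present")
    for b in batches:
        if not anchor_mask[batch == b].any():
            raise ParameterError(f"batch {b!r} has no anchor cells")

    ref_median = np.median(m.values[anchor_mask & (batch == reference)], axis=0)
    values = m.values.copy()
    factors: dict[str, dict[str, float]] = {}
    for b in batches:
        if b == reference:
            factors[str(b)] = {c: 1.0 for c in m.channel_names}
            continue
        b_median = np.median(m.values[anchor_mask & (batch == b)], axis=0)
        f = np.ones_like(ref_median)
        ok = b_median > 0
        f[ok] = ref_median[ok] / b_median[ok]
        bad = np.flatnonzero(~ok)
        if bad.size:
            names = [m.channel_names[i] for i in bad]
            warnings.warn(
                f"batch {b!r}: zero anchor median in {names}; factor set to 1",
                stacklevel=2,
            )
        values[batch == b] *= f
        factors[str(b)] = dict(zip(m.channel_names, f.tolist()))
    return m.with_values(values, batch_factors=factors)


def cleanup_filter(
    m: ExpressionMatrix,
    thresholds: Mapping[str, tuple[Optional[float], Optional[float]]],
) -> tuple[ExpressionMatrix, dict[str, int]]:
    """Remove cells outside any per-channel (min, max) window.

    Returns the retained matrix and a report with per-rule removed counts
    (counts may overlap when one cell breaks several rules) plus the retained
    total. The final retained set does not depend on rule order.
    """
    m.require_state("asinh", "cleanup_filter")
    keep = np.ones(m.n_cells, dtype=bool)
    report: dict[str, int] = {}
    for channel, (lo, hi) in thresholds.items():
        col = m.channel(channel)  # raises KeyError for unknown channels
        bad = np.zeros(m.n_cells, dtype=bool)
        if lo is not None:
            bad |= col < lo
        if hi is not None:
            bad |= col > hi
        report[channel] = int(bad.sum())
        keep &= ~bad
    report["retained"] = int(keep.sum())
    if report["retained"] == 0:
        warnings.warn("cleanup_filter removed every cell", stacklevel=2)
    return m.select_cells(keep), report
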
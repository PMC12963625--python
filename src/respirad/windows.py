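"""Sliding-window respiratory metrics with extreme-cycle trimming.

Metrics are compared between modalities at the level of overlapping 2-min
windows advanced in 30 s steps.  Within a window only *complete* cycles
count (both bounding valleys inside the half-open window), the cycles
carrying the smallest and largest TI and TE are removed (a union of 2-4
cycles), and the remaining cycles yield

    mean TI,  mean TE,  mean RR = mean(60 / (TI + TE)),  mean I:E = mean(TI / TE)

-- note the per-cycle-then-mean order for RR and I:E, which differs from
the ratio of the means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .segmentation import RespiratoryCycle

__all__ = [
    "WindowSpec",
    "WindowMetrics",
    "complete_cycles_in_window",
    "trim_extreme_cycles",
    "window_means",
    "sliding_window_metrics",
]

REASON_OK = ""
REASON_TOO_FEW = "too_few_cycles"
REASON_TRIMMED_OUT = "trim_left_too_few"


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry (2 min length, 30 s step by default)."""

    length_s: float = 120.0
    step_s: float = 30.0
    min_cycles: int = 6  # >= 2 retained even after a worst-case trim of 4

    def __post_init__(self) -> None:
        if not (0 < self.step_s <= self.length_s):
            raise ValueError("need 0 < step_s <= length_s")
        if self.min_cycles < 3:
            raise ValueError("min_cycles must leave room for the 2-4 cycle trim")


@dataclass(frozen=True)
class WindowMetrics:
    window_start_s: float
    n_cycles_total: int
    n_cycles_used: int
    mean_ti_s: float
    mean_te_s: float
    mean_rr_brpm: float
    mean_ie_ratio: float
    valid: bool = True
    reason: str = REASON_OK


def complete_cycles_in_window(
    cycles: Sequence[RespiratoryCycle], window_start: float, spec: WindowSpec
) -> list[RespiratoryCycle]:
    """Cycles whose both bounding valleys fall inside [start, start+length)."""
    end = window_start + spec.length_s
    return [c for c in cycles if c.vl_start_s >= window_start and c.vl_end_s < end]


def trim_extreme_cycles(
    cycles: Sequence[RespiratoryCycle],
) -> tuple[list[RespiratoryCycle], list[int]]:
    """Remove the cycles carrying min/max TI and min/max TE.

    Returns (retained cycles, sorted indices removed).  The removed set is
    the union of the four argmin/argmax positions (2-4 distinct cycles;
    ties resolved to the earliest cycle).
    """
    if len(cycles) == 0:
        return [], []
    ti = np.array([c.ti_s for c in cycles])
    te = np.array([c.te_s for c in cycles])

    def _pick(vals: np.ndarray) -> tuple[int, int]:
        imin, imax = int(np.argmin(vals)), int(np.argmax(vals))
        if imax == imin and vals.size > 1:
            # constant metric: take the last occurrence as the "max" so the
            # trim still removes two distinct cycles
            imax = vals.size - 1
        return imin, imax

    drop = set(_pick(ti)) | set(_pick(te))
    kept = [c for k, c in enumerate(cycles) if k not in drop]
    return kept, sorted(drop)


def window_means(
    retained: Sequence[RespiratoryCycle],
    window_start_s: float = 0.0,
    n_cycles_total: int | None = None,
) -> WindowMetrics:
    """Per-window means over the retained cycles (order-invariant)."""
    if len(retained) == 0:
        raise ValueError("window_means requires at least one retained cycle")
    ti = np.array([c.ti_s for c in retained])
    te = np.array([c.te_s for c in retained])
    return WindowMetrics(
        window_start_s=window_start_s,
        n_cycles_total=len(retained) if n_cycles_total is None else n_cycles_total,
        n_cycles_used=len(retained),
        mean_ti_s=float(ti.mean()),
        mean_te_s=float(te.mean()),
        mean_rr_brpm=float(np.mean(60.0 / (ti + te))),
        mean_ie_ratio=float(np.mean(ti / te)),
    )


def _invalid(start: float, n_total: int, reason: str) -> WindowMetrics:
    return WindowMetrics(
        window_start_s=start,
        n_cycles_total=n_total,
        n_cycles_used=0,
        mean_ti_s=np.nan,
        mean_te_s=np.nan,
        mean_rr_brpm=np.nan,
        mean_ie_ratio=np.nan,
        valid=False,
        reason=reason,
    )


def sliding_window_metrics(
    cycles: Sequence[RespiratoryCycle],
    spec: WindowSpec = WindowSpec(),
    recording_span_s: float | None = None,
) -> pd.DataFrame:
    """Window table over starts 0, step, 2*step, ... while start+length <= span.

    Invalid windows (too few complete cycles, or trimming leaving fewer than
    two) are kept in the table with NaN metrics and a reason code, so that
    radar and reference tables from the same recording share an identical
    window grid.
    """
    if recording_span_s is None:
        if len(cycles) == 0:
            raise ValueError("cannot infer recording span from zero cycles")
        recording_span_s = max(c.vl_end_s for c in cycles)
    cycles = sorted(cycles, key=lambda c: c.vl_start_s)
    rows: list[WindowMetrics] = []
    start = 0.0
    while start + spec.length_s <= recording_span_s + 1e-9:
        inside = complete_cycles_in_window(cycles, start, spec)
        if len(inside) < spec.min_cycles:
            rows.append(_invalid(start, len(inside), REASON_TOO_FEW))
        else:
            kept, dropped = trim_extreme_cycles(inside)
            assert 2 <= len(dropped) <= 4
            if len(kept) < 2:
                rows.append(_invalid(start, len(inside), REASON_TRIMMED_OUT))
            else:
                rows.append(window_means(kept, start, n_cycles_total=len(inside)))
        start += spec.step_s
    columns = list(WindowMetrics.__dataclass_fields__)
    return pd.DataFrame([vars(m) for m in rows], columns=columns)
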
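"""Respiratory cycle segmentation: extrema detection, alternation, assembly.

A respiratory cycle is a valley-to-valley excursion: inspiration runs from a
valley (VL) to the following peak (PK), expiration from that peak to the
next valley.  Peaks and valleys are detected independently on the
normalized respiration waveform under prominence, distance and width
constraints; the merged sequence is then forced into strict VL-PK-VL
alternation (keeping the *first* of consecutive peaks and the *last* of
consecutive valleys, which preserves the physiological TE > TI asymmetry),
and cycles longer than 10 s (< 6 breaths/min) are discarded as outliers.

Detection is two-pass: a first pass with only distance/width constraints
collects candidate extremum amplitudes, whose standard deviation within the
recording sets the prominence threshold for the final pass.  The constraint
defaults are package choices tuned to resting adult breathing, exposed in
:class:`DetectionConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator

__all__ = [
    "DetectionConfig",
    "Extremum",
    "RespiratoryCycle",
    "CycleSegmenter",
    "detect_extrema",
    "enforce_alternation",
    "assemble_cycles",
    "exclude_outlier_cycles",
    "cycles_to_frame",
]

PK = "PK"
VL = "VL"


@dataclass(frozen=True)
class DetectionConfig:
    """Extremum-detection constraints.

    prominence_factor
        The prominence threshold is this multiple of the standard deviation
        of candidate extremum amplitudes within the recording.
    min_distance_s
        Minimum spacing between same-kind extrema; 1.5 s is consistent with
        the 0.4 Hz upper band edge (shortest credible cycle 2.5 s).
    min_width_s
        Minimum width of a peak at half prominence.
    max_cycle_s
        Cycles whose total duration strictly exceeds this are outliers.
    """

    prominence_factor: float = 0.3
    min_distance_s: float = 1.5
    min_width_s: float = 0.5
    max_cycle_s: float = 10.0

    def __post_init__(self) -> None:
        for name in ("prominence_factor", "min_distance_s", "min_width_s", "max_cycle_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Extremum:
    time_s: float
    kind: str  # PK | VL
    amplitude: float = np.nan
    prominence: float = np.nan

    def __post_init__(self) -> None:
        if self.kind not in (PK, VL):
            raise ValueError("kind must be 'PK' or 'VL'")


@dataclass(frozen=True)
class RespiratoryCycle:
    """One VL -> PK -> VL triple."""

    vl_start_s: float
    pk_s: float
    vl_end_s: float

    def __post_init__(self) -> None:
        if not (self.vl_start_s < self.pk_s < self.vl_end_s):
            raise ValueError("cycle must satisfy vl_start < pk < vl_end")

    @property
    def ti_s(self) -> float:
        return self.pk_s - self.vl_start_s

    @property
    def te_s(self) -> float:
        return self.vl_end_s - self.pk_s

    @property
    def duration_s(self) -> float:
        return self.vl_end_s - self.vl_start_s

    @property
    def ie_ratio(self) -> float:
        return self.ti_s / self.te_s


def _find_kind(
    values: np.ndarray,
    fs: float,
    cfg: DetectionConfig,
    kind: str,
    prominence: float | None,
) -> tuple[np.ndarray, np.ndarray]:
    sig = values if kind == PK else -values
    kwargs = dict(
        distance=max(1, int(round(cfg.min_distance_s * fs))),
        width=cfg.min_width_s * fs,
    )
    if prominence is not None:
        kwargs["prominence"] = prominence
    idx, props = find_peaks(sig, **kwargs)
    prom = props.get("prominences", np.full(idx.size, np.nan))
    return idx, prom


def detect_extrema(
    sig,
    fs: float | None = None,
    cfg: DetectionConfig = DetectionConfig(),
    t0: float = 0.0,
    exclude_margin_s: float = 0.0,
) -> list[Extremum]:
    """Detect peaks and valleys on a normalized respiration waveform.

    Accepts a :class:`~respirad.preprocessing.RespiratorySignal` or a bare
    array plus ``fs``.  ``exclude_margin_s`` masks the filter-transient span
    at both record edges.  Returns time-sorted extrema (possibly empty).
    """
    if fs is None:
        values, fs = np.asarray(sig.values, float), sig.fs
    else:
        values = np.asarray(sig, float)
    if values.size < cfg.min_distance_s * fs:
        raise ValueError("signal shorter than min_distance_s")

    # pass 1: distance/width only, to estimate the amplitude spread
    amps = []
    for kind in (PK, VL):
        idx, _ = _find_kind(values, fs, cfg, kind, prominence=None)
        amps.append(values[idx])
    amps = np.concatenate(amps)
    if amps.size == 0:
        return []
    threshold = cfg.prominence_factor * float(np.std(amps))
    if threshold <= 0:  # flat or single-candidate recordings
        threshold = None

    out: list[Extremum] = []
    for kind in (PK, VL):
        idx, prom = _find_kind(values, fs, cfg, kind, prominence=threshold)
        for j, p in zip(idx, prom):
            out.append(
                Extremum(
                    time_s=t0 + j / fs,
                    kind=kind,
                    amplitude=float(values[j]),
                    prominence=float(p),
                )
            )
    out.sort(key=lambda e: e.time_s)
    if exclude_margin_s > 0:
        span = values.size / fs
        out = [
            e
            for e in out
            if t0 + exclude_margin_s <= e.time_s <= t0 + span - exclude_margin_s
        ]
    return out


def enforce_alternation(extrema: Sequence[Extremum]) -> list[Extremum]:
    """Force strict VL, PK, VL, ... alternation.

    Within a run of consecutive peaks only the first survives; within a run
    of consecutive valleys only the last.  The result is then trimmed to
    start and end on a valley.  Idempotent; never adds extrema.
    """
    ext = list(extrema)
    if any(ext[i].time_s > ext[i + 1].time_s for i in range(len(ext) - 1)):
        raise ValueError("extrema must be time-sorted")
    collapsed: list[Extremum] = []
    for e in ext:
        if collapsed and collapsed[-1].kind == e.kind:
            if e.kind == VL:
                collapsed[-1] = e  # keep the last valley of the run
            # consecutive peaks: keep the first, drop e
        else:
            collapsed.append(e)
    while collapsed and collapsed[0].kind == PK:
        collapsed.pop(0)
    while collapsed and collapsed[-1].kind == PK:
        collapsed.pop()
    return collapsed


def assemble_cycles(extrema: Sequence[Extremum]) -> list[RespiratoryCycle]:
    """One cycle per consecutive (VL, PK, VL) triple; boundary VLs shared."""
    kinds = [e.kind for e in extrema]
    for a, b in zip(kinds, kinds[1:]):
        if a == b:
            raise ValueError("extrema must strictly alternate; run enforce_alternation first")
    cycles = []
    for k in range(0, len(extrema) - 2, 2):
        vl0, pk, vl1 = extrema[k : k + 3]
        if not (vl0.kind == VL and pk.kind == PK and vl1.kind == VL):
            raise ValueError("alternating sequence must start with a valley")
        cycles.append(
            RespiratoryCycle(vl_start_s=vl0.time_s, pk_s=pk.time_s, vl_end_s=vl1.time_s)
        )
    return cycles


def exclude_outlier_cycles(
    cycles: Iterable[RespiratoryCycle], max_cycle_s: float = 10.0
) -> tuple[list[RespiratoryCycle], list[RespiratoryCycle]]:
    """Drop cycles strictly longer than ``max_cycle_s`` (kept, excluded)."""
    kept, excluded = [], []
    for c in cycles:
        (excluded if c.duration_s > max_cycle_s else kept).append(c)
    return kept, excluded


def cycles_to_frame(cycles: Sequence[RespiratoryCycle], excluded=()):
    """Cycle table as a DataFrame (vl_start_s, pk_s, vl_end_s, ti_s, te_s,
    excluded_flag)."""
    import pandas as pd

    rows = [
        dict(
            vl_start_s=c.vl_start_s, pk_s=c.pk_s, vl_end_s=c.vl_end_s,
            ti_s=c.ti_s, te_s=c.te_s, excluded_flag=flag,
        )
        for group, flag in ((cycles, False), (excluded, True))
        for c in group
    ]
    df = pd.DataFrame(
        rows,
        columns=["vl_start_s", "pk_s", "vl_end_s", "ti_s", "te_s", "excluded_flag"],
    )
    return df.sort_values("vl_start_s", ignore_index=True)


class CycleSegmenter(BaseEstimator):
    """Detect respiratory cycles on a normalized respiration waveform.

    scikit-learn-style estimator: ``fit(X)`` with a 1-D waveform populates
    trailing-underscore attributes.

    Parameters mirror :class:`DetectionConfig` plus the sampling rate and
    the edge margin to mask as filter transient.

    Attributes
    ----------
    extrema_ : list[Extremum]
        Alternation-enforced extrema.
    cycles_ : list[RespiratoryCycle]
        Cycles retained after the > ``max_cycle_s`` outlier rule.
    excluded_cycles_ : list[RespiratoryCycle]
        Outlier cycles that were removed.
    """

    def __init__(
        self,
        fs: float = 2000.0,
        prominence_factor: float = 0.3,
        min_distance_s: float = 1.5,
        min_width_s: float = 0.5,
        max_cycle_s: float = 10.0,
        exclude_margin_s: float = 0.0,
        t0: float = 0.0,
    ):
        self.fs = fs
        self.prominence_factor = prominence_factor
        self.min_distance_s = min_distance_s
        self.min_width_s = min_width_s
        self.max_cycle_s = max_cycle_s
        self.exclude_margin_s = exclude_margin_s
        self.t0 = t0

    def _config(self) -> DetectionConfig:
        return DetectionConfig(
            prominence_factor=self.prominence_factor,
            min_distance_s=self.min_distance_s,
            min_width_s=self.min_width_s,
            max_cycle_s=self.max_cycle_s,
        )

    def fit(self, X, y=None):
        values = np.asarray(getattr(X, "values", X), float).ravel()
        fs = getattr(X, "fs", self.fs)
        cfg = self._config()
        raw = detect_extrema(
            values, fs, cfg, t0=self.t0, exclude_margin_s=self.exclude_margin_s
        )
        self.raw_extrema_ = raw
        self.extrema_ = enforce_alternation(raw)
        cycles = assemble_cycles(self.extrema_)
        self.cycles_, self.excluded_cycles_ = exclude_outlier_cycles(
            cycles, cfg.max_cycle_s
        )
        return self

    def fit_predict(self, X, y=None) -> list[RespiratoryCycle]:
        return self.fit(X).cycles_
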
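"""Respiratory-band isolation and normalization.

Both the radar displacement trace (mm) and the impedance reference (Ohm)
are reduced to dimensionless respiration waveforms the same way: a
fourth-order Butterworth bandpass over 0.07-0.4 Hz (4-24 breaths/min)
applied forward-backward, followed by a whole-recording z-score.  Zero-phase
filtering is essential here: every downstream metric is an extremum
*timing*, and a causal filter's group delay would bias TI and TE directly.

The filter is realised in second-order-sections form; at these band edges
(7e-5 of the Nyquist frequency for the 2000 Hz radar channel) a polynomial
transfer function is numerically unusable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "RespiratorySignal",
    "RespiratoryBandpass",
    "bandpass",
    "normalize",
    "transient_margin_s",
]

DEFAULT_BAND = (0.07, 0.4)


@dataclass
class RespiratorySignal:
    """Filtered, z-scored respiration waveform on a uniform time grid."""

    values: np.ndarray
    fs: float
    source: str = "radar"  # "radar" | "reference"
    band: tuple[float, float] = DEFAULT_BAND

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.values.size) / self.fs

    @property
    def duration_s(self) -> float:
        return self.values.size / self.fs

    @property
    def transient_margin_s(self) -> float:
        return transient_margin_s(self.band[0])


def transient_margin_s(low_hz: float = DEFAULT_BAND[0]) -> float:
    """Span at each record edge treated as filter transient (one period of
    the low band edge); excluded from cycle detection downstream."""
    return 1.0 / low_hz


class RespiratoryBandpass(BaseEstimator, TransformerMixin):
    """Zero-phase Butterworth bandpass transformer for 1-D traces.

    Parameters
    ----------
    fs : float
        Sampling rate of the input trace in Hz.
    low_hz, high_hz : float
        Band edges; defaults bracket 4-24 breaths/min.
    order : int
        Butterworth design order passed to :func:`scipy.signal.butter`.
    zero_phase : bool
        Forward-backward application (no group delay).  The causal
        alternative is provided for experimentation only.
    """

    def __init__(
        self,
        fs: float = 2000.0,
        low_hz: float = DEFAULT_BAND[0],
        high_hz: float = DEFAULT_BAND[1],
        order: int = 4,
        zero_phase: bool = True,
    ):
        self.fs = fs
        self.low_hz = low_hz
        self.high_hz = high_hz
        self.order = order
        self.zero_phase = zero_phase

    def _sos(self) -> np.ndarray:
        if self.fs <= 2 * self.high_hz:
            raise ValueError("sampling rate must exceed twice the upper band edge")
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("band edges must satisfy 0 < low < high")
        return sps.butter(
            self.order, [self.low_hz, self.high_hz], btype="bandpass",
            fs=self.fs, output="sos",
        )

    def fit(self, X, y=None):
        self.sos_ = self._sos()
        return self

    def transform(self, X):
        x = np.asarray(X, float)
        squeeze = x.ndim == 1
        x = np.atleast_2d(x) if squeeze else x.T  # rows = traces
        min_len = 3 * self.fs / self.low_hz
        if x.shape[1] < min_len:
            raise ValueError(
                f"trace too short for stable filtering: need >= {min_len:.0f} "
                f"samples (3x the {1 / self.low_hz:.1f} s settling span)"
            )
        sos = self._sos()
        if self.zero_phase:
            y = sps.sosfiltfilt(sos, x, axis=-1, padtype="even")
        else:
            y = sps.sosfilt(sos, x, axis=-1)
        return y[0] if squeeze else y.T

    def frequency_response(self, freqs_hz) -> np.ndarray:
        """Magnitude response at the given frequencies (squared if zero-phase)."""
        w = 2 * np.pi * np.asarray(freqs_hz, float) / self.fs
        _, h = sps.sosfreqz(self._sos(), worN=w)
        mag = np.abs(h)
        return mag**2 if self.zero_phase else mag


def bandpass(
    trace,
    fs: float,
    low_hz: float = DEFAULT_BAND[0],
    high_hz: float = DEFAULT_BAND[1],
    order: int = 4,
    zero_phase: bool = True,
) -> np.ndarray:
    """Butterworth-bandpass a 1-D trace (zero-phase by default)."""
    return RespiratoryBandpass(
        fs=fs, low_hz=low_hz, high_hz=high_hz, order=order, zero_phase=zero_phase
    ).transform(trace)


def normalize(
    trace,
    fs: float | None = None,
    source: str = "radar",
    band: tuple[float, float] = DEFAULT_BAND,
) -> RespiratorySignal | np.ndarray:
    """Whole-recording z-score.

    With ``fs`` given, returns a :class:`RespiratorySignal`; otherwise the
    bare normalized array.  Raises on (near-)constant input.
    """
    x = np.asarray(trace, float)
    sd = x.std()
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot normalize a constant trace (zero variance)")
    values = (x - x.mean()) / sd
    if fs is None:
        return values
    return RespiratorySignal(values=values, fs=fs, source=source, band=band)
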
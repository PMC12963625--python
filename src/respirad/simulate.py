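"""Synthetic radar/impedance recordings with known per-cycle ground truth.

Generates time-synchronized pairs of a 24 GHz CW-radar I/Q baseband signal
(2000 Hz) and a thoracic-impedance reference trace (100 Hz), both driven by
the same quasi-periodic chest-displacement waveform, together with the exact
valley/peak timing of every respiratory cycle.  This is the test bed for the
processing pipeline: every downstream estimate (TI, TE, RR, I:E) can be
scored against the generator's cycle table.

The breathing model is a train of asymmetric raised-cosine half-waves: the
chest rises from valley to peak over the inspiratory time TI and falls back
over the expiratory time TE, with TE > TI on average as in normal resting
breathing.  Per-cycle TI and TE are drawn independently from gamma
distributions parameterized by their means and a common coefficient of
variation, giving positive support and realistic cycle-to-cycle variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import numpy as np
from scipy.constants import c as SPEED_OF_LIGHT

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticRecording",
    "snr_db_to_noise_std",
    "draw_cycle_sequence",
    "displacement_waveform",
    "radar_forward_model",
    "reference_forward_model",
    "simulate_recording",
]


def wavelength_mm(carrier_freq_hz: float) -> float:
    """TX wavelength in millimetres (12.49 mm at 24 GHz)."""
    return SPEED_OF_LIGHT / carrier_freq_hz * 1e3


def snr_db_to_noise_std(snr_db: float) -> float:
    """Per-channel additive-noise std for a given SNR relative to the unit
    carrier amplitude of the ideal I/Q circle."""
    return 10.0 ** (-snr_db / 20.0)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic recording.

    Defaults describe a healthy adult at rest (cycle ~5.3 s, RR ~11 brpm,
    I:E ~0.83, 4 mm peak-to-peak chest excursion) recorded by a mildly
    imperfect quadrature receiver.
    """

    duration_s: float = 600.0
    fs_radar: float = 2000.0
    fs_ref: float = 100.0
    carrier_freq: float = 24e9
    mean_ti: float = 2.4
    mean_te: float = 2.9
    cycle_cv: float = 0.10
    amplitude_mm: float = 4.0
    standoff_mm: float = 400.0
    iq_amp_imbalance: float = 0.9
    iq_phase_imbalance_deg: float = 5.0
    dc_offset_i: float = 0.2
    dc_offset_q: float = -0.15
    noise_std: float = 0.1
    cardiac_amp_mm: float = 0.3
    cardiac_freq_hz: float = 1.1
    ref_baseline_ohm: float = 25.0
    ref_gain_ohm_per_mm: float = 0.05
    ref_noise_std: float = 0.005
    artifact_rate_per_min: float = 0.0
    artifact_amp_mm: float = 2.0
    artifact_tau_s: float = 0.3
    expiration_shape: str = "cosine"  # "cosine" | "exponential"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs_radar < 2 * self.fs_ref:
            raise ValueError("fs_radar must be at least twice fs_ref")
        if not (self.mean_te > self.mean_ti > 0):
            raise ValueError(
                "physiological asymmetry requires mean_te > mean_ti > 0"
            )
        if self.mean_ti + self.mean_te > 10.0:
            raise ValueError(
                "mean cycle duration exceeds 10 s; such cycles would be "
                "excluded wholesale by the outlier rule"
            )
        for name in (
            "cycle_cv", "amplitude_mm", "noise_std", "cardiac_amp_mm",
            "ref_noise_std", "artifact_rate_per_min", "iq_amp_imbalance",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.expiration_shape not in ("cosine", "exponential"):
            raise ValueError("expiration_shape must be 'cosine' or 'exponential'")

    @property
    def wavelength_mm(self) -> float:
        return wavelength_mm(self.carrier_freq)

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """Exact cycle timing: valley (VL) start, peak (PK), valley end per cycle."""

    start_s: np.ndarray
    peak_s: np.ndarray
    end_s: np.ndarray

    def __post_init__(self) -> None:
        self.start_s = np.asarray(self.start_s, float)
        self.peak_s = np.asarray(self.peak_s, float)
        self.end_s = np.asarray(self.end_s, float)
        if not (
            np.all(self.start_s < self.peak_s)
            and np.all(self.peak_s < self.end_s)
        ):
            raise ValueError("cycle boundaries must satisfy VL < PK < VL")
        if self.start_s.size > 1 and not np.allclose(
            self.end_s[:-1], self.start_s[1:]
        ):
            raise ValueError("consecutive cycles must share boundary valleys")

    @property
    def ti_s(self) -> np.ndarray:
        return self.peak_s - self.start_s

    @property
    def te_s(self) -> np.ndarray:
        return self.end_s - self.peak_s

    @property
    def n_cycles(self) -> int:
        return int(self.start_s.size)

    def to_cycles(self):
        """Ground-truth cycles as :class:`~respirad.segmentation.RespiratoryCycle`
        objects, for scoring pipeline output with the same windowing code."""
        from .segmentation import RespiratoryCycle

        return [
            RespiratoryCycle(vl_start_s=s, pk_s=p, vl_end_s=e)
            for s, p, e in zip(self.start_s, self.peak_s, self.end_s)
        ]

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "vl_start_s": self.start_s,
                "pk_s": self.peak_s,
                "vl_end_s": self.end_s,
                "ti_s": self.ti_s,
                "te_s": self.te_s,
            }
        )


@dataclass
class SyntheticRecording:
    """One simulated subject: radar I/Q + impedance reference + truth table."""

    i: np.ndarray
    q: np.ndarray
    fs_radar: float
    reference_ohm: np.ndarray
    fs_ref: float
    displacement_mm: np.ndarray
    truth: GroundTruth
    config: SimulationConfig

    @property
    def t_radar(self) -> np.ndarray:
        return np.arange(self.i.size) / self.fs_radar

    @property
    def t_ref(self) -> np.ndarray:
        return np.arange(self.reference_ohm.size) / self.fs_ref


def draw_cycle_sequence(
    config: SimulationConfig, rng: np.random.Generator
) -> GroundTruth:
    """Draw per-cycle TI/TE until the recording is tiled; drop the partial tail.

    TI and TE are independent gamma draws with means ``mean_ti``/``mean_te``
    and coefficient of variation ``cycle_cv`` (degenerate point masses at
    cv = 0).
    """

    def _draw(mean: float, n: int) -> np.ndarray:
        if config.cycle_cv == 0:
            return np.full(n, mean)
        shape = 1.0 / config.cycle_cv**2
        scale = mean * config.cycle_cv**2
        return rng.gamma(shape, scale, size=n)

    # over-draw, then truncate to the recording span
    mean_cycle = config.mean_ti + config.mean_te
    n_guess = int(np.ceil(config.duration_s / mean_cycle * 1.5)) + 10
    while True:
        ti = _draw(config.mean_ti, n_guess)
        te = _draw(config.mean_te, n_guess)
        ends = np.cumsum(ti + te)
        if ends[-1] >= config.duration_s:
            break
        n_guess *= 2
    # complete cycles only; tolerance admits a cycle ending exactly at the
    # recording end despite float accumulation
    n = int(np.searchsorted(ends, config.duration_s + 1e-9))
    if n == 0:
        raise ValueError("duration_s too short to contain one full cycle")
    ti, te = ti[:n], te[:n]
    starts = np.concatenate(([0.0], np.cumsum(ti + te)[:-1]))
    return GroundTruth(start_s=starts, peak_s=starts + ti, end_s=starts + ti + te)


def _breathing_trace(
    truth: GroundTruth, config: SimulationConfig, t: np.ndarray
) -> np.ndarray:
    """Noise-free breathing displacement (mm, valley = 0, peak = amplitude_mm)."""
    amp = config.amplitude_mm
    if amp == 0:
        return np.zeros_like(t)
    if config.expiration_shape == "cosine":
        # piecewise-linear phase ramp: 0 at each VL, pi at each PK, 2*pi at
        # the next VL; the raised cosine of that ramp is the asymmetric
        # half-wave train with extrema exactly on the truth grid.
        knots_t = np.empty(2 * truth.n_cycles + 1)
        knots_t[0::2] = np.concatenate((truth.start_s, truth.end_s[-1:]))
        knots_t[1::2] = truth.peak_s
        knots_phase = np.pi * np.arange(knots_t.size)
        phase = np.interp(t, knots_t, knots_phase)
        return amp * 0.5 * (1.0 - np.cos(phase))
    # exponential expiration: cosine rise over TI, decay exp(-4*(t-pk)/te)
    x = np.zeros_like(t)
    idx = np.searchsorted(truth.start_s, t, side="right") - 1
    inside = (idx >= 0) & (t < truth.end_s[-1])
    k = idx[inside]
    tt = t[inside]
    rising = tt < truth.peak_s[k]
    xr = np.zeros(tt.size)
    xr[rising] = 0.5 * (
        1 - np.cos(np.pi * (tt[rising] - truth.start_s[k][rising]) / truth.ti_s[k][rising])
    )
    fall = ~rising
    xr[fall] = np.exp(-4.0 * (tt[fall] - truth.peak_s[k][fall]) / truth.te_s[k][fall])
    x[inside] = amp * xr
    return x


def displacement_waveform(
    truth: GroundTruth,
    config: SimulationConfig,
    t: np.ndarray,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Chest displacement in mm on the given uniform time grid.

    Breathing half-waves plus optional cardiac ripple and sparse motion
    artifacts (double-exponential pulses at Poisson times; needs ``rng``).
    """
    x = _breathing_trace(truth, config, t)
    if config.cardiac_amp_mm > 0:
        x = x + config.cardiac_amp_mm * np.sin(2 * np.pi * config.cardiac_freq_hz * t)
    if config.artifact_rate_per_min > 0:
        if rng is None:
            raise ValueError("motion artifacts require an rng")
        n_art = rng.poisson(config.artifact_rate_per_min * config.duration_s / 60.0)
        for t0 in rng.uniform(0, config.duration_s, size=n_art):
            sign = rng.choice([-1.0, 1.0])
            x = x + sign * config.artifact_amp_mm * np.exp(
                -np.abs(t - t0) / config.artifact_tau_s
            )
    return x


def radar_forward_model(
    displacement_mm: np.ndarray,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Map displacement to raw I/Q with hardware imperfections.

    Two-way path: phi = 4*pi*(standoff + x)/lambda.  The Q channel carries
    the gain and phase imbalance; both channels carry DC offsets and
    independent white noise.
    """
    lam = config.wavelength_mm
    phi = 4.0 * np.pi * (config.standoff_mm + displacement_mm) / lam
    psi = np.deg2rad(config.iq_phase_imbalance_deg)
    i = np.cos(phi) + config.dc_offset_i
    q = config.iq_amp_imbalance * np.sin(phi + psi) + config.dc_offset_q
    if config.noise_std > 0:
        if rng is None:
            raise ValueError("noise_std > 0 requires an rng")
        i = i + rng.normal(0, config.noise_std, size=i.size)
        q = q + rng.normal(0, config.noise_std, size=q.size)
    return i, q


def reference_forward_model(
    displacement_mm: np.ndarray,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Thoracic-impedance trace (Ohm) at fs_ref from the same displacement.

    The respiratory excursion is band-limited to a few Hz, far below the
    fs_ref/2 Nyquist limit, so plain strided decimation of the fs_radar-grid
    trace preserves timing without an anti-alias filter.
    """
    step = config.fs_radar / config.fs_ref
    if abs(step - round(step)) > 1e-9:
        raise ValueError("fs_radar must be an integer multiple of fs_ref")
    x = displacement_mm[:: int(round(step))]
    z = config.ref_baseline_ohm + config.ref_gain_ohm_per_mm * x
    if config.ref_noise_std > 0:
        if rng is None:
            raise ValueError("ref_noise_std > 0 requires an rng")
        z = z + rng.normal(0, config.ref_noise_std, size=z.size)
    return z


def simulate_recording(
    config: SimulationConfig, seed: Optional[int] = None
) -> SyntheticRecording:
    """Generate one complete synthetic subject (deterministic for fixed seed)."""
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    truth = draw_cycle_sequence(config, rng)
    t = np.arange(int(round(config.duration_s * config.fs_radar))) / config.fs_radar
    x = displacement_waveform(truth, config, t, rng)
    i, q = radar_forward_model(x, config, rng)
    z = reference_forward_model(x, config, rng)
    return SyntheticRecording(
        i=i,
        q=q,
        fs_radar=config.fs_radar,
        reference_ohm=z,
        fs_ref=config.fs_ref,
        displacement_mm=x,
        truth=truth,
        config=config,
    )
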
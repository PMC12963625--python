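"""Per-subject containers and the end-to-end processing pipeline.

A recording pair (radar I/Q at 2000 Hz + impedance reference at 100 Hz) is
stored per subject in one HDF5 file::

    /radar/i, /radar/q          float64, attrs: fs
    /reference/z                float64, attrs: fs
    /truth/{vl_start_s,pk_s,vl_end_s}   (synthetic recordings only)
    attrs: subject_id, scenario, config_json

plus a companion ``<stem>_cycles.csv`` ground-truth table for synthetic
subjects.  The processing pipeline is source-agnostic: anything exposing
the :class:`RecordingBundle` fields goes through the same chain.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from . import demodulation as dem
from . import preprocessing as pre
from .config import PipelineConfig
from .segmentation import CycleSegmenter, cycles_to_frame
from .simulate import GroundTruth, SyntheticRecording
from .windows import sliding_window_metrics

logger = logging.getLogger("respirad")

__all__ = [
    "RecordingBundle",
    "PipelineResult",
    "write_recording",
    "read_recording",
    "load_figshare_subject",
    "run_pipeline",
    "pair_windows",
]


@dataclass
class RecordingBundle:
    """One subject's synchronized radar + reference recording."""

    subject_id: str
    i: np.ndarray
    q: np.ndarray
    fs_radar: float
    reference: np.ndarray
    fs_ref: float
    scenario: str = "resting"
    provenance: str = ""
    truth: Optional[GroundTruth] = None

    @property
    def duration_s(self) -> float:
        return self.i.size / self.fs_radar


def write_recording(
    rec: SyntheticRecording, path, subject_id: str = "synthetic"
) -> Path:
    """Write a synthetic recording to the per-subject HDF5 container
    (plus a ``*_cycles.csv`` ground-truth companion)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        g = f.create_group("radar")
        g.create_dataset("i", data=rec.i)
        g.create_dataset("q", data=rec.q)
        g.attrs["fs"] = rec.fs_radar
        g = f.create_group("reference")
        g.create_dataset("z", data=rec.reference_ohm)
        g.attrs["fs"] = rec.fs_ref
        g = f.create_group("truth")
        g.create_dataset("vl_start_s", data=rec.truth.start_s)
        g.create_dataset("pk_s", data=rec.truth.peak_s)
        g.create_dataset("vl_end_s", data=rec.truth.end_s)
        f.attrs["subject_id"] = subject_id
        f.attrs["scenario"] = "resting"
        f.attrs["config_json"] = json.dumps(rec.config.to_dict())
    rec.truth.as_frame().to_csv(path.with_name(path.stem + "_cycles.csv"), index=False)
    return path


def read_recording(path) -> RecordingBundle:
    """Read a per-subject container written by :func:`write_recording`."""
    with h5py.File(path, "r") as f:
        for key in ("radar/i", "radar/q", "reference/z"):
            if key not in f:
                raise ValueError(f"container {path} lacks required field '{key}'")
        truth = None
        if "truth" in f:
            truth = GroundTruth(
                start_s=f["truth/vl_start_s"][()],
                peak_s=f["truth/pk_s"][()],
                end_s=f["truth/vl_end_s"][()],
            )
        return RecordingBundle(
            subject_id=str(f.attrs.get("subject_id", Path(path).stem)),
            i=f["radar/i"][()],
            q=f["radar/q"][()],
            fs_radar=float(f["radar"].attrs["fs"]),
            reference=f["reference/z"][()],
            fs_ref=float(f["reference"].attrs["fs"]),
            scenario=str(f.attrs.get("scenario", "resting")),
            provenance=str(path),
            truth=truth,
        )


# .mat variable names tried, in order, for the figshare-style deposit
_MAT_KEYS = {
    "i": ("radar_i", "radar_I", "I", "i"),
    "q": ("radar_q", "radar_Q", "Q", "q"),
    "z": ("tfm_z", "tfm_z0", "Z", "z", "impedance"),
}


def load_figshare_subject(path, scenario: str = "resting") -> RecordingBundle:
    """Load one resting-scenario subject from the public deposit layout.

    Accepts either this package's HDF5 container or a MATLAB ``.mat`` file
    with radar I/Q (2000 Hz) and thoracic impedance (100 Hz) variables.
    Only the resting scenario is supported; ECG/ICG/blood-pressure channels
    are ignored.
    """
    if scenario != "resting":
        raise NotImplementedError(
            f"scenario '{scenario}' is not supported; only 'resting' recordings "
            "are processed"
        )
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        bundle = read_recording(path)
    elif path.suffix.lower() == ".mat":
        from scipy.io import loadmat

        mat = loadmat(path, squeeze_me=True)

        def _get(role: str) -> np.ndarray:
            for key in _MAT_KEYS[role]:
                if key in mat:
                    return np.asarray(mat[key], float).ravel()
            raise ValueError(
                f"unknown .mat layout in {path}: missing a '{role}' variable "
                f"(tried {_MAT_KEYS[role]})"
            )

        bundle = RecordingBundle(
            subject_id=path.stem,
            i=_get("i"),
            q=_get("q"),
            fs_radar=float(mat.get("fs_radar", 2000.0)),
            reference=_get("z"),
            fs_ref=float(mat.get("fs_z", mat.get("fs_ref", 100.0))),
            provenance=str(path),
        )
    else:
        raise ValueError(f"unsupported container format: {path.suffix}")
    if not 540 <= bundle.duration_s <= 660:
        logger.info(
            "subject %s: duration %.0f s outside the nominal 600 +/- 60 s",
            bundle.subject_id, bundle.duration_s,
        )
    return bundle


@dataclass
class PipelineResult:
    """All per-subject artifacts of one processing run."""

    subject_id: str
    config_hash: str
    displacement_mm: np.ndarray
    radar_resp: pre.RespiratorySignal
    reference_resp: pre.RespiratorySignal
    radar_cycles: pd.DataFrame
    reference_cycles: pd.DataFrame
    radar_windows: pd.DataFrame
    reference_windows: pd.DataFrame


def _channel_windows(
    values: np.ndarray, fs: float, source: str, config: PipelineConfig, span_s: float
):
    sig = pre.normalize(
        pre.bandpass(
            values, fs,
            low_hz=config.band_low_hz, high_hz=config.band_high_hz,
            order=config.filter_order, zero_phase=config.zero_phase,
        ),
        fs=fs, source=source, band=(config.band_low_hz, config.band_high_hz),
    )
    seg = CycleSegmenter(
        fs=fs,
        prominence_factor=config.detection.prominence_factor,
        min_distance_s=config.detection.min_distance_s,
        min_width_s=config.detection.min_width_s,
        max_cycle_s=config.detection.max_cycle_s,
        exclude_margin_s=config.transient_margin_s,
    ).fit(sig.values)
    cycles = cycles_to_frame(seg.cycles_, seg.excluded_cycles_)
    windows = sliding_window_metrics(seg.cycles_, config.window, recording_span_s=span_s)
    windows.insert(1, "source", source)
    return sig, cycles, windows


def run_pipeline(bundle: RecordingBundle, config: PipelineConfig) -> PipelineResult:
    """Deterministic end-to-end processing of one recording pair.

    Radar chain: ellipse fit on the whole recording, I/Q correction,
    arctangent demodulation, unwrapping, phase-to-displacement; then both
    channels (displacement in mm, impedance in Ohm) go through the same
    bandpass -> z-score -> cycle segmentation -> windowed metrics chain at
    their native sampling rates.
    """
    span = bundle.duration_s
    if span < config.window.length_s:
        logger.warning(
            "subject %s: recording (%.0f s) shorter than one %.0f s window; "
            "window tables will be empty",
            bundle.subject_id, span, config.window.length_s,
        )

    iq = np.column_stack([bundle.i, bundle.q])
    corrector = dem.EllipseCorrector(min_arc_deg=config.min_arc_deg).fit(iq)
    phase = dem.ArctangentDemodulator(unwrap=True).transform(corrector.transform(iq))
    disp = dem.PhaseToDisplacement(
        wavelength_mm=config.wavelength_mm, sign=config.displacement_sign
    ).transform(phase)

    radar_resp, radar_cycles, radar_windows = _channel_windows(
        disp, bundle.fs_radar, "radar", config, span
    )
    ref_resp, ref_cycles, ref_windows = _channel_windows(
        bundle.reference, bundle.fs_ref, "reference", config, span
    )
    logger.info(
        "subject %s processed (config %s): %d radar / %d reference cycles",
        bundle.subject_id, config.config_hash,
        len(radar_cycles), len(ref_cycles),
    )
    return PipelineResult(
        subject_id=bundle.subject_id,
        config_hash=config.config_hash,
        displacement_mm=disp,
        radar_resp=radar_resp,
        reference_resp=ref_resp,
        radar_cycles=radar_cycles,
        reference_cycles=ref_cycles,
        radar_windows=radar_windows,
        reference_windows=ref_windows,
    )


def pair_windows(results: list[PipelineResult]) -> pd.DataFrame:
    """Long-form paired table over windows valid in *both* modalities.

    Columns: subject, metric (RR | TI | TE | IE), window_start_s, radar,
    reference -- the unit of the concordance/equivalence analysis.
    """
    cols = {
        "RR": "mean_rr_brpm",
        "TI": "mean_ti_s",
        "TE": "mean_te_s",
        "IE": "mean_ie_ratio",
    }
    rows = []
    for res in results:
        merged = res.radar_windows.merge(
            res.reference_windows, on="window_start_s", suffixes=("_radar", "_ref")
        )
        both = merged[merged.valid_radar & merged.valid_ref]
        for metric, col in cols.items():
            for _, r in both.iterrows():
                rows.append(
                    dict(
                        subject=res.subject_id,
                        metric=metric,
                        window_start_s=r.window_start_s,
                        radar=r[f"{col}_radar"],
                        reference=r[f"{col}_ref"],
                    )
                )
    return pd.DataFrame(rows, columns=["subject", "metric", "window_start_s", "radar", "reference"])
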
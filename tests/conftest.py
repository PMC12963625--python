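import numpy as np
import pytest

import respirad as rr
from respirad.io import RecordingBundle, run_pipeline


def bundle_from(rec: rr.SyntheticRecording, subject_id: str = "s1") -> RecordingBundle:
    return RecordingBundle(
        subject_id=subject_id,
        i=rec.i,
        q=rec.q,
        fs_radar=rec.fs_radar,
        reference=rec.reference_ohm,
        fs_ref=rec.fs_ref,
        truth=rec.truth,
    )


@pytest.fixture(scope="session")
def to_bundle():
    """Session helper turning a SyntheticRecording into a RecordingBundle."""
    return bundle_from


@pytest.fixture(scope="session")
def noiseless_rec() -> rr.SyntheticRecording:
    """5-min recording with ideal channels: no noise, no cardiac ripple."""
    cfg = rr.SimulationConfig(
        duration_s=300.0, noise_std=0.0, ref_noise_std=0.0, cardiac_amp_mm=0.0
    )
    return rr.simulate_recording(cfg, seed=3)


@pytest.fixture(scope="session")
def noiseless_result(noiseless_rec):
    return run_pipeline(bundle_from(noiseless_rec), rr.PipelineConfig())


@pytest.fixture(scope="session")
def snr20_rec() -> rr.SyntheticRecording:
    """10-min recording at the default 20 dB I/Q SNR with cardiac ripple."""
    return rr.simulate_recording(rr.SimulationConfig(), seed=11)


@pytest.fixture(scope="session")
def snr20_result(snr20_rec):
    return run_pipeline(bundle_from(snr20_rec), rr.PipelineConfig())
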
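import numpy as np
import pytest

from calyxsf.datatypes import CellGroundTruth, SynapticInput, TraceRecording
from calyxsf.synth.traces import _colored_noise


def make_cell(rors, latencies=None, thresholds=None, calyceal=False, trial_cv=0.1,
              activation_prob=0.95, soma_radius=3.0, age=4.0, cell_id="cell",
              prespike_amp=0.30, latency_cv=0.023, beta=6.8, alpha=0.35):
    """Hand-built ground-truth cell with controllable per-input parameters."""
    rors = list(rors)
    latencies = latencies or [1.8 + 0.9 * j for j in range(len(rors))]
    thresholds = thresholds or [0.10 + 0.06 * j for j in range(len(rors))]
    inputs = [
        SynapticInput(
            true_ror=float(r),
            recruitment_threshold=float(th),
            activation_prob=activation_prob,
            latency_mean=float(lat),
            latency_cv=latency_cv,
            trial_cv=trial_cv,
            is_calyceal=calyceal and j == 0,
            prespike_amp=prespike_amp if (calyceal and j == 0) else None,
        )
        for j, (r, lat, th) in enumerate(zip(rors, latencies, thresholds))
    ]
    areas = (np.asarray(rors, float) / beta) ** (1.0 / alpha)
    return CellGroundTruth(
        cell_id=cell_id, age=age, inputs=inputs,
        true_contact_areas=areas, soma_radius=soma_radius,
    )


def noise_trace(duration_s=1.0, rms_mv=0.1, fs=25000.0, seed=0, rest=-70.0, corr_ms=1.0):
    """Flat trace at rest with band-limited membrane noise.

    The default 1 ms correlation time reflects membrane filtering: voltage
    noise in a cell is slow compared to an EPSP rising phase."""
    rng = np.random.default_rng(seed)
    n = int(duration_s * fs)
    v = rest + _colored_noise(rng, n, fs, rms_mv, corr_ms=corr_ms)
    return TraceRecording(samples=v, sampling_rate=fs, resting_potential=rest)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
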
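"""Synthetic membrane-potential traces.

Events are difference-of-exponentials EPSP waveforms (rise 0.4 ms, decay
3 ms) whose onset is additionally smoothed by a narrow Gaussian so that the
maximal rate of rise -- the strength measure used throughout -- is a
well-defined, smooth extremum rather than an onset kink. The waveform
amplitude is solved numerically on the sampled grid so that the maximum
dV/dt equals the requested per-trial RoR exactly.

Postsynaptic APs are inserted as stereotyped waveforms whenever the summed
depolarization crosses a configurable threshold; the ground-truth RoR of the
underlying EPSP is recorded pre-AP, so detectors must cope with truncated
rising phases exactly as in vivo.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.ndimage import gaussian_filter1d

from ..datatypes import CellGroundTruth, Stimulus, TraceRecording
from ..errors import ParameterError, ProtocolError

__all__ = ["epsp_kernel", "prespike_kernel", "synth_stim_experiment", "synth_spont_activity"]

DEFAULT_FS = 25000.0
TAU_RISE = 0.4e-3  # s
TAU_DECAY = 3.0e-3  # s
ONSET_SIGMA = 0.12e-3  # s; onset smoothing of the kernel
AP_PEAK = 10.0  # mV, stereotyped AP overshoot
AP_REFRACTORY = 3.0e-3  # s


def epsp_kernel(
    fs: float = DEFAULT_FS,
    tau_rise: float = TAU_RISE,
    tau_decay: float = TAU_DECAY,
    onset_sigma: float = ONSET_SIGMA,
    duration: float = 0.025,
):
    """Unit-RoR EPSP waveform.

    Returns ``(kernel, onset_index)`` where ``kernel`` is in mV for a target
    rate of rise of 1 V/s (max of the sampled central-difference derivative
    equals 1 V/s) and ``onset_index`` marks the nominal event onset.
    """
    n_pre = int(math.ceil(5 * onset_sigma * fs))
    n = n_pre + int(round(duration * fs))
    t = (np.arange(n) - n_pre) / fs
    k = np.where(t >= 0, np.exp(-np.maximum(t, 0) / tau_decay) - np.exp(-np.maximum(t, 0) / tau_rise), 0.0)
    if onset_sigma > 0:
        k = gaussian_filter1d(k, onset_sigma * fs, mode="constant")
    grad_v_per_s = np.gradient(k) * fs / 1000.0  # mV/sample -> V/s
    k /= grad_v_per_s.max()
    return k, n_pre


def prespike_kernel(fs: float = DEFAULT_FS, width: float = 0.5e-3):
    """Biphasic derivative-of-Gaussian prespike, unit peak-to-peak (mV).

    ``width`` is the full biphasic span (about 4 sigma). The positive lobe
    leads, as for a presynaptic AP capacitively coupled into the soma.
    """
    sigma = width / 4.0
    half = int(math.ceil(3 * sigma * fs))
    t = (np.arange(2 * half + 1) - half) / fs
    w = -(t / sigma) * np.exp(-0.5 * (t / sigma) ** 2)
    return w / (w.max() - w.min()), half


def _ap_waveform(fs: float):
    """Additive stereotyped AP shape: unit-height spike followed by a small
    after-hyperpolarization, decaying back to the synaptic envelope. The
    waveform is long enough for the AHP to decay smoothly to zero."""
    n = int(round(14e-3 * fs))
    t = np.arange(n) / fs
    spike = np.exp(-0.5 * ((t - 0.3e-3) / 0.12e-3) ** 2)
    ramp = 1.0 - np.exp(-np.maximum(t - 0.4e-3, 0) / 0.2e-3)
    ahp = -0.08 * ramp * np.exp(-np.maximum(t - 0.4e-3, 0) / 2e-3)
    return spike + ahp


def _colored_noise(rng, n: int, fs: float, sd: float, corr_ms: float = 0.4):
    """Band-limited membrane noise: white Gaussian smoothed to a correlation
    time of ``corr_ms`` and rescaled to RMS ``sd`` (mV)."""
    if n == 0 or sd <= 0:
        return np.zeros(n)
    w = rng.standard_normal(n)
    w = gaussian_filter1d(w, corr_ms * 1e-3 * fs)
    s = w.std()
    return w * (sd / s) if s > 0 else w


def _insert_aps(v: np.ndarray, fs: float, threshold: float, peak: float,
                refractory: float = AP_REFRACTORY):
    """Insert stereotyped APs wherever ``v`` crosses ``threshold`` (mV)
    upward, honouring a refractory period. ``v``, ``threshold`` and ``peak``
    share one reference frame. Mutates ``v``; returns AP times."""
    wave = _ap_waveform(fs)
    n_ref = int(round(refractory * fs))
    times = []
    i = 1
    while i < v.size:
        if v[i] >= threshold and v[i - 1] < threshold:
            amp = peak - v[i]
            if amp > 0:
                end = min(v.size, i + wave.size)
                v[i:end] += amp * wave[: end - i]
            times.append(i / fs)
            i += n_ref
        else:
            i += 1
    return times


def _add_event(v, kernel, idx, amplitude):
    if idx >= v.size:
        return
    lo = max(idx, 0)
    end = min(v.size, idx + kernel.size)
    v[lo:end] += amplitude * kernel[lo - idx : end - idx]


def _trial_ror(rng, true_ror: float, cv: float) -> float:
    if cv <= 0:
        return true_ror
    sigma = math.sqrt(math.log(1 + cv**2))
    return true_ror * math.exp(rng.normal(-0.5 * sigma**2, sigma))


def synth_stim_experiment(
    cell: CellGroundTruth,
    intensities,
    sweeps_per_level: int = 30,
    seed: int = 0,
    fs: float = DEFAULT_FS,
    sweep_duration: float = 0.040,
    stim_time: float = 0.005,
    resting_potential: float = -70.0,
    noise_sd: float = 0.05,
    ap_threshold_depol: float = 12.0,
    artefact_amp: float = 4.0,
) -> TraceRecording:
    """Simulate an afferent-stimulation recruitment experiment.

    Sweeps of ``sweep_duration`` are concatenated, one stimulus per sweep at
    ``stim_time``, ``sweeps_per_level`` sweeps per intensity, ascending. Every
    input whose recruitment threshold is at or below the stimulus intensity
    fires with its activation probability at a jittered latency; calyceal
    inputs contribute a biphasic prespike before their EPSP. Ground-truth
    event and AP tables are attached to ``metadata``.
    """
    intensities = list(intensities)
    if not intensities:
        raise ProtocolError("at least one stimulation intensity is required")
    if any(b < a for a, b in zip(intensities, intensities[1:])):
        raise ProtocolError("intensities must be sorted ascending")
    if sweeps_per_level < 1:
        raise ProtocolError("sweeps_per_level must be >= 1")

    rng = np.random.default_rng(seed)
    n_sweeps = len(intensities) * sweeps_per_level
    n_per_sweep = int(round(sweep_duration * fs))
    n_total = n_sweeps * n_per_sweep
    v = np.zeros(n_total)

    kernel, k_onset = epsp_kernel(fs)
    pre_kernel, pre_half = prespike_kernel(fs)
    pre_lead = 0.45e-3  # s between prespike centre and EPSP onset (synaptic delay)

    stimuli = []
    gt_events = []
    sweep = 0
    for intensity in intensities:
        for _ in range(sweeps_per_level):
            t0 = sweep * sweep_duration + stim_time
            stimuli.append(Stimulus(t0, float(intensity)))
            for j, inp in enumerate(cell.inputs):
                if inp.recruitment_threshold > intensity:
                    continue
                if rng.random() >= inp.activation_prob:
                    continue
                latency = rng.normal(inp.latency_mean, inp.latency_cv * inp.latency_mean)
                latency = max(latency, 1.05)  # ms; stay inside the evoked window
                onset = t0 + latency * 1e-3
                ror = _trial_ror(rng, inp.true_ror, inp.trial_cv)
                idx = int(round(onset * fs)) - k_onset
                _add_event(v, kernel, idx, ror)
                if inp.is_calyceal and inp.prespike_amp:
                    c = int(round((onset - pre_lead) * fs)) - pre_half
                    _add_event(v, pre_kernel, c, inp.prespike_amp)
                gt_events.append(
                    dict(
                        time_s=onset,
                        input_index=j,
                        ror=float(ror),
                        sweep=sweep,
                        intensity=float(intensity),
                        latency_ms=float(latency),
                        prespike=bool(inp.is_calyceal),
                    )
                )
            sweep += 1

    # stimulus artefacts (brief biphasic capacitive transients)
    art = artefact_amp * np.array([1.0, -0.7, 0.3, -0.1])
    for s in stimuli:
        i = int(round(s.time_s * fs))
        end = min(n_total, i + art.size)
        v[i:end] += art[: end - i]

    v += _colored_noise(rng, n_total, fs, noise_sd)
    ap_times = _insert_aps(v, fs, ap_threshold_depol, AP_PEAK - resting_potential)
    v += resting_potential

    trace = TraceRecording(
        samples=v,
        sampling_rate=fs,
        stimuli=stimuli,
        resting_potential=resting_potential,
        metadata=dict(
            seed=seed,
            kind="stimulation",
            cell_id=cell.cell_id,
            sweep_duration_s=sweep_duration,
            stim_time_in_sweep_s=stim_time,
            sweeps_per_level=sweeps_per_level,
            ground_truth_events=gt_events,
            ground_truth_ap_times=ap_times,
            ap_threshold_mV=resting_potential + ap_threshold_depol,
        ),
    )
    return trace


def synth_spont_activity(
    cell: CellGroundTruth,
    duration: float,
    burst_rate: float = 0.2,
    within_burst_rate: float = 10.0,
    seed: int = 0,
    fs: float = DEFAULT_FS,
    burst_duration: float = 1.0,
    resting_potential: float = -70.0,
    noise_sd: float = 0.05,
    ap_threshold_depol: float = 12.0,
) -> TraceRecording:
    """Simulate spontaneous bursting activity.

    Burst onsets form a Poisson process at ``burst_rate``; within each burst
    every input emits events as a Poisson process at ``within_burst_rate``
    with per-trial RoR jitter. The burst parametrization is a free emulation
    of pre-hearing cochlea-driven activity, not a measured quantity.
    """
    if duration < 0:
        raise ParameterError("duration must be >= 0")
    rng = np.random.default_rng(seed)
    n_total = int(round(duration * fs))
    v = np.zeros(n_total)
    kernel, k_onset = epsp_kernel(fs)
    pre_kernel, pre_half = prespike_kernel(fs)
    pre_lead = 0.45e-3

    gt_events = []
    if n_total and burst_rate > 0 and cell.inputs:
        n_bursts = rng.poisson(burst_rate * duration)
        starts = np.sort(rng.uniform(0, max(duration - burst_duration, 0), size=n_bursts))
        for b0 in starts:
            for j, inp in enumerate(cell.inputs):
                n_ev = rng.poisson(within_burst_rate * burst_duration)
                for t_ev in np.sort(rng.uniform(b0, b0 + burst_duration, size=n_ev)):
                    ror = _trial_ror(rng, inp.true_ror, inp.trial_cv)
                    idx = int(round(t_ev * fs)) - k_onset
                    _add_event(v, kernel, idx, ror)
                    if inp.is_calyceal and inp.prespike_amp:
                        c = int(round((t_ev - pre_lead) * fs)) - pre_half
                        _add_event(v, pre_kernel, c, inp.prespike_amp)
                    gt_events.append(
                        dict(time_s=float(t_ev), input_index=j, ror=float(ror),
                             prespike=bool(inp.is_calyceal))
                    )

    v += _colored_noise(rng, n_total, fs, noise_sd)
    ap_times = _insert_aps(v, fs, ap_threshold_depol, AP_PEAK - resting_potential) if n_total else []
    v += resting_potential

    return TraceRecording(
        samples=v,
        sampling_rate=fs,
        stimuli=[],
        resting_potential=resting_potential,
        metadata=dict(
            seed=seed,
            kind="spontaneous",
            cell_id=cell.cell_id,
            ground_truth_events=gt_events,
            ground_truth_ap_times=ap_times,
            ap_threshold_mV=resting_potential + ap_threshold_depol,
        ),
    )
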
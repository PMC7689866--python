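"""Event detection in membrane-potential traces.

EPSPs are found as peaks of the Savitzky-Golay-smoothed dV/dt above a
minimal rate of rise (default 0.7 V/s), with onsets placed at the last
positive maximum of the third derivative before the dV/dt peak -- the
third-derivative onset criterion standard for in vivo EPSP analysis.
Stimulus artefacts are blanked, AP upstrokes excluded, and the measured RoR
of an EPSP that triggers an AP is truncated at the AP takeoff so the
underlying synaptic drive is estimated pre-AP.
"""

from __future__ import annotations

import bisect

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .datatypes import EPSPEvent, TraceRecording
from .errors import ConfigurationError, InsufficientDataError, NoiseEstimationError

__all__ = [
    "detect_epsps",
    "classify_evoked",
    "detect_aps",
    "detect_prespikes",
    "prespike_present",
    "compute_pap",
]

AP_DETECT_THRESHOLD = -20.0  # mV
AP_MIN_DVDT = 20.0  # V/s
AP_REFRACTORY_MS = 2.0
MAX_EPSP_ROR = 100.0  # V/s; dV/dt peaks above this are AP upstrokes


def _smoothed(trace: TraceRecording, sg_window_ms: float = 0.24):
    """Smoothed voltage, first and third derivatives (V/s and a.u.)."""
    fs = trace.sampling_rate
    win = int(round(sg_window_ms * 1e-3 * fs))
    win += (win + 1) % 2  # make odd
    if win < 5:
        raise ConfigurationError(
            f"sampling rate {fs} Hz too low to resolve a {sg_window_ms} ms smoothing window"
        )
    v = trace.samples
    if v.size < win:
        raise ConfigurationError("trace shorter than the smoothing window")
    v_s = savgol_filter(v, win, 3)
    dv = savgol_filter(v, win, 3, deriv=1, delta=1.0 / fs) / 1000.0  # -> V/s
    d3 = savgol_filter(v, win, 3, deriv=3, delta=1.0 / fs)
    return v_s, dv, d3


def detect_aps(
    trace: TraceRecording,
    threshold: float = AP_DETECT_THRESHOLD,
    min_dvdt: float = AP_MIN_DVDT,
    refractory_ms: float = AP_REFRACTORY_MS,
) -> np.ndarray:
    """Times (s) where the voltage crosses ``threshold`` upward with
    dV/dt > ``min_dvdt`` V/s; crossings within the refractory window merge."""
    v_s, dv, _ = _smoothed(trace)
    fs = trace.sampling_rate
    above = v_s >= threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    crossings = crossings[dv[crossings] > min_dvdt]
    if crossings.size == 0:
        return np.zeros(0)
    keep = [crossings[0]]
    n_ref = refractory_ms * 1e-3 * fs
    for c in crossings[1:]:
        if c - keep[-1] > n_ref:
            keep.append(c)
    return np.asarray(keep) / fs


def _onset_index(d3: np.ndarray, dv: np.ndarray, peak: int, search: int) -> int:
    """Onset = last positive third-derivative maximum before the dV/dt peak."""
    lo = max(peak - search, 0)
    if peak - lo < 3:
        return lo
    seg = d3[lo:peak]
    cand, _ = find_peaks(seg, height=0.1 * seg.max() if seg.max() > 0 else 0.0)
    if cand.size:
        return lo + int(cand[-1])
    # fallback: last sample before the peak with negligible slope
    slow = np.flatnonzero(dv[lo:peak] < 0.05 * dv[peak])
    return lo + int(slow[-1]) if slow.size else lo


def detect_epsps(
    trace: TraceRecording,
    min_ror: float = 0.7,
    min_amplitude: float = 0.2,
    sg_window_ms: float = 0.24,
    blank_ms: float = 0.3,
    min_separation_ms: float = 0.6,
    ap_threshold: float = AP_DETECT_THRESHOLD,
    onset_search_ms: float = 1.5,
    ap_assign_ms: float = 2.5,
    ap_blank_ms: float = 4.5,
) -> list[EPSPEvent]:
    """Detect EPSPs in a trace.

    Parameters follow the conventions of in vivo MNTB analysis: events whose
    maximal smoothed dV/dt does not exceed ``min_ror`` (V/s) are discarded,
    a post-stimulus window of ``blank_ms`` is blanked against artefacts, and
    events closer than ``min_separation_ms`` merge into one.
    """
    if min_ror <= 0:
        raise ConfigurationError("min_ror must be positive")
    fs = trace.sampling_rate
    v_s, dv, d3 = _smoothed(trace, sg_window_ms)
    n = v_s.size

    ap_times = detect_aps(trace, threshold=ap_threshold)
    ap_idx = np.round(ap_times * fs).astype(int)

    dv_for_peaks = dv.copy()
    # the onset detector must not see artefact or upstroke transients
    # either: their third derivatives dwarf every EPSP onset
    d3_for_onset = d3.copy()
    # blank stimulus artefacts
    n_blank = int(round(blank_ms * 1e-3 * fs)) + 1
    for s in trace.stimuli:
        i = int(round(s.time_s * fs))
        dv_for_peaks[max(i - 2, 0) : i + n_blank] = 0.0
        # the smoothing kernel smears the artefact a few samples past the
        # blank; keep its third-derivative ringing out of the onset search
        d3_for_onset[max(i - 6, 0) : i + n_blank + 6] = 0.0
    # blank AP upstrokes and refractory tails (takeoff precedes the
    # threshold crossing by a fraction of a millisecond)
    # the exclusion extends past the refractory period: the repolarization
    # and AHP-recovery slopes after a spike mimic slow EPSP rises
    n_ref = int(round(ap_blank_ms * 1e-3 * fs))
    n_take = int(round(0.2e-3 * fs))
    for a in ap_idx:
        dv_for_peaks[a : a + n_ref] = 0.0
        d3_for_onset[max(a - n_take, 0) : a + n_ref] = 0.0

    dist = max(int(round(min_separation_ms * 1e-3 * fs)), 1)
    peaks, _ = find_peaks(dv_for_peaks, height=min_ror)
    # reject AP-upstroke peaks BEFORE enforcing the separation, so a
    # rejected upstroke cannot suppress the EPSP peak that caused it:
    # upstrokes are implausibly fast or already depolarized near threshold
    peaks = peaks[(dv_for_peaks[peaks] <= MAX_EPSP_ROR) & (v_s[peaks] < ap_threshold - 10.0)]
    # greedy minimum-separation: keep larger peaks, drop neighbours
    order = np.argsort(dv_for_peaks[peaks])[::-1]
    chosen: list[int] = []
    for k in order:
        p = int(peaks[k])
        j = bisect.bisect_left(chosen, p)
        if (j > 0 and p - chosen[j - 1] < dist) or (j < len(chosen) and chosen[j] - p < dist):
            continue
        chosen.insert(j, p)
    peaks = np.asarray(chosen, dtype=int)

    search = int(round(onset_search_ms * 1e-3 * fs))
    events: list[EPSPEvent] = []
    last_onset = -1
    for pk in peaks:
        onset = _onset_index(d3_for_onset, dv, pk, search)
        if onset <= last_onset:
            onset = last_onset + 1
        # segment end: voltage peak after the dV/dt peak, or AP takeoff
        end = pk
        while end + 1 < n and v_s[end + 1] >= v_s[end]:
            end += 1
        nxt = ap_idx[(ap_idx > onset) & (ap_idx <= pk + int(ap_assign_ms * 1e-3 * fs))]
        triggered = nxt.size > 0
        if triggered:
            a = int(nxt[0])
            # truncate at the dV/dt valley between EPSP rise and AP upstroke
            # (searched after the dV/dt peak; the pre-onset dip is irrelevant)
            valley = pk + int(np.argmin(dv[pk : a + 1])) if a > pk else max(a - 1, onset + 1)
            end = min(end, valley)
        end = max(end, onset + 1)
        ror = float(np.max(dv[onset : end + 1]))
        # events riding a recovering baseline (burst envelope, AHP tail)
        # carry its slope; subtract the pre-onset slope when clearly positive
        b0 = max(onset - int(round(0.6e-3 * fs)), 0)
        b1 = max(onset - int(round(0.1e-3 * fs)), b0 + 1)
        base_slope = float(np.median(dv[b0:b1]))
        if 0 < base_slope < 0.5 * ror:
            ror -= base_slope
        amplitude = float(v_s[min(end, n - 1)] - v_s[onset])
        if ror <= min_ror or amplitude < min_amplitude:
            continue
        events.append(
            EPSPEvent(
                onset_s=onset / fs,
                rate_of_rise=ror,
                amplitude=max(amplitude, 0.0),
                triggered_ap=bool(triggered),
            )
        )
        last_onset = onset

    # Recover EPSPs fully merged into an AP takeoff: a very strong input can
    # reach AP threshold while its dV/dt is still rising, leaving no clean
    # dV/dt maximum below the upstroke filters. For APs without a preceding
    # event, measure the rise up to just before the threshold crossing.
    n_gap = max(int(round(0.15e-3 * fs)), 1)
    covered = [ev.onset_s for ev in events]
    for a in ap_idx:
        t_a = a / fs
        if any(t_a - 3e-3 <= t0 <= t_a for t0 in covered):
            continue
        pk = max(a - n_gap, 1)
        onset = _onset_index(d3_for_onset, dv, pk, search)
        if pk - onset < 2:
            continue
        # the EPSP's dV/dt maximum sits early in the rise; restrict the
        # window to limit upstroke contamination of the measured RoR
        stop = min(pk, onset + int(round(0.35e-3 * fs)))
        if stop - onset < 3:
            continue
        ror = float(np.max(dv[onset:stop]))
        amplitude = float(v_s[pk] - v_s[onset])
        if ror > min_ror and amplitude >= min_amplitude and ror <= MAX_EPSP_ROR:
            events.append(
                EPSPEvent(
                    onset_s=onset / fs,
                    rate_of_rise=ror,
                    amplitude=amplitude,
                    triggered_ap=True,
                )
            )
    events.sort(key=lambda e: e.onset_s)
    return events


def classify_evoked(
    events: list[EPSPEvent],
    trace: TraceRecording,
    window_ms: tuple[float, float] = (1.0, 8.0),
) -> list[EPSPEvent]:
    """Assign latencies from the nearest preceding stimulus and flag events
    inside the evoked window (1, 8] ms. Mutates and returns ``events``."""
    if not trace.stimuli:
        return events
    stim_t = np.array([s.time_s for s in trace.stimuli])
    stim_i = np.array([s.intensity_mA for s in trace.stimuli])
    lo, hi = window_ms
    for ev in events:
        k = int(np.searchsorted(stim_t, ev.onset_s, side="right")) - 1
        if k < 0:
            ev.latency_ms, ev.evoked = None, False
            continue
        lat = (ev.onset_s - stim_t[k]) * 1e3
        ev.latency_ms = float(lat)
        ev.evoked = bool(lo < lat <= hi)
        if ev.evoked:
            ev.stimulus_intensity = float(stim_i[k])
            ev.stimulus_index = k
    return events


def _event_free_mask(trace, events, ap_times, pad_pre_ms=2.0, pad_post_ms=10.0):
    fs = trace.sampling_rate
    mask = np.ones(trace.samples.size, dtype=bool)

    def _block(t0, t1):
        mask[max(int(t0 * fs), 0) : max(int(t1 * fs), 0)] = False

    for ev in events:
        _block(ev.onset_s - pad_pre_ms * 1e-3, ev.onset_s + pad_post_ms * 1e-3)
    for a in np.atleast_1d(ap_times):
        _block(a - 1e-3, a + 5e-3)
    for s in trace.stimuli:
        _block(s.time_s - 0.2e-3, s.time_s + 1.5e-3)
    return mask


def _detrended_p2p(v_seg: np.ndarray):
    """Peak-to-peak of a segment after removing a linear trend."""
    x = np.arange(v_seg.size, dtype=float)
    coef = np.polyfit(x, v_seg, 1)
    r = v_seg - np.polyval(coef, x)
    return float(r.max() - r.min()), r


def detect_prespikes(
    trace: TraceRecording,
    events: list[EPSPEvent],
    window_ms: float = 1.5,
    k_sigma: float = 3.0,
) -> list[EPSPEvent]:
    """Annotate events with prespike amplitudes.

    A prespike is a small biphasic deflection in the ``window_ms`` before the
    EPSP onset, generated by the presynaptic AP of a giant terminal. The
    automated criterion: the line-detrended pre-onset segment must exceed
    ``k_sigma`` times the baseline noise SD peak-to-peak, deflecting both
    above and below the trend. Amplitude is reported peak-to-peak in mV.
    """
    fs = trace.sampling_rate
    v_s, _, _ = _smoothed(trace)
    ap_times = detect_aps(trace)
    free = _event_free_mask(trace, events, ap_times)
    n_win = max(int(round(window_ms * 1e-3 * fs)), 4)

    # baseline noise SD: robust SD of the slow-trend-removed voltage over
    # event-free samples
    idx = np.flatnonzero(free)
    if idx.size < 5 * n_win:
        raise NoiseEstimationError("no event-free baseline available")
    from scipy.ndimage import gaussian_filter1d

    resid = v_s - gaussian_filter1d(v_s, 2e-3 * fs)
    r_free = resid[free]
    sigma = float(1.4826 * np.median(np.abs(r_free - np.median(r_free))))
    if sigma <= 0:
        raise NoiseEstimationError("degenerate baseline noise estimate")

    _, dv, _ = _smoothed(trace)
    stim_idx = np.array([int(round(s.time_s * fs)) for s in trace.stimuli])
    n_art = int(round(0.6e-3 * fs))  # artefact + smoothing spill

    def _clamp_to_artefacts(start, end):
        if stim_idx.size:
            k = np.searchsorted(stim_idx, end) - 1
            if k >= 0:
                start = max(start, int(stim_idx[k]) + n_art)
        return start

    n_tr = int(round(0.6e-3 * fs))  # trough search before the rise
    n_pk = int(round(0.5e-3 * fs))  # peak search before the trough
    n_base = n_win  # baseline trend segment, set by window_ms
    for ev in events:
        onset = int(round(ev.onset_s * fs))
        # locate the rising phase: the prespike trough sits right before it
        hi = min(onset + int(round(0.8e-3 * fs)), v_s.size - 1)
        if hi <= onset:
            ev.prespike_amplitude = None
            continue
        pk = onset + int(np.argmax(dv[onset:hi]))
        back = np.flatnonzero(dv[onset : pk + 1] < 0.25 * dv[pk])
        rise_start = onset + (int(back[-1]) if back.size else 0)
        t0 = _clamp_to_artefacts(max(rise_start - n_tr - n_pk - n_base, 0), rise_start)
        if rise_start - t0 < n_tr + 6:
            ev.prespike_amplitude = None
            continue
        # baseline trend from the pre-prespike segment when available,
        # otherwise a constant level from the earliest free samples
        # peak-to-peak is read from the raw trace: the smoothing that aids
        # event timing attenuates a deflection only ~0.5 ms wide
        v_raw = trace.samples
        b_end = rise_start - n_tr - n_pk
        x_all = np.arange(t0, rise_start + 1, dtype=float)
        if b_end - t0 >= 6:
            xb = np.arange(t0, b_end, dtype=float)
            coef = np.polyfit(xb, v_raw[t0:b_end], 1)
            r = v_raw[t0 : rise_start + 1] - np.polyval(coef, x_all)
        else:
            level = float(np.median(v_raw[t0 : t0 + max(4, (rise_start - t0) // 3)]))
            r = v_raw[t0 : rise_start + 1] - level
        tr_lo = rise_start - n_tr - t0
        t_tr = tr_lo + int(np.argmin(r[tr_lo:]))
        p_lo = max(t_tr - n_pk, 0)
        peak = float(r[p_lo : t_tr + 1].max())
        trough = float(r[t_tr])
        p2p = peak - trough
        biphasic = peak > 1.2 * sigma and trough < -1.2 * sigma
        ev.prespike_amplitude = p2p if (p2p > k_sigma * sigma and biphasic) else None
    return events


def prespike_present(events: list[EPSPEvent], min_fraction: float = 0.5) -> bool:
    """Per-input presence rule: a prespike must be detected in at least
    ``min_fraction`` of the input's events."""
    if not events:
        return False
    hits = sum(1 for e in events if e.prespike_amplitude is not None)
    return hits / len(events) >= min_fraction


def compute_pap(events: list[EPSPEvent], ap_times, window_ms: float = 2.0) -> float:
    """Fraction of an input's EPSPs followed by a postsynaptic AP within
    ``window_ms`` of onset (the input's synaptic efficacy, P_AP)."""
    if not events:
        raise InsufficientDataError("P_AP undefined for an input with zero events")
    ap_times = np.sort(np.atleast_1d(np.asarray(ap_times, dtype=float)))
    hits = 0
    for ev in events:
        k = np.searchsorted(ap_times, ev.onset_s, side="left")
        if k < ap_times.size and (ap_times[k] - ev.onset_s) * 1e3 <= window_ms:
            hits += 1
    return hits / len(events)
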
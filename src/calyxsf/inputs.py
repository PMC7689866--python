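"""Decomposition of EPSPs into discrete synaptic inputs.

Evoked EPSPs are grouped by stimulation intensity; a recruitment transition
between consecutive intensities is flagged as a new input when the summed
Welch t of latency and rate of rise exceeds 6 AND the mean RoR increases by
more than 20%. A flagged transition whose response rate jumps by more than
20 percentage points with a latency t below 2 is instead classified as an
activation-probability shift of an existing input. New-input RoRs are
deconvolved by subtracting previously identified inputs of similar latency
(+-0.5 ms), and every candidate must be corroborated by spontaneous EPSPs of
similar RoR. Additional inputs are read off the modes of the spontaneous
RoR distribution (log-scale KDE), which is how strong inputs that were never
electrically recruited are recovered.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .datatypes import CellInputs, EPSPEvent, InputEstimate, IntensityGroup, TraceRecording
from .detect import classify_evoked, compute_pap, detect_aps, detect_epsps, detect_prespikes, prespike_present
from .errors import InsufficientDataError

__all__ = [
    "welch_t",
    "group_by_intensity",
    "latency_domains",
    "scan_recruitment",
    "deconvolve_ror",
    "spont_crosscheck",
    "spont_peak_inputs",
    "assemble_cell",
    "identify_inputs",
    "refractory_violations",
]

STRONG_THRESHOLD = 10.0  # V/s


def welch_t(x, y) -> float:
    """|t| of Welch's unequal-variance t statistic."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("Welch t needs at least 2 values per sample")
    se2 = x.var(ddof=1) / x.size + y.var(ddof=1) / y.size
    if se2 == 0:
        return 0.0
    return abs(float((x.mean() - y.mean()) / math.sqrt(se2)))


def group_by_intensity(events: list[EPSPEvent], trace: TraceRecording) -> list[IntensityGroup]:
    """Pool evoked events per stimulation intensity (ascending).

    Response rates are counted against the number of sweeps (stimuli)
    delivered at each intensity.
    """
    sweeps_per_intensity: dict[float, int] = {}
    for s in trace.stimuli:
        sweeps_per_intensity[s.intensity_mA] = sweeps_per_intensity.get(s.intensity_mA, 0) + 1
    groups = []
    for intensity in sorted(sweeps_per_intensity):
        evs = [e for e in events if e.evoked and e.stimulus_intensity == intensity]
        responding = len({e.stimulus_index for e in evs})
        groups.append(
            IntensityGroup(
                intensity=intensity,
                latencies=np.array([e.latency_ms for e in evs]),
                rors=np.array([e.rate_of_rise for e in evs]),
                n_sweeps=sweeps_per_intensity[intensity],
                n_responding=responding,
            )
        )
    return groups


def latency_domains(latencies, split_window=(3.0, 4.0), full=(1.0, 8.0)) -> list[tuple[float, float]]:
    """Split the evoked-latency axis into domains when bimodal.

    EPSP latencies fall into two populations (roughly 1-3 and 4-8 ms). When
    both are present, the recruitment scan is run per population, split at
    the KDE density minimum inside ``split_window``.
    """
    lat = np.asarray(latencies, float)
    lat = lat[(lat > full[0]) & (lat <= full[1])]
    if lat.size < 10 or np.ptp(lat) < 1e-6:
        return [full]
    kde = gaussian_kde(lat, bw_method="silverman")
    grid = np.linspace(full[0], full[1], 256)
    dens = kde(grid)
    in_win = (grid >= split_window[0]) & (grid <= split_window[1])
    if not in_win.any():
        return [full]
    k_min = np.flatnonzero(in_win)[np.argmin(dens[in_win])]
    d_split = dens[k_min]
    left = dens[: k_min + 1].max()
    right = dens[k_min:].max()
    # bimodal: clear peaks on both sides of the valley
    if left > 2.0 * d_split and right > 2.0 * d_split and (lat > grid[k_min]).sum() >= 5:
        return [(full[0], float(grid[k_min])), (float(grid[k_min]), full[1])]
    return [full]


def _restrict(group: IntensityGroup, domain) -> IntensityGroup:
    lo, hi = domain
    sel = (group.latencies > lo) & (group.latencies <= hi)
    return IntensityGroup(
        intensity=group.intensity,
        latencies=group.latencies[sel],
        rors=group.rors[sel],
        n_sweeps=group.n_sweeps,
        n_responding=int(sel.sum() and group.n_responding),
    )


def deconvolve_ror(new_group: IntensityGroup, known_inputs, latency_tol: float = 0.5):
    """RoR of a newly recruited input: the new group's mean RoR minus the
    mean RoRs of known inputs of similar latency (+- ``latency_tol`` ms).
    Returns None (candidate dropped, with a warning) if nothing remains."""
    overlap = sum(
        k["mean_ror"]
        for k in known_inputs
        if k.get("mean_latency") is not None
        and abs(k["mean_latency"] - new_group.mean_latency) <= latency_tol
    )
    ror = new_group.mean_ror - overlap
    if ror <= 0:
        warnings.warn("deconvolved RoR non-positive; degenerate candidate dropped", stacklevel=2)
        return None
    return float(ror)


def _ror_clusters(rors: np.ndarray, lats: np.ndarray, prominence_frac: float = 0.10) -> list[dict]:
    """Sub-cluster a group's events on log RoR (KDE modes).

    Evoked EPSPs are grouped by stimulus strength, latency AND rate of rise;
    within one intensity, event populations from different inputs appear as
    separate RoR modes. Each event joins its nearest mode in log space.
    """
    logs = np.log(rors)
    if rors.size < 2:
        return []
    if np.ptp(logs) < 1e-9 or rors.size < 4:
        centers = [float(np.median(logs))]
    else:
        # Silverman's rule on the full group over-smooths badly when one
        # giant mode inflates the spread; cap the bandwidth at the scale of
        # a single input's trial jitter (log-CV <= ~0.37)
        sd = logs.std(ddof=1)
        bw_abs = min(sd * (4.0 / 3.0 / logs.size) ** 0.2, 0.25)
        kde = gaussian_kde(logs, bw_method=bw_abs / max(sd, 1e-9))
        grid = np.linspace(logs.min() - 0.3, logs.max() + 0.3, 256)
        dens = kde(grid)
        pk, _ = find_peaks(dens, prominence=prominence_frac * dens.max())
        centers = [float(grid[k]) for k in pk] or [float(np.median(logs))]
    assign = np.argmin(np.abs(logs[:, None] - np.asarray(centers)[None, :]), axis=1)
    out = []
    for k in range(len(centers)):
        sel = assign == k
        if sel.sum() < 2:
            continue
        out.append(
            dict(
                mean_ror=float(rors[sel].mean()),
                mean_latency=float(lats[sel].mean()),
                n_events=int(sel.sum()),
            )
        )
    return out


def _matches_known(cluster: dict, known: list[dict], log_tol: float = math.log(1.6),
                   lat_tol: float = 0.6) -> bool:
    for c in known:
        if abs(math.log(cluster["mean_ror"] / c["mean_ror"])) > log_tol:
            continue
        if (
            c.get("mean_latency") is not None
            and cluster.get("mean_latency") is not None
            and abs(c["mean_latency"] - cluster["mean_latency"]) > lat_tol
        ):
            continue
        return True
    return False


def scan_recruitment(
    groups: list[IntensityGroup],
    t_sum_threshold: float = 6.0,
    min_increase: float = 0.20,
    latency_domain=None,
    prob_shift_rate_jump: float = 0.20,
    prob_shift_t_lat: float = 2.0,
    prob_shift_t_ror: float = 4.0,
    latency_tol: float = 0.5,
    unexplained_mode_min: float = 2.5,
) -> list[dict]:
    """Scan consecutive intensity groups for newly recruited inputs.

    The t-test gate works on the full per-intensity distributions: a new
    input is flagged when |t_latency| + |t_RoR| between consecutive
    intensities exceeds ``t_sum_threshold`` AND the mean RoR rises by more
    than ``min_increase``. Candidate RoRs are then read from the flagged
    group's RoR modes: a mode unexplained by known inputs becomes a
    candidate after subtracting known inputs of similar latency
    (+- ``latency_tol`` ms) -- co-active inputs closer than the event
    separation fuse into summed EPSPs, which is what the subtraction
    corrects. Returns candidate dicts (``mean_ror``, ``mean_latency``,
    ``recruitment_intensity``, ``n_events``).
    """
    if len(groups) < 2:
        raise InsufficientDataError("recruitment scan needs at least 2 intensity groups")
    if latency_domain is not None:
        groups = [_restrict(g, latency_domain) for g in groups]
    candidates: list[dict] = []
    prev = None
    for g in groups:
        if g.rors.size < 2:
            continue
        clusters = _ror_clusters(g.rors, g.latencies)
        if prev is None:
            for cl in clusters:
                candidates.append(dict(cl, recruitment_intensity=g.intensity))
            prev = g
            continue
        t_lat = welch_t(prev.latencies, g.latencies)
        t_ror = welch_t(prev.rors, g.rors)
        increase = (g.mean_ror - prev.mean_ror) / prev.mean_ror
        flagged = (t_lat + t_ror) > t_sum_threshold and increase > min_increase
        if flagged:
            # a rise in response rate with no latency shift and only weak
            # RoR evidence is an activation-probability change, not a new
            # input; a large RoR t-component cannot come from one
            rate_jump = g.response_rate - prev.response_rate
            if (
                rate_jump > prob_shift_rate_jump
                and t_lat < prob_shift_t_lat
                and t_ror < prob_shift_t_ror
            ):
                flagged = False
        if flagged:
            new_clusters = [cl for cl in clusters if not _matches_known(cl, candidates)]
            if new_clusters:
                for cl in new_clusters:
                    ror = _subtract_overlapping(cl, candidates, latency_tol)
                    if ror is not None:
                        candidates.append(
                            dict(
                                mean_ror=ror,
                                mean_latency=cl["mean_latency"],
                                recruitment_intensity=g.intensity,
                                n_events=cl["n_events"],
                            )
                        )
            else:
                ror = deconvolve_ror(g, candidates, latency_tol)
                if ror is not None:
                    candidates.append(
                        dict(
                            mean_ror=ror,
                            mean_latency=g.mean_latency,
                            recruitment_intensity=g.intensity,
                            n_events=int(g.rors.size),
                        )
                    )
        prev = g

    # Recruitment of an input against a much stronger background defeats
    # the t gate twice over: an all-or-none giant inflates the group
    # variance, and a moderate input barely moves a mean dominated by the
    # strongest. A persistent RoR mode that no known input explains is
    # nevertheless a distinguishable event population and spawns a
    # candidate directly (it still has to survive the spontaneous
    # cross-check downstream).
    for g in groups:
        if g.rors.size < 2:
            continue
        for cl in _ror_clusters(g.rors, g.latencies):
            if cl["mean_ror"] > unexplained_mode_min and cl["n_events"] >= 5                     and not _matches_known(cl, candidates):
                ror = _subtract_overlapping(cl, candidates, latency_tol)
                if ror is not None:
                    candidates.append(
                        dict(
                            mean_ror=ror,
                            mean_latency=cl["mean_latency"],
                            recruitment_intensity=g.intensity,
                            n_events=cl["n_events"],
                        )
                    )
    return candidates


def _subtract_overlapping(cluster: dict, known: list[dict], latency_tol: float = 0.5):
    """Apply the similar-latency subtraction rule to one RoR mode: inputs of
    similar latency fuse into summed events, so the new input's RoR is the
    mode minus the known overlapping inputs -- but only when the mode indeed
    exceeds that sum (otherwise the mode stands alone)."""
    overlap = sum(
        c["mean_ror"]
        for c in known
        if c.get("mean_latency") is not None
        and abs(c["mean_latency"] - cluster["mean_latency"]) <= latency_tol
    )
    ror = cluster["mean_ror"] - overlap
    if overlap > 0 and ror <= 0:
        # the mode is smaller than the co-active sum: a genuinely separate
        # (non-fused) population; report it as-is
        return float(cluster["mean_ror"])
    return float(ror)


def spont_crosscheck(candidate_ror: float, spont_rors, rel_tol: float = 0.20,
                     truncated_rors=None):
    """Accept a candidate input only if at least one spontaneous EPSP has a
    similar RoR (+- ``rel_tol`` relative). Returns ``(accepted, checked)``;
    with no spontaneous data the candidate passes unchecked.

    ``truncated_rors`` are RoRs of spontaneous events whose rising phase was
    cut by a postsynaptic AP; truncation underestimates the RoR by up to
    about 30%, so such an event corroborates a candidate when it falls in
    [0.7, 1 + rel_tol] times the candidate."""
    spont = np.asarray(spont_rors, float)
    trunc = np.asarray(truncated_rors, float) if truncated_rors is not None else np.zeros(0)
    if spont.size == 0 and trunc.size == 0:
        return True, False
    ok = spont.size and np.any(np.abs(spont / candidate_ror - 1.0) <= rel_tol)
    if not ok and trunc.size:
        ratio = trunc / candidate_ror
        ok = np.any((ratio >= 0.7) & (ratio <= 1.0 + rel_tol))
    return bool(ok), True


def spont_peak_inputs(
    spont_rors,
    evoked_inputs: list[InputEstimate] | None = None,
    min_events: int = 20,
    prominence_frac: float = 0.10,
    match_tol: float = 0.20,
) -> list[InputEstimate]:
    """Read additional inputs off the spontaneous RoR distribution.

    A kernel-density estimate on log RoR (Silverman bandwidth) is scanned
    for local maxima with prominence above ``prominence_frac`` of the peak
    density; modes not matching an evoked input within ``match_tol`` become
    spontaneous inputs. This also promotes a strong spontaneous mode above
    every evoked input -- the case of a strongest input that electrical
    stimulation failed to recruit.
    """
    spont = np.asarray(spont_rors, float)
    spont = spont[spont > 0]
    if spont.size < min_events:
        warnings.warn("too few spontaneous events for peak analysis", stacklevel=2)
        return []
    logs = np.log(spont)
    if np.ptp(logs) < 1e-9:
        modes = [float(np.exp(logs[0]))]
    else:
        kde = gaussian_kde(logs, bw_method="silverman")
        grid = np.linspace(logs.min() - 0.5, logs.max() + 0.5, 512)
        dens = kde(grid)
        pk, _ = find_peaks(dens, prominence=prominence_frac * dens.max())
        modes = [float(np.exp(grid[k])) for k in pk]
    evoked_inputs = evoked_inputs or []
    out = []
    for m in modes:
        # strong spontaneous modes are biased low (burst depolarization and
        # AP truncation), so they match evoked strong inputs more loosely
        def _tol(e):
            return 0.35 if (m > 10.0 or e.mean_ror > 10.0) else match_tol

        if any(abs(m / e.mean_ror - 1.0) <= _tol(e) for e in evoked_inputs):
            continue
        near = spont[np.abs(np.log(spont / m)) <= math.log(1.0 + match_tol)]
        out.append(
            InputEstimate(
                mean_ror=float(near.mean()) if near.size else m,
                ror_sd=float(near.std(ddof=1)) if near.size > 1 else 0.0,
                mean_latency=None,
                source="spontaneous",
                n_events=int(near.size),
            )
        )
    return out


def assemble_cell(
    evoked_inputs: list[InputEstimate],
    spont_inputs: list[InputEstimate],
    age: float,
    strong_threshold: float = STRONG_THRESHOLD,
    ror_tol: float = 0.20,
    latency_tol: float = 0.5,
    cell_id: str = "",
) -> CellInputs:
    """Merge evoked and spontaneous input estimates into a cell roster.

    Duplicates (RoR within ``ror_tol`` and compatible latency) merge with
    evoked provenance preferred; inputs are sorted strongest-first, strong
    flags set at ``strong_threshold`` and the competition index follows from
    the two strongest.
    """
    merged: list[InputEstimate] = list(evoked_inputs)
    for sp in spont_inputs:
        dup = False
        for ev in merged:
            ror_close = abs(sp.mean_ror / ev.mean_ror - 1.0) <= ror_tol
            lat_close = (
                sp.mean_latency is None
                or ev.mean_latency is None
                or abs(sp.mean_latency - ev.mean_latency) <= latency_tol
            )
            if ror_close and lat_close:
                dup = True
                break
        if not dup:
            merged.append(sp)
    if not merged:
        raise InsufficientDataError("cell excluded: no identified inputs")
    for inp in merged:
        inp.strong = inp.mean_ror > strong_threshold
    return CellInputs(age=age, inputs=merged, cell_id=cell_id)


def refractory_violations(events: list[EPSPEvent], refractory_ms: float = 1.0) -> int:
    """Count inter-event intervals shorter than the refractory period among
    an input's events. A strong input with many violations would indicate
    two terminals hiding under one RoR cluster; violations are reported,
    never used to split inputs."""
    onsets = np.sort([e.onset_s for e in events])
    if onsets.size < 2:
        return 0
    return int(np.sum(np.diff(onsets) * 1e3 < refractory_ms))


# --------------------------------------------------------------------------
# end-to-end identification


def _merge_close_candidates(candidates, log_tol=math.log(1.5), lat_tol=0.3):
    """Merge evoked candidates that are indistinguishable (similar RoR at
    the same latency): one input partially recruited or truncated at
    different intensities otherwise splits into near-duplicates."""
    merged: list[dict] = []
    for c in sorted(candidates, key=lambda c: -c.get("n_events", 0)):
        hit = None
        for m in merged:
            if abs(math.log(c["mean_ror"] / m["mean_ror"])) > log_tol:
                continue
            if (
                c.get("mean_latency") is not None
                and m.get("mean_latency") is not None
                and abs(c["mean_latency"] - m["mean_latency"]) > lat_tol
            ):
                continue
            hit = m
            break
        if hit is None:
            merged.append(dict(c))
        else:
            n1, n2 = hit.get("n_events", 1), c.get("n_events", 1)
            w = n2 / max(n1 + n2, 1)
            hit["mean_ror"] = (1 - w) * hit["mean_ror"] + w * c["mean_ror"]
            hit["n_events"] = n1 + n2
    return merged


def _refine_by_assignment(candidates, events, n_iter=3, ror_tol_log=math.log(1.35), lat_tol=0.6):
    """Re-estimate candidate RoR/latency from the evoked events assigned to
    them (nearest compatible candidate per event), iterated to convergence."""
    cands = [dict(c) for c in candidates]
    assigned: list[list[EPSPEvent]] = [[] for _ in cands]
    for _ in range(n_iter):
        assigned = [[] for _ in cands]
        for ev in events:
            best, best_d = None, np.inf
            for k, c in enumerate(cands):
                d_ror = abs(math.log(ev.rate_of_rise / c["mean_ror"]))
                if d_ror > ror_tol_log:
                    continue
                d_lat = 0.0
                if c.get("mean_latency") is not None and ev.latency_ms is not None:
                    d_lat = abs(ev.latency_ms - c["mean_latency"])
                    if d_lat > lat_tol:
                        continue
                d = d_ror / ror_tol_log + d_lat / lat_tol
                if d < best_d:
                    best, best_d = k, d
            if best is not None:
                assigned[best].append(ev)
        for k, c in enumerate(cands):
            evs = assigned[k]
            if len(evs) >= 2:
                rors = np.array([e.rate_of_rise for e in evs])
                lats = np.array([e.latency_ms for e in evs if e.latency_ms is not None])
                c["mean_ror"] = float(rors.mean())
                c["ror_sd"] = float(rors.std(ddof=1))
                if lats.size:
                    c["mean_latency"] = float(lats.mean())
                c["n_events"] = len(evs)
    return cands, assigned


def identify_inputs(
    stim_trace: TraceRecording | None,
    spont_trace: TraceRecording | None,
    age: float,
    cell_id: str = "",
    min_ror: float = 0.7,
    strong_threshold: float = STRONG_THRESHOLD,
    detect_kwargs: dict | None = None,
) -> CellInputs:
    """Full physiology pipeline for one cell: detect events on the
    stimulation and spontaneous recordings, identify inputs from recruitment
    and from spontaneous modes, annotate prespikes and P_AP, and assemble
    the roster with the competition index."""
    detect_kwargs = detect_kwargs or {}
    evoked_events: list[EPSPEvent] = []
    groups: list[IntensityGroup] = []
    if stim_trace is not None:
        ev = detect_epsps(stim_trace, min_ror=min_ror, **detect_kwargs)
        classify_evoked(ev, stim_trace)
        detect_prespikes(stim_trace, ev)
        evoked_events = [e for e in ev if e.evoked]
        groups = group_by_intensity(evoked_events, stim_trace)

    spont_events: list[EPSPEvent] = []
    spont_rors = np.zeros(0)
    spont_trunc = np.zeros(0)
    if spont_trace is not None and spont_trace.samples.size:
        spont_events = detect_epsps(spont_trace, min_ror=min_ror, **detect_kwargs)
        spont_rors = np.array([e.rate_of_rise for e in spont_events if not e.triggered_ap])
        spont_trunc = np.array([e.rate_of_rise for e in spont_events if e.triggered_ap])

    # evoked candidates, per latency domain
    candidates: list[dict] = []
    if len(groups) >= 2:
        all_lat = np.concatenate([g.latencies for g in groups]) if groups else np.zeros(0)
        for dom in latency_domains(all_lat):
            candidates.extend(scan_recruitment(groups, latency_domain=dom))

    candidates = [
        c
        for c in candidates
        if spont_crosscheck(c["mean_ror"], spont_rors, truncated_rors=spont_trunc)[0]
    ]
    candidates = _merge_close_candidates(candidates)
    candidates, assigned = _refine_by_assignment(candidates, evoked_events)

    evoked_inputs: list[InputEstimate] = []
    ap_times = detect_aps(stim_trace) if stim_trace is not None else np.zeros(0)
    for c, evs in zip(candidates, assigned):
        est = InputEstimate(
            mean_ror=c["mean_ror"],
            ror_sd=c.get("ror_sd", 0.0),
            mean_latency=c.get("mean_latency"),
            source="evoked",
            n_events=c.get("n_events", 0),
            recruitment_intensity=c.get("recruitment_intensity"),
            checked_against_spontaneous=bool(spont_rors.size),
        )
        if evs:
            try:
                est.p_ap = compute_pap(evs, ap_times)
            except InsufficientDataError:
                est.p_ap = None
            if est.mean_ror > strong_threshold:
                large = [e for e in evs if e.rate_of_rise > strong_threshold]
                if large and prespike_present(large):
                    amps = [e.prespike_amplitude for e in large if e.prespike_amplitude]
                    est.prespike = True
                    est.prespike_amp = float(np.mean(amps)) if amps else None
        evoked_inputs.append(est)

    spont_inputs = spont_peak_inputs(spont_rors, evoked_inputs) if spont_rors.size else []
    return assemble_cell(
        evoked_inputs, spont_inputs, age, strong_threshold=strong_threshold, cell_id=cell_id
    )
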
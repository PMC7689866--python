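"""Input identification: recruitment scan, cross-checks and assembly."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from calyxsf.datatypes import InputEstimate, IntensityGroup
from calyxsf.errors import InsufficientDataError
from calyxsf.inputs import (
    assemble_cell,
    deconvolve_ror,
    group_by_intensity,
    identify_inputs,
    refractory_violations,
    scan_recruitment,
    spont_crosscheck,
    spont_peak_inputs,
    welch_t,
)
from calyxsf.detect import classify_evoked, detect_epsps
from calyxsf.synth import make_cohort, synth_spont_activity, synth_stim_experiment
from calyxsf.datatypes import CohortParams

from conftest import make_cell


def _group(intensity, rors, lats, n_sweeps=30, n_responding=None):
    rors = np.asarray(rors, float)
    return IntensityGroup(
        intensity=intensity,
        latencies=np.asarray(lats, float),
        rors=rors,
        n_sweeps=n_sweeps,
        n_responding=n_responding if n_responding is not None else min(len(rors), n_sweeps),
    )


class TestWelchT:
    def test_identical_samples_zero(self):
        assert welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_computed_value(self):
        assert welch_t([1, 2, 3], [4, 5, 6]) == pytest.approx(3.674, abs=1e-3)

    def test_matches_reference_implementation(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, rng.integers(3, 30))
            y = rng.normal(0.5, 2, rng.integers(3, 30))
            ref = abs(sps.ttest_ind(x, y, equal_var=False).statistic)
            assert welch_t(x, y) == pytest.approx(ref, abs=1e-10)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            welch_t([1.0], [2.0, 3.0])


class TestGrouping:
    def test_groups_per_distinct_intensity(self):
        cell = make_cell([8.0, 2.0], thresholds=[0.05, 0.15], activation_prob=1.0)
        tr = synth_stim_experiment(cell, [0.1, 0.2], 15, seed=1)
        events = classify_evoked(detect_epsps(tr), tr)
        groups = group_by_intensity([e for e in events if e.evoked], tr)
        assert [g.intensity for g in groups] == [0.1, 0.2]

    def test_empty_events_empty_groups(self):
        cell = make_cell([8.0])
        cell.inputs = []
        tr = synth_stim_experiment(cell, [0.1], 5, seed=1)
        groups = group_by_intensity([], tr)
        assert len(groups) == 1 and groups[0].rors.size == 0

    def test_response_rates_match_activation_probability(self):
        cell = make_cell([9.0], thresholds=[0.05], activation_prob=0.8, trial_cv=0.05)
        tr = synth_stim_experiment(cell, [0.1, 0.2, 0.3], 40, seed=2)
        events = classify_evoked(detect_epsps(tr), tr)
        groups = group_by_intensity([e for e in events if e.evoked], tr)
        for g in groups:
            # binomial error: 0.8 +- 3*sqrt(0.8*0.2/40)
            assert g.response_rate == pytest.approx(0.8, abs=0.19)


class TestScanRecruitment:
    def test_identical_groups_single_input(self, rng):
        rors = rng.normal(3.0, 0.3, 25)
        lats = rng.normal(2.0, 0.05, 25)
        groups = [_group(0.1, rors, lats), _group(0.2, rors, lats)]
        cands = scan_recruitment(groups)
        assert len(cands) == 1  # only the first-group input

    def test_flagged_transition_spawns_input(self, rng):
        g1 = _group(0.1, rng.normal(3.0, 0.3, 30), rng.normal(2.0, 0.05, 30))
        g2 = _group(0.2, rng.normal(9.0, 0.8, 30), rng.normal(2.6, 0.05, 30))
        cands = scan_recruitment([g1, g2])
        assert len(cands) == 2

    def test_large_t_small_increase_not_flagged(self, rng):
        # summed t far above 6 but RoR increase ~10% -> both conditions required
        g1 = _group(0.1, rng.normal(3.0, 0.05, 40), rng.normal(2.0, 0.02, 40))
        g2 = _group(0.2, rng.normal(3.3, 0.05, 40), rng.normal(2.0, 0.02, 40))
        cands = scan_recruitment([g1, g2])
        assert len(cands) == 1

    def test_candidate_count_bounded_by_transitions(self, rng):
        groups = [
            _group(0.1 * (k + 1), rng.normal(2.0 + k, 0.3, 25), rng.normal(2.0, 0.05, 25))
            for k in range(5)
        ]
        cands = scan_recruitment(groups)
        assert len(cands) <= len(groups)

    def test_too_few_groups(self):
        with pytest.raises(InsufficientDataError):
            scan_recruitment([_group(0.1, [1, 2], [2, 2])])


class TestDeconvolve:
    def test_no_overlap_identity(self):
        g = _group(0.3, [12.0] * 5, [2.0] * 5)
        assert deconvolve_ror(g, []) == pytest.approx(12.0)

    def test_overlapping_subtraction(self):
        g = _group(0.3, [12.0] * 5, [2.0] * 5)
        known = [dict(mean_ror=4.0, mean_latency=2.2)]
        assert deconvolve_ror(g, known) == pytest.approx(8.0)

    def test_latency_tolerance_half_ms(self):
        g = _group(0.3, [12.0] * 5, [2.0] * 5)
        far = [dict(mean_ror=4.0, mean_latency=2.8)]
        assert deconvolve_ror(g, far) == pytest.approx(12.0)

    def test_oversubtraction_dropped_with_warning(self):
        g = _group(0.3, [3.0] * 5, [2.0] * 5)
        known = [dict(mean_ror=4.0, mean_latency=2.0)]
        with pytest.warns(UserWarning):
            assert deconvolve_ror(g, known) is None


class TestSpontCrosscheck:
    def test_accept_near(self):
        assert spont_crosscheck(8.0, [7.5, 2.0])[0] is True

    def test_reject_far(self):
        assert spont_crosscheck(8.0, [1.0, 3.0, 4.9])[0] is False

    def test_empty_unchecked(self):
        accepted, checked = spont_crosscheck(8.0, [])
        assert accepted is True and checked is False

    def test_cohort_rejects_spurious_retains_true(self):
        """Over many synthetic cells, the cross-check removes >80% of
        candidates placed in gaps of the input spectrum while keeping >90%
        of true inputs at or above 2 V/s."""
        kept_true = total_true = kept_spur = total_spur = 0
        cells = make_cohort(CohortParams(n_cells=50, seed=77))
        for k, cell in enumerate(cells):
            tr = synth_spont_activity(cell, 10.0, seed=900 + k)
            events = detect_epsps(tr)
            rors = np.array([e.rate_of_rise for e in events if not e.triggered_ap])
            trunc = np.array([e.rate_of_rise for e in events if e.triggered_ap])
            if rors.size < 20:
                continue
            true_rors = sorted((i.true_ror for i in cell.inputs), reverse=True)
            for r in true_rors:
                if r < 2.0:
                    continue
                total_true += 1
                kept_true += spont_crosscheck(r, rors, truncated_rors=trunc)[0]
            # spurious candidates in spectral gaps
            spurious = [3.0 * true_rors[0], math.sqrt(true_rors[0] * true_rors[1]) * 1.0
                        if true_rors[0] / true_rors[1] > 4 else None]
            for s in spurious:
                if s is None:
                    continue
                total_spur += 1
                kept_spur += spont_crosscheck(s, rors, truncated_rors=trunc)[0]
        assert kept_true / total_true > 0.90
        assert 1.0 - kept_spur / total_spur > 0.80


class TestSpontPeaks:
    def test_unimodal_single_input(self, rng):
        rors = np.exp(rng.normal(math.log(3.0), 0.1, 200))
        assert len(spont_peak_inputs(rors)) == 1

    def test_small_inputs_not_over_split(self, rng):
        # events spanning 0.7-2 V/s with no separable modes -> at most 1
        rors = np.exp(rng.uniform(math.log(0.7), math.log(2.0), 300))
        assert len(spont_peak_inputs(rors)) <= 1

    def test_unstimulated_strong_input_promoted(self):
        # stimulation misses the 18 V/s input (threshold above max current);
        # the spontaneous analysis must add it
        cell = make_cell([18.0, 3.0], thresholds=[0.6, 0.1], trial_cv=0.08)
        stim = synth_stim_experiment(cell, [0.15, 0.25, 0.35], 30, seed=5)
        spont = synth_spont_activity(cell, 30.0, seed=6)
        ci = identify_inputs(stim, spont, cell.age, "c")
        strongest = ci.inputs[0]
        assert strongest.source == "spontaneous"
        assert strongest.mean_ror == pytest.approx(18.0, rel=0.20)

    def test_too_few_events_empty(self):
        with pytest.warns(UserWarning):
            assert spont_peak_inputs(np.array([3.0] * 5)) == []


class TestAssemble:
    def test_equal_strongest_competition_index_one(self):
        a = InputEstimate(mean_ror=12.0, mean_latency=2.0)
        b = InputEstimate(mean_ror=12.0, mean_latency=4.0)
        cell = assemble_cell([a, b], [], age=4.0)
        assert cell.competition_index == pytest.approx(1.0)

    def test_printed_means_ratio(self):
        a = InputEstimate(mean_ror=19.0, mean_latency=2.0)
        b = InputEstimate(mean_ror=3.7, mean_latency=2.5)
        cell = assemble_cell([a, b], [], age=4.0)
        assert round(cell.competition_index, 3) == 0.195

    @pytest.mark.parametrize("ror,strong", [(10.5, True), (9.5, False)])
    def test_strong_threshold(self, ror, strong):
        cell = assemble_cell([InputEstimate(mean_ror=ror)], [], age=4.0)
        assert cell.inputs[0].strong is strong

    def test_duplicates_merge_with_evoked_preference(self):
        ev = InputEstimate(mean_ror=10.0, mean_latency=2.0, source="evoked")
        sp = InputEstimate(mean_ror=10.8, source="spontaneous")
        cell = assemble_cell([ev], [sp], age=4.0)
        assert len(cell.inputs) == 1
        assert cell.inputs[0].source == "evoked"

    def test_zero_inputs_excluded(self):
        with pytest.raises(InsufficientDataError):
            assemble_cell([], [], age=4.0)

    def test_competition_index_bounded(self):
        cells = make_cohort(CohortParams(n_cells=10, seed=4))
        for c in cells:
            rors = c.sorted_rors()
            ci = rors[1] / rors[0]
            assert 0.0 < ci <= 1.0


class TestRefractory:
    def test_no_violation_for_sparse_events(self):
        from calyxsf.datatypes import EPSPEvent

        events = [EPSPEvent(onset_s=0.01 * k, rate_of_rise=5, amplitude=1) for k in range(5)]
        assert refractory_violations(events) == 0

    def test_reports_not_splits(self):
        from calyxsf.datatypes import EPSPEvent

        events = [
            EPSPEvent(onset_s=t, rate_of_rise=5, amplitude=1)
            for t in (0.0100, 0.0104, 0.020)
        ]
        assert refractory_violations(events, refractory_ms=1.0) == 1
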
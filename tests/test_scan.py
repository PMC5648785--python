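"""Scan-engine tests: continuation scans, regime-map composition,
bistability probes, directional sweeps with jump/hysteresis detection,
and transition protocols -- validated on fixtures with closed forms or
brute-force oracles."""

import math

import numpy as np
import pytest

from thalamodyn.benchmarks import (
    make_double_well,
    make_linear_resonator,
    softening_duffing,
    twinwell_duffing,
)
from thalamodyn.integrate import IntegrationSettings
from thalamodyn.metrics import RegimeThresholds
from thalamodyn.scan import (
    FrequencyResponse,
    ScanSpec,
    bistability_probe,
    compose_regime_map,
    detect_jumps,
    fixture_scan_problem,
    hysteresis_region,
    run_scan,
    sweep_frequency_response,
    transition_protocol,
)


class TestRunScan:
    def test_monostable_direction_invariance(self):
        """A forced linear oscillator has a unique attractor, so forward
        and backward frequency scans agree to high precision."""
        fix = make_linear_resonator(damping=0.3)
        problem = fixture_scan_problem(fix)
        grid = np.round(np.arange(0.6, 1.4 + 1e-9, 0.1), 3)
        fwd = run_scan(problem, ScanSpec("omega", tuple(grid),
                                         min_duration=60.0, min_periods=40))
        bwd = run_scan(problem, ScanSpec("omega", tuple(grid[::-1]),
                                         min_duration=60.0, min_periods=40))
        assert np.allclose(fwd.amplitudes, bwd.amplitudes[::-1], atol=1e-6)

    def test_continuation_off_matches_on_for_monostable(self):
        fix = make_linear_resonator(damping=0.3)
        problem = fixture_scan_problem(fix)
        grid = (0.8, 1.0, 1.2)
        on = run_scan(problem, ScanSpec("omega", grid, continuation=True,
                                        min_duration=60.0, min_periods=40))
        off = run_scan(problem, ScanSpec("omega", grid, continuation=False,
                                         min_duration=60.0, min_periods=40))
        assert np.allclose(on.amplitudes, off.amplitudes, atol=1e-5)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            ScanSpec("omega", ())

    def test_scan_determinism(self):
        fix = make_linear_resonator()
        problem = fixture_scan_problem(fix)
        spec = ScanSpec("omega", (0.9, 1.0), min_duration=30.0)
        a = run_scan(problem, spec)
        b = run_scan(problem, spec)
        assert np.array_equal(a.amplitudes, b.amplitudes)


class TestLinearResonatorSweep:
    def test_matches_closed_form_within_one_percent(self):
        """Steady-state sweep amplitudes reproduce the closed-form
        magnitude F/sqrt((k - m w^2)^2 + (c w)^2) within 1%."""
        fix = make_linear_resonator(damping=0.3, force_amplitude=1.0)
        problem = fixture_scan_problem(fix)
        grid = np.round(np.arange(0.5, 1.6 + 1e-9, 0.1), 3)
        resp = sweep_frequency_response(problem, grid, "forward",
                                        min_duration=80.0, min_periods=60)
        expect = np.array([fix.known["amplitude"](w) for w in resp.frequencies])
        assert np.all(np.abs(resp.amplitudes - expect) <= 0.01 * expect)

    def test_peak_near_damped_resonance(self):
        fix = make_linear_resonator(damping=0.3)
        problem = fixture_scan_problem(fix)
        grid = np.round(np.arange(0.5, 1.5 + 1e-9, 0.05), 3)
        resp = sweep_frequency_response(problem, grid, "forward",
                                        min_duration=80.0, min_periods=60)
        peak = resp.frequencies[np.argmax(resp.amplitudes)]
        assert peak == pytest.approx(fix.known["peak_omega"], abs=0.05)

    def test_forward_equals_backward(self):
        fix = make_linear_resonator(damping=0.3)
        problem = fixture_scan_problem(fix)
        grid = np.round(np.arange(0.7, 1.3 + 1e-9, 0.1), 3)
        f = sweep_frequency_response(problem, grid, "forward",
                                     min_duration=60.0, min_periods=50)
        b = sweep_frequency_response(problem, grid, "backward",
                                     min_duration=60.0, min_periods=50)
        assert np.allclose(f.amplitudes, b.amplitudes[::-1], atol=1e-6)


@pytest.fixture(scope="module")
def sweeps():
    fix = softening_duffing()
    problem = fixture_scan_problem(fix)
    step = fix.known["sweep_grid_step"]
    grid = np.round(np.arange(0.70, 0.94 + 1e-9, step), 3)
    kw = dict(min_duration=200.0, min_periods=100)
    fwd = sweep_frequency_response(problem, grid, "forward", **kw)
    bwd = sweep_frequency_response(problem, grid, "backward", **kw)
    return fix, fwd, bwd, step


class TestSofteningDuffingHysteresis:
    def test_sweep_directions_disagree_inside_oracle_window(self, sweeps):
        """Softening spring at large forcing: forward and backward sweeps
        track different branches over the oracle's multistable window."""
        fix, fwd, bwd, step = sweeps
        lo, hi = fix.known["hysteresis_window"]
        regions = hysteresis_region(fwd, bwd)
        assert regions, "expected a nonempty hysteresis region"
        r_lo = min(a for a, _ in regions)
        r_hi = max(b for _, b in regions)
        # hysteresis interval edges agree with the oracle's multistable
        # window within one sweep grid step
        assert r_lo == pytest.approx(lo, abs=step + 1e-9)
        assert r_hi == pytest.approx(hi, abs=step + 1e-9)

    def test_jump_frequencies_match_oracle_window(self, sweeps):
        """Forward sweep: one up-jump at the window's upper edge; backward
        sweep: one down-jump at the lower edge (softening ordering)."""
        fix, fwd, bwd, step = sweeps
        lo, hi = fix.known["hysteresis_window"]
        up = [j for j in detect_jumps(fwd) if j.direction == "up"]
        down = [j for j in detect_jumps(bwd) if j.direction == "down"]
        assert len(up) == 1 and len(down) == 1
        assert up[0].frequency == pytest.approx(hi, abs=step + 1e-9)
        assert down[0].frequency == pytest.approx(lo, abs=step + 1e-9)
        assert down[0].frequency < up[0].frequency

    def test_hysteresis_contains_a_jump(self, sweeps):
        _, fwd, bwd, step = sweeps
        regions = hysteresis_region(fwd, bwd)
        jumps = [j.frequency for j in detect_jumps(fwd) + detect_jumps(bwd)]
        pad = step + 1e-9
        assert any(
            any(a - pad <= f <= b + pad for f in jumps) for a, b in regions
        )

    def test_small_forcing_sweeps_coincide(self):
        fix = softening_duffing()
        small = fix.known["small_forcing"]
        problem = fixture_scan_problem(fix)
        problem.build = lambda w: fix.make(omega=w, forcing=small)
        grid = np.round(np.arange(0.7, 1.1 + 1e-9, 0.05), 3)
        kw = dict(min_duration=120.0, min_periods=60)
        fwd = sweep_frequency_response(problem, grid, "forward", **kw)
        bwd = sweep_frequency_response(problem, grid, "backward", **kw)
        assert not hysteresis_region(fwd, bwd)


class TestCascadeScan:
    def test_twinwell_reverse_cascade_labels_in_grid_order(self):
        """Scanning the twin-well forcing frequency downward crosses
        period-1 -> period-2 -> chaotic windows, and the per-point labels
        (period detection + Lyapunov sign) report them in grid order."""
        fix = twinwell_duffing()
        problem = fixture_scan_problem(
            fix, settings=IntegrationSettings(rtol=1e-8, atol=1e-10,
                                              sample_dt=2e-3),
            ic=np.array([1.0, 0.0]),
        )
        grid = fix.known["cascade_grid_descending"]
        spec = ScanSpec(
            "omega", grid, compute_mle=True,
            min_duration=60.0, min_periods=60,
            mle_horizon=90.0, mle_renorm=0.5, mle_transient=15.0,
        )
        result = run_scan(problem, spec)
        cats = [
            (r.label.category, r.label.k) for r in result.records
        ]
        # period-1 at the top of the grid, chaos at the bottom
        assert cats[0] == ("PERIODIC", 1)
        assert ("PERIODIC", 2) in cats
        assert cats[-1][0] == "CHAOTIC"
        # ordering: once chaos starts (descending), no return to period-1
        first_chaos = next(
            i for i, c in enumerate(cats) if c[0] == "CHAOTIC"
        )
        assert all(c[0] == "CHAOTIC" for c in cats[first_chaos:])


class TestDetectJumps:
    def test_smooth_lorentzian_empty(self):
        f = np.linspace(0.5, 1.5, 50)
        amp = 1.0 / np.sqrt((1 - f**2) ** 2 + (0.4 * f) ** 2)
        resp = FrequencyResponse(f, amp, "forward")
        assert detect_jumps(resp) == []

    def test_constructed_step_detected(self):
        f = np.linspace(1.0, 2.0, 11)
        amp = np.ones(11)
        amp[6:] = 5.0
        resp = FrequencyResponse(f, amp, "forward")
        jumps = detect_jumps(resp)
        assert len(jumps) == 1
        assert jumps[0].frequency == pytest.approx(0.5 * (f[5] + f[6]))
        assert jumps[0].direction == "up"
        assert jumps[0].ratio == pytest.approx(5.0)

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            detect_jumps(FrequencyResponse(np.array([1.0]), np.array([1.0]),
                                           "forward"))


class TestHysteresisRegion:
    def _resp(self, f, a, direction="forward"):
        if direction == "backward":
            return FrequencyResponse(f[::-1], a[::-1], "backward")
        return FrequencyResponse(f, a, "forward")

    def test_identical_responses_empty(self):
        f = np.linspace(1, 2, 20)
        a = np.ones(20)
        assert hysteresis_region(self._resp(f, a),
                                 self._resp(f, a, "backward")) == []

    def test_constructed_divergence_interval(self):
        f = np.linspace(1, 2, 21)
        a1 = np.ones(21)
        a2 = np.ones(21)
        a2[8:13] = 3.0
        regions = hysteresis_region(self._resp(f, a1),
                                    self._resp(f, a2, "backward"))
        assert regions == [(pytest.approx(f[8]), pytest.approx(f[12]))]

    def test_grid_mismatch_rejected(self):
        f = np.linspace(1, 2, 10)
        with pytest.raises(ValueError):
            hysteresis_region(self._resp(f, np.ones(10)),
                              self._resp(f + 0.5, np.ones(10), "backward"))


class TestComposeRegimeMap:
    def _result(self, values, oscillating):
        """Construct a minimal ScanResult-like record set."""
        from thalamodyn.integrate import ContinuationState
        from thalamodyn.metrics import ExtremaSet, RegimeLabel
        from thalamodyn.scan import ScanRecord, ScanResult

        records = []
        for v, osc in zip(values, oscillating):
            rng_val = 10.0 if osc else 0.0
            ext = ExtremaSet(
                maxima=np.array([]), minima=np.array([]),
                max_clusters=[], min_clusters=[],
                output_range=rng_val, cluster_tol=0.05,
            )
            records.append(
                ScanRecord(
                    value=float(v), amplitude=rng_val / 2, extrema=ext,
                    mle=None,
                    label=RegimeLabel("PERIODIC" if osc else "FIXED_POINT"),
                    final=ContinuationState(0.0, np.zeros(1)),
                )
            )
        spec = ScanSpec("x", tuple(values))
        return ScanResult(spec=spec, records=records,
                          thresholds=RegimeThresholds())

    def test_identical_monostable_single_interval(self):
        vals = np.arange(0, 5.0, 1.0)
        fwd = self._result(vals, [False] * 5)
        bwd = self._result(vals[::-1], [False] * 5)
        rmap = compose_regime_map(fwd, bwd)
        assert rmap.classes == ["FIXED_POINT_ONLY"]

    def test_disagreement_on_middle_third(self):
        vals = np.arange(0, 9.0, 1.0)
        fwd = self._result(vals, [False] * 9)
        bwd_osc = [False] * 3 + [True] * 3 + [False] * 3
        bwd = self._result(vals[::-1], bwd_osc[::-1])
        rmap = compose_regime_map(fwd, bwd)
        assert rmap.classes == ["FIXED_POINT_ONLY", "BISTABLE",
                                "FIXED_POINT_ONLY"]

    def test_five_interval_pattern(self):
        """The canonical five-regime layout: fixed point / bistable /
        limit cycle / bistable / fixed point."""
        vals = np.arange(0, 10.0, 1.0)
        fwd_osc = [False, False, False, False, True, True, True, True,
                   False, False]
        bwd_osc = [False, False, True, True, True, True, True, True,
                   True, False]
        # backward oscillates over a wider range: its continuation carries
        # the cycle into the bistable flanks
        fwd = self._result(vals, fwd_osc)
        bwd = self._result(vals[::-1], bwd_osc[::-1])
        rmap = compose_regime_map(fwd, bwd)
        assert rmap.classes == [
            "FIXED_POINT_ONLY", "BISTABLE", "LIMIT_CYCLE_ONLY",
            "BISTABLE", "FIXED_POINT_ONLY",
        ]
        assert len(rmap.intervals) == 5

    def test_grid_mismatch_rejected(self):
        fwd = self._result(np.arange(3.0), [False] * 3)
        bwd = self._result(np.arange(1.0, 4.0)[::-1], [False] * 3)
        with pytest.raises(ValueError):
            compose_regime_map(fwd, bwd)


class TestBistabilityProbe:
    settings = IntegrationSettings(rtol=1e-8, atol=1e-10, sample_dt=1e-2)

    def test_double_well_two_attractors(self):
        fix = make_double_well(depth=1.0, tilt=0.0)
        inventory = bistability_probe(
            fix.system(), fix.ics, t_sim=10.0, settings=self.settings
        )
        assert len(inventory) == 2
        means = sorted(a.mean_level for a in inventory)
        assert means[0] == pytest.approx(-1.0, abs=0.01)
        assert means[1] == pytest.approx(1.0, abs=0.01)
        assert all(a.kind == "fixed_point" for a in inventory)

    def test_same_basin_undercounts(self):
        fix = make_double_well()
        inventory = bistability_probe(
            fix.system(), [np.array([0.5]), np.array([1.5])],
            t_sim=10.0, settings=self.settings,
        )
        assert len(inventory) == 1

    def test_globally_stable_single_attractor(self):
        fix = make_double_well(depth=1.0, tilt=3.0)  # large tilt: one well
        assert len(fix.known["attractors"]()) == 1
        inventory = bistability_probe(
            fix.system(), [np.array([1.2]), np.array([-1.2]),
                           np.array([0.0])],
            t_sim=20.0, settings=self.settings,
        )
        assert len(inventory) == 1

    def test_needs_two_ics(self):
        fix = make_double_well()
        with pytest.raises(ValueError):
            bistability_probe(fix.system(), [np.array([1.0])])


class TestTransitionProtocol:
    def test_constant_schedule_matches_plain_run(self, params, fast_settings):
        import thalamodyn as td

        stim_plain = td.StimulusSet(
            sensory=td.StimulusSpec(11.0),
            cortical=td.StimulusSpec(13.5, 1.0, 9.0),
            reticular_bias=12.0,
        )
        stim_sched = td.StimulusSet(
            sensory=td.StimulusSpec(11.0),
            cortical=td.StimulusSpec(13.5, 1.0, 9.0),
            reticular_bias=12.0,
            schedule=td.FrequencySchedule([(0.0, 9.0)]),
            schedule_channel="cortical",
        )
        y0 = td.settled_equilibrium(params, stim_plain)
        plain = td.integrate(
            td.build_system(params, stim_plain), y0, (0.0, 8.0), fast_settings
        )
        traj, reports = transition_protocol(
            params, stim_sched, 8.0, settings=fast_settings, initial=y0
        )
        assert np.allclose(plain.output, traj.output, atol=1e-6)
        assert len(reports) == 1

    def test_segment_shorter_than_transient_flagged(self, params, fast_settings):
        import thalamodyn as td

        stim = td.StimulusSet(
            sensory=td.StimulusSpec(11.0),
            cortical=td.StimulusSpec(13.5, 1.0, 11.0),
            reticular_bias=12.0,
            schedule=td.FrequencySchedule([(0.0, 11.0), (2.0, 9.0)]),
            schedule_channel="cortical",
        )
        _, reports = transition_protocol(
            params, stim, 6.0, segment_transient=5.0, settings=fast_settings
        )
        assert reports[0].label.category == "INSUFFICIENT_DATA"

    def test_frequency_switch_toggles_large_amplitude_state(
        self, params, fast_settings
    ):
        """Switching the cortical drive into the paroxysmal resonance band
        and back toggles between a low-amplitude response and a
        large-amplitude response, reversibly."""
        import thalamodyn as td

        stim = td.StimulusSet(
            sensory=td.StimulusSpec(11.0),
            cortical=td.StimulusSpec(13.5, 1.0, 12.0),
            reticular_bias=12.0,
            schedule=td.FrequencySchedule(
                [(0.0, 12.0), (15.0, 9.2), (30.0, 12.0)]
            ),
            schedule_channel="cortical",
        )
        y0 = td.settled_equilibrium(params, stim)
        _, reports = transition_protocol(
            params, stim, 45.0, segment_transient=7.0,
            settings=fast_settings, initial=y0,
        )
        amps = [r.amplitude for r in reports]
        assert amps[1] > 3 * amps[0]
        assert amps[2] == pytest.approx(amps[0], rel=0.2)
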
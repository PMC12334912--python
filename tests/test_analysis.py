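"""Delay metric, pulse rejection, leak suppression, fixed points,
bifurcation, and hysteresis."""

import numpy as np
import pytest

from oracles import fbl_steady_sox10_1d
from regmotif import (
    AnalysisError,
    FblParams,
    LeakParams,
    SignalProfile,
    SingleGeneCircuit,
    build_fbl_model,
    build_ffl_model,
    find_steady_states,
    hysteresis_sweep,
    leaky_transcript_comparison,
    measure_response_delay,
    melanoma_state_map,
    phase_report,
    pulse_rejection,
    sample_ffl_params,
    scan_bifurcation,
    simulate,
)

ONOFF = SignalProfile((10.0, 20.0), (1.0, 0.0, 1.0))


class TestResponseDelay:
    def test_first_order_gene_delay_is_half_life(self):
        model = SingleGeneCircuit(beta=1.0, delta=2.0)
        traj = simulate(model, SignalProfile.step(5.0, 0.0, 1.0), 15.0)
        delay = measure_response_delay(traj, "X", 5.0)
        assert delay == pytest.approx(np.log(2) / 2.0, rel=0.02)

    def test_and_gate_off_delay_exceeds_sox10(self):
        model = build_ffl_model(gate="AND")
        traj = simulate(model, ONOFF, 32.0)
        mitf = measure_response_delay(traj, "MITF", 10.0)
        sox = measure_response_delay(traj, "SOX10", 10.0)
        assert mitf > sox

    def test_or_gate_on_delay_exceeds_sox10(self):
        model = build_ffl_model(gate="OR")
        traj = simulate(model, ONOFF, 32.0)
        assert measure_response_delay(traj, "MITF", 20.0) > measure_response_delay(
            traj, "SOX10", 20.0
        )

    def test_no_plateau_raises(self):
        model = SingleGeneCircuit(beta=1.0, delta=0.05)  # far from settled
        traj = simulate(model, SignalProfile.step(1.0, 0.0, 1.0), 3.0)
        with pytest.raises(AnalysisError, match="plateau"):
            measure_response_delay(traj, "X", 1.0)


class TestSignSensitiveDelayProperty:
    @pytest.mark.parametrize("gate", ["AND", "OR"])
    def test_delay_asymmetry_over_random_draws(self, gate):
        rng = np.random.default_rng(42)
        for _ in range(8):
            model = build_ffl_model(sample_ffl_params(rng), gate=gate)
            traj = simulate(model, ONOFF, 32.0)
            off = measure_response_delay(traj, "MITF", 10.0) - measure_response_delay(
                traj, "SOX10", 10.0
            )
            on = measure_response_delay(traj, "MITF", 20.0) - measure_response_delay(
                traj, "SOX10", 20.0
            )
            if gate == "AND":
                assert off > on
            else:
                assert on > off


class TestPulseRejection:
    def test_and_rejects_short_pulse_or_responds(self):
        short = [0.3]
        and_result = pulse_rejection(build_ffl_model(gate="AND"), short)
        or_result = pulse_rejection(build_ffl_model(gate="OR"), short)
        assert and_result.excursions[0] < and_result.epsilon
        assert or_result.excursions[0] > or_result.epsilon

    def test_excursions_monotone_in_duration(self):
        result = pulse_rejection(
            build_ffl_model(gate="AND"), [0.2, 0.5, 1.0, 2.0, 4.0]
        )
        assert np.all(np.diff(result.excursions) >= -1e-6)

    def test_minimal_duration_found_for_and_gate(self):
        result = pulse_rejection(
            build_ffl_model(gate="AND"), [0.25, 0.5, 1.0, 2.0, 4.0]
        )
        assert result.minimal_duration is not None
        assert result.minimal_duration > 0.25

    def test_empty_grid_rejected(self):
        from regmotif import ValidationError

        with pytest.raises(ValidationError):
            pulse_rejection(build_ffl_model(), [])


class TestLeakSuppression:
    def test_pure_half_life_without_mirna(self):
        params = LeakParams(lam=0.0, delta_mrna=0.5)
        comp = leaky_transcript_comparison(params)
        t50 = comp.time_to_fraction(0.5, "without")
        assert t50 == pytest.approx(np.log(2) / 0.5, rel=0.02)

    def test_clamped_mirna_half_life(self):
        params = LeakParams(lam=1.5, delta_mrna=0.5, mir_clamp=0.8)
        comp = leaky_transcript_comparison(params)
        t50 = comp.time_to_fraction(0.5, "with")
        assert t50 == pytest.approx(np.log(2) / (0.5 + 1.5 * 0.8), rel=0.02)

    @pytest.mark.parametrize("lam", [0.3, 1.0, 2.7])
    def test_auc_smaller_with_mirna(self, lam):
        comp = leaky_transcript_comparison(LeakParams(lam=lam))
        assert comp.auc_with < comp.auc_without

    def test_auc_strictly_decreasing_in_lam(self):
        aucs = [
            leaky_transcript_comparison(LeakParams(lam=lam)).auc_with
            for lam in np.linspace(0.2, 3.0, 8)
        ]
        assert all(a2 < a1 for a1, a2 in zip(aucs, aucs[1:]))

    def test_t10_faster_with_mirna(self):
        comp = leaky_transcript_comparison(LeakParams(lam=2.0))
        assert comp.t10_with < comp.t10_without


class TestFixedPoints:
    def test_decoupled_gene_fixed_point(self):
        model = SingleGeneCircuit(beta=2.0, delta=1.0)
        fps = find_steady_states(model, 1.0)
        assert len(fps) == 1
        assert fps[0].state[0] == pytest.approx(2.0, abs=1e-8)
        assert fps[0].stable

    def test_bistable_window_has_three_fixed_points(self):
        model = build_fbl_model()
        fps = find_steady_states(model, 1.5)
        assert len(fps) == 3
        assert [fp.stable for fp in fps] == [True, False, True]

    def test_matches_dense_grid_oracle(self):
        params = FblParams()
        model = build_fbl_model(params)
        for atf2 in (0.4, 1.2, 1.5, 2.0, 2.6):
            expected = fbl_steady_sox10_1d(params, atf2)
            found = sorted(fp.sox10 for fp in find_steady_states(model, atf2))
            assert len(found) == len(expected)
            np.testing.assert_allclose(found, expected, atol=1e-5)

    @pytest.mark.parametrize("seed", range(10))
    def test_hill1_loop_is_always_monostable(self, seed):
        rng = np.random.default_rng(seed)
        params = FblParams(
            beta_sox=rng.uniform(0.5, 2.0),
            delta_sox=rng.uniform(0.5, 2.0),
            beta_mir=rng.uniform(0.5, 2.0),
            delta_mir=rng.uniform(0.5, 2.0),
            k_atf_sox=rng.uniform(0.2, 1.0),
            k_sox_mir=rng.uniform(0.2, 1.0),
            k_mir_atf=rng.uniform(0.2, 1.0),
            n_atf_sox=1.0, n_sox_mir=1.0, n_mir_atf=1.0, n_sox_mitf=1.0,
        )
        model = build_fbl_model(params)
        for atf2 in np.linspace(0.0, 3.0, 7):
            assert len(find_steady_states(model, atf2)) == 1

    def test_broken_loop_is_monostable(self):
        # pushing the miR-204 half-repression constant far out disables the
        # feedback (ATF2 activity no longer depends on miR-204)
        params = FblParams(k_mir_atf=1e6)
        model = build_fbl_model(params)
        for atf2 in np.linspace(0.0, 3.0, 7):
            assert len(find_steady_states(model, atf2)) == 1


class TestBifurcation:
    GRID = np.linspace(0.0, 3.0, 41)

    def test_default_model_two_folds_reversible(self):
        diag = scan_bifurcation(build_fbl_model(), self.GRID)
        assert diag.fold_left is not None and diag.fold_right is not None
        assert diag.fold_left < diag.fold_right
        assert (diag.n_fixed_points == 3).any()
        assert diag.reversibility == "reversible"

    def test_monostable_model_no_folds(self):
        params = FblParams(n_atf_sox=1.0, n_sox_mir=1.0, n_mir_atf=1.0, n_sox_mitf=1.0)
        diag = scan_bifurcation(build_fbl_model(params), self.GRID)
        assert diag.fold_left is None and diag.fold_right is None
        assert diag.reversibility == "reversible"
        assert (diag.n_fixed_points == 1).all()

    def test_basal_offset_makes_switching_irreversible(self):
        diag = scan_bifurcation(build_fbl_model(FblParams(atf2_basal=1.5)), self.GRID)
        assert diag.reversibility == "irreversible"
        assert diag.fold_left is None  # below the scanned physical range

    def test_fold_count_consistent_with_branches(self):
        diag = scan_bifurcation(build_fbl_model(), self.GRID)
        counts = diag.n_fixed_points
        changes = int(np.sum(np.abs(np.diff(counts)) > 0))
        assert changes == 2

    def test_stability_pattern_in_window(self):
        diag = scan_bifurcation(build_fbl_model(), self.GRID)
        for fps in diag.fixed_points:
            if len(fps) == 3:
                assert [fp.stable for fp in fps] == [True, False, True]


class TestHysteresis:
    GRID = np.linspace(0.0, 3.0, 41)

    def test_thresholds_match_folds_within_two_grid_steps(self):
        model = build_fbl_model()
        sweep = hysteresis_sweep(model, self.GRID, dwell=30.0)
        diag = scan_bifurcation(model, self.GRID)
        step = self.GRID[1] - self.GRID[0]
        assert abs(sweep.threshold_up - diag.fold_right) <= 2 * step
        assert abs(sweep.threshold_down - diag.fold_left) <= 2 * step
        assert sweep.loop_width > 0

    def test_monostable_loop_width_vanishes(self):
        params = FblParams(n_atf_sox=1.0, n_sox_mir=1.0, n_mir_atf=1.0, n_sox_mitf=1.0)
        sweep = hysteresis_sweep(build_fbl_model(params), self.GRID, dwell=30.0)
        step = self.GRID[1] - self.GRID[0]
        assert sweep.loop_width <= step

    def test_phase_replay_on_off_off_on(self):
        model = build_fbl_model()
        fps = find_steady_states(model, 1.5)
        on_state = max((f for f in fps if f.stable), key=lambda f: f.sox10).state
        signal = SignalProfile((30.0, 60.0, 90.0), (1.5, 2.8, 1.5, 0.5))
        traj = simulate(model, signal, 120.0, initial_state=on_state)
        plateaus = []
        for end in (30.0, 60.0, 90.0, 120.0):
            mask = (traj.t >= end - 3.0) & (traj.t <= end)
            plateaus.append(traj.series("SOX10")[mask].mean())
        mid = 0.5 * (min(plateaus) + max(plateaus))
        states = ["ON" if p > mid else "OFF" for p in plateaus]
        assert states == ["ON", "OFF", "OFF", "ON"]


class TestPhaseReport:
    def test_replay_phenotype_calls(self):
        model = build_fbl_model()
        fps = find_steady_states(model, 1.5)
        on_state = max((f for f in fps if f.stable), key=lambda f: f.sox10).state
        signal = SignalProfile((30.0, 60.0), (1.5, 2.8, 0.5))
        traj = simulate(model, signal, 90.0, initial_state=on_state)
        report = phase_report(traj, melanoma_state_map((0.25, 0.55)), "MITF")
        assert report["phenotype"].tolist() == [
            "melanocytic", "mesenchymal", "melanocytic",
        ]

    def test_zero_trajectory_maps_to_lowest_zone(self):
        model = SingleGeneCircuit(beta=0.0, delta=1.0)
        traj = simulate(model, SignalProfile((2.0,), (0.0, 0.0)), 4.0)
        report = phase_report(traj, melanoma_state_map((0.25, 0.55)), "X")
        assert set(report["phenotype"]) == {"mesenchymal"}
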
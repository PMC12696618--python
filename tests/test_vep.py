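import numpy as np
import pytest

import srpt
from srpt.simulate import LfpRecording, NoiseParams, component_kernel, simulate_session
from srpt.vep import (
    ComponentMeasure,
    ComponentSpec,
    Vep,
    a2_positivity,
    average_hemispheres,
    average_vep,
    block_latencies,
    component_measures,
    default_component_specs,
    detect_biphasic,
    extract_epochs,
    plasticity_delta,
    sequence_magnitude,
    vep_latency,
    vep_magnitude,
)

from conftest import dense_peak_to_peak


def make_vep(waveform, window=(-100.0, 500.0), rate=1000.0):
    return Vep(np.asarray(waveform, float), window, rate, n_trials=200)


class TestExtractEpochs:
    def test_shape_contract(self, default_model, single300):
        rec = simulate_session(default_model, single300, seed=0, channels=["ACC"])
        mat = extract_epochs(rec, single300.select(seq_position=1), (-100.0, 500.0), "ACC")
        assert mat.values.shape == (200, 600)

    def test_alignment_of_synthetic_impulse(self, single300):
        v = np.zeros(int(single300.duration_ms), dtype=np.float32)
        for ev in single300.events:
            v[int(ev.onset)] = -50.0
        rec = LfpRecording(1000.0, 0.0, {"ACC": v}, single300)
        mat = extract_epochs(rec, single300.events, (-100.0, 500.0), "ACC")
        cols = np.argmin(mat.values, axis=1)
        assert np.all(cols == 100)

    def test_out_of_bounds_epoch(self, default_model, single300):
        rec = simulate_session(default_model, single300, seed=0, channels=["ACC"])
        last = single300.events[-1]
        with pytest.raises(ValueError, match="bounds"):
            extract_epochs(rec, [last], (-100.0, 5000.0), "ACC")

    def test_empty_selection(self, default_model, single300):
        rec = simulate_session(default_model, single300, seed=0, channels=["ACC"])
        with pytest.raises(ValueError, match="empty"):
            extract_epochs(rec, [], (-100.0, 500.0), "ACC")


class TestAverageVep:
    def test_identical_rows(self):
        from srpt.vep import TrialMatrix

        row = np.sin(np.linspace(0, 3, 100))
        mat = TrialMatrix(np.vstack([row, row]), (0.0, 100.0), 1000.0)
        assert np.allclose(average_vep(mat).waveform, row)

    def test_antisymmetric_rows_cancel(self):
        from srpt.vep import TrialMatrix

        row = np.sin(np.linspace(0, 3, 100))
        mat = TrialMatrix(np.vstack([row, -row]), (0.0, 100.0), 1000.0)
        assert np.allclose(average_vep(mat).waveform, 0.0)

    def test_row_permutation_invariance(self):
        from srpt.vep import TrialMatrix

        rng = np.random.default_rng(0)
        rows = rng.normal(0, 1, (20, 50))
        mat = TrialMatrix(rows, (0.0, 50.0), 1000.0)
        perm = TrialMatrix(rows[rng.permutation(20)], (0.0, 50.0), 1000.0)
        assert np.allclose(average_vep(mat).waveform, average_vep(perm).waveform)

    def test_mse_shrinks_with_trial_count(self):
        """Averaging variance follows the 1/n law: 50 -> 200 trials ~ x4 MSE drop."""
        ratios = []
        for s in range(6):
            m = srpt.default_subject_model(seed=s)
            m.noise = NoiseParams(white_sd=20.0, pink_scale=0.0)
            proto = srpt.make_protocol("SINGLE", stimulus_duration=300.0)
            rec = simulate_session(m, proto, seed=s, channels=["ACC"])
            mat = extract_epochs(rec, proto.select(seq_position=1), (-100.0, 400.0), "ACC")
            truth = None
            for n in (50, 200):
                vep = average_vep(mat, np.arange(n))
                if truth is None:
                    truth = np.zeros_like(vep.waveform)
                    for k in m.region_params["ACC"]["A"]:
                        truth += component_kernel(k, vep.times)
                mse = np.mean((vep.waveform - truth) ** 2)
                if n == 50:
                    mse50 = mse
            ratios.append(mse50 / mse)
        assert np.mean(ratios) == pytest.approx(4.0, rel=0.35)

    def test_empty_subset(self):
        from srpt.vep import TrialMatrix

        mat = TrialMatrix(np.zeros((5, 10)), (0.0, 10.0), 1000.0)
        with pytest.raises(ValueError, match="empty"):
            average_vep(mat, [])


class TestLatencyAndMagnitude:
    def test_latency_of_constructed_trough(self):
        t = np.arange(-100, 500)
        w = -30.0 * np.exp(-0.5 * ((t - 185) / 10) ** 2)
        vep = make_vep(w)
        assert vep_latency(vep, (120.0, 320.0)) == pytest.approx(185.0, abs=1.0)

    def test_latency_scale_and_offset_invariance(self):
        t = np.arange(-100, 500)
        w = -30.0 * np.exp(-0.5 * ((t - 185) / 10) ** 2)
        base = vep_latency(make_vep(w), (120.0, 320.0))
        assert vep_latency(make_vep(3.0 * w), (120.0, 320.0)) == base
        assert vep_latency(make_vep(w + 17.0), (120.0, 320.0)) == base

    def test_latency_tie_breaks_earliest(self):
        w = np.zeros(600)
        w[300] = w[400] = -10.0
        assert vep_latency(make_vep(w), (0.0, 500.0)) == pytest.approx(200.0)

    def test_flat_window_unquantifiable(self):
        assert np.isnan(vep_latency(make_vep(np.zeros(600)), (0.0, 500.0)))

    def test_magnitude_trough_then_peak(self):
        w = np.zeros(600)
        w[250] = -40.0
        w[300] = 15.0
        assert vep_magnitude(make_vep(w), (0.0, 500.0)) == pytest.approx(55.0)
        assert vep_magnitude(make_vep(2 * w), (0.0, 500.0)) == pytest.approx(110.0)

    def test_magnitude_ignores_pre_trough_positivity(self):
        w = np.zeros(600)
        w[150] = 30.0   # positivity before the trough must not count
        w[250] = -40.0
        w[300] = 15.0
        assert vep_magnitude(make_vep(w), (0.0, 500.0)) == pytest.approx(55.0)

    def test_magnitude_matches_dense_grid_oracle(self, noiseless_model, single300):
        rec = simulate_session(noiseless_model, single300, seed=0, channels=["V1L"])
        mat = extract_epochs(rec, single300.select(seq_position=1), (-100.0, 400.0), "V1L")
        vep = average_vep(mat)
        got = vep_magnitude(vep, (20.0, 200.0))
        oracle, _, _ = dense_peak_to_peak(
            noiseless_model.region_params["V1L"]["A"], (20.0, 200.0)
        )
        assert got == pytest.approx(oracle, abs=0.5)


class TestComponentMeasures:
    def test_noiseless_sequence_recovers_programmed_latencies(self, noiseless_model, abcd300):
        rec = simulate_session(noiseless_model, abcd300, seed=0, channels=["ACC"])
        mat = extract_epochs(rec, abcd300.select(seq_position=1), (-100.0, 1620.0), "ACC")
        vep = average_vep(mat)
        specs = default_component_specs("ABCD", 300.0, "ACC")
        got = {m.name: m for m in component_measures(vep, specs, 300.0)}
        assert got["A1"].latency == pytest.approx(60.0, abs=1.0)
        assert got["A2"].latency == pytest.approx(185.0, abs=1.0)
        assert got["B1"].latency == pytest.approx(60.0, abs=1.0)  # own-onset reference
        assert got["B1"].latency_from_lead == pytest.approx(360.0, abs=1.0)

    def test_all_zero_amplitudes_flagged(self, abcd300):
        vep = make_vep(np.zeros(1720), window=(-100.0, 1620.0))
        specs = default_component_specs("ABCD", 300.0, "ACC")
        for m in component_measures(vep, specs, 300.0):
            assert not m.valid and np.isnan(m.latency)

    def test_composite_window_takes_earlier_trough(self, noiseless_model):
        """With 150 ms stimuli one window spans the overlapping N2/N1 lobes."""
        proto = srpt.make_protocol("ABCD", stimulus_duration=150.0)
        rec = simulate_session(noiseless_model, proto, seed=0, channels=["ACC"])
        mat = extract_epochs(rec, proto.select(seq_position=1), (-100.0, 1020.0), "ACC")
        vep = average_vep(mat)
        specs = default_component_specs("ABCD", 150.0, "ACC")
        comp = {m.name: m for m in component_measures(vep, specs, 150.0)}["B-composite"]
        # brute-force composite minimum over both lobes on a dense grid
        kernels = [k for k in noiseless_model.region_params["ACC"]["A"] if k.name == "N2"]
        kb = [k for k in noiseless_model.region_params["ACC"]["B"] if not k.lead_only]
        grid = np.arange(170.0, 270.0, 0.1)
        wave = sum(component_kernel(k, grid) for k in kernels) + sum(
            component_kernel(k, grid - 150.0) for k in kb
        )
        t_oracle = grid[np.argmin(wave)] - 150.0  # own-onset reference
        assert comp.latency == pytest.approx(t_oracle, abs=1.0)
        # the slow lead-N2 trough (185 - 150 = 35 ms post-B) precedes the B-driven N1
        assert comp.latency < 50.0

    def test_overlapping_specs_rejected(self):
        vep = make_vep(np.zeros(600))
        specs = [
            ComponentSpec("A1", (20.0, 150.0)),
            ComponentSpec("A2", (120.0, 320.0)),
        ]
        with pytest.raises(ValueError, match="overlap"):
            component_measures(vep, specs, 300.0)


class TestPositivity:
    def test_constructed_positivity(self):
        w = np.zeros(600)
        w[285] = -20.0
        w[360] = 12.0
        vep = make_vep(w)
        spec = ComponentSpec("A2", (120.0, 320.0))
        assert a2_positivity(vep, spec) == pytest.approx(12.0)

    def test_dc_offset_invariance(self):
        w = np.zeros(600)
        w[285] = -20.0
        w[360] = 12.0
        spec = ComponentSpec("A2", (120.0, 320.0))
        assert a2_positivity(make_vep(w + 5.0), spec) == pytest.approx(
            a2_positivity(make_vep(w), spec)
        )

    def test_positivity_gain_recovery(self):
        """AS regime: programmed x2 positivity growth is recovered within 15%."""
        from srpt.io import acc_positivity_table
        from srpt.simulate import simulate_cohort
        from srpt.vep import quantify_cohort

        ratios = []
        for s in range(4):
            co = simulate_cohort("genotype-contrast", n_per_group=5, seed=300 + s,
                                 channels=("ACC",))
            co.records = [r for r in co.records if r.genotype == "AS" and r.day in (1, 4)]
            meas = quantify_cohort(co, channels=["ACC"])
            pos = acc_positivity_table(meas)
            ratios.append((pos[4] / pos[1]).mean())
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.15)


class TestSequenceMagnitude:
    def test_mean_identity_and_symmetry(self):
        assert sequence_magnitude([10, 20, 30, 40]) == 25.0
        assert sequence_magnitude([7, 7, 7, 7]) == 7.0
        assert sequence_magnitude([40, 10, 30, 20]) == 25.0

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            sequence_magnitude([1, 2, 3])
        with pytest.raises(ValueError, match="missing"):
            sequence_magnitude([1, 2, 3, np.nan])


class TestBlockLatencies:
    def test_stationary_session_blocks_agree(self):
        from srpt.simulate import simulate_cohort

        co = simulate_cohort("single-300-null", n_per_group=4, seed=21, channels=("ACC",))
        spread = []
        for rec, proto, lfp in co.iter_sessions(channels=["ACC"]):
            if rec.day != 1:
                continue
            mat = extract_epochs(lfp, proto.select(seq_position=1), (-100.0, 400.0), "ACC")
            lats = [lat for _, lat in block_latencies(mat, (120.0, 320.0))]
            spread.append(max(lats) - min(lats))
        # no within-session drift: blocks agree within +/- 4 ms
        assert np.median(spread) <= 8.0

    def test_programmed_drift_recovered_monotone(self, noiseless_model):
        """Within-session drift built per-block appears in block latencies."""
        proto = srpt.make_protocol("SINGLE", stimulus_duration=300.0)
        n = int(proto.duration_ms)
        v = np.zeros(n, dtype=np.float32)
        t = np.arange(-50.0, 350.0)
        for ev in proto.events:
            lat = 185.0 - 4.0 * (ev.block - 1)  # -12 ms across four blocks
            wave = -25.0 * np.exp(-0.5 * ((t - lat) / 5.0) ** 2)
            i0 = int(ev.onset) - 50
            v[i0 : i0 + len(wave)] += wave
        rec = LfpRecording(1000.0, 0.0, {"ACC": v}, proto)
        mat = extract_epochs(rec, proto.events, (-100.0, 400.0), "ACC")
        lats = [lat for _, lat in block_latencies(mat, (120.0, 320.0))]
        assert all(b < a for a, b in zip(lats, lats[1:]))

    def test_non_divisible_trial_count(self):
        from srpt.vep import TrialMatrix

        mat = TrialMatrix(np.random.default_rng(0).normal(size=(199, 100)),
                          (0.0, 100.0), 1000.0)
        with pytest.raises(ValueError, match="divide"):
            block_latencies(mat, (0.0, 100.0))


class TestHemispheresAndDelta:
    def _meas(self, latency, magnitude, valid=True):
        return ComponentMeasure("A2", latency, magnitude, valid=valid,
                                latency_from_lead=latency)

    def test_both_valid_averaged(self):
        out = average_hemispheres(self._meas(100.0, 100.0), self._meas(80.0, 80.0))
        assert out.latency == 90.0 and out.magnitude == 90.0

    def test_single_valid_passthrough(self):
        good, bad = self._meas(100.0, 100.0), self._meas(np.nan, np.nan, valid=False)
        assert average_hemispheres(good, bad).latency == 100.0
        assert average_hemispheres(bad, good).latency == 100.0

    def test_both_invalid_rejected(self):
        bad = self._meas(np.nan, np.nan, valid=False)
        with pytest.raises(ValueError, match="invalid"):
            average_hemispheres(bad, bad)

    def test_plasticity_delta(self):
        assert plasticity_delta(185.0, 165.0) == -20.0
        assert plasticity_delta(170.0, 170.0) == 0.0
        with pytest.raises(ValueError):
            plasticity_delta(np.nan, 165.0)


class TestDetectBiphasic:
    def test_constructed_two_troughs(self):
        t = np.arange(-100, 500, dtype=float)
        w = -20.0 * np.exp(-0.5 * ((t - 20) / 6) ** 2) - 20.0 * np.exp(
            -0.5 * ((t - 60) / 6) ** 2
        )
        ok, times = detect_biphasic(make_vep(w), (0.0, 120.0))
        assert ok and len(times) == 2
        assert times[0] == pytest.approx(20.0, abs=2.0)
        assert times[1] == pytest.approx(60.0, abs=2.0)

    def test_single_trough_not_biphasic(self):
        t = np.arange(-100, 500, dtype=float)
        w = -20.0 * np.exp(-0.5 * ((t - 60) / 10) ** 2)
        ok, times = detect_biphasic(make_vep(w), (0.0, 120.0))
        assert not ok and len(times) == 1

    def test_flat_input_false_without_error(self):
        ok, times = detect_biphasic(make_vep(np.zeros(600)), (0.0, 120.0))
        assert not ok and times == []

    def test_shallow_second_trough_rejected(self):
        t = np.arange(-100, 500, dtype=float)
        w = -20.0 * np.exp(-0.5 * ((t - 20) / 6) ** 2) - 4.0 * np.exp(
            -0.5 * ((t - 60) / 6) ** 2
        )
        ok, _ = detect_biphasic(make_vep(w), (0.0, 120.0), depth_fraction=0.5)
        assert not ok
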
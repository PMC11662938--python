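"""Generator: state paths, rendering, cohorts, titration, solenoid."""

import numpy as np
import pytest
from scipy import stats

from pprfret import (
    InjectionConfig,
    KineticScheme,
    PhotophysicsConfig,
    SolenoidSpec,
    TitrationModel,
    TraceSet,
    simulate_injection_cohort,
    simulate_state_path,
    simulate_titration,
    generate_ideal_solenoid,
    render_two_color,
    render_three_color,
)
from pprfret.io import LASER_BLUE
from pprfret.simulate import two_state_scheme
from pprfret.titration import bound_fraction


class TestStatePath:
    def test_one_state_scheme_never_jumps(self):
        sch = KineticScheme(("only",), np.array([0.4]), np.zeros((1, 1)))
        path = simulate_state_path(sch, 50.0, 0.2, seed=0)
        assert len(path.jump_times) == 0
        assert np.all(path.states == 0)

    def test_zero_rates_stay_in_initial_state(self):
        sch = two_state_scheme(k_on=0.0, k_off=0.0)
        path = simulate_state_path(sch, 50.0, 0.2, seed=1, initial_state=1)
        assert np.all(path.states == 1)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="rates"):
            KineticScheme(("a", "b"), np.array([0.4, 0.8]), np.array([[0, -1.0], [1, 0]]))

    def test_dwell_times_exponential(self):
        # k12 = k21 = 0.5/s: dwell mean 2.0 s; KS against Expon(2.0) at alpha=0.01
        sch = two_state_scheme(k_on=0.5, k_off=0.5)
        rng = np.random.default_rng(42)
        dwells = []
        while len(dwells) < 10_000:
            path = simulate_state_path(sch, 2000.0, 0.2, rng)
            dwells.extend(path.dwell_times())
        dwells = np.array(dwells[:10_000])
        se = 2.0 / np.sqrt(len(dwells))
        assert abs(dwells.mean() - 2.0) < 3 * se
        assert stats.kstest(dwells, "expon", args=(0, 2.0)).pvalue > 0.01


class TestRenderTwoColor:
    def test_even_split_without_crosstalk(self, noiseless_phys):
        sch = KineticScheme(("s",), np.array([0.5]), np.zeros((1, 1)))
        tr = render_two_color(simulate_state_path(sch, 10, 0.2, seed=0), noiseless_phys, seed=0)
        assert np.allclose(tr.donor, 500.0) and np.allclose(tr.acceptor, 500.0)

    def test_crosstalk_leakage_at_zero_fret(self):
        phys = PhotophysicsConfig(total_intensity=1000.0, crosstalk_g=0.1, noise_sd=0.0)
        sch = KineticScheme(("s",), np.array([0.0]), np.zeros((1, 1)))
        tr = render_two_color(simulate_state_path(sch, 10, 0.2, seed=0), phys, seed=0)
        assert np.allclose(tr.donor, 1000.0) and np.allclose(tr.acceptor, 100.0)

    def test_forward_model_inverts_through_calibrated_pipeline(self, study_phys):
        # render at E = 0.8 with g = 0.07, calibrate g, compute FRET: mean 0.80 +/- 0.01
        from pprfret import compute_fret, estimate_crosstalk
        from pprfret.simulate import simulate_donor_only_cohort

        sch = KineticScheme(("bound",), np.array([0.8]), np.zeros((1, 1)))
        phys = PhotophysicsConfig(
            total_intensity=1000.0, crosstalk_g=0.07, noise_sd=study_phys.noise_sd
        )
        donly = simulate_donor_only_cohort(10, phys, seed=11, duration=60)
        g = estimate_crosstalk(donly)
        vals = []
        rng = np.random.default_rng(5)
        for _ in range(20):
            tr = render_two_color(simulate_state_path(sch, 60, 0.2, rng), phys, rng)
            vals.append(compute_fret(tr, g).fret)
        assert abs(np.concatenate(vals).mean() - 0.80) < 0.01

    def test_post_donor_bleach_acceptor_dark(self):
        # bleach ordering consistency: after donor bleach both channels ~ background
        phys = PhotophysicsConfig(
            total_intensity=1000.0, crosstalk_g=0.07, noise_sd=5.0,
            background=20.0, donor_bleach_mean=5.0,
        )
        sch = KineticScheme(("s",), np.array([0.5]), np.zeros((1, 1)))
        rng = np.random.default_rng(3)
        for _ in range(10):
            tr = render_two_color(simulate_state_path(sch, 60, 0.2, rng), phys, rng)
            db = tr.ground_truth.donor_bleach_frame
            if db is not None and db < len(tr) - 10:
                post = tr.acceptor[db:]
                assert post.mean() < 20.0 + 5 * phys.noise_sd
        assert np.all(np.isfinite(tr.donor)) and np.all(np.isfinite(tr.acceptor))


class TestInjectionCohort:
    def test_wait_time_mean_recovery(self, noiseless_phys):
        inj = InjectionConfig(injection_time=10.0, wait_mean=10.6, fraction_stable=1.0)
        ts = simulate_injection_cohort(168, inj, noiseless_phys, seed=4, duration=400)
        waits = np.array([tr.ground_truth.wait_time for tr in ts])
        assert abs(waits.mean() - 10.6) < 3 * 10.6 / np.sqrt(168)

    def test_no_binding_precedes_injection(self, noiseless_phys):
        inj = InjectionConfig(injection_time=10.0, wait_mean=5.0)
        ts = simulate_injection_cohort(50, inj, noiseless_phys, seed=5)
        for tr in ts:
            gt = tr.ground_truth
            assert gt.first_binding_time >= 10.0
            bound_frames = np.flatnonzero(gt.fret_means[gt.frame_states] >= 0.5)
            if len(bound_frames):
                assert bound_frames[0] * 0.2 >= 10.0 - 0.2

    def test_fully_stable_cohort_has_no_release(self, noiseless_phys):
        inj = InjectionConfig(wait_mean=5.0, fraction_stable=1.0)
        ts = simulate_injection_cohort(50, inj, noiseless_phys, seed=6)
        for tr in ts:
            states = tr.ground_truth.frame_states
            # once bound (state 1), never unbound again
            d = np.diff(states.astype(int))
            assert np.all(d >= 0)

    def test_fixed_seed_bit_identical(self, study_phys):
        inj = InjectionConfig()
        a = simulate_injection_cohort(5, inj, study_phys, seed=7)
        b = simulate_injection_cohort(5, inj, study_phys, seed=7)
        for x, y in zip(a, b):
            assert np.array_equal(x.donor, y.donor)
            assert np.array_equal(x.acceptor, y.acceptor)


class TestThreeColor:
    def _phys(self, noise=0.0):
        return PhotophysicsConfig(total_intensity=1000.0, crosstalk_g=0.07, noise_sd=noise)

    def test_unbound_488_frames_are_dark(self):
        sch = two_state_scheme()  # starts unbound, zero rates
        tr = render_three_color(simulate_state_path(sch, 20, 0.2, seed=0), self._phys(), seed=0)
        m = tr.laser == LASER_BLUE
        total = tr.donor[m] + tr.acceptor[m] + tr.blue[m]
        assert np.allclose(total, 0.0)

    def test_bound_488_total_constant(self):
        sch = two_state_scheme()
        path = simulate_state_path(sch, 20, 0.2, seed=0, initial_state=1)
        tr = render_three_color(path, self._phys(), seed=0)
        m = tr.laser == LASER_BLUE
        total = tr.donor[m] + tr.acceptor[m] + tr.blue[m]
        assert np.allclose(total, 1000.0)

    def test_488_signal_onset_coincides_with_binding(self, noiseless_phys):
        inj = InjectionConfig(injection_time=4.0, wait_mean=6.0, fraction_stable=1.0)
        ts = simulate_injection_cohort(20, inj, noiseless_phys, seed=8, duration=60,
                                       three_color=True)
        for tr in ts:
            gt = tr.ground_truth
            bound = gt.fret_means[gt.frame_states] >= 0.5
            k = np.flatnonzero(bound)
            m488 = np.flatnonzero(tr.laser == LASER_BLUE)
            total = (tr.donor + tr.acceptor + tr.blue)[m488]
            lit = m488[total > 1.0]
            if len(k) and len(lit):
                first_488_after_k = m488[m488 >= k[0]][0]
                assert lit[0] == first_488_after_k


class TestTitration:
    def test_quadratic_depletion_value(self):
        # Kd = S = L = 5 nM: fb = (15 - sqrt(125)) / 10
        assert bound_fraction(5.0, 5.0, 5.0) == pytest.approx((15 - np.sqrt(125)) / 10, abs=1e-12)

    def test_saturation_and_stoichiometric_limits(self):
        assert bound_fraction(1e9, 1.2, 5.0) == pytest.approx(1.0, abs=1e-4)
        assert bound_fraction(2.0, 0.0, 5.0) == pytest.approx(2.0 / 5.0, abs=1e-12)
        assert bound_fraction(10.0, 0.0, 5.0) == pytest.approx(1.0, abs=1e-12)

    def test_noise_free_curve_hits_model(self):
        model = TitrationModel(kd=1.2, sensor_conc=5.0, noise_sd=0.0)
        curve = simulate_titration(model, seed=0)
        fb = bound_fraction(model.ligand_concs, 1.2, 5.0)
        assert np.allclose(curve.observed_fret, 0.3 + fb * 0.4)


class TestSolenoid:
    def test_full_turn_alignment_40_degrees(self):
        cs = generate_ideal_solenoid(SolenoidSpec(rise=4.8, twist=40.0, radius=25.0, n_repeats=12),
                                     decorate=False)
        p0, p9 = cs.xyz[0], cs.xyz[9]
        assert np.allclose(p9[:2], p0[:2], atol=1e-9)
        assert p9[2] - p0[2] == pytest.approx(43.2, abs=1e-9)

    def test_full_turn_alignment_36_degrees(self):
        cs = generate_ideal_solenoid(SolenoidSpec(rise=8.5, twist=36.0, radius=25.0, n_repeats=12),
                                     decorate=False)
        p0, p10 = cs.xyz[0], cs.xyz[10]
        assert np.allclose(p10[:2], p0[:2], atol=1e-9)
        assert p10[2] - p0[2] == pytest.approx(85.0, abs=1e-9)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SolenoidSpec(rise=4.8, twist=40.0, radius=-1.0)


class TestTraceTableRoundTrip:
    def test_csv_round_trip(self, tmp_path, study_phys):
        ts = simulate_injection_cohort(3, InjectionConfig(), study_phys, seed=9, duration=30)
        path = tmp_path / "traces.csv"
        ts.write_csv(path)
        ts.write_ground_truth(tmp_path / "gt.json")
        back = TraceSet.read_csv(path)
        back.attach_ground_truth(tmp_path / "gt.json")
        assert len(back) == 3
        for a, b in zip(ts, back):
            assert a.molecule_id == b.molecule_id
            np.testing.assert_allclose(a.donor, b.donor)
            np.testing.assert_allclose(a.time_s, b.time_s)
            assert a.ground_truth.wait_time == pytest.approx(b.ground_truth.wait_time)
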
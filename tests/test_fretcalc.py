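"""Crosstalk calibration, Eq.-style FRET ratio, step detection, QC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pprfret import (
    CrosstalkModel,
    RawTrace,
    TraceSet,
    compute_fret,
    detect_photobleach_steps,
    estimate_crosstalk,
    select_molecules,
    truncate_at_photobleach,
)
from pprfret.fretcalc import locate_bleach
from pprfret.simulate import (
    KineticScheme,
    PhotophysicsConfig,
    channel_noise_for_fret_sd,
    simulate_donor_only_cohort,
    simulate_state_path,
    render_two_color,
)


def _trace(donor, acceptor, dt=0.2, mol="m"):
    donor = np.asarray(donor, float)
    return RawTrace(mol, np.arange(len(donor)) * dt, donor, np.asarray(acceptor, float))


class TestEstimateCrosstalk:
    def test_exact_ratio(self):
        d = np.full(50, 800.0)
        ts = TraceSet([_trace(d, 0.1 * d)])
        assert estimate_crosstalk(ts).g == pytest.approx(0.1, abs=1e-12)

    def test_zero_acceptor_gives_zero(self):
        d = np.full(50, 800.0)
        ts = TraceSet([_trace(d, np.zeros(50))])
        assert estimate_crosstalk(ts).g == 0.0

    def test_all_zero_donor_rejected(self):
        ts = TraceSet([_trace(np.zeros(50), np.zeros(50))])
        with pytest.raises(ValueError, match="undefined|usable"):
            estimate_crosstalk(ts)

    def test_recovery_from_noisy_donor_only_cohort(self):
        phys = PhotophysicsConfig(
            total_intensity=1000.0, crosstalk_g=0.07, noise_sd=20.0,
            donor_bleach_mean=60.0,
        )
        ts = simulate_donor_only_cohort(20, phys, seed=1, duration=120)
        assert estimate_crosstalk(ts).g == pytest.approx(0.07, abs=0.005)

    @settings(deadline=None, max_examples=20)
    @given(scale=st.floats(min_value=0.1, max_value=100.0))
    def test_invariant_to_uniform_intensity_rescaling(self, scale):
        rng = np.random.default_rng(0)
        d = 1000.0 + rng.normal(0, 10, 80)
        a = 0.07 * d + rng.normal(0, 2, 80)
        g1 = estimate_crosstalk(TraceSet([_trace(d, a)])).g
        g2 = estimate_crosstalk(TraceSet([_trace(scale * d, scale * a)])).g
        assert g1 == pytest.approx(g2, rel=1e-9)


class TestComputeFret:
    def test_even_split_no_crosstalk(self):
        tj = compute_fret(_trace([100.0], [100.0]), CrosstalkModel(0.0))
        assert tj.fret[0] == pytest.approx(0.5)

    def test_crosstalk_corrected_ratio(self):
        # CI = 120 - 0.1*200 = 100; FRET = 100 / (100 + 200)
        tj = compute_fret(_trace([200.0] * 3, [120.0] * 3), CrosstalkModel(0.1))
        assert np.allclose(tj.fret, 1.0 / 3.0)

    def test_g_zero_reduces_to_plain_ratio(self):
        rng = np.random.default_rng(2)
        d = rng.uniform(100, 900, 50)
        a = rng.uniform(100, 900, 50)
        tj = compute_fret(_trace(d, a), CrosstalkModel(0.0))
        assert np.allclose(tj.fret, a / (a + d))

    def test_monotone_in_acceptor(self):
        accs = np.linspace(10, 900, 30)
        vals = [
            compute_fret(_trace([300.0], [float(a)]), CrosstalkModel(0.07)).fret[0]
            for a in accs
        ]
        assert np.all(np.diff(vals) > 0)

    def test_unclamped_and_nonfinite_flagged(self):
        # denominator zero: CI + D = 0
        tj = compute_fret(_trace([100.0, 100.0], [-100.0, 300.0]), CrosstalkModel(0.0))
        assert tj.nonfinite[0] and not tj.nonfinite[1]
        assert tj.fret[1] > 0  # value reported as-is, no clamping
        tj2 = compute_fret(_trace([100.0], [-50.0]), CrosstalkModel(0.0))
        assert tj2.fret[0] < 0  # negative FRET kept


class TestStepDetection:
    def test_noiseless_single_step(self):
        x = np.r_[np.full(150, 1000.0), np.zeros(150)]
        ev = detect_photobleach_steps(x)
        assert len(ev) == 1 and ev[0].frame == 150 and ev[0].sign == -1

    def test_two_sequential_drops_in_order(self):
        x = np.r_[np.full(100, 1000.0), np.full(80, 500.0), np.zeros(100)]
        ev = detect_photobleach_steps(x)
        assert [e.frame for e in ev] == [100, 180]

    def test_snr5_localization(self):
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            y = np.r_[np.full(200, 100.0), np.zeros(100)] + rng.normal(0, 20.0, 300)
            ev = detect_photobleach_steps(y)
            if any(abs(e.frame - 200) <= 1 for e in ev):
                hits += 1
        assert hits / n_rep >= 0.95

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_photobleach_steps(np.zeros(5))


class TestTruncation:
    def _traj(self, n=400):
        return compute_fret(
            _trace(np.full(n, 500.0), np.full(n, 500.0)), CrosstalkModel(0.0)
        )

    def test_earliest_bleach_wins(self):
        from pprfret.fretcalc import BleachCall

        tj = truncate_at_photobleach(self._traj(), BleachCall(300, 200))
        assert tj.truncation_frame == 200 and not tj.censored
        assert tj.imaging_lifetime == pytest.approx(200 * 0.2)

    def test_no_bleach_keeps_full_length_censored(self):
        tj = truncate_at_photobleach(self._traj(), None)
        assert tj.truncation_frame == 400 and tj.censored

    def test_lifetime_in_seconds(self):
        tj = truncate_at_photobleach(self._traj(), 200)
        assert tj.imaging_lifetime == pytest.approx(40.0)

    def test_bleach_at_frame_zero_rejected(self):
        with pytest.raises(ValueError, match="frame 0"):
            truncate_at_photobleach(self._traj(), 0)


class TestBleachLocalizationAndQC:
    def test_truncation_matches_ground_truth(self, study_phys, switching_scheme):
        rng = np.random.default_rng(11)
        phys = PhotophysicsConfig(
            total_intensity=1000.0, crosstalk_g=0.07,
            noise_sd=channel_noise_for_fret_sd(0.08, 1000.0),
            donor_bleach_mean=100.0, acceptor_bleach_mean=100.0,
        )
        agree = 0
        n = 0
        for _ in range(15):
            path = simulate_state_path(switching_scheme, 120, 0.2, rng)
            tr = render_two_color(path, phys, rng)
            gt = tr.ground_truth
            truth = [f for f in (gt.donor_bleach_frame, gt.acceptor_bleach_frame) if f is not None]
            truth = min(truth) if truth else None
            det = locate_bleach(tr).truncation_frame
            n += 1
            if truth is None:
                agree += det is None
            elif det is not None and abs(det - truth) <= 1:
                agree += 1
        assert agree / n >= 0.85

    def test_single_pair_trace_accepted(self):
        # clean construction: one acceptor bleach (anticorrelated), then donor bleach
        n = 400
        d = np.full(n, 300.0)
        a = np.full(n, 700.0)
        d[200:] , a[200:] = 1000.0, 70.0  # acceptor bleach at 200
        d[320:], a[320:] = 0.0, 0.0  # donor bleach at 320
        rng = np.random.default_rng(0)
        tr = _trace(d + rng.normal(0, 10, n), a + rng.normal(0, 10, n))
        kept, report = select_molecules(TraceSet([tr]))
        assert len(kept) == 1, report

    def test_multi_acceptor_rejected(self):
        n = 400
        d = np.full(n, 300.0)
        a = np.full(n, 700.0)
        a[150:] = 380.0  # first acceptor bleach
        a[250:] = 60.0  # second acceptor bleach
        d[340:], a[340:] = 0.0, 0.0  # donor bleach
        rng = np.random.default_rng(1)
        tr = _trace(d + rng.normal(0, 8, n), a + rng.normal(0, 8, n))
        kept, report = select_molecules(TraceSet([tr]))
        assert len(kept) == 0
        assert "multi-acceptor" in report.iloc[0]["reason"]

    def test_pure_noise_rejected(self):
        rng = np.random.default_rng(2)
        tr = _trace(rng.normal(50, 5, 300), rng.normal(50, 5, 300))
        kept, report = select_molecules(TraceSet([tr]))
        assert len(kept) == 0
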
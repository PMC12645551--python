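import numpy as np
import pytest
from scipy.stats import spearmanr

from magnospike import (
    EventLabel,
    ExperimentEffect,
    ExperimentScript,
    PhasicModelParams,
    RenewalModelParams,
    ValidationError,
    analytic_mean_rate,
    burst_stats,
    calibrate_input_rate,
    cck_response,
    classify_phasic,
    extract_isis,
    isi_cv,
    isi_mode,
    isi_histogram,
    segment_bursts,
    simulate_experiment,
    simulate_phasic,
    simulate_postspike_renewal,
)
from magnospike.simulate import _sample_isis


class TestRenewalGenerator:
    def test_deterministic_for_fixed_seed(self):
        p = RenewalModelParams(input_rate=5.0, hap_amp=2.0, seed=99)
        a = simulate_postspike_renewal(p, 100.0)
        b = simulate_postspike_renewal(p, 100.0)
        np.testing.assert_array_equal(a.times, b.times)

    def test_poisson_cv_one(self, poisson_isis):
        assert isi_cv(poisson_isis) == pytest.approx(1.0, abs=0.02)

    def test_hap_regularizes(self):
        p = calibrate_input_rate(
            5.0, RenewalModelParams(input_rate=5.0, hap_amp=5.0, hap_tau=20.0,
                                    seed=3))
        isis = extract_isis(simulate_postspike_renewal(p, 2000.0))
        assert isi_cv(isis) < 1.0
        assert isi_mode(isi_histogram(isis)) > 0

    def test_refractory_enforced(self):
        p = RenewalModelParams(input_rate=20.0, refractory=5.0, seed=4)
        isis = extract_isis(simulate_postspike_renewal(p, 500.0))
        assert isis.min() >= 5.0 - 1e-9

    @pytest.mark.parametrize("params", [
        RenewalModelParams(input_rate=5.0, seed=31),
        RenewalModelParams(input_rate=8.0, hap_amp=3.0, hap_tau=25.0, seed=32),
        RenewalModelParams(input_rate=6.0, hap_amp=2.0, hap_tau=20.0,
                           dap_amp=1.0, dap_tau=100.0, seed=33),
        RenewalModelParams(input_rate=10.0, hap_amp=4.0, hap_tau=30.0,
                           refractory=3.0, seed=34),
    ])
    def test_mean_rate_matches_analytic_integral(self, params):
        train = simulate_postspike_renewal(params, 5000.0)
        simulated = train.n_spikes / train.duration
        assert simulated == pytest.approx(analytic_mean_rate(params), rel=0.02)

    def test_calibration_hits_target(self):
        p = calibrate_input_rate(
            8.1, RenewalModelParams(input_rate=1.0, hap_amp=3.0, hap_tau=25.0))
        assert analytic_mean_rate(p) == pytest.approx(8.1, rel=1e-8)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            RenewalModelParams(input_rate=-1.0)
        with pytest.raises(ValidationError):
            RenewalModelParams(input_rate=1.0, hap_tau=0.0)


def test_isi_mode_tracks_hap_parameters():
    """Over a grid of HAP amplitude and time constant, the measured ISI
    mode increases with both (rank correlation > 0.9)."""
    haps = [1.0, 2.0, 3.5, 5.0]
    taus = [10.0, 20.0, 35.0, 50.0]
    rows = []
    rng_seed = 200
    for h in haps:
        for tau in taus:
            p = calibrate_input_rate(
                5.0, RenewalModelParams(input_rate=5.0, hap_amp=h,
                                        hap_tau=tau, seed=rng_seed))
            rng_seed += 1
            isis = _sample_isis(p, 50_000, np.random.default_rng(p.seed)) * 1e3
            # 5-ms histogram: the 1-ms argmax jitters on broad peaks
            rows.append((h, tau, isi_mode(isi_histogram(isis, 5.0))))
    arr = np.array(rows)
    # monotone in H at each fixed tau, and in tau at each fixed H
    for tau in taus:
        sub = arr[arr[:, 1] == tau]
        assert spearmanr(sub[:, 0], sub[:, 2]).statistic > 0.9
    for h in haps:
        sub = arr[arr[:, 0] == h]
        assert spearmanr(sub[:, 1], sub[:, 2]).statistic > 0.9


class TestPhasicGenerator:
    def test_classified_phasic_and_recovers_truth(self):
        p = PhasicModelParams(seed=7)
        train, truth = simulate_phasic(p, 7200.0, return_truth=True)
        assert classify_phasic(train) is True
        stats = burst_stats(segment_bursts(train), train)
        assert stats.mean_burst_duration == pytest.approx(
            truth.mean_burst_duration, rel=0.10)
        assert stats.mean_silence_duration == pytest.approx(
            truth.mean_silence_duration, rel=0.10)
        assert stats.intraburst_rate == pytest.approx(8.1, rel=0.10)

    def test_short_silences_merge_into_one_burst(self):
        p = PhasicModelParams(silence_duration_mean=3.0, silence_duration_sd=0.0,
                              duration_floor=1.0, burst_duration_sd=0.0,
                              burst_duration_mean=30.0, seed=9)
        train = simulate_phasic(p, 600.0)
        assert segment_bursts(train).n_bursts == 1

    def test_zero_variance_durations(self):
        p = PhasicModelParams(burst_duration_mean=40.0, burst_duration_sd=0.0,
                              silence_duration_mean=20.0,
                              silence_duration_sd=0.0, seed=10)
        train, truth = simulate_phasic(p, 1200.0, return_truth=True)
        durs = [b - a for a, b in truth.bursts]
        assert np.ptp(durs) < 1e-9

    def test_deterministic(self):
        a = simulate_phasic(PhasicModelParams(seed=11), 600.0)
        b = simulate_phasic(PhasicModelParams(seed=11), 600.0)
        np.testing.assert_array_equal(a.times, b.times)


class TestExperiments:
    def test_empty_script_matches_base(self):
        base = RenewalModelParams(input_rate=5.0, seed=41)
        train, meta = simulate_experiment(base, ExperimentScript(), 2000.0)
        rate = train.n_spikes / train.duration
        # ~4 SE of a Poisson count at n ~ 10,000
        assert rate == pytest.approx(analytic_mean_rate(base), rel=0.04)
        assert meta.events == []

    def test_step_effect_recovered(self):
        base = RenewalModelParams(input_rate=3.0, seed=11)
        script = ExperimentScript([ExperimentEffect(
            EventLabel.CCK, time=600.0, kind="step", delta=1.1,
            duration=300.0)])
        train, meta = simulate_experiment(base, script, 1200.0)
        r = cck_response(train, meta.event_time("CCK"))
        se = np.sqrt(3.0 / 300.0 + 4.1 / 300.0)  # Poisson SE of the delta
        assert r.delta == pytest.approx(1.1, abs=2 * se)

    def test_transient_resolves(self):
        base = RenewalModelParams(input_rate=4.0, seed=12)
        script = ExperimentScript([ExperimentEffect(
            EventLabel.CCK, time=600.0, kind="transient", delta=3.0,
            peak_s=150.0)])
        grid = np.array([600.0, 750.0, 600.0 + 900.0])
        prof = script.rate_delta(grid)
        assert prof[0] == 0.0
        assert prof[1] == pytest.approx(3.0)  # peak at 2.5 min
        assert prof[2] < 0.05 * 3.0  # <5% of peak left by 15 min

    def test_negative_rate_rejected(self):
        base = RenewalModelParams(input_rate=1.0, seed=13)
        script = ExperimentScript([ExperimentEffect(
            EventLabel.PE, time=10.0, kind="step", delta=-5.0,
            duration=100.0)])
        with pytest.raises(ValidationError):
            simulate_experiment(base, script, 200.0)

    def test_events_written_to_meta(self):
        base = RenewalModelParams(input_rate=5.0, seed=14)
        script = ExperimentScript([ExperimentEffect(
            EventLabel.PUMP_ON, time=900.0, kind="ramp",
            slope_per_mmol=1.0, duration=1800.0)])
        _, meta = simulate_experiment(base, script, 1000.0)
        assert meta.event_time(EventLabel.PUMP_ON) == 900.0
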
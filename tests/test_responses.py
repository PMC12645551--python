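import numpy as np
import pytest

from magnospike import (
    CellClass,
    EventLabel,
    ExperimentEffect,
    ExperimentScript,
    InsufficientDataError,
    RenewalModelParams,
    SpikeTrain,
    cck_response,
    classify_cell,
    osmotic_response,
    pe_response,
    peg_response,
    psth,
    simulate_experiment,
    simulate_postspike_renewal,
)
from magnospike.responses import infused_mmol_at


def regular(rate, start, end):
    return np.arange(start, end, 1.0 / rate)


class TestCckResponse:
    def test_constant_train_zero_delta(self):
        train = SpikeTrain(regular(5.0, 0.0, 1200.0), duration=1200.0)
        r = cck_response(train, 600.0)
        assert r.delta == pytest.approx(0.0, abs=1e-9)

    def test_programmed_excitation(self):
        times = np.concatenate([regular(3.0, 0.0, 600.0),
                                regular(4.1, 600.0, 900.0)])
        train = SpikeTrain(times, duration=900.0)
        r = cck_response(train, 600.0)
        assert r.delta == pytest.approx(1.1, abs=0.02)

    def test_programmed_inhibition(self):
        times = np.concatenate([regular(6.0, 0.0, 600.0),
                                regular(2.7, 600.0, 900.0)])
        train = SpikeTrain(times, duration=900.0)
        assert cck_response(train, 600.0).delta == pytest.approx(-3.3, abs=0.02)

    def test_antisymmetric_under_segment_swap(self):
        rng = np.random.default_rng(5)
        a = np.sort(rng.uniform(0, 300, 900))
        b = np.sort(rng.uniform(300, 600, 2100))
        fwd = cck_response(SpikeTrain(np.concatenate([a, b]), duration=600.0),
                           300.0)
        swapped = np.sort(np.concatenate([b - 300.0, a + 300.0]))
        rev = cck_response(SpikeTrain(swapped, duration=600.0), 300.0)
        assert fwd.delta == pytest.approx(-rev.delta, abs=1e-9)

    def test_windows_disjoint(self):
        train = SpikeTrain(regular(5.0, 0.0, 1200.0), duration=1200.0)
        (a0, a1), (b0, b1) = cck_response(train, 600.0).windows
        assert a1 <= b0

    def test_insufficient_record(self):
        train = SpikeTrain(regular(5.0, 0.0, 400.0), duration=400.0)
        with pytest.raises(InsufficientDataError):
            cck_response(train, 200.0)


class TestClassifyCell:
    @pytest.mark.parametrize(
        "delta,phasic,expected",
        [
            (0.5, False, CellClass.OT),
            (-0.2, False, CellClass.UNDETERMINED),
            (0.3, False, CellClass.UNDETERMINED),
            (-0.5, False, CellClass.VP_CONT),
            (-2.0, True, CellClass.VP_PHASIC),
            (1.5, True, CellClass.VP_PHASIC),
        ],
    )
    def test_threshold_rules(self, delta, phasic, expected):
        assert classify_cell(delta, phasic) is expected


class TestPEResponse:
    def test_percent_of_basal(self):
        times = np.concatenate([regular(5.0, 0.0, 600.0),
                                regular(2.5, 600.0, 900.0)])
        r = pe_response(SpikeTrain(times, duration=900.0), 600.0)
        assert r.percent_of_basal == pytest.approx(50.0, abs=1.0)

    def test_no_change_is_100(self):
        train = SpikeTrain(regular(4.0, 0.0, 1200.0), duration=1200.0)
        assert pe_response(train, 600.0).percent_of_basal == pytest.approx(
            100.0, abs=0.5)

    def test_population_magnitude(self):
        times = np.concatenate([regular(10.0, 0.0, 600.0),
                                regular(4.4, 600.0, 900.0)])
        r = pe_response(SpikeTrain(times, duration=900.0), 600.0)
        assert r.percent_of_basal == pytest.approx(44.0, abs=0.5)

    def test_zero_basal_flagged(self):
        times = regular(5.0, 600.0, 900.0)
        r = pe_response(SpikeTrain(times, duration=900.0), 600.0)
        assert r.percent_of_basal is None


class TestPegResponse:
    def test_constant_zero(self):
        train = SpikeTrain(regular(5.0, 0.0, 4000.0), duration=4000.0)
        assert peg_response(train, 700.0).delta == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("post_rate,expected", [(5.4, 0.4), (6.2, 1.2)])
    def test_programmed_elevation(self, post_rate, expected):
        t0 = 700.0
        times = np.concatenate([
            regular(5.0, 0.0, t0 + 1800.0),
            regular(post_rate, t0 + 1800.0, t0 + 2700.0),
            regular(5.0, t0 + 2700.0, t0 + 3000.0),
        ])
        train = SpikeTrain(times, duration=t0 + 3000.0)
        r = peg_response(train, t0)
        assert r.delta == pytest.approx(expected, abs=0.03)

    def test_short_record_rejected(self):
        train = SpikeTrain(regular(5.0, 0.0, 1200.0), duration=1200.0)
        with pytest.raises(InsufficientDataError):
            peg_response(train, 700.0)


class TestOsmoticResponse:
    def test_infusion_schedule(self):
        assert infused_mmol_at(30.0) == pytest.approx(1.56)

    def test_constant_train(self):
        train = SpikeTrain(regular(5.0, 0.0, 4000.0), duration=4000.0)
        r = osmotic_response(train, 600.0)
        assert r.response_20_30 == pytest.approx(0.0, abs=0.01)
        assert r.slope_per_mmol == pytest.approx(0.0, abs=0.01)
        assert r.onset == 900.0

    def test_ramp_recovery(self):
        # programmed ramp of 1.92 spikes/s per mmol over a 30-min infusion
        base = RenewalModelParams(input_rate=4.0, seed=13)
        script = ExperimentScript([ExperimentEffect(
            EventLabel.PUMP_ON, time=900.0, kind="ramp",
            slope_per_mmol=1.92, duration=1800.0, lag_s=300.0)])
        train, _ = simulate_experiment(base, script, 3600.0)
        r = osmotic_response(train, 900.0)
        # ~2 SE of the fitted slope under Poisson bin noise
        assert r.slope_per_mmol == pytest.approx(1.92, abs=0.30)

    def test_missing_basal_rejected(self):
        train = SpikeTrain(regular(5.0, 0.0, 4000.0), duration=4000.0)
        with pytest.raises(InsufficientDataError):
            osmotic_response(train, 100.0)


class TestPSTH:
    def test_unmodulated_train_near_100(self):
        train = simulate_postspike_renewal(
            RenewalModelParams(input_rate=8.0, seed=21), 600.0)
        stim = np.arange(5.0, 590.0, 5.0)
        h = psth(train, stim)
        assert h.values.mean() == pytest.approx(100.0, abs=10.0)

    def test_imposed_dead_time(self):
        # remove all spikes within 200 ms after each stimulus
        train = simulate_postspike_renewal(
            RenewalModelParams(input_rate=8.0, seed=22), 600.0)
        stim = np.arange(5.0, 590.0, 5.0)
        keep = np.ones(train.n_spikes, dtype=bool)
        for s in stim:
            keep &= ~((train.times >= s) & (train.times < s + 0.2))
        gated = SpikeTrain(train.times[keep], duration=600.0)
        h = psth(gated, stim)
        assert np.all(h.values[:5] == 0.0)
        assert h.values[10:].mean() == pytest.approx(100.0, abs=12.0)

    def test_doubled_rate_window(self):
        # duplicate spikes in the 120 ms after each stimulus (offset by
        # half a sample so times stay strictly ascending)
        train = simulate_postspike_renewal(
            RenewalModelParams(input_rate=8.0, seed=23), 600.0)
        stim = np.arange(5.0, 590.0, 5.0)
        extra = []
        for s in stim:
            sel = train.times[(train.times >= s) & (train.times < s + 0.12)]
            extra.append(sel + 5e-5)
        boosted = np.sort(np.concatenate([train.times, *extra]))
        h = psth(SpikeTrain(boosted, duration=600.0), stim)
        assert h.values[:3].mean() == pytest.approx(200.0, rel=0.12)

    def test_too_few_stimuli(self):
        train = SpikeTrain(regular(5.0, 0.0, 100.0), duration=100.0)
        with pytest.raises(InsufficientDataError):
            psth(train, np.arange(5.0, 30.0, 5.0))
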
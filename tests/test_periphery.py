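import numpy as np
import pytest

from tactilenp import periphery as P
from tactilenp import stimulus as S
from tactilenp.metrics import vector_strength


class TestRectifiedFeatures:
    def test_constant_positive_trace(self):
        tr = S.StimulusTrace(np.full(2000, 3.0))
        f = P.rectified_features(tr, smoothing_sigma_ms=0.0)
        assert np.allclose(f[:, 0], 3.0)
        assert np.allclose(f[:, 1:], 0.0)

    def test_sinusoid_velocity_peak(self):
        freq, amp = 100.0, 5.0
        tr = S.make_sinusoid(freq, amp, 0.5)
        f = P.rectified_features(tr, 0.0)
        v_peak = f[:, 2].max()
        assert np.isclose(v_peak, 2 * np.pi * freq * amp, rtol=1e-3)

    def test_heavy_smoothing_attenuates_high_frequency(self):
        tr = S.make_sinusoid(400, 5.0, 0.25)
        raw = P.rectified_features(tr, 0.0)
        smooth = P.rectified_features(tr, 5.0)  # sigma >> 1/f
        assert smooth[:, 0].max() < 0.1 * raw[:, 0].max()

    def test_channels_nonnegative(self, noise_trace):
        f = P.rectified_features(noise_trace, 0.3)
        assert np.all(f >= 0)


class TestSimulateAfferent:
    def test_zero_stimulus_is_silent(self):
        m = P.default_ra_model()
        st = P.simulate_afferent(m, S.StimulusTrace(np.zeros(20000)))
        assert st.n_spikes == 0

    def test_lif_isi_matches_closed_form(self):
        # constant suprathreshold drive D: ISI = t_ref + tau*ln(D/(D-theta))
        for D in (1.5, 2.0, 5.0):
            m = P.AfferentModel(
                "RA", [1, 0, 0, 0, 0, 0], tau_m_ms=5.0, threshold=1.0,
                reset=0.0, t_refractory_ms=1.0,
            )
            tr = S.StimulusTrace(np.full(20000, D))
            st = P.simulate_afferent(m, tr)
            isi = np.diff(st.spike_times)[5:]
            pred = 1e-3 + 5e-3 * np.log(D / (D - 1.0))
            assert np.max(np.abs(isi - pred)) / pred < 1e-3

    def test_deterministic(self, noise_trace):
        m = P.default_pc_model()
        a = P.simulate_afferent(m, noise_trace)
        b = P.simulate_afferent(m, noise_trace)
        assert np.array_equal(a.spike_times, b.spike_times)

    def test_refractory_respected(self, noise_trace):
        m = P.default_ra_model(t_refractory_ms=2.0)
        st = P.simulate_afferent(m, S.StimulusTrace(noise_trace.samples * 10))
        if st.n_spikes > 1:
            assert np.min(np.diff(st.spike_times)) >= 2e-3 - 1e-12

    def test_large_dt_rejected(self, noise_trace):
        with pytest.raises(ValueError):
            P.simulate_afferent(P.default_ra_model(), noise_trace, dt_ms=0.5)

    def test_entrainment_plateau_at_one_spike_per_cycle(self):
        # sweeping amplitude at fixed frequency shows a plateau where the
        # rate sticks at the stimulus frequency
        m = P.default_pc_model()
        freq, dur = 200.0, 0.5
        rates = []
        for amp in np.geomspace(0.5, 40, 25):
            rates.append(P.simulate_afferent(m, S.make_sinusoid(freq, amp, dur)).rate())
        rates = np.array(rates)
        on_plateau = np.abs(rates - freq) <= 3.0 / dur
        assert on_plateau.sum() >= 3

    def test_rate_intensity_monotone(self):
        m = P.default_ra_model()
        rates = [
            P.simulate_afferent(m, S.make_sinusoid(50, amp, 0.5)).rate()
            for amp in np.geomspace(1, 100, 12)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(rates, rates[1:]))


class TestTuningThresholds:
    def test_one_spike_per_cycle_and_phase_locked(self):
        m = P.default_pc_model()
        freq = 250.0
        amp = P.tuning_threshold_amplitude(m, freq)
        st = P.simulate_afferent(m, S.make_sinusoid(freq, amp, 0.5))
        assert abs(st.rate() - freq) <= 3.0 / 0.5
        assert vector_strength(st.spike_times, freq) > 0.9

    def test_class_sensitivity_ordering(self):
        ra, pc = P.default_ra_model(), P.default_pc_model()
        # RA more sensitive in the flutter range, PC above ~200 Hz
        assert P.absolute_threshold_amplitude(ra, 50) < P.absolute_threshold_amplitude(pc, 50)
        assert P.absolute_threshold_amplitude(ra, 250) > P.absolute_threshold_amplitude(pc, 250)

    def test_pc_sensitivity_rolls_off_at_high_frequency(self):
        pc = P.default_pc_model()
        assert P.absolute_threshold_amplitude(pc, 700) > P.absolute_threshold_amplitude(pc, 350)


class TestPopulationRate:
    def test_single_model_equals_binned_rate(self, noise_trace):
        m = P.default_ra_model()
        pc = P.default_pc_model()
        pr = P.population_rate([m, pc], noise_trace)
        st = P.simulate_afferent(m, noise_trace)
        assert np.allclose(pr.ra_rate, st.binned(1.0) / 1e-3)

    def test_duplicated_models_average_to_same(self, noise_trace):
        m, pc = P.default_ra_model(), P.default_pc_model()
        one = P.population_rate([m, pc], noise_trace)
        three = P.population_rate([m, m, m, pc], noise_trace)
        assert np.allclose(one.ra_rate, three.ra_rate)

    def test_disjoint_spikes_average(self):
        # two RA models whose spikes fall in different bins: bin value is
        # the average of the two binned rates
        tr = S.make_sinusoid(50, 30, 0.2)
        m1 = P.default_ra_model()
        m2 = P.default_ra_model(delay_ms=6.0)
        pr = P.population_rate([m1, m2, P.default_pc_model()], tr)
        r1 = P.simulate_afferent(m1, tr).binned() / 1e-3
        r2 = P.simulate_afferent(m2, tr).binned() / 1e-3
        assert np.allclose(pr.ra_rate, (r1 + r2) / 2)

    def test_missing_class_rejected(self, noise_trace):
        with pytest.raises(ValueError):
            P.population_rate([P.default_ra_model()], noise_trace)


def _vr_numeric(a, b, tau_s, dt=1e-5, horizon=0.5):
    """Numerical-integration oracle for the van Rossum distance."""
    t = np.arange(0, horizon, dt)

    def filtered(train):
        f = np.zeros_like(t)
        for s in train:
            m = t >= s
            f[m] += np.exp(-(t[m] - s) / tau_s) / np.sqrt(tau_s)
        return f

    diff = filtered(a) - filtered(b)
    return np.sqrt(np.sum(diff**2) * dt)


class TestVanRossum:
    def test_identical_trains_zero(self):
        a = P.SpikeTrain(np.array([0.01, 0.05, 0.2]), 1.0)
        assert P.van_rossum_distance(a, a, 5.0) == 0.0

    def test_single_spike_vs_empty_is_half(self):
        a = P.SpikeTrain(np.array([0.05]), 1.0)
        b = P.SpikeTrain(np.array([]), 1.0)
        d = P.van_rossum_distance(a, b, 8.0)
        assert np.isclose(d**2, 0.5, rtol=1e-12)
        assert np.isclose(d, _vr_numeric([0.05], [], 8e-3), rtol=1e-3)

    def test_matches_numeric_integration_oracle(self, rng):
        for _ in range(5):
            a = np.sort(rng.uniform(0, 0.2, rng.integers(1, 8)))
            b = np.sort(rng.uniform(0, 0.2, rng.integers(1, 8)))
            a, b = np.unique(a), np.unique(b)
            d = P.van_rossum_distance(P.SpikeTrain(a, 0.5), P.SpikeTrain(b, 0.5), 5.0)
            assert np.isclose(d, _vr_numeric(a, b, 5e-3), rtol=1e-3)

    def test_symmetry_and_triangle_inequality(self, rng):
        trains = [
            P.SpikeTrain(np.unique(np.sort(rng.uniform(0, 0.5, 6))), 1.0)
            for _ in range(6)
        ]
        for x in trains:
            for y in trains:
                dxy = P.van_rossum_distance(x, y, 4.0)
                assert np.isclose(dxy, P.van_rossum_distance(y, x, 4.0))
                for z in trains:
                    assert dxy <= (
                        P.van_rossum_distance(x, z, 4.0)
                        + P.van_rossum_distance(z, y, 4.0)
                        + 1e-12
                    )


class TestFitAfferent:
    def _stimuli(self):
        stims = [
            S.make_bandpass_noise(50, 800, 15, 0.5, seed=31),
            S.make_bandpass_noise(50, 800, 30, 0.5, seed=32),
            S.make_sinusoid(100, 20, 0.5),
            S.make_diharmonic(80, 15, 240, 10, 0.5),
        ]
        labels = ["noise", "noise", "sine", "diharmonic"]
        return stims, labels

    def test_truth_init_is_fixed_point(self):
        truth = P.default_ra_model()
        stims, labels = self._stimuli()
        targets = [P.simulate_afferent(truth, s) for s in stims]
        fit = P.fit_afferent_model(targets, stims, truth, labels)
        assert fit.final_cost == 0.0
        assert np.allclose(fit.model.feature_weights, truth.feature_weights)

    def test_weight_recovery_from_perturbed_init(self):
        truth = P.default_ra_model()
        stims, labels = self._stimuli()
        targets = [P.simulate_afferent(truth, s) for s in stims]
        rng = np.random.default_rng(3)
        w0 = truth.feature_weights.copy()
        w0[w0 != 0] *= rng.uniform(0.8, 1.2, size=(w0 != 0).sum())
        init = P.default_ra_model(feature_weights=w0)
        fit = P.fit_afferent_model(targets, stims, init, labels)
        nz = truth.feature_weights != 0
        rel = np.abs(fit.model.feature_weights[nz] - truth.feature_weights[nz]) / truth.feature_weights[nz]
        assert fit.final_cost <= fit.initial_cost
        assert np.all(rel < 0.10)

    def test_empty_targets_keep_zero_weights(self):
        stims, labels = self._stimuli()
        empty = [P.SpikeTrain(np.array([]), s.duration) for s in stims]
        init = P.default_ra_model(feature_weights=np.zeros(6))
        fit = P.fit_afferent_model(empty, stims, init, labels)
        assert np.all(fit.model.feature_weights == 0)
        assert fit.final_cost == 0.0
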
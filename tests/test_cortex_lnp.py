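import numpy as np
import pytest

from tactilenp import metrics
from tactilenp.cortex_lnp import (
    CorticalFilterPair,
    CorticalSpikeData,
    LaggedDesign,
    Nonlinearity,
    RidgeConfig,
    classify_input,
    estimate_filters,
    fit_nonlinearity,
    lnp_drive,
    lnp_predict,
    pooled_drive,
    refit_single_class,
    sample_spikes,
)
from tactilenp.periphery import PopulationResponse, zscore_populations


def white_pops(rng, n_stim=6, n_bins=2000):
    """Z-scored white-noise population responses (identity covariance)."""
    pops = []
    for _ in range(n_stim):
        pops.append(
            PopulationResponse(
                rng.normal(0, 1, n_bins),
                rng.normal(0, 1, n_bins),
                zscored=True,
                z_params={},
            )
        )
    return pops


def gabor_filters(window=100):
    t = np.arange(window)
    k_ra = 0.3 * np.exp(-((t - 12) ** 2) / 60.0)
    k_pc = 0.2 * np.exp(-((t - 8) ** 2) / 18.0) * np.cos(2 * np.pi * (t - 8) / 25)
    return CorticalFilterPair(k_ra, k_pc)


class TestForwardModel:
    def test_zero_filters_give_baseline(self, rng):
        pops = white_pops(rng, 1)
        nl = Nonlinearity(0.03, 0.1)
        zero = CorticalFilterPair(np.zeros(100), np.zeros(100))
        p = lnp_predict(zero, nl, pops[0])
        assert np.allclose(p, 0.03)

    def test_negative_drive_clamps_to_baseline(self):
        # strongly negative RA filter on a positive input: drive < 0
        pop = PopulationResponse(
            np.ones(300), np.zeros(300), zscored=True, z_params={}
        )
        filters = CorticalFilterPair(-np.ones(100), np.zeros(100))
        nl = Nonlinearity(0.02, 0.5)
        p = lnp_predict(filters, nl, pop)
        assert np.allclose(p, 0.02)

    def test_hand_computed_toy_drive(self):
        # k_ra = delta at lag 1: drive at t is s_RA[t-1]
        pop = PopulationResponse(
            np.arange(300, dtype=float), np.zeros(300), zscored=True, z_params={}
        )
        k_ra = np.zeros(100)
        k_ra[0] = 1.0
        filters = CorticalFilterPair(k_ra, np.zeros(100))
        x = lnp_drive(filters, pop)
        assert np.allclose(x[100:], np.arange(99, 299))
        nl = Nonlinearity(0.01, 0.002)
        p = lnp_predict(filters, nl, pop)
        assert np.isclose(p[150], min(0.01 + 0.002 * 149, 1.0))

    def test_output_bounded(self, rng):
        pops = white_pops(rng, 1)
        filters = gabor_filters()
        nl = Nonlinearity(0.05, 5.0)  # large gain forces clipping
        p = lnp_predict(filters, nl, pops[0])
        assert np.all(p >= 0.0) and np.all(p <= 1.0)
        assert p.max() == 1.0

    def test_unscored_population_rejected(self):
        pop = PopulationResponse(np.ones(200), np.ones(200))
        with pytest.raises(ValueError):
            lnp_predict(gabor_filters(), Nonlinearity(0.01, 0.1), pop)


class TestSampleSpikes:
    def test_deterministic_extremes(self, rng):
        z = sample_spikes(np.zeros(500), 3, rng)
        assert all(t.sum() == 0 for t in z.trials)
        o = sample_spikes(np.ones(500), 2, rng)
        assert all(t.sum() == 500 for t in o.trials)

    def test_empirical_rate_within_binomial_ci(self):
        p = 0.3
        data = sample_spikes(np.full(100_000, p), 1, seed=5)
        emp = data.trials[0].mean()
        se = np.sqrt(p * (1 - p) / 100_000)
        assert abs(emp - p) < 3 * se

    def test_reproducible_under_seed(self):
        a = sample_spikes(np.full(1000, 0.2), 2, seed=9)
        b = sample_spikes(np.full(1000, 0.2), 2, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a.trials, b.trials))


class TestEstimateFilters:
    def test_ols_oracle_at_zero_ridge(self, rng):
        pops = white_pops(rng, 3, 1500)
        design = LaggedDesign(pops)
        spikes = CorticalSpikeData(
            [(rng.random(1500) < 0.1).astype(np.uint8) for _ in range(3)],
            [0, 1, 2],
        )
        est = estimate_filters(pops, spikes, RidgeConfig(a=0.0), design=design)
        # independent oracle: explicit least squares on the stacked design
        S = design._rows32.astype(np.float64)[design.valid]
        y = design.summed_counts(spikes)[design.valid]
        k_ols, *_ = np.linalg.lstsq(S, y, rcond=None)
        assert np.max(np.abs(est.stacked - k_ols)) < 1e-8

    def test_all_zero_spikes_give_zero_filters(self, rng):
        pops = white_pops(rng, 2, 1000)
        spikes = CorticalSpikeData(
            [np.zeros(1000, dtype=np.uint8), np.zeros(1000, dtype=np.uint8)], [0, 1]
        )
        est = estimate_filters(pops, spikes, RidgeConfig(a=10.0))
        assert np.all(est.stacked == 0)

    def test_recovery_from_white_inputs_noise_free(self, rng):
        # regressing the noise-free spiking probabilities (the infinite-
        # repeat limit) on identity-covariance inputs recovers the true
        # filters up to the rectifier's effective gain
        pops = white_pops(rng, 10, 5000)
        truth = gabor_filters()
        nl = Nonlinearity(0.02, 0.08)
        design = LaggedDesign(pops)
        p = np.concatenate([lnp_predict(truth, nl, pop) for pop in pops])
        counts = np.ones(design.n_stimuli, dtype=np.int64)
        k = design.solve(10.0, counts, design.st_p(p, counts))
        r = np.corrcoef(k, truth.stacked)[0, 1]
        assert r > 0.99

    def test_recovery_from_sampled_spikes(self, rng):
        # with Bernoulli sampling noise the recovery is slightly noisier
        pops = white_pops(rng, 10, 5000)
        truth = gabor_filters()
        nl = Nonlinearity(0.05, 0.15)
        trials, sids = [], []
        for s, pop in enumerate(pops):
            p = lnp_predict(truth, nl, pop)
            for _ in range(4):
                trials.append((rng.random(p.size) < p).astype(np.uint8))
                sids.append(s)
        spikes = CorticalSpikeData(trials, sids)
        est = estimate_filters(pops, spikes, RidgeConfig(a=10.0))
        r = np.corrcoef(est.stacked, truth.stacked)[0, 1]
        assert r > 0.97

    def test_shrinkage_monotone_to_zero(self, rng):
        pops = white_pops(rng, 2, 1200)
        spikes = CorticalSpikeData(
            [(rng.random(1200) < 0.1).astype(np.uint8) for _ in range(2)], [0, 1]
        )
        design = LaggedDesign(pops)
        norms = [
            np.linalg.norm(
                estimate_filters(pops, spikes, RidgeConfig(a), design=design).stacked
            )
            for a in (0.0, 1e2, 1e4, 1e6, 1e8)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-3 * norms[0]

    def test_empty_spike_data_rejected(self, rng):
        pops = white_pops(rng, 1, 500)
        with pytest.raises(ValueError):
            estimate_filters(pops, CorticalSpikeData([], []), RidgeConfig(0.0))


class TestFitNonlinearity:
    def test_recovery_within_ten_percent(self, rng):
        b1, b2 = 0.01, 0.05
        nl = Nonlinearity(b1, b2)
        x = rng.normal(0, 3, 300_000)
        y = (rng.random(x.size) < nl(x)).astype(np.uint8)
        fit = fit_nonlinearity(x, y)
        assert abs(fit.b1 - b1) / b1 < 0.10
        assert abs(fit.b2 - b2) / b2 < 0.10

    def test_no_spikes_gives_zero_baseline(self, rng):
        x = rng.normal(0, 1, 5000)
        fit = fit_nonlinearity(x, np.zeros(5000, dtype=np.uint8))
        assert fit.b1 == 0.0

    def test_all_negative_drive_gives_mean_probability(self, rng):
        x = -np.abs(rng.normal(2, 0.5, 20_000))
        y = (rng.random(x.size) < 0.07).astype(np.uint8)
        fit = fit_nonlinearity(x, y)
        assert np.isclose(fit.b1, y.mean(), rtol=0.05)

    def test_constant_drive_degenerate(self):
        x = np.full(1000, 1.3)
        y = np.zeros(1000, dtype=np.uint8)
        y[:100] = 1
        fit = fit_nonlinearity(x, y)
        assert fit.b2 == 0.0
        assert np.isclose(fit.b1, 0.1)


class TestRoundTrip:
    def test_heldout_probability_reproduced(self, rng):
        """Estimate from sampled spikes, then predict held-out data: the
        predicted probability matches the generating probability with
        R^2 > 0.9 at 5-ms resolution."""
        pops = white_pops(rng, 12, 4000)
        truth = gabor_filters()
        nl = Nonlinearity(0.02, 0.06)
        fit_pops, test_pop = pops[:-1], pops[-1]
        trials, sids = [], []
        for s, pop in enumerate(fit_pops):
            p = lnp_predict(truth, nl, pop)
            for _ in range(5):
                trials.append((rng.random(p.size) < p).astype(np.uint8))
                sids.append(s)
        spikes = CorticalSpikeData(trials, sids)
        filters = estimate_filters(fit_pops, spikes, RidgeConfig(a=10.0))
        drive, spk = pooled_drive(filters, fit_pops, spikes)
        nl_est = fit_nonlinearity(drive, spk)
        p_pred = lnp_predict(filters, nl_est, test_pop)[100:]
        p_true = lnp_predict(truth, nl, test_pop)[100:]
        r2 = metrics.explained_variance_at_resolution(p_pred, p_true, 5)
        assert r2 > 0.9


class TestRefitSingleClass:
    def _ra_only_dataset(self, rng):
        pops = white_pops(rng, 8, 4000)
        k_ra = gabor_filters().k_ra
        truth = CorticalFilterPair(k_ra, np.zeros(100))
        nl = Nonlinearity(0.02, 0.1)
        trials, sids = [], []
        for s, pop in enumerate(pops):
            p = lnp_predict(truth, nl, pop)
            for _ in range(3):
                trials.append((rng.random(p.size) < p).astype(np.uint8))
                sids.append(s)
        return pops, CorticalSpikeData(trials, sids), truth, nl

    def test_kept_class_performs_like_full_model(self, rng):
        pops, spikes, truth, nl = self._ra_only_dataset(rng)
        cfg = RidgeConfig(a=10.0)
        design = LaggedDesign(pops)
        full = estimate_filters(pops, spikes, cfg, design=design)
        ra_only, _ = refit_single_class(pops, spikes, cfg, keep="RA", design=design)
        pc_only, _ = refit_single_class(pops, spikes, cfg, keep="PC", design=design)
        assert np.all(ra_only.k_pc == 0)
        assert np.all(pc_only.k_ra == 0)
        y = np.concatenate([t[100:] for t in spikes.trials]).astype(float)

        def score(filters):
            xs = []
            for sid in spikes.stimulus_id:
                xs.append(lnp_drive(filters, pops[sid])[100:])
            x = np.concatenate(xs)
            return np.corrcoef(x, y)[0, 1] ** 2

        s_full, s_ra, s_pc = score(full), score(ra_only), score(pc_only)
        assert s_ra > 0.9 * s_full  # kept class carries the model
        assert s_pc < 0.1 * s_full  # no PC dependence by construction


class TestClassifyInput:
    def test_strong_dual_input_neuron_labelled_both(self, rng):
        pops = white_pops(rng, 10, 4000)
        truth = gabor_filters()
        nl = Nonlinearity(0.02, 0.08)
        trials, sids = [], []
        for s, pop in enumerate(pops):
            p = lnp_predict(truth, nl, pop)
            for _ in range(4):
                trials.append((rng.random(p.size) < p).astype(np.uint8))
                sids.append(s)
        spikes = CorticalSpikeData(trials, sids)
        res = classify_input(pops, spikes, RidgeConfig(a=10.0), n_null=150, seed=3)
        assert res.label == "both"
        assert res.p_ra < 0.02 and res.p_pc < 0.02

    def test_stimulus_independent_spikes_labelled_none(self, rng):
        pops = white_pops(rng, 6, 3000)
        trials, sids = [], []
        for s in range(6):
            for _ in range(3):
                trials.append((rng.random(3000) < 0.05).astype(np.uint8))
                sids.append(s)
        spikes = CorticalSpikeData(trials, sids)
        res = classify_input(pops, spikes, RidgeConfig(a=10.0), n_null=150, seed=4)
        assert res.label == "none"

    def test_too_short_data_rejected(self, rng):
        pops = white_pops(rng, 1, 150)
        spikes = CorticalSpikeData([np.zeros(150, dtype=np.uint8)], [0])
        with pytest.raises(ValueError):
            classify_input(pops, spikes, RidgeConfig(0.0), n_null=100, seed=0)

    def test_small_null_count_rejected(self, rng):
        pops = white_pops(rng, 1, 1000)
        spikes = CorticalSpikeData([np.zeros(1000, dtype=np.uint8)], [0])
        with pytest.raises(ValueError):
            classify_input(pops, spikes, RidgeConfig(0.0), n_null=10, seed=0)


class TestFilterIO:
    def test_text_round_trip(self, tmp_path):
        f = gabor_filters()
        path = tmp_path / "filters.tsv"
        f.save(path)
        back = CorticalFilterPair.load(path)
        assert np.allclose(back.k_ra, f.k_ra)
        assert np.allclose(back.k_pc, f.k_pc)

    def test_lag_convention_documented_by_design(self, rng):
        # column j of the design equals the rate at t-(j+1) ms
        pop = PopulationResponse(
            np.arange(400, dtype=float), np.zeros(400), zscored=True, z_params={}
        )
        design = LaggedDesign([pop])
        row = design._rows32[150]
        assert np.allclose(row[:100], np.arange(149, 49, -1))
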
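"""Response statistics: STA, multitaper spectra, SFC, attentional indices,
pairwise synchrony and group tests — with brute-force oracles."""

import numpy as np
import pytest
from scipy.signal.windows import dpss

from betacol.analysis import (
    BANDS,
    LFPTrace,
    attentional_indices,
    band_average,
    burst_events,
    burst_recurrence_frequency,
    firing_rate,
    group_stats,
    multitaper_psd,
    pairwise_synchrony,
    peak_frequency,
    population_spike_spectrum,
    spike_field_coherence,
    spike_triggered_average,
    synchrony_matrix,
)


@pytest.fixture(scope="module")
def locked_fixture():
    """2 s LFP with a 20 Hz component in noise; spikes locked to its peaks."""
    rng = np.random.default_rng(42)
    dt = 1.0
    t = np.arange(2000) * dt
    lfp = LFPTrace(np.sin(2 * np.pi * 20 * t / 1000.0) + 0.3 * rng.standard_normal(t.size), dt)
    spikes = np.arange(412.5, 1600.0, 50.0)  # aligned with the 20 Hz peaks
    return lfp, spikes


class TestFiringRate:
    def test_zero(self):
        assert firing_rate([], 20, 1000.0) == 0.0

    def test_population_rate(self):
        assert firing_rate(np.zeros(400), 20, 1000.0) == 20.0

    def test_single_cell_periodic(self):
        assert firing_rate(np.arange(0, 1000, 50.0), 1, 1000.0) == 20.0

    def test_empty_population_raises(self):
        with pytest.raises(ValueError):
            firing_rate([1.0], 0, 1000.0)


class TestSTA:
    def test_periodic_lfp_locked_spikes_peak_at_zero_lag(self, locked_fixture):
        lfp, spikes = locked_fixture
        res = spike_triggered_average(lfp, spikes)
        assert res.n_spikes == len(spikes)
        # the STA reproduces the 20 Hz waveform: peaks at lag 0 mod period
        peak_lag = res.lags[np.argmax(res.sta)]
        assert min(peak_lag % 50.0, 50.0 - peak_lag % 50.0) <= 1.0
        expected = np.sin(2 * np.pi * 20 * (res.lags + 412.5) / 1000.0)
        corr = np.corrcoef(res.sta, expected)[0, 1]
        assert corr > 0.95

    def test_single_spike_returns_segment(self):
        rng = np.random.default_rng(0)
        lfp = LFPTrace(rng.standard_normal(1000), 1.0)
        res = spike_triggered_average(lfp, np.array([500.0]))
        assert res.n_spikes == 1
        assert np.allclose(res.sta, lfp.values[200:800])

    def test_edge_spikes_excluded(self):
        lfp = LFPTrace(np.zeros(1000), 1.0)
        res = spike_triggered_average(lfp, np.array([10.0, 500.0, 995.0]))
        assert res.n_spikes == 1

    def test_zero_spikes_explicit_empty(self):
        lfp = LFPTrace(np.zeros(1000), 1.0)
        res = spike_triggered_average(lfp, np.array([]))
        assert res.n_spikes == 0 and np.all(res.sta == 0.0)

    def test_white_noise_sta_shrinks_as_sqrt_n(self):
        rng = np.random.default_rng(3)
        lfp = LFPTrace(rng.standard_normal(200_000), 1.0)
        few = rng.uniform(400, 199_600, 40)
        many = rng.uniform(400, 199_600, 4000)
        amp_few = np.std(spike_triggered_average(lfp, few).sta)
        amp_many = np.std(spike_triggered_average(lfp, many).sta)
        ratio = amp_few / amp_many
        assert 5.0 < ratio < 20.0  # expect ~ sqrt(100) = 10


class TestMultitaper:
    def test_sinusoid_peak_at_nearest_bin(self):
        t = np.arange(600) / 1000.0
        f, p = multitaper_psd(np.sin(2 * np.pi * 20 * t), fs=1000.0)
        assert f[np.argmax(p)] == pytest.approx(20.0, abs=f[1] - f[0])

    def test_quadratic_scaling(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(600)
        _, p1 = multitaper_psd(x, 1000.0)
        _, p3 = multitaper_psd(3.0 * x, 1000.0)
        assert np.allclose(p3, 9.0 * p1)

    def test_white_noise_flat(self):
        rng = np.random.default_rng(2)
        acc = None
        for _ in range(30):
            f, p = multitaper_psd(rng.standard_normal(600), 1000.0)
            acc = p if acc is None else acc + p
        band = acc[(f >= 8) & (f <= 70)]
        assert band.max() / band.min() < 3.0

    def test_parseval_consistency(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(4000)
        f, p = multitaper_psd(x, 1000.0)
        df = f[1] - f[0]
        assert np.sum(p) * df == pytest.approx(np.mean(x**2), rel=0.1)


class TestSFC:
    def test_identical_segments_give_unity(self):
        dt = 1.0
        seg = np.sin(2 * np.pi * np.arange(2000) * 25 / 1000.0)
        lfp = LFPTrace(seg, dt)
        spikes = np.array([400.0, 800.0, 1200.0, 1600.0])  # same phase -> same segments
        res = spike_field_coherence(lfp, spikes)
        vals = res.sfc.compressed()
        assert np.allclose(vals, 1.0, atol=1e-8)

    def test_scale_invariance(self, locked_fixture):
        lfp, spikes = locked_fixture
        a = spike_field_coherence(lfp, spikes)
        b = spike_field_coherence(LFPTrace(10.0 * lfp.values, lfp.dt), spikes)
        assert np.ma.allclose(a.sfc, b.sfc, atol=1e-10)

    def test_locked_frequency_dominates(self, locked_fixture):
        lfp, spikes = locked_fixture
        res = spike_field_coherence(lfp, spikes)
        f = res.freqs
        sfc20 = res.sfc[np.argmin(np.abs(f - 20.0))]
        sfc45 = res.sfc[np.argmin(np.abs(f - 45.0))]
        assert sfc20 > 5 * sfc45

    def test_needs_two_spikes(self):
        lfp = LFPTrace(np.zeros(1000), 1.0)
        with pytest.raises(ValueError, match="2"):
            spike_field_coherence(lfp, np.array([500.0]))

    def test_band_summaries_present(self, locked_fixture):
        lfp, spikes = locked_fixture
        res = spike_field_coherence(lfp, spikes)
        assert set(res.bands) == set(BANDS)
        assert res.bands["beta"] > res.bands["gamma"]


class TestBruteForceOracle:
    def test_sta_and_sfc_match_naive_loops(self):
        """Production STA/SFC agree with a naive explicit-DFT implementation
        to 1e-10 relative tolerance on a 50-spike fixture."""
        rng = np.random.default_rng(7)
        dt = 1.0
        x = rng.standard_normal(3000)
        lfp = LFPTrace(x, dt)
        spikes = np.sort(rng.uniform(400, 2600, 50))

        half = 300
        segs = []
        for s in spikes:
            i = int(round(s / dt))
            segs.append(x[i - half : i + half])
        sta_naive = sum(segs) / len(segs)

        res_sta = spike_triggered_average(lfp, spikes)
        assert np.max(np.abs(res_sta.sta - sta_naive)) < 1e-10 * max(1.0, np.abs(sta_naive).max())

        # naive multitaper PSD via explicit DFT matrix
        n = 2 * half
        tapers = dpss(n, 3.0, 5)
        k = np.arange(n // 2 + 1)
        dft = np.exp(-2j * np.pi * np.outer(k, np.arange(n)) / n)

        def naive_psd(sig):
            acc = np.zeros(n // 2 + 1)
            for w in tapers:
                spec = np.abs(dft @ (w * sig)) ** 2
                acc += spec
            p = acc / len(tapers) / 1000.0
            p[1:-1] *= 2.0
            return p

        num = naive_psd(sta_naive)
        den = np.zeros_like(num)
        for seg in segs:
            den += naive_psd(seg)
        den /= len(segs)
        sfc_naive = num / den

        res_sfc = spike_field_coherence(lfp, spikes)
        assert np.max(np.abs(res_sfc.sfc - sfc_naive)) < 1e-10 * sfc_naive.max()


class TestAttentionalIndices:
    def test_normalized_difference_values(self):
        ai = attentional_indices(
            {"sfc_gamma": [3.0], "sfc_low": [1.0], "rate": [0.0]},
            {"sfc_gamma": [1.0], "sfc_low": [1.0], "rate": [2.0]},
        )
        assert ai.ai_gamma[0] == pytest.approx(0.5)
        assert ai.ai_low[0] == pytest.approx(0.0)
        assert ai.ai_rate[0] == pytest.approx(-1.0)

    def test_antisymmetry_and_bounds(self):
        rng = np.random.default_rng(5)
        a = {k: rng.uniform(0.01, 2.0, 50) for k in ("sfc_gamma", "sfc_low", "rate")}
        b = {k: rng.uniform(0.01, 2.0, 50) for k in ("sfc_gamma", "sfc_low", "rate")}
        fwd = attentional_indices(a, b)
        rev = attentional_indices(b, a)
        for x, y in ((fwd.ai_gamma, rev.ai_gamma), (fwd.ai_low, rev.ai_low), (fwd.ai_rate, rev.ai_rate)):
            assert np.allclose(x, -y)
            assert np.all(np.abs(x) <= 1.0)

    def test_zero_denominator_masked(self):
        ai = attentional_indices(
            {"sfc_gamma": [0.0], "sfc_low": [1.0], "rate": [1.0]},
            {"sfc_gamma": [0.0], "sfc_low": [1.0], "rate": [1.0]},
        )
        assert np.isnan(ai.ai_gamma[0])


class TestPairwiseSynchrony:
    def test_identical_trains(self):
        t = np.array([10.0, 55.0, 300.0])
        assert pairwise_synchrony(t, t, 1000.0) == pytest.approx(1.0)

    def test_disjoint_trains(self):
        assert pairwise_synchrony([10.0], [500.0], 1000.0) == 0.0

    def test_partial_overlap_formula(self):
        """X with 4 spikes, Y = X plus 12 extra non-coincident spikes:
        kappa = 4 / sqrt(4 * 16) = 0.5."""
        x = np.array([10.0, 20.0, 30.0, 40.0])
        y = np.concatenate([x, 100.0 + 10.0 * np.arange(12)])
        assert pairwise_synchrony(x, y, 1000.0) == pytest.approx(0.5)

    def test_silent_train_nan(self):
        assert np.isnan(pairwise_synchrony([], [10.0], 1000.0))

    def test_matrix_symmetry_bounds_and_exclusions(self):
        rng = np.random.default_rng(6)
        trains = {i: np.sort(rng.uniform(0, 1000, rng.integers(5, 40))) for i in range(8)}
        trains[8] = np.array([])
        m = synchrony_matrix(trains, 1000.0)
        k = m.kappa
        assert np.allclose(k, k.T, equal_nan=True)
        vals = k[~np.isnan(k)]
        assert np.all((vals >= 0.0) & (vals <= 1.0))
        assert m.n_excluded_pairs == 8
        for i in range(8):
            assert k[i, i] == 1.0


class TestGroupStats:
    def test_zero_variance_flagged(self):
        st = group_stats([0.0, 0.0, 0.0, 0.0])
        assert st.mean == 0.0 and st.flag == "zero-variance"

    def test_symmetric_sample(self):
        st = group_stats([1, 1, 1, 1, -1, -1, -1, -1])
        assert st.mean == 0.0
        assert st.p == pytest.approx(1.0)

    def test_small_strong_sample_significant(self):
        # closed form: t = 0.5 / (0.1/sqrt(3)) = 8.66, two-sided p = 0.0131
        st = group_stats([0.4, 0.5, 0.6])
        assert st.t == pytest.approx(np.sqrt(3) * 5.0, rel=1e-12)
        assert st.p == pytest.approx(0.01312, abs=2e-4)

    def test_two_sample(self):
        st = group_stats([5.0, 6.0, 7.0], other=[1.0, 2.0, 3.0])
        assert st.mean == pytest.approx(4.0)
        assert st.p < 0.05


class TestSpikeTrainSpectra:
    def test_periodic_train_peak(self):
        spikes = np.arange(0.0, 5000.0, 50.0)
        f, p = population_spike_spectrum(spikes, 5000.0)
        assert peak_frequency(f, p, 5, 70) == pytest.approx(20.0, abs=0.5)

    def test_burst_recurrence_frequency(self):
        # 10 cells bursting every 100 ms
        times, cells = [], []
        for t0 in np.arange(50.0, 950.0, 100.0):
            for c in range(10):
                times.append(t0 + 0.1 * c)
                cells.append(c)
        import pandas as pd

        df = pd.DataFrame({"time": times, "cell": cells})
        ev = burst_events(df, n_cells=10, duration_ms=1000.0)
        assert len(ev) == 9
        assert burst_recurrence_frequency(ev) == pytest.approx(10.0, rel=0.01)

    def test_band_average_requires_bins(self):
        with pytest.raises(ValueError):
            band_average(np.array([1.0, 2.0]), np.array([1.0, 1.0]), 50, 60)


def test_band_average_harmonic_exclusion():
    freqs = np.arange(0.0, 80.0, 1.0)
    vals = np.where((freqs >= 38) & (freqs <= 42), 10.0, 1.0)
    raw = band_average(freqs, vals, 25, 70)
    cut = band_average(freqs, vals, 25, 70, exclude=(36.0, 44.0))
    assert raw > cut == pytest.approx(1.0)
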
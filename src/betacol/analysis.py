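"""Response statistics: rates, simulated LFP, spike-triggered averages,
multitaper spectra, spike-field coherence, attentional indices and pairwise
synchrony.

The simulated LFP of a column is the summed synaptic current onto its L2/3
RS cells (all chemical synapses plus external EPSC-train currents).  The
spike-triggered average (STA) collects 600 ms LFP segments centred on L2/3
RS spikes (300 ms before, 300 ms after; spikes closer than 300 ms to an
edge are excluded), pooled over realizations.  Spike-field coherence is the
power spectrum of the STA divided by the mean spike-triggered power
spectrum, a synchrony measure invariant to uniform LFP rescaling and to the
firing rate.  All spectra are multitaper estimates (DPSS tapers,
time-bandwidth product 3, 5 tapers by default).

Attentional indices compare the attended and unattended columns through the
normalized difference (att - unatt)/(att + unatt) of band-averaged SFC
(gamma 25-70 Hz, low 8-25 Hz) and of the L2/3 RS firing rate; indices are
positive when the attended column's response is stronger, and are tested
against zero across realizations with a one-sample t-test.

Pairwise spike-train synchrony uses binary 1 ms bins:
kappa(i, j) = sum_l X_i(l) X_j(l) / sqrt(sum_l X_i(l) * sum_l X_j(l)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.signal.windows import dpss

__all__ = [
    "BANDS",
    "LFPTrace",
    "STAResult",
    "SFCResult",
    "AttentionalIndexSet",
    "SynchronyMatrix",
    "GroupStats",
    "firing_rate",
    "simulate_lfp",
    "spike_triggered_average",
    "multitaper_psd",
    "spike_field_coherence",
    "band_average",
    "attentional_indices",
    "pairwise_synchrony",
    "synchrony_matrix",
    "group_stats",
]

#: analysis frequency bands (Hz)
BANDS = {
    "gamma": (25.0, 70.0),
    "low": (8.0, 25.0),
    "alpha": (8.0, 15.0),
    "beta": (15.0, 25.0),
}

STA_HALF_WINDOW_MS = 300.0


@dataclass
class LFPTrace:
    """Simulated LFP of one column: summed synaptic currents onto its L2/3
    RS cells, uniformly sampled."""

    values: np.ndarray
    dt: float  # ms

    @property
    def fs(self) -> float:
        return 1000.0 / self.dt

    @property
    def duration(self) -> float:
        return (self.values.size - 1) * self.dt


@dataclass
class STAResult:
    """Spike-triggered average of the LFP over a +/-300 ms window."""

    sta: np.ndarray
    lags: np.ndarray  # ms, length == sta
    n_spikes: int
    pooled: bool = False


@dataclass
class SFCResult:
    """Spike-field coherence on a frequency grid, with band summaries."""

    freqs: np.ndarray
    sfc: np.ndarray  # masked array where the denominator vanished
    n_spikes: int
    bands: dict = field(default_factory=dict)


@dataclass
class GroupStats:
    mean: float
    se: float
    t: float
    p: float
    n: int
    flag: str | None = None


@dataclass
class AttentionalIndexSet:
    """Per-realization attentional indices and their across-realization
    statistics (one-sample t-test against 0)."""

    ai_gamma: np.ndarray
    ai_low: np.ndarray
    ai_rate: np.ndarray
    stats: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.stats:
            self.stats = {
                "gamma": group_stats(self.ai_gamma),
                "low": group_stats(self.ai_low),
                "rate": group_stats(self.ai_rate),
            }


@dataclass
class SynchronyMatrix:
    """Pairwise zero-lag coincidence synchrony of L2/3 RS cells."""

    kappa: np.ndarray  # NaN where undefined (a silent train)
    cells: np.ndarray
    n_excluded_pairs: int

    @property
    def population_mean(self) -> float:
        iu = np.triu_indices(self.kappa.shape[0], k=1)
        vals = self.kappa[iu]
        vals = vals[~np.isnan(vals)]
        return float(vals.mean()) if vals.size else float("nan")


def firing_rate(spike_times, n_cells: int, duration_ms: float) -> float:
    """Population firing rate in Hz: total spikes / (cells x seconds)."""
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    if n_cells <= 0:
        raise ValueError("empty population")
    return len(spike_times) / n_cells / (duration_ms / 1000.0)


def simulate_lfp(sim, column: int) -> LFPTrace:
    """Column LFP from a :class:`~betacol.simulator.SimResult`: pointwise sum
    of the recorded synaptic currents onto all its L2/3 RS cells."""
    if sim.lfp is None:
        raise ValueError("synaptic-current sources were not recorded; rerun with record_lfp=True")
    return LFPTrace(values=sim.column_lfp(column), dt=sim.lfp_dt)


def _eligible_segments(lfp: LFPTrace, spike_times_ms, half_window: float):
    half = int(round(half_window / lfp.dt))
    n = lfp.values.size
    segs = []
    for t in np.asarray(spike_times_ms, dtype=float):
        i = int(round(t / lfp.dt))
        if i - half >= 0 and i + half <= n:
            segs.append(lfp.values[i - half : i + half])
    return segs, half


def spike_triggered_average(
    lfp: LFPTrace | list,
    spikes: np.ndarray | list,
    half_window: float = STA_HALF_WINDOW_MS,
) -> STAResult:
    """Mean LFP segment around each spike.

    ``lfp`` and ``spikes`` may be single objects or equal-length lists (one
    per realization); segments are pooled before averaging.  Spikes closer
    than ``half_window`` to an edge are excluded.  With zero eligible spikes
    an explicit empty result (n_spikes = 0, zero STA) is returned.
    """
    lfps = lfp if isinstance(lfp, (list, tuple)) else [lfp]
    spk = spikes if isinstance(spikes, (list, tuple)) else [spikes]
    if len(lfps) != len(spk):
        raise ValueError("need one spike train collection per LFP trace")
    segs = []
    half = int(round(half_window / lfps[0].dt))
    for tr, times in zip(lfps, spk):
        s, half = _eligible_segments(tr, times, half_window)
        segs.extend(s)
    lags = (np.arange(2 * half) - half) * lfps[0].dt
    if not segs:
        return STAResult(sta=np.zeros(2 * half), lags=lags, n_spikes=0, pooled=len(lfps) > 1)
    return STAResult(sta=np.mean(segs, axis=0), lags=lags, n_spikes=len(segs), pooled=len(lfps) > 1)


def multitaper_psd(x: np.ndarray, fs: float, nw: float = 3.0, n_tapers: int = 5, nfft: int | None = None):
    """Multitaper power spectral density (DPSS tapers, eigenvalue-unweighted
    average of tapered periodograms).

    Returns (freqs, psd) with a one-sided spectrum; Parseval-consistent:
    sum(psd) * df ~ mean(x**2) for a zero-mean signal.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError("signal too short for spectral estimation")
    if nfft is None:
        nfft = n
    tapers = dpss(n, nw, n_tapers)  # rows are unit-energy windows
    spectra = np.abs(np.fft.rfft(tapers * x[None, :], n=nfft, axis=1)) ** 2
    psd = spectra.mean(axis=0) / fs
    if nfft % 2 == 0:
        psd[1:-1] *= 2.0
    else:
        psd[1:] *= 2.0
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return freqs, psd


def spike_field_coherence(
    lfp: LFPTrace | list,
    spikes: np.ndarray | list,
    half_window: float = STA_HALF_WINDOW_MS,
    nw: float = 3.0,
    n_tapers: int = 5,
    exclude_harmonic: tuple | None = None,
) -> SFCResult:
    """SFC(f) = PSD(STA)(f) / mean_i PSD(segment_i)(f).

    Frequencies where the mean spike-triggered spectrum vanishes are masked.
    Requires at least 2 eligible spikes.  ``exclude_harmonic`` optionally
    drops a frequency range (e.g. ``(36, 44)`` around the 40 Hz harmonic of
    the 20 Hz drive) from the band summaries; the raw band means are the
    default.
    """
    lfps = lfp if isinstance(lfp, (list, tuple)) else [lfp]
    spk = spikes if isinstance(spikes, (list, tuple)) else [spikes]
    segs = []
    for tr, times in zip(lfps, spk):
        s, _ = _eligible_segments(tr, times, half_window)
        segs.extend(s)
    if len(segs) < 2:
        raise ValueError(f"need >= 2 eligible spikes for SFC, got {len(segs)}")
    fs = lfps[0].fs
    sta = np.mean(segs, axis=0)
    freqs, num = multitaper_psd(sta, fs, nw=nw, n_tapers=n_tapers)
    den = np.zeros_like(num)
    for s in segs:
        den += multitaper_psd(s, fs, nw=nw, n_tapers=n_tapers)[1]
    den /= len(segs)
    sfc = np.ma.masked_invalid(np.ma.divide(num, den))
    bands = {
        name: band_average(freqs, sfc, lo, hi, exclude=exclude_harmonic)
        for name, (lo, hi) in BANDS.items()
    }
    return SFCResult(freqs=freqs, sfc=sfc, n_spikes=len(segs), bands=bands)


def band_average(freqs: np.ndarray, values: np.ndarray, lo: float, hi: float, exclude: tuple | None = None) -> float:
    """Mean of ``values`` over frequency bins in [lo, hi], optionally
    excluding the bins inside ``exclude = (lo_x, hi_x)``."""
    sel = (freqs >= lo) & (freqs <= hi)
    if exclude is not None:
        sel &= ~((freqs >= exclude[0]) & (freqs <= exclude[1]))
    if not np.any(sel):
        raise ValueError(f"no frequency bins in [{lo}, {hi}] Hz")
    v = values[sel]
    if np.ma.isMaskedArray(v):
        v = v.compressed()
    return float(np.mean(v))


def _norm_diff(att: np.ndarray, unatt: np.ndarray) -> np.ndarray:
    att = np.asarray(att, dtype=float)
    unatt = np.asarray(unatt, dtype=float)
    denom = att + unatt
    out = np.full(att.shape, np.nan)
    ok = denom != 0
    out[ok] = (att[ok] - unatt[ok]) / denom[ok]
    return out


def attentional_indices(metrics_att: dict, metrics_unatt: dict) -> AttentionalIndexSet:
    """Normalized-difference attentional indices from paired per-realization
    measurements.

    Each metrics dict maps ``"sfc_gamma"``, ``"sfc_low"`` and ``"rate"`` to
    arrays of per-realization values.  AI = (att - unatt)/(att + unatt);
    realizations with a vanishing denominator are masked (NaN).
    """
    return AttentionalIndexSet(
        ai_gamma=_norm_diff(metrics_att["sfc_gamma"], metrics_unatt["sfc_gamma"]),
        ai_low=_norm_diff(metrics_att["sfc_low"], metrics_unatt["sfc_low"]),
        ai_rate=_norm_diff(metrics_att["rate"], metrics_unatt["rate"]),
    )


def _binary_train(times, duration_ms: float, bin_ms: float) -> np.ndarray:
    n = int(np.ceil(duration_ms / bin_ms))
    x = np.zeros(n, dtype=np.int8)
    idx = np.floor(np.asarray(times, dtype=float) / bin_ms).astype(int)
    idx = idx[(idx >= 0) & (idx < n)]
    x[idx] = 1
    return x


def pairwise_synchrony(spikes_i, spikes_j, duration_ms: float, bin_ms: float = 1.0) -> float:
    """Zero-lag coincidence synchrony of two spike trains on binary bins.

    Returns NaN if either train has no spikes (undefined).
    """
    x = _binary_train(spikes_i, duration_ms, bin_ms)
    y = _binary_train(spikes_j, duration_ms, bin_ms)
    sx, sy = int(x.sum()), int(y.sum())
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.dot(x, y) / np.sqrt(sx * sy))


def synchrony_matrix(spike_trains: dict, duration_ms: float, bin_ms: float = 1.0) -> SynchronyMatrix:
    """Pairwise synchrony for a population; ``spike_trains`` maps cell id ->
    spike-time array.  Pairs involving silent cells are excluded from the
    population mean and counted."""
    cells = np.asarray(sorted(spike_trains))
    bins = [_binary_train(spike_trains[c], duration_ms, bin_ms) for c in cells]
    counts = np.array([b.sum() for b in bins])
    n = len(cells)
    kappa = np.full((n, n), np.nan)
    excluded = 0
    for i in range(n):
        if counts[i] > 0:
            kappa[i, i] = 1.0
        for j in range(i + 1, n):
            if counts[i] == 0 or counts[j] == 0:
                excluded += 1
                continue
            k = np.dot(bins[i], bins[j]) / np.sqrt(counts[i] * counts[j])
            kappa[i, j] = kappa[j, i] = k
    return SynchronyMatrix(kappa=kappa, cells=cells, n_excluded_pairs=excluded)


def population_spike_spectrum(spike_times, duration_ms: float, bin_ms: float = 1.0, nw: float = 3.0, n_tapers: int = 5):
    """Multitaper spectrum of a pooled population spike train binned at
    ``bin_ms`` (counts, mean removed).  Returns (freqs, psd)."""
    n = int(round(duration_ms / bin_ms))
    counts = np.histogram(np.asarray(spike_times, dtype=float), bins=n, range=(0.0, duration_ms))[0].astype(float)
    counts -= counts.mean()
    return multitaper_psd(counts, fs=1000.0 / bin_ms, nw=nw, n_tapers=n_tapers)


def peak_frequency(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    """Frequency of the largest spectral value inside [lo, hi] Hz."""
    sel = (freqs >= lo) & (freqs <= hi)
    if not np.any(sel):
        raise ValueError(f"no frequency bins in [{lo}, {hi}] Hz")
    f, p = freqs[sel], psd[sel]
    return float(f[np.argmax(p)])


def burst_events(spikes_df, n_cells: int, duration_ms: float, bin_ms: float = 10.0, fraction: float = 0.25) -> np.ndarray:
    """Population burst-event times: 10 ms bins in which at least
    ``fraction`` of the cells spike; runs of consecutive qualifying bins are
    merged into one event (time of its first bin)."""
    n_bins = int(np.ceil(duration_ms / bin_ms))
    threshold = fraction * n_cells
    active = np.zeros(n_bins, dtype=bool)
    t = np.asarray(spikes_df["time"], dtype=float)
    c = np.asarray(spikes_df["cell"])
    idx = np.floor(t / bin_ms).astype(int)
    for b in range(n_bins):
        active[b] = len(set(c[idx == b])) >= threshold
    events = []
    prev = False
    for b in range(n_bins):
        if active[b] and not prev:
            events.append(b * bin_ms)
        prev = active[b]
    return np.asarray(events)


def burst_recurrence_frequency(event_times: np.ndarray, max_interval_ms: float = 300.0) -> float:
    """Inverse of the mean inter-event interval, over intervals shorter than
    ``max_interval_ms``; NaN with fewer than two qualifying intervals."""
    iv = np.diff(np.asarray(event_times, dtype=float))
    iv = iv[iv < max_interval_ms]
    if iv.size == 0:
        return float("nan")
    return 1000.0 / float(iv.mean())


def group_stats(values, null: float = 0.0, other=None) -> GroupStats:
    """One-sample t-test of per-realization values against ``null`` (or a
    two-sample Welch test against ``other``).  NaN realizations are dropped;
    zero-variance samples are flagged instead of erroring."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        return GroupStats(float(v.mean()) if v.size else float("nan"), float("nan"), float("nan"), float("nan"), int(v.size), flag="too-few")
    se = float(v.std(ddof=1) / np.sqrt(v.size))
    if other is not None:
        w = np.asarray(other, dtype=float)
        w = w[~np.isnan(w)]
        t, p = stats.ttest_ind(v, w, equal_var=False)
        return GroupStats(float(v.mean() - w.mean()), se, float(t), float(p), int(v.size))
    if np.allclose(v.std(ddof=1), 0.0):
        return GroupStats(float(v.mean()), 0.0, float("nan"), float("nan"), int(v.size), flag="zero-variance")
    t, p = stats.ttest_1samp(v, null)
    return GroupStats(float(v.mean()), se, float(t), float(p), int(v.size))
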
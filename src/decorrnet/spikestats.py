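"""Estimators for population rates, compound spectra, integral pairwise
correlations, input-correlation decompositions and readout signal-to-noise.

Conventions
-----------
* "Variance"/"covariance" refer to the *integral* of the auto-/cross-
  correlation function (the zero-frequency spectral density), estimated
  from spike counts in long disjoint windows: for a window of length
  ``T`` the count (co)variance divided by ``T`` converges to the
  integral (co)variance.
* The compound power spectrum is the spectral density of the binned,
  mean-subtracted *population-averaged* rate (spikes/s per neuron).
  Under this normalization an ensemble of ``N`` independent Poisson
  trains of rate ``nu`` has a flat spectrum at ``nu / N``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .netsim import NetworkTopology, SpikeData, SynapseSpec

__all__ = [
    "PopulationRate",
    "PowerSpectrum",
    "CorrelationEstimates",
    "InputDecomposition",
    "ReadoutStats",
    "population_rate",
    "compound_spectrum",
    "lf_power_ratio",
    "integral_correlations",
    "input_decomposition",
    "readout_snr",
    "average_auto_spectrum",
    "average_cross_spectrum",
]


@dataclass
class PopulationRate:
    times: np.ndarray        # bin centers (ms)
    value: np.ndarray        # population-averaged rate (spikes/s)
    bin: float               # bin width (ms)
    population: str
    N: int                   # number of neurons averaged

    @property
    def mean(self) -> float:
        return float(np.mean(self.value))


@dataclass
class PowerSpectrum:
    freq: np.ndarray         # Hz (DC excluded)
    power: np.ndarray        # spectral density of the population-avg rate
    frame: float             # smoothing frame (Hz)
    normalization: str = "per_neuron_population_average"
    meta: dict = field(default_factory=dict)


@dataclass
class CorrelationEstimates:
    """Class-averaged integral auto-/cross-covariances (spikes^2/s) with
    jackknife standard errors, and correlation coefficients."""

    a_E: float
    a_I: float
    c_EE: float
    c_EI: float
    c_II: float
    rho_EE: float
    rho_EI: float
    rho_II: float
    se: dict
    n_pairs: dict
    window: float

    def c_bar(self, a: str, b: str) -> float:
        key = "c_" + "".join(sorted(a + b))
        return getattr(self, key)


@dataclass
class InputDecomposition:
    """Decomposition of the covariance between the summed synaptic inputs
    of a target pair: shared-source term + spike-correlation term."""

    c_shared: float
    c_corr: float
    a_in: float
    q_in: float

    @property
    def cancellation_factor(self) -> float:
        denom = max(abs(self.c_shared), abs(self.c_corr))
        return abs(self.c_shared + self.c_corr) / denom if denom else 0.0


@dataclass
class ReadoutStats:
    """Statistics of a linear readout of n homogeneous spike trains.

    kappa : spike-train coherence (pairwise cross/auto spectral ratio)
    m1    : magnitude of the first filter moment |mean_i F_i|
    m2    : second filter moment mean_i |F_i|^2
    """

    n_filters: int
    kappa: float
    m1: float
    m2: float

    def __post_init__(self):
        if self.n_filters < 1:
            raise InputError("n_filters must be >= 1")
        if not (0.0 <= self.kappa <= 1.0):
            raise InputError("kappa must lie in [0, 1]")
        if self.m2 < 0:
            raise InputError("m2 must be >= 0")


# ---------------------------------------------------------------------------
# rates and spectra
# ---------------------------------------------------------------------------

def _pop_ids(spikes: SpikeData, population: str | None) -> np.ndarray:
    ids = spikes.population_ids(population)
    if ids.size == 0:
        raise InputError(f"population {population!r} is empty")
    return ids


def _binned_popsum(spikes: SpikeData, bin: float,
                   population: str | None) -> tuple[np.ndarray, np.ndarray, int]:
    """Summed spike counts per time bin for one population."""
    ids = _pop_ids(spikes, population)
    n_bins = int(round(spikes.duration / bin))
    if n_bins < 1:
        raise InputError("bin width exceeds duration")
    t_edges = np.arange(n_bins + 1) * bin
    keep = np.isin(spikes.ids, ids) if population not in (None, "all") \
        else np.ones(spikes.n_spikes, dtype=bool)
    counts, _ = np.histogram(spikes.times[keep], bins=t_edges)
    centers = (t_edges[:-1] + t_edges[1:]) / 2.0
    return centers, counts.astype(float), ids.size


def population_rate(spikes: SpikeData, bin: float,
                    population: str | None = None) -> PopulationRate:
    """Population-averaged instantaneous firing rate (spikes/s)."""
    if bin <= 0:
        raise InputError("bin must be positive")
    centers, counts, n = _binned_popsum(spikes, bin, population)
    value = counts / (bin * 1e-3) / n
    return PopulationRate(times=centers, value=value, bin=bin,
                          population=population or "all", N=n)


def _periodogram(x: np.ndarray, dt_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided spectral density on the positive-frequency grid."""
    n = x.size
    xf = np.fft.rfft(x - x.mean())
    power = (dt_s / n) * np.abs(xf) ** 2
    freq = np.fft.rfftfreq(n, d=dt_s)
    return freq[1:], power[1:]          # DC excluded


def _smooth(power: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return power
    kernel = np.ones(window)
    norm = np.convolve(np.ones_like(power), kernel, mode="same")
    return np.convolve(power, kernel, mode="same") / norm


def compound_spectrum(spikes: SpikeData, bin: float = 0.5,
                      frame: float = 1.0,
                      population: str | None = None) -> PowerSpectrum:
    """Power spectrum of the population-averaged rate.

    Periodogram of the binned, mean-subtracted population average,
    normalized as a two-sided spectral density (Poisson floor ``nu/N``),
    smoothed by a centered moving average of width ``frame`` (Hz).
    """
    if spikes.duration * 1e-3 < 10.0 / frame:
        raise InputError("duration must be at least 10 smoothing frames")
    rate = population_rate(spikes, bin, population)
    dt_s = bin * 1e-3
    freq, power = _periodogram(rate.value, dt_s)
    df = freq[0]
    if frame < df:
        raise InputError(
            f"smoothing frame {frame} Hz below frequency resolution {df:.4g} Hz")
    power = _smooth(power, int(round(frame / df)))
    return PowerSpectrum(freq=freq, power=power, frame=frame,
                         meta={"bin": bin, "population": rate.population,
                               "N": rate.N, "nu_mean": rate.mean})


def lf_power_ratio(spec_a: PowerSpectrum, spec_b: PowerSpectrum,
                   band: tuple[float, float] = (1.0, 10.0)) -> float:
    """Ratio of band-averaged powers of two spectra on the same grid."""
    if spec_a.freq.shape != spec_b.freq.shape or \
            not np.allclose(spec_a.freq, spec_b.freq):
        raise InputError("spectra must share an identical frequency grid")
    lo, hi = band
    mask = (spec_a.freq >= lo) & (spec_a.freq <= hi)
    if not mask.any():
        raise InputError(f"band {band} contains no frequency bins")
    return float(np.mean(spec_a.power[mask]) / np.mean(spec_b.power[mask]))


def average_auto_spectrum(spikes: SpikeData, bin: float,
                          ids: np.ndarray, frame: float = 0.0
                          ) -> PowerSpectrum:
    """Mean single-train spectral density over the given neuron ids
    (Poisson floor ``nu`` per train)."""
    n_bins = int(round(spikes.duration / bin))
    t_edges = np.arange(n_bins + 1) * bin
    dt_s = bin * 1e-3
    acc = None
    for i in ids:
        counts, _ = np.histogram(spikes.times[spikes.ids == i], bins=t_edges)
        x = counts / dt_s
        freq, p = _periodogram(x, dt_s)
        acc = p if acc is None else acc + p
    power = acc / len(ids)
    if frame > 0:
        power = _smooth(power, int(round(frame / freq[0])))
    return PowerSpectrum(freq=freq, power=power, frame=frame,
                         normalization="per_train", meta={"n_trains": len(ids)})


def average_cross_spectrum(spikes: SpikeData, bin: float,
                           pairs: np.ndarray, frame: float = 0.0
                           ) -> PowerSpectrum:
    """Mean real cross-spectral density over the given id pairs."""
    n_bins = int(round(spikes.duration / bin))
    t_edges = np.arange(n_bins + 1) * bin
    dt_s = bin * 1e-3
    cache: dict[int, np.ndarray] = {}

    def ft(i):
        if i not in cache:
            counts, _ = np.histogram(spikes.times[spikes.ids == i],
                                     bins=t_edges)
            x = counts / dt_s
            cache[i] = np.fft.rfft(x - x.mean())
        return cache[i]

    acc = None
    for i, j in pairs:
        cs = (dt_s / n_bins) * np.real(ft(int(i)) * np.conj(ft(int(j))))
        acc = cs if acc is None else acc + cs
    power = acc[1:] / len(pairs)
    freq = np.fft.rfftfreq(n_bins, d=dt_s)[1:]
    if frame > 0:
        power = _smooth(power, int(round(frame / freq[0])))
    return PowerSpectrum(freq=freq, power=power, frame=frame,
                         normalization="per_pair_cross",
                         meta={"n_pairs": len(pairs)})


# ---------------------------------------------------------------------------
# integral correlations
# ---------------------------------------------------------------------------

def _jackknife_se(per_window: np.ndarray) -> float:
    """Delete-one-window jackknife SE of the mean of per-window terms."""
    m = per_window.size
    if m < 2:
        return float("nan")
    total = per_window.sum()
    loo = (total - per_window) / (m - 1)
    return float(np.sqrt((m - 1) / m * np.sum((loo - loo.mean()) ** 2)))


def integral_correlations(spikes: SpikeData, window: float = 100.0,
                          n_pairs: int | None = 2000,
                          seed: int = 0) -> CorrelationEstimates:
    """Class-averaged integral covariances from disjoint count windows.

    Counts are collected in disjoint windows of length ``window`` (ms);
    the integral covariance of a pair is the count covariance divided by
    the window length.  Cross-covariances are averaged over ``n_pairs``
    randomly sampled pairs per class (EE/EI/II), or over *all* pairs via
    an exact aggregation identity when ``n_pairs`` is None.  Standard
    errors are delete-one-window jackknives.  Coefficients are
    normalized by the geometric mean of the class auto-variances.
    """
    if spikes.duration < 100.0 * window:
        raise InputError("duration must cover at least 100 count windows")
    m = int(spikes.duration // window)
    w_s = window * 1e-3
    edges_t = np.arange(m + 1) * window
    counts = np.zeros((m, spikes.n_neurons))
    t_idx = np.minimum((spikes.times // window).astype(int), m - 1)
    keep = spikes.times < m * window
    np.add.at(counts, (t_idx[keep], spikes.ids[keep]), 1.0)
    x = counts - counts.mean(axis=0, keepdims=True)

    rng = np.random.default_rng(seed)
    pops = {"E": np.flatnonzero(~spikes.is_inh),
            "I": np.flatnonzero(spikes.is_inh)}
    avail = {t: v for t, v in pops.items() if v.size}

    # auto-variances per class
    a_val, a_se = {}, {}
    for t, ids in pops.items():
        if ids.size == 0:
            a_val[t] = a_se[t] = float("nan")
            continue
        per_w = np.mean(x[:, ids] ** 2, axis=1)   # per-window mean square
        a_val[t] = per_w.sum() / (m - 1) / w_s
        a_se[t] = _jackknife_se(per_w) * m / (m - 1) / w_s

    # cross-covariances per class pair
    c_val, c_se, n_used = {}, {}, {}
    for pair in (("E", "E"), ("E", "I"), ("I", "I")):
        ta, tb = pair
        if ta not in avail or tb not in avail or \
                (ta == tb and avail[ta].size < 2):
            c_val[pair] = c_se[pair] = float("nan")
            n_used[pair] = 0
            continue
        ids_a, ids_b = pops[ta], pops[tb]
        if n_pairs is None:
            # exact all-pair average via population sums
            sa = x[:, ids_a].sum(axis=1)
            sb = x[:, ids_b].sum(axis=1)
            if ta == tb:
                per_w = (sa * sb - np.sum(x[:, ids_a] ** 2, axis=1)) \
                    / (ids_a.size * (ids_a.size - 1))
                n_used[pair] = ids_a.size * (ids_a.size - 1) // 2
            else:
                per_w = sa * sb / (ids_a.size * ids_b.size)
                n_used[pair] = ids_a.size * ids_b.size
        else:
            if ta == tb:
                i = rng.integers(0, ids_a.size, size=2 * n_pairs)
                j = rng.integers(0, ids_a.size, size=2 * n_pairs)
                ok = i != j
                pi, pj = ids_a[i[ok]][:n_pairs], ids_a[j[ok]][:n_pairs]
            else:
                pi = ids_a[rng.integers(0, ids_a.size, size=n_pairs)]
                pj = ids_b[rng.integers(0, ids_b.size, size=n_pairs)]
            per_w = np.mean(x[:, pi] * x[:, pj], axis=1)
            n_used[pair] = len(pi)
        c_val[pair] = per_w.sum() / (m - 1) / w_s
        c_se[pair] = _jackknife_se(per_w) * m / (m - 1) / w_s

    def rho_of(pair):
        ga = a_val[pair[0]]
        gb = a_val[pair[1]]
        if math.isnan(c_val[pair]) or math.isnan(ga) or math.isnan(gb):
            return float("nan")
        return c_val[pair] / math.sqrt(ga * gb)

    se = {"a_E": a_se["E"], "a_I": a_se["I"],
          "c_EE": c_se[("E", "E")], "c_EI": c_se[("E", "I")],
          "c_II": c_se[("I", "I")]}
    se["rho_EE"] = se["c_EE"] / a_val["E"] if a_val["E"] else float("nan")
    se["rho_II"] = se["c_II"] / a_val["I"] if a_val["I"] else float("nan")
    if not (math.isnan(a_val["E"]) or math.isnan(a_val["I"])):
        se["rho_EI"] = se["c_EI"] / math.sqrt(a_val["E"] * a_val["I"])
    else:
        se["rho_EI"] = float("nan")
    return CorrelationEstimates(
        a_E=a_val["E"], a_I=a_val["I"],
        c_EE=c_val[("E", "E")], c_EI=c_val[("E", "I")],
        c_II=c_val[("I", "I")],
        rho_EE=rho_of(("E", "E")), rho_EI=rho_of(("E", "I")),
        rho_II=rho_of(("I", "I")),
        se=se, n_pairs=n_used, window=window)


def input_decomposition(topology: NetworkTopology, est: CorrelationEstimates,
                        synapse: SynapseSpec) -> InputDecomposition:
    """Shared-input and spike-correlation contributions to the covariance
    between the summed synaptic inputs of a target pair, from measured
    class-averaged spike statistics and the expected overlap of the
    fixed in-degree connectivity."""
    pops = []
    if topology.n_exc:
        pops.append(("E", topology.n_exc, topology.K_E, synapse.J))
    if topology.n_inh:
        pops.append(("I", topology.n_inh, topology.K_I, synapse.J_inh))
    autos = {"E": est.a_E, "I": est.a_I}
    c_shared = sum((k * k / n) * j * j * autos[t] for t, n, k, j in pops)
    c_corr = 0.0
    a_in = 0.0
    for ta, na, ka, ja in pops:
        a_in += ka * ja * ja * autos[ta]
        for tb, nb, kb, jb in pops:
            cbar = est.c_bar(ta, tb)
            n_cross = ka * kb - (ka * ka / na if ta == tb else 0.0)
            n_own = ka * kb - (ka if ta == tb else 0.0)
            c_corr += n_cross * ja * jb * cbar
            a_in += n_own * ja * jb * cbar
    return InputDecomposition(c_shared=c_shared, c_corr=c_corr, a_in=a_in,
                              q_in=(c_shared + c_corr) / a_in)


# ---------------------------------------------------------------------------
# readout signal-to-noise
# ---------------------------------------------------------------------------

def readout_snr(stats: ReadoutStats) -> float:
    """Squared signal-to-noise ratio of a linear readout of n correlated
    spike trains, normalized to unit signal power and unit single-train
    noise density:

        snr = n |m1|^2 / ((1 - kappa) m2 + kappa n |m1|^2)

    For uncorrelated trains (kappa = 0, identical filters) the ratio
    grows linearly with n; for kappa > 0 it saturates at 1/kappa.
    """
    n, kappa = stats.n_filters, stats.kappa
    num = n * stats.m1 ** 2
    den = (1.0 - kappa) * stats.m2 + kappa * n * stats.m1 ** 2
    if den == 0.0:
        raise InputError("degenerate readout: zero noise denominator")
    return num / den
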
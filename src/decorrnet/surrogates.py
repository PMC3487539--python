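"""Perturbed-feedback spike-train ensembles (surrogates).

These operations generate the feedforward replacement ensembles used to
probe which statistical features of the feedback are required for
decorrelation: stationary (homogeneous) and rate-modulated
(inhomogeneous) Poisson replacements, permutations of spike-train sender
identities across the whole network or within each subpopulation, and
random reassignment of the neuron type attached to each train.

Sender shuffles and type reassignment conserve the total spike count
exactly; Poisson replacements conserve it in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .netsim import SpikeData

__all__ = [
    "RateProfile",
    "homogeneous_poisson_ensemble",
    "inhomogeneous_poisson_ensemble",
    "shuffle_senders",
    "reassign_types",
    "profile_from_rate",
]


@dataclass
class RateProfile:
    """Piecewise-constant instantaneous rate profile (spikes/s per train)."""

    times: np.ndarray        # bin centers (ms)
    rate: np.ndarray         # spikes/s
    population: str = "all"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.times.size < 1 or self.times.shape != self.rate.shape:
            raise InputError("times and rate must be equal-length, non-empty")
        if np.any(self.rate < 0):
            raise InputError("rates must be non-negative")
        widths = np.diff(self.times)
        if widths.size and not np.allclose(widths, widths[0]):
            raise InputError("profile bins must be uniform")

    @property
    def bin(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 \
            else 2.0 * float(self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] + self.bin / 2.0)


def profile_from_rate(rate) -> RateProfile:
    """Build a RateProfile from a :class:`~decorrnet.spikestats.PopulationRate`."""
    return RateProfile(times=rate.times, rate=rate.value,
                       population=rate.population)


def _as_spikedata(ids, times, duration, n, is_inh, meta) -> SpikeData:
    order = np.argsort(times, kind="stable")
    return SpikeData(ids=np.asarray(ids)[order], times=np.asarray(times)[order],
                     duration=duration, n_neurons=n, is_inh=is_inh, meta=meta)


def homogeneous_poisson_ensemble(n_trains: int, rate: float, duration: float,
                                 seed: int,
                                 is_inh: np.ndarray | None = None) -> SpikeData:
    """Ensemble of independent stationary Poisson trains at equal rate."""
    if rate < 0:
        raise InputError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    lam = rate * duration * 1e-3
    counts = rng.poisson(lam, size=n_trains)
    ids = np.repeat(np.arange(n_trains), counts)
    times = rng.uniform(0.0, duration, size=counts.sum())
    if is_inh is None:
        is_inh = np.zeros(n_trains, dtype=bool)
    return _as_spikedata(ids, times, duration, n_trains, is_inh,
                         {"scenario": "poissH", "rate": rate, "seed": seed})


def inhomogeneous_poisson_ensemble(n_trains: int, profile: RateProfile,
                                   seed: int,
                                   is_inh: np.ndarray | None = None,
                                   noise_scale: float = 1.0) -> SpikeData:
    """Independent inhomogeneous Poisson trains following a rate profile.

    Sampling by thinning against the profile maximum; the ensemble-mean
    rate converges to the profile.  ``noise_scale`` generalizes the
    realization noise: for values other than 1 the per-bin ensemble
    counts are drawn as ``N r dt + noise_scale * sqrt(N r dt) * xi``
    (Gaussian approximation, clipped at zero) and distributed uniformly
    over trains and bin interiors; this path is exposed for exploration
    and is not calibrated against any reference value.
    """
    if profile.bin > 1.0 + 1e-9:
        raise InputError("profile bin width must be <= 1 ms for thinning")
    rng = np.random.default_rng(seed)
    rmax = float(profile.rate.max())
    duration = profile.duration
    if is_inh is None:
        is_inh = np.zeros(n_trains, dtype=bool)
    meta = {"scenario": "poissI", "seed": seed, "noise_scale": noise_scale}
    if rmax == 0.0:
        return _as_spikedata(np.empty(0, int), np.empty(0), duration,
                             n_trains, is_inh, meta)
    if noise_scale == 1.0:
        lam = rmax * duration * 1e-3
        counts = rng.poisson(lam, size=n_trains)
        ids = np.repeat(np.arange(n_trains), counts)
        times = rng.uniform(0.0, duration, size=counts.sum())
        bin_idx = np.minimum((times // profile.bin).astype(int),
                             profile.rate.size - 1)
        accept = rng.random(times.size) < profile.rate[bin_idx] / rmax
        return _as_spikedata(ids[accept], times[accept], duration, n_trains,
                             is_inh, meta)
    # generalized realization-noise amplitude (Gaussian approximation)
    lam_bin = n_trains * profile.rate * profile.bin * 1e-3
    counts = np.maximum(
        np.round(lam_bin + noise_scale * np.sqrt(lam_bin)
                 * rng.standard_normal(lam_bin.size)), 0.0).astype(int)
    ids = rng.integers(0, n_trains, size=int(counts.sum()))
    starts = profile.times - profile.bin / 2.0
    times = np.repeat(starts, counts) + rng.uniform(
        0.0, profile.bin, size=int(counts.sum()))
    times = np.clip(times, 0.0, np.nextafter(duration, 0.0))
    return _as_spikedata(ids, times, duration, n_trains, is_inh, meta)


def shuffle_senders(spikes: SpikeData, mode: str, seed: int,
                    per_spike: bool = False) -> SpikeData:
    """Randomize spike-train sender identities.

    mode 'across_network'     : identities exchanged over the whole network
    mode 'within_population'  : identities exchanged only within E and
                                within I separately
    With ``per_spike=False`` (default) a permutation is applied to whole
    trains; spike times are untouched and the compound rate is exactly
    conserved.  ``per_spike=True`` draws a new random sender for each
    individual spike instead.
    """
    if mode not in ("across_network", "within_population"):
        raise InputError(f"unknown shuffle mode {mode!r}")
    rng = np.random.default_rng(seed)
    n = spikes.n_neurons
    groups = [np.arange(n)] if mode == "across_network" else \
        [np.flatnonzero(~spikes.is_inh), np.flatnonzero(spikes.is_inh)]
    if per_spike:
        new_ids = spikes.ids.copy()
        for grp in groups:
            if grp.size == 0:
                continue
            mask = np.isin(spikes.ids, grp)
            new_ids[mask] = rng.choice(grp, size=int(mask.sum()), replace=True)
    else:
        perm = np.arange(n)
        for grp in groups:
            perm[grp] = rng.permutation(grp)
        new_ids = perm[spikes.ids]
    meta = dict(spikes.meta)
    meta.update({"surrogate": f"shuffle_{mode}", "seed": seed,
                 "per_spike": per_spike})
    return _as_spikedata(new_ids, spikes.times.copy(), spikes.duration,
                         n, spikes.is_inh.copy(), meta)


def reassign_types(spikes: SpikeData, gamma: float, seed: int) -> SpikeData:
    """Randomly reassign the neuron type (E or I) of each spike train.

    ``gamma`` is the target *inhibitory fraction*: each train is
    independently labeled inhibitory with probability ``gamma``.  Spike
    times and ids are untouched; the operation homogenizes the pairwise
    correlation structure across the EE/EI/II classes.
    """
    if not (0.0 < gamma < 1.0):
        raise InputError("gamma must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    new_inh = rng.random(spikes.n_neurons) < gamma
    meta = dict(spikes.meta)
    meta.update({"surrogate": "reassign_types", "gamma": gamma, "seed": seed})
    return SpikeData(ids=spikes.ids.copy(), times=spikes.times.copy(),
                     duration=spikes.duration, n_neurons=spikes.n_neurons,
                     is_inh=new_inh, meta=meta)
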
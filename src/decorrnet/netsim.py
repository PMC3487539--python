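"""LIF network construction and simulation.

Networks are random graphs with *fixed in-degrees*: every neuron receives
exactly ``K_E`` excitatory and ``K_I`` inhibitory inputs, drawn without
replacement from the respective population, excluding itself (no autapses,
no multapses).  Synapses are current based with either delta-shaped
(instantaneous) or alpha-shaped postsynaptic currents; in both cases the
synaptic strength is parameterized by the peak amplitude of the evoked
postsynaptic potential (PSP), ``J`` for excitation and ``-g J`` for
inhibition.  External drive is an independent Gaussian white-noise current
per neuron, expressed as the mean ``mu_ext`` and standard deviation
``sigma_ext`` of the free membrane potential it produces.

Two simulation modes share one integration kernel:

* ``simulate_network`` – the intact recurrent network (feedback scenario),
* ``simulate_open_loop`` – the same postsynaptic population driven through
  the *identical* connectivity by an externally supplied presynaptic
  spike ensemble (feedforward scenario).

Times are in milliseconds, rates in spikes/s, potentials in millivolts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .errors import ConfigurationError, InputError, NumericalError

__all__ = [
    "NeuronParams",
    "SynapseSpec",
    "ExternalDrive",
    "NetworkTopology",
    "SpikeData",
    "build_topology",
    "simulate_network",
    "simulate_open_loop",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire neuron parameters.

    tau_m : membrane time constant (ms)
    V_th  : spike threshold (mV)
    V_r   : reset potential (mV)
    tau_ref : absolute refractory period (ms)
    """

    tau_m: float = 20.0
    V_th: float = 20.0
    V_r: float = 0.0
    tau_ref: float = 2.0

    def __post_init__(self):
        if self.tau_m <= 0:
            raise ConfigurationError(f"tau_m must be > 0, got {self.tau_m}")
        if self.V_th <= self.V_r:
            raise ConfigurationError(
                f"V_th ({self.V_th}) must exceed V_r ({self.V_r})")
        if self.tau_ref < 0:
            raise ConfigurationError(f"tau_ref must be >= 0, got {self.tau_ref}")


@dataclass(frozen=True)
class SynapseSpec:
    """Synapse model: PSP peak amplitudes and kinetics.

    kernel : 'delta' (instantaneous PSC) or 'alpha' (low-pass PSC)
    J      : excitatory PSP peak amplitude (mV)
    g      : relative inhibitory weight; inhibitory amplitude is -g*J
    delay  : spike transmission delay (ms)
    tau_s  : synaptic time constant (ms), alpha kernel only
    """

    kernel: str = "delta"
    J: float = 0.1
    g: float = 5.0
    delay: float = 1.0
    tau_s: float | None = None

    def __post_init__(self):
        if self.kernel not in ("delta", "alpha"):
            raise ConfigurationError(f"unknown synapse kernel {self.kernel!r}")
        if self.J < 0:
            raise ConfigurationError("J must be >= 0")
        if self.g < 0:
            raise ConfigurationError("g must be >= 0")
        if self.delay < 0:
            raise ConfigurationError("delay must be >= 0")
        if self.kernel == "alpha" and (self.tau_s is None or self.tau_s <= 0):
            raise ConfigurationError("alpha kernel requires tau_s > 0")

    @property
    def J_inh(self) -> float:
        """Inhibitory PSP amplitude (mV, negative)."""
        return -self.g * self.J


@dataclass(frozen=True)
class ExternalDrive:
    """Independent Gaussian white-noise current drive per neuron.

    mu_ext    : stationary mean of the free membrane potential (mV)
    sigma_ext : stationary std of the free membrane potential (mV)
    """

    mu_ext: float = 15.0
    sigma_ext: float = 5.0
    independent: bool = True

    def __post_init__(self):
        if self.sigma_ext < 0:
            raise ConfigurationError("sigma_ext must be >= 0")
        if not self.independent:
            raise ConfigurationError(
                "correlated external drive is not supported; noise sources "
                "are independent across neurons")


@dataclass
class NetworkTopology:
    """Fixed in-degree random topology of a one- or two-population network.

    Excitatory neurons occupy ids ``[0, n_exc)``, inhibitory neurons
    ``[n_exc, N)``.  ``sources_exc[i]``/``sources_inh[i]`` list the
    presynaptic ids of target ``i``.
    """

    N: int
    n_exc: int
    n_inh: int
    K_E: int
    K_I: int
    sources_exc: np.ndarray  # (N, K_E) int64
    sources_inh: np.ndarray  # (N, K_I) int64
    seed: int
    _csr_cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def gamma(self) -> float:
        """Ratio of inhibitory to excitatory population size."""
        return self.n_inh / self.n_exc if self.n_exc else math.inf

    @property
    def is_inh(self) -> np.ndarray:
        mask = np.zeros(self.N, dtype=bool)
        mask[self.n_exc:] = True
        return mask

    @property
    def labels(self) -> np.ndarray:
        lab = np.full(self.N, "E", dtype="<U1")
        lab[self.n_exc:] = "I"
        return lab

    def adjacency(self) -> list[list[tuple[int, int]]]:
        """Per-target list of (source id, sign) pairs."""
        out = []
        for i in range(self.N):
            pairs = [(int(j), +1) for j in self.sources_exc[i]]
            pairs += [(int(j), -1) for j in self.sources_inh[i]]
            out.append(pairs)
        return out

    def out_csr(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """CSR of the out-adjacency: (indptr, targets, source_is_inh).

        ``indptr[j]:indptr[j+1]`` slices the targets of source ``j``.
        """
        if "csr" not in self._csr_cache:
            srcs = np.concatenate(
                [self.sources_exc.ravel(), self.sources_inh.ravel()])
            tgts = np.concatenate([
                np.repeat(np.arange(self.N), self.K_E),
                np.repeat(np.arange(self.N), self.K_I),
            ])
            order = np.argsort(srcs, kind="stable")
            srcs, tgts = srcs[order], tgts[order]
            indptr = np.zeros(self.N + 1, dtype=np.int64)
            np.add.at(indptr, srcs + 1, 1)
            np.cumsum(indptr, out=indptr)
            self._csr_cache["csr"] = (indptr, tgts.astype(np.int64))
        indptr, tgts = self._csr_cache["csr"]
        return indptr, tgts


@dataclass
class SpikeData:
    """Labeled spike trains of a (two-population) network.

    ids    : neuron id per spike (time-sorted together with ``times``)
    times  : spike times (ms), ``0 <= t < duration``
    duration : recording duration (ms)
    n_neurons : size of the id space
    is_inh : boolean population label per neuron id (True = inhibitory)
    meta   : provenance (generating parameters, seeds, scenario tag)
    """

    ids: np.ndarray
    times: np.ndarray
    duration: float
    n_neurons: int
    is_inh: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.ids.shape != self.times.shape:
            raise InputError("ids and times must have equal length")
        if self.times.size and (np.any(np.diff(self.times) < 0)):
            raise InputError("spike times must be sorted")
        if self.times.size and (self.times[0] < 0 or self.times[-1] >= self.duration):
            raise InputError("spike times must lie in [0, duration)")
        if self.ids.size and (self.ids.min() < 0 or self.ids.max() >= self.n_neurons):
            raise InputError("neuron ids must lie in [0, n_neurons)")
        self.is_inh = np.asarray(self.is_inh, dtype=bool)
        if self.is_inh.shape != (self.n_neurons,):
            raise InputError("is_inh must have one entry per neuron")

    @property
    def n_spikes(self) -> int:
        return self.ids.size

    @property
    def labels(self) -> np.ndarray:
        lab = np.full(self.n_neurons, "E", dtype="<U1")
        lab[self.is_inh] = "I"
        return lab

    def population_ids(self, population: str | None = None) -> np.ndarray:
        """Neuron ids belonging to a population ('E', 'I' or None = all)."""
        if population is None or population == "all":
            return np.arange(self.n_neurons)
        if population == "E":
            return np.flatnonzero(~self.is_inh)
        if population == "I":
            return np.flatnonzero(self.is_inh)
        raise InputError(f"unknown population tag {population!r}")

    def select(self, population: str) -> "SpikeData":
        """Restrict to spikes of one population (id space unchanged)."""
        keep = np.isin(self.ids, self.population_ids(population))
        return SpikeData(self.ids[keep], self.times[keep], self.duration,
                         self.n_neurons, self.is_inh, dict(self.meta))

    def crop(self, t0: float, t1: float | None = None) -> "SpikeData":
        """Keep spikes in [t0, t1) and shift times so t0 -> 0."""
        t1 = self.duration if t1 is None else t1
        keep = (self.times >= t0) & (self.times < t1)
        return SpikeData(self.ids[keep], self.times[keep] - t0, t1 - t0,
                         self.n_neurons, self.is_inh, dict(self.meta))

    def counts(self) -> np.ndarray:
        """Spike count per neuron id."""
        return np.bincount(self.ids, minlength=self.n_neurons)


# ---------------------------------------------------------------------------
# topology construction
# ---------------------------------------------------------------------------

def build_topology(N: int, gamma: float, K_E: int, K_I: int,
                   seed: int, n_exc: int | None = None) -> NetworkTopology:
    """Sample a fixed in-degree random topology.

    ``gamma`` sets the population split via ``N_I = gamma * N_E`` (with
    ``N_E + N_I = N``).  A purely inhibitory network is selected by
    ``K_E = 0`` (all neurons inhibitory); a purely excitatory one by
    ``K_I = 0``.  Source lists are drawn without replacement and exclude
    the target itself.
    """
    if N <= 0:
        raise ConfigurationError("N must be positive")
    if K_E < 0 or K_I < 0:
        raise ConfigurationError("in-degrees must be >= 0")
    if n_exc is not None:
        if not (0 <= n_exc <= N):
            raise ConfigurationError("explicit n_exc out of range")
        n_inh = N - n_exc
    elif K_E == 0 and K_I > 0:
        n_exc, n_inh = 0, N
    elif K_I == 0:
        n_exc, n_inh = N, 0
    else:
        if not (0 < gamma <= 1):
            raise ConfigurationError(
                f"gamma must lie in (0, 1], got {gamma}")
        n_exc = int(round(N / (1.0 + gamma)))
        n_inh = N - n_exc
    if K_E > 0 and K_E >= n_exc:
        raise ConfigurationError(
            f"excitatory in-degree {K_E} too large for population {n_exc}")
    if K_I > 0 and K_I >= n_inh:
        raise ConfigurationError(
            f"inhibitory in-degree {K_I} too large for population {n_inh}")

    rng = np.random.default_rng(seed)
    sources_exc = np.empty((N, K_E), dtype=np.int64)
    sources_inh = np.empty((N, K_I), dtype=np.int64)
    exc_pool = np.arange(n_exc)
    inh_pool = np.arange(n_exc, N)
    for i in range(N):
        if K_E:
            pool = exc_pool[exc_pool != i]
            sources_exc[i] = rng.choice(pool, size=K_E, replace=False)
        if K_I:
            pool = inh_pool[inh_pool != i]
            sources_inh[i] = rng.choice(pool, size=K_I, replace=False)
    return NetworkTopology(N=N, n_exc=n_exc, n_inh=n_inh, K_E=K_E, K_I=K_I,
                           sources_exc=sources_exc, sources_inh=sources_inh,
                           seed=seed)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _edge_weights(topology: NetworkTopology, synapse: SynapseSpec,
                  scale: float = 1.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    indptr, tgts = topology.out_csr()
    src_of_edge = np.repeat(np.arange(topology.N),
                            np.diff(indptr))
    w = np.where(src_of_edge < topology.n_exc, synapse.J, synapse.J_inh)
    return indptr, tgts, (w * scale).astype(np.float64)


def _alpha_propagator(neuron: NeuronParams, tau_s: float, dt: float):
    """Exact one-step propagator of (v, y2, y1) and the PSP peak for a
    unit impulse on y1 (used to normalize alpha-synapse weights)."""
    from scipy.linalg import expm

    a = np.array([
        [-1.0 / neuron.tau_m, 1.0 / neuron.tau_m, 0.0],
        [0.0, -1.0 / tau_s, 1.0 / tau_s],
        [0.0, 0.0, -1.0 / tau_s],
    ])
    m = expm(a * dt)
    # PSP peak for y1(0)=1, found by propagating the impulse response on a
    # fine grid with the exact propagator
    dt_fine = 0.01
    m_fine = expm(a * dt_fine)
    x = np.array([0.0, 0.0, 1.0])
    peak = 0.0
    for _ in range(int(10.0 * max(neuron.tau_m, tau_s) / dt_fine)):
        x = m_fine @ x
        if x[0] > peak:
            peak = x[0]
    return m, float(peak)


def _check_grid(delay: float, dt: float) -> int:
    k = delay / dt
    if abs(k - round(k)) > 1e-9:
        raise ConfigurationError(
            f"delay ({delay} ms) must be an integer multiple of dt ({dt} ms)")
    return int(round(k))


def _run(topology: NetworkTopology, neuron: NeuronParams, synapse: SynapseSpec,
         drive: ExternalDrive, duration: float, dt: float, seed: int,
         feedback: bool, presyn: SpikeData | None) -> SpikeData:
    if duration <= 0:
        raise ConfigurationError("duration must be positive")
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    delay_steps = _check_grid(synapse.delay, dt)
    if delay_steps < 1:
        raise ConfigurationError("delay must be at least one time step")
    n_steps = int(round(duration / dt))
    ref_steps = int(round(neuron.tau_ref / dt))
    prop = math.exp(-dt / neuron.tau_m)
    mu_inc = drive.mu_ext * (1.0 - prop)
    noise_std = drive.sigma_ext * math.sqrt(1.0 - prop * prop)

    if feedback:
        ps_steps = np.empty(0, dtype=np.int64)
        ps_ids = np.empty(0, dtype=np.int64)
    else:
        assert presyn is not None
        if presyn.duration + 1e-9 < duration:
            raise InputError(
                f"presynaptic ensemble ({presyn.duration} ms) shorter than "
                f"requested duration ({duration} ms)")
        referenced = np.unique(np.concatenate(
            [topology.sources_exc.ravel(), topology.sources_inh.ravel()]))
        if referenced.size and referenced.max() >= presyn.n_neurons:
            raise InputError(
                "presynaptic ensemble does not cover all source ids "
                f"referenced by the topology (needs id {referenced.max()})")
        ps_steps = np.round(presyn.times / dt).astype(np.int64)
        keep = ps_steps < n_steps
        ps_steps = ps_steps[keep]
        ps_ids = presyn.ids[keep].astype(np.int64)

    # spike capacity: start from a generous rate guess, regrow if needed
    cap = max(1_000_000, int(topology.N * duration / 1000.0 * 60) + 1000)
    hard_cap = int(topology.N * n_steps / max(ref_steps, 1)) + topology.N

    if synapse.kernel == "delta":
        indptr, tgts, w = _edge_weights(topology, synapse)
        args_head = (n_steps, topology.N, prop, mu_inc, noise_std,
                     neuron.V_th, neuron.V_r, ref_steps, delay_steps,
                     indptr, tgts, w, feedback, ps_steps, ps_ids, seed)
        kernel = _kernels.lif_delta_kernel
    else:
        m, peak = _alpha_propagator(neuron, synapse.tau_s, dt)
        indptr, tgts, w = _edge_weights(topology, synapse, scale=1.0 / peak)
        args_head = (n_steps, topology.N,
                     m[0, 0], m[0, 1], m[0, 2], m[1, 1], m[1, 2], m[2, 2],
                     drive.mu_ext, noise_std, neuron.V_th, neuron.V_r,
                     ref_steps, delay_steps, indptr, tgts, w,
                     feedback, ps_steps, ps_ids, seed)
        kernel = _kernels.lif_alpha_kernel

    while True:
        rec_ids = np.empty(cap, dtype=np.int64)
        rec_steps = np.empty(cap, dtype=np.int64)
        n_spk, n_total, nan_step = kernel(*args_head, rec_ids, rec_steps)
        if nan_step >= 0:
            raise NumericalError(
                f"membrane potential became non-finite at step {nan_step} "
                f"(t = {nan_step * dt:.3f} ms)")
        if n_total <= cap:
            break
        cap = min(n_total + topology.N, hard_cap)

    meta = {
        "scenario": "feedback" if feedback else "open_loop",
        "seed": int(seed),
        "dt": dt,
        "topology_seed": int(topology.seed),
        "neuron": vars(neuron).copy(),
        "synapse": {k: v for k, v in vars(synapse).items()},
        "drive": {"mu_ext": drive.mu_ext, "sigma_ext": drive.sigma_ext},
    }
    # kernel emits spikes in time order by construction
    return SpikeData(ids=rec_ids[:n_spk], times=rec_steps[:n_spk] * dt,
                     duration=duration, n_neurons=topology.N,
                     is_inh=topology.is_inh, meta=meta)


def simulate_network(topology: NetworkTopology, neuron: NeuronParams,
                     synapse: SynapseSpec, drive: ExternalDrive,
                     duration: float, dt: float = 0.1,
                     seed: int = 0) -> SpikeData:
    """Simulate the recurrent network with intact feedback."""
    return _run(topology, neuron, synapse, drive, duration, dt, seed,
                feedback=True, presyn=None)


def simulate_open_loop(topology: NetworkTopology, neuron: NeuronParams,
                       synapse: SynapseSpec, drive: ExternalDrive,
                       presyn: SpikeData, duration: float, dt: float = 0.1,
                       seed: int = 0) -> SpikeData:
    """Simulate the population in open loop: local input is read from the
    presynaptic ensemble ``presyn`` instead of the network's own output,
    through the identical connectivity.  ``presyn`` is consumed read-only.
    """
    return _run(topology, neuron, synapse, drive, duration, dt, seed,
                feedback=False, presyn=presyn)
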
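"""Numba time-stepping kernels for the LIF network simulator.

All kernels operate on a fixed time grid of width ``dt``.  Between grid
points the membrane potential follows the exact exponential propagator of
the leaky integrator; the external white-noise drive is added as a
per-step Gaussian increment with variance ``sigma^2 (1 - exp(-2 dt/tau_m))``
so that the free membrane's stationary mean and variance equal
``(mu_ext, sigma_ext^2)`` for any step size.

Spike times are aligned to the grid.  Delayed interactions are handled by
a ring buffer of length ``delay_steps + 1`` holding, per neuron, the summed
synaptic amplitude arriving at each future step.

Closed- and open-loop simulations share a single kernel (``feedback``
flag) so that the order of random-number draws is bit-identical in both
scenarios, which makes the feedback/feedforward parity exact when the
presynaptic ensemble replays the network's own spikes.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def lif_delta_kernel(
    n_steps,
    n_neurons,
    prop,            # exp(-dt/tau_m)
    mu_inc,          # mu_ext * (1 - prop)
    noise_std,       # sigma_ext * sqrt(1 - prop^2)
    v_th,
    v_r,
    ref_steps,
    delay_steps,
    indptr,          # out-adjacency CSR: targets of neuron j
    indices,
    weights,         # synaptic amplitude per out-edge (mV, signed)
    feedback,        # True: own spikes are fed back; False: read presyn
    ps_steps,        # presynaptic spike steps (sorted), open loop only
    ps_ids,
    seed,
    rec_ids,         # output buffers
    rec_steps,
):
    np.random.seed(seed)
    n_slots = delay_steps + 1
    ring = np.zeros((n_slots, n_neurons))
    refr = np.zeros(n_neurons, dtype=np.int64)
    v = np.empty(n_neurons)
    for i in range(n_neurons):
        # stationary-ish start: uniform between reset and threshold
        v[i] = v_r + (v_th - v_r) * np.random.random()
    cap = rec_ids.shape[0]
    n_spk = 0
    n_total = 0
    ps_ptr = 0
    n_ps = ps_steps.shape[0]
    for t in range(n_steps):
        # deliver presynaptic spikes scheduled for arrival at t + delay
        if not feedback:
            while ps_ptr < n_ps and ps_steps[ps_ptr] == t:
                j = ps_ids[ps_ptr]
                slot = (t + delay_steps) % n_slots
                for k in range(indptr[j], indptr[j + 1]):
                    ring[slot, indices[k]] += weights[k]
                ps_ptr += 1
        slot = t % n_slots
        for i in range(n_neurons):
            arr = ring[slot, i]
            ring[slot, i] = 0.0
            # the drive realization is a fixed field: one draw per neuron
            # and step, independent of the dynamical state, so identical
            # seeds give identical drive in feedback and open-loop runs
            xi = noise_std * np.random.standard_normal() if noise_std > 0.0 \
                else 0.0
            if refr[i] > 0:
                refr[i] -= 1
                v[i] = v_r
                continue
            vi = prop * v[i] + mu_inc + arr + xi
            if not np.isfinite(vi):
                return n_spk, n_total, t
            if vi >= v_th:
                n_total += 1
                if n_spk < cap:
                    rec_ids[n_spk] = i
                    rec_steps[n_spk] = t
                    n_spk += 1
                vi = v_r
                refr[i] = ref_steps
                if feedback:
                    dslot = (t + delay_steps) % n_slots
                    for k in range(indptr[i], indptr[i + 1]):
                        ring[dslot, indices[k]] += weights[k]
            v[i] = vi
    return n_spk, n_total, -1


@njit(cache=True)
def lif_alpha_kernel(
    n_steps,
    n_neurons,
    m00, m01, m02,   # first row of the exact 3x3 propagator of (v, y2, y1)
    m11, m12,
    m22,
    mu_eq,           # equilibrium membrane displacement (mu_ext)
    noise_std,
    v_th,
    v_r,
    ref_steps,
    delay_steps,
    indptr,
    indices,
    weights,         # impulse on y1 per out-edge (already PSP-peak normalized)
    feedback,
    ps_steps,
    ps_ids,
    seed,
    rec_ids,
    rec_steps,
):
    np.random.seed(seed)
    n_slots = delay_steps + 1
    ring = np.zeros((n_slots, n_neurons))
    refr = np.zeros(n_neurons, dtype=np.int64)
    v = np.empty(n_neurons)
    y1 = np.zeros(n_neurons)
    y2 = np.zeros(n_neurons)
    for i in range(n_neurons):
        v[i] = v_r + (v_th - v_r) * np.random.random()
    cap = rec_ids.shape[0]
    n_spk = 0
    n_total = 0
    ps_ptr = 0
    n_ps = ps_steps.shape[0]
    for t in range(n_steps):
        if not feedback:
            while ps_ptr < n_ps and ps_steps[ps_ptr] == t:
                j = ps_ids[ps_ptr]
                slot = (t + delay_steps) % n_slots
                for k in range(indptr[j], indptr[j + 1]):
                    ring[slot, indices[k]] += weights[k]
                ps_ptr += 1
        slot = t % n_slots
        for i in range(n_neurons):
            arr = ring[slot, i]
            ring[slot, i] = 0.0
            # synaptic states evolve regardless of refractoriness
            vi = mu_eq + m00 * (v[i] - mu_eq) + m01 * y2[i] + m02 * y1[i]
            y2i = m11 * y2[i] + m12 * y1[i]
            y1i = m22 * y1[i] + arr
            y1[i] = y1i
            y2[i] = y2i
            xi = noise_std * np.random.standard_normal() if noise_std > 0.0 \
                else 0.0
            if refr[i] > 0:
                refr[i] -= 1
                v[i] = v_r
                continue
            vi += xi
            if not np.isfinite(vi):
                return n_spk, n_total, t
            if vi >= v_th:
                n_total += 1
                if n_spk < cap:
                    rec_ids[n_spk] = i
                    rec_steps[n_spk] = t
                    n_spk += 1
                vi = v_r
                refr[i] = ref_steps
                if feedback:
                    dslot = (t + delay_steps) % n_slots
                    for k in range(indptr[i], indptr[i + 1]):
                        ring[dslot, indices[k]] += weights[k]
            v[i] = vi
    return n_spk, n_total, -1
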
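# decorrnet

Decorrelation of recurrent-network activity by inhibitory feedback:
simulation, surrogate analysis and linear theory for spiking
(leaky integrate-and-fire) networks.

## The problem

In a random network of `N` neurons with connection probability `p`, any
two neurons share on average `p²N` presynaptic partners.  Shared input
correlates responses, so pairwise spike-train correlations — and with
them the fluctuations of the population rate — should be substantial.
Measured correlations in recurrent networks are much smaller.  This
package implements the explanation: *negative feedback*.  The compound
activity of an inhibition-dominated network feeds back on itself with
effective weight `-w`; the loop cancels the low-frequency component of
the input fluctuations, suppressing the population-rate spectrum by
`S_fb/S_ff = 1/(|1+wH(ω)|² + w²|H(ω)|²)` relative to an open-loop
network with identical connectivity, rates and shared-input structure.
In excitatory-inhibitory networks a change to sum/difference
coordinates (a Schur decomposition of the coupling matrix
`w[[1, -γg], [1, -γg]]`) exposes the same negative loop: the sum mode
couples to itself with weight `w(1-γg) < 0` when inhibition dominates.

At the pair level the package solves the self-consistent class-averaged
integral covariances of the linearized network,
`(1-W) C (1-W)ᵀ = D·1`, reduced to four unknowns
`(V_E, V_I, c^u_EE, c^u_II)`.  The solution exhibits the
characteristic structure `c̄_EE > c̄_EI > c̄_II` with
`c̄_EI = (c̄_EE + c̄_II)/2`, and shows that the covariance between the
summed inputs of two neurons decomposes into a positive shared-source
term and a spike-correlation term that cancels most of it.

Audience: computational neuroscientists studying correlations,
population dynamics and mean-field/linear-response theory of recurrent
spiking networks.

## Worked example

```python
from decorrnet import (NeuronParams, build_topology, compound_spectrum,
                       homogeneous_poisson_ensemble, lf_power_ratio,
                       make_config, simulate_network, simulate_open_loop)

cfg = make_config("inhibitory", network=dict(N=500, K_I=50))
topo = build_topology(500, 1.0, 0, 50, seed=1)
neuron, syn, drive = NeuronParams(), cfg.synapse_spec(), cfg.external_drive()

fb = simulate_network(topo, neuron, syn, drive, duration=22000.0, seed=2)
nu = fb.crop(2000.0).n_spikes / 20.0 / topo.N
presyn = homogeneous_poisson_ensemble(topo.N, nu, 22000.0, seed=3,
                                      is_inh=topo.is_inh)
ff = simulate_open_loop(topo, neuron, syn, drive, presyn, 22000.0, seed=2)

ratio = lf_power_ratio(compound_spectrum(ff.crop(2000.0)),
                       compound_spectrum(fb.crop(2000.0)), band=(1, 10))
print(f"feedback mean rate: {nu:.2f} spikes/s")
print(f"low-frequency power, feedforward / feedback: {ratio:.0f}")
```

prints

```
feedback mean rate: 17.99 spikes/s
low-frequency power, feedforward / feedback: 747
```

i.e. even this reduced inhibitory network (500 neurons, 20 s) shows a
several-hundred-fold suppression of low-frequency population-rate power by
the intact loop; the full-size default network exceeds three orders of
magnitude.  The scripts in `examples/` walk through each capability
(population-model power ratios, the correlation structure and its
dense-matrix oracle, the LIF-to-linear mapping, feedback manipulations,
readout signal-to-noise).

A thin command-line interface mirrors the library:

```bash
decorrnet simulate --config cfg.yaml --out spikes.dat
decorrnet surrogate --mode shuff1d --in spikes.dat --out surr.dat
decorrnet openloop --config cfg.yaml --presyn surr.dat --out ff.dat
decorrnet analyze --in ff.dat --out stats.json --spectrum spec.csv
decorrnet theory popspec --w 3 --g 7 --out curves.csv
decorrnet run --config cfg.yaml --out bundle/
```

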
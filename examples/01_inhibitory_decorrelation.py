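"""Purely inhibitory network: intact feedback versus Poisson replacement.

Simulates a reduced inhibitory LIF network (N=500, 20 s), replaces the
feedback by independent Poisson trains at the matched mean rate and
compares the low-frequency power of the population rate.  The printed
ratio is the factor by which the recurrent loop suppresses compound
fluctuations below the shared-input-driven feedforward level.
"""

from decorrnet import (NeuronParams, build_topology, compound_spectrum,
                       homogeneous_poisson_ensemble, lf_power_ratio,
                       make_config, simulate_network, simulate_open_loop)

cfg = make_config("inhibitory", network=dict(N=500, K_I=50))
neuron = NeuronParams()
syn, drive = cfg.synapse_spec(), cfg.external_drive()
topo = build_topology(500, 1.0, 0, 50, seed=1)

duration, warmup = 22000.0, 2000.0
fb = simulate_network(topo, neuron, syn, drive, duration, seed=2)
nu = fb.crop(warmup).n_spikes / 20.0 / topo.N
print(f"feedback mean rate: {nu:.2f} spikes/s")

presyn = homogeneous_poisson_ensemble(topo.N, nu, duration, seed=3,
                                      is_inh=topo.is_inh)
ff = simulate_open_loop(topo, neuron, syn, drive, presyn, duration, seed=2)

spec_fb = compound_spectrum(fb.crop(warmup))
spec_ff = compound_spectrum(ff.crop(warmup))
ratio = lf_power_ratio(spec_ff, spec_fb, band=(1.0, 10.0))
print(f"low-frequency power, feedforward / feedback: {ratio:.0f}")
print("-> the intact inhibitory loop suppresses population-rate "
      "fluctuations by this factor relative to independent input with "
      "identical rates and shared-input structure.")
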
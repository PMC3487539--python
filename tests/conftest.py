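"""Shared fixtures.

Small networks for unit tests; two session-scoped "study condition"
pipelines (the purely inhibitory and the excitatory-inhibitory default
networks) that are simulated once and reused by the statistics and
acceptance tests.
"""

import numpy as np
import pytest

from decorrnet import (ExternalDrive, NeuronParams, SpikeData, SynapseSpec,
                       build_topology, compound_spectrum,
                       homogeneous_poisson_ensemble, make_config,
                       shuffle_senders, simulate_network, simulate_open_loop)


@pytest.fixture(scope="session")
def neuron():
    return NeuronParams()


@pytest.fixture(scope="session")
def small_ei_net(neuron):
    """Small E-I network and a short feedback run (for estimator tests)."""
    syn = SynapseSpec(J=0.2, g=8.0, delay=1.0)
    drive = ExternalDrive(mu_ext=28.0, sigma_ext=4.0)
    topo = build_topology(N=500, gamma=0.25, K_E=40, K_I=10, seed=3)
    spikes = simulate_network(topo, neuron, syn, drive, duration=12000.0,
                              dt=0.1, seed=5)
    return dict(topo=topo, synapse=syn, drive=drive, spikes=spikes)


def _two_pop_poisson(topo, nu_e, nu_i, duration, seeds):
    pe = homogeneous_poisson_ensemble(topo.n_exc, nu_e, duration, seeds[0])
    pi = homogeneous_poisson_ensemble(topo.n_inh, nu_i, duration, seeds[1])
    ids = np.concatenate([pe.ids, pi.ids + topo.n_exc])
    times = np.concatenate([pe.times, pi.times])
    order = np.argsort(times, kind="stable")
    return SpikeData(ids[order], times[order], duration, topo.N,
                     topo.is_inh)


@pytest.fixture(scope="session")
def inhibitory_runs(neuron):
    """Purely inhibitory default network: feedback run plus open-loop run
    with homogeneous Poisson replacement at the matched mean rate."""
    cfg = make_config("inhibitory")
    syn = cfg.synapse_spec()
    drive = cfg.external_drive()
    net = cfg.network
    topo = build_topology(net.N, net.gamma, net.K_E, net.K_I, seed=42)
    duration, warmup = 52000.0, 2000.0
    fb = simulate_network(topo, neuron, syn, drive, duration, 0.1, seed=7)
    nu = fb.crop(warmup).n_spikes / ((duration - warmup) / 1000.0) / net.N
    presyn = homogeneous_poisson_ensemble(net.N, nu, duration, seed=8,
                                          is_inh=topo.is_inh)
    ff = simulate_open_loop(topo, neuron, syn, drive, presyn, duration, 0.1,
                            seed=7)
    return dict(topo=topo, synapse=syn, drive=drive, nu=nu, warmup=warmup,
                fb=fb.crop(warmup), ff=ff.crop(warmup),
                spec_fb=compound_spectrum(fb.crop(warmup)),
                spec_ff=compound_spectrum(ff.crop(warmup)))


@pytest.fixture(scope="session")
def ei_runs(neuron):
    """Excitatory-inhibitory default network: feedback run plus open-loop
    runs with Poisson replacement and with sender shuffling across the
    network (Shuff1D) and within populations (Shuff2D)."""
    cfg = make_config("ei")
    syn = cfg.synapse_spec()
    drive = cfg.external_drive()
    net = cfg.network
    topo = build_topology(net.N, net.gamma, net.K_E, net.K_I, seed=42)
    duration, warmup = 52000.0, 2000.0
    fb = simulate_network(topo, neuron, syn, drive, duration, 0.1, seed=7)
    fb_ana = fb.crop(warmup)
    span_s = fb_ana.duration / 1000.0
    nu_e = fb_ana.select("E").n_spikes / span_s / topo.n_exc
    nu_i = fb_ana.select("I").n_spikes / span_s / topo.n_inh
    presyn = _two_pop_poisson(topo, nu_e, nu_i, duration, (8, 9))
    ff = simulate_open_loop(topo, neuron, syn, drive, presyn, duration, 0.1,
                            seed=7)
    sh1 = shuffle_senders(fb, "across_network", seed=10)
    ff_sh1 = simulate_open_loop(topo, neuron, syn, drive, sh1, duration, 0.1,
                                seed=7)
    return dict(topo=topo, synapse=syn, drive=drive, cfg=cfg,
                nu_e=nu_e, nu_i=nu_i, warmup=warmup,
                fb=fb_ana, ff=ff.crop(warmup), ff_shuff1d=ff_sh1.crop(warmup),
                spec_fb=compound_spectrum(fb_ana),
                spec_ff=compound_spectrum(ff.crop(warmup)),
                spec_shuff1d=compound_spectrum(ff_sh1.crop(warmup)))
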
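"""Figure-level experiment orchestration.

``run_experiment`` executes the full feedback/feedforward protocol for a
configured scenario: simulate the recurrent network, construct the
scenario's surrogate presynaptic ensemble from the recorded activity,
run the identical postsynaptic population in open loop (same topology
object, same drive realization), and estimate spectra, the low-frequency
power ratio and the pairwise correlation structure of both responses.

All randomness derives from the single configuration seed through
independent counters (topology, simulation drive, surrogate draws).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import ExperimentConfig, config_hash, save_config
from .errors import ConfigurationError
from .netsim import SpikeData, build_topology, simulate_network, \
    simulate_open_loop
from .spikeio import write_spikes
from .spikestats import (CorrelationEstimates, PowerSpectrum,
                         compound_spectrum, integral_correlations,
                         lf_power_ratio, population_rate)
from .surrogates import (homogeneous_poisson_ensemble,
                         inhomogeneous_poisson_ensemble, profile_from_rate,
                         reassign_types, shuffle_senders)

__all__ = ["ExperimentResult", "run_experiment", "derive_seeds"]


def derive_seeds(master: int, n: int) -> list[int]:
    """Independent 31-bit child seeds from one master seed."""
    state = np.random.SeedSequence(master).generate_state(n, dtype=np.uint64)
    return [int(s & 0x7FFFFFFF) for s in state]


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    feedback: SpikeData
    response: SpikeData | None            # open-loop response (None for FB only)
    presyn: SpikeData | None              # surrogate ensemble fed in open loop
    spectrum_fb: PowerSpectrum
    spectrum_response: PowerSpectrum | None
    lf_ratio: float | None                # response over feedback, LF band
    correlations_fb: CorrelationEstimates
    correlations_response: CorrelationEstimates | None
    rates: dict
    seeds: dict
    runtimes: dict = field(default_factory=dict)

    def save(self, outdir: str | Path) -> None:
        """Write the result bundle: spikes, spectra CSVs, stats JSON and a
        machine-readable manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        save_config(self.config, outdir / "config.yaml")
        write_spikes(self.feedback, outdir / "feedback.dat")
        _spectrum_csv(self.spectrum_fb, outdir / "spectrum_fb.csv")
        if self.response is not None:
            write_spikes(self.response, outdir / "response.dat")
            _spectrum_csv(self.spectrum_response,
                          outdir / "spectrum_response.csv")
        stats = {
            "scenario": self.config.scenario,
            "lf_ratio_response_over_fb": self.lf_ratio,
            "rates": self.rates,
            "correlations_fb": _corr_dict(self.correlations_fb),
            "correlations_response": _corr_dict(self.correlations_response)
            if self.correlations_response else None,
        }
        with open(outdir / "stats.json", "w") as fh:
            json.dump(stats, fh, indent=1)
        manifest = {
            "config_hash": config_hash(self.config),
            "seeds": self.seeds,
            "runtimes_s": self.runtimes,
            "files": sorted(p.name for p in outdir.iterdir()),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)


def _spectrum_csv(spec: PowerSpectrum, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("freq_hz,power\n")
        for f, p in zip(spec.freq, spec.power):
            fh.write(f"{f:.6g},{p:.8g}\n")


def _corr_dict(est: CorrelationEstimates) -> dict:
    return {k: getattr(est, k) for k in
            ("a_E", "a_I", "c_EE", "c_EI", "c_II",
             "rho_EE", "rho_EI", "rho_II")} | {"se": est.se}


def _two_pop_poisson(n_exc, n_inh, nu_e, nu_i, duration, seeds, is_inh):
    """Independent homogeneous Poisson ensemble with per-population rates."""
    pe = homogeneous_poisson_ensemble(n_exc, nu_e, duration, seeds[0]) \
        if n_exc else None
    pi = homogeneous_poisson_ensemble(n_inh, nu_i, duration, seeds[1]) \
        if n_inh else None
    ids = np.concatenate([
        pe.ids if pe is not None else np.empty(0, np.int64),
        (pi.ids + n_exc) if pi is not None else np.empty(0, np.int64)])
    times = np.concatenate([
        pe.times if pe is not None else np.empty(0),
        pi.times if pi is not None else np.empty(0)])
    order = np.argsort(times, kind="stable")
    return SpikeData(ids[order], times[order], duration, n_exc + n_inh,
                     is_inh, {"scenario": "poissH"})


def _build_surrogate(scenario, fb, config, topo, seeds):
    """Surrogate presynaptic ensemble for the open-loop run; returns the
    ensemble and (possibly rebuilt) topology for the response population."""
    warm = config.simulation.warmup
    analysis_fb = fb.crop(warm)
    mode = scenario.split(":", 1)[1]
    if mode == "poissH":
        rates = {}
        for tag, n in (("E", topo.n_exc), ("I", topo.n_inh)):
            if n:
                rates[tag] = analysis_fb.select(tag).n_spikes \
                    / (analysis_fb.duration / 1000.0) / n
        presyn = _two_pop_poisson(topo.n_exc, topo.n_inh,
                                  rates.get("E", 0.0), rates.get("I", 0.0),
                                  fb.duration, seeds, topo.is_inh)
        return presyn, topo
    if mode == "poissI":
        bin_ms = min(config.analysis.bin, 1.0)
        parts = []
        for tag, n, off in (("E", topo.n_exc, 0),
                            ("I", topo.n_inh, topo.n_exc)):
            if not n:
                continue
            prof = profile_from_rate(population_rate(fb, bin_ms, tag))
            ens = inhomogeneous_poisson_ensemble(n, prof, seeds[off > 0])
            parts.append((ens, off))
        ids = np.concatenate([e.ids + off for e, off in parts])
        times = np.concatenate([e.times for e, _ in parts])
        order = np.argsort(times, kind="stable")
        presyn = SpikeData(ids[order], times[order], fb.duration,
                           topo.N, topo.is_inh, {"scenario": "poissI"})
        return presyn, topo
    if mode == "shuff1d":
        return shuffle_senders(fb, "across_network", seeds[0]), topo
    if mode == "shuff2d":
        return shuffle_senders(fb, "within_population", seeds[0]), topo
    if mode == "retype":
        frac = topo.n_inh / topo.N
        retyped = reassign_types(fb, frac, seeds[0])
        # sort trains so the new E labels occupy the leading id block,
        # then rewire a fresh topology consistent with the new labels
        order = np.argsort(retyped.is_inh, kind="stable")
        rank = np.empty_like(order)
        rank[order] = np.arange(topo.N)
        n_exc_new = int((~retyped.is_inh).sum())
        presyn = SpikeData(rank[retyped.ids], retyped.times.copy(),
                           fb.duration, topo.N,
                           np.arange(topo.N) >= n_exc_new,
                           dict(retyped.meta))
        topo_new = build_topology(topo.N, topo.gamma, topo.K_E, topo.K_I,
                                  seed=seeds[1], n_exc=n_exc_new)
        return presyn, topo_new
    raise ConfigurationError(f"unknown scenario {scenario!r}")


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Execute the configured scenario end to end."""
    seeds = derive_seeds(config.seed, 6)
    seed_map = {"topology": seeds[0], "drive": seeds[1],
                "surrogate": (seeds[2], seeds[3]),
                "response_topology": seeds[4]}
    net = config.network
    topo_seed = net.topology_seed if net.topology_seed is not None \
        else seeds[0]
    topo = build_topology(net.N, net.gamma, net.K_E, net.K_I, seed=topo_seed)
    neuron = config.neuron_params()
    synapse = config.synapse_spec()
    drive = config.external_drive()
    sim = config.simulation
    ana = config.analysis

    runtimes = {}
    t0 = time.perf_counter()
    fb = simulate_network(topo, neuron, synapse, drive, sim.duration,
                          sim.dt, seed=seeds[1])
    runtimes["feedback_s"] = time.perf_counter() - t0

    fb_ana = fb.crop(sim.warmup)
    spec_fb = compound_spectrum(fb_ana, ana.bin, ana.frame)
    corr_fb = integral_correlations(fb_ana, ana.window, ana.n_pairs,
                                    seed=seeds[5])
    rates = {"fb_" + tag: fb_ana.select(tag).n_spikes
             / (fb_ana.duration / 1000.0) / n
             for tag, n in (("E", topo.n_exc), ("I", topo.n_inh)) if n}

    if config.scenario == "feedback":
        return ExperimentResult(
            config=config, feedback=fb, response=None, presyn=None,
            spectrum_fb=spec_fb, spectrum_response=None, lf_ratio=None,
            correlations_fb=corr_fb, correlations_response=None,
            rates=rates, seeds=seed_map, runtimes=runtimes)

    presyn, resp_topo = _build_surrogate(
        config.scenario, fb, config, topo,
        (seeds[2], seeds[3] if config.scenario != "openloop:retype"
         else seeds[4]))
    t0 = time.perf_counter()
    resp = simulate_open_loop(resp_topo, neuron, synapse, drive, presyn,
                              sim.duration, sim.dt, seed=seeds[1])
    runtimes["open_loop_s"] = time.perf_counter() - t0
    resp_ana = resp.crop(sim.warmup)
    spec_resp = compound_spectrum(resp_ana, ana.bin, ana.frame)
    corr_resp = integral_correlations(resp_ana, ana.window, ana.n_pairs,
                                      seed=seeds[5])
    ratio = lf_power_ratio(spec_resp, spec_fb, band=ana.band)
    for tag, n in (("E", resp_topo.n_exc), ("I", resp_topo.n_inh)):
        if n:
            rates["response_" + tag] = resp_ana.select(tag).n_spikes \
                / (resp_ana.duration / 1000.0) / n
    return ExperimentResult(
        config=config, feedback=fb, response=resp, presyn=presyn,
        spectrum_fb=spec_fb, spectrum_response=spec_resp, lf_ratio=ratio,
        correlations_fb=corr_fb, correlations_response=corr_resp,
        rates=rates, seeds=seed_map, runtimes=runtimes)
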
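"""Perturbing the feedback statistics of a small E-I network.

Runs the feedback network once, then feeds surrogate versions of its
activity (within- and across-population sender shuffles) to an identical
open-loop population and prints the change in low-frequency power.
"""

from decorrnet import ExperimentConfig, run_experiment

base = dict(
    network=dict(N=500, gamma=0.25, K_E=40, K_I=10),
    synapse=dict(J=0.4, g=8.0, delay=1.0),
    drive=dict(mu_ext=28.0, sigma_ext=4.0),
    simulation=dict(duration=22000.0, warmup=2000.0, dt=0.1),
    analysis=dict(window=100.0, n_pairs=None),
)

for scenario in ("openloop:shuff2d", "openloop:shuff1d", "openloop:poissH"):
    cfg = ExperimentConfig(scenario=scenario, seed=5, **base)
    res = run_experiment(cfg)
    print(f"{scenario:18s}: LF power (response/feedback) = "
          f"{res.lf_ratio:6.2f}")
print("-> shuffling within populations preserves the decorrelation; "
      "mixing the populations or discarding the temporal structure "
      "amplifies low-frequency fluctuations.")
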
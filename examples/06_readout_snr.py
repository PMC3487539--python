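"""Readout signal-to-noise versus population size.

A linear readout of n spike trains saturates at snr = 1/kappa when the
trains share a coherence kappa; only uncorrelated ensembles allow the
readout precision to grow without bound.
"""

from decorrnet import ReadoutStats, readout_snr

print("   n     kappa=0   kappa=0.01   kappa=0.1")
for n in (10, 100, 1000, 10000):
    row = [readout_snr(ReadoutStats(n, k, m1=1.0, m2=1.0))
           for k in (0.0, 0.01, 0.1)]
    print(f"{n:6d}   {row[0]:7.1f}   {row[1]:9.1f}   {row[2]:8.2f}")
print("-> with kappa = 0.1 the squared signal-to-noise ratio saturates "
      "near 10 no matter how many trains are read out.")
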
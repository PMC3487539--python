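"""Self-consistent correlation structure of the linear E-I network.

Solves the class-averaged covariance system over a range of effective
couplings and prints the characteristic ordering rho_EE > rho_EI >
rho_II together with the input-correlation decomposition (shared-input
versus spike-correlation contribution).
"""

from decorrnet import (CovarianceParams, fullmatrix_oracle,
                       input_correlation_theory, solve_covariances)

print("  w     rho_EE    rho_EI    rho_II    q_in   cancellation")
for w in (0.3, 0.6, 0.9, 1.2):
    params = CovarianceParams(N_E=300, N_I=75, p=0.1, w=w, g=6.0)
    sol = solve_covariances(params)
    dec = input_correlation_theory(params, sol)
    print(f"{w:5.2f}  {sol.rho_EE:+.5f}  {sol.rho_EI:+.5f}  "
          f"{sol.rho_II:+.5f}  {dec.q_in:+.4f}  {dec.cancellation_factor:.3f}")

print("\ndense-matrix ground truth at w = 0.9 (one realization):")
o = fullmatrix_oracle(300, 75, 0.1, 0.9 / 30, 6.0, 1.0, seed=0)
print(f"      rho_EE {o.rho_EE:+.5f}  rho_EI {o.rho_EI:+.5f}  "
      f"rho_II {o.rho_II:+.5f}")
print("-> q_in stays well below the connection probability p = 0.1: "
      "shared-input correlations are canceled by the correlation "
      "structure the feedback creates.")
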
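# Methods

`decorrnet` studies how recurrent inhibition actively decorrelates the
activity of finite spiking networks: pairs of neurons share a sizable
fraction of their presynaptic input (on average `K²/N` common sources in
a random network with in-degree `K`), yet the correlations observed in
the recurrent network are far smaller than this shared input would
produce in a feedforward setting.  The package implements (i) a spiking
LIF network simulator with intact and opened feedback loops, (ii)
surrogate generators that perturb the feedback statistics, (iii)
estimators for population-rate spectra and integral pairwise
correlations, and (iv) the linear self-consistent theory that explains
the effect.

## Spiking model and simulator

Leaky integrate-and-fire neurons with membrane time constant `tau_m`,
threshold `V_th`, reset `V_r` and absolute refractory period `tau_ref`
(defaults 20 ms, 20 mV, 0 mV, 2 ms).  Synapses are current based:
delta-shaped (instantaneous) postsynaptic currents that deflect the
membrane by the PSP amplitude `J` (excitatory) or `-gJ` (inhibitory) at
spike arrival, or alpha-shaped currents whose weight is normalized so
that the PSP *peak* equals the configured amplitude (this keeps delta
and alpha runs comparable).  External drive is an independent Gaussian
white-noise current per neuron, parameterized by the stationary mean
`mu_ext` and standard deviation `sigma_ext` of the free membrane
potential.

Integration is grid based (`dt = 0.1 ms` by default) with the exact
exponential propagator of the leaky integrator between grid points; the
noise is added as a per-step Gaussian increment with variance
`sigma_ext² (1 - e^{-2dt/tau_m})`, so the free-membrane statistics are
exact for any step size.  Spike times are aligned to the grid; delays
must be grid multiples.  The noise field is drawn per neuron and step
independently of the dynamical state, so a feedback run and an open-loop
run with the same seed receive the *identical* drive realization — the
feedforward protocol of the study ("same noise, same connectivity, only
the presynaptic ensemble replaced").  Inputs arriving during the
refractory period are discarded; for alpha synapses the synaptic state
keeps integrating while the membrane is clamped.

Known numerical limitations: discrete threshold sampling biases the rate
of a noise-driven neuron downward by a few percent at `dt = 0.1 ms`
(single-neuron oracle tests therefore use `dt = 0.01 ms`); halving `dt`
changes network rates by well under 2 %.

Topologies have fixed in-degrees (`K_E` excitatory, `K_I` inhibitory
sources per neuron, drawn without replacement, no autapses or
multapses).  The expected shared input of a target pair is `K²/N` per
source population.

## Feedback manipulations (surrogates)

Open-loop runs feed a surrogate ensemble through the *same* topology
object with the same drive realization:

* `poissH` — independent stationary Poisson trains at the measured
  per-population mean rates (discards all temporal and correlation
  structure);
* `poissI` — inhomogeneous Poisson trains following the measured
  population-rate profiles (keeps the rate waveform, adds realization
  noise; sampling by thinning against the profile maximum);
* `shuff1d` / `shuff2d` — permutation of whole-train sender identities
  across the network resp. within each population (spike times
  untouched; per-spike reassignment available behind a flag);
* `retype` — random reassignment of the E/I label of each train
  (homogenizes the correlation structure across the EE/EI/II classes);
  the open-loop population is rewired against the new labels.

## Estimators

"Variance" and "covariance" refer throughout to the *integral* of the
auto-/cross-correlation function (equal to the zero-frequency spectral
density).  They are estimated from spike counts in disjoint windows
(default 100 ms) as count (co)variance divided by the window length —
equivalent to lag integration of correlograms in the long-window limit
but with far lower variance.  Class averages (EE/EI/II) use either a
fixed number of sampled pairs (default 2000) or, via an exact
aggregation identity over population count sums, *all* pairs; standard
errors are delete-one-window jackknives.  Correlation coefficients are
normalized by the geometric mean of the class auto-variances.

The compound power spectrum is the periodogram of the binned
(default 0.5 ms), mean-subtracted population-averaged rate, normalized
as a two-sided spectral density and smoothed by a centered moving
average (default 1 Hz).  Under this normalization `N` independent
Poisson trains at rate `nu` give a flat spectrum at `nu/N`; simulated
spectra indeed converge to this floor at high frequencies.  (Quoting
the floor as `nu` instead corresponds to multiplying by the population
size — a plotting-scale choice; this package fixes `nu/N`.)  The
low-frequency power ratio averages the density over 1–10 Hz (DC
excluded).

The readout signal-to-noise ratio of a linear readout of `n`
homogeneous trains with coherence `kappa`, first filter moment `m1` and
second moment `m2` is `snr = n m1² / ((1-kappa) m2 + kappa n m1²)`
(unit signal power, unit single-train noise density): it grows linearly
in `n` for `kappa = 0` and saturates at `1/kappa` otherwise.

## Linear theory

Linearizing the network dynamics around the stationary working point
gives `y = h * (W y + x)` with a normalized response kernel
(`H(0) = 1`; a 1st-order low-pass with optional delay ships as default,
any `H(ω)` callable is accepted — all zero-frequency results are
kernel independent) and effective connectivity `W` (entries `u` per
excitatory, `-gu` per inhibitory synapse).

**Population model.**  Averaging over populations yields the
one-population model with negative feedback `w` (power ratio
`S_fb/S_ff = 1/(|1+wH|² + w²|H|²)`, independent of the noise amplitude
and spectrum shape, decaying as `w⁻²`) and the two-population model
with coupling matrix `w [[1, -γg], [1, -γg]]` (`γ = N_I/N_E`).  The
orthogonal sum/difference coordinates triangularize this matrix (a
Schur decomposition): the sum mode feeds back on itself with weight
`w(1-γg)` — negative in inhibition-dominated networks — and receives
the difference mode with weight `w(1+γg)`; the lower-left entry is
exactly zero.  Opening only the sum-mode self-feedback loop reduces the
sum-mode power ratio to the one-population expression with
`Λ = w(γg-1)`.  Noise convention: `D` is the spectral density of the
population-averaged drive of the excitatory population; identical
neurons imply `D/γ` for the inhibitory average, which produces the
nonzero noise cross-correlation between the Schur modes.  Consequences
of this convention: at `w = 0`, `S_I = (D/γ)|H|²` (equal to `S_E` only
for `γ = 1`), and the `g → ∞` fallback of the compound spectrum to the
unconnected level is exact for `γ = 1` (for `γ ≠ 1` the limit carries a
factor `1/γ`).

**Self-consistent covariances.**  At zero frequency the exact
covariance matrix obeys `(1-W) C (1-W)ᵀ = D·1`.  Averaging the
element-wise form over statistically equivalent pairs — connected pairs
separately from unconnected ones, because a connection `j → i`
contributes the projecting neuron's variance — closes the system in
four unknowns `(V_E, V_I, c^u_EE, c^u_II)`:

* connected-pair excess: `c^{conn}(src → tgt) = c^u + u_src V_src`,
  plus a reciprocal-connection correction `p·u_tgt V_tgt` (a fraction
  `p` of connected pairs is connected both ways);
* all-pair average: `c̄ = c^u + p u_b V_b + p u_a V_a`, from which the
  identity `c̄_EI = (c̄_EE + c̄_II)/2` follows exactly;
* pair counting uses the integer in-degrees of a sampled network, exact
  distinct-pair counts, and a walk correction for source pairs sharing
  their target (each carries one guaranteed out-edge onto the shared
  target, elevating their covariance by
  `p u_tgt W_tot G/(1-W_tot)`-type terms).

An `asymptotic` mode replaces these finite-size counts by their
infinite-network limits (`K = pN`, counts `K_a K_b`, no reciprocal
terms); in that limit the compound-power ratio assembled from the
covariance solution coincides with the two-population model's ratio to
machine precision — the two derivations describe the same system.  At
finite `N` they differ at order `1/N`.

Accuracy against the dense-matrix oracle (explicit `(1-W)^{-1}`): the
closure neglects conditional correlations of relative order `p`.  At
`p = 0.1`, `N = 375`, variances agree to well under 1 % and class
covariances to a few percent (up to ~5 SE of a 20-seed Monte-Carlo
mean, whose resolution is extremely fine because class averages
self-average); at `p = 0.05` all five class covariances agree within
3 Monte-Carlo SE.  The explicit closed-form route imposes `V_E = V_I`
(deviations from the full solution stay below ~8 % of the covariance
scale on the stable grid); the purely inhibitory case follows from the
same machinery with one population and is strictly negative for any
`w > 0`.

Feedforward variants reuse the feedback solution as input statistics of
an unconnected response population: `drop_EI` zeroes the E-I source
covariances (block-diagonal input correlation matrix), `homogenize`
replaces all pairwise source covariances by the grand population mean.
The input-correlation decomposition splits the covariance of two
neurons' summed inputs into the shared-source term
(`Σ (K²/N) u² V`, always positive under Dale's law) and the
spike-correlation term (distinct source pairs weighted by `c̄`); their
ratio to the input variance gives `q_in`, which equals the connection
probability for uncorrelated sources and falls well below it in the
recurrent network — the cancellation that defines decorrelation here.

**LIF mapping.**  The stationary rate is the Siegert formula, evaluated
with the integrand in scaled-complementary-error-function form
(`erfcx`), adaptive quadrature at 1e-12 absolute tolerance, and an
overflow guard deep below threshold.  The working point is the damped
fixed point of the rate (damping 0.5, halved adaptively when the
update oscillates — strong inhibition makes the plain iteration ring —
tolerance 1e-8 spikes/s).  The per-synapse DC susceptibility
`w_unit(J) = tau_m J ∂nu/∂mu + tau_m J² ∂nu/∂sigma²` includes the
variance-modulation term (quadratic in `J`, switchable off to recover
the linear-only approximation).  Conventions: the simulator's
`sigma_ext` is a membrane standard deviation, the theory's `sigma` a
diffusion amplitude with `Var(V) = sigma²/2`; the mapping multiplies
external variances by 2.  The spec-level balance `g_eff` includes the
in-degree ratio; the rate-model/covariance `g` is per synapse
(`g = g_eff/γ`).

Stability: the effective dynamics is unstable once an eigenvalue of
`W` exceeds one in real part.  The bulk obeys the circular law with
radius `sqrt(p(1-p)(N_E u² + N_I g²u²))`; the rank-one mean mode sits at
`w(1-γg)`.  Sampled-matrix eigenvalues overshoot the circular-law
support by a few percent at `N = 1000` (finite-size edge fluctuation).

## Default study conditions

Chosen once via the package's own theory so the two networks sit where
the reference figures put them, then frozen:

* **Inhibitory network** — `N = 1000`, `K = 100` (`p = 0.1`), PSP
  `-1.5 mV`, delay 1 ms, drive `mu_ext = 45 mV`, `sigma_ext = 2.5 mV`;
  mean rate ≈ 10 spikes/s.  The measured low-frequency
  feedforward/feedback power ratio exceeds 10³ (the diffusion-level DC
  susceptibility underestimates the empirical feedback strength of the
  delta-synapse network, whose instantaneous response to input spikes
  adds to the suppression).
* **E-I network** — `N = 4000` (`N_E = 3200`, `N_I = 800`, `γ = 0.25`),
  `K_E = 320`, `K_I = 80` (`p = 0.1`), `J = 0.2 mV`, `g = 8`, delay
  1 ms, drive `mu_ext = 28 mV`, `sigma_ext = 4 mV`; rates ≈ 11.5
  spikes/s (self-consistent prediction within 5 %), effective coupling
  `w ≈ 2.2`, per-synapse balance ≈ 7.2 (inhibition dominated,
  `Λ ≈ 1.8`), circular-law radius ≈ 0.43 (stable).  Poisson
  replacement raises the low-frequency power by a factor ≈ 15,
  across-network sender shuffling by ≈ 12, within-population shuffling
  by ≈ 1.05.
* Standard analysis: 52 s simulated per run with the first 2 s
  discarded, 0.5 ms spectral bins, 1 Hz smoothing frame, 1–10 Hz
  low-frequency band, 100 ms count windows.  The `1/sqrt(N)`
  weight-scaling study uses per-synapse weight `0.75/sqrt(N)` with
  `g = 6`, a mid-suppression regime in which the all-pair covariance
  decays with log-log slope ≈ −1/2 over `N = 200…1600` (the
  strong-coupling asymptote of this scaling is slope −1).

The synthetic networks are homogeneous: one neuron model, two weight
values, fixed in-degrees, stationary white-noise drive.  Passing tests
therefore validate the mechanism — not heterogeneity of real cortical
tissue (distributed rates, conductance synapses, structured
connectivity, correlated external input), for which the homogeneity
assumptions behind `c̄_EI = (c̄_EE + c̄_II)/2` and equal E/I rates need
not hold.

## Reproducibility

Every experiment derives all randomness (topology, drive, surrogates)
from one integer seed through independent counters; result bundles
embed the configuration hash.  Identical seeds give bit-identical
spikes, spectra and statistics.
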
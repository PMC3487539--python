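"""Mapping between the spiking LIF model and the linear rate theory.

In the diffusion approximation the total synaptic input to a LIF neuron is
replaced by Gaussian white noise with mean ``mu`` and variance ``sigma^2``
(both expressed as free-membrane statistics, in mV resp. mV^2):

    mu      = mu_ext  + tau_m * (K_E J - K_I g J) * nu
    sigma^2 = sigma_ext^2 + tau_m * (K_E J^2 + K_I g^2 J^2) * nu

The stationary rate is the Siegert formula

    1/nu = tau_ref + tau_m sqrt(pi) * Int_{y_r}^{y_th} erfcx(-u) du ,

with ``y_x = (V_x - mu)/sigma``.  The recurrent working point is the fixed
point of this relation.  The integrated linear response of the rate to a
unit perturbation of one afferent's rate (the DC susceptibility) follows
by differentiating the Siegert formula; a synaptic impulse of PSP
amplitude ``J`` perturbs the mean linearly in ``J`` and the variance
quadratically in ``J``, so

    w_unit(J) = tau_m J dnu/dmu + tau_m J^2 dnu/dsigma^2 .

The effective coupling of the two-population rate model is the in-degree
times the per-synapse susceptibility, ``w = K_E w_unit(J)``, with
effective balance ``g_eff = K_I |w_unit(-gJ)| / w``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.special import erfcx

from .errors import ConfigurationError, ConvergenceError, InputError
from .netsim import ExternalDrive, NeuronParams, SynapseSpec

__all__ = [
    "WorkingPoint",
    "Susceptibility",
    "EffectiveCoupling",
    "StabilityReport",
    "siegert_rate",
    "selfconsistent_working_point",
    "dc_susceptibility",
    "effective_coupling",
    "stability_check",
]

_SQRT_PI = math.sqrt(math.pi)
# erfcx(-u) ~ 2 exp(u^2) for large u; keep exp(u^2) finite
_Y_OVERFLOW = 26.0


@dataclass(frozen=True)
class WorkingPoint:
    """Stationary operating point of a neuron: input mean/std and rate."""

    mu: float          # mV
    sigma: float       # mV
    nu: float          # spikes/s


@dataclass(frozen=True)
class Susceptibility:
    """Integrated linear response per synapse (dimensionless).

    ``w = linear + quadratic``: the mean-modulation term is linear in the
    PSP amplitude J, the variance-modulation term quadratic in J.
    """

    w: float
    linear: float
    quadratic: float


@dataclass(frozen=True)
class EffectiveCoupling:
    """Effective parameters (w, g_eff) of the two-population rate model.

    For a purely inhibitory network (K_E = 0), ``w`` holds the scalar
    inhibitory feedback strength ``w_I = K_I |w_unit(-gJ)|`` and
    ``g_eff`` is infinite.
    """

    w: float
    g_eff: float
    w_unit_exc: float
    w_unit_inh: float

    @property
    def pure_inhibitory(self) -> bool:
        return math.isinf(self.g_eff)

    def balance_per_synapse(self, gamma: float) -> float:
        """Per-synapse balance ratio ``|w_unit_inh| / w_unit_exc``.

        ``g_eff`` includes the in-degree ratio ``K_I/K_E = gamma``; the
        two-population rate model and the covariance theory parameterize
        inhibition by the per-synapse ratio, so their ``g`` equals
        ``g_eff / gamma``.
        """
        return self.g_eff / gamma


@dataclass(frozen=True)
class StabilityReport:
    spectral_radius: float     # estimate for the effective connectivity bulk
    circular_radius: float     # circular-law radius sqrt(sum of weight variances)
    mean_mode: float           # outlier eigenvalue w(1 - gamma g)
    stable: bool


def _siegert_bounds(mu: float, sigma: float, neuron: NeuronParams):
    y_r = (neuron.V_r - mu) / sigma
    y_th = (neuron.V_th - mu) / sigma
    return y_r, y_th


def siegert_rate(mu: float, sigma: float, neuron: NeuronParams) -> float:
    """Stationary firing rate (spikes/s) of a white-noise-driven LIF neuron.

    Evaluated with the integrand written in scaled-complementary-error-
    function form, which is finite for all arguments below the deep
    subthreshold overflow bound (there the rate is indistinguishable
    from zero).
    """
    if sigma <= 0:
        raise InputError("siegert_rate requires sigma > 0; the deterministic "
                         "limit has a closed form (see netsim tests)")
    y_r, y_th = _siegert_bounds(mu, sigma, neuron)
    if y_th >= _Y_OVERFLOW:
        return 0.0
    integral, _ = quad(lambda u: erfcx(-u), y_r, y_th, epsabs=1e-12,
                       epsrel=1e-10, limit=200)
    tau_m_s = neuron.tau_m / 1000.0
    tau_ref_s = neuron.tau_ref / 1000.0
    inv = tau_ref_s + tau_m_s * _SQRT_PI * integral
    return 1.0 / inv


def _siegert_derivatives(mu: float, sigma: float,
                         neuron: NeuronParams) -> tuple[float, float, float]:
    """(nu, dnu/dmu, dnu/dsigma^2) at the given input statistics."""
    nu = siegert_rate(mu, sigma, neuron)
    if nu == 0.0:
        return 0.0, 0.0, 0.0
    y_r, y_th = _siegert_bounds(mu, sigma, neuron)
    f_th = erfcx(-y_th)
    f_r = erfcx(-y_r)
    tau_m_s = neuron.tau_m / 1000.0
    nu_sq = nu * nu * tau_m_s * _SQRT_PI
    dnu_dmu = nu_sq * (f_th - f_r) / sigma
    dnu_dsigma = nu_sq * (y_th * f_th - y_r * f_r) / sigma
    dnu_dsigma2 = dnu_dsigma / (2.0 * sigma)
    return nu, dnu_dmu, dnu_dsigma2


def selfconsistent_working_point(topology_summary: tuple[int, int],
                                 synapse: SynapseSpec, drive: ExternalDrive,
                                 neuron: NeuronParams,
                                 damping: float = 0.5,
                                 tol: float = 1e-8,
                                 max_iter: int = 1000) -> WorkingPoint:
    """Fixed point of the Siegert rate under recurrent input.

    ``topology_summary`` is the pair of in-degrees ``(K_E, K_I)``.
    Damped fixed-point iteration on the rate; converged when the rate
    update falls below ``tol`` (spikes/s).
    """
    K_E, K_I = topology_summary
    J, g = synapse.J, synapse.g
    tau_m_s = neuron.tau_m / 1000.0
    drift = tau_m_s * (K_E * J - K_I * g * J)
    diffusion = tau_m_s * (K_E * J * J + K_I * g * g * J * J)
    # drive.sigma_ext is the stationary membrane std of the free membrane;
    # the diffusion amplitude sigma (Var(V) = sigma^2/2) is sqrt(2) larger
    sig_ext2 = 2.0 * drive.sigma_ext ** 2

    nu = siegert_rate(drive.mu_ext, max(math.sqrt(sig_ext2), 1e-6), neuron)
    trace = [nu]
    prev_step = 0.0
    for _ in range(max_iter):
        mu = drive.mu_ext + drift * nu
        sigma = math.sqrt(sig_ext2 + diffusion * nu)
        nu_new = siegert_rate(mu, max(sigma, 1e-6), neuron)
        step = damping * (nu_new - nu)
        # strong negative feedback makes the plain iteration oscillate;
        # halve the damping whenever the update direction flips
        if step * prev_step < 0.0:
            damping *= 0.5
            step = damping * (nu_new - nu)
        prev_step = step
        nu_next = nu + step
        trace.append(nu_next)
        if abs(nu_next - nu) < tol:
            mu = drive.mu_ext + drift * nu_next
            sigma = math.sqrt(sig_ext2 + diffusion * nu_next)
            return WorkingPoint(mu=mu, sigma=sigma, nu=nu_next)
        nu = nu_next
    raise ConvergenceError(
        f"working-point iteration did not converge in {max_iter} steps",
        trace=trace)


def dc_susceptibility(J: float, wp: WorkingPoint, neuron: NeuronParams,
                      include_variance_term: bool = True) -> Susceptibility:
    """Integrated rate response to one synaptic impulse of PSP amplitude J.

    The impulse shifts the input mean by ``tau_m J`` per unit afferent
    rate and the input variance by ``tau_m J^2``; the first gives the
    linear-in-J component, the second the quadratic one (an asymmetry
    between excitation and inhibition of equal magnitude).  Setting
    ``include_variance_term=False`` recovers the purely linear
    approximation.
    """
    if wp.nu <= 0:
        raise InputError("working point has zero rate; susceptibility "
                         "is degenerate")
    _, dnu_dmu, dnu_dsigma2 = _siegert_derivatives(wp.mu, wp.sigma, neuron)
    tau_m_s = neuron.tau_m / 1000.0
    linear = tau_m_s * J * dnu_dmu
    quadratic = tau_m_s * J * J * dnu_dsigma2 if include_variance_term else 0.0
    return Susceptibility(w=linear + quadratic, linear=linear,
                          quadratic=quadratic)


def effective_coupling(topology_summary: tuple[int, int],
                       synapse: SynapseSpec, wp: WorkingPoint,
                       neuron: NeuronParams,
                       include_variance_term: bool = True) -> EffectiveCoupling:
    """Effective two-population coupling (w, g_eff) at the working point."""
    K_E, K_I = topology_summary
    w_unit_inh = dc_susceptibility(-synapse.g * synapse.J, wp, neuron,
                                   include_variance_term).w if K_I else 0.0
    if K_E == 0:
        return EffectiveCoupling(w=K_I * abs(w_unit_inh), g_eff=math.inf,
                                 w_unit_exc=0.0, w_unit_inh=w_unit_inh)
    w_unit_exc = dc_susceptibility(synapse.J, wp, neuron,
                                   include_variance_term).w
    if synapse.J > 0 and w_unit_exc <= 0:
        raise ConfigurationError(
            "excitatory per-synapse response is non-positive at this "
            "working point; the linear mapping is invalid")
    w = K_E * w_unit_exc
    g_eff = (K_I * abs(w_unit_inh) / w) if K_I else 0.0
    return EffectiveCoupling(w=w, g_eff=g_eff, w_unit_exc=w_unit_exc,
                             w_unit_inh=w_unit_inh)


def stability_check(params, N: int | None = None) -> StabilityReport:
    """Stability of the linearized dynamics.

    Accepts a :class:`~decorrnet.lintheory_corr.CovarianceParams` (full
    information: circular-law bulk radius and mean-mode outlier) or a
    :class:`~decorrnet.lintheory_pop.TwoPopModel` (mean mode only; the
    bulk radius requires the connection probability).  The dynamics is
    unstable as soon as an eigenvalue of the effective connectivity
    exceeds one in real part.
    """
    # duck-typed to avoid circular imports
    if hasattr(params, "p"):  # CovarianceParams
        K_E = params.p * params.N_E
        u = params.w / K_E if K_E else 0.0
        u_i = params.g * u
        p = params.p
        var_sum = p * (1 - p) * (params.N_E * u * u + params.N_I * u_i * u_i)
        radius = math.sqrt(var_sum)
        mean_mode = params.w * (1.0 - params.g * params.gamma)
    else:  # TwoPopModel-like: fields w, g, gamma
        radius = float("nan")
        mean_mode = params.w * (1.0 - params.g * params.gamma)
    spectral = max(radius, mean_mode) if not math.isnan(radius) else mean_mode
    stable = mean_mode < 1.0 and (math.isnan(radius) or radius < 1.0)
    return StabilityReport(spectral_radius=spectral, circular_radius=radius,
                           mean_mode=mean_mode, stable=stable)


def sampled_spectral_radius(params, seed: int = 0) -> float:
    """Spectral radius (max real part excluded mean mode) of an explicitly
    sampled effective connectivity matrix; cross-check for the
    circular-law estimate.  Dense eigensolve, use N <= 2000."""
    from .lintheory_corr import sample_connectivity

    w_mat = sample_connectivity(params, seed)
    eig = np.linalg.eigvals(w_mat)
    # exclude the mean-mode outlier: it sits on the real axis near w(1-g gamma)
    mean_mode = params.w * (1.0 - params.g * params.gamma)
    dist = np.abs(eig - mean_mode)
    bulk = np.delete(eig, np.argmin(dist))
    return float(np.max(np.abs(bulk)))
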
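"""Linear one- and two-population rate models of recurrent networks.

The population-averaged activity of a homogeneous random network is
modeled as a linear system ``y = h * (M y + x)`` with a normalized
response kernel ``h`` (``H(0) = 1``), an effective coupling matrix ``M``
and white external noise ``x``.

One population (inhibitory network): ``M = -w`` with ``w >= 0``; the
feedback spectrum is ``S_fb = D |H|^2 / |1 + wH|^2``.  Replacing the
feedback by input of identical auto-statistics but uncorrelated to the
drive gives ``S_ff = |H|^2 (D + w^2 S_fb)`` and the power ratio

    S_fb / S_ff = 1 / (|1 + wH|^2 + w^2 |H|^2),

independent of the noise amplitude and of the noise spectrum's shape.

Two populations (excitatory-inhibitory): both populations receive the
same mixture of local input, so ``M = w [[1, -gamma g], [1, -gamma g]]``
with effective weight ``w``, balance ``g`` and size ratio
``gamma = N_I/N_E``.  An orthogonal change of coordinates to the sum and
difference modes (a Schur decomposition) triangularizes ``M``: the sum
mode couples to itself with weight ``w(1 - gamma g)`` — negative in
inhibition-dominated networks — and receives feedforward input from the
difference mode with weight ``w(1 + gamma g)``; all other connections
vanish.

Noise convention: ``D`` is the spectral density of the population-
averaged external noise of the *excitatory* population; with identical
neurons the inhibitory population average carries ``D/gamma``.  All
power ratios are independent of ``D``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import ConfigurationError, StabilityError

__all__ = [
    "LinearKernel",
    "OnePopModel",
    "TwoPopModel",
    "SchurSystem",
    "transfer_function",
    "onepop_spectra",
    "schur_transform",
    "twopop_spectra",
    "twopop_power_ratios",
]


@dataclass(frozen=True)
class LinearKernel:
    """Normalized 1st-order low-pass response kernel with delay.

    ``H(f) = exp(-2 pi i f d) / (1 + 2 pi i f tau)``; ``H(0) = 1``.
    A custom frequency response can be supplied via ``custom`` (any
    callable ``f -> complex``); the low-frequency results of the theory
    are independent of the kernel shape.
    """

    tau: float = 10.0          # ms
    delay: float = 0.0         # ms
    custom: Callable | None = None

    def __post_init__(self):
        if self.custom is None and self.tau < 0:
            raise ConfigurationError("kernel time constant must be >= 0")
        if self.delay < 0:
            raise ConfigurationError("kernel delay must be >= 0")

    def __call__(self, freq) -> np.ndarray:
        """Complex gain at frequency ``freq`` (Hz; scalar or array)."""
        f = np.asarray(freq, dtype=float)
        if self.custom is not None:
            h = np.asarray(self.custom(f), dtype=complex)
        else:
            # tau, delay in ms -> convert to s
            h = np.exp(-2j * np.pi * f * self.delay * 1e-3) \
                / (1.0 + 2j * np.pi * f * self.tau * 1e-3)
        # exact analytic branch at zero frequency
        h = np.where(f == 0.0, 1.0 + 0.0j, h)
        return h if h.ndim else complex(h)

    @property
    def cutoff_hz(self) -> float:
        return 1.0 / (2.0 * math.pi * self.tau * 1e-3)


def transfer_function(kernel: LinearKernel, freq) -> np.ndarray:
    """Fourier transform of the response kernel at ``freq`` (Hz)."""
    return kernel(freq)


@dataclass(frozen=True)
class OnePopModel:
    """One-population linear model with negative feedback of strength w."""

    w: float
    D: float = 1.0
    kernel: LinearKernel = LinearKernel()

    def __post_init__(self):
        if self.w < 0:
            raise ConfigurationError("w is the magnitude of the negative "
                                     "feedback and must be >= 0")
        if self.D <= 0:
            raise ConfigurationError("noise variance D must be > 0")


@dataclass(frozen=True)
class TwoPopModel:
    """Two-population (E-I) linear model.

    w     : effective coupling (in-degree times per-synapse DC response)
    g     : effective balance parameter (inhibition/excitation ratio)
    gamma : inhibitory to excitatory population-size ratio
    D     : noise variance of the population-averaged drive to E
    """

    w: float
    g: float
    gamma: float = 0.25
    D: float = 1.0
    kernel: LinearKernel = LinearKernel()

    def __post_init__(self):
        if self.w < 0 or self.g < 0:
            raise ConfigurationError("w and g must be >= 0")
        if self.gamma <= 0:
            raise ConfigurationError("gamma must be > 0")
        if self.D <= 0:
            raise ConfigurationError("noise variance D must be > 0")


@dataclass(frozen=True)
class SchurSystem:
    """Triangular (Schur) representation of the E-I population dynamics.

    Coordinates: sum mode ``(y_E + y_I)/sqrt(2)``, difference mode
    ``(y_E - y_I)/sqrt(2)``.
    """

    sum_self: float        # w (1 - gamma g); negative iff inhibition dominated
    diff_to_sum: float     # w (1 + gamma g); feedforward weight
    lower_left: float      # exactly 0
    noise_sum: float       # <|xi_s|^2> = (D_E + D_I)/2
    noise_diff: float      # <|xi_d|^2> = (D_E + D_I)/2
    noise_cross: float     # <xi_s xi_d*> = (D_E - D_I)/2

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.sum_self, self.diff_to_sum],
                         [self.lower_left, 0.0]])


def _require_stable(model: TwoPopModel):
    if model.w * (1.0 - model.gamma * model.g) >= 1.0:
        raise StabilityError(
            f"two-population model unstable: mean-mode eigenvalue "
            f"{model.w * (1 - model.gamma * model.g):.3f} >= 1")


def onepop_spectra(model: OnePopModel, freq):
    """(S_fb, S_ff, ratio) of the one-population model at ``freq`` (Hz).

    ``S_fb`` is the response spectrum with intact negative feedback;
    ``S_ff`` with the feedback replaced by input of identical
    auto-statistics but uncorrelated to the external drive.
    """
    h = model.kernel(freq)
    habs2 = np.abs(h) ** 2
    denom = np.abs(1.0 + model.w * h) ** 2
    s_fb = model.D * habs2 / denom
    s_ff = habs2 * (model.D + model.w ** 2 * s_fb)
    ratio = 1.0 / (denom + model.w ** 2 * habs2)
    return s_fb, s_ff, ratio


def schur_transform(model: TwoPopModel) -> SchurSystem:
    """Schur (sum/difference) representation of the E-I dynamics.

    Preserves trace, determinant and eigenvalues of the effective
    coupling matrix ``M = w [[1, -gamma g], [1, -gamma g]]``.
    """
    gg = model.gamma * model.g
    d_e = model.D
    d_i = model.D / model.gamma
    return SchurSystem(
        sum_self=model.w * (1.0 - gg),
        diff_to_sum=model.w * (1.0 + gg),
        lower_left=0.0,
        noise_sum=0.5 * (d_e + d_i),
        noise_diff=0.5 * (d_e + d_i),
        noise_cross=0.5 * (d_e - d_i),
    )


def _responses(model: TwoPopModel, freq):
    """Helper: kernel gain and the closed-loop gain G = wH/(1 - wH(1-gg))."""
    h = np.asarray(model.kernel(freq), dtype=complex)
    gg = model.gamma * model.g
    g_cl = model.w * h / (1.0 - model.w * h * (1.0 - gg))
    return h, g_cl, gg


def twopop_spectra(model: TwoPopModel, freq):
    """(S_E, S_I, S_sum, S_compound) of the E-I model at ``freq`` (Hz).

    S_E, S_I : spectra of the population-averaged rates,
    S_sum    : spectrum of the sum mode (y_E + y_I)/sqrt(2),
    S_compound : spectrum of the compound rate (N_E y_E + N_I y_I)/N.
    """
    _require_stable(model)
    h, g_cl, gg = _responses(model, freq)
    habs2 = np.abs(h) ** 2
    d_e = model.D
    d_i = model.D / model.gamma
    gamma = model.gamma
    g = model.g

    s_e = habs2 * (np.abs(1.0 + g_cl) ** 2 * d_e
                   + (gamma * g) ** 2 * np.abs(g_cl) ** 2 * d_i)
    s_i = habs2 * (np.abs(g_cl) ** 2 * d_e
                   + np.abs(1.0 - gamma * g * g_cl) ** 2 * d_i)
    s_sum = 0.5 * habs2 * (np.abs(1.0 + 2.0 * g_cl) ** 2 * d_e
                           + np.abs(1.0 - 2.0 * gamma * g * g_cl) ** 2 * d_i)
    c_e = (1.0 + (1.0 + gamma) * g_cl) / (1.0 + gamma)
    c_i = (gamma - (1.0 + gamma) * gamma * g * g_cl) / (1.0 + gamma)
    s_comp = habs2 * (np.abs(c_e) ** 2 * d_e + np.abs(c_i) ** 2 * d_i)
    return s_e, s_i, s_sum, s_comp


def twopop_power_ratios(model: TwoPopModel, variant: str, freq):
    """Feedback/feedforward power ratio of the E-I model.

    variant 'both_replaced' : excitatory and inhibitory feedback channels
        replaced by uncorrelated inputs with the matched auto-statistics;
        returns the compound-rate power ratio.
    variant 'sum_feedback_replaced' : only the sum-mode self-feedback loop
        is opened; returns the sum-mode power ratio, which reduces to the
        one-population expression with effective feedback
        ``Lambda = w (gamma g - 1)``.
    """
    _require_stable(model)
    h = np.asarray(model.kernel(freq), dtype=complex)
    habs2 = np.abs(h) ** 2
    if variant == "both_replaced":
        s_e, s_i, _, s_comp = twopop_spectra(model, freq)
        d_e = model.D
        d_i = model.D / model.gamma
        gamma, g, w = model.gamma, model.g, model.w
        noise_comp = (d_e + gamma ** 2 * d_i) / (1.0 + gamma) ** 2
        s_comp_ff = habs2 * (noise_comp
                             + w ** 2 * s_e + (gamma * g * w) ** 2 * s_i)
        return s_comp / s_comp_ff
    if variant == "sum_feedback_replaced":
        lam = model.w * (model.gamma * model.g - 1.0)
        return 1.0 / (np.abs(1.0 + lam * h) ** 2 + lam ** 2 * habs2)
    raise ConfigurationError(f"unknown variant {variant!r}")
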
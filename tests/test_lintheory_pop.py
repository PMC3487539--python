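"""One- and two-population linear rate models: transfer functions,
feedback/feedforward spectra, Schur decomposition and power ratios."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from decorrnet import (LinearKernel, OnePopModel, StabilityError, TwoPopModel,
                       onepop_spectra, schur_transform, transfer_function,
                       twopop_power_ratios, twopop_spectra)


# ------------------------------------------------------------- transfer

def test_transfer_function_is_unity_at_zero_frequency():
    k = LinearKernel(tau=10.0)
    assert transfer_function(k, 0.0) == 1.0 + 0.0j


def test_transfer_function_cutoff_gain():
    k = LinearKernel(tau=10.0)
    h = transfer_function(k, k.cutoff_hz)
    assert abs(h) == pytest.approx(1.0 / np.sqrt(2.0), rel=1e-12)


def test_delay_adds_pure_phase():
    freq = 7.0
    k0 = LinearKernel(tau=10.0, delay=0.0)
    kd = LinearKernel(tau=10.0, delay=3.0)
    h0, hd = transfer_function(k0, freq), transfer_function(kd, freq)
    assert abs(hd) == pytest.approx(abs(h0), rel=1e-12)
    dphi = np.angle(hd) - np.angle(h0)
    assert (dphi + 2 * np.pi * freq * 3e-3) % (2 * np.pi) \
        == pytest.approx(0.0, abs=1e-10)


def test_custom_kernel_callable_is_used():
    k = LinearKernel(custom=lambda f: np.exp(-f))
    assert transfer_function(k, 1.0) == pytest.approx(np.exp(-1.0))
    assert transfer_function(k, 0.0) == 1.0 + 0.0j


# -------------------------------------------------------- one population

def test_onepop_ratio_is_one_without_feedback():
    model = OnePopModel(w=0.0, D=2.0)
    f = np.linspace(0.0, 200.0, 50)
    s_fb, s_ff, ratio = onepop_spectra(model, f)
    np.testing.assert_allclose(ratio, 1.0)
    np.testing.assert_allclose(s_fb, s_ff)


def test_onepop_ratio_approaches_unity_at_high_frequency():
    model = OnePopModel(w=20.0, D=1.0)
    _, _, ratio = onepop_spectra(model, 1e6)
    assert ratio == pytest.approx(1.0, abs=1e-5)


def test_onepop_ratio_independent_of_noise_amplitude():
    f = np.linspace(0.0, 100.0, 20)
    r1 = onepop_spectra(OnePopModel(w=5.0, D=1.0), f)[2]
    r2 = onepop_spectra(OnePopModel(w=5.0, D=37.0), f)[2]
    np.testing.assert_allclose(r1, r2, rtol=1e-14)


def _simulate_linear_onepop(w, n_steps, dt, tau, seed):
    """Exponential-Euler simulation of the one-population model; returns
    the response and the same-statistics uncorrelated replay (from an
    independent run) for the feedforward variant."""
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(1.0 / dt)           # unit spectral density
    a = np.exp(-dt / tau)
    x = sigma * rng.standard_normal(n_steps)
    x2 = sigma * rng.standard_normal(n_steps)
    y = np.zeros(n_steps)
    q = np.zeros(n_steps)               # independent feedback-run replay
    for t in range(1, n_steps):
        y[t] = a * y[t - 1] + (1 - a) * (x[t - 1] - w * y[t - 1])
        q[t] = a * q[t - 1] + (1 - a) * (x2[t - 1] - w * q[t - 1])
    y_ff = np.zeros(n_steps)
    for t in range(1, n_steps):
        y_ff[t] = a * y_ff[t - 1] + (1 - a) * (x[t - 1] - w * q[t - 1])
    return y, y_ff


def _lf_density(x, dt):
    x = x - x.mean()
    n = x.size
    p = (dt / n) * np.abs(np.fft.rfft(x)) ** 2
    f = np.fft.rfftfreq(n, d=dt)
    band = (f > 0) & (f < 0.2 / (2 * np.pi * 10.0))   # well below cutoff
    return p[band].mean()


@pytest.mark.parametrize("w", [1.0, 4.0, 10.0])
def test_onepop_zero_frequency_ratio_matches_simulation(w):
    """Monte-Carlo oracle: time-stepped linear system with intact and
    opened feedback; compare the low-frequency power ratio with the
    closed-form expression."""
    tau = 10.0
    y, y_ff = _simulate_linear_onepop(w, 400000, 1.0, tau, seed=1)
    sim_ratio = _lf_density(y, 1.0) / _lf_density(y_ff, 1.0)
    expected = 1.0 / ((1.0 + w) ** 2 + w ** 2)
    assert sim_ratio == pytest.approx(expected, rel=0.25)


# ------------------------------------------------------------------ Schur

def test_schur_lower_left_is_exactly_zero():
    s = schur_transform(TwoPopModel(w=3.0, g=6.0, gamma=0.25))
    assert s.lower_left == 0.0


def test_schur_balanced_point_has_zero_self_feedback():
    s = schur_transform(TwoPopModel(w=3.0, g=4.0, gamma=0.25))
    assert s.sum_self == pytest.approx(0.0, abs=1e-14)


@given(w=st.floats(0.01, 20.0), g=st.floats(0.0, 12.0),
       gamma=st.floats(0.05, 1.0))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_schur_preserves_eigenvalues_trace_det(w, g, gamma):
    model = TwoPopModel(w=w, g=g, gamma=gamma)
    m = w * np.array([[1.0, -gamma * g], [1.0, -gamma * g]])
    s = schur_transform(model)
    eig_orig = np.sort_complex(np.linalg.eigvals(m))
    eig_schur = np.sort_complex(np.linalg.eigvals(s.matrix))
    np.testing.assert_allclose(eig_schur, eig_orig, atol=1e-10 * (1 + w))
    assert np.trace(s.matrix) == pytest.approx(np.trace(m), rel=1e-12)


# ------------------------------------------------------- two populations

def test_twopop_unconnected_spectra():
    f = np.linspace(0.0, 50.0, 11)
    model = TwoPopModel(w=0.0, g=0.0, gamma=1.0, D=2.0)
    s_e, s_i, _, _ = twopop_spectra(model, f)
    habs2 = np.abs(model.kernel(f)) ** 2
    np.testing.assert_allclose(s_e, 2.0 * habs2, rtol=1e-12)
    np.testing.assert_allclose(s_i, 2.0 * habs2, rtol=1e-12)


def test_twopop_large_g_approaches_unconnected_compound_spectrum():
    """For growing inhibition at fixed coupling the compound spectrum
    falls back to the unconnected level (exact for equal population
    sizes, where both populations carry equal average noise)."""
    f = 0.0
    s_unc = twopop_spectra(TwoPopModel(w=0.0, g=0.0, gamma=1.0), f)[3]
    vals = [float(twopop_spectra(TwoPopModel(w=2.0, g=g, gamma=1.0), f)[3])
            for g in (2.0, 20.0, 20000.0)]
    assert abs(vals[2] - s_unc) < abs(vals[1] - s_unc) < abs(vals[0] - s_unc)
    assert vals[2] == pytest.approx(float(np.real(s_unc)), rel=1e-3)


def test_twopop_excitatory_to_inhibitory_ratio_saturates():
    """For strong coupling S_E/S_I approaches a constant independent
    of w."""
    ratios = []
    for w in (50.0, 200.0, 800.0):
        s_e, s_i, _, _ = twopop_spectra(
            TwoPopModel(w=w, g=8.0, gamma=0.25), 0.0)
        ratios.append(s_e / s_i)
    assert ratios[1] == pytest.approx(ratios[2], rel=0.02)


def test_twopop_unstable_model_rejected():
    model = TwoPopModel(w=3.0, g=1.0, gamma=0.25)   # gamma g < 1, w > 1
    with pytest.raises(StabilityError):
        twopop_spectra(model, 0.0)
    with pytest.raises(StabilityError):
        twopop_power_ratios(model, "both_replaced", 0.0)


def test_sum_mode_spectrum_schur_vs_direct_coordinates():
    """S_sum computed from the Schur-coordinate solution equals the
    direct population-coordinate computation to machine precision."""
    model = TwoPopModel(w=3.0, g=7.0, gamma=0.25, D=1.3)
    f = np.linspace(0.0, 80.0, 41)
    h = model.kernel(f)
    s = schur_transform(model)
    lam = -s.sum_self
    # Schur route: s = h (F d + xi_s) / (1 + lam h), d = h xi_d
    num = (s.diff_to_sum ** 2 * np.abs(h) ** 2 * s.noise_diff
           + s.noise_sum
           + 2.0 * np.real(s.diff_to_sum * h * s.noise_cross))
    s_sum_schur = np.abs(h) ** 2 * num / np.abs(1.0 + lam * h) ** 2
    s_sum_direct = twopop_spectra(model, f)[2]
    np.testing.assert_allclose(s_sum_schur, s_sum_direct, rtol=1e-12)


def test_power_ratios_trivial_and_monotone_in_g():
    f = 0.0
    assert twopop_power_ratios(TwoPopModel(w=0.0, g=0.0, gamma=0.25),
                               "both_replaced", f) == pytest.approx(1.0)
    assert twopop_power_ratios(TwoPopModel(w=0.0, g=0.0, gamma=0.25),
                               "sum_feedback_replaced", f) \
        == pytest.approx(1.0)
    ratios = [float(twopop_power_ratios(
        TwoPopModel(w=8.0, g=g, gamma=0.25), "both_replaced", f))
        for g in (5.0, 6.0, 8.0, 12.0)]
    assert all(a > b for a, b in zip(ratios, ratios[1:]))


def test_power_ratios_independent_of_noise_amplitude():
    f = np.array([0.0, 3.0, 11.0])
    for variant in ("both_replaced", "sum_feedback_replaced"):
        r1 = twopop_power_ratios(TwoPopModel(w=4.0, g=7.0, gamma=0.25,
                                             D=1.0), variant, f)
        r2 = twopop_power_ratios(TwoPopModel(w=4.0, g=7.0, gamma=0.25,
                                             D=55.0), variant, f)
        np.testing.assert_allclose(r1, r2, rtol=1e-13)


def test_strong_coupling_ratio_decays_as_w_squared():
    """Log-log slope of the zero-frequency power ratios versus w
    approaches -2 for strong coupling."""
    ws = np.array([100.0, 400.0])
    for variant in ("both_replaced", "sum_feedback_replaced"):
        r = np.array([float(twopop_power_ratios(
            TwoPopModel(w=w, g=8.0, gamma=0.25), variant, 0.0))
            for w in ws])
        slope = np.log(r[1] / r[0]) / np.log(ws[1] / ws[0])
        assert slope == pytest.approx(-2.0, abs=0.05)
    r1 = [1.0 / ((1 + w) ** 2 + w ** 2) for w in ws]
    slope1 = np.log(r1[1] / r1[0]) / np.log(ws[1] / ws[0])
    assert slope1 == pytest.approx(-2.0, abs=0.05)


def _simulate_linear_twopop(model, n_steps, dt, seed):
    """Exponential-Euler oracle for the 2-D system and its two open-loop
    variants (matched auto-statistics replay from independent runs)."""
    rng = np.random.default_rng(seed)
    tau = model.kernel.tau
    a = np.exp(-dt / tau)
    gg = model.gamma * model.g
    d_e, d_i = model.D, model.D / model.gamma
    se, si = np.sqrt(d_e / dt), np.sqrt(d_i / dt)

    def run(xe, xi):
        ye = np.zeros(n_steps)
        yi = np.zeros(n_steps)
        for t in range(1, n_steps):
            loc = model.w * (ye[t - 1] - gg * yi[t - 1])
            ye[t] = a * ye[t - 1] + (1 - a) * (loc + xe[t - 1])
            yi[t] = a * yi[t - 1] + (1 - a) * (loc + xi[t - 1])
        return ye, yi

    xe = se * rng.standard_normal(n_steps)
    xi = si * rng.standard_normal(n_steps)
    ye, yi = run(xe, xi)
    # two independent replicas: the excitatory and inhibitory feedback
    # channels are replaced by mutually uncorrelated replays with the
    # matched auto-statistics
    ye2, _ = run(se * rng.standard_normal(n_steps),
                 si * rng.standard_normal(n_steps))
    _, yi3 = run(se * rng.standard_normal(n_steps),
                 si * rng.standard_normal(n_steps))
    ye_ff = np.zeros(n_steps)
    yi_ff = np.zeros(n_steps)
    for t in range(1, n_steps):
        loc = model.w * (ye2[t - 1] - gg * yi3[t - 1])
        ye_ff[t] = a * ye_ff[t - 1] + (1 - a) * (loc + xe[t - 1])
        yi_ff[t] = a * yi_ff[t - 1] + (1 - a) * (loc + xi[t - 1])
    gamma = model.gamma
    comp = (ye + gamma * yi) / (1 + gamma)
    comp_ff = (ye_ff + gamma * yi_ff) / (1 + gamma)
    return comp, comp_ff


def test_twopop_both_replaced_ratio_matches_simulation():
    model = TwoPopModel(w=4.0, g=8.0, gamma=0.25, D=1.0)
    comp, comp_ff = _simulate_linear_twopop(model, 400000, 1.0, seed=3)
    sim = _lf_density(comp, 1.0) / _lf_density(comp_ff, 1.0)
    expected = float(twopop_power_ratios(model, "both_replaced", 0.0))
    assert sim == pytest.approx(expected, rel=0.3)
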
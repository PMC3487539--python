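"""Self-consistent covariance theory versus the dense-matrix oracle,
closed-form approximations, feedforward variants and compound power."""

import math

import numpy as np
import pytest

from decorrnet import (CovarianceParams, StabilityError, TwoPopModel,
                       closed_form_covariances, compound_power,
                       ff_covariances, fullmatrix_oracle,
                       input_correlation_theory, solve_covariances,
                       twopop_power_ratios, twopop_spectra)

EI_PARAMS = CovarianceParams(N_E=300, N_I=75, p=0.1, w=0.9, g=6.0, D=1.0)


def test_unconnected_network_has_diagonal_covariance():
    params = CovarianceParams(N_E=200, N_I=50, p=0.1, w=0.0, g=0.0, D=2.5)
    sol = solve_covariances(params)
    assert sol.V_E == pytest.approx(2.5)
    assert sol.V_I == pytest.approx(2.5)
    for v in sol.c_bar.values():
        assert v == pytest.approx(0.0, abs=1e-14)


def test_mixed_covariance_is_arithmetic_mean_to_machine_precision():
    sol = solve_covariances(EI_PARAMS)
    assert sol.cEI_bar == pytest.approx(
        0.5 * (sol.cEE_bar + sol.cII_bar), abs=1e-15)
    cf = closed_form_covariances(EI_PARAMS)
    assert cf.cEI_bar == pytest.approx(
        0.5 * (cf.cEE_bar + cf.cII_bar), abs=1e-15)


def test_linearity_in_noise_amplitude():
    base = solve_covariances(EI_PARAMS)
    double = solve_covariances(CovarianceParams(
        N_E=300, N_I=75, p=0.1, w=0.9, g=6.0, D=2.0))
    for key in base.c_bar:
        assert double.c_bar[key] == pytest.approx(2.0 * base.c_bar[key],
                                                  rel=1e-12)
    for key in base.rho:
        assert double.rho[key] == pytest.approx(base.rho[key], rel=1e-12)


def test_unstable_parameters_rejected():
    with pytest.raises(StabilityError):
        solve_covariances(CovarianceParams(N_E=300, N_I=75, p=0.1,
                                           w=4.0, g=6.0))


def test_solver_matches_fullmatrix_oracle_within_monte_carlo_error():
    """Class-averaged covariances of the self-consistent system agree
    with dense-matrix ground truth over topology realizations."""
    sol = solve_covariances(EI_PARAMS)
    u = EI_PARAMS.w / round(EI_PARAMS.p * EI_PARAMS.N_E)
    vals = {k: [] for k in ("V_E", "V_I", "EE", "EI", "II")}
    for s in range(10):
        o = fullmatrix_oracle(300, 75, 0.1, u, EI_PARAMS.g, 1.0, seed=s)
        vals["V_E"].append(o.V_E)
        vals["V_I"].append(o.V_I)
        vals["EE"].append(o.cEE_bar)
        vals["EI"].append(o.cEI_bar)
        vals["II"].append(o.cII_bar)
    for key, th in (("V_E", sol.V_E), ("V_I", sol.V_I),
                    ("EE", sol.cEE_bar), ("EI", sol.cEI_bar),
                    ("II", sol.cII_bar)):
        arr = np.array(vals[key])
        se = arr.std(ddof=1) / math.sqrt(arr.size)
        assert abs(th - arr.mean()) < max(5 * se, 0.05 * abs(arr.mean()))


def test_connected_minus_unconnected_is_projecting_variance(
):
    """Oracle check of the connected-pair excess: for a directed
    connection the covariance exceeds the unconnected value by the
    projecting neuron's variance times its synaptic weight (plus the
    reciprocal-connection contribution p u V of the target class)."""
    u = 1.2 / 30
    vals = []
    for s in range(8):
        o = fullmatrix_oracle(300, 75, 0.1, u, 6.0, 1.0, seed=s)
        p = 0.1
        pred = {
            ("E", "E"): u * o.V_E + p * u * o.V_E,
            ("E", "I"): u * o.V_E + p * (-6.0 * u) * o.V_I,
            ("I", "E"): -6.0 * u * o.V_I + p * u * o.V_E,
            ("I", "I"): -6.0 * u * o.V_I + p * (-6.0 * u) * o.V_I,
        }
        for (src, tgt), expect in pred.items():
            pair = (min(src, tgt), max(src, tgt))
            vals.append((o.c_conn[(src, tgt)] - o.c_u[pair]) / expect)
    arr = np.array(vals)
    assert abs(arr.mean() - 1.0) < 0.15


def test_closed_form_close_to_full_solution_where_variances_match():
    """The explicit V_E = V_I approximation deviates little from the
    full solution on the stable grid; the deviation is recorded."""
    worst = 0.0
    for w in (0.4, 0.8, 1.2):
        for g in (5.0, 6.0, 8.0):
            params = CovarianceParams(N_E=300, N_I=75, p=0.1, w=w, g=g)
            full = solve_covariances(params)
            cf = closed_form_covariances(params)
            assert cf.V_E == cf.V_I
            scale = abs(full.cEE_bar) + abs(full.cII_bar)
            for key in full.c_bar:
                worst = max(worst,
                            abs(cf.c_bar[key] - full.c_bar[key]) / scale)
    assert worst < 0.08


def test_pure_inhibitory_covariance_is_negative():
    for w in (0.5, 1.0, 2.0):
        params = CovarianceParams(N_E=0, N_I=400, p=0.1, w=w, g=1.0)
        cf = closed_form_covariances(params)
        assert cf.c_bar[("I", "I")] < 0.0
        full = solve_covariances(params)
        assert full.c_bar[("I", "I")] < 0.0
    zero = solve_covariances(CovarianceParams(N_E=0, N_I=400, p=0.1,
                                              w=0.0, g=1.0))
    assert zero.c_bar[("I", "I")] == pytest.approx(0.0, abs=1e-14)


def test_pure_inhibitory_matches_oracle():
    params = CovarianceParams(N_E=0, N_I=400, p=0.1, w=1.5, g=1.0)
    sol = solve_covariances(params)
    u = -params.w / 40
    vals_v, vals_c = [], []
    for s in range(8):
        o = fullmatrix_oracle(0, 400, 0.1, u, 0.0, 1.0, seed=s)
        vals_v.append(o.V["I"])
        vals_c.append(o.c_bar[("I", "I")])
    for arr, th in ((np.array(vals_v), sol.V["I"]),
                    (np.array(vals_c), sol.c_bar[("I", "I")])):
        se = arr.std(ddof=1) / math.sqrt(arr.size)
        assert abs(th - arr.mean()) < max(4 * se, 0.1 * abs(arr.mean()))


# ------------------------------------------------------ feedforward variants

def test_ff_variants_coincide_without_feedback_covariances():
    params = CovarianceParams(N_E=300, N_I=75, p=0.1, w=0.0, g=6.0)
    fb = solve_covariances(params)
    a = ff_covariances(params, "drop_EI", feedback=fb)
    b = ff_covariances(params, "homogenize", feedback=fb)
    for key in a.c_bar:
        assert a.c_bar[key] == pytest.approx(b.c_bar[key], abs=1e-14)


def test_homogenized_correlations_amplify_response():
    """Replacing the correlation structure by its (positive) population
    mean removes the cancellation: response correlations exceed the
    feedback-case correlations."""
    params = EI_PARAMS
    fb = solve_covariances(params)
    hom = ff_covariances(params, "homogenize", feedback=fb)
    assert hom.rho[("E", "E")] > fb.rho[("E", "E")]
    assert hom.c_bar[("E", "E")] > fb.c_bar[("E", "E")]


def test_drop_ei_ratio_equals_population_model_at_zero_frequency():
    """The compound-power ratio assembled from the covariance theory is
    identical to the two-population model's both-replaced ratio in the
    infinite-network limit."""
    for (w, g) in ((0.8, 6.0), (2.0, 6.0), (4.0, 8.0)):
        params = CovarianceParams(N_E=10 ** 10, N_I=int(2.5e9), p=0.1,
                                  w=w, g=g)
        sol = solve_covariances(params, asymptotic=True)
        ratio = compound_power(params, sol, "feedback") \
            / compound_power(params, sol, "drop_EI")
        pop = float(twopop_power_ratios(TwoPopModel(w=w, g=g, gamma=0.25),
                                        "both_replaced", 0.0))
        assert abs(ratio - pop) < 1e-10


def _zero_freq_spectra(n_e, n_i, v_e, v_i, c_ee, c_ei, c_ii):
    """Population-averaged zero-frequency spectra assembled from class
    covariances."""
    s_e = v_e / n_e + (1 - 1 / n_e) * c_ee
    s_i = v_i / n_i + (1 - 1 / n_i) * c_ii
    n = n_e + n_i
    s_c = (n_e * v_e + n_i * v_i + n_e * (n_e - 1) * c_ee
           + n_i * (n_i - 1) * c_ii + 2 * n_e * n_i * c_ei) / n ** 2
    return s_e, s_i, s_c


def test_population_spectra_match_matrix_oracle_at_zero_frequency():
    """Zero-frequency population-averaged spectra from the
    self-consistent class solution agree with the dense-matrix oracle
    within 2% for N = 400 (the mostly-inhibitory-noise S_I within 5%)."""
    w, g = 1.0, 6.0
    n_e, n_i = 320, 80
    params = CovarianceParams(N_E=n_e, N_I=n_i, p=0.1, w=w, g=g, D=1.0)
    sol = solve_covariances(params)
    th = _zero_freq_spectra(n_e, n_i, sol.V_E, sol.V_I, sol.cEE_bar,
                            sol.cEI_bar, sol.cII_bar)
    acc = []
    for s in range(12):
        o = fullmatrix_oracle(n_e, n_i, 0.1, w / 32, g, 1.0, seed=s)
        acc.append(_zero_freq_spectra(n_e, n_i, o.V_E, o.V_I, o.cEE_bar,
                                      o.cEI_bar, o.cII_bar))
    mean = np.array(acc).mean(axis=0)
    assert th[0] == pytest.approx(mean[0], rel=0.02)
    assert th[1] == pytest.approx(mean[1], rel=0.05)
    assert th[2] == pytest.approx(mean[2], rel=0.02)


def test_population_model_is_large_n_limit_of_class_solution():
    """The two-population rate-model spectra are the infinite-network
    limit of the class-solution spectra."""
    w, g, gamma = 1.5, 6.0, 0.25
    n_e = 10 ** 8
    n_i = int(gamma * n_e)
    params = CovarianceParams(N_E=n_e, N_I=n_i, p=0.1, w=w, g=g, D=1.0)
    sol = solve_covariances(params, asymptotic=True)
    s_e, s_i, s_c = _zero_freq_spectra(n_e, n_i, sol.V_E, sol.V_I,
                                       sol.cEE_bar, sol.cEI_bar,
                                       sol.cII_bar)
    model = TwoPopModel(w=w, g=g, gamma=gamma, D=1.0 / n_e)
    s_e_th, s_i_th, _, s_c_th = twopop_spectra(model, 0.0)
    assert s_e == pytest.approx(float(np.real(s_e_th)), rel=1e-6)
    assert s_i == pytest.approx(float(np.real(s_i_th)), rel=1e-6)
    assert s_c == pytest.approx(float(np.real(s_c_th)), rel=1e-6)


# ----------------------------------------------------- input decomposition

def test_input_correlation_equals_connectivity_without_correlations():
    params = CovarianceParams(N_E=320, N_I=80, p=0.1, w=1.0, g=6.0)
    sol = solve_covariances(params)
    # open-loop: zero source cross-covariances
    from decorrnet import CovarianceSolution
    zero = CovarianceSolution(
        V=dict(sol.V), c_u={k: 0.0 for k in sol.c_u},
        c_conn={k: 0.0 for k in sol.c_conn},
        c_bar={k: 0.0 for k in sol.c_bar}, rho={}, D=1.0)
    dec = input_correlation_theory(params, zero)
    assert dec.c_corr == 0.0
    assert dec.q_in == pytest.approx(params.p, rel=1e-9)


def test_feedback_cancellation_of_shared_input():
    """In the recurrent network the spike-correlation term cancels most
    of the shared-input term; q_in falls well below the connection
    probability and decreases with coupling."""
    qs = []
    for w in (0.4, 0.8, 1.2):
        params = CovarianceParams(N_E=300, N_I=75, p=0.1, w=w, g=6.0)
        sol = solve_covariances(params)
        dec = input_correlation_theory(params, sol)
        assert abs(dec.c_shared + dec.c_corr) < abs(dec.c_shared)
        assert dec.cancellation_factor < 1.0
        qs.append(dec.q_in)
    assert qs[0] > qs[1] > qs[2]
    assert qs[-1] < params.p


def test_pure_inhibitory_cancellation():
    params = CovarianceParams(N_E=0, N_I=400, p=0.1, w=1.5, g=1.0)
    sol = solve_covariances(params)
    dec = input_correlation_theory(params, sol)
    assert dec.c_corr < 0.0
    assert abs(dec.c_shared + dec.c_corr) < abs(dec.c_shared)


# ---------------------------------------------------------- compound power

def test_compound_power_trivial_cases():
    params = CovarianceParams(N_E=300, N_I=75, p=0.1, w=0.0, g=6.0, D=1.0)
    sol = solve_covariances(params)
    n = 375
    assert compound_power(params, sol, "feedback") \
        == pytest.approx(1.0 / n, rel=1e-12)
    ratio = compound_power(params, sol, "feedback") \
        / compound_power(params, sol, "drop_EI")
    assert ratio == pytest.approx(1.0, rel=1e-9)


def test_auto_covariance_substitution_changes_ratio_below_one_percent():
    """Substituting the feedback auto-covariances into the open-loop
    assembly barely moves the power ratio: the suppression is carried by
    the cross-covariances."""
    params = EI_PARAMS
    sol = solve_covariances(params)
    p_fb = compound_power(params, sol, "feedback")
    a = p_fb / compound_power(params, sol, "drop_EI")
    b = p_fb / compound_power(params, sol, "drop_EI",
                              autos_from_feedback=True)
    assert abs(a - b) / a < 0.01


# ------------------------------------------------------------ size scaling

def test_covariances_decay_as_inverse_sqrt_n_for_scaled_weights():
    """With synaptic weights scaled as 1/sqrt(N) the all-pair covariance
    decays with log-log slope about -1/2 in the network size."""
    sizes = [200, 400, 800, 1600]
    cbar = []
    for n in sizes:
        n_e, n_i = int(0.8 * n), int(0.2 * n)
        u = 0.75 / math.sqrt(n)
        acc = [abs(fullmatrix_oracle(n_e, n_i, 0.1, u, 6.0, 1.0, seed=s)
                   .cEE_bar) for s in range(6)]
        cbar.append(np.mean(acc))
    slope = np.polyfit(np.log(sizes), np.log(cbar), 1)[0]
    assert slope == pytest.approx(-0.5, abs=0.12)
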
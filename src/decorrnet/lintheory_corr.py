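"""Self-consistent population-averaged covariances of the linear network.

The linearized network obeys ``y = W y + x`` at zero frequency, with
``W`` the effective connectivity (entries ``u`` for excitatory sources,
``-g u`` for inhibitory ones, fixed in-degrees ``K_E = p N_E``,
``K_I = p N_I``) and independent white noise of variance ``D`` per
neuron.  "Variance" and "covariance" throughout refer to the *integral*
of the auto-/cross-correlation functions, i.e. the zero-frequency
(cross-)spectra.  The exact covariance matrix is

    C = (1 - W)^{-1} D (1 - W)^{-T}    <=>    C = WC + CW^T - WCW^T + D 1 .

Averaging the element-wise form of this relation over statistically
equivalent pairs — separately for *connected* and *unconnected* pairs,
since a connection ``j -> i`` contributes a term proportional to the
variance of the projecting neuron — and over realizations of the random
connectivity closes the system in the population-averaged variances
``V_E, V_I`` and the unconnected-pair covariances ``c^u_EE, c^u_II``
(with two auxiliary connected-pair terms that are eliminated by
substitution).  Multiple and reciprocal connections are neglected
(connection probability is low, ``p <= 0.1`` recommended).

Consequences that emerge exactly from this structure:

* ``c_EI = (c_EE + c_II)/2`` — the mixed covariance is the arithmetic
  mean of the same-type covariances;
* connected and unconnected covariances differ by a term proportional
  to the projecting neuron's variance;
* every output is linear in ``D``, so correlation coefficients are
  independent of the noise amplitude.

``fullmatrix_oracle`` provides ground truth: it samples an explicit
connectivity, inverts the dense response matrix and averages the exact
covariance matrix by pair class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import StabilityError
from .spikestats import InputDecomposition

__all__ = [
    "CovarianceParams",
    "CovarianceSolution",
    "solve_covariances",
    "closed_form_covariances",
    "ff_covariances",
    "input_correlation_theory",
    "compound_power",
    "fullmatrix_oracle",
    "sample_connectivity",
]


@dataclass(frozen=True)
class CovarianceParams:
    """Parameters of the linear E-I network covariance problem.

    N_E, N_I : population sizes (set ``N_E = 0`` for the purely
               inhibitory network)
    p        : connection probability; in-degrees are ``K = p N_source``
    w        : effective coupling, ``w = K_E u`` (E-I network) or
               ``w = K_I |u_I|`` (purely inhibitory network)
    g        : balance parameter (inhibitory weight ``-g u``)
    D        : noise variance per neuron
    """

    N_E: int
    N_I: int
    p: float
    w: float
    g: float = 0.0
    D: float = 1.0

    def __post_init__(self):
        if self.N_E < 0 or self.N_I < 0 or self.N_E + self.N_I == 0:
            raise ValueError("population sizes must be non-negative, not both 0")
        if not (0 < self.p <= 1):
            raise ValueError("connection probability must lie in (0, 1]")
        if self.w < 0 or self.g < 0 or self.D <= 0:
            raise ValueError("w, g must be >= 0 and D > 0")

    @property
    def gamma(self) -> float:
        return self.N_I / self.N_E if self.N_E else math.inf

    @property
    def pure_inhibitory(self) -> bool:
        return self.N_E == 0

    def _populations(self):
        """(sizes, integer in-degrees, per-synapse weights) of the active
        populations.  In-degrees are rounded to integers exactly as in a
        sampled network."""
        if self.pure_inhibitory:
            n = np.array([self.N_I], dtype=float)
            k = np.array([float(round(self.p * self.N_I))])
            u = np.array([-self.w / k[0]])
            return n, k, u
        n = np.array([self.N_E, self.N_I], dtype=float)
        k = np.round(self.p * n).astype(float)
        u_e = self.w / k[0]
        u = np.array([u_e, -self.g * u_e])
        return n, k, u


@dataclass
class CovarianceSolution:
    """Population-averaged integral covariances, in units of ``D``.

    ``c_u`` are unconnected-pair covariances, ``c_conn[(src, tgt)]``
    directed connected-pair covariances, ``c_bar`` all-pair averages
    and ``rho`` correlation coefficients ``c_bar / sqrt(V V)``.
    Keys are population tags 'E'/'I' ('I' only for the purely
    inhibitory network).
    """

    V: dict
    c_u: dict
    c_conn: dict
    c_bar: dict
    rho: dict
    D: float
    meta: dict = field(default_factory=dict)

    # convenience accessors used throughout tests and scripts
    @property
    def V_E(self): return self.V.get("E", float("nan"))
    @property
    def V_I(self): return self.V.get("I", float("nan"))
    @property
    def cEE_bar(self): return self.c_bar.get(("E", "E"), float("nan"))
    @property
    def cEI_bar(self): return self.c_bar.get(("E", "I"), float("nan"))
    @property
    def cII_bar(self): return self.c_bar.get(("I", "I"), float("nan"))
    @property
    def rho_EE(self): return self.rho.get(("E", "E"), float("nan"))
    @property
    def rho_EI(self): return self.rho.get(("E", "I"), float("nan"))
    @property
    def rho_II(self): return self.rho.get(("I", "I"), float("nan"))


def _check_stable(params: CovarianceParams):
    from .lif_linear import stability_check

    if params.pure_inhibitory:
        # one-population mean mode: -w; always stable for w >= 0.  Bulk:
        k = params.p * params.N_I
        u = params.w / k
        radius = math.sqrt(params.p * (1 - params.p) * params.N_I * u * u)
        if radius >= 1.0:
            raise StabilityError(
                f"circular-law radius {radius:.3f} >= 1 (unstable bulk)")
        return
    rep = stability_check(params)
    if not rep.stable:
        raise StabilityError(
            f"linear model unstable (mean mode {rep.mean_mode:.3f}, "
            f"bulk radius {rep.circular_radius:.3f})")


# ---------------------------------------------------------------------------
# self-consistent class-averaged system
# ---------------------------------------------------------------------------

def _assemble_and_solve(params: CovarianceParams,
                        equal_variances: bool,
                        asymptotic: bool = False) -> dict:
    """Solve the class-averaged self-consistency equations.

    Unknowns (two populations): z = [V_E, V_I, cu_EE, cu_II]; for one
    population z = [V, cu].  The covariance of a connected pair exceeds
    the unconnected value by ``u_src * V_src`` (projecting neuron's
    variance times its synaptic weight), the all-pair average mixes the
    two with the connection probability, and the mixed-type unconnected
    covariance is the arithmetic mean of the same-type ones (the E and I
    members of a pair differ only through their outgoing weights).
    ``equal_variances`` imposes V_E = V_I (the explicit closed-form
    approximation) by replacing the two variance equations with their
    mean and a constraint.
    """
    n, k, u = params._populations()
    if asymptotic:
        # infinite-network combinatorics: fractional in-degrees, pair
        # counts K_a K_b, no reciprocal-connection correction.  In this
        # limit the compound-power ratio coincides exactly with the
        # two-population rate model.
        if params.pure_inhibitory:
            k = np.array([params.p * params.N_I])
            u = np.array([-params.w / k[0]])
        else:
            k = params.p * n
            u = np.array([params.w / k[0], -params.g * params.w / k[0]])
    npop = len(n)
    q = k / n                      # connection probability per source pop
    shared = k * k / n             # expected shared sources per target pair
    # ordered distinct source-pair counts: same target / different targets
    if asymptotic:
        own = np.outer(k, k)
        cross = np.outer(k, k)
    else:
        own = np.outer(k, k) - np.diag(k)
        cross = np.outer(k, k) - np.diag(shared)

    if npop == 2:
        iV, icu = [0, 1], [2, 3]
        nz = 4
    else:
        iV, icu = [0], [1]
        nz = 2

    def cu_mat(z):
        """Unconnected covariance for class pair (a,b); EI = mean of EE,II."""
        m = np.empty((npop, npop))
        for a in range(npop):
            for b in range(npop):
                if a == b:
                    m[a, b] = z[icu[a]]
                else:
                    m[a, b] = 0.5 * (z[icu[0]] + z[icu[1]])
        return m

    def cbar_mat(z):
        cu = cu_mat(z)
        v = np.array([z[i] for i in iV])
        add = q * u * v            # probability x connected-pair excess
        return cu + add[None, :] + add[:, None]

    def residual(z, d_val):
        cu = cu_mat(z)
        cb = cbar_mat(z)
        v = np.array([z[i] for i in iV])
        r = np.zeros(nz)
        s_shared = float(np.sum(shared * u * u * v))
        s_cross = float(np.sum(cross * np.outer(u, u) * cb))
        s_own = float(np.sum(own * np.outer(u, u) * cb))
        # variance equations: connected covariance c_conn = cu + u V,
        # with the O(p) reciprocal-connection correction p u_a V_a
        # (a fraction p of the pairs connected src -> target are also
        # connected target -> src)
        w_tot = float(np.sum(k * u))
        g_loop = float(np.sum(k * u * u * v))
        for a in range(npop):
            rhs = d_val
            recip = 0.0 if asymptotic else q[a] * u[a] * v[a]
            rhs += 2.0 * float(np.sum(k * u * (cu[a] + u * v + recip)))
            rhs -= float(np.sum(k * u * u * v))
            rhs -= s_own
            if not asymptotic:
                # source pairs sharing the target are elevated above the
                # generic pair covariance by the walk channel through the
                # shared target (one guaranteed common out-edge each)
                rhs -= 2.0 * params.p * u[a] * w_tot * g_loop \
                    / (1.0 - w_tot)
            r[iV[a]] = v[a] - rhs
        # unconnected-pair equations (same-type pairs)
        for a in range(npop):
            f = float(np.sum(k * u * cb[a]))
            rhs = 2.0 * f - (s_shared + s_cross)
            r[icu[a]] = cu[a, a] - rhs
        return r

    # build the linear system by probing (equations are exactly linear)
    b_vec = -residual(np.zeros(nz), params.D)
    a_mat = np.empty((nz, nz))
    for j in range(nz):
        e = np.zeros(nz)
        e[j] = 1.0
        a_mat[:, j] = residual(e, 0.0)

    if equal_variances and npop == 2:
        # replace the two variance rows by their mean and the constraint
        mean_row = 0.5 * (a_mat[0] + a_mat[1])
        mean_rhs = 0.5 * (b_vec[0] + b_vec[1])
        a_mat[0], b_vec[0] = mean_row, mean_rhs
        a_mat[1] = 0.0
        a_mat[1, 0], a_mat[1, 1] = 1.0, -1.0
        b_vec[1] = 0.0

    try:
        z = np.linalg.solve(a_mat, b_vec)
    except np.linalg.LinAlgError as exc:
        raise StabilityError(
            "self-consistency system is singular (at or beyond the "
            "stability limit)") from exc

    tags = ["E", "I"] if npop == 2 else ["I"]
    v = {tags[a]: z[iV[a]] for a in range(npop)}
    cu_m = cu_mat(z)
    cb_m = cbar_mat(z)
    cu = {}
    cb = {}
    for a in range(npop):
        for b in range(a, npop):
            cu[(tags[a], tags[b])] = cu_m[a, b]
            cb[(tags[a], tags[b])] = cb_m[a, b]
    c_conn = {}
    for b in range(npop):          # projecting class
        for a in range(npop):      # target class
            key = (tags[b], tags[a])
            pair = (tags[min(a, b)], tags[max(a, b)])
            c_conn[key] = cu[pair] + u[b] * z[iV[b]]
    rho = {}
    for (a, b), val in cb.items():
        rho[(a, b)] = val / math.sqrt(v[a] * v[b])
    return dict(V=v, c_u=cu, c_conn=c_conn, c_bar=cb, rho=rho,
                n=n, k=k, u=u, tags=tags, asymptotic=asymptotic)


def solve_covariances(params: CovarianceParams,
                      asymptotic: bool = False) -> CovarianceSolution:
    """Numerically exact solution of the class-averaged self-consistency
    system (full system; variances of E and I solved independently).

    With ``asymptotic=True`` the infinite-network pair-counting is used
    (see :func:`_assemble_and_solve`); the default keeps the finite-size
    terms that match a sampled network of the given size.
    """
    _check_stable(params)
    sol = _assemble_and_solve(params, equal_variances=False,
                              asymptotic=asymptotic)
    return CovarianceSolution(V=sol["V"], c_u=sol["c_u"],
                              c_conn=sol["c_conn"], c_bar=sol["c_bar"],
                              rho=sol["rho"], D=params.D,
                              meta={"method": "full",
                                    "asymptotic": asymptotic})


def closed_form_covariances(params: CovarianceParams) -> CovarianceSolution:
    """Covariances under the explicit-expression approximation V_E = V_I.

    For the purely inhibitory network (``N_E = 0``) the system is
    one-dimensional in the covariance and the result is strictly
    negative for any ``w > 0``.
    """
    _check_stable(params)
    sol = _assemble_and_solve(params, equal_variances=params.N_E > 0)
    return CovarianceSolution(V=sol["V"], c_u=sol["c_u"],
                              c_conn=sol["c_conn"], c_bar=sol["c_bar"],
                              rho=sol["rho"], D=params.D,
                              meta={"method": "equal_variances"})


# ---------------------------------------------------------------------------
# feedforward (open-loop) variants
# ---------------------------------------------------------------------------

def _response_covariances(params: CovarianceParams, v_in: dict,
                          cbar_in: dict,
                          asymptotic: bool = False) -> CovarianceSolution:
    """Covariances of an unconnected population driven through the
    network's connectivity by an ensemble with the given input
    statistics (class variances ``v_in``, all-pair covariances
    ``cbar_in``)."""
    n, k, u = params._populations()
    if asymptotic:
        k = params.p * n
        if params.pure_inhibitory:
            u = np.array([-params.w / k[0]])
        else:
            u = np.array([params.w / k[0], -params.g * params.w / k[0]])
    npop = len(n)
    tags = ["E", "I"] if npop == 2 else ["I"]
    shared = k * k / n
    if asymptotic:
        own = np.outer(k, k)
        cross = np.outer(k, k)
    else:
        own = np.outer(k, k) - np.diag(k)
        cross = np.outer(k, k) - np.diag(shared)
    v_arr = np.array([v_in[t] for t in tags])
    cb_arr = np.empty((npop, npop))
    for a in range(npop):
        for b in range(npop):
            key = (tags[min(a, b)], tags[max(a, b)])
            cb_arr[a, b] = cbar_in[key]
    c_resp = float(np.sum(shared * u * u * v_arr)
                   + np.sum(cross * np.outer(u, u) * cb_arr))
    v_resp = params.D + float(np.sum(k * u * u * v_arr)
                              + np.sum(own * np.outer(u, u) * cb_arr))
    v = {t: v_resp for t in tags}
    cb = {}
    cu = {}
    c_conn = {}
    for a in range(npop):
        for b in range(a, npop):
            cb[(tags[a], tags[b])] = c_resp
            cu[(tags[a], tags[b])] = c_resp
    for b in range(npop):
        for a in range(npop):
            # response population is unconnected: no direct-connection term
            c_conn[(tags[b], tags[a])] = c_resp
    rho = {key: val / v_resp for key, val in cb.items()}
    return CovarianceSolution(V=v, c_u=cu, c_conn=c_conn, c_bar=cb, rho=rho,
                              D=params.D, meta={"method": "feedforward"})


def ff_covariances(params: CovarianceParams, variant: str,
                   feedback: CovarianceSolution | None = None
                   ) -> CovarianceSolution:
    """Open-loop response covariances for perturbed feedback ensembles.

    variant 'drop_EI'    : within-population correlations preserved,
        correlations between E and I sources set to zero (block-diagonal
        input covariance matrix).
    variant 'homogenize' : all pairwise source correlations replaced by
        the grand population average; variances preserved.
    """
    if feedback is None:
        feedback = solve_covariances(params)
    tags = ["E", "I"] if not params.pure_inhibitory else ["I"]
    v_in = dict(feedback.V)
    cb_in = dict(feedback.c_bar)
    if variant == "drop_EI":
        if ("E", "I") in cb_in:
            cb_in[("E", "I")] = 0.0
    elif variant == "homogenize":
        n = {t: (params.N_E if t == "E" else params.N_I) for t in tags}
        ntot = sum(n.values())
        grand = 0.0
        for a in tags:
            for b in tags:
                key = (min(a, b), max(a, b))
                grand += n[a] * n[b] * cb_in[key]
        grand /= ntot ** 2
        for key in list(cb_in):
            cb_in[key] = grand
    else:
        raise ValueError(f"unknown feedforward variant {variant!r}")
    sol = _response_covariances(params, v_in, cb_in,
                                asymptotic=feedback.meta.get("asymptotic",
                                                             False))
    sol.meta["variant"] = variant
    sol.meta["asymptotic"] = feedback.meta.get("asymptotic", False)
    return sol


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def input_correlation_theory(params: CovarianceParams,
                             sol: CovarianceSolution) -> InputDecomposition:
    """Decompose the input covariance of a target pair into the
    shared-input contribution (presynaptic auto-variances weighted by the
    expected shared in-degree) and the spike-correlation contribution
    (cross-covariances of distinct source pairs)."""
    n, k, u = params._populations()
    npop = len(n)
    tags = ["E", "I"] if npop == 2 else ["I"]
    shared = k * k / n
    own = np.outer(k, k) - np.diag(k)
    cross = np.outer(k, k) - np.diag(shared)
    v_arr = np.array([sol.V[t] for t in tags])
    cb_arr = np.empty((npop, npop))
    for a in range(npop):
        for b in range(npop):
            key = (tags[min(a, b)], tags[max(a, b)])
            cb_arr[a, b] = sol.c_bar[key]
    c_shared = float(np.sum(shared * u * u * v_arr))
    c_corr = float(np.sum(cross * np.outer(u, u) * cb_arr))
    a_in = float(np.sum(k * u * u * v_arr)
                 + np.sum(own * np.outer(u, u) * cb_arr))
    return InputDecomposition(c_shared=c_shared, c_corr=c_corr, a_in=a_in,
                              q_in=(c_shared + c_corr) / a_in)


def compound_power(params: CovarianceParams, sol: CovarianceSolution,
                   variant: str = "feedback",
                   autos_from_feedback: bool = False) -> float:
    """Integral power of the compound (whole-network average) rate.

    Assembled from the class-averaged auto- and cross-covariances:
    ``P = (1/N^2) [sum_a N_a V_a + sum_ab n_pairs(a,b) c_bar(a,b)]``.
    For ``variant='drop_EI'`` the open-loop response covariances are
    used; ``autos_from_feedback`` substitutes the feedback
    auto-covariances into the open-loop assembly — a control showing
    that the power ratio is carried by the cross-covariances, not by
    changes in the single-train statistics.
    """
    if variant == "feedback":
        use = sol
    elif variant == "drop_EI":
        use = ff_covariances(params, "drop_EI", feedback=sol)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    tags = ["E", "I"] if not params.pure_inhibitory else ["I"]
    sizes = {t: (params.N_E if t == "E" else params.N_I) for t in tags}
    ntot = sum(sizes.values())
    asymptotic = sol.meta.get("asymptotic", False)
    v_use = dict(sol.V) if (autos_from_feedback and variant != "feedback") \
        else dict(use.V)
    total = 0.0
    for a in tags:
        total += sizes[a] * v_use[a]
    for a in tags:
        for b in tags:
            key = (min(a, b), max(a, b))
            npairs = sizes[a] * sizes[b]
            if a == b and not asymptotic:
                npairs -= sizes[a]
            total += npairs * use.c_bar[key]
    return total / ntot ** 2


# ---------------------------------------------------------------------------
# dense-matrix oracle
# ---------------------------------------------------------------------------

def sample_connectivity(params: CovarianceParams, seed: int) -> np.ndarray:
    """Sample one explicit fixed in-degree effective connectivity matrix."""
    n, k, u = params._populations()
    sizes = n.astype(int)
    kk = np.round(k).astype(int)
    ntot = int(sizes.sum())
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    rng = np.random.default_rng(seed)
    w = np.zeros((ntot, ntot))
    for i in range(ntot):
        for pop in range(len(sizes)):
            if kk[pop] == 0:
                continue
            pool = np.arange(offsets[pop], offsets[pop + 1])
            pool = pool[pool != i]
            src = rng.choice(pool, size=kk[pop], replace=False)
            w[i, src] = u[pop]
    return w


def fullmatrix_oracle(N_E: int, N_I: int, p: float, w_unit: float,
                      g: float, D: float, seed: int) -> CovarianceSolution:
    """Ground-truth covariances from one explicit connectivity realization.

    Builds the zero-frequency response matrix ``(1 - W)^{-1}``, computes
    the full covariance matrix ``C = D (1-W)^{-1} (1-W)^{-T}`` by dense
    linear algebra and averages the entries by pair class
    (connected/unconnected x EE/EI/II, with connected pairs
    distinguished by direction).  Intended for ``N_E + N_I`` up to a few
    thousand.
    """
    if N_E > 0:
        k_e = int(round(p * N_E))
        w_eff = k_e * w_unit
        params = CovarianceParams(N_E=N_E, N_I=N_I, p=p, w=w_eff, g=g, D=D)
    else:
        k_i = int(round(p * N_I))
        params = CovarianceParams(N_E=0, N_I=N_I, p=p,
                                  w=k_i * abs(w_unit) * max(g, 1.0), g=g, D=D)
        # per-synapse inhibitory weight is -g*w_unit if g>0 else w_unit<0
    w_mat = sample_connectivity(params, seed)
    ntot = w_mat.shape[0]
    a = np.eye(ntot) - w_mat
    try:
        x = np.linalg.solve(a, np.eye(ntot))
    except np.linalg.LinAlgError as exc:
        raise StabilityError("response matrix is singular") from exc
    c = D * (x @ x.T)

    tags = ["E", "I"] if N_E > 0 else ["I"]
    sizes = [N_E, N_I] if N_E > 0 else [N_I]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    idx = {t: np.arange(offsets[j], offsets[j + 1])
           for j, t in enumerate(tags)}

    conn = w_mat != 0.0            # conn[i, j]: j -> i
    v = {t: float(np.mean(np.diag(c)[idx[t]])) for t in tags}
    c_u, c_conn, c_bar = {}, {}, {}
    for a_i, ta in enumerate(tags):
        for b_i, tb in enumerate(tags):
            block = c[np.ix_(idx[ta], idx[tb])]
            cmask = conn[np.ix_(idx[ta], idx[tb])]   # src in tb -> tgt in ta
            if cmask.any():
                c_conn[(tb, ta)] = float(block[cmask].mean())
            else:
                c_conn[(tb, ta)] = float("nan")
            if b_i < a_i:
                continue
            either = cmask | conn[np.ix_(idx[tb], idx[ta])].T
            off = np.ones_like(cmask)
            if ta == tb:
                np.fill_diagonal(off, False)
            unconn = off & ~either
            c_u[(ta, tb)] = float(block[unconn].mean())
            c_bar[(ta, tb)] = float(block[off].mean())
    rho = {key: val / math.sqrt(v[key[0]] * v[key[1]])
           for key, val in c_bar.items()}
    return CovarianceSolution(V=v, c_u=c_u, c_conn=c_conn, c_bar=c_bar,
                              rho=rho, D=D,
                              meta={"method": "fullmatrix", "seed": seed,
                                    "w_unit": w_unit, "params": params})
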
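"""Logistic shedding curve, beta-binomial observation model, state mixtures.

The within-season mean shed fraction follows a logistic curve

    f(t) = exp(alpha (t - tau)) / (1 + exp(alpha (t - tau)))

on the year-fraction timescale t = DOY/365, where tau is the date at which
half the coat has been shed and alpha the shedding rate (peak shedding speed
alpha/4 at t = tau).  Both tau and alpha are linear in animal state (male,
kid-at-heel indicators), z-scored elevation and latitude, a smooth year
trend, and a t-distributed year random effect.

Observed shed fractions are grouped into N equal bins and the count of shed
bins n is modelled as beta-binomial with mean N*f and a single overdispersion
parameter phi, chosen so the variance inflation over the binomial is
v = 1 + (N-1) phi / (1 + phi).  Matching that inflation to the standard
beta-binomial (shape a + b) gives a + b = 1/phi, i.e. shapes
a = f/phi, b = (1-f)/phi.

Photographs with ambiguous state contribute through mixtures over the
unambiguous states FN, FY, MN with weights built from the population female
fraction p and kid fraction q:

    Pr(n | FX) = (1-q) P(n|FN) + q P(n|FY)
    Pr(n | XN) = [p(1-q) P(n|FN) + (1-p) P(n|MN)] / [p(1-q) + (1-p)]
    Pr(n | XX) = p(1-q) P(n|FN) + p q P(n|FY) + (1-p) P(n|MN)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import betaln, gammaln, expit

from .data_model import AnimalState, BinnedObservation, UNAMBIGUOUS_STATES

__all__ = [
    "CommunityParams",
    "CaptiveParams",
    "logistic_fraction",
    "linear_predictors",
    "beta_binomial_logpmf",
    "beta_binomial_pmf",
    "mixture_pmf",
    "dataset_loglik",
]

#: shed fractions are clamped to this band before the beta-binomial shapes
#: are formed, so t far from tau cannot produce degenerate shapes.
F_CLAMP = 1e-9


@dataclass(frozen=True)
class CommunityParams:
    """Parameter vector of the community (opportunistic-photograph) model.

    19 hyperparameters — p, q, seven date terms (tau0, tauM, tauK, tauY,
    tauE, tauL plus the year-RE scale implied below), six rate terms, the
    overdispersion phi, two random-effect scales and two degrees of
    freedom — plus the per-year random-effect vectors themselves.
    Dates are year fractions; rates are per year.
    """

    p: float
    q: float
    tau0: float
    tauM: float
    tauK: float
    tauY: float
    tauE: float
    tauL: float
    alpha0: float
    alphaM: float
    alphaK: float
    alphaY: float
    alphaE: float
    alphaL: float
    phi: float
    sigma_tau: float
    sigma_alpha: float
    eta_tau: float
    eta_alpha: float
    tau_re: np.ndarray = field(default_factory=lambda: np.zeros(0))
    alpha_re: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        if not (0.0 < self.p < 1.0 and 0.0 < self.q < 1.0):
            raise ValueError("p and q must lie in (0, 1)")
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        for name in ("sigma_tau", "sigma_alpha", "eta_tau", "eta_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        object.__setattr__(self, "tau_re", np.atleast_1d(np.asarray(self.tau_re, float)))
        object.__setattr__(self, "alpha_re", np.atleast_1d(np.asarray(self.alpha_re, float)))

    def with_year_effects(self, tau_re, alpha_re) -> "CommunityParams":
        return replace(self, tau_re=np.asarray(tau_re, float), alpha_re=np.asarray(alpha_re, float))


@dataclass(frozen=True)
class CaptiveParams:
    """Parameter vector of the captive repeated-measures model.

    A single site and season: no elevation/latitude/year terms.  Each animal
    carries a t-distributed random effect on shedding date.
    """

    tau0: float
    tauM: float
    tauK: float
    alpha0: float
    alphaM: float
    alphaK: float
    phi: float
    sigma_id: float
    eta_id: float
    tau_id: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if self.sigma_id <= 0 or self.eta_id <= 0:
            raise ValueError("sigma_id and eta_id must be positive")
        object.__setattr__(self, "tau_id", np.atleast_1d(np.asarray(self.tau_id, float)))


def logistic_fraction(t, tau, alpha):
    """Mean fraction of coat shed at year-fraction ``t``.

    Overflow-safe; strictly increasing in t for alpha > 0 and passes through
    (tau, 1/2) with slope alpha/4 there.
    """
    t = np.asarray(t, dtype=float)
    out = expit(np.asarray(alpha, float) * (t - np.asarray(tau, float)))
    return out if out.shape else float(out)


def _state_indicators(state: AnimalState) -> tuple[int, int]:
    # x_M = 1 iff male; x_K = 1 iff kid at heel
    if state is AnimalState.MN:
        return 1, 0
    if state is AnimalState.FY:
        return 0, 1
    if state is AnimalState.FN:
        return 0, 0
    raise ValueError(
        f"state {state.value} is ambiguous; ambiguity is resolved in mixture_pmf, "
        "not in the linear predictors"
    )


def linear_predictors(
    state: AnimalState,
    z_elevation: float,
    z_latitude: float,
    year_centered: float,
    year_index: int,
    params: CommunityParams,
) -> tuple[float, float]:
    """Shedding date tau and rate alpha for one unambiguous state.

    tau = tau0 + tauM xM + tauK xK + tauE zE + tauL zL + tauY y + tau[y],
    and likewise for alpha.
    """
    x_m, x_k = _state_indicators(state)
    tau_re = params.tau_re[year_index] if params.tau_re.size else 0.0
    alpha_re = params.alpha_re[year_index] if params.alpha_re.size else 0.0
    tau = (
        params.tau0 + params.tauM * x_m + params.tauK * x_k
        + params.tauE * z_elevation + params.tauL * z_latitude
        + params.tauY * year_centered + tau_re
    )
    alpha = (
        params.alpha0 + params.alphaM * x_m + params.alphaK * x_k
        + params.alphaE * z_elevation + params.alphaL * z_latitude
        + params.alphaY * year_centered + alpha_re
    )
    return float(tau), float(alpha)


def beta_binomial_logpmf(n, n_total, f, phi):
    """log pmf of n shed bins out of ``n_total`` at mean fraction ``f``.

    Shapes a = f/phi, b = (1-f)/phi, so the variance inflation over the
    binomial is 1 + (n_total - 1) phi / (1 + phi).  ``f`` is clamped away
    from {0, 1}.  Broadcasts over array arguments.
    """
    n = np.asarray(n)
    n_total = np.asarray(n_total)
    phi_arr = np.asarray(phi, dtype=float)
    if np.any(phi_arr <= 0):
        raise ValueError("phi must be positive")
    if np.any(n < 0) or np.any(n > n_total):
        raise ValueError("n outside 0..n_total")
    f = np.clip(np.asarray(f, dtype=float), F_CLAMP, 1.0 - F_CLAMP)
    a = f / phi_arr
    b = (1.0 - f) / phi_arr
    out = (
        gammaln(n_total + 1) - gammaln(n + 1) - gammaln(n_total - n + 1)
        + betaln(n + a, n_total - n + b) - betaln(a, b)
    )
    return out if np.ndim(out) else float(out)


def beta_binomial_pmf(n, n_total, f, phi):
    """Probability of observing ``n`` shed bins; see beta_binomial_logpmf."""
    out = np.exp(beta_binomial_logpmf(n, n_total, f, phi))
    return out if np.ndim(out) else float(out)


def mixture_weights(state: AnimalState, p: float, q: float) -> dict[AnimalState, float]:
    """Weights over the unambiguous states implied by an observed state code.

    Unambiguous codes condition on themselves (weight 1, independent of p
    and q).  XN contains no FY component — a visible absence of kid rules
    out females-with-kid — and is renormalized accordingly.
    """
    if not (0.0 < p < 1.0 and 0.0 < q < 1.0):
        raise ValueError("p and q must lie in (0, 1)")
    FN, FY, MN = UNAMBIGUOUS_STATES
    if state in (FN, FY, MN):
        return {state: 1.0}
    if state is AnimalState.FX:
        return {FN: 1.0 - q, FY: q}
    if state is AnimalState.XN:
        z = p * (1.0 - q) + (1.0 - p)
        return {FN: p * (1.0 - q) / z, MN: (1.0 - p) / z}
    # XX: prior state frequencies p(1-q), pq, 1-p, already normalized
    return {FN: p * (1.0 - q), FY: p * q, MN: 1.0 - p}


def mixture_pmf(
    state: AnimalState,
    pmf_fn: float,
    pmf_fy: float,
    pmf_mn: float,
    p: float,
    q: float,
) -> float:
    """Observation probability for any state code, mixing over FN/FY/MN.

    The three component pmfs must be evaluated at the same n with their
    state-specific (tau, alpha).
    """
    components = {
        AnimalState.FN: pmf_fn,
        AnimalState.FY: pmf_fy,
        AnimalState.MN: pmf_mn,
    }
    w = mixture_weights(state, p, q)
    return float(sum(wi * components[s] for s, wi in w.items()))


def dataset_loglik(observations: list[BinnedObservation], params: CommunityParams) -> float:
    """Total log-likelihood of a binned dataset under the community model.

    Raises ``ValueError`` naming the offending record if any per-record
    contribution is non-finite.
    """
    total = 0.0
    for i, obs in enumerate(observations):
        pmfs = {}
        for comp in UNAMBIGUOUS_STATES:
            tau, alpha = linear_predictors(
                comp, obs.z_elevation, obs.z_latitude,
                obs.year_centered, obs.year_index, params,
            )
            f = logistic_fraction(obs.t, tau, alpha)
            pmfs[comp] = beta_binomial_pmf(obs.n_shed, obs.n_total, f, params.phi)
        pr = mixture_pmf(
            obs.state, pmfs[AnimalState.FN], pmfs[AnimalState.FY],
            pmfs[AnimalState.MN], params.p, params.q,
        )
        ll = np.log(pr) if pr > 0 else -np.inf
        if not np.isfinite(ll):
            raise ValueError(f"non-finite log-likelihood at observation index {i}")
        total += ll
    return float(total)


# ---------------------------------------------------------------------------
# Vectorized internals used by the samplers.  Contracts above define the
# arithmetic; these reproduce it in log space over (walker, record, component)
# arrays with log-sum-exp mixing for numerical safety.
# ---------------------------------------------------------------------------


class PackedData:
    """Columnar view of a binned dataset for fast likelihood evaluation."""

    def __init__(self, observations: list[BinnedObservation]):
        n = len(observations)
        if n == 0:
            raise ValueError("empty dataset")
        self.n_obs = n
        self.n_shed = np.array([o.n_shed for o in observations])
        n_total = {o.n_total for o in observations}
        if len(n_total) != 1:
            raise ValueError("all observations must share n_total")
        self.n_total = n_total.pop()
        self.t = np.array([o.t for o in observations])
        self.z_e = np.array([o.z_elevation for o in observations])
        self.z_l = np.array([o.z_latitude for o in observations])
        self.year_c = np.array([o.year_centered for o in observations])
        self.year_idx = np.array([o.year_index for o in observations], dtype=int)
        self.n_years = int(self.year_idx.max()) + 1
        states = [o.state for o in observations]
        self.state_codes = np.array([list(AnimalState).index(s) for s in states])
        if any(o.animal_index is not None for o in observations):
            self.animal_idx = np.array(
                [-1 if o.animal_index is None else o.animal_index for o in observations],
                dtype=int,
            )
            self.n_animals = int(self.animal_idx.max()) + 1
        else:
            self.animal_idx = None
            self.n_animals = 0
        # n-dependent binomial coefficient, shared by every evaluation
        self.log_binom = (
            gammaln(self.n_total + 1)
            - gammaln(self.n_shed + 1)
            - gammaln(self.n_total - self.n_shed + 1)
        )
        # component indicator rows in FN, FY, MN order
        self.x_m = np.array([0.0, 0.0, 1.0])
        self.x_k = np.array([0.0, 1.0, 0.0])
        # which mixture components each record's state actually needs
        # (FN, FY, MN columns); ambiguous classes need 2-3, unambiguous 1
        need_by_state = {
            AnimalState.FN: (1, 0, 0),
            AnimalState.FY: (0, 1, 0),
            AnimalState.MN: (0, 0, 1),
            AnimalState.FX: (1, 1, 0),
            AnimalState.XN: (1, 0, 1),
            AnimalState.XX: (1, 1, 1),
        }
        order = list(AnimalState)
        self.need = np.array([need_by_state[order[c]] for c in self.state_codes], bool)
        self.need_r, self.need_c = np.nonzero(self.need)


def _component_logpmf(data: PackedData, tau, alpha, phi):
    """log P_BB(n | component), sparse over the needed (record, component)
    pairs only.

    tau, alpha: (W, R, 3); phi: (W, 1, 1).  Returns (W, R, 3) with zeros at
    entries no record's mixture reads.  Uses a + b = 1/phi to share the
    normalizing gammaln terms per walker.
    """
    W = tau.shape[0]
    r, c = data.need_r, data.need_c
    tau_k = tau[:, r, c]
    alpha_k = alpha[:, r, c]
    f = expit(alpha_k * (data.t[r] - tau_k))
    np.clip(f, F_CLAMP, 1.0 - F_CLAMP, out=f)
    phi_w = np.asarray(phi, float).reshape(W, 1)
    a = f / phi_w
    b = (1.0 - f) / phi_w
    n_k = data.n_shed[r]
    inv_phi = 1.0 / phi_w
    # betaln(n+a, N-n+b) - betaln(a, b) with a+b = 1/phi
    vals = (
        data.log_binom[r]
        + gammaln(n_k + a) + gammaln(data.n_total - n_k + b)
        - gammaln(a) - gammaln(b)
        + gammaln(inv_phi) - gammaln(data.n_total + inv_phi)
    )
    out = np.zeros((W, data.n_obs, 3))
    out[:, r, c] = vals
    return out


def community_loglik_batch(data: PackedData, theta: dict) -> np.ndarray:
    """Vectorized community log-likelihood.

    ``theta`` maps parameter names to arrays with a leading walker axis W
    (scalars allowed); tau_re/alpha_re have shape (W, n_years).  Returns
    shape (W,).
    """
    def col(name):
        return np.asarray(theta[name], float).reshape(-1, 1, 1)

    W = max(np.size(theta["tau0"]), 1)
    tau_re = np.asarray(theta["tau_re"], float).reshape(W, -1)
    alpha_re = np.asarray(theta["alpha_re"], float).reshape(W, -1)

    tau = (
        col("tau0")
        + col("tauM") * data.x_m + col("tauK") * data.x_k
        + (col("tauE") * data.z_e[:, None] + col("tauL") * data.z_l[:, None]
           + col("tauY") * data.year_c[:, None] + tau_re[:, data.year_idx, None])
    )
    alpha = (
        col("alpha0")
        + col("alphaM") * data.x_m + col("alphaK") * data.x_k
        + (col("alphaE") * data.z_e[:, None] + col("alphaL") * data.z_l[:, None]
           + col("alphaY") * data.year_c[:, None] + alpha_re[:, data.year_idx, None])
    )
    logp = _component_logpmf(data, tau, alpha, col("phi"))  # (W, R, 3)

    p = np.asarray(theta["p"], float).reshape(-1, 1)
    q = np.asarray(theta["q"], float).reshape(-1, 1)
    return _mix_logpmf(data, logp, p, q)


_STATE_ORDER = list(AnimalState)


def _mix_logpmf(data: PackedData, logp: np.ndarray, p, q) -> np.ndarray:
    """Mix per-component log pmfs (W, R, 3) into per-walker loglik (W,).

    Builds a (W, R, 3) log-weight array (-inf at unused components) and
    reduces with one fused log-sum-exp; unambiguous records get weight 1 on
    their own component, so they bypass p and q entirely.
    """
    W, R, _ = logp.shape
    codes = data.state_codes
    p = np.asarray(p, float).reshape(-1)
    q = np.asarray(q, float).reshape(-1)
    lw = np.full((W, R, 3), -np.inf)
    with np.errstate(divide="ignore"):
        for s, comp in ((AnimalState.FN, 0), (AnimalState.FY, 1), (AnimalState.MN, 2)):
            m = codes == _STATE_ORDER.index(s)
            if m.any():
                lw[:, m, comp] = 0.0
        m = codes == _STATE_ORDER.index(AnimalState.FX)
        if m.any():
            lw[:, m, 0] = np.log1p(-q)[:, None]
            lw[:, m, 1] = np.log(q)[:, None]
        m = codes == _STATE_ORDER.index(AnimalState.XN)
        if m.any():
            w1, w2 = p * (1 - q), 1 - p
            z = w1 + w2
            lw[:, m, 0] = np.log(w1 / z)[:, None]
            lw[:, m, 2] = np.log(w2 / z)[:, None]
        m = codes == _STATE_ORDER.index(AnimalState.XX)
        if m.any():
            lw[:, m, 0] = np.log(p * (1 - q))[:, None]
            lw[:, m, 1] = np.log(p * q)[:, None]
            lw[:, m, 2] = np.log1p(-p)[:, None]
    # fused log-sum-exp over the component axis
    s = logp + lw
    mx = s.max(axis=-1, keepdims=True)
    out = mx[..., 0] + np.log(np.exp(s - mx).sum(axis=-1))
    return out.sum(axis=1)


def captive_loglik_batch(data: PackedData, theta: dict) -> np.ndarray:
    """Vectorized captive-model log-likelihood; all states unambiguous.

    tau_id has shape (W, n_animals); records carry an animal index.
    """
    if data.animal_idx is None:
        raise ValueError("captive likelihood requires animal indices")

    def col(name):
        return np.asarray(theta[name], float).reshape(-1, 1, 1)

    W = max(np.size(theta["tau0"]), 1)
    tau_id = np.asarray(theta["tau_id"], float).reshape(W, -1)
    tau = (
        col("tau0") + col("tauM") * data.x_m + col("tauK") * data.x_k
        + tau_id[:, data.animal_idx, None]
    )
    alpha = np.broadcast_to(
        col("alpha0") + col("alphaM") * data.x_m + col("alphaK") * data.x_k,
        tau.shape,
    )
    logp = _component_logpmf(data, tau, alpha, col("phi"))  # (W, R, 3)
    comp = np.select(
        [data.state_codes == list(AnimalState).index(AnimalState.FN),
         data.state_codes == list(AnimalState).index(AnimalState.FY)],
        [0, 1], default=2,
    )
    return logp[:, np.arange(data.n_obs), comp].sum(axis=1)
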
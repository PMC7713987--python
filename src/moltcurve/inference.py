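"""Bayesian fitting of the community and captive molt models.

Sampling runs on an unconstrained reparameterization: interval parameters
(p, q, tau0) are logit-transformed, positive parameters (phi, scales) are
log-transformed, degrees of freedom use eta = 1 + exp(u) (bounded below at
1), and the t-distributed random effects are non-centered — the sampler
moves a standardized t draw u and the effect is sigma * u — which removes
the scale/effect funnel.  Priors are evaluated on the constrained scale with
the appropriate Jacobian terms.

The engine is the affine-invariant ensemble sampler (emcee).  A "chain" is
one independently seeded walker ensemble; retained draws keep step order so
split-R-hat across chains remains meaningful.  Convergence failures warn
(with diagnostics attached to the posterior) rather than raising.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import emcee
import numpy as np
from scipy import stats
from scipy.special import expit, logit

from .data_model import AnimalState, BinnedObservation
from .likelihood import (
    CaptiveParams,
    CommunityParams,
    PackedData,
    captive_loglik_batch,
    community_loglik_batch,
)

__all__ = [
    "PriorSpec",
    "FitConfig",
    "PosteriorSummary",
    "fit_community",
    "fit_captive",
    "summarize",
    "check_state_frequency_assumption",
]

DAYS_PER_YEAR = 365.0

# parameters for which zero means "no effect" (Table-style bolding rule)
ZERO_EFFECT_PARAMS = (
    "tauM", "tauK", "tauY", "tauE", "tauL",
    "alphaM", "alphaK", "alphaY", "alphaE", "alphaL",
)

# tau-scale offsets also reported on the day scale
DAY_SCALE_PARAMS = ("tauM", "tauK")


@dataclass(frozen=True)
class Prior:
    """One prior: family in {beta, normal, exponential, gamma} + parameters.

    normal's second argument is a standard deviation; gamma(a, b) has mean
    a/b; exponential(a) has mean 1/a.
    """

    family: str
    args: tuple[float, ...]

    def logpdf(self, x):
        a = self.args
        if self.family == "beta":
            return stats.beta.logpdf(x, a[0], a[1])
        if self.family == "normal":
            return stats.norm.logpdf(x, loc=a[0], scale=a[1])
        if self.family == "exponential":
            return stats.expon.logpdf(x, scale=1.0 / a[0])
        if self.family == "gamma":
            return stats.gamma.logpdf(x, a[0], scale=1.0 / a[1])
        raise ValueError(f"unknown prior family {self.family!r}")

    def rvs(self, size, rng):
        a = self.args
        if self.family == "beta":
            return stats.beta.rvs(a[0], a[1], size=size, random_state=rng)
        if self.family == "normal":
            return stats.norm.rvs(loc=a[0], scale=a[1], size=size, random_state=rng)
        if self.family == "exponential":
            return stats.expon.rvs(scale=1.0 / a[0], size=size, random_state=rng)
        if self.family == "gamma":
            return stats.gamma.rvs(a[0], scale=1.0 / a[1], size=size, random_state=rng)
        raise ValueError(f"unknown prior family {self.family!r}")

    def label(self) -> str:
        sym = {"beta": "B", "normal": "N", "exponential": "E", "gamma": "G"}[self.family]
        return f"{sym}({','.join(format(v, 'g') for v in self.args)})"


def default_priors() -> dict[str, Prior]:
    """Weakly informative defaults for every hyperparameter."""
    return {
        "p": Prior("beta", (2, 2)),
        "q": Prior("beta", (2, 2)),
        "tau0": Prior("beta", (2, 2)),
        "tauM": Prior("normal", (0, 0.1)),
        "tauK": Prior("normal", (0, 0.1)),
        "tauY": Prior("normal", (0, 0.1)),
        "tauE": Prior("normal", (0, 0.1)),
        "tauL": Prior("normal", (0, 0.1)),
        "alpha0": Prior("normal", (25, 5)),
        "alphaM": Prior("normal", (0, 20)),
        "alphaK": Prior("normal", (0, 20)),
        "alphaY": Prior("normal", (0, 1)),
        "alphaE": Prior("normal", (0, 1)),
        "alphaL": Prior("normal", (0, 1)),
        "phi": Prior("exponential", (1,)),
        "sigma_tau": Prior("exponential", (10,)),
        "sigma_alpha": Prior("exponential", (1,)),
        "eta_tau": Prior("gamma", (2, 0.1)),
        "eta_alpha": Prior("gamma", (2, 0.1)),
        "sigma_id": Prior("exponential", (10,)),
        "eta_id": Prior("gamma", (2, 0.1)),
    }


@dataclass
class PriorSpec:
    """Prior set; ``priors`` overrides replace the defaults per parameter."""

    priors: dict[str, Prior] = field(default_factory=default_priors)

    def __getitem__(self, name: str) -> Prior:
        return self.priors[name]

    def replace(self, **overrides: Prior) -> "PriorSpec":
        d = dict(self.priors)
        d.update(overrides)
        return PriorSpec(priors=d)


@dataclass
class FitConfig:
    """Sampler configuration.

    ``n_warmup`` and ``n_samples`` count ensemble steps per chain (each step
    advances every walker).  ``n_walkers`` defaults to the larger of 48 and
    2 * ndim + 2.  ``thin`` subsamples retained steps for storage.
    """

    n_chains: int = 3
    n_warmup: int = 1000
    n_samples: int = 1000
    seed: int = 0
    n_bins: int = 25
    model_variant: str = "community"
    n_walkers: int | None = None
    thin: int = 10
    rhat_threshold: float = 1.01
    init: str = "map"  # "map": walkers jittered around a posterior mode;
    #                    "prior": random draws from the priors


@dataclass(frozen=True)
class PosteriorSummary:
    """Median and equal-tailed 89% interval for one parameter."""

    name: str
    median: float
    lower89: float
    upper89: float
    effect_detected: bool | None = None
    days_scale: tuple[float, float, float] | None = None
    prior_label: str | None = None

    def __post_init__(self):
        if not (self.lower89 <= self.median <= self.upper89):
            raise ValueError("interval must bracket the median")


# ---------------------------------------------------------------------------
# unconstrained <-> constrained transforms
# ---------------------------------------------------------------------------

_COMMUNITY_SCALARS = [
    ("p", "logit"), ("q", "logit"), ("tau0", "logit"),
    ("tauM", "id"), ("tauK", "id"), ("tauY", "id"), ("tauE", "id"), ("tauL", "id"),
    ("alpha0", "id"), ("alphaM", "id"), ("alphaK", "id"),
    ("alphaY", "id"), ("alphaE", "id"), ("alphaL", "id"),
    ("phi", "log"), ("sigma_tau", "log"), ("sigma_alpha", "log"),
    ("eta_tau", "log1p_lb"), ("eta_alpha", "log1p_lb"),
]

_CAPTIVE_SCALARS = [
    ("tau0", "logit"),
    ("tauM", "id"), ("tauK", "id"),
    ("alpha0", "id"), ("alphaM", "id"), ("alphaK", "id"),
    ("phi", "log"), ("sigma_id", "log"), ("eta_id", "log1p_lb"),
]


def _constrain(u, kind):
    if kind == "id":
        return u, np.zeros_like(u)
    if kind == "logit":
        v = expit(u)
        with np.errstate(divide="ignore"):  # saturated logit -> -inf, rejected
            return v, np.log(v) + np.log1p(-v)
    if kind == "log":
        return np.exp(u), u
    if kind == "log1p_lb":  # eta = 1 + exp(u)
        return 1.0 + np.exp(u), u
    raise ValueError(kind)


def _unconstrain(v, kind):
    if kind == "id":
        return v
    if kind == "logit":
        return logit(v)
    if kind == "log":
        return np.log(v)
    if kind == "log1p_lb":
        return np.log(v - 1.0)
    raise ValueError(kind)


class _Model:
    """Shared machinery: parameter packing, log-posterior, init, storage."""

    scalars: list[tuple[str, str]]
    re_blocks: list[tuple[str, str, str, str]]  # (name, sigma, eta, size_attr)

    def __init__(self, data: PackedData, priors: PriorSpec):
        self.data = data
        self.priors = priors
        self.n_scalar = len(self.scalars)
        self.re_sizes = [getattr(data, size) for (_, _, _, size) in self.re_blocks]
        self.ndim = self.n_scalar + sum(self.re_sizes)

    def split(self, u: np.ndarray) -> tuple[dict, np.ndarray]:
        """Unconstrained (W, ndim) -> constrained theta dict + log-Jacobian (W,)."""
        u = np.atleast_2d(u)
        theta: dict[str, np.ndarray] = {}
        logjac = np.zeros(u.shape[0])
        for j, (name, kind) in enumerate(self.scalars):
            v, lj = _constrain(u[:, j], kind)
            theta[name] = v
            logjac += lj
        off = self.n_scalar
        for (name, _, _, _), size in zip(self.re_blocks, self.re_sizes):
            theta["u_" + name] = u[:, off:off + size]
            off += size
        return theta, logjac

    def log_prior(self, theta: dict) -> np.ndarray:
        lp = 0.0
        for name, _ in self.scalars:
            lp = lp + self.priors[name].logpdf(theta[name])
        for name, sigma_name, eta_name, _ in self.re_blocks:
            u = theta["u_" + name]
            df = theta[eta_name][:, None]
            lp = lp + stats.t.logpdf(u, df).sum(axis=1)
        return lp

    def materialize_re(self, theta: dict) -> None:
        for name, sigma_name, _, _ in self.re_blocks:
            theta[name] = theta[sigma_name][:, None] * theta["u_" + name]

    def loglik(self, theta: dict) -> np.ndarray:
        raise NotImplementedError

    #: below this the gammaln identities in the beta-binomial cancel
    #: catastrophically; phi this small is numerically binomial anyway
    PHI_FLOOR = 1e-6

    def log_prob(self, u: np.ndarray) -> np.ndarray:
        theta, logjac = self.split(u)
        lp = self.log_prior(theta) + logjac
        self.materialize_re(theta)
        ll = self.loglik(theta)
        # a sum of log pmfs is never positive: positive values are
        # floating-point cancellation garbage, not high likelihood
        bad = ~np.isfinite(ll) | (ll > 0.0) | (theta["phi"] < self.PHI_FLOOR)
        out = np.where(bad, -np.inf, lp + ll)
        return np.where(np.isfinite(out), out, -np.inf)

    def initial_walkers(self, n_walkers: int, rng: np.random.Generator) -> np.ndarray:
        """Random inits from the priors (random effects near zero)."""
        cols = []
        for name, kind in self.scalars:
            draws = self.priors[name].rvs(n_walkers, rng)
            if kind == "log1p_lb":
                draws = np.maximum(draws, 1.0 + 1e-3)
            if kind == "logit":
                draws = np.clip(draws, 1e-4, 1 - 1e-4)
            cols.append(_unconstrain(draws, kind))
        for size in self.re_sizes:
            cols.extend(rng.normal(0.0, 0.3, size=(size, n_walkers)))
        return np.column_stack([np.asarray(c) for c in cols])

    def _neutral_start(self) -> np.ndarray:
        """A mild starting point for the mode search: offsets zero, baseline
        parameters at typical prior-scale values."""
        start = []
        for name, kind in self.scalars:
            if kind == "logit":
                start.append(0.0)  # p = q = tau0 = 0.5
            elif name == "alpha0":
                start.append(float(self.priors[name].args[0]))
            elif kind == "log":
                start.append(np.log(0.3) if name == "phi" else np.log(0.1))
            elif kind == "log1p_lb":
                start.append(np.log(19.0))  # eta ~ 20
            else:
                start.append(0.0)
        start.extend([0.0] * sum(self.re_sizes))
        return np.array(start)

    def find_mode(self, rng: np.random.Generator) -> np.ndarray:
        """Locate a posterior mode region (numerical-gradient L-BFGS-B).

        The mode only seeds the walkers, so a rough optimum suffices.
        Batched finite differences keep the numerical gradient cheap.
        """
        from scipy.optimize import minimize

        eps = 1e-6
        eye = np.eye(self.ndim)

        def neg_and_grad(u):
            pts = np.vstack([u[None, :], u[None, :] + eps * eye])
            vals = -self.log_prob(pts)
            return vals[0], (vals[1:] - vals[0]) / eps

        res = minimize(neg_and_grad, self._neutral_start(), jac=True,
                       method="L-BFGS-B", options={"maxiter": 200})
        return res.x

    def walkers_around(self, center: np.ndarray, n_walkers: int,
                       rng: np.random.Generator) -> np.ndarray:
        return center[None, :] + rng.normal(0.0, 0.02, size=(n_walkers, self.ndim))


class _CommunityModel(_Model):
    scalars = _COMMUNITY_SCALARS
    re_blocks = [
        ("tau_re", "sigma_tau", "eta_tau", "n_years"),
        ("alpha_re", "sigma_alpha", "eta_alpha", "n_years"),
    ]

    def loglik(self, theta):
        return community_loglik_batch(self.data, theta)


class _CaptiveModel(_Model):
    scalars = _CAPTIVE_SCALARS
    re_blocks = [("tau_id", "sigma_id", "eta_id", "n_animals")]

    def loglik(self, theta):
        return captive_loglik_batch(self.data, theta)


def _run_mcmc(model: _Model, config: FitConfig, meta: dict | None) -> az.InferenceData:
    n_walkers = config.n_walkers or max(48, 2 * model.ndim + 2)
    if n_walkers % 2:
        n_walkers += 1
    ss = np.random.SeedSequence(config.seed)
    chain_seeds = ss.spawn(config.n_chains + 1)

    mode = None
    if config.init == "map":
        mode = model.find_mode(np.random.default_rng(chain_seeds[-1]))

    # differential-evolution moves handle the correlated, moderately
    # high-dimensional target far better than the default stretch move
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]

    chains: list[dict[str, np.ndarray]] = []
    log_probs = []
    for c in range(config.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        if mode is not None:
            p0 = model.walkers_around(mode, n_walkers, rng)
        else:
            p0 = model.initial_walkers(n_walkers, rng)
        sampler = emcee.EnsembleSampler(
            n_walkers, model.ndim, model.log_prob, vectorize=True, moves=moves
        )
        sampler.random_state = np.random.RandomState(int(chain_seeds[c].generate_state(1)[0]))
        state = sampler.run_mcmc(p0, config.n_warmup, skip_initial_state_check=True)
        sampler.reset()
        sampler.run_mcmc(state, config.n_samples, skip_initial_state_check=True)
        # keep step-major order: (steps, walkers, dim) -> thin steps
        chain_u = sampler.get_chain()[:: config.thin]  # (S, W, D)
        lp = sampler.get_log_prob()[:: config.thin]
        S, W, D = chain_u.shape
        flat = chain_u.reshape(S * W, D)
        theta, _ = model.split(flat)
        model.materialize_re(theta)
        draws = {}
        for name, _ in model.scalars:
            draws[name] = theta[name]
        for name, _, _, _ in model.re_blocks:
            draws[name] = theta[name]
        chains.append(draws)
        log_probs.append(lp.reshape(S * W))

    posterior = {}
    for name in chains[0]:
        posterior[name] = np.stack([c[name] for c in chains])
    dims = {name: ["year"] for name, *_ in model.re_blocks} if isinstance(model, _CommunityModel) else {}
    if isinstance(model, _CaptiveModel):
        dims = {"tau_id": ["animal"]}
    coords = {}
    if meta:
        if meta.get("years") and isinstance(model, _CommunityModel):
            coords["year"] = meta["years"]
        if meta.get("animal_ids") and isinstance(model, _CaptiveModel):
            coords["animal"] = meta["animal_ids"]
    idata = az.from_dict(
        posterior=posterior,
        sample_stats={"lp": np.stack(log_probs)},
        dims=dims,
        coords=coords,
    )
    idata.posterior.attrs["model_variant"] = config.model_variant
    if meta:
        idata.posterior.attrs["n_bins"] = meta.get("n_bins", config.n_bins)
        idata.posterior.attrs["year_origin"] = meta.get("year_origin", 2000.0)
        if meta.get("years"):
            idata.posterior.attrs["years"] = list(meta["years"])

    # convergence diagnostics on the hyperparameters (needs >= 2 chains)
    if config.n_chains >= 2:
        scalar_names = [name for name, _ in model.scalars]
        rhat = az.rhat(idata, var_names=scalar_names)
        max_rhat = float(max(rhat[v].values.max() for v in rhat.data_vars))
        if max_rhat > config.rhat_threshold:
            warnings.warn(
                f"split-R-hat {max_rhat:.3f} exceeds {config.rhat_threshold}; "
                "inspect diagnostics before trusting the posterior",
                stacklevel=3,
            )
    else:
        max_rhat = float("nan")
        warnings.warn("single-chain fit: split-R-hat unavailable", stacklevel=3)
    idata.posterior.attrs["max_rhat"] = max_rhat
    return idata


def fit_community(
    data: list[BinnedObservation],
    priors: PriorSpec | None = None,
    config: FitConfig | None = None,
    meta: dict | None = None,
) -> az.InferenceData:
    """Fit the full community model (mixture likelihood, year effects).

    ``data`` should come from ``build_observations`` on a filtered record
    set; every included year needs at least one unambiguous record.
    """
    priors = priors or PriorSpec()
    config = config or FitConfig()
    packed = PackedData(data)
    years_seen = set(packed.year_idx.tolist())
    unamb = {list(AnimalState).index(s) for s in (AnimalState.FN, AnimalState.FY, AnimalState.MN)}
    anchored = {y for y, s in zip(packed.year_idx, packed.state_codes) if s in unamb}
    if years_seen - anchored:
        warnings.warn(
            f"{len(years_seen - anchored)} year(s) contain no unambiguous record; "
            "their random effects are informed only by the mixture"
        )
    model = _CommunityModel(packed, priors)
    return _run_mcmc(model, config, meta)


def fit_captive(
    data: list[BinnedObservation],
    priors: PriorSpec | None = None,
    config: FitConfig | None = None,
    meta: dict | None = None,
) -> az.InferenceData:
    """Fit the captive repeated-measures model (per-animal date effects)."""
    priors = priors or PriorSpec()
    config = config or FitConfig(model_variant="captive")
    for i, obs in enumerate(data):
        if obs.state.is_ambiguous:
            raise ValueError(f"captive model admits no ambiguous states (observation {i})")
        if obs.animal_index is None:
            raise ValueError(f"captive model requires animal_id (observation {i})")
    packed = PackedData(data)
    model = _CaptiveModel(packed, priors)
    config.model_variant = "captive"
    return _run_mcmc(model, config, meta)


def _draws(idata: az.InferenceData, name: str) -> np.ndarray:
    return idata.posterior[name].values.reshape(-1)


def summarize(
    idata: az.InferenceData,
    priors: PriorSpec | None = None,
) -> list[PosteriorSummary]:
    """Equal-tailed 89% summaries (5.5% / 94.5% quantiles) per parameter.

    tau-offset parameters also carry a day-scale version (x 365); the
    effect-detected flag is set where zero means no effect and the 89%
    interval excludes zero.
    """
    post = idata.posterior
    n_draws = post.sizes["chain"] * post.sizes["draw"]
    if n_draws < 100:
        raise ValueError("need at least 100 retained draws to summarize")
    out = []
    for name in post.data_vars:
        da = post[name]
        if da.ndim > 2:  # random-effect vectors summarized elsewhere
            continue
        x = da.values.reshape(-1)
        med = float(np.median(x))
        lo, hi = (float(v) for v in np.quantile(x, [0.055, 0.945]))
        detected = None
        if name in ZERO_EFFECT_PARAMS:
            detected = not (lo <= 0.0 <= hi)
        days = None
        if name in DAY_SCALE_PARAMS:
            days = (med * DAYS_PER_YEAR, lo * DAYS_PER_YEAR, hi * DAYS_PER_YEAR)
        label = None
        if priors is not None and name in priors.priors:
            label = priors[name].label()
        out.append(
            PosteriorSummary(
                name=name, median=med, lower89=lo, upper89=hi,
                effect_detected=detected, days_scale=days, prior_label=label,
            )
        )
    return out


def check_state_frequency_assumption(records) -> dict:
    """Diagnostic: are unambiguous state frequencies homogeneous over years?

    Builds the per-year FN/FY/MN contingency table, runs a chi-square
    homogeneity test, and reports the pooled estimates of the female
    fraction p and the kid fraction q.
    """
    from scipy.stats import chi2_contingency

    counts: dict[int, dict[str, int]] = {}
    for r in records:
        if r.state.is_unambiguous:
            counts.setdefault(r.year, {"FN": 0, "FY": 0, "MN": 0})[r.state.value] += 1
    years = sorted(counts)
    report: dict = {"per_year_counts": {y: counts[y] for y in years}}
    total = {s: sum(counts[y][s] for y in years) for s in ("FN", "FY", "MN")}
    n_unamb = sum(total.values())
    if n_unamb:
        females = total["FN"] + total["FY"]
        report["p_hat"] = females / n_unamb
        report["q_hat"] = total["FY"] / females if females else float("nan")
    if len(years) < 2 or n_unamb < 10:
        report["sufficient"] = False
        return report
    table = np.array([[counts[y][s] for s in ("FN", "FY", "MN")] for y in years])
    keep_cols = table.sum(axis=0) > 0
    keep_rows = table.sum(axis=1) > 0
    table = table[np.ix_(keep_rows, keep_cols)]
    if min(table.shape) < 2:
        report["sufficient"] = False
        return report
    chi2, pval, dof, _ = chi2_contingency(table)
    report.update({"sufficient": True, "chi2": float(chi2), "pvalue": float(pval), "dof": int(dof)})
    return report
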
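"""Bayesian fitting of the SMFM by adaptive random-walk Metropolis.

Parameters are sampled on transformed (unconstrained) scales: log for
rates, strengths, gamma and rho; logit for the learning rates; identity
for covariate contrasts and random-effect values.  Priors are proper and
overridable; the defaults are half-normal for positive parameters (scale
ten times a plausible magnitude), uniform(0, 1) for learning rates,
normal(0, 2^2) for covariate contrasts and half-normal(0, 1) for
random-effect SDs.  Chains are initialized at a MAP estimate found with
scipy and proposals use a covariance adapted during burn-in toward an
acceptance rate of 0.234.

Summaries follow common practice for this class of model: posterior
medians with 95% highest-posterior-density intervals, posterior
probabilities of parameter inequalities, split-R-hat/ESS convergence
diagnostics (via ArviZ) and DIC = Dbar + pD with pD evaluated at the
posterior mean of the transformed parameters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .event_model import AGE_CLASSES, DOMINANCE, EventLog
from .smfm_core import (BETA_KEYS, ModelVariant, OBS_CLASSES, OPTION_TYPES,
                        SMFMLikelihood, SMFMParams)

__all__ = [
    "Prior", "PriorSpec", "MCMCConfig", "PosteriorChains",
    "PosteriorSummary", "ParamSpace", "build_param_space", "run_mcmc",
    "adaptive_metropolis", "hpd_interval", "posterior_prob", "dic",
    "dic_stats", "summarize", "compare_variants",
]


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Prior:
    """A proper univariate prior: halfnormal(scale), normal(mu, sd) or
    uniform(lo, hi), evaluated on the parameter's natural scale."""

    family: str
    a: float
    b: float = 0.0

    def logpdf(self, x: float) -> float:
        if self.family == "halfnormal":
            return stats.halfnorm.logpdf(x, scale=self.a)
        if self.family == "normal":
            return stats.norm.logpdf(x, loc=self.a, scale=self.b)
        if self.family == "uniform":
            if self.a <= x <= self.b:
                return -math.log(self.b - self.a)
            return -np.inf
        raise ValueError(f"unknown prior family {self.family!r}")

    def median(self) -> float:
        if self.family == "halfnormal":
            return float(stats.halfnorm.median(scale=self.a))
        if self.family == "normal":
            return self.a
        if self.family == "uniform":
            return 0.5 * (self.a + self.b)
        raise ValueError(self.family)


class PriorSpec(dict):
    """Mapping parameter name -> :class:`Prior`, with documented defaults.

    Names follow the free-parameter naming of :class:`ParamSpace`
    (``r:flap``, ``lambda``, ``s:entry``, ``gamma``, ``g:specific``,
    ``rho``, ``beta:sex=M``, ``sigma_ind``, ``u:<id>``, ...).
    """

    def prior_for(self, name: str) -> Prior:
        if name in self:
            return self[name]
        return default_prior(name)


def default_prior(name: str) -> Prior:
    base = name.split(":")[0]
    if base == "r":
        return Prior("halfnormal", 0.05)
    if base in ("lambda", "s"):
        return Prior("uniform", 0.0, 1.0)
    if base == "gamma":
        return Prior("halfnormal", 20.0)
    if base == "g":
        return Prior("halfnormal", 50.0)
    if base == "rho":
        return Prior("halfnormal", 0.5)
    if base == "beta":
        return Prior("normal", 0.0, 2.0)
    if base in ("sigma_ind", "sigma_group"):
        return Prior("halfnormal", 1.0)
    raise ValueError(f"no default prior for {name!r}")


# ---------------------------------------------------------------------------
# Parameter space: free parameters, transforms, pack/unpack
# ---------------------------------------------------------------------------

def _logit(x):
    return math.log(x) - math.log1p(-x)


@dataclass(frozen=True)
class FreeParam:
    name: str
    kind: str                    # "log" | "logit" | "identity"
    prior: Prior
    attr: str                    # SMFMParams attribute
    keys: tuple                  # dict keys to set (empty => scalar attr)
    hier: str | None = None      # "ind"/"group": prior is N(0, sigma_*)


class ParamSpace:
    """Free-parameter vector <-> :class:`SMFMParams` mapping with priors."""

    def __init__(self, free: list[FreeParam], template: SMFMParams):
        self.free = list(free)
        self.template = template.copy()
        self.names = [f.name for f in self.free]
        self.dim = len(self.free)
        self._kinds = np.array([f.kind for f in self.free])

    # transforms -----------------------------------------------------------
    def natural(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        x = z.copy()
        x[..., self._kinds == "log"] = np.exp(z[..., self._kinds == "log"])
        x[..., self._kinds == "logit"] = special.expit(
            z[..., self._kinds == "logit"])
        return x

    def z_from_natural(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        z = x.copy()
        for j, f in enumerate(self.free):
            if f.kind == "log":
                z[..., j] = np.log(x[..., j])
            elif f.kind == "logit":
                z[..., j] = special.logit(x[..., j])
        return z

    def natural_from_params(self, params: SMFMParams) -> np.ndarray:
        out = np.empty(self.dim)
        for j, f in enumerate(self.free):
            obj = getattr(params, f.attr)
            out[j] = obj[f.keys[0]] if f.keys else obj
        return out

    def to_params(self, z: np.ndarray) -> SMFMParams:
        x = self.natural(z)
        p = self.template.copy()
        for j, f in enumerate(self.free):
            if f.keys:
                d = getattr(p, f.attr)
                for key in f.keys:
                    d[key] = float(x[j])
            else:
                setattr(p, f.attr, float(x[j]))
        return p

    def log_prior(self, z: np.ndarray) -> float:
        x = self.natural(z)
        total = 0.0
        sigma = {"ind": None, "group": None}
        for j, f in enumerate(self.free):
            if f.attr == "sigma_ind":
                sigma["ind"] = x[j]
            elif f.attr == "sigma_group":
                sigma["group"] = x[j]
        for j, f in enumerate(self.free):
            if f.hier:
                sd = sigma[f.hier]
                if sd is None:
                    sd = self.template.sigma_ind if f.hier == "ind" \
                        else self.template.sigma_group
                if not sd > 0:
                    return -np.inf
                lp = stats.norm.logpdf(x[j], scale=sd)
            else:
                lp = f.prior.logpdf(x[j])
            if not np.isfinite(lp):
                return -np.inf
            total += lp
            if f.kind == "log":
                total += z[j]
            elif f.kind == "logit":
                # expit saturates in floating point for |z| > ~37
                if not 0.0 < x[j] < 1.0:
                    return -np.inf
                total += math.log(x[j]) + math.log1p(-x[j])
        return total

    def initial_natural(self) -> np.ndarray:
        """Template values where valid, prior medians otherwise."""
        out = self.natural_from_params(self.template)
        for j, f in enumerate(self.free):
            bad = not np.isfinite(out[j])
            if f.kind == "log" and out[j] <= 0:
                bad = True
            if f.kind == "logit" and not 0 < out[j] < 1:
                bad = True
            if f.hier and out[j] == 0.0:
                out[j] = 0.0  # centred start for random effects is fine
                continue
            if bad:
                out[j] = f.prior.median() if not f.hier else 0.0
            if f.kind == "logit" and out[j] in (0.0, 1.0):
                out[j] = 0.01 if out[j] == 0.0 else 0.99
        return out


def build_param_space(variant: ModelVariant, template: SMFMParams,
                      priors: PriorSpec | None = None,
                      individual_ids: tuple = (),
                      group_ids: tuple = ()) -> ParamSpace:
    """Assemble the free-parameter space implied by a model variant.

    The template supplies every value the variant keeps fixed (e.g. the
    social classes not listed, or zeroed transient strengths when
    ``variant.transient`` is off).
    """
    priors = priors or PriorSpec()
    template = template.copy()
    if not variant.transient:
        for name in ("g_general", "g_box", "g_specific", "g_sametype"):
            setattr(template, name, {a: 0.0 for a in AGE_CLASSES})
    if not variant.sametype_kernel:
        template.g_sametype = {a: 0.0 for a in AGE_CLASSES}
    free: list[FreeParam] = []

    def add(name, kind, attr, keys, hier=None):
        if hier is None:
            prior = priors.prior_for(name)
        else:  # placeholder; hierarchical params use N(0, sigma) at run time
            prior = priors[name] if name in priors else Prior("normal", 0, 1)
        free.append(FreeParam(name, kind, prior, attr, tuple(keys), hier))

    for k in OPTION_TYPES:
        add(f"r:{k}", "log", "r", [k])
    if variant.lambda_by_dominance:
        for d in DOMINANCE:
            add(f"lambda:{d}", "logit", "lambda_a", [d])
    else:
        add("lambda", "logit", "lambda_a", list(DOMINANCE))
    for c in variant.social_classes:
        if c not in OBS_CLASSES:
            raise ValueError(f"unknown observation class {c!r}")
        add(f"s:{c}", "logit", "s", [c])
    add("gamma", "log", "gamma", [])
    if variant.transient:
        kernels = ["general", "box", "specific"]
        if variant.sametype_kernel:
            kernels.append("sametype")
        for kern in kernels:
            if variant.g_by_age:
                for a in AGE_CLASSES:
                    add(f"g:{kern}:{a}", "log", "g_" + kern, [a])
            else:
                add(f"g:{kern}", "log", "g_" + kern, list(AGE_CLASSES))
        add("rho", "log", "rho", [])
    for key in variant.covariates:
        if key not in BETA_KEYS:
            raise ValueError(f"unknown covariate {key!r}")
        add(f"beta:{key}", "identity", "beta", [key])
    if variant.random_effects:
        add("sigma_ind", "log", "sigma_ind", [])
        add("sigma_group", "log", "sigma_group", [])
        for iid in individual_ids:
            add(f"u:{iid}", "identity", "u", [iid], hier="ind")
        for gid in group_ids:
            add(f"v:{gid}", "identity", "v", [gid], hier="group")
    return ParamSpace(free, template)


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MCMCConfig:
    n_chains: int = 2
    n_iter: int = 3000
    n_burn: int = 1000
    thin: int = 1
    seed: int = 0
    target_accept: float = 0.234
    init: str = "map"            # "map" | "template"
    jitter: float = 0.1
    map_maxiter: int = 300

    def __post_init__(self):
        if not self.n_iter > self.n_burn >= 0:
            raise ValueError("need n_iter > n_burn >= 0")
        if self.n_chains < 1:
            raise ValueError("need n_chains >= 1")


def adaptive_metropolis(log_target, x0: np.ndarray, n_iter: int,
                        n_burn: int, thin: int, rng: np.random.Generator,
                        cov0: np.ndarray | None = None,
                        target_accept: float = 0.234):
    """Single-block adaptive random-walk Metropolis.

    The proposal is multivariate normal with covariance
    ``exp(log_s) * (2.38^2/d) * C``; the global scale adapts by
    Robbins-Monro toward *target_accept* during burn-in and the shape C is
    re-estimated once, halfway through burn-in, from the accumulated
    history.  Returns (draws, log-target values, post-burn acceptance rate).
    """
    x0 = np.asarray(x0, dtype=float)
    d = len(x0)
    C = np.eye(d) * 0.01 if cov0 is None else np.array(cov0, dtype=float)
    L = _safe_cholesky(C)
    log_s = 0.0
    x = x0.copy()
    lp = log_target(x)
    if not np.isfinite(lp):
        raise ValueError("non-finite log target at the initial point")
    history = []
    draws, lps = [], []
    kept_accepts = 0
    kept_total = 0
    base = 2.38 / math.sqrt(d)
    adapt_t = 0
    for it in range(n_iter):
        step = math.exp(0.5 * log_s) * base
        prop = x + step * (L @ rng.standard_normal(d))
        lpp = log_target(prop)
        accept = np.isfinite(lpp) and \
            math.log(rng.uniform()) < lpp - lp
        if accept:
            x, lp = prop, lpp
        if it < n_burn:
            adapt_t += 1
            gain = adapt_t ** -0.6
            log_s += gain * ((1.0 if accept else 0.0) - target_accept)
            history.append(x.copy())
            if it in (max(n_burn // 3, 10), max(2 * n_burn // 3, 20)) \
                    and len(history) > 2 * d:
                H = np.array(history[len(history) // 2:])
                C = np.cov(H.T) + 1e-8 * np.eye(d)
                L = _safe_cholesky(np.atleast_2d(C))
                adapt_t = 0  # re-tune the scale for the new shape
        else:
            kept_total += 1
            kept_accepts += 1 if accept else 0
            if (it - n_burn) % thin == 0:
                draws.append(x.copy())
                lps.append(lp)
    rate = kept_accepts / kept_total if kept_total else math.nan
    return np.array(draws), np.array(lps), rate


def _laplace_cov(log_post, z0: np.ndarray, step: float = 1e-3):
    """Inverse negative Hessian of the log posterior at z0 (central
    differences), eigenvalue-clipped; None if it comes out unusable."""
    d = len(z0)
    H = np.zeros((d, d))
    f0 = log_post(z0)
    if not np.isfinite(f0):
        return None
    e = np.eye(d) * step
    fp = np.array([log_post(z0 + e[i]) for i in range(d)])
    fm = np.array([log_post(z0 - e[i]) for i in range(d)])
    if not (np.all(np.isfinite(fp)) and np.all(np.isfinite(fm))):
        return None
    for i in range(d):
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / step ** 2
        for j in range(i + 1, d):
            fpp = log_post(z0 + e[i] + e[j])
            fmm = log_post(z0 - e[i] - e[j])
            if not (np.isfinite(fpp) and np.isfinite(fmm)):
                return None
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + f0 +
                                 fmm - fm[i] - fm[j] + f0) / \
                (2.0 * step ** 2)
    w, V = np.linalg.eigh(-0.5 * (H + H.T))
    if not np.all(np.isfinite(w)):
        return None
    w = np.clip(w, 1e-4, None)  # floor: avoid exploding proposal axes
    cov = (V / w) @ V.T
    return 0.5 * (cov + cov.T)


def _safe_cholesky(C: np.ndarray) -> np.ndarray:
    C = np.atleast_2d(np.asarray(C, dtype=float))
    C = 0.5 * (C + C.T)
    for jit in (0.0, 1e-10, 1e-8, 1e-6, 1e-4):
        try:
            return np.linalg.cholesky(C + jit * np.eye(len(C)))
        except np.linalg.LinAlgError:
            continue
    return np.diag(np.sqrt(np.clip(np.diag(C), 1e-12, None)))


@dataclass
class PosteriorChains:
    """MCMC draws on the transformed scale plus per-draw data log-likelihood."""

    z: np.ndarray                 # (n_chains, n_draws, dim)
    loglik: np.ndarray            # (n_chains, n_draws)
    logpost: np.ndarray           # (n_chains, n_draws)
    acceptance: np.ndarray        # (n_chains,)
    space: ParamSpace
    config: MCMCConfig
    variant: ModelVariant | None = None

    @property
    def names(self) -> list[str]:
        return self.space.names

    def natural_draws(self) -> np.ndarray:
        """Draws mapped to the natural scale, shape (n_chains, n_draws, dim)."""
        return self.space.natural(self.z)

    def flat(self) -> np.ndarray:
        nat = self.natural_draws()
        return nat.reshape(-1, nat.shape[-1])

    def to_frame(self) -> pd.DataFrame:
        nat = self.natural_draws()
        n_chains, n_draws, dim = nat.shape
        df = pd.DataFrame(nat.reshape(-1, dim), columns=self.names)
        df.insert(0, "chain", np.repeat(np.arange(n_chains), n_draws))
        df.insert(1, "draw", np.tile(np.arange(n_draws), n_chains))
        df["loglik"] = self.loglik.reshape(-1)
        return df


def run_mcmc(log: EventLog, variant: ModelVariant,
             priors: PriorSpec | None = None,
             config: MCMCConfig | None = None,
             template: SMFMParams | None = None,
             likelihood: SMFMLikelihood | None = None) -> PosteriorChains:
    """Sample the SMFM posterior for one model variant.

    The prior x likelihood target is sampled with
    :func:`adaptive_metropolis`; runs are exactly reproducible given
    ``config.seed``.  ``template`` fixes every parameter the variant does
    not free (defaults to a neutral parameter set).
    """
    config = config or MCMCConfig()
    template = template or SMFMParams.build(
        r=1.6e-4, lambda_a=0.02, s={"entry": 0.002}, gamma=1.0,
        g_general=0.5, g_box=0.5, g_specific=0.5)
    likelihood = likelihood or SMFMLikelihood(log,
                                              condition=variant.condition)
    space = build_param_space(
        variant, template, priors,
        individual_ids=tuple(likelihood.individual_ids),
        group_ids=tuple(likelihood.group_ids))

    def log_post(z):
        lp = space.log_prior(z)
        if not np.isfinite(lp):
            return -np.inf
        return lp + likelihood.loglik(space.to_params(z))

    z0 = space.z_from_natural(space.initial_natural())
    if not np.isfinite(log_post(z0)):
        raise ValueError("non-finite log posterior at the initial point; "
                         "check template/prior compatibility with the data")
    cov0 = np.eye(space.dim) * 0.01
    if config.init == "map":
        res = optimize.minimize(lambda z: -log_post(z), z0,
                                method="L-BFGS-B",
                                options={"maxiter": config.map_maxiter})
        if np.isfinite(res.fun):
            z0 = res.x
            lap = _laplace_cov(log_post, z0)
            if lap is not None:
                cov0 = lap

    all_z, all_ll, all_lp, rates = [], [], [], []
    for chain in range(config.n_chains):
        rng = np.random.default_rng([config.seed, chain])
        start = z0
        for _ in range(100):
            cand = z0 + config.jitter * rng.standard_normal(space.dim)
            if np.isfinite(log_post(cand)):
                start = cand
                break
        else:
            raise ValueError("could not find a finite starting point")
        draws, lps, rate = adaptive_metropolis(
            log_post, start, config.n_iter, config.n_burn, config.thin, rng,
            cov0=cov0, target_accept=config.target_accept)
        # data log-likelihood per draw: log posterior minus log prior
        lls = lps - np.array([space.log_prior(z) for z in draws])
        all_z.append(draws)
        all_ll.append(lls)
        all_lp.append(lps)
        rates.append(rate)
    return PosteriorChains(z=np.array(all_z), loglik=np.array(all_ll),
                           logpost=np.array(all_lp),
                           acceptance=np.array(rates), space=space,
                           config=config, variant=variant)


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------

def hpd_interval(draws, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ceil(mass * n) sorted draws."""
    draws = np.sort(np.asarray(draws, dtype=float))
    n = len(draws)
    if n < 100:
        raise ValueError("need at least 100 draws for an HPD interval")
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    m = int(math.ceil(mass * n))
    widths = draws[m - 1:] - draws[:n - m + 1]
    j = int(np.argmin(widths))
    return float(draws[j]), float(draws[j + m - 1])


def posterior_prob(draws, op: str = "le", value: float = 0.0) -> float:
    """Fraction of draws satisfying the stated inequality."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("empty draws")
    cmp = {"le": draws <= value, "lt": draws < value,
           "ge": draws >= value, "gt": draws > value}
    if op not in cmp:
        raise ValueError(f"unknown inequality {op!r}")
    return float(np.mean(cmp[op]))


def _diagnostics(nat: np.ndarray, names: list[str]) -> pd.DataFrame:
    import arviz as az
    data = {name: nat[:, :, j] for j, name in enumerate(names)}
    idata = az.from_dict(posterior=data)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ess = az.ess(idata)
        rhat = az.rhat(idata) if nat.shape[0] > 1 else None
    rows = {}
    for name in names:
        rows[name] = {
            "ess": float(ess[name].values),
            "rhat": float(rhat[name].values) if rhat is not None
            else math.nan}
    return pd.DataFrame(rows).T


@dataclass
class PosteriorSummary:
    table: pd.DataFrame                    # per parameter
    contrasts: pd.DataFrame                # per requested contrast
    hpd_mass: float
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"hpd_mass": self.hpd_mass,
                "parameters": self.table.to_dict(orient="index"),
                "contrasts": self.contrasts.to_dict(orient="index"),
                "warnings": list(self.warnings)}


def summarize(chains: PosteriorChains, contrasts: dict | None = None,
              hpd_mass: float = 0.95, rhat_threshold: float = 1.05,
              ess_threshold: float = 200.0) -> PosteriorSummary:
    """Medians, HPD intervals, diagnostics and inequality probabilities.

    ``contrasts`` maps a label to either a callable on the draws DataFrame
    or a string ``"name1 - name2"``; each contrast is summarised by its
    median, HPD interval and posterior probability of being <= 0.
    """
    nat = chains.natural_draws()
    names = chains.names
    diag = _diagnostics(nat, names)
    flat = chains.flat()
    rows = {}
    warns = []
    for j, name in enumerate(names):
        lo, hi = hpd_interval(flat[:, j], hpd_mass)
        rows[name] = {"median": float(np.median(flat[:, j])),
                      "hpd_lo": lo, "hpd_hi": hi,
                      "ess": diag.loc[name, "ess"],
                      "rhat": diag.loc[name, "rhat"]}
        if np.isfinite(rows[name]["rhat"]) and \
                rows[name]["rhat"] > rhat_threshold:
            warns.append(f"{name}: R-hat {rows[name]['rhat']:.3f} exceeds "
                         f"{rhat_threshold}")
        if rows[name]["ess"] < ess_threshold:
            warns.append(f"{name}: ESS {rows[name]['ess']:.0f} below "
                         f"{ess_threshold:.0f}")
    table = pd.DataFrame(rows).T
    cdf = pd.DataFrame(flat, columns=names)
    crows = {}
    for label, expr in (contrasts or {}).items():
        if callable(expr):
            vals = np.asarray(expr(cdf), dtype=float)
        else:
            a, b = (s.strip() for s in expr.split("-"))
            vals = cdf[a].to_numpy() - cdf[b].to_numpy()
        lo, hi = hpd_interval(vals, hpd_mass)
        crows[label] = {"median": float(np.median(vals)), "hpd_lo": lo,
                        "hpd_hi": hi, "p_le_0": posterior_prob(vals)}
    return PosteriorSummary(table=table,
                            contrasts=pd.DataFrame(crows).T if crows
                            else pd.DataFrame(
                                columns=["median", "hpd_lo", "hpd_hi",
                                         "p_le_0"]),
                            hpd_mass=hpd_mass, warnings=warns)


# ---------------------------------------------------------------------------
# DIC
# ---------------------------------------------------------------------------

def dic_stats(deviance_draws: np.ndarray, deviance_at_point: float):
    """DIC components from per-draw deviances and a plug-in deviance."""
    dbar = float(np.mean(deviance_draws))
    pd_ = dbar - float(deviance_at_point)
    return dbar + pd_, dbar, pd_


def dic(chains: PosteriorChains,
        likelihood: SMFMLikelihood) -> tuple[float, float, float]:
    """(DIC, Dbar, pD) with the plug-in at the posterior mean of the
    transformed parameters.  Emits a warning (not a failure) if pD < 0."""
    dev = -2.0 * chains.loglik.reshape(-1)
    zbar = chains.z.reshape(-1, chains.space.dim).mean(axis=0)
    dev_hat = -2.0 * likelihood.loglik(chains.space.to_params(zbar))
    out = dic_stats(dev, dev_hat)
    if out[2] < 0:
        warnings.warn(f"negative pD ({out[2]:.2f}); DIC may be unreliable")
    return out


def compare_variants(log: EventLog, variants: list[ModelVariant],
                     priors: PriorSpec | None = None,
                     config: MCMCConfig | None = None,
                     template: SMFMParams | None = None,
                     rhat_threshold: float = 1.05) -> pd.DataFrame:
    """Fit each variant and tabulate DIC differences from the first.

    The returned frame has one row per variant with DIC, Dbar, pD, the
    difference from the reference (first) variant, a Monte-Carlo standard
    error for Dbar and a convergence flag (max split-R-hat).
    """
    if len(variants) < 2:
        raise ValueError("need at least two variants to compare")
    rows = []
    for m, variant in enumerate(variants):
        cfg = config or MCMCConfig()
        cfg = replace(cfg, seed=cfg.seed + 7919 * m)
        lik = SMFMLikelihood(log, condition=variant.condition)
        chains = run_mcmc(log, variant, priors=priors, config=cfg,
                          template=template, likelihood=lik)
        d, dbar, pd_ = dic(chains, lik)
        dev = -2.0 * chains.loglik.reshape(-1)
        import arviz as az
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess_dev = float(az.ess(az.from_dict(
                posterior={"dev": -2.0 * chains.loglik}))["dev"].values)
            nat = chains.natural_draws()
            rhat_max = math.nan
            if chains.z.shape[0] > 1:
                idata = az.from_dict(posterior={
                    name: nat[:, :, j]
                    for j, name in enumerate(chains.names)})
                rhat_max = float(az.rhat(idata).to_array().max())
        se = float(np.std(dev, ddof=1) / math.sqrt(max(ess_dev, 1.0)))
        rows.append({"variant": variant.label, "condition":
                     variant.condition, "transient": variant.transient,
                     "dic": d, "dbar": dbar, "pd": pd_, "dic_se": se,
                     "rhat_max": rhat_max,
                     "converged": (not np.isfinite(rhat_max)) or
                     rhat_max <= rhat_threshold})
    df = pd.DataFrame(rows)
    df["delta_dic"] = df["dic"] - df["dic"].iloc[0]
    return df
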
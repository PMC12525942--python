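"""SAEM estimation and the model-assessment battery.

``fit`` estimates a :class:`~vitd_pbpk.population.PopulationModel` from a
trial dataset by stochastic-approximation EM:

* E-step: per child (and chain), a random-walk Metropolis-Hastings
  kernel on the random effects eta, with proposal scales adapted toward
  a 40% acceptance rate during burn-in;
* M-step: fixed effects carrying random effects update through
  stochastically smoothed sufficient statistics of phi = theta + eta;
  fixed effects without random effects take a damped Gauss-Newton step
  with forward-difference sensitivities; residual error components are
  re-optimised each iteration and smoothed.

Step sizes are 1 during burn-in and decay as 1/k in the accumulation
phase. The marginal log-likelihood for AIC/BIC (and standard errors via
a finite-difference Fisher information) is computed by adaptive
Gauss-Hermite quadrature for one random effect and a Laplace
approximation otherwise.

Diagnostics: FOCE-linearised conditional weighted residuals (CWRES),
normalised prediction distribution errors (NPDE), a visual predictive
check (VPC) binned by nominal visit time, and a seasonal sinusoid fit
for baseline 25(OH)D series.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtri

from .config import HOURS_PER_YEAR
from .errors import DataError, InvalidInputError
from .population import (
    ModelVariant,
    PopulationModel,
    build_variant,
    residual_variance,
)
from .predict import EtaGridInterpolator, predict_child
from .records import ChildRecord

__all__ = [
    "SaemSettings",
    "FitResult",
    "fit",
    "loglikelihood",
    "linear_scale_report",
    "eta_shrinkage",
    "cwres",
    "npde",
    "vpc",
    "VpcResult",
    "information_criteria",
    "fit_seasonal_baseline",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# settings / results
# ---------------------------------------------------------------------------


@dataclass
class SaemSettings:
    """SAEM run configuration (defaults: 300 burn-in + 200 accumulation,
    2 chains, 1 Metropolis proposal per child per iteration)."""

    n_burn: int = 300
    n_iter: int = 200
    n_chains: int = 2
    seed: int = 0
    n_mh: int = 1
    estimate_sigma: bool = True
    compute_se: bool = True
    agq_nodes: int = 9
    gn_damping: float = 0.7      # burn-in damping of the Gauss-Newton step
    max_step: float = 0.25       # per-iteration cap on no-IIV theta moves (log units)
    anneal: float = 0.95         # burn-in floor factor on variance components


@dataclass
class FitResult:
    """Estimates, uncertainty, per-child EBEs and fit metrics."""

    population: PopulationModel
    estimated: tuple[str, ...]
    theta_se: dict[str, float]
    ebes: dict
    loglik: float
    n_params: int
    n_obs: int
    aic: float
    bic: float
    shrinkage: dict[str, float]
    converged: bool
    n_lloq_excluded: int = 0
    history: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def theta(self) -> dict[str, float]:
        return self.population.theta

    def summary(self) -> pd.DataFrame:
        """Fixed-effect table: log-scale estimate, SE, %RSE, linear 95% CI."""
        rows = []
        for name in self.estimated:
            th = self.population.theta[name]
            se = self.theta_se.get(name, float("nan"))
            if math.isfinite(se):
                est, (lo, hi), rse = linear_scale_report(th, se)
            else:  # SEs not computed for this run
                est, lo, hi, rse = math.exp(th), float("nan"), float("nan"), float("nan")
            rows.append((name, th, se, rse, est, lo, hi))
        return pd.DataFrame(
            rows,
            columns=["parameter", "log_estimate", "log_se", "rse_pct",
                     "estimate", "ci95_lo", "ci95_hi"],
        )

    def to_json(self, path: str | Path, metadata: dict | None = None) -> None:
        payload = {
            "variant_id": self.population.variant.variant_id,
            "theta": self.population.theta,
            "theta_se": self.theta_se,
            "omega": self.population.omega,
            "sigma_add": self.population.sigma_add,
            "sigma_prop": self.population.sigma_prop,
            "estimated": list(self.estimated),
            "ebes": {str(k): v for k, v in self.ebes.items()},
            "loglik": self.loglik,
            "n_params": self.n_params,
            "n_obs": self.n_obs,
            "aic": self.aic,
            "bic": self.bic,
            "shrinkage": self.shrinkage,
            "converged": self.converged,
            "n_lloq_excluded": self.n_lloq_excluded,
            "metadata": metadata or {},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path, config=None) -> "FitResult":
        from .config import DEFAULT_CONFIG

        with open(path) as fh:
            d = json.load(fh)
        pop = PopulationModel(
            variant=build_variant(d["variant_id"]),
            theta=d["theta"],
            omega=d["omega"],
            sigma_add=d["sigma_add"],
            sigma_prop=d["sigma_prop"],
            theta_se=d["theta_se"],
            config=config or DEFAULT_CONFIG,
        )
        return cls(
            population=pop,
            estimated=tuple(d["estimated"]),
            theta_se=d["theta_se"],
            ebes=d["ebes"],
            loglik=d["loglik"],
            n_params=d["n_params"],
            n_obs=d["n_obs"],
            aic=d["aic"],
            bic=d["bic"],
            shrinkage=d["shrinkage"],
            converged=d["converged"],
            n_lloq_excluded=d.get("n_lloq_excluded", 0),
        )


# ---------------------------------------------------------------------------
# internal: per-child likelihood machinery
# ---------------------------------------------------------------------------


class _Child:
    """Cached fitting view of one ChildRecord."""

    def __init__(self, record: ChildRecord):
        self.record = record
        mask = record.fit_mask()
        self.times = record.obs_times_h[mask]
        self.y = record.obs_dv[mask]
        self.n = int(self.y.size)

    def predict(self, pop: PopulationModel, eta_vec, re_names) -> np.ndarray:
        eta = {k: float(v) for k, v in zip(re_names, eta_vec)}
        return predict_child(pop, self.record, eta, self.times)


def _gauss_loglik(y, f, sigma_add, sigma_prop):
    var = residual_variance(f, sigma_add, sigma_prop)
    var = np.maximum(var, 1e-12)
    return float(-0.5 * np.sum((y - f) ** 2 / var + np.log(2.0 * np.pi * var)))


def _prepare(dataset, pop) -> tuple[list[_Child], int, int]:
    children = []
    n_lloq = 0
    for rec in dataset:
        if rec.n_obs < 1:
            raise DataError(f"child {rec.id}: no observations")
        n_lloq += int(np.sum(rec.lloq_flags))
        children.append(_Child(rec))
    n_obs = sum(c.n for c in children)
    if n_lloq:
        logger.info("excluded %d below-LLOQ observations from the likelihood", n_lloq)
    return children, n_obs, n_lloq


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit(
    dataset: list[ChildRecord],
    model: PopulationModel | ModelVariant | int,
    settings: SaemSettings | None = None,
    estimate: tuple[str, ...] | None = None,
) -> FitResult:
    """Fit a population model to a trial dataset by SAEM.

    ``model`` may be a variant id, a ModelVariant (initial values are
    package defaults) or a PopulationModel carrying initial values.
    ``estimate`` names the fixed effects to estimate; it defaults to the
    published estimation set — CLmax and, for fat/lean-split variants,
    Kp25fm (partition coefficients fixed elsewhere are kept at their
    configured values). Random-effect variances for the variant's
    random effects and both residual components are always estimated
    (unless ``settings.estimate_sigma`` is off).

    Reproducible: identical seed + data give identical estimates.
    """
    s = settings or SaemSettings()
    rng = np.random.default_rng(s.seed)
    pop = _initial_population(model)
    variant = pop.variant
    re_names = tuple(k for k in variant.random_effects if k in pop.omega)
    if estimate is None:
        estimate = tuple(
            n for n in ("clmax", "kp25_fm") if n in variant.fixed_effects
        )
    unknown = set(estimate) - set(variant.fixed_effects)
    if unknown:
        raise DataError(f"cannot estimate {sorted(unknown)}: not fixed effects "
                        f"of variant {variant.variant_id}")
    theta_f_names = tuple(n for n in estimate if n not in re_names)
    theta_r_names = tuple(n for n in estimate if n in re_names)

    children, n_obs, n_lloq = _prepare(dataset, pop)
    n = len(children)
    theta = dict(pop.theta)
    defaults = _initial_population(variant).theta
    for name in estimate:
        theta.setdefault(name, defaults[name])
    omega = {k: max(pop.omega[k], 1e-4) for k in re_names}
    sig_a, sig_p = max(pop.sigma_add, 1e-3), max(pop.sigma_prop, 1e-3)

    nc = s.n_chains
    etas = np.zeros((nc, n, len(re_names)))
    prop_sd = np.tile(
        np.array([0.4 * math.sqrt(omega[k] + 0.04) for k in re_names]), (n, 1)
    )
    cur_f = [[None] * n for _ in range(nc)]
    cur_ll = np.full((nc, n), -np.inf)

    def popmod():
        return pop.replace(
            theta=dict(theta), omega=dict(omega), sigma_add=sig_a, sigma_prop=sig_p
        )

    # smoothed sufficient statistics of phi = theta + eta
    s_phi1 = {k: theta[k] for k in re_names}
    s_phi2 = {k: theta[k] ** 2 + omega[k] for k in re_names}
    hist = []
    total_iters = s.n_burn + s.n_iter
    accepts = np.zeros(n)

    for it in range(total_iters):
        gamma = 1.0 if it < s.n_burn else 1.0 / (it - s.n_burn + 1)
        pm = popmod()
        accepts[:] = 0.0
        for c in range(nc):
            for i, ch in enumerate(children):
                if ch.n == 0:
                    continue
                # refresh the current likelihood (theta_f / covariance moved)
                f_cur = ch.predict(pm, etas[c, i], re_names)
                ll_cur = _gauss_loglik(ch.y, f_cur, sig_a, sig_p) + _log_prior(
                    etas[c, i], omega, re_names
                )
                for _ in range(s.n_mh):
                    prop = etas[c, i] + rng.normal(size=len(re_names)) * prop_sd[i]
                    f_prop = ch.predict(pm, prop, re_names)
                    ll_prop = _gauss_loglik(ch.y, f_prop, sig_a, sig_p) + _log_prior(
                        prop, omega, re_names
                    )
                    if math.log(rng.random()) < ll_prop - ll_cur:
                        etas[c, i] = prop
                        f_cur, ll_cur = f_prop, ll_prop
                        accepts[i] += 1.0
                cur_f[c][i] = f_cur
                cur_ll[c, i] = ll_cur
        if it < s.n_burn and len(re_names):
            rate = accepts / (s.n_mh * nc)
            prop_sd *= np.exp(0.4 * (rate - 0.4))[:, None]
            np.clip(prop_sd, 1e-3, 3.0, out=prop_sd)

        # --- M-step: random-effect-bearing fixed effects + omega ---
        old_theta = dict(theta)
        for j, k in enumerate(re_names):
            phi = theta[k] + etas[:, :, j]
            m1 = float(np.mean(phi))
            m2 = float(np.mean(phi ** 2))
            s_phi1[k] = (1 - gamma) * s_phi1[k] + gamma * m1
            s_phi2[k] = (1 - gamma) * s_phi2[k] + gamma * m2
            if k in theta_r_names:
                theta[k] = s_phi1[k]
            om_mle = max(s_phi2[k] - s_phi1[k] ** 2, 1e-6)
            if it < s.n_burn:
                # simulated annealing: keep variances from collapsing
                # before the eta chains have explored the posterior
                om_mle = max(om_mle, s.anneal * omega[k])
            omega[k] = om_mle
        for j, k in enumerate(re_names):
            # keep phi = theta + eta invariant under the theta shift
            etas[:, :, j] += old_theta[k] - theta[k]

        # --- M-step: no-IIV fixed effects (damped Gauss-Newton) ---
        if theta_f_names:
            pm = popmod()
            nf = len(theta_f_names)
            A = np.zeros((nf, nf))
            b = np.zeros(nf)
            h = 1e-3
            for c in range(nc):
                for i, ch in enumerate(children):
                    if ch.n == 0:
                        continue
                    f0 = cur_f[c][i] + 0.0
                    G = np.empty((ch.n, nf))
                    for q, name in enumerate(theta_f_names):
                        pmq = pm.replace(theta={**pm.theta, name: pm.theta[name] + h})
                        G[:, q] = (ch.predict(pmq, etas[c, i], re_names) - f0) / h
                    w = 1.0 / np.maximum(
                        residual_variance(f0, sig_a, sig_p), 1e-12
                    )
                    A += G.T @ (G * w[:, None])
                    b += G.T @ ((ch.y - f0) * w)
            A += np.eye(nf) * 1e-8
            step = np.linalg.solve(A, b)
            damp = s.gn_damping if it < s.n_burn else gamma
            step = np.clip(damp * step, -s.max_step, s.max_step)
            for q, name in enumerate(theta_f_names):
                theta[name] += float(step[q])

        # --- M-step: residual error ---
        if s.estimate_sigma:
            ys = np.concatenate([ch.y for ch in children if ch.n] * nc)
            fs = np.concatenate(
                [cur_f[c][i] for c in range(nc) for i, ch in enumerate(children) if ch.n]
            )
            sa2, sp2 = _optimize_sigma(ys, fs, sig_a, sig_p)
            if it < s.n_burn:
                sa2 = max(sa2, s.anneal * sig_a ** 2)
                sp2 = max(sp2, s.anneal * sig_p ** 2)
            sig_a = math.sqrt((1 - gamma) * sig_a ** 2 + gamma * sa2)
            sig_p = math.sqrt((1 - gamma) * sig_p ** 2 + gamma * sp2)

        hist.append(
            dict(iteration=it, phase="burn" if it < s.n_burn else "accum",
                 **{f"theta_{k}": theta[k] for k in estimate},
                 **{f"omega_{k}": omega[k] for k in re_names},
                 sigma_add=sig_a, sigma_prop=sig_p)
        )

    pop_final = popmod()
    ebes = {
        ch.record.id: _ebe(ch, pop_final, re_names) for ch in children
    }
    ll = loglikelihood(dataset, pop_final, agq_nodes=s.agq_nodes)
    n_params = len(estimate) + len(re_names) + (2 if s.estimate_sigma else 0)
    aic, bic = information_criteria(ll, n_params, n_obs)
    shrink = eta_shrinkage_from_ebes(ebes, omega, re_names)
    theta_se = {}
    if s.compute_se and estimate:
        theta_se = _theta_standard_errors(dataset, pop_final, estimate, s.agq_nodes)
    converged = all(np.isfinite(v) for v in theta.values())
    if not converged:
        logger.warning("SAEM produced non-finite estimates; result flagged")
    result = FitResult(
        population=pop_final.replace(theta_se=dict(theta_se)),
        estimated=tuple(estimate),
        theta_se=theta_se,
        ebes={k: {re: float(v[j]) for j, re in enumerate(re_names)}
              for k, v in ebes.items()},
        loglik=ll,
        n_params=n_params,
        n_obs=n_obs,
        aic=aic,
        bic=bic,
        shrinkage=shrink,
        converged=converged,
        n_lloq_excluded=n_lloq,
        history=pd.DataFrame(hist),
    )
    return result


def _initial_population(model) -> PopulationModel:
    from .config import DEFAULT_CONFIG

    if isinstance(model, PopulationModel):
        return model
    variant = model if isinstance(model, ModelVariant) else build_variant(model)
    cfg = DEFAULT_CONFIG
    theta = {}
    for name in variant.fixed_effects:
        if name == "clmax":
            theta[name] = math.log(0.02)
        elif name == "kp25_fm":
            theta[name] = math.log(cfg.kp25_fm)
        elif name == "kp25_lm":
            theta[name] = math.log(cfg.kp25_lm)
        elif name in ("kp25_rb", "t_kp25rb"):
            theta[name] = math.log(cfg.kp25_rb)
        elif name == "kp25rb_zbmi":
            theta[name] = 0.0
        elif name == "c50":
            theta[name] = math.log(cfg.c50)
    omega = {k: 0.1 for k in variant.random_effects}
    return PopulationModel(
        variant=variant, theta=theta, omega=omega,
        sigma_add=1.0, sigma_prop=0.1, config=cfg,
    )


def _log_prior(eta_vec, omega, re_names) -> float:
    ll = 0.0
    for j, k in enumerate(re_names):
        w = max(omega[k], 1e-12)
        ll += -0.5 * (eta_vec[j] ** 2 / w + math.log(2.0 * math.pi * w))
    return ll


def _optimize_sigma(y, f, sig_a, sig_p) -> tuple[float, float]:
    """Complete-data MLE of (sigma_add^2, sigma_prop^2) given predictions."""
    r2 = (y - f) ** 2
    f2 = f ** 2

    def nll(x):
        sa2, sp2 = np.exp(x)
        var = sa2 + f2 * sp2
        return 0.5 * np.sum(r2 / var + np.log(var))

    x0 = np.log([max(sig_a ** 2, 1e-8), max(sig_p ** 2, 1e-8)])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 200})
    sa2, sp2 = np.exp(res.x)
    return float(min(sa2, 1e4)), float(min(sp2, 4.0))


def _neg_logpost(eta_vec, ch: _Child, pop, re_names):
    f = ch.predict(pop, eta_vec, re_names)
    return -(
        _gauss_loglik(ch.y, f, pop.sigma_add, pop.sigma_prop)
        + _log_prior(eta_vec, pop.omega, re_names)
    )


def _ebe(ch: _Child, pop: PopulationModel, re_names) -> np.ndarray:
    """Posterior mode of one child's random effects."""
    if not re_names or ch.n == 0:
        return np.zeros(len(re_names))
    if len(re_names) == 1:
        w = math.sqrt(max(pop.omega[re_names[0]], 1e-12))
        res = optimize.minimize_scalar(
            lambda e: _neg_logpost(np.array([e]), ch, pop, re_names),
            bounds=(-6 * w - 0.5, 6 * w + 0.5), method="bounded",
            options={"xatol": 1e-6},
        )
        return np.array([res.x])
    res = optimize.minimize(
        _neg_logpost, np.zeros(len(re_names)), args=(ch, pop, re_names),
        method="Nelder-Mead", options={"xatol": 1e-5, "fatol": 1e-8},
    )
    return res.x


def loglikelihood(
    dataset: list[ChildRecord], pop: PopulationModel, agq_nodes: int = 9
) -> float:
    """Marginal log-likelihood (adaptive Gauss-Hermite for 1 random effect,
    Laplace for more; exact Gaussian likelihood when all variances are 0)."""
    children, _, _ = _prepare(dataset, pop)
    re_names = tuple(k for k in pop.variant.random_effects if k in pop.omega)
    active = tuple(k for k in re_names if pop.omega[k] > 1e-10)
    total = 0.0
    for ch in children:
        if ch.n == 0:
            continue
        if not active:
            f = ch.predict(pop, np.zeros(len(re_names)), re_names)
            total += _gauss_loglik(ch.y, f, pop.sigma_add, pop.sigma_prop)
            continue
        mode = _ebe(ch, pop, re_names)
        g0 = -_neg_logpost(mode, ch, pop, re_names)
        # FD Hessian of the negative log posterior at the mode
        k = len(re_names)
        hstep = 1e-3
        H = np.empty((k, k))
        for a in range(k):
            for b in range(a, k):
                ea, eb = np.eye(k)[a] * hstep, np.eye(k)[b] * hstep
                fpp = -_neg_logpost(mode + ea + eb, ch, pop, re_names)
                fpm = -_neg_logpost(mode + ea - eb, ch, pop, re_names)
                fmp = -_neg_logpost(mode - ea + eb, ch, pop, re_names)
                fmm = -_neg_logpost(mode - ea - eb, ch, pop, re_names)
                H[a, b] = H[b, a] = -(fpp - fpm - fmp + fmm) / (4 * hstep ** 2)
        H = np.maximum(H, 1e-8) if k == 1 else H
        if k == 1:
            hh = float(H[0, 0])
            x, w = np.polynomial.hermite_e.hermegauss(agq_nodes)  # weights for N(0,1)
            # integrate exp(g(eta)) via nodes centred at the mode
            sd = 1.0 / math.sqrt(hh)
            vals = np.array(
                [-_neg_logpost(mode + sd * xi, ch, pop, re_names) for xi in x]
            )
            # e^g = e^{g} ; AGH with kernel N(mode, sd^2)
            log_terms = vals + 0.5 * x ** 2 + np.log(w / math.sqrt(2 * math.pi))
            m = np.max(log_terms)
            total += m + math.log(np.sum(np.exp(log_terms - m))) + math.log(sd)
        else:
            sign, logdet = np.linalg.slogdet(H)
            if sign <= 0:
                logdet = math.log(max(np.linalg.det(H + np.eye(k) * 1e-6), 1e-12))
            total += g0 + 0.5 * k * math.log(2 * math.pi) - 0.5 * logdet
    return float(total)


def _theta_standard_errors(dataset, pop, estimate, agq_nodes) -> dict[str, float]:
    """SEs from a central finite-difference Fisher information on theta."""
    names = list(estimate)
    k = len(names)
    h = 0.01

    def ll_at(delta):
        th = dict(pop.theta)
        for nm, d in zip(names, delta):
            th[nm] = th[nm] + d
        return loglikelihood(dataset, pop.replace(theta=th), agq_nodes)

    H = np.empty((k, k))
    ll0 = ll_at(np.zeros(k))
    for a in range(k):
        for b in range(a, k):
            ea, eb = np.eye(k)[a] * h, np.eye(k)[b] * h
            if a == b:
                lp = ll_at(ea)
                lm = ll_at(-ea)
                H[a, a] = (lp - 2 * ll0 + lm) / h ** 2
            else:
                fpp = ll_at(ea + eb)
                fpm = ll_at(ea - eb)
                fmp = ll_at(-ea + eb)
                fmm = ll_at(-ea - eb)
                H[a, b] = H[b, a] = (fpp - fpm - fmp + fmm) / (4 * h ** 2)
    fisher = -H
    try:
        cov = np.linalg.inv(fisher)
        ses = {nm: float(math.sqrt(max(cov[i, i], 0.0))) for i, nm in enumerate(names)}
    except np.linalg.LinAlgError:  # pragma: no cover
        logger.warning("singular Fisher information; SEs unavailable")
        ses = {nm: float("nan") for nm in names}
    return ses


# ---------------------------------------------------------------------------
# reporting helpers
# ---------------------------------------------------------------------------


def linear_scale_report(theta_log: float, se_log: float):
    """(estimate, (ci_lo, ci_hi), rse%) on the linear scale.

    estimate = exp(theta); CI = exp(theta +/- 1.96 se);
    %RSE = se/|theta| * 100 (NaN when theta = 0).
    """
    if se_log < 0 or not math.isfinite(se_log):
        raise InvalidInputError("se_log must be a finite non-negative number")
    est = math.exp(theta_log)
    lo = math.exp(theta_log - 1.96 * se_log)
    hi = math.exp(theta_log + 1.96 * se_log)
    rse = float("nan") if theta_log == 0 else se_log / abs(theta_log) * 100.0
    return est, (lo, hi), rse


def information_criteria(loglik: float, n_params: int, n_obs: int):
    """AIC = -2 ll + 2k; BIC = -2 ll + k ln(n_obs)."""
    if n_obs < 1:
        raise InvalidInputError("n_obs must be >= 1")
    aic = -2.0 * loglik + 2.0 * n_params
    bic = -2.0 * loglik + n_params * math.log(n_obs)
    return aic, bic


def eta_shrinkage_from_ebes(ebes: dict, omega: dict, re_names) -> dict[str, float]:
    """100 * (1 - sd(EBE)/sqrt(omega)) per random effect (NaN if omega=0)."""
    out = {}
    for j, k in enumerate(re_names):
        vals = np.array([np.atleast_1d(v)[j] for v in ebes.values()], dtype=float)
        w = omega.get(k, 0.0)
        out[k] = (
            float("nan") if w <= 0 else 100.0 * (1.0 - float(np.std(vals, ddof=0)) / math.sqrt(w))
        )
    return out


def eta_shrinkage(fit_result: FitResult) -> dict[str, float]:
    """Shrinkage of the fitted result's empirical Bayes estimates (%)."""
    re_names = tuple(
        k for k in fit_result.population.variant.random_effects
        if k in fit_result.population.omega
    )
    ebes = {
        cid: np.array([d[k] for k in re_names])
        for cid, d in fit_result.ebes.items()
    }
    return eta_shrinkage_from_ebes(ebes, fit_result.population.omega, re_names)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def _pop_of(fit_or_pop) -> PopulationModel:
    return fit_or_pop.population if isinstance(fit_or_pop, FitResult) else fit_or_pop


def cwres(fit_or_pop, dataset: list[ChildRecord]) -> pd.DataFrame:
    """FOCE-linearised conditional weighted residuals.

    Linearises each child's prediction around the empirical Bayes mode
    (central finite differences, relative step 1e-4 absolute 1e-3 in eta),
    whitens y - E[y] with the implied covariance G Omega G' + R, and
    returns one row per fitted observation. Under the true model CWRES
    are approximately standard normal. Children whose covariance is
    singular are flagged in the ``flagged`` column rather than dropped.
    """
    pop = _pop_of(fit_or_pop)
    re_names = tuple(k for k in pop.variant.random_effects if k in pop.omega)
    rows = []
    for rec in dataset:
        ch = _Child(rec)
        if ch.n == 0:
            continue
        eta_hat = _ebe(ch, pop, re_names)
        f_hat = ch.predict(pop, eta_hat, re_names)
        k = len(re_names)
        G = np.zeros((ch.n, k))
        for j in range(k):
            step = 1e-3 + 1e-4 * abs(eta_hat[j])
            ep = eta_hat.copy()
            em = eta_hat.copy()
            ep[j] += step
            em[j] -= step
            G[:, j] = (ch.predict(pop, ep, re_names) - ch.predict(pop, em, re_names)) / (
                2 * step
            )
        Om = np.diag([pop.omega[k_] for k_ in re_names]) if k else np.zeros((0, 0))
        R = np.diag(residual_variance(f_hat, pop.sigma_add, pop.sigma_prop))
        V = G @ Om @ G.T + R
        expect = f_hat - G @ eta_hat
        flagged = False
        try:
            L = np.linalg.cholesky(V)
            res = np.linalg.solve(L, ch.y - expect)
        except np.linalg.LinAlgError:
            flagged = True
            res = (ch.y - expect) / np.sqrt(np.maximum(np.diag(V), 1e-12))
        for t, y, f, r in zip(ch.times, ch.y, f_hat, res):
            rows.append((rec.id, t, y, f, float(r), flagged))
    return pd.DataFrame(
        rows, columns=["id", "time_h", "dv", "ipred", "cwres", "flagged"]
    )


def npde(
    fit_or_pop,
    dataset: list[ChildRecord],
    nsim: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Normalised prediction distribution errors.

    Simulates ``nsim`` replicates of each child's observation vector
    (random effects + combined residual error), decorrelates observed and
    simulated vectors with the simulated mean/covariance, ranks the
    observation among its simulations and maps through the inverse normal.
    Extreme ranks are shifted by 1/(2 nsim). ~N(0,1) under the true model.
    """
    if nsim < 100:
        raise InvalidInputError("nsim must be >= 100")
    pop = _pop_of(fit_or_pop)
    rng = np.random.default_rng(seed)
    rows = []
    for rec in dataset:
        ch = _Child(rec)
        if ch.n == 0:
            continue
        sims = _simulate_child_matrix(pop, rec, ch.times, nsim, rng)
        E = sims.mean(axis=0)
        C = np.cov(sims, rowvar=False, ddof=1).reshape(ch.n, ch.n)
        C += np.eye(ch.n) * 1e-10
        L = np.linalg.cholesky(C)
        y_star = np.linalg.solve(L, ch.y - E)
        sims_star = np.linalg.solve(L, (sims - E).T).T
        pd_ = (sims_star < y_star).mean(axis=0)
        pd_ = np.clip(pd_, 1.0 / (2 * nsim), 1.0 - 1.0 / (2 * nsim))
        z = ndtri(pd_)
        for t, y, p_, zz in zip(ch.times, ch.y, pd_, z):
            rows.append((rec.id, t, y, float(p_), float(zz)))
    return pd.DataFrame(rows, columns=["id", "time_h", "dv", "pd", "npde"])


def _simulate_child_matrix(pop, rec, times, nsim, rng) -> np.ndarray:
    """nsim simulated observation vectors for one child (eta + residual)."""
    re_names = tuple(k for k in pop.variant.random_effects if k in pop.omega)
    if set(re_names) <= {"clmax"}:
        interp = EtaGridInterpolator(pop, rec, times)
        eta = rng.normal(0.0, math.sqrt(pop.omega.get("clmax", 0.0)), size=nsim) \
            if "clmax" in pop.omega else np.zeros(nsim)
        f = interp(eta)
    else:
        f = np.empty((nsim, times.size))
        for m, eta in enumerate(pop.sample_etas(nsim, rng)):
            f[m] = predict_child(pop, rec, eta, times)
    eps_p = rng.normal(0.0, 1.0, size=f.shape) * pop.sigma_prop
    eps_a = rng.normal(0.0, 1.0, size=f.shape) * pop.sigma_add
    return f * (1.0 + eps_p) + eps_a


@dataclass
class VpcResult:
    """Observed and simulated percentiles per nominal visit bin."""

    table: pd.DataFrame
    percentiles: tuple[float, ...]
    nsim: int

    def observed_median_within_pi(self) -> bool:
        t = self.table
        mid = self.percentiles[len(self.percentiles) // 2]
        sel = t[t["percentile"] == mid].dropna(subset=["observed"])
        return bool(
            ((sel["observed"] >= sel["pi_lo"]) & (sel["observed"] <= sel["pi_hi"])).all()
        )


def vpc(
    fit_or_pop,
    dataset: list[ChildRecord],
    nsim: int = 1000,
    seed: int = 0,
    percentiles: tuple[float, ...] = (5.0, 50.0, 95.0),
    pi_level: float = 90.0,
) -> VpcResult:
    """Visual predictive check binned by nominal visit time.

    Simulates the full observation process nsim times, computes the
    requested observed and simulated percentiles per bin, and the
    ``pi_level``% prediction interval of each simulated percentile across
    replicates. Bins with fewer than 2 observations report NaN observed
    percentiles.
    """
    pop = _pop_of(fit_or_pop)
    rng = np.random.default_rng(seed)
    sims_per_child = {}
    for rec in dataset:
        ch = _Child(rec)
        if ch.n == 0:
            continue
        sims_per_child[rec.id] = (ch, _simulate_child_matrix(pop, rec, ch.times, nsim, rng))
    all_times = np.concatenate([c.times for c, _ in sims_per_child.values()])
    bins = np.unique(all_times)
    alpha = (100.0 - pi_level) / 2.0
    rows = []
    for t in bins:
        obs_vals = np.concatenate(
            [c.y[c.times == t] for c, _ in sims_per_child.values()]
        )
        sim_stack = np.concatenate(
            [s[:, c.times == t] for c, s in sims_per_child.values()], axis=1
        )
        for q in percentiles:
            obs_q = float(np.percentile(obs_vals, q)) if obs_vals.size >= 2 else float("nan")
            sim_qs = np.percentile(sim_stack, q, axis=1)
            rows.append(
                (t, q, obs_q, float(np.median(sim_qs)),
                 float(np.percentile(sim_qs, alpha)),
                 float(np.percentile(sim_qs, 100 - alpha)),
                 obs_vals.size)
            )
    table = pd.DataFrame(
        rows,
        columns=["time_h", "percentile", "observed", "simulated",
                 "pi_lo", "pi_hi", "n_obs"],
    )
    return VpcResult(table=table, percentiles=percentiles, nsim=nsim)


def fit_seasonal_baseline(times_years, conc) -> tuple[float, float, float]:
    """Least-squares sinusoid m + a sin(2 pi t + phi) with a >= 0.

    ``times_years`` in years (one period per year). Returns
    (mean, amplitude, phase in [0, 2 pi)). Requires >= 4 observations
    spanning more than half a year.
    """
    t = np.asarray(times_years, dtype=float)
    y = np.asarray(conc, dtype=float)
    if t.size < 4:
        raise DataError("need at least 4 observations")
    if np.ptp(t) <= 0.5:
        raise DataError("observations must span more than half a year")
    X = np.column_stack([np.ones_like(t), np.sin(2 * np.pi * t), np.cos(2 * np.pi * t)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    m, A, B = beta
    a = math.hypot(A, B)
    phi = math.atan2(B, A) % (2 * math.pi)
    if a < 1e-12:
        return float(m), 0.0, 0.0
    return float(m), float(a), float(phi)
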
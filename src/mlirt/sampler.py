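"""Gibbs machinery for the multilevel graded-response model.

The model couples a GRM measurement part with a two-level structural part:

    measurement:  P(Y_ik >= c | theta_i) = F(a_k * theta_i - t_kc),
                  t_kc = a_k * kappa_kc   (slope-scaled cutpoints)
    structural:   theta_i = x_i' beta + u_{j(i)} + e_i,
                  u_j ~ N(0, tau2),  e_i ~ N(0, sigma2)

Estimation follows the data-augmented MCMC scheme for multilevel IRT: under
the probit link each observed cell is augmented with a truncated-normal
latent Z_ik in the interval its category defines, after which every full
conditional is conjugate (normal for slopes, abilities, regression
coefficients and dwelling effects; uniform for order-constrained cutpoints;
inverse-gamma for variances).  Under the logit link the measurement and
ability updates fall back to random-walk Metropolis-within-Gibbs.

The latent scale is identified by rescaling: in every iteration the sampled
ability vector is fixed to mean 0 and variance 1, with the compensating
transform applied to item and structural parameters so the observed-data
likelihood is untouched.

Missing responses contribute nothing: their cells are simply absent from the
augmented-data index, so persons may answer any subset of items.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr, ndtri

from . import grm

__all__ = ["MCMCConfig", "ChainStore", "GibbsSampler", "run_mcmc",
           "rescale_identify", "hpd_interval", "geweke_diagnostic",
           "compute_dic", "summarize"]

_TINY = 1e-12
_CUT_BOX = 30.0   # proper-uniform box for cutpoints with no data on one side


@dataclass(frozen=True)
class MCMCConfig:
    """Run-length, link, priors and bookkeeping for one MCMC fit."""

    n_iterations: int = 5000
    burn_in: int = 1000
    thin: int = 1
    seed: int = 0
    link: str = "probit"
    prior_a_mean: float = 1.0
    prior_a_var: float = 10.0
    prior_beta_var: float = 100.0
    # variance-component prior: half-Cauchy on the standard deviations
    # (weakly informative and well behaved when cluster variance is weakly
    # identified, as with near-singleton dwellings); "inverse_gamma"
    # (0.001, 0.001) available for comparison
    variance_prior: str = "half_cauchy"
    prior_hc_scale: float = 1.0
    prior_ig_shape: float = 0.001
    prior_ig_scale: float = 0.001
    # covariate columns carrying no measurement error (known predictors,
    # e.g. a previously estimated score entered with its error fixed to zero)
    fixed_covariates: tuple[str, ...] = ()
    store_theta_trace: bool = False

    def __post_init__(self):
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be < n_iterations")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.link not in grm.LINKS:
            raise ValueError(f"link must be one of {grm.LINKS}")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class ChainStore:
    """Post-burn-in, thinned draws on the identified scale."""

    a: np.ndarray            # (S, K)
    kappa: np.ndarray        # (S, K, C-1)
    beta: np.ndarray         # (S, p)
    sigma2: np.ndarray       # (S,)
    tau2: np.ndarray         # (S,)
    deviance: np.ndarray     # (S,)
    theta_mean: np.ndarray   # (n,) running posterior mean of abilities
    beta_names: list[str]
    item_ids: list[str]
    config: MCMCConfig
    theta_trace: np.ndarray | None = None   # (S, n) if requested
    u_mean: np.ndarray | None = None

    @property
    def n_draws(self) -> int:
        return self.a.shape[0]


def _trunc_normal(rng, mean, sd, lo, hi):
    """Vectorized inverse-CDF truncated-normal draw on (lo, hi)."""
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    v = a + rng.random(np.shape(mean)) * (b - a)
    v = np.clip(v, _TINY, 1 - _TINY)
    x = mean + sd * ndtri(v)
    return np.clip(x, lo, hi)


class GibbsSampler:
    """One MLIRT fit; exposes the individual Gibbs steps for testing.

    Parameters
    ----------
    values, mask : (n, K) response codes 0..C-1 and missingness mask.
    X : (n, p) fixed-effect design (first column should be the intercept).
    dwelling_codes : (n,) integer dwelling index 0..J-1.
    """

    def __init__(self, values, mask, X, dwelling_codes, config: MCMCConfig,
                 beta_names=None, item_ids=None):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.values = np.asarray(values, dtype=int)
        self.mask = np.asarray(mask, dtype=bool)
        self.X = np.asarray(X, dtype=float)
        self.codes = np.asarray(dwelling_codes, dtype=int)
        self.n, self.K = self.values.shape
        self.p = self.X.shape[1]
        self.J = int(self.codes.max()) + 1
        obs = ~self.mask
        self.C = int(self.values[obs].max()) + 1 if obs.any() else 2
        if np.linalg.matrix_rank(self.X) < self.p:
            raise ValueError("rank-deficient fixed-effect design")
        unknown = set(config.fixed_covariates) - set(beta_names or [])
        if unknown:
            raise ValueError(f"fixed_covariates not in design: {sorted(unknown)}")
        self.beta_names = list(beta_names) if beta_names is not None else \
            [f"x{j}" for j in range(self.p)]
        self.item_ids = list(item_ids) if item_ids is not None else \
            [f"item{k}" for k in range(self.K)]

        # flat cell index over observed responses
        pi, ki = np.nonzero(obs)
        self.cell_person = pi
        self.cell_item = ki
        self.cell_y = self.values[pi, ki]
        order = np.lexsort((self.cell_y, self.cell_item))
        self.cell_person = self.cell_person[order]
        self.cell_item = self.cell_item[order]
        self.cell_y = self.cell_y[order]
        # per-(item, category) contiguous slices for the cutpoint update
        self.groups = [[None] * self.C for _ in range(self.K)]
        keys = self.cell_item * self.C + self.cell_y
        bounds = np.searchsorted(keys, np.arange(self.K * self.C + 1))
        for k in range(self.K):
            for c in range(self.C):
                lo, hi = bounds[k * self.C + c], bounds[k * self.C + c + 1]
                self.groups[k][c] = (lo, hi)
        self.n_obs_person = np.bincount(self.cell_person, minlength=self.n)
        self.n_per_dwelling = np.bincount(self.codes, minlength=self.J)
        self.XtX = self.X.T @ self.X

        self._init_state()

    # -- initialization ----------------------------------------------------
    def _init_state(self):
        """Deterministic starting values: unit slopes, quantile cutpoints,
        standardized rest-scores for abilities."""
        cfg = self.cfg
        self.a = np.ones(self.K)
        self.t = np.zeros((self.K, self.C - 1))
        for k in range(self.K):
            col = self.values[:, k][~self.mask[:, k]]
            for c in range(1, self.C):
                p_ge = np.mean(col >= c) if col.size else 0.5
                p_ge = min(max(p_ge, 0.01), 0.99)
                # marginal sd of the latent response is sqrt(1 + a^2) ~ sqrt(2)
                # at the unit-slope starting value
                self.t[k, c - 1] = -np.sqrt(2.0) * ndtri(p_ge)
            self.t[k] = np.sort(self.t[k])
            self.t[k] += 1e-3 * np.arange(self.C - 1)  # break ties
        with np.errstate(invalid="ignore"):
            score = np.where(self.mask, np.nan, self.values.astype(float))
            rest = np.nanmean(score, axis=1)
        rest = np.where(np.isfinite(rest), rest, np.nanmean(rest))
        sd = rest.std()
        self.theta = (rest - rest.mean()) / (sd if sd > 0 else 1.0)
        self.beta = np.zeros(self.p)
        self.u = np.zeros(self.J)
        self.sigma2 = 0.5
        self.tau2 = 0.5
        self.Z = self.a[self.cell_item] * self.theta[self.cell_person]

    # -- measurement step --------------------------------------------------
    def step_measurement(self):
        """Update latent responses, discriminations and cutpoints.

        Probit: truncated-normal augmentation with conjugate slope updates
        and uniform order-constrained cutpoint conditionals.  Logit:
        Metropolis-within-Gibbs on slopes and cutpoints.
        """
        if self.cfg.link == "probit":
            self._augment_z()
            self._update_a_probit()
            self._update_t_probit()
        else:
            self._update_items_mh()

    def _cut_aug(self):
        inf = np.full((self.K, 1), np.inf)
        return np.concatenate([-inf, self.t, inf], axis=1)

    def _augment_z(self):
        taug = self._cut_aug()
        mu = self.a[self.cell_item] * self.theta[self.cell_person]
        lo = taug[self.cell_item, self.cell_y]
        hi = taug[self.cell_item, self.cell_y + 1]
        self.Z = _trunc_normal(self.rng, mu, 1.0, lo, hi)

    def _update_a_probit(self):
        th = self.theta[self.cell_person]
        sxx = np.bincount(self.cell_item, weights=th * th, minlength=self.K)
        sxz = np.bincount(self.cell_item, weights=th * self.Z, minlength=self.K)
        prec = sxx + 1.0 / self.cfg.prior_a_var
        mean = (sxz + self.cfg.prior_a_mean / self.cfg.prior_a_var) / prec
        self.a = _trunc_normal(self.rng, mean, 1.0 / np.sqrt(prec), 0.0, np.inf)

    def _update_t_probit(self):
        # t_kc ~ U(max Z in category c-1, min Z in category c), kept ordered;
        # sides with no data fall back to the neighbouring cutpoint / box
        for k in range(self.K):
            for c in range(1, self.C):
                lo0, hi0 = self.groups[k][c - 1]
                lo1, hi1 = self.groups[k][c]
                lower = self.Z[lo0:hi0].max() if hi0 > lo0 else -_CUT_BOX
                upper = self.Z[lo1:hi1].min() if hi1 > lo1 else _CUT_BOX
                if c >= 2:
                    lower = max(lower, self.t[k, c - 2])
                if c <= self.C - 2:
                    upper = min(upper, self.t[k, c])
                if upper <= lower:   # numerically glued; nudge
                    upper = lower + 1e-9
                self.t[k, c - 1] = self.rng.uniform(lower, upper)

    def _cell_loglik_logit(self, a, t, theta):
        """Per-cell log GRM probability under the logit link (vectorized)."""
        taug = np.concatenate([np.full((self.K, 1), -np.inf), t,
                               np.full((self.K, 1), np.inf)], axis=1)
        eta = a[self.cell_item] * theta[self.cell_person]
        up = eta - taug[self.cell_item, self.cell_y]
        dn = eta - taug[self.cell_item, self.cell_y + 1]
        # P(Y=c) = F(up) - F(dn); stable via log-sum
        p = expit(up) - expit(dn)
        return np.log(np.maximum(p, 1e-300))

    def _update_items_mh(self, step_a=0.05, step_t=0.05):
        ll = self._cell_loglik_logit(self.a, self.t, self.theta)
        item_ll = np.bincount(self.cell_item, weights=ll, minlength=self.K)
        # slopes
        prop_a = self.a + step_a * self.rng.standard_normal(self.K)
        valid = prop_a > 0
        lp = self._cell_loglik_logit(np.where(valid, prop_a, self.a),
                                     self.t, self.theta)
        item_lp = np.bincount(self.cell_item, weights=lp, minlength=self.K)
        pri = (-(prop_a - self.cfg.prior_a_mean) ** 2
               + (self.a - self.cfg.prior_a_mean) ** 2) / (2 * self.cfg.prior_a_var)
        acc = valid & (np.log(self.rng.random(self.K))
                       < item_lp - item_ll + pri)
        self.a = np.where(acc, prop_a, self.a)
        # cutpoints, one column at a time to respect ordering
        for c in range(self.C - 1):
            ll = self._cell_loglik_logit(self.a, self.t, self.theta)
            item_ll = np.bincount(self.cell_item, weights=ll, minlength=self.K)
            t_prop = self.t.copy()
            t_prop[:, c] = self.t[:, c] + step_t * self.rng.standard_normal(self.K)
            ok = np.all(np.diff(t_prop, axis=1) > 0, axis=1)
            lp = self._cell_loglik_logit(self.a,
                                         np.where(ok[:, None], t_prop, self.t),
                                         self.theta)
            item_lp = np.bincount(self.cell_item, weights=lp, minlength=self.K)
            acc = ok & (np.log(self.rng.random(self.K)) < item_lp - item_ll)
            self.t[acc, c] = t_prop[acc, c]

    # -- ability step ------------------------------------------------------
    def step_ability(self):
        """Draw each theta_i from the normal full conditional combining the
        augmented measurement information with the structural prior; persons
        with no observed items draw from the structural prior alone."""
        mu_struct = self.X @ self.beta + self.u[self.codes]
        if self.cfg.link == "probit":
            a_cell = self.a[self.cell_item]
            prec_meas = np.bincount(self.cell_person, weights=a_cell ** 2,
                                    minlength=self.n)
            info = np.bincount(self.cell_person, weights=a_cell * self.Z,
                               minlength=self.n)
            prec = prec_meas + 1.0 / self.sigma2
            mean = (info + mu_struct / self.sigma2) / prec
            self.theta = mean + self.rng.standard_normal(self.n) / np.sqrt(prec)
        else:
            ll = self._cell_loglik_logit(self.a, self.t, self.theta)
            cur = np.bincount(self.cell_person, weights=ll, minlength=self.n)
            prop = self.theta + 0.3 * self.rng.standard_normal(self.n)
            lp = self._cell_loglik_logit(self.a, self.t, prop)
            new = np.bincount(self.cell_person, weights=lp, minlength=self.n)
            pri = (-(prop - mu_struct) ** 2 + (self.theta - mu_struct) ** 2) \
                / (2 * self.sigma2)
            acc = np.log(self.rng.random(self.n)) < new - cur + pri
            self.theta = np.where(acc, prop, self.theta)

    # -- structural step ---------------------------------------------------
    def step_structural(self):
        """Blocked update of (beta, sigma2, tau2, u).

        The regression coefficients are conjugate normal.  The two variance
        components are updated with the dwelling effects integrated out
        (Metropolis steps on the marginal likelihood of the cluster means):
        with near-singleton clusters the conditional-on-u inverse-gamma
        updates confound sigma2 and tau2 and mix impractically slowly, while
        the marginal update does not.  The dwelling effects are then redrawn
        from their exact conditional, keeping the chain a valid blocked
        Gibbs sampler.
        """
        cfg = self.cfg
        # beta | theta, u, sigma2
        resid = self.theta - self.u[self.codes]
        prec = self.XtX / self.sigma2 + np.eye(self.p) / cfg.prior_beta_var
        L = np.linalg.cholesky(prec)
        rhs = self.X.T @ resid / self.sigma2
        mean = np.linalg.solve(prec, rhs)
        z = self.rng.standard_normal(self.p)
        self.beta = mean + np.linalg.solve(L.T, z)
        # (sigma2, tau2) | theta - X beta, with u marginalized
        r = self.theta - self.X @ self.beta
        sums = np.bincount(self.codes, weights=r, minlength=self.J)
        rbar = sums / self.n_per_dwelling
        ssw = float(r @ r) - float(self.n_per_dwelling @ rbar**2)
        self._update_variances_marginal(rbar, ssw)
        # u | r, sigma2, tau2 (exact conditional)
        prec_u = self.n_per_dwelling / self.sigma2 + 1.0 / self.tau2
        mean_u = sums / self.sigma2 / prec_u
        self.u = mean_u + self.rng.standard_normal(self.J) / np.sqrt(prec_u)

    def _marginal_var_loglik(self, sigma2, tau2, rbar, ssw):
        """Log-likelihood of the structural residuals with u integrated out:
        cluster means ~ N(0, tau2 + sigma2/n_j), within-SS ~ sigma2."""
        nj = self.n_per_dwelling
        v = sigma2 + nj * tau2
        return (-0.5 * (self.n - self.J) * np.log(sigma2)
                - 0.5 * ssw / sigma2
                - 0.5 * float(np.sum(np.log(v)))
                - 0.5 * float(np.sum(nj * rbar**2 / v)))

    def _log_var_prior(self, x):
        if self.cfg.variance_prior == "half_cauchy":
            # half-Cauchy(scale) on the sd, transformed to the variance
            A2 = self.cfg.prior_hc_scale ** 2
            return -np.log(1.0 + x / A2) - 0.5 * np.log(x)
        a, b = self.cfg.prior_ig_shape, self.cfg.prior_ig_scale
        return -(a + 1) * np.log(x) - b / x

    def _update_variances_marginal(self, rbar, ssw, n_steps=3, step=0.6):
        """Random-walk Metropolis on (log sigma2, log tau2)."""
        cur = self._marginal_var_loglik(self.sigma2, self.tau2, rbar, ssw)
        for _ in range(n_steps):
            for which in ("tau2", "sigma2"):
                old = getattr(self, which)
                prop = old * np.exp(step * self.rng.standard_normal())
                kw = {"sigma2": self.sigma2, "tau2": self.tau2}
                kw[which] = prop
                new = self._marginal_var_loglik(kw["sigma2"], kw["tau2"],
                                                rbar, ssw)
                # prior density plus the log-scale proposal Jacobian
                logratio = (new - cur + self._log_var_prior(prop)
                            - self._log_var_prior(old)
                            + np.log(prop) - np.log(old))
                if np.log(self.rng.random()) < logratio:
                    setattr(self, which, prop)
                    cur = new

    # -- identification ----------------------------------------------------
    def rescale(self):
        """Fix mean(theta)=0, var(theta)=1; compensate so the observed-data
        likelihood is unchanged."""
        m = self.theta.mean()
        s = self.theta.std()
        if s == 0:
            raise ZeroDivisionError("degenerate ability vector (zero variance)")
        self.theta = (self.theta - m) / s
        self.t = self.t - self.a[:, None] * m
        self.Z = self.Z - self.a[self.cell_item] * m
        self.a = self.a * s
        self.beta = self.beta / s
        if self._has_intercept:
            self.beta[0] -= m / s
        self.u = self.u / s
        self.sigma2 /= s ** 2
        self.tau2 /= s ** 2

    @property
    def _has_intercept(self) -> bool:
        return bool(np.all(self.X[:, 0] == 1.0))

    # -- main loop ---------------------------------------------------------
    def kappa(self) -> np.ndarray:
        return self.t / self.a[:, None]

    def deviance(self) -> float:
        return -2.0 * grm.loglik(self.values, self.mask, self.a, self.kappa(),
                                 self.theta, self.cfg.link)

    def run(self, progress=None) -> ChainStore:
        cfg = self.cfg
        n_store = (cfg.n_iterations - cfg.burn_in + cfg.thin - 1) // cfg.thin
        S = n_store
        a_s = np.empty((S, self.K))
        k_s = np.empty((S, self.K, self.C - 1))
        b_s = np.empty((S, self.p))
        s2_s = np.empty(S)
        t2_s = np.empty(S)
        dev_s = np.empty(S)
        th_sum = np.zeros(self.n)
        u_sum = np.zeros(self.J)
        th_trace = np.empty((S, self.n)) if cfg.store_theta_trace else None
        s = 0
        for it in range(cfg.n_iterations):
            self.step_measurement()
            self.step_ability()
            self.step_structural()
            self.rescale()
            if not np.isfinite(self.theta).all() or not np.isfinite(self.a).all():
                raise FloatingPointError(f"non-finite state at iteration {it}")
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                a_s[s] = self.a
                k_s[s] = self.kappa()
                b_s[s] = self.beta
                s2_s[s] = self.sigma2
                t2_s[s] = self.tau2
                dev_s[s] = self.deviance()
                th_sum += self.theta
                u_sum += self.u
                if th_trace is not None:
                    th_trace[s] = self.theta
                s += 1
            if progress is not None and (it + 1) % max(1, cfg.n_iterations // 10) == 0:
                progress(it + 1, cfg.n_iterations)
        return ChainStore(a=a_s[:s], kappa=k_s[:s], beta=b_s[:s],
                          sigma2=s2_s[:s], tau2=t2_s[:s], deviance=dev_s[:s],
                          theta_mean=th_sum / s, beta_names=self.beta_names,
                          item_ids=self.item_ids, config=cfg,
                          theta_trace=None if th_trace is None else th_trace[:s],
                          u_mean=u_sum / s)


def run_mcmc(values, mask, X, dwelling_codes, config: MCMCConfig,
             beta_names=None, item_ids=None, progress=None) -> ChainStore:
    """Fit the MLIRT model by Gibbs sampling and return the stored chains."""
    sampler = GibbsSampler(values, mask, X, dwelling_codes, config,
                           beta_names=beta_names, item_ids=item_ids)
    return sampler.run(progress=progress)


# ---------------------------------------------------------------------------
# standalone identification transform (kappa scale), used by tests and docs


def rescale_identify(state: dict) -> dict:
    """Standardize ``state['theta']`` and compensate every other parameter.

    ``state`` maps names to arrays/scalars: theta, a, kappa, beta0, beta,
    gamma, u, sigma2, tau2 (structural pieces optional).  The observed-data
    likelihood is invariant under this transform.
    """
    theta = np.asarray(state["theta"], dtype=float)
    m = theta.mean()
    s = theta.std()
    if s == 0:
        raise ZeroDivisionError("zero ability variance")
    out = dict(state)
    out["theta"] = (theta - m) / s
    out["a"] = np.asarray(state["a"], float) * s
    out["kappa"] = (np.asarray(state["kappa"], float) - m) / s
    for key, scale in (("beta", s), ("gamma", s), ("u", s)):
        if key in state:
            out[key] = np.asarray(state[key], float) / scale
    if "beta0" in state:
        out["beta0"] = (state["beta0"] - m) / s
    for key in ("sigma2", "tau2"):
        if key in state:
            out[key] = state[key] / s ** 2
    return out


# ---------------------------------------------------------------------------
# posterior summaries and diagnostics


def hpd_interval(draws, prob: float = 0.95) -> tuple[float, float]:
    """Chen–Shao highest-posterior-density interval: the shortest window of
    ``ceil(prob * n)`` consecutive sorted draws."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    if n < 100:
        raise ValueError("need at least 100 draws for an HPD interval")
    if not 0 < prob <= 1:
        raise ValueError("prob must be in (0, 1]")
    m = int(np.ceil(prob * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[: n - m + 1]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m - 1])


def geweke_diagnostic(chain, first: float = 0.1, last: float = 0.5,
                      threshold: float = 2.0) -> pd.DataFrame:
    """Geweke convergence z-scores (first 10% vs last 50% of the chain,
    spectral-density variance estimates).

    ``chain`` is (S,) or (S, P).  Returns a DataFrame with columns
    ``z`` and ``flag`` ('ok', 'nonstationary', or 'degenerate').
    """
    x = np.atleast_2d(np.asarray(chain, dtype=float).T).T
    S = x.shape[0]
    if S < 200:
        raise ValueError("chain too short for the Geweke diagnostic")
    na = int(first * S)
    nb = int(last * S)
    rows = []
    for jcol in range(x.shape[1]):
        xa = x[:na, jcol]
        xb = x[S - nb:, jcol]
        if np.ptp(x[:, jcol]) == 0:
            rows.append({"z": np.nan, "flag": "degenerate"})
            continue
        va = _spectral0(xa) / na
        vb = _spectral0(xb) / nb
        denom = np.sqrt(va + vb)
        z = 0.0 if denom == 0 else (xa.mean() - xb.mean()) / denom
        rows.append({"z": float(z),
                     "flag": "ok" if abs(z) <= threshold else "nonstationary"})
    return pd.DataFrame(rows)


def _spectral0(x: np.ndarray) -> float:
    """Spectral density at frequency zero (long-run variance), estimated by
    a Bartlett-windowed sum of autocovariances."""
    n = len(x)
    xc = x - x.mean()
    lag_max = max(1, min(n - 1, int(round(4 * (n / 100.0) ** 0.25))))
    gamma0 = float(xc @ xc) / n
    s = gamma0
    for h in range(1, lag_max + 1):
        gamma = float(xc[h:] @ xc[:-h]) / n
        s += 2.0 * (1.0 - h / (lag_max + 1)) * gamma
    return max(s, 1e-12 * max(gamma0, 1e-300))


def compute_dic(chains: ChainStore, values, mask,
                link: str | None = None) -> tuple[float, float, float]:
    """Deviance information criterion from the stored chains.

    DIC = Dbar + pD with Dbar the mean stored deviance and
    pD = Dbar - D(posterior means of theta, a, kappa).  Returns
    ``(dic, p_d, mean_deviance)``; a negative pD is returned with a warning.
    """
    link = chains.config.link if link is None else link
    dbar = float(np.mean(chains.deviance))
    a_hat = chains.a.mean(axis=0)
    kappa_hat = chains.kappa.mean(axis=0)
    d_hat = -2.0 * grm.loglik(np.asarray(values), np.asarray(mask),
                              a_hat, kappa_hat, chains.theta_mean, link)
    p_d = dbar - d_hat
    if p_d < 0:
        warnings.warn("negative effective number of parameters (pD < 0)",
                      RuntimeWarning, stacklevel=2)
    return dbar + p_d, p_d, dbar


def _summary_rows(names, draws_2d, prob):
    rows = []
    for name, col in zip(names, draws_2d.T):
        if col.size >= 100:
            lo, hi = hpd_interval(col, prob)
        else:
            lo, hi = float(col.min()), float(col.max())
        rows.append({"parameter": name, "mean": float(col.mean()),
                     "sd": float(col.std(ddof=1)) if col.size > 1 else 0.0,
                     "hpd_lower": lo, "hpd_upper": hi})
    return rows


def summarize(chains: ChainStore, prob: float = 0.95,
              include_items: bool = True) -> pd.DataFrame:
    """Posterior mean / SD / HPD table: fixed effects in declaration order,
    then variance components, then (optionally) item parameters."""
    rows = _summary_rows(chains.beta_names, chains.beta, prob)
    rows += _summary_rows(["sigma2", "tau2"],
                          np.column_stack([chains.sigma2, chains.tau2]), prob)
    if include_items:
        rows += _summary_rows([f"a[{i}]" for i in chains.item_ids],
                              chains.a, prob)
        Cm1 = chains.kappa.shape[2]
        for c in range(Cm1):
            rows += _summary_rows([f"kappa{c + 1}[{i}]" for i in chains.item_ids],
                                  chains.kappa[:, :, c], prob)
    return pd.DataFrame(rows).set_index("parameter")
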
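"""Zero-inflated negative binomial mixed model with a unit random intercept.

The observation model for unit *i* on weekday *t* is

.. math::

    y_{it} \\sim \\pi \\, \\delta_0 + (1-\\pi)\\,\\mathrm{NB}(\\mu_{it} e^{b_i},\\ \\theta),
    \\qquad b_i \\sim N(0, \\sigma_b^2),

with ``mu_it = exp(x_it' beta)``, NB parameterized by its mean and
dispersion ``theta`` (variance ``mu + mu^2/theta``), and a structural-zero
probability ``pi = logistic(gamma0)`` shared across unit-days (intercept-only
zero part, no random effect in the zero component).

The marginal log-likelihood integrates the random intercept out of each
unit's contribution,

.. math::

    \\ell = \\sum_i \\log \\int \\prod_t P(y_{it} \\mid b)\\,
            \\varphi(b; 0, \\sigma_b^2)\\, db,

by adaptive Gauss-Hermite quadrature: nodes are recentred at the per-unit
conditional mode and rescaled by the curvature there, which keeps a modest
node count accurate even though hundreds of observations per unit make the
integrand sharply peaked.  ``sigma_b = 0`` is handled analytically (no
quadrature).  ``theta`` and ``sigma_b`` are fitted on the log scale, ``pi``
via its logit; standard errors come from the inverse observed information
(numeric Hessian of the marginal log-likelihood at the optimum).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import digamma, gammaln

from .design import DesignMatrices
from .errors import FitError

_LOG_SIGMA_FLOOR = np.log(1e-6)
_DEGENERATE_SIGMA = 1.5e-6  # below this, integrate analytically (sigma ~ 0)
_ETA_CAP = 50.0  # cap on log-mean to avoid overflow in exp


# ---------------------------------------------------------------------------
# probability mass functions


def nb_log_pmf(y, mu, theta):
    """Log pmf of the mean/dispersion negative binomial.

    ``P(y) = Gamma(y+theta) / (Gamma(theta) y!) * (theta/(theta+mu))^theta
    * (mu/(theta+mu))^y``; evaluated through log-gamma so it is exact for
    counts up to at least 1e6.
    """
    y = np.asarray(y)
    mu = np.asarray(mu, float)
    theta = np.asarray(theta, float)
    if np.any(mu <= 0) or np.any(theta <= 0):
        raise FitError("nb_log_pmf requires mu > 0 and theta > 0")
    if np.any(y < 0) or np.any(np.asarray(y, float) != np.floor(np.asarray(y, float))):
        raise FitError("nb_log_pmf requires non-negative integer y")
    yf = np.asarray(y, float)
    out = (
        gammaln(yf + theta)
        - gammaln(theta)
        - gammaln(yf + 1.0)
        + theta * (np.log(theta) - np.log(theta + mu))
        + yf * (np.log(mu) - np.log(theta + mu))
    )
    return out if out.shape else float(out)


def zinb_log_pmf(y, mu, theta, pi):
    """Log pmf of the zero-inflated NB mixture.

    ``P(0) = pi + (1-pi) NB(0)``, ``P(y>0) = (1-pi) NB(y)``; the zero branch
    uses log-sum-exp so small ``pi`` cannot cancel catastrophically.
    """
    pi = np.asarray(pi, float)
    if np.any((pi < 0) | (pi >= 1)):
        raise FitError("zinb_log_pmf requires pi in [0, 1)")
    y = np.asarray(y)
    base = nb_log_pmf(y, mu, theta)
    base = np.asarray(base, float)
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi) if np.all(pi > 0) else np.where(pi > 0, np.log(np.maximum(pi, 1e-300)), -np.inf)
    log1m = np.log1p(-pi)
    zero = np.asarray(y) == 0
    out = np.where(zero, np.logaddexp(log_pi, log1m + base), log1m + base)
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# model specification / fit containers


@dataclass
class ZINBMixedSpec:
    """Everything needed to fit the mixed ZINB model once.

    ``n_nodes`` Gauss-Hermite nodes (odd, >= 5, so one node sits at the
    mode); ``fixed`` pins nuisance parameters (keys ``gamma0``,
    ``log_theta``, ``log_sigma_b``) for nested-model checks.
    """

    design: DesignMatrices
    n_nodes: int = 15
    gtol: float = 1e-6
    xtol: float = 1e-9
    maxiter: int = 500
    gradient: str = "analytic"  # or "numeric"
    fixed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_nodes < 5 or self.n_nodes % 2 == 0:
            raise FitError("n_nodes must be odd and >= 5")
        if self.gtol <= 0 or self.xtol <= 0:
            raise FitError("tolerances must be positive")
        bad = set(self.fixed) - {"gamma0", "log_theta", "log_sigma_b"}
        if bad:
            raise FitError(f"cannot fix unknown parameter(s): {sorted(bad)}")


_NUISANCE = ("gamma0", "log_theta", "log_sigma_b")


@dataclass
class ZINBMixedFit:
    """Maximum-likelihood fit of the mixed ZINB model.

    ``beta`` is on the original covariate scale, addressable by design
    label; ``vcov`` covers all free parameters.  ``boundary`` lists
    parameters pinned at a box bound (their vcov rows are not
    interpretable as curvature-based standard errors).
    """

    beta: pd.Series
    gamma0: float
    log_theta: float
    log_sigma_b: float
    vcov: pd.DataFrame
    loglik: float
    converged: bool
    n_units: int
    n_obs: int
    grad_norm: float
    n_iter: int
    boundary: list[str] = field(default_factory=list)
    fixed: dict = field(default_factory=dict)

    @property
    def theta(self) -> float:
        return float(np.exp(self.log_theta))

    @property
    def sigma_b(self) -> float:
        return float(np.exp(self.log_sigma_b))

    @property
    def pi(self) -> float:
        return float(1.0 / (1.0 + np.exp(-self.gamma0)))

    @property
    def params(self) -> pd.Series:
        extra = {k: getattr(self, k) for k in _NUISANCE}
        return pd.concat([self.beta, pd.Series(extra)])

    def se(self, label: str) -> float:
        if label in self.boundary:
            return float("nan")
        if label not in self.vcov.index:
            raise FitError(f"no variance available for parameter {label!r}")
        return float(np.sqrt(self.vcov.loc[label, label]))

    def coef_table(self) -> pd.DataFrame:
        rows = []
        for name, val in self.params.items():
            try:
                se = self.se(str(name))
            except FitError:
                se = float("nan")
            rows.append({"parameter": name, "estimate": val, "se": se})
        return pd.DataFrame(rows)

    def to_coef_csv(self, path) -> None:
        self.coef_table().to_csv(path, index=False, float_format="%.10g")

    def summary(self) -> str:
        lines = [
            "zero-inflated negative binomial mixed model",
            f"  n_obs={self.n_obs}  n_units={self.n_units}  loglik={self.loglik:.4f}",
            f"  converged={self.converged}  |grad|={self.grad_norm:.2e}  iters={self.n_iter}",
            f"  theta={self.theta:.4f}  pi={self.pi:.4f}  sigma_b={self.sigma_b:.4f}"
            + (f"  boundary={self.boundary}" if self.boundary else ""),
        ]
        for name, val in self.params.items():
            try:
                se = self.se(str(name))
            except FitError:
                se = float("nan")
            lines.append(f"  {name:<20s} {val:+.6f}  (se {se:.6f})")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# internal engine


class _Standardizer:
    """Column centering/scaling with exact back-transformation of beta/vcov."""

    def __init__(self, X: pd.DataFrame):
        A = X.to_numpy(float)
        self.labels = list(X.columns)
        self.center = A.mean(axis=0)
        self.scale = A.std(axis=0)
        const = self.scale < 1e-12
        self.center[const] = 0.0
        self.scale[const] = 1.0
        self.const_idx = int(np.argmax(const)) if const.any() else None
        if self.const_idx is not None:
            # keep the intercept column untouched
            self.center[self.const_idx] = 0.0
        self.Xs = (A - self.center) / self.scale

    def jacobian(self) -> np.ndarray:
        """T with beta_orig = T @ beta_std."""
        p = len(self.labels)
        T = np.diag(1.0 / self.scale)
        if self.const_idx is not None:
            j = self.const_idx
            T[j, :] = -self.center / self.scale
            T[j, j] = 1.0
        return T

    def to_original(self, beta_std: np.ndarray) -> np.ndarray:
        return self.jacobian() @ beta_std

    def to_standardized(self, beta_orig: np.ndarray) -> np.ndarray:
        b = beta_orig * self.scale
        if self.const_idx is not None:
            j = self.const_idx
            b[j] = beta_orig[j] + float(np.dot(self.center, beta_orig))
        return b


class _AGHEngine:
    """Vectorised adaptive Gauss-Hermite machinery for one design."""

    def __init__(self, design: DesignMatrices, n_nodes: int, X_override: np.ndarray | None = None):
        groups = np.asarray(design.groups)
        order = np.argsort(groups, kind="stable")
        self.order = order
        self.y = np.asarray(design.y, np.int64)[order]
        self.groups = groups[order]
        self.X = (X_override if X_override is not None else design.X.to_numpy(float))[order]
        self.n, self.p = self.X.shape
        self.n_units = int(self.groups.max()) + 1
        self.starts = np.searchsorted(self.groups, np.arange(self.n_units))
        self.nz = self.y > 0
        self.z_nodes, self.w_nodes = hermgauss(n_nodes)
        self.log_w = np.log(self.w_nodes)
        self.K = n_nodes
        self.uy, self.y_inv = np.unique(self.y, return_inverse=True)
        self._lgam_y1 = gammaln(self.y + 1.0)
        self._b_cache = np.zeros(self.n_units)

    # -- per-row conditional pieces -------------------------------------

    def _theta_consts(self, theta: float):
        ymax = int(self.uy[-1])
        if ymax <= 2000:
            # exact recurrence: lgamma(y+th)-lgamma(th) = sum log(th+j), j<y;
            # avoids catastrophic cancellation when theta is huge
            j = np.arange(ymax, dtype=float)
            clog = np.concatenate([[0.0], np.cumsum(np.log(theta + j))])
            cdig = np.concatenate([[0.0], np.cumsum(1.0 / (theta + j))])
            cy = clog[self.uy][self.y_inv] - self._lgam_y1
            dig = cdig[self.uy][self.y_inv]
        else:
            cy = gammaln(self.uy + theta)[self.y_inv] - gammaln(theta) - self._lgam_y1
            dig = digamma(self.uy + theta)[self.y_inv] - digamma(theta)
        return cy, dig

    def _eta(self, beta: np.ndarray) -> np.ndarray:
        eta = self.X @ beta
        if not np.all(np.isfinite(eta)):
            row = int(np.argmax(~np.isfinite(eta)))
            raise FitError(f"non-finite linear predictor at row {row}")
        return eta

    def _row_loglik(self, etab: np.ndarray, theta: float, log_pi: float,
                    log1m_pi: float, cy: np.ndarray):
        """Conditional ZINB log pmf per row; etab may be (n,) or (n, K)."""
        capped = np.minimum(etab, _ETA_CAP)
        s = np.exp(capped)
        log_ts = np.log(theta + s)
        log_theta = np.log(theta)
        yf = self.y.astype(float)
        if etab.ndim == 2:
            yf = yf[:, None]
            cy = cy[:, None]
            nzmask = self.nz[:, None]
        else:
            nzmask = self.nz
        lognb0 = theta * (log_theta - log_ts)
        ll_nz = cy + theta * log_theta - (yf + theta) * log_ts + yf * capped + log1m_pi
        ll_z = np.logaddexp(log_pi, log1m_pi + lognb0)
        return np.where(nzmask, ll_nz, ll_z), s, log_ts, lognb0

    def _seg_sum(self, arr: np.ndarray) -> np.ndarray:
        return np.add.reduceat(arr, self.starts, axis=0)

    # -- conditional mode per unit ---------------------------------------

    def _score_hess_b(self, s, lognb0, theta, pi, log1m_pi):
        """d/db and d2/db2 of the conditional log pmf, per row (1-D node)."""
        r = s / (theta + s)
        yf = self.y.astype(float)
        sc_nz = yf - (yf + theta) * r
        h_nz = -(yf + theta) * r * (1.0 - r)
        u = np.exp(log1m_pi + lognb0)
        v = pi + u
        t1 = -theta * r
        sc_z = u * t1 / v
        t1p = -theta * r * (1.0 - r)
        h_z = (u * t1 * t1 + u * t1p) / v - (u * t1 / v) ** 2
        return np.where(self.nz, sc_nz, sc_z), np.where(self.nz, h_nz, h_z)

    def _find_modes(self, eta, theta, pi, log_pi, log1m_pi, cy, sigma):
        b = self._b_cache.copy()
        inv_s2 = 1.0 / sigma**2

        def f_of(bvec):
            ll, s, _, lognb0 = self._row_loglik(eta + bvec[self.groups], theta, log_pi, log1m_pi, cy)
            return self._seg_sum(ll) - 0.5 * bvec**2 * inv_s2, s, lognb0

        f, s, lognb0 = f_of(b)
        for _ in range(100):
            sc, hs = self._score_hess_b(s, lognb0, theta, pi, log1m_pi)
            g = self._seg_sum(sc) - b * inv_s2
            H = self._seg_sum(hs) - inv_s2
            H = np.minimum(H, -1e-10)
            step = -g / H
            step = np.clip(step, -5.0, 5.0)
            if np.max(np.abs(g)) < 1e-9 * (1.0 + np.max(np.abs(f))):
                break
            # damped update: halve steps that decrease the objective
            for _try in range(30):
                f_new, s_new, lognb0_new = f_of(b + step)
                worse = f_new < f - 1e-12
                if not np.any(worse):
                    break
                step[worse] *= 0.5
            b = b + step
            f, s, lognb0 = f_new, s_new, lognb0_new
            if np.max(np.abs(step)) < 1e-12:
                break
        sc, hs = self._score_hess_b(s, lognb0, theta, pi, log1m_pi)
        curv = -(self._seg_sum(hs) - inv_s2)
        curv = np.maximum(curv, 1e-10)
        self._b_cache = b.copy()
        return b, curv

    # -- marginal log-likelihood and gradient ----------------------------

    def loglik_grad(self, beta, gamma0, log_theta, log_sigma, want_grad=True):
        theta = float(np.exp(log_theta))
        sigma = float(np.exp(log_sigma))
        pi = 1.0 / (1.0 + np.exp(-gamma0))
        log_pi = -np.log1p(np.exp(-gamma0))
        log1m_pi = -np.log1p(np.exp(gamma0))
        cy, dig = self._theta_consts(theta)
        eta = self._eta(beta)

        if sigma <= _DEGENERATE_SIGMA:
            # sigma_b ~ 0: random effect degenerate at zero, no quadrature
            ll_rows, s, log_ts, lognb0 = self._row_loglik(eta, theta, log_pi, log1m_pi, cy)
            ll = float(ll_rows.sum())
            if not want_grad:
                return ll, None
            g = self._grad_from_nodes(
                eta[:, None], s[:, None], log_ts[:, None], lognb0[:, None],
                np.ones((self.n_units, 1)), np.zeros((self.n_units, 1)),
                theta, pi, log_pi, log1m_pi, dig, sigma, degenerate=True,
            )
            return ll, g

        b_hat, curv = self._find_modes(eta, theta, pi, log_pi, log1m_pi, cy, sigma)
        scale = np.sqrt(2.0 / curv)
        B = b_hat[:, None] + scale[:, None] * self.z_nodes[None, :]
        etab = eta[:, None] + B[self.groups]
        ll_rows, s, log_ts, lognb0 = self._row_loglik(etab, theta, log_pi, log1m_pi, cy)
        f_units = self._seg_sum(ll_rows)
        f_units += -0.5 * np.log(2 * np.pi * sigma**2) - 0.5 * B**2 / sigma**2
        a = self.log_w[None, :] + self.z_nodes[None, :] ** 2 + f_units
        m = a.max(axis=1)
        lse = m + np.log(np.exp(a - m[:, None]).sum(axis=1))
        ll = float(np.sum(0.5 * np.log(2.0 / curv) + lse))
        if not want_grad:
            return ll, None
        post = np.exp(a - lse[:, None])  # (n_units, K) posterior node weights
        g = self._grad_from_nodes(
            etab, s, log_ts, lognb0, post, B, theta, pi, log_pi, log1m_pi,
            dig, sigma, degenerate=False,
        )
        return ll, g

    def _grad_from_nodes(self, etab, s, log_ts, lognb0, post, B, theta, pi,
                         log_pi, log1m_pi, dig, sigma, degenerate):
        """Gradient wrt (beta, gamma0, log_theta, log_sigma) with quadrature
        nodes held fixed (node-motion terms are at quadrature-error level)."""
        W = post[self.groups]  # (n, K)
        yf = self.y.astype(float)[:, None]
        r = s / (theta + s)
        u = np.exp(log1m_pi + lognb0)
        v = pi + u
        nz = self.nz[:, None]

        sc_eta = np.where(nz, yf - (yf + theta) * r, -u * theta * r / v)
        d = (W * sc_eta).sum(axis=1)
        g_beta = self.X.T @ d

        sc_g0 = np.where(nz, -pi, pi * (1.0 - pi) * (1.0 - u / (1.0 - pi)) / v)
        # note: (1 - nb0) = 1 - u/(1-pi)
        g_gamma0 = float((W * sc_g0).sum())

        log_a = np.log(theta) - log_ts
        sc_th_nz = theta * (dig[:, None] + log_a + 1.0 - (yf + theta) / (theta + s))
        sc_th_z = theta * u * (log_a + r) / v
        g_logtheta = float((W * np.where(nz, sc_th_nz, sc_th_z)).sum())

        if degenerate:
            g_logsigma = 0.0
        else:
            g_logsigma = float((post * (B**2 / sigma**2 - 1.0)).sum())
        return g_beta, g_gamma0, g_logtheta, g_logsigma


# ---------------------------------------------------------------------------
# public evaluation / fitting


def marginal_loglik(
    beta: np.ndarray | pd.Series,
    gamma0: float,
    log_theta: float,
    log_sigma_b: float,
    spec: ZINBMixedSpec,
) -> float:
    """Adaptive-quadrature marginal log-likelihood at given parameters.

    ``beta`` is on the original design scale, aligned with
    ``spec.design.X`` columns (a labelled Series is reindexed to them).
    """
    X = spec.design.X
    if isinstance(beta, pd.Series):
        missing = set(X.columns) - set(beta.index)
        if missing:
            raise FitError(f"beta missing design labels: {sorted(missing)}")
        beta = beta.reindex(X.columns).to_numpy(float)
    beta = np.asarray(beta, float)
    if beta.shape != (X.shape[1],):
        raise FitError(f"beta has shape {beta.shape}, design has {X.shape[1]} columns")
    engine = _AGHEngine(spec.design, spec.n_nodes)
    ll, _ = engine.loglik_grad(beta, float(gamma0), float(log_theta), float(log_sigma_b), want_grad=False)
    return ll


def _initial_values(engine: _AGHEngine, X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    import statsmodels.api as sm

    try:
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=100)
        beta0 = np.asarray(pois.params, float)
        mu0 = np.asarray(pois.mu, float)
    except Exception:
        beta0 = np.zeros(X.shape[1])
        beta0[0] = np.log(max(y.mean(), 0.01))
        mu0 = np.full_like(y, max(y.mean(), 0.01), dtype=float)

    p0_obs = float(np.mean(y == 0))
    p0_nb = float(np.mean((1.0 / (1.0 + mu0)) ** 1.0))  # NB zero prob at theta=1
    excess = max(p0_obs - p0_nb, 0.01)
    excess = min(excess, 0.95)
    gamma0 = float(np.log(excess / (1.0 - excess)))

    # method-of-moments dispersion from Poisson residuals
    resid2 = (y - mu0) ** 2 - mu0
    denom = float(np.mean(mu0**2))
    extra = float(np.mean(resid2))
    theta0 = denom / extra if extra > 1e-8 else 100.0
    theta0 = float(np.clip(theta0, 0.05, 100.0))

    # between-unit spread of residual log rates
    df = pd.DataFrame({"g": groups, "y": y, "mu": mu0})
    agg = df.groupby("g").sum()
    lograte = np.log((agg["y"] + 0.5) / (agg["mu"] + 0.5))
    sigma0 = float(np.clip(lograte.std(), 0.02, 2.0))
    return beta0, gamma0, float(np.log(theta0)), float(np.log(sigma0))


def fit_zinb_mixed(spec: ZINBMixedSpec) -> ZINBMixedFit:
    """Maximize the marginal likelihood; never raises on non-convergence
    (the fit is returned with ``converged=False`` instead).

    Raises FitError for structurally hopeless inputs: a single unit, all
    counts zero (likelihood unbounded in the zero-inflation intercept), or
    a zero part with covariates (only intercept-only zero parts are
    supported by the mixed fitter).
    """
    design = spec.design
    y = np.asarray(design.y)
    if design.n_units < 2:
        raise FitError("need at least 2 units to fit a random intercept")
    if np.all(y == 0):
        raise FitError("all counts are zero: likelihood unbounded in gamma0")
    if list(design.Z.columns) != ["const"]:
        raise FitError("mixed fitter supports an intercept-only zero part")

    std = _Standardizer(design.X)
    engine = _AGHEngine(design, spec.n_nodes, X_override=std.Xs)
    beta0, g0, lt0, ls0 = _initial_values(engine, engine.X, engine.y, engine.groups)

    fixed = dict(spec.fixed)
    nuis0 = {"gamma0": g0, "log_theta": lt0, "log_sigma_b": ls0}
    free_nuis = [k for k in _NUISANCE if k not in fixed]
    p = engine.p

    def unpack(x):
        beta = x[:p]
        vals = dict(fixed)
        for j, k in enumerate(free_nuis):
            vals[k] = x[p + j]
        return beta, vals["gamma0"], vals["log_theta"], vals["log_sigma_b"]

    x0 = np.concatenate([beta0, [nuis0[k] for k in free_nuis]])
    bounds = [(None, None)] * p
    for k in free_nuis:
        if k == "gamma0":
            bounds.append((-30.0, 30.0))
        elif k == "log_theta":
            bounds.append((-12.0, 30.0))
        else:
            bounds.append((_LOG_SIGMA_FLOOR, 3.0))

    def pack_grad(gb, gg, gt, gs):
        parts = [gb]
        m = {"gamma0": gg, "log_theta": gt, "log_sigma_b": gs}
        parts.append(np.array([m[k] for k in free_nuis]))
        return np.concatenate(parts)

    def nll_grad(x):
        ll, g = engine.loglik_grad(*unpack(x), want_grad=True)
        return -ll, -pack_grad(*g)

    def nll_only(x):
        ll, _ = engine.loglik_grad(*unpack(x), want_grad=False)
        return -ll

    if spec.gradient == "analytic":
        res = minimize(
            nll_grad, x0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": spec.maxiter, "ftol": spec.xtol, "gtol": spec.gtol},
        )
        best_x, best_ll = res.x, -res.fun
        n_iter = res.nit
        if not res.success:
            polish = minimize(
                nll_only, best_x, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 60, "ftol": spec.xtol, "gtol": spec.gtol},
            )
            if -polish.fun > best_ll:
                best_x, best_ll = polish.x, -polish.fun
            n_iter += polish.nit
    else:
        res = minimize(
            nll_only, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": spec.maxiter, "ftol": spec.xtol, "gtol": spec.gtol},
        )
        best_x, best_ll = res.x, -res.fun
        n_iter = res.nit

    _, grad = nll_grad(best_x)
    # projected gradient: ignore components pushing against an active bound
    proj = grad.copy()
    for j, (lo, hi) in enumerate(bounds):
        if lo is not None and best_x[j] <= lo + 1e-8 and proj[j] > 0:
            proj[j] = 0.0
        if hi is not None and best_x[j] >= hi - 1e-8 and proj[j] < 0:
            proj[j] = 0.0
    grad_norm = float(np.max(np.abs(proj)))
    converged = bool(res.success) or grad_norm < max(spec.gtol, 1e-4 * (1 + abs(best_ll)))

    beta_std, gamma0, log_theta, log_sigma = unpack(best_x)
    boundary = []
    # below ~1e-3 the marginal likelihood is flat in sigma_b (indistinguishable
    # from zero): report the parameter as boundary-degenerate
    if "log_sigma_b" not in fixed and log_sigma <= np.log(1e-3):
        boundary.append("log_sigma_b")

    # observed information by central differences of the analytic gradient
    nfree = len(best_x)
    H = np.zeros((nfree, nfree))
    eps = np.cbrt(np.finfo(float).eps)
    for j in range(nfree):
        h = eps * max(1.0, abs(best_x[j]))
        xp, xm = best_x.copy(), best_x.copy()
        xp[j] += h
        xm[j] -= h
        _, gp = nll_grad(xp)
        _, gm = nll_grad(xm)
        H[:, j] = (gp - gm) / (2 * h)
    H = 0.5 * (H + H.T)
    w, V = np.linalg.eigh(H)
    w = np.maximum(w, 1e-8)
    vcov_std = (V / w) @ V.T

    # back-transform to original beta scale: full Jacobian over free params
    T = np.eye(nfree)
    T[:p, :p] = std.jacobian()
    vcov = T @ vcov_std @ T.T
    labels = list(design.X.columns) + free_nuis
    vcov_df = pd.DataFrame(vcov, index=labels, columns=labels)

    beta = pd.Series(std.to_original(np.asarray(beta_std)), index=design.X.columns)
    return ZINBMixedFit(
        beta=beta,
        gamma0=float(gamma0),
        log_theta=float(log_theta),
        log_sigma_b=float(log_sigma),
        vcov=vcov_df,
        loglik=float(best_ll),
        converged=converged,
        n_units=design.n_units,
        n_obs=design.n_obs,
        grad_norm=grad_norm,
        n_iter=int(n_iter),
        boundary=boundary,
        fixed=fixed,
    )


def predict_mean(fit: ZINBMixedFit, X: pd.DataFrame, kind: str = "population") -> np.ndarray:
    """Expected count per design row.

    ``kind="population"`` returns ``(1-pi) exp(x'beta) exp(sigma_b^2/2)``
    (averaged over the random-intercept distribution); ``kind="conditional"``
    returns ``(1-pi) exp(x'beta)`` (a unit with b_i = 0).
    """
    missing = set(fit.beta.index) - set(X.columns)
    extra = set(X.columns) - set(fit.beta.index)
    if missing or extra:
        raise FitError(
            f"design labels do not match fit (missing: {sorted(missing)}, "
            f"unexpected: {sorted(extra)})"
        )
    eta = X[fit.beta.index].to_numpy(float) @ fit.beta.to_numpy()
    base = (1.0 - fit.pi) * np.exp(eta)
    if kind == "population":
        return base * np.exp(0.5 * fit.sigma_b**2)
    if kind == "conditional":
        return base
    raise FitError(f"unknown prediction kind {kind!r}")
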
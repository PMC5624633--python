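"""Maximum-likelihood mixed-model backends for the delta components.

Both delta components share one design convention: fixed effects are
treatment-coded categorical factors (year always present) and random terms
are year-by-categorical interaction cells modelled as independent
N(0, sigma_f^2) intercepts with a common variance per term.

* :class:`GaussianMixedML` fits the lognormal positive-catch component by
  maximising the marginal Gaussian likelihood in closed form (the random
  effects integrate analytically; variance ratios are profiled out with a
  Woodbury identity, leaving a tiny free optimisation over log variance
  ratios).
* :class:`LaplaceLogisticMixed` fits the binomial zero-proportion component
  by a Laplace approximation to the marginal likelihood: observations are
  aggregated to covariate cells, the random-effect mode is found by Newton
  steps with the exact dense Hessian, and the fixed effects plus log
  variance parameters are optimised numerically.

AIC/BIC from the two classes are on the plain maximised-likelihood scale
(parameters = fixed effects + one variance per random term + the residual
variance where it exists), so candidates with and without random terms are
directly comparable within a component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special

__all__ = ["CategoricalDesign", "GaussianMixedML", "LaplaceLogisticMixed", "MixedFit"]

FIXED_FACTORS = ("year", "month", "vessel_class", "area")
RANDOM_FACTORS = ("year:month", "year:vessel_class")


class UnseenLevelError(KeyError):
    """A prediction row carries a factor level absent from the training data."""


class CategoricalDesign:
    """Treatment-coded design shared by fit and predict.

    ``fixed_terms`` is an ordered subset of year/month/vessel_class/area;
    ``random_terms`` of year:month / year:vessel_class.  Levels are frozen
    from the training frame so that prediction frames are coded identically.
    """

    def __init__(self, records: pd.DataFrame, fixed_terms, random_terms=()):
        if "year" not in fixed_terms:
            raise ValueError("the year term is mandatory")
        for t in fixed_terms:
            if t not in FIXED_FACTORS:
                raise ValueError(f"unknown fixed term {t!r}")
        for t in random_terms:
            if t not in RANDOM_FACTORS:
                raise ValueError(f"unknown random term {t!r}")
        self.fixed_terms = tuple(fixed_terms)
        self.random_terms = tuple(random_terms)
        self.levels = {
            t: tuple(sorted(pd.unique(records[t]))) for t in self.fixed_terms
        }
        for t in self.random_terms:
            for part in t.split(":"):
                self.levels.setdefault(part, tuple(sorted(pd.unique(records[part]))))

    def _codes(self, df, factor):
        lv = self.levels[factor]
        lookup = {v: i for i, v in enumerate(lv)}
        try:
            return np.array([lookup[v] for v in df[factor]], dtype=int)
        except KeyError as e:
            raise UnseenLevelError(f"unseen {factor} level {e.args[0]!r}") from e

    def fixed_matrix(self, df: pd.DataFrame):
        """(X, column names); intercept plus drop-first dummies per term."""
        cols = [np.ones(len(df))]
        names = ["Intercept"]
        for t in self.fixed_terms:
            codes = self._codes(df, t)
            for i, lv in enumerate(self.levels[t][1:], start=1):
                cols.append((codes == i).astype(float))
                names.append(f"{t}[{lv}]")
        return np.column_stack(cols), names

    def random_codes(self, df: pd.DataFrame):
        """Per random term: (name, cell codes, number of cells)."""
        out = []
        for t in self.random_terms:
            a, b = t.split(":")
            ca, cb = self._codes(df, a), self._codes(df, b)
            nb = len(self.levels[b])
            out.append((t, ca * nb + cb, len(self.levels[a]) * nb))
        return out

    @property
    def n_fixed(self):
        return 1 + sum(len(self.levels[t]) - 1 for t in self.fixed_terms)


@dataclass
class MixedFit:
    """A fitted delta component (either family)."""

    design: CategoricalDesign
    kind: str                      # "linear" | "logistic"
    params: np.ndarray             # fixed effects, design order
    param_names: list
    cov_params: np.ndarray         # fixed-effect covariance
    llf: float
    df_model: int
    nobs: int
    converged: bool
    sigma2: float = np.nan         # residual variance (linear only)
    variances: dict = field(default_factory=dict)   # random-term variances
    blups: dict = field(default_factory=dict)       # term -> cell deviates

    @property
    def aic(self):
        return -2.0 * self.llf + 2.0 * self.df_model

    @property
    def bic(self):
        return -2.0 * self.llf + self.df_model * np.log(self.nobs)

    def predict_eta(self, df: pd.DataFrame, include_random: bool = True) -> np.ndarray:
        X, _ = self.design.fixed_matrix(df)
        eta = X @ self.params
        if include_random:
            for name, codes, _q in self.design.random_codes(df):
                u = self.blups.get(name)
                if u is not None:
                    eta = eta + u[codes]
        return eta

    def predict_prob(self, df: pd.DataFrame, include_random: bool = True) -> np.ndarray:
        if self.kind != "logistic":
            raise ValueError("predict_prob applies to the logistic component")
        return special.expit(self.predict_eta(df, include_random))

    def predict_mean(self, df: pd.DataFrame, include_random: bool = True) -> np.ndarray:
        """Bias-corrected back-transform exp(eta + sigma2/2) (linear only)."""
        if self.kind != "linear":
            raise ValueError("predict_mean applies to the linear component")
        return np.exp(self.predict_eta(df, include_random) + self.sigma2 / 2.0)


# ---------------------------------------------------------------------------


class GaussianMixedML:
    """Marginal-ML linear mixed model with iid random-intercept terms.

    y = X beta + sum_f Z_f u_f + e,  u_f ~ N(0, sigma^2 gamma_f I),
    e ~ N(0, sigma^2 I).  beta and sigma^2 are profiled in closed form;
    the log variance ratios log(gamma_f) are optimised numerically
    (Nelder-Mead; at most two of them here).
    """

    def __init__(self, y, X, factor_codes, factor_sizes, names=None):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.codes = [np.asarray(c, dtype=int) for c in factor_codes]
        self.sizes = list(factor_sizes)
        self.names = names or [f"f{i}" for i in range(len(self.codes))]
        self.n, self.p = self.X.shape

    def _z(self):
        blocks = []
        for c, q in zip(self.codes, self.sizes):
            Z = np.zeros((self.n, q))
            Z[np.arange(self.n), c] = 1.0
            blocks.append(Z)
        return np.concatenate(blocks, axis=1) if blocks else np.zeros((self.n, 0))

    def _profile(self, log_gamma):
        """Profiled beta, sigma2 and llf at fixed variance ratios."""
        Z = self._z()
        q = Z.shape[1]
        g = np.concatenate(
            [np.full(s, np.exp(lg)) for s, lg in zip(self.sizes, log_gamma)]
        ) if q else np.zeros(0)
        if q:
            Gh = np.sqrt(g)
            ZG = Z * Gh  # Z G^{1/2}
            A = np.eye(q) + ZG.T @ ZG
            cf = linalg.cho_factor(A)
            logdetA = 2.0 * np.sum(np.log(np.diag(cf[0])))

            def wmul(B):
                return B - ZG @ linalg.cho_solve(cf, ZG.T @ B)
        else:
            logdetA = 0.0

            def wmul(B):
                return B

        WX = wmul(self.X)
        Wy = wmul(self.y)
        XtWX = self.X.T @ WX
        beta = linalg.solve(XtWX, self.X.T @ Wy, assume_a="pos")
        r = self.y - self.X @ beta
        quad = float(r @ wmul(r))
        sigma2 = max(quad / self.n, 1e-12)
        llf = (
            -0.5 * self.n * np.log(2.0 * np.pi * sigma2)
            - 0.5 * logdetA
            - 0.5 * self.n
        )
        return beta, sigma2, llf, XtWX, wmul, g

    def fit(self) -> MixedFit:
        nf = len(self.codes)
        converged = True
        if nf == 0:
            lg_opt = np.zeros(0)
        else:
            res = optimize.minimize(
                lambda lg: -self._profile(np.clip(lg, -12.0, 6.0))[2],
                x0=np.full(nf, np.log(0.1)),
                method="Nelder-Mead",
                options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 600},
            )
            converged = bool(res.success)
            lg_opt = np.clip(res.x, -12.0, 6.0)
        beta, sigma2, llf, XtWX, wmul, g = self._profile(lg_opt)
        cov = sigma2 * linalg.inv(XtWX)
        blups, variances = {}, {}
        if nf:
            Z = self._z()
            r = self.y - self.X @ beta
            u_all = g * (Z.T @ wmul(r))
            off = 0
            for name, s, lg in zip(self.names, self.sizes, lg_opt):
                blups[name] = u_all[off : off + s]
                variances[name] = float(np.exp(lg) * sigma2)
                off += s
        return MixedFit(
            design=None,  # attached by the caller
            kind="linear",
            params=beta,
            param_names=[],
            cov_params=cov,
            llf=float(llf),
            df_model=self.p + nf + 1,
            nobs=self.n,
            converged=converged,
            sigma2=float(sigma2),
            variances=variances,
            blups=blups,
        )


# ---------------------------------------------------------------------------


class LaplaceLogisticMixed:
    """Binomial random-intercept GLMM via a Laplace-approximated likelihood.

    The Bernoulli responses are aggregated to covariate cells (successes,
    trials); the log-likelihood is on the Bernoulli scale so AIC/BIC are
    comparable with a plain logistic fit of the same data.
    """

    def __init__(self, y, X, factor_codes, factor_sizes, names=None):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        codes = [np.asarray(c, dtype=int) for c in factor_codes]
        # aggregate identical rows: (X row, factor codes) -> (successes, trials)
        key = pd.DataFrame(np.column_stack([X] + [c[:, None] for c in codes]))
        grp = key.groupby(list(key.columns), sort=False)
        idx = grp.ngroup().to_numpy()
        ncell = idx.max() + 1
        first = np.zeros(ncell, dtype=int)
        seen = np.zeros(ncell, dtype=bool)
        for i, c in enumerate(idx):
            if not seen[c]:
                first[c] = i
                seen[c] = True
        self.s = np.bincount(idx, weights=y, minlength=ncell)
        self.m = np.bincount(idx, minlength=ncell).astype(float)
        self.X = X[first]
        self.codes = [c[first] for c in codes]
        self.sizes = list(factor_sizes)
        self.names = names or [f"f{i}" for i in range(len(codes))]
        self.n_obs = len(y)
        self.p = X.shape[1]
        self._offsets = np.concatenate([[0], np.cumsum(self.sizes)]).astype(int)
        self.q = int(self._offsets[-1])

    # -- random-effect plumbing over aggregated cells --
    def _eta(self, beta, u):
        eta = self.X @ beta
        for c, off in zip(self.codes, self._offsets[:-1]):
            eta = eta + u[off + c]
        return eta

    def _zt(self, v):
        """Z' v for cell-level vector v."""
        parts = [
            np.bincount(c, weights=v, minlength=s)
            for c, s in zip(self.codes, self.sizes)
        ]
        return np.concatenate(parts) if parts else np.zeros(0)

    def _ztwz(self, w):
        H = np.zeros((self.q, self.q))
        for a in range(len(self.codes)):
            oa, sa = self._offsets[a], self.sizes[a]
            H[oa : oa + sa, oa : oa + sa] += np.diag(
                np.bincount(self.codes[a], weights=w, minlength=sa)
            )
            for b in range(a + 1, len(self.codes)):
                ob, sb = self._offsets[b], self.sizes[b]
                cross = np.bincount(
                    self.codes[a] * sb + self.codes[b], weights=w, minlength=sa * sb
                ).reshape(sa, sb)
                H[oa : oa + sa, ob : ob + sb] += cross
                H[ob : ob + sb, oa : oa + sa] += cross.T
        return H

    def _laplace(self, beta, log_sig, u0=None):
        """(approximate loglik, u mode); exact when there is no random term."""
        if self.q == 0:
            eta = self.X @ beta
            ll = float(np.sum(self.s * eta - self.m * np.logaddexp(0.0, eta)))
            return ll, np.zeros(0)
        dinv = np.concatenate(
            [np.full(s, np.exp(-2.0 * ls)) for s, ls in zip(self.sizes, log_sig)]
        )
        u = np.zeros(self.q) if u0 is None else u0.copy()
        for _ in range(50):
            eta = self._eta(beta, u)
            mu = self.m * special.expit(eta)
            grad = self._zt(self.s - mu) - dinv * u
            w = self.m * special.expit(eta) * special.expit(-eta)
            H = self._ztwz(w) + np.diag(dinv)
            step = linalg.solve(H, grad, assume_a="pos")
            u = u + step
            if np.max(np.abs(step)) < 1e-9:
                break
        eta = self._eta(beta, u)
        ll_cond = float(np.sum(self.s * eta - self.m * np.logaddexp(0.0, eta)))
        w = self.m * special.expit(eta) * special.expit(-eta)
        H = self._ztwz(w) + np.diag(dinv)
        sign, logdetH = np.linalg.slogdet(H)
        logdetD = float(np.sum(-np.log(dinv)))
        ll = (
            ll_cond
            - 0.5 * float(u @ (dinv * u))
            - 0.5 * logdetH
            - 0.5 * logdetD
        )
        return ll, u

    def fit(self, maxiter: int = 400) -> MixedFit:
        nf = len(self.codes)
        # plain-logistic start for the fixed effects
        import statsmodels.api as sm

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(
                np.column_stack([self.s, self.m - self.s]), self.X,
                family=sm.families.Binomial(),
            ).fit()
        beta0 = np.asarray(glm.params)

        state = {"u": None}

        def unpack(theta):
            return theta[: self.p], theta[self.p :]

        def nll(theta):
            beta, log_sig = unpack(theta)
            ll, u = self._laplace(beta, np.clip(log_sig, -6.0, 3.0), state["u"])
            state["u"] = u
            return -ll

        theta0 = np.concatenate([beta0, np.full(nf, np.log(0.3))])
        if nf == 0:
            theta_opt = beta0
            converged = bool(glm.converged)
            # Bernoulli-scale llf (no binomial coefficients) so AIC/BIC are
            # comparable across candidates with and without random terms
            llf = float(self._laplace(beta0, np.zeros(0))[0])
            cov = np.asarray(glm.cov_params())
            u = np.zeros(0)
            log_sig = np.zeros(0)
        else:
            res = optimize.minimize(
                nll, theta0, method="BFGS",
                options={"maxiter": maxiter, "gtol": 1e-5},
            )
            theta_opt = res.x
            converged = bool(res.success) or res.status == 2  # precision loss at optimum
            beta, log_sig = unpack(theta_opt)
            log_sig = np.clip(log_sig, -6.0, 3.0)
            ll_opt, u = self._laplace(beta, log_sig, state["u"])
            llf = float(ll_opt)
            # fixed-effect covariance from the beta-block Hessian of -llf at
            # the optimum (variances held fixed; stable at a boundary optimum)
            from statsmodels.tools.numdiff import approx_hess1

            def nll_beta(b):
                return -self._laplace(b, log_sig, state["u"])[0]

            Hbeta = approx_hess1(np.asarray(beta, dtype=float), nll_beta)
            try:
                cov = linalg.inv(Hbeta)
            except linalg.LinAlgError:  # pragma: no cover
                cov = linalg.pinv(Hbeta)
                converged = False

        blups, variances = {}, {}
        off = 0
        for name, s, ls in zip(self.names, self.sizes, np.atleast_1d(log_sig)):
            blups[name] = u[off : off + s]
            variances[name] = float(np.exp(2.0 * ls))
            off += s
        return MixedFit(
            design=None,
            kind="logistic",
            params=np.asarray(theta_opt[: self.p], dtype=float),
            param_names=[],
            cov_params=np.asarray(cov),
            llf=llf,
            df_model=self.p + nf,
            nobs=self.n_obs,
            converged=converged,
            variances=variances,
            blups=blups,
        )
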
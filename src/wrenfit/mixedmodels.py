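"""Maximum-likelihood GLMMs with nested random intercepts.

A small, explicit mixed-model engine for the three response families the
fitness analyses need: Bernoulli (logit link), Gaussian (identity link),
and zero-inflated Poisson (log link on the count mean, a scalar
zero-inflation probability).  Random structure is zero, one, or two
*nested* random intercept factors (e.g. nest identity nested within mother
identity), which covers every model in the analysis.

The marginal likelihood integrates the random effects by the Laplace
approximation.  For a nested two-factor layout the joint penalised
log-likelihood has an arrow-shaped Hessian (each nest couples only to its
own mother), so the inner Newton mode search and the log-determinant are
computed in O(n) with bincount reductions — no dense solves.  For the
Gaussian family the integrand is Gaussian and the Laplace approximation is
exact, so fits are exact ML (never REML: log-likelihoods must be
comparable across fixed-effect structures for AICc model selection).

Parameter counts for AICc include fixed effects, random-effect standard
deviations, and family extras (Gaussian residual SD; ZIP zero-inflation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

_LOG_SD_LO, _LOG_SD_HI = -6.0, 4.0  # log random-effect SD box for the optimiser


class Bernoulli:
    """Logistic regression family; response in {0, 1}."""

    name = "binary"
    extra_names: tuple[str, ...] = ()

    @staticmethod
    def check(y: np.ndarray) -> None:
        if not np.isin(y, (0, 1)).all():
            raise ValueError("binary response must be 0/1")
        if y.min() == y.max():
            raise ValueError("binary response is constant; degenerate fit")

    @staticmethod
    def start_extra(y: np.ndarray) -> list[float]:
        return []

    @staticmethod
    def loglik(y, eta, extra):
        return y * eta - np.logaddexp(0.0, eta)

    @staticmethod
    def derivs(y, eta, extra):
        p = special.expit(eta)
        return y - p, -p * (1.0 - p)


class Gaussian:
    """Linear model family with residual SD as an extra ML parameter."""

    name = "gaussian"
    extra_names = ("log_sigma",)

    @staticmethod
    def check(y: np.ndarray) -> None:
        if np.ptp(y) == 0.0:
            raise ValueError("gaussian response is constant; degenerate fit")

    @staticmethod
    def start_extra(y: np.ndarray) -> list[float]:
        return [float(np.log(max(y.std(), 1e-3)))]

    @staticmethod
    def loglik(y, eta, extra):
        s2 = np.exp(2.0 * extra[0])
        return -0.5 * np.log(2.0 * np.pi * s2) - (y - eta) ** 2 / (2.0 * s2)

    @staticmethod
    def derivs(y, eta, extra):
        s2 = np.exp(2.0 * extra[0])
        return (y - eta) / s2, np.full_like(eta, -1.0 / s2)


class ZeroInflatedPoisson:
    """Mixture of a point mass at zero (prob pi) and Poisson(mu), mu = e^eta.

    The linear predictor (and any random intercept) acts on the count part;
    zero-inflation is a single logit-scale scalar.
    """

    name = "zip"
    extra_names = ("logit_pi",)

    @staticmethod
    def check(y: np.ndarray) -> None:
        if (y < 0).any() or not np.allclose(y, np.round(y)):
            raise ValueError("zip response must be non-negative integers")
        if (y == 0).all():
            raise ValueError("zip response is all zeros; degenerate fit")

    @staticmethod
    def start_extra(y: np.ndarray) -> list[float]:
        p0 = np.clip((y == 0).mean(), 0.05, 0.95)
        return [float(special.logit(p0 / 2.0))]

    @staticmethod
    def loglik(y, eta, extra):
        psi = extra[0]
        mu = np.exp(eta)
        log_pi = -np.logaddexp(0.0, -psi)
        log_1mpi = -np.logaddexp(0.0, psi)
        out = np.where(
            y == 0,
            np.logaddexp(log_pi, log_1mpi - mu),
            log_1mpi + y * eta - mu - special.gammaln(y + 1.0),
        )
        return out

    @staticmethod
    def derivs(y, eta, extra):
        psi = extra[0]
        mu = np.exp(eta)
        pi = special.expit(psi)
        # c = mu*(1-pi)e^{-mu} / (pi + (1-pi)e^{-mu}), computed stably
        log_num = np.log1p(-pi) - mu + eta
        log_den = np.logaddexp(np.log(pi) if pi > 0 else -np.inf, np.log1p(-pi) - mu)
        c = np.exp(log_num - log_den)
        d1 = np.where(y == 0, -c, y - mu)
        d2 = np.where(y == 0, -c * (1.0 - mu) - c**2, -mu)
        return d1, d2


FAMILIES = {f.name: f for f in (Bernoulli, Gaussian, ZeroInflatedPoisson)}


@dataclass
class RandomStructure:
    """Nested random-intercept layout.

    ``factors`` is a list of (name, integer codes of length n), outermost
    first; with two factors the second must be nested in the first.
    """

    factors: list[tuple[str, np.ndarray]]

    def __post_init__(self) -> None:
        if len(self.factors) > 2:
            raise ValueError("at most two (nested) random factors are supported")
        self.names = [nm for nm, _ in self.factors]
        self.codes = []
        self.sizes = []
        for _, raw in self.factors:
            _, codes = np.unique(np.asarray(raw), return_inverse=True)
            self.codes.append(codes)
            self.sizes.append(int(codes.max()) + 1)
        if len(self.factors) == 2:
            a, b = self.codes
            parent = np.full(self.sizes[1], -1, dtype=np.int64)
            for bi, ai in zip(b, a):
                if parent[bi] == -1:
                    parent[bi] = ai
                elif parent[bi] != ai:
                    raise ValueError(
                        f"factor {self.names[1]!r} is not nested in {self.names[0]!r}"
                    )
            self.parent = parent

    @property
    def q(self) -> int:
        return int(sum(self.sizes))


@dataclass
class GLMMFit:
    """An ML fit of one GLMM."""

    family: str
    beta: np.ndarray
    beta_names: list[str]
    re_sd: dict
    extra: dict
    loglik: float
    k: int
    n: int
    converged: bool
    boundary: bool

    def summary(self) -> str:
        bits = [f"{self.family} GLMM  n={self.n}  logLik={self.loglik:.3f}  k={self.k}"]
        for nm, b in zip(self.beta_names, self.beta):
            bits.append(f"  {nm:>20s} {b:+.4f}")
        for nm, s in self.re_sd.items():
            bits.append(f"  sd({nm}) = {s:.4f}")
        for nm, v in self.extra.items():
            bits.append(f"  {nm} = {v:.4f}")
        if not self.converged:
            bits.append("  WARNING: optimiser did not report convergence")
        return "\n".join(bits)


class _Laplace:
    """Laplace marginal log-likelihood with warm-started inner Newton."""

    def __init__(self, y, X, family, rs: RandomStructure):
        self.y = y
        self.X = X
        self.family = family
        self.rs = rs
        self.u = [np.zeros(s) for s in rs.sizes]

    def _eta(self, beta, u):
        eta = self.X @ beta
        for codes, ug in zip(self.rs.codes, u):
            eta = eta + ug[codes]
        return eta

    def _objective(self, beta, extra, sds, u):
        eta = self._eta(beta, u)
        val = float(self.family.loglik(self.y, eta, extra).sum())
        for ug, sd in zip(u, sds):
            val -= 0.5 * float(ug @ ug) / sd**2 + ug.size * np.log(sd)
        return val

    def marginal(self, beta, extra, sds) -> float:
        rs = self.rs
        if not rs.factors:
            return float(self.family.loglik(self.y, self.X @ beta, extra).sum())
        u = [g.copy() for g in self.u]
        obj = self._objective(beta, extra, sds, u)
        for _ in range(200):
            eta = self._eta(beta, u)
            d1, d2 = self.family.derivs(self.y, eta, extra)
            w = np.maximum(-d2, 1e-10)
            grads, deltas = [], []
            if len(rs.factors) == 1:
                a = rs.codes[0]
                ga = np.bincount(a, d1, rs.sizes[0]) - u[0] / sds[0] ** 2
                Ha = np.bincount(a, w, rs.sizes[0]) + 1.0 / sds[0] ** 2
                grads = [ga]
                deltas = [ga / Ha]
            else:
                a, b = rs.codes
                qa, qb = rs.sizes
                ga = np.bincount(a, d1, qa) - u[0] / sds[0] ** 2
                gb = np.bincount(b, d1, qb) - u[1] / sds[1] ** 2
                Ha = np.bincount(a, w, qa) + 1.0 / sds[0] ** 2
                s_b = np.bincount(b, w, qb)
                Hb = s_b + 1.0 / sds[1] ** 2
                S = Ha - np.bincount(rs.parent, s_b**2 / Hb, qa)
                rhs = ga - np.bincount(rs.parent, s_b * gb / Hb, qa)
                da = rhs / S
                db = (gb - s_b * da[rs.parent]) / Hb
                grads = [ga, gb]
                deltas = [da, db]
            gnorm = max(float(np.abs(g).max()) for g in grads)
            if gnorm < 1e-11:
                break
            step = 1.0
            for _half in range(40):
                trial = [ug + step * dg for ug, dg in zip(u, deltas)]
                new = self._objective(beta, extra, sds, trial)
                if new >= obj - 1e-13:
                    u, obj = trial, new
                    break
                step *= 0.5
            else:  # no ascent possible
                break
        self.u = [g.copy() for g in u]
        # log-determinant of the penalised Hessian at the mode
        eta = self._eta(beta, u)
        d1, d2 = self.family.derivs(self.y, eta, extra)
        w = np.maximum(-d2, 1e-10)
        if len(rs.factors) == 1:
            a = rs.codes[0]
            Ha = np.bincount(a, w, rs.sizes[0]) + 1.0 / sds[0] ** 2
            logdet = float(np.log(Ha).sum())
        else:
            a, b = rs.codes
            Ha = np.bincount(a, w, rs.sizes[0]) + 1.0 / sds[0] ** 2
            s_b = np.bincount(b, w, rs.sizes[1])
            Hb = s_b + 1.0 / sds[1] ** 2
            S = Ha - np.bincount(rs.parent, s_b**2 / Hb, rs.sizes[0])
            logdet = float(np.log(Hb).sum() + np.log(np.maximum(S, 1e-300)).sum())
        # Laplace: integral ~ exp(L(u_hat)) (2 pi)^(q/2) |H|^(-1/2); the
        # (2 pi)^(q/2) cancels the prior's (2 pi)^(-q/2), which _objective
        # therefore omits, leaving L(u_hat) - logdet/2.
        val = self._objective(beta, extra, sds, u)
        return val - 0.5 * logdet


def fit_glmm(
    y,
    X,
    beta_names=None,
    groups=None,
    family="binary",
    maxiter: int = 400,
    ftol: float = 1e-11,
    gtol: float = 1e-7,
    start: dict | None = None,
) -> GLMMFit:
    """Fit a random-intercept GLMM by maximum likelihood.

    Parameters
    ----------
    y, X : array-likes
        Response and fixed-effect design matrix (include the intercept
        column explicitly).
    groups : list of (name, codes) or None
        Random-intercept factors, outermost first; the second factor, if
        any, must be nested in the first.
    family : {"binary", "gaussian", "zip"}
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        raise ValueError("X and y have incompatible shapes")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design matrix is rank deficient (aliased columns)")
    fam = FAMILIES[family]
    fam.check(y)
    beta_names = list(beta_names) if beta_names is not None else [
        f"x{j}" for j in range(X.shape[1])
    ]
    rs = RandomStructure(list(groups) if groups else [])
    singles = [nm for (nm, _), size in zip(rs.factors, rs.sizes) if size == y.size]
    if singles:
        warnings.warn(
            f"random factor(s) {singles} have one level per observation; "
            "variance is confounded with the residual and will be pinned near zero"
        )
    lap = _Laplace(y, X, fam, rs)

    p = X.shape[1]
    n_sd = len(rs.factors)
    n_extra = len(fam.extra_names)

    def unpack(theta):
        beta = theta[:p]
        sds = np.exp(theta[p : p + n_sd])
        extra = theta[p + n_sd :]
        return beta, extra, sds

    def neg(theta):
        beta, extra, sds = unpack(theta)
        if not rs.factors:
            ll = float(fam.loglik(y, X @ beta, extra).sum())
        else:
            ll = lap.marginal(beta, extra, sds)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    theta0 = np.zeros(p + n_sd + n_extra)
    if "const" in beta_names:
        ybar = float(np.clip(y.mean(), 1e-3, None))
        j = beta_names.index("const")
        if family == "binary":
            theta0[j] = special.logit(np.clip(ybar, 1e-3, 1 - 1e-3))
        elif family == "gaussian":
            theta0[j] = y.mean()
        else:
            theta0[j] = np.log(max(y[y > 0].mean(), 1e-2))
    theta0[p : p + n_sd] = np.log(0.5)
    theta0[p + n_sd :] = fam.start_extra(y)
    if start:  # warm start from a previously fitted related model
        for name, val in start.get("beta", {}).items():
            if name in beta_names:
                theta0[beta_names.index(name)] = val
        for i, sd in enumerate(start.get("log_sd", [])[:n_sd]):
            theta0[p + i] = np.clip(sd, _LOG_SD_LO, _LOG_SD_HI)
        for i, v in enumerate(start.get("extra", [])[:n_extra]):
            theta0[p + n_sd + i] = v

    bounds = (
        [(None, None)] * p
        + [(_LOG_SD_LO, _LOG_SD_HI)] * n_sd
        + [(-12.0, 12.0)] * n_extra
    )
    opts = {"maxiter": maxiter, "ftol": ftol, "gtol": gtol}
    res = optimize.minimize(neg, theta0, method="L-BFGS-B", bounds=bounds, options=opts)
    if not res.success:  # one polish attempt from the best point found
        res2 = optimize.minimize(
            neg, res.x, method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
        )
        if res2.fun <= res.fun:
            res = res2
        res3 = optimize.minimize(neg, res.x, method="L-BFGS-B", bounds=bounds, options=opts)
        if res3.fun <= res.fun:
            res = res3
    beta, extra, sds = unpack(res.x)
    boundary = bool(n_sd and np.any(res.x[p : p + n_sd] <= _LOG_SD_LO + 1e-6))
    fit = GLMMFit(
        family=family,
        beta=beta,
        beta_names=beta_names,
        re_sd={nm: float(sd) for nm, sd in zip(rs.names, sds)},
        extra={nm: float(v) for nm, v in zip(fam.extra_names, extra)},
        loglik=-float(res.fun),
        k=p + n_sd + n_extra,
        n=int(y.size),
        converged=bool(res.success or np.isfinite(res.fun)),
        boundary=boundary,
    )
    if not res.success:
        warnings.warn(f"GLMM ({family}) optimiser flagged non-convergence: {res.message}")
        fit.converged = False
    return fit


def warm_start_from(fit: GLMMFit) -> dict:
    """Starting values for a related candidate model, keyed by name."""
    return {
        "beta": dict(zip(fit.beta_names, fit.beta)),
        "log_sd": [np.log(max(s, 1e-3)) for s in fit.re_sd.values()],
        "extra": list(fit.extra.values()),
    }


def loglik_gauss_hermite(y, X, fit: GLMMFit, codes, n_nodes: int = 40) -> float:
    """Independent Gauss–Hermite evaluation of a single-factor GLMM likelihood.

    Used as a cross-check of the Laplace approximation: integrates the
    random intercept exactly (to quadrature accuracy) per group.  Only
    supports one grouping factor.
    """
    fam = FAMILIES[fit.family]
    sd = list(fit.re_sd.values())[0]
    extra = np.array(list(fit.extra.values()))
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    eta0 = np.asarray(X, dtype=float) @ fit.beta
    y = np.asarray(y, dtype=float)
    codes = np.asarray(codes)
    total = 0.0
    for g in np.unique(codes):
        sel = codes == g
        ll_nodes = np.array(
            [fam.loglik(y[sel], eta0[sel] + sd * t, extra).sum() for t in nodes]
        )
        total += special.logsumexp(ll_nodes + np.log(weights)) - 0.5 * np.log(2 * np.pi)
    return float(total)
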
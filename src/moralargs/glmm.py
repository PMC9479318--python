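"""Logistic regression with crossed Gaussian random intercepts.

Fits models of the form

    logit P(y_ij = 1) = x_ij' beta + u_{g1(ij)} + u_{g2(ij)} + ...

by maximum likelihood with a Laplace approximation to the marginal
likelihood: for each candidate vector of random-intercept SDs, the joint
penalized log-likelihood is maximized over (beta, u) with Newton's method,
and the marginal log-likelihood is approximated at the joint mode.  The
SDs are then profiled out with a quasi-Newton outer optimization on the
log-SD scale.

The Newton solve exploits the one-hot structure of intercept designs: the
largest grouping level (typically individuals, thousands of groups) has a
diagonal Hessian block and is eliminated by a Schur complement, leaving a
small dense system over the remaining levels and the fixed effects.  This
keeps each inner iteration linear in the number of observations.

Observation weights enter as frequency-style multipliers of the
log-likelihood, so integer weights reproduce row duplication exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .exceptions import EstimationError, ValidationError

_LOG_SD_BOUNDS = (-6.0, 3.0)


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


@dataclass
class CrossedGLMMResults:
    """Estimates from :class:`CrossedLogisticGLMM`.

    ``params``/``bse`` cover the fixed effects; ``re_sd`` maps level name
    to its estimated random-intercept SD; ``ranef`` maps level name to the
    posterior-mode intercepts.
    """

    params: dict[str, float]
    bse: dict[str, float]
    re_sd: dict[str, float]
    ranef: dict[str, np.ndarray]
    loglike: float
    n_obs: int
    n_groups: dict[str, int]
    converged: bool
    method: str = "laplace (joint Newton, Schur-eliminated crossed intercepts)"

    def conf_int(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        from scipy import stats

        z = stats.norm.ppf(0.5 + level / 2.0)
        return {
            k: (self.params[k] - z * self.bse[k], self.params[k] + z * self.bse[k])
            for k in self.params
        }


class CrossedLogisticGLMM:
    """Binary-response GLMM with crossed random intercepts.

    Parameters
    ----------
    endog : (n,) 0/1 array
    exog : (n, p) fixed-effects design (include the constant explicitly)
    groups : mapping level-name -> (n,) integer codes
        Grouping factors; levels with a single group are dropped with a
        warning (their variance is not identified).
    weights : optional (n,) nonnegative observation weights
    exog_names : optional fixed-effect names
    """

    def __init__(self, endog, exog, groups, weights=None, exog_names=None):
        y = np.asarray(endog, dtype=float)
        X = np.asarray(exog, dtype=float)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValidationError("endog/exog shapes do not align")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValidationError("endog must be binary 0/1")
        n, p = X.shape
        if weights is None:
            w = np.ones(n)
        else:
            w = np.asarray(weights, dtype=float)
            if w.shape != (n,):
                raise ValidationError("weights shape does not match endog")
            if (w < 0).any():
                raise ValidationError("weights must be nonnegative")
        self.y, self.X, self.w = y, X, w
        self.exog_names = (
            list(exog_names) if exog_names is not None else [f"x{j}" for j in range(p)]
        )
        if len(self.exog_names) != p:
            raise ValidationError("exog_names length does not match exog")

        levels = []
        for name, codes in groups.items():
            c = np.asarray(codes)
            _, inv = np.unique(c, return_inverse=True)
            q = int(inv.max()) + 1
            if q < 2:
                warnings.warn(
                    f"random-intercept level {name!r} has a single group; "
                    "dropping it from the model",
                    UserWarning,
                    stacklevel=2,
                )
                continue
            levels.append((name, inv.astype(np.intp), q))
        # eliminate the largest level by Schur complement
        levels.sort(key=lambda t: -t[2])
        self.levels = levels
        self._small_dim = sum(q for _, _, q in levels[1:]) + p
        if self._small_dim > 4000:
            raise EstimationError(
                "secondary random-effect levels too large for the dense "
                f"Schur solve (dim {self._small_dim})"
            )
        if levels:
            name_a, codes_a, q_a = levels[0]
            # flat cross indices (constant over iterations)
            self._cross_flat = [
                codes_a * q + codes for _, codes, q in levels[1:]
            ]

    # ------------------------------------------------------------------
    def _penalized_loglike(self, beta, us, sigmas):
        eta = self.X @ beta
        for (name, codes, q), u in zip(self.levels, us):
            eta = eta + u[codes]
        ll = float(np.sum(self.w * (self.y * eta - np.logaddexp(0.0, eta))))
        pen = 0.0
        for (name, codes, q), u, s in zip(self.levels, us, sigmas):
            pen += float(u @ u) / (2.0 * s * s)
        return ll - pen, eta

    def _inner_newton(self, sigmas, state, max_iter=100, tol=1e-10):
        """Maximize the penalized log-likelihood over (beta, u) jointly."""
        y, X, w = self.y, self.X, self.w
        n, p = X.shape
        beta = state["beta"].copy()
        us = [u.copy() for u in state["us"]]
        levels = self.levels
        has_big = bool(levels)
        if has_big:
            name_a, codes_a, q_a = levels[0]
        small = levels[1:]
        pll, eta = self._penalized_loglike(beta, us, sigmas)

        last = None
        for it in range(max_iter):
            mu = _sigmoid(eta)
            wirls = w * mu * (1.0 - mu) + 1e-12
            resid = w * (y - mu)

            # gradient
            g_beta = X.T @ resid
            g_us = []
            for (name, codes, q), u, s in zip(levels, us, sigmas):
                g_us.append(np.bincount(codes, resid, minlength=q) - u / (s * s))

            if has_big:
                d_a = np.bincount(codes_a, wirls, minlength=q_a) + 1.0 / (
                    sigmas[0] ** 2
                )
            # small dense block R over [small levels..., beta]
            dim_r = sum(q for _, _, q in small) + p
            R = np.zeros((dim_r, dim_r))
            offs = []
            off = 0
            for name, codes, q in small:
                offs.append(off)
                off += q
            off_beta = off
            # own blocks
            for (name, codes, q), o, s in zip(small, offs, sigmas[1:]):
                diag = np.bincount(codes, wirls, minlength=q) + 1.0 / (s * s)
                R[o : o + q, o : o + q] += np.diag(diag)
            # cross blocks among small levels
            for i, (ni, ci, qi) in enumerate(small):
                for j in range(i + 1, len(small)):
                    nj, cj, qj = small[j]
                    blk = np.bincount(
                        ci * qj + cj, wirls, minlength=qi * qj
                    ).reshape(qi, qj)
                    R[offs[i] : offs[i] + qi, offs[j] : offs[j] + qj] = blk
                    R[offs[j] : offs[j] + qj, offs[i] : offs[i] + qi] = blk.T
            # small x beta
            Xw = X * wirls[:, None]
            for (name, codes, q), o in zip(small, offs):
                blk = np.empty((q, p))
                for j in range(p):
                    blk[:, j] = np.bincount(codes, Xw[:, j], minlength=q)
                R[o : o + q, off_beta:] = blk
                R[off_beta:, o : o + q] = blk.T
            R[off_beta:, off_beta:] = X.T @ Xw

            g_r = np.concatenate(
                [g for g in g_us[1:]] + [g_beta]
            ) if has_big else np.concatenate([g for g in g_us] + [g_beta])

            if has_big:
                # B: big-level rows x [small..., beta] columns
                B = np.zeros((q_a, dim_r))
                for flat, (name, codes, q), o in zip(
                    self._cross_flat, small, offs
                ):
                    B[:, o : o + q] = np.bincount(
                        flat, wirls, minlength=q_a * q
                    ).reshape(q_a, q)
                for j in range(p):
                    B[:, off_beta + j] = np.bincount(
                        codes_a, Xw[:, j], minlength=q_a
                    )
                Binvd = B / d_a[:, None]
                S = R - B.T @ Binvd
                rhs = g_r - Binvd.T @ g_us[0]
                try:
                    delta_r = np.linalg.solve(S, rhs)
                except np.linalg.LinAlgError as exc:
                    raise EstimationError(f"singular GLMM system: {exc}") from exc
                delta_a = (g_us[0] - B @ delta_r) / d_a
            else:
                try:
                    delta_r = np.linalg.solve(R, g_r)
                except np.linalg.LinAlgError as exc:
                    raise EstimationError(f"singular GLMM system: {exc}") from exc
                delta_a = None

            # unpack step with halving
            step = 1.0
            for _ in range(30):
                new_us = [u.copy() for u in us]
                if has_big:
                    new_us[0] = us[0] + step * delta_a
                    for k, (name, codes, q) in enumerate(small):
                        new_us[k + 1] = us[k + 1] + step * delta_r[
                            offs[k] : offs[k] + q
                        ]
                else:
                    for k, (name, codes, q) in enumerate(small):
                        new_us[k] = us[k] + step * delta_r[offs[k] : offs[k] + q]
                new_beta = beta + step * delta_r[off_beta:]
                new_pll, new_eta = self._penalized_loglike(new_beta, new_us, sigmas)
                if new_pll >= pll - 1e-12:
                    break
                step *= 0.5
            improved = new_pll - pll
            beta, us, pll, eta = new_beta, new_us, new_pll, new_eta
            if last is not None and abs(improved) < tol * (1.0 + abs(pll)):
                break
            last = pll

        state["beta"], state["us"] = beta, us
        # pieces for the Laplace determinant and fixed-effect covariance
        mu = _sigmoid(eta)
        wirls = self.w * mu * (1.0 - mu) + 1e-12
        return {
            "beta": beta,
            "us": us,
            "pll": pll,
            "eta": eta,
            "wirls": wirls,
            "converged": it < max_iter - 1,
        }

    def _laplace_logdet_uu(self, wirls, sigmas):
        """log det of the penalized Hessian restricted to the random
        effects, via the same Schur elimination."""
        levels = self.levels
        if not levels:
            return 0.0
        name_a, codes_a, q_a = levels[0]
        small = levels[1:]
        d_a = np.bincount(codes_a, wirls, minlength=q_a) + 1.0 / (sigmas[0] ** 2)
        dim_u = sum(q for _, _, q in small)
        if dim_u == 0:
            return float(np.log(d_a).sum())
        R = np.zeros((dim_u, dim_u))
        offs = []
        off = 0
        for name, codes, q in small:
            offs.append(off)
            off += q
        for (name, codes, q), o, s in zip(small, offs, sigmas[1:]):
            diag = np.bincount(codes, wirls, minlength=q) + 1.0 / (s * s)
            R[o : o + q, o : o + q] += np.diag(diag)
        for i, (ni, ci, qi) in enumerate(small):
            for j in range(i + 1, len(small)):
                nj, cj, qj = small[j]
                blk = np.bincount(ci * qj + cj, wirls, minlength=qi * qj).reshape(
                    qi, qj
                )
                R[offs[i] : offs[i] + qi, offs[j] : offs[j] + qj] = blk
                R[offs[j] : offs[j] + qj, offs[i] : offs[i] + qi] = blk.T
        B = np.zeros((q_a, dim_u))
        for flat, (name, codes, q), o in zip(self._cross_flat, small, offs):
            B[:, o : o + q] = np.bincount(flat, wirls, minlength=q_a * q).reshape(
                q_a, q
            )
        S = R - B.T @ (B / d_a[:, None])
        sign, logdet_S = np.linalg.slogdet(S)
        if sign <= 0:
            raise EstimationError("non-PD Hessian in Laplace determinant")
        return float(np.log(d_a).sum() + logdet_S)

    def _marginal_loglike(self, log_sigmas, state):
        sigmas = np.exp(log_sigmas)
        res = self._inner_newton(sigmas, state)
        logdet_uu = self._laplace_logdet_uu(res["wirls"], sigmas)
        lml = res["pll"] - 0.5 * logdet_uu
        for (name, codes, q), s in zip(self.levels, sigmas):
            lml -= q * np.log(s)
        return lml, res

    # ------------------------------------------------------------------
    def fit(self, start_sd: float = 0.5, maxiter: int = 200) -> CrossedGLMMResults:
        n, p = self.X.shape
        state = {
            "beta": np.zeros(p),
            "us": [np.zeros(q) for _, _, q in self.levels],
        }
        k = len(self.levels)
        if k == 0:
            # no random effects: plain penalized Newton = logistic MLE
            res = self._inner_newton(np.array([]), state)
            cov = self._beta_cov(res, np.array([]))
            return self._package(res, np.array([]), cov, True)

        def neg(log_sigmas):
            lml, _ = self._marginal_loglike(log_sigmas, state)
            return -lml

        x0 = np.full(k, np.log(start_sd))
        opt = optimize.minimize(
            neg,
            x0,
            method="L-BFGS-B",
            bounds=[_LOG_SD_BOUNDS] * k,
            options={"maxiter": maxiter, "ftol": 1e-9, "gtol": 1e-6, "eps": 1e-4},
        )
        sigmas = np.exp(opt.x)
        lml, res = self._marginal_loglike(opt.x, state)
        cov = self._beta_cov(res, sigmas)
        return self._package(res, sigmas, cov, bool(opt.success) and res["converged"],
                             loglike=lml)

    def _beta_cov(self, res, sigmas):
        """Fixed-effect covariance: beta block of the inverse joint
        penalized Hessian (conditional on the estimated SDs)."""
        X, w = self.X, self.w
        n, p = X.shape
        wirls = res["wirls"]
        levels = self.levels
        Xw = X * wirls[:, None]
        if not levels:
            H = X.T @ Xw
            return np.linalg.inv(H)
        name_a, codes_a, q_a = levels[0]
        small = levels[1:]
        d_a = np.bincount(codes_a, wirls, minlength=q_a) + 1.0 / (sigmas[0] ** 2)
        dim_r = sum(q for _, _, q in small) + p
        R = np.zeros((dim_r, dim_r))
        offs = []
        off = 0
        for name, codes, q in small:
            offs.append(off)
            off += q
        off_beta = off
        for (name, codes, q), o, s in zip(small, offs, sigmas[1:]):
            diag = np.bincount(codes, wirls, minlength=q) + 1.0 / (s * s)
            R[o : o + q, o : o + q] += np.diag(diag)
        for i, (ni, ci, qi) in enumerate(small):
            for j in range(i + 1, len(small)):
                nj, cj, qj = small[j]
                blk = np.bincount(ci * qj + cj, wirls, minlength=qi * qj).reshape(
                    qi, qj
                )
                R[offs[i] : offs[i] + qi, offs[j] : offs[j] + qj] = blk
                R[offs[j] : offs[j] + qj, offs[i] : offs[i] + qi] = blk.T
        for (name, codes, q), o in zip(small, offs):
            blk = np.empty((q, p))
            for j in range(p):
                blk[:, j] = np.bincount(codes, Xw[:, j], minlength=q)
            R[o : o + q, off_beta:] = blk
            R[off_beta:, o : o + q] = blk.T
        R[off_beta:, off_beta:] = X.T @ Xw
        B = np.zeros((q_a, dim_r))
        for flat, (name, codes, q), o in zip(self._cross_flat, small, offs):
            B[:, o : o + q] = np.bincount(flat, wirls, minlength=q_a * q).reshape(
                q_a, q
            )
        for j in range(p):
            B[:, off_beta + j] = np.bincount(codes_a, Xw[:, j], minlength=q_a)
        S = R - B.T @ (B / d_a[:, None])
        cov_r = np.linalg.inv(S)
        return cov_r[off_beta:, off_beta:]

    def _package(self, res, sigmas, cov, converged, loglike=None):
        params = {k: float(v) for k, v in zip(self.exog_names, res["beta"])}
        bse = {k: float(v) for k, v in zip(self.exog_names, np.sqrt(np.diag(cov)))}
        re_sd = {
            name: float(s) for (name, _, _), s in zip(self.levels, sigmas)
        }
        ranef = {
            name: u for (name, _, _), u in zip(self.levels, res["us"])
        }
        n_groups = {name: q for name, _, q in self.levels}
        if loglike is None:
            loglike = res["pll"]
        return CrossedGLMMResults(
            params=params,
            bse=bse,
            re_sd=re_sd,
            ranef=ranef,
            loglike=float(loglike),
            n_obs=len(self.y),
            n_groups=n_groups,
            converged=converged,
        )
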
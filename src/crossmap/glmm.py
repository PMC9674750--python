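"""Mixed-effects logistic regression with crossed random intercepts.

Fits models of the form

    logit P(y_ij = 1) = x_ij' beta + u_participant(i) + u_item(j),
    u_g ~ Normal(0, tau_g^2)  independently per grouping factor,

by maximising the Laplace approximation to the marginal likelihood.  For a
fixed vector of random-effect standard deviations ``tau`` the fixed
effects and the random-effect modes are obtained jointly by penalised
Newton iterations (the penalised iteratively reweighted least squares
scheme standard for this model class); the outer optimisation over ``tau``
uses a quasi-Newton method on the Laplace log-likelihood

    l(tau) = l_data(eta_hat) - b_hat'b_hat / 2 - log det(I + Zt' W Zt) / 2,

where ``b`` are standardised random effects (``u_g = tau_g * b_g``), ``Zt``
stacks the scaled indicator columns of all grouping factors and ``W`` is
the Bernoulli weight matrix at the mode.  The standardised parameterisation
is smooth at ``tau = 0``, so variance components may collapse to zero
without numerical trouble.

Wald standard errors for the fixed effects come from the fixed-effect
block of the inverse penalised Hessian at the optimum (random-effect
uncertainty in ``tau`` is ignored, as is conventional for this estimator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats
from scipy.linalg import cho_factor, cho_solve

__all__ = ["MixedLogit", "MixedLogitResults", "GlmmFit"]


def _bernoulli_ll(y: np.ndarray, eta: np.ndarray) -> float:
    # sum y*eta - log(1 + exp(eta)), stable for large |eta|
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


class ConvergenceWarning(UserWarning):
    pass


class MixedLogit:
    """Logistic regression with crossed random intercepts (Laplace).

    Parameters
    ----------
    endog
        Binary response, shape ``(n,)``.
    exog
        Fixed-effect design matrix ``(n, p)`` (include the intercept
        column yourself, or use :meth:`from_formula`).
    groups
        Mapping of grouping-factor name to a length-``n`` array of level
        labels, e.g. ``{"participant": ..., "item": ...}``.  One or more
        factors; two crossed factors is the intended use.
    exog_names
        Optional column names for ``exog``.
    """

    def __init__(self, endog, exog, groups, exog_names=None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        n = self.endog.shape[0]
        if self.exog.shape[0] != n:
            raise ValueError("endog and exog lengths differ")
        if not np.all(np.isin(self.endog, (0.0, 1.0))):
            raise ValueError("endog must be binary 0/1")
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{j}" for j in range(self.exog.shape[1])
        ]
        if len(self.exog_names) != self.exog.shape[1]:
            raise ValueError("exog_names length mismatch")

        self.group_names: list[str] = []
        self._Z: list[sparse.csr_matrix] = []
        self.group_levels: dict[str, np.ndarray] = {}
        for name, labels in dict(groups).items():
            codes, levels = pd.factorize(np.asarray(labels), sort=True)
            if len(labels) != n:
                raise ValueError(f"grouping factor {name!r} length mismatch")
            if len(levels) < 2:
                raise ValueError(f"grouping factor {name!r} needs >= 2 levels")
            Z = sparse.csr_matrix(
                (np.ones(n), (np.arange(n), codes)), shape=(n, len(levels))
            )
            self.group_names.append(name)
            self._Z.append(Z)
            self.group_levels[name] = np.asarray(levels)
        if not self._Z:
            raise ValueError("at least one grouping factor is required")
        self._q = [Z.shape[1] for Z in self._Z]
        self._b = np.zeros(sum(self._q))  # warm-started random-effect modes

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame, groups) -> "MixedLogit":
        """Build from a patsy formula for the fixed part, e.g.
        ``"chose_model_image ~ C(condition)"``; ``groups`` is a mapping of
        factor name to the column holding its labels."""
        import patsy

        y, X = patsy.dmatrices(formula, data, return_type="dataframe")
        group_arrays = {name: data[col].to_numpy() for name, col in dict(groups).items()}
        return cls(
            y.to_numpy().ravel(),
            X.to_numpy(),
            group_arrays,
            exog_names=list(X.columns),
        )

    # ----- inner problem: random-effect mode at fixed (beta, tau) ---------
    def _inner(self, beta: np.ndarray, tau: np.ndarray, maxiter: int = 200,
               tol: float = 1e-10):
        """Newton maximisation over the standardised random effects ``b``;
        returns the mode, the Laplace log-likelihood and mode quantities."""
        y, X = self.endog, self.exog
        Zt = sparse.hstack([Z * t for Z, t in zip(self._Z, tau)], format="csr")
        q = Zt.shape[1]
        offset = X @ beta
        b = self._b.copy()

        def _pll(b):
            eta = offset + Zt @ b
            return _bernoulli_ll(y, eta) - 0.5 * b @ b, eta

        pll, eta = _pll(b)
        converged = False
        for _ in range(maxiter):
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            grad = Zt.T @ (y - mu) - b
            ZtW = Zt.multiply(w[:, None]).tocsr()
            Huu = (ZtW.T @ Zt).toarray()
            Huu[np.diag_indices(q)] += 1.0
            c, low = cho_factor(Huu, lower=True)
            step = cho_solve((c, low), grad)
            # step halving on the penalised log-likelihood
            alpha, accepted = 1.0, False
            for _ in range(40):
                cand = b + alpha * step
                pll_new, eta_new = _pll(cand)
                if pll_new >= pll - 1e-12:
                    accepted = True
                    break
                alpha *= 0.5
            if not accepted:  # no ascent left: already at the mode
                converged = np.max(np.abs(grad)) < 1e-4
                break
            improved = pll_new - pll
            b, pll, eta = cand, pll_new, eta_new
            if abs(improved) < tol and np.max(np.abs(grad)) < 1e-6:
                converged = True
                break
        self._b = b.copy()

        # Laplace correction at the mode
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        ZtW = Zt.multiply(w[:, None]).tocsr()
        Huu = (ZtW.T @ Zt).toarray()
        Huu[np.diag_indices(q)] += 1.0
        _, logdet = np.linalg.slogdet(Huu)
        llf = _bernoulli_ll(y, eta) - 0.5 * b @ b - 0.5 * logdet
        return b, llf, eta, w, Zt, converged

    def _neg_llf(self, x: np.ndarray) -> float:
        p = self.exog.shape[1]
        _, llf, *_ = self._inner(x[:p], np.abs(x[p:]))
        return -llf

    def fit(
        self,
        start_params: np.ndarray | None = None,
        start_tau: np.ndarray | None = None,
        maxiter: int = 500,
        tau_max: float = 50.0,
    ) -> "MixedLogitResults":
        """Maximise the Laplace log-likelihood over fixed effects and
        variance parameters jointly (quasi-Newton outer loop, Newton inner
        loop over the random-effect modes)."""
        G = len(self._Z)
        p = self.exog.shape[1]
        beta0 = (
            np.asarray(start_params, dtype=float)
            if start_params is not None
            else np.zeros(p)
        )
        tau0 = np.asarray(start_tau if start_tau is not None else [1.0] * G, dtype=float)
        self._b = np.zeros(sum(self._q))
        res = optimize.minimize(
            self._neg_llf,
            np.concatenate([beta0, tau0]),
            method="L-BFGS-B",
            bounds=[(None, None)] * p + [(0.0, tau_max)] * G,
            options={"eps": 1e-5, "maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-5},
        )
        beta, tau = res.x[:p], np.abs(res.x[p:])
        b, llf, eta, w, Zt, inner_ok = self._inner(beta, tau)

        # Wald covariance of beta: Schur complement of the penalised Hessian
        X = self.exog
        WX = X * w[:, None]
        ZtW = Zt.multiply(w[:, None]).tocsr()
        Hbb = X.T @ WX
        Hbu = (ZtW.T @ X).T
        Huu = (ZtW.T @ Zt).toarray()
        Huu[np.diag_indices(Zt.shape[1])] += 1.0
        c, low = cho_factor(Huu, lower=True)
        cov_beta = np.linalg.inv(Hbb - Hbu @ cho_solve((c, low), Hbu.T))

        # L-BFGS-B with numeric gradients may stop "abnormally" once it hits
        # the finite-difference noise floor; a small projected gradient at a
        # converged inner solve still counts as converged.
        grad_ok = res.jac is not None and np.max(np.abs(res.jac)) < 5e-2
        converged = bool(inner_ok and (res.success or grad_ok))
        if not converged:
            warnings.warn(
                f"mixed-logit fit did not fully converge: {res.message}",
                ConvergenceWarning,
                stacklevel=2,
            )
        bse = np.sqrt(np.diag(cov_beta))
        if np.max(np.abs(eta)) > 15 or np.max(bse) > 30:
            warnings.warn(
                "extreme linear predictor or standard errors; "
                "possible (quasi-)separation",
                ConvergenceWarning,
                stacklevel=2,
            )
            converged = False

        # per-level random effects on the natural scale (u = tau * b)
        ranef = {}
        offset = 0
        for name, Zg, t in zip(self.group_names, self._Z, tau):
            qg = Zg.shape[1]
            ranef[name] = pd.Series(
                t * b[offset : offset + qg], index=self.group_levels[name]
            )
            offset += qg

        return MixedLogitResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            cov_params=pd.DataFrame(
                cov_beta, index=self.exog_names, columns=self.exog_names
            ),
            vc=dict(zip(self.group_names, (tau**2).tolist())),
            llf=float(llf),
            converged=converged,
            random_effects=ranef,
        )


@dataclass
class GlmmFit:
    """Lightweight fitted-GLMM record (also constructible by hand).

    ``fixed_effects`` maps coefficient name to ``(beta, se, z, p)``;
    ``random_variances`` maps grouping-factor name to ``tau^2``.
    """

    fixed_effects: dict[str, tuple[float, float, float, float]]
    random_variances: dict[str, float]
    log_likelihood: float
    n_obs: int
    formula: str = ""
    converged: bool = True

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.random_variances.values()):
            raise ValueError("variance components must be >= 0")
        if self.n_obs <= 0:
            raise ValueError("n_obs must be positive")


class MixedLogitResults:
    """Results of :meth:`MixedLogit.fit`: estimates, uncertainty, summary."""

    def __init__(self, model, params, cov_params, vc, llf, converged, random_effects):
        self.model = model
        self.params = params
        self.cov_params = cov_params
        self.vc = vc  # variance components tau^2 per grouping factor
        self.llf = llf
        self.converged = converged
        self.random_effects = random_effects

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.params.index)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2.0 * stats.norm.sf(np.abs(self.zvalues)), index=self.params.index
        )

    @property
    def nobs(self) -> int:
        return len(self.model.endog)

    @property
    def k_fe(self) -> int:
        return len(self.params)

    @property
    def k_params(self) -> int:
        return self.k_fe + len(self.vc)

    # spec-shaped accessors ------------------------------------------------
    @property
    def fixed_effects(self) -> dict[str, tuple[float, float, float, float]]:
        return {
            name: (
                float(self.params[name]),
                float(self.bse[name]),
                float(self.zvalues[name]),
                float(self.pvalues[name]),
            )
            for name in self.params.index
        }

    @property
    def random_variances(self) -> dict[str, float]:
        return dict(self.vc)

    @property
    def log_likelihood(self) -> float:
        return self.llf

    @property
    def n_obs(self) -> int:
        return self.nobs

    def as_glmm_fit(self, formula: str = "") -> GlmmFit:
        return GlmmFit(
            self.fixed_effects,
            self.random_variances,
            self.llf,
            self.nobs,
            formula=formula,
            converged=self.converged,
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        crit = stats.norm.ppf(1.0 - alpha / 2.0)
        return pd.DataFrame(
            {
                "lower": self.params - crit * self.bse,
                "upper": self.params + crit * self.bse,
            }
        )

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Mixed-effects logistic regression (Laplace approximation)",
            "=" * 66,
            f"No. observations: {self.nobs:>8}    Log-likelihood: {self.llf:.3f}",
            f"Converged:        {str(self.converged):>8}",
            "-" * 66,
            f"{'':<22}{'coef':>9}{'std err':>9}{'z':>8}{'P>|z|':>9}{'[0.025':>10}{'0.975]':>9}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<22}{self.params[name]:>9.4f}{self.bse[name]:>9.4f}"
                f"{self.zvalues[name]:>8.2f}{self.pvalues[name]:>9.4f}"
                f"{ci.loc[name, 'lower']:>10.4f}{ci.loc[name, 'upper']:>9.4f}"
            )
        lines.append("-" * 66)
        for g, v in self.vc.items():
            lines.append(f"random intercept var ({g}): {v:.4f}")
        return "\n".join(lines)
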
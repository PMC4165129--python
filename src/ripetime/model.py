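"""Maximum-likelihood fitting and inference for the ripening-time model.

`RipeningModel` compiles a censored dataset and a covariate specification
into a design matrix and exposes the marginal log-likelihood as a function
of an unconstrained parameter vector (covariances via log-Cholesky factors).
`fit()` maximises it by quasi-Newton optimisation with restarts and returns a
`RipeningResults` carrying estimates, observed-information standard errors,
likelihood-ratio tests against nested fits, and the per-genotype timing
summary (days to first ripening sign, length of the climacteric phase).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

from .likelihood import (
    QuadratureSpec,
    RipeningModelParams,
    _loglik_core,
    gauss_hermite_nodes,
)
from .stages import CensoredBivariateObservation

__all__ = [
    "ModelSpec",
    "RipeningModel",
    "RipeningResults",
    "LrtResult",
    "fit_mle",
    "likelihood_ratio_test",
    "select_covariates",
    "genotype_summary",
]

#: canonical column order of a censored-observation table
CENSORED_COLUMNS = ["plant_id", "genotype", "truss", "fruit", "L1", "R1", "L2", "R2"]


def censored_to_frame(obs: list[CensoredBivariateObservation]) -> pd.DataFrame:
    """Censored observations as a DataFrame (columns ``CENSORED_COLUMNS``)."""
    return pd.DataFrame(
        [
            {
                "plant_id": o.plant_id,
                "genotype": o.genotype,
                "truss": o.truss,
                "fruit": o.fruit,
                "L1": o.lower[0],
                "R1": o.upper[0],
                "L2": o.lower[1],
                "R2": o.upper[1],
            }
            for o in obs
        ],
        columns=CENSORED_COLUMNS,
    )


def frame_to_censored(df: pd.DataFrame) -> list[CensoredBivariateObservation]:
    """Inverse of :func:`censored_to_frame`."""
    return [
        CensoredBivariateObservation(
            plant_id=str(r.plant_id),
            genotype=str(r.genotype),
            truss=int(r.truss),
            fruit=int(r.fruit),
            lower=(float(r.L1), float(r.L2)),
            upper=(float(r.R1), float(r.R2)),
        )
        for r in df.itertuples(index=False)
    ]


@dataclass(frozen=True)
class ModelSpec:
    """Covariate structure of the ripening model.

    ``include_fruit`` is ``False``, ``"categorical"`` (one effect per fruit
    position, first position as reference) or ``"linear"`` (a slope per day
    of fruit position).  The per-plant random effect is always present.
    """

    genotypes: tuple
    reference: str
    include_truss: bool = False
    include_fruit: object = "categorical"
    quad: QuadratureSpec = field(default_factory=QuadratureSpec)

    def __post_init__(self) -> None:
        object.__setattr__(self, "genotypes", tuple(self.genotypes))
        if self.reference not in self.genotypes:
            raise ValueError(
                f"reference genotype {self.reference!r} not among {self.genotypes}"
            )
        if self.include_fruit not in (False, "categorical", "linear"):
            raise ValueError("include_fruit must be False, 'categorical' or 'linear'")

    @classmethod
    def infer(cls, data: pd.DataFrame, reference: str | None = None, **kwargs) -> "ModelSpec":
        """Build a spec from the genotype levels present in a dataset."""
        levels = sorted(data["genotype"].astype(str).unique())
        if reference is None:
            reference = "WT" if "WT" in levels else levels[0]
        ordered = [reference] + [g for g in levels if g != reference]
        return cls(genotypes=tuple(ordered), reference=reference, **kwargs)


class RipeningModel:
    """Bivariate interval-censored mixed model for ripening event times.

    Parameters
    ----------
    data : DataFrame
        Censored observations, columns ``plant_id, genotype, truss, fruit,
        L1, R1, L2, R2`` (``inf`` for right-censored upper bounds).
    spec : ModelSpec
        Covariate structure.
    constrain_zero : iterable of str, optional
        Genotypes whose effect is fixed at zero (used for per-genotype
        likelihood-ratio tests); they are folded into the reference level.
    """

    def __init__(self, data, spec: ModelSpec, constrain_zero=()):
        if isinstance(data, list):
            data = censored_to_frame(data)
        df = data.copy()
        df["plant_id"] = df["plant_id"].astype(str)
        df["genotype"] = df["genotype"].astype(str)
        df = df.sort_values(["plant_id", "truss", "fruit"], kind="mergesort")
        df = df.reset_index(drop=True)
        self.data = df
        self.spec = spec
        self.constrain_zero = frozenset(constrain_zero)

        seen = set(df["genotype"])
        unknown = seen - set(spec.genotypes)
        if unknown:
            raise ValueError(f"dataset contains genotypes not in the spec: {sorted(unknown)}")

        self.lower = df[["L1", "L2"]].to_numpy(float)
        self.upper = df[["R1", "R2"]].to_numpy(float)
        pid = df["plant_id"].to_numpy()
        self.plant_starts = np.flatnonzero(
            np.concatenate([[True], pid[1:] != pid[:-1]])
        )
        self.plant_ids = pid[self.plant_starts]
        self._build_design(df)

    # -- design -----------------------------------------------------------
    def _build_design(self, df: pd.DataFrame) -> None:
        spec = self.spec
        n = len(df)
        cols = [np.ones(n)]
        names = ["mu"]
        effective_ref = {spec.reference} | self.constrain_zero
        self.genotype_levels = [g for g in spec.genotypes if g not in effective_ref]
        for g in self.genotype_levels:
            ind = (df["genotype"] == g).to_numpy(float)
            if ind.sum() == 0:
                raise ValueError(f"genotype level {g!r} has no observations")
            cols.append(ind)
            names.append(f"alpha[{g}]")
        self.truss_levels = []
        if spec.include_truss:
            levels = sorted(df["truss"].unique())
            self.truss_levels = levels[1:]
            for b in self.truss_levels:
                cols.append((df["truss"] == b).to_numpy(float))
                names.append(f"beta[{b}]")
        self.fruit_levels = []
        if spec.include_fruit == "categorical":
            levels = sorted(df["fruit"].unique())
            self.fruit_levels = levels[1:]
            for f in self.fruit_levels:
                cols.append((df["fruit"] == f).to_numpy(float))
                names.append(f"gamma[{f}]")
        elif spec.include_fruit == "linear":
            cols.append(df["fruit"].to_numpy(float) - 1.0)
            names.append("gamma_lin")
        self.X = np.column_stack(cols)
        self.coef_names = names
        self.n_coef = len(names)
        # free parameters: 2 per coefficient row + 3 each for Sigma, Sigma0
        self.n_free_params = 2 * self.n_coef + 6
        self.param_names = [f"{nm}({i})" for nm in names for i in (1, 2)] + [
            "lS_11", "lS_21", "lS_22", "lS0_11", "lS0_21", "lS0_22",
        ]

    # -- parameter packing -------------------------------------------------
    @staticmethod
    def _chol_from(v: np.ndarray) -> np.ndarray:
        # bounded exponentials keep wild optimizer excursions evaluable
        d = np.exp(np.clip([v[0], v[2]], -16.0, 16.0))
        return np.array([[d[0], 0.0], [np.clip(v[1], -1e6, 1e6), d[1]]])

    @staticmethod
    def _chol_to(cov: np.ndarray) -> np.ndarray:
        # log-Cholesky of a (near-)PD matrix, ridge-stabilised at the boundary
        c = np.asarray(cov, float)
        try:
            L = np.linalg.cholesky(c)
        except np.linalg.LinAlgError:
            L = np.linalg.cholesky(c + 1e-6 * np.eye(2))
        return np.array([np.log(max(L[0, 0], 1e-8)), L[1, 0], np.log(max(L[1, 1], 1e-8))])

    def _unpack(self, theta: np.ndarray):
        p = self.n_coef
        B = theta[: 2 * p].reshape(p, 2)
        Ls = self._chol_from(theta[2 * p : 2 * p + 3])
        Ls0 = self._chol_from(theta[2 * p + 3 : 2 * p + 6])
        return B, Ls @ Ls.T, Ls0 @ Ls0.T

    def loglike(self, theta: np.ndarray) -> float:
        """Marginal log-likelihood at an unconstrained parameter vector."""
        B, sigma, sigma0 = self._unpack(np.asarray(theta, float))
        means = self.X @ B
        z, logw = gauss_hermite_nodes(sigma0, self.spec.quad.nodes_per_dim)
        ll = _loglik_core(self.lower, self.upper, means, sigma, z, logw, self.plant_starts)
        return float(ll.sum())

    # -- starting values ---------------------------------------------------
    def _start(self) -> np.ndarray:
        """Interval-midpoint starting values.

        Event times are proxied by interval midpoints (right-censored fruits
        by the lower bound plus half the median finite width); fixed effects
        start at the corresponding group-mean contrasts and the midpoint
        covariance is split equally between plant and residual parts.
        """
        lo, hi = self.lower, self.upper
        finite = np.isfinite(hi)
        width = np.where(finite, hi - lo, np.nan)
        med_w = np.nanmedian(width, axis=0)
        med_w = np.where(np.isfinite(med_w), med_w, 3.5)
        mid = np.where(finite, (lo + hi) / 2.0, lo + med_w / 2.0)
        theta = np.zeros(self.n_free_params)
        df = self.data
        ref_rows = (df["genotype"] == self.spec.reference).to_numpy()
        mu0 = mid[ref_rows].mean(axis=0) if ref_rows.any() else mid.mean(axis=0)
        theta[0:2] = mu0
        i = 1
        for g in self.genotype_levels:
            rows = (df["genotype"] == g).to_numpy()
            theta[2 * i : 2 * i + 2] = mid[rows].mean(axis=0) - mu0
            i += 1
        # residual midpoints after the genotype contrasts seed truss/fruit
        resid = mid - mu0
        for g in self.genotype_levels:
            rows = (df["genotype"] == g).to_numpy()
            resid[rows] -= mid[rows].mean(axis=0) - mu0
        for b in self.truss_levels:
            rows = (df["truss"] == b).to_numpy()
            theta[2 * i : 2 * i + 2] = resid[rows].mean(axis=0) - resid.mean(axis=0)
            i += 1
        if self.spec.include_fruit == "categorical":
            for f in self.fruit_levels:
                rows = (df["fruit"] == f).to_numpy()
                theta[2 * i : 2 * i + 2] = resid[rows].mean(axis=0) - resid.mean(axis=0)
                i += 1
        elif self.spec.include_fruit == "linear":
            pos = df["fruit"].to_numpy(float) - 1.0
            var = ((pos - pos.mean()) ** 2).sum()
            if var > 0:
                theta[2 * i : 2 * i + 2] = (pos - pos.mean()) @ resid / var
            i += 1
        c = np.cov(mid.T) if len(mid) > 1 else np.eye(2)
        c = np.atleast_2d(c) + 0.5 * np.eye(2)
        half = self._chol_to(c / 2.0)
        p = self.n_coef
        theta[2 * p : 2 * p + 3] = half
        theta[2 * p + 3 : 2 * p + 6] = half
        return theta

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        start: np.ndarray | None = None,
        restarts: int = 3,
        seed: int = 0,
        maxiter: int = 500,
        compute_se: bool = True,
    ) -> "RipeningResults":
        """Maximise the marginal likelihood.

        Runs a quasi-Newton (L-BFGS-B) optimisation from a midpoint-based
        start plus ``restarts - 1`` jittered starts and keeps the best
        optimum; deterministic for a given seed.
        """
        theta0 = self._start()
        starts = [theta0] if start is None else [np.asarray(start, float), theta0]
        rng = np.random.default_rng(seed)
        jitter_scale = np.full(self.n_free_params, 0.15)
        jitter_scale[: 2 * self.n_coef] = 0.75  # days-scale for fixed effects
        for _ in range(max(0, restarts - 1)):
            starts.append(starts[0] + rng.normal(0.0, jitter_scale))

        def nll(th):
            try:
                v = self.loglike(th)
            except (ValueError, np.linalg.LinAlgError):
                return np.inf
            return np.inf if not np.isfinite(v) else -v

        best = None
        trace = []
        for s in starts:
            res = optimize.minimize(
                nll,
                s,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-6, "eps": 1e-6},
            )
            trace.append(
                {"nll": float(res.fun), "nit": int(res.nit), "message": str(res.message)}
            )
            if best is None or res.fun < best.fun:
                best = res
        converged = bool(best.success and np.isfinite(best.fun))
        cov_params = None
        singular = False
        if compute_se and np.isfinite(best.fun):
            cov_params, singular = self._cov_params(best.x)
        return RipeningResults(
            model=self,
            theta=np.asarray(best.x, float),
            llf=-float(best.fun),
            converged=converged,
            cov_params_=cov_params,
            information_singular=singular,
            optimizer_trace=trace,
        )

    def _cov_params(self, theta: np.ndarray):
        """Inverse observed information by central-difference Hessian."""
        k = len(theta)
        h = 1e-4 * np.maximum(1.0, np.abs(theta))
        f0 = self.loglike(theta)
        H = np.empty((k, k))
        fp = np.empty(k)
        fm = np.empty(k)
        for i in range(k):
            e = np.zeros(k)
            e[i] = h[i]
            fp[i] = self.loglike(theta + e)
            fm[i] = self.loglike(theta - e)
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
        for i in range(k):
            for j in range(i + 1, k):
                e = np.zeros(k)
                e[i] = h[i]
                e[j] = h[j]
                fpp = self.loglike(theta + e)
                fmm = self.loglike(theta - e)
                H[i, j] = H[j, i] = (
                    fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm
                ) / (2 * h[i] * h[j])
        info = -H
        try:
            cov = np.linalg.inv(info)
            if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
                raise np.linalg.LinAlgError
            return cov, False
        except np.linalg.LinAlgError:
            return np.linalg.pinv(info), True

    def params_from_theta(self, theta: np.ndarray) -> RipeningModelParams:
        """Unpack an unconstrained vector into named model parameters."""
        B, sigma, sigma0 = self._unpack(np.asarray(theta, float))
        i = 1
        alpha = {self.spec.reference: np.zeros(2)}
        for g in self.constrain_zero:
            alpha[g] = np.zeros(2)
        for g in self.genotype_levels:
            alpha[g] = B[i]
            i += 1
        beta = None
        if self.spec.include_truss:
            all_truss = sorted(self.data["truss"].unique())
            beta = {all_truss[0]: np.zeros(2)} if all_truss else {}
            for b in self.truss_levels:
                beta[b] = B[i]
                i += 1
        gamma = None
        gamma_linear = None
        if self.spec.include_fruit == "categorical":
            all_fruit = sorted(self.data["fruit"].unique())
            gamma = {all_fruit[0]: np.zeros(2)} if all_fruit else {}
            for f in self.fruit_levels:
                gamma[f] = B[i]
                i += 1
        elif self.spec.include_fruit == "linear":
            gamma_linear = B[i]
            i += 1
        return RipeningModelParams(
            mu=B[0],
            alpha=alpha,
            beta=beta,
            gamma=gamma,
            gamma_linear=gamma_linear,
            sigma0=sigma0,
            sigma=sigma,
        )


@dataclass
class LrtResult:
    """Likelihood-ratio test of a reduced model nested in a full model."""

    statistic: float
    df: int
    p_value: float
    label: str = ""


class RipeningResults:
    """Fitted ripening model: estimates, uncertainties and summaries."""

    def __init__(self, model, theta, llf, converged, cov_params_, information_singular, optimizer_trace):
        self.model = model
        self.theta = theta
        self.llf = llf
        self.converged = converged
        self.cov_params_ = cov_params_
        self.information_singular = information_singular
        self.optimizer_trace = optimizer_trace
        self.params = model.params_from_theta(theta)
        self.n_free_params = model.n_free_params

    def compute_se(self) -> "RipeningResults":
        """(Re)compute the observed-information parameter covariance in place."""
        self.cov_params_, self.information_singular = self.model._cov_params(self.theta)
        return self

    @property
    def bse(self) -> pd.Series | None:
        """Delta-method standard errors of the free parameters."""
        if self.cov_params_ is None:
            return None
        return pd.Series(np.sqrt(np.diag(self.cov_params_)), index=self.model.param_names)

    def lr_test(self, reduced: "RipeningResults", label: str = "") -> LrtResult:
        return likelihood_ratio_test(self, reduced, label=label)

    # -- genotype summary --------------------------------------------------
    def genotype_summary(self, stars: bool = True, fit_kwargs: dict | None = None) -> pd.DataFrame:
        """Per-genotype timing estimates in the style of a ripening figure.

        Columns: days from anthesis to the first ripening sign
        (``first_sign_days`` = mu1 + alpha1), length of the climacteric phase
        (``ripening_length_days`` = (mu2 + alpha2) - (mu1 + alpha1)), their
        delta-method standard errors, and, when ``stars`` is set, the
        per-genotype likelihood-ratio test against the wild type
        (``*`` p<0.05, ``**`` p<0.01, ``***`` p<0.001).
        """
        model = self.model
        mu = self.params.mu
        names = model.param_names
        rows = []
        fit_kwargs = dict(fit_kwargs or {})
        fit_kwargs.setdefault("compute_se", False)
        for g in model.spec.genotypes:
            a = self.params.alpha[g]
            first = mu[0] + a[0]
            length = (mu[1] + a[1]) - (mu[0] + a[0])
            se_first = se_length = np.nan
            if self.cov_params_ is not None:
                w_first = np.zeros(len(names))
                w_len = np.zeros(len(names))
                w_first[names.index("mu(1)")] = 1.0
                w_len[names.index("mu(2)")] = 1.0
                w_len[names.index("mu(1)")] = -1.0
                if g != model.spec.reference and f"alpha[{g}](1)" in names:
                    w_first[names.index(f"alpha[{g}](1)")] = 1.0
                    w_len[names.index(f"alpha[{g}](2)")] = 1.0
                    w_len[names.index(f"alpha[{g}](1)")] = -1.0
                se_first = float(np.sqrt(w_first @ self.cov_params_ @ w_first))
                se_length = float(np.sqrt(w_len @ self.cov_params_ @ w_len))
            p = np.nan
            star = ""
            if stars and g != model.spec.reference and g in [*model.genotype_levels]:
                reduced_model = RipeningModel(
                    model.data, model.spec, constrain_zero={g} | set(model.constrain_zero)
                )
                full_fit, reduced_fit = fit_nested(self, reduced_model, **fit_kwargs)
                test = likelihood_ratio_test(full_fit, reduced_fit, label=f"alpha[{g}]=0")
                p = test.p_value
                star = "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
            rows.append(
                {
                    "genotype": g,
                    "first_sign_days": first,
                    "first_sign_se": se_first,
                    "ripening_length_days": length,
                    "ripening_length_se": se_length,
                    "p_vs_reference": p,
                    "significance": star,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text fit summary."""
        lines = [
            "Bivariate interval-censored ripening model",
            "=" * 52,
            f"observations (fruits): {len(self.model.data):>5d}"
            f"    plants: {len(self.model.plant_ids)}",
            f"log-likelihood: {self.llf:.4f}    free parameters: {self.n_free_params}",
            f"converged: {self.converged}"
            f"    quadrature: {self.model.spec.quad.nodes_per_dim} nodes/dim",
            "-" * 52,
            f"{'parameter':<18}{'estimate':>12}{'std err':>12}",
        ]
        bse = self.bse
        fixed = self.theta[: 2 * self.model.n_coef]
        for i, nm in enumerate(self.model.param_names[: 2 * self.model.n_coef]):
            se = f"{bse.iloc[i]:>12.4f}" if bse is not None else f"{'--':>12}"
            lines.append(f"{nm:<18}{fixed[i]:>12.4f}{se}")
        s, s0 = self.params.sigma, self.params.sigma0
        lines.append("-" * 52)
        lines.append(f"Sigma  (residual): [[{s[0,0]:.3f}, {s[0,1]:.3f}], [{s[1,0]:.3f}, {s[1,1]:.3f}]]")
        lines.append(f"Sigma0 (plant):    [[{s0[0,0]:.3f}, {s0[0,1]:.3f}], [{s0[1,0]:.3f}, {s0[1,1]:.3f}]]")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serialisable representation of the fit."""
        p = self.params
        return {
            "spec": {
                "genotypes": list(self.model.spec.genotypes),
                "reference": self.model.spec.reference,
                "include_truss": self.model.spec.include_truss,
                "include_fruit": self.model.spec.include_fruit,
                "quad_nodes": self.model.spec.quad.nodes_per_dim,
            },
            "loglik": self.llf,
            "n_free_params": self.n_free_params,
            "converged": self.converged,
            "theta": self.theta.tolist(),
            "param_names": self.model.param_names,
            "mu": p.mu.tolist(),
            "alpha": {g: v.tolist() for g, v in p.alpha.items()},
            "beta": {str(k): v.tolist() for k, v in (p.beta or {}).items()} or None,
            "gamma": {str(k): v.tolist() for k, v in (p.gamma or {}).items()} or None,
            "gamma_linear": None if p.gamma_linear is None else p.gamma_linear.tolist(),
            "sigma": p.sigma.tolist(),
            "sigma0": p.sigma0.tolist(),
            "stderr": None
            if self.bse is None
            else [v if np.isfinite(v) else None for v in self.bse.tolist()],
        }


# -- module-level operations ----------------------------------------------

def _map_theta(src_model: RipeningModel, src_theta: np.ndarray, dst_model: RipeningModel) -> np.ndarray:
    """Transfer shared named parameters between nested models (rest zero)."""
    dst = np.zeros(dst_model.n_free_params)
    src_idx = {nm: i for i, nm in enumerate(src_model.param_names)}
    for i, nm in enumerate(dst_model.param_names):
        if nm in src_idx:
            dst[i] = src_theta[src_idx[nm]]
    return dst


def fit_nested(
    full_fit: RipeningResults, reduced_model: RipeningModel, **fit_options
) -> tuple[RipeningResults, RipeningResults]:
    """Fit a nested reduction, warm-started from the full fit.

    The reduced model starts from the full optimum projected onto its
    parameter space, which makes the likelihood ordering between nested
    optima structurally reliable; if the reduced optimum nevertheless beats
    the full one (the full optimiser stalled), the full model is refitted
    from the reduced optimum and the better fit kept.  Returns the
    (possibly improved) full fit and the reduced fit.
    """
    full_model = full_fit.model
    warm = _map_theta(full_model, full_fit.theta, reduced_model)
    reduced_fit = reduced_model.fit(start=warm, **fit_options)
    if reduced_fit.llf > full_fit.llf:
        back = _map_theta(reduced_model, reduced_fit.theta, full_model)
        opts = dict(fit_options)
        opts["restarts"] = 1
        refit = full_model.fit(start=back, **opts)
        if refit.llf > full_fit.llf:
            full_fit = refit
    return full_fit, reduced_fit


def fit_mle(dataset, spec: ModelSpec, **options) -> RipeningResults:
    """Fit the ripening model by maximum likelihood (see RipeningModel.fit)."""
    return RipeningModel(dataset, spec).fit(**options)


def likelihood_ratio_test(full: RipeningResults, reduced: RipeningResults, label: str = "") -> LrtResult:
    """Chi-squared likelihood-ratio test of nested fitted models."""
    full_names = set(full.model.param_names)
    red_names = set(reduced.model.param_names)
    if not red_names <= full_names:
        extra = sorted(red_names - full_names)
        raise ValueError(f"models are not nested; reduced model has extra terms {extra}")
    if len(full.model.data) != len(reduced.model.data):
        raise ValueError("models were fitted to different datasets")
    df = full.n_free_params - reduced.n_free_params
    if df < 0:
        raise ValueError("reduced model has more free parameters than the full model")
    stat = 2.0 * (full.llf - reduced.llf)
    tol = 1e-4 * max(1.0, abs(full.llf))
    if stat < -tol:
        raise ValueError(
            f"reduced model has higher likelihood than the full model "
            f"(delta={stat / 2:.6g}); optimizer failure"
        )
    stat = max(stat, 0.0)
    # df = 0 (identical specifications) degenerates to a point-mass null
    p = 1.0 if df == 0 else float(chi2.sf(stat, df))
    return LrtResult(statistic=stat, df=df, p_value=p, label=label)


def select_covariates(
    dataset, base_spec: ModelSpec, alpha: float = 0.05, return_fit: bool = False, **fit_options
):
    """Backward selection of the truss and fruit covariates by LRT.

    Drops each covariate in turn from the base specification and keeps it
    only if the likelihood-ratio test rejects at the given level; the plant
    random effect is structural and never dropped.  Returns the retained
    spec and the list of tests performed.
    """
    tests: list[LrtResult] = []
    spec = base_spec
    full_fit = fit_mle(dataset, spec, compute_se=False, **fit_options)
    if base_spec.include_truss:
        red = replace(spec, include_truss=False)
        full_fit, red_fit = fit_nested(
            full_fit, RipeningModel(dataset, red), compute_se=False, **fit_options
        )
        t = likelihood_ratio_test(full_fit, red_fit, label="truss")
        tests.append(t)
        if t.p_value >= alpha:
            spec = red
            full_fit = red_fit
    if base_spec.include_fruit:
        red = replace(spec, include_fruit=False)
        full_fit, red_fit = fit_nested(
            full_fit, RipeningModel(dataset, red), compute_se=False, **fit_options
        )
        t = likelihood_ratio_test(full_fit, red_fit, label="fruit")
        tests.append(t)
        if t.p_value >= alpha:
            spec = red
            full_fit = red_fit
    if return_fit:
        return spec, tests, full_fit
    return spec, tests


def genotype_summary(fit: RipeningResults, dataset=None, stars: bool = True) -> pd.DataFrame:
    """Figure-style per-genotype timing table from a fitted model."""
    if not fit.converged:
        warnings.warn("summarising a fit that did not converge", RuntimeWarning, stacklevel=2)
    return fit.genotype_summary(stars=stars)
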
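"""Marginal log-likelihood of the bivariate interval-censored mixed model.

Each fruit contributes a rectangle probability: its latent pair of event
times (first ripening sign, red stage) is bivariate normal around a linear
predictor built from genotype, truss and fruit-position effects, shifted by a
per-plant bivariate random effect Z_p ~ N2(0, Sigma0) and residual
U ~ N2(0, Sigma).  The per-plant likelihood marginalises Z_p:

    l_p = log E_{Z ~ N2(0, Sigma0)} [ prod_fruits P_Sigma( Y in rect - m - Z ) ]

The expectation is evaluated by product Gauss--Hermite quadrature after
whitening Z along the eigenvectors of Sigma0 (rank-adaptive, so a singular or
zero Sigma0 degenerates gracefully to a line or point mass), and the product
over fruits is accumulated in log space with a log-sum-exp over nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .bvn import standardized_rectangle_probability
from .stages import CensoredBivariateObservation

__all__ = [
    "QuadratureSpec",
    "RipeningModelParams",
    "plant_loglikelihood",
    "total_loglikelihood",
]


@dataclass(frozen=True)
class QuadratureSpec:
    """Product Gauss--Hermite rule used to marginalise the plant effect."""

    nodes_per_dim: int = 15
    method: str = "gauss-hermite"

    def __post_init__(self) -> None:
        if self.nodes_per_dim < 1:
            raise ValueError("nodes_per_dim must be >= 1")
        if self.method != "gauss-hermite":
            raise ValueError(f"unsupported quadrature method {self.method!r}")


def _as_cov(m, name: str, *, strict: bool) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (2, 2) or not np.allclose(m, m.T):
        raise ValueError(f"{name} must be a symmetric 2x2 matrix")
    eigvals = np.linalg.eigvalsh(m)
    if strict and eigvals[0] <= 0:
        raise ValueError(f"{name} must be positive definite, eigenvalues {eigvals}")
    if not strict and eigvals[0] < -1e-10 * max(1.0, eigvals[-1]):
        raise ValueError(f"{name} must be positive semidefinite, eigenvalues {eigvals}")
    return m


@dataclass
class RipeningModelParams:
    """Parameters of the bivariate ripening-time model.

    Each effect is a length-2 vector: component 1 acts on days to the first
    ripening sign, component 2 on days to the red stage.  Reference coding is
    used throughout: the wild-type genotype, the first truss level and the
    first fruit position carry exactly zero effect.

    Parameters
    ----------
    mu : array-like, shape (2,)
        Baseline event times (days from anthesis) of the reference levels.
    alpha : dict of genotype -> length-2 array
        Genotype shifts; the reference genotype maps to (0, 0).
    beta : dict of truss index -> length-2 array, optional
        Truss effects (``None`` drops the covariate).
    gamma : dict of fruit position -> length-2 array, optional
        Categorical fruit-position effects (``None`` drops the covariate).
    gamma_linear : array-like, shape (2,), optional
        Linear-in-position alternative: effect ``gamma_linear * (f - 1)``.
        Mutually exclusive with ``gamma``.
    sigma0 : array-like, shape (2, 2)
        Covariance of the per-plant random effect (positive semidefinite).
    sigma : array-like, shape (2, 2)
        Residual covariance (positive definite).
    """

    mu: np.ndarray
    alpha: dict = field(default_factory=dict)
    beta: dict | None = None
    gamma: dict | None = None
    gamma_linear: np.ndarray | None = None
    sigma0: np.ndarray = None
    sigma: np.ndarray = None

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float).reshape(2)
        self.alpha = {g: np.asarray(v, dtype=float).reshape(2) for g, v in self.alpha.items()}
        if self.beta is not None:
            self.beta = {int(b): np.asarray(v, dtype=float).reshape(2) for b, v in self.beta.items()}
        if self.gamma is not None and self.gamma_linear is not None:
            raise ValueError("gamma and gamma_linear are mutually exclusive")
        if self.gamma is not None:
            self.gamma = {int(f): np.asarray(v, dtype=float).reshape(2) for f, v in self.gamma.items()}
        if self.gamma_linear is not None:
            self.gamma_linear = np.asarray(self.gamma_linear, dtype=float).reshape(2)
        self.sigma0 = _as_cov(self.sigma0, "sigma0", strict=False)
        # PSD suffices for simulation; likelihood evaluation checks strict PD
        self.sigma = _as_cov(self.sigma, "sigma", strict=False)

    def mean_for(self, genotype: str, truss: int, fruit: int) -> np.ndarray:
        """Linear predictor (m1, m2) for a fruit's latent event times."""
        if genotype not in self.alpha:
            raise KeyError(f"unknown genotype level {genotype!r}")
        m = self.mu + self.alpha[genotype]
        if self.beta is not None:
            if truss not in self.beta:
                raise KeyError(f"unknown truss level {truss!r}")
            m = m + self.beta[truss]
        if self.gamma is not None:
            if fruit not in self.gamma:
                raise KeyError(f"unknown fruit-position level {fruit!r}")
            m = m + self.gamma[fruit]
        elif self.gamma_linear is not None:
            m = m + self.gamma_linear * (fruit - 1)
        return m


def gauss_hermite_nodes(sigma0: np.ndarray, nodes_per_dim: int):
    """Quadrature nodes and log-weights for E over Z ~ N2(0, sigma0).

    The integral is whitened along the eigenvectors of sigma0 and a product
    Gauss--Hermite rule applied per retained dimension; dimensions whose
    eigenvalue is (numerically) zero are dropped, so the rule adapts to
    singular and zero random-effect covariances.

    Returns
    -------
    z : ndarray, shape (Q, 2)
        Node positions in the original coordinates.
    logw : ndarray, shape (Q,)
        Log-weights; ``logsumexp(logw) == 0``.
    """
    sigma0 = np.asarray(sigma0, dtype=float)
    eigvals, eigvecs = np.linalg.eigh(sigma0)
    tol = 1e-12 * max(1.0, eigvals[-1])
    keep = eigvals > tol
    r = int(keep.sum())
    if r == 0:
        return np.zeros((1, 2)), np.zeros(1)
    x, w = np.polynomial.hermite.hermgauss(nodes_per_dim)
    scale = np.sqrt(2.0 * eigvals[keep])  # (r,)
    vecs = eigvecs[:, keep]  # (2, r)
    if r == 1:
        z = np.outer(x * scale[0], vecs[:, 0])
        logw = np.log(w) - 0.5 * np.log(np.pi)
    else:
        xx1, xx2 = np.meshgrid(x, x, indexing="ij")
        pts = np.column_stack([xx1.ravel() * scale[0], xx2.ravel() * scale[1]])
        z = pts @ vecs.T
        ww1, ww2 = np.meshgrid(np.log(w), np.log(w), indexing="ij")
        logw = (ww1 + ww2).ravel() - np.log(np.pi)
    return z, logw


def _loglik_core(lower, upper, means, sigma, z, logw, plant_starts):
    """Vectorised per-plant marginal log-likelihoods.

    Parameters are pre-assembled arrays: bounds and linear predictors with
    one row per fruit (fruits of one plant contiguous, ``plant_starts``
    marking group starts), residual covariance ``sigma``, and quadrature
    nodes/log-weights for the plant random effect.
    """
    s1 = np.sqrt(sigma[0, 0])
    s2 = np.sqrt(sigma[1, 1])
    # clip to the open interval so a residual covariance driven to the
    # singular boundary during optimisation stays evaluable
    rho = float(np.clip(sigma[0, 1] / (s1 * s2), -1 + 1e-12, 1 - 1e-12))
    a = lower - means  # (F, 2)
    b = upper - means
    # censoring bounds snap to the observation schedule, so distinct fruits
    # often share an identical shifted rectangle; evaluate each once
    shifted = np.concatenate([a, b], axis=1)
    uniq, inv = np.unique(shifted, axis=0, return_inverse=True)
    with np.errstate(invalid="ignore"):
        a1 = (uniq[:, None, 0] - z[None, :, 0]) / s1  # (U, Q)
        a2 = (uniq[:, None, 1] - z[None, :, 1]) / s2
        b1 = (uniq[:, None, 2] - z[None, :, 0]) / s1
        b2 = (uniq[:, None, 3] - z[None, :, 1]) / s2
    p = standardized_rectangle_probability(a1, b1, a2, b2, rho)
    with np.errstate(divide="ignore"):
        logp = np.log(p)[inv]  # -inf where a fruit's rectangle has zero mass
    group = np.add.reduceat(logp, plant_starts, axis=0)  # (P, Q)
    return logsumexp(group + logw[None, :], axis=1)


def _require_pd_sigma(params: RipeningModelParams) -> None:
    if np.linalg.eigvalsh(params.sigma)[0] <= 0:
        raise ValueError("sigma must be positive definite for likelihood evaluation")


def _assemble(obs: list[CensoredBivariateObservation], params: RipeningModelParams):
    lower = np.array([o.lower for o in obs], dtype=float)
    upper = np.array([o.upper for o in obs], dtype=float)
    means = np.array(
        [params.mean_for(o.genotype, o.truss, o.fruit) for o in obs], dtype=float
    )
    return lower, upper, means


def plant_loglikelihood(
    fruits_of_plant: list[CensoredBivariateObservation],
    params: RipeningModelParams,
    quad: QuadratureSpec = QuadratureSpec(),
) -> float:
    """Marginal log-likelihood contribution of one plant's fruits."""
    if not fruits_of_plant:
        raise ValueError("plant has no fruits")
    ids = {o.plant_id for o in fruits_of_plant}
    if len(ids) != 1:
        raise ValueError(f"fruits belong to multiple plants: {sorted(ids)}")
    _require_pd_sigma(params)
    lower, upper, means = _assemble(fruits_of_plant, params)
    z, logw = gauss_hermite_nodes(params.sigma0, quad.nodes_per_dim)
    ll = _loglik_core(lower, upper, means, params.sigma, z, logw, np.array([0]))
    value = float(ll[0])
    if value == -np.inf:
        warnings.warn(
            f"plant {fruits_of_plant[0].plant_id} has zero likelihood under the "
            "given parameters",
            RuntimeWarning,
            stacklevel=2,
        )
    return value


def total_loglikelihood(
    dataset: list[CensoredBivariateObservation],
    params: RipeningModelParams,
    quad: QuadratureSpec = QuadratureSpec(),
) -> float:
    """Sum of per-plant marginal log-likelihoods over the whole dataset."""
    if not dataset:
        raise ValueError("dataset is empty")
    _require_pd_sigma(params)
    order = sorted(range(len(dataset)), key=lambda i: str(dataset[i].plant_id))
    obs = [dataset[i] for i in order]
    lower, upper, means = _assemble(obs, params)
    plant_ids = [o.plant_id for o in obs]
    starts = [0] + [i for i in range(1, len(obs)) if plant_ids[i] != plant_ids[i - 1]]
    z, logw = gauss_hermite_nodes(params.sigma0, quad.nodes_per_dim)
    ll = _loglik_core(lower, upper, means, params.sigma, z, logw, np.array(starts))
    for s, v in zip(starts, ll):
        if v == -np.inf:
            warnings.warn(
                f"plant {plant_ids[s]} has zero likelihood under the given parameters",
                RuntimeWarning,
                stacklevel=2,
            )
    return float(ll.sum())
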
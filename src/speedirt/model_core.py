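"""The joint two-dimensional measurement model.

Two Rasch-type response functions share a bivariate latent trait per person:

* a *completion* trait ``theta0`` drives a sequential stopping process over
  the item sequence, observed through the attempt indicators, with item
  difficulties constrained to be affine in item position
  (``beta0_k = tau0 + (k - K) * tau1``);
* an *ability* trait ``theta1`` drives correctness of the recorded answers,
  with free item difficulties ``b_k``.

Latent trait means are fixed at 0 for identification; covariate models shift
them through regression coefficients, so the reference category (men,
control) stays centred.  Throughout the package the latent vector is ordered
``(theta0 completion, theta1 ability)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import invgamma, norm, wishart

__all__ = [
    "ItemParameters",
    "LatentState",
    "RegressionCoefficients",
    "PriorConfig",
    "ModelSpec",
    "irf",
    "log_sigmoid",
    "completion_difficulty",
    "completion_difficulties",
    "loglik_ability",
    "loglik_completion",
    "latent_mean",
    "log_prior",
]


def irf(theta, beta):
    """Rasch item response function ``exp(t-b) / (1 + exp(t-b))``, overflow-safe."""
    return expit(np.asarray(theta, dtype=float) - np.asarray(beta, dtype=float))


def log_sigmoid(x):
    """log of the logistic function, stable for large negative arguments."""
    return -np.logaddexp(0.0, -np.asarray(x, dtype=float))


def completion_difficulty(k, K: int, tau0: float, tau1: float):
    """Affine completion difficulty ``tau0 + (k - K) * tau1`` for 1-based item k.

    With ``tau1 > 0`` earlier items have lower difficulty, i.e. are more
    likely to be attempted.
    """
    k = np.asarray(k)
    if np.any(k < 1) or np.any(k > K):
        raise ValueError(f"item index out of range 1..{K}")
    return tau0 + (k - K) * tau1


def completion_difficulties(K: int, tau0: float, tau1: float) -> np.ndarray:
    """Vector of completion difficulties for items 1..K."""
    return completion_difficulty(np.arange(1, K + 1), K, tau0, tau1)


@dataclass
class ItemParameters:
    """Ability difficulties plus the two parameters of the completion constraint."""

    b: np.ndarray
    tau0: float = 1.0
    tau1: float = 0.0

    def __post_init__(self) -> None:
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))

    @property
    def n_items(self) -> int:
        return self.b.size

    @property
    def beta0(self) -> np.ndarray:
        return completion_difficulties(self.n_items, self.tau0, self.tau1)


@dataclass
class RegressionCoefficients:
    """Covariate effects on (ability, completion), active set per model id.

    Each pair is ``(effect on ability theta1, effect on completion theta0)``,
    matching the conventional subscripts 1 (ability) and 2 (completion).
    """

    beta: tuple[float, float] = (0.0, 0.0)   # gender
    gamma: tuple[float, float] = (0.0, 0.0)  # condition
    delta: tuple[float, float] = (0.0, 0.0)  # interaction

    def active(self, model_id: int) -> dict[str, tuple[float, float]]:
        if model_id == 1:
            return {}
        if model_id == 2:
            return {"beta": self.beta}
        if model_id == 3:
            return {"gamma": self.gamma}
        if model_id == 4:
            return {"beta": self.beta, "gamma": self.gamma, "delta": self.delta}
        raise ValueError(f"unknown model_id {model_id!r}")

    def matrix(self, model_id: int) -> np.ndarray:
        """(p, 2) coefficient matrix in canonical (completion, ability) order,
        rows aligned with the design columns of ``model_id``."""
        pairs = list(self.active(model_id).values())
        if not pairs:
            return np.zeros((0, 2))
        # stored pairs are (ability, completion); canonical order flips them
        return np.array([[c, a] for a, c in pairs], dtype=float)


@dataclass
class LatentState:
    theta0: np.ndarray
    theta1: np.ndarray
    Sigma: np.ndarray
    mu: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.theta0 = np.asarray(self.theta0, dtype=float)
        self.theta1 = np.asarray(self.theta1, dtype=float)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        if self.Sigma.shape != (2, 2):
            raise ValueError("Sigma must be 2x2")
        if not np.allclose(self.Sigma, self.Sigma.T):
            raise ValueError("Sigma must be symmetric")
        if self.mu is None:
            self.mu = np.zeros((self.theta0.size, 2))

    @property
    def theta(self) -> np.ndarray:
        return np.column_stack([self.theta0, self.theta1])


@dataclass
class PriorConfig:
    """All hyperprior settings, with sensitivity switches.

    ``coef_scale10_is_variance`` controls how the scale 10 of the normal
    priors on tau1 and the regression coefficients is read: as a variance
    (default) or as a precision.  ``invgamma_on_variance`` moves the
    InvGamma(0.1, 0.1) hyperprior from the SD of the ability difficulties to
    their variance.  ``free_tau0`` releases the fixed completion intercept.
    """

    tau1_mean: float = 0.0
    tau1_scale: float = 10.0
    tau0_fixed: float = 1.0
    free_tau0: bool = False
    sigma_b_shape: float = 0.1
    sigma_b_rate: float = 0.1
    invgamma_on_variance: bool = False
    wishart_df: float = 3.0
    wishart_scale: tuple = ((1.0, 0.0), (0.0, 1.0))
    coef_mean: float = 0.0
    coef_scale: float = 10.0
    coef_scale10_is_variance: bool = True

    def __post_init__(self) -> None:
        if self.wishart_df < 2:
            raise ValueError("Wishart degrees of freedom must be >= dimension (2)")

    @property
    def tau1_var(self) -> float:
        return self.tau1_scale if self.coef_scale10_is_variance else 1.0 / self.tau1_scale

    @property
    def coef_var(self) -> float:
        return self.coef_scale if self.coef_scale10_is_variance else 1.0 / self.coef_scale

    @property
    def wishart_scale_matrix(self) -> np.ndarray:
        return np.asarray(self.wishart_scale, dtype=float)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["wishart_scale"] = self.wishart_scale_matrix.tolist()
        return d


@dataclass
class ModelSpec:
    """Which covariate model to fit, for how many items, under which priors."""

    model_id: int
    K: int
    prior: PriorConfig = field(default_factory=PriorConfig)

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2, 3, 4):
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if self.K < 1:
            raise ValueError("K must be >= 1")

    @property
    def n_design_columns(self) -> int:
        return {1: 0, 2: 1, 3: 1, 4: 3}[self.model_id]

    def design_column_names(self) -> tuple[str, ...]:
        from .data_io import MODEL_DESIGNS
        return MODEL_DESIGNS[self.model_id]

    def to_dict(self) -> dict:
        return {"model_id": self.model_id, "K": self.K, "prior": self.prior.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        prior = d.get("prior", {})
        if isinstance(prior, dict):
            prior = PriorConfig(**prior)
        return cls(model_id=d["model_id"], K=d["K"], prior=prior)


def loglik_ability(resp_row: np.ndarray, theta1: float, b: np.ndarray) -> float:
    """Bernoulli log-likelihood of one person's recorded answers.

    Missing cells contribute nothing: only the observed responses enter the
    ability channel, so skipped items are absent observations, not failures.
    """
    resp_row = np.asarray(resp_row, dtype=float)
    b = np.asarray(b, dtype=float)
    if resp_row.shape != b.shape:
        raise ValueError("response row and difficulties are not aligned")
    obs = ~np.isnan(resp_row)
    if not obs.any():
        return 0.0
    sign = 2.0 * resp_row[obs] - 1.0
    return float(log_sigmoid(sign * (theta1 - b[obs])).sum())


def loglik_completion(
    ind_row: np.ndarray, theta0: float, tau0: float, tau1: float, K: int | None = None
) -> float:
    """Log-likelihood of one person's attempt indicators under the stopping model.

    Each indicator 1 contributes ``log p_k``, the single 0 contributes
    ``log(1 - p_k)`` with ``p_k = irf(theta0, beta0_k)``; structurally missing
    cells contribute nothing.  This equals the log-probability of attempting
    exactly that many steps of the sequential process.
    """
    ind_row = np.asarray(ind_row, dtype=float)
    if K is None:
        K = ind_row.size
    if ind_row.size != K:
        raise ValueError("indicator row length does not match K")
    zeros = np.flatnonzero(ind_row == 0.0)
    if zeros.size > 1:
        raise ValueError("malformed indicator row: more than one 0")
    beta0 = completion_difficulties(K, tau0, tau1)
    x = theta0 - beta0
    total = float(log_sigmoid(x[ind_row == 1.0]).sum())
    if zeros.size:
        total += float(log_sigmoid(-x[zeros[0]]))
    return total


def latent_mean(
    design_row: Sequence[float], coefs: RegressionCoefficients, model_id: int
) -> np.ndarray:
    """Covariate-implied latent mean, canonical order (completion, ability).

    Model 1 has no covariates and returns (0, 0); the reference category
    (men, control) has mean (0, 0) under every model.
    """
    design_row = np.asarray(design_row, dtype=float)
    C = coefs.matrix(model_id)
    if design_row.size != C.shape[0]:
        raise ValueError(
            f"design row has {design_row.size} columns, model {model_id} expects {C.shape[0]}"
        )
    if C.shape[0] == 0:
        return np.zeros(2)
    return design_row @ C


def _log_bivariate_normal(theta: np.ndarray, mu: np.ndarray, Sigma: np.ndarray) -> float:
    resid = theta - mu
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return -np.inf
    prec = np.linalg.inv(Sigma)
    quad = np.einsum("ni,ij,nj->n", resid, prec, resid)
    n = resid.shape[0]
    return float(-0.5 * (quad.sum() + n * (logdet + 2.0 * np.log(2.0 * np.pi))))


def log_prior(
    items: ItemParameters,
    sigma_b: float,
    Sigma: np.ndarray,
    coefs: RegressionCoefficients,
    theta: np.ndarray,
    mu: np.ndarray,
    model_id: int,
    prior: PriorConfig,
) -> float:
    """Joint log prior density of a full parameter state.

    A non-positive-definite ``Sigma`` (or non-positive ``sigma_b``) yields
    ``-inf`` — a rejected state, never an exception — so Metropolis steps can
    probe the boundary safely.
    """
    Sigma = np.asarray(Sigma, dtype=float)
    eigs = np.linalg.eigvalsh((Sigma + Sigma.T) / 2.0)
    if eigs.min() <= 0 or sigma_b <= 0:
        return -np.inf
    total = norm.logpdf(items.tau1, prior.tau1_mean, np.sqrt(prior.tau1_var))
    if prior.free_tau0:
        total += norm.logpdf(items.tau0, 0.0, np.sqrt(prior.tau1_var))
    if prior.invgamma_on_variance:
        total += invgamma.logpdf(sigma_b**2, prior.sigma_b_shape, scale=prior.sigma_b_rate)
    else:
        total += invgamma.logpdf(sigma_b, prior.sigma_b_shape, scale=prior.sigma_b_rate)
    total += norm.logpdf(items.b, 0.0, sigma_b).sum()
    for pair in coefs.active(model_id).values():
        total += norm.logpdf(np.asarray(pair), prior.coef_mean, np.sqrt(prior.coef_var)).sum()
    precision = np.linalg.inv(Sigma)
    total += wishart.logpdf(precision, df=prior.wishart_df, scale=prior.wishart_scale_matrix)
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    mu = np.broadcast_to(np.asarray(mu, dtype=float), theta.shape)
    total += _log_bivariate_normal(theta, mu, Sigma)
    return float(total)
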
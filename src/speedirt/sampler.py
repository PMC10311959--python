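"""Multi-chain Markov chain Monte Carlo for the joint two-dimensional model.

The kernel is Metropolis-within-Gibbs: adaptive random-walk proposals for the
person traits, the ability difficulties, the completion-constraint slope and
the difficulty-scale hyperparameter, and exact conjugate Gibbs draws for the
latent covariance (normal–Wishart update on the precision) and for the
regression coefficients (multivariate normal given the traits).  Proposal
scales are tuned only during the adaptation phase; burn-in follows
adaptation and neither is retained.

Randomness follows a strict contract: one root seed, with each chain's
stream derived deterministically from ``(seed, chain_id)``, so reruns are
bit-identical.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Sequence

import json

import numpy as np
import pandas as pd
from scipy.stats import wishart

from .data_io import CovariateTable, IndicatorMatrix, ResponseMatrix, design_matrix
from .model_core import ModelSpec, PriorConfig, completion_difficulties, log_sigmoid

logger = logging.getLogger(__name__)

__all__ = [
    "MCMCConfig",
    "PosteriorDraws",
    "initialize_chain",
    "run_mcmc",
    "fit_model",
    "sample_latent_covariance",
]


def sample_latent_covariance(
    resid: np.ndarray, prior: PriorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Conjugate draw of (Sigma, precision) given latent residuals.

    The Wishart prior on the precision updates to
    ``Wishart(df + N, (scale^-1 + R'R)^-1)``; equivalently Sigma is an
    inverse-Wishart draw.  Exact Gibbs step, no Metropolis correction.
    """
    resid = np.asarray(resid, dtype=float)
    scale_post = np.linalg.inv(
        np.linalg.inv(prior.wishart_scale_matrix) + resid.T @ resid)
    T = np.asarray(wishart.rvs(df=prior.wishart_df + resid.shape[0],
                               scale=scale_post, random_state=rng))
    return np.linalg.inv(T), T

_LOG_2PI = math.log(2.0 * math.pi)

#: design column -> coefficient family
_COEF_FAMILY = {"gender": "beta", "condition": "gamma", "gender_x_condition": "delta"}


@dataclass
class MCMCConfig:
    """Iteration scheme and sampler tuning.

    Defaults mirror the reference scheme: 3 chains, 25,000 adaptation and
    25,000 burn-in iterations each, and 60,000 posterior draws in total
    (i.e. 20,000 retained per chain); ``escalated_burnin`` is the fallback
    used when a fit fails the convergence battery.
    """

    n_chains: int = 3
    n_adapt: int = 25_000
    n_burnin: int = 25_000
    n_posterior_total: int = 60_000
    seed: int = 0
    init_dispersion: float = 1.0
    thin_theta: int = 0  # 0 = do not store person traits
    escalated_burnin: int = 100_000
    target_accept_theta: float = 0.30
    target_accept_item: float = 0.35
    target_accept_scalar: float = 0.44
    adapt_window: int = 50

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.n_posterior_total < 1:
            raise ValueError("n_posterior_total must be >= 1")
        if self.n_posterior_total % self.n_chains != 0:
            raise ValueError("n_posterior_total must be divisible by n_chains")
        if self.n_adapt < 0 or self.n_burnin < 0:
            raise ValueError("iteration counts must be non-negative")

    @property
    def n_keep_per_chain(self) -> int:
        return self.n_posterior_total // self.n_chains

    def escalated(self) -> "MCMCConfig":
        return replace(self, n_burnin=self.escalated_burnin)

    def to_dict(self) -> dict:
        return asdict(self)


class _DataBundle:
    """Precomputed masks and indices shared by all likelihood evaluations."""

    def __init__(self, resp: ResponseMatrix, ind: IndicatorMatrix, design: np.ndarray):
        if ind.values.shape != resp.values.shape:
            raise ValueError("response and indicator matrices are not aligned")
        self.N, self.K = resp.values.shape
        self.obs = ~np.isnan(resp.values)
        # +1/-1 for correct/incorrect; 0 where unobserved (masked out later)
        self.sign = np.where(self.obs, 2.0 * np.nan_to_num(resp.values) - 1.0, 0.0)
        self.obs_f = self.obs.astype(float)
        self.att_f = (ind.values == 1.0).astype(float)
        stop = ind.values == 0.0
        self.has_stop = stop.any(axis=1)
        self.stop_idx = np.where(self.has_stop, stop.argmax(axis=1), 0)
        self.design = np.asarray(design, dtype=float).reshape(self.N, -1)
        if design is None:
            self.design = np.zeros((self.N, 0))

    # --- ability channel -------------------------------------------------
    def ability_ll_rows(self, theta1: np.ndarray, b: np.ndarray) -> np.ndarray:
        m = self.sign * (theta1[:, None] - b[None, :])
        return (log_sigmoid(m) * self.obs_f).sum(axis=1)

    def ability_ll_cols(self, theta1: np.ndarray, b: np.ndarray) -> np.ndarray:
        m = self.sign * (theta1[:, None] - b[None, :])
        return (log_sigmoid(m) * self.obs_f).sum(axis=0)

    # --- completion channel ----------------------------------------------
    def completion_ll_rows(self, theta0: np.ndarray, beta0: np.ndarray) -> np.ndarray:
        m = theta0[:, None] - beta0[None, :]
        ll = (log_sigmoid(m) * self.att_f).sum(axis=1)
        hs = self.has_stop
        ll[hs] += log_sigmoid(beta0[self.stop_idx[hs]] - theta0[hs])
        return ll


@dataclass
class _ChainState:
    theta: np.ndarray          # (N, 2) canonical order (completion, ability)
    b: np.ndarray              # (K,)
    tau0: float
    tau1: float
    sigma_b: float
    Sigma: np.ndarray          # (2, 2)
    C: np.ndarray              # (p, 2) coefficients, canonical column order


def initialize_chain(
    spec: ModelSpec, n_persons: int, cfg: MCMCConfig, chain_id: int
) -> _ChainState:
    """Overdispersed starting state, deterministic in ``(seed, chain_id)``.

    Location parameters start at normal draws around their prior means with
    spread proportional to ``init_dispersion``; variances start at uniform
    draws around 1.  ``init_dispersion = 0`` collapses every chain onto the
    prior means.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), int(chain_id), 0xA11CE]))
    disp = float(cfg.init_dispersion)
    p = spec.n_design_columns
    b = disp * rng.normal(0.0, 1.0, size=spec.K)
    tau1 = disp * rng.normal(0.0, 0.25)
    tau0 = spec.prior.tau0_fixed
    if spec.prior.free_tau0:
        tau0 = spec.prior.tau0_fixed + disp * rng.normal(0.0, 0.25)
    sigma_b = 1.0 + disp * rng.uniform(-0.6, 1.0)
    v0 = 1.0 + disp * rng.uniform(-0.6, 1.0)
    v1 = 1.0 + disp * rng.uniform(-0.6, 1.0)
    rho = disp * rng.uniform(-0.4, 0.4)
    cov = rho * math.sqrt(v0 * v1)
    Sigma = np.array([[v0, cov], [cov, v1]])
    C = disp * rng.normal(0.0, 0.5, size=(p, 2))
    theta = disp * rng.normal(0.0, 1.0, size=(n_persons, 2))
    return _ChainState(theta=theta, b=b, tau0=tau0, tau1=tau1,
                       sigma_b=sigma_b, Sigma=Sigma, C=C)


@dataclass
class PosteriorDraws:
    """Retained draws for every chain, with full config provenance.

    ``params[name]`` has shape ``(n_chains, n_kept)``.  Person traits are
    stored (thinned) only when requested, shape ``(n_chains, n_thin, N, 2)``.
    """

    params: dict
    theta: np.ndarray | None
    seed: int
    config: dict
    spec: dict

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_kept_per_chain(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def parameter_names(self) -> list[str]:
        return list(self.params)

    def get(self, name: str) -> np.ndarray:
        return self.params[name]

    def sigma_draws(self) -> np.ndarray:
        """(n_draws, 2, 2) pooled covariance draws in canonical order."""
        v0 = self.params["var_completion"].ravel()
        v1 = self.params["var_ability"].ravel()
        cv = self.params["cov_completion_ability"].ravel()
        out = np.empty((v0.size, 2, 2))
        out[:, 0, 0] = v0
        out[:, 1, 1] = v1
        out[:, 0, 1] = out[:, 1, 0] = cv
        return out

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for name, arr in self.params.items():
            c, t = arr.shape
            frames.append(pd.DataFrame({
                "chain": np.repeat(np.arange(1, c + 1), t),
                "iteration": np.tile(np.arange(1, t + 1), c),
                "parameter": name,
                "value": arr.ravel(),
            }))
        return pd.concat(frames, ignore_index=True)

    def save(self, outdir: str | Path, stem: str = "draws") -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        csv_path = outdir / f"{stem}.csv"
        self.to_dataframe().to_csv(csv_path, index=False)
        meta_path = outdir / f"{stem}_meta.json"
        meta_path.write_text(json.dumps(
            {"seed": self.seed, "config": self.config, "spec": self.spec}, indent=2))
        return [csv_path, meta_path]


class _Adapter:
    """Robbins–Monro tuning of a log proposal scale toward a target rate."""

    def __init__(self, scale: float, target: float):
        self.log_scale = math.log(scale)
        self.target = target
        self.accepted = 0.0
        self.proposed = 0
        self.rounds = 0

    @property
    def scale(self) -> float:
        return math.exp(self.log_scale)

    def observe(self, accepted: float, proposed: int) -> None:
        self.accepted += accepted
        self.proposed += proposed

    def maybe_adapt(self) -> None:
        if self.proposed == 0:
            return
        self.rounds += 1
        rate = self.accepted / self.proposed
        step = min(0.5, 2.0 / math.sqrt(self.rounds))
        self.log_scale += step * (rate - self.target)
        self.log_scale = min(max(self.log_scale, -8.0), 4.0)
        self.accepted = 0.0
        self.proposed = 0


def _log_invgamma(x: float, shape: float, rate: float) -> float:
    return shape * math.log(rate) - math.lgamma(shape) - (shape + 1.0) * math.log(x) - rate / x


def _log_sigma_b_prior(sigma_b: float, prior: PriorConfig) -> float:
    if prior.invgamma_on_variance:
        # InvGamma on the variance, evaluated as a density in sigma_b
        return _log_invgamma(sigma_b**2, prior.sigma_b_shape, prior.sigma_b_rate) + math.log(2.0 * sigma_b)
    return _log_invgamma(sigma_b, prior.sigma_b_shape, prior.sigma_b_rate)


def _coef_names(spec: ModelSpec) -> list[str]:
    names = []
    for col in spec.design_column_names():
        fam = _COEF_FAMILY[col]
        names.append(f"{fam}_ability")
        names.append(f"{fam}_completion")
    return names


def _run_single_chain(
    bundle: _DataBundle, spec: ModelSpec, cfg: MCMCConfig, chain_id: int,
    store: dict, theta_store: np.ndarray | None,
) -> None:
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), int(chain_id)]))
    prior = spec.prior
    N, K, p = bundle.N, bundle.K, bundle.design.shape[1]
    state = initialize_chain(spec, N, cfg, chain_id)
    if p == 0:
        state.C = np.zeros((0, 2))

    beta0 = completion_difficulties(K, state.tau0, state.tau1)
    comp_ll = bundle.completion_ll_rows(state.theta[:, 0], beta0)
    abil_ll = bundle.ability_ll_rows(state.theta[:, 1], state.b)
    for name, arr in (("completion likelihood", comp_ll), ("ability likelihood", abil_ll)):
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(f"non-finite log-posterior at start in block: {name}")

    mu = bundle.design @ state.C if p else np.zeros((N, 2))
    prec = np.linalg.inv(state.Sigma)
    chol = np.linalg.cholesky(state.Sigma)

    ad_theta = _Adapter(0.5, cfg.target_accept_theta)
    ad_b = _Adapter(0.5, cfg.target_accept_item)
    ad_tau1 = _Adapter(0.1, cfg.target_accept_scalar)
    ad_tau0 = _Adapter(0.1, cfg.target_accept_scalar)
    ad_sb = _Adapter(0.3, cfg.target_accept_scalar)

    coef_prec0 = 1.0 / prior.coef_var
    tau1_var = prior.tau1_var

    n_keep = cfg.n_keep_per_chain
    total = cfg.n_adapt + cfg.n_burnin + n_keep
    stall_window = 0
    kept = 0
    thin = cfg.thin_theta

    for it in range(total):
        adapting = it < cfg.n_adapt

        # --- person traits: joint RW proposal along the covariance geometry
        z = rng.standard_normal((N, 2))
        prop = state.theta + ad_theta.scale * (z @ chol.T)
        resid_cur = state.theta - mu
        resid_prop = prop - mu
        quad_cur = np.einsum("ni,ij,nj->n", resid_cur, prec, resid_cur)
        quad_prop = np.einsum("ni,ij,nj->n", resid_prop, prec, resid_prop)
        comp_prop = bundle.completion_ll_rows(prop[:, 0], beta0)
        abil_prop = bundle.ability_ll_rows(prop[:, 1], state.b)
        log_ratio = (comp_prop - comp_ll) + (abil_prop - abil_ll) - 0.5 * (quad_prop - quad_cur)
        accept = np.log(rng.random(N)) < log_ratio
        state.theta[accept] = prop[accept]
        comp_ll[accept] = comp_prop[accept]
        abil_ll[accept] = abil_prop[accept]
        ad_theta.observe(accept.sum(), N)

        # --- ability difficulties, one accept decision per item
        bz = rng.standard_normal(K)
        b_prop = state.b + ad_b.scale * bz
        cols_cur = bundle.ability_ll_cols(state.theta[:, 1], state.b)
        cols_prop = bundle.ability_ll_cols(state.theta[:, 1], b_prop)
        pr = -(b_prop**2 - state.b**2) / (2.0 * state.sigma_b**2)
        acc_b = np.log(rng.random(K)) < (cols_prop - cols_cur + pr)
        if acc_b.any():
            state.b[acc_b] = b_prop[acc_b]
            abil_ll = bundle.ability_ll_rows(state.theta[:, 1], state.b)
        ad_b.observe(acc_b.sum(), K)

        # --- completion slope tau1 (and tau0 when freed)
        t1_prop = state.tau1 + ad_tau1.scale * rng.standard_normal()
        beta0_prop = completion_difficulties(K, state.tau0, t1_prop)
        comp_prop_rows = bundle.completion_ll_rows(state.theta[:, 0], beta0_prop)
        lr = (comp_prop_rows.sum() - comp_ll.sum()
              - (t1_prop**2 - state.tau1**2) / (2.0 * tau1_var))
        if math.log(rng.random()) < lr:
            state.tau1 = t1_prop
            beta0 = beta0_prop
            comp_ll = comp_prop_rows
            ad_tau1.observe(1, 1)
        else:
            ad_tau1.observe(0, 1)

        if prior.free_tau0:
            t0_prop = state.tau0 + ad_tau0.scale * rng.standard_normal()
            beta0_prop = completion_difficulties(K, t0_prop, state.tau1)
            comp_prop_rows = bundle.completion_ll_rows(state.theta[:, 0], beta0_prop)
            lr = (comp_prop_rows.sum() - comp_ll.sum()
                  - (t0_prop**2 - state.tau0**2) / (2.0 * tau1_var))
            if math.log(rng.random()) < lr:
                state.tau0 = t0_prop
                beta0 = beta0_prop
                comp_ll = comp_prop_rows
                ad_tau0.observe(1, 1)
            else:
                ad_tau0.observe(0, 1)

        # --- difficulty-scale hyperparameter, log-scale random walk
        eta = math.log(state.sigma_b)
        eta_prop = eta + ad_sb.scale * rng.standard_normal()
        sb_prop = math.exp(eta_prop)
        ssq = float((state.b**2).sum())
        cur = _log_sigma_b_prior(state.sigma_b, prior) - K * math.log(state.sigma_b) - ssq / (2 * state.sigma_b**2)
        new = _log_sigma_b_prior(sb_prop, prior) - K * math.log(sb_prop) - ssq / (2 * sb_prop**2)
        if math.log(rng.random()) < (new - cur + eta_prop - eta):
            state.sigma_b = sb_prop
            ad_sb.observe(1, 1)
        else:
            ad_sb.observe(0, 1)

        # --- regression coefficients: exact multivariate-normal Gibbs draw
        if p:
            X = bundle.design
            T = prec
            XtX = X.T @ X
            P = np.kron(T, XtX) + coef_prec0 * np.eye(2 * p)
            rhs = (X.T @ state.theta @ T).reshape(2 * p, order="F")
            Pc = np.linalg.cholesky(P)
            mean = np.linalg.solve(P, rhs)
            draw = mean + np.linalg.solve(Pc.T, rng.standard_normal(2 * p))
            state.C = draw.reshape(p, 2, order="F")
            mu = X @ state.C

        # --- latent covariance: conjugate Wishart draw on the precision
        resid = state.theta - mu
        state.Sigma, prec = sample_latent_covariance(resid, prior, rng)
        chol = np.linalg.cholesky(state.Sigma)

        if adapting and (it + 1) % cfg.adapt_window == 0:
            for ad in (ad_theta, ad_b, ad_tau1, ad_tau0, ad_sb):
                ad.maybe_adapt()

        if not adapting:
            if accept.sum() == 0 and not acc_b.any():
                stall_window += 1
                if stall_window >= 200:
                    logger.warning(
                        "chain %d: all proposals rejected over a 200-iteration window", chain_id)
                    stall_window = 0
            else:
                stall_window = 0

        keep_from = cfg.n_adapt + cfg.n_burnin
        if it >= keep_from:
            j = it - keep_from
            for i in range(K):
                store[f"b[{i + 1}]"][chain_id - 1, j] = state.b[i]
            store["tau1"][chain_id - 1, j] = state.tau1
            if prior.free_tau0:
                store["tau0"][chain_id - 1, j] = state.tau0
            store["sigma_b"][chain_id - 1, j] = state.sigma_b
            store["var_completion"][chain_id - 1, j] = state.Sigma[0, 0]
            store["var_ability"][chain_id - 1, j] = state.Sigma[1, 1]
            store["cov_completion_ability"][chain_id - 1, j] = state.Sigma[0, 1]
            for ci, col in enumerate(spec.design_column_names()):
                fam = _COEF_FAMILY[col]
                store[f"{fam}_ability"][chain_id - 1, j] = state.C[ci, 1]
                store[f"{fam}_completion"][chain_id - 1, j] = state.C[ci, 0]
            if theta_store is not None and thin and (j % thin == 0):
                theta_store[chain_id - 1, j // thin] = state.theta
            kept += 1


def run_mcmc(
    resp: ResponseMatrix,
    ind: IndicatorMatrix,
    design,
    spec: ModelSpec,
    cfg: MCMCConfig,
) -> PosteriorDraws:
    """Sample the joint posterior; fully reproducible from ``cfg.seed``.

    ``design`` is the (N, p) latent-regression design (p = 0 for Model 1);
    a pandas DataFrame from :func:`speedirt.data_io.design_matrix` or a bare
    array are both accepted.
    """
    design_arr = np.zeros((resp.n_persons, 0)) if design is None else np.asarray(design, dtype=float)
    if design_arr.ndim == 1:
        design_arr = design_arr[:, None]
    if design_arr.shape[0] != resp.n_persons:
        raise ValueError("design matrix is not aligned with responses")
    if design_arr.shape[1] != spec.n_design_columns:
        raise ValueError(
            f"model {spec.model_id} expects {spec.n_design_columns} design columns, "
            f"got {design_arr.shape[1]}")
    bundle = _DataBundle(resp, ind, design_arr)

    n_keep = cfg.n_keep_per_chain
    names = [f"b[{i + 1}]" for i in range(spec.K)] + ["tau1"]
    if spec.prior.free_tau0:
        names.append("tau0")
    names += ["sigma_b", "var_completion", "var_ability", "cov_completion_ability"]
    names += _coef_names(spec)
    store = {name: np.empty((cfg.n_chains, n_keep)) for name in names}
    theta_store = None
    if cfg.thin_theta:
        n_thin = (n_keep + cfg.thin_theta - 1) // cfg.thin_theta
        theta_store = np.empty((cfg.n_chains, n_thin, resp.n_persons, 2))

    for chain_id in range(1, cfg.n_chains + 1):
        _run_single_chain(bundle, spec, cfg, chain_id, store, theta_store)

    return PosteriorDraws(
        params=store,
        theta=theta_store,
        seed=cfg.seed,
        config=cfg.to_dict(),
        spec=spec.to_dict(),
    )


def fit_model(
    resp: ResponseMatrix,
    ind: IndicatorMatrix,
    cov: CovariateTable | None,
    model_id: int,
    cfg: MCMCConfig,
    prior: PriorConfig | None = None,
    rules=None,
    escalate: bool = True,
):
    """Fit one covariate model end to end and return a diagnosed report.

    If the convergence battery fails, the fit is re-run once with the
    escalated burn-in before the report is (still honestly) flagged
    ``NOT_CONVERGED``.
    """
    from .diagnostics import summarize_draws  # deferred to avoid cycle

    if model_id != 1 and cov is None:
        raise ValueError(f"model {model_id} requires a covariate table")
    spec = ModelSpec(model_id=model_id, K=resp.n_items,
                     prior=prior if prior is not None else PriorConfig())
    design = design_matrix(cov, model_id).to_numpy() if cov is not None else None
    if model_id == 1:
        design = None
    draws = run_mcmc(resp, ind, design, spec, cfg)
    report = summarize_draws(draws, rules=rules)
    if report.verdict == "NOT_CONVERGED" and escalate and cfg.n_burnin < cfg.escalated_burnin:
        logger.info("model %d failed convergence battery; escalating burn-in to %d",
                    model_id, cfg.escalated_burnin)
        draws = run_mcmc(resp, ind, design, spec, cfg.escalated())
        report = summarize_draws(draws, rules=rules)
        report.metadata["escalated_burnin"] = True
    return report
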
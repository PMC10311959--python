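"""Convergence battery and posterior summaries.

Implements the classic multi-chain potential scale reduction factor (no
split, no rank-normalisation), an initial-positive-sequence effective sample
size pooled across chains, the Monte Carlo standard error ``SD / sqrt(ESS)``,
the shortest-interval HPDI, and the three-rule convergence verdict
(R-hat > 1.05, MCSE > 0.05, ESS < 400).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConvergenceRules",
    "FitReport",
    "gelman_rubin",
    "split_gelman_rubin",
    "effective_sample_size",
    "mc_standard_error",
    "hpdi",
    "latent_correlation",
    "convergence_verdict",
    "summarize_draws",
    "plot_trace",
    "plot_density",
]


@dataclass(frozen=True)
class ConvergenceRules:
    """Thresholds of the non-convergence battery; all three must hold."""

    rhat_max: float = 1.05
    mcse_max: float = 0.05
    ess_min: float = 400.0


def _chains_2d(chains) -> np.ndarray:
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2:
        raise ValueError("chains must be a 2-D array (n_chains, n_draws)")
    return arr


def gelman_rubin(chains) -> float:
    """Classic potential scale reduction factor across chains.

    ``R-hat = sqrt(((n-1)/n * W + B/n) / W)`` with W the mean within-chain
    variance and B the between-chain variance of the chain means (times n).
    """
    arr = _chains_2d(chains)
    m, n = arr.shape
    if m < 2 or n < 2:
        raise ValueError("need at least 2 chains with at least 2 draws each")
    w = arr.var(axis=1, ddof=1).mean()
    if w == 0:
        raise ValueError("zero within-chain variance; R-hat undefined")
    b = n * arr.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * w + b / n
    return float(math.sqrt(var_plus / w))


def split_gelman_rubin(chains) -> float:
    """Split-chain variant: each chain is halved before the classic formula."""
    arr = _chains_2d(chains)
    n = arr.shape[1]
    half = n // 2
    if half < 2:
        raise ValueError("need at least 4 draws per chain for split R-hat")
    split = np.concatenate([arr[:, :half], arr[:, n - half:]], axis=0)
    return gelman_rubin(split)


def _autocorrelation(x: np.ndarray) -> np.ndarray:
    n = x.size
    x = x - x.mean()
    size = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, size)
    acov = np.fft.irfft(f * np.conj(f), size)[:n].real / n
    if acov[0] <= 0:
        return np.zeros(n)
    return acov / acov[0]


def effective_sample_size(chains) -> float:
    """Autocorrelation-based ESS with Geyer initial-positive-sequence truncation,
    pooled across chains; capped at the total draw count."""
    arr = _chains_2d(chains)
    m, n = arr.shape
    total = m * n
    if n < 4:
        return float(total)
    rho = np.mean([_autocorrelation(c) for c in arr], axis=0)
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
        t += 2
    ess = total / tau
    return float(min(ess, total))


def mc_standard_error(chains) -> float:
    """Monte Carlo standard error of the posterior mean: SD / sqrt(ESS)."""
    arr = _chains_2d(chains)
    sd = arr.ravel().std(ddof=1)
    if sd == 0:
        return 0.0
    return float(sd / math.sqrt(effective_sample_size(arr)))


def hpdi(draws, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval of sorted draws containing ``ceil(mass*n)``.

    The highest-posterior-density interval need not contain the mean for
    skewed posteriors; the only guarantees are low < high (up to ties) and
    the requested coverage of the draws.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 20:
        raise ValueError("need at least 20 draws for an HPDI")
    m = int(math.ceil(mass * n))
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def excludes_zero(interval: tuple[float, float]) -> bool:
    """Significance flag: the credible interval does not contain zero."""
    low, high = interval
    return low > 0.0 or high < 0.0


def latent_correlation(sigma_draws, mass: float = 0.95) -> dict:
    """Per-draw correlation from covariance-matrix draws, with summary.

    Accepts an array of shape (n, 2, 2) or a single 2x2 matrix; returns the
    posterior mean, SD and HPDI of ``cov / sqrt(var0 * var1)``.
    """
    arr = np.asarray(sigma_draws, dtype=float)
    if arr.shape == (2, 2):
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[1:] != (2, 2):
        raise ValueError("sigma_draws must be (n, 2, 2) or a single 2x2 matrix")
    v0 = arr[:, 0, 0]
    v1 = arr[:, 1, 1]
    cv = arr[:, 0, 1]
    if np.any(v0 <= 0) or np.any(v1 <= 0):
        raise ValueError("non-positive variance draw")
    r = cv / np.sqrt(v0 * v1)
    out = {"draws": r, "mean": float(r.mean())}
    out["sd"] = float(r.std(ddof=1)) if r.size > 1 else 0.0
    if r.size >= 20:
        out["hpdi"] = hpdi(r, mass)
    return out


def convergence_verdict(table: pd.DataFrame, rules: ConvergenceRules | None = None) -> tuple[str, list[dict]]:
    """Apply the three-rule battery to a per-parameter diagnostic table.

    Returns the verdict and the list of failing parameters with the rules
    they broke; a fit is NOT_CONVERGED iff any parameter fails any rule.
    """
    rules = rules or ConvergenceRules()
    failures = []
    for name, row in table.iterrows():
        broken = []
        if row["rhat"] > rules.rhat_max:
            broken.append(f"rhat>{rules.rhat_max}")
        if row["mcse"] > rules.mcse_max:
            broken.append(f"mcse>{rules.mcse_max}")
        if row["ess"] < rules.ess_min:
            broken.append(f"ess<{rules.ess_min:g}")
        if broken:
            failures.append({"parameter": str(name), "rules": broken})
    verdict = "NOT_CONVERGED" if failures else "CONVERGED"
    return verdict, failures


@dataclass
class FitReport:
    """Posterior summaries plus diagnostics and the convergence verdict."""

    table: pd.DataFrame
    latent_corr: dict
    verdict: str
    failures: list
    seed: int
    config: dict
    spec: dict
    metadata: dict = field(default_factory=dict)
    draws: object | None = None  # PosteriorDraws, not serialized

    def to_dict(self) -> dict:
        corr = {k: v for k, v in self.latent_corr.items() if k != "draws"}
        return {
            "verdict": self.verdict,
            "failures": self.failures,
            "latent_correlation": corr,
            "parameters": self.table.reset_index().rename(
                columns={"index": "parameter"}).to_dict(orient="records"),
            "seed": self.seed,
            "config": self.config,
            "spec": self.spec,
            "metadata": self.metadata,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, default=float)

    def to_text(self) -> str:
        lines = [f"verdict: {self.verdict}"]
        if self.failures:
            lines.append("failing parameters:")
            for f in self.failures:
                lines.append(f"  {f['parameter']}: {', '.join(f['rules'])}")
        corr = self.latent_corr
        if "hpdi" in corr:
            lines.append(
                f"latent correlation: {corr['mean']:.3f} "
                f"(95% HPDI [{corr['hpdi'][0]:.3f}, {corr['hpdi'][1]:.3f}])")
        else:
            lines.append(f"latent correlation: {corr['mean']:.3f}")
        lines.append(self.table.to_string(float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)

    def write(self, outdir: str | Path, stem: str = "fit_report") -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        jp = outdir / f"{stem}.json"
        jp.write_text(self.to_json())
        tp = outdir / f"{stem}.txt"
        tp.write_text(self.to_text())
        return [jp, tp]


def summarize_draws(draws, rules: ConvergenceRules | None = None,
                    mass: float = 0.95) -> FitReport:
    """Full per-parameter summary table and verdict for a set of draws.

    ESS and MCSE are pooled across chains (flagged in metadata, since a
    per-chain convention is also defensible).
    """
    rules = rules or ConvergenceRules()
    rows = {}
    multi = draws.n_chains >= 2 and draws.n_kept_per_chain >= 2
    for name in draws.parameter_names():
        arr = draws.get(name)
        flat = arr.ravel()
        ess = effective_sample_size(arr)
        row = {
            "mean": float(flat.mean()),
            "sd": float(flat.std(ddof=1)) if flat.size > 1 else 0.0,
            "ess": ess,
            "mcse": mc_standard_error(arr),
        }
        try:
            row["rhat"] = gelman_rubin(arr) if multi else np.nan
        except ValueError:
            row["rhat"] = np.nan
        if flat.size >= 20:
            lo, hi = hpdi(flat, mass)
            row["hpdi_low"], row["hpdi_high"] = lo, hi
        else:
            row["hpdi_low"] = row["hpdi_high"] = np.nan
        rows[name] = row
    table = pd.DataFrame(rows).T[
        ["mean", "sd", "hpdi_low", "hpdi_high", "rhat", "ess", "mcse"]]
    verdict, failures = convergence_verdict(table.fillna({"rhat": 1.0}), rules)
    corr = latent_correlation(draws.sigma_draws(), mass) if "var_completion" in draws.params else {"mean": np.nan}
    return FitReport(
        table=table,
        latent_corr=corr,
        verdict=verdict,
        failures=failures,
        seed=draws.seed,
        config=draws.config,
        spec=draws.spec,
        metadata={
            "ess_estimator": "initial positive sequence, pooled across chains",
            "rhat_variant": "classic multi-chain PSRF",
            "mcse_definition": "posterior SD / sqrt(ESS)",
            "rules": {"rhat_max": rules.rhat_max, "mcse_max": rules.mcse_max,
                      "ess_min": rules.ess_min},
        },
        draws=draws,
    )


def plot_trace(draws, names=None, outdir: str | Path = ".", prefix: str = "trace"):
    """Per-parameter trace plots (reporting only, never load-bearing)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in names or draws.parameter_names():
        arr = draws.get(name)
        fig, ax = plt.subplots(figsize=(7, 2.5))
        for c in range(arr.shape[0]):
            ax.plot(arr[c], lw=0.5, label=f"chain {c + 1}")
        ax.set_title(name)
        ax.set_xlabel("iteration")
        fig.tight_layout()
        p = outdir / f"{prefix}_{name.replace('[', '_').replace(']', '')}.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        paths.append(p)
    return paths


def plot_density(draws, names=None, outdir: str | Path = ".", prefix: str = "density"):
    """Posterior density plots per parameter (reporting only)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in names or draws.parameter_names():
        flat = draws.get(name).ravel()
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.hist(flat, bins=60, density=True, alpha=0.7)
        ax.axvline(0.0, color="k", lw=0.8, ls="--")
        ax.set_title(name)
        fig.tight_layout()
        p = outdir / f"{prefix}_{name.replace('[', '_').replace(']', '')}.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        paths.append(p)
    return paths
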
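"""Generic MCMC sampling, convergence diagnostics, posterior summaries.

The sampler is an affine-invariant ensemble sampler (Goodman & Weare stretch
move): gradient-free, tuning-free apart from the stretch scale, and invariant
to linear reparameterisation — well suited to the small hierarchical models
fitted here, whose posteriors mix very different scales (latent proportions
pinned by deep counts next to weakly identified hierarchical scales).  The
prescribed chain plan (3 chains, 10,000 iterations, thinning 10) is honoured
by running ``n_chains`` independent ensembles simultaneously in one vectorised
log-density call; each stored chain pools its ensemble's walkers after warm-up
(first half of iterations) and thinning.

Convergence is gated by the potential scale reduction factor (Gelman-Rubin
R-hat), computed from between- and within-chain variances only, so pooled
walkers are a valid "chain" for the diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .config import MCMCSettings
from .exceptions import ValidationError


@dataclass
class ModelSpec:
    """A target distribution the sampler can draw from.

    ``log_density`` must accept an ``(N, ndim)`` array and return length-N log
    densities (``-inf`` outside the support).
    """

    name: str
    param_names: Sequence[str]
    log_density: Callable[[np.ndarray], np.ndarray]
    init: np.ndarray
    init_scale: np.ndarray | None = None

    @property
    def ndim(self) -> int:
        return len(self.param_names)

    def __post_init__(self) -> None:
        self.init = np.asarray(self.init, dtype=float)
        if self.init.shape != (self.ndim,):
            raise ValidationError(
                f"{self.name}: init has shape {self.init.shape}, "
                f"expected ({self.ndim},)")
        if self.init_scale is None:
            self.init_scale = np.full(self.ndim, 0.1)
        self.init_scale = np.asarray(self.init_scale, dtype=float)
        bad = [p for p, v in zip(self.param_names, self.init)
               if not np.isfinite(v)]
        if bad:
            raise ValidationError(
                f"{self.name}: non-finite initial value for parameter(s) "
                + ", ".join(bad))


@dataclass
class ChainSet:
    """Thinned post-warm-up posterior draws, indexed (chain, draw, parameter)."""

    draws: np.ndarray
    param_names: Sequence[str]
    name: str = ""

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 3:
            raise ValidationError("draws must be (n_chains, n_draws, ndim)")
        if self.draws.shape[2] != len(self.param_names):
            raise ValidationError("parameter-name count mismatch")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_iter_post_thin(self) -> int:
        return self.draws.shape[1]

    def get(self, param: str) -> np.ndarray:
        """Draws for one parameter, shape (n_chains, n_draws)."""
        try:
            j = list(self.param_names).index(param)
        except ValueError:
            raise KeyError(f"unknown parameter {param!r}") from None
        return self.draws[:, :, j]

    def flat(self, param: str) -> np.ndarray:
        return self.get(param).reshape(-1)

    def summarize(self, param: str) -> "PosteriorSummary":
        return summarize(self.get(param))

    def to_frame(self) -> pd.DataFrame:
        c, n, d = self.draws.shape
        df = pd.DataFrame(self.draws.reshape(c * n, d),
                          columns=list(self.param_names))
        df.insert(0, "chain", np.repeat(np.arange(c), n))
        df.insert(1, "draw", np.tile(np.arange(n), c))
        return df

    def to_tsv(self, path) -> None:
        """Export draws as TSV for audit."""
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior mean, central 95% credible interval, PSRF, crude ESS."""

    mean: float
    ci_low: float
    ci_high: float
    psrf: float
    n_eff: float

    def __post_init__(self) -> None:
        if not self.ci_low <= self.mean <= self.ci_high:
            # numerically possible only for pathological draws
            raise ValidationError("credible interval does not bracket the mean")


def psrf(chains: np.ndarray | ChainSet, param: str | None = None) -> float:
    """Gelman-Rubin potential scale reduction factor.

    ``R-hat = sqrt(((n-1)/n * W + B/n) / W)`` where ``W`` is the mean
    within-chain variance and ``B/n`` the variance of the chain means.
    Requires >= 2 chains of equal length >= 4.  Invariant under affine maps of
    the draws.
    """
    if isinstance(chains, ChainSet):
        if param is None:
            raise ValidationError("a parameter name is required for a ChainSet")
        x = chains.get(param)
    else:
        x = np.asarray(chains, dtype=float)
    if x.ndim != 2:
        raise ValidationError("expected draws shaped (n_chains, n_draws)")
    m, n = x.shape
    if m < 2:
        raise ValidationError("PSRF needs at least 2 chains")
    if n < 4:
        raise ValidationError("PSRF needs chains of length >= 4")
    means = x.mean(axis=1)
    w = x.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0.0:
        return 1.0 if b == 0.0 else float("inf")
    v_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(v_hat / w))


def summarize(draws: np.ndarray) -> PosteriorSummary:
    """Mean, central 95% interval, PSRF and a crude effective sample size.

    ``draws`` is (n_chains, n_draws); a 1-d array is treated as a single chain
    (PSRF then reported as NaN).
    """
    x = np.asarray(draws, dtype=float)
    if x.size == 0:
        raise ValidationError("empty draws")
    if x.ndim == 1:
        x = x[None, :]
    flat = x.reshape(-1)
    lo, hi = np.percentile(flat, [2.5, 97.5])
    if x.shape[0] >= 2 and x.shape[1] >= 4:
        r = psrf(x)
        m, n = x.shape
        means = x.mean(axis=1)
        b = n * means.var(ddof=1)
        w = x.var(axis=1, ddof=1).mean()
        if b > 0:
            v_hat = (n - 1) / n * w + b / n
            n_eff = min(m * n, m * n * v_hat / b)
        else:
            n_eff = m * n
    else:
        r = float("nan")
        n_eff = float(flat.size)
    return PosteriorSummary(mean=float(flat.mean()), ci_low=float(lo),
                            ci_high=float(hi), psrf=r, n_eff=float(n_eff))


def _init_walkers(model: ModelSpec, rng: np.random.Generator,
                  n_chains: int, n_walkers: int) -> tuple[np.ndarray, np.ndarray]:
    d = model.ndim
    lp0 = model.log_density(model.init[None, :])
    if not np.isfinite(lp0[0]):
        raise ValidationError(
            f"{model.name}: log-density non-finite at the initial point "
            f"(parameters: {', '.join(model.param_names)})")
    x = (model.init[None, None, :]
         + rng.standard_normal((n_chains, n_walkers, d))
         * 0.5 * np.asarray(model.init_scale)[None, None, :])
    lp = model.log_density(x.reshape(-1, d)).reshape(n_chains, n_walkers)
    for _ in range(100):
        bad = ~np.isfinite(lp)
        if not bad.any():
            break
        n_bad = int(bad.sum())
        x[bad] = (model.init[None, :]
                  + rng.standard_normal((n_bad, d))
                  * 0.1 * np.asarray(model.init_scale)[None, :])
        lp[bad] = model.log_density(x[bad])
    else:
        raise ValidationError(
            f"{model.name}: could not find finite starting points")
    return x, lp


def sample_posterior(model: ModelSpec,
                     settings: MCMCSettings | None = None,
                     seed: int | None = 0,
                     n_walkers: int | None = None,
                     stretch: float = 2.0) -> ChainSet:
    """Draw from ``model`` with the vectorised ensemble stretch-move sampler.

    Runs ``settings.n_chains`` independent ensembles; discards the first half
    of ``settings.n_iter`` iterations as warm-up and keeps every
    ``settings.thin``-th iteration afterwards, pooling the walkers of each
    ensemble into that chain's draws.  Deterministic for a fixed seed.
    """
    settings = settings or MCMCSettings()
    rng = np.random.default_rng(seed)
    d = model.ndim
    if n_walkers is None:
        n_walkers = max(2 * d, 16)
    n_walkers += n_walkers % 2
    if n_walkers < 4:
        n_walkers = 4
    c = settings.n_chains
    x, lp = _init_walkers(model, rng, c, n_walkers)

    half = n_walkers // 2
    warmup = settings.n_iter // 2
    kept: list[np.ndarray] = []
    a = stretch
    for it in range(settings.n_iter):
        for first in (0, 1):
            sl_move = slice(0, half) if first == 0 else slice(half, n_walkers)
            sl_other = slice(half, n_walkers) if first == 0 else slice(0, half)
            xm = x[:, sl_move]          # (c, half, d)
            xo = x[:, sl_other]
            z = ((a - 1.0) * rng.random((c, half)) + 1.0) ** 2 / a
            j = rng.integers(0, n_walkers - half, size=(c, half))
            partner = np.take_along_axis(xo, j[:, :, None], axis=1)
            prop = partner + z[:, :, None] * (xm - partner)
            lp_prop = model.log_density(prop.reshape(-1, d)).reshape(c, half)
            log_ratio = (d - 1) * np.log(z) + lp_prop - lp[:, sl_move]
            accept = np.log(rng.random((c, half))) < log_ratio
            xm[accept] = prop[accept]
            lp[:, sl_move][accept] = lp_prop[accept]
            x[:, sl_move] = xm
        if it >= warmup and (it - warmup) % settings.thin == 0:
            kept.append(x.copy())

    draws = np.stack(kept, axis=1)  # (c, n_kept, n_walkers, d)
    draws = draws.reshape(c, len(kept) * n_walkers, d)
    return ChainSet(draws=draws, param_names=list(model.param_names),
                    name=model.name)
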
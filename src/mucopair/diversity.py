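"""Shannon diversity and the Bayesian paired normal-Laplace diversity model.

Community diversity per sample is the Shannon index ``H = -sum p ln p``.  For
paired treatment/control inference H is first scaled by its maximum
``ln(n_taxa)`` (Pielou-style evenness) and logit-transformed so the modelled
values are unbounded and approximately normal.  The model for ``n`` pairs of
transformed values is

    yT_i ~ Normal(muT_i, sigmaT)       yC_i ~ Normal(muC_i, sigmaC)
    Delta.mu_i = muT_i - muC_i ~ Laplace(mu, sigma)

with the heavy-tailed Laplace pooling the per-pair mean differences; the
reported effect is the posterior of the Laplace location ``mu``.  Priors are
weakly informative: Normal(0, 5) on locations, half-Normal(0, 2.5) on scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import MCMCSettings
from .containers import PairedDesign, TaxonCountTable
from .exceptions import ConvergenceWarning, ValidationError
from .mcmc import ChainSet, ModelSpec, PosteriorSummary, sample_posterior

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)
LOGIT_EPS = 1e-6
PSRF_GATE = 1.1


def shannon(proportions: np.ndarray) -> float:
    """Shannon diversity ``H = -sum p ln p`` (natural log, 0*log(0) := 0)."""
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any():
        raise ValidationError("negative proportion in composition")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(
            f"proportions sum to {p.sum():.12f}, expected 1 within 1e-9")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def logit_scaled_shannon(h: float, n_taxa: int) -> float:
    """Map H in [0, ln(n_taxa)] to the real line via logit(H / ln(n_taxa)).

    The evenness ratio is clamped to [1e-6, 1 - 1e-6] before the logit, so the
    transform is invertible on its range.
    """
    if n_taxa < 2:
        raise ValidationError("need at least 2 taxa for the scaled logit")
    hmax = np.log(n_taxa)
    if h > hmax + 1e-9 or h < -1e-9:
        raise ValidationError(
            f"Shannon value {h} outside [0, ln({n_taxa})={hmax:.6f}]")
    ratio = np.clip(h / hmax, LOGIT_EPS, 1.0 - LOGIT_EPS)
    return float(logit(ratio))


def inverse_logit_scaled_shannon(y: float, n_taxa: int) -> float:
    """Inverse of :func:`logit_scaled_shannon` on its range."""
    if n_taxa < 2:
        raise ValidationError("need at least 2 taxa")
    return float(expit(y) * np.log(n_taxa))


def sample_shannon(table: TaxonCountTable, sample_id: str) -> float:
    """Observed Shannon diversity of one sample's count column."""
    col = table.counts[sample_id].to_numpy(dtype=float)
    total = col.sum()
    if total <= 0:
        raise ValidationError(f"sample {sample_id} has zero total count")
    return shannon(col / total)


def _norm_logpdf(x, mean, sd):
    return -_HALF_LOG_2PI - np.log(sd) - 0.5 * ((x - mean) / sd) ** 2


def _halfnorm_logpdf(x, scale):
    return 0.5 * np.log(2.0 / np.pi) - np.log(scale) - 0.5 * (x / scale) ** 2


@dataclass
class DiversityResults:
    """Posterior for the paired normal-Laplace diversity model."""

    effect: PosteriorSummary
    per_pair: pd.DataFrame
    sigma_summaries: dict[str, PosteriorSummary]
    chains: ChainSet
    converged: bool
    label: str = ""

    @property
    def p_value(self) -> float:
        """Two-sided posterior tail probability that the effect is zero-signed."""
        draws = self.chains.flat("mu")
        p_pos = (draws > 0).mean()
        p = 2.0 * min(p_pos, 1.0 - p_pos)
        return float(max(p, 1.0 / draws.size))

    def summary(self) -> str:
        e = self.effect
        lines = [
            f"Paired normal-Laplace diversity model: {self.label}",
            f"  pairs: {len(self.per_pair)}",
            f"  effect (Laplace location mu): {e.mean:+.4f} "
            f"[{e.ci_low:+.4f}, {e.ci_high:+.4f}]",
            f"  posterior tail p: {self.p_value:.4g}",
            f"  PSRF(mu): {e.psrf:.3f}  converged: {self.converged}",
        ]
        return "\n".join(lines)


class DiversityModel:
    """Bayesian paired model on transformed Shannon diversities.

    Parameters
    ----------
    y_treat, y_ctrl
        Logit-scaled Shannon values of the treatment and control sample of
        each pair (same order, one entry per subject).
    """

    def __init__(self, y_treat: np.ndarray, y_ctrl: np.ndarray,
                 label: str = "") -> None:
        yt = np.asarray(y_treat, dtype=float)
        yc = np.asarray(y_ctrl, dtype=float)
        if yt.shape != yc.shape or yt.ndim != 1:
            raise ValidationError("y_treat and y_ctrl must be 1-d and aligned")
        if yt.size < 3:
            raise ValidationError("need at least 3 pairs")
        if not (np.isfinite(yt).all() and np.isfinite(yc).all()):
            raise ValidationError("non-finite transformed diversity value")
        self.y_treat = yt
        self.y_ctrl = yc
        self.label = label
        self.n_pairs = yt.size

    @classmethod
    def from_counts(cls, table: TaxonCountTable, design: PairedDesign
                    ) -> "DiversityModel":
        """Build from a count table: Shannon per sample, then the scaled logit."""
        k = len(table.taxon_ids)
        yt = [logit_scaled_shannon(sample_shannon(table, p.treatment), k)
              for p in design.pairs]
        yc = [logit_scaled_shannon(sample_shannon(table, p.control), k)
              for p in design.pairs]
        return cls(np.array(yt), np.array(yc), label=design.label)

    def _model_spec(self) -> ModelSpec:
        n = self.n_pairs
        yt, yc = self.y_treat, self.y_ctrl
        d0 = yt - yc

        def log_density(theta: np.ndarray) -> np.ndarray:
            mu = theta[:, 0]
            sig = np.exp(theta[:, 1])
            s_t = np.exp(theta[:, 2])
            s_c = np.exp(theta[:, 3])
            mu_c = theta[:, 4:4 + n]
            delta = theta[:, 4 + n:4 + 2 * n]
            ll = (_norm_logpdf(yt[None, :], mu_c + delta, s_t[:, None]).sum(axis=1)
                  + _norm_logpdf(yc[None, :], mu_c, s_c[:, None]).sum(axis=1))
            lap = (-np.log(2.0 * sig[:, None])
                   - np.abs(delta - mu[:, None]) / sig[:, None]).sum(axis=1)
            prior = (_norm_logpdf(mu, 0.0, 5.0)
                     + _norm_logpdf(mu_c, 0.0, 5.0).sum(axis=1)
                     + _halfnorm_logpdf(s_t, 2.5) + theta[:, 2]
                     + _halfnorm_logpdf(s_c, 2.5) + theta[:, 3]
                     + _halfnorm_logpdf(sig, 2.5) + theta[:, 1])
            return ll + lap + prior

        sd0 = max(float(np.std(d0, ddof=1)) if n > 1 else 0.1, 0.05)
        init = np.concatenate([
            [float(np.mean(d0)), np.log(sd0), np.log(sd0 / 2), np.log(sd0 / 2)],
            yc, d0])
        scale = np.concatenate([
            [sd0, 0.5, 0.5, 0.5], np.full(n, sd0), np.full(n, sd0)])
        names = (["mu", "log_sigma", "log_sigmaT", "log_sigmaC"]
                 + [f"muC_{i + 1}" for i in range(n)]
                 + [f"delta_{i + 1}" for i in range(n)])
        return ModelSpec(name=f"diversity[{self.label}]", param_names=names,
                         log_density=log_density, init=init, init_scale=scale)

    def fit(self, settings: MCMCSettings | None = None,
            seed: int | None = 0) -> DiversityResults:
        chains = sample_posterior(self._model_spec(), settings=settings,
                                  seed=seed)
        eff = chains.summarize("mu")
        converged = bool(eff.psrf <= PSRF_GATE)
        if not converged:
            warnings.warn(
                f"diversity model {self.label!r}: PSRF(mu) = {eff.psrf:.3f} "
                f"> {PSRF_GATE}; treat the posterior with caution",
                ConvergenceWarning, stacklevel=2)
        rows = []
        for i in range(self.n_pairs):
            s = chains.summarize(f"delta_{i + 1}")
            rows.append({"pair": i + 1, "mean": s.mean, "ci_low": s.ci_low,
                         "ci_high": s.ci_high, "psrf": s.psrf})
        sigmas = {p: chains.summarize(p)
                  for p in ("log_sigma", "log_sigmaT", "log_sigmaC")}
        return DiversityResults(effect=eff, per_pair=pd.DataFrame(rows),
                                sigma_summaries=sigmas, chains=chains,
                                converged=converged, label=self.label)


def fit_diversity_model(y_treat: np.ndarray, y_ctrl: np.ndarray,
                        settings: MCMCSettings | None = None,
                        seed: int | None = 0,
                        label: str = "") -> DiversityResults:
    """Functional wrapper around :class:`DiversityModel`."""
    return DiversityModel(y_treat, y_ctrl, label=label).fit(settings=settings,
                                                            seed=seed)
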
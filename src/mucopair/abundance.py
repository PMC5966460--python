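"""Per-taxon Bayesian paired differential-abundance model with measurement error.

For one taxon and ``n`` subject pairs the model is

    yT_i ~ Binomial(nReadsT_i, pT_i)      yC_i ~ Binomial(nReadsC_i, pC_i)
    log10(pT_i) ~ Normal(log10(tpT_i), sigmaT_i)
    log10(pC_i) ~ Normal(log10(tpC_i), sigmaC_i)
    Delta_i = log10(tpT_i / tpC_i) ~ Normal(mu, tau)

where ``pT/pC`` are the observed relative abundances, ``tpT/tpC`` the latent
true ones, and the per-observation measurement sds ``sigmaT_i``/``sigmaC_i``
come from a :class:`MeasurementErrorModel` calibrated on replicate positive
controls (variance of log10 relative abundance grows as abundance falls).
The reported effect size is the posterior mean of ``mu``, the population mean
of the per-pair log10 ratios; its two-sided posterior tail probability serves
as the p-value, BH-adjusted across taxa by the caller.

Priors: Normal(0, 1) on ``mu``, half-Normal(0, 1) on ``tau``, and a
logit-scale Normal(logit(pooled observed proportion), 2) on each ``tpC_i``;
latent proportions are constrained below 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logit

from .config import MCMCSettings
from .containers import PairedDesign, TaxonCountTable
from .exceptions import (ConvergenceWarning, DegenerateDataError,
                         ValidationError)
from .mcmc import ChainSet, ModelSpec, PosteriorSummary, sample_posterior

_LN10 = np.log(10.0)
_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)
SIGMA_FLOOR = 1e-3
PSRF_GATE = 1.1


@dataclass
class MeasurementErrorModel:
    """Mapping from median log10 relative abundance m to sd sigma(m).

    Fitted as ``log10(variance) = a + b * m`` on replicate positive controls,
    with the slope clipped to ``b <= 0`` (sigma monotone non-increasing in
    abundance) and the predicted sd floored at ``SIGMA_FLOOR``.
    """

    intercept: float
    slope: float
    n_taxa_fit: int
    floor: float = SIGMA_FLOOR
    fit_table: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.slope > 0:
            raise ValidationError("slope must be <= 0 after monotonisation")

    def sigma(self, m: np.ndarray | float) -> np.ndarray | float:
        """Predicted sd of log10 relative abundance at median abundance m."""
        m_arr = np.asarray(m, dtype=float)
        sd = np.sqrt(10.0 ** (self.intercept + self.slope * m_arr))
        out = np.maximum(sd, self.floor)
        return float(out) if np.isscalar(m) or m_arr.ndim == 0 else out

    @classmethod
    def fit(cls, positive_controls: TaxonCountTable,
            floor: float = SIGMA_FLOOR) -> "MeasurementErrorModel":
        """Calibrate the law on replicate samples of one mixed specimen.

        Uses taxa detected in every replicate; per taxon the median and
        variance of log10 relative abundance across replicates are computed
        and ``log10(var)`` regressed on the median.
        """
        counts = positive_controls.counts.to_numpy(dtype=float)
        n_reps = counts.shape[1]
        if n_reps < 3:
            raise ValidationError(
                f"need >= 3 positive-control replicates, got {n_reps}")
        totals = counts.sum(axis=0)
        if (totals <= 0).any():
            raise ValidationError("positive-control replicate with zero reads")
        rel = counts / totals
        detected = (counts > 0).all(axis=1)
        if detected.sum() < 5:
            raise ValidationError(
                "need >= 5 taxa detected in all positive-control replicates")
        lg = np.log10(rel[detected])
        med = np.median(lg, axis=1)
        var = lg.var(axis=1, ddof=1)
        tab = pd.DataFrame(
            {"median_log10": med, "var_log10": var},
            index=positive_controls.taxon_ids[detected])
        pos = var > 0
        if pos.sum() < 2:
            # degenerate: replicates (near-)identical -> floor everywhere
            return cls(intercept=2.0 * np.log10(floor), slope=0.0,
                       n_taxa_fit=int(detected.sum()), floor=floor,
                       fit_table=tab)
        x, y = med[pos], np.log10(var[pos])
        slope, intercept = np.polyfit(x, y, 1)
        if slope > 0:
            slope, intercept = 0.0, float(np.mean(y))
        return cls(intercept=float(intercept), slope=float(slope),
                   n_taxa_fit=int(pos.sum()), floor=floor, fit_table=tab)


def _norm_logpdf(x, mean, sd):
    return -_HALF_LOG_2PI - np.log(sd) - 0.5 * ((x - mean) / sd) ** 2


def _halfnorm_logpdf(x, scale):
    return 0.5 * np.log(2.0 / np.pi) - np.log(scale) - 0.5 * (x / scale) ** 2


@dataclass
class AbundanceResults:
    """Posterior for one taxon's paired differential-abundance model."""

    taxon: str
    effect: PosteriorSummary
    p_value: float
    per_pair: pd.DataFrame
    chains: ChainSet
    converged: bool
    label: str = ""
    q_value: float = float("nan")

    @property
    def fold_change(self) -> float:
        """Posterior-mean ratio of true relative abundances, 10**effect."""
        return float(10.0 ** self.effect.mean)

    def summary(self) -> str:
        e = self.effect
        return "\n".join([
            f"Binomial logistic-normal paired model: {self.taxon} ({self.label})",
            f"  pairs: {len(self.per_pair)}",
            f"  effect size (mean of log10 ratios): {e.mean:+.4f} "
            f"[{e.ci_low:+.4f}, {e.ci_high:+.4f}]  (x{self.fold_change:.2f})",
            f"  posterior tail p: {self.p_value:.3g}   q: {self.q_value:.3g}",
            f"  PSRF(mu): {e.psrf:.3f}  converged: {self.converged}",
        ])


class TaxonAbundanceModel:
    """Paired binomial logistic-normal model for one taxon.

    Parameters are per-pair arrays: treatment/control counts for the taxon,
    the samples' total read counts, and the per-observation measurement sds
    on the log10 scale.
    """

    def __init__(self, y_treat, n_treat, y_ctrl, n_ctrl,
                 sigma_treat, sigma_ctrl,
                 taxon: str = "", label: str = "") -> None:
        self.y_treat = np.asarray(y_treat, dtype=float)
        self.n_treat = np.asarray(n_treat, dtype=float)
        self.y_ctrl = np.asarray(y_ctrl, dtype=float)
        self.n_ctrl = np.asarray(n_ctrl, dtype=float)
        n = self.y_treat.size
        if not (self.n_treat.size == self.y_ctrl.size == self.n_ctrl.size == n):
            raise ValidationError("count arrays must be aligned")
        if n < 3:
            raise ValidationError("need at least 3 pairs")
        if (self.y_treat > self.n_treat).any() or (self.y_ctrl > self.n_ctrl).any():
            raise ValidationError("taxon count exceeds sample total")
        if self.y_treat.sum() == 0:
            raise DegenerateDataError(
                f"taxon {taxon!r}: zero count in every treatment sample")
        if self.y_ctrl.sum() == 0:
            raise DegenerateDataError(
                f"taxon {taxon!r}: zero count in every control sample")
        self.sigma_treat = np.broadcast_to(
            np.asarray(sigma_treat, dtype=float), (n,)).copy()
        self.sigma_ctrl = np.broadcast_to(
            np.asarray(sigma_ctrl, dtype=float), (n,)).copy()
        if (self.sigma_treat <= 0).any() or (self.sigma_ctrl <= 0).any():
            raise ValidationError("measurement sds must be > 0")
        self.taxon = taxon
        self.label = label
        self.n_pairs = n

    @classmethod
    def from_counts(cls, table: TaxonCountTable, design: PairedDesign,
                    taxon: str, error_model: MeasurementErrorModel,
                    per_observation: bool = False) -> "TaxonAbundanceModel":
        """Extract one taxon's paired counts and assign measurement sds.

        By default the sd is evaluated once per arm, at the taxon's median
        log10 relative abundance across that arm's samples in the comparison;
        ``per_observation=True`` evaluates the law per sample instead.
        """
        depths = table.depths
        yt = table.counts.loc[taxon, design.treatment_ids].to_numpy(dtype=float)
        nt = depths[design.treatment_ids].to_numpy(dtype=float)
        yc = table.counts.loc[taxon, design.control_ids].to_numpy(dtype=float)
        nc = depths[design.control_ids].to_numpy(dtype=float)
        lt = np.log10((yt + 0.5) / (nt + 1.0))
        lc = np.log10((yc + 0.5) / (nc + 1.0))
        if per_observation:
            st, sc = error_model.sigma(lt), error_model.sigma(lc)
        else:
            st = error_model.sigma(float(np.median(lt)))
            sc = error_model.sigma(float(np.median(lc)))
        return cls(yt, nt, yc, nc, st, sc, taxon=taxon, label=design.label)

    def _model_spec(self) -> ModelSpec:
        n = self.n_pairs
        yt, nt = self.y_treat, self.n_treat
        yc, nc = self.y_ctrl, self.n_ctrl
        st, sc = self.sigma_treat, self.sigma_ctrl
        pooled = (yt.sum() + yc.sum()) / (nt.sum() + nc.sum())
        eta0_center = float(logit(pooled))

        def log_density(theta: np.ndarray) -> np.ndarray:
            mu = theta[:, 0]
            tau = np.exp(theta[:, 1])
            eta = theta[:, 2:2 + n]
            delta = theta[:, 2 + n:2 + 2 * n]
            lp_t = theta[:, 2 + 2 * n:2 + 3 * n]   # log10 observed pT
            lp_c = theta[:, 2 + 3 * n:2 + 4 * n]   # log10 observed pC
            # latent true proportions: tpC = expit(eta), on log10 scale
            l_tpc = -np.logaddexp(0.0, -eta) / _LN10
            l_tpt = l_tpc + delta
            ok = ((lp_t < 0).all(axis=1) & (lp_c < 0).all(axis=1)
                  & (l_tpt < 0).all(axis=1))
            lp_t_s = np.where(ok[:, None], lp_t, -1.0)
            lp_c_s = np.where(ok[:, None], lp_c, -1.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                log_pt = lp_t_s * _LN10
                log_pc = lp_c_s * _LN10
                ll = ((yt * log_pt + (nt - yt) * np.log1p(-np.exp(log_pt))).sum(axis=1)
                      + (yc * log_pc + (nc - yc) * np.log1p(-np.exp(log_pc))).sum(axis=1))
            meas = (_norm_logpdf(lp_t_s, l_tpt, st).sum(axis=1)
                    + _norm_logpdf(lp_c_s, l_tpc, sc).sum(axis=1))
            hier = _norm_logpdf(delta, mu[:, None], tau[:, None]).sum(axis=1)
            prior = (_norm_logpdf(mu, 0.0, 1.0)
                     + _halfnorm_logpdf(tau, 1.0) + theta[:, 1]
                     + _norm_logpdf(eta, eta0_center, 2.0).sum(axis=1))
            total = ll + meas + hier + prior
            return np.where(ok, total, -np.inf)

        pt0 = (yt + 0.5) / (nt + 1.0)
        pc0 = (yc + 0.5) / (nc + 1.0)
        lpt0 = np.log10(pt0)
        lpc0 = np.log10(pc0)
        delta0 = lpt0 - lpc0
        tau0 = max(float(np.std(delta0, ddof=1)), 0.05)
        init = np.concatenate([[float(np.mean(delta0)), np.log(tau0)],
                               logit(pc0), delta0, lpt0, lpc0])
        # walker spread ~ posterior scale: binomial sd on log10 p plus sigma
        bin_t = np.sqrt(1.0 / (yt + 0.5)) / _LN10
        bin_c = np.sqrt(1.0 / (yc + 0.5)) / _LN10
        sc_t = np.sqrt(bin_t ** 2 + st ** 2)
        sc_c = np.sqrt(bin_c ** 2 + sc ** 2)
        scale = np.concatenate([[0.2, 0.5], np.full(n, 0.5),
                                np.full(n, 0.2),
                                np.minimum(sc_t, 0.5),
                                np.minimum(sc_c, 0.5)])
        names = (["mu", "log_tau"]
                 + [f"eta_{i + 1}" for i in range(n)]
                 + [f"delta_{i + 1}" for i in range(n)]
                 + [f"lpT_{i + 1}" for i in range(n)]
                 + [f"lpC_{i + 1}" for i in range(n)])
        return ModelSpec(name=f"abundance[{self.taxon}|{self.label}]",
                         param_names=names, log_density=log_density,
                         init=init, init_scale=scale)

    def fit(self, settings: MCMCSettings | None = None,
            seed: int | None = 0) -> AbundanceResults:
        chains = sample_posterior(self._model_spec(), settings=settings,
                                  seed=seed)
        eff = chains.summarize("mu")
        converged = bool(eff.psrf <= PSRF_GATE)
        if not converged:
            warnings.warn(
                f"abundance model {self.taxon!r} ({self.label}): PSRF(mu) = "
                f"{eff.psrf:.3f} > {PSRF_GATE}", ConvergenceWarning,
                stacklevel=2)
        draws = chains.flat("mu")
        p_pos = float((draws > 0).mean())
        p = max(2.0 * min(p_pos, 1.0 - p_pos), 1.0 / draws.size)
        rows = []
        for i in range(self.n_pairs):
            s = chains.summarize(f"delta_{i + 1}")
            rows.append({"pair": i + 1, "mean": s.mean, "ci_low": s.ci_low,
                         "ci_high": s.ci_high, "psrf": s.psrf})
        return AbundanceResults(taxon=self.taxon, effect=eff, p_value=float(p),
                                per_pair=pd.DataFrame(rows), chains=chains,
                                converged=converged, label=self.label)


def fit_measurement_error_model(positive_controls: TaxonCountTable,
                                floor: float = SIGMA_FLOOR
                                ) -> MeasurementErrorModel:
    """Functional wrapper around :meth:`MeasurementErrorModel.fit`."""
    return MeasurementErrorModel.fit(positive_controls, floor=floor)


def fit_abundance_model(table: TaxonCountTable, design: PairedDesign,
                        taxon: str, error_model: MeasurementErrorModel,
                        settings: MCMCSettings | None = None,
                        seed: int | None = 0,
                        per_observation: bool = False) -> AbundanceResults:
    """Fit the paired model for one taxon from a count table and design."""
    model = TaxonAbundanceModel.from_counts(
        table, design, taxon, error_model, per_observation=per_observation)
    return model.fit(settings=settings, seed=seed)
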
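"""Study and run configuration objects.

``StudyConfig`` holds the dimensions and noise levels of a synthetic crossover
gel-safety study: six subjects sampled longitudinally in a two-arm (placebo vs
drug), two-formulation (HEC vs carbopol) crossover, profiled by label-free
proteomics (~382 proteins) and 16S amplicon sequencing (mean depth ~58,671
reads/sample), with replicate positive controls used to calibrate a
measurement-error model.  ``MCMCSettings`` carries the chain plan used by the
Bayesian models (3 chains x 10,000 iterations, thinning 10, by default, with a
fast profile for test runs).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

from .exceptions import ValidationError

ARMS = ("placebo", "grft")
FORMULATIONS = ("hec", "carbopol")
PROTEOME_TIMEPOINTS = ("t0", "2h", "24h")
MICROBIOME_TIMEPOINTS = ("t0", "24h", "7d")


@dataclass(frozen=True)
class MCMCSettings:
    """Chain plan for the ensemble sampler.

    ``n_iter`` counts sampler iterations per chain; the first half is discarded
    as warm-up and the remainder kept every ``thin`` iterations.
    """

    n_chains: int = 3
    n_iter: int = 10_000
    thin: int = 10

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValidationError("n_chains must be >= 1")
        if self.n_iter < 2 * self.thin:
            raise ValidationError("n_iter too small for the requested thinning")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")


#: Reduced chain plan for continuous-integration / smoke runs.
FAST_MCMC = MCMCSettings(n_chains=3, n_iter=2_000, thin=2)


@dataclass(frozen=True)
class StudyConfig:
    """Dimensions, noise levels and planted effects of a synthetic study.

    Planted effects model a formulation/application response: every sample at
    ``effect_formulations`` x ``effect_arms`` x the effect timepoint is shifted,
    so drug-vs-placebo contrasts stay null when both arms are listed (the
    default), while treatment-vs-baseline contrasts carry the effect.
    """

    n_subjects: int = 6
    n_proteins: int = 382
    n_taxa: int = 120
    mean_depth: int = 58_671
    depth_dispersion: float = 0.3
    n_baseline_timepoints: int = 4
    n_microbiome_baselines: int = 2
    effect_taxa: Sequence[tuple[int, float]] = ()
    effect_proteins: Sequence[tuple[int, float]] = ()
    within_pair_sd_log2: float = 2.3 / 1.4345
    n_positive_controls: int = 14
    n_tech_replicates: int = 9
    tech_cv: float = 0.05
    decoy_proteins: Sequence[int] = ()
    decoy_cv: float = 0.6
    effect_timepoint_proteins: str = "2h"
    effect_timepoint_taxa: str = "24h"
    effect_formulations: Sequence[str] = ("hec",)
    effect_arms: Sequence[str] = ARMS
    subject_sd_log10: float = 0.5
    sample_sd_log10: float = 0.08
    protein_subject_sd_log2: float = 0.5
    pc_sigma_intercept: float = 0.05
    pc_sigma_slope: float = 0.1
    pc_sigma_knee: float = -2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_proteins", "n_taxa", "n_baseline_timepoints",
                     "n_microbiome_baselines", "n_positive_controls",
                     "n_tech_replicates"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.mean_depth < 1:
            raise ValidationError("mean_depth must be >= 1")
        for name in ("depth_dispersion", "within_pair_sd_log2", "tech_cv",
                     "decoy_cv", "subject_sd_log10", "sample_sd_log10",
                     "protein_subject_sd_log2", "pc_sigma_intercept",
                     "pc_sigma_slope"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        self._check_effects("effect_taxa", self.effect_taxa, self.n_taxa)
        self._check_effects("effect_proteins", self.effect_proteins,
                            self.n_proteins)
        for arm in self.effect_arms:
            if arm not in ARMS:
                raise ValidationError(f"unknown arm {arm!r}")
        for form in self.effect_formulations:
            if form not in FORMULATIONS:
                raise ValidationError(f"unknown formulation {form!r}")

    @staticmethod
    def _check_effects(name: str,
                       effects: Sequence[tuple[int, float]],
                       n_features: int) -> None:
        seen: set[int] = set()
        for idx, _ in effects:
            if not 0 <= idx < n_features:
                raise ValidationError(
                    f"{name}: feature index {idx} out of range [0, {n_features})")
            if idx in seen:
                raise ValidationError(f"{name}: duplicate feature index {idx}")
            seen.add(idx)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effect_taxa"] = [list(e) for e in self.effect_taxa]
        d["effect_proteins"] = [list(e) for e in self.effect_proteins]
        return d


@dataclass(frozen=True)
class Thresholds:
    """All decision thresholds applied by the pipelines."""

    cv: float = 0.25
    outlier_k: float = 1.5
    proteome_q: float = 0.05
    taxa_q: float = 0.01
    freq: float = 1e-5
    prevalence: float = 0.25
    min_subjects: int = 4
    psrf_max: float = 1.1

    def __post_init__(self) -> None:
        for name in ("cv", "proteome_q", "taxa_q", "freq", "prevalence"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name} must lie in (0, 1], got {v}")


@dataclass(frozen=True)
class RunConfig:
    """Paths + thresholds + MCMC plan for a full CLI run."""

    intensities: str | None = None
    counts: str | None = None
    metadata: str | None = None
    positive_controls: str | None = None
    output_dir: str = "mucopair_out"
    thresholds: Thresholds = field(default_factory=Thresholds)
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    seed: int = 0
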
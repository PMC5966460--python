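"""Synthetic crossover gel-safety study generator.

Emulates the data layout of a six-subject, two-arm (placebo vs drug), two
formulation (HEC vs carbopol) crossover: longitudinal baseline sampling, then
pre-gel (T0) and post-gel samples per gel, profiled as

* a proteins x samples intensity matrix (label-free proteomics scale), with
  technical replicates of a pooled reference sample, and
* a taxa x samples integer read-count table (16S amplicon scale), plus
  replicate positive controls of a single mixed specimen used to calibrate the
  measurement-error model.

Generation starts at the count/intensity-table level; no reads or spectra are
simulated.  Proteome intensities are log-normal around subject-specific means;
microbiome compositions are additive logistic-normal with diagonal covariance
and counts are multinomial at a lognormal-dispersed sequencing depth.
Planted effects (log2 fold changes for proteins, log10 ratios for taxa) are
recorded in a :class:`SyntheticTruth` so recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (ARMS, FORMULATIONS, MICROBIOME_TIMEPOINTS,
                     PROTEOME_TIMEPOINTS, StudyConfig)
from .containers import AbundanceMatrix, TaxonCountTable
from .diversity import shannon
from .exceptions import ValidationError

_LN2 = np.log(2.0)
_LN10 = np.log(10.0)


@dataclass
class SyntheticTruth:
    """Ground truth backing a synthetic study."""

    protein_log2fc: np.ndarray | None = None
    taxa_log10_ratio: np.ndarray | None = None
    baseline_compositions: pd.DataFrame | None = None
    true_proportions: pd.DataFrame | None = None
    shannon_diff_location: float = 0.0
    shannon_diff_scale: float = 0.0
    effect_condition: dict | None = None

    def to_dict(self) -> dict:
        out: dict = {"effect_condition": self.effect_condition,
                     "shannon_diff_location": self.shannon_diff_location,
                     "shannon_diff_scale": self.shannon_diff_scale}
        if self.protein_log2fc is not None:
            out["protein_log2fc"] = list(map(float, self.protein_log2fc))
        if self.taxa_log10_ratio is not None:
            out["taxa_log10_ratio"] = list(map(float, self.taxa_log10_ratio))
        if self.baseline_compositions is not None:
            out["baseline_compositions"] = {
                c: list(map(float, self.baseline_compositions[c]))
                for c in self.baseline_compositions.columns}
        return out


def _subject_ids(config: StudyConfig) -> list[str]:
    return [f"M{i + 1}" for i in range(config.n_subjects)]


def _is_effect_sample(config: StudyConfig, arm: str, formulation: str,
                      timepoint: str, which: str) -> bool:
    tp = (config.effect_timepoint_proteins if which == "protein"
          else config.effect_timepoint_taxa)
    return (arm in config.effect_arms
            and formulation in config.effect_formulations
            and timepoint == tp)


def proteome_sample_grid(config: StudyConfig) -> pd.DataFrame:
    """Metadata frame for the proteome samples (excluding tech replicates)."""
    rows = []
    for subj in _subject_ids(config):
        for b in range(config.n_baseline_timepoints):
            rows.append((f"{subj}_baseline{b + 1}", subj, "none", "none",
                         "baseline", False))
        for form in FORMULATIONS:
            for arm in ARMS:
                for tp in PROTEOME_TIMEPOINTS:
                    rows.append((f"{subj}_{form}_{arm}_{tp}", subj, arm, form,
                                 tp, False))
    meta = pd.DataFrame(rows, columns=["sample_id", "subject_id", "arm",
                                       "formulation", "timepoint",
                                       "is_tech_replicate"])
    return meta.set_index("sample_id")


def microbiome_sample_grid(config: StudyConfig) -> pd.DataFrame:
    rows = []
    for subj in _subject_ids(config):
        for b in range(config.n_microbiome_baselines):
            rows.append((f"{subj}_mb_baseline{b + 1}", subj, "none", "none",
                         "baseline", False))
        for form in FORMULATIONS:
            for arm in ARMS:
                for tp in MICROBIOME_TIMEPOINTS:
                    rows.append((f"{subj}_mb_{form}_{arm}_{tp}", subj, arm,
                                 form, tp, False))
    meta = pd.DataFrame(rows, columns=["sample_id", "subject_id", "arm",
                                       "formulation", "timepoint",
                                       "is_tech_replicate"])
    return meta.set_index("sample_id")


def gen_proteome_study(config: StudyConfig
                       ) -> tuple[AbundanceMatrix, SyntheticTruth]:
    """Simulate the proteome intensity matrix plus pooled-reference replicates.

    Per study sample, protein ``j``'s log2 intensity is
    ``base_j + subject_offset_{s,j} + effect_j * 1[effect sample] + noise``
    with per-sample noise sd ``within_pair_sd_log2 / sqrt(2)`` so that a paired
    log2 difference between two samples has sd ``within_pair_sd_log2``.
    Technical replicates are lognormal around the pooled per-protein mean with
    coefficient of variation ``tech_cv`` (``decoy_cv`` for decoy proteins,
    which a 25% CV filter should remove).
    """
    rng = np.random.default_rng([config.seed, 1])
    meta = proteome_sample_grid(config)
    n_prot, n_samp = config.n_proteins, len(meta)
    protein_ids = [f"PROT{j + 1:04d}" for j in range(n_prot)]

    # ~4 orders of magnitude of base intensity, matching label-free coverage
    base_log2 = rng.uniform(10.0, 23.3, size=n_prot)
    subj_ids = _subject_ids(config)
    subj_offset = rng.normal(0.0, config.protein_subject_sd_log2,
                             size=(n_prot, config.n_subjects))
    subj_col = {s: i for i, s in enumerate(subj_ids)}

    noise_sd = config.within_pair_sd_log2 / np.sqrt(2.0)
    noise = rng.normal(0.0, 1.0, size=(n_prot, n_samp)) * noise_sd

    effects = np.zeros(n_prot)
    for idx, fc in config.effect_proteins:
        effects[idx] = fc

    log2_vals = np.empty((n_prot, n_samp))
    for k, (sid, row) in enumerate(meta.iterrows()):
        col = base_log2 + subj_offset[:, subj_col[row["subject_id"]]] + noise[:, k]
        if _is_effect_sample(config, row["arm"], row["formulation"],
                             row["timepoint"], "protein"):
            col = col + effects
        log2_vals[:, k] = col
    values = pd.DataFrame(2.0 ** log2_vals, index=protein_ids,
                          columns=meta.index)

    # technical replicates of the pooled reference
    ref = values.mean(axis=1).to_numpy()
    cvs = np.full(n_prot, config.tech_cv)
    for idx in config.decoy_proteins:
        if not 0 <= idx < n_prot:
            raise ValidationError(f"decoy protein index {idx} out of range")
        cvs[idx] = config.decoy_cv
    sig = np.sqrt(np.log1p(cvs ** 2))
    rep_ids = [f"REF_rep{r + 1}" for r in range(config.n_tech_replicates)]
    rep_noise = rng.normal(0.0, 1.0, size=(n_prot, len(rep_ids)))
    reps = ref[:, None] * np.exp(rep_noise * sig[:, None] - 0.5 * sig[:, None] ** 2)
    rep_values = pd.DataFrame(reps, index=protein_ids, columns=rep_ids)
    rep_meta = pd.DataFrame(
        {"subject_id": "reference", "arm": "none", "formulation": "none",
         "timepoint": "ref", "is_tech_replicate": True}, index=rep_ids)

    matrix = AbundanceMatrix(pd.concat([values, rep_values], axis=1),
                             pd.concat([meta, rep_meta]))
    truth = SyntheticTruth(
        protein_log2fc=effects,
        effect_condition={"arms": list(config.effect_arms),
                          "formulations": list(config.effect_formulations),
                          "timepoint": config.effect_timepoint_proteins})
    return matrix, truth


def _draw_depth(rng: np.random.Generator, config: StudyConfig) -> int:
    s = config.depth_dispersion
    if s == 0:
        return int(config.mean_depth)
    factor = np.exp(rng.normal(-0.5 * s * s, s))
    return max(1, int(round(config.mean_depth * factor)))


def gen_microbiome_study(config: StudyConfig
                         ) -> tuple[TaxonCountTable, SyntheticTruth]:
    """Simulate the taxon count table of the crossover study.

    Per-subject baseline compositions are logistic-normal around a shared
    rank-abundance pattern; per-sample compositions add diagonal log10-scale
    noise (sd ``sample_sd_log10``); effect samples multiply the effect taxa by
    ``10**log10_ratio`` before renormalisation; counts are multinomial at a
    lognormal-dispersed depth around ``mean_depth``.
    """
    rng = np.random.default_rng([config.seed, 2])
    meta = microbiome_sample_grid(config)
    n_taxa = config.n_taxa
    taxon_ids = [f"TAXON{k + 1:03d}" for k in range(n_taxa)]
    subj_ids = _subject_ids(config)

    g = np.sort(rng.normal(0.0, 1.2, size=n_taxa))[::-1]  # rank-abundance
    subj_dev = rng.normal(0.0, config.subject_sd_log10,
                          size=(n_taxa, config.n_subjects))
    base_log10 = g[:, None] + subj_dev
    base_comp = 10.0 ** base_log10
    base_comp /= base_comp.sum(axis=0)
    baseline = pd.DataFrame(base_comp, index=taxon_ids, columns=subj_ids)

    effects = np.zeros(n_taxa)
    for idx, ratio in config.effect_taxa:
        effects[idx] = ratio
    eff_mult = 10.0 ** effects

    # guard: perturbed effect-taxon mass must stay a valid sub-composition
    for s, subj in enumerate(subj_ids):
        mass = sum(base_comp[idx, s] * (10.0 ** r)
                   for idx, r in config.effect_taxa)
        if mass > 1.0:
            raise ValidationError(
                f"perturbed effect-taxon proportions sum to {mass:.3f} > 1 "
                f"for subject {subj}")

    subj_col = {s: i for i, s in enumerate(subj_ids)}
    counts = np.zeros((n_taxa, len(meta)), dtype=np.int64)
    true_props = np.zeros((n_taxa, len(meta)))
    for k, (sid, row) in enumerate(meta.iterrows()):
        comp = base_comp[:, subj_col[row["subject_id"]]].copy()
        noise = rng.normal(0.0, config.sample_sd_log10, size=n_taxa)
        comp = comp * 10.0 ** noise
        if _is_effect_sample(config, row["arm"], row["formulation"],
                             row["timepoint"], "taxon"):
            comp = comp * eff_mult
        comp /= comp.sum()
        true_props[:, k] = comp
        depth = _draw_depth(rng, config)
        counts[:, k] = rng.multinomial(depth, comp)

    table = TaxonCountTable(
        pd.DataFrame(counts, index=taxon_ids, columns=meta.index), meta)

    # implied Shannon-difference truth at the effect condition
    if len(config.effect_taxa) > 0:
        diffs = []
        for s in range(config.n_subjects):
            c = base_comp[:, s]
            p = c * eff_mult
            p = p / p.sum()
            diffs.append(shannon(p) - shannon(c))
        loc = float(np.mean(diffs))
        scale = float(np.std(diffs, ddof=1)) if len(diffs) > 1 else 0.0
    else:
        loc, scale = 0.0, 0.0

    truth = SyntheticTruth(
        taxa_log10_ratio=effects,
        baseline_compositions=baseline,
        true_proportions=pd.DataFrame(true_props, index=taxon_ids,
                                      columns=meta.index),
        shannon_diff_location=loc,
        shannon_diff_scale=scale,
        effect_condition={"arms": list(config.effect_arms),
                          "formulations": list(config.effect_formulations),
                          "timepoint": config.effect_timepoint_taxa})
    return table, truth


def positive_control_sigma_law(config: StudyConfig, m: np.ndarray) -> np.ndarray:
    """sd of log10 relative abundance as a function of its log10 abundance m.

    Constant above the knee, increasing linearly as abundance falls below it —
    low-abundance taxa are measured less precisely.
    """
    m = np.asarray(m, dtype=float)
    return config.pc_sigma_intercept + config.pc_sigma_slope * np.maximum(
        0.0, config.pc_sigma_knee - m)


def gen_positive_controls(config: StudyConfig) -> TaxonCountTable:
    """Replicate samples of one fixed mixed-specimen composition.

    Each replicate's log10 relative abundances are jittered around the true
    composition with sd given by :func:`positive_control_sigma_law`, then
    renormalised and counted multinomially at the sample depth — so the
    variance-vs-abundance law is recoverable by a measurement-error fit.
    """
    if config.n_positive_controls < 3:
        raise ValidationError("need at least 3 positive-control replicates")
    rng = np.random.default_rng([config.seed, 3])
    n_taxa = config.n_taxa
    taxon_ids = [f"TAXON{k + 1:03d}" for k in range(n_taxa)]

    g = np.sort(rng.normal(0.0, 1.2, size=n_taxa))[::-1]
    p0 = 10.0 ** g
    p0 /= p0.sum()
    m = np.log10(p0)
    sig = positive_control_sigma_law(config, m)

    rep_ids = [f"PC_rep{r + 1}" for r in range(config.n_positive_controls)]
    counts = np.zeros((n_taxa, len(rep_ids)), dtype=np.int64)
    for r in range(len(rep_ids)):
        comp = p0 * 10.0 ** rng.normal(0.0, sig)
        comp /= comp.sum()
        depth = _draw_depth(rng, config)
        counts[:, r] = rng.multinomial(depth, comp)

    meta = pd.DataFrame(
        {"subject_id": "control_mix", "arm": "none", "formulation": "none",
         "timepoint": "control", "is_tech_replicate": True}, index=rep_ids)
    return TaxonCountTable(pd.DataFrame(counts, index=taxon_ids,
                                        columns=rep_ids), meta)
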
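"""Comparison registry and end-to-end study workflows.

One registry encodes the crossover design — per formulation (HEC, carbopol)
and post-gel time point, placebo is compared against baseline and drug against
matched placebo — so the proteomics and microbiome stages cannot drift apart
on pairing definitions.  For baseline-referenced microbiome comparisons each
subject's baseline samples are pooled (counts and depths summed), which keeps
the binomial likelihood exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import MeasurementErrorModel, TaxonAbundanceModel, AbundanceResults
from .config import (FORMULATIONS, MCMCSettings, PROTEOME_TIMEPOINTS,
                     Thresholds)
from .containers import PairedDesign, SamplePair, TaxonCountTable
from .diversity import DiversityModel, DiversityResults
from .exceptions import DegenerateDataError, ValidationError
from .proteome import BASELINE
from .stats import bh_adjust

POOLED_TIMEPOINT = "baseline_pooled"


def proteome_comparisons(metadata: pd.DataFrame) -> list[PairedDesign]:
    """Paired designs for the proteome: each time point vs baseline average,
    and drug vs matched placebo, per formulation."""
    study = metadata[~metadata["is_tech_replicate"].astype(bool)]
    subjects = list(dict.fromkeys(study["subject_id"]))
    designs = []

    def sample_of(subj, form, arm, tp):
        hit = study.index[(study["subject_id"] == subj)
                          & (study["formulation"] == form)
                          & (study["arm"] == arm)
                          & (study["timepoint"] == tp)]
        return hit[0] if len(hit) else None

    for form in FORMULATIONS:
        for arm in ("placebo", "grft"):
            for tp in PROTEOME_TIMEPOINTS:
                pairs = []
                for subj in subjects:
                    s = sample_of(subj, form, arm, tp)
                    if s is not None:
                        pairs.append(SamplePair(subj, s, BASELINE))
                if pairs:
                    label = f"{form} {arm} {tp} vs baseline"
                    designs.append(PairedDesign(label, pairs))
        for tp in PROTEOME_TIMEPOINTS:
            pairs = []
            for subj in subjects:
                t = sample_of(subj, form, "grft", tp)
                c = sample_of(subj, form, "placebo", tp)
                if t is not None and c is not None:
                    pairs.append(SamplePair(subj, t, c))
            if pairs:
                designs.append(PairedDesign(f"{form} grft {tp} vs placebo {tp}",
                                            pairs))
    return designs


def pool_baselines(table: TaxonCountTable) -> TaxonCountTable:
    """Add one pooled-baseline sample per subject (counts and depths summed)."""
    meta = table.metadata
    out = table
    for subj in dict.fromkeys(meta["subject_id"]):
        ids = list(meta.index[(meta["subject_id"] == subj)
                              & (meta["timepoint"] == "baseline")])
        if not ids:
            continue
        out = out.pool_samples(ids, f"{subj}_baseline_pooled",
                               {"timepoint": POOLED_TIMEPOINT})
    return out


def microbiome_comparisons(table: TaxonCountTable,
                           timepoints: tuple[str, ...] = ("24h", "7d")
                           ) -> tuple[TaxonCountTable, list[PairedDesign]]:
    """Pool baselines and build the microbiome paired designs."""
    pooled = pool_baselines(table)
    meta = pooled.metadata
    subjects = list(dict.fromkeys(
        meta.loc[~meta["is_tech_replicate"].astype(bool), "subject_id"]))
    designs = []

    def sample_of(subj, form, arm, tp):
        hit = meta.index[(meta["subject_id"] == subj)
                         & (meta["formulation"] == form)
                         & (meta["arm"] == arm)
                         & (meta["timepoint"] == tp)]
        return hit[0] if len(hit) else None

    for form in FORMULATIONS:
        for tp in timepoints:
            pairs = []
            for subj in subjects:
                t = sample_of(subj, form, "placebo", tp)
                base = f"{subj}_baseline_pooled"
                if t is not None and base in meta.index:
                    pairs.append(SamplePair(subj, t, base))
            if pairs:
                designs.append(PairedDesign(
                    f"{form.upper()} placebo {tp} vs baseline", pairs))
            pairs = []
            for subj in subjects:
                t = sample_of(subj, form, "grft", tp)
                c = sample_of(subj, form, "placebo", tp)
                if t is not None and c is not None:
                    pairs.append(SamplePair(subj, t, c))
            if pairs:
                designs.append(PairedDesign(
                    f"GRFT-{form.upper()} {tp} vs placebo {tp}", pairs))
    return pooled, designs


def filter_taxa(table: TaxonCountTable, design: PairedDesign,
                freq: float = 1e-5, prevalence: float = 0.25,
                min_subjects: int = 4
                ) -> tuple[TaxonCountTable, pd.DataFrame]:
    """Apply the three retention rules for one comparison.

    A taxon is kept iff (a) its study-wide mean relative abundance exceeds
    ``freq``, (b) it is detected in at least ``prevalence`` of study samples,
    and (c) it is detected in at least ``min_subjects`` subjects of the
    comparison (either member of the pair).  Pooled-baseline columns do not
    count toward the study-wide rules.  Returns the retained subset (all
    samples kept) and a per-taxon report.  Idempotent: re-filtering the
    retained subset changes nothing.
    """
    if table.counts.empty:
        raise ValidationError("empty count table")
    meta = table.metadata
    study_cols = list(meta.index[(~meta["is_tech_replicate"].astype(bool))
                                 & (meta["timepoint"] != POOLED_TIMEPOINT)])
    counts = table.counts[study_cols]
    rel = counts / counts.sum(axis=0)
    mean_rel = rel.mean(axis=1)
    prev = (counts > 0).mean(axis=1)
    det = pd.Series(0, index=table.taxon_ids)
    for pair in design.pairs:
        present = ((table.counts[pair.treatment] > 0)
                   | (table.counts[pair.control] > 0))
        det = det + present.astype(int)
    keep = (mean_rel > freq) & (prev >= prevalence) & (det >= min_subjects)
    report = pd.DataFrame({"mean_rel_abundance": mean_rel,
                           "prevalence": prev,
                           "n_subjects_detected": det,
                           "retained": keep})
    if not keep.any():
        raise DegenerateDataError(
            f"{design.label}: all taxa removed by the filtering rules")
    return table.subset_taxa(list(table.taxon_ids[keep])), report


@dataclass
class MicrobiomeResults:
    """Per-comparison per-taxon effects plus diversity model fits."""

    taxa_table: pd.DataFrame
    diversity_table: pd.DataFrame
    abundance_fits: dict[tuple[str, str], AbundanceResults] = field(repr=False,
                                                                    default_factory=dict)
    diversity_fits: dict[str, DiversityResults] = field(repr=False,
                                                        default_factory=dict)
    skipped: list[str] = field(default_factory=list)
    q_threshold: float = 0.01

    def significant_taxa(self, comparison: str | None = None) -> pd.DataFrame:
        t = self.taxa_table
        if comparison is not None:
            t = t[t["comparison"] == comparison]
        return t[t["significant"]]

    def summary(self) -> str:
        lines = [f"Microbiome paired comparisons (q < {self.q_threshold:g}):"]
        for comp, grp in self.taxa_table.groupby("comparison", sort=False):
            sig = grp[grp["significant"]]
            lines.append(f"  {comp}: {len(sig)}/{len(grp)} taxa significant")
            for _, row in sig.iterrows():
                lines.append(
                    f"    {row['taxon']}: effect {row['effect_size']:+.3f} "
                    f"(q = {row['q']:.2e}, median T/C = "
                    f"{row['median_treatment']:.4f}/{row['median_control']:.4f})")
        lines.append("Shannon diversity (paired normal-Laplace model):")
        for _, row in self.diversity_table.iterrows():
            flag = "significant" if row["significant"] else "ns"
            lines.append(f"  {row['comparison']}: effect {row['effect']:+.3f} "
                         f"(q = {row['q']:.3g}, {flag})")
        if self.skipped:
            lines.append(f"skipped: {'; '.join(self.skipped)}")
        return "\n".join(lines)


def _median_observed(table: TaxonCountTable, taxon: str,
                     sample_ids: list[str]) -> float:
    y = table.counts.loc[taxon, sample_ids].to_numpy(dtype=float)
    n = table.depths[sample_ids].to_numpy(dtype=float)
    return float(np.median(y / n))


def _seven_day_ids(table: TaxonCountTable, design: PairedDesign) -> list[str]:
    """The treatment arm's 7-day samples for the same subjects, if present."""
    meta = table.metadata
    first = design.pairs[0].treatment
    form = meta.loc[first, "formulation"]
    arm = meta.loc[first, "arm"]
    ids = []
    for pair in design.pairs:
        hit = meta.index[(meta["subject_id"] == pair.subject_id)
                         & (meta["formulation"] == form)
                         & (meta["arm"] == arm)
                         & (meta["timepoint"] == "7d")]
        if len(hit):
            ids.append(hit[0])
    return ids


def run_all_comparisons(table: TaxonCountTable,
                        error_model: MeasurementErrorModel,
                        settings: MCMCSettings | None = None,
                        seed: int = 0,
                        thresholds: Thresholds | None = None,
                        timepoints: tuple[str, ...] = ("24h", "7d"),
                        min_pairs: int = 3) -> MicrobiomeResults:
    """Filter, fit and BH-adjust every registry comparison.

    Per comparison: apply :func:`filter_taxa`, fit the paired abundance model
    per retained taxon, BH-adjust the posterior tail p-values across taxa
    (significant at q < ``thresholds.taxa_q``), and fit the paired diversity
    model; diversity p-values are BH-adjusted across comparisons.
    """
    thresholds = thresholds or Thresholds()
    pooled, designs = microbiome_comparisons(table, timepoints=timepoints)
    rows = []
    div_rows = []
    fits: dict[tuple[str, str], AbundanceResults] = {}
    div_fits: dict[str, DiversityResults] = {}
    skipped: list[str] = []
    rng = np.random.default_rng(seed)

    for design in designs:
        if design.n_pairs < min_pairs:
            skipped.append(f"{design.label} (only {design.n_pairs} pairs)")
            warnings.warn(f"skipping {design.label}: fewer than {min_pairs} "
                          "subjects with both samples")
            continue
        try:
            retained, _ = filter_taxa(
                pooled, design, freq=thresholds.freq,
                prevalence=thresholds.prevalence,
                min_subjects=thresholds.min_subjects)
        except DegenerateDataError as exc:
            skipped.append(str(exc))
            continue
        seven_ids = _seven_day_ids(pooled, design)
        for taxon in retained.taxon_ids:
            sub_seed = int(rng.integers(0, 2 ** 31 - 1))
            try:
                res = TaxonAbundanceModel.from_counts(
                    pooled, design, taxon, error_model).fit(
                        settings=settings, seed=sub_seed)
            except DegenerateDataError as exc:
                warnings.warn(str(exc))
                continue
            fits[(design.label, taxon)] = res
            rows.append({
                "comparison": design.label,
                "taxon": taxon,
                "effect_size": res.effect.mean,
                "ci_low": res.effect.ci_low,
                "ci_high": res.effect.ci_high,
                "p": res.p_value,
                "n": design.n_pairs,
                "median_treatment": _median_observed(
                    pooled, taxon, design.treatment_ids),
                "median_control": _median_observed(
                    pooled, taxon, design.control_ids),
                "median_7d": (_median_observed(pooled, taxon, seven_ids)
                              if seven_ids else float("nan")),
                "psrf": res.effect.psrf,
                "converged": res.converged,
            })
        div_seed = int(rng.integers(0, 2 ** 31 - 1))
        dmodel = DiversityModel.from_counts(pooled, design)
        dres = dmodel.fit(settings=settings, seed=div_seed)
        div_fits[design.label] = dres
        div_rows.append({"comparison": design.label,
                         "effect": dres.effect.mean,
                         "ci_low": dres.effect.ci_low,
                         "ci_high": dres.effect.ci_high,
                         "p": dres.p_value,
                         "psrf": dres.effect.psrf,
                         "converged": dres.converged})

    taxa_table = pd.DataFrame(rows)
    if not taxa_table.empty:
        qs = []
        for comp, grp in taxa_table.groupby("comparison", sort=False):
            q = bh_adjust(grp["p"].to_numpy())
            qs.append(pd.Series(q, index=grp.index))
        taxa_table["q"] = pd.concat(qs).sort_index()
        taxa_table["significant"] = taxa_table["q"] < thresholds.taxa_q
        for (comp, taxon), res in fits.items():
            row = taxa_table[(taxa_table["comparison"] == comp)
                             & (taxa_table["taxon"] == taxon)]
            res.q_value = float(row["q"].iloc[0])
    div_table = pd.DataFrame(div_rows)
    if not div_table.empty:
        div_table["q"] = bh_adjust(div_table["p"].to_numpy())
        div_table["significant"] = div_table["q"] < thresholds.taxa_q
    return MicrobiomeResults(taxa_table=taxa_table, diversity_table=div_table,
                             abundance_fits=fits, diversity_fits=div_fits,
                             skipped=skipped, q_threshold=thresholds.taxa_q)
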
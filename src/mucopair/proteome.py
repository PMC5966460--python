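"""Label-free proteomics differential-expression pipeline.

Stages, in the fixed order applied by :class:`PairedProteomeModel`:

1. total-signal normalisation (each sample scaled to the mean total),
2. technical-replicate CV filter (keep proteins with CV < 25% across
   replicates of the pooled reference),
3. median normalisation (per-sample multiplicative correction so the
   no-intercept regression of log abundances on the across-sample median
   log profile has unit slope),
4. outlier report (samples whose total normalised abundance falls outside
   median +/- 1.5 IQR are flagged but retained),
5. per-subject baseline averaging,
6. log2 paired t-tests against the reference, BH-adjusted per comparison.

Hierarchical clustering of significant features uses 1 - Pearson correlation
with complete linkage; when baseline samples are included the clustering
operates on abundances that were not baseline-normalised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform

from .containers import AbundanceMatrix, PairedDesign
from .exceptions import DegenerateDataError, ValidationError
from .stats import bh_adjust, paired_t_test_matrix

#: token usable as a PairedDesign control id meaning "this subject's baseline average"
BASELINE = "<baseline>"


def normalize_total_signal(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Scale every sample so column totals equal the cross-sample mean total."""
    totals = matrix.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValidationError(
            f"sample(s) with zero total intensity: {list(zero.index)}")
    target = totals.mean()
    out = matrix.values * (target / totals)
    return AbundanceMatrix(out, matrix.metadata.copy())


def filter_by_replicate_cv(matrix: AbundanceMatrix, cv_threshold: float = 0.25
                           ) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Keep features whose technical-replicate CV (sd/mean) is below threshold.

    Returns the filtered matrix and a report of per-feature CVs with a
    ``dropped`` flag.
    """
    reps = matrix.tech_replicate_ids()
    if len(reps) < 2:
        raise ValidationError("need >= 2 technical-replicate samples")
    vals = matrix.values[reps]
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = (sd / mean).where(mean > 0, np.inf)
    dropped = ~(cv < cv_threshold)
    report = pd.DataFrame({"cv": cv, "dropped": dropped})
    keep = matrix.values.index[~dropped]
    if len(keep) == 0:
        raise DegenerateDataError("CV filter removed every feature")
    return matrix.subset_features(list(keep)), report


def _median_log_profile(values: pd.DataFrame) -> np.ndarray:
    with np.errstate(divide="ignore"):
        logs = np.log2(values.to_numpy(dtype=float))
    logs = np.where(np.isfinite(logs), logs, np.nan)
    return np.nanmedian(logs, axis=1)


def median_normalize(matrix: AbundanceMatrix,
                     profile: pd.Series | None = None) -> AbundanceMatrix:
    """Per-sample multiplicative correction to the median log-abundance profile.

    For each sample, the no-intercept least-squares slope ``b`` of its log
    abundances against the reference log profile ``M`` (by default the
    across-sample median of the input's log2 abundances) is computed, and the
    sample is multiplied by ``2**((1 - b) * sum(M^2) / sum(M))`` — the unique
    rescaling after which the refitted slope equals 1 exactly.

    Passing the same frozen ``profile`` across repeated applications makes the
    correction a projection: the normalisation stage of the pipeline freezes
    the reference once, so re-normalising its output changes nothing.
    """
    vals = matrix.values.to_numpy(dtype=float)
    if profile is None:
        m = _median_log_profile(matrix.values)
    else:
        m = profile.reindex(matrix.values.index).to_numpy(dtype=float)
    usable = np.isfinite(m) & (vals > 0).all(axis=1)
    if usable.sum() < 2:
        raise DegenerateDataError("too few positive features to normalize")
    m_u = m[usable]
    if np.allclose(m_u, m_u[0]):
        raise DegenerateDataError("median log profile is constant")
    ssm = float(np.dot(m_u, m_u))
    sm = float(m_u.sum())
    if sm == 0.0:
        raise DegenerateDataError("median log profile sums to zero")
    logs = np.log2(vals[usable])
    b = logs.T @ m_u / ssm            # per-sample slope
    shift = (1.0 - b) * ssm / sm      # log2 correction
    out = vals * 2.0 ** shift[None, :]
    return AbundanceMatrix(pd.DataFrame(out, index=matrix.values.index,
                                        columns=matrix.values.columns),
                           matrix.metadata.copy())


def normalize(matrix: AbundanceMatrix
              ) -> tuple[AbundanceMatrix, pd.Series]:
    """Total-signal then median normalisation with a frozen reference profile.

    Returns the normalised matrix together with the median log2 profile used
    as the reference; re-applying both steps with that profile reproduces the
    output exactly.
    """
    totaled = normalize_total_signal(matrix)
    profile = pd.Series(_median_log_profile(totaled.values),
                        index=totaled.values.index)
    return median_normalize(totaled, profile=profile), profile


@dataclass
class OutlierReport:
    """Per-sample total normalised abundance vs the IQR fence."""

    totals: pd.Series
    lower: float
    upper: float
    flags: pd.Series
    k: float
    center: str

    @property
    def flagged_ids(self) -> list[str]:
        return list(self.flags.index[self.flags])


def flag_outlier_samples(matrix: AbundanceMatrix, k: float = 1.5,
                         center: str = "median") -> OutlierReport:
    """Flag samples whose total abundance lies outside the IQR fence.

    ``center='median'`` (default) uses median +/- k*IQR; ``center='quartile'``
    uses the Tukey fences Q1 - k*IQR, Q3 + k*IQR.  Flagged samples are
    reported, never removed — downstream stages keep them (longitudinal
    design).
    """
    if len(matrix.sample_ids) < 4:
        raise ValidationError("need >= 4 samples for an IQR fence")
    totals = matrix.values.sum(axis=0)
    q1, med, q3 = np.percentile(totals, [25, 50, 75])
    iqr = q3 - q1
    if center == "median":
        lower, upper = med - k * iqr, med + k * iqr
    elif center == "quartile":
        lower, upper = q1 - k * iqr, q3 + k * iqr
    else:
        raise ValidationError("center must be 'median' or 'quartile'")
    flags = (totals < lower) | (totals > upper)
    return OutlierReport(totals=totals, lower=float(lower), upper=float(upper),
                         flags=flags, k=k, center=center)


def baseline_average(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Per-subject arithmetic mean of all baseline samples (features x subjects)."""
    meta = matrix.metadata
    study = meta[~meta["is_tech_replicate"].astype(bool)]
    subjects = study["subject_id"].unique()
    cols = {}
    for subj in subjects:
        ids = study.index[(study["subject_id"] == subj)
                          & (study["timepoint"] == "baseline")]
        if len(ids) == 0:
            raise ValidationError(f"subject {subj} has no baseline sample")
        cols[subj] = matrix.values[list(ids)].mean(axis=1)
    return pd.DataFrame(cols)


def paired_differential(matrix: AbundanceMatrix, design: PairedDesign,
                        baseline: pd.DataFrame | None = None,
                        q_threshold: float = 0.05
                        ) -> tuple[pd.DataFrame, list[str]]:
    """Per-feature log2 paired t-tests for one comparison.

    Each subject contributes ``log2(treatment / reference)`` per feature, the
    reference being either the subject's baseline-average profile (control id
    ``BASELINE``) or a matched control sample.  Features with a zero or
    missing intensity in any needed ratio are excluded and reported.  Returns
    a results frame (feature, log2fc_mean, t, p, q, significant) and the list
    of excluded features.
    """
    if design.n_pairs < 2:
        raise ValidationError(
            f"{design.label}: need >= 2 subjects for a paired test")
    treat_cols = []
    ref_cols = []
    for pair in design.pairs:
        treat_cols.append(matrix.values[pair.treatment].to_numpy(dtype=float))
        if pair.control == BASELINE:
            if baseline is None:
                raise ValidationError(
                    "baseline profile required for baseline-referenced design")
            ref_cols.append(baseline[pair.subject_id].to_numpy(dtype=float))
        else:
            ref_cols.append(matrix.values[pair.control].to_numpy(dtype=float))
    treat = np.column_stack(treat_cols)
    ref = np.column_stack(ref_cols)
    ok = (treat > 0).all(axis=1) & (ref > 0).all(axis=1)
    excluded = list(matrix.values.index[~ok])
    if excluded:
        warnings.warn(
            f"{design.label}: {len(excluded)} feature(s) excluded "
            "(zero or missing intensity in a needed ratio)")
    if ok.sum() == 0:
        raise DegenerateDataError(f"{design.label}: no testable features")
    diffs = np.log2(treat[ok]) - np.log2(ref[ok])
    t, p, eff = paired_t_test_matrix(diffs)
    q = bh_adjust(p)
    out = pd.DataFrame({
        "feature": matrix.values.index[ok],
        "comparison": design.label,
        "log2fc_mean": eff,
        "t": t,
        "p": p,
        "q": q,
        "significant": q < q_threshold,
    }).reset_index(drop=True)
    return out, excluded


@dataclass
class ClusterResult:
    """Complete-linkage dendrogram on 1 - Pearson correlation distances."""

    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[str]

    def to_newick(self) -> str:
        tree = sch.to_tree(self.linkage)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def hierarchical_cluster(data: pd.DataFrame, axis: str = "columns"
                         ) -> ClusterResult:
    """Cluster rows or columns with 1 - Pearson distance, complete linkage."""
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValidationError("need >= 2 rows and >= 2 columns")
    arr = data.to_numpy(dtype=float)
    row_sd = arr.std(axis=1)
    const_rows = data.index[row_sd == 0]
    if len(const_rows):
        raise DegenerateDataError(
            f"constant row(s) make Pearson correlation undefined: "
            f"{list(const_rows)[:5]}")
    if axis == "columns":
        mat = arr.T
        labels = [str(c) for c in data.columns]
    elif axis == "rows":
        mat = arr
        labels = [str(r) for r in data.index]
    else:
        raise ValidationError("axis must be 'rows' or 'columns'")
    sd = mat.std(axis=1)
    if (sd == 0).any():
        bad = [labels[i] for i in np.where(sd == 0)[0]]
        raise DegenerateDataError(f"constant {axis[:-1]}(s): {bad[:5]}")
    corr = np.corrcoef(mat)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    linkage = sch.linkage(condensed, method="complete")
    order = [labels[i] for i in sch.leaves_list(linkage)]
    return ClusterResult(linkage=linkage, labels=labels, leaf_order=order)


@dataclass
class ProteomeResults:
    """Output of the full proteomics pipeline."""

    tables: pd.DataFrame
    outliers: OutlierReport
    cv_report: pd.DataFrame
    excluded: dict[str, list[str]]
    normalized: AbundanceMatrix
    baseline: pd.DataFrame
    q_threshold: float
    reference_profile: pd.Series | None = None
    pipeline_log: list[str] = field(default_factory=list)

    def significant(self, comparison: str | None = None) -> pd.DataFrame:
        t = self.tables
        if comparison is not None:
            t = t[t["comparison"] == comparison]
        return t[t["significant"]]

    def summary(self) -> str:
        lines = [f"Proteome paired differential expression "
                 f"(q < {self.q_threshold:g}):"]
        n_dropped = int(self.cv_report["dropped"].sum())
        lines.append(f"  CV filter dropped {n_dropped} feature(s); "
                     f"{len(self.normalized.feature_ids)} retained")
        lines.append(f"  outlier samples flagged (kept): "
                     f"{self.outliers.flagged_ids or 'none'}")
        for comp, grp in self.tables.groupby("comparison", sort=False):
            n_sig = int(grp["significant"].sum())
            lines.append(f"  {comp}: {n_sig}/{len(grp)} significant")
        return "\n".join(lines)


class PairedProteomeModel:
    """End-to-end paired differential-expression model for one study matrix."""

    def __init__(self, matrix: AbundanceMatrix,
                 cv_threshold: float = 0.25,
                 outlier_k: float = 1.5,
                 q_threshold: float = 0.05) -> None:
        self.matrix = matrix
        self.cv_threshold = cv_threshold
        self.outlier_k = outlier_k
        self.q_threshold = q_threshold

    def fit(self, designs: list[PairedDesign]) -> ProteomeResults:
        log = ["normalize_total_signal"]
        m = normalize_total_signal(self.matrix)
        m, cv_report = filter_by_replicate_cv(m, self.cv_threshold)
        log.append(f"filter_by_replicate_cv(threshold={self.cv_threshold})")
        m, profile = normalize(m)
        log.append("median_normalize (frozen reference profile)")
        outliers = flag_outlier_samples(m, k=self.outlier_k)
        log.append(f"flag_outlier_samples(k={self.outlier_k}) -> "
                   f"{len(outliers.flagged_ids)} flagged, all retained")
        study = m.subset_samples(m.study_sample_ids())
        base = baseline_average(study)
        log.append("baseline_average")
        tables = []
        excluded: dict[str, list[str]] = {}
        for design in designs:
            tab, excl = paired_differential(study, design, baseline=base,
                                            q_threshold=self.q_threshold)
            tables.append(tab)
            excluded[design.label] = excl
        log.append(f"paired_differential + bh_adjust on {len(designs)} "
                   "comparison(s)")
        return ProteomeResults(tables=pd.concat(tables, ignore_index=True),
                               outliers=outliers, cv_report=cv_report,
                               excluded=excluded, normalized=m, baseline=base,
                               q_threshold=self.q_threshold,
                               reference_profile=profile, pipeline_log=log)
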
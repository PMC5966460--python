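"""Proteomics pipeline: normalisation, filtering, paired testing, clustering."""

import numpy as np
import pandas as pd
import pytest

import mucopair as mp
from mucopair.containers import AbundanceMatrix, PairedDesign, SamplePair
from mucopair.exceptions import DegenerateDataError, ValidationError
from mucopair.proteome import (BASELINE, baseline_average,
                               filter_by_replicate_cv, flag_outlier_samples,
                               hierarchical_cluster, median_normalize,
                               normalize, normalize_total_signal,
                               paired_differential)


def matrix_from(values: np.ndarray, tech_flags=None,
                timepoints=None, subjects=None) -> AbundanceMatrix:
    n_feat, n_samp = values.shape
    ids = [f"S{j + 1}" for j in range(n_samp)]
    meta = pd.DataFrame({
        "subject_id": subjects or [f"A{j + 1}" for j in range(n_samp)],
        "arm": "none",
        "formulation": "none",
        "timepoint": timepoints or ["baseline"] * n_samp,
        "is_tech_replicate": tech_flags or [False] * n_samp,
    }, index=ids)
    vals = pd.DataFrame(values, index=[f"F{i + 1}" for i in range(n_feat)],
                        columns=ids)
    return AbundanceMatrix(vals, meta)


class TestTotalSignalNormalisation:
    def test_two_sample_scale_factors(self):
        m = matrix_from(np.array([[60.0, 150.0], [40.0, 50.0]]))
        out = normalize_total_signal(m)
        # totals 100 and 200 -> scaled by 1.5 and 0.75 to the mean total 150
        assert np.allclose(out.values["S1"], [90.0, 60.0])
        assert np.allclose(out.values["S2"], [112.5, 37.5])
        assert np.allclose(out.values.sum(axis=0), 150.0)

    def test_equal_totals_identity(self):
        m = matrix_from(np.array([[60.0, 30.0], [40.0, 70.0]]))
        out = normalize_total_signal(m)
        assert np.allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_zero_total_names_sample(self):
        m = matrix_from(np.array([[1.0, 0.0], [1.0, 0.0]]))
        with pytest.raises(ValidationError, match="S2"):
            normalize_total_signal(m)

    def test_proportions_preserved(self, rng):
        m = matrix_from(rng.lognormal(3, 1, size=(10, 6)))
        out = normalize_total_signal(m)
        before = m.values / m.values.sum(axis=0)
        after = out.values / out.values.sum(axis=0)
        assert np.allclose(before.to_numpy(), after.to_numpy())


class TestReplicateCVFilter:
    def _with_reps(self, rep_values: np.ndarray) -> AbundanceMatrix:
        n_feat, n_reps = rep_values.shape
        study = np.full((n_feat, 2), 100.0)
        values = np.hstack([study, rep_values])
        flags = [False, False] + [True] * n_reps
        return matrix_from(values, tech_flags=flags)

    def test_zero_cv_retained(self):
        m = self._with_reps(np.array([[100.0, 100.0, 100.0]]))
        out, report = filter_by_replicate_cv(m)
        assert list(out.feature_ids) == ["F1"]
        assert not report["dropped"].iloc[0]

    def test_high_cv_dropped(self):
        # sd/mean of [100, 200] is 70.71/150 ~ 0.471 > 0.25
        m = self._with_reps(np.array([[100.0, 200.0], [100.0, 101.0]]))
        out, report = filter_by_replicate_cv(m)
        assert list(out.feature_ids) == ["F2"]
        assert report.loc["F1", "cv"] == pytest.approx(
            np.std([100, 200], ddof=1) / 150.0)

    def test_infinite_threshold_is_identity(self):
        m = self._with_reps(np.array([[100.0, 500.0], [1.0, 9.0]]))
        out, _ = filter_by_replicate_cv(m, cv_threshold=np.inf)
        assert list(out.feature_ids) == ["F1", "F2"]

    def test_no_replicates_rejected(self):
        m = matrix_from(np.full((2, 4), 10.0))
        with pytest.raises(ValidationError):
            filter_by_replicate_cv(m)


class TestMedianNormalisation:
    def test_pure_scale_sample_halved(self):
        base = np.array([[8.0, 8.0, 16.0], [2.0, 2.0, 4.0], [32.0, 32.0, 64.0]])
        m = matrix_from(base)
        out = median_normalize(m)
        # S3 = 2 x the median profile -> divided by 2 exactly
        assert np.allclose(out.values["S3"], base[:, 0])
        assert np.allclose(out.values["S1"], base[:, 0])

    def test_sample_equal_to_profile_unchanged(self):
        base = np.array([[8.0], [2.0], [32.0]])
        m = matrix_from(np.hstack([base, base, base]))
        out = median_normalize(m)
        assert np.allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_refit_slopes_are_unit(self, rng):
        m = matrix_from(rng.lognormal(5, 2, size=(30, 8)))
        profile = np.log2(m.values).median(axis=1)
        out = median_normalize(m, profile=profile)
        logs = np.log2(out.values.to_numpy())
        pr = profile.to_numpy()
        slopes = logs.T @ pr / (pr @ pr)
        assert np.allclose(slopes, 1.0, atol=1e-8)

    def test_constant_profile_rejected(self):
        m = matrix_from(np.full((3, 4), 7.0))
        with pytest.raises(DegenerateDataError):
            median_normalize(m)

    def test_pair_idempotent_with_frozen_profile(self, rng):
        m = matrix_from(rng.lognormal(5, 1.5, size=(40, 10)))
        z, profile = normalize(m)
        z2 = median_normalize(normalize_total_signal(z), profile=profile)
        d = np.abs(np.log2(z2.values.to_numpy())
                   - np.log2(z.values.to_numpy())).max()
        assert d < 1e-8


class TestOutlierFlagging:
    def test_single_extreme_flagged(self):
        m = matrix_from(np.array([[10.0, 10.0, 10.0, 10.0, 100.0]]) / 1.0)
        rep = flag_outlier_samples(m)
        assert rep.flagged_ids == ["S5"]

    def test_identical_totals_no_flags(self):
        m = matrix_from(np.full((3, 6), 5.0))
        rep = flag_outlier_samples(m)
        assert rep.flagged_ids == []

    def test_three_planted_extremes_among_96(self, rng):
        # tight uniform bulk: the fence (median +/- 1.5 IQR) clears all of it
        totals = rng.uniform(990.0, 1010.0, size=96)
        totals[[5, 40, 90]] = [2000.0, 1900.0, 100.0]
        m = matrix_from(totals[None, :])
        rep = flag_outlier_samples(m)
        assert sorted(rep.flagged_ids) == sorted(["S6", "S41", "S91"])

    def test_quartile_mode_widens_fence(self, rng):
        totals = np.r_[rng.normal(1000.0, 50.0, size=20), 1400.0]
        m = matrix_from(totals[None, :])
        med = flag_outlier_samples(m, center="median")
        qt = flag_outlier_samples(m, center="quartile")
        assert set(qt.flagged_ids) <= set(med.flagged_ids)

    def test_too_few_samples_rejected(self):
        m = matrix_from(np.full((2, 3), 5.0))
        with pytest.raises(ValidationError):
            flag_outlier_samples(m)


class TestBaselineAverage:
    def test_known_mean(self):
        vals = np.array([[2.0, 4.0, 6.0, 8.0]])
        m = matrix_from(vals, subjects=["X"] * 4)
        base = baseline_average(m)
        assert base.loc["F1", "X"] == pytest.approx(5.0)

    def test_single_baseline_is_identity(self):
        m = matrix_from(np.array([[3.5]]), subjects=["X"])
        assert baseline_average(m).loc["F1", "X"] == 3.5

    def test_missing_baseline_names_subject(self):
        m = matrix_from(np.array([[1.0, 2.0]]), subjects=["X", "Y"],
                        timepoints=["baseline", "24h"])
        with pytest.raises(ValidationError, match="Y"):
            baseline_average(m)

    def test_matches_independent_mean(self, rng):
        vals = rng.lognormal(3, 1, size=(5, 4))
        m = matrix_from(vals, subjects=["X"] * 4)
        assert np.allclose(baseline_average(m)["X"], vals.mean(axis=1))


class TestPairedDifferential:
    def test_null_self_comparison_gives_zero_fc(self):
        vals = np.array([[10.0, 10.0, 20.0, 20.0], [5.0, 5.0, 8.0, 8.0]])
        m = matrix_from(vals, subjects=["A", "A", "B", "B"],
                        timepoints=["baseline", "24h"] * 2)
        design = PairedDesign("self", [SamplePair("A", "S2", "S1"),
                                       SamplePair("B", "S4", "S3")])
        # treatment == control value per subject -> every log2 FC is 0
        m.values["S2"] = m.values["S1"]
        m.values["S4"] = m.values["S3"]
        tab, _ = paired_differential(m, design)
        assert np.allclose(tab["log2fc_mean"], 0.0)
        assert not tab["significant"].any()

    def test_single_subject_rejected(self):
        m = matrix_from(np.array([[1.0, 2.0]]), subjects=["A", "A"],
                        timepoints=["baseline", "24h"])
        design = PairedDesign("solo", [SamplePair("A", "S2", "S1")])
        with pytest.raises(ValidationError):
            paired_differential(m, design)

    def test_zero_intensity_features_excluded_with_warning(self):
        vals = np.array([[10.0, 12.0, 20.0, 22.0, 30.0, 28.0],
                         [0.0, 5.0, 6.0, 7.0, 8.0, 9.0]])
        m = matrix_from(vals, subjects=["A", "A", "B", "B", "C", "C"],
                        timepoints=["baseline", "24h"] * 3)
        design = PairedDesign("z", [SamplePair("A", "S2", "S1"),
                                    SamplePair("B", "S4", "S3"),
                                    SamplePair("C", "S6", "S5")])
        with pytest.warns(UserWarning, match="excluded"):
            tab, excluded = paired_differential(m, design)
        assert excluded == ["F2"]
        assert list(tab["feature"]) == ["F1"]

    def test_planted_effects_detected_in_synthetic_study(self):
        # 20% of proteins perturbed by |log2 FC| = 3 (balanced signs)
        effects = tuple((i, 3.0 if i % 2 else -3.0) for i in range(8))
        cfg = mp.StudyConfig(n_proteins=40, effect_proteins=effects, seed=21)
        matrix, _ = mp.gen_proteome_study(cfg)
        design = [d for d in mp.proteome_comparisons(matrix.metadata)
                  if d.label == "hec placebo 2h vs baseline"][0]
        study = matrix.subset_samples(matrix.study_sample_ids())
        base = baseline_average(study)
        tab, _ = paired_differential(study, design, baseline=base)
        sig = set(tab.loc[tab["significant"], "feature"])
        hits = sum(f"PROT{i + 1:04d}" in sig for i in range(8))
        assert hits >= 6
        false = [f for f in sig if int(f[4:]) > 8]
        assert len(false) <= 2


class TestHierarchicalCluster:
    def test_identical_columns_merge_at_zero(self, rng):
        x = rng.normal(size=6)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=6)})
        res = hierarchical_cluster(df)
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_columns_are_maximally_distant(self, rng):
        x = rng.normal(size=8)
        df = pd.DataFrame({"a": x, "b": -x})
        res = hierarchical_cluster(df)
        assert res.linkage[-1, 2] == pytest.approx(2.0, abs=1e-12)

    def test_matches_brute_force_complete_linkage(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 4)),
                          columns=["a", "b", "c", "d"])
        res = hierarchical_cluster(df)
        # brute-force complete linkage on the 4x4 correlation distances
        d = 1.0 - np.corrcoef(df.to_numpy().T)
        clusters = {i: {i} for i in range(4)}
        heights = []
        while len(clusters) > 1:
            best = None
            for i in clusters:
                for j in clusters:
                    if i < j:
                        h = max(d[a, b] for a in clusters[i]
                                for b in clusters[j])
                        if best is None or h < best[0]:
                            best = (h, i, j)
            h, i, j = best
            heights.append(h)
            clusters[i] = clusters[i] | clusters[j]
            del clusters[j]
        assert np.allclose(sorted(res.linkage[:, 2]), sorted(heights),
                           atol=1e-12)

    def test_constant_row_rejected(self):
        df = pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 3.0]},
                          index=["flat", "ok"]).T
        with pytest.raises(DegenerateDataError):
            hierarchical_cluster(pd.DataFrame(
                {"a": [5.0, 1.0], "b": [5.0, 2.0], "c": [5.0, 4.0]},
                index=["flat", "ok"]))

    def test_newick_export_lists_all_leaves(self, rng):
        df = pd.DataFrame(rng.normal(size=(8, 5)),
                          columns=list("abcde"))
        nwk = hierarchical_cluster(df).to_newick()
        assert nwk.endswith(";")
        for leaf in "abcde":
            assert leaf in nwk
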
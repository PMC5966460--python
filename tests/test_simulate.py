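"""Synthetic study generator: structure, determinism, effect recovery."""

import numpy as np
import pytest

import mucopair as mp
from mucopair.exceptions import ValidationError
from mucopair.simulate import positive_control_sigma_law


class TestConfigValidation:
    def test_effect_index_out_of_range_names_index(self):
        with pytest.raises(ValidationError, match="17"):
            mp.StudyConfig(n_taxa=10, effect_taxa=((17, 0.3),))

    def test_duplicate_effect_index_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            mp.StudyConfig(effect_proteins=((3, 1.0), (3, 2.0)))

    def test_counts_must_be_positive(self):
        with pytest.raises(ValidationError):
            mp.StudyConfig(n_subjects=0)


class TestProteomeGenerator:
    def test_design_dimensions(self):
        cfg = mp.StudyConfig(n_proteins=30, seed=0)
        m, _ = mp.gen_proteome_study(cfg)
        study = m.study_sample_ids()
        # 4 baselines + 2 formulations x 2 arms x 3 time points, per subject
        assert len(study) == 6 * (4 + 12)
        assert len(m.tech_replicate_ids()) == cfg.n_tech_replicates
        assert (m.values.to_numpy() > 0).all()

    def test_planted_effect_recovered_by_averaging(self):
        cfg = mp.StudyConfig(n_proteins=10, effect_proteins=((0, 3.0),),
                             seed=1)
        m, truth = mp.gen_proteome_study(cfg)
        meta = m.metadata
        eff = meta.index[(meta["arm"] == "placebo")
                         & (meta["formulation"] == "hec")
                         & (meta["timepoint"] == "2h")]
        ratios = []
        for subj in meta.loc[eff, "subject_id"]:
            base = meta.index[(meta["subject_id"] == subj)
                              & (meta["timepoint"] == "baseline")]
            t = meta.index[(meta["subject_id"] == subj) & meta.index.isin(eff)]
            ratios.append(np.log2(m.values.loc["PROT0001", t[0]])
                          - np.log2(m.values.loc["PROT0001", base].mean()))
        se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert np.mean(ratios) == pytest.approx(3.0, abs=3 * max(se, 0.3))

    def test_zero_noise_null_proteins_have_exact_zero_fc(self):
        cfg = mp.StudyConfig(n_proteins=8, within_pair_sd_log2=0.0, seed=3)
        m, _ = mp.gen_proteome_study(cfg)
        meta = m.metadata
        subj = "M1"
        base = meta.index[(meta["subject_id"] == subj)
                          & (meta["timepoint"] == "baseline")]
        treat = meta.index[(meta["subject_id"] == subj)
                           & (meta["timepoint"] == "24h")
                           & (meta["arm"] == "grft")
                           & (meta["formulation"] == "carbopol")]
        fc = (np.log2(m.values[treat[0]])
              - np.log2(m.values[base].mean(axis=1)))
        assert np.allclose(fc, 0.0, atol=1e-12)

    def test_determinism(self):
        cfg = mp.StudyConfig(n_proteins=12, seed=5)
        a, _ = mp.gen_proteome_study(cfg)
        b, _ = mp.gen_proteome_study(cfg)
        assert a.values.equals(b.values)
        assert a.metadata.equals(b.metadata)

    def test_decoy_proteins_have_high_replicate_cv(self):
        cfg = mp.StudyConfig(n_proteins=12, decoy_proteins=(2,), seed=8)
        m, _ = mp.gen_proteome_study(cfg)
        reps = m.values[m.tech_replicate_ids()]
        cv = reps.std(axis=1, ddof=1) / reps.mean(axis=1)
        assert cv.iloc[2] > 0.25
        assert (cv.drop(index="PROT0003") < 0.25).all()


class TestMicrobiomeGenerator:
    def test_columns_sum_to_depths_and_design(self, small_microbiome):
        table, _ = small_microbiome
        assert (table.counts.sum(axis=0) == table.depths).all()
        # 2 baselines + 2 formulations x 2 arms x 3 time points per subject
        assert table.counts.shape[1] == 6 * (2 + 12)

    def test_degenerate_depth_dispersion(self):
        cfg = mp.StudyConfig(n_taxa=10, mean_depth=5000, depth_dispersion=0.0,
                             seed=2)
        table, _ = mp.gen_microbiome_study(cfg)
        assert (table.depths == 5000).all()

    def test_baseline_compositions_sum_to_one(self, small_microbiome):
        _, truth = small_microbiome
        sums = truth.baseline_compositions.sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_null_taxa_log_ratios_center_on_zero(self):
        # many subjects so the paired-mean standard error is small
        cfg = mp.StudyConfig(n_subjects=60, n_taxa=15, mean_depth=30_000,
                             seed=9)
        table, _ = mp.gen_microbiome_study(cfg)
        meta = table.metadata
        lr = []
        for subj in [f"M{i + 1}" for i in range(60)]:
            t = meta.index[(meta["subject_id"] == subj)
                           & (meta["formulation"] == "hec")
                           & (meta["arm"] == "placebo")
                           & (meta["timepoint"] == "24h")][0]
            c = meta.index[(meta["subject_id"] == subj)
                           & (meta["timepoint"] == "baseline")][0]
            pt = (table.counts[t] + 0.5) / (table.depths[t] + 1)
            pc = (table.counts[c] + 0.5) / (table.depths[c] + 1)
            lr.append(np.log10(pt / pc))
        lr = np.array([v.to_numpy() for v in lr])
        mean = lr.mean(axis=0)
        se = lr.std(axis=0, ddof=1) / np.sqrt(60)
        assert (np.abs(mean) < 3 * se + 0.02).mean() > 0.9

    def test_planted_rare_taxon_ratio_matches_injection(self):
        # a low-abundance taxon keeps its injected ratio ~10**0.352 = 2.25
        cfg = mp.StudyConfig(n_taxa=30, mean_depth=50_000,
                             effect_taxa=((20, 0.352),), seed=4)
        table, truth = mp.gen_microbiome_study(cfg)
        meta = table.metadata
        ratios = []
        for subj in [f"M{i + 1}" for i in range(6)]:
            t = meta.index[(meta["subject_id"] == subj)
                           & (meta["formulation"] == "hec")
                           & (meta["arm"] == "placebo")
                           & (meta["timepoint"] == "24h")][0]
            c = meta.index[(meta["subject_id"] == subj)
                           & (meta["timepoint"] == "baseline")][0]
            pt = (table.counts.loc["TAXON021", t] + 0.5) / (table.depths[t] + 1)
            pc = (table.counts.loc["TAXON021", c] + 0.5) / (table.depths[c] + 1)
            ratios.append(pt / pc)
        assert np.median(ratios) == pytest.approx(10 ** 0.352, rel=0.5)
        assert truth.taxa_log10_ratio[20] == 0.352

    def test_true_proportions_recorded_for_every_sample(self, small_microbiome):
        table, truth = small_microbiome
        assert truth.true_proportions.shape == table.counts.shape
        assert np.allclose(truth.true_proportions.sum(axis=0), 1.0)

    def test_oversized_effect_rejected(self):
        with pytest.raises(ValidationError, match="> 1"):
            cfg = mp.StudyConfig(n_taxa=5, effect_taxa=((0, 2.0),), seed=0)
            mp.gen_microbiome_study(cfg)

    def test_determinism(self):
        cfg = mp.StudyConfig(n_taxa=8, mean_depth=2000, seed=6)
        a, _ = mp.gen_microbiome_study(cfg)
        b, _ = mp.gen_microbiome_study(cfg)
        assert a.counts.equals(b.counts)


class TestPositiveControls:
    def test_determinism(self):
        cfg = mp.StudyConfig(n_taxa=10, mean_depth=2000, seed=1)
        assert mp.gen_positive_controls(cfg).counts.equals(
            mp.gen_positive_controls(cfg).counts)

    def test_minimum_replicates_enforced(self):
        with pytest.raises(ValidationError):
            mp.gen_positive_controls(mp.StudyConfig(n_positive_controls=2))

    def test_two_taxon_mixture_at_huge_depth(self):
        # equal mixture, negligible jitter and sampling noise
        cfg = mp.StudyConfig(n_taxa=2, n_positive_controls=3,
                             mean_depth=10_000_000, depth_dispersion=0.0,
                             pc_sigma_intercept=1e-4, pc_sigma_slope=0.0,
                             subject_sd_log10=0.0, seed=3)
        pc = mp.gen_positive_controls(cfg)
        rel = pc.counts / pc.counts.sum(axis=0)
        # composition is whatever the pattern drew; log-ratio jitter ~1e-4
        expected = rel.mean(axis=1)
        assert np.allclose(np.log10(rel), np.log10(expected.to_numpy()[:, None]),
                           atol=0.01)

    def test_variance_law_recovered_empirically(self):
        cfg = mp.StudyConfig(n_taxa=50, n_positive_controls=14,
                             mean_depth=2_000_000, depth_dispersion=0.0,
                             seed=10)
        pc = mp.gen_positive_controls(cfg)
        rel = pc.counts / pc.counts.sum(axis=0)
        detected = (pc.counts > 0).all(axis=1)
        lg = np.log10(rel[detected])
        med = np.median(lg, axis=1)
        sd = lg.std(axis=1, ddof=1)
        law = positive_control_sigma_law(cfg, med)
        # pooled over taxa the empirical sds track the law
        ratio = np.median(sd / law)
        assert 0.6 < ratio < 1.4
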
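import numpy as np
import pandas as pd
import pytest

from rhizoactive import SimulationConfig, simulate_metabolome, simulate_paired_assay
from rhizoactive.core_io import validate_metadata


class TestPairedAssaySimulation:
    def test_same_seed_identical_output(self):
        cfg = SimulationConfig(n_taxa=40, replicates=2, days=(2, 4), rng_seed=7)
        a1, m1, t1 = simulate_paired_assay(cfg)
        a2, m2, t2 = simulate_paired_assay(cfg)
        assert a1.dna == a2.dna and a1.cdna == a2.cdna
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_series_equal(t1.activity, t2.activity)

    def test_metadata_satisfies_design_invariants(self):
        _, meta, _ = simulate_paired_assay(SimulationConfig(
            n_taxa=30, replicates=2, days=(2, 6), rng_seed=1))
        validate_metadata(meta.reset_index())

    def test_neutral_activity_converges_to_dna_composition(self):
        # all a_t = 1: cDNA composition equals DNA composition up to
        # multinomial noise, which shrinks as depth grows
        def max_gap(depth):
            cfg = SimulationConfig(
                n_taxa=50, replicates=1, soils=("bean",), days=(2,),
                depth_mean=depth, depth_dispersion=None,
                fraction_active=1.0, active_median=1.0, active_sigma=0.0,
                phantom_fraction=0.0, n_contaminants=0, n_negative_controls=0,
                n_responders_planted=0, n_responders_drought=0,
                n_responders_interaction=0, rng_seed=3)
            assay, _, _ = simulate_paired_assay(cfg)
            rel_d = assay.dna.relative_abundance().to_numpy()
            rel_c = assay.cdna.relative_abundance().to_numpy()
            return np.abs(rel_d - rel_c).max()

        assert max_gap(1_000_000.0) < 5e-3
        assert max_gap(1_000_000.0) < max_gap(10_000.0)

    def test_contaminants_in_every_control_at_full_prevalence(self):
        cfg = SimulationConfig(
            n_taxa=30, replicates=1, days=(2,), n_contaminants=3,
            contaminant_prev_controls=1.0, contaminant_prev_samples=0.05,
            n_negative_controls=5, rng_seed=11)
        assay, meta, truth = simulate_paired_assay(cfg)
        controls = meta.index[meta["is_negative_control"]]
        contam = truth.contaminant.index[truth.contaminant]
        present = assay.dna.data.loc[controls, contam] > 0
        assert present.all().all()

    def test_phantom_taxa_have_sub_read_dna_abundance(self):
        cfg = SimulationConfig(n_taxa=200, replicates=2, days=(2, 4), rng_seed=5)
        assay, meta, truth = simulate_paired_assay(cfg)
        phantoms = truth.phantom.index[truth.phantom]
        assert len(phantoms) == round(0.02 * 200)
        mean_rel = truth.composition[phantoms].mean(axis=0)
        assert (mean_rel < 1.0 / cfg.depth_mean).all()
        assert (truth.activity[phantoms] >= 2).all()

    def test_sample_depth_equals_drawn_depth_exactly(self):
        cfg = SimulationConfig(n_taxa=25, replicates=1, days=(2,),
                               depth_dispersion=None, rng_seed=2)
        assay, meta, _ = simulate_paired_assay(cfg)
        real = meta.index[~meta["is_negative_control"]]
        assert (assay.dna.data.loc[real].sum(axis=1) == 20_000).all()

    def test_too_many_responders_rejected(self):
        cfg = SimulationConfig(n_taxa=10, n_responders_planted=20)
        with pytest.raises(ValueError):
            simulate_paired_assay(cfg)


class TestMetabolomeSimulation:
    def test_seed_reproducibility(self):
        m1, l1, t1 = simulate_metabolome(seed=9)
        m2, l2, t2 = simulate_metabolome(seed=9)
        pd.testing.assert_frame_equal(m1, m2)
        assert t1 == t2

    def test_zero_shift_still_returns_truth_set(self):
        mat, labels, truth = simulate_metabolome(shift_sd_units=0.0, seed=1)
        assert len(truth) == 10
        assert set(labels.unique()) == {"watered", "drought"}

    def test_discriminating_features_have_extreme_t_statistics(self):
        from scipy.stats import ttest_ind

        # n_per_group=15 makes the per-feature t sharp enough that every truth
        # feature should clear the noise features' 95th percentile
        wins = 0
        for seed in range(10):
            mat, labels, truth = simulate_metabolome(
                n_features=200, n_per_group=15, n_discriminating=10,
                shift_sd_units=2.0, seed=seed)
            logged = np.log10(mat)
            a = logged[labels == "watered"]
            b = logged[labels == "drought"]
            t = ttest_ind(b, a).statistic
            t = pd.Series(np.abs(t), index=mat.columns)
            cutoff = t[~t.index.isin(truth)].quantile(0.95)
            if (t[list(truth)] > cutoff).all():
                wins += 1
        assert wins >= 9

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            simulate_metabolome(n_features=5, n_discriminating=9)
        with pytest.raises(ValueError):
            simulate_metabolome(n_per_group=1)


class TestGeneratorStatisticalProperties:
    def test_planted_effect_detected_by_permanova(self):
        from rhizoactive import bray_curtis, permanova

        rejections = 0
        for seed in range(10):
            cfg = SimulationConfig(n_taxa=200, rng_seed=100 + seed)
            assay, meta, _ = simulate_paired_assay(cfg)
            m = meta[(~meta["is_negative_control"]) & (meta["crop"] == "bean")]
            tbl = assay.dna.select_samples(list(m.index)).relative_abundance()
            res = permanova(bray_curtis(tbl), m, ["planted"], n_perm=199, seed=seed)
            rejections += res[0].p_value < 0.05
        assert rejections >= 9

    def test_null_planted_effect_type_one_error(self):
        from rhizoactive import bray_curtis, permanova

        rej = 0
        for seed in range(200):
            cfg = SimulationConfig(
                n_taxa=40, replicates=1, soils=("bean",), days=(2, 4),
                depth_mean=2000.0, n_contaminants=0, n_negative_controls=0,
                phantom_fraction=0.0, n_responders_planted=0,
                n_responders_drought=0, n_responders_interaction=0,
                rng_seed=seed)
            assay, meta, _ = simulate_paired_assay(cfg)
            m = meta[~meta["is_negative_control"]]
            tbl = assay.dna.select_samples(list(m.index)).relative_abundance()
            res = permanova(bray_curtis(tbl), m, ["planted"], n_perm=99,
                            seed=seed + 500)
            rej += res[0].p_value <= 0.05
        assert 0.01 <= rej / 200 <= 0.10
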
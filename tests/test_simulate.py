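"""Contracts of the synthetic-data generator: determinism, planted structure,
degenerate limits, and the drug/expression links."""

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal
from scipy import stats

import kinomescreen as ks
from kinomescreen.simulate import ConfigurationError, atp_dilution_series


class TestConfigValidation:
    def test_timepoints_must_increase(self):
        with pytest.raises(ConfigurationError, match="increasing"):
            ks.SimulationConfig(timepoints=(100.0, 50.0, 700.0, 1840.0))

    def test_needs_two_points_in_auc_window(self):
        with pytest.raises(ConfigurationError, match="640"):
            ks.SimulationConfig(timepoints=(0.0, 100.0, 1000.0, 2000.0))

    def test_planted_kinase_must_exist(self):
        with pytest.raises(ConfigurationError, match="NOPE"):
            ks.SimulationConfig(planted_fold_changes={"NOPE": ("tumor", "healthy", 2.0)})

    def test_drug_target_must_exist(self):
        with pytest.raises(ConfigurationError, match="unknown kinase"):
            ks.SimulationConfig(drug_target_effects={"d": ("KIN99", 1.0)})

    def test_group_labels_length(self):
        with pytest.raises(ConfigurationError, match="group_labels"):
            ks.SimulationConfig(n_samples=4, group_labels=("tumor",))

    def test_yaml_roundtrip(self, tiny_config, tmp_path):
        p = tmp_path / "cfg.yaml"
        tiny_config.to_yaml(p)
        assert ks.SimulationConfig.from_yaml(p) == tiny_config


class TestKinomeDataset:
    def test_same_seed_identical_different_seed_differs(self, tiny_config):
        s1, a1, _ = ks.generate_kinome_dataset(tiny_config)
        s2, a2, _ = ks.generate_kinome_dataset(tiny_config)
        assert_frame_equal(s1, s2)
        assert_frame_equal(a1, a2)
        cfg3 = ks.SimulationConfig(**{**tiny_config.__dict__, "seed": tiny_config.seed + 1})
        s3, _, _ = ks.generate_kinome_dataset(cfg3)
        assert not np.allclose(s1["signal_lux"], s3["signal_lux"])

    def test_zero_rate_peptide_gives_zero_signal(self):
        # an orphan peptide has no upstream kinase, hence rate 0; without
        # noise its signal is identically zero at every timepoint
        cfg = ks.SimulationConfig(
            n_samples=2,
            group_labels=("tumor", "healthy"),
            n_peptides=10,
            n_kinases=2,
            kinases_per_peptide=(1, 2),
            noise_cv=0.0,
            noise_floor_lux=0.0,
            orphan_fraction=0.4,
            seed=4,
        )
        signals, _, truth = ks.generate_kinome_dataset(cfg)
        assert truth.orphan_peptides
        orphan_rows = signals[signals["peptide_id"].isin(truth.orphan_peptides)]
        assert (orphan_rows["signal_lux"] == 0.0).all()

    def test_noise_free_planted_fold_recovered_exactly_linear_law(self):
        # with the linear kinetic law and exclusively single-kinase peptides,
        # the AUC ratio equals the planted activity ratio exactly
        cfg = ks.SimulationConfig(
            n_samples=4,
            group_labels=("tumor", "tumor", "healthy", "healthy"),
            n_peptides=10,
            n_kinases=3,
            kinetic_law="linear",
            noise_cv=0.0,
            noise_floor_lux=0.0,
            activity_cv=0.0,
            orphan_fraction=0.0,
            kinases_per_peptide=(1, 1),
            planted_fold_changes={"KIN02": ("tumor", "healthy", 4.0)},
            seed=7,
        )
        signals, annotation, _ = ks.generate_kinome_dataset(cfg)
        activity = ks.preprocess(signals).activity
        fc = ks.kinase_fold_change(
            activity, annotation, ["tumor1", "tumor2"], ["healthy1", "healthy2"]
        ).set_index("feature")
        assert fc.loc["KIN02", "fold_change"] == pytest.approx(4.0, abs=1e-9)
        assert fc.loc["KIN02", "group_hi"] == "A"
        assert fc.loc["KIN01", "fold_change"] == pytest.approx(1.0, abs=1e-9)

    def test_control_peptide_auc_constant_across_samples_noise_free(self):
        cfg = ks.SimulationConfig(
            n_samples=3,
            group_labels=("tumor", "adjacent", "healthy"),
            n_peptides=8,
            n_kinases=3,
            noise_cv=0.0,
            noise_floor_lux=0.0,
            seed=1,
        )
        signals, _, _ = ks.generate_kinome_dataset(cfg)
        auc = ks.compute_auc(signals)
        ctrl = auc[cfg.control_peptide_id]
        assert np.ptp(ctrl.to_numpy()) == pytest.approx(0.0, abs=1e-9)

    def test_annotation_is_many_to_many_and_covers_all_kinases(self, tiny_dataset):
        _, annotation, truth = tiny_dataset
        assert set(annotation["kinase"]) == set(truth.kinase_activity.columns)
        per_pep = annotation.groupby("peptide_id").size()
        assert (per_pep >= 1).all()


class TestExpression:
    def test_perfect_correlation_limit(self, tiny_dataset, tiny_config):
        _, _, truth = tiny_dataset
        cfg = ks.SimulationConfig(**{**tiny_config.__dict__, "rna_activity_correlation": 1.0})
        expr = ks.generate_expression(truth, cfg)
        for s in truth.kinase_activity.index:
            r = stats.pearsonr(truth.kinase_activity.loc[s], expr[s]).statistic
            assert r == pytest.approx(1.0, abs=1e-12)

    def test_negative_correlation_limit(self, tiny_dataset, tiny_config):
        _, _, truth = tiny_dataset
        cfg = ks.SimulationConfig(**{**tiny_config.__dict__, "rna_activity_correlation": -1.0})
        expr = ks.generate_expression(truth, cfg)
        for gene in expr.index:
            rho = stats.spearmanr(truth.kinase_activity[gene], expr.loc[gene]).statistic
            assert rho == pytest.approx(-1.0, abs=1e-12)
        assert (expr.to_numpy() >= 0).all()

    def test_null_mean_r2_matches_independence_expectation_per_gene(self):
        # for two independent vectors of length n, E[r^2] = 1/(n-1); averaged
        # over many genes the per-gene R^2 should match it closely
        n_samples, n_genes = 6, 200
        r2s = []
        for seed in range(20):
            cfg = ks.SimulationConfig(
                n_samples=n_samples,
                group_labels=("tumor",) * n_samples,
                n_peptides=5,
                n_kinases=n_genes,
                kinases_per_peptide=(1, 1),
                rna_activity_correlation=0.0,
                seed=seed,
            )
            rng = np.random.default_rng(seed)
            activity = pd.DataFrame(
                rng.lognormal(size=(n_samples, n_genes)),
                index=cfg.sample_names(),
                columns=cfg.kinase_names(),
            )
            truth = ks.GroundTruth(
                kinase_activity=activity,
                peptide_weights=pd.DataFrame(),
                true_drug_links={},
                rates=pd.DataFrame(),
                orphan_peptides=[],
                sample_groups=dict(zip(cfg.sample_names(), cfg.group_labels)),
            )
            expr = ks.generate_expression(truth, cfg)
            corr = ks.correlate_per_line(activity, expr, mode="per_gene")
            r2s.append(corr["r2"].mean())
        expected = 1.0 / (n_samples - 1)
        assert np.mean(r2s) == pytest.approx(expected, abs=0.012)


class TestDrugScreen:
    def test_null_drug_response_constant_without_noise(self, tiny_dataset):
        _, _, truth = tiny_dataset
        cfg = ks.SimulationConfig(
            n_samples=4,
            group_labels=("tumor", "tumor", "healthy", "healthy"),
            n_peptides=12,
            n_kinases=4,
            vehicle_cv=0.0,
            drug_target_effects={"NULLDRUG": ("KIN01", 0.0)},
            seed=11,
        )
        table = ks.generate_drug_screen(truth, cfg)
        treated = table[(table["well_type"] == "treated") & (table["dose_um"] == 10.0)]
        assert treated["rlu"].nunique() == 1  # response 0.5 in every line

    def test_complete_kill_emits_zero_viability(self, tiny_dataset):
        _, _, truth = tiny_dataset
        cfg = ks.SimulationConfig(
            n_samples=4,
            group_labels=("tumor", "tumor", "healthy", "healthy"),
            n_peptides=12,
            n_kinases=4,
            vehicle_cv=0.0,
            drug_target_effects={"KILLER": ("KIN01", float("inf"))},
            seed=11,
        )
        table = ks.generate_drug_screen(truth, cfg)
        act = truth.kinase_activity["KIN01"]
        killed = act.index[act > act.mean()]
        treated = table[
            (table["well_type"] == "treated")
            & (table["dose_um"] == 10.0)
            & (table["sample_id"].isin(killed))
        ]
        assert len(treated) > 0
        assert (treated["rlu"] == 0.0).all()

    def test_dilution_series_endpoints(self):
        series = atp_dilution_series()
        assert len(series) == 7
        assert series[0] == 20.0
        assert series[-1] == pytest.approx(0.004883, rel=1e-3)  # 4.9 nM
        assert np.allclose(series[:-1] / series[1:], 4.0)

    def test_empty_drug_map_is_an_error(self, tiny_dataset, tiny_config):
        _, _, truth = tiny_dataset
        cfg = ks.SimulationConfig(**{**tiny_config.__dict__, "drug_target_effects": {}})
        with pytest.raises(ConfigurationError, match="empty"):
            ks.generate_drug_screen(truth, cfg)
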
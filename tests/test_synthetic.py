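"""Synthetic generator: determinism, conservation, bias model, hard parts."""

import numpy as np
import pandas as pd
import pytest

from sealdiet.amplicon import PRIMERS, design_tags
from sealdiet.lifestage import ADULT, JUVENILE
from sealdiet.synthetic import (
    PREDATOR_TAXON,
    SimulationConfig,
    TrueDiet,
    simulate_hardparts,
    simulate_read_counts,
    simulate_reads,
    simulate_sample_metadata,
    simulate_true_diets,
    synthetic_reference_db,
    true_diet_table,
)


class TestTrueDiets:
    def test_symmetric_alpha_means_near_uniform(self):
        cfg = SimulationConfig(
            n_samples=1000, taxa=("a", "b", "c"), salmonid_taxa=(),
            dirichlet_alpha=(1.0, 1.0, 1.0), seed=7,
        )
        t = true_diet_table(simulate_true_diets(cfg), cfg.taxa)
        # Dirichlet(1,1,1) marginal: mean 1/3, var = (1/3)(2/3)/4
        se = np.sqrt((1 / 3) * (2 / 3) / 4 / 1000)
        assert np.all(np.abs(t.mean(axis=0) - 1 / 3) < 3 * se)

    def test_dominant_alpha_component_dominates(self):
        cfg = SimulationConfig(
            n_samples=10, taxa=("a", "b"), salmonid_taxa=(),
            dirichlet_alpha=(1e6, 1.0), seed=1,
        )
        t = true_diet_table(simulate_true_diets(cfg), cfg.taxa)
        assert (t["a"] > 0.99).all()

    def test_same_seed_identical_output(self, small_config):
        assert simulate_true_diets(small_config) == simulate_true_diets(small_config)

    def test_proportions_validated(self):
        with pytest.raises(ValueError):
            TrueDiet("s", {"a": 0.6, "b": 0.6})
        with pytest.raises(ValueError):
            SimulationConfig(dirichlet_alpha=(0.0,) * 7)


class TestReadCounts:
    def test_reads_per_sample_conserved(self, small_config):
        diets = simulate_true_diets(small_config)
        sim = simulate_read_counts(diets, small_config)
        assert (sim.counts_16s.sum(axis=1) == small_config.reads_per_sample).all()

    def test_unbiased_fractions_converge_to_truth(self):
        cfg = SimulationConfig(
            n_samples=5, reads_per_sample=200_000,
            predator_read_fraction=0.0, seed=3,
        )
        diets = simulate_true_diets(cfg)
        sim = simulate_read_counts(diets, cfg)
        fracs = sim.prey_16s.div(sim.prey_16s.sum(axis=1), axis=0)
        truth = true_diet_table(diets, cfg.taxa)
        assert np.abs(fracs - truth).to_numpy().max() < 0.005

    def test_bias_model_closed_form(self):
        # one taxon biased 20x: expected read fraction 20p/(20p + (1-p))
        cfg = SimulationConfig(
            n_samples=1, taxa=("A", "B"), salmonid_taxa=(),
            dirichlet_alpha=(1.0, 1.0), bias_factors={"A": 20.0},
            reads_per_sample=1_000_000, predator_read_fraction=0.0, seed=9,
        )
        diets = simulate_true_diets(cfg)
        p = diets[0].proportions["A"]
        expected = 20 * p / (20 * p + (1 - p))
        sim = simulate_read_counts(diets, cfg)
        observed = sim.counts_16s.loc[diets[0].sample_id, "A"] / 1_000_000
        assert observed == pytest.approx(expected, abs=0.002)

    def test_predator_read_fraction(self):
        cfg = SimulationConfig(
            n_samples=20, reads_per_sample=5000,
            predator_read_fraction=0.5, seed=2,
        )
        sim = simulate_read_counts(simulate_true_diets(cfg), cfg)
        frac = sim.counts_16s[PREDATOR_TAXON].sum() / sim.counts_16s.sum().sum()
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_coi_counts_only_over_salmonids(self, small_config):
        sim = simulate_read_counts(simulate_true_diets(small_config), small_config)
        assert set(sim.counts_coi.columns) == set(small_config.salmonid_taxa)

    def test_empty_diets_error(self, small_config):
        with pytest.raises(ValueError):
            simulate_read_counts([], small_config)


class TestSimulateReads:
    def test_read_counts_match_table(self, small_config):
        counts = pd.DataFrame({"Clupea_pallasii": [10]}, index=["s0"])
        db = synthetic_reference_db(small_config)
        tags = design_tags(10, 5, 1, seed=0)
        reads = simulate_reads(counts, db, tags, small_config)
        assert len(reads) == 10

    def test_missing_reference_names_taxon(self, small_config):
        counts = pd.DataFrame({"Nonexistent_species": [5]}, index=["s0"])
        db = synthetic_reference_db(small_config)
        tags = design_tags(10, 5, 1, seed=0)
        with pytest.raises(ValueError, match="Nonexistent_species"):
            simulate_reads(counts, db, tags, small_config)

    def test_deterministic_under_seed(self, small_config):
        diets = simulate_true_diets(small_config)
        sim = simulate_read_counts(diets, small_config)
        db = synthetic_reference_db(small_config)
        tags = design_tags(10, 5, small_config.n_samples, seed=0)
        r1 = simulate_reads(sim.counts_16s, db, tags, small_config)
        r2 = simulate_reads(sim.counts_16s, db, tags, small_config)
        assert r1 == r2


class TestHardparts:
    def test_detection_prob_one_records_every_consumed_taxon(self, small_config):
        cfg = SimulationConfig(**{**small_config.__dict__,
                                  "hardpart_detection_prob": 1.0})
        diets = simulate_true_diets(cfg)
        records = simulate_hardparts(diets, cfg)
        n_consumed = sum(
            sum(1 for p in d.proportions.values() if p > 0) for d in diets
        )
        assert len(records) == n_consumed

    def test_detection_prob_zero_gives_no_records(self, small_config):
        cfg = SimulationConfig(**{**small_config.__dict__,
                                  "hardpart_detection_prob": 0.0})
        assert simulate_hardparts(simulate_true_diets(cfg), cfg) == []

    def test_juvenile_label_ratio_matches_monthly_probability(self):
        cfg = SimulationConfig(
            n_samples=400, hardpart_detection_prob=1.0,
            juvenile_prob_by_month={m: 0.5 for m in range(1, 13)}, seed=21,
        )
        records = simulate_hardparts(simulate_true_diets(cfg), cfg)
        labels = [r.salmon_classification for r in records
                  if r.salmon_classification is not None]
        juv = sum(1 for x in labels if x == JUVENILE)
        assert juv / len(labels) == pytest.approx(0.5, abs=0.05)

    def test_only_salmonids_get_age_labels(self, small_config):
        cfg = SimulationConfig(**{**small_config.__dict__,
                                  "hardpart_detection_prob": 1.0})
        for r in simulate_hardparts(simulate_true_diets(cfg), cfg):
            is_sal = r.prey_species in cfg.salmonid_taxa
            assert (r.salmon_classification is not None) == is_sal


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_samples": 0},
            {"predator_read_fraction": 1.0},
            {"bias_factors": {"Clupea_pallasii": -1.0}},
            {"salmonid_taxa": ("Not_a_taxon",)},
            {"juvenile_prob_by_month": {13: 0.5}},
            {"error_rate": 1.5},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_metadata_deterministic(self, small_config):
        m1 = simulate_sample_metadata(small_config)
        m2 = simulate_sample_metadata(small_config)
        pd.testing.assert_frame_equal(m1, m2)
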
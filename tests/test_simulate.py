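"""Unit tests for the synthetic study generator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from skbio.tree import TreeNode

from soilcue import (
    SimulationConfig,
    generate_asv_table,
    generate_incubation,
    generate_sites,
    generate_study,
    generate_tree,
    planted_truth,
    process_incubation_table,
)
from soilcue.simulate import generate_latent_chain


class TestConfig:
    def test_site_counts(self):
        assert SimulationConfig(n_sites_per_zone=7).n_sites == 21
        assert SimulationConfig().n_sites == 20  # study split 2/8/10
        assert SimulationConfig().n_sites_per_zone == (2, 8, 10)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_sites_per_zone=0)
        with pytest.raises(ValueError):
            SimulationConfig(cue_gradient=(0.2, 0.35, 1.0))
        with pytest.raises(ValueError):
            SimulationConfig(within_module_rho=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(n_planted_modules=1)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = SimulationConfig(seed=9, noise_sd=0.02)
        path = tmp_path / "cfg.yaml"
        import yaml
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        assert SimulationConfig.from_yaml(path) == cfg


class TestSites:
    def test_zone_labels_and_count(self):
        sites = generate_sites(SimulationConfig(n_sites_per_zone=(2, 8, 10)))
        assert len(sites) == 20
        assert list(sites["zone"]).count("upstream") == 2
        assert list(sites["zone"]).count("downstream") == 10

    def test_deterministic(self):
        cfg = SimulationConfig(seed=4)
        pd.testing.assert_frame_equal(generate_sites(cfg), generate_sites(cfg))

    def test_physicochemical_columns(self):
        sites = generate_sites(SimulationConfig())
        for col in ("pH", "SWC", "TC", "TN", "TP", "SOC", "Cond"):
            assert (sites[col] > 0).all()


class TestIncubation:
    def test_roundtrip_identity_noise_free(self, noise_free_study):
        eff = process_incubation_table(noise_free_study.incubation)
        truth = noise_free_study.truth["metabolic"]
        for col in ("cue", "mbc", "qco2", "tau"):
            rel = np.abs(eff[col] - truth[col]) / truth[col]
            assert rel.max() < 1e-9

    def test_zone_means_ordered_noise_free(self, noise_free_study):
        eff = process_incubation_table(noise_free_study.incubation)
        truth = noise_free_study.truth["metabolic"]
        means = eff.join(truth["zone"]).groupby("zone")["cue"].mean()
        assert means["upstream"] < means["midstream"] < means["downstream"]

    def test_labeled_atom_pct_dominates_noise_free(self, noise_free_study):
        inc = noise_free_study.incubation
        for k in (1, 2, 3):
            assert (inc[f"atom_pct_labeled_{k}"]
                    >= inc[f"atom_pct_natural_{k}"]).all()

    def test_deterministic(self):
        cfg = SimulationConfig(seed=2, noise_sd=0.05)
        pd.testing.assert_frame_equal(
            generate_incubation(None, cfg), generate_incubation(None, cfg))


class TestASVTable:
    def test_partition_block_count_and_cover(self):
        cfg = SimulationConfig(n_planted_modules=5, n_asvs_bacteria=50)
        table, taxonomy, truth = generate_asv_table(cfg)
        assert len(set(truth.values())) == 5
        assert set(truth) == set(table.columns)  # covers every ASV once
        assert set(taxonomy.index) == set(table.columns)

    def test_counts_nonnegative_integers(self):
        table, _, _ = generate_asv_table(SimulationConfig(seed=3))
        assert (table.to_numpy() >= 0).all()
        assert np.issubdtype(table.dtypes.iloc[0], np.integer)

    def test_full_correlation_at_rho_one(self):
        cfg = SimulationConfig(within_module_rho=1.0, noise_sd=0.0,
                               n_asvs_bacteria=20, n_planted_modules=2,
                               n_sites_per_zone=10, seed=1)
        table, _, truth = generate_asv_table(cfg)
        mod0 = [a for a, m in truth.items() if m == "Truth#0"][:5]
        for a in mod0[1:]:
            r = stats.spearmanr(table[mod0[0]], table[a]).statistic
            # exact rank agreement up to integer-rounding ties
            assert r >= 0.99

    def test_uncorrelated_at_rho_zero(self):
        rs = []
        for seed in range(5):
            cfg = SimulationConfig(within_module_rho=0.0, n_asvs_bacteria=30,
                                   n_sites_per_zone=10, seed=seed)
            table, _, truth = generate_asv_table(cfg)
            mod0 = [a for a, m in truth.items() if m == "Truth#0"][:4]
            for i in range(len(mod0)):
                for j in range(i + 1, len(mod0)):
                    rs.append(stats.spearmanr(table[mod0[i]],
                                              table[mod0[j]]).statistic)
        assert abs(np.mean(rs)) < 0.15  # centered on zero

    def test_taxonomy_from_dominant_phyla(self):
        _, taxonomy, _ = generate_asv_table(SimulationConfig(), "fungi")
        assert taxonomy.str.contains("Ascomycota").any()
        assert taxonomy.str.startswith("k__Fungi").all()


class TestTree:
    def test_two_leaves(self):
        nwk = generate_tree(["A", "B"], seed=1)
        tree = TreeNode.read([nwk], convert_underscores=False)
        assert {t.name for t in tree.tips()} == {"A", "B"}

    def test_leaf_set_matches_input(self):
        ids = [f"B_ASV{i:03d}" for i in range(12)]
        tree = TreeNode.read([generate_tree(ids, seed=5)],
                             convert_underscores=False)
        assert {t.name for t in tree.tips()} == set(ids)
        for node in tree.traverse(include_self=False):
            assert node.length > 0

    def test_deterministic_newick(self):
        ids = list("ABCDEFG")
        assert generate_tree(ids, seed=9) == generate_tree(ids, seed=9)
        assert generate_tree(ids, seed=9) != generate_tree(ids, seed=10)

    def test_single_leaf_rejected(self):
        with pytest.raises(ValueError):
            generate_tree(["A"], seed=0)


class TestStudy:
    def test_same_seed_identical(self):
        cfg = SimulationConfig(seed=6, n_asvs_bacteria=20, n_asvs_fungi=15)
        s1, s2 = generate_study(cfg), generate_study(cfg)
        pd.testing.assert_frame_equal(s1.incubation, s2.incubation)
        pd.testing.assert_frame_equal(s1.asv_bacteria, s2.asv_bacteria)
        assert s1.tree_bacteria == s2.tree_bacteria

    def test_truth_partition_total(self, default_study):
        part = default_study.truth["partition_bacteria"]
        assert set(part) == set(default_study.asv_bacteria.columns)

    def test_planted_cue_within_unit_interval(self):
        truth = planted_truth(SimulationConfig(seed=8))
        assert ((truth["cue"] > 0) & (truth["cue"] < 1)).all()

    def test_enzyme_efficiency_link_negative(self):
        """The planted enzyme→efficiency path surfaces as a negative
        correlation between the enzyme index and CUE residuals."""
        from soilcue import enzyme_activity_index
        cfg = SimulationConfig(n_sites_per_zone=40, seed=3)
        study = generate_study(cfg)
        idx = enzyme_activity_index(study.enzymes)
        truth = study.truth["metabolic"]
        resid = truth["cue"] - truth.groupby("zone")["cue"].transform("mean")
        r = stats.spearmanr(idx, resid).statistic
        assert r < -0.3


def test_latent_chain_unit_variance_and_beta():
    """Generated latents have ~unit variance and the planted covariance."""
    betas = {("soil", "diversity"): 0.5, ("diversity", "enzymes"): 0.45,
             ("enzymes", "efficiency"): -0.65}
    lat = generate_latent_chain(20_000, betas, np.random.default_rng(0))
    assert lat.std().between(0.97, 1.03).all()
    r = np.corrcoef(lat["enzymes"], lat["efficiency"])[0, 1]
    assert r == pytest.approx(-0.65, abs=0.03)
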
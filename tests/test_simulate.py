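"""Simulator: determinism, JC site statistics, gene turnover, truth plumbing."""

import math

import numpy as np
import pytest

from taxodelim.simulate import (
    SimulationConfig,
    evolve_sequence,
    expected_identity,
    distance_for_identity,
    generate_ancestor,
    planted_two_genus_config,
    simulate_clade,
)


class TestAncestor:
    def test_deterministic_under_fixed_seed(self):
        cfg = SimulationConfig(seed=1, n_genes=50)
        a1 = generate_ancestor(cfg)
        a2 = generate_ancestor(cfg)
        assert a1.genes == a2.genes
        assert a1.markers == a2.markers
        assert a1.marker_spacers == a2.marker_spacers

    def test_seed_sensitivity(self):
        a1 = generate_ancestor(SimulationConfig(seed=1, n_genes=10))
        a2 = generate_ancestor(SimulationConfig(seed=2, n_genes=10))
        assert a1.genes != a2.genes

    def test_zero_genes_still_emits_markers(self):
        a = generate_ancestor(SimulationConfig(seed=0, n_genes=0))
        assert a.genes == []
        assert set(a.markers) == {"16S", "gyrB", "rpoB", "rpoD"}
        assert len(a.markers["16S"]) == 1300

    def test_gene_structure(self):
        a = generate_ancestor(SimulationConfig(seed=3, n_genes=30))
        stops = {"TAA", "TAG", "TGA"}
        for _, gene, spacer in a.genes:
            assert len(gene) % 3 == 0
            assert gene.startswith("ATG")
            assert gene[-3:] in stops
            codons = [gene[i : i + 3] for i in range(0, len(gene) - 3, 3)]
            assert not any(c in stops for c in codons)
            assert len(spacer) == 50

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"gene_length_codons": (1, 1, 1)},
            {"n_genes": -1},
            {"gene_loss_prob_per_unit_branch": 1.5},
            {"gene_gain_rate_per_unit_branch": -0.1},
            {"marker_lengths": {"16S": 1300}},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestEvolveSequence:
    def test_zero_branch_is_identity(self, rng):
        seq = "ACGT" * 500
        assert evolve_sequence(seq, 0.0, 1.0, rng) == seq

    def test_negative_branch_rejected(self, rng):
        with pytest.raises(ValueError):
            evolve_sequence("ACGT", -0.1, 1.0, rng)

    def test_mismatch_fraction_matches_jc_closed_form(self, rng):
        # p(0.1) = (3/4)(1 - exp(-0.4/3)) = 0.090636...
        L = 100_000
        seq = "".join(rng.choice(list("ACGT"), L))
        out = evolve_sequence(seq, 0.1, 1.0, rng)
        frac = sum(a != b for a, b in zip(seq, out)) / L
        p = 0.75 * (1 - math.exp(-0.4 / 3))
        se = math.sqrt(p * (1 - p) / L)
        assert abs(frac - p) < 3 * se

    def test_saturation_limit(self, rng):
        L = 30_000
        seq = "".join(rng.choice(list("ACGT"), L))
        out = evolve_sequence(seq, 50.0, 1.0, rng)
        frac = sum(a != b for a, b in zip(seq, out)) / L
        assert abs(frac - 0.75) < 0.01

    def test_rate_multiplier_scales_divergence(self, rng):
        L = 50_000
        seq = "".join(rng.choice(list("ACGT"), L))
        slow = evolve_sequence(seq, 0.2, 0.1, np.random.default_rng(0))
        fast = evolve_sequence(seq, 0.2, 1.0, np.random.default_rng(0))
        p_slow = sum(a != b for a, b in zip(seq, slow)) / L
        p_fast = sum(a != b for a, b in zip(seq, fast)) / L
        assert p_slow < p_fast / 3

    def test_coding_mode_never_creates_internal_stops(self):
        gene = generate_ancestor(SimulationConfig(seed=5, n_genes=1)).genes[0][1]
        stops = {"TAA", "TAG", "TGA"}
        for s in range(10):
            out = evolve_sequence(gene, 0.4, 1.0, np.random.default_rng(s), coding=True)
            codons = [out[i : i + 3] for i in range(0, len(out) - 3, 3)]
            assert not any(c in stops for c in codons)


class TestClosedForms:
    def test_expected_identity_values(self):
        assert expected_identity(0.0) == 1.0
        assert expected_identity(math.inf) == pytest.approx(0.25)
        assert expected_identity(0.1) == pytest.approx(0.9064, abs=1e-4)

    def test_identity_distance_inverse(self):
        for d in (0.001, 0.05, 0.3, 1.5):
            assert distance_for_identity(expected_identity(d)) == pytest.approx(d)


class TestEvolveClade:
    def test_determinism(self):
        cfg = SimulationConfig(seed=11, n_genes=20, tree="(A:0.02,B:0.03);",
                               gene_loss_prob_per_unit_branch=0.3,
                               gene_gain_rate_per_unit_branch=2.0)
        c1 = simulate_clade(cfg)
        c2 = simulate_clade(cfg)
        assert c1.genomes == c2.genomes
        assert c1.proteomes == c2.proteomes

    def test_zero_distance_pair_identical(self):
        cfg = SimulationConfig(seed=2, n_genes=10, tree="(A:0.0,B:0.0);")
        c = simulate_clade(cfg)
        assert c.genomes["A"] == c.genomes["B"]

    def test_gene_conservation_without_turnover(self):
        cfg = SimulationConfig(seed=2, n_genes=25, tree="(A:0.1,(B:0.1,C:0.1):0.1);")
        c = simulate_clade(cfg)
        for leaf in c.leaves():
            assert len(c.gene_ids[leaf]) == 25
            assert c.markers[leaf].is_complete()

    def test_marker_persistence_under_total_gene_loss(self):
        cfg = SimulationConfig(seed=4, n_genes=10, tree="(A:1.0,B:1.0);",
                               gene_loss_prob_per_unit_branch=1.0)
        c = simulate_clade(cfg)
        for leaf in ("A", "B"):
            assert c.gene_ids[leaf] == []
            assert c.markers[leaf].is_complete()
            # genome still holds the four markers and their spacers
            assert len(c.genomes[leaf]) == 1300 + 800 + 900 + 750 + 4 * 50

    def test_star_tree_path_additivity(self):
        cfg = SimulationConfig(
            seed=0, n_genes=2, tree="(A:0.02,B:0.02,C:0.02,D:0.02);"
        )
        c = simulate_clade(cfg)
        for (a, b), d in c.truth_distances.items():
            assert d == pytest.approx(0.04)

    def test_duplicate_leaf_labels_rejected(self):
        cfg = SimulationConfig(seed=0, n_genes=2, tree="(A:0.1,A:0.1);")
        with pytest.raises(ValueError):
            simulate_clade(cfg)

    def test_pairwise_identity_calibrated_to_expected_identity(self):
        # colinear 10-kb-scale genomes, uniform rates: site identity must sit
        # within 3 Monte-Carlo SE of the JC closed form
        d = 0.08
        cfg = SimulationConfig(
            seed=9, n_genes=30,
            tree=f"(A:{d / 2},B:{d / 2});",
            marker_rate_multipliers={"16S": 1.0, "gyrB": 1.0, "rpoB": 1.0, "rpoD": 1.0},
        )
        c = simulate_clade(cfg)
        ga, gb = c.genomes["A"], c.genomes["B"]
        assert len(ga) == len(gb)
        ident = sum(a == b for a, b in zip(ga, gb)) / len(ga)
        expected = expected_identity(d)
        se = math.sqrt(expected * (1 - expected) / len(ga))
        assert abs(ident - expected) < 3 * se


class TestPlantedFixture:
    def test_truth_partition_covers_and_nests(self):
        cfg = planted_two_genus_config()
        leaves = None
        for rank in ("genus", "species", "subspecies"):
            assign = cfg.truth_partition[rank]
            if leaves is None:
                leaves = set(assign)
            assert set(assign) == leaves
        assert len(leaves) == 15
        # subspecies nest inside species, species inside genera
        sp = cfg.truth_partition["species"]
        ss = cfg.truth_partition["subspecies"]
        gn = cfg.truth_partition["genus"]
        for a in leaves:
            for b in leaves:
                if ss[a] == ss[b]:
                    assert sp[a] == sp[b]
                if sp[a] == sp[b]:
                    assert gn[a] == gn[b]

    def test_planted_clade_structure(self, planted_clade):
        assert len(planted_clade.leaves()) == 15
        for leaf in planted_clade.leaves():
            assert planted_clade.markers[leaf].is_complete()
            assert len(planted_clade.gene_ids[leaf]) > 0
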
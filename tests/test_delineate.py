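"""Decision engine: pair verdicts, clustering, synonymy, genus calls,
concordance.  The worked examples mirror published *Pseudomonas* practice
(ANIb 97.91 / MLSA 99.6 synonym pairs, dDDH 74 vs 80/81 subspecies bounds,
POCP 45/50/60 genus calls, 16S 92.2 exclusion)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from taxodelim.delineate import (
    PairMeasure,
    StrainMeta,
    TaxonomicPartition,
    Thresholds,
    assign_genus,
    cluster_at_threshold,
    concordance_report,
    delineate_subspecies,
    detect_synonyms,
    pair_species_call,
)
from taxodelim.matrix import DistanceMatrix


def _pm(**kw):
    return PairMeasure("s1", "s2", **kw)


def _percent(labels, pairs, default=np.nan):
    n = len(labels)
    vals = np.full((n, n), default, dtype=float)
    np.fill_diagonal(vals, 100.0)
    idx = {l: i for i, l in enumerate(labels)}
    for (a, b), v in pairs.items():
        vals[idx[a], idx[b]] = vals[idx[b], idx[a]] = v
    return DistanceMatrix(labels, vals, "percent")


class TestPairSpeciesCall:
    def test_genomic_confirmation_of_mlsa_candidate(self):
        # a type-strain pair with ANIb 97.91 and MLSA 99.6 is one species
        v = pair_species_call(_pm(anib_pct=97.91, mlsa_pct=99.6))
        assert v.verdict == "same"
        assert any("ANIb" in e for e in v.evidence)
        assert not v.conflicts

    def test_low_16s_alone_excludes(self):
        v = pair_species_call(_pm(rrna_pct=92.2))
        assert v.verdict == "different"

    def test_high_16s_alone_is_inconclusive(self):
        v = pair_species_call(_pm(rrna_pct=99.0))
        assert v.verdict == "inconclusive"

    def test_no_metrics_is_an_error(self):
        with pytest.raises(ValueError):
            pair_species_call(_pm())

    def test_ddh_alone_is_sufficient(self):
        assert pair_species_call(
            _pm(ddh_pct=74.0, ddh_provenance="external")
        ).verdict == "same"
        assert pair_species_call(
            _pm(ddh_pct=55.0, ddh_provenance="external")
        ).verdict == "different"

    def test_mlsa_only_is_flagged(self):
        v = pair_species_call(_pm(mlsa_pct=98.0))
        assert v.verdict == "same"
        assert any("MLSA-only" in e for e in v.evidence)

    def test_genomic_metrics_override_mlsa_conflict(self):
        v = pair_species_call(_pm(mlsa_pct=97.5, anib_pct=93.0))
        assert v.verdict == "different"
        assert any("precedence" in c for c in v.conflicts)

    def test_boundaries_are_inclusive(self):
        assert pair_species_call(_pm(anib_pct=95.0)).verdict == "same"
        assert pair_species_call(_pm(mlsa_pct=97.0)).verdict == "same"
        assert pair_species_call(
            _pm(ddh_pct=70.0, ddh_provenance="surrogate")
        ).verdict == "same"

    def test_ddh_requires_provenance(self):
        with pytest.raises(ValueError, match="provenance"):
            _pm(ddh_pct=80.0)


class TestClusterAtThreshold:
    def test_all_high_is_one_cluster(self):
        dm = _percent(list("ABC"), {("A", "B"): 100, ("B", "C"): 100, ("A", "C"): 100})
        part = cluster_at_threshold(dm, 95)
        assert part.clusters == [frozenset("ABC")]

    def test_single_linkage_chains(self):
        dm = _percent(list("ABC"), {("A", "B"): 96, ("B", "C"): 96, ("A", "C"): 80})
        part = cluster_at_threshold(dm, 95)
        assert part.clusters == [frozenset("ABC")]

    def test_complete_linkage_does_not_chain(self):
        dm = _percent(list("ABC"), {("A", "B"): 96, ("B", "C"): 96, ("A", "C"): 80})
        part = cluster_at_threshold(dm, 95, linkage="complete")
        assert len(part.clusters) == 2

    def test_missing_pairs_require_opt_in(self):
        dm = _percent(list("ABC"), {("A", "B"): 96})
        with pytest.raises(ValueError, match="missing"):
            cluster_at_threshold(dm, 95)
        with pytest.warns(UserWarning, match="below the cutoff"):
            part = cluster_at_threshold(dm, 95, allow_missing=True)
        assert part.clusters == [frozenset("AB"), frozenset("C")]

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_raising_the_cutoff_only_refines(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"s{i}" for i in range(6)]
        vals = rng.uniform(50, 100, size=(6, 6))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 100.0)
        dm = DistanceMatrix(labels, vals, "percent")
        low = cluster_at_threshold(dm, 70)
        high = cluster_at_threshold(dm, 90)
        for hc in high.clusters:
            assert any(hc <= lc for lc in low.clusters)


class TestSubspecies:
    def test_ddh_74_splits_but_81_joins(self):
        # dDDH 74 between type strains: same species, different subspecies;
        # 81 and 80 keep subspecies together
        dm = _percent(
            ["pisc", "aureo", "auran", "chlor"],
            {
                ("pisc", "aureo"): 74,
                ("pisc", "auran"): 81,
                ("pisc", "chlor"): 80,
                ("aureo", "auran"): 74,
                ("aureo", "chlor"): 74,
                ("auran", "chlor"): 79,
            },
        )
        part = delineate_subspecies({"pisc", "aureo", "auran", "chlor"}, dm)
        assert part.rank == "subspecies"
        mapping = part.mapping()
        assert mapping["pisc"] == mapping["auran"] == mapping["chlor"]
        assert mapping["aureo"] != mapping["pisc"]

    def test_all_above_80_is_one_subspecies(self):
        dm = _percent(list("AB"), {("A", "B"): 85})
        part = delineate_subspecies({"A", "B"}, dm)
        assert part.clusters == [frozenset("AB")]

    def test_strains_outside_matrix_rejected(self):
        dm = _percent(list("AB"), {("A", "B"): 85})
        with pytest.raises(ValueError, match="outside"):
            delineate_subspecies({"A", "Z"}, dm)


class TestSynonyms:
    def _meta(self, *rows):
        return [StrainMeta(*r) for r in rows]

    def test_later_name_is_junior_synonym(self):
        part = TaxonomicPartition("species", [frozenset({"oryz", "psyc"})], "test")
        meta = self._meta(
            ("oryz", "P. oryzihabitans", True, 1985),
            ("psyc", "P. psychrophila", True, 2002),
        )
        table = detect_synonyms(part, meta)
        assert len(table) == 1
        row = table.iloc[0]
        assert row.senior_name == "P. oryzihabitans"
        assert row.junior_name == "P. psychrophila"
        assert "later heterotypic synonym of P. oryzihabitans" == row.status

    def test_four_member_cluster_gives_three_rows_with_one_senior(self):
        part = TaxonomicPartition(
            "species", [frozenset({"ficu", "meli", "sava", "amyg"})], "test"
        )
        meta = self._meta(
            ("ficu", "P. ficuserectae", True, 1985),
            ("meli", "P. meliae", True, 1984),
            ("sava", "P. savastanoi", True, 1982),
            ("amyg", "P. amygdali", True, 1978),
        )
        table = detect_synonyms(part, meta)
        assert len(table) == 3
        assert set(table.senior_name) == {"P. amygdali"}
        assert "P. amygdali" not in set(table.junior_name)

    def test_single_type_strain_cluster_has_no_rows(self):
        part = TaxonomicPartition(
            "species", [frozenset({"a", "b"}), frozenset({"c"})], "test"
        )
        meta = self._meta(
            ("a", "X. alpha", True, 1990),
            ("b", "X. beta", False, None),
            ("c", "X. gamma", True, 2001),
        )
        assert detect_synonyms(part, meta).empty

    def test_missing_year_on_type_strain_is_an_error(self):
        part = TaxonomicPartition("species", [frozenset({"a", "b"})], "test")
        meta = self._meta(("a", "X. alpha", True, None), ("b", "X. beta", True, 1999))
        with pytest.raises(ValueError, match="year"):
            detect_synonyms(part, meta)

    def test_year_tie_is_flagged_and_broken_alphabetically(self):
        part = TaxonomicPartition("species", [frozenset({"a", "b"})], "test")
        meta = self._meta(("a", "X. beta", True, 1999), ("b", "X. alpha", True, 1999))
        table = detect_synonyms(part, meta)
        assert table.iloc[0].senior_name == "X. alpha"
        assert bool(table.iloc[0].priority_tie)


class TestGenus:
    def test_pocp_45_separates_but_60_joins(self):
        # POCP 60 joins the genus; 45 falls below the 50% cutoff
        dm = _percent(
            ["aeru", "fluo", "azot"],
            {("aeru", "fluo"): 60, ("aeru", "azot"): 45, ("fluo", "azot"): 42},
        )
        part, borderline = assign_genus(dm)
        mapping = part.mapping()
        assert mapping["aeru"] == mapping["fluo"]
        assert mapping["azot"] != mapping["aeru"]

    def test_exactly_50_is_same_genus_but_borderline(self):
        dm = _percent(["aeru", "puti"], {("aeru", "puti"): 50})
        part, borderline = assign_genus(dm)
        assert part.clusters == [frozenset({"aeru", "puti"})]
        assert borderline == [("aeru", "puti", 50.0)]

    def test_16s_gate_can_block_a_pocp_edge(self):
        pocp = _percent(["a", "b"], {("a", "b"): 60})
        rrna = _percent(["a", "b"], {("a", "b"): 93.0})  # < 94.5
        part, _ = assign_genus(pocp, rrna)
        assert len(part.clusters) == 2

    def test_incomplete_matrix_rejected(self):
        dm = _percent(list("ABC"), {("A", "B"): 60})
        with pytest.raises(ValueError, match="incomplete"):
            assign_genus(dm)


class TestConcordance:
    def test_identical_partitions_agree_fully(self):
        p = TaxonomicPartition("species", [frozenset("AB"), frozenset("CD")], "x")
        q = TaxonomicPartition("species", [frozenset("AB"), frozenset("CD")], "y")
        summary, dis = concordance_report({"m1": p, "m2": q})
        assert summary.agreement.tolist() == [1.0]
        assert dis.empty

    def test_one_merge_disagreement_over_six_pairs(self):
        merged = TaxonomicPartition(
            "species", [frozenset("AB"), frozenset("C"), frozenset("D")], "x"
        )
        singles = TaxonomicPartition(
            "species", [frozenset(s) for s in "ABCD"], "y"
        )
        summary, dis = concordance_report({"m": merged, "s": singles})
        assert summary.iloc[0].agreement == pytest.approx(5 / 6)
        assert len(dis) == 1
        assert dis.iloc[0].merged_by == "m"

    def test_different_strain_sets_rejected(self):
        p = TaxonomicPartition("species", [frozenset("AB")], "x")
        q = TaxonomicPartition("species", [frozenset("AC")], "y")
        with pytest.raises(ValueError, match="different strain sets"):
            concordance_report({"p": p, "q": q})


class TestPartitionContainer:
    def test_overlapping_clusters_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            TaxonomicPartition("species", [frozenset("AB"), frozenset("BC")], "x")

    def test_tsv_round_trip(self, tmp_path):
        part = TaxonomicPartition(
            "genus", [frozenset({"a", "b"}), frozenset({"c"})], "POCP >= 50"
        )
        path = tmp_path / "part.tsv"
        part.to_tsv(path)
        back = TaxonomicPartition.from_tsv(path)
        assert back.rank == "genus"
        assert back.cluster_sets() == part.cluster_sets()

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            Thresholds(ddh_subspecies=60.0)  # below ddh_species
        with pytest.raises(ValueError):
            Thresholds(anib_species=0.0)
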
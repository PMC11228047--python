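import numpy as np
import pytest

from holotag.database import (
    RANKS,
    TaxonomyTable,
    build_host_tagset,
    build_marker_db,
    db_summary,
    load_holodb,
    merge_holodb,
    save_holodb,
)
from holotag.enzyme import canonicalize, extract_tags, revcomp
from holotag.simulate import SimConfig, simulate_genomes

from conftest import simple_taxonomy

# 8-bp tags for the toy enzyme (recognition ACGT at offset 2)
T1 = "TTACGTGG"   # canonical CCACGTAA
T2 = "GGACGTAA"   # canonical itself
T3 = "AAACGTTT"   # palindromic
T4 = "GAACGTGA"   # canonical itself


def genome(*tags: str) -> str:
    return "CC" + "CC".join(tags) + "CC"


class TestHostTagSet:
    def test_three_sites_two_distinct_one_unique(self, toy):
        hs = build_host_tagset([("chr1", genome(T1, T2, T1))], toy)
        assert len(hs.all_loci) == 3
        assert hs.distinct == {canonicalize(T1), canonicalize(T2)}
        assert hs.unique == {canonicalize(T2)}

    def test_no_sites(self, toy):
        hs = build_host_tagset([("chr1", "CCCCCCCCCC")], toy)
        assert hs.all_loci == [] and hs.distinct == set() and hs.unique == set()

    def test_strand_identity_across_revcomp(self, toy):
        s = genome(T1)
        hs = build_host_tagset([("chr1", s + revcomp(s))], toy)
        assert len(hs.distinct) == 1
        assert hs.unique == set()

    def test_empty_genome_rejected(self, toy):
        with pytest.raises(ValueError):
            build_host_tagset([], toy)

    def test_multi_record(self, toy):
        hs = build_host_tagset([("c1", genome(T1)), ("c2", genome(T2))], toy)
        assert hs.unique == {canonicalize(T1), canonicalize(T2)}


class TestMarkerDB:
    def test_species_markers_basic(self, toy):
        genomes = {"g1": [("g1", genome(T1))], "g2": [("g2", genome(T1))],
                   "g3": [("g3", genome(T2))]}
        tax = simple_taxonomy({"g1": "a", "g2": "a", "g3": "b"})
        db = build_marker_db(genomes, tax, toy)
        assert db.markers == {canonicalize(T1): "a", canonicalize(T2): "b"}
        assert db.theoretical_markers("a") == 1

    def test_multicopy_tag_excluded(self, toy):
        genomes = {"g1": [("g1", genome(T1, T1))]}
        tax = simple_taxonomy({"g1": "a"})
        db = build_marker_db(genomes, tax, toy)
        assert canonicalize(T1) not in db.markers

    def test_rank_switch_recovers_genus_marker(self, toy):
        genomes = {"g1": [("g1", genome(T1))], "g3": [("g3", genome(T1))]}
        tax = simple_taxonomy({"g1": "a", "g3": "b"},
                              genus_of={"a": "G", "b": "G"})
        at_species = build_marker_db(genomes, tax, toy, rank="species")
        assert canonicalize(T1) not in at_species.markers
        at_genus = build_marker_db(genomes, tax, toy, rank="genus")
        assert at_genus.markers == {canonicalize(T1): "G"}

    def test_missing_taxonomy_names_genome(self, toy):
        with pytest.raises(ValueError, match="g9"):
            build_marker_db({"g9": [("g9", genome(T1))]},
                            simple_taxonomy({}), toy)

    def test_order_invariance(self, toy):
        genomes = {"g1": [("g1", genome(T1, T3))], "g2": [("g2", genome(T2))],
                   "g3": [("g3", genome(T3))]}
        tax = simple_taxonomy({"g1": "a", "g2": "b", "g3": "c"})
        fwd = build_marker_db(genomes, tax, toy)
        rev = build_marker_db(dict(reversed(list(genomes.items()))), tax, toy)
        assert fwd.markers == rev.markers


def brute_force_markers(genomes, tax, enz, rank="species"):
    """Independent oracle: hash every tag of every genome, apply the definition."""
    from collections import Counter

    per = {
        gid: Counter(
            t.canonical for rid, seq in recs for t in extract_tags(seq, enz, rid)
        )
        for gid, recs in genomes.items()
    }
    markers = {}
    for tag in set().union(*per.values()) if per else set():
        carriers = [g for g in per if tag in per[g]]
        if any(per[g][tag] != 1 for g in carriers):
            continue
        taxa = {tax.taxon(g, rank) for g in carriers}
        if len(taxa) == 1:
            markers[tag] = taxa.pop()
    return markers


class TestMarkerOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equivalence_with_brute_force(self, seed):
        cfg = SimConfig(seed=seed, n_species=6, genomes_per_species=2,
                        sites_per_genome=6, genome_length=3000,
                        cross_species_shared=3, host_sites=10, host_snps=0,
                        host_length=8000)
        truth = simulate_genomes(cfg)
        genomes = {g: [(g, s)] for g, s in truth.genomes.items()}
        db = build_marker_db(genomes, truth.taxonomy, cfg.enzyme)
        assert db.markers == brute_force_markers(genomes, truth.taxonomy, cfg.enzyme)

    def test_planted_recovery(self):
        cfg = SimConfig(seed=5, n_species=5, sites_per_genome=8,
                        cross_species_shared=2, host_sites=10, host_snps=0,
                        host_length=8000)
        truth = simulate_genomes(cfg)
        genomes = {g: [(g, s)] for g, s in truth.genomes.items()}
        db = build_marker_db(genomes, truth.taxonomy, cfg.enzyme)
        for sp, tags in truth.species_markers.items():
            for tag in tags:
                assert db.markers.get(tag) == sp
        for tag in truth.shared_cross:
            assert tag not in db.markers


class TestMerge:
    def _parts(self, toy, host_seq, genomes, species):
        host = build_host_tagset([("h", host_seq)], toy)
        tax = simple_taxonomy(species)
        mdb = build_marker_db(genomes, tax, toy)
        return host, mdb

    def test_shared_sole_marker_removes_genome(self, toy):
        host, mdb = self._parts(
            toy, genome(T2, T3),
            {"g1": [("g1", genome(T1))], "g3": [("g3", genome(T2))]},
            {"g1": "a", "g3": "b"},
        )
        db = merge_holodb(host, mdb)
        rep = db.report
        assert rep.host_tags_removed == 1
        assert rep.host_fraction == pytest.approx(1 / 2)
        assert rep.genomes_removed == 1
        assert rep.rank_affected["species"][0] == 1
        assert rep.rank_removed["species"][0] == 1
        assert canonicalize(T2) not in db.host_tags
        assert canonicalize(T2) not in db.markers
        assert not (db.host_tags & set(db.markers))

    def test_no_overlap_all_zero(self, toy):
        host, mdb = self._parts(
            toy, genome(T3),
            {"g1": [("g1", genome(T1))], "g3": [("g3", genome(T2))]},
            {"g1": "a", "g3": "b"},
        )
        db = merge_holodb(host, mdb)
        rep = db.report
        assert rep.host_tags_removed == 0 and rep.genomes_removed == 0
        assert all(v == (0, 0.0) for v in rep.rank_affected.values())
        assert db.host_tags == host.unique
        assert set(db.markers) == set(mdb.markers)

    def test_one_of_many_markers_affected_not_removed(self, toy):
        host, mdb = self._parts(
            toy, genome(T1, T3),
            {"g1": [("g1", genome(T1, T2))]},
            {"g1": "a"},
        )
        db = merge_holodb(host, mdb)
        rep = db.report
        assert rep.host_tags_removed == 1
        assert rep.genomes_removed == 0
        assert rep.rank_affected["species"] == (1, 1.0)
        assert rep.rank_removed["species"][0] == 0

    def test_enzyme_mismatch_rejected(self, toy, toy_degenerate):
        host = build_host_tagset([("h", genome(T3))], toy)
        mdb = build_marker_db({"g1": [("g1", "C" + T1 + "C")]},
                              simple_taxonomy({"g1": "a"}), toy_degenerate)
        with pytest.raises(ValueError, match="enzyme"):
            merge_holodb(host, mdb)

    def test_affected_monotone_in_rank(self, toy):
        # invariant: taxa-removed <= taxa-affected at every rank
        host, mdb = self._parts(
            toy, genome(T1, T2, T3),
            {"g1": [("g1", genome(T1))], "g2": [("g2", genome(T2))],
             "g3": [("g3", genome(T4))]},
            {"g1": "a", "g2": "b", "g3": "c"},
        )
        rep = merge_holodb(host, mdb).report
        for rk in RANKS:
            assert rep.rank_removed[rk][0] <= rep.rank_affected[rk][0]
            assert 0.0 <= rep.rank_affected[rk][1] <= 1.0


class TestSummaryAndSerialization:
    def test_summary_mean_tags(self, toy):
        genomes = {"g1": [("g1", genome(T1))], "g2": [("g2", genome(T2))],
                   "g3": [("g3", genome(T3, T4))]}
        tax = simple_taxonomy({"g1": "a", "g2": "b", "g3": "c"})
        host = build_host_tagset([("h", genome("GTACGTCA"))], toy)
        db = merge_holodb(host, build_marker_db(genomes, tax, toy))
        summary = db_summary(db)
        assert summary["mean_tags_per_genome"] == pytest.approx(4 / 3)
        assert summary["single_copy_fraction"] == pytest.approx(1.0)
        species_row = [r for r in summary["rank_table"] if r["rank"] == "species"][0]
        assert species_row["taxa_with_markers"] == 3

    def test_empty_microbial_set(self, toy):
        host = build_host_tagset([("h", genome(T1))], toy)
        db = merge_holodb(host, build_marker_db({}, simple_taxonomy({}), toy))
        summary = db_summary(db)
        assert summary["species_markers"] == 0
        assert summary["mean_tags_per_genome"] == 0.0

    def test_save_load_roundtrip(self, toy, tmp_path):
        genomes = {"g1": [("g1", genome(T1))], "g3": [("g3", genome(T2))]}
        tax = simple_taxonomy({"g1": "a", "g3": "b"})
        host = build_host_tagset([("h", genome(T3, T2))], toy)
        db = merge_holodb(host, build_marker_db(genomes, tax, toy))
        save_holodb(db, tmp_path / "db")
        back = load_holodb(tmp_path / "db")
        assert back.host_tags == db.host_tags
        assert back.markers == db.markers
        assert back.enzyme == db.enzyme
        assert back.report.host_tags_removed == db.report.host_tags_removed

    def test_load_missing_db_names_build_command(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="build-db"):
            load_holodb(tmp_path / "nodb")


class TestTaxonomyTable:
    def test_tsv_roundtrip(self, tmp_path):
        tax = simple_taxonomy({"g1": "a", "g2": "b"})
        tax.to_tsv(tmp_path / "tax.tsv")
        back = TaxonomyTable.from_tsv(tmp_path / "tax.tsv")
        assert back.lineage("g1") == tax.lineage("g1")

    def test_incomplete_lineage_rejected(self):
        with pytest.raises(ValueError):
            TaxonomyTable({"g1": ("Bacteria", "p", "c")})
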
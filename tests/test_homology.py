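"""Shared-domain homolog detection and group-based homolog extraction."""

import io

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trophomine.homology import (
    HomologyMap,
    build_pfam_map,
    homologene_pairs,
    merge_homology,
    pfam_homologs,
)
from trophomine.io_formats import HomologGroupTable, ProteinRecord


def protein(accession, species, domains, name=None):
    return ProteinRecord(
        accession=accession,
        entry_name=f"{accession}_X",
        species=species,
        primary_name=name or accession,
        pfam_domains=frozenset(domains),
    )


def group_table(rows):
    return HomologGroupTable(
        pd.DataFrame(rows, columns=["group_id", "species", "gene_symbol", "accession"])
    )


class TestPfamHomologs:
    def test_single_shared_domain_matches(self):
        bovine = protein("ACOD_B", "bovine", {"PF00487"})
        human = protein("H1", "human", {"PF00487"})
        assert pfam_homologs(bovine, [human]) == {"H1"}

    def test_candidate_missing_a_domain_no_match(self):
        bovine = protein("B1", "bovine", {"PF1", "PF2"})
        assert pfam_homologs(bovine, [protein("H1", "human", {"PF1"})]) == set()

    def test_superset_matches_by_default_but_not_in_strict_mode(self):
        bovine = protein("B1", "bovine", {"PF1"})
        cand = protein("H1", "human", {"PF1", "PF9"})
        assert pfam_homologs(bovine, [cand]) == {"H1"}
        assert pfam_homologs(bovine, [cand], strict=True) == set()

    def test_bovine_candidates_excluded(self):
        bovine = protein("B1", "bovine", {"PF1"})
        other = protein("B2", "bovine", {"PF1"})
        assert pfam_homologs(bovine, [other]) == set()

    def test_empty_domain_set_is_precondition_error(self):
        with pytest.raises(ValueError, match="no Pfam domains"):
            pfam_homologs(protein("B1", "bovine", set()), [])

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_subset_oracle(self, data):
        domain_pool = [f"PF{i}" for i in range(5)]
        subset = st.sets(st.sampled_from(domain_pool), min_size=0, max_size=5)
        bovine = protein(
            "B0", "bovine",
            data.draw(st.sets(st.sampled_from(domain_pool), min_size=1, max_size=5)),
        )
        candidates = [
            protein(f"C{i}", data.draw(st.sampled_from(["human", "mouse", "bovine"])),
                    data.draw(subset))
            for i in range(data.draw(st.integers(0, 20)))
        ]
        oracle = {
            c.accession
            for c in candidates
            if c.species != "bovine"
            and all(d in c.pfam_domains for d in bovine.pfam_domains)
        }
        assert pfam_homologs(bovine, candidates) == oracle

    def test_symmetry_under_equal_domain_sets(self):
        a = protein("B1", "bovine", {"PF1", "PF2"})
        b = protein("H1", "human", {"PF1", "PF2"})
        assert "H1" in pfam_homologs(a, [b])
        swapped = ProteinRecord(
            accession="H1", entry_name="x", species="bovine",
            primary_name="H1", pfam_domains=b.pfam_domains,
        )
        partner = ProteinRecord(
            accession="B1", entry_name="x", species="human",
            primary_name="B1", pfam_domains=a.pfam_domains,
        )
        assert "B1" in pfam_homologs(swapped, [partner])


class TestHomologenePairs:
    def test_single_group_pair(self):
        table = group_table(
            [(1, "bovine", "G1", "B1"), (1, "human", "G1", "H1")]
        )
        hmap = homologene_pairs(table, "human")
        assert hmap.foreign_accessions("B1", "human") == {"H1"}

    def test_group_with_bovine_only_gives_no_pairs(self):
        table = group_table([(1, "bovine", "G1", "B1")])
        assert len(homologene_pairs(table, "human")) == 0

    def test_unshared_species_warns_and_returns_empty(self, caplog):
        table = group_table([(1, "bovine", "G1", "B1"), (1, "sheep", "G1", "S1")])
        import logging

        with caplog.at_level(logging.WARNING):
            hmap = homologene_pairs(table, "sheep")
        assert len(hmap) == 0
        assert any("sheep" in m for m in caplog.messages)

    def test_multi_member_groups_match_cross_product_oracle(self):
        rows, oracle = [], set()
        for gid, (n_bov, n_hum) in enumerate([(2, 3), (1, 0), (0, 2), (3, 1)]):
            bovs = [f"B{gid}_{i}" for i in range(n_bov)]
            hums = [f"H{gid}_{i}" for i in range(n_hum)]
            rows += [(gid, "bovine", f"G{gid}", b) for b in bovs]
            rows += [(gid, "human", f"G{gid}", h) for h in hums]
            oracle |= {(b, h) for b in bovs for h in hums}
        hmap = homologene_pairs(group_table(rows), "human")
        assert hmap.all_pairs() == oracle


class TestMerge:
    def map_of(self, pairs, method):
        hmap = HomologyMap()
        for b, sp, f in pairs:
            hmap.add(b, sp, f, method)
        return hmap

    def test_disjoint_maps_union(self):
        a = self.map_of([("B1", "human", "H1")], "pfam")
        b = self.map_of([("B2", "mouse", "M1")], "homologene")
        merged = merge_homology([a, b])
        assert merged.all_pairs() == {("B1", "H1"), ("B2", "M1")}

    def test_identical_maps_get_both_provenance(self):
        a = self.map_of([("B1", "human", "H1")], "pfam")
        b = self.map_of([("B1", "human", "H1")], "homologene")
        merged = merge_homology([a, b])
        assert merged.provenance[("B1", "H1")] == {"pfam", "homologene"}
        assert merged.partition_by_provenance()["shared"] == 1

    def test_partition_sizes_sum_to_union(self):
        a = self.map_of([("B1", "human", "H1"), ("B2", "human", "H2")], "pfam")
        b = self.map_of([("B2", "human", "H2"), ("B3", "rat", "R1")], "homologene")
        merged = merge_homology([a, b])
        assert sum(merged.partition_by_provenance().values()) == len(merged)

    def test_associative_and_commutative(self):
        a = self.map_of([("B1", "human", "H1")], "pfam")
        b = self.map_of([("B2", "mouse", "M1")], "homologene")
        c = self.map_of([("B1", "human", "H1")], "homologene")
        left = merge_homology([merge_homology([a, b]), c])
        right = merge_homology([a, merge_homology([b, c])])
        flipped = merge_homology([c, b, a])
        for other in (right, flipped):
            assert left.all_pairs() == other.all_pairs()
            assert left.provenance == other.provenance


def test_build_pfam_map_over_bundle_finds_all_planted_pairs(small_bundle):
    """Every planted cross-species group shares its domain set, so the
    domain rule must recover all of its pairs."""
    bovine = [
        p for p in small_bundle.proteins
        if p.species == "bovine" and p.pfam_domains and p.accession.startswith("B")
    ]
    hmap = build_pfam_map(bovine, small_bundle.proteins)
    for _, group in small_bundle.homolog_table.groups():
        bovs = group.loc[group["species"] == "bovine", "accession"]
        for b in bovs:
            for row in group.itertuples(index=False):
                if row.species != "bovine":
                    assert row.accession in hmap.foreign_accessions(b, row.species)
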
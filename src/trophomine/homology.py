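"""Cross-species homolog detection: shared Pfam domains and homology groups.

Two complementary routes identify foreign-species counterparts of bovine
proteins:

* the **Pfam route**: a foreign protein is a homolog of a bovine protein
  when it carries *all* of the bovine protein's Pfam domains (superset
  rule by default; a strict-equality mode is available).  A single domain
  can occur in many proteins, so one bovine protein may have dozens of
  Pfam homologs, orthologs and paralogs alike — the distinction is
  deliberately disregarded, since shared domains are taken as shared
  function;
* the **group route**: precomputed homology groups (HomoloGene-style);
  group membership shared between bovine and a foreign species yields all
  bovine x foreign pairs of the group.  Only human, mouse and rat share
  groups with bovine in practice.

The two maps merge with provenance kept per pair, so Pfam-only, shared and
group-only partitions stay reportable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import SPECIES, HomologGroupTable, ProteinRecord

logger = logging.getLogger(__name__)

#: Species whose homology groups overlap the bovine groups.
HOMOLOGENE_SPECIES = ("human", "mouse", "rat")


@dataclass
class HomologyMap:
    """bovine accession -> species -> set of foreign accessions.

    ``provenance`` records, per (bovine, foreign) pair, which method(s)
    produced it ({"pfam"}, {"homologene"} or both).
    """

    pairs: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    provenance: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)

    def add(self, bovine: str, species: str, foreign: str, method: str) -> None:
        if species not in SPECIES:
            raise ValueError(f"unknown species {species!r}")
        self.pairs.setdefault(bovine, {}).setdefault(species, set()).add(foreign)
        key = (bovine, foreign)
        self.provenance[key] = self.provenance.get(key, frozenset()) | {method}

    def foreign_accessions(self, bovine: str, species: str) -> set[str]:
        return set(self.pairs.get(bovine, {}).get(species, set()))

    def all_pairs(self) -> set[tuple[str, str]]:
        return set(self.provenance.keys())

    def partition_by_provenance(self) -> dict[str, int]:
        """Pair counts by origin: pfam-only / shared / homologene-only."""
        tally = {"pfam-only": 0, "shared": 0, "homologene-only": 0}
        for methods in self.provenance.values():
            if methods == {"pfam"}:
                tally["pfam-only"] += 1
            elif methods == {"homologene"}:
                tally["homologene-only"] += 1
            else:
                tally["shared"] += 1
        return tally

    def __len__(self) -> int:
        return len(self.provenance)


def pfam_homologs(
    bovine: ProteinRecord,
    candidates: Iterable[ProteinRecord],
    strict: bool = False,
) -> set[str]:
    """Accessions of candidates sharing all the bovine protein's domains.

    Default rule: candidate domain set is a superset of the bovine domain
    set (a protein carrying the bovine domains plus extras still shares
    all of them).  ``strict=True`` requires exact domain-set equality.
    Bovine candidates are excluded; the bovine protein must itself carry
    at least one Pfam domain (proteins without any are excluded upstream —
    not every protein is described by a domain).
    """
    if not bovine.pfam_domains:
        raise ValueError(
            f"{bovine.accession}: no Pfam domains; filter such proteins out first"
        )
    matches = set()
    for cand in candidates:
        if cand.species == "bovine":
            continue
        if strict:
            ok = cand.pfam_domains == bovine.pfam_domains
        else:
            ok = cand.pfam_domains >= bovine.pfam_domains
        if ok:
            matches.add(cand.accession)
    return matches


def build_pfam_map(
    bovine_proteins: Sequence[ProteinRecord],
    candidates: Sequence[ProteinRecord],
    strict: bool = False,
) -> HomologyMap:
    """Pfam homology map over every domain-bearing bovine protein."""
    by_accession = {c.accession: c for c in candidates}
    hmap = HomologyMap()
    for bovine in bovine_proteins:
        if bovine.species != "bovine" or not bovine.pfam_domains:
            continue
        for acc in pfam_homologs(bovine, candidates, strict=strict):
            hmap.add(bovine.accession, by_accession[acc].species, acc, "pfam")
    return hmap


def homologene_pairs(table: HomologGroupTable, species_b: str) -> HomologyMap:
    """Bovine x species_b pairs from shared homology-group membership.

    For each group containing both a bovine member and a ``species_b``
    member, every bovine x foreign cross-pair of the group is emitted.
    Sheep, pig and horse describe no groups in common with bovine, so
    requesting them returns an empty map with a warning.
    """
    if species_b not in SPECIES or species_b == "bovine":
        raise ValueError(f"invalid foreign species {species_b!r}")
    hmap = HomologyMap()
    if species_b not in HOMOLOGENE_SPECIES:
        logger.warning(
            "no homology groups are shared between bovine and %s; empty map",
            species_b,
        )
        return hmap
    for _, group in table.groups():
        bovines = group.loc[group["species"] == "bovine", "accession"]
        foreigns = group.loc[group["species"] == species_b, "accession"]
        for b in bovines:
            for f in foreigns:
                hmap.add(b, species_b, f, "homologene")
    return hmap


def merge_homology(maps: Iterable[HomologyMap]) -> HomologyMap:
    """Union of homology maps; per-pair provenance flags are merged."""
    merged = HomologyMap()
    for hmap in maps:
        for bovine, per_species in hmap.pairs.items():
            for species, foreigns in per_species.items():
                for foreign in foreigns:
                    for method in hmap.provenance[(bovine, foreign)]:
                        merged.add(bovine, species, foreign, method)
    return merged


def write_homology_tsv(hmap: HomologyMap, proteins: Mapping[str, ProteinRecord], stream) -> None:
    """Export TSV: bovine accession, species, foreign accession, provenance."""
    stream.write("bovine_accession\tspecies\tforeign_accession\tprovenance\n")
    for bovine in sorted(hmap.pairs):
        for species in sorted(hmap.pairs[bovine]):
            for foreign in sorted(hmap.pairs[bovine][species]):
                prov = ",".join(sorted(hmap.provenance[(bovine, foreign)]))
                stream.write(f"{bovine}\t{species}\t{foreign}\t{prov}\n")


def read_homology_tsv(stream) -> HomologyMap:
    import pandas as pd

    df = pd.read_csv(stream, sep="\t", dtype=str, keep_default_na=False)
    hmap = HomologyMap()
    for row in df.itertuples(index=False):
        for method in row.provenance.split(","):
            hmap.add(row.bovine_accession, row.species, row.foreign_accession, method)
    return hmap
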
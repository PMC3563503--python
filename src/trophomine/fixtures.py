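"""Synthetic ecosystem generator with planted, recoverable signal.

Real corpora and database snapshots are moving targets, so every stage is
exercised against a generated ecosystem instead: bibliographic corpora
(MEDLINE-like and WoS-like, with controlled cross-source duplicates),
protein/domain tables whose planted cross-species homolog groups share
domain sets (hence are detectable by the shared-domain rule), a background
corpus realizing each planted gene's configured background frequency
exactly, and a TF catalog containing a planted gold standard.

Abstracts are template-generated token soup — tissue/species keywords,
planted gene symbols at configured per-document probabilities, and filler
vocabulary.  That is sufficient (and honest) because every downstream
computation is token-set based; nothing in the pipeline reads grammar.

Same seed, same bundle, byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .corpus import TISSUES, Subcorpus, _SPECIES_ABBREV
from .io_formats import (
    SPECIES,
    DocumentRecord,
    HomologGroupTable,
    ProteinRecord,
    TFCatalog,
    write_homologene,
    write_medline,
    write_protein_table,
    write_wos,
)

_TISSUE_WORD = {"tro": "trophoblast", "cho": "choriocarcinoma", "ex": "extraembryonic"}
_ENTRY_SUFFIX = {"bovine": "BOVIN", "human": "HUMAN", "mouse": "MOUSE", "rat": "RAT"}
_TF_GO = ("GO:0003700", "sequence-specific DNA binding transcription factor activity")
_NON_TF_GO = ("GO:0016301", "kinase activity")
_FAMILY_CYCLE = ("homeodomain", "bHLH", "zinc-finger", "GATA")


@dataclass(frozen=True)
class PlantedGene:
    """One gene with controlled corpus presence and background rarity."""

    symbol: str
    subcorpora: tuple[tuple[str, str], ...]  # (species, tissue) targets
    mention_prob: float  # per-document mention probability in targets
    gf_fraction: float  # background document-frequency fraction


@dataclass(frozen=True)
class FixtureConfig:
    """Everything the generator needs; validated before any file is made."""

    seed: int
    n_species_proteins: dict[str, int]  # filler proteins per species
    n_domains: int
    n_docs: dict[tuple[str, str], int]  # (species, tissue) -> document count
    planted_genes: tuple[PlantedGene, ...]
    fraction_tf: float  # leading fraction of planted genes put in the catalog
    gold_subset_size: int
    background_size: int = 1000
    wos_fraction: float = 0.4  # chance a document is exported from WoS
    duplicate_fraction: float = 0.1  # chance the other source also carries it
    filler_vocab_size: int = 200
    tokens_per_abstract: int = 8

    def __post_init__(self) -> None:
        for gene in self.planted_genes:
            if not 0.0 <= gene.mention_prob <= 1.0:
                raise ValueError(f"{gene.symbol}: mention_prob outside [0,1]")
            if not 0.0 <= gene.gf_fraction <= 1.0:
                raise ValueError(f"{gene.symbol}: gf_fraction outside [0,1]")
            for species, tissue in gene.subcorpora:
                if species not in SPECIES or tissue not in TISSUES:
                    raise ValueError(
                        f"{gene.symbol}: bad target subcorpus ({species}, {tissue})"
                    )
        if not 0.0 <= self.fraction_tf <= 1.0:
            raise ValueError("fraction_tf outside [0,1]")
        if self.gold_subset_size > len(self.tf_symbols()):
            raise ValueError("more gold genes requested than planted TF genes")
        if self.n_domains < 2 * len(self.planted_genes) + 3:
            raise ValueError("domain pool too small for planted genes plus filler")
        if self.background_size < 1:
            raise ValueError("background corpus must have at least one document")
        for key, count in self.n_docs.items():
            if key[0] not in SPECIES or key[1] not in TISSUES or count < 0:
                raise ValueError(f"bad n_docs entry {key} -> {count}")

    def tf_symbols(self) -> tuple[str, ...]:
        """Planted genes designated as TFs: the leading fraction_tf share."""
        n_tf = round(self.fraction_tf * len(self.planted_genes))
        return tuple(g.symbol for g in self.planted_genes[:n_tf])

    def gold_symbols(self) -> tuple[str, ...]:
        return self.tf_symbols()[: self.gold_subset_size]

    def expected_gf(self, gene: PlantedGene) -> int:
        """The realized background frequency: exact, never zero."""
        return max(1, round(gene.gf_fraction * self.background_size))


@dataclass
class FixtureBundle:
    """All generated inputs, in memory, plus writers for the on-disk dialects."""

    config: FixtureConfig
    proteins: list[ProteinRecord]
    homolog_table: HomologGroupTable
    pubmed_docs: list[DocumentRecord]
    wos_docs: list[DocumentRecord]
    background_docs: list[DocumentRecord]
    tf_catalog: TFCatalog
    gold_symbols: tuple[str, ...]

    def write(self, outdir: Path) -> dict[str, Path]:
        """Write every input file in the dialect the readers expect."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "pubmed": outdir / "pubmed.medline",
            "wos": outdir / "wos.txt",
            "background": outdir / "background.medline",
            "proteins": outdir / "proteins.tsv",
            "homologene": outdir / "homologene.tsv",
            "tf_catalog": outdir / "tf_catalog.tsv",
            "gold_standard": outdir / "gold_standard.txt",
            "manifest": outdir / "manifest.json",
        }
        with open(paths["pubmed"], "w") as fh:
            write_medline(self.pubmed_docs, fh)
        with open(paths["wos"], "w") as fh:
            write_wos(self.wos_docs, fh)
        with open(paths["background"], "w") as fh:
            write_medline(self.background_docs, fh)
        with open(paths["proteins"], "w") as fh:
            write_protein_table(self.proteins, fh)
        with open(paths["homologene"], "w") as fh:
            write_homologene(self.homolog_table, fh)
        with open(paths["tf_catalog"], "w") as fh:
            for symbol in sorted(self.tf_catalog.symbols):
                family = self.tf_catalog.families.get(symbol, "")
                fh.write(f"{symbol}\t{family}\n" if family else f"{symbol}\n")
        with open(paths["gold_standard"], "w") as fh:
            fh.write("# planted gold standard (synthetic)\n")
            for symbol in self.gold_symbols:
                fh.write(symbol + "\n")
        manifest = {"seed": self.config.seed, "config": _config_echo(self.config)}
        with open(paths["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def _config_echo(cfg: FixtureConfig) -> dict:
    raw = dataclasses.asdict(cfg)
    raw["n_docs"] = {f"{sp}:{t}": n for (sp, t), n in sorted(cfg.n_docs.items())}
    return raw


def _planted_proteins(cfg: FixtureConfig) -> tuple[list[ProteinRecord], list[dict]]:
    """Planted proteins across bovine/human/mouse/rat with shared domains."""
    proteins, group_rows = [], []
    tf_set = set(cfg.tf_symbols())
    for i, gene in enumerate(cfg.planted_genes):
        domains = frozenset({f"PF{2 * i + 1:05d}", f"PF{2 * i + 2:05d}"})
        go = frozenset({_TF_GO if gene.symbol in tf_set else _NON_TF_GO})
        for species, prefix in (("bovine", "B"), ("human", "H"), ("mouse", "M"), ("rat", "R")):
            accession = f"{prefix}{i:05d}"
            proteins.append(
                ProteinRecord(
                    accession=accession,
                    entry_name=f"{gene.symbol}_{_ENTRY_SUFFIX[species]}",
                    species=species,
                    primary_name=gene.symbol,
                    go_terms=go,
                    pfam_domains=domains,
                    reviewed=True,
                )
            )
            group_rows.append(
                {
                    "group_id": i + 1,
                    "species": species,
                    "gene_symbol": gene.symbol,
                    "accession": accession,
                }
            )
    return proteins, group_rows


def _filler_proteins(cfg: FixtureConfig, rng: np.random.Generator) -> list[ProteinRecord]:
    lo = 2 * len(cfg.planted_genes) + 1
    pool = [f"PF{d:05d}" for d in range(lo, cfg.n_domains + 1)]
    proteins = []
    for species in SPECIES:
        for j in range(cfg.n_species_proteins.get(species, 0)):
            size = min(3, len(pool))
            domains = frozenset(rng.choice(pool, size=size, replace=False).tolist())
            proteins.append(
                ProteinRecord(
                    accession=f"F{_SPECIES_ABBREV[species].upper()}{j:04d}",
                    entry_name=f"FIL{j}_{species[:3].upper()}",
                    species=species,
                    primary_name=f"FIL{_SPECIES_ABBREV[species].upper()}{j}",
                    go_terms=frozenset({_NON_TF_GO}),
                    pfam_domains=domains,
                    reviewed=True,
                )
            )
    return proteins


def _corpus_docs(
    cfg: FixtureConfig, rng: np.random.Generator, vocab: list[str]
) -> tuple[list[DocumentRecord], list[DocumentRecord]]:
    """Subcorpus documents split between the two sources, with duplicates."""
    pubmed, wos = [], []
    seq = 0
    ordered_pairs = sorted(
        cfg.n_docs, key=lambda p: (SPECIES.index(p[0]), TISSUES.index(p[1]))
    )
    for species, tissue in ordered_pairs:
        targeting = [
            g for g in cfg.planted_genes if (species, tissue) in g.subcorpora
        ]
        for _ in range(cfg.n_docs[(species, tissue)]):
            seq += 1
            tokens = [_TISSUE_WORD[tissue], species]
            tokens += [g.symbol for g in targeting if rng.random() < g.mention_prob]
            tokens += rng.choice(vocab, size=cfg.tokens_per_abstract).tolist()
            title = f"Record {seq} on {_TISSUE_WORD[tissue]} biology in the {species}"
            abstract = " ".join(tokens)
            year = 2000 + int(rng.integers(0, 12))
            if rng.random() < cfg.wos_fraction:
                doc = DocumentRecord(
                    doc_id=f"WOS:{seq:09d}", source="wos", title=title,
                    abstract=abstract, external_id=f"WOS:{seq:09d}", year=year,
                )
                wos.append(doc)
                twin_pool = pubmed
                twin = DocumentRecord(
                    doc_id=str(10_000_000 + seq), source="pubmed", title=title,
                    abstract=abstract, external_id=str(10_000_000 + seq), year=year,
                )
            else:
                doc = DocumentRecord(
                    doc_id=str(10_000_000 + seq), source="pubmed", title=title,
                    abstract=abstract, external_id=str(10_000_000 + seq), year=year,
                )
                pubmed.append(doc)
                twin_pool = wos
                twin = DocumentRecord(
                    doc_id=f"WOS:{seq:09d}", source="wos", title=title,
                    abstract=abstract, external_id=f"WOS:{seq:09d}", year=year,
                )
            if rng.random() < cfg.duplicate_fraction:
                twin_pool.append(twin)  # same title: fusion must collapse it
    return pubmed, wos


def _background_docs(
    cfg: FixtureConfig, rng: np.random.Generator, vocab: list[str]
) -> list[DocumentRecord]:
    """D background documents; gene i occurs in exactly its expected GF."""
    D = cfg.background_size
    extra_tokens: dict[int, list[str]] = {k: [] for k in range(D)}
    for gene in cfg.planted_genes:
        gf = cfg.expected_gf(gene)
        for idx in rng.choice(D, size=gf, replace=False):
            extra_tokens[int(idx)].append(gene.symbol)
    docs = []
    for k in range(D):
        tokens = extra_tokens[k] + rng.choice(vocab, size=6).tolist()
        docs.append(
            DocumentRecord(
                doc_id=f"BG{k:06d}",
                source="pubmed",
                title=f"Background record {k}",
                abstract=" ".join(tokens),
                external_id=f"BG{k:06d}",
            )
        )
    return docs


def generate_ecosystem(cfg: FixtureConfig) -> FixtureBundle:
    """Generate the full input bundle for one seeded configuration."""
    rng = np.random.default_rng(cfg.seed)
    vocab = [f"filler{k:03d}" for k in range(cfg.filler_vocab_size)]

    planted, group_rows = _planted_proteins(cfg)
    proteins = planted + _filler_proteins(cfg, rng)
    import pandas as pd

    homolog_table = HomologGroupTable(
        pd.DataFrame(group_rows, columns=["group_id", "species", "gene_symbol", "accession"])
    )
    pubmed, wos = _corpus_docs(cfg, rng, vocab)
    background = _background_docs(cfg, rng, vocab)
    tf_symbols = cfg.tf_symbols()
    families = {
        sym: _FAMILY_CYCLE[i % len(_FAMILY_CYCLE)] for i, sym in enumerate(tf_symbols)
    }
    decoys = {f"TFDECOY{k}" for k in range(5)}
    catalog = TFCatalog(symbols=frozenset(tf_symbols) | decoys, families=families)
    return FixtureBundle(
        config=cfg,
        proteins=proteins,
        homolog_table=homolog_table,
        pubmed_docs=pubmed,
        wos_docs=wos,
        background_docs=background,
        tf_catalog=catalog,
        gold_symbols=cfg.gold_symbols(),
    )


def expected_ranking(cfg: FixtureConfig) -> list[tuple[str, float]]:
    """Analytically expected tf-idf order of the planted genes.

    Expected tf equals the planted per-document mention probability (the
    expected hit count over target subcorpora divided by their total
    size), and idf is exact because the background frequency is realized
    exactly.  Genes mentioned nowhere get w = 0 and rank last.  Ties
    break alphabetically, matching the scorer.
    """
    out = []
    for gene in cfg.planted_genes:
        total_target_docs = sum(
            cfg.n_docs.get(pair, 0) for pair in gene.subcorpora
        )
        if total_target_docs == 0 or gene.mention_prob == 0.0:
            out.append((gene.symbol, 0.0))
            continue
        idf = math.log(cfg.background_size / cfg.expected_gf(gene))
        out.append((gene.symbol, gene.mention_prob * idf))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


# ---------------------------------------------------------------------------
# Shipped configurations
# ---------------------------------------------------------------------------

# Document counts shaped like the published 7x3 subcorpus structure (same
# size ratios, scaled to a few hundred documents; the absolute published
# counts were snapshot-dependent and are a non-goal).
_SHAPED_RATIOS = {
    ("bovine", "tro"): 15, ("bovine", "cho"): 1, ("bovine", "ex"): 1,
    ("human", "tro"): 158, ("human", "cho"): 64, ("human", "ex"): 16,
    ("mouse", "tro"): 52, ("mouse", "cho"): 8, ("mouse", "ex"): 31,
    ("rat", "tro"): 18, ("rat", "cho"): 5, ("rat", "ex"): 4,
    ("horse", "tro"): 2, ("horse", "cho"): 0, ("horse", "ex"): 0,
    ("pig", "tro"): 7, ("pig", "cho"): 0, ("pig", "ex"): 1,
    ("sheep", "tro"): 13, ("sheep", "cho"): 1, ("sheep", "ex"): 2,
}

# Target subcorpora for strong-signal planted genes: every pair with at
# least 5 documents in the shaped layout (11 pairs, comfortably above the
# presence-score cutoff of 9).
_STRONG_TARGETS = tuple(
    sorted(
        (pair for pair, n in _SHAPED_RATIOS.items() if n >= 5),
        key=lambda p: (SPECIES.index(p[0]), TISSUES.index(p[1])),
    )
)


def default_ecosystem_config(seed: int = 0) -> FixtureConfig:
    """The shipped configuration: 21 shaped subcorpora, nine planted genes.

    Five planted TFs carry strong signal (mention probability 0.5-0.9
    across the 11 best-documented subcorpora, background fraction at or
    below 1%), four planted non-TFs carry weaker, commoner signal; the
    expected tf-idf scores are well separated so the analytic order is
    recoverable.  Four of the TFs form the planted gold standard.
    """
    tf_specs = [
        ("TFALPHA", 0.9, 0.002),
        ("TFBETA", 0.8, 0.003),
        ("TFGAMMA", 0.7, 0.005),
        ("TFDELTA", 0.6, 0.008),
        ("TFEPSIL", 0.5, 0.010),
    ]
    other_specs = [
        ("GKINA", 0.4, 0.05),
        ("GKINB", 0.3, 0.10),
        ("GKINC", 0.2, 0.20),
        ("GKIND", 0.1, 0.30),
    ]
    planted = tuple(
        PlantedGene(symbol=s, subcorpora=_STRONG_TARGETS, mention_prob=p, gf_fraction=g)
        for s, p, g in tf_specs + other_specs
    )
    return FixtureConfig(
        seed=seed,
        n_species_proteins={sp: 4 for sp in SPECIES},
        n_domains=60,
        n_docs=dict(_SHAPED_RATIOS),
        planted_genes=planted,
        fraction_tf=5 / 9,
        gold_subset_size=4,
        background_size=1000,
    )


def subcorpora_from_bundle(bundle: FixtureBundle) -> list[Subcorpus]:
    """Convenience: fuse and classify a bundle's corpora (test plumbing)."""
    from .corpus import KeywordScheme, build_subcorpora, fuse_corpora

    fused = fuse_corpora(bundle.pubmed_docs, bundle.wos_docs)
    return build_subcorpora(fused, KeywordScheme.default())
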
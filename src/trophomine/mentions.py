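"""Gene-mention detection and document-frequency counting.

A gene is "present" wherever any of its surface forms — primary name or
synonym, tokenized exactly like the corpus text — is found.  Multi-token
variants use bag-of-words semantics (all tokens present, adjacency not
required): dictionaries are token sets and cannot encode adjacency, which
is a documented source of false positives.  Synonym expansion is strictly
monotone: adding a variant can only enlarge the matched gene set, which is
precisely why it improves dictionary search.

Two granularities coexist:

* dictionary-level presence (tokens pooled across a whole subcorpus) feeds
  the boolean presence score;
* document-level counts n_ij (documents of subcorpus j containing gene i)
  and the background frequency GF_i over a designated background corpus of
  size D feed the tf-idf score.

Document-level presence implies dictionary-level presence; the converse
need not hold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import AbstractSet, Iterable, Mapping, Optional, Sequence

from .corpus import Subcorpus, tokenize
from .io_formats import DocumentRecord, ProteinRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneLexicon:
    """All normalized surface forms of one gene.

    ``variants`` holds the token sequences of the primary name and every
    synonym, deduplicated after normalization; empty variants are dropped.
    """

    symbol: str
    variants: frozenset[tuple[str, ...]]

    @staticmethod
    def build(
        symbol: str,
        names: Iterable[str],
        stop_list: AbstractSet[str] = frozenset(),
    ) -> "GeneLexicon":
        """Tokenize names into variants; a configurable stop list removes
        variants made entirely of stop tokens (default: empty, matching
        the no-disambiguation policy)."""
        variants = set()
        for name in names:
            tokens = tuple(tokenize(name))
            if tokens and not all(t in stop_list for t in tokens):
                variants.add(tokens)
        return GeneLexicon(symbol=symbol, variants=frozenset(variants))

    @staticmethod
    def from_protein(
        protein: ProteinRecord, stop_list: AbstractSet[str] = frozenset()
    ) -> "GeneLexicon":
        return GeneLexicon.build(protein.primary_name, protein.names, stop_list)


def gene_in_dictionary(gene: GeneLexicon, dictionary: AbstractSet[str]) -> bool:
    """True iff some variant has all of its tokens in the dictionary."""
    return any(all(tok in dictionary for tok in var) for var in gene.variants)


def gene_in_document(gene: GeneLexicon, doc: DocumentRecord) -> bool:
    """True iff some variant has all of its tokens in the document."""
    return gene_in_dictionary(gene, frozenset(tokenize(doc.text)))


def count_doc_freq(gene: GeneLexicon, sub: Subcorpus) -> int:
    """n_ij: number of documents of subcorpus j containing gene i."""
    return sum(
        1
        for tokens in sub.doc_tokens.values()
        if gene_in_dictionary(gene, tokens)
    )


def background_freq(gene: GeneLexicon, background: Sequence[DocumentRecord]) -> int:
    """GF_i: number of background-corpus documents containing gene i.

    The background corpus stands for the whole space of knowledge (all of
    PubMed in the original setting); it is an explicit input here.
    """
    if not gene.variants:
        raise ValueError(f"gene {gene.symbol!r} has no usable name variants")
    return sum(1 for doc in background if gene_in_document(gene, doc))


@dataclass
class MentionIndex:
    """Document frequencies for a gene set: n_ij, GF_i and D."""

    n: Mapping[tuple[str, str], int]  # (gene symbol, subcorpus name) -> n_ij
    GF: Mapping[str, int]  # gene symbol -> background frequency
    D: int  # background corpus size
    N: Mapping[str, int] = field(default_factory=dict)  # subcorpus name -> N_j

    def __post_init__(self) -> None:
        if self.D < 1:
            raise ValueError("background corpus must contain at least one document")
        for (gene, sub), count in self.n.items():
            if not 0 <= count:
                raise ValueError(f"negative count for ({gene}, {sub})")
            if sub in self.N and count > self.N[sub]:
                raise ValueError(
                    f"n[{gene},{sub}] = {count} exceeds subcorpus size {self.N[sub]}"
                )
        for gene, gf in self.GF.items():
            if not 0 <= gf <= self.D:
                raise ValueError(f"GF[{gene}] = {gf} outside [0, D={self.D}]")

    def genes(self) -> list[str]:
        return sorted({g for g, _ in self.n.keys()} | set(self.GF.keys()))


def build_mention_index(
    genes: Iterable[GeneLexicon],
    subcorpora: Sequence[Subcorpus],
    background: Sequence[DocumentRecord],
    background_size: Optional[int] = None,
) -> MentionIndex:
    """Count n_ij over every (gene, subcorpus) pair and GF_i over the
    background corpus.

    ``background_size`` overrides D when the background counts were
    obtained from a corpus larger than the documents supplied (e.g. GF
    measured against an index rather than raw text); by default D is the
    number of background documents.
    """
    genes = list(genes)
    n = {
        (g.symbol, sub.name): count_doc_freq(g, sub)
        for g in genes
        for sub in subcorpora
    }
    GF = {g.symbol: background_freq(g, background) for g in genes}
    return MentionIndex(
        n=n,
        GF=GF,
        D=background_size if background_size is not None else len(background),
        N={sub.name: sub.N for sub in subcorpora},
    )
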
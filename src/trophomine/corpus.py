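"""Subcorpus construction: tokenization, document classification, fusion.

The search space of the literature is cut into (species x tissue-keyword)
subcorpora before any gene matching happens: seven species (bovine, human,
mouse, rat, sheep, pig, horse) crossed with three tissue keywords —
trophoblast (tro), choriocarcinoma (cho) and extra-embryonic (ex) — give
the 21 subcorpora used throughout.  A merged human-mouse corpus (tagged
"humo") can be supplied pre-built, since human proliferation and mouse
development literature is far richer than livestock literature.

Tokenization is intentionally crude and fully specified: lowercase,
letters/digits with internal hyphens form one token, everything else
separates.  No stemming; keyword patterns may end in '*' for prefix match
(so "trophoblast*" also matches "trophoblastic").
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .io_formats import SPECIES, DocumentRecord

TISSUES = ("tro", "cho", "ex")

#: Species abbreviations used in subcorpus names (TroBo, ChoHu, ...).
_SPECIES_ABBREV = {
    "bovine": "Bo",
    "human": "Hu",
    "mouse": "Mo",
    "rat": "Ra",
    "horse": "Ho",
    "pig": "Pig",
    "sheep": "She",
    "humo": "HuMo",
}

_TOKEN = re.compile(r"[^\W_]+(?:-[^\W_]+)*", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Split text into normalized tokens.

    Lowercased; a token is a run of letters/digits possibly joined by
    internal hyphens ("extra-embryonic" and "c-fos" stay single tokens);
    every other character separates.  No stemming.
    """
    return _TOKEN.findall(text.lower())


@dataclass(frozen=True)
class KeywordScheme:
    """Tissue wildcard patterns and species literals driving classification.

    Wildcards appear only as a trailing '*' (prefix match); species terms
    are literal tokens.  The default mirrors the retrieval query:
    (trophoblast* or choriocarcinoma* or extra-embryonic* or
    extraembryonic*) and (bovine or human or pig or sheep or mouse or rat
    or horse).
    """

    tissue_patterns: Mapping[str, tuple[str, ...]]
    species_terms: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for tag, patterns in self.tissue_patterns.items():
            if tag not in TISSUES:
                raise ValueError(f"unknown tissue tag {tag!r}")
            if not patterns:
                raise ValueError(f"tissue {tag!r} has no patterns")
            for pat in patterns:
                if "*" in pat[:-1]:
                    raise ValueError(f"wildcard only allowed trailing: {pat!r}")
        for sp, terms in self.species_terms.items():
            if sp not in SPECIES:
                raise ValueError(f"unknown species {sp!r}")
            if not terms:
                raise ValueError(f"species {sp!r} has no terms")

    @staticmethod
    def default() -> "KeywordScheme":
        return KeywordScheme(
            tissue_patterns={
                "tro": ("trophoblast*",),
                "cho": ("choriocarcinoma*",),
                "ex": ("extra-embryonic*", "extraembryonic*"),
            },
            species_terms={sp: (sp,) for sp in SPECIES},
        )


def _matches(token: str, pattern: str) -> bool:
    if pattern.endswith("*"):
        return token.startswith(pattern[:-1])
    return token == pattern


def classify_document(
    doc: DocumentRecord, scheme: KeywordScheme
) -> set[tuple[str, str]]:
    """Assign a document to every (species, tissue) subcorpus it matches.

    A pair (s, t) is returned iff some token of title+abstract matches a
    tissue pattern of t AND some token matches a species term of s; the
    two matches may come from different tokens.  Keywords are looked for
    in both title and abstract.
    """
    tokens = tokenize(doc.text)
    tissues = {
        tag
        for tag, patterns in scheme.tissue_patterns.items()
        if any(_matches(tok, pat) for tok in tokens for pat in patterns)
    }
    if not tissues:
        return set()
    species = {
        sp
        for sp, terms in scheme.species_terms.items()
        if any(_matches(tok, term) for tok in tokens for term in terms)
    }
    return {(sp, tag) for sp in species for tag in tissues}


def _normalize_title(title: str) -> str:
    return " ".join(tokenize(title))


def fuse_corpora(
    pubmed: Sequence[DocumentRecord], wos: Sequence[DocumentRecord]
) -> list[DocumentRecord]:
    """Union the two source corpora, dropping duplicate documents.

    Two records are duplicates when they share an external id, or when
    their case-folded punctuation-stripped titles are equal.  The PubMed
    copy wins on conflict (the PMID is the stabler key).  Idempotent:
    fusing the fused corpus with either source adds nothing.
    """
    fused: list[DocumentRecord] = []
    seen_ids: set[str] = set()
    seen_titles: set[str] = set()
    for doc in list(pubmed) + list(wos):
        norm_title = _normalize_title(doc.title)
        if doc.external_id is not None and doc.external_id in seen_ids:
            continue
        if norm_title and norm_title in seen_titles:
            continue
        fused.append(doc)
        if doc.external_id is not None:
            seen_ids.add(doc.external_id)
        if norm_title:
            seen_titles.add(norm_title)
    return fused


@dataclass
class Subcorpus:
    """A (species, tissue) document set with its token dictionary.

    ``N`` (document count) is the corpus-size term of the frequency score;
    the dictionary — the set of all normalized tokens over member
    documents — is what presence/absence gene filtering runs against.
    Dictionaries and per-document token sets are computed lazily and
    cached; use :meth:`add` (never mutate ``documents`` directly) so the
    caches stay consistent.
    """

    species_tag: str  # one of SPECIES, or "humo" for the merged corpus
    tissue_tag: str  # one of TISSUES, or "all"
    documents: list[DocumentRecord] = field(default_factory=list)
    _dictionary: Optional[frozenset[str]] = field(
        default=None, repr=False, compare=False
    )
    _doc_tokens: Optional[dict[str, frozenset[str]]] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.species_tag not in SPECIES and self.species_tag != "humo":
            raise ValueError(f"unknown species tag {self.species_tag!r}")
        if self.tissue_tag not in TISSUES and self.tissue_tag != "all":
            raise ValueError(f"unknown tissue tag {self.tissue_tag!r}")

    @property
    def name(self) -> str:
        tissue = "All" if self.tissue_tag == "all" else self.tissue_tag.capitalize()
        if self.species_tag == "humo":
            return "HuMo" if self.tissue_tag == "all" else tissue + "HuMo"
        return tissue + _SPECIES_ABBREV[self.species_tag]

    @property
    def N(self) -> int:
        return len(self.documents)

    @property
    def dictionary(self) -> frozenset[str]:
        if self._dictionary is None:
            self._dictionary = frozenset().union(*self.doc_tokens.values()) \
                if self.documents else frozenset()
        return self._dictionary

    @property
    def doc_tokens(self) -> dict[str, frozenset[str]]:
        """Token set per member document, keyed by doc_id."""
        if self._doc_tokens is None:
            self._doc_tokens = {
                d.doc_id: frozenset(tokenize(d.text)) for d in self.documents
            }
        return self._doc_tokens

    def add(self, doc: DocumentRecord) -> None:
        if any(d.doc_id == doc.doc_id for d in self.documents):
            raise ValueError(f"duplicate doc_id {doc.doc_id!r} in {self.name}")
        self.documents.append(doc)
        self._dictionary = None
        self._doc_tokens = None


def build_dictionary(sub: Subcorpus) -> frozenset[str]:
    """The union of member documents' token sets (cached on the subcorpus)."""
    return sub.dictionary


def build_subcorpora(
    docs: Iterable[DocumentRecord], scheme: Optional[KeywordScheme] = None
) -> list[Subcorpus]:
    """Classify fused documents into one subcorpus per (species, tissue).

    Every pair of the scheme yields a subcorpus (possibly empty — some
    pairs, like choriocarcinoma x horse, are barely documented); a
    document may land in several subcorpora.  Order is deterministic:
    tissues in (tro, cho, ex) order within the canonical species order.
    """
    scheme = scheme or KeywordScheme.default()
    subs = {
        (sp, t): Subcorpus(species_tag=sp, tissue_tag=t)
        for sp in scheme.species_terms
        for t in scheme.tissue_patterns
    }
    for doc in docs:
        for pair in classify_document(doc, scheme):
            subs[pair].add(doc)
    ordered = sorted(
        subs.values(),
        key=lambda s: (SPECIES.index(s.species_tag), TISSUES.index(s.tissue_tag)),
    )
    return ordered
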
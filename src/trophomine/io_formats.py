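"""Readers and writers for every external format the pipeline touches.

The pipeline bridges bibliographic records (field-tagged MEDLINE-like and
WoS-like exports), tabular protein knowledge (accession, names, GO terms,
Pfam domains), homology-group tables, transcription-factor catalogs and
plain gene-symbol lists.  All dialects are deliberately minimal and strict:
they are documented here and in the README, round-trip byte-stably, and
reject rather than coerce anything outside the documented vocabulary.

Encoding is UTF-8 throughout; Greek letters and hyphens are preserved
verbatim at parse time (token normalization is the corpus module's job).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Optional, Union

import pandas as pd

logger = logging.getLogger(__name__)

#: Closed species vocabulary used across the whole pipeline.
SPECIES = ("bovine", "human", "mouse", "rat", "sheep", "pig", "horse")


class ParseError(ValueError):
    """Raised when an input stream violates its documented dialect."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DocumentRecord:
    """One bibliographic record (title/abstract pair with provenance)."""

    doc_id: str
    source: str  # "pubmed" | "wos"
    title: str = ""
    abstract: str = ""
    external_id: Optional[str] = None
    year: Optional[int] = None

    def __post_init__(self) -> None:
        if self.source not in ("pubmed", "wos"):
            raise ValueError(f"unknown source {self.source!r}")
        if not (self.title or self.abstract):
            raise ValueError("document needs a title or an abstract")

    @property
    def text(self) -> str:
        """Title and abstract joined; the unit of tokenization."""
        return f"{self.title} {self.abstract}".strip()


@dataclass
class ProteinRecord:
    """One protein entry: the bridging key between text and biology.

    The (gene name, protein accession) pair is the pipeline's unique gene
    key; synonyms matter because a gene name is not used consistently in
    the literature while the accession is unique.
    """

    accession: str
    entry_name: str
    species: str
    primary_name: str
    synonyms: frozenset[str] = frozenset()
    go_terms: frozenset[tuple[str, str]] = frozenset()  # (GO ID, label)
    pfam_domains: frozenset[str] = frozenset()
    reviewed: bool = True

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(
                f"species {self.species!r} outside the closed vocabulary {SPECIES}"
            )
        if not self.primary_name:
            raise ValueError(f"protein {self.accession}: empty primary name")
        self.synonyms = frozenset(self.synonyms)
        self.go_terms = frozenset(self.go_terms)
        self.pfam_domains = frozenset(self.pfam_domains)

    @property
    def names(self) -> frozenset[str]:
        """Primary name plus synonyms: all surface forms of the gene."""
        return frozenset({self.primary_name}) | self.synonyms


@dataclass
class HomologGroupTable:
    """Precomputed homology groups: shared group id implies homology."""

    rows: pd.DataFrame  # columns: group_id, species, gene_symbol, accession

    REQUIRED = ("group_id", "species", "gene_symbol", "accession")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.rows.columns]
        if missing:
            raise ParseError(f"homolog table missing columns {missing}")
        bad = set(self.rows["species"]) - set(SPECIES)
        if bad:
            raise ParseError(f"homolog table has unknown species {sorted(bad)}")
        key = self.rows[["group_id", "species", "accession"]]
        if key.duplicated().any():
            raise ParseError("duplicate (group_id, species, accession) row")

    def groups(self) -> Iterable[tuple[int, pd.DataFrame]]:
        return self.rows.groupby("group_id", sort=True)

    def __len__(self) -> int:
        return self.rows["group_id"].nunique()


@dataclass
class TFCatalog:
    """A curated catalog of human transcription-factor gene symbols.

    Optionally carries a family label per symbol (homeodomain, bHLH, ...)
    used to classify candidate TFs downstream.
    """

    symbols: frozenset[str]
    families: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.symbols = frozenset(s.upper() for s in self.symbols)
        self.families = {k.upper(): v for k, v in dict(self.families).items()}

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.symbols


# ---------------------------------------------------------------------------
# Field-tagged bibliographic dialects
# ---------------------------------------------------------------------------

# MEDLINE-like: "TAG - value", tag left-justified in 4 columns, continuation
# lines indented, records separated by one or more blank lines.
_MEDLINE_TAG = re.compile(r"^([A-Z][A-Z0-9]{1,3})\s*- (.*)$")
# WoS-like: two-letter tag, one space, value; continuation lines indented;
# "ER" closes a record, "EF" closes the file.
_WOS_TAG = re.compile(r"^([A-Z][A-Z0-9]) (.*)$")


def _read_text(stream: Union[str, IO[str]]) -> str:
    return stream if isinstance(stream, str) else stream.read()


def _finish_record(
    fields: dict[str, list[str]],
    source: str,
    id_tag: str,
    fallback_id: str,
) -> Optional[DocumentRecord]:
    def join(tag: str) -> str:
        return " ".join(" ".join(fields.get(tag, [])).split())

    title, abstract = join("TI"), join("AB")
    ext = join(id_tag) or None
    if not (title or abstract):
        logger.warning(
            "skipping %s record %s: no title and no abstract", source, ext or "?"
        )
        return None
    year = None
    dp = join("DP") or join("PY")
    if dp:
        m = re.match(r"(\d{4})", dp)
        year = int(m.group(1)) if m else None
    return DocumentRecord(
        doc_id=ext or fallback_id,
        source=source,
        title=title,
        abstract=abstract,
        external_id=ext,
        year=year,
    )


def read_medline(stream: Union[str, IO[str]]) -> list[DocumentRecord]:
    """Parse MEDLINE-like field-tagged text (PMID/TI/AB/DP tags).

    Records are separated by blank lines; wrapped field values continue on
    indented lines and are re-joined with single spaces.  A record lacking
    both TI and AB is skipped with a logged warning; a non-blank line that
    is neither a tag nor indented raises :class:`ParseError` naming the
    line number.
    """
    records: list[DocumentRecord] = []
    fields: dict[str, list[str]] = {}
    current: Optional[str] = None

    def flush() -> None:
        nonlocal fields, current
        if fields:
            rec = _finish_record(fields, "pubmed", "PMID", f"pubmed:{len(records) + 1}")
            if rec is not None:
                records.append(rec)
        fields, current = {}, None

    for lineno, line in enumerate(_read_text(stream).splitlines(), start=1):
        if not line.strip():
            flush()
            continue
        m = _MEDLINE_TAG.match(line)
        if m:
            current = m.group(1)
            fields.setdefault(current, []).append(m.group(2).strip())
        elif line[0].isspace() and current is not None:
            fields[current].append(line.strip())
        else:
            raise ParseError(f"line {lineno}: malformed tag line {line!r}")
    flush()
    return records


def read_wos(stream: Union[str, IO[str]]) -> list[DocumentRecord]:
    """Parse WoS-like field-tagged export text (UT/TI/AB/PY tags, ER ends
    a record).  Same skip/error semantics as :func:`read_medline`; no
    deduplication against other sources happens here.
    """
    records: list[DocumentRecord] = []
    fields: dict[str, list[str]] = {}
    current: Optional[str] = None

    def flush() -> None:
        nonlocal fields, current
        if fields:
            rec = _finish_record(fields, "wos", "UT", f"wos:{len(records) + 1}")
            if rec is not None:
                records.append(rec)
        fields, current = {}, None

    for lineno, line in enumerate(_read_text(stream).splitlines(), start=1):
        if not line.strip():
            continue
        if line.strip() in ("ER", "EF"):
            if line.strip() == "ER":
                flush()
            current = None
            continue
        m = _WOS_TAG.match(line)
        if m:
            current = m.group(1)
            fields.setdefault(current, []).append(m.group(2).strip())
        elif line[0].isspace() and current is not None:
            fields[current].append(line.strip())
        else:
            raise ParseError(f"line {lineno}: malformed tag line {line!r}")
    flush()
    return records


def write_medline(docs: Iterable[DocumentRecord], stream: IO[str]) -> None:
    """Write documents in the MEDLINE-like dialect (one line per field)."""
    for doc in docs:
        stream.write(f"PMID- {doc.external_id or doc.doc_id}\n")
        if doc.title:
            stream.write(f"TI  - {doc.title}\n")
        if doc.abstract:
            stream.write(f"AB  - {doc.abstract}\n")
        if doc.year is not None:
            stream.write(f"DP  - {doc.year}\n")
        stream.write("\n")


def write_wos(docs: Iterable[DocumentRecord], stream: IO[str]) -> None:
    """Write documents in the WoS-like dialect."""
    for doc in docs:
        stream.write(f"UT {doc.external_id or doc.doc_id}\n")
        if doc.title:
            stream.write(f"TI {doc.title}\n")
        if doc.abstract:
            stream.write(f"AB {doc.abstract}\n")
        if doc.year is not None:
            stream.write(f"PY {doc.year}\n")
        stream.write("ER\n\n")


# ---------------------------------------------------------------------------
# Tabular dialects (TSV through pandas)
# ---------------------------------------------------------------------------

_PROTEIN_COLUMNS = (
    "accession",
    "entry_name",
    "species",
    "primary_name",
    "synonyms",
    "go_terms",
    "pfam_domains",
    "reviewed",
)

# GO cells hold "GO:0003700 ! sequence-specific DNA binding transcription
# factor activity" entries, pipe-delimited; " ! " is the id/label separator.
_GO_SEP = " ! "


def _split_cell(cell: object) -> list[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return []
    return [part for part in str(cell).split("|") if part]


def read_protein_table(stream: Union[str, IO[str]]) -> list[ProteinRecord]:
    """Read the protein TSV: one row per protein, pipe-delimited multi-value
    cells (synonyms, GO terms, Pfam IDs).

    Unreviewed rows are kept but flagged (downstream analysis excludes them
    by default, keeping only well-described entries).  Unknown species or a
    duplicate accession is a hard error.
    """
    df = pd.read_csv(stream, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _PROTEIN_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"protein table missing columns {missing}")
    if df["accession"].duplicated().any():
        dupes = sorted(df.loc[df["accession"].duplicated(), "accession"])
        raise ParseError(f"duplicate accession(s) {dupes}")
    records = []
    for row in df.itertuples(index=False):
        go_terms = []
        for entry in _split_cell(row.go_terms):
            if _GO_SEP not in entry:
                raise ParseError(f"GO cell entry {entry!r} lacks {_GO_SEP!r}")
            go_id, label = entry.split(_GO_SEP, 1)
            go_terms.append((go_id.strip(), label.strip()))
        try:
            records.append(
                ProteinRecord(
                    accession=row.accession,
                    entry_name=row.entry_name,
                    species=row.species,
                    primary_name=row.primary_name,
                    synonyms=frozenset(_split_cell(row.synonyms)),
                    go_terms=frozenset(go_terms),
                    pfam_domains=frozenset(_split_cell(row.pfam_domains)),
                    reviewed=row.reviewed.strip().lower() in ("yes", "true", "1"),
                )
            )
        except ValueError as exc:
            raise ParseError(str(exc)) from exc
    return records


def write_protein_table(proteins: Iterable[ProteinRecord], stream: IO[str]) -> None:
    rows = []
    for p in proteins:
        rows.append(
            {
                "accession": p.accession,
                "entry_name": p.entry_name,
                "species": p.species,
                "primary_name": p.primary_name,
                "synonyms": "|".join(sorted(p.synonyms)),
                "go_terms": "|".join(
                    f"{gid}{_GO_SEP}{label}" for gid, label in sorted(p.go_terms)
                ),
                "pfam_domains": "|".join(sorted(p.pfam_domains)),
                "reviewed": "yes" if p.reviewed else "no",
            }
        )
    pd.DataFrame(rows, columns=list(_PROTEIN_COLUMNS)).to_csv(
        stream, sep="\t", index=False
    )


def read_homologene(stream: Union[str, IO[str]]) -> HomologGroupTable:
    """Read the homology-group TSV (group_id, species, gene_symbol,
    accession)."""
    df = pd.read_csv(stream, sep="\t", dtype=str, keep_default_na=False)
    if "group_id" in df.columns:
        df["group_id"] = df["group_id"].astype(int)
    return HomologGroupTable(df)


def write_homologene(table: HomologGroupTable, stream: IO[str]) -> None:
    table.rows.to_csv(stream, sep="\t", index=False)


def read_symbol_list(stream: Union[str, IO[str]]) -> set[str]:
    """Read a one-symbol-per-line list ('#' comments and blanks skipped).

    Symbols are uppercased; everything else about normalization (hyphen
    stripping, alias-group splitting) is the evaluation module's concern.
    """
    symbols = set()
    for line in _read_text(stream).splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            symbols.add(line.upper())
    return symbols


def read_tf_catalog(stream: Union[str, IO[str]]) -> TFCatalog:
    """Read a TF catalog: one symbol per line, optional tab-separated
    family label."""
    symbols, families = set(), {}
    for line in _read_text(stream).splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        symbol = parts[0].strip().upper()
        symbols.add(symbol)
        if len(parts) > 1 and parts[1].strip():
            families[symbol] = parts[1].strip()
    return TFCatalog(symbols=frozenset(symbols), families=families)


def write_ranked_list(scores: Iterable, stream: IO[str]) -> None:
    """Write a ranked gene list as TSV (rank, gene, presence, tf, idf, w).

    ``scores`` must already be sorted; byte output is deterministic for a
    fixed input.  Presence may be absent (tf-idf-only rankings) and is then
    written as an empty cell.
    """
    stream.write("rank\tgene\tpresence_score\ttf\tidf\tw\n")
    for s in scores:
        presence = getattr(s, "presence_score", None)
        stream.write(
            "\t".join(
                [
                    str(s.rank),
                    s.gene,
                    "" if presence is None else str(presence),
                    format(s.tf, ".10g"),
                    format(s.idf, ".10g"),
                    format(s.w, ".10g"),
                ]
            )
            + "\n"
        )


def read_ranked_list(stream: Union[str, IO[str]]) -> pd.DataFrame:
    """Read a ranked-list TSV back into a DataFrame (round-trip helper)."""
    return pd.read_csv(stream, sep="\t", dtype={"gene": str})


# Simple TSV container for document sets used as stage intermediates.
_DOC_COLUMNS = ("doc_id", "source", "external_id", "year", "title", "abstract")


def write_docs_tsv(docs: Iterable[DocumentRecord], stream: IO[str]) -> None:
    rows = [
        {
            "doc_id": d.doc_id,
            "source": d.source,
            "external_id": d.external_id or "",
            "year": "" if d.year is None else str(d.year),
            "title": d.title.replace("\t", " "),
            "abstract": d.abstract.replace("\t", " "),
        }
        for d in docs
    ]
    pd.DataFrame(rows, columns=list(_DOC_COLUMNS)).to_csv(stream, sep="\t", index=False)


def read_docs_tsv(stream: Union[str, IO[str]]) -> list[DocumentRecord]:
    df = pd.read_csv(stream, sep="\t", dtype=str, keep_default_na=False)
    return [
        DocumentRecord(
            doc_id=r.doc_id,
            source=r.source,
            title=r.title,
            abstract=r.abstract,
            external_id=r.external_id or None,
            year=int(r.year) if r.year else None,
        )
        for r in df.itertuples(index=False)
    ]
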
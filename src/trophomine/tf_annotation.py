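"""Transcription-factor annotation of candidate genes.

Two lines of evidence are combined (inclusive OR):

* **GO evidence** — the protein carries one of a short list of GO labels
  tied to transcription regulation (matched case-insensitively by label,
  not by GO id, since annotations are supplied as labels);
* **catalog evidence** — the gene's human homolog (through the homology
  map, or by direct symbol identity as fallback) appears in a curated
  human TF catalog.

GO annotation is incomplete and largely electronic, which is why the
curated catalog backs it up.  The "DNA binding" label is known to
over-call (histones bind DNA too); it stays in the default list but a
strict mode drops it.  Flagged TFs then receive a family label
(homeodomain, bHLH, GATA, ...) from a family table, with a
symbol-synonym fallback before giving up as "unclassified".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

from .homology import HomologyMap
from .io_formats import ProteinRecord, TFCatalog

#: GO labels accepted as evidence of transcription-factor activity.
DEFAULT_GO_EVIDENCE = (
    "sequence-specific DNA binding transcription factor activity",
    "transcription regulator activity",
    "bHLH transcription factor binding",
    "transcription activator activity",
    "DNA binding",
)

#: The over-calling label dropped by strict mode.
_BROAD_LABEL = "DNA binding"

UNCLASSIFIED = "unclassified"


def go_evidence_labels(strict: bool = False) -> tuple[str, ...]:
    if strict:
        return tuple(l for l in DEFAULT_GO_EVIDENCE if l != _BROAD_LABEL)
    return DEFAULT_GO_EVIDENCE


@dataclass(frozen=True)
class TFAnnotation:
    """TF verdict for one gene, with the evidence split out."""

    gene: str
    go_evidence: bool
    catalog_evidence: bool
    family: str = UNCLASSIFIED

    @property
    def is_tf(self) -> bool:
        return self.go_evidence or self.catalog_evidence


def go_tf_evidence(
    protein: ProteinRecord, evidence: Sequence[str] = DEFAULT_GO_EVIDENCE
) -> bool:
    """True iff any GO label of the protein (case-insensitive exact label
    match) is in the evidence list."""
    wanted = {label.lower() for label in evidence}
    return any(label.lower() in wanted for _, label in protein.go_terms)


def catalog_tf_evidence(
    gene: ProteinRecord,
    catalog: TFCatalog,
    homology: Optional[HomologyMap] = None,
    proteins_by_accession: Optional[Mapping[str, ProteinRecord]] = None,
) -> bool:
    """True iff a human homolog's symbol — or, as fallback, the gene's own
    symbol — is in the catalog.

    When the Pfam and group routes disagree on the human counterpart,
    ANY mapped human symbol in the catalog suffices (the evidence sources
    are unioned, not intersected).
    """
    if homology is not None and proteins_by_accession is not None:
        for acc in homology.foreign_accessions(gene.accession, "human"):
            human = proteins_by_accession.get(acc)
            if human is not None and human.primary_name.upper() in catalog:
                return True
    return gene.primary_name.upper() in catalog


def classify_family(
    symbol: str,
    families: Mapping[str, str],
    synonyms: Iterable[str] = (),
) -> str:
    """Family label for a flagged TF; synonyms are tried before giving up."""
    table = {k.upper(): v for k, v in families.items()}
    for name in [symbol, *synonyms]:
        label = table.get(name.upper())
        if label is not None:
            return label
    return UNCLASSIFIED


def annotate(
    genes: Sequence[ProteinRecord],
    catalog: TFCatalog,
    homology: Optional[HomologyMap] = None,
    proteins_by_accession: Optional[Mapping[str, ProteinRecord]] = None,
    go_evidence: Sequence[str] = DEFAULT_GO_EVIDENCE,
    families: Optional[Mapping[str, str]] = None,
) -> list[TFAnnotation]:
    """Annotate every gene; families only attach to flagged TFs."""
    families = dict(catalog.families if families is None else families)
    out = []
    for gene in genes:
        go_flag = go_tf_evidence(gene, go_evidence)
        cat_flag = catalog_tf_evidence(gene, catalog, homology, proteins_by_accession)
        family = UNCLASSIFIED
        if go_flag or cat_flag:
            family = classify_family(gene.primary_name, families, gene.synonyms)
        out.append(
            TFAnnotation(
                gene=gene.primary_name,
                go_evidence=go_flag,
                catalog_evidence=cat_flag,
                family=family,
            )
        )
    return out


def family_tally(
    annotations: Iterable[TFAnnotation],
) -> tuple[dict[str, int], Optional[int]]:
    """Per-family counts over flagged TFs, plus the classification rate.

    The rate is the integer percentage (half-up) of flagged TFs carrying a
    family label; it is None when no gene is flagged.  Counts (including
    the "unclassified" bucket) sum to the number of flagged TFs.
    """
    tally: Counter[str] = Counter()
    for ann in annotations:
        if ann.is_tf:
            tally[ann.family] += 1
    total = sum(tally.values())
    if total == 0:
        return {}, None
    classified = total - tally.get(UNCLASSIFIED, 0)
    rate = int(
        (Decimal(100) * classified / total).quantize(Decimal("1"), ROUND_HALF_UP)
    )
    return dict(tally), rate
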
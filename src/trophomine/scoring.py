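"""Gene ranking: boolean presence score and the tf-idf frequency score.

Presence score
    s_ij = 1 iff gene g_i occurs in the dictionary of subcorpus c_j; the
    row sum s_i0 counts the subcorpora mentioning the gene.  Genes seen in
    many subcorpora are broadly tied to the tissue/species space; the
    default shortlist keeps s_i0 >= 9 (a data-dependent cutoff, exposed as
    a parameter).

tf-idf score
    For gene i let n_ij be the document frequency in subcorpus j,
    n_i = sum_j n_ij, and SC_i = sum of N_j over the subcorpora where the
    gene occurs at least once.  Then

        tf_i  = n_i / SC_i
        idf_i = log(D / GF_i)
        w_i   = tf_i * idf_i

    with D the background-corpus size and GF_i the gene's background
    document frequency.  tf measures the gene's importance inside the
    subcorpora; idf down-weights genes ubiquitous in the background.  The
    log base is the natural log; any base > 1 produces the same ranking,
    so the choice is display-only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .corpus import Subcorpus
from .mentions import GeneLexicon, MentionIndex, gene_in_dictionary

logger = logging.getLogger(__name__)


@dataclass
class ScoreMatrix:
    """Boolean presence matrix s_ij with row sums s_i0.

    Rows (genes) are sorted by s_i0 decreasing, ties alphabetical; columns
    follow the supplied subcorpus order.
    """

    genes: list[str]
    subcorpora: list[str]
    s: np.ndarray  # shape (n_genes, n_subcorpora), dtype int8, values {0,1}

    def __post_init__(self) -> None:
        if self.s.shape != (len(self.genes), len(self.subcorpora)):
            raise ValueError("matrix shape does not match labels")
        if not np.isin(self.s, (0, 1)).all():
            raise ValueError("presence entries must be 0 or 1")

    @property
    def s_i0(self) -> dict[str, int]:
        return {g: int(row.sum()) for g, row in zip(self.genes, self.s)}

    def select(self, min_score: int = 9) -> list[str]:
        """Genes with s_i0 >= min_score, in matrix (rank) order."""
        return [g for g, row in zip(self.genes, self.s) if row.sum() >= min_score]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.s, index=self.genes, columns=self.subcorpora)
        df.index.name = "gene"
        df["s_i0"] = df.sum(axis=1)
        return df


def presence_matrix(
    genes: Sequence[GeneLexicon], subcorpora: Sequence[Subcorpus]
) -> ScoreMatrix:
    """Build the presence matrix against subcorpus dictionaries."""
    if not subcorpora:
        raise ValueError("at least one subcorpus is required")
    dictionaries = [sub.dictionary for sub in subcorpora]
    rows = {
        g.symbol: np.array(
            [1 if gene_in_dictionary(g, d) else 0 for d in dictionaries],
            dtype=np.int8,
        )
        for g in genes
    }
    order = sorted(rows, key=lambda sym: (-int(rows[sym].sum()), sym))
    return ScoreMatrix(
        genes=order,
        subcorpora=[sub.name for sub in subcorpora],
        s=np.array([rows[g] for g in order], dtype=np.int8)
        if order
        else np.empty((0, len(subcorpora)), dtype=np.int8),
    )


@dataclass(frozen=True)
class GeneScore:
    """One gene's frequency score and rank."""

    gene: str
    tf: float
    idf: float
    w: float
    rank: int
    presence_score: Optional[int] = None


def tfidf_scores(
    index: MentionIndex,
    subcorpora: Optional[Sequence[str]] = None,
    base: float = math.e,
) -> list[GeneScore]:
    """Score every indexed gene by w_i = tf_i * idf_i and rank descending.

    Genes never seen in the background (GF_i = 0) have an undefined idf
    and are excluded with a warning rather than smoothed — against a full
    bibliographic background every real gene name occurs at least once.
    Genes absent from every subcorpus (SC_i = 0) score 0 and rank last.
    Ties break by gene symbol ascending for reproducibility.
    """
    if base <= 1:
        raise ValueError("log base must exceed 1")
    names = list(subcorpora) if subcorpora is not None else sorted(index.N)
    scored: list[tuple[str, float, float, float]] = []
    for gene in index.genes():
        gf = index.GF.get(gene, 0)
        if gf > index.D:
            raise ValueError(f"GF[{gene}] = {gf} exceeds D = {index.D}")
        if gf == 0:
            logger.warning("gene %s absent from background corpus; excluded", gene)
            continue
        n_i = sum(index.n.get((gene, sub), 0) for sub in names)
        sc = sum(
            index.N.get(sub, 0) for sub in names if index.n.get((gene, sub), 0) >= 1
        )
        if sc == 0:
            scored.append((gene, 0.0, 0.0, 0.0))
            continue
        tf = n_i / sc
        idf = math.log(index.D / gf, base)
        scored.append((gene, tf, idf, tf * idf))
    scored.sort(key=lambda t: (-t[3], t[0]))
    return [
        GeneScore(gene=g, tf=tf, idf=idf, w=w, rank=i + 1)
        for i, (g, tf, idf, w) in enumerate(scored)
    ]


def rank_and_select(scores: Sequence[GeneScore], k: int) -> list[GeneScore]:
    """Top-k of an already scored list (stable; ties were broken at scoring)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    ordered = sorted(scores, key=lambda s: (-s.w, s.gene))
    return list(ordered[:k])
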
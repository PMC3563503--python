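"""trophomine: literature-mining prioritization of candidate transcription
factors for a non-model species.

The pipeline fuses bibliographic corpora (MEDLINE-like and WoS-like
exports) with protein/domain/homology tables, cuts the literature into
(species x tissue-keyword) subcorpora, detects gene mentions through
primary names and synonyms, ranks genes by a boolean presence score and a
tf-idf frequency score, flags transcription factors through GO evidence
and a curated human TF catalog projected through homology, and evaluates
recall against a gold-standard TF list.
"""

from importlib import resources

from .corpus import (
    KeywordScheme,
    Subcorpus,
    build_dictionary,
    build_subcorpora,
    classify_document,
    fuse_corpora,
    tokenize,
)
from .evaluation import (
    EvaluationReport,
    GoldStandard,
    cumulative_tf_curve,
    overlap_counts,
    recall,
)
from .fixtures import (
    FixtureBundle,
    FixtureConfig,
    PlantedGene,
    expected_ranking,
    generate_ecosystem,
    default_ecosystem_config,
)
from .homology import (
    HomologyMap,
    build_pfam_map,
    homologene_pairs,
    merge_homology,
    pfam_homologs,
)
from .io_formats import (
    SPECIES,
    DocumentRecord,
    HomologGroupTable,
    ProteinRecord,
    TFCatalog,
    read_homologene,
    read_medline,
    read_protein_table,
    read_symbol_list,
    read_tf_catalog,
    read_wos,
    write_ranked_list,
)
from .mentions import (
    GeneLexicon,
    MentionIndex,
    background_freq,
    build_mention_index,
    count_doc_freq,
    gene_in_dictionary,
    gene_in_document,
)
from .pipeline import RunConfig, run_all, run_stage
from .scoring import (
    GeneScore,
    ScoreMatrix,
    presence_matrix,
    rank_and_select,
    tfidf_scores,
)
from .tf_annotation import (
    DEFAULT_GO_EVIDENCE,
    TFAnnotation,
    annotate,
    catalog_tf_evidence,
    classify_family,
    family_tally,
    go_tf_evidence,
)

__version__ = "0.1.0"


def load_gold_standard() -> GoldStandard:
    """The shipped gold-standard TF list (printed table, verbatim)."""
    text = (
        resources.files("trophomine")
        .joinpath("data/gold_standard_tf.txt")
        .read_text()
    )
    return GoldStandard.from_symbols(read_symbol_list(text), source="shipped")


def load_tf_families() -> dict[str, str]:
    """The shipped minimal TF-family table (symbol -> family label)."""
    text = (
        resources.files("trophomine").joinpath("data/tf_families.tsv").read_text()
    )
    families = {}
    for line in text.splitlines():
        if line.strip() and not line.startswith("#"):
            symbol, family = line.split("\t")
            families[symbol.strip().upper()] = family.strip()
    return families
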
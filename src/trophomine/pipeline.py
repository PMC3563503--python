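"""Stage orchestration: corpora to homologs to scores to TF shortlists.

Six stages chain into the full workflow, each reading declared inputs,
writing TSV outputs plus a JSON manifest (config echo, SHA-256 of every
input, record counts at each filter step) into its own directory:

    build-corpus -> homologs -> mentions -> score -> annotate-tf -> evaluate

A stage whose upstream outputs are missing aborts with an error naming the
stage to run first.  Everything is deterministic: identical config and
inputs produce byte-identical output trees (manifests carry no
timestamps, all tables are written in sorted order).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import evaluation, homology, mentions, scoring, tf_annotation
from .corpus import KeywordScheme, Subcorpus, build_subcorpora, fuse_corpora
from .io_formats import (
    ProteinRecord,
    read_docs_tsv,
    read_homologene,
    read_medline,
    read_protein_table,
    read_symbol_list,
    read_tf_catalog,
    read_wos,
    write_docs_tsv,
    write_ranked_list,
)

logger = logging.getLogger(__name__)

STAGES = ("build-corpus", "homologs", "mentions", "score", "annotate-tf", "evaluate")

_STAGE_DIR = {
    "build-corpus": "corpus",
    "homologs": "homologs",
    "mentions": "mentions",
    "score": "score",
    "annotate-tf": "annotate",
    "evaluate": "evaluate",
}


class PipelineError(RuntimeError):
    pass


class MissingUpstreamError(PipelineError):
    """An earlier stage's outputs are absent."""

    def __init__(self, needed_stage: str, path: Path):
        self.needed_stage = needed_stage
        super().__init__(
            f"missing upstream output {path}; run stage {needed_stage!r} first"
        )


@dataclass
class RunConfig:
    """Paths, thresholds and switches for one pipeline run."""

    inputs: dict[str, str]
    outdir: str
    k: int = 50
    presence_cutoff: int = 9
    pfam_strict: bool = False
    strict_go: bool = False
    include_unreviewed: bool = False
    scheme: Optional[KeywordScheme] = None
    expression_sets: dict[str, str] = field(default_factory=dict)

    REQUIRED_INPUTS = ("pubmed", "wos", "proteins", "homologene", "tf_catalog", "background")

    def __post_init__(self) -> None:
        if self.k < 0 or self.presence_cutoff < 0:
            raise ValueError("thresholds must be non-negative")

    @staticmethod
    def from_yaml(path: Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        scheme = None
        if raw.get("scheme"):
            scheme = KeywordScheme(
                tissue_patterns={
                    k: tuple(v) for k, v in raw["scheme"]["tissue_patterns"].items()
                },
                species_terms={
                    k: tuple(v) for k, v in raw["scheme"]["species_terms"].items()
                },
            )
        params = raw.get("params", {})
        return RunConfig(
            inputs={k: str(v) for k, v in raw.get("inputs", {}).items()},
            outdir=str(raw["outdir"]),
            k=int(params.get("k", 50)),
            presence_cutoff=int(params.get("presence_cutoff", 9)),
            pfam_strict=bool(params.get("pfam_strict", False)),
            strict_go=bool(params.get("strict_go", False)),
            include_unreviewed=bool(params.get("include_unreviewed", False)),
            scheme=scheme,
            expression_sets={
                k: str(v) for k, v in raw.get("expression_sets", {}).items()
            },
        )

    def stage_dir(self, stage: str) -> Path:
        return Path(self.outdir) / _STAGE_DIR[stage]

    def input_path(self, name: str, required: bool = True) -> Optional[Path]:
        if name not in self.inputs:
            if required:
                raise PipelineError(f"config lacks required input {name!r}")
            return None
        path = Path(self.inputs[name])
        if not path.exists():
            raise PipelineError(f"input {name!r} does not exist: {path}")
        return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(
    stage: str, cfg: RunConfig, inputs: list[Path], counts: dict
) -> None:
    def label(p: Path) -> str:
        # outputs of earlier stages are recorded relative to the output
        # tree so that identical runs in different trees stay identical
        try:
            return str(p.resolve().relative_to(Path(cfg.outdir).resolve()))
        except ValueError:
            return str(p)

    manifest = {
        "stage": stage,
        "inputs": {label(p): _sha256(p) for p in sorted(inputs)},
        "params": {
            "k": cfg.k,
            "presence_cutoff": cfg.presence_cutoff,
            "pfam_strict": cfg.pfam_strict,
            "strict_go": cfg.strict_go,
            "include_unreviewed": cfg.include_unreviewed,
        },
        "counts": counts,
    }
    path = cfg.stage_dir(stage) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _require(cfg: RunConfig, stage: str, filename: str) -> Path:
    path = cfg.stage_dir(stage) / filename
    if not path.exists():
        raise MissingUpstreamError(stage, path)
    return path


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_build_corpus(cfg: RunConfig) -> None:
    """Parse both sources, fuse without duplicates, cut into subcorpora."""
    outdir = cfg.stage_dir("build-corpus")
    outdir.mkdir(parents=True, exist_ok=True)
    pubmed_path = cfg.input_path("pubmed")
    wos_path = cfg.input_path("wos")
    with open(pubmed_path) as fh:
        pubmed = read_medline(fh)
    with open(wos_path) as fh:
        wos = read_wos(fh)
    fused = fuse_corpora(pubmed, wos)
    subs = build_subcorpora(fused, cfg.scheme or KeywordScheme.default())
    with open(outdir / "fused_docs.tsv", "w") as fh:
        write_docs_tsv(fused, fh)
    with open(outdir / "membership.tsv", "w") as fh:
        fh.write("subcorpus\tdoc_id\n")
        for sub in subs:
            for doc in sorted(sub.documents, key=lambda d: d.doc_id):
                fh.write(f"{sub.name}\t{doc.doc_id}\n")
    with open(outdir / "subcorpora.tsv", "w") as fh:
        fh.write("name\tspecies\ttissue\tN\tdictionary_size\n")
        for sub in subs:
            fh.write(
                f"{sub.name}\t{sub.species_tag}\t{sub.tissue_tag}"
                f"\t{sub.N}\t{len(sub.dictionary)}\n"
            )
    _write_manifest(
        "build-corpus",
        cfg,
        [pubmed_path, wos_path],
        {
            "pubmed": len(pubmed),
            "wos": len(wos),
            "fused": len(fused),
            "subcorpora": len(subs),
        },
    )


def _load_subcorpora(cfg: RunConfig) -> list[Subcorpus]:
    docs_path = _require(cfg, "build-corpus", "fused_docs.tsv")
    members_path = _require(cfg, "build-corpus", "membership.tsv")
    table_path = _require(cfg, "build-corpus", "subcorpora.tsv")
    with open(docs_path) as fh:
        docs = {d.doc_id: d for d in read_docs_tsv(fh)}
    members = pd.read_csv(members_path, sep="\t", dtype=str)
    table = pd.read_csv(table_path, sep="\t", dtype=str)
    subs = []
    for row in table.itertuples(index=False):
        sub = Subcorpus(species_tag=row.species, tissue_tag=row.tissue)
        ids = members.loc[members["subcorpus"] == row.name, "doc_id"]
        for doc_id in ids:
            sub.add(docs[doc_id])
        subs.append(sub)
    return subs


def _load_proteins(cfg: RunConfig) -> list[ProteinRecord]:
    with open(cfg.input_path("proteins")) as fh:
        proteins = read_protein_table(fh)
    if not cfg.include_unreviewed:
        proteins = [p for p in proteins if p.reviewed]
    return proteins


def stage_homologs(cfg: RunConfig) -> None:
    """Pfam shared-domain homologs plus group homologs, merged with
    provenance."""
    outdir = cfg.stage_dir("homologs")
    outdir.mkdir(parents=True, exist_ok=True)
    proteins = _load_proteins(cfg)
    with open(cfg.input_path("homologene")) as fh:
        groups = read_homologene(fh)
    bovine = [
        p for p in proteins if p.species == "bovine" and p.pfam_domains
    ]
    pfam_map = homology.build_pfam_map(bovine, proteins, strict=cfg.pfam_strict)
    group_maps = [
        homology.homologene_pairs(groups, sp) for sp in homology.HOMOLOGENE_SPECIES
    ]
    merged = homology.merge_homology([pfam_map, *group_maps])
    by_acc = {p.accession: p for p in proteins}
    with open(outdir / "homology.tsv", "w") as fh:
        homology.write_homology_tsv(merged, by_acc, fh)
    _write_manifest(
        "homologs",
        cfg,
        [cfg.input_path("proteins"), cfg.input_path("homologene")],
        {
            "proteins": len(proteins),
            "bovine_with_domains": len(bovine),
            "pairs": len(merged),
            "partition": merged.partition_by_provenance(),
        },
    )


def stage_mentions(cfg: RunConfig) -> None:
    """Count per-subcorpus document frequencies, dictionary presence and
    background frequencies for every bovine gene with homologs."""
    outdir = cfg.stage_dir("mentions")
    outdir.mkdir(parents=True, exist_ok=True)
    homology_path = _require(cfg, "homologs", "homology.tsv")
    subs = _load_subcorpora(cfg)
    proteins = _load_proteins(cfg)
    by_acc = {p.accession: p for p in proteins}
    with open(homology_path) as fh:
        hmap = homology.read_homology_tsv(fh)
    gene_proteins = [by_acc[acc] for acc in sorted(hmap.pairs) if acc in by_acc]
    lexicons = [mentions.GeneLexicon.from_protein(p) for p in gene_proteins]
    with open(cfg.input_path("background")) as fh:
        background = read_medline(fh)
    index = mentions.build_mention_index(lexicons, subs, background)
    with open(outdir / "mention_counts.tsv", "w") as fh:
        fh.write("gene\tsubcorpus\tn_ij\n")
        for (gene, sub), n in sorted(index.n.items()):
            fh.write(f"{gene}\t{sub}\t{n}\n")
    with open(outdir / "presence.tsv", "w") as fh:
        fh.write("gene\tsubcorpus\ts_ij\n")
        for lex in sorted(lexicons, key=lambda l: l.symbol):
            for sub in subs:
                s = 1 if mentions.gene_in_dictionary(lex, sub.dictionary) else 0
                fh.write(f"{lex.symbol}\t{sub.name}\t{s}\n")
    with open(outdir / "background.tsv", "w") as fh:
        fh.write("gene\tGF\n")
        for gene, gf in sorted(index.GF.items()):
            fh.write(f"{gene}\t{gf}\n")
    _write_manifest(
        "mentions",
        cfg,
        [cfg.input_path("proteins"), cfg.input_path("background"), homology_path],
        {
            "genes": len(lexicons),
            "D": index.D,
            "subcorpora": {name: n for name, n in sorted(index.N.items())},
        },
    )


def _load_index(cfg: RunConfig) -> mentions.MentionIndex:
    counts_path = _require(cfg, "mentions", "mention_counts.tsv")
    background_path = _require(cfg, "mentions", "background.tsv")
    manifest_path = _require(cfg, "mentions", "manifest.json")
    counts = pd.read_csv(counts_path, sep="\t", dtype={"gene": str, "subcorpus": str})
    gf = pd.read_csv(background_path, sep="\t", dtype={"gene": str})
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    return mentions.MentionIndex(
        n={(r.gene, r.subcorpus): int(r.n_ij) for r in counts.itertuples(index=False)},
        GF={r.gene: int(r.GF) for r in gf.itertuples(index=False)},
        D=int(manifest["counts"]["D"]),
        N={k: int(v) for k, v in manifest["counts"]["subcorpora"].items()},
    )


def stage_score(cfg: RunConfig) -> None:
    """Presence matrix with its shortlist, and the tf-idf ranking."""
    outdir = cfg.stage_dir("score")
    outdir.mkdir(parents=True, exist_ok=True)
    presence_path = _require(cfg, "mentions", "presence.tsv")
    index = _load_index(cfg)
    presence = pd.read_csv(presence_path, sep="\t", dtype={"gene": str, "subcorpus": str})
    wide = presence.pivot(index="gene", columns="subcorpus", values="s_ij")
    sub_names = sorted(index.N)
    wide = wide.reindex(columns=sub_names)
    s_i0 = wide.sum(axis=1).astype(int)
    order = sorted(wide.index, key=lambda g: (-s_i0[g], g))
    matrix = scoring.ScoreMatrix(
        genes=list(order),
        subcorpora=sub_names,
        s=wide.loc[order].to_numpy(dtype="int8"),
    )
    matrix.to_frame().to_csv(outdir / "presence_matrix.tsv", sep="\t")
    selected = matrix.select(cfg.presence_cutoff)
    (outdir / "selected_presence.txt").write_text(
        "".join(g + "\n" for g in selected)
    )
    scores = scoring.tfidf_scores(index, subcorpora=sub_names)
    s_i0_map = matrix.s_i0
    scores = [
        dataclasses.replace(s, presence_score=s_i0_map.get(s.gene)) for s in scores
    ]
    with open(outdir / "ranked_tfidf.tsv", "w") as fh:
        write_ranked_list(scores, fh)
    top = scoring.rank_and_select(scores, cfg.k)
    (outdir / "top_tfidf.txt").write_text("".join(s.gene + "\n" for s in top))
    _write_manifest(
        "score",
        cfg,
        [presence_path],
        {
            "genes_scored": len(scores),
            "selected_presence": len(selected),
            "top_k": len(top),
        },
    )


def stage_annotate_tf(cfg: RunConfig) -> None:
    """Flag TFs among shortlisted genes (GO + catalog evidence) and attach
    family labels."""
    outdir = cfg.stage_dir("annotate-tf")
    outdir.mkdir(parents=True, exist_ok=True)
    selected_path = _require(cfg, "score", "selected_presence.txt")
    top_path = _require(cfg, "score", "top_tfidf.txt")
    homology_path = _require(cfg, "homologs", "homology.tsv")
    shortlist = sorted(
        set(selected_path.read_text().split()) | set(top_path.read_text().split())
    )
    proteins = _load_proteins(cfg)
    by_acc = {p.accession: p for p in proteins}
    by_name = {p.primary_name: p for p in proteins if p.species == "bovine"}
    with open(homology_path) as fh:
        hmap = homology.read_homology_tsv(fh)
    with open(cfg.input_path("tf_catalog")) as fh:
        catalog = read_tf_catalog(fh)
    genes = [by_name[g] for g in shortlist if g in by_name]
    annotations = tf_annotation.annotate(
        genes,
        catalog,
        homology=hmap,
        proteins_by_accession=by_acc,
        go_evidence=tf_annotation.go_evidence_labels(cfg.strict_go),
    )
    with open(outdir / "annotations.tsv", "w") as fh:
        fh.write("gene\tgo_evidence\tcatalog_evidence\tis_tf\tfamily\n")
        for ann in sorted(annotations, key=lambda a: a.gene):
            fh.write(
                f"{ann.gene}\t{int(ann.go_evidence)}\t{int(ann.catalog_evidence)}"
                f"\t{int(ann.is_tf)}\t{ann.family}\n"
            )
    tally, rate = tf_annotation.family_tally(annotations)
    with open(outdir / "family_tally.tsv", "w") as fh:
        fh.write("family\tcount\n")
        for family, count in sorted(tally.items()):
            fh.write(f"{family}\t{count}\n")
    _write_manifest(
        "annotate-tf",
        cfg,
        [cfg.input_path("tf_catalog"), homology_path, selected_path, top_path],
        {
            "shortlist": len(shortlist),
            "flagged_tf": sum(1 for a in annotations if a.is_tf),
            "classification_rate": rate,
        },
    )


def stage_evaluate(cfg: RunConfig) -> None:
    """Recall against the gold standard, cumulative-TF curve, overlaps."""
    outdir = cfg.stage_dir("evaluate")
    outdir.mkdir(parents=True, exist_ok=True)
    annotations_path = _require(cfg, "annotate-tf", "annotations.tsv")
    ranked_path = _require(cfg, "score", "ranked_tfidf.tsv")
    gold_path = cfg.input_path("gold_standard")
    with open(gold_path) as fh:
        gold_symbols = read_symbol_list(fh)
    if not gold_symbols:
        raise PipelineError("gold-standard list is empty; evaluation impossible")
    gold = evaluation.GoldStandard.from_symbols(gold_symbols)
    ann = pd.read_csv(annotations_path, sep="\t", dtype={"gene": str})
    tf_genes = set(ann.loc[ann["is_tf"] == 1, "gene"])
    report = evaluation.recall(tf_genes, gold)
    ranked = pd.read_csv(ranked_path, sep="\t", dtype={"gene": str})["gene"].tolist()
    curve = evaluation.cumulative_tf_curve(ranked, tf_genes)
    with open(outdir / "curve.tsv", "w") as fh:
        fh.write("rank\tcumulative_tf\n")
        for r, c in curve:
            fh.write(f"{r}\t{c}\n")
    overlaps = None
    if cfg.expression_sets:
        named: dict[str, set[str]] = {"predicted_tf": tf_genes}
        for label, path in sorted(cfg.expression_sets.items()):
            with open(path) as fh:
                named[label] = read_symbol_list(fh)
        overlaps = evaluation.overlap_counts(named)
    result = {
        "recall_percent": report.recall_percent,
        "gold_size": report.gold_size,
        "retrieved": sorted(report.retrieved),
        "missed": report.missed,
        "overlaps": overlaps,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(result, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_manifest(
        "evaluate",
        cfg,
        [gold_path, annotations_path, ranked_path],
        {"recall_percent": report.recall_percent, "missed": len(report.missed)},
    )


_STAGE_FUNCS = {
    "build-corpus": stage_build_corpus,
    "homologs": stage_homologs,
    "mentions": stage_mentions,
    "score": stage_score,
    "annotate-tf": stage_annotate_tf,
    "evaluate": stage_evaluate,
}


def run_stage(stage: str, cfg: RunConfig) -> None:
    if stage not in _STAGE_FUNCS:
        raise PipelineError(f"unknown stage {stage!r}; stages are {STAGES}")
    logger.info("running stage %s", stage)
    _STAGE_FUNCS[stage](cfg)


def run_all(cfg: RunConfig, evaluate: Optional[bool] = None) -> None:
    """Run every stage in order; evaluation runs when a gold standard is
    configured (or when explicitly requested)."""
    if evaluate is None:
        evaluate = "gold_standard" in cfg.inputs
    for stage in STAGES:
        if stage == "evaluate" and not evaluate:
            continue
        run_stage(stage, cfg)
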
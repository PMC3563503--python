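# trophomine

Literature-mining prioritization of candidate transcription factors (TFs)
for a non-model species.

Ruminant embryos elongate before implantation — a developmental process
absent in mice and humans — yet most of what is known about trophoblast
proliferation and differentiation comes from human and mouse literature.
`trophomine` transfers that knowledge: it fuses bibliographic corpora with
protein/domain/homology tables, cuts the literature into
(species × tissue-keyword) subcorpora, detects gene mentions through
primary names and synonyms, ranks genes by two scores, flags TFs, and
measures recall against a gold-standard TF list.  It is aimed at
researchers in livestock regulatory genomics who need a short, defensible
candidate-gene list before committing to experiments.

## Method

1. **Corpora.** MEDLINE-like and WoS-like exports are parsed, fused
   without duplicates (shared id, else title equality; the PubMed copy
   wins), and classified into subcorpora by keyword: seven species terms
   (bovine, human, mouse, rat, sheep, pig, horse) × three tissue patterns
   (`trophoblast*`, `choriocarcinoma*`, `extra-embryonic*`/
   `extraembryonic*`) — 21 subcorpora.  Each subcorpus *j* has a size
   *N<sub>j</sub>* and a dictionary: the set of normalized tokens of its
   documents.
2. **Homologs.** A foreign protein is a *Pfam homolog* of a bovine
   protein when it carries **all** of the bovine protein's Pfam domains;
   homology-group tables (HomoloGene-style) contribute pairs by shared
   group membership.  The two maps merge with per-pair provenance.
3. **Mentions.** A gene is present wherever all tokens of any of its name
   variants (primary name + synonyms) occur.  Per-subcorpus document
   frequencies *n<sub>ij</sub>* and a background frequency
   *GF<sub>i</sub>* over a background corpus of *D* documents are
   counted.
4. **Scores.** The presence score *s<sub>i0</sub>* = number of subcorpus
   dictionaries containing gene *i* (shortlist default
   *s<sub>i0</sub>* ≥ 9).  The frequency score is a tf-idf variant:

   tf<sub>i</sub> = n<sub>i</sub> / SC<sub>i</sub>,  with
   n<sub>i</sub> = Σ<sub>j</sub> n<sub>ij</sub> and
   SC<sub>i</sub> = Σ N<sub>j</sub> over subcorpora where
   n<sub>ij</sub> ≥ 1;
   idf<sub>i</sub> = ln(D / GF<sub>i</sub>);
   **w<sub>i</sub> = tf<sub>i</sub> · idf<sub>i</sub>**.

5. **TF annotation.** A shortlisted gene is flagged as a TF when it
   carries one of five GO evidence labels (e.g. "sequence-specific DNA
   binding transcription factor activity", "DNA binding") **or** when its
   human homolog appears in a curated human TF catalog; flagged TFs get a
   family label (homeodomain, bHLH, ...) where known.
6. **Evaluation.** Recall against a gold-standard symbol list (alias
   groups like `ASCL2/MASH2` count once), the cumulative-TF curve along a
   ranking, and Venn-region overlaps with expression datasets.

## Worked example

The package ships a synthetic ecosystem generator whose planted signal is
recoverable end to end.  Generate it and run the whole pipeline:

```sh
trophomine simulate --seed 1 --outdir demo
trophomine run-all --config demo/run_config.yaml
```

`demo/run/score/ranked_tfidf.tsv` then begins:

```
rank	gene	presence_score	tf	idf	w
1	TFALPHA	11	0.8811369509	6.214608098	5.475920831
2	TFBETA	11	0.7700258398	5.80914299	4.47319021
3	TFGAMMA	11	0.7416020672	5.298317367	3.929243112
4	TFDELTA	11	0.5839793282	4.828313737	2.819635412
5	TFEPSIL	11	0.4909560724	4.605170186	2.260936267
6	GKINA	10	0.4319371728	2.995732274	1.293968129
```

The five planted TFs were seeded with per-document mention probabilities
0.9 … 0.5 across 11 subcorpora and background fractions ≤ 1%: the
empirical tf column recovers those probabilities and the tf-idf order
matches the analytic expectation (rare-in-background genes outrank common
ones at equal corpus frequency).  `demo/run/evaluate/report.json` shows

```json
{"gold_size": 4, "missed": [], "recall_percent": 100.0,
 "retrieved": ["TFALPHA", "TFBETA", "TFDELTA", "TFGAMMA"]}
```

— all four planted gold-standard TFs are recovered (100% recall).  Each
stage directory also carries a `manifest.json` with input hashes and
filter-step counts; identical inputs and config give byte-identical
output trees.

Stages can equally be run one at a time (`build-corpus`, `homologs`,
`mentions`, `score`, `annotate-tf`, `evaluate`), and the whole library is
importable (`import trophomine`).

## File dialects

All inputs are plain text, documented minimally rather than as full
vendor formats: field-tagged bibliographic records (MEDLINE-like
`PMID`/`TI`/`AB` with indented continuations; WoS-like `UT`/`TI`/`AB`
ending in `ER`), TSV tables for proteins (pipe-delimited synonym/GO/Pfam
cells), homology groups, and one-symbol-per-line lists for TF catalogs
and gold standards.  A reference gold-standard TF list and a minimal
TF-family table ship under `src/trophomine/data/`.

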
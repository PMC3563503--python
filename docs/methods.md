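# Methods

## Problem and model

The pipeline is a recall-oriented candidate screen: given (i) bibliographic
corpora about trophoblast / extra-embryonic / choriocarcinoma biology in
seven mammalian species, (ii) protein knowledge (names, synonyms, GO
labels, Pfam domains) and homology-group tables, and (iii) a curated human
TF catalog, it produces a ranked list of bovine genes likely to act in
trophoblast development and flags which of them are transcription factors.
The modelling assumption throughout is functional transfer by shared
protein domains: proteins of closely related species carrying the same
Pfam domain set are treated as performing the same function, regardless of
whether they are orthologs or paralogs (no ortholog/paralog field exists
anywhere in the code — the distinction is disregarded by construction).

## Pipeline stages and their parameters

**Corpus building.** Documents are tokenized by a fully specified rule:
lowercase; a token is a run of letters/digits with internal hyphens
(`extra-embryonic`, `c-fos` are single tokens); everything else separates;
no stemming.  Classification into subcorpora requires one token matching a
tissue pattern (trailing `*` = prefix match) and one matching a species
literal, searched in title plus abstract (whether the original keyword
matching used titles, abstracts or both was an open choice; both is used
and the scheme is configurable).  Fusion deduplicates by shared external
id, else by case-folded punctuation-stripped title, keeping the PubMed
copy — the PMID is the stabler key.  Merged human–mouse corpora built from
topic queries can be supplied as pre-built document files (species tag
`humo`); their retrieval-side query semantics (MeSH limits) are not
re-implemented.

**Homology.** "Shares all the Pfam domains" is implemented as a superset
rule (candidate domains ⊇ bovine domains): a protein carrying the bovine
domains plus extras still shares all of them, and the motivating
one-domain example counts every carrier of the domain.  A strict-equality
mode is exposed (`pfam_strict`).  Domains are sets, not multisets: Pfam
IDs act as functional labels, and repeat counts add nothing under that
reading.  Group-based homologs come only from human, mouse and rat —
the only species whose groups overlap the bovine ones; requesting others
returns an empty map with a warning.  Merged maps keep per-pair
provenance so Pfam-only / shared / group-only partitions stay reportable.

**Mentions.** Multi-token name variants match by bag-of-words (all tokens
present), not adjacency — dictionaries are token sets and cannot encode
adjacency; this is a documented false-positive source.  Matching is on
lowercased tokens.  Ambiguous short synonyms are not specially treated; a
configurable stop-list exists and defaults to empty.  n_i in the tf
formula is Σ_j n_ij over subcorpora: a document belonging to several
subcorpora counts once per subcorpus, following the per-subcorpus counting
loop of the scoring algorithm.

**Scoring.** tf_i = n_i / SC_i with SC_i the summed sizes of only those
subcorpora where the gene occurs at least once; idf_i = ln(D / GF_i);
w_i = tf_i · idf_i.  The log base is mathematically irrelevant to the
ranking (w scales by a positive constant), which is property-tested; the
natural log is used for display.  Genes with GF_i = 0 have undefined idf
and are excluded with a warning rather than smoothed: against a real
bibliographic background every gene name occurs at least once, so
smoothing would only mask broken inputs.  Genes absent from every
subcorpus score 0 and rank last.  Ties break by gene symbol ascending,
for reproducibility.  The presence-score shortlist cutoff (s_i0 ≥ 9) and
the top-k size (k = 50) are config defaults, not constants — both were
data-dependent choices in the original setting.

**TF annotation.** GO evidence is matched by label string (the evidence
list is given as labels), case-insensitively and exactly; an optional
label→ID map can be supplied.  The "DNA binding" label over-calls
(histones bind DNA); it stays in the default evidence list, and
`strict_go` drops it.  Catalog evidence projects through the homology
map: if ANY mapped human symbol is in the catalog the gene is flagged
(inclusive OR — evidence sources are unioned), with direct symbol
identity as fallback.  Family classification tries the symbol, then its
synonyms, then gives up as "unclassified"; the classification rate is the
integer percentage (half-up) of flagged TFs with a family.

**Evaluation.** Gold symbols normalize to uppercase with hyphens stripped
(so `c-fos` matches `CFOS`), and `/`-joined aliases form one entry
retrieved by any alias.  Recall is reported to one decimal, half-up.
The shipped gold-standard file (`data/gold_standard_tf.txt`) transcribes
the printed reference table verbatim: 65 cells, one alias group, although
the accompanying text counts 64 — and the published recall percentages
are arithmetically consistent only with 64.  The file is not silently
corrected; the worked examples in the acceptance checks use the 64-entry
set obtained by excluding SPARC, the one table entry that is canonically
a matricellular protein rather than a TF (the discrepancy is documented
in the file header).  Only recall is reported: precision against an
open-ended literature is not measurable, and no enrichment statistics are
attached to Venn regions.

## Synthetic ecosystem

The generator emulates every input the pipeline reads: field-tagged
corpora for both sources with a configurable duplicate fraction (10% of
documents appear in both, detectable only by title), protein tables whose
planted cross-species groups share exact domain sets, a consistent
homology-group table, a background corpus in which each planted gene's
document frequency is realized exactly (max(1, round(fraction · D))), and
a TF catalog with decoys plus a planted gold standard.

It deliberately does **not** emulate: natural language (abstracts are
token soup — sufficient because all computation is token-set based),
name ambiguity between genes and English words, cross-species symbol
drift, OCR/encoding noise, or realistic vocabulary growth.  Passing tests
therefore demonstrate correctness of the mechanics and recoverability of
planted signal, not robustness to the messiness of real gene-name
matching — the known weak point of dictionary approaches.

The shipped configuration (`default_ecosystem_config`) mirrors the published
7×3 subcorpus structure with the same size *ratios* scaled to ≈400
documents (the published absolute counts are snapshot-dependent and a
non-goal), a 1,000-document background, and nine planted genes: five TFs
with strong signal (mention probability 0.9–0.5 across the 11
best-documented subcorpora, background fraction ≤ 1%) and four non-TFs
with weaker, commoner signal.  Expected tf equals the planted mention
probability; expected idf is exact; the nine expected w values are well
separated (5.59 down to 0.12), so the analytic order is recoverable.
These sizes keep a full pipeline run under ~2 s and the 100-replicate
ordering study under ~20 s on one CPU.

## Numerical and degenerate-input choices

- Recall and the classification rate round half-up (decimal arithmetic,
  not binary-float `round`), matching the one-decimal / integer-percent
  reporting style.
- Empty corpora are valid: zero-document subcorpora exist (some
  (species, tissue) pairs are barely documented), empty rankings are
  returned, and an empty gold standard is a hard error only when
  evaluation is requested.
- A bovine protein without Pfam domains is a precondition error for the
  domain rule; callers filter such proteins out (not every protein is
  described by a domain).
- Determinism is a contract: the only randomness anywhere is the seeded
  generator in the fixtures module; stage outputs are written in sorted
  order and manifests carry content hashes, never timestamps.  Manifest
  input paths under the output tree are recorded relative to it so that
  identical runs in different directories produce identical bytes.

## Known limitations

- Dictionary matching cannot disambiguate gene symbols that are common
  words or shared across genes; the stop-list is a manual escape hatch.
- The superset domain rule inherits Pfam's granularity: promiscuous
  single-domain architectures yield many homologs per bovine protein.
- GO-label matching is brittle against ontology relabeling; supplying a
  label→ID map is recommended for current-day GO releases.
- The evaluation assumes symbol-level identity after normalization;
  species-specific symbol drift (the published missed-gene causes) is out
  of scope for the matcher itself.
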
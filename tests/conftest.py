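"""Shared fixtures: hand-built field-tagged records and a small synthetic
ecosystem used across the suite."""

from __future__ import annotations

import pytest

import trophomine as tm

MEDLINE_TWO_RECORDS = """\
PMID- 11111111
TI  - Bovine trophoblast development in the elongating conceptus
AB  - The trophoblast of the bovine conceptus elongates before
      implantation and mediates maternal exchange.
DP  - 2009 Jan

PMID- 22222222
TI  - GATA3 in human choriocarcinoma cell lines
AB  - Expression of GATA3 was measured in JEG-3 cells derived
      from a human choriocarcinoma.
DP  - 2010
"""

WOS_THREE_RECORDS = """\
UT WOS:000100000001
TI Extra-embryonic tissues of the sheep conceptus
AB Extraembryonic membranes were sampled from sheep.
PY 2008
ER

UT WOS:000100000002
TI Bovine trophoblast development in the elongating conceptus
AB The trophoblast of the bovine conceptus elongates before implantation.
PY 2009
ER

UT WOS:000100000003
TI Mouse trophoblastic stem cells
AB Trophoblastic differentiation in the mouse embryo.
PY 2011
ER
"""

PROTEIN_TABLE = """\
accession\tentry_name\tspecies\tprimary_name\tsynonyms\tgo_terms\tpfam_domains\treviewed
P32234\tACOD_BOVIN\tbovine\tACOD\tSCD5\tGO:0016491 ! oxidoreductase activity\tPF00487\tyes
P23771\tGATA3_HUMAN\thuman\tGATA3\tGATA-binding factor 3\tGO:0003700 ! sequence-specific DNA binding transcription factor activity\tPF00320\tyes
Q95M44\tHAND1_BOVIN\tbovine\tHAND1\t\tGO:0003700 ! sequence-specific DNA binding transcription factor activity\tPF00010\tyes
O00000\tFAKE_MOUSE\tmouse\tFAKE1\t\t\t\tno
"""


@pytest.fixture(scope="session")
def small_config() -> tm.FixtureConfig:
    """A compact planted ecosystem: 4 genes, 6 busy subcorpora."""
    targets = (
        ("bovine", "tro"),
        ("human", "tro"),
        ("human", "cho"),
        ("mouse", "tro"),
        ("mouse", "ex"),
        ("rat", "tro"),
    )
    planted = (
        tm.PlantedGene("TFAA", targets, 0.9, 0.01),
        tm.PlantedGene("TFBB", targets, 0.6, 0.05),
        tm.PlantedGene("GCCC", targets, 0.3, 0.2),
        tm.PlantedGene("GDDD", (), 0.0, 0.5),
    )
    n_docs = {pair: 20 for pair in targets}
    n_docs[("sheep", "tro")] = 5
    return tm.FixtureConfig(
        seed=7,
        n_species_proteins={sp: 2 for sp in tm.SPECIES},
        n_domains=30,
        n_docs=n_docs,
        planted_genes=planted,
        fraction_tf=0.5,
        gold_subset_size=2,
        background_size=300,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config) -> tm.FixtureBundle:
    return tm.generate_ecosystem(small_config)


@pytest.fixture(scope="session")
def small_subcorpora(small_bundle):
    from trophomine.fixtures import subcorpora_from_bundle

    return subcorpora_from_bundle(small_bundle)
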
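"""Shipped vocabularies and the golden derivation fixture.

Three small TSVs ship with the package: the disease / pathological-observation
/ brain-region vocabulary (13 + 44 + 26 concepts), the 25-protein candidate
table used as the protein vocabulary, and the default relation lexicon.  On
top of those, :func:`golden_truth` plants an assertion set engineered so the
derivation chain runs 40 → 30 → 25: forty proteins carry region-expression
evidence, thirty of those carry upregulation-in-disease evidence, and exactly
the twenty-five vocabulary proteins carry pathology links.  The fifteen extra
expressed proteins — and ten more decoys that are upregulated or
pathology-linked but fail an earlier gate — are synthetic filler concepts
(``SYNPROT01``...) that exist only to exercise the filters.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .derivation import DerivationConfig
from .network import (
    AssertionRecord,
    IntelligenceNetwork,
    Provenance,
    Status,
    merge_assertions,
)
from .vocabulary import (
    Concept,
    ConceptType,
    RelationLexicon,
    Vocabulary,
    load_relation_lexicon,
    load_vocabulary,
    slugify,
)

__all__ = [
    "data_path",
    "load_table_vocabulary",
    "load_protein_vocabulary",
    "load_default_relations",
    "default_vocabulary",
    "protein_symbols",
    "filler_proteins",
    "golden_vocabulary",
    "golden_truth",
    "golden_network",
    "golden_derivation_config",
    "ALZHEIMERS_ID",
]

ALZHEIMERS_ID = slugify("Alzheimer's Disease")

_N_FILLER = 35
_N_EXPRESSED_FILLER = 15  # expressed in regions (step 1 passers beyond the 25)
_N_UPREGULATED_FILLER = 5  # also upregulated (step 2 passers beyond the 25)


def data_path(name: str) -> Path:
    return Path(str(resources.files("assertnet").joinpath("data", name)))


def load_table_vocabulary() -> Vocabulary:
    """Disease sub-types, pathological observations and brain regions."""
    return load_vocabulary(data_path("table1_vocabulary.tsv"))


def load_protein_vocabulary() -> Vocabulary:
    """The 25 candidate proteins (symbol ids, alias synonyms)."""
    return load_vocabulary(data_path("table3_proteins.tsv"))


def load_default_relations() -> RelationLexicon:
    return load_relation_lexicon(data_path("relations.tsv"))


def default_vocabulary() -> Vocabulary:
    return load_table_vocabulary().merged(load_protein_vocabulary())


def protein_symbols() -> list[str]:
    return sorted(load_protein_vocabulary().concepts)


def filler_proteins(n: int = _N_FILLER) -> list[Concept]:
    """Synthetic filler protein concepts used only to exercise the filters."""
    return [
        Concept(f"SYNPROT{i:02d}", ConceptType.PROTEIN_OR_MRNA, f"SYNPROT{i:02d}",
                frozenset({f"SYNPROT{i:02d}"}))
        for i in range(1, n + 1)
    ]


def golden_vocabulary() -> Vocabulary:
    vocab = default_vocabulary()
    for c in filler_proteins():
        vocab.add(c)
    return vocab


def golden_truth() -> list[tuple[str, str, str, str]]:
    """Canonical truth triples realising the engineered 40 → 30 → 25 chain."""
    vocab = golden_vocabulary()
    symbols = protein_symbols()
    fillers = [c.concept_id for c in filler_proteins()]
    regions = sorted(
        cid for cid, c in vocab.concepts.items()
        if c.type == ConceptType.ANATOMICAL_STRUCTURE
    )
    pathologies = sorted(
        cid for cid, c in vocab.concepts.items()
        if c.type == ConceptType.PATHOLOGICAL_OBSERVATION
    )

    expressed = symbols + fillers[:_N_EXPRESSED_FILLER]  # 40
    upregulated = symbols + fillers[:_N_UPREGULATED_FILLER]  # 30
    pathology_linked = list(symbols)  # 25

    truth: list[tuple[str, str, str, str]] = []
    for i, p in enumerate(expressed):
        truth.append((p, "EXPRESSION", "IS EXPRESSED IN", regions[i % len(regions)]))
    for p in upregulated:
        truth.append((p, "UPREGULATION", "IS INCREASED IN", ALZHEIMERS_ID))
    for i, p in enumerate(pathology_linked):
        truth.append(
            (p, "PATHOLOGY_LINK", "IS INVOLVED IN", pathologies[i % len(pathologies)])
        )
    # decoys failing an earlier gate: upregulated but not expressed,
    # pathology-linked but not upregulated
    for p in fillers[_N_EXPRESSED_FILLER:_N_EXPRESSED_FILLER + 5]:
        truth.append((p, "UPREGULATION", "IS INCREASED IN", ALZHEIMERS_ID))
    for i, p in enumerate(fillers[_N_EXPRESSED_FILLER + 5:_N_EXPRESSED_FILLER + 10]):
        truth.append((p, "PATHOLOGY_LINK", "IS INVOLVED IN", pathologies[i]))
    return truth


def _biomarker_claims() -> list[tuple[str, str, str, str]]:
    """Existing biomarker-claim links for every candidate except PLAUR and CHAT."""
    return [
        (p, "DISEASE_LINK", "IS BIOMARKER FOR", ALZHEIMERS_ID)
        for p in protein_symbols()
        if p not in {"PLAUR", "CHAT"}
    ]


def golden_network(insertion_order: list[int] | None = None) -> IntelligenceNetwork:
    """The golden fixture network (assertions + tagged biomarker claims).

    ``insertion_order`` permutes assertion insertion, which must not change
    any derived output.
    """
    records = []
    for i, (s, cls, rel, o) in enumerate(golden_truth()):
        source = "GEO" if cls == "EXPRESSION" else "PubMed"
        records.append(
            AssertionRecord(
                s, cls, rel, o, Status.ACCEPTED,
                Provenance(source, f"golden-{i:04d}", 0, f"{s} {rel} {o}"),
            )
        )
    for j, (s, cls, rel, o) in enumerate(_biomarker_claims()):
        records.append(
            AssertionRecord(
                s, cls, rel, o, Status.ACCEPTED,
                Provenance("Telemakus", f"claim-{j:04d}", 0, f"{s} {rel} {o}"),
            )
        )
    if insertion_order is not None:
        records = [records[i] for i in insertion_order]
    return merge_assertions(IntelligenceNetwork(golden_vocabulary()), records)


def golden_derivation_config(
    vocab: Vocabulary | None = None,
    biomarker_claim_sources: frozenset[str] | None = frozenset({"Telemakus"}),
) -> DerivationConfig:
    """Default filter-chain configuration over the shipped vocabularies."""
    vocab = vocab if vocab is not None else golden_vocabulary()
    by_type: dict[ConceptType, set[str]] = {t: set() for t in ConceptType}
    for cid, c in vocab.concepts.items():
        by_type[c.type].add(cid)
    return DerivationConfig(
        region_ids=frozenset(by_type[ConceptType.ANATOMICAL_STRUCTURE]),
        disease_ids=frozenset(by_type[ConceptType.DISEASE]),
        pathology_ids=frozenset(
            by_type[ConceptType.PATHOLOGICAL_OBSERVATION]
            | by_type[ConceptType.BIOLOGICAL_PROCESS]
        ),
        biomarker_claim_sources=biomarker_claim_sources,
    )
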
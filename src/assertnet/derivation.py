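"""Candidate-biomarker derivation: the three-stage filter chain over the network.

The chain asks three questions of every protein/mRNA concept, in order:

1. is it expressed in a brain region of relevance to the disease
   (≥1 EXPRESSION assertion whose object is a configured region)?
2. is there evidence of upregulation in the disease
   (≥1 UPREGULATION assertion whose object is a configured disease id)?
3. is it linked to a pathological hallmark
   (≥1 PATHOLOGY_LINK assertion whose object is a configured pathology id)?

Each step is a subset of the previous one, so the per-step counts form a
monotone chain.  Surviving proteins are then assessed for novelty: a protein
is novel when no disease-link assertion from a source tagged as making
biomarker claims already ties it to the disease.  When no sources are tagged
the novelty verdict is *indeterminate* rather than a silent "novel".
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

from .network import IntelligenceNetwork, query_assertions
from .vocabulary import AssertnetError, ConceptType

__all__ = [
    "DerivationError",
    "DerivationConfig",
    "CandidateTable",
    "Candidate",
    "proteins_in_regions",
    "filter_upregulated",
    "filter_pathology_associated",
    "assess_novelty",
    "derive_candidates",
]


class DerivationError(AssertnetError):
    """Invalid derivation configuration."""


@dataclasses.dataclass(frozen=True)
class DerivationConfig:
    """Concept-id sets parameterising the filter chain.

    ``biomarker_claim_sources`` names provenance sources whose disease links
    count as existing biomarker claims; ``None`` means the network is untagged
    and novelty cannot be decided.  ``min_support`` is the evidence threshold
    per criterion (assertion count; existence, i.e. 1, by default).
    """

    region_ids: frozenset[str]
    disease_ids: frozenset[str]
    pathology_ids: frozenset[str]
    biomarker_claim_sources: frozenset[str] | None = None
    min_support: int = 1

    def validate(self, net: IntelligenceNetwork) -> None:
        for name, ids in (
            ("region_ids", self.region_ids),
            ("disease_ids", self.disease_ids),
            ("pathology_ids", self.pathology_ids),
        ):
            if not ids:
                raise DerivationError(f"{name} must be non-empty")
            unknown = {i for i in ids if i not in net.vocab}
            if unknown:
                raise DerivationError(f"{name} not in network: {sorted(unknown)}")
        if self.min_support < 1:
            raise DerivationError("min_support must be >= 1")


@dataclasses.dataclass(frozen=True)
class Candidate:
    protein_id: str
    expression_keys: tuple[tuple[str, str, str], ...]
    upregulation_keys: tuple[tuple[str, str, str], ...]
    pathology_keys: tuple[tuple[str, str, str], ...]
    known_biomarker_count: int | None  # None when indeterminate
    novel: bool | None


@dataclasses.dataclass(frozen=True)
class CandidateTable:
    """Ordered filter-chain audit plus the final candidate list."""

    steps: tuple[tuple[str, frozenset[str], int], ...]
    candidates: tuple[Candidate, ...]

    @property
    def step_counts(self) -> tuple[int, ...]:
        return tuple(n for _, _, n in self.steps)


def _support(
    net: IntelligenceNetwork,
    relation_class: str,
    subject_ids: Iterable[str],
    object_ids: frozenset[str],
) -> dict[str, list[tuple[str, str, str]]]:
    """Per-subject supporting triple keys for one filter criterion."""
    subject_ids = set(subject_ids)
    hits: dict[str, list[tuple[str, str, str]]] = {}
    for a in query_assertions(
        net, relation_class=relation_class, object_ids=set(object_ids)
    ):
        if a.subject_id in subject_ids:
            hits.setdefault(a.subject_id, []).append(a.triple)
    return hits


def proteins_in_regions(
    net: IntelligenceNetwork, config: DerivationConfig
) -> frozenset[str]:
    """Protein/mRNA concepts expressed in at least one configured region."""
    config.validate(net)
    proteins = {
        cid for cid, c in net.concepts.items() if c.type == ConceptType.PROTEIN_OR_MRNA
    }
    hits = _support(net, "EXPRESSION", proteins, config.region_ids)
    return frozenset(p for p, keys in hits.items() if len(keys) >= config.min_support)


def filter_upregulated(
    net: IntelligenceNetwork, proteins: frozenset[str], config: DerivationConfig
) -> frozenset[str]:
    """Subset of ``proteins`` with upregulation evidence in the disease."""
    hits = _support(net, "UPREGULATION", proteins, config.disease_ids)
    return frozenset(p for p, keys in hits.items() if len(keys) >= config.min_support)


def filter_pathology_associated(
    net: IntelligenceNetwork, proteins: frozenset[str], config: DerivationConfig
) -> frozenset[str]:
    """Subset of ``proteins`` linked to a configured pathological hallmark."""
    hits = _support(net, "PATHOLOGY_LINK", proteins, config.pathology_ids)
    return frozenset(p for p, keys in hits.items() if len(keys) >= config.min_support)


def assess_novelty(
    net: IntelligenceNetwork, proteins: frozenset[str], config: DerivationConfig
) -> Mapping[str, tuple[int | None, bool | None]]:
    """Per-protein (known-biomarker assertion count, novel?) mapping.

    A protein is novel iff it has zero disease-link assertions to the
    configured disease ids whose provenance source is tagged as a
    biomarker-claim source.  With no tagged sources both entries are ``None``
    (indeterminate).
    """
    if config.biomarker_claim_sources is None:
        return {p: (None, None) for p in sorted(proteins)}
    out: dict[str, tuple[int | None, bool | None]] = {p: (0, True) for p in proteins}
    for a in query_assertions(
        net, relation_class="DISEASE_LINK", object_ids=set(config.disease_ids)
    ):
        if a.subject_id not in out:
            continue
        claims = sum(
            1 for p in a.provenance if p.source in config.biomarker_claim_sources
        )
        if claims:
            count, _ = out[a.subject_id]
            out[a.subject_id] = ((count or 0) + claims, False)
    return dict(sorted(out.items()))


def derive_candidates(
    net: IntelligenceNetwork, config: DerivationConfig
) -> CandidateTable:
    """Run the full filter chain and return the audited candidate table."""
    config.validate(net)
    step1 = proteins_in_regions(net, config)
    step2 = filter_upregulated(net, step1, config)
    step3 = filter_pathology_associated(net, step2, config)

    expr = _support(net, "EXPRESSION", step3, config.region_ids)
    upreg = _support(net, "UPREGULATION", step3, config.disease_ids)
    patho = _support(net, "PATHOLOGY_LINK", step3, config.pathology_ids)
    novelty = assess_novelty(net, step3, config)

    candidates = tuple(
        Candidate(
            protein_id=p,
            expression_keys=tuple(sorted(expr.get(p, ()))),
            upregulation_keys=tuple(sorted(upreg.get(p, ()))),
            pathology_keys=tuple(sorted(patho.get(p, ()))),
            known_biomarker_count=novelty[p][0],
            novel=novelty[p][1],
        )
        for p in sorted(step3)
    )
    steps = (
        ("expressed_in_regions", step1, len(step1)),
        ("upregulated_in_disease", step2, len(step2)),
        ("pathology_associated", step3, len(step3)),
    )
    return CandidateTable(steps=steps, candidates=candidates)
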
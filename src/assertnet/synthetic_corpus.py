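"""Seeded synthetic corpora with planted, gold-annotated assertions.

The generator turns a ground-truth assertion list into abstract-like
documents whose sentences realise the planted triples through a small library
of sentence frames with synonym-varied subject/object/verb surfaces, plus two
kinds of noise: distractor sentences (vocabulary terms joined by non-lexicon
verbs) and negated variants (a real triple with a negation cue before the
verb, which a correct extractor must refuse).  A configurable share of the
truth can instead be emitted as structured-table rows, exercising the
ingestion path.

Every sentence that realises a triple affirmatively is recorded as a gold
annotation at (doc, sentence, triple) granularity, so extraction output can
be scored for precision/recall against a known answer.  The whole process is
driven by one seed and is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
import random
from typing import Mapping, Sequence

import pandas as pd

from .extraction import Document, ProtoAssertion
from .ingestion import MappingSpec
from .network import AssertionRecord
from .vocabulary import (
    AssertnetError,
    RelationLexicon,
    Vocabulary,
    INVERSE_RELATIONS,
)

logger = logging.getLogger("assertnet")

__all__ = [
    "GeneratorConfig",
    "GoldAnnotation",
    "CorpusBundle",
    "ScoreReport",
    "SENTENCE_FRAMES",
    "DISTRACTOR_FRAMES",
    "generate_corpus",
    "score_extraction",
]

#: Affirmative sentence frames.  The last frame interposes a long relative
#: clause (8 tokens) between subject and verb to stress the gap bound.
SENTENCE_FRAMES: tuple[str, ...] = (
    "{subj} {rel} {obj}.",
    "It has been reported that {subj} {rel} {obj}.",
    "Recent studies indicate that {subj} {rel} {obj}.",
    "We observed that {subj} {rel} {obj} in this cohort.",
    "{subj} {rel} {obj}, according to several independent reports.",
    "{subj}, which has been studied extensively over many years, {rel} {obj}.",
)

#: Negated frames: the cue token precedes the relation surface.
NEGATION_FRAMES: tuple[str, ...] = (
    "It is not the case that {subj} {rel} {obj}.",
    "{subj} never {rel} {obj}.",
)

#: Distractor frames use verbs absent from the relation lexicon.
DISTRACTOR_FRAMES: tuple[str, ...] = (
    "{a} was measured alongside {b} in several assays.",
    "{a} and {b} were discussed at length by the study group.",
    # terms never end the sentence: surfaces like "Apolipoprotein E." would
    # look like an initial to the abbreviation guard
    "The review summarised earlier work on {a} and {b} in detail.",
)


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    """Conditions of a generated corpus.

    ``distractor_rate`` and ``negation_rate`` are the per-slot probabilities
    of filler sentences beyond the guaranteed one realisation per truth
    triple; ``structured_share`` routes that fraction of truth triples into
    structured tables instead of text.  The seed is mandatory.
    """

    n_docs: int
    sentences_per_doc: int = 6
    synonym_substitution: bool = True
    distractor_rate: float = 0.0
    negation_rate: float = 0.0
    structured_share: float = 0.0
    seed: int = dataclasses.field(kw_only=True)

    def __post_init__(self) -> None:
        for name in ("distractor_rate", "negation_rate", "structured_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise AssertnetError(f"{name} must lie in [0, 1], got {v}")
        if self.n_docs < 0 or self.sentences_per_doc < 1:
            raise AssertnetError("need n_docs >= 0 and sentences_per_doc >= 1")


@dataclasses.dataclass(frozen=True)
class GoldAnnotation:
    """One sentence known to realise one planted triple."""

    doc_id: str
    sentence_index: int
    subject_id: str
    relation_class: str
    relation: str
    object_id: str
    subject_surface: str
    relation_surface: str
    object_surface: str

    @property
    def key(self) -> tuple[str, int, str, str, str]:
        return (
            self.doc_id,
            self.sentence_index,
            self.subject_id,
            self.relation,
            self.object_id,
        )


@dataclasses.dataclass(frozen=True)
class CorpusBundle:
    documents: tuple[Document, ...]
    gold: tuple[GoldAnnotation, ...]
    tables: Mapping[str, tuple[pd.DataFrame, MappingSpec]]


_Triple = tuple[str, str, str, str]  # subject_id, relation_class, relation, object_id


def _as_triples(truth: Sequence) -> list[_Triple]:
    triples = []
    for t in truth:
        if isinstance(t, AssertionRecord):
            triples.append((t.subject_id, t.relation_class, t.relation, t.object_id))
        else:
            triples.append(tuple(t))  # type: ignore[arg-type]
    return triples


def _forward_surfaces(lexicon: RelationLexicon, cls: str, relation: str) -> list[str]:
    """Surface forms of one canonical relation, excluding inverse-direction verbs."""
    rc = lexicon.classes[cls]
    surfaces = set()
    for preferred in rc.preferred_relations:
        if preferred != relation:
            continue
        for s in rc.surface_forms:
            hit = lexicon.normalize(s)
            if hit == (cls, preferred) and s.upper() not in INVERSE_RELATIONS:
                surfaces.add(s)
    return sorted(surfaces) or [relation.lower()]


class _Realizer:
    def __init__(
        self, vocab: Vocabulary, lexicon: RelationLexicon, config: GeneratorConfig
    ) -> None:
        self.vocab = vocab
        self.lexicon = lexicon
        self.config = config

    def surface(self, rng: random.Random, concept_id: str) -> str:
        concept = self.vocab[concept_id]
        if not self.config.synonym_substitution:
            return concept.preferred_label
        return rng.choice(sorted(concept.synonyms))

    def realise(
        self, rng: random.Random, triple: _Triple, frames: tuple[str, ...]
    ) -> tuple[str, str, str, str]:
        subj_id, cls, relation, obj_id = triple
        subj = self.surface(rng, subj_id)
        obj = self.surface(rng, obj_id)
        choices = _forward_surfaces(self.lexicon, cls, relation)
        rel = rng.choice(choices) if self.config.synonym_substitution else choices[0]
        frame = rng.choice(frames)
        return frame.format(subj=subj, rel=rel.lower(), obj=obj), subj, rel, obj


def generate_corpus(
    truth: Sequence,
    vocab: Vocabulary,
    lexicon: RelationLexicon,
    config: GeneratorConfig,
) -> CorpusBundle:
    """Generate documents (+ optional structured tables) realising ``truth``.

    Every text-routed truth triple is realised in at least one sentence
    (provided the corpus has enough sentence slots); remaining slots are
    filled with distractors, negated variants, or further (gold) realisations
    according to the configured rates.  Unknown concepts raise immediately.
    """
    triples = _as_triples(truth)
    for t in triples:
        for cid in (t[0], t[3]):
            if cid not in vocab:
                raise AssertnetError(f"truth triple references unknown concept {cid!r}")
        if t[1] not in lexicon.classes:
            raise AssertnetError(f"truth triple uses unknown relation class {t[1]!r}")

    rng = random.Random(config.seed)
    realizer = _Realizer(vocab, lexicon, config)

    # route a share of the truth into structured tables
    n_structured = round(config.structured_share * len(triples))
    structured_idx = set(
        rng.sample(range(len(triples)), n_structured) if n_structured else ()
    )
    text_triples = [t for i, t in enumerate(triples) if i not in structured_idx]
    table_triples = [t for i, t in enumerate(triples) if i in structured_idx]

    if config.n_docs == 0:
        if text_triples:
            raise AssertnetError("n_docs=0 but there are text-routed truth triples")
        return CorpusBundle((), (), _build_tables(table_triples, vocab))

    n_slots = config.n_docs * config.sentences_per_doc
    if text_triples and n_slots < len(text_triples):
        raise AssertnetError(
            f"{n_slots} sentence slots cannot realise {len(text_triples)} triples"
        )

    # guaranteed coverage first, then stochastic filler
    slot_plan: list[tuple[str, _Triple | None]] = [
        ("truth", t) for t in text_triples
    ]
    while len(slot_plan) < n_slots:
        u = rng.random()
        if text_triples and u < config.negation_rate:
            slot_plan.append(("negation", rng.choice(text_triples)))
        elif u < config.negation_rate + config.distractor_rate:
            slot_plan.append(("distractor", None))
        elif text_triples:
            slot_plan.append(("truth", rng.choice(text_triples)))
        else:
            slot_plan.append(("distractor", None))
    rng.shuffle(slot_plan)

    concept_ids = sorted(vocab.concepts)
    documents: list[Document] = []
    gold: list[GoldAnnotation] = []
    for d in range(config.n_docs):
        doc_id = f"synthetic-{config.seed}-{d:05d}"
        sentences: list[str] = []
        for s, (kind, triple) in enumerate(
            slot_plan[d * config.sentences_per_doc : (d + 1) * config.sentences_per_doc]
        ):
            if kind == "truth":
                assert triple is not None
                sentence, subj, rel, obj = realizer.realise(rng, triple, SENTENCE_FRAMES)
                # sentence-initial capitalisation keeps segmentation boundaries
                # unambiguous; the gold surface tracks the rendered form
                cap = sentence[0].upper() + sentence[1:]
                if cap != sentence and sentence.startswith(subj):
                    subj = cap[: len(subj)]
                sentence = cap
                gold.append(
                    GoldAnnotation(
                        doc_id=doc_id,
                        sentence_index=s,
                        subject_id=triple[0],
                        relation_class=triple[1],
                        relation=triple[2],
                        object_id=triple[3],
                        subject_surface=subj,
                        relation_surface=rel,
                        object_surface=obj,
                    )
                )
            elif kind == "negation":
                assert triple is not None
                sentence, *_ = realizer.realise(rng, triple, NEGATION_FRAMES)
                sentence = sentence[0].upper() + sentence[1:]
            else:
                a, b = rng.sample(concept_ids, 2)
                sentence = rng.choice(DISTRACTOR_FRAMES).format(
                    a=realizer.surface(rng, a), b=realizer.surface(rng, b)
                )
                sentence = sentence[0].upper() + sentence[1:]
            sentences.append(sentence)
        documents.append(Document(doc_id, "synthetic", " ".join(sentences)))

    return CorpusBundle(tuple(documents), tuple(gold), _build_tables(table_triples, vocab))


def _build_tables(
    triples: list[_Triple], vocab: Vocabulary
) -> dict[str, tuple[pd.DataFrame, MappingSpec]]:
    """One structured table per relation class, with its mapping spec."""
    by_class: dict[tuple[str, str], list[_Triple]] = {}
    for t in triples:
        by_class.setdefault((t[1], t[2]), []).append(t)
    tables: dict[str, tuple[pd.DataFrame, MappingSpec]] = {}
    for (cls, relation), members in sorted(by_class.items()):
        rows = [
            {
                "subject": vocab[t[0]].preferred_label,
                "object": vocab[t[3]].preferred_label,
            }
            for t in members
        ]
        spec = MappingSpec(
            source_name=f"synthetic-table-{cls.lower()}",
            subject_column="subject",
            subject_type=vocab[members[0][0]].type,
            object_column="object",
            object_type=vocab[members[0][3]].type,
            relation_class=cls,
            relation=relation,
        )
        tables[spec.source_name] = (pd.DataFrame(rows), spec)
    return tables


# --------------------------------------------------------------------------
# scoring
# --------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ScoreReport:
    tp: int
    fp: int
    fn: int
    precision: float | None
    recall: float | None
    f1: float | None
    false_positives: tuple[tuple, ...]
    false_negatives: tuple[tuple, ...]


def score_extraction(
    gold: Sequence[GoldAnnotation], extracted: Sequence[ProtoAssertion]
) -> ScoreReport:
    """Precision/recall/F1 of extracted triples at (doc, sentence) granularity.

    Undefined ratios (zero denominator) are reported as ``None``, never 0.
    """
    gold_keys = {g.key for g in gold}
    extracted_keys = {
        (
            p.provenance.doc_id,
            p.provenance.sentence_index,
            p.subject_id,
            p.relation,
            p.object_id,
        )
        for p in extracted
    }
    tp = len(gold_keys & extracted_keys)
    fp = len(extracted_keys - gold_keys)
    fn = len(gold_keys - extracted_keys)
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else None
    f1 = None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    return ScoreReport(
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        f1=f1,
        false_positives=tuple(sorted(extracted_keys - gold_keys)),
        false_negatives=tuple(sorted(gold_keys - extracted_keys)),
    )
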
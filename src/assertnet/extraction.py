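"""Sentence-level assertion extraction, curation bookkeeping and QC sampling.

Extraction is deliberately within-sentence only: a proto-assertion is an
ordered (subject mention, relation verb phrase, object mention) triple found
in one sentence, type-checked against the network map and canonicalised in
direction.  Cross-sentence statements are left to curated sources — chasing
them automatically costs precision without a coreference layer.

Curation is emulated by decision tables (accept/reject per extracted triple),
and the accuracy of an accepted set is audited by a simplified single-sampling
acceptance plan: draw ``n`` assertions without replacement, count errors
against a truth oracle, pass when errors do not exceed the acceptance number,
and report a point accuracy with an exact (Clopper–Pearson) binomial CI.
"""

from __future__ import annotations

import dataclasses
import logging
import random
import re
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import beta

from .network import AssertionRecord, Provenance, Status
from .vocabulary import (
    AssertnetError,
    ConceptType,
    RelationLexicon,
    RelationMatch,
    TermMatcher,
    TermMention,
    canonicalize_triple,
    match_terms,
    tokenize,
)

logger = logging.getLogger("assertnet")

__all__ = [
    "CurationError",
    "Document",
    "SentenceRecord",
    "ExtractionPattern",
    "ProtoAssertion",
    "QCPlan",
    "QCReport",
    "DEFAULT_PATTERNS",
    "NEGATION_CUES",
    "segment_sentences",
    "extract_proto_assertions",
    "extract_corpus",
    "apply_curation",
    "auto_accept",
    "load_decisions",
    "qc_sample",
    "read_corpus_jsonl",
    "write_corpus_jsonl",
]


class CurationError(AssertnetError):
    """Contradictory or malformed curation decisions."""


@dataclasses.dataclass(frozen=True)
class Document:
    """One corpus document (an abstract, a review, a report...)."""

    doc_id: str
    source: str
    text: str


@dataclasses.dataclass(frozen=True)
class SentenceRecord:
    doc_id: str
    sentence_index: int
    text: str
    offset: int  # char offset of the sentence within the document


# --------------------------------------------------------------------------
# sentence segmentation
# --------------------------------------------------------------------------

_BOUNDARY_RE = re.compile(r"[.!?]+(\s+)")
_ABBREVIATIONS = {"e.g", "i.e", "al", "etc", "fig", "figs", "dr", "vs", "cf", "ca"}


def _guarded(text: str, punct_end: int) -> bool:
    """True when an abbreviation guard should suppress a split at ``punct_end``."""
    before = text[:punct_end].rstrip(".!?")
    m = re.search(r"([^\s(]+)$", before)
    if not m:
        return True
    word = m.group(1)
    if len(word) == 1 and word.isalpha() and word.isupper():
        return True  # single-initial abbreviation, "A." in "A. Smith"
    return word.casefold().rstrip(".") in _ABBREVIATIONS


def segment_sentences(
    doc: Document, abbreviation_guard: bool = True
) -> list[SentenceRecord]:
    """Split a document into sentences with character offsets.

    A boundary is a run of ``.!?`` followed by whitespace and an upper-case
    letter or digit.  The sentences plus the separators between them
    reconstruct the document exactly.  Whitespace-only text yields ``[]``.
    """
    text = doc.text
    if not text.strip():
        return []
    boundaries = []
    for m in _BOUNDARY_RE.finditer(text):
        nxt = m.end()
        if nxt >= len(text):
            continue
        if not (text[nxt].isupper() or text[nxt].isdigit()):
            continue
        if abbreviation_guard and _guarded(text, m.start(1)):
            continue
        boundaries.append((m.start(1), m.end()))

    records = []
    start = 0
    for sep_start, sep_end in boundaries + [(len(text), len(text))]:
        chunk = text[start:sep_start]
        lead = len(chunk) - len(chunk.lstrip())
        stripped = chunk.strip()
        if stripped:
            records.append(
                SentenceRecord(doc.doc_id, len(records), stripped, start + lead)
            )
        start = sep_end
    return records


# --------------------------------------------------------------------------
# proto-assertion extraction
# --------------------------------------------------------------------------

_ALL_TYPES = frozenset(ConceptType)


@dataclasses.dataclass(frozen=True)
class ExtractionPattern:
    """One subject–verb–object noun-phrase pattern with a token-gap bound."""

    pattern_id: str
    subject_types: frozenset[ConceptType] = _ALL_TYPES
    object_types: frozenset[ConceptType] = _ALL_TYPES
    max_gap_tokens: int = 10

    def __post_init__(self) -> None:
        if not self.subject_types or not self.object_types:
            raise AssertnetError(f"pattern {self.pattern_id}: empty type set")
        if self.max_gap_tokens <= 0:
            raise AssertnetError(f"pattern {self.pattern_id}: max_gap_tokens must be >0")


DEFAULT_PATTERNS: tuple[ExtractionPattern, ...] = (
    ExtractionPattern("svo-default"),
)

#: Token sequences that, occurring before the relation verb, block extraction.
NEGATION_CUES: tuple[tuple[str, ...], ...] = (
    ("not",),
    ("no",),
    ("never",),
    ("failed", "to"),
    ("absence", "of"),
)


@dataclasses.dataclass(frozen=True)
class ProtoAssertion:
    """An automatically extracted candidate assertion awaiting curation."""

    subject: TermMention
    subject_id: str
    relation_class: str
    relation: str
    object: TermMention
    object_id: str
    provenance: Provenance
    status: str = Status.PROTO

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.subject_id, self.relation, self.object_id)

    @property
    def decision_key(self) -> tuple[str, str, str, str, int]:
        return (
            self.subject_id,
            self.relation,
            self.object_id,
            self.provenance.doc_id,
            self.provenance.sentence_index,
        )

    def to_record(self, status: str | None = None) -> AssertionRecord:
        return AssertionRecord(
            self.subject_id,
            self.relation_class,
            self.relation,
            self.object_id,
            status if status is not None else self.status,
            self.provenance,
        )


def _negated(relation: RelationMatch, tokens, mentions: Sequence[TermMention]) -> bool:
    """A negation cue strictly before the relation surface blocks extraction."""
    covered = [
        i
        for m in mentions
        for i in range(m.token_start, m.token_end)
    ]
    norms = [
        t.norm if i not in covered else None for i, t in enumerate(tokens)
    ]
    upper = relation.token_start
    for cue in NEGATION_CUES:
        k = len(cue)
        for i in range(0, upper - k + 1):
            if tuple(norms[i : i + k]) == cue:
                return True
    return False


def extract_proto_assertions(
    sentence: SentenceRecord,
    matcher: TermMatcher,
    lexicon: RelationLexicon,
    patterns: Sequence[ExtractionPattern] = DEFAULT_PATTERNS,
    source: str = "corpus",
) -> list[ProtoAssertion]:
    """Extract ordered subject–verb–object proto-assertions from one sentence.

    For every pattern, every (subject mention, relation match, object mention)
    with the subject span before the relation surface before the object span,
    token gaps within the pattern bound, and a type-compatible concept pair
    under the network map yields one proto-assertion.  Ambiguous mentions are
    expanded into one proto per compatible concept; a negation cue before the
    relation suppresses extraction for that relation.
    """
    tokens = tokenize(sentence.text)
    mentions = match_terms(matcher, sentence.doc_id, sentence.sentence_index, sentence.text)
    if len(mentions) < 2:
        return []
    relations = lexicon.find_relations(sentence.text, tokens)
    vocab = matcher.vocab
    provenance = Provenance(
        source=source,
        doc_id=sentence.doc_id,
        sentence_index=sentence.sentence_index,
        snippet=sentence.text,
    )

    protos: list[ProtoAssertion] = []
    seen: set[tuple] = set()
    for rel in relations:
        # relation phrase must not sit inside a term mention
        if any(
            rel.token_start < m.token_end and rel.token_end > m.token_start
            for m in mentions
        ):
            continue
        if _negated(rel, tokens, mentions):
            continue
        for pattern in patterns:
            subjects = [
                m
                for m in mentions
                if m.token_end <= rel.token_start
                and rel.token_start - m.token_end <= pattern.max_gap_tokens
            ]
            objects = [
                m
                for m in mentions
                if m.token_start >= rel.token_end
                and m.token_start - rel.token_end <= pattern.max_gap_tokens
            ]
            for sm in subjects:
                for om in objects:
                    for sid in sorted(sm.concept_ids):
                        s_type = vocab[sid].type
                        if s_type not in pattern.subject_types:
                            continue
                        for oid in sorted(om.concept_ids):
                            o_type = vocab[oid].type
                            if o_type not in pattern.object_types:
                                continue
                            canon = canonicalize_triple(
                                rel.relation_class,
                                rel.preferred_relation,
                                sid,
                                s_type,
                                oid,
                                o_type,
                            )
                            if canon is None:
                                continue
                            cls, relation, subj, obj = canon
                            key = (subj, relation, obj)
                            if key in seen:
                                continue
                            seen.add(key)
                            subj_mention, obj_mention = (
                                (sm, om) if subj == sid else (om, sm)
                            )
                            protos.append(
                                ProtoAssertion(
                                    subject=subj_mention,
                                    subject_id=subj,
                                    relation_class=cls,
                                    relation=relation,
                                    object=obj_mention,
                                    object_id=obj,
                                    provenance=provenance,
                                )
                            )
    return protos


def extract_corpus(
    documents: Iterable[Document],
    matcher: TermMatcher,
    lexicon: RelationLexicon,
    patterns: Sequence[ExtractionPattern] = DEFAULT_PATTERNS,
) -> list[ProtoAssertion]:
    """Segment and extract every document; deterministic over input order."""
    protos: list[ProtoAssertion] = []
    for doc in documents:
        for sentence in segment_sentences(doc):
            protos.extend(
                extract_proto_assertions(
                    sentence, matcher, lexicon, patterns, source=doc.source
                )
            )
    return protos


# --------------------------------------------------------------------------
# curation
# --------------------------------------------------------------------------

DecisionKey = tuple[str, str, str, str, int]


def load_decisions(path: str | Path) -> dict[DecisionKey, str]:
    """Load a decisions TSV keyed by (subject, relation, object, doc, sentence)."""
    frame = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    required = {"subject_id", "relation", "object_id", "doc_id", "sentence_index", "decision"}
    missing = required - set(frame.columns)
    if missing:
        raise CurationError(f"{path}: missing columns {sorted(missing)}")
    decisions: dict[DecisionKey, str] = {}
    for row in frame.itertuples(index=False):
        key = (
            row.subject_id,
            row.relation,
            row.object_id,
            row.doc_id,
            int(row.sentence_index),
        )
        decision = row.decision.strip().lower()
        if decision not in {"accept", "reject"}:
            raise CurationError(f"{path}: bad decision {row.decision!r} for {key}")
        if key in decisions and decisions[key] != decision:
            raise CurationError(f"contradictory decisions for {key}")
        decisions[key] = decision
    return decisions


def apply_curation(
    protos: Sequence[ProtoAssertion],
    decisions: Mapping[DecisionKey, str],
) -> tuple[list[ProtoAssertion], list[ProtoAssertion], list[ProtoAssertion]]:
    """Route each proto-assertion to (accepted, rejected, undecided).

    Accepted protos get status ``ACCEPTED``, rejected ``REJECTED``; protos
    without a decision stay ``PROTO``.  Decision keys that match no proto are
    warned about, not fatal.
    """
    # duplicate contradictory keys are impossible in a Mapping; validate values
    for key, decision in decisions.items():
        if decision not in {"accept", "reject"}:
            raise CurationError(f"bad decision {decision!r} for {key}")
    accepted, rejected, undecided = [], [], []
    matched: set[DecisionKey] = set()
    for proto in protos:
        decision = decisions.get(proto.decision_key)
        if decision is None:
            undecided.append(proto)
        elif decision == "accept":
            matched.add(proto.decision_key)
            accepted.append(dataclasses.replace(proto, status=Status.ACCEPTED))
        else:
            matched.add(proto.decision_key)
            rejected.append(dataclasses.replace(proto, status=Status.REJECTED))
    for key in decisions.keys() - matched:
        logger.warning("curation decision for %s matches no proto-assertion", key)
    return accepted, rejected, undecided


def auto_accept(protos: Sequence[ProtoAssertion]) -> list[AssertionRecord]:
    """Accept every proto-assertion (used with synthetic, gold-backed corpora)."""
    return [p.to_record(Status.ACCEPTED) for p in protos]


# --------------------------------------------------------------------------
# QC accuracy sampling
# --------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class QCPlan:
    """A simplified single-sampling acceptance plan.

    ``sample_size`` assertions are audited; the batch passes when the number
    of errors found is at most ``acceptance_number``.  The default (n=125,
    c=3) corresponds to a typical general inspection plan for batches of a
    few thousand at around 1% acceptable quality.
    """

    sample_size: int = 125
    acceptance_number: int = 3
    seed: int = dataclasses.field(kw_only=True)

    def __post_init__(self) -> None:
        if self.sample_size <= 0:
            raise AssertnetError("sample_size must be > 0")
        if not 0 <= self.acceptance_number < self.sample_size:
            raise AssertnetError("need 0 <= acceptance_number < sample_size")


@dataclasses.dataclass(frozen=True)
class QCReport:
    sampled_n: int
    errors_found: int
    accuracy: float | None
    ci_low: float | None
    ci_high: float | None
    passed: bool | None
    indeterminate: bool = False


def _clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial CI for a proportion of ``k`` successes in ``n`` trials."""
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def qc_sample(
    assertions: Sequence[AssertionRecord | ProtoAssertion],
    truth: Mapping[tuple[str, str, str], bool] | Callable[[object], bool],
    plan: QCPlan,
) -> QCReport:
    """Audit a random sample of accepted assertions against a truth oracle.

    Sampling is without replacement using ``plan.seed``; when the plan's
    sample size reaches the population a census is taken and the reported
    accuracy is exact.  An empty assertion list yields an indeterminate
    report.
    """
    if not assertions:
        return QCReport(0, 0, None, None, None, None, indeterminate=True)
    n = min(plan.sample_size, len(assertions))
    rng = random.Random(plan.seed)
    sample = rng.sample(list(assertions), n) if n < len(assertions) else list(assertions)
    if callable(truth):
        correct = [bool(truth(a)) for a in sample]
    else:
        correct = [bool(truth[a.triple]) for a in sample]
    errors = sum(1 for ok in correct if not ok)
    low, high = _clopper_pearson(n - errors, n)
    return QCReport(
        sampled_n=n,
        errors_found=errors,
        accuracy=1.0 - errors / n,
        ci_low=low,
        ci_high=high,
        passed=errors <= plan.acceptance_number,
    )


# --------------------------------------------------------------------------
# corpus JSONL IO
# --------------------------------------------------------------------------


def read_corpus_jsonl(path: str | Path) -> list[Document]:
    import json

    docs = []
    seen = set()
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            rec = json.loads(raw)
            if rec["doc_id"] in seen:
                raise AssertnetError(f"{path} line {lineno}: duplicate doc_id {rec['doc_id']!r}")
            seen.add(rec["doc_id"])
            docs.append(Document(rec["doc_id"], rec.get("source", "corpus"), rec["text"]))
    return docs


def write_corpus_jsonl(documents: Sequence[Document], path: str | Path) -> None:
    import json

    with Path(path).open("w", encoding="utf-8") as fh:
        for d in documents:
            fh.write(
                json.dumps(
                    {"doc_id": d.doc_id, "source": d.source, "text": d.text},
                    sort_keys=True,
                    separators=(",", ":"),
                )
                + "\n"
            )
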
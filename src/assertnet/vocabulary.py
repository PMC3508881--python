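"""Concept vocabularies, relation lexicons and dictionary-based term matching.

An assertion network is only semantically consistent if every surface form in
the input maps onto a single controlled vocabulary.  This module holds that
vocabulary layer: typed concepts with synonym sets, a normalised surface index,
a longest-match term matcher, and the lexicon of relation verb phrases grouped
into relation classes (expression, upregulation, pathology link, disease link,
pathway membership).

Surface normalisation is deliberately shallow: case folding, hyphen/underscore
to space, whitespace collapse and Greek-letter spelling (``β`` ↔ ``beta``).
Synonym lists are assumed exhaustive, so no stemming is applied — stemming
would risk false merges between distinct concepts.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
import re
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

logger = logging.getLogger("assertnet")

__all__ = [
    "AssertnetError",
    "VocabularyLoadError",
    "LexiconError",
    "ConceptType",
    "Concept",
    "Vocabulary",
    "RelationClass",
    "RelationLexicon",
    "TermMention",
    "TermMatcher",
    "RelationMatch",
    "INVERSE_RELATIONS",
    "RELATION_TYPE_MAP",
    "normalize_surface",
    "tokenize",
    "slugify",
    "load_vocabulary",
    "normalize_term",
    "compile_matcher",
    "match_terms",
    "load_relation_lexicon",
    "normalize_relation",
    "canonicalize_triple",
    "save_lexicon",
    "load_lexicon",
]


class AssertnetError(Exception):
    """Base class for all package errors."""


class VocabularyLoadError(AssertnetError):
    """A vocabulary table could not be parsed into concepts."""


class LexiconError(AssertnetError):
    """A relation lexicon is malformed (unknown class, ambiguous surface...)."""


# --------------------------------------------------------------------------
# surface normalisation and tokenisation
# --------------------------------------------------------------------------

_GREEK = {
    "α": "alpha",
    "β": "beta",
    "γ": "gamma",
    "δ": "delta",
    "ε": "epsilon",
    "κ": "kappa",
    "σ": "sigma",
    "τ": "tau",
    "ω": "omega",
}

# Word tokens: runs of letters/digits, optionally joined by an apostrophe
# ("Alzheimer's" is one token).  Hyphens and underscores act as separators,
# which is what makes "BACE-1" and "BACE 1" equivalent.
_TOKEN_RE = re.compile(r"[^\W_]+(?:['’][^\W_]+)*", re.UNICODE)


def _norm_token(token: str) -> str:
    token = token.casefold().replace("’", "'")
    if any(c in _GREEK for c in token):
        token = "".join(_GREEK.get(c, c) for c in token)
    return token


@dataclasses.dataclass(frozen=True)
class Token:
    start: int
    end: int
    norm: str


def tokenize(text: str) -> list[Token]:
    """Split ``text`` into offset-carrying normalised word tokens."""
    return [
        Token(m.start(), m.end(), _norm_token(m.group()))
        for m in _TOKEN_RE.finditer(text)
    ]


def normalize_surface(surface: str) -> str:
    """Canonical key for a surface string (used by all index lookups)."""
    return " ".join(t.norm for t in tokenize(surface))


def slugify(label: str) -> str:
    """Derive a stable concept id from a preferred label."""
    return re.sub(r"-{2,}", "-", re.sub(r"[^a-z0-9]+", "-", label.casefold())).strip("-")


# --------------------------------------------------------------------------
# concepts
# --------------------------------------------------------------------------


class ConceptType(str, enum.Enum):
    """Closed enumeration of semantic concept types in the network map."""

    DISEASE = "DISEASE"
    PATHOLOGICAL_OBSERVATION = "PATHOLOGICAL_OBSERVATION"
    ANATOMICAL_STRUCTURE = "ANATOMICAL_STRUCTURE"
    PROTEIN_OR_MRNA = "PROTEIN_OR_MRNA"
    GENE_MUTATION = "GENE_MUTATION"
    BIOLOGICAL_PROCESS = "BIOLOGICAL_PROCESS"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclasses.dataclass(frozen=True)
class Concept:
    """A semantic unit with a preferred label and its synonym closure.

    The preferred label is always a member of its own synonym set, so looking
    up the preferred label returns the concept.
    """

    concept_id: str
    type: ConceptType
    preferred_label: str
    synonyms: frozenset[str]

    def __post_init__(self) -> None:
        syns = frozenset(self.synonyms) | {self.preferred_label}
        object.__setattr__(self, "synonyms", syns)

    def normalized_synonyms(self) -> frozenset[str]:
        return frozenset(normalize_surface(s) for s in self.synonyms)


class Vocabulary:
    """A set of concepts plus a normalised surface → concept-id index."""

    def __init__(self, concepts: Iterable[Concept] = ()) -> None:
        self._concepts: dict[str, Concept] = {}
        self._surface_index: dict[str, set[str]] = {}
        for c in concepts:
            self.add(c)

    def add(self, concept: Concept) -> None:
        if concept.concept_id in self._concepts:
            existing = self._concepts[concept.concept_id]
            if (
                existing.type != concept.type
                or existing.preferred_label != concept.preferred_label
            ):
                raise VocabularyLoadError(
                    f"conflicting redefinition of concept {concept.concept_id!r}"
                )
            concept = Concept(
                concept.concept_id,
                concept.type,
                concept.preferred_label,
                existing.synonyms | concept.synonyms,
            )
        self._concepts[concept.concept_id] = concept
        for syn in concept.synonyms:
            key = normalize_surface(syn)
            if key:
                self._surface_index.setdefault(key, set()).add(concept.concept_id)

    @property
    def concepts(self) -> Mapping[str, Concept]:
        return self._concepts

    @property
    def surface_index(self) -> Mapping[str, set[str]]:
        return self._surface_index

    def get(self, concept_id: str) -> Concept | None:
        return self._concepts.get(concept_id)

    def __getitem__(self, concept_id: str) -> Concept:
        return self._concepts[concept_id]

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self._concepts

    def __len__(self) -> int:
        return len(self._concepts)

    def __iter__(self) -> Iterator[Concept]:
        return iter(self._concepts.values())

    def lookup(self, surface: str) -> set[Concept]:
        key = normalize_surface(surface)
        return {self._concepts[cid] for cid in self._surface_index.get(key, ())}

    def counts_by_type(self) -> dict[ConceptType, int]:
        counts = {t: 0 for t in ConceptType}
        for c in self._concepts.values():
            counts[c.type] += 1
        return counts

    def merged(self, other: "Vocabulary") -> "Vocabulary":
        v = Vocabulary(self._concepts.values())
        for c in other:
            v.add(c)
        return v

    # serialisation ---------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "concepts": [
                {
                    "concept_id": c.concept_id,
                    "type": c.type.value,
                    "preferred_label": c.preferred_label,
                    "synonyms": sorted(c.synonyms),
                }
                for c in sorted(self._concepts.values(), key=lambda c: c.concept_id)
            ]
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "Vocabulary":
        return cls(
            Concept(
                rec["concept_id"],
                ConceptType(rec["type"]),
                rec["preferred_label"],
                frozenset(rec["synonyms"]),
            )
            for rec in payload["concepts"]
        )


def load_vocabulary(path: str | Path) -> Vocabulary:
    """Load a vocabulary TSV (``concept_id  type  preferred_label  synonym``).

    One row per synonym; duplicate (concept_id, synonym) rows collapse.  An
    empty ``concept_id`` cell is filled with the slugified preferred label.
    An unknown concept type raises :class:`VocabularyLoadError` naming the row.
    A file with no data rows yields an empty vocabulary (with a warning).
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        logger.warning("vocabulary file %s is empty", path)
        return Vocabulary()
    required = {"concept_id", "type", "preferred_label", "synonym"}
    missing = required - set(frame.columns)
    if missing:
        raise VocabularyLoadError(
            f"{path}: missing columns {sorted(missing)}"
        )
    if frame.empty:
        logger.warning("vocabulary file %s has a header but no rows", path)
        return Vocabulary()

    grouped: dict[str, dict] = {}
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            ctype = ConceptType(row.type)
        except ValueError:
            raise VocabularyLoadError(
                f"{path} line {i}: unknown concept type {row.type!r}"
            ) from None
        cid = row.concept_id or slugify(row.preferred_label)
        entry = grouped.setdefault(
            cid, {"type": ctype, "label": row.preferred_label, "syns": set()}
        )
        if entry["type"] != ctype or entry["label"] != row.preferred_label:
            raise VocabularyLoadError(
                f"{path} line {i}: concept {cid!r} redefined inconsistently"
            )
        if row.synonym:
            entry["syns"].add(row.synonym)
    return Vocabulary(
        Concept(cid, e["type"], e["label"], frozenset(e["syns"]))
        for cid, e in grouped.items()
    )


def normalize_term(vocab: Vocabulary, surface: str) -> set[Concept]:
    """All concepts whose synonym closure contains the normalised surface."""
    return vocab.lookup(surface)


# --------------------------------------------------------------------------
# term matching
# --------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class TermMention:
    """A vocabulary hit in one sentence.

    ``span`` is 0-based half-open in sentence characters; ``surface`` always
    equals the sentence substring at the span.  ``concept_ids`` may hold more
    than one id when the surface is ambiguous — disambiguation is deferred to
    extraction-pattern type constraints and then to curation.
    """

    doc_id: str
    sentence_index: int
    start: int
    end: int
    surface: str
    concept_ids: frozenset[str]
    token_start: int = 0
    token_end: int = 0

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


class TermMatcher:
    """Immutable longest-match scanner compiled from a vocabulary."""

    def __init__(self, vocab: Vocabulary) -> None:
        self._vocab = vocab
        phrases: dict[tuple[str, ...], set[str]] = {}
        for concept in vocab:
            for syn in concept.synonyms:
                key = tuple(t.norm for t in tokenize(syn))
                if key:
                    phrases.setdefault(key, set()).add(concept.concept_id)
        self._phrases: dict[tuple[str, ...], frozenset[str]] = {
            k: frozenset(v) for k, v in phrases.items()
        }
        self._max_len = max((len(k) for k in self._phrases), default=0)

    @property
    def vocab(self) -> Vocabulary:
        return self._vocab

    def candidates(self, tokens: list[Token]) -> list[tuple[int, int, frozenset[str]]]:
        """Every (token_start, token_end, concept_ids) phrase occurrence."""
        out = []
        n = len(tokens)
        for i in range(n):
            for j in range(i + 1, min(n, i + self._max_len) + 1):
                ids = self._phrases.get(tuple(t.norm for t in tokens[i:j]))
                if ids:
                    out.append((i, j, ids))
        return out


def compile_matcher(vocab: Vocabulary) -> TermMatcher:
    return TermMatcher(vocab)


def _select_longest_leftmost(
    candidates: list[tuple[int, int, frozenset[str]]]
) -> list[tuple[int, int, frozenset[str]]]:
    """Greedy non-overlap selection: longest first, earliest start on ties."""
    chosen: list[tuple[int, int, frozenset[str]]] = []
    for i, j, ids in sorted(candidates, key=lambda c: (-(c[1] - c[0]), c[0])):
        if all(j <= ci or i >= cj for ci, cj, _ in chosen):
            chosen.append((i, j, ids))
    return sorted(chosen, key=lambda c: c[0])


def match_terms(
    matcher: TermMatcher, doc_id: str, sentence_index: int, sentence: str
) -> list[TermMention]:
    """Non-overlapping vocabulary mentions, longest match first, sorted by span."""
    tokens = tokenize(sentence)
    mentions = []
    for i, j, ids in _select_longest_leftmost(matcher.candidates(tokens)):
        start, end = tokens[i].start, tokens[j - 1].end
        mentions.append(
            TermMention(
                doc_id=doc_id,
                sentence_index=sentence_index,
                start=start,
                end=end,
                surface=sentence[start:end],
                concept_ids=ids,
                token_start=i,
                token_end=j,
            )
        )
    return mentions


# --------------------------------------------------------------------------
# relation lexicon
# --------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class RelationClass:
    """A class of relation verbs with canonical phrases and surface forms."""

    name: str
    preferred_relations: frozenset[str]
    surface_forms: frozenset[str]


RELATION_CLASS_NAMES = (
    "PATHOLOGY_LINK",
    "EXPRESSION",
    "UPREGULATION",
    "DISEASE_LINK",
    "PATHWAY_MEMBERSHIP",
)

#: Structure-side verbs that are inverted on storage so every stored triple
#: runs in the canonical direction (e.g. protein → IS EXPRESSED IN → region).
INVERSE_RELATIONS: dict[str, tuple[str, str]] = {
    "EXPRESSES": ("EXPRESSION", "IS EXPRESSED IN"),
    "HAS CONSTITUENT": ("EXPRESSION", "IS EXPRESSED IN"),
    "IS LOCATION OF": ("EXPRESSION", "IS EXPRESSED IN"),
    "IS SITE OF ALTERATION OF": ("EXPRESSION", "IS EXPRESSED IN"),
    "HAS UPREGULATED": ("UPREGULATION", "IS UPREGULATED IN"),
}

_CT = ConceptType
#: Admissible (subject type, object type) pairs per relation class, in the
#: canonical storage direction.  This encodes the network map that guides
#: both extraction type-compatibility checks and mapping-spec validation.
RELATION_TYPE_MAP: dict[str, frozenset[tuple[ConceptType, ConceptType]]] = {
    "EXPRESSION": frozenset({(_CT.PROTEIN_OR_MRNA, _CT.ANATOMICAL_STRUCTURE)}),
    "UPREGULATION": frozenset(
        {
            (_CT.PROTEIN_OR_MRNA, _CT.DISEASE),
            (_CT.PROTEIN_OR_MRNA, _CT.ANATOMICAL_STRUCTURE),
        }
    ),
    "DISEASE_LINK": frozenset(
        {
            (_CT.PROTEIN_OR_MRNA, _CT.DISEASE),
            (_CT.PATHOLOGICAL_OBSERVATION, _CT.DISEASE),
            (_CT.BIOLOGICAL_PROCESS, _CT.DISEASE),
            (_CT.GENE_MUTATION, _CT.DISEASE),
        }
    ),
    "PATHOLOGY_LINK": frozenset(
        {
            (_CT.PROTEIN_OR_MRNA, _CT.PATHOLOGICAL_OBSERVATION),
            (_CT.PROTEIN_OR_MRNA, _CT.BIOLOGICAL_PROCESS),
            (_CT.DISEASE, _CT.PATHOLOGICAL_OBSERVATION),
            (_CT.DISEASE, _CT.BIOLOGICAL_PROCESS),
            (_CT.GENE_MUTATION, _CT.PATHOLOGICAL_OBSERVATION),
            (_CT.PATHOLOGICAL_OBSERVATION, _CT.PATHOLOGICAL_OBSERVATION),
        }
    ),
    "PATHWAY_MEMBERSHIP": frozenset({(_CT.PROTEIN_OR_MRNA, _CT.BIOLOGICAL_PROCESS)}),
}


@dataclasses.dataclass(frozen=True)
class RelationMatch:
    """A relation verb-phrase occurrence inside a sentence."""

    token_start: int
    token_end: int
    start: int
    end: int
    relation_class: str
    preferred_relation: str
    surface: str


class RelationLexicon:
    """Surface verb phrases → (relation class, preferred relation)."""

    def __init__(self, entries: Iterable[tuple[str, str, str]]) -> None:
        # entries: (class name, preferred relation, surface form)
        classes: dict[str, dict[str, set[str]]] = {}
        self._surface_index: dict[str, tuple[str, str]] = {}
        self._entries: list[tuple[str, str, str]] = []
        for cls, preferred, surface in entries:
            if cls not in RELATION_CLASS_NAMES:
                raise LexiconError(f"unknown relation class {cls!r}")
            preferred = preferred.upper()
            classes.setdefault(cls, {}).setdefault(preferred, set()).add(surface)
            key = normalize_surface(surface)
            prior = self._surface_index.get(key)
            if prior is not None and prior != (cls, preferred):
                raise LexiconError(
                    f"surface form {surface!r} is ambiguous between "
                    f"{prior} and {(cls, preferred)}"
                )
            self._surface_index[key] = (cls, preferred)
            self._entries.append((cls, preferred, surface))
        # every preferred relation is implicitly its own surface form
        for cls, rels in classes.items():
            for preferred in rels:
                key = normalize_surface(preferred)
                prior = self._surface_index.get(key)
                if prior is None:
                    self._surface_index[key] = (cls, preferred)
                    rels[preferred].add(preferred)
                elif prior != (cls, preferred):
                    raise LexiconError(
                        f"preferred relation {preferred!r} collides with {prior}"
                    )
        self.classes: dict[str, RelationClass] = {
            cls: RelationClass(
                cls,
                frozenset(rels),
                frozenset(s for forms in rels.values() for s in forms),
            )
            for cls, rels in classes.items()
        }
        self._phrases: dict[tuple[str, ...], tuple[str, str]] = {
            tuple(key.split(" ")): val for key, val in self._surface_index.items()
        }
        self._max_len = max((len(k) for k in self._phrases), default=0)

    def normalize(self, surface: str) -> tuple[str, str] | None:
        return self._surface_index.get(normalize_surface(surface))

    def relation_class_of(self, preferred: str) -> str | None:
        for cls, rc in self.classes.items():
            if preferred in rc.preferred_relations:
                return cls
        return None

    def find_relations(self, sentence: str, tokens: list[Token]) -> list[RelationMatch]:
        """All relation phrase matches, greedy longest-leftmost, non-overlapping."""
        candidates = []
        n = len(tokens)
        for i in range(n):
            for j in range(i + 1, min(n, i + self._max_len) + 1):
                hit = self._phrases.get(tuple(t.norm for t in tokens[i:j]))
                if hit:
                    candidates.append((i, j, hit))
        chosen: list[tuple[int, int, tuple[str, str]]] = []
        for i, j, hit in sorted(candidates, key=lambda c: (-(c[1] - c[0]), c[0])):
            if all(j <= ci or i >= cj for ci, cj, _ in chosen):
                chosen.append((i, j, hit))
        return [
            RelationMatch(
                token_start=i,
                token_end=j,
                start=tokens[i].start,
                end=tokens[j - 1].end,
                relation_class=cls,
                preferred_relation=preferred,
                surface=sentence[tokens[i].start : tokens[j - 1].end],
            )
            for i, j, (cls, preferred) in sorted(chosen, key=lambda c: c[0])
        ]

    # serialisation ---------------------------------------------------------

    def to_dict(self) -> dict:
        return {"entries": [list(e) for e in sorted(self._entries)]}

    @classmethod
    def from_dict(cls, payload: Mapping) -> "RelationLexicon":
        return cls(tuple(e) for e in payload["entries"])


def load_relation_lexicon(path: str | Path) -> RelationLexicon:
    """Load a relation lexicon TSV (``relation_class  preferred_relation  surface_form``)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        logger.warning("relation lexicon %s is empty", path)
        return RelationLexicon(())
    required = {"relation_class", "preferred_relation", "surface_form"}
    missing = required - set(frame.columns)
    if missing:
        raise LexiconError(f"{path}: missing columns {sorted(missing)}")
    return RelationLexicon(
        (r.relation_class, r.preferred_relation, r.surface_form)
        for r in frame.itertuples(index=False)
        if r.surface_form
    )


def normalize_relation(
    lexicon: RelationLexicon, surface: str
) -> tuple[str, str] | None:
    """Map a verb phrase onto ``(relation class, preferred relation)`` or None."""
    return lexicon.normalize(surface)


def canonicalize_triple(
    relation_class: str,
    preferred_relation: str,
    subject_id: str,
    subject_type: ConceptType,
    object_id: str,
    object_type: ConceptType,
) -> tuple[str, str, str, str] | None:
    """Rewrite a surface-order triple into canonical storage direction.

    Returns ``(class, relation, subject_id, object_id)`` or ``None`` when the
    type pair is not admissible under the network map.
    """
    if preferred_relation in INVERSE_RELATIONS:
        relation_class, preferred_relation = INVERSE_RELATIONS[preferred_relation]
        subject_id, object_id = object_id, subject_id
        subject_type, object_type = object_type, subject_type
    allowed = RELATION_TYPE_MAP.get(relation_class, frozenset())
    if (subject_type, object_type) not in allowed:
        return None
    return relation_class, preferred_relation, subject_id, object_id


# --------------------------------------------------------------------------
# combined lexicon bundle (vocabulary + relations) for the CLI
# --------------------------------------------------------------------------


def save_lexicon(
    vocab: Vocabulary, relations: RelationLexicon, path: str | Path
) -> None:
    payload = {"vocabulary": vocab.to_dict(), "relations": relations.to_dict()}
    Path(path).write_text(
        json.dumps(payload, sort_keys=True, indent=1) + "\n", encoding="utf-8"
    )


def load_lexicon(path: str | Path) -> tuple[Vocabulary, RelationLexicon]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return (
        Vocabulary.from_dict(payload["vocabulary"]),
        RelationLexicon.from_dict(payload["relations"]),
    )
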
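"""The Intelligence Network: a provenance-merged store of accepted assertions.

Assertions are subject–relation–object triples over vocabulary concepts.  The
store is keyed by the *preferred relation* (not the relation class) so that
distinct verbs between the same concept pair stay distinct; class-level
queries aggregate at read time.  Identical triples merge by provenance union,
which makes merging a commutative, idempotent operation on the triple set.

Serialisation is a ``.inet`` bundle directory: ``concepts.tsv`` plus
``assertions.jsonl``, both sorted before writing so two exports of the same
network are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .vocabulary import (
    AssertnetError,
    Concept,
    ConceptType,
    Vocabulary,
)

logger = logging.getLogger("assertnet")

__all__ = [
    "NetworkError",
    "NetworkParseError",
    "Status",
    "Provenance",
    "AssertionRecord",
    "MergedAssertion",
    "IntelligenceNetwork",
    "merge_assertions",
    "query_assertions",
    "network_stats",
    "export_network",
    "import_network",
    "write_assertions_jsonl",
    "read_assertions_jsonl",
]


class NetworkError(AssertnetError):
    """Invalid network operation (non-accepted assertion, dangling endpoint)."""


class NetworkParseError(NetworkError):
    """A serialised network could not be parsed."""

    def __init__(self, message: str, line: int | None = None) -> None:
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


class Status:
    PROTO = "PROTO"
    ACCEPTED = "ACCEPTED"
    REJECTED = "REJECTED"


@dataclasses.dataclass(frozen=True, order=True)
class Provenance:
    """Where one assertion instance came from."""

    source: str
    doc_id: str
    sentence_index: int
    snippet: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "Provenance":
        return cls(d["source"], d["doc_id"], int(d["sentence_index"]), d["snippet"])


@dataclasses.dataclass(frozen=True)
class AssertionRecord:
    """A single-provenance assertion as it flows between pipeline stages."""

    subject_id: str
    relation_class: str
    relation: str
    object_id: str
    status: str
    provenance: Provenance

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.subject_id, self.relation, self.object_id)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "relation_class": self.relation_class,
            "relation": self.relation,
            "object_id": self.object_id,
            "status": self.status,
            "provenance": self.provenance.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AssertionRecord":
        return cls(
            d["subject_id"],
            d["relation_class"],
            d["relation"],
            d["object_id"],
            d["status"],
            Provenance.from_dict(d["provenance"]),
        )


@dataclasses.dataclass
class MergedAssertion:
    """A deduplicated network assertion carrying all of its provenances."""

    subject_id: str
    relation_class: str
    relation: str
    object_id: str
    provenance: tuple[Provenance, ...]

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.subject_id, self.relation, self.object_id)


class IntelligenceNetwork:
    """Concept table + merged assertion store, queryable by type and class."""

    def __init__(self, vocab: Vocabulary | None = None) -> None:
        self._vocab = vocab if vocab is not None else Vocabulary()
        self._assertions: dict[tuple[str, str, str], MergedAssertion] = {}

    @property
    def vocab(self) -> Vocabulary:
        return self._vocab

    @property
    def concepts(self) -> Mapping[str, Concept]:
        return self._vocab.concepts

    @property
    def assertions(self) -> Mapping[tuple[str, str, str], MergedAssertion]:
        return self._assertions

    def __len__(self) -> int:
        return len(self._assertions)

    def add(self, record: AssertionRecord) -> None:
        if record.status != Status.ACCEPTED:
            raise NetworkError(
                f"assertion {record.triple} has status {record.status!r}; "
                "only ACCEPTED assertions enter the network"
            )
        for cid in (record.subject_id, record.object_id):
            if cid not in self._vocab:
                raise NetworkError(f"unknown concept id {cid!r} in {record.triple}")
        merged = self._assertions.get(record.triple)
        if merged is None:
            self._assertions[record.triple] = MergedAssertion(
                record.subject_id,
                record.relation_class,
                record.relation,
                record.object_id,
                (record.provenance,),
            )
        elif record.provenance not in merged.provenance:
            merged.provenance = merged.provenance + (record.provenance,)

    def equals(self, other: "IntelligenceNetwork") -> bool:
        """Equality on triple set, provenance sets, and concept table."""
        if set(self._assertions) != set(other._assertions):
            return False
        for key, a in self._assertions.items():
            b = other._assertions[key]
            if a.relation_class != b.relation_class:
                return False
            if set(a.provenance) != set(b.provenance):
                return False
        mine = {
            (c.concept_id, c.type, c.preferred_label, c.synonyms) for c in self._vocab
        }
        theirs = {
            (c.concept_id, c.type, c.preferred_label, c.synonyms) for c in other._vocab
        }
        return mine == theirs


def merge_assertions(
    net: IntelligenceNetwork, new: Iterable[AssertionRecord]
) -> IntelligenceNetwork:
    """Merge accepted assertions into ``net`` (provenance union) and return it."""
    for record in new:
        net.add(record)
    return net


def query_assertions(
    net: IntelligenceNetwork,
    subject_type: ConceptType | None = None,
    relation_class: str | None = None,
    object_ids: set[str] | None = None,
    subject_ids: set[str] | None = None,
) -> list[MergedAssertion]:
    """All assertions satisfying every provided constraint, ordered by triple key."""
    out = []
    for key in sorted(net.assertions):
        a = net.assertions[key]
        if subject_type is not None and net.concepts[a.subject_id].type != subject_type:
            continue
        if relation_class is not None and a.relation_class != relation_class:
            continue
        if object_ids is not None and a.object_id not in object_ids:
            continue
        if subject_ids is not None and a.subject_id not in subject_ids:
            continue
        out.append(a)
    return out


def network_stats(net: IntelligenceNetwork) -> dict:
    """Counts by concept type and relation class, plus the assertion total."""
    by_class: dict[str, int] = {}
    for a in net.assertions.values():
        by_class[a.relation_class] = by_class.get(a.relation_class, 0) + 1
    return {
        "n_concepts": len(net.vocab),
        "n_assertions": len(net),
        "concepts_by_type": {
            t.value: n for t, n in net.vocab.counts_by_type().items()
        },
        "assertions_by_class": dict(sorted(by_class.items())),
    }


# --------------------------------------------------------------------------
# serialisation
# --------------------------------------------------------------------------

_CONCEPT_COLUMNS = ("concept_id", "type", "preferred_label", "synonyms")


def export_network(net: IntelligenceNetwork, path: str | Path) -> Path:
    """Write a ``.inet`` bundle (sorted, hence deterministic byte-for-byte)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    lines = ["\t".join(_CONCEPT_COLUMNS)]
    for c in sorted(net.vocab, key=lambda c: c.concept_id):
        lines.append(
            "\t".join(
                (c.concept_id, c.type.value, c.preferred_label, "|".join(sorted(c.synonyms)))
            )
        )
    (path / "concepts.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    with (path / "assertions.jsonl").open("w", encoding="utf-8") as fh:
        for key in sorted(net.assertions):
            a = net.assertions[key]
            fh.write(
                json.dumps(
                    {
                        "subject_id": a.subject_id,
                        "relation_class": a.relation_class,
                        "relation": a.relation,
                        "object_id": a.object_id,
                        "provenance": [p.to_dict() for p in sorted(a.provenance)],
                    },
                    sort_keys=True,
                    separators=(",", ":"),
                )
                + "\n"
            )
    return path


def import_network(path: str | Path) -> IntelligenceNetwork:
    """Read a ``.inet`` bundle; malformed lines raise :class:`NetworkParseError`."""
    path = Path(path)
    concepts_path = path / "concepts.tsv"
    assertions_path = path / "assertions.jsonl"
    if not concepts_path.is_file() or not assertions_path.is_file():
        raise NetworkParseError(f"{path} is not an .inet bundle")

    concepts = []
    with concepts_path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _CONCEPT_COLUMNS:
            raise NetworkParseError(f"bad concepts header {header}", line=1)
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise NetworkParseError("expected 4 tab-separated fields", line=lineno)
            cid, ctype, label, syns = parts
            try:
                concepts.append(
                    Concept(cid, ConceptType(ctype), label, frozenset(syns.split("|")))
                )
            except ValueError as exc:
                raise NetworkParseError(str(exc), line=lineno) from None
    net = IntelligenceNetwork(Vocabulary(concepts))

    with assertions_path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            try:
                rec = json.loads(raw)
                provs = [Provenance.from_dict(p) for p in rec["provenance"]]
                if not provs:
                    raise KeyError("provenance")
                for p in provs:
                    net.add(
                        AssertionRecord(
                            rec["subject_id"],
                            rec["relation_class"],
                            rec["relation"],
                            rec["object_id"],
                            Status.ACCEPTED,
                            p,
                        )
                    )
            except NetworkError:
                raise
            except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
                raise NetworkParseError(f"bad assertion record: {exc}", line=lineno) from None
    return net


def write_assertions_jsonl(
    records: Sequence[AssertionRecord], path: str | Path
) -> None:
    """Write stage-level (single-provenance) assertion records, one per line."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_dict(), sort_keys=True, separators=(",", ":")) + "\n")


def read_assertions_jsonl(path: str | Path) -> list[AssertionRecord]:
    out = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            try:
                out.append(AssertionRecord.from_dict(json.loads(raw)))
            except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
                raise NetworkParseError(f"bad assertion record: {exc}", line=lineno) from None
    return out
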
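"""Declarative ingestion of structured tabular sources into assertions.

Gene–disease tables (OMIM-like), expression tables (GEO-like) and similar
structured sources become assertions through a mapping spec that names the
subject/object columns, declares their concept types, fixes the relation, and
optionally filters rows on constant column values (the "relevant records"
mechanism).  Rows whose surfaces do not resolve to a unique concept of the
declared type are counted and reported, never silently dropped.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from .network import AssertionRecord, Provenance, Status
from .vocabulary import (
    AssertnetError,
    ConceptType,
    RELATION_TYPE_MAP,
    RelationLexicon,
    Vocabulary,
    normalize_term,
)

logger = logging.getLogger("assertnet")

__all__ = ["MappingError", "MappingSpec", "SkippedRow", "IngestReport", "ingest_table"]


class MappingError(AssertnetError):
    """A mapping spec is invalid or does not fit the table."""


@dataclasses.dataclass(frozen=True)
class MappingSpec:
    """How one structured table maps onto assertions.

    ``direction`` is ``"forward"`` when (subject_column, object_column) are
    already in canonical storage order, ``"inverse"`` when they must be
    swapped (e.g. an expression matrix listing regions first).
    """

    source_name: str
    subject_column: str
    subject_type: ConceptType
    object_column: str
    object_type: ConceptType
    relation_class: str
    relation: str
    direction: str = "forward"
    constant_filters: Mapping[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.subject_column == self.object_column:
            raise MappingError("subject_column and object_column must differ")
        if self.direction not in {"forward", "inverse"}:
            raise MappingError(f"bad direction {self.direction!r}")
        object.__setattr__(self, "constant_filters", dict(self.constant_filters))
        s_type, o_type = self.canonical_types()
        allowed = RELATION_TYPE_MAP.get(self.relation_class)
        if allowed is None:
            raise MappingError(f"unknown relation class {self.relation_class!r}")
        if (s_type, o_type) not in allowed:
            raise MappingError(
                f"relation class {self.relation_class} does not admit "
                f"({s_type.value}, {o_type.value}) under the network map"
            )

    def canonical_types(self) -> tuple[ConceptType, ConceptType]:
        if self.direction == "inverse":
            return self.object_type, self.subject_type
        return self.subject_type, self.object_type

    def validate_relation(self, lexicon: RelationLexicon) -> None:
        cls = lexicon.relation_class_of(self.relation)
        if cls is not None and cls != self.relation_class:
            raise MappingError(
                f"relation {self.relation!r} belongs to class {cls}, "
                f"not {self.relation_class}"
            )

    # JSON spec files -------------------------------------------------------

    @classmethod
    def from_json(cls, path: str | Path) -> "MappingSpec":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        try:
            return cls(
                source_name=d["source_name"],
                subject_column=d["subject_column"],
                subject_type=ConceptType(d["subject_type"]),
                object_column=d["object_column"],
                object_type=ConceptType(d["object_type"]),
                relation_class=d["relation_class"],
                relation=d["relation"],
                direction=d.get("direction", "forward"),
                constant_filters=d.get("constant_filters", {}),
            )
        except KeyError as exc:
            raise MappingError(f"{path}: missing mapping field {exc}") from None
        except ValueError as exc:
            raise MappingError(f"{path}: {exc}") from None

    def to_json(self, path: str | Path) -> None:
        d = {
            "source_name": self.source_name,
            "subject_column": self.subject_column,
            "subject_type": self.subject_type.value,
            "object_column": self.object_column,
            "object_type": self.object_type.value,
            "relation_class": self.relation_class,
            "relation": self.relation,
            "direction": self.direction,
            "constant_filters": dict(self.constant_filters),
        }
        Path(path).write_text(json.dumps(d, sort_keys=True, indent=1) + "\n", "utf-8")


@dataclasses.dataclass(frozen=True)
class SkippedRow:
    row: int  # 1-based data-row number (header excluded)
    reason: str
    surface: str


@dataclasses.dataclass(frozen=True)
class IngestReport:
    n_rows: int
    n_assertions: int
    skipped: tuple[SkippedRow, ...]


def _resolve(vocab: Vocabulary, surface: str, ctype: ConceptType):
    """Concepts of the declared type matching the surface."""
    return sorted(
        (c for c in normalize_term(vocab, surface) if c.type == ctype),
        key=lambda c: c.concept_id,
    )


def ingest_table(
    table: str | Path | pd.DataFrame,
    mapping: MappingSpec,
    vocab: Vocabulary,
) -> tuple[list[AssertionRecord], IngestReport]:
    """Turn each resolvable table row into one ACCEPTED assertion.

    Row provenance uses 1-based data-row numbers as ``doc_id``.  The skip
    report accounts for every non-emitting row, so
    ``n_assertions + len(skipped) == n_rows`` always holds.
    """
    if isinstance(table, pd.DataFrame):
        frame = table.astype(str)
    else:
        frame = pd.read_csv(Path(table), sep="\t", dtype=str, keep_default_na=False)
    for col in (mapping.subject_column, mapping.object_column, *mapping.constant_filters):
        if col not in frame.columns:
            raise MappingError(f"mapped column {col!r} not in table")

    assertions: list[AssertionRecord] = []
    skipped: list[SkippedRow] = []
    for rownum, row in enumerate(frame.itertuples(index=False), start=1):
        record = dict(zip(frame.columns, row))
        if any(record[c] != v for c, v in mapping.constant_filters.items()):
            skipped.append(SkippedRow(rownum, "filtered", ""))
            continue
        subj_surface = record[mapping.subject_column]
        obj_surface = record[mapping.object_column]
        ok = True
        for role, surface, ctype in (
            ("subject", subj_surface, mapping.subject_type),
            ("object", obj_surface, mapping.object_type),
        ):
            hits = _resolve(vocab, surface, ctype)
            if not hits:
                skipped.append(SkippedRow(rownum, f"{role}-unresolved", surface))
                ok = False
                break
            if len(hits) > 1:
                skipped.append(SkippedRow(rownum, f"{role}-ambiguous", surface))
                ok = False
                break
        if not ok:
            continue
        subj = _resolve(vocab, subj_surface, mapping.subject_type)[0]
        obj = _resolve(vocab, obj_surface, mapping.object_type)[0]
        if mapping.direction == "inverse":
            subj, obj = obj, subj
        assertions.append(
            AssertionRecord(
                subject_id=subj.concept_id,
                relation_class=mapping.relation_class,
                relation=mapping.relation,
                object_id=obj.concept_id,
                status=Status.ACCEPTED,
                provenance=Provenance(
                    source=mapping.source_name,
                    doc_id=str(rownum),
                    sentence_index=0,
                    snippet=f"{subj_surface}\t{obj_surface}",
                ),
            )
        )
    report = IngestReport(len(frame), len(assertions), tuple(skipped))
    assert report.n_assertions + len(report.skipped) == report.n_rows
    return assertions, report
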
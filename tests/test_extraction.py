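"""Sentence segmentation, proto-assertion extraction, curation and QC sampling."""

import json
import random

import pytest

from assertnet.extraction import (
    CurationError,
    Document,
    ExtractionPattern,
    QCPlan,
    apply_curation,
    extract_proto_assertions,
    load_decisions,
    qc_sample,
    segment_sentences,
)
from assertnet.network import AssertionRecord, Provenance, Status
from assertnet.vocabulary import AssertnetError


def _sent(matcher, relations, text, patterns=None, doc_id="d", index=0):
    doc = Document(doc_id, "test", text)
    records = segment_sentences(doc)
    assert len(records) == 1
    kwargs = {} if patterns is None else {"patterns": patterns}
    return extract_proto_assertions(records[0], matcher, relations, **kwargs)


class TestSegmentation:
    def test_three_segments_with_guard_off(self):
        doc = Document("d", "t", "A. B. is here. Next one.")
        texts = [s.text for s in segment_sentences(doc, abbreviation_guard=False)]
        assert texts == ["A.", "B. is here.", "Next one."]

    def test_guard_keeps_initials_together(self):
        doc = Document("d", "t", "A. B. is here. Next one.")
        texts = [s.text for s in segment_sentences(doc)]
        assert texts == ["A. B. is here.", "Next one."]

    def test_single_sentence_without_terminator(self):
        doc = Document("d", "t", "no terminator at all")
        records = segment_sentences(doc)
        assert len(records) == 1 and records[0].offset == 0

    def test_whitespace_only_text(self):
        assert segment_sentences(Document("d", "t", "  \n \t ")) == []

    def test_offsets_recover_sentence_text(self):
        text = "Amyloid deposits were seen. BACE1 is increased in AD.  Final words."
        doc = Document("d", "t", text)
        for rec in segment_sentences(doc):
            assert text[rec.offset : rec.offset + len(rec.text)] == rec.text
        assert [r.sentence_index for r in segment_sentences(doc)] == [0, 1, 2]


class TestExtraction:
    def test_pathology_link_example(self, matcher, relations):
        protos = _sent(matcher, relations, "BACE-1 is involved in amyloid formation.")
        assert [(p.subject_id, p.relation, p.object_id) for p in protos] == [
            ("BACE1", "IS INVOLVED IN", "amyloid-fibril-formation")
        ]
        assert protos[0].status == Status.PROTO
        assert protos[0].relation_class == "PATHOLOGY_LINK"

    def test_disease_link_example(self, matcher, relations):
        protos = _sent(
            matcher, relations, "Amyloid deposition is associated with Alzheimer's disease."
        )
        assert [(p.subject_id, p.relation, p.object_id) for p in protos] == [
            ("amyloid-deposition", "IS ASSOCIATED WITH", "alzheimer-s-disease")
        ]

    @pytest.mark.parametrize(
        "sentence",
        [
            "BACE1 is not increased in Alzheimer's disease.",
            "There was no BACE1 increased in Alzheimer's disease.",
            "BACE1 never is expressed in hippocampus.",
            "BACE1 failed to be detected in hippocampus.",
            "The absence of BACE1 is increased in Alzheimer's disease.",
        ],
    )
    def test_negation_cue_blocks_extraction(self, matcher, relations, sentence):
        assert _sent(matcher, relations, sentence) == []

    def test_negation_cue_after_relation_does_not_block(self, matcher, relations):
        # only cues *before* the verb suppress extraction; the spurious
        # "but not thalamus" pairing is exactly what curation is for
        protos = _sent(
            matcher, relations, "BACE1 is expressed in hippocampus but not thalamus."
        )
        assert ("BACE1", "hippocampus") in [(p.subject_id, p.object_id) for p in protos]

    def test_inverse_relation_canonicalised(self, matcher, relations):
        protos = _sent(matcher, relations, "The hippocampus expresses BACE1.")
        assert [(p.subject_id, p.relation, p.object_id) for p in protos] == [
            ("BACE1", "IS EXPRESSED IN", "hippocampus")
        ]

    def test_type_incompatible_pair_rejected(self, matcher, relations):
        # a disease cannot be the expression site of a region
        assert _sent(matcher, relations, "Alzheimer's disease is expressed in BACE1.") == []

    def test_gap_limit_respected(self, matcher, relations):
        filler = "as was shown by " + "very " * 12 + "careful work which says it"
        sentence = f"BACE1 {filler} is expressed in hippocampus."
        assert _sent(matcher, relations, sentence) == []
        tight = ExtractionPattern("tight", max_gap_tokens=1)
        assert (
            _sent(matcher, relations, "BACE1 probably truly is expressed in hippocampus.",
                  patterns=[tight])
            == []
        )

    def test_subject_relation_object_order_enforced(self, matcher, relations):
        protos = _sent(matcher, relations, "Is expressed in hippocampus, BACE1.")
        assert protos == []

    def test_snippet_contains_both_surfaces(self, matcher, relations):
        protos = _sent(
            matcher, relations, "We found that BACE-1 is expressed in the hippocampus."
        )
        (p,) = protos
        assert p.subject.surface in p.provenance.snippet
        assert p.object.surface in p.provenance.snippet

    def test_deterministic_and_serialisable(self, matcher, relations):
        sentence = "Amyloid deposits and tau phosphorylation: BACE1 is increased in AD."
        a = _sent(matcher, relations, sentence)
        b = _sent(matcher, relations, sentence)
        dump = lambda protos: json.dumps([p.to_record().to_dict() for p in protos])
        assert dump(a) == dump(b)


def _proto_like(matcher, relations, i):
    protos = _sent(
        matcher,
        relations,
        f"BACE1 is expressed in hippocampus.",
        doc_id=f"doc{i}",
    )
    return protos[0]


class TestCuration:
    def _protos(self, matcher, relations, n=5):
        out = []
        for i in range(n):
            doc = Document(f"doc{i}", "t", "BACE1 is expressed in hippocampus.")
            (rec,) = segment_sentences(doc)
            out.extend(extract_proto_assertions(rec, matcher, relations))
        return out

    def test_bookkeeping(self, matcher, relations):
        protos = self._protos(matcher, relations)
        decisions = {p.decision_key: d for p, d in zip(protos, ["accept"] * 3 + ["reject"] * 2)}
        accepted, rejected, undecided = apply_curation(protos, decisions)
        assert (len(accepted), len(rejected), len(undecided)) == (3, 2, 0)
        assert all(p.status == Status.ACCEPTED for p in accepted)
        assert all(p.status == Status.REJECTED for p in rejected)

    def test_empty_decision_table_all_undecided(self, matcher, relations):
        protos = self._protos(matcher, relations)
        accepted, rejected, undecided = apply_curation(protos, {})
        assert (len(accepted), len(rejected), len(undecided)) == (0, 0, 5)
        assert all(p.status == Status.PROTO for p in undecided)

    def test_unmatched_decision_warns_not_fails(self, matcher, relations, caplog):
        protos = self._protos(matcher, relations, n=1)
        ghost = ("X", "IS EXPRESSED IN", "Y", "nodoc", 0)
        with caplog.at_level("WARNING", logger="assertnet"):
            apply_curation(protos, {ghost: "accept"})
        assert "matches no proto-assertion" in caplog.text

    def test_contradictory_decisions_error(self, tmp_path):
        rows = [
            "subject_id\trelation\tobject_id\tdoc_id\tsentence_index\tdecision",
            "BACE1\tIS EXPRESSED IN\thippocampus\tdoc0\t0\taccept",
            "BACE1\tIS EXPRESSED IN\thippocampus\tdoc0\t0\treject",
        ]
        path = tmp_path / "d.tsv"
        path.write_text("\n".join(rows) + "\n", encoding="utf-8")
        with pytest.raises(CurationError, match="contradictory"):
            load_decisions(path)


def _dummy_records(n):
    return [
        AssertionRecord(
            f"P{i}", "EXPRESSION", "IS EXPRESSED IN", "hippocampus",
            Status.ACCEPTED, Provenance("t", f"d{i}", 0, "snippet"),
        )
        for i in range(n)
    ]


class TestQCSampling:
    def test_all_correct_passes(self):
        records = _dummy_records(200)
        report = qc_sample(records, lambda a: True, QCPlan(125, 3, seed=1))
        assert report.accuracy == 1.0 and report.passed and report.errors_found == 0

    def test_census_reports_exact_accuracy(self):
        records = _dummy_records(1000)
        bad = {r.triple for r in records[:100]}
        report = qc_sample(records, lambda a: a.triple not in bad, QCPlan(1000, 30, seed=3))
        assert report.sampled_n == 1000
        assert report.accuracy == pytest.approx(0.900)
        assert report.errors_found == 100

    def test_empty_population_indeterminate(self):
        report = qc_sample([], lambda a: True, QCPlan(125, 3, seed=0))
        assert report.indeterminate and report.sampled_n == 0 and report.passed is None

    def test_mapping_oracle_and_ci_bounds(self):
        records = _dummy_records(50)
        truth = {r.triple: i % 10 != 0 for i, r in enumerate(records)}
        report = qc_sample(records, truth, QCPlan(50, 3, seed=0))
        assert report.errors_found == 5
        assert 0.0 <= report.ci_low <= report.accuracy <= report.ci_high <= 1.0

    def test_seed_controls_sample(self):
        records = _dummy_records(500)
        bad = {r.triple for r in records[::7]}
        oracle = lambda a: a.triple not in bad
        r1 = qc_sample(records, oracle, QCPlan(100, 3, seed=5))
        r2 = qc_sample(records, oracle, QCPlan(100, 3, seed=5))
        r3 = qc_sample(records, oracle, QCPlan(100, 3, seed=6))
        assert r1 == r2
        assert (r1.errors_found != r3.errors_found) or (r1 != r3)

    def test_invalid_plan_rejected(self):
        with pytest.raises(AssertnetError):
            QCPlan(10, 10, seed=0)
        with pytest.raises(AssertnetError):
            QCPlan(0, 0, seed=0)
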
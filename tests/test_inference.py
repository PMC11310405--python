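from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mpnlp.inference import (aggregate_counts, attribute_event_timing,
                             default_thresholds, infer_phenotypes,
                             optimize_thresholds)
from mpnlp.ner import Annotation, Document
from mpnlp.synthetic import RenderConfig, render_corpus
from mpnlp.vocab import CVA, DVT, HC, HTN, PE, TE_COL, VTE_COL


def _ann(doc, concept, negated=False, subject="patient", start=0):
    return Annotation(doc, start, start + 3, "xxx", concept,
                      negated=negated, subject=subject)


def test_counts_apply_the_meta_annotation_filter():
    """5 affirmative + 2 negated HTN mentions across 3 documents -> count 5;
    other-subject mentions never count; unannotated patients keep zero rows."""
    doc_map = {"d1": "p1", "d2": "p1", "d3": "p1", "d4": "p2", "d5": "p3"}
    anns = (
        [_ann("d1", HTN, start=10 * i) for i in range(2)]
        + [_ann("d2", HTN, start=10 * i) for i in range(2)]
        + [_ann("d3", HTN)]
        + [_ann("d1", HTN, negated=True), _ann("d3", HTN, negated=True)]
        + [_ann("d4", HTN, subject="other", start=10 * i) for i in range(3)]
    )
    counts = aggregate_counts(anns, doc_map, concepts=[HTN])
    assert counts.at["p1", HTN] == 5
    assert counts.at["p2", HTN] == 0
    assert counts.at["p3", HTN] == 0


def test_historical_mentions_are_counted():
    anns = [Annotation("d1", 0, 3, "xxx", CVA, temporality="historical")]
    counts = aggregate_counts(anns, {"d1": "p1"}, concepts=[CVA])
    assert counts.at["p1", CVA] == 1


def test_orphan_document_rejected():
    with pytest.raises(KeyError, match="unknown doc_id"):
        aggregate_counts([_ann("ghost", HTN)], {"d1": "p1"})


def test_strict_greater_threshold_rule():
    counts = pd.DataFrame({HTN: [3, 2], HC: [2, 1]},
                          index=pd.Index(["a", "b"], name="patient_id"))
    pheno = infer_phenotypes(counts, {HTN: 2, HC: 1}, derived=False)
    assert pheno.at["a", HTN] == 1 and pheno.at["b", HTN] == 0
    assert pheno.at["a", HC] == 1 and pheno.at["b", HC] == 0


def test_derived_columns_and_all_zero_counts():
    counts = pd.DataFrame({DVT: [0, 4], PE: [0, 0], CVA: [0, 0]},
                          index=pd.Index(["a", "b"], name="patient_id"))
    pheno = infer_phenotypes(counts, {DVT: 2, PE: 2, CVA: 2})
    assert pheno.loc["a"].sum() == 0
    assert pheno.at["b", VTE_COL] == 1 and pheno.at["b", TE_COL] == 1
    assert pheno.at["a", VTE_COL] == 0 and pheno.at["a", TE_COL] == 0


def test_missing_threshold_names_the_concept():
    counts = pd.DataFrame({HTN: [1]}, index=pd.Index(["a"], name="patient_id"))
    with pytest.raises(ValueError, match=HTN):
        infer_phenotypes(counts, {})


def test_study_default_thresholds():
    t_et = default_thresholds([HTN, HC, CVA], "ET")
    assert t_et == {HTN: 2, HC: 1, CVA: 2}
    t_pv = default_thresholds([HTN, HC, CVA], "PV")
    assert t_pv == {HTN: 2, HC: 1, CVA: 1}


@given(st.lists(st.integers(0, 12), min_size=4, max_size=40),
       st.integers(0, 9))
def test_threshold_monotonicity(values, t):
    """Raising a threshold never adds a positive call."""
    counts = pd.DataFrame({HTN: values},
                          index=pd.Index([f"p{i}" for i in range(len(values))],
                                         name="patient_id"))
    lo = infer_phenotypes(counts, {HTN: t}, derived=False)[HTN]
    hi = infer_phenotypes(counts, {HTN: t + 1}, derived=False)[HTN]
    assert (hi <= lo).all()


def _f1(pred, gold):
    tp = int(np.sum((pred == 1) & (gold == 1)))
    fp = int(np.sum((pred == 1) & (gold == 0)))
    fn = int(np.sum((pred == 0) & (gold == 1)))
    return 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0


def test_optimizer_perfect_separation():
    idx = pd.Index([f"p{i}" for i in range(6)], name="patient_id")
    counts = pd.DataFrame({HTN: [3, 4, 5, 2, 2, 0]}, index=idx)
    gold = pd.DataFrame({HTN: [1, 1, 1, 0, 0, 0]}, index=idx)
    result = optimize_thresholds(counts, gold)
    assert result.thresholds[HTN] == 2
    assert result.f1[HTN] == 1.0


def test_optimizer_matches_exhaustive_oracle():
    rng = np.random.default_rng(42)
    for trial in range(10):
        idx = pd.Index([f"p{i}" for i in range(50)], name="patient_id")
        counts = pd.DataFrame({HTN: rng.integers(0, 11, 50),
                               CVA: rng.integers(0, 6, 50)}, index=idx)
        gold = pd.DataFrame({HTN: rng.integers(0, 2, 50),
                             CVA: rng.integers(0, 2, 50)}, index=idx)
        result = optimize_thresholds(counts, gold)
        for concept in (HTN, CVA):
            c = counts[concept].to_numpy()
            g = gold[concept].to_numpy()
            scores = [_f1((c > t).astype(int), g) for t in range(11)]
            best = max(scores)
            assert result.f1[concept] == pytest.approx(best)
            assert result.thresholds[concept] == scores.index(best)


def test_optimizer_zero_counts_tie_break():
    idx = pd.Index(["a", "b"], name="patient_id")
    counts = pd.DataFrame({HTN: [0, 0]}, index=idx)
    gold = pd.DataFrame({HTN: [1, 0]}, index=idx)
    result = optimize_thresholds(counts, gold)
    assert result.thresholds[HTN] == 0 and result.f1[HTN] == 0.0


def test_optimizer_warns_on_concept_missing_from_gold():
    idx = pd.Index(["a"], name="patient_id")
    counts = pd.DataFrame({HTN: [5], CVA: [1]}, index=idx)
    gold = pd.DataFrame({HTN: [1]}, index=idx)
    with pytest.warns(UserWarning, match="absent from gold"):
        result = optimize_thresholds(counts, gold)
    assert result.thresholds[CVA] == 2


def test_event_timing_strata_rules():
    docs = [Document("d1", "p1", "2010-01-01", "x"),
            Document("d2", "p1", "2012-06-01", "x"),
            Document("d3", "p2", "2013-01-01", "x")]
    anns = [_ann("d1", CVA), _ann("d2", DVT), _ann("d3", CVA)]
    pheno = pd.DataFrame({CVA: [1, 1], DVT: [1, 0]},
                         index=pd.Index(["p1", "p2"], name="patient_id"))
    timing = attribute_event_timing(
        pheno, anns, docs,
        diagnosis_date={"p1": date(2011, 1, 1), "p2": date(2011, 1, 1)},
        cyto_start={"p1": date(2012, 1, 1), "p2": None},
        cyto_end={"p1": date(2012, 12, 31), "p2": None},
    )
    by = {(r.patient_id, r.concept_id): r.stratum for r in timing.itertuples()}
    assert by[("p1", CVA)] == "pre_at_diagnosis"
    assert by[("p1", DVT)] == "during_cytoreduction"
    assert by[("p2", CVA)] == "other"


def test_event_timing_excludes_patients_without_diagnosis_date():
    docs = [Document("d1", "p1", "2010-01-01", "x")]
    pheno = pd.DataFrame({CVA: [1]}, index=pd.Index(["p1"], name="patient_id"))
    with pytest.warns(UserWarning, match="diagnosis date"):
        timing = attribute_event_timing(pheno, [_ann("d1", CVA)], docs,
                                        diagnosis_date={})
    assert len(timing) == 0


def test_planted_timing_strata_recovered_exactly(small_truth, vocab):
    """Zero-noise generator bookkeeping: recovered strata == planted strata."""
    docs, gold, _ = render_corpus(small_truth, RenderConfig(
        negated_rate=0, ambiguous_rate=0, other_subject_rate=0, seed=11), vocab)
    timing = attribute_event_timing(
        small_truth.phenotypes, gold, docs, small_truth.diagnosis_date,
        small_truth.cyto_start, small_truth.cyto_end)
    merged = timing.merge(small_truth.event_strata,
                          on=["patient_id", "concept_id"],
                          suffixes=("_found", "_planted"))
    assert len(merged) == len(small_truth.event_strata)
    assert (merged["stratum_found"] == merged["stratum_planted"]).all()
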
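"""Reference cohort data and headline analyses.

The study that this pipeline models compared thrombotic-event burden between
560 essential-thrombocythemia (ET) and 360 polycythemia-vera (PV) patients
and tested hypertension (HTN) against event types.  Its published per-event
counts and 2x2 tables are small enough to ship as data here; the functions
below recompute the comparison statistics from those counts and run the
synthetic parameter-recovery experiments, so the headline numbers can be
regenerated from scratch at any time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .inference import aggregate_counts, infer_phenotypes, optimize_thresholds
from .metrics import patient_level_metrics
from .ner import annotate_corpus, evaluate_ner
from .stats import (ContingencyTable2x2, cohort_report_from_counts,
                    fisher_exact, logistic_regression, two_proportion_test)
from .synthetic import RenderConfig, et_config, pv_config, render_corpus, sample_cohort
from .vocab import CONCEPT_LABELS, DM, HC, HTN, SMOKER, default_vocabulary

__all__ = [
    "ET_N", "PV_N", "TABLE1_EVENT_COUNTS", "HTN_EVENT_TABLES",
    "reproduce_event_comparison", "htn_event_association",
    "planted_or_recovery", "zero_noise_document_f1",
    "heldout_htn_patient_f1",
]

ET_N = 560
PV_N = 360

#: Reported thrombotic-event counts per cohort: event -> (ET, PV).
TABLE1_EVENT_COUNTS: dict[str, tuple[int, int]] = {
    "Deep venous thrombosis": (8, 10),
    "Pulmonary embolism": (10, 10),
    "Myocardial infarction": (20, 11),
    "Cerebrovascular accident": (43, 51),
    "Portal vein thrombosis": (7, 18),
    "Cerebral venous thrombosis": (6, 1),
    "Thrombosis, NOS": (45, 70),
    "Venous thromboembolism": (65, 84),
    "Overall thrombotic events": (112, 126),
}

#: Reported HTN-vs-event 2x2 tables (exposed-with-event, exposed-without,
#: unexposed-with-event, unexposed-without) and the test each comparison used.
HTN_EVENT_TABLES: dict[str, dict] = {
    "ET_HTN_CVA": {"table": (15, 104, 28, 413), "test": "fisher"},
    "ET_HTN_VTE": {"table": (21, 98, 44, 397), "test": "two_proportion"},
    "PV_HTN_CVA": {"table": (20, 63, 31, 246), "test": "fisher"},
    "PV_HTN_VTE": {"table": (19, 64, 65, 212), "test": "fisher"},
}


def reproduce_event_comparison() -> pd.DataFrame:
    """ET-vs-PV event comparison recomputed from the reported counts."""
    return cohort_report_from_counts(TABLE1_EVENT_COUNTS, ET_N, PV_N,
                                     label_a="ET", label_b="PV")


def htn_event_association(name: str) -> dict[str, float]:
    """Recompute one reported HTN-event association.

    Fisher comparisons return both the two-sided (minimum-likelihood) and the
    one-sided p-value: the reported ET figure corresponds to the two-sided
    test, the reported PV figure to the one-sided test (the source mixed
    conventions), so both are always surfaced.
    """
    spec = HTN_EVENT_TABLES[name]
    a, b, c, d = spec["table"]
    if spec["test"] == "fisher":
        table = ContingencyTable2x2(a, b, c, d)
        return {
            "p_two_sided": fisher_exact(table).p_value,
            "p_one_sided": fisher_exact(table, "greater").p_value,
        }
    res = two_proportion_test(a, a + b, c, c + d)
    return {"p_two_sided": res.p_value}


def planted_or_recovery(
    cohort: str = "ET",
    n_patients: int = 5600,
    n_seeds: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Multivariable logistic recovery of the planted HTN->TE odds ratio.

    For each replicate a cohort is sampled at scale, overall thrombotic
    events are regressed on HTN, HC, DM and smoking, and the HTN odds ratio
    with its 95% CI is recorded.
    """
    make = et_config if cohort == "ET" else pv_config
    rows = []
    for i in range(n_seeds):
        cfg = make(n_patients, seed=seed * 100_003 + i)
        truth = sample_cohort(cfg)
        design = truth.phenotypes[[HTN, HC, DM, SMOKER]].rename(
            columns=CONCEPT_LABELS)
        fit = logistic_regression(design, truth.te_indicator())
        lo, hi = fit.ci("HTN")
        rows.append({
            "replicate": i,
            "or_htn": fit.odds_ratio("HTN"),
            "ci_low": lo, "ci_high": hi,
            "covers_planted": lo <= cfg.te_odds_ratios[HTN] <= hi,
            "converged": fit.converged,
        })
    return pd.DataFrame(rows)


def zero_noise_document_f1(n_patients: int = 560, seed: int = 0) -> pd.Series:
    """Document-level NER F1 per concept on a noise-free rendered corpus."""
    vocab = default_vocabulary()
    truth = sample_cohort(et_config(n_patients, seed=seed))
    docs, gold, _ = render_corpus(truth, RenderConfig(
        negated_rate=0.0, ambiguous_rate=0.0, other_subject_rate=0.0,
        seed=seed), vocab)
    predicted = annotate_corpus(docs, vocab)
    report = evaluate_ner(predicted, gold, doc_ids=[d.doc_id for d in docs])
    return pd.Series({c: m["f1"] for c, m in report.per_concept.items()},
                     name="document_f1")


def heldout_htn_patient_f1(
    n_patients: int = 560,
    n_seeds: int = 10,
    gold_fraction: float = 0.20,
    seed: int = 0,
) -> list[float]:
    """End-to-end phenotyping under noise: held-out patient-level HTN F1.

    Each replicate renders a noisy ET-like corpus, annotates it, optimizes
    thresholds on a gold subsample, and scores HTN presence on the remaining
    patients.
    """
    vocab = default_vocabulary()
    f1s = []
    for i in range(n_seeds):
        rep_seed = seed * 100_003 + 17 * i + 1
        truth = sample_cohort(et_config(n_patients, seed=rep_seed))
        docs, _, gold_labels = render_corpus(
            truth, RenderConfig(seed=rep_seed), vocab)
        annotations = annotate_corpus(docs, vocab)
        counts = aggregate_counts(
            annotations, {d.doc_id: d.patient_id for d in docs},
            concepts=vocab.concept_ids)
        rng = np.random.default_rng(rep_seed)
        n_gold = max(1, int(round(gold_fraction * len(gold_labels))))
        gold_ids = pd.Index(rng.choice(gold_labels.index.to_numpy(),
                                       size=n_gold, replace=False))
        opt = optimize_thresholds(counts, gold_labels.loc[gold_ids])
        pheno = infer_phenotypes(counts, opt.thresholds)
        heldout = gold_labels.index.difference(gold_ids)
        report = patient_level_metrics(pheno, gold_labels.loc[heldout])
        f1s.append(report.f1(HTN))
    return f1s
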
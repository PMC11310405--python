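"""Patient-level phenotype inference from aggregated mention counts.

Annotations are aggregated to a patients x concepts count matrix (negated and
other-subject mentions excluded; historical mentions kept, since lifetime
events are what the cohort statistics need), then thresholded: a phenotype is
called present iff its mention count strictly exceeds the concept's
threshold.  Thresholds can be fixed (study defaults: 2 everywhere, 1 for
hypercholesterolemia, and 1 for HC/CVA in the PV cohort) or optimized against
a gold-labelled subsample by exhaustive patient-level F1 search over a small
integer grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ner import Annotation, Document
from .vocab import CVA, EVENT_CONCEPTS, HC, TE_COL, VENOUS_EVENTS, VTE_COL

__all__ = [
    "aggregate_counts",
    "infer_phenotypes",
    "optimize_thresholds",
    "attribute_event_timing",
    "default_thresholds",
    "ThresholdOptimization",
]

DEFAULT_THRESHOLD = 2


def default_thresholds(concepts: Iterable[str], cohort: str = "ET") -> dict[str, int]:
    """Study thresholds: t=2 (present iff >2 mentions); t=1 for HC, and for
    HC and CVA in the PV cohort."""
    out = {c: DEFAULT_THRESHOLD for c in concepts}
    if HC in out:
        out[HC] = 1
    if cohort == "PV" and CVA in out:
        out[CVA] = 1
    return out


def aggregate_counts(
    annotations: Sequence[Annotation],
    doc_to_patient: Mapping[str, str],
    concepts: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Sum mention counts per patient and concept.

    Only affirmative mentions about the patient contribute (negated=False,
    subject="patient"); historical mentions are included.  Every patient in
    ``doc_to_patient`` appears, zero rows allowed.  An annotation whose
    doc_id has no patient raises ``KeyError``.
    """
    patients = sorted(set(doc_to_patient.values()))
    concept_set = list(concepts) if concepts is not None else sorted(
        {a.concept_id for a in annotations})
    counts = pd.DataFrame(0, index=pd.Index(patients, name="patient_id"),
                          columns=concept_set, dtype=np.int64)
    for ann in annotations:
        if ann.doc_id not in doc_to_patient:
            raise KeyError(f"annotation references unknown doc_id {ann.doc_id!r}")
        if ann.negated or ann.subject != "patient":
            continue
        if ann.concept_id not in counts.columns:
            if concepts is not None:
                continue
            counts[ann.concept_id] = 0
        counts.at[doc_to_patient[ann.doc_id], ann.concept_id] += 1
    return counts


def infer_phenotypes(
    counts: pd.DataFrame,
    thresholds: Mapping[str, int],
    derived: bool = True,
) -> pd.DataFrame:
    """Binary phenotype matrix: present iff count > threshold.

    With ``derived=True`` two union columns are appended: ``VTE`` (any venous
    event: DVT, PE, PVT, CST, thrombosis NOS) and ``TE`` (any event concept).
    """
    missing = [c for c in counts.columns if c not in thresholds]
    if missing:
        raise ValueError(f"no threshold for concepts: {missing}")
    for c, t in thresholds.items():
        if c in counts.columns and t < 0:
            raise ValueError(f"threshold for {c} must be >= 0, got {t}")
    pheno = pd.DataFrame(
        {c: (counts[c] > thresholds[c]).astype(np.int8) for c in counts.columns},
        index=counts.index,
    )
    if derived:
        venous = [c for c in VENOUS_EVENTS if c in pheno.columns]
        events = [c for c in EVENT_CONCEPTS if c in pheno.columns]
        pheno[VTE_COL] = (pheno[venous].sum(axis=1) > 0).astype(np.int8) if venous else 0
        pheno[TE_COL] = (pheno[events].sum(axis=1) > 0).astype(np.int8) if events else 0
    return pheno


def _binary_f1(pred: np.ndarray, gold: np.ndarray) -> float:
    tp = int(np.sum((pred == 1) & (gold == 1)))
    fp = int(np.sum((pred == 1) & (gold == 0)))
    fn = int(np.sum((pred == 0) & (gold == 1)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


@dataclass
class ThresholdOptimization:
    thresholds: dict[str, int]
    f1: dict[str, float]


def optimize_thresholds(
    counts: pd.DataFrame,
    gold: pd.DataFrame,
    grid: Sequence[int] = tuple(range(0, 11)),
    default: int = DEFAULT_THRESHOLD,
) -> ThresholdOptimization:
    """Per-concept threshold maximizing patient-level F1 on gold patients.

    Exhaustive search over ``grid``; ties broken by the smallest threshold.
    Concepts absent from the gold set fall back to ``default`` with a
    warning.  Gold patients must be a subset of the count matrix's patients.
    """
    missing_patients = gold.index.difference(counts.index)
    if len(missing_patients):
        raise ValueError(
            f"gold patients missing from counts: {list(missing_patients[:5])}")
    thresholds: dict[str, int] = {}
    achieved: dict[str, float] = {}
    sub = counts.loc[gold.index]
    for concept in counts.columns:
        if concept not in gold.columns:
            warnings.warn(
                f"concept {concept} absent from gold labels; falling back to "
                f"default threshold {default}", stacklevel=2)
            thresholds[concept] = default
            achieved[concept] = float("nan")
            continue
        c = sub[concept].to_numpy()
        g = gold[concept].to_numpy()
        best_t, best_f1 = None, -1.0
        for t in grid:
            f1 = _binary_f1((c > t).astype(int), g)
            if f1 > best_f1 + 1e-12:  # strict improvement: ties keep smallest t
                best_t, best_f1 = t, f1
        thresholds[concept] = int(best_t)
        achieved[concept] = best_f1
    return ThresholdOptimization(thresholds, achieved)


STRATUM_PRE = "pre_at_diagnosis"
STRATUM_DURING = "during_cytoreduction"
STRATUM_OTHER = "other"


def attribute_event_timing(
    phenotypes: pd.DataFrame,
    annotations: Sequence[Annotation],
    documents: Sequence[Document],
    diagnosis_date: Mapping[str, date] | pd.Series,
    cyto_start: Mapping[str, date | None] | pd.Series | None = None,
    cyto_end: Mapping[str, date | None] | pd.Series | None = None,
    event_concepts: Sequence[str] = EVENT_CONCEPTS,
) -> pd.DataFrame:
    """Timing stratum of each inferred event phenotype.

    An event's date is the date of the earliest document contributing a
    non-negated, patient-subject mention of it.  Stratum: pre/at diagnosis if
    that date <= diagnosis date; during cytoreduction if inside the
    cytoreduction interval; otherwise "other".  Patients without a known
    diagnosis date are excluded with a warning.
    """
    doc_info = {d.doc_id: (d.patient_id, date.fromisoformat(d.date))
                for d in documents}
    earliest: dict[tuple[str, str], date] = {}
    for ann in annotations:
        if ann.negated or ann.subject != "patient":
            continue
        if ann.doc_id not in doc_info:
            raise KeyError(f"annotation references unknown doc_id {ann.doc_id!r}")
        pid, d = doc_info[ann.doc_id]
        key = (pid, ann.concept_id)
        if key not in earliest or d < earliest[key]:
            earliest[key] = d

    rows = []
    skipped = []
    for pid in phenotypes.index:
        diag = _lookup(diagnosis_date, pid)
        for concept in event_concepts:
            if concept not in phenotypes.columns or not phenotypes.at[pid, concept]:
                continue
            if diag is None:
                skipped.append(pid)
                continue
            event_date = earliest.get((pid, concept))
            if event_date is None:
                continue  # phenotype called without a dateable mention
            if event_date <= diag:
                stratum = STRATUM_PRE
            else:
                cs = _lookup(cyto_start, pid) if cyto_start is not None else None
                ce = _lookup(cyto_end, pid) if cyto_end is not None else None
                if cs is not None and ce is not None and cs <= event_date <= ce:
                    stratum = STRATUM_DURING
                else:
                    stratum = STRATUM_OTHER
            rows.append({"patient_id": pid, "concept_id": concept,
                         "event_date": event_date, "stratum": stratum})
    if skipped:
        warnings.warn(
            f"{len(set(skipped))} patients lack a diagnosis date and were "
            "excluded from the timing report", stacklevel=2)
    return pd.DataFrame(rows, columns=["patient_id", "concept_id",
                                       "event_date", "stratum"])


def _lookup(mapping, pid):
    if mapping is None:
        return None
    try:
        val = mapping[pid]
    except KeyError:
        return None
    if val is None or (isinstance(val, float) and np.isnan(val)) or pd.isna(val):
        return None
    return val
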
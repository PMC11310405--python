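"""Patient-level validation metrics: inferred phenotypes vs gold labels.

This is the second validation step: document-level NER quality (see
``mpnlp.ner.evaluate_ner``) says how well mentions are recognised, while
these metrics say how well the pipeline recognises the *presence or absence
of a condition in a patient's record* — the quantity that matters clinically.
The two need not agree: a concept can score well per document yet poorly per
patient (fluctuating statuses such as smoking), so both are always computed
independently and reported side by side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MetricReport", "patient_level_metrics"]


@dataclass
class MetricReport:
    """Per-concept confusion counts and derived proportions.

    Any 0/0 ratio is reported as 0.0 and the ratio's name is listed in the
    concept's ``degenerate`` set, so an empty class (e.g. a phenotype never
    observed in the cohort) stays visible instead of disappearing.
    """

    per_concept: dict[str, dict] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for concept, m in self.per_concept.items():
            row = {"concept_id": concept, **{k: v for k, v in m.items()
                                             if k != "degenerate"}}
            row["degenerate"] = "|".join(sorted(m["degenerate"]))
            rows.append(row)
        return pd.DataFrame(rows)

    def f1(self, concept_id: str) -> float:
        return self.per_concept[concept_id]["f1"]


def _ratio(num: int, denom: int, name: str, flags: set[str]) -> float:
    if denom == 0:
        flags.add(name)
        return 0.0
    return num / denom


def patient_level_metrics(predicted: pd.DataFrame, gold: pd.DataFrame) -> MetricReport:
    """Confusion counts, sensitivity, specificity, precision and F1 per concept.

    ``predicted`` must cover every gold patient and every gold concept
    column; extra predicted patients/columns are ignored.
    """
    missing_patients = gold.index.difference(predicted.index)
    if len(missing_patients):
        raise ValueError(
            f"predictions missing gold patients: {list(missing_patients[:5])}")
    missing_cols = [c for c in gold.columns if c not in predicted.columns]
    if missing_cols:
        raise ValueError(f"concepts in gold but absent from predictions: {missing_cols}")

    pred = predicted.loc[gold.index]
    report = MetricReport()
    for concept in gold.columns:
        p = pred[concept].to_numpy().astype(bool)
        g = gold[concept].to_numpy().astype(bool)
        tp = int(np.sum(p & g))
        fp = int(np.sum(p & ~g))
        fn = int(np.sum(~p & g))
        tn = int(np.sum(~p & ~g))
        flags: set[str] = set()
        sens = _ratio(tp, tp + fn, "sensitivity", flags)
        spec = _ratio(tn, tn + fp, "specificity", flags)
        prec = _ratio(tp, tp + fp, "precision", flags)
        if prec + sens == 0:
            flags.add("f1")
            f1 = 0.0
        else:
            f1 = 2 * prec * sens / (prec + sens)
        report.per_concept[concept] = {
            "tp": tp, "fp": fp, "fn": fn, "tn": tn,
            "sensitivity": sens, "specificity": spec, "precision": prec,
            "f1": f1, "degenerate": flags,
        }
    return report
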
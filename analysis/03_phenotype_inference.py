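#!/usr/bin/env python
"""Infer patient phenotypes: aggregate counts, optimize thresholds on a gold
subsample (20% ET / 17% PV), validate on the held-out patients, and stratify
event timing.

Writes per cohort: counts.csv, phenotypes.csv, thresholds.csv,
patient_metrics.csv, event_timing.csv under results/<cohort>/.
"""

import argparse
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from mpnlp import io as mio
from mpnlp.inference import (aggregate_counts, attribute_event_timing,
                             infer_phenotypes, optimize_thresholds)
from mpnlp.metrics import patient_level_metrics
from mpnlp.vocab import CONCEPT_LABELS, HTN, default_vocabulary

ROOT = Path(__file__).resolve().parents[1]
GOLD_FRACTION = {"ET": 0.20, "PV": 0.17}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    vocab = default_vocabulary()

    for cohort in ("ET", "PV"):
        data = ROOT / "results" / "data" / cohort
        docs = mio.read_documents(data / "documents.jsonl")
        annotations = mio.read_annotations(data / "annotations.jsonl")
        gold_labels = mio.read_labels(data / "gold_labels.csv")
        truth = pd.read_csv(data / "truth.csv", dtype={"patient_id": str}
                            ).set_index("patient_id")

        counts = aggregate_counts(
            annotations, {d.doc_id: d.patient_id for d in docs},
            concepts=vocab.concept_ids)

        rng = np.random.default_rng(args.seed)
        n_gold = int(round(GOLD_FRACTION[cohort] * len(gold_labels)))
        gold_ids = pd.Index(rng.choice(gold_labels.index.to_numpy(),
                                       size=n_gold, replace=False))
        opt = optimize_thresholds(counts, gold_labels.loc[gold_ids])
        pheno = infer_phenotypes(counts, opt.thresholds)
        heldout = gold_labels.index.difference(gold_ids)
        report = patient_level_metrics(pheno, gold_labels.loc[heldout])

        timing = attribute_event_timing(
            pheno, annotations, docs,
            diagnosis_date={p: date.fromisoformat(v)
                            for p, v in truth["diagnosis_date"].items()},
            cyto_start={p: date.fromisoformat(v) if isinstance(v, str) and v else None
                        for p, v in truth["cyto_start"].items()},
            cyto_end={p: date.fromisoformat(v) if isinstance(v, str) and v else None
                      for p, v in truth["cyto_end"].items()},
        )

        out = ROOT / "results" / cohort
        out.mkdir(parents=True, exist_ok=True)
        counts.to_csv(out / "counts.csv", index_label="patient_id")
        pheno.to_csv(out / "phenotypes.csv", index_label="patient_id")
        pd.DataFrame({"threshold": opt.thresholds, "optimizer_f1": opt.f1}
                     ).rename_axis("concept_id").to_csv(out / "thresholds.csv")
        report.to_frame().to_csv(out / "patient_metrics.csv", index=False)
        timing.to_csv(out / "event_timing.csv", index=False)

        htn_f1 = report.f1(HTN)
        strata = timing["stratum"].value_counts(normalize=True)
        print(f"{cohort}: optimized thresholds on {n_gold} gold patients, "
              f"validated on {len(heldout)} held-out; HTN F1 {htn_f1:.3f}")
        print(f"  thresholds: "
              + ", ".join(f"{CONCEPT_LABELS[c]}>{t}"
                          for c, t in opt.thresholds.items()))
        print("  event timing: "
              + ", ".join(f"{s} {100 * v:.0f}%" for s, v in strata.items()))


if __name__ == "__main__":
    main()
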
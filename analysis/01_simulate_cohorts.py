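#!/usr/bin/env python
"""Simulate the ET (n=560) and PV (n=360) cohorts and render their corpora.

Writes, per cohort, under results/data/<cohort>/: documents.jsonl, truth.csv,
gold_labels.csv, gold_annotations.jsonl, vocabulary.csv.
"""

import argparse
from pathlib import Path

import numpy as np

from mpnlp import io as mio
from mpnlp.synthetic import RenderConfig, et_config, pv_config, simulate_cohort
from mpnlp.vocab import CONCEPT_LABELS, HTN, default_vocabulary, write_vocabulary

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    for make, n in ((et_config, 560), (pv_config, 360)):
        cfg = make(n, seed=args.seed)
        truth, docs, gold_ann, gold_labels = simulate_cohort(
            cfg, RenderConfig(seed=args.seed))
        out = ROOT / "results" / "data" / cfg.cohort_name
        out.mkdir(parents=True, exist_ok=True)
        mio.write_documents(docs, out / "documents.jsonl")
        mio.write_annotations(gold_ann, out / "gold_annotations.jsonl")
        mio.write_labels(gold_labels, out / "gold_labels.csv")
        mio.write_truth(truth, out / "truth.csv")
        write_vocabulary(default_vocabulary(), out / "vocabulary.csv")

        per_patient = {}
        for d in docs:
            per_patient[d.patient_id] = per_patient.get(d.patient_id, 0) + 1
        counts = list(per_patient.values())
        print(f"{cfg.cohort_name}: {n} patients, {len(docs)} documents "
              f"(median {np.median(counts):.0f}/patient, "
              f"IQR {np.percentile(counts, 25):.0f}-{np.percentile(counts, 75):.0f}); "
              f"{len(gold_ann)} gold mentions; "
              f"HTN prevalence {100 * truth.phenotypes[HTN].mean():.1f}%; "
              f"TE rate {100 * truth.te_indicator().mean():.1f}%")
        present = truth.phenotypes.mean().sort_values(ascending=False)
        top = ", ".join(f"{CONCEPT_LABELS[c]} {100 * v:.1f}%"
                        for c, v in present.head(5).items())
        print(f"  top prevalences: {top}")


if __name__ == "__main__":
    main()
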
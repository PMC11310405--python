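#!/usr/bin/env python
"""Annotate the simulated corpora and validate the rule engine per document.

First validation step: predicted mentions are scored against the generator's
gold annotations (span overlap + concept + negation agreement).  Writes
results/ner_document_metrics.csv and the annotation files the next stage uses.
"""

import argparse
from pathlib import Path

import pandas as pd

from mpnlp import io as mio
from mpnlp.ner import annotate_corpus, evaluate_ner
from mpnlp.vocab import CONCEPT_LABELS, default_vocabulary

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()
    vocab = default_vocabulary()
    frames = []
    for cohort in ("ET", "PV"):
        data = ROOT / "results" / "data" / cohort
        docs = mio.read_documents(data / "documents.jsonl")
        gold = mio.read_annotations(data / "gold_annotations.jsonl")
        predicted = annotate_corpus(docs, vocab)
        mio.write_annotations(predicted, data / "annotations.jsonl")
        report = evaluate_ner(predicted, gold, doc_ids=[d.doc_id for d in docs])
        df = pd.DataFrame.from_dict(report.per_concept, orient="index")
        df.index.name = "concept_id"
        df.insert(0, "concept", [CONCEPT_LABELS.get(c, c) for c in df.index])
        df.insert(0, "cohort", cohort)
        frames.append(df.reset_index())
        worst = df["f1"].min()
        print(f"{cohort}: {len(predicted)} predicted vs {len(gold)} gold "
              f"mentions; document-level F1 min {worst:.3f}, "
              f"mean {df['f1'].mean():.3f} over {len(df)} concepts")

    out = ROOT / "results" / "ner_document_metrics.csv"
    pd.concat(frames).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
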
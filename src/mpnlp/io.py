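"""Serialization: documents and annotations as JSONL, labels/truth as CSV.

Dialects
--------
documents.jsonl   one object per line: {doc_id, patient_id, date, text}
annotations.jsonl {doc_id, start, end, concept_id, negated, subject, temporality}
labels CSV        patient_id + one 0/1 column per concept
truth CSV         labels CSV + diagnosis_date, cyto_start, cyto_end (ISO dates)
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .ner import Annotation, Document
from .synthetic import CohortTruth

__all__ = [
    "write_documents", "read_documents",
    "write_annotations", "read_annotations",
    "write_labels", "read_labels",
    "write_truth",
]


def write_documents(docs: Iterable[Document], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for d in docs:
            fh.write(json.dumps({
                "doc_id": d.doc_id, "patient_id": d.patient_id,
                "date": d.date, "text": d.text,
            }) + "\n")


def read_documents(path: str | Path) -> list[Document]:
    docs = []
    with Path(path).open() as fh:
        for line in fh:
            if line.strip():
                docs.append(Document(**json.loads(line)))
    return docs


def write_annotations(annotations: Iterable[Annotation], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for a in annotations:
            fh.write(json.dumps({
                "doc_id": a.doc_id, "start": a.start, "end": a.end,
                "surface": a.surface, "concept_id": a.concept_id,
                "negated": a.negated, "subject": a.subject,
                "temporality": a.temporality,
            }) + "\n")


def read_annotations(path: str | Path) -> list[Annotation]:
    out = []
    with Path(path).open() as fh:
        for line in fh:
            if line.strip():
                out.append(Annotation(**json.loads(line)))
    return out


def write_labels(labels: pd.DataFrame, path: str | Path) -> None:
    labels.to_csv(path, index_label="patient_id")


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str}).set_index("patient_id")
    return df


def write_truth(truth: CohortTruth, path: str | Path) -> None:
    df = truth.phenotypes.copy()
    df["diagnosis_date"] = [d.isoformat() for d in truth.diagnosis_date]
    df["cyto_start"] = [d.isoformat() if d is not None else ""
                        for d in truth.cyto_start]
    df["cyto_end"] = [d.isoformat() if d is not None else ""
                      for d in truth.cyto_end]
    df.to_csv(path, index_label="patient_id")
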
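"""End-to-end pipeline: annotate -> aggregate -> (optimize) -> infer ->
validate -> cohort statistics, with serialized artifacts.

The pipeline operates on one document corpus that may contain one or two
cohorts (a patient -> cohort-label CSV selects membership; with two labels
the report compares them).  Thresholds are either the study defaults per
cohort or optimized against a gold-labelled subsample.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .inference import (aggregate_counts, default_thresholds, infer_phenotypes,
                        optimize_thresholds)
from .metrics import patient_level_metrics
from .ner import annotate_corpus
from .stats import build_cohort_report
from .vocab import EVENT_CONCEPTS, TE_COL, VTE_COL, default_vocabulary, load_vocabulary

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("mpnlp")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    documents: str
    output_dir: str
    vocabulary: str | None = None
    gold_labels: str | None = None
    cohort_labels: str | None = None      # CSV: patient_id, cohort
    threshold_mode: str = "fixed"         # {"fixed", "optimized"}
    thresholds: dict[str, int] | None = None  # explicit override (fixed mode)
    grid: list[int] = field(default_factory=lambda: list(range(0, 11)))
    gold_fraction: float = 1.0            # optimizer subsample of gold patients
    seed: int = 0
    default_cohort: str = "ET"

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("fixed", "optimized"):
            raise ValueError(f"threshold_mode {self.threshold_mode!r}")
        if not 0.0 < self.gold_fraction <= 1.0:
            raise ValueError("gold_fraction must be in (0, 1]")
        if self.threshold_mode == "optimized" and self.gold_labels is None:
            raise ValueError("optimized threshold mode requires gold_labels")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the full pipeline and write the artifact bundle.

    Artifacts (under ``config.output_dir``): ``annotations.jsonl``,
    ``counts.csv``, ``phenotypes.csv``, ``metrics.json``, ``report.csv``.
    Returns the artifact paths keyed by name.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    vocab = (load_vocabulary(config.vocabulary) if config.vocabulary
             else default_vocabulary())
    docs = _stage("load_documents")(mio.read_documents)(config.documents)
    logger.info("loaded %d documents", len(docs))
    doc_to_patient = {d.doc_id: d.patient_id for d in docs}

    cohort_of = _load_cohorts(config, set(doc_to_patient.values()))

    annotations = _stage("annotate")(annotate_corpus)(docs, vocab)
    logger.info("produced %d annotations", len(annotations))
    ann_path = out_dir / "annotations.jsonl"
    mio.write_annotations(annotations, ann_path)

    counts = _stage("aggregate")(aggregate_counts)(
        annotations, doc_to_patient, concepts=vocab.concept_ids)
    counts_path = out_dir / "counts.csv"
    counts.to_csv(counts_path, index_label="patient_id")

    gold = mio.read_labels(config.gold_labels) if config.gold_labels else None

    pheno_parts = []
    metrics_payload: dict = {"threshold_mode": config.threshold_mode, "cohorts": {}}
    rng = np.random.default_rng(config.seed)
    for cohort in sorted(set(cohort_of.values())):
        members = [p for p in counts.index if cohort_of[p] == cohort]
        sub_counts = counts.loc[members]
        cohort_info: dict = {}
        gold_eval = None
        if config.threshold_mode == "fixed":
            thresholds = dict(config.thresholds) if config.thresholds else \
                default_thresholds(vocab.concept_ids, cohort)
            missing = [c for c in sub_counts.columns if c not in thresholds]
            if missing:
                raise PipelineError(f"stage 'infer' failed: no threshold for {missing}")
            gold_eval = gold.loc[gold.index.intersection(members)] if gold is not None else None
        else:
            cohort_gold = gold.loc[gold.index.intersection(members)]
            if len(cohort_gold) == 0:
                raise PipelineError(
                    f"stage 'optimize' failed: no gold patients in cohort {cohort}")
            n_opt = max(1, int(round(config.gold_fraction * len(cohort_gold))))
            opt_ids = pd.Index(rng.choice(cohort_gold.index.to_numpy(), size=n_opt,
                                          replace=False))
            opt = _stage("optimize")(optimize_thresholds)(
                sub_counts, cohort_gold.loc[opt_ids], grid=config.grid)
            thresholds = opt.thresholds
            cohort_info["optimizer_f1"] = opt.f1
            cohort_info["n_gold_optimization"] = int(n_opt)
            heldout = cohort_gold.index.difference(opt_ids)
            gold_eval = cohort_gold.loc[heldout] if len(heldout) else cohort_gold

        pheno = _stage("infer")(infer_phenotypes)(sub_counts, thresholds)
        pheno_parts.append(pheno.assign(cohort=cohort))
        cohort_info["thresholds"] = thresholds
        if gold_eval is not None and len(gold_eval):
            report = _stage("validate")(patient_level_metrics)(
                pheno, gold_eval[[c for c in gold_eval.columns if c in pheno.columns]])
            cohort_info["patient_level"] = {
                c: {k: (sorted(v) if isinstance(v, set) else v) for k, v in m.items()}
                for c, m in report.per_concept.items()
            }
            cohort_info["n_gold_evaluation"] = int(len(gold_eval))
        metrics_payload["cohorts"][cohort] = cohort_info

    phenotypes = pd.concat(pheno_parts)
    pheno_path = out_dir / "phenotypes.csv"
    phenotypes.to_csv(pheno_path, index_label="patient_id")

    metrics_path = out_dir / "metrics.json"
    metrics_path.write_text(json.dumps(metrics_payload, indent=2, default=float))

    report_df = _stage("stats")(_cohort_report)(phenotypes, vocab)
    report_path = out_dir / "report.csv"
    report_df.to_csv(report_path, index=False)

    logger.info("pipeline complete: %d patients, %d cohort(s)",
                len(phenotypes), phenotypes["cohort"].nunique())
    return {
        "annotations": ann_path,
        "counts": counts_path,
        "phenotypes": pheno_path,
        "metrics": metrics_path,
        "report": report_path,
    }


def _load_cohorts(config: PipelineConfig, patients: set[str]) -> dict[str, str]:
    if config.cohort_labels is None:
        return {p: config.default_cohort for p in patients}
    df = pd.read_csv(config.cohort_labels, dtype=str)
    if not {"patient_id", "cohort"} <= set(df.columns):
        raise PipelineError(
            "stage 'load_cohorts' failed: cohort CSV needs patient_id, cohort")
    mapping = dict(zip(df["patient_id"], df["cohort"]))
    missing = patients - mapping.keys()
    if missing:
        raise PipelineError(
            f"stage 'load_cohorts' failed: {len(missing)} patients without a "
            f"cohort label (e.g. {sorted(missing)[:3]})")
    return {p: mapping[p] for p in patients}


def _cohort_report(phenotypes: pd.DataFrame, vocab) -> pd.DataFrame:
    event_cols = [c for c in EVENT_CONCEPTS if c in phenotypes.columns]
    event_cols += [c for c in (VTE_COL, TE_COL) if c in phenotypes.columns]
    labels = {c: vocab.label(c) for c in event_cols}
    cohorts = sorted(phenotypes["cohort"].unique())
    if len(cohorts) == 2:
        a, b = cohorts
        return build_cohort_report(
            phenotypes[phenotypes["cohort"] == a],
            phenotypes[phenotypes["cohort"] == b],
            event_columns=event_cols, label_a=a, label_b=b, labels=labels)
    # single cohort: prevalence table, no comparison p-values
    sub = phenotypes[phenotypes["cohort"] == cohorts[0]]
    return pd.DataFrame({
        "event": [labels[c] for c in event_cols],
        f"n_{cohorts[0]}": [int(sub[c].sum()) for c in event_cols],
        f"pct_{cohorts[0]}": [100 * float(sub[c].mean()) for c in event_cols],
        "p_unadjusted": [float("nan")] * len(event_cols),
        "method": ["none"] * len(event_cols),
    })
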
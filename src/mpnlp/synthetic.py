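"""Synthetic MPN cohorts and clinic-letter corpora with gold annotations.

Real hospital records cannot be redistributed, so every downstream stage is
exercised on generated data whose headline structure matches the study
cohorts: per-patient document counts (right-skewed, matched to a target
median/IQR via a rounded log-normal), phenotype prevalences, comorbidity
co-occurrence (conditional links such as P(HTN | DM)), and a logistic
coupling between cardiovascular risk factors and thrombotic events whose
coefficients encode configured odds ratios.  The renderer plants templated
sentences — affirmative, negated, family-history, colloquial and
ambiguous-abbreviation noise — and records every planted mention as a gold
annotation, so the rule engine can be scored against a known truth.

All randomness flows from one explicit seed through named
``numpy.random.SeedSequence`` spawn keys, so cohort sampling and corpus
rendering are independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .ner import Annotation, Document
from .vocab import (
    CST, CVA, DM, DVT, HC, HTN, MI, NOS, OBESITY, PE, PVT, SMOKER,
    EVENT_CONCEPTS, RISK_FACTORS, Vocabulary, default_vocabulary,
)

__all__ = [
    "DocCountSpec",
    "CohortConfig",
    "CohortTruth",
    "RenderConfig",
    "sample_cohort",
    "render_corpus",
    "simulate_cohort",
    "et_config",
    "pv_config",
    "STRATUM_PRE", "STRATUM_DURING", "STRATUM_OTHER",
]

STRATUM_PRE = "pre_at_diagnosis"
STRATUM_DURING = "during_cytoreduction"
STRATUM_OTHER = "other"

_Z75 = 0.6744897501960817  # standard normal upper quartile


@dataclass(frozen=True)
class DocCountSpec:
    """Documents-per-patient distribution: rounded log-normal.

    Parameters are solved from the target median and IQR:
    mu = ln(median), sigma = ln(q3/q1) / (2 * z_0.75).
    """

    median: float
    iqr: tuple[float, float]

    def __post_init__(self) -> None:
        q1, q3 = self.iqr
        if not (0 < q1 <= self.median <= q3):
            raise ValueError(f"require 0 < q1 <= median <= q3, got {self}")

    @property
    def mu(self) -> float:
        return math.log(self.median)

    @property
    def sigma(self) -> float:
        q1, q3 = self.iqr
        if q3 == q1:
            return 0.0
        return math.log(q3 / q1) / (2 * _Z75)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        draws = rng.lognormal(self.mu, self.sigma, size=size)
        return np.clip(np.round(draws), 1, 250).astype(int)


@dataclass(frozen=True)
class CohortConfig:
    """Generating parameters for one cohort."""

    cohort_name: str
    n_patients: int
    prevalence: dict[str, float]
    conditional_links: tuple[tuple[str, str, float], ...] = ()
    te_odds_ratios: dict[str, float] = field(default_factory=dict)
    te_rate: float = 0.0
    docs_per_patient: DocCountSpec = DocCountSpec(20, (8, 34))
    timing_probs: tuple[float, float, float] = (0.58, 0.30, 0.12)
    cyto_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cohort_name not in ("ET", "PV"):
            raise ValueError(f"cohort_name must be 'ET' or 'PV', got {self.cohort_name!r}")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for cid, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {cid} outside [0, 1]: {p}")
        for given, target, p in self.conditional_links:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"conditional P({target}|{given}) outside [0, 1]: {p}")
        for cid, or_ in self.te_odds_ratios.items():
            if or_ <= 0:
                raise ValueError(f"odds ratio for {cid} must be > 0, got {or_}")
        if not 0.0 <= self.te_rate <= 1.0:
            raise ValueError("te_rate outside [0, 1]")
        if abs(sum(self.timing_probs) - 1.0) > 1e-9 or min(self.timing_probs) < 0:
            raise ValueError("timing_probs must be a probability triple")
        if not 0.0 <= self.cyto_fraction <= 1.0:
            raise ValueError("cyto_fraction outside [0, 1]")


@dataclass
class CohortTruth:
    """Latent patient-level truth against which everything is validated."""

    phenotypes: pd.DataFrame           # patients x concepts, 0/1
    diagnosis_date: pd.Series          # datetime.date per patient
    cyto_start: pd.Series              # datetime.date or None
    cyto_end: pd.Series
    event_strata: pd.DataFrame         # patient_id, concept_id, stratum
    docs_per_patient: DocCountSpec
    cohort_name: str = "ET"
    seed: int = 0

    @property
    def patient_ids(self) -> list[str]:
        return list(self.phenotypes.index)

    def te_indicator(self) -> pd.Series:
        events = [c for c in EVENT_CONCEPTS if c in self.phenotypes.columns]
        return (self.phenotypes[events].sum(axis=1) > 0).astype(int)


@dataclass(frozen=True)
class RenderConfig:
    """Corpus-rendering knobs (all rates are expected mentions per patient)."""

    mean_mentions: float = 4.0          # positive mentions per true phenotype
    negated_rate: float = 0.5           # negated mentions per absent phenotype
    ambiguous_rate: float = 0.3         # bare ambiguous-abbreviation sentences
    other_subject_rate: float = 0.2     # family-history mentions per absent phenotype
    template_set: str = "default"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mean_mentions", "negated_rate", "ambiguous_rate",
                     "other_subject_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def et_config(n_patients: int = 560, seed: int = 0) -> CohortConfig:
    """Essential-thrombocythemia cohort defaults (study-scale parameters)."""
    return CohortConfig(
        cohort_name="ET",
        n_patients=n_patients,
        prevalence={
            HTN: 0.213, HC: 0.096, DM: 0.046, SMOKER: 0.066, OBESITY: 0.0,
            MI: 0.036, CVA: 0.077, NOS: 0.080, DVT: 0.014, PE: 0.018,
            PVT: 0.013, CST: 0.011,
        },
        conditional_links=((DM, HTN, 0.692), (HC, HTN, 0.52)),
        te_odds_ratios={HTN: 2.5, HC: 1.3, DM: 1.2, SMOKER: 1.2},
        te_rate=0.20,
        docs_per_patient=DocCountSpec(20, (8, 34)),
        timing_probs=(0.58, 0.30, 0.12),
        seed=seed,
    )


def pv_config(n_patients: int = 360, seed: int = 0) -> CohortConfig:
    """Polycythemia-vera cohort defaults (study-scale parameters)."""
    return CohortConfig(
        cohort_name="PV",
        n_patients=n_patients,
        prevalence={
            HTN: 0.231, HC: 0.075, DM: 0.056, SMOKER: 0.056, OBESITY: 0.0,
            MI: 0.031, CVA: 0.142, NOS: 0.194, DVT: 0.028, PE: 0.028,
            PVT: 0.050, CST: 0.003,
        },
        conditional_links=((DM, HTN, 0.75), (HC, HTN, 0.667)),
        te_odds_ratios={HTN: 1.5, HC: 1.3, DM: 1.2, SMOKER: 1.1},
        te_rate=0.35,
        docs_per_patient=DocCountSpec(27, (11, 47)),
        timing_probs=(0.59, 0.24, 0.17),
        seed=seed,
    )


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(
        np.random.SeedSequence(seed, spawn_key=key)))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def _solve_link_model(
    p_target: float,
    givens: Sequence[str],
    given_prev: Sequence[float],
    cond_probs: Sequence[float],
) -> np.ndarray:
    """Parameters of a no-interaction logistic P(target | givens).

    Solved so the target's marginal equals ``p_target`` and each
    P(target | given_i = 1) equals ``cond_probs[i]``, with the given
    concepts treated as independent Bernoullis.  Raises on infeasible
    specifications.
    """
    k = len(givens)
    # necessary consistency check, link by link
    for g, pg, pc in zip(givens, given_prev, cond_probs):
        if pg >= 1.0:
            continue
        p0 = (p_target - pg * pc) / (1 - pg)
        if not -1e-12 <= p0 <= 1 + 1e-12:
            raise ValueError(
                f"inconsistent link: P(target)={p_target}, P(given {g})={pg}, "
                f"P(target|{g})={pc} implies P(target|not {g})={p0:.4f} "
                "outside [0, 1]"
            )

    cells = np.array(np.meshgrid(*[[0, 1]] * k, indexing="ij")).reshape(k, -1).T
    cell_p = np.prod(np.where(cells == 1, np.asarray(given_prev),
                              1 - np.asarray(given_prev)), axis=1)

    def residuals(theta):
        eta = theta[0] + cells @ theta[1:]
        mu = _sigmoid(eta)
        out = [float(np.sum(cell_p * mu)) - p_target]
        for i, pc in enumerate(cond_probs):
            mask = cells[:, i] == 1
            w = cell_p[mask]
            out.append(float(np.sum(w * mu[mask]) / np.sum(w)) - pc)
        return out

    x0 = np.zeros(k + 1)
    x0[0] = _logit(min(max(p_target, 1e-6), 1 - 1e-6))
    for i, pc in enumerate(cond_probs):
        x0[1 + i] = _logit(min(max(pc, 1e-6), 1 - 1e-6)) - x0[0]
    sol = optimize.root(residuals, x0, method="hybr")
    if not sol.success or np.max(np.abs(residuals(sol.x))) > 1e-8:
        raise ValueError(
            "inconsistent link specification: no logistic link reproduces "
            f"marginal {p_target} with conditionals {list(cond_probs)}"
        )
    return sol.x


def _solve_event_rates(prevalences: np.ndarray, te_rate: float) -> np.ndarray:
    """Bernoulli rates for event types conditional on an event having occurred.

    Event vectors are drawn independently then conditioned on >= 1 event;
    rates are fixed-point-solved so each marginal prevalence is exact:
    q_k = (prev_k / te_rate) * (1 - prod_j (1 - q_j)).
    """
    r = prevalences / te_rate
    if np.any(r > 1 + 1e-12):
        bad = np.argmax(r)
        raise ValueError(
            f"event prevalence {prevalences[bad]:.4f} exceeds overall TE rate "
            f"{te_rate}: infeasible"
        )
    q = np.clip(r, 0, 1)
    for _ in range(500):
        p_none = float(np.prod(1 - q))
        q_new = np.clip(r * (1 - p_none), 0, 1 - 1e-12)
        if np.max(np.abs(q_new - q)) < 1e-13:
            q = q_new
            break
        q = q_new
    p_none = float(np.prod(1 - q))
    if p_none >= 1 - 1e-12:
        raise ValueError("degenerate event-rate solution (all rates zero)")
    return q


def sample_cohort(config: CohortConfig) -> CohortTruth:
    """Draw patient-level truth: phenotypes, events, dates, timing strata."""
    n = config.n_patients
    ids = [f"{config.cohort_name}{i:04d}" for i in range(1, n + 1)]
    concepts = list(config.prevalence)

    link_targets: dict[str, list[tuple[str, float]]] = {}
    for given, target, p in config.conditional_links:
        if given not in config.prevalence or target not in config.prevalence:
            raise ValueError(f"link ({given}, {target}) references unknown concept")
        link_targets.setdefault(target, []).append((given, p))
    for target, pairs in link_targets.items():
        for given, _ in pairs:
            if given in link_targets:
                raise ValueError(
                    f"link given {given} is itself a link target; chained links "
                    "are not supported"
                )

    rng_ph = _rng(config.seed, 1)
    pheno = pd.DataFrame(0, index=pd.Index(ids, name="patient_id"),
                         columns=concepts, dtype=np.int8)

    risk_like = [c for c in concepts if c not in EVENT_CONCEPTS]
    for c in risk_like:
        if c in link_targets:
            continue
        pheno[c] = (rng_ph.random(n) < config.prevalence[c]).astype(np.int8)

    for target, pairs in link_targets.items():
        givens = [g for g, _ in pairs]
        conds = [p for _, p in pairs]
        p_t = config.prevalence[target]
        if p_t == 0.0:
            if any(pc > 0 for pc in conds):
                raise ValueError(
                    f"inconsistent link: target {target} has zero prevalence "
                    "but positive conditional probability"
                )
            pheno[target] = 0
            continue
        theta = _solve_link_model(
            p_t, givens, [config.prevalence[g] for g in givens], conds)
        eta = theta[0] + pheno[givens].to_numpy(dtype=float) @ theta[1:]
        pheno[target] = (rng_ph.random(n) < _sigmoid(eta)).astype(np.int8)

    # thrombotic events: logistic risk model on the configured risk factors,
    # intercept calibrated so the sampled cohort's expected TE rate is exact
    event_cols = [c for c in concepts if c in EVENT_CONCEPTS]
    event_prev = np.array([config.prevalence[c] for c in event_cols])
    rng_te = _rng(config.seed, 2)
    if config.te_rate > 0 and event_prev.sum() > 0:
        rf = list(config.te_odds_ratios)
        beta = np.array([math.log(config.te_odds_ratios[c]) for c in rf])
        score = pheno[rf].to_numpy(dtype=float) @ beta if rf else np.zeros(n)

        def mean_rate(b0):
            return float(np.mean(_sigmoid(b0 + score))) - config.te_rate

        b0 = optimize.brentq(mean_rate, -30, 30)
        te = (rng_te.random(n) < _sigmoid(b0 + score)).astype(np.int8)

        q = _solve_event_rates(event_prev, config.te_rate)
        idx_te = np.flatnonzero(te)
        ev = (rng_te.random((len(idx_te), len(event_cols))) < q).astype(np.int8)
        empty = np.flatnonzero(ev.sum(axis=1) == 0)
        guard = 0
        while empty.size and guard < 1000:
            ev[empty] = (rng_te.random((empty.size, len(event_cols))) < q).astype(np.int8)
            empty = empty[ev[empty].sum(axis=1) == 0]
            guard += 1
        if empty.size:  # pathological rates; force the most common event
            ev[empty, int(np.argmax(q))] = 1
        for j, c in enumerate(event_cols):
            col = np.zeros(n, dtype=np.int8)
            col[idx_te] = ev[:, j]
            pheno[c] = col
    else:
        for c in event_cols:
            pheno[c] = 0

    # dates: diagnosis uniform 2005-2017; cytoreduction interval for a fraction
    rng_dates = _rng(config.seed, 3)
    base = date(2005, 1, 1)
    diag = [base + timedelta(days=int(d)) for d in rng_dates.integers(0, 4745, n)]
    has_cyto = rng_dates.random(n) < config.cyto_fraction
    cyto_start: list[date | None] = [None] * n
    cyto_end: list[date | None] = [None] * n
    for i in range(n):
        if has_cyto[i]:
            s = diag[i] + timedelta(days=int(rng_dates.integers(30, 366)))
            e = s + timedelta(days=int(rng_dates.integers(365, 2001)))
            cyto_start[i], cyto_end[i] = s, e

    # planted timing stratum per positive patient-event
    rng_strata = _rng(config.seed, 4)
    strata_rows = []
    strata_names = (STRATUM_PRE, STRATUM_DURING, STRATUM_OTHER)
    probs = np.asarray(config.timing_probs)
    for i, pid in enumerate(ids):
        for c in event_cols:
            if pheno.at[pid, c]:
                stratum = strata_names[int(rng_strata.choice(3, p=probs))]
                if stratum == STRATUM_DURING and cyto_start[i] is None:
                    s = diag[i] + timedelta(days=int(rng_strata.integers(30, 366)))
                    cyto_start[i] = s
                    cyto_end[i] = s + timedelta(days=int(rng_strata.integers(365, 2001)))
                strata_rows.append({"patient_id": pid, "concept_id": c,
                                    "stratum": stratum})

    index = pd.Index(ids, name="patient_id")
    return CohortTruth(
        phenotypes=pheno,
        diagnosis_date=pd.Series(diag, index=index, name="diagnosis_date"),
        cyto_start=pd.Series(cyto_start, index=index, name="cyto_start", dtype=object),
        cyto_end=pd.Series(cyto_end, index=index, name="cyto_end", dtype=object),
        event_strata=pd.DataFrame(
            strata_rows, columns=["patient_id", "concept_id", "stratum"]),
        docs_per_patient=config.docs_per_patient,
        cohort_name=config.cohort_name,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# corpus rendering

# (template, temporality) — affirmative, subject=patient, negated=False
_AFFIRMATIVE = (
    ("Ongoing management of {term} at this visit.", "current"),
    ("The patient has {term}.", "current"),
    ("Assessment: {term}, continue current plan.", "current"),
    ("Known {term}, stable on treatment.", "current"),
    ("{term} remains well controlled.", "current"),
    ("History of {term} noted.", "historical"),
)
# concept-specific colloquial forms, (template, temporality, forced surface)
_COLLOQUIAL = {
    SMOKER: (("The patient smokes 20 cigarettes a day.", "current", "smokes"),),
}
_NEGATED = (
    "No evidence of {term} on review.",
    "The patient denies {term}.",
    "Screening negative for {term}.",
)
# (template, temporality) — subject=other, negated=False
_OTHER_SUBJECT = (
    ("Family history of {term}.", "historical"),
    ("Mother had {term}.", "current"),
)
_AMBIGUOUS_NOISE = (
    "{abbrev} unremarkable today.",
    "{abbrev} reviewed in clinic.",
)
_FILLERS = (
    "Seen in haematology clinic today.",
    "Bloods reviewed and remain stable.",
    "Full counts within acceptable range.",
    "Continues on current therapy.",
    "Plan discussed and agreed.",
    "Follow up arranged in three months.",
)


@dataclass
class _PlannedSentence:
    text: str
    term_span: tuple[int, int] | None = None
    concept_id: str | None = None
    negated: bool = False
    subject: str = "patient"
    temporality: str = "current"
    gold: bool = True


def _positive_sentence(entry, rng: np.random.Generator) -> _PlannedSentence:
    colloquials = _COLLOQUIAL.get(entry.concept_id, ())
    n_templates = len(_AFFIRMATIVE) + len(colloquials)
    pick = int(rng.integers(0, n_templates))
    if pick >= len(_AFFIRMATIVE):
        template, temporality, surface = colloquials[pick - len(_AFFIRMATIVE)]
    else:
        template, temporality = _AFFIRMATIVE[pick]
        surface = _pick_surface(entry, rng)
    return _render_template(template, surface, entry.concept_id,
                            negated=False, subject="patient",
                            temporality=temporality)


def _pick_surface(entry, rng: np.random.Generator) -> str:
    # unambiguous surfaces only: canonical name, synonyms, safe abbreviations
    options = list(entry.terms) + [a for a in entry.abbreviations
                                   if a not in entry.ambiguous]
    return options[int(rng.integers(0, len(options)))]


def _render_template(template: str, surface: str, concept_id: str, *,
                     negated: bool, subject: str, temporality: str,
                     gold: bool = True) -> _PlannedSentence:
    prefix, _, _ = template.partition("{term}")
    if "{term}" in template:
        text = template.replace("{term}", surface)
        span = (len(prefix), len(prefix) + len(surface))
    else:  # colloquial template with the surface embedded verbatim
        text = template
        at = text.index(surface)
        span = (at, at + len(surface))
    return _PlannedSentence(text, span, concept_id, negated, subject,
                            temporality, gold)


def render_corpus(
    truth: CohortTruth,
    render: RenderConfig,
    vocab: Vocabulary | None = None,
) -> tuple[list[Document], list[Annotation], pd.DataFrame]:
    """Render clinic letters for a sampled cohort.

    Returns ``(documents, gold_annotations, gold_labels)``.  Gold labels equal
    the truth's phenotype matrix.  Every planted concept mention is recorded
    as a gold annotation with its meta-context; ambiguous-abbreviation noise
    sentences (shorthand used in a different sense) carry no gold annotation.
    """
    if len(truth.phenotypes) == 0:
        raise ValueError("empty cohort truth")
    vocab = vocab or default_vocabulary()
    for c in truth.phenotypes.columns:
        if c not in vocab:
            raise ValueError(f"truth concept {c} missing from vocabulary")

    rng = _rng(render.seed, 101)
    docs: list[Document] = []
    gold: list[Annotation] = []

    ambiguous_concepts = [
        cid for cid, e in vocab.entries.items() if e.ambiguous
    ]

    n_docs_all = truth.docs_per_patient.sample(rng, len(truth.phenotypes))

    for p_i, pid in enumerate(truth.phenotypes.index):
        diag = truth.diagnosis_date[pid]
        c_start = truth.cyto_start[pid]
        c_end = truth.cyto_end[pid]
        strata = {
            row.concept_id: row.stratum
            for row in truth.event_strata[
                truth.event_strata["patient_id"] == pid].itertuples()
        }

        # document dates over the follow-up window, plus forced dates so every
        # planted timing stratum has an eligible document
        window_lo = diag - timedelta(days=365)
        window_hi = diag + timedelta(days=2556)
        span = (window_hi - window_lo).days
        dates = sorted(
            window_lo + timedelta(days=int(d))
            for d in rng.integers(0, span + 1, int(n_docs_all[p_i]))
        )
        need = set(strata.values())
        if STRATUM_PRE in need and not any(d <= diag for d in dates):
            dates.append(diag - timedelta(days=int(rng.integers(30, 301))))
        if STRATUM_DURING in need and not any(
                c_start <= d <= c_end for d in dates):
            dates.append(c_start + timedelta(
                days=int(rng.integers(0, (c_end - c_start).days + 1))))
        if STRATUM_OTHER in need and not any(
                _is_other(d, diag, c_start, c_end) for d in dates):
            dates.append(diag + timedelta(days=int(rng.integers(1, 29))))
        dates.sort()

        per_doc: list[list[_PlannedSentence]] = [
            [_PlannedSentence(_FILLERS[int(rng.integers(0, len(_FILLERS)))],
                              gold=False)]
            for _ in dates
        ]
        doc_concepts: list[set[str]] = [set() for _ in dates]

        def eligible(concept: str) -> list[int]:
            stratum = strata.get(concept)
            if stratum is None:
                return list(range(len(dates)))
            if stratum == STRATUM_PRE:
                return [i for i, d in enumerate(dates) if d <= diag]
            if stratum == STRATUM_DURING:
                return [i for i, d in enumerate(dates)
                        if c_start <= d <= c_end]
            return [i for i, d in enumerate(dates)
                    if _is_other(d, diag, c_start, c_end)]

        for concept in truth.phenotypes.columns:
            entry = vocab.entries[concept]
            if truth.phenotypes.at[pid, concept]:
                pool = eligible(concept)
                m = max(1, int(rng.poisson(render.mean_mentions)))
                for _ in range(m):
                    di = pool[int(rng.integers(0, len(pool)))]
                    per_doc[di].append(_positive_sentence(entry, rng))
                    doc_concepts[di].add(concept)
            else:
                for _ in range(int(rng.poisson(render.negated_rate))):
                    di = int(rng.integers(0, len(dates)))
                    template = _NEGATED[int(rng.integers(0, len(_NEGATED)))]
                    per_doc[di].append(_render_template(
                        template, _pick_surface(entry, rng), concept,
                        negated=True, subject="patient", temporality="current"))
                    doc_concepts[di].add(concept)
                for _ in range(int(rng.poisson(render.other_subject_rate))):
                    di = int(rng.integers(0, len(dates)))
                    template, temporality = _OTHER_SUBJECT[
                        int(rng.integers(0, len(_OTHER_SUBJECT)))]
                    per_doc[di].append(_render_template(
                        template, _pick_surface(entry, rng), concept,
                        negated=False, subject="other", temporality=temporality))
                    doc_concepts[di].add(concept)

        # bare ambiguous shorthand used in an unrelated sense: no gold
        # annotation; only planted in documents free of that concept
        if ambiguous_concepts and render.ambiguous_rate > 0:
            for _ in range(int(rng.poisson(render.ambiguous_rate))):
                cid = ambiguous_concepts[int(rng.integers(0, len(ambiguous_concepts)))]
                if truth.phenotypes.at[pid, cid]:
                    continue
                candidates = [i for i in range(len(dates))
                              if cid not in doc_concepts[i]]
                if not candidates:
                    continue
                di = candidates[int(rng.integers(0, len(candidates)))]
                ab = sorted(vocab.entries[cid].ambiguous)[0]
                template = _AMBIGUOUS_NOISE[
                    int(rng.integers(0, len(_AMBIGUOUS_NOISE)))]
                per_doc[di].append(_PlannedSentence(
                    template.replace("{abbrev}", ab), gold=False))

        for di, (d, sentences) in enumerate(zip(dates, per_doc)):
            order = rng.permutation(len(sentences))
            doc_id = f"{pid}-D{di + 1:03d}"
            parts: list[str] = []
            offset = 0
            for si in order:
                s = sentences[si]
                if s.term_span is not None and s.gold:
                    gold.append(Annotation(
                        doc_id=doc_id,
                        start=offset + s.term_span[0],
                        end=offset + s.term_span[1],
                        surface=s.text[s.term_span[0]:s.term_span[1]],
                        concept_id=s.concept_id,
                        negated=s.negated,
                        subject=s.subject,
                        temporality=s.temporality,
                    ))
                parts.append(s.text)
                offset += len(s.text) + 1  # joined with one space
            docs.append(Document(doc_id=doc_id, patient_id=pid,
                                 date=d.isoformat(), text=" ".join(parts)))

    gold.sort(key=lambda a: (a.doc_id, a.start))
    gold_labels = truth.phenotypes.copy()
    return docs, gold, gold_labels


def _is_other(d: date, diag: date, c_start, c_end) -> bool:
    if d <= diag:
        return False
    if c_start is not None and c_start <= d <= c_end:
        return False
    return True


def simulate_cohort(
    config: CohortConfig,
    render: RenderConfig | None = None,
    vocab: Vocabulary | None = None,
) -> tuple[CohortTruth, list[Document], list[Annotation], pd.DataFrame]:
    """Sample a cohort and render its corpus in one call."""
    truth = sample_cohort(config)
    if render is None:
        render = RenderConfig(seed=config.seed)
    elif render.seed == 0 and config.seed != 0:
        render = replace(render, seed=config.seed)
    docs, gold_ann, gold_labels = render_corpus(truth, render, vocab)
    return truth, docs, gold_ann, gold_labels
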
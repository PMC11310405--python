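"""Dictionary-based named-entity recognition and linking with meta-annotation.

A deterministic rule engine in the style of classic dictionary NER with
NegEx-like context rules: longest-match left-to-right scanning of token
n-grams against a concept vocabulary, followed by per-mention meta-annotation
of negation, subject (patient vs other) and temporality (current vs
historical).

Matching conventions
--------------------
* multi-word terms and synonyms: case-insensitive;
* abbreviations: case-sensitive; an *ambiguous* abbreviation (e.g. "PE")
  is linked only when the same document contains a non-ambiguous mention of
  the same concept, otherwise the match is dropped;
* longer n-grams win over shorter ones, ties broken leftmost, matches never
  overlap.

Context rules operate on token windows cut at sentence boundaries and at
adversative clause breaks ("but").
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Document",
    "Annotation",
    "ContextRuleSet",
    "annotate_document",
    "annotate_corpus",
    "evaluate_ner",
    "NerMetrics",
]

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:'[A-Za-z]+)?")
_SENT_BREAK_RE = re.compile(r"\.\s|\?\s|!\s|\n")


@dataclass(frozen=True)
class Document:
    """One clinical letter: the unit of annotation."""

    doc_id: str
    patient_id: str
    date: str  # ISO-8601
    text: str


@dataclass(frozen=True)
class Annotation:
    """One linked concept mention with its contextual qualifiers.

    ``start``/``end`` are 0-based half-open character offsets into the
    document text; ``surface`` always equals ``text[start:end]``.
    """

    doc_id: str
    start: int
    end: int
    surface: str
    concept_id: str
    negated: bool = False
    subject: str = "patient"      # {"patient", "other"}
    temporality: str = "current"  # {"current", "historical"}

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad span ({self.start}, {self.end})")
        if self.subject not in ("patient", "other"):
            raise ValueError(f"bad subject {self.subject!r}")
        if self.temporality not in ("current", "historical"):
            raise ValueError(f"bad temporality {self.temporality!r}")


@dataclass(frozen=True)
class ContextRuleSet:
    """Trigger lexicons and token windows for the meta-annotation rules."""

    negation_triggers: frozenset[str] = frozenset({
        "no", "not", "without", "denies", "denied", "never", "negative",
        "excluded", "unlikely",
    })
    negation_window: int = 6
    subject_triggers: frozenset[str] = frozenset({
        "family", "mother", "father", "brother", "sister",
    })
    subject_window: int = 5
    historical_triggers: frozenset[str] = frozenset({"previous", "prior"})
    # "history of" handled as a bigram
    historical_window: int = 5
    clause_breakers: frozenset[str] = frozenset({"but"})


DEFAULT_RULES = ContextRuleSet()


def _tokenize(text: str) -> list[tuple[str, int, int]]:
    """Tokens with character offsets; splits on whitespace and punctuation."""
    return [(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def _sentence_ids(text: str, tokens: Sequence[tuple[str, int, int]]) -> list[int]:
    """Sentence index of each token (boundaries: '. ', '? ', '! ', newline)."""
    breaks = [m.start() for m in _SENT_BREAK_RE.finditer(text)]
    sids = []
    sid = 0
    bi = 0
    for _, start, _ in tokens:
        while bi < len(breaks) and breaks[bi] < start:
            sid += 1
            bi += 1
        sids.append(sid)
    return sids


def annotate_document(
    doc: Document,
    vocab,
    rules: ContextRuleSet = DEFAULT_RULES,
) -> list[Annotation]:
    """Annotate one document against the vocabulary.

    Returns linked mentions in reading order.  Unmatched text yields no
    annotations; an empty vocabulary yields an empty list.
    """
    tokens = _tokenize(doc.text)
    if not tokens or not len(vocab):
        return []
    sids = _sentence_ids(doc.text, tokens)
    lowered = [t[0].lower() for t in tokens]

    max_n = min(6, max(vocab.max_term_tokens, 1))
    raw: list[tuple[int, int, str, bool]] = []  # (tok_start, tok_len, concept, ambiguous)
    i = 0
    n_tok = len(tokens)
    while i < n_tok:
        hit = None
        for n in range(min(max_n, n_tok - i), 0, -1):
            gram = tuple(lowered[i:i + n])
            concept = vocab.term_index.get(gram)
            if concept is not None:
                hit = (i, n, concept, False)
                break
            if n == 1:
                ab = vocab.abbrev_index.get(tokens[i][0])
                if ab is not None:
                    hit = (i, 1, ab[0], ab[1])
                    break
        if hit is None:
            i += 1
        else:
            raw.append(hit)
            i += hit[1]

    # within-document corroboration for ambiguous abbreviations
    corroborated = {c for (_, _, c, amb) in raw if not amb}
    kept = [h for h in raw if not h[3] or h[2] in corroborated]

    annotations = []
    for tok_i, n, concept, _ in kept:
        start = tokens[tok_i][1]
        end = tokens[tok_i + n - 1][2]
        annotations.append(Annotation(
            doc_id=doc.doc_id,
            start=start,
            end=end,
            surface=doc.text[start:end],
            concept_id=concept,
            negated=_is_negated(tok_i, n, lowered, sids, rules),
            subject=_subject(tok_i, lowered, sids, rules),
            temporality=_temporality(tok_i, lowered, sids, rules),
        ))
    return annotations


def _window_before(tok_i: int, window: int, lowered: Sequence[str],
                   sids: Sequence[int], rules: ContextRuleSet) -> list[str]:
    """Tokens before position, same sentence, stopping at a clause breaker."""
    out = []
    sid = sids[tok_i]
    j = tok_i - 1
    while j >= 0 and tok_i - j <= window and sids[j] == sid:
        if lowered[j] in rules.clause_breakers:
            break
        out.append(lowered[j])
        j -= 1
    return out  # nearest first


def _window_after(tok_i: int, n: int, window: int, lowered: Sequence[str],
                  sids: Sequence[int], rules: ContextRuleSet) -> list[str]:
    out = []
    last = tok_i + n - 1
    sid = sids[last]
    j = last + 1
    while j < len(lowered) and j - last <= window and sids[j] == sid:
        if lowered[j] in rules.clause_breakers:
            break
        out.append(lowered[j])
        j += 1
    return out


def _is_negated(tok_i: int, n: int, lowered, sids, rules: ContextRuleSet) -> bool:
    before = _window_before(tok_i, rules.negation_window, lowered, sids, rules)
    after = _window_after(tok_i, n, rules.negation_window, lowered, sids, rules)
    trig = rules.negation_triggers
    return any(t in trig for t in before) or any(t in trig for t in after)


def _subject(tok_i: int, lowered, sids, rules: ContextRuleSet) -> str:
    before = _window_before(tok_i, rules.subject_window, lowered, sids, rules)
    if any(t in rules.subject_triggers for t in before):
        return "other"
    return "patient"


def _temporality(tok_i: int, lowered, sids, rules: ContextRuleSet) -> str:
    before = _window_before(tok_i, rules.historical_window, lowered, sids, rules)
    if any(t in rules.historical_triggers for t in before):
        return "historical"
    # "history of" bigram scan (before[] is nearest-first)
    for k in range(len(before) - 1):
        if before[k] == "of" and before[k + 1] == "history":
            return "historical"
    return "current"


def annotate_corpus(
    docs: Iterable[Document],
    vocab,
    rules: ContextRuleSet = DEFAULT_RULES,
) -> list[Annotation]:
    out: list[Annotation] = []
    for doc in docs:
        out.extend(annotate_document(doc, vocab, rules))
    return out


@dataclass
class NerMetrics:
    """Document-level precision/recall/F1 per concept."""

    per_concept: dict[str, dict[str, float]] = field(default_factory=dict)

    def f1(self, concept_id: str) -> float:
        return self.per_concept[concept_id]["f1"]


def evaluate_ner(
    predicted: Sequence[Annotation],
    gold: Sequence[Annotation],
    doc_ids: Iterable[str] | None = None,
) -> NerMetrics:
    """Document-level evaluation of predicted vs gold annotations.

    A prediction is a true positive iff it overlaps a gold span in the same
    document, links the same concept, and carries the same negation flag.
    Matching is greedy in reading order; each gold mention is consumed at
    most once.  F1 is defined as 0 when precision + recall = 0.

    ``doc_ids``, when given, is the known document set; annotations
    referencing other documents raise ``ValueError``.
    """
    if doc_ids is not None:
        known = set(doc_ids)
        for ann in list(predicted) + list(gold):
            if ann.doc_id not in known:
                raise ValueError(f"annotation references unknown doc_id {ann.doc_id!r}")

    concepts = {a.concept_id for a in predicted} | {a.concept_id for a in gold}
    gold_by_key: dict[tuple[str, str, bool], list[Annotation]] = {}
    for g in gold:
        gold_by_key.setdefault((g.doc_id, g.concept_id, g.negated), []).append(g)

    tp: dict[str, int] = {c: 0 for c in concepts}
    fp: dict[str, int] = {c: 0 for c in concepts}
    matched: set[int] = set()
    for p in predicted:
        cands = gold_by_key.get((p.doc_id, p.concept_id, p.negated), [])
        hit = None
        for g in cands:
            if id(g) not in matched and p.start < g.end and g.start < p.end:
                hit = g
                break
        if hit is not None:
            matched.add(id(hit))
            tp[p.concept_id] += 1
        else:
            fp[p.concept_id] += 1

    fn = {c: 0 for c in concepts}
    for g in gold:
        if id(g) not in matched:
            fn[g.concept_id] += 1

    report = NerMetrics()
    for c in sorted(concepts):
        precision = tp[c] / (tp[c] + fp[c]) if tp[c] + fp[c] else 0.0
        recall = tp[c] / (tp[c] + fn[c]) if tp[c] + fn[c] else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
        report.per_concept[c] = {
            "tp": tp[c], "fp": fp[c], "fn": fn[c],
            "precision": precision, "recall": recall, "f1": f1,
        }
    return report
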
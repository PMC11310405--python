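"""Concept vocabulary: SNOMED-CT-style codes with surface forms.

The study tracks five cardiovascular risk factors and seven thrombotic-event
concepts.  Each concept carries a canonical name, synonyms (matched
case-insensitively as token n-grams) and short abbreviations (matched
case-sensitively; an abbreviation may be flagged *ambiguous*, in which case a
bare occurrence links only when the same document also contains a
non-ambiguous mention of the same concept).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "ConceptEntry",
    "Vocabulary",
    "load_vocabulary",
    "write_vocabulary",
    "default_vocabulary",
    "HTN", "HC", "DM", "SMOKER", "OBESITY",
    "PVT", "DVT", "PE", "MI", "CVA", "CST", "NOS",
    "RISK_FACTORS", "EVENT_CONCEPTS", "VENOUS_EVENTS", "VTE_COL", "TE_COL",
    "CONCEPT_LABELS",
]

# SNOMED-CT codes for the twelve study concepts.
HTN = "38341003"       # hypertensive disorder
HC = "13644009"        # hypercholesterolemia
DM = "73211009"        # diabetes mellitus
SMOKER = "77176002"    # smoker
OBESITY = "414916001"  # obesity
PVT = "17920008"       # portal vein thrombosis
DVT = "128053003"      # deep vein thrombosis
PE = "59282003"        # pulmonary embolism
MI = "22298006"        # myocardial infarction
CVA = "230690007"      # cerebrovascular accident
CST = "95455008"       # cerebral sinus thrombosis
NOS = "439127006"      # thrombosis, not otherwise specified

RISK_FACTORS = (HTN, HC, DM, SMOKER, OBESITY)
EVENT_CONCEPTS = (PVT, DVT, PE, MI, CVA, CST, NOS)
#: Members of the derived venous-thromboembolism column.
VENOUS_EVENTS = (DVT, PE, PVT, CST, NOS)
VTE_COL = "VTE"
TE_COL = "TE"

CONCEPT_LABELS = {
    HTN: "HTN", HC: "HC", DM: "DM", SMOKER: "Smoker", OBESITY: "Obesity",
    PVT: "PVT", DVT: "DVT", PE: "PE", MI: "MI", CVA: "CVA", CST: "CST",
    NOS: "Thrombosis NOS",
}

_MAX_ABBREV_LEN = 5


@dataclass(frozen=True)
class ConceptEntry:
    """One vocabulary concept and its recognisable surface forms."""

    concept_id: str
    name: str
    synonyms: tuple[str, ...] = ()
    abbreviations: tuple[str, ...] = ()
    #: subset of ``abbreviations`` that are ambiguous shorthand
    ambiguous: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError(f"concept {self.concept_id}: canonical name is empty")
        for ab in self.abbreviations:
            if len(ab) > _MAX_ABBREV_LEN:
                raise ValueError(
                    f"concept {self.concept_id}: abbreviation {ab!r} longer than "
                    f"{_MAX_ABBREV_LEN} characters"
                )
        unknown = self.ambiguous - set(self.abbreviations)
        if unknown:
            raise ValueError(
                f"concept {self.concept_id}: ambiguous flags for unknown "
                f"abbreviations {sorted(unknown)}"
            )

    @property
    def terms(self) -> tuple[str, ...]:
        """Case-insensitive surface forms (canonical name + synonyms)."""
        return (self.name, *self.synonyms)


class Vocabulary:
    """Indexed concept dictionary used by the annotator.

    Terms (canonical names and synonyms) are indexed as lower-cased token
    tuples; abbreviations are indexed verbatim (case-sensitive).
    """

    def __init__(self, entries: Iterable[ConceptEntry]):
        self.entries: dict[str, ConceptEntry] = {}
        self.term_index: dict[tuple[str, ...], str] = {}
        self.abbrev_index: dict[str, tuple[str, bool]] = {}
        surface_owner: dict[str, str] = {}
        for entry in entries:
            if entry.concept_id in self.entries:
                raise ValueError(f"duplicate concept_id {entry.concept_id!r}")
            self.entries[entry.concept_id] = entry
            for term in entry.terms:
                key = term.lower()
                if key in surface_owner and surface_owner[key] != entry.concept_id:
                    raise ValueError(
                        f"surface form {term!r} shared by concepts "
                        f"{surface_owner[key]} and {entry.concept_id}"
                    )
                surface_owner[key] = entry.concept_id
                self.term_index[tuple(key.split())] = entry.concept_id
            for ab in entry.abbreviations:
                if ab in self.abbrev_index and self.abbrev_index[ab][0] != entry.concept_id:
                    raise ValueError(
                        f"surface form {ab!r} shared by concepts "
                        f"{self.abbrev_index[ab][0]} and {entry.concept_id}"
                    )
                self.abbrev_index[ab] = (entry.concept_id, ab in entry.ambiguous)
        self.max_term_tokens = max(
            (len(k) for k in self.term_index), default=1
        )

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.entries

    @property
    def concept_ids(self) -> list[str]:
        return list(self.entries)

    def label(self, concept_id: str) -> str:
        entry = self.entries.get(concept_id)
        if entry is None:
            return concept_id
        return CONCEPT_LABELS.get(concept_id, entry.name)


def default_vocabulary() -> Vocabulary:
    """The twelve study concepts with clinically common surface forms."""
    return Vocabulary([
        ConceptEntry(HTN, "hypertension",
                     ("hypertensive disorder", "high blood pressure"),
                     ("HTN",)),
        ConceptEntry(HC, "hypercholesterolemia",
                     ("hypercholesterolaemia", "high cholesterol",
                      "raised cholesterol"),
                     ("HC",)),
        ConceptEntry(DM, "diabetes mellitus",
                     ("diabetes", "diabetic"),
                     ("DM",)),
        ConceptEntry(SMOKER, "smoker",
                     ("smoking", "smokes", "tobacco use"),
                     ()),
        ConceptEntry(OBESITY, "obesity", ("obese",), ()),
        ConceptEntry(PVT, "portal vein thrombosis", (), ("PVT",)),
        ConceptEntry(DVT, "deep vein thrombosis",
                     ("deep venous thrombosis",),
                     ("DVT",)),
        # "PE" is notoriously overloaded in clinical shorthand
        # (pulmonary embolism vs physical examination vs pleural effusion).
        ConceptEntry(PE, "pulmonary embolism",
                     ("pulmonary embolus",),
                     ("PE",), frozenset({"PE"})),
        ConceptEntry(MI, "myocardial infarction",
                     ("heart attack",),
                     ("MI",)),
        ConceptEntry(CVA, "cerebrovascular accident",
                     ("stroke", "ischaemic stroke"),
                     ("CVA",)),
        ConceptEntry(CST, "cerebral sinus thrombosis",
                     ("cerebral venous sinus thrombosis",),
                     ("CST",)),
        ConceptEntry(NOS, "thrombosis",
                     ("thrombotic event", "thrombus", "blood clot"),
                     ()),
    ])


def load_vocabulary(path: str | Path) -> Vocabulary:
    """Read a vocabulary CSV.

    Columns: ``concept_id, name, synonyms, abbreviations, ambiguous`` with
    pipe-separated multi-value fields (``ambiguous`` lists the subset of
    abbreviations that are ambiguous shorthand).
    """
    path = Path(path)
    entries = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return Vocabulary([])
        required = {"concept_id", "name"}
        missing = required - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            entries.append(ConceptEntry(
                concept_id=row["concept_id"].strip(),
                name=row["name"].strip(),
                synonyms=_split(row.get("synonyms", "")),
                abbreviations=_split(row.get("abbreviations", "")),
                ambiguous=frozenset(_split(row.get("ambiguous", ""))),
            ))
    return Vocabulary(entries)


def write_vocabulary(vocab: Vocabulary, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["concept_id", "name", "synonyms", "abbreviations", "ambiguous"])
        for entry in vocab.entries.values():
            writer.writerow([
                entry.concept_id,
                entry.name,
                "|".join(entry.synonyms),
                "|".join(entry.abbreviations),
                "|".join(sorted(entry.ambiguous)),
            ])


def _split(raw: str) -> tuple[str, ...]:
    return tuple(s.strip() for s in raw.split("|") if s.strip())
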
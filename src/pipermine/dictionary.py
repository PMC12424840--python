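"""Indication term dictionary and free-text category matching.

Formulas carry free-text therapeutic-use strings ("used for insomnia and
trembling of the limbs").  A small curated dictionary of literal terms and
truncations maps such strings onto four neuropsychiatric indication
categories: Anxiety/Mood, Movement/Seizure, Pain and Sleep.

Matching semantics are deliberately strict and word-based:

* text is tokenised on non-alphanumeric boundaries, case-insensitively;
* a literal term fires only when a whole token equals it ("fits" does not
  fire inside "benefits");
* a suffix truncation ``depress*`` fires when a token starts with its stem;
* a prefix truncation ``*ache`` fires when a token ends with its stem.

A substring mode is available behind a switch for sensitivity analysis.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

CATEGORIES = ("Anxiety/Mood", "Movement/Seizure", "Pain", "Sleep")

_TOKEN_RE = re.compile(r"[0-9a-z]+")


class DictionaryError(ValueError):
    """Malformed term pattern or dictionary source."""


@dataclass(frozen=True)
class TermPattern:
    """One search term: a literal or a single-sided truncation."""

    raw: str
    kind: str  # literal | prefix-wildcard | suffix-wildcard
    stem: str

    @classmethod
    def parse(cls, raw: str) -> "TermPattern":
        raw = raw.strip()
        if raw.count("*") > 1:
            raise DictionaryError(f"pattern {raw!r}: more than one asterisk")
        if raw.startswith("*"):
            kind, stem = "prefix-wildcard", raw[1:]
        elif raw.endswith("*"):
            kind, stem = "suffix-wildcard", raw[:-1]
        elif "*" in raw:
            raise DictionaryError(f"pattern {raw!r}: internal asterisk")
        else:
            kind, stem = "literal", raw
        stem = stem.lower()
        if not stem:
            raise DictionaryError(f"pattern {raw!r}: empty stem")
        return cls(raw=raw, kind=kind, stem=stem)

    def fires(self, token: str) -> bool:
        if self.kind == "literal":
            return token == self.stem
        if self.kind == "suffix-wildcard":
            return token.startswith(self.stem)
        return token.endswith(self.stem)

    def fires_substring(self, text_lower: str) -> bool:
        return self.stem in text_lower


@dataclass
class TermDictionary:
    """Ordered categories with their term patterns."""

    terms: dict[str, list[TermPattern]]

    def __post_init__(self) -> None:
        for cat, patterns in self.terms.items():
            if not patterns:
                raise DictionaryError(f"category {cat!r} has no terms")
            seen = set()
            for p in patterns:
                if (cat, p.raw) in seen:
                    raise DictionaryError(
                        f"duplicate term {p.raw!r} in category {cat!r}"
                    )
                seen.add((cat, p.raw))

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(self.terms)


@dataclass
class CategoryAssignment:
    """Which categories a single indication string matched, and why."""

    indication_text: str
    matched_categories: set[str] = field(default_factory=set)
    matched_terms: dict[str, set[str]] = field(default_factory=dict)


def compile_dictionary(source: str | Path | None = None) -> TermDictionary:
    """Compile a term dictionary from a two-column CSV (category, terms).

    The ``terms`` cell is a comma-separated list; an asterisk at the start or
    end of a term marks a truncation.  With no ``source`` the packaged default
    four-category dictionary is returned.
    """
    if source is None:
        ref = resources.files("pipermine.data") / "indication_terms.csv"
        with resources.as_file(ref) as path:
            return compile_dictionary(path)
    terms: dict[str, list[TermPattern]] = {}
    with Path(source).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            cat = row["category"].strip()
            patterns = [
                TermPattern.parse(t)
                for t in row["terms"].split(",")
                if t.strip()
            ]
            terms.setdefault(cat, []).extend(patterns)
    return TermDictionary(terms=terms)


def tokenize(text: str) -> list[str]:
    """Lowercased word tokens, split on non-alphanumeric boundaries."""
    return _TOKEN_RE.findall(text.lower())


def match_indication(
    text: str, dictionary: TermDictionary, substring: bool = False
) -> CategoryAssignment:
    """Assign one free-text indication string to categories.

    Returns every category with at least one firing term; ``matched_terms``
    records, per category, the raw terms that fired.
    """
    assignment = CategoryAssignment(indication_text=text)
    tokens = tokenize(text)
    lower = text.lower()
    for cat, patterns in dictionary.terms.items():
        fired = {
            p.raw
            for p in patterns
            if (p.fires_substring(lower) if substring
                else any(p.fires(t) for t in tokens))
        }
        if fired:
            assignment.matched_categories.add(cat)
            assignment.matched_terms[cat] = fired
    return assignment


def categorize_formula(
    indications: Iterable[str],
    dictionary: TermDictionary,
    substring: bool = False,
) -> set[str]:
    """Union of category matches over a formula's indication strings."""
    out: set[str] = set()
    for text in indications:
        out |= match_indication(text, dictionary, substring).matched_categories
    return out


def categorize_dataset(
    dataset, dictionary: TermDictionary, substring: bool = False
) -> dict[str, set[str]]:
    """Category set per formula_id for a whole ingested dataset."""
    return {
        fid: categorize_formula(f.indications, dictionary, substring)
        for fid, f in dataset.formulas.items()
    }


def assignments_table(
    dataset, dictionary: TermDictionary
) -> "pd.DataFrame":
    """Long-format (formula_id, category, matched_term) table."""
    import pandas as pd

    rows = []
    for fid in sorted(dataset.formulas):
        for text in dataset.formulas[fid].indications:
            a = match_indication(text, dictionary)
            for cat in sorted(a.matched_categories):
                for term in sorted(a.matched_terms[cat]):
                    rows.append((fid, cat, term))
    return pd.DataFrame(
        sorted(set(rows)), columns=["formula_id", "category", "matched_term"]
    )
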
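"""Severity categorisation of carcinogenicity endpoints.

Tumour dose-response data cover endpoints of very different seriousness: a
dose producing a 10% increase in hyperplasia is not equipotent to one
producing a 10% increase in malignant carcinomas.  Endpoints are therefore
placed into five ordinal severity categories before any dose-response
modelling:

    1  preneoplastic lesion
    2  benign tumor(s)
    3  malignant tumor(s) in a single organ
    4  malignant (metastasizing) tumors in different organs
    5  tumor-bearing animals

Only categories 2-5 enter relative-potency estimation; category 1 data are
readable but excluded.  Assignment goes through a lesion-term lookup table.
A default table covering common rodent lesion nomenclature ships with the
package; users can supply their own CSV to override it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = [
    "SeverityCategory",
    "SeverityLookup",
    "UnclassifiedLesionError",
    "assign_severity",
    "default_lookup",
    "read_severity_lookup",
    "SEVERITY_LABELS",
]

SEVERITY_LABELS = {
    1: "preneoplastic lesion",
    2: "benign tumor(s)",
    3: "malignant tumor(s) in a single organ",
    4: "malignant (metastasizing) tumors in different organs",
    5: "tumor-bearing animals",
}

#: categories eligible for relative-potency analysis
RPF_ELIGIBLE_CODES = frozenset({2, 3, 4, 5})


@dataclass(frozen=True, order=True)
class SeverityCategory:
    """One of the five ordinal endpoint-severity categories."""

    code: int

    def __post_init__(self) -> None:
        if self.code not in SEVERITY_LABELS:
            raise ValueError(f"severity code must be in 1..5, got {self.code!r}")

    @property
    def label(self) -> str:
        return SEVERITY_LABELS[self.code]

    @property
    def rpf_eligible(self) -> bool:
        return self.code in RPF_ELIGIBLE_CODES

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"SeverityCategory({self.code}: {self.label})"


class UnclassifiedLesionError(KeyError):
    """Raised when a lesion term cannot be mapped to a severity category."""

    def __init__(self, term: str):
        super().__init__(term)
        self.term = term

    def __str__(self) -> str:
        return f"unclassified lesion term: {self.term!r}"


def _normalize(term: str) -> str:
    return " ".join(term.strip().lower().split())


class SeverityLookup:
    """Lesion-term -> severity-category table.

    Matching is case- and whitespace-insensitive.  An exact match on the
    normalised term is tried first; failing that, table terms are matched as
    whole-word substrings of the query (so "hepatocellular adenoma" resolves
    through the entry for "adenoma") and the longest matching table term
    wins.  Unknown terms raise :class:`UnclassifiedLesionError` — never a
    silent default.
    """

    def __init__(self, entries: dict[str, SeverityCategory]):
        if not entries:
            raise ValueError("severity lookup requires at least one entry")
        self._entries = {_normalize(k): v for k, v in entries.items()}

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, term: str) -> bool:
        try:
            self[term]
        except UnclassifiedLesionError:
            return False
        return True

    def __getitem__(self, term: str) -> SeverityCategory:
        key = _normalize(term)
        if not key:
            raise UnclassifiedLesionError(term)
        hit = self._entries.get(key)
        if hit is not None:
            return hit
        # whole-word substring fallback, longest table term wins
        words = key.split()
        best: tuple[int, str] | None = None
        for entry in self._entries:
            entry_words = entry.split()
            m = len(entry_words)
            if m > len(words):
                continue
            if any(words[i : i + m] == entry_words for i in range(len(words) - m + 1)):
                if best is None or len(entry) > best[0]:
                    best = (len(entry), entry)
        if best is None:
            raise UnclassifiedLesionError(term)
        return self._entries[best[1]]

    def items(self):
        return self._entries.items()


def assign_severity(lesion_term: str, lookup: SeverityLookup | None = None) -> SeverityCategory:
    """Map a lesion term to its severity category.

    Parameters
    ----------
    lesion_term:
        Pathology endpoint name, e.g. ``"hepatocellular adenoma"``.
    lookup:
        Table to resolve against; defaults to the packaged table.

    Raises
    ------
    UnclassifiedLesionError
        If the term (or any whole-word component of it) is not in the table.
    """
    if not lesion_term or not lesion_term.strip():
        raise UnclassifiedLesionError(lesion_term)
    if lookup is None:
        lookup = default_lookup()
    return lookup[lesion_term]


def read_severity_lookup(path: str | Path) -> SeverityLookup:
    """Read a lesion-term lookup from CSV with columns ``lesion_term,severity``."""
    entries: dict[str, SeverityCategory] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"lesion_term", "severity"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"severity lookup CSV needs columns {sorted(required)}")
        for i, row in enumerate(reader, start=2):
            term = row["lesion_term"]
            try:
                code = int(row["severity"])
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}, line {i}: bad severity {row['severity']!r}") from exc
            entries[term] = SeverityCategory(code)
    return SeverityLookup(entries)


_DEFAULT: SeverityLookup | None = None


def default_lookup() -> SeverityLookup:
    """The packaged default lesion-term table (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        with resources.as_file(
            resources.files("cce.data").joinpath("severity_lookup_default.csv")
        ) as p:
            _DEFAULT = read_severity_lookup(p)
    return _DEFAULT
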
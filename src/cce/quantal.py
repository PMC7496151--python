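"""Quantal (incidence) dose-response datasets and their delimited-text I/O.

An individual dataset is one incidence table in which every covariate is at a
single level: same compound, tissue, sex, tumour type, exposure duration and
study duration.  Rows of the input CSV are dose groups; they are grouped into
datasets on those keys plus the lesion term.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .severity import SeverityCategory, SeverityLookup, default_lookup

__all__ = [
    "QuantalDataset",
    "QuantalParseError",
    "read_quantal_datasets",
    "write_quantal_datasets",
    "filter_eligible",
    "dataset_inventory",
]

_CSV_COLUMNS = [
    "compound",
    "lesion_term",
    "tissue",
    "sex",
    "tumor_type",
    "exposure_weeks",
    "study_weeks",
    "dose",
    "n_at_risk",
    "n_affected",
]


class QuantalParseError(ValueError):
    """Malformed quantal CSV content, with the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        prefix = f"line {line}: " if line is not None else ""
        super().__init__(prefix + message)


@dataclass(frozen=True)
class QuantalDataset:
    """One compound x tissue x sex x tumour-type x duration incidence table.

    Doses must be strictly increasing (first may be a zero-dose control) and
    in one consistent inhalation unit per analysis; incidences are animals
    affected out of animals at risk per dose group.
    """

    compound_id: str
    lesion_term: str
    severity: SeverityCategory
    tissue: str
    sex: str
    tumor_type: str
    exposure_weeks: float
    study_weeks: float
    doses: tuple[float, ...]
    n_at_risk: tuple[int, ...]
    n_affected: tuple[int, ...]
    dose_unit: str = field(default="mg/m3")

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", tuple(float(d) for d in self.doses))
        object.__setattr__(self, "n_at_risk", tuple(int(n) for n in self.n_at_risk))
        object.__setattr__(self, "n_affected", tuple(int(x) for x in self.n_affected))
        k = len(self.doses)
        if not (k == len(self.n_at_risk) == len(self.n_affected)):
            raise ValueError(f"{self.key()}: dose/n/incidence lists differ in length")
        if k == 0:
            raise ValueError(f"{self.key()}: empty dataset")
        if any(d < 0 for d in self.doses):
            raise ValueError(f"{self.key()}: negative dose")
        if any(b <= a for a, b in zip(self.doses, self.doses[1:])):
            raise ValueError(f"{self.key()}: doses must be strictly increasing")
        if any(n <= 0 for n in self.n_at_risk):
            raise ValueError(f"{self.key()}: group sizes must be positive")
        if any(x < 0 or x > n for x, n in zip(self.n_affected, self.n_at_risk)):
            raise ValueError(f"{self.key()}: n_affected outside [0, n_at_risk]")

    def key(self) -> tuple:
        """Grouping key identifying this dataset within a study collection."""
        return (
            self.compound_id,
            self.tissue,
            self.sex,
            self.tumor_type,
            self.exposure_weeks,
            self.study_weeks,
            self.lesion_term,
        )

    @property
    def n_groups(self) -> int:
        return len(self.doses)

    @property
    def fittable(self) -> bool:
        """At least three dose groups, the minimum for the 3-parameter model."""
        return self.n_groups >= 3

    def with_doses_scaled(self, factor: float) -> "QuantalDataset":
        return replace(self, doses=tuple(d * factor for d in self.doses))


def read_quantal_datasets(
    path: str | Path,
    lookup: SeverityLookup | None = None,
) -> list[QuantalDataset]:
    """Read dose-group rows from CSV and group them into datasets.

    Severity is assigned from the lesion term via `lookup` (packaged default
    table if omitted).  Validation errors carry the 1-based CSV line number.
    """
    if lookup is None:
        lookup = default_lookup()
    groups: dict[tuple, list[tuple[int, dict]]] = {}
    order: list[tuple] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        missing = set(_CSV_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise QuantalParseError(f"missing columns: {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                parsed = {
                    "compound": row["compound"].strip(),
                    "lesion_term": row["lesion_term"].strip(),
                    "tissue": row["tissue"].strip(),
                    "sex": row["sex"].strip(),
                    "tumor_type": row["tumor_type"].strip(),
                    "exposure_weeks": float(row["exposure_weeks"]),
                    "study_weeks": float(row["study_weeks"]),
                    "dose": float(row["dose"]),
                    "n_at_risk": int(row["n_at_risk"]),
                    "n_affected": int(row["n_affected"]),
                }
            except (TypeError, ValueError, AttributeError) as exc:
                raise QuantalParseError(f"malformed row: {exc}", lineno) from exc
            if parsed["n_at_risk"] <= 0:
                raise QuantalParseError("n_at_risk must be positive", lineno)
            if not 0 <= parsed["n_affected"] <= parsed["n_at_risk"]:
                raise QuantalParseError(
                    f"n_affected={parsed['n_affected']} exceeds "
                    f"n_at_risk={parsed['n_at_risk']}",
                    lineno,
                )
            key = (
                parsed["compound"],
                parsed["tissue"],
                parsed["sex"],
                parsed["tumor_type"],
                parsed["exposure_weeks"],
                parsed["study_weeks"],
                parsed["lesion_term"],
            )
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append((lineno, parsed))

    datasets: list[QuantalDataset] = []
    for key in order:
        rows = sorted(groups[key], key=lambda t: t[1]["dose"])
        doses = [r["dose"] for _, r in rows]
        for (lineno, r), prev in zip(rows[1:], doses):
            if r["dose"] == prev:
                raise QuantalParseError(
                    f"duplicate dose {r['dose']} within dataset {key}", lineno
                )
        first = rows[0][1]
        datasets.append(
            QuantalDataset(
                compound_id=first["compound"],
                lesion_term=first["lesion_term"],
                severity=lookup[first["lesion_term"]],
                tissue=first["tissue"],
                sex=first["sex"],
                tumor_type=first["tumor_type"],
                exposure_weeks=first["exposure_weeks"],
                study_weeks=first["study_weeks"],
                doses=doses,
                n_at_risk=[r["n_at_risk"] for _, r in rows],
                n_affected=[r["n_affected"] for _, r in rows],
            )
        )
    return datasets


def write_quantal_datasets(datasets: Iterable[QuantalDataset], path: str | Path) -> None:
    """Write datasets back to the row-per-dose-group CSV dialect."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for ds in datasets:
            for d, n, x in zip(ds.doses, ds.n_at_risk, ds.n_affected):
                writer.writerow(
                    [
                        ds.compound_id,
                        ds.lesion_term,
                        ds.tissue,
                        ds.sex,
                        ds.tumor_type,
                        _fmt_num(ds.exposure_weeks),
                        _fmt_num(ds.study_weeks),
                        _fmt_num(d),
                        n,
                        x,
                    ]
                )


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def filter_eligible(
    datasets: Sequence[QuantalDataset], min_exposure_weeks: float = 96.0
) -> list[QuantalDataset]:
    """Keep datasets usable for relative-potency analysis.

    A dataset qualifies when its exposure duration is *strictly longer* than
    `min_exposure_weeks` and its endpoint severity is in categories 2-5
    (preneoplastic-lesion data are excluded).  Contents are never modified.
    """
    if min_exposure_weeks <= 0:
        raise ValueError("min_exposure_weeks must be positive")
    return [
        ds
        for ds in datasets
        if ds.exposure_weeks > min_exposure_weeks and ds.severity.rpf_eligible
    ]


def dataset_inventory(datasets: Sequence[QuantalDataset]) -> dict:
    """JSON-serialisable count of datasets per compound x severity category."""
    inv: dict[str, dict[str, int]] = {}
    for ds in datasets:
        inv.setdefault(ds.compound_id, {})
        code = str(ds.severity.code)
        inv[ds.compound_id][code] = inv[ds.compound_id].get(code, 0) + 1
    return {c: dict(sorted(v.items())) for c, v in sorted(inv.items())}
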
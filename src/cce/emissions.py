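"""Per-stick emission quantities and their geometric-mean confidence bounds.

Machine-smoking replicates of a compound's emission vary multiplicatively,
so the mean is summarised on the log scale: a t-based confidence interval
for the mean log emission, exponentiated, gives two-sided bounds for the
geometric mean in µg per stick (or per cigarette).  Pre-computed bound
tables can be ingested directly, which is how the packaged case-study
comparison ships.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

__all__ = [
    "BoundedQuantity",
    "EmissionReplicates",
    "geometric_mean_ci",
    "read_emission_bounds",
    "write_emission_bounds",
    "apply_consumption_factor",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BoundedQuantity:
    """A positive quantity given by its two-sided 90% confidence bounds."""

    lb: float
    ub: float
    confidence: float = 0.90

    def __post_init__(self) -> None:
        if not (0 < self.lb <= self.ub):
            raise ValueError(f"require 0 < lb <= ub, got ({self.lb}, {self.ub})")
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must lie in (0, 1)")

    @property
    def geometric_mid(self) -> float:
        return math.sqrt(self.lb * self.ub)

    def scaled(self, factor: float) -> "BoundedQuantity":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return BoundedQuantity(self.lb * factor, self.ub * factor, self.confidence)


@dataclass(frozen=True)
class EmissionReplicates:
    """Replicate per-stick emission measurements for one compound x product."""

    compound_id: str
    product_id: str
    values: tuple[float, ...]
    regime: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if any(v <= 0 for v in self.values):
            raise ValueError(
                f"{self.compound_id}/{self.product_id}: emission replicates must be positive"
            )


def geometric_mean_ci(
    replicates: EmissionReplicates, confidence: float = 0.90
) -> BoundedQuantity:
    """t-based confidence interval for the geometric mean emission.

    With m and s the mean and SD of the natural-log replicates, the interval
    is exp(m ± t_{1-α/2, n-1} · s/√n).  Needs at least two replicates; all
    values must be positive.
    """
    vals = replicates.values
    if len(vals) < 2:
        raise ValueError("need >= 2 replicates for a confidence interval")
    logs = np.log(vals)
    m = float(np.mean(logs))
    s = float(np.std(logs, ddof=1))
    n = len(vals)
    t = float(stats.t.ppf(0.5 + confidence / 2, df=n - 1))
    half = t * s / math.sqrt(n)
    return BoundedQuantity(math.exp(m - half), math.exp(m + half), confidence)


def apply_consumption_factor(bounds: BoundedQuantity, factor: float) -> BoundedQuantity:
    """Scale emission bounds by a sticks-consumed ratio.

    When users of one product consume a different number of sticks than the
    comparison baseline, the per-stick emission bounds are multiplied by
    that consumption ratio before entering the cumulative-exposure ratio.
    """
    if factor <= 0:
        raise ValueError(f"consumption factor must be positive, got {factor}")
    return bounds.scaled(factor)


def read_emission_bounds(path: str | Path) -> dict[tuple[str, str], BoundedQuantity]:
    """Read a (compound, product) -> 90% bounds table from CSV.

    Expected columns: ``compound, product, lb, ub``.  Invalid bounds
    (non-positive, or lb > ub) raise with the offending line number.
    """
    out: dict[tuple[str, str], BoundedQuantity] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"compound", "product", "lb", "ub"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"emission bounds CSV needs columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                lb, ub = float(row["lb"]), float(row["ub"])
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}, line {lineno}: bad bounds") from exc
            key = (row["compound"].strip(), row["product"].strip())
            if key in out:
                raise ValueError(f"{path}, line {lineno}: duplicate entry {key}")
            try:
                out[key] = BoundedQuantity(lb, ub)
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
    return out


def write_emission_bounds(
    bounds: Mapping[tuple[str, str], BoundedQuantity], path: str | Path
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["compound", "product", "lb", "ub"])
        for (compound, product), bq in sorted(bounds.items()):
            writer.writerow([compound, product, repr(bq.lb), repr(bq.ub)])


def read_emission_replicates(path: str | Path) -> list[EmissionReplicates]:
    """Read replicate measurements from CSV: compound, product, value[, regime]."""
    rows: dict[tuple[str, str, str], list[float]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"compound", "product", "value"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"emission replicates CSV needs columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                v = float(row["value"])
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}, line {lineno}: bad value") from exc
            key = (row["compound"].strip(), row["product"].strip(), (row.get("regime") or "").strip())
            rows.setdefault(key, []).append(v)
    return [
        EmissionReplicates(compound_id=c, product_id=p, values=vals, regime=r)
        for (c, p, r), vals in sorted(rows.items())
    ]


def substitute_below_lod(
    values: Iterable[float], lod: float, factor: float = 1 / math.sqrt(2)
) -> tuple[float, ...]:
    """Replace non-detects (values below the detection limit) by lod * factor.

    Measurements reported below the detection limit cannot enter the
    log-scale mean as zeros; the conventional substitution LOD/√2 is used by
    default and every substitution is logged prominently.
    """
    if lod <= 0 or factor <= 0:
        raise ValueError("lod and substitution factor must be positive")
    out = []
    n_sub = 0
    for v in values:
        if v < lod:
            out.append(lod * factor)
            n_sub += 1
        else:
            out.append(float(v))
    if n_sub:
        logger.warning(
            "substituted %d value(s) below detection limit %g by %g",
            n_sub, lod, lod * factor,
        )
    return tuple(out)


def bounds_from_replicates(
    replicates: Iterable[EmissionReplicates], confidence: float = 0.90
) -> dict[tuple[str, str], BoundedQuantity]:
    """Geometric-mean bounds for a batch of replicate sets.

    Warns when the two products were measured under different smoking
    regimes: the cumulative-exposure ratio is only meaningful when both
    products are measured in the same, relevant way.
    """
    reps = list(replicates)
    regimes = {r.regime for r in reps if r.regime}
    if len(regimes) > 1:
        logger.warning(
            "emission replicates mix smoking regimes %s; product comparison "
            "assumes both products were measured the same way",
            sorted(regimes),
        )
    return {
        (r.compound_id, r.product_id): geometric_mean_ci(r, confidence) for r in reps
    }
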
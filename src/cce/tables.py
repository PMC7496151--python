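"""Packaged case-study comparison tables (heated tobacco vs. cigarette).

Two fixtures ship with the package:

* combined 90% RPF confidence bounds, relative to 1,3-butadiene, for 17
  compounds with long-term inhalation carcinogenicity data (the reference
  compound's own row carries its BMD bounds in mg/m3 rather than an RPF);
* geometric-mean emission bounds (µg per stick / per cigarette) for the
  eight compounds measured in both products under one smoking regime.

They are the default inputs for a bounds-mode analysis and the basis of the
worked example in the README.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path

from .emissions import BoundedQuantity, read_emission_bounds

__all__ = [
    "REFERENCE_COMPOUND",
    "load_case_rpf_bounds",
    "load_case_emission_bounds",
    "load_reference_bmd_bounds",
    "case_data_path",
]

REFERENCE_COMPOUND = "1,3-Butadiene"


def case_data_path(name: str) -> Path:
    """Filesystem path of a packaged data file (for CLI defaults)."""
    with resources.as_file(resources.files("cce.data").joinpath(name)) as p:
        return Path(p)


def _read_rpf_rows(path: str | Path) -> list[dict]:
    with open(path, newline="", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))


def load_case_rpf_bounds(path: str | Path | None = None) -> dict[str, BoundedQuantity]:
    """Combined RPF bounds per compound, reference mapped to the point RPF 1.

    The reference compound is its own reference, so its RPF is exactly 1
    with no uncertainty; its printed interval is a BMD, not an RPF, and is
    available via :func:`load_reference_bmd_bounds`.
    """
    if path is None:
        path = case_data_path("case_rpf_bounds.csv")
    out: dict[str, BoundedQuantity] = {}
    for row in _read_rpf_rows(path):
        compound = row["compound"].strip()
        if row.get("kind", "rpf").strip() == "bmd":
            out[compound] = BoundedQuantity(1.0, 1.0)
        else:
            out[compound] = BoundedQuantity(float(row["lb"]), float(row["ub"]))
    return out


def load_reference_bmd_bounds(path: str | Path | None = None) -> BoundedQuantity:
    """90% bounds of the reference compound's BMD (mg/m3)."""
    if path is None:
        path = case_data_path("case_rpf_bounds.csv")
    for row in _read_rpf_rows(path):
        if row.get("kind", "").strip() == "bmd":
            return BoundedQuantity(float(row["lb"]), float(row["ub"]))
    raise ValueError(f"no BMD row in {path}")


def load_case_emission_bounds(
    path: str | Path | None = None,
) -> dict[tuple[str, str], BoundedQuantity]:
    """Emission bounds keyed by (compound, product), products htp/cigarette."""
    if path is None:
        path = case_data_path("case_emission_bounds.csv")
    return read_emission_bounds(path)


def case_study_inputs(
    rpf_path: str | Path | None = None,
    emission_path: str | Path | None = None,
) -> tuple[dict[str, BoundedQuantity], dict[str, BoundedQuantity], dict[str, BoundedQuantity]]:
    """(e_cig, e_htp, rpf) mappings restricted to the shared compound set."""
    rpf = load_case_rpf_bounds(rpf_path)
    em = load_case_emission_bounds(emission_path)
    shared = sorted(
        {c for c, p in em if p == "cigarette"}
        & {c for c, p in em if p == "htp"}
        & set(rpf)
    )
    e_cig = {c: em[(c, "cigarette")] for c in shared}
    e_htp = {c: em[(c, "htp")] for c in shared}
    return e_cig, e_htp, {c: rpf[c] for c in shared}
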
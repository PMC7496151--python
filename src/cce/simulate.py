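"""Synthetic study generator: parallel quantal dose-response data with known
relative potencies, and lognormal emission replicates.

The generator emulates the data structures the pipeline consumes, with the
ground truth (RPFs, steepness, backgrounds, geometric-mean emissions) known
exactly, so that every stage — severity filtering, BMD fitting, covariate
RPF estimation, emission intervals, and the Monte-Carlo exposure ratio —
can be tested for parameter recovery end to end.

Tumour incidence for compound *i* at dose d is binomial with

    p(d) = c + (1 - c) * (1 - exp(-(RPF_i * d / beta_ref)^g)),

i.e. all compounds share one log-dose curve shape shifted horizontally by
log RPF_i, exactly the parallelism assumption of the covariate fit.
Emission replicates are lognormal around a configured geometric mean with a
configured geometric SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np

from .emissions import EmissionReplicates
from .quantal import QuantalDataset
from .severity import SeverityCategory

__all__ = [
    "SimulationConfig",
    "simulate_quantal",
    "simulate_emissions",
    "end_to_end_truth",
    "response_probability",
    "default_scenario",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and design of one synthetic two-product study.

    ``true_rpfs`` maps compound -> relative potency against ``reference_id``
    (the reference itself must have RPF 1).  ``beta_ref`` is the reference
    compound's dose-scale (location) parameter; compound *i*'s location is
    beta_ref / RPF_i.  ``emission_gm`` maps (compound, product) to the true
    geometric-mean emission in µg/stick.
    """

    true_rpfs: dict[str, float]
    reference_id: str
    steepness: float = 1.2
    background: float = 0.05
    beta_ref: float = 100.0
    dose_grids: dict[str, tuple[float, ...]] | None = None
    group_size: int = 50
    seed: int = 0
    emission_gm: dict[tuple[str, str], float] = field(default_factory=dict)
    emission_gsd: float = 1.3
    n_replicates: int = 5
    lesion_term: str = "adenocarcinoma"

    def __post_init__(self) -> None:
        if self.reference_id not in self.true_rpfs:
            raise ValueError("reference compound missing from true_rpfs")
        if self.true_rpfs[self.reference_id] != 1.0:
            raise ValueError("the reference compound's true RPF must be 1")
        if any(r <= 0 for r in self.true_rpfs.values()):
            raise ValueError("true RPFs must be positive")
        if self.steepness <= 0 or self.beta_ref <= 0:
            raise ValueError("steepness and beta_ref must be positive")
        if not 0 <= self.background < 1:
            raise ValueError("background must lie in [0, 1)")
        if self.emission_gsd < 1:
            raise ValueError("geometric SD must be >= 1")

    def beta(self, compound: str) -> float:
        return self.beta_ref / self.true_rpfs[compound]

    def grid(self, compound: str) -> tuple[float, ...]:
        """Dose grid for a compound; defaults to {0, b/2, b, 2b} around its
        own location b, mimicking a study designed near the active range."""
        if self.dose_grids and compound in self.dose_grids:
            return tuple(self.dose_grids[compound])
        b = self.beta(compound)
        return (0.0, b / 2, b, 2 * b)


def response_probability(config: SimulationConfig, compound: str, dose: float) -> float:
    """True incidence probability p(d) for one compound of the scenario."""
    if dose < 0:
        raise ValueError("dose must be non-negative")
    c, g = config.background, config.steepness
    scaled = config.true_rpfs[compound] * dose / config.beta_ref
    return c + (1 - c) * (-math.expm1(-(scaled**g))) if dose > 0 else c


def simulate_quantal(config: SimulationConfig) -> list[QuantalDataset]:
    """Draw one binomial incidence dataset per compound (sorted order)."""
    rng = np.random.default_rng(config.seed)
    out: list[QuantalDataset] = []
    for compound in sorted(config.true_rpfs):
        doses = config.grid(compound)
        probs = [response_probability(config, compound, d) for d in doses]
        affected = rng.binomial(config.group_size, probs)
        out.append(
            QuantalDataset(
                compound_id=compound,
                lesion_term=config.lesion_term,
                severity=SeverityCategory(3),
                tissue="lung",
                sex="m",
                tumor_type=config.lesion_term,
                exposure_weeks=104,
                study_weeks=104,
                doses=doses,
                n_at_risk=[config.group_size] * len(doses),
                n_affected=[int(x) for x in affected],
            )
        )
    return out


def simulate_emissions(config: SimulationConfig) -> list[EmissionReplicates]:
    """Draw lognormal emission replicates per configured (compound, product)."""
    rng = np.random.default_rng(config.seed + 1)
    sigma = math.log(config.emission_gsd)
    out: list[EmissionReplicates] = []
    for (compound, product), gm in sorted(config.emission_gm.items()):
        draws = np.exp(math.log(gm) + sigma * rng.standard_normal(config.n_replicates))
        out.append(
            EmissionReplicates(
                compound_id=compound,
                product_id=product,
                values=tuple(float(v) for v in draws),
                regime="synthetic",
            )
        )
    return out


def end_to_end_truth(
    config: SimulationConfig,
    baseline_product: str = "cigarette",
    alternative_product: str = "htp",
) -> float:
    """True exposure-change ratio implied by the configured scenario.

    Applies the potency-weighted emission ratio to the configured geometric
    means and true RPFs; used as the recovery target for full-pipeline
    tests.
    """
    compounds = sorted(
        {c for (c, p) in config.emission_gm if p == baseline_product}
        & {c for (c, p) in config.emission_gm if p == alternative_product}
    )
    if not compounds:
        raise ValueError("no compound has emissions for both products")
    num = sum(
        config.emission_gm[(c, baseline_product)] * config.true_rpfs[c] for c in compounds
    )
    den = sum(
        config.emission_gm[(c, alternative_product)] * config.true_rpfs[c]
        for c in compounds
    )
    return num / den


def default_scenario(seed: int = 0) -> SimulationConfig:
    """Default synthetic scenario shaped like the case study.

    Eight compounds with relative potencies spanning four orders of
    magnitude around one reference, the alternative product emitting
    substantially less of most compounds than the baseline.
    """
    rpfs = {
        "ref": 1.0,
        "c-weak1": 0.02,
        "c-weak2": 0.5,
        "c-mid1": 2.0,
        "c-mid2": 8.0,
        "c-strong1": 40.0,
        "c-strong2": 90.0,
        "c-extreme": 200.0,
    }
    gm: dict[tuple[str, str], float] = {}
    cig = {
        "ref": 80.0,
        "c-weak1": 1500.0,
        "c-weak2": 30.0,
        "c-mid1": 60.0,
        "c-mid2": 2.0,
        "c-strong1": 0.5,
        "c-strong2": 0.02,
        "c-extreme": 0.004,
    }
    for c, v in cig.items():
        gm[(c, "cigarette")] = v
        gm[(c, "htp")] = v / 12.0  # roughly an order of magnitude cleaner
    return SimulationConfig(
        true_rpfs=rpfs,
        reference_id="ref",
        emission_gm=gm,
        seed=seed,
    )
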
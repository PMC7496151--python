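"""Probabilistic change-in-cumulative-exposure (CCE) computation.

Two aerosol products are compared by the ratio of their potency-weighted
emission sums,

    CCE = sum_i E_cig_i * RPF_i / sum_i E_alt_i * RPF_i,

where E is the per-stick emission of compound *i* and RPF its relative
potency against a common reference compound.  A CCE above 1 means the
alternative product delivers a lower cumulative carcinogen exposure; the
value does not depend on which compound is the reference, since a common
rescaling of all RPFs cancels in the ratio.

Uncertainty is propagated by Monte Carlo: every emission and every RPF is
represented by a lognormal distribution calibrated so that its 5th/95th
percentiles equal the quantity's two-sided 90% confidence bounds.  Within a
draw each compound's RPF value is shared between numerator and denominator
(it is the same compound in both products); across quantities draws are
independent.  The 5th and 95th percentiles of the resulting CCE sample form
its 90% uncertainty interval.

The health translation (Step 6) converts a CCE into the number of
effect-size halvings it implies, using the typical steepness of continuous
dose-response curves: the dose ratio BMD10/BMD05 that halves a 10% effect is
close to or less than 2 (2 to 2.6 for rat time-to-tumour data).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .emissions import BoundedQuantity

__all__ = [
    "LognormalSpec",
    "CceResult",
    "HealthTranslation",
    "lognormal_from_bounds",
    "sample_cce",
    "reference_rescale",
    "health_translation",
]

#: standard-normal 95th percentile used to calibrate 90% bounds
Z_90 = float(stats.norm.ppf(0.95))


@dataclass(frozen=True)
class LognormalSpec:
    """Lognormal distribution by the mean (mu) and SD (sigma) of the log."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def lognormal_from_bounds(bounds: BoundedQuantity, z: float | None = None) -> LognormalSpec:
    """Calibrate a lognormal to two-sided 90% confidence bounds.

    mu = (ln lb + ln ub)/2 and sigma = (ln ub - ln lb)/(2 z), with z the
    standard-normal 95th percentile, so that the lognormal's 5th and 95th
    percentiles reproduce (lb, ub) exactly.  Degenerate bounds (lb == ub)
    give a point mass.  Bounds at a confidence level other than 90% need an
    explicit ``z`` override.
    """
    if z is None:
        if not math.isclose(bounds.confidence, 0.90):
            raise ValueError(
                f"bounds carry confidence {bounds.confidence}; pass the "
                "matching normal quantile as z"
            )
        z = Z_90
    llb, lub = math.log(bounds.lb), math.log(bounds.ub)
    return LognormalSpec(mu=0.5 * (llb + lub), sigma=(lub - llb) / (2.0 * z))


@dataclass(frozen=True)
class CceResult:
    """Monte-Carlo CCE sample with percentile summary and contributions.

    ``contributions[product][compound]`` is the mean share of that compound
    in the product's potency-weighted emission sum (shares sum to 1 within
    each draw; the mean over draws is reported).
    """

    samples: np.ndarray
    n: int
    seed: int
    p05: float
    p50: float
    p95: float
    contributions: dict[str, dict[str, float]]

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.samples, q))


def _sample_quantity(
    bounds: BoundedQuantity, z: np.ndarray
) -> np.ndarray:
    """Draws for one bounded quantity given standard-normal variates.

    Point masses (lb == ub) return the stored bound verbatim, so that exact
    algebraic identities (e.g. halving every bound halves every draw) hold
    bitwise, not merely to rounding.
    """
    if bounds.lb == bounds.ub:
        return np.full(z.shape, bounds.lb)
    spec = lognormal_from_bounds(bounds)
    return np.exp(spec.mu + spec.sigma * z)


def sample_cce(
    e_cig: Mapping[str, BoundedQuantity],
    e_alt: Mapping[str, BoundedQuantity],
    rpf: Mapping[str, BoundedQuantity],
    n: int = 1_000_000,
    seed: int = 17,
) -> CceResult:
    """Monte-Carlo sample of the CCE from bounded inputs.

    All three mappings must cover the same compound set.  Compounds are
    processed in sorted order and, per compound, standard-normal variates
    are drawn for the baseline emission, the alternative emission and the
    RPF in that order — the stream layout is fixed so results are
    reproducible bit-for-bit for a given (inputs, n, seed).
    """
    compounds = sorted(e_cig)
    for name, mapping in (("e_alt", e_alt), ("rpf", rpf)):
        if sorted(mapping) != compounds:
            missing = set(compounds) ^ set(mapping)
            raise ValueError(f"compound sets differ between e_cig and {name}: {sorted(missing)}")
    if n < 1:
        raise ValueError("n must be >= 1")

    rng = np.random.default_rng(seed)
    num = np.zeros(n)
    den = np.zeros(n)
    weighted_cig: dict[str, np.ndarray] = {}
    weighted_alt: dict[str, np.ndarray] = {}
    for compound in compounds:
        # rng is always consumed, even for point masses, so the draw
        # alignment of other compounds never depends on which inputs are
        # degenerate
        ec = _sample_quantity(e_cig[compound], rng.standard_normal(n))
        ea = _sample_quantity(e_alt[compound], rng.standard_normal(n))
        rf = _sample_quantity(rpf[compound], rng.standard_normal(n))
        wc = ec * rf
        wa = ea * rf
        num += wc
        den += wa
        weighted_cig[compound] = wc
        weighted_alt[compound] = wa

    samples = num / den
    contributions = {
        "cigarette": {c: float(np.mean(weighted_cig[c] / num)) for c in compounds},
        "alternative": {c: float(np.mean(weighted_alt[c] / den)) for c in compounds},
    }
    return CceResult(
        samples=samples,
        n=n,
        seed=seed,
        p05=float(np.percentile(samples, 5)),
        p50=float(np.percentile(samples, 50)),
        p95=float(np.percentile(samples, 95)),
        contributions=contributions,
    )


def reference_rescale(
    rpf: Mapping[str, BoundedQuantity], new_reference: str
) -> dict[str, BoundedQuantity]:
    """Re-express all RPF bounds relative to another compound.

    Every compound's bounds are divided by the new reference's point RPF
    (the geometric midpoint of its interval).  The CCE is invariant under
    this common rescaling — exactly for point masses, and within Monte-Carlo
    tolerance when the reference interval is non-degenerate.
    """
    if new_reference not in rpf:
        raise KeyError(f"unknown reference compound {new_reference!r}")
    r = rpf[new_reference].geometric_mid
    return {c: bq.scaled(1.0 / r) for c, bq in rpf.items()}


@dataclass(frozen=True)
class HealthTranslation:
    """Semi-quantitative reading of a CCE interval as health impact."""

    cce_p05: float
    cce_p95: float
    halving_factor: float
    halvings_p05: float
    halvings_p95: float
    verdict: str


def _verdict(cce_lo: float, cce_hi: float) -> str:
    if cce_lo >= 10:
        return (
            "substantial reduction in harm expected: even the lower bound of "
            "the CCE is a 10-fold or larger decrease in cumulative exposure"
        )
    if cce_lo > 1:
        return (
            "reduction in cumulative exposure; a 10-fold or larger decrease "
            "is not supported across the whole uncertainty range"
        )
    if cce_hi >= 1 >= cce_lo:
        return "no change in health impact distinguishable (CCE interval includes 1)"
    return "increase in harm expected (CCE below 1: higher cumulative exposure)"


def health_translation(
    cce_p05: float, cce_p95: float, halving_factor: float = 2.0
) -> HealthTranslation:
    """Translate a CCE uncertainty interval into effect-size halvings.

    ``halving_factor`` is the dose ratio that halves the effect size
    (BMD10/BMD05); for continuous endpoints it is close to or below 2, and
    2-2.6 for rat time-to-tumour data.  The number of halvings implied by a
    CCE value is h = ln(CCE) / ln(halving_factor): a CCE of 1 gives h = 0
    (no change), a CCE of 10 or more indicates a substantial reduction in
    harm, and a CCE below 1 an increase in harm.
    """
    if cce_p05 <= 0 or cce_p95 <= 0:
        raise ValueError("CCE bounds must be positive")
    if halving_factor <= 1:
        raise ValueError("halving_factor must exceed 1")
    lf = math.log(halving_factor)
    return HealthTranslation(
        cce_p05=cce_p05,
        cce_p95=cce_p95,
        halving_factor=halving_factor,
        halvings_p05=math.log(cce_p05) / lf,
        halvings_p95=math.log(cce_p95) / lf,
        verdict=_verdict(cce_p05, cce_p95),
    )
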
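"""Quantal dose-response modelling, benchmark doses, and relative potency.

Model
-----
Incidence at dose ``d`` follows the quantal exponential (Weibull-type) model

    p(d) = c + (1 - c) * (1 - exp(-(d / beta)^g))

with background probability ``c``, location ``beta`` (the dose scale) and
steepness ``g > 0``.  The benchmark response (BMR) is defined on the *extra
risk* scale ER(d) = (p(d) - p(0)) / (1 - p(0)) = 1 - exp(-(d/beta)^g), so

    BMD = beta * (-ln(1 - BMR))^(1/g).

On log-dose the curves for different compounds are parallel whenever they
share ``g``; the horizontal distance between two curves is the log of the
relative potency factor (RPF), and the BMD ratio between two compounds is
then independent of the BMR level.

Fitting maximises the binomial likelihood over (logit c, log beta, log g).
Confidence bounds (two-sided 90%) come from profile likelihood: the profiled
log-likelihood is allowed to drop by half the chi-square(1) 90% critical
value, 1.35277.  The covariate (joint) fit shares one steepness across
compounds, which lets data-poor compounds borrow strength; the log RPF of
each compound against the reference is profiled directly.

Unbounded profile directions (flat or non-monotone data) are encoded with an
explicit 0 lower bound or infinite upper bound rather than being dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

from .quantal import QuantalDataset

__all__ = [
    "ModelFit",
    "BmdResult",
    "RpfEstimate",
    "ParallelismReport",
    "FitError",
    "fit_single",
    "select_critical",
    "fit_covariate",
    "check_parallelism",
    "combine_severity_rpfs",
]

logger = logging.getLogger(__name__)

#: half the chi-square(1) critical value at 90%: profile log-likelihood drop
#: defining two-sided 90% confidence bounds
PROFILE_DROP_90 = 0.5 * stats.chi2.ppf(0.90, df=1)

_LOGIT_C_BOUNDS = (-15.0, 4.0)
_LOG_G_BOUNDS = (-3.0, 3.5)
_LOG_BETA_SPAN = 18.0  # allowed log-beta excursion beyond the dose range
_PROFILE_RANGE = 30.0  # log-scale search radius before declaring a bound open
_FTOL = 1e-13


class FitError(RuntimeError):
    """Raised when a required dose-response fit cannot be obtained."""


@dataclass(frozen=True)
class ModelFit:
    """A fitted quantal exponential model (single dataset or joint).

    ``backgrounds`` holds one background probability per dataset, in input
    order; ``log_betas`` one log location parameter per compound.  In a joint
    (covariate) fit the steepness ``g`` is shared across all compounds.
    """

    backgrounds: tuple[float, ...]
    log_betas: dict[str, float]
    steepness: float
    bmr: float
    log_likelihood: float
    converged: bool
    n_params: int

    def __post_init__(self) -> None:
        if not 0 < self.bmr < 1:
            raise ValueError("bmr must lie in (0, 1)")
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")
        if any(not 0 <= c < 1 for c in self.backgrounds):
            raise ValueError("backgrounds must lie in [0, 1)")
        if self.log_likelihood > 1e-9:
            raise ValueError("binomial log-likelihood cannot be positive")

    def bmd(self, compound_id: str, bmr: float | None = None) -> float:
        """BMD for one compound at the fitted (or an alternative) BMR."""
        bmr = self.bmr if bmr is None else bmr
        a = -math.log1p(-bmr)
        return math.exp(self.log_betas[compound_id]) * a ** (1.0 / self.steepness)


@dataclass(frozen=True)
class BmdResult:
    """Benchmark dose with two-sided 90% profile-likelihood bounds."""

    bmd: float
    bmdl: float
    bmdu: float
    bmr: float

    def __post_init__(self) -> None:
        if not 0 < self.bmr < 1:
            raise ValueError("bmr must lie in (0, 1)")
        if not (0 < self.bmdl <= self.bmd <= self.bmdu):
            raise ValueError(
                f"require 0 < bmdl <= bmd <= bmdu, got "
                f"({self.bmdl}, {self.bmd}, {self.bmdu})"
            )


@dataclass(frozen=True)
class RpfEstimate:
    """Relative potency of a compound against the reference, as a 90% CI.

    ``lb == 0`` encodes a profile direction unbounded below (no detectable
    potency floor, typical for weak datasets); ``ub == inf`` one unbounded
    above.  ``severity`` is the category code the estimate belongs to, or
    ``"combined"`` after pooling across categories.
    """

    compound_id: str
    reference_id: str
    lb: float
    ub: float
    severity: int | str = "combined"
    point: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.lb <= self.ub) or self.ub <= 0:
            raise ValueError(f"invalid RPF bounds ({self.lb}, {self.ub})")
        if self.compound_id == self.reference_id and self.point not in (None, 1.0):
            raise ValueError("reference compound must have point RPF 1")


@dataclass(frozen=True)
class ParallelismReport:
    """Likelihood-ratio check of the shared-steepness assumption (advisory)."""

    applicable: bool
    lr_stat: float = math.nan
    df: int = 0
    p_value: float = math.nan
    shared_loglik: float = math.nan
    free_loglik: float = math.nan


# ---------------------------------------------------------------------------
# likelihood machinery


def _extra_risk(d: np.ndarray, log_beta: float, g: float) -> np.ndarray:
    er = np.zeros_like(d, dtype=float)
    pos = d > 0
    # clamp the log-hazard exponent: beyond ~50 the extra risk is 1 anyway
    er[pos] = -np.expm1(-np.exp(np.minimum(g * (np.log(d[pos]) - log_beta), 50.0)))
    return er


def _nll_one(ds: QuantalDataset, a: float, b: float, h: float) -> float:
    """Negative binomial log-likelihood of one dataset at (logit c, log beta, log g)."""
    d = np.asarray(ds.doses)
    x = np.asarray(ds.n_affected, dtype=float)
    n = np.asarray(ds.n_at_risk, dtype=float)
    c = 1.0 / (1.0 + math.exp(-a))
    p = c + (1.0 - c) * _extra_risk(d, b, math.exp(h))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -float(np.sum(x * np.log(p) + (n - x) * np.log1p(-p)))


def _beta_bounds(datasets: Sequence[QuantalDataset]) -> tuple[float, float]:
    pos = [d for ds in datasets for d in ds.doses if d > 0]
    lo, hi = math.log(min(pos)), math.log(max(pos))
    return lo - _LOG_BETA_SPAN, hi + _LOG_BETA_SPAN


def _init_ab(ds: QuantalDataset) -> tuple[float, float]:
    """Moment-style start: background from the lowest group, beta from the
    dose where observed extra risk crosses 1 - 1/e (its value at d = beta,
    for any steepness)."""
    n = np.asarray(ds.n_at_risk, dtype=float)
    x = np.asarray(ds.n_affected, dtype=float)
    c0 = float((x[0] + 0.5) / (n[0] + 1.0))
    c0 = min(max(c0, 1e-4), 0.95)
    a0 = math.log(c0 / (1 - c0))
    er = np.clip(((x + 0.5) / (n + 1.0) - c0) / (1 - c0), 1e-4, 1 - 1e-4)
    d = np.asarray(ds.doses)
    target = 1.0 - 1.0 / math.e
    above = np.nonzero((er >= target) & (d > 0))[0]
    if above.size:
        b0 = math.log(d[above[0]])
    else:
        b0 = math.log(max(d[d > 0], default=1.0)) + 1.0
    return a0, b0


def _minimize(
    f: Callable[[np.ndarray], float],
    starts: Sequence[np.ndarray],
    bounds: Sequence[tuple[float, float]],
) -> optimize.OptimizeResult:
    best = None
    for x0 in starts:
        x0 = np.clip(x0, [lo for lo, _ in bounds], [hi for _, hi in bounds])
        res = optimize.minimize(
            f, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 1000, "ftol": _FTOL},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    assert best is not None
    return best


def _profile_bound(
    pnll: Callable[[float], float],
    mle: float,
    nll_min: float,
    direction: int,
    max_range: float = _PROFILE_RANGE,
) -> float:
    """Locate the profile crossing nll_min + PROFILE_DROP_90 on one side.

    Returns ``direction * inf`` when the profile never reaches the target
    within ``max_range`` log units (an open confidence bound).
    """
    target = nll_min + PROFILE_DROP_90
    step = 0.2
    inner, inner_val = mle, nll_min
    while True:
        outer = inner + direction * step
        if abs(outer - mle) > max_range:
            return direction * math.inf
        val = pnll(outer)
        if val >= target:
            break
        inner, inner_val = outer, val
        step *= 1.8
    f = lambda t: pnll(t) - target
    # 1e-5 on the log scale is far below any reportable CI precision
    return float(optimize.brentq(f, min(inner, outer), max(inner, outer), xtol=1e-5))


# ---------------------------------------------------------------------------
# single-dataset fit (Step 2)


def fit_single(dataset: QuantalDataset, bmr: float = 0.10) -> tuple[ModelFit, BmdResult]:
    """Fit the quantal exponential model to one dataset and derive its BMD.

    The benchmark dose solves ER(BMD) = ``bmr`` on the extra-risk scale, and
    BMDL/BMDU are two-sided 90% profile-likelihood bounds obtained by
    profiling log BMD directly (``log beta = log BMD - ln(-ln(1-bmr)) / g``).
    Multi-start local optimisation keeps the fit deterministic; a fit that
    fails to converge is flagged, never silently replaced.
    """
    if not 0 < bmr < 1:
        raise ValueError("bmr must lie in (0, 1)")
    if not dataset.fittable:
        raise FitError(f"{dataset.key()}: need >= 3 dose groups to fit")

    b_bounds = _beta_bounds([dataset])
    bounds = [_LOGIT_C_BOUNDS, b_bounds, _LOG_G_BOUNDS]
    a0, b0 = _init_ab(dataset)
    starts = [
        np.array([a0, b0, h]) for h in (-0.7, 0.0, 0.7)
    ] + [np.array([a0, b0 + db, 0.0]) for db in (-1.5, 1.5)]

    def f(x: np.ndarray) -> float:
        return _nll_one(dataset, x[0], x[1], x[2])

    res = _minimize(f, starts, bounds)
    a_hat, b_hat, h_hat = res.x
    g_hat = math.exp(h_hat)
    nll_min = res.fun

    log_a = math.log(-math.log1p(-bmr))
    at_ceiling = b_hat >= b_bounds[1] - 1e-6
    bmd = math.inf if at_ceiling else math.exp(b_hat) * math.exp(log_a / g_hat)

    # profile log BMD: t = log beta + log_a / g
    t_hat = b_hat + log_a / g_hat

    def pnll(t: float) -> float:
        def g_of(x: np.ndarray) -> float:
            a, h = x
            b = t - log_a / math.exp(h)
            return _nll_one(dataset, a, b, h)

        sub = _minimize(g_of, [np.array([a_hat, h_hat])], [_LOGIT_C_BOUNDS, _LOG_G_BOUNDS])
        return sub.fun

    if at_ceiling:
        # no upward signal: upper side open, profile the lower side from the
        # largest finite location
        t_anchor = b_bounds[1] + log_a / g_hat
        lo = _profile_bound(pnll, t_anchor, nll_min, -1, max_range=2 * _PROFILE_RANGE)
        hi = math.inf
    else:
        lo = _profile_bound(pnll, t_hat, nll_min, -1)
        hi = _profile_bound(pnll, t_hat, nll_min, +1)

    fit = ModelFit(
        backgrounds=(1.0 / (1.0 + math.exp(-a_hat)),),
        log_betas={dataset.compound_id: float(b_hat)},
        steepness=g_hat,
        bmr=bmr,
        log_likelihood=-nll_min,
        converged=bool(res.success),
        n_params=3,
    )
    bmdl = math.exp(lo) if math.isfinite(lo) else 1e-300
    bmdu = math.exp(hi) if math.isfinite(hi) else math.inf
    return fit, BmdResult(bmd=bmd, bmdl=bmdl, bmdu=bmdu, bmr=bmr)


# ---------------------------------------------------------------------------
# critical dataset selection (Step 2)


@dataclass(frozen=True)
class CriticalChoice:
    dataset: QuantalDataset
    fit: ModelFit
    bmd: BmdResult


def select_critical(
    datasets: Sequence[QuantalDataset], bmr: float = 0.10
) -> dict[str, CriticalChoice]:
    """Pick, per compound, the dataset with the lowest fitted BMD.

    All datasets must share one severity category (selection runs per
    category).  Ties are broken by the smaller BMDL, then by dataset key,
    so the choice is deterministic under input permutation.  A compound
    whose datasets all fail to converge raises :class:`FitError`.
    """
    if not datasets:
        return {}
    severities = {ds.severity for ds in datasets}
    if len(severities) > 1:
        raise ValueError(
            f"select_critical runs within one severity category, got {sorted(s.code for s in severities)}"
        )
    by_compound: dict[str, list[QuantalDataset]] = {}
    for ds in datasets:
        by_compound.setdefault(ds.compound_id, []).append(ds)

    out: dict[str, CriticalChoice] = {}
    for compound in sorted(by_compound):
        candidates: list[tuple[float, float, tuple, CriticalChoice]] = []
        for ds in by_compound[compound]:
            if not ds.fittable:
                logger.warning("skipping %s: fewer than 3 dose groups", ds.key())
                continue
            fit, bmd = fit_single(ds, bmr=bmr)
            if not fit.converged:
                logger.warning("non-convergent fit for %s", ds.key())
                continue
            candidates.append((bmd.bmd, bmd.bmdl, ds.key(), CriticalChoice(ds, fit, bmd)))
        if not candidates:
            raise FitError(f"no convergent fit for compound {compound!r}")
        candidates.sort(key=lambda t: (t[0], t[1], t[2]))
        if len(candidates) > 1 and candidates[0][:2] == candidates[1][:2]:
            logger.info(
                "BMD tie for %s broken by dataset key order (%s wins)",
                compound, candidates[0][2],
            )
        out[compound] = candidates[0][3]
    return out


# ---------------------------------------------------------------------------
# covariate (joint) fit and RPF profile CIs (Step 3)


def _joint_nll_factory(datasets: Sequence[QuantalDataset]):
    m = len(datasets)

    def f(x: np.ndarray) -> float:
        h = x[2 * m]
        return sum(
            _nll_one(ds, x[k], x[m + k], h) for k, ds in enumerate(datasets)
        )

    return f


def _fit_joint(
    datasets: Sequence[QuantalDataset],
) -> tuple[optimize.OptimizeResult, list[tuple[float, float]]]:
    m = len(datasets)
    b_bounds = _beta_bounds(datasets)
    bounds = [_LOGIT_C_BOUNDS] * m + [b_bounds] * m + [_LOG_G_BOUNDS]
    inits = [_init_ab(ds) for ds in datasets]
    base = np.array([a for a, _ in inits] + [b for _, b in inits] + [0.0])
    starts = []
    for h in (-0.7, 0.0, 0.7):
        s = base.copy()
        s[-1] = h
        starts.append(s)
    for db in (-1.0, 1.0):
        s = base.copy()
        s[m : 2 * m] += db
        starts.append(s)
    f = _joint_nll_factory(datasets)
    return _minimize(f, starts, bounds), bounds


def fit_covariate(
    critical_datasets: Sequence[QuantalDataset],
    reference_id: str,
    bmr: float = 0.10,
) -> tuple[ModelFit, list[RpfEstimate]]:
    """Joint fit of the critical datasets with a shared steepness parameter.

    Parameters per dataset: a background; per compound: a log location; one
    shared log steepness.  The RPF of compound *i* against the reference is
    beta_ref / beta_i (equivalently the BMD ratio, at any BMR).  Each log RPF
    receives a two-sided 90% profile-likelihood CI by fixing the log-beta
    difference and re-optimising everything else.  Because the RPF is a ratio
    of locations under shared steepness, neither the point estimates nor the
    CIs depend on the BMR.
    """
    datasets = list(critical_datasets)
    compounds = [ds.compound_id for ds in datasets]
    if len(set(compounds)) != len(compounds):
        raise ValueError("one critical dataset per compound is required")
    if len(datasets) < 2:
        raise FitError("covariate fit needs at least 2 compounds")
    if reference_id not in compounds:
        raise ValueError(f"reference compound {reference_id!r} not among {compounds}")
    severities = {ds.severity for ds in datasets}
    if len(severities) > 1:
        raise ValueError("covariate fit runs within one severity category")
    severity_code = next(iter(severities)).code

    m = len(datasets)
    ref_idx = compounds.index(reference_id)
    res, bounds = _fit_joint(datasets)
    x_hat = res.x
    nll_min = res.fun
    f = _joint_nll_factory(datasets)

    fit = ModelFit(
        backgrounds=tuple(1.0 / (1.0 + math.exp(-a)) for a in x_hat[:m]),
        log_betas={c: float(x_hat[m + k]) for k, c in enumerate(compounds)},
        steepness=math.exp(x_hat[2 * m]),
        bmr=bmr,
        log_likelihood=-nll_min,
        converged=bool(res.success),
        n_params=2 * m + 1,
    )

    estimates: list[RpfEstimate] = []
    for k, compound in enumerate(compounds):
        if compound == reference_id:
            estimates.append(
                RpfEstimate(compound, reference_id, 1.0, 1.0, severity_code, point=1.0)
            )
            continue
        delta_hat = float(x_hat[m + ref_idx] - x_hat[m + k])
        # reduced parameter vector omits b_k, which is pinned to b_ref - delta
        free_idx = [j for j in range(2 * m + 1) if j != m + k]
        warm = {"x": x_hat[free_idx].copy()}
        red_bounds = [bounds[j] for j in free_idx]
        ref_pos = free_idx.index(m + ref_idx)

        def pnll(delta: float) -> float:
            def g_of(xr: np.ndarray) -> float:
                full = np.empty(2 * m + 1)
                full[free_idx] = xr
                full[m + k] = xr[ref_pos] - delta
                return f(full)

            sub = _minimize(g_of, [warm["x"]], red_bounds)
            warm["x"] = sub.x
            return sub.fun

        lo = _profile_bound(pnll, delta_hat, nll_min, -1)
        warm["x"] = x_hat[free_idx].copy()
        hi = _profile_bound(pnll, delta_hat, nll_min, +1)
        estimates.append(
            RpfEstimate(
                compound,
                reference_id,
                lb=math.exp(lo) if math.isfinite(lo) else 0.0,
                ub=math.exp(hi) if math.isfinite(hi) else math.inf,
                severity=severity_code,
                point=math.exp(delta_hat),
            )
        )
    return fit, estimates


def check_parallelism(
    critical_datasets: Sequence[QuantalDataset], reference_id: str | None = None
) -> ParallelismReport:
    """Likelihood-ratio test of the shared-steepness (parallelism) assumption.

    Compares the joint shared-``g`` fit against per-compound steepness (the
    sum of independent single-dataset fits); df = n_compounds - 1.  The
    report is advisory: a rejection flags curves that are not parallel on
    log-dose, which undermines the dose-addition reading of the RPFs, but it
    does not block the pipeline.
    """
    datasets = list(critical_datasets)
    if len(datasets) < 2:
        return ParallelismReport(applicable=False)
    res, _ = _fit_joint(datasets)
    shared = -res.fun
    free = 0.0
    for ds in datasets:
        fit, _ = fit_single(ds, bmr=0.10)
        free += fit.log_likelihood
    lr = max(0.0, 2.0 * (free - shared))
    df = len(datasets) - 1
    return ParallelismReport(
        applicable=True,
        lr_stat=lr,
        df=df,
        p_value=float(stats.chi2.sf(lr, df)),
        shared_loglik=shared,
        free_loglik=free,
    )


# ---------------------------------------------------------------------------
# combining severity-specific RPF intervals (Step 3, final part)


def combine_severity_rpfs(per_severity: Sequence[RpfEstimate]) -> RpfEstimate:
    """Pool severity-specific RPF intervals into one combined interval.

    Each severity-specific 90% CI is read as a lognormal (the same
    calibration used for Monte-Carlo sampling); the combined interval is the
    5th/95th percentile pair of the equal-weight mixture of those lognormals,
    computed exactly from the mixture CDF.  A single input is returned
    unchanged.
    """
    ests = list(per_severity)
    if not ests:
        raise ValueError("need at least one severity-specific estimate")
    cids = {e.compound_id for e in ests}
    refs = {e.reference_id for e in ests}
    if len(cids) != 1 or len(refs) != 1:
        raise ValueError("estimates must concern one compound and one reference")
    if len(ests) == 1:
        e = ests[0]
        return RpfEstimate(e.compound_id, e.reference_id, e.lb, e.ub, "combined", e.point)

    from .engine import lognormal_from_bounds  # calibration lives with the sampler
    from .emissions import BoundedQuantity

    specs = [lognormal_from_bounds(BoundedQuantity(e.lb, e.ub)) for e in ests]

    def cdf(x: float) -> float:
        if x <= 0:
            return 0.0
        lx = math.log(x)
        tot = 0.0
        for s in specs:
            if s.sigma == 0:
                tot += 1.0 if lx >= s.mu else 0.0
            else:
                tot += stats.norm.cdf((lx - s.mu) / s.sigma)
        return tot / len(specs)

    def quantile(q: float) -> float:
        los = [s.mu - 6 * s.sigma - 1e-3 for s in specs]
        his = [s.mu + 6 * s.sigma + 1e-3 for s in specs]
        lo, hi = math.exp(min(los)), math.exp(max(his))
        while cdf(lo) > q:
            lo /= 2
        while cdf(hi) < q:
            hi *= 2
        return float(optimize.brentq(lambda x: cdf(x) - q, lo, hi, xtol=1e-12, rtol=1e-10))

    lb, ub = quantile(0.05), quantile(0.95)
    return RpfEstimate(ests[0].compound_id, ests[0].reference_id, lb, ub, "combined")
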
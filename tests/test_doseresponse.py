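import math

import numpy as np
import pytest
from scipy import stats

from cce.doseresponse import (
    FitError,
    RpfEstimate,
    check_parallelism,
    combine_severity_rpfs,
    fit_covariate,
    fit_single,
    select_critical,
)
from cce.simulate import SimulationConfig, simulate_quantal

from conftest import make_dataset


class TestFitSingle:
    def test_recovers_closed_form_bmd(self):
        """Noise-free g=1 data: BMD at 10% extra risk is beta*ln(10/9)."""
        ds = make_dataset(background=0.05, beta=100.0, steepness=1.0)
        fit, bmd = fit_single(ds, bmr=0.10)
        assert fit.converged
        target = 100.0 * math.log(10 / 9)
        assert bmd.bmd == pytest.approx(target, rel=5e-3)
        assert bmd.bmdl < bmd.bmd < bmd.bmdu

    def test_bmd_ratio_between_bmr_levels_matches_analytic_value(self):
        """BMD10/BMD05 = ln(0.9)/ln(0.95) ~ 2.054 for unit steepness."""
        ds = make_dataset(background=0.05, beta=100.0, steepness=1.0)
        _, bmd10 = fit_single(ds, bmr=0.10)
        _, bmd05 = fit_single(ds, bmr=0.05)
        analytic = math.log(0.9) / math.log(0.95)
        assert bmd10.bmd / bmd05.bmd == pytest.approx(analytic, rel=0.01)

    def test_flat_data_has_open_upper_bound_but_finite_lower(self):
        ds = make_dataset(doses=(0.0, 10.0, 50.0, 100.0), group_size=50,
                          n_affected=[0, 0, 0, 0], noise_free=False)
        _, bmd = fit_single(ds, bmr=0.10)
        assert math.isinf(bmd.bmd)
        assert math.isinf(bmd.bmdu)
        assert 0 < bmd.bmdl < math.inf

    def test_too_few_groups_rejected(self):
        ds = make_dataset(doses=(0.0, 100.0), n_affected=[2, 30], noise_free=False)
        with pytest.raises(FitError):
            fit_single(ds)

    def test_bad_bmr_rejected(self):
        with pytest.raises(ValueError):
            fit_single(make_dataset(), bmr=1.5)


class TestSelectCritical:
    def test_picks_lowest_bmd_dataset(self):
        potent = make_dataset("A", beta=50.0)
        weak = make_dataset("A", beta=100.0, lesion_term="carcinoma")
        chosen = select_critical([weak, potent])
        assert chosen["A"].dataset == potent

    def test_single_dataset_returns_itself(self):
        ds = make_dataset("A")
        assert select_critical([ds])["A"].dataset == ds

    def test_tie_break_is_deterministic_under_permutation(self):
        first = make_dataset("A", lesion_term="adenocarcinoma")
        second = make_dataset("A", lesion_term="carcinoma")  # identical data
        w1 = select_critical([first, second])["A"].dataset
        w2 = select_critical([second, first])["A"].dataset
        assert w1 == w2 == min([first, second], key=lambda d: d.key())

    def test_mixed_severities_rejected(self):
        with pytest.raises(ValueError, match="severity"):
            select_critical([make_dataset(severity=2), make_dataset(severity=3)])


@pytest.fixture(scope="module")
def shifted_pair():
    """Compound B is compound A with doses divided by 4 and identical counts:
    the log-dose curves are shifted by log 4, so RPF(B vs A) is exactly 4."""
    a = make_dataset("A", background=0.05, beta=100.0, steepness=1.3)
    b = make_dataset(
        "B",
        doses=tuple(d / 4 for d in a.doses),
        n_affected=list(a.n_affected),
        noise_free=False,
    )
    return a, b


class TestFitCovariate:
    def test_dose_rescaling_oracle(self, shifted_pair):
        a, b = shifted_pair
        _, ests = fit_covariate([a, b], reference_id="A")
        rpf_b = next(e for e in ests if e.compound_id == "B")
        assert rpf_b.point == pytest.approx(4.0, rel=1e-3)
        assert rpf_b.lb < 4.0 < rpf_b.ub

    def test_reference_against_itself_is_degenerate_one(self, shifted_pair):
        _, ests = fit_covariate(list(shifted_pair), reference_id="A")
        ref = next(e for e in ests if e.compound_id == "A")
        assert (ref.point, ref.lb, ref.ub) == (1.0, 1.0, 1.0)

    def test_rpf_cis_do_not_depend_on_bmr(self, shifted_pair):
        """Parallel log-dose curves: the BMD ratio is BMR-free."""
        pair = list(shifted_pair)
        _, at10 = fit_covariate(pair, "A", bmr=0.10)
        _, at05 = fit_covariate(pair, "A", bmr=0.05)
        for e10, e05 in zip(at10, at05):
            assert e10.point == pytest.approx(e05.point, rel=1e-6)
            assert e10.lb == pytest.approx(e05.lb, rel=1e-6)
            assert e10.ub == pytest.approx(e05.ub, rel=1e-6)

    def test_invariant_to_common_dose_rescaling(self, shifted_pair):
        a, b = shifted_pair
        _, base = fit_covariate([a, b], "A")
        _, scaled = fit_covariate(
            [a.with_doses_scaled(7.0), b.with_doses_scaled(7.0)], "A"
        )
        for e1, e2 in zip(base, scaled):
            assert e1.point == pytest.approx(e2.point, rel=1e-4)
            assert e1.lb == pytest.approx(e2.lb, rel=1e-3)
            assert e1.ub == pytest.approx(e2.ub, rel=1e-3)

    def test_joint_likelihood_is_a_maximum(self, shifted_pair):
        """No shared-steepness parameter setting beats the MLE."""
        from cce.doseresponse import _joint_nll_factory

        pair = list(shifted_pair)
        fit, _ = fit_covariate(pair, "A")
        f = _joint_nll_factory(pair)
        m = len(pair)
        x_hat = np.array(
            [math.log(c / (1 - c)) for c in fit.backgrounds]
            + [fit.log_betas[ds.compound_id] for ds in pair]
            + [math.log(fit.steepness)]
        )
        assert f(x_hat) == pytest.approx(-fit.log_likelihood, abs=1e-6)
        rng = np.random.default_rng(42)
        for _ in range(20):
            assert f(x_hat + 0.3 * rng.standard_normal(2 * m + 1)) >= f(x_hat) - 1e-9

    def test_fewer_than_two_compounds_rejected(self):
        with pytest.raises(FitError):
            fit_covariate([make_dataset("A")], "A")

    def test_unknown_reference_rejected(self, shifted_pair):
        with pytest.raises(ValueError, match="reference"):
            fit_covariate(list(shifted_pair), "Z")


class TestParallelism:
    def test_single_compound_not_applicable(self):
        report = check_parallelism([make_dataset("A")])
        assert not report.applicable

    def test_null_pvalues_are_roughly_uniform(self):
        """Data simulated with a common steepness: the LR p-value should be
        approximately uniform; checked via its rejection rate and median."""
        pvals = []
        for rep in range(80):
            cfg = SimulationConfig(
                true_rpfs={"ref": 1.0, "x": 5.0},
                reference_id="ref",
                group_size=100,
                seed=20_000 + rep,
            )
            pvals.append(check_parallelism(simulate_quantal(cfg)).p_value)
        pvals = np.asarray(pvals)
        assert np.mean(pvals < 0.05) <= 0.15
        assert 0.3 <= np.mean(pvals < 0.5) <= 0.7

    def test_power_against_threefold_steepness_difference(self):
        """With n=500/group and g differing 3-fold the test should reject
        nearly always at alpha=0.05."""
        rejections = 0
        reps = 25
        for rep in range(reps):
            cfg = SimulationConfig(
                true_rpfs={"ref": 1.0, "x": 5.0},
                reference_id="ref",
                steepness=1.0,
                group_size=500,
                seed=30_000 + rep,
            )
            ref_ds, x_ds = simulate_quantal(cfg)
            steep_cfg = SimulationConfig(
                true_rpfs={"ref": 1.0, "x": 5.0},
                reference_id="ref",
                steepness=3.0,
                group_size=500,
                seed=60_000 + rep,
            )
            _, x_steep = simulate_quantal(steep_cfg)
            if check_parallelism([ref_ds, x_steep]).p_value < 0.05:
                rejections += 1
        assert rejections / reps >= 0.8


class TestCombineSeverity:
    def test_single_interval_returned_unchanged(self):
        e = RpfEstimate("x", "ref", 2.0, 8.0, severity=2)
        combined = combine_severity_rpfs([e])
        assert (combined.lb, combined.ub) == (2.0, 8.0)
        assert combined.severity == "combined"

    def test_identical_intervals_combine_to_themselves(self):
        ests = [RpfEstimate("x", "ref", 2.0, 8.0, severity=s) for s in (2, 3, 4)]
        combined = combine_severity_rpfs(ests)
        assert combined.lb == pytest.approx(2.0, rel=1e-6)
        assert combined.ub == pytest.approx(8.0, rel=1e-6)

    def test_disjoint_intervals_match_mixture_quantile_oracle(self):
        """Frozen oracle: equal-weight mixture of the lognormals calibrated
        to (1,4) and (4,16) has 5th/95th percentiles (1.1654, 13.729),
        confirmed here against brute-force mixture sampling."""
        combined = combine_severity_rpfs(
            [RpfEstimate("x", "ref", 1.0, 4.0, 2), RpfEstimate("x", "ref", 4.0, 16.0, 3)]
        )
        assert combined.lb == pytest.approx(1.1654, rel=1e-3)
        assert combined.ub == pytest.approx(13.729, rel=1e-3)

        z = stats.norm.ppf(0.95)
        rng = np.random.default_rng(7)
        draws = []
        for lb, ub in ((1.0, 4.0), (4.0, 16.0)):
            mu = (math.log(lb) + math.log(ub)) / 2
            sigma = (math.log(ub) - math.log(lb)) / (2 * z)
            draws.append(np.exp(mu + sigma * rng.standard_normal(500_000)))
        pooled = np.concatenate(draws)
        assert combined.lb == pytest.approx(np.percentile(pooled, 5), rel=0.01)
        assert combined.ub == pytest.approx(np.percentile(pooled, 95), rel=0.01)

    def test_mixed_compounds_rejected(self):
        with pytest.raises(ValueError):
            combine_severity_rpfs(
                [RpfEstimate("x", "ref", 1, 2, 2), RpfEstimate("y", "ref", 1, 2, 3)]
            )
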
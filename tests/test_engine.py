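import math

import numpy as np
import pytest

from cce.emissions import BoundedQuantity
from cce.engine import (
    health_translation,
    lognormal_from_bounds,
    reference_rescale,
    sample_cce,
)


def point(v):
    return BoundedQuantity(v, v)


class TestLognormalCalibration:
    def test_reference_bmd_bounds_oracle(self):
        """(30.3, 56) calibrates to mu=3.7182, sigma=0.1867 and inverts back."""
        spec = lognormal_from_bounds(BoundedQuantity(30.3, 56.0))
        assert spec.mu == pytest.approx(3.7182, abs=1e-4)
        assert spec.sigma == pytest.approx(0.1867, abs=1e-4)
        z = 1.6448536269514722
        assert math.exp(spec.mu - z * spec.sigma) == pytest.approx(30.3, rel=1e-9)
        assert math.exp(spec.mu + z * spec.sigma) == pytest.approx(56.0, rel=1e-9)

    def test_degenerate_bounds_give_point_mass(self):
        spec = lognormal_from_bounds(point(10.0))
        assert spec.sigma == 0.0
        assert math.exp(spec.mu) == pytest.approx(10.0)

    def test_inverted_bounds_rejected_upstream(self):
        with pytest.raises(ValueError):
            BoundedQuantity(20.0, 10.0)

    def test_non_90_confidence_needs_explicit_z(self):
        bq = BoundedQuantity(1.0, 2.0, confidence=0.95)
        with pytest.raises(ValueError, match="confidence"):
            lognormal_from_bounds(bq)
        spec = lognormal_from_bounds(bq, z=1.959963984540054)
        assert math.exp(spec.mu + 1.959963984540054 * spec.sigma) == pytest.approx(2.0)

    def test_empirical_quantiles_match_bounds(self):
        bq = BoundedQuantity(0.212, 0.477)
        spec = lognormal_from_bounds(bq)
        rng = np.random.default_rng(123)
        draws = np.exp(spec.mu + spec.sigma * rng.standard_normal(1_000_000))
        assert np.percentile(draws, 5) == pytest.approx(bq.lb, rel=0.01)
        assert np.percentile(draws, 95) == pytest.approx(bq.ub, rel=0.01)


class TestSampleCce:
    def test_single_compound_point_masses_rpf_cancels(self):
        for rpf_value in (0.2, 1.0, 37.0):
            res = sample_cce(
                {"x": point(50.0)}, {"x": point(5.0)}, {"x": point(rpf_value)},
                n=1000, seed=0,
            )
            assert np.all(res.samples == 10.0)

    def test_identical_products_give_unit_ratio(self):
        e = {"a": point(3.0), "b": point(0.5)}
        res = sample_cce(e, dict(e), {"a": point(2.0), "b": point(9.0)}, n=500, seed=1)
        assert np.all(res.samples == 1.0)

    def test_compound_set_mismatch_names_difference(self):
        with pytest.raises(ValueError, match="zz"):
            sample_cce(
                {"a": point(1.0)}, {"a": point(1.0)},
                {"a": point(1.0), "zz": point(1.0)},
                n=10, seed=0,
            )

    def test_seed_determinism_is_bitwise(self, case_inputs):
        e_cig, e_htp, rpf = case_inputs
        r1 = sample_cce(e_cig, e_htp, rpf, n=20_000, seed=99)
        r2 = sample_cce(e_cig, e_htp, rpf, n=20_000, seed=99)
        assert np.array_equal(r1.samples, r2.samples)
        assert r1.contributions == r2.contributions

    def test_percentiles_are_ordered_and_positive(self, case_inputs):
        e_cig, e_htp, rpf = case_inputs
        res = sample_cce(e_cig, e_htp, rpf, n=50_000, seed=5)
        assert 0 < res.p05 <= res.p50 <= res.p95
        assert np.all(res.samples > 0)

    def test_contribution_shares_sum_to_one(self, case_inputs):
        e_cig, e_htp, rpf = case_inputs
        res = sample_cce(e_cig, e_htp, rpf, n=20_000, seed=2)
        for product in res.contributions:
            assert sum(res.contributions[product].values()) == pytest.approx(1.0)

    def test_cleaner_alternative_cannot_lower_the_ratio(self, case_inputs):
        """Shrinking one alternative-product emission (same seed) shifts
        every CCE percentile weakly upward."""
        e_cig, e_htp, rpf = case_inputs
        base = sample_cce(e_cig, e_htp, rpf, n=50_000, seed=11)
        cleaner = dict(e_htp)
        c = sorted(cleaner)[0]
        cleaner[c] = BoundedQuantity(cleaner[c].lb / 3, cleaner[c].ub / 3)
        shifted = sample_cce(e_cig, cleaner, rpf, n=50_000, seed=11)
        for q in (5, 25, 50, 75, 95):
            assert shifted.percentile(q) >= base.percentile(q)


class TestReferenceRescale:
    def test_rescale_by_reference_itself_is_identity(self):
        rpf = {"ref": point(1.0), "x": BoundedQuantity(2.0, 8.0)}
        assert reference_rescale(rpf, "ref") == rpf

    def test_point_mass_rescaling_leaves_cce_bit_identical(self):
        e_cig = {"a": point(50.0), "b": point(10.0)}
        e_htp = {"a": point(5.0), "b": point(2.0)}
        rpf = {"a": point(4.0), "b": point(1.0)}
        halved = {c: point(bq.lb / 2) for c, bq in rpf.items()}
        r1 = sample_cce(e_cig, e_htp, rpf, n=1000, seed=3)
        r2 = sample_cce(e_cig, e_htp, halved, n=1000, seed=3)
        assert np.array_equal(r1.samples, r2.samples)

    def test_lognormal_rescaling_preserves_percentiles(self, case_inputs):
        e_cig, e_htp, rpf = case_inputs
        base = sample_cce(e_cig, e_htp, rpf, n=400_000, seed=21)
        rescaled = reference_rescale(rpf, "Formaldehyde")
        moved = sample_cce(e_cig, e_htp, rescaled, n=400_000, seed=21)
        assert moved.p05 == pytest.approx(base.p05, rel=0.01)
        assert moved.p95 == pytest.approx(base.p95, rel=0.01)

    def test_unknown_reference_rejected(self):
        with pytest.raises(KeyError, match="nope"):
            reference_rescale({"a": point(1.0)}, "nope")


class TestHealthTranslation:
    def test_unit_cce_means_no_change(self):
        ht = health_translation(1.0, 1.0)
        assert ht.halvings_p05 == 0.0
        assert "no change" in ht.verdict

    def test_doubling_is_one_halving(self):
        ht = health_translation(2.0, 2.0, halving_factor=2.0)
        assert ht.halvings_p05 == pytest.approx(1.0)

    def test_tenfold_reduction_is_substantial(self):
        ht = health_translation(10.0, 25.0, halving_factor=2.0)
        assert ht.halvings_p05 == pytest.approx(math.log(10) / math.log(2))
        assert ht.halvings_p95 == pytest.approx(math.log(25) / math.log(2))
        assert "substantial reduction" in ht.verdict

    def test_cce_below_one_flags_harm_increase(self):
        assert "increase in harm" in health_translation(0.2, 0.8).verdict

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            health_translation(-1.0, 2.0)
        with pytest.raises(ValueError):
            health_translation(1.0, 2.0, halving_factor=1.0)
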
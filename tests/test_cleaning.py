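import dataclasses

import numpy as np
import pytest
from scipy import stats

from vertraits import cleaning as cl
from vertraits.synthetic import PopulationSpec, gen_population

from conftest import make_group, make_record


class TestGate:
    def test_nine_records_too_few(self):
        keep, gated = cl.gate_min_records(make_group(range(1, 10)), 10)
        assert keep == {}
        assert len(gated) == 9
        assert all(r.measurement_status == cl.STATUS_TOO_FEW for r in gated)

    def test_ten_records_proceed(self):
        keep, gated = cl.gate_min_records(make_group(range(1, 11)), 10)
        assert gated == []
        assert sum(len(v) for v in keep.values()) == 10

    def test_empty_input(self):
        keep, gated = cl.gate_min_records([], 10)
        assert keep == {} and gated == []


class TestDetectAdultOutliers:
    def test_zero_variance(self):
        mask = cl.detect_adult_outliers([10.0] * 10)
        assert mask.sum() == 0 and mask.size == 10

    def test_single_gross_outlier(self):
        values = [1.0] * 10 + [1000.0]
        mask = cl.detect_adult_outliers(values, 0.95)
        # brute-force oracle
        x = np.array(values)
        d2 = ((x - x.mean()) / x.std(ddof=1)) ** 2
        expected = d2 > stats.chi2.ppf(0.95, 1)
        assert mask.tolist() == expected.tolist()
        assert mask[-1] and mask[:-1].sum() == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 51))
        x = rng.lognormal(3, 1, n)
        cutoff = float(rng.uniform(0.5, 0.999))
        mask = cl.detect_adult_outliers(x, cutoff)
        threshold = stats.chi2.ppf(cutoff, 1)
        expected = [((v - x.mean()) / x.std(ddof=1)) ** 2 > threshold for v in x]
        assert mask.tolist() == expected

    def test_mask_length_contract(self):
        for n in (0, 1, 5):
            assert cl.detect_adult_outliers(np.arange(n) + 1.0).size == n


class TestClassifyDistribution:
    def test_normal_draws(self):
        rng = np.random.default_rng(11)
        assert cl.classify_distribution(rng.normal(100, 5, 500)) == cl.NORMAL

    def test_lognormal_draws(self):
        rng = np.random.default_rng(12)
        x = 10 ** rng.normal(2, 0.5, 500)
        assert cl.classify_distribution(x) == cl.LOG_NORMAL

    def test_bimodal_mixture(self):
        rng = np.random.default_rng(13)
        x = np.concatenate(
            [rng.normal(20, 1, 250), rng.normal(200, 1, 250)]
        )
        assert cl.classify_distribution(x) == cl.NON_NORMAL

    def test_tiny_sample_warns(self):
        with pytest.warns(UserWarning):
            assert cl.classify_distribution([1.0, 2.0]) == cl.NON_NORMAL

    def test_large_sample_switch(self):
        rng = np.random.default_rng(14)
        x = rng.normal(50, 2, 6000)
        assert cl.classify_distribution(x, large_sample_switch=5000) == cl.NORMAL


class TestComputeLimits:
    @staticmethod
    def standardized_sample(mean, sd, n=40, seed=0):
        rng = np.random.default_rng(seed)
        z = rng.normal(0, 1, n)
        z = (z - z.mean()) / z.std(ddof=1)
        return mean + sd * z

    def test_normal_limits(self):
        x = self.standardized_sample(100.0, 10.0)
        lo, hi, lo_m, hi_m = cl.compute_limits(x, cl.NORMAL)
        assert lo == pytest.approx(70.0)
        assert hi == pytest.approx(130.0)
        assert (lo_m, hi_m) == ("sd", "sd")

    def test_log_normal_limits(self):
        lx = self.standardized_sample(2.0, 0.1, seed=1)
        x = 10**lx
        lo, hi, lo_m, hi_m = cl.compute_limits(x, cl.LOG_NORMAL)
        assert lo == pytest.approx(10 ** (2.0 - 0.3))
        assert hi == pytest.approx(10 ** (2.0 + 0.3))
        assert (lo_m, hi_m) == ("log sd", "log sd")

    def test_degenerate_constant(self):
        for klass in (cl.NORMAL, cl.LOG_NORMAL, cl.NON_NORMAL):
            lo, hi, *_ = cl.compute_limits([7.0] * 12, klass)
            assert lo == pytest.approx(7.0) and hi == pytest.approx(7.0)

    def test_quantile_limits_uniform(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, 10_000)
        lo, hi, lo_m, hi_m = cl.compute_limits(x, cl.NON_NORMAL)
        assert lo == pytest.approx(0.05, abs=0.01)
        assert hi == pytest.approx(0.95, abs=0.01)
        assert (lo_m, hi_m) == ("quantile", "quantile")

    def test_not_assessed_yields_no_limits(self):
        assert cl.compute_limits([1.0, 2.0], cl.NOT_ASSESSED) == (None, None, "", "")

    def test_ordering_invariant(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            x = rng.lognormal(2, 0.7, 30)
            for klass in (cl.NORMAL, cl.LOG_NORMAL, cl.NON_NORMAL):
                lo, hi, *_ = cl.compute_limits(x, klass)
                assert lo <= hi


class TestAnnotateUnknowns:
    def unknowns(self, values):
        return make_group(values, life_stage="unknown")

    def test_limit_comparison(self):
        out = cl.annotate_unknowns(self.unknowns([150.0, 40.0, 110.0]), 70.0, 130.0)
        assert [r.measurement_status for r in out] == [
            cl.STATUS_OUTLIER,
            cl.STATUS_POSSIBLE_JUVENILE,
            cl.STATUS_POSSIBLE_ADULT,
        ]

    def test_bounds_inclusive(self):
        out = cl.annotate_unknowns(self.unknowns([130.0, 70.0]), 70.0, 130.0)
        assert all(r.measurement_status == cl.STATUS_POSSIBLE_ADULT for r in out)

    def test_no_limits_no_adult_reference(self):
        out = cl.annotate_unknowns(self.unknowns([1.0]), None, None)
        assert out[0].measurement_status == cl.STATUS_NO_ADULT_REF

    def test_missing_value_left_unassessed(self):
        r = make_record(0, None, life_stage="unknown")
        out = cl.annotate_unknowns([r], 70.0, 130.0)
        assert out[0].measurement_status == ""


class TestCleanDataset:
    def test_squirrel_narrative(self, squirrel_fixture, cleaned_squirrel):
        _, records, truth = squirrel_fixture
        annotated, report = cleaned_squirrel
        counts = report.status_totals
        assert counts[cl.STATUS_KNOWN_ADULT] == 28
        assert counts[cl.STATUS_POSSIBLE_ADULT] == 194
        assert counts[cl.STATUS_POSSIBLE_JUVENILE] == 11
        # retained adults = labelled + in-limit unknowns
        retained = counts[cl.STATUS_KNOWN_ADULT] + counts[cl.STATUS_POSSIBLE_ADULT]
        assert retained == 222

    def test_squirrel_against_direct_limit_oracle(self, cleaned_squirrel):
        annotated, report = cleaned_squirrel
        (group,) = report.groups
        lo, hi = group.lower_limit, group.upper_limit
        for rec in annotated:
            if rec.life_stage != "unknown":
                continue
            v = rec.measurement_value
            expected = (
                cl.STATUS_OUTLIER
                if v > hi
                else cl.STATUS_POSSIBLE_JUVENILE
                if v < lo
                else cl.STATUS_POSSIBLE_ADULT
            )
            assert rec.measurement_status == expected

    def test_cardinality_preserved(self):
        for seed in (0, 1, 2):
            records, _ = gen_population(PopulationSpec(seed=seed))
            annotated, report = cl.clean_dataset(records)
            assert len(annotated) == len(records)
            assert report.total_records == len(records)

    def test_order_and_ids_preserved(self, squirrel_fixture, cleaned_squirrel):
        _, records, _ = squirrel_fixture
        annotated, _ = cleaned_squirrel
        assert [r.diagnostic_id for r in annotated] == [
            r.diagnostic_id for r in records
        ]

    def test_too_few_group(self):
        records = make_group(range(1, 10))
        annotated, report = cl.clean_dataset(records)
        assert all(r.measurement_status == cl.STATUS_TOO_FEW for r in annotated)
        (group,) = report.groups
        assert group.lower_limit is None and group.upper_limit is None

    def test_no_adult_reference_group(self):
        records = make_group(range(10, 25), life_stage="unknown")
        annotated, _ = cl.clean_dataset(records)
        assert all(
            r.measurement_status == cl.STATUS_NO_ADULT_REF for r in annotated
        )

    def test_no_adult_fallback_config(self):
        rng = np.random.default_rng(8)
        records = make_group(rng.normal(100, 5, 40), life_stage="unknown")
        config = cl.CleaningConfig(no_adult_fallback=True)
        annotated, _ = cl.clean_dataset(records, config)
        statuses = {r.measurement_status for r in annotated}
        assert cl.STATUS_NO_ADULT_REF not in statuses
        assert cl.STATUS_POSSIBLE_ADULT in statuses

    def test_known_juveniles_never_relabeled(self):
        adults = make_group(np.linspace(90, 110, 15))
        juveniles = make_group([40.0, 42.0], life_stage="juvenile", start=100)
        annotated, _ = cl.clean_dataset(adults + juveniles)
        juvenile_statuses = {
            r.measurement_status for r in annotated if r.life_stage == "juvenile"
        }
        assert juvenile_statuses == {cl.STATUS_KNOWN_JUVENILE}

    def test_inferred_unit_records_excluded_from_reference(self):
        adults = make_group(np.linspace(90, 110, 15))
        bad_unit = make_record(
            200, 5000.0, measurement_unit="lbs", unit_status="unit unresolved"
        )
        annotated, report = cl.clean_dataset(adults + [bad_unit])
        flagged = next(r for r in annotated if r.diagnostic_id == "d0200")
        assert flagged.measurement_status == cl.STATUS_NO_ADULT_REF

    def test_determinism(self):
        records, _ = gen_population(PopulationSpec(seed=9))
        first = cl.clean_dataset(records)
        second = cl.clean_dataset(records)
        assert first[0] == second[0]
        assert first[1].to_frame().equals(second[1].to_frame())


class TestCalibrationProperties:
    # The +/-3 sigma calibration claim presumes the normal branch is taken.
    # At the default screen cutoff (0.95) the screen trims 5% of clean
    # tails, the trimmed sample is platykurtic, and at n ~ 10,000 every
    # normality test rejects it, so calibration is exercised with an
    # extreme-only screen (0.999) that matches the screen's gross-error
    # purpose; the default interaction is pinned separately below.
    CALIBRATION_CONFIG = cl.CleaningConfig(outlier_cutoff=0.999)

    def test_same_distribution_unknowns_rarely_flagged(self):
        # n = 10,000 uncontaminated draws; <= 1% outside +/-3 sigma limits
        rng = np.random.default_rng(66)
        adults = make_group(rng.normal(500, 40, 10_000))
        unknowns = make_group(
            rng.normal(500, 40, 10_000), life_stage="unknown", start=20_000
        )
        annotated, _ = cl.clean_dataset(adults + unknowns, self.CALIBRATION_CONFIG)
        unknown_out = [
            r
            for r in annotated
            if r.life_stage == "unknown"
            and r.measurement_status != cl.STATUS_POSSIBLE_ADULT
        ]
        assert len(unknown_out) / 10_000 <= 0.01

    def test_default_cutoff_goes_quantile_at_large_n(self):
        # documents the default-config behaviour: the 5%-trimmed sample is
        # rejected as normal, limits fall to 5%/95% quantiles, and ~10% of
        # same-distribution unknowns are flagged (liberal, not conservative)
        rng = np.random.default_rng(123)
        adults = make_group(rng.normal(500, 40, 10_000))
        unknowns = make_group(
            rng.normal(500, 40, 10_000), life_stage="unknown", start=20_000
        )
        annotated, report = cl.clean_dataset(adults + unknowns)
        (group,) = report.groups
        assert group.lower_limit_method == "quantile"
        flagged = sum(
            r.life_stage == "unknown"
            and r.measurement_status != cl.STATUS_POSSIBLE_ADULT
            for r in annotated
        )
        assert 0.05 <= flagged / 10_000 <= 0.25

    def test_sigma_multiplier_monotonicity(self):
        records, _ = gen_population(PopulationSpec(seed=4, n_unknown_juveniles=40))
        kept_sets = []
        for k in (1.0, 2.0, 3.0, 4.0):
            config = cl.CleaningConfig(sigma_multiplier=k)
            annotated, _ = cl.clean_dataset(records, config)
            kept_sets.append(
                {
                    r.diagnostic_id
                    for r in annotated
                    if r.measurement_status == cl.STATUS_POSSIBLE_ADULT
                }
            )
        for smaller, larger in zip(kept_sets, kept_sets[1:]):
            assert smaller <= larger

    def test_status_counts_sum_to_input(self):
        records, _ = gen_population(
            PopulationSpec(seed=5, rate_unit_error=0.03, rate_transposition=0.03)
        )
        _, report = cl.clean_dataset(records)
        assert sum(report.status_totals.values()) == len(records)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            cl.CleaningConfig(min_records=1)
        with pytest.raises(ValueError):
            cl.CleaningConfig(quantile_bounds=(0.9, 0.1))
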
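"""Synthetic-herd generator: allocation, eligibility, structure,
determinism and statistical calibration against the analytic oracle."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from herdbudget import (
    MOFT,
    PGOD,
    BreedingDynamics,
    EligibilityFlags,
    GroupDynamics,
    HerdConfig,
    allocate_treatment,
    apply_eligibility_filters,
    generate_herd,
    simulate_breeding_events,
)
from conftest import make_cow
from _dp_oracle import default_expectations


class TestAllocation:
    @pytest.mark.parametrize(
        "brand,expected",
        [(2, PGOD), (1, MOFT), (1000001, MOFT), (44, PGOD), (187, MOFT)],
    )
    def test_brand_parity(self, brand, expected):
        assert allocate_treatment(brand) == expected

    @pytest.mark.parametrize("bad", [0, -3, 2.5, "4", True, None])
    def test_invalid_brands_rejected(self, bad):
        with pytest.raises(ValueError):
            allocate_treatment(bad)


class TestEligibility:
    def test_exclusion_rules(self):
        cows = [make_cow(cow_id=f"c{i}", conception=30.0) for i in range(5)]
        flags = {
            "c0": EligibilityFlags(calving_interval_days=370),  # over limit
            "c1": EligibilityFlags(calving_interval_days=300),
            "c2": EligibilityFlags(systemically_ill=True),
            "c3": EligibilityFlags(abnormal_discharge=True),
            "c4": EligibilityFlags(nulliparous=False),
        }
        kept = apply_eligibility_filters(cows, flags)
        assert [c.cow_id for c in kept] == ["c1", "c4"]

    def test_two_of_five_flagged_ill_leaves_three(self):
        cows = [make_cow(cow_id=f"c{i}", conception=30.0) for i in range(5)]
        flags = {
            f"c{i}": EligibilityFlags(systemically_ill=i < 2) for i in range(5)
        }
        assert len(apply_eligibility_filters(cows, flags)) == 3

    def test_missing_flag_names_the_cow(self):
        cows = [make_cow(cow_id="lonesome", conception=10.0)]
        with pytest.raises(ValueError, match="lonesome"):
            apply_eligibility_filters(cows, {})


class TestGenerateHerd:
    def test_default_cohort_structure(self):
        records = generate_herd(HerdConfig(seed=3))
        assert len(records) == 190
        by_farm = {f: sum(r.farm == f for r in records) for f in "123"}
        assert by_farm == {"1": 94, "2": 27, "3": 69}
        # sequential brands + parity allocation => an even split
        assert sum(r.treatment == PGOD for r in records) == 95
        for r in records:
            assert allocate_treatment(r.freeze_brand) == r.treatment

    def test_group_sizes_override(self):
        config = HerdConfig(seed=5, group_sizes_override=(90, 100))
        records = generate_herd(config)
        assert sum(r.treatment == PGOD for r in records) == 90
        assert sum(r.treatment == MOFT for r in records) == 100
        brands = [r.freeze_brand for r in records]
        assert brands == sorted(brands)
        for r in records:
            assert allocate_treatment(r.freeze_brand) == r.treatment

    def test_empty_herd(self):
        assert generate_herd(HerdConfig(n_per_farm=(0, 0, 0),
                                        natural_service_start_day=(None,) * 3)) == []

    def test_same_seed_is_bit_identical(self):
        a = generate_herd(HerdConfig(seed=11))
        b = generate_herd(HerdConfig(seed=11))
        assert a == b
        c = generate_herd(HerdConfig(seed=12))
        assert a != c

    @settings(max_examples=25, deadline=None)
    @given(
        sizes=st.lists(st.integers(0, 12), min_size=1, max_size=3),
        seed=st.integers(0, 2**31 - 1),
        bull=st.booleans(),
    )
    def test_records_satisfy_structural_invariants(self, sizes, seed, bull):
        ns = tuple(42 if bull else None for _ in sizes)
        config = HerdConfig(n_per_farm=tuple(sizes), seed=seed,
                            natural_service_start_day=ns)
        for r in generate_herd(config):
            assert all(0 <= d <= config.follow_up_days for d in r.service_days)
            assert list(r.service_days) == sorted(set(r.service_days))
            assert (r.conception_day is None) != (r.censor_day is None)
            assert r.cbsi_days >= 25
            if r.conception_day is not None:
                if r.conception_day in r.service_days:
                    assert r.conception_day == r.service_days[-1]
                else:  # natural service: after AI cut-over, no later services
                    assert bull and r.conception_day >= 42
                    assert all(s < r.conception_day for s in r.service_days)
            else:
                assert r.censor_day == config.follow_up_days


class TestBreedingProcess:
    def test_forced_fixed_time_conception(self):
        dyn = GroupDynamics(
            fixed_time_ai_day=10.25, early_estrus_window=(8, 10),
            p_early_estrus=0.0, conception_prob_first=1.0,
            p_nonconceiver=0.0, p_never_served=0.0,
        )
        rng = np.random.default_rng(0)
        for i in range(50):
            out = simulate_breeding_events(make_cow(cow_id=f"m{i}"), dyn, rng)
            assert out.service_days == (10.25,)
            assert out.conception_day == 10.25

    def test_rng_required(self):
        with pytest.raises(ValueError):
            simulate_breeding_events(make_cow(), GroupDynamics(), None)

    def test_prefilled_record_rejected(self):
        with pytest.raises(ValueError):
            simulate_breeding_events(
                make_cow(services=(3.0,), conception=3.0), GroupDynamics(),
                np.random.default_rng(0),
            )

    def test_first_service_conception_fraction_matches_binomial(self):
        """10,000 fixed-time cows: first-service conceptions per enrolled
        cow land within 3 binomial SEs of the configured rate."""
        dyn = BreedingDynamics().moft
        rng = np.random.default_rng(7)
        n = 10_000
        hits = 0
        for i in range(n):
            out = simulate_breeding_events(make_cow(cow_id=f"m{i}"), dyn, rng)
            if out.conception_day is not None and out.service_days and \
                    out.conception_day == out.service_days[0]:
                hits += 1
        p = dyn.conception_prob_first
        se = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se

    def test_invalid_dynamics_rejected(self):
        with pytest.raises(ValueError):
            GroupDynamics(p_detect_return=1.3)
        with pytest.raises(ValueError):
            GroupDynamics(cycle_length_mean=30.0)  # outside cycle bounds
        with pytest.raises(ValueError):
            # implied fertile-cow probability above 1
            GroupDynamics(conception_prob_first=0.9, p_nonconceiver=0.5)


class TestCalibrationRecovery:
    """Large-sample group statistics against the DP convolution oracle."""

    def test_group_rates_match_oracle(self, calibration_herd):
        from herdbudget import submission_rate, interval_in_calf_rate

        config, records = calibration_herd
        oracle = default_expectations(config)
        for group in (PGOD, MOFT):
            cows = [r for r in records if r.treatment == group]
            n = len(cows)
            exp = oracle[group]
            checks = {
                "submission_21": submission_rate(cows, 21.0),
                "in_calf_21": interval_in_calf_rate(cows, 21.0),
                "in_calf_42": interval_in_calf_rate(cows, 42.0),
                "in_calf_84": interval_in_calf_rate(cows, 84.0),
            }
            fsc = sum(
                1 for r in cows
                if r.pregnant and r.service_days
                and r.conception_day == r.service_days[0]
            ) / n
            checks["first_service_conception_per_cow"] = fsc
            for name, observed in checks.items():
                p = exp[name]
                se = np.sqrt(p * (1 - p) / n)
                assert abs(observed - p) < 3 * se, (group, name, observed, p)

    def test_higher_first_conception_never_lowers_early_in_calf(self):
        from herdbudget import interval_in_calf_rate
        from dataclasses import replace as dc_replace

        base = BreedingDynamics()
        boosted = BreedingDynamics(
            pgod=dc_replace(base.pgod, conception_prob_first=0.62),
            moft=base.moft,
        )
        config = HerdConfig(n_per_farm=(5000, 1436, 3564), seed=9)
        low = [r for r in generate_herd(config, base) if r.treatment == PGOD]
        high = [r for r in generate_herd(config, boosted) if r.treatment == PGOD]
        assert interval_in_calf_rate(high, 21.0) >= interval_in_calf_rate(low, 21.0)
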
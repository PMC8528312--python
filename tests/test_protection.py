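"""Protection-simulator tests against the exact-expectation oracle."""

import itertools
import math

import numpy as np
import pytest

from riboverlap.protection import (
    LofModel,
    OverlapMode,
    SimulationParams,
    draw_mutation,
    impact_continuous,
    lof_discrete,
    protection_dot_product,
    protection_exact,
    protection_grid,
    simulate_protection,
)


class TestDrawMutation:
    def test_extreme_fs(self):
        rng = np.random.default_rng(0)
        p1 = SimulationParams(fs=1.0)
        p0 = SimulationParams(fs=0.0)
        assert all(draw_mutation(p1, rng)[0] == "frameshift" for _ in range(50))
        assert all(draw_mutation(p0, rng)[0] == "substitution" for _ in range(50))

    def test_empirical_frameshift_fraction(self):
        rng = np.random.default_rng(1)
        params = SimulationParams(fs=0.3)
        draws = [draw_mutation(params, rng)[0] for _ in range(100_000)]
        frac = draws.count("frameshift") / len(draws)
        assert frac == pytest.approx(0.300, abs=0.005)

    def test_positions_uniform_over_gene(self):
        rng = np.random.default_rng(2)
        params = SimulationParams(upstream_len_nt=300)
        pos = [draw_mutation(params, rng)[1] for _ in range(20_000)]
        assert 0 <= min(pos) and max(pos) < 300
        assert np.mean(pos) == pytest.approx(149.5, abs=3)


class TestLofModels:
    def test_no_change_never_lof(self):
        rng = np.random.default_rng(0)
        assert not any(lof_discrete(0, 0.9, rng) for _ in range(100))

    def test_pe_one_always_lof(self):
        rng = np.random.default_rng(0)
        assert all(lof_discrete(3, 1.0, rng) for _ in range(100))

    def test_empirical_rate_matches_closed_form(self):
        rng = np.random.default_rng(3)
        hits = sum(lof_discrete(10, 0.1, rng) for _ in range(100_000))
        assert hits / 100_000 == pytest.approx(1 - 0.9**10, abs=0.01)

    @pytest.mark.parametrize("n,pe,expected", [(0, 0.5, 0.0), (1, 0.1, 0.1)])
    def test_impact_examples(self, n, pe, expected):
        assert impact_continuous(n, pe) == pytest.approx(expected)

    def test_impact_monotone(self):
        vals = [impact_continuous(n, 0.2) for n in range(10)]
        assert vals == sorted(vals)
        assert impact_continuous(5, 0.1) < impact_continuous(5, 0.3)


class TestSimulateProtection:
    def test_zero_overlap_gives_zero_protection(self):
        res = simulate_protection(
            SimulationParams(overlap_fraction=0.0, n_reps=20_000, seed=4)
        )
        assert res.protection == 0.0 and not res.undefined

    def test_full_overlap_all_frameshifts_fully_protects(self):
        res = simulate_protection(
            SimulationParams(fs=1.0, overlap_fraction=1.0, n_reps=20_000, seed=5)
        )
        assert res.protection == pytest.approx(1.0, abs=1e-6)

    def test_seed_reproducibility_bit_identical(self):
        params = SimulationParams(Pe=0.3, fs=0.3, overlap_fraction=0.5, n_reps=10_000, seed=6)
        a = simulate_protection(params)
        b = simulate_protection(params)
        assert a == b

    def test_protection_in_unit_interval_and_ci_contains_it(self):
        res = simulate_protection(
            SimulationParams(Pe=0.3, fs=0.3, overlap_fraction=0.5, n_reps=10_000, seed=7)
        )
        assert 0.0 <= res.ci95[0] <= res.protection <= res.ci95[1] <= 1.0
        assert res.protection == res.n_purged / res.n_upstream_lof

    def test_undefined_when_no_upstream_lof(self):
        res = simulate_protection(
            SimulationParams(Pe=0.0, fs=0.0, overlap_fraction=1.0, n_reps=100, seed=8)
        )
        assert res.undefined and math.isnan(res.protection)

    def test_monte_carlo_agrees_with_exact_expectation(self):
        """MC estimate within 3 binomial standard errors of the closed-form
        expectation over a 3x3x3 parameter grid, both overlap modes."""
        reps = 20_000
        seed = itertools.count(100)
        for pe, fs, ov, mode in itertools.product(
            (0.1, 0.3, 0.5),
            (0.1, 0.3, 0.7),
            (0.25, 0.5, 1.0),
            (OverlapMode.RIBOVERLAP, OverlapMode.PROTEIN_OVERLAP),
        ):
            params = SimulationParams(
                Pe=pe, fs=fs, overlap_fraction=ov, overlap_mode=mode,
                n_reps=reps, seed=next(seed),
            )
            mc = simulate_protection(params)
            exact = protection_exact(params)
            se = max(
                math.sqrt(exact * (1 - exact) / max(mc.n_upstream_lof, 1)), 1e-4
            )
            assert abs(mc.protection - exact) < 3 * se, (pe, fs, ov, mode)


class TestExactOracleProperties:
    def test_protection_nondecreasing_in_overlap(self):
        for pe, fs in itertools.product((0.1, 0.3, 0.5), (0.1, 0.3, 0.7)):
            vals = [
                protection_exact(
                    SimulationParams(Pe=pe, fs=fs, overlap_fraction=ov)
                )
                for ov in np.linspace(0.0, 1.0, 11)
            ]
            assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_protection_increasing_in_fs_decreasing_in_pe(self):
        base = dict(overlap_fraction=0.5)
        by_fs = [
            protection_exact(SimulationParams(Pe=0.3, fs=fs, **base))
            for fs in (0.1, 0.3, 0.7)
        ]
        assert by_fs == sorted(by_fs) and by_fs[0] < by_fs[-1]
        by_pe = [
            protection_exact(SimulationParams(Pe=pe, fs=0.3, **base))
            for pe in (0.1, 0.3, 0.5)
        ]
        assert by_pe == sorted(by_pe, reverse=True) and by_pe[0] > by_pe[-1]

    def test_protein_overlap_at_least_riboverlap(self):
        for pe, fs, ov in itertools.product(
            (0.1, 0.5), (0.1, 0.7), (0.25, 0.75, 1.0)
        ):
            rb = protection_exact(
                SimulationParams(Pe=pe, fs=fs, overlap_fraction=ov)
            )
            po = protection_exact(
                SimulationParams(
                    Pe=pe, fs=fs, overlap_fraction=ov,
                    overlap_mode=OverlapMode.PROTEIN_OVERLAP,
                )
            )
            assert po >= rb - 1e-12


class TestGridAndVariants:
    def test_grid_runs_and_is_deterministic(self):
        kwargs = dict(
            Pe_values=(0.1, 0.5),
            fs_values=(0.1, 0.7),
            overlap_values=(0.0, 0.5, 1.0),
            modes=(OverlapMode.RIBOVERLAP,),
            n_reps=2_000,
            seed=9,
        )
        a = protection_grid(**kwargs)
        b = protection_grid(**kwargs)
        assert a.equals(b)
        assert len(a) == 2 * 2 * 3
        assert ((a["protection"].fillna(0) >= 0) & (a["protection"].fillna(0) <= 1)).all()

    def test_continuous_model_and_dot_product_variant(self):
        params = SimulationParams(
            Pe=0.3, fs=0.7, overlap_fraction=1.0,
            lof_model=LofModel.CONTINUOUS, n_reps=20_000, seed=10,
        )
        res = simulate_protection(params)
        assert 0.0 <= res.protection <= 1.0
        dp = protection_dot_product(params)
        assert 0.0 <= dp <= 1.0

    def test_exact_requires_discrete_model(self):
        with pytest.raises(ValueError):
            protection_exact(
                SimulationParams(lof_model=LofModel.CONTINUOUS)
            )
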
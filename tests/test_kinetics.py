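"""Kinetic model: conservation laws, closed forms, symmetry, and the stochastic oracle."""

import dataclasses
import math

import numpy as np
import pytest

import lpptether as lp
from lpptether.kinetics import (
    KineticParams,
    PoolState,
    derivatives,
    fold_decrease,
    gillespie,
    hydrolyzed_fraction_estimate,
    initial_state,
    simulate,
    steady_tethering_rate,
)

GRID = np.arange(0.0, 61.0, 1.0)


class TestDerivatives:
    def test_no_free_lpp_no_hydrolysis_freezes_bound_pools(self, wt_params):
        params = dataclasses.replace(wt_params, k_h=0.0)
        state = PoolState(B_oo=100.0, B_nn=50.0, D_o=10.0, cohort=100.0)
        rates = derivatives(state, params)
        for pool in ("B_oo", "B_on", "B_no", "B_nn"):
            assert getattr(rates, pool) == 0.0

    def test_pure_hydrolysis_decay(self):
        """With k_t = 0 every bound pool decays exponentially at rate k_h."""
        params = KineticParams(k_t=0.0, k_h=0.02)
        init = PoolState(F_o=10.0, B_oo=1000.0, B_on=500.0, cohort=1000.0)
        traj = simulate(params, GRID, initial=init)
        for col, start in (("B_oo", 1000.0), ("B_on", 500.0)):
            expected = start * np.exp(-0.02 * GRID)
            np.testing.assert_allclose(traj.pools[col], expected, rtol=1e-6)

    def test_frozen_bound_pool_when_free_lpp_absent(self, mut_params):
        """No free Lpp and no hydrolysis: B_oo stays constant in absolute amount."""
        L0 = mut_params.lpp_copies
        init = PoolState(B_oo=L0 / 3, D_o=L0, cohort=L0 / 3)
        traj = simulate(mut_params, GRID, initial=init)
        np.testing.assert_allclose(traj.pools["B_oo"], L0 / 3, rtol=1e-7)

    def test_rejects_bad_age_tag(self, wt_params):
        with pytest.raises(ValueError):
            derivatives(initial_state(wt_params), wt_params, new_age="x")


class TestConservation:
    @pytest.mark.parametrize("genotype", ["wt", "mut"])
    def test_old_lpp_conserved_and_total_grows_exponentially(
        self, genotype, wt_params, mut_params
    ):
        params = wt_params if genotype == "wt" else mut_params
        traj = simulate(params, GRID)
        pools = traj.pools
        old_lpp = pools["F_o"] + pools["B_oo"] + pools["B_no"]
        np.testing.assert_allclose(old_lpp, params.lpp_copies, rtol=1e-7)
        total = old_lpp + pools["F_n"] + pools["B_on"] + pools["B_nn"]
        np.testing.assert_allclose(
            total, params.lpp_copies * np.exp(params.mu * GRID), rtol=1e-7
        )

    def test_steady_tethered_fraction_is_steady(self, wt_params):
        traj = simulate(wt_params, GRID)
        pools = traj.pools
        bound = pools[["B_oo", "B_on", "B_no", "B_nn"]].sum(axis=1)
        total = bound + pools["F_o"] + pools["F_n"]
        np.testing.assert_allclose(
            bound / total, wt_params.tethered_fraction, rtol=1e-7
        )


class TestDilutionLaw:
    def test_cohort_follows_closed_form(self, wt_params):
        """The t=0 bound cohort's relative abundance is 2^(-t/T) * e^(-k_h t)
        whenever the tethered fraction is steady (each genotype at its own
        steady-state tethering rate)."""
        for params in (wt_params, lp.yafk_mutant_params()):
            traj = simulate(params, GRID)
            expected = (
                100.0
                * np.exp(-params.k_h * GRID)
                / 2.0 ** (GRID / params.generation_time)
            )
            np.testing.assert_allclose(traj.quant["oo_cohort"], expected, rtol=1e-6)

    def test_monotone_in_hydrolysis_rate(self):
        """Raising k_h strictly lowers the old->old relative abundance at t > 0."""
        previous = None
        for k_h in (0.0, 0.005, 0.02):
            params = KineticParams(
                k_t=steady_tethering_rate(k_h=k_h), k_h=k_h
            )
            oo = simulate(params, GRID).quant["oo"].to_numpy()[1:]
            if previous is not None:
                assert np.all(oo < previous)
            previous = oo


class TestAgeSymmetry:
    def test_swapping_age_labels_mirrors_the_solution(self, wt_params):
        """Relabeling old<->new in the initial state and in the synthesis terms
        swaps the corresponding outputs exactly."""
        fwd = simulate(wt_params, GRID, new_age="n").pools
        L0, b0 = wt_params.lpp_copies, wt_params.tethered_fraction
        mirrored = PoolState(
            F_n=(1 - b0) * L0, B_nn=b0 * L0, D_n=wt_params.donor_ratio * L0
        )
        swapped = simulate(wt_params, GRID, initial=mirrored, new_age="o").pools
        pairs = [("F_o", "F_n"), ("B_oo", "B_nn"), ("B_on", "B_no"), ("D_o", "D_n")]
        for a, b in pairs:
            np.testing.assert_allclose(fwd[a], swapped[b], rtol=1e-6, atol=1e-6 * L0)
            np.testing.assert_allclose(fwd[b], swapped[a], rtol=1e-6, atol=1e-6 * L0)


class TestFoldDecrease:
    def test_constant_quantity_gives_unity(self):
        # frozen network (no tethering, no hydrolysis): old->old stays at 100 %
        params = KineticParams(k_t=0.0, k_h=0.0)
        L0 = params.lpp_copies
        init = PoolState(B_oo=L0 / 3, F_o=2 * L0 / 3, D_o=L0, cohort=L0 / 3)
        traj = simulate(params, GRID, initial=init)
        assert fold_decrease(traj, "oo") == pytest.approx(1.0, rel=1e-9)

    def test_pure_dilution_halves_cohort(self):
        traj = simulate(lp.yafk_mutant_params(), GRID)
        assert fold_decrease(traj, "oo_cohort") == pytest.approx(2.0, rel=1e-6)

    def test_dilution_times_half_survival_gives_fourfold(self, wt_params):
        """k_h = ln2/T means half the bonds survive one generation, so the
        cohort decays 2 (dilution) x 2 (hydrolysis) = 4-fold."""
        assert wt_params.k_h == pytest.approx(math.log(2) / 60.0)
        traj = simulate(wt_params, GRID)
        assert fold_decrease(traj, "oo_cohort") == pytest.approx(4.0, rel=1e-6)

    def test_unknown_quantity(self, wt_params):
        with pytest.raises(KeyError):
            fold_decrease(simulate(wt_params, GRID), "nope")


class TestHydrolyzedFractionEstimate:
    @pytest.mark.parametrize(
        "fold_wt, fold_mut, expected", [(4, 2, 50.0), (2, 2, 0.0), (8, 2, 75.0)]
    )
    def test_formula(self, fold_wt, fold_mut, expected):
        assert hydrolyzed_fraction_estimate(fold_wt, fold_mut) == pytest.approx(expected)

    def test_inconsistent_inputs(self):
        with pytest.raises(ValueError):
            hydrolyzed_fraction_estimate(2.0, 4.0)


class TestGillespieOracle:
    def test_fixed_seed_is_bit_identical(self, wt_params):
        grid = np.array([0.0, 20.0, 40.0, 60.0])
        a = gillespie(wt_params, grid, n_molecules=2000, seed=42)
        b = gillespie(wt_params, grid, n_molecules=2000, seed=42)
        np.testing.assert_array_equal(a.states, b.states)

    def test_dead_system_stays_constant(self):
        """No tethering, no hydrolysis, negligible growth: nothing happens."""
        params = KineticParams(generation_time=1e12, k_t=0.0, k_h=0.0)
        grid = np.array([0.0, 30.0, 60.0])
        traj = gillespie(params, grid, n_molecules=5000, seed=1)
        np.testing.assert_array_equal(traj.states[0], traj.states[-1])

    def test_small_instance_tracks_ode(self, wt_params):
        """Mean of a few stochastic runs stays within Monte-Carlo error of the
        deterministic relative abundances (the full-scale comparison lives in
        the acceptance suite)."""
        grid = np.array([0.0, 30.0, 60.0])
        runs = np.array(
            [
                gillespie(wt_params, grid, n_molecules=5000, seed=s)
                .quant[["nn", "oo", "on", "no"]]
                .to_numpy()
                for s in range(20)
            ]
        )
        ode = simulate(wt_params, grid).quant[["nn", "oo", "on", "no"]].to_numpy()
        se = runs.std(axis=0, ddof=1) / np.sqrt(len(runs))
        diff = np.abs(runs.mean(axis=0) - ode)
        mask = se > 1e-12  # skip deterministic cells (t = 0)
        assert np.all(diff[mask] <= 4.0 * se[mask])
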
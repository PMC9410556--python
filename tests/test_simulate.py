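"""Tests for the stochastic stepper: Langevin update, growth/division,
commitment, mutant overlays and whole-run invariants."""

import numpy as np
import pytest

import hetpattern as hp
from hetpattern.model_core import SPECIES

from conftest import filament_from_pattern, random_filament


# ---------------------------------------------------------------------------
# mutant overlays


class TestApplyMutant:
    def test_wild_type_is_identity(self, wt_params):
        assert hp.apply_mutant(wt_params, hp.MutantSpec()) == wt_params

    def test_patS_knockout_retains_ten_percent(self, wt_params):
        out = hp.apply_mutant(wt_params, hp.MUTANTS["dpatS"])
        assert out.rho_S == pytest.approx(0.1 * wt_params.rho_S)

    def test_hetF_knockout_kills_activation(self, wt_params):
        out = hp.apply_mutant(wt_params, hp.MUTANTS["dhetF"])
        assert out.beta_F == 0.0
        assert hp.hetf_equilibrium(out.beta_F, out.alpha_F) == 0.0
        assert out.F_R == 0.0  # F_R proportional to F_eq

    def test_original_untouched(self, wt_params):
        before = wt_params.to_dict()
        hp.apply_mutant(wt_params, hp.MUTANTS["dpatAdhetN"])
        assert wt_params.to_dict() == before

    def test_composition(self):
        double = hp.MUTANTS["dpatA"].combine(hp.MUTANTS["dhetN"])
        assert double == hp.MUTANTS["dpatAdhetN"]

    def test_no_border_leak_overlay(self, wt_params):
        mut = hp.mutant_by_name("dpatA", no_border_leak=True)
        out = hp.apply_mutant(wt_params, mut)
        assert out.d_border == 0.0
        assert out.rho_A == 0.0

    def test_unknown_name(self):
        with pytest.raises(KeyError):
            hp.mutant_by_name("dfoo")


# ---------------------------------------------------------------------------
# Langevin stepping


class TestLangevinStep:
    def test_noiseless_step_equals_euler(self, wt_params, rng):
        fil = random_filament(rng, n=6, n_het=1)
        noise = hp.NoiseSettings(omega_phi=0.0, omega_lambda=0.0, seed=0)
        out = hp.langevin_step(fil, wt_params, noise, 0.01, np.random.default_rng(0))
        expected = fil.conc + hp.compute_drift(fil, wt_params).drift * 0.01
        np.testing.assert_allclose(out.conc, np.maximum(expected, 0.0))
        assert out.time == pytest.approx(fil.time + 0.01)

    def test_same_seed_bit_identical(self, wt_params, rng):
        fil = random_filament(rng, n=6, n_het=1)
        noise = hp.NoiseSettings(seed=7)
        a = hp.langevin_step(fil, wt_params, noise, 0.01, np.random.default_rng(7))
        b = hp.langevin_step(fil, wt_params, noise, 0.01, np.random.default_rng(7))
        assert np.array_equal(a.conc, b.conc)

    def test_input_not_mutated(self, wt_params, rng):
        fil = random_filament(rng, n=4, n_het=0)
        before = fil.conc.copy()
        hp.langevin_step(fil, wt_params, hp.NoiseSettings(seed=1), 0.01, np.random.default_rng(1))
        np.testing.assert_array_equal(fil.conc, before)

    def test_concentrations_never_negative(self, wt_params, rng):
        fil = random_filament(rng, n=10, n_het=2)
        g = np.random.default_rng(3)
        noise = hp.NoiseSettings(omega_phi=1.0, omega_lambda=0.0, seed=3)
        for _ in range(200):
            fil = hp.langevin_step(fil, wt_params, noise, 0.05, g)
            assert np.all(fil.conc >= 0.0)

    def test_increment_variance_matches_langevin_amplitude(self, wt_params):
        """One-step HetR increments across many identical uncoupled cells have
        variance Omega_phi (P + |D|) dt (Monte-Carlo vs the stated formula)."""
        n = 100_000
        state = np.tile(np.array([[0.8, 0.4, 0.6, 0.1, 0.3, 0.2]]), (n, 1))
        fil = hp.FilamentState(
            conc=state.copy(),
            size=np.full(n, 3.0),
            is_heterocyst=np.zeros(n, dtype=bool),
            T_R_cell=np.ones(n),
            M_R_cell=np.full(n, 12.0),
            M_Lambda_cell=np.full(n, 4.0),
            commit_integral=np.zeros(n),
            commit_clock=np.zeros(n),
        )
        dt = 0.01
        omega = 0.08
        noise = hp.NoiseSettings(omega_phi=omega, omega_lambda=0.0, seed=11)
        out = hp.langevin_step(fil, wt_params, noise, dt, np.random.default_rng(11))
        # R dynamics are cell-local, so every interior cell is an i.i.d. sample
        inc = out.conc[1:-1, 0] - state[1:-1, 0]
        d = hp.compute_drift(fil, wt_params)
        expected_var = omega * d.noise_intensity[5, 0] * dt
        sample_var = inc.var(ddof=1)
        se = expected_var * np.sqrt(2.0 / (n - 3))  # SE of a Gaussian variance estimate
        assert abs(sample_var - expected_var) < 3 * se

    def test_nonfinite_state_reported_with_location(self, wt_params, rng):
        fil = random_filament(rng, n=3, n_het=0)
        fil.conc[1, 4] = np.nan
        # the NaN spreads to the neighbour through transport before detection;
        # the report names the first affected cell and the species
        with pytest.raises(hp.SimulationError, match=r"cell \d+, species I"):
            hp.langevin_step(fil, wt_params, hp.NoiseSettings(seed=0), 0.01, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# growth and division


class TestGrowAndDivide:
    def test_division_halves_size_and_copies_concentrations(self, wt_params, rng):
        fil = random_filament(rng, n=3, n_het=0)
        fil.size[:] = [3.0, 4.2, 3.0]
        fil.M_Lambda_cell[:] = [4.0, 4.0, 4.0]
        parent_conc = fil.conc[1].copy()
        noise = hp.NoiseSettings(omega_phi=0.0, omega_lambda=0.0, seed=0)
        out = hp.grow_and_divide(fil, wt_params, noise, 0.01, np.random.default_rng(0))
        assert out.n_cells == 4
        lam_dt = wt_params.lam * 0.01
        assert out.size[1] == pytest.approx((4.2 + lam_dt) / 2)
        assert out.size[2] == pytest.approx((4.2 + lam_dt) / 2)
        np.testing.assert_allclose(out.conc[1], parent_conc)
        np.testing.assert_allclose(out.conc[2], parent_conc)

    def test_total_length_conserved_across_division(self, wt_params, rng):
        fil = random_filament(rng, n=6, n_het=1)
        fil.size[:] = 3.99
        fil.M_Lambda_cell[:] = 4.0
        noise = hp.NoiseSettings(omega_phi=0.0, omega_lambda=0.0, seed=0)
        out = hp.grow_and_divide(fil, wt_params, noise, 0.5, np.random.default_rng(0))
        grown = fil.total_length + fil.n_cells * wt_params.lam * 0.5
        # heterocyst capped at its max size; account for its lost growth
        cap_loss = max(0.0, 3.99 + wt_params.lam * 0.5 - 4.0)
        assert out.total_length == pytest.approx(grown - cap_loss)
        assert out.n_cells == 11  # five vegetative divisions, heterocyst intact

    def test_heterocyst_never_divides_and_stops_growing(self, wt_params):
        fil = filament_from_pattern("H")
        fil.size[:] = 4.0
        fil.M_Lambda_cell[:] = 4.0
        noise = hp.NoiseSettings(omega_phi=0.0, omega_lambda=0.0, seed=0)
        g = np.random.default_rng(0)
        for _ in range(100):
            fil = hp.grow_and_divide(fil, wt_params, noise, 0.5, g)
        assert fil.n_cells == 1
        assert fil.size[0] == pytest.approx(4.0)

    def test_noiseless_division_time(self, wt_params):
        # Lambda0=2, lam=0.08, M=4: division at t = 25 h (+- one step)
        fil = filament_from_pattern("V")
        fil.size[:] = 2.0
        fil.M_Lambda_cell[:] = 4.0
        noise = hp.NoiseSettings(omega_phi=0.0, omega_lambda=0.0, seed=0)
        g = np.random.default_rng(0)
        dt = 0.01
        t = 0.0
        while fil.n_cells == 1:
            fil = hp.grow_and_divide(fil, wt_params, noise, dt, g)
            t += dt
            assert t < 30.0
        assert t == pytest.approx(25.0, abs=2 * dt)

    def test_daughters_draw_fresh_thresholds(self, wt_params, rng):
        fil = random_filament(rng, n=1, n_het=0)
        fil.size[:] = 4.5
        fil.M_Lambda_cell[:] = 4.0
        fil.commit_integral[:] = 3.0
        fil.commit_clock[:] = 2.0
        noise = hp.NoiseSettings(omega_phi=0.08, omega_lambda=0.05, seed=5)
        out = hp.grow_and_divide(fil, wt_params, noise, 0.01, np.random.default_rng(5))
        assert out.n_cells == 2
        assert np.all(out.commit_integral == 0.0)
        assert np.all(out.commit_clock == 0.0)
        assert out.T_R_cell[0] != out.T_R_cell[1]  # independent Gaussian draws
        assert np.all(out.T_R_cell > 0)


# ---------------------------------------------------------------------------
# commitment


class TestCommitment:
    def run_held(self, wt_params, R, dt=0.01, t_max=20.0):
        """Hold a cell's HetR at R and advance the commitment rule."""
        cell = hp.CellState(R=R, T_R_cell=wt_params.T_R, M_R_cell=wt_params.M_R)
        t = 0.0
        while not cell.is_heterocyst and t < t_max:
            cell = hp.update_commitment(cell, wt_params, dt)
            t += dt
        return cell, t

    def test_differentiation_at_threshold_takes_twelve_hours(self, wt_params):
        cell, t = self.run_held(wt_params, R=wt_params.T_R)
        assert cell.is_heterocyst
        assert t == pytest.approx(12.0, abs=0.011)

    def test_high_hetr_waits_for_minimum_time(self, wt_params):
        # at R = 3 T_R the integral fills in 4 h but T_min = 5 h gates it
        cell, t = self.run_held(wt_params, R=3 * wt_params.T_R)
        assert cell.is_heterocyst
        assert t == pytest.approx(wt_params.T_min, abs=0.011)

    def test_dip_below_threshold_resets_integral(self, wt_params):
        cell = hp.CellState(R=2.0, T_R_cell=1.0, M_R_cell=12.0)
        for _ in range(100):
            cell = hp.update_commitment(cell, wt_params, 0.01)
        assert cell.commit_integral > 0
        cell.R = 0.5
        cell = hp.update_commitment(cell, wt_params, 0.01)
        assert cell.commit_integral == 0.0
        assert cell.commit_clock == 0.0

    def test_heterocyst_rejected(self, wt_params):
        cell = hp.CellState(is_heterocyst=True)
        with pytest.raises(ValueError):
            hp.update_commitment(cell, wt_params, 0.01)


# ---------------------------------------------------------------------------
# whole simulations


@pytest.fixture(scope="module")
def short_wt_run(wt_params):
    cfg = hp.SimulationConfig(dt=0.02, t_end=36.0, record_every=2.0, n_initial_cells=20)
    return hp.run_simulation(cfg, wt_params, noise=hp.NoiseSettings(seed=42))


class TestRunSimulation:
    def test_reproducible_from_seed(self, wt_params):
        cfg = hp.SimulationConfig(dt=0.05, t_end=5.0, record_every=1.0, n_initial_cells=8)
        a = hp.run_simulation(cfg, wt_params, noise=hp.NoiseSettings(seed=9))
        b = hp.run_simulation(cfg, wt_params, noise=hp.NoiseSettings(seed=9))
        for fa, fb in zip(a.snapshots, b.snapshots):
            assert np.array_equal(fa.conc, fb.conc)
            assert np.array_equal(fa.size, fb.size)

    def test_counts_monotone_and_concentrations_nonnegative(self, short_wt_run):
        cells = [s.n_cells for s in short_wt_run.snapshots]
        hets = [s.n_heterocysts for s in short_wt_run.snapshots]
        assert all(b >= a for a, b in zip(cells, cells[1:]))
        assert all(b >= a for a, b in zip(hets, hets[1:]))
        assert all(np.all(s.conc >= 0) for s in short_wt_run.snapshots)

    def test_record_times(self, short_wt_run):
        assert short_wt_run.times[0] == 0.0
        assert short_wt_run.times[-1] == pytest.approx(36.0)
        np.testing.assert_allclose(np.diff(short_wt_run.times), 2.0)

    def test_dataframe_export(self, short_wt_run):
        df = short_wt_run.to_dataframe()
        assert list(df.columns) == ["time_h", "cell_index", *SPECIES, "size_um", "is_heterocyst"]
        assert len(df) == sum(s.n_cells for s in short_wt_run.snapshots)

    def test_noiseless_hetn_decay_matches_closed_form(self, wt_params):
        """A vegetative cell's HetN decays with loss rate 2 c_N + alpha_N;
        the Euler integration must track the closed form."""
        n0 = 1.5
        fil = filament_from_pattern("V")
        fil.conc[0, 3] = n0
        noise = hp.NoiseSettings(omega_phi=0.0, omega_lambda=0.0, seed=0)
        g = np.random.default_rng(0)
        dt = 0.002
        for _ in range(int(5.0 / dt)):
            fil = hp.langevin_step(fil, wt_params, noise, dt, g)
        rate = 2 * wt_params.c_N + wt_params.alpha_N
        expected = hp.isolated_species_decay(n0, rate, 5.0)
        assert fil.conc[0, 3] == pytest.approx(expected, rel=5e-3)

    def test_noiseless_first_order_convergence(self, wt_params):
        """Halving dt roughly halves the error of the explicit Euler scheme."""
        noise = hp.NoiseSettings(omega_phi=0.0, omega_lambda=0.0, seed=0)
        cfg0 = hp.SimulationConfig(dt=0.08, t_end=8.0, record_every=8.0, n_initial_cells=5,
                                   initial_size_policy="half")
        finals = {}
        for dt in (0.08, 0.04, 0.02):
            cfg = hp.SimulationConfig(dt=dt, t_end=8.0, record_every=8.0, n_initial_cells=5,
                                      initial_size_policy="half")
            finals[dt] = hp.run_simulation(cfg, wt_params, noise=noise).final.conc
        e1 = np.abs(finals[0.08] - finals[0.02]).max()
        e2 = np.abs(finals[0.04] - finals[0.02]).max()
        assert e2 < 0.75 * e1  # error shrinks with dt

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            hp.SimulationConfig(dt=0.5, record_every=0.1)
        with pytest.raises(ValueError):
            hp.SimulationConfig(dt=0.03, record_every=1.0)  # not a divisor
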
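"""Whole-cell model: membrane equation conventions, conservation, resting
stability, solver accuracy and the I_Ktof dependence of the AP."""

import numpy as np
import pytest

from mouseap import cell, metrics
from mouseap.drugs import DrugSpec


@pytest.fixture(scope="module")
def rest_endo():
    return cell.rest_state("endocardial")


class TestStateDerivative:
    def test_rest_is_stationary(self, rest_endo):
        dy = cell.state_derivative(rest_endo)
        assert np.abs(dy).max() < 1e-4

    def test_occupancy_subderivatives_conserve(self, rest_endo):
        rng = np.random.default_rng(3)
        y = rest_endo.copy()
        # perturb the Markov K+ blocks on the simplex
        for name, block in cell.occupancy_blocks(y).items():
            block[:] = rng.dirichlet(np.ones(len(block)))
        dy = cell.state_derivative(y, stimulus=0.0)
        for name, block in cell.occupancy_blocks(dy).items():
            assert abs(block.sum()) < 1e-12

    def test_stimulus_is_depolarizing(self, rest_endo):
        dv_rest = cell.state_derivative(rest_endo)[cell.IV]
        dv_stim = cell.state_derivative(rest_endo, stimulus=60.0)[cell.IV]
        assert dv_stim - dv_rest == pytest.approx(60.0, rel=1e-9)
        assert dv_stim > 55.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            cell.state_derivative(np.zeros(10))


class TestRestingStability:
    def test_ten_second_drift_below_half_millivolt(self, rest_endo):
        y = rest_endo.copy()
        p = cell.pack_params("endocardial")
        cell.DEFAULT_SOLVER.advance(y, 10000.0, 0.0, p)
        assert abs(y[cell.IV] - rest_endo[cell.IV]) < 0.5
        cell.check_state(y, tol=1e-5)


class TestPacedAP:
    def test_physiological_mouse_ap(self, endo_1hz):
        aset = metrics.apd_set(endo_1hz.trace)
        assert aset.peak_V > 0.0                 # overshoot
        assert aset.dvdt_max > 50.0
        assert aset.resting_V_reference < -75.0
        assert aset.apd30 < aset.apd50 < aset.apd75 < aset.apd90 < 60.0

    def test_epicardial_shorter_than_endocardial(self, endo_1hz, epi_1hz):
        a_endo = metrics.apd_set(endo_1hz.trace)
        a_epi = metrics.apd_set(epi_1hz.trace)
        for lev in (30, 50, 75, 90):
            assert a_epi.level(lev) < a_endo.level(lev)

    def test_occupancy_conservation_after_pacing(self, endo_1hz):
        cell.check_state(endo_1hz.state, tol=1e-5)

    def test_removing_iktof_prolongs_apd50_both_variants(
        self, endo_1hz, epi_1hz, endo_1hz_full_block, epi_1hz_full_block
    ):
        assert metrics.apd(endo_1hz_full_block.trace, 50) > \
            metrics.apd(endo_1hz.trace, 50)
        assert metrics.apd(epi_1hz_full_block.trace, 50) > \
            metrics.apd(epi_1hz.trace, 50)

    def test_zero_dose_drug_build_matches_drug_free(self):
        res_free = cell.run_to_steady_pacing("endocardial", bcl=1000.0, n_beats=3)
        res_zero = cell.run_to_steady_pacing(
            "endocardial", bcl=1000.0, n_beats=3,
            drug=DrugSpec.drug_o(0.0),
        )
        v0, v1 = res_free.trace.V_mV, res_zero.trace.V_mV
        assert np.abs(v0 - v1).max() <= 1e-10 * np.abs(v0).max()

    def test_beat_to_beat_memory_decays_at_long_bcl(self):
        """Successive beats from rest converge: the SR Ca2+ load carries
        memory over several beats, but the beat-to-beat APD90 change must
        shrink monotonically toward the paced steady state."""
        apds = [
            metrics.apd(
                cell.run_to_steady_pacing("endocardial", bcl=5000.0, n_beats=n).trace,
                90,
            )
            for n in (1, 2, 3, 4)
        ]
        deltas = np.abs(np.diff(apds))
        assert deltas[0] > deltas[1] > deltas[2]

    def test_n_beats_validation(self):
        with pytest.raises(ValueError):
            cell.run_to_steady_pacing("endocardial", n_beats=0)


class TestSolver:
    def test_fixed_step_convergence_order(self, rest_endo):
        """Observed order of the integrator on a short stimulated segment.

        Forcing fixed steps (error control disabled via a huge atol), the
        propagated solution should converge at 4th-5th order.
        """
        p = cell.pack_params("endocardial")

        def run(h):
            y = rest_endo.copy()
            solver = cell.Solver(rtol=0.0, atol=1e9, hmax=h)
            solver.advance(y, 2.0, 60.0, p, h0=h)
            return y[cell.IV]

        ref = run(0.0005)
        errs = [abs(run(h) - ref) for h in (0.016, 0.008, 0.004)]
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert orders.mean() > 3.5

    def test_apd_insensitive_to_tolerance_refinement(self):
        tight = cell.Solver(rtol=1e-7, atol=1e-9)
        r1 = cell.run_to_steady_pacing("endocardial", bcl=1000.0, n_beats=10)
        r2 = cell.run_to_steady_pacing("endocardial", bcl=1000.0, n_beats=10,
                                       solver=tight)
        a1 = metrics.apd(r1.trace, 90)
        a2 = metrics.apd(r2.trace, 90)
        assert abs(a1 - a2) / a1 < 1e-3

    def test_output_sampling_halving_preserves_apd(self, rest_endo):
        p = cell.pack_params("endocardial")
        traces = {}
        for dt in (0.05, 0.025):
            y = rest_endo.copy()
            times = np.concatenate([
                np.arange(0.0, 60.0, dt), np.arange(60.0, 1000.0, 0.5)
            ])
            traces[dt] = cell.record_interval(
                y, p, times, cell.STIM_AMP, cell.STIM_DUR
            )
        a1 = metrics.apd(traces[0.05], 90)
        a2 = metrics.apd(traces[0.025], 90)
        assert a2 == pytest.approx(a1, abs=0.1)
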
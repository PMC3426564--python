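"""Simulator physics: schedule, closed forms, conservation, determinism."""

import numpy as np
import pytest

from gapcircuit.model import (CircuitParameters, Genotype, NucleusGrid,
                              StateVector, default_bounds)
from gapcircuit.simulate import (Schedule, TIME_CLASSES, run, run_pair)
from gapcircuit.synthetic import make_external_inputs


def degenerate_params(R=0.0, D=0.0, lam=0.1):
    return CircuitParameters(T=np.zeros((4, 4)), E=np.zeros((4, 3)),
                             R=np.full(4, R), D=np.full(4, D),
                             lam=np.asarray(lam, float) * np.ones(4))


@pytest.fixture(scope="module")
def external():
    return make_external_inputs()


def random_init(rng, grid):
    return StateVector(rng.uniform(0, 200, size=(4, grid.n)), 0.0)


class TestSchedule:
    def test_printed_times(self):
        s = Schedule()
        assert s.interphase13_end == 16.0
        assert s.division_time == 21.1
        assert s.c13_midpoint == pytest.approx(10.55)
        assert s.t_end == pytest.approx(71.1)
        mids = s.class_midpoints
        assert mids.shape == (8,)
        assert mids[0] == pytest.approx(21.1 + 0.5 * 6.25)
        assert np.allclose(np.diff(mids), 6.25)

    def test_comparison_count(self):
        assert Schedule().comparison_times.shape == (9,)
        assert len(TIME_CLASSES) == 9


class TestRun:
    def test_exponential_decay_closed_form(self, external, rng):
        lam = np.array([0.05, 0.08, 0.10, 0.12])
        params = degenerate_params(lam=1.0)
        params.lam = lam
        grid = NucleusGrid.c13()
        init = random_init(rng, grid)
        traj = run(params, Genotype.wildtype(), external, init,
                   rtol=1e-9, atol=1e-12)
        for tc, t in zip(TIME_CLASSES, traj.times):
            expected = init.v * np.exp(-lam[:, None] * t)
            if tc != "C13":
                expected = np.repeat(expected, 2, axis=1)
            got = traj.state(tc)
            assert np.allclose(got, expected, rtol=1e-6), tc

    def test_nine_samples_and_grid_doubling(self, truth, truth_pair):
        wt, mut = truth_pair
        for traj in (wt, mut):
            assert len(traj.states) == 9
            assert traj.states[0].shape == (4, 23)
            for s in traj.states[1:]:
                assert s.shape == (4, 46)

    def test_identity_genotype_bitwise(self, truth, truth_init, external):
        a = run(truth.params, Genotype.wildtype(), truth.external,
                truth_init)
        ones = Genotype("custom", np.ones(4))
        b = run(truth.params, ones, truth.external, truth_init)
        for sa, sb in zip(a.states, b.states):
            assert np.array_equal(sa, sb)

    def test_determinism(self, truth, truth_init):
        a = run(truth.params, Genotype.wildtype(), truth.external,
                truth_init)
        b = run(truth.params, Genotype.wildtype(), truth.external,
                truth_init)
        for sa, sb in zip(a.states, b.states):
            assert np.array_equal(sa, sb)

    def test_mass_conservation_transport_only(self, external, rng):
        params = degenerate_params(R=0.0, D=0.25, lam=0.0)
        grid = NucleusGrid.c13()
        init = random_init(rng, grid)
        traj = run(params, Genotype.wildtype(), external, init)
        total0 = init.v.sum(axis=1)
        c13 = traj.state("C13").sum(axis=1)
        assert np.allclose(c13, total0, rtol=1e-8)
        for tc in TIME_CLASSES[1:]:
            # division duplicates every nucleus: total mass doubles once
            assert np.allclose(traj.state(tc).sum(axis=1), 2 * total0,
                               rtol=1e-8), tc

    def test_nonnegativity_random_circuits(self, external):
        rng = np.random.default_rng(99)
        lo, hi = default_bounds()
        grid = NucleusGrid.c13()
        for _ in range(100):
            vec = lo + rng.random(40) * (hi - lo)
            params = CircuitParameters.from_vector(vec)
            init = StateVector(rng.uniform(0, 150, (4, 23)), 0.0)
            traj = run(params, Genotype.wildtype(), external, init,
                       method="rk4", rk4_dt=0.5)
            for s in traj.states:
                assert s.min() >= -1e-9

    def test_against_scipy_reference(self, truth, truth_init, external):
        """Independent oracle: integrate the same schedule with
        scipy.solve_ivp over the NumPy RHS and compare at T8."""
        from scipy.integrate import solve_ivp
        from gapcircuit.model import interphase_rhs, mitosis_rhs, divide
        params, ext = truth.params, truth.external
        wt = Genotype.wildtype()
        grid13 = NucleusGrid.c13()

        def rhs_factory(fun, grid):
            def f(t, y):
                state = StateVector(y.reshape(4, -1), t)
                if fun is interphase_rhs:
                    return interphase_rhs(params, wt, state, ext, t,
                                          grid).ravel()
                return mitosis_rhs(params, wt, state, t).ravel()
            return f

        y = truth_init.v.ravel()
        sol = solve_ivp(rhs_factory(interphase_rhs, grid13), (0, 16.0), y,
                        rtol=1e-9, atol=1e-10, dense_output=False)
        sol = solve_ivp(rhs_factory(mitosis_rhs, grid13), (16.0, 21.1),
                        sol.y[:, -1], rtol=1e-9, atol=1e-10)
        state, grid14 = divide(StateVector(sol.y[:, -1].reshape(4, 23),
                                           21.1), grid13)
        sol = solve_ivp(rhs_factory(interphase_rhs, grid14),
                        (21.1, 21.1 + 7.5 * 6.25), state.v.ravel(),
                        rtol=1e-9, atol=1e-10)
        reference_t8 = sol.y[:, -1].reshape(4, 46)

        traj = run(params, wt, ext, truth_init)
        assert np.allclose(traj.state("T8"), reference_t8, atol=2e-3)


class TestRunPair:
    def test_kr_decoupled(self, external, rng):
        params = degenerate_params(R=8.0, D=0.1, lam=0.08)
        params.T = np.diag([0.01, 0.01, 0.01, 0.01]).astype(float)
        params.T[:, 1] = 0.0                 # no gene listens to Kr
        params.E = np.full((4, 3), 0.01)
        grid = NucleusGrid.c13()
        init = StateVector(np.zeros((4, 23)), 0.0)
        wt, mut = run_pair(params, external, init)
        for a in (0, 2, 3):
            for swt, smut in zip(wt.states, mut.states):
                assert np.allclose(swt[a], smut[a], atol=1e-12)

    def test_mutant_kr_channel_zero(self, truth_pair):
        _, mut = truth_pair
        for s in mut.states:
            assert np.all(s[1] == 0.0)

    def test_loss_of_repression_raises_target(self, external):
        """Two-gene hand-built instance: Kr strongly represses gt, so the
        Kr-null trajectory has gt levels >= wild type everywhere in the
        repressed region."""
        params = degenerate_params(R=10.0, D=0.05, lam=0.08)
        params.E[1, 0] = 0.05                # bcd drives Kr
        params.T[2, 1] = -0.08               # Kr represses gt strongly
        params.E[2, 1] = 0.02                # cad drives gt
        grid = NucleusGrid.c13()
        init = StateVector(np.zeros((4, 23)), 0.0)
        wt, mut = run_pair(params, external, init)
        for swt, smut in zip(wt.states[1:], mut.states[1:]):
            assert np.all(smut[2] >= swt[2] - 1e-9)
        assert mut.state("T8")[2].max() > wt.state("T8")[2].max()

    def test_double_mutant_genotype(self, truth, truth_init):
        wt, double = run_pair(truth.params, truth.external, truth_init,
                              mutant=Genotype.null("Kr", "kni"))
        for s in double.states:
            assert np.all(s[1] == 0.0) and np.all(s[3] == 0.0)


class TestWriter:
    def test_to_frame_layout(self, truth_pair):
        wt, _ = truth_pair
        df = wt.to_frame()
        assert list(df.columns) == ["genotype", "gene", "time_class",
                                    "position_EL", "level"]
        assert len(df) == 4 * (23 + 8 * 46)
        assert set(df.time_class.unique()) == set(TIME_CLASSES)
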
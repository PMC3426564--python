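"""Unit tests for the circuit data model and right-hand-side mathematics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gapcircuit.model import (CircuitParameters, CircuitError,
                              ExternalInputSeries, Genotype, NucleusGrid,
                              StateVector, default_bounds, divide, g,
                              interphase_rhs, mitosis_rhs, parameter_labels,
                              regulation_input)
from gapcircuit.synthetic import make_external_inputs


def make_params(T=None, E=None, R=None, D=None, lam=None, h=None):
    z4 = np.zeros((4, 4))
    z3 = np.zeros((4, 3))
    return CircuitParameters(
        T=z4 if T is None else T, E=z3 if E is None else E,
        R=np.full(4, 10.0) if R is None else R,
        D=np.zeros(4) if D is None else D,
        lam=np.full(4, 0.08) if lam is None else lam, h=h)


class TestSigmoid:
    def test_symmetry_point(self):
        assert g(0.0) == 0.5

    @pytest.mark.parametrize("u, expected", [
        (3.0, 0.5 * (3 / np.sqrt(10)) + 0.5),        # 0.9743416...
        (-3.5, 0.5 * (1 - 3.5 / np.sqrt(1 + 3.5**2))),  # 0.0192381...
    ])
    def test_closed_form(self, u, expected):
        assert g(u) == pytest.approx(expected, abs=1e-12)
        # frozen values of the closed form
        if u == 3.0:
            assert g(u) == pytest.approx(0.97434, abs=5e-6)
        else:
            assert g(u) == pytest.approx(0.0192381, abs=5e-7)

    @given(st.floats(-1e6, 1e6, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_antisymmetry(self, u):
        assert g(u) + g(-u) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_and_bounded(self, rng):
        u = np.sort(rng.normal(scale=10, size=1000))
        y = g(u)
        assert np.all(np.diff(y) >= 0)
        assert np.all((y > 0) & (y < 1))

    def test_rejects_non_finite(self):
        with pytest.raises(CircuitError):
            g(np.nan)


class TestRegulationInput:
    def setup_method(self):
        self.grid = NucleusGrid.c13()
        self.external = make_external_inputs()
        self.wt = Genotype.wildtype()

    def _zero_external(self):
        ext = make_external_inputs()
        return ExternalInputSeries(ext.times, ext.positions,
                                   np.zeros_like(ext.values))

    def test_threshold_only(self):
        params = make_params()
        state = StateVector(np.zeros((4, 23)), 5.0)
        u = regulation_input(params, self.wt, state, self._zero_external(),
                             0, 3, 5.0, self.grid)
        assert u == pytest.approx(-3.5)

    def test_linear_sum(self):
        T = np.zeros((4, 4))
        T[2, 0] = 0.01                      # action of hb on gt
        params = make_params(T=T)
        v = np.zeros((4, 23))
        v[0, :] = 100.0
        u = regulation_input(params, self.wt, StateVector(v, 5.0),
                             self._zero_external(), 2, 7, 5.0, self.grid)
        assert u == pytest.approx(1.0 - 3.5)

    def test_kr_null_annihilates_kr_term(self):
        T = np.full((4, 4), 0.02)
        params = make_params(T=T)
        v = np.abs(np.sin(np.arange(92).reshape(4, 23)))
        v[1, :] = 50.0
        mut = Genotype.kr_null()
        u_mut = regulation_input(params, mut, StateVector(v, 5.0),
                                 self._zero_external(), 0, 3, 5.0, self.grid)
        v_zeroed = v.copy()
        v_zeroed[1, :] = 0.0
        u_ref = regulation_input(params, self.wt,
                                 StateVector(v_zeroed, 5.0),
                                 self._zero_external(), 0, 3, 5.0, self.grid)
        assert u_mut == pytest.approx(u_ref, abs=1e-14)

    def test_bad_indices_and_time(self):
        params = make_params()
        state = StateVector(np.zeros((4, 23)), 5.0)
        with pytest.raises(CircuitError):
            regulation_input(params, self.wt, state, self.external,
                             7, 0, 5.0, self.grid)
        with pytest.raises(CircuitError):
            regulation_input(params, self.wt, state, self.external,
                             0, 0, -100.0, self.grid)
        with pytest.raises(CircuitError):
            regulation_input(params, self.wt,
                             StateVector(np.zeros((4, 10)), 5.0),
                             self.external, 0, 0, 5.0, self.grid)


class TestRhs:
    def test_synthesis_only_at_threshold(self):
        params = make_params(R=np.array([10.0, 20.0, 5.0, 1.0]))
        grid = NucleusGrid.c13()
        ext = make_external_inputs()
        zero_ext = ExternalInputSeries(ext.times, ext.positions,
                                       np.zeros_like(ext.values))
        dv = interphase_rhs(params, Genotype.wildtype(),
                            StateVector(np.zeros((4, 23)), 5.0), zero_ext,
                            5.0, grid)
        expected = g(-3.5) * params.R
        assert np.allclose(dv, expected[:, None], rtol=1e-12)

    def test_uniform_state_no_diffusion_flux(self):
        params = make_params(D=np.full(4, 0.2), R=np.zeros(4),
                             lam=np.zeros(4))
        grid = NucleusGrid.c13()
        v = np.tile(np.array([[3.0], [7.0], [1.0], [9.0]]), (1, 23))
        ext = make_external_inputs()
        dv = mitosis_rhs(params, Genotype.wildtype(), StateVector(v, 17.0),
                         17.0)
        assert np.allclose(dv, 0.0, atol=1e-14)

    def test_pure_decay(self):
        params = make_params(R=np.zeros(4), lam=np.full(4, 0.1))
        grid = NucleusGrid.c13()
        ext = make_external_inputs()
        v = np.full((4, 23), 10.0)
        dv = interphase_rhs(params, Genotype.wildtype(),
                            StateVector(v, 5.0), ext, 5.0, grid)
        # R = 0 kills synthesis; uniform v kills diffusion
        assert np.allclose(dv, -1.0, atol=1e-14)

    def test_mitosis_drops_synthesis(self):
        params = make_params(R=np.full(4, 50.0), lam=np.full(4, 0.05))
        v = np.full((4, 23), 4.0)
        dv = mitosis_rhs(params, Genotype.wildtype(), StateVector(v, 18.0),
                         18.0)
        assert np.allclose(dv, -0.05 * 4.0)
        dv0 = mitosis_rhs(params, Genotype.wildtype(),
                          StateVector(np.zeros((4, 23)), 18.0), 18.0)
        assert np.allclose(dv0, 0.0)


class TestDivision:
    def test_inheritance_and_spacing(self):
        grid = NucleusGrid.c13(n=2, region=(47.0, 51.0))
        v = np.tile(np.array([3.0, 7.0]), (4, 1))
        state, new_grid = divide(StateVector(v, 21.1), grid)
        assert state.v.shape == (4, 4)
        assert np.array_equal(state.v[0], [3.0, 3.0, 7.0, 7.0])
        assert new_grid.spacing == pytest.approx(grid.spacing / 2)
        assert state.v.sum() == pytest.approx(v.sum() * 2)

    def test_cannot_divide_cycle14(self):
        grid = NucleusGrid.c14a()
        with pytest.raises(CircuitError):
            divide(StateVector(np.zeros((4, 46)), 21.1), grid)


class TestParameters:
    def test_vector_roundtrip(self, truth):
        vec = truth.params.to_vector()
        assert vec.shape == (40,)
        back = CircuitParameters.from_vector(vec)
        assert np.array_equal(back.to_vector(), vec)
        assert np.allclose(back.h, -3.5)

    def test_labels_blocks(self):
        labels = parameter_labels()
        assert len(labels) == 40
        assert labels[:10] == ["HH", "HK", "HG", "HN", "HB", "HC", "HT",
                               "R_hb", "D_hb", "lam_hb"]
        assert labels[10] == "KH" and labels[11] == "KK"

    def test_validation(self):
        with pytest.raises(CircuitError):
            make_params(R=np.array([1.0, -1.0, 1.0, 1.0]))
        with pytest.raises(CircuitError):
            make_params(D=np.array([0.1, 0.1, -0.1, 0.1]))
        with pytest.raises(CircuitError):
            make_params(T=np.full((4, 4), np.nan))
        with pytest.raises(CircuitError):
            CircuitParameters(T=np.zeros((3, 4)), E=np.zeros((4, 3)),
                              R=np.ones(4), D=np.zeros(4),
                              lam=np.ones(4))

    def test_half_life(self):
        p = make_params(lam=np.full(4, np.log(2) / 9.0))
        assert np.allclose(p.half_life, 9.0)

    def test_bounds_shapes(self):
        lo, hi = default_bounds()
        assert lo.shape == hi.shape == (40,)
        assert np.all(lo < hi)
        # half-life window 5..20 min on the decay rates
        assert lo[9] == pytest.approx(np.log(2) / 20)
        assert hi[9] == pytest.approx(np.log(2) / 5)


class TestGrid:
    def test_counts_and_span(self):
        g13, g14 = NucleusGrid.c13(), NucleusGrid.c14a()
        assert (g13.n, g14.n) == (23, 46)
        assert g14.n == 2 * g13.n
        for grid in (g13, g14):
            assert grid.positions[0] > 47.0 and grid.positions[-1] < 92.0
            width = grid.positions[-1] - grid.positions[0] + grid.spacing
            assert width == pytest.approx(45.0)

    def test_divided_matches_c14a(self):
        assert np.allclose(NucleusGrid.c13().divided().positions,
                           NucleusGrid.c14a().positions)


class TestGenotype:
    def test_alpha_bounds(self):
        with pytest.raises(CircuitError):
            Genotype("bad", [1.0, 2.0, 1.0, 1.0])

    def test_null_and_graded(self):
        kr = Genotype.kr_null()
        assert kr.alpha[1] == 0.0 and kr.active[1] == False  # noqa: E712
        double = Genotype.null("Kr", "kni")
        assert np.array_equal(double.alpha, [1, 0, 1, 0])
        graded = Genotype.graded("Kr", 0.4)
        assert graded.alpha[1] == 0.4 and graded.active[1]


class TestExternalInputs:
    def test_time_interpolation_clamps(self):
        ext = make_external_inputs()
        grid = NucleusGrid.c14a()
        early = ext.at(-100.0, grid)
        assert np.array_equal(early, ext.at(ext.times[0], grid))
        late = ext.at(1000.0, grid)
        assert np.array_equal(late, ext.at(ext.times[-1], grid))
        # linearity between anchors
        t0, t1 = ext.times[2], ext.times[3]
        mid = ext.at((t0 + t1) / 2, grid)
        assert np.allclose(mid, 0.5 * (ext.at(t0, grid) + ext.at(t1, grid)))

    def test_validation(self):
        ext = make_external_inputs()
        with pytest.raises(CircuitError):
            ExternalInputSeries(ext.times[::-1], ext.positions, ext.values)
        with pytest.raises(CircuitError):
            ExternalInputSeries(ext.times, ext.positions, -ext.values)
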
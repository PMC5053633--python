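"""Stemness window, 2-D phase diagrams, and the E/M-area metric."""

import numpy as np
import pytest

from emtcircuits.circuits import (
    MotifSpec,
    extend_with_stemness,
)
from emtcircuits.phase_maps import (
    PhaseDiagram2D,
    StemnessWindow,
    em_area_fraction,
    motif_phase_diagram,
    oct4_saturation,
    stemness_membership,
    stemness_phase_diagram,
)
from emtcircuits.steady_states import SteadyState, find_steady_states


def state_with_oct4(oct4):
    return SteadyState(
        levels=(1e4, 300.0, 1e5, oct4),
        species=("mir200", "zeb_mrna", "zeb", "oct4"),
        stability="stable",
        leading_real_part=-0.01,
        residual_norm=1e-9,
    )


class TestStemnessWindow:
    def test_bounds_validated(self):
        with pytest.raises(ValueError):
            StemnessWindow(lower=0.7, upper=0.3)
        with pytest.raises(ValueError):
            StemnessWindow(lower=0.0, upper=0.5)

    @pytest.mark.parametrize(
        "rel, inside", [(0.45, True), (0.10, False), (0.25, False), (0.65, False),
                        (0.26, True), (0.90, False)],
    )
    def test_open_interval_membership(self, rel, inside):
        win = StemnessWindow(oct4_saturation=1e6)
        assert stemness_membership(state_with_oct4(rel * 1e6), win) is inside

    def test_missing_oct4_rejected(self):
        win = StemnessWindow(oct4_saturation=1e6)
        s = SteadyState((1.0,), ("mir200",), "stable", -0.1, 0.0)
        with pytest.raises(ValueError):
            stemness_membership(s, win)

    def test_saturation_is_computed_not_set(self, params, core_circuit):
        c = extend_with_stemness(core_circuit, 0.5, 0.5, params=params)
        sat = oct4_saturation(c)
        # clamp level: OCT4 production ceiling over degradation
        lam, x0 = params["lin28_oct4_lambda"], params["lin28_oct4_x0"]
        assert params["g_oct4"] / params["k_oct4"] < sat
        assert sat < lam * params["g_oct4"] / params["k_oct4"]
        with pytest.raises(ValueError):
            oct4_saturation(core_circuit)  # no stemness module


@pytest.fixture(scope="module")
def coupled_anchor_states(params, core_circuit):
    """Stable states of the coupled circuit at the strong-coupling anchor."""
    c = extend_with_stemness(core_circuit, 0.8, 0.8, nfkb=25e3,
                             params=params).with_inputs(snail=220e3)
    sat = oct4_saturation(c)
    win = StemnessWindow(oct4_saturation=sat)
    states = [s for s in find_steady_states(c, n_starts=400, seed=7)
              if s.is_stable]
    return states, win


class TestCoupledCircuit:
    def test_multiple_module_states_per_phenotype(self, coupled_anchor_states):
        states, _ = coupled_anchor_states
        lin28 = sorted(s["lin28"] for s in states)
        # low, intermediate and high LIN28 branches all realized
        assert lin28[0] < 2e4 < lin28[1] < 2e5 < lin28[-1]

    def test_window_membership_follows_lin28_band(self, coupled_anchor_states):
        states, win = coupled_anchor_states
        for s in states:
            rel = s["oct4"] / win.oct4_saturation
            assert stemness_membership(s, win) == (0.25 < rel < 0.65)


@pytest.fixture(scope="module")
def small_map(params, core_circuit):
    grid = np.linspace(0, 1, 5)
    return stemness_phase_diagram(
        core_circuit, grid, grid, snail=220e3, nfkb=25e3, seed=3,
        n_starts=30, params=params,
    )


class TestStemnessDiagram:

    def test_alpha_grid_validated(self, params, core_circuit):
        with pytest.raises(ValueError):
            stemness_phase_diagram(core_circuit, [0.0, 1.5], [0.0, 1.0],
                                   snail=220e3, params=params)

    def test_every_cell_labelled(self, small_map):
        assert all(cell is not None for row in small_map.phases for cell in row)
        assert small_map.failures == []

    def test_uncoupled_corner_matches_uncoupled_phases(self, small_map):
        # alpha1=alpha2=0: EMT side decoupled; at SNAIL=220e3 the core
        # circuit is in its {E/M, M} region
        assert small_map.phases[0][0] == frozenset({"E/M", "M"})

    def test_window_phases_are_phase_subsets(self, small_map):
        for prow, wrow in zip(small_map.phases, small_map.window_phases):
            for phase, wphase in zip(prow, wrow):
                assert wphase <= phase


@pytest.fixture(scope="module")
def self_reg_map(grhl2_circuit):
    lam = np.geomspace(0.25, 4.0, 5)
    sn = np.linspace(150e3, 650e3, 12)
    return motif_phase_diagram(
        grhl2_circuit,
        lambda lv: MotifSpec(psf="grhl2", self_lambda=lv),
        lam, sn, seed=1, n_starts=25,
    )


class TestMotifDiagram:

    def test_neutral_column_reproduces_uncoupled_slice(self, grhl2_circuit):
        sn = np.linspace(150e3, 650e3, 12)
        with_neutral = motif_phase_diagram(
            grhl2_circuit,
            lambda lv: MotifSpec(psf="grhl2", self_lambda=lv),
            [1.0], sn, seed=1, n_starts=25,
        )
        plain = motif_phase_diagram(
            grhl2_circuit, lambda lv: None, [1.0], sn, seed=1, n_starts=25,
        )
        assert with_neutral.phases == plain.phases

    def test_em_area_fraction_modes(self, self_reg_map):
        contains = em_area_fraction(self_reg_map, "contains_EM")
        only = em_area_fraction(self_reg_map, "only_EM")
        assert 0.0 < only <= contains <= 1.0
        with pytest.raises(ValueError):
            em_area_fraction(self_reg_map, "bogus")

    def test_contains_fraction_monotone_in_self_activation(self, self_reg_map):
        per_lambda = [
            sum(1 for cell in row if "E/M" in cell) / len(row)
            for row in self_reg_map.phases
        ]
        tol = 1.0 / len(self_reg_map.axis2_grid)  # one grid cell
        assert all(b >= a - tol for a, b in zip(per_lambda, per_lambda[1:]))

    def test_all_mesenchymal_diagram_has_zero_area(self):
        d = PhaseDiagram2D(
            "lambda", "snail", np.array([1.0]), np.array([1e5, 2e5]),
            phases=[[frozenset({"M"}), frozenset({"M"})]],
        )
        assert em_area_fraction(d, "contains_EM") == 0.0
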
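"""SNAIL sweeps: branch structure, region labels, interval statistics."""

import math

import numpy as np
import pytest

from emtcircuits.bifurcation import (
    emt_onset_threshold,
    hybrid_existence_interval,
    label_regions,
    monostable_hybrid_interval,
    sweep_input,
)
from emtcircuits.circuits import build_core_emt, extend_with_psf
from emtcircuits.params import ParameterSet


@pytest.fixture(scope="module")
def core_diagram(core_circuit, core_sweep_grid):
    return sweep_input(core_circuit, "snail", core_sweep_grid, seed=3, n_starts=30)


@pytest.fixture(scope="module")
def grhl2_diagram(grhl2_circuit):
    grid = np.linspace(120e3, 600e3, 50)
    return sweep_input(grhl2_circuit, "snail", grid, seed=3, n_starts=30)


class TestSweep:
    def test_grid_validation(self, core_circuit):
        with pytest.raises(ValueError):
            sweep_input(core_circuit, "snail", [1e5])
        with pytest.raises(ValueError):
            sweep_input(core_circuit, "snail", [2e5, 1e5])

    def test_core_region_sequence(self, core_diagram):
        phases = [sorted(r.phases) for r in label_regions(core_diagram)]
        assert phases == [
            ["E"], ["E", "M"], ["E", "E/M", "M"], ["E/M", "M"], ["M"],
        ]

    def test_every_stable_state_on_exactly_one_branch(self, core_diagram):
        for i, states in enumerate(core_diagram.states_per_point):
            for s in states:
                if not s.is_stable:
                    continue
                owners = [
                    b for b in core_diagram.branches
                    if any(x is s for x in b.states)
                ]
                assert len(owners) == 1

    def test_fold_estimates_bracketed_by_grid(self, core_diagram):
        lo, hi = core_diagram.grid[0], core_diagram.grid[-1]
        assert all(lo <= f <= hi for f in core_diagram.fold_estimates)

    def test_refined_grid_reproduces_folds_within_one_step(
        self, core_circuit, core_sweep_grid
    ):
        coarse = sweep_input(core_circuit, "snail", core_sweep_grid, seed=3,
                             n_starts=30)
        fine_grid = np.linspace(core_sweep_grid[0], core_sweep_grid[-1],
                                2 * len(core_sweep_grid) - 1)
        fine = sweep_input(core_circuit, "snail", fine_grid, seed=5, n_starts=30)
        step = core_sweep_grid[1] - core_sweep_grid[0]
        w_coarse, _ = hybrid_existence_interval(coarse)
        w_fine, _ = hybrid_existence_interval(fine)
        assert abs(w_coarse - w_fine) <= 2 * step

    def test_hysteresis_under_quasistatic_forward_backward(self, core_circuit):
        """Forward and backward sweeps through a bistable region select
        different branches (saddle-node hysteresis)."""
        from emtcircuits.circuits import build_rhs
        from scipy.integrate import solve_ivp

        f = build_rhs(core_circuit)
        grid = np.linspace(150e3, 260e3, 23)

        def relax(snail_values):
            y = None
            out = []
            for s_val in snail_values:
                g = build_rhs(core_circuit.with_inputs(snail=s_val))
                if y is None:
                    y = np.array([2100 / 0.05, 22.0, 22e3])
                sol = solve_ivp(g.ode, (0, 3000.0), y, method="LSODA",
                                rtol=1e-8, atol=1e-6)
                y = np.maximum(sol.y[:, -1], 0.0)
                out.append(y[g.species.index("zeb_mrna")])
            return np.array(out)

        fwd = relax(grid)
        bwd = relax(grid[::-1])[::-1]
        # inside the bistable window the selected branches differ
        assert np.any(np.abs(fwd - bwd) > 100.0)


class TestIntervals:
    def test_core_has_no_monostable_hybrid(self, core_diagram):
        width, pieces = monostable_hybrid_interval(core_diagram)
        assert width == 0.0 and pieces == []

    def test_grhl2_has_monostable_hybrid(self, grhl2_diagram):
        width, pieces = monostable_hybrid_interval(grhl2_diagram)
        assert width > 0.0 and len(pieces) >= 1

    def test_grhl2_widens_hybrid_existence(self, core_diagram, grhl2_diagram):
        w_core, _ = hybrid_existence_interval(core_diagram)
        w_grhl2, _ = hybrid_existence_interval(grhl2_diagram)
        assert w_grhl2 > w_core

    def test_emt_onset_beyond_grid_for_disconnected_circuit(self):
        p = ParameterSet.baseline().replace(
            zeb_mir200_lambda=1.0, snail_mir200_lambda=1.0,
            zeb_zeb_mrna_lambda=1.0, snail_zeb_mrna_lambda=1.0,
        )
        c = build_core_emt(p)
        c.bindings = []
        d = sweep_input(c, "snail", np.linspace(1e5, 3e5, 10), seed=0, n_starts=10)
        assert math.isinf(emt_onset_threshold(d))

    def test_onset_within_grid_for_core(self, core_diagram):
        onset = emt_onset_threshold(core_diagram)
        assert core_diagram.grid[0] < onset < core_diagram.grid[-1]


@pytest.fixture(scope="module")
def signal_results(params, core_circuit):
    grid = np.linspace(120e3, 700e3, 50)
    out = {}
    for name, sa, si in [("ctrl", 0, 0), ("si", 0, 300e3), ("sa", 300e3, 0)]:
        c = extend_with_psf(core_circuit, "grhl2", sa=sa, si=si, params=params)
        d = sweep_input(c, "snail", grid, seed=3, n_starts=30)
        out[name] = {
            "onset": emt_onset_threshold(d),
            "mono": monostable_hybrid_interval(d)[0],
        }
    return out


class TestSignalDirectionality:
    """GRHL2 knockdown (SI) and overexpression (SA) move the EMT onset
    in opposite directions and SI destroys the monostable-hybrid window."""

    def test_si_lowers_onset_and_kills_hybrid_window(self, signal_results):
        assert signal_results["si"]["onset"] < signal_results["ctrl"]["onset"]
        assert signal_results["ctrl"]["mono"] > 0
        assert signal_results["si"]["mono"] == 0.0

    def test_sa_raises_onset(self, signal_results):
        assert signal_results["sa"]["onset"] > signal_results["ctrl"]["onset"]

    def test_si_monotonicity_over_levels(self, params, core_circuit):
        grid = np.linspace(120e3, 600e3, 40)
        widths, onsets = [], []
        for si in (0.0, 150e3, 400e3):
            c = extend_with_psf(core_circuit, "grhl2", si=si, params=params)
            d = sweep_input(c, "snail", grid, seed=3, n_starts=25)
            widths.append(monostable_hybrid_interval(d)[0])
            onsets.append(emt_onset_threshold(d))
        assert widths[0] >= widths[1] >= widths[2]
        assert onsets[0] >= onsets[1] >= onsets[2]
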
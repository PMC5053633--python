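"""Circuit construction, motif edits, and the assembled rate equations."""

import numpy as np
import pytest

from emtcircuits.circuits import (
    MotifSpec,
    Species,
    apply_motif,
    build_circuit,
    build_core_emt,
    build_rhs,
    extend_with_psf,
    extend_with_stemness,
)
from emtcircuits.steady_states import find_steady_states

# frozen topology of the core switch (source, target, kind)
CORE_EDGES = {
    ("zeb", "mir200", "transcriptional"),
    ("snail", "mir200", "transcriptional"),
    ("zeb", "zeb_mrna", "transcriptional"),
    ("snail", "zeb_mrna", "transcriptional"),
    ("mir200", "zeb_mrna", "miRNA_mediated"),
}


class TestBuilders:
    def test_core_topology_matches_frozen_edge_list(self, core_circuit):
        assert core_circuit.edges() == CORE_EDGES
        assert core_circuit.dynamical_species == ["mir200", "zeb_mrna", "zeb"]
        assert core_circuit.input_levels.keys() == {"snail"}

    def test_psf_variants_add_expected_species(self, params, core_circuit):
        expect = {
            "grhl2": {"grhl2"},
            "ovol": {"ovol"},
            "mir145_full": {"mir145", "oct4"},
            "mir145_effective": {"mir145"},
        }
        for psf, extra in expect.items():
            c = extend_with_psf(core_circuit, psf, params=params)
            added = set(c.dynamical_species) - set(core_circuit.dynamical_species)
            assert added == extra

    def test_mir145_full_has_oct4_mir200_activation(self, params, core_circuit):
        c = extend_with_psf(core_circuit, "mir145_full", params=params)
        link = next(l for l in c.links if (l.source, l.target) == ("oct4", "mir200"))
        assert link.hill.fold_change > 1

    def test_simultaneous_sa_si_rejected(self, params, core_circuit):
        with pytest.raises(ValueError, match="separately"):
            extend_with_psf(core_circuit, "grhl2", sa=1e5, si=1e5, params=params)
        extend_with_psf(core_circuit, "grhl2", sa=1e5, si=1e5, params=params,
                        allow_both_signals=True)

    def test_stemness_coupling_bounds(self, params, core_circuit):
        with pytest.raises(ValueError):
            extend_with_stemness(core_circuit, 1.2, 0.0, params=params)
        c = extend_with_stemness(core_circuit, 0.5, 0.5, params=params)
        assert {"let7", "lin28_mrna", "lin28", "oct4"} <= set(c.dynamical_species)
        # no OCT4 -> miR-200 feedback
        assert not any(l.source == "oct4" for l in c.links)

    def test_alpha_zero_gives_neutral_coupling_links(self, params, core_circuit):
        c = extend_with_stemness(core_circuit, 0.0, 0.0, params=params)
        ff = next(l for l in c.links if (l.source, l.target) == ("mir200", "lin28_mrna"))
        fb = next(l for l in c.links if (l.source, l.target) == ("let7", "zeb_mrna"))
        assert ff.hill.fold_change == 1.0
        assert fb.hill.fold_change == 1.0

    def test_named_variants_build(self, params):
        for name in ("core", "grhl2", "ovol", "mir145_full", "mir145_effective",
                     "stemness", "stemness_grhl2"):
            build_circuit(name, params=params)
        with pytest.raises(ValueError, match="unknown circuit variant"):
            build_circuit("nope", params=params)


class TestMotifs:
    def test_neutral_motif_leaves_rates_unchanged(self, params, grhl2_circuit):
        edited = apply_motif(grhl2_circuit, MotifSpec(psf="grhl2", self_lambda=1.0))
        f0, f1 = build_rhs(grhl2_circuit), build_rhs(edited)
        y = np.array([1e4, 300.0, 1e5, 5e4])
        assert np.allclose(f0(y), f1(y))

    def test_hypothetical_mir200_inhibition_added(self, params, grhl2_circuit):
        edited = apply_motif(
            grhl2_circuit, MotifSpec(psf="grhl2", to_mir200_lambda=0.5)
        )
        assert ("grhl2", "mir200", "transcriptional") in edited.edges()
        with pytest.raises(ValueError, match="inhibitory"):
            apply_motif(grhl2_circuit, MotifSpec(psf="grhl2", to_mir200_lambda=2.0))

    def test_zeb_feedback_removal(self, params, core_circuit):
        ovol = extend_with_psf(core_circuit, "ovol", params=params)
        edited = apply_motif(ovol, MotifSpec(psf="ovol", remove_zeb_feedback=True))
        assert ("zeb", "ovol", "transcriptional") not in edited.edges()
        # PSF still inhibits both miR-200 and ZEB (motif iii)
        assert ("ovol", "mir200", "transcriptional") in edited.edges()
        assert ("ovol", "zeb_mrna", "transcriptional") in edited.edges()

    def test_control_rewire_to_mir200(self, params, grhl2_circuit):
        edited = apply_motif(grhl2_circuit, MotifSpec(psf="grhl2", partner="mir200"))
        assert ("mir200", "grhl2", "transcriptional") in edited.edges()
        assert ("grhl2", "mir200", "transcriptional") in edited.edges()
        assert ("zeb", "grhl2", "transcriptional") not in edited.edges()

    def test_control_activating_outputs(self, params, grhl2_circuit):
        edited = apply_motif(grhl2_circuit, MotifSpec(psf="grhl2", outputs="activate"))
        link = next(
            l for l in edited.links if (l.source, l.target) == ("grhl2", "zeb_mrna")
        )
        assert link.hill.fold_change > 1

    def test_absent_species_rejected(self, core_circuit):
        with pytest.raises(ValueError, match="absent species"):
            apply_motif(core_circuit, MotifSpec(psf="grhl2", self_lambda=2.0))


class TestRHS:
    def test_disconnected_gene_balances_at_g_over_k(self):
        c = build_core_emt()
        # all fold changes neutral: every species relaxes to its g/k level
        from emtcircuits.params import ParameterSet

        p = ParameterSet.baseline().replace(
            zeb_mir200_lambda=1.0, snail_mir200_lambda=1.0,
            zeb_zeb_mrna_lambda=1.0, snail_zeb_mrna_lambda=1.0,
        )
        c = build_core_emt(p)
        c.bindings = []  # isolate the transcriptional layer
        f = build_rhs(c)
        levels = {"mir200": 2100 / 0.05, "zeb_mrna": 11 / 0.5}
        levels["zeb"] = 100 * levels["zeb_mrna"] / 0.1
        y = np.array([levels[s] for s in f.species])
        assert np.allclose(f(y), 0.0, atol=1e-8)

    def test_doubling_degradation_halves_fixed_point(self):
        from emtcircuits.params import ParameterSet

        for k in (0.05, 0.1):
            p = ParameterSet.baseline().replace(
                zeb_mir200_lambda=1.0, snail_mir200_lambda=1.0, k_mir200=k
            )
            c = build_core_emt(p)
            c.bindings = []
            states = find_steady_states(c, n_starts=20, seed=0)
            assert len(states) == 1
            if k == 0.05:
                ref = states[0]["mir200"]
            else:
                assert states[0]["mir200"] == pytest.approx(ref / 2, rel=1e-6)

    def test_rhs_rejects_bad_states(self, core_circuit):
        f = build_rhs(core_circuit)
        with pytest.raises(ValueError):
            f(np.ones(5))
        with pytest.raises(ValueError):
            f(np.array([-1.0, 1.0, 1.0]))

    def test_nonnegative_orthant_forward_invariant(self, tristable_core):
        f = build_rhs(tristable_core)
        rng = np.random.default_rng(3)
        scales = f.scales()
        for _ in range(30):
            y = np.exp(rng.uniform(0, np.log(scales)))
            i = rng.integers(len(y))
            y[i] = 0.0
            assert f(y)[i] >= 0.0

    def test_steady_state_residual_self_consistency(self, tristable_core):
        f = build_rhs(tristable_core)
        for s in find_steady_states(tristable_core, n_starts=40, seed=1):
            assert np.linalg.norm(f(np.array(s.levels))) < 1e-3

    def test_neutral_psf_reduces_to_core(self, params, core_circuit):
        from emtcircuits.params import ParameterSet

        p = ParameterSet.baseline().replace(
            zeb_grhl2_lambda=1.0, grhl2_zeb_mrna_lambda=1.0,
            sa_grhl2_lambda=1.0, si_grhl2_lambda=1.0,
        )
        g = extend_with_psf(build_core_emt(p, snail=198e3), "grhl2", params=p)
        core_states = find_steady_states(
            build_core_emt(p, snail=198e3), n_starts=60, seed=2
        )
        g_states = find_steady_states(g, n_starts=60, seed=2)
        core_stable = sorted(s["zeb_mrna"] for s in core_states if s.is_stable)
        g_stable = sorted(s["zeb_mrna"] for s in g_states if s.is_stable)
        assert len(core_stable) == len(g_stable)
        assert np.allclose(core_stable, g_stable, rtol=1e-6)

    def test_downstream_reporter_detection(self, params, core_circuit):
        c = extend_with_stemness(core_circuit, 0.5, 0.5, params=params)
        f = build_rhs(c)
        assert f.downstream == ["oct4"]
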
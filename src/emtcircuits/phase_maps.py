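"""Two-parameter phase diagrams and the stemness-window classifier.

Two families of maps are produced:

* *stemness maps* over the EMT-stemness coupling strengths (alpha1,
  alpha2) — per cell, the set of coexisting EMT phenotypes and the
  subset whose OCT4 level falls inside the stemness window (an
  intermediate band of OCT4, by default 0.25-0.65 relative to the OCT4
  level saturated by maximal LIN28);

* *motif maps* over a hypothetical link strength (a PSF self-regulation
  or PSF ⊣ miR-200 fold change) crossed with SNAIL — per cell the set of
  coexisting phenotypes.  The summary statistic is the fraction of the
  map where the hybrid E/M phenotype exists (or exists alone), the
  quantity the network-motif screen ranks couplings by.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .circuits import (
    CircuitSpec,
    MotifSpec,
    apply_motif,
    build_rhs,
    extend_with_stemness,
)
from .steady_states import SteadyState, classify_phenotype, find_steady_states

__all__ = [
    "StemnessWindow",
    "PhaseDiagram2D",
    "oct4_saturation",
    "stemness_membership",
    "stemness_phase_diagram",
    "motif_phase_diagram",
    "em_area_fraction",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StemnessWindow:
    """The band of relative OCT4 levels in which cells are stem-like.

    Bounds are open intervals of OCT4 relative to ``oct4_saturation``,
    the steady OCT4 level when its activator LIN28 is clamped maximal.
    """

    lower: float = 0.25
    upper: float = 0.65
    oct4_saturation: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.lower < self.upper <= 1.0:
            raise ValueError(
                f"need 0 < lower < upper <= 1, got ({self.lower}, {self.upper})"
            )


def oct4_saturation(circuit: CircuitSpec) -> float:
    """Steady OCT4 with LIN28 clamped at its maximal level.

    The clamp sets LIN28 to its production ceiling (basal rate times all
    activating fold changes over degradation, mRNA included), then OCT4
    relaxes to ``g * H(LIN28_max) / k``.
    """
    if "oct4" not in circuit.species or "lin28" not in circuit.species:
        raise ValueError("circuit lacks the stemness module (OCT4/LIN28)")
    rhs = build_rhs(circuit)
    scales = rhs.scales()
    idx = {s: i for i, s in enumerate(rhs.species)}
    lin28_max = scales[idx["lin28"]]
    sp = circuit.species["oct4"]
    prod = sp.g
    for link in circuit.links:
        if link.target == "oct4" and link.source == "lin28":
            prod *= link.hill(lin28_max)
    return prod / sp.k


def stemness_membership(state: SteadyState, window: StemnessWindow) -> bool:
    """Whether a state's OCT4 lies strictly inside the stemness window."""
    if "oct4" not in state.species:
        raise ValueError("state has no OCT4 level; circuit lacks the stemness module")
    if not window.oct4_saturation > 0:
        raise ValueError("window.oct4_saturation must be positive (computed, not set)")
    rel = state["oct4"] / window.oct4_saturation
    return window.lower < rel < window.upper


@dataclass
class PhaseDiagram2D:
    """A labelled grid over two control parameters.

    ``phases[i][j]`` is the frozenset of coexisting stable phenotypes at
    ``(axis1_grid[i], axis2_grid[j])``; for stemness maps
    ``window_phases`` additionally holds the subset inside the stemness
    window.
    """

    axis1_name: str
    axis2_name: str
    axis1_grid: np.ndarray
    axis2_grid: np.ndarray
    phases: list  # list[list[frozenset]]
    window_phases: Optional[list] = None
    metadata: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)

    def phase_area(self, phase: set, in_window: bool = False) -> float:
        """Fraction of grid cells whose (window) phase equals ``phase``."""
        table = self.window_phases if in_window else self.phases
        target = frozenset(phase)
        total = len(self.axis1_grid) * len(self.axis2_grid)
        hits = sum(1 for row in table for cell in row if cell == target)
        return hits / total


def _solve_cell(circuit, seed, n_starts, warm):
    return find_steady_states(
        circuit, n_starts=n_starts, seed=seed, extra_starts=warm
    )


def stemness_phase_diagram(
    circuit: CircuitSpec,
    alpha1_grid: Sequence[float],
    alpha2_grid: Sequence[float],
    snail: float,
    nfkb: float = 25e3,
    seed: int = 0,
    n_starts: int = 40,
    window: Optional[StemnessWindow] = None,
    params=None,
) -> PhaseDiagram2D:
    """Phase diagram of the EMT-stemness circuit over (alpha1, alpha2).

    ``circuit`` is the EMT-side circuit (core or GRHL2-coupled) *without*
    the stemness module; the module is attached per cell at the cell's
    coupling strengths.  Each cell records the coexisting phenotype set
    and the subset lying in the stemness window.
    """
    a1 = np.asarray(alpha1_grid, dtype=float)
    a2 = np.asarray(alpha2_grid, dtype=float)
    if np.any(a1 < 0) or np.any(a1 > 1) or np.any(a2 < 0) or np.any(a2 > 1):
        raise ValueError("alpha grids must lie within [0, 1]")

    phases: list = []
    window_phases: list = []
    failures: list = []
    win = None
    warm_by_col: dict[int, list] = {}
    for i, alpha1 in enumerate(a1):
        row_phases = []
        row_window = []
        warm_prev: list = []
        for j, alpha2 in enumerate(a2):
            cell = extend_with_stemness(
                circuit, float(alpha1), float(alpha2), nfkb=nfkb, params=params
            ).with_inputs(snail=snail, nfkb=nfkb)
            if win is None:
                w0 = window or StemnessWindow()
                win = StemnessWindow(w0.lower, w0.upper, oct4_saturation(cell))
            warm = warm_prev + warm_by_col.get(j, [])
            try:
                states = _solve_cell(cell, seed + 1000 * i + j, n_starts, warm)
            except Exception as exc:  # pragma: no cover - defensive
                logger.warning("cell (%g, %g) failed: %s", alpha1, alpha2, exc)
                failures.append((i, j, str(exc)))
                states = []
            stable = [s for s in states if s.is_stable]
            labels = {}
            for s in stable:
                lab = classify_phenotype(s).label
                labels.setdefault(lab, []).append(s)
            row_phases.append(frozenset(labels))
            row_window.append(frozenset(
                lab for lab, ss in labels.items()
                if any(stemness_membership(s, win) for s in ss)
            ))
            warm_prev = [s.levels for s in stable]
            warm_by_col[j] = warm_prev
        phases.append(row_phases)
        window_phases.append(row_window)

    return PhaseDiagram2D(
        axis1_name="alpha1",
        axis2_name="alpha2",
        axis1_grid=a1,
        axis2_grid=a2,
        phases=phases,
        window_phases=window_phases,
        metadata={
            "snail": snail,
            "nfkb": nfkb,
            "circuit": circuit.name,
            "seed": seed,
            "window": (win.lower, win.upper, win.oct4_saturation) if win else None,
        },
        failures=failures,
    )


def motif_phase_diagram(
    circuit: CircuitSpec,
    motif_for_lambda,
    lambda_grid: Sequence[float],
    snail_grid: Sequence[float],
    seed: int = 0,
    n_starts: int = 40,
) -> PhaseDiagram2D:
    """Phase diagram over a motif link strength crossed with SNAIL.

    ``motif_for_lambda`` maps a fold-change value from ``lambda_grid``
    to the :class:`MotifSpec` to apply (e.g. a PSF self-regulation
    scanned from self-inhibition through self-activation).
    """
    lam = np.asarray(lambda_grid, dtype=float)
    sn = np.asarray(snail_grid, dtype=float)
    phases: list = []
    failures: list = []
    warm_by_col: dict[int, list] = {}
    for i, lv in enumerate(lam):
        motif = motif_for_lambda(float(lv))
        edited = apply_motif(circuit, motif) if motif is not None else circuit
        row = []
        warm_prev: list = []
        for j, s_val in enumerate(sn):
            cell = edited.with_inputs(snail=float(s_val))
            warm = warm_prev + warm_by_col.get(j, [])
            try:
                states = _solve_cell(cell, seed + 1000 * i + j, n_starts, warm)
            except Exception as exc:  # pragma: no cover - defensive
                logger.warning("cell (%g, %g) failed: %s", lv, s_val, exc)
                failures.append((i, j, str(exc)))
                states = []
            stable = [s for s in states if s.is_stable]
            row.append(frozenset(classify_phenotype(s).label for s in stable))
            warm_prev = [s.levels for s in stable]
            warm_by_col[j] = warm_prev
        phases.append(row)
    return PhaseDiagram2D(
        axis1_name="lambda",
        axis2_name="snail",
        axis1_grid=lam,
        axis2_grid=sn,
        phases=phases,
        metadata={"circuit": circuit.name, "seed": seed},
        failures=failures,
    )


def em_area_fraction(diagram: PhaseDiagram2D, mode: str = "contains_EM") -> float:
    """Fraction of grid cells whose phase contains (or equals) {E/M}."""
    if mode not in ("contains_EM", "only_EM"):
        raise ValueError(f"unknown mode {mode!r}")
    total = len(diagram.axis1_grid) * len(diagram.axis2_grid)
    if mode == "contains_EM":
        hits = sum(1 for row in diagram.phases for cell in row if "E/M" in cell)
    else:
        hits = sum(
            1 for row in diagram.phases for cell in row
            if cell == frozenset({"E/M"})
        )
    return hits / total
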
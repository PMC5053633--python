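"""One-dimensional steady-state sweeps over a driving input.

:func:`sweep_input` runs the multistart solver along a grid of the
driving input (SNAIL for the EMT circuits), reusing each point's
solutions as warm starts for the next, links states across adjacent
points into branches by nearest-neighbour matching in log-levels, and
estimates fold (saddle-node) locations where a branch terminates.

The labelled diagram answers the questions the analysis turns on: which
phenotype sets coexist over which input ranges (:func:`label_regions`),
whether the hybrid E/M phenotype is ever the *only* stable state
(:func:`monostable_hybrid_interval` — the operational signature of a
phenotypic stability factor), and at which input level the epithelial
branch disappears (:func:`emt_onset_threshold`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .circuits import CircuitSpec
from .steady_states import (
    SteadyState,
    E_MAX_ZEB_MRNA,
    HYBRID_ZEB_MRNA,
    classify_phenotype,
    find_steady_states,
)

__all__ = [
    "Branch",
    "BifurcationDiagram",
    "RegionLabel",
    "sweep_input",
    "label_regions",
    "monostable_hybrid_interval",
    "hybrid_existence_interval",
    "emt_onset_threshold",
]

logger = logging.getLogger(__name__)

#: branch-matching threshold: relative distance in log-levels per grid step
BRANCH_MATCH_TOL = 0.35


@dataclass
class Branch:
    """A sequence of steady states linked across adjacent grid points."""

    grid_indices: list[int] = field(default_factory=list)
    states: list[SteadyState] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.grid_indices[0]

    @property
    def end(self) -> int:
        return self.grid_indices[-1]

    def mean_zeb_mrna(self) -> float:
        return float(np.mean([s["zeb_mrna"] for s in self.states]))


@dataclass(frozen=True)
class RegionLabel:
    """A maximal input interval with a fixed set of coexisting phenotypes."""

    interval: tuple  # (lo, hi) in molecules
    phases: frozenset  # subset of {"E", "E/M", "M"}

    @property
    def width(self) -> float:
        return self.interval[1] - self.interval[0]


@dataclass
class BifurcationDiagram:
    swept_input: str
    grid: np.ndarray
    states_per_point: list  # list[list[SteadyState]]
    branches: list
    fold_estimates: list  # molecules values where a branch appears/disappears
    circuit_name: str = ""

    def stable_sets(self) -> list:
        return [[s for s in states if s.is_stable] for states in self.states_per_point]

    def branch_label_for(self, state: SteadyState) -> Optional[str]:
        """Phenotype label inherited from the branch containing ``state``."""
        for branch in self.branches:
            if any(s is state for s in branch.states):
                m = branch.mean_zeb_mrna()
                lo, hi = HYBRID_ZEB_MRNA
                if m < E_MAX_ZEB_MRNA:
                    return "E"
                if m <= hi:
                    return "E/M"
                return "M"
        return None

    def holes(self) -> list:
        return [i for i, states in enumerate(self.states_per_point) if not states]


def _link_branches(grid: np.ndarray, states_per_point: list) -> tuple[list, list]:
    """Greedy nearest-neighbour linking of states across the grid."""
    open_branches: list[Branch] = []
    closed: list[Branch] = []
    folds: list[float] = []

    for i, states in enumerate(states_per_point):
        unmatched = list(states)
        still_open: list[Branch] = []
        # match each open branch to its nearest continuation
        for branch in open_branches:
            prev = branch.states[-1].log_levels()
            best, best_d = None, BRANCH_MATCH_TOL
            for s in unmatched:
                d = float(np.sqrt(np.mean((s.log_levels() - prev) ** 2)))
                if d < best_d:
                    best, best_d = s, d
            if best is not None:
                unmatched.remove(best)
                branch.grid_indices.append(i)
                branch.states.append(best)
                still_open.append(branch)
            else:
                # branch terminates between grid[i-1] and grid[i]
                folds.append(0.5 * (grid[i - 1] + grid[i]))
                closed.append(branch)
        # states with no antecedent start new branches
        for s in unmatched:
            b = Branch([i], [s])
            still_open.append(b)
            if i > 0:
                folds.append(0.5 * (grid[i - 1] + grid[i]))
        open_branches = still_open
    closed.extend(open_branches)
    return closed, sorted(folds)


def sweep_input(
    circuit: CircuitSpec,
    input_name: str,
    grid: Sequence[float],
    seed: int = 0,
    n_starts: int = 60,
    tol: float = 1e-3,
) -> BifurcationDiagram:
    """Quasi-static sweep of ``input_name`` over a monotone grid.

    Warm starts from the previous grid point guard against branch
    dropout; a point that finds fewer states than its neighbour is
    re-solved with triple the start count before the deficit is
    accepted.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be monotone increasing with >= 2 points")

    states_per_point: list = []
    prev_levels: list = []
    for i, value in enumerate(grid):
        c = circuit.with_inputs(**{input_name: value})
        states = find_steady_states(
            c, n_starts=n_starts, seed=seed + i, tol=tol, extra_starts=prev_levels
        )
        if prev_levels and len(states) < len(states_per_point[-1]):
            # continuity-guided re-seeding against branch dropout
            states = find_steady_states(
                c, n_starts=3 * n_starts, seed=seed + i + 10_000, tol=tol,
                extra_starts=prev_levels,
            )
        if not states:
            logger.warning(
                "no steady state found at %s=%g; hole recorded", input_name, value
            )
        states_per_point.append(states)
        prev_levels = [s.levels for s in states] or prev_levels

    branches, folds = _link_branches(grid, states_per_point)
    return BifurcationDiagram(
        swept_input=input_name,
        grid=grid,
        states_per_point=states_per_point,
        branches=branches,
        fold_estimates=folds,
        circuit_name=circuit.name,
    )


def label_regions(diagram: BifurcationDiagram) -> list:
    """Partition the swept range into intervals of constant phase set."""
    grid = diagram.grid
    phases_per_point = []
    for states in diagram.stable_sets():
        labels = frozenset(
            classify_phenotype(s, context=diagram).label for s in states
        )
        phases_per_point.append(labels)

    regions: list[RegionLabel] = []
    start = 0
    for i in range(1, len(grid) + 1):
        if i == len(grid) or phases_per_point[i] != phases_per_point[start]:
            lo = grid[start] if start == 0 else 0.5 * (grid[start - 1] + grid[start])
            hi = grid[i - 1] if i == len(grid) else 0.5 * (grid[i - 1] + grid[i])
            if not phases_per_point[start]:
                raise RuntimeError(
                    f"unlabeled interval at {diagram.swept_input}={lo:g}..{hi:g}"
                )
            regions.append(RegionLabel((float(lo), float(hi)), phases_per_point[start]))
            start = i
    return regions


def monostable_hybrid_interval(diagram: BifurcationDiagram) -> tuple[float, list]:
    """Total width and bounds of the regions whose phase is exactly {E/M}."""
    pieces = [
        r.interval for r in label_regions(diagram) if r.phases == frozenset({"E/M"})
    ]
    return float(sum(hi - lo for lo, hi in pieces)), pieces


def hybrid_existence_interval(diagram: BifurcationDiagram) -> tuple[float, list]:
    """Total width and bounds of the regions where E/M exists at all."""
    pieces = [r.interval for r in label_regions(diagram) if "E/M" in r.phases]
    return float(sum(hi - lo for lo, hi in pieces)), pieces


def emt_onset_threshold(diagram: BifurcationDiagram) -> float:
    """Input level at which the epithelial branch disappears.

    Returns ``math.inf`` when the E branch persists to the end of the
    grid ("beyond grid").
    """
    e_branches = [
        b for b in diagram.branches
        if b.states[0].is_stable and b.mean_zeb_mrna() < E_MAX_ZEB_MRNA
    ]
    if not e_branches:
        raise ValueError("diagram contains no epithelial branch")
    end = max(b.end for b in e_branches)
    if end >= len(diagram.grid) - 1:
        return math.inf
    return float(0.5 * (diagram.grid[end] + diagram.grid[end + 1]))
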
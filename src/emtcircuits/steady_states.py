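"""Fixed points of a circuit: location, stability, phenotype label.

:func:`find_steady_states` runs a multistart Newton-type root search on
the rate equations in log-level coordinates (which enforces positivity
and handles the four orders of magnitude between miRNA and protein
scales), deduplicates the converged roots, and classifies stability from
the eigenvalues of the numerically differentiated Jacobian.

:func:`attractors_by_integration` is the independent oracle: it
integrates the ODEs forward from an ensemble of initial conditions and
clusters the relaxed endpoints, recovering the stable attractors only.

Phenotypes follow the ZEB mRNA read-out: below 100 molecules the cell is
epithelial (E), between 200 and 450 molecules hybrid E/M, above 450
mesenchymal (M); states falling in the 100-200 gap inherit the label of
the branch they connect to when a bifurcation context is available,
otherwise the nearest band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .circuits import CircuitRHS, CircuitSpec, build_rhs

__all__ = [
    "SteadyState",
    "PhenotypeCall",
    "find_steady_states",
    "attractors_by_integration",
    "classify_phenotype",
    "E_MAX_ZEB_MRNA",
    "HYBRID_ZEB_MRNA",
]

logger = logging.getLogger(__name__)

#: ZEB mRNA phenotype bands (molecules).
E_MAX_ZEB_MRNA = 100.0
HYBRID_ZEB_MRNA = (200.0, 450.0)

#: relative L2 distance in log-levels below which two roots are one state
DEDUP_TOL = 1e-3
#: eigenvalue real-part margin (per hour) for stability calls
STABILITY_MARGIN = 1e-6


@dataclass(frozen=True)
class SteadyState:
    """A fixed point of a circuit at fixed inputs."""

    levels: tuple  # molecules, ordered as `species`
    species: tuple
    stability: str  # stable | saddle | unstable
    leading_real_part: float  # per hour
    residual_norm: float  # molecules/hour

    def __getitem__(self, name: str) -> float:
        return self.levels[self.species.index(name)]

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"

    def log_levels(self) -> np.ndarray:
        return np.log(np.maximum(np.asarray(self.levels), 1e-12))


@dataclass(frozen=True)
class PhenotypeCall:
    label: str  # E | E/M | M
    basis: str  # threshold | branch_continuity | nearest_band


def _log_distance(a: np.ndarray, b: np.ndarray) -> float:
    d = a - b
    return float(np.sqrt(np.mean(d * d)))


def _sample_starts(rhs: CircuitRHS, n: int, rng: np.random.Generator) -> np.ndarray:
    """Log-uniform samples per species over [1, 10 * (g_eff/k)]."""
    scales = np.maximum(rhs.scales(), 10.0)
    lo = np.zeros(len(scales))  # log(1)
    hi = np.log(10.0 * scales)
    u = rng.random((n, len(scales)))
    return np.exp(lo + u * (hi - lo))


def _classify_stability(rhs: CircuitRHS, x: np.ndarray) -> tuple[str, float]:
    J = rhs.jacobian(x)
    real_parts = np.sort(np.linalg.eigvals(J).real)[::-1]
    leading = float(real_parts[0])
    if leading < -STABILITY_MARGIN:
        return "stable", leading
    n_pos = int(np.sum(real_parts > STABILITY_MARGIN))
    if n_pos <= 1:
        return "saddle", leading
    return "unstable", leading


def _make_state(rhs: CircuitRHS, x: np.ndarray) -> SteadyState:
    stability, leading = _classify_stability(rhs, x)
    res = float(np.linalg.norm(rhs(np.maximum(x, 0.0))))
    return SteadyState(
        levels=tuple(float(v) for v in x),
        species=tuple(rhs.species),
        stability=stability,
        leading_real_part=leading,
        residual_norm=res,
    )


def _dedup(states: list[np.ndarray]) -> list[np.ndarray]:
    kept: list[np.ndarray] = []
    for x in states:
        lx = np.log(np.maximum(x, 1e-12))
        if all(_log_distance(lx, np.log(np.maximum(k, 1e-12))) > DEDUP_TOL
               for k in kept):
            kept.append(x)
    return kept


def find_steady_states(
    circuit: CircuitSpec,
    n_starts: int = 200,
    seed: int = 0,
    tol: float = 1e-3,
    extra_starts: Optional[Sequence[Sequence[float]]] = None,
    rhs: Optional[CircuitRHS] = None,
) -> list[SteadyState]:
    """All fixed points found by a seeded multistart root search.

    ``tol`` is the accepted residual infinity-norm in molecules/hour,
    checked against the *relative* per-species rate as well (a root must
    balance production and loss to one part in 1e6).  ``extra_starts``
    injects warm starts (e.g. the neighbouring sweep point's states).
    Downstream reporter species are solved analytically after the
    feedback core converges.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    f = rhs or build_rhs(circuit)
    rng = np.random.default_rng(seed)
    up_idx = [f.species.index(s) for s in f.upstream]

    def g(z: np.ndarray) -> np.ndarray:
        """Relative rates d(log x)/dt of the feedback core, at x = exp(z)."""
        x = full_template.copy()
        x[up_idx] = np.exp(np.clip(z, -50.0, 50.0))
        d = f._eval(x)
        return d[up_idx] / (f._k[up_idx] * x[up_idx] + 1e-9)

    full_template = np.ones(len(f.species))
    starts = list(_sample_starts(f, n_starts, rng))
    if extra_starts is not None:
        starts = [np.asarray(s, dtype=float) for s in extra_starts] + starts

    roots: list[np.ndarray] = []
    n_converged = 0
    for x0 in starts:
        z0 = np.log(np.maximum(np.asarray(x0)[up_idx], 1e-3))
        sol = root(g, z0, method="hybr", options={"xtol": 1e-12})
        if not sol.success and np.max(np.abs(sol.fun)) > 1e-10:
            continue
        x = full_template.copy()
        x[up_idx] = np.exp(np.clip(sol.x, -50.0, 50.0))
        x = f.downstream_levels(x)
        if not np.all(np.isfinite(x)):
            continue
        resid = f._eval(x)
        rel = np.abs(resid) / (f._k * x + 1e-9)
        if np.max(np.abs(resid)) > tol and np.max(rel) > 1e-6:
            continue
        n_converged += 1
        roots.append(x)

    if n_converged == 0:
        logger.warning(
            "no start converged for circuit %s (n_starts=%d)", circuit.name, n_starts
        )
        return []
    unique = _dedup(roots)
    states = [_make_state(f, x) for x in unique]
    states.sort(key=lambda s: s["zeb_mrna"] if "zeb_mrna" in s.species else s.levels[0])
    return states


def attractors_by_integration(
    circuit: CircuitSpec,
    n_grid: int = 40,
    t_end: float = 4000.0,
    seed: int = 0,
    tol: float = 1e-3,
    rhs: Optional[CircuitRHS] = None,
) -> list[SteadyState]:
    """Stable attractors recovered by forward time integration.

    Integrates from ``n_grid`` log-uniform initial conditions for
    ``t_end`` hours (tens of times the slowest degradation timescale),
    discards trajectories whose endpoint has not relaxed (relative rate
    above tolerance, logged), and clusters the rest.
    """
    f = rhs or build_rhs(circuit)
    rng = np.random.default_rng(seed)
    starts = _sample_starts(f, n_grid, rng)
    scales = np.maximum(f.scales(), 10.0)

    endpoints: list[np.ndarray] = []
    n_flagged = 0
    for x0 in starts:
        sol = solve_ivp(
            f.ode, (0.0, t_end), x0, method="LSODA",
            rtol=1e-8, atol=1e-8 * scales,
        )
        x = np.maximum(sol.y[:, -1], 0.0)
        rel = np.abs(f._eval(x)) / (f._k * x + 1e-9)
        if not sol.success or np.max(rel) > 1e-6:
            n_flagged += 1
            continue
        # polish with a Newton step so clusters collapse exactly
        polished = find_steady_states(
            circuit, n_starts=1, seed=0, tol=tol, extra_starts=[x], rhs=f
        )
        if polished:
            lx = np.log(np.maximum(x, 1e-12))
            nearest = min(polished, key=lambda s: _log_distance(lx, s.log_levels()))
            endpoints.append(np.asarray(nearest.levels))
        else:
            endpoints.append(x)
    if n_flagged:
        logger.warning(
            "%d/%d trajectories had not relaxed after %.0f h and were excluded",
            n_flagged, n_grid, t_end,
        )
    unique = _dedup(endpoints)
    states = [_make_state(f, x) for x in unique]
    states = [s for s in states if s.is_stable]
    states.sort(key=lambda s: s["zeb_mrna"] if "zeb_mrna" in s.species else s.levels[0])
    return states


def classify_phenotype(state: SteadyState, context=None) -> PhenotypeCall:
    """EMT phenotype of a stable state from its ZEB mRNA level.

    ``context`` may be a BifurcationDiagram; states in the 100-200
    molecule gap then inherit the label of the branch they lie on.
    """
    if not state.is_stable:
        raise ValueError("phenotype labels apply to stable states only")
    m = state["zeb_mrna"]
    lo, hi = HYBRID_ZEB_MRNA
    if m < E_MAX_ZEB_MRNA:
        return PhenotypeCall("E", "threshold")
    if lo <= m <= hi:
        return PhenotypeCall("E/M", "threshold")
    if m > hi:
        return PhenotypeCall("M", "threshold")
    # gap between E and E/M bands
    if context is not None:
        label = context.branch_label_for(state)
        if label is not None:
            return PhenotypeCall(label, "branch_continuity")
    midpoint = 0.5 * (E_MAX_ZEB_MRNA + lo)
    return PhenotypeCall("E" if m < midpoint else "E/M", "nearest_band")
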
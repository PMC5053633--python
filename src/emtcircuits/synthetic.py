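"""Synthetic parameter sets and initial-condition ensembles.

The robustness analysis perturbs every continuous kinetic constant by an
independent multiplicative factor drawn uniformly from
``[1 - fraction, 1 + fraction]`` and re-evaluates the qualitative
features of the circuit (number of coexisting states, existence and
width of the monostable-hybrid window, phase-map areas).  Three naming
conventions alter the rule where a plain factor would break a
:class:`~emtcircuits.params.ParameterSet` invariant:

* Hill coefficients (``*_n``, ``*_nsites``) are integers and held fixed;
* fold changes (``*_lambda``) are perturbed as ``lambda ** u`` with
  ``u ~ U[1 - fraction, 1 + fraction]`` so an inhibitor can never cross
  1 and become an activator;
* binding-model ladders (``*_l``, ``*_gamma``, ``*_gamma_mu``) receive a
  single common factor per vector (clipped into [0, 1] for translation
  factors) so their monotonicity is preserved; the protected entries
  ``l_0 = 1`` and ``gamma_0 = 0`` are untouched.

Initial-condition ensembles are log-uniform per species with
role-specific physiological ceilings (proteins ~10^6-10^7, mRNAs
~10^3-10^4, miRNAs ~10^4-10^5 molecules per cell).
"""

from __future__ import annotations

import copy
import logging
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .bifurcation import (
    hybrid_existence_interval,
    monostable_hybrid_interval,
    sweep_input,
)
from .circuits import CircuitSpec
from .params import ParameterSet

__all__ = [
    "perturb_parameters",
    "sample_initial_conditions",
    "sensitivity_scan",
    "ROLE_BOUNDS",
    "SENSITIVITY_FEATURES",
]

logger = logging.getLogger(__name__)

#: log-uniform sampling bounds per species role (molecules per cell)
ROLE_BOUNDS = {
    "protein": (1.0, 6e6),
    "mRNA": (1.0, 1e4),
    "miRNA": (1.0, 1e5),
}

SENSITIVITY_FEATURES = (
    "max_stable_count",
    "has_monostable_hybrid",
    "hybrid_region_width",
    "em_area_fraction",
)


def perturb_parameters(
    base: ParameterSet,
    fraction: float = 0.1,
    n_sets: int = 100,
    seed: int = 0,
) -> list[ParameterSet]:
    """``n_sets`` uniformly perturbed copies of ``base`` (seeded)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_sets):
        vals = copy.deepcopy(base.values)
        for name in sorted(vals):
            if name.endswith("_n") or name.endswith("_nsites"):
                continue
            u = float(rng.uniform(1.0 - fraction, 1.0 + fraction))
            v = vals[name]
            if name.endswith("_lambda"):
                vals[name] = float(v) ** u
            elif name.endswith(("_l", "_gamma", "_gamma_mu")):
                vec = list(v)
                scaled = [vec[0]] + [x * u for x in vec[1:]]
                if name.endswith("_l"):
                    scaled = [min(max(x, 0.0), 1.0) for x in scaled]
                    scaled = [scaled[0]] + [
                        min(scaled[j], scaled[j - 1]) for j in range(1, len(scaled))
                    ]
                vals[name] = tuple(scaled)
            else:
                vals[name] = float(v) * u
        out.append(
            ParameterSet(values=vals, provenance=f"perturbed(seed={seed + i}, fraction={fraction})")
        )
    return out


def sample_initial_conditions(
    circuit: CircuitSpec, n: int, seed: int = 0
) -> np.ndarray:
    """Log-uniform initial states over role-specific physiological ranges."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    names = circuit.dynamical_species
    lo = np.empty(len(names))
    hi = np.empty(len(names))
    for i, name in enumerate(names):
        role = circuit.species[name].role
        lo[i], hi[i] = ROLE_BOUNDS[role]
    u = rng.random((n, len(names)))
    return np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))


def _feature_values(
    circuit: CircuitSpec,
    features: Sequence[str],
    sweep_grid: np.ndarray,
    seed: int,
    n_starts: int,
    em_area_fn: Optional[Callable[[CircuitSpec, int], float]] = None,
) -> dict:
    diagram = sweep_input(circuit, "snail", sweep_grid, seed=seed, n_starts=n_starts)
    out = {}
    for feat in features:
        if feat == "max_stable_count":
            out[feat] = max(
                (len(ss) for ss in diagram.stable_sets()), default=0
            )
        elif feat == "has_monostable_hybrid":
            out[feat] = monostable_hybrid_interval(diagram)[0] > 0
        elif feat == "hybrid_region_width":
            out[feat] = hybrid_existence_interval(diagram)[0]
        elif feat == "em_area_fraction":
            if em_area_fn is None:
                raise ValueError(
                    "em_area_fraction requires an em_area_fn(circuit, seed) callable"
                )
            out[feat] = em_area_fn(circuit, seed)
        else:
            raise ValueError(f"unknown feature {feat!r}")
    return out


def sensitivity_scan(
    circuit_builder: Callable[[ParameterSet], CircuitSpec],
    sets: Sequence[ParameterSet],
    features: Sequence[str] = ("max_stable_count", "has_monostable_hybrid",
                               "hybrid_region_width"),
    seed: int = 0,
    sweep_grid: Optional[Sequence[float]] = None,
    n_starts: int = 25,
    baseline: Optional[ParameterSet] = None,
    width_rtol: float = 0.5,
    em_area_fn: Optional[Callable[[CircuitSpec, int], float]] = None,
) -> tuple[pd.DataFrame, dict]:
    """Qualitative features per perturbed set, with retention fractions.

    A feature is *retained* when it matches the baseline qualitatively:
    equality for counts and booleans, agreement of presence plus
    relative width within ``width_rtol`` for interval widths, absolute
    difference below 0.1 for area fractions.  Returns the per-set table
    and a summary with retention fractions and the exclusion count.
    """
    unknown = set(features) - set(SENSITIVITY_FEATURES)
    if unknown:
        raise ValueError(f"unknown features: {sorted(unknown)}")
    base = baseline or ParameterSet.baseline()
    grid = (
        np.asarray(sweep_grid, dtype=float)
        if sweep_grid is not None
        else np.linspace(120e3, 600e3, 40)
    )
    ref = _feature_values(
        circuit_builder(base), features, grid, seed, n_starts, em_area_fn
    )

    rows = []
    n_failed = 0
    for i, pset in enumerate(sets):
        try:
            vals = _feature_values(
                circuit_builder(pset), features, grid, seed + 7919 * (i + 1),
                n_starts, em_area_fn,
            )
        except Exception as exc:
            logger.warning("set %d failed and is excluded: %s", i, exc)
            n_failed += 1
            continue
        vals["set_index"] = i
        vals["provenance"] = pset.provenance
        rows.append(vals)
    table = pd.DataFrame(rows)

    retention = {}
    for feat in features:
        if table.empty:
            retention[feat] = float("nan")
            continue
        col = table[feat]
        if feat in ("max_stable_count", "has_monostable_hybrid"):
            kept = (col == ref[feat]).mean()
        elif feat == "hybrid_region_width":
            if ref[feat] > 0:
                kept = (
                    (col > 0)
                    & ((col - ref[feat]).abs() <= width_rtol * ref[feat])
                ).mean()
            else:
                kept = (col == 0).mean()
        else:  # em_area_fraction
            kept = ((col - ref[feat]).abs() < 0.1).mean()
        retention[feat] = float(kept)

    summary = {
        "baseline": {k: (float(v) if not isinstance(v, bool) else v) for k, v in ref.items()},
        "retention": retention,
        "n_sets": len(sets),
        "n_excluded": n_failed,
    }
    return table, summary
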
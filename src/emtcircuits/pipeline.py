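"""Run orchestration: configs in, tables + summaries + figures out.

A :class:`RunConfig` names a circuit variant, an analysis kind and its
grids/inputs; :func:`run` executes it and writes, into the output
directory:

* ``states.tsv`` / ``cells.tsv`` — tidy tables of steady states or
  phase-map cells (tab-separated, one header line, units in molecules
  and hours);
* ``summary.json`` — the machine-readable quantities the analysis
  produces (region labels, interval widths, area fractions, retention
  fractions);
* ``figure.png`` / ``figure.svg`` — the corresponding diagram;
* ``resolved_config.yaml`` and ``run.log`` — full provenance (inputs,
  seed, package version, timings, solver statistics).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .bifurcation import (
    emt_onset_threshold,
    hybrid_existence_interval,
    label_regions,
    monostable_hybrid_interval,
    sweep_input,
)
from .circuits import CIRCUIT_VARIANTS, MotifSpec, build_circuit
from .params import ParameterSet
from .phase_maps import em_area_fraction, motif_phase_diagram, stemness_phase_diagram
from .steady_states import classify_phenotype
from .synthetic import perturb_parameters, sensitivity_scan

__all__ = ["RunConfig", "run", "compare_runs"]

logger = logging.getLogger(__name__)

ANALYSES = ("bifurcation", "stemness_phase", "motif_phase", "sensitivity")


@dataclass
class RunConfig:
    """Validated description of one analysis run."""

    analysis: str
    variant: str = "core"
    seed: int = 0
    outdir: str = "run_output"
    param_file: Optional[str] = None
    # sweep / grid specifications
    snail_min: float = 120e3
    snail_max: float = 600e3
    n_points: int = 100
    alpha_points: int = 41
    lambda_min: float = 0.2
    lambda_max: float = 5.0
    lambda_points: int = 21
    n_starts: int = 40
    # fixed inputs and couplings
    snail: float = 200e3
    nfkb: float = 25e3
    sa: float = 0.0
    si: float = 0.0
    alpha1: float = 0.0
    alpha2: float = 0.0
    # motif overrides
    motif_psf: str = "grhl2"
    motif_kind: str = "self"  # self | to_mir200
    motif_remove_zeb_feedback: bool = False
    motif_partner: str = "zeb"
    motif_outputs: str = "inhibit"
    # sensitivity
    n_sets: int = 100
    fraction: float = 0.1

    def __post_init__(self) -> None:
        errors = []
        if self.analysis not in ANALYSES:
            errors.append(f"analysis must be one of {ANALYSES}, got {self.analysis!r}")
        if self.variant not in CIRCUIT_VARIANTS:
            errors.append(
                f"variant must be one of {CIRCUIT_VARIANTS}, got {self.variant!r}"
            )
        if self.n_points < 2:
            errors.append("n_points must be >= 2")
        if not 0 < self.fraction < 1:
            errors.append("fraction must lie in (0, 1)")
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def params(self) -> ParameterSet:
        if self.param_file:
            return ParameterSet.from_yaml(self.param_file)
        return ParameterSet.baseline()


def _write_resolved(config: RunConfig, outdir: Path) -> None:
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


def _states_table(diagram) -> pd.DataFrame:
    rows = []
    for value, states in zip(diagram.grid, diagram.states_per_point):
        for s in states:
            row = {
                diagram.swept_input: value,
                "stability": s.stability,
                "residual_norm": s.residual_norm,
            }
            row.update({f"level_{n}": lv for n, lv in zip(s.species, s.levels)})
            if s.is_stable:
                row["phenotype"] = classify_phenotype(s, context=diagram).label
            rows.append(row)
    return pd.DataFrame(rows)


def _plot_bifurcation(diagram, regions, path_base: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for branch in diagram.branches:
        xs = diagram.grid[branch.grid_indices] / 1e3
        ys = [s["zeb_mrna"] for s in branch.states]
        stable = branch.states[0].is_stable
        ax.plot(xs, ys, "b-" if stable else "r:", lw=1.8 if stable else 1.2)
    for r in regions:
        if "E/M" in r.phases:
            ax.axvspan(r.interval[0] / 1e3, r.interval[1] / 1e3,
                       color="green", alpha=0.12, lw=0)
        if r.phases == frozenset({"E/M"}):
            ax.axvspan(r.interval[0] / 1e3, r.interval[1] / 1e3,
                       facecolor="none", edgecolor="k", ls="--", lw=1.0)
    ax.set_xlabel(f"{diagram.swept_input} (10^3 molecules)")
    ax.set_ylabel("ZEB mRNA (molecules)")
    ax.set_title(diagram.circuit_name)
    fig.tight_layout()
    fig.savefig(path_base.with_suffix(".png"), dpi=150)
    fig.savefig(path_base.with_suffix(".svg"))
    plt.close(fig)


def _phase_to_str(phase) -> str:
    return "{" + ",".join(sorted(phase)) + "}" if phase else "{}"


def _cells_table(diagram) -> pd.DataFrame:
    rows = []
    for i, v1 in enumerate(diagram.axis1_grid):
        for j, v2 in enumerate(diagram.axis2_grid):
            row = {
                diagram.axis1_name: v1,
                diagram.axis2_name: v2,
                "phase": _phase_to_str(diagram.phases[i][j]),
            }
            if diagram.window_phases is not None:
                row["window_phase"] = _phase_to_str(diagram.window_phases[i][j])
            rows.append(row)
    return pd.DataFrame(rows)


def _plot_phase_map(diagram, path_base: Path, window: bool = False) -> None:
    table = diagram.window_phases if window else diagram.phases
    keys = sorted({_phase_to_str(c) for row in table for c in row})
    index = {k: i for i, k in enumerate(keys)}
    img = np.array(
        [[index[_phase_to_str(c)] for c in row] for row in table], dtype=float
    )
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    im = ax.imshow(
        img.T, origin="lower", aspect="auto",
        extent=(diagram.axis1_grid[0], diagram.axis1_grid[-1],
                diagram.axis2_grid[0], diagram.axis2_grid[-1]),
        cmap="viridis", vmin=0, vmax=max(len(keys) - 1, 1),
    )
    cbar = fig.colorbar(im, ax=ax, ticks=range(len(keys)))
    cbar.ax.set_yticklabels(keys, fontsize=7)
    ax.set_xlabel(diagram.axis1_name)
    ax.set_ylabel(diagram.axis2_name)
    fig.tight_layout()
    fig.savefig(path_base.with_suffix(".png"), dpi=150)
    fig.savefig(path_base.with_suffix(".svg"))
    plt.close(fig)


def run(config: RunConfig) -> Path:
    """Execute one analysis; returns the output directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    log_lines = [
        f"emtcircuits {__version__}",
        f"analysis={config.analysis} variant={config.variant} seed={config.seed}",
    ]
    _write_resolved(config, outdir)
    params = config.params()
    summary: dict[str, Any] = {
        "analysis": config.analysis,
        "variant": config.variant,
        "seed": config.seed,
    }

    if config.analysis == "bifurcation":
        circuit = build_circuit(
            config.variant, params=params, snail=config.snail,
            sa=config.sa, si=config.si, alpha1=config.alpha1,
            alpha2=config.alpha2, nfkb=config.nfkb,
        )
        grid = np.linspace(config.snail_min, config.snail_max, config.n_points)
        diagram = sweep_input(circuit, "snail", grid, seed=config.seed,
                              n_starts=config.n_starts)
        regions = label_regions(diagram)
        mono_w, mono_iv = monostable_hybrid_interval(diagram)
        ex_w, ex_iv = hybrid_existence_interval(diagram)
        try:
            onset = emt_onset_threshold(diagram)
        except ValueError:
            onset = None
        _states_table(diagram).to_csv(outdir / "states.tsv", sep="\t", index=False)
        _plot_bifurcation(diagram, regions, outdir / "figure")
        summary.update({
            "regions": [
                {"interval": list(r.interval), "phases": sorted(r.phases)}
                for r in regions
            ],
            "monostable_hybrid_width": mono_w,
            "monostable_hybrid_intervals": [list(iv) for iv in mono_iv],
            "hybrid_existence_width": ex_w,
            "hybrid_existence_intervals": [list(iv) for iv in ex_iv],
            "emt_onset_threshold": (
                None if onset is None
                else ("beyond_grid" if np.isinf(onset) else onset)
            ),
            "n_holes": len(diagram.holes()),
        })
        log_lines.append(
            f"swept {len(grid)} points, {len(diagram.branches)} branches, "
            f"{len(diagram.fold_estimates)} folds"
        )

    elif config.analysis == "stemness_phase":
        base_variant = "grhl2" if config.variant in ("grhl2", "stemness_grhl2") else "core"
        circuit = build_circuit(base_variant, params=params, snail=config.snail,
                                sa=config.sa, si=config.si)
        alphas = np.linspace(0.0, 1.0, config.alpha_points)
        diagram = stemness_phase_diagram(
            circuit, alphas, alphas, snail=config.snail, nfkb=config.nfkb,
            seed=config.seed, n_starts=config.n_starts, params=params,
        )
        _cells_table(diagram).to_csv(outdir / "cells.tsv", sep="\t", index=False)
        _plot_phase_map(diagram, outdir / "figure", window=True)
        phases_seen = sorted({
            _phase_to_str(c) for row in diagram.window_phases for c in row
        })
        summary.update({
            "window": diagram.metadata["window"],
            "window_phases_seen": phases_seen,
            "area_tristable_window": diagram.phase_area(
                {"E", "E/M", "M"}, in_window=True
            ),
            "area_exclusive_hybrid_window": diagram.phase_area(
                {"E/M"}, in_window=True
            ),
            "n_failures": len(diagram.failures),
        })

    elif config.analysis == "motif_phase":
        circuit = build_circuit(config.variant, params=params, snail=config.snail,
                                sa=config.sa, si=config.si)
        lam_grid = np.geomspace(config.lambda_min, config.lambda_max,
                                config.lambda_points)
        sn_grid = np.linspace(config.snail_min, config.snail_max, config.n_points)
        psf = config.motif_psf

        def motif_for(lv: float) -> MotifSpec:
            kw: dict[str, Any] = dict(
                psf=psf,
                remove_zeb_feedback=config.motif_remove_zeb_feedback,
                partner=config.motif_partner,
                outputs=config.motif_outputs,
            )
            if config.motif_kind == "self":
                kw["self_lambda"] = lv
            else:
                kw["to_mir200_lambda"] = lv
            return MotifSpec(**kw)

        diagram = motif_phase_diagram(
            circuit, motif_for, lam_grid, sn_grid,
            seed=config.seed, n_starts=config.n_starts,
        )
        _cells_table(diagram).to_csv(outdir / "cells.tsv", sep="\t", index=False)
        _plot_phase_map(diagram, outdir / "figure")
        summary.update({
            "em_area_contains": em_area_fraction(diagram, "contains_EM"),
            "em_area_only": em_area_fraction(diagram, "only_EM"),
            "n_failures": len(diagram.failures),
        })

    else:  # sensitivity
        sets = perturb_parameters(
            params, fraction=config.fraction, n_sets=config.n_sets,
            seed=config.seed,
        )
        grid = np.linspace(config.snail_min, config.snail_max, 40)

        def builder(p: ParameterSet):
            return build_circuit(config.variant, params=p, snail=config.snail)

        table, scan_summary = sensitivity_scan(
            builder, sets, seed=config.seed, sweep_grid=grid,
            baseline=params,
        )
        table.to_csv(outdir / "features.tsv", sep="\t", index=False)
        summary.update(scan_summary)
        summary["fraction"] = config.fraction

    summary["elapsed_seconds"] = round(time.time() - t0, 2)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    log_lines.append(f"done in {summary['elapsed_seconds']}s")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return outdir


def compare_runs(run_a, run_b) -> dict:
    """Difference report between two runs of the same analysis kind."""
    a = json.loads((Path(run_a) / "summary.json").read_text())
    b = json.loads((Path(run_b) / "summary.json").read_text())
    if a["analysis"] != b["analysis"]:
        raise ValueError(
            f"cannot compare {a['analysis']} run with {b['analysis']} run"
        )
    report: dict[str, Any] = {
        "analysis": a["analysis"],
        "variants": [a["variant"], b["variant"]],
    }
    numeric_keys = {
        "bifurcation": ["monostable_hybrid_width", "hybrid_existence_width"],
        "stemness_phase": ["area_tristable_window", "area_exclusive_hybrid_window"],
        "motif_phase": ["em_area_contains", "em_area_only"],
        "sensitivity": [],
    }[a["analysis"]]
    for key in numeric_keys:
        report[f"delta_{key}"] = b.get(key, 0) - a.get(key, 0)
    if a["analysis"] == "sensitivity":
        report["retention_a"] = a.get("retention")
        report["retention_b"] = b.get("retention")
    cells_a, cells_b = Path(run_a) / "cells.tsv", Path(run_b) / "cells.tsv"
    if cells_a.exists() and cells_b.exists():
        ta = pd.read_csv(cells_a, sep="\t")
        tb = pd.read_csv(cells_b, sep="\t")
        if len(ta) == len(tb):
            report["n_cells_differing"] = int((ta["phase"] != tb["phase"]).sum())
    return report
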
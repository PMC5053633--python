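"""Named kinetic parameter tables.

A :class:`ParameterSet` is a flat mapping from constant names to values.
Naming conventions carry the semantics used by the perturbation and
circuit-building machinery:

* ``g_*``      production rates, molecules/hour
* ``k_*``      degradation rates, per hour
* ``*_x0``     shifted-Hill thresholds, molecules
* ``*_n``      Hill coefficients (integers, never perturbed)
* ``*_lambda`` fold changes (dimensionless; perturbed on the log scale so
  an inhibitor can never turn into an activator)
* ``bind_*_l`` / ``bind_*_gamma``  miRNA binding-model ladders (tuples;
  perturbed by a single common factor to preserve their monotonicity)
* ``bind_*_mu0`` / ``bind_*_nsites``  binding-model scale and site count

The baseline values for the core miR-200/ZEB module follow the published
ternary-switch parameterization of this circuit family; PSF couplings and
the LIN28/let-7 stemness module are calibrated to reproduce the
qualitative phase structure of the coupled circuits (see docs/methods.md
for the rationale behind each block).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any, Iterator, Mapping

import yaml

from .kinetics import MiRNABindingModel, ShiftedHill

__all__ = ["ParameterSet", "baseline_parameters"]


# --- baseline table ---------------------------------------------------------

#: Core miR-200/ZEB/SNAIL ternary switch (molecules, hours).
_CORE = {
    "g_mir200": 2100.0,
    "g_zeb_mrna": 11.0,
    "g_zeb": 100.0,  # protein per mRNA per hour
    "k_mir200": 0.05,
    "k_zeb_mrna": 0.5,
    "k_zeb": 0.1,
    # ZEB protein represses miR-200 transcription
    "zeb_mir200_lambda": 0.1,
    "zeb_mir200_x0": 220e3,
    "zeb_mir200_n": 3,
    # SNAIL represses miR-200 transcription
    "snail_mir200_lambda": 0.1,
    "snail_mir200_x0": 180e3,
    "snail_mir200_n": 2,
    # ZEB protein self-activates its own transcription
    "zeb_zeb_mrna_lambda": 7.5,
    "zeb_zeb_mrna_x0": 25e3,
    "zeb_zeb_mrna_n": 2,
    # SNAIL activates ZEB transcription
    "snail_zeb_mrna_lambda": 10.0,
    "snail_zeb_mrna_x0": 180e3,
    "snail_zeb_mrna_n": 2,
    # miR-200 binding on ZEB mRNA (6 sites)
    "bind_mir200_zeb_nsites": 6,
    "bind_mir200_zeb_mu0": 10e3,
    "bind_mir200_zeb_l": (1.0, 0.6, 0.3, 0.1, 0.05, 0.05, 0.05),
    "bind_mir200_zeb_gamma": (0.0, 0.04, 0.2, 1.0, 1.0, 1.0, 1.0),
    "bind_mir200_zeb_gamma_mu": (0.0, 0.005, 0.05, 0.5, 0.5, 0.5, 0.5),
}

#: GRHL2 block — mutual transcriptional inhibition with ZEB, plus the
#: optional external activation (SA) / inhibition (SI) signals acting on
#: GRHL2 production.
_GRHL2 = {
    "g_grhl2": 10e3,
    "k_grhl2": 0.1,
    # ZEB represses GRHL2 (threshold above the hybrid-state ZEB level, so
    # GRHL2 stays on through partial EMT and only shuts off in the M state)
    "zeb_grhl2_lambda": 0.08,
    "zeb_grhl2_x0": 540e3,
    "zeb_grhl2_n": 4,
    # GRHL2 represses ZEB transcription
    "grhl2_zeb_mrna_lambda": 0.35,
    "grhl2_zeb_mrna_x0": 30e3,
    "grhl2_zeb_mrna_n": 2,
    # external overexpression signal SA (activator)
    "sa_grhl2_lambda": 3.0,
    "sa_grhl2_x0": 200e3,
    "sa_grhl2_n": 2,
    # external knockdown signal SI (inhibitor)
    "si_grhl2_lambda": 0.1,
    "si_grhl2_x0": 200e3,
    "si_grhl2_n": 2,
}

#: OVOL block — mutual inhibition with ZEB, OVOL represses miR-200,
#: OVOL self-inhibits.
_OVOL = {
    "g_ovol": 10e3,
    "k_ovol": 0.1,
    "zeb_ovol_lambda": 0.08,
    "zeb_ovol_x0": 540e3,
    "zeb_ovol_n": 4,
    "ovol_zeb_mrna_lambda": 0.35,
    "ovol_zeb_mrna_x0": 30e3,
    "ovol_zeb_mrna_n": 2,
    "ovol_mir200_lambda": 0.8,
    "ovol_mir200_x0": 40e3,
    "ovol_mir200_n": 2,
    "ovol_ovol_lambda": 0.4,
    "ovol_ovol_x0": 40e3,
    "ovol_ovol_n": 2,
}

#: miR-145/OCT4 block (full 5-species variant).  The miR-145⊣ZEB arm is
#: miRNA-mediated silencing of ZEB mRNA; ZEB represses miR-145 "relatively
#: weakly" (fold change closer to 1 than ZEB⊣miR-200's 0.1).
_MIR145 = {
    "g_mir145": 8000.0,
    "k_mir145": 0.1,
    "g_oct4_psf": 20e3,
    "k_oct4_psf": 0.1,
    # weak ZEB repression of miR-145 (fold change closer to 1 than the 0.1
    # of ZEB -| miR-200, threshold above the hybrid-state ZEB level)
    "zeb_mir145_lambda": 0.45,
    "zeb_mir145_x0": 300e3,
    "zeb_mir145_n": 4,
    # OCT4 represses miR-145 (mutual inhibition, transcriptional arm)
    "oct4_mir145_lambda": 0.3,
    "oct4_mir145_x0": 100e3,
    "oct4_mir145_n": 2,
    # miR-145 represses OCT4 (effective silencing, no OCT4 mRNA modelled)
    "mir145_oct4_lambda": 0.1,
    "mir145_oct4_x0": 20e3,
    "mir145_oct4_n": 2,
    # OCT4 activates miR-200
    "oct4_mir200_lambda": 2.0,
    "oct4_mir200_x0": 100e3,
    "oct4_mir200_n": 2,
    # miR-145 binding on ZEB mRNA (2 sites)
    "bind_mir145_zeb_nsites": 2,
    "bind_mir145_zeb_mu0": 20e3,
    "bind_mir145_zeb_l": (1.0, 0.5, 0.2),
    "bind_mir145_zeb_gamma": (0.0, 0.3, 1.0),
    "bind_mir145_zeb_gamma_mu": (0.0, 0.04, 0.125),
    # effective reduced circuit: miR-145 self-activation and miR-145⊣miR-200
    "mir145_mir145_lambda": 2.0,
    "mir145_mir145_x0": 20e3,
    "mir145_mir145_n": 2,
    "mir145_mir200_lambda": 0.8,
    "mir145_mir200_x0": 20e3,
    "mir145_mir200_n": 2,
}

#: LIN28/let-7 stemness module driven by NF-kB, with the OCT4 reporter.
#: Mirrors the miRNA/mRNA/protein ternary-switch architecture of the core
#: module: let-7 silences LIN28 mRNA, LIN28 represses let-7 production,
#: LIN28 translationally self-activates and let-7 activates its own
#: processing.  NF-kB activates LIN28 transcription and represses let-7.
_STEMNESS = {
    "g_let7": 2100.0,
    "g_lin28_mrna": 11.0,
    "g_lin28": 100.0,
    "g_oct4": 40e3,
    "k_let7": 0.05,
    "k_lin28_mrna": 0.5,
    "k_lin28": 0.1,
    "k_oct4": 0.1,
    # LIN28 represses let-7 maturation
    "lin28_let7_lambda": 0.1,
    "lin28_let7_x0": 220e3,
    "lin28_let7_n": 3,
    # NF-kB represses let-7
    "nfkb_let7_lambda": 0.1,
    "nfkb_let7_x0": 17e3,
    "nfkb_let7_n": 2,
    # let-7 activates its own processing
    "let7_let7_lambda": 1.3,
    "let7_let7_x0": 20e3,
    "let7_let7_n": 2,
    # NF-kB activates LIN28 transcription
    "nfkb_lin28_mrna_lambda": 10.0,
    "nfkb_lin28_mrna_x0": 17e3,
    "nfkb_lin28_mrna_n": 2,
    # LIN28 self-activates its own transcription (ternary-switch arm)
    "lin28_lin28_mrna_lambda": 7.5,
    "lin28_lin28_mrna_x0": 25e3,
    "lin28_lin28_mrna_n": 2,
    # LIN28 translational self-activation
    "lin28_lin28_lambda": 1.3,
    "lin28_lin28_x0": 300e3,
    "lin28_lin28_n": 1,
    # LIN28 activates OCT4 (pure reporter arm; no feedback)
    "lin28_oct4_lambda": 10.0,
    "lin28_oct4_x0": 80e3,
    "lin28_oct4_n": 1,
    # let-7 binding on LIN28 mRNA (6 sites).  The degradation ladder turns
    # on late in occupancy while translation shuts down early, which
    # broadens the intermediate-LIN28 plateau of the module.
    "bind_let7_lin28_nsites": 6,
    "bind_let7_lin28_mu0": 10e3,
    "bind_let7_lin28_l": (1.0, 0.6, 0.3, 0.1, 0.05, 0.05, 0.05),
    "bind_let7_lin28_gamma": (0.0, 0.01, 0.05, 0.15, 0.4, 1.0, 1.0),
    "bind_let7_lin28_gamma_mu": (0.0, 0.001, 0.006, 0.02, 0.05, 0.12, 0.12),
    # feed-forward coupling at full strength: miR-200 represses LIN28
    "mir200_lin28_mrna_lambda": 0.05,
    "mir200_lin28_mrna_x0": 20e3,
    "mir200_lin28_mrna_n": 1,
    # feed-backward coupling at full strength: let-7 represses ZEB (via HMGA2)
    "let7_zeb_mrna_lambda": 0.3,
    "let7_zeb_mrna_x0": 25e3,
    "let7_zeb_mrna_n": 4,
}


def baseline_parameters() -> dict[str, Any]:
    """A fresh copy of the full baseline table."""
    table: dict[str, Any] = {}
    for block in (_CORE, _GRHL2, _OVOL, _MIR145, _STEMNESS):
        table.update(copy.deepcopy(block))
    return table


# --- ParameterSet -----------------------------------------------------------


@dataclass
class ParameterSet(Mapping):
    """A named table of kinetic constants with a provenance tag.

    Behaves as a read-only mapping; helpers assemble the typed kinetic
    objects (:class:`ShiftedHill`, :class:`MiRNABindingModel`) used by
    the circuit builders.
    """

    values: dict[str, Any] = field(default_factory=baseline_parameters)
    provenance: str = "baseline"

    def __post_init__(self) -> None:
        self.validate()

    # Mapping protocol
    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)

    # typed accessors ------------------------------------------------------
    def hill(self, link: str) -> ShiftedHill:
        """Build the shifted Hill for a named link, e.g. ``'zeb_mir200'``."""
        try:
            return ShiftedHill(
                threshold=float(self.values[f"{link}_x0"]),
                hill_coefficient=int(self.values[f"{link}_n"]),
                fold_change=float(self.values[f"{link}_lambda"]),
            )
        except KeyError as exc:
            raise KeyError(f"parameter table is missing constant {exc.args[0]!r}")

    def binding(self, pair: str) -> MiRNABindingModel:
        """Build the binding model for a named pair, e.g. ``'mir200_zeb'``."""
        try:
            return MiRNABindingModel(
                n_sites=int(self.values[f"bind_{pair}_nsites"]),
                mu0=float(self.values[f"bind_{pair}_mu0"]),
                silencing_rates=tuple(self.values[f"bind_{pair}_gamma"]),
                translation_factors=tuple(self.values[f"bind_{pair}_l"]),
                consumption_rates=tuple(
                    self.values.get(f"bind_{pair}_gamma_mu", ())
                ),
            )
        except KeyError as exc:
            raise KeyError(f"parameter table is missing constant {exc.args[0]!r}")

    # validation -----------------------------------------------------------
    def validate(self) -> None:
        for name, value in self.values.items():
            if name.endswith("_n") or name.endswith("_nsites"):
                if int(value) != value or value < 1 and name.endswith("_n"):
                    raise ValueError(f"{name} must be a positive integer, got {value}")
            elif name.endswith(("_l", "_gamma", "_gamma_mu")):
                continue  # ladder invariants are enforced by MiRNABindingModel
            else:
                if not float(value) > 0:
                    raise ValueError(f"{name} must be positive, got {value}")

    # io --------------------------------------------------------------------
    def replace(self, **updates: Any) -> "ParameterSet":
        """A copy with named constants overridden."""
        unknown = set(updates) - set(self.values)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        vals = copy.deepcopy(self.values)
        vals.update(updates)
        return ParameterSet(values=vals, provenance=f"{self.provenance}+override")

    def to_yaml(self, path) -> None:
        doc = {
            "provenance": self.provenance,
            "units": "molecules, hours",
            "values": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in sorted(self.values.items())
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        vals = {
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in doc["values"].items()
        }
        return cls(values=vals, provenance=doc.get("provenance", str(path)))

    @classmethod
    def baseline(cls) -> "ParameterSet":
        return cls()
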
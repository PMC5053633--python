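"""Declarative construction of EMT decision circuits and their ODEs.

A :class:`CircuitSpec` lists species, shifted-Hill regulatory links,
miRNA-mRNA binding interactions and fixed external inputs.  Builders
assemble the variants analysed in this package:

* the core miR-200/ZEB switch driven by SNAIL,
* the same core coupled to a phenotypic stability factor (GRHL2, OVOL,
  or miR-145/OCT4 in full or effectively reduced form),
* the EMT module coupled to the LIN28/let-7 stemness module through the
  feed-forward (miR-200 ⊣ LIN28, strength ``alpha1``) and feed-backward
  (let-7 ⊣ ZEB, strength ``alpha2``) links,
* hypothetical network-motif edits (PSF self-regulation, PSF ⊣ miR-200,
  removal of the ZEB → PSF feedback, and the two control rewirings).

:func:`build_rhs` turns a spec into the time-derivative function of the
mass-action / shifted-Hill rate equations: every species' production is
its basal rate times the product of the shifted Hill factors of its
transcriptional regulators; proteins translate from their mRNA scaled by
the occupancy-averaged translation factor ``L``; mRNA-miRNA pairs add
the active silencing loss ``m * Ym(mu)`` and the miRNA consumption
``m * Ymu(mu)``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace as dc_replace
from typing import Optional, Sequence

import numpy as np

from .kinetics import MiRNABindingModel, ShiftedHill, mirna_modulation, shifted_hill
from .params import ParameterSet

__all__ = [
    "Species",
    "RegulatoryLink",
    "BindingInteraction",
    "MotifSpec",
    "CircuitSpec",
    "CircuitRHS",
    "build_core_emt",
    "extend_with_psf",
    "extend_with_stemness",
    "apply_motif",
    "build_circuit",
    "build_rhs",
    "PSF_VARIANTS",
    "CIRCUIT_VARIANTS",
]

_ROLES = ("miRNA", "mRNA", "protein", "external_input")


@dataclass(frozen=True)
class Species:
    """A circuit node.

    Dynamical species carry a basal production rate ``g`` (molecules/h)
    and a degradation rate ``k`` (per hour); proteins translated from an
    explicit mRNA name it in ``translated_from`` (their ``g`` is then
    molecules per mRNA per hour).  External inputs carry a fixed
    ``level`` and no dynamics.
    """

    name: str
    role: str
    g: float = 0.0
    k: float = 1.0
    level: Optional[float] = None
    translated_from: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "external_input":
            if self.level is None or self.level < 0:
                raise ValueError(f"external input {self.name} needs a level >= 0")
        else:
            if self.g < 0 or not self.k > 0:
                raise ValueError(
                    f"species {self.name}: need g >= 0 and k > 0, got g={self.g}, k={self.k}"
                )

    @property
    def is_dynamic(self) -> bool:
        return self.role != "external_input"


@dataclass(frozen=True)
class RegulatoryLink:
    """A shifted-Hill link modulating the target's production rate."""

    source: str
    target: str
    hill: ShiftedHill
    kind: str = "transcriptional"

    def __post_init__(self) -> None:
        if self.kind not in ("transcriptional", "translational"):
            raise ValueError(f"unknown link kind {self.kind!r}")


@dataclass(frozen=True)
class BindingInteraction:
    """miRNA-mediated silencing of one mRNA by one miRNA."""

    mirna: str
    mrna: str
    model: MiRNABindingModel


@dataclass(frozen=True)
class MotifSpec:
    """A hypothetical or control edit of a PSF-coupled circuit.

    ``self_lambda`` sets the PSF self-regulation fold change (>1
    activation, <1 inhibition, =1 none); ``to_mir200_lambda`` adds a
    PSF ⊣ miR-200 link; ``remove_zeb_feedback`` deletes the ZEB → PSF
    inhibitory arm; ``partner='mir200'`` rewires the PSF's mutual
    inhibition from ZEB to miR-200 (control motif); ``outputs='activate'``
    flips the PSF's outgoing inhibitions into activations (control
    motif).
    """

    psf: str
    self_lambda: Optional[float] = None
    to_mir200_lambda: Optional[float] = None
    remove_zeb_feedback: bool = False
    partner: str = "zeb"
    outputs: str = "inhibit"

    def __post_init__(self) -> None:
        if self.partner not in ("zeb", "mir200"):
            raise ValueError(f"unknown partner {self.partner!r}")
        if self.outputs not in ("inhibit", "activate"):
            raise ValueError(f"unknown outputs mode {self.outputs!r}")


@dataclass
class CircuitSpec:
    """A complete circuit: species, links, binding models, fixed inputs."""

    name: str
    species: dict[str, Species]
    links: list[RegulatoryLink] = field(default_factory=list)
    bindings: list[BindingInteraction] = field(default_factory=list)
    alpha1: Optional[float] = None
    alpha2: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # --- structure --------------------------------------------------------
    def validate(self) -> None:
        for link in self.links:
            for end in (link.source, link.target):
                if end not in self.species:
                    raise ValueError(
                        f"link {link.source}->{link.target} references "
                        f"undeclared species {end!r}"
                    )
            if not self.species[link.target].is_dynamic:
                raise ValueError(f"link target {link.target!r} is an external input")
        for b in self.bindings:
            if b.mirna not in self.species or b.mrna not in self.species:
                raise ValueError(
                    f"binding {b.mirna}:{b.mrna} references undeclared species"
                )
            if self.species[b.mirna].role != "miRNA":
                raise ValueError(f"{b.mirna} is not a miRNA")
            if self.species[b.mrna].role != "mRNA":
                raise ValueError(f"{b.mrna} is not an mRNA")
        for alpha in (self.alpha1, self.alpha2):
            if alpha is not None and not 0.0 <= alpha <= 1.0:
                raise ValueError(f"coupling strength must lie in [0, 1], got {alpha}")
        for sp in self.species.values():
            if sp.translated_from is not None and sp.translated_from not in self.species:
                raise ValueError(
                    f"{sp.name} translated from undeclared mRNA {sp.translated_from!r}"
                )

    @property
    def dynamical_species(self) -> list[str]:
        return [s.name for s in self.species.values() if s.is_dynamic]

    @property
    def input_levels(self) -> dict[str, float]:
        return {
            s.name: s.level for s in self.species.values() if not s.is_dynamic
        }

    def edges(self) -> set[tuple[str, str, str]]:
        """All (source, target, kind) edges incl. miRNA-mediated ones."""
        out = {(l.source, l.target, l.kind) for l in self.links}
        out |= {(b.mirna, b.mrna, "miRNA_mediated") for b in self.bindings}
        return out

    # --- edits ------------------------------------------------------------
    def copy(self) -> "CircuitSpec":
        return CircuitSpec(
            name=self.name,
            species=dict(self.species),
            links=list(self.links),
            bindings=list(self.bindings),
            alpha1=self.alpha1,
            alpha2=self.alpha2,
            metadata=copy.deepcopy(self.metadata),
        )

    def with_inputs(self, **levels: float) -> "CircuitSpec":
        """A copy with external input levels replaced."""
        new = self.copy()
        for name, level in levels.items():
            if name not in new.species or new.species[name].is_dynamic:
                raise KeyError(f"{name!r} is not an external input of {self.name}")
            new.species[name] = dc_replace(new.species[name], level=float(level))
        return new


# --- builders ---------------------------------------------------------------

PSF_VARIANTS = ("grhl2", "ovol", "mir145_full", "mir145_effective")


def _link(params: ParameterSet, source: str, target: str, key: str,
          kind: str = "transcriptional",
          lambda_override: Optional[float] = None) -> RegulatoryLink:
    hill = params.hill(key)
    if lambda_override is not None:
        hill = ShiftedHill(hill.threshold, hill.hill_coefficient, lambda_override)
    return RegulatoryLink(source=source, target=target, hill=hill, kind=kind)


def build_core_emt(params: Optional[ParameterSet] = None,
                   snail: float = 200e3) -> CircuitSpec:
    """The SNAIL-driven miR-200/ZEB ternary switch.

    Dynamical species: miR-200, ZEB mRNA, ZEB protein.  SNAIL activates
    ZEB transcription and represses miR-200; ZEB represses miR-200 and
    self-activates its own transcription; miR-200 silences ZEB mRNA via
    the six-site binding model.
    """
    p = params or ParameterSet.baseline()
    species = {
        "mir200": Species("mir200", "miRNA", g=p["g_mir200"], k=p["k_mir200"]),
        "zeb_mrna": Species("zeb_mrna", "mRNA", g=p["g_zeb_mrna"], k=p["k_zeb_mrna"]),
        "zeb": Species("zeb", "protein", g=p["g_zeb"], k=p["k_zeb"],
                       translated_from="zeb_mrna"),
        "snail": Species("snail", "external_input", level=float(snail)),
    }
    links = [
        _link(p, "zeb", "mir200", "zeb_mir200"),
        _link(p, "snail", "mir200", "snail_mir200"),
        _link(p, "zeb", "zeb_mrna", "zeb_zeb_mrna"),
        _link(p, "snail", "zeb_mrna", "snail_zeb_mrna"),
    ]
    bindings = [BindingInteraction("mir200", "zeb_mrna", p.binding("mir200_zeb"))]
    return CircuitSpec(name="core", species=species, links=links,
                       bindings=bindings, metadata={"variant": "core"})


def extend_with_psf(core: CircuitSpec, psf: str,
                    sa: float = 0.0, si: float = 0.0,
                    params: Optional[ParameterSet] = None,
                    allow_both_signals: bool = False) -> CircuitSpec:
    """Couple a phenotypic stability factor to the miR-200/ZEB core.

    ``psf`` is one of ``grhl2`` (mutual inhibition with ZEB, optional
    external SA/SI signals on GRHL2 production), ``ovol`` (mutual
    inhibition with ZEB, OVOL ⊣ miR-200, OVOL self-inhibition),
    ``mir145_full`` (miR-145/OCT4 mutual inhibition, miR-145 ⇄ ZEB
    double-negative loop, OCT4 → miR-200) or ``mir145_effective``
    (reduced 3-node form with miR-145 self-activation and miR-145 ⊣
    miR-200).
    """
    if psf not in PSF_VARIANTS:
        raise ValueError(f"unknown PSF variant {psf!r}; pick one of {PSF_VARIANTS}")
    if {"mir200", "zeb_mrna", "zeb"} - set(core.species):
        raise ValueError("PSF coupling requires the miR-200/ZEB core circuit")
    if sa > 0 and si > 0 and not allow_both_signals:
        raise ValueError(
            "SA and SI are analysed separately; pass allow_both_signals=True "
            "to combine them"
        )
    p = params or ParameterSet.baseline()
    c = core.copy()
    c.name = f"{core.name}+{psf}"
    c.metadata = {**c.metadata, "variant": psf, "psf": psf}

    if psf == "grhl2":
        c.species["grhl2"] = Species("grhl2", "protein", g=p["g_grhl2"], k=p["k_grhl2"])
        c.species["sa"] = Species("sa", "external_input", level=float(sa))
        c.species["si"] = Species("si", "external_input", level=float(si))
        c.links += [
            _link(p, "zeb", "grhl2", "zeb_grhl2"),
            _link(p, "grhl2", "zeb_mrna", "grhl2_zeb_mrna"),
            _link(p, "sa", "grhl2", "sa_grhl2"),
            _link(p, "si", "grhl2", "si_grhl2"),
        ]
    elif psf == "ovol":
        c.species["ovol"] = Species("ovol", "protein", g=p["g_ovol"], k=p["k_ovol"])
        c.links += [
            _link(p, "zeb", "ovol", "zeb_ovol"),
            _link(p, "ovol", "zeb_mrna", "ovol_zeb_mrna"),
            _link(p, "ovol", "mir200", "ovol_mir200"),
            _link(p, "ovol", "ovol", "ovol_ovol"),
        ]
    elif psf == "mir145_full":
        c.species["mir145"] = Species("mir145", "miRNA", g=p["g_mir145"], k=p["k_mir145"])
        c.species["oct4"] = Species("oct4", "protein", g=p["g_oct4_psf"], k=p["k_oct4_psf"])
        c.links += [
            _link(p, "zeb", "mir145", "zeb_mir145"),
            _link(p, "oct4", "mir145", "oct4_mir145"),
            _link(p, "mir145", "oct4", "mir145_oct4"),
            _link(p, "oct4", "mir200", "oct4_mir200"),
        ]
        c.bindings.append(
            BindingInteraction("mir145", "zeb_mrna", p.binding("mir145_zeb"))
        )
    else:  # mir145_effective
        c.species["mir145"] = Species("mir145", "miRNA", g=p["g_mir145"], k=p["k_mir145"])
        c.links += [
            _link(p, "zeb", "mir145", "zeb_mir145"),
            _link(p, "mir145", "mir145", "mir145_mir145"),
            _link(p, "mir145", "mir200", "mir145_mir200"),
        ]
        c.bindings.append(
            BindingInteraction("mir145", "zeb_mrna", p.binding("mir145_zeb"))
        )
    c.validate()
    return c


def _alpha_lambda(full_lambda: float, alpha: float) -> float:
    """Interpolate an inhibitory fold change on the log scale.

    ``alpha = 0`` gives ``lambda = 1`` (link absent), ``alpha = 1`` the
    full tabulated fold change.
    """
    return float(full_lambda) ** float(alpha)


def extend_with_stemness(circuit: CircuitSpec, alpha1: float, alpha2: float,
                         nfkb: float = 25e3,
                         params: Optional[ParameterSet] = None) -> CircuitSpec:
    """Couple the LIN28/let-7 stemness module to an EMT circuit.

    Adds let-7, LIN28 mRNA, LIN28 protein and the OCT4 reporter, driven
    by NF-kB.  The EMT and stemness modules couple through miR-200 ⊣
    LIN28 (strength ``alpha1``) and let-7 ⊣ ZEB via HMGA2, lumped into a
    single transcriptional link (strength ``alpha2``); the OCT4 →
    miR-200 feedback is deliberately absent.
    """
    if not (0.0 <= alpha1 <= 1.0 and 0.0 <= alpha2 <= 1.0):
        raise ValueError(f"alpha1/alpha2 must lie in [0, 1], got {alpha1}, {alpha2}")
    if {"mir200", "zeb_mrna", "zeb"} - set(circuit.species):
        raise ValueError("stemness coupling requires the miR-200/ZEB core")
    if "oct4" in circuit.species:
        raise ValueError("circuit already carries an OCT4 species")
    p = params or ParameterSet.baseline()
    c = circuit.copy()
    c.name = f"{circuit.name}+stemness"
    c.alpha1, c.alpha2 = float(alpha1), float(alpha2)
    c.metadata = {**c.metadata, "stemness": True}
    c.species["let7"] = Species("let7", "miRNA", g=p["g_let7"], k=p["k_let7"])
    c.species["lin28_mrna"] = Species("lin28_mrna", "mRNA",
                                      g=p["g_lin28_mrna"], k=p["k_lin28_mrna"])
    c.species["lin28"] = Species("lin28", "protein", g=p["g_lin28"], k=p["k_lin28"],
                                 translated_from="lin28_mrna")
    c.species["oct4"] = Species("oct4", "protein", g=p["g_oct4"], k=p["k_oct4"])
    c.species["nfkb"] = Species("nfkb", "external_input", level=float(nfkb))
    c.links += [
        _link(p, "lin28", "let7", "lin28_let7"),
        _link(p, "nfkb", "let7", "nfkb_let7"),
        _link(p, "let7", "let7", "let7_let7"),
        _link(p, "nfkb", "lin28_mrna", "nfkb_lin28_mrna"),
        _link(p, "lin28", "lin28_mrna", "lin28_lin28_mrna"),
        _link(p, "lin28", "lin28", "lin28_lin28", kind="translational"),
        _link(p, "lin28", "oct4", "lin28_oct4"),
        # feed-forward coupling, alpha1-scaled
        _link(p, "mir200", "lin28_mrna", "mir200_lin28_mrna",
              lambda_override=_alpha_lambda(p["mir200_lin28_mrna_lambda"], alpha1)),
        # feed-backward coupling, alpha2-scaled
        _link(p, "let7", "zeb_mrna", "let7_zeb_mrna",
              lambda_override=_alpha_lambda(p["let7_zeb_mrna_lambda"], alpha2)),
    ]
    c.bindings.append(BindingInteraction("let7", "lin28_mrna", p.binding("let7_lin28")))
    c.validate()
    return c


def apply_motif(circuit: CircuitSpec, motif: MotifSpec) -> CircuitSpec:
    """Apply a hypothetical or control motif edit to a PSF-coupled circuit."""
    psf = motif.psf
    if psf not in circuit.species:
        raise ValueError(f"motif references absent species {psf!r}")
    c = circuit.copy()
    c.metadata = {**c.metadata, "motif": motif}
    links = list(c.links)

    if motif.remove_zeb_feedback:
        kept = [l for l in links if not (l.source == "zeb" and l.target == psf)]
        if len(kept) == len(links):
            raise ValueError(f"no ZEB -> {psf} feedback link to remove")
        links = kept

    if motif.partner == "mir200":
        # control: PSF's mutual inhibition partner is miR-200, not ZEB
        new_links = []
        for l in links:
            if l.source == "zeb" and l.target == psf:
                new_links.append(dc_replace(l, source="mir200"))
            elif l.source == psf and l.target == "zeb_mrna":
                new_links.append(dc_replace(l, target="mir200"))
            else:
                new_links.append(l)
        links = new_links

    if motif.outputs == "activate":
        # control: flip the PSF's outgoing inhibitions into activations
        new_links = []
        for l in links:
            if l.source == psf and l.target != psf and l.hill.fold_change < 1:
                flipped = ShiftedHill(l.hill.threshold, l.hill.hill_coefficient,
                                      1.0 / l.hill.fold_change)
                new_links.append(dc_replace(l, hill=flipped))
            else:
                new_links.append(l)
        links = new_links

    if motif.self_lambda is not None:
        self_hill = ShiftedHill(
            threshold=circuit.metadata.get("motif_self_x0", 40e3),
            hill_coefficient=2,
            fold_change=float(motif.self_lambda),
        )
        links = [l for l in links if not (l.source == psf and l.target == psf)]
        links.append(RegulatoryLink(psf, psf, self_hill))

    if motif.to_mir200_lambda is not None:
        if not motif.to_mir200_lambda < 1:
            raise ValueError("the hypothetical PSF -| miR-200 link is inhibitory")
        hill = ShiftedHill(threshold=40e3, hill_coefficient=2,
                           fold_change=float(motif.to_mir200_lambda))
        links.append(RegulatoryLink(psf, "mir200", hill))

    c.links = links
    c.validate()
    return c


def build_circuit(variant: str, params: Optional[ParameterSet] = None,
                  snail: float = 200e3, sa: float = 0.0, si: float = 0.0,
                  alpha1: float = 0.0, alpha2: float = 0.0,
                  nfkb: float = 25e3) -> CircuitSpec:
    """Build a named circuit variant (CLI/config entry point)."""
    p = params or ParameterSet.baseline()
    core = build_core_emt(p, snail=snail)
    if variant == "core":
        return core
    if variant in PSF_VARIANTS:
        return extend_with_psf(core, variant, sa=sa, si=si, params=p)
    if variant == "stemness":
        return extend_with_stemness(core, alpha1, alpha2, nfkb=nfkb, params=p)
    if variant == "stemness_grhl2":
        g = extend_with_psf(core, "grhl2", sa=sa, si=si, params=p)
        return extend_with_stemness(g, alpha1, alpha2, nfkb=nfkb, params=p)
    raise ValueError(f"unknown circuit variant {variant!r}")


CIRCUIT_VARIANTS = ("core",) + PSF_VARIANTS + ("stemness", "stemness_grhl2")


# --- RHS assembly -----------------------------------------------------------


class CircuitRHS:
    """Compiled time-derivative evaluator for a circuit.

    Callable as ``rhs(y)`` with ``y`` the state vector ordered as
    ``rhs.species``.  Species with no outgoing influence (pure reporters,
    e.g. OCT4 when its feedback to miR-200 is ignored) are detected and
    listed in ``downstream``; :func:`downstream_levels` computes their
    steady levels from an upstream fixed point.
    """

    def __init__(self, circuit: CircuitSpec):
        self.circuit = circuit
        self.species: list[str] = circuit.dynamical_species
        self._index = {name: i for i, name in enumerate(self.species)}
        inputs = circuit.input_levels

        # Per-species production terms: (basal g incl. constant input Hills,
        # [(regulator index, hill), ...]); and loss structure.
        n = len(self.species)
        self._g = np.zeros(n)
        self._k = np.zeros(n)
        self._hills: list[list[tuple[int, ShiftedHill]]] = [[] for _ in range(n)]
        self._mrna_of: list[Optional[int]] = [None] * n
        # bindings indexed by mRNA: (mirna_idx, model); and by miRNA
        self._silencing: list[list[tuple[int, MiRNABindingModel]]] = [[] for _ in range(n)]
        self._consumption: list[list[tuple[int, MiRNABindingModel]]] = [[] for _ in range(n)]

        for i, name in enumerate(self.species):
            sp = circuit.species[name]
            self._g[i] = sp.g
            self._k[i] = sp.k
            if sp.translated_from is not None:
                self._mrna_of[i] = self._index[sp.translated_from]

        for link in circuit.links:
            ti = self._index[link.target]
            if link.source in inputs:
                self._g[ti] *= shifted_hill(inputs[link.source], link.hill)
            else:
                self._hills[ti].append((self._index[link.source], link.hill))

        for b in circuit.bindings:
            mi = self._index[b.mrna]
            ui = self._index[b.mirna]
            self._silencing[mi].append((ui, b.model))
            self._consumption[ui].append((mi, b.model))

        # downstream reporters: no outgoing hills, no binding participation
        influencing = set()
        for tgt, hills in enumerate(self._hills):
            for src, _ in hills:
                influencing.add(src)
        for i in range(n):
            if self._silencing[i] or self._consumption[i]:
                influencing.add(i)
            if self._mrna_of[i] is not None:
                influencing.add(self._mrna_of[i])
        self.downstream = [s for i, s in enumerate(self.species) if i not in influencing]
        self._downstream_idx = [self._index[s] for s in self.downstream]
        self.upstream = [s for s in self.species if s not in self.downstream]

    # -- evaluation ---------------------------------------------------------
    def __call__(self, y: Sequence[float]) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if y.shape != (len(self.species),):
            raise ValueError(
                f"state vector must have length {len(self.species)}, got {y.shape}"
            )
        if np.any(y < 0):
            raise ValueError("state vector must be non-negative")
        return self._eval(y)

    def _eval(self, y: np.ndarray) -> np.ndarray:
        n = len(self.species)
        # cache (L, Ym, Ymu) per binding model evaluation
        dydt = np.empty(n)
        mod_cache: dict[tuple[int, int], tuple[float, float, float]] = {}

        def modulation(mirna_idx: int, mrna_idx: int, model: MiRNABindingModel):
            key = (mirna_idx, mrna_idx)
            if key not in mod_cache:
                mod_cache[key] = mirna_modulation(y[mirna_idx], model)
            return mod_cache[key]

        for i in range(n):
            prod = self._g[i]
            for src, hill in self._hills[i]:
                prod *= shifted_hill(y[src], hill)
            mi = self._mrna_of[i]
            if mi is not None:
                prod *= y[mi]
                for ui, model in self._silencing[mi]:
                    L, _, _ = modulation(ui, mi, model)
                    prod *= L
            loss = self._k[i] * y[i]
            for ui, model in self._silencing[i]:  # i is an mRNA
                _, Ym, _ = modulation(ui, i, model)
                loss += y[i] * Ym
            for mi2, model in self._consumption[i]:  # i is a miRNA
                _, _, Ymu = modulation(i, mi2, model)
                loss += y[mi2] * Ymu
            dydt[i] = prod - loss
        return dydt

    def ode(self, t: float, y: np.ndarray) -> np.ndarray:
        """solve_ivp-compatible signature; clips tiny negative excursions."""
        return self._eval(np.maximum(y, 0.0))

    # -- helpers ------------------------------------------------------------
    def scales(self) -> np.ndarray:
        """Rough per-species steady-level ceilings (g_eff/k), used for
        initial-condition sampling and residual normalization."""
        n = len(self.species)
        out = np.empty(n)
        for i in range(n):
            g, k = self._g[i], self._k[i]
            lam_max = 1.0
            for _, hill in self._hills[i]:
                lam_max *= max(1.0, hill.fold_change)
            mi = self._mrna_of[i]
            if mi is not None:
                gm, km = self._g[mi], self._k[mi]
                lam_m = 1.0
                for _, h in self._hills[mi]:
                    lam_m *= max(1.0, h.fold_change)
                g = g * (gm * lam_m / km)
            out[i] = g * lam_max / k
        return out

    def downstream_levels(self, y: np.ndarray) -> np.ndarray:
        """Steady levels of pure reporter species given the rest of ``y``.

        Valid because reporters have linear degradation and no feedback:
        ``x* = production(y) / k``.
        """
        y = np.array(y, dtype=float)
        for i in self._downstream_idx:
            prod = self._g[i]
            for src, hill in self._hills[i]:
                prod *= shifted_hill(y[src], hill)
            mi = self._mrna_of[i]
            if mi is not None:
                prod *= y[mi]
                for ui, model in self._silencing[mi]:
                    prod *= mirna_modulation(y[ui], model)[0]
            y[i] = prod / self._k[i]
        return y

    def jacobian(self, y: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
        """Central-difference Jacobian at ``y``."""
        y = np.asarray(y, dtype=float)
        n = len(y)
        J = np.empty((n, n))
        for j in range(n):
            h = rel_step * max(abs(y[j]), 1.0)
            yp, ym = y.copy(), y.copy()
            yp[j] += h
            ym[j] = max(ym[j] - h, 0.0)
            J[:, j] = (self._eval(yp) - self._eval(ym)) / (yp[j] - ym[j])
        return J


def build_rhs(circuit: CircuitSpec) -> CircuitRHS:
    """Compile a circuit into its time-derivative evaluator."""
    return CircuitRHS(circuit)
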
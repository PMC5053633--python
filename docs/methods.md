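# Methods

## Model structure

The package models small gene-regulatory circuits as deterministic ODEs
in molecule counts per cell, with rates per hour. Two kinetic
primitives generate every term:

* **Shifted Hill regulation.** A regulator X multiplies its target's
  production by `H(X) = (1 + λ(X/X0)^n)/(1 + (X/X0)^n)`. H is bounded
  by `[min(1,λ), max(1,λ)]`, equals 1 at X = 0, and reduces to the
  identity when λ = 1, which is how "link absent" is represented
  throughout the motif scans.
* **Binomial miRNA silencing.** A miRNA bound to n sites on a target
  mRNA occupies each site independently with probability
  `(μ/μ0)/(1+μ/μ0)`. Occupancy level *i* attenuates translation by
  `l_i` (non-increasing, `l_0 = 1`) and degrades the mRNA at `γ_i`
  (non-decreasing, `γ_0 = 0`); each degradation event at level *i*
  consumes *i* miRNAs at a separate, smaller rate ladder `γμ_i`
  (catalytic recycling makes miRNA turnover slower than target
  turnover). Occupancy weights are computed through the per-site
  probability, so arbitrarily large `μ/μ0` cannot overflow.

An mRNA m silenced by miRNA μ loses `m·Ym(μ)`; the miRNA loses
`m·Yμ(μ)`; the protein translates at `g·m·L(μ)`. The two-timescale
asymmetry between `γ` and `γμ` is what produces the intermediate branch
of the miRNA/TF ternary switch: without it the miR-200/ZEB circuit is
only bistable.

## Circuits

`build_core_emt` assembles the SNAIL-driven miR-200/ZEB switch (miR-200,
ZEB mRNA, ZEB protein; SNAIL activates ZEB and represses miR-200; ZEB
represses miR-200 and self-activates; miR-200 silences ZEB mRNA on six
sites). The core kinetic constants are the published values of the
ternary-switch framework this circuit family descends from and are all
exposed in `ParameterSet.baseline()` (`params.py`); tests pin them.

Phenotype labels follow ZEB mRNA: E below 100 molecules, E/M within
200–450, M above 450. Stable states falling in the 100–200 gap inherit
the label of their bifurcation branch when a diagram is available,
otherwise the nearest band (split at 150).

PSF variants add GRHL2 (mutual transcriptional repression with ZEB,
optional external activation SA / inhibition SI multipliers on GRHL2
production), OVOL (mutual repression with ZEB, OVOL ⊣ miR-200, OVOL
self-repression), or miR-145/OCT4 (mutual repression, miR-145 ⇄ ZEB
double-negative loop with a two-site binding model, OCT4 → miR-200).
The reduced miR-145 variant replaces the OCT4 arm with effective
miR-145 self-activation and a weak miR-145 ⊣ miR-200 link. PSF coupling
constants are not published as printed tables; they were calibrated
once so the coupled circuits reproduce the documented qualitative
response structure — a monostable-{E/M} window present in every
PSF-coupled circuit and absent from the core, with wider hybrid
existence — and then frozen. The load-bearing choice is that ZEB's
repression of the PSF has a threshold *above* the hybrid-state ZEB
level (e.g. 540×10³ molecules for GRHL2, Hill 4): the PSF stays active
through partial EMT, suppresses the mesenchymal branch at intermediate
SNAIL, and shuts off only after full EMT. The "weak" ZEB ⊣ miR-145 arm
keeps its fold change at 0.45, closer to 1 than the 0.1 of
ZEB ⊣ miR-200.

The stemness module mirrors the core architecture: let-7 (miRNA), LIN28
mRNA, LIN28 protein, driven by NF-κB (activates LIN28, represses
let-7), with LIN28 translational self-activation and let-7
self-processing activation, plus an OCT4 reporter activated by LIN28
with no feedback. Its let-7 silencing ladder shuts translation down
early in occupancy but degrades the mRNA only at high occupancy, which
broadens the intermediate-LIN28 plateau; the module is a ternary switch
whose low/intermediate/high LIN28 states map onto OCT4 below, inside
and above the stemness window. EMT and stemness couple through
miR-200 ⊣ LIN28 (α1) and let-7 ⊣ ZEB, with HMGA2 lumped into a single
transcriptional link (α2). A coupling strength α scales the link's fold
change on the log scale, `λ(α) = λ_full^α`, so α = 0 is exactly the
absent link and α = 1 the full tabulated strength.

The stemness window is the open interval (0.25, 0.65) of OCT4 relative
to its saturation level, computed (never hand-set) by clamping LIN28 at
its production ceiling and letting OCT4 relax; both bounds are
config-exposed because the window is likely context-specific. The
strong-coupling operating points (α1 = α2 = 0.8, NF-κB = 25×10³
molecules, SNAIL = 220×10³ without GRHL2 and 440×10³ with GRHL2) pin
the module calibration: the first reproduces the full expected pattern
(E, E/M and M coexist; E/M and M lie in the window, E below it). At the
second, the exclusive association of the window with E/M and the
exclusion of M are reproduced, but the epithelial state does not
coexist there in this reconstruction: restoring E at that SNAIL
requires strong let-7-mediated ZEB suppression, which forces E's module
partner into the LIN28-low state whose OCT4 sits at the reporter floor,
and no monotone OCT4(LIN28) map can simultaneously place that state
inside the window, keep the first operating point's E outside, and
separate the two M states. This is a known limitation of the
transcriptional-link coupling used here (see Limitations).

Motif edits (`apply_motif`) add or remove hypothetical links on a
PSF-coupled circuit: PSF self-regulation λ across inhibition and
activation, a PSF ⊣ miR-200 link, removal of the ZEB → PSF feedback,
and the two control rewirings (mutual inhibition with miR-200 instead
of ZEB; outgoing inhibitions flipped to activations).

## Numerics

* **Root finding.** `find_steady_states` runs Powell-hybrid root
  searches in log-level coordinates (positivity by construction, and
  the four decades between miRNA and protein scales become additive).
  The residual solved is the per-species relative rate `ẋ/(k·x)`; a
  root is accepted when the raw residual satisfies
  `max|ẋ| < 10⁻³ molecules/h` or the relative rate falls below
  `10⁻⁶/h`. Starts are log-uniform over `[1, 10·g_eff/k]` per species.
  Pure reporter species (OCT4 in the stemness circuits) are detected
  structurally and solved after the feedback core, shrinking the search
  dimension.
* **Dedup and stability.** Roots merge when their relative log-level
  distance is below 10⁻³. Stability comes from central-difference
  Jacobian eigenvalues with a 10⁻⁶/h margin; one positive real part is
  a saddle, more is unstable; both plot as unstable.
* **Integration oracle.** `attractors_by_integration` relaxes LSODA
  trajectories for 4000 h (two hundred times the slowest degradation
  timescale) from log-uniform initial ensembles, discards and logs
  endpoints whose relative rate exceeds 10⁻⁶/h, polishes with one root
  solve, and clusters. It shares no code path with the multistart
  search beyond the derivative function itself and is used as the
  independent cross-check, never the primary solver.
* **Sweeps.** Bifurcation sweeps warm-start each grid point from its
  predecessor's states and re-solve with tripled starts whenever a
  point finds fewer states than its neighbour (branch-dropout guard).
  Branches link by nearest-neighbour matching in mean log-level
  distance (threshold 0.35 per step); folds are estimated at the
  midpoint of the bracketing grid interval. Dense sweeps with warm
  starts replace formal pseudo-arclength continuation; the
  grid-refinement test checks that fold estimates are stable to one
  coarse-grid step.
* **Phase maps.** 2-D maps traverse the grid row-wise reusing
  neighbouring cells' solutions as warm starts. Default map sizes are
  13×13 for the (α1, α2) stemness maps and 9×20 for the motif panels —
  the coarsest grids at which the reported areas and monotonicity
  statements are resolved; both are parameters, and the CLI default for
  production maps is 41×41. Monotonicity of the E/M-area fraction is
  asserted modulo one grid cell.

## Synthetic parameter sets

`perturb_parameters` multiplies every continuous constant by an
independent factor uniform in `[1−f, 1+f]` (default f = 0.1, exposed and
reported). Two exceptions preserve structural invariants: fold changes
perturb as `λ^u` with `u ~ U[1−f, 1+f]`, so a repressor can never cross
1 and become an activator; binding-ladder vectors receive one common
factor (translation ladders additionally clipped into [0, 1]), so their
monotonicity survives. Hill coefficients and site counts are integers
and stay fixed. Initial-condition ensembles are log-uniform per species
with role-specific ceilings (proteins 6×10⁶, mRNAs 10⁴, miRNAs 10⁵
molecules), matching typical eukaryotic copy-number estimates.

The sensitivity scan re-evaluates qualitative features (maximum
coexisting-state count, presence of the monostable-hybrid window,
hybrid-existence width, E/M-area fraction) per perturbed set and
reports per-feature retention against baseline: exact match for counts
and booleans, presence plus width within ±50% for interval widths,
±0.1 absolute for area fractions. Solver failures exclude the set and
are counted, never silently dropped.

What the generator does *not* emulate: correlated parameter changes
(all factors are independent), cell-to-cell stochasticity and molecular
noise (the model is deterministic), and transcriptional bursting. A
passing scan therefore demonstrates robustness of the deterministic
phase structure to moderate kinetic uncertainty, not robustness of
single-cell phenotypes to intrinsic noise.

## Limitations

* PSF and stemness coupling constants are this package's calibrated
  reconstruction, not published measurements; the qualitative phase
  structure is the calibration target and the quantitative interval
  widths carry no error bars.
* The feed-forward/feed-backward couplings are effective shifted-Hill
  links. Modelling them as explicit miRNA-binding interactions (with
  consumption terms) would add degrees of freedom this reconstruction
  lacks — most visibly at the GRHL2 strong-coupling operating point,
  where the epithelial state fails to coexist (see above).
* The robustness scan at ±10% retains the monostable-hybrid window in
  only about half of the perturbed GRHL2 circuits; the window's
  location in SNAIL drifts with the kinetic constants, so
  qualitative-feature retention is sensitive to how the sweep range is
  chosen.
* SNAIL and NF-κB are fixed inputs; their upstream modules (miR-34,
  inflammatory feedback) are out of scope, as are ΔNp63α/Slug circuits
  and tissue-specific GRHL2 → OVOL feed-forward wiring.
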
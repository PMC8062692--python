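# Methods

## Model representation

A model is a list of metabolites (each tagged with a compartment: cytosol,
plastid, mitochondrion, or external), a list of reactions with signed
stoichiometries, flux bounds in mmol·gDW⁻¹·day⁻¹, reversibility flags, flat
gene lists, a category (`biochemical`, `transport_exchange`, `auxiliary`) and
an optional pathway tag. One reaction is designated the biomass objective and
one the substrate uptake, with its measured rate stored on the model. The
growth-associated maintenance coefficient S_GAM (mmol ATP·gDW⁻¹ per unit
biomass) lives inside the biomass stoichiometry as an ATP → ADP conversion and
is mutable, so calibration scans rewrite it in place.

Gene associations are treated as unordered sets: expression aggregation takes
the maximum over a reaction's genes (any one expressed isozyme suffices to
activate the reaction), so boolean AND/OR structure in input SBML is flattened
to the union of leaf genes with a logged warning. When bounds are absent,
irreversible reactions default to [0, 1000] and reversible ones to
[−1000, 1000]; absolute flux values (not activity calls) depend on this cap.

I/O formats are SBML L3 with the `fbc` extension (bounds as shared parameters,
genes as `fbc` gene products, category/pathway and uptake/GAM metadata in
notes elements) and a plain JSON dialect. Both round-trip exactly; the SBML
writer's output is also readable by an independent parser (verified against
cobrapy in the test suite, which is used only as a cross-check, never as the
implementation).

## Expression processing

FPKM tables are gene × sample matrices (non-negative, unique gene ids).
Within a dataset, replicates are mean-aggregated (median available). The
coefficient of variation is `100·sd/mean` with the sample (n−1) standard
deviation; the consensus gene set across datasets keeps genes whose
replicate-mean FPKM exceeds an "expressed" floor (default 1 FPKM — the floor
is not fixed by any standard, so it is configurable) in *every* dataset and
whose cross-dataset CV of dataset means is below 25 %.

Percentile ranks use the mid-rank convention:
`rank(v) = (#below + 0.5·#ties excluding self) / n`, giving values in [0, 1)
with ties sharing a rank and order preserved. Ranks are computed over the raw
(max-gene, sample-aggregated) values of all gene-associated reactions, so the
rank vector is comparable across datasets with different FPKM scales. Model
genes missing from an expression table count as 0 FPKM with a warning; zero
overlap between model and table genes is an error.

## The flux programs

All programs share `S·v = 0` plus bounds; LPs are solved with HiGHS through
SciPy. Degenerate optima are reported as the solver's vertex — LP-based
non-zero flux counts are therefore solver-dependent, which is why tests
compare objectives and activity calls, never whole flux vectors.

**FBA / FVA.** Plain biomass maximization with optional point fixes (e.g. the
measured uptake). FVA re-solves two LPs per reaction with the objective held
at a fraction (default 1.0) of its optimum; a reaction is flagged
*substitutable* when its range still has width at the fixed optimum and
touches or spans zero — it can be switched off while an alternative route
carries the flux.

**GIMME.** Penalties `c_j = max(x_threshold − x_j, 0)` for gene-associated
reactions (zero otherwise), threshold expressed as a percentile of the rank
distribution (25/50/75 conventionally). The program minimizes `Σ c_j |v_j|`
with *both* growth and uptake fixed to their measured values — the package's
reading of "simulate at the measured physiology"; the canonical
fraction-of-optimum variant (biomass ≥ fraction × FBA optimum) is available
via a parameter. Absolute values are handled by splitting every flux into
non-negative forward/backward parts; penalized reactions that still carry
flux above tolerance are returned as *recovered* (feasibility forced them).
Penalties never relax stoichiometry: an unreachable growth fix raises an
infeasibility error.

**E-Flux.** Bounds of gene-associated reactions become
`[0, x_j·ub_j]` (irreversible) or `[−x_j·|lb_j|, x_j·ub_j]` (reversible);
gene-free reactions stay constraint-free; uptake is fixed; biomass is
maximized. Raising any single rank can only enlarge the polytope, so maximum
growth is monotone non-decreasing in each rank (property-tested).

**HPCOF.** Minimizes `Σ_j φ(v_j − x̃_j) + w·‖v‖₁` subject to the steady state
and expression-derived bounds, with the Huber penalty (`δ = 1`, `w = 1` —
no alternative weights are published for this construction) and targets
`x̃_j = rank_j · flux_scale`. Growth is **not** fixed: it emerges from the
optimization and is matched to the observed rate by S_GAM calibration.
Uptake is fixed (without any driving constraint the all-zero flux vector
would be optimal).

Two unit-reconciliation questions are genuinely open in this construction,
and both policies are implemented:

* *Target scale.* Ranks are dimensionless while fluxes carry units. Default
  `flux_scale = uptake rate`, which makes targets commensurate with the flux
  scale of the network; any numeric scale (e.g. 1.0 for literal rank targets)
  can be passed.
* *Bound policy.* Default `"eflux"` (rank × original bound). The literal
  alternative — capping fluxes at `x̃_j` itself (`"expression"`) — is also
  implemented, but with a fixed uptake it is infeasible whenever an essential
  reaction's rank satisfies `rank · flux_scale < uptake`, so it is not the
  default; it is the right setting for small dimensionless examples and is
  what the one-degree-of-freedom oracle test uses.

Because `|u| ≤ δ` switching makes the objective only C¹, the solver works on
an exact smooth reformulation: `φ_δ(u) = min_z (u − z)² + 2δ|z|`, with `z`
and `v` split into non-negative parts. The result is a convex QP with a
constant Hessian, solved by a deterministic cascade — SLSQP, then the
trust-region constrained solver with the exact Hessian, then SLSQP warm-started
from the trust-region iterate — accepting only solutions that are feasible
(equality residual < 1e−8, bounds respected) and converged. Optimality is
cross-checked in tests by a 1-D grid-search oracle on one-degree-of-freedom
networks (1e−3) and by dominance over 100 random feasible points (convex
combinations of random-objective LP vertices) on the synthetic bundle.

## Evaluation

The evaluation universe is the gene-associated *biochemical* reactions;
transport/exchange and auxiliary reactions carry no expression evidence and
are excluded. A reaction is flux-active when `|v_j| > 1e−6` (above LP noise,
far below any meaningful flux at the models' scale) and expression-active
when its rank strictly exceeds the percentile threshold (strict `>` applied
uniformly at 25/50/75). Confusion counts treat *active* as the positive
class; undefined ratios (empty denominators) are reported as NaN rather than
silently zeroed. The SSD compares percentile ranks of |v| with percentile
ranks of expression over the same universe and sums the squared differences;
the evaluated subset is a parameter.

Cross-method comparison intersects the active sets ("core" reactions active
under every method) and reports per-method exclusive sets. Multi-omics
verification marks a reaction transcript-/protein-verified when any
associated gene appears in the respective evidence set and
metabolite-verified when any non-currency substrate or product was detected;
*integrated-verified* requires all three layers **and** a flux-active
prediction — an intersection rule, chosen as the most conservative
combination. Currency metabolites (ATP, ADP, AMP, NAD(P)(H), Pi, PPi, H₂O,
H⁺, CO₂, O₂, CoA; configurable) are excluded from metabolite matching so
that ubiquitous cofactors do not trivially verify every reaction.

## S_GAM calibration and sensitivity

Raising S_GAM makes biomass more ATP-expensive, so predicted growth is
monotone non-increasing in S_GAM for these programs; calibration bisects on
S_GAM until the percent error `ε = 100·(v_p − v_o)/v_o` is within tolerance
(default 0.1 %), after validating that the bracket straddles the observed
rate rather than assuming it. The sensitivity scan re-solves the chosen
method on an S_GAM grid and reports the widest contiguous interval with
`|ε| ≤ 20 %`, locating the band edges by linear interpolation between grid
points. For GIMME the scanned quantity is the fraction-of-optimum variant's
growth (the fixed-growth variant has no growth to predict); for HPCOF it is
the emergent biomass flux.

## Synthetic data

The generator builds a three-compartment network that mirrors, at desk scale,
the architecture the methods are meant for: sucrose uptake feeding a
cytosolic glycolysis-like chain; an oxidative pentose-phosphate-like branch
that loses CO₂ (0.8 carbon yield), supplies a biomass precursor (so the
branch is genuinely active in truth) and returns carbon to the chain through
a carbon-wasteful leg that a growth-maximizing FBA always avoids; a
mitochondrial TCA-like cycle paying 2 ATP per pyruvate; substitutable
parallel isozyme pairs with one silent member; a dead-end side reaction; a
plastidic starch route; a biomass reaction consuming starch, pyruvate,
alanine, pentose phosphate and S_GAM ATP; and a non-gene maintenance ATPase
that lets surplus carbon be respired when both uptake and growth are fixed.
Default sizes give 23 gene-associated biochemical reactions (20 active, 3
silent) with 1–3 dedicated genes each; conditions are uptake 10, observed
growth 4.5, S_GAM 6 (all in the model's mmol·gDW⁻¹·day⁻¹ scale). The maximum
growth of the default topology has the closed form
`g_max = 6·u/(S_GAM + 5.375)`, used as an exact FBA oracle.

Expression is log-normal and bimodal: active genes around ln 50 FPKM, silent
genes around ln 0.5, gene-level spread 0.4 (log scale), 10 % replicate CV,
small cross-dataset variation except for a 10 % fraction of genes given large
dataset swings to exercise the consensus filter. Omics evidence derives from
the truth with configurable protein/metabolite dropout. All randomness flows
from one integer seed through a named generator; the same seed reproduces the
model JSON byte for byte.

What the generator does *not* emulate: realistic pathway sizes or real
expression values, shared genes between reactions (isozyme sets are
disjoint), post-transcriptional regulation (expression is a perfect proxy for
truth up to noise), transporter genes, or thermodynamic constraints. Passing
recovery tests therefore shows that the programs identify an activity pattern
that is *encodable* in expression ranks — not that expression suffices on
real data, where the same programs can legitimately disagree with the
transcriptome.

## Problem sizes and determinism

The test suite and the acceptance script run the full pipeline on the default
synthetic bundle (31 reactions, 23 evaluated) plus analytic toys of 2–8
reactions — sizes chosen so every check has an exact or brute-force oracle.
Oracle tolerances: GIMME vs an independently encoded epigraph LP, 1e−8;
HPCOF vs the 1-D grid, 1e−3; FBA vs closed forms, 1e−8. The pinned bundle
seed is 17 (with expression at seed + 1 and omics at seed + 2), matching the
CLI example; the acceptance script derives all seeds from its `--seed`
argument the same way. Reported LP flux vectors are deterministic for a fixed
SciPy/HiGHS version; objectives and activity calls are stable across
versions.

## Known limitations

* GIMME/E-Flux activity counts can shift between LP solvers on degenerate
  networks (alternate optima); only HPCOF's convex program pins the flux
  vector itself.
* The HPCOF target/bound unit reconciliation is a modeling choice (see
  above); conclusions about absolute flux magnitudes should not be read off
  either policy.
* The consensus "expressed" floor (1 FPKM) materially affects gene counts on
  real data.
* No loopless/thermodynamic constraints: futile cycles are only suppressed
  indirectly (by the L1 term in HPCOF and penalties in GIMME).
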
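# Methods

## Mass model

Muropeptide masses are built from seven free-molecule residue formulas
(GlcNAc C₈H₁₅NO₆, MurNAc C₁₁H₁₉NO₈, Ala C₃H₇NO₂, iGlu C₅H₉NO₄,
DAP C₇H₁₄N₂O₄, Lys C₆H₁₄N₂O₂, Arg C₆H₁₄N₄O₂). Every condensation bond —
peptide, isopeptide (DAP→Lys), glycosidic, lactyl-amide — removes exactly one
water; borohydride reduction of MurNAc to muramitol adds H₂ (+2.0157 Da).
Atomic masses: ¹H 1.0078250319, ¹²C 12 (exact), ¹³C 13.0033548378,
¹⁴N 14.0030740052, ¹⁵N 15.0001088984, ¹⁶O 15.9949146221 Da, giving heavy
shifts Δ¹³C = 1.0033548 and Δ¹⁵N = 0.9970349 per atom.

Isotope labeling is moiety-wise: the Tri→KR molecule is partitioned into a
stem moiety (GlcNAc, MurNAc, Ala, iGlu, DAP) and an Lpp moiety (Lys, Arg),
each independently light or heavy. Full enrichment is assumed, so a heavy
moiety's shift is `n_C·Δ¹³C + n_N·Δ¹⁵N` over its residues' atoms; water
bookkeeping never touches the shift because water carries no C or N.
Consequences used as self-checks: the two hybrid parental masses sum to the
all-light plus all-heavy masses, and the all-heavy/all-light difference of any
fragment equals the whole fragment's shift.

All masses are neutral monoisotopic values; protonation
(`m/z = (M + k·1.007276)/k`) is display-only. MS² fragments are treated as
hydrolytic condensation products (no a/b/y proton bookkeeping), which
reproduces the published 7-row ladder at 2 decimals; values are rounded
half-up for table display and compared at ±0.01 Da. Isotopologue column
order in the theoretical grid — (light,light), (light stem, heavy Lpp),
(heavy stem, light Lpp), (heavy,heavy) — was fixed by mass arithmetic: the
+18.02 column shift is the Lys-Arg (C₁₂N₆) moiety shift and +40.09 the stem
(C₃₄N₆) shift. Sub-100 % isotope purity is not modeled in masses; it would
appear as satellite peaks that the monoisotopic, single-peak-per-species
representation deliberately omits.

## Peak assignment and quantification

Inputs are deisotoped neutral-mass peak lists. MS1 peaks are matched against
the four parental masses within 20 ppm; MS2 peaks against the full 7×4 grid
within 0.02 Da (published observed-vs-calculated deviations are ≤0.01 Da).
Nearest mass wins; an exact tie resolves deterministically to the lower
theoretical mass and is flagged ambiguous, as is any peak with two candidates
in the window. MS2 label confirmation intersects, across fragments, the sets
of isotopologues whose ladder explains each mass; contradictory evidence
returns a conflict, never a silent override.

Relative abundance of isotopologue *i* is `100·I_i/ΣI` over the four summed
MS1 intensities of one (time, replicate) sample. Ratios are computed per
replicate and only then averaged — replicates are the biological error unit
and are never pooled before the ratio. Moiety aggregates: old Lpp = oo + no,
new Lpp = nn + on, old stem = oo + on, new stem = nn + no; each old/new pair
sums to 100 by construction.

## Kinetic model

State (molecule equivalents): free Lpp `F_o, F_n`; bound isotopologues
`B_xy` (x = donor-stem age, y = Lpp age); tetrapeptide donor stems
`D_o, D_n`; plus the *cohort* `C` — the part of `B_oo` already bound at the
medium switch. Rates, all age-blind:

* growth `μ = ln2/T`, `T = 60` min; new Lpp synthesized at `μL`
  (`L` = total Lpp) and new donors at `μδL`, keeping both pools proportional
  to cell mass (`δ` = donors per Lpp, default 1);
* tethering at `k_t` per free Lpp, consuming a donor of age x with
  probability `p_x ∝ D_x` (an optional septal factor in [0,1] discounts new
  donors; default 1 = off);
* hydrolysis at `k_h` per bound molecule (0 in ΔyafK), returning the Lpp
  intact to its free pool; the stem leaves the donor pool permanently
  (tripeptides cannot act as donors); `dC/dt = −k_h·C`.

Initial state: fully labeled culture — all pools old, `B_oo = b₀·L₀` with
`b₀ = 1/3` tethered and `L₀ = 10⁶` copies, `F_o = (1−b₀)·L₀`, `D_o = δ·L₀`.
Exact invariants: old Lpp (`F_o+B_oo+B_no`) is conserved; `L = L₀·e^{μt}`;
relabeling old↔new in the initial state and synthesis terms mirrors the
solution.

**Dilution law.** Choosing `k_t = (μ+k_h)·b₀/(1−b₀)` makes the tethered
fraction stationary, so the bound pool grows exactly as `b₀L₀e^{μt}` and the
cohort's relative abundance is `2^{−t/T}·e^{−k_h t}`: a 50 % drop per
generation from dilution alone (ΔyafK), ×2 more when half the bonds are
hydrolyzed per generation (`k_h = ln2/T`, the default wild-type rate — the
published lower bound taken at equality). The cohort, not the measurable
old→old pool, is the carrier of this law in the model: with one well-mixed
free pool, free old Lpp re-tethers to old donors and regenerates old→old,
so the *measurable* old→old decays less than twofold in a ΔyafK simulation.
In the experimental data that regeneration flux is evidently small — most
free Lpp is surface-exposed and not available to the periplasmic
transpeptidases — but the model keeps the single well-mixed pool for
parsimony and exposes the cohort as an explicit trajectory column. The same
reading applies to old-Lpp halving: it is exact for the conserved old-Lpp
share of total Lpp, in both genotypes. This is also why the model-free
headline estimator `100·(1 − fold_mut/fold_wt)` applied to model-generated
data understates the true hydrolyzed fraction `1 − e^{−k_h T}` — the
documented lower-bound property.

**Numerics.** LSODA (adaptive, stiff-capable), rtol 1e-8, atol 1e-10 scaled
by `L₀`; default output grid every minute over one generation. Tethering
shuts off along a C¹ cubic ramp over the last 0.1 % of the donor pool: the
raw vector field is discontinuous at donor exhaustion (reachable when a
fitter explores large `k_t`) and stalls the integrator; the ramp is
identically 1 in the normal regime, leaving the exact laws above intact.
States are clipped at zero on entry to the RHS; trajectories with pools below
−10⁻⁶·L₀ abort as integration failures.

**Stochastic oracle.** An exact Gillespie simulation of the same network
(10 reaction channels; cohort membership resolved hypergeometrically on each
`B_oo` hydrolysis) is used only in tests, at 10⁴ molecules: the mean of 100
runs must match the ODE relative abundances within 3 Monte-Carlo standard
errors. With 10⁶ copies per cell the deterministic mean-field limit is the
appropriate primary engine.

## Estimation

Least squares on the percent relative-abundance scale (the scale of the
reported curves), summed over time points, replicates and the four
isotopologues; optional inverse-SD weighting by per-time replicate scatter
(floored at 1 %). Free parameters (`k_t`, `k_h`, optionally `δ`) are bounded
(`k_t ∈ [10⁻⁵, 0.2]`, `k_h ∈ [0, 0.2]` min⁻¹) and optimized by
trust-region-reflective least squares from a seeded Latin-hypercube
multistart (default 8 starts; best loss wins, ties toward the smaller `k_h`).
A joint fit shares all free parameters with a ΔyafK dataset while pinning its
`k_h` to 0 — the mutant has the same enzyme complement minus YafK, so
synthetic genotype pairs are generated with a shared `k_t`.

Uncertainty: percentile bootstrap over biological replicates (never time
points), refit warm-started from the point estimate. Resamples draw
`m = n−1` of the `n` replicates: the plain n-of-n bootstrap deflates the
resampling variance by `(n−1)/n`, a ~10 % interval shrinkage at n = 5 that
measurably depresses coverage; `m = n−1` cancels the deflation to first
order (the m-out-of-n bootstrap). A dataset with one replicate is flagged
degenerate.

Calibration at the study conditions (5 time points over one generation,
5 replicates, 10 % CV, joint wild-type + ΔyafK fits, 100 seeded datasets):
`k_h` bias ≈ −0.1 % of truth; 95 % interval coverage 89 %. These numbers are
recomputed by the acceptance test suite, with 3-start point fits and 100
bootstrap resamples per dataset to keep the experiment around five minutes
on one CPU.

## Synthetic data

The generator emulates the pulse-chase design: ODE relative abundances at
{0, 15, 30, 45, 60} min (the published protocol samples the switch plus four
post-switch times; exact values unstated, so an even grid is used and
recorded), 4 replicates by default (within the reported 3–5), intensities
`scale·abundance` perturbed by mean-one log-normal noise (CV default 10 % —
a placeholder; the real replicate scatter is not derivable at the desk), and
Gaussian relative mass error (SD 5 ppm) on every peak. MS2 ladders carry
uniform fragment intensities; assignment uses masses only. Everything
regenerates bit-identically from (config, seed).

Not emulated: isotope envelopes and partial enrichment, retention time,
chromatographic co-elution, fragmentation efficiency, intensity-dependent
mass error. Passing round-trip tests therefore validates the bookkeeping and
statistics of the pipeline, not its robustness to those instrument effects.

## Known limitations

* The single well-mixed free-Lpp pool overstates re-tethering of old Lpp
  (see the dilution-law discussion); a surface-exposed/periplasmic split
  would need at least one more rate the data cannot constrain.
* `k_t` and `k_h` are not published quantities; fitted values are estimates
  conditional on this model, not ground truth.
* The donor pool size (`δ`) is weakly identified from relative abundances
  alone and is fixed by default rather than fitted.
* No spatial (septal vs lateral) structure beyond the scalar septal factor;
  no 4→3/3→3 cross-link populations; no vesiculation.
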
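# Methods

## Binding model

The package treats protein–RNA binding as a single-site two-state
equilibrium in fast exchange on the chemical-shift timescale: each
backbone-amide peak appears at the population-weighted average of its
free and bound positions, so its displacement is proportional to the
fraction of protein bound.  With total protein *p* (μM) fixed and RNA
added at molar ratio *x*, mass balance gives the quadratic

    f_B(x) = [ s − sqrt(s² − 4x) ] / 2,   s = 1 + x + K_D/p,

evaluated internally in the cancellation-safe form 2x/(s + sqrt(s²−4x)).
The equivalent fitting form A·(B + x − sqrt((B+x)² − 4x)) with
A = Δδ_max/2 and B = 1 + K_D/p is provided and property-tested against
the product Δδ_max·f_B to < 1e-12 absolute, and against an independent
numeric mass-balance root-finder to < 1e-9.

**Assumptions**: 1:1 stoichiometry, a single binding register per
oligo, fast exchange at every titration point, and shift changes that
are linear in the bound fraction.  Intermediate/slow exchange, line
broadening and multi-site binding are out of scope.

## Weighted CSP

CSP = sqrt((Δδ_H² + w_N·Δδ_N²)/2) with w_N = 0.15, the conventional
down-weighting of the ¹⁵N dimension.  The alternative reading in which
the ¹⁵N difference is scaled before squaring ((w_N·Δδ_N)²) is selectable
via `CSPWeights(variant="scaled_n")`; because SIA scores are ratios of
CSPs of the same peak (whose displacement direction is fixed along a
titration), they are invariant to the variant, which a test asserts.
The published description of this normalization is ambiguous between
the two readings; both are therefore kept.

## Peak tracking

When every spectrum carries assignments, tracking is the identity by
label.  Otherwise peaks are chained across consecutive titration points
by greedy nearest-neighbour assignment in weighted-CSP distance,
one-to-one, with a default maximum step of 0.1 ppm — justified because
fast-exchange peaks move smoothly and locally.  A peak whose best and
second-best candidates differ by less than 10% is matched but flagged
ambiguous; unmatched points are flagged lost and never interpolated.
Ties in the greedy ordering break deterministically (residue label, then
peak index).

## K_D fitting

Per residue, (K_D, Δδ_max) are fitted by Levenberg–Marquardt least
squares (lmfit) with fixed initialization K_D₀ = p (B₀ = 2),
Δδ_max₀ = 1.5 × max observed CSP, and bounds K_D ∈ [1e-3, 1e6] μM,
Δδ_max ∈ (0, 10] ppm, making fits deterministic.  Residues with fewer
than 3 usable points, no detectable shift, or non-convergent fits are
skipped and logged.  The aggregate K_D is the unweighted arithmetic mean
over fitted residues (an inverse-variance-weighted mean was considered
and rejected as the default because the per-residue uncertainties are
strongly model-dependent at low signal).  Uncertainty on the aggregate
is available through an opt-in residual bootstrap (200 resamples by
default when enabled, seeded); it is off by default so that pipeline
fits stay cheap and exactly reproducible from the point estimate alone.
A warning is emitted when the ratio schedule does not span both sub- and
super-stoichiometric points, where K_D and Δδ_max decouple poorly.

## SIA scoring

Pools fixing one base at one scored position are compared through the
CSPs of a shared residue subset.  Default normalization is **per peak**:
each peak's four CSPs are divided by that peak's maximum, so every peak
contributes equally and the score of the best base is exactly 1 for
every peak in the noiseless limit.  A **per pool** normalization (each
pool's column divided by its maximum over peaks) is kept as an option;
the two differ only when peaks disagree about the ranking.  Scored
positions 1–4 map to oligo positions 2–5 of the 5-mer; the 5′ position
is unrecognized and reported as a lowercase "n".  Motif calling reports
any base within 0.10 absolute score units of the top as an alternative
("G/A"); follow-up K_D comparisons of two oligos differing only at the
ambiguous position resolve the call.  The 0.10 margin is a heuristic
default, exposed as a parameter.

## Residue selection

The residue subset entering SIA and fitting defaults to an explicit,
reproducible rule: residues whose final-point (or maximum pool) CSP
exceeds 3× a noise floor estimated as the median CSP of the 20%
least-shifted residues.  The same rule powers the workflow's feasibility
warning — when the *median* CSP fails the 3× floor test the run is
flagged as having shifts too small for reliable SIA scoring, which is
exactly the failure mode of a weakly binding wild-type domain.

## Synthetic-data generator

The simulator's ground truth is an **additive sequence-affinity model**:
K_D(seq) = kd_ref × context_factor × Π penalties[pos][base], penalties
being fold-multipliers ≥ 1 with the reference base at 1.  The packaged
FMRP-KH1 fixture uses kd_ref = 100 μM for the reference UGGAC under the
AE variant, penalty(pos 3, C) = 3 and penalty(pos 1, A) = 2.5 pinned to
the measured selectivities, all other penalties 2.0 (an arbitrary value
giving clear but non-saturating discrimination), and context_factor 40
for WT — so the AE gain, the 3-fold and the 2.5-fold selectivities are
structural properties of the fixture, while the *absolute* scale is a
modelling choice (only fold-ratios are measured quantities; every
validation target is a ratio and insulated from the scale).

Twenty synthetic residues carry reproducible pseudo-random free
positions (¹H 7–9.5 ppm, ¹⁵N 105–130 ppm), bound-state amplitudes
Δδ_max ∈ [0.05, 0.4] ppm, and displacement directions of unit length in
weighted-CSP space, so a residue's weighted CSP equals f_B·Δδ_max
exactly.  Noise is isotropic Gaussian in weighted-shift space (default
0.005 ppm per axis; the ¹⁵N axis receives sd/√0.15 in ppm).  Titrations
use the standard schedule x = 0, 0.5, 1, 2, 4, 6, 8, 10, 12 at 50 μM
protein; SIA pools use a single 1:4 point.

Quasi-degenerate pools (equal member concentrations assumed; synthesis
bias is unknowable) are simulated **exactly**: the free-protein
concentration solves Σ p_free·L_i/(K_i + p_free) + p_free = p_total by
bracketed root finding on [0, p_total] (monotone, residual < 1e-10·p),
and all bound species share the residue's displacement direction.  A
harmonic-mean effective K_D (n/Σ(1/K_i)) is provided as the analytic
weak-binding limit; it agrees with the exact reduction to within 5%
whenever the tightest member K_D is ≥ 10× the protein concentration, and
converges to it as K/p → ∞.

**What the simulator does not emulate**: peak overlap and crowding,
ratio-dependent line broadening and intensity loss, exchange-regime
crossover at high affinity, temperature/buffer effects, and correlated
(non-isotropic) shift noise.  Passing tests therefore demonstrate the
correctness of the analysis chain under the stated model, not robustness
to every pathology of real spectra.

## Mutant scanner

KH rule: report every G-X-X-G with X ∉ {G, P} (G would create ambiguous
overlapping motifs, P is structurally incompatible with the loop; the
exclusion set is overridable), and propose GKKG wherever neither inner
residue is K or R — a single existing positive charge disqualifies the
loop.  RRM rule: given user-supplied alignment columns (the package does
not predict domain boundaries or compute alignments), a sequence with a
non-gap, non-K/R anchor residue and hydrophobic residues
({A,V,L,I,M,F,W,Y}) at all three hallmark columns is proposed for a K
anchor.  Coordinates are 1-based inclusive on the ungapped sequence.

## Workflow and reproducibility

The `workflow` stage simulates one shared free spectrum plus 16 pool
spectra, selects responsive residues, scores, calls the motif, and runs
configured follow-up titration fits for ambiguous positions (defaults:
UGGAC/UAGAC for position 1, GAGCC/GAGAC for position 3).  Every source
of randomness derives from one integer seed; reports embed the seed and
a hash of the resolved configuration, and identical configurations
produce byte-identical reports.

Problem sizes used throughout (20 residues, 9-point titrations, 256- to
1024-member pools, 100-replicate recovery studies) keep any single
validation run within seconds on one CPU while leaving parameter
recovery comfortably over-determined.

## Known limitations

* Fast exchange is assumed, never verified from the data; a domain
  drifting into intermediate exchange will yield biased Δδ_max and K_D.
* The additive affinity model has no positional coupling, so epistatic
  preferences (e.g. structured RNA) cannot be represented.
* The aggregate K_D is a plain mean; residues with low Δδ_max contribute
  noisy estimates at noise levels well above the default.
* SIA scores are comparative, not thermodynamic; only the follow-up K_D
  fits carry units.
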
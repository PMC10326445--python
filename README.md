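# rnaae

An NMR toolbox for characterizing **low-affinity RNA-binding domains** —
the KH, RRM and zinc-finger domains whose dissociation constants sit in
the high-micromolar to millimolar range, where most specificity assays
fail.  The package implements the workflow built around an
*affinity-enhancing* (AE) mutant: a localized, structure-based mutation
(e.g. the KH GxxG→GKKG loop mutation) that strengthens backbone contacts
without changing base readout, bringing the interaction into a regime
where chemical-shift-perturbation (CSP) titrations and
scaffold-independent analysis (SIA) become quantitative.

It is aimed at NMR spectroscopists and RNA-biochemists who have assigned
¹H-¹⁵N correlation spectra of a domain free and in complex with RNA, and
want per-residue K_D fits, nucleobase-preference scores, a called motif,
and candidate AE mutations for new domains.

## The model

Peaks in **fast exchange** sit at the population-weighted average of the
free and bound positions, so the weighted CSP of residue *i* at
protein:RNA molar ratio *x* (protein fixed at *p* μM) follows the
single-site quadratic isotherm

```
CSP_i(x) = Δδ_max,i · f_B(x)
f_B(x)   = [ (1 + x + K_D/p) − sqrt((1 + x + K_D/p)² − 4x) ] / 2
CSP      = sqrt( (Δδ_H² + 0.15·Δδ_N²) / 2 )
```

K_D and Δδ_max are fitted per residue by nonlinear least squares and the
reported K_D is the arithmetic mean over residues.  Fold selectivity
between two RNAs (or two protein variants) is the ratio of their
aggregate K_Ds.  **SIA** scores come from four quasi-degenerate 5-mer
pools per sequence position (one base fixed, the rest randomized): each
peak's four CSPs are normalized by that peak's maximum and averaged over
peaks, giving per-base preference scores in (0, 1]; ambiguous positions
are resolved by direct K_D comparison of the competing oligos.

A synthetic-data module generates fast-exchange titrations from an
additive sequence-affinity model (per-position fold penalties on a
reference K_D) and simulates pools exactly via a competitive
multi-ligand equilibrium solver.  The packaged FMRP-KH1 fixture encodes
the domain's measured behaviour: an `nGGAC` preference, 3-fold C→A
selectivity at position 3, 2.5-fold A→G selectivity at position 1, and a
40-fold affinity gain for the AE (GTHG→GKKG) mutant.

## Worked example

```python
from rnaae import fmrp_fixture, simulate_titration, fit_kd, selectivity_ratio
from rnaae.csp import match_peaks, csp_profile

ae = fmrp_fixture("AE")
fits = {}
for oligo in ("GAGCC", "GAGAC"):
    series = simulate_titration(ae, oligo, protein_conc=50.0, noise_sd=0.0)
    fits[oligo] = fit_kd(csp_profile(match_peaks(series)), 50.0)
    print(oligo, f"K_D = {fits[oligo].aggregate_kd:.1f} uM")
sel = selectivity_ratio(fits["GAGCC"], fits["GAGAC"], labels=("GAGCC", "GAGAC"))
print(f"{sel.fold:.1f}-fold preference, tighter = {sel.tighter}")
```

prints

```
GAGCC K_D = 750.0 uM
GAGAC K_D = 250.0 uM
3.0-fold preference, tighter = GAGAC
```

i.e. the domain prefers an A over a C at sequence position 3 with 3-fold
selectivity.  The full specificity pipeline runs from the shell:

```
rnaae workflow --variant AE --seed 1 --noise-sd 0.005 --out-dir runs/ae
```

which simulates the 16 SIA pools, scores them, runs follow-up titrations
for any ambiguous positions, and reports `motif: nGGAC`.  The other
subcommands (`simulate`, `csp`, `fit`, `sia`, `scan`) expose each stage
separately; `rnaae scan --kind kh` lists GxxG loops without positive
charge and proposes the GKKG enhancement.

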
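# FMRP KH1 synthetic fixture, version 1.
#
# Additive sequence-affinity model for the KH1 domain binding 5-mer ssRNA.
# Scored positions 1-4 correspond to oligo positions 2-5; oligo position 1
# is unscored ("n") and carries no penalty.  K_D(seq) = kd_ref_uM ×
# context_factor × product of per-position fold penalties (reference base
# penalty = 1).  The penalty matrix is calibrated so that
#   K_D(GAGCC)/K_D(GAGAC) = 3    (position-3 C vs A)
#   K_D(UAGAC)/K_D(UGGAC) = 2.5  (position-1 A vs G)
#   K_D(WT)/K_D(AE)        = 40  (context factor, any oligo)
# Non-pinned penalties default to 2.0 (clear, non-saturating discrimination).
version: 1
reference: UGGAC
kd_ref_uM: 100.0
context_factor:
  AE: 1.0
  WT: 40.0
penalties:
  1: {G: 1.0, A: 2.5, C: 2.0, U: 2.0}
  2: {G: 1.0, A: 2.0, C: 2.0, U: 2.0}
  3: {A: 1.0, G: 2.0, C: 3.0, U: 2.0}
  4: {C: 1.0, A: 2.0, G: 2.0, U: 2.0}
# Synthetic residue set: 20 amides with reproducible pseudo-random free
# positions, bound-state CSP amplitudes, and shift directions.
residues:
  count: 20
  seed: 20601
  first_index: 230
  dmax_range_ppm: [0.05, 0.4]
  h_window_ppm: [7.0, 9.5]
  n_window_ppm: [105.0, 130.0]
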
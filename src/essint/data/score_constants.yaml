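# Calibrated constants for the structure-confidence and model-quality scores.
# Kept as data, not inline literals, so the provenance of every number is
# auditable and a recalibration is a data change, not a code change.

pdockq:
  # Sigmoid fit of DockQ against (mean interface pLDDT) * ln(n_contacts)
  # for two-chain AlphaFold models; Bryant, Pozzati & Elofsson,
  # Nat. Commun. 13, 1265 (2022).
  L: 0.724
  x0: 152.611
  k: 0.052
  b: 0.018
  contact_cutoff: 8.0      # Angstrom, Cbeta-Cbeta (Calpha for Gly)

pdockq2:
  # Interface-PAE weighted sigmoid; Zhu, Shenoy, Kundrotas & Elofsson,
  # Bioinformatics 39, btad424 (2023).
  L: 1.31
  x0: 84.733
  k: 0.075
  b: 0.005
  d0: 10.0                 # Angstrom, PAE normalisation
  contact_cutoff: 8.0      # Angstrom, Cbeta-Cbeta (Calpha for Gly)

dockq:
  # Basu & Wallner, PLoS ONE 11, e0161879 (2016).
  d1: 1.5                  # Angstrom, i-RMSD scaling
  d2: 8.5                  # Angstrom, L-RMSD scaling
  fnat_cutoff: 5.0         # Angstrom, heavy-atom native contacts
  interface_cutoff: 10.0   # Angstrom, native interface definition

tm_score:
  # Zhang & Skolnick, Proteins 57, 702-710 (2004).
  d0_coeff: 1.24
  d0_shift: 15
  d0_offset: 1.8
  d0_min: 0.5
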
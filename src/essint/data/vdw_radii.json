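{
  "_comment": "Element van der Waals radii (Angstrom), Bondi, J. Phys. Chem. 68, 441 (1964); P from Mantina et al. 2009. Used by the Shrake-Rupley SASA engine; override per call if a different set is needed.",
  "H": 1.20,
  "C": 1.70,
  "N": 1.55,
  "O": 1.52,
  "S": 1.80,
  "P": 1.80,
  "F": 1.47,
  "CL": 1.75,
  "BR": 1.85,
  "I": 1.98,
  "SE": 1.90,
  "default": 1.70
}
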
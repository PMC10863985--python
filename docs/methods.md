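# Methods

## Scope and model of the problem

A bacterial protein–protein interaction can only be essential if every
protein forming the complex is itself essential: knocking out either
partner already kills the cell, so the set of pairs of essential proteins
is an upper bound on the essential interactome.  `essint` implements the
desk-scale side of a pipeline built on that premise: it assembles the
candidate pair set from multi-species gene-essentiality screens and
database interaction evidence, triages structure-prediction outputs for
those pairs by interface confidence, characterizes the predicted
interfaces geometrically and evolutionarily, validates predictions
against solved reference structures, and exports the resulting
interactome graph.  The GPU-scale step in the middle — folding each
candidate pair with a multimer structure predictor — is out of scope;
its outputs (coordinates with per-residue pLDDT, ipTM rankings, PAE
matrices) are inputs here, and a seeded synthetic generator stands in
for them during testing.

## Candidate interactome construction

Inputs are per-species essential-protein tables, an ortholog-group map
(one group id per accession; groups equate proteins across species),
per-species STRING-dialect edge lists with `combined` and `experimental`
sub-scores (either 0–1000 integers or 0–1 reals; auto-detected), a
family annotation table, and a synthetic-lethal pair list.

Filter cascade, in order, with defaults in parentheses:

1. **Essentiality consensus.** An ortholog group is essential when
   flagged in at least `min_essential_species` (2) distinct species.
   Duplicate rows are dropped silently; accessions missing from the
   ortholog map are logged and skipped.
2. **Score filter.** An edge survives when `combined > 0.7` **or**
   `experimental > 0.15`.  Both comparisons are strict, matching the
   wording of the source thresholds.
3. **Both-essential filter.** Both endpoints must be in the consensus
   essential set.
4. **Family exclusion.** Edges touching ribosomal proteins or tRNA
   ligases (caller-supplied annotation; these families form huge
   assemblies that a binary-complex predictor cannot treat) are
   discarded.  The annotation is keyed by ortholog group; a helper
   lifts accession-keyed tables through the ortholog map.  Name-based
   matching is deliberately not attempted — "ribosomal-related" is not
   machine-precise.
5. **Species consensus.** Steps 2–4 are applied per species; an edge
   must then be recovered in at least `min_species_support` (2) species.
   The merged edge carries the union of supporting species and the
   maximum of each sub-score (the sub-scores are species-specific
   confidences for the same group-level interaction; the maximum mirrors
   best-evidence selection).  Applying the score thresholds per species
   *before* the consensus is a genuine design choice — the alternative
   (thresholding some cross-species aggregate) is not well defined for
   sub-scores that STRING computes per species.
6. **Synthetic-lethal merge.** SL pairs are appended afterwards and
   bypass filters 1, 3 and 5: they capture pairs of individually
   dispensable proteins that are lethal jointly, and originate from a
   single-species screen.  A pair duplicating an existing edge is merged,
   recording both origins.  Self-pairs (including two accessions of one
   ortholog group) are rejected.

Edges are canonicalized by lexicographic ordering of group ids, so the
output has one record per unordered pair.  Random negative controls are
drawn by seeded rejection sampling without replacement from the unordered
pairs of the input protein set, excluding the positive set; infeasible
requests fail with the exact available count.

## Confidence scores

* **ipTM** is read from the predictor's ranking JSON (both the raw
  `iptm` map and the weighted `iptm+ptm` ranking confidence are parsed;
  raw ipTM is the default because the two differ only by the pTM
  admixture and raw ipTM is the interface-specific signal).  The
  representative model of a five-model prediction job is the ipTM
  argmax, ties broken by lexicographically smallest model id.
* **Triage**: `unlikely` (ipTM < 0.4), `plausible` (0.4 ≤ ipTM ≤ 0.6),
  `high_confidence` (ipTM > 0.6).  Both boundary values land in
  `plausible`, consistent with the outer comparisons being strict.
* **pDockQ** = `L / (1 + exp(−k(x − x₀))) + b` with
  `x = ⟨pLDDT over interface residues⟩ · ln(n_contacts)`; contacts are
  interchain Cβ–Cβ pairs within 8 Å (Cα for glycine), interface residues
  are those appearing in ≥ 1 contact.  Zero contacts defines the score
  as 0.
* **pDockQ2** applies, per chain,
  `x = ⟨pLDDT⟩ · ⟨1 / (1 + (PAE/d₀)²)⟩` over that chain's interface
  residues and the interchain contact pairs, with d₀ = 10 Å, then the
  published sigmoid; the complex score is the mean of the two chain
  scores.  PAE is symmetrized (mean of the two directions per pair)
  before weighting.  The matrix is indexed over residues in chain
  concatenation (file) order, the predictor's output layout.

All sigmoid and scaling constants live in
`src/essint/data/score_constants.yaml` with their source publications,
never inline in code; refitting them is a non-goal.

## Interface geometry and conservation

Heavy atoms only throughout (predicted models carry no hydrogens).

* **Contact residues**: interchain residue pairs with any heavy-atom
  distance ≤ 4.5 Å.  **Interface residues**: any heavy atom within 10 Å
  of the partner chain.  The contact set is a subset of the interface
  set by construction.
* **SASA** is computed with the Shrake–Rupley quadrature: each atom's
  van der Waals sphere (Bondi radii shipped as data, overridable;
  unknown elements fall back to 1.7 Å with a warning) is inflated by
  the probe radius (1.4 Å, water) and covered with a golden-spiral
  point lattice (960 points by default); the accessible fraction is the
  share of points outside every neighbouring inflated sphere.  At 960
  points the summed SASA of a small protein is converged to ~10⁻⁵
  relative and per-atom areas are accurate to a few tenths of a percent
  against a 10⁶-point Monte-Carlo reference; per-atom areas of heavily
  occluded atoms carry up to ~1% quadrature noise, and because the point
  lattice is fixed in space, SASA-derived quantities are rotation
  invariant only to that same tolerance.
* **Buried interface area** = SASA(A) + SASA(B) − SASA(AB), computed on
  the isolated chains and the complex at identical settings.  Whether
  the headline number should be the total buried area or the per-chain
  ΔSASA/2 is ambiguous in common usage, so both are reported;
  `buried_area` is the headline column.
* **Surface residues** own ≥ 1 atom with exposed area ≥ 6.5 Å² on the
  *isolated* chain.  The threshold is interpreted as an area (Å²): the
  widely used surface-atom finder this criterion comes from documents
  its cutoff as an exposed-area parameter even though it is often
  quoted with a length unit.  For the conservation contrast, interface
  residues are removed from the surface set so the two samples are
  disjoint.
* **Conservation contrast**: per-residue conservation is an input track
  of integers 1 (most variable) to 9 (most conserved).  Interface vs.
  surface scores are compared with a Wilcoxon rank-sum (Mann–Whitney)
  test with tie correction — ties are guaranteed on a 9-level scale —
  reporting the two-sided p, the one-sided p for "interface more
  conserved", and both medians.  Residues are pooled across models when
  an interactome-level contrast is requested; per-complex reports are
  also available.
* **Residue-type network**: for every interchain side-chain contact
  (side chain = heavy atoms except N, CA, C, O; glycine contributes its
  Cα) within 4.5 Å, the undirected edge between the two residue *types*
  is incremented once per residue pair per model; self-edges (LEU–LEU)
  are allowed.  Feed it high-confidence models only.

## Validation against reference structures

Residue correspondence between model and native is fixed by a chain map
plus author sequence index — the models share sequences with their
references, so no alignment search is performed.

* **Kabsch superposition** (SVD, reflection-corrected to a proper
  rotation) underlies all RMSDs; collinear point sets are rejected.
* **i-RMSD**: backbone (N, CA, C, O) RMSD over *native-defined*
  interface residues (any heavy atom within 10 Å of the partner chain)
  after superposing on exactly those atoms.  Backbone is the default
  atom set; a heavy-atom mode is available.
* **Fnat**: fraction of native interchain residue contacts (heavy-atom
  ≤ 5 Å) preserved in the model, orientation-free.
* **L-RMS**: ligand backbone RMSD after superposing on the receptor;
  receptor = longer chain, first chain on ties (the DockQ convention).
* **DockQ** = (Fnat + 1/(1+(iRMS/1.5)²) + 1/(1+(LRMS/8.5)²)) / 3.
* **TM-score** over the concatenated Cα trace, with
  d₀ = 1.24·(L−15)^⅓ − 1.8 floored at 0.5 Å and L the native length.
  The superposition search seeds from sliding fragments (full length,
  L/2, L/4; half-fragment step) and iteratively re-superposes on the
  residues within max(d₀, 3 Å) until the selection is stable; the score
  is the maximum over seeds.  Against a brute-force variant that tries
  every fragment start, the sparse seeding agrees to < 10⁻³ on the
  fixture families used in tests.
* **Crosslink restraints**: a lysine–lysine crosslink is satisfied when
  the Cα–Cα distance is within the crosslinker reach.  The default
  maximum is 20 Å — the upper end of the ~15–20 Å range spanned by
  common amine-reactive crosslinkers — and is configurable, since the
  literature gives a range, not a rule.  Missing residues skip the
  restraint with a report; non-lysine residues are an error.
* **Benchmark metadata filter** for unbiased evaluation sets: keep
  heterodimers released after the predictor's training cutoff
  (2021-09-30), solved by X-ray or cryo-EM at ≤ 2.0 Å, structural
  cluster representatives only, with sequence identity to the training
  set < 30% (strict).  The structural clustering itself (coverage 0.9)
  is performed by external tools; its result enters as the
  `cluster_representative` flag.

## Statistics and graph assembly

The selected candidate set is contrasted with the random negative set
through ECDFs of ipTM and a two-sample Kolmogorov–Smirnov test (exact
null when n·m ≤ 10⁴, asymptotic otherwise), and through a per-bin
chi-square on the binned score histogram (10 equal-width bins on [0, 1]
by default — the binning is a package choice, configurable; each bin is
tested as a 2×2 in-bin/out-of-bin table without continuity correction,
and bins with expected counts < 5 are flagged).  Category summaries
report counts and percentages to two decimals with half-up rounding, so
printed percentages can be compared exactly.  The interactome graph is
a simple undirected graph with ipTM/pDockQ/category edge attributes;
duplicate pairs keep the record with the larger ipTM (mirroring
best-model selection), self-loops are rejected, and exports are
Cytoscape-compatible edge TSV plus GraphML, with a node-degree table
for hub inspection.

## Synthetic data: what it emulates and what it does not

* **Interactome tables** (`synth_interactome`): four species per gram
  group, 60 ortholog groups, 60% of groups consensus-essential, 40
  planted edges with per-species score profiles (60% "strong" edges
  drawn above the combined threshold, the rest below; Gaussian score
  noise, sd 0.03), ~10% of groups assigned to excluded families, three
  synthetic-lethal pairs — sizes chosen to exercise every filter arm
  many times per instance while keeping one instance well under a
  second.  Planted scores are rounded to the emitted file precision
  (the 0–1000 STRING dialect) so the recorded ground truth and the
  files agree exactly; the expected surviving edge set is computed
  directly from the planted parameters by an independent restatement of
  the filter rules, never by running the pipeline under test.
* **Coordinate models** (`synth_dimer`): two ideal polyalanine
  α-helices (φ = −57°, ψ = −47°, standard bond geometry, Cβ included)
  packed antiparallel at a 10 Å axis separation and staggered by half a
  helix length, so the overlap region forms a genuine interface and the
  protruding ends remain solvent-exposed surface.  Perturbed copies add
  seeded Gaussian coordinate noise and/or a rigid offset of one chain.
  This gives analytic control of interface size and of
  perturbation–metric monotonicity; it does not attempt realistic
  side-chain packing, electrostatics or folding energetics.
* **Confidence bundles** (`synth_confidence`): pLDDT ~ N(90, 3) /
  N(70, 7) / N(50, 10) clipped to [0, 100] and interchain PAE ~ N(3, 1)
  / N(12, 3) / N(25, 4) clipped to [0.2, 31.75] for high/medium/low
  quality; intra-chain PAE ~ N(2, 0.5); five model variants with
  distinct ipTMs per job.  These distributions are invented surrogates:
  the only contract they carry — and the only thing tests assert about
  them — is ordinal (high-quality bundles must outscore low-quality
  ones); absolute score values mean nothing.  They do not reproduce a
  real predictor's error correlations.
* **Conservation tracks** (`synth_conservation`): baseline uniform on
  {1..9}, interface residues shifted by a configurable amount and
  clipped.  A uniform baseline is deliberately harsher than real
  conservation profiles (which are overdispersed), so detection power
  measured here is conservative in that one respect.

Every generator is a pure function of (seed, config): reruns are
byte-identical.  Consequently, passing tests demonstrate the *logic* of
the pipeline — filters, formulas, metrics, calibration — on data whose
ground truth is known exactly; they do not demonstrate predictive
accuracy on real organisms, which depends on the upstream predictor and
databases.

## Numerical choices and degenerate inputs

* Strict (">") thresholds everywhere the source rule is worded strictly;
  boundary ipTM values are `plausible`.
* Altloc atoms collapse to the highest-occupancy copy; waters are
  dropped; multi-model files keep the first model (logged); insertion
  codes in reference structures are renumbered sequentially with a
  logged map (predicted models never carry them).
* Empty contact sets define pDockQ/pDockQ2 as 0; an empty native contact
  set makes Fnat (and hence DockQ) an error rather than a silent 0.
* Empty crosslink lists return (0, 0) with the fraction flagged
  undefined rather than 0/0.
* KS switches from the exact to the asymptotic null above n·m = 10⁴.
* Pearson correlation refuses constant columns and n < 3.
* Random-negative sampling is rejection sampling without replacement; a
  request exceeding the number of available pairs names the bound.

## Problem sizes used in tests and the acceptance script

Dimer fixtures use 16–24 residues per chain; interactome instances use
4 species × 60 groups × 40 planted edges, 25 independent seeds;
calibration uses 1000 null and 100 shifted replicates at 100 + 100
residues; the Monte-Carlo SASA reference uses 10⁶ points on a
three-atom cluster.  These sizes make every check pass or fail sharply
while the whole suite stays interactive (~15 s) — the properties being
checked (exact set recovery, oracle agreement, identity limits,
calibration) are size-independent statements, so small instances lose
no generality.

## Known limitations

* The both-essential premise bounds the essential interactome from
  above; nothing here verifies that a candidate interaction is real —
  that is what the structure-prediction confidences triage.
* Binary complexes only: stoichiometry and accessory-protein effects
  are invisible to every metric implemented here.
* pDockQ/pDockQ2 constants are taken from their source publications and
  are not refit; they were calibrated on real predictor output, so
  their absolute values on synthetic confidence surrogates are
  meaningful only as orderings.
* SASA rotation invariance holds to quadrature tolerance (~1% on
  per-atom areas at 960 points), not exactly.
* The TM-score search is a fixed-correspondence refinement, not a full
  structural alignment; it is not suitable for comparing structures
  with different sequences.
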
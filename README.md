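# essint

Assembly and structural triage of bacterial **essential interactomes**.

A protein–protein interaction can only be essential if both partners are
themselves essential: deleting either one already kills the cell.  The set
of interacting essential-protein pairs is therefore an upper bound on the
essential interactome — a prime hunting ground for antibiotic targets.
`essint` is for computational/structural biologists who want to build that
candidate set from gene-essentiality screens and database evidence, triage
structure-prediction outputs for each pair, and quantify how trustworthy
the predicted complexes are.

The pipeline:

1. **Candidate edges** — compile essential proteins across species
   (essential in ≥ 2 species, linked by ortholog groups), keep STRING-style
   edges with `combined > 0.7` **or** `experimental > 0.15`, require both
   endpoints essential, drop ribosomal/tRNA-ligase families, require
   recovery in ≥ 2 species, then merge synthetic-lethal pairs (which bypass
   the essentiality rules) and draw seeded random negatives as controls.
2. **Confidence triage** — per predicted binary complex, select the
   best-ipTM model and classify it: *unlikely* (ipTM < 0.4), *plausible*
   (0.4 ≤ ipTM ≤ 0.6), *high confidence* (ipTM > 0.6).  Two
   structure-aware scores complement ipTM:

   `pDockQ = L / (1 + e^{−k(x−x₀)}) + b`, `x = ⟨pLDDT⟩₍ᵢfᵃᶜᵉ₎ · ln N_contacts`

   and pDockQ2, which replaces the contact count with a PAE-derived
   contact weight `⟨1/(1+(PAE/d₀)²)⟩`.
3. **Interface analysis** — contacts at 4.5 Å, interface at 10 Å (heavy
   atoms), Shrake–Rupley SASA, buried area `SASA(A)+SASA(B)−SASA(AB)`,
   Wilcoxon contrast of interface vs. surface conservation (1–9 scale),
   and an aggregate residue-type contact network.
4. **Validation** — against solved references: Fnat, interface RMSD,
   ligand RMSD, `DockQ = (Fnat + 1/(1+(iRMS/1.5)²) + 1/(1+(LRMS/8.5)²))/3`,
   TM-score with `d₀ = 1.24(L−15)^⅓ − 1.8`, lysine–lysine crosslink
   restraint checks (Cα–Cα ≤ 20 Å), and the metadata filter for unbiased
   benchmarks (post-training-cutoff heterodimers, ≤ 2 Å, < 30% identity).
5. **Statistics & graph** — ECDF + two-sample Kolmogorov–Smirnov and
   per-bin chi-square of selected vs. random score distributions, category
   summaries, and Cytoscape-compatible GraphML/TSV export.

A seeded synthetic-data module generates every input class (essentiality
tables, STRING-dialect edges, two-chain coordinate models, pLDDT/PAE/ipTM
bundles, conservation tracks) with known ground truth, standing in for the
GPU-scale structure-prediction step.  See `docs/methods.md` for the full
model description, defaults and limitations.

## Worked example

```python
from pathlib import Path
from essint import synthetic as syn, interactome as ib, structio as sio
from essint import confidence as conf, interface as ia, validation as vm

out = Path("sim"); out.mkdir()
cfg = syn.SimConfig(seed=42)
truth = syn.synth_interactome(cfg, out)
kept = ib.run_interactome_pipeline(
    sorted(out.glob("essentiality_*.tsv")), out / "orthologs.tsv",
    {sp: out / f"edges_{sp}.tsv" for sp in truth.species},
    families_path=out / "families.tsv", sl_pairs_path=out / "sl_pairs.tsv")
print(f"{len(kept)} candidate edges survive the filters")

native, perturbed = syn.synth_dimer(syn.SimConfig(seed=42, rigid_offset=1.5))
scored, bundle = syn.synth_confidence(native, "high", seed=42)
best = sio.select_best_model(bundle)
print(f"best model: {best} (ipTM {bundle.iptm_by_model[best]:.3f})")
print(f"pDockQ  = {conf.compute_pdockq(scored):.3f}")
print(f"pDockQ2 = {conf.compute_pdockq2(scored, bundle.pae):.3f}")
report = ia.analyze_interface(
    native, conservation=syn.synth_conservation(native, shift=2, seed=42))
print(f"buried area: {report.buried_area:.0f} A^2, conservation one-sided "
      f"p = {report.conservation.p_one_sided:.3g}")
v = vm.validate_model(perturbed, native)
print(f"DockQ {v.dockq:.3f}, i-RMSD {v.i_rmsd:.2f} A, TM {v.tm_score:.3f}")
```

Output:

```
9 candidate edges survive the filters
best model: model_1 (ipTM 0.784)
pDockQ  = 0.734
pDockQ2 = 0.581
buried area: 116 A^2, conservation one-sided p = 0.00117
DockQ 0.761, i-RMSD 0.72 A, TM 0.932
```

Reading it: of the 40 planted edges, 6 satisfy every filter by
construction and all 6 are recovered, plus the 3 synthetic-lethal pairs
that bypass the essentiality rules.  The high-quality confidence
surrogate yields a high-confidence triage with consistent pDockQ/pDockQ2.
The +2 planted conservation shift at the interface is detected
(p ≈ 10⁻³), and the 1.5 Å rigid offset of one chain degrades DockQ to
"medium" quality (0.76) while the fold stays intact (TM > 0.9).

The same stages are scriptable via the `essint` command
(`build-interactome`, `score-models`, `analyze-interfaces`, `validate`,
`stats`, `graph`, `simulate`); run `essint --help`.

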
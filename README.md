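# statescan

Trajectory and free-energy analysis for G protein-coupled receptor (GPCR)
molecular-dynamics studies, built around the serotonin 2A receptor
(5HT₂ₐR, residues 70–399).  `statescan` takes coordinate trajectories and
umbrella-sampling records and computes the standard activation-state and
binding-thermodynamics observables:

* **Activation metrics** — Cα distance time series for the ionic-lock pair
  R173³·⁵⁰/E318⁶·³⁰ and the TM5–TM6 pair Q262⁵·⁶⁶/E318⁶·³⁰; the **A100
  activation index** for class A GPCRs,

  A100 = −14.43·r(V95–L382) − 7.62·r(D120–T160) + 9.11·r(H165–A192)
  − 6.32·r(Q262–C322) − 5.22·r(A346–L362) + 278.88,

  with the distances r in Å, classified by the three-state model
  (inactive < 0 ≤ intermediate < 55 ≤ active) or the two-state model
  (split at 25); backbone RMSD and per-residue RMSF.
* **Conformational landscapes** — mass-weighted PCA of the loop-masked
  helix core (intracellular loops 102–108, 179–189, 263–314 and
  extracellular loops 138–145, 217–231, 347–354 excluded), 2D projection,
  k-means clustering into up to four ensembles, centroid extraction,
  Kabsch-aligned RMSD against named "closed"/"open" reference structures,
  and a direct readout of the TM6 outward displacement that separates
  partially-open (~4 Å) from fully open (~8 Å) conformations.
* **Potential-of-mean-force estimation** — a from-scratch **WHAM** solver
  for harmonically biased umbrella windows, iterating

  P(b) ∝ Σᵢ nᵢ(b) / Σᵢ Nᵢ exp((Fᵢ − wᵢ(b))/RT),
  Fᵢ = −RT ln Σ_b P(b) exp(−wᵢ(b)/RT),

  with Bayesian-bootstrap errors (flat Dirichlet weights over whole
  windows), the zero-in-bulk convention, binding ΔG as the well depth,
  ΔΔG between subpockets and the Boltzmann occupancy ratio
  p_OBP/p_EBP = exp(ΔΔG_EBP−OBP / RT).

A synthetic-data module generates every input class with known ground
truth — a toy seven-helix receptor, open→closed collapse trajectories, and
Metropolis-sampled umbrella windows over analytic 1D potentials — so the
whole pipeline runs and validates without an MD engine.

## Worked example

The bundled demo synthesizes a collapse trajectory plus an umbrella run
over a binding-shaped potential (a deep orthosteric-like well at ξ≈0.4 nm,
a shallower extended-pocket-like well at ξ≈1.2 nm, flat bulk beyond
2.5 nm) and analyzes it end to end:

```sh
statescan all --outdir demo --seed 7
```

`demo/pmf_report.json` then contains (numbers from this exact command):

```json
"sites": {
  "OBP": {"dg_kcal_mol": -11.3731, "sd_kcal_mol": 0.131291},
  "EBP": {"dg_kcal_mol": -7.79705, "sd_kcal_mol": 0.1145}
},
"ddg_ebp_obp_kcal_mol": 3.57604,
"occupancy_ratio_obp_over_ebp": 331.939,
"orders_of_magnitude": 2
```

i.e. the WHAM profile recovers the two wells, the deeper well wins by
~3.6 kcal·mol⁻¹, and the Boltzmann factor puts the deep-pocket occupancy
about two orders of magnitude above the shallow pocket at 310 K (the demo
uses only 500 samples per window; accuracy scales with sampling).
`demo/landscape.json` reports two conformational clusters, one nearest the
"open" reference (TM6 displacement 5.4 Å at its centroid frame) and one
nearest "closed" (0.5 Å), matching the generating collapse schedule.

The same machinery works from files: structures as PDB, trajectories as
multi-model PDB or a flat TSV table, umbrella windows as per-window TSV
sample files plus a `windows.tsv` metadata table (filename, center in nm,
force constant in kJ·mol⁻¹·nm⁻², temperature).

For published per-pocket well depths, the `report` subcommand reproduces
the ΔΔG/occupancy table directly:

```sh
statescan report dg.json   # {"SERO/open": {"OBP": {"dg": -12.19, ...}, ...}}
```

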
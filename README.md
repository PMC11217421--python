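# perichrom

Analysis pipeline for studying how nucleoporin-anchored chromatin is
organised at the nuclear periphery. In *Drosophila*, the chromatin-binding
nucleoporin Elys occupies thousands of genomic sites, a large class of
which sit inside lamina-associated domains (LADs) at nuclear pore
complexes (NPCs), where they coincide with local dips in the lamina DamID
signal, A/T-rich sequence, and increased contact frequency between the
flanking regions. `perichrom` implements the full computational chain
behind that kind of study:

- **DamID domain calling** — reads-per-million normalisation of binned
  Dam/Dam-fusion counts, `log2(fusion_RPM / Dam_RPM)` tracks, Gaussian
  two- or three-state HMM segmentation, and sub-900-bp gap filling.
- **Site classification** — labelling binding sites as NPC-linked,
  nucleoplasmic, ambivalent or unassigned by overlap with reference sets,
  with an interval-shuffle permutation test for colocalisation
  (`p = (k+1)/(N+1)` over N reshuffles).
- **Hi-C compaction statistics** — short-range filtering, binomial
  downsampling, iterative correction, observed/expected maps, TAD calling
  with the Armatus dynamic program (`q = s/(size)^γ − μ(size)`), per-TAD
  average contact frequency (ACF) and its knockdown/control log2FC,
  activity grouping by `Jacc = (X−Y)/(X+Y)` (LAD fraction X vs active
  chromatin fraction Y, groups A/B/C at ±0.8), compartment PC1, saddle
  plots with extreme-quantile difference summaries, the modified
  insulation score IS^m (mean O/E over the 4×4 square of contacts
  bridging 2–8 kb on either side of a 2-kb bin), and anchor pileups.
- **Signal profiles** — anchor-centred averages, strand-aware metagene
  profiles, and A/T-content analysis (20-bp windows, A/T-rich window
  fraction within ±150 bp of site centres).
- **Nuclear geometry** — radial FISH distances normalised by the
  sphere-equivalent nuclear radius `r = (3V/4π)^(1/3)`, Mann–Whitney U
  comparisons, and diameter intensity profiles aligned to the nuclear
  envelope marker peaks with a 0–0.15R peripheral-zone test.
- **Synthetic data generators** — every input above can be simulated with
  planted structure (LADs, binding-site classes, TADs, compartments,
  anchor contacts, radial-position shifts, class-specific expression
  effects, A/T islands), so the entire pipeline is testable end to end
  with no external data.

## Worked example

Run the whole synthetic analysis from the shell:

```bash
perichrom run-all --seed 1 --out-dir results
```

which prints (abridged):

```
"damid_f1": 0.984,
"n_lad_domains": 48,
"lad_coverage_pct": 48.6,
"n_elys_sites": 46,
"class_fractions": {"Elys_NPC": 0.70, "Elys_nucl": 0.30, ...},
"permutation_p": 0.0001,
"n_tads_ctrl": 20,
"median_acf_log2fc": -0.026,
"pc1_agreement": 0.995,
"ism_center_over_flank": 1.45,
"geometry_mwu_p": 1.3e-16,
"npc_gene_median_log2fc": 0.19
```

Reading the numbers: the two-state HMM recovers the planted LADs at
base-level F1 0.98; the three-state caller finds 46 binding sites, 70% of
which classify as NPC-linked; their colocalisation with the NPC reference
is far beyond chance (permutation p ≈ 1e-4, the estimator's floor at the
permutation count used); all 20 planted TADs are called with identical
boundaries in both conditions, and weakening inactive-TAD contacts in the
knockdown drives the median ACF log2FC negative; compartment PC1 signs
match the planted checkerboard on 99.5% of bins; IS^m peaks 1.45-fold
over its flanks at anchor sites in the control map; attached loci sit
significantly closer to the envelope than detached ones; and genes
carrying only NPC-class sites are mildly up-regulated after knockdown.

The numbered scripts under `analysis/` run the same stages one at a time
(`01_simulate_inputs.py` … `07_expression.py`), each printing what it
found and writing its tables under `results/`.

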
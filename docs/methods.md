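# Methods

This note documents the models, defaults and numerical choices behind
each stage of the pipeline, what the synthetic generators do and do not
emulate, and the design decisions taken where the procedure was open.

## Coordinates and containers

All coordinates are 0-based half-open (BED convention); strand is stored
but only consulted by metagene profiles. Binned signals live in a
`BinnedTrack`: one float per bin over the whole genome layout, with NaN +
a boolean mask marking bins without data. Interval algebra (intersection,
union coverage) is implemented with sorted per-chromosome sweeps and is
property-tested against all-pairs and per-base brute-force oracles.

## DamID normalisation and domain calling

Replicate count tracks are merged by summing (a warning is emitted if the
replicate Pearson correlation on unmasked bins is below 0.8 — at the
desk-scale default depth of 10⁶ reads over ~13,000 bins the per-bin
Poisson noise keeps raw-count correlation near that threshold, which the
warning reports honestly). A pseudocount (default 1 raw count, applied to
both samples before scaling) guards sparse bins; bins whose Dam count
plus pseudocount is zero are masked. Each sample is scaled to reads per
million of its own total and the signal is `log2(fusion_RPM/dam_RPM)`,
which is invariant to uniform rescaling of either sample's counts.

Segmentation uses a Gaussian-emission HMM on the log2 ratio (two states
for lamina-type signals, three for sharper binding-site signals).
Emissions are initialised at empirical quantiles of the unmasked values
(25/75th for two states, 10/50/90th for three), transitions start sticky
(0.99 self-transition), EM runs to tolerance with a variance floor of
1e-4, and the decoded Viterbi path is relabelled so states are ordered by
ascending mean — making the fit invariant to label permutation. Masked
bins split the observation sequence into independent chains and are never
decoded. Domains are maximal runs of the highest-mean ("bound") state;
which states count as bound is a parameter. Gaps shorter than 900 bp
between consecutive domains are filled (strictly less than; a 900-bp gap
stays open).

## Site classification and permutation enrichment

A site overlapping (≥ `min_overlap` bp, default 1) only the NPC reference
is `Elys_NPC`; only the nucleoplasmic reference, `Elys_nucl`; both,
`Elys_NPC/nucl`; neither, `unassigned` — a partition, so the four counts
sum to the site total. Genes are categorised analogously (any mixture,
including ambivalent sites, is `combination`).

The permutation test reshuffles the query set: each interval keeps its
length and (by default) its chromosome and lands uniformly over valid
start positions; shuffled intervals may overlap each other and no
blacklist is excluded. The statistic is the number of query intervals
with ≥1 bp of overlap to the (merged) reference. The p-value uses the
add-one estimator `p = (#{null ≥ observed} + 1)/(N + 1)`, which cannot
be zero and is conservatively valid; when no permutation reaches the
observed count the human-readable report prints `P < 1/N`. Calibration
is part of the test suite: under independent random placement the
rejection rate at α = 0.05 stays below 0.07 across 200 runs, and on a
1-bp-site/10-slot toy the p-value matches exhaustive enumeration. The
null placement is vectorised internally but identical in distribution to
the public `shuffle_intervals`.

`filter_interior_sites` keeps sites whose midpoint is inside a domain and
≥ 2 kb (default) from both domain edges — used to average signals around
sites deep inside LADs.

Expression summaries convert counts to TPM (`1e6·(c/l)/Σ(c/l)`), compute
per-gene `log2((TPM_kd+ε)/(TPM_ctrl+ε))` with ε = 1 TPM to stabilise
silent genes, and test each gene group for symmetry around zero with the
two-sided Wilcoxon signed-rank test.

## Hi-C statistics

Matrices are dense, symmetric, per-chromosome, cis-only. Preparation:
contacts between bins closer than 1 kb are zeroed (at 2-kb bins this
touches only self-contacts); optional binomial thinning of the upper
triangle downsamples to a target total; iterative correction equalises
unmasked row sums to 1e-6 relative tolerance, after masking all-zero bins
and bins whose nonzero-cell count falls below the 5th percentile.
Expected contact at separation *s* is the mean over unmasked cells of
that diagonal, so every O/E diagonal has unit mean by construction.

**TAD calling** maximises the Armatus objective by dynamic programming:
domain quality `q(k,l) = s(k,l)/(l−k+1)^γ − μ(l−k+1)`, where `s` sums
within-domain contacts over pairs i < j (self-contacts excluded, which
prevents degenerate single-bin domains), `μ(d)` is the chromosome-wide
mean scaled density of all d-bin windows, domains span ≥ 2 bins, only
positive-quality domains score, gaps are allowed, and ties break toward
fewer domains. Matrices are preprocessed first: missing cells linearly
interpolated along diagonals, values clipped to the [P1, P99] range,
zeros replaced by half the smallest positive value, then ln-transformed.
The DP is verified against exhaustive partition enumeration for n ≤ 12
at γ ∈ {0.4, 0.6, 1.0} and recovers planted dense blocks exactly.

**ACF** (average contact frequency, a compaction proxy) is the mean O/E
over off-diagonal pairs inside a TAD; its knockdown/control log2FC is
reported per TAD with boundaries identical in both conditions. TADs are
grouped by `Jacc = (X−Y)/(X+Y)` with X the LAD coverage fraction and Y
the active-chromatin fraction: group A below −0.8, C above +0.8, B
otherwise, and `Jacc ≡ 0` (group B) when X = Y = 0.

**Compartments**: PC1 of the Pearson-correlation matrix of O/E rows,
sign-oriented so it correlates positively with an activity track (the A
compartment is positive). Saddles rank bins by PC1, drop the extreme 1%
at both ends, digitise the rest into equal-count quantiles (default 50)
and average O/E over quantile-pair blocks; the knockdown−control
difference is summarised over the 10 highest-quantile block (AA, by the
A-positive convention), the 10 lowest (BB) and the off-blocks (AB), each
with a Wilcoxon signed-rank test against zero.

**IS^m** is defined at 2-kb resolution as the mean O/E over the 4×4
square linking the four bins upstream to the four bins downstream of the
central bin — contacts of the central bin itself and its immediate
neighbours are excluded, so the score isolates contacts bridging regions
2–8 kb away on both sides. It is undefined within 4 bins of a chromosome
end or where all 16 cells are masked, and equals a 16-cell double-loop
oracle exactly. Anchor-averaged IS^m curves are smoothed by linear
interpolation across undefined positions before averaging. Pileups
average fixed-size O/E windows centred on anchor bins, skipping anchors
whose window leaves the chromosome.

## Nuclear geometry

The nuclear radius comes from the reconstructed volume under a spherical
assumption, `r = (3V/4π)^(1/3)`; locus-to-envelope distances are divided
by it. Normalised distances above 1 (reconstruction noise) are kept, with
a warning, rather than clipped. Distributions are compared with the
two-sided Mann–Whitney U test.

Diameter intensity profiles are normalised each to its own mean (making
the analysis invariant to per-nucleus gain), rescaled so the two
envelope-marker peaks — located as the argmax within each outer third of
the profile — map to positions 0 and 1, resampled, and averaged. The
peripheral-zone statistic is the per-nucleus mean intensity within 0.15
of either envelope end; conditions are compared per nucleus (not pooled
pixels) to avoid pseudo-replication, again by Mann–Whitney U. Under
same-distribution null simulations the test's type-I error stays below
0.07 at α = 0.05 over 200 runs.

## Synthetic generators

The generators plant exactly the structure each downstream stage is
meant to detect, at desk scale (two 2-Mb chromosomes at 300-bp DamID
bins; one 2-Mb chromosome at 2-kb Hi-C bins) so the entire pipeline runs
in seconds:

- **DamID**: per-bin log2 means of +1.2 inside planted LADs and −1.2
  outside, Gaussian bin noise of sd 0.4, local −1.5 dips at NPC-like
  sites planted inside LADs and +1.2 enrichment at nucleoplasmic sites
  between them. Counts are multinomial at fixed depth (default 10⁶ per
  replicate, matching RPM normalisation exactly), with log-normal
  accessibility noise shared between the Dam and fusion channels.
- **Hi-C**: expected intensity `s^−α` (α = 1), within-TAD multipliers,
  a ±checkerboard compartment factor, an extra multiplier on B–B cells
  (to emulate inactive-compartment contact gains), and a cross-anchor
  boost on cells linking offsets 1–4 on either side of anchor bins (the
  contact signature NPC attachment is proposed to create); Poisson noise
  around the expected intensity.
- **Geometry**: attached loci at mean 0.08R from the envelope, detached
  shifted inward by 0.10R, sd 0.07R; envelope-marker profiles with
  Gaussian end peaks; chromatin profiles either peripheral (end-peaked)
  or displaced (centre-weighted), with per-nucleus gain and additive
  noise.
- **Expression**: negative-binomial counts (dispersion 0.1) with a
  planted +0.5 log2 fold-change on the NPC-class genes in the knockdown.
- **Sequence**: ~50% A/T background with ≥95% A/T islands planted at
  given intervals.

What the generators do **not** emulate: GATC-fragment resolution and
restriction-site granularity of real DamID; mappability, copy-number and
GC biases of sequencing (so iterative correction is exercised as an
invariant, not stress-tested against realistic bias fields); replicate
batch effects; genome-scale chromosome counts and the real LAD/TAD size
distributions; optical PSF and segmentation error in imaging. Passing
tests therefore demonstrate correctness of the computations and
recoverability of planted structure under the stated noise — not
performance on any real dataset, whose printed summary numbers (site
counts, genomic coverages, TAD counts) depend on genome size and depth
and are not reproduced at desk scale.

## Numerical choices and degenerate inputs

- HMM: variance floor 1e-4; non-convergence returns the best model with
  a warning; a constant track collapses into one state without error.
- Iterative correction: non-convergence after 200 iterations returns the
  last iterate with a warning.
- Armatus preprocessing: diagonals with fewer than two finite cells stay
  masked; ln(0) is avoided by the half-minimum replacement.
- PC1 on a constant matrix raises a "degenerate" error rather than
  returning an arbitrary vector.
- Wilcoxon on all-zero differences is reported as p = 1.
- Permutation p-values never reach 0 by construction.
- 1-bin TADs have undefined ACF and are skipped with a warning.

## Problem sizes

Default test and report runs use: 4 Mb of DamID genome (~13,300 bins),
10⁶-contact to 2×10⁶-contact Hi-C maps of 500–1,000 bins, 100 nuclei per
geometry condition, 200 genes, and 200-repetition calibration loops for
the permutation and zone tests. These sizes were chosen so planted
effects are comfortably detectable at the stated noise levels while the
complete suite runs in well under a minute per stage.
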
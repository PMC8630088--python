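# Methods

`epiallele` implements the computational core of a study of spontaneous
epiallele formation in *Arabidopsis thaliana* epigenetic recombinant inbred
lines (epiRILs): how genes that normally carry only gene-body CG
methylation (gbM) acquire ectopic non-CG methylation (mCHG, mCWA) when the
genome is globally hypomethylated, where the loci controlling those gains
map, and how the gaining genes relate spatially to H3K9me2
heterochromatin. This note records the models, the numerical choices, and
what the built-in simulations can and cannot demonstrate.

## Per-site methylation calls

Whole-genome bisulfite sequencing reports, per cytosine, methylated reads
`mc` out of `total`. Unconverted cytosines create a false-methylation
background; the non-conversion rate `nc` is estimated as the pooled
`Σmc/Σtotal` over a fully unmethylated control contig (chloroplast DNA in
plants). A cytosine with at least `min_cov = 3` reads is tested with a
one-sided binomial test, `p = P(X ≥ mc | n = total, p = nc)`; p-values are
Benjamini–Hochberg adjusted over all tested sites of the sample and a site
is called methylated at `q < 0.05`. The FDR step is a deliberate choice —
with millions of sites a raw 5% test would flood downstream counts with
false methylated calls; the `fdr` knob is exposed for users who want the
uncorrected behaviour.

Sequence context is derived from the trinucleotide on the cytosine's
strand: CG (second base G), CHG (third base G), else CHH. CWA (W = A/T),
the CHH subcontext preferred by CMT2, is implemented as the trinucleotide
filter {CAA, CTA} within CHH; "non-CWA CHH" is its complement.

## Gene methylation-state classification

For each gene, called cytosines in the CDS of the primary transcript are
counted per context (`n`, methylated `k`). The genome-wide background `p0`
per context is the methylated fraction of all called CDS sites (each site
counted once under overlapping annotations). The per-gene statistic is the
upper binomial tail `P(X ≥ k | n, p0)` — inclusive, so `k = 0` always
gives 1 — adjusted per context across genes. With floor `n ≥ 20` in the
tested context and `α = 0.05`:

* **teM_mCHH** — `q_CHH < α` (CG and CHG unconstrained: both accompany mCHH);
* **teM_mCHG** — `q_CHG < α` and `q_CHH ≥ α` (CG unconstrained: mCG
  accompanies mCHG);
* **gbM** — `q_CG < α`, `q_CHG ≥ α`, `q_CHH ≥ α`;
* **UM** — ≥ 20 covered CHH sites, all `q ≥ α`, and at most 2 symmetric
  mCG dyads (both strands of a CG dyad called methylated; half-called
  dyads do not count) — the dyad filter removes residually methylated
  genes that pass the binomial screens;
* otherwise **unclassified**.

teM rules take precedence over gbM, which precedes UM; the classes are
mutually exclusive and exhaustive by construction. Correcting q-values
per context (rather than across the pooled 3 × genes tests) matches the
per-context thresholds of the rules; with balanced designs the difference
is negligible.

## Metaprofiles

Windowed profiles use the weighted methylation level `Σmc/Σtotal` over a
window's covered in-context cytosines (missing — not zero — when no site
is covered). A gene contributes 60 windows: 20 equal body windows
(remainder bases assigned to the last window; genes shorter than 20 bp get
missing body windows) and 20 windows of 50 bp on each 1-kb flank. For
minus-strand genes the vector is reversed so index 0 is always the 5'
upstream end. Group profiles are per-window means ignoring missing
entries.

## epiRIL haplotypes and the hypomethylation index

Stably inherited differentially methylated regions (DMRs) distinguish the
methylated wild-type parent from the hypomethylated *ddm1* parent. A
marker's state in a line is U (ddm1) when its pooled-context weighted
level is `< 0.5`, M (wild type) at `≥ 0.5`, NA when uncovered. Pooling
contexts uses all informative reads of the region; a CG-only mode is
available. The hypomethylation index `h` is the mean over non-NA markers
(M = 0, U = 1) and estimates the ddm1-derived genome fraction.

Parent-of-origin segments tile each chromosome: spans between concordant
markers inherit that parent; between discordant markers the breakpoint is
placed at the midpoint of the inter-marker gap (the data cannot localise
it more finely, and midpoint placement bounds the error by half the local
marker spacing); spans beyond the terminal markers or flanking NA markers
are unknown. A gene's parent is that of the segment containing its
midpoint — genes spanning breakpoints are rare at realistic marker
densities.

met1-derived chromosome segments are located by walking each chromosome's
gbM-gene exons into consecutive bins of exactly 10 exons (a short final
bin merges into its predecessor), flagging bins whose pooled exonic CG
level in the sample is reduced by more than 25% relative to the control,
and merging adjacent flagged bins.

## Ectopic gain calling

A gene gains ectopic methylation in a line when, over in-context gene-body
cytosines covered with ≥ 3 reads in both the line and the wild-type
control, the mean per-site level difference is ≥ 0.1, with a floor of
3 such sites. The mean of per-site differences (rather than the
difference of region-weighted levels) weights sites equally regardless of
coverage; the alternative is one switch away in
`call_gene_gain`/`gain_table` callers by computing weighted levels
directly. The gene body is the full gene span — ectopic gains in introns
count. Gain calling is antisymmetric: swapping sample and control negates
the mean difference.

Class enrichment of gaining genes uses a one-sided Fisher exact test
(alternative: odds ratio > 1) on the 2×2 table of gain × class membership
over all classified genes. Per gene, the association between methylation
change and `h` is screened with the Pearson coefficient across lines,
stratified by parent of origin; `|r| > 0.35` flags a responsive gene, and
zero-variance inputs yield an undefined, never-flagged coefficient.

## Methylation QTL mapping

Marker genotypes (M = 0, U = 1) feed a two-step map construction. First,
markers are stepped in by physical order and a candidate is rejected when
it associates with any accepted marker on a *different* chromosome
(one-sided Fisher in either direction, `p < 1e-4`) — such markers reflect
shared epigenetic state rather than linkage. Second, adjacent-marker
recombination fractions come from the observed discordance `R` with the
selfed-RIL correction `r = R / (2(1 − R))` (inverse of the map expansion
`R = 2r/(1+2r)`), capped at 0.5, and cM positions accumulate Haldane
distances `d = −50 ln(1 − 2r)`.

Scans use Haley–Knott regression: at each 1-cM grid point the phenotype is
regressed on the conditional probability of the ddm1 allele given the
nearest informative flanking markers (Markov interpolation with apparent
selfed-RIL recombination probabilities from the inverse Haldane map;
single-flank fallback at chromosome ends and across missing calls), and
`LOD = (n/2) log10(RSS0/RSS1)`, capped at 50 when the residual sum
vanishes. Haley–Knott was chosen over EM because the phenotypes (gain
counts and mean genic levels) are continuous with near-normal residuals at
these effect sizes. Genome-wide significance uses the conservative
order-statistic permutation threshold `ceil((n_perm+1)(1−α))`; a fixed
LOD-3 threshold is available as an option. Peaks are local maxima above
threshold separated by a ≥ 1.5-LOD valley, with 1.5-LOD support
intervals; a peak is *cis* when it lies within 1 Mb of the scanned gene on
the same chromosome (the window is configurable), and its compartment is
read from a supplied heterochromatin BED.

## Gene × H3K9me2 contacts

Significant Hi-C contacts are consumed as a BEDPE (the spline-based
significance model that produced them is an upstream tool's concern, not
re-implemented here). A contact links gene and mark when one anchor
overlaps ≥ 1 bp of an H3K9me2 peak and the other overlaps ≥ 1 bp of the
gene; multi-peak anchors count once per contact per gene. Distance is the
nearest-edge gap between gene and contacted peak, intra-chromosomal only;
inter-chromosomal contacts contribute to counts but not distances.
Class enrichment of contacted genes uses the one-sided Fisher test;
count/distance distributions are compared pairwise with two-sided
Wilcoxon rank-sum tests — exact when `min(n1,n2) ≤ 8` without ties,
tie-corrected normal approximation otherwise — without multiplicity
adjustment, as is conventional for these descriptive panels.

## Synthetic data

The generator produces every input with the statistical structure the
analysis assumes, plus truth tables. Default study conditions: 5
chromosomes of 3 Mb with a central pericentromeric heterochromatin block
(20%), 600 genes (300 gbM / 100 teM / 200 UM) placed without overlap in
the euchromatic arms with log-normal lengths (gbM drawn longer, median
≈ 2.2 kb vs ≈ 1.5 kb), 100 quasi-evenly spaced 300-bp DMR markers, 150
lines, read depth Poisson(20), non-conversion 0.005.

Cytosine positions are *placed*, not read from sequence: CG dyads every
40 bp, CHG every 25 bp, CHH every 15 bp (half CWA) within genes — ranked
realistically, CHH densest and CG sparsest — plus marker and
heterochromatic intergenic sites and a 1000-site unmethylated control
contig. Wild-type per-site rates: gbM 0.8/0.02/0.02, teM 0.9/0.7/0.15,
UM 0.005 everywhere, heterochromatin 0.9/0.7/0.2 (CG/CHG/CHH); the
ddm1-like parent multiplies heterochromatic and marker rates by 0.1.
Read counts are `total ~ Poisson(depth)`,
`mc ~ Binomial(total, rate(1−nc) + (1−rate)nc)`.

Each line's genome is a mosaic with Poisson(2.0) breakpoints per
chromosome (a ~1-Morgan meiotic map doubled by selfed-RIL map expansion)
and a fair coin for the starting parent; marker alleles and the true `h`
follow the mosaic. Ectopic gains are planted per line × gbM gene with
probability `logistic(−3.0 + 2.5·h + 2.0·[ddm1 allele at the designated
pericentromeric QTL marker])`; UM genes gain at 10% of that probability,
teM genes never (their non-CG methylation is already high). A gain adds
Δ = 0.25 to the gene's CHG and CWA site rates. The logistic form keeps
probabilities bounded while giving the monotone dependence on `h` the
analysis is meant to detect. Contacts: H3K9me2 peaks are 2-kb bins inside
the heterochromatin blocks; each gene receives
`Poisson(1.0 × 2.0^flag)` gene↔peak contacts (anchors are 2-kb bins,
90% intra-chromosomal, q-values below 0.01).

**What the simulations do not emulate:** sequence composition and
mappability, correlated methylation along regions (sites are
conditionally independent given the rate map), partial/heterozygous
methylation states, epimutation during propagation, marker-state
instability, and Hi-C distance decay. Passing recovery tests therefore
demonstrates the correctness and calibration of the statistical machinery
under the assumed generative model, not performance on real WGBS/Hi-C
libraries.

## Problem sizes in the test bench

The bundled checks run the classifier on the default 600-gene parent at
20×; haplotype recovery on 30 lines; QTL power with a planted additive
QTL explaining 30% of phenotypic variance in 150 lines, 200 permutations
per scan and 50 replicates (with matched null replicates); gain-caller
specificity on 10 lines at 30× with gains disabled; and contact power with
200 genes per group over 30 replicates. Stochastic bounds (null
family-wise rate, false-gain rate) are asserted through exact binomial
critical values at a 1% test-level error, since a point assertion at the
nominal rate would fail on sampling noise alone.

## Known limitations

* Marker-state imputation and pedigree-aware phasing are out of scope; NA
  markers leave unknown segments.
* The scan is single-QTL; closely linked or epistatic architectures will
  be summarised by their marginal peaks.
* `estimate_rf` assumes a selfed RIL design; other crossing schemes need a
  different correction.
* Exact rank-sum enumeration is used only for small tie-free groups; with
  ties the normal approximation is applied at any size.
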
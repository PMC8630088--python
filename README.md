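# epiallele

Analysis toolkit for **spontaneous epiallele formation** in *Arabidopsis
thaliana* epigenetic recombinant inbred lines (epiRILs), aimed at plant
epigenomics groups working with whole-genome bisulfite sequencing, DMR
marker panels and Hi-C. The package covers the full computational chain:

* **Gene methylation states** — per-cytosine binomial methylation calls
  against the bisulfite non-conversion rate (chloroplast control), then
  per-gene classification into gbM / teM (mCHG, mCHH) / UM using
  upper-tail binomial tests `P(X ≥ k | n, p₀)` on CDS cytosines against
  the genome-wide background `p₀`, BH-corrected, with a 20-site floor and
  a ≤ 2 symmetric-mCG filter for UM.
* **epiRIL haplotypes** — DMR-marker states at the 0.5 weighted-level
  cutoff, the hypomethylation index `h` (mean marker value, M = 0,
  U = 1), parent-of-origin segment maps, and met1-derived region
  detection (10-exon bins, > 25% mCG reduction).
* **Ectopic gains** — per-gene mCHG/mCWA gain calls (≥ 3 shared sites,
  mean per-site difference ≥ 0.1 vs the wild-type parent), one-sided
  Fisher class enrichment, and the per-gene Pearson screen of methylation
  change against `h` (|r| > 0.35).
* **Methylation QTL** — genetic-map construction from binary marker
  genotypes (selfed-RIL correction `r = R/(2(1−R))`, Haldane distances),
  Haley–Knott interval mapping with `LOD = (n/2)·log₁₀(RSS₀/RSS₁)`,
  permutation thresholds, 1.5-LOD support intervals, cis/trans and
  heterochromatin annotation.
* **Gene × H3K9me2 contacts** — overlap of significant Hi-C contacts
  with peak and gene intervals, contact-count/distance summaries, Fisher
  enrichment and two-sided rank-sum comparisons.
* **Synthetic data** — a generator that emulates the whole study design
  (two parents, recombination mosaics, planted gains driven by `h` and a
  pericentromeric trans-QTL, binomial read sampling, contact lists) with
  ground-truth tables, so every stage is testable without external data.

## Worked example

```python
import pandas as pd
from epiallele import (SimulationConfig, simulate_experiment,
                       estimate_nonconversion, call_site_methylation,
                       classify_genes, call_marker_states, hypomethylation_index,
                       gain_matrix, class_enrichment, build_map, hk_scan,
                       permutation_threshold, find_peaks_and_classify)

sim = simulate_experiment(SimulationConfig(n_lines=40), seed=11)

nc = estimate_nonconversion(sim.wt_sites, "ChrC")
called = call_site_methylation(sim.wt_sites, nc)
states = classify_genes(sim.genes, called)
print(round(nc.rate, 5), states["label"].value_counts().to_dict())

h = pd.Series({line: hypomethylation_index(call_marker_states(s, sim.markers))
               for line, s in sim.line_sites.items()})
calls, summary, levels = gain_matrix(sim.genes, sim.line_sites, sim.wt_sites, "CHG")

classes = states.set_index("gene_id")["label"].replace(
    {"teM_mCHG": "teM", "teM_mCHH": "teM"})
enr = class_enrichment(calls.groupby("gene_id")["is_gain"].any(), classes)
print(enr.to_string(index=False))

mpos = pd.DataFrame([(m.id, m.interval.chrom, m.interval.midpoint)
                     for m in sim.markers], columns=["marker", "chrom", "bp"])
geno = sim.truth.genotypes.astype(float)
gmap = build_map(geno, mpos)
y = summary.set_index("line_id")["n_gain"].reindex(geno.index).astype(float)
thr = permutation_threshold(gmap, geno, y, n_perm=200, alpha=0.05, seed=0)
curve = hk_scan(gmap, geno, y, trait="n_gain")
hits = find_peaks_and_classify(curve, thr, het_intervals=sim.het_intervals)
print("LOD threshold (200 perms): %.2f" % thr)
for hit in hits:
    print("QTL peak: %s @ %.0f cM (bp %d)  LOD %.1f  %s" %
          (hit.chrom, hit.peak_cM, hit.peak_bp, hit.lod, hit.compartment))
```

Output:

```
0.00463 {'gbM': 300, 'UM': 200, 'teM_mCHH': 100}
label  n_genes  prop_gaining  odds_ratio            p
   UM      200         0.755    1.027211 4.889225e-01
  gbM      300         1.000         inf 2.191357e-56
  teM      100         0.000    0.000000 1.000000e+00
LOD threshold (200 perms): 2.84
QTL peak: Chr1 @ 49 cM (bp 1559415)  LOD 22.3  heterochromatin
```

Reading it: the estimated non-conversion rate (0.0046) matches the
simulated 0.005; all 600 genes are recovered in their planted classes.
Across 40 lines, genes that ever gain mCHG are overwhelmingly gbM genes
(one-sided Fisher p ≈ 2e-56), while teM genes — already CHG-methylated —
never register a gain and UM genes gain at background. Mapping the
per-line count of gaining genes as a quantitative trait finds a single
QTL at 49 cM on chromosome 1 (LOD 22.3, genome-wide 5% threshold 2.84)
inside pericentromeric heterochromatin, 15 kb from the planted trans-QTL
marker.

See `docs/methods.md` for the models, default parameters and the
generator's assumptions.

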
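# epigenotyper

DNA-methylation epigenotyping of colorectal neoplasms from Infinium 450k
β-value matrices.

Colorectal cancer stratifies into DNA-methylation epigenotypes: a
high-methylation epigenotype (HME, the classical CIMP-high subtype, tied to
*BRAF* mutation), an intermediate epigenotype (IME, tied to *KRAS* mutation),
a low epigenotype (LME), and a normal-like epigenotype (NME) whose tumors
cluster with normal mucosa. This package re-implements, as a tested and
reusable pipeline, the genome-wide analysis that classifies familial
adenomatous polyposis (FAP) and sporadic colorectal neoplasms into these four
epigenotypes and characterises the FAP-specific pattern: most FAP neoplasms
are NME, a minority are IME with *KRAS* mutations, and FAP IME tumors carry
systematically **less** methylation than sporadic IME tumors.

It is aimed at epigenomics researchers who have probe × sample β-value
matrices (β ∈ [0, 1], the Infinium methylated-signal fraction) plus probe
annotation and want a reproducible epigenotype classification without
touching raw IDATs.

## The analysis

1. **FFPE-concordant probes.** For paired frozen/FFPE measurements of the
   same tumors, keep probes with |β_frozen − β_FFPE| < 0.1 in *every* pair
   (the intersection over pairs), removing probes distorted by fixation.
2. **Promoter, high-CpG genes.** Per gene, keep the single probe nearest the
   transcription start site; keep genes whose probe sits in CpG-rich sequence,
   i.e. observed/expected CpG ratio of the ±250 bp window
   `N_CpG / (N_C · N_G / L) > 0.48`.
3. **Variance filter.** Keep probes with across-sample SD (n−1 denominator)
   strictly above 0.10.
4. **Two-way hierarchical clustering.** Samples: Pearson correlation distance
   (1 − r) with average (UPGMA) linkage; probes: city-block distance with
   complete linkage. Cut the sample tree at k = 4, rank clusters by mean β and
   label them HME > IME > LME > NME; the lowest cluster must contain the
   majority of normal-mucosa samples. A FAP-only re-clustering at k = 2 (with
   smallest-cluster outlier flagging) confirms the IME/NME two-subtype split.
5. **Marker classes.** Per gene, mean β per epigenotype (sporadic CRC only);
   a gene is *methylated* in an epigenotype when its mean β ≥ 0.2. The nested
   patterns define four disjoint classes: high (HME only), intermediate
   (HME+IME), common (HME+IME+LME), and normally methylated (all four).
6. **Statistics.** Marker-set comparisons pool gene × sample β-values and use
   a pooled-variance two-sided t-test; epigenotype × phenotype 2×2 tables
   (KRAS status from pyrosequencing allele quantification at the BRAF 1799 /
   KRAS 34/35/37/38 hotspots, ≥20% mutant allele with ≥40% tumor content) are
   tested with an exact-enumeration two-sided Fisher test and the χ² closed
   form, reported side by side.

A fully deterministic synthetic-cohort generator (`epigenotyper.synthetic`)
plants all of this structure — four epigenotype blocks, the four marker
classes at the published group means, FAP-IME attenuation, the KRAS
association, FFPE perturbation — so every stage is testable end to end
without external downloads. See `docs/methods.md` for the model and its
assumptions.

## Worked example

```python
import epigenotyper as eg

cohort = eg.generate_cohort(eg.fast_cohort_config(), seed=7)   # ~107 samples x 301 genes
result = eg.run_pipeline(eg.PipelineConfig(seed=7), cohort.beta,
                         cohort.annotation, cohort.metadata)

print("epigenotype counts:", result.assignment.labels.value_counts().to_dict())
print("marker classes:", result.marker_sets.counts())
comp = next(c for c in result.comparisons if c.marker_class == "intermediate")
print(f"FAP IME vs sporadic IME (intermediate markers): "
      f"{comp.mean_a:.2f} +/- {comp.se_a:.2f} vs {comp.mean_b:.2f} +/- {comp.se_b:.2f}, "
      f"p = {comp.p_value:.2g}")
```

prints

```
epigenotype counts: {'LME': 38, 'IME': 29, 'NME': 22, 'HME': 18}
marker classes: {'high': 56, 'intermediate': 21, 'common': 45, 'normal': 12}
FAP IME vs sporadic IME (intermediate markers): 0.23 +/- 0.01 vs 0.35 +/- 0.00, p = 6.5e-26
```

All 107 samples land in their planted epigenotype (the counts are the planted
block sizes), the marker classes are recovered at the scaled gene counts, and
the FAP-IME methylation deficit (pooled mean β 0.23 vs 0.35 over the
intermediate markers) is highly significant even with two FAP IME samples.

The same flow is available from the shell:

```bash
epigenotyper simulate --seed 7 --sample-scale 0.25 --gene-scale 0.3 --out-dir sim/
epigenotyper run --matrix sim/beta.tsv --annotation sim/annotation.tsv \
    --metadata sim/metadata.tsv --seed 7 --out-dir results/
```

which writes `assignments.tsv`, `markers.tsv`, `comparisons.tsv`,
`associations.tsv`, Newick dendrograms and a `manifest.json` with per-stage
counts. Reruns with the same inputs and seed are byte-identical.

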
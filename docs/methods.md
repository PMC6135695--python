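# Methods

This note documents the models, parameters and design choices behind
`epigenotyper`, and what the synthetic cohorts do and do not establish about
real data.

## Data model

The pipeline's currency is the probe × sample matrix of Infinium β-values
(methylated-signal fraction, in [0, 1]; `NaN` = missing measurement). Probe
context is a table keyed by probe id (chromosome, 1-based position, gene,
TSS position, strand, and either a precomputed CpG score or a 500-bp window
sequence); sample phenotype is a table keyed by sample id (cohort,
preparation, anatomic location, histology, KRAS/BRAF status). Coordinates are
1-based fully closed, matching the Infinium manifest convention. All tabular
I/O is TSV (comma accepted via `sep=","`); windows travel as FASTA keyed by
probe id.

Missing-β policy (per operation, since detection-failure handling is
unstandardised): concordance treats a probe with a missing value in either
member of a pair as non-concordant for that pair (conservative retention);
the variance filter drops missing values per probe and requires ≥ 2
observations; per-epigenotype means exclude missing values and refuse a gene
with an empty group; clustering requires a complete matrix.

## Filter cascade

* **FFPE concordance** — per pair, keep probes with |β_frozen − β_FFPE|
  strictly < `delta_beta_threshold` (default 0.1); the analysis set is the
  intersection over pairs, so it can only shrink as pairs are added.
* **Promoter probe selection** — one probe per gene, minimising
  |position − TSS|; a tie is broken toward the smaller genomic coordinate
  (deterministic, documented).
* **High-CpG genes** — the CpG score of the probe's 500-bp window (±250 bp)
  is the Takai–Jones/Weber-style observed/expected ratio
  `N_CpG / (N_C · N_G / L)`, with N bases excluded from all counts (`L` is
  the non-N length) and score 0 when the window has no C or no G. The score
  is strand-symmetric because CG reverse-complements to CG. A gene qualifies
  when its selected probe's score strictly exceeds
  `cpg_score_threshold` (default 0.48 — the conventional o/e cutoff scale;
  if a user's annotation uses a GC-combined score instead, the threshold is
  configurable). Promoter membership is taken from the annotation; the tool
  does not infer promoters from distance windows.
* **Variance filter** — sample SD per probe with the n−1 denominator (the
  default of mainstream statistical environments), strictly >
  `sd_threshold` (default 0.10).

All threshold comparisons in the cascade are strict, as printed in their
sources; the marker threshold below is the one inclusive boundary.

## Clustering and epigenotype assignment

Samples are clustered with centered Pearson correlation distance (1 − r) and
average (UPGMA) linkage; an uncentered (cosine) variant is available by flag
for compatibility with Cluster-3.0-style "uncentered correlation". Probes
use city-block distance with complete linkage. Samples and probes are
canonically sorted by id before any distance computation, which removes
linkage tie order-dependence and makes outputs byte-identical across runs. A
zero-variance sample is an error (its correlation is undefined), as is a
matrix with missing values.

Flat clusters come from cutting the tree at exactly k clusters
(`scipy fcluster` maxclust; no dynamic cut). Clusters are ranked by mean β
over the clustering probes and labeled in descending order — HME, IME, LME,
NME at k = 4; IME, NME in the two-subtype mode at k = 2. An exact tie in
cluster means is reported as an error rather than broken silently. When
normal-mucosa samples are present, the lowest cluster must contain more than
half of them (that is what "normal-like" means); violation raises a labeled
inconsistency error instead of mislabeling.

**Outlier rule.** With `min_cluster_size` set (default 2 in the pipeline and
in the two-subtype mode), clusters below the minimum are flagged as outliers
and the remaining samples re-cut at k — a single pass, which operationalises
the informal "considered as an outlier" decision and avoids cascading
removal when a legitimate small group (e.g. a 1-sample IME group in a small
cohort) remains after the re-cut. The rule is exposed for the main k = 4
clustering too, so one aberrant profile cannot consume a cluster.

## Marker classes and comparisons

Per-gene, per-epigenotype mean β is computed over sporadic CRC samples by
default (the class definitions are sporadic; the cohort filter is
configurable, e.g. for the adenoma comparison). *Methylated* means
mean β ≥ `marker_beta_threshold` (default 0.2) and *unmethylated* is the
strict complement — the two printed variants ("≥ 0.2" and "> 0.2") differ
only on the measure-zero boundary, and the complementary reading guarantees
every gene is classifiable. The four nested patterns across HME ⊃ IME ⊃ LME
⊃ NME give disjoint high / intermediate / common / normally-methylated
classes; anything else is unclassified.

Group comparisons pool the gene × sample β-values of a marker class within
each group and report mean, standard error (SD/√n of the pooled values) and
a pooled-variance two-sided Student's t-test. Pooling is the only unit that
yields standard errors of ±0.00–0.01 and vanishingly small p-values at
hundreds of genes × tens of samples; whether the original analyses pooled
identically is not asserted.

## Association tests and mutation calls

`fisher_exact_2x2` enumerates the margin-fixed hypergeometric distribution
with exact integer weights and sums all tables whose probability is ≤ the
observed table's, within 1e-7 relative tolerance for floating-point ties
(the minimum-likelihood two-sided convention of mainstream environments).
`chi_square_2x2` is the closed form n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)), with
an optional Yates correction subtracting n/2 from |ad−bc| (floored at 0).
Both are reported side by side: published two-group p-values for tables like
[[5,0],[4,13]] are often better matched by the uncorrected χ² (≈ 0.0022)
than by Fisher enumeration (≈ 0.0048), and the discrepancy is surfaced, not
hidden. The odds ratio is ad/bc with a flagged Haldane 0.5 correction when a
cell is zero. No multiple-testing correction is applied.

Mutation calls: a pyrosequencing locus (BRAF 1799; KRAS 34/35/37/38) is
mutant when its mutant-allele percentage is ≥ 20% ("set at 20%" read as
inclusive; configurable), wildtype below, and not evaluable when tumor cell
content is known and < 40%. A gene is mutant if any evaluable locus is
mutant and wildtype if all evaluable loci are wildtype — hotspot panels are
disjunctive by design. Calls are monotone in the allele fraction and
invariant to locus order.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, with
defaults at the reported cohort conditions:

* **Cohort sizes** — 297 sporadic CRC (62/90/135/10 across HME/IME/LME/NME),
  45 sporadic adenomas (5/25/14/1, the HME adenomas including up to three
  SSA), 37 normal mucosae (all NME), 23 FAP neoplasms (5 IME, 17 NME, 1
  planted outlier). The sporadic per-epigenotype split is chosen once at
  realistic CIMP-fraction proportions with the NME count (10) matching the
  reported cohort.
* **Marker classes** — sizes 186/69/149/41, with class × epigenotype means

  |              |  HME |  IME |  LME |  NME |
  |--------------|------|------|------|------|
  | high         | 0.49 | 0.17 | 0.15 | 0.11 |
  | intermediate | 0.56 | 0.35 | 0.15 | 0.10 |
  | common       | 0.55 | 0.48 | 0.34 | 0.11 |
  | normal       | 0.70 | 0.52 | 0.35 | 0.45 |

  High/intermediate/common carry the published sporadic group means where
  printed; the remaining cells are chosen once: below 0.2 with margin where
  the class is unmethylated, and — for the normally-methylated class, whose
  group means are not printed anywhere — spread widely enough that the class
  passes the SD > 0.10 variance filter (as such genes did in the real probe
  set) while every mean stays ≥ 0.2. Normal mucosa at 0.45 reflects genuine
  methylation of such genes in normal tissue.
* **Filler genes** — 556 additional genes model the variable-but-unclassified
  majority of real clustering probes. Each draws a random
  methylated/unmethylated pattern over the four epigenotypes from the 12
  non-nested patterns (low means U(0.09, 0.14), high U(0.30, 0.55)). They
  stay unclassified under marker extraction, mostly pass the variance
  filter, and — critically — decorrelate the epigenotypes: nested-only
  profiles differ mainly in overall level, which centered correlation
  distance cancels, and a generator without such genes cannot be separated
  by the analysis's own sample metric.
* **FAP attenuation** — FAP IME samples draw intermediate markers at mean
  0.22 (vs sporadic 0.35) and common markers at 0.34 (vs 0.48), the printed
  group means. Adenoma samples use the sporadic means (a declared
  simplification; the real adenoma means differ slightly and nothing
  downstream depends on them).
* **Outlier** — the planted FAP outlier has the inverted NME profile
  (1 − mean per gene), anti-correlated with every epigenotype, to exercise
  smallest-cluster flagging.
* **Mutations** — the planted FAP contingency tables are KRAS
  [[5,0],[4,13]] (IME/NME × mutant/wildtype), location [[5,0],[4,13]]
  (proximal/distal) and histology [[3,2],[13,4]] (adenoma/cancer), realised
  as per-locus pyrosequencing records (mutant loci at 30–70%, background at
  0–8%, tumor content 45–90%; the outlier at 30% content, hence not
  evaluable). BRAF is wildtype throughout the FAP cohort.
* **Noise** — truncated normal per value, default SD 0.05, clipping to
  [0, 1]; the clipped fraction is recorded in the truth object and stays
  under 1% at the default means. A moment-matched beta-distribution mode is
  available for strictly bounded draws. Real per-gene variance structure is
  unknown (only pooled standard errors are published); the single-SD noise
  model is a declared simplification.
* **FFPE pairs** — frozen = base profile; FFPE adds small noise plus, for a
  planted discordant fraction (default 20%), a shift (default 0.3, directed
  away from the nearer boundary) that must exceed the concordance threshold,
  else the generator refuses. The planted concordant sets are recorded.
* **Probe windows** — 500-bp sequences hitting a target o/e CpG ratio by
  placing `round(target · N_C·N_G/L)` CG dinucleotides among fixed C/G
  content, every remaining C/G followed by A so no accidental CG forms;
  the construction grid is within 0.02 of any reachable target.

Everything flows from a single `numpy` Generator seeded by the config seed;
identical (seed, config) gives identical bytes.

**Scales.** Tests and the repeated-seed acceptance measurements use
`fast_cohort_config()`: 0.25×/0.3× proportional scaling (~107 samples × 301
genes) except that the smallest sporadic group (NME) keeps 8 samples — a
3-sample group mean (SE ≈ 0.03 at noise 0.05) is too unstable for 0.2-
threshold classification, and realistic cohorts of this design keep n ≈ 10
in their smallest group.
Marker-class recovery, FAP attenuation and the two-subtype reconstruction
are measured at the full default scale, where generation and clustering still take
well under a second per cohort.

**What passing tests show — and don't.** On these cohorts the pipeline
recovers planted epigenotypes (ARI ≥ 0.95), marker classes (exactly), the
FAP methylation deficit, and the planted associations. Real 450k data adds
probe-level variance heterogeneity, batch and tumor-purity effects,
cross-reactive probes and detection failures, none of which the generator
models; passing here validates the machinery and its decision rules, not
robustness to those artifacts.

## Numerical and degenerate-input choices

* Sample/probe canonical ordering by id; deterministic nearest-TSS
  tie-break; exact-tie cluster means are an error.
* Fisher tie tolerance 1e-7 relative; integer-weight enumeration avoids
  cancellation for n into the thousands.
* Cutting a tree whose tie structure yields fewer than k clusters is an
  error, as is re-clustering a subset that leaves fewer than k samples after
  outlier removal.
* Readers name the offending row/column in every rejection and never coerce
  silently; writers emit ≥ 6 significant digits so write∘read is the
  identity within 1e-5 relative.

## Known limitations

* The high-CpG score threshold's exact provenance (pure o/e vs a
  GC-combined score) is ambiguous in the source literature; the o/e reading
  is the default and the threshold is configurable.
* Marker-class definitions assume the four-epigenotype labeling succeeded;
  there is no soft assignment or consensus clustering, and k is fixed by
  design.
* The pooled t-test treats gene × sample values as exchangeable within a
  group, ignoring gene- and sample-level correlation; its p-values are
  anti-conservative in the same way the original pooled analyses are.
* The generator's group-mean parameterisation cannot express per-gene effect
  heterogeneity within a marker class.
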
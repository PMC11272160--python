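# amniowave

Tools for analyzing BMP4-driven amnion differentiation time courses in
human pluripotent stem cell models: gene filtering and median-of-ratios
normalization of bulk RNA-seq counts, consecutive-timepoint differential
expression, classification of upregulated genes into five temporal
activation waves, and projection of bulk samples onto an annotated
single-cell embryo reference to transfer cell-type identities.

It is written for computational biologists studying early lineage
specification who have a dense sampling of timepoints after a signaling
trigger (here, BMP4 addition at t = 0 over 0, 0.5, 1, 3, 6, 12, 24, 48 hr
in triplicate) and want to know *when* each responsive gene first switches
on, and *which* reference cell state each bulk sample most resembles.
Because the motivating datasets are controlled-access, the package ships a
synthetic-data module that emulates both the time course and the
single-cell reference with machine-readable ground truth, so the entire
pipeline is testable offline.

## The methods in brief

**Wave classification.** Counts are filtered (a gene is kept if some
sample has ≥ 10 reads and its maximum exceeds 30), normalized by DESeq2-style
median-of-ratios size factors
(sf<sub>s</sub> = median<sub>g</sub> K<sub>gs</sub>/(∏<sub>s</sub>K<sub>gs</sub>)<sup>1/n</sup>
over all-positive genes), and tested between every adjacent pair of
timepoints on log2(normalized + 1) values. The default test is a moderated
t: pooled per-gene variances are shrunk toward an empirical-Bayes prior
fitted across genes, which keeps the test both calibrated and powered at
triplicate group sizes. A gene joins a wave at the earliest contrast
showing significant upregulation (BH FDR < 0.05 and fold change > 2):
first significance at 0.5 or 1 hr ⇒ *immediate*, 3 or 6 hr ⇒ *early*,
12 hr ⇒ *intermediate-1*, 24 hr ⇒ *intermediate-2*, 48 hr ⇒ *late*;
otherwise *unassigned*.

**Atlas projection.** Each bulk sample is split into 100 multinomial
pseudo-single-cells at reference cell depth, embedded by the reference's
log-TF-IDF + truncated-SVD (LSI) model, placed in the reference's 2-D
embedding by inverse-distance-weighted k-nearest-neighbor transfer, and
summarized by the medoid of its pseudo-cells; the sample inherits the
cluster label of the Euclidean-nearest reference cell.

## Worked example

```python
import amniowave as aw

# simulate the default time course (8 timepoints x 3 replicates, 2000
# genes, 100 genes per wave activating at fold 8 under NB noise)
matrix, truth = aw.generate_time_course(aw.SimConfig(seed=1))
filtered = aw.filter_low_expression(matrix)
norm = aw.normalize_counts(filtered, aw.size_factors_median_ratio(filtered))
contrasts = aw.consecutive_contrasts(norm)      # 7 adjacent-timepoint tests
assignment = aw.assign_stages(contrasts)
print("genes after filtering:", filtered.n_genes)
print("wave sizes:", assignment.stage_counts())
```

prints

```
genes after filtering: 1813
wave sizes: {'immediate': 101, 'early': 100, 'intermediate-1': 100,
             'intermediate-2': 100, 'late': 100, 'unassigned': 1312}
```

i.e. the classifier recovers the five planted 100-gene waves (499 of the
500 planted genes get their true wave on this seed; one background gene is
mis-staged). The same stages run from the shell:

```sh
amniowave run-all --config examples/pipeline.json --outdir out/
```

which also generates a synthetic 5-cluster reference atlas
(Epiblast → PrimitiveStreak → TBXTlow → Amnion → NascentMesoderm laid
along a trajectory), projects all 24 bulk samples onto it, and writes a
`manifest.json` with content hashes of every output.

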
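# deadstab

Analysis toolkit for studying **mRNA deadenylation and stability in
pancreatic β cells** — for computational biologists who start from count
matrices, qPCR tables, fluorescence traces and gel profiles rather than raw
reads or images.

When a deadenylase subunit such as CNOT3 is lost, its target mRNAs keep
long poly(A) tails, decay more slowly, and accumulate — including β-cell
"disallowed" genes whose derepression erodes β-cell identity. Detecting
this requires several distinct quantitative readouts, which this package
implements as one tested, reusable pipeline:

| stage | module | core idea |
|---|---|---|
| Differential expression | `deadstab.de` | filter (CPM ≥ 1 in ≥ 3 samples), TMM normalization, NB exact test, BH-FDR |
| mRNA stability | `deadstab.stability` | ∆ = exon log₂FC − intron log₂FC; paired interaction test; target classes |
| Ca²⁺ connectivity | `deadstab.calcium` | all-pairs Pearson R, circular-shift permutation null, epoch AUC |
| Decay kinetics / qPCR | `deadstab.kinetics` | ∆∆CT, Act-D decay normalization, half-life fits, RIP enrichment |
| Poly(A) tails | `deadstab.polya` | gel-lane calibration, fraction of tails > 50 nt |
| Enrichment / proteome | `deadstab.enrich` | GSEA running-sum ES with permutation p; gene↔protein logFC correlation |
| Synthetic data | `deadstab.synthio` | seeded generators with recorded ground truth for every stage |

## The core statistic

Exonic reads report steady-state mRNA abundance; intronic reads report
transcription (pre-mRNA). For each gene the change in mRNA half-life
between knockout and control is estimated as

    ∆exon−∆intron  =  log₂FC(exon) − log₂FC(intron)

so transcriptional changes cancel and a positive ∆ means stabilization.
Because both read classes come from the same library, the package (a)
normalizes them with shared per-sample factors, so normalization error
cancels in ∆, and (b) tests significance by conditioning on each sample's
exon+intron total — the NB interaction model with per-sample intercepts
reduces exactly to binomial logistic regression of exon counts on
genotype. A transcript is called a deadenylase *target* when it is both
stabilized and upregulated. See `docs/methods.md` for the full model.

## Worked example

```python
from deadstab import synthio, stability, kinetics

# 2,000 genes, 3 control vs 3 knockout; 10% of genes stabilized (+1.5 log2),
# 10% transcription-changed; NB dispersion 0.1 — with ground truth recorded
exon, intron, truth = synthio.simulate_exon_intron_counts(2000, 3, seed=7)

records, summary = stability.stability_pipeline(exon, intron)
print("stabilized:", summary.n_stabilized,
      "stabilized+up:", summary.n_stabilized_and_up,
      "fraction_up: %.3f" % summary.fraction_up)
```

```
stabilized: 202 stabilized+up: 148 fraction_up: 0.733
```

202 genes are called stabilized (interaction FDR < 0.05 with ∆ > 0) —
close to the 200 planted — and 73% of them are also significantly
upregulated, the overlap that defines deadenylase targets. The top calls
show the anatomy of the statistic: both fold changes rise, but ∆ isolates
the post-transcriptional part:

```
gene_id  exon_logfc  intron_logfc    delta          fdr         class
 g01901    3.248204      1.629294 1.618910 2.196033e-50 stabilized_up
 g00002    3.121582      1.537849 1.583733 2.061787e-47 stabilized_up
 g00501    2.838308      1.279855 1.558453 1.060184e-45 stabilized_up
```

Checked against the generator's truth, the stabilized call recovers 99.5%
of planted genes at this depth. Decay kinetics work the same way:

```python
course = synthio.simulate_decay({"control": 2.0, "knockout": 8.0},
                                cv=0.05, n_reps=3, seed=7)
norm = kinetics.normalize_decay(course)          # 0 h -> 100%
fit = kinetics.fit_half_life(norm[norm.genotype == "knockout"])
res = kinetics.compare_decay(norm[norm.genotype == "control"],
                             norm[norm.genotype == "knockout"])
```

```
control:  t_half = 2.00 hr (95% CI 1.99-2.01)
knockout: t_half = 7.81 hr (95% CI 6.19-10.55)
stabilization test: p = 1.14e-06, direction = stabilized
```

## Command line

Every stage is also a `deadstab` subcommand operating on TSV/CSV files:

```bash
deadstab simulate counts --n-genes 2000 --seed 7 --out sim/
deadstab de --counts sim/exon_counts.tsv --groups sim/groups.tsv --out de.tsv
deadstab stability --exon sim/exon_counts.tsv --intron sim/intron_counts.tsv \
                   --groups sim/groups.tsv --out stability.tsv
deadstab connectivity --traces traces.csv --epochs epochs.csv --out conn/
deadstab decay --input decay.csv --out halflives.tsv
deadstab polya --profile lane.csv --marker marker.csv --threshold 50
deadstab gsea --ranking de.tsv --sets disallowed.gmt --nperm 1000
```

Count TSVs have a `gene_id` first column and one column per sample; trace
CSVs have a `t_s` time column plus one column per cell with an epochs
sidecar (`name,start_s,end_s`); Ct tables carry
`sample,group,ct_target,ct_ref`; decay tables carry
`gene,genotype,replicate,time_hr,value`.

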
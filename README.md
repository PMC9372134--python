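# markwriter

Chromatin-targeting analysis of histone-mark writers.

How does a histone methyltransferase find its target genes? Two broad
mechanisms are distinguished in plants and animals: *co-transcriptional*
recruitment (the writer travels with RNA polymerase II, so its mark tracks
transcription) and *epigenome/sequence-cue* recruitment (the writer reads
pre-existing chromatin modifications or promoter DNA motifs). `markwriter`
implements the computational pipeline that discriminates these modes for
H3K4 methyltransferases (the Arabidopsis ATX/ATXR and mammalian
SET1/MLL families are the motivating systems) from ChIP-seq, mRNA-seq and
promoter-sequence data — together with a seeded synthetic-data generator so
every stage is exercised end-to-end by parameter-recovery tests, without any
downloads.

## What the pipeline computes

1. **Occupancy regions** (`markwriter.regions`). Peak summits are placed
   relative to the nearest TSS or TTS; the summit histogram defines the
   writer's canonical occupancy region. Named regions follow the field's
   definitions: TSS region = [TSS − 150, TSS + 300), TTS region =
   [TTS − 200, TTS + 200), TSS region 2 = [TSS + 200, TSS + 600), enhancer
   region = center ± 900 bp, all strand-aware.
2. **Chromatin-feature random forest** (`markwriter.binding_rf`). Bound
   genes are the top *n* (genome scale: 3000) by tag-minus-control RPM in the
   occupancy region. Five repeats each downsample the unbound class to *n*,
   fit a random forest (500 trees) on chromosomes 1–4, and report mean
   decrease in Gini ± SD and held-out-chromosome ROC/AUC. *In-silico
   ablation* zeroes one feature in the trained ensemble and nominates "lost
   genes": genes that at least one repeat flips from predicted-bound to
   predicted-unbound under the ablation.
3. **k-mer SVM promoter model** (`markwriter.motif_svm`). Coding-strand
   TSS-region DNA becomes 4^k k-mer count vectors (k = 6 default);
   balanced linear SVMs are trained with 5-fold CV for the regularization
   parameter; averaged weights over the five fold models rank k-mers. The
   top-60 positive/negative k-mers are clustered by similarity (reverse
   complement > 1-nt offset > 1-nt offset on the opposite strand), extended
   into 3+6+3 flanking-context probability matrices (MEME export), and
   annotated against exact 6-mer catalogs of the GAGA, TATA, telobox and
   ARGCCCAWT families.
4. **Mutant and spike-in statistics** (`markwriter.mutants`). Per-mutant
   marked-gene sets (top genes by WT − mutant loss); standardized 6-bin
   TSS→TTS loss profiles clustered across mutants (Euclidean, UPGMA);
   spike-in global levels via R = target:spike-in read ratio and the
   actual/expected ratio R_mut,mark / (R_wt,mark · R_mut,H3 / R_wt,H3);
   hypergeometric gene-set overlap tests; and Spearman ρ between mark level
   and each mRNA-seq replicate, compared across genotypes by Welch's
   *t*-test — the statistic that separates co-transcriptional from
   cue-driven writers.
5. **Synthetic data** (`markwriter.simulate`). A seeded generator plants the
   causal structure each stage must recover: a bimodal driver feature
   controlling binding propensity, a GAGAGAGA promoter motif enriched in
   bound genes, per-bin mutant loss profiles, spike-in read counts under a
   planted global mark level, and transcription-coupled vs cue-coupled mark
   landscapes.

## Worked example

```python
from markwriter.simulate import SimConfig, simulate_binding_dataset
from markwriter.binding_rf import BindingForest

matrix, labels, truth = simulate_binding_dataset(SimConfig(seed=1))
result = BindingForest(matrix, labels, holdout="Chr5").fit(seed=1)
print(result.summary())
```

```
Binding random forest
  repeats: 5  trees/repeat: 500
  holdout: chromosome=Chr5
  holdout AUC: 0.937 +/- 0.001
  importance (mean decrease in Gini, mean +/- SD over repeats):
    driver                                   0.6126 +/- 0.0196
    nuisance_2                               0.0529 +/- 0.0025
    nuisance_5                               0.0506 +/- 0.0042
    nuisance_1                               0.0499 +/- 0.0050
    gene_length                              0.0498 +/- 0.0043
    nuisance_4                               0.0494 +/- 0.0044
    RNAP2                                    0.0482 +/- 0.0075
    nuisance_3                               0.0468 +/- 0.0022
    expression                               0.0397 +/- 0.0037
```

The generator planted one causal "driver" feature (effect size β_D = 2 on
the binding logit) among five nuisance features; the forest ranks it first
by an order of magnitude and classifies held-out Chr5 genes at AUC 0.94.
`result.ablate(track="driver")` then returns the genes whose predicted
binding depends on that feature.

The same objects are available from the shell:

```sh
markwriter run --config pipeline.toml --out results/
markwriter overlap --a setA.txt --b setB.txt --universe genes.txt --tail under
```

`markwriter run` executes simulate → feature quantification → random
forest (+ ablation) → k-mer SVM → mutant clustering → spike-in →
correlation and writes a `manifest.json` of output checksums; rerunning the
same config reproduces every byte.

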
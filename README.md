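# exactrna

A desk-scale, fully exact-match RNA-seq analysis pipeline for
two-condition comparisons (e.g. a morpholino knockdown vs. a standard
control in zebrafish embryos), together with the delta-Ct qPCR
arithmetic used to validate its calls and a ground-truthed simulator
that generates every input the pipeline needs. It is aimed at anyone who
wants a small, auditable re-implementation of this style of analysis —
every stage has an independent oracle in the test suite — rather than a
genome-scale aligner.

## The method

**Mapping.** Single-end reads (canonically 100 nt) are trimmed by 2 nt
at each end and split into three equal parts — three 32-mers at read
offsets 2/34/66 for a 100-nt read. Parts are placed by *exact* substring
lookup in a suffix array over the reference, on both strands; a read is
placed only where all three parts land collinearly at spacing k, i.e.
where the whole trimmed core occurs verbatim. Reads are classified
unique / multi / discordant / unmapped, and only unique reads count.

**Expression.** Unique placements add per-base depth over their 96-nt
trimmed span; a gene's expression is the **median depth** over its
annotated bases.

**Differential expression.** The genes × samples matrix is quantile
normalized; the expression level at the peak of the pooled density of
log2(1+x) values — the low-expression *noise floor* — is estimated by
Gaussian KDE; and per-gene fold change is the noise-regularized

```
lgFC(g) = log2( (mean_case(g) + noise) / (mean_ctrl(g) + noise) )
```

so that genes near the floor cannot dominate the ranking. Outlier
replicates are excluded by iterative mean-Pearson-correlation filtering
(default cutoff 0.8), and heat-map panels are clipped to ±1.5 on the
log2 scale.

**qPCR.** Triplicate Ct values are averaged, relative expression within
a sample is `2^-Ct(target) / 2^-Ct(reference)`, and condition fold
change is the ratio of condition means of per-sample relative
expressions (a clutch-paired mode is also provided).

See `docs/methods.md` for the full model, parameter defaults and
limitations.

## Worked example

Simulate a 60-gene experiment with six planted ±2 log2 fold changes,
three replicates per condition at ~20× depth, and run the whole
pipeline:

```python
import exactrna as x

cfg = x.SimulationConfig(seed=1, n_genes=60, n_de_genes=6,
                         mean_depth=20.0, n_replicates=3)
exp = x.simulate_experiment(cfg)
matrix, stats = x.quantify_samples(exp.refs, exp.annotation, exp.samples)
print("mapping stats (ctrl1):", stats["ctrl1"].as_dict())

res = x.differential_expression(matrix, exp.groups)
print(f"estimated noise level: {res.noise.value:.3f}")
print(res.de.table.head(6).round(2))
```

which prints:

```
mapping stats (ctrl1): {'total': 7471, 'unique': 6745, 'multi': 0,
                        'unmapped': 726, 'discordant': 0, 'geometry_skipped': 0}
estimated noise level: 0.764
         mean_ctrl  mean_case  lgFC
gene_id
g0029        45.19       9.72 -2.13
g0005        47.93      13.03 -1.82
g0044        36.33     112.69  1.61
g0008        36.69      11.71 -1.59
g0020        42.04     126.25  1.57
g0011        41.47     108.31  1.37
```

About 10% of reads are unmapped — exact matching discards any read with
a substitution error (rate 0.001/base here) inside its trimmed core.
The six genes topping the |lgFC| ranking are exactly the six planted
ones, with magnitudes shrunk slightly below the true ±2 by the noise
regularizer (the simulated floor genes sit at a median expression of
1.0, and the density-peak estimator placed the noise at 0.76). The same stages are available
from the shell:

```sh
exactrna simulate --seed 1 --outdir sim/ --n-genes 60 --n-de 6
exactrna index --fasta sim/ref.fa --out sim/ref.idx
exactrna map --index sim/ref.idx --fastq sim/ctrl1.fq --out sim/ctrl1.tsv
exactrna quant --placements ctrl1 sim/ctrl1.tsv ... --fasta sim/ref.fa \
               --bed sim/genes.bed --out sim/expr.tsv
exactrna de --expr sim/expr.tsv --groups sim/groups.tsv --out sim/de.tsv
exactrna qpcr --ct sim/ct.tsv --reference rpp0 --gene g0029 --out sim/fc.tsv
```

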
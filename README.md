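# polyploid-diel

Homoeolog expression bias (HEB) and diurnal rhythmicity analysis for
allopolyploid transcriptomes, modelled on the *Brachypodium* system: the
allotetraploid *B. hybridum* carries a Bd-subgenome (from *B. distachyon*)
and a Bs-subgenome (from *B. stacei*), and the question is how much of each
gene's expression — level and diurnal phase — is parental legacy versus
hybrid novelty.

The package is written for transcriptomics researchers who have gene-level
RNA-seq counts for an allopolyploid and its two diploid progenitors across a
diurnal time course (here: 6 time points every 4 h, 3 biological replicates,
20 h light / 4 h dark), plus the resequencing evidence needed to separate
subgenome reads. A synthetic-data generator emulates the full study design,
so every stage is testable without any sequencing data.

## What it computes

1. **Virtual progenitor genome** (`virtual_genome`) — discriminating SNPs are
   sites homozygous-alternate in all progenitor-2 reads and heterozygous in
   hybrid reads; substituting them into the progenitor-1 reference yields an
   *in silico* progenitor-2 genome for homoeolog-aware mapping.
2. **Homoeolog read sorting** (`homoeolog_sort`) — each hybrid read pair
   (fragment) is assigned to the subgenome it matches with strictly fewer
   mismatches; ties stay unassigned.
3. **Differential expression** (`diffexpr`) — RPM quantification, the
   expressed-gene rule (RPM ≥ 1 in all replicates of ≥ 1 time point),
   median-of-ratios size factors, and a per-gene negative-binomial Wald test

   &nbsp;&nbsp;&nbsp;&nbsp;y<sub>gj</sub> ~ NB(μ = s<sub>j</sub>·exp(β₀ + β₁x<sub>j</sub>), Var = μ + α<sub>g</sub>μ²)

   with empirical-Bayes dispersion shrinkage and Benjamini–Hochberg FDR
   (significant at FDR < 0.01), run separately at each time point.
4. **HEB classification** (`heb`) — the diploid-ortholog test (P1 vs P2) and
   the subgenome-homoeolog test (Bd vs Bs) combine into five categories per
   time point: balance retention, bias retention, bias gain, bias loss,
   bias switch; six-time-point patterns are balance-retention-throughout,
   constitutive (same bias category at all times), or temporal.
5. **Rhythm detection** (`rhythm`) — time-averaged Morlet-wavelet power
   (ω₀ = 6) at the 24-h scale on log₂(RPM+1), significance from
   variance-matched white-noise surrogates, and the strict calling rule:
   a gene is rhythmic only if P < 0.05 in **all six** replicate-permutation
   composite series (the 3! orderings of three replicates applied cyclically
   across time points). Peak time comes from the coefficient phase.
6. **Comparative statistics** (`comparative`) — Pearson-correlation
   distributions of diel profiles for ortholog vs homoeolog pairs, circular
   peak-time concordance (Fisher–Lee), and flat hypergeometric GO enrichment
   (raw P < 10⁻⁴).

## Worked example

```python
from polyploid_diel import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=1, n_genes=1000, pileup_depth=50))
print(report["sorting"])
print(report["heb"]["pattern_table"][0])
print(report["comparative"]["peak_concordance"])
```

prints (seed 1):

```
{'n_fragments': 10000, 'n_bd': 3823, 'n_bs': 3908, 'n_unassigned': 2269,
 'assignment_rate': 0.7731, 'accuracy_informative': 0.9971594577146546,
 'poisson_zero_prediction': 0.7768698398515702}
{'pattern': 'balance_retention_all', 'count': 139, 'percent': 13.9}
{'diploid_mean_abs_diff_h': 3.315820764968296,
 'subgenome_mean_abs_diff_h': 0.9178361770361672,
 'diploid_circular_correlation': 0.2976574325176605,
 'subgenome_circular_correlation': 0.9127837196774863, 'n_pairs': 118}
```

Reading this: 77.3% of simulated fragments were assigned to a subgenome —
matching the Poisson prediction 1 − e^(−λ) for the fraction of fragments
overlapping at least one discriminating SNP at λ = 1.5 — and assignments are
99.7% accurate where a SNP is overlapped. Of 1000 eligible gene groups,
13.9% keep balanced homoeolog expression at all six time points. Rhythmic
homoeolog pairs peak within ~0.9 h of each other while the diploid ortholog
pairs are ~3.3 h apart: the planted "averaging of *trans* inputs" signature
of diurnal synchronisation in the hybrid, recovered by the pipeline.

The same pipeline is scriptable from the shell:

```bash
polyploid-diel simulate --seed 1 --n-genes 1000 --outdir bundle/
polyploid-diel build-virtual-genome --pileup bundle/pileups.tsv \
    --reference bundle/reference.fasta \
    --out-fasta virtual.fasta --out-snps snps.tsv
polyploid-diel sort-homoeologs --fragments bundle/fragments.tsv --out calls.tsv
polyploid-diel run --seed 1 --outdir out/
```

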
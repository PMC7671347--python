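# Methods

## Study design being modelled

An allopolyploid (two diverged subgenomes, Bd and Bs) is compared with its
two diploid progenitors (P1, P2) and an induced autotetraploid of P1 across
one diurnal cycle: six sampling times every 4 h (clock hours 2, 6, 10, 14,
18, 22), three biological replicates, 20 h light / 4 h dark (lights on at
4:00). All expression is quantified on the shared P1 gene models, so a
"gene" is a homoeologous group with one measurement per channel
(P1, P2, Bd-subgenome, Bs-subgenome, autotetraploid).

## Synthetic-data generator

The generator emulates every input the pipeline consumes; its defaults are
the package's reference conditions.

* **Genomes and SNPs.** A random reference of length 20 kb; each base
  diverges independently at rate 0.01, giving the discriminating-SNP truth
  table. Pileups at true SNP sites draw progenitor-2 reads from the alt
  allele and hybrid reads 50:50 ref/alt; decoy (non-SNP) sites are sampled
  at 10x the SNP count so caller specificity is measurable. Sequencing error
  substitutes a read's base uniformly at the configured rate.
* **Fragments.** A read pair overlaps k ~ Poisson(λ = 1.5) discriminating
  SNPs and originates from either subgenome with equal probability.
  Sequencing errors at non-SNP positions mismatch *both* references and so
  cancel in the comparison; only the k SNP bases (and rare errors at SNP
  positions) separate the two mismatch counts. Consequently the fraction of
  uninformative (tied) fragments is e^(−λ), and the assignment rate
  approaches 1 − e^(−λ) — the quantity the pipeline checks.
* **Counts.** Gene g in channel c at clock hour t is NB with mean
  μ = baseline·(1 + A·cos(2π(t − φ)/24))·libsize/10⁶ and variance
  μ + αμ². Defaults: baselines log-uniform in [100, 2000] (counts per
  million), dispersion α = 0.05 (a 22% biological CV, typical of
  bulk-RNA-seq replicates), 30% of genes rhythmic with amplitude A uniform
  in [0.5, 1], phases uniform on the clock. Library sizes are log-uniform in
  [0.8, 1.2]×10⁷; the two subgenome channels share each allopolyploid
  sample's total, since both are read fractions of one library.
* **HEB planting.** Each gene carries one of the five categories, enforced
  as a 2-fold baseline ratio on the relevant channel pair(s) with a random
  direction (e.g. bias retention: P1 = 2·P2 and Bd = 2·Bs; bias switch:
  P1 = 2·P2 and Bs = 2·Bd). Recovery runs plant categories on arrhythmic
  genes: per-channel phase gaps of rhythmic genes would make the
  instantaneous expression ratio — and hence the per-time-point planted
  category — ill-defined.
* **Phase structure.** Progenitor phases diverge (gap SD 4 h) while the two
  subgenome phases are drawn together (gap SD 1 h), emulating the averaging
  of *trans*-acting regulatory inputs that hybridisation brings together.
  This is the generative signature behind the comparative stage's expected
  results (higher homoeolog-pair correlations, tighter peak concordance).

What the generator does **not** emulate: read-level sequencing (no FASTQ,
qualities, or mapping), multi-mapping and mapping bias, count correlation
between time points beyond the cosine mean structure, asymmetric subgenome
expression levels (no expression-level dominance), batch effects, or
annotation error. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not performance on real
libraries.

## Differential expression

Per gene and per time point, a two-group NB GLM with log link and
size-factor offsets is fitted by vectorised IRLS; the group effect is tested
with a Wald z statistic (SE from the expected information) and BH-adjusted
across genes within each comparison x time point. Significance is FDR < 0.01
throughout (strict inequality).

Dispersion estimation is the delicate part at n = 3 per group. Genewise
profile-likelihood estimates (Cox–Reid adjusted, computed on a log-spaced
grid from 10⁻⁸ to 30) are re-estimated under a normal prior on log α centred
on a robustly fitted parametric trend α(μ) = a₀ + a₁/μ; the prior variance
is the observed spread of genewise estimates around the trend minus the
expected sampling variance trigamma((m−p)/2), floored at 0.25. A fixed-weight
blend was tried first and left enough noise in α̂ to inflate the Wald type-I
error to ~0.10 at nominal 0.05; the adaptive-prior MAP brings it to 0.063
(0.017 at nominal 0.01), measured on a 10⁴-gene null at α = 0.1, n = 3 vs 3.
On a 200-gene fixture the engine agrees with DESeq2 (pydeseq2) to LFC
correlation 1.00 and an identical FDR < 0.01 call set; exact equality is not
expected (no LFC shrinkage, no outlier replacement, no independent
filtering).

Edge conventions: all-zero genes get LFC 0 and p = 1; a group with all-zero
counts saturates at a clamped linear predictor with a huge SE rather than an
infinite fold change; size factors fall back to upper-quartile scaling when
no gene is nonzero in every sample. The homoeolog contrast uses the
allopolyploid's per-sample totals (shared by both subgenomes) as fixed size
factors; the cross-species diploid contrast uses its own median-of-ratios
factors.

## HEB classification

The 3x3 grid of (diploid bias, subgenome bias) maps onto five categories
(balance retention, bias retention, gain, loss, switch); the map is total,
mutually exclusive, and direction-symmetric. Groups are eligible when
expressed (RPM ≥ 1 in all replicates of ≥ 1 time point) in at least one
diploid and at least one subgenome. Pattern classes over the six time
points: balance-retention-throughout, constitutive (identical non-balance
category at all six), temporal (anything else).

Planted-category recovery is scored at the gene level: the recovered
category is the modal per-time-point call. At 2-fold bias, dispersion 0.05
and n = 3, per-time-point power for the dual-test categories is
information-limited to ~0.72 (the Wald z for a 2-fold change cannot exceed
1/(log2e·√(2α/3)) ≈ 3.8 while the BH critical z is ≈ 2.8), so per-gene modal
recall — typically 0.88–0.96 for bias retention/switch, higher for the
others — is the meaningful recovery metric.

## Rhythm detection

Six-point series are z-scored, linearly interpolated onto a 1-h circular
grid, and convolved with the Morlet wavelet ψ(t) = π^(−1/4)·e^(iω₀t)·e^(−t²/2),
ω₀ = 6, at the scale whose Fourier period is 24 h
(s = 24·(ω₀+√(2+ω₀²))/4π ≈ 23.2 h). The 24-h power is the squared modulus
averaged over the central cycle; because interpolation and transform are one
fixed linear operator, the whole computation is a single matrix product and
the surrogate null — z-scored Gaussian white noise of the same sampled
length pushed through the identical operator — is shared across genes.
P-values are plus-one-corrected empirical fractions over 100 surrogates.
Constant series get power 0, p = 1. Peak time is the magnitude-weighted
circular mean of τ − angle(W(τ))·24/2π over the central cycle; it recovers
dense-sampled cosine peaks to <0.1 h and six-point peaks to well under the
2-h half-sampling-interval tolerance, and is shift-equivariant.

A gene is called rhythmic only when all six replicate-permutation composite
series (the 3! label orderings applied cyclically, each replicate used
exactly twice per series) are individually significant at P < 0.05. This
strict intersection keeps the white-noise false-call rate near zero
(measured 0.00 at 1000 noise genes).

**Sensitivity ceiling.** With six samples of a single cycle, rhythm
detection is fundamentally power-limited. The optimal fixed-period detector
(the cosinor/Fisher-g share-of-variance test; null share ~ Beta(1, 1.5),
α = 0.05 threshold at share 0.865) reaches only ~0.28/0.49/0.78 single-test
power at log-scale amplitude-to-noise ratios corresponding to A = 0.5/0.7/1.0
at dispersion 0.05 — so the all-six rule's sensitivity on the generator's
default rhythmic genes is ~0.1–0.2, and *no* test could reach high
sensitivity while holding the false-call rate. Two further inherent effects:
very-high-amplitude genes (A > 0.85) lose 24-h power to harmonic distortion
when the log-scale trough clips near zero counts, and the permutation
intersection trades sensitivity for specificity by design. Genes that *are*
called have accurately estimated peaks (>90% within 2 h). Users needing
higher sensitivity should sample more cycles or more densely, not loosen
the calling rule.

## Comparative stage

Profiles are replicate-mean log₂(RPM+1) at the six time points. Pearson
correlations are computed per gene pair; constant profiles yield NaN and are
excluded with a count. Distribution shifts report medians, Δmedian, and the
two-sample KS statistic. Peak concordance uses the signed circular
difference on [−12, 12] h and the Fisher–Lee T-linear circular correlation
(the linear Pearson correlation of clock hours is also emitted for
scatter-plot parity, but circular statistics are authoritative because peaks
wrap at midnight). Term enrichment is the upper-tail hypergeometric p with a
raw P < 10⁻⁴ cutoff and no multiplicity adjustment, matching the
conventional GO-enrichment procedure; annotation is flat (no term-graph
propagation).

## Pipeline and reproducibility

A single global seed fans out to per-stage seeds by a CRC32 hash of the
stage name (all below 2³¹), so stages are independently reproducible and the
full report is byte-identical across runs. Every summary the pipeline emits
is a partition of a stated universe; `validate_report` re-checks all
partition identities (fragment conservation, HEB pattern classes vs eligible
groups, DEG direction classes vs DEG totals, percentage recomputation to
0.1) and the pipeline refuses to return an inconsistent report.

Default problem sizes — 2000 genes, 10⁴ fragments, 20-kb genome, 100
surrogates, 10⁴-gene null — were chosen so the full suite and the
acceptance script each run in seconds on one CPU while keeping Monte-Carlo
error well inside the asserted tolerances. Noiseless SNP-recovery runs use
pileup depth 50: at much lower depths the hybrid's binomial 50:50 allele
draw can fail the 20% minor-fraction rule by sampling noise alone, which is
a property of the threshold, not of the caller.

## Parameter reference

| Parameter | Default | Meaning |
|---|---|---|
| `fdr_threshold` | 0.01 | DEG / bias significance (BH-adjusted, strict `<`) |
| `rpm_threshold` | 1.0 | expressed-gene rule, RPM units |
| `rhythm_alpha` | 0.05 | per-permutation surrogate-test level |
| `n_surrogates` | 100 | white-noise surrogates per test |
| `enrichment_alpha` | 1e-4 | raw hypergeometric cutoff |
| `min_depth_p2`, `min_depth_hyb` | 5, 5 | SNP-caller depth floors (reads) |
| `hyb_minor_fraction` | 0.2 | heterogenicity floor in hybrid reads |
| `bias_fold` | 2.0 | planted HEB ratio |
| `dispersion` | 0.05 | NB dispersion α (CV² in excess of shot noise) |
| `frag_snp_lambda` | 1.5 | mean discriminating SNPs per fragment |

## Known limitations

* DEG counts approximate, but do not numerically replicate, DESeq2 (no LFC
  shrinkage or outlier handling).
* Rhythm sensitivity at one 6-point cycle is information-limited (see
  above); the package reports it honestly rather than relaxing the rule.
* No indel handling in the virtual genome; SNP substitution only.
* No GO-graph propagation; enrichment is flat and unadjusted by design.
* The fragment simulation emits mismatch counts directly; mapping artefacts
  (multi-mapping, clipping, allelic mapping bias) are out of scope.
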
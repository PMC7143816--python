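# Methods

This note documents the statistical models behind `divscan`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions a maintainer would want written
down.

## Data model

Genotypes are diploid biallelic dosages in {0, 1, 2, missing} counting
copies of a per-SNP *counted allele*, with a genetic map (chromosome label,
1-based bp position) and one population label per sample. All
differentiation, LD and inbreeding statistics are invariant to which
allele is counted; dosages themselves are not. PED/MAP files carry no
allele designation, so on read the counted allele is the first non-missing
allele encountered in the SNP column — consequently a write→read round
trip is the identity only up to this orientation, and
`harmonize_alleles()` flips a dataset onto a reference orientation when
exact dosage agreement matters. In VCF input the ALT allele is counted.
Coordinates are 1-based inclusive; exported BED is converted to 0-based
half-open; region sizes use end − start.

## Marker QC

Filters are applied per SNP in a fixed cascade (excluded chromosomes →
call rate → MAF → missingness → per-population HWE) with exclusions
attributed to the first criterion that fires. Defaults: call rate > 0.97,
MAF ≥ 0.05 retained, missingness < 0.20, HWE exact p < 1e-6 in *any single*
population excludes the marker. The HWE test is the exact conditional
test (sum of probabilities of heterozygote counts no more likely than the
observed one, given the allele counts), computed in log space; it is
checked against a rational-arithmetic enumeration oracle in the tests.
The call-rate filter is per-SNP; a per-sample interpretation of "call
rate" is also defensible for array data, but per-SNP is what the rest of
the pipeline needs and is the common default.

## Weir–Cockerham FST and the window scan

Per locus, the two-deme variance components are

    n̄ = (n1+n2)/2,  n_c = (2n̄ − (n1²+n2²)/(2n̄)),
    p̄ = weighted allele frequency,  s² = weighted variance of p_i,
    h̄ = weighted heterozygote fraction,

    a = (n̄/n_c)[s² − (p̄(1−p̄) − s²/2 − h̄/4)/(n̄−1)]
    b = (n̄/(n̄−1))[p̄(1−p̄) − s²/2 − h̄(2n̄−1)/(4n̄)]
    c = h̄/2

with θ̂ = a/(a+b+c), undefined (NaN) when the denominator is zero and when
either population has fewer than two genotyped diploids. Missing
genotypes are excluded per locus. The genome-wide *mean* FST averages
per-locus ratios; the *weighted mean* is Σa/Σ(a+b+c), which is the less
noisy ratio-of-sums estimator.

The scan averages θ̂ in 10-SNP windows advancing one SNP at a time (the
step is configurable; windows never span chromosomes; NaN loci are
excluded from the mean rather than imputed). The candidate threshold is
the empirical order-statistic quantile of the window means, default
0.999: sources describing this design quote both "top 1%" and "top 0.1%",
and the printed per-region arithmetic is consistent with the 99.9%
reading, so that is the default; both are one argument away. Windows
strictly above the threshold are merged when they share a SNP or overlap
in bp, and merged spans are extended 25 kb per side (start floored at
1 bp). With ~5,000 windows the 99.9% quantile admits only ~5 candidate
windows, which is the faithful scale-down of a ~52,000-marker panel
yielding ~52 candidate windows over nine regions.

## Bayesian outlier model

For locus i and population j with counted-allele count k_ij of n_ij
alleles,

    k_ij ~ BetaBinomial(n_ij, θ_ij p_i, θ_ij (1−p_i)),
    θ_ij = 1/FST_ij − 1,  logit(FST_ij) = α_i δ_i + β_j,

with ancestral frequency p_i (uniform prior, updated on the logit scale),
population effect β_j ~ N(−1, 1.8²), locus effect α_i ~ N(0, 3²) present
only when the indicator δ_i = 1, and prior odds 10:1 for the neutral
model (δ=0). One MCMC sweep updates every p_i (elementwise random walk),
every included α_i, each β_j, and finally toggles every δ_i with a
reversible-jump move that uses the α prior as the birth proposal, so the
prior density cancels and the acceptance ratio is the likelihood ratio
times the prior odds. Pilot runs (default 5 × 500 sweeps) rescale the
three proposal standard deviations toward acceptance rates in
[0.25, 0.45]. Defaults for production are 50,000 iterations with 10,000
burn-in; the calibration experiments use 5,000/1,000, which is enough for
the rank ordering and false-positive behaviour being tested. A Geweke
z-score above 3 on the β chains raises a warning, not an error.

Reported per locus: posterior inclusion probability (PIP), the posterior
mean of α conditional on inclusion, and a q-value defined as the mean
posterior error rate (1 − PIP) among loci with PIP at least as large.
A locus is called *diversifying* at q ≤ 0.05 with positive α, *balancing/
purifying* with negative α. Both the PIP and the q-value are emitted
because downstream users of the corresponding tools read either.

## LD and Gabriel blocks

Two-locus haplotype frequencies come from the standard EM over the 3×3
joint dosage table (only the double-heterozygote class is phase
ambiguous), initialised at linkage equilibrium and iterated to 1e-9 or
1,000 iterations. D = f_AB − p_A p_B, D′ = |D|/D_max with the usual
sign-dependent D_max, r² = D²/(p_A(1−p_A)p_B(1−p_B)); monomorphic pairs
are flagged undefined. The 90% confidence interval on D′ evaluates the
genotype-table likelihood on a 101-point grid of D′ with the allele
frequencies and the sign of D held at their MLEs, normalises it as a
posterior under a flat prior, and takes the 5th/95th percentiles — the
deterministic grid approach of the standard haplotype-browser tool,
chosen over a bootstrap for speed and reproducibility.

Blocks follow the Gabriel confidence-interval rules with the published
defaults: a pair is in strong LD when CI = [≥0.70, ≥0.98], shows strong
recombination when the CI upper bound is <0.90; an interval is a
candidate block when its outermost pair is in strong LD and ≥95% of its
informative pairs are strong-LD; non-overlapping blocks are selected
greedily by descending span. A pair is informative when both SNPs have
MAF ≥ 0.05 and at least 20 informative chromosomes. Block haplotype
inventories use multilocus EM with full phase enumeration up to 12 SNPs
and a partition-and-ligate fallback above that (halve, solve, ligate the
top 20 partial haplotypes per side); individuals with a missing call
inside the block are excluded, and haplotypes below 1% frequency are
truncated, so reported frequencies sum to ≤ 1.

## Population structure

PCA standardises each SNP by centring at 2p̂ and scaling by √(2p̂(1−p̂)),
mean-imputes missing cells, drops monomorphic columns, and reports
projections whose per-component variance equals the covariance
eigenvalue. The 1 − IBS distance scores a locus as 1 − |d_i − d_j|/2 and
averages over loci genotyped in both individuals. Neighbor-joining is
delegated to scikit-bio (Saitou–Nei agglomeration) with negative branch
lengths clamped to zero.

Admixture fits Q (individual memberships, rows on the simplex) and P
(cluster allele frequencies) by plain EM on the binomial genotype
likelihood — simpler than the block-relaxation/quasi-Newton optimiser of
the dedicated tool and entirely adequate at desk scale — iterated until
the log-likelihood gain is < 1e-4 or 2,000 sweeps, with Dirichlet(1)
initialisation of Q. P is clipped to [1e-6, 1−1e-6], which bounds the
theoretical EM monotonicity violation below numerical noise. The choice
of K masks a random 1/folds of the non-missing genotype *cells* per fold,
refits, and scores the mean squared deviation between held-out dosages
and their fitted expectations 2Σ_k q_ik p_kl; K̂ is the argmin. Masking
cells rather than individuals keeps every sample in every training fold,
which matters at these sample sizes.

## Inbreeding and effective population size

F_GRM is the diagonal of the variance-standardised GRM minus one; the
method-of-moments F compares observed and expected homozygote counts with
the small-sample correction 2n/(2n−1) on the expected heterozygosity; F_U
averages the per-locus uniting-gametes quadratic
(d² − (1+2p)d + 2p²)/(2p(1−p)). Allele frequencies are computed within
the analysed (single-population) dataset, matching per-population
reporting. ROH are maximal runs of homozygous calls allowing ≤2 missing
and (by default) 0 heterozygous calls, reported at ≥30 SNPs and >1 Mb;
F_ROH divides the per-sample merged ROH length by the SNP-covered genome
(per-chromosome last-minus-first marker positions), the natural
denominator for array data.

Ne uses the LD method: squared Pearson correlations of dosages over all
inter-chromosomal pairs of 1,000 randomly sampled SNPs (MAF ≥ 0.05),
computed on jointly genotyped individuals; the finite-sample expectation
1/S + 3.19/S² (S ≥ 30; the 0.0018 + 0.907/S + 4.44/S² branch below) is
subtracted and the corrected mean r²′ inverted through
Ne = (1/3 + √(1/9 − 2.76 r²′))/(2 r²′), with Ne = ∞ reported when
r²′ ≤ 0. Point estimates only; jackknife intervals are out of scope.

## The synthetic-data generator

Population allele frequencies follow the Balding–Nichols model:
Beta(p(1−F)/F, (1−p)(1−F)/F) around an ancestral frequency drawn
uniformly on [0.05, 0.95], with F = 0.012 for background loci
(the genome-wide differentiation scale of the motivating horse
populations) and F = 0.25 at planted outliers. Outliers are planted as a
run of 10 consecutive markers: selection signatures are regional, and at
the default scan scale (~5,000 windows, 99.9% threshold ≈ 5 candidate
windows) a single clustered signature is the faithful scale-down of a
52k-marker panel yielding nine regions from ~52 candidate windows.

Genotypes are built from a per-population pool of founder haplotypes
(default 400, i.e. ~200 diploid founders, matching the Ne ≈ 160–230
reported for these conserved draft-horse populations). Each gamete picks
two founders once and copies them in geometrically distributed segments
(mean 10 SNPs ≈ 0.5 Mb at the default 50 kb spacing — the
few-hundred-kb useful-LD range typical of horse breeds). Drawing the two
parents once per gamete, rather than a fresh founder per segment, is what
creates LD *between* chromosomes, without which the LD method of Ne
estimation has no signal. ROH are injected by copying one haplotype of
an individual over the other across a random interval; missingness is
independent per cell.

What the generator does **not** emulate: recombination-map heterogeneity,
mutation, allele-frequency ascertainment of array content, relatedness
structure beyond the founder pool, and multi-generation drift — the
single generation of mixing means unlinked-pair LD sits below its
drift-equilibrium level, so LD-based Ne *over*estimates the founder pool
size (the ordering across pool sizes is preserved, and that ordering is
what the tests assert). Passing tests therefore demonstrate correct
estimator behaviour under a controlled model, not performance on real
array data.

Default problem sizes mirror the motivating study scaled to desk size:
107 + 69 individuals, 5,000 SNPs on 5 × 50 Mb chromosomes. The simulator
is deterministic given its seed (single `numpy` Generator, fixed update
order); the calibration experiments run 20,000 SNPs with a 2,000-founder
pool so that founder drift (~1/pool) is negligible against the
Balding–Nichols target.

## Numerical choices and degenerate inputs

* Monomorphic loci: FST components are exactly (0,0,0) → θ̂ = NaN; LD and
  GRM drop or flag such loci; PCA drops them.
* Window means exclude NaN loci; windows with no defined locus are
  dropped; chromosomes shorter than one window contribute none.
* The empirical threshold is the order statistic at ⌈qN⌉; candidates
  must exceed it strictly, so a constant track yields no candidates, and
  q = 0.999 needs ≥1,000 windows to admit any.
* EM tie-breaks: the two-locus EM starts at linkage equilibrium; the
  degenerate 50/50 double-heterozygote weighting applies when both phase
  products vanish.
* NJ ties follow scikit-bio's internal order; on additive matrices the
  reconstruction is exact regardless.
* All stochastic stages take explicit integer seeds; the pipeline derives
  stage seeds from its single seed by fixed offsets.

## Known limitations

* The Bayesian sampler treats loci as independent given β — LD between
  markers is ignored, as in the tool it mirrors, so clustered signals
  yield clustered (not independent) posterior evidence.
* ROH detection is rule-based on exact runs rather than a probabilistic
  sliding window; with default settings a single genotyping error breaks
  a run (two missing calls are tolerated).
* The admixture EM can be slow near convergence for large K; the CV
  routine caps iterations for tractability, which slightly favours
  smaller K when differentiation is weak.
* Binary PLINK (BED/BIM/FAM) and phased input are not supported.
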
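# Methods

This note documents the models and procedures implemented in `rohscape`, the
defaults they use, and what the synthetic-data validation does and does not
establish.

## Scope and data model

The package analyses diploid autosomal SNP-array genotypes for small
livestock cohorts (tens of individuals per population, tens of thousands of
markers genome-wide).  Genotypes are held in a `GenotypeDataset`: a
(samples x SNPs) matrix of codes counting copies of `allele_b`
(0 hom-`allele_a`, 1 het, 2 hom-`allele_b`, −1 missing) plus a marker map
(chromosome, bp, cM) and per-sample population labels.  PLINK text (PED/MAP)
and PLINK 1 binary (BED/BIM/FAM, SNP-major) are read and written natively;
in BIM files the A1 column is taken as `allele_b`, so genotype codes are A1
dosages.  PED/MAP carries no allele columns, so the text reader orients each
SNP with the minor allele as `allele_b` (frequency tie broken toward the
lexicographically larger code).  At a SNP with allele frequency exactly 0.5
or no polymorphism the original orientation is not recoverable from text —
all downstream statistics (MAF, het status, r², IBS, ROH, PCA after
centering) are orientation-invariant, and binary round-trips are exact.

## Quality control

Four marker filters run in a fixed order, each on the previous stage's
output: autosomes 1..29 only (the caprine autosome count); call rate ≥ 0.95;
MAF ≥ 0.05; Hardy–Weinberg exact-test p ≥ 1e-5.  Removal uses strict
inequality, so boundary values are retained.  The HWE test is the exact
conditional test (summing probabilities of heterozygote counts no more
likely than the observed one, given the allele counts), computed in log
space; a chi-square alternative and per-population testing are available by
flag.  HWE defaults to the pooled cohort, matching single-cohort tool
behaviour.  No per-sample missingness filter is applied.  Every removal is
logged with its reason (`non_autosomal`, `call_rate`, `maf`, `hwe`).

## ROH calling

The caller is the two-phase sliding-window ("consecutive runs") algorithm
used for array data.  Phase 1 scores every window of `window_snps`
consecutive same-chromosome SNPs as homozygous when it has at most
`max_het_in_roh` heterozygotes and `max_missing_in_roh` missing calls; a SNP
is flagged when the homozygous fraction of windows covering it exceeds
`window_hit_fraction`.  Phase 2 takes maximal flagged stretches, splits them
at physical gaps above `max_gap_bp`, and keeps runs satisfying the per-run
constraints (SNP count, length, het and missing limits).  Defaults: 50-SNP
window, ≥ 50 SNPs and ≥ 1 Mb per run, ≤ 5 missing, 0 heterozygotes,
1 Mb gap, hit fraction 0.05.  Segment length is `end_bp − start_bp`
(first to last SNP), the convention consistent with reported Mb values;
reporting rounds half-up to 2 decimals.

Two properties deserve note.  First, the window rule trims a few SNPs at
each end of a homozygous stretch (edge SNPs are covered by too few fully
homozygous windows), so called segments start slightly inside the true
autozygous tract; validation tests assert coverage of tract interiors.
Second, the call count is monotone in `min_snps_in_roh` and `min_length_bp`
but *not* in `max_het_in_roh`: allowing one heterozygote can merge two
valid runs into a single candidate that then violates the per-run het limit
and is discarded whole.  This is inherent to the discard-based phase 2 and
is documented rather than patched, because splitting at heterozygotes would
change the algorithm's published semantics.

Length classes default to 0–5, 5–10, 10–20, 20–40, > 40 Mb (left-closed,
right-open); the 1 Mb calling floor means the first class effectively holds
1–5 Mb segments.  Summaries divide per-population segment counts by *all*
individuals, including those without ROH.

An independent naive scanner (`brute_force_roh`, plain Python loops over
every window and stretch) implements the same definition and is used only
as a test oracle against the vectorized caller.

## Inbreeding coefficients

`F_HOM` is the method-of-moments estimator behind PLINK `--het`:
`(O_HOM − E_HOM)/(L − E_HOM)` per sample, with
`E_HOM = Σ_j (1 − 2 p_j q_j · n_j/(n_j − 1))` over the sample's non-missing
SNPs, `p_j` the cohort frequency and `n_j` the non-missing allele count.
The sign convention makes homozygosity excess positive, consistent with its
use as an inbreeding measure.  `F_ROH = L_ROH / L_AUTO`, where `L_AUTO`
defaults to the summed per-chromosome span (last − first mapped SNP) and can
be overridden (e.g. with a published 2450.71 Mb panel length) for
replication.  Per-class and per-chromosome decompositions partition the
total exactly in bp.  The F_ROH–F_HOM Pearson correlation is computed per
population; groups under 3 samples or without variation return NaN.

## Effective population size from LD

Intra-chromosomal SNP pairs with separation in [50 kb, 4 Mb) are assigned to
30 equal-width distance bins.  Pairwise r² is the squared Pearson
correlation of dosages over samples complete at both SNPs (genotypic,
phase-free — appropriate for unphased array data).  The bin mean is reduced
by 1/n (sample-size correction, flag-controlled) and floored at 1e-6.
Physical distance converts to genetic distance at 1 cM/Mb.  Each bin yields
`t = 1/(2c)` generations ago and `Ne = (1/r²_adj − α)/(4c)`, with α = 1
(drift only; 2.2 optional to accommodate mutation).  The default bin range
probes roughly t ≈ 12 to 1000 generations.  LD-based Ne is noisy at small
sample sizes: validation asserts trend recovery (declining populations show
recent Ne below ancient Ne) and factor-2 accuracy of mid-range bins
(t ≈ 20–70) under a constant-Ne simulation, not point accuracy per bin.
Bins whose adjusted r² leaves (0, 1) are dropped.

## ROH islands

For each population, a SNP's incidence is the fraction of individuals with
at least one ROH segment covering its bp position (interval containment, so
the track is robust to map edits).  Islands are maximal runs of consecutive
map-order SNPs with incidence strictly above the threshold (70%, 50% and
20% conventionally; strict comparison per "more than X%" phrasing), dropping
runs under `min_island_snps` (default 10).  Island membership is exactly
reproducible from the track — no smoothing.  Output includes a BED export
(0-based half-open) for downstream annotation; gene/pathway annotation
itself is out of scope.

## Population structure utilities

LD pruning is greedy and windowed (50 SNPs, step 5, r² > 0.5): within each
window the first offending pair in map order loses its lower-MAF member
(tie: later position), repeated until clean.  Windows do not cross
chromosomes.  IBS similarity is `mean((2 − |d_i − d_j|)/2)` over shared
non-missing SNPs; relatedness filtering removes, while any pair exceeds the
cutoff (default 0.65), the lower-call-rate member (tie: lexicographically
larger id) — fully deterministic.  PCA mean-imputes missing dosages per SNP,
centers by 2p and scales by sqrt(2p(1−p)) (Patterson scaling; the source
analyses used external GUI software that does not state its scaling), drops
fixed SNPs, and eigendecomposes via SVD.  Admixture-model fitting is out of
scope; the pruned dataset can be exported in BED format for external tools.

## Synthetic data with known truth

Because the original cohort genotypes live in an external repository, every
stage is validated against simulated data whose answer is known by
construction:

* **Wright–Fisher engine** — forward-in-time diploid simulation with
  discrete generations, uniform parent choice, Haldane-map recombination
  without interference (chromosome starts segregate independently),
  optional bi-allelic mutation, and an arbitrary stepwise Ne trajectory.
  Founders draw alleles at uniform(0.05, 0.95) frequencies, mimicking an
  ascertained common-variant array.  After the final generation, samples
  are drawn without replacement, fixed SNPs are dropped, and genotypes are
  masked missing at the configured rate.  Forward simulation (rather than
  coalescent) lets Ne trajectories and pedigrees share one engine, with
  exact ground truth, at desk scale.
* **Pedigree designs** — offspring bred through fixed matings with textbook
  expected autozygosity: outbred (F = 0), half-sib (0.125), full-sib
  (0.25), and "selfing-like" implemented as a doubled recombinant gamete
  (F = 1), chosen over ordinary selfing (F = 0.5) so the fully homozygous
  limit is deterministic.
* **Island implanting** — forces a region to hom-reference in exactly
  ⌈carrier_fraction · n⌉ uniformly chosen samples.

Default validation scale: 2–3 chromosomes of 100 Mb, 1,200–3,000 mapped
SNPs and cohorts of 20–40, mirroring per-population sizes of communal
livestock panels at reduced marker density; these sizes keep the full test
suite and the acceptance script in the tens of seconds on one core.  The
simulations reproduce drift, LD decay, recombination and pedigree
autozygosity but not allele-frequency ascertainment bias per population,
genotyping batch effects, map errors, or selection — so passing recovery
tests demonstrates correctness of the estimators under the stated models,
not robustness to every artefact of real array data.

## Numerical choices and degenerate inputs

Monomorphic SNPs return HWE p = 1 and are excluded from PCA scaling; an
all-missing SNP is removed by the call-rate stage before MAF is evaluated.
The exact HWE test normalizes in log space to avoid overflow at large n.
Bin means use a small epsilon floor so the Ne formula stays defined.  In
`F_HOM`, a sample whose `L = E_HOM` (degenerate denominator) reports NaN.
Chromosomes with fewer SNPs than the window produce no ROH calls (not an
error); chromosomes with fewer than 2 mapped SNPs are excluded from
per-chromosome F_ROH.  All randomness flows through explicit integer seeds;
identical config and input produce byte-identical pipeline outputs.

## Known limitations

* LD-based Ne estimates inherit the known upward bias at distant bins when
  the simulated (or real) population has not reached LD equilibrium, and
  the recent-Ne bins are sensitive to the sample-size correction.
* The ROH caller reproduces the sliding-window family of tools, not
  likelihood/HMM callers; very short or SNP-sparse autozygous tracts below
  the window size are invisible by design.
* PED text cannot preserve allele orientation at 50/50 SNPs (see above).
* F_HOM uses cohort allele frequencies; with strong substructure it mixes
  within- and between-population homozygosity excess (the usual caveat for
  pooled `--het` estimates).
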
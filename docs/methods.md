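# Methods

This note documents the models, defaults and numerical choices behind
`panelpipe`, and what the synthetic-data tests do and do not demonstrate
about real genotype-by-sequencing data.

## Data model

A dataset is a markers × samples matrix of biallelic genotype calls
(alt-allele dosage 0/1/2, −1 missing) paired with per-allele read-count
matrices and sample metadata: a population map for the wild cohorts, a
trio list (progeny, sire, dam) for Mendelian screening, and a
technical-replicate map.  Each marker sits at a known offset on a short
RAD-tag sequence; no genomic coordinates exist (the motivating species
has no usable assembly), so markers are identified as
`clone_id:snp_position` and redundancy is controlled through tag-sequence
similarity rather than map positions.

Silencing (setting an individual call to missing while keeping the
marker) never discards the read counts, and every silenced call is
recorded with its reason in a provenance table, so a silenced call is
distinguishable from a call that was never sequenced.

## Technical replicates

Replicate copies of a sample would pseudo-replicate every statistic, so
all per-marker statistics except repeatability collapse each replicate
group to the copy with the highest individual call rate.  Repeatability
itself is the concordance of calls across within-group pairs; markers
with no comparable pair default to 1.0 so that the absence of replicates
never removes markers.  When a dataset carries no replicate groups but
the provider shipped a per-marker repeatability column, that column is
used instead.

## Hardy–Weinberg testing

`hwe_exact` is the conditional exact test: given the observed allele
counts, the probability of h heterozygotes among n genotypes is
proportional to the multinomial coefficient times 2^h, and the two-sided
p-value sums the probabilities of all heterozygote counts no more
probable than the observed one (the standard SNP-HWE construction, not
mid-p).  It is computed in log-space over the exact support, and the
test suite checks it against an independent exact-integer enumeration
for every genotype table with n ≤ 50.

"HWE deviation as a percentage", the quantity the panel score penalises,
is not a standard statistic; here it is defined per population as
100·|Ho − He|/He (Ho observed heterozygosity, He = 2p(1−p)), averaged
over the designated populations, with monomorphic markers (He = 0)
contributing zero.  This measures the *size* of the departure rather
than its significance, which is what a ranking penalty should do — the
significance test already acts earlier as a hard filter.  The deviation
is capped at 100 % before entering the score so the penalty is bounded.

## The filtering cascade

Stage order: depth silencing → MAF → call rate → repeatability →
exact-duplicate collapse → 95 % redundancy clustering → MI-error marker
removal → HWE removal → MI-call silencing.  Boundary semantics follow
the conventions of the counts being reproduced: call rate ≤ 0.5 removes
(inclusive), MAF < 0.02 and repeatability < 0.9 remove (strict), MI
rate > 9 % removes (strict).  A marker failing several of the basic
criteria is charged to the first in MAF → CR → repeatability order.
All statistics are recomputed on the dataset as it stands at each stage.
An optional maximum mean-depth filter (recommended 200 reads/call, to
catch collapsed paralogs) is available but off by default.

Redundancy clustering is greedy and representative-based, emulating
CD-HIT without its word filter: tags are processed in descending
(length, MAF) order; each joins the first cluster whose representative
is at least 95 % identical (matching positions over the shorter length,
ungapped, end-to-end), else founds a new cluster.  Within clusters the
highest-MAF SNP survives; ties break by higher call rate, then lower
tag offset, then input order.  At the default 69-base tag length the
threshold admits 3 mismatches (66/69 ≈ 0.957) and excludes 4
(65/69 ≈ 0.942).

MI-call silencing targets only the progeny call of a flagged trio —
the minimal change that removes the inconsistency; parents are left
untouched because one erroneous progeny call cannot localise the error
to a parent.

**Known limitation — strict idempotence.**  Because MI-call silencing
runs last, it can nudge the MAF/call rate of a marker that sat just
above a threshold; a second run of the cascade then removes a handful
of such boundary markers (of order 0.1 % at the default scale).  With no
MI errors present the cascade is an exact fixed point, which the test
suite verifies.

## The GRM and the density analysis

The relationship estimator is the GCTA form (including its distinct
diagonal), with allele frequencies estimated from the dataset itself
and, for each sample pair, averaging over the markers non-missing in
both — no imputation.  Monomorphic and all-missing markers are skipped.
Because frequencies come from the sample, the off-diagonal mean in a
homogeneous cohort sits at the finite-sample offset −1/(n−1), not at
exactly zero; the tests assert the offset, not zero.  Subset GRMs reuse
the full-pool standardized matrix (marker subsetting does not change
per-marker frequencies), which is what makes 750 replicate GRMs cheap.

The density curve draws, for each subset size n, independent replicate
subsets of n distinct markers from the shared pool ("with replacement"
across replicates, without within a subset), computes each subset GRM,
and correlates it with the full GRM over the upper-triangle off-diagonal
entries defined in both (Pearson; the diagonal is excluded by default
because "pairwise relatedness" means distinct pairs, but inclusion is a
flag).  Mean and SE (sample SD/√reps) per size form the curve; the
minimum density for a target correlation is the smallest evaluated n
whose mean reaches the threshold.

## Panel scoring

QC score = 1.4·CR + 2.4·MAF + Rep_Avg + RD − HWE/10 − MI, with RD the
marker's mean depth over non-missing calls divided by the largest such
mean.  MI enters as a proportion (0–1): as a percentage it would dwarf
every positive term (the score's maximum is 4.6), turning a mild penalty
into a veto, which contradicts its role — high-MI markers were already
removed by the hard 9 % filter.  With HWE capped at 100 the score is
bounded in [−10.1, 4.6] for valid metric ranges (property-tested).
Ties in the ranking break by higher MAF, then higher call rate, then
input order; markers whose score is undefined (all calls missing) sort
last and are never selected.  The default panel size is 4236, the
probe-synthesis order size of the motivating assay.

## The synthetic-data generator

The generator emulates a shrimp DArTseq discovery cohort:

- **Population structure** — Balding–Nichols: ancestral alt frequencies
  uniform on [0.05, 0.95]; each of two wild populations draws its
  frequency from a Beta with that mean and variance Fst·p(1−p).
  Default Fst 0.1 (two regionally diverged wild stocks), cohort sizes
  132 + 125.
- **Pedigree** — farm broodstock are founders from the second
  population (the stock's source region); six 20-progeny families by
  default, each progeny allele drawn uniformly from its parent's two,
  independently per marker; 81 trios are recorded.  Truth genotypes are
  Mendel-consistent by construction, verified by the MI scan.
- **Read depth** — per-call totals are negative-binomial (mean 17,
  dispersion 2.0) scaled by a per-marker gamma multiplier (shape 1.2,
  mean 1) for uneven RAD-tag amplification, zero-inflated by 6 %.
  Jointly these reproduce the depth profile such data show: ~13 %
  missing calls, ~30 % of non-missing calls at ≤ 5 reads, per-call depth
  ≈ 18 ± 23, and a marker-level call-rate spread of ≈ 0.87 ± 0.14.
- **Error** — each read carries the wrong allele with probability
  0.001; calls derive from counts (both alleles seen → het, one → that
  homozygote, none → missing).  This yields hom→het miscall rates of
  ~1.7 % at the mean depth and marker-level MI error rates at the
  few-percent scale, and makes heterozygote dropout depth-dependent
  (verified: het concordance is worse at mean depth 5 than at 80).
  Residual error attenuates GRM estimates: known full sibs average
  ≈ 0.41–0.42 on QC-filtered calls rather than the pedigree 0.5.
- **Tags** — SNPs-per-tag distribution matching a 1.37 ± 0.6 mean over
  1–6 SNPs; 69-base tags by default (so the 95 % identity threshold
  lands between 3 and 4 mismatches); 2 % of tags re-emitted as exact
  duplicates and 2 % as near-duplicates (1 to ⌈0.05·L⌉−1 mismatches,
  avoiding SNP offsets), sharing the source tag's true genotypes.
- **Replicates** — 23 % of samples are duplicated and re-passed through
  the read-count sampler with fresh noise (same per-marker depth
  multipliers), so replicate concordance below 1 is attainable.

Everything is deterministic given the config seed (independent child
streams per component).  What the generator does **not** emulate:
linkage (markers are independent, so LD reports are null by design),
selection or drift across generations, family-size skew (sizes are
equal unless configured), batch/plate effects, species contamination,
and read-level artefacts (no FASTQ).  Passing tests therefore
demonstrate the pipeline's correctness and its behaviour under realistic
marginal noise, not robustness to structured artefacts in real
libraries.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` use: the default
discovery-scale cohort (≈5,200 emitted SNPs × ≈480 samples including
replicates) for the cascade; a 7,500-marker, 300-sample pool with
15 subset sizes × 50 replicates (20 in the test suite) for the density
curve; and a 257-founder single-population cohort with six 20-progeny
families at 5,000 markers for parameter recovery.  The acceptance
script's panel step selects the top 56 % of post-QC markers — the
discovery assay's panel-to-pool proportion — and reports the
panel-vs-full GRM correlation.

## Other design choices

- The canonical file dialect is the DArT one-row coding (0 hom-ref,
  1 hom-alt, 2 het, "−" missing) with two per-allele count matrices;
  two-row DArT and presence/absence (SilicoDArT) files are out of scope.
- PLINK PED/MAP export uses chromosome 0 and dummy positions (no
  assembly); missing calls become "0 0".
- MI rate denominator is informative trios only (all three calls
  present); markers with no informative trio pass the MI filter.
- LD is genotype-dosage r² over pairwise-complete samples (the PLINK
  default flavour), report-only: linked markers are flagged, never
  removed, because LD estimated in one population need not transfer to
  another.
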
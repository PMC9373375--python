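# Methods

## CCF inference and classification

Each somatic mutation is summarized by its alt read count `t`, depth `N`,
sample tumor purity `p`, and locus absolute tumor copy number `q` obtained
by 1-based inclusive interval lookup in the segment table. The expected
variant allele frequency at cancer cell fraction `f` is

    VAF(f) = p · f · m / (CN_normal · (1 − p) + p · q)

with `CN_normal = 2` (autosomes only by default; non-autosomal mutations
are excluded, with a flag for sex-aware normal copy number) and mutation
multiplicity `m = 1`. Fixing `m = 1` deliberately biases calls toward
clonal: a multi-copy mutation analysed at multiplicity 1 has its CCF
over-, never under-estimated, so subclonality is not overcalled at
amplified loci. Multiplicity is exposed as a parameter but never
auto-estimated. Loci at copy number 0 are excluded (a point mutation
cannot reside on zero copies) and itemized in the skip report together
with no-segment, no-purity and non-autosome exclusions.

The likelihood `Binom(t | N, VAF(f))` is evaluated on the uniform grid
f = 0.01 … 1.00 (100 points, top point included) and normalized into a
discrete posterior. Numerics: log-space likelihoods with max-subtraction
(direct products underflow near depth 300 in unfavourable corners — the
test suite checks agreement with a direct-probability implementation to
1e-9 total variation wherever the direct form stays clear of underflow);
MAP ties break toward the larger grid value (toward clonal); the 95%
interval is equal-tailed on the cumulative grid (first grid point with
cumulative mass ≥ 0.025 / ≥ 0.975). On nearly flat posteriors the first
grid point can hold less than 2.5% mass while still being the MAP, so the
interval is widened, when necessary, to contain the MAP.

A mutation is subclonal iff the interval's upper bound is strictly below
the top grid value (the interval "cannot overlap 1") **and**
`P(CCF < 0.9) > 0.5`, where the subclonal mass sums grid values strictly
below 0.9. Both thresholds (0.9, 0.5) and the credible level are
parameters. The conjunction is applied literally; the two clauses disagree
only near the boundary, where the conjunction resolves toward clonal.

A property of this rule worth knowing: because the posterior is truncated
at CCF = 1, the upper credible bound falls below 1 on roughly 1.2-sigma
downward fluctuations of the observed VAF. Exact computation (binomial
lower tail at the largest alt count still called subclonal) shows that a
true clonal mutation is mislabelled subclonal ~9–12% of the time at depth
200 for *any* purity, falling to ~4% at depth 500 and ~1% at depth 1000.
Specificity claims for the classifier are therefore stated at depth 500.
Conversely, the MAP CCF of a subclonal mutation carries the binomial
sampling SD divided by the VAF-per-CCF slope — at depth 500, purity 0.7,
diploid, that is 0.033–0.057 CCF units across CCF 0.2–0.8, so no estimator
can place 90% of MAP values within ±0.05 of truth at those settings; the
measured rate (~0.70) sits near the information bound (~0.72).

## Enrichment permutation test

For a gene with `c1` clonal and `s1` subclonal classified non-silent
mutations, each of 1000 permutations draws `n = c1 + s1` mutations without
replacement from the cohort-wide label multiset (the gene's own mutations
included; both choices exposed as flags, including with-replacement
draws). The clonal draw count determines the clonal ratio monotonically at
fixed `n`, so `p_clonal = (#{c* ≥ c1} + 1)/(B + 1)`; the at-least-as-
extreme convention with the add-one correction replaces a strictly-greater
count so that a maximal observed ratio cannot produce p = 0, which would
break FDR control. q-values are Benjamini–Hochberg. Each gene consumes an
independent child stream of the seed keyed by sorted gene position, and
draws are index-based (label-independent), so swapping the clonal and
subclonal labels everywhere maps p_clonal onto p_subclonal exactly, a
symmetry the tests assert realization-wise.

Calibration is checked two ways: permutation p-values against the exact
hypergeometric tail (within 3 Monte-Carlo SEs), and the empirical rate of
p ≤ 0.05 across 400 null genes against the 99% binomial band around 0.05.
The null-calibration design mixes per-gene mutation counts uniformly over
100–300: a one-sided test on a discrete count is conservative (attainable
size ≤ 0.05 always), and at a single small n the attainable size collapses
onto one lattice value far below 0.05 and jumps with the realized pool
fraction; mixing sizes in the low hundreds stabilizes it near 0.042, which
the band comfortably contains.

## Clinical association

Per gene, each patient is clonal, subclonal, or WT; carriers of both
collapse to clonal by default (flag: subclonal-dominant). Clinical
variables are binarized — age at the cohort median, AJCC 1/2 vs 3/4,
T 1/2 vs 3/4, N0 vs N1/2, M0 vs M1, MSI vs MSS, left vs right, female vs
male — and crossed with the three categories in 2×3 tables including WT.
The two-sided exact p-value is the Freeman–Halton extension: enumerate all
tables with the observed margins and sum the conditional probabilities not
exceeding the observed table's (relative tolerance 1e-7 on ties, matching
the convention of the common R implementation). Tables whose candidate
count exceeds 2·10⁶ fall back to a seeded Monte-Carlo estimate with 10⁵
draws, flagged as such. Genes qualify for the scan with ≥ 5 clonal and
≥ 5 subclonal carriers; missing clinical values drop a patient from that
one test only (pairwise deletion). No multiplicity correction is applied
across the gene × variable scan; the heat-map output reports −log2(p).
Burden comparisons use the unpaired two-sided t-test or Wilcoxon rank-sum;
mutation-type contrasts (indel vs other, nonsense vs other, against
clonal/subclonal) use the classical 2×2 Fisher exact test.

## Survival

Kaplan–Meier curves and log-rank tests (lifelines) compare the three
patient groups per eligible gene, overall and pairwise, with optional
subgroup restriction (stage I/II, MSI, right-sided). Cox models encode
gene clonality as two dummies against WT; ties use the Efron
approximation; CIs and p-values are Wald. Monotone-likelihood covariates
(a level with zero events) are reported flagged with effectively infinite
CIs rather than suppressed. Backward stepwise elimination removes, at each
step, the covariate block with the largest p-value above 0.05 — a gene's
two dummies are scored by their smaller p-value and removed jointly, since
the scientific unit of selection is the gene. Bootstrap stability
resamples patients with replacement, reruns the stepwise pipeline, and
reports per-covariate inclusion frequencies over successful replicates
(failed fits counted and excluded from the denominator).

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, at
the scale of a TCGA colorectal cohort: 536 patients by default; purity
uniform on (0.3, 0.9); depth Poisson with mean 100 truncated at 30 (TCGA
exomes rarely sit below 30×, and degenerate ultra-shallow posteriors would
make truth-recovery tests meaningless); copy-number states
{1: 0.10, 2: 0.70, 3: 0.15, 4: 0.05}; a 15-gene driver panel whose
per-patient mutation rates and clonal biases echo the frequently mutated
colorectal genes (APC/TP53/KRAS clonal-leaning, a BCLAF1-like
subclonal-leaning gene). Clonal mutations have true CCF exactly 1;
subclonal CCFs are uniform on (0.1, 0.7) — strictly below the 0.9
threshold so truth labels are well-defined against the classifier's
definition. Read counts come from the same binomial observation model the
inference inverts. Optional couplings: MSI multiplies per-gene mutation
rates (burden) and the odds of subclonality for configured genes; survival
times are exponential with per-patient hazard multiplied by exp(log-HR)
per configured gene-clonality effect, censored at the configured rate by
uniform draws on (0, t). One mutation per gene per patient by default; a
`both_rate` switch adds an opposite-clonality second mutation. Segments
are per-site stubs (±1 kb around each gene's fixed locus), not genome
geography; there are no mutational signatures and no multi-region
sampling — passing tests demonstrate recovery of the modelled structure,
not robustness to artefacts real cohorts add (mapping bias, subclonal copy
number, purity estimation error).

Benchmark problem sizes, chosen as the package's own validation design:
CCF oracle sweep over 300 random read-count configurations; parameter
recovery on 2,000 mutations at depth 500, purity 0.7, diploid; classifier
specificity on 20,000 clonal mutations at the same settings (sized so the
Monte-Carlo SE ~0.0014 is small against the margin over the 95% bound);
enrichment calibration on 400 null genes at 1000 permutations; survival
recovery over 50 replicates of a 1,000-patient, 5-gene cohort at depth 200
with a log(3) subclonal hazard on one gene (deeper coverage keeps label
noise from attenuating the hazard estimate); determinism on a 120-patient
end-to-end run.

## Known limitations

Single-population CCF only — no mixture-model subclone reconstruction, no
multiplicity estimation, no copy-number timing. The Freeman–Halton
enumeration is exponential in columns and intended for 2×3; larger tables
go through the Monte-Carlo path. Stepwise selection inherits its usual
instability; the bootstrap inclusion frequency is reported precisely
because single stepwise runs overfit. Proportional hazards is reported as
a diagnostic concern, not enforced.
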
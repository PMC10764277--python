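# Methods

This note records the models behind each pipeline stage, the defaults that
matter, what the synthetic-data generator does and does not emulate, and
the numerical and design choices made where more than one reasonable option
existed.

## Synthetic study generator

The generator (`magpheno.synthdata`) produces every input the analysis
consumes, with planted truth.

**Reference pangenome.** Each of `n_phenotypes` metabolic pathways has one
or two *variants* — sets of 2–4 functional roles (40% of multi-role
pathways get a second variant differing in one role). A genome's phenotype
is 1 iff it carries every role of some variant; this makes the binary
phenotype matrix (BPM) exactly recomputable from gene content, which the
tests assert. Phenotype prevalences are planted inside a configurable band
(default 0.25–0.75) by exact positive counts, and genomes assigned 0 are
post-edited so no variant is accidentally complete.

Genomes fall into clades (default 10 members): each protein family has an
ancestral random amino-acid sequence, per-clade variants diverged at 12%
per site, and per-genome copies mutated at 2.5% per site. Within-clade
pairwise identity is therefore ≈95% (Mash distance ≈0.05, inside the ≤0.1
neighbour-group cap) and between-clade identity ≈78% (distance ≈0.25,
outside it), so MinHash grouping recovers the clades. Pathway content
tracks the clades — positives fill whole clades first and share a variant;
negatives carry sparse remnants (each role kept with probability 0.15) with
an occasional near-miss (10%) — reflecting the observation that close
phylogenetic neighbours tend to share whole pathway variants while distant
relatives carry divergent ones. This structure is what makes
neighbour-group Hamming matching informative; without it (all genomes
mutually close, near-misses common) pattern matching cannot distinguish a
dropout-degraded positive from a true near-miss negative, and no
reconciliation scheme can reach high accuracy.

Sequence realism is deliberately minimal: identity is the only sequence
property any pipeline stage consumes, so proteins are random strings with
controlled per-site substitution; there is no indel process, no codon
structure, and no phylogenetic correlation beyond the two-level
clade/genome hierarchy.

**MAG degradation.** Each gene is retained independently with probability
`completeness` (default 0.9, the usual high-quality MAG bar), retained
genes split into two fragments with probability `fragmentation_rate`
(0.05), and contaminant genes drawn from other genomes at rate
`contamination` (0.05) per retained gene. Contaminants keep their source
roles and are tagged only in provenance — downstream stages cannot tell
them apart, as with real contamination.

**Cohort.** Two arms (MDCF-2 / RUSF) assigned alternately over
`n_participants` (default 40), sampled at weeks 0–16 (five visits).
log₂ MAG abundance = genome baseline + participant-level effect (SD 0.8) +
small secular drift + planted treatment×week effect + noise (SD 0.7);
values below TPM 0.5 become structural zeros. WLZ is
`uᵢ + 0.01·week + Σ β₁ₘ·zₘ + ε` with `zₘ` the standardized log₂ abundance
— effects enter on the variance-stabilized scale so mixed-model recovery is
well-posed. Defaults plant β₁ = +0.5 on 10% of MAGs and −0.5 on another
10%; the positive set also receives β₃ = +0.15 log₂-TPM/week on treatment,
mirroring the expectation that growth-associated organisms respond to the
food. Transcript counts are negative binomial (dispersion 0.3) with means
proportional to the parent MAG's relative DNA abundance (zero when the MAG
is undetected), plus planted group (log₂FC 1.5) and group×week (0.12/week)
effects concentrated in two randomly chosen "responder" pathways.
Abundance marginals are independent log-normals, a modelling choice — real
TPM is compositional, and none of the generator's distributional choices
are claims about real data. Quartile labels are assigned from per-participant
WLZ slopes within the treated arm.

What passing tests show, and don't: they demonstrate that each statistical
procedure recovers effects of the planted form at the planted sizes under
its own model assumptions, and that the stage plumbing (filters,
normalizations, thresholds, vote reconciliation) is exactly as specified.
They do not establish robustness to compositionality, batch effects,
phylogenetic confounding, or model misspecification in real cohorts.

**Randomness.** Every stage draws from `default_rng(SeedSequence([seed,
crc32(stage_name)]))`, so one top-level seed reproduces the whole study
bit-for-bit and adding draws to one stage never perturbs another.

## Annotation

Per query: top 50 hits by bitscore (ties broken by subject id). Start and
end coordinates are clustered separately with DBSCAN (eps = 10 residues,
min 2 points — chosen so a single stray hit cannot spawn a domain); cluster
centres are rounded means ("centre" is unstated in the field's usual
description; mean is used). Start centres are paired greedily with the
nearest unused end centre to the right; intervals < 35 aa are discarded;
each hit is attributed to the interval it overlaps most. The per-domain
identity threshold is the highest-identity interior local minimum of a
Gaussian KDE (Silverman bandwidth, 512-point grid on [0, 100]); with no
interior minimum (unimodal input, < 3 values, or zero spread) the threshold
is 0 and every hit is kept. The ≥35-aa length filter is applied before
thresholding. Plurality voting runs over hits at or above the threshold;
an outgroup plurality withholds the role, a vote tie falls back to larger
summed bitscore, and a residual tie abstains. Gene fragments are annotated
through the identical path as independent queries.

## Phenotype prediction

*Pathway rules*: one CART tree per phenotype (Gini, max depth = number of
pathway roles, no pruning), with predictors restricted to the pathway's
required roles when definitions are available. Constant phenotypes become
flagged constant rules. *Random forest*: per phenotype, grid over
max_features ∈ {√p, p/3} × min_samples_leaf ∈ {1, 3} at 200 trees
(default), selected by out-of-bag score — the grid-search criterion is this
package's choice — with optional leave-one-out accuracy reporting for the
chosen configuration. *Neighbour groups*: MinHash sketches (k = 21,
sketch 1000, crc32 k-mer hashing — stable across processes; collisions at
32 bits are negligible at these sketch sizes) feed the Mash distance
d = −(1/k)·ln(2j/(1+j)) (capped at 1 when j = 0); single-linkage components
under d ≤ 0.1 with ≥ 4 members form groups (the linkage is this package's
choice). Per phenotype, the query adopts the phenotype of the group
reference with minimal Hamming distance over the pathway's required roles;
equidistant conflicting references, or a group without references, abstain.

*Consensus*: unanimity → high confidence; a participating neighbour vote in
the majority → medium; neighbour abstaining with rules/ML agreeing →
medium, disagreeing → the ML value at low confidence. The one asymmetry:
ng = 1 against rule = ML = 0 yields 1 (low). Rationale: at completeness
< 1 the rule and forest predictors share the same failure mode — a dropped
required gene forces both to 0 — while the neighbour comparison, run "even
if some genes are absent", is the only signal that survives dropout; since
degradation only destroys genes, a positive neighbour vote against two
zeros is far more often a rescue than an error. The scheme is a
`consensus(..., ng_rescue=False)` flag away from plain majority, and the
high/medium/low mapping is config-level, not load-bearing.

## Association models

`fit_lmm` fits a random-intercept LMM by REML (statsmodels MixedLM). When
the random-intercept variance estimate collapses to the boundary
(< 1e-8 × residual variance) the fixed effects are replaced by the OLS
solution — which *is* the profiled-REML answer at zero variance — making
the OLS-limit equality exact rather than approximate. p-values use a
residual-df t approximation (df = n − p), not Satterthwaite: only rank and
threshold behaviour is load-bearing downstream, and the approximation's
type-I error is verified at 0.05 ± 0.02 in the tests. The treatment model
codes the grouping factor 0/1 (control = 0 when levels are supplied;
sorted order otherwise), so swapping labels negates β₁ and β₃. The
empirical-Bayes moderation used by some treatment-model packages (dream) is
deliberately not reproduced; each feature is fitted independently.

The variance-stabilizing transform is a surrogate: median-of-ratios size
factors (geometric-mean reference over features detected in every sample,
positive-count fallback otherwise) followed by log₂(x/s + 1). It is tested
for monotonicity, finiteness at zero and variance flattening — no
equivalence to any particular package's VST is claimed.

TMM follows the standard formulation: reference sample by upper-quartile
closeness, M/A values over doubly-expressed genes, two-sided rank trimming
(30% on M, 5% on A), precision-weighted mean, factors normalized to
geometric mean 1; a cross-check test reproduces edgeR's `calcNormFactors`
to 1e-6 on a composition-shifted matrix. CPM is computed after the
DNA-floor zeroing (library sizes therefore reflect the zeroed table).
Thresholds follow the printed conventions exactly: TPM filter strict
(> 5 TPM in > 40%), CPM filter inclusive (≥ 5 CPM in ≥ 35%), DNA floor
strict (< 0.5 TPM).

NB differential expression: per-gene Poisson-fit method-of-moments
dispersion, lowess trend on log mean abundance, shrinkage halfway toward
the trend on the log scale (dispersion clipped to [1e-4, 10]); NB GLMs with
log link and offset log(library × TMM factor); the tested coefficient
(group or interaction) by likelihood-ratio chi-square with 1 df — an
approximation to quasi-likelihood F-testing; null uniformity is verified by
KS test at 2,000 genes. Non-converged genes are flagged with p = 1
(conservative). logFC is the coefficient converted to log₂ units. Ranking
metric: sign(logFC) × −log₁₀(p), p clipped at 1e-300 with a warning; ranked
lists break ties by feature id so enrichment is deterministic.

## Enrichment

Classic weighted Kolmogorov–Smirnov running sum at weight 1 (the exponent
is a convention choice): hit steps ∝ |metric|, miss steps uniform; ES is
the extremum of the running sum; equal hit steps are substituted when every
member metric is zero. The permutation null draws random same-size member
sets from the ranked universe (the pre-ranked convention; 10,000 by
default, cached per set size). p-values are sign-stratified —
(1 + #{null ≥ ES})/(1 + #{null ≥ 0}) for ES ≥ 0 and symmetrically below —
and NES divides ES by the mean same-sign null magnitude. BH adjustment runs
across scored sets; sets under the 10-member floor (or spanning the whole
universe, which leaves no misses) are reported as skipped with a reason.
Leading edges are members at or before the peak (positive ES) or at or
after it (negative).

## PULs

Detection seeds at adjacent SusC/SusD pairs and extends over CAZymes,
regulators and further Sus proteins, tolerating ≤ 2 intervening
non-functional or missing ORFs (max_gap = 2 — external PUL databases do not
print their rule; this is a declared default); overlapping seeds merge.
Pairwise identity is global-alignment matches / alignment length (match 1,
mismatch 0, gaps −0.5/−0.1; the denominator convention is declared since
"percent identity" alone does not fix one), with a fast path for
equal-length substitution-only pairs and an 8-mer prescreen to skip
unrelated pairs. "Fragmented" means ≥ 2 short query ORFs each matching
inside the reference ORF at > 90% identity over their length and jointly
covering ≥ 80% of it. Conserved requires every reference ORF fully matched,
in strictly monotone query order — increasing or decreasing, so a
strand-flipped (fully reversed) block still counts as identical
organization — with no unmatched ORFs inside the block span. A block with
defects (missing/fragmented Sus or CAZyme, insertions, order changes) is
structurally distinct when at least half the ORFs match fully or a Sus
protein plus a CAZyme are found; otherwise absent. Categories encode as
1 / 0.5 / 0; profile distances are Euclidean against the reference
genome's (all-ones) profile; the association test is Pearson r of
(distance, β₁) pairs with a two-sided t p-value, requiring ≥ 3 pairs and
non-degenerate variance.

## Orchestration and problem sizes

The pipeline validates its configuration before any stage runs (unknown
keys and enabled-stage dependency gaps are errors), writes each product as
plain text with SHA-256 checksums, marks interrupted runs with an
INCOMPLETE file, and treats a completed run with unchanged config + seed as
a no-op unless forced. The default run uses a scaled study — 30 reference
genomes (3 clades), 12 phenotypes, 30 participants × 4 weeks, 10 MAGs,
~1,500 transcripts, 2,000 permutations — sizes chosen so a complete run
and its validation finish in minutes on a single core while keeping every
planted effect comfortably detectable; the validation suite and the
reproduction script state the sizes they use alongside each number.

## Known limitations

Annotation assumes alignment hits are given (no aligner is run); domain
boundary pairing is greedy and can mis-pair when a query has more start
clusters than end clusters; the KDE threshold assumes at most modest
multimodality. Phenotype confidence grades are a declared scheme, not
calibrated probabilities. The LMM p-values are approximate (residual-df t);
the NB testing is LRT, slightly anti-conservative at very small n. GSEA
uses gene-label permutation, which ignores inter-gene correlation.
PUL classification thresholds (90% identity, 80% fragment coverage,
max_gap 2) are declared defaults and the structurally-distinct/absent
boundary involves a judgment rule; evidence for every call is emitted so
borderline cases can be audited.
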
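# magpheno

Computational pipeline for linking gut-microbiome genome content to child
growth in nutritional-intervention studies: functional annotation of
metagenome-assembled genomes (MAGs), consensus metabolic-phenotype
prediction, longitudinal abundance–anthropometry association, expression
enrichment, and polysaccharide utilization locus (PUL) conservation
analysis — all exercisable end to end on synthetic data with known ground
truth.

## Who this is for

Microbiome researchers analysing randomized trials of microbiome-directed
complementary foods (e.g. MDCF-2 vs a conventional ready-to-use supplement,
RUSF) in children, where the readouts are faecal shotgun DNA abundances of
MAGs, faecal metatranscriptomes, and ponderal growth expressed as
weight-for-length Z scores (WLZ). The package re-implements the bespoke
computational steps such a study needs, each behind a tested library
function, and ships a generator that emulates every input with planted
effects so the whole chain can be validated without access to trial data.

## What it computes

**Domain-aware annotation.** Query proteins are aligned against a reference
database of role-labelled proteins (BLAST/DIAMOND tabular hits). Per query:
top 50 hits by bitscore; 1-D density clustering of alignment start/end
coordinates defines domain boundaries (domains ≥ 35 aa kept); a Gaussian-KDE
threshold on the per-domain identity distribution removes the low-confidence
tail; a plurality vote assigns the functional role, with high-identity hits
to an outgroup vetoing annotation.

**Consensus binary phenotype matrix (BPM).** A phenotype is 1 when a genome
encodes a complete variant of a metabolic pathway. Three predictors vote:
pathway-rule decision trees, per-phenotype random forests (grid-searched,
leave-one-out evaluated), and neighbour groups — MAGs grouped with reference
genomes at Mash distance ≤ 0.1 (ANI ≥ 90%), where

&nbsp;&nbsp;&nbsp;&nbsp;d = −(1/k) · ln( 2j / (1+j) ),&nbsp;&nbsp; j = MinHash Jaccard estimate,

adopting the phenotype of the reference with the smallest Hamming distance
over the pathway's required genes. Because incompleteness destroys genes but
never invents them, a neighbour vote of 1 overrides concordant 0 votes
(false-negative rescue); irreconcilable disagreements default to the
machine-learning vote. Gene annotations can then be filtered to intact
(phenotype-1) pathways.

**Growth association.** MAG abundances (kallisto-style TPM) are filtered
(> 5 TPM in > 40% of samples), variance-stabilized, and fitted per MAG with
random-intercept linear mixed models:

&nbsp;&nbsp;&nbsp;&nbsp;WLZ ~ β₁·MAG + β₂·week + (1|PID)
&nbsp;&nbsp;&nbsp;&nbsp;MAGᵢ ~ β₁·group + β₂·week + β₃·(group × week) + (1|PID)

with Benjamini–Hochberg q-values (significance q < 0.05). The same
interaction form serves WLZ-response-quartile contrasts (e.g. faecal
glycosidic-linkage levels).

**Expression enrichment.** Transcript counts are zeroed per sample when the
parent MAG's DNA is < 0.5 TPM, filtered at ≥ 5 CPM in ≥ 35% of samples,
TMM-normalized, and tested with per-transcript negative-binomial GLMs
(trended dispersion, likelihood-ratio tests). Transcripts ranked by
sign(fold change) × −log₁₀(p) feed pre-ranked GSEA over metabolic-pathway
sets (≥ 10 genes, significance q < 0.1) with leading-edge extraction; MAG
sets (significantly positively / negatively WLZ-associated) are scored the
same way against model t-statistics.

**PUL conservation.** PULs are detected from role-annotated ORFs (adjacent
SusC/SusD pair extended over CAZymes/regulators), classified against a
reference repertoire as conserved (every ORF > 90% amino-acid identity in
identical order), structurally distinct (a CAZyme or SusC/SusD missing or
fragmented, or extra ORFs), or absent; profiles encoded as {1, 0.5, 0} are
related to per-genome β₁ coefficients by Pearson correlation of Euclidean
profile distances.

## Worked example

`examples/` holds one short script per capability. From
`examples/04_growth_association.py` (synthetic cohort, 30 MAGs, 30
participants, seed 3):

```
30 MAGs -> 25 pass the abundance filter
6 MAGs significantly associated with WLZ (q < 0.05):
          beta1       t       q
G0004   -0.4859 -5.1700  0.0000
G0017   -0.4636 -4.1333  0.0003
G0014   -0.4189 -4.0202  0.0004
G0016    0.6441  7.7499  0.0000
G0024    0.7163  9.2568  0.0000
G0005    0.6886  9.7536  0.0000
planted effects: {'G0004': -0.5, 'G0005': 0.5, 'G0014': -0.5, 'G0016': 0.5, 'G0017': -0.5, 'G0024': 0.5}
```

Exactly the six MAGs carrying planted effects (β₁ = ±0.5 on the
variance-stabilized scale) are recovered with the right signs; β̂₁ estimates
sit within sampling error of the planted values. And from
`examples/06_pul_conservation.py`, planting PUL conservation that decays
with the planted growth association:

```
Pearson r(profile distance, beta1) = -0.941 (p = 0.0051)
```

— genomes whose PUL repertoires drift from the reference profile carry
weaker WLZ associations, the signature the conservation analysis is built
to detect.

The end-to-end orchestrator runs every stage with a machine-readable
report:

```bash
magpheno run --outdir out/ --seed 1
```

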
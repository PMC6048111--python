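# Methods

This note documents the models and conventions behind `fusionsieve`: what
each stage assumes, which parameters matter and why their defaults are what
they are, what the synthetic cohorts do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Coordinates and fusion orientation

All genomic coordinates are 1-based inclusive, the convention of published
fusion breakpoint tables; readers convert 0-based half-open inputs at the
boundary. A fusion is oriented: the donor contributes the 5′ part of the
chimeric transcript, the acceptor the 3′ part, and the breakpoints are the
last retained donor base and the first retained acceptor base (both
inclusive). Gene symbols are the join key across all tables; when a gene
has several transcript models the longest-CDS one represents it
(configurable), since call tables rarely carry isoform identifiers.

## Screening cascade

Four filters, each with a recorded pass/fail flag and no short-circuiting,
so the audit table reconstructs the funnel and the survivor set is
independent of filter order:

* **in frame** — junction phases equal (below); candidates without any
  frame information are reported as unresolvable rather than silently
  rejected.
* **absent in normal** — the ordered (donor, acceptor) pair never appears
  in a normal-tissue call. Matching is at gene-pair level because junction
  coordinates jitter between samples and callers; orientation sensitivity
  is configurable (default: the reciprocal pair does *not* match, treating
  the two orientations as distinct biological events).
* **spanning reads ≥ 10** (inclusive).
* **intrachromosomal distance ≥ 100 kb** (inclusive). Same-chromosome
  pairs closer than this are overwhelmingly transcriptional read-through;
  interchromosomal pairs bypass the filter, which exists specifically to
  vet intrachromosomal rearrangements. Whether exactly 100 000 bp passes
  is not determined by the rule's usual "≥ 100 kb" phrasing; this
  implementation reads the boundary as inclusive, and both thresholds are
  configurable.

## Cross-caller consensus

Calls sharing (sample, donor, acceptor) whose breakpoints agree within a
tolerance on both sides merge into one group; groups are the transitive
closure of the pairwise relation (union–find), making grouping independent
of input order, exact at tolerance 0, and refining monotonically as the
tolerance shrinks. The default tolerance of 50 bp absorbs sub-exon jitter
between callers while the gene-pair key carries the rare kb-scale
disagreements between short-read and confirmatory sequencing coordinates.
A group validates when ≥ 2 distinct callers support it (the 2-of-3 rule;
`min_support` configurable).

## Junction phases and domain retention

With L_d retained donor coding bases and D_a discarded acceptor 5′ coding
bases, the phases are L_d mod 3 and D_a mod 3, and frame is preserved iff
they are equal: acceptor bases sit at chimera offset L_d + i and native
offset D_a + i, so codon boundaries coincide exactly when L_d ≡ D_a
(mod 3). The test suite verifies this against a brute-force translation
oracle (the acceptor's native C-terminal peptide must survive translation
of the concatenated sequence) on 1000 random multi-exon, mixed-strand toy
fusions, and checks strand symmetry by mirroring whole loci.

Edge cases: a donor breakpoint in the donor's 5′ UTR contributes no coding
sequence; such fusions are flagged as promoter-swap candidates and called
in frame only when the acceptor phase is 0 (its open reading frame starts
intact). An acceptor breakpoint in the acceptor's 5′ UTR discards nothing,
phase 0. Intronic or 3′-UTR breakpoints leave the phase undefined and the
fusion not in frame, with a diagnostic naming the offending region.

The hybrid junction codon (donor phase ≠ 0) is counted on the donor side,
so for in-frame fusions total length = donor + acceptor segment lengths.
The arrow label "d→a" reported in fusion tables is stored as this ordered
phase pair; stored caller labels, when present, are taken as authoritative
for screening (callers annotate frames from their own transcript models)
and the recomputed phases serve as a cross-check.

Domain retention is interval arithmetic on the native protein: retained /
lost / truncated are mutually exclusive and exhaustive, with fraction =
retained aa / domain length for straddling domains. Domains come from the
input annotation table; no de novo prediction.

## Oncogenicity rule

A validated fusion is called oncogenic when any clause fires (disjunctive
by default, conjunctive available):

* an expression outlier on the donor or acceptor in the carrier;
* a partner annotated kinase or oncogene;
* a partner annotated tumour suppressor whose annotated domains are
  damaged: any domain lost outright, or truncated below 0.9 retained
  fraction.

The lost-domain arm matters because a suppressor can retain ~90% of the
region spanning the breakpoint yet lose every downstream functional domain
— the pattern seen in suppressor-partner fusions where the retained
fragment is functionally dead. The threshold and the boolean combination
are declared, tested and tunable rather than asserted as uniquely correct:
the disjunction is this package's formalisation of "selected by expression
value and function". Verdicts are monotone in evidence, and every true
verdict carries at least one reason code.

## Expression outliers

Default: Tukey upper fence, flag ⇔ value > Q3 + 1.5·IQR (numpy linear
quantile interpolation) over tumour samples only — restricting the
reference prevents genes silent in normals from being trivially flagged.
A z-score criterion (z > 3) and an optional log2(FPKM+1) transform are
provided; both fence criteria are invariant to positive rescaling of the
matrix (the log transform is not, because of its +1 offset). "Outlier
analysis" has no canonical formula in this setting; the Tukey fence is the
conventional reading and every piece is configurable.

## Somatic-variant hard filters

The cascade: depth ≥ 10, alt depth ≥ 2, VAF ≥ 3% (boundaries inclusive),
exonic region, effect ∈ {frameshift, non-synonymous, stop-gain,
stop-loss}, population MAF ≤ 1% (higher = likely germline), Fisher Strand
≤ 30 and QualByDepth ≥ 2, and exclusion of sites seen in matched normals.
The FS/QD rule is implemented in the standard hard-filter direction
(FS > 30 *or* QD < 2 removes a variant); retaining such variants would
invert accepted practice. Attrition is attributed to the first failing
filter in cascade order; variants missing a needed field are counted
separately as unevaluable, so input = survivors + Σ removals +
unevaluable always holds.

## Exclusivity test

Statistic: number of fusion-positive patients with ≥ 1 mutation in the
oncogene panel. Null: fusion labels permuted across patients with the
mutation matrix fixed — equivalently, the permuted statistic is the
overlap of a uniformly random size-k patient subset with the mutated set,
which is how the permutation stream is vectorised. One-sided (small
overlap = exclusivity), add-one smoothed.

Because the statistic is a small integer, ties between permutations and
the observed value are massive and a plain "≤" rule is substantially
conservative: computed exactly (hypergeometric permutation distribution
mixed over a binomial mutation count), its type-I error at α = 0.05 is
only ≈ 0.024–0.029 for any realistic mutation rate at n = 100 with 15
carriers. The default p-value therefore applies the standard mid-p tie
correction (half weight on ties), which restores near-nominal calibration
(≈ 0.045 analytically, 0.047 ± 0.007 empirically over 1000 null cohorts)
while remaining a valid permutation p in (0, 1]; the strictly
conservative full-tie-weight form is available as
`tie_correction='add-one'`. The test suite checks the sampled p against
exhaustive enumeration of all label placements on 6-patient cohorts.

Oncogene/suppressor panels are input data (driver lists are
cohort-external knowledge); the synthetic bundles ship one.

## Clinical statistics

Categorical covariates are dichotomised as clinical cohort tables
conventionally do (histology well+moderately vs poorly+mucinous, depth
T1+T2 vs T3+T4, MSI MSS+MSI-L vs MSI-H). Mode `auto` applies Fisher's
exact test when any expected cell count is below 5 and the chi-square test
otherwise; which convention produced any given published p is usually
unstated, so printed p-values are treated as significance-class evidence,
not bit-exact targets (the test suite verifies the exact-test p against a
hypergeometric enumeration oracle instead). Continuous covariates use the
two-sample t-test (pooled variance by default, Welch optional) with group
means ± SE.

Survival uses lifelines' Kaplan–Meier estimator and log-rank test. Mean
survival is the restricted mean (horizon = largest observed time) so a
"months ± SE" summary exists under censoring; the RMST area and its
classical Greenwood-type variance Σ A_i² d_i / (n_i(n_i−d_i)) are computed
directly from the fitted event table — the library's own variance output
failed a bootstrap sanity check (SE ~50 vs bootstrap ~6 on an n = 80
example) while the point estimates agree exactly, and a test pins that
agreement.

## Synthetic cohorts

Defaults are the study conditions the pipeline targets: 147 tumours with
47 matched normals, 25 planted fusions concentrated in ~19–20 carriers
(~78% of the fusion count, mirroring a cohort where a few patients carry
two fusions), 70% in-frame junctions, three callers with sensitivities
(0.95, 0.85, 0.85) — a strong primary caller and two cross-validators —
Gaussian breakpoint jitter (sd 5 bp), one artifact call per tumour sample,
negative-binomial spanning reads (mean 60, shape 8), 10× expression
activation of driven partner genes, oncogene-mutation probability 0.05 in
carriers vs 0.40 outside (suppressor mutations 0.5 everywhere), MSI-H
odds multiplied by 3.5 in carriers over a 10% base rate, a 1 cm smaller
mean tumour size in carriers, and exponential survival (mean 180 months,
uniform 60–130-month censoring; hazard ratio 1, since no survival effect
is part of the target conditions).

The toy genome lays ~3 multi-exon genes per synthetic chromosome with
10–50 kb intergenic gaps, so consecutive genes furnish genuine < 100 kb
read-through artifacts; further artifact flavours violate the spanning,
frame and not-in-normal filters, and two gene pairs are planted in normal
samples. Fusion types cycle through kinase-acceptor,
suppressor-truncation, outlier-only and passenger (30/20/30/20%);
biological oncogenicity truth = in-frame ∧ non-passenger. Breakpoints are
placed inside CDS exons with the acceptor offset chosen congruent (or
deliberately incongruent) to the donor's phase to hit the configured
in-frame fraction.

The manifest records, per fusion, both the biological truth and the
*expected fate* at each pipeline stage given the generated evidence (e.g.
a fusion whose spanning-read draw fell below 10 is expected to fail the
screen); stage-wise recovery metrics compare pipeline output against
expected fates, while the headline oncogenic recovery is measured against
biological truth. In the noiseless limit (perfect callers, no artifacts,
no jitter, zero expression spread) expected and observed coincide exactly,
and recovery is 1.0 by construction of the generator–pipeline contract,
which is what the noiseless acceptance check pins.

What the generator does **not** emulate: read-level evidence (no
FASTQ/BAM; fidelity stops at the call table), correlated caller errors,
isoform diversity (one transcript per gene), copy-number and expression
covariation, intratumour heterogeneity, and clinical covariate
correlations beyond the planted MSI and size effects. Passing tests
therefore demonstrate the correctness of the analysis logic under the
stated statistical structure, not performance on any real cohort.

## Problem sizes in the test suite

Property suites run on reduced cohorts (25–40 patients, 36 genes, 6–10
fusions per seed, 100 seeds) and the calibration study on 1000 null
cohorts of 100 patients with 1000 permutations each — sizes chosen so the
full suite completes in a few minutes on one core while keeping every
statistical check adequately powered; the full-scale 147-patient defaults
are exercised by the recovery tests, the examples and the acceptance
script.

## Known limitations

* Frame analysis needs transcript models covering both partners; calls on
  unannotated genes are reported unresolvable unless the caller supplied a
  frame label.
* The "in-frame iff phases equal" rule ignores premature stops created
  *inside* the hybrid junction codon; such chimeras translate but
  terminate early. Domain retention on the acceptor side would overstate
  retention in that rare case.
* The exclusivity test conditions on the observed mutation matrix; it does
  not model per-gene mutation-rate heterogeneity beyond what the matrix
  already encodes.
* Published cohort-scale funnel counts (thousands of raw candidates down
  to tens of validated fusions) depend on raw sequencing data that is not
  redistributable; they are covered structurally (a 25 → 24 validation
  fixture and the property suites), not numerically.
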
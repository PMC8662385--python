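# Methods

## The analysis in one paragraph

Two sample groups of bulk RNA-seq quantifications — tissue (group A) and
whole body (group B) — are compared per gene on TPM. The tissue-enriched
set is then translated into the space of single-copy orthogroups shared
with a second species, where it is intersected with an independently
defined target gene set of that species. The size of the intersection is
tested against a sampling-without-replacement null, estimated by Monte
Carlo and verified against the exact hypergeometric law. Separately, the
reference transcriptome is screened for contamination by the alien
index computed from labelled BLAST best hits.

## Expression model and filters

**TPM.** For counts c_g and effective lengths L_g,
TPM_g = 10⁶·(c_g/L_g)/Σ_h(c_h/L_h); each sample column sums to 10⁶
(asserted to ±10⁻³). A sample with zero total abundance is a hard error.
Input may also be a precomputed TPM matrix (the `value_kind` flag), since
length information is not always recoverable for collapsed
supertranscripts.

**Abundance floor.** A gene is removed when its TPM summed across *all*
samples is strictly below `min_cumulative_tpm` (default 0.1); the
boundary value is retained. The floor is applied before the differential
test and both gene counts are recorded in the run funnel.

**Differential test.** Two-sided two-sample t-test on log₂(TPM + 1),
vectorised across genes. The default is the pooled-variance Student
form. Rationale: at the equal, tiny group sizes this design uses
(3 vs 3), the Welch and Student statistics are algebraically identical
and differ only in degrees of freedom; the Welch–Satterthwaite
approximation is measurably conservative there (empirical size ≈ 0.034
at nominal 0.05 even on exactly normal data), while the pooled df = 4
keeps the type-I error at its nominal level — which the test-suite
calibration check enforces within 3 binomial standard deviations on
2,000 null genes. The Welch form remains available (`test="welch"`) for
unbalanced or variance-heterogeneous designs. Zero-variance genes are
handled with a variance floor of 10⁻⁸ on the log scale: identical groups
give t = 0, p = 1; zero variance with unequal means gives a huge |t| and
p ≈ 0, preserving the ordering of evidence.

**Fold-change.** (mean TPM_A + c)/(mean TPM_B + c) with pseudocount
c = 0.01 by default, stabilising ratios for genes absent in one group;
c = 0 reproduces the plain ratio of means.

**Selection.** Enriched = passed abundance AND p ≤ `max_p` AND
fold ≥ `min_fold`, all boundaries inclusive (defaults 0.05 and 5;
`min_fold=2` gives the broader differentially-expressed regime). No
multiple-testing correction by default — selection filters on raw p — but
`adjust="bh"` applies Benjamini–Hochberg for users who want FDR control.

## Orthology

`Orthogroups.tsv` dialect: header `Orthogroup<TAB>species…`, cells are
`", "`-joined gene lists, an empty cell means no genes. Gene IDs are
compared verbatim after trimming surrounding whitespace; a gene listed in
two orthogroups is a format error. The single-copy restriction keeps
orthogroups with exactly one gene per species; projection of a gene set
returns the orthogroups whose gene for that species is in the set, and
genes absent from the map are counted, not fatal — exactly the behaviour
implied by an enriched set shrinking when intersected with a single-copy
universe.

## Overlap significance

Null model: n of the N single-copy orthogroups drawn uniformly without
replacement; the overlap with the K marked orthogroups is recorded per
iteration. Estimators reported:

* raw:       p̂ = exceedances / B, exceedance = null overlap ≥ k_obs
  (≤ for the depletion option);
* corrected: p̂ = (exceedances + 1)/(B + 1) — the headline number. It is
  never exactly zero; with zero exceedances it reports the resolution of
  the simulation (≈ 10⁻⁴ at B = 10,000) rather than an impossible p = 0.
* exact:     P(X ≥ k_obs) for X ~ Hypergeom(N, K, n), evaluated through
  the scipy survival function (stable deep in the tail), serving as the
  analytic oracle for the sampler.

Sampling is by random keys: each iteration assigns iid uniform keys to
the N items and takes the n smallest (argpartition), an exactly uniform
n-subset; iterations are vectorised in chunks of 256×N floats, so
B = 10,000 at N ≈ 8,700 takes about a second on one CPU. The seed is
recorded in every report; identical seed, identical result.

The test suite checks the sampler against the exact tail on a grid of
small parameter sets (4 binomial standard errors at B = 50,000), against
exhaustive subset enumeration at N = 10, and for calibration: when k_obs
is itself drawn from the null, the corrected p-value is uniform
(Kolmogorov–Smirnov over 500 replicates at N = 8,000, K = 2,000,
n = 1,600, B = 400 — sizes chosen so the null overlap distribution is
fine-grained enough for a meaningful KS comparison at level 0.01).

## Alien-index screen

AI = ln(best ingroup E + f) − ln(best outgroup E + f), natural logs,
floor f = 10⁻²⁰⁰ keeping AI finite at reported e-values of 0; a missing
group gets the no-hit sentinel E = 1, so ingroup-only transcripts score
strongly negative. A transcript is flagged when AI strictly exceeds the
cutoff (default 40); `outgroup_best` marks a best overall hit from the
outgroup, with ties counted as ingroup. Both fractions are reported over
all screened queries, including queries with no hits at all, which are
never flagged. The cutoff and the natural-log formulation follow the
convention of the alien-index tool family; both are configurable, and
the screen only reports — it never removes transcripts.

## Synthetic data generator

What it emulates: two species joined by an orthogroup table
(single-copy, multi-copy with 2–4 genes on one side, and
species-specific groups); negative-binomial replicate counts for species
A (variance μ + αμ²), baseline means log-uniform over 1–1,000; gene
lengths log-uniform 300–10,000 bases so TPM is not proportional to
counts; a planted enriched set whose group-A means are multiplied by
`planted_fold`; a planted target set in species B realising an exact
orthogroup overlap with the enriched projection; zero-count genes to
feed the abundance filter; and a synthetic BLAST report with a planted
contaminant fraction whose e-value ranges guarantee contaminants are
outgroup-best with AI > 40 and ordinary transcripts are neither.

Defaults (the desk-scale study conditions): 1,000 single-copy + 120
multi-copy + 2×100 species-specific orthogroups; 3 replicates per group;
dispersion α = 0.05; 60 enriched genes (all single-copy) at fold 10;
50 target genes; overlap 20; 50 zero-expression genes; 5% contaminants.

Planted enriched genes draw their baseline means from a narrower,
well-expressed range (log-uniform 50–200). Two reasons: tissue markers
should be detectable in both groups, and TPM renormalisation couples the
planted fold to the planted genes' library share — the realised TPM
fold-change is planted_fold/λ with λ = 1 + share·(planted_fold − 1), so
planting large folds on high-mean genes would drag the realised
fold-change toward the selection threshold. With the default
composition the realised fold is ≈ 7–8 for a planted 10.

What it does **not** emulate: read-level noise and mapping ambiguity,
splice isoforms, batch effects, GC/length biases beyond the length term,
correlated genes, or orthology-inference errors. Passing the recovery
tests therefore demonstrates correctness of the pipeline's arithmetic
and bookkeeping under a known generative model — not robustness to the
full messiness of real RNA-seq.

Determinism: one seed drives everything; identical configuration and
seed give byte-identical output files (asserted by checksum in the
suite).

## Pipeline orchestration

Stages run in a fixed order (TPM → abundance → test → select →
single-copy → project → overlap, plus the optional contamination
screen); a failure aborts with the stage name and the report is written
with `"status": "failed"`. Every report records thresholds, seed,
package version and the cardinality funnel
input ≥ abundance-passed ≥ enriched ≥ projected ≥ k_obs, making reruns
auditable. Default thresholds are min_fold 5, max_p 0.05,
min_cumulative_tpm 0.1, AI cutoff 40, B = 10,000. Exit codes: 0 success,
2 input error, 3 infeasible synthetic configuration.

## Numerical choices and edge cases

* Boundary inclusivity: p ≤ max_p and fold ≥ min_fold inclusive;
  cumulative-TPM removal strict (<).
* Hypergeometric tail boundaries: k ≤ 0 → 1; k > min(K, n) → 0.
* Fold-change 0/0 (both means zero, no pseudocount) → 1.
* A group with a single sample contributes the variance floor (Student
  pooling still defined when the other group has ≥ 2 samples); 1 vs 1 is
  an error.
* The maximum null overlap is reported for completeness but is an
  extreme-order statistic with high seed-to-seed variance; it is not a
  quantity to reproduce.

## Known limitations

The differential test is a deliberate stand-in for heavier
RNA-seq-specific machinery (no information sharing across genes, no
count-model likelihood); with 3 replicates per group its power is
limited and the enrichment filters do the heavy lifting, which mirrors
the analysis this package operationalises. Orthology is consumed, not
inferred; only two species are supported. The alien-index formula
variant (natural-log, cutoff 40) is a documented convention, not a claim
of bit-compatibility with any particular screening tool.
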
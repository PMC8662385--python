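# orthoverlap

Cross-species tissue-enrichment analysis for non-model organisms.

A recurring question in comparative transcriptomics: genes enriched in a
tissue of species A (say, the sensory auricles of a planarian) — do they
overlap, more than chance allows, with a gene set defined independently in
species B (say, genes whose expression depends on a transcription factor
knocked down by RNAi)? The two species have different gene catalogues, so
the comparison must pass through orthology, and the overlap needs a
significance test.

`orthoverlap` implements that analysis as a reusable pipeline:

1. **Expression filtering** — convert replicate count matrices to TPM
   (TPM_g = 10⁶·(c_g/L_g)/Σ_h c_h/L_h), drop genes below a cumulative-TPM
   floor, score tissue vs. body differential abundance with a two-sided
   t-test on log₂(TPM+1), and select the enriched set
   (cumulative TPM ≥ 0.1, p ≤ 0.05, fold-change ≥ 5 by default).
2. **Orthology** — parse an OrthoFinder-dialect `Orthogroups.tsv`,
   restrict to single-copy orthogroups (exactly one gene per species),
   and project gene sets of either species into that common universe.
3. **Overlap test** — with N single-copy orthogroups, K of them marked by
   the target set and n drawn by the enriched projection, test the
   observed overlap k against the sampling-without-replacement null:
   B Monte Carlo draws of n orthogroups, p̂ = (#{null ≥ k}+1)/(B+1),
   reported alongside the exact hypergeometric tail
   P(X ≥ k), X ~ Hypergeom(N, K, n).
4. **Contamination screen** — alien-index screening of the reference
   transcriptome from labelled BLAST best hits:
   AI = ln(best ingroup E) − ln(best outgroup E), flagging AI > 40.
5. **Synthetic data** — a two-species generator with negative-binomial
   counts, planted enrichment, an exactly realised planted overlap, and
   planted contaminants, so the whole pipeline is testable offline with
   known ground truth.

## Worked example

Generate a synthetic study (1,000 single-copy orthogroups, 60 planted
enriched genes, 50 target genes, planted overlap 20) and run the full
pipeline on it:

```sh
orthoverlap simulate --out-dir demo --seed 11
orthoverlap run --config demo/config.yaml
```

The pipeline prints its report (abridged):

```json
{
 "status": "complete",
 "funnel": {
  "input_genes": 1358,
  "abundance_passed": 1308,
  "enriched": 60,
  "enriched_projected": 60,
  "target_input": 50,
  "target_projected": 50,
  "k_obs": 20,
  "single_copy_universe": 1000
 },
 "overlap": {
  "k_obs": 20,
  "p_mc_raw": 0.0,
  "p_mc_corrected": 9.999000099990002e-05,
  "p_exact": 1.7437961355168514e-13,
  "max_null": 10
 },
 "contamination": {
  "frac_outgroup_best": 0.050073637702503684,
  "frac_flagged": 0.050073637702503684
 }
}
```

Reading the funnel: of 1,358 input genes, 1,308 survive the cumulative-TPM
floor, 60 pass all three enrichment filters (exactly the planted set), all
60 lie in single-copy orthogroups, and 20 of them share an orthogroup with
the 50-gene target set — the planted overlap, recovered exactly. None of
the 10,000 null draws reached an overlap of 20 (the exact tail is ~2e-13),
so the corrected Monte Carlo p is 1/10,001 ≈ 1e-4, the resolution of the
simulation. The contamination screen recovers the planted 5% contaminant
fraction (68 of 1,358 queries).

The overlap test is also available standalone, e.g. at a published
analysis scale (universe 8,682, target 88, enriched 430, observed 31):

```sh
orthoverlap overlap -N 8682 -K 88 -n 430 -k 31 -B 10000 --seed 1
```

which reports `exceedances: 0`, `max_null: 14`,
`p_mc_corrected: 9.999e-05` and `p_exact: 4.95e-19` — an overlap of 31 is
unreachable under the null.

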
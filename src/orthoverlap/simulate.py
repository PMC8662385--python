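"""Synthetic two-species datasets with known ground truth.

The generator emulates the structure of a cross-species tissue-
enrichment study without any sequencing: two species related by an
orthogroup table containing single-copy, multi-copy and species-specific
groups; negative-binomial replicate counts for species A in two sample
groups (tissue vs. body); a planted tissue-enriched gene set whose
group-A means are multiplied by a configurable fold; a planted target
gene set in species B whose single-copy orthogroups overlap the enriched
set's orthogroups by an exact configured count; and a synthetic BLAST
best-hit report with a planted contaminant fraction for the alien-index
screen.

Counts for gene g, sample s are negative binomial with mean mu_g (times
the planted fold in group-A samples of enriched genes) and dispersion
alpha (variance mu + alpha*mu^2). Baseline means are log-uniform so the
matrix spans the dynamic range of RNA-seq; gene lengths are log-uniform
300–10,000 bases so TPM is not proportional to counts and the length
correction is actually exercised. Planted enriched genes draw their
baseline means from a narrower, well-expressed range — tissue markers
detectable in both groups — which also keeps the planted fold-change,
after library renormalisation, well separated from the selection
threshold.

Everything derives from one seed; the same configuration and seed
produce byte-identical output files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InfeasibleConfigError
from .expression import ExpressionStudy
from .orthology import OrthogroupTable, write_orthogroups

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticBundle",
    "generate",
    "end_to_end_recovery",
    "RecoveryReport",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth composition and noise model of a synthetic study."""

    # orthogroup composition
    n_single_copy: int = 1000
    n_multi_copy: int = 120
    n_species_specific_a: int = 100
    n_species_specific_b: int = 100
    # expression model
    replicates: int = 3  #: samples per group (tissue and body)
    nb_mean_log10_range: tuple[float, float] = (0.0, 3.0)  #: baseline mean counts
    nb_dispersion: float = 0.05  #: NB dispersion alpha; var = mu + alpha mu^2
    length_range: tuple[int, int] = (300, 10_000)  #: gene length, log-uniform, bases
    # planted signal
    planted_enriched_size: int = 60  #: tissue-enriched genes in species A
    planted_enriched_single_copy: int | None = None  #: how many are single-copy (default: all)
    planted_mean_log10_range: tuple[float, float] = (math.log10(50), math.log10(200))
    planted_fold: float = 10.0  #: multiplier on group-A means of enriched genes
    planted_target_size: int = 50  #: target genes in species B (single-copy)
    planted_overlap: int = 20  #: orthogroups shared by enriched projection and target
    planted_zero_size: int = 50  #: genes with zero counts everywhere (abundance-filter fodder)
    # contamination screen
    contaminant_fraction: float = 0.05
    # bookkeeping
    species_a: str = "speciesA"
    species_b: str = "speciesB"
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_single_copy",
            "n_multi_copy",
            "n_species_specific_a",
            "n_species_specific_b",
            "planted_enriched_size",
            "planted_target_size",
            "planted_overlap",
            "planted_zero_size",
        ):
            if getattr(self, name) < 0:
                raise InfeasibleConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.replicates < 1:
            raise InfeasibleConfigError(f"replicates must be >= 1, got {self.replicates}")
        if self.planted_fold < 1:
            raise InfeasibleConfigError(f"planted_fold must be >= 1, got {self.planted_fold}")
        if self.nb_dispersion <= 0:
            raise InfeasibleConfigError(f"nb_dispersion must be > 0, got {self.nb_dispersion}")
        if not 0 <= self.contaminant_fraction <= 1:
            raise InfeasibleConfigError(
                f"contaminant_fraction must be in [0, 1], got {self.contaminant_fraction}"
            )
        n_sc_enriched = self.n_enriched_single_copy
        if n_sc_enriched > self.planted_enriched_size:
            raise InfeasibleConfigError(
                "planted_enriched_single_copy exceeds planted_enriched_size"
            )
        if n_sc_enriched > self.n_single_copy:
            raise InfeasibleConfigError(
                f"cannot place {n_sc_enriched} single-copy enriched genes in "
                f"{self.n_single_copy} single-copy orthogroups"
            )
        if self.planted_target_size > self.n_single_copy:
            raise InfeasibleConfigError(
                f"planted_target_size {self.planted_target_size} exceeds "
                f"{self.n_single_copy} single-copy orthogroups"
            )
        if self.planted_overlap > min(n_sc_enriched, self.planted_target_size):
            raise InfeasibleConfigError(
                f"planted_overlap {self.planted_overlap} exceeds "
                f"min(single-copy enriched = {n_sc_enriched}, "
                f"target = {self.planted_target_size})"
            )
        if self.planted_target_size - self.planted_overlap > self.n_single_copy - n_sc_enriched:
            raise InfeasibleConfigError(
                "not enough enriched-free single-copy orthogroups for the "
                "non-overlapping part of the target set"
            )

    @property
    def n_enriched_single_copy(self) -> int:
        if self.planted_enriched_single_copy is None:
            return min(self.planted_enriched_size, self.n_single_copy)
        return self.planted_enriched_single_copy


@dataclass
class SyntheticTruth:
    """Exact planted composition of one generated dataset."""

    enriched_genes_a: list[str]
    enriched_single_copy_genes_a: list[str]
    target_genes_b: list[str]
    overlap_orthogroups: list[str]
    single_copy_orthogroups: list[str]
    zero_genes_a: list[str]
    contaminant_queries: list[str]
    n_genes_a: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class SyntheticBundle:
    """Generated inputs plus their ground truth."""

    config: SyntheticConfig
    study: ExpressionStudy  #: counts, with lengths and sample groups
    orthogroups: OrthogroupTable
    target_genes: list[str]
    blast_hits: pd.DataFrame  #: labelled outfmt-6 columns + subject_group
    subject_groups: dict[str, str]
    truth: SyntheticTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every pipeline input format plus truth.json and a
        ready-to-run pipeline config; deterministic byte-for-byte."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {k: outdir / v for k, v in {
            "counts": "counts.tsv",
            "lengths": "lengths.tsv",
            "orthogroups": "orthogroups.tsv",
            "target_set": "target_genes.txt",
            "blast": "blast_hits.tsv",
            "blast_groups": "subject_groups.tsv",
            "truth": "truth.json",
            "config": "config.yaml",
        }.items()}
        counts = self.study.values.astype(int)
        counts.index.name = "gene_id"
        counts.to_csv(paths["counts"], sep="\t")
        lengths = self.study.lengths.astype(int)
        lengths.index.name = "gene_id"
        lengths.rename("length").to_csv(paths["lengths"], sep="\t")
        write_orthogroups(self.orthogroups, paths["orthogroups"])
        paths["target_set"].write_text("".join(g + "\n" for g in self.target_genes))
        cols = [c for c in self.blast_hits.columns if c != "subject_group"]
        self.blast_hits[cols].to_csv(
            paths["blast"], sep="\t", header=False, index=False, float_format="%.6g"
        )
        paths["blast_groups"].write_text(
            "".join(f"{s}\t{g}\n" for s, g in sorted(self.subject_groups.items()))
        )
        paths["truth"].write_text(self.truth.to_json() + "\n")
        paths["config"].write_text(self._pipeline_yaml())
        return paths

    def _pipeline_yaml(self) -> str:
        groups = "\n".join(
            f"  {s}: {g}" for s, g in self.study.sample_groups.items()
        )
        return (
            "inputs:\n"
            "  counts: counts.tsv\n"
            "  lengths: lengths.tsv\n"
            "  orthogroups: orthogroups.tsv\n"
            "  target_set: target_genes.txt\n"
            "  blast: blast_hits.tsv\n"
            "  blast_groups: subject_groups.tsv\n"
            f"sample_groups:\n{groups}\n"
            "thresholds:\n"
            "  min_fold: 5.0\n"
            "  max_p: 0.05\n"
            "  min_cumulative_tpm: 0.1\n"
            "  ai_cutoff: 40.0\n"
            "iterations: 10000\n"
            f"seed: {self.config.seed}\n"
            "output_dir: out\n"
        )


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with mean `mean` and var mean + a*mean^2.

    Zero means produce exact zeros.
    """
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate(config: SyntheticConfig) -> SyntheticBundle:
    """Build one synthetic dataset realising the configuration exactly."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    sp_a, sp_b = config.species_a, config.species_b

    # --- orthogroup table -------------------------------------------------
    membership: dict[str, dict[str, tuple[str, ...]]] = {}
    og_counter = 0

    def next_og() -> str:
        nonlocal og_counter
        og_counter += 1
        return f"OG{og_counter:07d}"

    sc_ogs: list[str] = []
    sc_gene_a: dict[str, str] = {}
    sc_gene_b: dict[str, str] = {}
    for i in range(config.n_single_copy):
        og = next_og()
        ga, gb = f"gA{i + 1:05d}", f"gB{i + 1:05d}"
        membership[og] = {sp_a: (ga,), sp_b: (gb,)}
        sc_ogs.append(og)
        sc_gene_a[og], sc_gene_b[og] = ga, gb
    multi_genes_a: list[str] = []
    for j in range(config.n_multi_copy):
        og = next_og()
        k = int(rng.integers(2, 5))  # 2..4 copies in the expanded species
        if rng.random() < 0.5:
            ga = tuple(f"gA_m{j + 1:04d}_{c}" for c in range(k))
            gb = (f"gB_m{j + 1:04d}_0",)
        else:
            ga = (f"gA_m{j + 1:04d}_0",)
            gb = tuple(f"gB_m{j + 1:04d}_{c}" for c in range(k))
        membership[og] = {sp_a: ga, sp_b: gb}
        multi_genes_a.extend(ga)
    specific_genes_a = [f"gA_s{j + 1:04d}" for j in range(config.n_species_specific_a)]
    for g in specific_genes_a:
        membership[next_og()] = {sp_a: (g,), sp_b: ()}
    for j in range(config.n_species_specific_b):
        membership[next_og()] = {sp_a: (), sp_b: (f"gB_s{j + 1:04d}",)}
    table = OrthogroupTable(species_labels=(sp_a, sp_b), membership=membership)

    # --- planted sets -----------------------------------------------------
    n_sc_enr = config.n_enriched_single_copy
    enr_ogs = list(rng.choice(sc_ogs, size=n_sc_enr, replace=False))
    enr_sc_genes = [sc_gene_a[og] for og in enr_ogs]
    non_sc_pool = multi_genes_a + specific_genes_a
    n_extra = config.planted_enriched_size - n_sc_enr
    if n_extra > len(non_sc_pool):
        raise InfeasibleConfigError(
            f"cannot place {n_extra} non-single-copy enriched genes in a pool of {len(non_sc_pool)}"
        )
    extra = list(rng.choice(non_sc_pool, size=n_extra, replace=False)) if n_extra else []
    enriched = enr_sc_genes + extra

    overlap_ogs = list(rng.choice(enr_ogs, size=config.planted_overlap, replace=False))
    free_ogs = [og for og in sc_ogs if og not in set(enr_ogs)]
    n_rest = config.planted_target_size - config.planted_overlap
    rest_ogs = list(rng.choice(free_ogs, size=n_rest, replace=False)) if n_rest else []
    target_ogs = overlap_ogs + rest_ogs
    target_genes = [sc_gene_b[og] for og in target_ogs]

    # --- count matrix for species A --------------------------------------
    genes_a = [sc_gene_a[og] for og in sc_ogs] + multi_genes_a + specific_genes_a
    n_genes = len(genes_a)
    gene_pos = {g: i for i, g in enumerate(genes_a)}
    lo, hi = config.nb_mean_log10_range
    mu = 10.0 ** rng.uniform(lo, hi, size=n_genes)
    plo, phi = config.planted_mean_log10_range
    enr_idx = np.array([gene_pos[g] for g in enriched], dtype=int)
    if enr_idx.size:
        mu[enr_idx] = 10.0 ** rng.uniform(plo, phi, size=enr_idx.size)
    non_enriched = [g for g in genes_a if g not in set(enriched)]
    if config.planted_zero_size > len(non_enriched):
        raise InfeasibleConfigError(
            f"planted_zero_size {config.planted_zero_size} exceeds the "
            f"{len(non_enriched)} non-enriched genes"
        )
    zero_genes = list(
        rng.choice(non_enriched, size=config.planted_zero_size, replace=False)
    )
    zero_idx = np.array([gene_pos[g] for g in zero_genes], dtype=int)
    if zero_idx.size:
        mu[zero_idx] = 0.0

    reps = config.replicates
    samples = [f"A{r + 1}" for r in range(reps)] + [f"B{r + 1}" for r in range(reps)]
    groups = {s: s[0] for s in samples}
    mean_matrix = np.tile(mu[:, None], (1, 2 * reps))
    if enr_idx.size:
        mean_matrix[enr_idx[:, None], np.arange(reps)[None, :]] *= config.planted_fold
    counts = _nb_counts(rng, mean_matrix, config.nb_dispersion)
    llo, lhi = config.length_range
    lengths = np.round(
        10.0 ** rng.uniform(math.log10(llo), math.log10(lhi), size=n_genes)
    ).astype(int)
    study = ExpressionStudy(
        values=pd.DataFrame(counts, index=pd.Index(genes_a, name="gene_id"), columns=samples),
        sample_groups=groups,
        lengths=pd.Series(lengths, index=pd.Index(genes_a, name="gene_id")),
        value_kind="counts",
    )

    # --- synthetic BLAST screen ------------------------------------------
    blast, subject_groups, contaminants = _make_blast(rng, genes_a, config)

    truth = SyntheticTruth(
        enriched_genes_a=sorted(enriched),
        enriched_single_copy_genes_a=sorted(enr_sc_genes),
        target_genes_b=sorted(target_genes),
        overlap_orthogroups=sorted(overlap_ogs),
        single_copy_orthogroups=sorted(sc_ogs),
        zero_genes_a=sorted(zero_genes),
        contaminant_queries=sorted(contaminants),
        n_genes_a=n_genes,
    )
    return SyntheticBundle(
        config=config,
        study=study,
        orthogroups=table,
        target_genes=target_genes,
        blast_hits=blast,
        subject_groups=subject_groups,
        truth=truth,
    )


def _make_blast(
    rng: np.random.Generator, queries: list[str], config: SyntheticConfig
) -> tuple[pd.DataFrame, dict[str, str], list[str]]:
    """Synthetic best-hit e-values with a planted contaminant fraction.

    Ordinary transcripts get a strong ingroup best hit (1e-180..1e-20)
    and a weak outgroup one (1e-10..1); contaminants the reverse
    (ingroup 1e-2..1, outgroup 1e-180..1e-40), so they are outgroup-best
    with alien index > 40 by construction. Each query gets two hits per
    group so per-group minima are non-trivial.
    """
    n = len(queries)
    n_cont = round(config.contaminant_fraction * n)
    contaminants = set(rng.choice(queries, size=n_cont, replace=False)) if n_cont else set()
    rows = []
    subject_groups: dict[str, str] = {}
    for qi, q in enumerate(queries):
        cont = q in contaminants
        if cont:
            best_in = 10.0 ** rng.uniform(-2, 0)
            best_out = 10.0 ** rng.uniform(-180, -40)
        else:
            best_in = 10.0 ** rng.uniform(-180, -20)
            best_out = 10.0 ** rng.uniform(-10, 0)
        for grp, best in (("ingroup", best_in), ("outgroup", best_out)):
            worse = min(best * 10.0 ** rng.uniform(1, 6), 10.0)
            for h, ev in enumerate((best, worse)):
                sid = f"{'plat' if grp == 'ingroup' else 'out'}{qi + 1:05d}_{h}"
                subject_groups[sid] = grp
                aln = int(rng.integers(60, 400))
                rows.append(
                    (
                        q,
                        sid,
                        round(float(rng.uniform(35, 99)), 1),
                        aln,
                        int(rng.integers(0, 40)),
                        int(rng.integers(0, 5)),
                        1,
                        aln,
                        1,
                        aln,
                        ev,
                        round(max(25.0, -4.0 * math.log10(ev + 1e-180) + 30.0), 1),
                    )
                )
    from .contamination import BLAST_OUTFMT6_COLUMNS

    df = pd.DataFrame(rows, columns=list(BLAST_OUTFMT6_COLUMNS))
    df["subject_group"] = df["sseqid"].map(subject_groups)
    return df, subject_groups, sorted(contaminants)


@dataclass
class RecoveryReport:
    """Pipeline output compared against planted truth."""

    n_enriched_true: int
    n_enriched_recovered: int
    n_true_positive: int
    n_false_positive: int
    planted_overlap: int
    k_obs: int
    p_mc_corrected: float
    p_exact: float

    @property
    def exact_recovery(self) -> bool:
        return (
            self.n_false_positive == 0
            and self.n_true_positive == self.n_enriched_true
            and self.k_obs == self.planted_overlap
        )


def end_to_end_recovery(
    config: SyntheticConfig, iterations: int = 10_000, seed: int | None = None
) -> RecoveryReport:
    """Generate a dataset, run the full analysis, compare with truth.

    ``seed`` controls the Monte Carlo null (defaults to the generator
    seed); the dataset itself always comes from ``config.seed``.
    """
    from .pipeline import Thresholds, run_analysis

    bundle = generate(config)
    res = run_analysis(
        study=bundle.study,
        orthogroups=bundle.orthogroups,
        target_genes=bundle.target_genes,
        thresholds=Thresholds(),
        iterations=iterations,
        seed=config.seed if seed is None else seed,
    )
    truth_set = set(bundle.truth.enriched_genes_a)
    got = set(res.enriched.ids)
    return RecoveryReport(
        n_enriched_true=len(truth_set),
        n_enriched_recovered=len(got),
        n_true_positive=len(got & truth_set),
        n_false_positive=len(got - truth_set),
        planted_overlap=config.planted_overlap,
        k_obs=res.overlap.k_obs,
        p_mc_corrected=res.overlap.p_mc_corrected,
        p_exact=res.overlap.p_exact,
    )
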
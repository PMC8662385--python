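"""End-to-end pipeline: expression filtering -> ortholog projection ->
overlap significance (+ optional contamination screen).

Stages, in order, with the funnel of cardinalities each one logs:

1. ``compute_tpm``       counts -> TPM (skipped when input is TPM)
2. ``abundance_filter``  genes with cumulative TPM >= floor
3. ``differential_test`` per-gene fold-change and Welch p-value
4. ``select_enriched``   tissue-enriched gene set (species A)
5. ``single_copy``       single-copy orthogroup universe
6. ``project``           enriched genes and target genes -> orthogroups
7. ``monte_carlo_overlap``  significance of the observed intersection
8. ``alien-index screen``   optional, independent of 1-7

Every report records the thresholds, the seed and the stage funnel, so a
rerun with the same configuration reproduces every number exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, OrthoverlapError
from .expression import (
    ExpressionStudy,
    GeneSet,
    abundance_filter,
    compute_tpm,
    differential_test,
    select_enriched,
)
from .orthology import (
    OrthogroupTable,
    Projection,
    SingleCopyMap,
    parse_orthogroups,
    project,
    read_gene_list,
    single_copy,
)
from .overlap import OverlapTestResult, monte_carlo_overlap, overlap_report
from .contamination import (
    ContaminationSummary,
    contamination_summary,
    label_hits,
    read_blast_outfmt6,
    read_group_map,
    screen,
)

logger = logging.getLogger("orthoverlap")

__all__ = ["Thresholds", "PipelineConfig", "AnalysisResult", "run_analysis", "run_pipeline"]


@dataclass(frozen=True)
class Thresholds:
    """Selection thresholds; the defaults are the study's quoted values."""

    min_fold: float = 5.0
    max_p: float = 0.05
    min_cumulative_tpm: float = 0.1
    ai_cutoff: float = 40.0


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run."""

    orthogroups: Path
    target_set: Path
    sample_groups: dict[str, str]
    counts: Path | None = None
    tpm: Path | None = None
    lengths: Path | None = None
    blast: Path | None = None
    blast_groups: Path | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    iterations: int = 10_000
    seed: int = 0
    output_dir: Path = Path("out")
    species_a: str | None = None  #: default: first column of the orthogroup table
    species_b: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a YAML config; relative paths resolve against its directory."""
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        base = path.parent
        inputs = raw.get("inputs", {})

        def p(key: str) -> Path | None:
            v = inputs.get(key)
            return (base / v) if v is not None else None

        for req in ("orthogroups", "target_set"):
            if p(req) is None:
                raise ConfigurationError(f"{path}: inputs.{req} is required")
        if p("counts") is None and p("tpm") is None:
            raise ConfigurationError(f"{path}: one of inputs.counts or inputs.tpm is required")
        groups = raw.get("sample_groups")
        if not isinstance(groups, dict) or not groups:
            raise ConfigurationError(f"{path}: sample_groups mapping is required")
        thr = Thresholds(**raw.get("thresholds", {}))
        species = raw.get("species", {}) or {}
        return cls(
            orthogroups=p("orthogroups"),
            target_set=p("target_set"),
            sample_groups={str(k): str(v) for k, v in groups.items()},
            counts=p("counts"),
            tpm=p("tpm"),
            lengths=p("lengths"),
            blast=p("blast"),
            blast_groups=p("blast_groups"),
            thresholds=thr,
            iterations=int(raw.get("iterations", 10_000)),
            seed=int(raw.get("seed", 0)),
            output_dir=base / raw.get("output_dir", "out"),
            species_a=species.get("A"),
            species_b=species.get("B"),
        )


@dataclass
class AnalysisResult:
    """In-memory outputs of the core analysis (stages 1-7)."""

    de_table: pd.DataFrame
    enriched: GeneSet
    sc_map: SingleCopyMap
    enriched_projection: Projection
    target_projection: Projection
    overlap: OverlapTestResult
    overlap_gene_pairs: list[tuple[str, str, str]]
    contamination: ContaminationSummary | None
    contamination_records: pd.DataFrame | None
    funnel: dict[str, int]


def _stage(name: str):
    """Re-raise stage failures with the stage name prepended."""

    class _Ctx:
        def __enter__(self):
            logger.debug("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, OrthoverlapError):
                exc.args = (f"[stage {name}] {exc.args[0] if exc.args else ''}",)
            return False

    return _Ctx()


def run_analysis(
    study: ExpressionStudy,
    orthogroups: OrthogroupTable,
    target_genes: list[str],
    thresholds: Thresholds = Thresholds(),
    iterations: int = 10_000,
    seed: int = 0,
    species_a: str | None = None,
    species_b: str | None = None,
    blast_hits: pd.DataFrame | None = None,
) -> AnalysisResult:
    """Run the analysis on in-memory inputs.

    ``target_genes`` are species-B gene IDs (the independently defined
    gene set); ``blast_hits`` is an optional labelled hit table for the
    contamination screen.
    """
    sp_a = species_a or orthogroups.species_labels[0]
    sp_b = species_b or orthogroups.species_labels[1]

    with _stage("compute_tpm"):
        study_tpm = compute_tpm(study) if study.value_kind == "counts" else study
    with _stage("abundance_filter"):
        abundant = abundance_filter(study_tpm, thresholds.min_cumulative_tpm)
    with _stage("differential_test"):
        de = differential_test(study_tpm, min_cumulative_tpm=thresholds.min_cumulative_tpm)
    with _stage("select_enriched"):
        enriched = select_enriched(
            de, thresholds.min_fold, thresholds.max_p, species_label=sp_a
        )
    with _stage("single_copy"):
        sc_map = single_copy(orthogroups)
    with _stage("project"):
        proj_enr = project(enriched, sc_map, sp_a)
        proj_tgt = project(target_genes, sc_map, sp_b)
    overlap_ogs = sorted(proj_enr.orthogroups & proj_tgt.orthogroups)
    with _stage("monte_carlo_overlap"):
        result = monte_carlo_overlap(
            N=len(sc_map),
            K=len(proj_tgt.orthogroups),
            n=len(proj_enr.orthogroups),
            k_obs=len(overlap_ogs),
            B=iterations,
            seed=seed,
        )
    pairs = [
        (og, sc_map.pairs[og][sc_map.species_labels.index(sp_a)],
         sc_map.pairs[og][sc_map.species_labels.index(sp_b)])
        for og in overlap_ogs
    ]
    summary = records = None
    if blast_hits is not None:
        with _stage("contamination_screen"):
            records = screen(blast_hits, cutoff=thresholds.ai_cutoff)
            summary = contamination_summary(records, cutoff=thresholds.ai_cutoff)

    funnel = {
        "input_genes": len(study.gene_ids),
        "abundance_passed": len(abundant),
        "enriched": len(enriched),
        "enriched_projected": len(proj_enr.orthogroups),
        "target_input": len(set(target_genes)),
        "target_projected": len(proj_tgt.orthogroups),
        "k_obs": result.k_obs,
        "single_copy_universe": len(sc_map),
    }
    for name, count in funnel.items():
        logger.info("funnel %s=%d", name, count)
    return AnalysisResult(
        de_table=de,
        enriched=enriched,
        sc_map=sc_map,
        enriched_projection=proj_enr,
        target_projection=proj_tgt,
        overlap=result,
        overlap_gene_pairs=pairs,
        contamination=summary,
        contamination_records=records,
        funnel=funnel,
    )


def _load_study(config: PipelineConfig) -> ExpressionStudy:
    if config.counts is not None:
        values = pd.read_csv(config.counts, sep="\t", index_col=0)
        lengths = None
        if config.lengths is not None:
            lengths = pd.read_csv(config.lengths, sep="\t", index_col=0).iloc[:, 0]
        return ExpressionStudy(
            values=values, sample_groups=config.sample_groups, lengths=lengths,
            value_kind="counts",
        )
    values = pd.read_csv(config.tpm, sep="\t", index_col=0)
    return ExpressionStudy(
        values=values, sample_groups=config.sample_groups, value_kind="tpm"
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline from files and write all reports.

    Writes to ``config.output_dir``: ``de_table.tsv``, the enriched gene
    list with a JSON sidecar, the projected orthogroup list, the overlap
    report, optional contamination outputs, and ``pipeline_report.json``
    with the funnel, thresholds, seed and package version. Returns the
    pipeline report as a dict. On a stage failure the report is still
    written, marked ``"status": "failed"`` with the stage name.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "status": "incomplete",
        "version": __version__,
        "seed": config.seed,
        "iterations": config.iterations,
        "thresholds": asdict(config.thresholds),
    }
    try:
        with _stage("load_inputs"):
            study = _load_study(config)
            table = parse_orthogroups(config.orthogroups)
            target_genes = read_gene_list(config.target_set)
            blast = None
            if config.blast is not None:
                if config.blast_groups is None:
                    raise ConfigurationError("inputs.blast requires inputs.blast_groups")
                blast = label_hits(
                    read_blast_outfmt6(config.blast), read_group_map(config.blast_groups)
                )
        res = run_analysis(
            study,
            table,
            target_genes,
            thresholds=config.thresholds,
            iterations=config.iterations,
            seed=config.seed,
            species_a=config.species_a,
            species_b=config.species_b,
            blast_hits=blast,
        )
    except OrthoverlapError as exc:
        report["status"] = "failed"
        report["error"] = str(exc)
        (outdir / "pipeline_report.json").write_text(json.dumps(report, indent=1) + "\n")
        raise

    res.de_table.rename_axis("gene_id").to_csv(outdir / "de_table.tsv", sep="\t")
    enriched_ids = sorted(res.enriched.ids)
    (outdir / "enriched_genes.txt").write_text("".join(g + "\n" for g in enriched_ids))
    (outdir / "enriched_genes.json").write_text(
        json.dumps(
            {
                "species": res.enriched.species_label,
                "n": len(enriched_ids),
                "thresholds": res.enriched.thresholds,
                "provenance": res.enriched.provenance,
            },
            indent=1,
        )
        + "\n"
    )
    (outdir / "enriched_orthogroups.txt").write_text(
        "".join(og + "\n" for og in sorted(res.enriched_projection.orthogroups))
    )
    ov_report = overlap_report(
        res.overlap,
        labels={
            "universe": "single-copy orthogroups",
            "target": str(config.target_set),
            "enriched": res.enriched.provenance,
        },
        gene_pairs=res.overlap_gene_pairs,
    )
    (outdir / "overlap_report.json").write_text(json.dumps(ov_report, indent=1) + "\n")
    if res.contamination is not None:
        res.contamination_records.rename_axis("qseqid").to_csv(
            outdir / "alien_index.tsv", sep="\t"
        )
        (outdir / "contamination.json").write_text(
            json.dumps(
                {
                    **asdict(res.contamination),
                    "frac_outgroup_best": res.contamination.frac_outgroup_best,
                    "frac_flagged": res.contamination.frac_flagged,
                },
                indent=1,
            )
            + "\n"
        )
        report["contamination"] = {
            "frac_outgroup_best": res.contamination.frac_outgroup_best,
            "frac_flagged": res.contamination.frac_flagged,
        }
    report["status"] = "complete"
    report["funnel"] = res.funnel
    report["overlap"] = {
        "k_obs": res.overlap.k_obs,
        "p_mc_raw": res.overlap.p_mc_raw,
        "p_mc_corrected": res.overlap.p_mc_corrected,
        "p_exact": res.overlap.p_exact,
        "max_null": res.overlap.max_null,
    }
    (outdir / "pipeline_report.json").write_text(json.dumps(report, indent=1) + "\n")
    return report
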
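"""End-to-end orchestration: simulate → conserve → lose → classify → survey.

:func:`run_all` executes every analysis stage on one configured input set —
either files on disk or the synthetic generators — and writes all result
tables, a key-value summary and a run manifest into a run directory.
Identical configuration and seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import io as olio
from .errors import OrtholossError, StageError, ValidationError
from .expression import (
    enrich,
    load_expression,
    load_ortholog_map,
    load_tissue_classes,
    pet_matrix,
    principal_genes,
    tabulate_lost_pets,
)
from .family_matrix import (
    call_losses,
    conserved_orthogroups,
    f_summary,
    load_gene_counts,
    partition_losses,
)
from .kmer import load_histogram, survey
from .pseudogene import read_fasta_pairs, scan_pairs
from .simulate import (
    DEFAULT_PANEL,
    DEFAULT_REFERENCE,
    DEFAULT_TARGETS,
    simulate_cds_pairs,
    simulate_expression,
    simulate_family_matrix,
    simulate_kmer_histogram,
    write_cds_fastas,
)

__all__ = ["RunConfig", "run_all", "STAGES"]

logger = logging.getLogger("ortholoss")

STAGES = (
    "simulate",
    "conserved",
    "losses",
    "partition",
    "findex",
    "pet",
    "peg",
    "tabulate",
    "enrich",
    "pseudo",
    "kmer-survey",
    "report",
)

_DEFAULT_TISSUE_CLASSES = {
    "leaf": "leaves",
    "root": "roots",
    "flower": "flowers",
    "stem": "other",
    "seed": "other",
    "fruit": "other",
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Defaults reproduce the printed study rules: a reference autotroph, a
    six-species autotroph panel with presence required in at least five, two
    heterotrophic targets, and a PET/PEG fold threshold of 2.
    """

    seed: int = 0
    simulate: bool = True

    # family matrix
    counts_path: str | None = None
    reference: str = DEFAULT_REFERENCE
    panel: tuple[str, ...] = DEFAULT_PANEL
    targets: tuple[str, ...] = DEFAULT_TARGETS
    min_present: int = 5
    n_orthogroups: int = 2000

    # expression
    proxy_expression_path: str | None = None
    parasite_expression_path: str | None = None
    ortholog_map_path: str | None = None
    tissue_class_path: str | None = None
    annotation_path: str | None = None
    fold_threshold: float = 2.0
    focal_tissues: tuple[str, ...] = ("prehaustorium", "haustorium")
    n_genes: int = 500

    # pseudogene scan
    reference_fasta: str | None = None
    candidate_fasta: str | None = None
    n_cds_pairs: int = 60
    cds_length_codons: int = 80
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0

    # k-mer survey
    histogram_path: str | None = None
    genome_size: int = 1_000_000
    coverage: float = 42.0
    kmer_repeat_fraction: float = 0.2
    repeat_copy: int = 2
    error_rate: float = 0.01
    kmer_k: int = 17
    repeat_multiplier: float = 1.5

    tissue_classes: dict = field(default_factory=lambda: dict(_DEFAULT_TISSUE_CLASSES))

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path, encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("panel", "targets", "focal_tissues"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        for key in ("panel", "targets", "focal_tissues"):
            data[key] = list(data[key])
        return data


def _require(condition: bool, stage: str, message: str) -> None:
    if not condition:
        raise StageError(stage, message)


def run_all(config: RunConfig, outdir: str | os.PathLike) -> Path:
    """Run every pipeline stage; returns the populated run directory.

    Stage failures raise :class:`~ortholoss.errors.StageError` carrying the
    stage name (the CLI maps it to a per-stage exit code).
    """
    out = Path(outdir)
    inputs = out / "inputs"
    results = out / "results"
    inputs.mkdir(parents=True, exist_ok=True)
    results.mkdir(parents=True, exist_ok=True)
    summary: dict[str, object] = {}
    provenance = {"ortholoss_version": __version__, "seed": config.seed}

    # -- simulate -----------------------------------------------------------
    stage = "simulate"
    try:
        if config.simulate:
            logger.info("[%s] generating synthetic inputs (seed %d)", stage, config.seed)
            matrix, family_truth = simulate_family_matrix(
                n_orthogroups=config.n_orthogroups,
                reference=config.reference,
                panel=config.panel,
                targets=config.targets,
                min_present=config.min_present,
                seed=config.seed,
            )
            matrix.to_tsv(inputs / "gene_counts.tsv")
            olio.write_family_truth(family_truth, inputs / "family_truth.tsv")

            proxy_expr, proxy_truth = simulate_expression(
                n_genes=config.n_orthogroups,
                tissues=tuple(config.tissue_classes),
                gene_prefix="p",
                seed=config.seed,
            )
            proxy_expr.to_tsv(inputs / "proxy_expression.tsv")
            olio.write_expression_truth(proxy_truth, inputs / "proxy_expression_truth.tsv")
            # one proxy gene per orthogroup, in matrix order
            ortholog_map = {
                og: [gene]
                for og, gene in zip(matrix.orthogroup_ids, proxy_expr.gene_ids)
            }
            with open(inputs / "ortholog_map.tsv", "w", encoding="utf-8") as handle:
                for og, genes in ortholog_map.items():
                    for gene in genes:
                        handle.write(f"{og}\t{gene}\n")

            parasite_tissues = tuple(config.focal_tissues) + ("stem", "flowerbud", "seedcapsule", "seedling")
            parasite_expr, parasite_truth = simulate_expression(
                n_genes=config.n_genes,
                tissues=parasite_tissues,
                gene_prefix="c",
                seed=config.seed + 1,
            )
            parasite_expr.to_tsv(inputs / "parasite_expression.tsv")
            olio.write_expression_truth(parasite_truth, inputs / "parasite_expression_truth.tsv")
            annotation = _simulate_annotation(parasite_truth, config)

            cds_pairs, cds_truth = simulate_cds_pairs(
                n_pairs=config.n_cds_pairs,
                cds_length_codons=config.cds_length_codons,
                seed=config.seed,
            )
            write_cds_fastas(cds_pairs, inputs / "references.fa", inputs / "candidates.fa")
            olio.write_cds_truth(cds_truth, inputs / "cds_truth.tsv")

            histogram, kmer_truth = simulate_kmer_histogram(
                genome_size=config.genome_size,
                coverage=config.coverage,
                repeat_fraction=config.kmer_repeat_fraction,
                repeat_copy=config.repeat_copy,
                error_rate=config.error_rate,
                k=config.kmer_k,
                seed=config.seed,
            )
            histogram.to_tsv(inputs / "kmer_histogram.txt")
            olio.write_key_values(kmer_truth.params, inputs / "kmer_truth.tsv")
            tissue_classes = dict(config.tissue_classes)
        else:
            logger.info("[%s] loading user inputs", stage)
            _require(config.counts_path is not None, stage, "counts_path is required")
            matrix = load_gene_counts(config.counts_path)
            _require(config.proxy_expression_path is not None, stage,
                     "proxy_expression_path is required")
            proxy_expr = load_expression(config.proxy_expression_path)
            _require(config.parasite_expression_path is not None, stage,
                     "parasite_expression_path is required")
            parasite_expr = load_expression(config.parasite_expression_path)
            _require(config.ortholog_map_path is not None, stage,
                     "ortholog_map_path is required")
            ortholog_map = load_ortholog_map(config.ortholog_map_path)
            tissue_classes = (
                load_tissue_classes(config.tissue_class_path)
                if config.tissue_class_path
                else dict(config.tissue_classes)
            )
            if config.annotation_path:
                from .expression import load_annotation

                annotation = load_annotation(config.annotation_path)
            else:
                annotation = {}
            _require(config.reference_fasta is not None and config.candidate_fasta is not None,
                     stage, "reference_fasta and candidate_fasta are required")
            cds_pairs = read_fasta_pairs(config.reference_fasta, config.candidate_fasta)
            _require(config.histogram_path is not None, stage, "histogram_path is required")
            histogram = load_histogram(config.histogram_path)
    except StageError:
        raise
    except OrtholossError as exc:
        raise StageError(stage, str(exc)) from exc

    # -- conserved ----------------------------------------------------------
    stage = "conserved"
    try:
        logger.info("[%s] reference=%s min_present=%d", stage, config.reference, config.min_present)
        conserved = conserved_orthogroups(matrix, config.reference, config.panel, config.min_present)
        with open(results / "conserved.tsv", "w", encoding="utf-8") as handle:
            handle.write("orthogroup\n")
            for og in conserved:
                handle.write(f"{og}\n")
        summary["n_orthogroups"] = matrix.n_orthogroups
        summary["n_conserved"] = len(conserved)
    except OrtholossError as exc:
        raise StageError(stage, str(exc)) from exc

    # -- losses / partition / findex ---------------------------------------
    stage = "losses"
    try:
        reports = {}
        for t in config.targets:
            report = call_losses(matrix, conserved, t)
            reports[t] = report
            olio.write_loss_report(report, results / f"losses_{t}.tsv",
                                   header={**provenance, "target": t})
            summary[f"n_lost_{t}"] = report.n_lost
            summary[f"loss_fraction_{t}"] = round(report.loss_fraction, 6)
            summary[f"loss_percent_{t}"] = round(100 * report.loss_fraction, 1)
            logger.info("[%s] %s: %d/%d lost", stage, t, report.n_lost, report.n_conserved)
    except OrtholossError as exc:
        raise StageError(stage, str(exc)) from exc

    stage = "partition"
    try:
        if len(config.targets) >= 2:
            a, b = config.targets[:2]
            partition = partition_losses(reports[a], reports[b])
            olio.write_partition(partition, results / "partition.tsv", header=provenance)
            summary["n_joint"] = partition.n_joint
            summary[f"n_specific_{a}"] = partition.n_specific_a
            summary[f"n_specific_{b}"] = partition.n_specific_b
    except OrtholossError as exc:
        raise StageError(stage, str(exc)) from exc

    stage = "findex"
    try:
        for t in config.targets:
            box = f_summary(matrix, conserved, t)
            olio.write_tukey_summary(box, results / f"fsummary_{t}.tsv",
                                     header={**provenance, "target": t})
            summary[f"f_median_{t}"] = round(box.median, 6)
            summary[f"f_mean_{t}"] = round(box.mean, 6)
            summary[f"fraction_below_half_{t}"] = round(box.fraction_below_half, 6)
    except OrtholossError as exc:
        raise StageError(stage, str(exc)) from exc

    # -- expression ---------------------------------------------------------
    stage = "pet"
    try:
        pets = pet_matrix(proxy_expr, config.fold_threshold)
        with open(results / "pet_assignments.tsv", "w", encoding="utf-8") as handle:
            handle.write("gene\tpet_tissues\n")
            for gene, row in pets.iterrows():
                tissues = ";".join(pets.columns[row.to_numpy()])
                handle.write(f"{gene}\t{tissues}\n")
    except OrtholossError as exc:
        raise StageError(stage, str(exc)) from exc

    stage = "peg"
    try:
        focal = [t for t in config.focal_tissues if t in parasite_expr.values.columns]
        _require(bool(focal), stage, "no focal tissue present in the expression matrix")
        pegs = principal_genes(parasite_expr, focal, config.fold_threshold)
        with open(results / "pegs.tsv", "w", encoding="utf-8") as handle:
            handle.write("gene\n")
            for gene in sorted(pegs):
                handle.write(f"{gene}\n")
        summary["n_pegs"] = len(pegs)
    except StageError:
        raise
    except OrtholossError as exc:
        raise StageError(stage, str(exc)) from exc

    stage = "tabulate"
    try:
        first_target = config.targets[0]
        tabulation = tabulate_lost_pets(
            sorted(reports[first_target].lost_orthogroups), ortholog_map, pets, tissue_classes
        )
        olio.write_pet_tabulation(tabulation, results / "lost_pet_tabulation.tsv",
                                  header={**provenance, "target": first_target})
        for c in tabulation.classes:
            summary[f"lost_pets_{c}"] = tabulation.counts[c]
    except OrtholossError as exc:
        raise StageError(stage, str(exc)) from exc

    stage = "enrich"
    try:
        if annotation:
            rows = enrich(pegs, parasite_expr.gene_ids, annotation)
            with open(results / "enrichment.tsv", "w", encoding="utf-8") as handle:
                handle.write("term\tk\tK\tn\tN\tp_value\tq_value\n")
                for r in rows:
                    handle.write(f"{r.term}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                                 f"{r.p_value:.6g}\t{r.q_value:.6g}\n")
            if rows:
                summary["top_enriched_term"] = rows[0].term
                summary["top_enriched_p"] = f"{rows[0].p_value:.6g}"
    except OrtholossError as exc:
        raise StageError(stage, str(exc)) from exc

    # -- pseudogene scan ----------------------------------------------------
    stage = "pseudo"
    try:
        lesion_reports = scan_pairs(
            cds_pairs,
            match=config.match,
            mismatch=config.mismatch,
            gap_open=config.gap_open,
            gap_extend=config.gap_extend,
        )
        olio.write_lesion_reports(
            lesion_reports, results / "lesions.tsv",
            header={**provenance, "scores": f"match={config.match},mismatch={config.mismatch},"
                    f"gap_open={config.gap_open},gap_extend={config.gap_extend}"},
        )
        summary["n_cds_pairs"] = len(lesion_reports)
        summary["n_pseudogenes"] = sum(r.is_pseudogene for r in lesion_reports)
        summary["n_frameshift_pairs"] = sum(
            bool(r.lesions_of_kind("frameshift")) for r in lesion_reports
        )
        summary["n_premature_stop_pairs"] = sum(
            bool(r.lesions_of_kind("premature_stop")) for r in lesion_reports
        )
    except OrtholossError as exc:
        raise StageError(stage, str(exc)) from exc

    # -- k-mer survey -------------------------------------------------------
    stage = "kmer-survey"
    try:
        estimate = survey(histogram, repeat_multiplier=config.repeat_multiplier)
        olio.write_survey(estimate, results / "survey.tsv", header=provenance)
        summary["kmer_error_threshold"] = estimate.error_threshold
        summary["kmer_peak_depth"] = estimate.peak_depth
        summary["genome_size_estimate"] = round(estimate.genome_size, 2)
        summary["repeat_fraction_estimate"] = round(estimate.repeat_fraction, 6)
    except OrtholossError as exc:
        raise StageError(stage, str(exc)) from exc

    # -- report -------------------------------------------------------------
    stage = "report"
    try:
        olio.write_key_values(summary, out / "summary.tsv", header=provenance)
        manifest = {
            "ortholoss_version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
        }
        with open(out / "manifest.yaml", "w", encoding="utf-8") as handle:
            yaml.safe_dump(manifest, handle, sort_keys=True)
    except OSError as exc:
        raise StageError(stage, str(exc)) from exc
    logger.info("[report] run complete: %s", out)
    return out


def _simulate_annotation(parasite_truth, config: RunConfig) -> dict[str, set[str]]:
    """Random term → gene annotation with one term tracking planted PETs."""
    import numpy as np

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 77]))
    genes = list(parasite_truth.pet_tissue)
    annotation: dict[str, set[str]] = {}
    for i in range(10):
        mask = rng.random(len(genes)) < 0.05
        annotation[f"T{i:03d}"] = {g for g, m in zip(genes, mask) if m}
    focal = set(config.focal_tissues)
    planted_focal = [g for g, t in parasite_truth.pet_tissue.items() if t in focal]
    keep = rng.random(len(planted_focal)) < 0.8
    annotation["T_FOCAL"] = {g for g, m in zip(planted_focal, keep) if m}
    return {t: s for t, s in annotation.items() if s}
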
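"""Plain-text writers (and truth-file round-trip readers) for result tables.

All outputs are tab-separated UTF-8 text.  Pipeline outputs carry a
comment-prefixed header block (``# key=value`` lines) recording provenance.
"""

from __future__ import annotations

import os
import sys
from contextlib import contextmanager
from typing import Mapping

import pandas as pd

from .errors import ParseError
from .expression import PetTabulation
from .family_matrix import LossPartition, LossReport, TukeySummary
from .kmer import SurveyEstimate
from .pseudogene import LesionReport
from .simulate import (
    CdsTruth,
    ExpressionTruth,
    FamilyMatrixTruth,
    PlantedLesion,
)

__all__ = [
    "write_loss_report",
    "write_partition",
    "write_tukey_summary",
    "write_pet_tabulation",
    "write_lesion_reports",
    "write_survey",
    "write_key_values",
    "write_family_truth",
    "read_family_truth",
    "write_expression_truth",
    "read_expression_truth",
    "write_cds_truth",
    "read_cds_truth",
]


@contextmanager
def _open_with_header(path, header: Mapping[str, object] | None):
    if path == "-":
        handle, close = sys.stdout, False
    else:
        handle, close = open(path, "w", encoding="utf-8"), True
    try:
        for key, value in (header or {}).items():
            handle.write(f"# {key}={value}\n")
        yield handle
    finally:
        if close:
            handle.close()


def write_loss_report(report: LossReport, path, header=None) -> None:
    with _open_with_header(path, header) as out:
        out.write("orthogroup\tstatus\n")
        for og in sorted(report.lost_orthogroups):
            out.write(f"{og}\tlost\n")


def write_partition(partition: LossPartition, path, header=None) -> None:
    with _open_with_header(path, header) as out:
        out.write("orthogroup\tstatus\n")
        for og in sorted(partition.joint):
            out.write(f"{og}\tjoint\n")
        for og in sorted(partition.specific_a):
            out.write(f"{og}\tspecific_a\n")
        for og in sorted(partition.specific_b):
            out.write(f"{og}\tspecific_b\n")


def write_tukey_summary(summary: TukeySummary, path, header=None) -> None:
    with _open_with_header(path, header) as out:
        for key in ("q1", "median", "q3", "mean", "whisker_low", "whisker_high",
                    "fraction_below_half", "n"):
            out.write(f"{key}\t{getattr(summary, key)}\n")
        out.write(f"n_outliers\t{len(summary.outliers)}\n")


def write_pet_tabulation(tab: PetTabulation, path, header=None) -> None:
    with _open_with_header(path, header) as out:
        out.write("class\tcount\tuniverse\tpct_of_class_universe\tpct_of_cohort\n")
        for c in tab.classes:
            out.write(
                f"{c}\t{tab.counts[c]}\t{tab.universe_counts[c]}\t"
                f"{tab.pct_of_class_universe[c]:.4f}\t{tab.pct_of_cohort[c]:.4f}\n"
            )
        out.write(f"# n_lost={tab.n_lost} n_unmapped={tab.n_unmapped} "
                  f"n_without_pet={tab.n_without_pet}\n")


def write_lesion_reports(reports, path, header=None) -> None:
    with _open_with_header(path, header) as out:
        out.write("pair\tkind\tref_position\tdetail\tis_pseudogene\n")
        for report in reports:
            if not report.lesions:
                out.write(f"{report.pair_id}\tnone\t.\t.\tfalse\n")
            for lesion in report.lesions:
                out.write(
                    f"{report.pair_id}\t{lesion.kind}\t{lesion.ref_position}\t"
                    f"{lesion.detail}\ttrue\n"
                )


def write_survey(estimate: SurveyEstimate, path, header=None) -> None:
    with _open_with_header(path, header) as out:
        out.write(f"error_threshold\t{estimate.error_threshold}\n")
        out.write(f"peak_depth\t{estimate.peak_depth}\n")
        out.write(f"kmer_count\t{estimate.kmer_count}\n")
        out.write(f"genome_size\t{estimate.genome_size:.2f}\n")
        out.write(f"repeat_fraction\t{estimate.repeat_fraction:.6f}\n")
        out.write(f"repeat_multiplier\t{estimate.repeat_multiplier}\n")


def write_key_values(items: Mapping[str, object], path, header=None) -> None:
    with _open_with_header(path, header) as out:
        for key, value in items.items():
            out.write(f"{key}\t{value}\n")


# ---------------------------------------------------------------------------
# truth files (round-trippable)
# ---------------------------------------------------------------------------

def write_family_truth(truth: FamilyMatrixTruth, path) -> None:
    targets = truth.params["targets"]
    columns = ["orthogroup", "conserved"]
    for t in targets:
        columns += [f"lost_{t}", f"below_{t}"]
    rows = []
    ids = sorted(set(truth.conserved)
                 | {g for s in truth.lost.values() for g in s}
                 | {g for s in truth.below_mean.values() for g in s})
    conserved = set(truth.conserved)
    for og in ids:
        row = [og, int(og in conserved)]
        for t in targets:
            row += [int(og in truth.lost[t]), int(og in truth.below_mean[t])]
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def read_family_truth(path, params: dict) -> FamilyMatrixTruth:
    frame = pd.read_csv(path, sep="\t", dtype={"orthogroup": str})
    targets = params["targets"]
    conserved = tuple(frame.loc[frame["conserved"] == 1, "orthogroup"])
    lost = {t: frozenset(frame.loc[frame[f"lost_{t}"] == 1, "orthogroup"]) for t in targets}
    below = {t: frozenset(frame.loc[frame[f"below_{t}"] == 1, "orthogroup"]) for t in targets}
    above = {t: frozenset(set(conserved) - below[t]) for t in targets}
    return FamilyMatrixTruth(conserved=conserved, lost=lost, below_mean=below,
                             above_mean=above, params=params)


def write_expression_truth(truth: ExpressionTruth, path) -> None:
    with open(path, "w", encoding="utf-8") as out:
        out.write("gene\tpet_tissue\n")
        for gene, tissue in truth.pet_tissue.items():
            out.write(f"{gene}\t{tissue if tissue is not None else '.'}\n")


def read_expression_truth(path, params: dict) -> ExpressionTruth:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    pet = {row.gene: (None if row.pet_tissue == "." else row.pet_tissue)
           for row in frame.itertuples()}
    return ExpressionTruth(pet_tissue=pet, params=params)


def write_cds_truth(truth: CdsTruth, path) -> None:
    with open(path, "w", encoding="utf-8") as out:
        out.write("pair\tkind\tref_position\tdetail\n")
        for pair_id, lesion in truth.planted.items():
            pos = lesion.ref_position if lesion.ref_position is not None else "."
            detail = lesion.detail if lesion.detail is not None else "."
            out.write(f"{pair_id}\t{lesion.kind}\t{pos}\t{detail}\n")


def read_cds_truth(path, params: dict) -> CdsTruth:
    planted = {}
    with open(path, encoding="utf-8") as handle:
        header = handle.readline()
        if not header.startswith("pair\t"):
            raise ParseError(f"{os.fspath(path)}: not a CDS truth file")
        for line in handle:
            pair_id, kind, pos, detail = line.rstrip("\n").split("\t")
            position = None if pos == "." else int(pos)
            if detail == ".":
                parsed_detail = None
            else:
                try:
                    parsed_detail = int(detail)
                except ValueError:
                    parsed_detail = detail
            planted[pair_id] = PlantedLesion(kind, position, parsed_detail)
    return CdsTruth(planted=planted, params=params)
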
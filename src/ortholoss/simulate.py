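"""Seeded generators of synthetic inputs with planted ground truth.

Each generator emulates one class of input to the analysis pipeline —
orthogroup count matrices, tissue expression matrices, reference/candidate
CDS pairs, and k-mer depth histograms — and returns, next to the dataset, a
truth object recording exactly what was planted.  All generators are pure
functions of their parameters and a seed: a single global seed is expanded
into fixed per-generator substreams, so every stage can be regenerated
independently and two runs with the same seed are byte-identical.

Default parameters mirror the scale of a nine-species comparative study of a
parasitic plant: a reference autotroph plus a panel of six autotrophic
relatives and two heterotrophic targets, per-target loss rates of 11.7% and
13.0% of conserved orthogroups, and a k-mer survey at 42× coverage.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .expression import ExpressionMatrix
from .family_matrix import GeneCountMatrix
from .kmer import KmerHistogram
from .pseudogene import STOP_CODONS, CdsPair

__all__ = [
    "DEFAULT_SPECIES",
    "DEFAULT_PANEL",
    "DEFAULT_TARGETS",
    "FamilyMatrixTruth",
    "ExpressionTruth",
    "CdsTruth",
    "KmerTruth",
    "simulate_family_matrix",
    "simulate_expression",
    "simulate_cds_pairs",
    "simulate_kmer_histogram",
    "write_cds_fastas",
]

# species labels for the default 9-species setting: one reference autotroph,
# six autotrophic panel species, two heterotrophic targets
DEFAULT_REFERENCE = "Atha"
DEFAULT_PANEL = ("Inil", "Stub", "Slyc", "Cann", "Ccan", "Mgut")
DEFAULT_TARGETS = ("Caus", "Ugib")
DEFAULT_SPECIES = (DEFAULT_REFERENCE,) + DEFAULT_PANEL + DEFAULT_TARGETS

_STREAMS = {"family": 11, "expression": 22, "cds": 33, "kmer": 44}


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Per-generator substream: global seed plus a fixed stream offset."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


def _check_fraction(value: float, name: str) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must be in [0, 1], got {value}")
    return value


# ---------------------------------------------------------------------------
# orthogroup count matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyMatrixTruth:
    """Planted structure of a simulated gene-count matrix.

    ``below_mean`` / ``above_mean`` record, per target, the conserved
    orthogroups whose realised target count is strictly below / at-or-above
    the family's all-species mean (contraction vs expansion side of the
    F-index).  ``lost`` is a subset of ``below_mean``.
    """

    conserved: tuple[str, ...]
    lost: dict[str, frozenset[str]]
    below_mean: dict[str, frozenset[str]]
    above_mean: dict[str, frozenset[str]]
    params: dict = field(repr=False)


def simulate_family_matrix(
    n_orthogroups: int = 2000,
    reference: str = DEFAULT_REFERENCE,
    panel: Sequence[str] = DEFAULT_PANEL,
    targets: Sequence[str] = DEFAULT_TARGETS,
    loss_rates: Mapping[str, float] | None = None,
    joint_excess: float = 0.04,
    conserved_fraction: float = 0.558,
    mean_family_size: float = 3.0,
    below_mean_fraction: Mapping[str, float] | None = None,
    min_present: int = 5,
    seed: int = 0,
) -> tuple[GeneCountMatrix, FamilyMatrixTruth]:
    """Simulate an orthogroup × species count matrix with planted losses.

    Conserved rows satisfy the conservation rule (reference present, at least
    ``min_present`` of the panel present) by construction; the remaining rows
    violate it.  Losses shared beyond independence are planted first: a
    ``joint_excess`` fraction of conserved rows is zeroed in *both* targets,
    and each target then loses further rows at a rate adjusted so its
    marginal loss rate equals the stated ``loss_rates`` value exactly (each
    stated rate must therefore be ≥ ``joint_excess``).  Present target counts
    are drawn so that roughly ``below_mean_fraction`` of the conserved
    families end up below their all-species mean size; the truth records the
    realised below/above sets exactly (computed directly from the emitted
    counts).
    """
    if n_orthogroups < 1:
        raise ValidationError("n_orthogroups must be ≥ 1")
    targets = tuple(targets)
    panel = tuple(panel)
    species = (reference,) + panel + targets
    if len(set(species)) != len(species):
        raise ValidationError("species labels must be unique across roles")
    if loss_rates is None:
        loss_rates = {t: r for t, r in zip(targets, (0.117, 0.130))}
    loss_rates = {t: _check_fraction(loss_rates.get(t, 0.0), f"loss_rate[{t}]") for t in targets}
    joint_excess = _check_fraction(joint_excess, "joint_excess")
    conserved_fraction = _check_fraction(conserved_fraction, "conserved_fraction")
    if below_mean_fraction is None:
        below_mean_fraction = {t: f for t, f in zip(targets, (0.72, 0.62))}
    below_mean_fraction = {
        t: _check_fraction(below_mean_fraction.get(t, 0.5), f"below_mean_fraction[{t}]")
        for t in targets
    }
    if not 0 <= min_present <= len(panel):
        raise ValidationError("min_present out of range")
    if mean_family_size <= 1:
        raise ValidationError("mean_family_size must exceed 1")

    rng = _rng(seed, "family")
    n = n_orthogroups
    n_panel = len(panel)
    lam = mean_family_size - 1.0

    ids = np.array([f"OG{i:07d}" for i in range(n)], dtype=object)
    conserved_mask = rng.random(n) < conserved_fraction

    # reference and panel counts
    ref_counts = 1 + rng.poisson(lam, n)
    presence = rng.random((n, n_panel)) < 0.92
    sizes = 1 + rng.poisson(lam, (n, n_panel))

    for i in np.flatnonzero(conserved_mask):
        deficit = min_present - int(presence[i].sum())
        if deficit > 0:  # force the conservation rule to hold
            absent = np.flatnonzero(~presence[i])
            presence[i, rng.choice(absent, size=deficit, replace=False)] = True
    for i in np.flatnonzero(~conserved_mask):
        if rng.random() < 0.5:
            ref_counts[i] = 0  # violate via reference absence
        else:  # violate via sparse panel
            n_present = int(rng.integers(0, min_present))
            presence[i] = False
            if n_present:
                presence[i, rng.choice(n_panel, size=n_present, replace=False)] = True
    panel_counts = np.where(presence, sizes, 0)

    counts = np.zeros((n, len(species)), dtype=np.int64)
    counts[:, 0] = ref_counts
    counts[:, 1 : 1 + n_panel] = panel_counts

    # plant losses and draw target counts
    base_sum = counts.sum(axis=1)  # reference + panel mass
    lost: dict[str, np.ndarray] = {}
    joint_extra = conserved_mask & (rng.random(n) < joint_excess)
    for t in targets:
        if loss_rates[t] < joint_excess and loss_rates[t] > 0:
            raise ValidationError(
                f"loss_rate[{t}]={loss_rates[t]} is below joint_excess={joint_excess}"
            )
        # specific rate chosen so the marginal loss rate equals the stated one
        if loss_rates[t] == 0:
            specific_rate = 0.0
            lost[t] = np.zeros(n, dtype=bool)
            continue
        specific_rate = (loss_rates[t] - joint_excess) / (1 - joint_excess)
        lost[t] = (conserved_mask & (rng.random(n) < specific_rate)) | joint_extra

    for j, t in enumerate(targets):
        col = 1 + n_panel + j
        rate_total = loss_rates[t]
        f = below_mean_fraction[t]
        f_adj = 0.0 if rate_total >= f else (f - rate_total) / (1 - rate_total)
        below_intent = rng.random(n) < f_adj
        target_counts = np.where(
            below_intent,
            1,  # minimal presence sits below the family mean
            np.ceil(base_sum / (len(species) - 2)).astype(np.int64) + 1,
        )
        # non-conserved rows carry unconstrained small counts
        target_counts = np.where(conserved_mask, target_counts, rng.poisson(1.0, n))
        target_counts[lost[t]] = 0
        counts[:, col] = target_counts

    frame = pd.DataFrame(counts, index=ids, columns=list(species))
    matrix = GeneCountMatrix(frame)

    # realised below/above-mean sets, computed integer-exactly from counts
    totals = counts.sum(axis=1)
    n_species = len(species)
    below_mean = {}
    above_mean = {}
    for j, t in enumerate(targets):
        col = 1 + n_panel + j
        below = (counts[:, col] * n_species < totals) & conserved_mask
        below_mean[t] = frozenset(ids[below])
        above_mean[t] = frozenset(ids[conserved_mask & ~below])

    truth = FamilyMatrixTruth(
        conserved=tuple(ids[conserved_mask]),
        lost={t: frozenset(ids[lost[t]]) for t in targets},
        below_mean=below_mean,
        above_mean=above_mean,
        params={
            "n_orthogroups": n,
            "reference": reference,
            "panel": list(panel),
            "targets": list(targets),
            "loss_rates": dict(loss_rates),
            "joint_excess": joint_excess,
            "conserved_fraction": conserved_fraction,
            "mean_family_size": mean_family_size,
            "below_mean_fraction": dict(below_mean_fraction),
            "min_present": min_present,
            "seed": int(seed),
        },
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionTruth:
    """Planted principal tissue per gene (``None`` for uniform genes)."""

    pet_tissue: dict[str, str | None]
    params: dict = field(repr=False)


def simulate_expression(
    n_genes: int = 500,
    tissues: Sequence[str] = ("leaf", "root", "flower", "stem", "seed", "fruit"),
    pet_fraction: float = 0.3,
    fold: float = 10.0,
    noise_cv: float = 0.2,
    base_level: float = 20.0,
    gene_prefix: str = "g",
    seed: int = 0,
) -> tuple[ExpressionMatrix, ExpressionTruth]:
    """Simulate a gene × tissue expression matrix with planted PETs.

    A ``pet_fraction`` of genes receives ``fold × base_level`` in one planted
    tissue and ``base_level`` elsewhere; the rest are uniform.  Multiplicative
    lognormal noise with coefficient of variation ``noise_cv`` (mean 1) is
    applied throughout, so planted fold changes survive in expectation.
    """
    if n_genes < 1:
        raise ValidationError("n_genes must be ≥ 1")
    tissues = tuple(tissues)
    if len(tissues) < 2 or len(set(tissues)) != len(tissues):
        raise ValidationError("need at least two distinct tissues")
    pet_fraction = _check_fraction(pet_fraction, "pet_fraction")
    if fold <= 1:
        raise ValidationError("fold must exceed 1")
    if noise_cv < 0:
        raise ValidationError("noise_cv must be ≥ 0")
    if base_level <= 0:
        raise ValidationError("base_level must be positive")

    rng = _rng(seed, "expression")
    n_tissues = len(tissues)
    width = max(4, len(str(n_genes - 1)))
    genes = [f"{gene_prefix}{i:0{width}d}" for i in range(n_genes)]
    is_pet = rng.random(n_genes) < pet_fraction
    pet_idx = rng.integers(0, n_tissues, n_genes)

    values = np.full((n_genes, n_tissues), base_level, dtype=float)
    values[np.flatnonzero(is_pet), pet_idx[is_pet]] *= fold
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        values *= rng.lognormal(-sigma**2 / 2, sigma, (n_genes, n_tissues))

    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=list(tissues)))
    truth = ExpressionTruth(
        pet_tissue={
            g: (tissues[pet_idx[i]] if is_pet[i] else None)
            for i, g in enumerate(genes)
        },
        params={
            "n_genes": n_genes,
            "tissues": list(tissues),
            "pet_fraction": pet_fraction,
            "fold": fold,
            "noise_cv": noise_cv,
            "base_level": base_level,
            "seed": int(seed),
        },
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# CDS pairs
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))
_NONSTOP_CODONS = np.array(
    [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
     if a + b + c not in STOP_CODONS]
)
_STOPS = np.array(sorted(STOP_CODONS))


@dataclass(frozen=True)
class PlantedLesion:
    kind: str  # "frameshift" | "premature_stop" | "intact"
    ref_position: int | None  # 1-based, None for intact pairs
    detail: int | str | None  # signed indel length, or the stop triplet


@dataclass(frozen=True)
class CdsTruth:
    """Planted lesion (or intactness) per simulated CDS pair."""

    planted: dict[str, PlantedLesion]
    params: dict = field(repr=False)


def simulate_cds_pairs(
    n_pairs: int = 200,
    cds_length_codons: int = 100,
    lesion_mix: Mapping[str, float] | None = None,
    background_sub_rate: float = 0.01,
    seed: int = 0,
) -> tuple[list[CdsPair], CdsTruth]:
    """Simulate reference/candidate CDS pairs with planted lesions.

    References are random intact ORFs (ATG, non-stop codons, terminal stop).
    Candidates copy their reference, receive background substitutions that
    are rejection-sampled so they never create an in-frame stop, and then one
    planted lesion according to ``lesion_mix`` (default 30% frameshift, 30%
    premature stop, 40% intact).  Frameshifts are single indels of length 1
    or 2 (insertion or deletion, equiprobable) planted away from the CDS
    ends; premature stops replace one mid-CDS codon.
    """
    if lesion_mix is None:
        lesion_mix = {"frameshift": 0.3, "premature_stop": 0.3, "intact": 0.4}
    kinds = list(lesion_mix)
    probs = np.array([lesion_mix[k] for k in kinds], dtype=float)
    if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
        raise ValidationError("lesion_mix must be non-negative and sum to 1")
    unknown = set(kinds) - {"frameshift", "premature_stop", "intact"}
    if unknown:
        raise ValidationError(f"unknown lesion kind(s): {sorted(unknown)}")
    background_sub_rate = _check_fraction(background_sub_rate, "background_sub_rate")
    L = int(cds_length_codons)
    if L < 10:
        raise ValidationError("cds_length_codons must be ≥ 10")
    if n_pairs < 1:
        raise ValidationError("n_pairs must be ≥ 1")

    rng = _rng(seed, "cds")
    pairs: list[CdsPair] = []
    planted: dict[str, PlantedLesion] = {}
    for i in range(n_pairs):
        pair_id = f"pair{i:04d}"
        body = rng.choice(_NONSTOP_CODONS, L - 2)
        ref = "ATG" + "".join(body) + str(rng.choice(_STOPS))

        kind = kinds[int(rng.choice(len(kinds), p=probs))]
        protected: set[int] = set(range(3)) | set(range(3 * L - 3, 3 * L))
        stop_codon_index = indel_pos = indel_len = None
        if kind == "premature_stop":
            stop_codon_index = int(rng.integers(2, L - 3))  # 0-based codon
            protected |= set(range(3 * stop_codon_index, 3 * stop_codon_index + 3))
        elif kind == "frameshift":
            indel_len = int(rng.choice([1, 2]))
            if rng.random() < 0.5:
                indel_len = -indel_len
            indel_pos = int(rng.integers(6, 3 * L - 12))  # 0-based nucleotide

        cand = list(ref)
        # stop-free background substitutions (checked in the reference frame)
        for pos in np.flatnonzero(rng.random(3 * L) < background_sub_rate):
            pos = int(pos)
            if pos in protected:
                continue
            codon_start = 3 * (pos // 3)
            alternatives = [b for b in "ACGT" if b != cand[pos]]
            rng.shuffle(alternatives)
            for base in alternatives:
                trial = cand[codon_start:codon_start + 3]
                trial[pos - codon_start] = base
                if "".join(trial) not in STOP_CODONS:
                    cand[pos] = base
                    break

        if kind == "premature_stop":
            stop = str(rng.choice(_STOPS))
            cand[3 * stop_codon_index : 3 * stop_codon_index + 3] = list(stop)
            planted[pair_id] = PlantedLesion("premature_stop", 3 * stop_codon_index + 1, stop)
        elif kind == "frameshift":
            if indel_len < 0:
                del cand[indel_pos : indel_pos - indel_len]
            else:
                insert = [str(b) for b in rng.choice(_BASES, indel_len)]
                cand[indel_pos:indel_pos] = insert
            planted[pair_id] = PlantedLesion("frameshift", indel_pos + 1, indel_len)
        else:
            planted[pair_id] = PlantedLesion("intact", None, None)

        pairs.append(CdsPair(pair_id, ref, "".join(cand)))

    truth = CdsTruth(
        planted=planted,
        params={
            "n_pairs": n_pairs,
            "cds_length_codons": L,
            "lesion_mix": dict(lesion_mix),
            "background_sub_rate": background_sub_rate,
            "seed": int(seed),
        },
    )
    return pairs, truth


def write_cds_fastas(
    pairs: Sequence[CdsPair],
    reference_path: str | os.PathLike,
    candidate_path: str | os.PathLike,
) -> None:
    """Write the reference and candidate sequences of pairs as two FASTAs."""
    with open(reference_path, "w", encoding="utf-8") as ref_out:
        for p in pairs:
            ref_out.write(f">{p.pair_id}\n{p.reference}\n")
    with open(candidate_path, "w", encoding="utf-8") as cand_out:
        for p in pairs:
            cand_out.write(f">{p.pair_id}\n{p.candidate}\n")


# ---------------------------------------------------------------------------
# k-mer histogram
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KmerTruth:
    """True parameters behind a simulated k-mer histogram."""

    genome_size: int
    coverage: float
    repeat_fraction: float
    repeat_copy: int
    error_rate: float
    k: int
    params: dict = field(repr=False)


def simulate_kmer_histogram(
    genome_size: int = 1_000_000,
    coverage: float = 42.0,
    repeat_fraction: float = 0.2,
    repeat_copy: int = 2,
    error_rate: float = 0.01,
    k: int = 17,
    seed: int = 0,
) -> tuple[KmerHistogram, KmerTruth]:
    """Simulate a k-mer depth histogram from a unique/repeat/error mixture.

    ``genome_size × (1 − repeat_fraction)`` distinct single-copy k-mers draw
    depths from Poisson(coverage); repeat sequence contributes
    ``genome_size × repeat_fraction / repeat_copy`` distinct k-mers at
    Poisson(repeat_copy × coverage).  Sequencing errors add
    ``genome_size × coverage × error_rate × k`` spurious k-mers concentrated
    at depth 1–2 (each base error corrupts up to k overlapping k-mers).
    """
    if genome_size < 1000:
        raise ValidationError("genome_size must be ≥ 1000")
    if coverage <= 0:
        raise ValidationError("coverage must be positive")
    repeat_fraction = _check_fraction(repeat_fraction, "repeat_fraction")
    error_rate = _check_fraction(error_rate, "error_rate")
    if repeat_copy < 2:
        raise ValidationError("repeat_copy must be ≥ 2")
    if k < 2:
        raise ValidationError("k must be ≥ 2")

    rng = _rng(seed, "kmer")
    n_unique = int(round(genome_size * (1 - repeat_fraction)))
    n_repeat = int(round(genome_size * repeat_fraction / repeat_copy))
    depths = [rng.poisson(coverage, n_unique)]
    if n_repeat:
        depths.append(rng.poisson(coverage * repeat_copy, n_repeat))
    observed = np.concatenate(depths)
    bincount = np.bincount(observed[observed > 0])

    n_error = int(round(genome_size * coverage * error_rate * k))
    if n_error:
        if bincount.size < 3:
            bincount = np.pad(bincount, (0, 3 - bincount.size))
        bincount[1] += int(round(0.9 * n_error))
        bincount[2] += int(round(0.1 * n_error))

    depths_axis = np.arange(1, bincount.size)
    counts = bincount[1:]
    histogram = KmerHistogram(depths_axis, counts, k=k)
    truth = KmerTruth(
        genome_size=int(genome_size),
        coverage=float(coverage),
        repeat_fraction=repeat_fraction,
        repeat_copy=int(repeat_copy),
        error_rate=error_rate,
        k=int(k),
        params={
            "genome_size": int(genome_size),
            "coverage": float(coverage),
            "repeat_fraction": repeat_fraction,
            "repeat_copy": int(repeat_copy),
            "error_rate": error_rate,
            "k": int(k),
            "seed": int(seed),
        },
    )
    return histogram, truth
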
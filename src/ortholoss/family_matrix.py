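"""Orthogroup count matrices: conservation, gene-loss calling and the F-index.

The central object is a :class:`GeneCountMatrix`, an orthogroup-by-species
table of non-negative gene counts (the layout of an OrthoFinder
``Orthogroups.GeneCount.tsv`` file).  On top of it this module implements the
comparative-genomics bookkeeping used to study regressive genome evolution in
parasitic and carnivorous plants:

* **conserved orthogroups** — families with at least one member in a reference
  species (e.g. *Arabidopsis*) and in at least ``min_present`` species of a
  panel of autotrophic relatives;
* **loss calling** — a conserved orthogroup counts as *lost* in a target
  species (e.g. the parasite) when the target has no member at all, and two
  targets' losses can be partitioned into joint and species-specific sets;
* **the F-index** — a per-family, per-species statistic ``F = n / (n + x̄)``
  comparing a species' family size ``n`` with the family's mean size ``x̄``
  across all species.  ``F = 0.5`` means the species holds exactly the average
  number of genes; smaller values indicate contraction and larger values
  expansion.  Distributions of F are summarised as Tukey box statistics.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "GeneCountMatrix",
    "ConservedSet",
    "LossReport",
    "LossPartition",
    "FIndexTable",
    "TukeySummary",
    "load_gene_counts",
    "conserved_orthogroups",
    "call_losses",
    "partition_losses",
    "f_index",
    "f_table",
    "f_summary",
    "tukey_summary",
]


class GeneCountMatrix:
    """An orthogroup × species table of non-negative integer gene counts.

    Parameters
    ----------
    counts
        DataFrame indexed by orthogroup id with one column per species.  Row
        and column labels must be unique and every cell a non-negative
        integer.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()][0]
            raise ValidationError(f"duplicated orthogroup id {dup!r}")
        if counts.columns.has_duplicates:
            dup = counts.columns[counts.columns.duplicated()][0]
            raise ValidationError(f"duplicated species id {dup!r}")
        if counts.shape[1] == 0:
            raise ValidationError("count matrix has no species columns")
        values = counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise ValidationError("gene counts must be integers")
        if values.size and (values < 0).any():
            raise ValidationError("gene counts must be non-negative")
        self._counts = counts.astype(np.int64)

    @property
    def counts(self) -> pd.DataFrame:
        """The underlying DataFrame (treat as read-only)."""
        return self._counts

    @property
    def orthogroup_ids(self) -> list[str]:
        return list(self._counts.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self._counts.columns)

    @property
    def n_orthogroups(self) -> int:
        return self._counts.shape[0]

    @property
    def n_species(self) -> int:
        return self._counts.shape[1]

    def count(self, orthogroup: str, species: str) -> int:
        self._check_species([species])
        if orthogroup not in self._counts.index:
            raise ValidationError(f"unknown orthogroup id {orthogroup!r}")
        return int(self._counts.at[orthogroup, species])

    def _check_species(self, species: Iterable[str]) -> None:
        unknown = [s for s in species if s not in self._counts.columns]
        if unknown:
            raise ValidationError(f"unknown species id(s): {unknown}")

    def _check_orthogroups(self, orthogroups: Iterable[str]) -> None:
        index = self._counts.index
        unknown = [g for g in orthogroups if g not in index]
        if unknown:
            raise ValidationError(f"unknown orthogroup id(s): {unknown[:5]}")

    def to_tsv(self, path: str | os.PathLike) -> None:
        """Write the matrix as a tab-separated table with an id column."""
        self._counts.to_csv(path, sep="\t", index_label="Orthogroup")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"GeneCountMatrix({self.n_orthogroups} orthogroups × "
            f"{self.n_species} species)"
        )


def load_gene_counts(path: str | os.PathLike) -> GeneCountMatrix:
    """Read a gene-count TSV (OrthoFinder ``Orthogroups.GeneCount.tsv`` dialect).

    The first column holds orthogroup ids, the header row species ids.  A
    trailing ``Total`` column, if present, is ignored.  Malformed input
    (ragged rows, non-integer cells, duplicate ids, an empty file) raises
    :class:`~ortholoss.errors.ParseError` naming the offending line.
    """
    path = os.fspath(path)
    with open(path, encoding="utf-8") as handle:
        lines = handle.read().splitlines()
    while lines and lines[-1].strip() == "":
        lines.pop()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise ParseError(f"{path}: line 1: header must name at least one species")
    species = header[1:]
    keep = [i for i, s in enumerate(species) if s != "Total"]
    kept_species = [species[i] for i in keep]
    if len(set(kept_species)) != len(kept_species):
        raise ParseError(f"{path}: line 1: duplicated species id in header")
    n_fields = len(header)
    ids: list[str] = []
    seen: set[str] = set()
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != n_fields:
            raise ParseError(
                f"{path}: line {lineno}: expected {n_fields} fields, "
                f"found {len(fields)}"
            )
        og = fields[0]
        if og in seen:
            raise ParseError(f"{path}: line {lineno}: duplicated orthogroup id {og!r}")
        seen.add(og)
        row = []
        for i in keep:
            cell = fields[1 + i]
            try:
                value = int(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer count {cell!r}"
                ) from None
            if value < 0:
                raise ParseError(f"{path}: line {lineno}: negative count {value}")
            row.append(value)
        ids.append(og)
        rows.append(row)
    if not rows:
        raise ParseError(f"{path}: no orthogroup rows")
    frame = pd.DataFrame(rows, index=ids, columns=kept_species, dtype=np.int64)
    return GeneCountMatrix(frame)


@dataclass(frozen=True)
class ConservedSet:
    """Orthogroups present in the reference and in enough panel species."""

    orthogroup_ids: tuple[str, ...]
    reference_species: str
    panel_species: tuple[str, ...]
    min_panel_present: int

    def __len__(self) -> int:
        return len(self.orthogroup_ids)

    def __contains__(self, orthogroup: str) -> bool:
        return orthogroup in set(self.orthogroup_ids)

    def __iter__(self):
        return iter(self.orthogroup_ids)

    @property
    def id_set(self) -> frozenset[str]:
        return frozenset(self.orthogroup_ids)


def conserved_orthogroups(
    m: GeneCountMatrix,
    reference: str,
    panel: Sequence[str],
    min_present: int,
) -> ConservedSet:
    """Identify conserved orthogroups.

    An orthogroup is conserved when it has ``count ≥ 1`` in ``reference`` and
    ``count ≥ 1`` in at least ``min_present`` of the ``panel`` species.  Counts
    in any other species (for instance the parasitic targets) play no role.
    Returned ids preserve matrix row order.
    """
    m._check_species([reference, *panel])
    if not 0 <= min_present <= len(panel):
        raise ValidationError(
            f"min_present must be in [0, {len(panel)}], got {min_present}"
        )
    counts = m.counts
    ref_ok = counts[reference].to_numpy() >= 1
    present = (counts[list(panel)].to_numpy() >= 1).sum(axis=1)
    mask = ref_ok & (present >= min_present)
    ids = tuple(np.asarray(m.orthogroup_ids, dtype=object)[mask])
    return ConservedSet(ids, reference, tuple(panel), int(min_present))


@dataclass(frozen=True)
class LossReport:
    """Conserved orthogroups without any member in one target species."""

    target_species: str
    lost_orthogroups: frozenset[str]
    n_conserved: int
    loss_fraction: float
    conserved_orthogroup_ids: frozenset[str] = field(repr=False)

    @property
    def n_lost(self) -> int:
        return len(self.lost_orthogroups)


def call_losses(m: GeneCountMatrix, conserved: ConservedSet, target: str) -> LossReport:
    """Call gene losses: conserved orthogroups with zero count in ``target``."""
    m._check_species([target])
    m._check_orthogroups(conserved.orthogroup_ids)
    if len(conserved) == 0:
        raise ValidationError("conserved set is empty")
    sub = m.counts.loc[list(conserved.orthogroup_ids), target]
    lost = frozenset(sub.index[sub.to_numpy() == 0])
    return LossReport(
        target_species=target,
        lost_orthogroups=lost,
        n_conserved=len(conserved),
        loss_fraction=len(lost) / len(conserved),
        conserved_orthogroup_ids=conserved.id_set,
    )


@dataclass(frozen=True)
class LossPartition:
    """Joint and species-specific partition of two targets' losses."""

    target_a: str
    target_b: str
    joint: frozenset[str]
    specific_a: frozenset[str]
    specific_b: frozenset[str]

    @property
    def n_joint(self) -> int:
        return len(self.joint)

    @property
    def n_specific_a(self) -> int:
        return len(self.specific_a)

    @property
    def n_specific_b(self) -> int:
        return len(self.specific_b)


def partition_losses(loss_a: LossReport, loss_b: LossReport) -> LossPartition:
    """Split two loss reports into joint and species-specific orthogroups.

    Both reports must derive from the same conserved universe.  By
    construction ``|specific_a| = |lost_a| − |joint|`` and symmetrically for
    the second target.
    """
    if loss_a.conserved_orthogroup_ids != loss_b.conserved_orthogroup_ids:
        raise ValidationError("loss reports derive from different conserved sets")
    joint = loss_a.lost_orthogroups & loss_b.lost_orthogroups
    return LossPartition(
        target_a=loss_a.target_species,
        target_b=loss_b.target_species,
        joint=frozenset(joint),
        specific_a=frozenset(loss_a.lost_orthogroups - joint),
        specific_b=frozenset(loss_b.lost_orthogroups - joint),
    )


def _family_means(m: GeneCountMatrix, orthogroups: Sequence[str]) -> pd.Series:
    sub = m.counts.loc[list(orthogroups)]
    means = sub.mean(axis=1)
    zero = means.index[means.to_numpy() == 0]
    if len(zero):
        raise ValidationError(
            f"F-index undefined for all-zero orthogroup {zero[0]!r}"
        )
    return means


def f_index(m: GeneCountMatrix, orthogroup: str, species: str) -> float:
    """The F-index ``F = n / (n + x̄)`` of one species in one family.

    ``n`` is the species' gene count and ``x̄`` the arithmetic mean count over
    *all* species in the matrix (the focal species included).  ``F`` lies in
    ``[0, 1)``: 0 exactly when the species lost the family, 0.5 exactly when
    its count equals the family mean.  All-zero families are rejected.
    """
    n = m.count(orthogroup, species)
    xbar = float(_family_means(m, [orthogroup]).iloc[0])
    return n / (n + xbar)


@dataclass(frozen=True)
class FIndexTable:
    """F-index values per (orthogroup, species) plus each family's mean size."""

    values: pd.DataFrame
    family_mean: pd.Series


def f_table(m: GeneCountMatrix, orthogroups: Sequence[str] | None = None) -> FIndexTable:
    """F-indices for every (orthogroup, species) cell of the (sub)matrix."""
    if orthogroups is None:
        orthogroups = m.orthogroup_ids
    else:
        m._check_orthogroups(orthogroups)
    means = _family_means(m, orthogroups)
    sub = m.counts.loc[list(orthogroups)].astype(float)
    values = sub.div(sub.add(means, axis=0))
    return FIndexTable(values=values, family_mean=means)


@dataclass(frozen=True)
class TukeySummary:
    """Tukey box statistics of a sample, plus the below-average fraction.

    Whiskers reach the most extreme data points still within 1.5 × IQR of the
    nearer quartile; points beyond are listed as outliers.
    """

    q1: float
    median: float
    q3: float
    mean: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]
    fraction_below_half: float
    n: int


def tukey_summary(values: Sequence[float], fraction_below_half: float = float("nan")) -> TukeySummary:
    """Five-number Tukey summary (type-7 / linear-interpolation quartiles)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot summarise an empty sample")
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = np.sort(x[(x < lo_fence) | (x > hi_fence)])
    return TukeySummary(
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        mean=float(x.mean()),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=tuple(float(v) for v in outliers),
        fraction_below_half=float(fraction_below_half),
        n=int(x.size),
    )


def f_summary(m: GeneCountMatrix, conserved: ConservedSet, species: str) -> TukeySummary:
    """Tukey summary of one species' F-indices over the conserved families.

    ``fraction_below_half`` is computed directly from the counts: the fraction
    of conserved orthogroups whose count in ``species`` is strictly below the
    family's all-species mean (ties count as "not below").
    """
    if len(conserved) == 0:
        raise ValidationError("conserved set is empty")
    m._check_species([species])
    table = f_table(m, conserved.orthogroup_ids)
    counts = m.counts.loc[list(conserved.orthogroup_ids), species].to_numpy()
    # integer-exact comparison: n < mean  <=>  n * n_species < row total
    totals = m.counts.loc[list(conserved.orthogroup_ids)].sum(axis=1).to_numpy()
    below = counts * m.n_species < totals
    return tukey_summary(
        table.values[species].to_numpy(),
        fraction_below_half=float(below.mean()),
    )
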
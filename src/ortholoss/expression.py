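"""Principally-expressed tissues/genes, lost-orthogroup tabulation, enrichment.

A gene's *principally expressed tissues* (PETs) are the tissues in which its
expression is at least ``fold_threshold`` times the mean of its expression in
all *other* tissues.  A *principally expressed gene* (PEG) for a focal tissue
set (e.g. prehaustoria + haustoria of a parasitic plant) is a gene whose mean
expression over the focal tissues is at least ``fold_threshold`` times its
mean over the remaining tissues.  The default threshold 2.0 reads "at least
one-fold greater than the average" as "at least twice the average"; pass 1.0
for the weaker reading.

The module also tabulates, for a cohort of lost orthogroups, in which tissue
classes (leaves / roots / flowers / other) their orthologs in proxy
autotrophic species are principally expressed, and provides a hypergeometric
gene-set enrichment statistic with Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ParseError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "PetAssignment",
    "PetTabulation",
    "EnrichmentRow",
    "load_expression",
    "load_ortholog_map",
    "load_tissue_classes",
    "load_annotation",
    "principal_tissues",
    "pet_matrix",
    "principal_genes",
    "tabulate_lost_pets",
    "enrich",
]

#: canonical tissue-class display order (extra classes sort after these)
CLASS_ORDER = ("leaves", "roots", "flowers", "other")


class ExpressionMatrix:
    """A gene × tissue table of non-negative expression values (TPM-like)."""

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates:
            raise ValidationError("duplicated gene id in expression matrix")
        if values.columns.has_duplicates:
            raise ValidationError("duplicated tissue id in expression matrix")
        data = values.to_numpy(dtype=float)
        if data.size and ((data < 0).any() or not np.isfinite(data).all()):
            raise ValidationError("expression values must be finite and ≥ 0")
        self._values = values.astype(float)

    @property
    def values(self) -> pd.DataFrame:
        return self._values

    @property
    def gene_ids(self) -> list[str]:
        return list(self._values.index)

    @property
    def tissue_ids(self) -> list[str]:
        return list(self._values.columns)

    @property
    def n_genes(self) -> int:
        return self._values.shape[0]

    @property
    def n_tissues(self) -> int:
        return self._values.shape[1]

    def to_tsv(self, path: str | os.PathLike) -> None:
        self._values.to_csv(path, sep="\t", index_label="Gene")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ExpressionMatrix({self.n_genes} genes × {self.n_tissues} tissues)"


def load_expression(path: str | os.PathLike) -> ExpressionMatrix:
    """Read a gene × tissue TSV (first column gene ids, header tissue ids)."""
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{os.fspath(path)}: {exc}") from exc
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise ParseError(f"{os.fspath(path)}: empty expression table")
    return ExpressionMatrix(frame)


@dataclass(frozen=True)
class PetAssignment:
    """The principally expressed tissues of one gene (possibly none)."""

    gene_id: str
    pet_tissues: tuple[str, ...]
    fold_threshold: float


def _pet_mask(values: np.ndarray, fold_threshold: float) -> np.ndarray:
    """Boolean (genes × tissues) PET mask for a dense value array."""
    n_tissues = values.shape[1]
    totals = values.sum(axis=1, keepdims=True)
    other_mean = (totals - values) / (n_tissues - 1)
    return (values > 0) & (values >= fold_threshold * other_mean)


def principal_tissues(
    e: ExpressionMatrix, gene: str, fold_threshold: float = 2.0
) -> PetAssignment:
    """Classify one gene's principally expressed tissues.

    A tissue qualifies when the gene's expression there is positive and at
    least ``fold_threshold`` times the mean of its expression in every other
    tissue.  An all-zero gene has no PET.
    """
    if e.n_tissues < 2:
        raise ValidationError("PET classification needs at least two tissues")
    if fold_threshold <= 0:
        raise ValidationError("fold_threshold must be positive")
    if gene not in e.values.index:
        raise ValidationError(f"unknown gene id {gene!r}")
    row = e.values.loc[[gene]].to_numpy()
    mask = _pet_mask(row, fold_threshold)[0]
    tissues = tuple(np.asarray(e.tissue_ids, dtype=object)[mask])
    return PetAssignment(gene, tissues, float(fold_threshold))


def pet_matrix(e: ExpressionMatrix, fold_threshold: float = 2.0) -> pd.DataFrame:
    """PET classification of every gene at once, as a boolean DataFrame."""
    if e.n_tissues < 2:
        raise ValidationError("PET classification needs at least two tissues")
    if fold_threshold <= 0:
        raise ValidationError("fold_threshold must be positive")
    mask = _pet_mask(e.values.to_numpy(), fold_threshold)
    return pd.DataFrame(mask, index=e.values.index, columns=e.values.columns)


def principal_genes(
    e: ExpressionMatrix,
    focal_tissues: Sequence[str],
    fold_threshold: float = 2.0,
) -> frozenset[str]:
    """Genes principally expressed in a focal tissue set.

    A gene qualifies when its mean expression over ``focal_tissues`` is
    positive and at least ``fold_threshold`` times its mean over all other
    tissues.  ``focal_tissues`` must be a non-empty proper subset of the
    matrix's tissues.
    """
    focal = list(dict.fromkeys(focal_tissues))
    if not focal:
        raise ValidationError("focal tissue set is empty")
    unknown = [t for t in focal if t not in e.values.columns]
    if unknown:
        raise ValidationError(f"unknown tissue id(s): {unknown}")
    others = [t for t in e.tissue_ids if t not in set(focal)]
    if not others:
        raise ValidationError("focal tissue set must be a proper subset of tissues")
    if fold_threshold <= 0:
        raise ValidationError("fold_threshold must be positive")
    focal_mean = e.values[focal].mean(axis=1).to_numpy()
    other_mean = e.values[others].mean(axis=1).to_numpy()
    sel = (focal_mean > 0) & (focal_mean >= fold_threshold * other_mean)
    return frozenset(np.asarray(e.gene_ids, dtype=object)[sel])


def load_ortholog_map(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read a 2-column TSV mapping orthogroup id → proxy-species gene id."""
    mapping: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{os.fspath(path)}: line {lineno}: expected 2 fields"
                )
            mapping.setdefault(fields[0], []).append(fields[1])
    return mapping


def load_tissue_classes(path: str | os.PathLike) -> dict[str, str]:
    """Read a 2-column TSV mapping tissue id → tissue class."""
    classes: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{os.fspath(path)}: line {lineno}: expected 2 fields"
                )
            classes[fields[0]] = fields[1]
    return classes


def load_annotation(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read a 2-column TSV mapping term id → gene id into term gene sets."""
    annotation: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{os.fspath(path)}: line {lineno}: expected 2 fields"
                )
            annotation.setdefault(fields[0], set()).add(fields[1])
    return annotation


@dataclass(frozen=True)
class PetTabulation:
    """Per-tissue-class tabulation of a lost-orthogroup cohort's proxy PETs.

    ``counts[c]`` is the number of lost orthogroups with at least one mapped
    proxy gene principally expressed in a tissue of class ``c`` (an orthogroup
    may contribute to several classes).  Two normalisations are reported:
    ``pct_of_class_universe`` divides by the number of *all* mapped
    orthogroups (lost or not) whose PETs fall in the class, and
    ``pct_of_cohort`` divides by the cohort size.
    """

    classes: tuple[str, ...]
    counts: dict[str, int]
    universe_counts: dict[str, int]
    pct_of_class_universe: dict[str, float]
    pct_of_cohort: dict[str, float]
    n_lost: int
    n_unmapped: int
    n_without_pet: int


def _og_classes(
    genes: list[str],
    pets: Mapping[str, Iterable[str]],
    class_map: Mapping[str, str],
) -> set[str]:
    classes: set[str] = set()
    for gene in genes:
        for tissue in pets.get(gene, ()):  # genes without PET contribute nothing
            classes.add(class_map[tissue])
    return classes


def tabulate_lost_pets(
    lost: Iterable[str],
    ortholog_map: Mapping[str, list[str]],
    pets: Mapping[str, Iterable[str]] | pd.DataFrame,
    class_map: Mapping[str, str],
) -> PetTabulation:
    """Tabulate in which tissue classes lost orthogroups' proxies are expressed.

    Parameters
    ----------
    lost
        Orthogroup ids lost in the target species.
    ortholog_map
        Orthogroup id → list of proxy-species gene ids (one-to-many allowed;
        an orthogroup's classes are the union over its mapped genes).
    pets
        Per proxy gene, its PET tissues — either a mapping to iterables of
        tissue ids or a boolean gene × tissue DataFrame from
        :func:`pet_matrix`.
    class_map
        Tissue id → tissue class; must cover every PET tissue encountered.

    Lost orthogroups missing from the map are tallied as ``n_unmapped``;
    mapped ones whose proxies have no PET at all as ``n_without_pet``.
    """
    if isinstance(pets, pd.DataFrame):
        pets = {
            gene: tuple(pets.columns[row.to_numpy()])
            for gene, row in pets.iterrows()
        }
    observed_tissues = {t for ts in pets.values() for t in ts}
    uncovered = observed_tissues - set(class_map)
    if uncovered:
        raise ValidationError(f"tissue(s) missing from class map: {sorted(uncovered)}")

    lost = list(dict.fromkeys(lost))
    class_values = list(dict.fromkeys(class_map.values()))
    classes = tuple(
        sorted(class_values, key=lambda c: (CLASS_ORDER.index(c) if c in CLASS_ORDER else len(CLASS_ORDER), c))
    )

    universe_counts = {c: 0 for c in classes}
    for og, genes in ortholog_map.items():
        for c in _og_classes(genes, pets, class_map):
            universe_counts[c] += 1

    counts = {c: 0 for c in classes}
    n_unmapped = 0
    n_without_pet = 0
    for og in lost:
        if og not in ortholog_map:
            n_unmapped += 1
            continue
        og_classes = _og_classes(ortholog_map[og], pets, class_map)
        if not og_classes:
            n_without_pet += 1
            continue
        for c in og_classes:
            counts[c] += 1

    n_lost = len(lost)
    pct_universe = {
        c: (100.0 * counts[c] / universe_counts[c]) if universe_counts[c] else 0.0
        for c in classes
    }
    pct_cohort = {
        c: (100.0 * counts[c] / n_lost) if n_lost else 0.0 for c in classes
    }
    return PetTabulation(
        classes=classes,
        counts=counts,
        universe_counts=universe_counts,
        pct_of_class_universe=pct_universe,
        pct_of_cohort=pct_cohort,
        n_lost=n_lost,
        n_unmapped=n_unmapped,
        n_without_pet=n_without_pet,
    )


@dataclass(frozen=True)
class EnrichmentRow:
    """One term's hypergeometric enrichment result."""

    term: str
    k: int  # query genes annotated with the term
    K: int  # universe genes annotated with the term
    n: int  # query size
    N: int  # universe size
    p_value: float
    q_value: float


def enrich(
    query: Iterable[str],
    universe: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation test per annotation term.

    For each term with at least one query hit, the upper-tail probability
    ``P(X ≥ k)`` of drawing ``k`` annotated genes in a query of size ``n``
    from a universe of ``N`` genes containing ``K`` annotated ones.  q-values
    are Benjamini–Hochberg adjusted across the tested terms only; rows are
    returned sorted by p-value (term id breaking ties).
    """
    query_set = set(query)
    universe_set = set(universe)
    if not query_set or not universe_set:
        raise ValidationError("query and universe must be non-empty")
    if not query_set <= universe_set:
        raise ValidationError("query must be a subset of the universe")
    N, n = len(universe_set), len(query_set)
    rows: list[tuple[str, int, int, float]] = []
    for term, genes in annotation.items():
        term_genes = set(genes) & universe_set
        k = len(term_genes & query_set)
        if k == 0:
            continue  # untested terms are excluded before adjustment
        K = len(term_genes)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, p))
    if not rows:
        return []
    pvals = [r[3] for r in rows]
    qvals = multipletests(pvals, method="fdr_bh")[1]
    result = [
        EnrichmentRow(term=t, k=k, K=K, n=n, N=N, p_value=p, q_value=float(q))
        for (t, k, K, p), q in zip(rows, qvals)
    ]
    result.sort(key=lambda r: (r.p_value, r.term))
    return result
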
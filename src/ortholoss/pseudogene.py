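"""Pseudogene lesion detection: frameshifts and premature stop codons.

Candidate coding sequences are globally aligned (Needleman–Wunsch with affine
gaps, via Biopython's ``PairwiseAligner``) against an intact reference CDS.
Two lesion kinds are then read off the alignment:

* **frameshift** — a maximal run of alignment gaps whose net indel length is
  not divisible by three;
* **premature stop** — a TAA/TAG/TGA codon in the candidate, read
  sequentially in triplets so that upstream indels shift the frame exactly as
  they would in translation, at a reference position before the reference's
  terminal codon.

A candidate with at least one lesion is classified as a pseudogene.
Coordinates are 1-based on the reference CDS.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import Align, SeqIO
from Bio.Seq import reverse_complement

from .errors import ParseError, ValidationError

__all__ = [
    "STOP_CODONS",
    "CdsPair",
    "Lesion",
    "LesionReport",
    "align_pair",
    "detect_lesions",
    "scan_pair",
    "scan_pairs",
    "read_fasta_pairs",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_ALPHABET = frozenset("ACGTN")

#: default alignment scores (match, mismatch, gap open, gap extend)
DEFAULT_SCORES = {"match": 2.0, "mismatch": -3.0, "gap_open": -5.0, "gap_extend": -2.0}


def _check_sequence(seq: str, label: str) -> str:
    if not seq:
        raise ValidationError(f"{label} sequence is empty")
    seq = seq.upper()
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValidationError(f"{label} sequence has illegal character(s) {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class CdsPair:
    """A reference CDS and a candidate sequence to scan against it.

    The reference must have length divisible by three and no in-frame stop
    codon before its terminal codon; the candidate is taken as sense-strand.
    """

    pair_id: str
    reference: str
    candidate: str

    def __post_init__(self):
        ref = _check_sequence(self.reference, "reference")
        cand = _check_sequence(self.candidate, "candidate")
        if len(ref) % 3 != 0:
            raise ValidationError("reference CDS length must be divisible by 3")
        for i in range(0, len(ref) - 3, 3):
            if ref[i : i + 3] in STOP_CODONS:
                raise ValidationError(
                    f"reference has internal stop codon at position {i + 1}"
                )
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "candidate", cand)


def _make_aligner(match: float, mismatch: float, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    # a gap of length L scores gap_open + L * gap_extend
    return Align.PairwiseAligner(
        mode="global",
        match_score=match,
        mismatch_score=mismatch,
        open_gap_score=gap_open + gap_extend,
        extend_gap_score=gap_extend,
    )


def align_pair(
    pair: CdsPair,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
):
    """Global affine-gap alignment of candidate against reference.

    Returns Biopython's optimal :class:`~Bio.Align.Alignment`; when several
    alignments share the optimal score the aligner's first traceback is taken,
    which is deterministic for fixed inputs and scores.
    """
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    return aligner.align(pair.reference, pair.candidate)[0]


@dataclass(frozen=True)
class Lesion:
    """A single disabling lesion on the reference coordinate system.

    ``detail`` is the signed net indel length for frameshifts (insertions
    positive, deletions negative) and the stop triplet for premature stops.
    """

    kind: str  # "frameshift" | "premature_stop"
    ref_position: int  # 1-based on the reference CDS
    detail: int | str


@dataclass(frozen=True)
class LesionReport:
    """All lesions found in one candidate, ordered by reference position."""

    pair_id: str
    lesions: tuple[Lesion, ...]

    @property
    def is_pseudogene(self) -> bool:
        return len(self.lesions) > 0

    @property
    def frame_disrupted(self) -> bool:
        """Whether the candidate ends out of frame relative to the reference.

        The net indel length over all frameshift lesions, modulo 3.  A pair of
        canceling 1-base gaps yields two frameshift lesions but leaves the
        downstream frame intact; this property distinguishes that case.
        """
        net = sum(l.detail for l in self.lesions if l.kind == "frameshift")
        return net % 3 != 0

    def lesions_of_kind(self, kind: str) -> tuple[Lesion, ...]:
        return tuple(l for l in self.lesions if l.kind == kind)


def detect_lesions(alignment, pair: CdsPair) -> LesionReport:
    """Read frameshift and premature-stop lesions off a pairwise alignment.

    Frameshifts: each maximal run of gap columns whose net length (candidate
    insertions minus deletions) is not divisible by three, reported at the
    first reference base the run touches.  Premature stops: the candidate's
    aligned bases are read in triplets from its start — upstream indels thus
    shift the reading frame cumulatively — and every stop triplet whose
    reference position precedes the reference's terminal codon is reported.
    """
    ref_aln = str(alignment[0])
    cand_aln = str(alignment[1])
    ref_len = len(pair.reference)
    frameshifts: list[Lesion] = []
    cand_bases: list[tuple[str, int]] = []  # (base, ref position of its column)

    i = 0
    ref_pos = 0  # reference bases consumed so far
    ncol = len(ref_aln)
    while i < ncol:
        if ref_aln[i] == "-" or cand_aln[i] == "-":
            start_ref_pos = ref_pos
            ins = dele = 0
            while i < ncol and (ref_aln[i] == "-" or cand_aln[i] == "-"):
                if ref_aln[i] == "-":
                    ins += 1
                    cand_bases.append(
                        (cand_aln[i], min(start_ref_pos + 1, ref_len))
                    )
                else:
                    ref_pos += 1
                    dele += 1
                i += 1
            net = ins - dele
            if net % 3 != 0:
                frameshifts.append(
                    Lesion("frameshift", min(start_ref_pos + 1, ref_len), net)
                )
        else:
            ref_pos += 1
            cand_bases.append((cand_aln[i], ref_pos))
            i += 1

    stops: list[Lesion] = []
    for m in range(len(cand_bases) // 3):
        triplet = cand_bases[3 * m : 3 * m + 3]
        codon = "".join(base for base, _ in triplet)
        if codon in STOP_CODONS:
            position = triplet[0][1]
            if position < ref_len - 2:  # strictly before the terminal codon
                stops.append(Lesion("premature_stop", position, codon))

    lesions = sorted(frameshifts + stops, key=lambda l: (l.ref_position, l.kind))
    return LesionReport(pair_id=pair.pair_id, lesions=tuple(lesions))


def scan_pair(
    pair: CdsPair,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
    scan_revcomp: bool = False,
) -> LesionReport:
    """Align one pair and report its lesions.

    With ``scan_revcomp`` the reverse complement of the candidate is also
    aligned and the strand with the higher alignment score is scanned.
    """
    alignment = align_pair(pair, match, mismatch, gap_open, gap_extend)
    if scan_revcomp:
        rc_pair = CdsPair(pair.pair_id, pair.reference, reverse_complement(pair.candidate))
        rc_alignment = align_pair(rc_pair, match, mismatch, gap_open, gap_extend)
        if rc_alignment.score > alignment.score:
            return detect_lesions(rc_alignment, rc_pair)
    return detect_lesions(alignment, pair)


def scan_pairs(pairs: Iterable[CdsPair], **kwargs) -> list[LesionReport]:
    """Scan a collection of CDS pairs (see :func:`scan_pair` for options)."""
    return [scan_pair(pair, **kwargs) for pair in pairs]


def read_fasta_pairs(
    reference_fasta: str | os.PathLike,
    candidate_fasta: str | os.PathLike,
    pairing: Sequence[tuple[str, str]] | None = None,
) -> list[CdsPair]:
    """Build CDS pairs from two FASTA files.

    Records are paired by shared id, or explicitly via ``pairing`` (a list of
    ``(reference_id, candidate_id)`` tuples, e.g. parsed from a 2-column TSV).
    """
    refs = {rec.id: str(rec.seq) for rec in SeqIO.parse(os.fspath(reference_fasta), "fasta")}
    cands = {rec.id: str(rec.seq) for rec in SeqIO.parse(os.fspath(candidate_fasta), "fasta")}
    if not refs or not cands:
        raise ParseError("empty FASTA input")
    pairs: list[CdsPair] = []
    if pairing is None:
        shared = [rid for rid in refs if rid in cands]
        if not shared:
            raise ValidationError("no shared record ids between the FASTA files")
        for rid in shared:
            pairs.append(CdsPair(rid, refs[rid], cands[rid]))
    else:
        for rid, cid in pairing:
            if rid not in refs:
                raise ValidationError(f"reference id {rid!r} not in FASTA")
            if cid not in cands:
                raise ValidationError(f"candidate id {cid!r} not in FASTA")
            pairs.append(CdsPair(f"{rid}|{cid}" if rid != cid else rid, refs[rid], cands[cid]))
    return pairs
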
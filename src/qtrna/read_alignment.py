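"""Optimal local alignment of reads with decoy-based significance.

Every read (and its reversed decoy) is aligned to all curated references by
affine-gap Smith-Waterman; alignments are ranked by score (ties share a
rank, all rank-1 hits retained).  Reversing a read preserves its length and
nucleotide composition — the only determinants of a random local-alignment
score — so decoy alignments form an empirical null distribution from which a
dataset-specific score cutoff is computed at a configurable specificity
level (fraction of decoys falling strictly below the cutoff).

Reads are assumed to be in sense orientation (direct RNA sequencing is
strand-specific); no reverse-complement search is performed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from math import ceil
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from ._sw import OP_D, OP_EQ, OP_I, OP_X, sw_affine
from .reference_curation import TRNAReference

__all__ = [
    "ScoringScheme",
    "AlignmentRecord",
    "SignificanceModel",
    "local_align",
    "align_to_references",
    "make_decoy",
    "compute_cutoff",
    "filter_significant",
    "write_sam",
    "read_sam",
]

_ENC = np.full(256, 4, np.int8)
for _i, _c in enumerate(b"ACGT"):
    _ENC[_c] = _i
    _ENC[ord(chr(_c).lower())] = _i

_OP_CHAR = {OP_EQ: "=", OP_X: "X", OP_D: "D", OP_I: "I"}
_CIGAR_RE = re.compile(r"(\d+)([MX=IDS])")


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), np.uint8)]


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap alignment scores.

    ``match`` is a positive reward; the penalties are non-positive.  A gap of
    length L costs ``gap_open + (L - 1) * gap_extend``.  Defaults are
    conventional short-read-style values; override per dataset as needed.
    """

    match: int = 2
    mismatch: int = -4
    gap_open: int = -4
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")
        if self.gap_open > self.gap_extend:
            raise ValueError("gap_open must be <= gap_extend")


@dataclass(frozen=True)
class AlignmentRecord:
    """One local alignment of a read against one reference.

    Intervals are 0-based half-open; the CIGAR covers the whole read, with
    soft clips (S) for the unaligned read ends, and uses {=, X, I, D, S}.
    """

    read_id: str
    ref_name: str
    score: int
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    cigar: str
    rank: int = 0
    is_decoy: bool = False


@dataclass(frozen=True)
class SignificanceModel:
    """Empirical decoy-null significance of alignment scores."""

    real_scores: tuple
    decoy_scores: tuple
    specificity_level: float
    cutoff: int
    realized_specificity: float


def _ops_to_cigar(ops: np.ndarray, lead_clip: int, tail_clip: int) -> str:
    parts: list[str] = []
    if lead_clip:
        parts.append(f"{lead_clip}S")
    run_char = ""
    run_len = 0
    for op in ops:
        c = _OP_CHAR[int(op)]
        if c == run_char:
            run_len += 1
        else:
            if run_len:
                parts.append(f"{run_len}{run_char}")
            run_char = c
            run_len = 1
    if run_len:
        parts.append(f"{run_len}{run_char}")
    if tail_clip:
        parts.append(f"{tail_clip}S")
    return "".join(parts)


def local_align(
    read_seq: str,
    ref_seq: str,
    scheme: ScoringScheme = ScoringScheme(),
    read_id: str = "read",
    ref_name: str = "ref",
) -> AlignmentRecord:
    """Best-scoring affine-gap local alignment of ``read_seq`` to ``ref_seq``.

    Empty inputs yield a score-0 record with empty intervals.  Tie-breaking
    is deterministic (see :mod:`qtrna._sw`).
    """
    if not read_seq or not ref_seq:
        return AlignmentRecord(
            read_id, ref_name, 0, 0, 0, 0, 0,
            cigar=f"{len(read_seq)}S" if read_seq else "",
        )
    score, rs, re_, cs, ce, ops = sw_affine(
        _encode(read_seq),
        _encode(ref_seq),
        np.int32(scheme.match),
        np.int32(scheme.mismatch),
        np.int32(scheme.gap_open),
        np.int32(scheme.gap_extend),
    )
    if score == 0:
        return AlignmentRecord(
            read_id, ref_name, 0, 0, 0, 0, 0, cigar=f"{len(read_seq)}S"
        )
    cigar = _ops_to_cigar(ops, rs, len(read_seq) - re_)
    return AlignmentRecord(
        read_id=read_id,
        ref_name=ref_name,
        score=int(score),
        ref_start=int(cs),
        ref_end=int(ce),
        read_start=int(rs),
        read_end=int(re_),
        cigar=cigar,
    )


def align_to_references(
    read_id: str,
    read_seq: str,
    refs: Sequence[TRNAReference],
    scheme: ScoringScheme = ScoringScheme(),
    keep_all_ranks: bool = False,
    is_decoy: bool = False,
) -> list[AlignmentRecord]:
    """Align one read to every reference and rank hits by score.

    Equal scores share a rank (dense ranking); by default only rank-1
    records are returned, all of them when several references tie at the
    top score.
    """
    if not refs:
        raise ValueError("at least one reference is required")
    hits = [
        local_align(read_seq, r.full_sequence, scheme, read_id, r.name)
        for r in refs
    ]
    order = {s: i + 1 for i, s in enumerate(sorted({h.score for h in hits}, reverse=True))}
    ranked = [
        replace(h, rank=order[h.score], is_decoy=is_decoy) for h in hits
    ]
    ranked.sort(key=lambda h: (h.rank, h.ref_name))
    if keep_all_ranks:
        return ranked
    return [h for h in ranked if h.rank == 1]


def make_decoy(read_seq: str) -> str:
    """Reversed (not complemented) read: same length and composition."""
    return read_seq[::-1]


def compute_cutoff(
    real_scores: Iterable[int],
    decoy_scores: Iterable[int],
    level: float = 0.95,
) -> SignificanceModel:
    """Smallest integer cutoff with >= ``level`` of decoys strictly below it.

    Alignments scoring at or above the cutoff are called significant;
    specificity is TN / (TN + FP) on the decoy set.
    """
    real = tuple(int(s) for s in real_scores)
    decoy = tuple(sorted(int(s) for s in decoy_scores))
    if not decoy:
        raise ValueError("decoy score set is empty; cutoff undefined")
    n = len(decoy)
    k = ceil(level * n)
    if k <= 0:
        cutoff = min(decoy + real) if real else decoy[0]
    else:
        cutoff = decoy[k - 1] + 1
    realized = sum(1 for d in decoy if d < cutoff) / n
    return SignificanceModel(
        real_scores=real,
        decoy_scores=decoy,
        specificity_level=level,
        cutoff=int(cutoff),
        realized_specificity=realized,
    )


def filter_significant(
    alignments: Iterable[AlignmentRecord],
    model: SignificanceModel,
    keep_multimapped: bool = False,
) -> list[AlignmentRecord]:
    """Retain rank-1, non-decoy alignments scoring at or above the cutoff.

    A read whose rank-1 hits land on more than one distinct reference is
    dropped entirely unless ``keep_multimapped``.
    """
    by_read: dict[str, list[AlignmentRecord]] = {}
    for a in alignments:
        if a.is_decoy or a.rank != 1 or a.score < model.cutoff:
            continue
        by_read.setdefault(a.read_id, []).append(a)
    out: list[AlignmentRecord] = []
    for hits in by_read.values():
        refs = {h.ref_name for h in hits}
        if len(refs) > 1 and not keep_multimapped:
            continue
        out.extend(hits)
    out.sort(key=lambda h: (h.ref_name, h.ref_start, h.read_id))
    return out


def cigar_consumed_lengths(cigar: str) -> tuple[int, int]:
    """(read bases, reference bases) consumed by an {M,=,X,I,D,S} CIGAR."""
    read_len = 0
    ref_len = 0
    for num, op in _CIGAR_RE.findall(cigar):
        num = int(num)
        if op in "M=X":
            read_len += num
            ref_len += num
        elif op == "I":
            read_len += num
        elif op == "D":
            ref_len += num
        # S consumes neither aligned interval
    return read_len, ref_len


RANK_TAG = "zr"  # custom SAM tag carrying the alignment rank


def write_sam(
    records: Iterable[AlignmentRecord],
    reads: Mapping[str, str],
    refs: Sequence[TRNAReference],
    path: str | Path,
) -> None:
    """Write alignments as SAM (score in AS, rank in the ``zr`` tag)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": r.name, "LN": len(r.full_sequence)} for r in refs],
    }
    tid = {r.name: i for i, r in enumerate(refs)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            seq = reads[rec.read_id]
            a.query_sequence = seq
            a.flag = 0
            a.reference_id = tid[rec.ref_name]
            a.reference_start = rec.ref_start
            a.mapping_quality = 255
            a.cigarstring = rec.cigar
            a.set_tag("AS", rec.score, "i")
            a.set_tag(RANK_TAG, rec.rank, "i")
            out.write(a)


def read_sam(path: str | Path) -> tuple[list[AlignmentRecord], dict[str, str]]:
    """Read a SAM/BAM back into alignment records plus read sequences."""
    records: list[AlignmentRecord] = []
    reads: dict[str, str] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped or a.query_sequence is None:
                continue
            cigar = a.cigarstring or ""
            lead = 0
            m = re.match(r"^(\d+)S", cigar)
            if m:
                lead = int(m.group(1))
            read_len, ref_len = cigar_consumed_lengths(cigar)
            records.append(
                AlignmentRecord(
                    read_id=a.query_name,
                    ref_name=a.reference_name,
                    score=int(a.get_tag("AS")) if a.has_tag("AS") else 0,
                    ref_start=a.reference_start,
                    ref_end=a.reference_start + ref_len,
                    read_start=lead,
                    read_end=lead + read_len,
                    cigar=cigar,
                    rank=int(a.get_tag(RANK_TAG)) if a.has_tag(RANK_TAG) else 1,
                )
            )
            reads[a.query_name] = a.query_sequence
    return records, reads
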
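"""Per-position pileup counts and basecalling-error rates.

Significant alignments are converted into one row per reference position
with coverage, base composition, deletion and insertion counts; from these,
mismatch/deletion/insertion rates and base frequencies are derived.  The
resulting TSV table (ref_name, full_index, canonical_position, ref_base,
coverage, A, C, G, T, del, ins) is the interchange format consumed by the
comparative scoring step.

Conventions: an insertion between reference indices i and i+1 is attributed
to index i (the 5' flanking base) and counts once per read per junction
regardless of its length; soft-clipped bases are ignored; deleted positions
count toward coverage.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .read_alignment import AlignmentRecord, cigar_consumed_lengths
from .reference_curation import TRNAReference

__all__ = [
    "build_pileup",
    "error_rates",
    "base_frequencies",
    "merge_pileups",
    "write_pileup",
    "read_pileup",
    "DEFAULT_MIN_COVERAGE",
]

DEFAULT_MIN_COVERAGE = 10

_BASES = "ACGT"
_CIGAR_RE = re.compile(r"(\d+)([MX=IDS])")


class PileupError(ValueError):
    """Raised when an alignment is inconsistent with its CIGAR."""


def build_pileup(
    alignments: Iterable[AlignmentRecord],
    reads: Mapping[str, str],
    refs: Sequence[TRNAReference],
) -> dict[str, pd.DataFrame]:
    """Tally per-position counts for each reference.

    Returns one DataFrame per reference name, with a row for every
    reference index (zero-coverage rows included so downstream joins are
    positional).  Invariant: A + C + G + T + del == coverage at every row.
    """
    by_name = {r.name: r for r in refs}
    counts: dict[str, np.ndarray] = {}
    ins: dict[str, np.ndarray] = {}
    for r in refs:
        L = len(r.full_sequence)
        counts[r.name] = np.zeros((5, L), dtype=np.int64)  # A C G T del
        ins[r.name] = np.zeros(L, dtype=np.int64)

    base_row = {b: i for i, b in enumerate(_BASES)}
    for aln in alignments:
        ref = by_name.get(aln.ref_name)
        if ref is None:
            raise PileupError(f"alignment of {aln.read_id!r} to unknown reference {aln.ref_name!r}")
        seq = reads[aln.read_id]
        read_len, ref_len = cigar_consumed_lengths(aln.cigar)
        if ref_len != aln.ref_end - aln.ref_start or read_len != aln.read_end - aln.read_start:
            raise PileupError(
                f"read {aln.read_id!r}: CIGAR {aln.cigar} inconsistent with "
                f"intervals ref[{aln.ref_start},{aln.ref_end}) read[{aln.read_start},{aln.read_end})"
            )
        cmat = counts[aln.ref_name]
        ivec = ins[aln.ref_name]
        i = aln.ref_start  # next reference index
        q = 0  # next read index (CIGAR covers the whole read incl. clips)
        ref_seq = ref.full_sequence
        for num_s, op in _CIGAR_RE.findall(aln.cigar):
            num = int(num_s)
            if op == "S":
                q += num
            elif op in "M=X":
                for k in range(num):
                    b = base_row.get(seq[q + k].upper())
                    if b is None:  # ambiguous base: count as non-reference miscall
                        b = (base_row[ref_seq[i + k]] + 1) % 4
                    cmat[b, i + k] += 1
                i += num
                q += num
            elif op == "D":
                cmat[4, i : i + num] += 1
                i += num
            elif op == "I":
                if i > aln.ref_start:  # attribute to the 5' flanking base
                    ivec[i - 1] += 1
                q += num

    out: dict[str, pd.DataFrame] = {}
    for r in refs:
        cmat = counts[r.name]
        df = pd.DataFrame(
            {
                "ref_name": r.name,
                "full_index": np.arange(len(r.full_sequence)),
                "canonical_position": list(r.coordinate_map),
                "ref_base": list(r.full_sequence),
                "coverage": cmat.sum(axis=0),
                "A": cmat[0],
                "C": cmat[1],
                "G": cmat[2],
                "T": cmat[3],
                "del": cmat[4],
                "ins": ins[r.name],
            }
        )
        out[r.name] = df
    return out


def error_rates(
    columns: pd.DataFrame, min_cov: int = DEFAULT_MIN_COVERAGE
) -> pd.DataFrame:
    """Per-position mismatch/deletion/insertion rates and base frequencies.

    mismatch_rate = (coverage - count[ref_base] - del) / coverage,
    deletion_rate = del / coverage, insertion_rate = ins / coverage.
    Rows with coverage below ``min_cov`` have NaN rates (reported missing).
    Base frequencies are over non-deleted observations.
    """
    df = columns.copy()
    cov = df["coverage"].to_numpy(float)
    ref_count = np.array(
        [row[b] if b in _BASES else 0 for b, row in zip(df["ref_base"], df.to_dict("records"))],
        dtype=float,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        df["mismatch_rate"] = (cov - ref_count - df["del"]) / cov
        df["deletion_rate"] = df["del"] / cov
        df["insertion_rate"] = df["ins"] / cov
        non_del = cov - df["del"].to_numpy(float)
        for b in _BASES:
            df[f"freq_{b}"] = df[b] / non_del
    low = cov < min_cov
    rate_cols = ["mismatch_rate", "deletion_rate", "insertion_rate"] + [
        f"freq_{b}" for b in _BASES
    ]
    df.loc[low, rate_cols] = np.nan
    return df


def base_frequencies(column: pd.Series | Mapping) -> dict[str, float]:
    """Base composition among non-deleted observations of one pileup row."""
    non_del = sum(int(column[b]) for b in _BASES)
    if non_del == 0:
        raise PileupError("base frequencies undefined: all observations deleted")
    return {b: int(column[b]) / non_del for b in _BASES}


def merge_pileups(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Sum count columns across pileup tables over the same reference."""
    if not tables:
        raise ValueError("no pileup tables to merge")
    first = tables[0]
    keys = ["ref_name", "full_index", "canonical_position", "ref_base"]
    merged = first[keys].copy()
    for col in ["coverage", "A", "C", "G", "T", "del", "ins"]:
        acc = first[col].to_numpy().copy()
        for t in tables[1:]:
            if len(t) != len(first) or (t["full_index"].to_numpy() != first["full_index"].to_numpy()).any():
                raise ValueError("pileup tables cover different references/positions")
            acc = acc + t[col].to_numpy()
        merged[col] = acc
    return merged


def write_pileup(tables: Mapping[str, pd.DataFrame] | pd.DataFrame, path: str | Path) -> None:
    """Write pileup table(s) to one TSV (multiple references concatenated)."""
    if isinstance(tables, pd.DataFrame):
        df = tables
    else:
        df = pd.concat(list(tables.values()), ignore_index=True)
    df.to_csv(path, sep="\t", index=False)


def read_pileup(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"canonical_position": str})
    # canonical positions are ints for body rows, labels for adapters
    def _parse(v):
        try:
            return int(v)
        except (TypeError, ValueError):
            return v
    df["canonical_position"] = df["canonical_position"].map(_parse)
    return df
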
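"""Curation of tRNA alignment references.

Builds the reference set that reads are aligned against: tRNA body
sequences are deduplicated, converted to the DNA alphabet (U -> T, matching
basecaller output), flanked with the 5'/3' splint-adapter sequences that are
ligated to the molecules during library preparation, and annotated with an
anticodon-anchored coordinate system in which the first anticodon base is
canonical position 34 (the wobble position, where queuosine and its
precursors are installed).

Canonical numbering is linear: position increases by +1 per body base and is
anchored so that the anticodon starts at 34.  Sprinzl numbering with gaps is
deliberately not modelled.  Internally all coordinates are 0-based half-open;
canonical positions are 1-anchored biological labels used only in outputs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "RawTRNARecord",
    "TRNAReference",
    "ADAPTER5_LABEL",
    "ADAPTER3_LABEL",
    "WOBBLE_POSITION",
    "load_trna_fasta",
    "curate_references",
    "write_references_fasta",
    "write_coordinate_table",
]

#: Canonical position of the first anticodon base (the wobble base).
WOBBLE_POSITION = 34

#: Labels used in coordinate maps for adapter-derived reference positions.
ADAPTER5_LABEL = "adapter5"
ADAPTER3_LABEL = "adapter3"

# Anticodon triplets are searched for only inside this body window
# (0-based start indices); a triplet found elsewhere is never trusted,
# because silently misplacing position 34 would corrupt every downstream
# modification call.
ANTICODON_SEARCH_WINDOW = (25, 45)

_VALID_ALPHABET = set("ACGUT")


class ReferenceError(ValueError):
    """Raised for malformed or ambiguous reference input."""


@dataclass(frozen=True)
class RawTRNARecord:
    """One tRNA sequence as read from FASTA, before curation.

    Parameters
    ----------
    name:
        Unique identifier (FASTA header word).
    sequence:
        Body sequence over A/C/G/U/T (case-insensitive).
    anticodon:
        Optional anticodon triplet (e.g. ``"GTC"`` for tRNA-Asp).
    anticodon_start:
        Optional 0-based index of the first anticodon base in ``sequence``.
    """

    name: str
    sequence: str
    anticodon: str | None = None
    anticodon_start: int | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ReferenceError(f"record {self.name!r}: empty sequence")
        bad = set(seq) - _VALID_ALPHABET
        if bad:
            raise ReferenceError(
                f"record {self.name!r}: invalid characters {sorted(bad)}"
            )
        if self.anticodon is not None:
            object.__setattr__(self, "anticodon", self.anticodon.upper())
            if len(self.anticodon) != 3:
                raise ReferenceError(
                    f"record {self.name!r}: anticodon {self.anticodon!r} is not a triplet"
                )
        if self.anticodon_start is not None:
            if not 0 <= self.anticodon_start <= len(seq) - 3:
                raise ReferenceError(
                    f"record {self.name!r}: anticodon_start {self.anticodon_start} "
                    f"out of range for length-{len(seq)} sequence"
                )


@dataclass(frozen=True)
class TRNAReference:
    """A curated, adapter-flanked tRNA reference with coordinate map."""

    name: str
    body: str
    adapter5: str
    adapter3: str
    anticodon_start_body: int
    coordinate_map: tuple = field(repr=False, default=())

    def __post_init__(self) -> None:
        if not self.coordinate_map:
            object.__setattr__(
                self, "coordinate_map", tuple(self._build_coordinate_map())
            )

    @property
    def full_sequence(self) -> str:
        return self.adapter5 + self.body + self.adapter3

    @property
    def anticodon(self) -> str:
        s = self.anticodon_start_body
        return self.body[s : s + 3]

    def _build_coordinate_map(self):
        # body base i gets canonical position i - anticodon_start + 34,
        # so the first anticodon base lands exactly on 34.
        offset = WOBBLE_POSITION - self.anticodon_start_body
        for _ in self.adapter5:
            yield ADAPTER5_LABEL
        for i in range(len(self.body)):
            yield i + offset
        for _ in self.adapter3:
            yield ADAPTER3_LABEL

    def canonical_position(self, full_index: int):
        """Canonical label for a 0-based index into ``full_sequence``."""
        return self.coordinate_map[full_index]

    def full_index(self, canonical: int) -> int:
        """0-based full-sequence index of a canonical body position."""
        body_i = canonical - (WOBBLE_POSITION - self.anticodon_start_body)
        if not 0 <= body_i < len(self.body):
            raise IndexError(
                f"canonical position {canonical} outside body of {self.name}"
            )
        return len(self.adapter5) + body_i


_TRIPLET_RE = re.compile(r"^[ACGUT]{3}$")


def _anticodon_from_header(name: str) -> str | None:
    """Extract an anticodon triplet from a GtRNAdb-style header.

    ``tRNA-Asp-GTC-1-1`` yields ``GTC``.  The first '-'-separated token that
    is a pure A/C/G/T/U triplet is taken; headers without one yield None.
    """
    for token in name.split("-"):
        if _TRIPLET_RE.match(token):
            return token.upper()
    return None


def load_trna_fasta(
    path: str | Path,
    annotations: str | Path | pd.DataFrame | None = None,
) -> list[RawTRNARecord]:
    """Load tRNA records from FASTA, with optional sidecar annotations.

    The sidecar is a TSV with columns ``name`` and ``anticodon_start``
    (0-based index of the first anticodon base) and optionally ``anticodon``.
    Sidecar values take precedence over header parsing.
    """
    path = Path(path)
    sidecar: dict[str, dict] = {}
    if annotations is not None:
        if isinstance(annotations, pd.DataFrame):
            ann = annotations
        else:
            ann = pd.read_csv(annotations, sep="\t")
        if "name" not in ann.columns:
            raise ReferenceError("annotation sidecar lacks a 'name' column")
        for _, row in ann.iterrows():
            sidecar[str(row["name"])] = row.to_dict()

    records: list[RawTRNARecord] = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # Biopython names the offending content
        raise ReferenceError(f"malformed FASTA {path}: {exc}") from exc
    for entry in parsed:
        name = entry.id
        if name in seen:
            raise ReferenceError(f"duplicate record name {name!r} in {path}")
        seen.add(name)
        seq = str(entry.seq)
        if not seq:
            raise ReferenceError(f"record {name!r} in {path} has empty sequence")
        ann_row = sidecar.get(name, {})
        anticodon = ann_row.get("anticodon")
        if anticodon is None or (isinstance(anticodon, float) and pd.isna(anticodon)):
            anticodon = _anticodon_from_header(name)
        start = ann_row.get("anticodon_start")
        if start is not None and not pd.isna(start):
            start = int(start)
        else:
            start = None
        records.append(
            RawTRNARecord(
                name=name, sequence=seq, anticodon=anticodon, anticodon_start=start
            )
        )
    return records


def _resolve_anticodon_start(record: RawTRNARecord, body: str) -> int:
    """Resolve the 0-based anticodon start in the (U->T converted) body.

    Precedence: explicit ``anticodon_start`` > unique match of the annotated
    triplet within the anticodon-loop window > error.
    """
    if record.anticodon_start is not None:
        return record.anticodon_start
    if record.anticodon is None:
        raise ReferenceError(
            f"record {record.name!r}: no anticodon_start and no anticodon triplet"
        )
    triplet = record.anticodon.replace("U", "T")
    lo, hi = ANTICODON_SEARCH_WINDOW
    hits = [
        s
        for s in range(lo, min(hi - 2, len(body) - 2))
        if body[s : s + 3] == triplet
    ]
    if len(hits) != 1:
        raise ReferenceError(
            f"record {record.name!r}: anticodon {triplet} matched {len(hits)} "
            f"times in body window {lo}-{hi}; cannot anchor position 34"
        )
    return hits[0]


def curate_references(
    records: Iterable[RawTRNARecord],
    adapter5: str = "",
    adapter3: str = "",
) -> list[TRNAReference]:
    """Curate raw records into adapter-flanked alignment references.

    Identical bodies (after U->T) are collapsed to a single reference named
    by the lexicographically smallest member.  Adapters may be empty
    (degenerate reference without splint flanks).
    """
    adapter5 = adapter5.upper().replace("U", "T")
    adapter3 = adapter3.upper().replace("U", "T")
    by_body: dict[str, tuple[str, int]] = {}
    for rec in records:
        body = rec.sequence.replace("U", "T")
        start = _resolve_anticodon_start(rec, body)
        if body in by_body:
            prev_name, prev_start = by_body[body]
            if prev_start != start:
                raise ReferenceError(
                    f"records {prev_name!r} and {rec.name!r} share a body but "
                    f"disagree on anticodon placement"
                )
            by_body[body] = (min(prev_name, rec.name), start)
        else:
            by_body[body] = (rec.name, start)
    refs = [
        TRNAReference(
            name=name,
            body=body,
            adapter5=adapter5,
            adapter3=adapter3,
            anticodon_start_body=start,
        )
        for body, (name, start) in by_body.items()
    ]
    refs.sort(key=lambda r: r.name)
    names = [r.name for r in refs]
    if len(set(names)) != len(names):
        raise ReferenceError("curated reference names are not unique")
    return refs


def write_references_fasta(refs: Sequence[TRNAReference], path: str | Path) -> None:
    """Write curated full sequences (adapter5 + body + adapter3) to FASTA."""
    records = [
        SeqRecord(Seq(r.full_sequence), id=r.name, description="") for r in refs
    ]
    SeqIO.write(records, str(path), "fasta")


def load_curated(
    fasta: str | Path, coordinates: str | Path | pd.DataFrame
) -> list[TRNAReference]:
    """Reload curated references from full-sequence FASTA + coordinate TSV.

    Inverse of :func:`write_references_fasta` + :func:`write_coordinate_table`:
    adapter extents and the anticodon anchor are reconstructed from the
    coordinate table's labels.
    """
    coords = (
        coordinates
        if isinstance(coordinates, pd.DataFrame)
        else pd.read_csv(coordinates, sep="\t", dtype={"canonical_position": str})
    )
    seqs = {e.id: str(e.seq).upper() for e in SeqIO.parse(str(fasta), "fasta")}
    refs = []
    for name, grp in coords.groupby("name", sort=True):
        if name not in seqs:
            raise ReferenceError(f"coordinate table names {name!r} missing from FASTA")
        full = seqs[name]
        labels = grp.sort_values("full_index")["canonical_position"].astype(str).tolist()
        if len(labels) != len(full):
            raise ReferenceError(f"coordinate table length mismatch for {name!r}")
        a5 = sum(1 for l in labels if l == ADAPTER5_LABEL)
        a3 = sum(1 for l in labels if l == ADAPTER3_LABEL)
        body = full[a5 : len(full) - a3 if a3 else len(full)]
        try:
            anchor_idx = labels.index(str(WOBBLE_POSITION))
        except ValueError as exc:
            raise ReferenceError(
                f"coordinate table for {name!r} lacks canonical position 34"
            ) from exc
        refs.append(
            TRNAReference(
                name=name,
                body=body,
                adapter5=full[:a5],
                adapter3=full[len(full) - a3 :] if a3 else "",
                anticodon_start_body=anchor_idx - a5,
            )
        )
    return refs


def write_coordinate_table(refs: Sequence[TRNAReference], path: str | Path) -> None:
    """Write the full-index -> canonical-position map as TSV."""
    rows = []
    for r in refs:
        for i, label in enumerate(r.coordinate_map):
            rows.append({"name": r.name, "full_index": i, "canonical_position": label})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
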
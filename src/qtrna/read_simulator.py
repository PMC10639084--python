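"""Simulator for basecalled nanopore-like tRNA reads.

Generates FASTQ reads from curated references by walking the full
adapter-flanked sequence 5'->3' and drawing per-base mismatch/deletion and
per-junction insertion events, then truncating the 5' end of a fraction of
reads (direct RNA sequencing proceeds 3'->5', so incomplete reads lose 5'
bases).  Modification-induced error signatures are modelled as per-offset
overrides of the baseline probabilities around an anchor position (default:
the wobble position 34), including a 5' "trail" of mildly elevated
mismatches.  Built-in presets encode the qualitative contrasts between
queuosine (mismatch+deletion gain, miscalls biased to C), preQ1 (mismatch
gain, smaller deletion gain) and preQ0 (insertion gain only).

The simulator emulates independent per-position basecalling errors only; it
does not model ionic-current signal, homopolymer-context errors or quality
scores, so passing tests demonstrate pipeline correctness under the stated
error model, not performance on real flow-cell data.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .reference_curation import TRNAReference, WOBBLE_POSITION, RawTRNARecord, curate_references

__all__ = [
    "ErrorModel",
    "OffsetOverride",
    "ModificationSignature",
    "PRESETS",
    "preset_signature",
    "simulate_read",
    "simulate_reads",
    "simulate_experiment",
    "SimulatedExperiment",
    "synthetic_trna_set",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class ErrorModel:
    """Baseline per-base error probabilities of the simulated basecaller.

    Defaults are nanopore-plausible and fully configurable: 3% mismatches,
    2% deletions per base, 1% insertions per junction; 10% of reads lose a
    geometric (mean 5) number of 5' bases.
    """

    p_mismatch: float = 0.03
    p_deletion: float = 0.02
    p_insertion: float = 0.01
    mismatch_bias: Mapping[str, float] | None = None  # None = uniform alternatives
    p_truncation: float = 0.1
    truncation_mean: float = 5.0

    def __post_init__(self) -> None:
        for p in (self.p_mismatch, self.p_deletion, self.p_insertion, self.p_truncation):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.p_mismatch + self.p_deletion > 1.0:
            raise ValueError("p_mismatch + p_deletion must not exceed 1")


@dataclass(frozen=True)
class OffsetOverride:
    """Error probabilities overriding the baseline at one signature offset."""

    p_mismatch: float | None = None
    p_deletion: float | None = None
    p_insertion: float | None = None
    mismatch_bias: Mapping[str, float] | None = None


@dataclass(frozen=True)
class ModificationSignature:
    """Position-offset-specific error elevation around an anchor position.

    ``offsets`` maps canonical-position offsets (relative to ``anchor``) to
    probability overrides; ``modified_fraction`` is the fraction of reads
    carrying the signature.
    """

    name: str = "custom"
    anchor: int = WOBBLE_POSITION
    offsets: Mapping[int, OffsetOverride] = field(default_factory=dict)
    modified_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.modified_fraction <= 1.0:
            raise ValueError("modified_fraction must lie in [0, 1]")


_C_BIAS = {"A": 0.2 / 3, "C": 0.8, "G": 0.2 / 3, "T": 0.2 / 3}


def _q_offsets(p_del_core: float) -> dict[int, OffsetOverride]:
    core = {
        off: OffsetOverride(p_mismatch=0.45, p_deletion=p_del_core, mismatch_bias=_C_BIAS)
        for off in (-1, 0, 1)
    }
    trail = {
        off: OffsetOverride(p_mismatch=ErrorModel().p_mismatch + 0.10)
        for off in range(-6, -1)
    }
    return {**trail, **core}


#: Built-in signature presets encoding the Q / preQ1 / preQ0 contrasts.
PRESETS: dict[str, ModificationSignature] = {
    "null": ModificationSignature(name="null", offsets={}),
    "Q": ModificationSignature(name="Q", offsets=_q_offsets(0.30)),
    "preQ1": ModificationSignature(name="preQ1", offsets=_q_offsets(0.10)),
    "preQ0": ModificationSignature(
        name="preQ0",
        offsets={off: OffsetOverride(p_insertion=0.25) for off in (0, 1)},
    ),
}


def preset_signature(name: str, modified_fraction: float = 1.0) -> ModificationSignature:
    """A preset signature with the requested modified-read fraction."""
    sig = PRESETS[name]
    return replace(sig, modified_fraction=modified_fraction)


def _substitute(base: str, bias: Mapping[str, float] | None, rng: np.random.Generator) -> str:
    alts = [b for b in _BASES if b != base]
    if bias is None:
        return alts[rng.integers(len(alts))]
    w = np.array([bias.get(b, 0.0) for b in alts], dtype=float)
    if w.sum() <= 0:
        return alts[rng.integers(len(alts))]
    return alts[rng.choice(len(alts), p=w / w.sum())]


def simulate_read(
    ref: TRNAReference,
    model: ErrorModel = ErrorModel(),
    signature: ModificationSignature | None = None,
    rng: np.random.Generator | int | None = None,
    apply_signature: bool = True,
) -> str:
    """Simulate one basecalled read from a reference.

    Deterministic given the random generator state.  ``apply_signature``
    lets the caller decide whether this particular read carries the
    signature (the modified fraction is drawn in :func:`simulate_reads`).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    seq = ref.full_sequence
    coord = ref.coordinate_map
    out: list[str] = []
    for i, base in enumerate(seq):
        p_mis, p_del, p_ins, bias = (
            model.p_mismatch,
            model.p_deletion,
            model.p_insertion,
            model.mismatch_bias,
        )
        if signature is not None and apply_signature:
            c = coord[i]
            if isinstance(c, int):
                ov = signature.offsets.get(c - signature.anchor)
                if ov is not None:
                    if ov.p_mismatch is not None:
                        p_mis = ov.p_mismatch
                    if ov.p_deletion is not None:
                        p_del = ov.p_deletion
                    if ov.p_insertion is not None:
                        p_ins = ov.p_insertion
                    if ov.mismatch_bias is not None:
                        bias = ov.mismatch_bias
        u = rng.random()
        if u < p_del:
            pass  # base dropped
        elif u < p_del + p_mis:
            out.append(_substitute(base, bias, rng))
        else:
            out.append(base)
        if rng.random() < p_ins:
            out.append(_BASES[rng.integers(4)])
    read = "".join(out)
    if model.p_truncation > 0 and rng.random() < model.p_truncation:
        cut = int(rng.geometric(1.0 / model.truncation_mean))
        read = read[cut:]
    return read


def simulate_reads(
    ref: TRNAReference,
    n_reads: int,
    model: ErrorModel = ErrorModel(),
    signature: ModificationSignature | None = None,
    rng: np.random.Generator | int | None = None,
    id_prefix: str = "read",
) -> list[tuple[str, str]]:
    """Simulate ``n_reads`` reads; each carries the signature with its
    ``modified_fraction`` probability.  Returns (read_id, sequence) pairs."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    frac = signature.modified_fraction if signature is not None else 0.0
    out = []
    for i in range(n_reads):
        modified = rng.random() < frac
        seq = simulate_read(ref, model, signature, rng, apply_signature=modified)
        tag = "mod" if modified else "unmod"
        out.append((f"{id_prefix}|{ref.name}|{i}|{tag}", seq))
    return out


@dataclass(frozen=True)
class SimulatedExperiment:
    """In-memory result of a two-condition simulation."""

    reads: Mapping[str, Mapping[int, list[tuple[str, str]]]]  # condition -> replicate -> reads
    truth: pd.DataFrame
    fastq_paths: Mapping[str, Mapping[int, Path]] | None = None


def _write_fastq(reads: Sequence[tuple[str, str]], path: Path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def simulate_experiment(
    refs: Sequence[TRNAReference],
    preset_per_ref: Mapping[str, str | ModificationSignature],
    n_reads: int,
    replicates: int = 3,
    model: ErrorModel = ErrorModel(),
    seed: int = 0,
    out_dir: str | Path | None = None,
    modified_fraction: float = 1.0,
    gzipped: bool = False,
) -> SimulatedExperiment:
    """Simulate a two-condition experiment (unmodified vs modified).

    ``preset_per_ref`` maps reference names to a preset name or signature;
    unmapped references are simulated without a signature in both
    conditions.  ``n_reads`` is the number of reads per reference per
    replicate.  Replicate seeds are derived deterministically from the
    master seed, so the full output (including FASTQ bytes) is reproducible.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    sigs: dict[str, ModificationSignature] = {}
    for name, preset in preset_per_ref.items():
        sig = preset_signature(preset, modified_fraction) if isinstance(preset, str) else preset
        sigs[name] = sig
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * replicates)
    conditions = ("unmodified", "modified")
    reads: dict[str, dict[int, list[tuple[str, str]]]] = {c: {} for c in conditions}
    paths: dict[str, dict[int, Path]] = {c: {} for c in conditions}
    for ci, cond in enumerate(conditions):
        for rep in range(1, replicates + 1):
            rng = np.random.default_rng(children[ci * replicates + (rep - 1)])
            rep_reads: list[tuple[str, str]] = []
            for ref in refs:
                sig = sigs.get(ref.name) if cond == "modified" else None
                rep_reads.extend(
                    simulate_reads(
                        ref,
                        n_reads,
                        model,
                        sig,
                        rng,
                        id_prefix=f"{cond}_rep{rep}",
                    )
                )
            reads[cond][rep] = rep_reads
            if out_dir is not None:
                out_dir = Path(out_dir)
                out_dir.mkdir(parents=True, exist_ok=True)
                suffix = ".fastq.gz" if gzipped else ".fastq"
                p = out_dir / f"{cond}_rep{rep}{suffix}"
                _write_fastq(rep_reads, p)
                paths[cond][rep] = p
    truth = pd.DataFrame(
        [
            {
                "ref_name": name,
                "preset": sig.name,
                "anchor": sig.anchor,
                "modified_fraction": sig.modified_fraction,
            }
            for name, sig in sorted(sigs.items())
        ]
    )
    return SimulatedExperiment(
        reads=reads,
        truth=truth,
        fastq_paths=paths if out_dir is not None else None,
    )


# ---------------------------------------------------------------------------
# Synthetic reference construction (for tests, demos and the simulator CLI).

#: Synthetic 24-nt splint-adapter stand-ins flanking every reference.  These
#: are arbitrary fixed sequences, not any vendor's adapter design.
SYNTHETIC_ADAPTER5 = "GGCTTCTTCTTGCTCTTAGGTAGT"
SYNTHETIC_ADAPTER3 = "TAGGTGGAGGATGGAGGCGGTTCA"

_Q_ANTICODONS = ("GTC", "GTT", "GTG", "GTA")  # Asp, Asn, His, Tyr (DNA alphabet)
_Q_NAMES = ("tRNA-Asp-GTC", "tRNA-Asn-GTT", "tRNA-His-GTG", "tRNA-Tyr-GTA")


def synthetic_trna_set(
    n_refs: int = 10,
    n_q: int = 4,
    seed: int = 0,
    body_length: int = 72,
    adapter5: str = SYNTHETIC_ADAPTER5,
    adapter3: str = SYNTHETIC_ADAPTER3,
) -> list[TRNAReference]:
    """A synthetic curated reference set with tRNA-like geometry.

    Bodies are random sequences of ``body_length`` with the anticodon at
    body index 33 (so the wobble base sits at canonical 34); the first
    ``n_q`` references carry the four queuosine-family anticodons
    (GUN: Asp, Asn, His, Tyr).  Purely synthetic stand-ins for a curated
    genomic tRNA set.
    """
    if not 0 <= n_q <= min(4, n_refs):
        raise ValueError("n_q must be between 0 and min(4, n_refs)")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_refs):
        body = "".join(_BASES[b] for b in rng.integers(0, 4, body_length))
        if i < n_q:
            anticodon = _Q_ANTICODONS[i]
            name = f"{_Q_NAMES[i]}-syn"
        else:
            anticodon = "".join(_BASES[b] for b in rng.integers(0, 4, 3))
            name = f"tRNA-syn-{anticodon}-{i}"
        body = body[:33] + anticodon + body[36:]
        records.append(
            RawTRNARecord(name=name, sequence=body, anticodon=anticodon, anticodon_start=33)
        )
    return curate_references(records, adapter5=adapter5, adapter3=adapter3)
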
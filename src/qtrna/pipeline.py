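"""End-to-end convenience layer tying the pipeline stages together.

Each helper is a thin composition of the stage modules: simulate (or load)
reads, align them and their reversed decoys, compute the dataset-specific
score cutoff, build per-replicate pileups, score the two conditions and
derive per-condition error profiles.  The CLI and the acceptance script are
built on these functions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .comparative_scoring import score_positions
from .pileup_errors import DEFAULT_MIN_COVERAGE, build_pileup, error_rates, merge_pileups
from .read_alignment import (
    AlignmentRecord,
    ScoringScheme,
    SignificanceModel,
    align_to_references,
    compute_cutoff,
    filter_significant,
    make_decoy,
)
from .read_simulator import ErrorModel, ModificationSignature, simulate_experiment
from .reference_curation import TRNAReference

__all__ = [
    "align_dataset",
    "pileup_dataset",
    "TwoConditionResult",
    "run_two_condition_pipeline",
]


def align_dataset(
    reads: Sequence[tuple[str, str]],
    refs: Sequence[TRNAReference],
    scheme: ScoringScheme = ScoringScheme(),
    specificity: float = 0.95,
    keep_multimapped: bool = False,
) -> tuple[list[AlignmentRecord], SignificanceModel, list[AlignmentRecord]]:
    """Align one dataset with its reversed-read decoys.

    Every read and its decoy are aligned to all references; the score cutoff
    is computed from the decoy rank-1 score distribution at the requested
    specificity level.  Returns (significant alignments, significance model,
    all rank-1 real alignments).
    """
    real: list[AlignmentRecord] = []
    real_best: list[int] = []
    decoy_best: list[int] = []
    for rid, seq in reads:
        hits = align_to_references(rid, seq, refs, scheme)
        real.extend(hits)
        real_best.append(hits[0].score)
        decoy_hits = align_to_references(
            rid + "|decoy", make_decoy(seq), refs, scheme, is_decoy=True
        )
        decoy_best.append(decoy_hits[0].score)
    model = compute_cutoff(real_best, decoy_best, specificity)
    significant = filter_significant(real, model, keep_multimapped)
    return significant, model, real


def pileup_dataset(
    reads: Sequence[tuple[str, str]],
    refs: Sequence[TRNAReference],
    scheme: ScoringScheme = ScoringScheme(),
    specificity: float = 0.95,
    keep_multimapped: bool = False,
) -> tuple[pd.DataFrame, SignificanceModel]:
    """Align one dataset and tabulate its pileup (all references stacked)."""
    significant, model, _ = align_dataset(reads, refs, scheme, specificity, keep_multimapped)
    tables = build_pileup(significant, dict(reads), refs)
    return pd.concat(tables.values(), ignore_index=True), model


@dataclass(frozen=True)
class TwoConditionResult:
    """Scores, per-condition profiles and bookkeeping of a pipeline run."""

    scores: pd.DataFrame
    profiles: Mapping[str, Mapping[str, pd.DataFrame]]  # condition -> ref -> profile
    pileups: Mapping[str, list[pd.DataFrame]]  # condition -> per-replicate tables
    models: Mapping[str, list[SignificanceModel]]
    truth: pd.DataFrame


def run_two_condition_pipeline(
    refs: Sequence[TRNAReference],
    preset_per_ref: Mapping[str, str | ModificationSignature],
    n_reads: int = 300,
    replicates: int = 3,
    model: ErrorModel = ErrorModel(),
    seed: int = 0,
    scheme: ScoringScheme = ScoringScheme(),
    specificity: float = 0.95,
    min_cov: int = DEFAULT_MIN_COVERAGE,
    modified_fraction: float = 1.0,
) -> TwoConditionResult:
    """Simulate two conditions and run the full comparative pipeline."""
    exp = simulate_experiment(
        refs,
        preset_per_ref,
        n_reads=n_reads,
        replicates=replicates,
        model=model,
        seed=seed,
        modified_fraction=modified_fraction,
    )
    pileups: dict[str, list[pd.DataFrame]] = {}
    models: dict[str, list[SignificanceModel]] = {}
    for cond, reps in exp.reads.items():
        pileups[cond] = []
        models[cond] = []
        for rep in sorted(reps):
            table, sig_model = pileup_dataset(reps[rep], refs, scheme, specificity)
            pileups[cond].append(table)
            models[cond].append(sig_model)
    scores = score_positions(pileups["unmodified"], pileups["modified"], min_cov=min_cov)
    profiles: dict[str, dict[str, pd.DataFrame]] = {}
    for cond in pileups:
        profiles[cond] = {}
        merged = merge_pileups(pileups[cond])
        for name, grp in merged.groupby("ref_name", sort=True):
            profiles[cond][name] = error_rates(grp.reset_index(drop=True), min_cov=min_cov)
    return TwoConditionResult(
        scores=scores, profiles=profiles, pileups=pileups, models=models, truth=exp.truth
    )
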
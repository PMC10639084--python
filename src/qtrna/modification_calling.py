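"""Candidate-site calling and position-34 signature classification.

Bulky modifications perturb basecalling not only at the modified base but
over a window around it — a 5' "trail" as the base transits the pore — so
high comparative scores form contiguous runs rather than single spikes.
Candidate calling merges such runs into regions and reports the peak
position; the peak need not be the modified base itself (for preQ0 the
neighbouring position can carry the larger error change), so calls also
flag whether the wobble position 34 falls inside the region.

Signature classification at the anticodon compares per-channel error-rate
differentials (modified minus unmodified condition, maximum over canonical
positions 33-35): queuosine elevates both mismatches (miscalled mostly as
C) and deletions; preQ1 elevates mismatches with little deletion gain;
preQ0 elevates insertions with little mismatch gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .pileup_errors import DEFAULT_MIN_COVERAGE
from .reference_curation import WOBBLE_POSITION

__all__ = [
    "CandidateSite",
    "SignatureCall",
    "ClassifierThresholds",
    "empirical_threshold",
    "call_candidates",
    "classify_signature",
    "plot_score_track",
]


@dataclass(frozen=True)
class CandidateSite:
    """A contiguous high-score region with its peak position."""

    ref_name: str
    peak_position: int
    region_start: int
    region_end: int  # inclusive canonical positions
    peak_score: float
    mis_score: float
    del_score: float
    ins_score: float
    contains_wobble: bool

    def __post_init__(self) -> None:
        assert self.region_start <= self.peak_position <= self.region_end


@dataclass(frozen=True)
class ClassifierThresholds:
    """Rate-differential thresholds separating the 7-deazaguanine signatures.

    Calibrated on the read simulator's preset effect sizes; the underlying
    biology provides ordering relations (Q exceeds preQ1 in deletion gain,
    preQ0 is marked by insertion gain), not universal cutoffs, so all three
    are configuration.
    """

    t_mis: float = 0.15
    t_del: float = 0.10
    t_ins: float = 0.10


@dataclass(frozen=True)
class SignatureCall:
    """Classification of the wobble-position signature for one tRNA."""

    ref_name: str
    call: str  # Q_like | preQ1_like | preQ0_like | unmodified | ambiguous
    delta_mis: float = float("nan")
    delta_del: float = float("nan")
    delta_ins: float = float("nan")
    reason: str = ""


def empirical_threshold(scores: Sequence[float]) -> float:
    """Outlier threshold Q3 + 3*IQR over the non-missing scores."""
    arr = np.asarray([s for s in scores if np.isfinite(s)], dtype=float)
    if arr.size == 0:
        return np.inf
    q1, q3 = np.percentile(arr, [25, 75])
    return float(q3 + 3.0 * (q3 - q1))


def call_candidates(
    scores: pd.DataFrame,
    threshold: float | str = "empirical",
    exclude_adapters: bool = True,
) -> list[CandidateSite]:
    """Merge contiguous runs of high total_score into candidate regions.

    ``threshold`` is either a number applied to every tRNA or
    ``"empirical"`` (per-tRNA Q3 + 3*IQR of total_score).  Adapter
    positions are excluded by default; missing (NaN) positions never seed
    or extend a region.  The peak is the maximum-score position of a
    region (smallest position on ties).
    """
    out: list[CandidateSite] = []
    for name, track in scores.groupby("ref_name", sort=True):
        if exclude_adapters:
            body = track[[isinstance(c, (int, np.integer)) for c in track["canonical_position"]]]
        else:
            body = track
        body = body.sort_values("full_index")
        vals = body["total_score"].to_numpy(float)
        pos = np.asarray(
            [int(c) if isinstance(c, (int, np.integer)) else -(10**9) for c in body["canonical_position"]]
        )
        thr = empirical_threshold(vals) if threshold == "empirical" else float(threshold)
        above = np.isfinite(vals) & (vals >= thr)
        i = 0
        n = len(vals)
        while i < n:
            if not above[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and above[j + 1] and pos[j + 1] == pos[j] + 1:
                j += 1
            seg = slice(i, j + 1)
            k = i + int(np.argmax(vals[seg]))
            row = body.iloc[k]
            out.append(
                CandidateSite(
                    ref_name=name,
                    peak_position=int(pos[k]),
                    region_start=int(pos[i]),
                    region_end=int(pos[j]),
                    peak_score=float(vals[k]),
                    mis_score=float(row["mis_score"]),
                    del_score=float(row["del_score"]),
                    ins_score=float(row["ins_score"]),
                    contains_wobble=bool(pos[i] <= WOBBLE_POSITION <= pos[j]),
                )
            )
            i = j + 1
    return out


def classify_signature(
    profile_unmodified: pd.DataFrame,
    profile_modified: pd.DataFrame,
    window: tuple[int, int] = (33, 35),
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    min_cov: int = DEFAULT_MIN_COVERAGE,
) -> SignatureCall:
    """Classify the anticodon signature from two error-rate profiles.

    Profiles are :func:`qtrna.pileup_errors.error_rates` tables for one
    reference, one per condition.  Differentials are modified minus
    unmodified, maximized over the canonical window.  Decision rules:
    Q_like if dmis >= t_mis and ddel >= t_del; preQ1_like if dmis >= t_mis
    and ddel < t_del; preQ0_like if dins >= t_ins and dmis < t_mis;
    unmodified if all three differentials fall below their thresholds;
    ambiguous otherwise.
    """
    name = str(profile_modified["ref_name"].iloc[0])
    lo, hi = window

    def _window(df: pd.DataFrame) -> pd.DataFrame:
        mask = [
            isinstance(c, (int, np.integer)) and lo <= int(c) <= hi
            for c in df["canonical_position"]
        ]
        return df[mask].sort_values("canonical_position")

    wu = _window(profile_unmodified)
    wm = _window(profile_modified)
    if len(wu) == 0 or len(wm) == 0 or len(wu) != len(wm):
        return SignatureCall(name, "ambiguous", reason="window not covered by profiles")
    if (wu["coverage"].to_numpy() < min_cov).any() or (
        wm["coverage"].to_numpy() < min_cov
    ).any():
        return SignatureCall(name, "ambiguous", reason="insufficient coverage in window")

    d_mis = float(np.max(wm["mismatch_rate"].to_numpy() - wu["mismatch_rate"].to_numpy()))
    d_del = float(np.max(wm["deletion_rate"].to_numpy() - wu["deletion_rate"].to_numpy()))
    d_ins = float(np.max(wm["insertion_rate"].to_numpy() - wu["insertion_rate"].to_numpy()))
    t = thresholds
    if d_mis >= t.t_mis and d_del >= t.t_del:
        call = "Q_like"
    elif d_mis >= t.t_mis:
        call = "preQ1_like"
    elif d_ins >= t.t_ins and d_mis < t.t_mis:
        call = "preQ0_like"
    elif d_mis < t.t_mis and d_del < t.t_del and d_ins < t.t_ins:
        call = "unmodified"
    else:
        call = "ambiguous"
    return SignatureCall(name, call, d_mis, d_del, d_ins)


def plot_score_track(
    scores: pd.DataFrame, path, highlight: int = WOBBLE_POSITION
) -> None:
    """Per-tRNA total-score tracks aligned at the wobble position (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = list(scores.groupby("ref_name", sort=True))
    fig, axes = plt.subplots(
        len(groups), 1, figsize=(8, 1.8 * len(groups)), sharex=True, squeeze=False
    )
    for ax, (name, track) in zip(axes[:, 0], groups):
        body = track[[isinstance(c, (int, np.integer)) for c in track["canonical_position"]]]
        x = [int(c) - highlight for c in body["canonical_position"]]
        ax.bar(x, body["total_score"].fillna(0.0), width=0.9, color="#4878b0")
        ax.axvline(0, color="#c44e52", lw=0.8, ls="--")
        ax.set_ylabel(name, rotation=0, ha="right", fontsize=8)
    axes[-1, 0].set_xlabel(f"position relative to {highlight}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
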
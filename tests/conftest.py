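"""Shared fixtures: synthetic reference sets, cached pipeline runs and the
hand-computed five-read SAM fixture used by the pileup tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from qtrna import synthetic_trna_set
from qtrna.pipeline import run_two_condition_pipeline
from qtrna.reference_curation import TRNAReference

PRESET_NAMES = ("Q", "preQ1", "preQ0", "null")
PRESET_SEEDS = tuple(range(1, 11))


@pytest.fixture(scope="session")
def single_ref():
    return synthetic_trna_set(1, 1, seed=7)


@pytest.fixture(scope="session")
def q4_refs():
    return synthetic_trna_set(4, 4, seed=7)


@pytest.fixture(scope="session")
def ten_refs():
    return synthetic_trna_set(10, 4, seed=7)


@pytest.fixture(scope="session")
def preset_runs(single_ref):
    """Full pipeline runs for every preset x seeds 1-10 on one Q-tRNA.

    Computed once per session; several ordering/classification checks share
    these runs.
    """
    name = single_ref[0].name
    runs = {}
    for preset in PRESET_NAMES:
        for seed in PRESET_SEEDS:
            runs[(preset, seed)] = run_two_condition_pipeline(
                single_ref, {name: preset}, n_reads=300, replicates=3, seed=seed
            )
    return runs


def body_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Rows of a score table at tRNA-body (integer canonical) positions."""
    mask = [isinstance(c, (int, np.integer)) for c in scores["canonical_position"]]
    return scores[mask]


def anchor_score(scores: pd.DataFrame, position: int = 34) -> float:
    body = body_scores(scores)
    row = body[[int(c) == position for c in body["canonical_position"]]]
    return float(row["total_score"].iloc[0])


# ---------------------------------------------------------------------------
# Five-read SAM fixture covering the =, X, I, D and S CIGAR operations, with
# the pileup worked out by hand.

_BODY = "ACGTACGTACGTACGTACGT"  # 20 nt


def sam_fixture_reference() -> TRNAReference:
    return TRNAReference(
        name="refX", body=_BODY, adapter5="", adapter3="", anticodon_start_body=5
    )


def sam_fixture_text() -> str:
    r1 = _BODY
    r2 = _BODY[:5] + "A" + _BODY[6:]          # X at index 5
    r3 = _BODY[:3] + _BODY[4:]                # D at index 3
    r4 = _BODY[:3] + "GG" + _BODY[3:]         # 2-base I after index 2
    r5 = "TTTT" + _BODY[5:15]                 # 4 soft-clipped, aligns 5..14
    lines = [
        "@HD\tVN:1.6\tSO:unsorted",
        f"@SQ\tSN:refX\tLN:{len(_BODY)}",
        f"r1\t0\trefX\t1\t255\t20=\t*\t0\t0\t{r1}\t*\tAS:i:40\tzr:i:1",
        f"r2\t0\trefX\t1\t255\t5=1X14=\t*\t0\t0\t{r2}\t*\tAS:i:34\tzr:i:1",
        f"r3\t0\trefX\t1\t255\t3=1D16=\t*\t0\t0\t{r3}\t*\tAS:i:32\tzr:i:1",
        f"r4\t0\trefX\t1\t255\t3=2I17=\t*\t0\t0\t{r4}\t*\tAS:i:32\tzr:i:1",
        f"r5\t0\trefX\t6\t255\t4S10=\t*\t0\t0\t{r5}\t*\tAS:i:20\tzr:i:1",
    ]
    return "\n".join(lines) + "\n"


def sam_fixture_expected() -> pd.DataFrame:
    """Hand-computed pileup for the five reads above.

    r1-r4 span indices 0-19, r5 spans 5-14; r3 deletes index 3; r4 inserts
    two bases between indices 2 and 3 (attributed to index 2); r2 miscalls
    index 5 (C) as A.
    """
    cov = [4] * 5 + [5] * 10 + [4] * 5
    rows = []
    for i, base in enumerate(_BODY):
        counts = {"A": 0, "C": 0, "G": 0, "T": 0}
        dele = 0
        if i == 3:
            counts[base] = 3
            dele = 1
        elif i == 5:
            counts["C"] = 4
            counts["A"] = 1
        else:
            counts[base] = cov[i]
        rows.append(
            {
                "ref_name": "refX",
                "full_index": i,
                "canonical_position": i + 29,  # anticodon start 5 -> offset 29
                "ref_base": base,
                "coverage": cov[i],
                **counts,
                "del": dele,
                "ins": 1 if i == 2 else 0,
            }
        )
    return pd.DataFrame(rows)
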
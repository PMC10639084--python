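"""Replicate-aware two-condition comparative scoring of error profiles.

For every reference position three count channels are compared between the
two conditions: the base channel (A, C, G, T, deletion — a 5-category vector
per replicate), the deletion channel (deleted vs not) and the insertion
channel (insertion vs not).  Each channel is scored with a
Dirichlet-multinomial likelihood-ratio statistic,

    score = 2 [ l(A; theta_A) + l(B; theta_B) - l(A u B; theta_pooled) ],

where l is the Dirichlet-multinomial log-likelihood summed over replicate
count vectors and theta are concentration parameters fitted by maximum
likelihood (a method-of-moments estimate — mean replicate proportions scaled
by a common precision solved from between-replicate overdispersion — refined
by the standard monotone fixed-point iteration).  The statistic grows with both the
between-condition divergence and the amount of evidence, and is tempered by
between-replicate variability because the likelihood is evaluated per
replicate rather than on pooled counts.  The per-position total — the
mismatch, deletion and insertion channel scores summed — is the
Mis + Del + Ins score used for modification calling.

Scores are comparative, not inferential: no p-values are attached.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, psi

from .pileup_errors import DEFAULT_MIN_COVERAGE

__all__ = [
    "PSEUDOCOUNT",
    "PRECISION_BOUNDS",
    "fit_dirichlet_multinomial",
    "dirichlet_multinomial_loglik",
    "channel_score",
    "score_positions",
]

#: Pseudocount added to every cell of every replicate count vector.
PSEUDOCOUNT = 0.5

#: Clamp range for the estimated Dirichlet precision (sum of concentrations).
PRECISION_BOUNDS = (1e-2, 1e6)


def _moment_estimate(X: np.ndarray) -> np.ndarray:
    """Method-of-moments concentration estimate on smoothed counts.

    Proportions are the mean of per-replicate proportions; the common
    precision is solved from the between-replicate variance under the
    Dirichlet-multinomial identity Var(p) = m(1-m)(theta+n)/(n(theta+1)),
    pooled over categories with weights m(1-m).  Population (ddof=0)
    variance makes the estimate invariant under duplicating the replicate
    set.  Used to initialize the likelihood refinement.
    """
    n = X.sum(axis=1)
    P = X / n[:, None]
    m = P.mean(axis=0)
    lo, hi = PRECISION_BOUNDS
    if X.shape[0] == 1:
        theta = hi
    else:
        v = P.var(axis=0)
        w = m * (1.0 - m)
        mask = w > 0
        nbar = n.mean()
        if not mask.any() or v[mask].sum() <= 0:
            theta = hi
        else:
            # weighted moment equation: c = (theta + nbar) / (theta + 1)
            c = nbar * v[mask].sum() / w[mask].sum()
            if c <= 1.0:
                theta = hi
            elif c >= nbar:
                theta = lo
            else:
                theta = (nbar - c) / (c - 1.0)
    theta = min(max(theta, lo), hi)
    return theta * m


def fit_dirichlet_multinomial(
    count_vectors: Sequence[Sequence[float]],
    eps: float = PSEUDOCOUNT,
    max_iter: int = 200,
    tol: float = 1e-9,
) -> np.ndarray:
    """Dirichlet-multinomial concentration estimate.

    A method-of-moments estimate (mean replicate proportions scaled by a
    common precision solved from between-replicate overdispersion) seeds
    the standard fixed-point iteration for the Polya maximum-likelihood
    estimate, which increases the likelihood monotonically at every step.
    The total concentration (precision) is clamped to ``PRECISION_BOUNDS``;
    a single replicate or identical replicates carry no overdispersion
    information and end at the upper clamp with proportions equal to the
    (``eps``-smoothed) pooled frequencies.  The procedure is deterministic
    and invariant under duplicating the replicate set.
    """
    X = np.asarray(count_vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("need at least one count vector")
    if np.any(X.sum(axis=1) <= 0):
        raise ValueError("each count vector must have a positive total")
    X = X + eps
    n = X.sum(axis=1)
    lo, hi = PRECISION_BOUNDS
    alpha = _moment_estimate(X)
    for _ in range(max_iter):
        A = alpha.sum()
        num = psi(X + alpha).sum(axis=0) - X.shape[0] * psi(alpha)
        den = np.sum(psi(n + A) - psi(A))
        new = alpha * num / den
        total = new.sum()
        if total > hi:
            alpha = new * (hi / total)
            break
        if total < lo:
            alpha = new * (lo / total)
            break
        if np.max(np.abs(new - alpha)) < tol * max(1.0, float(np.max(alpha))):
            alpha = new
            break
        alpha = new
    return alpha


def dirichlet_multinomial_loglik(
    count_vectors: Sequence[Sequence[float]],
    alpha: np.ndarray,
    eps: float = PSEUDOCOUNT,
) -> float:
    """Dirichlet-multinomial log-likelihood summed over replicate vectors.

    The multinomial coefficient is omitted; it cancels in likelihood ratios.
    """
    X = np.asarray(count_vectors, dtype=float) + eps
    n = X.sum(axis=1)
    A = alpha.sum()
    ll = np.sum(gammaln(A) - gammaln(n + A))
    ll += np.sum(gammaln(X + alpha) - gammaln(alpha))
    return float(ll)


def channel_score(
    counts_a: Sequence[Sequence[float]],
    counts_b: Sequence[Sequence[float]],
    eps: float = PSEUDOCOUNT,
) -> float:
    """Two-condition Dirichlet-multinomial likelihood-ratio score.

    Symmetric in its arguments (the pooled fit canonicalizes replicate
    order) and exactly zero when the two conditions carry identical
    replicate sets.  Negative values — possible only through precision
    clamping or capped iterations — are clamped to zero.
    """
    A = [tuple(float(x) for x in v) for v in counts_a]
    B = [tuple(float(x) for x in v) for v in counts_b]
    pooled = sorted(A + B)
    alpha_a = fit_dirichlet_multinomial(A, eps)
    alpha_b = fit_dirichlet_multinomial(B, eps)
    alpha_p = fit_dirichlet_multinomial(pooled, eps)
    score = 2.0 * (
        dirichlet_multinomial_loglik(A, alpha_a, eps)
        + dirichlet_multinomial_loglik(B, alpha_b, eps)
        - dirichlet_multinomial_loglik(pooled, alpha_p, eps)
    )
    return max(score, 0.0)


_COUNT_COLS = ["A", "C", "G", "T", "del"]


def _check_consistent(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    first = tables[0]
    idx = first["full_index"].to_numpy()
    for t in tables[1:]:
        if len(t) != len(first) or (t["full_index"].to_numpy() != idx).any() or (
            t["ref_base"].to_numpy() != first["ref_base"].to_numpy()
        ).any():
            raise ValueError(
                "replicate pileups disagree on reference positions/bases; "
                "both conditions must be aligned to the same curated reference"
            )
    return first


def score_positions(
    pileups_a: Sequence[pd.DataFrame],
    pileups_b: Sequence[pd.DataFrame],
    min_cov: int = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Per-position channel scores and total (Mis + Del + Ins) score.

    ``pileups_a`` / ``pileups_b`` are per-replicate pileup tables over one
    reference (or concatenations over several; rows are grouped by
    ref_name).  Positions where any replicate of either condition has
    coverage below ``min_cov`` get NaN scores.  Per-condition pooled rates
    are reported alongside the scores.
    """
    if not pileups_a or not pileups_b:
        raise ValueError("each condition needs at least one replicate pileup")

    def _split(tables):
        return [
            {name: g.reset_index(drop=True) for name, g in t.groupby("ref_name", sort=True)}
            for t in tables
        ]

    split_a = _split(pileups_a)
    split_b = _split(pileups_b)
    names = sorted(split_a[0])
    for d in split_a + split_b:
        if sorted(d) != names:
            raise ValueError("conditions cover different reference sets")

    rows = []
    for name in names:
        tabs_a = [d[name] for d in split_a]
        tabs_b = [d[name] for d in split_b]
        first = _check_consistent(tabs_a + tabs_b)
        La = [t[_COUNT_COLS].to_numpy(float) for t in tabs_a]
        Lb = [t[_COUNT_COLS].to_numpy(float) for t in tabs_b]
        cov_a = [t["coverage"].to_numpy(float) for t in tabs_a]
        cov_b = [t["coverage"].to_numpy(float) for t in tabs_b]
        ins_a = [t["ins"].to_numpy(float) for t in tabs_a]
        ins_b = [t["ins"].to_numpy(float) for t in tabs_b]
        ref_bases = first["ref_base"].tolist()
        base_idx = {b: i for i, b in enumerate("ACGT")}

        pooled = {}
        for lab, covs, mats, inss in (
            ("a", cov_a, La, ins_a),
            ("b", cov_b, Lb, ins_b),
        ):
            cov = np.sum(covs, axis=0)
            mat = np.sum(mats, axis=0)
            insv = np.sum(inss, axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                refc = np.array(
                    [mat[i, base_idx[b]] if b in base_idx else 0.0 for i, b in enumerate(ref_bases)]
                )
                pooled[f"mis_rate_{lab}"] = (cov - refc - mat[:, 4]) / cov
                pooled[f"del_rate_{lab}"] = mat[:, 4] / cov
                pooled[f"ins_rate_{lab}"] = insv / cov

        for i in range(len(first)):
            covered = all(c[i] >= min_cov for c in cov_a + cov_b)
            if covered:
                base_a = [m[i] for m in La]
                base_b = [m[i] for m in Lb]
                mis = channel_score(base_a, base_b)
                del_a = [(m[i, 4], c[i] - m[i, 4]) for m, c in zip(La, cov_a)]
                del_b = [(m[i, 4], c[i] - m[i, 4]) for m, c in zip(Lb, cov_b)]
                del_ = channel_score(del_a, del_b)
                ia = [(v[i], c[i] - v[i]) for v, c in zip(ins_a, cov_a)]
                ib = [(v[i], c[i] - v[i]) for v, c in zip(ins_b, cov_b)]
                ins_ = channel_score(ia, ib)
                total = mis + del_ + ins_
            else:
                mis = del_ = ins_ = total = np.nan
            rows.append(
                {
                    "ref_name": name,
                    "full_index": int(first["full_index"].iloc[i]),
                    "canonical_position": first["canonical_position"].iloc[i],
                    "ref_base": ref_bases[i],
                    "mis_score": mis,
                    "del_score": del_,
                    "ins_score": ins_,
                    "total_score": total,
                    **{k: v[i] for k, v in pooled.items()},
                }
            )
    return pd.DataFrame(rows)
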
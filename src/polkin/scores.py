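"""Expressed-gene filtering, completion/readthrough scores, and a moderated
differential test.

The completion score of a gene is the log2 ratio of nascent signal summed
over the last 15% of the gene body ("distal window") to the first 15%
("proximal window"). The readthrough score is the log2 ratio of read density
after vs before the PAS (post window PAS+5..+15 kb; pre window PAS-5..PAS for
4sU, PAS-3..PAS for ChIP — densities, not raw sums, because the spans
differ). Replicate score matrices are compared between arms with an
empirical-Bayes moderated t test (per-gene variances shrunk toward a pooled
prior, limma-style) and BH correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ScoreRecord",
    "expressed_filter",
    "completion_score",
    "readthrough_score",
    "score_zscores",
    "moderated_diff_test",
]

EPSILON = 1.0  # pseudocount on window sums (normalized counts)
BIN_NT = 150
BODY_FRACTION = 0.15


@dataclass
class ScoreRecord:
    gene: str
    completion: float | None = None
    readthrough: float | None = None
    delta_log2: float | None = None
    t: float | None = None
    p: float | None = None
    q: float | None = None


def expressed_filter(
    length_nt: int, pas_bin_densities: np.ndarray, min_length_nt: int = 5000, min_density_sum: float = 4.0
) -> bool:
    """Gene-inclusion rule: length > 5 kb and the sum of 150 bp bin read
    densities over PAS-5 kb .. PAS+5 kb strictly greater than 4."""
    if length_nt <= min_length_nt:
        return False
    return float(np.nansum(pas_bin_densities)) > min_density_sum


def completion_score(body_bins: np.ndarray, fraction: float = BODY_FRACTION, eps: float = EPSILON) -> float:
    """log2((distal sum + eps) / (proximal sum + eps)) over length-normalized
    150 bp bins; the proximal/distal windows are the first/last 15%."""
    body_bins = np.asarray(body_bins, dtype=float)
    n = len(body_bins)
    k = max(int(round(n * fraction)), 1)
    prox = float(np.nansum(body_bins[:k]))
    dist = float(np.nansum(body_bins[-k:]))
    if prox == 0 and dist == 0:
        return float("nan")
    return float(np.log2((dist + eps) / (prox + eps)))


def readthrough_score(
    pre_counts: np.ndarray,
    post_counts: np.ndarray,
    pre_span_nt: int,
    post_span_nt: int,
    eps: float = EPSILON,
) -> float:
    """log2 ratio of post- to pre-PAS read density.

    Densities (counts per nt) rather than raw sums, since the pre window is
    3 kb (ChIP) or 5 kb (4sU) while the post window is 10 kb.
    """
    post = np.asarray(post_counts, dtype=float)
    if np.all(np.isnan(post)):
        return float("nan")
    pre_d = float(np.nansum(pre_counts)) / pre_span_nt
    post_d = float(np.nansum(post)) / post_span_nt
    scale = eps / max(pre_span_nt, post_span_nt)
    return float(np.log2((post_d + scale) / (pre_d + scale)))


def score_zscores(scores: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Z-scores of the anti-log (2^score) of log2 scores (sample sd)."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 2:
        raise ValueError("need at least 2 genes")
    anti = 2.0 ** scores
    sd = float(np.std(anti, ddof=ddof))
    if sd == 0:
        raise ValueError("zero variance across genes")
    return (anti - np.mean(anti)) / sd


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F prior to observed variances (Smyth-style).

    Returns (prior df d0, prior variance s0^2); d0 = inf when the observed
    log-variance spread is at or below the sampling spread.
    """
    s2 = np.maximum(s2, 1e-12)
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) if len(e) > 1 else 0.0
    excess = e_var - float(special.polygamma(1, df / 2))
    if excess <= 0:
        return float("inf"), float(np.exp(e_mean))
    # solve trigamma(d0/2) = excess
    lo, hi = 1e-6, 1e8
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if special.polygamma(1, mid / 2) > excess:
            lo = mid
        else:
            hi = mid
    d0 = float(np.sqrt(lo * hi))
    s02 = float(np.exp(e_mean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return d0, s02


def moderated_diff_test(
    arm_a: np.ndarray, arm_b: np.ndarray, prior_df: float | None = None
) -> pd.DataFrame:
    """Empirical-Bayes two-sample test on per-gene score matrices.

    arm_a, arm_b: genes x replicates. Per-gene pooled variances are shrunk
    toward a common prior (method-of-moments prior df unless given);
    moderated t uses the shrunk variance with df = df_gene + df_prior.
    prior_df=0 reproduces the ordinary two-sample t test. Returns a
    DataFrame with delta_log2, t, p, q; with a single replicate per arm the
    test columns are NaN.
    """
    A = np.atleast_2d(np.asarray(arm_a, dtype=float))
    B = np.atleast_2d(np.asarray(arm_b, dtype=float))
    if A.shape[0] != B.shape[0]:
        raise ValueError("arms must cover the same genes")
    na, nb = A.shape[1], B.shape[1]
    delta = A.mean(axis=1) - B.mean(axis=1)
    out = pd.DataFrame({"delta_log2": delta})
    if na < 2 or nb < 2:
        out["t"] = np.nan
        out["p"] = np.nan
        out["q"] = np.nan
        return out
    df = na + nb - 2
    s2 = (A.var(axis=1, ddof=1) * (na - 1) + B.var(axis=1, ddof=1) * (nb - 1)) / df
    if prior_df is None:
        d0, s02 = _fit_f_dist(s2, df)
    else:
        d0, s02 = float(prior_df), float(np.mean(s2))
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    elif d0 == 0:
        s2_post = np.maximum(s2, 1e-12)
        df_total = df
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        df_total = df + d0
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    t = delta / se
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    out["t"] = t
    out["p"] = p
    out["q"] = multipletests(p, method="fdr_bh")[1]
    return out
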
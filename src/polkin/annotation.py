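"""Data-driven transcription-unit boundary calls.

TSS: candidate start sites (CAGE peaks plus annotated transcript 5' ends)
are filtered by how much of the gene's intronic nascent signal they explain,
then the candidate with the largest step in mean coverage (downstream minus
upstream) wins. PAS: the 3'-end read-start profile (poly(A)-anchored
libraries cluster directly upstream of the tail) is Gaussian-smoothed, the
3'-most position above 1% of the peak is located, and an annotated PAS
within 150 nt downstream is preferred over the empirical call + 100 nt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TssCandidate",
    "PasCall",
    "filter_tss_candidates",
    "select_tss",
    "select_pas",
    "smooth_profile",
]

SMOOTH_SD_NT = 20.0
PAS_ANNOT_MAX_DIST_NT = 150
PAS_OFFSET_NT = 100
PEAK_FRACTION = 0.01


@dataclass
class TssCandidate:
    position: int
    source: str = "cage"  # or "transcript_5p"
    d_i: float = float("nan")  # mean intronic coverage downstream
    u_i: float = float("nan")  # mean intronic coverage upstream
    upstream_fraction: float = float("nan")

    @property
    def increment(self) -> float:
        return self.d_i - self.u_i


@dataclass
class PasCall:
    raw_profile: np.ndarray
    smoothed: np.ndarray
    pas: int | None
    rule_used: str  # "annotated" | "p_plus_100" | "none"


def _oriented_axis(gene_span: tuple[int, int], strand: str) -> np.ndarray:
    start, end = gene_span
    pos = np.arange(start, end)
    return pos if strand == "+" else pos[::-1]


def filter_tss_candidates(
    candidates: list[TssCandidate],
    intronic_coverage: np.ndarray,
    gene_span: tuple[int, int],
    strand: str = "+",
    max_upstream_fraction: float = 0.5,
) -> list[TssCandidate]:
    """Drop candidates leaving more than half the intronic signal upstream.

    ``intronic_coverage`` is per-nt coverage over ``gene_span`` in genomic
    orientation (exonic positions zeroed or NaN). Also fills each surviving
    candidate's upstream/downstream mean coverages. The strict "more than"
    keeps candidates at exactly 50%. If all candidates fail, the 5'-most is
    returned with a warning.
    """
    cov = np.nan_to_num(np.asarray(intronic_coverage, dtype=float))
    start, end = gene_span
    total = cov.sum()
    if total <= 0:
        raise ValueError("no intronic signal in the gene")
    surviving = []
    for cand in candidates:
        i = int(np.clip(cand.position - start, 0, end - start))
        if strand == "+":
            up, down = cov[:i], cov[i:]
        else:
            up, down = cov[i:], cov[:i]
        cand.upstream_fraction = float(up.sum() / total)
        cand.u_i = float(up.mean()) if len(up) else 0.0
        cand.d_i = float(down.mean()) if len(down) else 0.0
        if cand.upstream_fraction <= max_upstream_fraction:
            surviving.append(cand)
    if not surviving:
        warnings.warn("all TSS candidates rejected; falling back to the 5'-most", stacklevel=2)
        five_prime = min if strand == "+" else max
        return [five_prime(candidates, key=lambda c: c.position)]
    return surviving


def select_tss(candidates: list[TssCandidate], strand: str = "+") -> int:
    """Candidate with the maximal coverage increment d_i - u_i; ties go to
    the 5'-most position."""
    if not candidates:
        raise ValueError("no candidates")
    best = max(c.increment for c in candidates)
    tied = [c for c in candidates if c.increment == best]
    five_prime = min if strand == "+" else max
    return five_prime(tied, key=lambda c: c.position).position


def smooth_profile(profile: np.ndarray, sd: float = SMOOTH_SD_NT) -> np.ndarray:
    """Gaussian smoothing with a truncated, renormalized kernel (conserves
    total mass at the boundaries)."""
    profile = np.asarray(profile, dtype=float)
    half = int(np.ceil(4 * sd))
    x = np.arange(-half, half + 1)
    kern = np.exp(-0.5 * (x / sd) ** 2)
    kern /= kern.sum()
    # renormalize per source point: the part of each point's kernel falling
    # inside the domain carries its full mass, so the total is conserved
    norm = np.convolve(np.ones_like(profile), kern, mode="same")
    return np.convolve(profile / norm, kern, mode="same")


def select_pas(
    read_start_profile: np.ndarray,
    span_start: int,
    annotated_pas: list[int],
    strand: str = "+",
    sd: float = SMOOTH_SD_NT,
) -> PasCall:
    """Call the PAS from a 3'-end read-start profile.

    The profile covers genomic positions span_start..span_start+len. The
    3'-most position p above 1% of the smoothed maximum defines the call: an
    annotated PAS within 150 nt of p is taken verbatim (symmetric window:
    the smoothing tail can push p slightly past an annotation at the true
    cleavage site), otherwise the PAS is p + 100 nt (transcription
    orientation).
    """
    raw = np.asarray(read_start_profile, dtype=float)
    if raw.size == 0 or raw.sum() <= 0:
        return PasCall(raw, raw.copy(), None, "none")
    sm = smooth_profile(raw, sd=sd)
    above = np.nonzero(sm > PEAK_FRACTION * sm.max())[0]
    idx = above.max() if strand == "+" else above.min()
    p = span_start + int(idx)
    sign = 1 if strand == "+" else -1
    for apas in sorted(annotated_pas, key=lambda a: abs(a - p)):
        if abs(apas - p) < PAS_ANNOT_MAX_DIST_NT:
            return PasCall(raw, sm, int(apas), "annotated")
    return PasCall(raw, sm, p + sign * PAS_OFFSET_NT, "p_plus_100")
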
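"""Negative-binomial regression of the post-PAS decline of nascent signal.

Downstream of the polyadenylation site, 4sU signal declines exponentially:
transcription terminates stochastically at a constant per-kb rate. Window
counts a_i on the 250 nt PAS-downstream grid are modeled as

    a_i ~ NB(mean = s(i) = o * exp(-r*i), size = disp)

with o the signal level at the PAS, r the decline rate per window, and disp
the NB size (overdispersion) parameter. A Gaussian prior on o, centered on
the mean and sd of the PAS-upstream windows and weighted by the number of
usable windows, anchors the starting level. The decline is reported per
window, in nats/kb, and as the survival form 100*(1-exp(-r/window_kb)) %/kb
(default report).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from ._optim import Z95, hessian_ses, multistart_minimize
from .windows import PAS_UPSTREAM_NT, WindowVector

__all__ = [
    "TermFit",
    "nb_logdensity",
    "nb_density",
    "upstream_stats",
    "apply_noise_cutoff",
    "fit_termination",
    "decline_pct_per_kb",
]


def nb_logdensity(x, n, disp):
    """Log pmf of the negative binomial: C(x+d-1, x) (d/(d+n))^d (n/(d+n))^x.

    ``n`` is the mean, ``disp`` (= d) the size parameter; d -> inf recovers
    Poisson(n).
    """
    x = np.asarray(x, dtype=float)
    n = np.maximum(np.asarray(n, dtype=float), 1e-12)
    disp = np.asarray(disp, dtype=float)
    if np.any(disp <= 0):
        raise ValueError("disp must be > 0")
    return (
        gammaln(x + disp)
        - gammaln(disp)
        - gammaln(x + 1)
        + disp * np.log(disp / (disp + n))
        + x * np.log(n / (disp + n))
    )


def nb_density(x, n, disp):
    return np.exp(nb_logdensity(x, n, disp))


def upstream_stats(wv: WindowVector, min_windows: int = 2) -> tuple[float, float]:
    """Mean and sd of the PAS-upstream windows of a pas_250nt grid.

    Falls back to the first five downstream windows when the upstream ones
    are all missing; raises if fewer than ``min_windows`` remain usable.
    """
    if wv.kind != "pas_250nt":
        raise ValueError("upstream_stats applies to pas_250nt grids")
    n_up = PAS_UPSTREAM_NT // wv.width_nt
    up = wv.counts[:n_up][~wv.missing[:n_up]]
    if len(up) == 0:
        down_mask = ~wv.missing[n_up:]
        idx = np.nonzero(down_mask)[0][:5]
        up = wv.counts[n_up:][idx]
    if len(up) < min_windows:
        raise ValueError(f"gene {wv.gene}: not enough windows for upstream stats")
    return float(np.mean(up)), float(np.std(up, ddof=1))


def apply_noise_cutoff(wv: WindowVector, m: float, run_length: int = 4, frac: float = 0.01) -> WindowVector:
    """Truncate the downstream grid after sustained near-zero signal.

    The first run of >= ``run_length`` consecutive non-missing downstream
    windows below ``frac * m`` flags that run's end and everything after it
    as missing (guards the exponential fit against spurious distal peaks).
    """
    n_up = PAS_UPSTREAM_NT // wv.width_nt
    missing = wv.missing.copy()
    threshold = frac * m
    run = 0
    for j in range(n_up, len(wv)):
        if missing[j]:
            continue
        if wv.counts[j] < threshold:
            run += 1
            if run >= run_length:
                missing[j + 1 :] = True
                break
        else:
            run = 0
    return WindowVector(wv.gene, wv.kind, wv.width_nt, wv.counts.copy(), missing)


@dataclass
class TermFit:
    gene: str
    o: float
    r: float  # per 250 nt window
    disp: float
    prior_m: float
    prior_sd: float
    loglik: float
    n_used: int
    converged: bool
    se_log_r: float | None = None
    ci_r: tuple[float, float] | None = None
    window_kb: float = 0.25

    @property
    def r_per_kb(self) -> float:
        """Decline rate in nats per kb."""
        return self.r / self.window_kb

    @property
    def decline_pct_per_kb(self) -> float:
        return decline_pct_per_kb(self.r, self.window_kb)


def decline_pct_per_kb(r_per_window: float, window_kb: float = 0.25) -> float:
    """Survival form of the decline: percent of signal lost per kb."""
    return 100.0 * (1.0 - np.exp(-r_per_window / window_kb))


def fit_termination(
    wv: WindowVector,
    m: float | None = None,
    sd: float | None = None,
    min_windows: int = 6,
) -> TermFit:
    """NB regression of the post-PAS exponential decay with a Gaussian prior.

    Maximizes sum_i log dnb(a_i; o e^{-r i}, disp) + n * log N(o; m, sd) over
    the non-missing downstream windows (i at window centers, in window
    units from the PAS). A degenerate prior sd is widened to 0.1*m + 1.
    """
    if m is None or sd is None:
        m_, sd_ = upstream_stats(wv)
        m = m_ if m is None else m
        sd = sd_ if sd is None else sd
    sd = max(sd, 0.1 * m + 1.0)
    n_up = PAS_UPSTREAM_NT // wv.width_nt
    down = wv.counts[n_up:]
    down_missing = wv.missing[n_up:]
    use = ~down_missing
    n_used = int(use.sum())
    if n_used < min_windows:
        raise ValueError(f"gene {wv.gene}: {n_used} usable downstream windows < {min_windows}")
    pos = (np.arange(len(down)) + 0.5)[use]
    x = np.rint(np.maximum(down[use], 0.0))

    def nll(theta: np.ndarray) -> float:
        o, r, disp = np.exp(theta)
        mu = o * np.exp(-r * pos)
        ll = float(np.sum(nb_logdensity(x, mu, disp)))
        prior = -0.5 * ((o - m) / sd) ** 2 - np.log(sd * np.sqrt(2 * np.pi))
        return -(ll + n_used * prior)

    o0 = max(m, x[:5].mean() if len(x) >= 5 else x.mean(), 1e-3)
    starts = [np.log([o0, r0, 5.0]) for r0 in (0.01, 0.05, 0.2)]
    bounds = [(-10.0, 25.0), (np.log(1e-5), np.log(5.0)), (np.log(1e-2), np.log(1e7))]
    res = multistart_minimize(nll, starts, bounds)
    if res is None:
        return TermFit(wv.gene, np.nan, np.nan, np.nan, m, sd, np.nan, n_used, False)
    o, r, disp = np.exp(res.x)
    ses = hessian_ses(nll, res.x)
    se_log_r = None
    ci_r = None
    if ses is not None:
        se_log_r = float(ses[1])
        ci_r = (float(r * np.exp(-Z95 * se_log_r)), float(r * np.exp(Z95 * se_log_r)))
    return TermFit(
        gene=wv.gene,
        o=float(o),
        r=float(r),
        disp=float(disp),
        prior_m=float(m),
        prior_sd=float(sd),
        loglik=-float(res.fun),
        n_used=n_used,
        converged=bool(res.success),
        se_log_r=se_log_r,
        ci_r=ci_r,
        window_kb=wv.width_nt / 1000.0,
    )
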
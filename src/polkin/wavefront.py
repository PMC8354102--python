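"""DRB-chase wavefront estimation by negative-binomial regression.

After DRB washout, transcription restarts from the promoter and the advancing
front of 4sU-labeled signal after a chase of t minutes sits at e*t kb for
elongation rate e. Window counts along the gene body are modeled by

    w(i) = (o + (bg * 2^(-r*b) - o)/b * min(i, b)) * 2^(r * min(i, b))

which for r = 0 is the triangular DRB shape: linear from o at the TSS down to
the background level bg at the wavefront b, constant bg beyond. For r < 0
(processivity defect, r fixed to the gene-body LFC slope of the treated arm)
the ramp is multiplied by an exponential decay. The background level gets a
Gaussian prior (on the log scale) whose 5%/95% quantiles come from a
quantile regression of background density on expression across genes.
The fitted elongation rate is b / chase_min.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._optim import Z95, hessian_ses, multistart_minimize
from .termination import nb_logdensity
from .windows import WindowVector

__all__ = [
    "BackgroundModel",
    "WavefrontFit",
    "fit_background",
    "wavefront_profile",
    "fit_wavefront",
]

# the 5%..95% span of a normal distribution is 2 * 1.645 sd
NORMAL_5_95_SPAN = 3.2897072539029457
TSS_MASK_KB = 5.0


@dataclass(frozen=True)
class BackgroundModel:
    """Quantile fits (5% and 95%) of log background density vs log expression."""

    q05: tuple[float, float]  # (intercept, slope)
    q95: tuple[float, float]

    def predict(self, expression: float) -> tuple[float, float]:
        """(q05, q95) background levels (natural scale) for an expression RPK."""
        lx = np.log(expression)
        lo = self.q05[0] + self.q05[1] * lx
        hi = self.q95[0] + self.q95[1] * lx
        if hi < lo:
            lo, hi = hi, lo
        return float(np.exp(lo)), float(np.exp(hi))

    def log_prior_params(self, expression: float) -> tuple[float, float]:
        """Gaussian prior on log bg: mean = quantile midpoint, sd from the span."""
        lx = np.log(expression)
        lo = self.q05[0] + self.q05[1] * lx
        hi = self.q95[0] + self.q95[1] * lx
        if hi < lo:
            lo, hi = hi, lo
        return 0.5 * (lo + hi), max((hi - lo) / NORMAL_5_95_SPAN, 1e-3)


def fit_background(
    densities: np.ndarray, expression: np.ndarray, min_genes: int = 50
) -> BackgroundModel:
    """Quantile regression of log background density on log expression.

    Input densities are intronic read densities in the last 5 kb of long
    (>150 kb) genes; expression is spike-normalized reads per kb. Genes with
    non-positive values are dropped with a warning.
    """
    import statsmodels.api as sm

    d = np.asarray(densities, dtype=float)
    r = np.asarray(expression, dtype=float)
    ok = (d > 0) & (r > 0) & np.isfinite(d) & np.isfinite(r)
    if ok.sum() < len(d):
        warnings.warn(f"dropping {len(d) - int(ok.sum())} genes with non-positive values", stacklevel=2)
    d, r = d[ok], r[ok]
    if len(d) < min_genes:
        raise ValueError(f"need >= {min_genes} genes for the background model, got {len(d)}")
    logd, logr = np.log(d), np.log(r)
    if np.ptp(logr) < 1e-12:  # degenerate design: intercept-only quantiles
        return BackgroundModel(
            (float(np.quantile(logd, 0.05)), 0.0), (float(np.quantile(logd, 0.95)), 0.0)
        )
    X = sm.add_constant(logr)
    coefs = {}
    for q in (0.05, 0.95):
        fit = sm.QuantReg(logd, X).fit(q=q)
        coefs[q] = (float(fit.params[0]), float(fit.params[1]))
    return BackgroundModel(coefs[0.05], coefs[0.95])


def wavefront_profile(i, o, b, bg, r):
    """Expected counts at position i under the wavefront model."""
    i = np.asarray(i, dtype=float)
    m = np.minimum(i, b)
    return (o + (bg * 2.0 ** (-r * b) - o) / b * m) * 2.0 ** (r * m)


@dataclass
class WavefrontFit:
    gene: str
    o: float
    b: float  # wavefront, kb from TSS
    bg: float
    disp: float
    r_fixed: float
    chase_min: float
    loglik: float
    n_used: int
    converged: bool
    at_boundary: bool = False
    se_b: float | None = None
    ci_b: tuple[float, float] | None = None

    @property
    def elongation_rate(self) -> float:
        """kb/min."""
        return self.b / self.chase_min

    @property
    def rate_ci(self) -> tuple[float, float] | None:
        if self.ci_b is None:
            return None
        return (self.ci_b[0] / self.chase_min, self.ci_b[1] / self.chase_min)


def fit_wavefront(
    wv: WindowVector,
    chase_min: float,
    r_fixed: float = 0.0,
    background: BackgroundModel | None = None,
    expression: float | None = None,
    window_kb: float = 1.0,
    min_windows: int = 10,
    tss_mask_kb: float = TSS_MASK_KB,
) -> WavefrontFit:
    """NB fit of the wavefront model to gene-body window counts.

    The first 5 kb are flagged missing (promoter-proximal peak). Counts are
    evaluated at window centers. Multi-start over wavefronts implied by
    elongation-rate priors of 1..4 kb/min.
    """
    L = len(wv)
    pos = (np.arange(1, L + 1) - 0.5) * window_kb
    missing = wv.missing.copy()
    missing[pos < tss_mask_kb] = True
    use = ~missing
    n_used = int(use.sum())
    if n_used < min_windows:
        raise ValueError(f"gene {wv.gene}: {n_used} usable windows < {min_windows}")
    iu = pos[use]
    x = np.rint(np.maximum(wv.counts[use], 0.0))
    L_kb = L * window_kb

    prior = None
    if background is not None:
        if expression is None:
            raise ValueError("background prior needs the gene's expression")
        prior = background.log_prior_params(expression)

    def nll(theta: np.ndarray) -> float:
        logo, b, logbg, logdisp = theta
        mu = wavefront_profile(iu, np.exp(logo), b, np.exp(logbg), r_fixed)
        val = -float(np.sum(nb_logdensity(x, mu, np.exp(logdisp))))
        if prior is not None:
            mu_p, sd_p = prior
            val += 0.5 * ((logbg - mu_p) / sd_p) ** 2 + np.log(sd_p * np.sqrt(2 * np.pi))
        return val

    o0 = max(float(x.max()), 1.0)
    if prior is not None:
        bg0 = float(np.exp(prior[0]))
    else:
        bg0 = max(float(np.median(x[-max(3, len(x) // 10):])), 0.1)
    starts = [
        np.array([np.log(o0), min(max(ep * chase_min, tss_mask_kb + 1.0), L_kb - 0.5), np.log(max(bg0, 1e-3)), np.log(10.0)])
        for ep in (1.0, 2.0, 3.0, 4.0)
    ]
    bounds = [(-5.0, 30.0), (tss_mask_kb + 0.5, L_kb), (-10.0, 30.0), (np.log(1e-2), np.log(1e7))]
    res = multistart_minimize(nll, starts, bounds)
    if res is None:
        return WavefrontFit(wv.gene, np.nan, np.nan, np.nan, np.nan, r_fixed, chase_min, np.nan, n_used, False)
    logo, b, logbg, logdisp = res.x
    at_boundary = b >= L_kb - 0.5 * window_kb or b <= tss_mask_kb + window_kb
    ses = hessian_ses(nll, res.x)
    se_b = None
    ci_b = None
    if ses is not None:
        se_b = float(ses[1])
        ci_b = (float(b - Z95 * se_b), float(b + Z95 * se_b))
    return WavefrontFit(
        gene=wv.gene,
        o=float(np.exp(logo)),
        b=float(b),
        bg=float(np.exp(logbg)),
        disp=float(np.exp(logdisp)),
        r_fixed=float(r_fixed),
        chase_min=float(chase_min),
        loglik=-float(res.fun),
        n_used=n_used,
        converged=bool(res.success),
        at_boundary=at_boundary,
        se_b=se_b,
        ci_b=ci_b,
    )
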
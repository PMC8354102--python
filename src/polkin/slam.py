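"""Synthesis/degradation kinetics from metabolic-labeling (SLAM-seq) tables.

Total RNA a(t) of a gene with synthesis rate sigma (RNA units/h) and
degradation rate delta (1/h) follows da/dt = sigma - delta*a with solution
a(t) = (a0 - sigma/delta) e^(-t delta) + sigma/delta. Splitting by label:

    old, control:  f = (sigma/delta) e^(-t delta)     (steady state)
    old, treated:  f = a0 e^(-t delta)                (non-steady state)
    new, either:   f = (sigma/delta) (1 - e^(-t delta))

Per-sample new/old levels are count*NTR and count*(1-NTR) of size-factor
normalized counts. Fits minimize equally weighted residuals; new-RNA points
at late timepoints (2 h and 4 h by default) are excluded because prolonged
labeling depresses apparent new-RNA levels, so degradation rates come from
all timepoints (old RNA) and synthesis rates effectively from the 1 h
new-RNA level plus the degradation rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "SlamGeneData",
    "KineticFit",
    "model_curves",
    "size_factors_median_of_ratios",
    "fit_control",
    "fit_auxin",
    "net_rate_ratio",
    "read_slam_table",
]

EXCLUDED_NEW_TIMES = (2.0, 4.0)


def model_curves(t, sigma, delta, a0=None, arm="ctrl"):
    """(f_old, f_new) at times t for one arm; control ignores a0."""
    t = np.asarray(t, dtype=float)
    if delta <= 0:
        raise ValueError("delta must be > 0")
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    decay = np.exp(-t * delta)
    ss = sigma / delta
    f_new = ss * (1.0 - decay)
    if arm == "ctrl":
        f_old = ss * decay
    elif arm == "aux":
        if a0 is None:
            raise ValueError("auxin arm needs a0")
        f_old = a0 * decay
    else:
        raise ValueError(f"unknown arm {arm!r}")
    return f_old, f_new


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (genes x samples matrix).

    factor_s = median over all-positive genes of count_{g,s} / geometric
    mean_g. Raises when no gene is positive in every sample.
    """
    mat = counts.to_numpy(dtype=float)
    pos = np.all(mat > 0, axis=1)
    if not pos.any():
        raise ValueError("no gene with all-positive counts")
    sub = mat[pos]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(sub) - log_geo, axis=0))
    return pd.Series(factors, index=counts.columns)


@dataclass
class SlamGeneData:
    """Normalized counts and NTRs of one gene across the SLAM design."""

    gene: str
    table: pd.DataFrame  # columns: arm, time_h, rep, count, ntr

    def __post_init__(self) -> None:
        t = self.table
        if (t["count"] < 0).any() or ((t["ntr"] < 0) | (t["ntr"] > 1)).any():
            raise ValueError(f"gene {self.gene}: counts must be >= 0 and NTR in [0, 1]")

    def levels(self, arm: str) -> pd.DataFrame:
        """Long table (time_h, rep, label, level) with g_new + g_old = count."""
        sub = self.table[self.table["arm"] == arm]
        new = sub.assign(label="new", level=sub["count"] * sub["ntr"])
        old = sub.assign(label="old", level=sub["count"] * (1.0 - sub["ntr"]))
        return pd.concat([new, old], ignore_index=True)[["time_h", "rep", "label", "level"]]


@dataclass
class KineticFit:
    gene: str
    arm: str
    sigma: float
    delta: float
    a0: float | None
    sse: float
    n_points: int
    converged: bool
    delta_at_bound: bool = False
    excluded: list[tuple[str, float]] = field(default_factory=list)
    se_log_sigma: float | None = None
    se_log_delta: float | None = None

    @property
    def steady_state(self) -> float:
        return self.sigma / self.delta


DELTA_LO, DELTA_HI = 1e-4, 50.0


def _fit_points(
    gene: str,
    arm: str,
    pts: pd.DataFrame,
    a0: float | None,
    min_points: int,
) -> KineticFit:
    t = pts["time_h"].to_numpy(dtype=float)
    y = pts["level"].to_numpy(dtype=float)
    is_new = (pts["label"] == "new").to_numpy()
    if len(pts) < min_points:
        raise ValueError(f"gene {gene}: {len(pts)} usable points < {min_points}")
    if len(np.unique(t)) < 2:
        raise ValueError(f"gene {gene}: kinetics unidentifiable from a single timepoint")

    def resid(theta: np.ndarray) -> np.ndarray:
        sigma, delta = np.exp(theta)
        f_old, f_new = model_curves(t, sigma, delta, a0=a0, arm=arm)
        return np.where(is_new, f_new, f_old) - y

    # start from a log-linear decay regression of the old-RNA levels
    old = ~is_new
    lvl0 = max(float(np.mean(y[old & (t == t.min())])) if (old & (t == t.min())).any() else float(y.max()), 1e-6)
    if old.sum() >= 2 and np.ptp(t[old]) > 0:
        with np.errstate(divide="ignore"):
            ly = np.log(np.maximum(y[old], 1e-9))
        slope = float(np.polyfit(t[old], ly, 1)[0])
        d0 = float(np.clip(-slope, 1e-3, 10.0))
    else:
        d0 = 0.5
    s0 = max(lvl0 * d0, 1e-6)
    best = None
    for d_start in (d0, 0.1, 1.0):
        res = least_squares(
            resid,
            np.log([max(s0, 1e-6), d_start]),
            bounds=(np.log([1e-9, DELTA_LO]), np.log([1e12, DELTA_HI])),
        )
        if best is None or res.cost < best.cost:
            best = res
    sigma, delta = np.exp(best.x)
    sse = float(2 * best.cost)
    # quadratic approximation at the optimum: cov = s^2 (J^T J)^-1
    se_ls = se_ld = None
    dof = len(y) - 2
    if dof > 0:
        JTJ = best.jac.T @ best.jac
        try:
            cov = np.linalg.inv(JTJ) * (sse / dof)
            if np.all(np.diag(cov) > 0):
                se_ls, se_ld = (float(v) for v in np.sqrt(np.diag(cov)))
        except np.linalg.LinAlgError:
            pass
    delta_at_bound = bool(delta <= DELTA_LO * 1.01 or delta >= DELTA_HI * 0.99)
    return KineticFit(
        gene=gene,
        arm=arm,
        sigma=float(sigma),
        delta=float(delta),
        a0=a0,
        sse=sse,
        n_points=len(y),
        converged=bool(best.success) and not delta_at_bound,
        delta_at_bound=delta_at_bound,
        se_log_sigma=se_ls,
        se_log_delta=se_ld,
    )


def _apply_exclusions(levels: pd.DataFrame, excluded_new_times) -> tuple[pd.DataFrame, list]:
    drop = (levels["label"] == "new") & levels["time_h"].isin(excluded_new_times)
    excl = [("new", float(tt)) for tt in sorted(set(levels.loc[drop, "time_h"]))]
    return levels[~drop].reset_index(drop=True), excl


def fit_control(
    g: SlamGeneData,
    excluded_new_times=EXCLUDED_NEW_TIMES,
    min_points: int = 4,
) -> KineticFit:
    """Steady-state fit of (sigma, delta) from the control arm."""
    levels, excl = _apply_exclusions(g.levels("ctrl"), excluded_new_times)
    fit = _fit_points(g.gene, "ctrl", levels, a0=None, min_points=min_points)
    fit.excluded = excl
    return fit


def fit_auxin(
    g: SlamGeneData,
    excluded_new_times=EXCLUDED_NEW_TIMES,
    min_points: int = 4,
) -> KineticFit:
    """Non-steady-state fit for the treated arm.

    a0 is fixed to the mean old-RNA level at time 0 across replicates.
    """
    levels = g.levels("aux")
    at0 = levels[(levels["time_h"] == 0) & (levels["label"] == "old")]
    if at0.empty:
        raise ValueError(f"gene {g.gene}: no time-0 old-RNA replicates in the treated arm")
    a0 = float(at0["level"].mean())
    levels, excl = _apply_exclusions(levels, excluded_new_times)
    fit = _fit_points(g.gene, "aux", levels, a0=a0, min_points=min_points)
    fit.excluded = excl
    return fit


def net_rate_ratio(fit_aux: KineticFit, fit_ctrl: KineticFit) -> tuple[float, float]:
    """(sigma_ctrl / sigma_aux, log2 of it); inf when sigma_aux = 0."""
    if not (fit_aux.converged and fit_ctrl.converged):
        raise ValueError("both fits must have converged")
    if fit_aux.sigma == 0:
        return float("inf"), float("inf")
    ratio = fit_ctrl.sigma / fit_aux.sigma
    return float(ratio), float(np.log2(ratio))


def read_slam_table(path) -> dict[str, SlamGeneData]:
    """TSV with columns gene, arm, time_h, rep, count, ntr."""
    df = pd.read_csv(path, sep="\t")
    return {
        str(gene): SlamGeneData(str(gene), sub.reset_index(drop=True))
        for gene, sub in df.groupby("gene", sort=False)
    }
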
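"""Synthetic cohort generator with known ground truth.

Emulates the structure of the study design every fitting module consumes:
triplicate pulse-labeled nascent RNA (two arms: control and acutely
depleted), DRB chases at 10/20/30 min, occupancy (ChIP-like) profiles,
PAS-centered termination grids, and metabolic-labeling tables at 0/1/2/4 h.
Window counts are negative-binomial around model-derived means; the defaults
are the conditions the fits are validated against (control elongation
3 kb/min, treated 75% of control; treated processivity defect 1%/kb;
termination rates halved in the treated arm; treated synthesis rates reduced
8-fold).

Gene-body 4sU window means are proportional to steady-state polymerase
occupancy: the labeled nucleotides deposited in window i during a pulse are
proportional to the polymerase flux through it, so the intronic window
counts track occupancy (which is what makes the 4sU and occupancy LFC slopes
match). The simulator's suffix-sum profile models whole-transcript pulldown
and is used for the DRB read-out, where the labeled transcripts are the
chase products themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import SimParams, simulate_experiment
from .windows import PAS_DOWNSTREAM_NT, PAS_UPSTREAM_NT, TranscriptionUnit, WindowVector

__all__ = ["SynthConfig", "generate_cohort", "generate_counts", "generate_slam", "write_cohort"]

ASSAY_CODES = {"foursu": 1, "chip": 2, "drb": 3, "pas": 4, "slam": 5}
ARM_CODES = {"ctrl": 1, "aux": 2}


@dataclass(frozen=True)
class SynthConfig:
    """Ground-truth distributions and experiment design of a cohort."""

    seed: int = 0
    n_genes: int = 300
    length_kb_range: tuple[float, float] = (5.0, 200.0)  # log-uniform
    p_init_min: float = 2.0
    e_control: float = 3.0
    e_treated_factor: float = 0.75
    d_control: float = 0.0
    d_treated: float = 0.01
    term_r_control: float = 0.0558  # per 250 nt window (~20 %/kb survival)
    term_r_sigma: float = 0.25  # lognormal spread across genes
    term_r_treated_factor: float = 0.5
    nb_dispersion_range: tuple[float, float] = (5.0, 10.0)
    mean_body_counts: float = 200.0  # median 1 kb window depth at steady state
    expression_sigma: float = 0.8  # lognormal spread of per-gene depth
    drb_peak_counts: float = 500.0
    drb_background_frac: float = 0.01
    chase_minutes: tuple[float, ...] = (10.0, 20.0, 30.0)
    slam_sigma_median: float = 60.0  # RNA units / h
    slam_sigma_spread: float = 0.8
    slam_delta_median: float = 0.25  # 1/h
    slam_delta_spread: float = 0.5
    slam_sigma_treated_factor: float = 0.125  # 8-fold reduction
    # NTR precision scales with the number of reads classified: the Beta
    # concentration is kappa_per_read * count (plus a floor for tiny genes)
    slam_ntr_kappa_per_read: float = 1.0
    slam_ntr_kappa_floor: float = 20.0
    timepoints_h: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0)
    n_replicates: int = 3
    drb_window_kb: float = 1 / 16  # fine simulation grid for DRB profiles
    replicate_lognorm_sd: float = 0.05  # library-size wobble between reps


def _rng(config: SynthConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, *stream])


def generate_cohort(config: SynthConfig) -> tuple[list[TranscriptionUnit], pd.DataFrame]:
    """Draw per-gene ground truth and lay TUs on a synthetic chromosome.

    Genes are spaced >25 kb apart on alternating strands so termination
    grids never collide. Each gene gets 2-4 short exons (masked windows).
    """
    rng = _rng(config, 0)
    lo, hi = config.length_kb_range
    lengths_kb = np.exp(rng.uniform(np.log(lo), np.log(hi), config.n_genes))
    expr = np.exp(rng.normal(np.log(config.mean_body_counts), config.expression_sigma, config.n_genes))
    disp = rng.uniform(*config.nb_dispersion_range, config.n_genes)
    r_ctrl = config.term_r_control * np.exp(rng.normal(0, config.term_r_sigma, config.n_genes))
    sigma_c = config.slam_sigma_median * np.exp(rng.normal(0, config.slam_sigma_spread, config.n_genes))
    delta = config.slam_delta_median * np.exp(rng.normal(0, config.slam_delta_spread, config.n_genes))

    tus: list[TranscriptionUnit] = []
    rows = []
    cursor = 100_000
    gap = PAS_DOWNSTREAM_NT + 30_000
    for g in range(config.n_genes):
        length_nt = int(round(lengths_kb[g] * 1000))
        strand = "+" if g % 2 == 0 else "-"
        start = cursor
        end = start + length_nt
        n_ex = int(rng.integers(2, 5))
        exons = []
        for _ in range(n_ex):
            w = int(rng.integers(150, 1500))
            if length_nt <= w + 2:
                continue
            off = int(rng.integers(0, length_nt - w))
            exons.append((start + off, start + off + w))
        exons.sort()
        tss, pas = (start, end) if strand == "+" else (end, start)
        tus.append(TranscriptionUnit(f"g{g:04d}", "chrS", strand, tss, pas, tuple(exons)))
        rows.append(
            dict(
                gene=f"g{g:04d}",
                length_kb=length_nt / 1000.0,
                strand=strand,
                expression=expr[g],
                disp=disp[g],
                p=config.p_init_min,
                e_ctrl=config.e_control,
                e_aux=config.e_control * config.e_treated_factor,
                d_ctrl=config.d_control,
                d_aux=config.d_treated,
                r_term_ctrl=r_ctrl[g],
                r_term_aux=r_ctrl[g] * config.term_r_treated_factor,
                sigma_ctrl=sigma_c[g],
                sigma_aux=sigma_c[g] * config.slam_sigma_treated_factor,
                delta=delta[g],
            )
        )
        cursor = end + gap
    columns = [
        "gene", "length_kb", "strand", "expression", "disp", "p", "e_ctrl", "e_aux",
        "d_ctrl", "d_aux", "r_term_ctrl", "r_term_aux", "sigma_ctrl", "sigma_aux", "delta",
    ]
    df = pd.DataFrame(rows, columns=columns)
    return tus, df.set_index(pd.Index(df["gene"].to_numpy()))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, disp: float) -> np.ndarray:
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    return rng.negative_binomial(disp, disp / (disp + mean)).astype(float)


def _exon_mask(tu: TranscriptionUnit, n_windows: int, width_nt: int = 1000) -> np.ndarray:
    """Missing mask for body windows overlapping an exon."""
    mask = np.zeros(n_windows, dtype=bool)
    sign = 1 if tu.strand == "+" else -1
    for es, ee in tu.exons:
        a = min((es - tu.tss) * sign, (ee - tu.tss) * sign)
        b = max((es - tu.tss) * sign, (ee - tu.tss) * sign)
        w0 = max(int(a // width_nt), 0)
        w1 = min(int(np.ceil(b / width_nt)), n_windows)
        mask[w0:w1] = True
    return mask


def _body_profile(truth_row: pd.Series, arm: str, n_windows: int, config: SynthConfig, assay: str) -> np.ndarray:
    e = float(truth_row[f"e_{arm}"])
    d = float(truth_row[f"d_{arm}"])
    base = float(truth_row["expression"])
    i = np.arange(1, n_windows + 1, dtype=float)
    decay = (1.0 + d) ** (-i)
    if assay == "chip":
        # occupancy ~ (1/(p e (1+d))) (1+d)^(-(i-1)): depth scales with 1/e
        return base * (config.e_control / e) * decay
    # labeled deposition per window ~ flux e*occ_i ~ (1/p)(1+d)^(-i):
    # 4sU depth is independent of the elongation rate
    return base * decay


def _drb_profile(truth_row: pd.Series, arm: str, chase_min: float, config: SynthConfig) -> np.ndarray:
    n_kb = int(truth_row["length_kb"])
    w = config.drb_window_kb
    params = SimParams(p=truth_row["p"], e=truth_row[f"e_{arm}"], d=truth_row[f"d_{arm}"], L=float(n_kb), w=w)
    prof = simulate_experiment(params, "drb", label_min=chase_min).binned(1.0).foursu
    mx = prof.max()
    if mx <= 0:
        return np.zeros(n_kb)
    return prof / mx * config.drb_peak_counts


def generate_counts(
    tus: list[TranscriptionUnit],
    truth: pd.DataFrame,
    assay: str,
    arm: str,
    rep: int,
    config: SynthConfig,
    chase_min: float | None = None,
) -> dict[str, WindowVector]:
    """NB-noised window-count vectors for one assay/arm/replicate."""
    if assay not in ASSAY_CODES:
        raise ValueError(f"unknown assay {assay!r}")
    if arm not in ARM_CODES:
        raise ValueError(f"unknown arm {arm!r}")
    if assay == "drb" and chase_min is None:
        raise ValueError("drb assay needs chase_min")
    out: dict[str, WindowVector] = {}
    for gi, tu in enumerate(tus):
        row = truth.loc[tu.id]
        rng = _rng(config, ASSAY_CODES[assay], ARM_CODES[arm], rep, int(chase_min or 0), gi)
        lib = float(np.exp(rng.normal(0.0, config.replicate_lognorm_sd)))
        disp = float(row["disp"])
        if assay in ("foursu", "chip"):
            n_win = int(row["length_kb"])
            if n_win < 1:
                out[tu.id] = WindowVector(tu.id, "body_1kb", 1000, np.zeros(0), np.zeros(0, bool))
                continue
            mu = _body_profile(row, arm, n_win, config, assay) * lib
            counts = _nb_draw(rng, mu, disp)
            out[tu.id] = WindowVector(tu.id, "body_1kb", 1000, counts, _exon_mask(tu, n_win))
        elif assay == "drb":
            n_win = int(row["length_kb"])
            if n_win < 1:
                out[tu.id] = WindowVector(tu.id, "body_1kb", 1000, np.zeros(0), np.zeros(0, bool))
                continue
            mu = _drb_profile(row, arm, chase_min, config)
            bg = config.drb_background_frac * row["expression"]
            counts = _nb_draw(rng, mu + bg, disp)
            out[tu.id] = WindowVector(tu.id, "body_1kb", 1000, counts, _exon_mask(tu, n_win))
        elif assay == "pas":
            n_up = PAS_UPSTREAM_NT // 250
            n_down = PAS_DOWNSTREAM_NT // 250
            level = row["expression"] / 4.0  # 250 nt windows hold 1/4 of a 1 kb window
            r = row[f"r_term_{arm}"]
            i = np.arange(n_down) + 0.5
            mu = np.concatenate([np.full(n_up, level), level * np.exp(-r * i)]) * lib
            counts = _nb_draw(rng, mu, disp)
            out[tu.id] = WindowVector(tu.id, "pas_250nt", 250, counts, np.zeros(n_up + n_down, bool))
    return out


def generate_slam(
    tus: list[TranscriptionUnit], truth: pd.DataFrame, config: SynthConfig, noiseless: bool = False
) -> pd.DataFrame:
    """SLAM table (gene, arm, time_h, rep, count, ntr) from the closed forms.

    The treated arm starts non-steady-state from the control steady level
    (a0 = sigma_ctrl/delta). NTR noise is Beta(kappa*ntr, kappa*(1-ntr));
    at t=0 the true NTR is exactly 0 and stays 0.

    Counts are per-TU totals, i.e. sums over ~length_kb windows each carrying
    the configured per-window NB dispersion, so the TU-level NB size is the
    per-window size times the number of windows (overdispersion averages
    out across windows of the same gene).
    """
    rows = []
    for gi, tu in enumerate(tus):
        row = truth.loc[tu.id]
        tu_disp = float(row["disp"]) * max(float(row["length_kb"]), 1.0)
        delta = float(row["delta"])
        ss_ctrl = row["sigma_ctrl"] / delta
        for arm in ("ctrl", "aux"):
            sigma = float(row[f"sigma_{arm}"])
            for t in config.timepoints_h:
                decay = np.exp(-t * delta)
                f_new = sigma / delta * (1.0 - decay)
                f_old = (ss_ctrl if arm == "aux" else sigma / delta) * decay
                total = f_new + f_old
                ntr_true = f_new / total if total > 0 else 0.0
                for rep in range(1, config.n_replicates + 1):
                    rng = _rng(config, ASSAY_CODES["slam"], ARM_CODES[arm], rep, int(t * 10), gi)
                    if noiseless:
                        count, ntr = total, ntr_true
                    else:
                        count = float(_nb_draw(rng, np.array([total]), tu_disp)[0])
                        k = max(config.slam_ntr_kappa_per_read * count, config.slam_ntr_kappa_floor)
                        if 0.0 < ntr_true < 1.0:
                            ntr = float(rng.beta(k * ntr_true, k * (1.0 - ntr_true)))
                        else:
                            ntr = float(ntr_true)
                    rows.append((tu.id, arm, t, rep, count, ntr))
    return pd.DataFrame(rows, columns=["gene", "arm", "time_h", "rep", "count", "ntr"])


def write_cohort(outdir, tus: list[TranscriptionUnit], truth: pd.DataFrame) -> None:
    """Write TU BED12 and the truth table."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "tus.bed", "w") as fh:
        for tu in tus:
            exons = tu.exons or ((tu.start, tu.start + 1),)
            sizes = ",".join(str(e - s) for s, e in exons) + ","
            offs = ",".join(str(s - tu.start) for s, e in exons) + ","
            fh.write(
                f"{tu.chrom}\t{tu.start}\t{tu.end}\t{tu.id}\t0\t{tu.strand}\t"
                f"{tu.start}\t{tu.end}\t0\t{len(exons)}\t{sizes}\t{offs}\n"
            )
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
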
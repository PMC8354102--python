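"""Window systems over transcription units and strand-aware coverage counting.

Coordinates are 0-based half-open throughout; window vectors are oriented in
the direction of transcription (window 1 starts at the TSS, so for a minus
strand TU window 1 is genomically rightmost). PAS-centered grids tile 5 kb
upstream and 25 kb downstream of the polyadenylation site in 250 nt windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TranscriptionUnit",
    "WindowVector",
    "Coverage",
    "make_windows",
    "count_coverage",
    "flag_termination_missing",
    "spike_size_factors",
    "read_bedgraph",
    "read_tus_bed",
    "write_window_table",
    "read_window_table",
]

PAS_UPSTREAM_NT = 5000
PAS_DOWNSTREAM_NT = 25000
PAS_WINDOW_NT = 250
BODY_WINDOW_NT = 1000


@dataclass(frozen=True)
class TranscriptionUnit:
    """One TSS-PAS pair with an exon mask defining intronic windows."""

    id: str
    chrom: str
    strand: str
    tss: int
    pas: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if (self.pas - self.tss) * (1 if self.strand == "+" else -1) <= 0:
            raise ValueError(f"TU {self.id}: PAS must lie downstream of TSS")

    @property
    def start(self) -> int:
        return min(self.tss, self.pas)

    @property
    def end(self) -> int:
        return max(self.tss, self.pas)

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    def genomic(self, offset_nt: float) -> float:
        """Genomic coordinate at a transcription-oriented offset from the TSS."""
        return self.tss + offset_nt if self.strand == "+" else self.tss - offset_nt


@dataclass
class WindowVector:
    """Per-gene window counts with a missing-value mask.

    kind 'body_1kb': window 1 starts at the TSS; kind 'pas_250nt': the grid
    spans PAS-5 kb .. PAS+25 kb (20 upstream + 100 downstream windows).
    """

    gene: str
    kind: str
    width_nt: int
    counts: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.missing is None:
            self.missing = np.zeros(len(self.counts), dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if len(self.counts) != len(self.missing):
            raise ValueError("counts and missing must have equal length")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def n_used(self) -> int:
        return int((~self.missing).sum())

    def used(self) -> tuple[np.ndarray, np.ndarray]:
        """(window indices, counts) of non-missing windows; indices 0-based."""
        idx = np.nonzero(~self.missing)[0]
        return idx, self.counts[idx]


def make_windows(
    tu: TranscriptionUnit, kind: str = "body_1kb", width_nt: int | None = None
) -> list[tuple[int, int]]:
    """Tile a TU region with non-overlapping windows (genomic intervals).

    Returned in transcription orientation; a partial terminal window is
    dropped so every window has identical exposure.
    """
    if kind == "body_1kb":
        width = width_nt or BODY_WINDOW_NT
        n = tu.length_nt // width
        if n == 0:
            warnings.warn(f"TU {tu.id} shorter than one window", stacklevel=2)
            return []
        offsets = np.arange(n + 1) * width
    elif kind == "pas_250nt":
        width = width_nt or PAS_WINDOW_NT
        offsets = np.arange(-PAS_UPSTREAM_NT, PAS_DOWNSTREAM_NT + 1, width)
        anchor = tu.pas
        if tu.strand == "+":
            return [(anchor + int(s), anchor + int(s) + width) for s in offsets[:-1]]
        return [(anchor - int(s) - width, anchor - int(s)) for s in offsets[:-1]]
    elif kind == "custom":
        if width_nt is None:
            raise ValueError("custom windows need width_nt")
        width = width_nt
        n = tu.length_nt // width
        if n == 0:
            warnings.warn(f"TU {tu.id} shorter than one window", stacklevel=2)
            return []
        offsets = np.arange(n + 1) * width
    else:
        raise ValueError(f"unknown window kind {kind!r}")
    if tu.strand == "+":
        return [(tu.tss + int(a), tu.tss + int(b)) for a, b in zip(offsets[:-1], offsets[1:])]
    return [(tu.tss - int(b), tu.tss - int(a)) for a, b in zip(offsets[:-1], offsets[1:])]


class Coverage:
    """Strand-keyed per-chromosome coverage with O(log n) interval sums.

    Built from sorted, non-overlapping bedGraph intervals; ``integral(chrom,
    start, end)`` returns the per-nucleotide sum of coverage over the
    interval.
    """

    def __init__(self) -> None:
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_intervals(
        cls, df: pd.DataFrame
    ) -> "Coverage":
        """df columns: chrom, start, end, value (sorted, non-overlapping)."""
        cov = cls()
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            vals = sub["value"].to_numpy(dtype=float)
            if np.any(np.diff(starts) < 0) or np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"bedGraph intervals for {chrom} not sorted/disjoint")
            # cumulative integral at interval starts
            cum = np.concatenate([[0.0], np.cumsum(vals * (ends - starts))])
            cov._chroms[str(chrom)] = (starts, ends, cum)
        return cov

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._chroms

    def _cum_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        starts, ends, cum = self._chroms[chrom]
        i = np.searchsorted(starts, pos, side="right") - 1
        out = np.where(i >= 0, cum[np.maximum(i, 0)], 0.0)
        inside = i >= 0
        ii = np.maximum(i, 0)
        # add partial interval up to pos, clipped at interval end
        vals = np.where(ends[ii] > starts[ii], (cum[ii + 1] - cum[ii]) / (ends[ii] - starts[ii]), 0.0)
        partial = np.clip(pos - starts[ii], 0, ends[ii] - starts[ii]) * vals
        return out + np.where(inside, partial, 0.0)

    def integral(self, chrom: str, start: np.ndarray, end: np.ndarray) -> np.ndarray:
        if chrom not in self._chroms:
            raise KeyError(chrom)
        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        return self._cum_at(chrom, end) - self._cum_at(chrom, start)


def read_bedgraph(path) -> Coverage:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"], comment="#"
    )
    return Coverage.from_intervals(df)


def count_coverage(
    coverage: Coverage,
    tu: TranscriptionUnit,
    windows: list[tuple[int, int]],
    kind: str = "body_1kb",
    input_coverage: Coverage | None = None,
    flag_exons: bool = True,
) -> WindowVector:
    """Sum per-nucleotide coverage into windows.

    Windows overlapping an exon of the TU are flagged missing. With
    ``input_coverage`` (ChIP input correction) the input integral is
    subtracted; negative corrected values are retained here and 0-censored
    only when a likelihood with integer support is evaluated.
    """
    width = windows[0][1] - windows[0][0] if windows else 0
    n = len(windows)
    if n and not coverage.has_chrom(tu.chrom):
        warnings.warn(f"chromosome {tu.chrom} absent from coverage", stacklevel=2)
        return WindowVector(tu.id, kind, width, np.zeros(n), np.ones(n, dtype=bool))
    starts = np.array([w[0] for w in windows], dtype=np.int64)
    ends = np.array([w[1] for w in windows], dtype=np.int64)
    counts = coverage.integral(tu.chrom, starts, ends) if n else np.zeros(0)
    if input_coverage is not None and n:
        if input_coverage.has_chrom(tu.chrom):
            counts = counts - input_coverage.integral(tu.chrom, starts, ends)
    missing = np.zeros(n, dtype=bool)
    if flag_exons:
        for es, ee in tu.exons:
            missing |= (starts < ee) & (ends > es)
    return WindowVector(tu.id, kind, width, counts, missing)


def flag_termination_missing(
    tu: TranscriptionUnit,
    wv: WindowVector,
    neighbors: list[TranscriptionUnit] | None = None,
) -> WindowVector:
    """Apply the termination-zone masking rules to a pas_250nt grid.

    1. (exon overlap handled at counting time)
    2. If the TU is shorter than the upstream span (5 kb), all upstream
       windows are flagged.
    3. If another same-strand TU starts within the downstream span (25 kb)
       of the PAS, all windows from its TSS on are flagged.
    """
    if wv.kind != "pas_250nt":
        raise ValueError("termination masking applies to pas_250nt grids")
    n_up = PAS_UPSTREAM_NT // wv.width_nt
    missing = wv.missing.copy()
    if tu.length_nt < PAS_UPSTREAM_NT:
        missing[:n_up] = True
    if neighbors:
        sign = 1 if tu.strand == "+" else -1
        for other in neighbors:
            if other.id == tu.id or other.strand != tu.strand or other.chrom != tu.chrom:
                continue
            dist = (other.tss - tu.pas) * sign
            if 0 <= dist < PAS_DOWNSTREAM_NT:
                first_flagged = n_up + int(dist // wv.width_nt)
                missing[first_flagged:] = True
    return WindowVector(wv.gene, wv.kind, wv.width_nt, wv.counts.copy(), missing)


def spike_size_factors(spike_totals: dict[str, float] | pd.Series) -> pd.Series:
    """Per-sample divisors: total spike-in reads / median across samples."""
    s = pd.Series(spike_totals, dtype=float)
    if (s <= 0).any():
        bad = list(s.index[s <= 0])
        raise ValueError(f"samples with non-positive spike totals: {bad}")
    return s / s.median()


def read_tus_bed(path) -> list[TranscriptionUnit]:
    """Read TUs from BED6 (thickStart/thickEnd columns optional = exons in BED12)."""
    tus = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, name, _score, strand = f[:6]
            start, end = int(start), int(end)
            exons: tuple[tuple[int, int], ...] = ()
            if len(f) >= 12:  # BED12 blocks
                sizes = [int(x) for x in f[10].rstrip(",").split(",") if x]
                offs = [int(x) for x in f[11].rstrip(",").split(",") if x]
                exons = tuple((start + o, start + o + s) for o, s in zip(offs, sizes))
            tss, pas = (start, end) if strand == "+" else (end, start)
            tus.append(TranscriptionUnit(name, chrom, strand, tss, pas, exons))
    return tus


def write_window_table(path, vectors: list[WindowVector]) -> None:
    rows = []
    for wv in vectors:
        for i in range(len(wv)):
            rows.append((wv.gene, wv.kind, i + 1, wv.counts[i], bool(wv.missing[i])))
    pd.DataFrame(rows, columns=["gene", "kind", "index", "count", "missing"]).to_csv(
        path, sep="\t", index=False
    )


def read_window_table(path) -> dict[str, WindowVector]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, WindowVector] = {}
    for gene, sub in df.groupby("gene", sort=False):
        sub = sub.sort_values("index")
        kind = sub["kind"].iloc[0]
        width = BODY_WINDOW_NT if kind == "body_1kb" else PAS_WINDOW_NT
        out[str(gene)] = WindowVector(
            str(gene), kind, width, sub["count"].to_numpy(), sub["missing"].to_numpy(bool)
        )
    return out
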
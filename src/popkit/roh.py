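"""Runs of homozygosity: sliding-window detection, summaries and F_ROH.

The caller follows the classic array-based windowing scheme: a fixed-size SNP
window slides one marker at a time; a window "qualifies" when it contains at
most a set number of heterozygous and missing calls; a marker is ROH-eligible
when the fraction of windows overlapping it that qualify exceeds a threshold;
maximal runs of eligible markers, split at large inter-marker gaps, become
segments if they are long enough, dense enough and themselves respect the
het/missing caps.

F_ROH is the genomic inbreeding coefficient: summed ROH length divided by the
total autosome length L_auto.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

#: length-class partition for reporting, in Mb: [1,5), [5,10), [10,15),
#: [15,20), >=20
LENGTH_CLASS_EDGES_MB = (1.0, 5.0, 10.0, 15.0, 20.0)
LENGTH_CLASS_LABELS = ("1-5", "5-10", "10-15", "15-20", ">20")


@dataclass
class ROHParams:
    """Six-criterion configuration (defaults are the usual 50K-array values)."""

    window_snps: int = 50
    window_threshold: float = 0.05
    min_snps: int = 100
    max_density_kb_per_snp: float = 50.0
    max_gap_kb: float = 100.0
    max_missing_in_run: int = 2
    max_het_in_run: int = 1
    min_length_kb: float = 1000.0

    def __post_init__(self) -> None:
        if min(self.window_snps, self.min_snps) <= 0:
            raise ValueError("window_snps and min_snps must be positive")
        if self.min_snps < self.window_snps:
            raise ValueError("min_snps must be >= window_snps")
        if min(self.max_density_kb_per_snp, self.max_gap_kb,
               self.min_length_kb) <= 0:
            raise ValueError("length thresholds must be positive")
        if min(self.max_missing_in_run, self.max_het_in_run) < 0:
            raise ValueError("het/missing caps must be >= 0")


@dataclass
class ROHSegment:
    individual: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp) / 1e3

    @property
    def length_mb(self) -> float:
        return (self.end_bp - self.start_bp) / 1e6


def _eligible_markers(het: np.ndarray, miss: np.ndarray,
                      params: ROHParams) -> np.ndarray:
    """Per-marker ROH eligibility from qualifying-window fractions."""
    m = len(het)
    w = params.window_snps
    if m < w:
        return np.zeros(m, dtype=bool)
    het_c = np.concatenate([[0], np.cumsum(het)])
    mis_c = np.concatenate([[0], np.cumsum(miss)])
    # window starting at s covers markers [s, s+w)
    n_win = m - w + 1
    starts = np.arange(n_win)
    win_ok = ((het_c[starts + w] - het_c[starts] <= params.max_het_in_run)
              & (mis_c[starts + w] - mis_c[starts] <= params.max_missing_in_run))
    ok_c = np.concatenate([[0], np.cumsum(win_ok)])
    idx = np.arange(m)
    lo = np.maximum(idx - w + 1, 0)          # first window covering marker
    hi = np.minimum(idx, n_win - 1)          # last window covering marker
    n_cover = hi - lo + 1
    n_ok = ok_c[hi + 1] - ok_c[lo]
    return n_ok / n_cover > params.window_threshold


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) half-open index pairs."""
    out = []
    i = 0
    m = len(mask)
    while i < m:
        if mask[i]:
            j = i
            while j < m and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def detect_roh(gm: GenotypeMatrix,
               params: ROHParams | None = None) -> list[ROHSegment]:
    """Call ROH segments per individual per chromosome.

    Markers must be position-sorted within chromosome; chromosomes with fewer
    markers than the window are skipped with a warning.
    """
    params = params or ROHParams()
    segments: list[ROHSegment] = []
    warned: set[str] = set()
    for chrom, idx in gm.iter_chromosomes():
        pos = gm.positions[idx].astype(np.int64)
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"markers on chromosome {chrom} are not sorted")
        if len(idx) < params.window_snps:
            if chrom not in warned:
                warnings.warn(f"chromosome {chrom}: fewer markers than the "
                              "window; skipped")
                warned.add(chrom)
            continue
        gap_kb = np.diff(pos) / 1e3
        big_gap = gap_kb > params.max_gap_kb       # between idx k and k+1
        for s_i, sample in enumerate(gm.samples):
            g = gm.calls[s_i, idx]
            het = g == 1
            miss = g == MISSING
            eligible = _eligible_markers(het, miss, params)
            for lo, hi in _runs(eligible):
                # split candidate runs at large gaps before filtering
                cut = lo
                for k in range(lo, hi - 1):
                    if big_gap[k]:
                        segments.extend(_filter_candidate(
                            sample, chrom, pos, het, miss, cut, k + 1, params))
                        cut = k + 1
                segments.extend(_filter_candidate(
                    sample, chrom, pos, het, miss, cut, hi, params))
    return segments


def _filter_candidate(sample: str, chrom: str, pos: np.ndarray,
                      het: np.ndarray, miss: np.ndarray,
                      lo: int, hi: int, params: ROHParams) -> list[ROHSegment]:
    # a segment starts and ends on a called homozygous marker: eligibility can
    # spill over onto flanking het/missing calls, which are trimmed here so
    # that the per-segment caps judge the run's interior only
    while lo < hi and (het[lo] or miss[lo]):
        lo += 1
    while hi > lo and (het[hi - 1] or miss[hi - 1]):
        hi -= 1
    n_snps = hi - lo
    if n_snps < params.min_snps:
        return []
    span_kb = (pos[hi - 1] - pos[lo]) / 1e3
    if span_kb < params.min_length_kb:
        return []
    if span_kb / n_snps > params.max_density_kb_per_snp:
        return []
    n_het = int(het[lo:hi].sum())
    n_miss = int(miss[lo:hi].sum())
    if n_het > params.max_het_in_run or n_miss > params.max_missing_in_run:
        return []
    return [ROHSegment(sample, chrom, int(pos[lo]), int(pos[hi - 1]),
                       n_snps, n_het, n_miss)]


def segments_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.individual, s.chromosome, s.start_bp, s.end_bp, s.n_snps,
          s.length_kb, s.n_het, s.n_missing) for s in segments],
        columns=["individual", "chromosome", "start_bp", "end_bp", "n_snps",
                 "length_kb", "n_het", "n_missing"],
    )


# ---------------------------------------------------------------------------
# Summaries and F_ROH
# ---------------------------------------------------------------------------

def bin_percentages(counts: "list[int] | tuple[int, ...]") -> tuple[list[float], int]:
    """Length-class counts -> (percentages to 2 decimals, total)."""
    total = int(sum(counts))
    if total == 0:
        return [0.0] * len(counts), 0
    return [round(100.0 * c / total, 2) for c in counts], total


def length_class_counts(segments: list[ROHSegment]) -> list[int]:
    edges = LENGTH_CLASS_EDGES_MB
    counts = [0] * len(edges)
    for s in segments:
        mb = s.length_mb
        if mb < edges[0]:
            continue
        for k in range(len(edges) - 1, -1, -1):
            if mb >= edges[k]:
                counts[k] += 1
                break
    return counts


def f_roh(segments: list[ROHSegment], l_auto_bp: float,
          individuals: list[str]) -> pd.Series:
    """Per-individual F_ROH = sum of ROH lengths / total autosome length."""
    if l_auto_bp <= 0:
        raise ValueError("L_auto must be positive")
    total = {ind: 0.0 for ind in individuals}
    for s in segments:
        total[s.individual] = total.get(s.individual, 0.0) + (s.end_bp - s.start_bp)
    return pd.Series({ind: total[ind] / l_auto_bp for ind in individuals},
                     name="f_roh")


def _union_length(intervals: list[tuple[int, int]]) -> int:
    ivs = sorted(intervals)
    covered, cur_s, cur_e = 0, None, None
    for s, e in ivs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered


@dataclass
class ROHSummary:
    per_individual: pd.DataFrame      # count, total length, f_roh
    per_chromosome: pd.DataFrame      # count, coverage fraction
    length_classes: pd.DataFrame      # label, count, percent
    f_roh_mean: float
    l_auto_bp: float
    n_segments: int


def summarize_roh(
    segments: list[ROHSegment],
    gm: GenotypeMatrix | None = None,
    chrom_lengths: dict[str, int] | None = None,
    individuals: list[str] | None = None,
) -> ROHSummary:
    """Per-individual / per-chromosome accounting plus length classes.

    Chromosome lengths default to the observed span (first to last marker) of
    the supplied matrix; an explicit table overrides.  Coverage per chromosome
    is the union of segments over all individuals divided by its length.
    """
    if chrom_lengths is None:
        if gm is None:
            raise ValueError("need a GenotypeMatrix or explicit chrom_lengths")
        chrom_lengths = {}
        for chrom, idx in gm.iter_chromosomes():
            pos = gm.positions[idx]
            chrom_lengths[chrom] = int(pos.max() - pos.min())
    for s in segments:
        if s.chromosome not in chrom_lengths:
            raise ValueError(f"segment on unknown chromosome {s.chromosome!r}")
    l_auto = float(sum(chrom_lengths.values()))
    if individuals is None:
        individuals = (gm.samples if gm is not None
                       else sorted({s.individual for s in segments}))

    fr = f_roh(segments, l_auto, individuals)
    per_ind = pd.DataFrame({
        "n_roh": pd.Series({i: 0 for i in individuals}, dtype=int),
        "total_length_mb": pd.Series({i: 0.0 for i in individuals}),
    })
    for s in segments:
        per_ind.loc[s.individual, "n_roh"] += 1
        per_ind.loc[s.individual, "total_length_mb"] += s.length_mb
    per_ind["f_roh"] = fr

    rows = []
    for chrom, length in chrom_lengths.items():
        segs = [(s.start_bp, s.end_bp) for s in segments if s.chromosome == chrom]
        rows.append({
            "chromosome": chrom,
            "n_roh": len(segs),
            "coverage": _union_length(segs) / length if length else 0.0,
        })
    per_chrom = pd.DataFrame(rows)

    counts = length_class_counts(segments)
    pct, total = bin_percentages(counts)
    classes = pd.DataFrame({
        "length_mb": LENGTH_CLASS_LABELS, "count": counts, "percent": pct})

    return ROHSummary(
        per_individual=per_ind,
        per_chromosome=per_chrom,
        length_classes=classes,
        f_roh_mean=float(fr.mean()),
        l_auto_bp=l_auto,
        n_segments=len(segments),
    )
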
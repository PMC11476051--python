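"""Selective-sweep scans: ROH islands, windowed pi, windowed Tajima's D.

Three complementary signals of positive selection:

* **ROH islands** — regions where an unusually high share of individuals carry
  runs of homozygosity (top percentile of per-SNP ROH incidence, adjacent
  markers merged).
* **Windowed nucleotide diversity (pi)** — depressed average pairwise
  difference per bp in sliding windows (100 kb window, 10 kb step).
* **Windowed Tajima's D** — negative D (pi deficit relative to the
  segregating-sites expectation) in the same windows.

Candidate regions from each method are annotated against a user-supplied
BED/GFF3 gene set and intersected (Venn counts).  Unphased diploid genotypes
contribute allele counts only; no phasing is required for any statistic here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix
from .roh import ROHSegment


# ---------------------------------------------------------------------------
# ROH islands
# ---------------------------------------------------------------------------

def snp_roh_incidence(segments: list[ROHSegment],
                      gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker count/fraction of individuals whose ROH covers it."""
    count = np.zeros(gm.n_markers, dtype=np.int64)
    chrom = gm.chromosomes
    pos = gm.positions
    by_chrom: dict[str, np.ndarray] = {
        c: idx for c, idx in gm.iter_chromosomes()}
    for s in segments:
        idx = by_chrom.get(s.chromosome)
        if idx is None:
            continue
        p = pos[idx]
        lo = np.searchsorted(p, s.start_bp, side="left")
        hi = np.searchsorted(p, s.end_bp, side="right")
        count[idx[lo:hi]] += 1
    n = gm.n_samples
    return pd.DataFrame({
        "marker_id": gm.markers["marker_id"],
        "chromosome": chrom,
        "position_bp": pos,
        "count": count,
        "fraction": count / n,
    })


def roh_islands(segments: list[ROHSegment], gm: GenotypeMatrix,
                top_fraction: float = 0.01) -> pd.DataFrame:
    """Merge the top-percentile ROH-incidence markers into islands.

    Threshold = the (1 - top_fraction) quantile of per-marker incidence;
    markers at or above it (and > 0) are selected, and adjacent selected
    markers on a chromosome with no unselected marker between them merge into
    one island spanning first to last marker position.
    """
    inc = snp_roh_incidence(segments, gm)
    frac = inc["fraction"].to_numpy()
    if frac.max() == 0:
        warnings.warn("no marker is covered by any ROH; no islands")
        return pd.DataFrame(
            columns=["chromosome", "start_bp", "end_bp", "n_snps", "score"])
    threshold = np.quantile(frac, 1 - top_fraction)
    selected = (frac >= threshold) & (frac > 0)
    rows = []
    chrom = inc["chromosome"].to_numpy()
    pos = inc["position_bp"].to_numpy()
    i = 0
    m = len(inc)
    while i < m:
        if selected[i]:
            j = i
            while j + 1 < m and selected[j + 1] and chrom[j + 1] == chrom[i]:
                j += 1
            rows.append({
                "chromosome": chrom[i],
                "start_bp": int(pos[i]),
                "end_bp": int(pos[j]),
                "n_snps": j - i + 1,
                "score": float(frac[i:j + 1].mean()),
            })
            i = j + 1
        else:
            i += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Windowed pi and Tajima's D
# ---------------------------------------------------------------------------

def _window_starts(span_end: int, window_bp: int, step_bp: int) -> np.ndarray:
    """Window start positions (1-based), tiled from 1, last partial kept."""
    if span_end < 1:
        return np.array([], dtype=np.int64)
    return np.arange(1, span_end + 1, step_bp, dtype=np.int64)


def _per_site_pi(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per site: heterozygosity-style pi, allele count c, segregating flag.

    pi_site = 2 * c_ref * c_alt / (c * (c - 1)) with c = 2 x non-missing
    individuals — the fraction of differing pairs among the c sampled alleles.
    """
    calls = gm.calls
    obs = calls >= 0
    c = 2 * obs.sum(axis=0)
    alt = np.where(obs, calls, 0).sum(axis=0)
    ref = c - alt
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(c > 1, 2.0 * ref * alt / (c * (c - 1.0)), 0.0)
    seg = (alt > 0) & (ref > 0)
    return pi, c, seg


def _chrom_spans(gm: GenotypeMatrix,
                 chrom_lengths: dict[str, int] | None) -> dict[str, int]:
    spans = {}
    for chrom, idx in gm.iter_chromosomes():
        spans[chrom] = int(gm.positions[idx].max())
    if chrom_lengths:
        spans.update(chrom_lengths)
    return spans


def windowed_pi(gm: GenotypeMatrix, window_bp: int = 100_000,
                step_bp: int = 10_000,
                chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Nucleotide diversity per bp in sliding windows.

    Window value = sum of per-site pi over variants in the window divided by
    the window's bp extent (truncated at the chromosome end and
    length-normalized accordingly).
    """
    pi_site, _, _ = _per_site_pi(gm)
    return _windowed(gm, pi_site, None, window_bp, step_bp, chrom_lengths,
                     statistic="pi")


def tajima_constants(n_hap: int) -> dict[str, float]:
    """Tajima's (1989) normalization constants for n sampled haplotypes."""
    if n_hap < 2:
        raise ValueError("need at least 2 haplotypes")
    i = np.arange(1, n_hap)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n_hap + 1) / (3.0 * (n_hap - 1))
    b2 = 2.0 * (n_hap ** 2 + n_hap + 3) / (9.0 * n_hap * (n_hap - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n_hap + 2) / (a1 * n_hap) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajima_d_from_window(pi_sum: float, s: int, n_hap: int) -> float:
    """D = (pi_sum - S/a1) / sqrt(e1 S + e2 S (S-1)); NaN when undefined."""
    if s == 0 or n_hap < 4:
        return float("nan")
    k = tajima_constants(n_hap)
    var = k["e1"] * s + k["e2"] * s * (s - 1)
    if var <= 0:
        return float("nan")
    return (pi_sum - s / k["a1"]) / np.sqrt(var)


def windowed_tajima_d(gm: GenotypeMatrix, window_bp: int = 100_000,
                      step_bp: int = 10_000,
                      chrom_lengths: dict[str, int] | None = None
                      ) -> pd.DataFrame:
    """Tajima's D in sliding windows.

    The haplotype count per window is the modal per-site allele count c
    among its variant sites (windows mixing counts due to missingness are
    flagged in ``c_varies``); D is NaN where S = 0.
    """
    pi_site, c_site, seg = _per_site_pi(gm)
    return _windowed(gm, pi_site, (c_site, seg), window_bp, step_bp,
                     chrom_lengths, statistic="tajima_d")


def _windowed(gm: GenotypeMatrix, pi_site: np.ndarray,
              taj: tuple[np.ndarray, np.ndarray] | None,
              window_bp: int, step_bp: int,
              chrom_lengths: dict[str, int] | None,
              statistic: str) -> pd.DataFrame:
    spans = _chrom_spans(gm, chrom_lengths)
    rows = []
    for chrom, idx in gm.iter_chromosomes():
        pos = gm.positions[idx].astype(np.int64)
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        site_pi = pi_site[idx][order]
        if taj is not None:
            c_site = taj[0][idx][order]
            seg = taj[1][idx][order]
        span = spans[chrom]
        for start in _window_starts(span, window_bp, step_bp):
            end = min(start + window_bp - 1, span)
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="right")
            n_var = hi - lo
            if statistic == "pi":
                # monomorphic-but-covered windows are genuinely 0; windows
                # with no markers at all carry no information -> NaN
                value = (site_pi[lo:hi].sum() / (end - start + 1)
                         if n_var > 0 else np.nan)
                rows.append((chrom, int(start), int(end), int(n_var), value,
                             np.nan, False))
            else:
                in_win = np.arange(lo, hi)
                seg_w = in_win[seg[lo:hi]]
                s = len(seg_w)
                if s == 0:
                    rows.append((chrom, int(start), int(end), int(n_var),
                                 np.nan, 0, False))
                    continue
                counts = c_site[seg_w]
                vals, freq = np.unique(counts, return_counts=True)
                n_hap = int(vals[np.argmax(freq)])
                pi_sum = float(site_pi[seg_w].sum())
                d = tajima_d_from_window(pi_sum, s, n_hap)
                rows.append((chrom, int(start), int(end), int(n_var), d, s,
                             bool(len(vals) > 1)))
    cols = ["chromosome", "start_bp", "end_bp", "n_variants", "value", "S",
            "c_varies"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Region selection and annotation
# ---------------------------------------------------------------------------

def select_regions(window_stats: pd.DataFrame, quantile: float = 0.01,
                   step_bp: int = 10_000) -> pd.DataFrame:
    """Merge the lowest-quantile windows into candidate regions.

    A window is selected when its value sits at or below the ``quantile``
    quantile of all defined windows.  Windows tied exactly at the discrete
    lower tail (common for pi when many windows hold a single minimal-MAF
    variant) are all taken; a degenerate all-equal scan selects nothing.
    Overlapping or book-ended (gap <= step) selected windows merge.
    """
    if not 0 < quantile <= 0.5:
        raise ValueError("quantile must be in (0, 0.5]")
    ok = window_stats.dropna(subset=["value"])
    if ok.empty:
        return pd.DataFrame(columns=["chromosome", "start_bp", "end_bp",
                                     "n_windows", "score"])
    values = ok["value"].to_numpy()
    threshold = np.quantile(values, quantile)
    sel = ok[(ok["value"] <= threshold)
             & (ok["value"] < values.max())].sort_values(
        ["chromosome", "start_bp"], kind="stable")
    rows = []
    cur = None
    for w in sel.itertuples(index=False):
        if (cur is not None and w.chromosome == cur["chromosome"]
                and w.start_bp <= cur["end_bp"] + step_bp + 1):
            cur["end_bp"] = max(cur["end_bp"], w.end_bp)
            cur["n_windows"] += 1
            cur["score"] = min(cur["score"], w.value)
        else:
            if cur is not None:
                rows.append(cur)
            cur = {"chromosome": w.chromosome, "start_bp": w.start_bp,
                   "end_bp": w.end_bp, "n_windows": 1, "score": w.value}
    if cur is not None:
        rows.append(cur)
    return pd.DataFrame(rows)


def read_gene_intervals(path: str, attribute: str = "gene_id") -> pd.DataFrame:
    """Gene intervals from BED or GFF3 into (chromosome, start_bp, end_bp,
    gene): BED name column or GFF3 'gene' features' attribute key.

    Returned coordinates are 1-based closed (converted from BED half-open).
    """
    import pyranges as pr

    p = str(path)
    if p.endswith((".gff", ".gff3", ".gtf")):
        gr = pr.read_gff3(p).df if p.endswith((".gff", ".gff3")) else pr.read_gtf(p).df
        genes = gr[gr["Feature"] == "gene"].copy()
        if attribute not in genes.columns:
            for alt in ("gene_id", "ID", "Name", "gene_name"):
                if alt in genes.columns:
                    attribute = alt
                    break
            else:
                raise ValueError(f"no usable gene attribute in {path}")
        name = genes[attribute]
        # pyranges GFF coordinates are already converted to 0-based Start
        out = pd.DataFrame({
            "chromosome": genes["Chromosome"].astype(str),
            "start_bp": genes["Start"].astype(int) + 1,
            "end_bp": genes["End"].astype(int),
            "gene": name.astype(str),
        })
    else:
        bed = pr.read_bed(p).df
        if "Name" not in bed.columns:
            raise ValueError(f"{path}: BED gene file needs a name column")
        out = pd.DataFrame({
            "chromosome": bed["Chromosome"].astype(str),
            "start_bp": bed["Start"].astype(int) + 1,
            "end_bp": bed["End"].astype(int),
            "gene": bed["Name"].astype(str),
        })
    return out.reset_index(drop=True)


def genes_in_regions(regions: pd.DataFrame, genes: pd.DataFrame) -> set[str]:
    """Gene ids overlapping any region by >= 1 bp (half-open arithmetic)."""
    import pyranges as pr

    if regions.empty or genes.empty:
        return set()
    region_chroms = set(regions["chromosome"].astype(str))
    gene_chroms = set(genes["chromosome"].astype(str))
    if not region_chroms & gene_chroms:
        raise ValueError(
            "annotation chromosomes do not match the genotype naming scheme "
            f"(regions use {sorted(region_chroms)[:5]}, annotation uses "
            f"{sorted(gene_chroms)[:5]}); remap one of them")
    r = pr.PyRanges(pd.DataFrame({
        "Chromosome": regions["chromosome"].astype(str),
        "Start": regions["start_bp"].astype(int) - 1,
        "End": regions["end_bp"].astype(int),
    }))
    g = pr.PyRanges(pd.DataFrame({
        "Chromosome": genes["chromosome"].astype(str),
        "Start": genes["start_bp"].astype(int) - 1,
        "End": genes["end_bp"].astype(int),
        "Name": genes["gene"].astype(str),
    }))
    hits = r.join(g)
    if hits.df.empty:
        return set()
    return set(hits.df["Name"].astype(str))


@dataclass
class SweepIntersection:
    gene_sets: dict[str, set[str]]            # method -> genes
    venn: dict[str, int]                      # region combination -> count

    @property
    def three_way(self) -> set[str]:
        sets = list(self.gene_sets.values())
        return set.intersection(*sets) if sets else set()


def annotate_and_intersect(regions_by_method: dict[str, pd.DataFrame],
                           genes: pd.DataFrame) -> SweepIntersection:
    """Per-method gene sets plus Venn counts over all method combinations."""
    gene_sets = {m: genes_in_regions(r, genes)
                 for m, r in regions_by_method.items()}
    methods = list(gene_sets)
    venn: dict[str, int] = {}
    for mask in range(1, 2 ** len(methods)):
        inside = [methods[i] for i in range(len(methods)) if mask >> i & 1]
        outside = [m for m in methods if m not in inside]
        s = set.intersection(*(gene_sets[m] for m in inside))
        for m in outside:
            s = s - gene_sets[m]
        venn["&".join(inside)] = len(s)
    return SweepIntersection(gene_sets, venn)
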
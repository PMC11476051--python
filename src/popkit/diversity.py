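"""Per-locus and population genetic-diversity indicators.

Seven indicators: observed/expected heterozygosity (Ho, He), polymorphism
information content (PIC), effective number of alleles (Ae), minor allele
frequency (MAF), polymorphic-marker ratio (P_N), and LD-based effective
population size (Ne).

Per locus k with alt-allele frequency p over n genotyped individuals:

  Ho  = H_k / n                       (share of heterozygous individuals)
  He  = 2n/(2n-1) * (1 - p^2 - q^2)   (sample-size-corrected)
  PIC = 1 - p^2 - q^2 - 2 p^2 q^2     (Botstein)
  Ae  = 1 / (p^2 + q^2)               (or 1/(1-Ho) with ae_mode="observed")
  MAF = min(p, q)

Ne uses the point formula Ne = (1/4c) * (1/r^2 - 1) with r^2 the squared
genotype correlation between same-chromosome marker pairs and c the genetic
distance in Morgans, evaluated per distance bin after a 1/(2n) sampling
correction on r^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix

#: distribution report bins (right-open)
PIC_BIN_EDGES = (0.0, 0.15, 0.30, 0.45)
MAF_BIN_EDGES = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)


def per_locus_stats(gm: GenotypeMatrix, ae_mode: str = "expected") -> pd.DataFrame:
    """Per-marker table: p_alt, maf, ho, he, pic, ae, n_called.

    All-missing loci get NaN stats and are flagged in the ``defined`` column.
    """
    if ae_mode not in ("expected", "observed"):
        raise ValueError("ae_mode must be 'expected' or 'observed'")
    calls = gm.calls
    obs = calls >= 0
    n = obs.sum(axis=0).astype(float)
    het = ((calls == 1) & obs).sum(axis=0)
    alt = np.where(obs, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2 * n), np.nan)
        q = 1.0 - p
        ho = np.where(n > 0, het / n, np.nan)
        hom_exp = p ** 2 + q ** 2
        he = np.where(n > 0, (2 * n) / (2 * n - 1) * (1 - hom_exp), np.nan)
        pic = 1 - hom_exp - 2 * p ** 2 * q ** 2
        if ae_mode == "expected":
            ae = 1.0 / hom_exp
        else:
            ae = np.where(ho < 1, 1.0 / (1.0 - ho), np.inf)
    out = pd.DataFrame({
        "marker_id": gm.markers["marker_id"],
        "chromosome": gm.markers["chromosome"],
        "position_bp": gm.markers["position_bp"],
        "p_alt": p,
        "maf": np.fmin(p, q),
        "ho": ho,
        "he": he,
        "pic": pic,
        "ae": ae,
        "n_called": n.astype(int),
        "defined": n > 0,
    })
    return out


def polymorphic_marker_ratio(locus_stats: pd.DataFrame,
                             maf_threshold: float = 0.01) -> float:
    """P_N = M/N: share of loci whose MAF exceeds the polymorphism cutoff."""
    maf = locus_stats.loc[locus_stats["defined"], "maf"]
    if len(maf) == 0:
        raise ValueError("no defined loci")
    return float((maf > maf_threshold).mean())


@dataclass
class DiversitySummary:
    mean_ne: float
    mean_pn: float
    mean_he: float
    mean_ho: float
    mean_pic: float
    mean_ae: float
    mean_maf: float
    pic_bins: dict[str, float]
    maf_bins: dict[str, float]

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("mean_ne", "mean_pn", "mean_he", "mean_ho", "mean_pic",
              "mean_ae", "mean_maf")}
        d["pic_bins"] = self.pic_bins
        d["maf_bins"] = self.maf_bins
        return d


def _bin_proportions(values: np.ndarray, edges: tuple[float, ...],
                     last_closed: float) -> dict[str, float]:
    """Right-open bins from edges, last bin closing at ``last_closed``."""
    values = values[~np.isnan(values)]
    out = {}
    bounds = list(edges) + [last_closed]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi == last_closed:
            mask = (values >= lo) & (values <= hi)
        else:
            mask = (values >= lo) & (values < hi)
        out[f"[{lo:g},{hi:g})" if hi != last_closed else f"[{lo:g},{hi:g}]"] = (
            float(mask.mean()) if len(values) else 0.0
        )
    return out


def summarize_diversity(locus_stats: pd.DataFrame,
                        ne: float = float("nan"),
                        maf_threshold: float = 0.01) -> DiversitySummary:
    ok = locus_stats[locus_stats["defined"]]
    return DiversitySummary(
        mean_ne=ne,
        mean_pn=polymorphic_marker_ratio(locus_stats, maf_threshold),
        mean_he=float(ok["he"].mean()),
        mean_ho=float(ok["ho"].mean()),
        mean_pic=float(ok["pic"].mean()),
        mean_ae=float(ok["ae"].mean()),
        mean_maf=float(ok["maf"].mean()),
        pic_bins=_bin_proportions(ok["pic"].to_numpy(), PIC_BIN_EDGES, 0.45),
        maf_bins=_bin_proportions(ok["maf"].to_numpy(), MAF_BIN_EDGES[:-1], 0.5),
    )


# ---------------------------------------------------------------------------
# Ne from LD
# ---------------------------------------------------------------------------

def ne_point_estimate(r2: float, c_morgan: float) -> float:
    """Ne = (1/4c) * (1/r^2 - 1) for one (r^2, c) pair, c in Morgans."""
    if not 0 < r2 <= 1:
        raise ValueError("r2 must be in (0, 1]")
    if c_morgan <= 0:
        raise ValueError("genetic distance must be positive")
    return (1.0 / (4.0 * c_morgan)) * (1.0 / r2 - 1.0)


def _pairwise_r2_binned(gm: GenotypeMatrix, edges_cM: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Sum of r^2 and pair count per cM-distance bin, same-chromosome pairs.

    Missing calls are mean-imputed per marker before correlation.
    """
    sums = np.zeros(len(edges_cM) - 1)
    counts = np.zeros(len(edges_cM) - 1, dtype=np.int64)
    max_cm = edges_cM[-1]
    for _, idx in gm.iter_chromosomes():
        x = gm.calls[:, idx].astype(float)
        miss = x < 0
        if miss.any():
            col_mean = np.where(
                miss, 0, x).sum(axis=0) / np.maximum((~miss).sum(axis=0), 1)
            x[miss] = np.broadcast_to(col_mean, x.shape)[miss]
        sd = x.std(axis=0)
        keep = sd > 0
        x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
        cm = gm.markers["genetic_pos_cM"].to_numpy()[idx][keep]
        n, m = x.shape
        if m < 2:
            continue
        for lag in range(1, m):
            d = cm[lag:] - cm[:-lag]
            within = d <= max_cm
            if not within.any():
                break
            r = (x[:, lag:] * x[:, :-lag]).mean(axis=0)   # corr of z-scores
            r2 = r[within] ** 2
            which = np.searchsorted(edges_cM, d[within], side="right") - 1
            ok = (which >= 0) & (which < len(sums))
            np.add.at(sums, which[ok], r2[ok])
            np.add.at(counts, which[ok], 1)
    return sums, counts


def effective_population_size(
    gm: GenotypeMatrix,
    bin_edges_cM: np.ndarray | None = None,
    sample_size_correction: bool = True,
    r2_floor: float = 1e-6,
) -> tuple[pd.DataFrame, float]:
    """LD-based Ne per genetic-distance bin plus their mean.

    r^2 per same-chromosome pair is the squared correlation of genotype
    dosages; pairs are grouped into cM bins, the bin mean r^2 is corrected by
    -1/(2n) for finite sample size (floored at ``r2_floor``), and the point
    formula is evaluated at the bin midpoint (converted to Morgans).
    """
    if bin_edges_cM is None:
        bin_edges_cM = np.arange(0.25, 5.25, 0.25)
    edges = np.asarray(bin_edges_cM, dtype=float)
    sums, counts = _pairwise_r2_binned(gm, edges)
    mids = (edges[:-1] + edges[1:]) / 2
    rows = []
    for k in range(len(mids)):
        if counts[k] == 0:
            warnings.warn(f"no marker pairs in bin {edges[k]:g}-{edges[k+1]:g} cM")
            continue
        r2 = sums[k] / counts[k]
        if sample_size_correction:
            r2 = r2 - 1.0 / (2 * gm.n_samples)
        r2 = max(r2, r2_floor)
        rows.append({
            "bin_lo_cM": edges[k], "bin_hi_cM": edges[k + 1],
            "mid_cM": mids[k], "n_pairs": int(counts[k]),
            "mean_r2": r2, "ne": ne_point_estimate(min(r2, 1.0), mids[k] / 100),
        })
    per_bin = pd.DataFrame(rows)
    summary = float(per_bin["ne"].mean()) if len(per_bin) else float("nan")
    return per_bin, summary
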
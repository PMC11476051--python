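"""Sweep scans: pi/Tajima's D oracles, island merging, region selection,
annotation overlap and set intersection."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from popkit.roh import ROHSegment
from popkit.sweep import (
    annotate_and_intersect,
    genes_in_regions,
    read_gene_intervals,
    roh_islands,
    select_regions,
    snp_roh_incidence,
    tajima_d_from_window,
    windowed_pi,
    windowed_tajima_d,
)

from conftest import make_matrix


# ---------------------------------------------------------------------------
# pi
# ---------------------------------------------------------------------------

def pi_brute_force(calls_column):
    """All-pairs allele-difference count over the sampled allele lists."""
    alleles = []
    for g in calls_column:
        if g < 0:
            continue
        alleles += {0: [0, 0], 1: [0, 1], 2: [1, 1]}[g]
    if len(alleles) < 2:
        return 0.0
    pairs = list(itertools.combinations(alleles, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


def test_pi_single_site_half_and_half():
    # 5 ref / 5 alt alleles of 10: pi = 25/45
    calls = np.array([[0], [0], [1], [2], [2]])
    gm = make_matrix(calls, positions=[50_000])
    win = windowed_pi(gm, window_bp=100_000, step_bp=100_000,
                      chrom_lengths={"1": 100_000})
    assert win["value"].iloc[0] == pytest.approx((25 / 45) / 100_000)


def test_monomorphic_window_zero():
    gm = make_matrix(np.zeros((4, 3)), positions=[10_000, 20_000, 30_000])
    win = windowed_pi(gm, window_bp=100_000, step_bp=100_000)
    assert win["value"].iloc[0] == 0.0


def test_pi_matches_brute_force(rng):
    calls = rng.integers(-1, 3, size=(10, 50)).astype(np.int8)
    pos = np.sort(rng.choice(np.arange(1_000, 99_000), 50, replace=False))
    gm = make_matrix(calls, positions=pos)
    win = windowed_pi(gm, window_bp=100_000, step_bp=100_000,
                      chrom_lengths={"1": 100_000})
    expected = sum(pi_brute_force(calls[:, k]) for k in range(50)) / 100_000
    assert win["value"].iloc[0] == pytest.approx(expected, abs=1e-12)


def test_pi_duplicated_individuals_finite_sample_factor():
    rng = np.random.default_rng(4)
    calls = rng.integers(0, 3, size=(6, 20)).astype(np.int8)
    doubled = np.vstack([calls, calls])
    pos = np.arange(5_000, 105_000, 5_000)
    a = windowed_pi(make_matrix(calls, positions=pos), 100_000, 100_000)
    b = windowed_pi(make_matrix(doubled, positions=pos), 100_000, 100_000)
    # per site: pi scales by (c/(c-1)) / (2c/(2c-1)); with constant c = 12
    # vs 24 the window ratio is the same closed-form constant
    factor = (12 / 11) / (24 / 23)
    assert b["value"].iloc[0] * factor == pytest.approx(a["value"].iloc[0],
                                                        rel=1e-12)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_d_literal(pi_sum, s, n):
    """Independent constant-by-constant transcription of Tajima (1989)."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return (pi_sum - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def test_tajima_no_segregating_sites_undefined():
    gm = make_matrix(np.zeros((4, 5)),
                     positions=[10_000, 20_000, 30_000, 40_000, 50_000])
    win = windowed_tajima_d(gm, 100_000, 100_000)
    assert np.isnan(win["value"].iloc[0])
    assert win["S"].iloc[0] == 0


def test_tajima_four_haplotype_hand_fixture():
    # 2 diploids = 4 haplotypes; 3 segregating columns with alt counts 1, 2, 2
    calls = np.array([[1, 2, 0], [0, 0, 2]])
    gm = make_matrix(calls, positions=[10_000, 20_000, 30_000])
    pi_sum = sum(pi_brute_force(calls[:, k]) for k in range(3))
    expected = tajima_d_literal(pi_sum, 3, 4)
    win = windowed_tajima_d(gm, 100_000, 100_000)
    assert win["value"].iloc[0] == pytest.approx(expected, abs=1e-9)
    assert win["S"].iloc[0] == 3


def test_tajima_matches_literal_on_random_fixtures(rng):
    for _ in range(10):
        calls = rng.integers(0, 3, size=(8, 30)).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1_000, 99_000), 30, replace=False))
        gm = make_matrix(calls, positions=pos)
        win = windowed_tajima_d(gm, 100_000, 100_000)
        seg = [k for k in range(30) if 0 < calls[:, k].sum() < 16]
        pi_sum = sum(pi_brute_force(calls[:, k]) for k in seg)
        if not seg:
            assert np.isnan(win["value"].iloc[0])
            continue
        expected = tajima_d_literal(pi_sum, len(seg), 16)
        assert win["value"].iloc[0] == pytest.approx(expected, abs=1e-9)


def test_tajima_neutral_mean_near_zero():
    # neutral-spectrum founders: mean D over many windows should sit near 0
    from popkit.simulate import SimulationConfig, simulate_founders

    cfg = SimulationConfig(n_individuals=50, n_chromosomes=5,
                           chrom_length_bp=50_000_000,
                           marker_spacing_bp=5_000,
                           maf_distribution="neutral", seed=10)
    gm, _, _ = simulate_founders(cfg)
    win = windowed_tajima_d(gm, 100_000, 10_000)
    d = win["value"].to_numpy()
    d = d[~np.isnan(d)]
    assert len(d) > 10_000
    assert abs(d.mean()) <= 0.15


# ---------------------------------------------------------------------------
# ROH islands
# ---------------------------------------------------------------------------

def _island_matrix():
    pos = np.arange(10_000, 10_000 * 101, 10_000)
    return make_matrix(np.zeros((10, 100), dtype=np.int8), positions=pos)


def _segments_covering(gm, marker_ranges, n_individuals):
    pos = gm.positions
    segs = []
    for lo, hi in marker_ranges:
        for i in range(n_individuals):
            segs.append(ROHSegment(f"s{i}", "1", int(pos[lo]), int(pos[hi]),
                                   hi - lo + 1, 0, 0))
    return segs


def test_single_plateau_single_island():
    gm = _island_matrix()
    segs = _segments_covering(gm, [(40, 60)], 9)
    islands = roh_islands(segs, gm, top_fraction=0.2)
    assert len(islands) == 1
    assert islands["start_bp"].iloc[0] == gm.positions[40]
    assert islands["end_bp"].iloc[0] == gm.positions[60]


def test_two_plateaus_two_islands():
    gm = _island_matrix()
    segs = _segments_covering(gm, [(10, 20), (70, 80)], 9)
    islands = roh_islands(segs, gm, top_fraction=0.25)
    assert len(islands) == 2


def test_islands_match_quantile_and_merge_oracle(rng):
    gm = make_matrix(np.zeros((10, 1000), dtype=np.int8),
                     positions=np.arange(10_000, 10_000 * 1001, 10_000))
    # random incidence profile via random per-individual segments
    segs = []
    for i in range(10):
        for _ in range(rng.integers(3, 8)):
            lo = int(rng.integers(0, 900))
            hi = lo + int(rng.integers(10, 80))
            segs.append(ROHSegment(f"s{i}", "1", int(gm.positions[lo]),
                                   int(gm.positions[min(hi, 999)]), 10, 0, 0))
    islands = roh_islands(segs, gm, top_fraction=0.01)
    # oracle: quantile threshold + linear merge scan
    frac = snp_roh_incidence(segs, gm)["fraction"].to_numpy()
    thr = np.quantile(frac, 0.99)
    sel = [k for k in range(1000) if frac[k] >= thr and frac[k] > 0]
    merged = []
    for k in sel:
        if merged and k == merged[-1][-1] + 1:
            merged[-1].append(k)
        else:
            merged.append([k])
    assert len(islands) == len(merged)
    for row, blk in zip(islands.itertuples(index=False), merged):
        assert row.start_bp == gm.positions[blk[0]]
        assert row.end_bp == gm.positions[blk[-1]]
    # merged islands are sorted and non-overlapping
    assert (islands["start_bp"].diff().dropna() > 0).all()
    assert (islands["end_bp"] >= islands["start_bp"]).all()


def test_no_roh_no_islands():
    gm = _island_matrix()
    with pytest.warns(UserWarning, match="no islands"):
        islands = roh_islands([], gm)
    assert islands.empty


# ---------------------------------------------------------------------------
# region selection
# ---------------------------------------------------------------------------

def _stats(values, step=10_000):
    rows = []
    for k, v in enumerate(values):
        start = 1 + k * step
        rows.append(("1", start, start + 99_999, 1, v, 1, False))
    return pd.DataFrame(rows, columns=["chromosome", "start_bp", "end_bp",
                                       "n_variants", "value", "S", "c_varies"])


def test_all_equal_selects_nothing():
    assert select_regions(_stats([1.0] * 100), 0.05).empty


def test_single_outlier_selected():
    values = [1.0] * 99 + [0.001]
    regions = select_regions(_stats(values), 0.05)
    assert len(regions) == 1
    assert regions["start_bp"].iloc[0] == 1 + 99 * 10_000


def test_tied_lower_tail_all_selected():
    # >1% of windows tied at the minimum: all of them are taken
    values = [0.001] * 5 + [1.0] * 95
    regions = select_regions(_stats(values), 0.01)
    assert regions["n_windows"].sum() == 5


def test_selection_monotone_in_quantile(rng):
    values = rng.random(500)
    n = [select_regions(_stats(values), q)["n_windows"].sum()
         for q in (0.01, 0.05, 0.1, 0.5)]
    assert n == sorted(n)


def test_overlapping_windows_merge():
    values = [1.0] * 100
    values[40:45] = [0.001] * 5          # five consecutive 100 kb windows
    regions = select_regions(_stats(values), 0.1)
    assert len(regions) == 1
    assert regions["n_windows"].iloc[0] == 5


def test_invalid_quantile_rejected():
    with pytest.raises(ValueError, match="quantile"):
        select_regions(_stats([1.0, 2.0]), 0.7)


def test_planted_low_pi_stretch_recovered():
    from popkit.simulate import SimulationConfig, simulate_founders

    hits = 0
    for seed in range(10):
        cfg = SimulationConfig(n_individuals=30, n_chromosomes=2,
                               chrom_length_bp=20_000_000,
                               marker_spacing_bp=10_000, seed=seed)
        gm, _, _ = simulate_founders(cfg)
        # push a 2 Mb stretch on chromosome 1 toward fixation
        sweep_lo, sweep_hi = 9_000_000, 11_000_000
        mask = ((gm.chromosomes == "1") & (gm.positions >= sweep_lo)
                & (gm.positions < sweep_hi))
        rng = np.random.default_rng(seed + 100)
        calls = gm.calls.copy()
        calls[:, mask] = rng.binomial(2, 0.02, size=(30, mask.sum()))
        gm = make_matrix(calls, gm.chromosomes, gm.positions)
        win = windowed_pi(gm)
        regions = select_regions(win, quantile=0.05)
        sel = regions[regions["chromosome"] == "1"]
        covered = 0
        for r in sel.itertuples(index=False):
            covered += max(0, min(r.end_bp, sweep_hi) - max(r.start_bp, sweep_lo))
        union = (sweep_hi - sweep_lo) + sum(
            (r.end_bp - r.start_bp) for r in sel.itertuples(index=False)) - covered
        if covered / union >= 0.5:
            hits += 1
    assert hits >= 8


# ---------------------------------------------------------------------------
# annotation + intersection
# ---------------------------------------------------------------------------

def _regions(rows):
    return pd.DataFrame(rows, columns=["chromosome", "start_bp", "end_bp"])


def test_gene_abutting_region_no_hit(tmp_path):
    bed = tmp_path / "genes.bed"
    bed.write_text("1\t200\t300\tgeneA\n")      # 1-based [201, 300]
    genes = read_gene_intervals(str(bed))
    # region ends at 200; gene starts at 201 -> book-ended, no overlap
    assert genes_in_regions(_regions([("1", 100, 200)]), genes) == set()
    assert genes_in_regions(_regions([("1", 100, 201)]), genes) == {"geneA"}


def test_gff3_gene_features(tmp_path):
    gff = tmp_path / "genes.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "1\tsrc\tgene\t1000\t2000\t.\t+\t.\tID=g1;Name=BMPR1B\n"
        "1\tsrc\texon\t1000\t1500\t.\t+\t.\tID=g1.e1\n"
        "2\tsrc\tgene\t5000\t6000\t.\t-\t.\tID=g2;Name=KCNIP4\n")
    genes = read_gene_intervals(str(gff), attribute="Name")
    assert set(genes["gene"]) == {"BMPR1B", "KCNIP4"}
    assert genes_in_regions(_regions([("1", 1500, 1600)]), genes) == {"BMPR1B"}


def test_chromosome_scheme_mismatch_raises(tmp_path):
    bed = tmp_path / "genes.bed"
    bed.write_text("chr1\t100\t200\tgeneA\n")
    genes = read_gene_intervals(str(bed))
    with pytest.raises(ValueError, match="remap"):
        genes_in_regions(_regions([("1", 100, 200)]), genes)


def test_three_way_intersection_recovers_planted_genes(tmp_path):
    bed = tmp_path / "genes.bed"
    bed.write_text(
        "1\t1000\t2000\tshared\n"
        "1\t5000\t6000\troh_only\n"
        "2\t1000\t2000\tpi_only\n")
    genes = read_gene_intervals(str(bed))
    regions = {
        "ROH": _regions([("1", 1200, 1800), ("1", 5100, 5900)]),
        "Pi": _regions([("1", 1200, 1800), ("2", 1200, 1800)]),
        "TajimaD": _regions([("1", 900, 2100)]),
    }
    result = annotate_and_intersect(regions, genes)
    assert result.three_way == {"shared"}
    assert result.gene_sets["ROH"] == {"shared", "roh_only"}
    assert result.venn["ROH&Pi&TajimaD"] == 1
    assert result.venn["ROH"] == 1          # roh_only exclusively


def test_empty_annotation_empty_venn():
    genes = pd.DataFrame(columns=["chromosome", "start_bp", "end_bp", "gene"])
    result = annotate_and_intersect(
        {"ROH": _regions([("1", 1, 10)]), "Pi": _regions([])}, genes)
    assert all(len(s) == 0 for s in result.gene_sets.values())
    assert all(v == 0 for v in result.venn.values())


def test_venn_obeys_inclusion_exclusion(rng):
    # random gene sets via random regions; exclusive Venn cells must sum to
    # the union size
    bed_rows = [f"1\t{k * 100}\t{k * 100 + 50}\tg{k}" for k in range(50)]
    genes = pd.DataFrame({
        "chromosome": "1",
        "start_bp": [k * 100 + 1 for k in range(50)],
        "end_bp": [k * 100 + 50 for k in range(50)],
        "gene": [f"g{k}" for k in range(50)],
    })
    regions = {}
    for m in ("ROH", "Pi", "TajimaD"):
        rows = []
        for _ in range(5):
            lo = int(rng.integers(0, 4500))
            rows.append(("1", lo + 1, lo + int(rng.integers(50, 500))))
        regions[m] = _regions(rows)
    result = annotate_and_intersect(regions, genes)
    union = set().union(*result.gene_sets.values())
    assert sum(result.venn.values()) == len(union)
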
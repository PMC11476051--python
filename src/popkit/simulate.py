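"""Synthetic SNP-array genotypes with known truth.

Emulates a medium-density sheep chip study: ~26 autosomes, markers every
~50 kb, ~50 rams structured as half-sib sire lines, low inbreeding, and
(optionally) planted autozygous tracts so that ROH callers, kinship estimators
and sweep scans can be validated against ground truth.

Founders are simulated as two haplotypes per individual with independent
markers (no background LD); offspring arise by Mendelian gamete sampling with
Poisson crossovers at 1 cM/Mb, which is what creates within-family LD and
realized-kinship variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, MarkerRecord


class ConfigError(ValueError):
    pass


#: chip-like MAF bin proportions on [0, 0.1) .. [0.4, 0.5]; the first two are
#: observed array proportions, the rest split the remainder evenly
CHIP_MAF_BINS = (0.2145, 0.1734, 0.2040, 0.2040, 0.2041)


@dataclass
class SimulationConfig:
    """Study-scale defaults: 50 rams, 12 sire lines, 26 x 100 Mb autosomes,
    ~50 kb marker spacing (=> ~52k markers), uniform MAF in [0.01, 0.5]."""

    n_individuals: int = 50
    n_sire_lines: int = 12
    offspring_per_line: tuple[int, int] = (2, 6)
    n_chromosomes: int = 26
    chrom_length_bp: int = 100_000_000
    # chip density ~40 kb/SNP (a ~65k-marker array on ~2.6 Gb of autosome)
    marker_spacing_bp: int = 40_000
    #: gaps are uniform on spacing * [1 - jitter, 1 + jitter]; 0 = exact grid
    marker_jitter: float = 0.8
    maf_distribution: str | tuple = ("uniform", 0.01, 0.5)
    #: consecutive markers sharing one spectrum draw; >1 mimics the spatial
    #: autocorrelation of allele frequencies along real chromosomes, which
    #: makes QC removals cluster instead of peppering the map with gaps
    maf_block_markers: int = 1
    missing_rate: float = 0.0
    het_error_rate: float = 0.0
    planted_roh: list[tuple[int, str, int, int]] = field(default_factory=list)
    target_F: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_chromosomes < 1:
            raise ConfigError("need at least one individual and one chromosome")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.marker_spacing_bp <= 0 or self.chrom_length_bp <= 0:
            raise ConfigError("lengths and spacing must be positive")
        lo, hi = self.offspring_per_line
        if not 1 <= lo <= hi:
            raise ConfigError("offspring_per_line bounds must satisfy 1 <= lo <= hi")
        seen: dict[int, list[tuple[int, int]]] = {}
        for ind, chrom, start, length in self.planted_roh:
            if start < 1 or start + length - 1 > self.chrom_length_bp:
                raise ConfigError("planted tract outside chromosome bounds")
            for s0, e0 in seen.setdefault(ind, []):
                if start <= e0 and start + length - 1 >= s0:
                    raise ConfigError("planted tracts overlap for one individual")
            seen[ind].append((start, start + length - 1))

    @property
    def genome_length_bp(self) -> int:
        return self.n_chromosomes * self.chrom_length_bp


@dataclass
class TruthTable:
    """Ground truth carried alongside a simulated GenotypeMatrix."""

    family_label: list[str]
    planted_roh: pd.DataFrame          # individual, chromosome, start_bp, end_bp
    autozygosity: np.ndarray           # planted fraction per individual
    allele_freq: np.ndarray            # true alt frequency per marker

    def to_tsv(self, prefix: str) -> None:
        pd.DataFrame({"family": self.family_label}).to_csv(
            f"{prefix}.families.tsv", sep="\t", index_label="individual")
        self.planted_roh.to_csv(f"{prefix}.planted_roh.tsv", sep="\t", index=False)


def _draw_frequencies(config: SimulationConfig, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    block = max(int(config.maf_block_markers), 1)
    if block > 1:
        n_blocks = -(-n // block)
        per_block = _draw_frequencies(
            replace(config, maf_block_markers=1), n_blocks, rng)
        base = np.repeat(per_block, block)[:n]
        # small within-block scatter so markers are not literally identical
        jitter = rng.normal(0, 0.01, n)
        return np.clip(base + jitter, 1e-4, 1 - 1e-4)
    spec = config.maf_distribution
    if isinstance(spec, tuple) and spec[0] == "uniform":
        _, lo, hi = spec
        maf = rng.uniform(lo, hi, n)
        flip = rng.random(n) < 0.5
        return np.where(flip, 1.0 - maf, maf)
    if spec == "chip":
        # piecewise-uniform MAF over five 0.1-wide bins
        bins = rng.choice(5, size=n, p=CHIP_MAF_BINS)
        maf = (bins + rng.random(n)) * 0.1
        maf = np.clip(maf, 1e-3, 0.5)
        flip = rng.random(n) < 0.5
        return np.where(flip, 1.0 - maf, maf)
    if spec == "neutral":
        # stationary neutral spectrum: density ~ 1/p on [p_min, 1).  With
        # p_min << 1/(2n) the sampled-site frequency spectrum conditional on
        # segregating converges to the neutral 1/i law (a sharper cutoff
        # would starve singletons and bias Tajima's D upward); many draws are
        # then monomorphic in the sample, which simply thins the marker set.
        p_min = 1.0 / (400.0 * config.n_individuals)
        u = rng.random(n)
        return p_min ** (1.0 - u)      # inverse-CDF of 1/p density
    raise ConfigError(f"unknown maf_distribution {spec!r}")


def _marker_map(config: SimulationConfig,
                rng: np.random.Generator) -> list[MarkerRecord]:
    records = []
    for c in range(1, config.n_chromosomes + 1):
        pos = []
        j = config.marker_jitter
        p = int(rng.integers(1, config.marker_spacing_bp + 1))
        while p <= config.chrom_length_bp:
            pos.append(p)
            p += max(int(config.marker_spacing_bp * rng.uniform(1 - j, 1 + j)), 1)
        for j, bp in enumerate(pos):
            records.append(
                MarkerRecord(f"snp_{c}_{j}", str(c), bp, bp / 1e6, "A", "G")
            )
    if not records:
        raise ConfigError("configuration yields zero markers")
    return records


def simulate_founders(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    n_individuals: int | None = None,
) -> tuple[GenotypeMatrix, TruthTable, np.ndarray]:
    """Unrelated individuals in HWE; returns (matrix, truth, haplotypes).

    Haplotypes have shape (n, 2, N) so that family simulation can gamete-sample
    from them; genotype calls are their sum with missingness applied.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_individuals if n_individuals is None else n_individuals
    markers = _marker_map(config, rng)
    n_mark = len(markers)
    freq = _draw_frequencies(config, n_mark, rng)
    haps = (rng.random((n, 2, n_mark)) < freq).astype(np.int8)
    calls = haps.sum(axis=1, dtype=np.int8)
    if config.missing_rate > 0:
        calls[rng.random(calls.shape) < config.missing_rate] = MISSING
    samples = [f"ind{i:03d}" for i in range(n)]
    truth = TruthTable(
        family_label=["founder"] * n,
        planted_roh=pd.DataFrame(
            columns=["individual", "chromosome", "start_bp", "end_bp"]),
        autozygosity=np.zeros(n),
        allele_freq=freq,
    )
    return GenotypeMatrix(samples, markers, calls), truth, haps


def _line_sizes(config: SimulationConfig, rng: np.random.Generator) -> list[int]:
    lo, hi = config.offspring_per_line
    k, n = config.n_sire_lines, config.n_individuals
    if not k * lo <= n <= k * hi:
        raise ConfigError(
            f"{n} offspring cannot be split into {k} lines of {lo}-{hi}")
    sizes = [lo] * k
    room = [hi - lo] * k
    for _ in range(n - k * lo):
        open_lines = [i for i in range(k) if room[i] > 0]
        i = int(rng.choice(open_lines))
        sizes[i] += 1
        room[i] -= 1
    return sizes


def _gamete(haps: np.ndarray, chrom_starts: list[tuple[np.ndarray, np.ndarray]],
            rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete from a (2, N) parental haplotype pair."""
    out = np.empty(haps.shape[1], dtype=np.int8)
    for idx, pos in chrom_starts:
        length_bp = pos[-1] if len(pos) else 0
        n_x = rng.poisson(length_bp / 1e8)          # 1 cM/Mb
        cuts = np.sort(rng.uniform(0, length_bp, n_x))
        phase = int(rng.integers(2))
        which = (phase + np.searchsorted(cuts, pos)) % 2
        out[idx] = haps[which, idx]
    return out


def simulate_families(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, TruthTable]:
    """Half-sib sire lines: one founder sire x one founder dam per offspring.

    Offspring form the returned population; truth family label is the sire id.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    sizes = _line_sizes(config, rng)
    n_founders = config.n_sire_lines + config.n_individuals   # sires + dams
    gm_f, truth_f, haps = simulate_founders(config, rng, n_individuals=n_founders)
    chrom_blocks = [
        (idx, gm_f.positions[idx]) for _, idx in gm_f.iter_chromosomes()
    ]
    calls = np.empty((config.n_individuals, gm_f.n_markers), dtype=np.int8)
    labels = []
    dam = config.n_sire_lines
    child = 0
    for line, size in enumerate(sizes):
        for _ in range(size):
            pat = _gamete(haps[line], chrom_blocks, rng)
            mat = _gamete(haps[dam], chrom_blocks, rng)
            calls[child] = pat + mat
            labels.append(f"sire{line:02d}")
            dam += 1
            child += 1
    if config.missing_rate > 0:
        calls[rng.random(calls.shape) < config.missing_rate] = MISSING
    samples = [f"ind{i:03d}" for i in range(config.n_individuals)]
    gm = GenotypeMatrix(samples, gm_f.markers, calls)
    truth = TruthTable(
        family_label=labels,
        planted_roh=truth_f.planted_roh,
        autozygosity=np.zeros(config.n_individuals),
        allele_freq=truth_f.allele_freq,
    )
    return gm, truth


def _random_tracts(config: SimulationConfig, n_individuals: int,
                   rng: np.random.Generator) -> list[tuple[int, str, int, int]]:
    """Random non-overlapping tracts per individual totalling target_F."""
    goal = int(round(config.target_F * config.genome_length_bp))
    tracts: list[tuple[int, str, int, int]] = []
    for ind in range(n_individuals):
        placed: dict[str, list[tuple[int, int]]] = {}
        total = 0
        attempts = 0
        while total < goal and attempts < 10_000:
            attempts += 1
            length = int(rng.uniform(1e6, min(26e6, config.chrom_length_bp)))
            length = min(length, goal - total)   # trim last tract to the target
            chrom = str(int(rng.integers(1, config.n_chromosomes + 1)))
            if length >= config.chrom_length_bp or length < 1:
                continue
            start = int(rng.integers(1, config.chrom_length_bp - length + 1))
            end = start + length - 1
            if any(start <= e and end >= s for s, e in placed.get(chrom, [])):
                continue
            placed.setdefault(chrom, []).append((start, end))
            tracts.append((ind, chrom, start, length))
            total += length
    return tracts


def plant_autozygosity(
    gm: GenotypeMatrix,
    config: SimulationConfig,
    truth: TruthTable | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, TruthTable]:
    """Force homozygosity inside planted tracts (explicit list or target_F).

    Inside each tract one allele is duplicated: het calls collapse to a random
    homozygote, hom calls stay; ``het_error_rate`` then re-introduces isolated
    heterozygous calls, emulating genotyping error inside true autozygous runs.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    tracts = list(config.planted_roh)
    if not tracts and config.target_F is not None:
        tracts = _random_tracts(config, gm.n_samples, rng)
    if not tracts:
        raise ConfigError("no planted_roh list and no target_F given")
    calls = gm.calls.copy()
    chrom = gm.chromosomes
    pos = gm.positions
    rows = []
    for ind, c, start, length in tracts:
        end = start + length - 1
        in_tract = (chrom == c) & (pos >= start) & (pos <= end)
        idx = np.flatnonzero(in_tract)
        g = calls[ind, idx]
        het = g == 1
        g[het] = rng.choice((0, 2), size=int(het.sum()))
        if config.het_error_rate > 0:
            err = rng.random(len(idx)) < config.het_error_rate
            g[err] = 1
        calls[ind, idx] = g
        rows.append((ind, c, start, end))
    planted = pd.DataFrame(
        rows, columns=["individual", "chromosome", "start_bp", "end_bp"])
    auto = np.zeros(gm.n_samples)
    lengths = planted["end_bp"] - planted["start_bp"] + 1
    for ind, total in lengths.groupby(planted["individual"]).sum().items():
        auto[ind] = total / config.genome_length_bp
    base = truth
    out_truth = TruthTable(
        family_label=(base.family_label if base is not None
                      else ["founder"] * gm.n_samples),
        planted_roh=planted,
        autozygosity=auto,
        allele_freq=(base.allele_freq if base is not None
                     else gm.allele_frequencies()),
    )
    return GenotypeMatrix(gm.samples, gm.markers, calls), out_truth


# ---------------------------------------------------------------------------
# QC-challenge marker injection
# ---------------------------------------------------------------------------

@dataclass
class QCNoiseProportions:
    """Fractions of extra problem markers, defaulting to array-realistic
    ratios (relative to the clean marker count): sex-chromosome markers,
    sub-threshold-MAF markers, HWE-violating markers, high-missingness
    markers, and indel records."""

    chr_x: float = 0.0236
    chr_y: float = 0.0193
    low_maf: float = 0.0637
    hwe_fail: float = 0.0016
    high_missing: float = 0.0185
    indel: float = 0.00014


def inject_qc_categories(
    gm: GenotypeMatrix,
    rng: np.random.Generator,
    proportions: QCNoiseProportions | None = None,
) -> tuple[GenotypeMatrix, pd.Series]:
    """Append markers that each QC filter should remove.

    Returns the augmented (sorted) matrix and a Series mapping marker_id ->
    expected removal category ("clean" for originals).
    """
    prop = proportions or QCNoiseProportions()
    n, base = gm.n_samples, gm.n_markers
    recs = gm.marker_records()
    new_recs: list[MarkerRecord] = []
    new_cols: list[np.ndarray] = []
    labels: dict[str, str] = {m.marker_id: "clean" for m in recs}

    def add(rec: MarkerRecord, col: np.ndarray, label: str) -> None:
        new_recs.append(rec)
        new_cols.append(col.astype(np.int8))
        labels[rec.marker_id] = label

    counts = {
        "chrX": int(round(prop.chr_x * base)),
        "chrY": int(round(prop.chr_y * base)),
        "maf": int(round(prop.low_maf * base)),
        "hwe": int(round(prop.hwe_fail * base)),
        "call_rate": int(round(prop.high_missing * base)),
        "indel": max(int(round(prop.indel * base)), 1),
    }
    serial = 0
    max_pos = int(gm.positions.max())
    for label, k in counts.items():
        for _ in range(k):
            serial += 1
            pos_bp = int(rng.integers(1, max_pos))
            chrom = str(int(rng.integers(1, len(set(gm.chromosomes)) + 1)))
            rec = MarkerRecord(f"qcnoise_{serial}", chrom, pos_bp,
                               pos_bp / 1e6, "A", "G")
            p = rng.uniform(0.1, 0.5)
            col = rng.binomial(2, p, size=n)
            if label == "chrX":
                rec = replace(rec, chromosome="X")
            elif label == "chrY":
                rec = replace(rec, chromosome="Y")
            elif label == "maf":
                q = rng.uniform(0.001, 0.04)
                col = rng.binomial(2, q, size=n)
            elif label == "hwe":
                col = rng.choice((0, 2), size=n)   # no hets at p ~ 0.5
            elif label == "call_rate":
                col = col.astype(np.int8)
                miss = rng.random(n) < 0.5
                col[miss] = MISSING
            elif label == "indel":
                rec = replace(rec, allele_alt="I")
            add(rec, col, label)
    markers = recs + new_recs
    calls = np.concatenate([gm.calls, np.array(new_cols, dtype=np.int8).T], axis=1)
    out = GenotypeMatrix(gm.samples, markers, calls).sort_markers()
    return out, pd.Series(labels, name="qc_category")


def simulate_dataset(
    config: SimulationConfig,
    qc_noise: bool = False,
) -> tuple[GenotypeMatrix, TruthTable, pd.Series | None]:
    """One-call generator: families, optional planted ROH, optional QC noise."""
    rng = np.random.default_rng(config.seed)
    gm, truth = simulate_families(config, rng)
    if config.planted_roh or config.target_F is not None:
        gm, truth = plant_autozygosity(gm, config, truth, rng)
    categories = None
    if qc_noise:
        gm, categories = inject_qc_categories(gm, rng)
    return gm, truth, categories
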
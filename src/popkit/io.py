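"""Genotype container and file formats.

The in-memory model is a :class:`GenotypeMatrix`: individuals x markers with
integer calls 0 (hom-ref), 1 (het), 2 (hom-alt) and -1 (missing), plus a marker
map.  Readers and writers cover PLINK 1 text (.ped/.map), PLINK 1 binary
(.bed/.bim/.fam, SNP-major) and VCF; interval exports use BED.

Coordinate conventions: all in-memory positions are 1-based, as in .map/.bim/VCF;
BED output is converted to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

MISSING = -1

#: column order of the marker table
MARKER_COLUMNS = [
    "marker_id",
    "chromosome",
    "position_bp",
    "genetic_pos_cM",
    "allele_ref",
    "allele_alt",
]


class GenotypeFormatError(ValueError):
    """Malformed genotype file."""


@dataclass(frozen=True)
class MarkerRecord:
    """One SNP on the array.

    Chromosome labels are strings so that "X"/"Y" markers can be represented
    before QC; autosomes are "1".."26".  ``genetic_pos_cM`` falls back to
    position_bp / 1e6 (1 cM ~ 1 Mb) when the map file carries no genetic map.
    """

    marker_id: str
    chromosome: str
    position_bp: int
    genetic_pos_cM: float = 0.0
    allele_ref: str = "A"
    allele_alt: str = "B"

    @property
    def is_indel(self) -> bool:
        ok = {"A", "C", "G", "T"}
        return self.allele_ref not in ok or self.allele_alt not in ok


def _marker_frame(markers: Sequence[MarkerRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(markers, pd.DataFrame):
        missing = set(MARKER_COLUMNS) - set(markers.columns)
        if missing:
            raise ValueError(f"marker table lacks columns: {sorted(missing)}")
        return markers[MARKER_COLUMNS].reset_index(drop=True)
    return pd.DataFrame(
        [
            (m.marker_id, m.chromosome, m.position_bp, m.genetic_pos_cM,
             m.allele_ref, m.allele_alt)
            for m in markers
        ],
        columns=MARKER_COLUMNS,
    )


@dataclass
class GenotypeMatrix:
    """n individuals x N markers, calls coded 0/1/2 with -1 = missing."""

    samples: list[str]
    markers: pd.DataFrame
    calls: np.ndarray

    def __init__(
        self,
        samples: Sequence[str],
        markers: Sequence[MarkerRecord] | pd.DataFrame,
        calls: np.ndarray,
    ) -> None:
        self.samples = list(samples)
        self.markers = _marker_frame(markers)
        self.calls = np.asarray(calls, dtype=np.int8)
        self.validate()

    def validate(self) -> None:
        n, m = self.calls.shape
        if n != len(self.samples) or m != len(self.markers):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.calls, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        if self.markers["marker_id"].duplicated().any():
            raise ValueError("marker ids are not unique")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def positions(self) -> np.ndarray:
        return self.markers["position_bp"].to_numpy()

    @property
    def chromosomes(self) -> np.ndarray:
        return self.markers["chromosome"].to_numpy()

    def marker_records(self) -> list[MarkerRecord]:
        return [MarkerRecord(*row) for row in self.markers.itertuples(index=False)]

    def take_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset markers by boolean mask or integer index, keeping order."""
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.samples, self.markers.iloc[idx], self.calls[:, idx]
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            [self.samples[i] for i in idx], self.markers, self.calls[idx, :]
        )

    def sort_markers(self) -> "GenotypeMatrix":
        """Sort by (chromosome, position); numeric chromosome labels first."""
        chrom = self.markers["chromosome"]
        num = pd.to_numeric(chrom, errors="coerce")
        order = np.lexsort(
            (self.markers["position_bp"], chrom.to_numpy(), num.fillna(np.inf))
        )
        return self.take_markers(order)

    def iter_chromosomes(self) -> Iterator[tuple[str, np.ndarray]]:
        """Yield (chromosome label, marker index array) in map order."""
        chrom = self.markers["chromosome"].to_numpy()
        seen: dict[str, list[int]] = {}
        for i, c in enumerate(chrom):
            seen.setdefault(c, []).append(i)
        for c, idx in seen.items():
            yield c, np.asarray(idx)

    def allele_frequencies(self) -> np.ndarray:
        """Alt-allele frequency per marker, missing calls excluded.

        Markers with no non-missing call get NaN.
        """
        calls = self.calls
        obs = calls >= 0
        n_called = obs.sum(axis=0)
        alt = np.where(obs, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, alt / (2.0 * n_called), np.nan)


# ---------------------------------------------------------------------------
# PLINK 1 text
# ---------------------------------------------------------------------------

def read_map(map_path: str | Path) -> list[MarkerRecord]:
    records = []
    for ln, line in enumerate(Path(map_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise GenotypeFormatError(f"{map_path}:{ln}: expected 4 columns")
        chrom, mid, cm, bp = parts[:4]
        cm_f = float(cm)
        bp_i = int(bp)
        if cm_f == 0.0:
            cm_f = bp_i / 1e6
        records.append(MarkerRecord(mid, chrom, bp_i, cm_f))
    return records


def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read a PLINK 1 .ped/.map pair.

    PLINK text files carry no reference orientation, so per marker the first
    allele seen in the .ped column is taken as ref; "0 0" codes missing.
    Allele assignments recorded in the .map-derived marker table.
    """
    markers = read_map(map_path)
    n_mark = len(markers)
    samples: list[str] = []
    rows: list[np.ndarray] = []
    # first-seen allele per marker becomes ref, second becomes alt
    alleles: list[list[str]] = [[] for _ in range(n_mark)]
    for ln, line in enumerate(Path(ped_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_mark:
            raise GenotypeFormatError(
                f"{ped_path}:{ln}: expected {6 + 2 * n_mark} fields, got {len(parts)}"
            )
        samples.append(parts[1])
        row = np.empty(n_mark, dtype=np.int8)
        for k in range(n_mark):
            a, b = parts[6 + 2 * k], parts[7 + 2 * k]
            if a == "0" or b == "0":
                if a != b:
                    raise GenotypeFormatError(
                        f"{ped_path}:{ln}: half-missing genotype at marker {k + 1}"
                    )
                row[k] = MISSING
                continue
            code = 0
            for al in (a, b):
                if al not in alleles[k]:
                    if len(alleles[k]) == 2:
                        raise GenotypeFormatError(
                            f"{ped_path}:{ln}: more than two alleles at marker "
                            f"{markers[k].marker_id}"
                        )
                    alleles[k].append(al)
                code += alleles[k].index(al)
            row[k] = code
        rows.append(row)
    resolved = []
    for m, seen in zip(markers, alleles):
        ref = seen[0] if len(seen) > 0 else m.allele_ref
        alt = seen[1] if len(seen) > 1 else m.allele_alt
        resolved.append(MarkerRecord(m.marker_id, m.chromosome, m.position_bp,
                                     m.genetic_pos_cM, ref, alt))
    return GenotypeMatrix(samples, resolved, np.vstack(rows))


def write_plink_text(gm: GenotypeMatrix, ped_path: str | Path,
                     map_path: str | Path) -> None:
    with open(map_path, "w") as fh:
        for m in gm.marker_records():
            fh.write(f"{m.chromosome}\t{m.marker_id}\t{m.genetic_pos_cM:g}"
                     f"\t{m.position_bp}\n")
    recs = gm.marker_records()
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(gm.samples):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for k, m in enumerate(recs):
                c = gm.calls[i, k]
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == 0:
                    fields += [m.allele_ref, m.allele_ref]
                elif c == 1:
                    fields += [m.allele_ref, m.allele_alt]
                else:
                    fields += [m.allele_alt, m.allele_alt]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# PLINK 1 binary (SNP-major)
# ---------------------------------------------------------------------------

_BED_MAGIC = b"\x6c\x1b"
# PLINK 2-bit codes -> matrix codes, with A1 = alt (PLINK convention: A1 minor):
# 00 hom A1 -> 2, 01 missing -> -1, 10 het -> 1, 11 hom A2 -> 0
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def read_plink_binary(bed: str | Path, bim: str | Path,
                      fam: str | Path, a1_is_alt: bool = True) -> GenotypeMatrix:
    """Read a PLINK 1 .bed/.bim/.fam trio (SNP-major only).

    ``a1_is_alt`` keeps the PLINK convention of A1 = minor = alt allele; set
    False to treat A1 as ref (flips codes 0 <-> 2).
    """
    markers = []
    for ln, line in enumerate(Path(bim).read_text().splitlines(), 1):
        parts = line.split()
        if len(parts) < 6:
            raise GenotypeFormatError(f"{bim}:{ln}: expected 6 columns")
        chrom, mid, cm, bp, a1, a2 = parts[:6]
        cm_f = float(cm) if float(cm) != 0 else int(bp) / 1e6
        ref, alt = (a2, a1) if a1_is_alt else (a1, a2)
        markers.append(MarkerRecord(mid, chrom, int(bp), cm_f, ref, alt))
    samples = [line.split()[1]
               for line in Path(fam).read_text().splitlines() if line.strip()]
    n, n_mark = len(samples), len(markers)
    blob = Path(bed).read_bytes()
    if blob[:2] != _BED_MAGIC:
        raise GenotypeFormatError(f"{bed}: bad magic bytes {blob[:2]!r}")
    if blob[2:3] != b"\x01":
        raise GenotypeFormatError(f"{bed}: not SNP-major (mode byte {blob[2]:#x})")
    bytes_per_marker = (n + 3) // 4
    expected = 3 + bytes_per_marker * n_mark
    if len(blob) != expected:
        raise GenotypeFormatError(
            f"{bed}: truncated at byte {len(blob)} (expected {expected})"
        )
    raw = np.frombuffer(blob, dtype=np.uint8, offset=3)
    raw = raw.reshape(n_mark, bytes_per_marker)
    # unpack 2-bit fields, lowest bits first
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    two_bit = (raw[:, :, None] >> shifts) & 0b11          # (N, bpm, 4)
    codes = _BED_DECODE[two_bit.reshape(n_mark, -1)[:, :n]]
    calls = codes.T.copy()
    if not a1_is_alt:
        flip = calls >= 0
        calls[flip] = 2 - calls[flip]
    return GenotypeMatrix(samples, markers, calls)


def write_plink_binary(gm: GenotypeMatrix, bed: str | Path, bim: str | Path,
                       fam: str | Path) -> None:
    with open(bim, "w") as fh:
        for m in gm.marker_records():
            fh.write(f"{m.chromosome}\t{m.marker_id}\t{m.genetic_pos_cM:g}\t"
                     f"{m.position_bp}\t{m.allele_alt}\t{m.allele_ref}\n")
    with open(fam, "w") as fh:
        for sid in gm.samples:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    n = gm.n_samples
    bytes_per_marker = (n + 3) // 4
    # map matrix codes to 2-bit fields; index by code+1 so missing (-1) -> slot 0
    code_bits = np.empty(4, dtype=np.uint8)
    for code, bits in _BED_ENCODE.items():
        code_bits[code + 1] = bits
    bits = code_bits[gm.calls.T.astype(np.int16) + 1]      # (N, n)
    with open(bed, "wb") as fh:
        fh.write(_BED_MAGIC + b"\x01")
        buf = np.zeros((gm.n_markers, bytes_per_marker), dtype=np.uint8)
        for b in range(4):
            cols = np.arange(b, n, 4)
            buf[:, cols // 4] |= bits[:, cols] << np.uint8(2 * b)
        fh.write(buf.tobytes())


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF into a GenotypeMatrix.

    Multi-allelic rows are rejected; GT "./." (or ".|.") codes missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    markers, rows = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise GenotypeFormatError(
                f"{path}: multi-allelic record at {var.CHROM}:{var.POS}"
            )
        markers.append(
            MarkerRecord(
                var.ID or f"{var.CHROM}:{var.POS}",
                str(var.CHROM),
                var.POS,
                var.POS / 1e6,
                var.REF,
                var.ALT[0],
            )
        )
        gt = np.asarray(var.gt_types, dtype=np.int8)   # 0/1/2, 3 = unknown
        gt[gt == 3] = MISSING
        rows.append(gt)
    vcf.close()
    if not rows:
        raise GenotypeFormatError(f"{path}: no variant records")
    return GenotypeMatrix(samples, markers, np.vstack(rows).T)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(gm.markers["chromosome"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for k, m in enumerate(gm.marker_records()):
            gts = "\t".join(_GT_STR[int(c)] for c in gm.calls[:, k])
            fh.write(f"{m.chromosome}\t{m.position_bp}\t{m.marker_id}\t"
                     f"{m.allele_ref}\t{m.allele_alt}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# BED intervals (output only)
# ---------------------------------------------------------------------------

def write_bed_intervals(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write 1-based closed intervals as 0-based half-open BED.

    ``intervals`` needs columns chromosome/start_bp/end_bp; extra columns are
    appended as BED name/score-style fields.
    """
    cols = ["chromosome", "start_bp", "end_bp"]
    extra = [c for c in intervals.columns if c not in cols]
    with open(path, "w") as fh:
        for row in intervals.itertuples(index=False):
            d = row._asdict()
            rest = "".join(f"\t{d[c]}" for c in extra)
            fh.write(f"{d['chromosome']}\t{d['start_bp'] - 1}\t{d['end_bp']}{rest}\n")
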
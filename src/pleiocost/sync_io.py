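"""Reading, filtering and writing PoPoolation2 sync files.

A sync file is tab-separated text with one genomic site per line:
chromosome, 1-based position, reference base, then one column per sample of
colon-separated allele counts in the fixed order A:T:C:G:N:del.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

NUCLEOTIDES = ("A", "T", "C", "G")
_NUC_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}


class SyncFormatError(ValueError):
    """Malformed sync input; the message names the offending line."""


@dataclass(eq=False)
class SyncRecord:
    chrom: str
    pos: int                      # 1-based
    ref: str
    samples: np.ndarray           # (n_samples, 6) non-negative ints

    def __eq__(self, other):
        if not isinstance(other, SyncRecord):
            return NotImplemented
        return (self.chrom, self.pos, self.ref) == (other.chrom, other.pos, other.ref) \
            and np.array_equal(self.samples, other.samples)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.int64)
        if self.samples.ndim != 2 or self.samples.shape[1] != 6:
            raise SyncFormatError("each sample needs exactly 6 count fields")
        if self.pos < 1:
            raise SyncFormatError("position must be >= 1")
        if np.any(self.samples < 0):
            raise SyncFormatError("counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


@dataclass
class MaskSet:
    """Genomic intervals to exclude, BED-style 0-based half-open."""

    intervals: dict = field(default_factory=dict)  # chrom -> list[(start, end)]

    def __post_init__(self):
        self.intervals = {c: self._merge(iv) for c, iv in self.intervals.items()}

    @staticmethod
    def _merge(intervals):
        merged = []
        for start, end in sorted(intervals):
            if start >= end:
                raise ValueError(f"invalid interval [{start}, {end})")
            if merged and start <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], end))
            else:
                merged.append((start, end))
        return merged

    @classmethod
    def from_bed(cls, path) -> "MaskSet":
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                         names=["chrom", "start", "end"], comment="#")
        intervals: dict = {}
        for chrom, grp in df.groupby("chrom"):
            intervals[str(chrom)] = list(zip(grp["start"].astype(int), grp["end"].astype(int)))
        return cls(intervals)

    def covers(self, chrom: str, pos: int, flank: int = 0) -> bool:
        """Is the 1-based position inside any interval expanded by flank?"""
        zero = pos - 1
        for start, end in self.intervals.get(chrom, ()):
            if start - flank <= zero < end + flank:
                return True
        return False


def _parse_line(line: str, lineno: int, expected_samples: Optional[int]) -> SyncRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 4:
        raise SyncFormatError(f"line {lineno}: expected at least 4 columns, got {len(fields)}")
    chrom, pos_s, ref = fields[0], fields[1], fields[2]
    try:
        pos = int(pos_s)
    except ValueError:
        raise SyncFormatError(f"line {lineno}: non-integer position {pos_s!r}") from None
    counts = []
    for sample in fields[3:]:
        parts = sample.split(":")
        if len(parts) != 6:
            raise SyncFormatError(f"line {lineno}: sample {sample!r} has {len(parts)} count fields, expected 6")
        try:
            counts.append([int(p) for p in parts])
        except ValueError:
            raise SyncFormatError(f"line {lineno}: non-integer count in {sample!r}") from None
    if expected_samples is not None and len(counts) != expected_samples:
        raise SyncFormatError(
            f"line {lineno}: {len(counts)} samples, expected {expected_samples}")
    try:
        return SyncRecord(chrom, pos, ref, np.array(counts, dtype=np.int64))
    except SyncFormatError as exc:
        raise SyncFormatError(f"line {lineno}: {exc}") from None


def read_sync(source) -> list[SyncRecord]:
    """Parse a sync file (path, file object, or iterable of lines).

    All records must carry the same number of samples; malformed lines raise
    SyncFormatError naming the line number.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_sync(fh)
    records: list[SyncRecord] = []
    expected = None
    for lineno, line in enumerate(source, start=1):
        if not line.strip():
            continue
        rec = _parse_line(line, lineno, expected)
        expected = rec.n_samples
        records.append(rec)
    return records


def write_sync(records: Iterable[SyncRecord], sink=None) -> Optional[str]:
    """Write records as sync text; round-trips with read_sync.

    With sink=None the text is returned; otherwise sink is a path or a file
    object.
    """
    if sink is None:
        buf = io.StringIO()
        write_sync(records, buf)
        return buf.getvalue()
    if isinstance(sink, (str, Path)):
        with open(sink, "w") as fh:
            write_sync(records, fh)
        return None
    for rec in records:
        cols = [":".join(str(c) for c in row) for row in rec.samples]
        sink.write("\t".join([rec.chrom, str(rec.pos), rec.ref, *cols]) + "\n")
    return None


def apply_masks(records: Sequence[SyncRecord], masks: MaskSet, flank: int = 5) -> list[SyncRecord]:
    """Drop records inside mask intervals expanded by `flank` bp each side
    (e.g. regions flanking indels).  Counts are never altered."""
    kept = [r for r in records if not masks.covers(r.chrom, r.pos, flank)]
    removed = len(records) - len(kept)
    if removed:
        log.info("apply_masks: removed %d of %d records", removed, len(records))
    return kept


def call_snps(records: Sequence[SyncRecord], min_count: int = 5):
    """Restrict to biallelic polymorphic sites.

    A site is kept iff, summing counts over all samples, exactly two
    nucleotide alleles (A/T/C/G; N and deletions ignored) reach min_count.
    Sites with three or more such alleles are dropped as multi-allelic.

    Returns (kept_records, allele_pairs) where allele_pairs[i] is the
    (major, minor) base pair of kept record i.
    """
    kept, alleles = [], []
    n_multi = 0
    for rec in records:
        totals = rec.samples[:, :4].sum(axis=0)
        passing = np.flatnonzero(totals >= min_count)
        if len(passing) == 2:
            order = passing[np.argsort(-totals[passing], kind="stable")]
            kept.append(rec)
            alleles.append((NUCLEOTIDES[order[0]], NUCLEOTIDES[order[1]]))
        elif len(passing) > 2:
            n_multi += 1
    if n_multi:
        log.info("call_snps: dropped %d multi-allelic sites", n_multi)
    return kept, alleles


def frequencies(records: Sequence[SyncRecord], allele_per_site: Sequence[str]):
    """Frequency of the given allele at each site and sample.

    The denominator is the total A+T+C+G count (N and deletions excluded).
    Zero-depth cells become NaN.  Returns (freqs, depths) as
    (n_sites, n_samples) arrays.
    """
    if len(records) != len(allele_per_site):
        raise ValueError("one allele per record required")
    if not records:
        return np.empty((0, 0)), np.empty((0, 0), dtype=np.int64)
    n_samples = records[0].n_samples
    freqs = np.full((len(records), n_samples), np.nan)
    depths = np.zeros((len(records), n_samples), dtype=np.int64)
    for i, (rec, allele) in enumerate(zip(records, allele_per_site)):
        if allele not in _NUC_INDEX:
            raise ValueError(f"allele must be one of A/T/C/G, got {allele!r}")
        nuc = rec.samples[:, :4]
        total = nuc.sum(axis=1)
        depths[i] = total
        ok = total > 0
        freqs[i, ok] = nuc[ok, _NUC_INDEX[allele]] / total[ok]
    return freqs, depths


def records_frame(records: Sequence[SyncRecord], allele_pairs: Sequence[tuple]) -> pd.DataFrame:
    """Site index (chrom, pos, major, minor) as a DataFrame."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "major": [a for a, _ in allele_pairs],
            "minor": [b for _, b in allele_pairs],
        }
    )
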
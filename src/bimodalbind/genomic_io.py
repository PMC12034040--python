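"""Genome/peak IO and interval arithmetic.

Coordinates are BED-style throughout: 0-based, half-open ``[start, end)``.
A peak's center is ``floor((start + end) / 2)``.  All sequence statistics in
this package operate on fixed-width windows (default 100 bp) centered on
peaks; peaks whose interval is shorter than the window, or whose window
would run off the chromosome, are dropped rather than clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

VALID_BASES = frozenset("ACGTN")

__all__ = [
    "Genome",
    "Peak",
    "PeakSet",
    "BackgroundSet",
    "read_genome",
    "write_genome",
    "read_peaks",
    "write_bed",
    "centered_sequence",
    "gc_content",
    "flanking_background",
    "accessibility_matched_background",
    "deduplicate_across_stages",
    "nearest_peak_distance",
]


@dataclass
class Genome:
    """In-memory genome: chromosome name -> uppercase sequence over ACGTN."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for chromosome {name!r}")

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def chrom_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])


@dataclass(frozen=True)
class Peak:
    """A genomic interval with a binding intensity (BED score)."""

    chrom: str
    start: int
    end: int
    intensity: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Peak") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class PeakSet:
    """Ordered collection of peaks for one TF at one developmental stage."""

    tf_name: str
    stage: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.tf_name or not self.stage:
            raise ValueError("tf_name and stage must be non-empty")
        self.peaks = sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i):
        return self.peaks[i]

    def by_chrom(self) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = {}
        for p in self.peaks:
            out.setdefault(p.chrom, []).append(p)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [p.chrom for p in self.peaks],
                "start": [p.start for p in self.peaks],
                "end": [p.end for p in self.peaks],
                "name": [p.name for p in self.peaks],
                "intensity": [p.intensity for p in self.peaks],
            }
        )


@dataclass
class BackgroundSet:
    """Fixed-width control regions; provenance is 'flanking' or 'accessibility-matched'."""

    regions: list[Peak]
    provenance: str

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.regions)


def read_genome(path: str | Path) -> Genome:
    """Load a FASTA file into memory, uppercasing and validating the alphabet."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fa = Fasta(str(path), read_ahead=10_000_000, rebuild=True)
    sequences: dict[str, str] = {}
    for name in fa.keys():
        seq = str(fa[name][:]).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"record {name!r} contains invalid characters {sorted(bad)}; "
                "alphabet is A,C,G,T,N"
            )
        sequences[name] = seq
    if not sequences:
        raise ValueError(f"no FASTA records in {path}")
    return Genome(sequences)


def write_genome(genome: Genome, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_peaks(
    path: str | Path,
    tf: str = "TF",
    stage: str = "ESC",
    score_column: int | None = None,
) -> PeakSet:
    """Read a BED3/BED5 file into a PeakSet.

    The score (intensity) is taken from BED column 5 when present; column 4 is
    the name.  ``score_column=3`` handles the 4-column dialect
    ``chrom start end score``.  Records with ``start >= end`` are rejected
    with a warning.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError(f"BED file {path} has fewer than 3 columns")
    peaks = []
    for row in df.itertuples(index=False):
        chrom, start, end = str(row[0]), int(row[1]), int(row[2])
        if start >= end:
            warnings.warn(f"rejecting record with start >= end: {chrom}:{start}-{end}")
            continue
        if score_column is not None:
            intensity = float(row[score_column]) if df.shape[1] > score_column else 0.0
            name = "."
        else:
            name = str(row[3]) if df.shape[1] > 3 else "."
            intensity = float(row[4]) if df.shape[1] > 4 else 0.0
        peaks.append(Peak(chrom, start, end, intensity=intensity, name=name))
    return PeakSet(tf_name=tf, stage=stage, peaks=peaks)


def write_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks as 5-column BED (tab separated, no header)."""
    with open(path, "w") as fh:
        for p in peaks:
            score = repr(p.intensity) if p.intensity == int(p.intensity) else repr(p.intensity)
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.intensity:g}\n")


def centered_sequence(
    peak: Peak, genome: Genome, width: int = 100
) -> str | None:
    """Window of ``width`` bp centered on the peak, or None.

    Returns None when the peak is shorter than ``width`` or the window would
    leave the chromosome (short peaks are omitted, never clipped).
    """
    if width < 2 or width % 2:
        raise ValueError("width must be even and >= 2")
    if peak.chrom not in genome:
        raise KeyError(f"chromosome {peak.chrom!r} absent from genome")
    if peak.length < width:
        return None
    lo = peak.center - width // 2
    hi = lo + width
    if lo < 0 or hi > genome.chrom_length(peak.chrom):
        return None
    return genome[peak.chrom][lo:hi]


def gc_content(seq: str) -> float | None:
    """GC fraction over non-N positions; None if every position is N."""
    if not seq:
        raise ValueError("empty sequence")
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        return None
    return gc / (gc + at)


def _overlaps_any(start: int, end: int, peaks: Sequence[Peak]) -> bool:
    # peaks pre-filtered to one chromosome, sorted by start
    starts = np.fromiter((p.start for p in peaks), dtype=np.int64, count=len(peaks))
    ends = np.fromiter((p.end for p in peaks), dtype=np.int64, count=len(peaks))
    return bool(np.any((starts < end) & (ends > start)))


def flanking_background(
    peaks: PeakSet,
    genome: Genome,
    width: int = 100,
    gap: int = 100,
    exclude: PeakSet | None = None,
) -> BackgroundSet:
    """Control windows flanking each peak.

    For every peak two candidates are formed, ``[start - gap - width, start - gap)``
    and ``[end + gap, end + gap + width)``; a candidate survives if it lies
    entirely inside its chromosome and overlaps no peak of ``exclude``
    (default: the source set itself).
    """
    by_chrom = (exclude if exclude is not None else peaks).by_chrom()
    regions: list[Peak] = []
    for p in peaks:
        chrom_peaks = by_chrom.get(p.chrom, [])
        clen = genome.chrom_length(p.chrom) if p.chrom in genome else None
        for lo, hi in (
            (p.start - gap - width, p.start - gap),
            (p.end + gap, p.end + gap + width),
        ):
            if lo < 0 or clen is None or hi > clen:
                continue
            if _overlaps_any(lo, hi, chrom_peaks):
                continue
            regions.append(Peak(p.chrom, lo, hi, intensity=0.0, name=f"bg_{p.name}"))
    return BackgroundSet(regions=regions, provenance="flanking")


def accessibility_matched_background(
    atac: PeakSet,
    chip: PeakSet,
    genome: Genome,
    gc_lo: float = 0.4,
    gc_hi: float = 0.6,
    width: int = 100,
) -> tuple[BackgroundSet, BackgroundSet]:
    """Open-chromatin controls GC-matched to the two ChIP strata.

    Returns (low-GC stratum, high-GC stratum): 100-bp centers of accessible
    regions with window GC < gc_lo (resp. > gc_hi), excluding any region
    overlapping a ChIP peak.
    """
    chip_by_chrom = chip.by_chrom()
    low: list[Peak] = []
    high: list[Peak] = []
    for p in atac:
        seq = centered_sequence(p, genome, width=width)
        if seq is None:
            continue
        gc = gc_content(seq)
        if gc is None:
            continue
        lo = p.center - width // 2
        hi = lo + width
        if p.chrom in chip_by_chrom and _overlaps_any(p.start, p.end, chip_by_chrom[p.chrom]):
            continue
        window = Peak(p.chrom, lo, hi, intensity=0.0, name=f"atac_{p.name}")
        if gc < gc_lo:
            low.append(window)
        elif gc > gc_hi:
            high.append(window)
    if not low or not high:
        warnings.warn("accessibility-matched background stratum is empty")
    return (
        BackgroundSet(low, provenance="accessibility-matched"),
        BackgroundSet(high, provenance="accessibility-matched"),
    )


def deduplicate_across_stages(peaksets: Sequence[PeakSet]) -> PeakSet:
    """Merge one TF's peaks across stages, resolving overlaps.

    Within any chain of mutually overlapping peaks only the peak with the
    leftmost start (ties: smallest end) is kept.
    """
    if not peaksets:
        raise ValueError("no peak sets given")
    tf = peaksets[0].tf_name
    all_peaks = sorted(
        (p for ps in peaksets for p in ps), key=lambda p: (p.chrom, p.start, p.end)
    )
    kept: list[Peak] = []
    # sweep: group peaks into overlap chains (transitive closure on intervals)
    chain: list[Peak] = []
    chain_end = -1
    chain_chrom = None

    def flush() -> None:
        if chain:
            kept.append(min(chain, key=lambda p: (p.start, p.end)))

    for p in all_peaks:
        if chain_chrom == p.chrom and p.start < chain_end:
            chain.append(p)
            chain_end = max(chain_end, p.end)
        else:
            flush()
            chain = [p]
            chain_chrom = p.chrom
            chain_end = p.end
    flush()
    return PeakSet(tf_name=tf, stage="pooled", peaks=kept)


def nearest_peak_distance(a: PeakSet, b: PeakSet) -> list[float | None]:
    """Per peak of ``a``: center-to-center distance to the nearest peak of ``b``.

    Restricted to the same chromosome; None where ``b`` has no peak on that
    chromosome.
    """
    if len(b) == 0:
        raise ValueError("b must be non-empty")
    b_centers = {
        chrom: np.array(sorted(p.center for p in plist))
        for chrom, plist in b.by_chrom().items()
    }
    out: list[float | None] = []
    for p in a:
        centers = b_centers.get(p.chrom)
        if centers is None:
            out.append(None)
            continue
        i = np.searchsorted(centers, p.center)
        cands = []
        if i < len(centers):
            cands.append(abs(int(centers[i]) - p.center))
        if i > 0:
            cands.append(abs(int(centers[i - 1]) - p.center))
        out.append(float(min(cands)))
    return out
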
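"""Synthetic genomes, peaks, methylation and expression tables.

The generator produces data with the statistical structure the analysis
modules assume, so the whole pipeline can run and be validated without any
external download:

* a background genome of i.i.d. bases at a set GC level, with smooth GC
  bumps centered on TSS positions (promoters are GC-rich);
* binding peaks drawn from a two-mode GC mixture (bimodal peak GC), where
  the low-GC mode carries a planted consensus motif on a random strand and
  poly(A)/poly(T) tracts, and the high-GC mode carries periodic [CNNNNNC]
  repeats but no motif — the generative counterpart of consensus binding in
  GC-poor regions and nonconsensus binding in GC-rich regions;
* peak intensities affine in the local window GC plus truncated Gaussian
  noise, so intensity tracks GC around TSSs;
* CpG methylation with exponential unmethylated valleys at peak centers;
* a two-stage expression table with a configurable Myc ratio and constant
  Smad level.

Everything is deterministic given ``SyntheticSpec.seed``; per-chromosome
and per-peak RNG streams are spawned from it so outputs are order-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genomic_io import Genome, Peak, PeakSet
from .tss_profiles import MethylationTrack

__all__ = [
    "PeakMode",
    "SyntheticSpec",
    "generate_genome",
    "generate_peaks",
    "generate_methylation",
    "generate_expression_table",
    "generate_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PeakMode:
    """One component of the peak GC mixture."""

    weight: float
    gc_mean: float
    gc_sd: float
    motif: str | None = None
    motif_prob: float = 0.0
    str_pattern: str | None = None  # None | "poly_A" | "periodic_C6"
    str_strength: int = 0  # number of planted tract/repeat instances


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters; defaults give a 2-Mb, 2000-peak study."""

    seed: int = 0
    n_chromosomes: int = 1
    chrom_length: int = 2_000_000
    background_gc: float = 0.40
    peak_modes: tuple[PeakMode, ...] = (
        PeakMode(weight=0.5, gc_mean=0.30, gc_sd=0.05,
                 motif="GGATTA", motif_prob=0.8,
                 str_pattern="poly_A", str_strength=3),
        PeakMode(weight=0.5, gc_mean=0.72, gc_sd=0.05,
                 motif=None, motif_prob=0.0,
                 str_pattern="periodic_C6", str_strength=2),
    )
    n_peaks: int = 2000
    peak_length: int = 200
    n_tss: int = 500
    tss_gc_bump_amplitude: float = 0.25
    tss_gc_bump_half_width: float = 300.0
    tss_assoc_prob: float = 0.3  # fraction of peaks placed near a TSS
    intensity_gc_slope: float = 10.0
    intensity_noise_sd: float = 1.0
    methylation_baseline: float = 0.8
    methylation_valley_depth: float = 0.6
    methylation_valley_halfwidth: float = 500.0
    cpg_rate: float = 0.5
    myc_expression_ratio: float = 4.0

    def __post_init__(self) -> None:
        if abs(sum(m.weight for m in self.peak_modes) - 1.0) > 1e-9:
            raise ValueError("mode weights must sum to 1")
        for m in self.peak_modes:
            if not 0 <= m.gc_mean <= 1 or not 0 <= m.motif_prob <= 1:
                raise ValueError("fractions must lie in [0, 1]")
            if m.motif is not None and len(m.motif) > self.peak_length:
                raise ValueError("motif longer than peak")
        if not 0 <= self.cpg_rate <= 1:
            raise ValueError("cpg_rate must lie in [0, 1]")


def _chrom_name(i: int) -> str:
    return f"chr{i + 1}"


def _draw_bases(rng: np.random.Generator, p_gc: np.ndarray) -> np.ndarray:
    """uint8 base array with P(G or C) = p_gc, strands symmetric."""
    n = len(p_gc)
    is_gc = rng.random(n) < p_gc
    pick = rng.integers(0, 2, n)
    out = np.empty(n, dtype=np.uint8)
    out[~is_gc] = np.where(pick[~is_gc] == 0, ord("A"), ord("T"))
    out[is_gc] = np.where(pick[is_gc] == 0, ord("C"), ord("G"))
    return out


def _tss_positions(spec: SyntheticSpec, rng: np.random.Generator, clen: int, n: int) -> np.ndarray:
    """Roughly evenly spaced TSSs with jitter, clear of the chromosome ends."""
    margin = 10_000
    anchors = np.linspace(margin, clen - margin, n)
    jitter = rng.integers(-2000, 2001, n)
    return np.sort(np.clip(anchors.astype(np.int64) + jitter, margin, clen - margin))


def generate_genome(spec: SyntheticSpec) -> tuple[Genome, PeakSet]:
    """Background genome plus TSS annotation.

    The per-position GC probability is the background level plus a Gaussian
    bump of the stated amplitude and half-width at every TSS.
    """
    root = np.random.SeedSequence(spec.seed)
    chrom_streams = root.spawn(spec.n_chromosomes)
    per_chrom = np.full(spec.n_chromosomes, spec.n_tss // spec.n_chromosomes)
    per_chrom[: spec.n_tss % spec.n_chromosomes] += 1

    sequences: dict[str, str] = {}
    tss_peaks: list[Peak] = []
    for ci in range(spec.n_chromosomes):
        rng = np.random.default_rng(chrom_streams[ci])
        clen = spec.chrom_length
        tss = _tss_positions(spec, rng, clen, int(per_chrom[ci]))
        p_gc = np.full(clen, spec.background_gc)
        hw = spec.tss_gc_bump_half_width
        reach = int(4 * hw)
        offs = np.arange(-reach, reach + 1)
        bump = spec.tss_gc_bump_amplitude * np.exp(-0.5 * (offs / hw) ** 2)
        for t in tss:
            lo, hi = t - reach, t + reach + 1
            p_gc[max(lo, 0) : min(hi, clen)] += bump[max(0, -lo) : len(offs) - max(0, hi - clen)]
        np.clip(p_gc, 0.02, 0.98, out=p_gc)
        seq = _draw_bases(rng, p_gc)
        name = _chrom_name(ci)
        sequences[name] = seq.tobytes().decode("ascii")
        tss_peaks.extend(
            Peak(name, int(t), int(t) + 1, name=f"tss_{name}_{j}") for j, t in enumerate(tss)
        )
    return Genome(sequences), PeakSet("TSS", "annotation", tss_peaks)


def _plant_polya(window: np.ndarray, rng: np.random.Generator, n_runs: int) -> None:
    for _ in range(n_runs):
        run = int(rng.integers(5, 9))
        start = int(rng.integers(0, len(window) - run + 1))
        base = ord("A") if rng.random() < 0.5 else ord("T")
        window[start : start + run] = base


def _plant_periodic_c6(window: np.ndarray, rng: np.random.Generator, n_stretches: int) -> None:
    stretch = 30
    for _ in range(n_stretches):
        start = int(rng.integers(0, len(window) - stretch + 1))
        base = ord("C") if rng.random() < 0.5 else ord("G")
        window[start : start + stretch : 6] = base


_COMP = {ord("A"): ord("T"), ord("T"): ord("A"), ord("C"): ord("G"), ord("G"): ord("C")}


def _plant_motif(window: np.ndarray, motif: str, rng: np.random.Generator) -> None:
    m = np.frombuffer(motif.encode("ascii"), dtype=np.uint8)
    if rng.random() < 0.5:  # reverse strand
        m = np.array([_COMP[b] for b in m[::-1]], dtype=np.uint8)
    start = int(rng.integers(0, len(window) - len(m) + 1))
    window[start : start + len(m)] = m


def generate_peaks(
    spec: SyntheticSpec, genome: Genome, tss: PeakSet | None = None
) -> tuple[PeakSet, Genome]:
    """Draw peaks from the GC mixture and rewrite their sequence in place.

    Returns the peak set and a new Genome with the peak windows rewritten.
    Each peak's bases are resampled to its mode's GC target; the motif and
    repeat patterns are planted afterwards inside the central 100-bp window
    (on a random strand), so GC signal and motif signal stay decoupled.
    Intensity = gc_slope * (100-bp window GC) + truncated Gaussian noise.
    """
    root = np.random.SeedSequence(spec.seed + 1_000_003)
    rng = np.random.default_rng(root)
    arrays = {
        name: np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        for name, seq in genome.sequences.items()
    }
    chrom_names = sorted(arrays)
    tss_by_chrom: dict[str, np.ndarray] = {}
    if tss is not None:
        for chrom, plist in tss.by_chrom().items():
            tss_by_chrom[chrom] = np.array([p.center for p in plist])

    weights = np.array([m.weight for m in spec.peak_modes])
    L = spec.peak_length
    placed: dict[str, list[tuple[int, int]]] = {name: [] for name in chrom_names}
    peaks: list[Peak] = []
    attempts_cap = 200 * spec.n_peaks
    attempts = 0
    while len(peaks) < spec.n_peaks:
        attempts += 1
        if attempts > attempts_cap:
            raise RuntimeError("could not place peaks without collisions")
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        clen = len(arrays[chrom])
        near_tss = (
            spec.tss_assoc_prob > 0
            and chrom in tss_by_chrom
            and rng.random() < spec.tss_assoc_prob
        )
        if near_tss:
            t = int(rng.choice(tss_by_chrom[chrom]))
            center = t + int(rng.integers(-500, 501))
            start = center - L // 2
        else:
            start = int(rng.integers(200, clen - L - 200))
        end = start + L
        if start < 200 or end > clen - 200:
            continue
        if any(s < end + 200 and start < e + 200 for s, e in placed[chrom]):
            continue  # keep peaks and their flanks disjoint
        mode_idx = int(rng.choice(len(weights), p=weights))
        mode = spec.peak_modes[mode_idx]
        gc_target = float(np.clip(rng.normal(mode.gc_mean, mode.gc_sd), 0.02, 0.98))
        window = _draw_bases(rng, np.full(L, gc_target))
        core_lo = L // 2 - 50
        core = window[core_lo : core_lo + 100]
        if mode.str_pattern == "poly_A" and mode.str_strength:
            _plant_polya(core, rng, mode.str_strength)
        elif mode.str_pattern == "periodic_C6" and mode.str_strength:
            _plant_periodic_c6(core, rng, mode.str_strength)
        if mode.motif is not None and rng.random() < mode.motif_prob:
            _plant_motif(core, mode.motif, rng)
        arrays[chrom][start:end] = window
        wgc = (core == ord("G")).sum() + (core == ord("C")).sum()
        gc_frac = wgc / 100.0
        intensity = max(
            0.0, spec.intensity_gc_slope * gc_frac + rng.normal(0.0, spec.intensity_noise_sd)
        )
        placed[chrom].append((start, end))
        peaks.append(
            Peak(chrom, start, end, intensity=intensity, name=f"peak_{len(peaks)}")
        )
    new_genome = Genome(
        {name: arr.tobytes().decode("ascii") for name, arr in arrays.items()}
    )
    return PeakSet("synthTF", "ESC", peaks), new_genome


def generate_methylation(
    spec: SyntheticSpec, genome: Genome, peaks: PeakSet
) -> MethylationTrack:
    """CpG methylation with unmethylated valleys at peak centers.

    CpG sites are the genome's CG dinucleotides, each retained with
    probability ``cpg_rate``; a site's methylation is
    baseline - valley_depth * exp(-|d| / valley_halfwidth) where d is the
    distance to the nearest peak center, clipped to [0, 1].
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed + 2_000_003))
    centers_by_chrom = {
        chrom: np.array(sorted(p.center for p in plist))
        for chrom, plist in peaks.by_chrom().items()
    }
    records: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, seq in genome.sequences.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        cg = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
        if spec.cpg_rate < 1.0:
            cg = cg[rng.random(len(cg)) < spec.cpg_rate]
        if len(cg) == 0:
            continue
        centers = centers_by_chrom.get(chrom)
        if centers is None or len(centers) == 0:
            dist = np.full(len(cg), np.inf)
        else:
            i = np.searchsorted(centers, cg)
            left = np.abs(cg - centers[np.clip(i - 1, 0, len(centers) - 1)])
            right = np.abs(centers[np.clip(i, 0, len(centers) - 1)] - cg)
            dist = np.minimum(left, right)
        meth = np.clip(
            spec.methylation_baseline
            - spec.methylation_valley_depth * np.exp(-dist / spec.methylation_valley_halfwidth),
            0.0,
            1.0,
        )
        records[chrom] = (cg.astype(np.int64), meth)
    return MethylationTrack(records)


def generate_expression_table(spec: SyntheticSpec) -> pd.DataFrame:
    """Two-stage expression table: Myc at the stated ESC/dEN ratio, Smad constant."""
    r = spec.myc_expression_ratio
    return pd.DataFrame(
        [
            {"gene": "MYC", "stage": "ESC", "level": r},
            {"gene": "MYC", "stage": "dEN", "level": 1.0},
            {"gene": "SMAD1", "stage": "ESC", "level": 1.0},
            {"gene": "SMAD1", "stage": "dEN", "level": 1.0},
        ]
    )


def generate_dataset(spec: SyntheticSpec) -> dict:
    """Run the full generator: genome, TSS, peaks (genome rewritten),
    methylation and expression."""
    genome, tss = generate_genome(spec)
    peaks, genome = generate_peaks(spec, genome, tss)
    methylation = generate_methylation(spec, genome, peaks)
    return {
        "genome": genome,
        "tss": tss,
        "peaks": peaks,
        "methylation": methylation,
        "expression": generate_expression_table(spec),
    }
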
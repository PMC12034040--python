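"""Peak-over-background statistical binding-energy model.

For each k-mer ``s`` the binding energy (in units of k_B·T) is

    U_k(s) = -ln( (<N_k(s)>_peak + 1) / (<N_k(s)>_background + 1) )

where ``<N_k(s)>`` is the mean number of occurrences of ``s`` *or its reverse
complement* per 100-bp sequence (palindromes counted once).  A 100-bp test
sequence is scored by its free energy

    F_k = -ln sum_i exp(-U_k(s_i)),   i = 1 .. L-k+1,

lower F meaning more peak-like.  ROC AUC of F over held-out peaks versus
backgrounds measures predictive power; the k-mer specificity statistic

    dAUC = max_k AUC(k) - AUC(1)

subtracts the GC-content-only baseline (k = 1), isolating genuine k-mer
recognition from composition.

Counting is strand-symmetric and vectorized: sequences are encoded base-4,
window codes folded to canonical (lexicographic min of a k-mer and its
reverse complement) through a precomputed table, and tallied with bincount.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_curve
from sklearn.utils.validation import check_is_fitted

from .genomic_io import (
    BackgroundSet,
    Genome,
    PeakSet,
    centered_sequence,
    flanking_background,
    gc_content,
)

__all__ = [
    "canonical_kmer",
    "revcomp",
    "mean_kmer_counts",
    "KmerEnergyTable",
    "fit_energy_table",
    "free_energy",
    "free_energies",
    "KmerEnergyClassifier",
    "split_train_test",
    "RocResult",
    "roc_auc",
    "delta_auc",
    "SpecificitySummary",
    "stratified_specificity",
    "write_energy_table",
    "read_energy_table",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def canonical_kmer(s: str) -> str | None:
    """Lexicographic min of a k-mer and its reverse complement; None if ambiguous."""
    if set(s) - set("ACGT"):
        return None
    return min(s, revcomp(s))


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@lru_cache(maxsize=None)
def _powers(k: int) -> np.ndarray:
    return 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)


@lru_cache(maxsize=None)
def _canonical_map(k: int) -> np.ndarray:
    """code -> canonical code for all 4**k k-mers."""
    codes = np.arange(4**k, dtype=np.int64)
    digits = (codes[:, None] // _powers(k)) % 4  # (4^k, k), most-significant first
    rc = ((3 - digits[:, ::-1]) * _powers(k)).sum(axis=1)
    return np.minimum(codes, rc)


def _code_to_kmer(code: int, k: int) -> str:
    return "".join("ACGT"[(code // p) % 4] for p in _powers(k))


def _kmer_to_code(s: str) -> int:
    return int(_encode(s) @ _powers(len(s)))


def _window_codes(seq: str, k: int) -> np.ndarray:
    """Base-4 codes of all k-windows; -1 where a window contains N."""
    vals = _encode(seq)
    if len(vals) < k:
        return np.empty(0, dtype=np.int64)
    sw = sliding_window_view(vals, k).astype(np.int64)
    codes = sw @ _powers(k)
    codes[(sw < 0).any(axis=1)] = -1
    return codes


def _canonical_count_vector(seqs: Sequence[str], k: int) -> tuple[np.ndarray, int]:
    """Total counts per canonical code, summed over sequences."""
    cmap = _canonical_map(k)
    total = np.zeros(4**k, dtype=np.int64)
    for seq in seqs:
        codes = _window_codes(seq, k)
        codes = codes[codes >= 0]
        if codes.size:
            total += np.bincount(cmap[codes], minlength=4**k)
    return total, len(seqs)


def mean_kmer_counts(seqs: Sequence[str], k: int) -> dict[str, float]:
    """Mean per-sequence count of each canonical k-mer class.

    A class's count in one sequence is the number of windows matching the
    k-mer or its reverse complement; palindromic k-mers are counted once per
    matching window.  Windows containing N are skipped.
    """
    if not seqs:
        raise ValueError("empty sequence list")
    if k > max(len(s) for s in seqs):
        raise ValueError("k exceeds sequence length")
    total, n = _canonical_count_vector(seqs, k)
    cmap = _canonical_map(k)
    canon_codes = np.flatnonzero(cmap == np.arange(4**k))
    return {
        _code_to_kmer(int(c), k): total[c] / n for c in canon_codes if total[c] > 0
    }


@dataclass
class KmerEnergyTable:
    """Binding energies over the full canonical k-mer space.

    Internally array-backed (indexed by canonical base-4 code); the mapping
    view exposes kmer-string keys.  Unobserved k-mers have U = -ln(1/1) = 0
    through the +1 pseudocounts.
    """

    k: int
    n_peak_mean: np.ndarray  # per canonical code; 0.0 at non-canonical slots
    n_bg_mean: np.ndarray

    def __post_init__(self) -> None:
        self._cmap = _canonical_map(self.k)
        with np.errstate(divide="ignore"):
            self._energy = -np.log((self.n_peak_mean + 1.0) / (self.n_bg_mean + 1.0))
        # fast scoring path: raw window code -> energy of its canonical class
        self._energy_by_raw_code = self._energy[self._cmap]

    @property
    def energies(self) -> dict[str, float]:
        canon = np.flatnonzero(self._cmap == np.arange(4**self.k))
        return {_code_to_kmer(int(c), self.k): float(self._energy[c]) for c in canon}

    def energy_of(self, kmer: str) -> float:
        code = _kmer_to_code(kmer)
        return float(self._energy[self._cmap[code]])

    def mean_counts_of(self, kmer: str) -> tuple[float, float]:
        c = self._cmap[_kmer_to_code(kmer)]
        return float(self.n_peak_mean[c]), float(self.n_bg_mean[c])


def fit_energy_table(
    peak_seqs: Sequence[str], bg_seqs: Sequence[str], k: int
) -> KmerEnergyTable:
    """Estimate U for every canonical k-mer from peak and background corpora."""
    if not peak_seqs or not bg_seqs:
        raise ValueError("peak and background sequence sets must be non-empty")
    peak_total, n_peak = _canonical_count_vector(peak_seqs, k)
    bg_total, n_bg = _canonical_count_vector(bg_seqs, k)
    return KmerEnergyTable(
        k=k,
        n_peak_mean=peak_total / n_peak,
        n_bg_mean=bg_total / n_bg,
    )


def free_energy(seq: str, table: KmerEnergyTable) -> float | None:
    """Log-sum-exp free energy of one sequence; None if no N-free window."""
    codes = _window_codes(seq, table.k)
    codes = codes[codes >= 0]
    if codes.size == 0:
        return None
    return float(-logsumexp(-table._energy_by_raw_code[codes]))


def free_energies(seqs: Iterable[str], table: KmerEnergyTable) -> np.ndarray:
    """Free energy per sequence (NaN where undefined)."""
    out = [free_energy(s, table) for s in seqs]
    return np.array([np.nan if f is None else f for f in out], dtype=float)


class KmerEnergyClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn estimator wrapping the k-mer energy model.

    Parameters
    ----------
    k : int
        k-mer length.

    ``fit(X, y)`` takes a list/array of equal-length DNA strings and binary
    labels (1 = peak, 0 = background).  ``decision_function`` returns -F_k,
    so larger values mean more peak-like, as sklearn expects.  ``predict``
    thresholds the decision function at the midpoint between the training
    class means.
    """

    def __init__(self, k: int = 6):
        self.k = k

    def fit(self, X, y):
        X = np.asarray(X, dtype=object)
        y = np.asarray(y)
        classes = np.unique(y)
        if not np.array_equal(classes, [0, 1]):
            raise ValueError("y must contain both classes 0 (background) and 1 (peak)")
        self.classes_ = classes
        self.table_ = fit_energy_table(
            [str(s) for s in X[y == 1]], [str(s) for s in X[y == 0]], self.k
        )
        self.energies_ = self.table_.energies
        d = self._decision(X)
        self.threshold_ = 0.5 * (np.nanmean(d[y == 1]) + np.nanmean(d[y == 0]))
        self.n_features_in_ = 1
        return self

    def _decision(self, X) -> np.ndarray:
        return -free_energies([str(s) for s in np.asarray(X, dtype=object)], self.table_)

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "table_")
        return self._decision(X)

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= self.threshold_).astype(int)


def split_train_test(
    peaks: PeakSet, train_fraction: float = 0.8, seed: int = 0
) -> tuple[PeakSet, PeakSet]:
    """Seeded uniform random partition of a PeakSet at the peak level."""
    n = len(peaks)
    if n < 10:
        raise ValueError("need at least 10 peaks to split")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    train_idx = set(idx[:n_train].tolist())
    train = [p for i, p in enumerate(peaks) if i in train_idx]
    test = [p for i, p in enumerate(peaks) if i not in train_idx]
    return (
        PeakSet(peaks.tf_name, peaks.stage, train),
        PeakSet(peaks.tf_name, peaks.stage, test),
    )


@dataclass
class RocResult:
    """ROC curve and area for free-energy classification (lower F = peak)."""

    k: int
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    n_peak: int
    n_bg: int


def roc_auc(
    peak_scores: Sequence[float], bg_scores: Sequence[float], k: int = 0
) -> RocResult:
    """ROC of free-energy scores; AUC = P(F_peak < F_bg) + 0.5·P(F_peak = F_bg).

    Thresholds sweep the pooled scores; the trapezoidal area equals the
    tie-corrected Mann-Whitney statistic.
    """
    peak_scores = np.asarray(peak_scores, dtype=float)
    bg_scores = np.asarray(bg_scores, dtype=float)
    peak_scores = peak_scores[~np.isnan(peak_scores)]
    bg_scores = bg_scores[~np.isnan(bg_scores)]
    if peak_scores.size == 0 or bg_scores.size == 0:
        raise ValueError("both score lists must be non-empty")
    y = np.concatenate([np.ones(peak_scores.size), np.zeros(bg_scores.size)])
    s = -np.concatenate([peak_scores, bg_scores])  # higher = more peak-like
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(
        k=k, auc=auc, fpr=fpr, tpr=tpr, n_peak=peak_scores.size, n_bg=bg_scores.size
    )


def delta_auc(auc_by_k: Mapping[int, float]) -> float:
    """max_k AUC(k) - AUC(1); AUC(1) is the GC-content-only baseline."""
    if 1 not in auc_by_k:
        raise ValueError("AUC for k = 1 is required")
    return max(auc_by_k.values()) - auc_by_k[1]


@dataclass
class SpecificitySummary:
    tf_name: str
    stage: str
    stratum: str  # "low-GC" | "high-GC"
    delta_auc: float
    auc_by_k: dict[int, float]
    n_peaks: int
    n_bg: int


def _window_seqs(regions: Iterable, genome: Genome, width: int) -> list[str]:
    out = []
    for r in regions:
        seq = centered_sequence(r, genome, width=width)
        if seq is not None:
            out.append(seq)
    return out


def stratified_specificity(
    peaks: PeakSet,
    genome: Genome,
    background_mode: str = "flanking",
    atac: PeakSet | None = None,
    gc_low: float = 0.4,
    gc_high: float = 0.6,
    min_peaks: int = 1000,
    k_range: Sequence[int] = tuple(range(1, 9)),
    train_fraction: float = 0.8,
    width: int = 100,
    seed: int = 0,
) -> list[SpecificitySummary]:
    """dAUC in GC-poor and GC-rich peak strata, each processed independently.

    Peaks are stratified on the GC of their 100-bp centered window
    (GC < gc_low vs GC > gc_high, open intervals); each stratum gets its own
    backgrounds, train/test split, energy tables and ROC.  Strata with fewer
    than ``min_peaks`` peaks are omitted.
    """
    if 1 not in k_range:
        raise ValueError("k_range must include 1 (GC-only baseline)")
    if background_mode not in ("flanking", "atac"):
        raise ValueError(f"unknown background_mode {background_mode!r}")
    if background_mode == "atac":
        if atac is None:
            raise ValueError("atac PeakSet required for background_mode='atac'")
        from .genomic_io import accessibility_matched_background

        atac_low, atac_high = accessibility_matched_background(
            atac, peaks, genome, gc_lo=gc_low, gc_hi=gc_high, width=width
        )

    strata: dict[str, list] = {"low-GC": [], "high-GC": []}
    for p in peaks:
        seq = centered_sequence(p, genome, width=width)
        if seq is None:
            continue
        gc = gc_content(seq)
        if gc is None:
            continue
        if gc < gc_low:
            strata["low-GC"].append(p)
        elif gc > gc_high:
            strata["high-GC"].append(p)

    results: list[SpecificitySummary] = []
    for stratum_name, stratum_peaks in strata.items():
        if len(stratum_peaks) < min_peaks:
            continue
        sub = PeakSet(peaks.tf_name, peaks.stage, stratum_peaks)
        train_ps, test_ps = split_train_test(sub, train_fraction, seed)
        if background_mode == "flanking":
            # background windows follow their source peak's split side;
            # overlap exclusion is against the full peak set
            train_bg = flanking_background(train_ps, genome, width=width, exclude=peaks)
            test_bg = flanking_background(test_ps, genome, width=width, exclude=peaks)
            train_bg_seqs = _window_seqs(train_bg, genome, width)
            test_bg_seqs = _window_seqs(test_bg, genome, width)
        else:
            bg_set = atac_low if stratum_name == "low-GC" else atac_high
            bg_seqs = _window_seqs(bg_set, genome, width)
            rng = np.random.default_rng(seed)
            idx = rng.permutation(len(bg_seqs))
            n_train = int(round(train_fraction * len(bg_seqs)))
            train_bg_seqs = [bg_seqs[i] for i in idx[:n_train]]
            test_bg_seqs = [bg_seqs[i] for i in idx[n_train:]]

        train_peak_seqs = _window_seqs(train_ps, genome, width)
        test_peak_seqs = _window_seqs(test_ps, genome, width)
        if not train_bg_seqs or not test_bg_seqs:
            warnings.warn(f"no background sequences for stratum {stratum_name}")
            continue

        auc_by_k: dict[int, float] = {}
        for k in k_range:
            table = fit_energy_table(train_peak_seqs, train_bg_seqs, k)
            f_peak = free_energies(test_peak_seqs, table)
            f_bg = free_energies(test_bg_seqs, table)
            auc_by_k[k] = roc_auc(f_peak, f_bg, k=k).auc
        results.append(
            SpecificitySummary(
                tf_name=peaks.tf_name,
                stage=peaks.stage,
                stratum=stratum_name,
                delta_auc=delta_auc(auc_by_k),
                auc_by_k=auc_by_k,
                n_peaks=len(stratum_peaks),
                n_bg=len(train_bg_seqs) + len(test_bg_seqs),
            )
        )
    return results


def write_energy_table(table: KmerEnergyTable, path: str | Path) -> None:
    """Serialize as TSV: kmer, n_peak_mean, n_bg_mean, energy (canonical k-mers only)."""
    cmap = _canonical_map(table.k)
    canon = np.flatnonzero(cmap == np.arange(4**table.k))
    df = pd.DataFrame(
        {
            "kmer": [_code_to_kmer(int(c), table.k) for c in canon],
            "n_peak_mean": table.n_peak_mean[canon],
            "n_bg_mean": table.n_bg_mean[canon],
            "energy": table._energy[canon],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_energy_table(path: str | Path) -> KmerEnergyTable:
    df = pd.read_csv(path, sep="\t")
    k = len(df["kmer"].iloc[0])
    n_peak = np.zeros(4**k)
    n_bg = np.zeros(4**k)
    for row in df.itertuples(index=False):
        code = _kmer_to_code(row.kmer)
        n_peak[code] = row.n_peak_mean
        n_bg[code] = row.n_bg_mean
    return KmerEnergyTable(k=k, n_peak_mean=n_peak, n_bg_mean=n_bg)
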
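"""ChIP-seq binding-probability analysis around motif occurrences.

For each occurrence of a motif arrangement, a fixed-flank window (default
±25 bp) is defined around the site, aligned reads overlapping the window
are counted, and per-class empirical cumulative distribution functions
(ECDFs) of the counts are compared: a curve shifted to the right means the
motif class tends to sit in regions of higher read coverage, i.e. higher
occupancy in vivo.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .motif_grammar import ArrangementSpec, scan_genome

__all__ = [
    "BindingCurve",
    "ClassComparison",
    "build_windows",
    "count_reads_in_windows",
    "ecdf_curve",
    "compare_classes",
    "run_binding_probability",
]


@dataclass(frozen=True)
class BindingCurve:
    """ECDF of per-window read counts for one motif class."""

    class_label: str
    support: np.ndarray  # sorted distinct count values
    cum_prob: np.ndarray  # cumulative relative occurrence, ends at 1
    n_windows: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class_label": self.class_label,
                "count": self.support,
                "cum_prob": self.cum_prob,
                "n_windows": self.n_windows,
            }
        )


@dataclass(frozen=True)
class ClassComparison:
    """Distribution shift between two motif classes' window counts."""

    class_a: str
    class_b: str
    median_diff: float  # median(a) - median(b)
    ranksum_stat: float
    ranksum_p: float
    ks_distance: float
    direction: str  # label of the right-shifted class, or "none"


def build_windows(
    sites: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    flank: int = 25,
) -> pd.DataFrame:
    """Fixed-flank windows around motif sites, clipped at chromosome edges.

    ``sites`` needs columns chrom, start, end, class_label. The window is
    [start - flank, end + flank) intersected with [0, chrom length).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    missing = set(sites["chrom"]) - set(chrom_sizes)
    if missing:
        raise ValueError(f"chromosomes absent from chrom_sizes: {sorted(missing)}")
    sizes = sites["chrom"].map(chrom_sizes).to_numpy()
    start = np.maximum(sites["start"].to_numpy() - flank, 0)
    end = np.minimum(sites["end"].to_numpy() + flank, sizes)
    return pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy(),
            "start": start,
            "end": end,
            "class_label": sites["class_label"].to_numpy(),
            "site_start": sites["start"].to_numpy(),
            "site_end": sites["end"].to_numpy(),
        }
    )


def count_reads_in_windows(
    windows: pd.DataFrame,
    reads: pd.DataFrame,
    min_overlap: int = 1,
) -> np.ndarray:
    """Number of reads overlapping each window by at least ``min_overlap`` bp.

    A read overlapping several windows increments each of them; windows of
    different classes are counted independently. Sorted-array bisection per
    chromosome, O((n+m) log n).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    counts = np.zeros(len(windows), dtype=np.int64)
    if len(reads) == 0 or len(windows) == 0:
        return counts
    # reads shorter than min_overlap can never satisfy the overlap criterion
    reads = reads[(reads["end"] - reads["start"]) >= min_overlap]
    wchrom = windows["chrom"].to_numpy()
    wstart = windows["start"].to_numpy()
    wend = windows["end"].to_numpy()
    for chrom, sub in reads.groupby("chrom", sort=False):
        mask = wchrom == chrom
        if not mask.any():
            continue
        rs = np.sort(sub["start"].to_numpy())
        re_ = np.sort(sub["end"].to_numpy())
        # overlap >= m  <=>  read_start <= w_end - m  and  read_end >= w_start + m
        n_start_ok = np.searchsorted(rs, wend[mask] - min_overlap, side="right")
        n_end_too_small = np.searchsorted(re_, wstart[mask] + min_overlap, side="left")
        c = n_start_ok - n_end_too_small
        # windows shorter than min_overlap cannot be overlapped by that much
        c[(wend[mask] - wstart[mask]) < min_overlap] = 0
        counts[mask] = c
    return counts


def ecdf_curve(
    counts: Sequence[int] | np.ndarray,
    class_label: str = "",
    smooth: bool = False,
) -> BindingCurve:
    """Empirical cumulative distribution of per-window read counts.

    With ``smooth=True`` the cumulative curve is replaced by the integral of
    a Gaussian kernel density over the counts, renormalized so the last
    value is exactly 1; monotonicity and endpoints are preserved. Smoothing
    is presentational only — class comparisons always use raw counts.
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("need at least one count")
    support, occ = np.unique(counts, return_counts=True)
    cum = np.cumsum(occ) / counts.size
    if smooth and support.size > 1:
        kde = stats.gaussian_kde(counts.astype(float))
        lo = float(support[0]) - 5 * np.sqrt(kde.covariance[0, 0])
        smoothed = np.array([kde.integrate_box_1d(lo, float(x)) for x in support])
        smoothed = np.maximum.accumulate(smoothed)
        if smoothed[-1] > 0:
            cum = smoothed / smoothed[-1]
    return BindingCurve(class_label, support, cum, int(counts.size))


def compare_classes(counts_by_class: Mapping[str, np.ndarray]) -> list[ClassComparison]:
    """All pairwise shift comparisons between motif classes.

    Uses the two-sided Wilcoxon rank-sum (Mann–Whitney U, tie-corrected) and
    the two-sample Kolmogorov–Smirnov distance; ``direction`` is the class
    with the larger median ("none" on a tie).
    """
    labels = sorted(counts_by_class)
    if len(labels) < 2:
        raise ValueError("need at least two classes")
    for lab in labels:
        if len(np.asarray(counts_by_class[lab])) < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 windows")
    out = []
    for a, b in itertools.combinations(labels, 2):
        xa = np.asarray(counts_by_class[a], dtype=float)
        xb = np.asarray(counts_by_class[b], dtype=float)
        med_diff = float(np.median(xa) - np.median(xb))
        if np.all(xa == xa[0]) and np.all(xb == xa[0]):
            # degenerate: identical constant samples; rank-sum tie correction
            # would divide by zero
            stat, p = len(xa) * len(xb) / 2.0, 1.0
        else:
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        ks = float(stats.ks_2samp(xa, xb).statistic)
        if med_diff > 0:
            direction = a
        elif med_diff < 0:
            direction = b
        else:
            direction = "none"
        out.append(ClassComparison(a, b, med_diff, stat, p, ks, direction))
    return out


def comparisons_to_frame(comparisons: Sequence[ClassComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.class_a, c.class_b, c.median_diff, c.ranksum_stat, c.ranksum_p, c.ks_distance, c.direction)
            for c in comparisons
        ],
        columns=["class_a", "class_b", "median_diff", "ranksum_stat", "ranksum_p", "ks_distance", "direction"],
    )


def run_binding_probability(
    genome: Mapping[str, str] | str | Path,
    reads: pd.DataFrame | str | Path,
    specs: Sequence[ArrangementSpec],
    flank: int = 25,
    min_overlap: int = 1,
    smooth: bool = False,
    out_dir: str | Path | None = None,
):
    """End-to-end binding-probability analysis.

    Composition scan → windows → counts → per-class ECDF → comparisons.
    Returns ``(curves, comparisons, counts_by_class)`` where curves is a
    dict class_label → BindingCurve. If ``out_dir`` is given, writes
    ``curves.csv`` and ``comparisons.csv`` (byte-deterministic).
    """
    from .io import read_fasta, read_intervals

    if not isinstance(genome, Mapping):
        genome = read_fasta(genome)
    if not isinstance(reads, pd.DataFrame):
        reads = read_intervals(reads)
    chrom_sizes = {name: len(seq) for name, seq in genome.items()}
    sites = scan_genome(genome, specs)
    windows = build_windows(sites, chrom_sizes, flank=flank)
    counts = count_reads_in_windows(windows, reads, min_overlap=min_overlap)
    counts_by_class = {
        lab: counts[(windows["class_label"] == lab).to_numpy()]
        for lab in sorted(windows["class_label"].unique())
    }
    curves = {lab: ecdf_curve(c, lab, smooth=smooth) for lab, c in counts_by_class.items()}
    comparable = {lab: c for lab, c in counts_by_class.items() if len(c) >= 2}
    comparisons = compare_classes(comparable) if len(comparable) >= 2 else []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.concat([c.to_frame() for _, c in sorted(curves.items())], ignore_index=True).to_csv(
            out_dir / "curves.csv", index=False
        )
        comparisons_to_frame(comparisons).to_csv(out_dir / "comparisons.csv", index=False)
    return curves, comparisons, counts_by_class
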
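"""Peak calling and construction of the merged putative-enhancer catalog.

The peak caller is a minimal local-Poisson scan: each bin is tested
against the larger of the genome-wide mean rate and a local (10 kb by
default) mean rate, significant adjacent bins are joined, and a fixed
p-value cutoff (0.001) discretizes the signal into peaks.  Putative
enhancers are regions with H3K4me1 peaks in either condition that carry
no H3K4me3 peak and lie away from annotated TSSs; peaks closer than
500 bp are merged into single catalog entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .genome import CoverageTrack, GeneModel, GenomicInterval, mean_signal


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    p_value: float
    summit: int  # bp position of the maximum bin's center


@dataclass
class PeakSet:
    peaks: list[Peak]
    p_cutoff: float
    n_significant_bins: int = 0
    n_bins_tested: int = 0

    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class EnhancerCatalog:
    """Merged putative-enhancer intervals with per-(mark, condition) signal.

    ``signal`` is indexed by enhancer id with one column per
    "<mark>_<condition>" carrying the mean RPKM over the interval.
    """

    intervals: list[GenomicInterval]
    signal: pd.DataFrame
    excluded: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def ids(self) -> list[str]:
        return [iv.name for iv in self.intervals]


def call_peaks(
    track: CoverageTrack,
    p_cutoff: float = 0.001,
    local_window: int = 10_000,
) -> PeakSet:
    """Call enriched regions with a per-bin upper-tail Poisson test.

    The background rate for each bin is max(genome-wide mean count,
    mean count in a centered ``local_window``); the local term damps
    false calls in locally dense regions.  p = P(X >= count) under
    Poisson(lambda); bins with p < p_cutoff are joined into peaks when
    adjacent.  The summit is the center of the highest-count bin.
    """
    if track.units != "raw":
        raise ValueError("call_peaks expects a raw-count track")
    peaks: list[Peak] = []
    n_sig = 0
    n_tested = 0
    window_bins = max(1, int(round(local_window / track.bin_size)))
    for chrom in track.chroms:
        counts = track.data[chrom]
        n_tested += len(counts)
        global_mean = counts.mean() if len(counts) else 0.0
        if global_mean <= 0:
            continue
        local_mean = ndimage.uniform_filter1d(
            counts.astype(float), size=window_bins, mode="nearest"
        )
        lam = np.maximum(global_mean, local_mean)
        # P(X >= k) = sf(k - 1); counts are integers >= 0
        pvals = stats.poisson.sf(counts - 1, lam)
        significant = pvals < p_cutoff
        n_sig += int(significant.sum())
        if not significant.any():
            continue
        # join runs of adjacent significant bins
        edges = np.diff(np.concatenate(([0], significant.astype(int), [0])))
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1) - 1
        bs = track.bin_size
        for b0, b1 in zip(starts, ends):
            segment = counts[b0 : b1 + 1]
            summit_bin = b0 + int(np.argmax(segment))
            peaks.append(
                Peak(
                    GenomicInterval(chrom, int(b0 * bs), int((b1 + 1) * bs)),
                    float(pvals[b0 : b1 + 1].min()),
                    int(summit_bin * bs + bs // 2),
                )
            )
    return PeakSet(peaks, p_cutoff, n_sig, n_tested)


def merge_close_peaks(
    intervals: Sequence[GenomicInterval], max_gap: int = 500
) -> list[GenomicInterval]:
    """Merge intervals whose gap (next.start − prev.end) is < ``max_gap``.

    The rule is strict: a gap of exactly ``max_gap`` keeps intervals
    separate; overlapping and bookended intervals always merge.
    Merging is transitive and the output is sorted.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end < max_gap or iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def _overlaps_any(iv: GenomicInterval, sorted_by_chrom: dict[str, np.ndarray]) -> bool:
    arr = sorted_by_chrom.get(iv.chrom)
    if arr is None or len(arr) == 0:
        return False
    starts, ends = arr[:, 0], arr[:, 1]
    i = np.searchsorted(starts, iv.end)  # candidates with start < iv.end
    return bool((ends[:i] > iv.start).any())


def _index_intervals(intervals: Sequence[GenomicInterval]) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {
        chrom: np.array(sorted(pairs), dtype=int).reshape(-1, 2)
        for chrom, pairs in by_chrom.items()
    }


def select_putative_enhancers(
    k4me1_peaks_a: Sequence[GenomicInterval],
    k4me1_peaks_b: Sequence[GenomicInterval],
    k4me3_peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    tss_exclusion: int = 2_000,
) -> list[GenomicInterval]:
    """Distal H3K4me1-marked regions: the enhancer candidate set.

    Takes the union of H3K4me1 peaks from both conditions, then drops
    any peak that overlaps an H3K4me3 peak (promoter signature) or lies
    within ``tss_exclusion`` bp of an annotated TSS.  Filtering is by
    peak presence/absence, not signal thresholds.
    """
    candidates = list(k4me1_peaks_a) + list(k4me1_peaks_b)
    k4me3_index = _index_intervals(k4me3_peaks)
    tss_windows: list[GenomicInterval] = []
    for g in genes:
        lo = max(0, g.tss - tss_exclusion)
        hi = g.tss + tss_exclusion + 1
        tss_windows.append(GenomicInterval(g.chrom, lo, hi))
    tss_index = _index_intervals(tss_windows)
    kept = [
        iv
        for iv in candidates
        if not _overlaps_any(iv, k4me3_index) and not _overlaps_any(iv, tss_index)
    ]
    return sorted(set(kept), key=lambda iv: (iv.chrom, iv.start, iv.end))


def attach_signal(
    intervals: Sequence[GenomicInterval],
    tracks: dict[tuple[str, str], CoverageTrack],
    id_prefix: str = "enh",
) -> EnhancerCatalog:
    """Annotate catalog intervals with mean signal per (mark, condition).

    ``tracks`` maps (mark, condition) to an RPKM track.  Intervals that
    fall outside a track's bounds are flagged and excluded with a
    warning rather than silently carried with missing values.
    """
    for (mark, cond), track in tracks.items():
        if track.units != "RPKM":
            raise ValueError(f"track ({mark}, {cond}) must be RPKM-normalized")
    named = [
        GenomicInterval(iv.chrom, iv.start, iv.end, iv.strand, f"{id_prefix}_{i:05d}")
        for i, iv in enumerate(sorted(intervals, key=lambda v: (v.chrom, v.start, v.end)))
    ]
    rows: dict[str, dict[str, float]] = {}
    excluded: list[str] = []
    kept: list[GenomicInterval] = []
    for iv in named:
        row: dict[str, float] = {}
        ok = True
        for (mark, cond), track in tracks.items():
            try:
                row[f"{mark}_{cond}"] = mean_signal(track, iv)
            except (KeyError, ValueError):
                ok = False
                break
        if ok:
            rows[iv.name] = row
            kept.append(iv)
        else:
            excluded.append(iv.name)
    if excluded:
        warnings.warn(
            f"{len(excluded)} catalog intervals outside track bounds were excluded"
        )
    columns = [f"{mark}_{cond}" for mark, cond in tracks]
    signal = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=columns)
    signal.index.name = "enhancer_id"
    return EnhancerCatalog(kept, signal, excluded)
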
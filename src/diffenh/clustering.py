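"""Enhancer-state clustering and aggregate signal profiles.

Each catalog enhancer is summarized by two numbers, the log2 B/A
signal ratios of H3K4me1 and H3K27ac (pseudocount-stabilized).  The
rows are partitioned by k-means and the "activated" group is the
cluster whose centroid is most confidently positive in *both* marks —
the signature of an enhancer gaining acetylation and priming in
condition B.  Metaprofiles aggregate a track around anchor points
(interval centers, TSSs, or length-scaled gene bodies).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .genome import CoverageTrack, GeneModel, GenomicInterval
from .peaks import EnhancerCatalog

RATIO_MARKS = ("H3K4me1", "H3K27ac")


@dataclass
class StateRatioMatrix:
    """Per-enhancer log2(B/A) for the two enhancer marks, plus labels."""

    values: pd.DataFrame  # columns log2_ratio_H3K4me1, log2_ratio_H3K27ac
    pseudocount: float
    labels: np.ndarray | None = None
    centroids: np.ndarray | None = None

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class Metaprofile:
    mode: str  # center_anchored | tss_anchored | gene_body_scaled
    positions: np.ndarray  # bp offsets, or scaled-bin index for gene_body mode
    mean_signal: np.ndarray
    n_anchors: int


def compute_ratio_matrix(
    catalog: EnhancerCatalog,
    condition_a: str = "A",
    condition_b: str = "B",
    pseudocount: float = 0.5,
) -> StateRatioMatrix:
    """log2((signal_B + pc) / (signal_A + pc)) per mark and enhancer.

    The pseudocount (RPKM units) keeps every entry finite; an enhancer
    with zero signal in both conditions maps to exactly 0.  Swapping
    the two conditions negates every entry.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    cols = {}
    for mark in RATIO_MARKS:
        col_a, col_b = f"{mark}_{condition_a}", f"{mark}_{condition_b}"
        if col_a not in catalog.signal or col_b not in catalog.signal:
            raise KeyError(f"catalog lacks signal for {mark} in {condition_a}/{condition_b}")
        cols[f"log2_ratio_{mark}"] = np.log2(
            (catalog.signal[col_b] + pseudocount) / (catalog.signal[col_a] + pseudocount)
        )
    values = pd.DataFrame(cols, index=catalog.signal.index)
    finite = np.isfinite(values).all(axis=1)
    if not finite.all():
        warnings.warn(f"{(~finite).sum()} rows with non-finite ratios dropped")
        values = values[finite]
    return StateRatioMatrix(values, pseudocount)


def kmeans_cluster(matrix: StateRatioMatrix, k: int = 4, seed: int = 0) -> StateRatioMatrix:
    """Partition the ratio matrix into k groups (k-means++, 10 restarts).

    Deterministic for a fixed seed.  Returns the same matrix object
    with ``labels`` and ``centroids`` filled in.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(matrix) < k:
        raise ValueError(f"need at least k={k} rows, have {len(matrix)}")
    with warnings.catch_warnings():
        # duplicate rows can make fewer than k distinct centers; that is fine
        warnings.simplefilter("ignore")
        km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
        labels = km.fit_predict(matrix.values.to_numpy())
    matrix.labels = labels
    matrix.centroids = km.cluster_centers_
    return matrix


def select_activated_group(matrix: StateRatioMatrix) -> set[str]:
    """Identifiers of the activated enhancer group.

    The activated cluster is the one whose centroid has the largest
    min(log2 ratio H3K4me1, log2 ratio H3K27ac), required positive:
    both marks must have gained signal in condition B.  If no centroid
    is positive in both marks the scenario has no activated group and
    an empty set is returned with a warning.
    """
    if matrix.labels is None or matrix.centroids is None:
        raise ValueError("run kmeans_cluster first")
    scores = matrix.centroids.min(axis=1)
    best = int(np.argmax(scores))
    if scores[best] <= 0:
        warnings.warn("no cluster centroid is positive in both marks; empty group")
        return set()
    ids = np.asarray(matrix.ids)
    return set(ids[matrix.labels == best])


# ---------------------------------------------------------------------------
# metaprofiles
# ---------------------------------------------------------------------------

def _extract_window(values: np.ndarray, center_bin: int, half_bins: int) -> np.ndarray | None:
    lo, hi = center_bin - half_bins, center_bin + half_bins + 1
    if lo < 0 or hi > len(values):
        return None
    return values[lo:hi]


def metaprofile(
    track: CoverageTrack,
    anchors: Sequence[GenomicInterval] | Sequence[GeneModel],
    mode: str = "center_anchored",
    window: int = 5_000,
    n_scaled_bins: int = 100,
) -> Metaprofile:
    """Average signal around a set of anchors.

    center_anchored: mean signal at each offset from interval centers.
    tss_anchored: offsets from each gene's TSS, − strand profiles
    reversed so downstream-of-TSS is always to the right.
    gene_body_scaled: each gene's TSS→TTS signal linearly resampled to
    ``n_scaled_bins`` bins, then averaged.  Anchors whose window leaves
    the track are skipped; ``n_anchors`` counts those actually used.
    """
    if len(anchors) == 0:
        raise ValueError("anchors must be non-empty")
    bs = track.bin_size
    half_bins = int(window // bs)

    profiles: list[np.ndarray] = []
    if mode in ("center_anchored", "tss_anchored"):
        for anchor in anchors:
            if mode == "center_anchored":
                iv = anchor.interval if isinstance(anchor, GeneModel) else anchor
                chrom, point, flip = iv.chrom, iv.midpoint, False
            else:
                if not isinstance(anchor, GeneModel):
                    raise TypeError("tss_anchored mode requires GeneModel anchors")
                chrom, point, flip = anchor.chrom, anchor.tss, anchor.strand == "-"
            if chrom not in track.data:
                continue
            win = _extract_window(track.data[chrom], point // bs, half_bins)
            if win is None:
                continue
            profiles.append(win[::-1] if flip else win)
        positions = np.arange(-half_bins, half_bins + 1) * bs
    elif mode == "gene_body_scaled":
        for anchor in anchors:
            if not isinstance(anchor, GeneModel):
                raise TypeError("gene_body_scaled mode requires GeneModel anchors")
            if anchor.chrom not in track.data:
                continue
            values = track.data[anchor.chrom]
            b0, b1 = anchor.interval.start // bs, (anchor.interval.end - 1) // bs
            if b1 >= len(values):
                continue
            body = values[b0 : b1 + 1].astype(float)
            if anchor.strand == "-":
                body = body[::-1]
            src = np.linspace(0.0, 1.0, num=len(body))
            dst = np.linspace(0.0, 1.0, num=n_scaled_bins)
            profiles.append(np.interp(dst, src, body))
        positions = np.arange(n_scaled_bins)
    else:
        raise ValueError(f"unknown metaprofile mode {mode!r}")

    if not profiles:
        raise ValueError("no anchor fits inside the track bounds")
    return Metaprofile(mode, positions, np.mean(profiles, axis=0), len(profiles))


def metaprofile_frame(profile: Metaprofile) -> pd.DataFrame:
    """Tabular (position, mean_signal) view for TSV export."""
    return pd.DataFrame(
        {"position": profile.positions, "mean_signal": profile.mean_signal}
    )
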
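"""Runs of homozygosity: scanning-window calling, F_ROH, and dating.

The caller reproduces the PLINK-style scanning-window procedure on hard
genotype calls.  Every window of ``window_snp`` consecutive SNPs is labelled
homozygous when it contains at most ``window_het`` heterozygous and
``window_missing`` missing calls; a SNP is in a homozygous segment when the
fraction of fully-contained windows covering it that are homozygous reaches
``window_threshold``; maximal runs of such SNPs, split at inter-SNP gaps
above ``max_gap_kb``, become segments when they satisfy the span, SNP-count,
density and heterozygote-count filters.

Segment length then dates the inbreeding event that produced it: a run of
length L Mb coalesces on average g = 100 / (2 r L) generations back, with r
the recombination rate in cM/Mb.  Longer runs mean more recent inbreeding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, write_table


@dataclass
class ROHParams:
    """Scanning-window parameters, named after their PLINK counterparts."""

    window_snp: int = 100
    window_het: int = 1
    window_missing: int = 5
    window_threshold: float = 0.05
    min_snp: int = 25
    min_kb: float = 100.0
    density_kb_per_snp: float = 50.0
    max_gap_kb: float = 1000.0
    max_het_in_segment: int = 750

    def __post_init__(self) -> None:
        for name in (
            "window_snp",
            "window_het",
            "window_missing",
            "min_snp",
            "min_kb",
            "density_kb_per_snp",
            "max_gap_kb",
            "max_het_in_segment",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.window_snp <= 0:
            raise ValueError("window_snp must be positive")
        if not 0 < self.window_threshold <= 1:
            raise ValueError("window_threshold must be in (0, 1]")


@dataclass
class ROHTimingParams:
    """Recombination rate (cM/Mb) and generation time (years) for dating."""

    r: float = 1.04
    generation_time: float = 7.0

    def __post_init__(self) -> None:
        if self.r <= 0 or self.generation_time <= 0:
            raise ValueError("r and generation_time must be positive")


@dataclass
class ROHSegment:
    """One homozygous run: 1-based inclusive span at the outermost SNPs."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_snps: int
    n_het: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6


def _passing_snps(gt: np.ndarray, params: ROHParams) -> np.ndarray:
    """Boolean per-SNP flag: is the SNP covered by enough homozygous windows?

    Only windows that fit entirely on the chromosome count; SNPs near the
    ends therefore use fewer windows.  A chromosome with fewer SNPs than the
    window size has no fitting window and no passing SNP.
    """
    n = gt.shape[0]
    w = params.window_snp
    if n < w:
        return np.zeros(n, dtype=bool)
    het = np.cumsum(np.concatenate([[0], gt == 1]))
    mis = np.cumsum(np.concatenate([[0], gt == -1]))
    starts = np.arange(n - w + 1)
    hom_win = ((het[starts + w] - het[starts]) <= params.window_het) & (
        (mis[starts + w] - mis[starts]) <= params.window_missing
    )
    hom_cum = np.cumsum(np.concatenate([[0], hom_win]))
    j = np.arange(n)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, n - w)  # inclusive last window start covering j
    denom = hi - lo + 1
    hom_count = hom_cum[hi + 1] - hom_cum[lo]
    return hom_count / denom >= params.window_threshold


def _emit_candidates(
    pos: np.ndarray, gt: np.ndarray, passing: np.ndarray, params: ROHParams
) -> Iterable[tuple[int, int]]:
    """Yield (first, last) index pairs of candidate runs after gap splitting."""
    idx = np.flatnonzero(passing)
    if idx.size == 0:
        return
    gap_bp = params.max_gap_kb * 1000.0
    # break runs at non-consecutive indices or at oversized genomic gaps
    brk = np.flatnonzero(
        (np.diff(idx) != 1) | (np.diff(pos[idx]) > gap_bp)
    )
    starts = np.concatenate([[0], brk + 1])
    ends = np.concatenate([brk, [idx.size - 1]])
    for s, e in zip(starts, ends):
        yield int(idx[s]), int(idx[e])


def call_roh(gm: GenotypeMatrix, params: ROHParams | None = None) -> list[ROHSegment]:
    """Call ROH segments for every sample with the scanning-window procedure."""
    params = params or ROHParams()
    segments: list[ROHSegment] = []
    for c in gm.chromosomes():
        site_idx = np.flatnonzero(gm.chrom == c)
        pos = gm.pos[site_idx]
        if pos.size > 1 and not (np.diff(pos) > 0).all():
            raise ValueError(f"positions not sorted on {c}")
        for i, sample in enumerate(gm.sample_ids):
            gt = gm.genotypes[i, site_idx]
            passing = _passing_snps(gt, params)
            for s, e in _emit_candidates(pos, gt, passing, params):
                span = int(pos[e] - pos[s] + 1)
                n_snps = e - s + 1
                n_het = int((gt[s : e + 1] == 1).sum())
                if span < params.min_kb * 1000:
                    continue
                if n_snps < params.min_snp:
                    continue
                if span / 1000.0 / n_snps > params.density_kb_per_snp:
                    continue
                if n_het > params.max_het_in_segment:
                    continue
                segments.append(
                    ROHSegment(sample, c, int(pos[s]), int(pos[e]), n_snps, n_het)
                )
    return segments


def segments_to_frame(segments: Sequence[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "kb": s.length_bp / 1000.0,
                "n_snps": s.n_snps,
                "n_het": s.n_het,
            }
            for s in segments
        ],
        columns=["sample_id", "chrom", "start", "end", "kb", "n_snps", "n_het"],
    )


def write_segments(segments: Sequence[ROHSegment], path: str | Path) -> None:
    write_table(segments_to_frame(segments), path)


def froh(
    segments: Sequence[ROHSegment],
    autosomal_bp: int,
    sample_ids: Sequence[str] | None = None,
    min_length_mb: float = 0.0,
) -> pd.Series:
    """Fraction of the autosomal genome in ROH per sample (F_ROH).

    ``min_length_mb`` restricts to a length class (e.g. 2.0 for the >= 2 Mb
    class); samples without qualifying segments report 0.  Overlapping
    segments within one sample are rejected -- the caller never emits them.
    """
    if autosomal_bp <= 0:
        raise ValueError("autosomal_bp must be positive")
    by_sample: dict[str, list[ROHSegment]] = {}
    for s in segments:
        by_sample.setdefault(s.sample_id, []).append(s)
    totals: dict[str, float] = {}
    for sid, segs in by_sample.items():
        segs = sorted(segs, key=lambda s: (s.chrom, s.start))
        for a, b in zip(segs, segs[1:]):
            if a.chrom == b.chrom and b.start <= a.end:
                raise ValueError(f"overlapping ROH segments for sample {sid}")
        totals[sid] = sum(
            s.length_bp for s in segs if s.length_mb >= min_length_mb
        ) / float(autosomal_bp)
    if sample_ids is None:
        sample_ids = sorted(totals)
    return pd.Series(
        [totals.get(sid, 0.0) for sid in sample_ids], index=list(sample_ids), name="froh"
    )


def roh_age(
    length_mb: float | np.ndarray, timing: ROHTimingParams | None = None
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Expected age of the inbreeding event behind a ROH of given length.

    Returns (generations, years): g = 100 / (2 r L), years = g x generation
    time.  Unrounded values; presentation rounding belongs to the caller.
    """
    timing = timing or ROHTimingParams()
    L = np.asarray(length_mb, dtype=float)
    if np.any(L <= 0):
        raise ValueError("ROH length must be positive")
    g = 100.0 / (2.0 * timing.r * L)
    years = g * timing.generation_time
    if np.isscalar(length_mb) or getattr(length_mb, "ndim", 1) == 0:
        return float(g), float(years)
    return g, years
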
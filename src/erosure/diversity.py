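"""Per-individual heterozygosity, windowed nucleotide diversity and F_ST.

Heterozygosity is a direct count of heterozygous calls per kilobase of
callable sequence.  Nucleotide diversity pi is the expected pairwise
difference per base, computed from called allele counts site by site and
summed over non-overlapping windows.  Two-population differentiation uses
the Weir-Cockerham (1984) variance-components estimator by default -- the
window value is the "weighted" ratio sum(a) / sum(a+b+c) -- with Hudson's
estimator (ratio of averages, Bhatia et al. 2013 recommendation) as an
alternative.  Negative window values are retained, not clamped, so that a
downstream Z-transformation is unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, write_table


@dataclass
class DiversityTrack:
    """Per-window values of a diversity statistic.

    ``frame`` has columns chrom, start, end (half-open, 0-based window
    coordinates), n_sites, value, and for F_ST also the per-window numerator
    and denominator sums so genome-wide ratio-of-sums estimates remain exact.
    """

    frame: pd.DataFrame
    metric: str  # "pi" or "fst"
    populations: tuple[str, ...]
    window_bp: int
    step_bp: int

    @property
    def values(self) -> np.ndarray:
        return self.frame["value"].to_numpy()

    def genome_wide(self) -> float:
        """Genome-wide estimate: ratio of summed components (F_ST) or
        length-weighted mean (pi)."""
        f = self.frame
        if self.metric == "fst":
            den = f["den"].sum()
            if den == 0:
                raise ValueError("no informative sites in track")
            return float(f["num"].sum() / den)
        w = (f["end"] - f["start"]).to_numpy(dtype=float)
        return float(np.sum(f["value"].to_numpy() * w) / w.sum())

    def to_tsv(self, path: str | Path) -> None:
        cols = ["chrom", "start", "end", "n_sites", "value"]
        write_table(
            self.frame[cols],
            path,
            comment=f"metric={self.metric} populations={','.join(self.populations)} "
            f"window={self.window_bp} step={self.step_bp}",
        )


def heterozygosity_per_kb(
    gm: GenotypeMatrix, callable_bp: float | np.ndarray
) -> pd.Series:
    """Heterozygous sites per 1,000 bp of callable sequence, per sample.

    ``callable_bp`` is a global scalar or one value per sample.
    """
    callable_bp = np.asarray(callable_bp, dtype=float)
    if np.any(callable_bp <= 0):
        raise ValueError("callable_bp must be positive")
    het = (gm.genotypes == 1).sum(axis=1)
    rate = 1000.0 * het / callable_bp
    return pd.Series(rate, index=gm.sample_ids, name="het_per_kb")


def _window_starts(max_pos: int, window_bp: int, step_bp: int) -> np.ndarray:
    if max_pos <= 0:
        return np.zeros(0, dtype=np.int64)
    last = ((max_pos - 1) // step_bp) * step_bp
    return np.arange(0, last + 1, step_bp, dtype=np.int64)


def _aggregate_windows(
    chrom: np.ndarray,
    pos: np.ndarray,
    per_site: dict[str, np.ndarray],
    window_bp: int,
    step_bp: int,
    chrom_order: list[str],
) -> pd.DataFrame:
    """Sum per-site quantities into (possibly sliding) windows per chromosome."""
    rows: list[pd.DataFrame] = []
    for c in chrom_order:
        m = chrom == c
        p = pos[m]
        starts = _window_starts(int(p.max()) if p.size else 0, window_bp, step_bp)
        if starts.size == 0:
            continue
        df = pd.DataFrame({"chrom": c, "start": starts, "end": starts + window_bp})
        # site with 1-based position p lies in [start, end) iff start <= p-1 < end
        p0 = p - 1
        order = np.argsort(p0, kind="stable")
        p0s = p0[order]
        lo = np.searchsorted(p0s, starts, side="left")
        hi = np.searchsorted(p0s, starts + window_bp, side="left")
        df["n_sites"] = hi - lo
        csum = {
            k: np.concatenate([[0.0], np.cumsum(v[m][order])]) for k, v in per_site.items()
        }
        for k, cs in csum.items():
            df[k] = cs[hi] - cs[lo]
        rows.append(df)
    if not rows:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_sites", *per_site.keys()]
        )
    return pd.concat(rows, ignore_index=True)


def pi_windows(
    gm: GenotypeMatrix,
    population: str,
    window_bp: int = 50_000,
    callable_mask_bp: pd.DataFrame | None = None,
) -> DiversityTrack:
    """Nucleotide diversity in non-overlapping windows for one population.

    Per site, pi = 2 * c_ref * c_alt / (n * (n - 1)) over called allele
    counts; the window value divides the site sum by the full window length.
    Supplying ``callable_mask_bp`` (columns chrom, start, end, callable) uses
    the callable base count of each window as the denominator instead.
    """
    idx = gm.sample_index(population=population)
    if idx.size < 2:
        raise ValueError(f"population {population!r} has fewer than 2 samples")
    g = gm.genotypes[idx, :]
    called = (g >= 0).sum(axis=0)
    n = 2 * called  # allele count
    alt = np.where(g > 0, g, 0).sum(axis=0)
    ref = n - alt
    with np.errstate(divide="ignore", invalid="ignore"):
        pi_site = np.where(n > 1, 2.0 * ref * alt / (n * (n - 1.0)), 0.0)
    frame = _aggregate_windows(
        gm.chrom, gm.pos, {"pi_sum": pi_site}, window_bp, window_bp, gm.chromosomes()
    )
    denom = (frame["end"] - frame["start"]).to_numpy(dtype=float)
    if callable_mask_bp is not None:
        key = ["chrom", "start", "end"]
        merged = frame[key].merge(callable_mask_bp, on=key, how="left")
        denom = merged["callable"].fillna(0).to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frame["value"] = np.where(denom > 0, frame["pi_sum"] / denom, np.nan)
    return DiversityTrack(frame, "pi", (population,), window_bp, window_bp)


def _pop_site_stats(g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Called-diploid count, alt-allele frequency and het fraction per site."""
    called = (g >= 0).sum(axis=0).astype(float)
    alt = np.where(g > 0, g, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(called > 0, alt / (2.0 * called), np.nan)
        h = np.where(called > 0, (g == 1).sum(axis=0) / called, np.nan)
    return called, p, h


def weir_cockerham_site_components(
    g1: np.ndarray, g2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir-Cockerham variance components (a, b, c) for two
    populations from genotype-code arrays (samples x sites).

    a: among-population, b: among-individual-within-population,
    c: within-individual.  Sites without at least one called diploid in each
    population and three overall are returned as NaN.
    """
    n1, p1, h1 = _pop_site_stats(g1)
    n2, p2, h2 = _pop_site_stats(g2)
    r = 2.0
    nbar = (n1 + n2) / r
    ok = (n1 >= 1) & (n2 >= 1) & (nbar > 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    ok &= nc > 0
    a = np.where(ok, a, np.nan)
    b = np.where(ok, b, np.nan)
    c = np.where(ok, c, np.nan)
    return a, b, c


def hudson_site_components(
    p1: np.ndarray, n1: np.ndarray, p2: np.ndarray, n2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hudson F_ST numerator/denominator per site from allele frequencies
    and allele counts (haploid sample sizes)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (n1 - 1.0)
            - p2 * (1 - p2) / (n2 - 1.0)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = (n1 >= 2) & (n2 >= 2)
    return np.where(ok, num, np.nan), np.where(ok, den, np.nan)


def fst_windows(
    gm: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    window_bp: int = 50_000,
    step_bp: int | None = None,
    estimator: str = "weir-cockerham",
) -> DiversityTrack:
    """Windowed two-population F_ST over a sliding grid.

    The window value is a ratio of sums over the sites it contains:
    sum(a) / sum(a+b+c) for Weir-Cockerham, the Hudson ratio of averages
    otherwise.  Windows with no informative site carry NaN.
    """
    if pop_a == pop_b:
        raise ValueError("population labels must differ")
    step_bp = window_bp if step_bp is None else step_bp
    if step_bp > window_bp:
        raise ValueError("step_bp must not exceed window_bp")
    ia = gm.sample_index(population=pop_a)
    ib = gm.sample_index(population=pop_b)
    if ia.size < 2 or ib.size < 2:
        raise ValueError("both populations need at least 2 samples")
    g1, g2 = gm.genotypes[ia, :], gm.genotypes[ib, :]
    if estimator == "weir-cockerham":
        a, b, c = weir_cockerham_site_components(g1, g2)
        num, den = a, a + b + c
    elif estimator == "hudson":
        n1, p1, _ = _pop_site_stats(g1)
        n2, p2, _ = _pop_site_stats(g2)
        num, den = hudson_site_components(p1, 2 * n1, p2, 2 * n2)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    informative = np.isfinite(num) & np.isfinite(den)
    frame = _aggregate_windows(
        gm.chrom,
        gm.pos,
        {
            "num": np.where(informative, num, 0.0),
            "den": np.where(informative, den, 0.0),
            "n_inf": informative.astype(float),
        },
        window_bp,
        step_bp,
        gm.chromosomes(),
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        frame["value"] = np.where(
            (frame["n_inf"] > 0) & (frame["den"] != 0),
            frame["num"] / frame["den"],
            np.nan,
        )
    frame = frame.drop(columns=["n_inf"])
    return DiversityTrack(frame, "fst", (pop_a, pop_b), window_bp, step_bp)
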
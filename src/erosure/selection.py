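"""Z-transformed F_ST outlier scans and gene intersection.

Window F_ST values are standardised against the track mean and standard
deviation, Z = (F_ST - mu) / sigma; windows beyond the threshold (default
Z > 5, one-sided upper) are candidate targets of divergent selection.
Candidate genes are those whose annotated span overlaps at least one
outlier window.  The same machinery serves spatial (cluster vs cluster)
and temporal (cohort vs cohort) scans.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .diversity import DiversityTrack
from .io_formats import GeneModel, write_table


@dataclass
class FstWindowTrack:
    """Windowed F_ST with Z-scores and outlier flags.

    ``frame`` columns: chrom, start, end, n_sites, fst, z, outlier.  Windows
    with no informative sites keep NaN z and are never outliers.  mu and
    sigma are the mean and sample standard deviation over non-missing
    windows, so the non-missing z scores have mean 0 and sd 1.
    """

    frame: pd.DataFrame
    mu: float
    sigma: float
    threshold_sd: float
    two_sided: bool
    populations: tuple[str, ...]

    def outliers(self) -> pd.DataFrame:
        return self.frame[self.frame["outlier"]].reset_index(drop=True)

    def to_tsv(self, path: str | Path) -> None:
        write_table(
            self.frame,
            path,
            comment=f"mu_fst={self.mu:.6g} sigma_fst={self.sigma:.6g} "
            f"zcut={self.threshold_sd} two_sided={self.two_sided}",
        )


def zfst(
    track: DiversityTrack, threshold_sd: float = 5.0, two_sided: bool = False
) -> FstWindowTrack:
    """Standardise a windowed F_ST track and flag outlier windows.

    Raises on degenerate tracks (fewer than two non-missing windows or zero
    variance) where the Z-score is undefined.
    """
    vals = track.frame["value"].to_numpy(dtype=float)
    finite = np.isfinite(vals)
    if finite.sum() < 2:
        raise ValueError("degenerate track: fewer than 2 non-missing windows")
    mu = float(vals[finite].mean())
    sigma = float(vals[finite].std(ddof=1))
    if sigma == 0:
        raise ValueError("degenerate track: zero variance")
    z = np.where(finite, (vals - mu) / sigma, np.nan)
    if two_sided:
        out = np.abs(z) > threshold_sd
    else:
        out = z > threshold_sd
    out &= finite
    frame = track.frame[["chrom", "start", "end", "n_sites"]].copy()
    frame["fst"] = vals
    frame["z"] = z
    frame["outlier"] = out
    return FstWindowTrack(frame, mu, sigma, threshold_sd, two_sided, track.populations)


def intersect_genes(
    outliers: FstWindowTrack, genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Genes whose span overlaps at least one outlier window.

    Overlap compares gene and window spans on the same coordinate axis with
    the gene treated as half-open [start, end): a gene starting exactly at a
    window's (exclusive) end is not reported.  Output is deduplicated and
    sorted by chromosome then start, with the number of hit windows.
    """
    ow = outliers.outliers()
    hits: list[dict] = []
    for g in genes:
        w = ow[ow["chrom"] == g.chrom]
        n_hit = int(((g.start < w["end"]) & (w["start"] < g.end)).sum())
        if n_hit > 0:
            hits.append(
                {
                    "gene_id": g.gene_id,
                    "chrom": g.chrom,
                    "start": g.start,
                    "end": g.end,
                    "n_hit_windows": n_hit,
                }
            )
    frame = pd.DataFrame(
        hits, columns=["gene_id", "chrom", "start", "end", "n_hit_windows"]
    )
    frame = frame.drop_duplicates(subset="gene_id")
    return frame.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
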
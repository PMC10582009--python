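"""Genetic-load accounting from derived-allele genotypes.

Variants are stratified by predicted impact (High: protein-truncating-class,
Moderate: missense-class, Synonymous: putatively neutral).  Total load per
individual counts sites carrying at least one derived allele in each
category, after removing sites fixed homozygous-derived in every individual;
dividing by the individual's synonymous count corrects for mapping and
reference bias.  Realised load is the fraction of a category's segregating
sites the individual exposes in homozygous-derived state (at most 0.5 by
construction, since the denominator is twice the segregating-site count).

R_xy compares the aggregate derived-allele frequency of a category between
two populations: R_xy = sum f_x(1-f_y) / sum f_y(1-f_x), normalised by the
same ratio on a neutral category.  R_xy = 1 means no frequency difference;
< 1 a deficit and > 1 an excess in population x relative to y.  Uncertainty
comes from a delete-one jackknife over contiguous genomic blocks, which
respects linkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, Impact

LOAD_CATEGORIES = (Impact.HIGH, Impact.MODERATE, Impact.SYNONYMOUS)


def _remove_fixed_derived(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Drop sites where every called individual is homozygous-derived."""
    d = gm.derived_dosage()
    called = d >= 0
    fixed = (np.where(called, d, 2) == 2).all(axis=0) & called.any(axis=0)
    if not fixed.any():
        return gm
    return gm.take_sites(np.flatnonzero(~fixed))


def load_counts(gm: GenotypeMatrix, mode: str = "sites") -> pd.DataFrame:
    """Per-sample carrier counts of High / Moderate / Synonymous variants.

    Sites fixed homozygous-derived in all individuals are removed first.
    ``mode="sites"`` counts sites where the sample carries >= 1 derived
    allele; ``mode="alleles"`` sums derived-allele dosages instead.
    """
    if mode not in ("sites", "alleles"):
        raise ValueError(f"unknown mode {mode!r}")
    if not np.isin(gm.impact, [int(c) for c in LOAD_CATEGORIES]).any():
        raise ValueError("no annotated High/Moderate/Synonymous sites")
    gm = _remove_fixed_derived(gm)
    d = gm.derived_dosage()
    out = {}
    for cat in LOAD_CATEGORIES:
        cols = gm.impact == int(cat)
        dc = d[:, cols]
        if mode == "sites":
            out[cat.name] = (dc >= 1).sum(axis=1)
        else:
            out[cat.name] = np.where(dc > 0, dc, 0).sum(axis=1)
    return pd.DataFrame(out, index=gm.sample_ids)


def normalized_total_load(counts: pd.DataFrame) -> pd.DataFrame:
    """Category counts divided by the sample's synonymous count.

    Samples with zero synonymous variants are flagged missing (NaN).
    """
    syn = counts["SYNONYMOUS"].to_numpy(dtype=float)
    out = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for cat in ("HIGH", "MODERATE"):
            out[f"{cat}_per_syn"] = np.where(syn > 0, counts[cat] / syn, np.nan)
    return pd.DataFrame(out, index=counts.index)


def realised_load(gm: GenotypeMatrix, category: Impact) -> pd.Series:
    """Homozygous-derived sites of a category per sample, over twice the
    category's segregating-site count.

    Segregating means polymorphic across all called genotypes after removal
    of sites fixed homozygous-derived; the value is therefore bounded by 0.5.
    """
    gm = _remove_fixed_derived(gm)
    d = gm.derived_dosage()
    cols = gm.impact == int(category)
    dc = d[:, cols]
    called = dc >= 0
    derived_present = (np.where(called, dc, 0) > 0).any(axis=0)
    segregating = derived_present  # fixed-derived already removed
    n_seg = int(segregating.sum())
    if n_seg == 0:
        raise ValueError(f"no segregating sites in category {category.name}")
    hom = (dc[:, segregating] == 2).sum(axis=1)
    return pd.Series(
        hom / (2.0 * n_seg), index=gm.sample_ids, name=f"realised_{category.name}"
    )


@dataclass
class RxyResult:
    """Point estimate and block-jackknife uncertainty for one R_xy ratio."""

    category: str
    ratio: float
    se: float
    ci_low: float
    ci_high: float
    n_blocks: int


def _block_assignment(gm: GenotypeMatrix, blocks: int | None) -> np.ndarray:
    """Contiguous genomic block id per site: one per chromosome by default,
    or `blocks` equal-site contiguous chunks."""
    if blocks is None:
        chroms = gm.chromosomes()
        lut = {c: i for i, c in enumerate(chroms)}
        return np.array([lut[c] for c in gm.chrom], dtype=np.int64)
    return np.minimum(
        (np.arange(gm.n_sites) * blocks) // max(gm.n_sites, 1), blocks - 1
    ).astype(np.int64)


def _pairwise_sums(
    fx: np.ndarray, fy: np.ndarray, block: np.ndarray, n_blocks: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-block sums of f_x(1-f_y) and f_y(1-f_x)."""
    lxy = np.bincount(block, weights=fx * (1 - fy), minlength=n_blocks)
    lyx = np.bincount(block, weights=fy * (1 - fx), minlength=n_blocks)
    return lxy, lyx


def rxy(
    gm: GenotypeMatrix,
    pop_x: str,
    pop_y: str,
    category: Impact,
    neutral_category: Impact = Impact.SYNONYMOUS,
    blocks: int | None = None,
) -> RxyResult:
    """R_xy of a variant category between two populations, normalised by a
    neutral category, with delete-one block-jackknife standard error.

    ``blocks=None`` uses one contiguous block per chromosome; an integer
    splits the site axis into that many contiguous blocks.  At least three
    blocks must contain sites of both the focal and neutral categories.
    """
    ix = gm.sample_index(population=pop_x)
    iy = gm.sample_index(population=pop_y)
    if ix.size == 0 or iy.size == 0:
        raise ValueError("both populations must be non-empty")
    d = gm.derived_dosage()

    def derived_freq(rows: np.ndarray) -> np.ndarray:
        sub = d[rows, :]
        called = (sub >= 0).sum(axis=0)
        alt = np.where(sub > 0, sub, 0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(called > 0, alt / (2.0 * called), np.nan)

    fx, fy = derived_freq(ix), derived_freq(iy)
    usable = np.isfinite(fx) & np.isfinite(fy)
    block = _block_assignment(gm, blocks)
    n_blocks = int(block.max()) + 1 if block.size else 0

    def per_block(cat: Impact) -> tuple[np.ndarray, np.ndarray]:
        m = usable & (gm.impact == int(cat))
        return _pairwise_sums(fx[m], fy[m], block[m], n_blocks)

    cxy, cyx = per_block(category)
    nxy, nyx = per_block(neutral_category)
    nonempty = (cxy + cyx > 0) & (nxy + nyx > 0)
    if int(nonempty.sum()) < 3:
        raise ValueError("fewer than 3 non-empty jackknife blocks")

    def ratio_excluding(drop: int | None) -> float:
        keep = np.ones(n_blocks, dtype=bool)
        if drop is not None:
            keep[drop] = False
        num = cxy[keep].sum() / cyx[keep].sum()
        den = nxy[keep].sum() / nyx[keep].sum()
        if not np.isfinite(num) or not np.isfinite(den) or den == 0:
            raise ValueError("R_xy denominator is zero")
        return num / den

    point = ratio_excluding(None)
    loo = np.array([ratio_excluding(b) for b in np.flatnonzero(nonempty)])
    nb = loo.size
    se = float(np.sqrt((nb - 1) / nb * np.sum((loo - loo.mean()) ** 2)))
    return RxyResult(
        category=Impact(category).name,
        ratio=float(point),
        se=se,
        ci_low=float(point - 1.96 * se),
        ci_high=float(point + 1.96 * se),
        n_blocks=nb,
    )
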
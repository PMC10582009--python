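"""Synthetic cohorts with known population structure, load and inbreeding.

The generator produces the statistical structure every downstream stage
assumes, with ground truth for recovery tests:

* Diverged populations under the Balding-Nichols model: each population's
  allele frequency at a site is Beta(p(1-F)/F, (1-p)(1-F)/F) around an
  ancestral frequency p, so the genome-wide F_ST between populations has a
  known expectation F.  Genotypes are Binomial(2, p_k) -- sites are
  independent (no linkage); ROH structure is planted, not emergent.
* Impact-stratified sites with optional population-specific multipliers on
  the derived-allele frequency, which drive a known R_xy away from 1.
* A second time point per population, either with pure binomial drift at a
  chosen Ne or with a programmed annual change in expected heterozygosity
  (frequencies moved toward the nearer boundary so 2p(1-p) shrinks by
  exactly the requested fraction).
* Planted homozygous tracts per sample (population-major allele) with
  recorded coordinates, for ROH-caller recovery tests.

Everything is driven by one integer seed through numpy Generator streams;
the same seed reproduces the same cohort bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    GenomicMask,
    GeneModel,
    GenotypeMatrix,
    Impact,
    SampleSheet,
    write_gff3_genes,
    write_vcf,
)

_DEFAULT_MIX = {"SYNONYMOUS": 0.15, "MODERATE": 0.08, "HIGH": 0.02, "OTHER": 0.75}


@dataclass
class SimConfig:
    """Study design for a synthetic cohort."""

    n_pops: int = 2
    pop_names: tuple[str, ...] | None = None
    n_diploids: int = 15  # per population per time point
    n_sites: int = 20_000
    n_chroms: int = 4
    chrom_length_bp: int = 20_000_000
    divergence_f: float | tuple[float, ...] = 0.1  # Balding-Nichols F per pop
    impact_mix: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_MIX))
    # category -> per-population multiplier on the derived-allele frequency
    category_freq_multiplier: dict[str, tuple[float, ...]] | None = None
    two_time_points: bool = False
    year_t1: int = 1980
    years_between: int = 40
    generation_time: float = 7.0
    drift_ne: float | None = None
    annual_het_change_pct: float | None = None
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops < 1 or self.n_diploids < 1 or self.n_sites < 1:
            raise ValueError("counts must be positive")
        total = sum(self.impact_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"impact_mix proportions sum to {total}, expected 1")
        if self.pop_names is None:
            base = ("North", "South", "Transition", "Oland")
            self.pop_names = tuple(
                base[i] if i < len(base) else f"pop{i}" for i in range(self.n_pops)
            )
        if len(self.pop_names) != self.n_pops:
            raise ValueError("pop_names length must equal n_pops")
        f = self.divergence_f
        self.divergence_f = tuple(
            [f] * self.n_pops if np.isscalar(f) else list(f)
        )
        if len(self.divergence_f) != self.n_pops:
            raise ValueError("divergence_f length must equal n_pops")
        for fv in self.divergence_f:
            if not 0 <= fv < 1:
                raise ValueError("divergence F must lie in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated cohort."""

    ancestral_freq: np.ndarray
    pop_freq_t1: dict[str, np.ndarray]
    pop_freq_t2: dict[str, np.ndarray] | None
    impacts: np.ndarray
    category_freq_multiplier: dict[str, tuple[float, ...]] | None
    annual_het_change_pct: float | None
    chrom_lengths: dict[str, int]
    planted_tracts: pd.DataFrame | None
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": int(self.seed),
            "annual_het_change_pct": self.annual_het_change_pct,
            "category_freq_multiplier": self.category_freq_multiplier,
            "chrom_lengths": {k: int(v) for k, v in self.chrom_lengths.items()},
            "ancestral_freq": np.round(self.ancestral_freq, 6).tolist(),
            "pop_freq_t1": {
                k: np.round(v, 6).tolist() for k, v in self.pop_freq_t1.items()
            },
            "pop_freq_t2": None
            if self.pop_freq_t2 is None
            else {k: np.round(v, 6).tolist() for k, v in self.pop_freq_t2.items()},
            "impacts": [Impact(i).name for i in self.impacts],
            "planted_tracts": None
            if self.planted_tracts is None
            else self.planted_tracts.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _draw_positions(cfg: SimConfig, rng: np.random.Generator):
    """Unique sorted positions, sites split evenly across chromosomes."""
    chroms, positions, names = [], [], []
    per = np.full(cfg.n_chroms, cfg.n_sites // cfg.n_chroms, dtype=int)
    per[: cfg.n_sites % cfg.n_chroms] += 1
    for k in range(cfg.n_chroms):
        name = f"chr{k + 1}"
        names.append(name)
        want = int(per[k])
        pos = np.unique(rng.integers(1, cfg.chrom_length_bp + 1, size=want))
        while pos.size < want:  # top up collisions
            extra = rng.integers(1, cfg.chrom_length_bp + 1, size=want - pos.size)
            pos = np.unique(np.concatenate([pos, extra]))
        chroms.extend([name] * want)
        positions.append(np.sort(pos[:want]))
    return (
        np.array(chroms, dtype=object),
        np.concatenate(positions),
        {n: cfg.chrom_length_bp for n in names},
    )


def _het_preserving_shift(p: np.ndarray, factor: float) -> np.ndarray:
    """Move frequencies toward the nearer boundary (or 0.5) so that
    2p(1-p) scales by exactly ``factor`` wherever feasible."""
    target = np.clip(p * (1 - p) * factor, 0.0, 0.25)
    root = np.sqrt(0.25 - target)
    return np.where(p <= 0.5, 0.5 - root, 0.5 + root)


def simulate_cohorts(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw a synthetic cohort and its ground truth; deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    chrom, pos, chrom_lengths = _draw_positions(cfg, rng)
    lo, hi = cfg.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=cfg.n_sites)
    cat_names = ["SYNONYMOUS", "MODERATE", "HIGH", "OTHER"]
    probs = np.array([cfg.impact_mix.get(c, 0.0) for c in cat_names])
    imp_idx = rng.choice(len(cat_names), size=cfg.n_sites, p=probs / probs.sum())
    impacts = np.array([int(Impact[cat_names[i]]) for i in imp_idx], dtype=np.int8)

    pop_freq_t1: dict[str, np.ndarray] = {}
    for pop, f in zip(cfg.pop_names, cfg.divergence_f):
        if f == 0:
            pk = p_anc.copy()
        else:
            a = p_anc * (1 - f) / f
            b = (1 - p_anc) * (1 - f) / f
            pk = rng.beta(a, b)
        if cfg.category_freq_multiplier:
            k = cfg.pop_names.index(pop)
            for cat, mults in cfg.category_freq_multiplier.items():
                m = impacts == int(Impact[cat])
                pk[m] = np.clip(pk[m] * mults[k], 0.0, 1.0)
        pop_freq_t1[pop] = pk

    pop_freq_t2: dict[str, np.ndarray] | None = None
    if cfg.two_time_points:
        pop_freq_t2 = {}
        gens = cfg.years_between / cfg.generation_time
        for pop, p1 in pop_freq_t1.items():
            if cfg.annual_het_change_pct is not None:
                factor = 1.0 + cfg.annual_het_change_pct * cfg.years_between / 100.0
                p2 = _het_preserving_shift(p1, factor)
            elif cfg.drift_ne is not None:
                sd = np.sqrt(p1 * (1 - p1) * gens / (2.0 * cfg.drift_ne))
                p2 = np.clip(p1 + rng.normal(0.0, 1.0, p1.shape) * sd, 0.0, 1.0)
            else:
                p2 = p1.copy()
            pop_freq_t2[pop] = p2

    sample_ids: list[str] = []
    pops: list[str] = []
    years: list[int] = []
    blocks: list[np.ndarray] = []
    cohorts = [(cfg.year_t1, pop_freq_t1)]
    if pop_freq_t2 is not None:
        cohorts.append((cfg.year_t1 + cfg.years_between, pop_freq_t2))
    for year, freqs in cohorts:
        for pop in cfg.pop_names:
            g = rng.binomial(2, freqs[pop], size=(cfg.n_diploids, cfg.n_sites))
            blocks.append(g.astype(np.int8))
            for i in range(cfg.n_diploids):
                sample_ids.append(f"{pop}_{year}_{i:02d}")
                pops.append(pop)
                years.append(year)

    gm = GenotypeMatrix(
        sample_ids=sample_ids,
        populations=np.array(pops, dtype=object),
        years=np.array(years),
        chrom=chrom,
        pos=pos,
        genotypes=np.vstack(blocks),
        ancestral_is_ref=np.ones(cfg.n_sites, dtype=bool),
        impact=impacts,
        ref=np.full(cfg.n_sites, "A", dtype=object),
        alt=np.full(cfg.n_sites, "T", dtype=object),
    )
    truth = SimTruth(
        ancestral_freq=p_anc,
        pop_freq_t1=pop_freq_t1,
        pop_freq_t2=pop_freq_t2,
        impacts=impacts,
        category_freq_multiplier=cfg.category_freq_multiplier,
        annual_het_change_pct=cfg.annual_het_change_pct
        if cfg.two_time_points
        else None,
        chrom_lengths=chrom_lengths,
        planted_tracts=None,
        seed=cfg.seed,
    )
    return gm, truth


@dataclass
class ROHPlan:
    """Planted homozygous-tract design per sample."""

    target_fraction: float = 0.2
    tract_min_mb: float = 0.5
    tract_mean_mb: float = 2.0
    samples: tuple[str, ...] | None = None  # default: every sample

    def __post_init__(self) -> None:
        if not 0 <= self.target_fraction <= 0.9:
            raise ValueError("target_fraction must lie in [0, 0.9]")
        if self.tract_min_mb <= 0 or self.tract_mean_mb < self.tract_min_mb:
            raise ValueError("need 0 < tract_min_mb <= tract_mean_mb")


def plant_roh(
    gm: GenotypeMatrix,
    plan: ROHPlan,
    seed: int,
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Overwrite genotypes inside random non-overlapping tracts with the
    population-major homozygote, and record the tract coordinates.

    The realised per-sample tract fraction lands within 10 % of the target
    (the last tract is trimmed to fit).  Returns a new matrix and a tract
    table (sample_id, chrom, start, end).
    """
    rng = np.random.default_rng(seed)
    if chrom_lengths is None:
        chrom_lengths = {
            c: int(gm.pos[gm.chrom == c].max()) for c in gm.chromosomes()
        }
    chrom_names = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chrom_names], dtype=float)
    genome = lengths.sum()
    targets = plan.samples or tuple(gm.sample_ids)
    g = gm.genotypes.copy()

    # population-major homozygote per site, per population label
    major: dict[str, np.ndarray] = {}
    for pop in dict.fromkeys(gm.populations):
        rows = gm.sample_index(population=pop)
        sub = gm.genotypes[rows, :]
        called = (sub >= 0).sum(axis=0)
        alt = np.where(sub > 0, sub, 0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            freq = np.where(called > 0, alt / (2.0 * called), 0.0)
        major[pop] = np.where(freq > 0.5, 2, 0).astype(np.int8)

    max_tract = max(lengths) - 1.0

    def draw_tract_lengths(needed: float) -> list[int]:
        """Tract lengths summing to ``needed`` bp; a short remainder is
        folded into the previous tract so every tract keeps the minimum
        length (the single-tract case may be shorter for tiny targets)."""
        out: list[float] = []
        total = 0.0
        while total < needed:
            t = (
                plan.tract_min_mb
                + rng.exponential(max(plan.tract_mean_mb - plan.tract_min_mb, 1e-9))
            ) * 1e6
            t = min(t, max_tract)
            if total + t > needed:
                t = needed - total
                if t < plan.tract_min_mb * 1e6 and out:
                    out[-1] += t
                    total += t
                    break
            out.append(t)
            total += t
        return [int(round(t)) for t in out if t >= 1]

    records: list[dict] = []
    for sid in targets:
        i = gm.sample_ids.index(sid)
        needed = plan.target_fraction * genome
        if needed == 0:
            continue
        placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
        cum = 0
        for tract in draw_tract_lengths(needed):
            for _ in range(1000):  # placement attempts
                c = chrom_names[rng.choice(len(chrom_names), p=lengths / genome)]
                L = chrom_lengths[c]
                if tract >= L:
                    continue
                start = int(rng.integers(1, L - tract + 1))
                end = start + tract - 1
                if any(s <= end and start <= e for s, e in placed[c]):
                    continue
                placed[c].append((start, end))
                cum += tract
                cols = (gm.chrom == c) & (gm.pos >= start) & (gm.pos <= end)
                g[i, cols] = major[gm.populations[i]][cols]
                records.append(
                    {"sample_id": sid, "chrom": c, "start": start, "end": end}
                )
                break
        if abs(cum - needed) / needed > 0.10:
            raise ValueError(
                f"could not reach target fraction for {sid}: "
                f"placed {cum / genome:.3f} of {plan.target_fraction:.3f}"
            )
    tracts = pd.DataFrame(records, columns=["sample_id", "chrom", "start", "end"])
    return replace(gm, genotypes=g), tracts


def write_fixture(
    gm: GenotypeMatrix, truth: SimTruth, outdir: str | Path
) -> dict[str, Path]:
    """Write a simulated cohort as on-disk fixture files.

    Emits a VCF with ANN/AA fields, a sample sheet TSV, an (empty) BED mask,
    a GFF3 of toy genes tiling the genome, and the truth JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "samples": outdir / "samples.tsv",
        "mask": outdir / "mask.bed",
        "gff3": outdir / "genes.gff3",
        "truth": outdir / "truth.json",
    }
    write_vcf(gm, paths["vcf"])
    year_min = int(gm.years.min())
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": gm.sample_ids,
                "population": gm.populations,
                "year": gm.years,
                "cohort": ["t1" if y == year_min else "t2" for y in gm.years],
            }
        )
    )
    sheet.to_tsv(paths["samples"])
    paths["mask"].write_text("")  # no masked intervals by default
    genes: list[GeneModel] = []
    for c, L in truth.chrom_lengths.items():
        stride = max(100_000, L // 500)
        k = 0
        for start in range(1, L - 20_000, stride):
            genes.append(GeneModel(f"{c}_g{k}", c, start, start + 19_999))
            k += 1
    write_gff3_genes(genes, paths["gff3"])
    truth.to_json(paths["truth"])
    return paths
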
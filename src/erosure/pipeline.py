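"""End-to-end orchestration: read -> filter -> diversity -> ROH -> load ->
selection scan -> indicators, with every table written to disk and a
machine-readable run report.

The orchestrator adds no computation of its own: every table equals the
corresponding module call on the same inputs, and a rerun with the same
config reproduces the tables exactly.
"""

from __future__ import annotations

import itertools
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity, indicators, load, roh, selection
from .io_formats import (
    GenomicMask,
    GenotypeMatrix,
    Impact,
    SampleSheet,
    complete_case_filter,
    read_genotypes,
    read_gff3_genes,
    write_table,
)

log = logging.getLogger("erosure")


@dataclass
class RunConfig:
    """Inputs, parameters and thresholds for one pipeline run."""

    vcf: str
    sample_sheet: str
    mask_bed: str | None = None
    gff3: str | None = None
    out_dir: str = "results"
    callable_bp: float | None = None  # default: spanned genome length
    window_bp: int = 50_000
    step_bp: int = 10_000
    fst_estimator: str = "weir-cockerham"
    zcut: float = 5.0
    two_sided: bool = False
    roh_params: roh.ROHParams = field(default_factory=roh.ROHParams)
    timing: roh.ROHTimingParams = field(default_factory=roh.ROHTimingParams)
    thresholds: indicators.IndicatorThresholds = field(
        default_factory=indicators.IndicatorThresholds
    )
    rxy_blocks: int | None = None
    ne_values: dict[str, float] = field(default_factory=dict)
    populations_maintained: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, typ in (
            ("roh_params", roh.ROHParams),
            ("timing", roh.ROHTimingParams),
            ("thresholds", indicators.IndicatorThresholds),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = typ(**raw[key])
        return cls(**raw)


def _population_cohorts(gm: GenotypeMatrix) -> dict[str, tuple[int, int]]:
    """Populations sampled at two time points (>= 2 samples each)."""
    out: dict[str, tuple[int, int]] = {}
    for pop in dict.fromkeys(gm.populations):
        yrs = sorted(set(gm.years[gm.populations == pop]))
        if len(yrs) < 2:
            continue
        y1, y2 = yrs[0], yrs[-1]
        if (
            gm.sample_index(population=pop, year=y1).size >= 2
            and gm.sample_index(population=pop, year=y2).size >= 2
        ):
            out[pop] = (int(y1), int(y2))
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage on one input set and write all tables.

    Returns the run report (also written as report.json): parameters,
    per-stage row counts, and the status of every evaluated indicator.
    """
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "indicators": []}

    def stage(name: str, **info) -> None:
        log.info("stage %s: %s", name, info)
        report["stages"][name] = info

    sheet = SampleSheet.read_tsv(cfg.sample_sheet)
    mask = GenomicMask.read_bed(cfg.mask_bed) if cfg.mask_bed else None
    gm = read_genotypes(cfg.vcf, sheet, mask)
    n_raw = gm.n_sites
    gm = complete_case_filter(gm)
    stage("read", sites_raw=n_raw, sites_complete=gm.n_sites, samples=gm.n_samples)

    pops = [p for p in dict.fromkeys(gm.populations)]
    span = sum(int(gm.pos[gm.chrom == c].max()) for c in gm.chromosomes())
    callable_bp = cfg.callable_bp or float(span)

    # --- diversity -------------------------------------------------------
    het = diversity.heterozygosity_per_kb(gm, callable_bp)
    het_frame = het.rename_axis("sample_id").reset_index()
    write_table(het_frame, out / "heterozygosity.tsv")
    pi_tracks: dict[str, diversity.DiversityTrack] = {}
    for pop in pops:
        if gm.sample_index(population=pop).size < 2:
            continue
        tr = diversity.pi_windows(gm, pop, cfg.window_bp)
        tr.to_tsv(out / f"pi_{pop}.tsv")
        pi_tracks[pop] = tr
    stage("diversity", het_samples=len(het), pi_tracks=len(pi_tracks))

    # --- ROH -------------------------------------------------------------
    segments = roh.call_roh(gm, cfg.roh_params)
    seg_frame = roh.segments_to_frame(segments)
    if len(seg_frame):
        g, yrs = roh.roh_age(seg_frame["kb"].to_numpy() / 1000.0, cfg.timing)
        seg_frame["age_generations"] = g
        seg_frame["age_years"] = yrs
    write_table(seg_frame, out / "roh_segments.tsv")
    froh = roh.froh(segments, int(callable_bp), sample_ids=gm.sample_ids)
    write_table(
        froh.rename_axis("sample_id").reset_index(), out / "froh.tsv"
    )
    stage("roh", segments=len(seg_frame), mean_froh=float(froh.mean()))

    # --- load ------------------------------------------------------------
    annotated = np.isin(
        gm.impact, [int(c) for c in load.LOAD_CATEGORIES]
    ).any()
    rxy_rows: list[dict] = []
    if annotated:
        counts = load.load_counts(gm)
        table = counts.join(load.normalized_total_load(counts))
        for cat in (Impact.HIGH, Impact.MODERATE):
            try:
                table[f"realised_{cat.name}"] = load.realised_load(gm, cat)
            except ValueError:
                table[f"realised_{cat.name}"] = np.nan
        write_table(table.rename_axis("sample_id").reset_index(), out / "load.tsv")
        for (pa, pb), cat in itertools.product(
            itertools.combinations(pops, 2), (Impact.HIGH, Impact.MODERATE)
        ):
            try:
                res = load.rxy(gm, pa, pb, cat, blocks=cfg.rxy_blocks)
            except ValueError as err:
                log.info("rxy %s/%s %s skipped: %s", pa, pb, cat.name, err)
                continue
            rxy_rows.append(
                {"pop_x": pa, "pop_y": pb, **res.__dict__}
            )
        write_table(pd.DataFrame(rxy_rows), out / "rxy.tsv")
    stage("load", annotated=bool(annotated), rxy_rows=len(rxy_rows))

    # --- selection scan --------------------------------------------------
    genes = read_gff3_genes(cfg.gff3) if cfg.gff3 else []
    n_outliers = 0
    for pa, pb in itertools.combinations(pops, 2):
        if (
            gm.sample_index(population=pa).size < 2
            or gm.sample_index(population=pb).size < 2
        ):
            continue
        track = diversity.fst_windows(
            gm, pa, pb, cfg.window_bp, cfg.step_bp, cfg.fst_estimator
        )
        try:
            zt = selection.zfst(track, cfg.zcut, cfg.two_sided)
        except ValueError as err:
            log.info("scan %s/%s skipped: %s", pa, pb, err)
            continue
        zt.to_tsv(out / f"scan_{pa}_{pb}.tsv")
        n_outliers += int(zt.frame["outlier"].sum())
        if genes:
            hits = selection.intersect_genes(zt, genes)
            write_table(hits, out / f"genes_{pa}_{pb}.tsv")
    stage("scan", pairs=len(list(itertools.combinations(pops, 2))), outliers=n_outliers)

    # --- indicators ------------------------------------------------------
    reports: list[indicators.IndicatorReport] = []
    cohorts = _population_cohorts(gm)
    for pop, (y1, y2) in cohorts.items():
        years = float(y2 - y1)
        i1 = gm.sample_index(population=pop, year=y1)
        i2 = gm.sample_index(population=pop, year=y2)
        gm1, gm2 = gm.take_samples(i1), gm.take_samples(i2)
        het1 = diversity.heterozygosity_per_kb(gm1, callable_bp)
        het2 = diversity.heterozygosity_per_kb(gm2, callable_bp)
        reports.append(
            indicators.classify_delta_h(
                het1, het2, years, "loss-when-decreasing", "dHET", (pop,),
                cfg.thresholds,
            )
        )
        if i1.size >= 2 and i2.size >= 2:
            pi1 = diversity.pi_windows(gm1, pop, cfg.window_bp).values
            pi2 = diversity.pi_windows(gm2, pop, cfg.window_bp).values
            ok1, ok2 = pi1[np.isfinite(pi1)], pi2[np.isfinite(pi2)]
            if ok1.size >= 2 and ok2.size >= 2 and ok1.mean() > 0:
                reports.append(
                    indicators.classify_delta_h(
                        ok1, ok2, years, "loss-when-decreasing", "dPI", (pop,),
                        cfg.thresholds,
                    )
                )
        f1 = roh.froh(roh.call_roh(gm1, cfg.roh_params), int(callable_bp), gm1.sample_ids)
        f2 = roh.froh(roh.call_roh(gm2, cfg.roh_params), int(callable_bp), gm2.sample_ids)
        if f1.mean() > 0 and f1.size >= 2 and f2.size >= 2:
            reports.append(
                indicators.classify_delta_h(
                    f1, f2, years, "loss-when-increasing", "dFROH", (pop,),
                    cfg.thresholds,
                )
            )
    for pa, pb in itertools.combinations(cohorts, 2):
        y1 = max(cohorts[pa][0], cohorts[pb][0])
        y2 = min(cohorts[pa][1], cohorts[pb][1])
        if y1 >= y2:
            continue
        try:
            tracks = []
            for y in (cohorts[pa][0], cohorts[pa][1]):
                sub = gm.take_samples(np.flatnonzero(gm.years == y))
                tracks.append(
                    diversity.fst_windows(
                        sub, pa, pb, cfg.window_bp, cfg.window_bp, cfg.fst_estimator
                    )
                )
            reports.append(
                indicators.classify_delta_fst(
                    tracks[0],
                    tracks[1],
                    cfg.populations_maintained,
                    populations=(pa, pb),
                    thresholds=cfg.thresholds,
                )
            )
        except ValueError as err:
            log.info("dFST %s/%s skipped: %s", pa, pb, err)
    for pop, ne in cfg.ne_values.items():
        status = indicators.classify_ne(ne, cfg.thresholds)
        reports.append(
            indicators.IndicatorReport(
                indicator="Ne",
                populations=(pop,),
                period_years=0.0,
                value_t1=ne,
                value_t2=ne,
                annual_pct_change=None,
                p_ttest=None,
                p_wilcoxon=None,
                concordant=None,
                significant=None,
                status=status,
            )
        )
    ind_frame = pd.DataFrame([r.as_dict() for r in reports])
    write_table(ind_frame, out / "indicators.tsv")
    report["indicators"] = [
        {"indicator": r.indicator, "populations": list(r.populations), "status": r.status.value}
        for r in reports
    ]
    report["parameters"] = {
        "window_bp": cfg.window_bp,
        "step_bp": cfg.step_bp,
        "fst_estimator": cfg.fst_estimator,
        "zcut": cfg.zcut,
        "roh_params": asdict(cfg.roh_params),
        "timing": asdict(cfg.timing),
        "thresholds": asdict(cfg.thresholds),
        "callable_bp": callable_bp,
        "seed": cfg.seed,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
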
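"""Genetic-load accounting: carrier counts, realised load, and R_xy.

The simulation plants a 1.5x excess of High-impact derived-allele
frequencies in the North population; R_xy normalised by synonymous sites
detects the excess (R_xy > 1) while Moderate sites stay near 1.
"""

from erosure import Impact, SimConfig, load_counts, normalized_total_load, realised_load, rxy, simulate_cohorts

cfg = SimConfig(
    n_pops=2, n_diploids=15, n_sites=30_000, n_chroms=4,
    divergence_f=0.05,
    category_freq_multiplier={"HIGH": (1.5, 1.0)},  # excess in North only
    seed=4,
)
gm, truth = simulate_cohorts(cfg)

counts = load_counts(gm)
norm = normalized_total_load(counts)
print("first two samples (sites carrying >= 1 derived allele):")
print(counts.head(2).to_string())
print(f"mean High load normalised by synonymous count: {norm['HIGH_per_syn'].mean():.4f}")
print(f"mean realised High load (homozygous exposure, max 0.5): "
      f"{realised_load(gm, Impact.HIGH).mean():.4f}")

for cat in (Impact.HIGH, Impact.MODERATE):
    r = rxy(gm, "North", "South", cat, blocks=20)
    print(f"R_xy North/South [{cat.name}]: {r.ratio:.3f} "
          f"(95% CI {r.ci_low:.3f}-{r.ci_high:.3f}, {r.n_blocks} jackknife blocks)")
# R_xy > 1 for HIGH reflects the planted frequency excess in North.
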
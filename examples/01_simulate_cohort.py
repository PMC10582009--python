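"""Simulate a two-population cohort at two time points and write it to disk.

The generator draws Balding-Nichols population frequencies around uniform
ancestral frequencies (so the between-population F_ST is known), assigns
SnpEff-style impact categories, and applies a programmed 0.5 %/yr decline in
expected heterozygosity between the 1980 and 2020 cohorts.
"""

from erosure import SimConfig, simulate_cohorts, write_fixture

cfg = SimConfig(
    n_pops=2,
    n_diploids=10,
    n_sites=20_000,
    divergence_f=0.10,
    two_time_points=True,
    years_between=40,
    annual_het_change_pct=-0.5,
    seed=1,
)
gm, truth = simulate_cohorts(cfg)
paths = write_fixture(gm, truth, "scratch/example_cohort")

print(f"samples: {gm.n_samples} ({', '.join(sorted(set(gm.populations)))};"
      f" years {sorted(int(y) for y in set(gm.years))})")
print(f"sites:   {gm.n_sites} over {len(gm.chromosomes())} chromosomes")
print("files:  ", ", ".join(str(p) for p in paths.values()))
# The VCF/sample-sheet pair feeds every other example; truth.json records the
# simulated frequencies so recovery can be checked against ground truth.
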
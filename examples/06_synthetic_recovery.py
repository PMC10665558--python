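"""Parameter recovery on fully synthetic data.

Generates a 34-tip chronogram, traits with a known allometric slope, and
intraspecific specimen replicates, then runs the pipeline end to end:
summarize specimens to species medians, fit the PGLS, and check the
generating slope is recovered.
"""

import numpy as np

import phyloallom as pa

tree = pa.simulate_tree(34, birth_rate=0.05, seed=11, depth=73.0)
cfg = pa.SimulationConfig(slope=1.3, seed=11)
species = pa.simulate_allometric_traits(tree, cfg)
specimens = pa.simulate_specimens(species[["cerebellum", "cerebrum"]],
                                  {"cerebellum": 10.0, "cerebrum": 10.0},
                                  n_per_species=5, seed=12)

summary = pa.summarize_species(specimens)
x = np.log10(summary["cerebrum_median"]).rename("log_cerebrum")
y = np.log10(summary["cerebellum_median"]).rename("log_cerebellum")
fit = pa.pgls_fit(tree, x, y)
iso = pa.isometry_test(fit)

print(f"generating slope 1.30; recovered b = {fit.slope:.3f} "
      f"[{fit.ci95[0]:.3f}, {fit.ci95[1]:.3f}] -> {iso['at95']} at 95%")
mad = summary["cerebellum_mad_pct"].mean()
print(f"target intraspecific MAD 10%; recovered mean MAD% = {mad:.1f} (n=5/species;")
print("sample MAD at n=5 is biased low — it converges to the target as n grows)")
print("The CI should exclude 1: at this noise level the pipeline reliably")
print("detects hyper-allometry of the generating strength.")
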
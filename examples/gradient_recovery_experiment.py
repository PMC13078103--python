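"""Recovery experiment across the 5-site temperature gradient (reduced scale).

Runs the disturbance-replant-recovery experiment with a small ensemble
(8 members x 5 patches x 200 years to keep this example quick), then prints
the ensemble-mean percent deviation of per-tree wood carbon from the
fixed-density baseline per site, and the post-closure change in stocking.
"""

import numpy as np

from ringdemog.experiments import ExperimentConfig, relative_difference_table, run_recovery

cfg = ExperimentConfig(n_members=8, n_patches=5, recovery_years=200)
result = run_recovery(cfg, seed=1)

rel = relative_difference_table(result, "cwood_per_tree_kgC", modes=["wd-range"])
rel = rel.groupby(["site", "year"], as_index=False)["rel_diff_pct"].mean()
closure = (
    result.closure[result.closure["mode"] == "static"]
    .dropna(subset=["closure_year"])
    .groupby("site")["closure_year"]
    .mean()
)
em = result.ensemble_mean()

print(f"{'site':>7} {'dCwood/tree %':>14} {'closure yr':>10} {'dtrees/ha':>10}")
for site in sorted(rel["site"].unique()):
    sub = rel[(rel.site == site) & rel.year.between(20, 100)]
    start = int(np.ceil(closure.loc[site]))
    post = em[(em.site == site) & (em.year >= start)]
    dyn = post[post["mode"] == "wd-range"]["trees_ha"].mean()
    stat = post[post["mode"] == "static"]["trees_ha"].mean()
    print(f"{site:>7} {sub['rel_diff_pct'].mean():14.2f} {closure.loc[site]:10.1f} {dyn - stat:10.2f}")
print()
print("Sites are ordered cold (site01) to hot (site05).  Cold sites compose")
print("lighter-than-baseline wood, so dynamic-density trees carry more")
print("carbon each (positive dCwood/tree) but thin harder after closure")
print("(negative dtrees/ha); hot sites show the mirror image, and the")
print("midpoint site is nearly unaffected.")
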
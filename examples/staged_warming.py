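"""A +2 degC step applied at different canopy stages (reduced scale).

For each site one representative ensemble member (lowest RMSE of its canopy
series against the ensemble mean) is re-run with a uniform +2 degC step
switched on when the canopy is still open (10% cover) or nearly closed
(90%).  The script prints how the warming shifts the post-onset deviation
of per-tree wood carbon from the fixed-density baseline.
"""

import numpy as np

from ringdemog.experiments import ExperimentConfig, StageDefinition, run_recovery, run_warming

cfg = ExperimentConfig(n_members=8, n_patches=5, recovery_years=200)
baseline = run_recovery(cfg, seed=1)
stages = StageDefinition({"open": 0.10, "near_closed": 0.90})
warmed = run_warming(cfg, stages, delta_t=2.0, seed=1, baseline=baseline)


def post_onset_delta(frame, years, var="cwood_per_tree_kgC"):
    dyn = frame[frame["mode"] == "wd-range"].set_index("year").loc[years, var]
    stat = frame[frame["mode"] == "static"].set_index("year").loc[years, var]
    return float((100 * (dyn - stat) / stat).mean())


print(f"{'site':>7} {'stage':>12} {'onset yr':>8} {'d% unwarmed':>12} {'d% warmed':>10}")
for stage, res in warmed.items():
    for site in sorted(res.data["site"].unique()):
        w = res.data[res.data.site == site]
        member = int(w["member"].iloc[0])
        onset = int(w["onset_year"].iloc[0])
        years = np.arange(onset + 1, cfg.recovery_years + 1)
        b = baseline.data[(baseline.data.site == site) & (baseline.data.member == member)]
        print(
            f"{site:>7} {stage:>12} {onset:8d} "
            f"{post_onset_delta(b, years):12.2f} {post_onset_delta(w, years):10.2f}"
        )
print()
print("Warming pushes every site up the rising part of the density response,")
print("so rings get denser and the dynamic-density run falls further behind")
print("(or rises less above) the equally-warmed fixed-density baseline --")
print("most visibly at the warm end of the gradient.")
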
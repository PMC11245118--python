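"""Track organelles and compare mean straight velocity across conditions.

Simulates two conditions with different diffusion coefficients (a mobility
increase, as seen when the ER-anchored actin regulator is lost), tracks
the per-frame centroids, filters tracks shorter than 10 s, and summarises
per-cell mean straight velocities with a one-way ANOVA.
"""

import numpy as np
import pandas as pd

from orgdyn.chancestat import one_way_anova
from orgdyn.mobility import (
    filter_tracks,
    mean_straight_velocity,
    summarize_mobility,
    track_organelles,
)
from orgdyn.synthgen import SynthParams, simulate_trajectories

rows = []
for cond, D, base_seed in (("control", 0.0005, 0), ("KO", 0.001, 100)):
    for cell in range(8):
        p = SynthParams(
            seed=base_seed + cell,
            n_organelles=20,
            diffusion_coeff_um2_s=D,
            fission_rate_per_org_per_min=0.0,
        )
        truth = simulate_trajectories(p)
        dets = [truth.centroids_at(t) for t in range(p.n_frames)]
        tracks = filter_tracks(
            track_organelles(dets, p.frame_interval_s, max_link_um=1.0),
            min_duration_s=10.0,
        )
        for tr in tracks:
            rows.append(
                {
                    "condition": cond,
                    "cell_id": f"{cond}_{cell}",
                    "velocity_um_s": mean_straight_velocity(tr),
                }
            )

df = pd.DataFrame(rows)
summary = summarize_mobility(per_cell_velocities=df)["velocity_per_condition"]
print(summary.to_string(index=False))
groups = [
    g["cell_mean"].to_numpy()
    for _, g in summarize_mobility(per_cell_velocities=df)[
        "velocity_per_cell"
    ].groupby("condition")
]
f, pval = one_way_anova(*groups)
ctrl = summary[summary.condition == "control"]["mean"].iloc[0]
ko = summary[summary.condition == "KO"]["mean"].iloc[0]
print(f"velocity increase in KO: {100 * (ko / ctrl - 1):.0f}%  (ANOVA F={f:.1f}, p={pval:.2g})")
# Doubling D raises the mean straight velocity by roughly sqrt(2)-1 ~ 41%;
# the per-cell averages are the unit of analysis, as in live-cell practice.
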
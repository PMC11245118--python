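"""Observed AC-ER presence at fission sites versus the by-chance estimate.

Renders an enriched movie (hotspot painted at 95 % of sites over a 20 %
background), scores marker presence within 0.25 um of each detected site
during the 30 s before the split, estimates the chance probability from
the mask overlap, and runs Fisher's exact test on observed vs expected.
"""

import numpy as np

from orgdyn.chancestat import (
    binomial_test_presence,
    build_contingency,
    chance_overlap_probability,
    fisher_exact,
)
from orgdyn.fissionscan import (
    build_lineage,
    detect_fission_events,
    score_marker_presence,
)
from orgdyn.segmental import top_fraction_mask
from orgdyn.synthgen import SynthParams, render_stack, simulate_trajectories

params = SynthParams(
    seed=5,
    field_size_px=(320, 320),
    n_organelles=60,
    fission_rate_per_org_per_min=0.35,
    acer_enrichment_prob=0.95,
    acer_background_fraction=0.2,
)
truth = simulate_trajectories(params)
stack = render_stack(truth, params)
labels = truth.label_stack()

events = detect_fission_events(
    build_lineage(labels), labels, params.pixel_size_um, params.frame_interval_s
)
marker_masks = np.stack([top_fraction_mask(f) for f in stack.channel("acer")])
score_marker_presence(
    events, marker_masks, params.pixel_size_um, params.frame_interval_s,
    radius_um=0.25, window_s=30.0,
)

n = len(events)
n_present = sum(e.marker_present["marker"] for e in events)
est = chance_overlap_probability(
    stack.channel("organelle")[0], stack.channel("acer")[0]
)
table = build_contingency(n_present, n, est.p_chance)
print(f"events scored: {n}")
print(f"observed AC-ER presence: {100 * n_present / n:.1f}%")
print(f"chance overlap estimate: {100 * est.p_chance:.1f}%")
print(f"contingency table (rows observed/expected): {table.table.tolist()}")
print(f"Fisher exact p = {fisher_exact(table):.2e}")
print(f"one-sample binomial p = {binomial_test_presence(n_present, n, est.p_chance):.2e}")
# Presence near 100 % against a ~20 % chance level: the marker is at
# fission sites far more often than the organelle-overlap null predicts.
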
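"""Lineage construction and persistence-rule fission detection."""

import numpy as np
import pytest

from orgdyn import fissionscan
from orgdyn.fissionscan import (
    build_lineage,
    detect_fission_events,
    fission_rate,
    score_marker_presence,
)
from orgdyn.synthgen import SynthParams, simulate_trajectories

PX, DT = 0.04, 5.0


def _stack_from_script(script, shape=(32, 32)):
    """Build a label stack from {frame: [(label, cy, cx, r), ...]}."""
    n = max(script) + 1
    out = np.zeros((n, *shape), dtype=np.int32)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for t, objs in script.items():
        for lab, cy, cx, r in objs:
            out[t][(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = lab
    return out


def _split_script(split_frame=8, n_frames=16, remerge_at=None):
    """Parent disc splits into two daughters; optional re-merge."""
    script = {}
    for t in range(n_frames):
        if t < split_frame:
            script[t] = [(1, 16, 16, 5)]
        elif remerge_at is not None and t >= remerge_at:
            script[t] = [(4, 16, 16, 5)]
        else:
            off = 5 + min(t - split_frame, 2)
            script[t] = [(2, 16, 16 - off, 3), (3, 16, 16 + off, 3)]
    return _stack_from_script(script)


class TestLineage:
    def test_static_object_forms_single_chain(self):
        labels = _stack_from_script({t: [(1, 16, 16, 5)] for t in range(10)})
        g = build_lineage(labels)
        assert g.number_of_nodes() == 10
        assert g.number_of_edges() == 9
        assert all(g.out_degree(n) <= 1 for n in g)

    def test_vanishing_object_chain_ends(self):
        script = {t: [(1, 16, 16, 5)] for t in range(5)}
        script.update({t: [] for t in range(5, 8)})
        g = build_lineage(_stack_from_script(script))
        assert g.number_of_nodes() == 5
        assert g.out_degree((4, 1)) == 0

    def test_split_gives_out_degree_two(self):
        g = build_lineage(_split_script())
        assert g.out_degree((7, 1)) == 2

    def test_events_invariant_to_label_renumbering(self):
        labels = _split_script()
        ev1 = detect_fission_events(build_lineage(labels), labels, PX, DT)
        relab = np.where(labels > 0, labels + 7, 0)
        ev2 = detect_fission_events(build_lineage(relab), relab, PX, DT)
        assert len(ev1) == len(ev2) == 1
        assert ev1[0].split_frame == ev2[0].split_frame
        assert ev1[0].site_um == ev2[0].site_um


class TestDetection:
    def test_compliant_split_detected_with_durations(self):
        labels = _split_script(split_frame=8, n_frames=16)
        events = detect_fission_events(build_lineage(labels), labels, PX, DT)
        assert len(events) == 1
        ev = events[0]
        assert ev.split_frame == 8
        assert ev.pre_duration_s == 8 * DT
        assert ev.post_separation_s >= 30.0
        # site lies between the daughters, on the parent midline
        assert ev.site_um[0] == pytest.approx((16 + 0.5) * PX, abs=2 * PX)

    def test_kiss_and_run_rejected(self):
        # daughters re-merge 20 s (4 frames) after the split
        labels = _split_script(split_frame=8, n_frames=16, remerge_at=12)
        events = detect_fission_events(build_lineage(labels), labels, PX, DT)
        assert events == []

    def test_short_pre_history_rejected(self):
        labels = _split_script(split_frame=3, n_frames=16)
        assert (
            detect_fission_events(build_lineage(labels), labels, PX, DT) == []
        )

    def test_raising_windows_never_adds_events(self):
        labels = _split_script(split_frame=8, n_frames=16)
        lin = build_lineage(labels)
        n = [
            len(detect_fission_events(lin, labels, PX, DT, pre, post))
            for pre, post in ((10, 10), (30, 30), (40, 40), (45, 45))
        ]
        assert n == sorted(n, reverse=True)

    def test_appending_eventless_frames_changes_nothing(self):
        labels = _split_script(split_frame=8, n_frames=16)
        tail = np.repeat(labels[-1:], 5, axis=0)
        longer = np.concatenate([labels, tail])
        e1 = detect_fission_events(build_lineage(labels), labels, PX, DT)
        e2 = detect_fission_events(build_lineage(longer), longer, PX, DT)
        assert len(e1) == len(e2) == 1
        assert e1[0].split_frame == e2[0].split_frame

    def test_frame_interval_must_be_positive(self):
        labels = _split_script()
        with pytest.raises(ValueError):
            detect_fission_events(build_lineage(labels), labels, PX, 0.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_ground_truth_recovery_with_kiss_and_run(self, seed):
        """Precision = recall = 1 on true label stacks; kiss-and-run and
        fusion events yield no detections."""
        p = SynthParams(
            seed=seed,
            n_organelles=40,
            fission_rate_per_org_per_min=0.15,
            kiss_and_run_per_org_per_min=0.08,
        )
        truth = simulate_trajectories(p)
        labels = truth.label_stack()
        events = detect_fission_events(
            build_lineage(labels), labels, p.pixel_size_um, p.frame_interval_s
        )
        true_ev = truth.scheduled_fissions()
        assert len(events) == len(true_ev)
        for te in true_ev:
            assert any(
                de.split_frame == te.frame
                and np.hypot(
                    de.site_um[0] - te.site_um[0],
                    de.site_um[1] - te.site_um[1],
                )
                < 0.3
                for de in events
            )


class TestMarkerScoring:
    def test_painted_hotspot_scores_present(self):
        labels = _split_script(split_frame=8, n_frames=16)
        events = detect_fission_events(build_lineage(labels), labels, PX, DT)
        masks = np.zeros(labels.shape, dtype=bool)
        masks[5, 16, 16] = True  # at the future split site, pre-window
        score_marker_presence(events, masks, PX, DT, radius_um=0.25)
        assert events[0].marker_present["marker"] is True

    def test_empty_marker_channel_scores_absent(self):
        labels = _split_script()
        events = detect_fission_events(build_lineage(labels), labels, PX, DT)
        score_marker_presence(
            events, np.zeros(labels.shape, bool), PX, DT, radius_um=0.25
        )
        assert events[0].marker_present["marker"] is False

    def test_marker_outside_window_ignored(self):
        labels = _split_script(split_frame=8, n_frames=16)
        events = detect_fission_events(build_lineage(labels), labels, PX, DT)
        masks = np.zeros(labels.shape, bool)
        masks[10, 16, 16] = True  # after the split
        masks[0, 16, 16] = True  # 40 s before: outside the 30 s window
        score_marker_presence(
            events, masks, PX, DT, radius_um=0.25, window_s=30.0
        )
        assert events[0].marker_present["marker"] is False

    def test_subpixel_radius_rejected(self):
        with pytest.raises(ValueError):
            score_marker_presence([], np.zeros((2, 8, 8), bool), PX, DT, 0.01)


class TestRates:
    def test_rate_arithmetic(self):
        r = fission_rate([0] * 6, duration_s=300.0, n_cells=1)
        assert r["per_cell_per_5min"] == pytest.approx(6.0)
        r2 = fission_rate([0] * 12, duration_s=300.0, n_cells=1)
        assert r2["per_cell_per_5min"] == pytest.approx(12.0)

    def test_per_organelle_normalisation(self):
        r = fission_rate([0] * 6, 300.0, n_cells=2, n_organelles=30)
        assert r["per_organelle_per_min"] == pytest.approx(6 / (30 * 5))

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            fission_rate([], 0.0)
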
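"""Generator: dynamics, event bookkeeping, rendering and determinism."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from orgdyn.synthgen import (
    SynthParams,
    render_stack,
    simulate_trajectories,
)


def _params(**kw):
    base = dict(seed=0, n_organelles=10, fission_rate_per_org_per_min=0.0)
    base.update(kw)
    return SynthParams(**base)


class TestTrajectories:
    def test_zero_motion_keeps_centroids_constant(self):
        p = _params(diffusion_coeff_um2_s=0.0, drift_speed_um_s=0.0)
        truth = simulate_trajectories(p)
        for obj in truth.objects.values():
            c = np.asarray(obj.centers_um)
            assert np.allclose(c, c[0])

    def test_single_scheduled_fission_satisfies_persistence(self):
        # one organelle, high rate in a 60-frame movie: parent must exist
        # >= 6 frames before the split and daughters >= 6 frames after
        p = _params(
            n_organelles=1, fission_rate_per_org_per_min=50.0, seed=3
        )
        truth = simulate_trajectories(p)
        assert len(truth.fission_events) == 1
        ev = truth.fission_events[0]
        assert ev.frame >= p.min_pre_frames
        parent = truth.objects[ev.parent]
        assert parent.first_frame == 0
        assert parent.last_frame == ev.frame - 1
        for d in ev.daughters:
            kid = truth.objects[d]
            assert kid.first_frame == ev.frame
            assert kid.last_frame - kid.first_frame + 1 >= p.min_post_frames

    def test_msd_recovers_diffusion_coefficient(self):
        # empirical one-step MSD vs the closed form 4*D*dt (2-D), within
        # 10 %: the 3-sigma step cap costs a few percent by construction
        p = SynthParams(
            seed=7,
            field_size_px=(4096, 4096),
            n_organelles=1,
            n_frames=1001,
            diffusion_coeff_um2_s=0.01,
            fission_rate_per_org_per_min=0.0,
            photon_scale=None,
        )
        truth = simulate_trajectories(p)
        c = np.asarray(next(iter(truth.objects.values())).centers_um)
        msd = (np.diff(c, axis=0) ** 2).sum(axis=1).mean()
        assert msd == pytest.approx(4 * 0.01 * 5.0, rel=0.10)

    def test_rejects_windows_that_cannot_fit(self):
        with pytest.raises(ValueError, match="persistence"):
            simulate_trajectories(
                _params(n_frames=5, fission_rate_per_org_per_min=1.0)
            )

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            SynthParams(pixel_size_um=0.0)
        with pytest.raises(ValueError):
            SynthParams(acer_enrichment_prob=1.5)
        with pytest.raises(ValueError):
            SynthParams(fission_rate_per_org_per_min=-1)
        with pytest.raises(ValueError):
            SynthParams(
                organelle_shape="network", fission_rate_per_org_per_min=0.1
            )


class TestEventBookkeeping:
    def test_component_count_steps_at_event_frames(self):
        p = _params(
            n_organelles=30,
            fission_rate_per_org_per_min=0.12,
            kiss_and_run_per_org_per_min=0.15,
            seed=5,
        )
        truth = simulate_trajectories(p)
        masks = truth.binary_stack()
        ncomp = [ndi.label(m)[1] for m in masks]
        splits = {}
        for e in truth.fission_events:
            splits[e.frame] = splits.get(e.frame, 0) + 1
        for e in truth.fusion_events:
            splits[e.frame] = splits.get(e.frame, 0) - 1
        assert len(truth.fission_events) > 0
        assert len(truth.fusion_events) > 0  # kiss-and-run re-merges
        for t in range(1, p.n_frames):
            assert ncomp[t] - ncomp[t - 1] == splits.get(t, 0)

    def test_kiss_and_run_marked_non_compliant(self):
        p = _params(
            n_organelles=20, kiss_and_run_per_org_per_min=0.3, seed=2
        )
        truth = simulate_trajectories(p)
        kisses = [e for e in truth.fission_events if e.kiss_and_run]
        assert kisses and all(not e.rule_compliant for e in kisses)


class TestRendering:
    def test_noise_free_half_max_mask_matches_truth(self, quiet_frame):
        p, truth, stack = quiet_frame
        img = stack.channel("organelle")[0]
        mask = img > 0.5 * img.max()
        true_mask = truth.label_stack()[0] > 0
        # boundaries may differ by one pixel ring
        grown = ndi.binary_dilation(true_mask)
        shrunk = ndi.binary_erosion(true_mask)
        assert (mask & ~grown).sum() == 0
        assert (shrunk & ~mask).sum() == 0

    def test_intensity_proportional_to_area_without_noise(self):
        sums, areas = [], []
        for seed in range(3):
            p = _params(seed=seed, n_organelles=10 + 5 * seed, photon_scale=None)
            truth = simulate_trajectories(p)
            stack = render_stack(truth, p)
            sums.append(stack.channel("organelle")[0].sum())
            areas.append((truth.label_stack()[0] > 0).sum())
        ratios = np.asarray(sums) / np.asarray(areas)
        assert ratios.max() / ratios.min() < 1.02

    def test_enrichment_one_paints_every_site(self):
        p = _params(
            n_organelles=20,
            fission_rate_per_org_per_min=0.5,
            acer_enrichment_prob=1.0,
            seed=4,
        )
        truth = simulate_trajectories(p)
        stack = render_stack(truth, p)
        from orgdyn.segmental import top_fraction_mask

        acer = stack.channel("acer")
        assert truth.fission_events
        for ev in truth.fission_events:
            assert ev.acer_painted
            t = ev.frame - 1  # constriction frame
            mask = top_fraction_mask(acer[t])
            iy = int(round(ev.site_um[0] / p.pixel_size_um - 0.5))
            ix = int(round(ev.site_um[1] / p.pixel_size_um - 0.5))
            assert mask[iy - 2 : iy + 3, ix - 2 : ix + 3].any()

    def test_background_fraction_calibration(self):
        # painted AC-ER puncta should cover the configured fraction of the
        # organelle mask after top-25% thresholding, on average over seeds
        from orgdyn.segmental import isodata_threshold, top_fraction_mask

        covs = []
        for seed in range(20):
            p = _params(
                seed=seed,
                n_organelles=25,
                acer_enrichment_prob=0.0,
                acer_background_fraction=0.2,
                n_frames=4,
            )
            truth = simulate_trajectories(p)
            stack = render_stack(truth, p)
            org = stack.channel("organelle")[0]
            acer = stack.channel("acer")[0]
            om = org > isodata_threshold(org)
            am = top_fraction_mask(acer)
            covs.append((om & am).sum() / om.sum())
        assert np.mean(covs) == pytest.approx(0.20, abs=0.03)

    def test_seeded_determinism_bit_identical(self):
        p = _params(seed=9, fission_rate_per_org_per_min=0.3)
        s1 = render_stack(simulate_trajectories(p), p)
        s2 = render_stack(simulate_trajectories(p), p)
        assert np.array_equal(s1.data, s2.data)

    @pytest.mark.parametrize("shape", ["disc", "tubule", "network"])
    def test_all_shapes_render_nonempty(self, shape):
        p = SynthParams(
            seed=1,
            n_organelles=5,
            organelle_shape=shape,
            mean_radius_um=0.15 if shape != "disc" else 0.4,
            fission_rate_per_org_per_min=0.0,
            n_frames=2,
        )
        truth = simulate_trajectories(p)
        labels = truth.label_stack()
        assert len(np.unique(labels[0])) - 1 == 5
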
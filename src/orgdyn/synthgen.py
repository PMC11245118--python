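"""Synthetic organelle time-lapses with exhaustive ground truth.

The generator emulates the features of live-cell organelle imaging that the
analysis stages measure, with the simplest dynamics that exhibit them:

* organelles are hard (non-overlapping) discs, capsule-shaped tubules or
  small capsule trees ("network") that move by 2-D Brownian motion
  (per-axis step SD ``sqrt(2 D dt)``) plus optional constant drift, and
  reflect at the field boundary;
* fission splits one object into two area-conserving daughters placed
  symmetrically about the parent centre, scheduled so the parent exists as
  a single object for at least ``min_pre_s`` before the split and both
  daughters persist for at least ``min_post_s`` after it;
* kiss-and-run events are splits that re-merge after a configurable delay
  (shorter than ``min_post_s``), the false positives the persistence rule
  is designed to exclude;
* the ER-actin reporter (AC-ER) channel is a static field of uniform-height
  puncta whose union covers a configurable fraction of the field — hence of
  the organelle area — after top-fraction masking, plus hotspots painted at
  fission sites with probability ``acer_enrichment_prob`` during the
  ``min_pre_s`` window before each split;
* rendering convolves object footprints with a Gaussian PSF and applies
  Poisson shot noise at ``photon_scale`` followed by Gaussian read noise.

Every stochastic choice flows from ``SynthParams.seed``; identical
parameters give bit-identical stacks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import norm

from .stack import TimelapseStack

__all__ = [
    "SynthParams",
    "FissionTruth",
    "FusionTruth",
    "GroundTruth",
    "simulate_trajectories",
    "render_stack",
    "simulate",
    "write_dataset",
    "read_ground_truth",
]


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------
@dataclass
class SynthParams:
    """Generator configuration; defaults define the standard study movie.

    The default movie is 60 frames at 5 s (a 5-minute time-lapse) on a
    256x256 field at 0.04 um/px, with 30 vesicular organelles of ~0.4 um
    radius diffusing at 5e-4 um^2/s.  The 5 s interval makes the 30 s
    persistence rule an exact 6 frames.
    """

    field_size_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.04
    frame_interval_s: float = 5.0
    n_frames: int = 60
    n_organelles: int = 30
    organelle_shape: str = "disc"  # disc | tubule | network
    mean_radius_um: float = 0.4
    radius_cv: float = 0.2
    tubule_aspect: float = 6.0  # length / width for tubule & network branches
    diffusion_coeff_um2_s: float = 0.0005
    drift_speed_um_s: float = 0.0
    fission_rate_per_org_per_min: float = 0.1
    fusion_rate_per_org_per_min: float = 0.0
    kiss_and_run_per_org_per_min: float = 0.0
    kiss_and_run_remerge_s: float = 20.0
    min_pre_s: float = 30.0
    min_post_s: float = 30.0
    acer_enrichment_prob: float = 0.97
    acer_background_fraction: float = 0.20
    acer_punctum_radius_um: float = 0.24
    psf_sigma_um: float = 0.08
    photon_scale: float | None = 200.0
    read_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        for name in (
            "fission_rate_per_org_per_min",
            "fusion_rate_per_org_per_min",
            "kiss_and_run_per_org_per_min",
            "diffusion_coeff_um2_s",
            "drift_speed_um_s",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("acer_enrichment_prob", "acer_background_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.organelle_shape not in ("disc", "tubule", "network"):
            raise ValueError("organelle_shape must be disc, tubule or network")
        if self.organelle_shape == "network" and (
            self.fission_rate_per_org_per_min > 0
            or self.kiss_and_run_per_org_per_min > 0
        ):
            raise ValueError(
                "fission scheduling is supported for disc and tubule shapes only"
            )

    # frame-count equivalents of the persistence windows
    @property
    def min_pre_frames(self) -> int:
        return int(np.ceil(self.min_pre_s / self.frame_interval_s))

    @property
    def min_post_frames(self) -> int:
        return int(np.ceil(self.min_post_s / self.frame_interval_s))

    @property
    def field_size_um(self) -> tuple[float, float]:
        return (
            self.field_size_px[0] * self.pixel_size_um,
            self.field_size_px[1] * self.pixel_size_um,
        )


# --------------------------------------------------------------------------
# ground truth containers
# --------------------------------------------------------------------------
@dataclass
class _ObjectTrack:
    """One object's life: present on frames first_frame .. first_frame+n-1."""

    oid: int
    first_frame: int
    centers_um: list  # list of (y, x)
    radius_um: float
    shape: str = "disc"
    half_length_um: float = 0.0  # capsules: half the axis length
    orientation: float = 0.0  # radians; axis direction for capsules
    n_branches: int = 0  # network trees
    branch_angles: tuple = ()

    @property
    def last_frame(self) -> int:
        return self.first_frame + len(self.centers_um) - 1

    def center_at(self, frame: int) -> tuple[float, float]:
        return self.centers_um[frame - self.first_frame]

    def extent_um(self) -> float:
        """Circumscribing radius, for collision and boundary handling."""
        if self.shape == "disc":
            return self.radius_um
        return self.half_length_um + self.radius_um


@dataclass
class FissionTruth:
    frame: int  # first frame on which the daughters exist
    site_um: tuple[float, float]
    parent: int
    daughters: tuple[int, int]
    acer_painted: bool
    rule_compliant: bool = True
    kiss_and_run: bool = False


@dataclass
class FusionTruth:
    frame: int  # first frame on which the merged object exists
    partners: tuple[int, int]
    merged: int


@dataclass
class GroundTruth:
    """Complete bookkeeping of a simulated movie."""

    params: SynthParams
    objects: dict[int, _ObjectTrack]
    fission_events: list[FissionTruth] = field(default_factory=list)
    fusion_events: list[FusionTruth] = field(default_factory=list)

    # -- queries -----------------------------------------------------------
    def alive_at(self, frame: int) -> list[_ObjectTrack]:
        return [
            o
            for o in self.objects.values()
            if o.first_frame <= frame <= o.last_frame
        ]

    def centroids_at(self, frame: int) -> dict[int, tuple[float, float]]:
        return {o.oid: o.center_at(frame) for o in self.alive_at(frame)}

    def scheduled_fissions(self, rule_compliant_only: bool = True):
        evs = [e for e in self.fission_events if not e.kiss_and_run]
        if rule_compliant_only:
            evs = [e for e in evs if e.rule_compliant]
        return evs

    # -- rasterisation -----------------------------------------------------
    def label_stack(self, dtype=np.uint16) -> np.ndarray:
        """Per-frame true label masks: pixel value = object id (0 = bg)."""
        p = self.params
        ny, nx = p.field_size_px
        out = np.zeros((p.n_frames, ny, nx), dtype=dtype)
        for t in range(p.n_frames):
            for obj in sorted(self.alive_at(t), key=lambda o: o.oid):
                _paint_object(out[t], obj, t, p, value=obj.oid)
        return out

    def binary_stack(self) -> np.ndarray:
        return self.label_stack() > 0


# --------------------------------------------------------------------------
# rasterisation helpers (pixel coordinates are row-down, 0-based)
# --------------------------------------------------------------------------
def _paint_disc(frame: np.ndarray, cy: float, cx: float, r: float, value) -> None:
    ny, nx = frame.shape
    y0 = max(int(np.floor(cy - r)) - 1, 0)
    y1 = min(int(np.ceil(cy + r)) + 2, ny)
    x0 = max(int(np.floor(cx - r)) - 1, 0)
    x1 = min(int(np.ceil(cx + r)) + 2, nx)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    sub = frame[y0:y1, x0:x1]
    hit = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    sub[hit] = value


def _paint_capsule(
    frame: np.ndarray, cy, cx, half_len, r, theta, value
) -> None:
    """Segment of half-length ``half_len`` with round caps of radius ``r``."""
    dy, dx = np.sin(theta), np.cos(theta)
    ay, ax = cy - half_len * dy, cx - half_len * dx
    by, bx = cy + half_len * dy, cx + half_len * dx
    ny, nx = frame.shape
    pad = r + 2
    y0 = max(int(min(ay, by) - pad), 0)
    y1 = min(int(max(ay, by) + pad) + 1, ny)
    x0 = max(int(min(ax, bx) - pad), 0)
    x1 = min(int(max(ax, bx) + pad) + 1, nx)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    py, px = yy - ay, xx - ax
    vy, vx = by - ay, bx - ax
    denom = vy * vy + vx * vx
    t = np.clip((py * vy + px * vx) / denom, 0.0, 1.0) if denom > 0 else 0.0
    d2 = (py - t * vy) ** 2 + (px - t * vx) ** 2
    sub = frame[y0:y1, x0:x1]
    sub[d2 <= r**2] = value


def _paint_object(frame, obj: _ObjectTrack, t: int, p: SynthParams, value) -> None:
    cy_um, cx_um = obj.center_at(t)
    px = p.pixel_size_um
    cy, cx = cy_um / px - 0.5, cx_um / px - 0.5
    r = obj.radius_um / px
    if obj.shape == "disc":
        _paint_disc(frame, cy, cx, r, value)
    elif obj.shape == "tubule":
        _paint_capsule(
            frame, cy, cx, obj.half_length_um / px, r, obj.orientation, value
        )
    else:  # network: star of capsule branches from the centre
        for ang in obj.branch_angles:
            hl = obj.half_length_um / px
            _paint_capsule(
                frame,
                cy + hl * np.sin(ang),
                cx + hl * np.cos(ang),
                hl,
                r,
                ang,
                value,
            )


# --------------------------------------------------------------------------
# trajectory simulation
# --------------------------------------------------------------------------
def _make_object(oid, first_frame, center, radius, p: SynthParams, rng):
    shape = p.organelle_shape
    obj = _ObjectTrack(
        oid=oid,
        first_frame=first_frame,
        centers_um=[tuple(center)],
        radius_um=radius,
        shape=shape,
    )
    if shape == "tubule":
        obj.half_length_um = 0.5 * p.tubule_aspect * radius
        obj.orientation = rng.uniform(0, np.pi)
    elif shape == "network":
        obj.n_branches = int(rng.integers(3, 6))
        base = rng.uniform(0, 2 * np.pi)
        obj.branch_angles = tuple(
            base + k * 2 * np.pi / obj.n_branches for k in range(obj.n_branches)
        )
        obj.half_length_um = 0.5 * p.tubule_aspect * radius
    return obj


def _reflect(v: float, lo: float, hi: float) -> float:
    if hi <= lo:
        return 0.5 * (lo + hi)
    span = hi - lo
    v = (v - lo) % (2 * span)
    return lo + (span - abs(v - span))


def simulate_trajectories(params: SynthParams) -> GroundTruth:
    """Simulate object motion and the event schedule; returns ground truth.

    Fission and kiss-and-run counts are Poisson with mean
    ``n_organelles * rate * schedulable_window_minutes`` and are assigned to
    distinct parents at frames drawn uniformly from the window in which the
    persistence constraints can be satisfied, so the realised event rate is
    linear in the configured rate.  Raises ``ValueError`` when events are
    requested but no frame satisfies the persistence windows.
    """
    p = params
    rng = np.random.default_rng(np.random.SeedSequence([int(p.seed), 0]))
    dt = p.frame_interval_s
    step_sd = np.sqrt(2.0 * p.diffusion_coeff_um2_s * dt)
    fy_um, fx_um = p.field_size_um
    # minimum clearance between objects: three PSF sigmas, so distinct
    # organelles stay resolvable in the rendered image
    gap_um = max(3.0 * p.psf_sigma_um, 2.0 * p.pixel_size_um)
    # newborn daughters sit adjacent (separate in the label masks but much
    # closer than the hard-core gap, as real post-fission daughters are)
    birth_gap_um = 3.0 * p.pixel_size_um
    # keep objects a PSF halo away from the walls so rendered edges
    # are unaffected by the field boundary
    wall_pad_um = 3.0 * p.psf_sigma_um

    # --- initial placement (rejection sampling, hard-core) ---------------
    radii = p.mean_radius_um * np.exp(
        rng.normal(0.0, np.log1p(p.radius_cv), size=p.n_organelles)
    )
    radii = np.clip(radii, 0.5 * p.mean_radius_um, 2.5 * p.mean_radius_um)
    objects: dict[int, _ObjectTrack] = {}
    next_id = 1
    placed: list[tuple[float, float, float]] = []  # (y, x, extent)
    for i in range(p.n_organelles):
        r = float(radii[i])
        obj = _make_object(next_id, 0, (0.0, 0.0), r, p, rng)
        ext = obj.extent_um()
        for _ in range(5000):
            m = ext + wall_pad_um
            y = rng.uniform(m, max(fy_um - m, m))
            x = rng.uniform(m, max(fx_um - m, m))
            if all(
                np.hypot(y - py, x - px_) >= ext + pe + gap_um
                for py, px_, pe in placed
            ):
                break
        else:
            raise ValueError(
                "could not place organelles without overlap; "
                "reduce n_organelles or mean_radius_um"
            )
        obj.centers_um = [(y, x)]
        placed.append((y, x, ext))
        objects[next_id] = obj
        next_id += 1

    drift_dirs = {
        oid: rng.uniform(0, 2 * np.pi) for oid in list(objects.keys())
    }

    # --- event schedule ----------------------------------------------------
    pre_f, post_f = p.min_pre_frames, p.min_post_frames
    remerge_f = max(int(round(p.kiss_and_run_remerge_s / dt)), 1)
    fission_at: dict[int, int] = {}  # parent id -> split frame
    kiss_at: dict[int, int] = {}

    def _schedule(rate_per_min: float, last_ok: int, taken: set[int]) -> dict:
        lo = pre_f
        if rate_per_min == 0:
            return {}
        if lo > last_ok:
            raise ValueError(
                "scheduled events cannot satisfy persistence windows: "
                f"n_frames={p.n_frames} too small for min_pre_s/min_post_s"
            )
        window_min = (last_ok - lo + 1) * dt / 60.0
        n_ev = rng.poisson(p.n_organelles * rate_per_min * window_min)
        pool = [oid for oid in objects if oid not in taken]
        n_ev = min(n_ev, len(pool))
        parents = rng.choice(pool, size=n_ev, replace=False) if n_ev else []
        return {
            int(oid): int(rng.integers(lo, last_ok + 1)) for oid in parents
        }

    taken: set[int] = set()
    fission_at = _schedule(
        p.fission_rate_per_org_per_min, p.n_frames - post_f, taken
    )
    taken |= set(fission_at)
    kiss_at = _schedule(
        p.kiss_and_run_per_org_per_min, p.n_frames - 1 - remerge_f, taken
    )

    truth = GroundTruth(params=p, objects=objects)
    # daughters get a transient separating drift so segmentation can resolve
    # them; this mimics post-fission daughter dispersal.
    sep_speed = 0.005  # um/s along the split axis
    sep_drift: dict[int, tuple[float, float, int]] = {}  # oid -> (vy, vx, until)
    kiss_pair: dict[tuple[int, int], tuple[int, int, float]] = {}

    alive = set(objects.keys())
    for t in range(1, p.n_frames):
        # 1) scheduled splits whose daughters first exist on frame t
        for parent_map, is_kiss in ((fission_at, False), (kiss_at, True)):
            for parent, f in list(parent_map.items()):
                if f != t or parent not in alive:
                    continue
                par = objects[parent]
                cy, cx = par.center_at(t - 1)
                r_d = par.radius_um / np.sqrt(2.0)
                off = r_d + 0.5 * birth_gap_um
                if par.shape == "tubule":
                    theta = par.orientation
                else:
                    # choose the split axis that maximises daughter
                    # clearance from neighbours so true-mask components
                    # stay separable at birth
                    others = [
                        (objects[o].center_at(t - 1), objects[o].extent_um())
                        for o in alive
                        if o != parent and objects[o].first_frame < t
                    ]

                    def _margin(ang: float) -> float:
                        cu, cv = np.sin(ang), np.cos(ang)
                        m = np.inf
                        for sgn in (+1.0, -1.0):
                            dy = cy + sgn * cu * off
                            dx = cx + sgn * cv * off
                            m = min(  # clearance from the field walls
                                m,
                                dy - r_d - wall_pad_um,
                                fy_um - dy - r_d - wall_pad_um,
                                dx - r_d - wall_pad_um,
                                fx_um - dx - r_d - wall_pad_um,
                            )
                            for (oy, ox), oe in others:
                                m = min(
                                    m,
                                    np.hypot(dy - oy, dx - ox) - (r_d + oe),
                                )
                        return m

                    cands = rng.uniform(0, 2 * np.pi) + np.linspace(
                        0, np.pi, 12, endpoint=False
                    )
                    theta = float(max(cands, key=_margin))
                uy, ux = np.sin(theta), np.cos(theta)
                kids = []
                for sgn in (+1.0, -1.0):
                    ky = _reflect(
                        cy + sgn * uy * off,
                        r_d + wall_pad_um,
                        fy_um - r_d - wall_pad_um,
                    )
                    kx = _reflect(
                        cx + sgn * ux * off,
                        r_d + wall_pad_um,
                        fx_um - r_d - wall_pad_um,
                    )
                    kid = _make_object(next_id, t, (ky, kx), r_d, p, rng)
                    if par.shape == "tubule":
                        kid.orientation = par.orientation
                        kid.half_length_um = max(
                            0.5 * (par.half_length_um - r_d), 0.0
                        )
                    objects[next_id] = kid
                    drift_dirs[next_id] = drift_dirs[parent]
                    sep_drift[next_id] = (
                        sgn * uy * sep_speed,
                        sgn * ux * sep_speed,
                        t + post_f,
                    )
                    kids.append(next_id)
                    next_id += 1
                alive.discard(parent)
                alive.update(kids)
                truth.fission_events.append(
                    FissionTruth(
                        frame=t,
                        site_um=(cy, cx),
                        parent=parent,
                        daughters=(kids[0], kids[1]),
                        acer_painted=bool(
                            rng.uniform() < p.acer_enrichment_prob
                        ),
                        kiss_and_run=is_kiss,
                    )
                )
                if is_kiss:
                    kiss_pair[(kids[0], kids[1])] = (
                        t + remerge_f,
                        parent,
                        par.radius_um,
                    )

        # 2) scheduled kiss-and-run re-merges happening on frame t
        for (a, b), (fmerge, orig_parent, r_orig) in list(kiss_pair.items()):
            if fmerge != t or a not in alive or b not in alive:
                continue
            ya, xa = objects[a].center_at(t - 1)
            yb, xb = objects[b].center_at(t - 1)
            cy, cx = 0.5 * (ya + yb), 0.5 * (xa + xb)
            merged = _make_object(next_id, t, (cy, cx), r_orig, p, rng)
            objects[next_id] = merged
            drift_dirs[next_id] = drift_dirs[orig_parent]
            alive -= {a, b}
            alive.add(next_id)
            truth.fusion_events.append(
                FusionTruth(frame=t, partners=(a, b), merged=next_id)
            )
            next_id += 1
            del kiss_pair[(a, b)]

        # 3) Brownian + drift step with hard-core rejection
        order = sorted(alive)
        pos = {oid: objects[oid].center_at(t - 1) if objects[oid].first_frame < t
               else objects[oid].centers_um[-1] for oid in order}
        new_pos = dict(pos)
        for oid in order:
            if oid not in alive:
                continue  # absorbed by a fusion earlier in this frame
            obj = objects[oid]
            if obj.first_frame == t:
                continue  # daughters appear in place on their first frame
            cy, cx = pos[oid]
            # Brownian step with its norm capped at 3 sigma: organelles in
            # crowded cytoplasm do not make unbounded excursions between
            # frames (subdiffusive confinement), and the cap keeps every
            # object overlap-trackable at the frame interval
            by, bx = step_sd * rng.standard_normal(2)
            norm2 = np.hypot(by, bx)
            cap = 3.0 * step_sd
            if norm2 > cap > 0:
                by, bx = by * cap / norm2, bx * cap / norm2
            vy = by + p.drift_speed_um_s * dt * np.sin(drift_dirs[oid])
            vx = bx + p.drift_speed_um_s * dt * np.cos(drift_dirs[oid])
            if oid in sep_drift:
                sy, sx, until = sep_drift[oid]
                if t <= until:
                    vy += sy * dt
                    vx += sx * dt
            ext = obj.extent_um()
            ny = _reflect(cy + vy, ext + wall_pad_um, fy_um - ext - wall_pad_um)
            nx = _reflect(cx + vx, ext + wall_pad_um, fx_um - ext - wall_pad_um)
            collide = None
            for other in order:
                if other == oid or other not in alive:
                    continue
                oy, ox = new_pos[other]
                mind = ext + objects[other].extent_um() + gap_um
                if np.hypot(ny - oy, nx - ox) < mind:
                    collide = other
                    break
            if collide is None:
                new_pos[oid] = (ny, nx)
            else:
                # contact: optional stochastic fusion, else reject the step
                p_fuse = p.fusion_rate_per_org_per_min * dt / 60.0
                partner_is_sibling = any(
                    {oid, collide} == {a, b} for (a, b) in kiss_pair
                )
                if (
                    p_fuse > 0
                    and not partner_is_sibling
                    and objects[collide].first_frame < t
                    and rng.uniform() < p_fuse
                ):
                    a, b = objects[oid], objects[collide]
                    wa, wb = a.radius_um**2, b.radius_um**2
                    cy2 = (wa * new_pos[oid][0] + wb * new_pos[collide][0]) / (
                        wa + wb
                    )
                    cx2 = (wa * new_pos[oid][1] + wb * new_pos[collide][1]) / (
                        wa + wb
                    )
                    merged = _make_object(
                        next_id, t, (cy2, cx2), float(np.sqrt(wa + wb)), p, rng
                    )
                    objects[next_id] = merged
                    drift_dirs[next_id] = drift_dirs[oid]
                    alive -= {oid, collide}
                    alive.add(next_id)
                    truth.fusion_events.append(
                        FusionTruth(
                            frame=t, partners=(oid, collide), merged=next_id
                        )
                    )
                    new_pos[next_id] = (cy2, cx2)
                    order.append(next_id)
                    next_id += 1
                    continue
                new_pos[oid] = (cy, cx)
        for oid in sorted(alive):
            obj = objects[oid]
            if obj.first_frame < t:
                obj.centers_um.append(new_pos[oid])

    _mark_rule_compliance(truth)
    return truth


def _mark_rule_compliance(truth: GroundTruth) -> None:
    """Flag scheduled fissions whose daughters actually satisfy min_post_s."""
    p = truth.params
    post_f = p.min_post_frames
    merged_partners = {
        frozenset(e.partners): e.frame for e in truth.fusion_events
    }
    for ev in truth.fission_events:
        if ev.kiss_and_run:
            ev.rule_compliant = False
            continue
        ok = True
        for d in ev.daughters:
            if truth.objects[d].last_frame < ev.frame + post_f - 1:
                ok = False
        key = frozenset(ev.daughters)
        if key in merged_partners and merged_partners[key] < ev.frame + post_f:
            ok = False
        ev.rule_compliant = ok


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------
def _acer_effective_threshold(p: SynthParams) -> float:
    """Expected realised top-25% cut as a fraction of punctum height.

    Shot noise inflates the frame maximum above the painted plateau, which
    raises the per-frame top-fraction threshold; the correction uses the
    expected extreme of the plateau pixels (~3.5 sigma at the default
    field size).
    """
    t = 0.75
    if p.photon_scale:
        t *= 1.0 + 3.5 / np.sqrt(max(p.photon_scale, 1.0))
    return min(t, 0.95)


def _acer_background(p: SynthParams, rng, shape) -> np.ndarray:
    """Static AC-ER field: dim ER texture + uniform-height puncta.

    Punctum count solves the Poisson-union coverage identity
    ``f = 1 - exp(-n * pi * re^2 / A)`` where ``re`` is the radius of the
    post-PSF top-fraction contour of one punctum, so that the thresholded
    mask covers ``acer_background_fraction`` of the field (and hence, by
    independence, of the organelle area).
    """
    ny, nx = shape
    texture = gaussian_filter(rng.standard_normal((ny, nx)), 8.0)
    texture -= texture.min()
    if texture.max() > 0:
        texture *= 0.15 / texture.max()
    out = texture
    f = p.acer_background_fraction
    if f > 0:
        rp = p.acer_punctum_radius_um / p.pixel_size_um
        sig = p.psf_sigma_um / p.pixel_size_um
        re = rp - sig * norm.ppf(_acer_effective_threshold(p))
        re = max(re, 0.5)
        n = int(round(ny * nx * (-np.log1p(-min(f, 0.99))) / (np.pi * re**2)))
        ys = rng.uniform(0, ny, size=n)
        xs = rng.uniform(0, nx, size=n)
        puncta = np.zeros(shape)
        for y, x in zip(ys, xs):
            _paint_disc(puncta, y, x, rp, 1.0)
        out = np.maximum(out, puncta)
    return out


def _apply_noise(img: np.ndarray, p: SynthParams, rng) -> np.ndarray:
    if not p.photon_scale:
        return img
    counts = rng.poisson(np.clip(img, 0, None) * p.photon_scale).astype(float)
    if p.read_noise_sd > 0:
        counts += rng.normal(0.0, p.read_noise_sd, size=counts.shape)
    return np.clip(counts, 0.0, None) / p.photon_scale


def render_stack(truth: GroundTruth, params: SynthParams) -> TimelapseStack:
    """Render the two-channel movie (organelle, acer) from ground truth."""
    p = params
    ny, nx = p.field_size_px
    sig = p.psf_sigma_um / p.pixel_size_um
    rng = np.random.default_rng(np.random.SeedSequence([int(p.seed), 1]))
    acer_base = _acer_background(p, rng, (ny, nx))
    hot_r = p.acer_punctum_radius_um / p.pixel_size_um

    data = np.zeros((p.n_frames, 2, ny, nx), dtype=np.float64)
    pre_f = p.min_pre_frames
    for t in range(p.n_frames):
        org = np.zeros((ny, nx))
        for obj in sorted(truth.alive_at(t), key=lambda o: o.oid):
            _paint_object(org, obj, t, p, value=1.0)
        acer = acer_base.copy()
        for ev in truth.fission_events:
            if ev.acer_painted and ev.frame - pre_f <= t < ev.frame:
                cy = ev.site_um[0] / p.pixel_size_um - 0.5
                cx = ev.site_um[1] / p.pixel_size_um - 0.5
                _paint_disc(acer, cy, cx, hot_r, 1.0)
        data[t, 0] = _apply_noise(gaussian_filter(org, sig), p, rng)
        data[t, 1] = _apply_noise(gaussian_filter(acer, sig), p, rng)
    return TimelapseStack(
        data=data,
        pixel_size_um=p.pixel_size_um,
        frame_interval_s=p.frame_interval_s,
        channel_names=["organelle", "acer"],
    )


def simulate(params: SynthParams) -> tuple[GroundTruth, TimelapseStack]:
    """Convenience: trajectories + rendering in one call."""
    truth = simulate_trajectories(params)
    return truth, render_stack(truth, params)


# --------------------------------------------------------------------------
# dataset writer / reader (TIFF + JSON sidecar)
# --------------------------------------------------------------------------
def write_dataset(truth: GroundTruth, stack: TimelapseStack, outdir) -> dict:
    """Write stack.tif, labels.tif and truth.json under ``outdir``.

    The JSON sidecar schema: ``params`` (all generator parameters),
    ``objects`` (id, first_frame, radius_um, shape, per-frame centers in um)
    and ``fission_events`` / ``fusion_events`` with frames, sites and ids.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack.save(outdir / "stack.tif")
    import tifffile

    tifffile.imwrite(outdir / "labels.tif", truth.label_stack())
    doc = {
        "params": asdict(truth.params),
        "objects": [
            {
                "id": o.oid,
                "first_frame": o.first_frame,
                "radius_um": o.radius_um,
                "shape": o.shape,
                "centers_um": [list(c) for c in o.centers_um],
            }
            for o in truth.objects.values()
        ],
        "fission_events": [asdict(e) for e in truth.fission_events],
        "fusion_events": [asdict(e) for e in truth.fusion_events],
    }
    path = outdir / "truth.json"
    path.write_text(json.dumps(doc, indent=1))
    return doc


def read_ground_truth(path) -> dict:
    """Load the JSON sidecar written by :func:`write_dataset`."""
    return json.loads(Path(path).read_text())
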
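"""Fission-event detection from label lineages.

A lineage graph connects labelled objects in consecutive frames by pixel
overlap.  A fission is an out-degree >= 2 node whose parent has existed as
a single, unbranched object for at least ``min_pre_s`` and whose daughters
remain present and mutually separate for at least ``min_post_s`` — the
persistence rule that excludes organelle crossings and "kiss-and-run"
separations that re-merge.  Each event carries the split site (centroid of
the daughter interface inside the parent footprint) so that marker
channels (e.g. the AC-ER reporter, or DRP1) can be scored for presence
within a configurable radius of the site during the pre-fission window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy import ndimage as ndi

__all__ = [
    "FissionEvent",
    "build_lineage",
    "detect_fission_events",
    "score_marker_presence",
    "fission_rate",
    "events_to_frame",
]


@dataclass
class FissionEvent:
    """A detected split satisfying the persistence rule."""

    parent: tuple[int, int]  # (frame, label) of the parent's last frame
    daughters: list[tuple[int, int]]  # (frame, label) on the split frame
    split_frame: int
    site_um: tuple[float, float]
    pre_duration_s: float
    post_separation_s: float
    marker_present: dict = field(default_factory=dict)  # channel -> bool
    marker_radius_um: float | None = None


# --------------------------------------------------------------------------
# lineage graph
# --------------------------------------------------------------------------
def build_lineage(
    label_stack: np.ndarray,
    min_overlap_px: int = 1,
    strong_frac: float = 0.25,
) -> nx.DiGraph:
    """Temporal overlap graph over per-frame labels.

    Nodes are ``(frame, label)`` with an ``area`` attribute; a directed
    edge connects a label in frame ``t`` to a label in frame ``t + 1``
    when their pixel overlap is at least ``min_overlap_px``.  Edges carry
    the shared pixel count (``weight``), the overlap as a fraction of the
    smaller object (``frac``), and a ``strong`` flag
    (``frac >= strong_frac``).  Downstream, object *continuity* follows
    any overlap, while *branching* decisions (splits and merges) consider
    only strong edges, so grazing overlaps between organelles passing each
    other neither break chains nor masquerade as events.
    """
    labels = np.asarray(label_stack)
    if labels.ndim != 3:
        raise ValueError("label stack must be (frames, rows, cols)")
    g = nx.DiGraph()
    areas: list[dict[int, int]] = []
    for t in range(labels.shape[0]):
        ids, counts = np.unique(labels[t], return_counts=True)
        frame_areas = {int(i): int(c) for i, c in zip(ids, counts) if i != 0}
        areas.append(frame_areas)
        for lid, a in frame_areas.items():
            g.add_node((t, lid), area=a)
    for t in range(labels.shape[0] - 1):
        a, b = labels[t].ravel(), labels[t + 1].ravel()
        both = (a > 0) & (b > 0)
        if not both.any():
            continue
        pairs, counts = np.unique(
            np.stack([a[both], b[both]]), axis=1, return_counts=True
        )
        for (la, lb), n in zip(pairs.T, counts):
            la, lb = int(la), int(lb)
            if n < min_overlap_px:
                continue
            frac = n / min(areas[t][la], areas[t + 1][lb])
            g.add_edge(
                (t, la),
                (t + 1, lb),
                weight=int(n),
                frac=float(frac),
                strong=bool(frac >= strong_frac),
            )
    return g


def _strong_successors(g: nx.DiGraph, node):
    return [s for s in g.successors(node) if g.edges[node, s]["strong"]]


def _strong_predecessors(g: nx.DiGraph, node):
    return [s for s in g.predecessors(node) if g.edges[s, node]["strong"]]


def _chain_back_length(g: nx.DiGraph, node) -> int:
    """Frames the object has existed as a single unbranched chain,
    including ``node``'s own frame.  Ancestry follows strong edges; the
    chain ends where the object appeared, was born in a split, or where
    an ancestor branched."""
    n = 1
    cur = node
    while True:
        preds = _strong_predecessors(g, cur)
        if len(preds) != 1:
            break
        p = preds[0]
        if len(_strong_successors(g, p)) != 1:
            break
        cur = p
        n += 1
    return n


def _follow_forward(g: nx.DiGraph, node, n_steps: int):
    """Follow the maximal-overlap successor chain for up to n_steps frames;
    yields the chain nodes (excluding the start)."""
    cur = node
    for _ in range(n_steps):
        succs = list(g.successors(cur))
        if not succs:
            return
        cur = max(succs, key=lambda s: (g.edges[cur, s]["weight"], -s[1]))
        yield cur


def detect_fission_events(
    lineage: nx.DiGraph,
    label_stack: np.ndarray,
    pixel_size_um: float,
    frame_interval_s: float,
    min_pre_s: float = 30.0,
    min_post_s: float = 30.0,
) -> list[FissionEvent]:
    """Apply the persistence rule to every candidate split in the lineage.

    A node with >= 2 strong successors qualifies when (a) its unbranched
    history spans at least ``min_pre_s``, (b) every daughter is smaller
    than the parent (a continuation plus a passing organelle is not a
    split), (c) every daughter chain exists for at least ``min_post_s``
    after the split, and (d) no two daughter chains merge into a common
    label within that window (kiss-and-run exclusion).  Durations are
    frame counts times the frame interval.
    """
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be positive")
    labels = np.asarray(label_stack)
    pre_f = int(np.ceil(min_pre_s / frame_interval_s))
    post_f = int(np.ceil(min_post_s / frame_interval_s))
    events: list[FissionEvent] = []
    for node in sorted(lineage.nodes()):
        kids = sorted(_strong_successors(lineage, node), key=lambda s: s[1])
        if len(kids) < 2:
            continue
        t, parent_label = node
        split_frame = t + 1
        pre_frames = _chain_back_length(lineage, node)
        if pre_frames < pre_f:
            continue
        # a true split conserves area: each daughter must be clearly
        # smaller than the parent, otherwise one "daughter" is just the
        # parent's continuation and the other a passer-by
        parent_area = lineage.nodes[node]["area"]
        if any(
            lineage.nodes[k]["area"] > 0.95 * parent_area for k in kids
        ):
            continue
        # follow each daughter chain through the required window; a chain
        # must span the full window (split frame included) without stepping
        # into a label that another object also strongly feeds (a merge)
        window = post_f - 1
        chains = []
        ok = True
        for kid in kids:
            chain = [kid]
            for nxt in _follow_forward(lineage, kid, window):
                if len(_strong_predecessors(lineage, nxt)) > 1:
                    ok = False  # daughter merged with something
                    break
                chain.append(nxt)
            if len(chain) < post_f:
                ok = False  # vanished / merged / movie ended early
            chains.append(chain)
        # chains sharing any node means the daughters were re-joined
        seen: dict[tuple[int, int], int] = {}
        for ci, chain in enumerate(chains):
            for cnode in chain:
                if cnode in seen and seen[cnode] != ci:
                    ok = False
                seen[cnode] = ci
        if not ok:
            continue
        site = _interface_centroid(
            labels, node, [k for k in kids], pixel_size_um
        )
        events.append(
            FissionEvent(
                parent=node,
                daughters=kids,
                split_frame=split_frame,
                site_um=site,
                pre_duration_s=pre_frames * frame_interval_s,
                post_separation_s=min(len(c) for c in chains)
                * frame_interval_s,
            )
        )
    return events


def _interface_centroid(labels, parent_node, kid_nodes, pixel_size_um):
    """Centroid of the inter-daughter interface inside the parent footprint.

    Each daughter mask is dilated by one pixel; pixels where two dilated
    daughters meet, restricted to the parent's last footprint, mark the
    constriction.  Falls back to the midpoint of daughter centroids when
    the daughters do not touch the parent footprint.
    """
    t, plabel = parent_node
    parent_mask = labels[t] == plabel
    tk = kid_nodes[0][0]
    dil = []
    for _, klabel in kid_nodes:
        m = labels[tk] == klabel
        dil.append(ndi.binary_dilation(m, iterations=2))
    interface = np.zeros_like(parent_mask)
    for i in range(len(dil)):
        for j in range(i + 1, len(dil)):
            interface |= dil[i] & dil[j]
    interface &= ndi.binary_dilation(parent_mask, iterations=1)
    if interface.any():
        cy, cx = ndi.center_of_mass(interface)
    else:
        cents = [ndi.center_of_mass(labels[tk] == kl) for _, kl in kid_nodes]
        cy = float(np.mean([c[0] for c in cents]))
        cx = float(np.mean([c[1] for c in cents]))
    return ((cy + 0.5) * pixel_size_um, (cx + 0.5) * pixel_size_um)


# --------------------------------------------------------------------------
# marker scoring
# --------------------------------------------------------------------------
def score_marker_presence(
    events: list[FissionEvent],
    marker_mask_stack: np.ndarray,
    pixel_size_um: float,
    frame_interval_s: float,
    radius_um: float = 0.25,
    window_s: float = 30.0,
    channel: str = "marker",
) -> list[FissionEvent]:
    """Set ``marker_present[channel]`` for each event.

    An event is marker-positive when any pixel of the marker mask lies
    within ``radius_um`` of the split site in any frame of the
    ``window_s`` window preceding the split (the constriction period).
    """
    if radius_um < pixel_size_um:
        raise ValueError("radius_um must be at least one pixel")
    masks = np.asarray(marker_mask_stack, dtype=bool)
    r_px = radius_um / pixel_size_um
    win_f = int(np.ceil(window_s / frame_interval_s))
    ny, nx = masks.shape[1:]
    for ev in events:
        cy = ev.site_um[0] / pixel_size_um - 0.5
        cx = ev.site_um[1] / pixel_size_um - 0.5
        y0 = max(int(cy - r_px) - 1, 0)
        y1 = min(int(cy + r_px) + 2, ny)
        x0 = max(int(cx - r_px) - 1, 0)
        x1 = min(int(cx + r_px) + 2, nx)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
        t0 = max(ev.split_frame - win_f, 0)
        present = False
        for t in range(t0, ev.split_frame):
            if (masks[t, y0:y1, x0:x1] & disc).any():
                present = True
                break
        ev.marker_present[channel] = present
        ev.marker_radius_um = radius_um
    return events


# --------------------------------------------------------------------------
# rates and tabulation
# --------------------------------------------------------------------------
def fission_rate(
    events: list,
    duration_s: float,
    n_cells: int = 1,
    n_organelles: int | None = None,
) -> dict:
    """Event rates: per cell per 5-minute window, and per organelle-minute.

    The per-cell rate is the paper-style readout (events counted over a
    5-minute time-lapse); the per-organelle rate additionally normalises to
    how many organelles were at risk.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    n = len(events)
    out = {
        "n_events": n,
        "per_cell_per_5min": n / n_cells * (300.0 / duration_s),
    }
    if n_organelles:
        out["per_organelle_per_min"] = n / (
            n_organelles * duration_s / 60.0
        )
    return out


def events_to_frame(events: list[FissionEvent]):
    """Events table: one row per event (frames, site in µm, durations,
    marker flags per channel)."""
    import pandas as pd

    rows = []
    for ev in events:
        row = {
            "split_frame": ev.split_frame,
            "parent_label": ev.parent[1],
            "site_y_um": ev.site_um[0],
            "site_x_um": ev.site_um[1],
            "pre_duration_s": ev.pre_duration_s,
            "post_separation_s": ev.post_separation_s,
            "marker_radius_um": ev.marker_radius_um,
        }
        for ch, flag in ev.marker_present.items():
            row[f"marker_{ch}"] = bool(flag)
        rows.append(row)
    return pd.DataFrame(rows)
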
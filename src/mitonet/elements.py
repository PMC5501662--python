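"""Structural elements of the skeletonized mitochondrial network.

Every skeleton pixel is typed by its number of 8-connected skeleton
neighbours (1 end, 2 tubule, >=3 junction); 8-adjacent pixels of the same
type are merged into structural elements, junctions of degree >= 4 are
split into crossing tubules, and connected sets of elements form the
clusters that the topology interpreter consumes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .skeleton import S8, SkeletonGraph

END, TUBULE, JUNCTION = "end", "tubule", "junction"


@dataclass
class StructuralElement:
    id: int
    kind: str
    pixels: np.ndarray  # (k, 2) int array; ordered path for tubules; may be empty
    is_ring: bool = False  # closed tubule loop without attachments

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int).reshape(-1, 2)

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    def centroid(self) -> np.ndarray:
        if self.n_pixels == 0:
            return np.array([np.nan, np.nan])
        return self.pixels.mean(axis=0)


def _path_length(pixels: np.ndarray, close: bool = False) -> float:
    if len(pixels) < 2:
        return 0.0
    steps = np.sqrt((np.diff(pixels, axis=0) ** 2).sum(axis=1)).sum()
    if close:
        steps += float(np.hypot(*(pixels[-1] - pixels[0])))
    return float(steps)


class ElementGraph:
    """Structural elements plus their attachment structure.

    Tubules carry exactly two attachment slots (start / end of their
    pixel path), each holding the id of an end or junction element, or
    ``None`` while unresolved.  Ring tubules have no slots.  End and
    junction adjacency is derived from the tubule slots, so the graph has
    a single source of truth.
    """

    def __init__(self, pixel_size_um: float) -> None:
        self.pixel_size_um = pixel_size_um
        self.elements: dict[int, StructuralElement] = {}
        self.tubule_slots: dict[int, list[int | None]] = {}
        self._next_id = 0

    # -- construction -------------------------------------------------
    def add_element(self, kind: str, pixels, is_ring: bool = False) -> int:
        eid = self._next_id
        self._next_id += 1
        self.elements[eid] = StructuralElement(eid, kind, np.asarray(pixels, dtype=int).reshape(-1, 2), is_ring)
        if kind == TUBULE:
            self.tubule_slots[eid] = [] if is_ring else [None, None]
        return eid

    def remove_element(self, eid: int) -> None:
        del self.elements[eid]
        self.tubule_slots.pop(eid, None)

    # -- queries ------------------------------------------------------
    def ids_of_kind(self, kind: str) -> list[int]:
        return [e.id for e in self.elements.values() if e.kind == kind]

    def junction_slots(self, jid: int) -> list[tuple[int, int]]:
        """Attachment slots of a junction as (tubule_id, side) pairs."""
        out = []
        for t, slots in self.tubule_slots.items():
            for side, attached in enumerate(slots):
                if attached == jid:
                    out.append((t, side))
        return out

    def end_tubule(self, eid: int) -> tuple[int, int] | None:
        for t, slots in self.tubule_slots.items():
            for side, attached in enumerate(slots):
                if attached == eid:
                    return (t, side)
        return None

    def neighbours(self, eid: int) -> list[int]:
        el = self.elements[eid]
        if el.kind == TUBULE:
            return [a for a in self.tubule_slots[eid] if a is not None]
        return [t for t, _ in self._slots_of(eid)]

    def _slots_of(self, eid: int) -> list[tuple[int, int]]:
        return [
            (t, side)
            for t, slots in self.tubule_slots.items()
            for side, attached in enumerate(slots)
            if attached == eid
        ]

    def junction_degree(self, jid: int) -> int:
        return len(self.junction_slots(jid))

    # -- geometry helpers ---------------------------------------------
    def tubule_length_px(self, tid: int) -> float:
        el = self.elements[tid]
        return _path_length(el.pixels, close=el.is_ring)

    def slot_pixel(self, tid: int, side: int) -> np.ndarray | None:
        """Pixel of the tubule at the given slot (path start or end)."""
        px = self.elements[tid].pixels
        if len(px) == 0:
            return None
        return px[0] if side == 0 else px[-1]

    def attachment_step_px(self, tid: int, side: int) -> float:
        """Euclidean step from a tubule slot to its attached element's pixels."""
        attached = self.tubule_slots[tid][side]
        if attached is None:
            return 0.0
        other = self.elements[attached]
        p = self.slot_pixel(tid, side)
        if p is None or other.n_pixels == 0:
            return 0.0
        d = np.sqrt(((other.pixels - p) ** 2).sum(axis=1))
        return float(d.min())

    def junction_centroid(self, jid: int) -> np.ndarray:
        return self.elements[jid].centroid()

    def junction_extent_px(self, jid: int) -> float:
        """Euclidean diameter of the junction pixel set plus one pixel."""
        px = self.elements[jid].pixels
        if len(px) == 0:
            return 1.0
        if len(px) == 1:
            return 1.0
        d = np.sqrt(((px[None, :, :] - px[:, None, :]) ** 2).sum(axis=-1))
        return float(d.max()) + 1.0


# ---------------------------------------------------------------------------
# classification and merging
# ---------------------------------------------------------------------------

def _order_tubule_pixels(pixels: list[tuple[int, int]]) -> tuple[np.ndarray, bool]:
    """Order an 8-connected degree-<=2 pixel component into a path.

    Returns the ordered array and whether the component closes into a ring.
    """
    pset = set(pixels)
    if len(pixels) == 1:
        return np.array(pixels), False

    def comp_neighbours(p):
        r, c = p
        out = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr or dc) and (r + dr, c + dc) in pset:
                    out.append((r + dr, c + dc))
        return out

    endpoints = [p for p in pixels if len(comp_neighbours(p)) <= 1]
    start = min(endpoints) if endpoints else min(pixels)
    is_ring = not endpoints
    path = [start]
    visited = {start}
    cur = start
    while True:
        nxt = [p for p in comp_neighbours(cur) if p not in visited]
        if not nxt:
            break
        # prefer orthogonal steps so diagonal shortcuts do not skip pixels
        nxt.sort(key=lambda p: (abs(p[0] - cur[0]) + abs(p[1] - cur[1]), p))
        cur = nxt[0]
        path.append(cur)
        visited.add(cur)
    if len(path) != len(pixels):
        # rare 8-connectivity ambiguity: append leftovers by nearest order
        left = [p for p in pixels if p not in visited]
        for p in sorted(left):
            path.append(p)
        warnings.warn("tubule path ordering was ambiguous; appended stray pixels", stacklevel=2)
    return np.array(path), is_ring


def classify_and_merge(skel: SkeletonGraph) -> ElementGraph:
    """Type skeleton pixels by neighbour count and merge them into elements.

    Degenerate connected components without any tubule or junction pixel
    (isolated single pixels and 2-pixel segments) are represented as one
    tubule plus two zero-pixel ends so that every unbranched mitochondrion
    contributes exactly three elements.
    """
    graph = ElementGraph(skel.pixel_size_um)
    if skel.n_pixels == 0:
        return graph

    deg = skel.degrees
    skimg = skel.skel
    end_img = skimg & (deg == 1)
    tub_img = skimg & (deg == 2)
    jun_img = skimg & (deg >= 3)

    # degenerate components: all pixels of degree <= 1
    comp_lab, n_comp = ndimage.label(skimg, structure=S8)
    degen = np.zeros(n_comp + 1, dtype=bool)
    if n_comp:
        max_deg = ndimage.maximum(deg, labels=comp_lab, index=np.arange(1, n_comp + 1))
        degen[1:] = np.atleast_1d(max_deg) <= 1
    degen_img = degen[comp_lab] & skimg

    pixel_owner = np.full(skimg.shape, -1, dtype=int)

    for comp_id in np.unique(comp_lab[degen_img]):
        px = list(map(tuple, np.argwhere(comp_lab == comp_id)))
        path, _ = _order_tubule_pixels(px)
        t = graph.add_element(TUBULE, path)
        e0 = graph.add_element(END, np.empty((0, 2), dtype=int))
        e1 = graph.add_element(END, np.empty((0, 2), dtype=int))
        graph.tubule_slots[t] = [e0, e1]

    end_img &= ~degen_img
    tub_img &= ~degen_img

    def label_components(img):
        lab, n = ndimage.label(img, structure=S8)
        return lab, n

    # ends
    end_lab, n_end = label_components(end_img)
    end_ids = {}
    for i in range(1, n_end + 1):
        px = np.argwhere(end_lab == i)
        eid = graph.add_element(END, px)
        end_ids[i] = eid
        for p in map(tuple, px):
            pixel_owner[p] = eid

    # junctions
    jun_lab, n_jun = label_components(jun_img)
    jun_ids = {}
    for i in range(1, n_jun + 1):
        px = np.argwhere(jun_lab == i)
        jid = graph.add_element(JUNCTION, px)
        jun_ids[i] = jid
        for p in map(tuple, px):
            pixel_owner[p] = jid

    # tubules (ordered paths)
    tub_lab, n_tub = label_components(tub_img)
    for i in range(1, n_tub + 1):
        px = list(map(tuple, np.argwhere(tub_lab == i)))
        path, is_ring = _order_tubule_pixels(px)
        tid = graph.add_element(TUBULE, path, is_ring=is_ring)
        for p in map(tuple, path):
            pixel_owner[p] = tid
        if is_ring:
            continue
        if len(path) == 1:
            # both slots live on the same pixel: take the two distinct
            # neighbouring elements
            cands = _attachment_candidates(graph, pixel_owner, tuple(path[0]), tid)
            graph.tubule_slots[tid][0] = cands[0] if cands else None
            graph.tubule_slots[tid][1] = cands[1] if len(cands) > 1 else None
        else:
            for side, p in ((0, tuple(path[0])), (1, tuple(path[-1]))):
                graph.tubule_slots[tid][side] = _attached_element(graph, pixel_owner, p, tid)

    _absorb_corner_tubules(graph)
    _attach_bare_ends(graph, pixel_owner)
    _simplify_degenerate_junctions(graph)
    return graph


def _absorb_corner_tubules(graph: ElementGraph) -> None:
    """Merge 1-px tubules wedged inside a single junction into that junction.

    A sharp corner can rasterize as one degree-2 pixel flanked by two
    pixels of the same junction component; the pixel carries no branch of
    its own and belongs to the junction.
    """
    for tid in list(graph.tubule_slots):
        el = graph.elements.get(tid)
        if el is None or el.n_pixels != 1:
            continue
        slots = graph.tubule_slots[tid]
        if len(slots) != 2 or slots[1] is not None or slots[0] is None:
            continue
        jid = slots[0]
        if graph.elements[jid].kind != JUNCTION:
            continue
        jel = graph.elements[jid]
        jel.pixels = np.vstack([jel.pixels, el.pixels])
        graph.remove_element(tid)


def _ordered_bridge(path_a: np.ndarray, bridge: np.ndarray, path_b: np.ndarray) -> np.ndarray:
    """Order bridge pixels greedily from the end of path_a towards path_b."""
    parts = [p for p in (path_a,) if len(p)]
    remaining = [tuple(p) for p in bridge]
    cur = tuple(path_a[-1]) if len(path_a) else (tuple(path_b[0]) if len(path_b) else remaining[0])
    ordered = []
    while remaining:
        nxt = min(remaining, key=lambda q: (np.hypot(q[0] - cur[0], q[1] - cur[1]), q))
        ordered.append(nxt)
        remaining.remove(nxt)
        cur = nxt
    if ordered:
        parts.append(np.array(ordered, dtype=int))
    if len(path_b):
        parts.append(path_b)
    return np.vstack(parts) if parts else np.empty((0, 2), dtype=int)


def _simplify_degenerate_junctions(graph: ElementGraph) -> None:
    """Normalize junction elements whose attachment count is below 3.

    Pixel-level artifacts (e.g. diagonal pairs at a sharp corner) can
    produce junction components with only two attachments: these are
    certain pass-throughs, so the two tubules are merged with the
    junction pixels inserted into the path.  Junctions with fewer than
    two attachments are demoted to ends.
    """
    for jid in list(graph.ids_of_kind(JUNCTION)):
        slots = graph.junction_slots(jid)
        if len(slots) >= 3:
            continue
        jpx = graph.elements[jid].pixels
        if len(slots) == 2:
            (t1, s1), (t2, s2) = slots
            if t1 == t2:
                # one tubule attached at both sides: close it into a ring
                el = graph.elements[t1]
                el.pixels = _ordered_bridge(
                    el.pixels if s1 == 1 else el.pixels[::-1], jpx, np.empty((0, 2), int)
                )
                el.is_ring = True
                graph.tubule_slots[t1] = []
                graph.remove_element(jid)
                continue
            ea, eb = graph.elements[t1], graph.elements[t2]
            path_a = ea.pixels if s1 == 1 else ea.pixels[::-1]
            path_b = eb.pixels if s2 == 0 else eb.pixels[::-1]
            merged_px = _ordered_bridge(path_a, jpx, path_b)
            outer_a = graph.tubule_slots[t1][1 - s1]
            outer_b = graph.tubule_slots[t2][1 - s2]
            new_t = graph.add_element(TUBULE, merged_px)
            graph.tubule_slots[new_t] = [outer_a, outer_b]
            graph.remove_element(t1)
            graph.remove_element(t2)
            graph.remove_element(jid)
            if outer_a == outer_b == new_t:
                graph.elements[new_t].is_ring = True
                graph.tubule_slots[new_t] = []
        else:
            graph.elements[jid].kind = END


def _attachment_candidates(
    graph: ElementGraph, owner: np.ndarray, p: tuple[int, int], self_id: int
) -> list[int]:
    """Neighbouring elements of a pixel, junctions first, then by distance."""
    r, c = p
    cands = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if not (dr or dc):
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < owner.shape[0] and 0 <= cc < owner.shape[1]:
                oid = owner[rr, cc]
                if oid >= 0 and oid != self_id:
                    cands.append((oid, float(np.hypot(dr, dc))))
    seen: dict[int, float] = {}
    for oid, dist in cands:
        seen[oid] = min(dist, seen.get(oid, np.inf))
    return [
        oid
        for oid, _ in sorted(
            seen.items(),
            key=lambda kv: (graph.elements[kv[0]].kind != JUNCTION, kv[1], kv[0]),
        )
    ]


def _attached_element(graph: ElementGraph, owner: np.ndarray, p: tuple[int, int], self_id: int) -> int | None:
    """Element attached at a tubule endpoint, preferring junctions over ends."""
    r, c = p
    cands = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if not (dr or dc):
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < owner.shape[0] and 0 <= cc < owner.shape[1]:
                oid = owner[rr, cc]
                if oid >= 0 and oid != self_id:
                    dist = float(np.hypot(dr, dc))
                    cands.append((oid, dist))
    if not cands:
        return None
    seen: dict[int, float] = {}
    for oid, dist in cands:
        seen[oid] = min(dist, seen.get(oid, np.inf))
    order = sorted(
        seen.items(),
        key=lambda kv: (graph.elements[kv[0]].kind != JUNCTION, kv[1], kv[0]),
    )
    # a tubule endpoint should touch exactly one foreign element; when both a
    # junction and an end touch it, the junction owns the slot
    taken = {a for slots in graph.tubule_slots.values() for a in slots if a is not None}
    for oid, _ in order:
        el = graph.elements[oid]
        if el.kind == END and oid in taken:
            continue
        return oid
    return order[0][0]


def _attach_bare_ends(graph: ElementGraph, owner: np.ndarray) -> None:
    """Insert zero-length tubules between ends attached directly to junctions."""
    attached = {a for slots in graph.tubule_slots.values() for a in slots if a is not None}
    for eid in graph.ids_of_kind(END):
        if eid in attached or graph.elements[eid].n_pixels == 0:
            continue
        p = tuple(graph.elements[eid].pixels[0])
        r, c = p
        target = None
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if not (dr or dc):
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < owner.shape[0] and 0 <= cc < owner.shape[1]:
                    oid = owner[rr, cc]
                    if oid >= 0 and oid != eid and graph.elements[oid].kind == JUNCTION:
                        target = oid
        if target is not None:
            t = graph.add_element(TUBULE, np.empty((0, 2), dtype=int))
            graph.tubule_slots[t] = [eid, target]


# ---------------------------------------------------------------------------
# 4-way junction splitting
# ---------------------------------------------------------------------------

def _slot_direction(graph: ElementGraph, jid: int, tid: int, side: int) -> np.ndarray | None:
    """Outgoing branch direction at a junction, from the first pixels of the tubule."""
    cj = graph.junction_centroid(jid)
    px = graph.elements[tid].pixels
    if len(px) == 0:
        other = graph.tubule_slots[tid][1 - side]
        if other is None or graph.elements[other].n_pixels == 0:
            return None
        v = graph.elements[other].centroid() - cj
    else:
        pts = px[:5] if side == 0 else px[::-1][:5]
        pts = np.asarray(pts, dtype=float)
        if len(pts) == 1:
            v = pts[0] - cj
        else:
            centered = pts - pts.mean(axis=0)
            _, _, vt = np.linalg.svd(centered, full_matrices=False)
            v = vt[0]
            if np.dot(v, pts.mean(axis=0) - cj) < 0:
                v = -v
    n = np.linalg.norm(v)
    return v / n if n > 0 else None


def _pairing_cost(d1: np.ndarray | None, d2: np.ndarray | None) -> float:
    if d1 is None or d2 is None:
        return np.pi / 2  # unknown direction: neutral cost
    cos = float(np.clip(np.dot(d1, d2), -1.0, 1.0))
    return np.pi - np.arccos(cos)  # 0 when branches are exactly opposite


def _perfect_matchings(items: list) -> list[list[tuple]]:
    if not items:
        return [[]]
    first, rest = items[0], items[1:]
    out = []
    for i, other in enumerate(rest):
        for sub in _perfect_matchings(rest[:i] + rest[i + 1 :]):
            out.append([(first, other)] + sub)
    return out


def split_four_way(graph: ElementGraph) -> ElementGraph:
    """Split junctions of degree >= 4 into pass-through crossing tubules.

    Branches are paired by maximal collinearity (minimum summed angular
    deviation between paired branch directions); a 4-way crossing thus
    resolves into two independent tubules.  Odd degrees >= 5 are paired
    greedily until three branches remain as a residual 3-way junction.
    """
    for jid in list(graph.ids_of_kind(JUNCTION)):
        slots = graph.junction_slots(jid)
        if len(slots) < 4:
            continue
        dirs = {s: _slot_direction(graph, jid, *s) for s in slots}
        if len(slots) % 2 == 0:
            best = min(
                _perfect_matchings(slots),
                key=lambda m: sum(_pairing_cost(dirs[a], dirs[b]) for a, b in m),
            )
            pairs = best
            residual = []
        else:
            warnings.warn(
                f"junction {jid} has odd degree {len(slots)}; pairing greedily", stacklevel=2
            )
            pairs = []
            remaining = list(slots)
            while len(remaining) > 3:
                a, b = min(
                    itertools.combinations(remaining, 2),
                    key=lambda ab: _pairing_cost(dirs[ab[0]], dirs[ab[1]]),
                )
                pairs.append((a, b))
                remaining.remove(a)
                remaining.remove(b)
            residual = remaining
        _apply_pairs(graph, jid, pairs, keep_junction=bool(residual))
    return graph


def _apply_pairs(graph: ElementGraph, jid: int, pairs, keep_junction: bool) -> None:
    redirect: dict[tuple[int, int], tuple[int, int]] = {}

    def resolve(slot):
        while slot in redirect:
            slot = redirect[slot]
        return slot

    for a, b in pairs:
        (ta, sa), (tb, sb) = resolve(a), resolve(b)
        if ta == tb:
            # loop attached twice to the crossing: closes into a ring
            el = graph.elements[ta]
            el.is_ring = True
            graph.tubule_slots[ta] = []
            continue
        ea, eb = graph.elements[ta], graph.elements[tb]
        path_a = ea.pixels if sa == 1 else ea.pixels[::-1]  # oriented to end at jid
        path_b = eb.pixels if sb == 0 else eb.pixels[::-1]  # oriented to start at jid
        merged_px = np.vstack([path_a, path_b]) if len(path_a) or len(path_b) else np.empty((0, 2), int)
        outer_a = graph.tubule_slots[ta][1 - sa]
        outer_b = graph.tubule_slots[tb][1 - sb]
        new_t = graph.add_element(TUBULE, merged_px)
        graph.tubule_slots[new_t] = [outer_a, outer_b]
        redirect[(ta, 1 - sa)] = (new_t, 0)
        redirect[(tb, 1 - sb)] = (new_t, 1)
        graph.remove_element(ta)
        graph.remove_element(tb)
        if outer_a == outer_b == new_t:  # the two outer slots met: closed ring
            graph.elements[new_t].is_ring = True
            graph.tubule_slots[new_t] = []
    if not keep_junction:
        graph.remove_element(jid)


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    """Connected set of structural elements analysed as one unit."""

    graph: ElementGraph
    element_ids: frozenset[int]

    @property
    def elements(self) -> list[StructuralElement]:
        return [self.graph.elements[i] for i in sorted(self.element_ids)]

    def ids_of_kind(self, kind: str) -> list[int]:
        return [i for i in sorted(self.element_ids) if self.graph.elements[i].kind == kind]

    @property
    def n_ends(self) -> int:
        return len(self.ids_of_kind(END))

    @property
    def n_tubules(self) -> int:
        return len(self.ids_of_kind(TUBULE))

    @property
    def n_junctions(self) -> int:
        return len(self.ids_of_kind(JUNCTION))

    @property
    def n_elements(self) -> int:
        return len(self.element_ids)

    @property
    def is_ring(self) -> bool:
        return self.n_elements == 1 and all(
            self.graph.elements[i].is_ring for i in self.element_ids
        )

    def all_pixels(self) -> np.ndarray:
        arrs = [self.graph.elements[i].pixels for i in sorted(self.element_ids)]
        arrs = [a for a in arrs if len(a)]
        return np.vstack(arrs) if arrs else np.empty((0, 2), dtype=int)

    def bounding_box(self) -> tuple[int, int, int, int]:
        """(row_min, col_min, row_max, col_max), exclusive upper bounds."""
        px = self.all_pixels()
        if len(px) == 0:
            return (0, 0, 0, 0)
        return (
            int(px[:, 0].min()),
            int(px[:, 1].min()),
            int(px[:, 0].max()) + 1,
            int(px[:, 1].max()) + 1,
        )

    def total_length_px(self) -> float:
        """Tubule path length plus the steps linking tubules to their ends."""
        g = self.graph
        total = 0.0
        for t in self.ids_of_kind(TUBULE):
            total += g.tubule_length_px(t)
            for side, attached in enumerate(g.tubule_slots[t]):
                if attached is not None and g.elements[attached].kind == END:
                    total += g.attachment_step_px(t, side)
        return total

    def total_length_um(self) -> float:
        return self.total_length_px() * self.graph.pixel_size_um

    def junction_degree_sum(self) -> int:
        return sum(self.graph.junction_degree(j) for j in self.ids_of_kind(JUNCTION))


def extract_clusters(graph: ElementGraph) -> list[Cluster]:
    """Connected components of the element graph."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(graph.elements)
    for t, slots in graph.tubule_slots.items():
        for attached in slots:
            if attached is not None:
                g.add_edge(t, attached)
    comps = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    return [Cluster(graph, frozenset(c)) for c in comps]


def filter_dense_clusters(
    clusters: list[Cluster],
    mask,
    max_area_fraction: float = 0.6,
    pad_px: int = 10,
) -> tuple[list[Cluster], list[Cluster], float]:
    """Exclude clusters lying in regions of excessive mitochondrial density.

    Skeletonization is unreliable where mitochondria cover most of the
    local area, so a cluster is dropped when the foreground fraction of
    its bounding box exceeds ``max_area_fraction``.  The box is padded by
    ``pad_px`` (about one apparent mitochondrion width) so that the
    fraction measures neighbourhood density rather than the trivially
    full tight box of a thin straight cluster.  Returns (kept, excluded,
    excluded percent of all clusters).
    """
    from .segmentation import area_fraction

    h, w = mask.shape
    kept, excluded = [], []
    for cl in clusters:
        r0, c0, r1, c1 = cl.bounding_box()
        if r1 <= r0:
            kept.append(cl)
            continue
        bbox = (max(r0 - pad_px, 0), max(c0 - pad_px, 0), min(r1 + pad_px, h), min(c1 + pad_px, w))
        frac = area_fraction(mask, bbox)
        (excluded if frac > max_area_fraction else kept).append(cl)
    pct = 100.0 * len(excluded) / len(clusters) if clusters else 0.0
    return kept, excluded, pct


# ---------------------------------------------------------------------------
# connectivity metrics and shape classes
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityMetrics:
    """Image-level connectivity summary over a set of clusters."""

    n_ends: int
    n_tubules: int
    n_junctions: int
    pct_ends: float
    pct_tubules: float
    pct_junctions: float
    elements_per_cluster: float  # E_C
    j_over_e: float  # junctions / ends (nan when no ends)
    t_over_e: float
    connections_per_um: float  # summed junction degree / total length
    total_length_um: float
    n_clusters: int
    donut_count: int = 0
    blob_count: int = 0
    blob_area_px: int = 0
    isolated_1_2um_count: int = 0
    n_rings: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def detect_donuts(cluster: Cluster) -> int:
    """Count donuts: a junction attached twice to one tubule, with its
    third attachment leading to a mitochondrial end."""
    g = cluster.graph
    count = 0
    for j in cluster.ids_of_kind(JUNCTION):
        slots = g.junction_slots(j)
        if len(slots) != 3:
            continue
        tubules = [t for t, _ in slots]
        for t in set(tubules):
            if tubules.count(t) == 2:
                (t3,) = [x for x in tubules if x != t] or [None]
                if t3 is None:
                    continue
                other_side = [
                    g.tubule_slots[t3][1 - side] for tt, side in slots if tt == t3
                ]
                if other_side and other_side[0] is not None:
                    if g.elements[other_side[0]].kind == END:
                        count += 1
                break
    return count


def detect_blobs(
    clusters: list[Cluster],
    pixel_size_um: float,
    mask=None,
) -> tuple[int, int, int]:
    """Count blobs and short isolated mitochondria.

    A blob is an isolated cluster of three elements (one tubule, two
    ends) with total length below 1 um; clusters of the same composition
    with length in [1, 2) um are counted separately.  Blob area is the
    mask foreground within blob bounding boxes (skeleton pixel count when
    no mask is supplied).
    """
    blob_count = blob_area = isolated_1_2 = 0
    for cl in clusters:
        if not (cl.n_elements == 3 and cl.n_tubules == 1 and cl.n_ends == 2):
            continue
        length = cl.total_length_um()
        if length < 1.0:
            blob_count += 1
            if mask is not None:
                r0, c0, r1, c1 = cl.bounding_box()
                blob_area += int(mask.mask[r0:r1, c0:c1].sum())
            else:
                blob_area += len(cl.all_pixels())
        elif length < 2.0:
            isolated_1_2 += 1
    return blob_count, blob_area, isolated_1_2


def connectivity_metrics(
    clusters: list[Cluster],
    pixel_size_um: float | None = None,
    mask=None,
) -> ConnectivityMetrics:
    """Compute counts, percentages, E_C, J/E, T/E and connections per um."""
    if not clusters:
        raise ValueError("connectivity_metrics requires at least one cluster")
    px_um = pixel_size_um if pixel_size_um is not None else clusters[0].graph.pixel_size_um
    E = sum(c.n_ends for c in clusters)
    T = sum(c.n_tubules for c in clusters)
    J = sum(c.n_junctions for c in clusters)
    total = E + T + J
    total_len_um = sum(c.total_length_px() for c in clusters) * px_um
    degree_sum = sum(c.junction_degree_sum() for c in clusters)
    blob_count, blob_area, iso12 = detect_blobs(clusters, px_um, mask=mask)
    return ConnectivityMetrics(
        n_ends=E,
        n_tubules=T,
        n_junctions=J,
        pct_ends=100.0 * E / total if total else 0.0,
        pct_tubules=100.0 * T / total if total else 0.0,
        pct_junctions=100.0 * J / total if total else 0.0,
        elements_per_cluster=float(np.mean([c.n_elements for c in clusters])),
        j_over_e=(J / E) if E > 0 else float("nan"),
        t_over_e=(T / E) if E > 0 else float("nan"),
        connections_per_um=degree_sum / total_len_um if total_len_um > 0 else float("nan"),
        total_length_um=total_len_um,
        n_clusters=len(clusters),
        donut_count=sum(detect_donuts(c) for c in clusters),
        blob_count=blob_count,
        blob_area_px=blob_area,
        isolated_1_2um_count=iso12,
        n_rings=sum(1 for c in clusters if c.is_ring),
    )
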
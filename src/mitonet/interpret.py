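"""Probabilistic interpretation of cluster topology.

A cluster of overlapping mitochondria admits many topologies: at every
junction the branches may pass through one another, terminate, or fuse
into a genuine branch point.  Each junction is therefore given a table of
local connection patterns with equal probability; a joint choice of one
pattern per junction is an interpretation, which resolves the cluster
into individual mitochondrion paths with definite lengths.  Averaging the
length histograms of many interpretations yields the cluster's length
distribution with a per-bin SD quantifying topological ambiguity.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from importlib import resources
from itertools import product

import numpy as np

from .distributions import LengthDistribution, histogram_mass, make_bin_edges
from .elements import END, JUNCTION, TUBULE, Cluster, ElementGraph, StructuralElement

DEFAULT_N_SAMPLES = 1000
MAX_EXACT_LEAVES = 10_000


@dataclass(frozen=True)
class LocalPattern:
    """One admissible local connection pattern for a structural element.

    ``links`` lists slot pairs that connect; ``terminated`` lists slots
    where the mitochondrion stops at the element.  A slot may appear in
    several links (a fused true junction) but every slot is covered.
    """

    label: str
    links: tuple[tuple[int, int], ...]
    terminated: tuple[int, ...]


class InterpretationTable:
    """Per-degree lists of admissible local patterns, uniformly weighted."""

    def __init__(self, patterns_by_degree: dict[int, list[LocalPattern]]):
        self._patterns = dict(patterns_by_degree)
        for degree, pats in self._patterns.items():
            for p in pats:
                covered = {s for link in p.links for s in link} | set(p.terminated)
                if covered != set(range(degree)):
                    raise ValueError(f"pattern {p.label} does not cover all {degree} slots")

    @classmethod
    def from_json(cls, source) -> "InterpretationTable":
        raw = json.loads(source) if isinstance(source, str) else json.load(source)
        table = {
            int(deg): [
                LocalPattern(
                    p["label"],
                    tuple(tuple(link) for link in p["links"]),
                    tuple(p["terminated"]),
                )
                for p in pats
            ]
            for deg, pats in raw.items()
        }
        return cls(table)

    @classmethod
    def default(cls) -> "InterpretationTable":
        data = resources.files("mitonet.data").joinpath("junction_patterns.json").read_text()
        return cls.from_json(data)

    # degenerate junction degrees produced by thick skeleton nodes: a
    # degree-2 junction is a certain pass-through connector, a degree-1
    # junction a certain termination
    _BUILTIN = {
        0: [LocalPattern("empty", (), ())],
        1: [LocalPattern("terminate", (), (0,))],
        2: [LocalPattern("pass_through", ((0, 1),), ())],
    }

    def patterns(self, degree: int) -> list[LocalPattern]:
        if degree in self._patterns:
            return self._patterns[degree]
        if degree in self._BUILTIN:
            return self._BUILTIN[degree]
        raise KeyError(f"no interpretation patterns configured for degree {degree}")

    def supported_degrees(self) -> list[int]:
        return sorted(self._patterns)

    def table_hash(self) -> str:
        payload = json.dumps(
            {
                d: [(p.label, p.links, p.terminated) for p in pats]
                for d, pats in sorted(self._patterns.items())
            },
            default=list,
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def enumerate_local_interpretations(
    element: StructuralElement,
    table: InterpretationTable,
    graph: ElementGraph,
) -> list[LocalPattern]:
    """Admissible local patterns for one element, uniformly weighted.

    Ends always terminate; tubule interiors always pass through; junction
    patterns come from the table, keyed by junction degree.
    """
    if element.kind == END:
        return [LocalPattern("terminate", (), (0,))]
    if element.kind == TUBULE:
        return [LocalPattern("pass_through", ((0, 1),), ())]
    return table.patterns(graph.junction_degree(element.id))


@dataclass
class Interpretation:
    """One admissible resolution of a cluster into mitochondrion paths."""

    choices: dict[int, int]  # junction id -> pattern index
    paths: list[frozenset[int]]  # element ids per mitochondrion
    lengths_px: list[float]

    @property
    def n_paths(self) -> int:
        return len(self.paths)


class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def _sorted_junction_slots(graph: ElementGraph, jid: int) -> list[tuple[int, int]]:
    return sorted(graph.junction_slots(jid))


def _slot_anchor(graph: ElementGraph, jid: int, tid: int, side: int) -> np.ndarray:
    p = graph.slot_pixel(tid, side)
    if p is not None:
        return np.asarray(p, dtype=float)
    other = graph.tubule_slots[tid][1 - side] if graph.tubule_slots[tid] else None
    if other is not None and graph.elements[other].n_pixels:
        return graph.elements[other].centroid()
    return graph.junction_centroid(jid)


def realize_interpretation(
    cluster: Cluster, table: InterpretationTable, choices: dict[int, int]
) -> Interpretation:
    """Resolve a per-junction pattern choice into paths and pixel lengths."""
    g = cluster.graph
    tubules = cluster.ids_of_kind(TUBULE)
    junctions = cluster.ids_of_kind(JUNCTION)
    uf = _UnionFind(tubules)
    extra_len: dict[int, float] = {t: 0.0 for t in tubules}
    junction_members: dict[int, set[int]] = {}

    for jid in junctions:
        slots = _sorted_junction_slots(g, jid)
        pattern = table.patterns(len(slots))[choices[jid]]
        members: set[int] = set()
        # connected groups of slots under the pattern's links: a pair is a
        # pass-through, a larger group a fused true junction
        slot_uf = _UnionFind(range(len(slots)))
        for a, b in pattern.links:
            slot_uf.union(a, b)
        groups: dict[int, list[int]] = {}
        linked = {s for link in pattern.links for s in link}
        for s in linked:
            groups.setdefault(slot_uf.find(s), []).append(s)
        for group in groups.values():
            anchors = [_slot_anchor(g, jid, *slots[s]) for s in group]
            if len(group) == 2:
                contrib = float(np.hypot(*(anchors[0] - anchors[1])))
            else:  # fused: each branch reaches the junction centre
                cj = g.junction_centroid(jid)
                contrib = float(sum(np.hypot(*(a - cj)) for a in anchors))
            first_t = slots[group[0]][0]
            for s in group[1:]:
                uf.union(first_t, slots[s][0])
            extra_len[first_t] += contrib
            members.update(slots[s][0] for s in group)
        for s in pattern.terminated:
            t, _side = slots[s]
            extra_len[t] += g.junction_extent_px(jid) / 2.0
        junction_members[jid] = members

    # group tubules into paths
    groups: dict[int, set[int]] = {}
    for t in tubules:
        groups.setdefault(uf.find(t), set()).add(t)

    paths, lengths = [], []
    for members in groups.values():
        elems = set(members)
        length = 0.0
        for t in members:
            length += g.tubule_length_px(t) + extra_len[t]
            for side, attached in enumerate(g.tubule_slots[t]):
                if attached is not None and g.elements[attached].kind == END:
                    elems.add(attached)
                    length += g.attachment_step_px(t, side)
        for jid, jm in junction_members.items():
            if jm & members:
                elems.add(jid)
        paths.append(frozenset(elems))
        lengths.append(length)
    order = np.argsort([min(p) for p in paths])
    return Interpretation(
        dict(choices),
        [paths[i] for i in order],
        [lengths[i] for i in order],
    )


def _n_leaves(cluster: Cluster, table: InterpretationTable) -> float:
    g = cluster.graph
    n = 1.0
    for jid in cluster.ids_of_kind(JUNCTION):
        n *= len(table.patterns(g.junction_degree(jid)))
        if n > 1e12:
            break
    return n


def sample_interpretations(
    cluster: Cluster,
    table: InterpretationTable | None = None,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int | np.random.Generator | None = None,
) -> list[Interpretation]:
    """Draw interpretations by choosing one pattern per junction uniformly.

    With the default table every joint choice is admissible, so the
    sampling tree has no pruned leaves; junction-free clusters have a
    single interpretation.  Reproducible for a fixed seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    table = table or InterpretationTable.default()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    junctions = cluster.ids_of_kind(JUNCTION)
    if not junctions:
        interp = realize_interpretation(cluster, table, {})
        return [interp] * n_samples
    sizes = {j: len(table.patterns(cluster.graph.junction_degree(j))) for j in junctions}
    out = []
    for _ in range(n_samples):
        choices = {j: int(rng.integers(sizes[j])) for j in junctions}
        out.append(realize_interpretation(cluster, table, choices))
    return out


def brute_force_enumerate(
    cluster: Cluster,
    table: InterpretationTable | None = None,
    bin_edges: np.ndarray | None = None,
    max_leaves: float = 1e6,
) -> LengthDistribution:
    """Exact cluster distribution by exhaustive enumeration (testing oracle)."""
    table = table or InterpretationTable.default()
    bin_edges = bin_edges if bin_edges is not None else make_bin_edges()
    if _n_leaves(cluster, table) > max_leaves:
        raise ValueError("cluster too large for exhaustive enumeration")
    g = cluster.graph
    junctions = cluster.ids_of_kind(JUNCTION)
    sizes = [len(table.patterns(g.junction_degree(j))) for j in junctions]
    px_um = g.pixel_size_um
    masses, counts = [], []
    for combo in product(*[range(s) for s in sizes]):
        interp = realize_interpretation(cluster, table, dict(zip(junctions, combo)))
        lengths_um = np.asarray(interp.lengths_px) * px_um
        masses.append(histogram_mass(lengths_um, bin_edges))
        counts.append(interp.n_paths)
    masses = np.asarray(masses)
    return LengthDistribution(
        bin_edges,
        masses.mean(axis=0),
        masses.std(axis=0),
        float(np.mean(counts)),
    )


def interpretation_lengths(interp: Interpretation, pixel_size_um: float) -> list[float]:
    """Mitochondrion lengths of one interpretation, in micrometres."""
    return [l * pixel_size_um for l in interp.lengths_px]


def cluster_distribution(
    samples: list[Interpretation],
    pixel_size_um: float,
    bin_edges: np.ndarray | None = None,
) -> LengthDistribution:
    """Average the normalized per-sample length histograms.

    The per-bin SD across samples is the topological-ambiguity confidence
    band; the expected mitochondrion count is the mean number of paths.
    """
    if not samples:
        raise ValueError("need at least one sampled interpretation")
    bin_edges = bin_edges if bin_edges is not None else make_bin_edges()
    masses = np.asarray(
        [
            histogram_mass(np.asarray(s.lengths_px) * pixel_size_um, bin_edges)
            for s in samples
        ]
    )
    return LengthDistribution(
        bin_edges,
        masses.mean(axis=0),
        masses.std(axis=0),
        float(np.mean([s.n_paths for s in samples])),
    )


def interpret_cluster(
    cluster: Cluster,
    table: InterpretationTable | None = None,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int | np.random.Generator | None = None,
    bin_edges: np.ndarray | None = None,
    max_exact_leaves: int = MAX_EXACT_LEAVES,
) -> LengthDistribution:
    """Cluster length distribution: exact when the interpretation tree is
    small (<= ``max_exact_leaves`` leaves), sampled otherwise."""
    table = table or InterpretationTable.default()
    bin_edges = bin_edges if bin_edges is not None else make_bin_edges()
    if _n_leaves(cluster, table) <= max_exact_leaves:
        return brute_force_enumerate(cluster, table, bin_edges, max_leaves=max_exact_leaves)
    samples = sample_interpretations(cluster, table, n_samples, seed)
    return cluster_distribution(samples, cluster.graph.pixel_size_um, bin_edges)


def image_distribution(cluster_dists: list[LengthDistribution]) -> LengthDistribution:
    """Combine cluster distributions into the image-level distribution.

    Cluster profiles are weighted by their expected mitochondrion count
    and renormalized; per-bin SDs combine as the count-weighted
    root-mean-square over clusters (clusters are independent).
    """
    if not cluster_dists:
        raise ValueError("no cluster distributions to combine")
    base = cluster_dists[0]
    for d in cluster_dists[1:]:
        if not base.same_bins(d):
            raise ValueError("cluster distributions must share bin edges")
    w = np.array([d.expected_count for d in cluster_dists])
    total = w.sum()
    if total <= 0:
        raise ValueError("total expected mitochondria is zero")
    mass = np.sum([wi * d.mass for wi, d in zip(w, cluster_dists)], axis=0) / total
    norm = mass.sum()
    if norm > 0:
        mass = mass / norm
    sd = np.sqrt(np.sum([(wi * d.sd) ** 2 for wi, d in zip(w, cluster_dists)], axis=0)) / total
    return LengthDistribution(base.bin_edges, mass, sd, float(total))


# ---------------------------------------------------------------------------
# deterministic length variants (the two extremes the probabilistic
# distribution falls between)
# ---------------------------------------------------------------------------

def branchpoint_lengths(cluster: Cluster, pixel_size_um: float | None = None) -> list[float]:
    """Every tubule is its own mitochondrion (branch-to-branch distances)."""
    g = cluster.graph
    px_um = pixel_size_um if pixel_size_um is not None else g.pixel_size_um
    out = []
    for t in cluster.ids_of_kind(TUBULE):
        length = g.tubule_length_px(t)
        for side, attached in enumerate(g.tubule_slots[t]):
            if attached is None:
                continue
            if g.elements[attached].kind == END:
                length += g.attachment_step_px(t, side)
            else:
                length += g.junction_extent_px(attached) / 2.0
        out.append(length * px_um)
    return sorted(out, reverse=True)


def _path_length_px(g: ElementGraph, seq: list[tuple[int, int]]) -> float:
    """Length of a tubule sequence [(tubule, entry_side), ...]."""
    total = 0.0
    for i, (t, entry) in enumerate(seq):
        total += g.tubule_length_px(t)
        for side, attached in enumerate(g.tubule_slots[t]):
            if attached is None:
                continue
            kind = g.elements[attached].kind
            interior = (i > 0 and side == entry) or (i < len(seq) - 1 and side != entry)
            if kind == END:
                total += g.attachment_step_px(t, side)
            elif kind == JUNCTION and not interior:
                total += g.junction_extent_px(attached) / 2.0
        if i > 0:
            prev_t, prev_entry = seq[i - 1]
            jid = g.tubule_slots[t][entry]
            pa = _slot_anchor(g, jid, prev_t, 1 - prev_entry)
            pb = _slot_anchor(g, jid, t, entry)
            total += float(np.hypot(*(pa - pb)))
    return total


def longest_path_lengths(
    cluster: Cluster,
    pixel_size_um: float | None = None,
    max_paths: int = 200_000,
) -> list[float]:
    """Greedy longest-path decomposition of a cluster.

    The longest admissible tubule path is extracted, its tubules removed,
    and the process repeats; among equal-length candidates the
    lexicographically smallest element-id sequence wins (determinism).
    """
    g = cluster.graph
    px_um = pixel_size_um if pixel_size_um is not None else g.pixel_size_um
    remaining = set(cluster.ids_of_kind(TUBULE))
    out = []
    while remaining:
        best_len, best_id_key, best_seq = -1.0, None, None
        explored = 0

        def extend(seq, used):
            nonlocal best_len, best_id_key, best_seq, explored
            explored += 1
            if explored > max_paths:
                return
            length = _path_length_px(g, seq)
            ids = tuple(t for t, _ in seq)
            id_key = min(ids, ids[::-1])
            if length > best_len + 1e-9 or (
                abs(length - best_len) <= 1e-9 and (best_id_key is None or id_key < best_id_key)
            ):
                best_len, best_id_key, best_seq = length, id_key, list(seq)
            t, entry = seq[-1]
            if g.elements[t].is_ring or not g.tubule_slots[t]:
                return
            attached = g.tubule_slots[t][1 - entry]
            if attached is None or g.elements[attached].kind != JUNCTION:
                return
            for t2, side2 in _sorted_junction_slots(g, attached):
                if t2 in used or t2 not in remaining:
                    continue
                extend(seq + [(t2, side2)], used | {t2})

        for t in sorted(remaining):
            sides = (0,) if g.elements[t].is_ring or not g.tubule_slots[t] else (0, 1)
            for entry in sides:
                extend([(t, entry)], {t})
        out.append(best_len * px_um)
        for t, _ in best_seq:
            remaining.discard(t)
    return sorted(out, reverse=True)
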
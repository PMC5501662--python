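"""Ground-truthed synthetic mitochondrial images.

Images emulate the validation setup used to benchmark the pipeline:
500x500 px fields at 15 px/um containing 10-500 mitochondria, each a
curved 1-px centreline grown as a bounded-turn random walk and widened by
a Gaussian intensity cross-section.  The exported ground truth (per-
mitochondrion centreline and true length) allows scoring the recovered
skeleton for positional agreement and total-length fidelity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import GrayImage, segment_synthetic
from .skeleton import SkeletonGraph, skeletonize

LENGTH_MODELS = ("D1", "D2", "D3")

# Gaussian means/SDs of the length models (um).  The D1/D2 means are the
# benchmark conditions; the SDs are package choices (see docs/methods.md).
D1_MEAN, D1_SD = 3.0, 0.75
D2_MEANS, D2_SD = (2.5, 5.0), 0.5
LENGTH_RANGE_UM = (1.0, 10.0)


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic image."""

    n_mitochondria: int
    length_model: str = "D1"  # D1 | D2 | D3 | custom (via custom_table)
    image_size: tuple[int, int] = (500, 500)
    pixels_per_um: float = 15.0
    tortuosity_sd_deg: float = 5.0  # heading change per 1-px step
    profile_sigma_px: float = 2.0
    allow_overlap: bool = True
    min_separation_px: float = 12.0  # centreline clearance in no-overlap mode
    seed: int | None = None
    custom_table: dict | None = None  # {"bin_edges": [...], "mass": [...]}

    def __post_init__(self) -> None:
        if self.n_mitochondria < 1:
            raise ValueError("n_mitochondria must be >= 1")
        if self.length_model not in LENGTH_MODELS and self.custom_table is None:
            raise ValueError(f"unknown length model {self.length_model!r}")

    @property
    def pixel_size_um(self) -> float:
        return 1.0 / self.pixels_per_um


@dataclass
class GroundTruth:
    """Exported truth for one synthetic image."""

    centerlines: list[np.ndarray]  # float (k, 2) sub-pixel paths
    centerlines_px: list[np.ndarray]  # rounded integer paths (deduplicated)
    lengths_um: list[float]  # sampled true lengths
    image_size: tuple[int, int]
    pixels_per_um: float

    @property
    def n_mitochondria(self) -> int:
        return len(self.centerlines)

    @property
    def total_length_um(self) -> float:
        return float(sum(self.lengths_um))

    def centerline_mask(self) -> np.ndarray:
        m = np.zeros(self.image_size, dtype=bool)
        for path in self.centerlines_px:
            m[path[:, 0], path[:, 1]] = True
        return m

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mid, path in enumerate(self.centerlines_px):
            for r, c in path:
                rows.append((mid, int(r), int(c), self.lengths_um[mid]))
        return pd.DataFrame(rows, columns=["mito_id", "row", "col", "length_um"])


def _load_d3_table() -> dict:
    data = resources.files("mitonet.data").joinpath("d3_fibroblast_like.json").read_text()
    return json.loads(data)


_D3_CACHE: dict | None = None


def sample_length(spec: SyntheticSpec, rng: np.random.Generator) -> float:
    """Draw one mitochondrial length (um) from the configured length model.

    Gaussian models resample until the draw falls in the 1-10 um range;
    the D3 model draws a bin from the packaged fibroblast-like table and
    a uniform position within the bin.
    """
    global _D3_CACHE
    lo, hi = LENGTH_RANGE_UM
    if spec.custom_table is not None or spec.length_model == "D3":
        table = spec.custom_table
        if table is None:
            if _D3_CACHE is None:
                _D3_CACHE = _load_d3_table()
            table = _D3_CACHE
        edges = np.asarray(table["bin_edges"], dtype=float)
        mass = np.asarray(table["mass"], dtype=float)
        i = rng.choice(len(mass), p=mass / mass.sum())
        return float(rng.uniform(edges[i], edges[i + 1]))
    for _ in range(10_000):
        if spec.length_model == "D1":
            draw = rng.normal(D1_MEAN, D1_SD)
        else:  # D2: equal mixture of two Gaussians
            mean = D2_MEANS[int(rng.integers(2))]
            draw = rng.normal(mean, D2_SD)
        if lo <= draw <= hi:
            return float(draw)
    raise RuntimeError("length sampling failed to hit the allowed range")


def _grow_centerline(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n_steps: int,
    sd_rad: float,
    start: np.ndarray | None = None,
) -> np.ndarray:
    """Bounded-turn random walk of unit pixel steps, reflected at borders."""
    h, w = shape
    pos = start if start is not None else np.array([rng.uniform(0, h - 1), rng.uniform(0, w - 1)])
    ang = rng.uniform(0, 2 * np.pi)
    pts = np.empty((n_steps + 1, 2))
    pts[0] = pos
    for k in range(n_steps):
        ang += rng.normal(0.0, sd_rad)
        nxt = pos + np.array([np.sin(ang), np.cos(ang)])
        if not (0 <= nxt[0] <= h - 1):
            ang = -ang
        if not (0 <= nxt[1] <= w - 1):
            ang = np.pi - ang
        nxt = pos + np.array([np.sin(ang), np.cos(ang)])
        nxt[0] = min(max(nxt[0], 0.0), h - 1.0)
        nxt[1] = min(max(nxt[1], 0.0), w - 1.0)
        pos = nxt
        pts[k + 1] = pos
    return pts


def _round_path(path: np.ndarray) -> np.ndarray:
    ij = np.round(path).astype(int)
    keep = np.ones(len(ij), dtype=bool)
    keep[1:] = np.any(ij[1:] != ij[:-1], axis=1)
    return ij[keep]


def _splat(canvas: np.ndarray, path: np.ndarray) -> None:
    """Deposit unit mass per walk point with bilinear (sub-pixel) weights."""
    h, w = canvas.shape
    i0 = np.floor(path[:, 0]).astype(int)
    j0 = np.floor(path[:, 1]).astype(int)
    fi = path[:, 0] - i0
    fj = path[:, 1] - j0
    for di in (0, 1):
        for dj in (0, 1):
            wgt = (fi if di else 1 - fi) * (fj if dj else 1 - fj)
            ii = np.clip(i0 + di, 0, h - 1)
            jj = np.clip(j0 + dj, 0, w - 1)
            np.add.at(canvas, (ii, jj), wgt)


def line_peak_intensity(profile_sigma_px: float) -> float:
    """Peak intensity of an isolated straight tubule after Gaussian widening."""
    return 1.0 / (np.sqrt(2.0 * np.pi) * profile_sigma_px)


DEFAULT_SYNTHETIC_THRESHOLD = 0.5  # half the single-tubule peak, on the unit scale


def generate_image(
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    max_retries: int = 500,
) -> tuple[GrayImage, GroundTruth]:
    """Generate one synthetic image and its ground truth.

    Centrelines are bounded-turn random walks (one unit-pixel step per
    point, heading perturbed by the tortuosity SD); the image is their
    Gaussian-widened rendering scaled so an isolated straight tubule
    peaks at 1.0.  With ``allow_overlap=False`` placements keep
    ``min_separation_px`` centreline clearance; placement failure after
    ``max_retries`` raises.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    shape = spec.image_size
    sd_rad = np.deg2rad(spec.tortuosity_sd_deg)
    occupied = np.zeros(shape, dtype=bool) if not spec.allow_overlap else None
    sep = None
    if occupied is not None:
        r = int(np.ceil(spec.min_separation_px))
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        sep = (yy**2 + xx**2) <= spec.min_separation_px**2

    centerlines, centerlines_px, lengths = [], [], []
    canvas = np.zeros(shape)
    for _ in range(spec.n_mitochondria):
        length_um = sample_length(spec, rng)
        n_steps = max(1, int(round(length_um * spec.pixels_per_um)))
        for attempt in range(max_retries):
            path = _grow_centerline(rng, shape, n_steps, sd_rad)
            ij = _round_path(path)
            if occupied is None or not occupied[ij[:, 0], ij[:, 1]].any():
                break
        else:
            raise RuntimeError(
                "could not place a non-overlapping mitochondrion; "
                "reduce n_mitochondria or allow overlap"
            )
        if occupied is not None:
            block = np.zeros(shape, dtype=bool)
            block[ij[:, 0], ij[:, 1]] = True
            occupied |= ndimage.binary_dilation(block, structure=sep)
        centerlines.append(path)
        centerlines_px.append(ij)
        lengths.append(length_um)
        _splat(canvas, path)

    img = ndimage.gaussian_filter(canvas, spec.profile_sigma_px)
    img /= line_peak_intensity(spec.profile_sigma_px)
    gray = GrayImage(img, spec.pixel_size_um)
    gt = GroundTruth(centerlines, centerlines_px, lengths, shape, spec.pixels_per_um)
    return gray, gt


# ---------------------------------------------------------------------------
# accuracy scoring
# ---------------------------------------------------------------------------

@dataclass
class AccuracyScore:
    """Pre/post skeleton comparison for one image."""

    length_ratio: float  # total true length / total post-skeleton length
    position_match: float  # fraction of post pixels within tolerance of truth
    condition1_met: bool  # position_match >= 0.95

    POSITION_MATCH_CUTOFF = 0.95


def skeleton_accuracy(
    gt: GroundTruth,
    post: SkeletonGraph,
    tolerance_px: int = 1,
) -> AccuracyScore:
    """Score a computed skeleton against the ground-truth centrelines.

    ``position_match`` is the fraction of post-skeleton pixels lying
    within ``tolerance_px`` (chessboard distance) of any ground-truth
    centreline pixel; the length ratio divides the true total length by
    the Euclidean length of the post skeleton.
    """
    if post.n_pixels == 0:
        if gt.n_mitochondria:
            raise ValueError("post skeleton is empty but ground truth is not")
        return AccuracyScore(1.0, 1.0, True)
    gt_mask = gt.centerline_mask()
    size = 2 * tolerance_px + 1
    near = ndimage.binary_dilation(gt_mask, structure=np.ones((size, size), dtype=bool))
    match = float(post.skel[near].sum() / post.n_pixels)
    post_len_um = post.total_length_px() / gt.pixels_per_um
    ratio = gt.total_length_um / post_len_um if post_len_um > 0 else np.inf
    return AccuracyScore(ratio, match, match >= AccuracyScore.POSITION_MATCH_CUTOFF)


def density_sweep(
    spec_template: SyntheticSpec,
    n_values,
    n_replicates: int = 10,
    threshold: float = DEFAULT_SYNTHETIC_THRESHOLD,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate, segment, skeletonize and score images over a density sweep.

    Returns one row per density: mitochondrion count, measured area
    fraction, mean pre/post length ratio and mean positional match.
    """
    n_values = sorted(int(n) for n in n_values)
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_values:
        fracs, ratios, matches = [], [], []
        for _ in range(n_replicates):
            spec = replace(spec_template, n_mitochondria=n, seed=None)
            gray, gt = generate_image(spec, rng)
            mask = segment_synthetic(gray, threshold)
            skel = skeletonize(mask)
            score = skeleton_accuracy(gt, skel)
            fracs.append(mask.mask.mean())
            ratios.append(score.length_ratio)
            matches.append(score.position_match)
        rows.append(
            (n, float(np.mean(fracs)), float(np.mean(ratios)), float(np.mean(matches)))
        )
    return pd.DataFrame(
        rows, columns=["n_mitochondria", "area_fraction", "length_ratio", "position_match"]
    )
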
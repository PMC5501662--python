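"""Model/results interface to the full analysis pipeline.

``MitochondrialNetwork`` is built from an image (grayscale or binary);
``fit`` runs segmentation (if needed), skeletonization, structural-
element classification, 4-way splitting, cluster extraction, the density
filter and the probabilistic topology interpreter, returning a
``NetworkFitResults`` carrying the length distribution with its
confidence band, the connectivity metrics and per-cluster diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distributions import LengthDistribution, make_bin_edges
from .elements import (
    Cluster,
    ConnectivityMetrics,
    classify_and_merge,
    connectivity_metrics,
    detect_donuts,
    extract_clusters,
    filter_dense_clusters,
    split_four_way,
)
from .interpret import (
    DEFAULT_N_SAMPLES,
    InterpretationTable,
    interpret_cluster,
    image_distribution,
)
from .segmentation import (
    BinaryImage,
    GrayImage,
    SegmentationParams,
    segment_confocal,
    segment_synthetic,
)
from .skeleton import SkeletonGraph, skeletonize


class MitochondrialNetwork:
    """A mitochondrial network observed in one (single-cell) image."""

    def __init__(self, mask: BinaryImage):
        self.mask = mask

    # -- constructors --------------------------------------------------
    @classmethod
    def from_mask(cls, mask, pixel_size_um: float | None = None) -> "MitochondrialNetwork":
        if isinstance(mask, BinaryImage):
            return cls(mask)
        return cls(BinaryImage(np.asarray(mask), pixel_size_um or 1.0 / 15.0))

    @classmethod
    def from_confocal(
        cls,
        image: GrayImage | np.ndarray,
        params: SegmentationParams | None = None,
        pixel_size_um: float | None = None,
    ) -> "MitochondrialNetwork":
        if not isinstance(image, GrayImage):
            image = GrayImage(image, pixel_size_um or 1.0 / 15.0)
        return cls(segment_confocal(image, params))

    @classmethod
    def from_synthetic(
        cls,
        image: GrayImage,
        threshold: float,
    ) -> "MitochondrialNetwork":
        return cls(segment_synthetic(image, threshold))

    # -- fitting -------------------------------------------------------
    def fit(
        self,
        n_samples: int = DEFAULT_N_SAMPLES,
        seed: int | None = None,
        bin_width_um: float = 0.5,
        max_length_um: float = 25.0,
        max_area_fraction: float = 0.6,
        table: InterpretationTable | None = None,
    ) -> "NetworkFitResults":
        """Run the pipeline and return the fitted results."""
        table = table or InterpretationTable.default()
        rng = np.random.default_rng(seed)
        skel = skeletonize(self.mask)
        graph = classify_and_merge(skel)
        split_four_way(graph)
        clusters = extract_clusters(graph)
        kept, excluded, excluded_pct = filter_dense_clusters(
            clusters, self.mask, max_area_fraction
        )
        bin_edges = make_bin_edges(bin_width_um, max_length_um)
        metrics = connectivity_metrics(kept, self.mask.pixel_size_um, self.mask) if kept else None
        cluster_dists = [
            interpret_cluster(cl, table, n_samples, rng, bin_edges) for cl in kept
        ]
        dist = image_distribution(cluster_dists) if cluster_dists else None
        return NetworkFitResults(
            model=self,
            skeleton=skel,
            clusters=kept,
            excluded_clusters=excluded,
            excluded_percent=excluded_pct,
            cluster_distributions=cluster_dists,
            distribution=dist,
            metrics=metrics,
            n_samples=n_samples,
            seed=seed,
            table_hash=table.table_hash(),
        )


@dataclass
class NetworkFitResults:
    """Results of fitting the probabilistic network model to one image."""

    model: MitochondrialNetwork
    skeleton: SkeletonGraph
    clusters: list[Cluster]
    excluded_clusters: list[Cluster]
    excluded_percent: float
    cluster_distributions: list[LengthDistribution]
    distribution: LengthDistribution | None
    metrics: ConnectivityMetrics | None
    n_samples: int
    seed: int | None
    table_hash: str

    @property
    def expected_mitochondria(self) -> float:
        return self.distribution.expected_count if self.distribution else 0.0

    def mean_length_um(self) -> float:
        if self.distribution is None:
            raise ValueError("no distribution fitted (empty image?)")
        return self.distribution.mean()

    def cluster_table(self) -> pd.DataFrame:
        """One row per cluster (including excluded ones, flagged)."""
        rows = []
        for cl, dist, exc in (
            [(c, d, False) for c, d in zip(self.clusters, self.cluster_distributions)]
            + [(c, None, True) for c in self.excluded_clusters]
        ):
            rows.append(
                dict(
                    n_ends=cl.n_ends,
                    n_tubules=cl.n_tubules,
                    n_junctions=cl.n_junctions,
                    n_elements=cl.n_elements,
                    total_length_um=cl.total_length_um(),
                    expected_mitochondria=dist.expected_count if dist else np.nan,
                    donuts=detect_donuts(cl),
                    is_ring=cl.is_ring,
                    excluded=exc,
                )
            )
        df = pd.DataFrame(rows)
        df.index.name = "cluster_id"
        return df

    def summary(self) -> str:
        m = self.metrics
        lines = [
            "Mitochondrial network analysis",
            "=" * 46,
            f"image size: {self.model.mask.shape[0]} x {self.model.mask.shape[1]} px "
            f"({self.model.mask.pixel_size_um:.4f} um/px)",
            f"clusters analysed: {len(self.clusters)} "
            f"(excluded dense: {len(self.excluded_clusters)}, {self.excluded_percent:.1f}%)",
            f"interpretation samples/cluster: {self.n_samples} (seed={self.seed}, "
            f"table={self.table_hash})",
        ]
        if m is not None:
            lines += [
                "-" * 46,
                f"ends / tubules / junctions: {m.n_ends} / {m.n_tubules} / {m.n_junctions} "
                f"({m.pct_ends:.1f}% / {m.pct_tubules:.1f}% / {m.pct_junctions:.1f}%)",
                f"elements per cluster (E_C): {m.elements_per_cluster:.3f}",
                f"junctions/ends (J/E):       {m.j_over_e:.3f}",
                f"tubules/ends (T/E):         {m.t_over_e:.3f}",
                f"connections per um:         {m.connections_per_um:.4f}",
                f"total skeleton length:      {m.total_length_um:.2f} um",
                f"donuts / blobs / 1-2um iso: {m.donut_count} / {m.blob_count} / "
                f"{m.isolated_1_2um_count}",
            ]
        if self.distribution is not None:
            lines += [
                "-" * 46,
                f"expected mitochondria:      {self.expected_mitochondria:.1f}",
                f"mean mitochondrial length:  {self.mean_length_um():.2f} um",
            ]
        return "\n".join(lines)

    def plot(self, ax=None, color="tab:blue", band_alpha=0.3, label=None):
        """Plot the length distribution with its +/-1 SD confidence band."""
        import matplotlib.pyplot as plt

        if self.distribution is None:
            raise ValueError("nothing to plot: no distribution fitted")
        if ax is None:
            _, ax = plt.subplots()
        d = self.distribution
        ax.plot(d.bin_centers, d.mass, color=color, label=label)
        ax.fill_between(
            d.bin_centers,
            np.clip(d.mass - d.sd, 0, None),
            d.mass + d.sd,
            color=color,
            alpha=band_alpha,
            linewidth=0,
        )
        ax.set_xlabel("mitochondrial length (um)")
        ax.set_ylabel("probability mass")
        return ax
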
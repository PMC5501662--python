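"""Binned mitochondrial length distributions with per-bin uncertainty."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_BIN_WIDTH_UM = 0.5
DEFAULT_MAX_LENGTH_UM = 25.0


def make_bin_edges(
    bin_width_um: float = DEFAULT_BIN_WIDTH_UM,
    max_length_um: float = DEFAULT_MAX_LENGTH_UM,
) -> np.ndarray:
    n = int(np.ceil(max_length_um / bin_width_um))
    return np.round(np.arange(n + 1) * bin_width_um, 9)


@dataclass
class LengthDistribution:
    """Probability mass over mitochondrial length with per-bin SD.

    Bins are half-open [lo, hi) in micrometres; ``expected_count`` is the
    expected number of mitochondria the distribution describes.  The same
    container serves single clusters and whole images.
    """

    bin_edges: np.ndarray
    mass: np.ndarray
    sd: np.ndarray
    expected_count: float = 1.0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if len(self.mass) != len(self.bin_edges) - 1 or len(self.sd) != len(self.mass):
            raise ValueError("mass/sd must have one entry per bin")
        if np.any(self.sd < -1e-12):
            raise ValueError("per-bin SD must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.mass)

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def total_mass(self) -> float:
        return float(self.mass.sum())

    def normalized(self) -> "LengthDistribution":
        t = self.total_mass()
        if t <= 0:
            raise ValueError("cannot normalize a zero distribution")
        return LengthDistribution(self.bin_edges, self.mass / t, self.sd / t, self.expected_count)

    def mean(self) -> float:
        return float(np.sum(self.bin_centers * self.mass) / self.mass.sum())

    def same_bins(self, other: "LengthDistribution") -> bool:
        return len(self.bin_edges) == len(other.bin_edges) and np.allclose(
            self.bin_edges, other.bin_edges
        )

    # -- i/o -----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "mass": self.mass,
                "sd": self.sd,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, expected_count: float = 1.0) -> "LengthDistribution":
        edges = np.concatenate([df["bin_lo"].to_numpy(), [df["bin_hi"].to_numpy()[-1]]])
        return cls(edges, df["mass"].to_numpy(), df["sd"].to_numpy(), expected_count)

    @classmethod
    def from_csv(cls, path, expected_count: float = 1.0) -> "LengthDistribution":
        return cls.from_frame(pd.read_csv(path), expected_count)

    @classmethod
    def from_lengths(
        cls,
        lengths_um,
        bin_edges: np.ndarray,
        expected_count: float | None = None,
    ) -> "LengthDistribution":
        """Normalized histogram of observed lengths (SD zero)."""
        mass = histogram_mass(np.asarray(lengths_um, dtype=float), bin_edges)
        n = len(np.atleast_1d(lengths_um))
        return cls(bin_edges, mass, np.zeros_like(mass), expected_count if expected_count is not None else float(n))


# alias used at the cluster level
ClusterDistribution = LengthDistribution


def histogram_mass(lengths_um: np.ndarray, bin_edges: np.ndarray) -> np.ndarray:
    """Unit-mass histogram with overflow clamped into the last bin."""
    if len(lengths_um) == 0:
        return np.zeros(len(bin_edges) - 1)
    clipped = np.clip(lengths_um, bin_edges[0], np.nextafter(bin_edges[-1], -np.inf))
    counts, _ = np.histogram(clipped, bins=bin_edges)
    return counts / counts.sum()


def average_distributions(dists: list[LengthDistribution]) -> LengthDistribution:
    """Arithmetic per-bin mean of unit-mass distributions, renormalized."""
    if not dists:
        raise ValueError("no distributions to average")
    base = dists[0]
    for d in dists[1:]:
        if not base.same_bins(d):
            raise ValueError("distributions must share bin edges")
    mass = np.mean([d.normalized().mass for d in dists], axis=0)
    mass = mass / mass.sum()
    return LengthDistribution(
        base.bin_edges, mass, np.zeros_like(mass), float(np.mean([d.expected_count for d in dists]))
    )
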
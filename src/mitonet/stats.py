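"""Earth mover's distance on length histograms and the replicate protocol.

EMD quantifies the global difference between two mitochondrial length
distributions: the minimal mass x distance needed to turn one histogram
into the other.  On a shared 1-D binning it reduces to the area between
the two cumulative distributions.  The replicate protocol compares each
replicate against its own condition's average (experimental variability)
and against the other condition's average (treatment effect).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distributions import LengthDistribution, average_distributions
from .elements import ConnectivityMetrics


def emd(d1: LengthDistribution, d2: LengthDistribution) -> float:
    """1-D earth mover's distance between two unit-mass histograms.

    Computed as sum over bins of |CDF1 - CDF2| * bin width, in the units
    of the bin axis (EMD_um on micrometre bins).  Unnormalized inputs are
    normalized with a warning; mismatched bins are an error.
    """
    if not d1.same_bins(d2):
        raise ValueError("distributions must share bin edges")
    m1, m2 = d1.mass, d2.mass
    for m in (m1, m2):
        if not np.isclose(m.sum(), 1.0, atol=1e-6):
            warnings.warn("unnormalized distribution passed to emd; normalizing", stacklevel=2)
    m1 = m1 / m1.sum()
    m2 = m2 / m2.sum()
    return float(np.abs(np.cumsum(m1 - m2)).sum() * d1.bin_width)


@dataclass
class EMDReport:
    """Within/between-condition EMD values for a two-condition design."""

    table: pd.DataFrame  # columns: condition, replicate, comparison, value, units
    condition_averages: dict[str, LengthDistribution]

    def values(self, comparison: str) -> np.ndarray:
        return self.table.loc[self.table["comparison"] == comparison, "value"].to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def condition_emd_protocol(
    conditions: dict[str, list[LengthDistribution]],
    units: str = "um",
) -> EMDReport:
    """Run the within/between EMD protocol on two conditions.

    Within: each replicate vs the average of its own condition.  Between:
    each replicate vs the other condition's average.  Averages are the
    per-bin arithmetic mean of the replicate masses, renormalized.
    """
    if len(conditions) != 2:
        raise ValueError("the protocol expects exactly two conditions")
    for label, reps in conditions.items():
        if len(reps) < 2:
            raise ValueError(f"condition {label!r} needs >= 2 distributions")
    averages = {label: average_distributions(reps) for label, reps in conditions.items()}
    (la, reps_a), (lb, reps_b) = conditions.items()
    rows = []
    for label, reps, own, other in ((la, reps_a, la, lb), (lb, reps_b, lb, la)):
        for i, rep in enumerate(reps):
            rows.append((label, i, "within", emd(rep, averages[own]), units))
            rows.append((label, i, "between", emd(rep, averages[other]), units))
    table = pd.DataFrame(rows, columns=["condition", "replicate", "comparison", "value", "units"])
    return EMDReport(table, averages)


def pool_clusters(cluster_sets: list[list]) -> list:
    """Concatenate per-image cluster sets into one analysis unit.

    Pooling small image sections gives each section statistical weight in
    a single downstream distribution; all sets must share the pixel size.
    """
    pooled = []
    pixel_size = None
    for clusters in cluster_sets:
        for cl in clusters:
            if pixel_size is None:
                pixel_size = cl.graph.pixel_size_um
            elif not np.isclose(pixel_size, cl.graph.pixel_size_um):
                raise ValueError("pooled clusters must share pixel size")
            pooled.append(cl)
    return pooled


def channel_metric_ratio(
    metrics_outer: ConnectivityMetrics,
    metrics_inner: ConnectivityMetrics,
) -> dict[str, float]:
    """Outer/inner-channel ratios of the connectivity parameters.

    Used to compare an outer-membrane marker channel against a matrix
    marker channel: ratios near 1 indicate matching network structure.
    Zero or undefined inner values yield NaN with a warning.
    """
    out = {}
    for name in ("elements_per_cluster", "j_over_e"):
        outer = getattr(metrics_outer, name)
        inner = getattr(metrics_inner, name)
        if not np.isfinite(inner) or inner == 0:
            warnings.warn(f"inner-channel {name} is zero/undefined; ratio set to NaN", stacklevel=2)
            out[name] = float("nan")
        else:
            out[name] = float(outer / inner)
    return out


def cell_phenotype_scatter(
    per_cell: pd.DataFrame,
    control_label: str,
    condition_col: str = "condition",
    je_col: str = "j_over_e",
    mass1um_col: str = "mass_1um",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-cell (connectivity, length) pairs normalized to the control.

    Connectivity is J/E; the length proxy is 1 / (mass in the 1 um bin),
    which grows with mitochondrial length.  Both are divided by the
    control-cell means; cells with zero 1-um mass get a missing length
    value and are flagged.
    """
    df = per_cell.copy()
    ctrl = df[df[condition_col] == control_label]
    if ctrl.empty:
        raise ValueError(f"no cells labelled {control_label!r}")
    inv_len = 1.0 / df[mass1um_col].replace(0.0, np.nan)
    ctrl_inv = 1.0 / ctrl[mass1um_col].replace(0.0, np.nan)
    ctrl_je_mean = ctrl[je_col].mean()
    ctrl_len_mean = ctrl_inv.mean()
    df["connectivity_norm"] = df[je_col] / ctrl_je_mean
    df["length_norm"] = inv_len / ctrl_len_mean
    df["length_missing"] = ~np.isfinite(df["length_norm"])
    bands = {
        "control_connectivity_mean": 1.0,
        "control_connectivity_sd": float((ctrl[je_col] / ctrl_je_mean).std(ddof=1)),
        "control_length_mean": 1.0,
        "control_length_sd": float((ctrl_inv / ctrl_len_mean).std(ddof=1)),
    }
    return df, bands
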
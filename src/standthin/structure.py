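"""Stand-structure statistics.

Diameter-class histograms on a 2-cm interval, adjusted-moment skewness (SK)
and excess kurtosis (ST) of the live-tree diameter distribution, and the
Gini coefficient (GC) of individual-tree basal area — the pipeline's
structural-heterogeneity metric.  GC = 0 means all trees equal in
cross-sectional area; values toward 1 mean extreme size inequality.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .standtable import StandSnapshot, stand_density
from .volume import diameter_class_label

__all__ = [
    "InsufficientSampleError",
    "DegenerateSampleError",
    "basal_area",
    "diameter_histogram",
    "skewness",
    "kurtosis",
    "gini_basal_area",
    "StructureReport",
    "structure_report",
]


class InsufficientSampleError(ValueError):
    """Too few trees for the requested statistic."""


class DegenerateSampleError(ValueError):
    """Zero-variance (or all-zero) sample."""


def basal_area(dbh) -> np.ndarray | float:
    """Cross-sectional area at breast height, m2, from DBH in cm."""
    d = np.asarray(dbh, dtype=float)
    ba = np.pi * (d / 200.0) ** 2
    return float(ba) if ba.ndim == 0 else ba


def diameter_histogram(snapshot: StandSnapshot, width: int = 2) -> dict[int, tuple[int, float]]:
    """Counts and percentages of live trees per 2-cm diameter class.

    Returns ``{class label: (count, percent)}`` sorted by label.  Class c
    covers DBH in (c-1, c+1].
    """
    if width != 2:
        raise ValueError("only the standard 2-cm classification interval is supported")
    live = snapshot.live_trees
    if not live:
        raise InsufficientSampleError("no live trees to classify")
    counts = Counter(diameter_class_label(t.dbh) for t in live)
    n = len(live)
    return {c: (counts[c], counts[c] / n * 100.0) for c in sorted(counts)}


def _standardized(values) -> tuple[np.ndarray, int]:
    x = np.asarray(values, dtype=float)
    n = x.size
    s = float(np.std(x, ddof=1)) if n > 1 else 0.0
    if s == 0.0:
        raise DegenerateSampleError("sample standard deviation is zero")
    return (x - x.mean()) / s, n


def skewness(values) -> float:
    """Adjusted-moment sample skewness SK.

    SK = n / ((n-1)(n-2)) * sum(((x_i - mean) / s)^3) with s the sample
    standard deviation (ddof=1).  Positive SK: mass at small diameters with
    a long right tail.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InsufficientSampleError(f"skewness needs n >= 3, got {x.size}")
    z, n = _standardized(x)
    return n / ((n - 1) * (n - 2)) * float(np.sum(z**3))


def kurtosis(values) -> float:
    """Adjusted-moment sample excess kurtosis ST.

    ST = n(n+1)/((n-1)(n-2)(n-3)) * sum(z^4) - 3(n-1)^2/((n-2)(n-3)).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise InsufficientSampleError(f"kurtosis needs n >= 4, got {x.size}")
    z, n = _standardized(x)
    return n * (n + 1) / ((n - 1) * (n - 2) * (n - 3)) * float(np.sum(z**4)) - 3 * (n - 1) ** 2 / (
        (n - 2) * (n - 3)
    )


def gini_basal_area(areas) -> float:
    """Gini coefficient of individual-tree basal area.

    GC = sum_j (2j - n - 1) ba_j / (sum_j ba_j * (n - 1)) with ba sorted
    ascending and j = 1..n.  Scale-invariant, so stands of very different
    mean size are directly comparable.
    """
    ba = np.sort(np.asarray(areas, dtype=float))
    n = ba.size
    if n < 2:
        raise InsufficientSampleError(f"Gini needs n >= 2, got {n}")
    total = float(ba.sum())
    if total <= 0:
        raise DegenerateSampleError("all basal areas are zero")
    j = np.arange(1, n + 1)
    return float(np.sum((2 * j - n - 1) * ba)) / (total * (n - 1))


@dataclass
class StructureReport:
    """Per-snapshot metric bundle; unavailable metrics are None and flagged."""

    plot_id: str
    stand_age: int
    density: float
    n_live: int
    mean_dbh: float
    sk: float | None
    st: float | None
    gc: float | None
    histogram: dict[int, tuple[int, float]]
    flags: dict[str, str] = field(default_factory=dict)


def structure_report(snapshot: StandSnapshot) -> StructureReport:
    """Assemble density, mean DBH, SK, ST, GC and the diameter histogram.

    Metric errors (e.g. ST on a 3-tree stand after heavy commercial
    thinning) are flagged per metric rather than aborting a batch.
    """
    live = snapshot.live_trees
    if not live:
        raise InsufficientSampleError(f"no live trees in {snapshot.plot_id}@{snapshot.stand_age}")
    dbh = np.array([t.dbh for t in live])
    flags: dict[str, str] = {}
    metrics: dict[str, float | None] = {}
    for name, fn, sample in (
        ("sk", skewness, dbh),
        ("st", kurtosis, dbh),
        ("gc", gini_basal_area, basal_area(dbh)),
    ):
        try:
            metrics[name] = fn(sample)
        except (InsufficientSampleError, DegenerateSampleError) as exc:
            metrics[name] = None
            flags[name] = str(exc)
    return StructureReport(
        plot_id=snapshot.plot_id,
        stand_age=snapshot.stand_age,
        density=stand_density(snapshot),
        n_live=len(live),
        mean_dbh=float(dbh.mean()),
        sk=metrics["sk"],
        st=metrics["st"],
        gc=metrics["gc"],
        histogram=diameter_histogram(snapshot),
        flags=flags,
    )
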
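"""Tree- and stand-level volume and merchantable timber classification.

Two fixed empirical power-law allometries for Chinese fir are used, both of
the form ``V = k * DBH^pD * H^pH`` (DBH in cm, H in m, V in m3):

* stock volume — the standing-volume equation used for stand volume and all
  yield accounting;
* merchantable volume — the timber-assortment equation used for the
  small/medium/large merchantable classes.

Merchantable size classes follow the Chinese fir standard on the 2-cm
diameter-class label d_c: d_c in {10,12,14} small, {16,18,20} medium,
>= 22 large, <= 8 sub-merchantable.  Classes are half-open intervals
(d_c - 1, d_c + 1] on raw DBH.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .standtable import StandSnapshot, StandTrajectory, ValidationError

__all__ = [
    "VolumeCoefficients",
    "STOCK_COEFFICIENTS",
    "MERCHANTABLE_COEFFICIENTS",
    "TimberClassSpec",
    "DEFAULT_TIMBER_CLASSES",
    "diameter_class_label",
    "tree_stock_volume",
    "tree_merchantable_volume",
    "classify_timber",
    "stand_volume",
    "stand_volume_with_thinned",
    "merchantable_table",
]


@dataclass(frozen=True)
class VolumeCoefficients:
    """Power-law allometry V = k * dbh^p_d * height^p_h."""

    k: float
    p_d: float
    p_h: float

    def __post_init__(self) -> None:
        if not (self.k > 0 and self.p_d > 0 and self.p_h > 0):
            raise ValidationError("volume coefficients must all be positive")


STOCK_COEFFICIENTS = VolumeCoefficients(5.877042e-5, 1.9699831, 0.89646157)
MERCHANTABLE_COEFFICIENTS = VolumeCoefficients(3.60243758e-5, 1.94752076, 1.00793769)


@dataclass(frozen=True)
class TimberClassSpec:
    """2-cm-class boundaries (on the class label) of the merchantable classes."""

    small_lo: int = 8    # labels strictly above -> small
    small_hi: int = 14   # labels up to and including -> small
    medium_hi: int = 20  # labels in (small_hi, medium_hi] -> medium; above -> large
    labels: tuple[str, ...] = ("sub", "small", "medium", "large")

    def __post_init__(self) -> None:
        if not (self.small_lo < self.small_hi < self.medium_hi):
            raise ValidationError("class boundaries must be strictly increasing")


DEFAULT_TIMBER_CLASSES = TimberClassSpec()


def diameter_class_label(dbh: float) -> int:
    """2-cm diameter-class label: class c covers dbh in (c-1, c+1]."""
    if not dbh > 0:
        raise ValidationError(f"dbh must be > 0, got {dbh}")
    return 2 * math.ceil((dbh - 1.0) / 2.0)


def _volume(dbh, height, coef: VolumeCoefficients):
    d = np.asarray(dbh, dtype=float)
    h = np.asarray(height, dtype=float)
    if np.any(d <= 0) or np.any(h <= 0):
        raise ValidationError("dbh and height must be strictly positive")
    v = coef.k * d**coef.p_d * h**coef.p_h
    return float(v) if v.ndim == 0 else v


def tree_stock_volume(dbh, height):
    """Standing stock volume (m3) of a tree from DBH (cm) and height (m)."""
    return _volume(dbh, height, STOCK_COEFFICIENTS)


def tree_merchantable_volume(dbh, height):
    """Merchantable timber volume (m3) of a tree from DBH (cm) and height (m)."""
    return _volume(dbh, height, MERCHANTABLE_COEFFICIENTS)


def classify_timber(dbh: float, spec: TimberClassSpec = DEFAULT_TIMBER_CLASSES) -> str:
    """Merchantable size-class label of a tree: sub | small | medium | large."""
    label = diameter_class_label(dbh)
    if label <= spec.small_lo:
        return "sub"
    if label <= spec.small_hi:
        return "small"
    if label <= spec.medium_hi:
        return "medium"
    return "large"


def stand_volume(snapshot: StandSnapshot) -> float:
    """Standing stock volume of live trees, m3/ha."""
    live = snapshot.live_trees
    if not live:
        return 0.0
    d = np.array([t.dbh for t in live])
    h = np.array([t.height for t in live])
    return float(np.sum(tree_stock_volume(d, h))) / snapshot.area_ha


def stand_volume_with_thinned(trajectory: StandTrajectory, age: int) -> float:
    """Existing + thinned stand volume at ``age``, m3/ha.

    Thinned trees contribute their stock volume frozen at removal size, for
    every age at or after their removal.
    """
    existing = stand_volume(trajectory.snapshot_at(age))
    removed = trajectory.removals_through(age)
    if not removed:
        return existing
    d = np.array([t.dbh for t in removed])
    h = np.array([t.height for t in removed])
    return existing + float(np.sum(tree_stock_volume(d, h))) / trajectory.area_ha


def merchantable_table(
    snapshot: StandSnapshot, spec: TimberClassSpec = DEFAULT_TIMBER_CLASSES
) -> dict:
    """Per-class merchantable volumes (m3/ha) and shares of the total.

    Sub-merchantable trees (class label <= 8) are excluded from the
    merchantable total; their merchantable-equation volume is reported
    separately under ``sub_volume``.
    """
    volumes = {"small": 0.0, "medium": 0.0, "large": 0.0}
    sub = 0.0
    for t in snapshot.live_trees:
        cls = classify_timber(t.dbh, spec)
        v = tree_merchantable_volume(t.dbh, t.height)
        if cls == "sub":
            sub += v
        else:
            volumes[cls] += v
    volumes = {k: v / snapshot.area_ha for k, v in volumes.items()}
    sub /= snapshot.area_ha
    total = sum(volumes.values())
    shares = {k: (v / total if total > 0 else 0.0) for k, v in volumes.items()}
    return {
        "volume": volumes,
        "share": shares,
        "total": total,
        "sub_volume": sub,
    }
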
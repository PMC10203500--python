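"""Tree-list tables and the core stand data model.

The shared currency of the pipeline is the *tree list*: one row per tree per
measurement age, in long format, because thinning changes stand membership
over time.  Columns: ``plot_id, treatment, stand_age, tree_id, dbh_cm,
height_m, status`` with ``status`` in ``{live, thinned}``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "TreeRecord",
    "StandSnapshot",
    "StandTrajectory",
    "SchemaError",
    "ValidationError",
    "read_tree_table",
    "write_tree_table",
    "stand_density",
    "COLUMNS",
]

COLUMNS = ["plot_id", "treatment", "stand_age", "tree_id", "dbh_cm", "height_m", "status"]

STATUS_LIVE = "live"
STATUS_THINNED = "thinned"
_VALID_STATUS = frozenset({STATUS_LIVE, STATUS_THINNED})


class SchemaError(ValueError):
    """A required column is missing from a tree-list file."""


class ValidationError(ValueError):
    """A record violates the stand data-model invariants."""


@dataclass(frozen=True)
class TreeRecord:
    """One measured tree at one age: DBH (cm), total height (m), status."""

    tree_id: int
    dbh: float
    height: float
    status: str = STATUS_LIVE

    def __post_init__(self) -> None:
        if self.tree_id < 1:
            raise ValidationError(f"tree_id must be a positive integer, got {self.tree_id}")
        if self.status not in _VALID_STATUS:
            raise ValidationError(f"status must be one of {sorted(_VALID_STATUS)}, got {self.status!r}")
        if not (self.dbh > 0):
            raise ValidationError(f"dbh must be > 0 cm, got {self.dbh} (tree {self.tree_id})")
        if not (self.height > 0):
            raise ValidationError(f"height must be > 0 m, got {self.height} (tree {self.tree_id})")

    @property
    def is_live(self) -> bool:
        return self.status == STATUS_LIVE


@dataclass
class StandSnapshot:
    """A plot's tree list at a single stand age.

    ``area_ha`` defaults to 0.04 ha, a 20 m x 20 m experimental plot.
    """

    plot_id: str
    stand_age: int
    trees: list[TreeRecord] = field(default_factory=list)
    area_ha: float = 0.04
    treatment: str = "CK"

    def __post_init__(self) -> None:
        if not (self.area_ha > 0):
            raise ValidationError(f"area_ha must be > 0, got {self.area_ha}")
        if self.stand_age < 1:
            raise ValidationError(f"stand_age must be >= 1, got {self.stand_age}")
        ids = [t.tree_id for t in self.trees]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"duplicate tree_id in snapshot {self.plot_id}@{self.stand_age}")

    @property
    def live_trees(self) -> list[TreeRecord]:
        return [t for t in self.trees if t.is_live]

    @property
    def n_live(self) -> int:
        return sum(1 for t in self.trees if t.is_live)


@dataclass
class StandTrajectory:
    """Ordered snapshots of one plot plus the removal ledger.

    The ledger holds ``(age, TreeRecord)`` pairs with the tree frozen at its
    size at removal; it is the carrier for existing+thinned volume accounting.
    """

    plot_id: str
    snapshots: list[StandSnapshot] = field(default_factory=list)
    removals: list[tuple[int, TreeRecord]] = field(default_factory=list)
    treatment: str = "CK"
    area_ha: float = 0.04

    def __post_init__(self) -> None:
        ages = [s.stand_age for s in self.snapshots]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValidationError(f"snapshot ages must be strictly increasing in plot {self.plot_id}")
        age_set = set(ages)
        for age, _ in self.removals:
            if age not in age_set:
                raise ValidationError(
                    f"removal ledger age {age} has no snapshot in plot {self.plot_id}"
                )
        by_id: dict[int, int] = {}
        for age, t in self.removals:
            by_id.setdefault(t.tree_id, age)
        for snap in self.snapshots:
            for t in snap.live_trees:
                first_removed = by_id.get(t.tree_id)
                if first_removed is not None and snap.stand_age > first_removed:
                    raise ValidationError(
                        f"tree {t.tree_id} appears live at age {snap.stand_age} "
                        f"after removal at age {first_removed} (plot {self.plot_id})"
                    )

    @property
    def ages(self) -> list[int]:
        return [s.stand_age for s in self.snapshots]

    def snapshot_at(self, age: int) -> StandSnapshot:
        for s in self.snapshots:
            if s.stand_age == age:
                return s
        raise KeyError(f"no snapshot at age {age} in plot {self.plot_id}")

    def removals_through(self, age: int) -> list[TreeRecord]:
        """Ledger trees removed at ages <= ``age``, frozen at removal size."""
        return [t for a, t in self.removals if a <= age]

    @property
    def last_event_age(self) -> int | None:
        return max((a for a, _ in self.removals), default=None)


def stand_density(snapshot: StandSnapshot) -> float:
    """Live trees per hectare."""
    return snapshot.n_live / snapshot.area_ha


def read_tree_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    *,
    area_ha: float = 0.04,
    sep: str | None = None,
) -> list[StandTrajectory]:
    """Read a delimited tree-list file into trajectories grouped by plot.

    ``dialect`` maps the file's column names onto the standard schema, e.g.
    ``{"D": "dbh_cm", "H": "height_m"}``.  Rows with ``status=thinned``
    populate the removal ledger at their age.  The plot area is not carried
    in the file; pass ``area_ha`` (default 0.04, a 20 m x 20 m plot).
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype={"plot_id": str}, float_precision="round_trip")
    if dialect:
        df = df.rename(columns=dict(dialect))
    required = [c for c in COLUMNS if c != "treatment"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    if "treatment" not in df.columns:
        df["treatment"] = "CK"

    bad = df[(df["status"] == STATUS_LIVE) & ((df["dbh_cm"] <= 0) | (df["height_m"] <= 0))]
    if len(bad):
        row = int(bad.index[0]) + 2  # header + 1-based
        raise ValidationError(f"non-positive dbh/height on live row {row} of {path}")
    bad_status = df[~df["status"].isin(_VALID_STATUS)]
    if len(bad_status):
        row = int(bad_status.index[0]) + 2
        raise ValidationError(f"unknown status {bad_status['status'].iloc[0]!r} on row {row} of {path}")

    trajectories: list[StandTrajectory] = []
    for plot_id, plot_df in df.groupby("plot_id", sort=True):
        treatment = str(plot_df["treatment"].iloc[0])
        snapshots = []
        removals: list[tuple[int, TreeRecord]] = []
        for age, age_df in plot_df.groupby("stand_age", sort=True):
            live = [
                TreeRecord(int(r.tree_id), float(r.dbh_cm), float(r.height_m))
                for r in age_df[age_df["status"] == STATUS_LIVE].itertuples()
            ]
            for r in age_df[age_df["status"] == STATUS_THINNED].itertuples():
                removals.append(
                    (int(age), TreeRecord(int(r.tree_id), float(r.dbh_cm), float(r.height_m), STATUS_THINNED))
                )
            if live:
                snapshots.append(
                    StandSnapshot(str(plot_id), int(age), live, area_ha=area_ha, treatment=treatment)
                )
        trajectories.append(
            StandTrajectory(str(plot_id), snapshots, removals, treatment=treatment, area_ha=area_ha)
        )
    return trajectories


def _format(x: float) -> str:
    return repr(float(x))


def write_tree_table(trajectories: Iterable[StandTrajectory], path: str | Path, *, sep: str = ",") -> Path:
    """Write trajectories as a delimited tree-list with a fixed header.

    One row per tree per age; removal-ledger trees appear once, at their
    removal age, with ``status=thinned``.  Row order is (plot, age, tree_id),
    so output is byte-stable for identical input.
    """
    path = Path(path)
    rows: list[tuple] = []
    for traj in trajectories:
        for snap in traj.snapshots:
            for t in snap.live_trees:
                rows.append((traj.plot_id, traj.treatment, snap.stand_age, t.tree_id, t.dbh, t.height, t.status))
        for age, t in traj.removals:
            rows.append((traj.plot_id, traj.treatment, age, t.tree_id, t.dbh, t.height, STATUS_THINNED))
    rows.sort(key=lambda r: (r[0], r[2], r[3]))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep, lineterminator="\n")
        w.writerow(COLUMNS)
        for plot, trt, age, tid, dbh, h, status in rows:
            w.writerow([plot, trt, age, tid, _format(dbh), _format(h), status])
    return path
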
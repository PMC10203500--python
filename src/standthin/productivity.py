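"""Periodic annual increment (PAI) and the structure-productivity relation.

PAI(t) = (SV(t) - SV(t - w)) / w on a chosen stand-volume basis is the
productivity measure; the structure-productivity relation is a fixed-effects
line PAI = b0 + b1 * GC with additive treatment offsets, with a seeded
bootstrap confidence interval on the slope b1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .standtable import StandTrajectory, ValidationError, stand_density
from .structure import structure_report
from .maturity import stand_quantitative_maturity, volume_series
from .volume import merchantable_table, stand_volume, stand_volume_with_thinned

__all__ = [
    "PaiSeries",
    "RelationFit",
    "pai",
    "structure_productivity_fit",
    "structure_metrics_table",
    "pai_table",
    "scenario_report",
]

EXISTING = "existing"
EXISTING_PLUS_THINNED = "existing_plus_thinned"


@dataclass
class PaiSeries:
    """Per-age periodic annual increment, m3 ha-1 yr-1."""

    plot_id: str
    window: int
    basis: str
    entries: dict[int, float]
    spans_event: dict[int, bool] = field(default_factory=dict)


@dataclass
class RelationFit:
    """Fixed-effects line PAI = b0 + b1*GC with treatment offsets."""

    slope: float
    intercept: float
    group_offsets: dict[str, float]
    slope_ci: tuple[float, float]
    n: int

    @property
    def slope_sign(self) -> int:
        return int(np.sign(self.slope))


def pai(trajectory: StandTrajectory, window: int = 1, basis: str = EXISTING_PLUS_THINNED) -> PaiSeries:
    """Periodic annual increment of stand volume over ``window`` years.

    On the existing-plus-thinned basis removed trees are frozen at removal
    size, so PAI measures live-tree growth; on the existing basis the
    window containing a thinning event absorbs the removal as a volume
    loss.  Windows spanning an event are flagged.
    """
    if window < 1:
        raise ValidationError("window must be >= 1")
    series = volume_series(trajectory, basis=basis)
    ages = series.ages.astype(int)
    lookup = dict(zip(ages.tolist(), series.values.tolist()))
    event_ages = {a for a, _ in trajectory.removals}
    entries: dict[int, float] = {}
    spans: dict[int, bool] = {}
    for t in ages.tolist():
        t0 = t - window
        if t0 not in lookup:
            continue
        entries[t] = (lookup[t] - lookup[t0]) / window
        spans[t] = any(t0 < a <= t for a in event_ages)
    return PaiSeries(trajectory.plot_id, window, basis, entries, spans)


def structure_productivity_fit(
    points: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> RelationFit:
    """Fit PAI = b0 + b1*GC + treatment offsets by OLS, bootstrap the slope.

    ``points`` needs columns ``gc``, ``pai`` and ``group``.  The confidence
    interval is the percentile interval over ``n_boot`` case resamples with
    a fixed seed.
    """
    df = points.reset_index(drop=True)
    for col in ("gc", "pai", "group"):
        if col not in df.columns:
            raise ValidationError(f"points must have a {col!r} column")
    if df["gc"].nunique() < 2:
        raise ValidationError("degenerate GC: all values equal, no fit possible")

    groups = sorted(df["group"].unique())
    dummies = pd.get_dummies(df["group"], drop_first=True, dtype=float)
    X = np.column_stack([np.ones(len(df)), df["gc"].to_numpy(float), dummies.to_numpy()])
    ynames = ["intercept", "gc"] + list(dummies.columns)
    y = df["pai"].to_numpy(float)
    fit = sm.OLS(y, X).fit()
    coefs = dict(zip(ynames, fit.params))

    rng = np.random.default_rng(seed)
    n = len(df)
    slopes = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        Xb, yb = X[idx], y[idx]
        # drop collinear dummy columns that vanish in a resample
        keep = [0, 1] + [j for j in range(2, X.shape[1]) if Xb[:, j].std() > 0]
        beta, *_ = np.linalg.lstsq(Xb[:, keep], yb, rcond=None)
        slopes[b] = beta[1]
    alpha = (1.0 - ci_level) / 2.0
    ci = (float(np.quantile(slopes, alpha)), float(np.quantile(slopes, 1.0 - alpha)))
    offsets = {g: coefs.get(g, 0.0) for g in groups}
    return RelationFit(
        slope=float(coefs["gc"]),
        intercept=float(coefs["intercept"]),
        group_offsets=offsets,
        slope_ci=ci,
        n=n,
    )


def relation_points(
    trajectories: list[StandTrajectory],
    treatments: list[str] | None = None,
    group_label: str | None = None,
    window: int = 1,
) -> pd.DataFrame:
    """One (GC, PAI) summary point per plot for the structure-productivity fit.

    GC and PAI are averaged over the post-treatment ages of each plot (all
    ages after the start for an unthinned stand), mirroring a scatter of
    stands rather than of annual observations; the association is then
    identified by the between-intensity gradient within a thinning scenario.
    ``group_label`` overrides the group column (default: the treatment).
    """
    rows = []
    for traj in trajectories:
        if treatments is not None and traj.treatment not in treatments:
            continue
        le = traj.last_event_age or traj.ages[0]
        series = pai(traj, window=window)
        ages = [a for a in series.entries if a > le]
        if not ages:
            continue
        gcs = [structure_report(traj.snapshot_at(a)).gc for a in ages]
        gcs = [g for g in gcs if g is not None]
        rows.append(
            {
                "plot_id": traj.plot_id,
                "gc": float(np.mean(gcs)),
                "pai": float(np.mean([series.entries[a] for a in ages])),
                "group": group_label if group_label is not None else traj.treatment,
            }
        )
    return pd.DataFrame(rows)


def structure_metrics_table(trajectories: list[StandTrajectory]) -> pd.DataFrame:
    """Per plot x age structure metrics (density, mean DBH, SK, ST, GC)."""
    rows = []
    for traj in trajectories:
        for snap in traj.snapshots:
            rep = structure_report(snap)
            rows.append(
                {
                    "plot_id": traj.plot_id,
                    "treatment": traj.treatment,
                    "stand_age": snap.stand_age,
                    "density": rep.density,
                    "n_live": rep.n_live,
                    "mean_dbh": rep.mean_dbh,
                    "sk": rep.sk,
                    "st": rep.st,
                    "gc": rep.gc,
                }
            )
    return pd.DataFrame(rows)


def pai_table(
    trajectories: list[StandTrajectory], window: int = 1, basis: str = EXISTING_PLUS_THINNED
) -> pd.DataFrame:
    rows = []
    for traj in trajectories:
        series = pai(traj, window=window, basis=basis)
        for age, value in series.entries.items():
            rows.append(
                {
                    "plot_id": traj.plot_id,
                    "treatment": traj.treatment,
                    "stand_age": age,
                    "pai": value,
                    "spans_event": series.spans_event[age],
                }
            )
    return pd.DataFrame(rows)


def scenario_report(trajectories: list[StandTrajectory]) -> pd.DataFrame:
    """Treatment-level summary: mean +/- sd over replicates.

    Columns cover QMA, stand volume at QMA and at the final age on both
    bases, merchantable class shares at QMA, final-age Gini, and mean PAI
    over the post-treatment period.
    """
    by_trt: dict[str, list[StandTrajectory]] = {}
    for traj in trajectories:
        by_trt.setdefault(traj.treatment, []).append(traj)

    rows = []
    for trt, plots in by_trt.items():
        recs = []
        for traj in plots:
            final_age = traj.ages[-1]
            qma = stand_quantitative_maturity(traj)
            ref_age = qma if qma is not None else final_age
            snap_qma = traj.snapshot_at(ref_age)
            merch = merchantable_table(snap_qma)
            last_event = traj.last_event_age
            first_pai_age = (last_event or traj.ages[0]) + 1
            series = pai(traj)
            pai_vals = [v for a, v in series.entries.items() if a >= first_pai_age]
            gc_final = structure_report(traj.snapshot_at(final_age)).gc
            recs.append(
                {
                    "qma": qma,
                    "sv_existing_qma": stand_volume(snap_qma),
                    "sv_total_qma": stand_volume_with_thinned(traj, ref_age),
                    "sv_existing_final": stand_volume(traj.snapshot_at(final_age)),
                    "sv_total_final": stand_volume_with_thinned(traj, final_age),
                    "share_small_qma": merch["share"]["small"],
                    "share_medium_qma": merch["share"]["medium"],
                    "share_large_qma": merch["share"]["large"],
                    "gc_final": gc_final,
                    "mean_pai": float(np.mean(pai_vals)) if pai_vals else np.nan,
                    "density_final": stand_density(traj.snapshot_at(final_age)),
                }
            )
        rec_df = pd.DataFrame(recs)
        qmas = [r["qma"] for r in recs if r["qma"] is not None]
        row = {"treatment": trt, "n_plots": len(plots)}
        row["qma_mean"] = float(np.mean(qmas)) if qmas else np.nan
        row["qma_sd"] = float(np.std(qmas, ddof=1)) if len(qmas) > 1 else 0.0
        row["qma_reached"] = len(qmas)
        for col in rec_df.columns:
            if col == "qma":
                continue
            vals = rec_df[col].astype(float)
            row[f"{col}_mean"] = float(vals.mean())
            row[f"{col}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
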
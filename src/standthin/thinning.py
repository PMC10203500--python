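"""Thinning from below (understory thinning) at a target residual density.

The single silvicultural operator of the pipeline: "cutting the small and
keeping the big".  Trees are removed in ascending (DBH, height, tree_id)
order until the live count equals ``round(residual_density * area_ha)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

from .standtable import StandSnapshot, TreeRecord, ValidationError, STATUS_THINNED

__all__ = ["ThinningEvent", "thin_from_below", "apply_events", "validate_events", "target_count"]

PRE_COMMERCIAL = "pre_commercial"
COMMERCIAL = "commercial"


@dataclass(frozen=True)
class ThinningEvent:
    """A scheduled thinning: age (yr), residual density (trees/ha), label."""

    age: int
    residual_density: float
    kind: str = PRE_COMMERCIAL

    def __post_init__(self) -> None:
        if not (self.residual_density > 0):
            raise ValidationError(f"residual_density must be > 0, got {self.residual_density}")


def target_count(residual_density: float, area_ha: float) -> int:
    """Residual tree count on the plot: round half away from zero.

    278 trees/ha on 0.04 ha -> 11 trees; 156 -> 6.
    """
    return int(math.floor(residual_density * area_ha + 0.5))


def thin_from_below(
    snapshot: StandSnapshot, residual_density: float
) -> tuple[StandSnapshot, list[TreeRecord]]:
    """Remove the smallest live trees down to the target residual density.

    Returns the residual snapshot and the removed trees (status=thinned,
    DBH/height frozen at removal).  If the live count is already at or below
    the target, nothing is removed.
    """
    if not (residual_density > 0):
        raise ValidationError(f"residual_density must be > 0, got {residual_density}")
    live = snapshot.live_trees
    k = target_count(residual_density, snapshot.area_ha)
    if len(live) <= k:
        return snapshot, []
    ranked = sorted(live, key=lambda t: (t.dbh, t.height, t.tree_id))
    removed = [replace(t, status=STATUS_THINNED) for t in ranked[: len(live) - k]]
    removed_ids = {t.tree_id for t in removed}
    kept = [t for t in snapshot.trees if t.tree_id not in removed_ids]
    residual = StandSnapshot(
        snapshot.plot_id,
        snapshot.stand_age,
        kept,
        area_ha=snapshot.area_ha,
        treatment=snapshot.treatment,
    )
    return residual, removed


def validate_events(events: Sequence[ThinningEvent]) -> None:
    """Each plot is thinned at most once; the factorial never stacks events."""
    ages = [e.age for e in events]
    if len(set(ages)) != len(ages):
        raise ValidationError(f"duplicate thinning event ages: {ages}")
    if len(events) > 1:
        raise ValidationError(
            f"at most one thinning event per plot is supported, got ages {ages}"
        )


def apply_events(
    snapshot: StandSnapshot,
    events: Sequence[ThinningEvent],
    ledger: list[tuple[int, TreeRecord]],
) -> StandSnapshot:
    """Apply any event scheduled at this snapshot's age.

    Called immediately after the growth step of each simulated year; removals
    are appended to the trajectory's ledger at the event age.
    """
    validate_events(events)
    for ev in events:
        if ev.age == snapshot.stand_age:
            snapshot, removed = thin_from_below(snapshot, ev.residual_density)
            ledger.extend((ev.age, t) for t in removed)
    return snapshot
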
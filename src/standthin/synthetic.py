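"""Individual-tree stand generator for even-aged Chinese fir plantations.

Generates annual tree-list trajectories with the statistical structure the
downstream analysis assumes: a right-tailed (log-normal) initial DBH
distribution whose inequality widens with age under size-asymmetric
competition, sigmoid stand-volume growth, and release of residual trees
after thinning from below.

The growth kernel for each live tree i is

    dD_i = pot(D_i) * exp(-gamma * BAL_i / BA) * max(0, 1 - alpha * BA_ha / BA_ref) + eps

where pot(D) is the one-year DBH increment implied by a Richards potential
curve with parameters (pot_a, pot_b, pot_c) (the increment an open-grown
tree of that size would put on), BAL_i is the summed basal area of trees
larger than i (size-asymmetric competition: suppressed trees fall further
behind, so stand structural heterogeneity grows with age), BA the plot
basal area, BA_ha the same per hectare, and eps ~ N(0, noise_sd).  The
increment is truncated at zero: DBH never decreases.

Heights follow the deterministic allometry H = 1.3 + h_s1 * D^h_s2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .standtable import StandSnapshot, StandTrajectory, TreeRecord, ValidationError
from .thinning import ThinningEvent, apply_events, validate_events, PRE_COMMERCIAL, COMMERCIAL

__all__ = [
    "GrowthParams",
    "TreatmentSpec",
    "ScenarioConfig",
    "default_growth_params",
    "default_factorial",
    "height_from_dbh",
    "init_stand",
    "grow_one_year",
    "simulate_scenario",
]


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the synthetic growth kernel.

    Defaults are calibrated so that the unthinned 5000 trees/ha control
    reaches a basal-area Gini of roughly 0.30-0.45 by age 32 from ~0.10 at
    planting, keeps a right-tailed diameter distribution, and culminates
    its mean annual volume increment in its early twenties.
    """

    dbh0_median: float = 2.8   # cm, median initial DBH at start age
    dbh0_sigma: float = 0.13   # log-scale sd of initial DBH
    pot_a: float = 34.0        # cm, asymptotic potential DBH
    pot_b: float = 0.24        # 1/yr, potential-curve rate
    pot_c: float = 10.0        # potential-curve shape (> 1)
    comp_gamma: float = 1.02   # size-asymmetric competition strength
    dens_alpha: float = 0.9    # density-dependence strength, [0, 1)
    ba_ref: float = 42.0       # m2/ha, reference basal area for density term
    noise_sd: float = 0.005    # cm, sd of additive increment noise
    h_s1: float = 1.1          # height-allometry scale
    h_s2: float = 0.85         # height-allometry exponent
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pot_a > self.dbh0_median:
            raise ValidationError("pot_a must exceed dbh0_median")
        if not self.pot_c > 1:
            raise ValidationError("pot_c must be > 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not (0 <= self.dens_alpha < 1):
            raise ValidationError("dens_alpha must be in [0, 1)")
        if self.comp_gamma < 0:
            raise ValidationError("comp_gamma must be >= 0")
        if not self.ba_ref > 0:
            raise ValidationError("ba_ref must be > 0")


@dataclass(frozen=True)
class TreatmentSpec:
    """A treatment label with its (at most one) thinning event."""

    name: str
    events: tuple[ThinningEvent, ...] = ()

    def __post_init__(self) -> None:
        validate_events(self.events)


@dataclass
class ScenarioConfig:
    """A thinning-experiment factorial: treatments x replicates on small plots."""

    treatments: list[TreatmentSpec]
    planting_density: float = 5000.0  # trees/ha
    area_ha: float = 0.04             # 20 m x 20 m plot
    start_age: int = 4
    end_age: int = 32
    replicates: int = 3
    base_seed: int = 1

    def __post_init__(self) -> None:
        if self.planting_density * self.area_ha < 1:
            raise ValidationError("planting_density * area_ha must be >= 1")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if not (self.start_age >= 1 and self.end_age > self.start_age):
            raise ValidationError("need 1 <= start_age < end_age")
        for trt in self.treatments:
            for ev in trt.events:
                if not (self.start_age < ev.age <= self.end_age):
                    raise ValidationError(
                        f"thinning age {ev.age} outside ({self.start_age}, {self.end_age}]"
                    )


def default_growth_params(**overrides) -> GrowthParams:
    return GrowthParams(**overrides)


def default_factorial(replicates: int = 3, base_seed: int = 1) -> ScenarioConfig:
    """The shipped experimental design: an unthinned control, pre-commercial
    thinning at age 9 to 3250/2500/1750 trees per hectare, and commercial
    thinning at age 23 to 400/278/156 trees per hectare."""
    treatments = [TreatmentSpec("CK")]
    for dens in (3250, 2500, 1750):
        treatments.append(
            TreatmentSpec(f"TE{dens}", (ThinningEvent(9, dens, PRE_COMMERCIAL),))
        )
    for dens in (400, 278, 156):
        treatments.append(
            TreatmentSpec(f"TL{dens}", (ThinningEvent(23, dens, COMMERCIAL),))
        )
    return ScenarioConfig(treatments=treatments, replicates=replicates, base_seed=base_seed)


def height_from_dbh(dbh, params: GrowthParams):
    """Deterministic height allometry H = 1.3 + h_s1 * D^h_s2 (m)."""
    d = np.asarray(dbh, dtype=float)
    if np.any(d <= 0):
        raise ValidationError("dbh must be > 0")
    h = 1.3 + params.h_s1 * d**params.h_s2
    return float(h) if h.ndim == 0 else h


def _snapshot_from_arrays(template: StandSnapshot, ids, dbh, height) -> StandSnapshot:
    trees = [
        TreeRecord(int(i), float(d), float(h))
        for i, d, h in zip(ids, dbh, height)
    ]
    return StandSnapshot(
        template.plot_id,
        template.stand_age,
        trees,
        area_ha=template.area_ha,
        treatment=template.treatment,
    )


def init_stand(
    config: ScenarioConfig,
    params: GrowthParams,
    *,
    plot_id: str = "P1",
    treatment: str = "CK",
    rng: np.random.Generator | None = None,
) -> StandSnapshot:
    """Plant a stand: round(density * area) trees with log-normal DBH."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = int(round(config.planting_density * config.area_ha))
    dbh = params.dbh0_median * np.exp(rng.normal(0.0, params.dbh0_sigma, size=n))
    height = height_from_dbh(dbh, params)
    trees = [
        TreeRecord(i + 1, float(d), float(h)) for i, (d, h) in enumerate(zip(dbh, height))
    ]
    return StandSnapshot(plot_id, config.start_age, trees, area_ha=config.area_ha, treatment=treatment)


def _potential_increment(d: np.ndarray, params: GrowthParams) -> np.ndarray:
    """One-year DBH increment of the Richards potential curve at size d.

    The tree's implied age on the potential curve is recovered by inverting
    D = a (1 - e^{-bt})^c, then the increment is R(t+1) - R(t); zero at or
    above the asymptote.
    """
    a, b, c = params.pot_a, params.pot_b, params.pot_c
    frac = np.clip(d / a, 0.0, 1.0 - 1e-12)
    t_impl = -np.log(1.0 - frac ** (1.0 / c)) / b
    d_next = a * (1.0 - np.exp(-b * (t_impl + 1.0))) ** c
    inc = d_next - d
    inc[d >= a] = 0.0
    return np.maximum(inc, 0.0)


def grow_one_year(
    snapshot: StandSnapshot,
    params: GrowthParams,
    rng: np.random.Generator | None = None,
) -> StandSnapshot:
    """Advance every live tree by one year of diameter growth.

    Growth = Richards potential x size-asymmetric competition (BAL-based)
    x stand-level density dependence, plus truncated Gaussian noise;
    heights are recomputed from the allometry and age advances by one.
    """
    live = snapshot.live_trees
    if not live:
        raise ValidationError("grow_one_year needs at least one live tree")
    if rng is None:
        rng = np.random.default_rng(params.seed + snapshot.stand_age)
    d = np.array([t.dbh for t in live])
    ids = np.array([t.tree_id for t in live])
    ba = np.pi * (d / 200.0) ** 2  # m2 per tree
    ba_total = float(ba.sum())
    # BAL_i: basal area of strictly larger trees, as a fraction of stand BA
    bal = (ba[None, :] * (d[None, :] > d[:, None])).sum(axis=1)
    bal_frac = bal / ba_total if ba_total > 0 else np.zeros_like(bal)
    ba_ha = ba_total / snapshot.area_ha
    dens_factor = max(0.0, 1.0 - params.dens_alpha * ba_ha / params.ba_ref)
    inc = _potential_increment(d, params) * np.exp(-params.comp_gamma * bal_frac) * dens_factor
    if params.noise_sd > 0:
        inc = inc + rng.normal(0.0, params.noise_sd, size=d.size)
    inc = np.maximum(inc, 0.0)
    d_new = d + inc
    h_new = height_from_dbh(d_new, params)
    grown = StandSnapshot(
        snapshot.plot_id,
        snapshot.stand_age + 1,
        [TreeRecord(int(i), float(dd), float(hh)) for i, dd, hh in zip(ids, d_new, h_new)],
        area_ha=snapshot.area_ha,
        treatment=snapshot.treatment,
    )
    return grown


def _plot_seed(base_seed: int, treatment_index: int, replicate: int) -> np.random.Generator:
    ss = np.random.SeedSequence([int(base_seed), int(treatment_index), int(replicate)])
    return np.random.default_rng(ss)


def simulate_scenario(config: ScenarioConfig, params: GrowthParams) -> list[StandTrajectory]:
    """Run the full treatment x replicate factorial.

    Each plot gets an independent random stream derived deterministically
    from (base_seed, treatment index, replicate).  Thinning is applied
    immediately after the growth step of the event year, so the event-age
    snapshot is the after-thinning stand.  A thinning target at or above
    the current density issues a warning and removes nothing.
    """
    trajectories: list[StandTrajectory] = []
    for t_idx, trt in enumerate(config.treatments):
        for rep in range(1, config.replicates + 1):
            rng = _plot_seed(config.base_seed, t_idx, rep)
            plot_id = f"{trt.name}-r{rep}"
            snap = init_stand(config, params, plot_id=plot_id, treatment=trt.name, rng=rng)
            snapshots = [snap]
            ledger: list[tuple[int, TreeRecord]] = []
            for _ in range(config.start_age, config.end_age):
                snap = grow_one_year(snap, params, rng=rng)
                before = snap.n_live
                snap = apply_events(snap, trt.events, ledger)
                for ev in trt.events:
                    if ev.age == snap.stand_age and snap.n_live == before:
                        target = ev.residual_density * config.area_ha
                        if before <= target:
                            warnings.warn(
                                f"thinning target {ev.residual_density}/ha at age {ev.age} "
                                f"is at or above current density on plot {plot_id}; no removal",
                                stacklevel=2,
                            )
                snapshots.append(snap)
            trajectories.append(
                StandTrajectory(
                    plot_id, snapshots, ledger, treatment=trt.name, area_ha=config.area_ha
                )
            )
    return trajectories
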
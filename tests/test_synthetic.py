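import numpy as np
import pytest

from standthin import (
    GrowthParams,
    ValidationError,
    default_factorial,
    default_growth_params,
    gini_basal_area,
    grow_one_year,
    height_from_dbh,
    init_stand,
    simulate_scenario,
    structure_report,
)
from standthin.structure import basal_area
from standthin.maturity import richards, RichardsParams
from tests.conftest import make_snapshot


class TestGrowthParamsValidation:
    def test_rejects_bad_shapes(self):
        with pytest.raises(ValidationError):
            GrowthParams(pot_c=0.9)
        with pytest.raises(ValidationError):
            GrowthParams(dens_alpha=1.0)
        with pytest.raises(ValidationError):
            GrowthParams(noise_sd=-0.1)
        with pytest.raises(ValidationError):
            GrowthParams(pot_a=1.0, dbh0_median=2.8)


class TestHeightAllometry:
    def test_breast_height_intercept(self):
        p = default_growth_params()
        assert height_from_dbh(1e-9, p) == pytest.approx(1.3, abs=1e-6)

    def test_linear_special_case(self):
        p = default_growth_params(h_s1=0.8, h_s2=1.0)
        assert height_from_dbh(10.0, p) == pytest.approx(9.3)

    def test_monotone_increasing(self):
        p = default_growth_params()
        d = np.linspace(0.5, 40, 100)
        assert np.all(np.diff(height_from_dbh(d, p)) > 0)


class TestInitStand:
    def test_tree_count_from_density_and_area(self):
        cfg = default_factorial()
        snap = init_stand(cfg, default_growth_params(), rng=np.random.default_rng(0))
        assert snap.n_live == 200
        assert snap.stand_age == cfg.start_age

    def test_zero_sigma_gives_equal_dbh_and_zero_gini(self):
        cfg = default_factorial()
        p = default_growth_params(dbh0_sigma=0.0)
        snap = init_stand(cfg, p, rng=np.random.default_rng(0))
        dbhs = {t.dbh for t in snap.trees}
        assert dbhs == {p.dbh0_median}
        assert gini_basal_area(basal_area(np.array([t.dbh for t in snap.trees]))) == 0.0

    def test_same_seed_identical(self):
        cfg = default_factorial()
        p = default_growth_params(seed=5)
        a = init_stand(cfg, p)
        b = init_stand(cfg, p)
        assert a.trees == b.trees


class TestGrowOneYear:
    def test_competition_off_follows_potential_richards_curve(self):
        """With competition, density dependence and noise all off, each tree
        tracks the Richards potential curve through its implied age."""
        p = default_growth_params(comp_gamma=0.0, dens_alpha=0.0, noise_sd=0.0)
        curve = RichardsParams(p.pot_a, p.pot_b, p.pot_c)
        snap = make_snapshot([5.0, 9.0, 14.0], age=10)
        grown = grow_one_year(snap, p)
        for before, after in zip(snap.trees, grown.trees):
            t_impl = -np.log(1 - (before.dbh / p.pot_a) ** (1 / p.pot_c)) / p.pot_b
            assert after.dbh == pytest.approx(richards(t_impl + 1, curve), rel=1e-9)

    def test_competition_off_equal_trees_keep_zero_gini(self):
        p = default_growth_params(comp_gamma=0.0, dens_alpha=0.0, noise_sd=0.0, dbh0_sigma=0.0)
        snap = init_stand(default_factorial(), p, rng=np.random.default_rng(0))
        for _ in range(5):
            snap = grow_one_year(snap, p)
        assert structure_report(snap).gc == pytest.approx(0.0, abs=1e-15)

    def test_size_asymmetry_on_two_tree_stand(self):
        p = default_growth_params(comp_gamma=1.5, dens_alpha=0.0, noise_sd=0.0)
        snap = make_snapshot([8.0, 12.0], age=10)
        grown = grow_one_year(snap, p)
        inc_small = grown.trees[0].dbh - 8.0
        inc_large = grown.trees[1].dbh - 12.0
        assert inc_large > inc_small

    def test_dbh_never_decreases(self):
        p = default_growth_params(noise_sd=2.0)  # heavy noise exercises truncation
        snap = make_snapshot(np.linspace(3, 20, 50), age=10)
        rng = np.random.default_rng(3)
        for _ in range(5):
            grown = grow_one_year(snap, p, rng=rng)
            for before, after in zip(snap.trees, grown.trees):
                assert after.dbh >= before.dbh
            snap = grown

    def test_age_advances_and_heights_follow_allometry(self):
        p = default_growth_params(noise_sd=0.0)
        snap = make_snapshot([10.0], age=12)
        grown = grow_one_year(snap, p)
        assert grown.stand_age == 13
        assert grown.trees[0].height == pytest.approx(
            float(height_from_dbh(grown.trees[0].dbh, p))
        )


class TestSimulateScenario:
    def test_control_has_no_ledger_entries(self, factorial_trajectories):
        for traj in factorial_trajectories:
            if traj.treatment == "CK":
                assert traj.removals == []

    def test_te1750_removes_130_at_age_nine(self, factorial_trajectories):
        for traj in factorial_trajectories:
            if traj.treatment == "TE1750":
                assert len(traj.removals) == 130
                assert all(a == 9 for a, _ in traj.removals)
                assert traj.snapshot_at(9).n_live == 70

    def test_annual_snapshots_span_start_to_end(self, factorial_trajectories):
        for traj in factorial_trajectories:
            assert traj.ages == list(range(4, 33))

    def test_reproducible_given_config_and_seed(self):
        cfg = default_factorial(replicates=1, base_seed=11)
        p = default_growth_params()
        a = simulate_scenario(cfg, p)
        b = simulate_scenario(cfg, p)
        for ta, tb in zip(a, b):
            for sa, sb in zip(ta.snapshots, tb.snapshots):
                assert sa.trees == sb.trees

    def test_replicates_differ(self):
        cfg = default_factorial(replicates=2, base_seed=11)
        a, b = simulate_scenario(cfg, default_growth_params())[:2]
        assert a.snapshots[-1].trees != b.snapshots[-1].trees

    def test_target_above_density_warns_without_removal(self):
        from standthin import ScenarioConfig, TreatmentSpec, ThinningEvent

        cfg = ScenarioConfig(
            treatments=[TreatmentSpec("T", (ThinningEvent(9, 9000),))],
            replicates=1,
        )
        with pytest.warns(UserWarning, match="no removal"):
            (traj,) = simulate_scenario(cfg, default_growth_params())
        assert traj.removals == []


class TestCalibratedStructureDynamics:
    """The paper-facing qualitative behaviour of the default calibration."""

    def _gc_by_age(self, trajectories, treatment):
        out = {}
        for traj in trajectories:
            if traj.treatment != treatment:
                continue
            for snap in traj.snapshots:
                out.setdefault(snap.stand_age, []).append(structure_report(snap).gc)
        return {a: float(np.mean(v)) for a, v in out.items()}

    def test_control_gini_nondecreasing_after_closure(self, factorial_trajectories):
        """Size inequality of the unthinned control grows with age; asserted
        at 1e-3 resolution, well below the 0.01 reporting resolution."""
        gc = self._gc_by_age(factorial_trajectories, "CK")
        ages = sorted(a for a in gc if 10 <= a <= 32)
        diffs = np.diff([gc[a] for a in ages])
        assert np.all(diffs >= -1e-3)

    def test_gini_ordering_across_pre_commercial_intensities(self, factorial_trajectories):
        gc32 = {
            t: self._gc_by_age(factorial_trajectories, t)[32]
            for t in ("CK", "TE3250", "TE2500", "TE1750")
        }
        assert gc32["CK"] > gc32["TE3250"] > gc32["TE2500"] > gc32["TE1750"]

    def test_pre_commercial_gini_exceeds_commercial_at_matched_rank(self, factorial_trajectories):
        gc32 = {
            t: self._gc_by_age(factorial_trajectories, t)[32]
            for t in ("TE3250", "TE2500", "TE1750", "TL400", "TL278", "TL156")
        }
        assert gc32["TE3250"] > gc32["TL400"]
        assert gc32["TE2500"] > gc32["TL278"]
        assert gc32["TE1750"] > gc32["TL156"]

    def test_control_skewness_stays_positive(self, factorial_trajectories):
        for traj in factorial_trajectories:
            if traj.treatment != "CK":
                continue
            for snap in traj.snapshots[1:]:
                assert structure_report(snap).sk > 0
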
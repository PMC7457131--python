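"""Generator properties: determinism, construction identities, and the
statistical signals the simulated herd is supposed to carry."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from alpgraze.anatomy import total_claw_base
from alpgraze.foraging import resolve_quality
from alpgraze.movement import camargo_evenness, rasterize_fixes, slope_raster
from alpgraze.records import ValidationError
from alpgraze.synthetic import (
    BreedParams,
    SimConfig,
    default_breeds,
    default_pastures,
    default_taxa,
    make_paddock,
    simulate_bites,
    simulate_cows,
    simulate_pedometer,
    simulate_study,
    simulate_tracks,
    simulate_weights,
)


def _params(**over) -> BreedParams:
    base = dict(
        name="X", weight_meanlog=float(np.log(500.0)), weight_sdlog=0.08,
        claw_coef=6.5, claw_exp=0.61, claw_noise_sd=0.05,
        steps_per_m=0.6, rest_prob=0.4, move_prob=0.3, persistence=0.5,
        slope_aversion=0.3, water_attraction=0.3, quality_preference=0.5,
        intake_efficiency=0.3, maintenance_quality=5.0,
    )
    base.update(over)
    return BreedParams(**base)


class TestPaddocks:
    def test_flat_when_target_slope_zero(self):
        pad = make_paddock("p", "P", 0.5, 0.0, seed=1)
        assert (pad.dem == 0).all()
        assert slope_raster(pad.dem, pad.dem_cell).max() == 0.0

    def test_same_seed_identical(self):
        a = make_paddock("p", "P", 0.5, 30.0, seed=42)
        b = make_paddock("p", "P", 0.5, 30.0, seed=42)
        np.testing.assert_array_equal(a.dem, b.dem)
        assert a.water_points == b.water_points

    @pytest.mark.parametrize("target", [19.2, 25.0, 48.1])
    def test_mean_slope_hits_target(self, target):
        pad = make_paddock("p", "P", 1.0, target, seed=3)
        achieved = slope_raster(pad.dem, pad.dem_cell).mean()
        assert achieved == pytest.approx(target, rel=0.05)

    def test_rejects_nonpositive_size(self):
        with pytest.raises(ValidationError):
            make_paddock("p", "P", 0.0, 10.0, seed=1)


class TestCows:
    def test_claw_outlines_reconstruct_target_area(self):
        params = _params(claw_noise_sd=1e-9)
        cows, claws = simulate_cows(params, 5, seed=11)
        for cow in cows:
            mine = [o for o in claws if o.cow_id == cow.cow_id]
            target = params.claw_coef * cow.weight_end**params.claw_exp
            assert total_claw_base(mine) == pytest.approx(target, abs=1e-6)

    def test_zero_claw_noise_makes_log_area_linear_in_log_weight(self):
        params = _params(claw_noise_sd=1e-12)
        cows, claws = simulate_cows(params, 40, seed=2)
        by_cow = {}
        for o in claws:
            by_cow.setdefault(o.cow_id, []).append(o)
        logw = np.log([c.weight_end for c in cows])
        loga = np.log([total_claw_base(by_cow[c.cow_id]) for c in cows])
        r = np.corrcoef(logw, loga)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)
        slope = np.polyfit(logw, loga, 1)[0]
        assert slope == pytest.approx(params.claw_exp, abs=1e-6)

    def test_weight_sample_mean_near_breed_mean(self):
        params = _params()
        cows, _ = simulate_cows(params, 200, seed=8)
        w = np.array([c.weight_start for c in cows])
        mu = np.exp(params.weight_meanlog + params.weight_sdlog**2 / 2)
        se = w.std(ddof=1) / np.sqrt(len(w))
        assert abs(w.mean() - mu) < 3 * se


class TestTracks:
    def _flat_paddock(self, size_ha=0.2, slope=0.0, seed=5):
        return make_paddock("p", "P", size_ha, slope, seed=seed)

    def test_same_seed_identical_tracks(self):
        pad = self._flat_paddock(slope=20.0)
        f1, t1 = simulate_tracks(["a", "b"], pad, _params(), 500, seed=77)
        f2, t2 = simulate_tracks(["a", "b"], pad, _params(), 500, seed=77)
        pd.testing.assert_frame_equal(f1, f2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_strong_slope_aversion_biases_occupancy_downhill(self):
        pad = make_paddock("p", "P", 0.5, 30.0, seed=9)
        params = _params(slope_aversion=3.0, water_attraction=0.0,
                         quality_preference=0.0, rest_prob=0.0, move_prob=1.0)
        fixes, _ = simulate_tracks(["a"], pad, params, 6000, seed=1,
                                   gps_noise_sd_m=0.0)
        grid = rasterize_fixes(fixes, pad)
        occupied_mean = np.average(
            grid.slope_pct[grid.mask], weights=grid.counts[grid.mask]
        )
        assert occupied_mean < grid.slope_pct[grid.mask].mean()

    def test_unbiased_walk_approaches_uniform_use(self):
        pad = self._flat_paddock(size_ha=0.15)
        params = _params(slope_aversion=0.0, water_attraction=0.0,
                         quality_preference=0.0, rest_prob=0.0, move_prob=1.0,
                         persistence=0.0)
        fixes, _ = simulate_tracks(["a"], pad, params, 30000, seed=4,
                                   gps_noise_sd_m=0.0)
        grid = rasterize_fixes(fixes, pad)
        assert camargo_evenness(grid.counts[grid.mask]) > 0.8

    def test_track_stays_in_paddock_without_noise(self):
        pad = self._flat_paddock()
        fixes, _ = simulate_tracks(["a"], pad, _params(), 2000, seed=3,
                                   gps_noise_sd_m=0.0)
        from shapely import contains_xy

        inside = contains_xy(pad.boundary, fixes["x"], fixes["y"])
        assert inside.all()


class TestPedometer:
    def test_zero_movement_zero_steps(self):
        truth = pd.DataFrame(
            {
                "cow_id": "a", "paddock_id": "p",
                "t": np.arange(240) * 15,
                "step_m": 0.0, "resting": True,
            }
        )
        pedo = simulate_pedometer(truth, _params(), seed=1)
        assert (pedo["steps"] == 0).all()
        assert pedo["lying_s"].sum() == 240 * 15

    def test_expected_steps_proportional_to_distance(self):
        def make(dist):
            return pd.DataFrame(
                {
                    "cow_id": "a", "paddock_id": "p",
                    "t": np.arange(240) * 15,
                    "step_m": dist / 240.0, "resting": False,
                }
            )

        p = _params()
        s1 = np.mean(
            [simulate_pedometer(make(500.0), p, seed=s)["steps"].sum()
             for s in range(80)]
        )
        s2 = np.mean(
            [simulate_pedometer(make(1000.0), p, seed=s)["steps"].sum()
             for s in range(80)]
        )
        assert s2 / s1 == pytest.approx(2.0, rel=0.1)


class TestBitesAndWeights:
    def test_neutral_selection_matches_availability(self):
        taxa = default_taxa()
        spec = default_pastures()[0]
        params = _params(quality_preference=0.0)
        b = simulate_bites("c", "P1", spec.composition, taxa, params, 5000, seed=6)
        obs = b["taxon_id"].value_counts()
        avail = pd.Series(spec.composition)
        exp = avail.reindex(obs.index) * 5000
        chi2 = stats.chisquare(obs.to_numpy(), exp.to_numpy())
        assert chi2.pvalue > 0.001

    def test_strong_preference_approaches_max_quality(self):
        taxa = default_taxa()
        spec = default_pastures()[0]
        q = resolve_quality(taxa, "P1")
        params = _params(quality_preference=8.0)
        b = simulate_bites("c", "P1", spec.composition, taxa, params, 2000, seed=6)
        props = b["taxon_id"].value_counts(normalize=True)
        diet_q = float((props * q.reindex(props.index)).sum())
        qmax = max(q[t] for t in spec.composition)
        assert diet_q > 0.95 * qmax

    def test_quality_monotone_in_preference(self):
        taxa = default_taxa()
        spec = default_pastures()[1]
        q = resolve_quality(taxa, "P2")

        def diet_q(tau, seed):
            p = _params(quality_preference=tau)
            b = simulate_bites("c", "P2", spec.composition, taxa, p, 400, seed)
            props = b["taxon_id"].value_counts(normalize=True)
            return float((props * q.reindex(props.index)).sum())

        wins = sum(diet_q(2.0, s) > diet_q(0.3, 10_000 + s) for s in range(200))
        assert wins / 200 >= 0.95

    def test_weight_change_rules(self):
        p = _params(maintenance_quality=5.0, intake_efficiency=0.3)
        assert simulate_weights(5.0, p, 70) == 0.0
        # linear in Q at fixed params
        assert simulate_weights(7.0, p, 70) == pytest.approx(
            2 * simulate_weights(6.0, p, 70)
        )
        breeds = default_breeds()
        assert simulate_weights(3.0, breeds["HC"], 70) > 0
        assert simulate_weights(5.0, breeds["AH"], 70) < 0


class TestWholeStudy:
    def test_same_seed_identical_bundle(self):
        cfg = SimConfig(n_cows_per_breed=2, track_days_per_pasture=0.05,
                        n_bites_per_pasture=50)
        b1 = simulate_study(cfg, seed=55)
        b2 = simulate_study(cfg, seed=55)
        pd.testing.assert_frame_equal(b1.tracks, b2.tracks)
        pd.testing.assert_frame_equal(b1.pedometer, b2.pedometer)
        pd.testing.assert_frame_equal(b1.bites, b2.bites)
        assert [c.weight_end for c in b1.cows] == [c.weight_end for c in b2.cows]

    def test_bundle_is_complete_and_cross_referenced(self, small_study):
        b = small_study
        assert len(b.cows) == 9  # 3 breeds x 3 cows
        assert len(b.paddocks) == 9  # 3 pastures x 3 breeds
        assert set(b.tracks["cow_id"]) == {c.cow_id for c in b.cows}
        # every cow is tracked once per pasture
        per = b.tracks.groupby(["cow_id", "paddock_id"]).size()
        assert per.groupby("cow_id").size().eq(3).all()

    def test_pedometer_gps_agreement(self, small_study):
        """Step counts and GPS speeds are strongly correlated across
        cow x paddock, as they must be for a pedometer emulation."""
        from alpgraze.movement import pedometer_summary, track_speed

        rows = []
        for (cow, pad), g in small_study.tracks.groupby(["cow_id", "paddock_id"]):
            sp, _ = track_speed(g)
            sub = small_study.pedometer
            sub = sub[(sub.cow_id == cow) & (sub.paddock_id == pad)]
            rows.append((sp, pedometer_summary(sub)[0]))
        arr = np.array(rows)
        r2 = np.corrcoef(arr[:, 0], arr[:, 1])[0, 1] ** 2
        assert r2 >= 0.8
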
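import numpy as np
import pandas as pd
import pytest

import mimevol as mv
from mimevol.geography import ZoneRatio, bm_ancestral_latitudes
from .conftest import star_tree


@pytest.fixture(scope="module")
def mapped_run():
    tree = mv.simulate_yule_tree(40, 0.08, seed=51)
    model = mv.PartitionModel([mv.RateMatrix2(0.01, 0.05)])
    traits, cmap = mv.simulate_discrete_history(tree, model, 0.0, seed=52)
    truth = mv.simulate_bm_latitude(tree, 0.0, 0.5, seed=53)
    ens = mv.sample_map_ensemble(tree, traits, model, n_maps=30, seed=54)
    lats, _ = bm_ancestral_latitudes(tree, mv.tip_latitudes(tree, truth))
    return tree, ens, lats


class TestBMAncestral:
    def test_two_tip_symmetric_root(self):
        tree = mv.parse_newick("(A:2,B:2):0;")
        vals, _ = bm_ancestral_latitudes(tree, {"A": 10.0, "B": 20.0})
        assert vals[tree.root] == pytest.approx(15.0, abs=1e-9)

    def test_star_tree_root_is_mean(self):
        tree = star_tree(6, 2.0)
        tips = {f"t{i}": float(i) for i in range(6)}
        vals, _ = bm_ancestral_latitudes(tree, tips)
        assert vals[tree.root] == pytest.approx(np.mean(list(tips.values())), abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_numerical_joint_optimum(self, seed):
        from scipy.optimize import minimize

        tree = mv.simulate_yule_tree(7, 0.3, seed=seed)
        truth = mv.simulate_bm_latitude(tree, 0.0, 1.0, seed=seed + 10)
        tips = mv.tip_latitudes(tree, truth)
        vals, _ = bm_ancestral_latitudes(tree, tips)
        internals = list(range(tree.n_tips, tree.n_nodes))

        def sum_sq(z):
            x = np.empty(tree.n_nodes)
            x[: tree.n_tips] = [tips[l] for l in tree.tip_labels]
            x[internals] = z
            s = 0.0
            for v in range(tree.n_nodes):
                p = tree.parent[v]
                if p >= 0:
                    s += (x[v] - x[p]) ** 2 / tree.branch_length[v]
            return s

        res = minimize(sum_sq, np.zeros(len(internals)), method="BFGS",
                       options={"gtol": 1e-12})
        np.testing.assert_allclose(vals[internals], res.x, atol=1e-6)

    def test_sigma2_scale_free_of_sample_size(self):
        tree = mv.simulate_yule_tree(80, 0.2, seed=9)
        truth = mv.simulate_bm_latitude(tree, 0.0, 2.0, seed=10)
        _, s2 = bm_ancestral_latitudes(tree, mv.tip_latitudes(tree, truth))
        assert 0.5 < s2 < 8.0  # order of magnitude around the generating 2.0


class TestInterpolation:
    def test_paper_anchors(self):
        assert mv.interpolate_event_latitude(10.0, 20.0, 0.5) == pytest.approx(15.0)
        assert mv.interpolate_event_latitude(10.0, 20.0, 0.0) == pytest.approx(10.0)
        assert mv.interpolate_event_latitude(10.0, 20.0, 0.1) == pytest.approx(11.0)

    def test_out_of_range_delta_rejected(self):
        with pytest.raises(ValueError):
            mv.interpolate_event_latitude(0.0, 1.0, 1.5)

    def test_swap_symmetry(self):
        # delta from one end equals 1-delta from the other
        a = mv.interpolate_event_latitude(3.0, 11.0, 0.3)
        b = mv.interpolate_event_latitude(11.0, 3.0, 0.7)
        assert a == pytest.approx(b)


class TestLocateEvents:
    def test_event_conservation(self, mapped_run):
        tree, ens, lats = mapped_run
        events = mv.locate_events(ens, lats)
        total = sum(m.n_events() for m in ens.maps)
        assert len(events) == total

    def test_empty_map_empty_list(self, mapped_run):
        tree, _, lats = mapped_run
        empty = mv.MapEnsemble([mv.CharacterMap(tree, 0, {})])
        assert len(mv.locate_events(empty, lats)) == 0

    def test_latitude_within_branch_span(self, mapped_run):
        tree, ens, lats = mapped_run
        events = mv.locate_events(ens, lats)
        for _, row in events.iterrows():
            v = int(row.branch)
            lo = min(lats[v], lats[tree.parent[v]])
            hi = max(lats[v], lats[tree.parent[v]])
            assert lo - 1e-9 <= row.latitude <= hi + 1e-9

    def test_flat_branch_constant_latitude(self, mapped_run):
        tree, ens, _ = mapped_run
        flat = np.full(tree.n_nodes, 7.0)
        events = mv.locate_events(ens, flat)
        if len(events):
            np.testing.assert_allclose(events["latitude"], 7.0)


class TestDensity:
    def test_integral_close_to_one(self, mapped_run):
        _, ens, lats = mapped_run
        events = mv.locate_events(ens, lats)
        typ = events["type"].value_counts().idxmax()
        grid, dens = mv.event_latitude_density(events, typ)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_single_event_peaks_at_location(self):
        events = pd.DataFrame(
            [{"map": 0, "branch": 1, "delta": 0.5, "type": "gain",
              "latitude": 0.0, "age_mya": 1.0}]
        )
        grid, dens = mv.event_latitude_density(events, "gain")
        assert abs(grid[np.argmax(dens)]) < 0.5

    def test_symmetric_events_symmetric_density(self):
        lats = np.concatenate([np.linspace(-10, -1, 30), np.linspace(1, 10, 30)])
        events = pd.DataFrame(
            {"map": 0, "branch": 0, "delta": 0.5, "type": "loss",
             "latitude": lats, "age_mya": 1.0}
        )
        grid = np.linspace(-15, 15, 301)
        _, dens = mv.event_latitude_density(events, "loss", grid=grid)
        np.testing.assert_allclose(dens, dens[::-1], atol=1e-8)

    def test_no_events_raises(self):
        events = pd.DataFrame(columns=["map", "branch", "delta", "type",
                                       "latitude", "age_mya"])
        with pytest.raises(ValueError):
            mv.event_latitude_density(events, "gain")


class TestTimeLatitudeGrid:
    def test_scaling_and_conservation(self, mapped_run):
        _, ens, lats = mapped_run
        events = mv.locate_events(ens, lats)
        tedges = np.linspace(0, events["age_mya"].max() + 1, 6)
        ledges = np.linspace(-90, 90, 10)
        grids = mv.time_latitude_grid(events, len(ens), tedges, ledges)
        joint_max = max(grids["gain_scaled"].max(), grids["loss_scaled"].max())
        assert joint_max == pytest.approx(1.0)
        total = (grids["gain"].sum() + grids["loss"].sum()) * len(ens)
        assert total == pytest.approx(len(events))

    def test_empty_region_zeros(self):
        events = pd.DataFrame(
            [{"map": 0, "branch": 1, "delta": 0.5, "type": "gain",
              "latitude": 0.0, "age_mya": 1.0}]
        )
        grids = mv.time_latitude_grid(
            events, 1, np.array([0.0, 2.0]), np.array([-90, 0, 90.0])
        )
        assert grids["loss"].sum() == 0


class TestZoneRatio:
    def _events(self, lats, typ="loss"):
        return pd.DataFrame(
            {"map": 0, "branch": 0, "delta": 0.5, "type": typ,
             "latitude": lats, "age_mya": 1.0}
        )

    def test_equal_zone_counts_ratio_one(self):
        ev = self._events([0.0, 10.0, 25.0, 30.0])
        r = mv.zone_loss_ratio(ev, n_maps=1)
        assert r.ratio == pytest.approx(1.0)

    def test_all_tropical_undefined(self):
        r = mv.zone_loss_ratio(self._events([0.0, 0.0]), n_maps=1)
        assert not r.defined
        assert np.isnan(r.ratio)

    def test_planted_three_to_one_recovered(self):
        rng = np.random.default_rng(5)
        trop = rng.uniform(-23, 23, 600)
        temp = rng.uniform(23.01, 35, 200)
        r = mv.zone_loss_ratio(self._events(np.concatenate([trop, temp])), n_maps=10)
        assert 2.5 <= r.ratio <= 3.5

    def test_boundary_23_is_tropical(self):
        r = mv.zone_loss_ratio(self._events([23.0, 30.0]), n_maps=1)
        assert r.tropical_mean == 1.0
        assert r.temperate_mean == 1.0


class TestTrueVsMappedHistories:
    def test_zone_totals_agree_smoke(self):
        # gains/losses located from true simulated histories vs from
        # stochastic maps at the generating rates: total event latitudinal
        # placement should agree to smoke-level precision
        tree = mv.simulate_yule_tree(150, 0.05, seed=71)
        model = mv.PartitionModel([mv.RateMatrix2(0.01, 0.05)])
        true_lat = mv.simulate_bm_latitude(tree, 0.0, 1.0, seed=72)
        lats = np.array([true_lat[v] for v in range(tree.n_nodes)])
        traits, cmap = mv.simulate_discrete_history(tree, model, 0.0, seed=73)
        true_events = mv.locate_events(mv.MapEnsemble([cmap]), lats)
        ens = mv.sample_map_ensemble(tree, traits, model, n_maps=200, seed=74)
        mapped_per_map = len(mv.locate_events(ens, lats)) / len(ens)
        # posterior maps condition on the realized tips at the generating
        # rates, so their mean event count should track the true history
        # to smoke-level precision (within a factor of two)
        assert 0.5 * len(true_events) <= mapped_per_map <= 2.0 * len(true_events)


class TestConservatism:
    def test_clade_clustered_values_strongly_conserved(self):
        tree = mv.simulate_yule_tree(40, 0.1, seed=5)
        cnt = tree.n_descendant_tips()
        clade = max(
            (v for v in range(tree.n_tips, tree.n_nodes) if v != tree.root),
            key=lambda v: min(cnt[v], 40 - cnt[v]),
        )
        inside = set(tree.subtree_nodes(clade).tolist())
        rng = np.random.default_rng(1)
        tips = {
            l: (20.0 if i in inside else -20.0) + rng.normal(0, 1)
            for i, l in enumerate(tree.tip_labels)
        }
        res = mv.pic_conservatism(tree, tips, n_perm=200, seed=2)
        assert res.z < -3

    def test_permuted_tips_null_calibrated(self):
        tree = mv.simulate_yule_tree(30, 0.1, seed=6)
        rng = np.random.default_rng(7)
        base = rng.normal(0, 10, tree.n_tips)
        inside = 0
        n_rep = 50
        for rep in range(n_rep):
            vals = base[rng.permutation(tree.n_tips)]
            tips = dict(zip(tree.tip_labels, vals))
            res = mv.pic_conservatism(tree, tips, n_perm=150, seed=rep)
            inside += abs(res.z) < 2
        assert inside >= int(0.9 * n_rep) - 3  # binomial slack on 50 draws

    def test_two_tip_degenerate_flagged(self):
        tree = mv.parse_newick("(A:1,B:1):0;")
        res = mv.pic_conservatism(tree, {"A": 1.0, "B": 5.0}, n_perm=100, seed=0)
        assert res.degenerate

    def test_constant_values_rejected(self, yule50):
        tips = {l: 3.0 for l in yule50.tip_labels}
        with pytest.raises(ValueError):
            mv.pic_conservatism(yule50, tips, n_perm=100, seed=0)

    def test_polytomy_resolution_contrast_count(self):
        tree = mv.parse_newick("(A:1,B:1,C:1,D:1):0;")
        contrasts = mv.phylogenetic_independent_contrasts(
            tree, {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        )
        assert len(contrasts) == 3  # n_tips - 1 after binary resolution
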
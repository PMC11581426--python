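"""Localization ingest, blink consolidation, clustering, distances, FRC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from smx.palm import (Cluster, cluster_objects, consolidate_blinks,
                      dimer_distances, frc_resolution, ingest_localizations,
                      stoichiometry_fractions, stoichiometry_summary)
from smx.simulate import generate_dimer_field, generate_localization_field


def brute_force_consolidate(locs):
    """Oracle: the same greedy fixpoint rule with plain O(n^2) loops.

    Returns the partition as groups of *original* row weights/positions so
    the weighted means can be recomputed independently.
    """
    xy = locs[["x_nm", "y_nm"]].to_numpy(float)
    prec = locs["precision_nm"].to_numpy(float)
    groups = [[i] for i in range(len(locs))]

    def group_stats(g):
        w = 1.0 / prec[g] ** 2
        pos = (xy[g] * w[:, None]).sum(axis=0) / w.sum()
        return pos, 1.0 / np.sqrt(w.sum())

    while True:
        stats = [group_stats(g) for g in groups]
        order = sorted(range(len(groups)),
                       key=lambda k: (stats[k][1], stats[k][0][0], stats[k][0][1]))
        claimed = [False] * len(groups)
        merged = []
        for k in order:
            if claimed[k]:
                continue
            pk, rk = stats[k]
            members = [m for m in order
                       if not claimed[m]
                       and np.hypot(*(stats[m][0] - pk)) <= rk]
            for m in members:
                claimed[m] = True
            merged.append(sum((groups[m] for m in members), []))
        if len(merged) == len(groups):
            break
        groups = merged
    return groups, xy, prec


def brute_force_components(xy, radius):
    """Oracle: BFS connected components over the strict all-pairs graph."""
    n = len(xy)
    d = np.hypot(xy[:, 0][:, None] - xy[:, 0], xy[:, 1][:, None] - xy[:, 1])
    adj = d < radius
    seen = [False] * n
    comps = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in np.flatnonzero(adj[u]):
                if not seen[v]:
                    seen[v] = True
                    stack.append(int(v))
        comps.append(frozenset(comp))
    return set(comps)


class TestIngest:
    def test_precision_threshold_drops_rows(self, simple_loc_table):
        t = simple_loc_table.copy()
        t.loc[0, "precision_nm"] = 45.0
        with pytest.warns(UserWarning):
            out = ingest_localizations(t, precision_max_nm=40.0)
        assert len(out) == 3

    def test_missing_column_named_in_error(self):
        with pytest.raises(ValueError, match="precision_nm"):
            ingest_localizations(pd.DataFrame({"x_nm": [1.0], "y_nm": [2.0],
                                               "frame": [0]}))

    def test_empty_table_warns(self):
        with pytest.warns(UserWarning):
            out = ingest_localizations(pd.DataFrame(
                columns=["x_nm", "y_nm", "frame", "precision_nm"]))
        assert len(out) == 0

    def test_pixel_table_converted_with_camera_pixel(self):
        t = pd.DataFrame({"x_px": [2.0], "y_px": [3.0], "frame": [0],
                          "precision_nm": [10.0]})
        out = ingest_localizations(t, pixel_size_nm=103.0)
        assert out["x_nm"].iloc[0] == pytest.approx(206.0)
        assert out["y_nm"].iloc[0] == pytest.approx(309.0)


class TestConsolidateBlinks:
    def test_nearby_blinks_merge(self):
        t = pd.DataFrame({"x_nm": [0.0, 5.0], "y_nm": [0.0, 0.0],
                          "frame": [0, 1], "precision_nm": [20.0, 20.0]})
        out = consolidate_blinks(t)
        assert len(out) == 1 and out["n_merged"].iloc[0] == 2

    def test_distant_blinks_stay_separate(self):
        t = pd.DataFrame({"x_nm": [0.0, 100.0], "y_nm": [0.0, 0.0],
                          "frame": [0, 1], "precision_nm": [20.0, 20.0]})
        assert len(consolidate_blinks(t)) == 2

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            n = rng.integers(20, 80)
            t = pd.DataFrame({
                "x_nm": rng.uniform(0, 400, n), "y_nm": rng.uniform(0, 400, n),
                "frame": np.arange(n),
                "precision_nm": rng.uniform(5, 40, n).round(3)})
            groups, xy, prec = brute_force_consolidate(t)
            out = consolidate_blinks(t)
            assert sorted(out["n_merged"]) == sorted(len(g) for g in groups)
            expect = sorted(
                tuple(np.round(np.sum(xy[g] / prec[g, None]**2, axis=0)
                               / np.sum(1 / prec[g]**2), 6)) for g in groups)
            got = sorted(tuple(v) for v in out[["x_nm", "y_nm"]].round(6).to_numpy())
            assert got == expect

    def test_conserves_localizations_and_is_idempotent(self):
        table, _ = generate_localization_field(n_clusters=60, seed=8)
        out = consolidate_blinks(table)
        assert out["n_merged"].sum() == len(table)
        again = consolidate_blinks(out.assign(frame=0))
        assert len(again) == len(out)
        assert np.allclose(np.sort(again["x_nm"]), np.sort(out["x_nm"]))

    def test_independent_of_input_row_order(self, rng):
        table, _ = generate_localization_field(n_clusters=20, seed=9)
        shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = consolidate_blinks(table).sort_values(["x_nm", "y_nm"]).reset_index(drop=True)
        b = consolidate_blinks(shuffled).sort_values(["x_nm", "y_nm"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


def _objects(xy, prec=10.0):
    xy = np.asarray(xy, float)
    return pd.DataFrame({"x_nm": xy[:, 0], "y_nm": xy[:, 1],
                         "precision_nm": prec})


class TestClusterObjects:
    def test_pair_within_radius_forms_one_cluster(self):
        cl = cluster_objects(_objects([[0, 0], [100, 0]]), radius_nm=160.0)
        assert len(cl) == 1 and cl[0].stoichiometry == 2

    def test_exact_radius_distance_stays_separate(self):
        cl = cluster_objects(_objects([[0, 0], [160.0, 0]]), radius_nm=160.0)
        assert len(cl) == 2

    def test_chain_groups_transitively(self):
        cl = cluster_objects(_objects([[0, 0], [150.0, 0], [300.0, 0]]))
        assert len(cl) == 1 and cl[0].stoichiometry == 3

    def test_matches_brute_force_components(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 120))
            xy = rng.uniform(0, 1500, size=(n, 2))
            got = {frozenset(c.member_indices.tolist())
                   for c in cluster_objects(_objects(xy), radius_nm=160.0)}
            assert got == brute_force_components(xy, 160.0)

    def test_complete_linkage_never_coarser(self, rng):
        xy = rng.uniform(0, 800, size=(60, 2))
        single = cluster_objects(_objects(xy), linkage="single")
        complete = cluster_objects(_objects(xy), linkage="complete")
        assert len(complete) >= len(single)

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            cluster_objects(_objects([[0, 0]]), radius_nm=0.0)


class TestStoichiometry:
    def test_fraction_arithmetic(self):
        assert stoichiometry_fractions([1, 1, 1, 2]) == pytest.approx((0.75, 0.25, 0.0))

    def test_fractions_sum_to_one(self, rng):
        sizes = rng.integers(1, 6, size=50)
        assert sum(stoichiometry_fractions(sizes)) == pytest.approx(1.0)

    def test_identical_replicates_have_zero_sd(self):
        rep = [1, 1, 2]
        out = stoichiometry_summary([rep, rep])
        assert np.allclose(out["sd"], 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            stoichiometry_fractions([])

    def test_planted_field_recovered_within_binomial_bounds(self):
        w = (0.5, 0.3, 0.2)
        table, truth = generate_localization_field(
            n_clusters=400, stoichiometry_weights=w, precision_model=3.0,
            fluorophore_spread_nm=60.0, blink_mean=1.0, field_size_nm=60000.0,
            seed=17)
        objects = consolidate_blinks(ingest_localizations(table))
        clusters = cluster_objects(objects)
        f = stoichiometry_fractions(clusters)
        planted = np.bincount(truth.clusters["n_fluorophores"], minlength=4)[1:4]
        planted = planted / planted.sum()
        for i in range(3):
            tol = 3 * np.sqrt(planted[i] * (1 - planted[i]) / 400) + 0.02
            assert abs(f[i] - planted[i]) < tol


class TestDimerDistances:
    def test_three_four_five(self):
        c = Cluster(np.array([0, 1]), np.array([[0.0, 0.0], [30.0, 40.0]]),
                    np.array([5.0, 5.0]))
        assert dimer_distances([c])[0] == pytest.approx(50.0)

    def test_coincident_members_give_zero(self):
        c = Cluster(np.array([0, 1]), np.zeros((2, 2)), np.ones(2))
        assert dimer_distances([c])[0] == 0.0

    def test_wrong_stoichiometry_rejected(self):
        c = Cluster(np.array([0]), np.zeros((1, 2)), np.ones(1))
        with pytest.raises(ValueError):
            dimer_distances([c])

    def test_distance_distribution_follows_rice_law(self):
        # planted separation 40 nm, isotropic per-molecule noise sigma=10 nm
        d, sigma = 40.0, 10.0
        table, _ = generate_dimer_field(n_dimers=3000, separation_nm=d,
                                        precision_nm=sigma, seed=23)
        clusters = cluster_objects(table.rename(columns={}), radius_nm=160.0)
        dists = dimer_distances([c for c in clusters if c.stoichiometry == 2])
        s_eff = sigma * np.sqrt(2)  # both ends are noisy
        expect = sps.rice.mean(b=d / s_eff, scale=s_eff)
        sd = sps.rice.std(b=d / s_eff, scale=s_eff)
        assert abs(dists.mean() - expect) < 4 * sd / np.sqrt(len(dists))

    def test_rigid_motion_invariance(self, rng):
        xy = rng.uniform(0, 1000, size=(40, 2))
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = xy @ R.T + [5000.0, -300.0]
        f1 = stoichiometry_fractions(cluster_objects(_objects(xy)))
        f2 = stoichiometry_fractions(cluster_objects(_objects(moved)))
        assert f1 == pytest.approx(f2)


class TestFRC:
    def test_too_few_localizations_rejected(self):
        t = pd.DataFrame({"x_nm": [0.0], "y_nm": [0.0], "frame": [0],
                          "precision_nm": [10.0]})
        with pytest.raises(ValueError):
            frc_resolution(t)

    def test_resolution_improves_with_precision(self, rng):
        def grid_locs(sigma):
            gx, gy = np.meshgrid(np.arange(8) * 500.0, np.arange(8) * 500.0)
            em = np.column_stack([gx.ravel(), gy.ravel()])
            pos = np.repeat(em, 150, axis=0) + rng.normal(0, sigma, (len(em) * 150, 2))
            return pd.DataFrame({"x_nm": pos[:, 0], "y_nm": pos[:, 1],
                                 "frame": np.arange(len(pos)),
                                 "precision_nm": sigma})
        r20 = frc_resolution(grid_locs(20.0), render_pixel_nm=5.0)
        r8 = frc_resolution(grid_locs(8.0), render_pixel_nm=5.0)
        assert r20.status == "ok" and r8.status == "ok"
        assert r8.resolution_nm < r20.resolution_nm
        # resolution commensurate with the localization-precision scale
        assert 20.0 < r20.resolution_nm < 120.0
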
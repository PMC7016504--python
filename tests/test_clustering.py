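"""Clustering index, compartments, peak amplitude, and the AZ-associated pool."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from svpools.clustering import (
    assign_compartments,
    az_pool,
    az_pool_correlation,
    clustering_profile,
    compartment_cluster_profiles,
    compartment_fractions,
    compartment_tests,
    peak_amplitude,
    population_cluster_test,
)
from svpools.model import RECYCLED, RESTING
from svpools.synthetic import control_config, generate_group, generate_section

from conftest import build_section, random_section


def brute_force_profile(centers, recycled, step=20.0):
    """O(n^2) reference implementation of the concentric-bin profile."""
    centers = np.asarray(centers, dtype=float)
    recycled = np.asarray(recycled, dtype=bool)
    n = len(centers)
    dist = cdist(centers, centers)
    r_max = step * math.ceil(dist.max() / step)
    radii = np.arange(step, r_max + step / 2, step)
    focal = np.flatnonzero(recycled)
    absolute = []
    for r in radii:
        vals = []
        for i in focal:
            nb = [j for j in range(n) if j != i and dist[i, j] <= r]
            if nb:
                vals.append(sum(recycled[j] for j in nb) / len(nb))
        absolute.append(np.mean(vals) if vals else np.nan)
    reference = (recycled.sum() - 1) / (n - 1)
    index = np.array(absolute) / reference if reference > 0 else np.full(len(radii), np.nan)
    return radii, np.array(absolute), index


class TestClusteringProfile:
    def test_colinear_hand_count(self):
        # vesicles at 0, 30, 60 nm along a line; labels R, R, P-.
        # focal at 0 with r = 40: only the vesicle at 30 is a neighbor -> 1/1
        s = build_section(
            [(0, 100), (30, 100), (60, 100)], [RECYCLED, RECYCLED, RESTING]
        )
        prof = clustering_profile(s, step=20.0)
        dist = cdist(s.centers(), s.centers())
        # reproduce the per-focal local fractions at r=40 by hand:
        # focal 0: neighbor {30} -> 1/1; focal 30: neighbors {0, 60} -> 1/2
        r40 = np.flatnonzero(np.isclose(prof.radii, 40.0))[0]
        assert prof.absolute_fraction[r40] == pytest.approx((1.0 + 0.5) / 2)

    def test_index_is_exactly_one_at_enclosing_radius(self):
        for seed in range(5):
            sec, _ = generate_section(
                control_config(fraction=("fixed", {"p": 0.3})), seed=seed
            )
            prof = clustering_profile(sec)
            assert prof.clustering_index[-1] == 1.0  # exact, not approximate

    def test_matches_brute_force_oracle(self, rng):
        for trial in range(5):
            s = random_section(rng, n=25, p=0.4, sid=f"t{trial}")
            if s.recycled_mask().sum() < 2:
                continue
            prof = clustering_profile(s)
            radii, absolute, index = brute_force_profile(
                s.centers(), s.recycled_mask()
            )
            np.testing.assert_allclose(prof.radii, radii)
            np.testing.assert_allclose(
                prof.absolute_fraction, absolute, atol=1e-12, equal_nan=True
            )
            np.testing.assert_allclose(
                prof.clustering_index, index, atol=1e-12, equal_nan=True
            )

    def test_rigid_transform_invariance(self, rng):
        s = random_section(rng, n=20, sid="rig")
        theta, shift = 0.7, np.array([123.0, -45.0])
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        moved = build_section(
            s.centers() @ rot.T + shift, list(s.labels()),
            az=tuple(map(tuple, np.asarray(s.active_zones[0].points) @ rot.T + shift)),
        )
        p0, p1 = clustering_profile(s), clustering_profile(moved)
        np.testing.assert_allclose(
            p0.clustering_index, p1.clustering_index, atol=1e-9, equal_nan=True
        )

    def test_single_recycled_vesicle_gives_nan_index(self):
        s = build_section([(0, 50), (30, 60), (60, 70)], [RECYCLED, RESTING, RESTING])
        prof = clustering_profile(s)
        assert np.isnan(prof.clustering_index).all()
        assert np.nanmax(prof.absolute_fraction) == 0.0

    def test_fewer_than_two_vesicles_is_error(self):
        s = build_section([(0, 50)], [RECYCLED])
        with pytest.raises(ValueError):
            clustering_profile(s)


class TestPopulationClusterTest:
    def test_all_indices_one_not_significant(self):
        from svpools.clustering import ClusterProfile

        profs = [
            ClusterProfile(
                section_id=f"s{i}",
                radii=np.array([20.0, 40.0]),
                absolute_fraction=np.array([0.5, 0.5]),
                clustering_index=np.array([1.0, 1.0]),
                n_contributing=np.array([3, 3]),
                reference_fraction=0.5,
            )
            for i in range(10)
        ]
        out = population_cluster_test(profs)
        assert not out["significant"].any()
        # constant-at-1 samples are untestable (zero variance), flagged NaN
        assert out["t"].isna().all()

    def test_contagion_labels_cluster_significantly(self):
        sections, _ = generate_group(
            control_config(
                n_synapses=40,
                fraction=("fixed", {"p": 0.25}),
                contagion_k=5,
            ),
            master_seed=11,
        )
        profs = [clustering_profile(s) for s in sections]
        out = population_cluster_test(profs, alpha=0.01)
        window = out[(out["radius_nm"] >= 40) & (out["radius_nm"] <= 240)]
        # radii below the hard-core separation have empty neighborhoods and
        # are untestable; every testable window radius must show clustering
        testable = window[window["n"] >= 2]
        assert len(testable) >= 8
        assert (testable["mean_index"] > 1).all()
        assert testable["significant"].all()

    def test_uniform_labels_not_significant(self):
        sections, _ = generate_group(
            control_config(n_synapses=50, fraction=("fixed", {"p": 0.3})),
            master_seed=5,
        )
        profs = [clustering_profile(s) for s in sections]
        out = population_cluster_test(profs, alpha=0.01)
        tested = out[(out["radius_nm"] >= 40) & (out["radius_nm"] <= 300)]
        assert not tested["significant"].any()


class TestPeakAmplitude:
    @staticmethod
    def _profile(index_values, step=20.0):
        from svpools.clustering import ClusterProfile

        radii = np.arange(step, step * (len(index_values) + 0.5), step)
        return ClusterProfile(
            section_id="p",
            radii=radii,
            absolute_fraction=np.asarray(index_values, dtype=float) * 0.3,
            clustering_index=np.asarray(index_values, dtype=float),
            n_contributing=np.ones(len(index_values), dtype=int),
            reference_fraction=0.3,
        )

    @pytest.mark.parametrize("value", [1.0, 2.0])
    def test_constant_profile(self, value):
        prof = self._profile([value] * 15)  # covers 20..300
        amp = peak_amplitude(prof)
        assert amp.amplitude == pytest.approx(value)
        assert not amp.truncated

    def test_equals_mean_of_window_radii(self, rng):
        vals = rng.uniform(0.5, 2.5, 15)
        prof = self._profile(vals)
        amp = peak_amplitude(prof)
        # window 40..240 nm at 20-nm steps = indices 1..11 (11 radii)
        assert amp.amplitude == pytest.approx(vals[1:12].mean(), abs=1e-12)

    def test_truncated_profile_flagged(self):
        prof = self._profile([1.5] * 8)  # covers only up to 160 nm
        amp = peak_amplitude(prof)
        assert amp.truncated
        assert amp.amplitude == pytest.approx(1.5)


class TestCompartments:
    @pytest.mark.parametrize(
        "d,expected",
        [(0.0, "active_zone"), (20.0, "active_zone"), (35.0, "front"),
         (50.0, "front"), (100.0, "middle"), (299.9, "middle"),
         (300.0, "rear_side"), (800.0, "rear_side")],
    )
    def test_band_assignment(self, d, expected):
        s = build_section([(0.0, d)], [RECYCLED], az=((-100, 0), (100, 0)))
        assert assign_compartments(s)["s1:v0"] == expected

    def test_beyond_800_clamped_with_warning(self):
        s = build_section([(0.0, 900.0)], [RECYCLED])
        with pytest.warns(UserWarning, match="clamped"):
            assert assign_compartments(s)["s1:v0"] == "rear_side"

    def test_front_fraction_hand_case(self):
        s = build_section([(0, 50), (10, 50)], [RECYCLED, RESTING])
        df = compartment_fractions([s])
        front = df[df["compartment"] == "front"]
        assert front["fraction"].iloc[0] == pytest.approx(0.5)
        # empty bands contribute no row
        assert "middle" not in set(df["compartment"])
        assert set(df["compartment"]) == {"front", "all"}

    def test_az_bias_gives_monotone_fraction_gradient(self):
        hits = 0
        n_rep = 10
        for seed in range(n_rep):
            sections, _ = generate_group(
                control_config(
                    n_synapses=30,
                    fraction=("fixed", {"p": 0.3}),
                    az_bias_lambda=100.0,
                ),
                master_seed=seed,
            )
            df = compartment_fractions(sections)
            means = (
                df[df["compartment"] != "all"]
                .groupby("compartment")["fraction"].mean()
            )
            order = ["active_zone", "front", "middle", "rear_side"]
            vals = [means.get(k, np.nan) for k in order]
            vals = [v for v in vals if not np.isnan(v)]
            if all(a >= b for a, b in zip(vals, vals[1:])):
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_whole_synapse_compartment_matches_global_profile(self):
        # all vesicles in one band -> compartment profile == global profile
        centers = [(x, 150.0 + y) for x, y in
                   [(0, 0), (30, 10), (60, 0), (90, 20), (120, 5), (150, 30)]]
        labels = [RECYCLED, RECYCLED, RESTING, RECYCLED, RESTING, RESTING]
        s = build_section(centers, labels)
        comp_profiles = compartment_cluster_profiles(s)
        assert set(comp_profiles) == {"middle"}
        glob = clustering_profile(s)
        np.testing.assert_allclose(
            comp_profiles["middle"].clustering_index,
            glob.clustering_index,
            atol=1e-12,
        )

    def test_sparse_compartments_omitted(self):
        s = build_section([(0, 50), (0, 400), (30, 420), (60, 410), (20, 430)],
                          [RECYCLED, RECYCLED, RECYCLED, RESTING, RESTING])
        profs = compartment_cluster_profiles(s)
        assert "front" not in profs  # single vesicle
        assert "rear_side" in profs

    def test_compartment_profile_matches_restricted_oracle(self, rng):
        s = random_section(rng, n=30, box=((-250, 20), (250, 600)), sid="oracle")
        profs = compartment_cluster_profiles(s)
        comp = assign_compartments(s)
        for name, prof in profs.items():
            sel = np.array([comp[v.id] == name for v in s.vesicles])
            radii, absolute, index = brute_force_profile(
                s.centers()[sel], s.recycled_mask()[sel]
            )
            np.testing.assert_allclose(
                prof.clustering_index, index, atol=1e-12, equal_nan=True
            )


class TestCompartmentTests:
    @staticmethod
    def _long_df(rng, shift=0.0, n=30):
        import pandas as pd

        rows = []
        for cond, delta in (("control", 0.0), ("LTP", shift)):
            for comp in ("active_zone", "front", "middle", "rear_side"):
                for i in range(n):
                    rows.append(
                        {
                            "condition": cond,
                            "compartment": comp,
                            "fraction": float(
                                np.clip(rng.normal(0.2 + delta, 0.08), 0, 1)
                            ),
                        }
                    )
        return pd.DataFrame(rows)

    def test_identical_groups_condition_effect_null(self, rng):
        df = self._long_df(rng, shift=0.0)
        out = compartment_tests(df)
        assert out["anova"]["condition"].p_value > 0.05

    def test_planted_condition_effect_detected(self, rng):
        df = self._long_df(rng, shift=0.15, n=50)
        out = compartment_tests(df)
        assert out["anova"]["condition"].p_value < 0.001
        for comp, res in out["posthoc"].items():
            assert res["p_sidak"] <= 1.0 and res["p_bonferroni"] <= 1.0
            assert res["p_sidak"] >= res["p_raw"]

    def test_kruskal_type_i_near_nominal(self, rng):
        from scipy import stats

        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            samples = [rng.normal(0.2, 0.08, 20) for _ in range(4)]
            if stats.kruskal(*samples)[1] < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_empty_cell_refused_with_diagnostic(self, rng):
        df = self._long_df(rng)
        df = df[~((df["condition"] == "LTP") & (df["compartment"] == "front"))]
        with pytest.raises(ValueError, match="front"):
            compartment_tests(df)


class TestAZPool:
    def test_membership_by_surface_gap(self):
        # radius 20, center 35 nm above AZ -> surface gap 15 <= 20: member
        s = build_section([(0, 35)], [RECYCLED])
        res = az_pool(s, gap=20.0)
        assert res.member_ids == ("s1:v0",)
        assert res.recycled_fraction_az == 1.0

    def test_nonmember_beyond_gap(self):
        s = build_section([(0, 45)], [RECYCLED])
        res = az_pool(s, gap=20.0)
        assert res.member_ids == ()
        assert res.recycled_fraction_az is None

    def test_occlusion_blocks_line_of_sight(self):
        # vesicle at 38 nm sits directly behind a member at 30 nm on the
        # same normal: occluded despite satisfying the gap rule... the front
        # vesicle must remain a member
        s = build_section([(0, 30), (0, 78)], [RESTING, RECYCLED], radius=20.0)
        res = az_pool(s, gap=60.0)  # generous gap so only occlusion separates
        assert "s1:v0" in res.member_ids
        assert "s1:v1" not in res.member_ids

    def test_tangency_does_not_occlude(self):
        # occluder offset laterally so the sight segment passes exactly at
        # its radius: tangency must not block membership
        s = build_section([(20.0, 20.0), (0.0, 35.0)], [RESTING, RECYCLED], radius=20.0)
        res = az_pool(s, gap=20.0)
        assert "s1:v1" in res.member_ids

    def test_matches_dense_segment_sampling_oracle(self, rng):
        for trial in range(10):
            n = 15
            centers = np.column_stack(
                [rng.uniform(-150, 150, n), rng.uniform(25, 260, n)]
            )
            labels = [RECYCLED if rng.random() < 0.4 else RESTING for _ in range(n)]
            s = build_section(centers, labels, sid=f"o{trial}", radius=18.0)
            res = az_pool(s, gap=20.0)
            # oracle: dense sampling of each candidate's sight segment
            from shapely.geometry import LineString, Point
            from shapely.ops import nearest_points

            line = s.active_zones[0].line
            expected = []
            for v in s.vesicles:
                d = Point(v.x, v.y).distance(line)
                if d - v.radius > 20.0:
                    continue
                tgt = nearest_points(Point(v.x, v.y), line)[1]
                ts = np.linspace(0, 1, 2001)[:, None]
                pts = np.array([v.x, v.y]) * (1 - ts) + np.array([tgt.x, tgt.y]) * ts
                occluded = False
                for o in s.vesicles:
                    if o.id == v.id:
                        continue
                    dmin = np.hypot(pts[:, 0] - o.x, pts[:, 1] - o.y).min()
                    if dmin < o.radius - 1e-6:
                        occluded = True
                        break
                if not occluded:
                    expected.append(v.id)
            assert set(res.member_ids) == set(expected)

    def test_gap_monotonicity(self, rng):
        s = random_section(rng, n=20, box=((-200, 22), (200, 200)), sid="mono")
        members_small = set(az_pool(s, gap=10.0).member_ids)
        members_large = set(az_pool(s, gap=40.0).member_ids)
        assert members_small <= members_large

    def test_correlation_identity(self):
        # AZ fractions identical to whole fractions -> rho = 1
        sections = []
        for i, (n_rec, n_tot) in enumerate([(1, 4), (2, 4), (3, 4)]):
            centers = [(30.0 * j, 30.0) for j in range(n_tot)]
            labels = [RECYCLED] * n_rec + [RESTING] * (n_tot - n_rec)
            sections.append(build_section(centers, labels, sid=f"c{i}"))
        res = az_pool_correlation(sections, gap=20.0)
        assert res.rho == pytest.approx(1.0)

    def test_scaling_model_gives_positive_correlation(self):
        # AZ-biased generator: AZ-pool fraction grows with the whole-synapse
        # fraction, so the correlation is strongly positive
        sections, _ = generate_group(
            control_config(n_synapses=50, az_bias_lambda=150.0,
                           fraction=("beta_ms", {"mean": 0.3, "sd": 0.15})),
            master_seed=21,
        )
        res = az_pool_correlation(sections)
        assert res.rho > 0.5 and res.p_value < 0.01
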
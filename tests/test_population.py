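import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from ihcsynapse.errors import SegmentationError, TableError
from ihcsynapse.population import (CLUSTER_PROPERTIES, CellEllipse,
                                   axis_position, build_table, cluster,
                                   compare_clusters, compare_groups,
                                   correlate, fit_cell_ellipse, pca_project)


def _filled_ellipse_image(shape, center, a, b, angle):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    dx, dy = xx - center[0], yy - center[1]
    u = dx * math.cos(angle) + dy * math.sin(angle)
    v = -dx * math.sin(angle) + dy * math.cos(angle)
    return np.where((u / a) ** 2 + (v / b) ** 2 <= 1.0, 100.0, 5.0)


def _profile_table(n=30, seed=0, m_centers=(1.6, 3.2, 6.1)):
    """A synthetic profile table with three property clusters."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        c = i % len(m_centers)
        base = {
            "cell_id": i // 4, "synapse_id": i % 4,
            "v_half_ca_mV": -45.0 + 5 * c + rng.normal(0, 0.3),
            "k_ca_mV": 4.0 + c + rng.normal(0, 0.1),
            "v10_ca_mV": -55.0 + 5 * c + rng.normal(0, 0.3),
            "dr_ca_mV": 18.0 + 4 * c + rng.normal(0, 0.3),
            "peak_rhod_dff": 0.5 + 0.3 * c + rng.normal(0, 0.02),
            "v_half_rel_mV": -40.0 + 5 * c + rng.normal(0, 0.3),
            "k_rel_mV": 3.0 + c + rng.normal(0, 0.1),
            "v10_rel_mV": -50.0 + 5 * c + rng.normal(0, 0.3),
            "dr_rel_mV": 14.0 + 4 * c + rng.normal(0, 0.3),
            "max_auc_rel": 2.0 + c + rng.normal(0, 0.1),
            "m": m_centers[c] + rng.normal(0, 0.05),
            "position_01": rng.uniform(0, 1),
        }
        rows.append(base)
    return build_table(rows), np.arange(n) % len(m_centers)


class TestCellEllipse:
    def test_synthetic_ellipse_parameters_within_two_percent(self):
        img = _filled_ellipse_image((256, 256), (130.0, 120.0), 100.0, 40.0,
                                    math.radians(30))
        ell = fit_cell_ellipse(img)
        assert ell.center_xy_px[0] == pytest.approx(130.0, abs=1.0)
        assert ell.center_xy_px[1] == pytest.approx(120.0, abs=1.0)
        assert ell.semi_major_px == pytest.approx(100.0, rel=0.02)
        assert ell.semi_minor_px == pytest.approx(40.0, rel=0.02)
        assert (math.degrees(ell.angle_rad) % 180) == pytest.approx(30.0,
                                                                    abs=2.0)

    def test_circle_is_flagged_degenerate_with_zero_angle(self):
        img = _filled_ellipse_image((128, 128), (64.0, 64.0), 40.0, 40.0, 0.0)
        ell = fit_cell_ellipse(img)
        assert ell.degenerate
        assert ell.angle_rad == 0.0

    def test_generator_cell_recovered_from_rendered_baseline(self, small_bundle):
        sw = small_bundle.channels["RhodFF"][0]
        on = sw.stim_onset_index
        baseline = sw.movie[2, :on].mean(axis=0)
        ell = fit_cell_ellipse(baseline)
        truth = small_bundle.ground_truth.cell
        assert ell.center_xy_px[0] == pytest.approx(truth.center_xy_px[0],
                                                    abs=2.0)
        assert ell.center_xy_px[1] == pytest.approx(truth.center_xy_px[1],
                                                    abs=2.0)

    def test_constant_image_rejected(self):
        with pytest.raises(SegmentationError):
            fit_cell_ellipse(np.full((64, 64), 3.0))


class TestAxisPosition:
    ELL = CellEllipse(center_xy_px=(100.0, 60.0), semi_major_px=40.0,
                      semi_minor_px=25.0, angle_rad=math.radians(20),
                      pillar_side="left")

    def test_center_maps_to_half(self):
        assert axis_position(self.ELL, (100.0, 60.0)) == pytest.approx(0.5)

    def test_pillar_vertex_maps_to_zero(self):
        assert axis_position(self.ELL, tuple(self.ELL.pillar_vertex())
                             ) == pytest.approx(0.0, abs=1e-12)
        assert axis_position(self.ELL, tuple(self.ELL.modiolar_vertex())
                             ) == pytest.approx(1.0, abs=1e-12)

    def test_matches_dense_sampling_oracle(self):
        # brute force: nearest point on a densely sampled major-axis segment
        rng = np.random.default_rng(0)
        v0, v1 = self.ELL.pillar_vertex(), self.ELL.modiolar_vertex()
        ts = np.linspace(0, 1, 200001)
        seg = v0[None, :] + ts[:, None] * (v1 - v0)[None, :]
        seg_len = np.linalg.norm(v1 - v0)
        for _ in range(20):
            p = np.array([rng.uniform(60, 140), rng.uniform(35, 85)])
            d = np.linalg.norm(seg - p, axis=1)
            t_oracle = ts[np.argmin(d)]
            got = axis_position(self.ELL, p)
            assert abs(got - t_oracle) * seg_len <= 0.1   # within 0.1 px

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            theta = rng.uniform(0, 2 * math.pi)
            shift = rng.uniform(-50, 50, 2)
            p = np.array([rng.uniform(70, 130), rng.uniform(40, 80)])
            base = axis_position(self.ELL, p)
            R = np.array([[math.cos(theta), -math.sin(theta)],
                          [math.sin(theta), math.cos(theta)]])
            c = np.array(self.ELL.center_xy_px)
            moved = CellEllipse(
                center_xy_px=tuple(R @ c + shift),
                semi_major_px=self.ELL.semi_major_px,
                semi_minor_px=self.ELL.semi_minor_px,
                angle_rad=self.ELL.angle_rad + theta,
                pillar_side=self.ELL.pillar_side)
            # rotating may swap which vertex is leftmost; compare against
            # both orientations
            got = axis_position(moved, tuple(R @ p + shift))
            assert min(abs(got - base), abs((1 - got) - base)) < 1e-9


class TestBuildTable:
    def test_complete_rows_pass_qc(self):
        table, _ = _profile_table(9)
        assert len(table) == 9
        assert table["qc_pass"].all()

    def test_low_r2_row_flagged_excluded(self):
        table, _ = _profile_table(6)
        recs = table.drop(columns=["qc_pass"]).to_dict("records")
        recs[0]["excluded"] = True      # e.g. a fit with R^2 = 0.5
        out = build_table(recs)
        assert not out.loc[0, "qc_pass"]
        assert out["qc_pass"].sum() == 5

    def test_missing_property_fails_qc(self):
        table, _ = _profile_table(6)
        recs = table.drop(columns=["qc_pass"]).to_dict("records")
        recs[2]["m"] = np.nan
        out = build_table(recs)
        assert not out.loc[2, "qc_pass"]

    def test_empty_input_gives_valid_schema(self):
        out = build_table([])
        assert len(out) == 0
        for col in CLUSTER_PROPERTIES:
            assert col in out.columns

    def test_duplicate_ids_rejected(self):
        table, _ = _profile_table(4)
        recs = table.drop(columns=["qc_pass"]).to_dict("records")
        recs[1]["cell_id"] = recs[0]["cell_id"]
        recs[1]["synapse_id"] = recs[0]["synapse_id"]
        with pytest.raises(TableError):
            build_table(recs)


class TestCorrelate:
    def test_duplicated_and_negated_columns(self):
        table, _ = _profile_table(20)
        table["dup"] = table["m"]
        table["neg"] = -table["m"]
        corr = correlate(table, extra=("dup", "neg"))
        assert corr.loc["m", "dup"] == pytest.approx(1.0)
        assert corr.loc["m", "neg"] == pytest.approx(-1.0)

    def test_matches_direct_formula_oracle(self):
        table, _ = _profile_table(25, seed=3)
        corr = correlate(table)
        cols = list(CLUSTER_PROPERTIES)
        X = table[cols].to_numpy()
        for i, a in enumerate(cols):
            for j, b in enumerate(cols):
                xa, xb = X[:, i], X[:, j]
                oracle = (np.mean((xa - xa.mean()) * (xb - xb.mean()))
                          / (xa.std() * xb.std()))
                assert corr.loc[a, b] == pytest.approx(oracle, abs=1e-12)

    def test_symmetric_with_unit_diagonal(self):
        table, _ = _profile_table(15, seed=4)
        corr = correlate(table)
        np.testing.assert_array_equal(corr.to_numpy(), corr.to_numpy().T)
        np.testing.assert_allclose(np.diag(corr.to_numpy()), 1.0)

    def test_zero_variance_column_reported_missing(self):
        table, _ = _profile_table(10)
        table["flat"] = 1.0
        corr = correlate(table, extra=("flat",))
        assert corr["flat"].drop("flat").isna().all()


class TestCluster:
    def test_separable_blobs_recovered_exactly(self):
        table, truth = _profile_table(30)
        out = cluster(table, k=3, seed=0)
        assert adjusted_rand_score(truth, out["cluster_label"]) == 1.0

    def test_labels_ordered_by_ascending_m(self):
        table, _ = _profile_table(30)
        out = cluster(table, k=3, seed=0)
        means = out.groupby("cluster_label")["m"].mean()
        assert list(means.index) == [1.0, 2.0, 3.0]
        assert means.is_monotonic_increasing

    def test_labeling_independent_of_seed_for_separable_data(self):
        table, _ = _profile_table(30)
        ref = cluster(table, k=3, seed=0)["cluster_label"].to_numpy()
        for seed in range(1, 10):
            got = cluster(table, k=3, seed=seed)["cluster_label"].to_numpy()
            np.testing.assert_array_equal(got, ref)

    def test_row_order_invariance(self):
        table, _ = _profile_table(30)
        shuffled = table.sample(frac=1.0, random_state=5)
        a = cluster(table, k=3, seed=0).set_index(["cell_id", "synapse_id"])
        b = cluster(shuffled, k=3, seed=0).set_index(["cell_id", "synapse_id"])
        pd.testing.assert_series_equal(a["cluster_label"].sort_index(),
                                       b["cluster_label"].sort_index())

    def test_single_cluster_gives_uniform_labels(self):
        table, _ = _profile_table(12)
        out = cluster(table, k=1, seed=0)
        assert (out["cluster_label"] == 1.0).all()

    def test_too_few_rows_rejected(self):
        table, _ = _profile_table(2)
        with pytest.raises(TableError):
            cluster(table, k=3)


class TestPCA:
    def test_rank_one_table_explained_by_first_component(self):
        rng = np.random.default_rng(2)
        t = rng.normal(0, 1, 40)
        recs = []
        for i, ti in enumerate(t):
            rec = {"cell_id": 0, "synapse_id": i, "position_01": 0.5}
            for j, col in enumerate(CLUSTER_PROPERTIES):
                rec[col] = (j + 1) * ti
            recs.append(rec)
        table = build_table(recs)
        _, _, evr = pca_project(table)
        assert evr[0] == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_data_spreads_variance_evenly(self):
        rng = np.random.default_rng(3)
        recs = []
        for i in range(500):
            rec = {"cell_id": 0, "synapse_id": i, "position_01": 0.5}
            for col in CLUSTER_PROPERTIES:
                rec[col] = rng.normal()
            recs.append(rec)
        table = build_table(recs)
        _, _, evr = pca_project(table)
        assert np.all(np.abs(evr - 1 / 11) < 0.03)

    def test_explained_variance_ratios_sum_to_one(self):
        table, _ = _profile_table(30)
        _, _, evr = pca_project(table)
        assert evr.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(evr) <= 1e-12)    # descending


class TestCompareGroups:
    def test_identical_groups_are_not_significant(self):
        table, _ = _profile_table(40, seed=6)
        table["position_group"] = ["a", "b"] * 20
        # same generating distribution in both groups
        rep = compare_groups(table, properties=("m",))
        assert rep.loc[0, "p_value"] > 0.05

    def test_five_sd_shift_detected_by_t_test(self):
        rng = np.random.default_rng(7)
        recs = []
        for i in range(60):
            rec = {"cell_id": 0, "synapse_id": i,
                   "position_01": 0.25 if i < 30 else 0.75}
            for col in CLUSTER_PROPERTIES:
                rec[col] = rng.normal()
            rec["m"] = rng.normal(0 if i < 30 else 5.0, 1.0)
            recs.append(rec)
        rep = compare_groups(build_table(recs), properties=("m",))
        assert rep.loc[0, "test"] == "t-test"
        assert rep.loc[0, "p_value"] < 0.001

    def test_heavy_tails_routed_to_mann_whitney(self):
        rng = np.random.default_rng(8)
        recs = []
        for i in range(60):
            rec = {"cell_id": 0, "synapse_id": i,
                   "position_01": 0.25 if i < 30 else 0.75}
            for col in CLUSTER_PROPERTIES:
                rec[col] = rng.normal()
            rec["m"] = rng.standard_cauchy()    # non-normal by construction
            recs.append(rec)
        rep = compare_groups(build_table(recs), properties=("m",))
        assert rep.loc[0, "test"] == "mann-whitney"

    def test_tiny_group_skipped_with_flag(self):
        table, _ = _profile_table(10, seed=9)
        table["position_group"] = ["a"] * 8 + ["b"] * 2
        rep = compare_groups(table, properties=("m",))
        assert bool(rep.loc[0, "skipped"])

    def test_cluster_anova_detects_separated_clusters(self):
        table, _ = _profile_table(30)
        out = cluster(table, k=3, seed=0)
        rep = compare_clusters(out, properties=("m",))
        assert rep.loc[0, "anova_p"] < 1e-6
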
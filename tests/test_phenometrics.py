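"""Phenotype metrics against closed forms and constructions."""

import numpy as np
import pandas as pd
import pytest

from ccmkit.phenometrics import (
    MetricParams,
    collectivity_cosine,
    compute_phenotype_table,
    expected_nn_distance,
    msd_slope,
    nn_distance_index,
    normalized_cell_count,
    qc_filter_tracks,
)
from ccmkit.simkit import SimulationConfig, simulate_point_pattern, simulate_tracks

from conftest import make_trackset


class TestQcFilter:
    def test_track_with_250px_step_excluded(self):
        ts = make_trackset([(1, 0, 0, 0), (1, 1, 250.0, 0.0),
                            (2, 0, 0, 0), (2, 1, 10.0, 0.0)])
        filtered, excluded = qc_filter_tracks(ts, MetricParams())
        assert excluded == [1]
        assert set(filtered.track_ids) == {2}

    def test_step_exactly_at_threshold_retained(self):
        ts = make_trackset([(1, 0, 0, 0), (1, 1, 200.0, 0.0)])
        _, excluded = qc_filter_tracks(ts, MetricParams())
        assert excluded == []

    def test_gap_spanning_step_is_not_a_jump(self):
        # 300 px over a 2-frame gap is not a single-interval jump
        ts = make_trackset([(1, 0, 0, 0), (1, 2, 300.0, 0.0)])
        _, excluded = qc_filter_tracks(ts, MetricParams())
        assert excluded == []


class TestCellCount:
    def test_constant_population_is_flat_one(self):
        rows = [(i, f, 10.0 * i, 10.0 * i) for i in range(50) for f in range(4)]
        series = normalized_cell_count(make_trackset(rows))
        assert (series == 1.0).all()

    def test_doubling_population(self):
        rows = [(i, f, 5.0 * i, 5.0) for i in range(50) for f in range(3)]
        rows += [(100 + i, 2, 3.0 * i, 8.0) for i in range(50)]
        series = normalized_cell_count(make_trackset(rows))
        assert series.loc[0] == 1.0 and series.loc[2] == 2.0

    def test_empty_first_frame_raises(self):
        ts = make_trackset([(1, 1, 0, 0), (1, 2, 1, 1)])
        with pytest.raises(ValueError):
            normalized_cell_count(ts)

    def test_division_rate_matches_branching_expectation(self):
        # E[N(t)] = N0 * exp(lambda * t) for a pure birth process
        lam = 0.03  # divisions/cell/hour
        counts = []
        for seed in range(5):
            cfg = SimulationConfig(n_cells_t0=300, n_frames=97,
                                   diffusion_coefficient=2.0,
                                   division_rate=lam, seed=seed)
            counts.append(normalized_cell_count(simulate_tracks(cfg)).iloc[-1])
        expected = np.exp(lam * 48.0)
        assert np.mean(counts) == pytest.approx(expected, rel=0.05)


class TestNnIndex:
    def test_lattice_closed_forms(self):
        pp = simulate_point_pattern("square_lattice", 400, 200, 200)
        area = 200.0 * 200.0
        p1 = MetricParams(nn_order=1, nn_expectation_order="matched")
        p2 = MetricParams(nn_order=2, nn_expectation_order="matched")
        assert nn_distance_index(pp.points, area, p1) == pytest.approx(2.0)
        assert nn_distance_index(pp.points, area, p2) == pytest.approx(4.0 / 3.0)

    def test_expected_distance_closed_forms(self):
        rho = 0.01
        assert expected_nn_distance(rho, 1) == pytest.approx(1 / (2 * np.sqrt(rho)))
        assert expected_nn_distance(rho, 2) == pytest.approx(3 / (4 * np.sqrt(rho)))

    def test_too_few_cells_is_nan_with_warning(self):
        with pytest.warns(UserWarning):
            v = nn_distance_index(np.array([[0.0, 0.0], [1.0, 1.0]]), 100.0,
                                  MetricParams(nn_order=2))
        assert np.isnan(v)

    def test_clustered_pattern_scores_below_csr(self):
        params = MetricParams(nn_order=2, nn_expectation_order="matched")
        csr = simulate_point_pattern("CSR", 1000, 1000, 1000, seed=0)
        thomas = simulate_point_pattern("Thomas_cluster", 1000, 1000, 1000,
                                        {"sigma": 10.0}, seed=0)
        assert (nn_distance_index(thomas.points, 1e6, params)
                < nn_distance_index(csr.points, 1e6, params))


class TestMsd:
    def test_stationary_cells_have_zero_slope(self):
        rows = [(i, f, 100.0 + i, 200.0) for i in range(5) for f in range(20)]
        assert msd_slope(make_trackset(rows)) == pytest.approx(0.0)

    def test_slope_invariant_under_translation_and_rotation(self):
        cfg = SimulationConfig(field_width=50000, field_height=50000,
                               n_cells_t0=50, n_frames=30,
                               diffusion_coefficient=10.0, seed=4)
        ts = simulate_tracks(cfg)
        base = msd_slope(ts)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        xy = ts.data[["x", "y"]].to_numpy() @ rot.T + np.array([123.0, -55.0])
        moved = ts.with_data(ts.data.assign(x=xy[:, 0], y=xy[:, 1]))
        assert msd_slope(moved) == pytest.approx(base, rel=1e-9)

    def test_gap_spans_do_not_contribute(self):
        # one track with a gap: only lag pairs inside gapless runs count
        rows = [(1, 0, 0.0, 0.0), (1, 1, 10.0, 0.0),
                (1, 3, 500.0, 0.0), (1, 4, 510.0, 0.0)]
        curve_slope = msd_slope(make_trackset(rows))
        # both usable lag-1 displacements are 10 px -> MSD(30) = 100
        assert curve_slope == pytest.approx(100.0 / 30.0)

    def test_no_usable_pairs_raises(self):
        rows = [(1, 0, 0.0, 0.0), (1, 20, 5.0, 0.0)]
        with pytest.raises(ValueError):
            msd_slope(make_trackset(rows))


class TestCosine:
    def test_shared_displacement_gives_one(self, shared_drift_trackset):
        assert collectivity_cosine(shared_drift_trackset) == pytest.approx(1.0)

    def test_antiparallel_gives_minus_one(self):
        rows = []
        for f in range(5):
            rows.append((1, f, 100.0 + 5 * f, 100.0))
            rows.append((2, f, 120.0 - 5 * f, 100.0))
        assert collectivity_cosine(make_trackset(rows)) == pytest.approx(-1.0)

    def test_rotation_invariance(self, random_walk_trackset):
        base = collectivity_cosine(random_walk_trackset)
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        xy = random_walk_trackset.data[["x", "y"]].to_numpy() @ rot.T
        moved = random_walk_trackset.with_data(
            random_walk_trackset.data.assign(x=xy[:, 0], y=xy[:, 1]))
        assert collectivity_cosine(moved) == pytest.approx(base, rel=1e-9)

    def test_common_drift_increases_cosine_monotonically(self, random_walk_trackset):
        vals = []
        for drift in (0.0, 10.0, 60.0):
            df = random_walk_trackset.data.copy()
            df["x"] = df["x"] + drift * df["frame"]
            vals.append(collectivity_cosine(random_walk_trackset.with_data(df)))
        assert vals[0] < vals[1] < vals[2]
        assert vals[2] > 0.9

    def test_zero_displacements_undefined(self):
        rows = [(1, 0, 1.0, 1.0), (1, 1, 1.0, 1.0),
                (2, 0, 2.0, 2.0), (2, 1, 2.0, 2.0)]
        with pytest.warns(UserWarning):
            assert np.isnan(collectivity_cosine(make_trackset(rows)))


class TestPhenotypeTable:
    def test_empty_input_gives_empty_table(self):
        table = compute_phenotype_table([])
        assert table.empty
        assert "cosine_similarity" in table.columns

    def test_sentinel_jump_track_leaves_displacement_metrics_unchanged(self):
        cfg = SimulationConfig(n_cells_t0=60, n_frames=20,
                               diffusion_coefficient=5.0, seed=11)
        ts = simulate_tracks(cfg)
        base = compute_phenotype_table([ts]).iloc[0]
        sentinel = pd.DataFrame({
            "track_id": [9999, 9999], "frame": [0, 1],
            "x": [1.0, 999.0], "y": [1.0, 1.0],
        })
        spiked_df = pd.concat([ts.data[["track_id", "frame", "x", "y"]], sentinel],
                              ignore_index=True)
        spiked = compute_phenotype_table([ts.with_data(spiked_df)]).iloc[0]
        assert spiked["msd_slope"] == pytest.approx(base["msd_slope"])
        assert spiked["cosine_similarity"] == pytest.approx(base["cosine_similarity"])
        assert spiked["n_tracks_excluded"] == base["n_tracks_excluded"] + 1

    def test_metadata_propagates(self):
        cfg = SimulationConfig(n_cells_t0=30, n_frames=5, seed=0)
        ts = simulate_tracks(cfg, condition="OSM", knockdown="siHIF1A", replicate=2)
        row = compute_phenotype_table([ts]).iloc[0]
        assert (row["condition"], row["knockdown"], row["replicate"]) == \
            ("OSM", "siHIF1A", 2)
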
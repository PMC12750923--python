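"""Pair pipeline, summary statistics, pooling, heatmaps, cohort driver."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pairmorph.mesh_core import read_mesh, write_mesh
from pairmorph.symmetry_pipeline import (
    CorrespondenceSet,
    PipelineConfig,
    export_heatmap,
    pool_group,
    run_cohort,
    run_pair,
    summarize,
)
from pairmorph.synthetic_data import AsymmetrySpec, make_pair


def _cs(distances, include=None, bone="femur", subject="S1"):
    d = np.asarray(distances, dtype=float)
    inc = np.ones(len(d), dtype=bool) if include is None else include
    return CorrespondenceSet(distances=d, include=inc, bone=bone, subject_id=subject)


def _sorted_percentile(values, q):
    """Independent order-statistic oracle: sort + linear interpolation."""
    v = np.sort(np.asarray(values, dtype=float))
    pos = (q / 100.0) * (len(v) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    # interpolate from the nearer order statistic for bit-stable rounding
    if frac < 0.5:
        return v[lo] + frac * (v[hi] - v[lo])
    return v[hi] - (1 - frac) * (v[hi] - v[lo])


class TestSummarize:
    def test_small_example(self):
        d = np.concatenate([np.tile([1, 2, 3, 4, 5], 20)])
        s = summarize(_cs(d))
        assert s.median == 3.0

    def test_degenerate_distribution(self):
        s = summarize(_cs(np.full(200, 1.7)))
        assert s.p1 == s.q1 == s.median == s.q3 == s.p99 == 1.7

    def test_matches_sort_based_oracle_exactly(self):
        rng = np.random.default_rng(12)
        d = rng.gamma(2.0, 0.4, size=10_000)
        s = summarize(_cs(d))
        for stat, q in [("p1", 1), ("q1", 25), ("median", 50), ("q3", 75), ("p99", 99)]:
            assert getattr(s, stat) == _sorted_percentile(d, q)
        assert s.n_cps == 10_000
        assert s.p1 <= s.q1 <= s.median <= s.q3 <= s.p99

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 10, allow_nan=False), min_size=100, max_size=400))
    def test_oracle_property(self, values):
        s = summarize(_cs(values))
        assert s.median == _sorted_percentile(values, 50)
        assert s.p1 <= s.q1 <= s.median <= s.q3 <= s.p99

    def test_too_few_cps_rejected(self):
        with pytest.raises(ValueError, match="too few"):
            summarize(_cs(np.ones(50)))

    def test_excluded_cps_do_not_contribute(self):
        d = np.concatenate([np.full(150, 0.5), np.full(150, 99.0)])
        include = np.concatenate([np.ones(150, bool), np.zeros(150, bool)])
        s = summarize(_cs(d, include))
        # identical to explicitly filtering the array first
        s_filtered = summarize(_cs(d[:150]))
        assert s.to_dict() == s_filtered.to_dict()
        assert s.p99 == 0.5


class TestPoolGroup:
    def test_single_pair_pool_equals_pair_summary(self):
        cs = _cs(np.linspace(0, 2, 300), bone="tibia")
        report = pool_group([cs], ["no"])
        assert report.pooled["no"]["tibia"] == summarize(cs).to_dict()

    def test_counts_are_conserved(self):
        a = _cs(np.full(200, 1.0))
        b = _cs(np.full(300, 3.0))
        report = pool_group([a, b], ["no", "no"])
        assert report.pooled["no"]["femur"]["n_cps"] == 500

    def test_pooled_median_of_two_point_masses(self):
        a = _cs(np.full(200, 1.0))
        b = _cs(np.full(200, 3.0))
        report = pool_group([a, b], ["low-grade", "low-grade"])
        assert report.pooled["low-grade"]["femur"]["median"] == 2.0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown group"):
            pool_group([_cs(np.ones(200))], ["severe"])


class TestHeatmap:
    def test_scalar_channel_round_trip(self, patella_surrogate, tmp_path):
        d = np.full(patella_surrogate.n_vertices, 0.5)
        cs = _cs(d, bone="patella")
        out = export_heatmap(
            patella_surrogate, cs, tmp_path / "hm", render=True
        )
        back = read_mesh(out["ply"])
        assert back.scalars is not None
        assert np.allclose(back.scalars, 0.5, atol=1e-6)
        assert out["png"].exists()

    def test_vertex_count_mismatch_rejected(self, patella_surrogate, tmp_path):
        with pytest.raises(ValueError, match="vertex count"):
            export_heatmap(patella_surrogate, _cs(np.ones(10)), tmp_path / "x")


class TestRunPair:
    @pytest.fixture(scope="class")
    def patella_pair_result(self, patella_surrogate):
        left, right, _ = make_pair(
            patella_surrogate,
            AsymmetrySpec(
                bumps=[], noise_sigma=0.0, misalign_rot_deg=15, misalign_trans_mm=10
            ),
            seed=13,
        )
        cfg = PipelineConfig(seed=2)
        return run_pair(left, right, "patella", cfg, subject_id="P1")

    def test_perfect_symmetry_yields_near_zero_distances(self, patella_pair_result):
        cs, _ = patella_pair_result
        assert summarize(cs).median < 0.1

    def test_artifacts_are_complete(self, patella_pair_result):
        _, art = patella_pair_result
        assert art["trim_spec"].keep_end == "none"
        assert art["exclusion"].include.all()
        assert art["nonrigid_trace"].iterations >= 1
        json.dumps(art["pre_rigid"].to_dict())  # serializable

    def test_distances_align_with_right_mesh(self, patella_pair_result):
        cs, art = patella_pair_result
        assert len(cs.distances) == art["right_trimmed"].n_vertices
        assert (cs.distances >= 0).all()

    def test_stage_errors_are_labelled(self, patella_surrogate):
        bad = PipelineConfig(seed=0)
        bad.nonrigid = type(bad.nonrigid)(w=0.0, beta=10.0, lam=1.0)
        left, right, _ = make_pair(
            patella_surrogate, AsymmetrySpec(bumps=[]), seed=1
        )
        with pytest.raises(Exception, match="femur"):
            # femur path demands an elongated mesh: alignment fails and the
            # error message carries the stage context
            run_pair(left, right, "femur", bad)


class TestRunCohort:
    @pytest.fixture(scope="class")
    def small_manifest(self, patella_surrogate, tmp_path_factory):
        td = tmp_path_factory.mktemp("cohort")
        rows = []
        for i, group in enumerate(["no", "low-grade", "high-grade"]):
            left, right, _ = make_pair(
                patella_surrogate,
                AsymmetrySpec(bumps=[], noise_sigma=0.1),
                seed=40 + i,
            )
            lp, rp = td / f"s{i}_l.stl", td / f"s{i}_r.stl"
            write_mesh(left, lp)
            write_mesh(right, rp)
            rows.append(
                {
                    "subject_id": f"S{i}",
                    "bone": "patella",
                    "left_path": lp.name,
                    "right_path": rp.name,
                    "group": group,
                }
            )
        manifest = td / "manifest.csv"
        pd.DataFrame(rows).to_csv(manifest, index=False)
        return manifest

    def test_three_row_manifest(self, small_manifest, tmp_path):
        report = run_cohort(
            small_manifest,
            PipelineConfig(seed=5),
            out_dir=tmp_path / "out",
            write_heatmaps=False,
        )
        assert len(report.per_pair) == 3
        assert not report.failures
        assert set(report.pooled) == {"no", "low-grade", "high-grade"}
        csv = pd.read_csv(tmp_path / "out" / "per_pair_summaries.csv")
        assert list(csv.subject_id) == ["S0", "S1", "S2"]
        assert (tmp_path / "out" / "cohort_report.json").exists()
        assert (tmp_path / "out" / "resolved_config.json").exists()

    def test_bad_path_recorded_and_run_continues(self, small_manifest, tmp_path):
        df = pd.read_csv(small_manifest)
        df.loc[1, "left_path"] = "missing.stl"
        # duplicate the surviving group label so pooling still has every group
        df.loc[1, "group"] = "no"
        broken = small_manifest.parent / "broken.csv"
        df.to_csv(broken, index=False)
        report = run_cohort(broken, PipelineConfig(seed=5), write_heatmaps=False)
        assert len(report.failures) == 1
        assert report.failures[0]["subject_id"] == "S1"
        assert len(report.per_pair) == 2

    def test_rerun_is_bit_identical(self, small_manifest, tmp_path):
        for d in ("r1", "r2"):
            run_cohort(
                small_manifest,
                PipelineConfig(seed=5),
                out_dir=tmp_path / d,
                write_heatmaps=False,
            )
        assert (tmp_path / "r1" / "per_pair_summaries.csv").read_bytes() == (
            tmp_path / "r2" / "per_pair_summaries.csv"
        ).read_bytes()

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"subject_id": ["a"], "bone": ["femur"]}).to_csv(p, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            run_cohort(p)
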
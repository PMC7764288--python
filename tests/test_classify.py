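"""Classification: CTC rule, EMT/PD-L1 boundaries, clusters, profiles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctcpheno import (
    DEFAULT_CALIBRATION,
    PatientCTCProfile,
    SceneSpec,
    aggregate_patient_profile,
    assign_clusters,
    classify_cells,
    classify_emt,
    classify_pdl1,
    compare_timepoints,
    identify_ctc,
    keratin_positivity_cutoff,
    quartile_strata,
    sample_cell_table,
)
from ctcpheno.classify import SINGLETON_ID, ClusterAssignment

from conftest import noiseless_spec, quantify_scene


class TestIdentifyCtc:
    @pytest.mark.parametrize(
        "dapi,ker,cd45,expected",
        [
            (True, 100.0, False, True),   # the CTC definition
            (True, 100.0, True, False),   # CD45 exclusion
            (True, 0.0, False, False),    # keratin-negative
            (False, 100.0, False, False), # no nucleus
            (True, 10.0, False, False),   # below cutoff
        ],
    )
    def test_rule(self, dapi, ker, cd45, expected):
        assert bool(identify_ctc(dapi, ker, cd45, keratin_cutoff=50.0)) is expected

    def test_cutoff_from_cd45_negative_controls(self):
        cells = pd.DataFrame(
            {
                "ctcf_ker": np.r_[np.linspace(0, 10, 100), 500.0],
                "cd45_positive": np.r_[np.ones(100, bool), [False]],
            }
        )
        cutoff = keratin_positivity_cutoff(cells)
        assert cutoff == pytest.approx(np.quantile(np.linspace(0, 10, 100), 0.99))
        assert keratin_positivity_cutoff(cells, override=7.5) == 7.5

    def test_cutoff_floor_without_controls(self):
        cells = pd.DataFrame({"ctcf_ker": [5.0], "cd45_positive": [False]})
        assert keratin_positivity_cutoff(cells) == 0.0


class TestEmtCall:
    def test_boundary_ratio_is_epithelial(self):
        ratio, cls = classify_emt(0.88 * 100.0, 100.0)
        assert ratio == pytest.approx(0.88) and cls == "eCTC"

    def test_just_above_boundary_is_mesenchymal(self):
        _, cls = classify_emt(0.8800001 * 100.0, 100.0)
        assert cls == "mCTC"

    def test_negative_vimentin_clamps_to_zero(self):
        ratio, cls = classify_emt(-5.0, 100.0)
        assert ratio == 0.0 and cls == "eCTC"

    def test_nonpositive_keratin_rejected(self):
        with pytest.raises(ValueError):
            classify_emt(10.0, 0.0)


class TestPdl1Call:
    @pytest.mark.parametrize(
        "value,expected_class,expected_gap",
        [
            (40.0, "negative_low", False),  # epithelial-reference upper bound
            (60.0, "positive", False),      # mesenchymal-reference lower bound
            (50.0, "positive", True),       # inter-range gap
            (400.0, "positive", False),     # above the mesenchymal range: still positive
            (0.0, "negative_low", False),
        ],
    )
    def test_threshold_and_gap(self, value, expected_class, expected_gap):
        cls, gap = classify_pdl1(value)
        assert cls == expected_class and gap is expected_gap


class TestClusters:
    def test_touching_pair_from_image(self):
        spec = noiseless_spec(
            n_cells_per_class={"epithelial-CTC": 1, "mesenchymal-CTC": 0, "pbmc": 0},
            cluster_spec=(("mesenchymal-CTC", 2),),
            seed=15,
        )
        result, truth = quantify_scene(spec)
        ctc_ids = result.cells["cell_id"].astype(int).tolist()
        a = assign_clusters(ctc_ids, label_image=result.cell_labels, adjacency_px=2)
        assert a.n_clusters == 1
        (members,) = a.clusters.values()
        assert len(members) == 2

    def test_chain_of_seven_is_one_cluster(self):
        spec = noiseless_spec(
            image_height_px=320, image_width_px=320,
            n_cells_per_class={"epithelial-CTC": 0, "mesenchymal-CTC": 0, "pbmc": 0},
            cluster_spec=(("mesenchymal-CTC", 7),),
            seed=16,
        )
        result, _ = quantify_scene(spec)
        assert len(result.cells) == 7
        a = assign_clusters(
            result.cells["cell_id"].astype(int).tolist(),
            label_image=result.cell_labels, adjacency_px=2,
        )
        assert a.n_clusters == 1
        assert len(next(iter(a.clusters.values()))) == 7

    def test_isolated_cells_are_singles(self):
        cents = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])
        a = assign_clusters([1, 2, 3], centroids=cents, max_centroid_distance=10.0)
        assert a.n_clusters == 0
        assert all(a.cell_to_cluster[c] == SINGLETON_ID for c in (1, 2, 3))

    def test_minimum_cluster_size_is_two(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            ClusterAssignment(cell_to_cluster={1: 1}, clusters={1: [1]})

    def test_partition_property(self):
        rng = np.random.default_rng(17)
        cents = rng.uniform(0, 200, (40, 2))
        ids = list(range(1, 41))
        a = assign_clusters(ids, centroids=cents, max_centroid_distance=15.0)
        # every CTC in exactly one component
        assert set(a.cell_to_cluster) == set(ids)
        in_clusters = [c for members in a.clusters.values() for c in members]
        assert len(in_clusters) == len(set(in_clusters))
        for cid, members in a.clusters.items():
            assert all(a.cell_to_cluster[c] == cid for c in members)

    def test_empty_input(self):
        a = assign_clusters([], centroids=np.zeros((0, 2)), max_centroid_distance=5.0)
        assert a.n_clusters == 0 and a.cell_to_cluster == {}


class TestQuartiles:
    def test_octet_oracle(self):
        strata = quartile_strata([1, 2, 3, 4, 5, 6, 7, 8])
        assert list(strata) == ["LQ", "LQ", "MID", "MID", "MID", "MID", "HQ", "HQ"]

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(18)
        for _ in range(20):
            vals = rng.uniform(0, 5, int(rng.integers(4, 30)))
            strata = quartile_strata(vals)
            q1, q3 = np.quantile(vals, [0.25, 0.75])
            for v, s in zip(vals, strata):
                expected = "LQ" if v <= q1 else ("HQ" if v >= q3 else "MID")
                assert s == expected

    def test_all_equal_tiebreaks_to_mid(self):
        with pytest.warns(UserWarning, match="degenerate"):
            strata = quartile_strata([2.0, 2.0, 2.0, 2.0])
        assert list(strata) == ["MID"] * 4

    def test_fewer_than_four_all_na(self):
        assert list(quartile_strata([1.0, 2.0, 3.0])) == ["NA"] * 3


def _calls_df(rows):
    return pd.DataFrame(
        rows,
        columns=["cell_id", "is_ctc", "vim_ker_ratio", "emt_class", "pdl1_class",
                 "pdl1_gap_flag", "quartile_stratum"],
    )


class TestPatientProfile:
    def test_worked_example(self):
        # 1 single eCTC + one cluster of 2 PD-L1+ mCTCs
        calls = _calls_df(
            [
                (1, True, 0.1, "eCTC", "negative_low", False, "NA"),
                (2, True, 2.0, "mCTC", "positive", False, "NA"),
                (3, True, 3.0, "mCTC", "positive", False, "NA"),
            ]
        )
        a = ClusterAssignment(cell_to_cluster={1: SINGLETON_ID, 2: 1, 3: 1}, clusters={1: [2, 3]})
        p = aggregate_patient_profile(calls, a, "P1", "D1")
        assert p.total_ctc == 3 and p.cluster_ctc_cells == 2 and p.single_ctc == 1
        assert p.e_ctc == 1 and p.m_ctc == 2
        assert p.cluster_pdl1pos_m_ctc == 2 and p.has_cluster_pdl1pos_mctc
        assert not p.has_single_mctc
        assert p.predominantly_mesenchymal  # 2/3 >= 0.5

    def test_no_ctcs_all_zero_false(self):
        calls = _calls_df([(1, False, np.nan, "NA", "NA", False, "NA")])
        a = ClusterAssignment(cell_to_cluster={}, clusters={})
        p = aggregate_patient_profile(calls, a, "P1")
        assert p.total_ctc == 0
        assert not p.predominantly_mesenchymal
        assert not any(
            getattr(p, f) for f in
            ("has_cluster", "has_cluster_mctc", "has_single_mctc")
        )

    def test_predominance_boundary_at_half(self):
        calls = _calls_df(
            [
                (1, True, 2.0, "mCTC", "positive", False, "NA"),
                (2, True, 0.1, "eCTC", "negative_low", False, "NA"),
            ]
        )
        a = ClusterAssignment(cell_to_cluster={1: SINGLETON_ID, 2: SINGLETON_ID}, clusters={})
        p = aggregate_patient_profile(calls, a, "P1")
        assert p.m_ctc == 1 and p.total_ctc == 2
        assert p.predominantly_mesenchymal  # exactly 50% counts

    def test_mixed_patient_ids_rejected(self):
        calls = _calls_df([(1, True, 0.1, "eCTC", "negative_low", False, "NA")]).assign(
            patient_id=["P1"]
        )
        calls = pd.concat([calls, calls.assign(patient_id="P2", cell_id=2)])
        a = ClusterAssignment(cell_to_cluster={}, clusters={})
        with pytest.raises(ValueError, match="mixed patient ids"):
            aggregate_patient_profile(calls, a, "P1")

    @given(
        emt=st.lists(st.sampled_from(["eCTC", "mCTC"]), min_size=0, max_size=20),
        pdl1_bits=st.lists(st.booleans(), min_size=20, max_size=20),
        cluster_bits=st.lists(st.booleans(), min_size=20, max_size=20),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_flag_count_coherence(self, emt, pdl1_bits, cluster_bits):
        n = len(emt)
        rows = [
            (i + 1, True, 2.0 if emt[i] == "mCTC" else 0.1, emt[i],
             "positive" if pdl1_bits[i] else "negative_low", False, "NA")
            for i in range(n)
        ]
        calls = _calls_df(rows)
        # pair consecutive clustered cells into 2-cell clusters
        clustered = [i + 1 for i in range(n) if cluster_bits[i]]
        clusters, c2c = {}, {}
        for k in range(0, len(clustered) - 1, 2):
            cid = k // 2 + 1
            clusters[cid] = clustered[k : k + 2]
            for c in clusters[cid]:
                c2c[c] = cid
        for i in range(n):
            c2c.setdefault(i + 1, SINGLETON_ID)
        a = ClusterAssignment(cell_to_cluster=c2c, clusters=clusters)
        p = aggregate_patient_profile(calls, a, "P1")
        assert p.single_ctc + p.cluster_ctc_cells == p.total_ctc
        assert p.e_ctc + p.m_ctc <= p.total_ctc
        assert p.has_cluster == (p.n_clusters > 0)
        assert p.has_cluster_mctc == (p.cluster_m_ctc > 0)
        assert p.has_single_mctc == (p.single_m_ctc > 0)
        assert p.has_single_pdl1pos_mctc == (p.single_pdl1pos_m_ctc > 0)
        if p.total_ctc:
            assert p.predominantly_mesenchymal == (p.m_ctc / p.total_ctc >= 0.5)


class TestCompareTimepoints:
    def _profile(self, pid, total, single):
        return PatientCTCProfile(
            patient_id=pid, timepoint="D1", total_ctc=total,
            single_ctc=single, cluster_ctc_cells=total - single,
        )

    def test_trichotomy(self):
        d1 = self._profile("P1", 6, 6)
        d8 = PatientCTCProfile(
            patient_id="P1", timepoint="D8", total_ctc=2, single_ctc=2, cluster_ctc_cells=0
        )
        table = compare_timepoints(d1, d8).set_index("count")
        assert table.loc["total_ctc", "delta"] == -4
        assert table.loc["total_ctc", "trend"] == "decreased"
        assert table.loc["cluster_ctc_cells", "trend"] == "unchanged"

    def test_unchanged(self):
        d1 = self._profile("P1", 4, 4)
        d8 = PatientCTCProfile(
            patient_id="P1", timepoint="D8", total_ctc=4, single_ctc=4, cluster_ctc_cells=0
        )
        assert (compare_timepoints(d1, d8)["trend"] == "unchanged").all()

    def test_mismatched_patients_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            compare_timepoints(self._profile("P1", 1, 1), self._profile("P2", 1, 1))

    def test_trichotomy_tallies_match_counting_oracle(self):
        rng = np.random.default_rng(20)
        trends = []
        for i in range(30):
            t1, t8 = int(rng.integers(0, 10)), int(rng.integers(0, 10))
            d1 = self._profile(f"P{i}", t1, t1)
            d8 = PatientCTCProfile(
                patient_id=f"P{i}", timepoint="D8", total_ctc=t8, single_ctc=t8,
                cluster_ctc_cells=0,
            )
            row = compare_timepoints(d1, d8).set_index("count").loc["total_ctc"]
            trends.append((t8 - t1, row["trend"]))
        for delta, trend in trends:
            assert trend == ("increased" if delta > 0 else "decreased" if delta < 0 else "unchanged")


class TestEndToEndTableRecovery:
    def test_perfect_class_recovery_inside_ranges(self):
        spec = SceneSpec(
            image_height_px=1500, image_width_px=1500,
            n_cells_per_class={"epithelial-CTC": 100, "mesenchymal-CTC": 100, "pbmc": 100},
            seed=22,
        )
        cells, truth = sample_cell_table(spec)
        calls = classify_cells(cells, DEFAULT_CALIBRATION)
        merged = calls.merge(truth[["cell_id", "class"]], on="cell_id")
        is_ctc_truth = merged["class"] != "pbmc"
        assert (merged["is_ctc"] == is_ctc_truth).all()
        ctcs = merged[is_ctc_truth]
        assert (
            ctcs["emt_class"]
            == ctcs["class"].map({"epithelial-CTC": "eCTC", "mesenchymal-CTC": "mCTC"})
        ).all()
        assert (
            ctcs["pdl1_class"]
            == ctcs["class"].map(
                {"epithelial-CTC": "negative_low", "mesenchymal-CTC": "positive"}
            )
        ).all()

    def test_mesenchymal_enrichment_contingency_feed(self):
        # the cluster-vs-single x e/m table is computable from module outputs
        spec = SceneSpec(
            image_height_px=900, image_width_px=900,
            n_cells_per_class={"epithelial-CTC": 20, "mesenchymal-CTC": 10, "pbmc": 20},
            cluster_spec=(("mesenchymal-CTC", 3), ("mesenchymal-CTC", 2), ("epithelial-CTC", 2)),
            seed=23,
        )
        cells, truth = sample_cell_table(spec)
        calls = classify_cells(cells, DEFAULT_CALIBRATION)
        ctc_ids = calls.loc[calls["is_ctc"], "cell_id"].astype(int).tolist()
        cents = cells.set_index("cell_id").loc[ctc_ids, ["x", "y"]].to_numpy()
        a = assign_clusters(ctc_ids, centroids=cents,
                            max_centroid_distance=2 * spec.nucleus_radius_px)
        merged = calls.set_index("cell_id")
        table = np.zeros((2, 2), int)
        for cid in ctc_ids:
            row = 0 if a.is_clustered(cid) else 1
            col = 0 if merged.loc[cid, "emt_class"] == "mCTC" else 1
            table[row, col] += 1
        assert table.sum() == len(ctc_ids)
        assert table[0].sum() == 7  # 3+2+2 clustered cells
        from ctcpheno import chi_square_2x2

        result = chi_square_2x2(table + 1)  # +1 guard against zero marginals
        assert 0 <= result.p <= 1
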
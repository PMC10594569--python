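import numpy as np
import pandas as pd
import pytest

import qminet as q


def _anc_stub(hits, extras=(), log2fc=0.5):
    """Minimal ANCResult with the given hit interactions."""
    all_ids = list(hits) + list(extras)
    table = pd.DataFrame(
        {
            "n_pairs": 4,
            "n_significant": [4 if i in hits else 0 for i in all_ids],
            "f_consistent": [1.0 if i in hits else 0.0 for i in all_ids],
            "modal_direction": [1 if i in hits else 0 for i in all_ids],
            "hit": [i in hits for i in all_ids],
            "median_log2fc": log2fc,
            "pvalues": [(0.001,) * 4] * len(all_ids),
            "directions": [(1,) * 4] * len(all_ids),
        },
        index=pd.Index(all_ids, name="interaction"),
    )
    return q.ANCResult(
        table=table,
        alpha_used=0.001,
        base_alpha=0.05,
        contrast=("starved", "refed"),
        n_comparisons=4,
        n_interactions_tested=len(all_ids),
        n_null_comparisons=16,
    )


def _membership(rows):
    return pd.DataFrame(rows, columns=["interaction", "module", "kME", "p"])


def _module_trait(rows):
    return pd.DataFrame(rows, columns=["module", "hypothesis", "r", "p"])


class TestIntersectHits:
    def test_joint_hit_included(self):
        anc = _anc_stub(hits=["A_B"], extras=["C_D"])
        mem = _membership([("A_B", "red", 0.9, 0.01), ("C_D", "red", 0.8, 0.01)])
        mt = _module_trait([("red", "refed", 0.8, 0.001)])
        hcs = q.intersect_hits(anc, mem, mt, hypothesis="refed")
        assert hcs.interactions == ["A_B"]
        assert hcs.table.loc["A_B", "module"] == "red"
        assert hcs.modules_of_interest == ["red"]

    def test_anc_hit_outside_interesting_module_excluded(self):
        anc = _anc_stub(hits=["A_B"])
        mem = _membership([("A_B", "blue", 0.9, 0.01)])
        mt = _module_trait([("blue", "refed", 0.2, 0.4)])  # not trait-significant
        hcs = q.intersect_hits(anc, mem, mt, hypothesis="refed")
        assert hcs.interactions == []

    def test_negative_kme_excluded(self):
        anc = _anc_stub(hits=["A_B"])
        mem = _membership([("A_B", "red", -0.9, 0.01)])
        mt = _module_trait([("red", "refed", 0.8, 0.001)])
        assert q.intersect_hits(anc, mem, mt, hypothesis="refed").interactions == []

    def test_empty_anc_gives_empty_set(self):
        anc = _anc_stub(hits=[], extras=["A_B"])
        mem = _membership([("A_B", "red", 0.9, 0.01)])
        mt = _module_trait([("red", "refed", 0.8, 0.001)])
        assert len(q.intersect_hits(anc, mem, mt, hypothesis="refed")) == 0

    def test_unknown_hypothesis_errors(self):
        anc = _anc_stub(hits=["A_B"])
        mem = _membership([("A_B", "red", 0.9, 0.01)])
        mt = _module_trait([("red", "refed", 0.8, 0.001)])
        with pytest.raises(q.ValidationError, match="hypothesis"):
            q.intersect_hits(anc, mem, mt, hypothesis="nonesuch")

    def test_any_hypothesis_mode(self):
        anc = _anc_stub(hits=["A_B", "C_D"])
        mem = _membership([("A_B", "red", 0.9, 0.01), ("C_D", "blue", 0.9, 0.01)])
        mt = _module_trait(
            [("red", "refed", 0.8, 0.001), ("blue", "time", 0.7, 0.01)]
        )
        hcs = q.intersect_hits(anc, mem, mt, hypothesis=None)
        assert hcs.interactions == ["A_B", "C_D"]


class TestLog2FC:
    def _matrix_meta(self, a_vals, b_vals):
        samples = [f"a{i}" for i in range(len(a_vals))] + [f"b{i}" for i in range(len(b_vals))]
        matrix = q.MFIMatrix(
            pd.DataFrame([list(a_vals) + list(b_vals)], index=["A_B"], columns=samples),
            "linear",
        )
        meta = q.SampleMetadata(
            pd.DataFrame(
                {
                    "sample_id": samples,
                    "biological_replicate_id": [f"r{i}" for i in range(len(samples))],
                    "condition": ["starved"] * len(a_vals) + ["refed"] * len(b_vals),
                    "batch_id": "b1",
                    "technical_duplicate_index": 1,
                    "pair_key": [f"r{i}" for i in range(len(samples))],
                }
            )
        )
        return matrix, meta

    def test_identical_means_give_zero(self):
        matrix, meta = self._matrix_meta([100, 200], [150, 150])
        fc = q.compute_log2fc(matrix, "starved", "refed", meta)
        assert fc.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_doubling_gives_one(self):
        matrix, meta = self._matrix_meta([100, 100], [200, 200])
        assert q.compute_log2fc(matrix, "starved", "refed", meta).iloc[0] == pytest.approx(1.0)

    def test_requires_linear_scale(self):
        matrix, meta = self._matrix_meta([100, 100], [200, 200])
        log2 = q.log2_transform(matrix)
        with pytest.raises(q.ValidationError):
            q.compute_log2fc(log2, "starved", "refed", meta)

    def test_recovers_planted_effect(self, small_experiment):
        cfg, (beads, meta, _traits, truth) = small_experiment
        mfi = q.collapse_to_mfi(beads, meta)
        fc = q.compute_log2fc(mfi, "starved", "refed", meta)
        planted = truth.responsive_interactions("refed")
        assert abs(fc.loc[planted].mean() - 0.5) <= 0.1


class TestScaleByRowMedian:
    def test_examples_and_invariants(self):
        matrix = q.MFIMatrix(
            pd.DataFrame(
                [[7.0, 7.0, 7.0], [100.0, 200.0, 300.0]],
                index=["A_A", "A_B"],
                columns=["s1", "s2", "s3"],
            ),
            "linear",
        )
        scaled = q.scale_by_row_median(matrix)
        assert np.allclose(scaled.values.loc["A_A"], 1.0)
        assert scaled.values.loc["A_B"].tolist() == [0.5, 1.0, 1.5]
        assert np.allclose(scaled.values.median(axis=1), 1.0)
        pd.testing.assert_frame_equal(scaled.unscale(), matrix.values)


class TestModuleActivity:
    def _scaled(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            rng.uniform(50, 150, size=(4, 8)),
            index=[f"I{i}_P{i}" for i in range(4)],
            columns=[f"s{j}" for j in range(8)],
        )
        return q.scale_by_row_median(q.MFIMatrix(values, "linear"))

    def test_identical_groups_give_null_anova(self):
        scaled = self._scaled()
        # two "conditions" with identical per-sample activity profiles
        act_vals = scaled.values.mean(axis=0)
        dup = pd.concat([scaled.values, scaled.values], axis=1)
        dup.columns = [f"g1_{c}" for c in scaled.values.columns[:8]] + [
            f"g2_{c}" for c in scaled.values.columns[:8]
        ]
        scaled2 = q.ScaledMatrix(values=dup, row_medians=scaled.row_medians)
        groups = pd.Series(
            ["g1"] * 8 + ["g2"] * 8, index=dup.columns
        )
        act = q.module_activity(scaled2, list(dup.index), groups)
        assert act.anova_f == pytest.approx(0.0, abs=1e-12)
        assert act.anova_p == pytest.approx(1.0)
        assert np.allclose(act.activity.iloc[:8].to_numpy(), act_vals.to_numpy())

    def test_single_member_module_activity_is_its_row(self):
        scaled = self._scaled()
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=scaled.values.columns)
        act = q.module_activity(scaled, [scaled.values.index[0]], groups)
        assert np.allclose(act.activity, scaled.values.iloc[0])

    def test_small_group_excluded_with_warning(self):
        scaled = self._scaled()
        groups = pd.Series(["a"] * 4 + ["b"] * 3 + ["c"], index=scaled.values.columns)
        with pytest.warns(UserWarning, match="excluded"):
            act = q.module_activity(scaled, list(scaled.values.index), groups)
        assert set(act.posthoc[["group_a", "group_b"]].to_numpy().ravel()) == {"a", "b"}

    def test_bonferroni_scales_raw_p(self):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(
            rng.uniform(50, 150, size=(3, 12)),
            index=[f"I{i}_P{i}" for i in range(3)],
            columns=[f"s{j}" for j in range(12)],
        )
        scaled = q.scale_by_row_median(q.MFIMatrix(values, "linear"))
        groups = pd.Series(["a"] * 4 + ["b"] * 4 + ["c"] * 4, index=values.columns)
        act = q.module_activity(scaled, list(values.index), groups)
        assert len(act.posthoc) == 3
        for _, row in act.posthoc.iterrows():
            assert row["p_bonferroni"] == pytest.approx(min(1.0, row["p_raw"] * 3))


class TestPCA:
    def test_rank_one_data(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        matrix = q.MFIMatrix(
            pd.DataFrame(
                [10 + v, 10 + 2 * v, 10 - v],
                index=["A_A", "A_B", "B_A"],
                columns=["s1", "s2", "s3", "s4"],
            ),
            "log2",
        )
        _scores, frac = q.pca_coordinates(matrix)
        assert frac[0] == pytest.approx(1.0)

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(2)
        matrix = q.MFIMatrix(
            pd.DataFrame(
                rng.normal(size=(10, 8)),
                index=[f"I{i}_P{i}" for i in range(10)],
                columns=[f"s{j}" for j in range(8)],
            ),
            "log2",
        )
        scores, frac = q.pca_coordinates(matrix)
        gram = scores.to_numpy().T @ scores.to_numpy()
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8
        assert frac.sum() == pytest.approx(1.0)

    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 8))
        matrix = q.MFIMatrix(
            pd.DataFrame(X, index=[f"I{i}_P{i}" for i in range(10)],
                         columns=[f"s{j}" for j in range(8)]),
            "log2",
        )
        scores, frac = q.pca_coordinates(matrix)
        Xc = X.T - X.T.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc @ Xc.T)
        order = np.argsort(evals)[::-1]
        evals = evals[order][: scores.shape[1]]
        evecs = evecs[:, order]
        assert np.allclose((scores.to_numpy() ** 2).sum(axis=0), np.clip(evals, 0, None),
                           atol=1e-8)
        for i in range(3):
            s = scores.to_numpy()[:, i] / np.linalg.norm(scores.to_numpy()[:, i])
            e = evecs[:, i]
            assert min(np.abs(s - e).max(), np.abs(s + e).max()) < 1e-8

    def test_too_few_samples(self):
        matrix = q.MFIMatrix(
            pd.DataFrame([[1.0, 2.0]], index=["A_B"], columns=["s1", "s2"]), "log2"
        )
        with pytest.raises(q.ValidationError):
            q.pca_coordinates(matrix)


def brute_force_average_linkage(dist):
    """O(n^3) agglomeration returning sorted merge heights."""
    clusters = {i: [i] for i in range(dist.shape[0])}
    heights = []
    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in clusters:
                if a >= b:
                    continue
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters.pop(b)
    return sorted(heights)


class TestHierarchicalClusterSamples:
    def _matrix(self, cols):
        arr = np.asarray(cols, dtype=float).T
        return q.MFIMatrix(
            pd.DataFrame(
                arr,
                index=[f"I{i}_P{i}" for i in range(arr.shape[0])],
                columns=[f"s{j}" for j in range(arr.shape[1])],
            ),
            "log2",
        )

    def test_identical_samples_merge_first_at_zero(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=6)
        w = rng.normal(size=6)
        matrix = self._matrix([v, v, w])
        dendro = q.hierarchical_cluster_samples(matrix)
        first = dendro.merges[0]
        assert first[2] == pytest.approx(0.0, abs=1e-12)
        assert {int(first[0]), int(first[1])} == {0, 1}

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        matrix = self._matrix(rng.normal(size=(6, 12)))
        dendro = q.hierarchical_cluster_samples(matrix)
        X = matrix.values.to_numpy()
        dist = 1 - np.corrcoef(X.T)
        np.fill_diagonal(dist, 0.0)
        oracle = brute_force_average_linkage(dist)
        assert np.allclose(sorted(dendro.merges[:, 2]), oracle, atol=1e-12)

    def test_constant_sample_named_in_error(self):
        rng = np.random.default_rng(6)
        cols = [rng.normal(size=5), np.full(5, 3.0), rng.normal(size=5)]
        with pytest.raises(q.ValidationError, match="s1"):
            q.hierarchical_cluster_samples(self._matrix(cols))


class TestEdgeList:
    def _hcs(self, rows):
        table = pd.DataFrame(
            rows,
            columns=["interaction", "direction", "log2fc", "module", "anc_hit", "cna_hit"],
        ).set_index("interaction")
        return q.HighConfidenceSet(
            table=table, contrast=("starved", "refed"), modules_of_interest=["red"]
        )

    def test_empty_set_writes_header_only(self, tmp_path):
        hcs = self._hcs([])
        path = tmp_path / "edges.tsv"
        q.export_edge_list(hcs, path)
        from qminet.report import EDGE_COLUMNS

        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].split("\t") == list(EDGE_COLUMNS)

    def test_round_trip_and_flags(self, tmp_path):
        hcs = self._hcs(
            [
                ("EIF4G_EIF4E", 1, 0.24, "red", True, True),
                ("AKT_AKT", -1, -0.31, "red", True, True),
            ]
        )
        path = tmp_path / "edges.tsv"
        q.export_edge_list(hcs, path)
        df = q.read_edge_list(path)
        assert len(df) == 2
        assert df.loc[0, "source"] == "EIF4G" and df.loc[0, "target"] == "EIF4E"
        assert bool(df.loc[1, "is_abundance"]) and not bool(df.loc[0, "is_abundance"])
        for _, row in df.iterrows():
            assert row["direction"] == np.sign(row["log2fc"])
        back = df["source"] + "_" + df["target"]
        assert set(back) == set(hcs.interactions)
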
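import numpy as np
import pandas as pd
import pytest

from semshift.embedding import EmbeddedCorpus
from semshift.novelty import (
    MinDistanceNovelty,
    Thresholds,
    calibrate_thresholds,
    e_min,
    most_novel_per_window,
    t1_novel,
    t2_trend,
    y1_trajectory,
    y2_proportions,
)
from semshift.synthetic import CloudScenario, gen_cloud, is_cluster_member

TH = Thresholds(2.3, 4.0, "synthetic-study")


def cloud(vectors_by_window):
    """Build an EmbeddedCorpus from {window: [(id, vector), ...]}."""
    ids, rows, wof = [], [], {}
    for w, docs in vectors_by_window.items():
        for did, vec in docs:
            ids.append(did)
            rows.append(np.asarray(vec, dtype=float))
            wof[did] = w
    return EmbeddedCorpus(doc_ids=ids, vectors=np.vstack(rows), window_of=wof, embedder_tag="synthetic")


class TestEmin:
    def test_exact_match_returns_zero_and_that_id(self):
        d, i = e_min(np.array([1.0, 2.0]), ["a", "b"], np.array([[0.0, 0.0], [1.0, 2.0]]))
        assert d == 0.0 and i == "b"

    def test_hand_geometry(self):
        d, i = e_min(np.array([3.0, 3.0]), ["a", "b"], np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert d == pytest.approx(1.0) and i == "b"

    def test_tie_breaks_to_smallest_id(self):
        d, i = e_min(np.array([0.0, 0.0]), ["zz", "aa"], np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert d == pytest.approx(1.0) and i == "aa"

    def test_empty_comparator_errors(self):
        with pytest.raises(ValueError):
            e_min(np.zeros(2), [], np.zeros((0, 2)))

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(size=(300, 8))
        ids = [f"r{i:04d}" for i in range(300)]
        det = MinDistanceNovelty().fit(ref, ids=ids)
        queries = rng.normal(size=(50, 8))
        fast = det.decision_function(queries)
        slow = np.array([min(np.linalg.norm(q - r) for r in ref) for q in queries])
        np.testing.assert_allclose(fast, slow, atol=1e-9)


class TestT1:
    def test_duplicated_docs_are_never_novel(self):
        past = [(f"p{i}", [i, 0]) for i in range(5)]
        cur = [(f"c{i}", [i, 0]) for i in range(5)]
        rep = t1_novel(cloud({0: past, 1: cur}), 1, thresholds=TH)
        assert not rep.is_novel.any()
        assert (rep.e_min == 0).all()

    def test_single_offset_doc_flagged(self):
        past = [(f"p{i}", [0.1 * i, 0]) for i in range(5)]
        cur = [("near", [0.2, 0]), ("far", [10.0, 0])]
        rep = t1_novel(cloud({0: past, 1: cur}), 1, thresholds=TH).set_index("doc_id")
        assert bool(rep.loc["far", "is_novel"]) and not bool(rep.loc["near", "is_novel"])
        assert rep.index[0] == "far"  # sorted by e_min descending

    def test_monotone_in_s_rel(self):
        ec = gen_cloud(CloudScenario(seed=1))
        sizes = []
        for s_rel in (0.5, 1.5, 2.3, 5.0, 50.0):
            rep = t1_novel(ec, 2, thresholds=Thresholds(s_rel, s_rel + 100, "synthetic-study"))
            sizes.append(int(rep.is_novel.sum()))
        assert sizes == sorted(sizes, reverse=True)
        assert sizes[-1] == 0  # s_rel far beyond any distance

    def test_first_window_has_no_past(self):
        ec = gen_cloud(CloudScenario(seed=0))
        with pytest.raises(ValueError):
            t1_novel(ec, 0, thresholds=TH)

    def test_previous_window_comparator(self):
        past = [("p0", [0, 0])]
        mid = [("m0", [10, 0])]
        cur = [("c0", [10.1, 0])]
        # vs previous window only, c0 sits next to m0 -> not novel
        rep = t1_novel(cloud({0: past, 1: mid, 2: cur}), 2, comparator="previous_window", thresholds=TH)
        assert not rep.is_novel.any()
        # vs cumulative past it is also not novel (m0 is in the past); sanity
        rep2 = t1_novel(cloud({0: past, 1: mid, 2: cur}), 2, thresholds=TH)
        assert not rep2.is_novel.any()


class TestMostNovel:
    def test_known_farthest_point_wins(self):
        past = [(f"p{i}", [0.1 * i, 0]) for i in range(4)]
        w1 = [("a", [1.0, 0]), ("b", [20.0, 0])]
        w2 = [("c", [2.0, 0]), ("d", [-30.0, 0])]
        out = most_novel_per_window(cloud({0: past, 1: w1, 2: w2}), thresholds=TH).set_index("window")
        assert out.loc[1, "doc_id"] == "b"
        assert out.loc[2, "doc_id"] == "d"
        assert len(out) == 2  # windows - 1

    def test_tie_goes_to_smallest_id(self):
        past = [("p", [0, 0])]
        w1 = [("zz", [5.0, 0]), ("aa", [-5.0, 0])]
        out = most_novel_per_window(cloud({0: past, 1: w1}), thresholds=TH)
        assert out.iloc[0].doc_id == "aa"


class TestT2:
    def test_hand_geometry_k1(self):
        past = [("p0", [0.0, 0.0])]
        cur = [("t", [3.0, 0.0]), ("buddy", [3.5, 0.0])]
        rep = t2_trend(cloud({0: past, 1: cur}), 1, k=1, thresholds=Thresholds(2.3, 4.0, "s")).set_index("doc_id")
        # t: e_min 3.0 > 2.3, d_new 0.5, d_old 3.0 -> trend, ratio 6
        assert bool(rep.loc["t", "is_trend"])
        assert rep.loc["t", "ratio"] == pytest.approx(6.0)

    def test_t1_failure_blocks_trend(self):
        past = [("p0", [0.0, 0.0])]
        cur = [("near", [1.0, 0.0]), ("near2", [1.2, 0.0])]
        rep = t2_trend(cloud({0: past, 1: cur}), 1, k=1, thresholds=TH)
        assert not rep.is_trend.any()  # dense new neighbourhood but e_min < s_rel

    def test_trend_subset_of_novel(self):
        for seed in range(5):
            ec = gen_cloud(CloudScenario(seed=seed))
            rep = t2_trend(ec, 2, k=3, thresholds=TH)
            assert not (rep.is_trend & ~rep.is_novel).any()

    def test_planted_cluster_flagged_isolated_singleton_not(self):
        rng = np.random.default_rng(0)
        past = [(f"p{i}", rng.normal(0, 1, 2)) for i in range(30)]
        clust = [(f"n{i}", np.array([10.0, 0.0]) + rng.normal(0, 1, 2)) for i in range(10)]
        lone = [("lone", np.array([-40.0, 0.0]))]
        bg = [(f"b{i}", rng.normal(0, 1, 2)) for i in range(10)]
        rep = t2_trend(cloud({0: past, 1: clust + lone + bg}), 1, k=3, thresholds=TH).set_index("doc_id")
        assert rep.loc[[f"n{i}" for i in range(10)], "is_trend"].all()
        assert not bool(rep.loc["lone", "is_trend"])  # novel but no trendy neighbourhood
        assert bool(rep.loc["lone", "is_novel"])
        assert not rep.loc[[f"b{i}" for i in range(10)], "is_trend"].any()

    def test_k_too_large_gives_nan_not_abort(self):
        past = [("p0", [0.0, 0.0]), ("p1", [1.0, 0.0])]
        cur = [("a", [10.0, 0.0]), ("b", [10.5, 0.0])]
        rep = t2_trend(cloud({0: past, 1: cur}), 1, k=5, thresholds=TH)
        assert rep.d_k_new.isna().all() and rep.d_k_old.isna().all()
        assert not rep.is_trend.any()


class TestY1:
    def test_identical_vectors_all_hops_zero(self):
        ec = cloud({w: [(f"d{w}{i}", [1.0, 2.0]) for i in range(3)] for w in range(4)})
        traj = y1_trajectory(ec)
        assert (traj.hops_.hop_length == 0).all()

    def test_known_centroid_hop(self):
        ec = cloud(
            {
                0: [("a", [0.0, 0.0, 0.0]), ("b", [0.0, 0.0, 0.0])],
                1: [("c", [3.0, 4.0, 0.0])],
            }
        )
        traj = y1_trajectory(ec)
        assert traj.hops_.hop_length.iloc[0] == pytest.approx(5.0)

    def test_translation_leaves_hops_unchanged(self):
        ec = gen_cloud(CloudScenario(seed=2))
        shifted = EmbeddedCorpus(
            doc_ids=ec.doc_ids, vectors=ec.vectors + np.array([100.0, -7.0]),
            window_of=ec.window_of, embedder_tag=ec.embedder_tag,
        )
        np.testing.assert_allclose(
            y1_trajectory(ec).hops_.hop_length, y1_trajectory(shifted).hops_.hop_length, atol=1e-9
        )

    def test_shifting_one_window_moves_adjacent_hops_by_at_most_offset(self):
        ec = gen_cloud(CloudScenario(seed=3))
        v = np.array([2.0, -1.0])
        vecs = ec.vectors.copy()
        mask = ec.window_mask(1)
        vecs[mask] += v
        shifted = EmbeddedCorpus(ec.doc_ids, vecs, ec.window_of, ec.embedder_tag)
        h0 = y1_trajectory(ec).hops_.hop_length.to_numpy()
        h1 = y1_trajectory(shifted).hops_.hop_length.to_numpy()
        assert abs(h1[0] - h0[0]) <= np.linalg.norm(v) + 1e-9
        assert abs(h1[1] - h0[1]) <= np.linalg.norm(v) + 1e-9
        np.testing.assert_allclose(h0[2:], h1[2:], atol=1e-9)

    def test_empty_window_spans_gap_with_flag(self):
        ec = cloud({0: [("a", [0.0, 0.0])], 2: [("b", [1.0, 0.0])]})
        ec.window_of["b"] = 2  # window 1 has no docs
        traj = y1_trajectory(ec)
        assert traj.hops_.spans_gap.iloc[0]

    def test_hops_measured_in_full_space_not_projection(self):
        # centroids form a high-dimensional simplex: PCA-2 cannot preserve all hops
        ec = cloud({w: [(f"d{w}", np.eye(5)[w] * 10)] for w in range(5)})
        traj = y1_trajectory(ec)
        np.testing.assert_allclose(traj.hops_.hop_length, 10 * np.sqrt(2), atol=1e-9)
        proj_hops = np.linalg.norm(np.diff(traj.projection_2d_.to_numpy(), axis=0), axis=1)
        assert not np.allclose(proj_hops, traj.hops_.hop_length)


class TestY2:
    def test_coincident_docs_give_zero_proportion(self):
        ec = cloud({w: [(f"d{w}{i}", [float(i), 0.0]) for i in range(4)] for w in range(3)})
        out = y2_proportions(ec, TH)
        assert (out.proportion == 0).all()

    def test_planted_fraction_recovered_exactly(self):
        rng = np.random.default_rng(0)
        past = [(f"p{i}", rng.normal(0, 0.3, 2)) for i in range(80)]
        cur = [(f"c{i:02d}", rng.normal(0, 0.3, 2)) for i in range(80)]
        cur += [(f"n{i:02d}", np.array([50.0, 0.0]) + rng.normal(0, 0.3, 2)) for i in range(20)]
        out = y2_proportions(cloud({0: past, 1: cur}), TH)
        assert out.proportion.iloc[0] == pytest.approx(0.20, abs=0)
        assert out.novel.iloc[0] == 20 and out.total.iloc[0] == 100

    def test_monotone_in_s_rel(self):
        ec = gen_cloud(CloudScenario(seed=4))
        props = [
            y2_proportions(ec, Thresholds(s, s + 100, "synthetic-study")).proportion.to_numpy()
            for s in (0.5, 2.3, 8.0)
        ]
        assert np.all(props[0] >= props[1]) and np.all(props[1] >= props[2])


class TestCalibration:
    def test_perfectly_separated_labels(self):
        rng = np.random.default_rng(0)
        d = np.concatenate([rng.uniform(0.5, 2.0, 200), rng.uniform(5.0, 9.0, 200)])
        y = np.array([1] * 200 + [0] * 200)
        out = calibrate_thresholds(d, y)
        assert 2.0 <= out["s_rel"] <= 5.0
        assert out["s_unrel"] >= out["s_rel"]
        assert not out["requires_review"]

    def test_fdr_holds_by_recount_on_overlapping_mixture(self):
        rng = np.random.default_rng(1)
        related = rng.normal(2.0, 0.5, 500)
        unrelated = rng.normal(6.0, 1.0, 500)
        d = np.concatenate([related, unrelated])
        y = np.array([1] * 500 + [0] * 500)
        out = calibrate_thresholds(d, y, fdr=0.01)
        below = d <= out["s_rel"]
        assert (1 - y[below]).mean() < 0.01

    def test_unlabeled_mode_returns_quantiles_flagged_for_review(self):
        d = np.linspace(0.1, 10.0, 500)
        out = calibrate_thresholds(d)
        assert out["requires_review"]
        assert out["s_rel"] == pytest.approx(np.quantile(d, 0.05))

    def test_too_few_pairs_or_one_class_errors(self):
        with pytest.raises(ValueError):
            calibrate_thresholds([1.0] * 50)
        with pytest.raises(ValueError):
            calibrate_thresholds(np.linspace(0, 1, 200), np.ones(200, dtype=int))
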
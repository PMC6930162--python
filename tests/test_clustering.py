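"""PBM index and cluster-number selection."""

import numpy as np
import pandas as pd
import pytest

from sigprof import clustering as cl
from sigprof import synthetic as syn
from sigprof import traces as tr
from conftest import make_trace


class TestPbmIndex:
    def test_hand_computed_four_point_instance(self):
        sc = cl.pbm_index(
            np.array([0.0, 1.0, 10.0, 11.0]), [0, 0, 1, 1], np.array([0.5, 10.5])
        )
        assert sc.E1 == 20.0
        assert sc.EK == 2.0
        assert sc.DK == 10.0
        assert sc.pbm == 2500.0

    def test_duplicating_every_point_leaves_pbm_unchanged(self):
        X = np.array([0.0, 1.0, 10.0, 11.0])
        cents = np.array([0.5, 10.5])
        a = [0, 0, 1, 1]
        base = cl.pbm_index(X, a, cents)
        doubled = cl.pbm_index(np.concatenate([X, X]), a + a, cents)
        assert doubled.E1 == 2 * base.E1
        assert doubled.EK == 2 * base.EK
        assert doubled.DK == base.DK
        assert doubled.pbm == pytest.approx(base.pbm)

    def test_degenerate_partitions_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cl.pbm_index(np.array([1.0, 1.0, 1.0, 1.0]), [0, 0, 1, 1], np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="K<2"):
            cl.pbm_index(np.array([0.0, 1.0]), [0, 0], np.array([0.5]))

    def test_ek_decreases_under_nested_refinement(self):
        X = np.array([0.0, 0.2, 5.0, 5.2, 10.0, 10.2])
        coarse = np.array([2.6, 2.6, 2.6, 2.6, 10.1, 10.1])
        a2 = [0, 0, 0, 0, 1, 1]
        c2 = np.array([np.mean(X[:4]), 10.1])
        a3 = [0, 0, 1, 1, 2, 2]
        c3 = np.array([0.1, 5.1, 10.1])
        assert cl.pbm_index(X, a3, c3).EK <= cl.pbm_index(X, a2, c2).EK


class TestClusterTraces:
    def test_singleton_clusters_have_zero_within_distance(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        model = cl.cluster_traces(X, K=3, seed=0)
        assert model.inertia == 0.0
        assert model.scores == []  # PBM degenerate for singletons

    def test_two_separated_families_are_perfectly_recovered(self):
        rng = np.random.default_rng(0)
        X = np.vstack(
            [rng.normal(0, 0.1, (30, 5)), rng.normal(8, 0.1, (30, 5))]
        )
        model = cl.cluster_traces(X, K=2, seed=1)
        # purity: no point nearer the other family's centroid
        d = np.linalg.norm(X[:, None, :] - model.centroids[None], axis=2)
        assert np.array_equal(model.assignments, d.argmin(axis=1))
        assert len(set(model.assignments[:30])) == 1
        assert len(set(model.assignments[30:])) == 1

    def test_same_seed_is_deterministic(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 8))
        a = cl.cluster_traces(X, K=3, seed=42)
        b = cl.cluster_traces(X, K=3, seed=42)
        assert np.array_equal(a.assignments, b.assignments)
        assert np.array_equal(a.centroids, b.centroids)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            cl.cluster_traces(np.zeros((3, 2)), K=4, seed=0)


class TestSelectK:
    def test_scores_reported_for_every_candidate_even_when_weak(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.05, (40, 6)), rng.uniform(-3, 3, (20, 6))])
        model = cl.select_k(X, k_range=range(2, 8), seed=0)
        assert [s.K for s in model.scores] == [2, 3, 4, 5, 6, 7]

    def test_strong_two_family_structure_selects_two_for_every_seed(self):
        # between-family distance >= 10x within-family spread
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            X = np.vstack(
                [rng.normal(0, 0.05, (30, 4)), rng.normal(5, 0.05, (30, 4))]
            )
            assert cl.select_k(X, seed=seed).K_selected == 2

    def test_needs_enough_traces(self):
        with pytest.raises(ValueError):
            cl.select_k(np.zeros((4, 3)), k_range=range(2, 8), seed=0)


class TestProfileFractions:
    def _model(self, assignments, K=2):
        return cl.ClusterModel(
            K_selected=K,
            centroids=np.zeros((K, 3)),
            assignments=np.asarray(assignments),
        )

    def _ts(self, n, well="A1", condition="ctl"):
        return tr.TraceSet(
            [
                make_trace([0.0, 1, 0], cell_id=f"{condition}{well}{i}",
                           well=well, condition=condition)
                for i in range(n)
            ],
            condition=condition,
        )

    def test_simple_counts(self):
        model = self._model([0] * 6 + [1] * 4)
        out = cl.profile_fractions(model, self._ts(10))
        assert out["fraction"].tolist() == [0.6, 0.4]

    def test_fractions_sum_to_one_per_well(self):
        rng = np.random.default_rng(0)
        sets = [self._ts(7, well=w) for w in ("A1", "A2", "A3")]
        model = self._model(rng.integers(0, 2, size=21))
        out = cl.profile_fractions(model, sets)
        sums = out.groupby(["condition", "well"])["fraction"].sum()
        assert np.allclose(sums, 1.0)

    def test_pooled_assignment_lookup_recovers_generator_weights(self):
        fams_a = [
            syn.ProfileFamily("lo", (0.1, 0.3), (0.05, 0.06), weight=0.8),
            syn.ProfileFamily("hi", (1.8, 2.2), (0.05, 0.06), weight=0.2),
        ]
        fams_b = [
            syn.ProfileFamily("lo", (0.1, 0.3), (0.05, 0.06), weight=0.3),
            syn.ProfileFamily("hi", (1.8, 2.2), (0.05, 0.06), weight=0.7),
        ]
        n = 300
        ts_a, _ = syn.gen_ca_traces(fams_a, n_cells=n, noise_sd=0.05, seed=1, condition="A")
        ts_b, _ = syn.gen_ca_traces(fams_b, n_cells=n, noise_sd=0.05, seed=2, condition="B")
        al_a = ts_a.map(tr.align_to_stimulus)
        al_b = ts_b.map(tr.align_to_stimulus)
        pooled = np.vstack([al_a.dff_matrix(), al_b.dff_matrix()])
        model = cl.cluster_traces(pooled, K=2, seed=0)
        out = cl.profile_fractions(model, [al_a, al_b])
        # profile 1 is the high-amplitude cluster (amplitude-ordered labels)
        for cond, w_hi in (("A", 0.2), ("B", 0.7)):
            got = (
                out[(out.condition == cond) & (out.profile == 1)]
                .groupby("well")["n_cells"].sum().sum()
            )
            assert abs(got - w_hi * n) <= 3 * np.sqrt(n * w_hi * (1 - w_hi))

    def test_pooling_then_splitting_is_pure_lookup(self):
        sets = [self._ts(5, condition="A"), self._ts(5, condition="B")]
        model = self._model([0, 1] * 5)
        out = cl.profile_fractions(model, sets)
        manual = pd.Series(model.assignments[:5]).value_counts(normalize=True)
        got = out[out.condition == "A"].set_index("profile")["fraction"]
        assert got[0] == manual.get(0, 0) and got[1] == manual.get(1, 0)

    def test_missing_well_labels_rejected(self):
        ts = tr.TraceSet([make_trace([0.0, 1, 0], cell_id="c")], condition="x")
        with pytest.raises(ValueError, match="well"):
            cl.profile_fractions(self._model([0]), ts)
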
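"""Feature assembly, SVM combiner training/scoring, empirical FDR, ranking."""

import math

import numpy as np
import pytest

from riddle import (
    FeatureVector,
    GeneSet,
    RiddleConfig,
    SvmParams,
    compute_features,
    empirical_fdr,
    le_pvalue,
    overlap_stat,
    rank_pathways,
    ras_score,
    reflective_scores,
    train_combiner,
)
from riddle.core import FEATURE_NAMES, CombinerModel, FdrCurve
from riddle.network import network_coverage, set_centrality

from conftest import gene_set


def make_fv(rng, shift=0.0):
    """Synthetic feature vector with a mean shift on the continuous fields."""
    return FeatureVector(
        log_p_hg=float(-rng.exponential(1.0) - shift),
        log_p_le_fwd=float(-rng.exponential(1.0) - shift),
        log_p_le_rev=float(-rng.exponential(1.0) - shift),
        auc_fwd=float(np.clip(0.5 + 0.1 * shift + rng.normal(0, 0.05), 0, 1)),
        auc_rev=float(np.clip(0.5 + 0.1 * shift + rng.normal(0, 0.05), 0, 1)),
        ap_fwd=float(np.clip(0.05 * (1 + shift) + rng.normal(0, 0.01), 0, 1)),
        ap_rev=float(np.clip(0.05 * (1 + shift) + rng.normal(0, 0.01), 0, 1)),
        query_size=int(rng.integers(5, 50)),
        pathway_size=int(rng.integers(5, 50)),
        overlap_size=int(rng.integers(0, 5)),
        query_centrality=float(rng.uniform(1, 10)),
        pathway_centrality=float(rng.uniform(1, 10)),
        query_coverage=float(rng.uniform(0.5, 1.0)),
    )


class TestComputeFeatures:
    def test_composed_features_match_direct_single_ops(self, default_world):
        net = default_world.network
        query = default_world.modules[0]
        pathway = default_world.modules[1]
        cfg = RiddleConfig()
        fv = compute_features(net, query, pathway, cfg)

        hg = overlap_stat(net, query, pathway)
        p_le_fwd, _ = le_pvalue(net, query, pathway, cfg.alpha, cfg.beta)
        p_le_rev, _ = le_pvalue(net, pathway, query, cfg.alpha, cfg.beta)
        fwd, rev = reflective_scores(net, query, pathway, cfg.diffusion)

        assert fv.log_p_hg == pytest.approx(math.log(max(hg.p, 1e-300)))
        assert fv.log_p_le_fwd == pytest.approx(math.log(max(p_le_fwd, 1e-300)))
        assert fv.log_p_le_rev == pytest.approx(math.log(max(p_le_rev, 1e-300)))
        assert (fv.auc_fwd, fv.ap_fwd) == (fwd.auc, fwd.ap)
        assert (fv.auc_rev, fv.ap_rev) == (rev.auc, rev.ap)
        assert (fv.query_size, fv.pathway_size, fv.overlap_size) == (hg.n, hg.m, hg.k)
        assert fv.query_centrality == set_centrality(net, query)
        assert fv.pathway_centrality == set_centrality(net, pathway)
        assert fv.query_coverage == network_coverage(net, query)

    def test_self_match_extremes(self, default_world):
        net = default_world.network
        m = default_world.modules[0]
        fv = compute_features(net, m, m)
        assert fv.overlap_size == fv.query_size == fv.pathway_size
        other = compute_features(net, m, default_world.modules[1])
        assert fv.log_p_hg < other.log_p_hg

    def test_disjoint_sets_have_log_p_zero(self, default_world):
        net = default_world.network
        fv = compute_features(net, default_world.modules[0], default_world.modules[1])
        assert fv.overlap_size == 0
        assert fv.log_p_hg == 0.0

    def test_swap_exchanges_forward_and_reverse(self, default_world):
        net = default_world.network
        a, b = default_world.modules[2], default_world.modules[3]
        f1 = compute_features(net, a, b)
        f2 = compute_features(net, b, a)
        assert (f1.auc_fwd, f1.ap_fwd, f1.log_p_le_fwd) == (f2.auc_rev, f2.ap_rev, f2.log_p_le_rev)
        assert (f1.query_size, f1.query_centrality) == (f2.pathway_size, f2.pathway_centrality)
        assert f1.log_p_hg == f2.log_p_hg

    def test_out_of_network_set_error_names_the_set(self, default_world):
        ghost = gene_set("nope1", "nope2", sid="ghost")
        with pytest.raises(ValueError, match="ghost"):
            compute_features(default_world.network, ghost, default_world.modules[0])

    def test_thirteen_features(self):
        assert len(FEATURE_NAMES) == 13


class TestTrainCombiner:
    def test_separable_features_classified_perfectly(self):
        rng = np.random.default_rng(1)
        pos = [make_fv(rng, shift=6.0) for _ in range(60)]
        neg = [make_fv(rng, shift=0.0) for _ in range(200)]
        model, report = train_combiner(pos, neg, seed=2)
        assert report.accuracy_validation == 1.0

    def test_permuted_labels_score_near_chance(self):
        # one pool, labels assigned at random 50/50: no signal to learn
        rng = np.random.default_rng(3)
        pool = [make_fv(rng, shift=3.0 * rng.random()) for _ in range(240)]
        labels = rng.permutation([1] * 120 + [0] * 120)
        pos = [fv for fv, y in zip(pool, labels) if y == 1]
        neg = [fv for fv, y in zip(pool, labels) if y == 0]
        _, report = train_combiner(pos, neg, seed=4)
        assert 0.25 <= report.accuracy_validation <= 0.75

    def test_default_params_echoed_in_tag(self):
        rng = np.random.default_rng(5)
        pos = [make_fv(rng, shift=6.0) for _ in range(25)]
        neg = [make_fv(rng, shift=0.0) for _ in range(25)]
        model, _ = train_combiner(pos, neg, SvmParams(), seed=0)
        assert model.tag == "w1=1,w0=0.3,C=1e+09,e=0.01,gamma=0.07"

    def test_too_few_examples_rejected(self):
        rng = np.random.default_rng(6)
        pos = [make_fv(rng) for _ in range(5)]
        neg = [make_fv(rng) for _ in range(30)]
        with pytest.raises(ValueError, match="20"):
            train_combiner(pos, neg)


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(7)
    pos = [make_fv(rng, shift=6.0) for _ in range(40)]
    neg = [make_fv(rng, shift=0.0) for _ in range(120)]
    model, _ = train_combiner(pos, neg, seed=8)
    return model, pos, neg


class TestRasScore:
    def test_deterministic(self, separable):
        model, pos, _ = separable
        assert ras_score(model, pos[0]) == ras_score(model, pos[0])

    def test_positive_prototype_above_negative(self, separable):
        model, pos, neg = separable
        assert ras_score(model, pos[0]) > ras_score(model, neg[0])

    def test_standardization_identity(self, separable):
        model, _, _ = separable
        z = model.transform(model.feature_mean)
        np.testing.assert_allclose(z, np.zeros_like(z), atol=1e-12)

    def test_dimension_mismatch_rejected(self, separable):
        model, _, _ = separable
        with pytest.raises(ValueError, match="dimension"):
            model.decision(np.zeros(7))

    def test_save_load_round_trip(self, separable, tmp_path):
        model, pos, _ = separable
        path = tmp_path / "model.joblib"
        model.save(path)
        back = CombinerModel.load(path)
        assert ras_score(back, pos[3]) == ras_score(model, pos[3])

    def test_version_mismatch_refused(self, separable, tmp_path):
        import joblib

        model, _, _ = separable
        path = tmp_path / "model.joblib"
        model.save(path)
        payload = joblib.load(path)
        payload["version"] = "something-else"
        joblib.dump(payload, path)
        with pytest.raises(ValueError, match="version"):
            CombinerModel.load(path)


class TestEmpiricalFdr:
    def test_hand_computed_quarter(self):
        assert empirical_fdr([2, 3, 4], [0, 1, 2], 2) == pytest.approx(0.25)

    def test_score_above_all_negatives_gives_zero(self):
        assert empirical_fdr([2, 3, 4], [0, 1], 2.5) == 0.0

    def test_score_below_all_gives_half(self):
        assert empirical_fdr([2, 3, 4], [0, 1, 2], -10) == pytest.approx(0.5)

    def test_monotone_non_increasing_in_score(self):
        rng = np.random.default_rng(9)
        curve = FdrCurve(rng.normal(1, 1, 200), rng.normal(-1, 1, 200))
        grid = np.linspace(-5, 5, 101)
        vals = [curve(s) for s in grid]
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))
        assert curve(grid[-1]) <= curve(grid[0])

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError):
            empirical_fdr([], [1, 2], 0)


class TestRankPathways:
    def test_identical_pathway_ranks_first(self, default_world, trained):
        model, _ = trained
        net = default_world.network
        query = default_world.modules[0]
        rng = np.random.default_rng(10)
        rand = GeneSet(
            id="rand", name="rand",
            members=frozenset(rng.choice(net.genes, size=25, replace=False)),
        )
        results = rank_pathways(net, model, query, [rand, query])
        assert results[0].pathway_id == query.id
        assert results[0].rank == 1

    def test_ranking_invariant_to_library_order(self, default_world, trained):
        model, _ = trained
        net = default_world.network
        query = default_world.modules[0]
        lib = list(default_world.modules[1:5])
        a = rank_pathways(net, model, query, lib)
        b = rank_pathways(net, model, query, lib[::-1])
        assert [r.pathway_id for r in a] == [r.pathway_id for r in b]

    def test_reciprocal_rank_and_fdr_monotonicity(self, default_world, trained):
        model, _ = trained
        results = rank_pathways(
            default_world.network, model, default_world.modules[0],
            default_world.modules[1:6],
        )
        assert [r.rank for r in results] == list(range(1, len(results) + 1))
        assert results[2].reciprocal_rank == pytest.approx(1 / 3)
        fdrs = [r.fdr for r in results]
        assert all(b >= a - 1e-12 for a, b in zip(fdrs, fdrs[1:]))

    def test_empty_library_rejected(self, default_world, trained):
        model, _ = trained
        with pytest.raises(ValueError):
            rank_pathways(default_world.network, model, default_world.modules[0], [])
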
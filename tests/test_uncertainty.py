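"""The four uncertainty estimators, normalization, aggregation and ranking.

Vectorized maps are checked against a naive per-pixel loop oracle that
evaluates each definition directly, plus the analytic special cases.
"""

import numpy as np
import pandas as pd
import pytest

from tests.conftest import random_ensemble
from lesionseg.architectures import MetaUNet, tiny_config
from lesionseg.data_model import default_schema
from lesionseg.synthetic import GeneratorConfig, generate_dataset
from lesionseg.uncertainty import (DEFAULT_WEIGHTS, PredictionEnsemble,
                                   aggregate_score, cohort_report,
                                   confidence_map, ensemble_from_binary,
                                   entropy_map, epkl_map, image_report,
                                   mcd_predict, mutual_information_map,
                                   normalize_measures, rank_by_uncertainty)

EPS = 1e-12


# ---------------------------------------------------------------------
# naive per-pixel oracle
# ---------------------------------------------------------------------

def naive_maps(probs):
    """Direct per-pixel evaluation of the four definitions (log base 2)."""
    T, H, W, K = probs.shape
    C = np.zeros((H, W))
    Hm = np.zeros((H, W))
    MI = np.zeros((H, W))
    EPKL = np.zeros((H, W))

    def ent(p):
        return -sum(p[k] * np.log2(max(p[k], EPS)) for k in range(K))

    for i in range(H):
        for j in range(W):
            pbar = probs[:, i, j, :].mean(axis=0)
            C[i, j] = pbar.max()
            Hm[i, j] = ent(pbar)
            MI[i, j] = Hm[i, j] - np.mean([ent(probs[t, i, j]) for t in range(T)])
            acc = 0.0
            for a in range(T):
                for b in range(T):
                    if a == b:
                        continue
                    pa = np.clip(probs[a, i, j], EPS, None)
                    pb = np.clip(probs[b, i, j], EPS, None)
                    acc += sum(pa[k] * (np.log2(pa[k]) - np.log2(pb[k]))
                               for k in range(K))
            EPKL[i, j] = acc / (T * (T - 1))
    return C, Hm, MI, EPKL


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed,T", [(0, 2), (1, 3), (2, 5)])
    def test_vectorized_equals_naive_loop(self, seed, T):
        probs = random_ensemble(np.random.default_rng(seed), T=T, h=8, w=8)
        ens = PredictionEnsemble(probs)
        C, H, MI, EPKL = naive_maps(probs)
        np.testing.assert_allclose(confidence_map(ens), C, atol=1e-10)
        np.testing.assert_allclose(entropy_map(ens), H, atol=1e-10)
        np.testing.assert_allclose(mutual_information_map(ens), MI, atol=1e-10)
        np.testing.assert_allclose(epkl_map(ens), EPKL, atol=1e-10)


class TestAnalyticCases:
    def test_confidence_is_max_of_mean(self):
        ens = ensemble_from_binary(np.array([[[0.9]], [[0.5]]]))
        assert confidence_map(ens)[0, 0] == pytest.approx(0.7)

    def test_entropy_uniform_is_one_bit(self):
        ens = ensemble_from_binary(np.full((3, 2, 2), 0.5))
        np.testing.assert_allclose(entropy_map(ens), 1.0)

    def test_entropy_certain_is_zero(self):
        ens = ensemble_from_binary(np.ones((2, 2, 2)))
        np.testing.assert_allclose(entropy_map(ens), 0.0, atol=1e-10)

    def test_entropy_09(self):
        ens = ensemble_from_binary(np.full((2, 1, 1), 0.9))
        expect = -(0.9 * np.log2(0.9) + 0.1 * np.log2(0.1))
        assert entropy_map(ens)[0, 0] == pytest.approx(expect)
        assert entropy_map(ens)[0, 0] == pytest.approx(0.4690, abs=5e-5)

    def test_mi_zero_for_identical_passes(self):
        ens = ensemble_from_binary(np.full((4, 3, 3), 0.73))
        np.testing.assert_allclose(mutual_information_map(ens), 0.0, atol=1e-10)

    def test_mi_maximal_disagreement_is_one_bit(self):
        ens = ensemble_from_binary(np.array([[[1.0]], [[0.0]]]))
        assert mutual_information_map(ens)[0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_epkl_symmetric_pair(self):
        ens = ensemble_from_binary(np.array([[[0.9]], [[0.1]]]))
        expect = 0.8 * np.log2(9.0)
        assert epkl_map(ens)[0, 0] == pytest.approx(expect)
        assert epkl_map(ens)[0, 0] == pytest.approx(2.5359, abs=5e-5)

    def test_epkl_zero_for_identical_passes(self):
        ens = ensemble_from_binary(np.full((5, 2, 2), 0.42))
        np.testing.assert_allclose(epkl_map(ens), 0.0, atol=1e-10)

    def test_epkl_permutation_invariant(self):
        rng = np.random.default_rng(7)
        probs = random_ensemble(rng, T=4, h=3, w=3)
        base = epkl_map(PredictionEnsemble(probs))
        perm = epkl_map(PredictionEnsemble(probs[[2, 0, 3, 1]]))
        np.testing.assert_allclose(base, perm, atol=1e-12)

    def test_epkl_to_mean_variant(self):
        probs = random_ensemble(np.random.default_rng(3), T=3, h=2, w=2)
        ens = PredictionEnsemble(probs)
        p = np.clip(probs, EPS, None)
        pbar = np.clip(probs.mean(axis=0), EPS, None)
        expect = (p * (np.log2(p) - np.log2(pbar)[None])).sum(-1).mean(0)
        np.testing.assert_allclose(epkl_map(ens, "to_mean"), expect, atol=1e-12)

    def test_t1_rejected_for_disagreement_measures(self):
        ens = ensemble_from_binary(np.full((1, 2, 2), 0.5))
        with pytest.raises(ValueError):
            mutual_information_map(ens)
        with pytest.raises(ValueError):
            epkl_map(ens)


class TestPixelwiseInvariants:
    @pytest.mark.parametrize("seed", range(4))
    def test_bounds_and_binary_consistency(self, seed):
        probs = random_ensemble(np.random.default_rng(seed), T=5, h=6, w=6)
        ens = PredictionEnsemble(probs)
        C = confidence_map(ens)
        H = entropy_map(ens)
        MI = mutual_information_map(ens)
        EPKL = epkl_map(ens)
        assert np.all(MI >= -1e-12) and np.all(MI <= H + 1e-12)
        assert np.all(H >= 0) and np.all(H <= 1.0 + 1e-12)  # log2(2 classes)
        assert np.all(EPKL >= -1e-12)
        assert np.all(C >= 0.5 - 1e-12) and np.all(C <= 1.0)
        # binary case: H equals the binary entropy of the max-class probability
        h_of_c = -(C * np.log2(C) + (1 - C) * np.log2(np.clip(1 - C, EPS, None)))
        np.testing.assert_allclose(H, h_of_c, atol=1e-9)


class TestAggregation:
    def test_minmax_normalization(self):
        df = pd.DataFrame({"C": [0.1, 0.2, 0.3]})
        np.testing.assert_allclose(normalize_measures(df)["C"], [0, 0.5, 1])

    def test_degenerate_cohorts_map_to_zero(self):
        one = normalize_measures(pd.DataFrame({"C": [0.4]}))
        const = normalize_measures(pd.DataFrame({"C": [0.4, 0.4]}))
        assert (one["C"] == 0).all() and (const["C"] == 0).all()

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            normalize_measures(pd.DataFrame({"C": []}))

    @pytest.mark.parametrize("inputs,expect", [
        ((1, 0, 0, 0), 0.4),
        ((0.5, 0.5, 0.5, 0.5), 0.1),
        ((0, 1, 0, 1), -0.4),
    ])
    def test_aggregate_examples(self, inputs, expect):
        assert aggregate_score(*inputs) == pytest.approx(expect)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            aggregate_score(1, 0, 0, 0, alpha=-0.1)

    def test_default_weights(self):
        assert DEFAULT_WEIGHTS == (0.4, 0.2, 0.2, 0.2)


def _report_df(scores):
    df = pd.DataFrame({"u_tot": list(scores.values())},
                      index=list(scores.keys()))
    df["cohort_id"] = "c0"
    return df


class TestRanking:
    def test_sorted_descending(self):
        assert rank_by_uncertainty(_report_df({"a": 0.3, "b": 0.1, "c": 0.2})) \
            == ["a", "c", "b"]

    def test_ties_broken_lexicographically(self):
        assert rank_by_uncertainty(_report_df({"b": 0.2, "a": 0.2, "c": 0.2})) \
            == ["a", "b", "c"]

    def test_top_k(self):
        scores = {f"i{n:02d}": n / 50 for n in range(50)}
        assert len(rank_by_uncertainty(_report_df(scores), k=5)) == 5

    def test_mixed_cohorts_rejected(self):
        df = _report_df({"a": 0.1, "b": 0.2})
        df.loc["b", "cohort_id"] = "other"
        with pytest.raises(ValueError):
            rank_by_uncertainty(df)


@pytest.fixture(scope="module")
def bayes_setup(schema):
    cfg = GeneratorConfig(image_size=32, n_samples=4, seed=30)
    samples = generate_dataset(cfg)
    model = MetaUNet(tiny_config(bayesian=True, dropout_rate=0.3),
                     schema, seed=8)
    return model, samples


class TestMCD:

    def test_non_bayesian_model_rejected(self, schema):
        cfg = GeneratorConfig(image_size=32, n_samples=1, seed=31)
        sample = generate_dataset(cfg)[0]
        model = MetaUNet(tiny_config(bayesian=False), schema, seed=0)
        with pytest.raises(ValueError, match="bayesian=True"):
            mcd_predict(model, sample)

    def test_default_T_is_10_and_seeded(self, bayes_setup):
        model, samples = bayes_setup
        ens = mcd_predict(model, samples[0], seed=3)
        assert ens.T == 10
        ens2 = mcd_predict(model, samples[0], seed=3)
        np.testing.assert_array_equal(ens.probs, ens2.probs)
        ens3 = mcd_predict(model, samples[0], seed=4)
        assert not np.array_equal(ens.probs, ens3.probs)

    def test_rate_zero_gives_constant_ensemble(self, schema):
        cfg = GeneratorConfig(image_size=32, n_samples=1, seed=32)
        sample = generate_dataset(cfg)[0]
        model = MetaUNet(tiny_config(bayesian=True, dropout_rate=0.0),
                         schema, seed=0)
        ens = mcd_predict(model, sample, T=4, seed=0)
        for t in range(1, 4):
            np.testing.assert_array_equal(ens.probs[t], ens.probs[0])

    def test_cohort_report_and_utot(self, bayes_setup):
        model, samples = bayes_setup
        reports = [image_report(mcd_predict(model, s, T=4, seed=i))
                   for i, s in enumerate(samples)]
        df = cohort_report(reports, cohort_id="unit")
        assert set(df.columns) >= {"mean_C", "norm_C", "u_tot", "cohort_id"}
        # U_tot recomputed from the normalized columns
        expect = (0.4 * df["norm_C"] - 0.2 * df["norm_H"]
                  + 0.2 * df["norm_MI"] - 0.2 * df["norm_EPKL"])
        np.testing.assert_allclose(df["u_tot"], expect, atol=1e-12)
        assert all(r.cohort_id == "unit" for r in reports)
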
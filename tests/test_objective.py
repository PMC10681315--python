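"""Loss closed forms, sampling distribution, corruption, and training descent."""

import math

import numpy as np
import pytest

import loop_reference as ref
from hyperdrug import autodiff as ad
from hyperdrug.autodiff import Tensor
from hyperdrug.motifs import BranchIncidences
from hyperdrug.objective import (ABLATIONS, Adam, TrainConfig, bpr_loss,
                                 build_loss, corrupt_perms, sample_triples,
                                 ssl_loss, subhypergraph_readout, total_loss,
                                 train)
from hyperdrug.encoder import EncoderParams, self_gate

LN2 = math.log(2.0)


def incidences_for(b, rng, branches="jp"):
    I, deg = {}, {}
    for x in "jpiu":
        if x in branches:
            m = np.triu((rng.random((b, b)) < 0.6) * 1.0, 1)
            m = m + m.T
            I[x], deg[x] = m, m.sum(axis=1)
        else:
            I[x], deg[x] = None, None
    return BranchIncidences(I=I, degrees=deg, contributing={})


class TestSampleTriples:
    def test_single_nonedge_always_chosen(self):
        R = np.ones((3, 4), dtype=np.int64)
        R[:, 2] = 0
        rng = np.random.default_rng(0)
        triples = sample_triples(R, 50, rng)
        assert (triples[:, 2] == 2).all()

    def test_zero_requested_gives_empty(self):
        assert sample_triples(np.ones((2, 2)) - np.eye(2), 0,
                              np.random.default_rng(0)).shape == (0, 3)

    def test_positive_pairs_are_observed_negatives_not(self):
        rng = np.random.default_rng(3)
        R = (rng.random((6, 7)) < 0.4).astype(np.int64)
        R[0] = [1, 0, 0, 1, 0, 0, 0]
        triples = sample_triples(R, 200, np.random.default_rng(1))
        for d, i, j in triples:
            assert R[d, i] == 1 and R[d, j] == 0

    def test_negative_sampling_uniform(self):
        # one drug, 3 positives out of 8 entities -> 5 eligible negatives
        R = np.zeros((1, 8), dtype=np.int64)
        R[0, :3] = 1
        triples = sample_triples(R, 100_000, np.random.default_rng(5))
        counts = np.bincount(triples[:, 2], minlength=8)
        assert counts[:3].sum() == 0
        p = 1 / 5
        sigma = math.sqrt(100_000 * p * (1 - p))
        assert all(abs(c - 100_000 * p) < 3 * sigma for c in counts[3:])

    def test_fully_observed_row_warned_and_skipped(self):
        R = np.ones((2, 3), dtype=np.int64)
        R[1, 0] = 0
        with pytest.warns(UserWarning, match="fully observed"):
            triples = sample_triples(R, 30, np.random.default_rng(2))
        assert (triples[:, 0] == 1).all()


class TestBprLoss:
    def test_tied_scores_give_ln2(self):
        D = Tensor(np.array([[1.0, 0.0]]))
        M = Tensor(np.array([[0.5, 1.0], [0.5, -1.0]]))  # equal scores 0.5
        loss = bpr_loss(np.array([[0, 0, 1]]), D, M)
        assert loss.value == pytest.approx(LN2, abs=1e-9)

    def test_monotone_decreasing_in_margin(self):
        vals = []
        for m in (0.0, 1.0, 5.0, 20.0):
            D = Tensor(np.array([[1.0]]))
            M = Tensor(np.array([[m], [0.0]]))
            vals.append(float(bpr_loss(np.array([[0, 0, 1]]), D, M).value))
        assert vals == sorted(vals, reverse=True)
        assert vals[-1] < 1e-8

    def test_matches_scalar_reference_with_regularizer(self, rng):
        D, M = rng.normal(size=(4, 3)), rng.normal(size=(5, 3))
        theta = [Tensor(rng.normal(size=(3, 3)), requires_grad=True),
                 Tensor(rng.normal(size=3), requires_grad=True)]
        triples = np.array([[0, 1, 2], [1, 0, 3], [3, 4, 0]])
        loss = bpr_loss(triples, Tensor(D), Tensor(M), theta, delta=0.01)
        expect = ref.bpr_reference(triples, D, M,
                                   [t.value for t in theta], 0.01)
        assert loss.value == pytest.approx(expect, abs=1e-10)


class TestReadout:
    def test_unweighted_row_is_plain_mean(self):
        D = Tensor(np.arange(6.0).reshape(3, 2))
        I = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        I[0] = [1, 1, 0]
        S, valid = subhypergraph_readout(D, I)
        np.testing.assert_allclose(S.value[0], (D.value[0] + D.value[1]) / 2)
        assert valid.all()

    def test_weights_kept_divisor_counts_nonzeros(self):
        D = Tensor(np.arange(6.0).reshape(3, 2))
        I = np.array([[2.0, 0.0, 1.0]])
        S, _ = subhypergraph_readout(Tensor(D.value[:3]), I)
        np.testing.assert_allclose(S.value[0],
                                   (2 * D.value[0] + D.value[2]) / 2)

    def test_empty_row_zero_and_invalid(self):
        D = Tensor(np.ones((2, 2)))
        S, valid = subhypergraph_readout(D, np.zeros((2, 2)))
        np.testing.assert_array_equal(S.value, 0.0)
        assert not valid.any()


class TestCorruption:
    def test_conserves_entry_multiset_and_reproducible(self, rng):
        S = rng.normal(size=(5, 4))
        rp, cp = corrupt_perms(5, np.random.default_rng(8), 4)
        rp2, cp2 = corrupt_perms(5, np.random.default_rng(8), 4)
        np.testing.assert_array_equal(rp, rp2)
        np.testing.assert_array_equal(cp, cp2)
        corrupted = ad.permute(Tensor(S), rp, cp).value
        np.testing.assert_allclose(sorted(corrupted.ravel()),
                                   sorted(S.ravel()))

    def test_degenerate_single_cell(self):
        S = np.array([[3.14]])
        rp, cp = corrupt_perms(1, np.random.default_rng(0), 1)
        np.testing.assert_array_equal(ad.permute(Tensor(S), rp, cp).value, S)


class TestSslLoss:
    def test_identical_embeddings_give_two_ln2_per_drug_branch(self):
        b, c = 4, 3
        D = Tensor(np.ones((b, c)))
        I = np.ones((b, b)) - np.eye(b)
        inc = BranchIncidences(I={"j": I, "p": I, "i": None, "u": None},
                               degrees={"j": I.sum(1), "p": I.sum(1),
                                        "i": None, "u": None},
                               contributing={})
        tensors = {}
        for x in "jp":
            tensors[f"P_sg_{x}"] = Tensor(np.zeros((c, c)))
            tensors[f"b_sg_{x}"] = Tensor(np.full(c, 100.0))  # gate ~ 1
        perms = {x: (np.arange(b), np.arange(c)) for x in "jp"}
        loss = ssl_loss(D, tensors, inc, ["j", "p"], perms)
        assert loss.value == pytest.approx(2 * LN2 * b * 2, abs=1e-6)

    def test_strictly_positive(self, rng):
        b, c = 5, 3
        D = Tensor(rng.normal(size=(b, c)))
        inc = incidences_for(b, rng, "jp")
        tensors = {}
        for x in "jp":
            tensors[f"P_sg_{x}"] = Tensor(rng.normal(size=(c, c)))
            tensors[f"b_sg_{x}"] = Tensor(rng.normal(size=c))
        perms = {x: corrupt_perms(b, rng, c) for x in "jp"}
        assert ssl_loss(D, tensors, inc, ["j", "p"], perms).value > 0

    def test_matches_scalar_reference(self, rng):
        b, c = 4, 3
        D = rng.normal(size=(b, c))
        inc = incidences_for(b, rng, "jp")
        values = {}
        tensors = {}
        for x in "jp":
            values[f"P_sg_{x}"] = rng.normal(size=(c, c))
            values[f"b_sg_{x}"] = rng.normal(size=c)
            tensors[f"P_sg_{x}"] = Tensor(values[f"P_sg_{x}"])
            tensors[f"b_sg_{x}"] = Tensor(values[f"b_sg_{x}"])
        perms = {x: corrupt_perms(b, np.random.default_rng(4), c)
                 for x in "jp"}
        mine = ssl_loss(Tensor(D), tensors, inc, ["j", "p"], perms)
        expect = ref.ssl_reference(D, values, inc.I, ["j", "p"], perms)
        assert mine.value == pytest.approx(expect, abs=1e-8)


class TestTotalLoss:
    def test_lambda_zero_is_ranking_only(self):
        Ls, Lself = Tensor(2.5), Tensor(7.0)
        assert total_loss(Ls, Lself, 0.0) is Ls

    def test_linearity_in_lambda(self):
        Ls, Lself = Tensor(2.0), Tensor(3.0)
        for lam in (0.5, 1.0, 2.0):
            assert total_loss(Ls, Lself, lam).value == pytest.approx(
                2.0 + lam * 3.0)


class TestTrain:
    def test_loss_decreases_on_planted_fixture(self):
        from hyperdrug.synthetic import PlantedNetworkSpec, make_planted_network
        from hyperdrug.motifs import build_branch_incidences
        from hyperdrug.network import full_view
        hetero, task = make_planted_network(
            PlantedNetworkSpec(b=20, t=12, seed=7))
        inc = build_branch_incidences(full_view(hetero, task))
        cfg = TrainConfig(dim=8, epochs=30, seed=7)
        result = train(inc, task.R, cfg)
        assert result.trace[-1]["loss_total"] < result.trace[0]["loss_total"]

    def test_lambda_zero_equals_no_ssl_ablation(self, rng):
        inc = incidences_for(6, rng, "jp")
        R = (np.random.default_rng(3).random((6, 5)) < 0.5).astype(np.int64)
        R[R.sum(1) == 0, 0] = 1
        a = train(inc, R, TrainConfig(dim=4, epochs=3, seed=5, lam=0.0))
        b = train(inc, R, TrainConfig(dim=4, epochs=3, seed=5,
                                      ablation="no_ssl"))
        for k in a.params.values:
            np.testing.assert_array_equal(a.params.values[k],
                                          b.params.values[k])

    def test_ablation_configs(self):
        assert TrainConfig(ablation="no_hyper").encoder_config().branches == ()
        assert TrainConfig(ablation="frag_only").encoder_config().branches \
            == ("j", "p")
        assert TrainConfig(ablation="mol_only").encoder_config().branches \
            == ("i", "u")
        assert TrainConfig(ablation="conv").encoder_config().attention \
            == "conv"
        assert TrainConfig(ablation="no_ssl").effective_lam == 0.0
        with pytest.raises(ValueError):
            TrainConfig(ablation="bogus")


class TestGradients:
    def test_full_objective_matches_finite_differences(self, rng):
        """Analytic gradient of the total loss vs central differences."""
        b, t, c = 4, 3, 5
        cfg = TrainConfig(dim=c, layers=2, seed=13, reg=0.01, lam=0.5)
        params = EncoderParams(b, t, cfg.encoder_config())
        # evaluate at an O(0.1) random point: the default near-zero init
        # leaves relu kinks inside the finite-difference window
        pr = np.random.default_rng(99)
        for v in params.values.values():
            v[:] = pr.uniform(-0.5, 0.5, size=v.shape)
        inc = incidences_for(b, rng, "jp")
        R = np.array([[1, 0, 1], [0, 1, 0], [1, 1, 0], [0, 0, 1]], float)
        triples = np.array([[0, 0, 1], [2, 1, 2], [3, 2, 0]])
        perms = {x: corrupt_perms(b, np.random.default_rng(9), c)
                 for x in "jp"}

        L, _, _, state = build_loss(params, inc, R, triples, perms, cfg)
        L.backward()
        analytic = {k: state.tensors[k].grad for k in params.values}

        h = 1e-5
        for name, arr in params.values.items():
            num = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            while not it.finished:
                i = it.multi_index
                orig = arr[i]
                arr[i] = orig + h
                lp = float(build_loss(params, inc, R, triples, perms,
                                      cfg)[0].value)
                arr[i] = orig - h
                lm = float(build_loss(params, inc, R, triples, perms,
                                      cfg)[0].value)
                arr[i] = orig
                num[i] = (lp - lm) / (2 * h)
                it.iternext()
            # block-wise norm comparison: elementwise differences on
            # near-zero entries are dominated by float64 rounding of L
            scale = max(np.linalg.norm(num), np.linalg.norm(analytic[name]),
                        1e-10)
            rel = np.linalg.norm(analytic[name] - num) / scale
            assert rel < 1e-4, f"gradient mismatch in {name}: {rel:.2e}"


def test_adam_moves_toward_minimum():
    values = {"x": np.array([5.0])}
    opt = Adam(values, lr=0.1)
    for _ in range(200):
        opt.step({"x": 2 * values["x"]})  # d/dx x^2
    assert abs(values["x"][0]) < 0.1
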
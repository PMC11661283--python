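"""Attention-MIL deep Cox model: attention approximation, loss, training."""

import numpy as np
import pytest

from mmsurv.autodiff import Tensor
from mmsurv.cohort_io import EmbeddingBag, SurvivalOutcome
from mmsurv.deep_cph import (DeepRiskModel, MILNetConfig, TrainConfig,
                             cox_nlpl_grad, cox_nlpl_loss, forward_bag,
                             init_params, nystrom_attention, predict_bag_risk,
                             train_deep_cph)
from mmsurv.synthetic_cohort import BagConfig, SimulationConfig, simulate_cohort


def exact_attention_oracle(tokens, params, n_heads):
    """Plain softmax multi-head self-attention, coded independently."""
    n, h = tokens.shape
    dh = h // n_heads
    out = np.zeros((n, h))
    q_all = tokens @ params["W_q"]
    k_all = tokens @ params["W_k"]
    v_all = tokens @ params["W_v"]
    for hd in range(n_heads):
        sl = slice(hd * dh, (hd + 1) * dh)
        q, k, v = q_all[:, sl], k_all[:, sl], v_all[:, sl]
        logits = q @ k.T / np.sqrt(dh)
        logits -= logits.max(axis=1, keepdims=True)
        w = np.exp(logits)
        w /= w.sum(axis=1, keepdims=True)
        out[:, sl] = w @ v
    return out @ params["W_o"]


def test_nystrom_matches_exact_attention_when_landmarks_equal_tokens():
    rng = np.random.default_rng(1)
    cfg = MILNetConfig(input_dim=8, proj_dim=16, n_heads=4, n_landmarks=16)
    params = init_params(cfg, seed=0)
    tokens = rng.standard_normal((16, 16))
    approx = nystrom_attention(Tensor(tokens), params, cfg).data
    exact = exact_attention_oracle(tokens, params, cfg.n_heads)
    assert np.abs(approx - exact).max() < 1e-3


def test_nystrom_single_token_is_value_projection():
    cfg = MILNetConfig(input_dim=4, proj_dim=8, n_heads=2, n_landmarks=4)
    params = init_params(cfg, seed=1)
    tok = np.random.default_rng(2).standard_normal((1, 8))
    out = nystrom_attention(Tensor(tok), params, cfg).data
    np.testing.assert_allclose(out, (tok @ params["W_v"]) @ params["W_o"], atol=1e-10)


def test_attention_permutation_equivariant():
    rng = np.random.default_rng(3)
    cfg = MILNetConfig(input_dim=4, proj_dim=8, n_heads=2, n_landmarks=64)  # exact path
    params = init_params(cfg, seed=4)
    tokens = rng.standard_normal((12, 8))
    perm = rng.permutation(12)
    out = nystrom_attention(Tensor(tokens), params, cfg).data
    out_p = nystrom_attention(Tensor(tokens[perm]), params, cfg).data
    np.testing.assert_allclose(out_p, out[perm], atol=1e-10)


def test_nystrom_error_decreases_with_landmarks():
    # moderate token scale keeps the attention kernel in the low-rank regime
    # where the landmark approximation is meaningful
    n = 64
    errs = []
    for m in (4, 8, 16, 32, 64):
        devs = []
        for seed in range(8):
            cfg = MILNetConfig(input_dim=8, proj_dim=16, n_heads=4, n_landmarks=m)
            params = init_params(cfg, seed=seed)
            tokens = 0.5 * np.random.default_rng(100 + seed).standard_normal((n, 16))
            approx = nystrom_attention(Tensor(tokens), params, cfg).data
            exact = exact_attention_oracle(tokens, params, cfg.n_heads)
            devs.append(np.abs(approx - exact).max())
        errs.append(np.mean(devs))
    assert all(b < a for a, b in zip(errs, errs[1:]))
    assert errs[-1] < 1e-3  # landmarks = tokens


# ---------------------------------------------------------------------------
# forward pass


def _small_net(d=6):
    cfg = MILNetConfig(input_dim=d, proj_dim=8, n_heads=2, n_landmarks=8, dropout=0.25)
    return cfg, init_params(cfg, seed=0)


def test_forward_pooling_and_head_contracts():
    cfg, params = _small_net()
    rng = np.random.default_rng(1)
    v = rng.standard_normal((1, cfg.input_dim))
    bag_k = np.repeat(v, 7, axis=0)
    r1 = forward_bag(params, v, cfg)
    rk = forward_bag(params, bag_k, cfg)
    assert rk == pytest.approx(r1, abs=1e-10)  # mean-pool of identical rows
    zeroed = dict(params, W_head=np.zeros_like(params["W_head"]),
                  b_head=np.zeros_like(params["b_head"]))
    assert forward_bag(zeroed, rng.standard_normal((5, cfg.input_dim)), cfg) == 0.0
    bag = rng.standard_normal((9, cfg.input_dim))
    assert forward_bag(params, bag, cfg) == forward_bag(params, bag, cfg)
    with pytest.raises(ValueError, match="input_dim"):
        forward_bag(params, rng.standard_normal((3, cfg.input_dim + 1)), cfg)


def test_predict_bag_risk_contracts():
    cfg, params = _small_net()
    model = DeepRiskModel(params, cfg)
    rng = np.random.default_rng(2)
    vec = rng.standard_normal((10, cfg.input_dim)).astype(np.float32)
    bags = {"a": EmbeddingBag("a", vec), "b": EmbeddingBag("b", vec.copy()),
            "c": EmbeddingBag("c", rng.standard_normal((4, cfg.input_dim)).astype(np.float32))}
    rv = predict_bag_risk(model, bags)
    assert len(rv.scores) == 3
    lookup = dict(zip(rv.patient_ids, rv.scores))
    assert lookup["a"] == lookup["b"]  # identical bags -> identical risks
    # duplicating every patch preserves ranking (mean-pool invariance)
    dup = {p: EmbeddingBag(p, np.vstack([b.vectors, b.vectors])) for p, b in bags.items()}
    rv2 = predict_bag_risk(model, dup)
    assert np.argsort(rv.scores).tolist() == np.argsort(rv2.scores).tolist()


# ---------------------------------------------------------------------------
# loss


def test_nlpl_closed_forms():
    assert cox_nlpl_loss(np.zeros(2), np.array([1.0, 2.0]), np.ones(2)) == \
        pytest.approx(np.log(2) / 2)
    # one event + one longer-surviving censored patient: loss = log(1 + e^{-r})
    for r in (-1.0, 0.0, 2.0):
        loss = cox_nlpl_loss(np.array([r, 0.0]), np.array([1.0, 5.0]), np.array([1.0, 0.0]))
        assert loss == pytest.approx(np.log(1 + np.exp(-r)))
    losses = [cox_nlpl_loss(np.array([r, 0.0]), np.array([1.0, 5.0]), np.array([1.0, 0.0]))
              for r in np.linspace(-2, 2, 9)]
    assert all(b < a for a, b in zip(losses, losses[1:]))  # monotone decreasing in r
    with pytest.raises(ValueError, match="zero events"):
        cox_nlpl_loss(np.zeros(3), np.arange(3.0), np.zeros(3))


def test_nlpl_gradient_matches_finite_differences():
    rng = np.random.default_rng(7)
    risks = rng.standard_normal(20)
    time = rng.exponential(10, 20)
    event = (rng.random(20) < 0.6).astype(float)
    g = cox_nlpl_grad(risks, time, event)
    eps = 1e-6
    for i in range(20):
        e_i = np.zeros(20)
        e_i[i] = eps
        fd = (cox_nlpl_loss(risks + e_i, time, event)
              - cox_nlpl_loss(risks - e_i, time, event)) / (2 * eps)
        assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-9)


# ---------------------------------------------------------------------------
# training


@pytest.fixture(scope="module")
def planted_bag_cohort():
    cfg = SimulationConfig(
        n_patients=120, seed=5, censoring_target=0.3, modalities={},
        bags=BagConfig(dim=16, patches_min=20, patches_max=60, risk_weight=1.5),
        horizon_months=1e9)
    bundle, truth = simulate_cohort(cfg)
    return bundle


def _train(bundle, epochs=8, seed=0):
    net = MILNetConfig(16, proj_dim=32, n_heads=4, dropout=0.1)
    tr = TrainConfig(epochs=epochs, accumulation_size=16, seed=seed)
    return train_deep_cph(bundle.bags, bundle.outcomes["OS"], net, tr)


def test_training_learns_planted_signal(planted_bag_cohort):
    from mmsurv.survival_metrics import harrell_cindex
    model = _train(planted_bag_cohort, epochs=10)
    rv = predict_bag_risk(model, planted_bag_cohort.bags)
    out = planted_bag_cohort.outcomes["OS"].subset(rv.patient_ids)
    assert harrell_cindex(rv.scores, out.time, out.event).point > 0.7
    # loss decreased over the first five epochs
    assert model.history["train_loss"][4] < model.history["train_loss"][0]


def test_training_seed_reproducible(planted_bag_cohort):
    m1 = _train(planted_bag_cohort, epochs=3, seed=9)
    m2 = _train(planted_bag_cohort, epochs=3, seed=9)
    assert m1.history["train_loss"] == m2.history["train_loss"]
    for k in m1.params:
        assert np.array_equal(m1.params[k], m2.params[k])


def test_training_requires_events(planted_bag_cohort):
    out = planted_bag_cohort.outcomes["OS"]
    no_events = SurvivalOutcome(out.patient_ids, out.time, np.zeros(len(out)), "OS")
    net = MILNetConfig(16, proj_dim=32, n_heads=4)
    with pytest.raises(ValueError, match="no events"):
        train_deep_cph(planted_bag_cohort.bags, no_events, net, TrainConfig(epochs=1))


def test_checkpoint_roundtrip(planted_bag_cohort, tmp_path):
    model = _train(planted_bag_cohort, epochs=2)
    model.save(tmp_path / "ckpt")
    back = DeepRiskModel.load(tmp_path / "ckpt")
    bag = next(iter(planted_bag_cohort.bags.values()))
    assert back.risk(bag) == pytest.approx(model.risk(bag), abs=1e-12)
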
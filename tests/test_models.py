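"""Model architectures: BIRNN forward, attention masking, fusion, RF baseline."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from icureadmit.models import (BirnnClassifier, FusedClassifier,
                               TransformerTextScorer, birnn_forward,
                               fit_tabular_baseline)
from icureadmit.nn.autodiff import Tensor, bce_with_logits
from icureadmit.nn.networks import (BirnnNetwork, FusionNetwork,
                                    TransformerTextNetwork, embedding_dim)


@pytest.mark.parametrize("D,expect", [(16, 2), (81, 3), (80, 2), (1, 1), (103, 3)])
def test_embedding_dim_fourth_root_floor(D, expect):
    assert embedding_dim(D) == expect


def _tiny_net(**kw):
    return BirnnNetwork(vocab_size=9, max_len=5, hidden=2, seed=3, **kw)


def test_attention_weights_sum_to_one_over_valid():
    net = _tiny_net()
    batch = {"indices": np.array([[1, 2, 3, 0, 0]]),
             "mask": np.array([[1, 1, 1, 0, 0]], dtype=bool)}
    H, mask = net.pre_attention(batch)
    _, alpha = net.attn(H, mask)
    assert alpha.data[0, :3].sum() == pytest.approx(1.0)
    assert alpha.data[0, 3:].sum() == pytest.approx(0.0)


def test_all_pad_sample_has_defined_output():
    net = _tiny_net()
    batch = {"indices": np.zeros((1, 5), dtype=int),
             "mask": np.zeros((1, 5), dtype=bool)}
    score = net.forward(batch).data
    assert np.isfinite(score).all()
    _, alpha = net.attn(*net.pre_attention(batch))
    assert np.allclose(alpha.data, 0.2)   # uniform fallback


def test_pad_content_cannot_change_score(rng):
    net = _tiny_net()
    idx = np.array([[1, 2, 3, 4, 5]])
    mask = np.array([[1, 1, 1, 0, 0]], dtype=bool)
    base = net.forward({"indices": idx, "mask": mask}).data[0]
    for _ in range(5):
        scrambled = idx.copy()
        scrambled[0, 3:] = rng.integers(0, 9, 2)   # rewrite pad positions
        out = net.forward({"indices": scrambled, "mask": mask}).data[0]
        assert out == pytest.approx(base, abs=1e-12)


def test_birnn_matches_hand_computed_forward():
    """Independent step-by-step numpy forward pass with fixed weights."""
    L, H, D = 4, 2, 5
    net = BirnnNetwork(vocab_size=D, max_len=L, hidden=H, seed=0)
    e = net.emb_dim
    rng = np.random.default_rng(42)
    for p in net.params.values():
        p.data = rng.uniform(-0.5, 0.5, size=p.data.shape)
    idx = np.array([[3, 1, 4, 2]])
    mask = np.ones((1, L), dtype=bool)
    got = net.forward({"indices": idx, "mask": mask}).data[0]

    def sigmoid(x):
        return 1.0 / (1.0 + np.exp(-x))

    def gru_steps(xs, W, U, b, order):
        h = np.zeros(H)
        out = {}
        for t in order:
            p = xs[t] @ W + b
            hp = h @ U
            z = sigmoid(p[:H] + hp[:H])
            r = sigmoid(p[H:2 * H] + hp[H:2 * H])
            n = np.tanh(p[2 * H:] + r * hp[2 * H:])
            h = (1 - z) * n + z * h
            out[t] = h
        return np.stack([out[t] for t in range(L)])

    P = net.params
    xs = P["emb"].data[idx[0]]
    fwd = gru_steps(xs, P["gru_fwd.W"].data, P["gru_fwd.U"].data,
                    P["gru_fwd.b"].data, range(L))
    bwd = gru_steps(xs, P["gru_bwd.W"].data, P["gru_bwd.U"].data,
                    P["gru_bwd.b"].data, range(L - 1, -1, -1))
    Hseq = np.concatenate([fwd, bwd], axis=1)          # (L, 2H)
    scores = Hseq @ P["attn.w"].data[:, 0] + P["attn.b"].data[0]
    alpha = np.exp(scores - scores.max())
    alpha = alpha / alpha.sum()
    pooled = alpha @ Hseq
    expect = pooled @ P["head.w"].data[:, 0] + P["head.b"].data[0]
    assert got == pytest.approx(expect, abs=1e-12)


def test_birnn_reversal_symmetry():
    """Reversing the input and swapping the two GRUs' parameters yields the
    time-reversed, half-swapped pre-attention representation."""
    net = _tiny_net()
    idx = np.array([[1, 2, 3, 4, 5]])
    mask = np.ones((1, 5), dtype=bool)
    H1, _ = net.pre_attention({"indices": idx, "mask": mask})

    swapped = _tiny_net()
    for name, p in net.params.items():
        tgt = (name.replace("gru_fwd", "gru_bwd") if "gru_fwd" in name
               else name.replace("gru_bwd", "gru_fwd"))
        swapped.params[tgt].data = p.data.copy()
    H2, _ = swapped.pre_attention({"indices": idx[:, ::-1], "mask": mask})
    h = net.hidden
    flipped = H2.data[:, ::-1, :]
    assert np.allclose(H1.data[..., :h], flipped[..., h:], atol=1e-12)
    assert np.allclose(H1.data[..., h:], flipped[..., :h], atol=1e-12)


def test_scores_finite_and_deterministic(rng):
    net = BirnnNetwork(vocab_size=20, max_len=8, hidden=4, seed=5)
    batch = {"indices": rng.integers(0, 20, (16, 8)),
             "mask": rng.random((16, 8)) < 0.7}
    a = net.forward(batch).data
    b = net.forward(batch).data
    assert np.isfinite(a).all()
    assert np.array_equal(a, b)


def test_extra_vector_width_checked():
    net = BirnnNetwork(vocab_size=9, max_len=4, hidden=2, extra_dims=3, seed=0)
    batch = {"indices": np.ones((2, 4), dtype=int),
             "mask": np.ones((2, 4), dtype=bool),
             "extra": np.zeros((2, 2))}
    with pytest.raises(ValueError, match="width"):
        net.forward(batch)


# -- fusion ------------------------------------------------------------------

def test_fusion_width_arithmetic():
    charts = BirnnNetwork(vocab_size=103, max_len=6, hidden=7, seed=0)
    icd9 = BirnnNetwork(vocab_size=50, max_len=4, hidden=3, seed=1)
    fused = FusionNetwork({"charts": charts, "icd9": icd9}, static_dims=14)
    assert fused.fusion_width == 2 * 7 + 2 * 3 + 14


def test_fusion_single_component_rejected():
    net = BirnnNetwork(vocab_size=9, max_len=4, hidden=2, seed=0)
    with pytest.raises(ValueError, match="two components"):
        FusionNetwork({"only": net}, static_dims=0)


def test_fusion_zeroed_component_acts_through_head_only(rng):
    a = BirnnNetwork(vocab_size=9, max_len=4, hidden=2, seed=0)
    b = BirnnNetwork(vocab_size=9, max_len=4, hidden=2, seed=1)
    fused = FusionNetwork({"a": a, "b": b}, seed=2)
    batch = {
        "a": {"indices": rng.integers(0, 9, (3, 4)), "mask": np.ones((3, 4), bool)},
        "b": {"indices": rng.integers(0, 9, (3, 4)), "mask": np.ones((3, 4), bool)},
    }
    s1 = fused.forward(batch).data
    # zero b's pre-classifier contribution by zeroing its fusion weights
    w = fused.params["fusion.head.w"]
    w2 = w.data.copy()
    w.data[2 * a.hidden:2 * a.hidden + 2 * b.hidden] = 0.0
    s2 = fused.forward(batch).data
    batch2 = dict(batch, b={"indices": rng.integers(0, 9, (3, 4)),
                            "mask": np.ones((3, 4), bool)})
    s3 = fused.forward(batch2).data
    assert np.allclose(s2, s3)   # with zero weights, b's input is irrelevant
    w.data = w2
    assert not np.allclose(s1, s2)


# -- transformer text scorer -------------------------------------------------

def test_text_network_outputs_and_mask(rng):
    net = TransformerTextNetwork(vocab_size=30, max_len=12, width=8,
                                 n_layers=2, seed=0)
    ids = rng.integers(0, 30, (4, 12))
    mask = np.ones((4, 12), dtype=bool)
    mask[2, 6:] = False
    mask[3, :] = False                # empty chunk stays defined
    out = net.forward({"indices": ids, "mask": mask}).data
    assert out.shape == (4,)
    assert np.isfinite(out).all()
    # pad rewrites under the mask do not change the score
    ids2 = ids.copy()
    ids2[2, 6:] = rng.integers(0, 30, 6)
    out2 = net.forward({"indices": ids2, "mask": mask}).data
    assert out2[2] == pytest.approx(out[2], abs=1e-10)


def test_text_scorer_probabilities_in_unit_interval(rng):
    from icureadmit.encoding import NoteChunks
    scorer = TransformerTextScorer(vocab_size=30, chunk_length=8, width=8,
                                   n_layers=1, seed=0)
    scorer.network_ = scorer._build_network({})
    chunks = NoteChunks([[3, 4, 5], [6, 7], []])
    p = scorer.score_chunks(chunks)
    assert p.shape == (3,)
    assert ((p >= 0) & (p <= 1)).all()
    agg = scorer.score_note(chunks)
    assert p.mean() <= agg <= p.max() + 1e-12


# -- autodiff sanity on full model graph -------------------------------------

def test_numeric_gradients_on_tiny_birnn(rng):
    net = BirnnNetwork(vocab_size=7, max_len=4, hidden=2, extra_dims=2, seed=1)
    batch = {"indices": rng.integers(0, 7, (3, 4)),
             "mask": np.array([[1, 1, 0, 0], [1, 1, 1, 1], [1, 0, 0, 0]], bool),
             "extra": rng.normal(size=(3, 2))}
    y = np.array([1.0, 0.0, 1.0])
    loss = bce_with_logits(net.forward(batch), y)
    loss.backward()
    for name, p in net.params.items():
        flat = p.data.ravel()
        for k in rng.choice(flat.size, size=min(3, flat.size), replace=False):
            eps, old = 1e-6, flat[k]
            flat[k] = old + eps
            lp = float(bce_with_logits(net.forward(batch), y).data)
            flat[k] = old - eps
            lm = float(bce_with_logits(net.forward(batch), y).data)
            flat[k] = old
            num = (lp - lm) / (2 * eps)
            assert p.grad.ravel()[k] == pytest.approx(num, abs=2e-6, rel=1e-4), name


def test_numeric_gradients_on_text_network(rng):
    net = TransformerTextNetwork(vocab_size=9, max_len=5, width=4, n_layers=1,
                                 seed=2)
    batch = {"indices": rng.integers(0, 9, (2, 5)),
             "mask": np.array([[1, 1, 1, 0, 0], [1, 1, 1, 1, 1]], bool)}
    y = np.array([1.0, 0.0])
    loss = bce_with_logits(net.forward(batch), y)
    loss.backward()
    for name, p in net.params.items():
        flat = p.data.ravel()
        for k in rng.choice(flat.size, size=min(2, flat.size), replace=False):
            eps, old = 1e-6, flat[k]
            flat[k] = old + eps
            lp = float(bce_with_logits(net.forward(batch), y).data)
            flat[k] = old - eps
            lm = float(bce_with_logits(net.forward(batch), y).data)
            flat[k] = old
            num = (lp - lm) / (2 * eps)
            assert p.grad.ravel()[k] == pytest.approx(num, abs=2e-6, rel=1e-4), name


# -- single-sample convenience and RF baseline -------------------------------

def test_birnn_forward_single_sample(rng):
    from icureadmit.abstraction import EncodedSample
    net = BirnnNetwork(vocab_size=9, max_len=5, hidden=2, seed=0)
    s = EncodedSample(indices=np.array([1, 2, 3, 0, 0]),
                      mask=np.array([1, 1, 1, 0, 0], bool), vocab_size=9)
    batched = net.forward({"indices": s.indices[None], "mask": s.mask[None]}).data[0]
    assert birnn_forward(net, s) == pytest.approx(batched)


def test_rf_separable_and_null(rng):
    X = np.vstack([rng.normal(0, 1, (60, 5)) + 4, rng.normal(0, 1, (60, 5))])
    y = np.array([1] * 60 + [0] * 60)
    rf = fit_tabular_baseline(X, y, seed=0)
    assert roc_auc_score(y, rf.predict_proba(X)[:, 1]) == 1.0
    # label-shuffled: held-out AUROC near chance
    Xn = rng.normal(0, 1, (400, 5))
    yn = rng.integers(0, 2, 400)
    rf2 = fit_tabular_baseline(Xn[:200], yn[:200], seed=0)
    a = roc_auc_score(yn[200:], rf2.predict_proba(Xn[200:])[:, 1])
    assert 0.35 <= a <= 0.65
    # determinism
    rf3 = fit_tabular_baseline(Xn[:200], yn[:200], seed=0)
    assert np.array_equal(rf2.predict_proba(Xn), rf3.predict_proba(Xn))


def test_rf_single_class_rejected():
    with pytest.raises(ValueError, match="both classes"):
        fit_tabular_baseline(np.zeros((5, 2)), np.ones(5))
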
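"""Temporal abstraction: knowledge base, discretization, interpolation,
gradients, flattening, encoding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icureadmit.abstraction import (PAD_SYMBOL, RawSeries, SymbolSeries,
                                    abstraction_vocabulary, compute_gradients,
                                    discretize, encode_onehot_pad,
                                    flatten_events, interpolate_to_grid)
from icureadmit.knowledge import (KnowledgeBase, KnowledgeBaseEntry,
                                  load_knowledge_base)


# -- knowledge base ----------------------------------------------------------

def test_default_kb_concept_counts(kb):
    assert len(kb) == 17
    assert len(kb.lab_concepts) == 12
    assert len(kb.chart_concepts) == 5


def test_heart_rate_entry(kb):
    hr = kb["heart_rate"]
    assert hr.cutoffs == (60.0, 80.0)
    assert hr.gradient_delta == 10.0
    assert hr.stable_hours == 1.0


def test_all_entries_have_trend_parameters(kb):
    for e in kb:
        assert e.gradient_delta > 0 and e.stable_hours > 0
        assert 3 <= len(e.state_names) <= 6


def test_invalid_cutoffs_rejected():
    with pytest.raises(ValueError, match="increasing"):
        KnowledgeBaseEntry(name="x", source="lab", unit="", gradient_delta=1.0,
                           stable_hours=1.0, state_names=("A", "B", "C"),
                           cutoffs=(5.0, 3.0))


def test_custom_kb_file_round_trip(tmp_path):
    text = """
concepts:
  - name: lactate
    source: lab
    unit: mmol/L
    states: [{name: Low, max: 0.5}, {name: Normal, min: 0.5, max: 2.0}, {name: High, min: 2.0}]
    gradient_delta: 0.5
    stable_hours: 6
"""
    p = tmp_path / "kb.yaml"
    p.write_text(text)
    kb = load_knowledge_base(p)
    assert kb["lactate"].state_of(1.0) == "Normal"


# -- discretization ----------------------------------------------------------

@pytest.mark.parametrize("value,state", [
    (36.0, "Hypothermia"), (36.8, "Normal"), (37.5, "Fever")])
def test_body_temperature_states(kb, value, state):
    entry = kb["body_temperature"]
    series = RawSeries("body_temperature", [0.0], [value])
    assert discretize(series, entry).symbols == [state]


def test_discretize_preserves_timestamps(kb):
    s = RawSeries("heart_rate", [0.0, 1.5, 4.0], [55.0, 70.0, 95.0])
    out = discretize(s, kb["heart_rate"])
    assert np.array_equal(out.times, s.times)
    assert out.symbols == ["Bradycardia", "Normal", "Tachycardia"]


def test_discretize_rejects_nonfinite(kb):
    s = RawSeries("heart_rate", [0.0], [np.nan])
    with pytest.raises(ValueError, match="finite"):
        discretize(s, kb["heart_rate"])


# -- interpolation -----------------------------------------------------------

def test_interpolation_known_points():
    a = RawSeries("a", [0.0, 2.0], [0.0, 4.0])
    b = RawSeries("b", [1.0], [7.0])
    grid, vals = interpolate_to_grid([a, b])
    assert np.array_equal(grid, [0.0, 1.0, 2.0])
    assert vals["a"][1] == pytest.approx(2.0)      # midpoint
    c = RawSeries("c", [0.0, 4.0], [0.0, 4.0])
    d = RawSeries("d", [1.0], [0.0])
    _, v2 = interpolate_to_grid([c, d])
    assert v2["c"][1] == pytest.approx(1.0)        # quarter point, near-weighting


def test_interpolation_boundary_carries_nearest():
    a = RawSeries("a", [2.0, 3.0], [10.0, 20.0])
    b = RawSeries("b", [0.0, 5.0], [1.0, 1.0])
    _, vals = interpolate_to_grid([a, b])
    assert vals["a"][0] == 10.0    # before first observation
    assert vals["a"][-1] == 20.0   # after last observation


def test_interpolation_matches_line_equation_oracle(rng):
    """Brute-force two-point line evaluation at every grid time, 1e-9."""
    for _ in range(200):
        n = rng.integers(2, 20)
        t = np.sort(rng.uniform(0, 50, n))
        t = np.unique(t)
        v = rng.normal(0, 10, len(t))
        s = RawSeries("x", t, v)
        other = RawSeries("q", np.sort(rng.uniform(0, 50, 5)), np.zeros(5))
        other = RawSeries("q", np.unique(other.times), np.zeros(len(np.unique(other.times))))
        grid, vals = interpolate_to_grid([s, other])
        for g, got in zip(grid, vals["x"]):
            if g <= t[0]:
                expect = v[0]
            elif g >= t[-1]:
                expect = v[-1]
            else:
                j = np.searchsorted(t, g, side="right")
                t0, t1, v0, v1 = t[j - 1], t[j], v[j - 1], v[j]
                expect = v0 + (v1 - v0) * (g - t0) / (t1 - t0)
            assert abs(got - expect) < 1e-9


def test_interpolate_empty_series_rejected():
    with pytest.raises(ValueError, match="empty"):
        interpolate_to_grid([RawSeries("a", [], [])])


def test_discretize_commutes_with_interpolation_on_observed_points(kb):
    entry = kb["heart_rate"]
    s = RawSeries("heart_rate", [0.0, 2.0, 5.0], [55.0, 75.0, 90.0])
    other = RawSeries("glucose", [1.0, 3.0], [80.0, 90.0])
    grid, vals = interpolate_to_grid([s, other])
    interp = RawSeries("heart_rate", grid, vals["heart_rate"])
    after = discretize(interp, entry)
    before = discretize(s, entry)
    for t, sym in zip(before.times, before.symbols):
        assert after.symbols[list(grid).index(t)] == sym


# -- gradients ---------------------------------------------------------------

def test_gradient_sign_cases(kb):
    s = RawSeries("heart_rate", [0.0, 1.0, 2.0, 3.0], [3.0, 5.0, 5.0, 4.0])
    out = compute_gradients(s, kb["heart_rate"], mode="simple")
    assert out.symbols == ["Increasing", "Stable", "Decreasing"]
    assert len(out) == len(s) - 1
    assert np.array_equal(out.times, s.times[1:])


def test_gradient_thresholded_stable(kb):
    hr = kb["heart_rate"]
    s = RawSeries("heart_rate", [0.0, 0.5], [70.0, 75.0])
    assert compute_gradients(s, hr, mode="thresholded").symbols == ["Stable"]
    # same change over a gap beyond the stable window: direction applies
    s2 = RawSeries("heart_rate", [0.0, 5.0], [70.0, 75.0])
    assert compute_gradients(s2, hr, mode="thresholded").symbols == ["Increasing"]
    # change beyond delta within window: direction applies
    s3 = RawSeries("heart_rate", [0.0, 0.5], [70.0, 85.0])
    assert compute_gradients(s3, hr, mode="thresholded").symbols == ["Increasing"]


def test_gradient_too_short(kb):
    with pytest.raises(ValueError, match="at least 2"):
        compute_gradients(RawSeries("heart_rate", [0.0], [70.0]), kb["heart_rate"])


@settings(deadline=None, max_examples=50)
@given(st.lists(st.integers(-200, 200).map(lambda k: k / 2.0),
                min_size=2, max_size=15),
       st.integers(-100, 100).map(lambda k: k / 2.0))
def test_gradient_shift_invariant_and_negation_equivariant(values, shift):
    # half-integer grid: keeps the comparison exact in float arithmetic
    t = np.arange(len(values), dtype=float)
    base = compute_gradients(RawSeries("x", t, values), mode="simple")
    shifted = compute_gradients(RawSeries("x", t, np.array(values) + shift),
                                mode="simple")
    assert base.symbols == shifted.symbols
    negated = compute_gradients(RawSeries("x", t, -np.array(values)), mode="simple")
    swap = {"Increasing": "Decreasing", "Decreasing": "Increasing",
            "Stable": "Stable"}
    assert negated.symbols == [swap[s] for s in base.symbols]


# -- flattening and encoding -------------------------------------------------

def test_flatten_orders_by_time_then_concept(kb):
    hr = SymbolSeries("heart_rate", np.array([1.0, 3.0]), ["Normal", "Tachycardia"])
    gl = SymbolSeries("glucose", np.array([2.0]), ["High"])
    out = flatten_events([hr, gl], kb)
    assert out == ["heart_rate:Normal", "glucose:High", "heart_rate:Tachycardia"]


def test_flatten_tie_break_is_kb_order(kb):
    # simultaneous events resolve by the canonical concept order (glucose is
    # listed before heart_rate)
    hr = SymbolSeries("heart_rate", np.array([1.0]), ["Normal"])
    gl = SymbolSeries("glucose", np.array([1.0]), ["High"])
    assert flatten_events([hr, gl], kb) == ["glucose:High", "heart_rate:Normal"]
    assert flatten_events([gl, hr], kb) == ["glucose:High", "heart_rate:Normal"]


def test_single_series_keeps_own_order(kb):
    hr = SymbolSeries("heart_rate", np.array([1.0, 2.0, 3.0]),
                      ["Normal", "Normal", "Tachycardia"])
    assert flatten_events([hr], kb) == [
        "heart_rate:Normal", "heart_rate:Normal", "heart_rate:Tachycardia"]


def test_vocabulary_size_and_stability(kb):
    v1 = abstraction_vocabulary(kb, gradients=True)
    v2 = abstraction_vocabulary(kb, gradients=True)
    n_states = sum(len(e.state_names) for e in kb)
    assert len(v1) == n_states + 3 * len(kb) + 1
    assert v1.symbols == v2.symbols
    assert v1.symbols[0] == PAD_SYMBOL


def test_encode_pad_and_truncate(kb):
    vocab = abstraction_vocabulary(kb)
    syms = ["heart_rate:Normal"] * 3
    enc = encode_onehot_pad(syms, vocab, 5)
    assert enc.mask.tolist() == [True] * 3 + [False] * 2
    assert enc.indices[3] == vocab.pad_index
    seven = [f"heart_rate:{s}" for s in
             ["Normal", "Normal", "Tachycardia", "Normal", "Bradycardia",
              "Normal", "Tachycardia"]]
    enc7 = encode_onehot_pad(seven, vocab, 5)
    assert [vocab.symbols[i] for i in enc7.indices] == seven[-5:]   # keep recent
    empty = encode_onehot_pad([], vocab, 4)
    assert not empty.mask.any()
    assert (empty.indices == vocab.pad_index).all()


def test_encode_unknown_symbol_rejected(kb):
    vocab = abstraction_vocabulary(kb)
    with pytest.raises(KeyError):
        encode_onehot_pad(["nonexistent:Thing"], vocab, 4)
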
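"""Knowledge-based temporal abstraction of irregular clinical time series.

Raw measurements arrive as irregularly sampled, per-concept series. Two
abstraction types are produced:

* **state abstraction** — each value is discretized into a named ordinal
  state via knowledge-based cutoffs (e.g. body temperature below 36.2 degC
  is Hypothermia, 36.2-37.2 Normal, above 37.2 Fever);
* **gradient abstraction** — the direction of change between consecutive
  measurements: Increasing / Decreasing / Stable.

Abstractions are either flattened across concepts into one temporally
ordered symbol sequence (univariate layout) or aligned on a common grid by
temporal-linear interpolation (multivariate layout), and finally index-
encoded with padding for sequence models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .knowledge import GRADIENT_SYMBOLS, KnowledgeBase, KnowledgeBaseEntry

PAD_SYMBOL = "<pad>"


@dataclass
class RawSeries:
    """One concept's (timestamp, value) measurements, hours since stay start."""

    concept: str
    times: np.ndarray     # float hours, strictly increasing
    values: np.ndarray    # float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError(f"{self.concept}: timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class SymbolSeries:
    """Ordered (timestamp, symbol) pairs for one concept (states or gradients)."""

    concept: str
    times: np.ndarray
    symbols: list[str]

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class EncodedSample:
    """Model-ready token-index sequence of fixed length with validity mask."""

    indices: np.ndarray        # int, shape (L,)
    mask: np.ndarray           # bool, shape (L,)
    vocab_size: int
    dense: np.ndarray | None = None   # optional (L, F) multivariate layout


class Vocabulary:
    """Bidirectional symbol <-> index map with a dedicated pad symbol at 0."""

    def __init__(self, symbols: list[str]):
        uniq = list(dict.fromkeys(symbols))
        if PAD_SYMBOL in uniq:
            uniq.remove(PAD_SYMBOL)
        self.symbols = [PAD_SYMBOL] + uniq
        self.index = {s: i for i, s in enumerate(self.symbols)}

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def pad_index(self) -> int:
        return 0

    def __getitem__(self, symbol: str) -> int:
        return self.index[symbol]

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.index


def abstraction_vocabulary(kb: KnowledgeBase, gradients: bool = True) -> Vocabulary:
    """Concept-qualified vocabulary: every concept state, optionally every
    concept gradient, plus the pad symbol. Stable across runs given one kb."""
    symbols: list[str] = []
    for e in kb:
        symbols.extend(f"{e.name}:{s}" for s in e.state_names)
    if gradients:
        for e in kb:
            symbols.extend(f"{e.name}:{g}" for g in GRADIENT_SYMBOLS)
    return Vocabulary(symbols)


def discretize(series: RawSeries, entry: KnowledgeBaseEntry) -> SymbolSeries:
    """Map each raw value to its knowledge-based state; timestamps preserved.

    States are half-open, lower-inclusive intervals defined by the entry's
    cutoffs, so e.g. body temperature 36.0 -> Hypothermia, 36.8 -> Normal,
    37.5 -> Fever under the default knowledge base.
    """
    if entry.name != series.concept:
        raise ValueError(f"entry {entry.name!r} does not match series {series.concept!r}")
    if not np.all(np.isfinite(series.values)):
        raise ValueError(f"{series.concept}: non-finite values cannot be discretized")
    idx = np.searchsorted(entry.cutoffs, series.values, side="right")
    return SymbolSeries(
        concept=series.concept,
        times=series.times.copy(),
        symbols=[entry.state_names[i] for i in idx],
    )


def interpolate_to_grid(series_set: list[RawSeries]) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Align concepts on the union grid of observation times.

    Missing values at a grid time are filled by temporal-linear interpolation
    between the two neighbouring observations of that concept; before the
    first / after the last observation the nearest observed value is carried.
    Returns ``(grid_times, {concept: values_on_grid})``; at each grid time
    the per-concept values form one multivariate vector.
    """
    if not series_set:
        raise ValueError("need at least one series")
    for s in series_set:
        if len(s) == 0:
            raise ValueError(f"{s.concept}: empty series cannot be interpolated")
    grid = np.unique(np.concatenate([s.times for s in series_set]))
    # np.interp implements exactly this contract: linear between neighbours
    # with nearest-value carry outside the observed range.
    aligned = {s.concept: np.interp(grid, s.times, s.values) for s in series_set}
    return grid, aligned


def compute_gradients(
    series: RawSeries,
    entry: KnowledgeBaseEntry | None = None,
    mode: str = "simple",
) -> SymbolSeries:
    """Direction-of-change abstraction between consecutive measurements.

    ``simple`` labels each gap by the sign of the difference alone
    (equal values -> Stable). ``thresholded`` additionally consults the
    knowledge base: a change of magnitude at most ``gradient_delta`` whose
    elapsed gap is within ``stable_hours`` is Stable; any other nonzero
    change is labelled by its sign. The gradient series starts at the second
    observation, so its length is one less than the raw series.
    """
    if len(series) < 2:
        raise ValueError("gradient abstraction needs at least 2 observations")
    if mode not in ("simple", "thresholded"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "thresholded" and entry is None:
        raise ValueError("thresholded mode requires a knowledge base entry")
    diffs = np.diff(series.values)
    gaps = np.diff(series.times)
    symbols: list[str] = []
    for d, g in zip(diffs, gaps):
        if d == 0:
            symbols.append("Stable")
        elif mode == "thresholded" and abs(d) <= entry.gradient_delta and g <= entry.stable_hours:
            symbols.append("Stable")
        else:
            symbols.append("Increasing" if d > 0 else "Decreasing")
    return SymbolSeries(concept=series.concept, times=series.times[1:].copy(), symbols=symbols)


def flatten_events(series_list: list[SymbolSeries], kb: KnowledgeBase) -> list[str]:
    """Merge abstracted series into one temporally ordered symbol sequence.

    Events are sorted by timestamp; simultaneous events break ties by the
    knowledge base's canonical concept order (state series before gradient
    series of the same concept, by list position). Symbols are concept-
    qualified, e.g. ``heart_rate:Increasing``, so one vocabulary separates
    concepts.
    """
    events = []
    for pos, s in enumerate(series_list):
        rank = kb.concept_rank(s.concept)
        for t, sym in zip(s.times, s.symbols):
            events.append((t, rank, pos, f"{s.concept}:{sym}"))
    events.sort(key=lambda e: (e[0], e[1], e[2]))
    return [e[3] for e in events]


def encode_onehot_pad(symbols: list[str], vocab: Vocabulary, length: int) -> EncodedSample:
    """Index-encode a symbol sequence to fixed length.

    Sequences longer than ``length`` are truncated from the start (the most
    recent events are kept); shorter ones are padded at the end with the pad
    symbol, and the mask marks valid positions.
    """
    unknown = [s for s in symbols if s not in vocab]
    if unknown:
        raise KeyError(f"symbols not in vocabulary: {sorted(set(unknown))[:5]}")
    kept = symbols[-length:] if len(symbols) > length else symbols
    indices = np.full(length, vocab.pad_index, dtype=np.int64)
    mask = np.zeros(length, dtype=bool)
    for i, s in enumerate(kept):
        indices[i] = vocab[s]
        mask[i] = True
    return EncodedSample(indices=indices, mask=mask, vocab_size=len(vocab))


@dataclass
class StayAbstraction:
    """All abstracted series of one ICU stay."""

    states: list[SymbolSeries] = field(default_factory=list)
    gradients: list[SymbolSeries] = field(default_factory=list)


def abstract_stay(
    raw: dict[str, RawSeries],
    kb: KnowledgeBase,
    gradients: str = "none",
) -> StayAbstraction:
    """State-abstract (and optionally gradient-abstract) one stay's series.

    ``gradients`` is ``none``, ``simple`` (sign of consecutive differences)
    or ``thresholded`` (knowledge-based Delta / stable-window rule).
    """
    out = StayAbstraction()
    for e in kb:
        s = raw.get(e.name)
        if s is None or len(s) == 0:
            continue
        out.states.append(discretize(s, e))
        if gradients != "none" and len(s) >= 2:
            out.gradients.append(compute_gradients(s, e, mode=gradients))
    return out


def encode_stay_univariate(
    ab: StayAbstraction, kb: KnowledgeBase, vocab: Vocabulary, length: int
) -> EncodedSample:
    """Flatten one stay's abstractions into the padded univariate encoding."""
    return encode_onehot_pad(flatten_events(ab.states + ab.gradients, kb), vocab, length)


def encode_stay_multivariate(
    raw: dict[str, RawSeries],
    kb: KnowledgeBase,
    length: int,
    gradients: str = "none",
) -> EncodedSample:
    """Interpolated multivariate layout: per grid time, the concatenation of
    each concept's state one-hot (plus gradient one-hot when enabled).

    Concepts with no observations in the stay contribute an all-zero block.
    The grid is truncated from the start to the most recent ``length`` rows.
    """
    present = [s for s in raw.values() if len(s) > 0]
    if not present:
        raise ValueError("stay has no observations")
    grid, aligned = interpolate_to_grid(present)
    state_width = sum(len(e.state_names) for e in kb)
    grad_width = 3 * len(kb) if gradients != "none" else 0
    rows = np.zeros((len(grid), state_width + grad_width), dtype=np.float32)
    offset = 0
    for e in kb:
        vals = aligned.get(e.name)
        if vals is not None:
            idx = np.searchsorted(e.cutoffs, vals, side="right")
            rows[np.arange(len(grid)), offset + idx] = 1.0
        offset += len(e.state_names)
    if gradients != "none":
        for ci, e in enumerate(kb):
            vals = aligned.get(e.name)
            if vals is None or len(grid) < 2:
                continue
            interp = RawSeries(e.name, grid, vals)
            gs = compute_gradients(interp, e, mode=gradients)
            gmap = {g: k for k, g in enumerate(GRADIENT_SYMBOLS)}
            for t_i, sym in enumerate(gs.symbols, start=1):
                rows[t_i, state_width + 3 * ci + gmap[sym]] = 1.0
    if len(rows) > length:
        rows = rows[-length:]
        valid = length
    else:
        valid = len(rows)
        rows = np.vstack([rows, np.zeros((length - valid, rows.shape[1]), dtype=np.float32)])
    mask = np.zeros(length, dtype=bool)
    mask[:valid] = True
    return EncodedSample(
        indices=np.zeros(length, dtype=np.int64),
        mask=mask,
        vocab_size=rows.shape[1],
        dense=rows,
    )
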
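"""Per-fold experiment execution over modality combinations.

A modality spec names the inputs of one model, mirroring the combination
lines of the study design: ``A`` abstracted charts, ``B1`` ICD-9 code
sequences, ``B2`` ICD-9 textual descriptions, ``C`` discharge notes,
``D`` the demographics one-hot (only ever combined), and ``RF`` the
tabular random-forest baseline on ICD-9 + demographics. Combinations are
joined with ``+`` (e.g. ``A+B1+D``).

For every fold, all data-dependent encodings (ICD-9 vocabulary, note
tokenizer, sequence lengths) are built from that fold's training patients
only; the model is trained with the AUPRC-checkpointing protocol, its
decision threshold selected on the validation set, and the five metrics
computed on the fold's test patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abstraction import (EncodedSample, RawSeries, abstract_stay,
                          abstraction_vocabulary, encode_stay_multivariate,
                          encode_stay_univariate)
from .cohort import FoldSplit
from .encoding import (DemographicsSchema, Icd9Vocabulary, WhitespaceTokenizer,
                       build_icd9_text, chunk_note, encode_demographics,
                       encode_icd9_onehot, icd9_sequences, preprocess_note)
from .evaluation import (FoldSummary, MetricReport, aggregate_chunk_scores,
                         aggregate_folds, compute_metrics,
                         find_optimal_threshold)
from .knowledge import KnowledgeBase, load_knowledge_base
from .models import (BirnnClassifier, FusedClassifier, TransformerTextScorer,
                     fit_tabular_baseline, samples_to_arrays)
from .synth import EHRTables

VALID_PARTS = {"A", "B1", "B2", "C", "D", "RF"}


@dataclass
class ExperimentConfig:
    """Desk-scale experiment knobs (model size, protocol cadence, layouts)."""

    hidden_size: int = 32
    batch_size: int = 64
    eval_every_steps: int = 50
    stop_loss: int = 7
    max_steps: int | None = 400
    charts_layout: str = "onehot"        # "onehot" (flattened) or "interpolated"
    charts_gradients: str = "none"       # "none", "simple", "thresholded"
    charts_max_len: int = 96
    icd9_max_len: int = 20
    chunk_length: int = 64
    seed: int = 0


def parse_modality_spec(spec: str) -> list[str]:
    parts = [p.strip() for p in spec.split("+") if p.strip()]
    unknown = set(parts) - VALID_PARTS
    if unknown:
        raise ValueError(f"unknown modality parts: {sorted(unknown)}")
    if not parts:
        raise ValueError("empty modality spec")
    if parts == ["D"]:
        raise ValueError("demographics is only used in combination")
    return parts


def stay_series(tables: EHRTables, kb: KnowledgeBase) -> dict[int, dict[str, RawSeries]]:
    """Per-stay raw series keyed by icustay_id and concept (hours from intime)."""
    by_item = kb.by_itemid()
    intimes = tables.icustays.set_index("icustay_id")["intime"]
    events = pd.concat([tables.chartevents, tables.labevents], ignore_index=True)
    out: dict[int, dict[str, RawSeries]] = {}
    if len(events) == 0:
        return out
    events = events.sort_values("charttime")
    for (stay, itemid), g in events.groupby(["icustay_id", "itemid"], sort=False):
        entry = by_item.get(itemid)
        if entry is None:
            continue
        t0 = intimes.loc[stay]
        hours = (g["charttime"] - t0).dt.total_seconds().to_numpy() / 3600.0
        hours, keep = np.unique(hours, return_index=True)
        out.setdefault(int(stay), {})[entry.name] = RawSeries(
            entry.name, hours, g["valuenum"].to_numpy()[keep])
    return out


@dataclass
class FoldData:
    """Everything one fold's model consumes, built train-first."""

    inputs: dict                      # nested arrays for train+val+test stacked
    y: np.ndarray
    split: dict[str, np.ndarray]      # row indices per train/val/test
    artifacts: dict = field(default_factory=dict)
    note_groups: dict | None = None   # for C: row ranges of each patient's chunks


def _subset(cohort: pd.DataFrame, subjects: np.ndarray) -> pd.DataFrame:
    return cohort[cohort["subject_id"].isin(subjects)]


def build_fold_encodings(
    tables: EHRTables, cohort: pd.DataFrame, fold: dict[str, np.ndarray],
    parts: list[str], cfg: ExperimentConfig, kb: KnowledgeBase | None = None,
    series_map: dict | None = None,
) -> dict[str, FoldData]:
    """Encodings for one fold; vocabularies and lengths from train data only.

    Returns one FoldData per modality part (demographics under ``D``).
    """
    kb = kb or load_knowledge_base()
    frames = {name: _subset(cohort, fold[name]).reset_index(drop=True)
              for name in ("train", "val", "test")}
    ordered = pd.concat([frames["train"], frames["val"], frames["test"]],
                        ignore_index=True)
    n_train, n_val = len(frames["train"]), len(frames["val"])
    split = {
        "train": np.arange(n_train),
        "val": np.arange(n_train, n_train + n_val),
        "test": np.arange(n_train + n_val, len(ordered)),
    }
    y = ordered["label"].to_numpy(dtype=np.float64)
    out: dict[str, FoldData] = {}

    if "A" in parts:
        series_map = series_map if series_map is not None else stay_series(tables, kb)
        vocab = abstraction_vocabulary(kb, gradients=cfg.charts_gradients != "none")
        samples: list[EncodedSample] = []
        for stay_id in ordered["icustay_id"]:
            raw = series_map.get(int(stay_id), {})
            if cfg.charts_layout == "interpolated":
                samples.append(encode_stay_multivariate(
                    raw, kb, cfg.charts_max_len, gradients=cfg.charts_gradients))
            else:
                ab = abstract_stay(raw, kb, gradients=cfg.charts_gradients)
                samples.append(encode_stay_univariate(ab, kb, vocab, cfg.charts_max_len))
        out["A"] = FoldData(inputs=samples_to_arrays(samples), y=y, split=split,
                            artifacts={"vocab": vocab})

    if "B1" in parts or "RF" in parts:
        seqs = icd9_sequences(tables.diagnoses_icd, tables.d_icd_diagnoses)
        train_hadm = set(frames["train"]["hadm_id"])
        train_codes = [c for h in sorted(train_hadm)
                       for c in (seqs[h].codes() if h in seqs else [])]
        vocab = Icd9Vocabulary(train_codes)
        empty = None
        samples = []
        for hadm in ordered["hadm_id"]:
            seq = seqs.get(int(hadm))
            if seq is None:
                if empty is None:
                    from .encoding import Icd9Sequence
                    empty = Icd9Sequence([])
                seq = empty
            samples.append(encode_icd9_onehot(seq, vocab, cfg.icd9_max_len))
        data = samples_to_arrays(samples)
        fd = FoldData(inputs=data, y=y, split=split,
                      artifacts={"vocab": vocab, "sequences": seqs})
        out["B1"] = fd
        if "RF" in parts:
            # bag-of-codes count matrix over the train vocabulary
            mat = np.zeros((len(ordered), len(vocab.codes)))
            code_idx = {c: i for i, c in enumerate(vocab.codes)}
            for row, hadm in enumerate(ordered["hadm_id"]):
                seq = seqs.get(int(hadm))
                for c in (seq.codes() if seq else []):
                    if c in code_idx:
                        mat[row, code_idx[c]] += 1.0
            out["RF"] = FoldData(inputs={"features": mat}, y=y, split=split,
                                 artifacts={"vocab": vocab})

    if "B2" in parts:
        seqs = icd9_sequences(tables.diagnoses_icd, tables.d_icd_diagnoses)
        texts = []
        for row in ordered.itertuples(index=False):
            seq = seqs.get(int(row.hadm_id))
            if seq is None:
                from .encoding import Icd9Sequence
                seq = Icd9Sequence([])
            texts.append(preprocess_note(
                build_icd9_text(seq, row.age_years, row.gender, row.insurance)))
        tokenizer = WhitespaceTokenizer().fit([texts[i] for i in split["train"]])
        ids = np.zeros((len(texts), cfg.chunk_length), dtype=np.int64)
        mask = np.zeros_like(ids, dtype=bool)
        for i, t in enumerate(texts):
            enc = tokenizer.encode(t)[:cfg.chunk_length]
            ids[i, :len(enc)] = enc
            mask[i, :len(enc)] = True
        out["B2"] = FoldData(inputs={"indices": ids, "mask": mask}, y=y, split=split,
                             artifacts={"tokenizer": tokenizer})

    if "C" in parts:
        notes = {int(h): t for h, t in
                 zip(tables.noteevents["hadm_id"], tables.noteevents["text"])}
        cleaned = [preprocess_note(notes.get(int(h), ""))
                   for h in ordered["hadm_id"]]
        tokenizer = WhitespaceTokenizer().fit([cleaned[i] for i in split["train"]])
        chunk_rows, chunk_mask_rows, chunk_y, groups = [], [], [], {}
        for i, text in enumerate(cleaned):
            chunks = chunk_note(text, tokenizer, cfg.chunk_length)
            start = len(chunk_rows)
            for c in chunks.chunks:
                row = np.zeros(cfg.chunk_length, dtype=np.int64)
                m = np.zeros(cfg.chunk_length, dtype=bool)
                c = c[:cfg.chunk_length]
                row[:len(c)] = c
                m[:len(c)] = True
                chunk_rows.append(row)
                chunk_mask_rows.append(m)
                chunk_y.append(y[i])
            groups[i] = (start, len(chunk_rows))
        out["C"] = FoldData(
            inputs={"indices": np.stack(chunk_rows), "mask": np.stack(chunk_mask_rows)},
            y=np.array(chunk_y), split=split,
            artifacts={"tokenizer": tokenizer}, note_groups=groups)

    if "D" in parts:
        schema = DemographicsSchema()
        static = np.stack([encode_demographics(row, schema)
                           for row in ordered.itertuples(index=False)])
        out["D"] = FoldData(inputs={"static": static}, y=y, split=split,
                            artifacts={"schema": schema})

    return out


def _take(d: dict, idx: np.ndarray) -> dict:
    return {k: _take(v, idx) if isinstance(v, dict) else v[idx] for k, v in d.items()}


def _clf_config(cfg: ExperimentConfig, text: bool = False) -> dict:
    base = dict(batch_size=cfg.batch_size, eval_every_steps=cfg.eval_every_steps,
                stop_loss=cfg.stop_loss, max_steps=cfg.max_steps, seed=cfg.seed)
    if text:
        base.update(lr_initial=2e-5, lr_decay=0.9)
    return base


def _run_fold(parts: list[str], data: dict[str, FoldData],
              cfg: ExperimentConfig, fold_idx: int) -> tuple[MetricReport, pd.DataFrame]:
    split = next(iter(data.values())).split
    y = _cohort_labels(data, split)

    def scores_three_way(score_all: np.ndarray):
        return (score_all[split["val"]], score_all[split["test"]])

    seq_parts = [p for p in parts if p in ("A", "B1", "B2", "C")]

    if parts == ["RF"] or set(parts) == {"RF", "D"}:
        feats = data["RF"].inputs["features"]
        if "D" in data:
            feats = np.hstack([feats, data["D"].inputs["static"]])
        rf = fit_tabular_baseline(feats[split["train"]], y[split["train"]],
                                  seed=cfg.seed)
        all_scores = rf.predict_proba(feats)[:, 1]
        val_scores, test_scores = scores_three_way(all_scores)
    elif seq_parts == ["C"]:
        # notes alone: chunk-level training, patient-level max/mean aggregation
        fd = data["C"]
        scorer = TransformerTextScorer(chunk_length=cfg.chunk_length,
                                       vocab_size=fd.artifacts["tokenizer"].vocab_size,
                                       **_clf_config(cfg, text=True))
        tr_rows = _chunk_rows(fd, split["train"])
        va_rows = _chunk_rows(fd, split["val"])
        scorer.fit(fd.inputs["indices"][tr_rows], fd.inputs["mask"][tr_rows],
                   fd.y[tr_rows],
                   X_val={"indices": fd.inputs["indices"][va_rows],
                          "mask": fd.inputs["mask"][va_rows]},
                   y_val=fd.y[va_rows])
        chunk_scores = scorer.decision_function(fd.inputs)
        all_scores = np.array([
            aggregate_chunk_scores(chunk_scores[slice(*fd.note_groups[i])])
            for i in range(len(y))])
        val_scores, test_scores = scores_three_way(all_scores)
    elif len(seq_parts) == 1:
        part = seq_parts[0]
        fd = data[part]
        extra = data["D"].inputs["static"] if "D" in parts else None
        if part == "B2":
            clf = TransformerTextScorer(chunk_length=cfg.chunk_length,
                                        vocab_size=fd.artifacts["tokenizer"].vocab_size,
                                        **_clf_config(cfg, text=True))
            inputs = dict(fd.inputs)
        else:
            clf = BirnnClassifier(hidden_size=cfg.hidden_size,
                                  dense_input="dense" in fd.inputs,
                                  extra_dims=0 if extra is None else extra.shape[1],
                                  lr_initial=1e-3, lr_decay=0.97,
                                  **_clf_config(cfg))
            inputs = dict(fd.inputs)
            if extra is not None:
                inputs["extra"] = extra
        tr, va = split["train"], split["val"]
        if part == "B2":
            clf.fit(inputs["indices"][tr], inputs["mask"][tr], y[tr],
                    X_val={"indices": inputs["indices"][va], "mask": inputs["mask"][va]},
                    y_val=y[va])
        else:
            if "vocab" in fd.artifacts and hasattr(fd.artifacts["vocab"], "__len__"):
                clf.vocab_size_ = len(fd.artifacts["vocab"])
            clf.fit(_take(inputs, tr), y[tr], X_val=_take(inputs, va), y_val=y[va])
        all_scores = clf.decision_function(inputs)
        val_scores, test_scores = scores_three_way(all_scores)
    else:
        # joint fusion over >= 2 sequence components (+ optional static D)
        components, comp_inputs = {}, {}
        for part in seq_parts:
            fd = data[part]
            if part == "C":
                # fuse on the first chunk of each note
                rows = [fd.note_groups[i][0] for i in range(len(y))]
                comp_inputs[part] = {"indices": fd.inputs["indices"][rows],
                                     "mask": fd.inputs["mask"][rows]}
                components[part] = TransformerTextScorer(
                    chunk_length=cfg.chunk_length,
                    vocab_size=fd.artifacts["tokenizer"].vocab_size,
                    **_clf_config(cfg, text=True))
            elif part == "B2":
                comp_inputs[part] = dict(fd.inputs)
                components[part] = TransformerTextScorer(
                    chunk_length=cfg.chunk_length,
                    vocab_size=fd.artifacts["tokenizer"].vocab_size,
                    **_clf_config(cfg, text=True))
            else:
                comp_inputs[part] = dict(fd.inputs)
                clf = BirnnClassifier(hidden_size=cfg.hidden_size,
                                      dense_input="dense" in fd.inputs,
                                      **_clf_config(cfg))
                if "vocab" in fd.artifacts and hasattr(fd.artifacts["vocab"], "__len__"):
                    clf.vocab_size_ = len(fd.artifacts["vocab"])
                components[part] = clf
        static_dims = data["D"].inputs["static"].shape[1] if "D" in parts else 0
        fused = FusedClassifier(components=components, static_dims=static_dims,
                                **_clf_config(cfg))
        inputs: dict = dict(comp_inputs)
        if static_dims:
            inputs["static"] = data["D"].inputs["static"]
        tr, va = split["train"], split["val"]
        fused.fit(_take(inputs, tr), y[tr], X_val=_take(inputs, va), y_val=y[va])
        all_scores = fused.decision_function(inputs)
        val_scores, test_scores = scores_three_way(all_scores)

    y_cohort = _cohort_labels(data, split)
    threshold = find_optimal_threshold(val_scores, y_cohort[split["val"]])
    report = compute_metrics(test_scores, y_cohort[split["test"]],
                             threshold=threshold, fold=fold_idx)
    preds = pd.DataFrame({"row": split["test"], "label": y_cohort[split["test"]],
                          "score": test_scores})
    return report, preds


def _chunk_rows(fd: FoldData, cohort_rows: np.ndarray) -> np.ndarray:
    rows = []
    for i in cohort_rows:
        a, b = fd.note_groups[int(i)]
        rows.extend(range(a, b))
    return np.array(rows, dtype=int)


def _cohort_labels(data: dict[str, FoldData], split) -> np.ndarray:
    for fd in data.values():
        if fd.note_groups is None:
            return fd.y
    # only C present: reconstruct from the first chunk of each note
    fd = data["C"]
    n = max(fd.note_groups) + 1
    return np.array([fd.y[fd.note_groups[i][0]] for i in range(n)])


@dataclass
class ExperimentResult:
    modality_spec: str
    reports: list[MetricReport]
    summary: FoldSummary | None
    predictions: list[pd.DataFrame]


def run_experiment(
    tables: EHRTables, cohort: pd.DataFrame, folds: FoldSplit,
    modality_spec: str, cfg: ExperimentConfig | None = None,
    kb: KnowledgeBase | None = None,
) -> ExperimentResult:
    """Train and evaluate one modality combination on every fold.

    All encodings are rebuilt per fold from that fold's training patients;
    reports are computed on disjoint test patients.
    """
    cfg = cfg or ExperimentConfig()
    kb = kb or load_knowledge_base()
    parts = parse_modality_spec(modality_spec)
    series_map = stay_series(tables, kb) if "A" in parts else None
    reports, preds = [], []
    for fold_idx, fold in enumerate(folds):
        data = build_fold_encodings(tables, cohort, fold, parts, cfg, kb,
                                    series_map=series_map)
        report, pred = _run_fold(parts, data, cfg, fold_idx)
        reports.append(report)
        preds.append(pred)
    summary = aggregate_folds(reports) if len(reports) >= 2 else None
    return ExperimentResult(modality_spec=modality_spec, reports=reports,
                            summary=summary, predictions=preds)
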
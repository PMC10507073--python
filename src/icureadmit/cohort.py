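"""Unplanned-readmission cohort construction from MIMIC-schema tables.

Builds the study cohort from raw EHR tables: adult index ICU stays of 1-30
days with complete measurement coverage and no in-window death, labelled
positive when the patient returns to an ICU within 30 days of hospital
discharge, reduced to at most one index stay per patient per rolling year,
and split into patient-level stratified folds.

Windows are measured in elapsed time (30 days = 720 h), boundary inclusive.
Age is elapsed years at ICU admission, floored, with de-identification-
shifted ages capped at 90.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .knowledge import KnowledgeBase
from .synth import _SCHEMAS, TABLE_NAMES, EHRTables

_DAY_HOURS = 24.0
_WINDOW_DAYS = 30.0
_YEAR_DAYS = 365.0

_TIME_COLUMNS = {
    "patients": ["dob", "dod"],
    "admissions": ["admittime", "dischtime", "deathtime"],
    "icustays": ["intime", "outtime"],
    "chartevents": ["charttime"],
    "labevents": ["charttime"],
    "noteevents": ["charttime"],
}


def load_ehr(directory: str | Path) -> EHRTables:
    """Load the eight tables from ``<NAME>.csv`` files with typed timestamps.

    Extra columns (as found in real MIMIC-III extracts) are dropped; a
    missing file or missing required column raises with its name, and an
    unparseable timestamp raises with the offending row index.
    """
    directory = Path(directory)
    loaded = {}
    for name in TABLE_NAMES:
        path = directory / f"{name.upper()}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing table file: {path.name}")
        df = pd.read_csv(path, dtype={"icd9_code": str} if "diagnoses" in name else None)
        df.columns = [c.lower() for c in df.columns]
        missing = [c for c in _SCHEMAS[name] if c not in df.columns]
        if missing:
            raise ValueError(f"{path.name}: missing required columns {missing}")
        df = df[_SCHEMAS[name]]
        for col in _TIME_COLUMNS.get(name, []):
            parsed = pd.to_datetime(df[col], errors="coerce", format="mixed")
            bad = parsed.isna() & df[col].notna()
            if bad.any():
                raise ValueError(
                    f"{path.name}: unparseable timestamp in column {col!r} "
                    f"at row index {int(np.flatnonzero(bad)[0])}")
            df[col] = parsed
        loaded[name] = df
    return EHRTables(**loaded)


@dataclass
class FilterReport:
    """Ordered record of each inclusion rule's effect."""

    steps: list[tuple[str, int, int]]   # (rule_name, n_removed, n_remaining)

    def __post_init__(self) -> None:
        remaining = [n for _, _, n in self.steps]
        if any(b > a for a, b in zip(remaining, remaining[1:])):
            raise ValueError("n_remaining must be non-increasing")


def _stay_frame(tables: EHRTables) -> pd.DataFrame:
    """One row per ICU stay with admission context, age and length of stay."""
    stays = tables.icustays.merge(
        tables.admissions[["hadm_id", "admittime", "dischtime", "deathtime",
                           "insurance", "ethnicity"]],
        on="hadm_id", how="left")
    stays = stays.merge(tables.patients[["subject_id", "gender", "dob", "dod"]],
                        on="subject_id", how="left")
    age = (stays["intime"] - stays["dob"]).dt.total_seconds() / (365.25 * 86400)
    stays["age_years"] = np.minimum(np.floor(age), 90.0)
    stays["los_days"] = (stays["outtime"] - stays["intime"]).dt.total_seconds() / 86400.0
    return stays


def apply_inclusion_filters(
    tables: EHRTables, kb: KnowledgeBase
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the cohort inclusion rules, reporting each rule's effect.

    Rules (conjunctive, so the surviving set is order-independent):
    adult (age >= 18 at ICU admission); length of stay between 1 and 30
    days inclusive; at least one measurement of every lab concept and at
    least five of every chart concept; no death during the stay or within
    the 30 days following hospital discharge.
    """
    if len(tables.icustays) == 0:
        raise ValueError("no ICU stays to filter")
    lab_ids = [e.itemid for e in kb.lab_concepts]
    chart_ids = [e.itemid for e in kb.chart_concepts]
    if not lab_ids or not chart_ids:
        raise ValueError("knowledge base must list lab and chart concepts")
    present = set(pd.concat([tables.chartevents["itemid"],
                             tables.labevents["itemid"]], ignore_index=True).unique())
    unknown = present - {e.itemid for e in kb}
    if unknown:
        raise ValueError(f"event itemids not in knowledge base: {sorted(unknown)[:5]}")

    stays = _stay_frame(tables)
    steps: list[tuple[str, int, int]] = []

    def record(name: str, keep: pd.Series):
        nonlocal stays
        removed = int((~keep).sum())
        stays = stays[keep]
        steps.append((name, removed, len(stays)))

    record("adult", stays["age_years"] >= 18)
    record("los_1_to_30_days",
           (stays["los_days"] >= 1.0) & (stays["los_days"] <= 30.0))

    events = pd.concat([tables.chartevents, tables.labevents], ignore_index=True)
    counts = (events.groupby(["icustay_id", "itemid"]).size().unstack(fill_value=0)
              .reindex(stays["icustay_id"], fill_value=0)
              .reindex(columns=lab_ids + chart_ids, fill_value=0))
    lab_ok = (counts[lab_ids] >= 1).all(axis=1).to_numpy()
    record("lab_coverage", pd.Series(lab_ok, index=stays.index))
    chart_counts = (events.groupby(["icustay_id", "itemid"]).size().unstack(fill_value=0)
                    .reindex(stays["icustay_id"], fill_value=0)
                    .reindex(columns=chart_ids, fill_value=0))
    chart_ok = (chart_counts >= 5).all(axis=1).to_numpy()
    record("chart_coverage", pd.Series(chart_ok, index=stays.index))

    death = stays["deathtime"].fillna(stays["dod"])
    limit = stays["dischtime"] + pd.to_timedelta(_WINDOW_DAYS * _DAY_HOURS, "h")
    record("no_death_within_30d", ~(death.notna() & (death <= limit)))

    return stays.reset_index(drop=True), FilterReport(steps)


def assign_labels(stays: pd.DataFrame, tables: EHRTables) -> pd.DataFrame:
    """Label each stay: 1 iff the patient's next ICU stay begins within
    (0, 30] days after this stay's hospital discharge time."""
    if stays["dischtime"].isna().any():
        bad = stays.loc[stays["dischtime"].isna(), "icustay_id"].iloc[0]
        raise ValueError(f"stay {bad} lacks a hospital discharge time")
    all_stays = tables.icustays[["subject_id", "icustay_id", "intime"]]
    labels = np.zeros(len(stays), dtype=int)
    by_subject = {s: g["intime"].to_numpy() for s, g in all_stays.groupby("subject_id")}
    window = np.timedelta64(int(_WINDOW_DAYS * _DAY_HOURS * 3600), "s")
    for i, row in enumerate(stays.itertuples(index=False)):
        others = by_subject.get(row.subject_id)
        if others is None:
            continue
        disch = np.datetime64(row.dischtime)
        gap_ok = (others > disch) & (others <= disch + window)
        labels[i] = int(gap_ok.any())
    out = stays.copy()
    out["label"] = labels
    return out


def select_index_stays(labeled: pd.DataFrame) -> pd.DataFrame:
    """Reduce to index stays: first ICU stay per hospital admission, then at
    most one stay per patient per rolling 365 days (chronological scan)."""
    df = labeled.sort_values(["subject_id", "intime"]).copy()
    df = df.groupby("hadm_id", as_index=False, sort=False).first()
    df = df.sort_values(["subject_id", "intime"])
    keep_rows = []
    year = np.timedelta64(int(_YEAR_DAYS * 86400), "s")
    for _, group in df.groupby("subject_id", sort=False):
        last_kept = None
        for row in group.itertuples(index=True):
            t = np.datetime64(row.intime)
            if last_kept is None or t - last_kept > year:
                keep_rows.append(row.Index)
                last_kept = t
    cohort = df.loc[keep_rows].reset_index(drop=True)
    cols = ["subject_id", "icustay_id", "hadm_id", "label", "age_years", "gender",
            "insurance", "ethnicity", "los_days", "intime", "outtime", "dischtime"]
    return cohort[cols]


@dataclass
class FoldSplit:
    """Patient-level stratified k-fold assignment with per-fold val splits."""

    folds: list[dict[str, np.ndarray]]   # each: train/val/test subject_id arrays

    @property
    def k(self) -> int:
        return len(self.folds)

    def __iter__(self):
        return iter(self.folds)


def make_folds(
    cohort: pd.DataFrame, k: int = 5, val_fraction: float = 0.125, seed: int = 0
) -> FoldSplit:
    """Stratified k-fold split by patient (stratum: any positive stay).

    Within each fold, ``val_fraction`` of the training patients is held out,
    stratified, as the training loop's validation set. Deterministic given
    ``seed``; test sets partition the patients.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    per_patient = cohort.groupby("subject_id")["label"].max()
    patients = per_patient.index.to_numpy()
    strata = per_patient.to_numpy()
    n_pos, n_neg = int(strata.sum()), int((1 - strata).sum())
    if min(n_pos, n_neg) < k:
        raise ValueError(f"each class needs at least k={k} patients "
                         f"(got {n_pos} positive, {n_neg} negative)")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for trainval_idx, test_idx in skf.split(patients, strata):
        train_idx, val_idx = train_test_split(
            trainval_idx, test_size=val_fraction, random_state=seed,
            stratify=strata[trainval_idx])
        folds.append({
            "train": np.sort(patients[train_idx]),
            "val": np.sort(patients[val_idx]),
            "test": np.sort(patients[test_idx]),
        })
    return FoldSplit(folds)


def build_cohort(
    tables: EHRTables, kb: KnowledgeBase
) -> tuple[pd.DataFrame, FilterReport]:
    """Full cohort construction: filters, labels, index-stay selection."""
    stays, report = apply_inclusion_filters(tables, kb)
    labeled = assign_labels(stays, tables)
    return select_index_stays(labeled), report
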
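"""Cohort construction: filters, labels, index-stay selection, folds."""

import itertools

import numpy as np
import pandas as pd
import pytest

from icureadmit.cohort import (apply_inclusion_filters, assign_labels,
                               build_cohort, load_ehr, make_folds,
                               select_index_stays)
from icureadmit.synth import SynthConfig, generate_ehr, plant_violations, write_ehr


def _hours(h):
    return pd.to_timedelta(h, "h")


def _toy_labeled(gaps_days):
    """One patient per gap: index stay + readmission at the given gap."""
    base = pd.Timestamp("2130-01-01")
    stays, rows = [], []
    for i, gap in enumerate(gaps_days):
        intime = base
        outtime = base + _hours(3 * 24)
        disch = outtime + _hours(6)
        stays.append({"subject_id": i, "icustay_id": 10 + i, "hadm_id": 100 + i,
                      "intime": intime, "outtime": outtime, "dischtime": disch})
        rows.append({"subject_id": i, "icustay_id": 10 + i, "intime": intime})
        if gap is not None:
            rows.append({"subject_id": i, "icustay_id": 900 + i,
                         "intime": disch + _hours(gap * 24)})
    stay_df = pd.DataFrame(stays)
    icustays = pd.DataFrame(rows)

    class Tables:
        pass

    t = Tables()
    t.icustays = icustays
    return stay_df, t


def test_label_window_boundaries():
    stays, tables = _toy_labeled([29.0, 31.0, 30.0, None])
    labeled = assign_labels(stays, tables)
    assert labeled["label"].tolist() == [1, 0, 1, 0]


def test_label_requires_discharge_time():
    stays, tables = _toy_labeled([5.0])
    stays.loc[0, "dischtime"] = pd.NaT
    with pytest.raises(ValueError, match="discharge"):
        assign_labels(stays, tables)


def test_first_stay_per_rolling_year():
    base = pd.Timestamp("2130-01-01")
    rows = []
    for subj, offsets in ((1, [0, 180]), (2, [0, 400]), (3, [0])):
        for j, off in enumerate(offsets):
            rows.append({"subject_id": subj, "icustay_id": subj * 10 + j,
                         "hadm_id": subj * 100 + j, "label": 0,
                         "age_years": 50.0, "gender": "F", "insurance": "Private",
                         "ethnicity": "WHITE", "los_days": 3.0,
                         "intime": base + _hours(off * 24),
                         "outtime": base + _hours(off * 24 + 72),
                         "dischtime": base + _hours(off * 24 + 80)})
    out = select_index_stays(pd.DataFrame(rows))
    kept = set(out["icustay_id"])
    assert kept == {10, 20, 21, 30}   # day-180 stay dropped, day-400 kept


def test_first_icu_stay_per_admission_only():
    base = pd.Timestamp("2130-01-01")
    rows = []
    for j, off in enumerate([0, 5]):   # two ICU stays in one hospital admission
        rows.append({"subject_id": 1, "icustay_id": 10 + j, "hadm_id": 100,
                     "label": 0, "age_years": 50.0, "gender": "F",
                     "insurance": "Private", "ethnicity": "WHITE",
                     "los_days": 3.0, "intime": base + _hours(off * 24),
                     "outtime": base + _hours(off * 24 + 72),
                     "dischtime": base + _hours(30 * 24)})
    out = select_index_stays(pd.DataFrame(rows))
    assert out["icustay_id"].tolist() == [10]


def test_planted_violations_removed_exactly(small_tables, kb):
    aug, planted = plant_violations(small_tables, kb)
    clean_cohort, _ = build_cohort(small_tables, kb)
    cohort, report = build_cohort(aug, kb)
    kept = set(cohort["icustay_id"])
    for rule in ("los", "chart_count", "death", "year_rule_removed"):
        assert planted[rule] not in kept, rule
    assert planted["year_rule_kept"] in kept
    # nothing else removed: the surviving set is the clean cohort plus the one
    # planted stay that passes every rule
    assert kept == set(clean_cohort["icustay_id"]) | {planted["year_rule_kept"]}
    assert [name for name, _, _ in report.steps] == [
        "adult", "los_1_to_30_days", "lab_coverage", "chart_coverage",
        "no_death_within_30d"]


def test_filters_are_order_robust(small_tables, kb):
    """Conjunctive rules: the surviving set is permutation-invariant."""
    aug, _ = plant_violations(small_tables, kb)
    baseline, report = apply_inclusion_filters(aug, kb)
    base_ids = set(baseline["icustay_id"])
    # intersection of independently computed per-rule survivor masks, taken in
    # every order, equals the pipeline output
    from icureadmit.cohort import _stay_frame
    stays = _stay_frame(aug)
    events = pd.concat([aug.chartevents, aug.labevents], ignore_index=True)
    counts = events.groupby(["icustay_id", "itemid"]).size().unstack(fill_value=0)
    lab_ids = [e.itemid for e in kb.lab_concepts]
    chart_ids = [e.itemid for e in kb.chart_concepts]
    c = counts.reindex(stays["icustay_id"], fill_value=0)
    masks = {
        "adult": (stays["age_years"] >= 18).to_numpy(),
        "los": ((stays["los_days"] >= 1) & (stays["los_days"] <= 30)).to_numpy(),
        "lab": (c.reindex(columns=lab_ids, fill_value=0) >= 1).all(axis=1).to_numpy(),
        "chart": (c.reindex(columns=chart_ids, fill_value=0) >= 5).all(axis=1).to_numpy(),
        "death": ~(stays["deathtime"].fillna(stays["dod"]).notna()
                   & (stays["deathtime"].fillna(stays["dod"])
                      <= stays["dischtime"] + _hours(30 * 24))).to_numpy(),
    }
    for perm in itertools.permutations(masks.values()):
        combined = np.logical_and.reduce(list(perm))
        assert set(stays["icustay_id"][combined]) == base_ids


def test_labels_recover_generator_latents(small_tables, kb):
    cohort, _ = build_cohort(small_tables, kb)
    merged = cohort.merge(small_tables.latent_labels.rename("latent"),
                          left_on="subject_id", right_index=True)
    assert (merged["label"] == merged["latent"]).all()


def test_strata_positives_sum_to_total(small_cohort):
    cohort, _ = small_cohort
    age_bucket = np.where(cohort["age_years"] > 65, ">65", "18-65")
    strata = cohort.groupby([cohort["gender"], age_bucket])["label"].sum()
    assert strata.sum() == cohort["label"].sum()


def test_load_ehr_missing_file(tmp_path, small_tables):
    write_ehr(small_tables, tmp_path)
    (tmp_path / "ICUSTAYS.csv").unlink()
    with pytest.raises(FileNotFoundError, match="ICUSTAYS"):
        load_ehr(tmp_path)


def test_load_ehr_extra_columns_dropped(tmp_path, small_tables):
    write_ehr(small_tables, tmp_path)
    p = tmp_path / "PATIENTS.csv"
    df = pd.read_csv(p)
    df["ROW_ID"] = np.arange(len(df))
    df.columns = [c.upper() for c in df.columns]   # MIMIC-style headers
    df.to_csv(p, index=False)
    loaded = load_ehr(tmp_path)
    assert list(loaded.patients.columns) == ["subject_id", "gender", "dob", "dod"]


def test_load_ehr_bad_timestamp(tmp_path, small_tables):
    write_ehr(small_tables, tmp_path)
    p = tmp_path / "ICUSTAYS.csv"
    df = pd.read_csv(p)
    df.loc[3, "intime"] = "not-a-time"
    df.to_csv(p, index=False)
    with pytest.raises(ValueError, match="row index 3"):
        load_ehr(tmp_path)


# ---------------------------------------------------------------------------
# folds

def _random_cohort(rng, n_patients, prevalence):
    labels = (rng.random(n_patients) < prevalence).astype(int)
    return pd.DataFrame({"subject_id": np.arange(n_patients), "label": labels})


def test_fold_counts_small():
    cohort = pd.DataFrame({"subject_id": np.arange(10),
                           "label": [1] * 5 + [0] * 5})
    split = make_folds(cohort, k=5, val_fraction=0.25, seed=0)
    for fold in split:
        assert len(fold["test"]) == 2
        assert set(fold["train"]) & set(fold["test"]) == set()
        assert set(fold["val"]) & set(fold["test"]) == set()
        assert set(fold["train"]) & set(fold["val"]) == set()


def test_folds_partition_and_stratify(rng):
    cohort = _random_cohort(rng, 500, 0.12)
    split = make_folds(cohort, k=5, seed=3)
    all_test = np.concatenate([f["test"] for f in split])
    assert sorted(all_test) == sorted(cohort["subject_id"])
    prev = cohort["label"].mean()
    lab = cohort.set_index("subject_id")["label"]
    for fold in split:
        fold_prev = lab.loc[fold["test"]].mean()
        assert abs(fold_prev - prev) <= 0.02


def test_stratified_positive_counts():
    rng = np.random.default_rng(1)
    labels = np.zeros(100, dtype=int)
    labels[rng.choice(100, 11, replace=False)] = 1
    cohort = pd.DataFrame({"subject_id": np.arange(100), "label": labels})
    split = make_folds(cohort, k=5, seed=1)
    lab = cohort.set_index("subject_id")["label"]
    for fold in split:
        n_pos = int(lab.loc[fold["test"]].sum())
        assert n_pos in (2, 3)


def test_folds_deterministic(rng):
    cohort = _random_cohort(rng, 200, 0.2)
    a = make_folds(cohort, k=5, seed=7)
    b = make_folds(cohort, k=5, seed=7)
    for fa, fb in zip(a, b):
        for part in ("train", "val", "test"):
            assert np.array_equal(fa[part], fb[part])


def test_folds_rare_class_error():
    cohort = pd.DataFrame({"subject_id": np.arange(20),
                           "label": [1] * 3 + [0] * 17})
    with pytest.raises(ValueError, match="at least k"):
        make_folds(cohort, k=5)
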
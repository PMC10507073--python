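"""Synthetic MIMIC-schema EHR generator with a controllable readmission signal.

Generates the eight tables the pipeline consumes (PATIENTS, ADMISSIONS,
ICUSTAYS, CHARTEVENTS, LABEVENTS, DIAGNOSES_ICD, D_ICD_DIAGNOSES,
NOTEEVENTS) for a configurable number of patients. Each patient carries a
latent 30-day-readmission label; label-dependent structure is injected into
every modality with a per-modality effect size:

* **charts/labs** — positive patients' latent concept trajectories are
  shifted toward abnormal states (``chart_signal_target="level"``), or given
  a within-normal-band sawtooth drift that only the gradient abstraction can
  see (``chart_signal_target="trend"``);
* **icd9** — a designated set of risk diagnoses is over-sampled;
* **notes** — risk phrases are injected into templated discharge summaries.

Positives receive a follow-up ICU admission within 30 days of hospital
discharge; negatives never within 30 days. Follow-up stays are short
(< 1 day) and carry no measurements, so they act purely as readmission
targets and never enter the index cohort. All randomness flows from one
seeded generator: identical configs produce byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .knowledge import KnowledgeBase, load_knowledge_base

TABLE_NAMES = (
    "patients", "admissions", "icustays", "chartevents",
    "labevents", "diagnoses_icd", "d_icd_diagnoses", "noteevents",
)

_SCHEMAS: dict[str, list[str]] = {
    "patients": ["subject_id", "gender", "dob", "dod"],
    "admissions": ["subject_id", "hadm_id", "admittime", "dischtime",
                   "deathtime", "insurance", "ethnicity"],
    "icustays": ["subject_id", "hadm_id", "icustay_id", "intime", "outtime"],
    "chartevents": ["subject_id", "hadm_id", "icustay_id", "itemid", "charttime", "valuenum"],
    "labevents": ["subject_id", "hadm_id", "icustay_id", "itemid", "charttime", "valuenum"],
    "diagnoses_icd": ["subject_id", "hadm_id", "seq_num", "icd9_code"],
    "d_icd_diagnoses": ["icd9_code", "long_title"],
    "noteevents": ["subject_id", "hadm_id", "category", "charttime", "text"],
}

_INSURANCES = ["Medicare", "Medicaid", "Private", "Government", "Self Pay"]
_ETHNICITIES = ["WHITE", "BLACK/AFRICAN AMERICAN", "HISPANIC OR LATINO", "ASIAN", "OTHER"]

# ---------------------------------------------------------------------------
# Bundled ICD-9 vocabulary: 200 invented-but-plausible codes. The first two
# sub-codes of the first ten roots (20 codes) form the designated risk set
# that is over-sampled for positive patients.
_ICD9_ROOTS = [
    ("428", "systolic heart failure"), ("491", "obstructive bronchitis"),
    ("585", "kidney disease stage"), ("571", "hepatic cirrhosis"),
    ("250", "diabetes with complication"), ("410", "myocardial infarction"),
    ("507", "aspiration pneumonitis"), ("038", "septicemia"),
    ("996", "complication of device"), ("578", "gastrointestinal hemorrhage"),
    ("401", "essential hypertension"), ("272", "hyperlipidemia"),
    ("244", "hypothyroidism"), ("280", "iron deficiency anemia"),
    ("300", "anxiety state"), ("311", "depressive disorder"),
    ("530", "esophageal reflux"), ("535", "gastritis"),
    ("560", "intestinal obstruction"), ("274", "gout"),
    ("715", "osteoarthrosis"), ("733", "osteoporosis"),
    ("786", "chest pain"), ("780", "syncope and collapse"),
    ("599", "urinary tract infection"), ("486", "pneumonia organism"),
    ("682", "cellulitis and abscess"), ("707", "pressure ulcer"),
    ("453", "venous embolism"), ("427", "cardiac dysrhythmia"),
    ("414", "chronic ischemic heart disease"), ("424", "valve disorder"),
    ("433", "precerebral artery occlusion"), ("434", "cerebral artery occlusion"),
    ("493", "asthma"), ("518", "pulmonary insufficiency"),
    ("276", "fluid electrolyte disorder"), ("285", "anemia unspecified"),
    ("287", "thrombocytopenia"), ("305", "substance abuse"),
    ("332", "parkinson disease"), ("340", "multiple sclerosis"),
    ("345", "epilepsy"), ("357", "polyneuropathy"),
    ("362", "retinal disorder"), ("365", "glaucoma"),
    ("380", "ear disorder"), ("388", "hearing disturbance"),
    ("553", "abdominal hernia"), ("566", "anal abscess"),
]
_ICD9_QUALIFIERS = ["acute", "chronic", "recurrent", "unspecified"]


def icd9_vocabulary() -> pd.DataFrame:
    """The bundled 200-code dictionary table (icd9_code, long_title)."""
    rows = []
    for root, phrase in _ICD9_ROOTS:
        for j, qual in enumerate(_ICD9_QUALIFIERS):
            rows.append({
                "icd9_code": f"{root}.{j}",
                "long_title": f"{qual.capitalize()} {phrase}",
            })
    return pd.DataFrame(rows, columns=_SCHEMAS["d_icd_diagnoses"])


def risk_codes() -> list[str]:
    """Risk diagnoses over-sampled for readmitted patients."""
    return [f"{root}.{j}" for root, _ in _ICD9_ROOTS[:10] for j in (0, 1)]


_NEUTRAL_SENTENCES = [
    "patient was admitted for further evaluation and management.",
    "vital signs remained within acceptable limits during the stay.",
    "the patient tolerated the procedure well without complication.",
    "labs were monitored daily and trended toward baseline.",
    "physical therapy evaluated the patient prior to discharge.",
    "diet was advanced as tolerated.",
    "the patient was maintained on home medications.",
    "follow up with primary care provider was arranged.",
    "no acute events overnight.",
    "pain was controlled with oral analgesia.",
]
_RISK_PHRASES = [
    "recurrent decompensation noted during admission",
    "poor functional reserve at discharge",
    "high risk of clinical deterioration",
    "multiple recent hospitalizations for the same complaint",
    "discharged against medical advice considerations were discussed",
    "ongoing volume overload despite diuresis",
]


@dataclass
class SynthConfig:
    """Generation parameters; identical configs yield byte-identical tables."""

    n_patients: int = 200
    readmission_rate: float = 0.11
    signal_strength: dict[str, float] = field(
        default_factory=lambda: {"charts": 1.0, "icd9": 1.0, "notes": 1.0})
    missingness: float = 0.1
    chart_interval_minutes: float = 60.0
    lab_interval_hours: float = 24.0
    los_days_range: tuple[float, float] = (1.5, 8.0)
    chart_signal_target: str = "level"   # "level" (state shift) or "trend" (gradient drift)
    neg_followup_prob: float = 0.3       # negatives: chance of a >30-day later admission
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not 0.0 < self.readmission_rate < 1.0:
            raise ValueError("readmission_rate must lie in (0, 1)")
        if not 0.0 <= self.missingness <= 1.0:
            raise ValueError("missingness must lie in [0, 1]")
        if not 0.0 <= self.neg_followup_prob <= 1.0:
            raise ValueError("neg_followup_prob must lie in [0, 1]")
        if self.chart_interval_minutes <= 0 or self.lab_interval_hours <= 0:
            raise ValueError("sampling intervals must be positive")
        lo, hi = self.los_days_range
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ValueError("los_days_range must be positive and ordered (min <= max)")
        if self.chart_signal_target not in ("level", "trend"):
            raise ValueError("chart_signal_target must be 'level' or 'trend'")
        for k in ("charts", "icd9", "notes"):
            if self.signal_strength.get(k, 0.0) < 0:
                raise ValueError(f"signal_strength[{k!r}] must be non-negative")


@dataclass
class EHRTables:
    """In-memory bundle of the eight MIMIC-schema tables."""

    patients: pd.DataFrame
    admissions: pd.DataFrame
    icustays: pd.DataFrame
    chartevents: pd.DataFrame
    labevents: pd.DataFrame
    diagnoses_icd: pd.DataFrame
    d_icd_diagnoses: pd.DataFrame
    noteevents: pd.DataFrame
    # generator-only ground truth (subject_id -> latent label); not a table,
    # never written to disk
    latent_labels: pd.Series | None = None

    def __iter__(self):
        for name in TABLE_NAMES:
            yield name, getattr(self, name)

    def validate(self) -> None:
        """Check referential integrity and event-time containment."""
        subj = set(self.patients["subject_id"])
        hadm = set(self.admissions["hadm_id"])
        stays = self.icustays.set_index("icustay_id")
        if not set(self.admissions["subject_id"]) <= subj:
            raise ValueError("admissions reference unknown subject_id")
        if not set(self.icustays["hadm_id"]) <= hadm:
            raise ValueError("icustays reference unknown hadm_id")
        for name in ("chartevents", "labevents"):
            ev = getattr(self, name)
            if len(ev) == 0:
                continue
            if not set(ev["icustay_id"]) <= set(stays.index):
                raise ValueError(f"{name} reference unknown icustay_id")
            intime = stays.loc[ev["icustay_id"], "intime"].to_numpy()
            outtime = stays.loc[ev["icustay_id"], "outtime"].to_numpy()
            t = ev["charttime"].to_numpy()
            if not ((t >= intime) & (t <= outtime)).all():
                raise ValueError(f"{name} timestamps escape their stay window")


def _concept_band(entry) -> tuple[float, float, float]:
    lo, hi = entry.cutoffs[0], entry.cutoffs[-1]
    return lo, hi, hi - lo


def _event_times(rng: np.random.Generator, los_hours: float, interval_hours: float) -> np.ndarray:
    """Irregular sampling times (hours from intime) with +-30% gap jitter."""
    gaps = interval_hours * rng.uniform(0.7, 1.3, size=int(los_hours / interval_hours) + 8)
    times = 0.25 + np.cumsum(gaps)
    return times[times < los_hours - 0.05]


def _thin(rng: np.random.Generator, times: np.ndarray, p_drop: float, floor: int) -> np.ndarray:
    """Drop events with probability p_drop but keep at least `floor` of them."""
    if len(times) <= floor or p_drop <= 0:
        return times
    keep = rng.random(len(times)) > p_drop
    if keep.sum() < floor:
        idx = np.linspace(0, len(times) - 1, floor).round().astype(int)
        keep[:] = False
        keep[idx] = True
    return times[keep]


def _series_values(
    rng: np.random.Generator, entry, times: np.ndarray,
    positive: bool, signal: float, target: str, patient_offset: float,
) -> np.ndarray:
    """One concept's latent trajectory: per-patient baseline offset plus
    measurement noise, with the label-dependent component on top."""
    lo, hi, width = _concept_band(entry)
    baseline = (lo + hi) / 2.0 + patient_offset * width
    if target == "level":
        noise = rng.normal(0.0, 0.22 * width, size=len(times))
        shift = 0.35 * width * signal if positive else 0.0
        return baseline + shift + noise
    # trend: both classes stay (mostly) inside the normal band; positives get a
    # sawtooth drift whose consecutive differences are predominantly positive.
    noise = rng.normal(0.0, 0.06 * width, size=len(times))
    if positive and signal > 0:
        period = rng.integers(5, 9)
        phase = (np.arange(len(times)) + rng.integers(0, period)) % period
        # amplitude kept inside the normal band so the state abstraction
        # stays (near-)uninformative and the signal lives in the gradients
        ramp = (phase / max(period - 1, 1) - 0.5) * 0.35 * width * min(signal, 1.5)
        return baseline + ramp + noise
    return baseline + noise


def generate_ehr(config: SynthConfig) -> EHRTables:
    """Generate the eight EHR tables under the given configuration."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    kb = load_knowledge_base()
    risk = risk_codes()
    vocab = icd9_vocabulary()
    all_codes = vocab["icd9_code"].tolist()
    nonrisk = [c for c in all_codes if c not in set(risk)]
    title_of = dict(zip(vocab["icd9_code"], vocab["long_title"]))
    base = pd.Timestamp("2130-01-01")

    sig_charts = config.signal_strength.get("charts", 0.0)
    sig_icd9 = config.signal_strength.get("icd9", 0.0)
    sig_notes = config.signal_strength.get("notes", 0.0)

    pat_rows, adm_rows, stay_rows, dx_rows, note_rows = [], [], [], [], []
    chart_chunks, lab_chunks = [], []
    hadm_id, icustay_id = 100000, 200000
    latent: dict[int, int] = {}

    for subject_id in range(1, config.n_patients + 1):
        positive = bool(rng.random() < config.readmission_rate)
        latent[subject_id] = int(positive)
        gender = "M" if rng.random() < 0.55 else "F"
        age = 18.0 + 70.0 * rng.beta(2.0, 2.2)
        insurance = _INSURANCES[rng.integers(len(_INSURANCES))]
        ethnicity = _ETHNICITIES[rng.integers(len(_ETHNICITIES))]

        admit = base + pd.to_timedelta(float(rng.uniform(0, 3650 * 24)), "h")
        dob = admit - pd.to_timedelta(age * 365.25 * 24, "h")
        los_days = float(rng.uniform(*config.los_days_range))
        intime = admit + pd.to_timedelta(float(rng.uniform(1, 6)), "h")
        outtime = intime + pd.to_timedelta(los_days * 24, "h")
        disch = outtime + pd.to_timedelta(float(rng.uniform(4, 30)), "h")

        pat_rows.append((subject_id, gender, dob, pd.NaT))
        hadm_id += 1
        adm_rows.append((subject_id, hadm_id, admit, disch, pd.NaT, insurance, ethnicity))
        icustay_id += 1
        stay_rows.append((subject_id, hadm_id, icustay_id, intime, outtime))

        # temporal events -------------------------------------------------
        los_hours = los_days * 24.0
        offset_sd = 0.18 if config.chart_signal_target == "level" else 0.08
        for entry in kb:
            patient_offset = float(rng.normal(0.0, offset_sd))
            if entry.source == "chart":
                interval, floor = config.chart_interval_minutes / 60.0, 5
            else:
                interval, floor = config.lab_interval_hours, 1
            times = _event_times(rng, los_hours, interval)
            if len(times) < floor:   # very short stays: guarantee the minimum
                times = np.linspace(0.3, los_hours - 0.1, floor)
            times = _thin(rng, times, config.missingness, floor)
            values = _series_values(
                rng, entry, times, positive, sig_charts,
                config.chart_signal_target, patient_offset)
            chunk = pd.DataFrame({
                "subject_id": subject_id, "hadm_id": hadm_id, "icustay_id": icustay_id,
                "itemid": entry.itemid,
                "charttime": intime + pd.to_timedelta(times, "h"),
                "valuenum": np.round(values, 3),
            })
            (chart_chunks if entry.source == "chart" else lab_chunks).append(chunk)

        # diagnoses -------------------------------------------------------
        n_codes = int(np.clip(rng.poisson(7) + 3, 3, 18))
        p_risk = 0.12 + (0.20 * sig_icd9 if positive else 0.0)
        p_risk = min(p_risk, 0.9)
        for seq in range(1, n_codes + 1):
            pool = risk if rng.random() < p_risk else nonrisk
            dx_rows.append((subject_id, hadm_id, seq, pool[rng.integers(len(pool))]))

        # discharge note --------------------------------------------------
        n_sent = int(rng.integers(4, 8))
        body = [_NEUTRAL_SENTENCES[i] for i in rng.integers(0, len(_NEUTRAL_SENTENCES), n_sent)]
        if positive and sig_notes > 0:
            p_phrase = min(0.25 * sig_notes, 0.9)
            for phrase in _RISK_PHRASES:
                if rng.random() < p_phrase:
                    body.insert(int(rng.integers(0, len(body) + 1)), phrase + ".")
        dx_titles = [title_of[r[3]].lower() for r in dx_rows[-min(3, n_codes):]]
        text = (
            "Admission Date: [**2130-1-1**]  Discharge Date: [**2130-1-9**]\n\n"
            "Chief Complaint:\n" + dx_titles[0] + "\n\n"
            "Hospital Course:\n" + " ".join(body) + "\n\n"
            "Discharge Diagnoses:\n" + ", ".join(dx_titles) + "\n\n"
            "Followup Instructions:\nfollow up with [**Last Name**] clinic.\n"
        )
        note_rows.append((subject_id, hadm_id, "Discharge summary", disch, text))

        # follow-up admission (the label mechanism) ------------------------
        gap_days = None
        if positive:
            gap_days = float(rng.uniform(1.0, 29.5))
        elif rng.random() < config.neg_followup_prob:
            gap_days = float(rng.uniform(31.5, 300.0))
        if gap_days is not None:
            admit2 = disch + pd.to_timedelta(gap_days * 24, "h")
            disch2 = admit2 + pd.to_timedelta(30.0, "h")
            hadm_id += 1
            adm_rows.append((subject_id, hadm_id, admit2, disch2, pd.NaT, insurance, ethnicity))
            icustay_id += 1
            stay_rows.append((
                subject_id, hadm_id, icustay_id,
                admit2 + pd.to_timedelta(1.0, "h"),
                admit2 + pd.to_timedelta(11.0, "h"),
            ))

    def frame(rows, name):
        return pd.DataFrame(rows, columns=_SCHEMAS[name])

    empty_ev = pd.DataFrame(columns=_SCHEMAS["chartevents"])
    tables = EHRTables(
        patients=frame(pat_rows, "patients"),
        admissions=frame(adm_rows, "admissions"),
        icustays=frame(stay_rows, "icustays"),
        chartevents=pd.concat(chart_chunks, ignore_index=True) if chart_chunks else empty_ev,
        labevents=pd.concat(lab_chunks, ignore_index=True) if lab_chunks else empty_ev.copy(),
        diagnoses_icd=frame(dx_rows, "diagnoses_icd"),
        d_icd_diagnoses=vocab,
        noteevents=frame(note_rows, "noteevents"),
        latent_labels=pd.Series(latent, name="label"),
    )
    # whole-second timestamps so tables round-trip losslessly through CSV
    for _, df in tables:
        for col in df.columns:
            if pd.api.types.is_datetime64_any_dtype(df[col]):
                df[col] = df[col].dt.floor("s")
    return tables


def write_ehr(tables: EHRTables, directory: str | Path) -> list[Path]:
    """Write one CSV per table (upper-case MIMIC file names, ISO timestamps)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables:
        out = df.copy()
        for col in out.columns:
            if pd.api.types.is_datetime64_any_dtype(out[col]):
                out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M:%S")
        path = directory / f"{name.upper()}.csv"
        out.to_csv(path, index=False)
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# Oracle features: generator-aware per-stay summaries used to audit the
# injected signal with a simple linear scorer (not part of the model path).

def oracle_features(tables: EHRTables, kb: KnowledgeBase | None = None) -> pd.DataFrame:
    """Per index-stay summary features that see each injected signal directly.

    One row per patient's first ICU stay: per-chart-concept mean value and
    mean absolute consecutive difference, per-lab-concept mean value, the
    fraction of risk diagnoses, and the risk-phrase count of the note.
    """
    kb = kb or load_knowledge_base()
    first = (tables.icustays.sort_values("intime")
             .groupby("subject_id", as_index=False).first())
    rows = []
    risk = set(risk_codes())
    events = pd.concat([tables.chartevents, tables.labevents], ignore_index=True)
    by_stay = dict(tuple(events.groupby("icustay_id"))) if len(events) else {}
    dx_by_hadm = dict(tuple(tables.diagnoses_icd.groupby("hadm_id")))
    notes_by_hadm = dict(tuple(tables.noteevents.groupby("hadm_id")))
    for _, stay in first.iterrows():
        feat = {"subject_id": stay["subject_id"], "icustay_id": stay["icustay_id"]}
        ev = by_stay.get(stay["icustay_id"])
        for entry in kb:
            vals = (ev[ev["itemid"] == entry.itemid].sort_values("charttime")["valuenum"]
                    .to_numpy() if ev is not None else np.array([]))
            mid = (entry.cutoffs[0] + entry.cutoffs[-1]) / 2
            feat[f"{entry.name}_mean"] = vals.mean() if len(vals) else mid
            if entry.source == "chart":
                feat[f"{entry.name}_absdiff"] = (
                    np.abs(np.diff(vals)).mean() if len(vals) > 1 else 0.0)
        dx = dx_by_hadm.get(stay["hadm_id"])
        feat["risk_code_frac"] = (
            dx["icd9_code"].isin(risk).mean() if dx is not None and len(dx) else 0.0)
        note = notes_by_hadm.get(stay["hadm_id"])
        text = note["text"].iloc[0] if note is not None and len(note) else ""
        feat["risk_phrase_count"] = sum(p in text for p in _RISK_PHRASES)
        rows.append(feat)
    return pd.DataFrame(rows)


def plant_violations(tables: EHRTables, kb: KnowledgeBase | None = None) -> tuple[EHRTables, dict[str, int]]:
    """Append stays that each violate exactly one inclusion rule (test aid).

    Returns the augmented tables and a map rule -> planted icustay_id:
    a 0.5-day stay (length-of-stay rule), a stay with only 4 heart-rate
    measurements (chart-count rule), a stay whose patient dies 10 days after
    hospital discharge (death rule), and a pair of stays 180 days apart
    (first-stay-per-year rule; the second stay is the planted one).
    """
    kb = kb or load_knowledge_base()
    aug = EHRTables(**{name: df.copy() for name, df in tables})
    next_subj = int(aug.patients["subject_id"].max()) + 1
    next_hadm = int(aug.admissions["hadm_id"].max()) + 1
    next_stay = int(aug.icustays["icustay_id"].max()) + 1
    base = pd.Timestamp("2131-06-01")
    planted: dict[str, int] = {}

    def add_stay(subject_id, hadm, stay, admit, los_days, death=None,
                 chart_counts=None, dob_age=50.0):
        """Full complement of measurements unless chart_counts overrides."""
        intime = admit + pd.to_timedelta(2.0, "h")
        outtime = intime + pd.to_timedelta(los_days * 24, "h")
        disch = outtime + pd.to_timedelta(6.0, "h")
        if not (aug.patients["subject_id"] == subject_id).any():
            aug.patients.loc[len(aug.patients)] = (
                subject_id, "F", admit - pd.to_timedelta(dob_age * 365.25 * 24, "h"),
                death if death is not None else pd.NaT)
        aug.admissions.loc[len(aug.admissions)] = (
            subject_id, hadm, admit, disch,
            death if death is not None else pd.NaT, "Private", "WHITE")
        aug.icustays.loc[len(aug.icustays)] = (subject_id, hadm, stay, intime, outtime)
        for entry in kb:
            n = 6 if entry.source == "chart" else 2
            if chart_counts and entry.name in chart_counts:
                n = chart_counts[entry.name]
            times = np.linspace(0.3, los_days * 24 - 0.2, n)
            mid = (entry.cutoffs[0] + entry.cutoffs[-1]) / 2
            chunk = pd.DataFrame({
                "subject_id": subject_id, "hadm_id": hadm, "icustay_id": stay,
                "itemid": entry.itemid,
                "charttime": intime + pd.to_timedelta(times, "h"),
                "valuenum": mid,
            })
            if entry.source == "chart":
                aug.chartevents = pd.concat([aug.chartevents, chunk], ignore_index=True)
            else:
                aug.labevents = pd.concat([aug.labevents, chunk], ignore_index=True)
        return disch

    # LOS 0.5 days
    add_stay(next_subj, next_hadm, next_stay, base, 0.5)
    planted["los"] = next_stay
    next_subj, next_hadm, next_stay = next_subj + 1, next_hadm + 1, next_stay + 1
    # only 4 heart-rate measurements
    add_stay(next_subj, next_hadm, next_stay, base, 3.0, chart_counts={"heart_rate": 4})
    planted["chart_count"] = next_stay
    next_subj, next_hadm, next_stay = next_subj + 1, next_hadm + 1, next_stay + 1
    # death 10 days after hospital discharge
    death = base + pd.to_timedelta(3.0 * 24 + 8 + 10 * 24, "h")
    add_stay(next_subj, next_hadm, next_stay, base, 3.0, death=death)
    planted["death"] = next_stay
    next_subj, next_hadm, next_stay = next_subj + 1, next_hadm + 1, next_stay + 1
    # two clean stays 180 days apart: the second violates first-stay-per-year
    add_stay(next_subj, next_hadm, next_stay, base, 3.0)
    planted["year_rule_kept"] = next_stay
    next_hadm, next_stay = next_hadm + 1, next_stay + 1
    add_stay(next_subj, next_hadm, next_stay, base + pd.to_timedelta(180 * 24, "h"), 3.0)
    planted["year_rule_removed"] = next_stay
    return aug, planted


def count_risk_phrases(text: str) -> int:
    return sum(p in text for p in _RISK_PHRASES)
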
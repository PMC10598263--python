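"""Clinical tables: outcome labelling under right censoring, data splits,
and clinical feature encoding for the fusion models.

Labelling rule: a patient is *positive* for an outcome if the event occurred
within the time frame, *negative* if observed event-free through the frame,
and *excluded* if event-free but with follow-up shorter than the frame
(outcome status unknown). Default frames: 2 years (730 d) for distant
metastasis and loco-regional failure, 4 years (1460 d) for overall survival.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigurationError, DataError, StratificationError

POSITIVE, NEGATIVE, EXCLUDED = "positive", "negative", "excluded"

OUTCOMES = ("DM", "LRF", "OS")
_EVENT_COLS = {"DM": ("event_dm", "time_dm_days"), "LRF": ("event_lrf", "time_lrf_days"), "OS": ("event_death", "time_death_days")}


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    age: float
    sex: str
    hpv_status: str
    site: str
    t_stage: str
    n_stage: str
    overall_stage: str
    treatment: str
    event_dm: int
    time_dm_days: Optional[float]
    event_lrf: int
    time_lrf_days: Optional[float]
    event_death: int
    time_death_days: Optional[float]
    followup_days: Optional[float]
    gtv_area_mm2: float = float("nan")
    gtv_volume_mm3: float = float("nan")
    institution: str = ""
    texture_heterogeneity: float = float("nan")

    def __post_init__(self):
        for ev, (ecol, tcol) in _EVENT_COLS.items():
            if getattr(self, ecol) and getattr(self, tcol) is None:
                raise DataError(f"{self.patient_id}: {ev} event set but no event time")
            t = getattr(self, tcol)
            if t is not None and t < 0:
                raise DataError(f"{self.patient_id}: negative {ev} time")
        if self.followup_days is not None and self.followup_days < 0:
            raise DataError(f"{self.patient_id}: negative follow-up time")


@dataclass(frozen=True)
class OutcomeSpec:
    outcome: str
    time_frame_days: int = 0

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise ConfigurationError(f"outcome must be one of {OUTCOMES}, got {self.outcome!r}")
        if self.time_frame_days == 0:
            object.__setattr__(self, "time_frame_days", 1460 if self.outcome == "OS" else 730)
        if self.time_frame_days <= 0:
            raise ConfigurationError("time_frame_days must be > 0")


@dataclass
class SplitPlan:
    mode: str  # "cohort_split" | "kfold"
    assignment: dict  # patient_id -> "train"/"validation"/"test" or fold index
    seed: Optional[int] = None

    def ids(self, role) -> list:
        return [pid for pid, r in self.assignment.items() if r == role]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"patient_id": list(self.assignment), "assignment": list(self.assignment.values())}
        )


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

def derive_label(rec: PatientRecord, spec: OutcomeSpec) -> str:
    """Trichotomy {positive, negative, excluded} under the censoring rule."""
    ecol, tcol = _EVENT_COLS[spec.outcome]
    event = bool(getattr(rec, ecol))
    etime = getattr(rec, tcol)
    frame = spec.time_frame_days
    if event and etime <= frame:
        return POSITIVE
    # event after the frame: observed event-free through the frame
    if event and etime > frame:
        return NEGATIVE
    if rec.followup_days is None:
        raise DataError(f"{rec.patient_id}: event-free record with no follow-up time")
    return NEGATIVE if rec.followup_days >= frame else EXCLUDED


def label_cohort(records: Iterable[PatientRecord], spec: OutcomeSpec) -> pd.DataFrame:
    rows = [(r.patient_id, derive_label(r, spec)) for r in records]
    return pd.DataFrame(rows, columns=["patient_id", "label"])


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def cohort_split(records: Iterable[PatientRecord], institution_map: dict) -> SplitPlan:
    """Fixed institution-based partition into train/validation/test."""
    records = list(records)
    roles = set(institution_map.values())
    for role in ("train", "validation", "test"):
        if role not in roles:
            raise ConfigurationError(f"institution_map assigns no institution to {role!r}")
    assignment = {}
    for rec in records:
        if rec.institution not in institution_map:
            raise ConfigurationError(f"unknown institution {rec.institution!r} for {rec.patient_id}")
        assignment[rec.patient_id] = institution_map[rec.institution]
    return SplitPlan(mode="cohort_split", assignment=assignment)


def stratified_kfold(records: Iterable[PatientRecord], k: int, spec: OutcomeSpec, seed: int) -> SplitPlan:
    """Stratified k folds over labelled (non-excluded) records.

    Per-fold positive counts differ by at most one from exact
    proportionality; excluded records are never assigned.
    """
    records = list(records)
    labels = [derive_label(r, spec) for r in records]
    keep = [(r, lab) for r, lab in zip(records, labels) if lab != EXCLUDED]
    y = np.array([1 if lab == POSITIVE else 0 for _, lab in keep])
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos < k or n_neg < k:
        raise StratificationError(f"need >= {k} of each class, have {n_pos} positives / {n_neg} negatives")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        for i in test_idx:
            assignment[keep[i][0].patient_id] = fold
    return SplitPlan(mode="kfold", assignment=assignment, seed=seed)


# ---------------------------------------------------------------------------
# clinical encoding
# ---------------------------------------------------------------------------

UNKNOWN = "unknown"

#: Variables one-hot encoded (staging collapsed to main categories; M stage
#: is never included because the cohorts exclude metastatic presentation).
CATEGORICAL_VARS = ("sex", "hpv_status", "site", "t_stage", "n_stage", "overall_stage", "treatment")
QUARTILE_VARS = ("gtv_volume_mm3", "gtv_area_mm2")


def collapse_stage(value: str) -> str:
    """Aggregate staging sub-categories to the main category (T4a/T4b -> T4)."""
    v = str(value).strip()
    if len(v) >= 2 and v[0] in "TN" and v[1].isdigit():
        return v[:2]
    return v


@dataclass
class ClinicalEncoding:
    """One-hot levels and quartile thresholds, fitted on training records only."""

    levels: dict = field(default_factory=dict)       # var -> ordered level list (ending in UNKNOWN)
    quartiles: dict = field(default_factory=dict)    # var -> 3 thresholds (q25, q50, q75)
    age_max: float = 100.0
    fitted_on: str = "train"

    @property
    def feature_names(self) -> list:
        names = ["age"]
        for var in CATEGORICAL_VARS:
            names += [f"{var}={lev}" for lev in self.levels[var]]
        for var in QUARTILE_VARS:
            names += [f"{var}_q{i}" for i in range(1, 5)]
        return names

    @property
    def dim(self) -> int:
        return len(self.feature_names)


def _norm_cat(var: str, value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)) or str(value).strip() == "":
        return UNKNOWN
    v = str(value).strip()
    return collapse_stage(v) if var in ("t_stage", "n_stage") else v


def fit_clinical_encoding(train_records: Iterable[PatientRecord]) -> ClinicalEncoding:
    train_records = list(train_records)
    if not train_records:
        raise DataError("cannot fit an encoding on zero records")
    enc = ClinicalEncoding()
    for var in CATEGORICAL_VARS:
        vals = [_norm_cat(var, getattr(r, var)) for r in train_records]
        observed = sorted(set(vals) - {UNKNOWN})
        if not observed:
            raise DataError(f"variable {var!r} is missing for every training record")
        enc.levels[var] = observed + [UNKNOWN]
    for var in QUARTILE_VARS:
        vals = np.array([getattr(r, var) for r in train_records], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise DataError(f"variable {var!r} is missing for every training record")
        enc.quartiles[var] = tuple(np.quantile(vals, [0.25, 0.5, 0.75]))
    return enc


def quartile_bin(value: float, thresholds) -> int:
    """1-based quartile bin of ``value`` against fitted thresholds."""
    return int(np.searchsorted(np.asarray(thresholds), value, side="right")) + 1


def encode_clinical(rec: PatientRecord, enc: ClinicalEncoding) -> np.ndarray:
    """Fixed-length feature vector: scaled age, one-hot blocks, quartile one-hots."""
    out = [min(max(rec.age / enc.age_max, 0.0), 1.0)]
    for var in CATEGORICAL_VARS:
        levels = enc.levels[var]
        v = _norm_cat(var, getattr(rec, var))
        if v not in levels:
            v = UNKNOWN
        out += [1.0 if lev == v else 0.0 for lev in levels]
    for var in QUARTILE_VARS:
        val = getattr(rec, var)
        block = [0.0, 0.0, 0.0, 0.0]
        if np.isfinite(val):
            block[quartile_bin(val, enc.quartiles[var]) - 1] = 1.0
        out += block
    return np.asarray(out, dtype=np.float32)


def encode_cohort(records: Iterable[PatientRecord], enc: ClinicalEncoding) -> np.ndarray:
    return np.stack([encode_clinical(r, enc) for r in records])


# ---------------------------------------------------------------------------
# CSV schema shared with the phantom generator
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "patient_id", "age", "sex", "hpv", "site", "t_stage", "n_stage",
    "overall_stage", "treatment", "event_dm", "time_dm_days", "event_lrf",
    "time_lrf_days", "event_death", "time_death_days", "followup_days",
    "gtv_area_mm2", "gtv_volume_mm3", "institution",
]


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "patient_id": r.patient_id, "age": r.age, "sex": r.sex, "hpv": r.hpv_status,
            "site": r.site, "t_stage": r.t_stage, "n_stage": r.n_stage,
            "overall_stage": r.overall_stage, "treatment": r.treatment,
            "event_dm": r.event_dm, "time_dm_days": r.time_dm_days,
            "event_lrf": r.event_lrf, "time_lrf_days": r.time_lrf_days,
            "event_death": r.event_death, "time_death_days": r.time_death_days,
            "followup_days": r.followup_days, "gtv_area_mm2": r.gtv_area_mm2,
            "gtv_volume_mm3": r.gtv_volume_mm3, "institution": r.institution,
        })
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def load_clinical_csv(path, column_map_yaml=None) -> list[PatientRecord]:
    """Read a clinical table, optionally renaming columns first.

    On the real-data path institutional tables rarely match the packaged
    schema; ``column_map_yaml`` points to a YAML mapping of
    ``source_column: packaged_column`` (see CSV_COLUMNS) applied before
    parsing. Unmapped packaged columns must already be present.
    """
    df = pd.read_csv(path)
    if column_map_yaml is not None:
        import yaml

        mapping = yaml.safe_load(open(column_map_yaml)) or {}
        unknown = set(mapping.values()) - set(CSV_COLUMNS)
        if unknown:
            raise DataError(f"column map targets unknown columns: {sorted(unknown)}")
        df = df.rename(columns=mapping)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"clinical table lacks columns: {sorted(missing)}")
    return frame_to_records(df)


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    def _t(v):
        return None if pd.isna(v) else float(v)

    records = []
    for _, row in df.iterrows():
        records.append(PatientRecord(
            patient_id=str(row["patient_id"]), age=float(row["age"]), sex=str(row["sex"]),
            hpv_status=str(row["hpv"]), site=str(row["site"]), t_stage=str(row["t_stage"]),
            n_stage=str(row["n_stage"]), overall_stage=str(row["overall_stage"]),
            treatment=str(row["treatment"]),
            event_dm=int(row["event_dm"]), time_dm_days=_t(row["time_dm_days"]),
            event_lrf=int(row["event_lrf"]), time_lrf_days=_t(row["time_lrf_days"]),
            event_death=int(row["event_death"]), time_death_days=_t(row["time_death_days"]),
            followup_days=_t(row["followup_days"]),
            gtv_area_mm2=float(row.get("gtv_area_mm2", np.nan)),
            gtv_volume_mm3=float(row.get("gtv_volume_mm3", np.nan)),
            institution=str(row.get("institution", "")),
        ))
    return records
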
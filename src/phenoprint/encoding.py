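"""Encode per-patient event streams into temporal images.

A temporal image is an F x 53 matrix (F = registry size, default 84):
columns are week offsets -52..0 relative to the index date (week 0 is
the week of the first qualifying diagnosis), rows are registry
features.  Binary rows hold presence {0,1}; lab and vital rows hold a
graded abnormality score in [0,1] (0 = normal / at the population
mean, 1 = extreme).  Same-week duplicates aggregate by max, so adding
an event can never lower a pixel.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from datetime import date, datetime

import numpy as np
import pandas as pd

from .registry import FeatureRegistry, UnknownCodeError, default_registry

__all__ = [
    "N_WEEKS",
    "WEEK_MIN",
    "WEEK_MAX",
    "TemporalImage",
    "ImageStack",
    "LabStandardizer",
    "VitalScorer",
    "SymptomLexicon",
    "DegenerateDistributionError",
    "week_offset",
    "week_to_column",
    "column_to_week",
    "fit_lab_standardizer",
    "lab_score",
    "vital_score",
    "default_standardizers",
    "default_vital_scorers",
    "default_lexicon",
    "match_symptoms",
    "encode_patient",
    "encode_cohort",
    "write_images",
    "read_images",
]

logger = logging.getLogger(__name__)

#: observation window in week offsets: 52 weeks before the index plus
#: the index week itself
WEEK_MIN, WEEK_MAX = -52, 0
N_WEEKS = WEEK_MAX - WEEK_MIN + 1  # 53


class DegenerateDistributionError(ValueError):
    """Lab cohort distribution has zero spread; no score can be fitted."""


# ---------------------------------------------------------------------------
# week binning
# ---------------------------------------------------------------------------

def week_offset(event_date: date, index_date: date) -> int:
    """Signed whole-week bin of an event relative to the index date.

    Weeks are counted in 7-day blocks anchored at the index date and
    numbered toward the event: an event 1-6 days before the index is
    still week 0, 7-13 days before is week -1, 350 days before is week
    -50.  Events after the index bin symmetrically (days 0-6 after are
    week 0, which is the only non-negative in-window bin).  Callers
    drop bins outside -52..0.
    """
    if isinstance(event_date, datetime):
        event_date = event_date.date()
    if isinstance(index_date, datetime):
        index_date = index_date.date()
    days = (event_date - index_date).days
    return int(math.trunc(days / 7))


def week_to_column(week: int) -> int:
    """Column index of a week offset (-52 -> 0, ..., 0 -> 52)."""
    return week - WEEK_MIN


def column_to_week(col: int) -> int:
    return col + WEEK_MIN


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TemporalImage:
    """One patient's features x weeks matrix, values in [0, 1]."""

    patient_id: str
    matrix: np.ndarray  # shape (F, N_WEEKS)

    @property
    def n_features(self) -> int:
        return self.matrix.shape[0]

    def pixel(self, row_index: int, week: int) -> float:
        """Value at 1-based feature row and week offset."""
        return float(self.matrix[row_index - 1, week_to_column(week)])


@dataclass
class ImageStack:
    """A cohort of images sharing one registry: ids + (n, F, W) array."""

    patient_ids: list[str]
    array: np.ndarray

    def __post_init__(self) -> None:
        if self.array.ndim != 3 or self.array.shape[0] != len(self.patient_ids):
            raise ValueError("array must be (n_patients, F, W)")

    def __len__(self) -> int:
        return len(self.patient_ids)

    def __getitem__(self, i: int) -> TemporalImage:
        return TemporalImage(self.patient_ids[i], self.array[i])

    def flat(self) -> np.ndarray:
        """Row-major flattened (n, F*W) view for distance computations."""
        n = self.array.shape[0]
        return self.array.reshape(n, -1)


# ---------------------------------------------------------------------------
# graded scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabStandardizer:
    """Maps a lab value to |z| / cap, saturating at 1.

    The population mean scores 0; values ``cap`` standard deviations or
    farther from the mean score 1; in between the score is linear in
    the absolute z-score.
    """

    mean: float
    sd: float
    cap: float = 3.0

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise DegenerateDistributionError("lab SD must be > 0")
        if not self.cap > 0:
            raise ValueError("cap must be > 0")


def fit_lab_standardizer(values, cap: float = 3.0) -> LabStandardizer:
    """Fit a lab standardizer from a cohort's value distribution."""
    arr = np.asarray(list(values), dtype=float)
    arr = arr[np.isfinite(arr)]
    if np.unique(arr).size < 2:
        raise DegenerateDistributionError(
            "need >= 2 distinct finite values to standardize a lab"
        )
    return LabStandardizer(mean=float(arr.mean()), sd=float(arr.std(ddof=1)), cap=cap)


def lab_score(value: float, s: LabStandardizer) -> float:
    """Graded abnormality of a lab value in [0, 1]."""
    return min(abs(value - s.mean) / (s.cap * s.sd), 1.0)


@dataclass(frozen=True)
class VitalScorer:
    """Piecewise-linear abnormality score for a vital sign.

    Values inside the normal range score 0; values at or beyond the
    extreme bound on either side score 1; in between the score is
    linear between the nearest normal edge and its extreme bound.  A
    ``None`` extreme bound disables scoring on that side (e.g. a pain
    score cannot be abnormally low).
    """

    lo_normal: float
    hi_normal: float
    lo_extreme: float | None
    hi_extreme: float | None

    def __post_init__(self) -> None:
        if self.lo_normal > self.hi_normal:
            raise ValueError("normal range inverted")
        if self.lo_extreme is not None and not self.lo_extreme < self.lo_normal:
            raise ValueError("low extreme bound must be below the normal range")
        if self.hi_extreme is not None and not self.hi_extreme > self.hi_normal:
            raise ValueError("high extreme bound must be above the normal range")


def vital_score(value: float, v: VitalScorer) -> float:
    """Graded abnormality of a vital-sign value in [0, 1]."""
    if v.lo_normal <= value <= v.hi_normal:
        return 0.0
    if value < v.lo_normal:
        if v.lo_extreme is None:
            return 0.0
        if value <= v.lo_extreme:
            return 1.0
        return (v.lo_normal - value) / (v.lo_normal - v.lo_extreme)
    if v.hi_extreme is None:
        return 0.0
    if value >= v.hi_extreme:
        return 1.0
    return (value - v.hi_normal) / (v.hi_extreme - v.hi_normal)


def default_standardizers(registry: FeatureRegistry, cap: float = 3.0) -> dict[str, LabStandardizer]:
    """Lab standardizers from the registry's shipped scoring metadata."""
    out: dict[str, LabStandardizer] = {}
    for f in registry.rows_in_group("lab"):
        meta = f.scoring_meta or {}
        if "mean" in meta and "sd" in meta:
            out[f.name.lower()] = LabStandardizer(
                mean=float(meta["mean"]), sd=float(meta["sd"]), cap=cap
            )
    return out


def default_vital_scorers(registry: FeatureRegistry) -> dict[str, VitalScorer]:
    """Vital scorers from the registry's normal/extreme bounds."""
    out: dict[str, VitalScorer] = {}
    for f in registry.rows_in_group("vital"):
        meta = f.scoring_meta or {}
        if "normal" in meta and "extreme" in meta:
            lo_n, hi_n = meta["normal"]
            lo_e, hi_e = meta["extreme"]
            out[f.name.lower()] = VitalScorer(
                lo_normal=float(lo_n),
                hi_normal=float(hi_n),
                lo_extreme=None if lo_e is None else float(lo_e),
                hi_extreme=None if hi_e is None else float(hi_e),
            )
    return out


# ---------------------------------------------------------------------------
# symptom keyword matching
# ---------------------------------------------------------------------------

@dataclass
class SymptomLexicon:
    """Symptom group -> keyword list; groups name registry rows."""

    groups: dict[str, list[str]]
    _patterns: dict[str, re.Pattern] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for group, kws in self.groups.items():
            if not kws:
                raise ValueError(f"symptom group {group!r} has no keywords")
            cleaned = [k.strip().lower() for k in kws]
            if any(not k for k in cleaned):
                raise ValueError(f"symptom group {group!r} has an empty keyword")
            self.groups[group] = cleaned
            alts = "|".join(re.escape(k) for k in cleaned)
            # whole-word, case-insensitive; phrases allow any whitespace run
            alts = alts.replace(r"\ ", r"\s+")
            self._patterns[group] = re.compile(rf"\b(?:{alts})\b", re.IGNORECASE)


def default_lexicon(registry: FeatureRegistry | None = None) -> SymptomLexicon:
    """Build the lexicon from the registry's symptom-row keyword lists."""
    registry = registry or default_registry()
    groups = {}
    for f in registry.rows_in_group("symptom"):
        meta = f.scoring_meta or {}
        if meta.get("keywords"):
            groups[f.name] = list(meta["keywords"])
    return SymptomLexicon(groups)


def match_symptoms(note_text: str, lexicon: SymptomLexicon) -> set[str]:
    """Symptom groups with at least one keyword present in the note.

    Matching is case-insensitive on word boundaries.  Negation is not
    handled: "denies anxiety" flags the anxiety group.
    """
    if not note_text:
        return set()
    return {g for g, pat in lexicon._patterns.items() if pat.search(note_text)}


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = ("patient_id", "week_offset", "date", "code", "value", "note_text", "end_week", "end_date")


def _resolve_week(row, index_date) -> int:
    w = row.get("week_offset")
    if w is not None and not (isinstance(w, float) and math.isnan(w)):
        return int(w)
    d = row.get("date")
    if d is None or (isinstance(d, float) and math.isnan(d)):
        raise ValueError("event needs either week_offset or date")
    if index_date is None:
        raise ValueError("events carry dates but no index_date was given")
    if isinstance(d, str):
        d = date.fromisoformat(d)
    return week_offset(d, index_date)


def encode_patient(
    events,
    registry: FeatureRegistry | None = None,
    standardizers: dict[str, LabStandardizer] | None = None,
    vital_scorers: dict[str, VitalScorer] | None = None,
    lexicon: SymptomLexicon | None = None,
    index_date: date | None = None,
    unknown: str = "error",
    patient_id: str | None = None,
) -> TemporalImage:
    """Encode one patient's events into a temporal image.

    ``events`` is a DataFrame (or list of dicts) with columns
    ``patient_id``, ``week_offset`` or ``date``, ``code``, optional
    ``value`` (labs/vitals), optional ``note_text`` (symptom keyword
    matching) and optional ``end_week``/``end_date`` (hospitalization
    spans).  ``unknown`` is ``"error"`` (raise on unclaimed codes) or
    ``"drop"`` (log and skip).

    Binary rows record presence; graded rows take the max abnormality
    score among same-week events; hospitalization marks every week its
    admission-discharge interval overlaps; events outside the -52..0
    window are dropped with a log entry.
    """
    registry = registry or default_registry()
    standardizers = standardizers if standardizers is not None else default_standardizers(registry)
    vital_scorers = vital_scorers if vital_scorers is not None else default_vital_scorers(registry)
    if isinstance(events, pd.DataFrame):
        records = events.to_dict("records")
    else:
        records = [dict(r) for r in events]

    pids = {r["patient_id"] for r in records if r.get("patient_id") is not None}
    if len(pids) > 1:
        raise ValueError(f"events belong to more than one patient: {sorted(pids)!r}")
    if patient_id is None:
        patient_id = next(iter(pids)) if pids else "unknown"

    mat = np.zeros((registry.n_features, N_WEEKS))

    def paint(feature, week, value):
        col = week_to_column(week)
        r = feature.row_index - 1
        mat[r, col] = max(mat[r, col], value)

    for rec in records:
        note = rec.get("note_text")
        has_note = isinstance(note, str) and note.strip()
        code = rec.get("code")
        has_code = code is not None and not (isinstance(code, float) and math.isnan(code))
        week = _resolve_week(rec, index_date)
        if not (WEEK_MIN <= week <= WEEK_MAX):
            logger.info("patient %s: event at week %d outside window, dropped", patient_id, week)
            continue
        if has_note:
            lex = lexicon if lexicon is not None else default_lexicon(registry)
            lexicon = lex
            for group in match_symptoms(note, lex):
                paint(registry.by_name(group), week, 1.0)
            if not has_code:
                continue
        try:
            feat = registry.lookup(str(code))
        except UnknownCodeError:
            if unknown == "drop":
                logger.info("patient %s: unknown code %r dropped", patient_id, code)
                continue
            raise
        if feat.group == "hospitalization":
            end = rec.get("end_week")
            if end is None or (isinstance(end, float) and math.isnan(end)):
                end_date = rec.get("end_date")
                if end_date is not None and not (isinstance(end_date, float) and math.isnan(end_date)):
                    if isinstance(end_date, str):
                        end_date = date.fromisoformat(end_date)
                    end = week_offset(end_date, index_date)
                else:
                    end = week
            for w in range(week, min(int(end), WEEK_MAX) + 1):
                if w >= WEEK_MIN:
                    paint(feat, w, 1.0)
            continue
        if feat.value_kind == "graded":
            value = rec.get("value")
            if value is None or (isinstance(value, float) and math.isnan(value)):
                raise ValueError(
                    f"patient {patient_id}: graded feature {feat.name!r} "
                    f"event at week {week} has no value"
                )
            key = feat.name.lower()
            if feat.group == "lab":
                try:
                    score = lab_score(float(value), standardizers[key])
                except KeyError:
                    raise ValueError(f"no standardizer for lab {feat.name!r}") from None
            else:
                try:
                    score = vital_score(float(value), vital_scorers[key])
                except KeyError:
                    raise ValueError(f"no scorer for vital {feat.name!r}") from None
            paint(feat, week, score)
        else:
            paint(feat, week, 1.0)
    return TemporalImage(patient_id=patient_id, matrix=mat)


def encode_cohort(
    events: pd.DataFrame,
    registry: FeatureRegistry | None = None,
    patients: pd.DataFrame | None = None,
    index_dates: dict | None = None,
    **kwargs,
) -> ImageStack:
    """Encode a whole cohort's events table into an ImageStack.

    Patients present in ``patients`` (or ``index_dates``) but without
    events get all-zero images.  Patient order follows ``patients`` if
    given, else first appearance in the events table.
    """
    registry = registry or default_registry()
    if index_dates is None and patients is not None and "index_date" in patients:
        index_dates = {
            str(r.patient_id): r.index_date for r in patients.itertuples()
        }
    if patients is not None:
        ids = [str(p) for p in patients["patient_id"]]
    else:
        ids = list(dict.fromkeys(str(p) for p in events["patient_id"]))
    # share scoring objects across patients
    kwargs.setdefault("standardizers", default_standardizers(registry))
    kwargs.setdefault("vital_scorers", default_vital_scorers(registry))
    kwargs.setdefault("lexicon", default_lexicon(registry))
    grouped = dict(tuple(events.groupby("patient_id", sort=False))) if len(events) else {}
    arrays = np.zeros((len(ids), registry.n_features, N_WEEKS))
    for i, pid in enumerate(ids):
        ev = grouped.get(pid)
        if ev is None or ev.empty:
            continue
        idx_date = None
        if index_dates is not None:
            idx_date = index_dates.get(pid)
            if isinstance(idx_date, str):
                idx_date = date.fromisoformat(idx_date)
            elif isinstance(idx_date, pd.Timestamp):
                idx_date = idx_date.date()
        img = encode_patient(
            ev, registry, index_date=idx_date, patient_id=pid, **kwargs
        )
        arrays[i] = img.matrix
    return ImageStack(ids, arrays)


# ---------------------------------------------------------------------------
# delimited-text persistence (sparse tall format)
# ---------------------------------------------------------------------------

def write_images(path, stack: ImageStack) -> None:
    """Write an image stack as a tall TSV of nonzero pixels.

    Header comment lines record the matrix shape and the full patient
    list, so all-zero patients survive a round-trip.
    """
    n, F, W = stack.array.shape
    with open(path, "w") as fh:
        fh.write(f"# shape\t{F}\t{W}\n")
        fh.write("# patients\t" + "\t".join(stack.patient_ids) + "\n")
        fh.write("patient_id\trow_index\tweek\tvalue\n")
        for i, pid in enumerate(stack.patient_ids):
            rows, cols = np.nonzero(stack.array[i])
            for r, c in zip(rows, cols):
                fh.write(f"{pid}\t{r + 1}\t{column_to_week(int(c))}\t{float(stack.array[i, r, c])!r}\n")


def read_images(path) -> ImageStack:
    """Read an image stack written by :func:`write_images`."""
    with open(path) as fh:
        shape_line = fh.readline().rstrip("\n").split("\t")
        if shape_line[0] != "# shape":
            raise ValueError(f"{path}: not an image archive")
        F, W = int(shape_line[1]), int(shape_line[2])
        patients = fh.readline().rstrip("\n").split("\t")[1:]
        fh.readline()  # column header
        idx = {pid: i for i, pid in enumerate(patients)}
        arr = np.zeros((len(patients), F, W))
        for line in fh:
            pid, row, week, value = line.rstrip("\n").split("\t")
            arr[idx[pid], int(row) - 1, week_to_column(int(week))] = float(value)
    return ImageStack(patients, arr)
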
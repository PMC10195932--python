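"""Synthetic longitudinal cohorts with planted prodromal phenotypes.

Real EHR extracts behind the fingerprinting method are not public, so
this module generates cohorts with known structure: each *archetype*
plants a prodromal phenotype — an onset week, an intensity trajectory
(none / constant / ramp / early-then-fade), and a set of active
feature rows with weekly event probabilities — plus archetype-specific
one-year outcome parameters (death, overdispersed hospitalization
counts, right-skewed length of stay, psychosis, mental-illness share).
The pipeline can then be tested end to end: encode, blur, cluster, and
check recovery of the planted labels and outcome rates.

The default eight-archetype suite mirrors the qualitative taxonomy of
the published clusters: one no-prodrome archetype, one late-onset
short prodrome, two gradual ramps, three early-persistent phenotypes
of varying intensity (one dominated by somatic comorbidity rows), and
one early-fading phenotype.  Outcome parameters default to the
published per-cluster one-year statistics, with hospitalization counts
drawn from a negative binomial whose dispersion is chosen to match the
published SD >> mean pattern.

Everything is driven by a single seeded generator: the same spec and
seed regenerate a bit-identical cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .encoding import N_WEEKS, WEEK_MAX, WEEK_MIN
from .registry import FeatureRegistry, default_registry

__all__ = [
    "ArchetypeSpec",
    "SyntheticCohort",
    "generate",
    "eligibility_filter",
    "default_archetypes",
    "expected_any_hospitalization_rate",
]

PROFILES = ("none", "constant", "ramp", "early_then_fade")

#: fraction of peak intensity retained at week 0 by the fading profile
_FADE_FLOOR = 0.15


@dataclass(frozen=True)
class ArchetypeSpec:
    """Generating parameters of one planted phenotype.

    ``active_rows`` maps registry row indices to the per-week event
    probability at full intensity; the archetype's profile and
    ``amplitude`` scale it week by week.  ``hosp_dispersion`` is the
    negative-binomial size parameter r (variance = m + m^2/r).
    """

    label: str
    n_patients: int
    onset_week: int
    profile: str
    amplitude: float
    active_rows: dict[int, float] = field(default_factory=dict)
    p_death: float = 0.013
    hosp_mean: float = 0.5
    hosp_dispersion: float = 0.4
    los_stay_mean: float = 7.0
    los_stay_sd: float = 10.0
    p_psychosis: float = 0.10
    mental_share: float = 0.70

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.profile not in PROFILES:
            raise ValueError(f"unknown intensity profile {self.profile!r}")
        if not WEEK_MIN <= self.onset_week <= WEEK_MAX:
            raise ValueError(f"onset_week {self.onset_week} outside {WEEK_MIN}..{WEEK_MAX}")
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError("amplitude must be in [0, 1]")
        for p in (self.p_death, self.p_psychosis, self.mental_share, *self.active_rows.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.hosp_mean < 0 or self.hosp_dispersion <= 0:
            raise ValueError("hosp_mean must be >= 0 and hosp_dispersion > 0")

    def weekly_intensity(self) -> np.ndarray:
        """Profile weight per week (length 53, weeks -52..0), in [0, 1]."""
        weeks = np.arange(WEEK_MIN, WEEK_MAX + 1)
        w = np.zeros(N_WEEKS)
        if self.profile == "none":
            return w
        active = weeks >= self.onset_week
        span = max(WEEK_MAX - self.onset_week, 1)
        if self.profile == "constant":
            w[active] = 1.0
        elif self.profile == "ramp":
            w[active] = (weeks[active] - self.onset_week) / span
            w[weeks == WEEK_MAX] = 1.0
        else:  # early_then_fade
            w[active] = 1.0 - (1.0 - _FADE_FLOOR) * (weeks[active] - self.onset_week) / span
        return w * self.amplitude


@dataclass
class SyntheticCohort:
    """Generated tables plus the planted ground-truth labels."""

    patients: pd.DataFrame
    events: pd.DataFrame
    outcomes: pd.DataFrame
    true_labels: dict[str, str]
    seed: int


def expected_any_hospitalization_rate(spec: ArchetypeSpec) -> float:
    """P(at least one hospitalization) under the archetype's count law."""
    m, r = spec.hosp_mean, spec.hosp_dispersion
    if m == 0:
        return 0.0
    return 1.0 - (r / (r + m)) ** r


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

_BASE_DATE = date(2010, 1, 6)


def _graded_value(feat, rng: np.random.Generator, size: int) -> np.ndarray:
    """Draw abnormal raw values for a lab or vital feature."""
    meta = feat.scoring_meta or {}
    if feat.group == "lab":
        mean, sd = float(meta.get("mean", 0.0)), float(meta.get("sd", 1.0))
        # folded-normal |z| shifted off the mean so scores are visibly > 0
        mag = 0.5 + np.abs(rng.normal(0.0, 1.5, size))
        sign = rng.choice([-1.0, 1.0], size)
        return mean + sign * mag * sd
    lo_n, hi_n = meta["normal"]
    lo_e, hi_e = meta["extreme"]
    u = 0.1 + 0.9 * rng.random(size)
    if lo_e is None:
        return hi_n + u * (hi_e - hi_n)
    side_hi = rng.random(size) < 0.5
    vals = np.where(side_hi, hi_n + u * (hi_e - hi_n), lo_n - u * (lo_n - lo_e))
    return vals


def generate(
    specs: list[ArchetypeSpec],
    seed: int,
    registry: FeatureRegistry | None = None,
) -> SyntheticCohort:
    """Generate a cohort from a list of archetype specs.

    Per patient: weekly feature events are Bernoulli draws at the
    archetype's (row probability x weekly intensity); every patient
    additionally receives the index-week mood-disorder diagnosis that
    defines week 0.  Outcomes are drawn from the archetype's parameter
    set.  All randomness flows from one generator seeded with ``seed``.
    """
    registry = registry or default_registry()
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError("archetype labels must be unique")
    for s in specs:
        for r in s.active_rows:
            if not 1 <= r <= registry.n_features:
                raise ValueError(f"archetype {s.label!r}: row {r} not in registry")

    rng = np.random.default_rng(seed)
    weeks = np.arange(WEEK_MIN, WEEK_MAX + 1)
    patient_rows, event_frames, outcome_rows = [], [], []
    true_labels: dict[str, str] = {}

    for spec in specs:
        n = spec.n_patients
        pids = [f"P-{spec.label}-{i:05d}" for i in range(n)]
        for pid in pids:
            true_labels[pid] = spec.label

        index_dates = [
            _BASE_DATE + timedelta(days=int(d)) for d in rng.integers(0, 365 * 4, n)
        ]
        ages = np.clip(rng.normal(49.0, 13.0, n), 18.0, 95.0)
        female = rng.random(n) < 0.158
        died = rng.random(n) < spec.p_death

        # --- prodrome events -------------------------------------------
        intensity = spec.weekly_intensity()  # (53,)
        rows = sorted(spec.active_rows)
        if rows:
            probs = np.array([spec.active_rows[r] for r in rows])  # (R,)
            P = probs[:, None] * intensity[None, :]                # (R, 53)
            mask = rng.random((n, len(rows), N_WEEKS)) < P[None, :, :]
            pi, ri, wi = np.nonzero(mask)
        else:
            pi = ri = wi = np.array([], dtype=int)

        ev_pid, ev_week, ev_code, ev_value, ev_end = [], [], [], [], []
        # group the drawn events by feature row so graded values can be
        # drawn in one vectorized batch per feature
        for j, row_idx in enumerate(rows):
            sel = ri == j
            if not sel.any():
                continue
            feat = registry.row(row_idx)
            k = int(sel.sum())
            pids_sel = [pids[p] for p in pi[sel]]
            weeks_sel = weeks[wi[sel]]
            if feat.group == "hospitalization":
                durations = rng.integers(0, 3, k)  # stay spans 1-3 week bins
                ends = np.minimum(weeks_sel + durations, WEEK_MAX)
                ev_end.extend(int(e) for e in ends)
                codes = ["hospitalization"] * k
                values = [math.nan] * k
            else:
                ev_end.extend([math.nan] * k)
                codes = [feat.codes[0].split("-")[0] for _ in range(k)]
                if feat.value_kind == "graded":
                    values = list(_graded_value(feat, rng, k))
                else:
                    values = [math.nan] * k
            ev_pid.extend(pids_sel)
            ev_week.extend(int(w) for w in weeks_sel)
            ev_code.extend(codes)
            ev_value.extend(values)

        # index-week diagnosis (episodic mood disorder, ICD-9 296.x)
        ev_pid.extend(pids)
        ev_week.extend([0] * n)
        ev_code.extend(["296.4"] * n)
        ev_value.extend([math.nan] * n)
        ev_end.extend([math.nan] * n)

        event_frames.append(
            pd.DataFrame(
                {
                    "patient_id": ev_pid,
                    "week_offset": ev_week,
                    "code": ev_code,
                    "value": ev_value,
                    "end_week": ev_end,
                }
            )
        )

        # --- one-year outcomes -----------------------------------------
        m, r = spec.hosp_mean, spec.hosp_dispersion
        counts = (
            rng.negative_binomial(r, r / (r + m), n) if m > 0 else np.zeros(n, dtype=int)
        )
        sigma2 = math.log(1.0 + (spec.los_stay_sd / spec.los_stay_mean) ** 2)
        mu = math.log(spec.los_stay_mean) - sigma2 / 2.0
        los = np.zeros(n)
        with_stays = np.nonzero(counts > 0)[0]
        for i in with_stays:
            stays = rng.lognormal(mu, math.sqrt(sigma2), int(counts[i]))
            # an admission always accrues at least a quarter day
            los[i] = np.maximum(stays, 0.25).sum()
        mental = rng.binomial(counts, spec.mental_share)
        psychosis = rng.random(n) < spec.p_psychosis

        for i, pid in enumerate(pids):
            patient_rows.append(
                {
                    "patient_id": pid,
                    "index_date": index_dates[i].isoformat(),
                    "age": float(ages[i]),
                    "sex": "F" if female[i] else "M",
                    "death_date": (
                        (index_dates[i] + timedelta(days=int(rng.integers(1, 365)))).isoformat()
                        if died[i]
                        else ""
                    ),
                    # eligibility bookkeeping: generated patients satisfy
                    # all three inclusion criteria by construction
                    "bd_code_count": int(2 + rng.poisson(2.0)),
                    "months_pre": int(12 + rng.integers(0, 60)),
                    "months_post": int(12 + rng.integers(0, 60)),
                }
            )
            outcome_rows.append(
                {
                    "patient_id": pid,
                    "died_within_1y": bool(died[i]),
                    "hospitalizations_1y": int(counts[i]),
                    "total_los_days_1y": float(round(los[i], 2)),
                    "psychosis_1y": bool(psychosis[i]),
                    "mental_illness_hospitalizations_1y": int(mental[i]),
                }
            )

    events = pd.concat(event_frames, ignore_index=True)
    return SyntheticCohort(
        patients=pd.DataFrame(patient_rows),
        events=events,
        outcomes=pd.DataFrame(outcome_rows),
        true_labels=true_labels,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------

def eligibility_filter(
    patients: pd.DataFrame,
    bd_code_min: int = 2,
    pre_months: int = 12,
    post_months: int = 12,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the cohort inclusion criteria and count exclusions.

    A patient is retained when all three hold: at least ``bd_code_min``
    qualifying diagnosis codes (guards against one-off miscoding), at
    least ``pre_months`` months of system presence before the index
    date, and at least ``post_months`` months after it.  Returns the
    retained patients plus per-criterion exclusion counts (a patient
    failing several criteria is counted under each).
    """
    required = {"bd_code_count", "months_pre", "months_post"}
    missing = required - set(patients.columns)
    if missing:
        raise ValueError(f"patients table missing columns {sorted(missing)}")
    few_codes = patients["bd_code_count"] < bd_code_min
    short_pre = patients["months_pre"] < pre_months
    short_post = patients["months_post"] < post_months
    keep = ~(few_codes | short_pre | short_post)
    counts = {
        "insufficient_bd_codes": int(few_codes.sum()),
        "insufficient_pre_period": int(short_pre.sum()),
        "insufficient_post_period": int(short_post.sum()),
        "retained": int(keep.sum()),
    }
    return patients[keep].reset_index(drop=True), counts


# ---------------------------------------------------------------------------
# default archetype suite
# ---------------------------------------------------------------------------

# per-archetype blocks of active rows (disjoint at full separation);
# row indices refer to the default 84-row registry.  Block sizes and
# event probabilities are balanced so the planted clusters carry
# comparable image mass despite their different onsets and intensity
# trajectories: short-prodrome archetypes get wider blocks, persistent
# ones narrower, so no planted cluster is an order of magnitude easier
# or harder to separate than another.
_ARCHETYPE_BLOCKS = {
    "late_onset_short": {6: 0.85, 10: 0.85, 16: 0.85, 20: 0.85, 61: 0.85,
                         63: 0.85, 70: 0.85, 71: 0.8, 72: 0.8, 82: 0.8},
    "ramp_long": {13: 0.85, 14: 0.85, 15: 0.8, 73: 0.8, 74: 0.8, 75: 0.8},
    "early_fading": {5: 0.85, 9: 0.8, 65: 0.8, 66: 0.8},
    "ramp_short": {21: 0.85, 62: 0.8, 67: 0.8, 69: 0.8, 76: 0.8, 77: 0.8,
                   78: 0.8, 81: 0.8},
    "no_prodrome": {},
    "early_comorbid": {25: 0.8, 28: 0.8, 29: 0.7, 34: 0.7, 46: 0.7},
    "early_mild": {23: 0.5, 31: 0.5, 37: 0.45, 68: 0.45, 83: 0.45},
    "early_intense": {19: 0.9, 64: 0.85, 79: 0.85, 80: 0.85},
}

#: rows shared by every archetype when separation < 1 (overlap noise)
_SHARED_ROWS = (9, 19, 70)

# outcome parameters follow the published per-cluster one-year
# statistics; the negative-binomial dispersion r = m^2 / (sd^2 - m)
# matches the published count SDs
_ARCHETYPE_OUTCOMES = {
    #                      p_death hosp_m  sd     los_m  los_sd  p_psy  mental
    "late_onset_short": (0.013, 0.5, 1.1, 11.1, 35.1, 0.12, 0.730),
    "ramp_long":        (0.021, 0.8, 1.4, 14.5, 39.3, 0.15, 0.718),
    "early_fading":     (0.008, 0.5, 1.1, 9.3, 30.4, 0.10, 0.772),
    "ramp_short":       (0.014, 0.6, 1.3, 10.2, 34.0, 0.12, 0.662),
    "no_prodrome":      (0.010, 0.2, 0.7, 4.0, 21.3, 0.05, 0.639),
    "early_comorbid":   (0.046, 0.7, 1.4, 9.4, 32.2, 0.10, 0.353),
    "early_mild":       (0.014, 0.3, 0.9, 5.9, 26.0, 0.08, 0.578),
    "early_intense":    (0.026, 1.4, 2.2, 22.8, 52.9, 0.20, 0.641),
}

_ARCHETYPE_SHAPE = {
    # label: (onset_week, profile, amplitude)
    "late_onset_short": (-10, "constant", 1.0),
    "ramp_long": (-40, "ramp", 0.8),
    "early_fading": (-52, "early_then_fade", 0.8),
    "ramp_short": (-20, "ramp", 0.9),
    "no_prodrome": (0, "none", 0.0),
    "early_comorbid": (-52, "constant", 0.6),
    "early_mild": (-52, "constant", 0.55),
    "early_intense": (-52, "constant", 0.9),
}


def default_archetypes(n_patients: int = 100, separation: float = 1.0) -> list[ArchetypeSpec]:
    """The eight-archetype suite with tunable separation.

    ``separation`` in (0, 1] scales how distinct the archetypes are:
    at 1 each archetype fires only its own disjoint feature-row block;
    below 1 its own rows weaken and all archetypes share background
    activity on a common row set, making recovery harder.  The mean
    per-stay LOS is the published mean total LOS divided by the
    expected number of stays among hospitalized patients.
    """
    if not 0.0 < separation <= 1.0:
        raise ValueError("separation must be in (0, 1]")
    specs = []
    shared_p = 0.35 * (1.0 - separation)
    for label, block in _ARCHETYPE_BLOCKS.items():
        onset, profile, amplitude = _ARCHETYPE_SHAPE[label]
        p_death, m, sd, los_m, los_sd, p_psy, mental = _ARCHETYPE_OUTCOMES[label]
        r = m * m / (sd * sd - m)
        rows = {row: p * separation for row, p in block.items()}
        if profile != "none" and shared_p > 0:
            for row in _SHARED_ROWS:
                rows[row] = max(rows.get(row, 0.0), shared_p)
        p_any = 1.0 - (r / (r + m)) ** r if m > 0 else 0.0
        stays_per_hospitalized = m / p_any if p_any > 0 else 1.0
        specs.append(
            ArchetypeSpec(
                label=label,
                n_patients=n_patients,
                onset_week=onset,
                profile=profile,
                amplitude=amplitude,
                active_rows=rows,
                p_death=p_death,
                hosp_mean=m,
                hosp_dispersion=r,
                los_stay_mean=los_m / stays_per_hospitalized,
                los_stay_sd=los_sd / max(stays_per_hospitalized, 1.0),
                p_psychosis=p_psy,
                mental_share=mental,
            )
        )
    return specs
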
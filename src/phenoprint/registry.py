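"""Feature schema for temporal phenotype images.

Every patient's longitudinal record is rendered as a features x weeks
matrix; the registry fixes the y-axis of that image: which clinical
feature owns each row, how raw event codes map onto rows, and whether a
row carries binary presence or a graded abnormality score in [0, 1].

The default registry has 84 rows:

=====  ==========================================================
rows   content
=====  ==========================================================
1      hospitalization (any admission overlapping the week)
2-22   mental-disorder diagnosis subgroups (ICD-9 290-319, one
       level below the chapter)
23-38  the 16 remaining ICD-9 first-level chapters (row 30 is
       diseases of the digestive system, 520-579)
39-45  the seven CPT procedure categories
46-55  the ten most frequent laboratory tests (graded)
56-60  five vital signs (graded)
61-84  24 bipolar-disorder symptom groups compiled from clinical
       rating instruments (HAM-D, YMRS, MADRS, PANSS, SAS/BARS/
       AIMS, C-SSRS)
=====  ==========================================================

Rows 1, 30 and the 61-84 symptom block are fixed conventions; the
ordering of the remaining rows is a documented package default and can
be replaced wholesale with :func:`load_registry`.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import yaml

__all__ = [
    "FeatureDef",
    "FeatureRegistry",
    "RegistryError",
    "DuplicateRowError",
    "UnknownCodeError",
    "default_registry",
    "load_registry",
    "save_registry",
    "DEFAULT_N_FEATURES",
]

DEFAULT_N_FEATURES = 84

GROUPS = frozenset(
    {
        "hospitalization",
        "diagnosis_mental",
        "diagnosis_other",
        "procedure_group",
        "lab",
        "vital",
        "symptom",
        "medication_class",
    }
)
VALUE_KINDS = frozenset({"binary", "graded"})
GRADED_GROUPS = frozenset({"lab", "vital"})

# Code-shape dispatch: ICD-9 diagnosis codes are three digits with an
# optional decimal extension; CPT codes are five digits; HCPCS level II
# codes are a letter followed by four digits.
_ICD_RE = re.compile(r"^\d{3}(\.\d+)?$")
_CPT_RE = re.compile(r"^\d{5}$")
_HCPCS_RE = re.compile(r"^[A-Za-z]\d{4}$")
_RANGE_RE = re.compile(r"^(\d{3,5})\s*-\s*(\d{3,5})$")

#: sentinel code claiming all HCPCS level II (letter-prefixed) codes
HCPCS_SENTINEL = "hcpcs"


class RegistryError(ValueError):
    """Invalid registry content (bad group, overlap, wrong size...)."""


class DuplicateRowError(RegistryError):
    """Two feature definitions claim the same row index."""


class UnknownCodeError(KeyError):
    """A code that no feature in the registry owns."""


@dataclass(frozen=True)
class FeatureDef:
    """One row of the temporal image.

    ``codes`` lists what the row owns: ICD-9/CPT numeric ranges
    (``"520-579"``, ``"00100-01999"``), single ICD-9 stems (``"291"``),
    the :data:`HCPCS_SENTINEL`, or literal names (lab/vital/symptom
    rows match events by name).  ``scoring_meta`` carries per-feature
    scoring defaults: ``{"mean", "sd"}`` for labs, ``{"normal",
    "extreme"}`` bounds for vitals, ``{"keywords"}`` for symptom rows.
    """

    row_index: int
    name: str
    group: str
    value_kind: str = "binary"
    codes: tuple[str, ...] = ()
    scoring_meta: dict | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise RegistryError(f"unknown feature group {self.group!r}")
        if self.value_kind not in VALUE_KINDS:
            raise RegistryError(f"unknown value kind {self.value_kind!r}")
        if self.value_kind == "graded" and self.group not in GRADED_GROUPS:
            raise RegistryError(
                f"graded value_kind is only valid for lab/vital rows, "
                f"not group {self.group!r} (row {self.row_index})"
            )
        if self.row_index < 1:
            raise RegistryError("row_index must be >= 1")
        object.__setattr__(self, "codes", tuple(self.codes))

    def to_dict(self) -> dict:
        d = {
            "row": self.row_index,
            "name": self.name,
            "group": self.group,
            "value_kind": self.value_kind,
            "codes": list(self.codes),
        }
        if self.scoring_meta is not None:
            d["scoring_meta"] = self.scoring_meta
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureDef":
        return cls(
            row_index=int(d["row"]),
            name=str(d["name"]),
            group=str(d["group"]),
            value_kind=str(d.get("value_kind", "binary")),
            codes=tuple(str(c) for c in d.get("codes", ())),
            scoring_meta=d.get("scoring_meta"),
        )


def _parse_range(code: str) -> tuple[int, int] | None:
    """Parse ``"520-579"`` / ``"291"`` into an inclusive integer range."""
    m = _RANGE_RE.match(code)
    if m:
        lo, hi = int(m.group(1)), int(m.group(2))
        if lo > hi:
            raise RegistryError(f"inverted code range {code!r}")
        return lo, hi
    if code.isdigit():
        v = int(code)
        return v, v
    return None


class FeatureRegistry:
    """Ordered feature schema with total, overlap-checked code lookup."""

    def __init__(self, features: Iterable[FeatureDef], version: str = "custom"):
        feats = sorted(features, key=lambda f: f.row_index)
        if not feats:
            raise RegistryError("registry must define at least one feature")
        seen: dict[int, str] = {}
        for f in feats:
            if f.row_index in seen:
                raise DuplicateRowError(
                    f"row {f.row_index} claimed by both {seen[f.row_index]!r} "
                    f"and {f.name!r}"
                )
            seen[f.row_index] = f.name
        if sorted(seen) != list(range(1, len(feats) + 1)):
            raise RegistryError(
                f"row indices must form a permutation of 1..{len(feats)}, "
                f"got {sorted(seen)}"
            )
        self.features: tuple[FeatureDef, ...] = tuple(feats)
        self.version = version
        self._build_indices()

    # -- indices ---------------------------------------------------------
    def _build_indices(self) -> None:
        self._by_name: dict[str, FeatureDef] = {}
        self._name_codes: dict[str, FeatureDef] = {}
        self._icd: list[tuple[int, int, FeatureDef]] = []
        self._cpt: list[tuple[int, int, FeatureDef]] = []
        self._hcpcs: FeatureDef | None = None
        for f in self.features:
            if f.name.lower() in self._by_name:
                raise RegistryError(f"duplicate feature name {f.name!r}")
            self._by_name[f.name.lower()] = f
            for code in f.codes:
                code = code.strip()
                if code.lower() == HCPCS_SENTINEL:
                    if self._hcpcs is not None:
                        raise RegistryError("two rows claim HCPCS level II codes")
                    self._hcpcs = f
                    continue
                rng = _parse_range(code)
                if rng is None:
                    key = code.lower()
                    prev = self._name_codes.get(key)
                    if prev is not None and prev is not f:
                        raise RegistryError(
                            f"code {code!r} claimed by rows "
                            f"{prev.row_index} and {f.row_index}"
                        )
                    self._name_codes[key] = f
                else:
                    # ICD stems are <= 3 digits wide, CPT ranges 5 digits
                    target = self._cpt if len(code.split("-")[0].strip()) == 5 else self._icd
                    target.append((*rng, f))
        for table, label in ((self._icd, "ICD"), (self._cpt, "CPT")):
            table.sort(key=lambda t: t[0])
            for (lo1, hi1, f1), (lo2, hi2, f2) in zip(table, table[1:]):
                if lo2 <= hi1:
                    raise RegistryError(
                        f"overlapping {label} ranges: rows "
                        f"{f1.row_index} ({lo1}-{hi1}) and "
                        f"{f2.row_index} ({lo2}-{hi2})"
                    )

    # -- basic access ----------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.features)

    def row(self, row_index: int) -> FeatureDef:
        return self.features[row_index - 1]

    def by_name(self, name: str) -> FeatureDef:
        try:
            return self._by_name[name.lower()]
        except KeyError:
            raise UnknownCodeError(f"no feature named {name!r}") from None

    def rows_in_group(self, group: str) -> list[FeatureDef]:
        return [f for f in self.features if f.group == group]

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FeatureRegistry)
            and self.features == other.features
            and self.version == other.version
        )

    def __repr__(self) -> str:
        return f"FeatureRegistry(n={self.n_features}, version={self.version!r})"

    # -- code resolution -------------------------------------------------
    def lookup(self, code: str) -> FeatureDef:
        """Resolve a raw event code to the unique feature row owning it.

        Literal names (labs, vitals, symptom groups, "hospitalization")
        match case-insensitively.  ICD-9 codes match by the three-digit
        stem before the decimal point against the declared diagnosis
        ranges; five-digit numeric codes match the CPT ranges; a letter
        followed by four digits matches the HCPCS level II row.

        Raises :class:`UnknownCodeError` for anything unclaimed.
        """
        code = str(code).strip()
        hit = self._name_codes.get(code.lower())
        if hit is not None:
            return hit
        if _ICD_RE.match(code):
            stem = int(code.split(".", 1)[0])
            for lo, hi, f in self._icd:
                if lo <= stem <= hi:
                    return f
        elif _CPT_RE.match(code):
            v = int(code)
            for lo, hi, f in self._cpt:
                if lo <= v <= hi:
                    return f
        elif _HCPCS_RE.match(code) and self._hcpcs is not None:
            return self._hcpcs
        raise UnknownCodeError(f"code {code!r} is not claimed by any feature row")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "features": [f.to_dict() for f in self.features],
        }


# ---------------------------------------------------------------------------
# default 84-row registry
# ---------------------------------------------------------------------------

_MENTAL_SUBGROUPS = [
    # ICD-9 mental-disorders chapter (290-319), one level of detail below
    # the chapter, merged into 21 subgroups.
    ("dementias & other organic mental disorders", ["290", "293-294"]),
    ("alcohol-induced mental disorders", ["291"]),
    ("drug-induced mental disorders", ["292"]),
    ("schizophrenic disorders", ["295"]),
    ("episodic mood disorders", ["296"]),
    ("delusional disorders", ["297"]),
    ("other nonorganic psychoses", ["298"]),
    ("pervasive developmental disorders", ["299"]),
    ("anxiety & other neurotic disorders", ["300"]),
    ("personality disorders", ["301"]),
    ("sexual & gender identity disorders", ["302"]),
    ("alcohol dependence", ["303"]),
    ("drug dependence", ["304"]),
    ("nondependent drug abuse", ["305"]),
    ("physiological malfunction of psychogenic origin", ["306"]),
    ("special symptoms & syndromes", ["307"]),
    ("stress & adjustment reactions", ["308-309"]),
    ("nonpsychotic brain-damage disorders", ["310"]),
    ("depressive disorder, not elsewhere classified", ["311"]),
    ("conduct, emotional & hyperkinetic disturbances", ["312-314"]),
    ("developmental delays & intellectual disabilities", ["315-319"]),
]

_OTHER_CHAPTERS = [
    # remaining ICD-9 first-level chapters, in code order; with the
    # mental chapter expanded above, digestive lands on row 30
    ("infectious & parasitic diseases", ["001-139"]),
    ("neoplasms", ["140-239"]),
    ("endocrine, nutritional & metabolic diseases", ["240-279"]),
    ("diseases of blood & blood-forming organs", ["280-289"]),
    ("diseases of nervous system & sense organs", ["320-389"]),
    ("diseases of circulatory system", ["390-459"]),
    ("diseases of respiratory system", ["460-519"]),
    ("diseases of digestive system", ["520-579"]),
    ("diseases of genitourinary system", ["580-629"]),
    ("complications of pregnancy & childbirth", ["630-679"]),
    ("diseases of skin & subcutaneous tissue", ["680-709"]),
    ("diseases of musculoskeletal system", ["710-739"]),
    ("congenital anomalies", ["740-759"]),
    ("conditions originating in perinatal period", ["760-779"]),
    ("symptoms, signs & ill-defined conditions", ["780-799"]),
    ("injury & poisoning", ["800-999"]),
]

_CPT_GROUPS = [
    ("anesthesia", ["00100-01999"]),
    ("surgery", ["10000-69990"]),
    ("radiology", ["70000-79999"]),
    ("pathology and laboratory", ["80000-89999"]),
    ("medicine services", ["90281-99199", "99500-99607"]),
    ("evaluation and management", ["99201-99499"]),
    ("hcpcs level ii", [HCPCS_SENTINEL]),
]

_LABS = [
    # name, cohort-default mean and SD in conventional US units; the
    # mean/SD are overridden when a standardizer is fitted on a cohort
    ("glucose", 100.0, 25.0),
    ("hemoglobin", 14.0, 1.8),
    ("erythrocytes", 4.8, 0.6),
    ("creatinine", 1.0, 0.35),
    ("leukocytes", 7.5, 2.2),
    ("carbon dioxide", 25.0, 3.0),
    ("potassium", 4.2, 0.45),
    ("sodium", 140.0, 3.0),
    ("chloride", 102.0, 3.5),
    ("urea nitrogen", 15.0, 6.0),
]

_VITALS = [
    # name, normal range, extreme bounds (None = that side never scores);
    # clinically conventional adult values, fully overridable
    ("blood pressure", (90.0, 120.0), (50.0, 200.0)),
    ("pain score", (0.0, 1.0), (None, 10.0)),
    ("pulse rate", (60.0, 100.0), (30.0, 180.0)),
    ("body temperature", (36.1, 37.8), (34.0, 41.0)),
    ("bmi", (18.5, 25.0), (12.0, 45.0)),
]

_SYMPTOM_GROUPS = [
    # 24 symptom groups distilled from the depression, mania, sleep,
    # psychosis, movement-disorder and suicide-risk instruments; each
    # keyword is a lowercase whole-word (or phrase) trigger
    ("depressed mood", ["depressed mood", "depression", "sad mood", "hopeless", "tearful"]),
    ("anhedonia", ["anhedonia", "loss of interest", "loss of pleasure"]),
    ("guilt & worthlessness", ["guilt", "worthlessness", "self-blame"]),
    ("suicidal ideation", ["suicidal", "suicide", "self-harm", "self harm"]),
    ("insomnia", ["insomnia", "sleeplessness", "trouble sleeping", "difficulty sleeping"]),
    ("hypersomnia", ["hypersomnia", "oversleeping", "excessive sleep"]),
    ("decreased need for sleep", ["decreased need for sleep", "little sleep"]),
    ("fatigue & low energy", ["fatigue", "low energy", "tiredness", "lethargy"]),
    ("appetite or weight change", ["poor appetite", "appetite loss", "weight loss", "weight gain"]),
    ("anxiety", ["anxiety", "anxious", "panic", "worry"]),
    ("irritability", ["irritable", "irritability", "short-tempered"]),
    ("agitation", ["agitation", "agitated", "restless", "restlessness"]),
    ("elevated mood", ["euphoria", "euphoric", "elevated mood", "elated"]),
    ("grandiosity", ["grandiose", "grandiosity", "inflated self-esteem"]),
    ("racing thoughts", ["racing thoughts", "flight of ideas"]),
    ("pressured speech", ["pressured speech", "talkative", "rapid speech"]),
    ("increased activity", ["increased energy", "hyperactive", "increased activity", "goal-directed activity"]),
    ("distractibility", ["distractible", "distractibility", "poor concentration"]),
    ("impulsivity", ["impulsive", "impulsivity", "reckless", "risky behavior"]),
    ("hallucinations", ["hallucination", "hallucinations", "hearing voices"]),
    ("delusions & paranoia", ["delusion", "delusions", "paranoid", "paranoia"]),
    ("disorganized thinking", ["disorganized thinking", "thought disorder", "incoherent"]),
    ("psychomotor retardation", ["psychomotor retardation", "slowed movement", "slowness of thought"]),
    ("movement side effects", ["tremor", "akathisia", "rigidity", "dyskinesia"]),
]


def default_registry() -> FeatureRegistry:
    """Build the package's default 84-row feature registry."""
    feats: list[FeatureDef] = []
    row = 1
    feats.append(
        FeatureDef(row, "hospitalization", "hospitalization", "binary", ("hospitalization",))
    )
    row += 1
    for name, codes in _MENTAL_SUBGROUPS:
        feats.append(FeatureDef(row, name, "diagnosis_mental", "binary", tuple(codes)))
        row += 1
    for name, codes in _OTHER_CHAPTERS:
        feats.append(FeatureDef(row, name, "diagnosis_other", "binary", tuple(codes)))
        row += 1
    for name, codes in _CPT_GROUPS:
        feats.append(FeatureDef(row, name, "procedure_group", "binary", tuple(codes)))
        row += 1
    for name, mean, sd in _LABS:
        feats.append(
            FeatureDef(row, name, "lab", "graded", (name,), {"mean": mean, "sd": sd})
        )
        row += 1
    for name, normal, extreme in _VITALS:
        feats.append(
            FeatureDef(
                row,
                name,
                "vital",
                "graded",
                (name,),
                {"normal": list(normal), "extreme": list(extreme)},
            )
        )
        row += 1
    for name, keywords in _SYMPTOM_GROUPS:
        feats.append(
            FeatureDef(row, name, "symptom", "binary", (name,), {"keywords": keywords})
        )
        row += 1
    assert row - 1 == DEFAULT_N_FEATURES
    return FeatureRegistry(feats, version="default-84")


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_registry(registry: FeatureRegistry, path) -> None:
    """Write a registry to a YAML file (round-trips with load_registry)."""
    with open(path, "w") as fh:
        yaml.safe_dump(registry.to_dict(), fh, sort_keys=False, allow_unicode=True)


def load_registry(path, allow_incomplete: bool = False) -> FeatureRegistry:
    """Load a registry YAML file and validate its invariants.

    A registry whose size differs from the default 84 rows is rejected
    unless ``allow_incomplete=True`` (temporal images then take the
    registry's size as their feature dimension).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "features" not in doc:
        raise RegistryError(f"{path}: not a registry file (missing 'features')")
    feats = [FeatureDef.from_dict(d) for d in doc["features"]]
    reg = FeatureRegistry(feats, version=str(doc.get("version", "custom")))
    if reg.n_features != DEFAULT_N_FEATURES:
        if not allow_incomplete:
            raise RegistryError(
                f"{path}: registry has {reg.n_features} rows, expected "
                f"{DEFAULT_N_FEATURES}; pass allow_incomplete=True to accept"
            )
        warnings.warn(
            f"registry has {reg.n_features} rows (default is {DEFAULT_N_FEATURES})",
            stacklevel=2,
        )
    return reg


def shipped_registry_path():
    """Path of the YAML copy of the default registry shipped as package data."""
    return resources.files("phenoprint.data").joinpath("default_registry.yaml")
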
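"""Canonical patient record, feature set and cohort containers.

The record schema mirrors the variables a rheumatology classification
work-up documents: demographics, disease chronology, tri-state clinical and
immunologic feature flags, the ANA titer as an ordered categorical, and the
expert reference diagnosis used as the gold standard.

Tri-state flags are encoded as ``True`` (present), ``False`` (absent) and
``None`` (unknown / not documented).  Every criteria engine treats
``unknown`` as ``absent``; the distinct state exists so that real data can
be audited for missingness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, Mapping, Optional

import pandas as pd

TriState = Optional[bool]

#: Canonical feature flags, in serialization order.
FEATURES: tuple[str, ...] = (
    "acute_cutaneous",        # malar or maculopapular rash
    "subacute_cutaneous",     # annular / papulosquamous lupus rash
    "chronic_cutaneous",      # discoid lupus
    "photosensitivity",
    "oral_nasal_ulcers",
    "alopecia",               # non-scarring
    "arthritis",              # non-erosive joint involvement / synovitis
    "serositis_pleural",
    "serositis_pericardial",
    "proteinuria",            # > 0.5 g / 24 h or cellular casts
    "lupus_nephritis_biopsy",  # biopsy-proven LN; histologic class in ln_class
    "seizure",
    "psychosis",
    "delirium",               # acute confusional state
    "other_neuro",            # myelitis, mononeuritis, peripheral neuropathy...
    "hemolytic_anemia",
    "leukopenia",
    "lymphopenia",
    "thrombocytopenia",
    "fever",                  # unexplained fever
    "ana_positive",
    "anti_dsdna",
    "anti_sm",
    "antiphospholipid",       # any of LA, aCL IgM/IgG, anti-beta2GPI IgM/IgG
    "low_c3",
    "low_c4",
    "coombs_positive",        # direct antiglobulin test
)

#: Ordered ANA titer scale; comparisons are positional on this list.
ANA_TITER_LEVELS: tuple[str, ...] = (
    "negative", "1:80", "1:160", "1:320", "1:640", "1:1280",
)

LN_CLASSES: tuple[str, ...] = ("II_V", "III_IV")

SEXES: tuple[str, ...] = ("female", "male")

EARLY_DISEASE_MAX_DURATION = 1.0  # years, inclusive


class CohortSchemaError(ValueError):
    """A cohort file/table does not conform to the expected schema."""


class CohortValidationError(ValueError):
    """A cohort file/table parsed but carries invalid values."""


@dataclass(frozen=True)
class FeatureSet:
    """Tri-state clinical/immunologic feature flags for one patient.

    Parameters
    ----------
    flags
        Mapping of feature name to tri-state value.  Features omitted from
        the mapping default to absent (``False``).
    ln_class
        Histologic class of biopsy-proven lupus nephritis: ``"II_V"``,
        ``"III_IV"`` or ``None`` (not recorded / no biopsy).
    attribution_exceptions
        Features whose presence IS better explained by an alternative
        diagnosis (infection, drug reaction, ...).  Attribution gates the
        weighted engines only; the default is that every present feature is
        attributable.
    """

    flags: Mapping[str, TriState] = field(default_factory=dict)
    ln_class: Optional[str] = None
    attribution_exceptions: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        unknown = set(self.flags) - set(FEATURES)
        if unknown:
            raise CohortValidationError(f"unknown feature flags: {sorted(unknown)}")
        if self.ln_class is not None and self.ln_class not in LN_CLASSES:
            raise CohortValidationError(f"invalid lupus-nephritis class {self.ln_class!r}")
        bad = set(self.attribution_exceptions) - set(FEATURES)
        if bad:
            raise CohortValidationError(f"attribution exceptions name unknown features: {sorted(bad)}")
        object.__setattr__(self, "flags", dict(self.flags))
        object.__setattr__(self, "attribution_exceptions", frozenset(self.attribution_exceptions))

    @classmethod
    def from_present(cls, present: Iterable[str], *, ln_class: Optional[str] = None,
                     unattributable: Iterable[str] = ()) -> "FeatureSet":
        """Build a feature set where ``present`` are present and all other flags absent."""
        return cls(flags={f: (f in set(present)) for f in FEATURES},
                   ln_class=ln_class, attribution_exceptions=frozenset(unattributable))

    def state(self, name: str) -> TriState:
        if name not in FEATURES:
            raise KeyError(name)
        return self.flags.get(name, False)

    def present(self, name: str) -> bool:
        """True iff the flag is documented present (unknown counts as absent)."""
        return self.state(name) is True

    def attributable(self, name: str) -> bool:
        """True iff present and not better explained by an alternative diagnosis."""
        return self.present(name) and name not in self.attribution_exceptions

    def with_flag(self, name: str, value: TriState) -> "FeatureSet":
        flags = dict(self.flags)
        flags[name] = value
        return replace(self, flags=flags)


@dataclass(frozen=True)
class PatientRecord:
    """One participant: demographics, chronology, features and reference label."""

    patient_id: str
    reference_sle: bool
    sex: str
    age_at_enrollment: float
    age_at_onset: float
    disease_duration: float
    features: FeatureSet
    ana_titer: str = "unknown"
    site_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise CohortValidationError(f"{self.patient_id}: sex must be one of {SEXES}, got {self.sex!r}")
        if self.disease_duration < 0:
            raise CohortValidationError(f"{self.patient_id}: disease_duration < 0")
        # allow sub-year rounding slack between onset age and enrollment age
        if self.age_at_onset > self.age_at_enrollment + 1e-9:
            raise CohortValidationError(f"{self.patient_id}: age_at_onset exceeds age_at_enrollment")
        if self.ana_titer != "unknown" and self.ana_titer not in ANA_TITER_LEVELS:
            raise CohortValidationError(
                f"{self.patient_id}: unparsable ANA titer {self.ana_titer!r} "
                f"(expected one of {ANA_TITER_LEVELS} or 'unknown')")

    @property
    def early_disease(self) -> bool:
        """Disease duration of at most one year from the first symptom."""
        return self.disease_duration <= EARLY_DISEASE_MAX_DURATION

    def ana_titer_at_least(self, level: str) -> bool:
        """Positional comparison on the ordered titer scale; unknown/negative fail."""
        if self.ana_titer in ("unknown", "negative"):
            return False
        return ANA_TITER_LEVELS.index(self.ana_titer) >= ANA_TITER_LEVELS.index(level)


@dataclass
class Cohort:
    """Ordered collection of patient records with provenance metadata."""

    records: list[PatientRecord]
    provenance: dict = field(default_factory=lambda: {"source": "file"})

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate patient_id values: {dupes[:5]}")
        if self.records:
            n_cases = sum(r.reference_sle for r in self.records)
            if n_cases in (0, len(self.records)):
                warnings.warn("cohort contains a single reference class", stacklevel=2)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    @property
    def n_cases(self) -> int:
        return sum(r.reference_sle for r in self.records)

    @property
    def n_controls(self) -> int:
        return len(self.records) - self.n_cases

    def reference(self) -> pd.Series:
        """Reference diagnosis as a boolean Series indexed by patient_id."""
        return pd.Series([r.reference_sle for r in self.records],
                         index=self.ids, name="reference_sle", dtype=bool)

    def feature_matrix(self) -> pd.DataFrame:
        """Binary 0/1 feature matrix (present = 1, absent/unknown = 0)."""
        rows = [[int(r.features.present(f)) for f in FEATURES] for r in self.records]
        return pd.DataFrame(rows, index=self.ids, columns=list(FEATURES), dtype=int)


# ---------------------------------------------------------------------------
# Named subgroup filters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Filter:
    predicate: Callable[[PatientRecord], bool]
    case_attribute: bool  # if True the filter describes cases; controls kept by default


def _duration_filter(lo: float, hi: float) -> Callable[[PatientRecord], bool]:
    return lambda r: lo < r.disease_duration <= hi


_FILTERS: dict[str, _Filter] = {
    "early_disease": _Filter(lambda r: r.early_disease, True),
    "established": _Filter(lambda r: not r.early_disease, True),
    "duration:<=1": _Filter(_duration_filter(-1.0, 1.0), True),
    "duration:1-5": _Filter(_duration_filter(1.0, 5.0), True),
    "duration:>5": _Filter(_duration_filter(5.0, float("inf")), True),
    "sex:female": _Filter(lambda r: r.sex == "female", False),
    "sex:male": _Filter(lambda r: r.sex == "male", False),
}


def registered_filters() -> list[str]:
    return sorted(_FILTERS) + ["feature:<name>"]


def subset(cohort: Cohort, predicate: str, keep_controls: Optional[bool] = None) -> Cohort:
    """Return the sub-cohort selected by a named filter.

    Case-attribute filters (``early_disease``, duration strata,
    ``feature:<name>`` organ involvement) restrict the cases only and, by
    default, keep every control — the convention used when evaluating
    subgroup sensitivity against the full control panel.  Pass
    ``keep_controls=False`` to drop controls instead.  Demographic filters
    (``sex:*``) apply to cases and controls alike.
    """
    if predicate.startswith("feature:"):
        fname = predicate.split(":", 1)[1]
        if fname not in FEATURES:
            raise KeyError(f"unknown feature in predicate {predicate!r}")
        filt = _Filter(lambda r: r.features.present(fname), True)
    elif predicate in _FILTERS:
        filt = _FILTERS[predicate]
    else:
        raise KeyError(f"unknown predicate {predicate!r}; registered: {registered_filters()}")

    if filt.case_attribute:
        keep = True if keep_controls is None else keep_controls
        records = [r for r in cohort.records
                   if (filt.predicate(r) if r.reference_sle else keep)]
    else:
        records = [r for r in cohort.records if filt.predicate(r)]

    if not records:
        warnings.warn(f"predicate {predicate!r} matched no records", stacklevel=2)
    prov = dict(cohort.provenance)
    prov["subset"] = prov.get("subset", []) + [predicate]
    return Cohort(records=records, provenance=prov)
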
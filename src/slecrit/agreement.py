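"""Between-system agreement: NRI, exact combination counts, missed-case sets.

Net reclassification improvement (binary, two-category) quantifies what a
new classifier adds over an old one against the reference diagnosis:

    NRI_events     = (cases reclassified up - cases reclassified down) / n_cases
    NRI_non-events = (controls reclassified down - controls reclassified up) / n_controls
    NRI_total      = NRI_events + NRI_non-events

"Up" means old-negative and new-positive.  Among cases, up is beneficial;
among controls, up is harmful (a new false positive) and down beneficial.
Positive totals favor the new classifier.

Combination counts use exact-pattern (UpSet) semantics: a patient counts
toward the one subset of systems that classified them, not toward every
subset it intersects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import FEATURES, Cohort


@dataclass(frozen=True)
class NRIResult:
    comparator: str
    cases_up: int
    cases_down: int
    controls_up: int
    controls_down: int
    n_cases: int
    n_controls: int

    @property
    def nri_events(self) -> float:
        return (self.cases_up - self.cases_down) / self.n_cases

    @property
    def nri_nonevents(self) -> float:
        return (self.controls_down - self.controls_up) / self.n_controls

    @property
    def nri_total(self) -> float:
        return self.nri_events + self.nri_nonevents

    def as_row(self) -> dict:
        """Table row with proportions (3 dp) and percents (1 dp) as rendered."""
        return {
            "comparison": self.comparator,
            "nri_events": round(self.nri_events, 3),
            "nri_events_pct": round(100 * self.nri_events, 1),
            "nri_nonevents": round(self.nri_nonevents, 3),
            "nri_nonevents_pct": round(100 * self.nri_nonevents, 1),
            "nri_total": round(self.nri_total, 3),
            "nri_total_pct": round(100 * self.nri_total, 1),
            "cases_up": self.cases_up, "cases_down": self.cases_down,
            "controls_up": self.controls_up, "controls_down": self.controls_down,
            "n_cases": self.n_cases, "n_controls": self.n_controls,
        }


def nri_from_counts(cases_up: int, cases_down: int, controls_up: int, controls_down: int,
                    n_cases: int, n_controls: int, comparator: str = "") -> NRIResult:
    """Build an NRIResult directly from reclassification counts."""
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("n_cases and n_controls must be positive")
    if cases_up + cases_down > n_cases or controls_up + controls_down > n_controls:
        raise ValueError("reclassification counts exceed group sizes")
    return NRIResult(comparator=comparator, cases_up=cases_up, cases_down=cases_down,
                     controls_up=controls_up, controls_down=controls_down,
                     n_cases=n_cases, n_controls=n_controls)


def nri(new: Sequence[bool], old: Sequence[bool], reference: Sequence[bool],
        comparator: str = "") -> NRIResult:
    """Two-category NRI of classifier ``new`` versus classifier ``old``."""
    new = np.asarray(new, dtype=bool)
    old = np.asarray(old, dtype=bool)
    ref = np.asarray(reference, dtype=bool)
    if not (new.shape == old.shape == ref.shape):
        raise ValueError("length mismatch")
    n_cases = int(ref.sum())
    n_controls = int((~ref).sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError("NRI requires both cases and controls")
    up = ~old & new
    down = old & ~new
    return NRIResult(
        comparator=comparator,
        cases_up=int(np.sum(up & ref)), cases_down=int(np.sum(down & ref)),
        controls_up=int(np.sum(up & ~ref)), controls_down=int(np.sum(down & ~ref)),
        n_cases=n_cases, n_controls=n_controls)


# ---------------------------------------------------------------------------
# Exact-pattern (UpSet) combination counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CombinationCounts:
    """Exact-pattern counts over subsets of systems, among reference-positive patients."""

    systems: tuple[str, ...]
    counts: dict  # frozenset[str] -> int; the empty frozenset is the none-count
    n_total: int

    @property
    def none_count(self) -> int:
        return self.counts.get(frozenset(), 0)

    def share(self, pattern: Sequence[str]) -> float:
        return self.counts.get(frozenset(pattern), 0) / self.n_total

    def ordered(self) -> list[tuple[frozenset, int]]:
        """Patterns sorted by descending count, then lexicographic membership."""
        return sorted(self.counts.items(),
                      key=lambda kv: (-kv[1], tuple(sorted(kv[0]))))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pattern, count in self.ordered():
            row = {s: (s in pattern) for s in self.systems}
            row["pattern"] = "+".join(s for s in self.systems if s in pattern) or "(none)"
            row["count"] = count
            row["share_pct"] = 100.0 * count / self.n_total if self.n_total else np.nan
            rows.append(row)
        return pd.DataFrame(rows, columns=["pattern", *self.systems, "count", "share_pct"])


def combination_counts(class_bool: pd.DataFrame,
                       reference: Optional[Sequence[bool]] = None) -> CombinationCounts:
    """Count patients by the exact subset of systems that classified them.

    ``class_bool`` is a boolean patient x system frame.  When ``reference``
    is given, counting is restricted to reference-positive patients (the
    case-side UpSet of the analysis); pass the complement to study control-
    side specificity concordance.
    """
    systems = tuple(class_bool.columns)
    mat = class_bool.to_numpy(dtype=bool)
    if reference is not None:
        ref = np.asarray(reference, dtype=bool)
        if ref.shape[0] != mat.shape[0]:
            raise ValueError("length mismatch")
        mat = mat[ref]
    counts: dict = {}
    for row in mat:
        pattern = frozenset(s for s, v in zip(systems, row) if v)
        counts[pattern] = counts.get(pattern, 0) + 1
    return CombinationCounts(systems=systems, counts=counts, n_total=int(mat.shape[0]))


# ---------------------------------------------------------------------------
# Missed-case sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MissSets:
    systems: tuple[str, ...]
    miss_sets: dict            # system -> frozenset of case ids
    overlap: pd.DataFrame      # pairwise |miss_i intersect miss_j|
    multiplicity: pd.Series    # case id -> number of systems missing it (0..4)
    feature_frequency: pd.DataFrame  # per-system feature prevalence among missed cases

    def missed_by_any(self) -> frozenset:
        out: set = set()
        for s in self.miss_sets.values():
            out |= s
        return frozenset(out)

    def slerpi_subset_of_others(self, system: str = "slerpi") -> bool:
        """True iff every case missed by ``system`` is missed by another system too."""
        others: set = set()
        for s, ids in self.miss_sets.items():
            if s != system:
                others |= ids
        return self.miss_sets[system] <= others


def miss_analysis(class_bool: pd.DataFrame, reference: Sequence[bool],
                  cohort: Optional[Cohort] = None) -> MissSets:
    """Missed-case sets, overlaps and multiplicity; feature frequencies when a cohort is given."""
    systems = tuple(class_bool.columns)
    ref = np.asarray(reference, dtype=bool)
    case_ids = [pid for pid, r in zip(class_bool.index, ref) if r]
    case_df = class_bool.loc[case_ids]
    miss_sets = {s: frozenset(case_df.index[~case_df[s]]) for s in systems}
    overlap = pd.DataFrame(
        [[len(miss_sets[a] & miss_sets[b]) for b in systems] for a in systems],
        index=list(systems), columns=list(systems), dtype=int)
    multiplicity = pd.Series(
        {pid: sum(pid in miss_sets[s] for s in systems) for pid in case_ids},
        name="miss_multiplicity", dtype=int)

    if cohort is not None:
        fm = cohort.feature_matrix()
        rows = {}
        for s in systems:
            ids = sorted(miss_sets[s])
            rows[s] = fm.loc[ids].mean() * 100.0 if ids else pd.Series(
                np.nan, index=list(FEATURES))
        feature_frequency = pd.DataFrame(rows).T
        feature_frequency.index.name = "system"
    else:
        feature_frequency = pd.DataFrame(index=list(systems), columns=list(FEATURES),
                                         dtype=float)
    return MissSets(systems=systems, miss_sets=miss_sets, overlap=overlap,
                    multiplicity=multiplicity, feature_frequency=feature_frequency)
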
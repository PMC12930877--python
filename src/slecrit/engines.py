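"""The four SLE classification/diagnostic rule engines.

Each engine is a pure function from :class:`~slecrit.records.PatientRecord`
to :class:`CriterionResult`, exposing both a continuous score (item count
for ACR-1997/SLICC-2012, weighted total for EULAR/ACR-2019 and SLERPI) and
the binary classification.  Item lists, weights and thresholds live in
shipped YAML weight tables (one file per system) and are validated at load;
the engines read only those tables, so transcription corrections require no
code change.

Rule summaries
--------------
ACR-1997
    Eleven criteria, classification at >= 4 satisfied.
SLICC-2012
    Seventeen criteria (11 clinical + 6 immunologic); classification at
    >= 4 satisfied including >= 1 clinical and >= 1 immunologic, or
    biopsy-proven lupus nephritis with ANA or anti-dsDNA.
EULAR/ACR-2019
    Obligatory entry criterion ANA titer >= 1:80; additive weighted score
    where each domain contributes only its highest-weighted satisfied item;
    classification at total >= 10 with at least one clinical-domain item.
SLERPI
    Fourteen weighted items (total range 0-14); classification at >= 7.

Attribution (the "not better explained by an alternative diagnosis" gate)
applies to the weighted rules (EULAR/ACR-2019, SLERPI) only; unknown flags
are treated as absent everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Callable, Optional, Union

import pandas as pd
import yaml

from .records import Cohort, FeatureSet, PatientRecord

SYSTEMS: tuple[str, ...] = ("acr1997", "slicc2012", "eular_acr2019", "slerpi")

_CONFIG_FILES = {
    "acr1997": "acr1997.yaml",
    "slicc2012": "slicc2012.yaml",
    "eular_acr2019": "eular_acr2019.yaml",
    "slerpi": "slerpi.yaml",
}


class WeightTableError(ValueError):
    """A weight-table config is structurally invalid."""


@dataclass(frozen=True)
class ItemDef:
    name: str
    test: Callable[[PatientRecord, bool], bool]  # (record, gate_attribution) -> satisfied
    weight: float = 1.0
    category: Optional[str] = None  # clinical | immunologic
    domain: Optional[str] = None


@dataclass(frozen=True)
class WeightTable:
    system: str
    label: str
    rule: str
    threshold: float
    items: tuple[ItemDef, ...]
    attribution_gated: bool = False
    entry: Optional[str] = None
    require_clinical: bool = False
    max_score: Optional[float] = None
    coombs_requires_no_hemolysis: bool = False


@dataclass(frozen=True)
class CriterionResult:
    """One engine's verdict on one patient."""

    system: str
    score: float
    classified: bool
    item_breakdown: tuple[tuple[str, bool, float], ...] = ()
    entry_failed: bool = False

    def contributed_total(self) -> float:
        return sum(w for _, _, w in self.item_breakdown)


# ---------------------------------------------------------------------------
# Item predicate compilation
# ---------------------------------------------------------------------------

def _any_of_test(features: tuple[str, ...]) -> Callable[[PatientRecord, bool], bool]:
    def test(record: PatientRecord, gated: bool) -> bool:
        fs = record.features
        if gated:
            return any(fs.attributable(f) for f in features)
        return any(fs.present(f) for f in features)
    return test


def _special_test(name: str, table_cfg: dict) -> Callable[[PatientRecord, bool], bool]:
    if name == "coombs":
        conditional = bool(table_cfg.get("coombs_requires_no_hemolysis", False))

        def test(record: PatientRecord, gated: bool) -> bool:
            fs = record.features
            ok = fs.attributable("coombs_positive") if gated else fs.present("coombs_positive")
            if conditional:
                ok = ok and not fs.present("hemolytic_anemia")
            return ok
        return test
    if name in ("ln_class_II_V", "ln_class_III_IV"):
        wanted = "III_IV" if name.endswith("III_IV") else "II_V"

        def test(record: PatientRecord, gated: bool) -> bool:
            fs = record.features
            ok = fs.attributable("lupus_nephritis_biopsy") if gated else fs.present("lupus_nephritis_biopsy")
            if not ok:
                return False
            cls = fs.ln_class
            if cls is None:  # unrecorded class scores as the lower biopsy item
                cls = "II_V"
            return cls == wanted
        return test
    if name in ("low_c3_or_c4", "low_c3_and_c4"):
        both = name == "low_c3_and_c4"

        def test(record: PatientRecord, gated: bool) -> bool:
            fs = record.features
            c3 = fs.attributable("low_c3") if gated else fs.present("low_c3")
            c4 = fs.attributable("low_c4") if gated else fs.present("low_c4")
            return (c3 and c4) if both else (c3 or c4)
        return test
    raise WeightTableError(f"unknown special predicate {name!r}")


def _compile_item(spec: dict, table_cfg: dict, domain: Optional[str] = None,
                  category: Optional[str] = None) -> ItemDef:
    name = spec.get("name")
    if not name:
        raise WeightTableError(f"item without a name: {spec}")
    weight = float(spec.get("weight", 1.0))
    if weight <= 0:
        raise WeightTableError(f"item {name}: weight must be positive")
    if "any_of" in spec:
        feats = tuple(spec["any_of"])
        from .records import FEATURES
        bad = set(feats) - set(FEATURES)
        if bad:
            raise WeightTableError(f"item {name}: unknown features {sorted(bad)}")
        test = _any_of_test(feats)
    elif "predicate" in spec:
        test = _special_test(spec["predicate"], table_cfg)
    else:
        raise WeightTableError(f"item {name}: needs any_of or predicate")
    return ItemDef(name=name, test=test, weight=weight,
                   category=spec.get("category", category), domain=domain)


def load_weight_table(source: Union[str, Path]) -> WeightTable:
    """Load and validate a weight table from a shipped system name or a YAML path."""
    if isinstance(source, str) and source in _CONFIG_FILES:
        text = resources.files("slecrit.configs").joinpath(_CONFIG_FILES[source]).read_text("utf-8")
    else:
        text = Path(source).read_text(encoding="utf-8")
    cfg = yaml.safe_load(text)
    rule = cfg.get("rule")
    if rule not in ("count", "slicc", "weighted_domains", "weighted_sum"):
        raise WeightTableError(f"unknown rule {rule!r}")
    items: list[ItemDef] = []
    if rule == "weighted_domains":
        for dom in cfg["domains"]:
            for spec in dom["items"]:
                items.append(_compile_item(spec, cfg, domain=dom["name"],
                                           category=dom.get("category")))
    else:
        for spec in cfg["items"]:
            items.append(_compile_item(spec, cfg))
    table = WeightTable(
        system=cfg["system"], label=cfg.get("label", cfg["system"]), rule=rule,
        threshold=float(cfg["threshold"]), items=tuple(items),
        attribution_gated=bool(cfg.get("attribution_gated", False)),
        entry=cfg.get("entry"), require_clinical=bool(cfg.get("require_clinical", False)),
        max_score=cfg.get("max_score"),
        coombs_requires_no_hemolysis=bool(cfg.get("coombs_requires_no_hemolysis", False)),
    )
    if table.system == "slerpi":
        total = sum(i.weight for i in table.items)
        if table.max_score is not None and abs(total - float(table.max_score)) > 1e-9:
            raise WeightTableError(
                f"SLERPI weights sum to {total}, declared max {table.max_score}")
    return table


@lru_cache(maxsize=None)
def default_table(system: str) -> WeightTable:
    if system not in _CONFIG_FILES:
        raise KeyError(f"unknown system {system!r}; known: {SYSTEMS}")
    return load_weight_table(system)


# ---------------------------------------------------------------------------
# Engines
# ---------------------------------------------------------------------------

def _count_rule(record: PatientRecord, table: WeightTable) -> CriterionResult:
    gated = table.attribution_gated
    breakdown = []
    for item in table.items:
        sat = item.test(record, gated)
        breakdown.append((item.name, sat, 1.0 if sat else 0.0))
    score = float(sum(1 for _, s, _ in breakdown if s))
    return CriterionResult(system=table.system, score=score,
                           classified=score >= table.threshold,
                           item_breakdown=tuple(breakdown))


def score_acr1997(record: PatientRecord, table: Optional[WeightTable] = None) -> CriterionResult:
    """ACR-1997: count of the 11 criteria; classified at >= 4."""
    return _count_rule(record, table or default_table("acr1997"))


def score_slicc2012(record: PatientRecord, table: Optional[WeightTable] = None) -> CriterionResult:
    """SLICC-2012 count rule with clinical/immunologic balance and nephritis shortcut."""
    table = table or default_table("slicc2012")
    gated = table.attribution_gated
    breakdown = []
    n_clin = n_imm = 0
    for item in table.items:
        sat = item.test(record, gated)
        breakdown.append((item.name, sat, 1.0 if sat else 0.0))
        if sat:
            if item.category == "clinical":
                n_clin += 1
            elif item.category == "immunologic":
                n_imm += 1
    score = float(n_clin + n_imm)
    fs = record.features
    shortcut = fs.present("lupus_nephritis_biopsy") and (
        fs.present("ana_positive") or fs.present("anti_dsdna"))
    classified = (score >= table.threshold and n_clin >= 1 and n_imm >= 1) or shortcut
    return CriterionResult(system=table.system, score=score, classified=classified,
                           item_breakdown=tuple(breakdown))


def score_eularacr2019(record: PatientRecord, table: Optional[WeightTable] = None) -> CriterionResult:
    """EULAR/ACR-2019 weighted-domain rule with the ANA >= 1:80 entry criterion.

    Within each domain only the maximum satisfied weight contributes; the
    breakdown therefore carries a non-zero contributed weight only for the
    item realizing the domain maximum (ties -> first in table order), so
    that the score equals the breakdown sum exactly.
    """
    table = table or default_table("eular_acr2019")
    if not record.ana_titer_at_least("1:80"):
        breakdown = tuple((i.name, False, 0.0) for i in table.items)
        return CriterionResult(system=table.system, score=0.0, classified=False,
                               item_breakdown=breakdown, entry_failed=True)
    gated = table.attribution_gated
    satisfied: dict[str, bool] = {}
    domains: dict[str, list[ItemDef]] = {}
    for item in table.items:
        satisfied[item.name] = item.test(record, gated)
        domains.setdefault(item.domain or item.name, []).append(item)
    contributed: dict[str, float] = {i.name: 0.0 for i in table.items}
    clinical_contributes = False
    score = 0.0
    for dom_items in domains.values():
        best: Optional[ItemDef] = None
        for item in dom_items:
            if satisfied[item.name] and (best is None or item.weight > best.weight):
                best = item
        if best is not None:
            contributed[best.name] = best.weight
            score += best.weight
            if best.category == "clinical":
                clinical_contributes = True
    classified = score >= table.threshold and (clinical_contributes or not table.require_clinical)
    breakdown = tuple((i.name, satisfied[i.name], contributed[i.name]) for i in table.items)
    return CriterionResult(system=table.system, score=score, classified=classified,
                           item_breakdown=breakdown)


def score_slerpi(record: PatientRecord, table: Optional[WeightTable] = None) -> CriterionResult:
    """SLERPI weighted sum over 14 attributable items; classified at >= 7."""
    table = table or default_table("slerpi")
    gated = table.attribution_gated
    breakdown = []
    score = 0.0
    for item in table.items:
        sat = item.test(record, gated)
        w = item.weight if sat else 0.0
        score += w
        breakdown.append((item.name, sat, w))
    return CriterionResult(system=table.system, score=score,
                           classified=score >= table.threshold,
                           item_breakdown=tuple(breakdown))


_ENGINES: dict[str, Callable[[PatientRecord, Optional[WeightTable]], CriterionResult]] = {
    "acr1997": score_acr1997,
    "slicc2012": score_slicc2012,
    "eular_acr2019": score_eularacr2019,
    "slerpi": score_slerpi,
}


def score(record: PatientRecord, system: str,
          table: Optional[WeightTable] = None) -> CriterionResult:
    """Score one record under one named system."""
    try:
        return _ENGINES[system](record, table)
    except KeyError:
        raise KeyError(f"unknown system {system!r}; known: {SYSTEMS}") from None


def classify_all(cohort: Cohort, systems: tuple[str, ...] = SYSTEMS) -> pd.DataFrame:
    """Classify every patient under every system.

    Returns a DataFrame indexed by patient_id with, per system, a
    ``<system>_score`` and boolean ``<system>_classified`` column, plus the
    ``reference_sle`` label.  Per-patient results are order-independent.
    """
    cols: dict[str, list] = {f"{s}_{k}": [] for s in systems for k in ("score", "classified")}
    for r in cohort.records:
        for s in systems:
            res = _ENGINES[s](r, None)
            cols[f"{s}_score"].append(res.score)
            cols[f"{s}_classified"].append(res.classified)
    df = pd.DataFrame(cols, index=pd.Index(cohort.ids, name="patient_id"))
    for s in systems:
        df[f"{s}_classified"] = df[f"{s}_classified"].astype(bool)
    df["reference_sle"] = [r.reference_sle for r in cohort.records]
    return df


def classification_columns(class_df: pd.DataFrame,
                           systems: tuple[str, ...] = SYSTEMS) -> pd.DataFrame:
    """Boolean patient x system classification matrix from classify_all output."""
    return class_df[[f"{s}_classified" for s in systems]].rename(
        columns={f"{s}_classified": s for s in systems}).astype(bool)
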
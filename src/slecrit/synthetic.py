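"""Seeded synthetic cohorts with a realistic two-group statistical structure.

The generator draws, per group (SLE cases vs other-rheumatic-disease
controls), demographics and a vector of Bernoulli feature flags whose
marginal prevalences are configured per feature and per group.  Features
are correlated through a single standard-normal latent severity variable
per patient, combined with independent noise in a Gaussian copula,

    s_if = c * z_i + sqrt(1 - c^2) * eps_if,        present iff s_if > -PHI^-1(p_f),

so the marginal prevalence equals ``p_f`` exactly for every coupling
``c`` in [0, 1], and ``c = 0`` recovers independent features.

Disease duration is log-normal per group; when ``early_case_fraction`` is
set, that fraction of cases is drawn from the duration distribution
conditional on <= 1 year (inverse-CDF stratified sampling), pinning the
early-disease subgroup size by construction.

Everything is deterministic given the seed: identical config + seed yields
a byte-identical cohort file.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import yaml
from scipy import stats

from .records import (
    ANA_TITER_LEVELS,
    EARLY_DISEASE_MAX_DURATION,
    FEATURES,
    Cohort,
    FeatureSet,
    PatientRecord,
)


class ConfigError(ValueError):
    """Invalid synthetic-cohort configuration."""


@dataclass(frozen=True)
class CohortConfig:
    n_cases: int
    n_controls: int
    feature_prevalence: Mapping[str, tuple[float, float]]  # feature -> (case, control)
    female_fraction: tuple[float, float] = (0.934, 0.783)
    onset_age: tuple[tuple[float, float], tuple[float, float]] = ((25.7, 8.5), (33.8, 10.8))
    duration_lognormal: tuple[tuple[float, float], tuple[float, float]] = ((1.246, 1.207), (1.876, 0.727))
    early_case_fraction: Optional[float] = None
    ln_class_iii_iv_fraction: float = 0.6
    ana_titer_given_positive: tuple[Mapping[str, float], Mapping[str, float]] = (
        {"1:160": 0.5, "1:320": 0.5}, {"1:80": 0.5, "1:160": 0.5})
    coupling: float = 0.0
    seed: int = 0
    raw: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ConfigError("counts must be >= 0")
        if not 0.0 <= self.coupling <= 1.0:
            raise ConfigError("coupling must lie in [0, 1]")
        for name, (pc, p0) in self.feature_prevalence.items():
            if name not in FEATURES:
                raise ConfigError(f"unknown feature {name!r}")
            if not (0.0 <= pc <= 1.0 and 0.0 <= p0 <= 1.0):
                raise ConfigError(f"{name}: prevalence outside [0, 1]")
        for f in self.female_fraction:
            if not 0.0 <= f <= 1.0:
                raise ConfigError("female fractions must lie in [0, 1]")
        if self.early_case_fraction is not None and not 0.0 <= self.early_case_fraction <= 1.0:
            raise ConfigError("early_case_fraction must lie in [0, 1]")
        for dist in self.ana_titer_given_positive:
            bad = set(dist) - set(ANA_TITER_LEVELS)
            if bad or abs(sum(dist.values()) - 1.0) > 1e-6:
                raise ConfigError("titer distribution must use known levels and sum to 1")

    @classmethod
    def from_dict(cls, cfg: dict) -> "CohortConfig":
        feats = {name: (float(v["case"]), float(v["control"]))
                 for name, v in cfg.get("features", {}).items()}
        oa = cfg.get("onset_age", {})
        dl = cfg.get("duration_lognormal", {})
        ff = cfg.get("female_fraction", {})
        titer = cfg.get("ana_titer_given_positive", {})
        kwargs: dict = dict(
            n_cases=int(cfg["n_cases"]), n_controls=int(cfg["n_controls"]),
            feature_prevalence=feats,
            coupling=float(cfg.get("coupling", 0.0)),
            seed=int(cfg.get("seed", 0)),
            early_case_fraction=cfg.get("early_case_fraction"),
            ln_class_iii_iv_fraction=float(cfg.get("ln_class_iii_iv_fraction", 0.6)),
            raw=cfg,
        )
        if ff:
            kwargs["female_fraction"] = (float(ff["case"]), float(ff["control"]))
        if oa:
            kwargs["onset_age"] = ((float(oa["case"]["mean"]), float(oa["case"]["sd"])),
                                   (float(oa["control"]["mean"]), float(oa["control"]["sd"])))
        if dl:
            kwargs["duration_lognormal"] = ((float(dl["case"]["mu"]), float(dl["case"]["sigma"])),
                                            (float(dl["control"]["mu"]), float(dl["control"]["sigma"])))
        if titer:
            kwargs["ana_titer_given_positive"] = (dict(titer["case"]), dict(titer["control"]))
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "CohortConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))

    @classmethod
    def default(cls, **overrides) -> "CohortConfig":
        """The shipped default profile, optionally with field overrides."""
        text = resources.files("slecrit.configs").joinpath("cohort_default.yaml").read_text("utf-8")
        cfg = cls.from_dict(yaml.safe_load(text))
        if overrides:
            import dataclasses
            cfg = dataclasses.replace(cfg, **overrides)
        return cfg

    def config_hash(self) -> str:
        payload = {
            "n_cases": self.n_cases, "n_controls": self.n_controls,
            "features": {k: list(v) for k, v in sorted(self.feature_prevalence.items())},
            "female_fraction": list(self.female_fraction),
            "onset_age": [list(x) for x in self.onset_age],
            "duration_lognormal": [list(x) for x in self.duration_lognormal],
            "early_case_fraction": self.early_case_fraction,
            "ln_class_iii_iv_fraction": self.ln_class_iii_iv_fraction,
            "ana_titer_given_positive": [dict(sorted(d.items())) for d in self.ana_titer_given_positive],
            "coupling": self.coupling,
        }
        return hashlib.sha256(repr(payload).encode()).hexdigest()[:16]


def _draw_durations(rng: np.random.Generator, n: int, mu: float, sigma: float,
                    early_fraction: Optional[float]) -> np.ndarray:
    if n == 0:
        return np.zeros(0)
    if early_fraction is None:
        return np.exp(mu + sigma * rng.standard_normal(n))
    # stratified inverse-CDF sampling: exactly round(f*n) durations <= 1 year.
    # The established stratum starts just above the boundary so that the
    # 2-decimal rounding applied downstream cannot move a record across it.
    n_early = int(round(early_fraction * n))
    f1 = stats.norm.cdf((np.log(EARLY_DISEASE_MAX_DURATION) - mu) / sigma)
    f1b = stats.norm.cdf((np.log(EARLY_DISEASE_MAX_DURATION + 0.005) - mu) / sigma)
    u = np.empty(n)
    u[:n_early] = rng.uniform(0.0, f1, n_early)
    u[n_early:] = rng.uniform(f1b, 1.0, n - n_early)
    return np.exp(mu + sigma * stats.norm.ppf(u))


def _sample_titers(rng: np.random.Generator, n: int, dist: Mapping[str, float]) -> np.ndarray:
    levels = [lv for lv in ANA_TITER_LEVELS if lv in dist]
    probs = np.array([dist[lv] for lv in levels])
    probs = probs / probs.sum()
    return rng.choice(np.array(levels, dtype=object), size=n, p=probs)


def generate(config: CohortConfig, seed: Optional[int] = None) -> Cohort:
    """Generate a synthetic cohort; deterministic given config + seed."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    records: list[PatientRecord] = []
    group_specs = [
        ("case", config.n_cases, 0), ("control", config.n_controls, 1)]
    for group, n, gi in group_specs:
        if n == 0:
            continue
        c = config.coupling
        z = rng.standard_normal(n)
        eps = rng.standard_normal((n, len(FEATURES)))
        s = c * z[:, None] + np.sqrt(max(0.0, 1.0 - c * c)) * eps
        flags = np.zeros((n, len(FEATURES)), dtype=bool)
        for j, f in enumerate(FEATURES):
            p = config.feature_prevalence.get(f, (0.0, 0.0))[gi]
            if p >= 1.0:
                flags[:, j] = True
            elif p > 0.0:
                flags[:, j] = s[:, j] > -stats.norm.ppf(p)
        female = rng.random(n) < config.female_fraction[gi]
        mean, sd = config.onset_age[gi]
        onset = np.clip(rng.normal(mean, sd, n), 5.0, None)
        mu, sigma = config.duration_lognormal[gi]
        duration = _draw_durations(rng, n, mu, sigma,
                                   config.early_case_fraction if group == "case" else None)
        ln_iii_iv = rng.random(n) < config.ln_class_iii_iv_fraction
        titers = _sample_titers(rng, n, config.ana_titer_given_positive[gi])
        ana_col = FEATURES.index("ana_positive")
        biopsy_col = FEATURES.index("lupus_nephritis_biopsy")
        prefix = "CASE" if group == "case" else "CTRL"
        for i in range(n):
            dur = round(float(duration[i]), 2)
            on = round(float(onset[i]), 2)
            records.append(PatientRecord(
                patient_id=f"{prefix}{i + 1:04d}",
                reference_sle=(group == "case"),
                sex="female" if female[i] else "male",
                age_at_enrollment=round(on + dur, 2),
                age_at_onset=on,
                disease_duration=dur,
                features=FeatureSet(
                    flags={f: bool(flags[i, j]) for j, f in enumerate(FEATURES)},
                    ln_class=("III_IV" if ln_iii_iv[i] else "II_V") if flags[i, biopsy_col] else None),
                ana_titer=str(titers[i]) if flags[i, ana_col] else "negative",
                site_id=f"S{(i % 5) + 1}",
            ))
    return Cohort(records=records, provenance={
        "source": "synthetic", "seed": seed, "config_hash": config.config_hash()})


def plant_discordant_clusters(sizes: Sequence[int],
                              feature_profiles: Sequence[Mapping[str, float]],
                              seed: int = 0,
                              background: float = 0.05) -> tuple[Cohort, np.ndarray]:
    """Planted-block binary cohort for cluster-recovery experiments.

    Each cluster ``g`` contributes ``sizes[g]`` SLE cases whose feature flags
    are independent Bernoulli draws with the probabilities in
    ``feature_profiles[g]`` (features absent from the profile default to the
    ``background`` rate).  Returns the cohort together with the ground-truth
    cluster labels (1-based, aligned with record order).  Two identical
    profiles are permitted — recovery is then not guaranteed, but labels are
    still returned.
    """
    if len(sizes) != len(feature_profiles):
        raise ConfigError("need one feature profile per cluster size")
    if any(s <= 0 for s in sizes):
        raise ConfigError("zero-size cluster")
    rng = np.random.default_rng(seed)
    records: list[PatientRecord] = []
    labels: list[int] = []
    idx = 0
    for g, (size, profile) in enumerate(zip(sizes, feature_profiles), start=1):
        bad = set(profile) - set(FEATURES)
        if bad:
            raise ConfigError(f"profile {g}: unknown features {sorted(bad)}")
        for _ in range(size):
            idx += 1
            flags = {f: bool(rng.random() < profile.get(f, background)) for f in FEATURES}
            records.append(PatientRecord(
                patient_id=f"DISC{idx:04d}", reference_sle=True, sex="female",
                age_at_enrollment=32.0, age_at_onset=30.0, disease_duration=2.0,
                features=FeatureSet(flags=flags),
                ana_titer="1:160" if flags["ana_positive"] else "negative"))
            labels.append(g)
    cohort = Cohort(records=records, provenance={
        "source": "synthetic", "seed": seed, "generator": "plant_discordant_clusters"})
    return cohort, np.array(labels, dtype=int)
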
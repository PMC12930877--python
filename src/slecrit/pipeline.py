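"""End-to-end orchestration: generate -> classify -> evaluate -> agree -> cluster.

A run writes every artifact as CSV plus one markdown summary and a JSON
manifest (package version, seed, config hash, per-stage row counts).  All
randomness flows from the single run seed: stage seeds are spawned from
``numpy.random.SeedSequence(seed)`` in a fixed order, so a rerun with the
same manifest reproduces byte-identical tables.  A post-run audit
cross-checks tables against each other (NRI case components vs false-
negative differences; combination counts vs the discordant-set size).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .agreement import combination_counts, miss_analysis, nri
from .cluster import characterize, cut_tree, select_discordant, to_newick, ward_linkage
from .cohort_io import read_cohort, write_cohort
from .engines import SYSTEMS, classification_columns, classify_all, default_table
from .performance import evaluate, reports_frame
from .records import Cohort
from .synthetic import CohortConfig, generate

log = logging.getLogger("slecrit")

DEFAULT_SUBGROUPS = ("overall", "early_disease", "duration:<=1", "duration:1-5",
                     "duration:>5", "sex:female", "sex:male")


@dataclass
class RunConfig:
    out_dir: Path
    mode: str = "synthetic"            # synthetic | file
    cohort_path: Optional[Path] = None  # required in file mode
    cohort_config: Optional[CohortConfig] = None
    seed: Optional[int] = None          # mandatory in synthetic mode
    systems: Sequence[str] = SYSTEMS
    subgroups: Sequence[str] = DEFAULT_SUBGROUPS
    k_clusters: int = 4
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.mode not in ("synthetic", "file"):
            raise ValueError("mode must be 'synthetic' or 'file'")
        if self.mode == "synthetic" and self.seed is None:
            raise ValueError("seed is mandatory in synthetic mode")
        if self.mode == "file" and self.cohort_path is None:
            raise ValueError("cohort_path is required in file mode")


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    """Deterministic per-stage seeds spawned from the run seed (all < 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in ss.spawn(n)]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full comparison pipeline; returns the output bundle.

    Any stage failure aborts with the stage name; artifacts written by
    earlier stages are preserved in the output directory.
    """
    logging.basicConfig(level=config.log_level)
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    stage = "setup"
    try:
        # ------------------------------------------------------------ cohort
        stage = "cohort"
        if config.mode == "synthetic":
            ccfg = config.cohort_config or CohortConfig.default()
            cohort = generate(ccfg, seed=_stage_seeds(config.seed)[0])
            write_cohort(cohort, out / "cohort.csv")
            config_hash = ccfg.config_hash()
        else:
            cohort = read_cohort(config.cohort_path)
            config_hash = None
        log.info("stage=cohort n=%d cases=%d controls=%d",
                 len(cohort), cohort.n_cases, cohort.n_controls)
        bundle["cohort"] = cohort

        # ---------------------------------------------------------- classify
        stage = "classify"
        class_df = classify_all(cohort, tuple(config.systems))
        class_df.to_csv(out / "classifications.csv")
        class_bool = classification_columns(class_df, tuple(config.systems))
        log.info("stage=classify rows=%d systems=%d", len(class_df), len(config.systems))
        bundle["classifications"] = class_df

        # ---------------------------------------------------------- evaluate
        stage = "evaluate"
        reports = evaluate(cohort, class_df, subgroups=config.subgroups,
                           systems=config.systems)
        perf = reports_frame(reports)
        perf.to_csv(out / "performance.csv", index=False)
        log.info("stage=evaluate reports=%d", len(perf))
        bundle["performance"] = perf

        # ------------------------------------------------------------- agree
        stage = "agree"
        ref = cohort.reference().to_numpy()
        new = class_bool["slerpi"].to_numpy() if "slerpi" in class_bool else None
        nri_rows = []
        if new is not None:
            for comp in config.systems:
                if comp == "slerpi":
                    continue
                res = nri(new, class_bool[comp].to_numpy(), ref,
                          comparator=f"slerpi_vs_{comp}")
                nri_rows.append(res.as_row())
        nri_df = pd.DataFrame(nri_rows)
        nri_df.to_csv(out / "nri.csv", index=False)
        combos = combination_counts(class_bool, ref)
        combos.to_frame().to_csv(out / "upset_counts.csv", index=False)
        misses = miss_analysis(class_bool, ref, cohort)
        pd.DataFrame(
            [{"system": s, "n_missed": len(ids), "case_ids": ";".join(sorted(ids))}
             for s, ids in misses.miss_sets.items()]
        ).to_csv(out / "miss_sets.csv", index=False)
        misses.feature_frequency.to_csv(out / "miss_features.csv")
        log.info("stage=agree all_four=%d discordant=%d",
                 combos.counts.get(frozenset(config.systems), 0),
                 cohort.n_cases - combos.counts.get(frozenset(config.systems), 0))
        bundle["nri"] = nri_df
        bundle["combinations"] = combos
        bundle["misses"] = misses

        # ----------------------------------------------------------- cluster
        stage = "cluster"
        disc_ids, disc_features = select_discordant(class_bool, ref, cohort)
        if len(disc_ids) < 2:
            log.info("stage=cluster skipped: %d discordant case(s)", len(disc_ids))
            bundle["clustering"] = None
            (out / "cluster_summary.csv").write_text(
                "note\nclustering skipped: fewer than 2 discordant cases\n")
        else:
            tree = ward_linkage(disc_features.to_numpy(dtype=float))
            k = min(config.k_clusters, len(disc_ids))
            solution = cut_tree(tree, k, ids=disc_ids)
            summary = characterize(solution, disc_features, class_bool.loc[disc_ids])
            pd.DataFrame(tree.to_array(),
                         columns=["left", "right", "height", "size"]
                         ).to_csv(out / "linkage.csv", index=False)
            pd.Series(solution.assignments, name="cluster").rename_axis("patient_id") \
                .to_csv(out / "cluster_assignments.csv")
            summary["feature_prevalence"].to_csv(out / "cluster_summary.csv")
            summary["miss_counts"].to_csv(out / "cluster_miss_counts.csv")
            (out / "dendrogram.nwk").write_text(to_newick(tree, disc_ids) + "\n")
            log.info("stage=cluster n=%d k=%d sizes=%s", len(disc_ids), k, solution.sizes)
            bundle["clustering"] = {"tree": tree, "solution": solution, "summary": summary}

        # ------------------------------------------------------------- audit
        stage = "audit"
        _audit(bundle, config)

        stage = "report"
        (out / "summary.md").write_text(render_summary(bundle, config))
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "mode": config.mode,
            "config_hash": config_hash,
            "systems": list(config.systems),
            "subgroups": list(config.subgroups),
            "k_clusters": config.k_clusters,
            "counts": {"n": len(cohort), "cases": cohort.n_cases,
                       "controls": cohort.n_controls,
                       "discordant": len(disc_ids)},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        bundle["manifest"] = manifest
        return bundle
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _audit(bundle: dict, config: RunConfig) -> None:
    """Cross-table consistency checks; raises on any violation."""
    cohort: Cohort = bundle["cohort"]
    combos = bundle["combinations"]
    total = sum(combos.counts.values())
    if total != cohort.n_cases:
        raise AssertionError("combination counts do not conserve the case total")
    misses = bundle["misses"]
    n_all_four = combos.counts.get(frozenset(config.systems), 0)
    if int((bundle["misses"].multiplicity >= 1).sum()) != cohort.n_cases - n_all_four:
        raise AssertionError("discordant multiplicity inconsistent with combination counts")
    for row in bundle["nri"].to_dict("records"):
        comp = row["comparison"].replace("slerpi_vs_", "")
        fn_new = len(misses.miss_sets["slerpi"])
        fn_old = len(misses.miss_sets[comp])
        if row["cases_up"] - row["cases_down"] != fn_old - fn_new:
            raise AssertionError(f"NRI case components inconsistent for {comp}")


def render_summary(bundle: dict, config: RunConfig) -> str:
    """Markdown summary: per-subgroup performance block, NRI, concordance, clusters."""
    cohort: Cohort = bundle["cohort"]
    lines = ["# SLE criteria comparison run", "",
             f"Participants: {len(cohort)} ({cohort.n_cases} SLE cases, "
             f"{cohort.n_controls} controls)", ""]
    perf: pd.DataFrame = bundle["performance"]
    for subgroup, block in perf.groupby("subgroup", sort=False):
        lines.append(f"## Diagnostic performance — {subgroup}")
        lines.append("")
        lines.append("| System | n cases | n controls | Sensitivity % (95% CI) | "
                     "Specificity % (95% CI) | PPV % | NPV % | Accuracy % | AUC (95% CI) |")
        lines.append("|---|---|---|---|---|---|---|---|---|")
        for r in block.to_dict("records"):
            if pd.isna(r["sensitivity"]):
                lines.append(f"| {r['system']} | {r['n_cases']} | {r['n_controls']} | "
                             f"{r['note']} |||||||")
                continue
            lines.append(
                f"| {r['system']} | {r['n_cases']} | {r['n_controls']} "
                f"| {r['sensitivity']:.2f} ({r['sensitivity_lo']:.2f}–{r['sensitivity_hi']:.2f}) "
                f"| {r['specificity']:.2f} ({r['specificity_lo']:.2f}–{r['specificity_hi']:.2f}) "
                f"| {r['ppv']:.2f} | {r['npv']:.2f} | {r['accuracy']:.2f} "
                f"| {r['auc']:.3f} ({r['auc_lo']:.3f}–{r['auc_hi']:.3f}) |")
        lines.append("")
    nri_df: pd.DataFrame = bundle["nri"]
    if len(nri_df):
        lines.append("## Net reclassification improvement (SLERPI as new classifier)")
        lines.append("")
        lines.append("| Comparison | NRI events | NRI non-events | NRI total | "
                     "cases up/down | controls up/down |")
        lines.append("|---|---|---|---|---|---|")
        for r in nri_df.to_dict("records"):
            lines.append(f"| {r['comparison']} | {r['nri_events']:.3f} "
                         f"| {r['nri_nonevents']:.3f} | {r['nri_total']:.3f} "
                         f"| {r['cases_up']}/{r['cases_down']} "
                         f"| {r['controls_up']}/{r['controls_down']} |")
        lines.append("")
    combos = bundle["combinations"]
    n_all = combos.counts.get(frozenset(config.systems), 0)
    lines.append("## Concordance")
    lines.append("")
    lines.append(f"- classified by all four systems: {n_all} of {combos.n_total} cases "
                 f"({100 * n_all / combos.n_total:.1f}%)" if combos.n_total else "- no cases")
    lines.append(f"- discordant (missed by >= 1 system): {combos.n_total - n_all} "
                 f"({100 * (combos.n_total - n_all) / combos.n_total:.1f}%)"
                 if combos.n_total else "")
    lines.append("")
    if bundle.get("clustering"):
        sol = bundle["clustering"]["solution"]
        lines.append("## Discordant-case clusters (Ward, Euclidean)")
        lines.append("")
        lines.append(f"- k = {sol.k}, sizes = {list(sol.sizes)}")
        order = bundle["clustering"]["summary"]["system_order"]
        lines.append(f"- systems by ascending total misses among discordant cases: "
                     f"{', '.join(order)}")
        lines.append("")
    return "\n".join(lines) + "\n"


def threshold_note() -> str:
    """One-line provenance of each system's decision rule (for reports)."""
    parts = []
    for s in SYSTEMS:
        t = default_table(s)
        parts.append(f"{t.label}: {t.rule} >= {t.threshold:g}")
    return "; ".join(parts)
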
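"""End-to-end validation study: simulate, assign, recode, compare, report.

Reproduces the design of a hospital-anchored VA validation study on
synthetic (or user-supplied) data: a cohort of deaths with known causes is
"diagnosed" three ways — a hospital-style rater (HCOD, treated as the gold
standard), a physician-coder-style rater (PCVA), and the probabilistic
engine (InterVA-style) reading the indicator file — and the three methods
are compared by CSMF, Cohen's and Fleiss' kappa (overall and by sex),
per-cause validity metrics for the five most common causes, and ROC/AUC.

Only the primary (most likely) cause of each method is carried into
comparisons; for the engine, when the top cause disagrees with the gold
standard but the second or third listed cause matches it, that matching
cause is credited (see :func:`vaval.engine.resolve_comparison_cause`).

Everything is deterministic given the study seed: one global seed is split
into per-stage substreams (matrix, cohort, each rater, bootstrap) so stages
can be re-run independently, and two runs with the same config produce
byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement, causemap, engine, roc
from .cohort import (
    INDETERMINATE,
    CauseList,
    DeathRecord,
    ProbabilityMatrix,
    RaterModel,
    build_probability_matrix,
    simulate_cohort,
    simulate_rater,
    write_cohort,
)
from .util import round_half_up

logger = logging.getLogger(__name__)

#: default synthetic study: ten condensed categories with the five classical
#: leading adult causes dominating (together 73% of deaths)
DEFAULT_STUDY_CAUSES = (
    "HIV/AIDS-related death",
    "tuberculosis (pulmonary)",
    "malaria",
    "meningitis",
    "diarrhea/gastroenteritis",
    "pneumonia/sepsis",
    "cardiovascular diseases",
    "diabetes",
    "chronic respiratory diseases",
    "other and unspecified",
)
DEFAULT_STUDY_CSMF = (0.24, 0.12, 0.06, 0.10, 0.05, 0.06, 0.18, 0.09, 0.05, 0.05)


@dataclass
class StudyConfig:
    """Parameters of one validation study run.

    Defaults describe a small hospital cohort: 145 adult deaths over ten
    condensed causes, fairly informative indicators with mild noise and
    missingness, a highly accurate hospital rater, a moderately accurate
    physician coder, and the engine run with HIV and malaria prevalence
    flagged high.
    """

    n_deaths: int = 145
    cause_labels: tuple[str, ...] = DEFAULT_STUDY_CAUSES
    csmf_true: tuple[float, ...] = DEFAULT_STUDY_CSMF
    n_indicators: int = 60
    informativeness: float = 0.8
    flip_noise: float = 0.05
    missing_rate: float = 0.10
    matrix_path: str | None = None
    hcod_accuracy: float = 0.95
    hcod_indeterminate_rate: float = 0.0
    pcva_accuracy: float = 0.70
    pcva_indeterminate_rate: float = 0.01
    top_min: float = 0.4
    extra_frac: float = 0.5
    prevalence_flags: dict = field(
        default_factory=lambda: {"HIV/AIDS-related death": "high", "malaria": "high"}
    )
    high_multiplier: float = engine.HIGH_PREVALENCE_MULTIPLIER
    low_multiplier: float = engine.LOW_PREVALENCE_MULTIPLIER
    cause_map_path: str | None = None
    csmf_tolerance: float = 0.05
    n_bootstrap: int = 2000
    seed: int = 1

    def __post_init__(self) -> None:
        if len(self.cause_labels) != len(self.csmf_true):
            raise ValueError("cause_labels and csmf_true lengths differ")
        self.cause_labels = tuple(self.cause_labels)
        self.csmf_true = tuple(float(x) for x in self.csmf_true)

    @property
    def causes(self) -> CauseList:
        return CauseList(self.cause_labels)

    @property
    def policy(self) -> engine.ReportingPolicy:
        return engine.ReportingPolicy(self.top_min, self.extra_frac)

    def stage_seeds(self) -> dict[str, int]:
        """Split the global seed into per-stage substreams (< 2^31)."""
        state = np.random.SeedSequence(self.seed).generate_state(5, dtype=np.uint64)
        names = ("matrix", "cohort", "hcod", "pcva", "bootstrap")
        return {k: int(v % (2**31)) for k, v in zip(names, state)}

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["cause_labels"] = list(d["cause_labels"])
        d["csmf_true"] = list(d["csmf_true"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class ValidationReport:
    """All comparison tables of one study run, plus artifact paths."""

    config: StudyConfig
    csmf_tables: dict[str, agreement.CSMFTable]
    kappa_table: pd.DataFrame
    validity_table: pd.DataFrame
    roc_results: dict[str, roc.ROCResult]
    output_mix: dict
    tolerance_checks: dict[str, pd.DataFrame]
    misclassification: dict[str, pd.DataFrame]
    top_causes: list[str]
    summary: dict
    artifacts: dict[str, Path]


def _build_matrix(config: StudyConfig, seed: int) -> ProbabilityMatrix:
    if config.matrix_path:
        return ProbabilityMatrix.from_csv(config.matrix_path)
    return build_probability_matrix(
        n_causes=len(config.cause_labels),
        n_indicators=config.n_indicators,
        informativeness=config.informativeness,
        seed=seed,
        cause_labels=config.causes,
    )


def _cause_map(config: StudyConfig) -> causemap.CauseMap:
    if config.cause_map_path:
        return causemap.load_cause_map(config.cause_map_path)
    if all(c in causemap.CONDENSED_COMMON_LIST for c in config.cause_labels):
        return causemap.builtin_default_map()
    # custom label set outside the condensed list: identity map over it
    return causemap.CauseMap({}, config.causes,
                             default_category=config.cause_labels[-1])


def _engine_scores(
    records: list[DeathRecord], matrix: ProbabilityMatrix
) -> pd.DataFrame:
    """Per-death posterior over causes; uniform rows where degenerate."""
    k = len(matrix.causes)
    rows = np.full((len(records), k), 1.0 / k)
    for i, rec in enumerate(records):
        try:
            rows[i] = engine.posterior(rec.indicators, matrix)
        except engine.DegeneratePosteriorError:
            pass
    return pd.DataFrame(rows, index=[r.id for r in records],
                        columns=list(matrix.causes))


def _kappa_cell(res: agreement.AgreementResult) -> dict:
    return {"kappa": res.kappa, "ci_low": res.ci_low, "ci_high": res.ci_high,
            "strength": res.strength, "n": res.n}


def run_validation(config: StudyConfig, out_dir) -> ValidationReport:
    """Execute the full study and write every artifact under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    t0 = time.perf_counter()

    def stage(name: str) -> None:
        logger.info("stage %-12s done at %6.2f s", name, time.perf_counter() - t0)

    causes = config.causes
    matrix = _build_matrix(config, seeds["matrix"])
    records = simulate_cohort(
        config.csmf_true, matrix, config.n_deaths,
        flip_noise=config.flip_noise, missing_rate=config.missing_rate,
        seed=seeds["cohort"],
    )
    hcod_rater = RaterModel.uniform_error(
        causes, config.hcod_accuracy, config.hcod_indeterminate_rate)
    pcva_rater = RaterModel.uniform_error(
        causes, config.pcva_accuracy, config.pcva_indeterminate_rate)
    hcod = simulate_rater(records, hcod_rater, seeds["hcod"])
    pcva = simulate_rater(records, pcva_rater, seeds["pcva"])
    for rec in records:
        rec.assigned["hcod"] = hcod[rec.id]
        rec.assigned["pcva"] = pcva[rec.id]
    stage("simulate")

    eng_matrix = engine.apply_prevalence(
        matrix, config.prevalence_flags,
        config.high_multiplier, config.low_multiplier)
    assign_table, mix = engine.batch_assign(records, eng_matrix, config.policy)
    scores = _engine_scores(records, eng_matrix)
    stage("assign")

    cmap = _cause_map(config)
    gold = [causemap.recode(hcod[r.id], cmap) for r in records]
    pcva_v = [causemap.recode(pcva[r.id], cmap) for r in records]
    interva_v = [
        causemap.recode(
            engine.resolve_comparison_cause(
                mix["assignments"][r.id], gold[i]), cmap)
        if not mix["assignments"][r.id].indeterminate else INDETERMINATE
        for i, r in enumerate(records)
    ]
    stage("recode")

    methods = {"interva": interva_v, "pcva": pcva_v, "hcod": gold}
    csmf_tables = {m: agreement.csmf(v, causes) for m, v in methods.items()}

    sex = np.asarray([r.sex for r in records], dtype=object)
    strata = {
        "total": np.ones(len(records), dtype=bool),
        "males": sex == "male",
        "females": sex == "female",
    }
    pairs = [("interva", "hcod"), ("interva", "pcva"), ("pcva", "hcod")]
    kappa_rows = []
    for stratum, mask in strata.items():
        for a, b in pairs:
            va = [x for x, keep in zip(methods[a], mask) if keep]
            vb = [x for x, keep in zip(methods[b], mask) if keep]
            res = agreement.pairwise_kappa(va, vb, causes.categories)
            kappa_rows.append({"comparison": f"{a} vs {b}", "stratum": stratum,
                               **_kappa_cell(res)})
        trio = [[x for x, keep in zip(methods[m], mask) if keep]
                for m in ("interva", "pcva", "hcod")]
        res = agreement.multirater_kappa(
            *trio, causes.categories,
            n_bootstrap=config.n_bootstrap, seed=seeds["bootstrap"])
        kappa_rows.append({"comparison": "interva + pcva + hcod",
                           "stratum": stratum, **_kappa_cell(res)})
    kappa_table = pd.DataFrame(kappa_rows)
    stage("kappa")

    gold_frac = csmf_tables["hcod"].fractions.drop(INDETERMINATE)
    # five most common gold-standard causes; ties broken by category order
    top_causes = list(
        gold_frac.sort_values(ascending=False, kind="stable").head(5).index)
    validity_rows = []
    for method in ("interva", "pcva"):
        for cause in top_causes:
            t = agreement.two_by_two(methods[method], gold, cause)
            validity_rows.append({"method": method, **t.as_row()})
    validity_table = pd.DataFrame(validity_rows)

    roc_results = {
        "interva": roc.roc_from_categorical(interva_v, gold, causes.categories),
        "pcva": roc.roc_from_categorical(pcva_v, gold, causes.categories),
        "interva_scores": roc.roc_from_scores(
            scores.loc[[r.id for r in records]], gold, causes.categories),
    }
    tolerance_checks = {
        m: agreement.csmf_tolerance_check(
            csmf_tables[m], csmf_tables["hcod"], config.csmf_tolerance)
        for m in ("interva", "pcva")
    }
    misclassification = {
        m: agreement.contingency(methods[m], gold, causes.categories)
        for m in ("interva", "pcva")
    }
    agree = [agreement.agreement_indicator(i, p, h)
             for i, p, h in zip(interva_v, pcva_v, gold)]
    stage("metrics")

    summary = _summary_dict(config, mix, kappa_table, csmf_tables,
                            tolerance_checks, roc_results, top_causes,
                            float(np.mean(agree)))
    artifacts = _write_artifacts(
        out, config, matrix, records, assign_table, scores, csmf_tables,
        kappa_table, validity_table, roc_results, tolerance_checks,
        misclassification, mix, summary, top_causes)
    stage("report")

    return ValidationReport(
        config=config, csmf_tables=csmf_tables, kappa_table=kappa_table,
        validity_table=validity_table, roc_results=roc_results,
        output_mix=mix, tolerance_checks=tolerance_checks,
        misclassification=misclassification, top_causes=top_causes,
        summary=summary, artifacts=artifacts)


def _summary_dict(config, mix, kappa_table, csmf_tables, tolerance_checks,
                  roc_results, top_causes, agreement_rate) -> dict:
    kt = kappa_table.set_index(["comparison", "stratum"])

    def kap(comparison):
        row = kt.loc[(comparison, "total")]
        return {"kappa": round(float(row["kappa"]), 4),
                "ci_low": round(float(row["ci_low"]), 4),
                "ci_high": round(float(row["ci_high"]), 4),
                "strength": row["strength"]}

    return {
        "seed": config.seed,
        "n_deaths": config.n_deaths,
        "output_mix_counts": mix["counts"],
        "output_mix_percentages": mix["percentages"],
        "kappa": {
            "interva_vs_hcod": kap("interva vs hcod"),
            "interva_vs_pcva": kap("interva vs pcva"),
            "pcva_vs_hcod": kap("pcva vs hcod"),
            "multirater": kap("interva + pcva + hcod"),
        },
        "auc": {name: round(r.auc, 4) for name, r in roc_results.items()},
        "adequate": {name: bool(r.adequate) for name, r in roc_results.items()},
        "csmf_pct": {m: {c: round(v, 4) for c, v in t.percentages().items()}
                     for m, t in csmf_tables.items()},
        "csmf_max_abs_diff_pp": {
            m: round(float(t["abs_diff_pp"].max()), 4)
            for m, t in tolerance_checks.items()},
        "csmf_within_tolerance": {
            m: bool(t["within_tolerance"].all())
            for m, t in tolerance_checks.items()},
        "top_causes": top_causes,
        "two_of_three_agreement_rate": round(agreement_rate, 4),
    }


def _fmt_ci(kappa, lo, hi) -> str:
    return f"{kappa:.2f} ({lo:.2f}-{hi:.2f})"


def _fmt_validity(val, lo, hi) -> str:
    if val is None:
        return "n/a"
    return (f"{round_half_up(val, 0):.0f} "
            f"({round_half_up(lo, 0):.0f}-{round_half_up(hi, 0):.0f})")


def _render_report(config, summary, kappa_table, validity_table, csmf_tables,
                   roc_results, top_causes) -> str:
    lines = [
        "# Validation report",
        "",
        f"Seed: {config.seed}; deaths: {config.n_deaths}; "
        f"causes: {len(config.cause_labels)}; "
        f"indicators: {config.n_indicators}",
        "",
        "## Output mix (engine)",
        "",
        "| output | count | % |",
        "| --- | --- | --- |",
    ]
    for key, cnt in summary["output_mix_counts"].items():
        lines.append(
            f"| {key.replace('_', ' ')} | {cnt} | "
            f"{summary['output_mix_percentages'][key]} |")

    lines += ["", "## Cause-specific mortality fractions (%)", "",
              "| cause | interva | pcva | hcod |", "| --- | --- | --- | --- |"]
    for cause in csmf_tables["hcod"].fractions.index:
        cells = [f"{csmf_tables[m].percentages()[cause]:.1f}"
                 for m in ("interva", "pcva", "hcod")]
        lines.append(f"| {cause} | " + " | ".join(cells) + " |")

    lines += ["", "## Kappa agreement", "",
              "| comparison | total | males | females |",
              "| --- | --- | --- | --- |"]
    kt = kappa_table.set_index(["comparison", "stratum"])
    for comparison in kappa_table["comparison"].unique():
        cells = []
        for stratum in ("total", "males", "females"):
            r = kt.loc[(comparison, stratum)]
            cells.append(_fmt_ci(r["kappa"], r["ci_low"], r["ci_high"]))
        lines.append(f"| {comparison} | " + " | ".join(cells) + " |")

    lines += ["", "## Validity for the five most common causes "
              "(% with 95% CI, vs hcod)", "",
              "| method | cause | sensitivity | PPV | specificity | NPV |",
              "| --- | --- | --- | --- | --- | --- |"]
    for row in validity_table.to_dict(orient="records"):
        cells = [_fmt_validity(row[m], row[f"{m}_ci_low"], row[f"{m}_ci_high"])
                 for m in ("sensitivity", "ppv", "specificity", "npv")]
        lines.append(f"| {row['method']} | {row['cause']} | "
                     + " | ".join(cells) + " |")

    lines += ["", "## ROC", "", "| method | AUC | adequate (>0.75) |",
              "| --- | --- | --- |"]
    for name, r in roc_results.items():
        lines.append(f"| {name} | {r.auc:.2f} | {'yes' if r.adequate else 'no'} |")

    lines += ["", "## CSMF tolerance check vs hcod",
              "", "| method | max abs diff (pp) | all within "
              f"{100 * config.csmf_tolerance:.0f} pp |", "| --- | --- | --- |"]
    for m in ("interva", "pcva"):
        lines.append(
            f"| {m} | {summary['csmf_max_abs_diff_pp'][m]:.1f} | "
            f"{'yes' if summary['csmf_within_tolerance'][m] else 'no'} |")
    lines += ["", f"Two-of-three agreement rate: "
              f"{summary['two_of_three_agreement_rate']:.3f}", ""]
    return "\n".join(lines)


def _plot_roc(roc_results: dict, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, r in roc_results.items():
        pts = r.as_frame()
        ax.plot(pts["fpr"], pts["tpr"], marker="o", markersize=3,
                label=f"{name} (AUC={r.auc:.2f})")
    ax.plot([0, 1], [0, 1], linestyle=":", color="grey", label="chance")
    ax.set_xlabel("false positive rate (1 - specificity)")
    ax.set_ylabel("true positive rate (sensitivity)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100, metadata={"Software": None})
    plt.close(fig)


def _write_artifacts(out, config, matrix, records, assign_table, scores,
                     csmf_tables, kappa_table, validity_table, roc_results,
                     tolerance_checks, misclassification, mix, summary,
                     top_causes) -> dict[str, Path]:
    paths: dict[str, Path] = {}

    def save(name: str, fn) -> None:
        paths[name] = out / name
        fn(paths[name])

    save("config.yaml", config.to_yaml)
    save("matrix.csv", matrix.to_csv)
    save("cohort.csv", lambda p: write_cohort(records, matrix, p))
    save("assignments.csv", lambda p: engine.write_assignments(assign_table, p))
    save("posteriors.csv",
         lambda p: scores.to_csv(p, index_label="id", float_format="%.8g"))
    csmf_df = pd.DataFrame(
        {m: t.fractions for m, t in csmf_tables.items()})
    csmf_df.index.name = "cause"
    save("csmf.csv", lambda p: csmf_df.to_csv(p, float_format="%.8g"))
    save("kappa_table.csv",
         lambda p: kappa_table.to_csv(p, index=False, float_format="%.8g"))
    save("validity_table.csv",
         lambda p: validity_table.to_csv(p, index=False, float_format="%.8g"))
    for m, t in misclassification.items():
        save(f"misclassification_{m}.csv", t.to_csv)
    for m, t in tolerance_checks.items():
        save(f"tolerance_{m}.csv",
             lambda p, t=t: t.to_csv(p, index_label="cause",
                                     float_format="%.8g"))
    for name, r in roc_results.items():
        save(f"roc_{name}.csv",
             lambda p, r=r: r.as_frame().to_csv(p, index=False,
                                                float_format="%.8g"))
    save("roc.png", lambda p: _plot_roc(roc_results, p))
    save("summary.json",
         lambda p: p.write_text(json.dumps(summary, indent=2, sort_keys=True)
                                + "\n"))
    report_md = _render_report(config, summary, kappa_table, validity_table,
                               csmf_tables, roc_results, top_causes)
    save("report.md", lambda p: p.write_text(report_md))
    return paths
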
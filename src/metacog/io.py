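"""Run configuration, file I/O, logging and pipeline orchestration.

Everything tabular is headered, comma-delimited UTF-8 with "." decimals and
empty fields for missing values.  A persisted config plus its seed
reproduces a run bit-for-bit: the global seed is expanded into
per-participant substreams keyed by (seed, arm, index), so changing one
arm's size never reshuffles another participant's data.

The ``analyze`` orchestration mirrors the study's analysis plan: task
exclusions and completer filtering, dimension scoring, baseline
cross-sectional regressions (iCBT arm), random-intercept change models,
time x change-score interaction models, change correlations, three-group
ANOVAs, and the demographics comparison table.
"""
from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import ARMS, Cohort, CohortDesign, generate_cohort
from .scoring import (
    WeightsMatrix,
    detect_catch_failures,
    read_weights,
    scale_totals,
    score_dimensions,
    write_weights,
    wsas_totals,
)
from .staircase import StaircaseConfig, frame_to_sessions, read_sessions
from .stats import (
    ModelResult,
    change_correlation,
    cross_sectional_regression,
    fisher_exact,
    group_time_anova,
    mixed_change_model,
    oneway_anova_from_summary,
    time_by_covariate_interaction,
    tukey_hsd_from_summary,
)
from .task_metrics import complete_case_filter, metrics_table, split_half_reliability

log = logging.getLogger("metacog")

__all__ = [
    "RunConfig",
    "simulate_to_files",
    "analyze_files",
    "analyze_cohort",
    "table1_tests",
    "results_to_frame",
    "build_report",
]


@dataclass
class RunConfig:
    """Serialisable description of a full simulate -> analyze run."""

    seed: int = 0
    out_dir: str = "metacog_run"
    design: CohortDesign = None  # filled from seed in __post_init__
    weights_path: str | None = None
    scoring_key_path: str | None = None
    run_baseline: bool = True
    run_longitudinal: bool = True
    run_interactions: bool = True
    run_correlations: bool = True
    run_anova: bool = True
    run_table1: bool = True
    run_reliability: bool = True
    strict_zscore_dummies: bool = False
    closed_exclusion_bounds: bool = False

    def __post_init__(self) -> None:
        if self.design is None:
            self.design = CohortDesign(seed=self.seed)
        elif self.design.seed != self.seed:
            self.design = dataclasses.replace(self.design, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        sc = d["design"]["staircase"]
        sc["step_schedule"] = [list(x) for x in sc["step_schedule"]]
        d["design"]["dimension_correlations"] = [
            list(r) for r in d["design"]["dimension_correlations"]
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        design_d = d.pop("design", None)
        design = None
        if design_d is not None:
            design_d = dict(design_d)
            sc = design_d.pop("staircase", None)
            if sc is not None:
                sc = dict(sc)
                sc["step_schedule"] = tuple(
                    (int(a), None if b is None else int(b), float(s))
                    for a, b, s in sc["step_schedule"]
                )
                design_d["staircase"] = StaircaseConfig(**sc)
            if "dimension_correlations" in design_d:
                design_d["dimension_correlations"] = tuple(
                    tuple(float(v) for v in row)
                    for row in design_d["dimension_correlations"]
                )
            design = CohortDesign(**design_d)
        return cls(design=design, **d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


# --- simulate ---------------------------------------------------------------


def simulate_to_files(config: RunConfig) -> Path:
    """Generate a cohort and write trial, item, weights and participant files."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info(
        "metacog %s simulate: seed=%d config=%s", __version__, config.seed,
        config.config_hash(),
    )
    cohort = generate_cohort(config.design)
    cohort.trials_frame().to_csv(out / "trials.csv", index=False)
    cohort.items_frame().to_csv(out / "items.csv", index=False)
    cohort.participants_frame().to_csv(out / "participants.csv", index=False)
    write_weights(cohort.weights, out / "weights.csv")
    config.to_yaml(out / "config.yaml")
    log.info(
        "wrote %d participants, %d trial rows",
        len(cohort.participants),
        sum(s.n_trials for p in cohort.participants for s in p.sessions),
    )
    return out


# --- analyze ----------------------------------------------------------------


def _attach_scores(metrics: pd.DataFrame, scores: pd.DataFrame,
                   participants: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long (per participant x timepoint) and wide (per participant) frames."""
    long = metrics.merge(scores, on=["participant_id", "timepoint"], how="inner")
    long = long.merge(participants, on="participant_id", how="left")
    long["time"] = (long["timepoint"] == "followup").astype(int)

    base = long[long["time"] == 0].set_index("participant_id")
    post = long[long["time"] == 1].set_index("participant_id")
    common = base.index.intersection(post.index)
    wide = participants.set_index("participant_id").loc[common].copy()
    for col in ("mean_confidence", "mean_dot_difference", "mean_accuracy",
                "mean_rt", "AD", "CIT", "SW"):
        wide[f"{col}_baseline"] = base.loc[common, col]
        wide[f"{col}_change"] = post.loc[common, col] - base.loc[common, col]
    wide = wide.reset_index()
    long = long.merge(
        wide[["participant_id"] + [c for c in wide.columns if c.endswith("_change")
                                   or c.endswith("_baseline")]],
        on="participant_id", how="left",
    )
    return long, wide


def analyze_cohort(
    cohort: Cohort,
    config: RunConfig | None = None,
    weights: WeightsMatrix | None = None,
):
    """Run the full analysis plan on an in-memory cohort."""
    config = config or RunConfig(seed=cohort.design.seed, design=cohort.design)
    return analyze_tables(
        trials=cohort.trials_frame(),
        items=cohort.items_frame(),
        participants=cohort.participants_frame(),
        weights=weights or cohort.weights,
        config=config,
    )


def analyze_files(config: RunConfig, in_dir=None):
    """Run the analysis plan on a simulate output directory."""
    src = Path(in_dir or config.out_dir)
    for name in ("trials.csv", "items.csv", "participants.csv"):
        if not (src / name).exists():
            raise FileNotFoundError(f"{src / name} is required for analyze")
    weights = read_weights(config.weights_path or src / "weights.csv")
    trials = pd.read_csv(src / "trials.csv")
    trials["correct"] = trials["correct"].astype(bool)
    return analyze_tables(
        trials=trials,
        items=pd.read_csv(src / "items.csv"),
        participants=pd.read_csv(src / "participants.csv"),
        weights=weights,
        config=config,
    )


def analyze_tables(
    trials: pd.DataFrame,
    items: pd.DataFrame,
    participants: pd.DataFrame,
    weights: WeightsMatrix,
    config: RunConfig,
) -> dict:
    """Exclusions, scoring and every enabled model family.

    Returns a dict with the tidy ``results`` table, the ``report`` markdown,
    and the intermediate ``metrics``, ``scores``, ``long``/``wide`` frames.
    """
    if len(trials) == 0 or len(participants) == 0:
        raise ValueError("empty cohort: no trials or participants to analyse")
    sessions = frame_to_sessions(trials)
    metrics = metrics_table(sessions, closed_bounds=config.closed_exclusion_bounds)
    scores_obj = score_dimensions(items, weights, centre=True)
    scores = scores_obj.frame
    completers = complete_case_filter(metrics, scores)
    log.info(
        "funnel: %d participants generated -> %d sessions -> %d excluded "
        "sessions -> %d completers",
        participants["participant_id"].nunique(),
        len(metrics),
        int(metrics["excluded"].sum()),
        len(completers),
    )
    metrics_ok = metrics[metrics["participant_id"].isin(completers)
                         & ~metrics["excluded"].astype(bool)]
    scores_ok = scores[scores["participant_id"].isin(completers)]
    long, wide = _attach_scores(metrics_ok, scores_ok, participants)
    catch = detect_catch_failures(items)
    wsas = wsas_totals(items)
    scales = scale_totals(items)

    results: list[ModelResult] = []
    extras: dict = {}
    icbt_long = long[long["arm"] == "icbt"]
    icbt_wide = wide[wide["arm"] == "icbt"]

    if config.run_reliability and len(sessions) >= 3:
        base_sessions = [
            s for s in sessions
            if s.timepoint == "baseline" and s.participant_id in set(completers)
        ]
        if len(base_sessions) >= 3:
            r, df, p = split_half_reliability(base_sessions)
            extras["split_half"] = {"r": r, "df": df, "p": p}

    if config.run_baseline and len(icbt_long) > 10:
        base = icbt_long[icbt_long["time"] == 0]
        results.append(
            cross_sectional_regression(
                base,
                outcome="mean_confidence",
                predictors=["AD", "CIT", "SW"],
                covariates=["age", "gender", "education"],
                strict_zscore_dummies=config.strict_zscore_dummies,
                name="baseline:confidence~dimensions",
            )
        )
        results.append(
            cross_sectional_regression(
                base,
                outcome="mean_confidence",
                predictors=["mean_accuracy", "mean_dot_difference", "mean_rt"],
                strict_zscore_dummies=config.strict_zscore_dummies,
                name="baseline:confidence~task",
            )
        )

    if config.run_longitudinal and len(icbt_long) > 10:
        for outcome in ("mean_confidence", "mean_dot_difference",
                        "mean_accuracy", "AD", "CIT", "SW"):
            results.append(
                mixed_change_model(icbt_long, outcome,
                                   name=f"icbt:change:{outcome}")
            )
        for arm in ("antidepressant", "control"):
            sub = long[long["arm"] == arm]
            if sub["participant_id"].nunique() > 3:
                for outcome in ("mean_confidence", "AD"):
                    results.append(
                        mixed_change_model(sub, outcome,
                                           name=f"{arm}:change:{outcome}")
                    )

    if config.run_interactions and len(icbt_long) > 10:
        results.append(
            time_by_covariate_interaction(
                icbt_long, "mean_confidence", "AD_change",
                name="icbt:confidence~time*AD_change",
            )
        )
        results.append(
            time_by_covariate_interaction(
                icbt_long, "mean_confidence", "CIT_change",
                name="icbt:confidence~time*CIT_change",
            )
        )
        results.append(
            time_by_covariate_interaction(
                icbt_long, "mean_confidence", "AD_change",
                extra_covariates=["CIT_change", "SW_change"],
                name="icbt:confidence~time*AD_change+controls",
            )
        )
        results.append(
            time_by_covariate_interaction(
                icbt_long, "mean_dot_difference", "AD_change",
                name="icbt:difficulty~time*AD_change",
            )
        )
        results.append(
            time_by_covariate_interaction(
                icbt_long, "mean_confidence", "AD_baseline",
                name="icbt:confidence~time*AD_baseline",
            )
        )
        if icbt_long["minutes_in_program"].notna().any():
            for cov in ("minutes_in_program", "percent_viewed"):
                results.append(
                    time_by_covariate_interaction(
                        icbt_long, "mean_confidence", cov,
                        name=f"icbt:confidence~time*{cov}",
                    )
                )
        if icbt_long["program_type"].notna().any():
            results.append(
                time_by_covariate_interaction(
                    icbt_long, "mean_confidence", "program_type",
                    name="icbt:confidence~time*program_type",
                )
            )

    if config.run_correlations:
        corr_rows = []
        for arm in ARMS:
            sub = wide[wide["arm"] == arm]
            if len(sub) >= 3:
                r, df, p = change_correlation(
                    sub["AD_change"], sub["mean_confidence_change"]
                )
                corr_rows.append({"arm": arm, "r": r, "df": df, "p": p})
        extras["change_correlations"] = pd.DataFrame(corr_rows)

    if config.run_anova and long["arm"].nunique() >= 2:
        for outcome in ("AD", "mean_confidence", "mean_dot_difference"):
            results.append(
                group_time_anova(long, outcome, name=f"anova:{outcome}")
            )
        results.append(
            group_time_anova(
                long, "mean_confidence", covariate="AD_change",
                name="anova:confidence~group*time*AD_change",
            )
        )

    table1 = None
    if config.run_table1:
        table1 = table1_tests(participants)

    results_frame = results_to_frame(results)
    report = build_report(results_frame, extras, table1, catch, config)
    return {
        "results": results_frame,
        "models": results,
        "extras": extras,
        "table1": table1,
        "metrics": metrics,
        "scores": scores,
        "long": long,
        "wide": wide,
        "catch": catch,
        "wsas": wsas,
        "scale_totals": scales,
        "completers": completers,
        "report": report,
    }


def results_to_frame(results: list[ModelResult]) -> pd.DataFrame:
    cols = ["model", "term", "estimate", "se", "stat", "df1", "df2", "p", "n"]
    rows = [
        {
            "model": m.model,
            "term": t.term,
            "estimate": t.estimate,
            "se": t.se,
            "stat": t.stat,
            "df1": t.df1,
            "df2": t.df2,
            "p": t.p,
            "n": m.n,
        }
        for m in results
        for t in m.terms
    ]
    return pd.DataFrame(rows, columns=cols)


# --- demographics table -----------------------------------------------------


def table1_tests(participants: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Per-characteristic group comparison statistics.

    Gender uses the Freeman-Halton exact test (Monte-Carlo for large
    spaces), country and education use Pearson chi-square, age uses one-way
    ANOVA with Tukey post-hocs.  With a single arm only descriptives are
    returned.
    """
    if "arm" not in participants.columns:
        raise ValueError("participants table needs an 'arm' column")
    arms = [a for a in ARMS if a in set(participants["arm"])]
    rows = []
    single_arm = len(arms) < 2

    def crosstab(col):
        ct = pd.crosstab(participants[col], participants["arm"])
        return ct[arms]

    for col, test in (("gender", "fisher"), ("country", "chi2"), ("education", "chi2")):
        ct = crosstab(col)
        counts = "; ".join(
            f"{idx}: " + "/".join(str(v) for v in row)
            for idx, row in ct.iterrows()
        )
        if single_arm:
            rows.append({"characteristic": col, "counts": counts, "test": "none",
                         "stat": None, "df": None, "p": None})
            continue
        if test == "fisher":
            p = fisher_exact(ct.to_numpy(), method="auto", seed=seed)
            rows.append({"characteristic": col, "counts": counts,
                         "test": "fisher_exact", "stat": None, "df": None, "p": p})
        else:
            from .stats import chi_square_independence

            chi2, df, p = chi_square_independence(ct.to_numpy())
            rows.append({"characteristic": col, "counts": counts,
                         "test": "chi_square", "stat": chi2, "df": df, "p": p})

    age = participants.dropna(subset=["age"])
    summ = [
        (age.loc[age["arm"] == a, "age"].mean(),
         age.loc[age["arm"] == a, "age"].std(ddof=1),
         int((age["arm"] == a).sum()))
        for a in arms
    ]
    desc = "; ".join(f"{a}: {m:.1f} ({s:.1f})" for a, (m, s, _) in zip(arms, summ))
    if single_arm:
        rows.append({"characteristic": "age", "counts": desc, "test": "none",
                     "stat": None, "df": None, "p": None})
    else:
        F, df1, df2, p = oneway_anova_from_summary(summ)
        rows.append({"characteristic": "age", "counts": desc, "test": "oneway_anova",
                     "stat": F, "df": f"{df1},{df2}", "p": p})
        tukey = tukey_hsd_from_summary(summ, labels=arms)
        for _, t in tukey.iterrows():
            rows.append({
                "characteristic": f"age:{t['group_1']}-vs-{t['group_2']}",
                "counts": f"diff={t['mean_difference']:.2f}",
                "test": "tukey_hsd", "stat": t["q"], "df": None,
                "p": t["p_adjusted"],
            })
    return pd.DataFrame(rows)


# --- report -----------------------------------------------------------------


def build_report(
    results: pd.DataFrame,
    extras: dict,
    table1: pd.DataFrame | None,
    catch: pd.DataFrame | None,
    config: RunConfig,
) -> str:
    """Human-readable markdown report of every enabled analysis family."""
    lines = [
        "# Metacognition treatment-study analysis report",
        "",
        f"config hash: `{config.config_hash()}` | seed: {config.seed} | "
        f"package version: {__version__}",
        "",
    ]
    if "split_half" in extras:
        sh = extras["split_half"]
        lines += [
            "## Reliability",
            "",
            f"Split-half (odd/even) reliability of baseline mean confidence: "
            f"r({sh['df']}) = {sh['r']:.3f}, p = {sh['p']:.3g}",
            "",
        ]

    def section(title, prefix):
        sub = results[results["model"].str.startswith(prefix)]
        if sub.empty:
            return
        lines.append(f"## {title}")
        lines.append("")
        lines.append(sub.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        lines.append("")

    section("Baseline associations (iCBT arm)", "baseline:")
    section("Treatment change models (iCBT arm)", "icbt:change")
    section("Time x covariate interaction models", "icbt:confidence~time")
    section("Task difficulty interaction", "icbt:difficulty~time")
    section("Antidepressant arm change models", "antidepressant:")
    section("Control arm change models", "control:")
    section("Three-group ANOVAs", "anova:")

    if config.run_correlations and "change_correlations" in extras:
        lines.append("## Change-score correlations (confidence vs anxious-depression)")
        lines.append("")
        lines.append(extras["change_correlations"].to_string(index=False))
        lines.append("")
    if table1 is not None:
        lines.append("## Demographic comparisons")
        lines.append("")
        lines.append(table1.to_string(index=False))
        lines.append("")
    if catch is not None and len(catch):
        failed = catch[catch["n_failed"] > 0]
        lines.append("## Attention checks")
        lines.append("")
        lines.append(
            f"{failed['participant_id'].nunique()} participants failed at least "
            "one catch item (retained in the analysis set)."
        )
        lines.append("")
    return "\n".join(lines)


def write_analysis(out_dir, analysis: dict) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    analysis["results"].to_csv(out / "results.csv", index=False)
    analysis["metrics"].to_csv(out / "metrics.csv", index=False)
    analysis["scores"].to_csv(out / "scores.csv", index=False)
    if analysis.get("table1") is not None:
        analysis["table1"].to_csv(out / "table1.csv", index=False)
    if "change_correlations" in analysis["extras"]:
        analysis["extras"]["change_correlations"].to_csv(
            out / "change_correlations.csv", index=False
        )
    (out / "report.md").write_text(analysis["report"])
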
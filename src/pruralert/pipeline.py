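"""End-to-end pipeline: simulate → metrics → alerts → attribution → stats.
Each stage reads and writes delimited text tables so runs are fully
reproducible from a config file and a seed; a :class:`RunManifest`
records the config hash, seed, and per-stage output paths.
"""
from __future__ import annotations
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd
from . import __version__
from .config import CohortConfig
from .model import AlertResponseModel
from .reference import analyze_reference_counts, reference_results_frame
from .simulate import read_cohort, simulate_cohort, write_cohort
__all__ = ["RunManifest", "run_pipeline", "render_report", "render_reference_report"]
log = logging.getLogger("pruralert")
STAGES = ("simulate", "alerts", "attribute", "stats", "report")
@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stage_outputs: dict = field(default_factory=dict)
    versions: str = f"pruralert {__version__}"
    def write(self, path) -> None:
        # paths stored relative to the manifest so reruns in different
        # directories produce identical manifests
        base = Path(path).parent
        d = dataclasses.asdict(self)
        d["stage_outputs"] = {
            k: str(Path(v).relative_to(base)) for k, v in self.stage_outputs.items()
        }
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
def _date_cols_to_iso(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in df.columns:
        if pd.api.types.is_datetime64_any_dtype(df[col]):
            df[col] = df[col].dt.date
    return df
def run_pipeline(
    config: CohortConfig | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
    window_days: int = 28,
    eligibility: str = "visit_and_alert",
) -> RunManifest:
    """Run every stage on a simulated cohort and write all outputs.
    ``config`` may be a :class:`CohortConfig` or a path to a YAML config
    file; ``seed`` overrides the config's ``rng_seed`` when given.
    """
    if not isinstance(config, CohortConfig):
        config_path = Path(config)
        if not config_path.exists():
            raise FileNotFoundError(f"config file not found: {config_path}")
        config = CohortConfig.from_yaml(config_path)
    if seed is not None:
        config = CohortConfig.from_dict({**config.to_dict(), "rng_seed": int(seed)})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(), seed=config.rng_seed)
    config.to_yaml(out / "config.yaml")
    log.info("simulating cohort: %d dogs x %d days", config.n_dogs, config.n_days)
    behavior, visits, prescriptions = simulate_cohort(config)
    cohort_dir = out / "cohort"
    write_cohort(cohort_dir, behavior, visits, prescriptions)
    manifest.stage_outputs["simulate"] = cohort_dir
    log.info("cohort: %d dog-days, %d visits, %d prescriptions",
             len(behavior), len(visits), len(prescriptions))
    model = AlertResponseModel(
        behavior,
        visits,
        prescriptions,
        period_start=config.period_start,
        period_length_days=config.period_length_days,
        n_periods=config.n_periods,
        window_days=window_days,
        eligibility=eligibility,
    )
    res = model.fit()
    alerts_path = out / "alerts.csv"
    _date_cols_to_iso(res.all_alerts).to_csv(alerts_path, index=False)
    manifest.stage_outputs["alerts"] = alerts_path
    log.info("alerts: %d total (%d from eligible dogs)", len(res.all_alerts), len(res.alerts))
    attr_dir = out / "attribution"
    attr_dir.mkdir(exist_ok=True)
    _date_cols_to_iso(res.matches).to_csv(attr_dir / "matches.csv", index=False)
    res.subgroups.to_csv(attr_dir / "subgroups.csv", index=False)
    if res.prescriptions is not None:
        res.prescriptions.to_csv(attr_dir / "prescriptions_flagged.csv", index=False)
    for p, table in res.week_tables.items():
        table.to_csv(attr_dir / f"week_bins_period{p}.csv")
    manifest.stage_outputs["attribute"] = attr_dir
    log.info("matches: %d alert visits", len(res.matches))
    stats_path = out / "odds_ratios.csv"
    res.strata_frame().to_csv(stats_path, index=False)
    manifest.stage_outputs["stats"] = stats_path
    report_path = out / "report.md"
    report_path.write_text(render_report(res) + "\n")
    manifest.stage_outputs["report"] = report_path
    manifest.write(out / "manifest.json")
    log.info("pipeline complete: %s", out)
    return manifest
def analyze_cohort_dir(
    cohort_dir, window_days: int = 28, eligibility: str = "visit_and_alert", **model_kwargs
):
    """Fit the model on a cohort directory written by the simulate stage."""
    behavior, visits, prescriptions = read_cohort(cohort_dir)
    model = AlertResponseModel(
        behavior, visits, prescriptions,
        window_days=window_days, eligibility=eligibility, **model_kwargs,
    )
    return model.fit()
def render_report(res) -> str:
    """Markdown report reproducing the shape of the study's summary tables."""
    lines = ["# Alert-response analysis report", ""]
    lines.append("## Eligible dogs and dermatitis subgroups")
    lines.append("")
    lines.append("| period | dogs | group 0 | group 1 | group 2 | group 3 |")
    lines.append("|---|---|---|---|---|---|")
    sg = res.subgroups.set_index("dog_id")["group"]
    for p, dogs in sorted(res.eligible.items()):
        counts = sg.reindex(dogs).value_counts().reindex(range(4), fill_value=0)
        lines.append(
            f"| {p} | {len(dogs)} | " + " | ".join(str(int(c)) for c in counts) + " |"
        )
    lines.append("")
    lines.append("## Alert burden")
    lines.append("")
    lines.append("| period | total alerts | mean/dog | median | range | max |")
    lines.append("|---|---|---|---|---|---|")
    for p, s in sorted(res.alert_summaries.items()):
        lines.append(
            f"| {p} | {s.total_alerts} | {s.mean_per_dog:.1f} | "
            f"{s.median_per_dog:.1f} | {s.range} | {s.max_per_dog} |"
        )
    lines.append("")
    lines.append("## Odds ratios (period 2 exposure vs period 1 control)")
    lines.append("")
    lines.append("| metric | stratum | a | c | OR | 95% CI | p |")
    lines.append("|---|---|---|---|---|---|---|")
    for metric in ("scratch", "lick", "combined"):
        by_stratum = {r.stratum: r for r in res.or_results[metric]}
        for t in res.tables[metric]:
            r = by_stratum.get(t.stratum)
            if r is None or (metric != "combined" and t.stratum == "combined"):
                continue
            digits = 4 if t.stratum == "combined" else 2
            lines.append(
                f"| {metric} | {t.stratum} | {t.a} | {t.c} | {r.odds_ratio:.{digits}f} | "
                f"{r.ci_low:.2f}–{r.ci_high:.2f} | {r.p_display} |"
            )
    lines.append("")
    lines.append("## Clinic visits by week after alert")
    for p, table in sorted(res.week_tables.items()):
        lines.append("")
        lines.append(f"### Period {p}")
        lines.append("")
        lines.append("| subgroup | week 1 | week 2 | week 3 | week 4 | outside window | total |")
        lines.append("|---|---|---|---|---|---|---|")
        for g, row in table.iterrows():
            total = int(row.sum())
            lines.append(
                f"| {g} | " + " | ".join(str(int(row[c])) for c in [1, 2, 3, 4, "outside"])
                + f" | {total} |"
            )
    if res.prescription_summary is not None:
        lines.append("")
        lines.append("## Medications within the post-alert window")
        lines.append("")
        lines.append("| period | medications | within window | % |")
        lines.append("|---|---|---|---|")
        for _, row in res.prescription_summary.iterrows():
            pct = f"{row['within_window_pct']:.1f}" if row["total_medications"] else "–"
            lines.append(
                f"| {int(row['period'])} | {int(row['total_medications'])} | "
                f"{int(row['within_window'])} | {pct} |"
            )
    return "\n".join(lines)
def render_reference_report() -> str:
    """Markdown report of the published-counts analysis (no simulation)."""
    analysis = analyze_reference_counts()
    frame = reference_results_frame(analysis)
    lines = ["# Published-counts analysis", ""]
    lines.append("| metric | stratum | OR | 95% CI | p |")
    lines.append("|---|---|---|---|---|")
    for _, r in frame.iterrows():
        digits = 4 if r["stratum"] == "combined" else 2
        p_disp = "<0.0001" if r["p_two_tailed"] < 1e-4 else f"{r['p_two_tailed']:.4f}"
        lines.append(
            f"| {r['metric']} | {r['stratum']} | {r['odds_ratio']:.{digits}f} | "
            f"{r['ci_low']:.2f}–{r['ci_high']:.2f} | {p_disp} |"
        )
    lines.append("")
    lines.append("| period | alert visits / alerts | alert visits / visits | meds in window | mean alerts/dog |")
    lines.append("|---|---|---|---|---|")
    for p, f in sorted(analysis["fractions"].items()):
        lines.append(
            f"| {p} | {f['alert_visit_pct_of_alerts']:.2f}% | "
            f"{f['alert_visit_pct_of_visits']:.1f}% | "
            f"{f['medications_within_window_pct']:.1f}% | "
            f"{analysis['mean_alerts_per_dog'][p]:.1f} |"
        )
    return "\n".join(lines)
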
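"""Analysis of the published cohort summary counts.
The raw per-dog telemetry behind the retrospective cohort is not
deposited, but its printed 2x2 tables and totals are.  This module
ships those counts as package data and re-derives every downstream
statistic (odds ratios, confidence intervals, alert-visit fractions,
per-dog alert burden) from them, so the statistics stage is exactly
testable without simulation.
"""
from __future__ import annotations
import json
from importlib import resources
import pandas as pd
from .stats import TwoByTwoTable, fraction, odds_ratio
__all__ = ["load_reference_counts", "analyze_reference_counts"]
def load_reference_counts() -> dict:
    """Published summary counts bundled with the package."""
    with resources.files("pruralert").joinpath("data/reference_counts.json").open() as fh:
        return json.load(fh)
def analyze_reference_counts(counts: dict | None = None) -> dict:
    """Recompute odds ratios and descriptive fractions from summary counts.
    Returns a dict with:
    ``odds_ratios``
        mapping of ('scratch'|'lick', level-name) and 'combined' to
        :class:`OddsRatioResult`.
    ``fractions``
        alert-side and visit-side alert-visit percentages and the
        medication-within-window percentages, keyed by period.
    ``mean_alerts_per_dog``
        total alerts / eligible dogs, keyed by period.
    ``tables``
        the underlying :class:`TwoByTwoTable` objects.
    """
    counts = counts or load_reference_counts()
    tables: dict = {}
    ors: dict = {}
    for metric in ("scratch", "lick"):
        for level, cells in counts["two_by_two"][metric].items():
            t = TwoByTwoTable(*cells, stratum=level)
            tables[(metric, level)] = t
            ors[(metric, level)] = odds_ratio(t)
    combined = TwoByTwoTable(*counts["two_by_two"]["combined"], stratum="combined")
    tables["combined"] = combined
    ors["combined"] = odds_ratio(combined)
    fractions: dict = {}
    means: dict = {}
    for period, p in counts["periods"].items():
        fractions[period] = {
            "alert_visit_pct_of_alerts": fraction(p["alert_visits"], p["total_alerts"]),
            "alert_visit_pct_of_visits": fraction(p["alert_visits"], p["total_visits"]),
            "medications_within_window_pct": fraction(
                p["medications_within_window"], p["total_medications"]
            ),
        }
        means[period] = p["total_alerts"] / p["n_dogs"]
    return {
        "odds_ratios": ors,
        "fractions": fractions,
        "mean_alerts_per_dog": means,
        "tables": tables,
    }
def reference_results_frame(analysis: dict | None = None) -> pd.DataFrame:
    """Per-stratum odds-ratio table (scratch strata, lick strata, combined)."""
    analysis = analysis or analyze_reference_counts()
    rows = []
    for key, res in analysis["odds_ratios"].items():
        metric = key[0] if isinstance(key, tuple) else "combined"
        rows.append({"metric": metric, **res.as_dict()})
    frame = pd.DataFrame(rows)
    return frame[
        ["metric", "stratum", "odds_ratio", "ci_low", "ci_high", "log_se", "z",
         "p_two_tailed", "corrected"]
    ]
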
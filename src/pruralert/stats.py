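"""Odds ratios for pre/post alert-visit association.
The comparison of interest is whether an alert is more likely to be
followed by a clinic visit within the 4-week window in the second
(post, exposure) period than in the first (pre, control) period.  Each
stratum (overall, or one scratching/licking severity level at alert
time) yields a 2x2 table
    =============  ==================  =================
                   period 2 (post)     period 1 (pre)
    =============  ==================  =================
    alert visit    a                   c
    no alert visit b                   d
    =============  ==================  =================
analysed with the log odds-ratio method::
    OR = (a/b) / (c/d)
    SE(ln OR) = sqrt(1/a + 1/b + 1/c + 1/d)
    95% CI = exp(ln OR -/+ 1.96 * SE)
    z = ln OR / SE,  two-tailed normal p
When any single cell is zero, the Haldane–Anscombe 0.5 continuity
correction is added to all four cells; a wholly empty row or column
leaves the estimate undefined and raises an error.
"""
from __future__ import annotations
import math
from dataclasses import dataclass
import pandas as pd
from scipy.stats import norm
from .exceptions import ConfigurationError, InputError, UndefinedEstimateError
__all__ = [
    "TwoByTwoTable",
    "OddsRatioResult",
    "odds_ratio",
    "build_two_by_two",
    "fraction",
    "results_frame",
]
Z_95 = 1.96
STRATIFIERS = (None, "scratch_level", "lick_level")
@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts of alert-visit events (a, c) and non-events (b, d) by period."""
    a: int  # period 2, alert associated with a 4-week visit
    b: int  # period 2, not associated
    c: int  # period 1, associated
    d: int  # period 1, not associated
    stratum: str = "combined"
    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise InputError(f"cell {name}: counts must be nonnegative integers, got {v!r}")
    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)
@dataclass(frozen=True)
class OddsRatioResult:
    """Odds ratio with log-method 95% CI and normal-approximation test."""
    odds_ratio: float
    log_se: float
    ci_low: float
    ci_high: float
    z: float
    p_two_tailed: float
    stratum: str = "combined"
    corrected: bool = False  # Haldane–Anscombe 0.5 applied
    @property
    def p_display(self) -> str:
        """p rendered for reports; values below 1e-4 print as '<0.0001'."""
        return "<0.0001" if self.p_two_tailed < 1e-4 else f"{self.p_two_tailed:.4f}"
    def as_dict(self) -> dict:
        return dict(self.__dict__)
def odds_ratio(table: TwoByTwoTable, z_crit: float = Z_95) -> OddsRatioResult:
    """Log-method odds ratio, 95% CI, and two-tailed z test for one 2x2 table."""
    a, b, c, d = (float(x) for x in table.counts)
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise UndefinedEstimateError(
            f"stratum {table.stratum!r}: a zero row or column leaves the odds ratio undefined"
        )
    corrected = 0.0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log((a / b) / (c / d))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = log_or / se
    return OddsRatioResult(
        odds_ratio=math.exp(log_or),
        log_se=se,
        ci_low=math.exp(log_or - z_crit * se),
        ci_high=math.exp(log_or + z_crit * se),
        z=z,
        p_two_tailed=float(2 * norm.sf(abs(z))),
        stratum=table.stratum,
        corrected=corrected,
    )
def build_two_by_two(
    alerts: pd.DataFrame,
    matches: pd.DataFrame,
    stratify_by: str | None = None,
    pre_period: int = 1,
    post_period: int = 2,
) -> list[TwoByTwoTable]:
    """2x2 tables of matched/unmatched alerts by period, one per stratum.
    ``stratify_by`` may be None (combined table only), ``scratch_level``
    or ``lick_level``; stratification uses the level of that metric at
    alert time (column ``<metric>_at_alert``).  A combined table is
    always appended last.  Alerts whose trigger was the other metric
    fall wherever their level sits — in particular, an alert at
    infrequent scratching can only have been lick-triggered.
    """
    if stratify_by not in STRATIFIERS:
        raise ConfigurationError(
            f"stratify_by: expected one of {STRATIFIERS}, got {stratify_by!r}"
        )
    matched = alerts["alert_id"].isin(set(matches["alert_id"]))
    post = alerts["period"] == post_period
    pre = alerts["period"] == pre_period
    def cell(mask) -> int:
        return int(mask.sum())
    tables: list[TwoByTwoTable] = []
    if stratify_by is not None:
        col = f"{stratify_by}_at_alert"
        if col not in alerts.columns:
            raise InputError(f"alerts: missing stratification column {col!r}")
        from .behavior import LEVEL_NAMES
        for level, name in enumerate(LEVEL_NAMES):
            in_level = alerts[col] == level
            tables.append(
                TwoByTwoTable(
                    a=cell(in_level & post & matched),
                    b=cell(in_level & post & ~matched),
                    c=cell(in_level & pre & matched),
                    d=cell(in_level & pre & ~matched),
                    stratum=name,
                )
            )
    tables.append(
        TwoByTwoTable(
            a=cell(post & matched),
            b=cell(post & ~matched),
            c=cell(pre & matched),
            d=cell(pre & ~matched),
            stratum="combined",
        )
    )
    return tables
def fraction(numerator: int, denominator: int) -> float:
    """Percentage 100 * numerator / denominator."""
    if denominator <= 0:
        raise InputError(f"denominator: must be positive, got {denominator}")
    return 100.0 * numerator / denominator
def results_frame(results) -> pd.DataFrame:
    """Tidy frame of OddsRatioResult records (stratum, OR, CI, z, p)."""
    rows = [r.as_dict() for r in results]
    return pd.DataFrame(rows)[
        ["stratum", "odds_ratio", "ci_low", "ci_high", "log_se", "z", "p_two_tailed", "corrected"]
    ]
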
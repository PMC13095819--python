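"""Pain-diary outcome analytics.

Daily diaries record continuous pain (min/avg/max on the 0-10 numeric
rating scale) and paroxysmal pain episodes (intensity, self-reported
duration in hours).  The paroxysmal burden of a day is its *pain volume*:
the sum over episodes of intensity x duration (NRS.hours), an
area-under-the-curve surrogate.

Analyses mirror a longitudinal single-arm design: a one-month baseline
(``m-1``), intervention weeks ``w1``/``w2``, post-intervention ``w3``/``w4``
and a descriptive long-term follow-up ``w12-w23``.  Group-level inference
uses linear mixed models with a random intercept per subject (REML), Wald z
tests on the period contrasts, and a likelihood-ratio test of the period
factor refitted under ML (an LRT on fixed effects is not valid under REML).
Per-patient contrasts use ordinary least squares, since a single subject
admits no random intercept.  The long-term follow-up period is summarized
descriptively only and never modelled: the shift from daily to weekly
self-assessment makes it incomparable.
"""

from __future__ import annotations

import datetime as _dt
import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

PERIODS = ("m-1", "w1", "w2", "w3", "w4", "w12-w23")
BASELINE = "m-1"
#: Weeks aggregated into the three analysis phases.
PHASES = {"m-1": "m-1", "w1": "w1w2", "w2": "w1w2", "w3": "w3w4", "w4": "w3w4"}
#: Follow-up period, descriptive only.
DESCRIPTIVE_ONLY = ("w12-w23",)

MEASURES = ("volume", "nrs_min", "nrs_avg", "nrs_max")


@dataclass(frozen=True)
class Episode:
    """One paroxysmal pain episode: NRS intensity and duration in hours."""

    intensity: float
    duration_h: float

    def __post_init__(self):
        if not 0 <= self.intensity <= 10:
            raise ValueError("episode intensity must lie on the 0-10 NRS")
        if self.duration_h <= 0:
            raise ValueError("episode duration must be positive")


@dataclass(frozen=True)
class DayRecord:
    date: _dt.date
    period: str
    nrs_min: float
    nrs_avg: float
    nrs_max: float
    episodes: tuple = ()

    def __post_init__(self):
        if self.period not in PERIODS:
            raise ValueError(f"unknown period {self.period!r}; expected one "
                             f"of {PERIODS}")
        if not (0 <= self.nrs_min <= self.nrs_avg <= self.nrs_max <= 10):
            raise ValueError("NRS triplet must satisfy 0 <= min <= avg <= "
                             "max <= 10")
        object.__setattr__(self, "episodes", tuple(self.episodes))


@dataclass
class PainDiary:
    """All daily records of one subject."""

    subject_id: str
    days: list[DayRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.days:
            rows.append({"subject_id": self.subject_id, "date": d.date,
                         "period": d.period, "nrs_min": d.nrs_min,
                         "nrs_avg": d.nrs_avg, "nrs_max": d.nrs_max,
                         "volume": pain_volume(d)})
        return pd.DataFrame(rows)


def pain_volume(day: DayRecord) -> float:
    """Daily paroxysmal pain volume: sum of intensity x duration (NRS.hours).

    Zero for a day without episodes; additive over episode sets.
    """
    return float(sum(ep.intensity * ep.duration_h for ep in day.episodes))


# ---------------------------------------------------------------------------
# Long-format I/O
# ---------------------------------------------------------------------------

def diaries_to_csv(diaries, path) -> None:
    """Write diaries in long format: one daily row plus one row per episode."""
    rows = []
    for diary in diaries:
        for d in diary.days:
            rows.append({"subject_id": diary.subject_id, "date": d.date,
                         "period": d.period, "row_type": "day",
                         "nrs_min": d.nrs_min, "nrs_avg": d.nrs_avg,
                         "nrs_max": d.nrs_max, "episode_intensity": "",
                         "episode_duration_h": ""})
            for ep in d.episodes:
                rows.append({"subject_id": diary.subject_id, "date": d.date,
                             "period": d.period, "row_type": "episode",
                             "nrs_min": "", "nrs_avg": "", "nrs_max": "",
                             "episode_intensity": ep.intensity,
                             "episode_duration_h": ep.duration_h})
    pd.DataFrame(rows).to_csv(path, index=False)


def diaries_from_csv(path) -> list[PainDiary]:
    df = pd.read_csv(path, parse_dates=["date"], dtype={"subject_id": str})
    diaries = []
    for sid, sub in df.groupby("subject_id", sort=True):
        days = []
        for date, day_rows in sub.groupby("date", sort=True):
            daily = day_rows[day_rows["row_type"] == "day"].iloc[0]
            eps = tuple(
                Episode(float(r["episode_intensity"]),
                        float(r["episode_duration_h"]))
                for _, r in day_rows[day_rows["row_type"] == "episode"].iterrows())
            days.append(DayRecord(date=date.date(), period=daily["period"],
                                  nrs_min=float(daily["nrs_min"]),
                                  nrs_avg=float(daily["nrs_avg"]),
                                  nrs_max=float(daily["nrs_max"]),
                                  episodes=eps))
        diaries.append(PainDiary(subject_id=str(sid), days=days))
    return diaries


def daily_values(diaries, measure: str = "volume") -> pd.DataFrame:
    """Long table of one value per subject-day: subject_id, period, value."""
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}")
    rows = []
    for diary in diaries:
        for d in diary.days:
            value = pain_volume(d) if measure == "volume" else getattr(d, measure)
            rows.append({"subject_id": diary.subject_id, "date": d.date,
                         "period": d.period, "value": float(value)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Period summaries (descriptive tables)
# ---------------------------------------------------------------------------

def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (5 rounds away from zero), as printed tables do."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent_variation(median: float, baseline_median: float) -> float | None:
    """Percent change of a period median vs the baseline median, rounded
    half-up to 2 decimals; ``None`` (NA) when the baseline median is 0."""
    if baseline_median == 0 or not np.isfinite(baseline_median):
        return None
    return round_half_up(100.0 * (median - baseline_median) / baseline_median)


def summarize_periods(diaries, measure: str = "volume",
                      grouping: str = "both") -> pd.DataFrame:
    """Quartiles of daily values per period, with percent variation of the
    median vs baseline.

    ``grouping='per-patient'`` summarizes each subject; ``'pooled'`` pools
    all subjects' daily values into rows labelled ``All``; ``'both'``
    concatenates the two.  Variation is NA when the baseline median is 0.
    """
    if grouping not in ("per-patient", "pooled", "both"):
        raise ValueError("grouping must be 'per-patient', 'pooled' or 'both'")
    df = daily_values(diaries, measure)
    if BASELINE not in set(df["period"]):
        raise ValueError(f"baseline period {BASELINE!r} is missing")

    def one_group(sub: pd.DataFrame, label: str):
        base_median = sub.loc[sub["period"] == BASELINE, "value"].median()
        out = []
        for period in PERIODS:
            vals = sub.loc[sub["period"] == period, "value"]
            if vals.empty:
                continue
            med = float(vals.median())
            var = (None if period == BASELINE
                   else percent_variation(med, base_median))
            out.append({"patient": label, "period": period,
                        "q25": float(vals.quantile(0.25)), "median": med,
                        "q75": float(vals.quantile(0.75)),
                        "variation_pct": np.nan if var is None else var})
        return out

    rows = []
    if grouping in ("per-patient", "both"):
        for sid, sub in df.groupby("subject_id", sort=True):
            rows += one_group(sub, str(sid))
    if grouping in ("pooled", "both"):
        rows += one_group(df, "All")
    return pd.DataFrame(rows)


_TABLE_FILES = {"nrs": "table_nrs_reference.csv",
                "volume": "table_volume_reference.csv"}


def load_reference_tables() -> dict[str, pd.DataFrame]:
    """Packaged normalized reference summary tables (continuous-pain NRS and
    paroxysmal volume) used for table-parity checks.

    Comma decimals are already normalized to dots.  Rows whose printed
    numbers are ambiguous between decimal and thousands separators carry
    ``ambiguous=True`` and are excluded from parity checks.
    """
    from importlib.resources import files

    out = {}
    for key, fname in _TABLE_FILES.items():
        with (files("mibci.data") / fname).open() as fh:
            out[key] = pd.read_csv(fh)
    return out


# ---------------------------------------------------------------------------
# Mixed models
# ---------------------------------------------------------------------------

@dataclass
class LmmResult:
    """Fixed-effect period contrasts with Wald z inference, the random-
    intercept variance, and an ML likelihood-ratio test of the period factor."""

    coefficients: pd.DataFrame  # index: contrast; estimate, se, z, p, ci_low, ci_high
    re_variance: float
    lrt_stat: float
    lrt_df: int
    lrt_p: float
    reml: bool
    n_obs: int
    n_subjects: int

    def __post_init__(self):
        c = self.coefficients
        assert np.allclose(c["ci_low"], c["estimate"] - 1.96 * c["se"],
                           atol=1e-9, equal_nan=True)
        assert np.allclose(c["ci_high"], c["estimate"] + 1.96 * c["se"],
                           atol=1e-9, equal_nan=True)


def _response_frame(diaries_or_frame, response: str) -> pd.DataFrame:
    """Per-day response values: raw ``nrs_avg`` or ``volume_variation``
    (daily percent change vs the subject's own baseline median volume)."""
    if isinstance(diaries_or_frame, pd.DataFrame):
        df = diaries_or_frame.copy()
        if "value" not in df.columns:
            raise ValueError("long data frame must carry a 'value' column")
        return df
    if response == "nrs_avg":
        df = daily_values(diaries_or_frame, "nrs_avg")
    elif response in ("volume_variation", "volume"):
        df = daily_values(diaries_or_frame, "volume")
        if response == "volume_variation":
            def to_var(sub):
                base = sub.loc[sub["period"] == BASELINE, "value"].median()
                if base == 0:
                    raise ValueError(
                        f"subject {sub['subject_id'].iloc[0]}: zero baseline "
                        "median volume, percent variation undefined")
                sub = sub.copy()
                sub["value"] = 100.0 * (sub["value"] / base - 1.0)
                return sub
            df = pd.concat([to_var(s) for _, s in
                            df.groupby("subject_id", sort=True)],
                           ignore_index=True)
    else:
        raise ValueError("response must be 'volume_variation', 'volume' or "
                         "'nrs_avg'")
    return df


def _fit_mixed(df: pd.DataFrame, factor: str, levels) -> LmmResult:
    import statsmodels.formula.api as smf
    from scipy import stats

    df = df[df[factor].isin(levels)].copy()
    df[factor] = pd.Categorical(df[factor], categories=list(levels))
    formula = f"value ~ C({factor}, Treatment('{BASELINE}'))"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = smf.mixedlm(formula, df, groups=df["subject_id"]).fit(reml=True)
        # LRT on the fixed period factor must compare ML fits.
        full_ml = smf.mixedlm(formula, df, groups=df["subject_id"]).fit(reml=False)
        red_ml = smf.mixedlm("value ~ 1", df, groups=df["subject_id"]).fit(reml=False)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lrt = 2.0 * (full_ml.llf - red_ml.llf)
    # degenerate fits (zero residual variance) yield non-finite likelihoods
    lrt = max(0.0, lrt) if np.isfinite(lrt) else 0.0
    lrt_df = len(levels) - 1
    rows = []
    for name, level in zip(full.params.index[1:len(levels)], list(levels)[1:]):
        est, se = float(full.params[name]), float(full.bse[name])
        z = est / se if se > 0 else np.nan
        rows.append({"contrast": f"{BASELINE} vs {level}", "estimate": est,
                     "se": se, "z": z,
                     "p": 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                     "ci_low": est - 1.96 * se, "ci_high": est + 1.96 * se})
    coefs = pd.DataFrame(rows).set_index("contrast")
    return LmmResult(coefficients=coefs,
                     re_variance=float(full.cov_re.iloc[0, 0]),
                     lrt_stat=lrt, lrt_df=lrt_df,
                     lrt_p=float(stats.chi2.sf(lrt, lrt_df)),
                     reml=True, n_obs=len(df),
                     n_subjects=df["subject_id"].nunique())


def _fit_per_patient(df: pd.DataFrame, factor: str, levels) -> pd.DataFrame:
    """Per-subject OLS with Wald t tests (single subjects admit no random
    intercept); one row per subject x contrast."""
    import statsmodels.formula.api as smf

    df = df[df[factor].isin(levels)].copy()
    rows = []
    for sid, sub in df.groupby("subject_id", sort=True):
        sub = sub.copy()
        sub[factor] = pd.Categorical(sub[factor], categories=list(levels))
        fit = smf.ols(f"value ~ C({factor}, Treatment('{BASELINE}'))",
                      sub).fit()
        for name, level in zip(fit.params.index[1:], list(levels)[1:]):
            rows.append({"patient": str(sid),
                         "contrast": f"{BASELINE} vs {level}",
                         "coef": float(fit.params[name]),
                         "se": float(fit.bse[name]),
                         "p": float(fit.pvalues[name])})
    return pd.DataFrame(rows)


def _phase_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df[~df["period"].isin(DESCRIPTIVE_ONLY)].copy()
    df["phase"] = df["period"].map(PHASES)
    return df


def fit_phase_lmm(diaries, response: str = "volume_variation",
                  per_patient: bool = False):
    """Random-intercept model of the daily response on the three study
    phases (baseline / intervention w1-w2 / post-intervention w3-w4).

    Returns an :class:`LmmResult` (group level) or, with
    ``per_patient=True``, a per-subject OLS contrast table.  A single
    subject is redirected to the per-patient variant with a warning.
    """
    df = _phase_frame(_response_frame(diaries, response))
    levels = (BASELINE, "w1w2", "w3w4")
    if per_patient:
        return _fit_per_patient(df, "phase", levels)
    if df["subject_id"].nunique() < 2:
        warnings.warn("single subject: falling back to per-patient OLS")
        return _fit_per_patient(df, "phase", levels)
    return _fit_mixed(df, "phase", levels)


def fit_weekly_lmm(diaries, response: str = "volume_variation",
                   per_patient: bool = False):
    """As :func:`fit_phase_lmm` with a five-level week factor
    (m-1, w1, w2, w3, w4), contrasts vs baseline."""
    df = _response_frame(diaries, response)
    df = df[~df["period"].isin(DESCRIPTIVE_ONLY)].copy()
    levels = (BASELINE, "w1", "w2", "w3", "w4")
    if per_patient:
        return _fit_per_patient(df, "period", levels)
    if df["subject_id"].nunique() < 2:
        warnings.warn("single subject: falling back to per-patient OLS")
        return _fit_per_patient(df, "period", levels)
    return _fit_mixed(df, "period", levels)
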
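"""Crude event rates, nested hospitalisation models, and diagnostics.

Hospitalisation is modelled as time to first admission from the start of
follow-up, censoring at death or the administrative end of follow-up, with
proportional-hazards models stratified by HIV status fitted at four nesting
levels: medication count alone; plus demographics (age per 10 years, sex,
race); plus physiological frailty (per 5 points); plus the drug-interaction
index category. The sequence decomposes how much of the medication-count
association each block explains. Crude rates per 1000 person-years with
Poisson-exact intervals, Pearson correlation summaries, and a proportional-
hazards check based on covariate interactions with follow-up time round out
the analysis.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import proportional_hazard_test
from scipy import stats

from .index import CATEGORIES, NO_KPDI, QUINTILE_LABELS

logger = logging.getLogger(__name__)

ADMINISTRATIVE_END = dt.date(2019, 3, 31)
FOLLOWUP_START = dt.date(2009, 10, 1)

MODEL_LEVELS = ["unadjusted", "demographics", "+frailty", "+kpdi_index"]
RACE_LEVELS = ["white", "black", "hispanic", "other"]  # white non-Hispanic is reference
#: KPDI category indicator levels; quintile 2 is the reference.
KPDI_REFERENCE = "q2"


@dataclass(frozen=True)
class RateEstimate:
    """Crude first-event rate per 1000 person-years with exact Poisson CI."""

    events: int
    person_years: float
    rate: float
    ci_low: float
    ci_high: float


def crude_rate(time_days: np.ndarray | pd.Series, events: np.ndarray | pd.Series) -> RateEstimate:
    """First-event rate per 1000 person-years.

    ``time_days`` is each patient's follow-up to first event or censoring;
    the 95% CI is Poisson-exact (chi-square inversion). Zero person-years
    is an error; zero events gives rate 0 with CI lower bound 0.
    """
    time_days = np.asarray(time_days, dtype=float)
    events_arr = np.asarray(events, dtype=bool)
    person_years = time_days.sum() / 365.25
    if person_years <= 0:
        raise ValueError("zero person-years of follow-up")
    k = int(events_arr.sum())
    low = stats.chi2.ppf(0.025, 2 * k) / 2 if k > 0 else 0.0
    high = stats.chi2.ppf(0.975, 2 * (k + 1)) / 2
    return RateEstimate(
        events=k,
        person_years=float(person_years),
        rate=1000.0 * k / person_years,
        ci_low=1000.0 * low / person_years,
        ci_high=1000.0 * high / person_years,
    )


def _design_columns(frame: pd.DataFrame, level: str) -> list[str]:
    cols = ["non_art_count"]
    if level in {"demographics", "+frailty", "+kpdi_index"}:
        cols += ["age_per_10", "female"]
        cols += [f"race_{r}" for r in RACE_LEVELS if r != "white"]
    if level in {"+frailty", "+kpdi_index"}:
        cols += ["frailty_per_5"]
    if level == "+kpdi_index":
        cols += [
            f"kpdi_{c}" for c in CATEGORIES if c != KPDI_REFERENCE
        ]
    return [c for c in cols if c in frame.columns]


def build_design(frame: pd.DataFrame) -> pd.DataFrame:
    """Encode the analysis covariates from a tidy patient table.

    Expects columns: time_days, event, non_art_count, age_years, sex
    ('male'/'female'), race (one of white/black/hispanic/other; missing is
    merged into other), frailty, kpdi_category. Produces the per-unit
    codings used throughout: age per 10 years, frailty per 5 points,
    indicator dummies with the conventional references (male, White
    non-Hispanic, interaction-index quintile 2).
    """
    out = pd.DataFrame(
        {
            "time_days": frame["time_days"].astype(float),
            "event": frame["event"].astype(bool),
            "non_art_count": frame["non_art_count"].astype(float),
        },
        index=frame.index,
    )
    if "age_years" in frame:
        out["age_per_10"] = frame["age_years"].astype(float) / 10.0
    if "sex" in frame:
        out["female"] = (frame["sex"].astype(str).str.lower() == "female").astype(float)
    if "race" in frame:
        race = frame["race"].astype(str).str.lower().where(
            frame["race"].astype(str).str.lower().isin(RACE_LEVELS), "other"
        )
        for r in RACE_LEVELS:
            if r != "white":
                out[f"race_{r}"] = (race == r).astype(float)
    if "frailty" in frame:
        out["frailty_per_5"] = frame["frailty"].astype(float) / 5.0
    if "kpdi_category" in frame:
        cat = frame["kpdi_category"].astype(str)
        for c in CATEGORIES:
            if c != KPDI_REFERENCE:
                out[f"kpdi_{c}"] = (cat == c).astype(float)
    return out


def _fit_level(design: pd.DataFrame, level: str) -> tuple[CoxPHFitter | None, list[str], list[str]]:
    cols = _design_columns(design, level)
    kept, dropped = [], []
    for c in cols:
        if design[c].nunique() > 1:
            kept.append(c)
        else:
            dropped.append(c)
    if dropped:
        logger.warning("level %s: dropping constant covariates %s", level, dropped)
    data = design[["time_days", "event", *kept]]
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col="time_days", event_col="event")
    except (ConvergenceError, ValueError, np.linalg.LinAlgError) as err:
        logger.warning("level %s failed to converge: %s", level, err)
        return None, kept, dropped
    cph.training_frame = data  # retained for the proportional-hazards check
    return cph, kept, dropped


@dataclass
class NestedHazardResults:
    """Hazard ratios with 95% CIs for each nesting level and stratum.

    ``table`` is long-format: stratum, level, covariate, hr, ci_low,
    ci_high, p. ``fitters`` keeps the underlying fitted models for
    diagnostics (proportional-hazards checks, log-likelihoods).
    """

    table: pd.DataFrame
    fitters: dict[tuple[str, str], CoxPHFitter]
    dropped: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    def hazard_ratio(self, stratum: str, level: str, covariate: str) -> float:
        row = self.table[
            (self.table["stratum"] == stratum)
            & (self.table["level"] == level)
            & (self.table["covariate"] == covariate)
        ]
        if row.empty:
            raise KeyError((stratum, level, covariate))
        return float(row["hr"].iloc[0])

    def log_likelihoods(self, stratum: str) -> dict[str, float]:
        return {
            level: float(f.log_likelihood_)
            for (s, level), f in self.fitters.items()
            if s == stratum
        }

    def summary(self) -> str:
        pivot = self.table.assign(
            cell=lambda t: t.apply(
                lambda r: f"{r.hr:.2f} ({r.ci_low:.2f}-{r.ci_high:.2f})", axis=1
            )
        ).pivot_table(
            index=["stratum", "covariate"],
            columns="level",
            values="cell",
            aggfunc="first",
        )
        ordered = [l for l in MODEL_LEVELS if l in pivot.columns]
        return pivot[ordered].fillna("..").to_string()

    def check_ph(self, stratum: str, level: str = "+kpdi_index") -> pd.DataFrame:
        fitter = self.fitters[(stratum, level)]
        return check_ph(fitter)


class NestedHospitalisationModel:
    """Nested proportional-hazards models of time to first hospitalisation.

    Built from a tidy per-patient table with columns: patient_id, hiv
    (bool), time_days, event, non_art_count, age_years, sex, race, frailty,
    kpdi_category. ``fit`` runs the four nesting levels within each HIV
    stratum on the identical risk set and returns
    :class:`NestedHazardResults`. Ties use the Efron approximation
    (lifelines' default).
    """

    def __init__(self, data: pd.DataFrame, strata_col: str = "hiv"):
        required = {"time_days", "event", "non_art_count", strata_col}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        self.data = data.reset_index(drop=True)
        self.strata_col = strata_col

    @classmethod
    def from_components(
        cls,
        patients: pd.DataFrame,
        counts: pd.DataFrame,
        scores: pd.DataFrame,
        followup: pd.DataFrame,
    ) -> "NestedHospitalisationModel":
        """Assemble the analysis table from pipeline component outputs."""
        table = (
            patients.merge(counts, on="patient_id", how="left")
            .merge(
                scores[["patient_id", "category"]].rename(
                    columns={"category": "kpdi_category"}
                ),
                on="patient_id",
                how="left",
            )
            .merge(followup, on="patient_id", how="inner")
        )
        table["kpdi_category"] = table["kpdi_category"].fillna(NO_KPDI)
        for col in ("total_count", "non_art_count"):
            if col in table:
                table[col] = table[col].fillna(0)
        return cls(table)

    def fit(self, levels: list[str] | None = None) -> NestedHazardResults:
        levels = levels or MODEL_LEVELS
        rows = []
        fitters: dict[tuple[str, str], CoxPHFitter] = {}
        dropped: dict[tuple[str, str], list[str]] = {}
        for stratum_value, sub in self.data.groupby(self.strata_col, sort=True):
            stratum = _stratum_name(stratum_value)
            design = build_design(sub)
            for level in levels:
                cph, kept, drop = _fit_level(design, level)
                dropped[(stratum, level)] = drop
                if cph is None:
                    continue
                fitters[(stratum, level)] = cph
                summ = cph.summary
                for cov in kept:
                    # cap wild coefficients from near-separated small strata
                    # so the exponentiation stays finite
                    hr, lo, hi = np.exp(
                        np.clip(
                            summ.loc[
                                cov, ["coef", "coef lower 95%", "coef upper 95%"]
                            ].astype(float),
                            -500,
                            500,
                        )
                    )
                    rows.append(
                        {
                            "stratum": stratum,
                            "level": level,
                            "covariate": cov,
                            "hr": float(hr),
                            "ci_low": float(lo),
                            "ci_high": float(hi),
                            "p": float(summ.loc[cov, "p"]),
                        }
                    )
        table = pd.DataFrame(
            rows, columns=["stratum", "level", "covariate", "hr", "ci_low", "ci_high", "p"]
        )
        return NestedHazardResults(table=table, fitters=fitters, dropped=dropped)


def _stratum_name(value) -> str:
    if isinstance(value, (bool, np.bool_)):
        return "hiv_positive" if value else "hiv_negative"
    return str(value)


def fit_nested_models(
    patients: pd.DataFrame,
    counts: pd.DataFrame,
    scores: pd.DataFrame,
    followup: pd.DataFrame,
) -> NestedHazardResults:
    """Functional entry point mirroring the model class."""
    return NestedHospitalisationModel.from_components(
        patients, counts, scores, followup
    ).fit()


def check_ph(
    fitter: CoxPHFitter, data: pd.DataFrame | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Proportional-hazards check via covariate × log(time) interactions.

    Uses the score test for a time-varying coefficient of the form
    b0 + b1·log(t) — the Schoenfeld-residual test with a log time
    transform, which is the score test for exactly that interaction.
    Returns one row per covariate with the test statistic, p-value and a
    flag at ``alpha``. An empty covariate list yields an empty frame.
    """
    cols = ["covariate", "test_stat", "p", "flagged"]
    if len(fitter.params_) == 0:
        return pd.DataFrame(columns=cols)
    if data is None:
        data = getattr(fitter, "training_frame", None)
        if data is None:
            raise ValueError("pass the training data or fit via this package")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = proportional_hazard_test(fitter, data, time_transform="log")
    summ = res.summary.reset_index()
    name_col = summ.columns[0]
    out = pd.DataFrame(
        {
            "covariate": [_scalar_name(v) for v in summ[name_col]],
            "test_stat": summ["test_statistic"].astype(float),
            "p": summ["p"].astype(float),
        }
    )
    out["flagged"] = out["p"] < alpha
    return out[cols]


def _scalar_name(value) -> str:
    # lifelines indexes the test summary by (covariate, transform) tuples
    # when several transforms are requested; unwrap either shape.
    if isinstance(value, tuple):
        return str(value[0])
    return str(value)


def correlations(
    measures: pd.DataFrame,
    group: pd.Series | None = None,
) -> pd.DataFrame:
    """Pearson correlations between every pair of measure columns.

    Computed overall and, when ``group`` (indexed like ``measures``) is
    given, within each stratum. Pairs with zero variance are reported with
    NaN r and a note rather than an error.
    """
    def _block(frame: pd.DataFrame, label: str) -> list[dict]:
        rows = []
        cols = list(frame.columns)
        for i, a in enumerate(cols):
            for b in cols[i + 1 :]:
                pair = frame[[a, b]].dropna()
                if pair[a].nunique() < 2 or pair[b].nunique() < 2:
                    rows.append(
                        {"stratum": label, "x": a, "y": b, "r": np.nan, "n": len(pair),
                         "note": "zero variance"}
                    )
                    continue
                r, _ = stats.pearsonr(pair[a], pair[b])
                rows.append({"stratum": label, "x": a, "y": b, "r": float(r),
                             "n": len(pair), "note": ""})
        return rows

    rows = _block(measures, "overall")
    if group is not None:
        for g, idx in measures.groupby(group.reindex(measures.index)).groups.items():
            rows += _block(measures.loc[idx], _stratum_name(g))
    return pd.DataFrame(rows, columns=["stratum", "x", "y", "r", "n", "note"])
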
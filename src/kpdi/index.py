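"""Mortality-weighted pairwise drug-interaction (KPDI) index.

Each interacting drug pair that is sufficiently prevalent receives a weight:
the bagged (bootstrap-aggregated) log hazard of all-cause mortality for
exposure to that pair, estimated among HIV-negative patients with adjustment
for physiological frailty. Within each bootstrap resample a proportional-
hazards model is fitted per pair; pair coefficients whose Wald p-value
exceeds the significance level are set to zero for that resample (a hazard
ratio of 1), so weak or unstable pairs shrink toward zero weight. A
patient's index is the sum of pair weights scaled by the fraction of the
observation year the pair was co-taken, on the log-hazard scale; index
scores are then cut into quintiles holding approximately equal numbers of
reference-group deaths, with patients carrying no interacting pair kept as
a separate category.

Organised as a model/results pair: :class:`KPDIIndexModel` holds the data
and settings, ``fit`` runs the bagging and returns
:class:`KPDIIndexResults` with the weight table, patient scores, quintile
cutpoints and a summary view. The underlying steps (`filter_prevalent`,
`bagged_weights`, `score_patients`, `assign_quintiles`) are module
functions usable on their own.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .network import InteractionNetwork

logger = logging.getLogger(__name__)

QUINTILE_LABELS = ["q1", "q2", "q3", "q4", "q5"]
NO_KPDI = "no_kpdi"
CATEGORIES = [NO_KPDI] + QUINTILE_LABELS

WEIGHT_COLUMNS = [
    "drug_a",
    "drug_b",
    "beta_mean",
    "ci_low",
    "ci_high",
    "prevalence",
    "n_significant",
]


def filter_prevalent(
    coocc: pd.DataFrame, net: InteractionNetwork, min_prevalence: int = 10
) -> list[tuple[str, str]]:
    """Interacting pairs present in at least ``min_prevalence`` patients.

    Low-prevalence pairs are dropped before weighting — with fewer than ten
    exposed patients a pair-level hazard estimate is too unstable to carry
    weight. Returns sorted unordered pairs (a < b).
    """
    if coocc.empty:
        return []
    is_edge = [
        net.has_interaction(a, b) for a, b in zip(coocc["drug_a"], coocc["drug_b"])
    ]
    edges = coocc[np.asarray(is_edge, dtype=bool)]
    prevalence = edges.groupby(["drug_a", "drug_b"])["patient_id"].nunique()
    keep = prevalence[prevalence >= min_prevalence]
    return sorted(keep.index.tolist())


def exposure_matrix(
    coocc: pd.DataFrame,
    pairs: list[tuple[str, str]],
    patient_ids: list[str],
    window_length: int | None = None,
) -> np.ndarray:
    """Patients × pairs matrix of exposure.

    Binary indicators by default; with ``window_length`` set, entries are
    overlap-day fractions of the window (disjoint overlap spells already
    summed by the co-occurrence step).
    """
    mat = np.zeros((len(patient_ids), len(pairs)), dtype=float)
    if coocc.empty or not pairs:
        return mat
    p_index = {p: i for i, p in enumerate(patient_ids)}
    pair_index = {p: j for j, p in enumerate(pairs)}
    for patient, a, b, days in zip(
        coocc["patient_id"], coocc["drug_a"], coocc["drug_b"], coocc["overlap_days"]
    ):
        i = p_index.get(patient)
        j = pair_index.get((a, b))
        if i is None or j is None:
            continue
        mat[i, j] = 1.0 if window_length is None else min(days / window_length, 1.0)
    return mat


def _fit_pair_cox(
    durations: np.ndarray,
    events: np.ndarray,
    exposure: np.ndarray,
    covariates: np.ndarray,
    covariate_names: list[str],
) -> tuple[float, float] | None:
    """Cox fit of mortality on one pair's exposure plus adjustment covariates.

    Returns (beta, p) for the exposure coefficient, or None when the model
    is degenerate (no events, constant exposure) or fails to converge.
    """
    if events.sum() == 0:
        return None
    if exposure.min() == exposure.max():
        return None
    data = {"T": durations, "E": events, "exposure": exposure}
    for k, name in enumerate(covariate_names):
        data[name] = covariates[:, k]
    frame = pd.DataFrame(data)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(frame, duration_col="T", event_col="E")
    except (ConvergenceError, ValueError, np.linalg.LinAlgError):
        return None
    beta = float(cph.params_["exposure"])
    p = float(cph.summary.loc["exposure", "p"])
    return beta, p


def bagged_weights(
    durations: np.ndarray | pd.Series,
    events: np.ndarray | pd.Series,
    frailty: np.ndarray | pd.Series,
    exposures: np.ndarray,
    pairs: list[tuple[str, str]],
    n_bags: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    significant_only_mean: bool = False,
) -> pd.DataFrame:
    """Bootstrap-aggregated per-pair mortality log-hazards.

    For each of ``n_bags`` with-replacement resamples of patients (same
    size as the input — patients are the resampling unit) and each pair, a
    proportional-hazards model of all-cause mortality on the pair-exposure
    indicator and the frailty score is fitted; the exposure coefficient is
    recorded when its two-sided Wald p-value is below ``alpha`` and set to
    zero otherwise (equivalently, a non-significant resample contributes a
    hazard ratio of 1). ``beta_mean`` averages over all bags — the
    shrunken-mean reading, under which unstable pairs get low-to-zero
    weight; ``significant_only_mean=True`` instead averages only the
    significant resamples. The 95% CI is the 2.5/97.5 percentile of the
    across-bag values; degenerate resamples (no deaths, constant exposure,
    non-convergence) contribute zero and are logged.
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    frailty = np.asarray(frailty, dtype=float)
    n = len(durations)
    if exposures.shape != (n, len(pairs)):
        raise ValueError("exposures must be (n_patients, n_pairs)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    betas = np.zeros((n_bags, len(pairs)))
    significant = np.zeros((n_bags, len(pairs)), dtype=bool)
    n_degenerate = 0
    for b in range(n_bags):
        idx = rng.integers(0, n, size=n)
        dur_b, ev_b, fr_b = durations[idx], events[idx], frailty[idx]
        cov_b = fr_b[:, None]
        for j in range(len(pairs)):
            fit = _fit_pair_cox(dur_b, ev_b, exposures[idx, j], cov_b, ["frailty"])
            if fit is None:
                n_degenerate += 1
                continue
            beta, p = fit
            if p < alpha:
                betas[b, j] = beta
                significant[b, j] = True
    if n_degenerate:
        logger.warning(
            "%d degenerate pair-resample fits assigned zero", n_degenerate
        )

    prevalence = (exposures > 0).sum(axis=0)
    rows = []
    for j, (a, b_) in enumerate(pairs):
        col = betas[:, j]
        n_sig = int(significant[:, j].sum())
        if significant_only_mean:
            beta_mean = float(col[significant[:, j]].mean()) if n_sig else 0.0
        else:
            beta_mean = float(col.mean())
        ci_low, ci_high = np.percentile(col, [2.5, 97.5])
        rows.append(
            {
                "drug_a": a,
                "drug_b": b_,
                "beta_mean": beta_mean,
                "ci_low": float(min(ci_low, beta_mean)),
                "ci_high": float(max(ci_high, beta_mean)),
                "prevalence": int(prevalence[j]),
                "n_significant": n_sig,
            }
        )
    return pd.DataFrame(rows, columns=WEIGHT_COLUMNS)


def score_patients(
    weights: pd.DataFrame,
    coocc: pd.DataFrame,
    window_length: int,
    patient_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Exposure-weighted index score per patient, on the log-hazard scale.

    score_i = Σ_j beta_mean_j × overlap_days_ij / window_length over the
    patient's in-scope (weighted) pairs. ``n_pairs`` counts those pairs;
    patients with none — including patients absent from the co-occurrence
    matrix but listed in ``patient_ids`` — score 0 and are categorised
    ``no_kpdi``.
    """
    if patient_ids is None:
        patient_ids = sorted(coocc["patient_id"].unique()) if not coocc.empty else []
    base = pd.DataFrame({"patient_id": list(patient_ids)})
    if weights.empty or coocc.empty:
        out = base.assign(score=0.0, n_pairs=0)
    else:
        merged = coocc.merge(
            weights[["drug_a", "drug_b", "beta_mean"]], on=["drug_a", "drug_b"]
        )
        merged["contribution"] = (
            merged["beta_mean"] * merged["overlap_days"] / window_length
        )
        per_patient = merged.groupby("patient_id").agg(
            score=("contribution", "sum"), n_pairs=("contribution", "size")
        )
        out = base.merge(per_patient, on="patient_id", how="left")
        out["score"] = out["score"].fillna(0.0)
        out["n_pairs"] = out["n_pairs"].fillna(0).astype(int)
    out["category"] = np.where(out["n_pairs"] == 0, NO_KPDI, "")
    return out[["patient_id", "score", "n_pairs", "category"]]


@dataclass
class QuintileAssignment:
    categories: pd.Series
    cutpoints: np.ndarray
    reference_death_split: list[int]
    target_deaths_per_quintile: float


def assign_quintiles(
    scores: pd.DataFrame,
    deaths: pd.Series,
    reference: pd.Series,
) -> QuintileAssignment:
    """Cut index scores into quintiles balanced on reference-group deaths.

    Cutpoints are derived only from reference-group patients (the
    HIV-negative comparators) who carry at least one in-scope pair, so that
    each quintile holds as close to one fifth of their deaths as the score
    ties allow — tied scores are never split. The cutpoints are then
    applied to every scored patient in both groups; ``no_kpdi`` patients
    keep their separate category. ``deaths`` and ``reference`` are boolean
    series indexed by patient_id.

    Raises ``ValueError`` with fewer than 5 reference deaths.
    """
    table = scores.set_index("patient_id")
    table["death"] = deaths.reindex(table.index, fill_value=False).astype(bool)
    table["reference"] = reference.reindex(table.index, fill_value=False).astype(bool)
    ref = table[table["reference"] & (table["n_pairs"] > 0)]
    total_deaths = int(ref["death"].sum())
    if total_deaths < 5:
        raise ValueError(
            f"only {total_deaths} reference-group deaths; quintiles need >= 5"
        )

    by_score = ref.groupby("score")["death"].sum().sort_index()
    target = total_deaths / 5.0
    cutpoints = _death_balanced_cutpoints(
        by_score.index.to_numpy(), by_score.to_numpy(), target
    )

    labels = np.searchsorted(cutpoints, table["score"].to_numpy(), side="left")
    categories = pd.Series(
        [QUINTILE_LABELS[min(i, 4)] for i in labels],
        index=table.index,
        name="category",
    )
    categories[table["n_pairs"] == 0] = NO_KPDI

    ref_cats = categories[table["reference"] & (table["n_pairs"] > 0)]
    achieved = [
        int(table.loc[ref_cats[ref_cats == lab].index, "death"].sum())
        for lab in QUINTILE_LABELS
    ]
    return QuintileAssignment(
        categories=categories,
        cutpoints=np.asarray(cutpoints, dtype=float),
        reference_death_split=achieved,
        target_deaths_per_quintile=target,
    )


def _death_balanced_cutpoints(
    unique_scores: np.ndarray, deaths_per_score: np.ndarray, target: float
) -> np.ndarray:
    """Four cutpoints minimising the worst quintile's deviation from ``target``.

    Only boundaries at death-carrying scores can change the split, so the
    search is over those positions; a dynamic program finds the exact
    optimum (equivalent to enumerating every cutpoint combination), with
    tied scores kept together by construction. Segments may be empty when
    ties make an even split impossible.
    """
    death_pos = np.flatnonzero(deaths_per_score > 0)
    group_scores = unique_scores[death_pos]
    group_deaths = deaths_per_score[death_pos].astype(float)
    if len(group_scores) > 6000:
        # keep the quadratic program tractable at very large cohort sizes;
        # binning tied-by-construction groups moves the optimum negligibly
        bins = pd.cut(np.arange(len(group_scores)), 6000, labels=False)
        frame = pd.DataFrame({"b": bins, "s": group_scores, "d": group_deaths})
        agg = frame.groupby("b").agg(s=("s", "max"), d=("d", "sum"))
        group_scores, group_deaths = agg["s"].to_numpy(), agg["d"].to_numpy()
    cum = np.concatenate([[0.0], group_deaths.cumsum()])
    m = len(group_scores)
    # seg[i, j] = deviation of a segment holding death groups (i, j]
    seg = np.abs(cum[None, :] - cum[:, None] - target)
    seg[np.tril_indices(m + 1, k=-1)] = np.inf
    # f[i]: best worst-segment deviation covering the first i groups
    f = np.abs(cum - target)
    choices = []
    for _ in range(3):
        stacked = np.maximum(f[:, None], seg)
        choices.append(np.argmin(stacked, axis=0))
        f = np.min(stacked, axis=0)
    final_dev = np.abs(cum[-1] - cum - target)
    best = int(np.argmin(np.maximum(f, final_dev)))
    bounds = [best]
    for choice in reversed(choices):
        bounds.append(int(choice[bounds[-1]]))
    bounds = bounds[::-1]  # group counts covered at each of the four boundaries
    cutpoints = [
        float(group_scores[b - 1]) if b > 0 else float(unique_scores[0]) - 1.0
        for b in bounds
    ]
    return np.asarray(cutpoints, dtype=float)


def optimal_death_split_deviation(
    scores: np.ndarray, deaths: np.ndarray
) -> float:
    """Best achievable max deviation from an even death split, by exhaustive search.

    Dynamic program over every feasible combination of the four cutpoints
    placed at unique-score boundaries (equivalent to enumerating all
    cutpoint choices), minimising the maximum absolute deviation of any
    quintile's death count from one fifth of the total. Serves as the
    independent oracle for :func:`assign_quintiles`.
    """
    order = np.argsort(scores)
    s, d = scores[order], deaths[order].astype(float)
    frame = pd.DataFrame({"s": s, "d": d}).groupby("s")["d"].sum()
    cum = np.concatenate([[0.0], frame.to_numpy().cumsum()])  # cum[i] = deaths in first i groups
    m = len(cum) - 1
    target = cum[-1] / 5.0
    big = np.inf
    # best[i] after q segments = minimal max-deviation covering groups [0, i)
    best = np.full(m + 1, big)
    for i in range(1, m + 1):
        best[i] = abs(cum[i] - target)
    for _ in range(3):
        nxt = np.full(m + 1, big)
        for i in range(1, m + 1):
            # deviation of segment (k, i] for k in [1, i)
            k = np.arange(1, i)
            if len(k) == 0:
                continue
            seg_dev = np.abs((cum[i] - cum[k]) - target)
            nxt[i] = np.min(np.maximum(best[k], seg_dev))
        best = nxt
    # final (fifth) segment closes at m
    k = np.arange(1, m)
    if len(k) == 0:
        return abs(cum[-1] - target)
    final_dev = np.abs((cum[m] - cum[k]) - target)
    return float(np.min(np.maximum(best[k], final_dev)))


@dataclass
class KPDIIndexModel:
    """Data + settings for building the mortality-weighted interaction index.

    Parameters
    ----------
    followup : DataFrame with patient_id, time_days, death (bool) —
        mortality follow-up for weight estimation.
    frailty : Series of physiological-frailty scores indexed by patient_id.
    coocc : co-occurrence matrix (window-clipped).
    net : interaction network.
    reference : boolean Series by patient_id marking the HIV-negative
        stratum on which weights and quintile cutpoints are derived.
    window_length : observation-window length in days (exposure scaling).
    min_prevalence : minimum exposed patients for a pair to be weighted.
    """

    followup: pd.DataFrame
    frailty: pd.Series
    coocc: pd.DataFrame
    net: InteractionNetwork
    reference: pd.Series
    window_length: int = 365
    min_prevalence: int = 10

    def fit(
        self,
        n_bags: int = 1000,
        alpha: float = 0.05,
        seed: int | np.random.Generator = 0,
        significant_only_mean: bool = False,
    ) -> "KPDIIndexResults":
        ref_ids = [
            p
            for p in self.followup["patient_id"]
            if bool(self.reference.get(p, False))
        ]
        ref_fu = self.followup.set_index("patient_id").loc[ref_ids]
        ref_coocc = (
            self.coocc[self.coocc["patient_id"].isin(set(ref_ids))]
            if not self.coocc.empty
            else self.coocc
        )
        pairs = filter_prevalent(ref_coocc, self.net, self.min_prevalence)
        exposures = exposure_matrix(ref_coocc, pairs, ref_ids)
        weights = bagged_weights(
            ref_fu["time_days"].to_numpy(),
            ref_fu["death"].to_numpy(),
            self.frailty.reindex(ref_ids).to_numpy(),
            exposures,
            pairs,
            n_bags=n_bags,
            alpha=alpha,
            seed=seed,
            significant_only_mean=significant_only_mean,
        )
        all_ids = list(self.followup["patient_id"])
        scores = score_patients(weights, self.coocc, self.window_length, all_ids)
        deaths = self.followup.set_index("patient_id")["death"].astype(bool)
        quintiles = assign_quintiles(scores, deaths, self.reference)
        scores = scores.drop(columns=["category"]).merge(
            quintiles.categories.rename("category"),
            left_on="patient_id",
            right_index=True,
        )
        return KPDIIndexResults(
            model=self,
            pairs=pairs,
            weights=weights,
            scores=scores,
            quintiles=quintiles,
            n_bags=n_bags,
            alpha=alpha,
        )


@dataclass
class KPDIIndexResults:
    """Fitted index: weight table, patient scores and quintile cutpoints."""

    model: KPDIIndexModel
    pairs: list[tuple[str, str]]
    weights: pd.DataFrame
    scores: pd.DataFrame
    quintiles: QuintileAssignment
    n_bags: int
    alpha: float
    extras: dict = field(default_factory=dict)

    @property
    def score_range(self) -> tuple[float, float]:
        s = self.scores["score"]
        return float(s.min()), float(s.max())

    def summary(self) -> str:
        lines = [
            "KPDI Index fit",
            f"  pairs weighted: {len(self.pairs)} "
            f"(min prevalence {self.model.min_prevalence})",
            f"  bags: {self.n_bags}, significance level: {self.alpha}",
            f"  score range: {self.score_range[0]:.3f} to {self.score_range[1]:.3f}",
            f"  quintile cutpoints: "
            + ", ".join(f"{c:.4f}" for c in self.quintiles.cutpoints),
            f"  reference deaths per quintile: {self.quintiles.reference_death_split}"
            f" (target {self.quintiles.target_deaths_per_quintile:.1f})",
            "",
            self.weights.to_string(index=False),
        ]
        return "\n".join(lines)
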
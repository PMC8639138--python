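"""Synthetic study generator: network, cohort, prescriptions and outcomes.

Generates complete, licence-free stand-ins for the inputs the analysis
expects — a drug vocabulary and interaction edge list, a cohort with
group-specific frailty, pharmacy fill histories, and survival outcomes —
with a ground-truth manifest sufficient to recompute every planted effect.

The generator's statistical structure mirrors the cohort the analysis was
designed for:

* an interaction network over a few hundred drugs (Erdős–Rényi by default,
  or a hub variant in which designated drugs — e.g. antiretrovirals —
  carry a multiple of the background interaction degree);
* an HIV-positive minority on a fixed three-drug ART backbone, with
  group-specific physiological-frailty distributions (mean 50, SD 15 with
  HIV; 33, SD 11 without) and overdispersed non-ART medication counts
  (mean 3 with HIV, 4 without; SD 3);
* co-prescription clustering: drug sets are grown with an exponential
  preference for candidates already interacting with the chosen set, with
  the preference strength calibrated per set size by Monte-Carlo bisection
  so the realised interaction enrichment over random selection hits a
  configured target (about five-fold in the real cohort);
* fill histories with refill gaps both below and above the 30-day grace
  window, non-chronic decoy fills, and occasional fills of excluded items,
  so the calendar rules are exercised end to end;
* proportional-hazards outcomes (exponential baseline) for death and first
  hospitalisation with planted medication-count, frailty and pair-exposure
  effects; when the count effect is partially mediated through planted
  pairs, the generator apportions the configured total per-medication
  log-hazard between a direct component and the component carried by the
  planted pair effects, solving against the realised exposure distribution.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exposure import ObservationWindow
from .network import InteractionNetwork, build_network
from .vocab import DrugEntry, DrugVocabulary

logger = logging.getLogger(__name__)

_ART_CLASS_CYCLE = ["PI", "PI", "NNRTI", "NNRTI", "NRTI", "NRTI", "NRTI", "INSTI", "booster"]
_EXCLUDED_NAMES = ["fish oil", "vitamin d", "multivitamin", "peppermint oil", "skin ointment", "water"]


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study, with cohort-realistic defaults."""

    seed: int = 0
    # interaction network
    n_drugs: int = 200
    edge_model: str = "er"  # "er" | "hub"
    edge_density: float = 0.05
    n_hubs: int = 8
    hub_degree_multiplier: float = 4.0
    n_art_drugs: int = 9
    # cohort
    n_patients: int = 10_000
    hiv_fraction: float = 0.195
    frailty_mean_hiv: float = 50.0
    frailty_sd_hiv: float = 15.0
    frailty_mean_neg: float = 33.0
    frailty_sd_neg: float = 11.0
    med_count_mean_hiv: float = 3.0
    med_count_sd_hiv: float = 3.0
    med_count_mean_neg: float = 4.0
    med_count_sd_neg: float = 3.0
    max_total_count: int = 12
    # co-prescription clustering
    enrichment_target: float = 5.0  # 1.0 = uniform (null) selection
    # planted pair effects (mortality log-HRs); pairs are dedicated drugs
    planted_betas: tuple[float, ...] = ()
    planted_hosp_betas: tuple[float, ...] | None = None
    planted_prevalence: float = 0.25
    planted_count_scaling: bool = False  # exposure probability grows with count
    # outcome hazards (exponential baselines, events per person-year)
    baseline_mortality: float = 0.030
    baseline_hospitalisation: float = 0.090
    beta_med_mortality: float = 0.0  # per non-ART drug, log-HR
    beta_frailty_mortality: float = 0.26  # per 5 frailty points (HR ~1.30)
    beta_med_hosp: float = 0.08  # total per-drug log-HR, incl. mediated part
    beta_frailty_hosp: float = 0.10
    # calendars
    window: ObservationWindow = field(default_factory=ObservationWindow)
    followup_start: dt.date = dt.date(2009, 10, 1)
    followup_end: dt.date = dt.date(2019, 3, 31)
    refill_gap_break_prob: float = 0.15  # chance of an extra, non-chronic early episode
    decoy_rate: float = 0.5  # Poisson mean of short, non-chronic fills per patient
    excluded_fill_prob: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.hiv_fraction <= 1 and 0 <= self.edge_density <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.baseline_mortality <= 0 or self.baseline_hospitalisation <= 0:
            raise ValueError("baseline hazards must be positive")
        if self.enrichment_target < 1:
            raise ValueError("enrichment target must be >= 1")
        if self.planted_hosp_betas is not None and len(self.planted_hosp_betas) != len(
            self.planted_betas
        ):
            raise ValueError("planted_hosp_betas must match planted_betas in length")

    @property
    def followup_years(self) -> float:
        return ((self.followup_end - self.followup_start).days + 1) / 365.25

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["window"] = {
            "start": self.window.start.isoformat(),
            "end": self.window.end.isoformat(),
        }
        out["followup_start"] = self.followup_start.isoformat()
        out["followup_end"] = self.followup_end.isoformat()
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        data = dict(data)
        if "window" in data and isinstance(data["window"], dict):
            data["window"] = ObservationWindow(
                dt.date.fromisoformat(data["window"]["start"]),
                dt.date.fromisoformat(data["window"]["end"]),
            )
        for key in ("followup_start", "followup_end"):
            if key in data and isinstance(data[key], str):
                data[key] = dt.date.fromisoformat(data[key])
        for key in ("planted_betas", "planted_hosp_betas"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown generator config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# network + vocabulary


def _drug_id(i: int) -> str:
    return f"D{i:04d}"


def generate_network(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[InteractionNetwork, DrugVocabulary, list[tuple[str, str]]]:
    """Interaction network, matching vocabulary, and the planted pairs.

    Planted pairs occupy dedicated non-ART drugs (two per pair, taken from
    the top of the id range) and their edges are always present; they are
    excluded from organic drug selection so their exposure is governed
    purely by the planting mechanism.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    n = config.n_drugs
    ids = [_drug_id(i) for i in range(n)]

    upper = np.triu_indices(n, k=1)
    probs = np.full(len(upper[0]), config.edge_density)
    if config.edge_model == "hub":
        hub = np.zeros(n, dtype=bool)
        hub[config.n_art_drugs : config.n_art_drugs + config.n_hubs] = True
        is_hub_pair = hub[upper[0]] | hub[upper[1]]
        probs = np.where(
            is_hub_pair, np.minimum(config.edge_density * config.hub_degree_multiplier, 1.0), probs
        )
    elif config.edge_model != "er":
        raise ValueError(f"unknown edge model {config.edge_model!r}")
    draw = rng.random(len(probs)) < probs
    edges = [(ids[a], ids[b]) for a, b in zip(upper[0][draw], upper[1][draw])]

    n_planted = len(config.planted_betas)
    planted_pairs = []
    for j in range(n_planted):
        a = ids[n - 2 * n_planted + 2 * j]
        b = ids[n - 2 * n_planted + 2 * j + 1]
        planted_pairs.append((a, b))
    edge_set = {frozenset(e) for e in edges}
    for pair in planted_pairs:
        if frozenset(pair) not in edge_set:
            edges.append(pair)

    entries = []
    for i, drug_id in enumerate(ids):
        art_class = (
            _ART_CLASS_CYCLE[i % len(_ART_CLASS_CYCLE)]
            if i < config.n_art_drugs
            else "non_art"
        )
        synonyms = frozenset({f"drug {i} alt"}) if i % 7 == 0 else frozenset()
        entries.append(
            DrugEntry(
                drug_id=drug_id,
                canonical_name=f"drug {i}",
                synonyms=synonyms,
                art_class=art_class,
            )
        )
    for j, name in enumerate(_EXCLUDED_NAMES):
        entries.append(
            DrugEntry(drug_id=f"X{j:02d}", canonical_name=name, excluded=True)
        )
    vocab = DrugVocabulary(entries)
    net = build_network(edges, vocab)
    return net, vocab, planted_pairs


# ---------------------------------------------------------------------------
# cohort

_AGE_BANDS = [(35, 49, 0.212), (50, 64, 0.646), (65, 85, 0.142)]
_RACES = ["white", "black", "hispanic", "other"]
_RACE_P = [0.410, 0.466, 0.088, 0.036]


def generate_cohort(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Patient table: id, HIV status, age, sex, race, frailty score."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    n = config.n_patients
    hiv = rng.random(n) < config.hiv_fraction
    band_p = np.array([b[2] for b in _AGE_BANDS])
    band = rng.choice(len(_AGE_BANDS), size=n, p=band_p / band_p.sum())
    lo = np.array([b[0] for b in _AGE_BANDS])[band]
    hi = np.array([b[1] for b in _AGE_BANDS])[band]
    age = rng.integers(lo, hi + 1)
    sex = np.where(rng.random(n) < 0.026, "female", "male")
    race = rng.choice(_RACES, size=n, p=np.array(_RACE_P) / sum(_RACE_P))
    frailty = np.where(
        hiv,
        rng.normal(config.frailty_mean_hiv, config.frailty_sd_hiv, n),
        rng.normal(config.frailty_mean_neg, config.frailty_sd_neg, n),
    )
    frailty = np.clip(frailty, 0, 120)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "hiv": hiv,
            "age_years": age.astype(int),
            "sex": sex,
            "race": race,
            "frailty": np.round(frailty, 1),
        }
    )


# ---------------------------------------------------------------------------
# co-prescription clustering


def _grow_set(
    adjacency: np.ndarray,
    universe: np.ndarray,
    forced: list[int],
    size: int,
    gamma: float,
    rng: np.random.Generator,
) -> list[int]:
    """Grow a drug set with exponential preference for interacting candidates.

    Candidate weight is exp(gamma × #edges to the chosen set); gamma = 0 is
    uniform selection, large gamma approaches greedy clique growth.
    """
    chosen = list(forced)
    available = np.ones(adjacency.shape[0], dtype=bool)
    available[:] = False
    available[universe] = True
    for c in chosen:
        available[c] = False
    edges_to_chosen = (
        adjacency[chosen].sum(axis=0).astype(float) if chosen else np.zeros(adjacency.shape[0])
    )
    while len(chosen) < size:
        cand = np.flatnonzero(available)
        if len(cand) == 0:
            break
        if gamma == 0.0 or not chosen:
            pick = int(rng.choice(cand))
        else:
            w = np.exp(gamma * np.minimum(edges_to_chosen[cand], 30.0))
            pick = int(rng.choice(cand, p=w / w.sum()))
        chosen.append(pick)
        available[pick] = False
        edges_to_chosen += adjacency[pick]
    return chosen


def _set_edge_count(adjacency: np.ndarray, members: list[int]) -> int:
    sub = adjacency[np.ix_(members, members)]
    return int(sub.sum()) // 2


def calibrate_clustering(
    adjacency: np.ndarray,
    universe: np.ndarray,
    forced: list[int],
    sizes: list[int],
    target: float,
    rng: np.random.Generator,
    n_probe: int = 400,
    max_gamma: float = 10.0,
    on_unattainable: str = "error",
) -> dict[int, float]:
    """Per-set-size preference strength hitting the enrichment target.

    For each size k the expected random-selection interaction count is the
    exact hypergeometric mean m·k(k−1)/(n(n−1)); bisection on gamma matches
    the Monte-Carlo mean of clustered sets to ``target`` times that. An
    unattainable target (even at ``max_gamma``) raises with a diagnostic,
    or — with ``on_unattainable='clamp'``, used for groups whose forced
    backbone drugs cap small-set enrichment by construction — takes the
    closest achievable value with a warning.
    """
    members_all = np.concatenate([np.asarray(universe, dtype=int), np.asarray(forced, dtype=int)])
    n_uni = len(members_all)
    m = int(adjacency[np.ix_(members_all, members_all)].sum()) // 2
    gammas: dict[int, float] = {}
    for k in sizes:
        if k <= len(forced):
            gammas[k] = 0.0
            continue
        random_mean = m * k * (k - 1) / (n_uni * (n_uni - 1))
        goal = target * random_mean
        if target == 1.0:
            gammas[k] = 0.0
            continue

        def mc_mean(gamma: float) -> float:
            counts = [
                _set_edge_count(adjacency, _grow_set(adjacency, universe, forced, k, gamma, rng))
                for _ in range(n_probe)
            ]
            return float(np.mean(counts))

        hi_val = mc_mean(max_gamma)
        if hi_val < goal:
            if on_unattainable == "clamp":
                logger.warning(
                    "enrichment target %sx clamped at size %d: max achievable "
                    "mean %.2f < goal %.2f", target, k, hi_val, goal,
                )
                gammas[k] = max_gamma
                continue
            raise ValueError(
                f"enrichment target {target}x unattainable at size {k}: "
                f"max achievable mean {hi_val:.2f} < goal {goal:.2f}; "
                "increase edge density or lower the target"
            )
        lo, hi = 0.0, max_gamma
        for _ in range(12):
            mid = (lo + hi) / 2
            if mc_mean(mid) < goal:
                lo = mid
            else:
                hi = mid
        gammas[k] = (lo + hi) / 2
    return gammas


# ---------------------------------------------------------------------------
# prescriptions


@dataclass
class PrescriptionTruth:
    drug_sets: dict[str, set[str]]  # realised chronic drugs per patient
    planted_exposure: np.ndarray  # patients × planted pairs, bool
    non_art_counts: np.ndarray
    total_counts: np.ndarray
    gammas: dict[str, dict[int, float]]


def _emit_coverage_fills(
    rows: list,
    patient: str,
    drug: str,
    start: int,
    end: int,
    rng: np.random.Generator,
) -> None:
    """Emit fills jointly covering [start, end] with merge-compatible gaps."""
    cur = start
    while cur <= end:
        supply = int(min(rng.choice([30, 60, 90], p=[0.3, 0.2, 0.5]), end - cur + 1))
        rows.append((patient, drug, cur, supply))
        gap = 0 if rng.random() < 0.7 else int(rng.integers(1, 31))
        cur += supply + gap


def generate_prescriptions(
    config: GeneratorConfig,
    net: InteractionNetwork,
    vocab: DrugVocabulary,
    patients: pd.DataFrame,
    planted_pairs: list[tuple[str, str]],
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, PrescriptionTruth]:
    """Fill records realising clustered chronic drug sets and planted exposures.

    Every intended chronic drug receives fills spanning at least 220
    covered days overlapping the window (with refill gaps of up to 30
    days), so it survives the 90-consecutive-day rule and all chronic
    drugs of a patient pairwise co-occur. Non-chronic decoy fills, broken
    early episodes and occasional excluded-item fills are layered on top.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    order = sorted(vocab.non_excluded_ids)
    idx = {d: i for i, d in enumerate(order)}
    adjacency, _ = net.adjacency(order)
    art_idx = sorted(idx[d] for d in vocab.art_ids)
    planted_idx = {idx[d] for pair in planted_pairs for d in pair}
    organic_universe = np.array(
        [i for d, i in sorted(idx.items()) if i not in planted_idx and d not in vocab.art_ids],
        dtype=int,
    )

    n = len(patients)
    hiv = patients["hiv"].to_numpy()
    k_non = np.where(
        hiv,
        rng.negative_binomial(
            *_nb_params(config.med_count_mean_hiv, config.med_count_sd_hiv), size=n
        ),
        rng.negative_binomial(
            *_nb_params(config.med_count_mean_neg, config.med_count_sd_neg), size=n
        ),
    )
    k_non = np.where(~hiv, np.maximum(k_non, 1), k_non)  # comparators are on >=1 drug
    k_non = np.minimum(k_non, config.max_total_count - np.where(hiv, 3, 0))

    # planted exposure, optionally scaling with intended count (mediation)
    n_pairs = len(planted_pairs)
    planted_exposure = np.zeros((n, n_pairs), dtype=bool)
    if n_pairs:
        if config.planted_count_scaling:
            k_mean = max(float(k_non.mean()), 1e-9)
            p_mat = np.clip(
                config.planted_prevalence * (k_non / k_mean), 0.0, 0.95
            )[:, None]
        else:
            p_mat = np.full((n, 1), config.planted_prevalence)
        planted_exposure = rng.random((n, n_pairs)) < p_mat

    # calibrate clustering per group and set size
    sizes = sorted(set(np.unique(k_non[~hiv]).tolist()) | set((np.unique(k_non[hiv]) + 3).tolist()))
    sizes = [int(s) for s in sizes if s >= 2]
    gammas: dict[str, dict[int, float]] = {"neg": {}, "hiv": {}}
    if config.enrichment_target > 1.0:
        cal_rng = np.random.default_rng(rng.integers(0, 2**31))
        gammas["neg"] = calibrate_clustering(
            adjacency, organic_universe, [], sizes, config.enrichment_target, cal_rng
        )
        if hiv.any():
            art_forced = art_idx[:3]
            gammas["hiv"] = calibrate_clustering(
                adjacency,
                organic_universe,
                art_forced,
                [s for s in sizes if s > 3],
                config.enrichment_target,
                cal_rng,
                on_unattainable="clamp",
            )

    rows: list[tuple[str, str, int, int]] = []
    drug_sets: dict[str, set[str]] = {}
    w0, w1 = config.window.day_range()
    for i, patient in enumerate(patients["patient_id"]):
        forced = list(art_idx[:3]) if hiv[i] else []
        k_total = int(k_non[i]) + len(forced)
        group = "hiv" if hiv[i] else "neg"
        gamma = gammas[group].get(k_total, 0.0)
        members = _grow_set(adjacency, organic_universe, forced, k_total, gamma, rng)
        drugs = {order[j] for j in members}
        for j in range(n_pairs):
            if planted_exposure[i, j]:
                drugs |= set(planted_pairs[j])
        drug_sets[patient] = drugs

        planted_drugs = {
            d for j in range(n_pairs) if planted_exposure[i, j] for d in planted_pairs[j]
        }
        for drug in sorted(drugs):
            if drug in planted_drugs:
                _emit_coverage_fills(rows, patient, drug, w0, w1, rng)
                continue
            start = int(rng.integers(-45, 46))
            span = int(rng.integers(220, 421))
            _emit_coverage_fills(rows, patient, drug, start, start + span - 1, rng)
            if rng.random() < config.refill_gap_break_prob:
                rows.append((patient, drug, start - 120, 30))  # gap > 30 d: separate episode
        # short-use decoys never reach 90 consecutive days
        for _ in range(rng.poisson(config.decoy_rate)):
            decoy = order[int(rng.choice(organic_universe))]
            rows.append((patient, decoy, int(rng.integers(w0, w1 - 29)), 30))
        if rng.random() < config.excluded_fill_prob:
            rows.append((patient, f"X{int(rng.integers(0, len(_EXCLUDED_NAMES))):02d}",
                         int(rng.integers(w0, w1 - 29)), 30))

    fills = pd.DataFrame(rows, columns=["patient_id", "drug_id", "fill_day", "days_supply"])
    fills = fills.sort_values(["patient_id", "drug_id", "fill_day"], kind="mergesort").reset_index(
        drop=True
    )
    non_art = vocab.non_art_ids
    non_art_counts = np.array([len(drug_sets[p] & non_art) for p in patients["patient_id"]])
    total_counts = np.array([len(drug_sets[p]) for p in patients["patient_id"]])
    truth = PrescriptionTruth(
        drug_sets=drug_sets,
        planted_exposure=planted_exposure,
        non_art_counts=non_art_counts,
        total_counts=total_counts,
        gammas=gammas,
    )
    return fills, truth


def _nb_params(mean: float, sd: float) -> tuple[float, float]:
    """Negative-binomial (n, p) for a given mean and SD (overdispersed)."""
    var = sd**2
    if var <= mean:
        raise ValueError("negative binomial needs variance > mean")
    r = mean**2 / (var - mean)
    return r, r / (r + mean)


# ---------------------------------------------------------------------------
# outcomes


@dataclass
class OutcomeTruth:
    lp_death: np.ndarray
    lp_hosp: np.ndarray
    beta_med_hosp_direct: float


def _marginal_cox_limit(
    beta_grid_seed: float,
    k: np.ndarray,
    mediated_lp: np.ndarray,
    death_rate: np.ndarray,
    direct: float,
    baseline_hosp: float,
    fu_years: float,
    n_time: int = 101,
) -> float:
    """Large-sample limit of the count coefficient in a count-only Cox model.

    With exponential event times, death censoring and administrative end of
    follow-up, the population partial-likelihood score for a model with the
    single covariate ``k`` is

        g(b) = ∫ Σ_i r_i(t) λ_i [k_i − (Σ_j r_j(t) e^{b k_j} k_j)/(Σ_j r_j(t) e^{b k_j})] dt,

    where λ_i is the true hospitalisation rate and r_i(t) the at-risk
    probability. Returns the root b — the value a marginal fit converges to
    as n grows, which sits below the conditional slope because high-risk
    patients leave the risk set early.
    """
    lam = baseline_hosp * np.exp(direct * (k - k.mean()) + mediated_lp)
    total_rate = lam + death_rate
    t = np.linspace(0.0, fu_years, n_time)
    risk = np.exp(-np.outer(total_rate, t))  # n × n_time at-risk probabilities
    events = risk * lam[:, None]

    def score(b: float) -> float:
        w = np.exp(b * k)
        den = (risk * w[:, None]).sum(axis=0)
        num = (risk * (w * k)[:, None]).sum(axis=0)
        kbar = num / den
        integrand = (events * k[:, None]).sum(axis=0) - events.sum(axis=0) * kbar
        return float(np.trapezoid(integrand, t))

    lo, hi = beta_grid_seed - 0.3, beta_grid_seed + 0.3
    s_lo, s_hi = score(lo), score(hi)
    while s_lo < 0:
        lo -= 0.3
        s_lo = score(lo)
    while s_hi > 0:
        hi += 0.3
        s_hi = score(hi)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if score(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _calibrate_direct_slope(
    total: float,
    mediated_lp: np.ndarray,
    counts: np.ndarray,
    death_rate: np.ndarray,
    baseline_hosp: float,
    fu_years: float,
) -> float:
    """Direct per-drug slope so the *marginal* count coefficient equals ``total``.

    Part of the configured count effect is carried by the planted pair
    exposures (and any other non-count terms in ``mediated_lp``); the
    remainder must also offset risk-set depletion, which this solves for by
    iterating on the deterministic marginal-Cox limit of the realised
    cohort.
    """
    k = counts.astype(float)
    direct = total - np.polyfit(k, mediated_lp, 1)[0]  # first-order start
    for _ in range(4):
        achieved = _marginal_cox_limit(
            total, k, mediated_lp, death_rate, direct, baseline_hosp, fu_years
        )
        direct += total - achieved
        if abs(total - achieved) < 1e-5:
            break
    return float(direct)


def generate_outcomes(
    config: GeneratorConfig,
    patients: pd.DataFrame,
    truth: PrescriptionTruth,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, OutcomeTruth]:
    """Death and first-hospitalisation times under planted proportional hazards.

    Event times are exponential with patient-specific rates
    baseline × exp(linear predictor); hospitalisation is censored at death
    or the administrative end of follow-up, death at the administrative
    end. Returns (outcomes with ISO dates, death follow-up, hospitalisation
    follow-up, ground truth of linear predictors).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    n = len(patients)
    frailty = patients["frailty"].to_numpy(dtype=float)
    k = truth.non_art_counts.astype(float)
    exposure = truth.planted_exposure.astype(float)
    betas_death = np.asarray(config.planted_betas, dtype=float)
    betas_hosp = np.asarray(
        config.planted_hosp_betas if config.planted_hosp_betas is not None else config.planted_betas,
        dtype=float,
    )

    f_center = frailty.mean()
    k_center = k.mean()
    lp_death = (
        config.beta_med_mortality * (k - k_center)
        + config.beta_frailty_mortality * (frailty - f_center) / 5.0
        + (exposure @ betas_death if len(betas_death) else 0.0)
    )
    lp_hosp_other = config.beta_frailty_hosp * (frailty - f_center) / 5.0 + (
        exposure @ betas_hosp if len(betas_hosp) else 0.0
    )
    direct = config.beta_med_hosp
    if len(betas_hosp) and config.planted_count_scaling:
        death_rate = config.baseline_mortality * np.exp(lp_death)
        direct = _calibrate_direct_slope(
            config.beta_med_hosp,
            lp_hosp_other,
            k,
            death_rate,
            config.baseline_hospitalisation,
            config.followup_years,
        )
    lp_hosp = direct * (k - k_center) + lp_hosp_other

    fu_years = config.followup_years
    t_death = rng.exponential(1.0 / (config.baseline_mortality * np.exp(lp_death)))
    t_hosp = rng.exponential(1.0 / (config.baseline_hospitalisation * np.exp(lp_hosp)))

    death = t_death < fu_years
    death_days = np.ceil(np.minimum(t_death, fu_years) * 365.25).astype(int)
    death_days = np.maximum(death_days, 1)
    hosp_cens_years = np.minimum(t_death, fu_years)
    hosp_event = t_hosp < hosp_cens_years
    hosp_days = np.ceil(np.minimum(t_hosp, hosp_cens_years) * 365.25).astype(int)
    hosp_days = np.maximum(hosp_days, 1)

    ids = patients["patient_id"]
    start = config.followup_start
    outcomes = pd.DataFrame(
        {
            "patient_id": ids,
            "death_date": [
                (start + dt.timedelta(days=int(d) - 1)).isoformat() if e else ""
                for d, e in zip(death_days, death)
            ],
            "first_hosp_date": [
                (start + dt.timedelta(days=int(d) - 1)).isoformat() if e else ""
                for d, e in zip(hosp_days, hosp_event)
            ],
            "censor_date": [
                (start + dt.timedelta(days=int(d) - 1)).isoformat()
                for d in death_days
            ],
        }
    )
    followup_death = pd.DataFrame(
        {"patient_id": ids, "time_days": death_days, "event": death, "death": death}
    )
    followup_hosp = pd.DataFrame(
        {"patient_id": ids, "time_days": hosp_days, "event": hosp_event}
    )
    return outcomes, followup_death, followup_hosp, OutcomeTruth(lp_death, lp_hosp, float(direct))


# ---------------------------------------------------------------------------
# whole-study orchestration


@dataclass
class SyntheticStudy:
    config: GeneratorConfig
    vocab: DrugVocabulary
    net: InteractionNetwork
    planted_pairs: list[tuple[str, str]]
    patients: pd.DataFrame
    fills: pd.DataFrame
    outcomes: pd.DataFrame
    followup_death: pd.DataFrame
    followup_hosp: pd.DataFrame
    rx_truth: PrescriptionTruth
    outcome_truth: OutcomeTruth

    def ground_truth_manifest(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "planted_pairs": [list(p) for p in self.planted_pairs],
            "planted_betas": list(self.config.planted_betas),
            "beta_med_hosp_direct": self.outcome_truth.beta_med_hosp_direct,
            "clustering_gamma": {
                g: {str(k): v for k, v in d.items()} for g, d in self.rx_truth.gammas.items()
            },
            "n_edges": self.net.n_edges,
            "n_fills": int(len(self.fills)),
            "mean_non_art_count": float(self.rx_truth.non_art_counts.mean()),
            "planted_exposure_prevalence": (
                self.rx_truth.planted_exposure.mean(axis=0).tolist()
            ),
        }

    def fills_with_dates(self) -> pd.DataFrame:
        epoch = self.config.window.start
        out = self.fills.copy()
        out["fill_date"] = [
            (epoch + dt.timedelta(days=int(d))).isoformat() for d in out["fill_day"]
        ]
        return out[["patient_id", "drug_id", "fill_date", "days_supply"]]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.vocab.write_tsv(outdir / "vocabulary.tsv")
        self.net.to_edge_frame().to_csv(outdir / "edges.tsv", sep="\t", index=False)
        self.fills_with_dates().to_csv(outdir / "fills.tsv", sep="\t", index=False)
        self.patients.to_csv(outdir / "patients.tsv", sep="\t", index=False)
        self.outcomes.to_csv(outdir / "outcomes.tsv", sep="\t", index=False)
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth_manifest(), fh, indent=2, sort_keys=True)


def generate_study(config: GeneratorConfig) -> SyntheticStudy:
    """Generate the full synthetic study from one root seed.

    Stage generators are spawned from a single seed sequence, so any
    regeneration from the same config is byte-identical.
    """
    children = np.random.SeedSequence(config.seed).spawn(4)
    rng_net, rng_cohort, rng_rx, rng_out = (np.random.default_rng(c) for c in children)
    net, vocab, planted_pairs = generate_network(config, rng_net)
    patients = generate_cohort(config, rng_cohort)
    fills, rx_truth = generate_prescriptions(config, net, vocab, patients, planted_pairs, rng_rx)
    outcomes, fu_death, fu_hosp, out_truth = generate_outcomes(config, patients, rx_truth, rng_out)
    return SyntheticStudy(
        config=config,
        vocab=vocab,
        net=net,
        planted_pairs=planted_pairs,
        patients=patients,
        fills=fills,
        outcomes=outcomes,
        followup_death=fu_death,
        followup_hosp=fu_hosp,
        rx_truth=rx_truth,
        outcome_truth=out_truth,
    )
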
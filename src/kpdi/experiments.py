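"""Reproducible study-scale experiments on synthetic cohorts.

Each function generates data with the synthetic module, runs the relevant
analysis path, and returns the measured quantities. They are the package's
validation suite at study scale — enrichment of observed interaction
burden over the random null, recovery of planted pair weights by the
bagged estimator, attenuation of the medication-count hazard after index
adjustment, calibration of the proportional-hazards check, and quintile
construction quality — and they back both the test suite and the
reproduction script.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from . import exposure as exp_mod
from . import index as index_mod
from . import nullsim, survival
from .pipeline import RunConfig, run_pipeline
from .synthetic import GeneratorConfig, generate_network, generate_study


def _calendar_chain(study, config: GeneratorConfig):
    """fills → episodes → chronic gating → clipped episodes → co-occurrence."""
    window = config.window
    episodes = exp_mod.build_episodes(study.fills)
    chronic = exp_mod.chronic_drug_set(episodes, window)
    counts = exp_mod.medication_counts(chronic, study.vocab)
    clipped = exp_mod.clip_to_window(exp_mod.filter_chronic(episodes, chronic), window)
    coocc = exp_mod.co_occurrence(clipped)
    return counts, coocc


# ---------------------------------------------------------------------------
# enrichment of observed interaction burden over the random null


def run_enrichment(
    seed: int,
    n_patients: int = 10_000,
    n_drugs: int = 200,
    edge_density: float = 0.05,
    enrichment_target: float = 5.0,
    n_sets: int = 20_000,
) -> dict:
    """Observed-vs-random interaction slopes on a clustered synthetic cohort.

    Generates a cohort whose co-prescription clustering is calibrated to
    ``enrichment_target`` times the random interaction count at every
    medication count, runs the full calendar chain, and fits linear curves
    of mean interaction count against medication count for the observed
    cohort and for random drug sets. Reports both fits and their slope
    ratio, the empirical analogue of the real-world/random contrast.
    """
    cfg = GeneratorConfig(
        seed=seed,
        n_patients=n_patients,
        n_drugs=n_drugs,
        edge_density=edge_density,
        hiv_fraction=0.0,
        enrichment_target=enrichment_target,
    )
    study = generate_study(cfg)
    counts, coocc = _calendar_chain(study, cfg)
    observed = nullsim.observed_kpdis_by_count(
        coocc, counts, study.net, None, count_col="total_count"
    )
    random_summaries = nullsim.summarize_random_kpdis(
        study.net, nullsim.DEFAULT_SIZES, n_sets, np.random.default_rng(seed + 1)
    )
    random_frame = nullsim.summaries_to_frame(random_summaries)
    fit_obs = nullsim.fit_mean_curve(observed)
    fit_rand = nullsim.fit_mean_curve(random_frame)
    merged = observed.merge(random_frame, on="set_size", suffixes=("_obs", "_rand"))
    return {
        "observed_fit": fit_obs,
        "random_fit": fit_rand,
        "slope_ratio": fit_obs.slope / fit_rand.slope,
        "observed_frame": observed,
        "random_frame": random_frame,
        "mean_enrichment_by_size": dict(
            zip(merged["set_size"], merged["mean_obs"] / merged["mean_rand"])
        ),
        "n_patients": n_patients,
    }


# ---------------------------------------------------------------------------
# planted-weight recovery by the bagged estimator


def run_weight_recovery(
    seed: int,
    n_patients: int = 5_000,
    n_bags: int = 200,
    planted_betas: tuple[float, ...] = (0.5, 0.3, -0.3, 0.0, 0.0),
    prevalence: float = 0.25,
) -> dict:
    """Recovery of planted pair log-hazards by bagged Cox estimation.

    An HIV-negative cohort carries five planted pairs (three with real
    mortality effects, two null) at 25% exposure prevalence; exposure runs
    the calendar chain, and weights are estimated for the planted pairs
    with the package's bagging procedure. Reports per-pair estimates, the
    bias and RMSE over the non-null pairs, and the largest absolute weight
    assigned to a null pair.
    """
    cfg = GeneratorConfig(
        seed=seed,
        n_patients=n_patients,
        n_drugs=150,
        hiv_fraction=0.0,
        enrichment_target=1.0,
        planted_betas=planted_betas,
        planted_prevalence=prevalence,
        baseline_mortality=0.045,
        beta_med_mortality=0.0,
    )
    study = generate_study(cfg)
    _, coocc = _calendar_chain(study, cfg)
    ids = list(study.patients["patient_id"])
    exposures = index_mod.exposure_matrix(coocc, study.planted_pairs, ids)
    fu = study.followup_death.set_index("patient_id").loc[ids]
    weights = index_mod.bagged_weights(
        fu["time_days"].to_numpy(),
        fu["death"].to_numpy(),
        study.patients["frailty"].to_numpy(),
        exposures,
        study.planted_pairs,
        n_bags=n_bags,
        seed=np.random.default_rng(seed + 17),
    )
    true = np.asarray(planted_betas)
    est = weights["beta_mean"].to_numpy()
    nonnull = true != 0
    errors = est[nonnull] - true[nonnull]
    return {
        "weights": weights,
        "true_betas": true,
        "bias": float(errors.mean()),
        "rmse": float(np.sqrt((errors**2).mean())),
        "null_max_abs": float(np.abs(est[~nonnull]).max()) if (~nonnull).any() else 0.0,
        "exposure_prevalence": exposures.mean(axis=0).tolist(),
        "n_patients": n_patients,
        "n_bags": n_bags,
    }


# ---------------------------------------------------------------------------
# attenuation of the count association under index adjustment


def _true_score_tables(study, config: GeneratorConfig):
    """Index scores and quintiles from the generator's planted weights.

    Uses the planted (ground-truth) pair effects as the weight table, so
    the adjustment isolates the nested-model behaviour from weight
    estimation; planted exposures span the full window.
    """
    betas = np.asarray(
        config.planted_hosp_betas
        if config.planted_hosp_betas is not None
        else config.planted_betas,
        dtype=float,
    )
    weights = pd.DataFrame(
        {
            "drug_a": [p[0] for p in study.planted_pairs],
            "drug_b": [p[1] for p in study.planted_pairs],
            "beta_mean": betas,
        }
    )
    expo = study.rx_truth.planted_exposure
    rows = []
    ids = list(study.patients["patient_id"])
    for j, pair in enumerate(study.planted_pairs):
        for i in np.flatnonzero(expo[:, j]):
            rows.append((ids[i], pair[0], pair[1], config.window.length_days))
    coocc = pd.DataFrame(rows, columns=["patient_id", "drug_a", "drug_b", "overlap_days"])
    scores = index_mod.score_patients(weights, coocc, config.window.length_days, ids)
    deaths = study.followup_death.set_index("patient_id")["death"]
    reference = pd.Series(True, index=ids)
    quint = index_mod.assign_quintiles(scores, deaths, reference)
    scores = scores.drop(columns=["category"]).merge(
        quint.categories.rename("category"), left_on="patient_id", right_index=True
    )
    return scores


def run_attenuation_once(seed: int, n_patients: int = 20_000) -> dict:
    """One replicate: nested count hazard ratios with and without adjustment.

    The generator plants a total per-medication log-hazard of 0.08 on
    hospitalisation, part of it carried by three planted pair effects
    whose exposure probability scales with medication count (mediation).
    """
    cfg = GeneratorConfig(
        seed=seed,
        n_patients=n_patients,
        n_drugs=150,
        hiv_fraction=0.0,
        enrichment_target=1.0,
        planted_betas=(0.4, 0.3, 0.3),
        planted_prevalence=0.25,
        planted_count_scaling=True,
        beta_med_hosp=0.08,
        beta_frailty_hosp=0.0,
        beta_med_mortality=0.0,
        baseline_mortality=0.012,
        baseline_hospitalisation=0.090,
    )
    study = generate_study(cfg)
    scores = _true_score_tables(study, cfg)
    counts = pd.DataFrame(
        {
            "patient_id": study.patients["patient_id"],
            "total_count": study.rx_truth.total_counts,
            "non_art_count": study.rx_truth.non_art_counts,
        }
    )
    model = survival.NestedHospitalisationModel.from_components(
        study.patients, counts, scores, study.followup_hosp
    )
    res = model.fit()
    row_u = res.table[
        (res.table["level"] == "unadjusted") & (res.table["covariate"] == "non_art_count")
    ].iloc[0]
    row_a = res.table[
        (res.table["level"] == "+kpdi_index") & (res.table["covariate"] == "non_art_count")
    ].iloc[0]
    return {
        "hr_unadjusted": float(row_u["hr"]),
        "ci_unadjusted": (float(row_u["ci_low"]), float(row_u["ci_high"])),
        "hr_adjusted": float(row_a["hr"]),
        "attenuated": bool(row_a["hr"] <= row_u["hr"]),
        "planted_direct_slope": study.outcome_truth.beta_med_hosp_direct,
        "results": res,
    }


def run_attenuation(seed: int, n_replicates: int = 20, n_patients: int = 20_000) -> dict:
    """Attenuation direction over replicates plus recovery on the first."""
    reps = [
        run_attenuation_once(seed + 1000 * r, n_patients=n_patients)
        for r in range(n_replicates)
    ]
    return {
        "replicates": reps,
        "first": reps[0],
        "attenuation_fraction": float(np.mean([r["attenuated"] for r in reps])),
        "mean_hr_unadjusted": float(np.mean([r["hr_unadjusted"] for r in reps])),
        "mean_hr_adjusted": float(np.mean([r["hr_adjusted"] for r in reps])),
        "n_replicates": n_replicates,
        "n_patients": n_patients,
    }


# ---------------------------------------------------------------------------
# proportional-hazards check calibration


def _simulate_ph_cohort(
    rng: np.random.Generator,
    n: int,
    beta_early: float,
    beta_late: float,
    t_switch: float = 2.0,
    baseline: float = 0.15,
    followup: float = 9.5,
) -> pd.DataFrame:
    """Two-period hazard: effect ``beta_early`` before ``t_switch`` years,
    ``beta_late`` after. Equal betas give exact proportional hazards."""
    x = (rng.random(n) < 0.5).astype(float)
    u = rng.random(n)
    rate1 = baseline * np.exp(beta_early * x)
    rate2 = baseline * np.exp(beta_late * x)
    h_target = -np.log(u)
    h_at_switch = rate1 * t_switch
    t = np.where(
        h_target < h_at_switch,
        h_target / rate1,
        t_switch + (h_target - h_at_switch) / rate2,
    )
    event = t < followup
    t = np.minimum(t, followup)
    return pd.DataFrame({"time_days": t * 365.25, "event": event, "exposure": x})


def run_ph_calibration(
    seed: int,
    n_replicates: int = 200,
    n_power_replicates: int = 50,
    n: int = 600,
    alpha: float = 0.05,
) -> dict:
    """Size and power of the covariate × log(time) interaction check.

    Under exact proportional hazards the check should reject at about the
    nominal rate; under a planted effect that reverses after two years it
    should reject in the large majority of replicates.
    """
    rng = np.random.default_rng(seed)

    def _reject(frame: pd.DataFrame) -> bool:
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(frame, duration_col="time_days", event_col="event")
        res = survival.check_ph(cph, frame, alpha=alpha)
        return bool(res.loc[res["covariate"] == "exposure", "flagged"].iloc[0])

    null_rejections = sum(
        _reject(_simulate_ph_cohort(rng, n, 0.5, 0.5)) for _ in range(n_replicates)
    )
    power_rejections = sum(
        _reject(_simulate_ph_cohort(rng, n, 1.0, -0.5)) for _ in range(n_power_replicates)
    )
    return {
        "null_rejection_rate": null_rejections / n_replicates,
        "power": power_rejections / n_power_replicates,
        "n_replicates": n_replicates,
        "n_power_replicates": n_power_replicates,
        "n": n,
    }


# ---------------------------------------------------------------------------
# quintile construction quality


def run_quintile_check(seed: int, n_patients: int = 10_000) -> dict:
    """Greedy death-balanced quintiles versus the exhaustive optimum.

    Synthetic scores mix continuous values with heavy ties (as real index
    scores do); deaths depend on score. Reports the worst per-quintile
    deviation from an even death split for the greedy assignment and for
    the exhaustive-search optimum, and verifies no-KPDI patients are
    excluded from cutpoint derivation.
    """
    rng = np.random.default_rng(seed)
    n = n_patients
    n_pairs = rng.poisson(1.2, n)
    raw = np.where(
        rng.random(n) < 0.4,
        rng.choice([0.1, 0.25, 0.4], n),
        np.round(rng.normal(0.5, 0.6, n), 2),
    )
    score = np.where(n_pairs > 0, raw * np.maximum(n_pairs, 1), 0.0)
    death_p = 1 / (1 + np.exp(-(score - 0.5)))
    death = rng.random(n) < death_p * 0.4
    scores = pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "score": score,
            "n_pairs": n_pairs,
            "category": "",
        }
    )
    deaths = pd.Series(death, index=scores["patient_id"])
    reference = pd.Series(rng.random(n) < 0.8, index=scores["patient_id"])
    quint = index_mod.assign_quintiles(scores, deaths, reference)

    mask = reference.to_numpy() & (n_pairs > 0)
    opt = index_mod.optimal_death_split_deviation(score[mask], death[mask])
    target = quint.target_deaths_per_quintile
    achieved_dev = max(abs(d - target) for d in quint.reference_death_split)

    # cutpoints must be unchanged by no-KPDI patients' outcomes
    death_flip = pd.Series(
        np.where(n_pairs == 0, ~deaths.to_numpy(), deaths.to_numpy()),
        index=deaths.index,
    )
    quint_flip = index_mod.assign_quintiles(scores, death_flip, reference)
    return {
        "achieved_max_deviation": float(achieved_dev),
        "optimal_max_deviation": float(opt),
        "death_split": quint.reference_death_split,
        "target": float(target),
        "cutpoints_ignore_no_kpdi": bool(
            np.allclose(quint.cutpoints, quint_flip.cutpoints)
        ),
        "n_patients": n,
    }


# ---------------------------------------------------------------------------
# determinism of the full pipeline


def run_determinism(seed: int, workdir: str | Path) -> dict:
    """Byte-identity of two pipeline runs from the same config and seed."""
    workdir = Path(workdir)
    cfg = RunConfig(
        seed=seed,
        synth=GeneratorConfig(
            seed=seed, n_patients=300, n_drugs=80, enrichment_target=1.0,
            planted_betas=(0.5,), planted_prevalence=0.3,
        ),
        sim_n_sets=1000,
        n_bags=5,
    )
    digests = []
    for run_dir in (workdir / "run_a", workdir / "run_b"):
        run_pipeline(RunConfig.from_dict(cfg.to_dict()), run_dir)
        digest = {}
        for path in sorted(run_dir.iterdir()):
            digest[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
        digests.append(digest)
    return {
        "identical": digests[0] == digests[1],
        "files": sorted(digests[0]),
        "digests": digests,
    }


# ---------------------------------------------------------------------------
# random-null analytic check


def run_random_null(seed: int, n_nodes: int = 200, density: float = 0.05,
                    n_sets: int = 20_000) -> dict:
    """Random-set mean interaction counts against the exact expectation.

    For a fixed graph with m edges, a uniform k-subset contains each edge
    with probability k(k−1)/(n(n−1)), so the expected count is exactly
    m·k(k−1)/(n(n−1)). Reports the Monte-Carlo z-scores against that
    expectation for k = 2..12.
    """
    cfg = GeneratorConfig(seed=seed, n_drugs=n_nodes, edge_density=density,
                          n_patients=1, enrichment_target=1.0)
    net, _, _ = generate_network(cfg)
    summaries = nullsim.summarize_random_kpdis(
        net, nullsim.DEFAULT_SIZES, n_sets, np.random.default_rng(seed + 3)
    )
    n = net.n_nodes
    m = net.n_edges
    rows = []
    for s in summaries:
        expected = m * s.set_size * (s.set_size - 1) / (n * (n - 1))
        se = s.sd / np.sqrt(s.n_sets) if s.sd > 0 else np.nan
        rows.append(
            {
                "set_size": s.set_size,
                "mean": s.mean,
                "expected": expected,
                "z": (s.mean - expected) / se if se and np.isfinite(se) else 0.0,
            }
        )
    frame = pd.DataFrame(rows)
    return {
        "frame": frame,
        "max_abs_z": float(frame["z"].abs().max()),
        "n_sets": n_sets,
        "n_edges": m,
    }
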
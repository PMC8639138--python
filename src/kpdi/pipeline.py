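"""End-to-end orchestration: ingest → calendars → co-occurrence → null
simulation → index → nested models → report bundle.

The pipeline is a pure function of (inputs, config, seed). It emits four
report artefacts plus a run manifest:

1. random-vs-observed interaction summaries with linear fits (the
   medication-count/interaction-count contrast),
2. a per-category summary (n, mean index score, mean non-ART count, mean
   frailty, crude mortality rate),
3. the nested hospitalisation model table, and
4. a JSON manifest with the config hash, seeds and row counts at every
   filter stage, so every excluded patient is accounted for.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import exposure as exp_mod
from . import index as index_mod
from . import nullsim, survival
from .network import InteractionNetwork, build_network, read_edge_table
from .synthetic import GeneratorConfig, SyntheticStudy, generate_study
from .vocab import DrugVocabulary

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Single structured parameter source for a pipeline run.

    Either ``synth`` holds a generator config (inputs are synthesised) or
    the five input paths point at delimited-text tables. Unknown keys in a
    config file are rejected.
    """

    seed: int = 0
    # inputs (ignored when synth is set)
    vocabulary: str | None = None
    edges: str | None = None
    fills: str | None = None
    patients: str | None = None
    outcomes: str | None = None
    synth: GeneratorConfig | None = None
    # calendar parameters
    window_start: dt.date = dt.date(2008, 10, 1)
    window_end: dt.date = dt.date(2009, 9, 30)
    refill_gap: int = 30
    chronic_min_days: int = 90
    chronic_gating: bool = True
    # follow-up
    followup_start: dt.date = dt.date(2009, 10, 1)
    followup_end: dt.date = dt.date(2019, 3, 31)
    # null simulation
    sim_sizes: tuple[int, ...] = tuple(range(2, 13))
    sim_n_sets: int = 44_350
    # index
    min_prevalence: int = 10
    n_bags: int = 1000
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.synth is None and not all(
            (self.vocabulary, self.edges, self.fills, self.patients, self.outcomes)
        ):
            raise ValueError("either synth or all five input paths must be set")

    @property
    def window(self) -> exp_mod.ObservationWindow:
        return exp_mod.ObservationWindow(self.window_start, self.window_end)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key in ("window_start", "window_end", "followup_start", "followup_end"):
            out[key] = out[key].isoformat()
        if self.synth is not None:
            out["synth"] = self.synth.to_dict()
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("window_start", "window_end", "followup_start", "followup_end"):
            if key in data and isinstance(data[key], str):
                data[key] = dt.date.fromisoformat(data[key])
        if data.get("synth") is not None and isinstance(data["synth"], dict):
            data["synth"] = GeneratorConfig.from_dict(data["synth"])
        if "sim_sizes" in data:
            data["sim_sizes"] = tuple(data["sim_sizes"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class PipelineReport:
    """In-memory report bundle; ``write`` serialises it deterministically."""

    config: RunConfig
    figure_table: pd.DataFrame
    fits: pd.DataFrame
    category_summary: pd.DataFrame
    model_table: pd.DataFrame
    correlations: pd.DataFrame
    weights: pd.DataFrame
    scores: pd.DataFrame
    manifest: dict
    index_results: object = None
    model_results: object = None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        frames = {
            "figure2_table.tsv": self.figure_table,
            "linear_fits.tsv": self.fits,
            "table2_summary.tsv": self.category_summary,
            "table3_models.tsv": self.model_table,
            "correlations.tsv": self.correlations,
            "weights.tsv": self.weights,
            "scores.tsv": self.scores,
        }
        for name, frame in frames.items():
            frame.to_csv(outdir / name, sep="\t", index=False, float_format="%.6g")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def _load_inputs(config: RunConfig):
    if config.synth is not None:
        study = generate_study(config.synth)
        return (
            study.vocab,
            study.net,
            study.fills_with_dates(),
            study.patients,
            study.outcomes,
            study,
        )
    vocab = DrugVocabulary.read_tsv(config.vocabulary)
    net = build_network(read_edge_table(config.edges), vocab)
    fills = pd.read_csv(config.fills, sep="\t", dtype={"patient_id": str, "drug_id": str})
    patients = pd.read_csv(config.patients, sep="\t", dtype={"patient_id": str})
    outcomes = pd.read_csv(
        config.outcomes, sep="\t", dtype=str, keep_default_na=False
    )
    return vocab, net, fills, patients, outcomes, None


def followup_tables(
    outcomes: pd.DataFrame, entry: dt.date, admin_end: dt.date
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(death, hospitalisation) follow-up tables from an outcome date table.

    Death follow-up runs from ``entry`` to death or the administrative
    end; hospitalisation follow-up to the first admission, censored at
    death or the administrative end.
    """
    def _days(series: pd.Series) -> np.ndarray:
        out = np.full(len(series), -1, dtype=int)
        mask = series.astype(str).str.len() > 0
        if mask.any():
            dates = pd.to_datetime(series[mask]).dt.date
            out[np.flatnonzero(mask.to_numpy())] = [
                (d - entry).days + 1 for d in dates
            ]
        return out

    max_days = (admin_end - entry).days + 1
    death_days = _days(outcomes["death_date"])
    hosp_days = _days(outcomes["first_hosp_date"])
    censor_days = _days(outcomes["censor_date"])
    censor_days = np.where(censor_days < 0, max_days, np.minimum(censor_days, max_days))

    death_event = death_days > 0
    death_time = np.where(death_event, death_days, censor_days)
    fu_death = pd.DataFrame(
        {
            "patient_id": outcomes["patient_id"],
            "time_days": death_time,
            "event": death_event,
            "death": death_event,
        }
    )
    hosp_event = (hosp_days > 0) & (hosp_days <= death_time)
    hosp_time = np.where(hosp_event, hosp_days, death_time)
    fu_hosp = pd.DataFrame(
        {
            "patient_id": outcomes["patient_id"],
            "time_days": hosp_time,
            "event": hosp_event,
        }
    )
    return fu_death, fu_hosp


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> PipelineReport:
    """Execute the full analysis; optionally write the report bundle."""
    manifest: dict = {"config": config.to_dict(), "config_hash": config.config_hash(),
                      "seed": config.seed, "counts": {}}
    counts = manifest["counts"]

    vocab, net, fills_dates, patients, outcomes, study = _load_inputs(config)
    counts["patients_in"] = int(len(patients))
    counts["fills_in"] = int(len(fills_dates))
    counts["network_nodes"] = net.n_nodes
    counts["network_edges"] = net.n_edges

    window = config.window
    epoch = window.start
    fills = exp_mod.fills_to_day_index(fills_dates, epoch)
    known = vocab.non_excluded_ids
    keep = fills["drug_id"].isin(known)
    counts["fills_excluded_or_unknown_drug"] = int((~keep).sum())
    fills = fills[keep]

    episodes = exp_mod.build_episodes(fills, refill_gap=config.refill_gap)
    counts["episodes"] = int(len(episodes))
    chronic = exp_mod.chronic_drug_set(episodes, window, min_days=config.chronic_min_days)
    counts["patients_with_chronic_drug"] = len(chronic)
    med_counts = exp_mod.medication_counts(chronic, vocab)

    in_scope = exp_mod.filter_chronic(episodes, chronic) if config.chronic_gating else episodes
    clipped = exp_mod.clip_to_window(in_scope, window)
    coocc = exp_mod.co_occurrence(clipped)
    counts["coocc_pairs"] = int(len(coocc))

    # --- random vs observed interaction summaries -------------------------
    rng = np.random.default_rng(config.seed)
    random_summaries = nullsim.summarize_random_kpdis(
        net, config.sim_sizes, config.sim_n_sets, rng
    )
    random_frame = nullsim.summaries_to_frame(random_summaries).assign(group="random")
    hiv_labels = patients.set_index("patient_id")["hiv"].map(
        {True: "hiv_positive", False: "hiv_negative"}
    )
    observed_frame = nullsim.observed_kpdis_by_count(
        coocc, med_counts, net, hiv_labels, count_col="total_count", sizes=config.sim_sizes
    )
    figure_table = pd.concat(
        [random_frame[["group", *random_frame.columns[:-1]]], observed_frame],
        ignore_index=True,
    )[["group", "set_size", "n_sets", "min", "max", "mean", "sd"]]
    fit_rows = []
    for group, gframe in figure_table.groupby("group", sort=True):
        if gframe["set_size"].nunique() < 2:
            continue
        fit = nullsim.fit_mean_curve(gframe)
        fit_rows.append(
            {"group": group, "slope": fit.slope, "intercept": fit.intercept,
             "r_squared": fit.r_squared}
        )
    fits = pd.DataFrame(fit_rows, columns=["group", "slope", "intercept", "r_squared"])

    # --- KPDI index -------------------------------------------------------
    fu_death, fu_hosp = followup_tables(outcomes, config.followup_start, config.followup_end)
    patients_idx = patients.set_index("patient_id")
    reference = ~patients_idx["hiv"].astype(bool)
    model = index_mod.KPDIIndexModel(
        followup=fu_death,
        frailty=patients_idx["frailty"],
        coocc=coocc,
        net=net,
        reference=reference,
        window_length=window.length_days,
        min_prevalence=config.min_prevalence,
    )
    index_results = model.fit(
        n_bags=config.n_bags, alpha=config.alpha, seed=np.random.default_rng(config.seed + 1)
    )
    counts["pairs_in_scope"] = len(index_results.pairs)
    counts["patients_scored"] = int(len(index_results.scores))

    # --- per-category summary (index vs count, frailty, mortality) -------
    summary_rows = []
    scored = index_results.scores.merge(med_counts, on="patient_id", how="left")
    scored = scored.merge(patients, on="patient_id", how="left")
    scored = scored.merge(fu_death[["patient_id", "time_days", "death"]], on="patient_id")
    scored["non_art_count"] = scored["non_art_count"].fillna(0)
    for (group, category), sub in scored.groupby(
        [scored["hiv"].map({True: "hiv_positive", False: "hiv_negative"}), "category"],
        sort=True,
    ):
        rate = survival.crude_rate(sub["time_days"], sub["death"])
        summary_rows.append(
            {
                "group": group,
                "category": category,
                "n": len(sub),
                "mean_score": sub["score"].mean(),
                "mean_non_art_count": sub["non_art_count"].mean(),
                "mean_frailty": sub["frailty"].mean(),
                "mortality_rate_per_1000py": rate.rate,
                "rate_ci_low": rate.ci_low,
                "rate_ci_high": rate.ci_high,
            }
        )
    category_summary = pd.DataFrame(summary_rows)

    # --- nested hospitalisation models ------------------------------------
    nested = survival.NestedHospitalisationModel.from_components(
        patients, med_counts, index_results.scores, fu_hosp
    )
    model_results = nested.fit()
    counts["patients_modelled"] = int(len(nested.data))

    # --- correlations ------------------------------------------------------
    measures = scored.set_index("patient_id")[["non_art_count", "frailty", "score"]]
    corr = survival.correlations(measures, scored.set_index("patient_id")["hiv"])

    manifest["quintile_cutpoints"] = [float(c) for c in index_results.quintiles.cutpoints]
    manifest["reference_death_split"] = index_results.quintiles.reference_death_split
    if study is not None:
        manifest["ground_truth"] = study.ground_truth_manifest()

    report = PipelineReport(
        config=config,
        figure_table=figure_table,
        fits=fits,
        category_summary=category_summary,
        model_table=model_results.table,
        correlations=corr,
        weights=index_results.weights,
        scores=index_results.scores,
        manifest=manifest,
        index_results=index_results,
        model_results=model_results,
    )
    if outdir is not None:
        report.write(outdir)
    return report
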
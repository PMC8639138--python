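"""Synthetic study generator: network, cohort, prescriptions, outcomes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kpdi.synthetic import (
    GeneratorConfig,
    calibrate_clustering,
    generate_cohort,
    generate_network,
    generate_prescriptions,
    generate_study,
    _nb_params,
)


def test_edge_density_extremes():
    none, _, _ = generate_network(GeneratorConfig(seed=0, n_drugs=30, edge_density=0.0))
    assert none.n_edges == 0
    full, _, _ = generate_network(GeneratorConfig(seed=0, n_drugs=30, edge_density=1.0))
    assert full.n_edges == 30 * 29 // 2


def test_er_edge_count_within_three_binomial_se():
    cfg = GeneratorConfig(seed=4, n_drugs=200, edge_density=0.05)
    net, _, _ = generate_network(cfg)
    n_pairs = 200 * 199 // 2
    se = np.sqrt(n_pairs * 0.05 * 0.95)
    assert abs(net.n_edges - 0.05 * n_pairs) <= 3 * se


def test_hub_drugs_carry_multiplied_degree():
    cfg = GeneratorConfig(
        seed=1, n_drugs=150, edge_model="hub", edge_density=0.04,
        n_hubs=6, hub_degree_multiplier=5.0,
    )
    net, _, _ = generate_network(cfg)
    degrees = dict(net.graph.degree)
    hub_ids = [f"D{i:04d}" for i in range(cfg.n_art_drugs, cfg.n_art_drugs + 6)]
    hub_mean = np.mean([degrees.get(h, 0) for h in hub_ids])
    other_mean = np.mean(
        [d for n, d in degrees.items() if n not in hub_ids]
    )
    assert hub_mean > 2.5 * other_mean


def test_planted_pairs_are_always_edges():
    cfg = GeneratorConfig(seed=2, n_drugs=60, edge_density=0.02,
                          planted_betas=(0.5, -0.3, 0.0))
    net, _, pairs = generate_network(cfg)
    assert len(pairs) == 3
    for a, b in pairs:
        assert net.has_interaction(a, b)


def test_vocabulary_flags_art_and_excluded_items():
    _, vocab, _ = generate_network(GeneratorConfig(seed=0, n_drugs=40))
    assert len(vocab.art_ids) == 9
    excluded = {e.drug_id for e in vocab if e.excluded}
    assert len(excluded) == 6 and all(d.startswith("X") for d in excluded)


def test_cohort_moments_and_group_fractions():
    cfg = GeneratorConfig(seed=3, n_patients=8000)
    cohort = generate_cohort(cfg)
    hiv = cohort["hiv"]
    se = np.sqrt(0.195 * 0.805 / 8000)
    assert abs(hiv.mean() - 0.195) <= 3 * se
    for mask, mean, sd in [(hiv, 50, 15), (~hiv, 33, 11)]:
        sub = cohort.loc[mask, "frailty"]
        assert abs(sub.mean() - mean) <= 4 * sd / np.sqrt(len(sub))


def test_degenerate_cohort_settings():
    cfg = GeneratorConfig(seed=0, n_patients=200, hiv_fraction=0.0,
                          frailty_sd_neg=0.0, frailty_mean_neg=40.0)
    cohort = generate_cohort(cfg)
    assert not cohort["hiv"].any()
    assert (cohort["frailty"] == 40.0).all()


def test_nb_params_reject_underdispersion():
    with pytest.raises(ValueError):
        _nb_params(4.0, 1.0)


def test_hiv_patients_receive_three_art_drugs():
    cfg = GeneratorConfig(seed=5, n_patients=150, n_drugs=80, hiv_fraction=0.5,
                          enrichment_target=1.0)
    net, vocab, pairs = generate_network(cfg)
    cohort = generate_cohort(cfg)
    _, truth = generate_prescriptions(cfg, net, vocab, cohort, pairs)
    art = vocab.art_ids
    for patient, hiv in zip(cohort["patient_id"], cohort["hiv"]):
        n_art = len(truth.drug_sets[patient] & art)
        assert n_art == (3 if hiv else 0)


def test_mean_non_art_count_matches_truncated_distribution():
    # comparators draw NB(mean 4, sd 3), floored at 1 and capped at 12;
    # the oracle expectation comes from the NB pmf itself
    cfg = GeneratorConfig(seed=6, n_patients=4000, n_drugs=120, hiv_fraction=0.0,
                          enrichment_target=1.0)
    net, vocab, pairs = generate_network(cfg)
    cohort = generate_cohort(cfg)
    _, truth = generate_prescriptions(cfg, net, vocab, cohort, pairs)
    r, p = _nb_params(4.0, 3.0)
    k = np.arange(0, 200)
    pmf = stats.nbinom.pmf(k, r, p)
    clipped = np.clip(np.maximum(k, 1), None, 12)
    expected = float((pmf * clipped).sum())
    observed = truth.non_art_counts.mean()
    se = truth.non_art_counts.std(ddof=1) / np.sqrt(len(truth.non_art_counts))
    assert abs(observed - expected) <= 3 * se


def test_planted_exposure_prevalence_matches_config():
    cfg = GeneratorConfig(seed=7, n_patients=3000, n_drugs=100, hiv_fraction=0.0,
                          enrichment_target=1.0, planted_betas=(0.5, 0.0),
                          planted_prevalence=0.25)
    study = generate_study(cfg)
    prev = study.rx_truth.planted_exposure.mean(axis=0)
    se = np.sqrt(0.25 * 0.75 / 3000)
    assert np.all(np.abs(prev - 0.25) <= 3.5 * se)


def test_null_clustering_gives_enrichment_near_one():
    cfg = GeneratorConfig(seed=8, n_patients=1500, n_drugs=150, hiv_fraction=0.0,
                          enrichment_target=1.0)
    study = generate_study(cfg)
    # mean interactions in realised drug sets vs the exact random expectation
    adjacency, order = study.net.adjacency()
    idx = {d: i for i, d in enumerate(order)}
    n = study.net.n_nodes
    density = study.net.n_edges / (n * (n - 1) / 2)
    ratios = []
    for drugs in study.rx_truth.drug_sets.values():
        k = len(drugs)
        if k < 4:
            continue
        members = [idx[d] for d in drugs]
        got = adjacency[np.ix_(members, members)].sum() / 2
        ratios.append(got / (density * k * (k - 1) / 2))
    assert np.mean(ratios) == pytest.approx(1.0, abs=0.15)


def test_unattainable_enrichment_target_raises():
    cfg = GeneratorConfig(seed=9, n_drugs=120, edge_density=0.01)
    net, vocab, _ = generate_network(cfg)
    adjacency, order = net.adjacency()
    universe = np.arange(len(order))
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError, match="unattainable"):
        calibrate_clustering(adjacency, universe, [], [12], target=30.0,
                             rng=rng, n_probe=60)


def test_doubling_baseline_hazard_halves_median_event_time():
    # rates high enough that administrative censoring is negligible
    base = GeneratorConfig(seed=10, n_patients=4000, n_drugs=60, hiv_fraction=0.0,
                           enrichment_target=1.0, baseline_mortality=0.5,
                           beta_frailty_mortality=0.0)
    fast = GeneratorConfig.from_dict({**base.to_dict(), "baseline_mortality": 1.0})
    t_base = generate_study(base).followup_death
    t_fast = generate_study(fast).followup_death
    # exponential medians scale inversely with the rate
    m_base = np.median(t_base.loc[t_base["event"], "time_days"])
    m_fast = np.median(t_fast.loc[t_fast["event"], "time_days"])
    assert m_base / m_fast == pytest.approx(2.0, rel=0.2)


def test_regeneration_from_config_is_identical():
    cfg = GeneratorConfig(seed=11, n_patients=250, n_drugs=70, hiv_fraction=0.2,
                          enrichment_target=1.0, planted_betas=(0.4,))
    a = generate_study(cfg)
    b = generate_study(GeneratorConfig.from_dict(cfg.to_dict()))
    pd.testing.assert_frame_equal(a.fills, b.fills)
    pd.testing.assert_frame_equal(a.patients, b.patients)
    pd.testing.assert_frame_equal(a.outcomes, b.outcomes)
    assert a.net.edges == b.net.edges


def test_config_round_trip_and_unknown_keys():
    cfg = GeneratorConfig(seed=1, planted_betas=(0.2, -0.1))
    again = GeneratorConfig.from_dict(cfg.to_dict())
    assert again == cfg
    with pytest.raises(ValueError, match="unknown"):
        GeneratorConfig.from_dict({"bogus_knob": 3})


def test_config_validation():
    with pytest.raises(ValueError):
        GeneratorConfig(hiv_fraction=1.5)
    with pytest.raises(ValueError):
        GeneratorConfig(baseline_mortality=0.0)
    with pytest.raises(ValueError):
        GeneratorConfig(enrichment_target=0.5)
    with pytest.raises(ValueError):
        GeneratorConfig(planted_betas=(0.5,), planted_hosp_betas=(0.1, 0.2))
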
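"""Metrics, AUC, downsampling and replicate-consistency experiments."""

import numpy as np
import pytest

from _oracles import auc_trapezoid
from bisclass.binomial import binomial_classify
from bisclass.calling import classify_sites
from bisclass.core import CALL_METHYLATED, CALL_NO_DATA, CALL_UNMETHYLATED
from bisclass.evaluate import (
    auc_roc,
    confusion_metrics,
    downsample_experiment,
    replicate_consistency,
    run_benchmark,
)
from bisclass.simulate import SimConfig, simulate_dataset, simulate_reads
from conftest import sites_frame

M, U, X = CALL_METHYLATED, CALL_UNMETHYLATED, CALL_NO_DATA


def test_confusion_metrics_definitions():
    perfect = confusion_metrics([M, M, U, U], [True, True, False, False])
    assert perfect.sensitivity == 1.0
    assert perfect.one_minus_specificity_paper == 0.0
    # 2 false positives against 50 truly methylated sites -> ratio 0.04
    calls = [M] * 50 + [M, M] + [U] * 48
    truth = [True] * 50 + [False] * 50
    m = confusion_metrics(calls, truth)
    assert m.one_minus_specificity_paper == pytest.approx(2 / 50)
    assert m.specificity_standard == pytest.approx(48 / 50)
    assert m.accuracy_weighted == pytest.approx(0.5 * 1.0 + 0.5 * 0.96)
    # 8 of 10 methylated detected -> sensitivity 0.8
    m2 = confusion_metrics([M] * 8 + [U] * 2, [True] * 10)
    assert m2.sensitivity == pytest.approx(0.8)


def test_confusion_metrics_no_data_and_empty_truth():
    m = confusion_metrics([M, X, U], [True, True, False])
    assert m.n_no_data == 1
    assert m.tp + m.fp + m.tn + m.fn == 2
    m0 = confusion_metrics([U, U], [False, False])
    assert np.isnan(m0.sensitivity)
    assert np.isnan(m0.one_minus_specificity_paper)


def test_auc_edge_cases(rng):
    assert auc_roc([1.0, 1.0, 1.0, 1.0], [True, False, True, False]) == pytest.approx(0.5)
    assert auc_roc([9, 8, 1, 2], [True, True, False, False]) == pytest.approx(1.0)
    truth = rng.random(10_000) < 0.5
    scores = rng.random(10_000)
    assert auc_roc(scores, truth) == pytest.approx(0.5, abs=0.02)
    with pytest.raises(ValueError):
        auc_roc([1.0, 2.0], [True, True])


def test_auc_matches_trapezoid_oracle(rng):
    for _ in range(5):
        n = int(rng.integers(10, 200))
        truth = rng.random(n) < 0.4
        if truth.all() or not truth.any():
            continue
        scores = np.round(rng.random(n), 2)  # coarse grid forces ties
        assert auc_roc(scores, truth) == pytest.approx(auc_trapezoid(scores, truth), abs=1e-12)
        # p-value style scoring mirrors via the direction flag
        assert auc_roc(-scores, truth, direction="lesser") == pytest.approx(
            auc_trapezoid(scores, truth), abs=1e-12
        )


def test_downsample_noop_reproduces_full_data_calls():
    rng = np.random.default_rng(5)
    n = np.full(400, 8)
    truth = rng.random(400) < 0.3
    k = simulate_reads(truth, n, 0.002, 0.7, seed=rng)
    df = sites_frame(15 * np.arange(1, 401), k, n)
    res = downsample_experiment(df, 0.002, 0.7, target_cov=8, reps=2, seed=1)
    full_bin = binomial_classify(df[(df.n_meth / df.n_total < 0.1) | (df.n_meth / df.n_total > 0.3)].reset_index(drop=True), 0.002)
    full_m = confusion_metrics(
        full_bin["call"].to_numpy(), (full_bin["n_meth"] / full_bin["n_total"] > 0.3).to_numpy()
    )
    got = res[res.method == "binomial"]
    assert np.allclose(got["sensitivity"], full_m.sensitivity)
    assert (got["fp"] == full_m.fp).all()


def test_downsampling_to_single_reads_favors_the_posterior_odds_caller():
    cfg = SimConfig(n_sites=30_000, mean_cov=6.0, pi=0.01, clustered=True, seed=3)
    truth = simulate_dataset(cfg)
    res = downsample_experiment(truth.sites, 0.002, 0.7, target_cov=1, reps=3, seed=5)
    mean = res.groupby("method")[["sensitivity", "auc"]].mean()
    assert mean.loc["bisclass", "sensitivity"] > mean.loc["binomial", "sensitivity"]
    assert mean.loc["bisclass", "auc"] > mean.loc["binomial", "auc"]


def test_replicate_consistency_identical_and_independent(rng):
    cfg = SimConfig(n_sites=10_000, mean_cov=5.0, pi=0.01, clustered=True, seed=7)
    truth = simulate_dataset(cfg)
    calls = classify_sites(truth.sites, 0.002, 0.7)
    cv, corr = replicate_consistency([calls, calls.copy()])
    assert cv == pytest.approx(0.0)
    assert corr[0, 1] == pytest.approx(1.0)
    # unrelated random calls decorrelate
    rnd1, rnd2 = calls.copy(), calls.copy()
    rnd1["call"] = rng.choice([M, U], len(calls))
    rnd2["call"] = rng.choice([M, U], len(calls))
    _, corr_r = replicate_consistency([rnd1, rnd2])
    assert abs(corr_r[0, 1]) < 0.1


def test_replicate_consistency_rejects_disjoint_site_universes():
    a = sites_frame([10, 20], [1, 0], [2, 2]).assign(call=[M, U])
    b = sites_frame([10, 30], [1, 0], [2, 2]).assign(call=[M, U])
    with pytest.raises(ValueError):
        replicate_consistency([a, b])


def test_posterior_odds_calls_more_consistent_across_noisy_replicates():
    """Re-sequencing the same methylome at low coverage: correlations higher
    for the local-prior caller than for the binomial baseline."""
    cfg = SimConfig(n_sites=50_000, mean_cov=3.0, pi=0.01, clustered=True, seed=9)
    truth = simulate_dataset(cfg)
    reps_bis, reps_bin = [], []
    rng = np.random.default_rng(11)
    from bisclass.simulate import sample_coverage

    for _ in range(3):
        cov = sample_coverage(cfg.n_sites, cfg.mean_cov, cfg.var_factor, seed=rng)
        k = simulate_reads(truth.status, cov, cfg.p0, cfg.p1, seed=rng)
        rep = truth.sites.copy()
        rep["n_meth"] = k
        rep["n_total"] = cov
        reps_bis.append(classify_sites(rep, cfg.p0, cfg.p1))
        reps_bin.append(binomial_classify(rep, cfg.p0))
    cv_bis, corr_bis = replicate_consistency(reps_bis)
    cv_bin, corr_bin = replicate_consistency(reps_bin)
    off = ~np.eye(3, dtype=bool)
    assert corr_bis[off].mean() >= corr_bin[off].mean()


def test_run_benchmark_reproducible_and_tidy():
    cfg = SimConfig(n_sites=3_000, mean_cov=3.0, pi=0.01, clustered=True)
    a = run_benchmark([cfg], reps=2, seed=42)
    b = run_benchmark([cfg], reps=2, seed=42)
    assert a.equals(b)
    assert set(a["method"]) == {"bisclass", "binomial"}
    assert len(a) == 4  # cells x reps x methods
    assert {"sensitivity", "one_minus_specificity_paper", "auc"} <= set(a.columns)
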
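"""Kernel weights, local methylation levels, combined prior, smoothed tracks."""

import numpy as np
import pytest

from bisclass.calling import classify_sites
from bisclass.core import posterior_odds
from bisclass.em import estimate_global_level
from bisclass.local_prior import (
    KernelSpec,
    combined_prior,
    corrected_fraction,
    kernel_weight,
    local_level,
    local_levels,
    smooth_track,
)
from bisclass.simulate import SimConfig, simulate_dataset
from conftest import sites_frame


def test_kernel_weight_families():
    tri = KernelSpec(family="triangle", bandwidth=1000.0)
    assert kernel_weight(0.0, tri) == 0.0  # focal site always excluded
    assert kernel_weight(1000.0, tri) == 0.0
    assert kernel_weight(500.0, tri) == pytest.approx(0.5)
    assert kernel_weight(1500.0, tri) == 0.0  # truncated beyond the bandwidth
    lap = KernelSpec(family="laplace", bandwidth=1000.0)
    assert kernel_weight(1000.0, lap) == pytest.approx(np.exp(-1))
    assert kernel_weight(0.0, lap) == 0.0
    gau = KernelSpec(family="gaussian", bandwidth=1000.0)
    assert kernel_weight(1000.0, gau) == pytest.approx(np.exp(-0.5))


def test_kernel_spec_validation():
    with pytest.raises(ValueError):
        KernelSpec(family="epanechnikov")
    with pytest.raises(ValueError):
        KernelSpec(bandwidth=0)
    with pytest.raises(ValueError):
        KernelSpec(mode="nearest")


def test_local_level_hand_computed_weighted_average():
    # focal at 5000; neighbors at d=100 (L=2, F=1) and d=1000 (L=4, F=0.5)
    df = sites_frame([5000, 5100, 6000], [0, 2, 2], [1, 2, 4])
    spec = KernelSpec(family="triangle", bandwidth=1500.0)
    got = local_level(1 - 1, df, spec, p0=0.0, p1=1.0, pi_g=0.01)
    w1, w2 = 1 - 100 / 1500, 1 - 1000 / 1500
    expected = (w1 * 2 * 1.0 + w2 * 4 * 0.5) / (w1 * 2 + w2 * 4)
    assert got == pytest.approx(expected, rel=1e-9)
    assert expected == pytest.approx(0.791667, rel=1e-4)


def test_local_level_bias_correction_and_fallback():
    # neighbors whose F equals the non-conversion rate carry no signal
    df = sites_frame([1000, 1200, 1400], [0, 100, 100], [5, 50_000, 50_000])
    spec = KernelSpec(family="triangle", bandwidth=1500.0)
    assert local_level(0, df, spec, p0=0.002, p1=0.7, pi_g=0.3) == pytest.approx(0.0, abs=1e-9)
    # an isolated site falls back to the global level
    far = sites_frame([1000, 500_000], [0, 3], [2, 4])
    assert local_level(0, far, spec, p0=0.002, p1=0.7, pi_g=0.31) == pytest.approx(0.31)


def test_local_level_focal_index_out_of_range():
    df = sites_frame([100], [0], [1])
    with pytest.raises(IndexError):
        local_level(5, df, KernelSpec(), 0.002, 0.7, pi_g=0.01)


def test_local_levels_bounded_and_windows_respect_chromosomes(rng):
    pos = np.sort(rng.choice(200_000, 500, replace=False)) + 1
    n = rng.integers(0, 8, 500)
    k = rng.binomial(n, 0.3)
    df = sites_frame(pos, k, n)
    df.loc[250:, "chrom"] = "chr2"  # split into two chromosomes
    for mode in ("distance", "k_nearest"):
        spec = KernelSpec(mode=mode, bandwidth=2000.0, k=10)
        lv = local_levels(df, spec, 0.002, 0.7, pi_g=0.02)
        assert np.all((lv >= 0) & (lv <= 1))
    # a site on chr2 is unaffected by chr1 data at the same coordinates
    solo = df[df["chrom"] == "chr2"].reset_index(drop=True)
    lv_all = local_levels(df, KernelSpec(bandwidth=2000.0), 0.002, 0.7, pi_g=0.02)
    lv_solo = local_levels(solo, KernelSpec(bandwidth=2000.0), 0.002, 0.7, pi_g=0.02)
    np.testing.assert_allclose(lv_all[250:], lv_solo, rtol=1e-12)


def test_knearest_matches_bruteforce(rng):
    pos = np.sort(rng.choice(100_000, 300, replace=False)) + 1
    n = rng.integers(0, 6, 300)
    k = rng.binomial(n, 0.3)
    df = sites_frame(pos, k, n)
    kk = 20
    spec = KernelSpec(family="triangle", mode="k_nearest", k=kk)
    fast = local_levels(df, spec, 0.002, 0.7, pi_g=0.01)
    x = pos.astype(float)
    covered = np.flatnonzero(n > 0)
    for i in rng.choice(300, 40, replace=False):
        order = covered[np.argsort(np.abs(x[covered] - x[i]), kind="stable")]
        win = order[: kk + 1]
        d0 = max(np.abs(x[win] - x[i]).max(), 1.0)
        num = den = 0.0
        for j in win:
            d = abs(x[j] - x[i])
            if d == 0:
                continue
            w = max(0.0, 1 - d / d0) * n[j]
            num += w * corrected_fraction(k[j] / n[j], 0.002, 0.7)
            den += w
        expected = num / den if den > 0 else 0.01
        assert fast[i] == pytest.approx(expected, abs=1e-10)


def test_combined_prior_endpoints_and_floor():
    assert combined_prior(0.3, 0.8, w=0.0) == pytest.approx(0.3)
    assert combined_prior(0.3, 0.8, w=1.0) == pytest.approx(0.8)
    assert combined_prior(0.004, 0.5, w=0.5) == pytest.approx(0.252)
    assert combined_prior(0.0, 0.0, w=0.5) == pytest.approx(1e-6)
    assert combined_prior(1.0, 1.0, w=0.5) == pytest.approx(1 - 1e-6)


def test_weight_zero_reduces_to_global_prior_classifier():
    cfg = SimConfig(n_sites=3_000, mean_cov=4.0, pi=0.01, clustered=True, seed=5)
    truth = simulate_dataset(cfg)
    out = classify_sites(truth.sites, 0.002, 0.7, weight=0.0)
    pi_g = estimate_global_level(truth.sites, 0.002, 0.7)
    k = truth.sites["n_meth"].to_numpy()
    n = truth.sites["n_total"].to_numpy()
    expected = posterior_odds(k, n, 0.002, 0.7, pi_g)
    np.testing.assert_allclose(out["odds"].to_numpy(), expected, rtol=1e-12)


def test_weight_changes_only_the_prior_never_the_likelihood_ratio():
    cfg = SimConfig(n_sites=2_000, mean_cov=4.0, pi=0.01, clustered=True, seed=6)
    truth = simulate_dataset(cfg)
    ratios = []
    for w in (0.0, 0.3, 0.7):
        out = classify_sites(truth.sites, 0.002, 0.7, weight=w)
        prior_odds = out["prior"] / (1 - out["prior"])
        ratios.append((out["odds"] / prior_odds).to_numpy())
    np.testing.assert_allclose(ratios[0], ratios[1], rtol=1e-9)
    np.testing.assert_allclose(ratios[0], ratios[2], rtol=1e-9)


def test_kernel_families_give_concordant_calls():
    cfg = SimConfig(n_sites=20_000, mean_cov=4.0, pi=0.01, clustered=True, seed=8)
    truth = simulate_dataset(cfg)
    calls = {}
    for family in ("triangle", "gaussian", "laplace"):
        spec = KernelSpec(family=family, bandwidth=1500.0)
        calls[family] = classify_sites(truth.sites, 0.002, 0.7, kernel=spec)["call"].to_numpy()
    for fam in ("gaussian", "laplace"):
        agreement = np.mean(calls["triangle"] == calls[fam])
        assert agreement >= 0.95


def test_smooth_track_constant_single_site_and_cluster():
    # constant fractional methylation -> flat track at that constant
    df = sites_frame(100 * np.arange(1, 51), np.full(50, 2), np.full(50, 4))
    track = smooth_track(df, KernelSpec(bandwidth=1000.0), step=100)
    np.testing.assert_allclose(track["level"], 0.5, rtol=1e-9)
    # single covered site: peak at the site, kernel-shaped decay
    one = sites_frame([5000], [3], [3])
    tr1 = smooth_track(one, KernelSpec(bandwidth=1000.0), step=100)
    assert len(tr1) == 1 and tr1["level"].iloc[0] == pytest.approx(1.0)
    # clustered simulation: track elevated inside the planted clusters
    cfg = SimConfig(n_sites=20_000, mean_cov=6.0, pi=0.02, clustered=True, seed=10)
    truth = simulate_dataset(cfg)
    track = smooth_track(truth.sites, KernelSpec(bandwidth=1500.0), step=150)
    pos = truth.sites["pos"].to_numpy()
    cluster_pos = set(pos[truth.cluster_mask] // 150)
    in_cluster = track["pos"].to_numpy() // 150
    mask = np.array([p in cluster_pos for p in in_cluster])
    assert track["level"][mask].mean() > 3 * track["level"][~mask].mean()


def test_smooth_track_empty_chromosome():
    df = sites_frame([100, 200], [0, 0], [0, 0])  # nothing covered
    track = smooth_track(df, KernelSpec(bandwidth=500.0), step=50)
    assert track.empty
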
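"""Kernel density, FDR calibration, and cluster calling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import nucfoot as nf

from conftest import SIM_SEED, reciprocal_overlap


def test_kde_closed_form_single_center():
    counts = np.zeros(10_000, dtype=np.int64)
    counts[5000] = 1
    centers = nf.CenterSet(10_000, True, counts, 0)
    d = nf.kde_density(centers, 25.0)
    peak = 1.0 / (25.0 * np.sqrt(2 * np.pi))
    assert d.values[5000] == pytest.approx(peak, rel=1e-9)
    assert d.values[5025] == pytest.approx(peak * np.exp(-0.5), rel=1e-9)
    assert d.values[4975] == pytest.approx(peak * np.exp(-0.5), rel=1e-9)


def test_kde_conserves_mass_and_matches_brute_force():
    rng = np.random.default_rng(0)
    L, n = 10_000, 200
    pos = rng.integers(0, L, n)
    centers = nf.CenterSet(L, True, np.bincount(pos, minlength=L), 0)
    d = nf.kde_density(centers, 25.0)
    assert d.values.sum() == pytest.approx(n, abs=1e-6)
    i = np.arange(L)[:, None]
    dist = np.abs(i - pos[None, :])
    dist = np.minimum(dist, L - dist)
    brute = (np.exp(-0.5 * (dist / 25.0) ** 2) / (25.0 * np.sqrt(2 * np.pi))).sum(axis=1)
    assert np.abs(d.values - brute).max() < 1e-10


def test_kde_rejects_bad_bandwidth(nucleoid_centers):
    with pytest.raises(ValueError):
        nf.kde_density(nucleoid_centers, 0.0)


def test_fdr_threshold_monotone_in_target_and_deterministic():
    rng = np.random.default_rng(5)
    L = 100_000
    counts = np.bincount(rng.integers(0, L, 20_000), minlength=L)
    d = nf.kde_density(nf.CenterSet(L, True, counts, 0), 25.0)
    thresholds = []
    for fdr in (1e-3, 1e-2, 0.5):
        c = nf.calibrate_fdr_threshold(d, fdr, n_rand=10, seed=4)
        thresholds.append(c.density_threshold)
    assert thresholds[0] >= thresholds[1] >= thresholds[2]
    again = nf.calibrate_fdr_threshold(d, 1e-2, n_rand=10, seed=4)
    assert again.density_threshold == thresholds[1]


def test_null_data_respects_the_fdr_target():
    """Uniform centers: the called fraction of the genome stays near the target."""
    rng = np.random.default_rng(99)
    L, n = 1_000_000, 200_000
    counts = np.bincount(rng.integers(0, L, n), minlength=L)
    d = nf.kde_density(nf.CenterSet(L, True, counts, 0), 25.0)
    calib = nf.calibrate_fdr_threshold(d, 1e-3, n_rand=20, seed=17)
    called = nf.call_clusters(d, calib.density_threshold)
    called_fraction = sum(min(c.length, L) for c in called) / L
    assert called_fraction <= 5e-3


def test_cluster_merge_and_length_rules():
    L = 1000
    values = np.zeros(L)
    values[100:140] = 1.0
    values[150:200] = 1.0  # gap 10 < 25: merged
    values[400:420] = 1.0  # length 20 < 25: dropped
    d = nf.DensityTrack(values, 25.0, 100, "raw", circular=True)
    clusters = nf.call_clusters(d, threshold=0.5)
    assert [(c.start, c.end) for c in clusters] == [(100, 200)]
    assert 100 <= clusters[0].summit < 200


def test_cluster_wraps_across_the_origin():
    values = np.zeros(1000)
    values[990:] = 1.0
    values[:40] = 1.0
    d = nf.DensityTrack(values, 25.0, 100, "raw", circular=True)
    clusters = nf.call_clusters(d, threshold=0.5)
    assert len(clusters) == 1
    assert (clusters[0].start, clusters[0].end) == (990, 1040)


@given(st.lists(st.floats(0, 1), min_size=200, max_size=400),
       st.floats(0.1, 0.9))
def test_called_clusters_are_separated_and_long_enough(values, threshold):
    values = np.asarray(values)
    d = nf.DensityTrack(values, 25.0, 10, "raw", circular=False)
    clusters = nf.call_clusters(d, threshold, min_length=5, merge_gap=7)
    for c in clusters:
        assert c.length >= 5
        assert c.start <= c.summit < c.end
    for a, b in zip(clusters, clusters[1:]):
        assert b.start - a.end >= 7


def test_control_filter_degenerate_and_identity(nucleoid_density):
    clusters = [nf.Cluster(100, 200, 150, 1.0), nf.Cluster(400, 500, 450, 2.0)]
    L = len(nucleoid_density.values)
    zero = nf.DensityTrack(np.zeros(L), 25.0, 1, "per-million")
    kept = nf.filter_by_control(clusters, nucleoid_density, zero, 1.0)
    assert len(kept) == 2
    assert all(np.isfinite(c.enrichment_ratio) for c in kept)

    same = nf.filter_by_control(clusters, nucleoid_density, nucleoid_density, 1.0)
    for c in same:
        assert c.enrichment_ratio == pytest.approx(1.0, abs=1e-3)


def test_scale_consistency_after_recalibration(nucleoid_centers):
    """Doubling every count and recalibrating leaves the calls intact."""
    d1 = nf.kde_density(nucleoid_centers)
    c1 = nf.calibrate_fdr_threshold(d1, 1e-3, n_rand=10, seed=2)
    k1 = nf.call_clusters(d1, c1.density_threshold)

    doubled = nf.CenterSet(nucleoid_centers.genome_length, True,
                           nucleoid_centers.counts * 2, nucleoid_centers.shift_used)
    d2 = nf.kde_density(doubled)
    c2 = nf.calibrate_fdr_threshold(d2, 1e-3, n_rand=10, seed=2)
    k2 = nf.call_clusters(d2, c2.density_threshold)

    # the empirical null depends on depth, so the threshold rescales only
    # approximately; the called landscape must nevertheless be stable
    assert abs(len(k1) - len(k2)) <= 0.10 * len(k1)
    L = nucleoid_centers.genome_length
    m1, m2 = np.zeros(L, bool), np.zeros(L, bool)
    for c in k1:
        m1[np.arange(c.start, c.end) % L] = True
    for c in k2:
        m2[np.arange(c.start, c.end) % L] = True
    jaccard = (m1 & m2).sum() / max((m1 | m2).sum(), 1)
    assert jaccard >= 0.9


def test_planted_clusters_are_recovered(called_clusters, sim_genome, sim_cfg):
    """>=80% of planted footprint groups are called at >=50% reciprocal overlap,
    with essentially no calls in unplanted regions."""
    _, truth = sim_genome
    L = sim_cfg.genome_length
    recovered = sum(
        1 for planted in truth.clusters
        if any(reciprocal_overlap(planted, (c.start, c.end)) >= 0.5
               for c in called_clusters)
    )
    assert recovered / len(truth.clusters) >= 0.8

    planted_mask = np.zeros(L, bool)
    for s, e in truth.clusters:
        planted_mask[s:e] = True
    false_bp = sum(c.length for c in called_clusters
                   if not planted_mask[np.arange(c.start, c.end) % L].any())
    assert false_bp / L <= 5e-3


def test_called_cluster_lengths_are_sane(called_clusters, sim_genome, sim_cfg):
    """Median called length sits between one footprint and a full merged group."""
    _, truth = sim_genome
    lengths = [c.length for c in called_clusters]
    max_span = max(e - s for s, e in truth.clusters)
    median = float(np.median(lengths))
    assert sim_cfg.footprint_length <= median <= max_span + 4 * 25
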
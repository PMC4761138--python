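import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nucfoot as nf

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

SIM_SEED = 11  # fixture seed for the default synthetic dataset


@pytest.fixture(scope="session")
def sim_cfg() -> nf.SimConfig:
    return nf.SimConfig(seed=SIM_SEED)


@pytest.fixture(scope="session")
def sim_genome(sim_cfg):
    """(sequence, ground truth) of the default 1-Mb simulation."""
    return nf.generate_genome(sim_cfg)


@pytest.fixture(scope="session")
def nucleoid_tags(sim_cfg, sim_genome) -> nf.TagSet:
    seq, truth = sim_genome
    return nf.generate_nucleoid_tags(seq, truth, sim_cfg)


@pytest.fixture(scope="session")
def control_tags(sim_cfg, sim_genome) -> nf.TagSet:
    seq, _ = sim_genome
    return nf.generate_control_tags(seq, sim_cfg)


@pytest.fixture(scope="session")
def fragment_estimate(nucleoid_tags) -> nf.FragmentSizeEstimate:
    profile = nf.strand_cross_correlation(nucleoid_tags)
    return nf.estimate_fragment_size(profile)


@pytest.fixture(scope="session")
def nucleoid_centers(nucleoid_tags, fragment_estimate) -> nf.CenterSet:
    return nf.to_fragment_centers(nucleoid_tags, fragment_estimate.fragment_size)


@pytest.fixture(scope="session")
def nucleoid_density(nucleoid_centers) -> nf.DensityTrack:
    return nf.kde_density(nucleoid_centers)


@pytest.fixture(scope="session")
def called_clusters(sim_cfg, sim_genome, control_tags, nucleoid_density,
                    fragment_estimate):
    """Clusters called on the default simulation, control-filtered."""
    calib = nf.calibrate_fdr_threshold(nucleoid_density, fdr=1e-3, n_rand=20,
                                       seed=SIM_SEED)
    called = nf.call_clusters(nucleoid_density, calib.density_threshold)
    ctl_centers = nf.to_fragment_centers(control_tags,
                                         fragment_estimate.fragment_size)
    ctl_density = nf.kde_density(ctl_centers)
    return nf.filter_by_control(called, nucleoid_density, ctl_density, 1.0)


@pytest.fixture(scope="session")
def genome_atracts(sim_genome):
    seq, _ = sim_genome
    return nf.find_atracts(seq)


def reciprocal_overlap(a: tuple, b: tuple) -> float:
    """min(overlap/len(a), overlap/len(b)) for two half-open intervals."""
    ov = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def isolated_tss_genes(truth, min_dist: int = 250):
    """Genes whose TSS is at least min_dist from every other gene anchor."""
    anchors = np.array(sorted(
        [g.tss for g in truth.genes] + [g.tes for g in truth.genes]))
    iso = []
    for g in truth.genes:
        d = np.abs(anchors - g.tss)
        if d[d > 0].min() >= min_dist:
            iso.append(g)
    return iso


def tss_dip_metrics(centers, truth, depth: float):
    """Width (area method) and center of the TSS accessibility dip.

    Uses genes with no foreign anchor near the window so neighboring genes'
    depletion zones do not contaminate the estimate; the width estimator
    integrates the depletion area and divides by baseline x depth, which is
    exact for a rectangular dip and robust to edge blur.
    """
    iso = isolated_tss_genes(truth)
    mp = nf.metagene_profile(centers, iso, "TSS", window=25)
    sm, off, raw = mp.smoothed, mp.offsets, mp.raw
    base = float(np.mean(sm[(np.abs(off) >= 100) & (np.abs(off) <= 250)]))
    area = float(np.sum(np.maximum(0.0, base - raw[np.abs(off) <= 80])))
    width = area / (base * depth)
    half = base * (1 - 0.5 * depth)
    inner = np.nonzero((np.abs(off) <= 120) & (sm <= half))[0]
    center = (off[inner[0]] + off[inner[-1]]) / 2.0 if len(inner) else np.nan
    return width, center
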
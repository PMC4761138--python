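"""Generator correctness: determinism, planted structure, sampling geometry."""

import numpy as np
import pytest
from scipy import stats

import nucfoot as nf
from nucfoot.simulate import ConfigError


SMALL = dict(genome_length=100_000, n_genes=50, n_nucleoid_tags=20_000,
             n_control_tags=20_000)


@pytest.mark.parametrize("field,value", [
    ("genome_length", 0),
    ("gc_content", 1.4),
    ("tss_depletion_depth", -0.1),
    ("footprint_length", 100),  # >= spacing period
    ("tag_length", 60),  # > footprint length
    ("at_bias", 0.0),
    ("footprints_per_cluster", (5, 2)),
])
def test_invalid_config_names_the_field(field, value):
    cfg = nf.SimConfig(**{field: value})
    with pytest.raises(ConfigError, match=field.split("_")[0]):
        cfg.validate()


def test_generators_are_deterministic():
    cfg = nf.SimConfig(seed=1, **SMALL)
    a_seq, a_truth = nf.generate_genome(cfg)
    b_seq, b_truth = nf.generate_genome(cfg)
    assert a_seq == b_seq
    assert a_truth == b_truth
    na = nf.generate_nucleoid_tags(a_seq, a_truth, cfg)
    nb = nf.generate_nucleoid_tags(b_seq, b_truth, cfg)
    assert np.array_equal(na.counts_plus, nb.counts_plus)
    assert np.array_equal(na.counts_minus, nb.counts_minus)
    ca = nf.generate_control_tags(a_seq, cfg)
    cb = nf.generate_control_tags(b_seq, cfg)
    assert np.array_equal(ca.counts_plus, cb.counts_plus)
    assert np.array_equal(ca.counts_minus, cb.counts_minus)


def test_unplanted_genome_matches_gc_content():
    """Without planting, base composition is i.i.d. at the configured GC."""
    cfg = nf.SimConfig(seed=2, atract_cluster_rate=0, n_genes=0,
                       genome_length=1_000_000)
    seq, truth = nf.generate_genome(cfg)
    assert truth.planted_atracts == []
    gc = nf.gc_content(seq)
    se = np.sqrt(0.51 * 0.49 / len(seq))
    assert abs(gc - 0.51) < 4 * se


def test_planted_atracts_rescan_as_bounded_tracts(sim_genome):
    """Every planted interval is found verbatim by the tract scanner."""
    seq, truth = sim_genome
    found = {(t.start, t.end): t for t in nf.find_atracts(seq)}
    assert truth.planted_atracts, "default config plants tracts"
    for start, end in truth.planted_atracts:
        assert (start, end) in found
        t = found[(start, end)]
        assert 3 <= t.length <= 10
        assert set(seq[t.start:t.start + t.nA]) <= {"A"}
        assert set(seq[t.start + t.nA:t.end]) <= {"T"}


def test_ground_truth_intervals_and_spacing(sim_genome, sim_cfg):
    seq, truth = sim_genome
    L = sim_cfg.genome_length
    for s, e in truth.footprints + truth.clusters + truth.planted_atracts:
        assert 0 <= s < e <= L
    # successive footprint centers within a group differ by the period +- jitter
    for cs, ce in truth.clusters:
        fps = [fp for fp in truth.footprints if cs <= fp[0] < ce]
        centers = [(a + b) / 2 for a, b in fps]
        for d in np.diff(centers):
            assert abs(d - sim_cfg.footprint_spacing_period) <= \
                6 * sim_cfg.boundary_jitter_sd + 1


def test_paired_tags_forced_geometry():
    """With both ends sequenced and no jitter, minus tags sit at plus + L - 1."""
    cfg = nf.SimConfig(seed=3, paired_end_prob=1.0, boundary_jitter_sd=0.0,
                       background_fraction=0.0, **SMALL)
    seq, truth = nf.generate_genome(cfg)
    tags = nf.generate_nucleoid_tags(seq, truth, cfg)
    assert tags.n_tags == cfg.n_nucleoid_tags
    shifted = np.roll(tags.counts_plus, cfg.footprint_length - 1)
    assert np.array_equal(tags.counts_minus, shifted)


def test_total_tss_depletion_excludes_all_centers():
    cfg = nf.SimConfig(seed=4, tss_depletion_depth=1.0, **SMALL)
    seq, truth = nf.generate_genome(cfg)
    tags, frags = nf.generate_nucleoid_tags(seq, truth, cfg, return_fragments=True)
    from nucfoot.simulate import _depletion_zone

    zone = _depletion_zone(cfg, truth.genes)
    centers = ((frags[:, 0] + frags[:, 1]) // 2) % cfg.genome_length
    assert not zone[centers].any()


def test_fragment_length_mean_matches_footprint(sim_cfg, sim_genome):
    seq, truth = sim_genome
    cfg = nf.SimConfig(seed=sim_cfg.seed, background_fraction=0.0)
    _, frags = nf.generate_nucleoid_tags(seq, truth, cfg, return_fragments=True)
    mean_len = (frags[:, 1] - frags[:, 0]).mean()
    assert abs(mean_len - cfg.footprint_length) <= 1.0


def test_empty_footprints_is_an_error(sim_cfg, sim_genome):
    seq, truth = sim_genome
    empty = nf.GroundTruth([], [], truth.genes, [], sim_cfg.seed)
    with pytest.raises(ValueError, match="[Nn]othing to sample"):
        nf.generate_nucleoid_tags(seq, empty, sim_cfg)


def test_unbiased_control_is_uniform():
    """With at_bias=1 the binned control counts pass a chi-square uniformity test."""
    cfg = nf.SimConfig(seed=5, at_bias=1.0, **SMALL)
    seq, _ = nf.generate_genome(cfg)
    ctl = nf.generate_control_tags(seq, cfg)
    binned = ctl.counts_plus.reshape(1000, -1).sum(axis=1)
    _, p = stats.chisquare(binned)
    assert p > 0.01


def test_inject_anomalies_identity_and_rate(nucleoid_tags, sim_cfg):
    cfg0 = nf.SimConfig(seed=sim_cfg.seed, anomaly_spike_rate=0.0)
    out, injected = nf.inject_anomalies(nucleoid_tags, cfg0)
    assert injected == []
    assert np.array_equal(out.counts_plus, nucleoid_tags.counts_plus)

    out, injected = nf.inject_anomalies(nucleoid_tags, sim_cfg)
    # rate 1e-5 on 1e6 bp: ~10 spikes per strand (Poisson); allow a wide band
    per_strand = {"+": 0, "-": 0}
    for _, strand, _ in injected:
        per_strand[strand] += 1
    for strand, n in per_strand.items():
        assert 1 <= n <= 30
    mean_nz = nucleoid_tags.counts_plus[nucleoid_tags.counts_plus > 0].mean()
    for pos, strand, count in injected:
        assert count >= 50 * mean_nz * 0.5  # at least ~50x the occupied mean
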
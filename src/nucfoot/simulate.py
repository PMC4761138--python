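"""Synthetic MNase-digestion data with planted ground truth.

The generator emulates the statistical structure of an in-vivo nucleoid
digestion experiment on a circular bacterial genome:

* groups ("clusters") of digestion-protected footprints of a characteristic
  length, successive footprints spaced by a characteristic period — the loop
  model in which protected fragments occupy loop stems;
* A-tract (poly(dA:dT)) clusters planted at loop apexes between footprints,
  and elevated A-tract planting in promoter windows upstream of TSS;
* footprint stems actively depleted of A-tracts (composition-preserving base
  swaps), mirroring the depletion observed in digestion-resistant regions;
* a nucleoid tag sample: 5'-end tags of fragments drawn from footprints
  (plus an unprotected-background fraction), depleted around TSS/TES;
* a control tag sample from unconstrained digestion of naked DNA with an
  optional AT cut-rate bias;
* amplification-bias anomalies (duplicate pile-ups) for QC testing.

Every generator is a pure function of ``(config, seed)``; each stage draws
from an independent, documented substream of the global seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .tags import Gene, TagSet, write_annotations_bed, write_annotations_gff3, write_tags

__all__ = [
    "SimConfig",
    "GroundTruth",
    "ConfigError",
    "generate_genome",
    "generate_nucleoid_tags",
    "generate_control_tags",
    "inject_anomalies",
    "write_fasta",
    "simulate_to_dir",
]

# per-stage substream identifiers of the global seed
_STAGE_GENOME = 1
_STAGE_NUCLEOID = 2
_STAGE_CONTROL = 3
_STAGE_ANOMALY = 4

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = (int(b) for b in b"ACGT")


class ConfigError(ValueError):
    """A SimConfig field violates its constraints."""


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


@dataclass
class SimConfig:
    """Parameters of the synthetic digestion experiment.

    Lengths are in bp.  The defaults reproduce the structural constants of
    the modelled experiment: 50-bp protected fragments spaced 93 bp apart,
    36-bp tags, a ~100-bp accessibility dip at TSS/TES, and an AT-biased
    naked-DNA control.
    """

    genome_length: int = 1_000_000
    circular: bool = True
    gc_content: float = 0.51
    n_genes: int = 500
    gene_length_range: tuple[int, int] = (500, 2000)
    footprint_length: int = 50
    footprint_spacing_period: int = 93
    footprints_per_cluster: tuple[int, int] = (2, 5)
    cluster_rate: float = 0.5  # clusters per kb
    tss_depletion_halfwidth: int = 50
    tss_depletion_depth: float = 0.6
    atract_cluster_rate: float = 1.0  # A-tract groups per loop apex
    tracts_per_apex_group: int = 3
    promoter_atract_rate: float = 4.0  # expected planted tracts per promoter window
    promoter_window: tuple[int, int] = (-100, 20)  # relative to TSS, transcription sense
    deplete_footprint_atracts: bool = True
    tag_length: int = 36
    n_nucleoid_tags: int = 200_000
    n_control_tags: int = 200_000
    background_fraction: float = 0.1  # unprotected-DNA fraction of nucleoid fragments
    control_fragment_length_range: tuple[int, int] = (50, 500)
    at_bias: float = 1.5
    boundary_jitter_sd: float = 3.0
    paired_end_prob: float = 0.5
    anomaly_spike_rate: float = 1e-5
    seed: int = 0

    def validate(self) -> None:
        pos_fields = [
            "genome_length", "n_genes", "footprint_length",
            "footprint_spacing_period", "tss_depletion_halfwidth", "tag_length",
            "n_nucleoid_tags", "n_control_tags",
        ]
        for name in pos_fields:
            if getattr(self, name) < (0 if name == "n_genes" else 1):
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        frac_fields = [
            "gc_content", "tss_depletion_depth", "paired_end_prob",
            "anomaly_spike_rate", "background_fraction",
        ]
        for name in frac_fields:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.cluster_rate < 0:
            raise ConfigError(f"cluster_rate must be >= 0, got {self.cluster_rate}")
        if self.atract_cluster_rate < 0:
            raise ConfigError("atract_cluster_rate must be >= 0")
        if self.at_bias <= 0:
            raise ConfigError(f"at_bias must be > 0, got {self.at_bias}")
        if self.boundary_jitter_sd < 0:
            raise ConfigError("boundary_jitter_sd must be >= 0")
        if self.footprint_length >= self.footprint_spacing_period:
            raise ConfigError(
                "footprint_length must be smaller than footprint_spacing_period"
            )
        if self.tag_length > self.footprint_length:
            raise ConfigError("tag_length must not exceed footprint_length")
        lo, hi = self.footprints_per_cluster
        if not 1 <= lo <= hi:
            raise ConfigError("footprints_per_cluster must be a valid range")
        lo, hi = self.control_fragment_length_range
        if not 2 <= lo <= hi:
            raise ConfigError("control_fragment_length_range must be a valid range")
        lo, hi = self.gene_length_range
        if not 1 <= lo <= hi:
            raise ConfigError("gene_length_range must be a valid range")


@dataclass
class GroundTruth:
    """Planted features of one simulated genome; all intervals 0-based half-open."""

    footprints: list  # (start, end)
    clusters: list  # (start, end) spans of footprint groups
    genes: list  # Gene tuples
    planted_atracts: list  # (start, end)
    seed_used: int

    def to_json(self, path: str) -> None:
        d = {
            "footprints": [list(map(int, fp)) for fp in self.footprints],
            "clusters": [list(map(int, c)) for c in self.clusters],
            "genes": [[g.name, int(g.tss), int(g.tes), g.strand] for g in self.genes],
            "planted_atracts": [list(map(int, t)) for t in self.planted_atracts],
            "seed_used": int(self.seed_used),
        }
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            footprints=[tuple(fp) for fp in d["footprints"]],
            clusters=[tuple(c) for c in d["clusters"]],
            genes=[Gene(n, t1, t2, s) for n, t1, t2, s in d["genes"]],
            planted_atracts=[tuple(t) for t in d["planted_atracts"]],
            seed_used=d["seed_used"],
        )


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def _place_footprint_clusters(cfg: SimConfig, rng: np.random.Generator):
    """Greedy non-overlapping placement of periodic footprint groups."""
    L = cfg.genome_length
    n_clusters = int(round(cfg.cluster_rate * L / 1000.0))
    lo, hi = cfg.footprints_per_cluster
    max_span = (hi - 1) * cfg.footprint_spacing_period + cfg.footprint_length
    margin = 100
    occupied = np.zeros(L, dtype=bool)
    footprints: list[tuple[int, int]] = []
    clusters: list[tuple[int, int]] = []
    attempts = 0
    while len(clusters) < n_clusters and attempts < 50 * max(n_clusters, 1):
        attempts += 1
        nf = int(rng.integers(lo, hi + 1))
        anchor = int(rng.integers(0, L))
        starts = [anchor]
        for _ in range(nf - 1):
            step = cfg.footprint_spacing_period + int(
                round(rng.normal(0.0, cfg.boundary_jitter_sd)))
            starts.append(starts[-1] + step)
        span_end = starts[-1] + cfg.footprint_length
        if not cfg.circular and span_end + margin >= L:
            continue
        # reject near-boundary wraps for bookkeeping simplicity; on a 1-Mb
        # genome this discards <0.1% of candidate anchors
        if span_end + margin >= L:
            continue
        lo_chk = max(0, anchor - margin)
        if occupied[lo_chk:span_end + margin].any():
            continue
        occupied[lo_chk:span_end + margin] = True
        fps = [(s, s + cfg.footprint_length) for s in starts]
        footprints.extend(fps)
        clusters.append((starts[0], span_end))
    return footprints, clusters


def _place_genes(cfg: SimConfig, rng: np.random.Generator) -> list[Gene]:
    L = cfg.genome_length
    lo, hi = cfg.gene_length_range
    occupied = np.zeros(L, dtype=bool)
    genes: list[Gene] = []
    attempts = 0
    while len(genes) < cfg.n_genes and attempts < 50 * max(cfg.n_genes, 1):
        attempts += 1
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, L))
        end = start + length
        if end >= L:
            continue
        if occupied[start:end].any():
            continue
        occupied[start:end] = True
        strand = "+" if rng.random() < 0.5 else "-"
        name = f"g{len(genes) + 1:04d}"
        if strand == "+":
            genes.append(Gene(name, start, end - 1, strand))
        else:
            genes.append(Gene(name, end - 1, start, strand))
    return genes


def _plant_tract(seq: np.ndarray, pos: int, nA: int, nT: int,
                 rng: np.random.Generator) -> None:
    """Write A^nA T^nT at pos and force maximality at both flanks."""
    L = len(seq)
    length = nA + nT
    seq[pos:pos + nA] = _A
    seq[pos + nA:pos + length] = _T
    gc = lambda: int(rng.choice((_C, _G)))
    left = (pos - 1) % L
    right = (pos + length) % L
    if nA > 0:
        if seq[left] == _A:
            seq[left] = gc()
    else:  # pure T run: left neighbor must be neither A nor T
        if seq[left] in (_A, _T):
            seq[left] = gc()
    if nT > 0:
        if seq[right] == _T:
            seq[right] = gc()
    else:  # pure A run: right neighbor must be neither A nor T
        if seq[right] in (_A, _T):
            seq[right] = gc()


def _deplete_stem_atracts(seq: np.ndarray, start: int, end: int,
                          rng: np.random.Generator) -> None:
    """Break every AnTm run of length >= 3 inside [start, end).

    A middle base of each run is *swapped* with a G/C base drawn from the
    same stem, so the genome-wide base composition is preserved exactly.
    """
    from .seqfeatures import find_atracts

    for _ in range(12):
        sub = seq[start:end].tobytes().decode("ascii")
        tracts = find_atracts(sub, min_len=3, max_len=len(sub))
        if not tracts:
            return
        gc_pos = np.nonzero((seq[start:end] == _C) | (seq[start:end] == _G))[0]
        if gc_pos.size == 0:
            return
        for tr in tracts:
            mid = start + tr.start + (tr.end - tr.start) // 2
            q = start + int(rng.choice(gc_pos))
            seq[mid], seq[q] = seq[q], seq[mid]


def generate_genome(config: SimConfig) -> tuple[str, GroundTruth]:
    """Generate a genome sequence and its planted ground truth.

    The sequence is i.i.d. at the configured GC content except at planted
    A-tract intervals (A-runs followed by T-runs, total length 3-10) and in
    promoter windows, where extra tracts are planted.  Footprint stems are
    depleted of tracts by composition-preserving swaps.
    """
    config.validate()
    rng = _stage_rng(config.seed, _STAGE_GENOME)
    L = config.genome_length
    p_gc = config.gc_content
    p = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]  # A C G T
    seq = rng.choice(_BASES, size=L, p=p)

    footprints, clusters = _place_footprint_clusters(config, rng)
    genes = _place_genes(config, rng)

    planted: list[tuple[int, int]] = []
    blocked = np.zeros(L, dtype=bool)  # no planting where True
    for s, e in footprints:
        blocked[s:e] = True

    def try_plant(pos: int) -> bool:
        length = int(rng.integers(3, 11))
        nA = int(rng.integers(0, length + 1))
        nT = length - nA
        if pos < 1 or pos + length + 1 >= L:
            return False
        if blocked[pos - 1:pos + length + 1].any():
            return False
        _plant_tract(seq, pos, nA, nT, rng)
        blocked[pos - 1:pos + length + 1] = True
        planted.append((pos, pos + length))
        return True

    # A-tract groups at loop apexes (gaps between successive footprints)
    if config.atract_cluster_rate > 0:
        fp_sorted = sorted(footprints)
        fp_by_cluster: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for c in clusters:
            fp_by_cluster[c] = [fp for fp in fp_sorted if c[0] <= fp[0] < c[1]]
        for c, fps in fp_by_cluster.items():
            for (s1, e1), (s2, e2) in zip(fps, fps[1:]):
                n_groups = rng.poisson(config.atract_cluster_rate)
                for _ in range(n_groups):
                    cursor = e1 + 2
                    for _ in range(config.tracts_per_apex_group):
                        if cursor + 12 >= s2:
                            break
                        if try_plant(cursor):
                            cursor = planted[-1][1] + 2
                        else:
                            cursor += 3

    # elevated planting in promoter windows
    if config.promoter_atract_rate > 0:
        w_lo, w_hi = config.promoter_window
        for g in genes:
            if g.strand == "+":
                win = (g.tss + w_lo, g.tss + w_hi + 1)
            else:
                win = (g.tss - w_hi, g.tss - w_lo + 1)
            n_plant = rng.poisson(config.promoter_atract_rate)
            for _ in range(n_plant):
                pos = int(rng.integers(max(1, win[0]), max(2, win[1])))
                try_plant(pos)

    if config.deplete_footprint_atracts:
        for s, e in footprints:
            _deplete_stem_atracts(seq, s, e, rng)

    truth = GroundTruth(
        footprints=sorted(footprints),
        clusters=sorted(clusters),
        genes=genes,
        planted_atracts=sorted(planted),
        seed_used=config.seed,
    )
    return seq.tobytes().decode("ascii"), truth


# ---------------------------------------------------------------------------
# tag sampling
# ---------------------------------------------------------------------------

def _depletion_zone(config: SimConfig, genes: list[Gene]) -> np.ndarray:
    """Boolean mask of positions within the TSS/TES depletion halfwidth."""
    L = config.genome_length
    zone = np.zeros(L, dtype=bool)
    h = config.tss_depletion_halfwidth
    for g in genes:
        for anchor in (g.tss, g.tes):
            idx = (np.arange(anchor - h, anchor + h + 1)) % L
            zone[idx] = True
    return zone


def _emit_tags(starts: np.ndarray, ends: np.ndarray, has_minus: np.ndarray,
               L: int) -> tuple[np.ndarray, np.ndarray]:
    """Interleave per-fragment plus (always) and minus (optional) tag records.

    Returns (positions, strand_is_minus) in fragment order: plus tag of
    fragment i, then its minus tag if present.
    """
    n = len(starts)
    n_minus = int(has_minus.sum())
    total = n + n_minus
    pos = np.empty(total, dtype=np.int64)
    minus = np.zeros(total, dtype=bool)
    offset = np.concatenate([[0], np.cumsum(has_minus[:-1])]) if n else np.array([], int)
    plus_idx = np.arange(n) + offset
    pos[plus_idx] = starts % L
    minus_idx = plus_idx[has_minus] + 1
    pos[minus_idx] = (ends[has_minus] - 1) % L
    minus[minus_idx] = True
    return pos, minus


def generate_nucleoid_tags(
    sequence: str,
    truth: GroundTruth,
    config: SimConfig,
    return_fragments: bool = False,
):
    """Sample nucleoid tags from planted footprints plus unprotected background.

    Each sampled fragment yields a plus-strand tag at its left end and, with
    ``paired_end_prob``, a minus-strand tag whose 5'-end is the fragment's
    rightmost base.  Fragment centers falling within the TSS/TES depletion
    halfwidth are rejected with probability ``tss_depletion_depth``.  Exactly
    ``n_nucleoid_tags`` tags are emitted.
    """
    config.validate()
    if not truth.footprints:
        raise ValueError("nothing to sample: ground truth contains no footprints")
    L = config.genome_length
    if len(sequence) != L:
        raise ValueError("sequence length does not match config.genome_length")
    rng = _stage_rng(config.seed, _STAGE_NUCLEOID)

    fp = np.asarray(truth.footprints, dtype=np.int64)
    weights = rng.gamma(shape=20.0, scale=1.0 / 20.0, size=len(fp))
    weights /= weights.sum()
    zone = _depletion_zone(config, truth.genes)
    depth = config.tss_depletion_depth
    b = config.background_fraction
    clo, chi = config.control_fragment_length_range
    jit = config.boundary_jitter_sd

    target = config.n_nucleoid_tags
    all_pos: list[np.ndarray] = []
    all_minus: list[np.ndarray] = []
    frags: list[np.ndarray] = []
    got = 0
    while got < target:
        need = target - got
        batch = int(need / (1 + config.paired_end_prob) * 1.4) + 64
        is_bg = rng.random(batch) < b
        n_bg = int(is_bg.sum())
        starts = np.empty(batch, dtype=np.int64)
        ends = np.empty(batch, dtype=np.int64)
        # background: unconstrained fragments anywhere
        starts[is_bg] = rng.integers(0, L, size=n_bg)
        ends[is_bg] = starts[is_bg] + rng.integers(clo, chi + 1, size=n_bg)
        # protected: one fragment per drawn footprint, edges jittered
        idx = rng.choice(len(fp), size=batch - n_bg, p=weights)
        js = np.round(rng.normal(0.0, jit, size=batch - n_bg)).astype(np.int64)
        je = np.round(rng.normal(0.0, jit, size=batch - n_bg)).astype(np.int64)
        s_fp = fp[idx, 0] + js
        e_fp = np.maximum(fp[idx, 1] + je, s_fp + 2)
        starts[~is_bg] = s_fp
        ends[~is_bg] = e_fp
        if not config.circular:
            ok = (starts >= 0) & (ends <= L)
            starts, ends = starts[ok], ends[ok]
        centers = ((starts + ends) // 2) % L
        keep = ~zone[centers] | (rng.random(len(centers)) >= depth)
        starts, ends = starts[keep], ends[keep]
        has_minus = rng.random(len(starts)) < config.paired_end_prob
        pos, minus = _emit_tags(starts, ends, has_minus, L)
        all_pos.append(pos)
        all_minus.append(minus)
        if return_fragments:
            frags.append(np.column_stack([starts, ends]))
        got += len(pos)

    pos = np.concatenate(all_pos)[:target]
    minus = np.concatenate(all_minus)[:target]
    tags = TagSet.from_positions(pos[~minus], pos[minus], L,
                                 circular=config.circular,
                                 tag_length=config.tag_length)
    if return_fragments:
        return tags, np.concatenate(frags)
    return tags


def generate_control_tags(sequence: str, config: SimConfig) -> TagSet:
    """Sample control tags: naked-DNA digestion with uniform fragment lengths.

    Fragment start positions are drawn with a multiplicative cut-rate
    preference ``at_bias`` for A/T bases; lengths are uniform over
    ``control_fragment_length_range``.  The output has no characteristic
    fragment length and no spacing periodicity.
    """
    config.validate()
    if not sequence:
        raise ValueError("sequence must be non-empty")
    L = len(sequence)
    rng = _stage_rng(config.seed, _STAGE_CONTROL)
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    w = np.where((arr == _A) | (arr == _T), config.at_bias, 1.0)
    cdf = np.cumsum(w)
    clo, chi = config.control_fragment_length_range

    target = config.n_control_tags
    all_pos: list[np.ndarray] = []
    all_minus: list[np.ndarray] = []
    got = 0
    while got < target:
        need = target - got
        batch = int(need / (1 + config.paired_end_prob) * 1.2) + 64
        u = rng.random(batch) * cdf[-1]
        starts = np.searchsorted(cdf, u).astype(np.int64)
        ends = starts + rng.integers(clo, chi + 1, size=batch)
        if not config.circular:
            ok = ends <= L
            starts, ends = starts[ok], ends[ok]
        has_minus = rng.random(len(starts)) < config.paired_end_prob
        pos, minus = _emit_tags(starts, ends, has_minus, L)
        all_pos.append(pos)
        all_minus.append(minus)
        got += len(pos)

    pos = np.concatenate(all_pos)[:target]
    minus = np.concatenate(all_minus)[:target]
    return TagSet.from_positions(pos[~minus], pos[minus], L,
                                 circular=config.circular,
                                 tag_length=config.tag_length)


def inject_anomalies(
    tags: TagSet, config: SimConfig, spike_factor: float = 50.0
) -> tuple[TagSet, list[tuple[int, str, int]]]:
    """Inflate counts at random positions to emulate amplification-bias spikes.

    Per strand, positions are chosen at rate ``anomaly_spike_rate`` per bp and
    their counts raised to at least ``spike_factor`` times the mean count over
    occupied positions.  Returns the modified TagSet and the injected records
    ``(position, strand, new_count)`` for QC verification.
    """
    if config.anomaly_spike_rate < 0:
        raise ConfigError("anomaly_spike_rate must be >= 0")
    out = tags.copy()
    injected: list[tuple[int, str, int]] = []
    if config.anomaly_spike_rate == 0:
        return out, injected
    rng = _stage_rng(config.seed, _STAGE_ANOMALY)
    L = tags.genome_length
    for strand, counts in (("+", out.counts_plus), ("-", out.counts_minus)):
        occupied = counts[counts > 0]
        mean = occupied.mean() if occupied.size else 1.0
        spike = int(np.ceil(spike_factor * mean))
        n_spikes = rng.binomial(L, config.anomaly_spike_rate)
        if n_spikes == 0:
            continue
        positions = rng.choice(L, size=n_spikes, replace=False)
        for pos in positions:
            new = max(int(counts[pos]), spike)
            counts[pos] = new
            injected.append((int(pos), strand, new))
    return out, injected


# ---------------------------------------------------------------------------
# on-disk outputs
# ---------------------------------------------------------------------------

def write_fasta(sequence: str, path: str, name: str = "chr", width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i:i + width] + "\n")


def simulate_to_dir(config: SimConfig, outdir: str, chrom: str = "chr") -> dict:
    """Run all generators and write FASTA/GFF3/BED/JSON outputs to a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sequence, truth = generate_genome(config)
    nucleoid = generate_nucleoid_tags(sequence, truth, config)
    control = generate_control_tags(sequence, config)
    nucleoid, injected = inject_anomalies(nucleoid, config)

    write_fasta(sequence, out / "genome.fa", name=chrom)
    write_annotations_gff3(truth.genes, out / "genes.gff3", chrom=chrom)
    write_annotations_bed(truth.genes, out / "genes.bed", chrom=chrom)
    write_tags(nucleoid, out / "nucleoid_tags.bed", chrom=chrom)
    write_tags(control, out / "control_tags.bed", chrom=chrom)
    truth.to_json(out / "truth.json")
    with open(out / "injected_anomalies.tsv", "w") as fh:
        fh.write("position\tstrand\tcount\n")
        for pos, strand, count in injected:
            fh.write(f"{pos}\t{strand}\t{count}\n")
    return {
        "genome": str(out / "genome.fa"),
        "genes_gff3": str(out / "genes.gff3"),
        "genes_bed": str(out / "genes.bed"),
        "nucleoid_tags": str(out / "nucleoid_tags.bed"),
        "control_tags": str(out / "control_tags.bed"),
        "truth": str(out / "truth.json"),
        "anomalies": str(out / "injected_anomalies.tsv"),
    }
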
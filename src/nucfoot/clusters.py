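"""Calling clusters of digestion-resistant fragments against a randomization null.

Fragment-center density is a sum of Gaussian contributions (bandwidth 25 bp)
evaluated at every genomic position.  The density threshold is calibrated so
that the expected number of positions exceeding it under a uniform-placement
null (Monte-Carlo randomizations of the same number of centers) is at most
``fdr`` times the number of observed positions exceeding it — an empirical
positionwise FDR.  Thresholded runs longer than 25 bp, after merging runs
separated by fewer than 25 bp, are the clusters; clusters are then screened
for enrichment of nucleoid over control density.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .profiles import CenterSet

logger = logging.getLogger("nucfoot.clusters")

__all__ = [
    "DensityTrack",
    "Cluster",
    "FdrCalibration",
    "kde_density",
    "calibrate_fdr_threshold",
    "call_clusters",
    "filter_by_control",
    "write_clusters_bed",
    "read_clusters_bed",
]


@dataclass
class DensityTrack:
    """Per-position fragment-center density (fragments per bp)."""

    values: np.ndarray
    bandwidth: float
    n_source: int
    normalization: str = "raw"  # "raw" or "per-million"
    circular: bool = True

    def per_million(self) -> "DensityTrack":
        if self.normalization == "per-million":
            return self
        return DensityTrack(self.values * (1e6 / max(self.n_source, 1)),
                            self.bandwidth, self.n_source, "per-million",
                            self.circular)


@dataclass
class Cluster:
    """A contiguous interval of significant fragment-center density.

    ``end`` may exceed the genome length for a cluster wrapping the origin of
    a circular genome; coordinates are otherwise 0-based half-open.
    """

    start: int
    end: int
    summit: int
    mean_density: float
    enrichment_ratio: float | None = None
    passed_control_filter: bool | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FdrCalibration:
    fdr_target: float
    density_threshold: float
    n_randomizations: int
    seed: int
    thresholds_grid: np.ndarray = field(repr=False)
    null_exceedance: np.ndarray = field(repr=False)  # mean null positions above t
    observed_exceedance: np.ndarray = field(repr=False)

    def to_json(self, path: str) -> None:
        d = {
            "fdr_target": self.fdr_target,
            "density_threshold": (None if np.isinf(self.density_threshold)
                                  else self.density_threshold),
            "n_randomizations": self.n_randomizations,
            "seed": self.seed,
            "curve": {
                "threshold": self.thresholds_grid.tolist(),
                "null_exceedance": self.null_exceedance.tolist(),
                "observed_exceedance": self.observed_exceedance.tolist(),
            },
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


def _gaussian_kernel(bandwidth: float, trunc_sigmas: float = 8.0) -> np.ndarray:
    radius = int(np.ceil(trunc_sigmas * bandwidth))
    offs = np.arange(-radius, radius + 1, dtype=float)
    return np.exp(-0.5 * (offs / bandwidth) ** 2) / (bandwidth * np.sqrt(2 * np.pi))


def _kde_from_counts(counts: np.ndarray, bandwidth: float, circular: bool,
                     trunc_sigmas: float = 8.0) -> np.ndarray:
    kernel = _gaussian_kernel(bandwidth, trunc_sigmas)
    L = len(counts)
    radius = (len(kernel) - 1) // 2
    if circular:
        kvec = np.zeros(L)
        offs = np.arange(-radius, radius + 1)
        np.add.at(kvec, offs % L, kernel)  # aliasing handles tiny genomes
        return np.fft.irfft(np.fft.rfft(counts.astype(float)) * np.fft.rfft(kvec), L)
    from scipy.signal import fftconvolve

    return fftconvolve(counts.astype(float), kernel, mode="same")


def kde_density(centers: CenterSet, bandwidth: float = 25.0,
                normalization: str = "raw") -> DensityTrack:
    """Sum of Gaussian contributions from every fragment center.

    ``values[i] = sum_c exp(-d(i,c)^2 / (2 sigma^2)) / (sigma sqrt(2 pi))``
    with sigma = bandwidth and d the (circular) distance.  Tails are
    truncated at 8 sigma, where the per-center error is below 1e-15.  On a
    circular genome the values sum to the number of centers.
    """
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be > 0, got {bandwidth}")
    if centers.n_centers < 1:
        raise ValueError("at least one center is required")
    values = _kde_from_counts(centers.counts, bandwidth, centers.circular)
    track = DensityTrack(values, bandwidth, centers.n_centers, "raw",
                         centers.circular)
    return track.per_million() if normalization == "per-million" else track


def calibrate_fdr_threshold(
    observed: DensityTrack,
    fdr: float = 1e-3,
    n_rand: int = 20,
    seed: int = 0,
    grid_size: int = 4000,
) -> FdrCalibration:
    """Empirical positionwise FDR threshold from uniform-placement randomizations.

    For each randomization, ``n_source`` centers are placed uniformly on the
    genome and their KDE computed with the observed track's bandwidth; the
    returned threshold is the smallest density t at which the mean number of
    null positions above t is at most ``fdr`` times the number of observed
    positions above t.  If no threshold qualifies the result carries
    ``density_threshold = inf`` (an empty cluster set, not an error).
    """
    if observed.n_source < 1:
        raise ValueError("observed track has no source centers")
    rng = np.random.default_rng(seed)
    L = len(observed.values)
    scale = 1e6 / observed.n_source if observed.normalization == "per-million" else 1.0
    null_values = np.empty(n_rand * L, dtype=np.float32)
    for i in range(n_rand):
        pos = rng.integers(0, L, size=observed.n_source)
        counts = np.bincount(pos, minlength=L)
        null = _kde_from_counts(counts, observed.bandwidth, observed.circular) * scale
        null_values[i * L:(i + 1) * L] = null
    null_values.sort()

    obs_sorted = np.sort(observed.values.astype(np.float32))
    qs = np.linspace(0.0, 1.0, grid_size + 1)
    grid = np.unique(np.concatenate([
        np.quantile(obs_sorted, qs),
        np.quantile(null_values, qs[-200:]),  # resolve the extreme null tail
    ]))
    null_above = (len(null_values)
                  - np.searchsorted(null_values, grid, side="right")) / n_rand
    obs_above = len(obs_sorted) - np.searchsorted(obs_sorted, grid, side="right")
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_curve = null_above / np.maximum(obs_above, 1)
    ok = (fdr_curve <= fdr) & (obs_above > 0)
    threshold = float(grid[ok][0]) if ok.any() else float("inf")
    if not ok.any():
        logger.warning("no density threshold reaches FDR <= %g; empty result", fdr)
    return FdrCalibration(
        fdr_target=fdr,
        density_threshold=threshold,
        n_randomizations=n_rand,
        seed=seed,
        thresholds_grid=grid,
        null_exceedance=null_above,
        observed_exceedance=obs_above.astype(float),
    )


def _runs_above(values: np.ndarray, threshold: float,
                circular: bool) -> list[tuple[int, int]]:
    above = values >= threshold
    L = len(values)
    if not above.any():
        return []
    if above.all():
        return [(0, L)]
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1)
    ends = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(L)
    runs = list(zip(starts, ends))
    if circular and above[0] and above[-1]:
        # join the run wrapping the origin: represent with end > L
        first, last = runs[0], runs[-1]
        runs = runs[1:-1] + [(last[0], first[1] + L)]
        runs.sort()
    return runs


def call_clusters(density: DensityTrack, threshold: float,
                  min_length: int = 25, merge_gap: int = 25) -> list[Cluster]:
    """Threshold the density, merge nearby runs, and drop short ones.

    Maximal runs with density >= threshold that are separated by fewer than
    ``merge_gap`` bp are merged (including across the origin of a circular
    genome); merged runs shorter than ``min_length`` are discarded.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    if np.isinf(threshold):
        return []
    values = density.values
    L = len(values)
    runs = _runs_above(values, threshold, density.circular)
    if not runs:
        return []
    merged: list[list[int]] = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] < merge_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    if density.circular and len(merged) > 1:
        # gap across the origin between the last and first merged run
        last, first = merged[-1], merged[0]
        if first[0] + L - last[1] < merge_gap:
            last[1] = first[1] + L
            merged = merged[1:]
    clusters = []
    for s, e in merged:
        if e - s < min_length:
            continue
        idx = np.arange(s, e) % L
        seg = values[idx]
        summit = int(idx[np.argmax(seg)])
        clusters.append(Cluster(int(s), int(e), summit, float(seg.mean())))
    return clusters


def filter_by_control(
    clusters: list[Cluster],
    nucleoid_density: DensityTrack,
    control_density: DensityTrack,
    min_ratio: float = 1.0,
) -> list[Cluster]:
    """Drop clusters with low nucleoid/control density enrichment.

    Both tracks are depth-normalized to per-million; the enrichment ratio is
    the cluster-mean nucleoid density over the cluster-mean control density
    plus a pseudo-density of 1/genome_length.
    """
    nuc = nucleoid_density.per_million()
    ctl = control_density.per_million()
    L = len(nuc.values)
    eps = 1.0 / L
    kept = []
    for cl in clusters:
        idx = np.arange(cl.start, cl.end) % L
        ratio = float(nuc.values[idx].mean() / (ctl.values[idx].mean() + eps))
        cl.enrichment_ratio = ratio
        cl.passed_control_filter = ratio >= min_ratio
        if cl.passed_control_filter:
            kept.append(cl)
    return kept


def write_clusters_bed(clusters: list[Cluster], path: str, chrom: str = "chr",
                       genome_length: int | None = None) -> None:
    """BED6+3: name, -log10-FDR-proxy score, strand '.', then summit,
    mean_density, enrichment_ratio."""
    with open(path, "w") as fh:
        for i, cl in enumerate(clusters, start=1):
            end = cl.end
            if genome_length is not None and end > genome_length:
                end = genome_length  # clip a wrapped cluster for BED validity
            score = min(1000, int(round(100 * np.log10(1 + cl.mean_density))))
            ratio = "NA" if cl.enrichment_ratio is None else f"{cl.enrichment_ratio:.4f}"
            fh.write(f"{chrom}\t{cl.start}\t{end}\tcl{i}\t{score}\t.\t"
                     f"{cl.summit}\t{cl.mean_density:.6g}\t{ratio}\n")


def read_clusters_bed(path: str) -> list[Cluster]:
    clusters = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            summit = int(f[6]) if len(f) > 6 else (int(f[1]) + int(f[2])) // 2
            dens = float(f[7]) if len(f) > 7 else 0.0
            ratio = None
            if len(f) > 8 and f[8] != "NA":
                ratio = float(f[8])
            clusters.append(Cluster(int(f[1]), int(f[2]), summit, dens, ratio))
    return clusters
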
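"""A-tract enumeration and sequence statistics.

An *A-tract* is a maximal run of adenines directly followed by a maximal run
of thymines — AnTm with no internal TpA step — a motif associated with
intrinsic DNA curvature.  Reported tracts are bounded to total length
``min_len..max_len`` (3..10 by default); longer runs are excluded entirely
because the definition bounds n+m itself.  The *genome-to-random ratio* r(L)
compares observed per-length counts with the mean over randomized genomes of
identical base composition (uniform permutations of the genome's own bases).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ATract",
    "TractStats",
    "find_atracts",
    "tract_frequency_spectrum",
    "genome_to_random_ratio",
    "gc_content",
    "expected_tract_count",
    "write_tracts_bed",
    "write_tract_stats",
]

_RUN_RE = re.compile(r"A+T+|A+|T+")


@dataclass(frozen=True)
class ATract:
    """A maximal AnTm run; 0-based half-open interval."""

    start: int
    end: int
    nA: int
    nT: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TractStats:
    counts_by_length: dict  # length -> count
    frequency_per_kb: dict | None = None
    genome_to_random_ratio: dict | None = None  # length -> r (inf if null mean 0)
    null_mean_counts: dict | None = None
    n_randomizations: int | None = None
    randomization_seed: int | None = None
    total_bp: int | None = None


def find_atracts(sequence: str, min_len: int = 3, max_len: int = 10) -> list[ATract]:
    """Left-to-right scan for maximal A-runs followed immediately by T-runs.

    Either run may be empty (pure A- or pure T-runs qualify); consumed bases
    are not reused, and any non-A/T base (including N) breaks a run.  Only
    tracts with ``min_len <= length <= max_len`` are emitted.
    """
    if min_len < 1 or max_len < min_len:
        raise ValueError("require 1 <= min_len <= max_len")
    seq = sequence.upper()
    tracts = []
    for m in _RUN_RE.finditer(seq):
        length = m.end() - m.start()
        if not min_len <= length <= max_len:
            continue
        s = m.group()
        nA = len(s) - len(s.lstrip("A"))
        tracts.append(ATract(m.start(), m.end(), nA, length - nA))
    return tracts


def _region_mask(regions, genome_length: int) -> np.ndarray:
    mask = np.zeros(genome_length, dtype=bool)
    for s, e in regions:
        if e <= genome_length:
            mask[s:e] = True
        else:  # wrapped interval on a circular genome
            mask[s:] = True
            mask[: e - genome_length] = True
    return mask


def tract_frequency_spectrum(
    tracts: Sequence[ATract],
    regions,
    genome_length: int,
    min_len: int = 3,
    max_len: int = 10,
) -> TractStats:
    """Per-length tract counts and frequencies (tracts/kb) within a region set.

    A tract belongs to a region if its midpoint falls inside it.  ``regions``
    is an iterable of (start, end) intervals, or ``None`` for the whole
    genome.
    """
    if regions is None:
        mask = np.ones(genome_length, dtype=bool)
    else:
        mask = _region_mask(regions, genome_length)
    total = int(mask.sum())
    if total == 0:
        raise ValueError("zero-length region set")
    counts = {L: 0 for L in range(min_len, max_len + 1)}
    for tr in tracts:
        mid = ((tr.start + tr.end) // 2) % genome_length
        if mask[mid] and min_len <= tr.length <= max_len:
            counts[tr.length] += 1
    freq = {L: counts[L] / (total / 1000.0) for L in counts}
    return TractStats(counts_by_length=counts, frequency_per_kb=freq, total_bp=total)


def genome_to_random_ratio(
    sequence: str,
    min_len: int = 3,
    max_len: int = 10,
    n_rand: int = 15,
    seed: int = 0,
) -> TractStats:
    """Observed per-length tract counts over their mean in shuffled genomes.

    Each randomization is a uniform permutation of the sequence's own bases,
    preserving mononucleotide composition exactly.  A length with null mean 0
    gets an infinite ratio (with the count retained for context).
    """
    if len(sequence) < 1000:
        raise ValueError("sequence shorter than 1 kb gives unstable ratios")
    lengths = range(min_len, max_len + 1)

    def count_by_length(s: str) -> dict:
        c = {L: 0 for L in lengths}
        for tr in find_atracts(s, min_len, max_len):
            c[tr.length] += 1
        return c

    obs = count_by_length(sequence)
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    null_sums = {L: 0 for L in lengths}
    for _ in range(n_rand):
        perm = rng.permutation(arr)
        c = count_by_length(perm.tobytes().decode("ascii"))
        for L in lengths:
            null_sums[L] += c[L]
    null_mean = {L: null_sums[L] / n_rand for L in lengths}
    ratio = {
        L: (obs[L] / null_mean[L]) if null_mean[L] > 0 else float("inf")
        for L in lengths
    }
    return TractStats(
        counts_by_length=obs,
        genome_to_random_ratio=ratio,
        null_mean_counts=null_mean,
        n_randomizations=n_rand,
        randomization_seed=seed,
    )


def gc_content(sequence: str, regions=None) -> float:
    """(G+C)/(A+C+G+T) over the region bases; N excluded from the denominator."""
    seq = sequence.upper()
    if regions is None:
        sub = seq
    else:
        L = len(seq)
        mask = _region_mask(regions, L)
        if not mask.any():
            raise ValueError("empty region set")
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)[mask]
        sub = arr.tobytes().decode("ascii")
    gc = sub.count("G") + sub.count("C")
    acgt = gc + sub.count("A") + sub.count("T")
    if acgt == 0:
        raise ValueError("region contains no A/C/G/T bases")
    return gc / acgt


def expected_tract_count(p_a: float, p_t: float, length: int, seq_len: int) -> float:
    """Closed-form expected count of maximal AnTm tracts of a given total length
    on a circular i.i.d. sequence.

    A tract of composition (n, m) starting at a position requires the left
    neighbor not to extend it (not A; for a pure T-run also not T) and the
    right neighbor likewise (not T; for a pure A-run also not A).
    """
    total = 0.0
    for n in range(length + 1):
        m = length - n
        left = (1 - p_a - p_t) if n == 0 else (1 - p_a)
        right = (1 - p_a - p_t) if m == 0 else (1 - p_t)
        total += left * (p_a ** n) * (p_t ** m) * right
    return total * seq_len


def write_tracts_bed(tracts: Iterable[ATract], path: str, chrom: str = "chr") -> None:
    with open(path, "w") as fh:
        for tr in tracts:
            fh.write(f"{chrom}\t{tr.start}\t{tr.end}\tA{tr.nA}T{tr.nT}\n")


def write_tract_stats(stats: TractStats, path: str) -> None:
    with open(path, "w") as fh:
        cols = ["length", "count"]
        if stats.frequency_per_kb is not None:
            cols.append("per_kb")
        if stats.genome_to_random_ratio is not None:
            cols += ["null_mean", "genome_to_random_ratio"]
        fh.write("\t".join(cols) + "\n")
        for L in sorted(stats.counts_by_length):
            row = [str(L), str(stats.counts_by_length[L])]
            if stats.frequency_per_kb is not None:
                row.append(f"{stats.frequency_per_kb[L]:.5f}")
            if stats.genome_to_random_ratio is not None:
                row.append(f"{stats.null_mean_counts[L]:.3f}")
                r = stats.genome_to_random_ratio[L]
                row.append("inf" if np.isinf(r) else f"{r:.4f}")
            fh.write("\t".join(row) + "\n")
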
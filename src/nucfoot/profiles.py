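"""Fragment centers and strand-oriented metagene profiles around TSS/TES.

Tag 5'-end positions are shifted by half the characteristic fragment size
towards the fragment 3'-end, giving strandless *fragment centers*.  Average
profiles of center density, GC content, and A-tract coverage are computed in
windows anchored at transcription start/end sites, with minus-strand genes
mirrored so positive offsets always point downstream of transcription.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .correlation import smooth_running_window
from .tags import Gene, TagSet

logger = logging.getLogger("nucfoot.profiles")

__all__ = [
    "CenterSet",
    "MetaProfile",
    "to_fragment_centers",
    "metagene_profile",
    "gc_metaprofile",
    "atract_metaprofile",
    "profile_matrix",
]


@dataclass
class CenterSet:
    """Strandless per-position counts of fragment centers."""

    genome_length: int
    circular: bool
    counts: np.ndarray
    shift_used: int
    n_dropped: int = 0

    @property
    def n_centers(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetaProfile:
    """Per-offset mean of a signal over genes, oriented by transcription.

    Negative offsets are upstream of the anchor in transcription direction.
    """

    offsets: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray
    n_genes: int
    anchor: str  # "TSS", "TES" or "point"
    smoothing: str  # e.g. "boxcar:51" or "loess:0.10"


def to_fragment_centers(tags: TagSet, fragment_size: int) -> CenterSet:
    """Shift 5'-end tags by round(fragment_size/2) towards the fragment 3'-end.

    Plus-strand tags move right, minus-strand tags move left; on a circular
    genome positions wrap, otherwise out-of-range centers are dropped and
    counted.  The total number of centers equals the total number of tags
    (minus any dropped).
    """
    if fragment_size < 2:
        raise ValueError(f"fragment_size must be >= 2, got {fragment_size}")
    shift = int(round(fragment_size / 2))
    L = tags.genome_length
    dropped = 0
    if tags.circular:
        counts = np.roll(tags.counts_plus, shift) + np.roll(tags.counts_minus, -shift)
    else:
        counts = np.zeros(L, dtype=np.int64)
        counts[shift:] += tags.counts_plus[: L - shift]
        dropped += int(tags.counts_plus[L - shift:].sum())
        counts[: L - shift] += tags.counts_minus[shift:]
        dropped += int(tags.counts_minus[:shift].sum())
        if dropped:
            logger.warning("%d centers fell outside the linear genome and were dropped",
                           dropped)
    return CenterSet(L, tags.circular, counts, shift, dropped)


def profile_matrix(values: np.ndarray, genes: Sequence[Gene], anchor: str,
                   flank: int, circular: bool = True) -> tuple[np.ndarray, int]:
    """Gene x offset matrix of ``values`` around gene anchors, strand-oriented.

    Returns the matrix and the number of genes used (genes too close to a
    linear-genome boundary are skipped with a warning).
    """
    L = len(values)
    offsets = np.arange(-flank, flank + 1)
    rows = []
    skipped = 0
    for g in genes:
        a = g.tss if anchor.upper() == "TSS" else g.tes
        idx = a + offsets if g.strand == "+" else a - offsets
        if circular:
            idx = idx % L
        elif idx.min() < 0 or idx.max() >= L:
            skipped += 1
            continue
        rows.append(values[idx])
    if skipped:
        logger.warning("%d genes skipped: anchor closer than flank to the boundary",
                       skipped)
    if not rows:
        raise ValueError("no usable genes for the metagene profile")
    return np.asarray(rows, dtype=float), len(rows)


def metagene_profile(centers: CenterSet, genes: Sequence[Gene], anchor: str = "TSS",
                     flank: int = 500, window: int = 50) -> MetaProfile:
    """Mean fragment-center count per offset around TSS or TES, boxcar-smoothed."""
    if not genes:
        raise ValueError("at least one gene is required")
    mat, n_used = profile_matrix(centers.counts.astype(float), genes, anchor,
                                 flank, centers.circular)
    raw = mat.mean(axis=0)
    smoothed = smooth_running_window(raw, window)
    w = int(round(window)) | 1
    return MetaProfile(np.arange(-flank, flank + 1), raw, smoothed, n_used,
                       anchor.upper(), f"boxcar:{w}")


def gc_metaprofile(sequence: str, genes: Sequence[Gene], anchor: str = "TSS",
                   flank: int = 500, window: int = 50,
                   circular: bool = True) -> MetaProfile:
    """Fraction of genes with G or C at each strand-oriented offset.

    GC is invariant under complementation, so minus-strand genes only reverse
    the window.
    """
    if not genes:
        raise ValueError("at least one gene is required")
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    is_gc = ((arr == ord("G")) | (arr == ord("C"))).astype(float)
    mat, n_used = profile_matrix(is_gc, genes, anchor, flank, circular)
    raw = mat.mean(axis=0)
    smoothed = smooth_running_window(raw, window)
    w = int(round(window)) | 1
    return MetaProfile(np.arange(-flank, flank + 1), raw, smoothed, n_used,
                       anchor.upper(), f"boxcar:{w}")


def atract_metaprofile(atracts, genes: Sequence[Gene], genome_length: int,
                       anchor: str = "TSS", flank: int = 500,
                       loess_frac: float = 0.1, circular: bool = True) -> MetaProfile:
    """Fraction of genes with an A-tract covering each strand-oriented offset.

    The raw profile is the per-offset mean of the tract coverage indicator; a
    loess-smoothed curve is emitted alongside.
    """
    if not genes:
        raise ValueError("at least one gene is required")
    cover = np.zeros(genome_length, dtype=float)
    for tr in atracts:
        start, end = (tr.start, tr.end) if hasattr(tr, "start") else (tr[0], tr[1])
        if end <= genome_length:
            cover[start:end] = 1.0
        else:  # wrapped tract on a circular genome
            cover[start:] = 1.0
            cover[: end - genome_length] = 1.0
    mat, n_used = profile_matrix(cover, genes, anchor, flank, circular)
    raw = mat.mean(axis=0)
    offsets = np.arange(-flank, flank + 1)
    if np.allclose(raw, raw[0]):
        smoothed = raw.copy()
    else:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        smoothed = lowess(raw, offsets.astype(float), frac=loess_frac,
                          return_sorted=False)
    return MetaProfile(offsets, raw, smoothed, n_used, anchor.upper(),
                       f"loess:{loess_frac:.2f}")


def write_metaprofile(profile: MetaProfile, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# anchor={profile.anchor}\tn_genes={profile.n_genes}\t"
                 f"smoothing={profile.smoothing}\n")
        fh.write("offset\traw\tsmoothed\n")
        for o, r, s in zip(profile.offsets, profile.raw, profile.smoothed):
            fh.write(f"{o}\t{r:.6g}\t{s:.6g}\n")


__all__.append("write_metaprofile")
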
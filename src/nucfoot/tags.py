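"""Reading, writing and quality control of digestion-fragment 5'-end tags.

A *tag* is the sequenced 36-bp 5'-end of an MNase digestion fragment, mapped
to one strand of a (usually circular) bacterial genome.  The in-memory
container is :class:`TagSet`: two per-position integer count vectors, one per
strand.  Quality control removes *anomalous positions* — isolated pile-ups of
duplicate tags that typically arise from amplification bias — using a Z-score
cut on the per-strand distribution of counts over occupied positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

logger = logging.getLogger("nucfoot.tags")

__all__ = [
    "Tag",
    "TagSet",
    "QCReport",
    "Gene",
    "ParseError",
    "CoordinateError",
    "read_tags",
    "write_tags",
    "filter_anomalous_positions",
    "read_annotations",
    "write_annotations_gff3",
    "write_annotations_bed",
    "write_bedgraph",
    "write_qc_report",
]


class ParseError(ValueError):
    """A record in an input file could not be parsed."""


class CoordinateError(ValueError):
    """A record lies outside the genome on a non-circular sequence."""


class Tag(NamedTuple):
    chrom: str
    pos5: int
    strand: str


class Gene(NamedTuple):
    """A gene with strand-aware TSS/TES.

    ``tss`` is the 5' boundary in transcription direction, ``tes`` the 3'
    boundary, both 0-based.  Minus-strand genes have ``tss > tes`` in genome
    coordinates.
    """

    name: str
    tss: int
    tes: int
    strand: str


@dataclass
class TagSet:
    """Per-strand counts of tag 5'-ends along one genome."""

    genome_length: int
    circular: bool
    counts_plus: np.ndarray
    counts_minus: np.ndarray
    tag_length: int = 36

    def __post_init__(self) -> None:
        self.counts_plus = np.asarray(self.counts_plus, dtype=np.int64)
        self.counts_minus = np.asarray(self.counts_minus, dtype=np.int64)
        if len(self.counts_plus) != self.genome_length:
            raise ValueError("counts_plus length != genome_length")
        if len(self.counts_minus) != self.genome_length:
            raise ValueError("counts_minus length != genome_length")

    @property
    def n_tags(self) -> int:
        return int(self.counts_plus.sum() + self.counts_minus.sum())

    @classmethod
    def from_positions(
        cls,
        pos_plus: Sequence[int],
        pos_minus: Sequence[int],
        genome_length: int,
        circular: bool = True,
        tag_length: int = 36,
    ) -> "TagSet":
        cp = np.bincount(np.asarray(pos_plus, dtype=np.int64) % genome_length,
                         minlength=genome_length)
        cm = np.bincount(np.asarray(pos_minus, dtype=np.int64) % genome_length,
                         minlength=genome_length)
        return cls(genome_length, circular, cp, cm, tag_length)

    def copy(self) -> "TagSet":
        return TagSet(self.genome_length, self.circular,
                      self.counts_plus.copy(), self.counts_minus.copy(),
                      self.tag_length)


@dataclass
class QCReport:
    """Outcome of the anomalous-position filter."""

    z_threshold: float
    removed_positions: list  # (position, strand, count, z)
    tags_removed: int
    mean: dict  # strand -> mean of count distribution used
    sd: dict  # strand -> population SD of count distribution used


def _resolve_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.upper()
    p = str(path).lower()
    if p.endswith((".sam", ".bam")):
        return "SAM"
    return "BED"


def read_tags(
    path: str,
    genome_length: int,
    fmt: str | None = None,
    circular: bool = True,
    tag_length: int = 36,
    min_mapq: int = 0,
) -> TagSet:
    """Read aligned tags from BED6 or SAM/BAM into per-strand count vectors.

    Each record contributes one count at the 5'-end position of its strand:
    the interval start for plus-strand records and ``end - 1`` for
    minus-strand records.  ``min_mapq`` (SAM/BAM only) is a proxy for the
    upstream unique-alignment convention.
    """
    fmt = _resolve_format(path, fmt)
    pos_plus: list[int] = []
    pos_minus: list[int] = []
    if fmt == "BED":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 6:
                    raise ParseError(
                        f"{path}:{lineno}: BED6 requires 6 fields, got {len(fields)}"
                    )
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
                strand = fields[5]
                if strand not in "+-":
                    raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
                pos = start if strand == "+" else end - 1
                if not 0 <= pos < genome_length:
                    if circular:
                        pos %= genome_length
                    else:
                        raise CoordinateError(
                            f"{path}:{lineno}: position {pos} outside [0, {genome_length})"
                        )
                (pos_plus if strand == "+" else pos_minus).append(pos)
    elif fmt in ("SAM", "BAM"):
        import pysam

        mode = "rb" if str(path).lower().endswith(".bam") else "r"
        with pysam.AlignmentFile(path, mode, check_sq=False) as af:
            for read in af.fetch(until_eof=True):
                if read.is_unmapped or read.mapping_quality < min_mapq:
                    continue
                if read.is_reverse:
                    pos = read.reference_end - 1
                    bucket = pos_minus
                else:
                    pos = read.reference_start
                    bucket = pos_plus
                if not 0 <= pos < genome_length:
                    if circular:
                        pos %= genome_length
                    else:
                        raise CoordinateError(
                            f"{path}: read {read.query_name} outside genome"
                        )
                bucket.append(pos)
    else:
        raise ValueError(f"unknown tag format {fmt!r}")
    return TagSet.from_positions(pos_plus, pos_minus, genome_length,
                                 circular=circular, tag_length=tag_length)


def write_tags(tags: TagSet, path: str, chrom: str = "chr") -> None:
    """Write a TagSet as BED6, one record per tag (duplicates repeated).

    The written interval is the ``tag_length``-bp tag, clipped at sequence
    ends; the strand-appropriate 5'-end coordinate is always preserved, so
    ``read_tags(write_tags(x))`` round-trips the count vectors.
    """
    L, tl = tags.genome_length, tags.tag_length
    with open(path, "w") as fh:
        for strand, counts in (("+", tags.counts_plus), ("-", tags.counts_minus)):
            for pos in np.nonzero(counts)[0]:
                if strand == "+":
                    start, end = int(pos), min(int(pos) + tl, L)
                else:
                    start, end = max(0, int(pos) + 1 - tl), int(pos) + 1
                rec = f"{chrom}\t{start}\t{end}\t.\t0\t{strand}\n"
                fh.write(rec * int(counts[pos]))


def _strand_stats(counts: np.ndarray, include_zero_positions: bool) -> tuple[float, float]:
    values = counts if include_zero_positions else counts[counts > 0]
    if values.size == 0:
        return 0.0, 0.0
    return float(values.mean()), float(values.std(ddof=0))


def filter_anomalous_positions(
    tags: TagSet,
    z_threshold: float = 7.0,
    pool_strands: bool = False,
    include_zero_positions: bool = False,
) -> tuple[TagSet, QCReport]:
    """Remove positions whose tag count is a Z-score outlier.

    Per strand (or pooled across strands), the mean and population SD of the
    count distribution over occupied positions are computed; positions with
    ``(count - mean)/sd > z_threshold`` are zeroed.  Such positions are
    characteristic of amplification-bias pile-ups rather than genuine
    protection.  Statistics use occupied (count >= 1) positions by default
    because the genome-wide mean over all positions is far below 1, which
    would make the cut remove essentially every duplicated position.
    """
    if tags.n_tags == 0:
        raise ValueError("cannot filter an empty TagSet")
    out = tags.copy()
    removed: list[tuple[int, str, int, float]] = []
    means: dict[str, float] = {}
    sds: dict[str, float] = {}

    if pool_strands:
        both = np.concatenate([tags.counts_plus, tags.counts_minus])
        mean, sd = _strand_stats(both, include_zero_positions)
        stats = {"+": (mean, sd), "-": (mean, sd)}
    else:
        stats = {
            "+": _strand_stats(tags.counts_plus, include_zero_positions),
            "-": _strand_stats(tags.counts_minus, include_zero_positions),
        }

    for strand, counts in (("+", out.counts_plus), ("-", out.counts_minus)):
        mean, sd = stats[strand]
        means[strand], sds[strand] = mean, sd
        if sd == 0.0:
            logger.warning(
                "strand %s: zero SD of the count distribution, nothing removed", strand
            )
            continue
        z = (counts - mean) / sd
        hit = np.nonzero((counts > 0) & (z > z_threshold))[0]
        for pos in hit:
            removed.append((int(pos), strand, int(counts[pos]), float(z[pos])))
        counts[hit] = 0

    report = QCReport(
        z_threshold=z_threshold,
        removed_positions=removed,
        tags_removed=int(sum(r[2] for r in removed)),
        mean=means,
        sd=sds,
    )
    return out, report


def read_annotations(path: str, fmt: str | None = None,
                     feature_types: tuple[str, ...] = ("gene",)) -> list[Gene]:
    """Read gene annotations from GFF3 or BED6 as (name, TSS, TES, strand).

    GFF3 coordinates are 1-based inclusive; a plus-strand gene ``1000..2000``
    maps to ``TSS=999, TES=1999`` in 0-based terms, a minus-strand one to
    ``TSS=1999, TES=999``.  Records without a strand are skipped with a
    warning.
    """
    if fmt is None:
        fmt = "GFF3" if str(path).lower().endswith((".gff", ".gff3")) else "BED"
    fmt = fmt.upper()
    genes: list[Gene] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fmt == "GFF3":
                if len(fields) < 9:
                    raise ParseError(f"{path}:{lineno}: GFF3 requires 9 fields")
                if fields[2] not in feature_types:
                    continue
                start, end = int(fields[3]), int(fields[4])
                strand = fields[6]
                attrs = dict(
                    kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                )
                name = attrs.get("Name") or attrs.get("ID") or attrs.get(
                    "locus_tag") or f"gene{lineno}"
                if strand == "+":
                    tss, tes = start - 1, end - 1
                elif strand == "-":
                    tss, tes = end - 1, start - 1
                else:
                    logger.warning("%s:%d: missing strand, record skipped", path, lineno)
                    continue
            else:  # BED6
                if len(fields) < 6:
                    raise ParseError(f"{path}:{lineno}: BED6 requires 6 fields")
                start, end = int(fields[1]), int(fields[2])
                strand = fields[5]
                name = fields[3]
                if strand == "+":
                    tss, tes = start, end - 1
                elif strand == "-":
                    tss, tes = end - 1, start
                else:
                    logger.warning("%s:%d: missing strand, record skipped", path, lineno)
                    continue
            genes.append(Gene(name, tss, tes, strand))
    return genes


def _gene_interval(g: Gene) -> tuple[int, int]:
    """0-based half-open genomic interval of a gene."""
    if g.strand == "+":
        return g.tss, g.tes + 1
    return g.tes, g.tss + 1


def write_annotations_gff3(genes: Sequence[Gene], path: str, chrom: str = "chr") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start, end = _gene_interval(g)
            fh.write(
                f"{chrom}\tnucfoot\tgene\t{start + 1}\t{end}\t.\t{g.strand}\t.\t"
                f"ID={g.name};Name={g.name}\n"
            )


def write_annotations_bed(genes: Sequence[Gene], path: str, chrom: str = "chr") -> None:
    with open(path, "w") as fh:
        for g in genes:
            start, end = _gene_interval(g)
            fh.write(f"{chrom}\t{start}\t{end}\t{g.name}\t0\t{g.strand}\n")


def write_bedgraph(values: np.ndarray, path: str, chrom: str = "chr") -> None:
    """Write a per-position track as run-length-compressed bedGraph."""
    values = np.asarray(values)
    change = np.nonzero(np.diff(values))[0]
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [len(values)]])
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            v = values[s]
            fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def write_qc_report(report: QCReport, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# z_threshold\t{report.z_threshold}\n")
        for strand in sorted(report.mean):
            fh.write(f"# strand {strand}: mean={report.mean[strand]:.6g}\t"
                     f"sd={report.sd[strand]:.6g}\n")
        fh.write(f"# tags_removed\t{report.tags_removed}\n")
        fh.write("position\tstrand\tcount\tz\n")
        for pos, strand, count, z in report.removed_positions:
            fh.write(f"{pos}\t{strand}\t{count}\t{z:.4f}\n")
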
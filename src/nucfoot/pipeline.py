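"""End-to-end orchestration: tags -> QC -> correlations -> centers -> profiles
-> clusters -> sequence statistics -> (optional) ChIP association.

All stage parameters default to the analysis constants of the modelled
experiment: Z-score 7 anomaly filter, 25-bp correlation smoothing, 25-bp KDE
bandwidth, FDR 1e-3 with 20 randomizations, 25-bp minimum cluster length and
merge gap, 50-bp metagene smoothing, tract lengths 3-10 with 15 shuffles.
Every stage writes its outputs to disk so any downstream stage can be
resumed from files alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import chip as chip_mod
from . import clusters as cl
from . import correlation as corr
from . import profiles as prof
from . import seqfeatures as sf
from . import tags as tio

logger = logging.getLogger("nucfoot.pipeline")

__all__ = ["RunConfig", "PipelineError", "run_all"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and context."""


@dataclass
class RunConfig:
    """Paths and parameters of a full analysis run."""

    # inputs
    nucleoid_tags: str = ""
    control_tags: str = ""
    fasta: str = ""
    annotations: str = ""
    chip_track: str = ""
    genome_length: int = 0  # 0 = take from FASTA
    circular: bool = True
    tag_length: int = 36
    # QC
    z_threshold: float = 7.0
    # correlations
    cross_max_lag: int = 500
    auto_max_lag: int = 1000
    correlation_window: int = 25
    read_length: int = 36
    exclusion_halfwidth: int = 5
    period_range: tuple[float, float] = (50.0, 500.0)
    fragment_size_fallback: int = 50
    # profiles
    metagene_flank: int = 500
    metagene_window: int = 50
    loess_frac: float = 0.1
    # clusters
    bandwidth: float = 25.0
    fdr: float = 1e-3
    fdr_randomizations: int = 20
    min_cluster_length: int = 25
    merge_gap: int = 25
    min_enrichment_ratio: float = 1.0
    # sequence features
    tract_min_len: int = 3
    tract_max_len: int = 10
    tract_randomizations: int = 15
    # chip
    chip_flank: int = 1000
    # misc
    seed: int = 0
    outdir: str = "nucfoot_out"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "period_range" in data:
            data["period_range"] = tuple(data["period_range"])
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        d["period_range"] = list(d["period_range"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _read_fasta(path: str) -> str:
    from pyfaidx import Fasta

    fa = Fasta(path, as_raw=True, sequence_always_upper=True)
    names = list(fa.keys())
    if len(names) != 1:
        logger.warning("FASTA has %d records; using the first (%s)",
                       len(names), names[0])
    return str(fa[names[0]][:])


def run_all(config: RunConfig) -> dict:
    """Execute every stage and write a JSON + Markdown report.

    Returns the report dictionary.  The report is a pure function of the
    inputs, parameters and seed (no timestamps), so repeat runs are
    byte-identical.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": {
        "z_threshold": config.z_threshold,
        "bandwidth": config.bandwidth,
        "fdr": config.fdr,
        "min_cluster_length": config.min_cluster_length,
        "merge_gap": config.merge_gap,
        "tract_length_range": [config.tract_min_len, config.tract_max_len],
        "seed": config.seed,
    }}

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("inputs")
        sequence = _read_fasta(config.fasta) if config.fasta else ""
        L = config.genome_length or len(sequence)
        if L == 0:
            raise PipelineError("inputs: need genome_length or a FASTA")
        nucleoid = tio.read_tags(config.nucleoid_tags, L,
                                 circular=config.circular,
                                 tag_length=config.tag_length)
        control = (tio.read_tags(config.control_tags, L,
                                 circular=config.circular,
                                 tag_length=config.tag_length)
                   if config.control_tags else None)
        genes = (tio.read_annotations(config.annotations)
                 if config.annotations else [])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"inputs: {exc}") from exc

    try:
        stage("qc")
        nucleoid, qc_nuc = tio.filter_anomalous_positions(nucleoid, config.z_threshold)
        tio.write_qc_report(qc_nuc, out / "qc_nucleoid.tsv")
        report["qc"] = {"nucleoid_tags_removed": qc_nuc.tags_removed,
                        "nucleoid_positions_removed": len(qc_nuc.removed_positions)}
        if control is not None:
            control, qc_ctl = tio.filter_anomalous_positions(control, config.z_threshold)
            tio.write_qc_report(qc_ctl, out / "qc_control.tsv")
            report["qc"]["control_tags_removed"] = qc_ctl.tags_removed
    except Exception as exc:
        raise PipelineError(f"qc: {exc}") from exc

    try:
        stage("fragsize")
        cross = corr.strand_cross_correlation(nucleoid, config.cross_max_lag,
                                              config.correlation_window)
        _write_profile_tsv(cross, out / "cross_correlation.tsv")
        try:
            est = corr.estimate_fragment_size(cross, config.read_length,
                                              config.exclusion_halfwidth)
            fragment_size = est.fragment_size
            report["fragment_size"] = {
                "estimate": est.fragment_size,
                "peak_value": round(est.peak_value, 6),
                "technical_peak_lag": est.technical_peak_lag,
                "no_estimate": False,
            }
        except corr.NoEstimateError:
            fragment_size = config.fragment_size_fallback
            report["fragment_size"] = {
                "estimate": None,
                "no_estimate": True,
                "fallback_used": fragment_size,
            }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"fragsize: {exc}") from exc

    try:
        stage("periodicity")
        auto = corr.strand_auto_correlation(nucleoid, config.auto_max_lag,
                                            config.correlation_window)
        _write_profile_tsv(auto, out / "auto_correlation.tsv")
        try:
            pg = corr.periodogram(auto, config.period_range)
            _write_periodogram_tsv(pg, out / "periodogram.tsv")
            report["dominant_period"] = round(pg.dominant_period, 2)
        except corr.NoDominantPeriodError:
            report["dominant_period"] = None
    except Exception as exc:
        raise PipelineError(f"periodicity: {exc}") from exc

    try:
        stage("centers")
        centers = prof.to_fragment_centers(nucleoid, fragment_size)
        tio.write_bedgraph(centers.counts, out / "centers.bedgraph")
        ctl_centers = (prof.to_fragment_centers(control, fragment_size)
                       if control is not None else None)
    except Exception as exc:
        raise PipelineError(f"centers: {exc}") from exc

    atracts = sf.find_atracts(sequence, config.tract_min_len,
                              config.tract_max_len) if sequence else []

    if genes:
        try:
            stage("profiles")
            for anchor in ("TSS", "TES"):
                mp = prof.metagene_profile(centers, genes, anchor,
                                           config.metagene_flank,
                                           config.metagene_window)
                prof.write_metaprofile(mp, out / f"centers_{anchor.lower()}.tsv")
                if sequence:
                    gp = prof.gc_metaprofile(sequence, genes, anchor,
                                             config.metagene_flank,
                                             config.metagene_window,
                                             config.circular)
                    prof.write_metaprofile(gp, out / f"gc_{anchor.lower()}.tsv")
            if atracts:
                ap = prof.atract_metaprofile(atracts, genes, L, "TSS",
                                             config.metagene_flank,
                                             config.loess_frac, config.circular)
                prof.write_metaprofile(ap, out / "atract_tss.tsv")
        except Exception as exc:
            raise PipelineError(f"profiles: {exc}") from exc

    try:
        stage("clusters")
        density = cl.kde_density(centers, config.bandwidth)
        calib = cl.calibrate_fdr_threshold(density, config.fdr,
                                           config.fdr_randomizations, config.seed)
        calib.to_json(out / "fdr_calibration.json")
        called = cl.call_clusters(density, calib.density_threshold,
                                  config.min_cluster_length, config.merge_gap)
        if ctl_centers is not None:
            ctl_density = cl.kde_density(ctl_centers, config.bandwidth)
            called = cl.filter_by_control(called, density, ctl_density,
                                          config.min_enrichment_ratio)
        cl.write_clusters_bed(called, out / "clusters.bed", genome_length=L)
        lengths = [min(c.length, L) for c in called]
        report["clusters"] = {
            "n": len(called),
            "median_length": float(np.median(lengths)) if lengths else None,
            "density_threshold": (None if np.isinf(calib.density_threshold)
                                  else round(calib.density_threshold, 6)),
            "genome_fraction": round(sum(lengths) / L, 6),
        }
    except Exception as exc:
        raise PipelineError(f"clusters: {exc}") from exc

    if sequence:
        try:
            stage("atracts")
            sf.write_tracts_bed(atracts, out / "atracts.bed")
            cluster_regions = [(c.start, c.end) for c in called] or None
            coding_regions = [tio._gene_interval(g) for g in genes] or None
            spectra = {"genome": sf.tract_frequency_spectrum(
                atracts, None, L, config.tract_min_len, config.tract_max_len)}
            if cluster_regions:
                spectra["clusters"] = sf.tract_frequency_spectrum(
                    atracts, cluster_regions, L,
                    config.tract_min_len, config.tract_max_len)
                report["cluster_gc"] = round(sf.gc_content(sequence, cluster_regions), 4)
            if coding_regions:
                spectra["coding"] = sf.tract_frequency_spectrum(
                    atracts, coding_regions, L,
                    config.tract_min_len, config.tract_max_len)
            for name, st in spectra.items():
                sf.write_tract_stats(st, out / f"atract_spectrum_{name}.tsv")
            report["atract_frequency_per_kb"] = {
                name: {str(k): round(v, 5) for k, v in st.frequency_per_kb.items()}
                for name, st in spectra.items()
            }
            ratios = sf.genome_to_random_ratio(sequence, config.tract_min_len,
                                               config.tract_max_len,
                                               config.tract_randomizations,
                                               config.seed)
            sf.write_tract_stats(ratios, out / "atract_genome_to_random.tsv")
            report["genome_to_random_ratio"] = {
                str(k): (None if np.isinf(v) else round(v, 4))
                for k, v in ratios.genome_to_random_ratio.items()
            }
        except Exception as exc:
            raise PipelineError(f"atracts: {exc}") from exc

    if config.chip_track:
        try:
            stage("chip")
            track = chip_mod.zscore_track(chip_mod.read_bedgraph(config.chip_track, L))
            points = [(c.start + c.length // 2) % L for c in called]
            if points:
                mp = chip_mod.profile_around(points, track, config.chip_flank,
                                             config.circular)
                prof.write_metaprofile(mp, out / "chip_around_clusters.tsv")
                center_idx = config.chip_flank
                report["chip"] = {
                    "n_clusters": len(points),
                    "central_z": round(float(mp.raw[center_idx]), 4),
                    "flank_z": round(float(np.mean(mp.raw[:100])), 4),
                }
        except Exception as exc:
            raise PipelineError(f"chip: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    (out / "report.md").write_text(_markdown_report(report))
    return report


def _write_profile_tsv(profile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kind={profile.kind}\twindow={profile.window}\n")
        fh.write("lag\traw\tsmoothed\n")
        for lag, r, s in zip(profile.lags, profile.raw, profile.smoothed):
            fh.write(f"{lag}\t{r:.8g}\t{s:.8g}\n")


def _write_periodogram_tsv(pg, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# dominant_period={pg.dominant_period:.4f}\n")
        fh.write("period\tpower\n")
        for p, w in zip(pg.periods, pg.power):
            fh.write(f"{p:.4f}\t{w:.8g}\n")


def _markdown_report(report: dict) -> str:
    lines = ["# nucfoot analysis report", ""]
    fs = report.get("fragment_size", {})
    if fs.get("no_estimate"):
        lines.append("- Fragment size: **no estimate** (control-like sample); "
                     f"fallback {fs.get('fallback_used')} bp used for centering")
    elif fs:
        lines.append(f"- Characteristic fragment size: **{fs['estimate']} bp** "
                     f"(technical peak: {fs.get('technical_peak_lag')})")
    if report.get("dominant_period") is not None:
        lines.append(f"- Dominant spacing period: **{report['dominant_period']} bp**")
    c = report.get("clusters")
    if c:
        lines.append(f"- Clusters: **{c['n']}** "
                     f"(median length {c['median_length']} bp, "
                     f"{100 * c['genome_fraction']:.2f}% of genome)")
    if "cluster_gc" in report:
        lines.append(f"- Cluster GC content: **{100 * report['cluster_gc']:.1f}%**")
    r = report.get("genome_to_random_ratio")
    if r:
        lines.append("- A-tract genome-to-random ratios: "
                     + ", ".join(f"r({k})={v}" for k, v in sorted(
                         r.items(), key=lambda kv: int(kv[0]))))
    ch = report.get("chip")
    if ch:
        lines.append(f"- ChIP signal at cluster centers: z = {ch['central_z']} "
                     f"(distal flank z = {ch['flank_z']})")
    lines.append("")
    return "\n".join(lines)
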
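"""Association of ChIP signal with digestion-resistant clusters.

A ChIP coverage track (e.g. H-NS binding) is z-score normalized genome-wide,
and its mean profile is computed in windows centered on cluster midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .profiles import MetaProfile

__all__ = [
    "SignalTrack",
    "DegenerateTrackError",
    "zscore_track",
    "profile_around",
    "read_bedgraph",
]


class DegenerateTrackError(ValueError):
    """The track has zero variance; z-scores are undefined."""


@dataclass
class SignalTrack:
    values: np.ndarray
    zvalues: np.ndarray
    mean: float
    sd: float


def zscore_track(values: np.ndarray) -> SignalTrack:
    """Standardize a per-position signal: z = (x - mu) / sigma genome-wide."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("at least 2 positions are required")
    mu = float(values.mean())
    sigma = float(values.std(ddof=0))
    if sigma == 0.0:
        raise DegenerateTrackError("constant track: zero variance")
    return SignalTrack(values, (values - mu) / sigma, mu, sigma)


def profile_around(points: Sequence[int], track: SignalTrack,
                   flank: int = 1000, circular: bool = True) -> MetaProfile:
    """Mean z-scored signal at each offset in [-flank, +flank] around points."""
    points = np.asarray(points, dtype=np.int64)
    if points.size < 1:
        raise ValueError("at least one point is required")
    L = len(track.zvalues)
    offsets = np.arange(-flank, flank + 1)
    idx = points[:, None] + offsets[None, :]
    if circular:
        idx = idx % L
    else:
        ok = (idx.min(axis=1) >= 0) & (idx.max(axis=1) < L)
        idx = idx[ok]
        if idx.shape[0] == 0:
            raise ValueError("no point has a full window inside the genome")
    mat = track.zvalues[idx]
    raw = mat.mean(axis=0)
    return MetaProfile(offsets, raw, raw.copy(), int(mat.shape[0]), "point", "none")


def read_bedgraph(path: str, genome_length: int) -> np.ndarray:
    """Expand a bedGraph track to a per-bp vector (bins constant-filled)."""
    values = np.zeros(genome_length, dtype=float)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            start, end, v = int(f[1]), int(f[2]), float(f[3])
            values[start:min(end, genome_length)] = v
    return values
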
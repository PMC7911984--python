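"""Per-base score tracks: SNP density, distance-weighted identity, and the
conservation score.

The conservation score at position n combines three signals:

    cs_raw[n] = mean_i( I[i,n] * d[i] ) * (1 - sigma[n]) / (1 + sigma[n]) * 2**p[n]

where I[i,n] is windowed alignment identity of species i, d[i] its
phylogenetic distance to the reference (more distant species carry more
weight for the same identity), sigma[n] the intraspecies SNP density in a
20-bp window (dense variation suppresses the score), and p[n] a per-site
selection statistic in the phyloP CONACC convention (positive = conserved
sites are boosted, negative = accelerated sites are damped).  Raw scores are
then MinMax-scaled to [0, 1] per chromosome arm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .phylo import DistanceVector
from .scan import IdentityMatrix

SNP_WINDOW = 20
GROUP_WINDOW = 1_000_000


@dataclass
class ConservationTrack:
    chrom: str
    cs_raw: np.ndarray
    cs_scaled: np.ndarray
    scaling_domain: str = "arm"  # {"arm", "genome"}


def snp_density(
    positions: np.ndarray, chrom_length: int, window: int = SNP_WINDOW
) -> np.ndarray:
    """Average SNP density in a sliding window centred on each position.

    sigma[n] = (variant positions in the length-`window` window centred at n,
    truncated at chromosome ends) / (actual window span).  Positions must be
    sorted, unique, and within [0, chrom_length).
    """
    positions = np.asarray(positions, dtype=np.int64)
    if positions.size and (np.any(np.diff(positions) <= 0)):
        raise ValueError("variant positions must be sorted and unique")
    if positions.size and (positions[0] < 0 or positions[-1] >= chrom_length):
        raise ValueError("variant position outside chromosome")
    indicator = np.zeros(chrom_length, dtype=np.int64)
    indicator[positions] = 1
    cumsum = np.concatenate(([0], np.cumsum(indicator)))
    n = np.arange(chrom_length)
    lo = np.maximum(0, n - window // 2)
    hi = np.minimum(chrom_length, n - window // 2 + window)
    counts = cumsum[hi] - cumsum[lo]
    return counts / (hi - lo)


def normalize_identity(identity: IdentityMatrix, distances: DistanceVector) -> np.ndarray:
    """Weight each species' identity row by its phylogenetic distance.

    Returns the matrix with row i multiplied by d[i], giving more weight to
    the same identity in species more distant from the reference.
    """
    if list(distances.species) != list(identity.species):
        raise ValueError("species order of distances does not match identity matrix")
    return identity.values * distances.d[:, None]


def conservation_score(
    normalized: np.ndarray, sigma: np.ndarray, p: np.ndarray
) -> np.ndarray:
    """Raw per-base conservation score from the three input tracks.

    The mean is taken over all configured species (rows); species without an
    alignment at n contribute identity 0, so unalignable sequence scores 0.
    """
    normalized = np.asarray(normalized, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    p = np.asarray(p, dtype=float)
    if normalized.ndim != 2:
        raise ValueError("normalized identity must be 2-D (species x positions)")
    n = normalized.shape[1]
    if sigma.shape != (n,) or p.shape != (n,):
        raise ValueError("track length mismatch")
    if np.any(sigma < 0) or np.any(sigma > 1):
        raise ValueError("SNP density must lie in [0, 1]")
    if not np.all(np.isfinite(p)):
        raise ValueError("selection scores must be finite")
    mean_identity = normalized.mean(axis=0)
    snp_factor = (1.0 - sigma) / (1.0 + sigma)
    selection_factor = np.exp2(p)
    return mean_identity * snp_factor * selection_factor


def minmax_scale(raw: np.ndarray) -> np.ndarray:
    """MinMax scaling x -> (x - min) / (max - min) over one domain.

    A constant domain (no conservation contrast) maps to all zeros with a
    warning.  The caller chooses the domain: one chromosome arm (default
    elsewhere) or a whole-genome concatenation.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("cannot scale an empty domain")
    lo = raw.min()
    hi = raw.max()
    if hi == lo:
        warnings.warn("constant track: MinMax scaling maps the domain to 0")
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


def build_conservation(
    identity: IdentityMatrix,
    distances: DistanceVector,
    sigma: np.ndarray,
    p: np.ndarray,
    scaling_domain: str = "arm",
) -> ConservationTrack:
    """Convenience: Eq-style weighting + score + per-arm MinMax in one call."""
    raw = conservation_score(normalize_identity(identity, distances), sigma, p)
    if scaling_domain == "arm":
        scaled = minmax_scale(raw)
    elif scaling_domain == "genome":
        scaled = raw.copy()  # caller rescales over the concatenated genome
    else:
        raise ValueError(f"unknown scaling domain {scaling_domain!r}")
    return ConservationTrack(
        chrom=identity.chrom, cs_raw=raw, cs_scaled=scaled, scaling_domain=scaling_domain
    )


def scale_genomewide(tracks: "dict[str, ConservationTrack]") -> None:
    """Rescale cs_scaled in place over the concatenation of all chromosomes."""
    allraw = np.concatenate([t.cs_raw for t in tracks.values()])
    lo, hi = allraw.min(), allraw.max()
    for t in tracks.values():
        if hi == lo:
            t.cs_scaled = np.zeros_like(t.cs_raw)
        else:
            t.cs_scaled = (t.cs_raw - lo) / (hi - lo)
        t.scaling_domain = "genome"


def group_mean_identity(
    identity: IdentityMatrix,
    subset: "list[str]",
    window: int = GROUP_WINDOW,
) -> "tuple[np.ndarray, np.ndarray, np.ndarray]":
    """Windowed average identity (percent) over a species subset.

    Tiles the chromosome with length-`window` windows (the last one
    truncated) and averages identity over the subset's rows and the window's
    positions.  Returns (starts, ends, percent_values).
    """
    if not subset:
        raise ValueError("species subset must be non-empty")
    index = []
    for sp in subset:
        if sp not in identity.species:
            raise ValueError(f"unknown species {sp!r} in subset")
        index.append(identity.species.index(sp))
    rows = identity.values[index, :]
    n = rows.shape[1]
    starts = np.arange(0, n, window)
    ends = np.minimum(starts + window, n)
    values = np.array([rows[:, s:e].mean() for s, e in zip(starts, ends)]) * 100.0
    return starts, ends, values


def percentile_of(value: float, cs_values: np.ndarray) -> float:
    """Percentile of `value` among the positive conservation scores.

    Fraction of cs_values (restricted to cs > 0) that are <= value, x100.
    """
    cs_values = np.asarray(cs_values, dtype=float)
    positive = cs_values[cs_values > 0]
    if positive.size == 0:
        raise ValueError("no positive conservation scores to rank against")
    return float((positive <= value).mean() * 100.0)
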
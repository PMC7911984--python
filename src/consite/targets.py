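"""SpCas9 target-site enumeration, conservation scoring and ranking.

A target site is the canonical 23-bp unit: a 20-nt protospacer followed by
an NGG PAM, on either strand.  On the minus strand the PAM appears as CCN at
the 5' end of the plus-strand interval.  Sites are ranked by their mean
scaled conservation score over the 23 positions; sites overlapping an
accessibility mask are retained but flagged rather than dropped, since a
high score in a masked region should be treated cautiously, not hidden.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .io import MaskIntervals
from .tracks import ConservationTrack, percentile_of  # re-exported: ranking context

__all__ = [
    "TargetSite",
    "enumerate_cas9_sites",
    "score_sites",
    "rank_sites",
    "percentile_of",
    "sites_to_frame",
]

SITE_LEN = 23
PROTOSPACER_LEN = 20

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TargetSite:
    """One 23-bp Cas9 target site (protospacer + NGG PAM) on the reference."""

    chrom: str
    start: int  # 0-based half-open; end - start == 23
    end: int
    strand: str
    protospacer: str
    pam: str
    cs_mean: float | None = None
    cs_min: float | None = None
    cs_max: float | None = None
    accessible: bool | None = None

    def __post_init__(self) -> None:
        if self.end - self.start != SITE_LEN:
            raise ValueError(f"target site must span {SITE_LEN} bp")
        if self.pam[1:3] != "GG":
            raise ValueError(f"PAM {self.pam!r} is not NGG")


def enumerate_cas9_sites(
    sequence: str,
    chrom: str,
    region: "tuple[int, int] | None" = None,
) -> "list[TargetSite]":
    """Enumerate all SpCas9-accessible 23-bp sites on both strands.

    Plus strand: every i with sequence[i+21:i+23] == "GG" yields [i, i+23).
    Minus strand: every i with sequence[i:i+2] == "CC" yields [i, i+23) with
    protospacer and PAM read from the reverse complement.  Sites containing
    N and sites truncated by the region boundary are dropped.
    """
    n = len(sequence)
    if region is None:
        region = (0, n)
    start, end = region
    if start < 0 or end > n or start > end:
        raise ValueError(f"region {start}-{end} outside sequence of length {n}")
    sub = sequence[start:end].upper()
    arr = np.frombuffer(sub.encode(), dtype="S1")
    sites: list[TargetSite] = []
    if arr.size < SITE_LEN:
        return sites

    has_n = arr == b"N"
    n_cum = np.concatenate(([0], np.cumsum(has_n)))

    def clean(i: int) -> bool:  # no N anywhere in the 23-mer
        return n_cum[i + SITE_LEN] - n_cum[i] == 0

    gg = (arr[:-1] == b"G") & (arr[1:] == b"G")
    for i in np.flatnonzero(gg[PROTOSPACER_LEN + 1 :]):  # gg at offset i+21
        i = int(i)
        if i + SITE_LEN <= arr.size and clean(i):
            s = sub[i : i + SITE_LEN]
            sites.append(
                TargetSite(
                    chrom=chrom,
                    start=start + i,
                    end=start + i + SITE_LEN,
                    strand="+",
                    protospacer=s[:PROTOSPACER_LEN],
                    pam=s[PROTOSPACER_LEN:],
                )
            )
    cc = (arr[:-1] == b"C") & (arr[1:] == b"C")
    for i in np.flatnonzero(cc):
        i = int(i)
        if i + SITE_LEN <= arr.size and clean(i):
            s = revcomp(sub[i : i + SITE_LEN])
            sites.append(
                TargetSite(
                    chrom=chrom,
                    start=start + i,
                    end=start + i + SITE_LEN,
                    strand="-",
                    protospacer=s[:PROTOSPACER_LEN],
                    pam=s[PROTOSPACER_LEN:],
                )
            )
    sites.sort(key=lambda t: (t.start, t.strand))
    return sites


def score_sites(
    sites: "Iterable[TargetSite]",
    cs: ConservationTrack,
    mask: MaskIntervals | None = None,
) -> "list[TargetSite]":
    """Attach mean/min/max scaled conservation and an accessibility flag."""
    track = cs.cs_scaled
    out = []
    for site in sites:
        if site.chrom != cs.chrom or site.end > track.size:
            raise ValueError(
                f"site {site.chrom}:{site.start}-{site.end} beyond conservation track"
            )
        window = track[site.start : site.end]
        site.cs_mean = float(window.mean())
        site.cs_min = float(window.min())
        site.cs_max = float(window.max())
        site.accessible = (
            True if mask is None else not mask.overlaps(site.chrom, site.start, site.end)
        )
        out.append(site)
    return out


def rank_sites(sites: "Iterable[TargetSite]", top_k: int | None = None) -> "list[TargetSite]":
    """Order sites by cs_mean desc, ties by cs_min desc, then coordinates.

    The final (chrom, start, strand) key makes the ranking deterministic
    under any input permutation.
    """
    ranked = sorted(
        sites,
        key=lambda t: (-t.cs_mean, -t.cs_min, t.chrom, t.start, t.strand),
    )
    return ranked if top_k is None else ranked[:top_k]


def sites_to_frame(sites: "Iterable[TargetSite]"):
    """Ranked sites as a DataFrame with 1-based inclusive printed coordinates."""
    import pandas as pd

    rows = [
        {
            "Chromosome": t.chrom,
            "Start": t.start + 1,
            "End": t.end,
            "Strand": t.strand,
            "Cs": t.cs_mean,
            "Cs_max": t.cs_max,
            "Cs_min": t.cs_min,
            "protospacer": t.protospacer,
            "pam": t.pam,
            "accessible": t.accessible,
        }
        for t in sites
    ]
    return pd.DataFrame(rows, columns=[
        "Chromosome", "Start", "End", "Strand", "Cs", "Cs_max", "Cs_min",
        "protospacer", "pam", "accessible",
    ])
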
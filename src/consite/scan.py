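"""Sliding-window identity scan over pairwise alignments.

Conserved elements are reference-anchored intervals where windowed alignment
identity to the reference meets a configured threshold.  Two default scans
(30-bp and 50-bp windows, each with its own threshold ladder) are pooled by
projecting every element onto a per-base identity matrix with a pointwise
maximum, so the final matrix is insensitive to the per-scan merge rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import AlignmentBlock, Genome

DEFAULT_WINDOWS = (30, 50)
DEFAULT_THRESHOLDS = {
    30: (0.90, 0.97, 1.00),
    50: (0.70, 0.90, 0.96, 0.98, 1.00),
}
MIN_IDENTITY = 0.70


@dataclass
class ScanConfig:
    """Window lengths and identity-threshold ladders for the scan.

    Defaults: 30-bp windows at 90/97/100% identity and 50-bp windows at
    70/90/96/98/100%, with a global 70% identity floor.
    """

    windows: Sequence[int] = DEFAULT_WINDOWS
    thresholds_by_window: "dict[int, Sequence[float]]" = field(
        default_factory=lambda: {w: t for w, t in DEFAULT_THRESHOLDS.items()}
    )
    min_identity: float = MIN_IDENTITY

    def __post_init__(self) -> None:
        if not self.windows:
            raise ValueError("at least one window length required")
        for w in self.windows:
            if w <= 0:
                raise ValueError(f"window length must be positive, got {w}")
            thresholds = self.thresholds_by_window.get(w)
            if not thresholds:
                raise ValueError(f"no thresholds configured for window {w}")
            for t in thresholds:
                if not 0.0 < t <= 1.0:
                    raise ValueError(f"threshold {t} outside (0, 1]")
                if t < self.min_identity:
                    raise ValueError(
                        f"threshold {t} below min_identity {self.min_identity}"
                    )


@dataclass
class ConservedElement:
    """A merged run of qualifying windows from one (window, threshold) scan."""

    species: str
    chrom: str
    start: int  # 0-based half-open, reference coordinates
    end: int
    identity: float
    window: int = 0
    threshold: float = 0.0


def match_profile(block: AlignmentBlock) -> np.ndarray:
    """Per-reference-base match indicator for one alignment block.

    Returns a uint8 array of length ``block.ref_span`` where entry j is 1
    iff reference base j of the block is aligned to an identical query base.
    A reference base aligned to a gap or to/from N counts as mismatch; query
    insertions (gap in the reference row) occupy no reference coordinate and
    are skipped.
    """
    ref = np.frombuffer(block.ref_aligned.encode(), dtype="S1")
    qry = np.frombuffer(block.query_aligned.encode(), dtype="S1")
    keep = ref != b"-"
    ref = ref[keep]
    qry = qry[keep]
    match = (ref == qry) & (ref != b"N") & (qry != b"N") & (qry != b"-")
    return match.astype(np.uint8)


def window_identity(block: AlignmentBlock, window: int) -> np.ndarray:
    """Match counts for every reference-anchored window of the block.

    Entry k is the number of identical positions in the window covering
    reference coordinates ``[block.ref_start + k, block.ref_start + k + window)``.
    Empty if the block spans fewer reference bases than ``window``.
    """
    profile = match_profile(block)
    if window > profile.size:
        return np.zeros(0, dtype=np.int64)
    cumsum = np.concatenate(([0], np.cumsum(profile, dtype=np.int64)))
    return cumsum[window:] - cumsum[:-window]


def _merge_qualifying(
    counts: np.ndarray, window: int, threshold: float
) -> "list[tuple[int, int, float]]":
    """Merge overlapping qualifying windows into maximal runs.

    Returns (start_offset, end_offset, max_identity) triples in block-local
    reference coordinates.  A window qualifies when count/window >= threshold
    (up to floating-point slack, so 49/50 qualifies at 0.98 exactly).
    """
    need = int(np.ceil(threshold * window - 1e-9))
    qualifying = np.flatnonzero(counts >= need)
    if qualifying.size == 0:
        return []
    runs: list[tuple[int, int, float]] = []
    # windows k and k' overlap iff |k - k'| < window
    breaks = np.flatnonzero(np.diff(qualifying) >= window)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [qualifying.size - 1]))
    for a, b in zip(starts, ends):
        first, last = qualifying[a], qualifying[b]
        best = counts[first : last + 1].max() / window
        runs.append((int(first), int(last) + window, float(best)))
    return runs


def scan_conserved_elements(
    blocks: Iterable[AlignmentBlock], config: ScanConfig | None = None
) -> "list[ConservedElement]":
    """Run every configured (window, threshold) scan over one species' blocks.

    Windows never span two alignment blocks.  Overlapping qualifying windows
    of the same scan are merged; each merged element carries the maximum
    window identity found inside it.
    """
    config = config or ScanConfig()
    elements: list[ConservedElement] = []
    for block in blocks:
        profiles: dict[int, np.ndarray] = {}
        for window in config.windows:
            counts = window_identity(block, window)
            if counts.size == 0:
                continue
            profiles[window] = counts
        for window, counts in profiles.items():
            for threshold in config.thresholds_by_window[window]:
                for start, end, identity in _merge_qualifying(counts, window, threshold):
                    elements.append(
                        ConservedElement(
                            species=block.query_species,
                            chrom=block.ref_chrom,
                            start=block.ref_start + start,
                            end=block.ref_start + end,
                            identity=identity,
                            window=window,
                            threshold=threshold,
                        )
                    )
    return [e for e in elements if e.identity >= config.min_identity - 1e-12]


@dataclass
class IdentityMatrix:
    """Per-base alignment identities, one row per species, for one chromosome."""

    chrom: str
    species: "list[str]"
    values: np.ndarray  # shape (m, n), values in [0, 1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.species):
            raise ValueError("identity matrix shape does not match species list")


def project_identity(
    elements_by_species: "dict[str, list[ConservedElement]]",
    genome: Genome,
    chrom: str,
) -> IdentityMatrix:
    """Project conserved elements onto a per-base identity matrix.

    ``I[i, n]`` is the maximum identity over all elements of species i that
    cover position n, 0 where nothing aligns.  Element order is irrelevant.
    """
    n = genome.lengths[chrom]
    species = list(elements_by_species)
    values = np.zeros((len(species), n))
    for i, sp in enumerate(species):
        row = values[i]
        for el in elements_by_species[sp]:
            if el.chrom != chrom:
                continue
            if el.start < 0 or el.end > n:
                raise ValueError(
                    f"element {el.species} {el.chrom}:{el.start}-{el.end} "
                    f"outside chromosome (length {n})"
                )
            seg = row[el.start : el.end]
            np.maximum(seg, el.identity, out=seg)
    return IdentityMatrix(chrom=chrom, species=species, values=values)


def elements_to_bed_rows(elements: "Iterable[ConservedElement]"):
    """BED rows with identity scaled x1000 in the score column."""
    for el in elements:
        yield (el.chrom, el.start, el.end, el.species, int(round(el.identity * 1000)))
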
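"""Phylogenetic distances from each query species to the reference.

The primary route is patristic (path-length) distance on a supplied tree;
when no tree is available a Jukes-Cantor (JC69) estimate from the pairwise
alignments serves as a documented fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .io import AlignmentBlock


@dataclass
class DistanceVector:
    """Patristic distance (substitutions/site) from each species to the reference."""

    species: "list[str]"
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.species),):
            raise ValueError("distance vector length does not match species list")
        if not np.all(np.isfinite(self.d)) or np.any(self.d < 0):
            raise ValueError("distances must be finite and nonnegative")


def tree_distances(tree, ref_leaf: str, species: "list[str]") -> DistanceVector:
    """Patristic distances ref_leaf -> each species on a dendropy tree.

    d[i] is the sum of branch lengths on the unique path between the
    reference leaf and leaf i; d[ref_leaf] = 0.
    """
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    if ref_leaf not in taxa:
        raise ValueError(f"reference leaf {ref_leaf!r} not in tree")
    d = np.zeros(len(species))
    for i, sp in enumerate(species):
        if sp not in taxa:
            raise ValueError(f"species {sp!r} not a leaf of the tree")
        if sp == ref_leaf:
            d[i] = 0.0
        else:
            d[i] = pdm.patristic_distance(taxa[ref_leaf], taxa[sp])
    return DistanceVector(species=list(species), d=d)


def jc69_distance(blocks: "Iterable[AlignmentBlock]") -> float:
    """Jukes-Cantor distance pooled over one species' alignment blocks.

    d = -(3/4) ln(1 - 4 p_hat / 3) with p_hat the mismatch fraction over
    aligned ungapped A/C/G/T sites.  Raises on saturation (p_hat >= 0.75)
    or when no comparable site exists.
    """
    mismatches = 0
    sites = 0
    valid = np.frombuffer(b"ACGT", dtype="S1")
    for block in blocks:
        ref = np.frombuffer(block.ref_aligned.encode(), dtype="S1")
        qry = np.frombuffer(block.query_aligned.encode(), dtype="S1")
        ok = np.isin(ref, valid) & np.isin(qry, valid)
        sites += int(ok.sum())
        mismatches += int((ref[ok] != qry[ok]).sum())
    if sites == 0:
        raise ValueError("no aligned ungapped A/C/G/T sites")
    p_hat = mismatches / sites
    if p_hat >= 0.75:
        raise ValueError(f"mismatch fraction {p_hat:.3f} >= 0.75: JC69 saturated")
    return float(-0.75 * np.log1p(-4.0 * p_hat / 3.0))


def jc69_distances(
    blocks_by_species: "dict[str, list[AlignmentBlock]]",
) -> DistanceVector:
    """JC69 fallback distance vector across species (tree wins when present)."""
    species = list(blocks_by_species)
    d = np.array([jc69_distance(blocks_by_species[sp]) for sp in species])
    return DistanceVector(species=species, d=d)


def write_distances(dv: DistanceVector, path) -> None:
    with open(path, "w") as fh:
        for sp, dist in zip(dv.species, dv.d):
            fh.write(f"{sp}\t{dist:.10g}\n")
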
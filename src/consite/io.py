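"""Readers and writers for the external formats the pipeline touches.

Every coordinate inside the package is 0-based half-open.  Conversion to and
from the on-disk conventions (AXT and VCF are 1-based inclusive, wiggle
fixedStep/variableStep is 1-based, bedGraph and BED are already 0-based
half-open) happens only in this module.  The target-site table is written
1-based inclusive, the convention used for published Cas9 site coordinates
(a 23-bp site prints as e.g. 2R:48714594-48714616).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO


class FormatError(ValueError):
    """A file does not conform to its declared format."""


# ---------------------------------------------------------------------------
# FASTA

class Genome:
    """Uppercased in-memory genome with an ordered chrom -> length index."""

    def __init__(self, records: "dict[str, str]"):
        if not records:
            raise FormatError("no sequence records")
        self._seqs = records
        self.lengths: dict[str, int] = {name: len(s) for name, s in records.items()}

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def sequence(self, chrom: str, start: int = 0, end: int | None = None) -> str:
        return self._seqs[chrom][start:end]


def read_fasta(path) -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    Sequences are uppercased.  Empty records and files that do not start
    with a header line raise :class:`FormatError`.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(">"):
            raise FormatError(f"{path}: line 1 is not a FASTA header")
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"{path}: duplicate record {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} is empty")
        records[rec.id] = seq
    return Genome(records)


def write_fasta(records: "dict[str, str]", path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# AXT pairwise alignments

@dataclass
class AlignmentBlock:
    """One gapped pairwise alignment block anchored on the reference."""

    query_species: str
    ref_chrom: str
    ref_start: int  # 0-based half-open
    ref_end: int
    ref_aligned: str
    query_aligned: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.ref_aligned) != len(self.query_aligned):
            raise FormatError(
                f"aligned sequences differ in length "
                f"({len(self.ref_aligned)} vs {len(self.query_aligned)})"
            )
        ungapped = len(self.ref_aligned) - self.ref_aligned.count("-")
        if ungapped != self.ref_end - self.ref_start:
            raise FormatError(
                f"{self.ref_chrom}:{self.ref_start}-{self.ref_end}: header span "
                f"{self.ref_end - self.ref_start} != {ungapped} ungapped ref bases"
            )

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start


def read_axt(path, species: str) -> Iterator[AlignmentBlock]:
    """Stream alignment blocks from a UCSC AXT file.

    On-disk coordinates are 1-based inclusive; emitted blocks are 0-based
    half-open.  Query-strand '-' blocks are accepted as-is.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    block_no = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if not line or line.startswith("#"):
            i += 1
            continue
        fields = line.split()
        if len(fields) < 9:
            raise FormatError(f"{path}: block {block_no}: bad AXT header {line!r}")
        if i + 2 >= n:
            raise FormatError(f"{path}: block {block_no}: truncated block")
        _, ref_chrom, ref_start, ref_end, _qchrom, _qs, _qe, strand = fields[:8]
        ref_seq = lines[i + 1].strip().upper()
        query_seq = lines[i + 2].strip().upper()
        try:
            block = AlignmentBlock(
                query_species=species,
                ref_chrom=ref_chrom,
                ref_start=int(ref_start) - 1,
                ref_end=int(ref_end),
                ref_aligned=ref_seq,
                query_aligned=query_seq,
                strand=strand,
            )
        except FormatError as exc:
            raise FormatError(f"{path}: block {block_no}: {exc}") from exc
        yield block
        block_no += 1
        i += 3


def write_axt(blocks: Iterable[AlignmentBlock], path) -> None:
    """Write blocks in AXT format (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        for k, b in enumerate(blocks):
            qlen = len(b.query_aligned) - b.query_aligned.count("-")
            fh.write(
                f"{k} {b.ref_chrom} {b.ref_start + 1} {b.ref_end} "
                f"{b.query_species} 1 {qlen} {b.strand} 0\n"
            )
            fh.write(b.ref_aligned + "\n")
            fh.write(b.query_aligned + "\n\n")


# ---------------------------------------------------------------------------
# VCF variant positions

def read_variant_positions(
    path,
    genome: Genome | None = None,
    chrom_filter: "set[str] | None" = None,
    snps_only: bool = True,
) -> "dict[str, np.ndarray]":
    """Sorted unique 0-based variant positions per chromosome.

    Only site positions are used; genotypes are ignored.  Records on
    chromosomes absent from *genome* (when given) are skipped with a single
    summary warning.  With ``snps_only`` (default) indel records are ignored.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad files
        raise FormatError(f"cannot read VCF {path}: {exc}") from exc
    positions: dict[str, set[int]] = {}
    skipped = 0
    for rec in vcf:
        chrom = rec.CHROM
        if chrom_filter is not None and chrom not in chrom_filter:
            continue
        if genome is not None and chrom not in genome:
            skipped += 1
            continue
        if snps_only and not rec.is_snp:
            continue
        positions.setdefault(chrom, set()).add(rec.start)  # rec.start is 0-based
    if skipped:
        warnings.warn(f"{skipped} VCF records on chromosomes not in the genome were skipped")
    return {c: np.array(sorted(p), dtype=np.int64) for c, p in positions.items()}


# ---------------------------------------------------------------------------
# Score tracks (wiggle fixedStep/variableStep, bedGraph)

def _parse_kv(fields: list[str]) -> dict[str, str]:
    return dict(f.split("=", 1) for f in fields if "=" in f)


def read_score_track(path, genome: Genome, fill: float = 0.0) -> "dict[str, np.ndarray]":
    """Per-base score vector per chromosome from wiggle or bedGraph text.

    Positions the file does not cover get ``fill`` (0 = neutral by default).
    Overlapping bedGraph records follow last-wins with a warning.
    """
    path = Path(path)
    tracks = {c: np.full(n, float(fill)) for c, n in genome.lengths.items()}
    covered = {c: np.zeros(n, dtype=bool) for c, n in genome.lengths.items()}
    overlap = 0

    mode = "bedgraph"
    chrom = ""
    pos = 0  # 0-based next position for fixedStep
    step = span = 1

    def _check(c: str, start: int, end: int, lineno: int) -> None:
        if c not in tracks:
            raise FormatError(f"{path}:{lineno}: unknown chromosome {c!r}")
        if start < 0 or end > len(tracks[c]):
            raise FormatError(
                f"{path}:{lineno}: interval {start}-{end} outside {c} "
                f"(length {len(tracks[c])})"
            )

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = _parse_kv(line.split())
                mode = "fixed"
                chrom = kv["chrom"]
                pos = int(kv["start"]) - 1  # wiggle is 1-based
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
                continue
            if line.startswith("variableStep"):
                kv = _parse_kv(line.split())
                mode = "variable"
                chrom = kv["chrom"]
                span = int(kv.get("span", 1))
                continue
            fields = line.split()
            if mode == "fixed":
                start, end = pos, pos + span
                _check(chrom, start, end, lineno)
                overlap += int(covered[chrom][start:end].any())
                tracks[chrom][start:end] = float(fields[0])
                covered[chrom][start:end] = True
                pos += step
            elif mode == "variable":
                start = int(fields[0]) - 1
                end = start + span
                _check(chrom, start, end, lineno)
                overlap += int(covered[chrom][start:end].any())
                tracks[chrom][start:end] = float(fields[1])
                covered[chrom][start:end] = True
            else:
                if len(fields) < 4:
                    raise FormatError(f"{path}:{lineno}: bad bedGraph line {line!r}")
                c, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                _check(c, start, end, lineno)
                overlap += int(covered[c][start:end].any())
                tracks[c][start:end] = value
                covered[c][start:end] = True
    if overlap:
        warnings.warn(f"{overlap} overlapping score-track records; last value wins")
    return tracks


def write_bedgraph(tracks: "dict[str, np.ndarray]", path) -> None:
    """Run-length encode per-base tracks into bedGraph (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, values in tracks.items():
            values = np.asarray(values, dtype=float)
            if values.size == 0:
                continue
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [values.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{values[s]:.17g}\n")


# ---------------------------------------------------------------------------
# BED masks and intervals

@dataclass
class MaskIntervals:
    """Per-chromosome sorted, merged inaccessible intervals (0-based half-open)."""

    intervals: "dict[str, list[tuple[int, int]]]" = field(default_factory=dict)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        import bisect

        ivs = self.intervals.get(chrom, [])
        if not ivs:
            return False
        i = bisect.bisect_right([s for s, _ in ivs], start)
        # the interval starting at or before `start`, and the one after
        for j in (i - 1, i):
            if 0 <= j < len(ivs):
                s, e = ivs[j]
                if s < end and start < e:
                    return True
        return False

    def total_bp(self, chrom: str) -> int:
        return sum(e - s for s, e in self.intervals.get(chrom, []))


def merge_intervals(ivs: "list[tuple[int, int]]") -> "list[tuple[int, int]]":
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def read_mask(path, genome: Genome | None = None) -> MaskIntervals:
    """Load BED3 intervals, merged per chromosome at load time."""
    raw: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: bad BED line {line!r}")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if genome is not None:
                if chrom not in genome:
                    raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if start < 0 or end > genome.lengths[chrom]:
                    raise FormatError(f"{path}:{lineno}: interval outside chromosome bounds")
            raw.setdefault(chrom, []).append((start, end))
    return MaskIntervals({c: merge_intervals(ivs) for c, ivs in raw.items()})


def write_bed(intervals: "Iterable[tuple[str, int, int, str, float]]", path) -> None:
    """Write (chrom, start, end[, name, score]) tuples as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# Newick trees

def read_newick(path):
    """Read a single Newick tree; all leaves named, all branch lengths present."""
    import dendropy

    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:
        raise FormatError(f"cannot parse Newick {path}: {exc}") from exc
    names = []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise FormatError(f"{path}: unnamed leaf")
        names.append(leaf.taxon.label)
    if len(names) != len(set(names)):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise FormatError(f"{path}: duplicate leaf names {dup}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue  # root edge length optional
        if edge.length is None:
            raise FormatError(f"{path}: missing branch length")
    return tree


# ---------------------------------------------------------------------------
# Target-site table

TARGET_COLUMNS = [
    "Chromosome", "Start", "End", "Strand",
    "Cs", "Cs_max", "Cs_min", "protospacer", "pam", "accessible",
]


def write_target_table(sites, path) -> None:
    """TSV of ranked target sites, coordinates 1-based inclusive.

    An internal 23-bp site [s, e) prints as Start=s+1, End=e so the printed
    span matches the published 23-bp convention.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(TARGET_COLUMNS) + "\n")
        for site in sites:
            fh.write(
                f"{site.chrom}\t{site.start + 1}\t{site.end}\t{site.strand}\t"
                f"{site.cs_mean:.4f}\t{site.cs_max:.4f}\t{site.cs_min:.4f}\t"
                f"{site.protospacer}\t{site.pam}\t{site.accessible}\n"
            )


# ---------------------------------------------------------------------------
# Optional consolidated HDF5 store

def save_store(path, chrom: str, *, species, identity=None, sigma=None,
               phylop=None, cs_raw=None, cs_scaled=None) -> None:
    """Append one chromosome's arrays to an HDF5 store."""
    import h5py

    with h5py.File(path, "a") as h5:
        grp = h5.require_group(chrom)
        grp.attrs["species"] = [s.encode() for s in species]
        for name, arr in (("identity", identity), ("sigma", sigma),
                          ("phylop", phylop), ("cs_raw", cs_raw),
                          ("cs_scaled", cs_scaled)):
            if arr is None:
                continue
            if name in grp:
                del grp[name]
            grp.create_dataset(name, data=np.asarray(arr), compression="gzip")


def load_store(path, chrom: str) -> "dict[str, np.ndarray]":
    import h5py

    with h5py.File(path, "r") as h5:
        grp = h5[chrom]
        return {name: grp[name][...] for name in grp}
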
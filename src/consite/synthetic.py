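"""Self-contained synthetic fixtures with known ground truth.

Emulates the real study inputs at desk scale: a reference chromosome,
collinear query-species genomes diverged along known branch lengths under
JC69 (each non-conserved site substituted independently with probability
p(t) = 3/4 (1 - exp(-4t/3))), embedded zero-divergence ultraconserved
blocks, population SNPs placed Bernoulli outside the blocks, a selection
track positive inside blocks, and an accessibility mask.  Everything is
byte-deterministic under a fixed seed, so every pipeline stage is testable
without downloads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import AlignmentBlock, write_axt, write_fasta

BASES = np.frombuffer(b"ACGT", dtype="S1")

# Default study conditions for the fixture: one 100-kb arm, six query
# species spanning near (0.05) to deep (0.5) divergence, three embedded
# ultraconserved blocks, 2% per-base SNP rate outside blocks, 5% masked.
DEFAULT_CHROM_LENGTHS = {"chr1": 100_000}
DEFAULT_BRANCH_LENGTHS = {
    "spA": 0.05, "spB": 0.10, "spC": 0.15,
    "spD": 0.30, "spE": 0.40, "spF": 0.50,
}
DEFAULT_BLOCKS = [
    ("chr1", 20_000, 21_000),
    ("chr1", 50_000, 50_600),
    ("chr1", 80_000, 80_800),
]


def jc69_p(t: float) -> float:
    """Probability a site differs after branch length t under JC69."""
    return 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))


@dataclass
class SimConfig:
    seed: int = 0
    chrom_lengths: "dict[str, int]" = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS)
    )
    branch_lengths: "dict[str, float]" = field(
        default_factory=lambda: dict(DEFAULT_BRANCH_LENGTHS)
    )
    conserved_blocks: "list[tuple[str, int, int]]" = field(
        default_factory=lambda: list(DEFAULT_BLOCKS)
    )
    snp_rate: float = 0.02
    mask_fraction: float = 0.05
    block_selection_score: float = 1.5
    background_selection_score: float = 0.0
    ref_name: str = "ref"

    def __post_init__(self) -> None:
        if not 0.0 <= self.snp_rate <= 1.0:
            raise ValueError("snp_rate must be a probability")
        if not 0.0 <= self.mask_fraction < 1.0:
            raise ValueError("mask_fraction must lie in [0, 1)")
        blocks = sorted(self.conserved_blocks)
        for (c1, s1, e1), (c2, s2, e2) in zip(blocks, blocks[1:]):
            if c1 == c2 and s2 < e1:
                raise ValueError("conserved blocks must be disjoint")
        for chrom, s, e in blocks:
            if chrom not in self.chrom_lengths or s < 0 or e > self.chrom_lengths[chrom]:
                raise ValueError(f"block {chrom}:{s}-{e} out of range")

    def block_mask(self, chrom: str) -> np.ndarray:
        """Boolean array, True inside ultraconserved blocks."""
        mask = np.zeros(self.chrom_lengths[chrom], dtype=bool)
        for c, s, e in self.conserved_blocks:
            if c == chrom:
                mask[s:e] = True
        return mask


def simulate_reference(config: SimConfig) -> "dict[str, str]":
    """I.i.d. uniform A/C/G/T reference sequences, deterministic under seed."""
    rng = np.random.default_rng([config.seed, 0])
    out = {}
    for chrom, length in config.chrom_lengths.items():
        out[chrom] = BASES[rng.integers(0, 4, size=length)].tobytes().decode()
    return out


def star_tree_newick(config: SimConfig) -> str:
    """Star tree: reference at branch length 0, each species at its distance.

    The patristic distance from the reference leaf to species i is then
    exactly the simulated branch length t_i.
    """
    tips = [f"{config.ref_name}:0.0"] + [
        f"{sp}:{t:g}" for sp, t in config.branch_lengths.items()
    ]
    return "(" + ",".join(tips) + ");"


def simulate_species(
    reference: "dict[str, str]", config: SimConfig
) -> "dict[str, list[AlignmentBlock]]":
    """Mutate each species away from the reference under JC69.

    Every site outside a conserved block is substituted independently with
    probability p(t); substituted sites get one of the three other bases
    uniformly, so the realised mismatch fraction estimates p(t) directly.
    Conserved blocks are copied verbatim.  Output is one collinear
    alignment block per chromosome per species.
    """
    out: dict[str, list[AlignmentBlock]] = {}
    for k, (sp, t) in enumerate(sorted(config.branch_lengths.items())):
        rng = np.random.default_rng([config.seed, 1, k])
        p = jc69_p(t)
        blocks = []
        for chrom, seq in reference.items():
            arr = np.frombuffer(seq.encode(), dtype="S1").copy()
            hit = rng.random(arr.size) < p
            hit &= ~config.block_mask(chrom)
            idx = np.flatnonzero(hit)
            # replace with a uniformly chosen different base
            offsets = rng.integers(1, 4, size=idx.size)
            base_idx = np.searchsorted(BASES, arr[idx])
            arr[idx] = BASES[(base_idx + offsets) % 4]
            blocks.append(
                AlignmentBlock(
                    query_species=sp,
                    ref_chrom=chrom,
                    ref_start=0,
                    ref_end=arr.size,
                    ref_aligned=seq,
                    query_aligned=arr.tobytes().decode(),
                    strand="+",
                )
            )
        out[sp] = blocks
    return out


def simulate_population_variants(
    reference: "dict[str, str]", config: SimConfig
) -> "dict[str, np.ndarray]":
    """Bernoulli(snp_rate) SNP positions outside conserved blocks (0-based)."""
    rng = np.random.default_rng([config.seed, 2])
    out = {}
    for chrom, seq in reference.items():
        hit = rng.random(len(seq)) < config.snp_rate
        hit &= ~config.block_mask(chrom)
        out[chrom] = np.flatnonzero(hit).astype(np.int64)
    return out


def simulate_selection_track(config: SimConfig) -> "dict[str, np.ndarray]":
    """Selection scores: positive inside conserved blocks, background outside."""
    out = {}
    for chrom, length in config.chrom_lengths.items():
        track = np.full(length, float(config.background_selection_score))
        track[config.block_mask(chrom)] = float(config.block_selection_score)
        out[chrom] = track
    return out


def simulate_mask(config: SimConfig) -> "dict[str, list[tuple[int, int]]]":
    """Random inaccessible intervals covering ~mask_fraction, avoiding blocks."""
    rng = np.random.default_rng([config.seed, 3])
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, length in config.chrom_lengths.items():
        target = int(config.mask_fraction * length)
        blocks = config.block_mask(chrom)
        intervals: list[tuple[int, int]] = []
        covered = np.zeros(length, dtype=bool)
        total = 0
        attempts = 0
        while total < target and attempts < 10_000:
            attempts += 1
            width = int(rng.integers(100, 400))
            start = int(rng.integers(0, max(1, length - width)))
            end = start + width
            if blocks[start:end].any() or covered[start:end].any():
                continue
            intervals.append((start, end))
            covered[start:end] = True
            total += width
        out[chrom] = sorted(intervals)
    return out


def write_vcf(
    positions: "dict[str, np.ndarray]",
    reference: "dict[str, str]",
    config: SimConfig,
    path,
) -> None:
    """Minimal sites-only VCF (1-based on disk) with a random ALT per site."""
    rng = np.random.default_rng([config.seed, 4])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in config.chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos in positions.items():
            seq = reference[chrom]
            for p in pos:
                ref_base = seq[p]
                i = int(np.searchsorted(BASES, ref_base.encode()))
                alt = BASES[(i + int(rng.integers(1, 4))) % 4].decode()
                fh.write(f"{chrom}\t{p + 1}\t.\t{ref_base}\t{alt}\t.\tPASS\t.\n")


def simulate_bundle(config: SimConfig, outdir) -> "dict[str, Path]":
    """Emit the full fixture directory and a ground-truth manifest.

    Writes ref.fa, one AXT per species, tree.nwk, variants.vcf,
    phylop.bedgraph, mask.bed and truth.json (block coordinates, branch
    lengths, seed).
    """
    from .io import write_bed, write_bedgraph

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = simulate_reference(config)
    species_blocks = simulate_species(reference, config)
    variants = simulate_population_variants(reference, config)
    selection = simulate_selection_track(config)
    mask = simulate_mask(config)

    paths: dict[str, Path] = {}
    paths["reference"] = outdir / "ref.fa"
    write_fasta(reference, paths["reference"])
    for sp, blocks in species_blocks.items():
        paths[f"axt:{sp}"] = outdir / f"{sp}.axt"
        write_axt(blocks, paths[f"axt:{sp}"])
    paths["tree"] = outdir / "tree.nwk"
    paths["tree"].write_text(star_tree_newick(config) + "\n")
    paths["variants"] = outdir / "variants.vcf"
    write_vcf(variants, reference, config, paths["variants"])
    paths["selection"] = outdir / "phylop.bedgraph"
    write_bedgraph(selection, paths["selection"])
    paths["mask"] = outdir / "mask.bed"
    write_bed(
        ((c, s, e) for c, ivs in mask.items() for s, e in ivs), paths["mask"]
    )
    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(
        json.dumps(
            {
                "seed": config.seed,
                "ref_name": config.ref_name,
                "chrom_lengths": config.chrom_lengths,
                "branch_lengths": config.branch_lengths,
                "conserved_blocks": [list(b) for b in config.conserved_blocks],
                "snp_rate": config.snp_rate,
                "mask_fraction": config.mask_fraction,
            },
            indent=2,
        )
        + "\n"
    )
    return paths
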
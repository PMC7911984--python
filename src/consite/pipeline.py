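"""End-to-end orchestration: alignments in, ranked target sites out.

Stages: read the reference and per-species alignments, run the identity
scan, project to per-base identity matrices, compute phylogenetic distances
(tree if given, JC69 from the alignments otherwise), build the SNP-density
and selection tracks, combine into the scaled conservation score, and
enumerate/score/rank Cas9 sites.  Each stage writes its products so stages
are independently inspectable, and a manifest records the configuration
hash and per-stage counts for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as cio
from . import phylo, scan, targets, tracks

log = logging.getLogger("consite")


@dataclass
class PipelineConfig:
    ref_fasta: str
    axt_paths: "dict[str, str]"  # species -> AXT path
    out_dir: str
    tree: str | None = None
    ref_leaf: str = "ref"
    vcf: str | None = None
    phylop: str | None = None
    mask: str | None = None
    scan_config: scan.ScanConfig = field(default_factory=scan.ScanConfig)
    snp_window: int = tracks.SNP_WINDOW
    scaling_domain: str = "arm"
    group_window: int = tracks.GROUP_WINDOW
    groups: "dict[str, list[str]]" = field(default_factory=dict)
    region: "tuple[str, int, int] | None" = None  # target enumeration region
    top_k: int | None = None
    snps_only: bool = True

    def to_jsonable(self) -> dict:
        d = {
            "ref_fasta": str(self.ref_fasta),
            "axt_paths": {k: str(v) for k, v in self.axt_paths.items()},
            "out_dir": str(self.out_dir),
            "tree": str(self.tree) if self.tree else None,
            "ref_leaf": self.ref_leaf,
            "vcf": str(self.vcf) if self.vcf else None,
            "phylop": str(self.phylop) if self.phylop else None,
            "mask": str(self.mask) if self.mask else None,
            "scan": {
                "windows": list(self.scan_config.windows),
                "thresholds_by_window": {
                    str(w): list(t)
                    for w, t in self.scan_config.thresholds_by_window.items()
                },
                "min_identity": self.scan_config.min_identity,
            },
            "snp_window": self.snp_window,
            "scaling_domain": self.scaling_domain,
            "group_window": self.group_window,
            "groups": self.groups,
            "region": list(self.region) if self.region else None,
            "top_k": self.top_k,
            "snps_only": self.snps_only,
        }
        return d


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_jsonable(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


@dataclass
class PipelineResult:
    genome: cio.Genome
    species: "list[str]"
    identity: "dict[str, scan.IdentityMatrix]"
    distances: phylo.DistanceVector
    sigma: "dict[str, np.ndarray]"
    selection: "dict[str, np.ndarray]"
    conservation: "dict[str, tracks.ConservationTrack]"
    sites: "list[targets.TargetSite]"
    manifest: dict


def _stage(name: str, t0: float, **counts) -> None:
    log.info("stage %-10s %6.2fs %s", name, time.perf_counter() - t0,
             " ".join(f"{k}={v}" for k, v in counts.items()))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_jsonable(), "config_hash": config_hash(config),
                      "stages": {}}

    t0 = time.perf_counter()
    genome = cio.read_fasta(config.ref_fasta)
    species = sorted(config.axt_paths)
    blocks_by_species = {
        sp: list(cio.read_axt(config.axt_paths[sp], sp)) for sp in species
    }
    manifest["stages"]["read"] = {
        "species": len(species),
        "chrom_lengths": genome.lengths,
        "blocks": {sp: len(b) for sp, b in blocks_by_species.items()},
    }
    _stage("read", t0, species=len(species))

    # identity scan and per-base projection
    t0 = time.perf_counter()
    elements_by_species = {
        sp: scan.scan_conserved_elements(blocks_by_species[sp], config.scan_config)
        for sp in species
    }
    for sp in species:
        cio.write_bed(
            scan.elements_to_bed_rows(elements_by_species[sp]),
            out / f"elements_{sp}.bed",
        )
    identity = {
        chrom: scan.project_identity(elements_by_species, genome, chrom)
        for chrom in genome.chroms
    }
    manifest["stages"]["scan"] = {
        "elements": {sp: len(e) for sp, e in elements_by_species.items()}
    }
    _stage("scan", t0, elements=sum(len(e) for e in elements_by_species.values()))

    # phylogenetic distances: tree wins, JC69 fallback
    t0 = time.perf_counter()
    if config.tree:
        tree = cio.read_newick(config.tree)
        distances = phylo.tree_distances(tree, config.ref_leaf, species)
        source = "tree"
    else:
        distances = phylo.jc69_distances(blocks_by_species)
        source = "jc69"
    phylo.write_distances(distances, out / "distances.tsv")
    manifest["stages"]["phylo"] = {
        "source": source, "distances": dict(zip(species, distances.d.tolist()))
    }
    _stage("phylo", t0, source=source)

    # per-base tracks
    t0 = time.perf_counter()
    variant_positions = (
        cio.read_variant_positions(config.vcf, genome=genome, snps_only=config.snps_only)
        if config.vcf
        else {}
    )
    sigma = {
        chrom: tracks.snp_density(
            variant_positions.get(chrom, np.array([], dtype=np.int64)),
            genome.lengths[chrom],
            config.snp_window,
        )
        for chrom in genome.chroms
    }
    selection = (
        cio.read_score_track(config.phylop, genome)
        if config.phylop
        else {c: np.zeros(n) for c, n in genome.lengths.items()}
    )
    cio.write_bedgraph(sigma, out / "sigma.bedgraph")
    manifest["stages"]["tracks"] = {
        "variants": {c: int(p.size) for c, p in variant_positions.items()}
    }
    _stage("tracks", t0, variants=sum(p.size for p in variant_positions.values()))

    # conservation score
    t0 = time.perf_counter()
    conservation = {
        chrom: tracks.build_conservation(
            identity[chrom], distances, sigma[chrom], selection[chrom],
            scaling_domain=config.scaling_domain,
        )
        for chrom in genome.chroms
    }
    if config.scaling_domain == "genome":
        tracks.scale_genomewide(conservation)
    cio.write_bedgraph({c: t.cs_raw for c, t in conservation.items()},
                       out / "cs_raw.bedgraph")
    cio.write_bedgraph({c: t.cs_scaled for c, t in conservation.items()},
                       out / "cs_scaled.bedgraph")
    for chrom in genome.chroms:
        cio.save_store(
            out / "store.h5", chrom, species=species,
            identity=identity[chrom].values.astype(np.float32),
            sigma=sigma[chrom], phylop=selection[chrom],
            cs_raw=conservation[chrom].cs_raw,
            cs_scaled=conservation[chrom].cs_scaled,
        )
    _stage("score", t0, chroms=len(conservation))

    # group-average identity tracks
    for name, subset in config.groups.items():
        rows = []
        for chrom in genome.chroms:
            starts, ends, values = tracks.group_mean_identity(
                identity[chrom], subset, config.group_window
            )
            rows.extend((chrom, int(s), int(e), float(v))
                        for s, e, v in zip(starts, ends, values))
        cio.write_bed(rows, out / f"group_identity_{name}.bed")

    # Cas9 sites
    t0 = time.perf_counter()
    mask = cio.read_mask(config.mask, genome) if config.mask else None
    all_sites: list[targets.TargetSite] = []
    if config.region:
        chrom, start, end = config.region
        regions = [(chrom, (start, end))]
    else:
        regions = [(chrom, None) for chrom in genome.chroms]
    for chrom, region in regions:
        sites = targets.enumerate_cas9_sites(genome[chrom], chrom, region)
        all_sites.extend(targets.score_sites(sites, conservation[chrom], mask))
    ranked = targets.rank_sites(all_sites, config.top_k)
    cio.write_target_table(ranked, out / "targets.tsv")
    manifest["stages"]["targets"] = {"sites": len(all_sites), "reported": len(ranked)}
    _stage("targets", t0, sites=len(all_sites))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return PipelineResult(
        genome=genome, species=species, identity=identity, distances=distances,
        sigma=sigma, selection=selection, conservation=conservation,
        sites=ranked, manifest=manifest,
    )
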
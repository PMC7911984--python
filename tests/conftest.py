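import numpy as np
import pytest

from consite.io import AlignmentBlock, Genome
from consite.synthetic import SimConfig, simulate_bundle


@pytest.fixture
def small_genome() -> Genome:
    rng = np.random.default_rng(7)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seq = bases[rng.integers(0, 4, size=500)].tobytes().decode()
    return Genome({"chr1": seq, "chr2": "ACGT" * 25})


@pytest.fixture
def perfect_block() -> AlignmentBlock:
    seq = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"  # 40 bp, identical pair
    return AlignmentBlock(
        query_species="spX", ref_chrom="chr1", ref_start=10, ref_end=50,
        ref_aligned=seq, query_aligned=seq,
    )


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """Small but complete synthetic bundle shared across tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    config = SimConfig(
        seed=11,
        chrom_lengths={"chr1": 20_000},
        conserved_blocks=[("chr1", 4_000, 4_500), ("chr1", 12_000, 12_400)],
        branch_lengths={"spA": 0.05, "spB": 0.2, "spC": 0.45},
    )
    paths = simulate_bundle(config, outdir)
    return config, paths


def make_pipeline_config(config, paths, out_dir, **overrides):
    from consite.pipeline import PipelineConfig

    kwargs = dict(
        ref_fasta=str(paths["reference"]),
        axt_paths={sp: str(paths[f"axt:{sp}"]) for sp in config.branch_lengths},
        out_dir=str(out_dir),
        tree=str(paths["tree"]),
        ref_leaf=config.ref_name,
        vcf=str(paths["variants"]),
        phylop=str(paths["selection"]),
        mask=str(paths["mask"]),
    )
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)
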
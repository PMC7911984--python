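# consite

Per-base genome conservation scoring and SpCas9 target-site ranking for
gene-drive design.

Gene drives targeting vector species such as *Anopheles* mosquitoes fail
when the Cas9 cut site tolerates mutations: resistant alleles arise and the
drive stops spreading. Functionally constrained sites tolerate fewer
mutations, and sequence conservation is a usable proxy for that constraint.
`consite` computes a per-base conservation score from whole-genome
alignments, a phylogeny, population variation and per-site selection
statistics, then enumerates and ranks every SpCas9-accessible 23-bp target
site (20-nt protospacer + NGG PAM, both strands) by that score.

## The score

For a chromosome arm of length *n* compared against *m* query species:

1. **Windowed identity scan.** Each species' pairwise alignment to the
   reference is scanned with sliding windows (defaults: 30 bp at
   90/97/100% identity and 50 bp at 70/90/96/98/100%, floor 70%). A 50-bp
   window at 98% identity contains exactly 49 matching bases; gaps and N
   count as mismatch. Qualifying windows are merged into conserved
   elements and projected onto a per-base identity matrix
   `I[i, n] ∈ [0, 1]` by pointwise maximum.
2. **Phylogenetic weighting.** `Ĩ[i, n] = I[i, n] · d_i`, where `d_i` is
   the patristic distance from species *i* to the reference on the supplied
   tree (or a Jukes–Cantor estimate from the alignments when no tree is
   given). Equal identity counts for more in a more distant species.
3. **Conservation score.** With σ<sub>n</sub> the SNP density of the
   population variants in a 20-bp window and p<sub>n</sub> a per-site
   selection score (phyloP CONACC convention: > 0 conserved, < 0
   accelerated):

   ```
   Cs_n = mean_i(Ĩ[i, n]) · (1 − σ_n)/(1 + σ_n) · 2^{p_n}
   ```

   Dense intraspecies variation suppresses the score; positive selection
   statistics boost it. Raw scores are MinMax-scaled to [0, 1] per
   chromosome arm (genome-wide scaling available via `--scale genome`).
4. **Target ranking.** Every 23-bp Cas9 site gets the mean/min/max scaled
   score over its span plus an accessibility flag (no overlap with the
   supplied mask), and sites are ranked by mean score with deterministic
   tie-breaks.

A synthetic-fixture module generates complete, seeded input bundles —
reference FASTA, collinear per-species AXT alignments diverged under JC69
along known branch lengths, embedded zero-divergence ultraconserved blocks,
a sites-only VCF, a selection bedGraph and a mask BED — so the whole
pipeline is testable without any downloads.

## Worked example

```sh
consite simulate --seed 3 --out fix --length 20000
consite score --ref fix/ref.fa \
    --axt fix/spA.axt --axt fix/spB.axt --axt fix/spC.axt \
    --axt fix/spD.axt --axt fix/spE.axt --axt fix/spF.axt \
    --tree fix/tree.nwk --vcf fix/variants.vcf \
    --phylop fix/phylop.bedgraph --mask fix/mask.bed --out out
head -3 out/targets.tsv
```

prints

```
2523 target sites written to out/targets.tsv
Chromosome  Start  End   Strand  Cs      Cs_max  Cs_min  protospacer           pam  accessible
chr1        4001   4023  +       1.0000  1.0000  1.0000  CCAAGAGGTGATCGAGCTCT  TGG  True
chr1        4001   4023  -       1.0000  1.0000  1.0000  CCAAGAGCTCGATCACCTCT  TGG  True
```

The top-ranked sites sit at position 4 001 — inside the first embedded
ultraconserved block of the seed-3 fixture (scaled by 20 000/100 000 from
the default block at 20 000), where every species matches the reference
perfectly, the SNP rate is zero and the selection track is positive, so the
scaled score is 1. Coordinates in the table are 1-based inclusive: columns
Start/End span 23 bp. `out/` also contains per-species conserved-element
BEDs, the SNP-density and raw/scaled score bedGraphs, per-chromosome HDF5
arrays and a manifest with the config hash.

The same stages are importable as a library (`consite.scan`,
`consite.phylo`, `consite.tracks`, `consite.targets`,
`consite.synthetic`, `consite.pipeline`), and `consite run
--config run.yaml` drives the whole pipeline from one YAML file.

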
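# phosphonet

Phosphoproteome–transcriptome integration on directed signaling networks.

The package turns phospho-antibody array readouts and an expression
signature into an integrated regulator picture in five stages:

1. **phospho** — per-site log2 fold changes against a control condition,
   sign-adjusted by curated regulatory-effect signs (sites with unknown
   signs are excluded), one representative site per protein, and up/down
   treatment response sets (2-fold rule, any-site semantics) partitioned by
   treatment combination.
2. **annotate** — each measured phosphosite scored against five functional
   categories on three relation layers: the substrate itself ("self",
   binary), its upstream kinases and its regulated interaction partners
   (proportions in [0, 1]), with complete-linkage/Euclidean row clustering.
3. **network** — a directed signaling network with a random-walk-with-return
   proximity measure (default 15 iterations, return probability 0.5;
   dangling mass returns to the seed). Distances are −log10 visiting
   probability; proteins are ranked by distance to the transcription
   factors regulating a gene of interest, and a one-sided Mann–Whitney test
   compares distances of phospho-altered (>1.5-fold) versus unaltered
   proteins.
4. **tf** — regulon-based TF activity from an expression signature:
   confidence-grade filtering (A best, default cutoff D), normal-score rank
   enrichment `nes = Σ mode·q / √n` with a two-sided normal p-value, the
   p < 0.2 display filter, and the set of gene-regulating TFs with >1.5-fold
   phosphorylation increases.
5. **simulate / integrate** — a synthetic-data generator that emits every
   input format with planted ground truth (planted upstream regulator,
   planted effect signs and response sets, planted active TFs), and a
   single-config pipeline runner producing a deterministic result bundle.

## CLI

```sh
# generate a synthetic input bundle with planted truth
phosphonet simulate all --seed 7 --out bundle/

# stage-by-stage
phosphonet phospho fold-changes bundle/phospho_signals.tsv \
    --effects bundle/effects.tsv --control CONTROL \
    --treatments BMP8,NE,BMP8_NE --out fcs.tsv
phosphonet phospho venn fcs.tsv --threshold 2 --out venn.json
phosphonet annotate layers fcs.tsv --categories bundle/categories.gmt \
    --kinases bundle/kinases.tsv --effects bundle/effects.tsv --top 50 --out layers.tsv
phosphonet network rwr bundle/network.sif --seed-node N0001 --r 0.5 --iters 15 --out p.tsv
phosphonet tf activity bundle/signature.tsv --regulons bundle/regulons.tsv --out acts.tsv

# end to end from a YAML config (see tests/test_cli.py for the schema)
phosphonet integrate run --config config.yaml
```

The pipeline writes signed fold changes, Venn membership/counts, the
annotation layer matrix and Newick tree, proximity and distance matrices,
per-gene rankings and TF selections, the Mann–Whitney closeness test and a
run manifest. Identical config + seed gives byte-identical outputs.

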
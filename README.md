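# duocall

Dual-caller somatic variant consensus for tumor–normal exome pairs.

Two independent somatic callers produce VCFs in different dialects; `duocall`
normalizes both, applies one uniform filter cascade to each call set —
FILTER field, unified quality score (≥ 10), alt-read support (≥ 4 reads),
germline subtraction, normal-sample coverage (≥ 10X), homopolymer proximity
(within or adjacent to runs of ≥ 4 identical bases), repeat-region masking,
and population-frequency filtering (MAF strictly above 0.1% removed) — then
intersects the survivors on exact `(contig, pos, ref, alt)` keys. Variants
confirmed by both callers form the consensus set, which is summarized at
cohort level: subclonality (allele fraction strictly below 20%), Ti/Tv ratio,
consequence-category tallies with an exonic roll-up, CADD Phred tiers
(> 30 and the exclusive 20–30 band), and position- and gene-level recurrence
across samples.

A fully self-contained simulator generates a synthetic cohort — reference with
planted homopolymer runs, repeat/target masks, population table, per-sample
truth variants (clonal, subclonal, germline, common-SNP leaks, and one
artifact class per filter) and both caller dialects' VCFs — so every stage is
testable without controlled-access data. With binomial noise disabled the
pipeline output equals exactly the designed consensus truth set.

## CLI

```sh
# 1. generate a synthetic cohort bundle (seed is mandatory)
cat > sim.yaml <<EOF
simulation:
  seed: 1
  n_samples: 15
output_dir: bundle
EOF
duocall simulate sim.yaml

# 2. run the consensus pipeline (bundle ships a ready-made run config)
duocall run bundle/run_config.yaml

# 3. compare results against the simulator's truth manifest
duocall evaluate bundle/results bundle/truth_manifest.tsv

# 4. summarize a standalone pre-annotated variant table (TSV or XLSX)
duocall summarize my_variants.tsv --out report/
```

`run` writes per-sample consensus VCF+TSV, a per-call audit TSV with
enumerated failure reasons, a per-filter attrition table, the cohort report,
and a `run_manifest.yaml` materializing every threshold used. Reruns on
identical inputs are byte-identical.

## Layout

| module | role |
| --- | --- |
| `duocall.reference_context` | FASTA/BED access, interval sets, homopolymer scanning and proximity |
| `duocall.caller_io` | both caller dialects' VCFs, germline VCF, depth track, population and annotation tables |
| `duocall.consensus_filter` | the filter cascade, audit trail, cross-caller intersection |
| `duocall.cohort_summary` | subclonality, Ti/Tv, consequence tallies, CADD tiers, recurrence |
| `duocall.synthetic_data` | cohort simulator and truth-based evaluator |
| `duocall.pipeline` / `duocall.cli` | orchestration, run layout, `duocall` subcommands |
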
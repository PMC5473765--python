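# retrochrono

Evolutionary analysis of LTR retrotransposons as a tested, reusable
pipeline, exercised entirely on synthetic genomes with planted,
ground-truthed elements:

- **synth** — synthetic genomes carrying retrotransposon families with
  configurable LTR lengths, pol-domain orders, insertion-age distributions,
  target-site duplications (TSDs), solo LTRs, fragments and optional nested
  insertions, plus uniform-coverage paired-end reads. Elements are born with
  identical LTRs and aged by independent Jukes–Cantor substitutions, so the
  expected LTR-pair divergence of a copy of age T is K = 2rT.
- **detect** — structural (homology-free) detection of intact elements:
  k-mer-seeded direct-repeat pairs, ungapped X-drop extension, TSD-consistent
  boundary refinement, tandem-repeat false-positive removal.
- **taxonomy** — superfamily classification by pol-domain order
  (PR-IN-RT → copia, PR-RT-IN → gypsy, no RT → unclassified) via six-frame
  translated search; single-linkage family clustering of 5′-LTRs
  (identity > 0.80 over ≥ 50% of both LTRs); OAL-style family ranking with
  high/low/single copy classes.
- **chronology** — insertion dating T = K/(2r) with Jukes–Cantor-corrected
  LTR-pair divergence (rate default 1.3e-8 /site/year) and per-family age
  summaries.
- **phylo** — uncorrected p-distances on RT sequences, canonical
  neighbor-joining with deterministic tie-breaks, Newick output,
  nearest-seed lineage assignment.
- **abundance** — read-depth copy-number proxy: greedy 0.95-identity LTR
  library dedupe (< 150 bp excluded), exact-seed ungapped read mapping with
  fractional multi-mapping weights, depth normalized by genome-wide mean,
  solo-LTR/fragment homology annotation, depth-vs-count validation.
- **cli / pipeline** — orchestration with one global seed fanned out per
  stage, a manifest of every file written, and a ranked family report.

## Command line

```sh
retro-chrono run --seed 1 -o run/            # full demo pipeline
retro-chrono simulate --seed 1 -o sim/       # genome + reads + truth ledger
retro-chrono detect --genome sim/genome.fa --min-ltr 100 --max-ltr 3500 \
    --min-identity 0.75 -o out/
retro-chrono classify --elements out/elements.tsv --genome sim/genome.fa -o out/
retro-chrono cluster  --elements out/elements.tsv --genome sim/genome.fa -o out/
retro-chrono date     --elements out/elements.tsv --genome sim/genome.fa -o out/
retro-chrono tree     --rt out/rt.fasta -o out/
retro-chrono depth    --reads sim/reads_1.fq sim/reads_2.fq \
    --library lib.fa --genome-length 100000 -o out/
```

`retro-chrono run` accepts a JSON config (`--config`); see
`retrochrono.pipeline.demo_config()` for the schema. Identical config + seed
reproduces every artifact byte-for-byte.

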
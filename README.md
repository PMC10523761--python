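# modulimpact

Network-level analysis of **convergent knockdown impact** on protein
functional modules, for systems biologists studying how several distinct
gene perturbations disturb the same cellular machinery.

The motivating setting is motor neuron disease: the fly orthologs of
three RNA-binding proteins mutated in SMA and ALS (*Smn*, *caz*/FUS,
*TBPH*/TDP-43) bind almost disjoint transcript sets, yet their
knockdowns produce overlapping phenotypes.  `modulimpact` tests the
hypothesis that such perturbations converge not on shared target
*genes* but on shared protein *complexes*: each knockdown alters
different members of the same functional module.

## Method

Given a protein–protein interaction edge list, a tissue expression
table, flat term annotations (e.g. GO Biological Process), and
per-knockdown differential-expression (DE) and altered-splicing (AS)
tables, the pipeline:

1. **Tissue network** — keeps interactions whose *both* partners pass
   the expression filter (FPKM > 1), removes self-loops, duplicate
   edges and isolated proteins.
2. **Enrichment** — tests every annotation term for over-representation
   in the tissue network versus the unspecific network with the
   hypergeometric upper tail P(X ≥ k), and estimates a false-discovery
   rate empirically from 1000 random candidate sets of the same size
   (flagging terms at FDR ≤ 0.1).
3. **Module library** — induces each enriched term's genes on the
   tissue network.  Modules may consist of several connected
   components; when the largest component holds > 90 % of the induced
   nodes the remaining isolated clusters are discarded.  Modules of
   10–100 proteins (inclusive) form the library.
4. **Impact scoring** — for module *M* and knockdown *c*,
   `impact(M, c) = 100 · |M ∩ altered(c)| / |M|` where
   `altered(c) = DE-up ∪ DE-down ∪ AS` (adjusted p < 0.05, FDR < 0.05,
   strict).  The **overall impact** is `min_c impact(M, c)` — the
   impact in the least-affected knockdown — and modules with overall
   impact ≥ 20 % are selected as convergently impacted.
5. **Super-modules** — selected modules whose node sets overlap with
   Jaccard ≥ 0.2 are coalesced by connected components of the
   thresholded overlap graph.
6. **Association statistics** — disease-ortholog enrichment of selected
   vs non-selected modules (two-sided Wilcoxon–Mann–Whitney), RIP-bound
   prevalence among altered transcripts in/out of selected modules
   (chi-square with Yates correction), and exact multi-set intersection
   tests for DE/AS overlaps across knockdowns via the chained
   hypergeometric distribution (the SuperExactTest construction).

A seeded synthetic benchmark generator produces all six input table
types with planted convergently impacted modules, planted RIP-binding
and planted disease-label enrichment, so every stage is verifiable by
recovery against the recorded ground truth.

## Worked example

```bash
modulimpact benchmark --seed 1 --out bench/
cat > run.yaml <<EOF
bundle_dir: bench/
params: {seed: 1, n_rand: 1000}
EOF
modulimpact run --config run.yaml --out out/
```

which prints

```
1600 tissue-network proteins, 24 library modules, 12 selected, 11 super-modules -> out/
```

Of the 2000 genes, the 1600 expressed ones (FPKM > 1) form the tissue
network.  27 of 60 annotation terms are enriched against the unspecific
network at the randomization FDR; 24 of their modules fall in the
10–100 size window.  Exactly the 12 planted modules carry ≥ 20 %
overall impact across all three knockdowns (100 % recall, no false
positive), and two overlapping planted terms coalesce, leaving 11
super-modules.  `out/stats.tsv` records the association tests: on this
bundle the selected modules hold a median of 27.2 % disease-linked
proteins versus 0 % in non-selected modules (Wilcoxon p ≈ 3.6e-5), and
31.9 % of their altered transcripts are RIP-bound versus 12.1 % of
altered transcripts outside any module (chi-square p ≈ 9.4e-5) —
recovering the planted effects.

The same analysis runs on real exported tables by listing their paths
under `inputs:` in the YAML config (see `modulimpact.pipeline.run_pipeline`).

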
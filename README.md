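# netsel

Recurrent positive selection and protein-protein interaction network
centrality, as one tested, reproducible pipeline.

## The scientific problem

Whether adaptive evolution preferentially targets the center or the
periphery of an interactome is an open comparative question: highly
connected proteins have more phenotypic leverage (favoring detection of
selection) but are also more pleiotropic and constrained (disfavoring
it), and the answer differs between organisms.  Answering it requires a
chain of analyses that are usually scattered across ad-hoc scripts:

1. **Orthology** — one-to-one orthologs across a small species clade by
   best reciprocal hits (E < 10⁻¹⁰ in both BLAST directions).
2. **Alignment QC** — a conserved-block filter plus exact sliding-window
   singleton rules (15-residue windows with ≥ 10 singletons in one
   sequence; 5-residue all-singleton windows), the standard defense
   against gene-model annotation errors that fake positive selection.
3. **Selection scan** — the M8-vs-M7 codon site-model test.  Both models
   draw a site's ω = dN/dS from Beta(p, q) on [0, 1]; M8 adds a class
   with ω_s > 1 and weight 1 − p₀.  Twice the log-likelihood difference,
   2Δℓ = 2(ℓ_M8 − ℓ_M7), is referred to χ²₂; a gene is called under
   positive selection when P < 0.05 (or P < 0.01, or BH q < 0.1) **and**
   ω̂_s > 1.  Likelihoods use the GY94 codon model (κ, π, ω; F3x4 or
   equal frequencies), Felsenstein pruning over the 61 sense codons, K=10
   discretized beta classes, and three ω starting points (0.04, 0.4, 4).
4. **Network centrality** — degree, betweenness (fraction of shortest
   paths through the protein) and closeness (reciprocal mean distance)
   on physical, deduplicated PPI networks, with evidence-class (LTP/HTP)
   and STRING-style confidence-score (≥ 40%) subnetworks.
5. **Association statistics** — two-sided Mann-Whitney comparisons of
   centralities between selected and no-signature genes, Spearman
   correlations of degree with expression/abundance/length/publication
   covariates, and the partial rank correlation of 2Δℓ with degree
   controlling for publication count.

`netsel` implements all of it as a library plus CLI, together with a
synthetic-data generator that produces codon alignments with known
selection regimes, annotation-error artifacts, scale-free interactomes
and degree-correlated covariates — so the entire chain is testable
without any external downloads.  Planting the selection-degree coupling
with a negative sign yields a "selection at the periphery" world, a
positive sign the opposite; the pipeline recovers the planted direction.

## Worked example

Run a full synthetic study in which selection is planted at the network
periphery (β₁ = −1 on log-degree):

```python
from netsel.pipeline import PipelineConfig, run
from netsel.synthetic import SimulationConfig, NetworkSpec, EffectSpec

cfg = PipelineConfig(
    synthetic=SimulationConfig(
        n_genes=200, n_codons=150,
        network=NetworkSpec(n_nodes=1500, m=3),
        effect=EffectSpec(beta1=-1.0),
    ),
    seed=42,
)
report = run(cfg, "out/")
print(open("out/report.txt").read())
```

which prints (exact output, reproducible from the seed):

```
netsel run summary
==================
criterion: p05    seed: 42

funnel:
  network_nodes              1500
  network_edges              4494
  input_genes                200
  with_complete_orthologs    199
  after_filtering            199
  tested                     199
  selected_p05               106
  selected_p01               105
  selected_q10               106

centrality comparisons (selected vs no-signature genes):
  degree       mean selected 3.877 | mean others 6.774 | U=3788 P=0.00379
  betweenness  mean selected 0.0007736 | mean others 0.00337 | U=3724 P=0.00296
  closeness    mean selected 0.2587 | mean others 0.2679 | U=4298 P=0.12

correlations:
  degree~mrna_abundance            rho=+0.327 P=1e-38
  degree~protein_abundance         rho=+0.318 P=1.43e-36
  degree~protein_length            rho=+0.098 P=0.000134
  degree~publications              rho=+0.466 P=1.25e-81
  degree~breadth                   rho=+0.136 P=1.14e-07
  two_delta_l~degree|publications  rho=-0.050 P=0.486

breadth-vs-selection trend: rho=+0.106 P=0.687
```

Reading it: of 200 simulated ortholog groups, 199 survive the BRH and
filtering funnel; 106 are called under positive selection at P < 0.05
with ω̂_s > 1.  Selected genes have markedly fewer interaction partners
(mean degree 3.9 vs 6.8, Mann-Whitney P = 0.0038) and lower betweenness —
the planted periphery effect — while degree correlates with expression
and publication covariates exactly as the copula prescribed, and the
breadth-vs-selection trend is flat because breadth was given no causal
role.  Per-stage tables (`selection_calls.tsv`, `centralities.tsv`,
`gene_table.tsv`, `comparisons.tsv`, masks, ortholog groups) land next
to the report.

The same run is available from the shell:

```bash
netsel run-all --config config.yaml --seed 42 --outdir out/
```

with subcommands `simulate`, `orthologs`, `filter`, `selection-test`,
`centrality` and `stats` exposing the individual stages for file-based
inputs (BLAST outfmt-6 hit tables, FASTA alignments, Newick trees,
BioGRID/STRING-style edge lists).

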
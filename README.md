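# trnreduce

Tools for studying how transcriptional regulatory networks (TRNs) decay as
bacterial genomes shrink — and which kinds of transcription factors (TFs)
survive the process.

Endosymbiotic and obligately host-associated bacteria lose genes
relentlessly. Starting from a well-characterized reference TRN (such as
that of *E. coli*), `trnreduce` reconstructs the regulatory networks of
smaller, related genomes by the regulog rule, asks whether activators,
repressors or dual regulators are preferentially conserved, and corrects
every comparative statistic for the phylogeny relating the genomes. It is
aimed at comparative genomicists and systems biologists who want a tested,
scriptable version of this analysis, plus a synthetic-data generator that
makes every stage verifiable without any genome downloads.

## What it computes

* **Orthology** — bidirectional best hits over BLAST-tabular (`-outfmt 6`)
  hit tables, accepting a pair only when both directions' best hits have
  e-value < 1e-6, identity > 30% and alignment length > 60% of *each*
  protein.
* **Regulog reconstruction** — a reference interaction TF→TG is inferred
  as conserved in a target genome iff both endpoints have orthologs.
* **Conservation tests** — per genome and TF type, the number *k* of
  conserved TFs of that type, out of *n* conserved TFs drawn from a
  reference pool of *N* TFs (*K* of the type), is referred to the upper
  tail of Hypergeometric(*N*, *K*, *n*); one-sided p-values are combined
  across genomes with Fisher's method, −2Σln *p* ~ χ²(2m).
* **Globality** — for each TF *x*,
  `G(x) = ¼·(TFR/(N_TF+N_SF−1) + GR/N_G + SF/N_SF + CR/(N_TF−1)) ∈ [0,1]`,
  where TFR counts regulators regulated by *x*, GR its non-regulatory
  targets, and SF/CR the sigma factors and TFs co-regulating its targets.
* **Phylogenetically independent contrasts** — Felsenstein's recursion
  with positivized x-contrasts, then correlation and regression through
  the origin with *n*−1 degrees of freedom.
* **Standardized multivariate regression** — each TF-type fraction on
  genome size, global-regulator fraction and NAP fraction, reporting
  standardized partial coefficients `b_j = β_j·sd(X_j)/sd(Y)`.
* **Synthetic scenarios** — Yule trees, a scale-free-ish reference network
  with exact node/edge totals, irreversible per-type gene loss with a
  relaxed loss clock, genome sizes, and reciprocal hit tables with
  optional decoys.

## Worked example

```python
import trnreduce as tr

# the 17-node, 26-interaction example network around one hub TF
from trnreduce.examples import hub_example_network
net = hub_example_network()
print(net.summary())                                   # (4, 2, 11, 26)
stats = tr.tf_regulatory_stats(net, "TF_G")
print(stats)                                           # (2, 10, 2, 3)
print(round(tr.globality_score(stats, (4, 2, 11)), 4)) # 0.8273

# a full synthetic genome-reduction study
bundle = tr.generate_scenario(tr.ReductionScenario(seed=1))
result = tr.run_pipeline_on_bundle(bundle)
print({t.value: round(c.combined_p, 4) for t, c in result.combined.items()})
# {'activator': 1.0, 'repressor': 0.0484, 'dual': 0.0}
print(result.contrast_stats.set_index("y").loc["frac_duals", "r"].round(3))
# -0.909
```

The hub TF regulates 2 TFs and 10 of the 11 target genes and co-regulates
with both sigma factors and all 3 other TFs, so its globality score is
(2/5 + 10/11 + 2/2 + 3/3)/4 ≈ 0.8273 — a near-maximal hub. In the
synthetic study, gene-loss hazards are ordered activator > repressor >
dual, and the pipeline recovers that: the Fisher-combined conservation
p-value is overwhelming for dual regulators (underflowing to 0), near 1
for activators (and above 0.05 for repressors in nearly every seed; this
seed is the borderline one), and the contrast correlation between genome
size and dual fraction is strongly negative — duals dominate what
remains in the smallest genomes.

A command-line interface mirrors the stages
(`trnreduce simulate | orthologs | reconstruct | stats | globality | pic |
regress | run-all`); `trnreduce config --init c.txt` writes a config
populated with every default, and `trnreduce run-all --config c.txt --out
report/` produces the TSV tables plus `summary.txt`.

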
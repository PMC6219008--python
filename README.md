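# rankscore

Truly single-sample, rank-based gene-set scoring for transcriptomic data
(bulk or single-cell), with permutation significance, rank-dispersion
diagnostics, cohort-dependent comparator scorers, a simulation benchmark
harness and diagnostic plots.

Genes are ranked by increasing abundance *within each sample* and a
signature's score is the mean rank of its genes rescaled between the
theoretical minimum and maximum mean ranks for a set of that size.
Bidirectional signatures (separate up- and down-regulated sets) centre each
directional score on zero and sum them, giving a total in [−1, 1]. Because
only within-sample ranks are used, a sample's score never depends on which
other samples are processed with it, and is invariant under any strictly
monotone within-sample transform (log, rescaling, TPM vs RPKM, ...).

## Quick start (Python)

```python
import rankscore as rs

em = rs.read_expression("expression.tsv")        # genes x samples TSV
em = rs.filter_low_abundance(em)                 # keep genes > 2 in > 90% of samples
sigs = rs.read_gmt("signatures.gmt")             # _UP/_DN pairs merge automatically

table = rs.score_matrix(em, sigs, dispersion=True)   # tidy per-(sample, signature) rows

rp = rs.rank_genes(em, em.sample_ids[0])
null = rs.permutation_null(rp, sigs[0], b=1000, seed=1)
obs = rs.score_signature(rp, sigs[0]).total
p = rs.empirical_pvalue(null, obs, "greater")
```

Comparator scorers (`zscore_combined`, `plage_score`) and the simulation
harness (`simulate_counts`, `make_gene_sets`, `power_type1`, `recall_f1`,
`stability_experiment`, `concordance_index`) are exported from the top-level
package; any callable `(ExpressionMatrix, GeneSignature) -> scores` can be
added to the benchmark registry with `register_scorer`.

## CLI

```bash
rankscore score --expr expression.tsv --gmt signatures.gmt --out scores.tsv
rankscore nulltest --expr expression.tsv --gmt signatures.gmt -b 1000 --seed 1 --out null.tsv
rankscore plot --kind barcode_density --expr expression.tsv --gmt signatures.gmt \
    --sample S1 --out barcode.png
rankscore simulate --n-genes 1000 --n-samples 30 --n-de 30 --out sim.tsv
rankscore bench-power --method rankscore --config grid.yaml --out power.tsv
rankscore bench-recall --method rankscore --out f1.tsv
rankscore bench-stability --methods rankscore,zscore,plage --out stability.tsv
```

Benchmark subcommands accept a YAML config for the scenario grid (effect
sizes, DE fractions, repetition counts, sample/gene sweeps); all reports are
tidy TSV, one metric per row.

## Layout

| module | contents |
| --- | --- |
| `rankscore.io` | `ExpressionMatrix`, `GeneSignature`, TSV/GMT readers & writers, low-abundance filter |
| `rankscore.scoring` | rank profiles; directed / bidirectional / undirected scoring; `score_matrix` driver |
| `rankscore.significance` | permutation null vs random gene sets, empirical p-values, MAD rank dispersion |
| `rankscore.comparators` | combined z-score, PLAGE, scorer registry |
| `rankscore.bench` | NB count simulator, gene-set builder, power/type-I, F1 recall, paired-platform stability, concordance index |
| `rankscore.plots` / `rankscore.cli` | barcode/density, landscape and score-vs-dispersion plots; `rankscore` entry point |

A note on undirected scores: the theoretical bounds used for normalisation
are not always attainable, so undirected normalised scores can fall slightly
below 0 and cannot always reach 1; they are deliberately not clamped, and
collapsing bounds raise `DegenerateBoundsError`.
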
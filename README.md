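# phylobrt

**Phylogenetically informed boosted regression trees for comparative trait
analysis.**

`phylobrt` asks a classic question of comparative biology: when a
molecular phenotype varies across species, how much of that variation
tracks measurable species traits, and how much simply tracks the
phylogeny? It was built around a concrete instance of the question —
ranking 17 avian life-history traits against phylogenetic relatedness as
correlates of dioxin sensitivity, using in vitro TCDD EC₅₀ values of the
aryl hydrocarbon receptor 1 ligand-binding domain (AHR1 LBD) subtypes as
a continuous sensitivity proxy across 89 bird species — but every stage
is generic.

## The method

1. **Consensus phylogeny.** A set of candidate trees (e.g. a posterior
   sample) is summarised into a 50% majority-rule consensus tree: the
   tree containing exactly the clades present in strictly more than half
   of the input trees, with branch lengths averaged over the trees
   supporting each clade.
2. **Phylogenetic eigenvectors (PVR).** From the consensus tree's
   patristic distance matrix `D` (path lengths between tips), principal
   coordinate analysis eigendecomposes the Gower-centred matrix
   `B = -½ J D² J`. The leading eigenvectors, scaled by √λ and ranked by
   eigenvalue, represent relatedness as coordinates; the smallest prefix
   of axes explaining ≥ 99% of the variation is carried forward.
3. **Boosted regression trees (BRT).** A from-scratch least-squares
   gradient boosting machine fits the response on the traits plus the
   eigenvectors: shallow regression trees (default 3 splits) are grown
   on residuals over bagged subsamples (default 75%) and added with
   shrinkage (default learning rate 0.01); the number of trees is chosen
   by k-fold cross-validation. Nominal traits split on level subsets,
   ordinal traits split as integers, and missing values are routed to the
   heavier child — no dummy coding or imputation.
4. **Variable importance and the deviance partition.** A predictor's
   relative influence (VI) is its summed split-improvement across the
   ensemble, scaled so all VI scores sum to 100. Summing VI within the
   two predictor groups splits the *model* deviance into trait and
   phylogeny shares; multiplying by the total percent deviance explained
   (cross-validated) gives each group's share of the *response* deviance.
5. **Interpretation.** Partial-dependence curves show each top
   predictor's marginal effect; a pairwise interaction screen measures
   each pair's departure from additivity on the bivariate
   partial-dependence grid.

A synthetic-data module generates the whole input bundle — Yule trees
with perturbed replicates, Brownian-motion and Markov-jump traits with
phylogenetic signal, and a subtype/EC₅₀ response pathway with a
controllable trait-vs-phylogeny mix — so the full analysis and its
recovery properties are testable without any downloads.

## Worked example

```python
import phylobrt as pb

sim_config = pb.SimConfig(rng_seed=1)          # 89 species, 17 traits, 13 subtypes
brt_config = pb.BRTConfig(
    learning_rate=0.1, max_trees=250, step_size=25, n_folds=5, rng_seed=1
)
report = pb.run_pipeline(
    pb.PipelineConfig(simulate=sim_config, brt=brt_config)
)

part = report.partition.rounded()
print(f"eigenvectors retained: {report.n_eigenvectors} "
      f"({100 * report.cum_fraction:.1f}% of phylogenetic structure)")
print(f"total deviance explained (CV): {part['total_pct']}%")
print(f"group share of model deviance: {part['group_vi_pct']}")
print(f"group share of response deviance: {part['group_abs_pct']}")
print("top predictors:")
print(report.vi_table.head(5).round(1).to_string())
```

prints

```
eigenvectors retained: 41 (99.0% of phylogenetic structure)
total deviance explained (CV): 68.7%
group share of model deviance: {'trait': 74.4, 'phylogeny': 25.6}
group share of response deviance: {'trait': 51.1, 'phylogeny': 17.6}
top predictors:
incubation_period       68.1
eigenvector_41           3.8
eigenvector_4            3.4
eigenvector_25           3.1
residual_testes_mass     2.3
```

Read: the boosted model explains 68.7% of the cross-validated deviance in
the simulated sensitivity proxy. Of the model deviance, the 17 traits
carry 74.4% and the 41 phylogenetic eigenvectors 25.6% — i.e. 51.1% and
17.6% of the response deviance respectively (summing back to 68.7%). The
simulation's true driver trait (incubation period, the one trait given a
nonzero effect in `SimConfig`) dominates the influence ranking, as it
should.

The same analysis runs from the shell on files
(`phylobrt simulate`, `phylobrt consensus`, `phylobrt distances`,
`phylobrt pcoa`, `phylobrt run --config run.yaml --out outdir`), reading
Newick tree sets, a trait CSV with a YAML column schema, and two-column
species→subtype and subtype→EC₅₀ CSVs.

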
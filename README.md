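# colonynet

Multilayer analysis of social organisation in ant colonies: from automated
tracking of individually tagged workers to social network position ("social
maturity"), and from there to behaviour, space use, age, brain gene
expression and gut microbiota.

In *Camponotus* colonies, workers divide labour along a nurse-forager axis.
`colonynet` implements the full analysis chain used to study how a worker's
position in the colony's social network relates to every other measured
aspect of its biology:

- **Interaction inference** — pairwise contacts are detected geometrically
  from frame-level tag detections: two workers interact in a frame when
  their head disks (placed ahead of the tag along the body axis) overlap;
  contact bouts become edge weights of a weighted social network.
- **Social maturity** — the network `W` is factorised as
  `W ≈ X Λ Xᵀ` (nonnegative `X`, column-stochastic; community weights `Λ`)
  by minimising the KL divergence `D(W ‖ XΛXᵀ)` with multiplicative EM
  updates — static soft community detection in the FacetNet family with
  `k = 2` overlapping communities. The row-normalised membership of the
  forager community is the worker's *social maturity* `∈ [0, 1]`.
- **Multiplex network** — five layers (social, behaviour, expression,
  microbiota, physical environment) over the same workers; non-social
  layers use Euclidean profile distances, intralayer edges connect pairs
  beyond the upper quartile of the edge-weight distribution, interlayer
  edges couple each worker with itself.
- **Interlayer R² network** — each layer reduced to one scalar per worker
  (social maturity; PCA component otherwise — for expression, the component
  carrying biology rather than extraction batch), then squared Pearson
  correlations among the six variables (5 layers + age), per colony and
  averaged. The variable with the largest strength (sum of incident R²) is
  the hub.
- **Differential expression** — per-gene negative-binomial Wald tests of a
  continuous covariate with colony terms and an optional control covariate
  (median-of-ratios size factors, trend-shrunk method-of-moments
  dispersions, Benjamini-Hochberg correction), and the controlled-DE
  accounting matrix: what fraction of one variable's DE genes survive
  controlling each other variable.
- **Prediction** — iterated half-split support-vector regression (linear
  kernel) on DE-selected genes: the distribution of held-out R² over 100
  random splits measures how strongly each variable is written in the brain
  transcriptome.

A synthetic colony generator produces datasets with the causal structure
this analysis assumes — a latent U-shaped maturity driving role-assortative
interactions, arena use, task behaviours, age, expression and microbiota —
so the entire pipeline runs and is tested without any external data.

## Worked example

```python
from colonynet import RunConfig, run_full_analysis

results = run_full_analysis(RunConfig(master_seed=7), outdir="runs/demo")
print(open("runs/demo/report.txt").read())
```

prints (numbers from this exact run):

```
hub variable: social
strength ranking: social=2.942, physical=2.886, expression=2.718, behavior=2.527, age=1.855, microbiota=1.331
maturity U-shape ratio: 1.284
LMER maturity~age: R2=0.416 t=16.71
LMER maturity~foraging: R2=0.888 t=55.83
prediction mean R2: social=0.466, behavior_pc1=0.342, age=0.268, permuted=0.003
```

Reading this: the social-maturity variable is the most strongly connected
node of the interlayer R² network (the hub), the recovered maturity scores
keep the U-shaped (bimodal) distribution of the latent trait, maturity
correlates with age and foraging under a random-intercept-per-colony
regression, and brain expression predicts social maturity better than it
predicts behaviour, age, or a permuted control.

The same pipeline is available from the shell:

```sh
colonynet run-all --seed 7 --out runs/demo
colonynet simulate --seed 1 --out data/
colonynet track-features --detections data/detections.csv --out features/
colonynet maturity --edges features/interactions.csv --foraging features/foraging.csv --out maturity.csv
```

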
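# anni

Artificial-neural-network inference (ANNI) of signed, directed gene–gene
interaction networks from expression data.

Given a panel of genes measured across samples (a microarray biomarker
panel, say), `anni` asks for every gene: *how well, and in which
direction, do all the other genes explain it?* Each gene in turn becomes
the output node of a small backpropagation perceptron whose inputs are
all remaining genes (an N-2-1 architecture). The trained connection
weights are distilled into one signed score per ordered gene pair —
positive for stimulatory, negative for inhibitory influence — and the
resulting G×G interaction matrix is filtered and simplified into an
interactome map that tools like Cytoscape can display. The intended
audience is anyone who has a ranked biomarker panel and wants a
data-driven hypothesis about which markers drive which.

## The model

For target gene *t* with predictor genes *i = 1..N* (all genes except
*t*, min–max scaled to [0, 1]), a 3-layer perceptron with H sigmoid
hidden units computes

```
h_j = σ(a·(Σ_i w_ij x_i + b_j)),   y = σ(a·(Σ_j v_j h_j + b_o)),   σ(z) = 1/(1+e^(−z))
```

and is trained by per-sample backpropagation on ½(d − y)² with learning
rate η = 0.1 and momentum α = 0.5:

```
Δw(T) = η · δ · x + α · Δw(T−1)
```

Training runs under Monte-Carlo cross-validation: 50 random 60:20:20
train/test/validation splits, 10 restarts each (500 models per gene at
full depth). The training partition updates weights; the test partition
drives early stopping (MSE < 0.01, or no improvement over 100 epochs,
capped at 300 epochs); the validation partition is only scored. The
influence of input *i* on the target is read off the trained weights as
the connection-weight product `Σ_j w_ij v_j`, averaged over all models.
Interactions whose raw expression correlation falls below |r| = 0.7 are
filtered out, and the map is simplified to each gene's single strongest
incoming association.

A synthetic benchmark module generates datasets with a planted
correlated block (latent-factor design, known population correlations)
and scores recovery by three metrics: Pearson correlation of predicted
scores against true pairwise correlations, percentage of correctly
assigned interaction signs, and the true positive rate of the
correlation filter.

## Worked example

```python
from anni import ANNI, AnniConfig, SyntheticSpec, generate_dataset, evaluate

expr, truth = generate_dataset(SyntheticSpec(n_samples=60, n_features=10,
                                             n_correlated=4, n_predictive=2, seed=7))
cfg = AnniConfig(n_reshuffles=10, n_repeats=3, rng_seed=7)
res = ANNI(expr, config=cfg).fit()      # scales, trains 10 x 30 models
print(res.summary(top=5))
```

```
ANNI interaction model
==========================================================
Genes: 10    defined interactions: 90
Architecture: N-2-1  (N = 9 inputs per target)
MCCV: 10 reshuffles x 3 repeats, split 0.6:0.2:0.2
Validation MSE: mean 0.0344  min 0.0118  max 0.0598

Strongest 5 associations (by |score|):
      source       target      score sign
        F002         F004     9.1816 stimulatory
        F003         F004    -8.6255 inhibitory
        F001         F004    -7.2956 inhibitory
        F004         F003    -6.2356 inhibitory
        F001         F003     5.1557 stimulatory
```

The four planted block features (F001–F004) dominate the strongest
associations, with signs matching their alternating latent-factor
loadings (F002 and F004 share a loading sign, hence stimulatory).
Scoring the fit against the planted truth:

```python
print(evaluate(res.scores, truth, expr, scope="correlated_only"))
```

```
Evaluation (correlated_only, 4 features, 2 hidden nodes, 6 pairs)
  Pearson coefficient (score vs actual r): 0.966
  Correctly assigned signs:                100.00%
  True positive rate:                      100.00%
```

`res.filter()` applies the |r| ≥ 0.7 expression-correlation filter,
`res.network()` builds the strongest-edge-per-gene map, and
`anni.export_network(map, "sif", path)` writes Cytoscape input.

## Command line

```sh
anni simulate --out-dir sim --seed 1          # synthetic dataset + truth
anni infer sim/expression.tsv --out-dir run --reduced --seed 1
anni evaluate --scores run/scores.tsv --truth sim/truth.tsv \
              --expression sim/expression.tsv --out report.tsv
anni export --edges run/network_edges.tsv --format graphml --out net.graphml
```

Every output directory contains a `manifest.json` (config snapshot,
input digests, seed) from which a run reproduces bit for bit.

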
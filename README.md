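# ordnet — network psychometrics for ordinal questionnaire data

`ordnet` estimates and analyses **regularised partial-correlation networks**
("Gaussian graphical models", GGMs) from Likert-type questionnaire items —
the workflow used to study how behaviours, cognitions and emotions such as
perceived stress, coping and social support hang together as a psychological
network. It is written for applied researchers who have a respondents × items
table of ordinal scores (and for methodologists who want every stage
testable against synthetic ground truth).

## The model

Item scores 1..K are treated as discretised views of latent standard-normal
variables. The analysis chain is:

1. **Polychoric correlations** `R` under pairwise deletion: for each item
   pair, thresholds come from the marginal cumulative proportions
   (`τ = Φ⁻¹(cum. prop.)`) and the latent correlation maximises the
   bivariate-normal likelihood of the contingency table.
2. **Graphical lasso**: the penalised precision matrix `K` maximises
   `log det K − tr(RK) − λ Σᵢ≠ⱼ |Kᵢⱼ|` along a decreasing λ-path; the
   penalty is selected by minimising the **extended BIC**
   `−2L + E log n + 4 E γ log p` (γ = 0.5). Edges are the partial
   correlations `wᵢⱼ = −Kᵢⱼ / √(Kᵢᵢ Kⱼⱼ)`.
3. **Network description**: edge density, weighted global clustering
   (Zhang–Horvath), walktrap communities with a parametric bootstrap CI for
   the number of communities, within/between-community RMSEW, strength /
   eigencentrality / bridge-strength centrality (raw and z-scores), and the
   minimum-spanning-tree backbone from Gower distances `d = √(2(1−w))`.
4. **Uncertainty**: nonparametric edge bootstrap, and case-dropping
   **CS coefficients** — the largest fraction of respondents that can be
   dropped while the re-estimated statistic still correlates ≥ 0.7 with the
   original in 95% of subsamples (≥ 0.25 acceptable, ≥ 0.5 good).
5. **Sample-size planning**: Monte-Carlo search for the smallest n at which
   edge-recovery sensitivity `TP/(TP+FN)` reaches a target in a target
   fraction of replications.

A synthetic-data module generates ground-truth sparse GGMs with planted
stress/coping/support communities (positive edges within communities,
negative stress–coping and stress–support bridges) and samples ordinal
datasets from them, so the full pipeline runs and is tested without any
sensitive study data.

## Worked example

```python
import ordnet

model = ordnet.generate_true_ggm(seed=1)            # 17 items, 3 communities
data  = ordnet.sample_ordinal(model, n=367, seed=2) # 5-point ordinal scores
data  = ordnet.inject_missing(data, rate=0.011, seed=3)

net = ordnet.select_network(ordnet.correlation_matrix(data))
print(ordnet.edge_density(net), ordnet.walktrap(net).n_communities)
```

Running `python examples/01_simulate_and_estimate.py` prints:

```
data: 367 respondents x 17 items, 88 missing cells
selected penalty lambda = 0.0511 (gamma = 0.5)
edges: 73 of 136 possible -> edge density 0.54
weighted global clustering = 0.29
recovered 81% of true edges
```

i.e. at n = 367 the EBIC-glasso keeps 73 partial-correlation edges (density
0.54 — typical of questionnaire networks), and recovers 81% of the planted
true edges. The other scripts in `examples/` walk through communities and
centrality, bootstrap stability (CS coefficients) and sample-size planning,
each printing and explaining its numbers.

A thin CLI wraps the same library calls:

```bash
ordnet simulate --n 367 --seed 1 --outdir sim/
ordnet run --input sim/data.csv --outdir out/ --seed 1
ordnet power --reps 100 --seed 1
```

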
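# emonet

Perceived-emotion networks from multi-rater character annotation matrices.

`emonet` implements a computational-psychometrics pipeline for quantifying
emotional storytelling. A panel of judges watches a narrative (originally a
feature film) and fills one square matrix per emotion — anger, fear, joy,
sadness by default — whose rows and columns are the story's characters. The
cell (i, j) holds a Likert value in [1, 10] for how strongly character *i*
expresses that emotion toward character *j*; repeated annotations of the
same cell accumulate additively. The pipeline then:

1. **Scores inter-observer disagreement per cell** with the
   information-based measure of disagreement (IBMD). For observers
   *x_a*, *x_b* the pair term is
   `log2(|x_a − x_b| / max(x_a, x_b) + 1)` (0/0 defined as 0), and the
   multi-observer IBMD is the mean over all M(M−1)/2 observer pairs. It is
   0 exactly when the observers agree and grows toward 1 with the relative
   distance between their values.
2. **Filters cells by agreement**: a percentile bootstrap over the observers
   yields a 95% confidence interval for each cell's IBMD; only cells whose
   CI *upper bound* lies strictly below a threshold (default **0.15**) are
   retained. Pairwise judge agreement is cross-checked with the intraclass
   correlation coefficient, ICC(A,1) by default (two-way random, absolute
   agreement, single measure).
3. **Builds one weighted directed network per emotion** from the retained
   cells (edge weight = mean of the judges' values, configurable), and
   computes degree centrality: the weighted outdegree of a character is how
   much of the emotion it *expresses*, the weighted indegree how much it
   *receives*; `d_i(g) = #{j : g_ji = 1}` gives the unweighted counts. On
   every such network total in-weight equals total out-weight, so mean
   indegree = mean outdegree and mean total degree is twice either.

Because real annotation panels are expensive, the package ships a
first-class synthetic generator with known ground truth (latent weight
matrices, per-rater Gaussian noise, annotation sparsity, accumulating
repeats) and a parameter-recovery harness, so every stage is testable end
to end.

## Worked example

```python
import emonet as em

gt = em.random_ground_truth(n_characters=6, noise_sd=0.2, seed=42)
ms, _ = em.generate(gt)                      # 11 simulated judges x 4 emotions
cells = em.filter_cells(em.cell_observations(ms),
                        threshold=0.15, n_boot=2000, seed=42)
print(f"{sum(c.retained for c in cells)}/{len(cells)} cells retained")
nets = em.build_networks(cells, ms, aggregator="mean")
table = em.degree_indices(nets["anger"])
print(table[["weighted_indegree", "weighted_outdegree", "weighted_degree"]])
print(em.descriptive_stats(table).round(3))
```

prints

```
143/144 cells retained
              weighted_indegree  weighted_outdegree  weighted_degree
character
Character AA                0.0                 4.0              4.0
Character AB                7.0                10.0             17.0
Character AC               10.0                13.0             23.0
Character AD                6.0                 0.0              6.0
Character AE                4.0                 9.0             13.0
Character AF                9.0                 0.0              9.0

                    weighted_indegree  weighted_outdegree  weighted_degree
statistic
Mean                            6.000               6.000           12.000
Std. Error of Mean              1.483               2.236            2.921
Median                          6.500               6.500           11.000
Std. Deviation                  3.633               5.477            7.155
Maximum                        10.000              13.000           23.000
```

With 11 judges and mild rater noise (σ = 0.2 Likert points) 143 of the 144
cells pass the 0.15 agreement cutoff, and the recovered anger network's
degrees match the latent truth. Character AC both expresses (13) and
receives (10) the most anger; the Mean row shows the structural identity
mean-in = mean-out, with the mean weighted degree exactly twice either.

The same pipeline is available from the shell:

```sh
emonet simulate --n-characters 6 --noise-sd 0.2 --seed 42 --out-dir panel/
emonet pipeline panel/ --seed 42 --out-dir results/
```

which writes the agreement report (JSON), the pairwise judge ICC matrix,
per-emotion GraphML/GEXF networks with degree attributes, ranked centrality
tables, descriptive statistics, the in/out-degree correlations, and a
`run_config.json` recording every parameter and seed; re-running with the
same inputs and configuration reproduces the bundle byte for byte.

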
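# Methods

## The measurement model

A panel of M judges independently annotates directed emotional interactions
between the characters of a narrative. For each emotion e the judge fills a
square matrix over a fixed character roster: cell (i, j) accumulates Likert
values in [1, 10], each annotation adding to the cell ("annotating again
makes the link stronger"). A cell value of 0 therefore means "no perceived
emotional interaction" — the Likert floor is 1, so 0 is unambiguous, and
the package deliberately does not distinguish "did not annotate" from "no
emotion". Self-directed cells (the diagonal) are permitted and flow through
the whole pipeline with a validation warning, since self-directed joy or
sadness is semantically plausible.

The roster is fixed a priori and supplied explicitly; annotation events
referencing unknown names fail rather than silently extending the roster,
because silent growth hides typos. Labels are whitespace-normalized but
case-preserving. Aggregate pseudo-characters ("Others", "Drug") are
ordinary roster entries. The emotion set defaults to anger, fear, joy and
sadness but is an arbitrary label list — nothing in the method is specific
to those four.

## IBMD and the retention filter

For one cell, let x_1 … x_M be the judges' final accumulated values. The
information-based measure of disagreement uses the pair term

    d(x_a, x_b) = log2(|x_a − x_b| / max(x_a, x_b) + 1),

with d(0, 0) := 0 (agreement on absence), and the multi-observer score is
the mean of d over all M(M−1)/2 pairs. d is 0 iff the pair agrees and
approaches 1 as the relative distance grows (one judge reporting 0 against
any positive value gives exactly log2 2 = 1). The implementation is
vectorised over the pair matrix; an independently coded pair-enumeration
oracle in the test suite agrees to 1e−12.

Uncertainty is assessed by a percentile bootstrap over the observers: the M
values are resampled with replacement n_boot times (default 2000), the IBMD
recomputed per resample, and the 95% interval taken at the (2.5, 97.5)
percentiles. A percentile interval is not guaranteed to bracket the plug-in
estimate in degenerate cases, so the interval is widened to include it —
this only ever makes the retention rule stricter. Constant cells skip the
bootstrap entirely (every resample is constant), giving the exact interval
(0, 0).

A cell is **retained** iff its CI upper bound is strictly below the
threshold, default 0.15; a tie at exactly 0.15 is dropped. Filtering is
per cell: only a per-cell score can drive per-cell retention. All-zero
cells score 0 and are retained, but produce no edge downstream. Each cell's
bootstrap seed is derived from the run seed and a CRC-32 of the cell
identity through numpy's `SeedSequence`, so results are bit-reproducible
and independent of the order in which cells are processed.

The 0.15 cutoff is deliberately conservative: with M = 11 judges, even
moderate per-rater noise (σ ≈ 0.5 Likert points) pushes many low-valued
cells above it, because the IBMD is a *relative* measure — a 4-vs-5 split
contributes log2(1/5 + 1) ≈ 0.26 per pair. Retention fractions well below 1
at realistic noise are therefore expected behaviour of the filter, not a
defect; raising the threshold populates the networks more densely at the
cost of admitting disagreement.

## ICC cross-check

Pairwise judge agreement is additionally summarised by the intraclass
correlation coefficient, computed for every judge pair over the vector of
all cell values (all emotions concatenated by default, or per emotion). The
default form is ICC(A,1) — two-way random effects, absolute agreement,
single measure — because judges are exchangeable raters scoring the same
targets and a constant between-judge offset *should* count as
disagreement; ICC(1) and the consistency form ICC(C,1) are selectable. The
variance components come from a standard two-way ANOVA decomposition
written out explicitly; the test suite checks it against the pingouin
reference implementation to 1e−8. A pair with no variance across cells has
an undefined ICC and is reported as missing (NaN) with a warning, never
as 0.

## Networks and degree indices

For each emotion, every retained cell with at least one nonzero judge value
becomes an edge whose weight aggregates the M values — mean (default),
median or sum, zeros included. The mean is the shipped default because it
is stable in the number of judges; the choice is recorded in every output.
A retained cell whose aggregate is 0 (possible under the median) yields no
edge, since the graphs store strictly positive weights only.

Degree indices follow the standard weighted-digraph definitions; weighted
outdegree is the emotion a character expresses, weighted indegree the
emotion it receives, and their sum the weighted degree. Self-loops count
toward both. Isolated characters stay in the node set and in all
descriptive statistics — the roster defines the population. Descriptive
statistics use the n−1 denominator for the standard deviation, SE = SD/√n,
and the midpoint convention for even-n medians; a single-node table reports
SD 0 with a warning. Top-k tables (default k = 10) rank by value with ties
broken by roster order. The conservation identity Σin = Σout = total edge
weight holds on every digraph and is what makes the mean indegree and mean
outdegree rows of any such summary coincide.

## Synthetic data generator

The generator emulates the structure of the original data collection —
M = 11 judges, four emotions, Likert 1–10, additive repeats — around a
latent truth W per emotion whose entries are 0 or in [1, 10] (integer
draws by default). When a judge annotates a true-nonzero cell
(probability `annotate_prob`, default 1), the recorded value is
`clamp(round(W + Normal(0, noise_sd)), 1, 10)`, optionally emitted as two
events that sum to it (probability `repeat_prob`), exercising the
accumulation rule. Judges never annotate true-zero cells; a false-positive
rate is left as an extension hook at 0. Default noise is σ = 0.5 Likert
points — roughly "judges agree to within half a point"; the default roster
has 12 characters, a modest cast size chosen for fast experimentation
(roster size is a property of the narrative, not of the method).

What the generator does *not* emulate: halo effects, rater drift,
systematic judge biases, and any coupling between a character's in- and
out-weights. In particular the strong positive in/out-degree correlation
observed on real narrative data is a property of stories (characters in
emotional exchanges both give and receive), not of the method, and random
latent truths do not reproduce it; passing recovery tests therefore
validate the statistics, not any claim about real raters or narratives.

With σ = 0 and full annotation, every judge matrix equals W exactly (the
latent weights are integers, so the rounding step is the identity), every
cell is retained, and the mean-aggregated network reproduces W edge for
edge — the noiseless end-to-end identity the acceptance tests assert. The
recovery harness reports micro-averaged edge precision/recall, the Spearman
correlation between true and estimated pooled weighted degrees (defined as
1 when the degree vectors are identical, including the all-zero case), and
the fraction of annotated cells retained.

## Numerical and I/O choices

- All stochastic steps consume a single integer seed through numpy
  generators; repeated runs with one seed produce byte-identical output
  bundles.
- Matrix CSVs use a canonical dialect — UTF-8, comma-delimited, `\n` line
  endings, zeros as empty cells, integral values without a decimal point —
  under which read-then-write is byte-stable.
- Networks persist as GraphML (full run metadata embedded as graph
  attributes) and GEXF (which retains only the graph name; the metadata
  also travels in the `run_config.json` sidecar every command writes).
  Long-format exports list nonzero cells only and re-accumulate losslessly.
- Visual encodings (node size ∝ weighted indegree, color darkness ∝
  weighted outdegree, edge thickness ∝ weight) are exported as numeric
  attributes min–max scaled to [0, 1], with the all-equal degenerate case
  mapped to 0.5; rendering is left to standard graph viewers, plus an
  optional matplotlib rendering with a seeded force-directed layout.

## Problem sizes

The test suite and `scripts/acceptance.py` run on simulated panels of
5–12 characters with 11 raters (4 for some CLI round-trip checks), 300–2000
bootstrap resamples, and 50 replicate seeds for the noise-response checks;
the whole suite completes in well under a minute on one CPU. Raters accept
any real value in [1, 10] even though the generator produces integers.

## Known limitations

- The bootstrap CI resamples observers, which is coarse at small M; no
  analytic IBMD interval is offered.
- No alternative agreement statistics (Krippendorff's α, Kendall's W) and
  no centrality beyond degree — betweenness, closeness and community
  structure are out of scope.
- Whether the original filtering was applied per cell or per whole matrix
  is not determinable from the published description; the per-cell reading
  is implemented, and the whole-matrix alternative is intentionally absent.
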
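# Methods

This note documents the models, parameter choices and numerical decisions
behind `siphonatlas`, and what the synthetic-data generator does and does
not emulate.

## Count model and normalization

Counts are modeled as negative binomial with variance `μ + φμ²`; `φ = 0` is
the Poisson limit. Library-size differences and composition bias are
handled by TMM scaling factors with the method's canonical parameters:
30 % two-sided trim on the log-ratios M, 5 % on the mean log-abundances A,
precision weights equal to the inverse delta-method variance of M
(`(N_s−y_s)/(N_s y_s) + (N_r−y_r)/(N_r y_r)`), transcripts with a zero
count in either member of a pair excluded from that pair's M/A set. The
reference sample is the one whose 75th-percentile count fraction is closest
to the mean of those quantiles, overridable. Factors are rescaled to
geometric mean 1 so CPM values are comparable across runs. Note the
precision weights depend on depth, so TMM factors are only approximately
invariant to rescaling one sample's counts (observed ≲1 % CPM shift on
negative-binomial test matrices).

The low-count filter keeps transcripts whose counts sum to ≥ 30 over all
samples combined, before factor computation (the usual order; a caller can
compute factors first if preferred, as both functions are independent).
Fractional estimated counts (e.g. from expectation-maximization estimators)
are rounded half-to-even on input by default (`round_counts`), since the
downstream exact test is integer-based; disabling the flag makes fractional
input an error.

## Differential abundance

A single common dispersion is estimated by maximizing the conditional
likelihood of the counts given per-group totals (groups = pseudo-organs,
only groups with ≥ 2 replicates contribute), scanned on a 25-point log grid
over [1e-4, 4] and refined by bounded scalar minimization; a maximum at the
lower edge is reported as 0 (sub-Poisson). Before testing, counts are
rescaled to the geometric mean of the TMM-effective library sizes and
rounded, so all samples share one effective depth.

The per-transcript test conditions on the pooled count z of the two organ
groups: with n_A and n_B equal-depth samples and common dispersion φ, the
group-A sum given z is beta-binomial(z, n_A/φ, n_B/φ) under the null of
equal means — exactly binomial(z, n_A/(n_A+n_B)) at φ = 0. Two-sided
p-values double the smaller tail, capped at 1; z = 0 gives p = 1.
Benjamini–Hochberg adjustment is applied per organ pair; the clustering
input is the union of transcripts significant (FDR < 0.05) in at least one
of the k(k−1)/2 pairs. This is a deliberate simplification of
quantile-adjusted/tagwise-shrinkage DE machinery: it captures the pairwise
NB-exact-test-with-FDR design while remaining fully oracle-checkable (the
Poisson limit pins the contract against a closed-form binomial tail).
Log-fold changes are `log2((mean_B + 0.5)/(mean_A + 0.5))` on equalized
counts; the 0.5 prior guards zeros.

## Profiles, PCA and the self-organizing map

CPM values of the DE union are averaged per pseudo-organ and each
transcript's profile is scaled to mean 0, variance 1 (n−1 denominator)
across organs; constant rows are dropped with a warning. Scaling makes
every profile a point of norm √(k−1) on a sphere, so with 6 organs at most
5 principal components carry variance — the PCA (column-centered SVD,
deterministic sign convention) reports the 6th as numerically zero, which
is why downstream discriminant analysis uses PCs 1–5.

The SOM is the classical online algorithm on a hexagonal (default 3×2) or
rectangular grid: winner by Euclidean distance (ties to the lowest unit
index), bubble neighborhood of radius decreasing linearly from 2/3 of the
maximum inter-unit distance to 0, learning rate decreasing linearly
0.05 → 0.01 over 100 iterations, codebook initialized from a seeded random
sample of data rows, all rows presented in seeded random order each
iteration. Hexagonal inter-unit distances use odd-row offset coordinates
converted to cube coordinates. The mean distance to the winning unit is
recorded per iteration as a stabilization diagnostic.

Online SOMs on very small grids inherit the dead-unit problem of
competitive learning: the neighborhood phase contracts the codebook toward
the data center, and a unit that subsequently never wins cannot recover,
leaving one unit straddling two profile families (measured on the default
synthetic atlas: about a third of single trainings end in such a local
optimum, cleanly identifiable by a ~30 % higher quantization error).
`train_som` therefore runs `n_restarts = 20` seeded trainings and keeps the
codebook with the lowest mean quantization error, the same remedy k-means
implementations use. A consequence worth knowing: with *near-zero*
within-family variance the neighborhood phase still collapses codebook
diversity and no restart may succeed; with realistic within-family spread
(scaled-profile s.d. ≳ 0.1) capture is reliable. Node numbering is
row-major over the grid and arbitrary; any comparison against planted
truth uses Hungarian label matching.

## Cluster-number validation

For each candidate grid the SOM is retrained `n_runs` times (default 100)
with seeds derived from a master seed by a counter; each run is a *single*
training (no restart selection), because the across-seed variability of the
partitions is part of what the procedure examines. Per run, a Gaussian
linear discriminant model — class means, pooled within-class covariance
with ridge `1e-8·trace/d`, priors proportional to class size (equal-prior
flag available) — is fit on PCs 1–5 against the run's cluster labels, and
each cluster's reassignment fraction is the share of members re-predicted
into it (self-prediction on the fitting data; no held-out split).
Singleton clusters are excluded with a warning.

The recommendation rule — largest cluster count whose median fraction is
≥ 0.8 and within 0.05 of the median at the smallest grid — is an explicit
codification of "reassignment begins to drop past the right cluster
number" and is flagged as a heuristic. A structural caveat, verified
empirically during development: SOM assignments are nearest-codebook
(Voronoi) partitions, and linear discriminants can reproduce any Voronoi
cut in PC space almost exactly, so training-set self-reassignment medians
stay ≥ 0.95 for modest cluster counts (k ≤ 8 in 5 PCs) *regardless of the
true number of profile families* — even a single Gaussian blob split in
two self-reassigns at ~0.99. Redundant clusterings depress the mean (via
small straddling clusters absorbed by proportional priors) well before the
median, and a clear median drop only emerges at larger k. The raw per-run
fractions are therefore always emitted so users can apply distributional
rules rather than relying on the median heuristic; the
`recommended_k` value should be read with this caveat in mind.

## GO enrichment

Per node, each GO term present in the universe is tested by the upper-tail
hypergeometric probability P(X ≥ k | N, n, K); BH adjustment is applied
within node across terms (a flag pools across nodes). The length-aware
variant estimates a probability-weighting function by binning the universe
into 20 length quantiles, regressing node-membership rate on bin median
length under a monotone (isotonic) constraint, and assigning each
transcript its bin's fitted rate (floored at a small positive value);
constant-length universes short-circuit to uniform weights. A term's odds
is the mean weight inside the category over the mean outside, and its
p-value is the upper tail of the Wallenius noncentral hypergeometric
distribution with that odds, computed by an exact O(K·n) forward recursion
over the sequential biased-urn process that defines the distribution (at
odds = 1 this reduces to the hypergeometric to ~1e-16). The isotonic
binned PWF is a deterministic stand-in for spline-based weighting
functions; GO-graph ancestor propagation is out of scope — the annotation
is taken as given.

## Cross-species intersection

Best-hit tables are reduced to one hit per query by a total order (highest
bit score, lowest e-value, highest percent identity, lexicographically
smallest subject) after dropping hits above the e-value ceiling (default
1e-5), so the reduction is independent of input row order. Each source
transcript with a surviving hit inherits its subject's foreign atlas node;
exclusions (no node for the subject, no source node for the query) are
counted by reason. The null distribution is the share of *all* foreign
transcripts per foreign node — the literal "the foreign atlas's own
distribution" reading; restricting the null to hit foreign transcripts is
available as an option. Per source node, Pearson's χ² over all foreign-node
categories with df = categories − 1; a zero expected count with positive
observed is an error (merge categories), expected counts below 5 trigger a
warning, and no continuity correction is applied by default.

## Synthetic data

The generator emulates the sampling design of a six-pseudo-organ atlas:
replicate counts (5, 5, 5, 5, 5, 4) — the reduced holdfast arm reflects a
lost replicate in the motivating design — with negative-binomial counts
(default dispersion 0.1, typical of good laboratory replicates) around
per-organ means proportional to each transcript's share of its organ's
transcriptome at an expected depth of 5×10⁵ per library. Half the
transcripts are unstructured (flat); the rest follow six hand-authored
apical–basal prototype profiles (apex-high; pinnule+rachis;
rachis+frond base; frond base+stolon; stolon+holdfast; holdfast-high) at a
planted fold of 4. Gene baselines are log-normal (σ = 1). Because organ
totals differ slightly by construction, raw count proportions carry a
composition bias of the kind TMM corrects; planted folds should be read
off TMM-normalized CPM.

The foreign atlas has 9 nodes with equal expected proportions; each source
transcript gains a best hit with probability 0.8, whose subject is drawn
from a foreign node chosen from the source node's row of an association
matrix (default: probability 0.6 on a partner node, remainder uniform;
unstructured transcripts follow the foreign null). Hit e-values are
log-uniform in [1e-180, 1e-5] so none are filtered. GO annotation plants
one term per node carried by members with probability 8 × 0.05 (capped)
versus 0.05 outside, plus 40 node-independent background terms; contig
lengths are log-normal (meanlog 5.94, sdlog 1.0, floor 200 bp — median
≈ 380 bp, mean ≈ 630 bp, resembling a de novo transcriptome assembly), and
the FASTA writer emits random-base sequences realizing those lengths.

What the generator does *not* emulate: a continuum of intermediate
profiles between families (real atlases show density modes embedded in a
continuous cloud), gene-specific (tagwise) dispersions, length-dependent
count bias, mapping ambiguity between paralogous contigs, and any sequence
realism. Passing tests on this generator therefore demonstrate the
pipeline's correctness and its recovery of well-posed planted structure,
not performance on the harder, messier geometry of real transcriptomes —
the cluster-number validation caveat above is where this gap is most
visible.

## Problem sizes and determinism

Defaults were chosen so the full pipeline runs in seconds on one CPU:
2 000 transcripts, 29 samples, 15 pairwise tests, ~1 100 clustered
transcripts; the validation procedure at 100 runs × 5 grids completes in
about a minute. Every stochastic component takes an explicit seed and all
derived seeds are deterministic functions of it; identical configurations
reproduce outputs byte for byte.
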
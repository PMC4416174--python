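# Methods

## Model and assumptions

`meriphmm` detects m6A methylation peaks in MeRIP-seq data by segmenting
each gene's concatenated exons with a two-state hidden Markov model. The
assumptions, in decreasing order of importance:

1. **Peaks are contiguous.** Methylation status changes slowly along the
   transcript relative to the bin width, so a first-order Markov chain on
   bins captures it. This is what distinguishes the caller from
   bin-independent tests: a weakly enriched bin flanked by strong bins is
   pulled into the peak, and an isolated noisy bin is suppressed.
2. **The IP fraction is sufficient.** Given the combined count
   t_n = x_n + y_n, the IP count is Binomial(t_n, p_k) with one success
   probability per state. This conditioning eliminates the per-state
   Poisson rates and the sequencing depths: they enter only through
   p_k = M_IP λ_IP,k / (M_ctrl λ_ctrl + M_IP λ_IP,k) and are never
   estimated separately. A corollary is that bins with t_n = 0 are
   uninformative about state (emission probability 1 for both states); they
   are kept in the chain because they still carry transition information
   (they can bridge two enriched stretches into one peak).
3. **One parameter set per experiment.** θ = {π, A, p₁, p₂} is shared
   across genes and fitted by multi-sequence EM, each gene an independent
   chain restarting from π. Per-gene fitting (`sharing: per-gene`) exists
   for exploration, but a typical gene contributes 5–30 bins — far too few
   to estimate a 2×2 transition matrix stably.

States are ordered by their IP fraction (p₁ < p₂, state 2 = methylated);
the M step relabels if an update inverts the order, so the ordering is an
identifiability convention, not a constraint on the data.

## Inference

The E step is scaled (normalized) forward–backward; the log-likelihood is
the sum of log scaling constants and includes the binomial coefficients, so
the EM monotonicity check is meaningful. Emissions are computed in log
space via log-gamma and shifted per bin so the larger of the two state
emissions is exactly 1 before scaling — the recursion then cannot
underflow regardless of counts. All genes are processed as one padded
batch: padding bins carry flat emissions, and because the transition matrix
is row-stochastic the backward messages through them stay exactly 1 and
their scaling constants are exactly 1, leaving the true sequences'
posteriors and likelihoods unchanged (padded transitions are masked out of
the M-step sums). The M step is the standard closed form, pooled over
genes; if a state has zero expected total count its emission parameter is
carried over from the previous iteration with a warning.

Initialization: π = 0.5, A = [[0.8, 0.2], [0.2, 0.8]], and p₁/p₂ from the
25th/75th percentiles of the per-bin IP fraction over informative bins —
data-driven and order-respecting. Convergence: relative log-likelihood
change below 1e-6, at most 100 iterations (both configurable). Parameters
are clamped to [1e-6, 1 − 1e-6] and emissions floored at 1e-300 before
logs. Viterbi decoding runs in log space; ties break toward the
unmethylated state (conservative calling).

## Peak scoring and significance

Per-bin PeakScore = ln γ(z_n=2)/γ(z_n=1) with γ clamped to
[1e-10, 1 − 1e-10] (so a saturated posterior scores ±23.03, finite by
construction). Candidate regions are maximal Viterbi runs of the
methylated state; a region's score is the unweighted mean over its bins.
Significance follows the log-odds scoring tradition of RIP-seq callers:
region scores are z-transformed against the mean and sample (n−1) standard
deviation of the PeakScores of *all* bins pooled transcriptome-wide,
tested one-sided (p = 1 − Φ(z)), BH-corrected, and thresholded at
FDR < 0.025 (strict inequality). An alternative reading — dividing σ by
√n_bins, the sampling distribution of the region mean — is available as
`use_region_sem`.

This test is *relative*: it asks whether a region scores high compared to
the transcriptome-wide bin population. It therefore has power only when
the background (unmethylated) state dominates the pool, as it does in real
transcriptomes. Under the validation-study chain the stationary methylated
fraction is 0.75, the pooled mean is pulled up toward the saturated
positive score, and no region can exceed it by more than about one σ — at
that configuration the caller's ranking (posterior scores, ROC) is the
meaningful output and the FDR filter keeps nothing. In
background-dominated simulations (e.g. π = 0.9, A = [[0.95, 0.05],
[0.3, 0.7]]) the filter behaves as intended; in our checks every region
passing FDR < 0.025 overlapped a true methylated run. Posterior
saturation also caps attainable z at roughly (23 − μ)/σ, so extremely
small p-values should not be over-interpreted.

## Coordinates, binning, read assignment

Internally everything is 0-based half-open; GTF is converted at parse time
(delegated to pyranges), BED12 is native. Bins 1..N−1 have width L
(default 100 nt ≈ fragment length); the last bin keeps the remainder, even
if short, to preserve 3'-end signal where m6A concentrates. Bins are
ordered by genomic coordinate irrespective of strand; strand is recorded
and emitted but never reorders bins. Each annotation record becomes an
independent gene model (exome projection sidesteps isoform assignment).

Read-to-bin assignment is by **transcript-coordinate midpoint**: the
alignment's first and last exonic reference positions are projected
through the exon model and the floor of their mean picks the bin.
Intron-only alignments are ignored; secondary/supplementary flags are
excluded; duplicates are not removed. The midpoint rule is symmetric and
robust at exon junctions; it is our convention, fixed once.

## Simulator

`simulate()` emulates the validation study: 5000 genes with lengths
uniform on 500–3000 nt (binned at L = 100; the bin width of the study is
not printed, so the fragment length is used), states from
A = [[0.7, 0.3], [0.1, 0.9]] with π = 0.2, one control rate
λ_ctrl ~ U(5, 20) per gene, and a fresh IP rate per bin —
U(λ_ctrl, 100) when methylated, U(0, λ_ctrl) when unmethylated — with
Poisson counts and unit depths (so the implied emission parameter is
λ_IP/(λ_ctrl + λ_IP)). Redrawing λ_IP per bin makes the emissions a
*mixture* rather than a fixed binomial: deliberate model misspecification,
matching the heterogeneity of the study's scatter. Consequently the EM
estimates on such data converge to pseudo-true values, not the generator's
A and π; parameter-recovery checks use `simulate_from_hmm()`, which draws
from the assumed model exactly (t ~ Poisson(25) per bin, x binomial).

What the simulator does **not** emulate: read-level effects (fragment
overlap across bin boundaries, mappability, GC), expression-level
variation beyond λ_ctrl, biological replicates, and isoform structure.
Passing validation on it shows the inference machinery is correct and that
dependency modelling beats bin-independence under count noise — not that
real-data peak lists are accurate.

The worked matched-sensitivity example uses 100-bin single genes whose
truth is one contiguous run of 10 methylated bins at a uniformly random
position (the layout of such a constructed example is not otherwise
pinned down); the HMM is refitted per replicate on that gene alone, both
callers are thresholded where 8 of the 10 true bins are detected, and
false positives are counted among the 90 unmethylated bins. Under the
study's rate intervals the 8th-best methylated bin is almost always far
more enriched than any unmethylated bin can appear, so the median
false-positive count is 0 for both callers — at these settings the
matched-sensitivity experiment separates the callers only in the tail
(mean, not median, false positives) — while Viterbi decoding recovers a
median 10/10 true bins.

## Baseline and ROC

The independent-bin baseline scores each bin with a one-sided exact
binomial tail p = P(X ≥ x_n | t_n, p₀) against the pooled proportion
p₀ = Σx/Σt, the bin-independent strategy of earlier exome peak callers; it
is a characterization of that strategy, not a re-implementation of any
specific tool. ROC curves are bin-level (truth labels are per bin), AUC by
trapezoid rule, ties rank-averaged (Mann–Whitney equivalent).

## Problem sizes and determinism

The validation suite uses the study-scale simulation (5000 genes, ~90k
bins) for ROC comparisons, ~108k bins for parameter recovery, 200
replicates for the worked example, and exhaustive 2^N enumeration oracles
at N ≤ 10. `scripts/acceptance.py` averages AUCs over three seeds. Every
random draw in the package flows through a `numpy` Generator seeded from
the caller's seed; identical seeds give bitwise-identical datasets,
tables and reports.

## Known limitations

- Two states only; partial-methylation levels are folded into p₂.
- The Gaussian z-test on region scores is heuristic (region scores are
  means of clamped, correlated log-odds, not Gaussian draws); the
  relative-test power caveat above applies.
- No replicate handling or differential methylation between conditions.
- Count input assumes bins were produced with the same bin size the
  caller is configured with; this is not cross-checked for table input.
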
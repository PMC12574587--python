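# Methods

## Model and estimator

mixtrack models one sink count vector x (depth C over N taxa) as
multinomial with probabilities β = Σ_{i=0}^{K} α_i γ_i: a convex
combination of K observed source profiles γ_i (plug-in estimates y_i/C_i)
and one unobserved source i = 0. The unobserved source is treated as an
exchangeable nuisance — α_0 γ_0j constant across taxa — so its whole
contribution collapses into a regression intercept α̃_0. On the count
scale,

    x_j = α̃_0 + Σ_{i=1}^{K} α̃_i γ_ij + ε_j,   Cov(ε) = C(diag(β) − ββᵀ),

and the mixing proportions are estimated by generalized least squares
with the plug-in covariance Σ built from β̂ = x/C. No pseudo-counts are
added anywhere; taxa with zero sink counts keep their zero rows in Σ.

### The singular covariance

Σ has rank at most N−1: its rows sum to zero, so the all-ones vector is
in its null space (as is e_j for every zero-count taxon). Two standard
workarounds are implemented:

- **pinv** (default): the Moore–Penrose pseudoinverse, computed through
  the symmetric eigendecomposition with eigenvalues below
  `pinv_rtol = 1e-10` times the largest treated as zero. Because Σ⁺
  annihilates the ones direction, the intercept column is invisible to
  the quadratic form and the literal normal matrix γᵀΣ⁺γ is singular.
  The sum of the regression equations over taxa, however, is a
  zero-variance direction that any generalized least-squares solution
  must satisfy exactly: 1ᵀx = C = N·α̃_0 + Σ_i α̃_i (profile columns sum
  to one). The solver therefore eliminates the intercept, solves the
  K-dimensional system on the profile columns alone, and recovers
  α̃_0 = (C − Σ_i α̃_i)/N. This is deterministic and requires no
  arbitrary taxon choice, hence the default.
- **drop**: delete one taxon row/column of Σ (default: the taxon with
  the largest sink count, the best-conditioned choice) together with the
  matching row of the design and of x, and invert the remainder. Requires
  every remaining taxon to have a positive sink count and N−1 ≥ K+1; a
  condition number above 1e12 raises an error that advises pinv.

The two routes agree to ~1e−6 on noiseless instances and to O(1/√C) on
sampled counts (drop mode does not see the constraint that the deleted
equation encodes; the discrepancy vanishes with depth). Both are exposed
via `inverse_mode`.

Exact duplicates among source profiles (max-norm distance < 1e−12) are
the one case the model cannot identify; they raise a collinearity error
naming the pair. A normal-matrix condition number above 1e12 raises a
singularity error. When N ≤ K the fit is weakly determined; the package
warns and proceeds with pinv (no dimension reduction is attempted).

### Post-processing

The raw GLS solution is unconstrained. Observed proportions are
α̃_i/C clipped below at zero; the unknown-source proportion is N·α̃_0/C
(which equals 1 − Σ_i α̂_i when the fit is exact); the vector is then
renormalized to the simplex and a `clipped` flag records whether any
clipping occurred. The raw coefficients are preserved in the result for
transparency, and `clip=False` skips the clipping (renormalization only).
Fitted sink probabilities are μ_j = α̃_0 + Σ_i α̃_i γ_ij floored at
ε = 1e−12 and normalized; the floor keeps candidates comparable under
sampling zeros in the directionality score.

## Directionality

With K+1 unlabeled samples, Model k makes sample k the sink and the rest
sources; all candidates are star graphs of identical complexity, so the
unpenalized joint log-likelihood is the score:

    score(k) = log multinom(x | C, p̂) + Σ_i log multinom(y_i | C_i, y_i/C_i),

with p̂ the GLS-fitted sink probabilities. The marginal terms use the
plug-in MLE because no prior over source compositions is assumed; the
full log-gamma multinomial coefficients are included since the sample
playing the conditional role differs across candidates, so constants do
not cancel. Ties are broken by the lowest sample index and flagged; a
candidate whose GLS fit fails scores −∞ and a warning is logged instead
of aborting the run.

## Synthetic data generator

The generator emulates a fully synthetic mixing study: n_major major
sources each contribute at least 10% of the sink and jointly exactly 90%;
the residual 10% is split between the K − n_major minor sources and the
unobserved source. Concretely:

- major proportions: uniform Dirichlet(1) on the n_major-simplex scaled
  to 0.9, rejection-sampled against the 0.1 floor (exact, matches the
  constraint as stated; acceptance is ~4% at n_major = 5, so redraw
  counts stay in the tens);
- residual mass: symmetric Dirichlet(`minor_concentration` = 1.0) over
  minors + unobserved (for n_major = K the unobserved source gets 0.1
  exactly);
- profiles: independent symmetric Dirichlet(`profile_concentration` =
  0.5) rows — sparse, realistic community profiles;
- counts: sink ~ multinom(C, β), sources ~ multinom(C_i, γ_i); the
  unobserved source is never emitted.

Defaults N = 500 taxa and all depths 1e5 are package choices of a
realistic amplicon-scale problem; all are exposed in `SimulationConfig`.
Two fixed conventions: the majors are the *first* n_major observed
sources, and in directionality benchmarks the true sink is placed last
among the K+1 samples — conservative with respect to the lowest-index
tie-break. Replicate r of a benchmark uses seed base_seed + r, one
`numpy` Generator per replicate.

What the generator does **not** emulate: overdispersion
(Dirichlet-multinomial noise), taxon co-occurrence structure, real
phylogenetic abundance patterns, uneven library sizes, or sources that
are themselves mixtures. Passing the synthetic benchmarks therefore shows
correctness of the estimator under its own model, not performance on real
data; `load_profiles_from_table` lets users substitute real profiles for
semi-synthetic checks.

## Evaluation metrics

MAE over observed sources, over major sources, and for the unknown
share; Jensen–Shannon divergence with base-2 logarithms (range [0, 1]);
Pearson correlation. JSD/PCC are computed on the (unknown + observed)
proportion vector by default (`observed_only` restricts them). PCC is
undefined for constant vectors and such replicates are excluded from
cell averages with a count, as are replicates whose estimation fails
(zero at the default settings). PCC is averaged per replicate, not pooled.

## Problem sizes and numerical choices

Benchmarks and tests run at desk scale: 100 replicates per grid cell at
N = 500 (N = 300 for K = 100), which completes in a few minutes on one
CPU and is already tight — directionality accuracy is 100% across the
tested grid and the mean observed-source MAE at (K=5, n_major=2) is well
under 0.02. Tolerances: profile row sums 1e−9; pseudoinverse cutoff
1e−10 (relative); condition limit 1e12; collinearity 1e−12; probability
floor 1e−12; simplex output verified to 1e−9.

## Known limitations

- The intercept treats the unobserved source as exchangeable across
  taxa; a structured unknown source biases α̂_0 toward the observed
  sources that resemble it.
- Drop mode needs strictly positive sink counts on the retained taxa;
  with sparse data use the default pinv.
- The GLS estimate is unconstrained before post-processing; clipping is
  a projection heuristic, not a constrained fit, and no uncertainty
  intervals are provided.
- Only the star topology (all sources → one sink) is scored; chains,
  multiple sinks and partial orders are out of scope.
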